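"""Synthetic CHR/HC cohort generator.

The generator emulates the measured structure of a clinical high-risk
emotion study: two groups (47 CHR, 58 HC by default), 18 mDES Likert
ratings with group-specific latent means, eleven SIPS symptom severities
driven by the same latent emotions, demographics matched to the published
group summaries, and a ~19% antipsychotic prevalence in the CHR group.

Model
-----
Each participant draws a standard-normal latent vector z over the 18
items with an exchangeable correlation ``rho`` within each valence block
and zero correlation across valence. The latent item value is
``v_i = mean_i + sd_i * z_i`` and the observed Likert rating is the
number of fixed thresholds (-1.5, -0.5, 0.5, 1.5) below ``v_i`` —
threshold discretization keeps rank correlations analytically trackable.

Each SIPS item is ``S = clip(round(b + w . z + eps), 0, 6)`` with
Gaussian noise eps. The intercept ``b`` is calibrated in closed form so
that E[S] equals the group's target mean (per-symptom targets default to
an even split of the published group totals), using
``E[S] = sum_{k=1..6} P(x > k - 1/2)`` for Gaussian x. Healthy-control
loadings are scaled toward zero (symptom variance in HCs is minimal).

Because (z_i, x) is bivariate normal and both the rating and the symptom
are threshold transforms of it, the item-criterion correlation has a
closed form in bivariate-normal orthant probabilities;
:func:`plant_item_effect` inverts it to hit a requested correlation.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .cohort import (
    ALL_SYMPTOMS,
    Cohort,
    NEGATIVE_SYMPTOMS,
    POSITIVE_SYMPTOMS,
    SIPS_MAX,
    cohort_from_arrays,
)
from .items import ALL_ITEMS, NEGATIVE_ITEMS, POSITIVE_ITEMS, canonical_item

logger = logging.getLogger("emodiv")

#: Fixed latent thresholds separating the five Likert responses.
LIKERT_CUTS = np.array([-1.5, -0.5, 0.5, 1.5])

_MAX_LOADING = 50.0


class SimulationError(ValueError):
    pass


@dataclass
class SimulationSpec:
    """Full parameterization of a synthetic cohort.

    All mappings are keyed by group ("CHR"/"HC"), canonical item name and
    symptom label (P1..P5, N1..N6). ``symptom_target_means`` holds the
    desired E[score] per symptom and group; the Gaussian intercepts are
    re-derived from them at generation time, so edits to loadings or noise
    never drift the planted symptom means.
    """

    n_chr: int
    n_hc: int
    emotion_means: dict[str, dict[str, float]]
    emotion_sds: dict[str, dict[str, float]]
    emotion_corr: dict[str, float]  # valence -> exchangeable rho in [0, 1)
    symptom_loadings: dict[str, dict[str, float]]
    symptom_target_means: dict[str, dict[str, float]]
    symptom_noise_sd: float
    hc_loading_scale: float
    antipsychotic_prevalence_chr: float
    age: dict[str, dict[str, float]]  # group -> {"mean": .., "sd": ..}
    parent_education: dict[str, dict[str, float]]
    sex_male_proportion: dict[str, float]
    seed: int = 0

    def validate(self) -> None:
        if self.n_chr < 2 or self.n_hc < 2:
            raise SimulationError("group sizes must be >= 2")
        for valence, rho in self.emotion_corr.items():
            if not 0.0 <= rho < 1.0:
                raise SimulationError(
                    f"emotion_corr[{valence!r}] must lie in [0, 1), got {rho}"
                )
        for group in ("CHR", "HC"):
            for item in ALL_ITEMS:
                sd = self.emotion_sds[group][item]
                if not sd > 0:
                    raise SimulationError(f"emotion sd for {item} must be > 0")
                if not np.isfinite(self.emotion_means[group][item]):
                    raise SimulationError(f"emotion mean for {item} not finite")
        if not self.symptom_noise_sd > 0:
            raise SimulationError("symptom_noise_sd must be > 0")
        if not 0.0 <= self.antipsychotic_prevalence_chr <= 1.0:
            raise SimulationError("antipsychotic prevalence must lie in [0, 1]")
        for sym, loads in self.symptom_loadings.items():
            for item, w in loads.items():
                if not np.isfinite(w):
                    raise SimulationError(f"loading {sym}<-{item} not finite")
        for group in ("CHR", "HC"):
            for sym in ALL_SYMPTOMS:
                m = self.symptom_target_means[group][sym]
                if not 0.0 < m < SIPS_MAX:
                    raise SimulationError(
                        f"symptom target mean {group}/{sym} must be in (0, 6)"
                    )

    # -- JSON round trip (CLI --spec config) --------------------------------
    def to_dict(self) -> dict:
        return {
            "n_chr": self.n_chr,
            "n_hc": self.n_hc,
            "emotion_means": self.emotion_means,
            "emotion_sds": self.emotion_sds,
            "emotion_corr": self.emotion_corr,
            "symptom_loadings": self.symptom_loadings,
            "symptom_target_means": self.symptom_target_means,
            "symptom_noise_sd": self.symptom_noise_sd,
            "hc_loading_scale": self.hc_loading_scale,
            "antipsychotic_prevalence_chr": self.antipsychotic_prevalence_chr,
            "age": self.age,
            "parent_education": self.parent_education,
            "sex_male_proportion": self.sex_male_proportion,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationSpec":
        return cls(**data)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


# -- defaults ---------------------------------------------------------------

# Published group summaries used as calibration anchors: group sizes 47/58,
# age 19.04 (1.63) vs 19.24 (2.58), parent education 15.66 (2.20) vs
# 15.71 (2.68), sex 26/21 vs 22/36 male/female, 9/47 CHR on antipsychotics,
# SIPS totals 11.45/9.28 (CHR) vs 0.41/0.24 (HC).
_TABLE_ANCHORS = {
    "n_chr": 47,
    "n_hc": 58,
    "age": {"CHR": {"mean": 19.04, "sd": 1.63}, "HC": {"mean": 19.24, "sd": 2.58}},
    "parent_education": {
        "CHR": {"mean": 15.66, "sd": 2.20},
        "HC": {"mean": 15.71, "sd": 2.68},
    },
    "sex_male_proportion": {"CHR": 26 / 47, "HC": 22 / 58},
    "antipsychotic_prevalence_chr": 9 / 47,
    "total_positive": {"CHR": 11.45, "HC": 0.41},
    "total_negative": {"CHR": 9.28, "HC": 0.24},
}

# Illustrative default loadings: negative-emotion latents (sadness, anger in
# particular) push symptom severity up, joy pulls it down — the qualitative
# pattern reported for discrete-emotion/symptom correlations in this
# population. Free parameters: no item-level descriptives are published.
_DEFAULT_LOADINGS: dict[str, dict[str, float]] = {
    "P1": {"sadness": 0.35, "anger": 0.30, "joy": -0.25},
    "P2": {"guilt": 0.25, "fear": 0.22, "embarrassment": 0.18},
    "P3": {"joy": -0.25, "anger": 0.22, "sadness": 0.20},
    "P4": {"joy": -0.28, "anger": 0.28, "sadness": 0.25},
    "P5": {"anger": 0.28, "fear": 0.24, "sadness": 0.22},
    "N1": {"sadness": 0.35, "anger": 0.28, "contempt": 0.22},
    "N2": {"sadness": 0.38, "anger": 0.30, "joy": -0.30},
    "N3": {"sadness": 0.32, "anger": 0.28, "joy": -0.26},
    "N4": {"disgust": 0.35, "anger": 0.32, "joy": -0.30},
    "N5": {"sadness": 0.28, "anger": 0.25, "shame": 0.22},
    "N6": {"sadness": 0.34, "joy": -0.28, "anger": 0.26},
}


def default_spec(seed: int = 0) -> SimulationSpec:
    """Spec calibrated to the published cohort summaries.

    CHR positive-item latent means are concentrated on a single dominant
    item (low positive emodiversity) while CHR negative items are uniformly
    elevated (higher negative emodiversity) relative to healthy controls.
    Per-symptom target means split the published group totals evenly over
    the 5 positive / 6 negative SIPS items.
    """
    means: dict[str, dict[str, float]] = {"CHR": {}, "HC": {}}
    sds: dict[str, dict[str, float]] = {"CHR": {}, "HC": {}}
    for item in POSITIVE_ITEMS:
        means["HC"][item] = 0.8
        means["CHR"][item] = 1.0 if item == "interest" else -0.4
    for item in NEGATIVE_ITEMS:
        means["HC"][item] = -1.2
        means["CHR"][item] = -0.2
    for group in ("CHR", "HC"):
        for item in ALL_ITEMS:
            sds[group][item] = 1.0
    targets: dict[str, dict[str, float]] = {"CHR": {}, "HC": {}}
    for group in ("CHR", "HC"):
        for sym in POSITIVE_SYMPTOMS:
            targets[group][sym] = _TABLE_ANCHORS["total_positive"][group] / len(
                POSITIVE_SYMPTOMS
            )
        for sym in NEGATIVE_SYMPTOMS:
            targets[group][sym] = _TABLE_ANCHORS["total_negative"][group] / len(
                NEGATIVE_SYMPTOMS
            )
    return SimulationSpec(
        n_chr=_TABLE_ANCHORS["n_chr"],
        n_hc=_TABLE_ANCHORS["n_hc"],
        emotion_means=means,
        emotion_sds=sds,
        emotion_corr={"positive": 0.3, "negative": 0.3},
        symptom_loadings=copy.deepcopy(_DEFAULT_LOADINGS),
        symptom_target_means=targets,
        symptom_noise_sd=1.5,
        hc_loading_scale=0.15,
        antipsychotic_prevalence_chr=_TABLE_ANCHORS["antipsychotic_prevalence_chr"],
        age=copy.deepcopy(_TABLE_ANCHORS["age"]),
        parent_education=copy.deepcopy(_TABLE_ANCHORS["parent_education"]),
        sex_male_proportion=dict(_TABLE_ANCHORS["sex_male_proportion"]),
        seed=seed,
    )


def matched_spec(n_chr: int = 47, n_hc: int = 58, seed: int = 0) -> SimulationSpec:
    """A null spec: both groups share the HC emotion distribution.

    Used for coverage and false-positive studies where the only systematic
    group difference is the label itself (and the antipsychotic flag, which
    is independent of the ratings).
    """
    spec = default_spec(seed=seed)
    spec.n_chr = n_chr
    spec.n_hc = n_hc
    spec.emotion_means["CHR"] = dict(spec.emotion_means["HC"])
    spec.emotion_sds["CHR"] = dict(spec.emotion_sds["HC"])
    return spec


# -- latent machinery -------------------------------------------------------


def _latent_cov(spec: SimulationSpec) -> np.ndarray:
    """18x18 covariance of the standardized latents z."""
    n = len(ALL_ITEMS)
    cov = np.eye(n)
    for valence, items in (("positive", POSITIVE_ITEMS), ("negative", NEGATIVE_ITEMS)):
        rho = spec.emotion_corr[valence]
        idx = [ALL_ITEMS.index(i) for i in items]
        for a in idx:
            for b in idx:
                if a != b:
                    cov[a, b] = rho
    return cov


def _loading_vector(spec: SimulationSpec, symptom: str, group: str) -> np.ndarray:
    scale = 1.0 if group == "CHR" else spec.hc_loading_scale
    w = np.zeros(len(ALL_ITEMS))
    for item, value in spec.symptom_loadings.get(symptom, {}).items():
        w[ALL_ITEMS.index(canonical_item(item))] = value * scale
    return w


def expected_clipped_score(base: float, s: float) -> float:
    """E[clip(round(x), 0, 6)] for x ~ Normal(base, s)."""
    ks = np.arange(1, SIPS_MAX + 1)
    return float(stats.norm.sf((ks - 0.5 - base) / s).sum())


def _calibrate_base(target_mean: float, s: float) -> float:
    """Solve expected_clipped_score(b, s) == target_mean for b."""
    return float(
        optimize.brentq(
            lambda b: expected_clipped_score(b, s) - target_mean, -40.0, 40.0
        )
    )


def _symptom_gaussian(spec: SimulationSpec, symptom: str, group: str):
    """(base, s, w) of the pre-round/clip Gaussian symptom score."""
    w = _loading_vector(spec, symptom, group)
    cov = _latent_cov(spec)
    s = float(np.sqrt(w @ cov @ w + spec.symptom_noise_sd**2))
    base = _calibrate_base(spec.symptom_target_means[group][symptom], s)
    return base, s, w


def expected_rating(mean: float, sd: float) -> float:
    """E[Likert rating] under the threshold model: sum_k P(v > cut_k)."""
    return float(stats.norm.sf((LIKERT_CUTS - mean) / sd).sum())


def _threshold_moments(cuts_z: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Marginal moments of R = sum_k 1[z > c_k] for standard-normal z.

    Returns (survival probs p_k, E[R], Var[R]).
    """
    p = stats.norm.sf(cuts_z)
    mean = float(p.sum())
    var = 0.0
    for j, cj in enumerate(cuts_z):
        for k, ck in enumerate(cuts_z):
            both = stats.norm.sf(max(cj, ck))
            var += both - p[j] * p[k]
    return p, mean, float(var)


def _orthant_upper(c1: float, c2: float, rho: float) -> float:
    """P(Z1 > c1, Z2 > c2) for standard bivariate normal with corr rho."""
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    return float(mvn.cdf([-c1, -c2]))


def predicted_item_symptom_r(
    spec: SimulationSpec, item: str, symptom: str, group: str = "CHR"
) -> float:
    """Closed-form Pearson correlation between an item's Likert rating and
    a symptom score implied by the latent-Gaussian model.

    Both observables are threshold transforms of the jointly Gaussian pair
    (item latent, symptom Gaussian), so the covariance reduces to bivariate
    normal orthant probabilities; no simulation involved.
    """
    item = canonical_item(item)
    i = ALL_ITEMS.index(item)
    base, s, w = _symptom_gaussian(spec, symptom, group)
    cov = _latent_cov(spec)
    rho_lat = float((cov @ w)[i] / s)
    rho_lat = float(np.clip(rho_lat, -0.999999, 0.999999))
    # rating thresholds on the standardized item latent
    m = spec.emotion_means[group][item]
    sd = spec.emotion_sds[group][item]
    c_r = (LIKERT_CUTS - m) / sd
    # symptom thresholds on the standardized symptom Gaussian
    a_s = (np.arange(1, SIPS_MAX + 1) - 0.5 - base) / s
    p_r, _, var_r = _threshold_moments(c_r)
    p_s, _, var_s = _threshold_moments(a_s)
    cov_rs = 0.0
    for j, c in enumerate(c_r):
        for k, a in enumerate(a_s):
            cov_rs += _orthant_upper(c, a, rho_lat) - p_r[j] * p_s[k]
    return float(cov_rs / np.sqrt(var_r * var_s))


def plant_item_effect(
    spec: SimulationSpec,
    item: str,
    symptom: str,
    target_r: float,
    group: str = "CHR",
) -> SimulationSpec:
    """Return a spec whose (item, symptom) loading yields the requested
    item-criterion Pearson correlation in the given group.

    Solves the closed-form correlation of :func:`predicted_item_symptom_r`
    for the loading by root finding; the symptom intercept recalibration is
    inside the closed form, so planted symptom means are preserved. Raises
    with the attainable bound when the target exceeds what the noise model
    permits.
    """
    if not abs(target_r) < 0.9:
        raise SimulationError("|target_r| must be < 0.9")
    item = canonical_item(item)
    if symptom not in ALL_SYMPTOMS:
        raise SimulationError(f"unknown symptom {symptom!r}")
    new = copy.deepcopy(spec)
    new.symptom_loadings.setdefault(symptom, {})
    if target_r == 0.0:
        new.symptom_loadings[symptom][item] = 0.0
        return new

    def f(w: float) -> float:
        trial = copy.deepcopy(new)
        trial.symptom_loadings[symptom][item] = w
        return predicted_item_symptom_r(trial, item, symptom, group) - target_r

    lo, hi = -_MAX_LOADING, _MAX_LOADING
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        bound = max(abs(flo + target_r), abs(fhi + target_r))
        raise SimulationError(
            f"target r={target_r} unreachable under noise sd "
            f"{spec.symptom_noise_sd}; attainable |r| <= {bound:.3f}"
        )
    w_star = float(optimize.brentq(f, lo, hi, xtol=1e-6))
    new.symptom_loadings[symptom][item] = w_star
    return new


# -- generation -------------------------------------------------------------


def _simulate_group(
    spec: SimulationSpec, group: str, n: int, rng: np.random.Generator
):
    n_pos, n_neg = len(POSITIVE_ITEMS), len(NEGATIVE_ITEMS)
    rho_p = spec.emotion_corr["positive"]
    rho_n = spec.emotion_corr["negative"]
    common_p = rng.standard_normal((n, 1))
    common_n = rng.standard_normal((n, 1))
    unique = rng.standard_normal((n, len(ALL_ITEMS)))
    z = np.empty((n, len(ALL_ITEMS)))
    z[:, :n_pos] = np.sqrt(rho_p) * common_p + np.sqrt(1 - rho_p) * unique[:, :n_pos]
    z[:, n_pos:] = np.sqrt(rho_n) * common_n + np.sqrt(1 - rho_n) * unique[:, n_pos:]

    means = np.array([spec.emotion_means[group][i] for i in ALL_ITEMS])
    sds = np.array([spec.emotion_sds[group][i] for i in ALL_ITEMS])
    latent = means + sds * z
    ratings = (latent[:, :, None] > LIKERT_CUTS[None, None, :]).sum(axis=2)

    sips = np.empty((n, len(ALL_SYMPTOMS)), dtype=int)
    for j, sym in enumerate(ALL_SYMPTOMS):
        base, s, w = _symptom_gaussian(spec, sym, group)
        x = base + z @ w + rng.normal(0.0, spec.symptom_noise_sd, size=n)
        sips[:, j] = np.clip(np.rint(x), 0, SIPS_MAX).astype(int)

    age = rng.normal(spec.age[group]["mean"], spec.age[group]["sd"], size=n)
    pe = rng.normal(
        spec.parent_education[group]["mean"],
        spec.parent_education[group]["sd"],
        size=n,
    )
    male = rng.random(n) < spec.sex_male_proportion[group]
    if group == "CHR":
        antipsy = (rng.random(n) < spec.antipsychotic_prevalence_chr).astype(int)
    else:
        antipsy = np.zeros(n, dtype=int)
    return ratings, sips, age, pe, male, antipsy, z


def generate_cohort(spec: SimulationSpec) -> Cohort:
    """Draw one cohort; identical output for identical specs (incl. seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    blocks = []
    for group, n in (("CHR", spec.n_chr), ("HC", spec.n_hc)):
        ratings, sips, age, pe, male, antipsy, _ = _simulate_group(
            spec, group, n, rng
        )
        ids = [f"{group}-{k + 1:04d}" for k in range(n)]
        sex = ["male" if m else "female" for m in male]
        blocks.append(
            cohort_from_arrays(
                ids, [group] * n, age, sex, pe, antipsy, ratings, sips
            )
        )
    return Cohort(blocks[0].participants + blocks[1].participants)
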