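"""Emodiversity scoring: Shannon-entropy indices of emotional variety.

Emodiversity quantifies the variety and relative abundance of the emotions
a person reports. Given the 18 mDES ratings r_i in {0..4}, the index is
computed in five steps:

1. rescale each rating to x_i = r_i - 2 in [-2, 2] and map it through the
   standard logistic sigma(x) = 1/(1 + e^(-x)) to a strictly positive
   intensity;
2. divide each intensity by the sum of intensities across all 18 emotions,
   giving proportions p_i that sum to one;
3. form p_i * ln(p_i) for each emotion;
4. repeat across items;
5. sum over all items (total), over the 10 positive items (positive), or
   over the 8 negative items (negative).

The literal sum in step 5 is negative; this package returns its negation,
D = -sum p_i ln p_i, so that larger values mean a more diverse emotional
life. Because steps 1-2 use the 18-item denominator for every subset, the
decomposition ``total = positive + negative`` holds exactly.

The logistic keeps every intensity inside (sigma(-2), sigma(2)) ~
(0.1192, 0.8808), so proportions never vanish and total diversity is
bounded: the maximum ln 18 ~ 2.8904 is attained exactly when all 18
ratings are equal, and the lattice minimum ~2.4169 at the extreme pattern
of four items rated 4 against fourteen rated 0 (entropy is Schur-concave,
so minima sit at vertices of the intensity box; scanning the k-of-18
vertices gives k = 4).

An alternative convention found in some earlier emodiversity work
renormalizes within each valence subset; it is available via
``within_valence_denominator=True`` but breaks the additive decomposition
and is off by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortValidationError, MdesRatings
from .items import ALL_ITEMS, NEGATIVE_ITEMS, POSITIVE_ITEMS

logger = logging.getLogger("emodiv")

_POS_IDX = np.array([ALL_ITEMS.index(i) for i in POSITIVE_ITEMS])
_NEG_IDX = np.array([ALL_ITEMS.index(i) for i in NEGATIVE_ITEMS])

#: Entropy of the uniform 18-item distribution — the attainable maximum.
MAX_TOTAL_DIVERSITY = math.log(len(ALL_ITEMS))


@dataclass(frozen=True)
class DiversityScores:
    """Per-participant emodiversity indices (nats) and valence means.

    ``mean_positive_emotion`` / ``mean_negative_emotion`` are arithmetic
    means of the raw 0-4 ratings over the corresponding valence block; they
    serve as the mean-level covariates in the adjusted models.
    """

    total: float
    positive: float
    negative: float
    mean_positive_emotion: float
    mean_negative_emotion: float


def rescale_rating(r: int | np.ndarray) -> float | np.ndarray:
    """Map a 0-4 Likert rating linearly onto [-2, 2] (step 1, first half)."""
    arr = np.asarray(r)
    if not np.all(np.isin(arr, [0, 1, 2, 3, 4])):
        raise CohortValidationError(f"rating(s) outside 0..4: {r!r}")
    out = arr.astype(float) - 2.0
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def logistic_intensity(x: float | np.ndarray) -> float | np.ndarray:
    """Standard logistic sigma(x) = 1/(1+e^-x); strictly positive."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("logistic_intensity requires finite input")
    out = 1.0 / (1.0 + np.exp(-arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def _ratings_vector(mdes: MdesRatings | np.ndarray) -> np.ndarray:
    if isinstance(mdes, MdesRatings):
        mdes.validate()
        return mdes.as_array()
    arr = np.asarray(mdes, dtype=float)
    if arr.shape[-1] != len(ALL_ITEMS):
        raise ValueError(f"expected {len(ALL_ITEMS)} ratings, got {arr.shape}")
    if not np.all(np.isin(arr, [0, 1, 2, 3, 4])):
        raise CohortValidationError("ratings outside 0..4")
    return arr


def emotion_proportions(mdes: MdesRatings | np.ndarray) -> pd.Series:
    """Intensity of each emotion divided by the 18-item intensity sum.

    Always strictly positive and sums to 1 (the logistic never returns 0).
    """
    ratings = _ratings_vector(mdes)
    intensities = logistic_intensity(ratings - 2.0)
    props = intensities / intensities.sum(axis=-1, keepdims=True)
    if props.ndim == 1:
        return pd.Series(props, index=list(ALL_ITEMS))
    return pd.DataFrame(props, columns=list(ALL_ITEMS))


def emotional_diversity(
    mdes: MdesRatings | np.ndarray,
    subset: str = "all",
    within_valence_denominator: bool = False,
) -> float:
    """Shannon-entropy emodiversity, in nats, over the requested item set.

    ``subset`` is ``"all"``, ``"positive"`` or ``"negative"``. By default
    proportions use the global 18-item denominator for every subset, so
    ``total == positive + negative`` exactly.
    """
    ratings = _ratings_vector(mdes)
    if subset == "all":
        idx = np.arange(len(ALL_ITEMS))
    elif subset == "positive":
        idx = _POS_IDX
    elif subset == "negative":
        idx = _NEG_IDX
    else:
        raise ValueError(f"subset must be all|positive|negative, got {subset!r}")
    intensities = logistic_intensity(ratings - 2.0)
    if within_valence_denominator and subset != "all":
        sub = intensities[..., idx]
        p = sub / sub.sum(axis=-1, keepdims=True)
    else:
        p = (intensities / intensities.sum(axis=-1, keepdims=True))[..., idx]
    return float(-(p * np.log(p)).sum())


def score_ratings(
    ratings: np.ndarray, within_valence_denominator: bool = False
) -> pd.DataFrame:
    """Vectorized scoring of an (n, 18) ratings matrix.

    Returns a DataFrame with columns ``diversity_total``,
    ``diversity_positive``, ``diversity_negative``,
    ``mean_positive_emotion``, ``mean_negative_emotion``.
    """
    arr = np.atleast_2d(np.asarray(ratings, dtype=float))
    if not np.all(np.isin(arr, [0, 1, 2, 3, 4])):
        raise CohortValidationError("ratings outside 0..4")
    intensities = logistic_intensity(arr - 2.0)
    p = intensities / intensities.sum(axis=1, keepdims=True)
    plogp = p * np.log(p)
    total = -plogp.sum(axis=1)
    if within_valence_denominator:
        pos_i = intensities[:, _POS_IDX]
        neg_i = intensities[:, _NEG_IDX]
        pp = pos_i / pos_i.sum(axis=1, keepdims=True)
        pn = neg_i / neg_i.sum(axis=1, keepdims=True)
        positive = -(pp * np.log(pp)).sum(axis=1)
        negative = -(pn * np.log(pn)).sum(axis=1)
    else:
        positive = -plogp[:, _POS_IDX].sum(axis=1)
        negative = -plogp[:, _NEG_IDX].sum(axis=1)
    return pd.DataFrame(
        {
            "diversity_total": total,
            "diversity_positive": positive,
            "diversity_negative": negative,
            "mean_positive_emotion": arr[:, _POS_IDX].mean(axis=1),
            "mean_negative_emotion": arr[:, _NEG_IDX].mean(axis=1),
        }
    )


def score_participant(
    mdes: MdesRatings, within_valence_denominator: bool = False
) -> DiversityScores:
    row = score_ratings(
        _ratings_vector(mdes)[None, :],
        within_valence_denominator=within_valence_denominator,
    ).iloc[0]
    return DiversityScores(
        total=float(row["diversity_total"]),
        positive=float(row["diversity_positive"]),
        negative=float(row["diversity_negative"]),
        mean_positive_emotion=float(row["mean_positive_emotion"]),
        mean_negative_emotion=float(row["mean_negative_emotion"]),
    )


SCORE_COLUMNS = (
    "id",
    "group",
    "antipsychotic",
    "diversity_total",
    "diversity_positive",
    "diversity_negative",
    "mean_positive_emotion",
    "mean_negative_emotion",
    "sips_total_positive",
    "sips_total_negative",
)


def score_cohort(
    cohort: Cohort | pd.DataFrame, within_valence_denominator: bool = False
) -> pd.DataFrame:
    """Score every participant; one row per participant.

    Carries group, antipsychotic flag and SIPS totals alongside the
    diversity scores so the output is a self-contained input for the
    group-difference and symptom-association models. Participants failing
    validation are excluded with a logged warning.
    """
    frame = cohort.to_frame() if isinstance(cohort, Cohort) else cohort.copy()
    needed = list(ALL_ITEMS)
    n0 = len(frame)
    frame = frame.dropna(subset=[c for c in needed if c in frame.columns])
    ok = np.ones(len(frame), dtype=bool)
    ratings = frame[list(ALL_ITEMS)].to_numpy(dtype=float)
    ok &= np.isin(ratings, [0, 1, 2, 3, 4]).all(axis=1)
    if (~ok).any():
        logger.warning(
            "score_cohort: excluding %d participant(s) with invalid ratings",
            int((~ok).sum()),
        )
    if n0 - len(frame):
        logger.warning(
            "score_cohort: excluding %d participant(s) with missing ratings",
            n0 - len(frame),
        )
    frame = frame.loc[ok]
    ratings = ratings[ok]
    scores = score_ratings(
        ratings, within_valence_denominator=within_valence_denominator
    )
    scores.index = frame.index
    from .cohort import NEGATIVE_SYMPTOMS, POSITIVE_SYMPTOMS  # local to avoid cycle

    out = pd.DataFrame(
        {
            "id": frame["id"].astype(str),
            "group": frame["group"],
            "antipsychotic": frame["antipsychotic"].astype(int),
        }
    )
    out = pd.concat([out, scores], axis=1)
    out["sips_total_positive"] = (
        frame[list(POSITIVE_SYMPTOMS)].sum(axis=1).astype(int)
    )
    out["sips_total_negative"] = (
        frame[list(NEGATIVE_SYMPTOMS)].sum(axis=1).astype(int)
    )
    return out.reset_index(drop=True)
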