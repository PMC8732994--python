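"""End-to-end pipeline: simulate -> score -> analyze -> profile -> report.

Every stage writes CSV with deterministic column order and no timestamps,
so a re-run with the same configuration reproduces byte-identical score
and profile tables. The run manifest (JSON) records the seed, a hash of
the configuration, package/library versions, output paths and the SHA-256
of each table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    NEGATIVE_SYMPTOMS,
    POSITIVE_SYMPTOMS,
    read_cohort_csv,
    write_cohort_csv,
)
from .glm import (
    GroupDifferenceModel,
    SymptomAssociationModel,
    welch_t_from_summary,
    yates_chi_square,
)
from .profiler import profile_all_symptoms, profiles_to_frame, render_profile_table
from .scoring import score_cohort
from .simulate import SimulationSpec, default_spec, generate_cohort

logger = logging.getLogger("emodiv")

METRICS = ("total", "positive", "negative")
SYMPTOM_TOTALS = ("positive", "negative")

ANALYSIS_COLUMNS = (
    "model",
    "outcome",
    "focal",
    "b",
    "ci_low",
    "ci_high",
    "r2_partial",
    "r2_model",
    "p",
    "n",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (JSON-serializable)."""

    out_dir: str = "emodiv_run"
    seed: int = 0
    cohort_csv: str | None = None  # analyse an existing cohort instead of simulating
    chr_only: bool = True
    within_valence_denominator: bool = False
    k_folds: int = 10
    n_keep: int = 3
    spec: dict | None = None  # SimulationSpec override as a dict

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "cohort_csv": self.cohort_csv,
            "chr_only": self.chr_only,
            "within_valence_denominator": self.within_valence_denominator,
            "k_folds": self.k_folds,
            "n_keep": self.n_keep,
            "spec": self.spec,
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def validate(self) -> None:
        if self.k_folds < 2:
            raise PipelineError("k_folds must be >= 2")
        if not 1 <= self.n_keep <= 18:
            raise PipelineError("n_keep must be in 1..18")
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise FileNotFoundError(self.cohort_csv)


def run_analysis_grid(scores: pd.DataFrame, chr_only: bool = True) -> pd.DataFrame:
    """The full analysis grid: 3 group-difference models (one per diversity
    metric) and 6 symptom-association models (3 metrics x 2 symptom totals)."""
    rows = []
    for metric in METRICS:
        res = GroupDifferenceModel(scores, metric).fit()
        rows.append(("group_difference", res))
    for metric in METRICS:
        for sym in SYMPTOM_TOTALS:
            res = SymptomAssociationModel(scores, metric, sym, chr_only).fit()
            rows.append(("symptom_association", res))
    return pd.DataFrame(
        [
            {
                "model": kind,
                "outcome": r.outcome,
                "focal": r.focal_term,
                "b": r.b,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "r2_partial": r.r2_partial,
                "r2_model": r.r2_model,
                "p": r.p,
                "n": r.n,
            }
            for kind, r in rows
        ],
        columns=list(ANALYSIS_COLUMNS),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _versions() -> dict[str, str]:
    try:
        own = metadata.version("emodiv")
    except metadata.PackageNotFoundError:  # pragma: no cover
        own = "unknown"
    return {
        "emodiv": own,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    Stages: obtain a cohort (read the configured CSV or simulate one from
    the spec), score emodiversity, fit the 9-model analysis grid, profile
    the 11 SIPS symptoms, render the report. Any stage failure aborts with
    the stage name attached.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "cohort"
    try:
        if config.cohort_csv is not None:
            cohort = read_cohort_csv(config.cohort_csv)
            logger.info("stage cohort: read %d participants", len(cohort))
        else:
            spec = (
                SimulationSpec.from_dict(config.spec)
                if config.spec is not None
                else default_spec()
            )
            spec.seed = config.seed
            cohort = generate_cohort(spec)
            logger.info("stage cohort: simulated %d participants", len(cohort))
        cohort_path = write_cohort_csv(cohort, out_dir / "cohort.csv")

        stage = "score"
        scores = score_cohort(
            cohort, within_valence_denominator=config.within_valence_denominator
        )
        scores_path = out_dir / "scores.csv"
        scores.to_csv(scores_path, index=False)
        logger.info("stage score: %d rows", len(scores))

        stage = "analyze"
        analysis = run_analysis_grid(scores, chr_only=config.chr_only)
        analysis_path = out_dir / "analysis.csv"
        analysis.to_csv(analysis_path, index=False)
        logger.info("stage analyze: %d models", len(analysis))

        stage = "profile"
        profiles = profile_all_symptoms(
            cohort,
            k=config.k_folds,
            n_keep=config.n_keep,
            seed=config.seed,
            chr_only=config.chr_only,
        )
        profiles_frame = profiles_to_frame(profiles)
        profiles_path = out_dir / "profiles.csv"
        profiles_frame.to_csv(profiles_path, index=False)
        logger.info("stage profile: %d symptom profiles", len(profiles))
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "versions": _versions(),
        "outputs": {
            "cohort": str(cohort_path),
            "scores": str(scores_path),
            "analysis": str(analysis_path),
            "profiles": str(profiles_path),
            "report": str(out_dir / "report.md"),
        },
        "tables_sha256": {
            "scores": _sha256(scores_path),
            "profiles": _sha256(profiles_path),
        },
        "counts": {
            "participants": len(cohort),
            "group_difference_models": int(
                (analysis["model"] == "group_difference").sum()
            ),
            "symptom_association_models": int(
                (analysis["model"] == "symptom_association").sum()
            ),
            "symptom_profiles": len(profiles),
        },
    }
    stage = "report"
    try:
        report = render_report(manifest)
        (out_dir / "report.md").write_text(report)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def _demographics_block(cohort_frame: pd.DataFrame) -> str:
    chr_f = cohort_frame[cohort_frame["group"] == "CHR"]
    hc_f = cohort_frame[cohort_frame["group"] == "HC"]
    if len(chr_f) < 2 or len(hc_f) < 2:
        return (
            "Demographic comparisons require at least two participants in "
            "each group; this cohort does not have both groups populated."
        )
    lines = [
        "| Variable | CHR mean (SD) | HC mean (SD) | Statistic | p |",
        "|---|---|---|---|---|",
    ]
    numeric = [
        ("Age", "age"),
        ("Parent education", "parent_education"),
    ]
    for label, col in numeric:
        a, b = chr_f[col].dropna(), hc_f[col].dropna()
        if len(a) < 2 or len(b) < 2 or a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
            continue
        res = welch_t_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        lines.append(
            f"| {label} | {a.mean():.2f} ({a.std(ddof=1):.2f}) "
            f"| {b.mean():.2f} ({b.std(ddof=1):.2f}) "
            f"| t = {res.t:.2f} | {res.p:.3f} |"
        )
    for label, cols in (
        ("Total positive symptoms", list(POSITIVE_SYMPTOMS)),
        ("Total negative symptoms", list(NEGATIVE_SYMPTOMS)),
    ):
        a = chr_f[cols].sum(axis=1)
        b = hc_f[cols].sum(axis=1)
        if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
            continue
        res = welch_t_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        lines.append(
            f"| {label} | {a.mean():.2f} ({a.std(ddof=1):.2f}) "
            f"| {b.mean():.2f} ({b.std(ddof=1):.2f}) "
            f"| t = {res.t:.2f} | {res.p:.3f} |"
        )
    sex_table = [
        [int((chr_f["sex"] == "male").sum()), int((hc_f["sex"] == "male").sum())],
        [int((chr_f["sex"] == "female").sum()), int((hc_f["sex"] == "female").sum())],
    ]
    try:
        chi = yates_chi_square(sex_table)
        lines.append(
            f"| Sex (male/female) | {sex_table[0][0]}/{sex_table[1][0]} "
            f"| {sex_table[0][1]}/{sex_table[1][1]} "
            f"| chi2 = {chi.statistic:.2f} | {chi.p:.3f} |"
        )
    except ValueError:
        pass
    return "\n".join(lines)


def _diversity_block(scores: pd.DataFrame) -> str:
    from .glm import standardize

    lines = [
        "Group means (SD) of standardized, unadjusted diversity metrics:",
        "",
        "| Metric | CHR | HC |",
        "|---|---|---|",
    ]
    for metric, col in (
        ("Total", "diversity_total"),
        ("Positive", "diversity_positive"),
        ("Negative", "diversity_negative"),
    ):
        z = standardize(scores[col])
        s = scores.assign(z=z)
        cells = []
        for grp in ("CHR", "HC"):
            sub = s[s["group"] == grp]["z"]
            if len(sub) >= 2:
                cells.append(f"{sub.mean():+.2f} ({sub.std(ddof=1):.2f})")
            else:
                cells.append("n/a")
        lines.append(f"| {metric} | {cells[0]} | {cells[1]} |")
    return "\n".join(lines)


def _glm_block(analysis: pd.DataFrame) -> str:
    lines = [
        "| Model | Outcome | Focal | b | 95% CI | partial R2 | p | n |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for _, r in analysis.iterrows():
        lines.append(
            f"| {r['model']} | {r['outcome']} | {r['focal']} "
            f"| {r['b']:+.2f} | [{r['ci_low']:+.2f}, {r['ci_high']:+.2f}] "
            f"| {r['r2_partial']:.3f} | {r['p']:.3g} | {int(r['n'])} |"
        )
    return "\n".join(lines)


def _profiles_block(profiles_frame: pd.DataFrame, top: int = 3) -> str:
    lines = [
        "| Symptom | " + " | ".join(f"Item {j + 1}" for j in range(top)) + " |",
        "|" + "---|" * (top + 1),
    ]
    for criterion, grp in profiles_frame.groupby("criterion", sort=False):
        chosen = grp.sort_values("rank").head(top)
        cells = [
            f"{row['item']} r = {row['mean_r']:+.2f} ({row['sd_r']:.2f})"
            for _, row in chosen.iterrows()
        ]
        lines.append(f"| {criterion} | " + " | ".join(cells) + " |")
    return "\n".join(lines)


def render_report(manifest: dict) -> str:
    """Markdown run report with demographics, diversity summaries, the GLM
    table and the top-item emotion profiles."""
    outputs = manifest["outputs"]
    for key in ("cohort", "scores", "analysis", "profiles"):
        if not Path(outputs[key]).exists():
            raise PipelineError(f"missing pipeline output: {outputs[key]}")
    cohort_frame = pd.read_csv(outputs["cohort"])
    scores = pd.read_csv(outputs["scores"])
    analysis = pd.read_csv(outputs["analysis"])
    profiles_frame = pd.read_csv(outputs["profiles"])
    parts = [
        "# Emodiversity run report",
        "",
        f"Seed: {manifest['seed']}  |  Config hash: `{manifest['config_hash'][:12]}`",
        "",
        "## Cohort demographics",
        "",
        _demographics_block(cohort_frame),
        "",
        "## Diversity score summaries",
        "",
        _diversity_block(scores),
        "",
        "## General linear models",
        "",
        _glm_block(analysis),
        "",
        "## Emotion item profiles",
        "",
        _profiles_block(profiles_frame),
        "",
    ]
    return "\n".join(parts)
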