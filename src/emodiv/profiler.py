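"""Cross-validated, unit-weighted emotion-item profiles per SIPS symptom.

For each attenuated symptom, the profiler estimates which discrete
emotions carry the signal: within each of k (default 10) seeded folds it
computes zero-order (plain Pearson) correlations of the 18 item ratings
with the criterion on the training portion, keeps the top ``n_keep``
items by |r|, signs each kept item by its correlation, and evaluates the
unit-weighted composite (sum of +/-1-signed, training-standardized items)
on the held-out portion. Items are reported with their mean and SD of r
across the k training fits; ``cv_composite_r`` is the mean held-out
correlation — an honest, leakage-free estimate of how well a parsimonious
unit-weighted emotion scale tracks the symptom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ALL_SYMPTOMS, Cohort
from .items import ALL_ITEMS

logger = logging.getLogger("emodiv")


class ProfilerError(ValueError):
    pass


@dataclass
class ItemProfile:
    """Per-criterion ranked emotion items with cross-fold statistics."""

    criterion: str
    per_item: pd.DataFrame  # index: item; columns: mean_r, sd_r, rank, selected
    selected: list[str]
    n_keep: int
    cv_composite_r: float
    k_folds: int
    seed: int
    fold_train_r: pd.DataFrame = field(repr=False, default=None)  # items x folds
    fold_test_r: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        out = self.per_item.reset_index(names="item")
        out.insert(0, "criterion", self.criterion)
        out["cv_composite_r"] = self.cv_composite_r
        out["k_folds"] = self.k_folds
        out["n_keep"] = self.n_keep
        out["seed"] = self.seed
        return out

    def summary(self, top: int | None = None) -> str:
        top = top if top is not None else self.n_keep
        parts = [
            f"{item} r = {self.per_item.loc[item, 'mean_r']:+.2f} "
            f"({self.per_item.loc[item, 'sd_r']:.2f})"
            for item in self.selected[:top]
        ]
        return f"{self.criterion}: " + "; ".join(parts) + (
            f"  [cv composite r = {self.cv_composite_r:+.2f}]"
        )


def zero_order_correlations(items: np.ndarray, criterion) -> pd.Series:
    """Pearson correlation of each item column with the criterion.

    Zero-variance items get r = 0 with a logged warning; a constant
    criterion is an error.
    """
    X = np.asarray(items, dtype=float)
    y = np.asarray(criterion, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ProfilerError("items must be (n, p) aligned with criterion")
    if X.shape[0] < 3:
        raise ProfilerError("need >= 3 participants")
    y_sd = y.std(ddof=0)
    if y_sd == 0:
        raise ProfilerError("criterion is constant")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    x_sd = X.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).mean(axis=0) / (x_sd * y_sd)
    zero_var = x_sd == 0
    if zero_var.any():
        logger.warning(
            "zero-variance item(s) given r = 0: %s",
            [ALL_ITEMS[j] for j in np.where(zero_var)[0] if j < len(ALL_ITEMS)],
        )
        r[zero_var] = 0.0
    names = list(ALL_ITEMS) if X.shape[1] == len(ALL_ITEMS) else list(range(X.shape[1]))
    return pd.Series(r, index=names)


def unit_weighted_score(
    items: np.ndarray,
    keys: dict[str, int] | dict[int, int],
    center: dict | None = None,
    scale: dict | None = None,
    item_names: list[str] | None = None,
) -> np.ndarray:
    """Sum of +/-1-signed standardized item ratings.

    ``keys`` maps item -> sign in {-1, +1}. Standardization parameters
    (``center``/``scale`` per item) come from the data the keys were
    derived on — the training fold — and are applied unchanged to new data.
    When omitted they are computed from ``items`` itself.
    """
    if not keys:
        raise ProfilerError("keys must be non-empty")
    X = np.asarray(items, dtype=float)
    names = item_names if item_names is not None else (
        list(ALL_ITEMS) if X.shape[1] == len(ALL_ITEMS) else list(range(X.shape[1]))
    )
    col = {name: j for j, name in enumerate(names)}
    composite = np.zeros(X.shape[0])
    for item, sign in keys.items():
        if sign not in (-1, 1):
            raise ProfilerError(f"sign for {item!r} must be -1 or +1")
        j = col[item]
        mu = center[item] if center is not None else X[:, j].mean()
        sd = scale[item] if scale is not None else X[:, j].std(ddof=1)
        if sd == 0:
            sd = 1.0  # degenerate training item contributes its sign only
        composite += sign * (X[:, j] - mu) / sd
    return composite


def _rank_items(mean_r: pd.Series) -> list[str]:
    """Items by |r| descending; ties broken by canonical item order."""
    order = {item: j for j, item in enumerate(mean_r.index)}
    return sorted(mean_r.index, key=lambda it: (-abs(mean_r[it]), order[it]))


def cross_validated_profile(
    table: pd.DataFrame,
    criterion: str,
    k: int = 10,
    n_keep: int = 3,
    seed: int = 0,
    r_threshold: float | None = None,
) -> ItemProfile:
    """k-fold cross-validated unit-weighted item profile for one symptom.

    ``table`` holds the 18 item columns plus the criterion column.
    Selection within each training fold keeps the top ``n_keep`` items by
    |r| (or, if ``r_threshold`` is given, every item with |r| >= threshold,
    falling back to the single best item when none passes).
    """
    n = len(table)
    if n < 2 * k:
        raise ProfilerError(f"need n >= 2k = {2 * k}, got {n}")
    X = table[list(ALL_ITEMS)].to_numpy(dtype=float)
    y = table[criterion].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    train_r = np.zeros((len(ALL_ITEMS), k))
    test_r = np.full(k, np.nan)
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        X_tr, y_tr = X[train_mask], y[train_mask]
        if y_tr.std(ddof=0) == 0:
            raise ProfilerError(f"criterion constant in training fold {f}")
        r = zero_order_correlations(X_tr, y_tr)
        train_r[:, f] = r.to_numpy()
        ranked = _rank_items(r)
        if r_threshold is not None:
            chosen = [it for it in ranked if abs(r[it]) >= r_threshold] or ranked[:1]
        else:
            chosen = ranked[:n_keep]
        keys = {it: (1 if r[it] >= 0 else -1) for it in chosen}
        center = {it: X_tr[:, ALL_ITEMS.index(it)].mean() for it in chosen}
        scale = {it: X_tr[:, ALL_ITEMS.index(it)].std(ddof=1) for it in chosen}
        comp = unit_weighted_score(X[test_idx], keys, center, scale)
        y_te = y[test_idx]
        if y_te.std(ddof=0) == 0 or comp.std(ddof=0) == 0:
            logger.warning(
                "fold %d: degenerate held-out data for %s; fold r skipped",
                f,
                criterion,
            )
            continue
        test_r[f] = np.corrcoef(comp, y_te)[0, 1]

    mean_r = pd.Series(train_r.mean(axis=1), index=list(ALL_ITEMS))
    sd_r = pd.Series(train_r.std(axis=1, ddof=1), index=list(ALL_ITEMS))
    ranked = _rank_items(mean_r)
    per_item = pd.DataFrame({"mean_r": mean_r, "sd_r": sd_r})
    per_item["rank"] = [ranked.index(it) + 1 for it in per_item.index]
    selected = ranked[:n_keep]
    per_item["selected"] = [int(it in selected) for it in per_item.index]
    return ItemProfile(
        criterion=criterion,
        per_item=per_item,
        selected=selected,
        n_keep=n_keep,
        cv_composite_r=float(np.nanmean(test_r)),
        k_folds=k,
        seed=seed,
        fold_train_r=pd.DataFrame(train_r, index=list(ALL_ITEMS)),
        fold_test_r=test_r,
    )


class EmotionProfiler:
    """Model-style interface: configure on a cohort table, ``fit()`` per
    criterion or ``fit_all()`` across the eleven SIPS symptoms."""

    def __init__(
        self,
        table: pd.DataFrame,
        k: int = 10,
        n_keep: int = 3,
        seed: int = 0,
        r_threshold: float | None = None,
    ):
        self.table = table
        self.k = k
        self.n_keep = n_keep
        self.seed = seed
        self.r_threshold = r_threshold

    def fit(self, criterion: str) -> ItemProfile:
        return cross_validated_profile(
            self.table,
            criterion,
            k=self.k,
            n_keep=self.n_keep,
            seed=self.seed,
            r_threshold=self.r_threshold,
        )

    def fit_all(self) -> list[ItemProfile]:
        profiles = []
        for sym in ALL_SYMPTOMS:
            if self.table[sym].std(ddof=0) == 0:
                logger.warning(
                    "symptom %s constant in the analysed subset; skipped", sym
                )
                continue
            profiles.append(self.fit(sym))
        return profiles


def profile_all_symptoms(
    cohort: Cohort | pd.DataFrame,
    k: int = 10,
    n_keep: int = 3,
    seed: int = 0,
    chr_only: bool = True,
) -> list[ItemProfile]:
    """One profile per SIPS symptom (P1-P5, N1-N6).

    Defaults to the CHR subsample, where symptom variance exists; constant
    symptoms are flagged and skipped rather than erroring the whole run.
    """
    frame = cohort.to_frame() if isinstance(cohort, Cohort) else cohort
    if chr_only:
        frame = frame[frame["group"] == "CHR"]
    return EmotionProfiler(frame, k=k, n_keep=n_keep, seed=seed).fit_all()


def profiles_to_frame(profiles: list[ItemProfile]) -> pd.DataFrame:
    """Long-format table: criterion, item, mean_r, sd_r, rank, selected."""
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)


def render_profile_table(profiles: list[ItemProfile], top: int = 3) -> str:
    """Markdown table of the top items per symptom, signed r with fold SD."""
    header = (
        "| Symptom | "
        + " | ".join(f"Item {j + 1}" for j in range(top))
        + " |\n|"
        + "---|" * (top + 1)
    )
    rows = []
    for p in profiles:
        cells = []
        for item in p.selected[:top]:
            cells.append(
                f"{item} r = {p.per_item.loc[item, 'mean_r']:+.2f} "
                f"({p.per_item.loc[item, 'sd_r']:.2f})"
            )
        cells += [""] * (top - len(cells))
        rows.append(f"| {p.criterion} | " + " | ".join(cells) + " |")
    return header + "\n" + "\n".join(rows)
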