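"""Diagnostic-accuracy protocol: quartile dichotomization, 2x2 metrics,
Fisher's exact tests, ROC grids and the paired MIE-vs-FPM comparison.

The protocol dichotomizes each hematological outcome at every point of a
fixed cutoff grid (outcome positive = biomarker >= cutoff, i.e. "iron
sufficient") and each dietary variable at its cohort quartile boundaries
(Q1 = top quartile).  Enhancers of iron absorption (iron, ascorbic acid)
test positive above their threshold; inhibitors (phytate, phytate:iron
ratio) test positive below it.  A value exactly at a dietary threshold is
test-negative.  Every (outcome cutoff x quartile threshold) cell yields a
2x2 table; cells with an empty margin are degenerate and excluded from
summaries.  Per method/variable/outcome, the summary is the unweighted mean
of each accuracy metric over retained cells (reported as percentages), and
the two methods are compared by a paired two-sided t-test across matched
cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from math import comb
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from fpmiron.composition import VARIABLES, InvalidInputError

logger = logging.getLogger(__name__)

Direction = Literal["enhancer", "inhibitor"]
Method = Literal["MIE", "FPM"]

#: default test-positivity direction per dietary variable
DEFAULT_DIRECTIONS: dict[str, Direction] = {
    "iron": "enhancer",
    "ascorbic": "enhancer",
    "phytate": "inhibitor",
    "ratio": "inhibitor",
}

OUTCOME_COLUMNS = {
    "hemoglobin": "hemoglobin_g_dl",
    "ferritin": "ferritin_ng_dl",
    "absorption": "absorption_pct",
}

HEMATOLOGY_COLUMNS = ["participant_id", *OUTCOME_COLUMNS.values()]

THRESHOLD_RANKS = ("q25", "q50", "q75")


@dataclass(frozen=True)
class OutcomeCutoffGrid:
    """Inclusive arithmetic grid of dichotomization cutoffs for one outcome."""

    outcome: str
    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise InvalidInputError(f"{self.outcome}: grid step must be > 0")
        if not self.start < self.stop:
            raise InvalidInputError(f"{self.outcome}: grid start must be < stop")

    @property
    def points(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step))
        return self.start + self.step * np.arange(n + 1)


def default_grids() -> dict[str, OutcomeCutoffGrid]:
    """The standard cutoff grids: hemoglobin 11.0-14.0 g/dL by 0.5, ferritin
    5-55 ng/dL by 5, acute iron absorption 0-50% by 5."""
    return {
        "hemoglobin": OutcomeCutoffGrid("hemoglobin", 11.0, 14.0, 0.5),
        "ferritin": OutcomeCutoffGrid("ferritin", 5.0, 55.0, 5.0),
        "absorption": OutcomeCutoffGrid("absorption", 0.0, 50.0, 5.0),
    }


@dataclass(frozen=True)
class QuartileThresholds:
    """Cohort quartile boundaries of one dietary variable.

    Quartile labels are descending: Q1 is the 76th-100th percentile band, Q4
    the 0th-25th, so q75 is the Q1/Q2 boundary.
    """

    variable: str
    method: str
    q25: float
    q50: float
    q75: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.q25 <= self.q50 <= self.q75):
            raise InvalidInputError("quartile boundaries must be non-decreasing")

    def as_dict(self) -> dict[str, float]:
        return {"q25": self.q25, "q50": self.q50, "q75": self.q75}


@dataclass(frozen=True)
class ConfusionTable:
    """One 2x2 test-vs-outcome contingency table."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Accuracy statistics of one 2x2 table; ``None`` marks an undefined
    metric (zero denominator)."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    lr_plus: float | None
    fisher_p: float


def load_hematology(path) -> pd.DataFrame:
    """Read and validate a hematology-panel CSV (one row per participant)."""
    panels = pd.read_csv(path)
    return validate_hematology(panels)


def validate_hematology(panels: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in HEMATOLOGY_COLUMNS if c not in panels.columns]
    if missing:
        raise InvalidInputError(f"hematology table missing column(s): {missing}")
    panels = panels.copy()
    panels["participant_id"] = panels["participant_id"].astype(str)
    if panels["participant_id"].duplicated().any():
        raise InvalidInputError("duplicate participant_id in hematology table")
    for col in OUTCOME_COLUMNS.values():
        values = pd.to_numeric(panels[col], errors="coerce")
        if not np.isfinite(values).all():
            raise InvalidInputError(f"hematology column {col} has non-finite values")
        panels[col] = values.astype(float)
    if (panels["hemoglobin_g_dl"] <= 0).any():
        raise InvalidInputError("hemoglobin must be > 0")
    if (panels["ferritin_ng_dl"] < 0).any():
        raise InvalidInputError("ferritin must be >= 0")
    absorption = panels["absorption_pct"]
    if ((absorption < 0) | (absorption > 100)).any():
        raise InvalidInputError("absorption must lie in [0, 100]")
    return panels


def quartile_thresholds(
    values: Iterable[float], variable: str = "", method: str = ""
) -> QuartileThresholds:
    """25th/50th/75th percentile boundaries by linear interpolation between
    closest ranks (the inclusive convention).  Requires at least 4 values;
    an all-equal input is flagged degenerate."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4:
        raise InvalidInputError(f"need >= 4 values for quartiles, got {arr.size}")
    if not np.isfinite(arr).all():
        raise InvalidInputError("quartile input must be finite")
    q25, q50, q75 = np.percentile(arr, [25, 50, 75], method="linear")
    degenerate = bool(np.all(arr == arr[0]))
    if degenerate:
        logger.warning("quartile input for %s/%s is constant", method, variable)
    return QuartileThresholds(variable, method, float(q25), float(q50), float(q75), degenerate)


def dichotomize_test(values, threshold: float, direction: Direction) -> np.ndarray:
    """Dietary test labels: enhancers positive strictly above the threshold,
    inhibitors strictly below (predicting the iron-replete outcome); a value
    exactly at the threshold is negative."""
    arr = np.asarray(values, dtype=float)
    if direction == "enhancer":
        return arr > threshold
    if direction == "inhibitor":
        return arr < threshold
    raise InvalidInputError(f"unknown direction {direction!r}")


def confusion(test_labels, outcome_labels) -> ConfusionTable:
    """Cross-tabulate paired boolean test and outcome labels."""
    t = np.asarray(test_labels, dtype=bool)
    o = np.asarray(outcome_labels, dtype=bool)
    if t.shape != o.shape:
        raise InvalidInputError(f"label length mismatch: {t.shape} vs {o.shape}")
    if t.size == 0:
        raise InvalidInputError("empty label vectors")
    return ConfusionTable(
        tp=int(np.sum(t & o)),
        fp=int(np.sum(t & ~o)),
        fn=int(np.sum(~t & o)),
        tn=int(np.sum(~t & ~o)),
    )


def fisher_exact(ct: ConfusionTable) -> float:
    """Two-sided Fisher exact p-value by direct hypergeometric enumeration.

    p is the total probability of all 2x2 tables with the observed margins
    whose probability does not exceed the observed table's.  Comparisons are
    done on exact integer numerators, so mathematically tied tables are
    always included.
    """
    n_total = ct.total
    if n_total == 0:
        raise InvalidInputError("empty confusion table")
    k_outcome = ct.tp + ct.fn
    n_test = ct.tp + ct.fp
    lo = max(0, n_test + k_outcome - n_total)
    hi = min(n_test, k_outcome)
    obs = comb(k_outcome, ct.tp) * comb(n_total - k_outcome, n_test - ct.tp)
    total = 0
    for k in range(lo, hi + 1):
        w = comb(k_outcome, k) * comb(n_total - k_outcome, n_test - k)
        if w <= obs:
            total += w
    return min(1.0, total / comb(n_total, n_test))


def _safe_div(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(ct: ConfusionTable, with_fisher: bool = True) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV, LR+ and Fisher p of one table.

    Zero-denominator metrics come back ``None`` rather than raising, so grid
    sweeps can flag and skip them.
    """
    if ct.total == 0:
        raise InvalidInputError("empty confusion table")
    sens = _safe_div(ct.tp, ct.tp + ct.fn)
    spec = _safe_div(ct.tn, ct.tn + ct.fp)
    ppv = _safe_div(ct.tp, ct.tp + ct.fp)
    npv = _safe_div(ct.tn, ct.tn + ct.fn)
    lr_plus = None
    if sens is not None and spec is not None and spec < 1.0:
        lr_plus = sens / (1.0 - spec)
    p = fisher_exact(ct) if with_fisher else math.nan
    return DiagnosticMetrics(sens, spec, ppv, npv, lr_plus, p)


_CELL_COLUMNS = [
    "outcome",
    "variable",
    "method",
    "outcome_cutoff",
    "threshold_rank",
    "threshold",
    "tp",
    "fp",
    "fn",
    "tn",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "lr_plus",
    "fisher_p",
    "degenerate",
]


def _join_cohort(profiles: pd.DataFrame, panels: pd.DataFrame) -> pd.DataFrame:
    joined = profiles.merge(panels, on="participant_id", how="inner", validate="one_to_one")
    if joined.empty:
        raise InvalidInputError("profiles and hematology panels share no participants")
    return joined


def roc_grid(
    profiles: pd.DataFrame,
    panels: pd.DataFrame,
    grid: OutcomeCutoffGrid,
    variable: str,
    method: Method,
    direction: Direction | None = None,
    with_fisher: bool = True,
) -> pd.DataFrame:
    """All (outcome cutoff x quartile threshold) cells for one method/variable.

    Returns one row per cell with its confusion counts, accuracy metrics and
    a ``degenerate`` flag (empty outcome or test margin); degenerate cells
    carry NaN metrics and are excluded from downstream summaries.
    """
    if variable not in VARIABLES:
        raise InvalidInputError(f"unknown variable {variable!r}")
    if direction is None:
        direction = DEFAULT_DIRECTIONS[variable]
    cohort = _join_cohort(profiles, panels)
    test_values = cohort[f"{method.lower()}_{variable}"].to_numpy()
    outcome_values = cohort[OUTCOME_COLUMNS[grid.outcome]].to_numpy()
    qt = quartile_thresholds(test_values, variable, method)
    rows = []
    for cutoff in grid.points:
        outcome_pos = outcome_values >= cutoff  # outcome positive = iron sufficient
        for rank, threshold in qt.as_dict().items():
            test_pos = dichotomize_test(test_values, threshold, direction)
            ct = confusion(test_pos, outcome_pos)
            degenerate = (
                outcome_pos.all()
                or not outcome_pos.any()
                or test_pos.all()
                or not test_pos.any()
            )
            if degenerate:
                logger.debug(
                    "degenerate cell %s/%s/%s cutoff=%g rank=%s",
                    grid.outcome,
                    variable,
                    method,
                    cutoff,
                    rank,
                )
                m = DiagnosticMetrics(None, None, None, None, None, math.nan)
            else:
                m = metrics(ct, with_fisher=with_fisher)
            rows.append(
                (
                    grid.outcome,
                    variable,
                    method,
                    float(cutoff),
                    rank,
                    threshold,
                    ct.tp,
                    ct.fp,
                    ct.fn,
                    ct.tn,
                    np.nan if m.sensitivity is None else m.sensitivity,
                    np.nan if m.specificity is None else m.specificity,
                    np.nan if m.ppv is None else m.ppv,
                    np.nan if m.npv is None else m.npv,
                    np.nan if m.lr_plus is None else m.lr_plus,
                    m.fisher_p,
                    degenerate,
                )
            )
    cells = pd.DataFrame(rows, columns=_CELL_COLUMNS)
    n_deg = int(cells["degenerate"].sum())
    if n_deg:
        logger.info(
            "%s/%s/%s: %d of %d cells degenerate, excluded from summaries",
            grid.outcome,
            variable,
            method,
            n_deg,
            len(cells),
        )
    return cells


def summarize_method(cells: pd.DataFrame) -> dict[str, float]:
    """Unweighted mean sensitivity/specificity/PPV/NPV over retained cells,
    as percentages.  Cells with an undefined metric are dropped for that
    metric's mean only (count logged)."""
    retained = cells[~cells["degenerate"]]
    if retained.empty:
        raise InvalidInputError("no retained (non-degenerate) cells to summarize")
    out = {}
    for metric_name in ("sensitivity", "specificity", "ppv", "npv"):
        col = retained[metric_name]
        n_undef = int(col.isna().sum())
        if n_undef:
            logger.info("%d cells with undefined %s dropped from its mean", n_undef, metric_name)
        out[metric_name] = float(col.mean(skipna=True) * 100.0)
    return out


def paired_compare(
    cells_mie: pd.DataFrame, cells_fpm: pd.DataFrame
) -> tuple[float, float, dict[str, bool]]:
    """Paired two-sided t-tests of per-cell sensitivity and specificity
    between the two methods, matched on (outcome cutoff, threshold rank).

    Only pairs where both methods have a defined metric enter each test.  A
    zero-variance difference vector is reported as p = 1.0 with a degenerate
    flag instead of failing, so comparison reports always complete.
    """
    key = ["outcome_cutoff", "threshold_rank"]
    merged = cells_mie.merge(cells_fpm, on=key, suffixes=("_mie", "_fpm"), validate="one_to_one")
    flags = {}
    pvalues = {}
    for metric_name in ("sensitivity", "specificity"):
        a = merged[f"{metric_name}_mie"]
        b = merged[f"{metric_name}_fpm"]
        ok = a.notna() & b.notna()
        if int(ok.sum()) < 2:
            raise InvalidInputError(
                f"paired comparison needs >= 2 complete pairs for {metric_name}"
            )
        diff = (a[ok] - b[ok]).to_numpy()
        if np.all(diff == diff[0]):
            pvalues[metric_name] = 1.0
            flags[metric_name] = True
        else:
            pvalues[metric_name] = float(stats.ttest_rel(a[ok], b[ok]).pvalue)
            flags[metric_name] = False
    return pvalues["sensitivity"], pvalues["specificity"], flags


SUMMARY_COLUMNS = [
    "outcome",
    "variable",
    "method",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "p_sensitivity",
    "p_specificity",
]


def compare_all(
    profiles: pd.DataFrame,
    panels: pd.DataFrame,
    grids: dict[str, OutcomeCutoffGrid] | None = None,
    directions: dict[str, Direction] | None = None,
    with_fisher: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full head-to-head comparison: MIE vs FPM for every variable x outcome.

    Returns ``(summary, roc)``: a 24-row summary table (3 outcomes x 4
    variables x 2 methods) with mean accuracy percentages and the paired
    t-test p-values, and a tidy ROC table with one row per grid cell
    including (1-specificity, sensitivity) plotting coordinates.
    """
    if grids is None:
        grids = default_grids()
    if directions is None:
        directions = dict(DEFAULT_DIRECTIONS)
    summary_rows = []
    roc_frames = []
    for outcome, grid in grids.items():
        for variable in VARIABLES:
            per_method = {}
            for method in ("MIE", "FPM"):
                cells = roc_grid(
                    profiles,
                    panels,
                    grid,
                    variable,
                    method,
                    directions[variable],
                    with_fisher=with_fisher,
                )
                if cells["degenerate"].all():
                    raise InvalidInputError(
                        f"every grid cell degenerate for {outcome}/{variable}/{method}; "
                        "the outcome or the dietary variable does not vary in this cohort"
                    )
                per_method[method] = cells
                roc_frames.append(cells)
            p_sens, p_spec, _ = paired_compare(per_method["MIE"], per_method["FPM"])
            for method in ("MIE", "FPM"):
                means = summarize_method(per_method[method])
                summary_rows.append(
                    {
                        "outcome": outcome,
                        "variable": variable,
                        "method": method,
                        **means,
                        "p_sensitivity": p_sens,
                        "p_specificity": p_spec,
                    }
                )
    summary = pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS)
    roc = pd.concat(roc_frames, ignore_index=True)
    roc["fpr"] = 1.0 - roc["specificity"]
    roc["tpr"] = roc["sensitivity"]
    return summary, roc
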