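"""Cross-tabulation and diagnostic test characteristics.

Surname-derived ethnicity is treated as a diagnostic test; self-reported
ethnicity is the reference.  For a target group the k×k cross-tabulation
collapses to a 2×2 table

    TP = cell(target, target)          FP = row(target) − TP
    FN = col(target) − TP              TN = total − TP − FP − FN

and the four characteristics are

    sensitivity = TP/(TP+FN)    specificity = TN/(TN+FP)
    PPV         = TP/(TP+FP)    NPV         = TN/(TN+FN)

computed on unweighted respondent counts or on weighted (person-level
weight) sums.  A zero denominator makes the metric *undefined* (``None``),
never silently 0 — a stratum with no predicted positives has no PPV.
Percentile-bootstrap confidence intervals resample respondents with
replacement, carrying their weights along.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "CrossTab",
    "TestCharacteristics",
    "cross_tabulate",
    "test_characteristics",
    "stratified_characteristics",
    "compare_lists",
    "bootstrap_ci",
    "METRICS",
]

METRICS = ("sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class CrossTab:
    """k×k cross-tabulation of surname-derived (rows) vs gold-standard
    (columns) groups, unweighted counts and weighted sums."""

    labels: tuple[str, ...]
    unweighted: pd.DataFrame
    weighted: pd.DataFrame

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, weights: pd.DataFrame | None = None) -> "CrossTab":
        """Build from a square count table (rows = surname-derived).  When
        no weighted table is given the counts serve as weights (weight 1
        per respondent)."""
        labels = tuple(counts.index)
        if tuple(counts.columns) != labels:
            raise ValueError("count table must have identical row/column labels")
        w = counts.astype(float) if weights is None else weights
        return cls(labels, counts.astype(int), w)

    @property
    def n_respondents(self) -> int:
        return int(self.unweighted.to_numpy().sum())

    @property
    def total_weight(self) -> float:
        return float(self.weighted.to_numpy().sum())

    def row_totals(self, weighted: bool = False) -> pd.Series:
        return (self.weighted if weighted else self.unweighted).sum(axis=1)

    def col_totals(self, weighted: bool = False) -> pd.Series:
        return (self.weighted if weighted else self.unweighted).sum(axis=0)


@dataclass(frozen=True)
class TestCharacteristics:
    """The four diagnostic metrics as proportions in [0,1]; ``None`` marks
    an undefined metric (empty denominator).  ``n_effective`` holds each
    metric's denominator on the scale used (count or weight).  ``ci`` maps
    a metric name to a (lower, upper) percentile-bootstrap interval."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    n_effective: dict[str, float] = field(default_factory=dict, compare=False)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict, compare=False)

    def as_dict(self) -> dict[str, float | None]:
        return {m: getattr(self, m) for m in METRICS}

    def as_percentages(self) -> dict[str, float | None]:
        """Metrics as percentages rounded half-up to one decimal, the
        conventional reporting precision; ``None`` stays ``None``."""
        out = {}
        for m, v in self.as_dict().items():
            if v is None:
                out[m] = None
            else:
                out[m] = float(
                    Decimal(repr(float(v) * 100)).quantize(
                        Decimal("0.1"), rounding=ROUND_HALF_UP
                    )
                )
        return out


def _merged(assignments: pd.DataFrame, gold: pd.DataFrame, survey: pd.DataFrame) -> pd.DataFrame:
    """Link gold-labelled respondents with their surname-derived group."""
    df = survey[["person_id", "weight"] + [c for c in ("sex", "age_band", "immigration") if c in survey.columns]]
    df = df.merge(gold, on="person_id", validate="one_to_one")
    df = df.merge(assignments, on="person_id", how="left", validate="one_to_one")
    missing = df.loc[df["group"].isna(), "person_id"]
    if len(missing):
        raise ValueError(
            f"respondents with no surname-derived assignment: {sorted(missing.astype(str))[:10]}"
        )
    return df


def cross_tabulate(
    assignments: pd.DataFrame,
    gold: pd.DataFrame,
    survey: pd.DataFrame,
    labels: tuple[str, ...] | None = None,
) -> CrossTab:
    """Cross-tabulate surname-derived versus gold-standard group.

    ``assignments`` has columns ``person_id, group``; ``gold`` has
    ``person_id, gold``; ``survey`` supplies (pooled) weights.  Cell (r, c)
    holds the count / weight sum of respondents surname-assigned to r and
    self-identified as c.  Every gold-labelled respondent must have an
    assignment; missing ids are an error.
    """
    df = _merged(assignments, gold, survey)
    if labels is None:
        labels = tuple(sorted(set(df["group"]) | set(df["gold"])))
    unw = (
        df.groupby(["group", "gold"], sort=False).size().unstack(fill_value=0)
        .reindex(index=labels, columns=labels, fill_value=0)
    )
    wt = (
        df.groupby(["group", "gold"], sort=False)["weight"].sum().unstack(fill_value=0.0)
        .reindex(index=labels, columns=labels, fill_value=0.0)
    )
    return CrossTab(tuple(labels), unw.astype(int), wt.astype(float))


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def test_characteristics(tab: CrossTab, target_group: str, weighted: bool = False) -> TestCharacteristics:
    """Collapse a cross-tabulation to 2×2 for ``target_group`` and compute
    sensitivity, specificity, PPV and NPV on counts or weights."""
    if target_group not in tab.labels:
        raise KeyError(f"{target_group!r} not among {tab.labels}")
    table = tab.weighted if weighted else tab.unweighted
    arr = table.to_numpy(dtype=float)
    i = tab.labels.index(target_group)
    tp = arr[i, i]
    fp = arr[i, :].sum() - tp
    fn = arr[:, i].sum() - tp
    tn = arr.sum() - tp - fp - fn
    return TestCharacteristics(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        n_effective={
            "sensitivity": tp + fn,
            "specificity": tn + fp,
            "ppv": tp + fp,
            "npv": tn + fn,
        },
    )


# the name happens to match pytest's collection prefix
test_characteristics.__test__ = False  # type: ignore[attr-defined]

STRATA_FIELDS = ("sex", "age_band", "immigration")


def stratified_characteristics(
    assignments: pd.DataFrame,
    gold: pd.DataFrame,
    survey: pd.DataFrame,
    stratify_by: str,
    target_group: str,
    weighted: bool = True,
) -> dict[str, TestCharacteristics]:
    """Test characteristics computed independently within each stratum of
    ``stratify_by`` (one of ``sex``, ``age_band``, ``immigration``)."""
    if stratify_by not in STRATA_FIELDS:
        raise ValueError(f"unknown stratification field {stratify_by!r}; use one of {STRATA_FIELDS}")
    df = _merged(assignments, gold, survey)
    labels = tuple(sorted(set(df["group"]) | set(df["gold"])))
    out: dict[str, TestCharacteristics] = {}
    for stratum, sub in df.groupby(stratify_by, sort=True):
        tab = cross_tabulate(
            sub[["person_id", "group"]],
            sub[["person_id", "gold"]].rename(columns={"gold": "gold"}),
            sub[["person_id", "weight"]],
            labels=labels,
        )
        out[str(stratum)] = test_characteristics(tab, target_group, weighted=weighted)
    return out


def compare_lists(
    collection_a,
    collection_b,
    roster: pd.DataFrame,
    gold: pd.DataFrame,
    survey: pd.DataFrame,
    target_group: str,
    weighted: bool = True,
) -> dict[str, object]:
    """Validate two list collections against the same gold standard.

    Both collections are applied to the identical roster and respondents,
    so the two sets of test characteristics are directly comparable; the
    report includes per-metric differences (B − A).
    """
    from .assign import assign_roster  # local import to avoid a cycle

    results = {}
    for key, coll in (("A", collection_a), ("B", collection_b)):
        res = assign_roster(roster, coll)
        tab = cross_tabulate(res.assignments, gold, survey)
        results[key] = test_characteristics(tab, target_group, weighted=weighted)
    diffs = {}
    for m in METRICS:
        a, b = getattr(results["A"], m), getattr(results["B"], m)
        diffs[m] = None if a is None or b is None else b - a
    return {"A": results["A"], "B": results["B"], "difference": diffs}


def bootstrap_ci(
    assignments: pd.DataFrame,
    gold: pd.DataFrame,
    survey: pd.DataFrame,
    target_group: str,
    metric: str,
    B: int = 1000,
    seed: int = 0,
    weighted: bool = True,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile-bootstrap interval for one metric.

    Respondents are resampled with replacement, weights carried along
    (weights represent population counts, not sampling probabilities, so
    respondent-level resampling is the appropriate unit).  Reproducible
    given ``seed``.  If the metric is undefined in more than half of the
    replicates the sample is too sparse and an error is raised.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if B < 1:
        raise ValueError("B must be >= 1")
    df = _merged(assignments, gold, survey)
    labels = tuple(sorted(set(df["group"]) | set(df["gold"])))
    rng = np.random.default_rng(seed)
    n = len(df)
    group = df["group"].to_numpy()
    goldv = df["gold"].to_numpy()
    w = df["weight"].to_numpy(dtype=float)
    k = len(labels)
    lab_index = {l: j for j, l in enumerate(labels)}
    gi = np.array([lab_index[g] for g in group])
    ci_ = np.array([lab_index[g] for g in goldv])
    t = lab_index[target_group]
    values = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        cell = np.zeros((k, k))
        np.add.at(cell, (gi[idx], ci_[idx]), w[idx] if weighted else 1.0)
        tp = cell[t, t]
        fp = cell[t, :].sum() - tp
        fn = cell[:, t].sum() - tp
        tn = cell.sum() - tp - fp - fn
        num, den = {
            "sensitivity": (tp, tp + fn),
            "specificity": (tn, tn + fp),
            "ppv": (tp, tp + fp),
            "npv": (tn, tn + fn),
        }[metric]
        values.append(np.nan if den == 0 else num / den)
    values = np.asarray(values, dtype=float)
    n_undef = int(np.isnan(values).sum())
    if n_undef > B / 2:
        raise ValueError(
            f"{metric} undefined in {n_undef}/{B} bootstrap replicates; "
            "increase the sample size"
        )
    valid = values[~np.isnan(values)]
    lo, hi = np.percentile(valid, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
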