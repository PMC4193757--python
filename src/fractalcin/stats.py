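"""Case aggregation, group statistics, classification and confusion matrices.

Patients can contribute several regions of interest; the per-case statistic
is the median of the ROI-level d_BOX values, so each patient counts once.
Group comparisons use one-way ANOVA with Tukey HSD post-hoc tests (four
grades) and a pooled-variance Student t-test (low-grade CIN 1 vs
high-grade CIN 2+3).  Normality is screened with a Kolmogorov-Smirnov test
(Lilliefors-corrected by default, since mean and variance are estimated
from the sample).  Grade prediction uses the nearest group reference
median in absolute d_BOX distance, ties broken toward the less severe
grade; agreement with the pathologist is summarized in a confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .multifractal import MultifractalSpectrum

__all__ = [
    "SEVERITY_ORDER",
    "CaseRecord",
    "GroupSummary",
    "ConfusionMatrix",
    "AnovaTukeyResult",
    "aggregate_case",
    "build_case_record",
    "group_summaries",
    "anova_tukey",
    "two_sample_t",
    "ks_normality",
    "per_q_comparison",
    "classify_case",
    "confusion",
    "low_high_split",
]

#: ordering of labels from least to most severe (used for tie-breaking)
SEVERITY_ORDER = ("normal", "CIN1", "CIN2", "CIN3", "low", "high")


def _severity(label: str) -> int:
    try:
        return SEVERITY_ORDER.index(label)
    except ValueError:
        return len(SEVERITY_ORDER)


def aggregate_case(roi_values: list[float]) -> float:
    """Median over a patient's ROI-level values (one number per case).

    For even n this is the mean of the two central order statistics.
    """
    if len(roi_values) == 0:
        raise ValueError("cannot aggregate an empty list of ROI values")
    return float(np.median(roi_values))


@dataclass
class CaseRecord:
    """One patient: grade label, ROI-level d_BOX values and their median."""

    case_id: str
    grade: str
    roi_dbox: list[float]
    spectrum: MultifractalSpectrum | None = None
    case_dbox: float = field(init=False)

    def __post_init__(self) -> None:
        self.case_dbox = aggregate_case(self.roi_dbox)


def build_case_record(case_id, grade, roi_dbox, spectrum=None) -> CaseRecord:
    return CaseRecord(case_id=case_id, grade=grade, roi_dbox=list(roi_dbox), spectrum=spectrum)


@dataclass
class GroupSummary:
    group: str
    n: int
    median: float
    min: float
    max: float


def low_high_split(cases: list[CaseRecord]) -> dict[str, list[float]]:
    """Map cases to the low/high grouping: CIN1 -> low, CIN2+CIN3 -> high.

    Normal epithelium is excluded from this grouping.
    """
    groups: dict[str, list[float]] = {"low": [], "high": []}
    for c in cases:
        if c.grade == "CIN1":
            groups["low"].append(c.case_dbox)
        elif c.grade in ("CIN2", "CIN3"):
            groups["high"].append(c.case_dbox)
        elif c.grade != "normal":
            raise ValueError(f"unknown grade {c.grade!r} for case {c.case_id!r}")
    return groups


def group_summaries(
    cases: list[CaseRecord], grouping: str = "four_group"
) -> list[GroupSummary]:
    """n/median/min/max per group under the chosen grouping."""
    if grouping == "four_group":
        groups: dict[str, list[float]] = {}
        for c in cases:
            if c.grade not in ("normal", "CIN1", "CIN2", "CIN3"):
                raise ValueError(f"unknown grade {c.grade!r} for case {c.case_id!r}")
            groups.setdefault(c.grade, []).append(c.case_dbox)
    elif grouping == "low_high":
        groups = {k: v for k, v in low_high_split(cases).items() if v}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    out = []
    for g in sorted(groups, key=_severity):
        v = groups[g]
        out.append(GroupSummary(group=g, n=len(v), median=float(np.median(v)),
                                min=float(np.min(v)), max=float(np.max(v))))
    return out


@dataclass
class AnovaTukeyResult:
    anova_p: float
    anova_f: float
    pairwise_p: dict[tuple[str, str], float]

    def p_for(self, a: str, b: str) -> float:
        key = tuple(sorted((a, b)))
        return self.pairwise_p[key]


def anova_tukey(groups: dict[str, list[float]], alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA followed by Tukey HSD pairwise comparisons.

    Unequal group sizes are handled by the Tukey-Kramer form (pairwise
    standard errors from 1/n_i + 1/n_j against the studentized-range
    distribution).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has n < 2")
    labels = sorted(groups)
    f, p = sps.f_oneway(*[groups[g] for g in labels])
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    tags = np.concatenate([[g] * len(groups[g]) for g in labels])
    tk = pairwise_tukeyhsd(values, tags, alpha=alpha)
    pairs = list(combinations([str(g) for g in tk.groupsunique], 2))
    pairwise = {
        tuple(sorted(pair)): float(padj) for pair, padj in zip(pairs, tk.pvalues)
    }
    return AnovaTukeyResult(anova_p=float(p), anova_f=float(f), pairwise_p=pairwise)


def two_sample_t(a: list[float], b: list[float], welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled-variance Student form by default."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    if not np.isfinite(t):
        raise ValueError("degenerate variance in both samples")
    return float(t), float(p)


def ks_normality(values: list[float], lilliefors: bool = True) -> float:
    """Kolmogorov-Smirnov normality p-value with estimated mean/sd.

    ``lilliefors=True`` (default) applies the Lilliefors correction, which
    is required for valid p-values when the parameters are estimated from
    the sample; ``False`` gives the plain (anti-conservative) KS p.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need n >= 4 for a normality test")
    if np.std(v) == 0:
        raise ValueError("degenerate sample (zero standard deviation)")
    if lilliefors:
        _, p = _lilliefors(v, dist="norm")
        return float(p)
    _, p = sps.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    return float(p)


def per_q_comparison(
    table: pd.DataFrame,
    grouping: str = "four_group",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[tuple[str, str], tuple[float, float] | None]]:
    """Per-q group tests on a tidy spectrum table (case_id, label, q, Dq).

    For each q on the shared grid, runs one-way ANOVA across groups plus
    Tukey HSD pairwise comparisons.  Returns the per-q long-form result
    (q, pair, p_adj, p_anova) and, per pair, the maximal contiguous
    q-interval where the adjusted p is below ``alpha`` (None if never
    significant).  No multiple-testing correction is applied across q.
    """
    required = {"case_id", "label", "q", "Dq"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if grouping == "low_high":
        mapping = {"CIN1": "low", "CIN2": "high", "CIN3": "high"}
        table = table[table["label"].isin(mapping)].copy()
        table["label"] = table["label"].map(mapping)
    rows = []
    for q, sub in table.groupby("q", sort=True):
        groups = {lab: g["Dq"].tolist() for lab, g in sub.groupby("label")}
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            raise ValueError(f"q={q}: need >= 2 groups with >= 2 spectra each")
        res = anova_tukey(groups, alpha=alpha)
        for pair, padj in res.pairwise_p.items():
            rows.append({"q": float(q), "pair": pair, "p_adj": padj, "p_anova": res.anova_p})
    per_q = pd.DataFrame(rows)
    intervals: dict[tuple[str, str], tuple[float, float] | None] = {}
    for pair, sub in per_q.groupby("pair"):
        sub = sub.sort_values("q")
        sig = (sub["p_adj"] < alpha).to_numpy()
        qs = sub["q"].to_numpy()
        best = None
        start = None
        for i, s in enumerate(sig):
            if s and start is None:
                start = i
            if (not s or i == len(sig) - 1) and start is not None:
                end = i if s else i - 1
                if best is None or (qs[end] - qs[start]) > (best[1] - best[0]):
                    best = (float(qs[start]), float(qs[end]))
                start = None
        intervals[pair] = best
    return per_q, intervals


def classify_case(case_dbox: float, reference_medians: dict[str, float]) -> str:
    """Predict the grade whose reference median is nearest in |d_BOX|.

    Exact ties go to the less severe grade (normal < CIN1 < CIN2 < CIN3).
    """
    if not reference_medians:
        raise ValueError("empty reference-median map")
    if len(set(reference_medians.values())) != len(reference_medians):
        raise ValueError("reference medians must be distinct")
    best = min(
        reference_medians.items(),
        key=lambda kv: (abs(case_dbox - kv[1]), _severity(kv[0])),
    )
    return best[0]


@dataclass
class ConfusionMatrix:
    """Pathologist (rows) vs predicted (columns) cross-tabulation."""

    labels: list[str]
    counts: np.ndarray
    row_percents: np.ndarray = field(init=False)
    overall_percent: float = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        row_sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.row_percents = np.where(row_sums > 0, 100.0 * self.counts / row_sums, 0.0)
        total = self.counts.sum()
        self.overall_percent = 100.0 * float(np.trace(self.counts)) / total if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def row_percent(self, label: str) -> np.ndarray:
        return self.row_percents[self.labels.index(label)]


def confusion(truth: list[str], predicted: list[str], labels: list[str] | None = None) -> ConfusionMatrix:
    """Build the confusion matrix from paired label sequences.

    ``labels`` fixes the row/column order; by default labels are ordered
    by severity.  Overall agreement is 100 * trace / total.
    """
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted sequences differ in length")
    if labels is None:
        labels = sorted(set(truth) | set(predicted), key=_severity)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(truth, predicted):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(labels=list(labels), counts=counts)
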