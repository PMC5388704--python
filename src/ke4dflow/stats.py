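"""Cohort statistics: Mann–Whitney, Pearson, Cohen's kappa, interobserver
variability and group summary tables.

Group differences between small patient and control samples are assessed
with the Mann–Whitney U test (exact null distribution when samples are
small and tie-free, tie-corrected normal approximation otherwise);
agreement between categorical labelings (ventricular morphology vs KE
pattern) with unweighted Cohen's kappa.  Comparisons between subgroups
below a minimum size are suppressed with a notice instead of a p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError, DegenerateDataError

#: exact Mann–Whitney when min(n) <= this (and data are tie-free) in auto mode
EXACT_MIN_N = 8
EXACT_MAX_PRODUCT = 200

#: below this per-group n, subgroup comparisons are suppressed
MIN_GROUP_N = 5


@dataclass
class StatResult:
    method: str
    statistic: float
    p_value: float
    n1: int
    n2: int = 0
    exact: bool = False
    detail: dict = dc_field(default_factory=dict)


def _as_clean_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    if a.size == 0:
        raise DegenerateDataError(f"empty sample {name}")
    if np.any(np.isnan(a)):
        raise AnalysisError(f"NaN in sample {name}")
    return a


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 mode: str = "auto") -> StatResult:
    """Two-sided Mann–Whitney U test.

    ``mode`` is ``exact`` (full enumeration of the tie-free U null
    distribution; refuses tied data), ``approx`` (normal approximation with
    tie correction and continuity correction), or ``auto`` (exact when the
    samples are small — min(n) <= 8 or n1·n2 <= 200 — and tie-free).
    The two-sided exact p is twice the one-sided tail probability, capped
    at 1.
    """
    xa = _as_clean_array(x, "x")
    ya = _as_clean_array(y, "y")
    if mode not in ("exact", "approx", "auto"):
        raise AnalysisError(f"unknown mode {mode!r}")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    n1, n2 = xa.size, ya.size

    if mode == "exact" and has_ties:
        raise AnalysisError(
            "exact Mann–Whitney is defined here for tie-free data; the "
            "pooled sample contains ties — use mode='approx'"
        )
    if mode == "auto":
        small = min(n1, n2) <= EXACT_MIN_N or n1 * n2 <= EXACT_MAX_PRODUCT
        mode = "exact" if (small and not has_ties) else "approx"

    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return StatResult(method=f"mann_whitney_{mode}", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n1=n1, n2=n2,
                      exact=(mode == "exact"))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson r with the two-sided p from the t transform (n−2 df)."""
    xa = _as_clean_array(x, "x")
    ya = _as_clean_array(y, "y")
    if xa.size != ya.size:
        raise AnalysisError("samples must have equal length")
    if xa.size < 3:
        raise AnalysisError("correlation needs n >= 3")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise DegenerateDataError("zero variance: correlation undefined")
    r, p = sps.pearsonr(xa, ya)
    return StatResult(method="pearson", statistic=float(r), p_value=float(p),
                      n1=xa.size, n2=xa.size, exact=False)


@dataclass
class KappaResult:
    """Chance-corrected agreement between two categorical labelings."""

    kappa: float
    observed_agreement: float
    expected_agreement: float
    n: int


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> KappaResult:
    """Unweighted Cohen's kappa from the cross-tabulation.

    kappa = (po − pe) / (1 − pe) with po the observed and pe the chance
    agreement; kappa = 1 iff agreement is perfect.  Invariant under any
    consistent relabeling of the categories.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise AnalysisError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise DegenerateDataError("empty label vectors")
    n = len(a)
    cats = sorted(set(a) | set(b), key=str)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for ai, bi in zip(a, b):
        table[idx[ai], idx[bi]] += 1
    po = float(np.trace(table) / n)
    pe = float(np.sum(table.sum(axis=1) * table.sum(axis=0)) / n**2)
    kappa = 1.0 if pe == 1.0 and po == 1.0 else (po - pe) / (1.0 - pe)
    return KappaResult(kappa=kappa, observed_agreement=po,
                       expected_agreement=pe, n=n)


def interobserver_variability(a: Sequence[float], b: Sequence[float]
                              ) -> tuple[float, float]:
    """Paired relative difference, mean ± SD in percent.

    Per pair: 100·(a−b)/((a+b)/2).  Antisymmetric in its arguments.
    """
    aa = _as_clean_array(a, "a")
    bb = _as_clean_array(b, "b")
    if aa.size != bb.size:
        raise AnalysisError("paired measurements must have equal length")
    if aa.size < 2:
        raise AnalysisError("need at least 2 pairs")
    means = (aa + bb) / 2.0
    if np.any(means <= 0):
        raise AnalysisError("nonpositive pair mean: relative difference undefined")
    rel = 100.0 * (aa - bb) / means
    return float(rel.mean()), float(rel.std(ddof=1))


@dataclass
class SuppressionNotice:
    """Emitted instead of a p-value when a subgroup is too small to test."""

    reason: str
    n1: int
    n2: int


def compare_groups(x: Sequence[float], y: Sequence[float],
                   min_n: int = MIN_GROUP_N, mode: str = "auto"):
    """Mann–Whitney comparison, suppressed below the minimum group size.

    Returns a :class:`StatResult`, or a :class:`SuppressionNotice` when
    either group has fewer than ``min_n`` members (small subgroups are
    summarized but not tested).
    """
    n1, n2 = len(x), len(y)
    if min(n1, n2) < min_n:
        return SuppressionNotice(
            reason=f"group sizes ({n1}, {n2}) below minimum {min_n}; "
                   "statistical comparison suppressed",
            n1=n1, n2=n2)
    return mann_whitney(x, y, mode=mode)


@dataclass
class SubjectRecord:
    """Per-subject summary feeding the cohort table."""

    subject_id: str
    group: str
    morphology: str
    edvi: Optional[float] = None  # ml/m^2
    esvi: Optional[float] = None
    ef: Optional[float] = None  # %
    co: Optional[float] = None  # l/min
    ci: Optional[float] = None  # l/min/m^2
    peak_systolic_ke_sv: Optional[float] = None  # mJ/ml
    peak_diastolic_ke_sv: Optional[float] = None
    peak_systolic_ke_bsa: Optional[float] = None  # mJ/m^2
    peak_diastolic_ke_bsa: Optional[float] = None
    peak_systolic_ke_ci: Optional[float] = None  # mJ/(l/min/m^2)
    peak_diastolic_ke_ci: Optional[float] = None
    ke_pattern: Optional[str] = None
    plateau: Optional[bool] = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


TABLE_METRICS = [
    "edvi", "esvi", "ef", "co", "ci",
    "peak_systolic_ke_sv", "peak_diastolic_ke_sv",
    "peak_systolic_ke_bsa", "peak_diastolic_ke_bsa",
    "peak_systolic_ke_ci", "peak_diastolic_ke_ci",
]


def cohort_table(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Mean ± SD of every cohort metric per (group, morphology) cell.

    Returns a tidy, CSV-writable frame with one row per group × morphology
    × metric; single-member cells report SD 0 with an ``n`` flag; empty
    cells are simply absent.
    """
    if not records:
        raise DegenerateDataError("no records")
    df = pd.DataFrame([r.to_dict() for r in records])
    rows = []
    for (group, morph), sub in df.groupby(["group", "morphology"], sort=True):
        for metric in TABLE_METRICS:
            vals = sub[metric].dropna()
            if vals.empty:
                continue
            n = len(vals)
            rows.append({
                "group": group, "morphology": morph, "metric": metric,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if n > 1 else 0.0,
                "n": n,
            })
    return pd.DataFrame(rows)
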