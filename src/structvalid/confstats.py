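"""Statistical procedures used across the toolkit.

Welch's unequal-variance t-test compares RMSD/IRDM value groups; Pearson
and Spearman correlations (with t-statistic significance) relate structural
deviation to resolution and prediction confidence to crystallographic
B-factors.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .structio import PAEMatrix, ResidueProfile

__all__ = [
    "TestResult",
    "ScoreCategories",
    "welch_t",
    "pearson",
    "spearman",
    "confidence_vs_flexibility",
    "categorize_scores",
]


@dataclass
class TestResult:
    statistic: float
    p: float
    kind: Literal["welch_t", "pearson_t", "spearman"]
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p={self.p} outside [0,1]")


# pLDDT category thresholds: high >= 98.5, low < 96.0, medium between.
@dataclass
class ScoreCategories:
    high_min: float = 98.5
    low_max: float = 96.0
    assignment: dict = field(default_factory=dict)

    def classify(self, score: float) -> str:
        if score >= self.high_min:
            return "high"
        if score < self.low_max:
            return "low"
        return "medium"


def _as_array(v: Sequence[float], name: str, min_len: int) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or len(arr) < min_len:
        raise ValueError(f"{name}: need a 1-D sample of at least {min_len} values")
    return arr


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t-test (two-sided), with Welch–Satterthwaite df."""
    a = _as_array(a, "a", 2)
    b = _as_array(b, "b", 2)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # identical constant groups: no evidence of difference
            return TestResult(statistic=0.0, p=1.0, kind="welch_t", df=float(len(a) + len(b) - 2))
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), kind="welch_t", df=float(res.df))


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson r with two-sided p from t = r·sqrt((n−2)/(1−r²)) on n−2 df."""
    x = _as_array(x, "x", 3)
    y = _as_array(y, "y", 3)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), kind="pearson_t", df=float(len(x) - 2))


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation (mid-ranks for ties), p via the t approximation."""
    x = _as_array(x, "x", 3)
    y = _as_array(y, "y", 3)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return TestResult(statistic=float(rho), p=float(p), kind="spearman", df=float(len(x) - 2))


def categorize_scores(plddt: ResidueProfile, categories: ScoreCategories | None = None) -> ScoreCategories:
    cats = categories or ScoreCategories()
    cats.assignment = {k: cats.classify(v) for k, v in zip(plddt.keys, plddt.values)}
    return cats


def confidence_vs_flexibility(
    plddt: ResidueProfile,
    bfac: ResidueProfile,
    pae: PAEMatrix | None = None,
    pae_reduction: str = "row_mean",
    categories: ScoreCategories | None = None,
) -> dict:
    """Relate prediction confidence to crystallographic flexibility.

    Computes Spearman ρ between per-residue pLDDT and B-factors on their
    shared residues, assigns each residue a confidence category and
    summarizes B-factors per category, and — when a PAE matrix is supplied —
    the Pearson r between per-residue mean expected position error and the
    B-factor.  The PAE matrix is assumed to cover the predicted model's
    residues in ``plddt.keys`` order.
    """
    p_vals, b_vals = plddt.align_with(bfac)
    if len(p_vals) < 3:
        raise ValueError("fewer than 3 shared residues between pLDDT and B-factor profiles")
    rho = spearman(p_vals, b_vals)

    cats = categorize_scores(plddt, categories)
    shared = [k for k in plddt.keys if k in set(bfac.keys)]
    b_map = dict(zip(bfac.keys, bfac.values))
    per_cat: dict[str, dict] = {}
    for cat in ("high", "medium", "low"):
        members = [b_map[k] for k in shared if cats.assignment[k] == cat]
        per_cat[cat] = {
            "n": len(members),
            "mean_b": float(np.mean(members)) if members else float("nan"),
            "median_b": float(np.median(members)) if members else float("nan"),
        }

    report = {
        "spearman_plddt_vs_b": rho,
        "n_shared": len(p_vals),
        "categories": cats,
        "per_category_b": per_cat,
    }

    if pae is not None:
        if pae.n != len(plddt):
            raise ValueError(f"PAE size {pae.n} != predicted model length {len(plddt)}")
        per_res_pae = ResidueProfile(list(plddt.keys), pae.per_residue(pae_reduction), label="pae")
        pae_vals, b_vals2 = per_res_pae.align_with(bfac)
        report["pearson_pae_vs_b"] = pearson(pae_vals, b_vals2)
        report["pae_reduction"] = pae_reduction
    return report
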