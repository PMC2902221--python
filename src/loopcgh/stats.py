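"""Scalar statistical tests: exact binomial, Wilcoxon rank-sum, dN/dS by class.

The binomial test is exact (minimum-likelihood two-sided convention, no
normal approximation). The rank-sum test uses midranks, an exact
enumeration null for small samples and a tie- and continuity-corrected
normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import AnalysisError, InvalidArgumentError

EXACT_WILCOXON_MAX_N = 20

DNDS_CLASSES = ("duplication", "deletion", "none")


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    sidedness: str
    n: tuple[int, ...]
    flagged: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not (self.p_value != self.p_value or 0 <= self.p_value <= 1):
            raise InvalidArgumentError("p-value outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "sidedness": self.sidedness,
            "n": list(self.n),
            "flagged": self.flagged,
            "note": self.note,
        }


def exact_binomial(
    k: int, n: int, p0: float = 0.5, sidedness: str = "two-sided"
) -> TestResult:
    """Exact binomial test.

    Two-sided p sums the probabilities of all outcomes no more likely than
    the observed one (the minimum-likelihood convention, as in R's
    ``binom.test``), with a small relative tolerance to absorb floating
    error at the likelihood boundary.
    """
    if not 0 <= k <= n or n < 1:
        raise InvalidArgumentError(f"need 0 <= k <= n with n >= 1, got k={k} n={n}")
    if not 0 < p0 < 1:
        raise InvalidArgumentError("p0 must be in (0, 1)")
    outcomes = np.arange(n + 1)
    pmf = sps.binom.pmf(outcomes, n, p0)
    if sidedness == "greater":
        p = float(pmf[k:].sum())
    elif sidedness == "less":
        p = float(pmf[: k + 1].sum())
    elif sidedness == "two-sided":
        p = float(pmf[pmf <= pmf[k] * (1 + 1e-7)].sum())
    else:
        raise InvalidArgumentError(f"unknown sidedness {sidedness!r}")
    return TestResult(
        name="exact_binomial",
        statistic=float(k),
        p_value=min(1.0, p),
        sidedness=sidedness,
        n=(n,),
    )


def _exact_rank_sum_p(
    ranks: np.ndarray, nx: int, r_obs: float
) -> tuple[float, float]:
    """(P(R <= r_obs), P(R >= r_obs)) by enumeration of all selections."""
    total = comb(len(ranks), nx)
    le = ge = 0
    eps = 1e-9
    for idx in combinations(range(len(ranks)), nx):
        r = ranks[list(idx)].sum()
        if r <= r_obs + eps:
            le += 1
        if r >= r_obs - eps:
            ge += 1
    return le / total, ge / total


def wilcoxon_rank_sum(x, y, sidedness: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum test with midrank ties.

    Exact enumeration null when the combined sample size is <= 20;
    otherwise a normal approximation with continuity correction and the
    standard tie correction of the variance. Two-sided p doubles the
    smaller tail (capped at 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InvalidArgumentError("both samples must be non-empty")
    if sidedness not in ("two-sided", "greater", "less"):
        raise InvalidArgumentError(f"unknown sidedness {sidedness!r}")
    nx, ny = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r_obs = float(ranks[:nx].sum())

    if nx + ny <= EXACT_WILCOXON_MAX_N:
        p_le, p_ge = _exact_rank_sum_p(ranks, nx, r_obs)
    else:
        mu = nx * (ny + nx + 1) / 2.0
        n = nx + ny
        _, counts = np.unique(combined, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / ((n) * (n - 1))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        sd = sqrt(max(var, 1e-300))
        p_ge = float(sps.norm.sf((r_obs - mu - 0.5) / sd))
        p_le = float(sps.norm.cdf((r_obs - mu + 0.5) / sd))
    if sidedness == "greater":
        p = p_ge
    elif sidedness == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return TestResult(
        name="wilcoxon_rank_sum",
        statistic=r_obs,
        p_value=p,
        sidedness=sidedness,
        n=(nx, ny),
    )


def dnds_by_class(
    table: pd.DataFrame,
    summary: str = "median",
    sidedness: str = "two-sided",
) -> dict:
    """Per-class dN/dS summary and rank-sum tests of each CNV class vs none.

    ``table`` columns: gene_id, dn, ds, cnv_class (duplication / deletion /
    none). Genes with ds == 0 are excluded from per-gene ratios; classes
    with a single usable gene are reported but flagged as degenerate.
    ``summary`` selects median (default), mean, or ratio_of_sums.
    """
    required = {"gene_id", "dn", "ds", "cnv_class"}
    if not required <= set(table.columns):
        raise InvalidArgumentError(f"gene table needs columns {sorted(required)}")
    if summary not in ("median", "mean", "ratio_of_sums"):
        raise InvalidArgumentError(f"unknown summary {summary!r}")
    bad = set(table["cnv_class"]) - set(DNDS_CLASSES)
    if bad:
        raise InvalidArgumentError(f"unknown CNV classes: {sorted(bad)}")
    if (table["dn"] < 0).any() or (table["ds"] < 0).any():
        raise InvalidArgumentError("dn and ds must be non-negative")

    ratios: dict[str, np.ndarray] = {}
    summaries: dict[str, float] = {}
    for cls in DNDS_CLASSES:
        sub = table[table["cnv_class"] == cls]
        if len(sub) == 0:
            raise AnalysisError(f"class {cls!r} has no genes")
        usable = sub[sub["ds"] > 0]
        if len(usable) == 0:
            raise AnalysisError(f"class {cls!r} has no genes with ds > 0")
        r = (usable["dn"] / usable["ds"]).to_numpy()
        ratios[cls] = r
        if summary == "median":
            summaries[cls] = float(np.median(r))
        elif summary == "mean":
            summaries[cls] = float(np.mean(r))
        else:
            summaries[cls] = float(usable["dn"].sum() / usable["ds"].sum())

    tests: dict[str, TestResult] = {}
    for cls in ("duplication", "deletion"):
        degenerate = min(len(ratios[cls]), len(ratios["none"])) < 2
        result = wilcoxon_rank_sum(ratios[cls], ratios["none"], sidedness)
        if degenerate:
            result = TestResult(
                name=result.name,
                statistic=result.statistic,
                p_value=result.p_value,
                sidedness=result.sidedness,
                n=result.n,
                flagged=True,
                note="degenerate sample size",
            )
        tests[cls] = result
    return {
        "summary": summary,
        "dnds": summaries,
        "n_genes": {cls: int(len(ratios[cls])) for cls in DNDS_CLASSES},
        "tests": tests,
    }
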