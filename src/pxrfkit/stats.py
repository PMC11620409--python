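"""Statistical battery for the variation tests.

Three families:

* per-element **median quantile regression** on a binary factor — the tau=0.5
  check-loss fit, which for a two-level design equals the pair of group
  medians — with exact-style permutation inference on the median difference;
* an **overall multi-response test**: one Gaussian linear model per element
  on transformed concentrations, per-element likelihood-ratio statistics
  n*ln(RSS0/RSS1) summed across elements, significance by joint permutation
  of rows (Freedman-Lane under an intercept-only null);
* **replicate precision** via Spearman's rank correlation between duplicate
  scans, pooled and per element.

All resampling is driven by explicit seeds; p-values use the tie-inclusive
(1 + exceedances) / (n_perm + 1) convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "PrecisionResult",
    "median_regression_binary",
    "median_permutation_test",
    "pairwise_comparisons",
    "manyglm_overall",
    "replicate_precision",
    "bh_adjust",
    "summarize_study",
]

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    """One statistical comparison (a row of the study summary)."""

    factor: str  # state | scan_time | location
    comparison: str  # e.g. "leg vs tail"
    scope: str  # element symbol or "overall"
    estimate: float  # median difference (per-element) or sum-of-LR (overall)
    statistic: float
    p_value: float
    p_adjusted: float = float("nan")
    n_per_group: tuple = ()
    method: str = ""
    taxon: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class PrecisionResult:
    scope: str  # element symbol or "overall"
    rho: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("need at least 2 pairs")
        if not -1.0000001 <= self.rho <= 1.0000001:
            raise ValueError("rho outside [-1, 1]")


def _two_groups(y, g):
    y = np.asarray(y, dtype=float)
    g = np.asarray(g)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"factor must have exactly 2 levels, got {len(levels)}")
    y1, y2 = y[g == levels[0]], y[g == levels[1]]
    y1, y2 = y1[np.isfinite(y1)], y2[np.isfinite(y2)]
    return levels, y1, y2


def median_regression_binary(y, g):
    """tau=0.5 quantile regression on a binary factor.

    Minimises the check loss sum(|y - (b0 + b1*[g = level2])|)/2; the
    solution is (median(level1), median(level2) - median(level1)), with the
    median of an even-sized group the midpoint of its central order
    statistics.  Returns (intercept, slope).
    """
    _, y1, y2 = _two_groups(y, g)
    if y1.size == 0 or y2.size == 0:
        raise ValueError("each level needs at least one finite observation")
    m1, m2 = float(np.median(y1)), float(np.median(y2))
    return m1, m2 - m1


class ComparisonSkipped(Exception):
    """Raised when a comparison lacks the observations to run."""


def median_permutation_test(
    y, g, n_perm: int = 999, seed: int = 0,
    factor: str = "", comparison: str = "", scope: str = "", taxon: str = "",
) -> TestResult:
    """Permutation test on the absolute median difference between two groups.

    p = (1 + #{permuted >= observed}) / (n_perm + 1); deterministic given
    (data, n_perm, seed).  Raises ComparisonSkipped when either group has
    fewer than 3 finite observations.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    levels, y1, y2 = _two_groups(y, g)
    if y1.size < 3 or y2.size < 3:
        raise ComparisonSkipped(
            f"{scope or 'comparison'}: needs >= 3 finite observations per level "
            f"(got {y1.size}, {y2.size})"
        )
    pooled = np.concatenate([y1, y2])
    n1 = y1.size
    intercept, slope = median_regression_binary(
        pooled, np.repeat([0, 1], [n1, y2.size])
    )
    observed = abs(slope)

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    permuted = pooled[order]
    stat = np.abs(
        np.median(permuted[:, :n1], axis=1) - np.median(permuted[:, n1:], axis=1)
    )
    p = (1.0 + np.sum(stat >= observed - 1e-12)) / (n_perm + 1.0)
    return TestResult(
        factor=factor,
        comparison=comparison or f"{levels[0]} vs {levels[1]}",
        scope=scope,
        estimate=slope,
        statistic=observed,
        p_value=float(p),
        n_per_group=(int(n1), int(y2.size)),
        method=f"median permutation ({n_perm} perms, seed {seed})",
        taxon=taxon,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def pairwise_comparisons(
    y, g, n_perm: int = 999, seed: int = 0,
    factor: str = "", scope: str = "", taxon: str = "",
) -> list[TestResult]:
    """One median permutation test per unordered level pair, BH-adjusted
    within the family of k(k-1)/2 comparisons.  Skipped pairs are logged."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g)
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("factor must have >= 2 levels")
    results: list[TestResult] = []
    for i, (a, b) in enumerate(combinations(levels, 2)):
        mask = (g == a) | (g == b)
        try:
            results.append(
                median_permutation_test(
                    y[mask], g[mask], n_perm=n_perm, seed=seed + i,
                    factor=factor, comparison=f"{a} vs {b}", scope=scope, taxon=taxon,
                )
            )
        except ComparisonSkipped as exc:
            logger.info("skipping %s %s vs %s: %s", factor, a, b, exc)
    if results:
        adjusted = bh_adjust([r.p_value for r in results])
        for r, pa in zip(results, adjusted):
            r.p_adjusted = float(pa)
    return results


def _sum_of_lr(X: np.ndarray, codes: np.ndarray, k: int) -> float:
    """Sum over columns of n*ln(RSS0/RSS1) for a k-level one-way design."""
    n = X.shape[0]
    grand = X.mean(axis=0)
    rss0 = ((X - grand) ** 2).sum(axis=0)
    rss1 = np.zeros_like(rss0)
    for level in range(k):
        block = X[codes == level]
        rss1 += ((block - block.mean(axis=0)) ** 2).sum(axis=0)
    return float(np.sum(n * np.log(rss0 / rss1)))


def manyglm_overall(
    Y, g, transform: str = "log", n_perm: int = 999, seed: int = 0,
    factor: str = "", comparison: str = "", taxon: str = "",
) -> TestResult:
    """Overall multi-response test: sum of per-element LR statistics.

    Per element j, Gaussian linear models are fitted on transformed values
    under the null (intercept only) and alternative (one-way factor)
    designs; LR_j = n * ln(RSS0_j / RSS1_j).  The overall statistic is
    sum_j LR_j, its p-value obtained by jointly permuting rows of the
    response matrix (Freedman-Lane under the intercept-only null).

    transform: "log" (log(x + delta), delta = half the smallest positive
    value) or "none".
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be an n x p matrix")
    g = np.asarray(g)
    levels = pd.unique(g)
    k = len(levels)
    if k < 2:
        raise ValueError("factor must have >= 2 levels")
    codes = np.searchsorted(np.sort(levels.astype(str)), g.astype(str))
    counts = np.bincount(codes, minlength=k)
    if counts.min() < 2:
        raise ValueError("each level needs n >= 2")

    if transform == "log":
        positive = Y[np.isfinite(Y) & (Y > 0)]
        if positive.size == 0:
            raise ValueError("no positive values to log-transform")
        delta = 0.5 * positive.min()
        X = np.log(Y + delta)
    elif transform == "none":
        X = Y.copy()
    else:
        raise ValueError(f"unknown transform {transform!r}")

    # drop degenerate columns
    keep = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if not np.all(np.isfinite(col)) or np.var(col) == 0:
            logger.warning("dropping column %d (non-finite or zero variance)", j)
            continue
        rss1 = sum(
            float(((col[codes == lv] - col[codes == lv].mean()) ** 2).sum())
            for lv in range(k)
        )
        if rss1 == 0:
            logger.warning("dropping column %d (perfect within-group fit)", j)
            continue
        keep.append(j)
    if not keep:
        raise ValueError("all response columns were dropped")
    X = X[:, keep]

    observed = _sum_of_lr(X, codes, k)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _sum_of_lr(X[perm], codes, k) >= observed - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return TestResult(
        factor=factor,
        comparison=comparison or " vs ".join(str(l) for l in levels),
        scope="overall",
        estimate=observed,
        statistic=observed,
        p_value=float(p),
        n_per_group=tuple(int(c) for c in counts),
        method=f"sum-of-LR Gaussian manyglm, transform={transform} "
               f"({n_perm} perms, seed {seed})",
        taxon=taxon,
    )


_PAIR_KEYS = ["specimen_id", "taxon", "location", "state", "dwell_time_s", "backed", "element"]


def replicate_precision(table: pd.DataFrame, value_col: str = "concentration_pct"):
    """Spearman correlation between duplicate scans.

    `table` is the long concentration table with a `replicate` column.
    Pairs are matched on all metadata except replicate; below-LOD /
    missing values drop the pair.  Returns a list of PrecisionResult with
    the pooled "overall" coefficient first, then one per element (elements
    with < 2 complete pairs are skipped).  Spearman uses mid-ranks for ties.
    """
    reps = sorted(table["replicate"].unique())
    if len(reps) < 2:
        raise ValueError("need scans from at least 2 replicates")
    r1, r2 = reps[:2]
    keys = [k for k in _PAIR_KEYS if k in table.columns]
    wide = (
        table[table["replicate"].isin([r1, r2])]
        .pivot_table(index=keys, columns="replicate", values=value_col, observed=True)
        .dropna()
    )
    if wide.empty:
        raise ValueError("no complete replicate pairs")
    x, y = wide[r1].to_numpy(), wide[r2].to_numpy()
    results = [PrecisionResult("overall", float(spearmanr(x, y).statistic), len(wide))]
    element_level = wide.index.get_level_values("element")
    for element in pd.unique(element_level):
        sub = wide[element_level == element]
        if len(sub) < 2:
            continue
        rho = spearmanr(sub[r1], sub[r2]).statistic
        if np.isnan(rho):  # constant input
            continue
        results.append(PrecisionResult(str(element), float(rho), len(sub)))
    return results


def summarize_study(
    results: Sequence[TestResult],
    verdicts: pd.DataFrame | None = None,
    precision: Sequence[PrecisionResult] = (),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Taxon x test summary matrix (the study's at-a-glance result grid).

    A factor cell is "significant" when any overall comparison for that
    taxon has p < alpha (strict), "ns" otherwise, blank when untested.
    Thickness cells report "met" / "not met" from the QC verdicts; the
    precision cell carries the pooled Spearman rho.
    """
    if not results and (verdicts is None or verdicts.empty) and not precision:
        raise ValueError("nothing to summarise")
    taxa = sorted(
        {r.taxon for r in results if r.taxon}
        | (set(verdicts["taxon"].unique()) if verdicts is not None and "taxon" in verdicts else set())
    )
    factors = ("state", "scan_time", "location")
    rows = []
    for taxon in taxa:
        row: dict = {"taxon": taxon}
        for fac in factors:
            overall = [
                r for r in results
                if r.taxon == taxon and r.factor == fac and r.scope == "overall"
            ]
            if not overall:
                row[fac] = ""
            else:
                row[fac] = "significant" if any(r.p_value < alpha for r in overall) else "ns"
            per_el = [
                r for r in results
                if r.taxon == taxon and r.factor == fac and r.scope not in ("", "overall")
            ]
            row[f"{fac}_n_sig_elements"] = sum(r.p_value < alpha for r in per_el)
        if verdicts is not None and "taxon" in verdicts.columns:
            v = verdicts[verdicts["taxon"] == taxon]
            if len(v):
                row["infinite_thickness"] = "met" if v["met"].all() else "not met"
            else:
                row["infinite_thickness"] = ""
        rows.append(row)
    out = pd.DataFrame(rows)
    overall_rho = next((p.rho for p in precision if p.scope == "overall"), None)
    if overall_rho is not None:
        out["replicate_spearman"] = round(overall_rho, 3)
    return out
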