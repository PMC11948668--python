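"""Nonparametric tests and distribution summaries.

Self-contained implementations of the two-sample Kolmogorov–Smirnov test,
the Mann–Whitney U test, and Kruskal–Wallis one-way ANOVA on ranks with
Dunn's pairwise post-hoc.  Only low-level distribution primitives (normal
CDF, chi-square survival function) come from scipy.

Method conventions
------------------
KS : D = sup |ECDF_x - ECDF_y| over the pooled data points, two-sided.
     Exact p by integer lattice-path counting over the null distribution of
     D (valid without ties; refused and replaced by the asymptotic value,
     with a flag, when ties are present).  The asymptotic p uses the
     Kolmogorov series with the small-sample effective-n correction
     lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D.
MW : U statistic of the first sample via midranks.  Exact two-sided p by
     enumeration of rank assignments when n1 + n2 <= 12 and there are no
     ties; otherwise the normal approximation with tie and continuity
     corrections.  Two-sided p is the probability of |U - n1 n2 / 2| at
     least as extreme as observed.
KW : H with tie correction; p from chi-square with k - 1 df; all pooled
     values identical gives H = 0, p = 1 by convention.  Pairwise
     comparisons are Dunn z-tests on pooled midranks with Bonferroni
     adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import chi2

from .errors import InputError

__all__ = [
    "TestResult",
    "ks_2samp",
    "mann_whitney",
    "kruskal_wallis",
    "summarize_distribution",
    "DistributionSummary",
]


@dataclass
class TestResult:
    """Statistic + p-value + method metadata for one comparison."""

    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    tie_correction: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")

    def to_dict(self) -> dict:
        d = {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": list(self.n),
            "method": self.method,
            "tie_correction": self.tie_correction,
        }
        d.update({k: v for k, v in self.extras.items() if not isinstance(v, pd.DataFrame)})
        return d


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..N with ties sharing their average (mid) rank."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sa = pooled[order]
    i = 0
    while i < len(sa):
        j = i
        while j + 1 < len(sa) and sa[j + 1] == sa[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_counts(pooled: np.ndarray) -> np.ndarray:
    _, counts = np.unique(pooled, return_counts=True)
    return counts


def _validate_sample(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float).reshape(-1)
    if arr.size == 0:
        raise InputError(f"sample {name} is empty")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"sample {name} contains non-finite values")
    return arr


# ---------------------------------------------------------------------------
# Kolmogorov–Smirnov
# ---------------------------------------------------------------------------


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    xs, ys = np.sort(x), np.sort(y)
    pooled = np.concatenate([xs, ys])
    cdf_x = np.searchsorted(xs, pooled, side="right") / len(xs)
    cdf_y = np.searchsorted(ys, pooled, side="right") / len(ys)
    return float(np.max(np.abs(cdf_x - cdf_y)))


def _ks_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """P(D >= D_obs) under the permutation null, by lattice-path counting.

    Works in integer units h = |i*n2 - j*n1| so the boundary comparison is
    exact.  Counts the interleavings whose path stays strictly below the
    observed deviation; p = 1 - that fraction.
    """
    n1, n2 = len(x), len(y)
    xs, ys = np.sort(x), np.sort(y)
    # observed path in integer units (no ties: merge order is unambiguous)
    i = j = 0
    h_obs = 0
    while i < n1 or j < n2:
        if j >= n2 or (i < n1 and xs[i] < ys[j]):
            i += 1
        else:
            j += 1
        h_obs = max(h_obs, abs(i * n2 - j * n1))
    # DP over the (i, j) lattice; float64 counts (relative error ~1e-13).
    # For each row i the admissible j form a contiguous window
    # (i*n2 - h)/n1 < j < (i*n2 + h)/n1, so each row is a windowed cumsum.
    prev = np.zeros(n2 + 1)
    prev[0] = 1.0  # virtual row: unit mass enters at (0, 0)
    for ii in range(0, n1 + 1):
        jlo = max(0, (ii * n2 - h_obs) // n1 + 1)
        jhi = min(n2, (ii * n2 + h_obs - 1) // n1)
        cur = np.zeros(n2 + 1)
        if jlo <= jhi:
            cur[jlo : jhi + 1] = np.cumsum(prev[jlo : jhi + 1])
        prev = cur
    total = math.comb(n1 + n2, n1)
    p = 1.0 - prev[n2] / total
    return float(min(max(p, 0.0), 1.0))


def _ks_asymptotic_p(d: float, n1: int, n2: int) -> float:
    ne = n1 * n2 / (n1 + n2)
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * d
    if lam < 1e-9:
        return 1.0
    s = 0.0
    for k in range(1, 101):
        term = 2.0 * (-1) ** (k - 1) * math.exp(-2.0 * k * k * lam * lam)
        s += term
        if abs(term) < 1e-16:
            break
    return float(min(max(s, 0.0), 1.0))


def ks_2samp(x, y, method: str = "auto") -> TestResult:
    """Two-sample two-sided Kolmogorov–Smirnov test.

    ``method``: ``exact`` (n1*n2 <= 10^4 and no ties), ``asymptotic``
    (corrected series), or ``auto`` (exact when admissible).  Ties always
    force the asymptotic p and set ``tie_correction``.
    """
    x = _validate_sample(x, "x")
    y = _validate_sample(y, "y")
    if method not in ("auto", "exact", "asymptotic", "asymptotic_corrected"):
        raise ValueError(f"unknown method {method!r}")
    n1, n2 = len(x), len(y)
    d = _ks_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2
    want_exact = method == "exact" or (method == "auto" and n1 * n2 <= 10_000)
    if method == "exact" and n1 * n2 > 10_000:
        raise ValueError("exact KS p restricted to n1*n2 <= 10^4")
    if want_exact and not has_ties:
        p = _ks_exact_p(x, y)
        used = "exact"
    else:
        p = _ks_asymptotic_p(d, n1, n2)
        used = "asymptotic_corrected"
    return TestResult(
        test="ks_2samp",
        statistic=d,
        p_value=p,
        n=(n1, n2),
        method=used,
        tie_correction=has_ties,
    )


# ---------------------------------------------------------------------------
# Mann–Whitney
# ---------------------------------------------------------------------------


def _mw_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p over all rank assignments (no ties, small n)."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = _midranks(np.concatenate([x, y]))
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    base = np.arange(1, n + 1)
    for pos in combinations(range(n), n1):
        u = float(base[list(pos)].sum() - n1 * (n1 + 1) / 2)
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def mann_whitney(x, y, method: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U test; statistic is U of the first sample.

    Exact enumeration when ``n1 + n2 <= 12`` and the pooled sample is
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.  Group medians are reported in ``extras``.
    """
    x = _validate_sample(x, "x")
    y = _validate_sample(y, "y")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u1 = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2)
    has_ties = len(np.unique(pooled)) < n1 + n2
    small = n1 + n2 <= 12
    if method == "exact" and (has_ties or not small):
        raise ValueError("exact MW p requires n1+n2 <= 12 and no ties")
    if (method == "exact") or (method == "auto" and small and not has_ties):
        p = _mw_exact_p(x, y)
        used = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        tie_term = sum(t**3 - t for t in _tie_counts(pooled))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            diff = u1 - mu
            z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var) if diff != 0 else 0.0
            p = float(min(1.0, 2.0 * ndtr(-abs(z))))
        used = "asymptotic"
    return TestResult(
        test="mann_whitney",
        statistic=u1,
        p_value=p,
        n=(n1, n2),
        method=used,
        tie_correction=has_ties,
        extras={"median_x": float(np.median(x)), "median_y": float(np.median(y))},
    )


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Dunn
# ---------------------------------------------------------------------------


def kruskal_wallis(groups, pairwise: bool = False) -> TestResult:
    """Kruskal–Wallis H test across >= 2 groups, with optional Dunn post-hoc.

    When ``pairwise`` is set, ``extras['pairwise']`` holds a DataFrame of
    Dunn z-tests on pooled midranks with Bonferroni-adjusted p-values.
    """
    groups = [np.asarray(g, dtype=float).reshape(-1) for g in groups]
    if len(groups) < 2:
        raise InputError("Kruskal-Wallis needs at least two groups")
    for gi, g in enumerate(groups):
        if g.size == 0:
            raise InputError(f"group {gi} is empty")
        if not np.all(np.isfinite(g)):
            raise InputError(f"group {gi} contains non-finite values")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _midranks(pooled)
    edges = np.cumsum([0] + sizes)
    group_ranks = [ranks[edges[i] : edges[i + 1]] for i in range(len(groups))]
    mean_rank = (n + 1) / 2.0
    h = 12.0 / (n * (n + 1)) * sum(
        ni * (gr.mean() - mean_rank) ** 2 for ni, gr in zip(sizes, group_ranks)
    )
    tie_counts = _tie_counts(pooled)
    tie_term = float(sum(t**3 - t for t in tie_counts))
    denom = 1.0 - tie_term / (n**3 - n)
    has_ties = tie_term > 0
    if denom <= 0:
        # all pooled values identical
        h_corr, p = 0.0, 1.0
    else:
        h_corr = h / denom
        p = float(chi2.sf(h_corr, len(groups) - 1))
    extras: dict = {"medians": [float(np.median(g)) for g in groups]}
    if pairwise:
        m = len(groups) * (len(groups) - 1) // 2
        var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
        rows = []
        for i, j in combinations(range(len(groups)), 2):
            se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (group_ranks[i].mean() - group_ranks[j].mean()) / se if se > 0 else 0.0
            p_un = float(2.0 * ndtr(-abs(z)))
            rows.append(
                {
                    "group_i": i,
                    "group_j": j,
                    "z": z,
                    "p_unadjusted": p_un,
                    "p_bonferroni": min(1.0, p_un * m),
                }
            )
        extras["pairwise"] = pd.DataFrame(rows)
    return TestResult(
        test="kruskal_wallis",
        statistic=float(h_corr),
        p_value=p,
        n=tuple(sizes),
        method="asymptotic",
        tie_correction=has_ties,
        extras=extras,
    )


# ---------------------------------------------------------------------------
# Distribution summaries
# ---------------------------------------------------------------------------


@dataclass
class DistributionSummary:
    counts: np.ndarray
    bin_edges: np.ndarray
    median: float
    n: int
    fitted_peaks: list[tuple[float, float, float]] = field(default_factory=list)
    truncated_at: float | None = None


def summarize_distribution(
    values,
    bins=30,
    fit_peaks: bool = False,
    max_components: int = 5,
    truncate_at: float | None = None,
) -> DistributionSummary:
    """Histogram + median (+ optional multimodal Gaussian fit) of a sample.

    ``truncate_at`` reproduces the display convention for nanoblock areas
    (cut off at 3,500 nm^2): values above the cutoff are excluded from the
    *histogram and fit only* — the median always uses all values.
    """
    vals = _validate_sample(values, "values")
    shown = vals if truncate_at is None else vals[vals <= truncate_at]
    if shown.size == 0:
        counts, edges = np.array([]), np.array([])
    else:
        counts, edges = np.histogram(shown, bins=bins)
    peaks: list[tuple[float, float, float]] = []
    if fit_peaks and shown.size > 0 and len(counts) >= 8:
        from .slab import fit_gaussian_peaks

        centers = 0.5 * (edges[:-1] + edges[1:])
        peaks, _ = fit_gaussian_peaks(centers, counts.astype(float), max_components)
    return DistributionSummary(
        counts=counts,
        bin_edges=edges,
        median=float(np.median(vals)),
        n=len(vals),
        fitted_peaks=peaks,
        truncated_at=truncate_at,
    )
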