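"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths (and where possible the libraries)
they are checking: the OLS here is the explicit normal-equation solution,
the quartiles are computed from a sorted list by hand, and the
hypergeometric tail is exhaustive enumeration over all draws.
"""

from __future__ import annotations

from itertools import combinations


def brute_ols(x: list[float], y: list[float]) -> tuple[float, float]:
    """Slope and intercept from the normal equations, no numpy."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    return slope, intercept


def brute_quartile(values: list[float], p: float) -> float:
    """Linear interpolation at fractional order-statistic position p*(n-1)."""
    s = sorted(values)
    pos = p * (len(s) - 1)
    lo = int(pos)
    frac = pos - lo
    if lo + 1 < len(s):
        return s[lo] + frac * (s[lo + 1] - s[lo])
    return s[lo]


def brute_outliers(
    genes: list[str], x: list[float], y: list[float]
) -> tuple[list[str], list[str]]:
    """Full re-derivation of the directional outlier calls."""
    slope, intercept = brute_ols(x, y)
    residuals = [yy - (slope * xx + intercept) for xx, yy in zip(x, y)]
    q1 = brute_quartile(residuals, 0.25)
    q3 = brute_quartile(residuals, 0.75)
    d = q3 - q1
    upper = q3 + 6.0 * d
    lower = q1 - 6.0 * d
    case = sorted(g for g, r in zip(genes, residuals) if r > upper)
    control = sorted(g for g, r in zip(genes, residuals) if r < lower)
    return case, control


def enumerate_hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by enumerating every size-n draw from a size-N universe."""
    hits = 0
    total = 0
    members = set(range(K))
    for draw in combinations(range(N), n):
        total += 1
        if len(members.intersection(draw)) >= k:
            hits += 1
    return hits / total


def enumerate_overlap_distribution(N: int, K: int, n: int) -> list[int]:
    """Count of draws by overlap size; index = overlap."""
    counts = [0] * (min(K, n) + 1)
    for draw in combinations(range(N), n):
        overlap = sum(1 for g in draw if g < K)
        counts[overlap] += 1
    return counts


def brute_bh(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, by the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end  # 1-based rank of this p-value
        val = min(1.0, pvals[idx] * m / rank)
        running_min = min(running_min, val)
        adjusted[idx] = running_min
    return adjusted
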