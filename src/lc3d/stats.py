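"""Reproducibility and group-comparison statistics.

Covers the measurement study's statistical toolkit: coefficient of variation
for intrasession reproducibility, Kruskal-Wallis with the Steel-Dwass
all-pairs follow-up for three-group comparison, chi-square independence for
sex ratios, Spearman correlation and its first-order (age-corrected) partial,
and ROC analysis with the Youden-index cutoff.

Steel-Dwass is implemented here (pairwise tie-corrected Wilcoxon rank-sum
statistics referred to the studentized-range distribution, ``q = z * sqrt(2)``
convention), with an exhaustive/Monte-Carlo permutation mode for small
samples; the remaining procedures delegate to scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "coefficient_of_variation",
    "kruskal_wallis",
    "steel_dwass",
    "chi_square_independence",
    "spearman",
    "partial_spearman",
    "roc_youden",
    "ROCResult",
]


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * sample SD (n-1 denominator) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 repeated measurements")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV is undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square (k-1 df) p value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def _pair_z(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected standardized rank-sum statistic for one pair."""
    n1, n2 = len(a), len(b)
    n = n1 + n2
    ranks = sps.rankdata(np.concatenate([a, b]))
    w = ranks[:n1].sum()
    e = n1 * (n + 1) / 2.0
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    v = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if v <= 0:
        return 0.0
    return float((w - e) / math.sqrt(v))


def _pairwise_z_stats(groups):
    return {
        (i, j): _pair_z(groups[i], groups[j])
        for i, j in itertools.combinations(range(len(groups)), 2)
    }


def _enumerate_partitions(n_total, sizes):
    """All ways to split range(n_total) into ordered groups of the given sizes."""
    def rec(remaining, sizes):
        if len(sizes) == 1:
            yield (tuple(remaining),)
            return
        for combo in itertools.combinations(remaining, sizes[0]):
            rest = [x for x in remaining if x not in set(combo)]
            for tail in rec(rest, sizes[1:]):
                yield (combo,) + tail
    return rec(list(range(n_total)), sizes)


def _n_partitions(sizes) -> int:
    total = sum(sizes)
    out = 1
    for s in sizes:
        out *= math.comb(total, s)
        total -= s
    return out


def steel_dwass(
    groups,
    method: str = "asymptotic",
    n_resamples: int = 20000,
    seed: int | None = 0,
) -> dict[tuple[int, int], tuple[float, float]]:
    """All-pairs Steel-Dwass comparison after Kruskal-Wallis.

    Returns ``{(i, j): (z, p)}`` for every group pair.  ``method``:

    - ``"asymptotic"``: p = P(Q >= |z| * sqrt(2)) under the studentized-range
      distribution with k groups and infinite df (mid-rank tie correction in
      z).
    - ``"permutation"``: single-step max-|z| permutation adjustment —
      exhaustive over all group relabelings when feasible (<= ~200k
      arrangements), Monte-Carlo otherwise.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError("Steel-Dwass needs >= 3 groups; use a two-group rank-sum test")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs >= 2 observations")

    observed = _pairwise_z_stats(groups)
    if method == "asymptotic":
        return {
            pair: (z, float(sps.studentized_range.sf(abs(z) * math.sqrt(2), k, np.inf)))
            for pair, z in observed.items()
        }
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    offs = np.cumsum([0] + sizes)

    exhaustive = _n_partitions(sizes) <= 200_000
    if exhaustive:
        assign = np.array(
            [np.concatenate(p) for p in _enumerate_partitions(len(pooled), sizes)],
            dtype=np.intp,
        )
    else:
        rng = np.random.default_rng(seed)
        assign = np.array([rng.permutation(len(pooled)) for _ in range(n_resamples)])

    maxes = np.zeros(len(assign))
    for i, j in itertools.combinations(range(k), 2):
        cols = np.concatenate([assign[:, offs[i]:offs[i + 1]], assign[:, offs[j]:offs[j + 1]]],
                              axis=1)
        maxes = np.maximum(maxes, np.abs(_z_rows(pooled[cols], sizes[i])))

    if exhaustive:
        out = {
            pair: (z, float(np.mean(maxes >= abs(z) - 1e-12)))
            for pair, z in observed.items()
        }
    else:
        out = {
            pair: (z, float((1 + np.sum(maxes >= abs(z) - 1e-12)) / (n_resamples + 1)))
            for pair, z in observed.items()
        }
    return out


def _tie_term_rows(C: np.ndarray) -> np.ndarray:
    """Row-wise sum over tie groups of (t^3 - t), via sum over elements of (t^2 - 1)."""
    s = np.sort(C, axis=1)
    P, n = s.shape
    idx = np.arange(n)
    start = np.ones_like(s, dtype=bool)
    start[:, 1:] = s[:, 1:] != s[:, :-1]
    startpos = np.maximum.accumulate(np.where(start, idx, 0), axis=1)
    rev = s[:, ::-1]
    end = np.ones_like(s, dtype=bool)
    end[:, 1:] = rev[:, 1:] != rev[:, :-1]
    endpos = (n - 1) - np.maximum.accumulate(np.where(end, idx, 0), axis=1)[:, ::-1]
    t = endpos - startpos + 1
    return (t * t - 1).sum(axis=1).astype(float)


def _z_rows(C: np.ndarray, n1: int) -> np.ndarray:
    """Vectorized tie-corrected rank-sum z for each row of C (first n1 columns = group 1)."""
    P, n = C.shape
    n2 = n - n1
    ranks = sps.rankdata(C, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    e = n1 * (n + 1) / 2.0
    v = n1 * n2 / 12.0 * ((n + 1) - _tie_term_rows(C) / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(v > 0, (w - e) / np.sqrt(np.maximum(v, 1e-300)), 0.0)
    return z


def chi_square_independence(table) -> tuple[float, float]:
    """Pearson chi-square without continuity correction; df = (rows-1)(cols-1)."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("table must hold nonnegative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all row and column sums must be positive")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks) with t-approximation p value."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho is undefined for a constant input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def partial_spearman(x, y, covariate, method: str = "formula") -> float:
    """Spearman correlation of x and y corrected for one covariate.

    ``method="formula"`` applies the first-order partial-correlation formula
    to the three pairwise Spearman coefficients:
    ``(rho_xy - rho_xz * rho_yz) / sqrt((1 - rho_xz^2)(1 - rho_yz^2))``.
    ``method="residuals"`` instead correlates the residuals of rank-on-rank
    regressions of x and y on the covariate (alternative estimator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    if not (len(x) == len(y) == len(z)) or len(x) < 4:
        raise ValueError("need >= 4 complete triples")
    if method == "formula":
        rxy, _ = spearman(x, y)
        rxz, _ = spearman(x, z)
        ryz, _ = spearman(y, z)
        if abs(rxz) >= 1.0 - 1e-12 or abs(ryz) >= 1.0 - 1e-12:
            raise ValueError("covariate is perfectly rank-correlated with an input")
        return float((rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2)))
    if method == "residuals":
        rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
        rz_c = np.column_stack([np.ones_like(rz), rz])
        res_x = rx - rz_c @ np.linalg.lstsq(rz_c, rx, rcond=None)[0]
        res_y = ry - rz_c @ np.linalg.lstsq(rz_c, ry, rcond=None)[0]
        return float(np.corrcoef(res_x, res_y)[0, 1])
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC summary at the Youden-optimal cutoff."""

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str


def roc_youden(scores, labels, direction: str = "lower_is_positive") -> ROCResult:
    """Empirical ROC with the Youden-index cutoff.

    ``labels`` are truthy for positives (diseased).  With the default
    ``lower_is_positive`` (thinner LC indicates glaucoma) a case is called
    positive iff ``score <= cutoff``.  AUC is the normalized (tie-corrected)
    Mann-Whitney statistic; the cutoff maximizes sensitivity + specificity -
    1, ties broken toward higher specificity, then the smaller cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if direction not in ("lower_is_positive", "higher_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")

    oriented = -scores if direction == "lower_is_positive" else scores
    ranks = sps.rankdata(oriented)
    auc = (ranks[labels].sum() - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg))

    best = None
    for c in np.unique(scores):
        if direction == "lower_is_positive":
            sens = np.mean(pos <= c)
            spec = np.mean(neg > c)
        else:
            sens = np.mean(pos >= c)
            spec = np.mean(neg < c)
        j = sens + spec - 1.0
        key = (round(j, 15), round(spec, 15), -c)
        if best is None or key > best[0]:
            best = (key, float(c), float(sens), float(spec))
    _, cutoff, sens, spec = best
    return ROCResult(auc=float(auc), cutoff=cutoff, sensitivity=sens,
                     specificity=spec, direction=direction)
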