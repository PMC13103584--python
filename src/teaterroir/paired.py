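"""Exact and classical paired tests on within-pair contrasts.

With n = 8 matched pairs the exact null spaces are tiny (2^8 sign flips,
8! rank orders), so every "exact" p-value here is a ratio of integers over
the fully enumerated null rather than an approximation:

* exact sign test — doubled binomial tail, p on the grid {2k/2^n};
* McNemar's exact test — doubled binomial tail over discordant pairs;
* Wilcoxon signed-rank — full 2^n enumeration of sign assignments on
  midranks (exact for n ≤ 25, normal approximation above);
* Spearman on paired deltas — full n! enumeration for n ≤ 8.

Two-sided p is always the doubled smaller tail capped at 1, which
reproduces the printed desk-scale values (2/256 = 0.0078, 18/256 = 0.0703,
2/128 = 0.0156). Cohen's dz (mean delta / sd of deltas) with a pair
bootstrap CI, and Benjamini–Hochberg FDR within endpoint families, round
out the univariate layer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import PairedDelta

_WILCOXON_EXACT_MAX = 25
_SPEARMAN_EXACT_MAX = 8


@dataclass(frozen=True)
class PairedTestResult:
    test: str
    statistic: float
    p: float
    n_effective: int
    n_pos: int = 0
    n_neg: int = 0
    n_zero: int = 0
    dz: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    degenerate: bool = False


def _doubled_tail_binom(k: int, n: int) -> float:
    """Two-sided p = min(1, 2·min(P(K ≤ k), P(K ≥ k))) under Binomial(n, ½)."""
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def exact_sign_test(delta: PairedDelta) -> PairedTestResult:
    """Exact paired sign test; zero deltas are dropped before testing."""
    n = delta.n_pos + delta.n_neg
    if n == 0:
        return PairedTestResult(
            "exact_sign", float("nan"), 1.0, delta.n_effective,
            delta.n_pos, delta.n_neg, delta.n_zero, degenerate=True,
        )
    p = _doubled_tail_binom(delta.n_pos, n)
    return PairedTestResult(
        "exact_sign", float(delta.n_pos), p, delta.n_effective,
        delta.n_pos, delta.n_neg, delta.n_zero,
    )


def mcnemar_exact(
    detect_a: Sequence[bool], detect_b: Sequence[bool]
) -> PairedTestResult:
    """McNemar's exact test on paired detect/non-detect outcomes.

    Concordant pairs are ignored; with d discordant pairs of which b are in
    the A-detected direction, p is the doubled binomial tail at Binomial(d, ½).
    """
    a = np.asarray(detect_a, dtype=bool)
    b = np.asarray(detect_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired detection vectors must have equal length")
    discordant = a != b
    d = int(discordant.sum())
    n_b = int((a & ~b).sum())  # discordant in the A-detected direction
    if d == 0:
        return PairedTestResult(
            "mcnemar_exact", float("nan"), 1.0, len(a), degenerate=True
        )
    p = _doubled_tail_binom(n_b, d)
    return PairedTestResult("mcnemar_exact", float(n_b), p, len(a), n_pos=n_b, n_neg=d - n_b)


def _signed_rank_null(ranks: np.ndarray) -> np.ndarray:
    """Distribution of W+ over all 2^n sign assignments (doubling construction)."""
    null = np.zeros(1)
    for r in ranks:
        null = np.concatenate([null, null + r])
    return null


def wilcoxon_signed_rank(delta: PairedDelta) -> PairedTestResult:
    """Wilcoxon signed-rank test, exact by full sign-flip enumeration.

    Zeros are dropped; |deltas| are midranked (so ties are handled), and for
    n ≤ 25 the null of W+ is enumerated over all 2^n sign assignments. Above
    that a normal approximation with tie correction is used.
    """
    d = delta.deltas[delta.deltas != 0]
    n = len(d)
    if n == 0:
        return PairedTestResult(
            "wilcoxon", float("nan"), 1.0, delta.n_effective,
            delta.n_pos, delta.n_neg, delta.n_zero, degenerate=True,
        )
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= _WILCOXON_EXACT_MAX:
        null = _signed_rank_null(ranks)
        m = len(null)
        lower = np.count_nonzero(null <= w_pos + 1e-9) / m
        upper = np.count_nonzero(null >= w_pos - 1e-9) / m
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        mu = ranks.sum() / 2.0
        sigma2 = np.sum(ranks**2) / 4.0
        z = (w_pos - mu) / np.sqrt(sigma2)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return PairedTestResult(
        "wilcoxon", w_pos, float(p), delta.n_effective,
        delta.n_pos, delta.n_neg, delta.n_zero,
    )


def paired_t(delta: PairedDelta) -> PairedTestResult:
    """Paired t-test on the within-pair differences."""
    d = delta.deltas
    if len(d) < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance deltas: t statistic undefined")
    res = stats.ttest_1samp(d, 0.0)
    return PairedTestResult(
        "paired_t", float(res.statistic), float(res.pvalue), len(d),
        delta.n_pos, delta.n_neg, delta.n_zero,
    )


def cohens_dz(
    delta: PairedDelta, n_boot: int = 2000, seed: int = 0
) -> PairedTestResult:
    """Cohen's dz = mean(delta) / sd(delta), with a percentile bootstrap CI.

    The bootstrap resamples pairs with replacement (the pair is the unit of
    inference); degenerate resamples with zero sd are redrawn implicitly by
    being skipped.
    """
    d = delta.deltas
    if len(d) < 2:
        raise ValueError("dz needs at least 2 pairs")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValueError("zero-variance deltas: dz undefined")
    dz = float(np.mean(d)) / sd
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        s = rng.choice(d, size=len(d), replace=True)
        bsd = np.std(s, ddof=1)
        if bsd > 0:
            boots.append(np.mean(s) / bsd)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return PairedTestResult(
        "cohens_dz", dz, float("nan"), len(d),
        delta.n_pos, delta.n_neg, delta.n_zero,
        dz=dz, ci_low=float(lo), ci_high=float(hi),
    )


def bh_fdr(p_by_family: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    """Benjamini–Hochberg step-up within each endpoint family independently."""
    out: dict[str, np.ndarray] = {}
    for family, ps in p_by_family.items():
        ps = np.asarray(ps, dtype=float)
        if np.any((ps <= 0) | (ps > 1)):
            raise ValueError(f"family {family!r}: p-values must be in (0, 1]")
        out[family] = multipletests(ps, method="fdr_bh")[1]
    return out


def delta_spearman(
    deltas_x: Sequence[float], deltas_y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rho between two paired-delta vectors with exact permutation p.

    For n ≤ 8 the two-sided p enumerates all n! orderings of one rank vector
    (ties via midranks / Pearson on ranks); above that the large-sample
    p-value is used.
    """
    x = np.asarray(deltas_x, dtype=float)
    y = np.asarray(deltas_y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equal-length vectors of ≥ 3 paired deltas")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def _pearson(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    rho = _pearson(rx, ry)
    n = len(x)
    if n <= _SPEARMAN_EXACT_MAX:
        perms = np.array(list(itertools.permutations(range(n))))
        permuted = ry[perms]  # (n!, n)
        a = rx - rx.mean()
        b = permuted - permuted.mean(axis=1, keepdims=True)
        rhos = (b @ a) / np.sqrt((a @ a) * np.sum(b * b, axis=1))
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p
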