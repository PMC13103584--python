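"""Distance-based community analyses with exact pair-restricted inference.

All statistics operate on a Bray–Curtis (or other) dissimilarity matrix and
are wired to the :mod:`teaterroir.permute` engine, so their p-values
(``p_pair``) come from enumerating the 2^n within-pair region-label swaps
of the matched design rather than from unrestricted shuffles. An
unrestricted 999-permutation Monte-Carlo p can be attached as a descriptive
reference.

Statistics:

* PERMANOVA pseudo-R² = SS_between / SS_total computed directly from
  squared dissimilarities (one-factor region model; the cultivar effect is
  controlled by the pair restriction itself, not by a model term);
* a betadisper-style dispersion F on per-sample distances to the group
  centroid in the positive-eigenvalue PCoA space (labels are permuted
  before centroids are recomputed — the stricter choice);
* symmetric scaled Procrustes m² between two ordinations (permuted
  quantity is the concordance 1 − m², so upper tail applies);
* db-RDA: PCoA axes regressed on standardized covariates, with Ezekiel
  adjusted R².

PCoA handles negative eigenvalues by dropping those axes (no Lingoes or
Cailliez correction) and reporting the negative-inertia fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import squareform, pdist

from .permute import PairPermutationResult, exact_p_pair, unrestricted_p
from .tables import FeatureTable, MatchedDesign

_EIG_REL_TOL = 1e-10


@dataclass(frozen=True)
class DistanceMatrix:
    sample_ids: tuple[str, ...]
    values: np.ndarray
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.min(v) < 0:
            raise ValueError("distances must be nonnegative")

    def reorder(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(
            tuple(sample_ids), self.values[np.ix_(idx, idx)], self.metric
        )

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.sample_ids
        ).to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, metric: str = "braycurtis") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return cls(tuple(df.columns), df.to_numpy(dtype=float), metric)


@dataclass(frozen=True)
class Ordination:
    """Sample coordinates on the retained (positive-eigenvalue) axes."""

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # (n_samples, n_axes), sqrt-eigenvalue scaled
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_inertia: float  # |sum of negative eigenvalues| / sum |eigenvalues|


@dataclass(frozen=True)
class CommunityTestResult:
    kind: str  # pseudo_R2 | dispersion_F | procrustes_m2 | dbRDA_adjR2
    value: float
    p_pair: float | None = None
    p_unrestricted: float | None = None
    permutation: PairPermutationResult | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Distances and ordination
# ---------------------------------------------------------------------------


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between composites (columns of the table)."""
    x = table.data.to_numpy(dtype=float).T
    zero = np.where(x.sum(axis=1) == 0)[0]
    if len(zero) >= 1:
        bad = [table.sample_ids[i] for i in zero]
        raise ValueError(f"all-zero samples make Bray–Curtis undefined: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(tuple(table.sample_ids), d, "braycurtis")


def pcoa(d: DistanceMatrix) -> Ordination:
    """Principal coordinates: eigendecomposition of the Gower-centered matrix.

    Axes with eigenvalue ≤ tolerance are dropped; coordinates are scaled by
    sqrt(eigenvalue) so Euclidean distances in the full positive space
    approximate the input dissimilarities.
    """
    dm = d.values
    n = dm.shape[0]
    a = -0.5 * dm**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * _EIG_REL_TOL
    keep = eigvals > tol
    neg = eigvals[eigvals < -tol]
    total_abs = np.sum(np.abs(eigvals))
    negative_inertia = float(np.abs(neg).sum() / total_abs) if total_abs > 0 else 0.0
    lam = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(lam)
    prop = lam / lam.sum() if lam.size else lam
    return Ordination(d.sample_ids, coords, lam, prop, negative_inertia)


# ---------------------------------------------------------------------------
# PERMANOVA pseudo-R²
# ---------------------------------------------------------------------------


def permanova_pseudo_r2(d: DistanceMatrix, labels) -> float:
    """Pseudo-R² = SS_between / SS_total from squared dissimilarities.

    SS_total = Σ_{j<k} d²_{jk} / N; SS_within sums the per-group analogues.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    d2 = d.values**2
    n = len(labels)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.where(labels == g)[0]
        if idx.size == 0:
            raise ValueError(f"empty group: {g!r}")
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return float((ss_total - ss_within) / ss_total)


def _mask_labels(design: MatchedDesign, sample_ids, mask) -> np.ndarray:
    """Region label per sample after applying a within-pair swap mask."""
    members = design.swapped_members(mask)
    a_name, b_name = design.region_names
    lab = {}
    for a, b in members:
        lab[a] = a_name
        lab[b] = b_name
    return np.array([lab[s] for s in sample_ids])


def permanova_pair_test(
    d: DistanceMatrix,
    design: MatchedDesign,
    n_unrestricted: int | None = 999,
    seed: int = 0,
) -> CommunityTestResult:
    """Region PERMANOVA with exact pair-restricted p_pair."""
    ids = list(d.sample_ids)

    def stat(mask: np.ndarray) -> float:
        return permanova_pseudo_r2(d, _mask_labels(design, ids, mask))

    perm = exact_p_pair(stat, design.n_pairs, "pseudo_R2")
    p_unr = None
    if n_unrestricted:
        p_unr = unrestricted_p(
            lambda lab: permanova_pseudo_r2(d, lab),
            design.labels(ids),
            n_perm=n_unrestricted,
            seed=seed,
        )
    return CommunityTestResult(
        "pseudo_R2", perm.observed, perm.p_pair, p_unr, perm
    )


# ---------------------------------------------------------------------------
# Dispersion (betadisper-style)
# ---------------------------------------------------------------------------


def _dispersion_f(coords: np.ndarray, labels: np.ndarray) -> float:
    """One-way F on per-sample distances to their group centroid."""
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    dists = np.empty(len(labels))
    for g in groups:
        idx = np.where(labels == g)[0]
        centroid = coords[idx].mean(axis=0)
        dists[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
    grand = dists.mean()
    ss_between = sum(
        len(idx := np.where(labels == g)[0]) * (dists[idx].mean() - grand) ** 2
        for g in groups
    )
    ss_within = sum(
        ((dists[idx := np.where(labels == g)[0]] - dists[idx].mean()) ** 2).sum()
        for g in groups
    )
    df1 = len(groups) - 1
    df2 = len(labels) - len(groups)
    if ss_within == 0:
        return float("inf") if ss_between > 0 else 0.0
    return float((ss_between / df1) / (ss_within / df2))


def dispersion_test(
    d: DistanceMatrix,
    design: MatchedDesign,
    n_unrestricted: int | None = 999,
    seed: int = 0,
) -> CommunityTestResult:
    """Homogeneity-of-dispersion F with exact pair-restricted p_pair.

    Distances are measured to the group centroid in the full
    positive-eigenvalue PCoA space; centroids are recomputed per relabeling.
    """
    ord_ = pcoa(d)
    coords = ord_.coordinates
    ids = list(d.sample_ids)

    def stat(mask: np.ndarray) -> float:
        return _dispersion_f(coords, _mask_labels(design, ids, mask))

    perm = exact_p_pair(stat, design.n_pairs, "dispersion_F")
    p_unr = None
    if n_unrestricted:
        p_unr = unrestricted_p(
            lambda lab: _dispersion_f(coords, np.asarray(lab)),
            design.labels(ids),
            n_perm=n_unrestricted,
            seed=seed,
        )
    return CommunityTestResult(
        "dispersion_F", perm.observed, perm.p_pair, p_unr, perm,
        extra={"negative_inertia": ord_.negative_inertia},
    )


# ---------------------------------------------------------------------------
# Procrustes concordance
# ---------------------------------------------------------------------------


def procrustes_m2(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Symmetric scaled Procrustes residual m² ∈ [0, 1].

    Both configurations are centered and scaled to unit trace; the optimal
    rotation comes from the SVD of the cross-covariance, giving
    m² = 1 − (Σ singular values)².
    """
    _, _, disparity = _scipy_procrustes(coords_a, coords_b)
    return float(disparity)


def procrustes_pair_test(
    ord_a: Ordination,
    ord_b: Ordination,
    design: MatchedDesign,
    n_unrestricted: int | None = 999,
    seed: int = 0,
) -> CommunityTestResult:
    """Cross-ordination Procrustes m² with exact pair-restricted p_pair.

    Axes are truncated to k = min(positive axes of A, positive axes of B).
    The permuted quantity is the concordance 1 − m² (large under agreement);
    the relabeling swaps the within-pair rows of ordination B.
    """
    if ord_a.sample_ids != ord_b.sample_ids:
        raise ValueError("ordinations must share the same samples in order")
    k = min(ord_a.coordinates.shape[1], ord_b.coordinates.shape[1])
    if k < 1:
        raise ValueError("no common positive axes after truncation")
    a = ord_a.coordinates[:, :k]
    b = ord_b.coordinates[:, :k]
    ids = list(ord_a.sample_ids)
    pos = {s: i for i, s in enumerate(ids)}

    def stat(mask: np.ndarray) -> float:
        idx = np.arange(len(ids))
        for (_, sa, sb), m in zip(design.pairs, mask):
            if m:
                ia, ib = pos[sa], pos[sb]
                idx[ia], idx[ib] = idx[ib], idx[ia]
        return 1.0 - procrustes_m2(a, b[idx])

    perm = exact_p_pair(stat, design.n_pairs, "procrustes_concordance")
    p_unr = None
    if n_unrestricted:
        rng_labels = np.arange(len(ids))

        def stat_unr(order: np.ndarray) -> float:
            return 1.0 - procrustes_m2(a, b[np.asarray(order)])

        p_unr = unrestricted_p(stat_unr, rng_labels, n_perm=n_unrestricted, seed=seed)
    return CommunityTestResult(
        "procrustes_m2", 1.0 - perm.observed, perm.p_pair, p_unr, perm
    )


# ---------------------------------------------------------------------------
# db-RDA
# ---------------------------------------------------------------------------


def _standardize_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    sds = covariates.std(ddof=1)
    bad = list(sds.index[(sds == 0) | sds.isna()])
    if bad:
        raise ValueError(f"zero-variance covariates: {bad}")
    return (covariates - covariates.mean()) / sds


def _dbrda_r2(y: np.ndarray, x: np.ndarray) -> float:
    """Multivariate redundancy R² = tr(Ŷ'Ŷ) / tr(Y'Y) for centered Y."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    return float(np.sum(fitted**2) / np.sum(y**2))


def dbrda_pair_test(
    d: DistanceMatrix,
    covariates: pd.DataFrame,
    design: MatchedDesign,
    n_unrestricted: int | None = 999,
    seed: int = 0,
) -> CommunityTestResult:
    """Distance-based RDA global model with Ezekiel-adjusted R² and p_pair.

    The positive-eigenvalue PCoA axes of ``d`` (the multivariate response)
    are regressed on the standardized covariate matrix; the pair-restricted
    null swaps the within-pair response rows while covariates stay fixed.
    adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1).
    """
    ids = list(d.sample_ids)
    x_df = _standardize_covariates(covariates.loc[ids])
    x = x_df.to_numpy(dtype=float)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError("need n_samples > n_covariates + 1")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        corr = np.corrcoef(x, rowvar=False)
        collinear = [
            (x_df.columns[i], x_df.columns[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient covariates; collinear columns: {collinear}")
    ord_ = pcoa(d)
    y = ord_.coordinates - ord_.coordinates.mean(axis=0, keepdims=True)
    pos = {s: i for i, s in enumerate(ids)}

    def stat(mask: np.ndarray) -> float:
        idx = np.arange(n)
        for (_, sa, sb), m in zip(design.pairs, mask):
            if m:
                ia, ib = pos[sa], pos[sb]
                idx[ia], idx[ib] = idx[ib], idx[ia]
        return _dbrda_r2(y[idx], x)

    perm = exact_p_pair(stat, design.n_pairs, "dbRDA_R2")
    r2 = perm.observed
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    p_unr = None
    if n_unrestricted:
        p_unr = unrestricted_p(
            lambda order: _dbrda_r2(y[np.asarray(order)], x),
            np.arange(n),
            n_perm=n_unrestricted,
            seed=seed,
        )
    return CommunityTestResult(
        "dbRDA_adjR2", float(adj), perm.p_pair, p_unr, perm,
        extra={"R2": float(r2), "negative_inertia": ord_.negative_inertia},
    )
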