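"""Core-taxa classification and the threshold robustness audit.

A genus is "core" (definition v1.0) when its prevalence — the fraction of
all composites with nonzero relative abundance — is ≥ 70% and its median
relative abundance across composites is ≥ 0.1%. Prevalence 30–70% is
"intermittent", < 30% "transient". Genera with high prevalence but median
abundance below the floor fall in a definitional gap and get their own
explicit class rather than being silently coerced.

The audit reruns the shortlist over a 5 × 4 grid of thresholds (prevalence
60–80% in 5% steps × abundance 0.05–0.20% in 0.05% steps) and summarizes
stability per cell with (1) direction consistency — the per-genus fraction
of pairs sharing the modal within-pair delta sign, averaged over the
shortlist — and (2) rank concordance — the Spearman correlation of genus
effect-size ranks (mean within-pair delta, A − B) against the v1.0 ranks
on the shortlist intersection. A pair-restricted null (all 2^n within-pair
label swaps) contextualizes both metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .permute import enumerate_relabelings
from .tables import FeatureTable, MatchedDesign

CLASS_CORE = "core"
CLASS_INTERMITTENT = "intermittent"
CLASS_TRANSIENT = "transient"
CLASS_GAP = "high_prevalence_low_abundance"

DEFAULT_PREVALENCE_GRID = (0.60, 0.65, 0.70, 0.75, 0.80)
DEFAULT_ABUNDANCE_GRID = (0.0005, 0.0010, 0.0015, 0.0020)


@dataclass(frozen=True)
class CoreDefinition:
    """Prevalence/abundance thresholds; v1.0 = 70% prevalence, 0.1% median."""

    prevalence_threshold: float = 0.70
    abundance_threshold: float = 0.001
    intermittent_low: float = 0.30

    def __post_init__(self) -> None:
        if not 0 < self.intermittent_low <= self.prevalence_threshold <= 1:
            raise ValueError("need 0 < intermittent bound ≤ prevalence threshold ≤ 1")
        if self.abundance_threshold < 0:
            raise ValueError("abundance threshold must be ≥ 0")


def _prevalence_abundance(table: FeatureTable) -> tuple[pd.Series, pd.Series]:
    rel = table.relative_abundance().data
    if rel.empty:
        raise ValueError("empty genus table")
    prevalence = (rel > 0).mean(axis=1)
    median_ab = rel.median(axis=1)
    return prevalence, median_ab


def classify_genera(table: FeatureTable, defn: CoreDefinition) -> pd.Series:
    """Class per genus: core / intermittent / transient / definitional gap.

    Prevalence is computed over all composites (both regions pooled);
    presence means relative abundance > 0 after identical filtering.
    """
    prevalence, median_ab = _prevalence_abundance(table)
    out = {}
    for g in prevalence.index:
        p, m = prevalence[g], median_ab[g]
        if p >= defn.prevalence_threshold:
            out[g] = CLASS_CORE if m >= defn.abundance_threshold else CLASS_GAP
        elif p >= defn.intermittent_low:
            out[g] = CLASS_INTERMITTENT
        else:
            out[g] = CLASS_TRANSIENT
    return pd.Series(out, name="class")


def shortlist(table: FeatureTable, defn: CoreDefinition) -> list[str]:
    """Genera passing both thresholds (the core set for one grid cell)."""
    return list(classify_genera(table, defn).pipe(lambda s: s[s == CLASS_CORE]).index)


def _pair_delta_matrix(table: FeatureTable, design: MatchedDesign) -> pd.DataFrame:
    """Genus × pair matrix of within-pair deltas (A − B) of relative abundance."""
    rel = table.relative_abundance().data
    cols = {}
    for pid, a, b in design.pairs:
        cols[pid] = rel[a] - rel[b]
    return pd.DataFrame(cols)


def effect_size_per_genus(
    table: FeatureTable, design: MatchedDesign
) -> pd.DataFrame:
    """Per-genus mean within-pair delta, ranked by |effect| (midranks).

    Rank 1 is the largest |effect|.
    """
    deltas = _pair_delta_matrix(table, design)
    effect = deltas.mean(axis=1)
    rank = pd.Series(
        stats.rankdata(-np.abs(effect)), index=effect.index, name="rank"
    )
    return pd.DataFrame({"effect": effect, "rank": rank}).sort_values("rank")


def _direction_consistency(deltas: pd.DataFrame, genera: list[str]) -> pd.Series:
    """Per-genus fraction of pairs sharing the modal delta sign."""
    out = {}
    for g in genera:
        d = deltas.loc[g].to_numpy()
        nz = d[d != 0]
        if nz.size == 0:
            out[g] = np.nan
            continue
        n_pos = int((nz > 0).sum())
        out[g] = max(n_pos, nz.size - n_pos) / len(d)
    return pd.Series(out)


@dataclass(frozen=True)
class AuditGridResult:
    """Per-cell shortlists and stability metrics over the threshold grid."""

    v1: CoreDefinition
    cells: pd.DataFrame  # prevalence_threshold, abundance_threshold, n_core,
    #                      direction_consistency, rank_concordance, flag
    shortlists: dict[tuple[float, float], list[str]]
    per_genus: pd.DataFrame  # long format: cell thresholds, genus, effect, rank,
    #                          direction_consistency


def audit_grid(
    table: FeatureTable,
    design: MatchedDesign,
    v1: CoreDefinition | None = None,
    prevalence_grid=DEFAULT_PREVALENCE_GRID,
    abundance_grid=DEFAULT_ABUNDANCE_GRID,
    summary: str = "mean",
) -> AuditGridResult:
    """Robustness grid over prevalence × abundance thresholds.

    ``summary`` ∈ {"mean", "median"} controls how per-genus direction
    consistencies aggregate over a cell's shortlist. Rank concordance
    compares effect-size ranks on the intersection with the v1.0
    shortlist; an empty intersection is flagged, not guessed.
    """
    if v1 is None:
        v1 = CoreDefinition()
    if summary not in {"mean", "median"}:
        raise ValueError("summary must be 'mean' or 'median'")
    agg = np.nanmean if summary == "mean" else np.nanmedian

    v1_short = shortlist(table, v1)
    if not v1_short:
        raise ValueError("v1.0 shortlist is empty")
    deltas = _pair_delta_matrix(table, design)
    effects = deltas.mean(axis=1)

    rows, per_genus_rows = [], []
    shortlists: dict[tuple[float, float], list[str]] = {}
    for pt in prevalence_grid:
        for at in abundance_grid:
            defn = CoreDefinition(pt, at, min(v1.intermittent_low, pt))
            cell_short = shortlist(table, defn)
            shortlists[(pt, at)] = cell_short
            flag = ""
            if cell_short:
                cons = _direction_consistency(deltas, cell_short)
                dc = float(agg(cons.to_numpy()))
                inter = [g for g in cell_short if g in v1_short]
                if len(inter) >= 2:
                    cell_rank = stats.rankdata(-np.abs(effects[cell_short]))
                    v1_rank = stats.rankdata(-np.abs(effects[v1_short]))
                    cr = pd.Series(cell_rank, index=cell_short)[inter]
                    vr = pd.Series(v1_rank, index=v1_short)[inter]
                    if cr.nunique() > 1 and vr.nunique() > 1:
                        rc = float(stats.spearmanr(cr, vr).statistic)
                    else:
                        rc, flag = np.nan, "constant_ranks"
                else:
                    rc, flag = np.nan, "intersection_too_small"
                cell_rankmap = pd.Series(
                    stats.rankdata(-np.abs(effects[cell_short])), index=cell_short
                )
                for g in cell_short:
                    per_genus_rows.append(
                        {
                            "prevalence_threshold": pt,
                            "abundance_threshold": at,
                            "genus": g,
                            "effect": float(effects[g]),
                            "rank": float(cell_rankmap[g]),
                            "direction_consistency": float(cons[g]),
                        }
                    )
            else:
                dc, rc, flag = np.nan, np.nan, "empty_shortlist"
            rows.append(
                {
                    "prevalence_threshold": pt,
                    "abundance_threshold": at,
                    "n_core": len(cell_short),
                    "direction_consistency": dc,
                    "rank_concordance": rc,
                    "flag": flag,
                }
            )
    return AuditGridResult(v1, pd.DataFrame(rows), shortlists, pd.DataFrame(per_genus_rows))


@dataclass(frozen=True)
class AuditNullResult:
    """Pair-restricted null distributions of the v1.0 stability metrics."""

    observed_direction_consistency: float
    observed_rank_concordance: float
    null_direction_consistency: np.ndarray  # length 2^n
    null_rank_concordance: np.ndarray
    exceedance_direction: float  # fraction of null ≥ observed
    exceedance_rank: float


def audit_null(
    table: FeatureTable,
    design: MatchedDesign,
    v1: CoreDefinition | None = None,
    summary: str = "mean",
) -> AuditNullResult:
    """Recompute the v1.0 stability metrics under every within-pair swap.

    Swapping a pair's region labels negates that pair's delta column, so the
    null recomputes effects, direction consistency, and rank concordance
    (against the observed v1.0 ranks) for each of the 2^n sign patterns.
    The identity relabeling reproduces the observed metrics exactly.
    """
    if v1 is None:
        v1 = CoreDefinition()
    agg = np.nanmean if summary == "mean" else np.nanmedian
    v1_short = shortlist(table, v1)
    if not v1_short:
        raise ValueError("v1.0 shortlist is empty")
    deltas = _pair_delta_matrix(table, design).loc[v1_short]
    dmat = deltas.to_numpy()  # genus × pair
    obs_rank = stats.rankdata(-np.abs(dmat.mean(axis=1)))

    masks = enumerate_relabelings(design.n_pairs)
    null_dc = np.empty(len(masks))
    null_rc = np.empty(len(masks))
    for i, mask in enumerate(masks):
        signs = np.where(mask, -1.0, 1.0)
        d = dmat * signs
        n_pos = (d > 0).sum(axis=1)
        n_neg = (d < 0).sum(axis=1)
        cons = np.maximum(n_pos, n_neg) / d.shape[1]
        null_dc[i] = agg(cons)
        rank = stats.rankdata(-np.abs(d.mean(axis=1)))
        if len(obs_rank) >= 2 and len(set(obs_rank)) > 1 and len(set(rank)) > 1:
            null_rc[i] = stats.spearmanr(rank, obs_rank).statistic
        else:
            null_rc[i] = np.nan
    return AuditNullResult(
        observed_direction_consistency=float(null_dc[0]),
        observed_rank_concordance=float(null_rc[0]),
        null_direction_consistency=null_dc,
        null_rank_concordance=null_rc,
        exceedance_direction=float(np.mean(null_dc >= null_dc[0])),
        exceedance_rank=float(np.nanmean(null_rc >= null_rc[0])),
    )
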