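"""Composite flavour indices (VSI and NPI).

VSI, the volatile signature index, contrasts a fixed floral/fruity volatile
set V+ = {linalool, geraniol, linalool oxide, decanal} against a fixed
resinous/woody set V− = {β-caryophyllene, 1-octen-3-ol}:

    VSI = mean of z(v) over V+  −  mean of z(v) over V−

NPI, the non-volatile pool index, contrasts a phenolic/alkaloid pool
X+ = {caffeine, EGCG, ECG, EGC, EC} against an amino/nitrogenous pool
X− = {theanine, GABA} the same way. Variable sets are fixed a priori with
equal weights inside each set — no data-driven selection or weight tuning.

z-scores are computed across composites with a :class:`Standardizer` that
stores its fitted means and standard deviations, so cross-validation can
fit on a training fold and transform held-out composites without leakage.
Volatile non-detects enter the z-scoring as the stored 0 (never imputed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .tables import (
    FeatureTable,
    MatchedDesign,
    PairedDelta,
    canonical_feature_name,
    paired_deltas,
)


@dataclass(frozen=True)
class IndexDefinition:
    """A named composite index: equal-weight positive set minus negative set."""

    name: str
    positive_set: tuple[str, ...]
    negative_set: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.positive_set or not self.negative_set:
            raise ValueError(f"{self.name}: both variable sets must be non-empty")
        pos = {canonical_feature_name(f) for f in self.positive_set}
        neg = {canonical_feature_name(f) for f in self.negative_set}
        if pos & neg:
            raise ValueError(f"{self.name}: variable sets must be disjoint")

    @property
    def features(self) -> tuple[str, ...]:
        return self.positive_set + self.negative_set

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "positive_set": list(self.positive_set),
            "negative_set": list(self.negative_set),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IndexDefinition":
        return cls(d["name"], tuple(d["positive_set"]), tuple(d["negative_set"]))


def default_definitions() -> tuple[IndexDefinition, IndexDefinition]:
    """The fixed a-priori VSI and NPI variable sets."""
    vsi = IndexDefinition(
        "VSI",
        positive_set=("linalool", "geraniol", "linalool oxide", "decanal"),
        negative_set=("beta-caryophyllene", "1-octen-3-ol"),
    )
    npi = IndexDefinition(
        "NPI",
        positive_set=("caffeine", "EGCG", "ECG", "EGC", "EC"),
        negative_set=("theanine", "GABA"),
    )
    return vsi, npi


def definitions_from_yaml(path: str | Path) -> list[IndexDefinition]:
    with open(path) as fh:
        docs = yaml.safe_load(fh)
    if isinstance(docs, dict):
        docs = [docs]
    return [IndexDefinition.from_dict(d) for d in docs]


def definitions_to_yaml(defs: Sequence[IndexDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([d.to_dict() for d in defs], fh, sort_keys=False)


@dataclass(frozen=True)
class Standardizer:
    """Per-feature z-scoring parameters (sample sd, n−1 denominator)."""

    means: pd.Series
    sds: pd.Series
    n_samples: int

    @property
    def features(self) -> list[str]:
        return list(self.means.index)

    def transform(self, table: FeatureTable) -> pd.DataFrame:
        """z-score the stored features of ``table`` using fitted parameters only."""
        rows = {}
        for fid in self.means.index:
            vals = table.values_for(fid)
            rows[fid] = (vals - self.means[fid]) / self.sds[fid]
        return pd.DataFrame(rows).T


def fit_standardizer(
    table: FeatureTable,
    features: Sequence[str],
    sample_ids: Sequence[str] | None = None,
) -> Standardizer:
    """Fit per-feature mean/sd on ``sample_ids`` (default: all composites).

    Raises on zero-variance features, naming the offenders.
    """
    cols = list(sample_ids) if sample_ids is not None else table.sample_ids
    if len(cols) < 2:
        raise ValueError("standardizer needs at least 2 samples")
    means, sds = {}, {}
    degenerate = []
    for name in features:
        fid = table.find_feature(name)
        vals = table.data.loc[fid, cols].to_numpy(dtype=float)
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd <= 0:
            degenerate.append(fid)
        means[fid], sds[fid] = mu, sd
    if degenerate:
        raise ValueError(f"zero-variance features: {degenerate}")
    return Standardizer(pd.Series(means), pd.Series(sds), len(cols))


@dataclass(frozen=True)
class IndexResult:
    """Per-composite index values with the signed decomposition.

    ``values = positive_scores − negative_scores`` holds everywhere.
    """

    name: str
    values: pd.Series
    positive_scores: pd.Series
    negative_scores: pd.Series


def compute_index(
    defn: IndexDefinition, table: FeatureTable, standardizer: Standardizer
) -> IndexResult:
    """Equal-weight mean z over the positive set minus the negative set."""
    z = standardizer.transform(table)

    def _mean_z(names: tuple[str, ...]) -> pd.Series:
        fids = [table.find_feature(n) for n in names]
        missing = [n for n, f in zip(names, fids) if f not in z.index]
        if missing:
            raise KeyError(f"features absent from standardizer: {missing}")
        return z.loc[fids].mean(axis=0)

    pos = _mean_z(defn.positive_set)
    neg = _mean_z(defn.negative_set)
    return IndexResult(defn.name, pos - neg, pos, neg)


@dataclass(frozen=True)
class IndexDeltas:
    """Per-pair index deltas (A − B) with median / IQR summaries."""

    delta: PairedDelta
    median: float
    iqr: tuple[float, float]


def index_deltas(result: IndexResult, design: MatchedDesign) -> IndexDeltas:
    table = FeatureTable(result.values.to_frame(result.name).T, "generic")
    delta = paired_deltas(table, design, result.name)
    q1, med, q3 = np.percentile(delta.deltas, [25, 50, 75])
    return IndexDeltas(delta, float(med), (float(q1), float(q3)))
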