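"""Feature tables, matched-pair designs, and within-pair contrasts.

The unit of inference throughout the package is the genotype-matched pair:
the same cultivar grown in two regions, giving one composite sample per
region. :class:`MatchedDesign` records that pairing; :class:`FeatureTable`
holds a features × composites numeric matrix for one data layer (volatiles
as Area%, non-volatile chemistry, e-tongue readouts, soil physicochemistry,
or genus-level microbial counts / relative abundances); and
:func:`paired_deltas` turns the two into per-pair contrasts (region A −
region B) with explicit sign bookkeeping.

Conventions enforced here:

* a volatile value of 0 means "not detected" under the fixed integration /
  blank-filtering rule and is never imputed;
* abundance-like tables (volatile, genus) must be non-negative, and
  relative-abundance columns must sum to 1;
* pairs with a missing value in either member are dropped (complete-case
  analysis), which is how a failed e-tongue readout removes one pair.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TABLE_KINDS = frozenset(
    {
        "volatile",
        "nonvolatile",
        "etongue",
        "soil",
        "genus_counts",
        "genus_relabund",
        "clr",
        "generic",
    }
)

_NONNEGATIVE_KINDS = frozenset({"volatile", "genus_counts", "genus_relabund"})


class TableValidationError(ValueError):
    """A table or design violated a structural invariant."""


def canonical_feature_name(name: str) -> str:
    """Canonical form used for feature-name matching.

    Unicode-normalizes (NFKC), case-folds, and spells out the Greek beta so
    that e.g. ``β-Caryophyllene`` and ``beta-caryophyllene`` match.
    """
    s = unicodedata.normalize("NFKC", str(name)).casefold()
    return s.replace("β", "beta").strip()


# ---------------------------------------------------------------------------
# Matched design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchedDesign:
    """Pairing structure: n cultivar pairs × 2 regions.

    ``pairs`` is an ordered tuple of ``(pair_id, composite_a, composite_b)``
    where ``composite_a`` is the sample from the reference region (first in
    ``region_names``; deltas are computed as A − B).
    """

    pairs: tuple[tuple[str, str, str], ...]
    region_names: tuple[str, str] = ("Menghai", "Puer")

    def __post_init__(self) -> None:
        if len(self.pairs) < 2:
            raise TableValidationError("a matched design needs at least 2 pairs")
        seen: set[str] = set()
        for _, a, b in self.pairs:
            for cid in (a, b):
                if cid in seen:
                    raise TableValidationError(f"duplicate composite id: {cid!r}")
                seen.add(cid)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def pair_ids(self) -> list[str]:
        return [p for p, _, _ in self.pairs]

    @property
    def sample_ids(self) -> list[str]:
        """All composite ids, pair-major, region A member first."""
        out: list[str] = []
        for _, a, b in self.pairs:
            out.extend((a, b))
        return out

    def region_of(self, composite_id: str) -> str:
        for _, a, b in self.pairs:
            if composite_id == a:
                return self.region_names[0]
            if composite_id == b:
                return self.region_names[1]
        raise KeyError(composite_id)

    def labels(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """Region label per sample (default: :attr:`sample_ids` order)."""
        ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        return np.array([self.region_of(c) for c in ids])

    def subset(self, pair_ids: Iterable[str]) -> "MatchedDesign":
        keep = set(pair_ids)
        return MatchedDesign(
            tuple(p for p in self.pairs if p[0] in keep), self.region_names
        )

    def drop_pairs(self, pair_ids: Iterable[str]) -> "MatchedDesign":
        drop = set(pair_ids)
        return MatchedDesign(
            tuple(p for p in self.pairs if p[0] not in drop), self.region_names
        )

    def swapped_members(self, mask: Sequence[bool]) -> list[tuple[str, str]]:
        """(region-A composite, region-B composite) per pair after applying
        a within-pair swap mask (True = labels exchanged for that pair)."""
        if len(mask) != self.n_pairs:
            raise ValueError("mask length must equal n_pairs")
        return [
            (b, a) if m else (a, b) for (_, a, b), m in zip(self.pairs, mask)
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid, a, b in self.pairs:
            rows.append({"composite_id": a, "cultivar": pid, "region": self.region_names[0]})
            rows.append({"composite_id": b, "cultivar": pid, "region": self.region_names[1]})
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> MatchedDesign:
    """Read and validate a design TSV (columns: composite_id, cultivar, region).

    Region order follows first appearance in the file, so the first region
    listed is the delta reference (Menghai first by convention).
    Collects all validation problems and reports them together.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"composite_id", "cultivar", "region"}
    missing = required - set(df.columns)
    if missing:
        raise TableValidationError(f"design file missing columns: {sorted(missing)}")

    problems: list[str] = []
    regions = list(dict.fromkeys(df["region"]))
    if len(regions) != 2:
        problems.append(f"expected exactly 2 regions, found {regions}")

    dup = df["composite_id"][df["composite_id"].duplicated()].tolist()
    if dup:
        problems.append(f"duplicate composite ids: {dup}")

    pairs: list[tuple[str, str, str]] = []
    if len(regions) == 2:
        for cultivar, grp in df.groupby("cultivar", sort=False):
            by_region = dict(zip(grp["region"], grp["composite_id"]))
            if set(by_region) != set(regions) or len(grp) != 2:
                problems.append(
                    f"cultivar {cultivar!r} does not form a complete pair "
                    f"(regions seen: {sorted(grp['region'])})"
                )
                continue
            pairs.append((str(cultivar), by_region[regions[0]], by_region[regions[1]]))

    if problems:
        raise TableValidationError("; ".join(problems))
    return MatchedDesign(tuple(pairs), (regions[0], regions[1]))


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """A features × composites numeric matrix for one data layer.

    ``data`` is a DataFrame with feature ids as the index and composite ids
    as columns. NaN entries are only legal for the e-tongue kind, where a
    failed readout leaves a composite missing.
    """

    data: pd.DataFrame
    kind: str = "generic"

    def __post_init__(self) -> None:
        if self.kind not in TABLE_KINDS:
            raise TableValidationError(f"unknown table kind: {self.kind!r}")
        self.data = self.data.astype(float)
        self.data.index.name = "feature_id"
        vals = self.data.to_numpy()
        if self.kind != "etongue" and np.isnan(vals).any():
            raise TableValidationError(f"NaN values not allowed in kind {self.kind!r}")
        if self.kind in _NONNEGATIVE_KINDS and np.nanmin(vals) < 0:
            raise TableValidationError(f"negative values not allowed in kind {self.kind!r}")
        if self.kind == "genus_relabund":
            sums = np.nansum(vals, axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise TableValidationError(
                    "relative-abundance columns must sum to 1 ± 1e-9"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def find_feature(self, name: str) -> str:
        """Resolve a feature name via canonical matching; raise KeyError."""
        target = canonical_feature_name(name)
        for fid in self.data.index:
            if canonical_feature_name(fid) == target:
                return fid
        raise KeyError(f"feature {name!r} not found in {self.kind} table")

    def values_for(self, name: str) -> pd.Series:
        return self.data.loc[self.find_feature(name)]

    def relative_abundance(self) -> "FeatureTable":
        """Total-sum scale a counts table to column proportions."""
        if self.kind not in {"genus_counts", "genus_relabund"}:
            raise TableValidationError("relative_abundance expects a genus table")
        if self.kind == "genus_relabund":
            return FeatureTable(self.data.copy(), "genus_relabund")
        totals = self.data.sum(axis=0)
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise TableValidationError(f"zero-total samples: {bad}")
        return FeatureTable(self.data / totals, "genus_relabund")

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str = "generic") -> "FeatureTable":
        # round_trip parsing makes write→read bit-exact
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        df.index.name = "feature_id"
        return cls(df, kind)


# ---------------------------------------------------------------------------
# Paired contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedDelta:
    """Per-pair within-pair differences (region A − region B) for one feature."""

    feature_id: str
    pair_ids: tuple[str, ...]
    deltas: np.ndarray
    n_pos: int
    n_neg: int
    n_zero: int

    @property
    def n_effective(self) -> int:
        return len(self.deltas)

    @classmethod
    def from_values(
        cls, feature_id: str, pair_ids: Sequence[str], deltas: Sequence[float]
    ) -> "PairedDelta":
        d = np.asarray(deltas, dtype=float)
        return cls(
            feature_id=feature_id,
            pair_ids=tuple(pair_ids),
            deltas=d,
            n_pos=int((d > 0).sum()),
            n_neg=int((d < 0).sum()),
            n_zero=int((d == 0).sum()),
        )

    def negated(self) -> "PairedDelta":
        return PairedDelta.from_values(self.feature_id, self.pair_ids, -self.deltas)


def paired_deltas(
    table: FeatureTable, design: MatchedDesign, feature_id: str
) -> PairedDelta:
    """Within-pair deltas (A − B) for one feature, complete cases only.

    A pair is dropped when either member's value is missing (NaN); sign
    counts keep an explicit zero category (exact ties).
    """
    fid = table.find_feature(feature_id)
    row = table.data.loc[fid]
    pair_ids: list[str] = []
    deltas: list[float] = []
    for pid, a, b in design.pairs:
        if a not in row.index or b not in row.index:
            raise KeyError(f"composite missing from table: pair {pid!r}")
        va, vb = row[a], row[b]
        if np.isnan(va) or np.isnan(vb):
            continue
        pair_ids.append(pid)
        deltas.append(float(va - vb))
    return PairedDelta.from_values(fid, pair_ids, deltas)


# ---------------------------------------------------------------------------
# Rarefaction and CLR
# ---------------------------------------------------------------------------

#: depths used for the reference analysis (16S / ITS); any depth is allowed
DEFAULT_RAREFACTION_DEPTHS = {"bacteria": 44_867, "fungi": 41_725}


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample each composite's counts without replacement to ``depth``.

    Each column is an independent multivariate-hypergeometric draw, so a
    taxon absent before subsampling stays absent. Deterministic under seed.
    """
    if table.kind != "genus_counts":
        raise TableValidationError("rarefy expects a genus_counts table")
    if depth <= 0:
        raise TableValidationError("depth must be positive")
    counts = table.data.to_numpy()
    totals = counts.sum(axis=0)
    low = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if low:
        raise TableValidationError(
            f"samples below rarefaction depth {depth}: {low}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        col = counts[:, j].astype(np.int64)
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return FeatureTable(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        "genus_counts",
    )


def clr_transform(table: FeatureTable, pseudocount: float | None = None) -> FeatureTable:
    """Centered log-ratio transform of a genus table.

    Counts are total-sum scaled first. Zeros are replaced by ``pseudocount``
    (default: half the smallest nonzero relative abundance in the table)
    before taking logs; each column is then centered by its mean log, so
    every CLR column has mean 0 across features.
    """
    rel = table.relative_abundance().data.to_numpy()
    nonzero = rel[rel > 0]
    if nonzero.size == 0:
        raise TableValidationError("table has no nonzero abundances")
    if pseudocount is None:
        pseudocount = float(nonzero.min()) / 2.0
    if pseudocount <= 0:
        raise TableValidationError("pseudocount must be > 0")
    x = np.where(rel == 0, pseudocount, rel)
    logx = np.log(x)
    clr = logx - logx.mean(axis=0, keepdims=True)
    return FeatureTable(
        pd.DataFrame(clr, index=table.data.index, columns=table.data.columns), "clr"
    )
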