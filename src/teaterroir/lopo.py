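"""Leave-one-pair-out (LOPO) validation with an exact pair-respecting null.

Each fold holds out both composites of one cultivar pair and trains a
random-forest classifier of region on the remaining 2(n−1) composites, so
generalization is forced across genotypes (no genotype leakage). All
standardization — per-feature z-scoring and the composite-index
standardizers — is re-fit inside each training fold and applied to the
held-out pair using stored parameters only. Out-of-fold predicted
probabilities are pooled over all 2n composites and summarized as a single
midrank ROC AUC.

Significance uses the exact pair-respecting permutation null: every one of
the 2^n within-pair label swaps reruns the LOPO loop, and

    p = (1 + #{non-identity relabelings with AUC ≥ observed}) / (1 + (2^n − 1))

— the standard +1 adjustment, identical to counting the identity in both
numerator and denominator. Fold feature matrices are label-independent (the
z-scoring and indices are unsupervised), so the null refits only the
classifier and relabels the truth; the classifier's own randomness is held
fixed across relabelings so the null isolates label structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .indices import IndexDefinition, Standardizer, compute_index, fit_standardizer
from .permute import MAX_ENUMERABLE_PAIRS, enumerate_relabelings
from .tables import FeatureTable, MatchedDesign

LOPO_NULL_GUARD = 10  # 2^10 full LOPO reruns is the desk-scale ceiling


@dataclass(frozen=True)
class PanelSpec:
    """What goes into the integrated feature panel.

    ``raw_features`` maps a table key to feature names included as
    fold-standardized z-scores; ``index_features`` lists (index definition,
    table key) pairs whose composite index is computed with a fold-fitted
    standardizer.
    """

    raw_features: tuple[tuple[str, str], ...] = ()
    index_features: tuple[tuple[IndexDefinition, str], ...] = ()

    @property
    def n_features(self) -> int:
        return len(self.raw_features) + len(self.index_features)


@dataclass(frozen=True)
class LopoModelConfig:
    trees: int = 200
    max_depth: int | None = None


@dataclass(frozen=True)
class FoldData:
    """One fold's leakage-safe matrices and its fitted standardizers."""

    pair_id: str
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    x_train: pd.DataFrame
    x_test: pd.DataFrame
    standardizers: dict


@dataclass(frozen=True)
class LopoResult:
    predictions: pd.DataFrame  # fold, composite, truth, probability
    auc: float
    null_auc: np.ndarray | None = None
    p_value: float | None = None


def assemble_panel(
    tables: dict[str, FeatureTable],
    design: MatchedDesign,
    panel: PanelSpec,
    sample_ids=None,
) -> pd.DataFrame:
    """Raw (unstandardized) panel matrix, one row per composite.

    Useful for inspection and complete-case checks; the LOPO loop itself
    rebuilds standardized panels per fold. Raises on unknown tables or
    features; rows with any missing value are dropped (complete cases).
    """
    ids = list(sample_ids) if sample_ids is not None else design.sample_ids
    cols = {}
    for key, feat in panel.raw_features:
        if key not in tables:
            raise KeyError(f"panel references unknown table {key!r}")
        cols[f"{key}:{feat}"] = tables[key].values_for(feat).reindex(ids)
    for defn, key in panel.index_features:
        if key not in tables:
            raise KeyError(f"panel references unknown table {key!r}")
        std = fit_standardizer(tables[key], defn.features, ids)
        cols[defn.name] = compute_index(defn, tables[key], std).values.reindex(ids)
    df = pd.DataFrame(cols, index=ids)
    return df.dropna(axis=0, how="any")


def complete_case_design(
    tables: dict[str, FeatureTable], design: MatchedDesign, panel: PanelSpec
) -> MatchedDesign:
    """Restrict the design to pairs with complete panel rows for both members."""
    rows = assemble_panel(tables, design, panel).index
    keep = [
        pid for pid, a, b in design.pairs if a in rows and b in rows
    ]
    return design.subset(keep)


def _build_fold(
    tables: dict[str, FeatureTable],
    panel: PanelSpec,
    pair_id: str,
    train_ids: list[str],
    test_ids: list[str],
) -> FoldData:
    standardizers: dict = {}
    tr_cols, te_cols = {}, {}
    for key, feat in panel.raw_features:
        table = tables[key]
        std = fit_standardizer(table, [feat], train_ids)
        standardizers[f"{key}:{feat}"] = std
        z = std.transform(table).iloc[0]
        tr_cols[f"{key}:{feat}"] = z[train_ids]
        te_cols[f"{key}:{feat}"] = z[test_ids]
    for defn, key in panel.index_features:
        table = tables[key]
        std = fit_standardizer(table, defn.features, train_ids)
        standardizers[defn.name] = std
        vals = compute_index(defn, table, std).values
        tr_cols[defn.name] = vals[train_ids]
        te_cols[defn.name] = vals[test_ids]
    x_train = pd.DataFrame(tr_cols, index=train_ids)
    x_test = pd.DataFrame(te_cols, index=test_ids)
    if not np.isfinite(x_train.to_numpy()).all() or not np.isfinite(x_test.to_numpy()).all():
        raise ValueError(f"non-finite panel features in fold {pair_id!r}")
    return FoldData(pair_id, tuple(train_ids), tuple(test_ids), x_train, x_test, standardizers)


def lopo_folds(
    tables: dict[str, FeatureTable], design: MatchedDesign, panel: PanelSpec
) -> list[FoldData]:
    """Build the n leakage-safe folds (one held-out pair each)."""
    if design.n_pairs < 3:
        raise ValueError("LOPO needs at least 3 pairs")
    if panel.n_features == 0:
        raise ValueError("panel has no features")
    folds = []
    for pid, a, b in design.pairs:
        train_ids = [s for q, x, y in design.pairs if q != pid for s in (x, y)]
        folds.append(_build_fold(tables, panel, pid, train_ids, [a, b]))
    return folds


def _run_lopo(
    folds: list[FoldData],
    design: MatchedDesign,
    config: LopoModelConfig,
    rf_seed: int,
    mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """One full LOPO pass under an optional within-pair swap mask."""
    n = design.n_pairs
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    members = design.swapped_members(mask)  # (region-A id, region-B id) per pair
    label_of = {}
    for a, b in members:
        label_of[a] = 1  # region A = positive class
        label_of[b] = 0
    rows = []
    for fold in folds:
        y_train = np.array([label_of[s] for s in fold.train_ids])
        clf = RandomForestClassifier(
            n_estimators=config.trees,
            max_depth=config.max_depth,
            random_state=rf_seed,
        )
        clf.fit(fold.x_train.to_numpy(), y_train)
        prob = clf.predict_proba(fold.x_test.to_numpy())
        pos_col = int(np.where(clf.classes_ == 1)[0][0])
        for sid, p in zip(fold.test_ids, prob[:, pos_col]):
            rows.append(
                {
                    "fold": fold.pair_id,
                    "composite": sid,
                    "truth": label_of[sid],
                    "probability": float(p),
                }
            )
    pred = pd.DataFrame(rows)
    auc = float(roc_auc_score(pred["truth"], pred["probability"]))
    return pred, auc


def lopo_classify(
    tables: dict[str, FeatureTable],
    design: MatchedDesign,
    panel: PanelSpec,
    config: LopoModelConfig | None = None,
    seed: int = 0,
) -> LopoResult:
    """Observed LOPO run: pooled out-of-fold probabilities and midrank AUC."""
    config = config or LopoModelConfig()
    folds = lopo_folds(tables, design, panel)
    rf_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    pred, auc = _run_lopo(folds, design, config, rf_seed)
    return LopoResult(pred, auc)


def lopo_permutation_null(
    tables: dict[str, FeatureTable],
    design: MatchedDesign,
    panel: PanelSpec,
    config: LopoModelConfig | None = None,
    seed: int = 0,
) -> LopoResult:
    """Exact pair-respecting permutation test of the LOPO AUC.

    Reruns the LOPO loop for every within-pair relabeling with the
    classifier seed held fixed; returns the observed result plus the full
    null AUC vector (identity first) and the +1-adjusted exact p.
    """
    config = config or LopoModelConfig()
    n = design.n_pairs
    if n > LOPO_NULL_GUARD:
        raise ValueError(
            f"2^{n} LOPO reruns exceed the guard ({LOPO_NULL_GUARD} pairs); "
            "subsample relabelings instead"
        )
    folds = lopo_folds(tables, design, panel)
    rf_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    masks = enumerate_relabelings(n)
    null = np.empty(len(masks))
    pred_obs = None
    for i, mask in enumerate(masks):
        pred, auc = _run_lopo(folds, design, config, rf_seed, mask)
        null[i] = auc
        if i == 0:
            pred_obs = pred
    observed = null[0]
    n_nonid = len(masks) - 1
    p = (1 + int(np.count_nonzero(null[1:] >= observed))) / (1 + n_nonid)
    return LopoResult(pred_obs, float(observed), null, float(p))
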