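"""End-to-end pipeline: data → indices → paired tests → community → audit → LOPO.

A :class:`RunConfig` (YAML-expressible) either names input TSV paths or
embeds a synthetic :class:`~teaterroir.synthetic.CohortSpec`. ``run_all``
executes every stage deterministically under the global seed (per-stage
seeds are derived by hashing the stage name, so stages never share a
stream), writes each stage's TSV outputs into the output directory, and
finishes with a machine-readable manifest (config hash, library versions,
per-file SHA-256) so identical configs can be verified to give identical
results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (
    bray_curtis,
    dbrda_pair_test,
    dispersion_test,
    pcoa,
    permanova_pair_test,
    procrustes_pair_test,
)
from .coretaxa import CoreDefinition, audit_grid, audit_null
from .indices import default_definitions, compute_index, fit_standardizer, index_deltas
from .lopo import (
    LopoModelConfig,
    PanelSpec,
    complete_case_design,
    lopo_classify,
    lopo_permutation_null,
)
from .paired import (
    bh_fdr,
    cohens_dz,
    delta_spearman,
    exact_sign_test,
    mcnemar_exact,
    paired_t,
    wilcoxon_signed_rank,
)
from .synthetic import CohortSpec, generate_cohort
from .tables import FeatureTable, MatchedDesign, paired_deltas, rarefy, read_design


class ConfigError(ValueError):
    """Invalid run configuration; message lists every problem found."""


_DEFAULT_FAMILIES = {
    "indices": [["index", "VSI"], ["index", "NPI"]],
    "nonvolatile": [
        ["nonvolatile", "EGCG"],
        ["nonvolatile", "caffeine"],
        ["nonvolatile", "theanine"],
    ],
    "soil": [["soil", "OM"], ["soil", "TN"], ["soil", "TK"]],
}

_DEFAULT_COVARIATES = [
    ["soil", "pH"],
    ["soil", "OM"],
    ["soil", "TN"],
    ["soil", "sucrase"],
    ["index", "VSI"],
    ["index", "NPI"],
]

_DEFAULT_PANEL_RAW = [
    ["nonvolatile", "EGCG"],
    ["nonvolatile", "caffeine"],
    ["nonvolatile", "theanine"],
    ["soil", "pH"],
    ["soil", "OM"],
    ["soil", "TN"],
    ["soil", "sucrase"],
]

_KNOWN_KEYS = {
    "synthetic",
    "inputs",
    "seed",
    "outdir",
    "rarefy",
    "families",
    "core",
    "covariates",
    "lopo",
    "n_unrestricted",
}


@dataclass
class RunConfig:
    synthetic: CohortSpec | None = None
    inputs: dict | None = None  # paths: design, volatile, nonvolatile, ...
    seed: int = 0
    outdir: str = "terroir_run"
    rarefy_depth: dict = field(
        default_factory=lambda: {"bacteria": None, "fungi": None}
    )
    families: dict = field(default_factory=lambda: dict(_DEFAULT_FAMILIES))
    core: CoreDefinition = field(default_factory=CoreDefinition)
    covariates: list = field(default_factory=lambda: list(_DEFAULT_COVARIATES))
    panel_raw: list = field(default_factory=lambda: list(_DEFAULT_PANEL_RAW))
    lopo_trees: int = 200
    lopo_null: bool = True
    n_unrestricted: int = 999


def _stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def validate_config(path: str | Path) -> RunConfig:
    """Parse + validate a YAML config, filling defaults; lists all problems."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    problems: list[str] = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        problems.append(f"unknown config keys: {sorted(unknown)}")
    if ("synthetic" in raw) == ("inputs" in raw):
        problems.append("config must have exactly one of 'synthetic' or 'inputs'")

    cfg = RunConfig()
    cfg.seed = int(raw.get("seed", 0))
    cfg.outdir = str(raw.get("outdir", cfg.outdir))
    cfg.n_unrestricted = int(raw.get("n_unrestricted", 999))

    if "synthetic" in raw:
        try:
            syn = dict(raw["synthetic"] or {})
            syn.setdefault("seed", cfg.seed)
            if "region_labels" in syn:
                syn["region_labels"] = tuple(syn["region_labels"])
            cfg.synthetic = CohortSpec(**syn)
        except (TypeError, ValueError) as exc:
            problems.append(f"synthetic: {exc}")
    if "inputs" in raw:
        cfg.inputs = dict(raw["inputs"])
        for key in ("design", "volatile", "nonvolatile", "etongue", "soil",
                    "bacteria", "fungi"):
            p = cfg.inputs.get(key)
            if p is None:
                problems.append(f"inputs: missing path for {key!r}")
            elif not Path(p).exists():
                problems.append(f"inputs: path does not exist: {p}")
    if "rarefy" in raw:
        cfg.rarefy_depth.update(raw["rarefy"] or {})
    if "families" in raw:
        cfg.families = {k: [list(x) for x in v] for k, v in raw["families"].items()}
    if "core" in raw:
        c = raw["core"] or {}
        try:
            cfg.core = CoreDefinition(
                float(c.get("prevalence_threshold", 0.70)),
                float(c.get("abundance_threshold", 0.001)),
                float(c.get("intermittent_low", 0.30)),
            )
        except ValueError as exc:
            problems.append(f"core: {exc}")
    if "covariates" in raw:
        cfg.covariates = [list(x) for x in raw["covariates"]]
    if "lopo" in raw:
        lo = raw["lopo"] or {}
        cfg.lopo_trees = int(lo.get("trees", 200))
        cfg.lopo_null = bool(lo.get("null", True))
        if "raw_features" in lo:
            cfg.panel_raw = [list(x) for x in lo["raw_features"]]
        if cfg.lopo_trees < 1:
            problems.append("lopo: trees must be ≥ 1")

    if problems:
        raise ConfigError("; ".join(problems))
    return cfg


def _load_data(cfg: RunConfig) -> tuple[MatchedDesign, dict[str, FeatureTable], dict]:
    if cfg.synthetic is not None:
        bundle = generate_cohort(cfg.synthetic)
        return bundle.design, bundle.tables(), bundle.truth
    kinds = {
        "volatile": "volatile",
        "nonvolatile": "nonvolatile",
        "etongue": "etongue",
        "soil": "soil",
        "bacteria": "genus_counts",
        "fungi": "genus_counts",
    }
    design = read_design(cfg.inputs["design"])
    tables = {
        key: FeatureTable.read_tsv(cfg.inputs[key], kind)
        for key, kind in kinds.items()
    }
    return design, tables, {}


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns a summary dict and writes TSVs + manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design, tables, truth = _load_data(cfg)
    summary: dict = {"n_pairs": design.n_pairs}

    if cfg.synthetic is not None:
        design.write_tsv(outdir / "design.tsv")
        for name, t in tables.items():
            t.write_tsv(outdir / f"{name}.tsv")

    # ---- indices --------------------------------------------------------
    vsi_def, npi_def = default_definitions()
    std_v = fit_standardizer(tables["volatile"], vsi_def.features)
    std_n = fit_standardizer(tables["nonvolatile"], npi_def.features)
    vsi = compute_index(vsi_def, tables["volatile"], std_v)
    npi = compute_index(npi_def, tables["nonvolatile"], std_n)
    idx_df = pd.DataFrame(
        {
            "VSI": vsi.values, "VSI_pos": vsi.positive_scores,
            "VSI_neg": vsi.negative_scores,
            "NPI": npi.values, "NPI_pos": npi.positive_scores,
            "NPI_neg": npi.negative_scores,
        }
    )
    idx_df.index.name = "composite_id"
    idx_df.to_csv(outdir / "indices.tsv", sep="\t")
    index_table = FeatureTable(idx_df[["VSI", "NPI"]].T, "generic")
    d_vsi = index_deltas(vsi, design)
    d_npi = index_deltas(npi, design)
    summary["delta_VSI_median"] = d_vsi.median
    summary["delta_VSI_n_pos"] = d_vsi.delta.n_pos
    summary["delta_NPI_median"] = d_npi.median

    # ---- paired tests ---------------------------------------------------
    table_lookup = dict(tables)
    table_lookup["index"] = index_table
    rows, fam_ps = [], {}
    dz_seed = _stage_seed(cfg.seed, "dz_bootstrap")
    for family, feats in cfg.families.items():
        ps = []
        for tkey, feat in feats:
            delta = paired_deltas(table_lookup[tkey], design, feat)
            sign = exact_sign_test(delta)
            wil = wilcoxon_signed_rank(delta)
            try:
                tt = paired_t(delta)
                dz = cohens_dz(delta, seed=dz_seed)
            except ValueError:
                tt = dz = None
            for res in (sign, wil, tt):
                if res is None:
                    continue
                rows.append(
                    {
                        "family": family, "feature": feat, "test": res.test,
                        "n": res.n_effective, "statistic": res.statistic,
                        "p": res.p,
                        "dz": dz.dz if dz else np.nan,
                        "ci_low": dz.ci_low if dz else np.nan,
                        "ci_high": dz.ci_high if dz else np.nan,
                    }
                )
            ps.append(sign.p)
        fam_ps[family] = ps
    adj = bh_fdr(fam_ps)
    paired_df = pd.DataFrame(rows)
    adj_map = {
        (fam, feats[i][1]): adj[fam][i]
        for fam, feats in ((f, cfg.families[f]) for f in cfg.families)
        for i in range(len(feats))
    }
    paired_df["p_adjusted_sign"] = [
        adj_map[(r.family, r.feature)] for r in paired_df.itertuples()
    ]
    paired_df.to_csv(outdir / "paired_tests.tsv", sep="\t", index=False)
    summary["n_sign_tests_adjusted_below_0.05"] = int(
        sum(np.sum(v < 0.05) for v in adj.values())
    )

    # within-pair delta association: does the soil TN gradient track theanine?
    try:
        d_tn = paired_deltas(tables["soil"], design, "TN")
        d_th = paired_deltas(tables["nonvolatile"], design, "theanine")
        common = [p for p in d_tn.pair_ids if p in d_th.pair_ids]
        x = [d_tn.deltas[d_tn.pair_ids.index(p)] for p in common]
        y = [d_th.deltas[d_th.pair_ids.index(p)] for p in common]
        rho, p_rho = delta_spearman(x, y)
        summary["spearman_dTN_dtheanine_rho"] = rho
        summary["spearman_dTN_dtheanine_p"] = p_rho
    except (KeyError, ValueError):
        pass

    # hurdle volatile: detect/non-detect McNemar
    try:
        bc = tables["volatile"].values_for("beta-caryophyllene")
        det_a = [bc[a] > 0 for _, a, _ in design.pairs]
        det_b = [bc[b] > 0 for _, _, b in design.pairs]
        mc = mcnemar_exact(det_a, det_b)
        summary["mcnemar_p_hurdle"] = mc.p
    except KeyError:
        pass

    # ---- community ------------------------------------------------------
    comm_rows = []
    ordinations = {}
    rare_seed = _stage_seed(cfg.seed, "rarefaction")
    unres_seed = _stage_seed(cfg.seed, "unrestricted")
    for kingdom in ("bacteria", "fungi"):
        t = tables[kingdom]
        depth = cfg.rarefy_depth.get(kingdom)
        if depth:
            t = rarefy(t, int(depth), rare_seed)
        rel = t.relative_abundance()
        dm = bray_curtis(rel)
        ordinations[kingdom] = pcoa(dm.reorder(design.sample_ids))
        perma = permanova_pair_test(dm, design, cfg.n_unrestricted, unres_seed)
        disp = dispersion_test(dm, design, cfg.n_unrestricted, unres_seed)
        for res in (perma, disp):
            comm_rows.append(
                {
                    "kingdom": kingdom, "statistic": res.kind,
                    "value": res.value, "p_pair": res.p_pair,
                    "p_unrestricted": res.p_unrestricted,
                }
            )
        summary[f"permanova_p_pair_{kingdom}"] = perma.p_pair
        coords = pd.DataFrame(
            ordinations[kingdom].coordinates,
            index=design.sample_ids,
            columns=[f"PCo{i+1}" for i in range(ordinations[kingdom].coordinates.shape[1])],
        )
        coords.index.name = "composite_id"
        coords.to_csv(outdir / f"pcoa_{kingdom}.tsv", sep="\t")

    proc = procrustes_pair_test(
        ordinations["bacteria"], ordinations["fungi"], design,
        cfg.n_unrestricted, unres_seed,
    )
    comm_rows.append(
        {
            "kingdom": "cross", "statistic": proc.kind, "value": proc.value,
            "p_pair": proc.p_pair, "p_unrestricted": proc.p_unrestricted,
        }
    )
    summary["procrustes_m2"] = proc.value
    summary["procrustes_p_pair"] = proc.p_pair

    cov_cols = {}
    for tkey, feat in cfg.covariates:
        cov_cols[f"{tkey}:{feat}"] = table_lookup[tkey].values_for(feat)
    covariates = pd.DataFrame(cov_cols).loc[design.sample_ids]
    t_bact = tables["bacteria"]
    depth = cfg.rarefy_depth.get("bacteria")
    if depth:
        t_bact = rarefy(t_bact, int(depth), rare_seed)
    dbrda = dbrda_pair_test(
        bray_curtis(t_bact.relative_abundance()), covariates, design,
        cfg.n_unrestricted, unres_seed,
    )
    comm_rows.append(
        {
            "kingdom": "bacteria", "statistic": dbrda.kind, "value": dbrda.value,
            "p_pair": dbrda.p_pair, "p_unrestricted": dbrda.p_unrestricted,
        }
    )
    summary["dbrda_adj_r2"] = dbrda.value
    summary["dbrda_p_pair"] = dbrda.p_pair
    pd.DataFrame(comm_rows).to_csv(outdir / "community_tests.tsv", sep="\t", index=False)

    # ---- core-taxa audit ------------------------------------------------
    for kingdom in ("bacteria", "fungi"):
        rel = tables[kingdom].relative_abundance()
        try:
            grid = audit_grid(rel, design, cfg.core)
            nul = audit_null(rel, design, cfg.core)
        except ValueError as exc:
            summary[f"audit_{kingdom}"] = f"skipped: {exc}"
            continue
        grid.cells.to_csv(outdir / f"audit_grid_{kingdom}.tsv", sep="\t", index=False)
        grid.per_genus.to_csv(
            outdir / f"audit_genera_{kingdom}.tsv", sep="\t", index=False
        )
        summary[f"audit_direction_consistency_{kingdom}"] = (
            nul.observed_direction_consistency
        )
        summary[f"audit_null_exceedance_{kingdom}"] = nul.exceedance_direction

    # ---- LOPO -----------------------------------------------------------
    vsi_def, npi_def = default_definitions()
    panel = PanelSpec(
        raw_features=tuple((k, f) for k, f in cfg.panel_raw),
        index_features=((vsi_def, "volatile"), (npi_def, "nonvolatile")),
    )
    lopo_design = complete_case_design(tables, design, panel)
    model = LopoModelConfig(trees=cfg.lopo_trees)
    lopo_seed = _stage_seed(cfg.seed, "lopo")
    if cfg.lopo_null:
        lres = lopo_permutation_null(tables, lopo_design, panel, model, lopo_seed)
        summary["lopo_p"] = lres.p_value
        pd.DataFrame({"auc": lres.null_auc}).to_csv(
            outdir / "lopo_null_auc.tsv", sep="\t", index=False
        )
    else:
        lres = lopo_classify(tables, lopo_design, panel, model, lopo_seed)
    lres.predictions.to_csv(outdir / "lopo_predictions.tsv", sep="\t", index=False)
    summary["lopo_auc"] = lres.auc

    # ---- manifest -------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(summary_config(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.glob("*.tsv"))
        },
        "summary": _jsonable(summary),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return summary


def summary_config(cfg: RunConfig) -> dict:
    d = {
        "seed": cfg.seed,
        "families": cfg.families,
        "covariates": cfg.covariates,
        "panel_raw": cfg.panel_raw,
        "lopo_trees": cfg.lopo_trees,
        "core": [cfg.core.prevalence_threshold, cfg.core.abundance_threshold],
        "rarefy": cfg.rarefy_depth,
    }
    if cfg.synthetic is not None:
        from dataclasses import asdict

        d["synthetic"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg.synthetic).items()
        }
    else:
        d["inputs"] = cfg.inputs
    return d


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        out[k] = v
    return out
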