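"""Synthetic genotype-matched cohort generator.

Emulates the statistical structure the downstream analyses assume for a
matched-pair terroir study: n cultivar pairs (default 8), each pair one
composite per region, with

* a volatile layer (Area%, columns renormalized to 100) in which a fixed
  floral/fruity set (linalool, geraniol, linalool oxide, decanal) receives
  a uniform standardized region shift, and a hurdle sesquiterpene
  (β-caryophyllene) is detected in region B with probability 7/8 per pair
  and never in region A — non-detects stored as exact 0;
* a non-volatile layer in which EGCG- and caffeine-like analytes shift
  pair-consistently (EC/CG-like analytes shift the opposite way) while the
  theanine-like analyte gets a mean-zero, between-pair-varying shift, so
  its delta signs are mixed;
* an e-tongue layer (5 attributes) with a configurable number of
  composites missing entirely;
* a soil/enzyme layer with its own region shifts (OM/TN/HN up in region A,
  TK and urease down);
* genus-level bacterial and fungal count tables from a logistic-normal /
  multinomial compositional model: per-genus baselines, per-pair latent
  site factors shared across kingdoms (scaled by ``cross_kingdom_rho``),
  a log-fold region effect on a designated 20% subset of genera, and
  per-sample noise; every column sums to the requested depth.

Regenerating with the same spec and seed is byte-identical, and
:func:`truth_record` exposes the simulated ground truth for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tables import FeatureTable, MatchedDesign


class CohortSpecError(ValueError):
    """A cohort parameter is out of range; the message names the field."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic matched-pair cohort.

    Effects are standardized shifts: the region contrast is ``effect`` times
    the between-composite standard deviation of the affected variable.
    ``contingent_sd`` sets the between-pair SD of the mean-zero
    theanine-like shift; ``microbe_effect`` is a log-fold change split
    evenly between up- and down-shifted genera.
    """

    n_pairs: int = 8
    region_labels: tuple[str, str] = ("Menghai", "Puer")
    volatile_effect: float = 1.0
    hurdle_prob_b: float = 7 / 8
    hurdle_prob_a: float = 0.0
    stable_nonvolatile_effect: float = 0.8
    contingent_sd: float = 1.5
    soil_effect: float = 1.2
    microbe_effect: float = 1.0
    cross_kingdom_rho: float = 0.6
    depth: int = 50_000
    missing_etongue: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise CohortSpecError("n_pairs must be ≥ 2")
        for name in ("hurdle_prob_b", "hurdle_prob_a"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortSpecError(f"{name} must be in [0, 1]")
        if self.depth <= 0:
            raise CohortSpecError("depth must be > 0")
        if self.missing_etongue < 0 or self.missing_etongue > 2 * self.n_pairs:
            raise CohortSpecError("missing_etongue must be in [0, 2·n_pairs]")
        if self.contingent_sd < 0:
            raise CohortSpecError("contingent_sd must be ≥ 0")
        if len(self.region_labels) != 2 or self.region_labels[0] == self.region_labels[1]:
            raise CohortSpecError("region_labels must be two distinct names")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["region_labels"] = list(d["region_labels"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "region_labels" in d:
            d["region_labels"] = tuple(d["region_labels"])
        return cls(**d)


@dataclass(frozen=True)
class CohortBundle:
    design: MatchedDesign
    volatile: FeatureTable
    nonvolatile: FeatureTable
    etongue: FeatureTable
    soil: FeatureTable
    bacteria: FeatureTable
    fungi: FeatureTable
    truth: dict

    def tables(self) -> dict[str, FeatureTable]:
        return {
            "volatile": self.volatile,
            "nonvolatile": self.nonvolatile,
            "etongue": self.etongue,
            "soil": self.soil,
            "bacteria": self.bacteria,
            "fungi": self.fungi,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.design.write_tsv(outdir / "design.tsv")
        for name, t in self.tables().items():
            t.write_tsv(outdir / f"{name}.tsv")


# Noise scales (fractions of the feature mean, or SD on the log scale).
# Pair-level variation dominates within-composite noise, which is what makes
# a within-pair design powerful at these effect sizes.
_VOL_PAIR_SD = 0.35  # log-Area latent, between cultivar pairs
_VOL_EPS_SD = 0.15  # log-Area latent, within composite
_NV_PAIR_FRAC = 0.13
_NV_EPS_FRAC = 0.03
_SOIL_PAIR_FRAC = 0.10
_SOIL_EPS_FRAC = 0.03
_ET_PAIR_SD = 0.8
_ET_EPS_SD = 0.25

_FLORAL = ("linalool", "geraniol", "linalool oxide", "decanal")
_WOODY_CONT = "1-octen-3-ol"
_HURDLE = "beta-caryophyllene"
_FILLER_VOLATILES = (
    "hexanal", "nonanal", "benzaldehyde", "phenylethyl alcohol",
    "methyl salicylate", "cis-3-hexenol", "alpha-terpineol", "nerolidol",
    "indole", "beta-ionone", "geranyl acetone", "limonene", "ocimene",
    "2-heptanone", "benzyl alcohol", "safranal", "theaspirane",
    "dihydroactinidiolide",
)

# (mean level, direction of the stable region shift: +1 up in region A)
_NONVOLATILES = {
    "caffeine": (35.0, +1),
    "EGCG": (80.0, +1),
    "ECG": (20.0, 0),
    "EGC": (15.0, 0),
    "EC": (8.0, -1),
    "C": (2.0, 0),
    "CG": (1.5, -1),
    "GA": (1.0, 0),
    "theanine": (18.0, 0),  # contingent: mean-zero pair-varying shift
    "GABA": (0.3, 0),
}

_ETONGUE = {
    "sourness": (-5.0, 0),
    "bitterness": (6.0, -1),
    "umami": (5.0, 0),
    "astringency": (4.0, -1),
    "aftertaste": (3.0, 0),
}

_SOIL = {
    "pH": (5.0, 0),
    "OM": (35.0, +1),
    "TN": (1.8, +1),
    "HN": (120.0, +1),
    "TK": (12.0, -1),
    "AP": (15.0, 0),
    "AK": (90.0, 0),
    "urease": (45.0, -1),
    "sucrase": (20.0, 0),
    "acid_phosphatase": (800.0, 0),
    "beta_glucosidase": (150.0, +1),
    "catalase": (12.0, 0),
}

_N_BACTERIA = 60
_N_FUNGI = 40
_AFFECTED_FRACTION = 0.2
_MIC_BASE_SD = 1.5
_MIC_LOADING_SD = 0.4
_MIC_EPS_SD = 0.25


def _layer_values(
    rng: np.random.Generator,
    means: np.ndarray,
    dirs: np.ndarray,
    pair_frac: float,
    eps_frac: float,
    effect: float,
    n_pairs: int,
) -> np.ndarray:
    """Additive layer: mean + pair effect + noise + region shift (features × 2n).

    Columns are pair-major, region A first. The shift is ``effect`` times
    the between-composite SD (sqrt(pair² + eps²)) applied in region A with
    the per-feature direction.
    """
    n_feat = len(means)
    sd_pair = pair_frac * np.abs(means)
    sd_eps = eps_frac * np.abs(means)
    sd_x = np.sqrt(sd_pair**2 + sd_eps**2)
    pair_eff = rng.normal(0.0, 1.0, size=(n_feat, n_pairs)) * sd_pair[:, None]
    eps = rng.normal(0.0, 1.0, size=(n_feat, 2 * n_pairs)) * sd_eps[:, None]
    vals = np.empty((n_feat, 2 * n_pairs))
    for i in range(n_pairs):
        base = means[:, None] + pair_eff[:, [i]]
        vals[:, 2 * i] = base[:, 0] + eps[:, 2 * i] + effect * dirs * sd_x
        vals[:, 2 * i + 1] = base[:, 0] + eps[:, 2 * i + 1]
    return vals


def _genus_counts(
    rng: np.random.Generator,
    genus_ids: list[str],
    n_pairs: int,
    site_factor: np.ndarray,
    rho: float,
    effect: float,
    depth: int,
) -> tuple[np.ndarray, list[str], dict[str, int]]:
    """Multinomial counts from a logistic-normal model; returns (counts,
    affected genus ids, direction per affected genus)."""
    n_gen = len(genus_ids)
    base = np.sort(rng.normal(0.0, _MIC_BASE_SD, size=n_gen))[::-1]
    loadings = rng.normal(0.0, _MIC_LOADING_SD, size=n_gen)
    kingdom_factor = rng.normal(0.0, 1.0, size=n_pairs)
    rho = float(np.clip(rho, -1.0, 1.0))
    pair_factor = rho * site_factor + np.sqrt(1.0 - rho**2) * kingdom_factor

    n_aff = int(round(_AFFECTED_FRACTION * n_gen)) if effect != 0 else 0
    aff_idx = rng.choice(n_gen, size=n_aff, replace=False) if n_aff else np.array([], int)
    dirs = np.zeros(n_gen)
    signs = {}
    for j, gi in enumerate(aff_idx):
        s = 1 if j % 2 == 0 else -1
        dirs[gi] = s
        signs[genus_ids[gi]] = s

    counts = np.empty((n_gen, 2 * n_pairs), dtype=np.int64)
    for i in range(n_pairs):
        for r in range(2):  # r=0 region A, r=1 region B
            eta = (
                base
                + loadings * pair_factor[i]
                + rng.normal(0.0, _MIC_EPS_SD, size=n_gen)
                + (effect / 2.0) * dirs * (1 if r == 0 else -1)
            )
            p = np.exp(eta - eta.max())
            p /= p.sum()
            counts[:, 2 * i + r] = rng.multinomial(depth, p)
    affected = [genus_ids[i] for i in sorted(aff_idx)]
    return counts, affected, signs


def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Generate the full synthetic bundle; deterministic under spec.seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pairs
    ra, rb = spec.region_labels
    cultivars = [f"cv{i + 1:02d}" for i in range(n)]
    pairs = tuple((cv, f"{cv}_{ra}", f"{cv}_{rb}") for cv in cultivars)
    design = MatchedDesign(pairs, (ra, rb))
    cols = design.sample_ids
    truth: dict = {"spec": asdict(spec)}

    # ---- volatiles (latent log-Area, floral shift in region A) ----------
    vol_names = list(_FLORAL) + [_WOODY_CONT] + list(_FILLER_VOLATILES)
    n_vol = len(vol_names)
    base = rng.uniform(-1.5, 1.5, size=n_vol)
    dirs = np.array([1.0 if v in _FLORAL else 0.0 for v in vol_names])
    sd_x = np.sqrt(_VOL_PAIR_SD**2 + _VOL_EPS_SD**2)
    pair_eff = rng.normal(0.0, _VOL_PAIR_SD, size=(n_vol, n))
    eps = rng.normal(0.0, _VOL_EPS_SD, size=(n_vol, 2 * n))
    log_area = np.empty((n_vol, 2 * n))
    for i in range(n):
        log_area[:, 2 * i] = (
            base + pair_eff[:, i] + eps[:, 2 * i] + spec.volatile_effect * dirs * sd_x
        )
        log_area[:, 2 * i + 1] = base + pair_eff[:, i] + eps[:, 2 * i + 1]
    raw = np.exp(log_area)

    # hurdle sesquiterpene: Bernoulli(detect) × log-normal Area% target
    det_a = rng.random(n) < spec.hurdle_prob_a
    det_b = rng.random(n) < spec.hurdle_prob_b
    target_pct = np.exp(rng.normal(np.log(0.08), 0.25, size=(n, 2)))
    bc_row = np.zeros(2 * n)
    for i in range(n):
        for r, det in ((0, det_a[i]), (1, det_b[i])):
            if det:
                t = float(np.clip(target_pct[i, r], 0.02, 0.5))
                total_others = raw[:, 2 * i + r].sum()
                # raw value whose share of the renormalized column is t percent
                bc_row[2 * i + r] = t / (100.0 - t) * total_others
    raw = np.vstack([raw, bc_row])
    vol_names = vol_names + [_HURDLE]
    area_pct = raw / raw.sum(axis=0, keepdims=True) * 100.0
    volatile = FeatureTable(pd.DataFrame(area_pct, index=vol_names, columns=cols), "volatile")
    truth["hurdle_detect"] = {ra: det_a.tolist(), rb: det_b.tolist()}

    # ---- non-volatiles ---------------------------------------------------
    nv_names = list(_NONVOLATILES)
    nv_means = np.array([_NONVOLATILES[k][0] for k in nv_names])
    nv_dirs = np.array([float(_NONVOLATILES[k][1]) for k in nv_names])
    nv = _layer_values(
        rng, nv_means, nv_dirs, _NV_PAIR_FRAC, _NV_EPS_FRAC,
        spec.stable_nonvolatile_effect, n,
    )
    # contingent theanine shift: mean-zero between-pair delta
    ti = nv_names.index("theanine")
    sd_the = np.sqrt(_NV_PAIR_FRAC**2 + _NV_EPS_FRAC**2) * nv_means[ti]
    the_shift = rng.normal(0.0, spec.contingent_sd * sd_the, size=n)
    for i in range(n):
        nv[ti, 2 * i] += the_shift[i] / 2.0
        nv[ti, 2 * i + 1] -= the_shift[i] / 2.0
    nonvolatile = FeatureTable(pd.DataFrame(nv, index=nv_names, columns=cols), "nonvolatile")
    truth["theanine_shift"] = the_shift.tolist()
    truth["nonvolatile_means"] = dict(zip(nv_names, nv_means.tolist()))
    truth["stable_directions"] = {
        k: int(v[1]) for k, v in _NONVOLATILES.items() if v[1] != 0
    }

    # ---- e-tongue --------------------------------------------------------
    et_names = list(_ETONGUE)
    et_means = np.array([_ETONGUE[k][0] for k in et_names])
    et_dirs = np.array([float(_ETONGUE[k][1]) for k in et_names])
    sd_et = np.sqrt(_ET_PAIR_SD**2 + _ET_EPS_SD**2)
    pair_eff = rng.normal(0.0, _ET_PAIR_SD, size=(len(et_names), n))
    eps = rng.normal(0.0, _ET_EPS_SD, size=(len(et_names), 2 * n))
    et = np.empty((len(et_names), 2 * n))
    for i in range(n):
        et[:, 2 * i] = (
            et_means + pair_eff[:, i] + eps[:, 2 * i]
            + spec.stable_nonvolatile_effect * et_dirs * sd_et
        )
        et[:, 2 * i + 1] = et_means + pair_eff[:, i] + eps[:, 2 * i + 1]
    missing = rng.choice(2 * n, size=spec.missing_etongue, replace=False)
    et[:, missing] = np.nan
    etongue = FeatureTable(pd.DataFrame(et, index=et_names, columns=cols), "etongue")
    truth["missing_etongue"] = [cols[j] for j in sorted(missing)]

    # ---- soil ------------------------------------------------------------
    soil_names = list(_SOIL)
    soil = _layer_values(
        rng,
        np.array([_SOIL[k][0] for k in soil_names]),
        np.array([float(_SOIL[k][1]) for k in soil_names]),
        _SOIL_PAIR_FRAC, _SOIL_EPS_FRAC, spec.soil_effect, n,
    )
    soil_t = FeatureTable(pd.DataFrame(soil, index=soil_names, columns=cols), "soil")

    # ---- microbes: shared latent site factor across kingdoms ------------
    site_factor = rng.normal(0.0, 1.0, size=n)
    bact_ids = [f"g_bact{i + 1:03d}" for i in range(_N_BACTERIA)]
    fung_ids = [f"g_fung{i + 1:03d}" for i in range(_N_FUNGI)]
    bact_counts, bact_aff, bact_signs = _genus_counts(
        rng, bact_ids, n, site_factor, spec.cross_kingdom_rho,
        spec.microbe_effect, spec.depth,
    )
    fung_counts, fung_aff, fung_signs = _genus_counts(
        rng, fung_ids, n, site_factor, spec.cross_kingdom_rho,
        spec.microbe_effect, spec.depth,
    )
    bacteria = FeatureTable(pd.DataFrame(bact_counts, index=bact_ids, columns=cols), "genus_counts")
    fungi = FeatureTable(pd.DataFrame(fung_counts, index=fung_ids, columns=cols), "genus_counts")
    truth["affected_bacteria"] = bact_aff
    truth["affected_fungi"] = fung_aff
    truth["genus_effect_sign"] = {**bact_signs, **fung_signs}
    truth["site_factor"] = site_factor.tolist()

    return CohortBundle(
        design, volatile, nonvolatile, etongue, soil_t, bacteria, fungi, truth
    )


def truth_record(spec: CohortSpec) -> dict:
    """Ground truth of the cohort a given spec generates.

    Includes the affected-genus sets (empty when ``microbe_effect`` is 0),
    the per-pair theanine-like shifts, the hurdle detection draws, and the
    population means of the non-volatile analytes.
    """
    return generate_cohort(spec).truth
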