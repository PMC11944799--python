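"""Seeded synthetic datasets with the statistical structure the analysis assumes.

The generator emulates a 41-plot saline-cropland survey: four crop groups
(soybean 10, cotton 11, sorghum 5, maize 15), per-crop nutrient means/SDs
from the study's physicochemical summary, lognormal species-abundance
distributions with both a >0.05% and a <0.001% relative-abundance tail, and
a planted causal chain

    salinity -> rare bacterial Shannon -> MNC   (+0.40, -0.31)
    rare fungal Shannon -> MNC                  (+0.47)

whose standardized magnitudes are recorded in a *truth* dictionary for
parameter-recovery tests. Effects are planted on the pooled (cross-crop)
standardized scale: the diversity -> nutrient coupling shifts the seven MNC
nutrients linearly in the *realized* standardized Shannon values, so the
generative arrows match the fitted path model and recovery is well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import alpha_diversity
from .tables import MNC_VARIABLES, NUTRIENT_VARIABLES, NutrientTable, OTUTable
from .taxa import classify_taxa, subset_by_class

__all__ = [
    "SynthConfig",
    "CoupledDataset",
    "generate_nutrients",
    "generate_otu_table",
    "generate_coupled_dataset",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_CROP_NUTRIENTS",
]

#: Study design: plots per crop.
DEFAULT_GROUP_SIZES = {"soybean": 10, "cotton": 11, "sorghum": 5, "maize": 15}

#: Per-crop (mean, SD) for each soil variable, in the units of
#: :data:`rarecycle.tables.NUTRIENT_UNITS`.
DEFAULT_CROP_NUTRIENTS: dict[str, dict[str, tuple[float, float]]] = {
    "pH":      {"soybean": (8.64, 0.08), "sorghum": (8.53, 0.02), "cotton": (8.65, 0.07), "maize": (8.59, 0.05)},
    "salt":    {"soybean": (0.76, 0.13), "sorghum": (1.34, 0.19), "cotton": (1.69, 0.26), "maize": (0.74, 0.12)},
    "BD":      {"soybean": (1.37, 0.02), "sorghum": (1.46, 0.03), "cotton": (1.43, 0.03), "maize": (1.39, 0.03)},
    "SWC":     {"soybean": (11.51, 1.17), "sorghum": (18.70, 1.73), "cotton": (16.29, 1.25), "maize": (14.07, 1.58)},
    "NH4_N":   {"soybean": (1.29, 0.09), "sorghum": (2.75, 0.24), "cotton": (2.53, 0.10), "maize": (2.56, 0.10)},
    "NO3_N":   {"soybean": (45.6, 13.87), "sorghum": (99.0, 9.98), "cotton": (79.7, 13.97), "maize": (78.5, 9.87)},
    "Olsen_P": {"soybean": (14.90, 4.18), "sorghum": (22.54, 5.87), "cotton": (28.13, 8.23), "maize": (17.13, 2.83)},
    "Avail_K": {"soybean": (116.0, 5.93), "sorghum": (135.0, 19.26), "cotton": (158.0, 14.70), "maize": (149.0, 16.25)},
    "AN":      {"soybean": (0.05, 0.01), "sorghum": (0.10, 0.01), "cotton": (0.08, 0.01), "maize": (0.08, 0.01)},
    "TP":      {"soybean": (2.75, 0.34), "sorghum": (2.96, 0.33), "cotton": (2.51, 0.24), "maize": (3.13, 0.37)},
    "TK":      {"soybean": (18.2, 2.10), "sorghum": (24.3, 3.20), "cotton": (14.7, 1.58), "maize": (15.6, 1.28)},
    "TN":      {"soybean": (1.46, 0.43), "sorghum": (6.23, 2.20), "cotton": (1.64, 0.62), "maize": (2.14, 0.46)},
    "SOC":     {"soybean": (5.76, 0.36), "sorghum": (8.69, 1.22), "cotton": (6.87, 0.73), "maize": (7.66, 0.72)},
}

#: Per-crop (mean, SD) of the multi-nutrient cycling index used as the
#: crop-structured component of the coupled generator's latent MNC target.
DEFAULT_CROP_MNC = {
    "soybean": (0.25, 0.03), "sorghum": (0.48, 0.07),
    "cotton": (0.33, 0.03), "maize": (0.35, 0.04),
}

#: Dominant phyla used for taxonomy strings, most-abundant first.
BACTERIAL_PHYLA = [
    "Proteobacteria", "Acidobacteriota", "Actinobacteria", "Chloroflexi",
    "Planctomycetes", "Gemmatimonadota", "Bacteroidota", "Firmicutes",
    "Myxococcota", "Methylomirabilota",
]
FUNGAL_PHYLA = [
    "Ascomycota", "Mortierellomycota", "Basidiomycota", "unclassified_k_Fungi",
    "Chytridiomycota", "Glomeromycota", "Rozellomycota", "Zoopagomycota",
    "Blastocladiomycota", "Kickxellomycota",
]


@dataclass
class SynthConfig:
    """Generator settings; defaults are the emulated study's conditions."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_otus_bacteria: int = 5000
    n_otus_fungi: int = 800
    sad_sigma: float = 2.0          # lognormal shape of the abundance profile
    depth: int = 30000              # reads per sample
    pert_sigma: float = 0.3         # per-sample lognormal abundance noise
    tilt_sigma: float = 0.4         # log-scale spread of the rare-tail mass
    nutrient_noise: float = 0.4     # per-nutrient residual share (delta)
    crop_nutrient_params: dict = field(default_factory=lambda: {
        var: dict(crops) for var, crops in DEFAULT_CROP_NUTRIENTS.items()
    })
    crop_mnc_params: dict = field(default_factory=lambda: dict(DEFAULT_CROP_MNC))
    path_effects: dict = field(default_factory=lambda: {
        "salt_to_rare_bact": 0.40,
        "rare_bact_to_mnc": -0.31,
        "rare_fung_to_mnc": 0.47,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every crop group needs at least two samples")
        if self.sad_sigma < 0:
            raise ValueError("sad_sigma must be non-negative")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if any(abs(v) >= 1 for v in self.path_effects.values()):
            raise ValueError("path effects must lie strictly inside (-1, 1)")
        for var, crops in self.crop_nutrient_params.items():
            for crop, (_, sd) in crops.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {var}/{crop}")

    # -- helpers ----------------------------------------------------------
    @property
    def crops(self) -> list[str]:
        return list(self.group_sizes)

    def sample_layout(self) -> tuple[list[str], pd.Series]:
        ids, crops = [], []
        for crop, n in self.group_sizes.items():
            for i in range(n):
                ids.append(f"{crop}_{i + 1:02d}")
                crops.append(crop)
        return ids, pd.Series(crops, index=ids, name="crop")

    def scaled(self, factor: float) -> "SynthConfig":
        """Same conditions with every group size multiplied by ``factor``."""
        import copy

        cfg = copy.deepcopy(self)
        cfg.group_sizes = {
            c: max(2, int(round(n * factor))) for c, n in self.group_sizes.items()
        }
        return cfg


@dataclass
class CoupledDataset:
    """Output of :func:`generate_coupled_dataset` plus the planted truth."""

    bacteria: OTUTable
    fungi: OTUTable
    nutrients: NutrientTable
    truth: dict


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_nutrients(cfg: SynthConfig, seed: int | None = None) -> NutrientTable:
    """Per-crop normal draws (truncated at zero) matching configured means/SDs."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ids, crops = cfg.sample_layout()
    data = {}
    for var in NUTRIENT_VARIABLES:
        params = cfg.crop_nutrient_params[var]
        column = np.empty(len(ids))
        for i, crop in enumerate(crops):
            mean, sd = params[crop]
            column[i] = max(0.0, rng.normal(mean, sd))
        data[var] = column
    return NutrientTable(data=pd.DataFrame(data, index=ids), crop=crops)


def _taxonomy(rng, n_otus: int, kingdom: str) -> list[str]:
    phyla = BACTERIAL_PHYLA if kingdom == "bacteria" else FUNGAL_PHYLA
    king = "Bacteria" if kingdom == "bacteria" else "Fungi"
    # geometric-ish phylum frequencies plus a small unclassified remainder
    weights = np.array([0.78**i for i in range(len(phyla))] + [0.05])
    weights /= weights.sum()
    choices = rng.choice(len(phyla) + 1, size=n_otus, p=weights)
    return [
        f"k__{king};p__{phyla[c]}" if c < len(phyla) else f"k__{king};p__unclassified"
        for c in choices
    ]


def _base_profile(rng, cfg: SynthConfig, kingdom: str) -> np.ndarray:
    n_otus = cfg.n_otus_bacteria if kingdom == "bacteria" else cfg.n_otus_fungi
    if n_otus < 10:
        raise ValueError("n_otus must be at least 10")
    return rng.lognormal(mean=0.0, sigma=cfg.sad_sigma, size=n_otus)


def _sample_counts(
    rng, cfg: SynthConfig, base: np.ndarray, tilt: np.ndarray | None
) -> np.ndarray:
    """Multinomial counts per sample from the tilted, perturbed profile.

    ``tilt`` (one value per sample, unit scale) multiplies the rare tail of
    the base profile by ``exp(tilt_sigma * tilt)``; the tail is the set of
    OTUs whose base relative abundance is below the rare threshold, i.e. the
    prospective rare sub-community.
    """
    n_samples = len(tilt) if tilt is not None else None
    rel = base / base.sum()
    tail = rel < 1e-5
    rows = []
    for i in range(n_samples):
        weights = base * np.exp(
            rng.normal(0.0, cfg.pert_sigma, size=base.size) - cfg.pert_sigma**2 / 2
        )
        if tilt is not None and tail.any():
            weights = weights.copy()
            weights[tail] *= np.exp(cfg.tilt_sigma * tilt[i])
        rows.append(rng.multinomial(cfg.depth, weights / weights.sum()))
    return np.array(rows)


def generate_otu_table(
    cfg: SynthConfig,
    kingdom: str = "bacteria",
    seed: int | None = None,
    tilt: np.ndarray | None = None,
) -> OTUTable:
    """Multinomial OTU table from a lognormal abundance profile.

    Row sums equal ``cfg.depth`` exactly. With default parameters the mean
    relative-abundance spectrum spans both classification tails (>0.05% and
    <0.001%). ``tilt`` optionally modulates each sample's rare-tail mass
    (used by :func:`generate_coupled_dataset`).
    """
    if kingdom not in ("bacteria", "fungi"):
        raise ValueError(f"unknown kingdom {kingdom!r}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ids, crops = cfg.sample_layout()
    base = _base_profile(rng, cfg, kingdom)
    if tilt is None:
        tilt = np.zeros(len(ids))
    if len(tilt) != len(ids):
        raise ValueError("tilt must have one value per sample")
    counts = _sample_counts(rng, cfg, base, tilt)
    prefix = "B" if kingdom == "bacteria" else "F"
    otu_ids = [f"{prefix}OTU{j + 1:05d}" for j in range(base.size)]
    taxonomy = pd.Series(_taxonomy(rng, base.size, kingdom), index=otu_ids)
    return OTUTable(
        counts=pd.DataFrame(counts, index=ids, columns=otu_ids),
        crop=crops,
        taxonomy=taxonomy,
    )


def _realized_shannon_z(table: OTUTable, which: str) -> np.ndarray:
    """Pooled-standardized Shannon of one sub-community of a table."""
    classes = classify_taxa(table)
    sub = subset_by_class(table, classes, which)
    shannon = alpha_diversity(sub, allow_empty=True).shannon.to_numpy()
    return _standardize(shannon)


def generate_coupled_dataset(cfg: SynthConfig) -> CoupledDataset:
    """Full coupled triple (bacteria, fungi, nutrients) plus planted truth.

    Generative order: salinity (per-crop) -> latent rare-bacterial diversity
    target -> OTU tables (rare-tail tilt) -> realized standardized Shannon
    values -> latent MNC target -> the seven MNC nutrients. The remaining
    soil variables are independent per-crop draws. All planted standardized
    effects are recorded in ``truth``.
    """
    rng = np.random.default_rng(cfg.seed)
    ids, crops = cfg.sample_layout()
    n = len(ids)
    beta_salt = cfg.path_effects["salt_to_rare_bact"]
    beta_b = cfg.path_effects["rare_bact_to_mnc"]
    beta_f = cfg.path_effects["rare_fung_to_mnc"]

    # 1. salinity, per-crop truncated normal
    salt = np.array(
        [max(0.0, rng.normal(*cfg.crop_nutrient_params["salt"][c])) for c in crops]
    )
    z_salt = _standardize(salt)

    # 2. latent diversity drivers
    t_rb = beta_salt * z_salt + np.sqrt(1 - beta_salt**2) * rng.normal(size=n)
    t_rf = rng.normal(size=n)

    # 3. community tables, rare-tail mass tilted by the latents
    bacteria = generate_otu_table(
        cfg, "bacteria", seed=int(rng.integers(2**31 - 1)), tilt=t_rb
    )
    fungi = generate_otu_table(
        cfg, "fungi", seed=int(rng.integers(2**31 - 1)), tilt=t_rf
    )

    # 4. realized standardized Shannon values (these, not the latents, drive
    #    the nutrients, so the fitted arrows match the generative ones)
    z_rb = _realized_shannon_z(bacteria, "rare")
    z_rf = _realized_shannon_z(fungi, "rare")
    z_ab = _realized_shannon_z(bacteria, "abundant")
    z_af = _realized_shannon_z(fungi, "abundant")

    # 5. latent MNC target: planted effects plus a crop-structured residual
    #    orthogonalized against every regressor of the MNC equation
    eta_raw = np.array(
        [rng.normal(*cfg.crop_mnc_params[c]) for c in crops]
    )
    design = np.column_stack([np.ones(n), z_rb, z_rf, z_salt, z_ab, z_af])
    coef, *_ = np.linalg.lstsq(design, eta_raw, rcond=None)
    eta = _standardize(eta_raw - design @ coef)
    z_mnc = beta_b * z_rb + beta_f * z_rf + np.sqrt(max(0.0, 1 - beta_b**2 - beta_f**2)) * eta

    # 6. the seven MNC nutrients: pooled-scale coupling to the MNC target
    delta = cfg.nutrient_noise
    data = {}
    for var in MNC_VARIABLES:
        params = cfg.crop_nutrient_params[var]
        weights = np.array([cfg.group_sizes[c] for c in cfg.crops], dtype=float)
        weights /= weights.sum()
        crop_means = np.array([params[c][0] for c in cfg.crops])
        crop_sds = np.array([params[c][1] for c in cfg.crops])
        grand = float(weights @ crop_means)
        pooled_sd = float(
            np.sqrt(weights @ crop_sds**2 + weights @ (crop_means - grand) ** 2)
        )
        noise = rng.normal(size=n)
        values = grand + pooled_sd * (
            np.sqrt(1 - delta**2) * z_mnc + delta * noise
        )
        data[var] = np.maximum(0.0, values)

    # 7. remaining soil variables: independent per-crop draws
    data["salt"] = salt
    for var in ("pH", "BD", "SWC", "NH4_N", "AN"):
        params = cfg.crop_nutrient_params[var]
        data[var] = np.array([max(0.0, rng.normal(*params[c])) for c in crops])

    nutrients = NutrientTable(data=pd.DataFrame(data, index=ids), crop=crops)

    truth = {
        "edges": {
            "salt->rare_bact_shannon": beta_salt,
            "salt->abundant_bact_shannon": 0.0,
            "salt->rare_fung_shannon": 0.0,
            "salt->abundant_fung_shannon": 0.0,
            "rare_bact_shannon->MNC": beta_b,
            "abundant_bact_shannon->MNC": 0.0,
            "rare_fung_shannon->MNC": beta_f,
            "abundant_fung_shannon->MNC": 0.0,
            "salt->MNC": 0.0,
        },
        "seed": cfg.seed,
    }
    return CoupledDataset(bacteria=bacteria, fungi=fungi, nutrients=nutrients, truth=truth)
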