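"""End-to-end orchestration: synth/ingest -> partition -> diversity -> MNC ->
per-crop networks -> correlation screens -> path model + forest importance.

One global seed expands into per-stage seeds through a documented counter
scheme (``stage_seed = (seed * 1000003 + stage_index) mod (2^31 - 1)``), so
adding a stage never silently changes an earlier stage's draws. Identical
config + seed produces a byte-identical JSON report; with ``resume=True``
stages whose artifact files already exist are loaded instead of recomputed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as dv
from . import drivers as drv
from . import io_formats as io
from . import mnc as mncmod
from . import network as net
from . import synthetic as synth
from . import taxa
from .tables import NUTRIENT_VARIABLES

__all__ = ["RunConfig", "run_pipeline", "default_run_config"]

_STAGES = [
    "synth",
    "partition",
    "diversity",
    "mnc",
    "networks",
    "correlations",
    "drivers",
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: Path
    synth: synth.SynthConfig | None = None
    otu_bacteria: Path | None = None
    otu_fungi: Path | None = None
    nutrients: Path | None = None
    rare_max: float = 1e-5
    abundant_min: float = 5e-4
    keep_fraction: float = 0.8
    r_min: float = 0.60
    alpha: float = 0.05
    n_permutations: int = 999
    nmds_starts: int = 20
    rf_trees: int = 500
    seed: int = 0
    resume: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.synth is None:
            for p in (self.otu_bacteria, self.otu_fungi, self.nutrients):
                if p is None or not Path(p).exists():
                    raise ValueError(
                        "without a synth block, otu_bacteria/otu_fungi/nutrients "
                        "paths must all exist"
                    )
        net.NetworkConfig(  # validates thresholds
            keep_fraction=self.keep_fraction, r_min=self.r_min, alpha=self.alpha
        )
        if not 0 < self.rare_max < self.abundant_min:
            raise ValueError("need 0 < rare_max < abundant_min")

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000003 + _STAGES.index(stage)) % (2**31 - 1)

    def config_hash(self) -> str:
        payload = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in self.__dict__.items()
            if k not in ("out_dir", "resume")
        }
        if self.synth is not None:
            payload["synth"] = json.dumps(
                self.synth.__dict__, sort_keys=True, default=str
            )
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def default_run_config(out_dir, seed: int = 0, **overrides) -> RunConfig:
    """Desk-scale synthetic run: full study design with a reduced community
    size (1200 bacterial / 500 fungal OTUs) so a run completes in seconds."""
    cfg = synth.SynthConfig(n_otus_bacteria=1200, n_otus_fungi=500, seed=seed)
    return RunConfig(out_dir=out_dir, synth=cfg, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Stage implementations (each returns a JSON-serializable summary)
# ---------------------------------------------------------------------------

def _stage_synth(cfg: RunConfig, state: dict) -> dict:
    if cfg.synth is not None:
        sc = synth.SynthConfig(**{**cfg.synth.__dict__, "seed": cfg.stage_seed("synth")})
        coupled = synth.generate_coupled_dataset(sc)
        bacteria, fungi, nutrients = coupled.bacteria, coupled.fungi, coupled.nutrients
        io.write_otu_table(bacteria, cfg.out_dir / "otu_bacteria.tsv")
        io.write_otu_table(fungi, cfg.out_dir / "otu_fungi.tsv")
        io.write_nutrient_table(nutrients, cfg.out_dir / "nutrients.csv")
        (cfg.out_dir / "truth.json").write_text(
            json.dumps(coupled.truth, indent=2, sort_keys=True)
        )
        truth = coupled.truth
    else:
        nutrients = io.read_nutrient_table(cfg.nutrients)
        crop = nutrients.crop
        bacteria = io.read_otu_table(cfg.otu_bacteria, crop=crop)
        fungi = io.read_otu_table(cfg.otu_fungi, crop=crop)
        truth = None
    state.update(bacteria=bacteria, fungi=fungi, nutrients=nutrients)
    return {
        "n_samples": bacteria.n_samples,
        "n_otus": {"bacteria": bacteria.n_otus, "fungi": fungi.n_otus},
        "crops": {c: int(n) for c, n in bacteria.crop.value_counts().sort_index().items()},
        "planted": truth,
    }


def _stage_partition(cfg: RunConfig, state: dict) -> dict:
    out = {}
    for kingdom in ("bacteria", "fungi"):
        table = state[kingdom]
        classes = taxa.classify_taxa(table, cfg.rare_max, cfg.abundant_min)
        state[f"classes_{kingdom}"] = classes
        labels = pd.DataFrame(
            {
                "mean_rel_abund": classes.mean_rel_abundance,
                "class": classes.labels,
            }
        )
        labels.index.name = "otu_id"
        labels.to_csv(cfg.out_dir / f"partition_{kingdom}.tsv", sep="\t")
        per_crop = {
            crop: table.subset_samples(table.crop.index[table.crop == crop])
            for crop in sorted(table.crop.unique())
        }
        overlap = taxa.otu_overlap(per_crop)
        _, top, _ = taxa.phylum_aggregate(table)
        out[kingdom] = {
            "class_counts": classes.counts,
            "per_crop_otus": overlap["totals"],
            "per_crop_unique": overlap["unique"],
            "shared_all": overlap["shared_all"],
            "top_phyla": top,
        }
    return out


def _stage_diversity(cfg: RunConfig, state: dict) -> dict:
    seed = cfg.stage_seed("diversity")
    out = {}
    for kingdom in ("bacteria", "fungi"):
        table = state[kingdom]
        profile = dv.alpha_diversity(table)
        profile.to_frame().to_csv(cfg.out_dir / f"alpha_{kingdom}.tsv", sep="\t")
        dm = dv.bray_curtis(table)
        dm.to_frame().to_csv(cfg.out_dir / f"bray_curtis_{kingdom}.tsv", sep="\t")
        coords, stress = dv.nmds(dm, n_starts=cfg.nmds_starts, seed=seed)
        coords.to_csv(cfg.out_dir / f"nmds_{kingdom}.tsv", sep="\t")
        perm = dv.permanova(dm, table.crop, n_perm=cfg.n_permutations, seed=seed)
        nutr_z = (state["nutrients"].data - state["nutrients"].data.mean()) / state[
            "nutrients"
        ].data.std(ddof=0)
        env = dv.DistanceMatrix(
            np.sqrt(
                ((nutr_z.to_numpy()[:, None, :] - nutr_z.to_numpy()[None, :, :]) ** 2).sum(-1)
            ),
            ids=list(nutr_z.index),
        )
        mant = dv.mantel(dm, env, method="spearman", n_perm=cfg.n_permutations, seed=seed)
        kw = {
            name: dv.kruskal_wallis(series.to_numpy(), table.crop.to_numpy()).as_dict()
            for name, series in profile.to_frame().items()
        }
        state[f"alpha_{kingdom}"] = profile
        out[kingdom] = {
            "nmds_stress": stress,
            "permanova": perm.as_dict(),
            "mantel_env": mant.as_dict(),
            "kruskal_wallis": kw,
            "alpha_mean": {
                k: float(v) for k, v in profile.to_frame().mean().items()
            },
        }
    return out


def _stage_mnc(cfg: RunConfig, state: dict) -> dict:
    nutrients = state["nutrients"]
    result = mncmod.compute_mnc(nutrients)
    state["mnc"] = result
    frame = result.normalized.copy()
    frame["MNC"] = result.mnc
    frame.to_csv(cfg.out_dir / "mnc.tsv", sep="\t")
    duncan = dv.anova_duncan(result.mnc.to_numpy(), nutrients.crop.to_numpy())
    ratios = mncmod.availability_ratios(nutrients)
    ratios.to_csv(cfg.out_dir / "availability_ratios.tsv", sep="\t")
    return {
        "crop_means": {
            crop: {"mean": float(row["mean"]), "n": int(row["n"]), "letters": row["letters"]}
            for crop, row in duncan.iterrows()
        },
        "ratio_means": {k: float(v) for k, v in ratios.mean().items()},
    }


def _stage_networks(cfg: RunConfig, state: dict) -> dict:
    seed = cfg.stage_seed("networks")
    ncfg = net.NetworkConfig(
        keep_fraction=cfg.keep_fraction, r_min=cfg.r_min, alpha=cfg.alpha
    )
    out = {}
    for kingdom in ("bacteria", "fungi"):
        table = state[kingdom]
        out[kingdom] = {}
        for crop in sorted(table.crop.unique()):
            sub = table.subset_samples(table.crop.index[table.crop == crop])
            kept = taxa.prevalence_filter_top(sub, cfg.keep_fraction)
            r, p = net.spearman_matrix(kept)
            network = net.build_network(r, p, ncfg)
            if network.n_edges > 0:
                summary = net.topology_summary(network, seed=seed).as_dict()
                io.write_network(
                    network, cfg.out_dir / f"network_{kingdom}_{crop}.graphml"
                )
            else:
                summary = {"node_num": 0, "edge_num": 0}
            out[kingdom][crop] = summary
    return out


def _stage_correlations(cfg: RunConfig, state: dict) -> dict:
    nutrients = state["nutrients"]
    diversity_cols = {}
    for kingdom, short in (("bacteria", "bact"), ("fungi", "fung")):
        table = state[kingdom]
        classes = state[f"classes_{kingdom}"]
        for which in ("rare", "abundant"):
            sub = taxa.subset_by_class(table, classes, which)
            diversity_cols[f"{which}_{short}_shannon"] = dv.alpha_diversity(
                sub, allow_empty=True
            ).shannon
    screen = dv.correlation_screen(
        pd.DataFrame(diversity_cols),
        nutrients.data[NUTRIENT_VARIABLES],
        method="spearman",
    )
    screen.to_csv(cfg.out_dir / "correlation_screen.tsv", sep="\t", index=False)
    strongest = screen.loc[screen.r.abs().idxmax()]
    return {
        "n_pairs": int(len(screen)),
        "n_significant": int((screen.p < 0.05).sum()),
        "strongest": {
            "x": strongest.x, "y": strongest.y,
            "r": float(strongest.r), "p": float(strongest.p),
        },
    }


def _stage_drivers(cfg: RunConfig, state: dict) -> dict:
    seed = cfg.stage_seed("drivers")
    table = drv.assemble_driver_table(
        state["bacteria"], state["fungi"], state["nutrients"],
        mnc=state.get("mnc"), rare_max=cfg.rare_max, abundant_min=cfg.abundant_min,
    )
    table.to_csv(cfg.out_dir / "driver_table.tsv", sep="\t")
    fit = drv.fit_path_model(table, drv.default_path_spec())
    (cfg.out_dir / "path_fit.json").write_text(
        json.dumps(fit.as_dict(), indent=2, sort_keys=True)
    )
    importance = {}
    for kingdom, col in (("bacteria", "rare_bact_shannon"), ("fungi", "rare_fung_shannon")):
        report = drv.rf_importance(
            table[drv.MNC_VARIABLES], table[col], n_trees=cfg.rf_trees, seed=seed
        )
        importance[kingdom] = {
            "importance_pct_inc_mse": {k: float(v) for k, v in report.importance.items()},
            "r_squared": report.r_squared,
            "top_predictor": report.ranking[0],
        }
    (cfg.out_dir / "importance.json").write_text(
        json.dumps(importance, indent=2, sort_keys=True)
    )
    return {"path_model": fit.as_dict(), "random_forest": importance}


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "partition": _stage_partition,
    "diversity": _stage_diversity,
    "mnc": _stage_mnc,
    "networks": _stage_networks,
    "correlations": _stage_correlations,
    "drivers": _stage_drivers,
}

#: Stages whose summaries can be reloaded on resume without recomputation.
#: ``synth``/``partition``/``mnc`` rebuild cheap in-memory state needed later.
_RESUMABLE = {"diversity", "networks", "correlations", "drivers"}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order and return (and write) the run report.

    A stage failure marks the stage and every downstream stage as skipped;
    the report is still written and the error re-raised summary-side via the
    ``"status"`` fields.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    report = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    failed = False
    for stage in _STAGES:
        stage_file = cfg.out_dir / f"stage_{stage}.json"
        entry: dict = {"seed": cfg.stage_seed(stage)}
        if failed:
            entry["status"] = "skipped"
            report["stages"][stage] = entry
            continue
        cached = (
            cfg.resume
            and stage in _RESUMABLE
            and stage_file.exists()
        )
        try:
            if cached:
                entry.update(json.loads(stage_file.read_text()))
                entry["status"] = "ok (resumed)"
                if stage == "diversity":  # recompute light state for later stages
                    pass
            else:
                summary = _STAGE_FUNCS[stage](cfg, state)
                entry.update(summary)
                entry["status"] = "ok"
                stage_file.write_text(json.dumps(entry, indent=2, sort_keys=True))
        except Exception as exc:  # noqa: BLE001 — report and halt downstream
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            failed = True
        report["stages"][stage] = entry
    report["ok"] = not failed
    text = json.dumps(report, indent=2, sort_keys=True)
    (cfg.out_dir / "report.json").write_text(text)
    report["report_sha256"] = hashlib.sha256(text.encode()).hexdigest()
    if failed:
        bad = [s for s, e in report["stages"].items() if e["status"] == "failed"]
        raise RuntimeError(f"pipeline stage(s) failed: {bad}")
    return report
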