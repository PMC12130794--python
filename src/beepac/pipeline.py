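"""End-to-end orchestration: records -> networks -> indices -> models.

Stages communicate via CSV files in the output directory so any stage can
be rerun independently; a manifest (config hash, seed, package version,
row counts) makes every run reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import data_model as dm
from . import network_builder as nb
from .abundance import abundance_table, estimate_abundances
from .completeness import chao2_completeness, completeness_table
from .glmm import (
    add_transforms,
    assemble_model_table,
    fit_interspecific_model,
    fit_intraspecific_model,
)
from .pac import competition_indices
from .synthetic import SyntheticConfig, generate_community

log = logging.getLogger("beepac")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run."""

    outdir: str
    seed: int = 0
    # input files; when absent, a synthetic community is generated
    visits_path: str | None = None
    plots_path: str | None = None
    traits_path: str | None = None
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    min_total: int = 20
    core_season: bool = True
    chao2_bias_corrected: bool = True
    reml: bool = True
    years: list[int] | None = None  # optional year-subset refit

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}


def _model_report(result, outdir: Path, stem: str) -> None:
    result.fixed_effects.to_csv(outdir / f"{stem}_coefficients.csv", index=False)
    result.wald.to_csv(outdir / f"{stem}_wald.csv", index=False)
    pd.DataFrame([result.random_effect]).assign(group="species").to_csv(
        outdir / f"{stem}_random_effect.csv", index=False
    )
    pd.DataFrame(
        [{"predictor": k, "vif": v} for k, v in result.vif.items()]
    ).to_csv(outdir / f"{stem}_vif.csv", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle to ``config.outdir``.

    Returns a dict of the in-memory stage outputs (networks, tables,
    fitted models) for programmatic use.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.visits_path:
        stage = "read"
        visits = dm.read_visitation(config.visits_path)
        plots = dm.read_floral_plots(config.plots_path)
        traits = dm.read_traits(config.traits_path)
    else:
        stage = "simulate"
        syn = SyntheticConfig(seed=config.seed, **config.synthetic)
        visits, plots, traits, truth = generate_community(syn)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh)
        visits.to_csv(outdir / "visits.csv", index=False)
        plots.to_csv(outdir / "floral_plots.csv", index=False)
        traits.to_csv(outdir / "traits.csv", index=False)
    log.info("[%s] %d visit rows, %d plot rows", stage, len(visits), len(plots))

    # --- filters ----------------------------------------------------------
    if config.core_season:
        visits = dm.restrict_to_core_season(visits)
    visits = dm.filter_rare_species(visits, min_total=config.min_total)
    if len(visits) == 0:
        raise RuntimeError("filter stage: no records left after filtering")
    summary = dm.summarize_visitation(visits)
    with open(outdir / "summary.json", "w") as fh:
        fh.write(summary.to_json())
    summary.species_shares.to_csv(outdir / "species_shares.csv", index=False)
    log.info("[filter] %d rows, %d species", len(visits), len(summary.species_shares))

    # --- networks ---------------------------------------------------------
    networks = nb.build_daily_networks(visits)
    pd.concat([n.to_long() for n in networks]).to_csv(
        outdir / "networks_long.csv", index=False
    )
    visited = nb.visited_plants(visits)
    densities = nb.floral_density_series(plots, [n.date for n in networks], visited)
    densities.reset_index().to_csv(outdir / "floral_density.csv", index=False)
    log.info("[networks] %d daily networks", len(networks))

    # --- PAC indices ------------------------------------------------------
    indices = competition_indices(networks)
    indices.to_csv(outdir / "pac_indices.csv", index=False)
    log.info("[pac] %d (day, species) rows", len(indices))

    # --- abundance --------------------------------------------------------
    estimates = [estimate_abundances(n) for n in networks]
    abund = abundance_table(networks, estimates)
    abund.to_csv(outdir / "abundance.csv", index=False)
    log.info("[abundance] %d rows", len(abund))

    # --- completeness -----------------------------------------------------
    by_year: dict[int, list] = {}
    for n in networks:
        by_year.setdefault(n.year, []).append(n)
    comp = [
        chao2_completeness(nets, bias_corrected=config.chao2_bias_corrected)
        for nets in by_year.values()
        if len(nets) >= 2
    ]
    comp_df = completeness_table(comp)
    comp_df.to_csv(outdir / "completeness.csv", index=False)
    log.info("[completeness] %d years", len(comp_df))

    # --- models -----------------------------------------------------------
    table = assemble_model_table(indices, abund, densities, traits)
    table = add_transforms(table)
    table.to_csv(outdir / "competition_table.csv", index=False)
    inter = fit_interspecific_model(table, years=config.years, reml=config.reml)
    intra = fit_intraspecific_model(table, years=config.years, reml=config.reml)
    _model_report(inter, outdir, "model_interspecific")
    _model_report(intra, outdir, "model_intraspecific")
    log.info(
        "[model] inter n=%d converged=%s; intra n=%d converged=%s",
        inter.n_obs, inter.converged, intra.n_obs, intra.converged,
    )

    # --- manifest ---------------------------------------------------------
    cfg = config.to_dict()
    manifest = {
        "package": "beepac",
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "rows": {
            "visits": len(visits),
            "networks": len(networks),
            "pac_indices": len(indices),
            "abundance": len(abund),
            "completeness": len(comp_df),
            "model_table": len(table),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {
        "visits": visits,
        "plots": plots,
        "traits": traits,
        "summary": summary,
        "networks": networks,
        "densities": densities,
        "indices": indices,
        "abundance": abund,
        "completeness": comp_df,
        "table": table,
        "model_interspecific": inter,
        "model_intraspecific": intra,
        "manifest": manifest,
    }
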