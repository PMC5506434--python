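"""End-to-end runs from a YAML config: simulate/discover -> null check ->
enrichment -> waterfall -> compound screen, with a manifest per run."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import __version__
from . import crm_screen as _crm
from . import synthetic as _synthetic
from .io_formats import (
    ExpressionStudy,
    GeneSetCollection,
    read_expression_study,
    read_gmt,
    write_expression_study,
    write_gmt,
)
from .models import MimicryScreen, MultiStrainCR, RandomSetEnrichment

logger = logging.getLogger("crmarkers")

# consensus thresholds used in the discovery screen, per tissue
DEFAULT_K = {"heart": 5, "gastrocnemius": 5, "WAT": 6, "neocortex": 3}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; read from YAML, all thresholds surfaced."""

    out_dir: str = "crmarkers_run"
    seed: int = 0
    tissue: str = "WAT"
    matrix_path: Optional[str] = None
    meta_path: Optional[str] = None
    gmt_path: Optional[str] = None
    plate_paths: Dict[str, str] = field(default_factory=dict)  # tissue -> csv
    panel_paths: Dict[str, str] = field(default_factory=dict)  # tissue -> tsv (gene, cr_fold)
    alpha_strain: float = 0.01
    k_per_tissue: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_K))
    enrichment_alpha: float = 0.05
    set_size_min: int = 10
    set_size_max: int = 1000
    min_overlap: int = 5
    crm_alpha: float = 0.05
    simulation: Optional[dict] = None  # overrides for SimulationConfig
    n_sim_sets: int = 200

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def k_for(self, tissue: str) -> int:
        return self.k_per_tissue.get(tissue, 5)


def _write_manifest(out: Path, config: RunConfig, extra: Optional[dict] = None) -> None:
    manifest = {
        "package": "crmarkers",
        "version": __version__,
        "config": asdict(config),
        **(extra or {}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _setup_out(config: RunConfig, force: bool = False) -> Path:
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty; pass force=True/--force")
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setLevel(logging.INFO)
    logger.addHandler(fh)
    return out


def _discover(study: ExpressionStudy, config: RunConfig, out: Path,
              collection: Optional[GeneSetCollection]) -> dict:
    tissue = config.tissue
    k = config.k_for(tissue)
    model = MultiStrainCR(study, tissue=tissue)
    res = model.fit(alpha=config.alpha_strain, k=k)
    res.scan.to_csv(out / "strain_scan.tsv", sep="\t", index=False)
    cons = res.consensus.copy()
    cons["hit_strains"] = cons["hit_strains"].apply(lambda t: ";".join(t))
    cons.to_csv(out / "consensus.tsv", sep="\t")
    if res.anova_q is not None:
        res.anova_q.to_csv(out / "anova_q.tsv", sep="\t")
    null_summary = {
        "p_s": res.null.p_s.to_dict(),
        "n_genes": res.null.n_genes,
        "expected_ge_k": res.null.expected_ge_k,
        "observed_ge_k": {kk: res.observed_ge_k(kk) for kk in res.null.expected_ge_k},
    }
    (out / "null_expectations.json").write_text(json.dumps(null_summary, indent=2) + "\n")
    (out / "discovery_summary.txt").write_text(res.summary() + "\n")
    logger.info("discovery: %d genes selected at k=%d", len(res.selected_genes), k)
    outcome = {"n_selected": len(res.selected_genes), "k": k}
    if collection is not None and res.selected_genes:
        enr = RandomSetEnrichment(
            study.genes, res.selected_genes, collection,
            size_min=config.set_size_min, size_max=config.set_size_max,
            min_overlap=config.min_overlap,
        ).fit(alpha=config.enrichment_alpha)
        enr.table.to_csv(out / "enrichment.tsv", sep="\t")
        plan = enr.waterfall()
        plan.to_frame().to_csv(out / "waterfall.tsv", sep="\t", index=False)
        (out / "enrichment_summary.txt").write_text(enr.summary() + "\n")
        outcome["n_significant_sets"] = int(enr.table["significant"].sum())
        outcome["n_waterfall_steps"] = len(plan.steps)
    return outcome


def run_discovery(config: RunConfig, force: bool = False) -> dict:
    """Load real data per the config and run discovery + enrichment."""
    if not config.matrix_path or not config.meta_path:
        raise ValueError("run_discovery needs matrix_path and meta_path")
    for p in (config.matrix_path, config.meta_path, config.gmt_path):
        if p and not Path(p).exists():
            raise FileNotFoundError(p)
    out = _setup_out(config, force)
    study = read_expression_study(config.matrix_path, config.meta_path)
    collection = read_gmt(config.gmt_path) if config.gmt_path else None
    outcome = _discover(study, config, out, collection)
    _write_manifest(out, config, {"mode": "discovery", "outcome": outcome})
    return outcome


def run_screen(config: RunConfig, force: bool = False) -> pd.DataFrame:
    """Score compounds on qPCR plates against per-tissue panels."""
    if not config.plate_paths or not config.panel_paths:
        raise ValueError("run_screen needs plate_paths and panel_paths")
    for p in list(config.plate_paths.values()) + list(config.panel_paths.values()):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    out = _setup_out(config, force)
    plates = {t: _crm.read_ct_plate(p) for t, p in config.plate_paths.items()}
    panels = {}
    for tissue, path in config.panel_paths.items():
        tab = pd.read_csv(path, sep="\t")
        panels[tissue] = _crm.PanelDefinition(
            tissue=tissue, genes=dict(zip(tab["gene"], tab["cr_fold"]))
        )
    res = MimicryScreen(plates, panels).fit(alpha=config.crm_alpha)
    res.tally.to_csv(out / "mimicry_tally.tsv", sep="\t")
    (out / "screen_summary.md").write_text("```\n" + res.summary() + "\n```\n")
    _write_manifest(out, config, {"mode": "screen"})
    return res.tally


def run_null(run_dir) -> dict:
    """Recompute Poisson-Binomial null expectations from a run's strain scan."""
    from .consensus import PoissonBinomialNull

    run_dir = Path(run_dir)
    scan = pd.read_csv(run_dir / "strain_scan.tsv", sep="\t")
    null = PoissonBinomialNull.from_scan(scan)
    cons = pd.read_csv(run_dir / "consensus.tsv", sep="\t")
    summary = {
        "p_s": null.p_s.to_dict(),
        "n_genes": null.n_genes,
        "expected_ge_k": null.expected_ge_k,
        "observed_ge_k": {k: int((cons["hit_count"] >= k).sum()) for k in null.expected_ge_k},
    }
    (run_dir / "null_expectations.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def _selection_from_run(run_dir: Path) -> tuple:
    cons = pd.read_csv(run_dir / "consensus.tsv", sep="\t")
    universe = list(cons["gene"])
    selection = list(cons.loc[cons["selected_at_k"], "gene"])
    return universe, selection


def run_enrich(run_dir, gmt_path, config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Random-set enrichment of a run's consensus selection against a GMT file."""
    config = config or RunConfig()
    run_dir = Path(run_dir)
    universe, selection = _selection_from_run(run_dir)
    enr = RandomSetEnrichment(
        universe, selection, read_gmt(gmt_path),
        size_min=config.set_size_min, size_max=config.set_size_max,
        min_overlap=config.min_overlap,
    ).fit(alpha=config.enrichment_alpha)
    enr.table.to_csv(run_dir / "enrichment.tsv", sep="\t")
    return enr.table


def run_waterfall(run_dir, gmt_path, config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Greedy waterfall coverage of a run's consensus selection."""
    config = config or RunConfig()
    run_dir = Path(run_dir)
    universe, selection = _selection_from_run(run_dir)
    enr = RandomSetEnrichment(
        universe, selection, read_gmt(gmt_path),
        size_min=config.set_size_min, size_max=config.set_size_max,
        min_overlap=config.min_overlap,
    ).fit(alpha=config.enrichment_alpha)
    plan = enr.waterfall().to_frame()
    plan.to_csv(run_dir / "waterfall.tsv", sep="\t", index=False)
    return plan


def run_simulation(config: RunConfig, force: bool = False) -> dict:
    """Simulate a study (+ gene sets + plates) and run the full pipeline on it."""
    out = _setup_out(config, force)
    sim_kwargs = dict(config.simulation or {})
    sim_kwargs.setdefault("seed", config.seed)
    sim_kwargs.setdefault("tissue", config.tissue)
    sim = _synthetic.SimulationConfig(**sim_kwargs)
    study, truth = _synthetic.simulate_multistrain_study(sim)
    write_expression_study(study, out / "expression.tsv", out / "samples.tsv")
    pd.DataFrame(
        {"gene": list(truth.shared_effect_genes), "log2fc": list(truth.shared_effect_genes.values())}
    ).to_csv(out / "truth_shared.tsv", sep="\t", index=False)
    planted_sets = ("SET:00000", "SET:00001")
    collection = _synthetic.simulate_genesets(
        study.genes,
        n_sets=config.n_sim_sets,
        size_range=(config.set_size_min, min(200, config.set_size_max)),
        planted=(planted_sets, list(truth.shared_effect_genes), 25.0),
        seed=sim.seed + 1,
    )
    write_gmt(collection, out / "genesets.gmt")
    outcome = _discover(study, config, out, collection)

    panel = {g: float(2.0 ** fc if fc >= 0 else -(2.0 ** -fc))
             for g, fc in list(truth.shared_effect_genes.items())[:8]}
    plate = _synthetic.simulate_qpcr_plate(
        panel,
        compounds=["mimic", "inert"],
        concordant_map={"mimic": panel},
        seed=sim.seed + 2,
    )
    plate.to_csv(out / "plate_sim.csv", index=False)
    panel_def = _crm.PanelDefinition(tissue=config.tissue, genes=panel)
    screen = MimicryScreen({config.tissue: plate}, {config.tissue: panel_def}).fit(
        alpha=config.crm_alpha
    )
    screen.tally.to_csv(out / "mimicry_tally.tsv", sep="\t")
    outcome["screen_tally"] = screen.tally.to_dict()
    _write_manifest(out, config, {"mode": "simulation", "outcome": {"n_selected": outcome["n_selected"]}})
    return outcome
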