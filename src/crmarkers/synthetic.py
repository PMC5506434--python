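"""Synthetic multi-strain expression studies, gene-set collections and qPCR
plates with the statistical structure the analysis assumes.

The generator emulates the discovery design: seven inbred mouse strains,
eight control and eight calorically restricted animals per strain, ~20k
genes on a log2 scale. A small block of genes carries the same signed CR
effect in every strain (optionally attenuated in one strain, emulating a
weak-responder like BALB/cJ), another block carries effects in exactly one
strain, and the rest are null. Noise is Gaussian on the log2 scale, strain
baselines differ by a per-strain offset so the across-strain ANOVA has a
genuine strain main effect, and everything derives deterministically from a
single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import ExpressionStudy, GeneSetCollection

STUDY_STRAINS = (
    "C3H/HeJ",
    "CBA/J",
    "DBA/2J",
    "B6C3F1/J",
    "129S1/SvImJ",
    "C57BL/6J",
    "BALB/cJ",
)


@dataclass
class SimulationConfig:
    """Parameters of the multi-strain study generator.

    Defaults mirror the discovery design: 7 strains x 2 diet groups x 8
    biological replicates, 20,000 genes, per-gene effects of +-1 on the log2
    scale against residual noise of sd 0.5 log2 units, and the last strain
    (BALB/cJ position) responding at half strength.
    """

    n_strains: int = 7
    n_per_group: int = 8
    n_genes: int = 20_000
    n_shared_effect: int = 150
    n_strain_specific: int = 350
    shared_effect_log2fc: float = 1.0
    effect_sign_mix: float = 0.5  # fraction of effect genes going up
    noise_sd_log2: float = 0.5
    baseline_mean_log2: float = 7.0
    baseline_sd_log2: float = 1.5  # spread of per-gene baselines
    strain_offset_sd_log2: float = 0.25
    attenuated_strain_index: Optional[int] = 6
    attenuation_factor: float = 0.5
    noise_df: Optional[float] = None  # Student-t noise df; None = Gaussian
    tissue: str = "WAT"
    seed: int = 0

    def validate(self) -> None:
        if self.n_strains < 1 or self.n_per_group < 2 or self.n_genes < 1:
            raise ValueError("need >=1 strain, >=2 per group, >=1 gene")
        if self.n_shared_effect + self.n_strain_specific > self.n_genes:
            raise ValueError("effect genes exceed n_genes")
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise_sd_log2 must be positive")
        if not 0.0 <= self.effect_sign_mix <= 1.0:
            raise ValueError("effect_sign_mix must be in [0, 1]")
        if self.attenuated_strain_index is not None and not (
            0 <= self.attenuated_strain_index < self.n_strains
        ):
            raise ValueError("attenuated_strain_index out of range")
        if not 0.0 <= self.attenuation_factor <= 1.0:
            raise ValueError("attenuation_factor must be in [0, 1]")
        if self.noise_df is not None and self.noise_df <= 2:
            raise ValueError("noise_df must exceed 2 (finite variance)")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated study; the categories partition the genes."""

    shared_effect_genes: Dict[str, float]  # gene -> true log2 fold change
    strain_specific_map: Dict[str, Dict[str, float]]  # strain -> gene -> log2fc
    null_genes: Tuple[str, ...]


def _strain_names(n: int) -> List[str]:
    if n <= len(STUDY_STRAINS):
        return list(STUDY_STRAINS[:n])
    return list(STUDY_STRAINS) + [f"Strain{i}" for i in range(len(STUDY_STRAINS), n)]


def simulate_multistrain_study(config: SimulationConfig) -> Tuple[ExpressionStudy, SimulationTruth]:
    """Simulate a multi-strain two-group expression study with known truth.

    Per gene g, strain s and sample i:
    ``value = baseline_g + offset_s + 1[group == CR] * effect_{g,s} + N(0, sd)``.
    Shared-effect genes carry the same signed log2 effect in every strain
    (scaled by ``attenuation_factor`` in the attenuated strain);
    strain-specific genes carry theirs in exactly one strain. The same seed
    always reproduces the identical study.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    strains = _strain_names(config.n_strains)
    genes = [f"Gene{i:05d}" for i in range(config.n_genes)]

    baselines = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, config.n_genes)
    offsets = rng.normal(0.0, config.strain_offset_sd_log2, config.n_strains)

    n_eff = config.n_shared_effect + config.n_strain_specific
    effect_idx = rng.choice(config.n_genes, size=n_eff, replace=False)
    shared_idx = effect_idx[: config.n_shared_effect]
    specific_idx = effect_idx[config.n_shared_effect :]
    signs = np.where(rng.random(n_eff) < config.effect_sign_mix, 1.0, -1.0)
    magnitudes = np.full(n_eff, config.shared_effect_log2fc)
    effects = signs * magnitudes

    # effect matrix genes x strains
    E = np.zeros((config.n_genes, config.n_strains))
    E[shared_idx, :] = effects[: config.n_shared_effect, None]
    if config.attenuated_strain_index is not None and config.n_shared_effect:
        E[shared_idx, config.attenuated_strain_index] *= config.attenuation_factor
    owner = rng.integers(0, config.n_strains, size=config.n_strain_specific)
    for j, (gi, s) in enumerate(zip(specific_idx, owner)):
        E[gi, s] = effects[config.n_shared_effect + j]

    def noise(shape):
        if config.noise_df is None:
            return rng.normal(0.0, config.noise_sd_log2, shape)
        # t noise rescaled to the requested sd
        scale = config.noise_sd_log2 / np.sqrt(config.noise_df / (config.noise_df - 2))
        return scale * rng.standard_t(config.noise_df, shape)

    cols, meta_rows = [], []
    blocks = []
    for s, strain in enumerate(strains):
        for group in ("control", "CR"):
            n = config.n_per_group
            mean = baselines[:, None] + offsets[s]
            if group == "CR":
                mean = mean + E[:, [s]]
            block = mean + noise((config.n_genes, n))
            blocks.append(block)
            for r in range(n):
                sid = f"{strain.replace('/', '_')}_{group}_{r + 1}"
                cols.append(sid)
                meta_rows.append((sid, strain, config.tissue, group, r + 1))
    values = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(genes, name="gene"), columns=cols
    )
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "strain", "tissue", "group", "replicate"]
    ).set_index("sample_id")
    study = ExpressionStudy(values, meta)

    # truth records the unattenuated effect
    shared = {genes[i]: float(effects[j]) for j, i in enumerate(shared_idx)}
    specific: Dict[str, Dict[str, float]] = {st: {} for st in strains}
    for j, (gi, s) in enumerate(zip(specific_idx, owner)):
        specific[strains[s]][genes[gi]] = float(effects[config.n_shared_effect + j])
    null_genes = tuple(g for i, g in enumerate(genes) if i not in set(effect_idx))
    truth = SimulationTruth(
        shared_effect_genes=shared,
        strain_specific_map=specific,
        null_genes=null_genes,
    )
    return study, truth


def simulate_genesets(
    genes: Sequence[str],
    n_sets: int,
    size_range: Tuple[int, int] = (10, 200),
    planted: Optional[Tuple[Sequence[str], Sequence[str], float]] = None,
    seed: int = 0,
) -> GeneSetCollection:
    """Simulate a GO-like collection, optionally with planted enrichment.

    Non-planted sets are uniform samples of the gene universe. A planted set
    samples its members with weight ``enrichment_factor`` on the genes in
    ``selected_genes`` and weight 1 elsewhere, so factor 1 reduces to the
    uniform null.

    Parameters
    ----------
    planted : (set_ids, selected_genes, enrichment_factor), optional
    """
    genes = list(genes)
    lo, hi = size_range
    if not (2 <= lo <= hi <= len(genes)):
        raise ValueError(f"infeasible size_range {size_range} for {len(genes)} genes")
    rng = np.random.default_rng(seed)
    planted_ids: Tuple[str, ...] = ()
    weights = None
    if planted is not None:
        set_ids, selected_genes, factor = planted
        if factor < 0:
            raise ValueError("enrichment_factor must be >= 0")
        planted_ids = tuple(set_ids)
        selected = set(selected_genes)
        weights = np.array([factor if g in selected else 1.0 for g in genes])
        weights = weights / weights.sum()
    sets: Dict[str, Tuple[str, Tuple[str, ...]]] = {}
    for i in range(n_sets):
        set_id = f"SET:{i:05d}"
        size = int(rng.integers(lo, hi + 1))
        if set_id in planted_ids:
            members = rng.choice(genes, size=size, replace=False, p=weights)
        else:
            members = rng.choice(genes, size=size, replace=False)
        sets[set_id] = (f"simulated set {i}", tuple(members))
    missing = [sid for sid in planted_ids if sid not in sets]
    if missing:
        raise ValueError(f"planted set_ids not of the form SET:<i> within n_sets: {missing}")
    return GeneSetCollection(sets)


def simulate_qpcr_plate(
    panel: Mapping[str, float],
    compounds: Sequence[str],
    concordant_map: Optional[Mapping[str, Mapping[str, float]]] = None,
    n_biological: int = 3,
    n_technical: int = 3,
    noise_sd_biological: float = 0.15,
    noise_sd_technical: float = 0.05,
    reference_gene: str = "Actb",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct plate for a marker panel, CR, and compound groups.

    ``panel`` maps target gene -> CR signed fold change (magnitude >= 1); the
    CR group's target Ct shifts by ``-log2(|fold|) * sign`` relative to
    controls (one cycle per doubling). ``concordant_map`` maps compound ->
    {gene -> signed fold} for genes that compound truly moves; unlisted
    compounds or genes are simulated as no-effect. Biological replicates get
    independent Ct noise; technical replicates jitter around them.
    """
    rng = np.random.default_rng(seed)
    concordant_map = concordant_map or {}
    groups = ["control", "CR"] + [f"compound:{c}" for c in compounds]
    base_ct = {g: float(rng.uniform(22.0, 28.0)) for g in panel}
    rows = []
    for group in groups:
        name = group.split(":", 1)[1] if ":" in group else group
        for b in range(n_biological):
            sid = f"{name}_{b + 1}"
            ref_level = 20.0 + rng.normal(0.0, noise_sd_biological)
            for t in range(n_technical):
                rows.append((sid, group, reference_gene,
                             ref_level + rng.normal(0.0, noise_sd_technical), True))
            for gene, cr_fold in panel.items():
                shift = 0.0
                if group == "CR":
                    shift = -np.sign(cr_fold) * np.log2(abs(cr_fold))
                elif group.startswith("compound:"):
                    fold = concordant_map.get(name, {}).get(gene)
                    if fold is not None:
                        shift = -np.sign(fold) * np.log2(abs(fold))
                level = base_ct[gene] + (ref_level - 20.0) + shift + rng.normal(
                    0.0, noise_sd_biological
                )
                for t in range(n_technical):
                    rows.append((sid, group, gene,
                                 level + rng.normal(0.0, noise_sd_technical), False))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct", "is_reference"])
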