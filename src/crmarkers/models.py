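"""Model/Results interface over the discovery and screening pipeline.

Three model classes mirror the three analyses:

* :class:`MultiStrainCR` — per-strain differential testing plus k-of-n
  consensus selection with the Poisson-Binomial chance expectation and the
  pooled two-way ANOVA / q-value cross-check.
* :class:`RandomSetEnrichment` — random-set z-scores for a gene-set
  collection against a selection, with Bonferroni threshold and the greedy
  waterfall summarisation.
* :class:`MimicryScreen` — delta-delta Ct scoring of compound groups against
  tissue marker panels.

Each model is built from data and configuration; ``fit()`` returns a Results
object carrying the tables, diagnostics and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import consensus as _consensus
from . import crm_screen as _crm
from . import diffexpr as _diffexpr
from . import enrichment as _enrichment
from .io_formats import ExpressionStudy, GeneSetCollection


class MultiStrainCR:
    """Multi-strain consensus differential-expression model for one tissue.

    Parameters
    ----------
    study : ExpressionStudy
        Log2 expression with strain/tissue/group metadata.
    tissue : str, optional
        Restrict to one tissue (required when the study mixes tissues).
    control_label, treated_label : str
        Group labels of the two diets.
    welch : bool
        Use Welch's t instead of the pooled-variance Student t.
    """

    def __init__(
        self,
        study: ExpressionStudy,
        tissue: Optional[str] = None,
        control_label: str = "control",
        treated_label: str = "CR",
        welch: bool = False,
    ) -> None:
        self.study = study if tissue is None else study.subset_tissue(tissue)
        self.tissue = tissue or "/".join(self.study.samples["tissue"].unique())
        self.control_label = control_label
        self.treated_label = treated_label
        self.welch = welch

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, samples: pd.DataFrame, **kwargs) -> "MultiStrainCR":
        return cls(ExpressionStudy(values, samples), **kwargs)

    def fit(
        self,
        alpha: float = 0.01,
        k: int = 5,
        anova: bool = True,
        use_nominal_alpha: bool = False,
    ) -> "MultiStrainCRResults":
        """Run the per-strain scan, consensus selection and cross-checks.

        Parameters
        ----------
        alpha : float
            Per-strain uncorrected p-value cut for list membership.
        k : int
            Minimum number of strain lists a consensus gene must populate.
        anova : bool
            Also fit the pooled strain+diet ANOVA and Storey q-values.
        use_nominal_alpha : bool
            Build the Poisson-Binomial null from the nominal alpha instead
            of the observed per-strain list fractions.
        """
        scan = _diffexpr.strain_scan(
            self.study,
            control_label=self.control_label,
            treated_label=self.treated_label,
            welch=self.welch,
        )
        table = _consensus.consensus_select(scan, alpha=alpha, k=k)
        null = _consensus.PoissonBinomialNull.from_scan(
            scan, alpha=alpha, use_nominal_alpha=use_nominal_alpha
        )
        anova_q = None
        if anova and self.study.samples["strain"].nunique() >= 2:
            anova_q = _diffexpr.anova_cr_effect(
                self.study,
                control_label=self.control_label,
                treated_label=self.treated_label,
            )
            qr = _diffexpr.storey_qvalue(anova_q["p_cr"].to_numpy())
            anova_q["q_value"] = qr.q_values
            anova_q.attrs["pi0"] = qr.pi0
        return MultiStrainCRResults(
            model=self, alpha=alpha, k=k, scan=scan, consensus=table, null=null, anova_q=anova_q
        )


@dataclass
class MultiStrainCRResults:
    """Fitted consensus scan: selection, chance expectation, diagnostics."""

    model: MultiStrainCR
    alpha: float
    k: int
    scan: pd.DataFrame
    consensus: pd.DataFrame
    null: _consensus.PoissonBinomialNull
    anova_q: Optional[pd.DataFrame] = None

    @property
    def selected_genes(self) -> List[str]:
        return list(self.consensus.index[self.consensus["selected_at_k"]])

    def observed_ge_k(self, k: int) -> int:
        return int((self.consensus["hit_count"] >= k).sum())

    def expression_level_bias(self) -> Dict[str, float]:
        return _consensus.expression_level_bias(self.model.study, self.selected_genes)

    def summary(self) -> str:
        n_strains = self.scan["strain"].nunique()
        lines = [
            "Multi-strain consensus differential expression",
            "=" * 54,
            f"tissue: {self.model.tissue}   strains: {n_strains}   genes: {self.model.study.n_genes}",
            f"per-strain test: {'Welch' if self.model.welch else 'pooled'} t, p < {self.alpha} (uncorrected)",
            f"consensus rule: >= {self.k}/{n_strains} strains",
            "",
            "per-strain list sizes (fraction of genes at p < alpha):",
        ]
        for strain, frac in self.null.p_s.items():
            lines.append(f"  {strain:<14} {frac:8.4f}  ({int(round(frac * self.null.n_genes))} genes)")
        lines.append("")
        lines.append("   k   observed >=k   expected by chance")
        for kk in range(1, n_strains + 1):
            lines.append(
                f"  {kk:>2}   {self.observed_ge_k(kk):>10}   {self.null.expected_ge_k[kk]:>15.3g}"
            )
        nsel = len(self.selected_genes)
        lines.append("")
        lines.append(
            f"selected at k={self.k}: {nsel} genes "
            f"(chance expectation {self.null.expected_ge_k[self.k]:.3g})"
        )
        if self.anova_q is not None:
            pi0 = self.anova_q.attrs.get("pi0", float("nan"))
            sel_q = self.anova_q.loc[self.selected_genes, "q_value"] if nsel else pd.Series(dtype=float)
            lines.append(
                f"ANOVA cross-check: pi0 = {pi0:.3f}; "
                f"max q among selected = {sel_q.max() if nsel else float('nan'):.3g}"
            )
        return "\n".join(lines)


class RandomSetEnrichment:
    """Random-set enrichment of a gene selection over a set collection.

    The collection is size-filtered against the measured universe on
    construction (inclusive bounds, defaults 10..1000 genes).
    """

    def __init__(
        self,
        universe: Sequence[str],
        selection: Iterable[str],
        collection: GeneSetCollection,
        size_min: int = 10,
        size_max: int = 1000,
        min_overlap: int = 5,
    ) -> None:
        self.universe = list(universe)
        self.selection = sorted(set(selection))
        self.collection = _enrichment.filter_sets(
            collection, self.universe, size_min=size_min, size_max=size_max
        )
        self.min_overlap = min_overlap

    def fit(self, alpha: float = 0.05) -> "RandomSetEnrichmentResults":
        threshold = _enrichment.bonferroni_z_threshold(alpha, max(len(self.collection), 1))
        table = _enrichment.randomset_z(
            self.universe,
            self.selection,
            self.collection,
            z_threshold=threshold,
            min_overlap=self.min_overlap,
        )
        return RandomSetEnrichmentResults(model=self, alpha=alpha, z_threshold=threshold, table=table)


@dataclass
class RandomSetEnrichmentResults:
    model: RandomSetEnrichment
    alpha: float
    z_threshold: float
    table: pd.DataFrame

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].sort_values("z", ascending=False)

    def waterfall(self) -> _enrichment.WaterfallPlan:
        return _enrichment.waterfall_cover(self.model.selection, self.table, self.model.collection)

    def summary(self) -> str:
        sig = self.significant
        lines = [
            "Random-set gene-set enrichment",
            "=" * 54,
            f"universe: {len(self.model.universe)} genes; selection: {len(self.model.selection)}",
            f"sets tested: {len(self.model.collection)}; "
            f"z threshold {self.z_threshold:.2f} (Bonferroni alpha={self.alpha}, one-sided), "
            f"min overlap {self.model.min_overlap}",
            f"significant sets: {len(sig)}",
        ]
        for sid, row in sig.head(10).iterrows():
            lines.append(
                f"  {sid:<14} z={row['z']:7.2f}  overlap {int(row['overlap'])}/{int(row['m'])}  "
                f"{row['description']}"
            )
        return "\n".join(lines)


class MimicryScreen:
    """Screen compound groups against tissue marker panels on qPCR plates.

    ``plates`` maps tissue -> Ct plate DataFrame, ``panels`` maps tissue ->
    :class:`crmarkers.crm_screen.PanelDefinition`.
    """

    def __init__(
        self,
        plates: Mapping[str, pd.DataFrame],
        panels: Mapping[str, _crm.PanelDefinition],
        control_group: str = "control",
    ) -> None:
        missing = [t for t in panels if t not in plates]
        if missing:
            raise ValueError(f"no plate supplied for tissues: {missing}")
        self.plates = dict(plates)
        self.panels = dict(panels)
        self.control_group = control_group

    def fit(self, alpha: float = 0.05) -> "MimicryScreenResults":
        reports: List[_crm.MimicryReport] = []
        for tissue, panel in self.panels.items():
            plate = self.plates[tissue]
            compound_groups = sorted(
                g for g in plate["group"].unique() if str(g).startswith("compound:")
            )
            for cg in compound_groups:
                reports.append(
                    _crm.score_compound(
                        plate, panel, cg, control_group=self.control_group, alpha=alpha
                    )
                )
        tally = _crm.mimicry_tally(reports)
        return MimicryScreenResults(model=self, alpha=alpha, reports=reports, tally=tally)


@dataclass
class MimicryScreenResults:
    model: MimicryScreen
    alpha: float
    reports: List[_crm.MimicryReport]
    tally: pd.DataFrame

    def report_for(self, compound: str, tissue: str) -> _crm.MimicryReport:
        for r in self.reports:
            if r.compound == compound and r.tissue == tissue:
                return r
        raise KeyError((compound, tissue))

    def summary(self) -> str:
        lines = [
            "CR-mimetic qPCR screen",
            "=" * 54,
            f"tissues: {', '.join(self.model.panels)}   "
            f"panel sizes: {', '.join(str(len(p.genes)) for p in self.model.panels.values())}",
            f"significance: two-sided t on per-sample delta Ct, p < {self.alpha}",
            "",
            "compound ranking (genes moved in CR direction / opposite / unchanged):",
        ]
        for compound, row in self.tally.iterrows():
            lines.append(
                f"  {compound:<16} {int(row['same']):>3} same  {int(row['opposite']):>3} opposite  "
                f"{int(row['unchanged']):>3} unchanged"
            )
        return "\n".join(lines)
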