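"""qPCR-based scoring of candidate caloric-restriction mimetics.

A compound is scored against a tissue-specific marker panel by the delta-delta
Ct method: per sample, Ct of the target gene minus Ct of the reference gene
(delta Ct); the group mean difference against controls (delta-delta Ct) maps
to a relative expression of 2**(-ddCt). Each panel gene is then classified as
changed in the same direction as CR, the opposite direction, or unchanged
(not significant), and compounds are ranked by how many panel genes they move
the CR way without moving any the other way.

Plates arrive as CSV with columns ``sample_id, group, gene, ct, is_reference``
(one reference-gene measurement per sample). Technical replicates of the same
(sample, gene) are averaged before testing, so biological n drives the
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .diffexpr import signed_fold_change, student_ttest

PLATE_COLUMNS = ("sample_id", "group", "gene", "ct", "is_reference")


@dataclass
class PanelDefinition:
    """A tissue's qPCR marker panel with the CR reference direction per gene.

    ``genes`` maps gene symbol -> signed CR fold change (magnitude >= 1);
    the sign is the direction the compound must reproduce to count as a
    CR-mimetic hit. Default panel sizes in this screen are 7 (heart),
    10 (gastrocnemius) and 11 (WAT), but any panel is accepted.
    """

    tissue: str
    genes: Dict[str, float]

    def __post_init__(self) -> None:
        for g, f in self.genes.items():
            if abs(f) < 1.0:
                raise ValueError(f"panel fold for {g!r} must use the signed magnitude->=1 convention")


def read_ct_plate(path) -> pd.DataFrame:
    plate = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"Ct plate {path} missing columns {missing}")
    if not np.isfinite(plate["ct"]).all() or (plate["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    return plate


def write_ct_plate(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, index=False)


def _delta_ct(plate: pd.DataFrame, gene: str, group: str) -> np.ndarray:
    """Per-biological-sample delta Ct (target - reference), technical reps averaged.

    When a sample carries several reference genes their Ct values are
    averaged, which on the cycle (log2) scale is the geometric mean of the
    reference expression levels — the standard multi-reference normaliser.
    """
    sub = plate[plate["group"] == group]
    ref = sub[sub["is_reference"].astype(bool)].groupby("sample_id")["ct"].mean()
    tgt = sub[(sub["gene"] == gene) & (~sub["is_reference"].astype(bool))].groupby("sample_id")[
        "ct"
    ].mean()
    if tgt.empty:
        raise ValueError(f"gene {gene!r} not measured in group {group!r}")
    if ref.empty:
        raise ValueError(f"no reference-gene measurements in group {group!r}")
    common = tgt.index.intersection(ref.index)
    if len(common) == 0:
        raise ValueError(f"no sample has both {gene!r} and the reference gene in group {group!r}")
    return (tgt.loc[common] - ref.loc[common]).to_numpy()


def ddct_fold_change(
    plate: pd.DataFrame, gene: str, group: str, control_group: str = "control"
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Delta-delta Ct relative expression of ``group`` vs ``control_group``.

    Returns ``(signed_fold, dct_group, dct_control)`` where the per-sample
    delta Ct vectors feed the significance test. Relative expression is
    2**(-ddCt) with ddCt the group-mean delta Ct difference, reported in the
    signed magnitude->=1 fold convention.
    """
    dct_g = _delta_ct(plate, gene, group)
    dct_c = _delta_ct(plate, gene, control_group)
    ddct = dct_g.mean() - dct_c.mean()
    log2_rel = -ddct  # one PCR cycle = one doubling
    return signed_fold_change(log2_rel), dct_g, dct_c


def classify_concordance(
    compound_fold: float,
    compound_p: float,
    cr_fold: float,
    alpha: float = 0.05,
) -> str:
    """Classify a compound's effect on one panel gene vs the CR reference.

    ``unchanged`` if the compound effect is not significant (p >= alpha),
    otherwise ``same``/``opposite`` by agreement of the signed fold
    direction with the CR reference direction.
    """
    if compound_p >= alpha:
        return "unchanged"
    return "same" if (compound_fold > 0) == (cr_fold > 0) else "opposite"


@dataclass
class MimicryReport:
    """Per compound x tissue classification of the panel genes."""

    compound: str
    tissue: str
    genes_same: List[str] = field(default_factory=list)
    genes_opposite: List[str] = field(default_factory=list)
    genes_unchanged: List[str] = field(default_factory=list)
    folds: Dict[str, float] = field(default_factory=dict)
    p_values: Dict[str, float] = field(default_factory=dict)

    @property
    def panel_genes(self) -> List[str]:
        return sorted(self.genes_same + self.genes_opposite + self.genes_unchanged)


def score_compound(
    plate: pd.DataFrame,
    panel: PanelDefinition,
    compound_group: str,
    control_group: str = "control",
    alpha: float = 0.05,
) -> MimicryReport:
    """Score one compound group against a panel on a single plate."""
    compound = compound_group.split(":", 1)[1] if ":" in compound_group else compound_group
    report = MimicryReport(compound=compound, tissue=panel.tissue)
    for gene, cr_fold in panel.genes.items():
        fold, dct_g, dct_c = ddct_fold_change(plate, gene, compound_group, control_group)
        _, p = student_ttest(dct_g, dct_c)
        report.folds[gene] = fold
        report.p_values[gene] = p
        label = classify_concordance(fold, p, cr_fold, alpha=alpha)
        {"same": report.genes_same,
         "opposite": report.genes_opposite,
         "unchanged": report.genes_unchanged}[label].append(gene)
    return report


def mimicry_tally(reports: Sequence[MimicryReport]) -> pd.DataFrame:
    """Aggregate per-tissue reports into a compound ranking table.

    Compounds are ranked by total genes moved in the CR direction
    (descending), then genes moved opposite (ascending). Reports must cover
    disjoint (tissue, gene) panels.
    """
    seen: Dict[Tuple[str, str, str], None] = {}
    for r in reports:
        for g in r.panel_genes:
            key = (r.compound, r.tissue, g)
            if key in seen:
                raise ValueError(f"duplicate (tissue, gene) across reports: {key}")
            seen[key] = None
    rows: Dict[str, Dict[str, int]] = {}
    for r in reports:
        d = rows.setdefault(r.compound, {"same": 0, "opposite": 0, "unchanged": 0})
        d["same"] += len(r.genes_same)
        d["opposite"] += len(r.genes_opposite)
        d["unchanged"] += len(r.genes_unchanged)
    table = pd.DataFrame.from_dict(rows, orient="index").rename_axis("compound")
    return table.sort_values(["same", "opposite"], ascending=[False, True])
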