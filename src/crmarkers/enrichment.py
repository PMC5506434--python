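"""Random-set gene-set enrichment and greedy waterfall summarisation.

Each gene carries a binary score (1 if in the consensus selection, 0
otherwise). For a set of m genes drawn from a universe of N, the mean score
of a uniformly random same-size set has mean mu = mean(x) and variance
(sigma^2 / m) * (N - m) / (N - 1) with sigma^2 the population variance of
the scores — sampling without replacement. Standardising the observed
set mean against these moments gives the random-set z-score, which for
binary scores equals the standardised hypergeometric overlap count.

Significance uses a one-sided (over-representation) normal quantile at a
Bonferroni-corrected level plus a minimum-overlap rule. The waterfall plan
then summarises the significant sets by greedy sequential coverage: at each
step, claim the significant set covering the most still-uncovered selected
genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSetCollection


def randomset_z(
    universe: Sequence[str],
    selection: Iterable[str],
    sets: GeneSetCollection,
    z_threshold: Optional[float] = None,
    min_overlap: int = 5,
    scores: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Random-set enrichment z-scores for every set against a gene selection.

    Sets are intersected with the universe before sizing; sets of size 0 or
    covering the whole universe have zero sampling variance and are skipped
    rather than raising.

    By default gene scores are binary (selection membership), in which case
    z is the standardised hypergeometric overlap. Passing ``scores`` (gene ->
    real score over the whole universe) switches to the continuous random-set
    statistic with the same moments formula; ``overlap`` still counts
    selected genes for the min-overlap rule.

    Returns a DataFrame indexed by set_id with columns ``description, m,
    overlap, z, significant`` (``significant`` requires a ``z_threshold``;
    it additionally demands ``overlap >= min_overlap``).
    """
    universe = list(universe)
    N = len(universe)
    uni_pos = {g: i for i, g in enumerate(universe)}
    sel = set(selection)
    stray = sel - uni_pos.keys()
    if stray:
        raise ValueError(f"selection contains genes outside the universe: {sorted(stray)[:5]}")
    if scores is None:
        x = np.zeros(N)
        for g in sel:
            x[uni_pos[g]] = 1.0
    else:
        missing = [g for g in universe if g not in scores]
        if missing:
            raise ValueError(f"scores missing for universe genes: {missing[:5]}")
        x = np.array([float(scores[g]) for g in universe])
    mu = x.mean()
    sigma2 = x.var()  # population variance
    rows = []
    for set_id in sets:
        members = [g for g in sets.members(set_id) if g in uni_pos]
        m = len(members)
        if m == 0 or m == N:
            continue
        overlap = sum(1 for g in members if g in sel)
        mean_set = float(np.mean([x[uni_pos[g]] for g in members]))
        se = np.sqrt((sigma2 / m) * (N - m) / (N - 1))
        z = (mean_set - mu) / se if se > 0 else 0.0
        rows.append((set_id, sets.description(set_id), m, overlap, z))
    table = pd.DataFrame(
        rows, columns=["set_id", "description", "m", "overlap", "z"]
    ).set_index("set_id")
    if z_threshold is not None:
        table["significant"] = (table["z"] > z_threshold) & (table["overlap"] >= min_overlap)
        table.attrs["z_threshold"] = z_threshold
    table.attrs["min_overlap"] = min_overlap
    return table


def bonferroni_z_threshold(alpha: float, n_sets: int) -> float:
    """One-sided upper-normal quantile at the Bonferroni-corrected level alpha/n_sets."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    return float(stats.norm.isf(alpha / n_sets))


def filter_sets(
    sets: GeneSetCollection,
    universe: Sequence[str],
    size_min: int = 10,
    size_max: int = 1000,
) -> GeneSetCollection:
    """Drop sets whose size after universe intersection is outside [size_min, size_max].

    Bounds are inclusive: a set annotating exactly ``size_min`` genes stays.
    """
    inter = sets.intersect_universe(universe)
    kept = {
        sid: payload
        for sid, payload in inter.sets.items()
        if size_min <= len(payload[1]) <= size_max
    }
    return GeneSetCollection(kept)


@dataclass
class WaterfallStep:
    set_id: str
    description: str
    z: float
    newly_covered: Tuple[str, ...]
    overlap_with_prior: Tuple[str, ...]


@dataclass
class WaterfallPlan:
    """Ordered greedy coverage of the selection by significant sets."""

    steps: List[WaterfallStep] = field(default_factory=list)
    uncovered_remainder: Tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set_id": [s.set_id for s in self.steps],
                "description": [s.description for s in self.steps],
                "z": [s.z for s in self.steps],
                "n_new": [len(s.newly_covered) for s in self.steps],
                "n_prior": [len(s.overlap_with_prior) for s in self.steps],
                "newly_covered": [";".join(s.newly_covered) for s in self.steps],
            }
        )


def waterfall_cover(
    selection: Iterable[str],
    table: pd.DataFrame,
    sets: GeneSetCollection,
) -> WaterfallPlan:
    """Greedy sequential coverage of the selected genes by significant sets.

    At each step the significant set with the largest overlap with the
    still-uncovered selection is claimed; ties break by larger z, then
    lexicographic set_id. The procedure stops when no significant set covers
    a single uncovered gene, so the steps' newly-covered groups partition
    the covered part of the selection.
    """
    if "significant" not in table.columns:
        raise ValueError("enrichment table lacks a 'significant' column; pass a z_threshold")
    selection = sorted(set(selection))
    uncovered: Set[str] = set(selection)
    covered: Set[str] = set()
    sig_ids = [sid for sid in table.index[table["significant"]]]
    members = {sid: set(sets.members(sid)) & set(selection) for sid in sig_ids}
    steps: List[WaterfallStep] = []
    used: Set[str] = set()
    while uncovered:
        # max overlap, then larger z; lexicographically smallest set_id wins ties
        candidates = [
            (-len(members[sid] & uncovered), -float(table.at[sid, "z"]), sid)
            for sid in sig_ids
            if sid not in used and members[sid] & uncovered
        ]
        if not candidates:
            break
        _, _, sid = min(candidates)
        new = tuple(sorted(members[sid] & uncovered))
        prior = tuple(sorted(members[sid] & covered))
        steps.append(
            WaterfallStep(
                set_id=sid,
                description=table.at[sid, "description"],
                z=float(table.at[sid, "z"]),
                newly_covered=new,
                overlap_with_prior=prior,
            )
        )
        used.add(sid)
        uncovered -= set(new)
        covered |= set(new)
    return WaterfallPlan(steps=steps, uncovered_remainder=tuple(sorted(uncovered)))


def plot_waterfall(plan: WaterfallPlan, ax=None):
    """Stacked horizontal-bar rendering of a waterfall plan.

    Each row is one claimed set; the filled segment counts newly covered
    genes, the hatched segment genes already described by earlier rows.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * max(len(plan.steps), 1) + 1))
    labels, offset = [], 0
    for i, step in enumerate(plan.steps):
        ax.barh(i, len(step.newly_covered), left=offset, color="steelblue")
        ax.barh(i, len(step.overlap_with_prior), left=offset - len(step.overlap_with_prior),
                color="lightgray", hatch="//")
        offset += len(step.newly_covered)
        labels.append(f"{step.description or step.set_id} (z={step.z:.1f})")
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=8)
    ax.invert_yaxis()
    ax.set_xlabel("genes covered (cumulative)")
    return ax
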