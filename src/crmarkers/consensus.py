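"""k-of-n multi-strain consensus selection and its Poisson-Binomial null.

A gene is declared a caloric-restriction marker when it passes the per-strain
test (p < alpha, any direction) in at least k of the n strains. Under the
null hypothesis that CR effects in different strains are unrelated, a gene's
strain-hit count is a sum of independent Bernoulli trials with per-strain
success probabilities p_s, i.e. Poisson-Binomial distributed; multiplying
the upper-tail probability P(X >= k) by the number of genes gives the count
of consensus genes expected by chance alone. The per-strain probabilities
may be taken as the observed per-strain list fractions (default: accounts
for list-size inflation by real effects) or as the nominal alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionStudy


def consensus_select(scan: pd.DataFrame, alpha: float = 0.01, k: int = 5) -> pd.DataFrame:
    """Count per-gene strain hits at p < alpha and select genes with >= k hits.

    Hits are counted irrespective of the direction of change (strict
    inequality p < alpha). Direction consistency — all hit strains agreeing
    on the sign of the mean difference — is reported as a diagnostic but is
    never used as a filter.

    Parameters
    ----------
    scan : pandas.DataFrame
        Tidy per-(gene, strain) table from :func:`crmarkers.diffexpr.strain_scan`.
    """
    n_strains = scan["strain"].nunique()
    if not 1 <= k <= n_strains:
        raise ValueError(f"k={k} out of range for {n_strains} strains")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    hit = scan["p_value"] < alpha
    up = scan["delta_log2"] > 0
    df = scan.assign(hit=hit, up=up)
    grouped = df.groupby("gene", sort=True)
    hit_count = grouped["hit"].sum().astype(int)

    hits_only = df[df["hit"]]
    by_gene = hits_only.groupby("gene")
    hit_strains = by_gene["strain"].agg(lambda s: tuple(sorted(s)))
    n_up = by_gene["up"].sum()
    n_hit = by_gene["up"].size()
    consistent = (n_up == 0) | (n_up == n_hit)

    out = pd.DataFrame(index=hit_count.index)
    out["hit_count"] = hit_count
    out["hit_strains"] = hit_strains.reindex(out.index, fill_value=()).apply(tuple)
    out["direction_consistent"] = consistent.reindex(out.index, fill_value=True)
    out["selected_at_k"] = out["hit_count"] >= k
    out.index.name = "gene"
    return out


def pb_pmf(p_s: Sequence[float]) -> np.ndarray:
    """Exact Poisson-Binomial pmf of a sum of independent Bernoulli trials.

    Computed by iterative convolution (dynamic programming, O(n^2)), which
    is exact and stable for the small n used here (one trial per strain).
    """
    p = np.asarray(p_s, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for pi in p:
        pmf = np.convolve(pmf, [1.0 - pi, pi])
    return pmf


def pb_sf(p_s: Sequence[float], k: int) -> float:
    """P(X >= k) under the Poisson-Binomial with success probabilities p_s."""
    pmf = pb_pmf(p_s)
    if k <= 0:
        return 1.0
    return float(pmf[k:].sum())


def expected_multistrain_count(p_s: Sequence[float], k: int, n_genes: int) -> float:
    """Expected number of genes on >= k per-strain lists by chance alone."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return n_genes * pb_sf(p_s, k)


def observed_strain_hit_rates(scan: pd.DataFrame, alpha: float = 0.01) -> pd.Series:
    """Per-strain fraction of genes with p < alpha (the observed list sizes).

    This is the default plug-in estimate of the per-strain Bernoulli
    probabilities for the null: real treatment effects inflate the lists
    beyond the nominal alpha, and the chance-overlap expectation should
    reflect the lists actually in use.
    """
    return scan.groupby("strain")["p_value"].apply(lambda p: float((p < alpha).mean()))


@dataclass
class PoissonBinomialNull:
    """Null expectations for the strain-hit count at every k."""

    p_s: pd.Series
    n_genes: int
    pmf: np.ndarray
    expected_ge_k: Dict[int, float]

    @classmethod
    def from_scan(
        cls,
        scan: pd.DataFrame,
        alpha: float = 0.01,
        use_nominal_alpha: bool = False,
    ) -> "PoissonBinomialNull":
        n_genes = scan["gene"].nunique()
        if use_nominal_alpha:
            strains = sorted(scan["strain"].unique())
            p_s = pd.Series(alpha, index=pd.Index(strains, name="strain"))
        else:
            p_s = observed_strain_hit_rates(scan, alpha)
        pmf = pb_pmf(p_s.to_numpy())
        sf = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
        expected = {k: float(n_genes * sf[k]) for k in range(len(p_s) + 1)}
        return cls(p_s=p_s, n_genes=n_genes, pmf=pmf, expected_ge_k=expected)


def expression_level_bias(
    study: ExpressionStudy, selected_genes: Iterable[str]
) -> Dict[str, float]:
    """Compare mean log2 expression of selected genes against the full transcriptome.

    Returns the two means and a two-sided Wilcoxon rank-sum p-value for the
    selected genes' per-gene mean expression against that of all genes.
    Consensus markers tend to sit above the transcriptome-wide level, and
    this diagnostic quantifies that expression-level bias.
    """
    selected = list(dict.fromkeys(selected_genes))
    if not selected:
        raise ValueError("empty gene selection")
    missing = [g for g in selected if g not in study.values.index]
    if missing:
        raise ValueError(f"selected genes absent from study: {missing[:5]}")
    per_gene = study.values.mean(axis=1)
    sel = per_gene.loc[selected].to_numpy()
    allg = per_gene.to_numpy()
    if np.ptp(allg) == 0 or set(selected) == set(study.genes):
        p = 1.0
        stat = float(len(sel) * len(allg) / 2.0)
    else:
        stat, p = stats.mannwhitneyu(sel, allg, alternative="two-sided")
    return {
        "mean_selected": float(sel.mean()),
        "mean_all": float(allg.mean()),
        "rank_sum_u": float(stat),
        "p_value": float(p),
    }
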