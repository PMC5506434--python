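"""Per-strain two-group tests, signed fold changes, and the across-strain
ANOVA with Storey q-value FDR.

The discovery design is deliberately simple: within each strain, every gene
gets an uncorrected pooled-variance two-sample t-test between control and
treated (CR) groups; cross-strain error control comes later, from requiring
membership on several per-strain lists (see :mod:`crmarkers.consensus`). As
an independent check, the strains are combined in a per-gene two-way ANOVA
(strain + diet, additive) and the diet main-effect p-values are converted to
q-values with Storey's pi0-adaptive FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .io_formats import ExpressionStudy


def student_ttest(group_a: np.ndarray, group_b: np.ndarray, welch: bool = False) -> Tuple[float, float]:
    """Two-sided two-sample t-test, pooled variance by default.

    Returns ``(t, p)`` with ``df = n_a + n_b - 2`` for the pooled form. When
    both groups have zero pooled variance the test is undefined; we return
    ``t=0, p=1`` with a warning rather than NaN so genome-wide scans never
    propagate missing values.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("each group needs >= 2 finite values")
    if welch:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    na, nb = a.size, b.size
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled == 0.0:
        if a.mean() == b.mean():
            warnings.warn("zero pooled variance and equal means; returning t=0, p=1")
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means; p -> 0")
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t = (a.mean() - b.mean()) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df=na + nb - 2)
    return float(t), float(p)


def signed_fold_change(delta_log2: float) -> float:
    """Signed ratio convention with magnitude >= 1.

    A log2 difference d maps to 2**d when d >= 0 and to -2**(-d) otherwise,
    so a 2.47-fold decrease prints as -2.47 rather than 0.405.
    """
    if delta_log2 >= 0:
        return float(2.0 ** delta_log2)
    return float(-(2.0 ** (-delta_log2)))


def _ttest_matrix(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised pooled t over gene rows: a, b are (genes, n) arrays."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    zero = se == 0
    t[zero & (ma == mb)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=na + nb - 2)
    p[zero & (ma == mb)] = 1.0
    p[zero & (ma != mb)] = 0.0
    return t, p


def strain_scan(
    study: ExpressionStudy,
    tissue: Optional[str] = None,
    control_label: str = "control",
    treated_label: str = "CR",
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene, per-strain differential test of treated vs control.

    Each strain is tested separately with a two-sided pooled-variance t-test
    (or Welch when requested); no multiple-testing correction is applied by
    design — error control happens at the multi-strain consensus step.

    Returns a tidy DataFrame with one row per (gene, strain):
    ``gene, strain, t_stat, p_value, mean_control, mean_treated, delta_log2,
    signed_fc, direction``. The t statistic is oriented treated minus
    control, so its sign matches the direction of the CR effect.
    """
    if tissue is not None:
        study = study.subset_tissue(tissue)
    meta = study.samples
    frames = []
    for strain in meta["strain"].unique():
        rows = meta.index[(meta["strain"] == strain)]
        groups = meta.loc[rows, "group"]
        ctrl = rows[groups == control_label]
        trt = rows[groups == treated_label]
        if len(ctrl) < 2 or len(trt) < 2:
            warnings.warn(
                f"strain {strain!r}: needs >=2 samples in both {control_label!r} "
                f"and {treated_label!r}; skipped"
            )
            continue
        a = study.values[list(trt)].to_numpy()
        b = study.values[list(ctrl)].to_numpy()
        if welch:
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        else:
            t, p = _ttest_matrix(a, b)
        delta = a.mean(axis=1) - b.mean(axis=1)
        sfc = np.where(delta >= 0, 2.0 ** delta, -(2.0 ** (-delta)))
        direction = np.where(delta > 0, "up", np.where(delta < 0, "down", "none"))
        frames.append(
            pd.DataFrame(
                {
                    "gene": study.genes,
                    "strain": strain,
                    "t_stat": t,
                    "p_value": p,
                    "mean_control": b.mean(axis=1),
                    "mean_treated": a.mean(axis=1),
                    "delta_log2": delta,
                    "signed_fc": sfc,
                    "direction": direction,
                }
            )
        )
    if not frames:
        raise ValueError("no strain had both groups with >= 2 samples")
    return pd.concat(frames, ignore_index=True)


def anova_cr_effect(
    study: ExpressionStudy,
    tissue: Optional[str] = None,
    control_label: str = "control",
    treated_label: str = "CR",
    interaction: bool = False,
) -> pd.DataFrame:
    """Per-gene two-way fixed-effects ANOVA of diet pooled over strains.

    Fits ``expression ~ strain + diet`` (additive by default) per gene and
    reports the F statistic and p-value for the diet main effect, computed
    as a model comparison against the strain-only fit (Type II sums of
    squares, which is what an unbalanced group count requires). With
    ``interaction=True`` the residual comes from the strain*diet model
    instead.
    """
    if tissue is not None:
        study = study.subset_tissue(tissue)
    meta = study.samples
    keep = meta.index[meta["group"].isin([control_label, treated_label])]
    meta = meta.loc[keep]
    strains = meta["strain"].unique()
    if len(strains) < 2:
        raise ValueError("ANOVA needs >= 2 strains; use strain_scan for a single strain")
    if set(meta["group"]) != {control_label, treated_label}:
        raise ValueError("both diet groups must be present")
    Y = study.values[list(keep)].to_numpy()
    strain_dummies = pd.get_dummies(meta["strain"], drop_first=False).to_numpy(float)
    diet = (meta["group"] == treated_label).to_numpy(float)[:, None]
    X_reduced = strain_dummies
    X_full = np.hstack([strain_dummies, diet])
    if interaction:
        inter = strain_dummies[:, 1:] * diet
        X_res = np.hstack([X_full, inter])
    else:
        X_res = X_full

    def rss(X: np.ndarray) -> Tuple[np.ndarray, int]:
        Q, _ = np.linalg.qr(X)
        resid = Y.T - Q @ (Q.T @ Y.T)
        rank = np.linalg.matrix_rank(X)
        return (resid ** 2).sum(axis=0), rank

    rss_r, _ = rss(X_reduced)
    rss_f, rank_f = rss(X_full)
    rss_res, rank_res = rss(X_res)
    df_den = len(keep) - rank_res
    F = (rss_r - rss_f) / (rss_res / df_den)
    F = np.clip(F, 0.0, None)
    p = stats.f.sf(F, 1, df_den)
    return pd.DataFrame({"F_cr": F, "p_cr": p}, index=pd.Index(study.genes, name="gene"))


@dataclass
class QValueResult:
    q_values: np.ndarray
    pi0: float


def estimate_pi0(p_values: np.ndarray, lambdas: Optional[np.ndarray] = None) -> float:
    """Estimate the null proportion pi0 on a lambda grid with spline smoothing.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed over
    lambda in {0.05, 0.10, ..., 0.95}, smoothed with a cubic smoothing
    spline, evaluated at the largest lambda, and clipped to (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    spline = interpolate.UnivariateSpline(lambdas, pi0_lambda, k=3)
    pi0 = float(spline(lambdas.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalue(p_values: np.ndarray, pi0: Optional[float] = None) -> QValueResult:
    """Storey q-values for a vector of p-values.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j over the sorted p-values, with
    the original order restored. Forcing ``pi0=1`` recovers the
    Benjamini-Hochberg adjusted p-values exactly.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(q_values=q, pi0=float(pi0))
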