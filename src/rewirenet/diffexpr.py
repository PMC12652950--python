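"""Negative-binomial GLM differential expression with Wald tests.

This is a deliberately transparent emulation of the DESeq2 workflow:
median-of-ratios size factors, per-gene method-of-moments dispersion
shrunk toward a fitted ``phi(mu) = a/mu + b`` trend, an NB log-linear model
fit by IRLS with the size factors as offsets, and a two-sided normal Wald
p-value on the group coefficient.  There is no Cook's-distance filtering,
no independent filtering and no fold-change shrinkage.

Significance calls intentionally use the *unadjusted* p-value together with
a fold-change cut (defaults ``p <= 0.05`` and ``|log2FC| >= 0.5``); BH-
adjusted p-values are reported alongside for transparency.  Positive log2FC
means higher expression in the non-reference (second) group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "size_factors",
    "estimate_dispersion",
    "fit_glm_wald",
    "classify_deg",
]

LN2 = np.log(2.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, scaled to geometric mean 1.

    Falls back to library-size ratios (with a warning) when no gene has
    all-positive counts.
    """
    x = counts.to_numpy(dtype=float)
    if (x.sum(axis=0) <= 0).any():
        raise ValueError("every sample needs at least one nonzero count")
    allpos = np.all(x > 0, axis=1)
    if allpos.any():
        logx = np.log(x[allpos])
        ratios = logx - logx.mean(axis=1, keepdims=True)
        logf = np.median(ratios, axis=0)
    else:
        logger.warning(
            "no gene with all-positive counts; using library-size ratios"
        )
        logf = np.log(x.sum(axis=0))
    logf = logf - logf.mean()  # geometric mean 1
    return pd.Series(np.exp(logf), index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    shrink_weight: float = 0.5,
    floor: float = 1e-8,
) -> pd.DataFrame:
    """Per-gene NB dispersion: moments estimate shrunk toward a mean trend.

    ``phi_mom = max(0, (var - mu) / mu^2)`` on size-factor-normalized
    counts; the trend ``phi(mu) = a/mu + b`` is fit by least squares over
    genes with positive moments estimates, and the final value is
    ``shrink_weight * trend + (1 - shrink_weight) * phi_mom``, floored.
    With fewer than 10 positive estimates the trend is skipped.
    """
    if counts.shape[1] < 3:
        raise ValueError("dispersion estimation needs at least 3 samples")
    norm = counts.to_numpy(dtype=float) / factors.to_numpy()
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_mom = np.where(mu > 0, (var - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
    phi_mom = np.maximum(phi_mom, 0.0)

    pos = (phi_mom > 0) & (mu > 0)
    if pos.sum() >= 10:
        design = np.column_stack([1.0 / mu[pos], np.ones(pos.sum())])
        coef, *_ = np.linalg.lstsq(design, phi_mom[pos], rcond=None)
        a, b = float(coef[0]), float(coef[1])
        a, b = max(a, 0.0), max(b, 0.0)
        with np.errstate(divide="ignore"):
            phi_trend = np.where(mu > 0, a / np.maximum(mu, 1e-300) + b, b)
    else:
        logger.warning("too few positive dispersion estimates; trend skipped")
        phi_trend = phi_mom.copy()
    phi = shrink_weight * phi_trend + (1.0 - shrink_weight) * phi_mom
    return pd.DataFrame(
        {
            "mu": mu,
            "phi_mom": phi_mom,
            "phi_trend": phi_trend,
            "phi": np.maximum(phi, floor),
        },
        index=counts.index,
    )


def _design_matrix(
    samples: pd.DataFrame, covariates: tuple[str, ...], group_col: str, reference: str
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(samples))]
    names = ["intercept"]
    for cov in covariates:
        levels = sorted(samples[cov].unique())
        for lev in levels[1:]:
            cols.append((samples[cov] == lev).to_numpy(dtype=float))
            names.append(f"{cov}[{lev}]")
    glevels = samples[group_col].unique().tolist()
    other = [g for g in glevels if g != reference]
    if len(other) != 1 or reference not in glevels:
        raise ValueError("group column must have exactly two levels incl. reference")
    cols.append((samples[group_col] == other[0]).to_numpy(dtype=float))
    names.append(f"{group_col}[{other[0]}]")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is not full rank")
    return x, names


def fit_glm_wald(
    counts: pd.DataFrame,
    factors: pd.Series,
    phi: pd.Series | np.ndarray,
    samples: pd.DataFrame,
    covariates: tuple[str, ...] = ("location",),
    group_col: str = "group",
    reference: str = "fertile",
    p_cut: float = 0.05,
    lfc_cut: float = 0.5,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Fit ``log mu = log(size factor) + X beta`` per gene; Wald-test the
    group coefficient.

    Returns a table with base_mean, log2fc (group effect in log2 units),
    se, stat (Wald z), p (two-sided normal), padj (BH), direction, plus
    ``converged`` and ``stabilized`` diagnostic flags.  Genes with one group
    entirely at zero get a 0.5 pseudo-count on every observation
    (``stabilized``) to avoid infinite estimates.
    """
    x, names = _design_matrix(samples, covariates, group_col, reference)
    y = counts.to_numpy(dtype=float)
    sf = factors.to_numpy(dtype=float)
    phi_arr = np.maximum(np.asarray(phi, dtype=float).reshape(-1), 1e-12)
    n_genes, n_samples = y.shape
    p_params = x.shape[1]
    gidx = p_params - 1  # group coefficient is last

    group2 = (samples[group_col] != reference).to_numpy()
    zero1 = y[:, ~group2].sum(axis=1) == 0
    zero2 = y[:, group2].sum(axis=1) == 0
    stabilized = (zero1 | zero2) & ~(zero1 & zero2)
    if stabilized.any():
        y = y.copy()
        y[stabilized] += 0.5

    offset = np.log(sf)[None, :]
    mu = np.maximum(y, 0.5)
    eta = np.log(mu)
    beta = np.zeros((n_genes, p_params))
    converged = np.zeros(n_genes, dtype=bool)
    xtwx = np.empty((n_genes, p_params, p_params))
    for _ in range(max_iter):
        w = mu / (1.0 + phi_arr[:, None] * mu)
        z = (eta - offset) + (y - mu) / mu
        xtwx = np.einsum("gs,sp,sq->gpq", w, x, x, optimize=True)
        xtwz = np.einsum("gs,sp,gs->gp", w, x, z, optimize=True)
        try:
            new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            xtwx += 1e-8 * np.eye(p_params)[None]
            new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta), axis=1)
        beta = new_beta
        eta = np.clip(offset + beta @ x.T, -30.0, 30.0)
        mu = np.exp(eta)
        converged |= delta < tol
        if converged.all():
            break

    cov = np.linalg.pinv(xtwx)
    se_ln = np.sqrt(np.maximum(cov[:, gidx, gidx], 0.0))
    beta_group = beta[:, gidx]
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se_ln > 0, beta_group / se_ln, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(stat))
    pvals = np.clip(pvals, 0.0, 1.0)
    stat = np.where(converged, stat, np.nan)

    padj = multipletests(pvals, method="fdr_bh")[1]
    log2fc = beta_group / LN2
    base_mean = (counts.to_numpy(dtype=float) / sf).mean(axis=1)
    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se_ln / LN2,
            "stat": stat,
            "p": pvals,
            "padj": padj,
            "direction": classify_deg(log2fc, pvals, p_cut=p_cut, lfc_cut=lfc_cut),
            "converged": converged,
            "stabilized": stabilized,
        },
        index=counts.index,
    )
    n_up = int((table["direction"] == "up").sum())
    n_down = int((table["direction"] == "down").sum())
    logger.info("DE genes: %d up, %d down of %d tested", n_up, n_down, n_genes)
    return table


def classify_deg(
    log2fc: np.ndarray | float,
    p: np.ndarray | float,
    p_cut: float = 0.05,
    lfc_cut: float = 0.5,
) -> np.ndarray | str:
    """Call up / down / ns at inclusive thresholds on p and |log2FC|."""
    lfc = np.asarray(log2fc, dtype=float)
    pv = np.asarray(p, dtype=float)
    sig = pv <= p_cut
    out = np.where(
        sig & (lfc >= lfc_cut), "up", np.where(sig & (lfc <= -lfc_cut), "down", "ns")
    )
    if out.ndim == 0:
        return str(out)
    return out
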