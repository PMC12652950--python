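"""Expression filtering, CPM normalization, exploratory PCA, covariate screen.

The expression filter re-implements the edgeR ``filterByExpr`` rule in its
documented simplified form: with ``L`` the median library size in millions
and ``cpm_cut = min_count / L``, a gene is kept iff its CPM reaches
``cpm_cut`` in at least as many samples as the smallest group has, and its
total count reaches ``min_total``.  The large-sample adjustments of the
original are deliberately omitted; this rule is the contract.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["filter_low_expression", "cpm", "pca_explore", "covariate_screen"]


def _check_samples(counts: pd.DataFrame, samples: pd.DataFrame) -> None:
    if list(counts.columns) != list(samples["sample"]):
        raise ValueError("sample metadata does not match count matrix columns")


def filter_low_expression(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    min_count: float = 10.0,
    min_total: float = 15.0,
    group_col: str = "group",
) -> pd.DataFrame:
    """Remove lowly expressed genes; returns the row-subset count matrix."""
    _check_samples(counts, samples)
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every sample must have a positive library size")
    smallest_group = int(samples[group_col].value_counts().min())
    cpm_cut = min_count / (np.median(lib) / 1e6)
    cpm_mat = counts / lib * 1e6
    keep = ((cpm_mat >= cpm_cut).sum(axis=1) >= smallest_group) & (
        counts.sum(axis=1) >= min_total
    )
    if not keep.any():
        raise ValueError(
            f"all genes removed by expression filter (min_count={min_count}, "
            f"min_total={min_total}, cpm cutoff={cpm_cut:.3g})"
        )
    logger.info("expression filter kept %d / %d genes", int(keep.sum()), len(counts))
    return counts.loc[keep]


def cpm(counts: pd.DataFrame, log: bool = False, prior: float = 0.5) -> pd.DataFrame:
    """Counts per million; optionally ``log2(CPM + prior)``.

    The log offset is applied on the CPM scale (a flat ``prior`` pseudo-CPM,
    default 0.5), which keeps the transform library-size free.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    vals = counts / lib * 1e6
    if log:
        vals = np.log2(vals + prior)
    return vals


def pca_explore(logcpm: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space PCA of a gene-by-sample expression matrix.

    Genes (features) are centered across samples; scores come from the SVD
    of the centered sample-by-gene matrix.  Returns ``(scores, varfrac)``
    with one row of scores per sample and variance fractions summing to 1.
    """
    if logcpm.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    centered = logcpm.sub(logcpm.mean(axis=1), axis=0)
    x = centered.to_numpy().T  # samples x genes
    if not np.any(np.abs(x) > 1e-12):
        raise ValueError("constant expression matrix has no principal components")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = pd.DataFrame(
        u * s,
        index=logcpm.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    varfrac = s**2 / np.sum(s**2)
    return scores, varfrac


def covariate_screen(
    logcpm: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    n_pcs: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen sample covariates for association with global expression.

    Each covariate is tested against the top ``n_pcs`` PC scores: one-way
    ANOVA for categorical covariates, least-squares regression for numeric
    ones.  A covariate's p-value is the minimum across PCs, Bonferroni
    multiplied by the number of PCs tested; covariates at ``p <= alpha``
    are flagged for inclusion in the differential-expression design.
    """
    _check_samples(logcpm, samples)
    if covariates is None:
        covariates = [c for c in samples.columns if c not in ("sample", "group")]
    scores, _ = pca_explore(logcpm)
    n_use = min(n_pcs, scores.shape[1])
    rows = []
    for cov in covariates:
        values = samples[cov]
        if values.nunique() < 2:
            logger.warning("covariate %r is constant across samples; skipped", cov)
            continue
        numeric = pd.api.types.is_numeric_dtype(values)
        p_pcs = []
        for i in range(n_use):
            pc = scores.iloc[:, i].to_numpy()
            if numeric:
                res = stats.linregress(values.to_numpy(dtype=float), pc)
                p_pcs.append(res.pvalue)
            else:
                groups = [pc[(values == lev).to_numpy()] for lev in values.unique()]
                p_pcs.append(stats.f_oneway(*groups).pvalue)
        p_min = float(np.nanmin(p_pcs))
        p_adj = min(1.0, p_min * n_use)
        rows.append(
            {
                "covariate": cov,
                "kind": "numeric" if numeric else "categorical",
                "p": p_min,
                "p_adj": p_adj,
                "selected": p_adj <= alpha,
            }
        )
    return pd.DataFrame(rows, columns=["covariate", "kind", "p", "p_adj", "selected"])
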