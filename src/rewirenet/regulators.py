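"""Regulatory impact factors (RIF1/RIF2) for transcription factors.

For each TF *i* and the set of differentially expressed genes (DEGs) *j*,
with ``e1_j, e2_j`` the condition-wise mean expression (log2-CPM by default)
of DEG *j*, ``a_j = (e1_j + e2_j)/2``, ``d_j = e1_j - e2_j``, phenotype
impact ``PIF_j = a_j * d_j``, and ``r1_ij, r2_ij`` the within-condition
Pearson correlations of TF *i* with DEG *j* (differential wiring
``DW_ij = r1_ij - r2_ij``):

    RIF1_i = (1 / n_de) * sum_j PIF_j * DW_ij^2
    RIF2_i = (1 / n_de) * sum_j [ (e1_j * r1_ij)^2 - (e2_j * r2_ij)^2 ]

RIF1 rewards TFs whose wiring to phenotype-relevant DEGs changes between
conditions; RIF2 rewards change in the TF's ability to predict DEG
abundance.  Each score is z-standardized across TFs and |z| >= 2 (a
configurable cut) flags a significant regulator.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["load_tf_list", "rif_scores"]


def load_tf_list(path: str | Path, expressed_gene_ids) -> list[str]:
    """Read one gene id per line and keep those present in the dataset.

    Ids are whitespace-trimmed; duplicates are dropped (with a warning)
    keeping first occurrence; original file order is preserved.
    """
    raw = [line.strip() for line in Path(path).read_text().splitlines()]
    raw = [r for r in raw if r]
    seen: dict[str, None] = {}
    dups = 0
    for r in raw:
        if r in seen:
            dups += 1
        else:
            seen[r] = None
    if dups:
        logger.warning("%d duplicate ids in TF list dropped", dups)
    expressed = set(expressed_gene_ids)
    kept = [r for r in seen if r in expressed]
    if not kept:
        raise ValueError("no TF from the list is present in the expression data")
    logger.info("TF list: retained %d of %d ids", len(kept), len(seen))
    return kept


def _group_correlations(expr: np.ndarray, tf_rows: np.ndarray, deg_rows: np.ndarray):
    """Pearson correlations TF x DEG within one condition; zero-variance
    vectors yield r = 0 (flagged by the caller via the returned mask)."""
    centered = expr - expr.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    ok = sd > 0
    denom = np.where(ok, sd, 1.0)
    zscored = centered / denom[:, None]
    n = expr.shape[1]
    r = zscored[tf_rows] @ zscored[deg_rows].T / n
    bad = ~ok[tf_rows][:, None] | ~ok[deg_rows][None, :]
    r[bad] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    return r, bad


def rif_scores(
    logcpm_group1: pd.DataFrame,
    logcpm_group2: pd.DataFrame,
    tf_ids: list[str],
    deg_ids: list[str],
    z_cut: float = 2.0,
) -> pd.DataFrame:
    """Compute RIF1/RIF2 raw and z-standardized scores for each TF.

    Both expression matrices are gene-by-sample with identical gene indexes
    (group 1 = reference condition).  A gene appearing in both ``tf_ids``
    and ``deg_ids`` is scored as a TF against the remaining DEGs.
    """
    if logcpm_group1.shape[1] < 3 or logcpm_group2.shape[1] < 3:
        raise ValueError("RIF needs at least 3 samples per group")
    if not list(logcpm_group1.index) == list(logcpm_group2.index):
        raise ValueError("group matrices must share the same gene index")
    deg_ids = [g for g in deg_ids if g in logcpm_group1.index]
    tf_ids = [t for t in tf_ids if t in logcpm_group1.index]
    if not deg_ids:
        raise ValueError("no DEG present in the expression matrices")
    if not tf_ids:
        raise ValueError("no TF present in the expression matrices")

    pos = {g: i for i, g in enumerate(logcpm_group1.index)}
    tf_rows = np.array([pos[t] for t in tf_ids])
    deg_rows = np.array([pos[g] for g in deg_ids])
    x1 = logcpm_group1.to_numpy(dtype=float)
    x2 = logcpm_group2.to_numpy(dtype=float)

    e1 = x1[deg_rows].mean(axis=1)
    e2 = x2[deg_rows].mean(axis=1)
    avg = 0.5 * (e1 + e2)
    diff = e1 - e2
    pif = avg * diff

    r1, bad1 = _group_correlations(x1, tf_rows, deg_rows)
    r2, bad2 = _group_correlations(x2, tf_rows, deg_rows)
    if (bad1 | bad2).any():
        logger.warning(
            "%d TF-DEG pairs had a zero-variance vector; their r set to 0",
            int((bad1 | bad2).sum()),
        )
    dw = r1 - r2

    # mask self-pairs: a TF that is also a DEG is scored against the others
    self_mask = tf_rows[:, None] == deg_rows[None, :]
    n_de = (~self_mask).sum(axis=1).astype(float)
    if (n_de == 0).any():
        raise ValueError("a TF has no DEG left to score against")

    rif1_terms = pif[None, :] * dw**2
    rif2_terms = (e1[None, :] * r1) ** 2 - (e2[None, :] * r2) ** 2
    rif1 = np.where(self_mask, 0.0, rif1_terms).sum(axis=1) / n_de
    rif2 = np.where(self_mask, 0.0, rif2_terms).sum(axis=1) / n_de

    def zstd(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    rif1_z, rif2_z = zstd(rif1), zstd(rif2)
    return pd.DataFrame(
        {
            "rif1_raw": rif1,
            "rif2_raw": rif2,
            "rif1_z": rif1_z,
            "rif2_z": rif2_z,
            "significant_rif1": np.abs(rif1_z) >= z_cut,
            "significant_rif2": np.abs(rif2_z) >= z_cut,
        },
        index=pd.Index(tf_ids, name="tf"),
    )
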