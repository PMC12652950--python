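"""Condition-wise co-expression networks: PCIT, hubs, differential connectivity.

PCIT (partial correlation and information theory) decides, for every gene
pair, whether its correlation survives comparison against all triads.  For
a triad (x, y, z) the first-order partial correlations are

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) * (1 - r_yz^2))

and cyclic analogues.  The information-theoretic local tolerance is the
mean of the defined ratios |r_xy.z / r_xy|, |r_xz.y / r_xz|,
|r_yz.x / r_yz| (a ratio is skipped when its correlation is zero, or when a
variance factor ``1 - r^2`` falls below 1e-12, making the partial
undefined).  Edge (x, y) is eliminated if some z yields

    |r_xy| <= eps_xyz * |r_xz|  and  |r_xy| <= eps_xyz * |r_yz|.

Surviving nonzero-correlation edges are PCIT-significant.

Three interchangeable implementations are provided: a brute-force
triple-loop reference (:func:`pcit_reference`, the testing oracle), a
vectorized full-matrix version (:func:`pcit`), and a pair-targeted version
used by :func:`build_group_network`, which only needs the PCIT status of
pairs that already pass the |r| and membership filters (the status of a
pair depends only on its two correlation profiles, so restricting the
output set loses nothing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "partial_correlation",
    "pcit",
    "pcit_reference",
    "GroupNetwork",
    "build_group_network",
    "find_hubs",
    "exclusive_hubs",
    "differential_connectivity",
]

_VAR_EPS = 1e-12  # 1 - r^2 below this makes a partial correlation undefined


def partial_correlation(rxy: float, rxz: float, ryz: float) -> float:
    """First-order partial correlation of x and y given z."""
    denom = (1.0 - rxz**2) * (1.0 - ryz**2)
    if denom < _VAR_EPS:
        raise ValueError("partial correlation undefined: conditioning r too close to 1")
    return (rxy - rxz * ryz) / np.sqrt(denom)


def _check_corr(corr: np.ndarray) -> np.ndarray:
    c = np.asarray(corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if c.shape[0] < 3:
        raise ValueError("PCIT needs at least 3 genes")
    if np.max(np.abs(c)) > 1.0 + 1e-12:
        raise ValueError("correlation entries must lie in [-1, 1]")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    return np.clip(c, -1.0, 1.0)


def pcit_reference(corr: np.ndarray) -> np.ndarray:
    """Brute-force triple-loop PCIT; boolean significance matrix.

    O(n^3) scalar loops — the independent oracle for the vectorized
    implementations; only suitable for small matrices.
    """
    c = _check_corr(corr)
    n = c.shape[0]
    eliminated = np.zeros((n, n), dtype=bool)
    for x in range(n):
        for y in range(x + 1, n):
            rxy = c[x, y]
            for z in range(n):
                if z == x or z == y:
                    continue
                rxz, ryz = c[x, z], c[y, z]
                vxy = 1.0 - rxy**2
                vxz = 1.0 - rxz**2
                vyz = 1.0 - ryz**2
                terms = []
                if vxz >= _VAR_EPS and vyz >= _VAR_EPS and rxy != 0.0:
                    p1 = (rxy - rxz * ryz) / np.sqrt(vxz * vyz)
                    terms.append(abs(p1 / rxy))
                if vxy >= _VAR_EPS and vyz >= _VAR_EPS and rxz != 0.0:
                    p2 = (rxz - rxy * ryz) / np.sqrt(vxy * vyz)
                    terms.append(abs(p2 / rxz))
                if vxy >= _VAR_EPS and vxz >= _VAR_EPS and ryz != 0.0:
                    p3 = (ryz - rxy * rxz) / np.sqrt(vxy * vxz)
                    terms.append(abs(p3 / ryz))
                if not terms:
                    continue
                eps = sum(terms) / len(terms)
                if abs(rxy) <= eps * abs(rxz) and abs(rxy) <= eps * abs(ryz):
                    eliminated[x, y] = eliminated[y, x] = True
                    break
    significant = ~eliminated & (c != 0.0)
    np.fill_diagonal(significant, False)
    return significant


def _tolerance_terms(p_num, p_den_sqrt_arg, ratio_den, defined_mask):
    """|partial / r| with masks for undefined terms; returns (term, mask)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        part = p_num / np.sqrt(p_den_sqrt_arg)
        term = np.abs(part / ratio_den)
    mask = defined_mask & (ratio_den != 0.0)
    return np.where(mask, term, 0.0), mask


def pcit(corr: np.ndarray) -> np.ndarray:
    """Vectorized PCIT; boolean significance matrix (symmetric, no diag)."""
    c = _check_corr(corr)
    n = c.shape[0]
    eliminated = np.zeros((n, n), dtype=bool)
    one_minus_sq = 1.0 - c**2
    for z in range(n):
        a = c[:, z]
        vz = 1.0 - a**2
        rxz = a[:, None]
        ryz = a[None, :]
        vxz = vz[:, None]
        vyz = vz[None, :]
        t1, m1 = _tolerance_terms(
            c - rxz * ryz,
            vxz * vyz,
            c,
            (vxz >= _VAR_EPS) & (vyz >= _VAR_EPS),
        )
        t2, m2 = _tolerance_terms(
            rxz - c * ryz,
            one_minus_sq * vyz,
            rxz,
            (one_minus_sq >= _VAR_EPS) & (vyz >= _VAR_EPS),
        )
        t3, m3 = _tolerance_terms(
            ryz - c * rxz,
            one_minus_sq * vxz,
            ryz,
            (one_minus_sq >= _VAR_EPS) & (vxz >= _VAR_EPS),
        )
        count = m1.astype(int) + m2.astype(int) + m3.astype(int)
        with np.errstate(invalid="ignore"):
            eps = np.where(count > 0, (t1 + t2 + t3) / np.maximum(count, 1), np.nan)
        absc = np.abs(c)
        elim_z = (
            (count > 0)
            & (absc <= eps * np.abs(rxz))
            & (absc <= eps * np.abs(ryz))
        )
        elim_z[z, :] = False
        elim_z[:, z] = False
        eliminated |= elim_z
    significant = ~eliminated & (c != 0.0)
    np.fill_diagonal(significant, False)
    return significant


def _pcit_pairs(corr: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """PCIT significance for selected (x, y) index pairs only.

    Applies the identical triad rule, with z running over every gene in the
    matrix; returns a boolean vector aligned with ``pairs`` rows.
    """
    c = _check_corr(corr)
    n = c.shape[0]
    out = np.zeros(len(pairs), dtype=bool)
    for k, (x, y) in enumerate(pairs):
        rxy = c[x, y]
        if rxy == 0.0:
            continue
        a = c[x, :]
        b = c[y, :]
        vxy = 1.0 - rxy**2
        va = 1.0 - a**2
        vb = 1.0 - b**2
        t1, m1 = _tolerance_terms(
            rxy - a * b, va * vb, np.full(n, rxy), (va >= _VAR_EPS) & (vb >= _VAR_EPS)
        )
        t2, m2 = _tolerance_terms(
            a - rxy * b, np.full(n, vxy) * vb, a, (vxy >= _VAR_EPS) & (vb >= _VAR_EPS)
        )
        t3, m3 = _tolerance_terms(
            b - rxy * a, np.full(n, vxy) * va, b, (vxy >= _VAR_EPS) & (va >= _VAR_EPS)
        )
        count = m1.astype(int) + m2.astype(int) + m3.astype(int)
        with np.errstate(invalid="ignore"):
            eps = np.where(count > 0, (t1 + t2 + t3) / np.maximum(count, 1), np.nan)
        elim = (
            (count > 0)
            & (abs(rxy) <= eps * np.abs(a))
            & (abs(rxy) <= eps * np.abs(b))
        )
        elim[x] = elim[y] = False
        out[k] = not elim.any()
    return out


@dataclass
class GroupNetwork:
    """One condition's filtered co-expression network.

    ``edges`` has canonical ``gene_a < gene_b`` ordering with the Pearson r
    and its t-test p-value; ``degree`` covers connected genes only;
    ``universe`` lists every gene that entered the correlation analysis.
    """

    group: str
    edges: pd.DataFrame
    degree: pd.Series
    universe: list[str]

    @property
    def n_genes_total(self) -> int:
        return len(self.universe)


def _corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t distribution with n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    denom = np.maximum(1.0 - r**2, 1e-300)
    t = np.abs(r) * np.sqrt((n - 2) / denom)
    return 2.0 * stats.t.sf(t, df=n - 2)


def build_group_network(
    logcpm_group: pd.DataFrame,
    deg_ids,
    tf_ids,
    group: str = "group",
    r_cut: float = 0.99,
    p_cut: float = 0.05,
) -> GroupNetwork:
    """Infer one condition's network from gene-by-sample log-CPM.

    Pearson correlations are screened by PCIT; retained edges must be
    PCIT-significant, have ``|r| >= r_cut``, a correlation p-value
    ``<= p_cut`` at this group's sample size, and at least one endpoint in
    ``deg_ids | tf_ids``.  Zero-variance genes are excluded up front.
    """
    n_samples = logcpm_group.shape[1]
    if n_samples < 3:
        raise ValueError("network inference needs at least 3 samples")
    x = logcpm_group.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "%d zero-variance genes excluded from %s network",
            int((~keep).sum()),
            group,
        )
    genes = logcpm_group.index.to_numpy()[keep]
    c = np.corrcoef(x[keep])
    c = np.clip(np.nan_to_num(c, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(c, 1.0)

    members = set(deg_ids) | set(tf_ids)
    incident = np.array([g in members for g in genes])
    iu, ju = np.triu_indices(len(genes), k=1)
    sel = (np.abs(c[iu, ju]) >= r_cut) & (incident[iu] | incident[ju])
    iu, ju = iu[sel], ju[sel]
    pvals = _corr_pvalue(c[iu, ju], n_samples)
    psel = pvals <= p_cut
    iu, ju, pvals = iu[psel], ju[psel], pvals[psel]
    if len(iu):
        pairs = np.column_stack([iu, ju])
        significant = _pcit_pairs(c, pairs)
    else:
        significant = np.zeros(0, dtype=bool)
    iu, ju, pvals = iu[significant], ju[significant], pvals[significant]

    ga, gb = genes[iu], genes[ju]
    swap = ga > gb
    ga, gb = np.where(swap, gb, ga), np.where(swap, ga, gb)
    edges = pd.DataFrame(
        {"gene_a": ga, "gene_b": gb, "r": c[iu, ju], "p": pvals}
    ).sort_values(["gene_a", "gene_b"], ignore_index=True)
    degree = (
        pd.concat([edges["gene_a"], edges["gene_b"]])
        .value_counts()
        .sort_index()
        .rename("degree")
    )
    logger.info("%s network: %d edges, %d connected genes", group, len(edges), len(degree))
    return GroupNetwork(
        group=group, edges=edges, degree=degree, universe=list(genes)
    )


def find_hubs(net: GroupNetwork, n_sd: float = 2.0) -> tuple[list[str], float]:
    """Hub genes: degree >= mean + n_sd * SD over connected genes.

    Degree statistics run over genes with degree >= 1 (including the zeros
    of the full universe would drown the SD).  When the SD is zero the rule
    degenerates to a strict ``>`` and returns no hubs for uniform degrees.
    Returns ``(hubs, threshold)``.
    """
    if len(net.edges) == 0:
        raise ValueError("cannot call hubs on an empty network")
    deg = net.degree.to_numpy(dtype=float)
    mean = deg.mean()
    sd = deg.std(ddof=1) if len(deg) > 1 else 0.0
    if sd > 0:
        threshold = mean + n_sd * sd
        hubs = net.degree.index[deg >= threshold]
    else:
        threshold = mean
        hubs = net.degree.index[deg > threshold]
    return sorted(hubs), float(threshold)


def exclusive_hubs(hubs1, hubs2) -> tuple[set, set, set]:
    """Set partition of two hub lists: (only-in-1, only-in-2, shared)."""
    a, b = set(hubs1), set(hubs2)
    only1, only2, shared = a - b, b - a, a & b
    logger.info(
        "hub overlap: %d exclusive to first, %d exclusive to second, %d shared",
        len(only1),
        len(only2),
        len(shared),
    )
    return only1, only2, shared


def differential_connectivity(
    net1: GroupNetwork, net2: GroupNetwork, z_cut: float = 1.96
) -> pd.DataFrame:
    """Differential connectivity (DK) of each gene between two networks.

    Degrees are scaled by each network's maximum degree (``K in [0, 1]``,
    0 for absent genes); ``dk = K1 - K2`` is z-scored over the union of the
    two node sets and |z| >= ``z_cut`` flags a significantly rewired gene.
    ``gained_in`` names the network where the gene is better connected.
    """
    if set(net1.universe) != set(net2.universe):
        raise ValueError("networks must be built over the same gene universe")
    if len(net1.edges) == 0 or len(net2.edges) == 0:
        raise ValueError("differential connectivity needs edges in both networks")
    nodes = sorted(set(net1.degree.index) | set(net2.degree.index))
    k1 = net1.degree.reindex(nodes).fillna(0.0)
    k2 = net2.degree.reindex(nodes).fillna(0.0)
    K1 = k1 / net1.degree.max()
    K2 = k2 / net2.degree.max()
    dk = K1 - K2
    sd = dk.std(ddof=1) if len(dk) > 1 else 0.0
    z = (dk - dk.mean()) / sd if sd > 0 else dk * 0.0
    gained = np.where(dk > 0, net1.group, np.where(dk < 0, net2.group, "neither"))
    table = pd.DataFrame(
        {
            "k1": k1.astype(int),
            "k2": k2.astype(int),
            "K1": K1,
            "K2": K2,
            "dk": dk,
            "dk_z": z,
            "significant": np.abs(z) >= z_cut,
            "gained_in": gained,
        },
        index=pd.Index(nodes, name="gene"),
    )
    logger.info(
        "DK: %d of %d genes differentially connected",
        int(table["significant"].sum()),
        len(table),
    )
    return table
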