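"""Gene-set enrichment: pre-ranked GSEA, hypergeometric ORA, kappa grouping.

Genes are ranked by ``sign(log2FC) * -log10(p)`` (p floored at 1e-300; a
zero fold change ranks at 0).  GSEA uses the weighted Kolmogorov-Smirnov
running sum — hits increment by ``|score|^weight`` normalized to sum 1,
misses decrement by ``1/(N - n_set)`` — with a gene-label permutation null:
the empirical p compares the enrichment score (ES) with same-sign
permutation ES values and the NES divides the ES by the same-sign
permutation mean.  Over-representation uses the upper-tail hypergeometric
test against the expressed-gene universe, and redundant significant terms
are merged into groups by connecting term pairs whose membership vectors
agree at Cohen's kappa >= 0.4 (connected components; the representative is
the smallest-p member) — a declared simplification of iterative
kappa-clustering heuristics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "rank_genes",
    "enrichment_score",
    "enrichment_score_reference",
    "gsea_preranked",
    "ora_hypergeometric",
    "cohen_kappa",
    "kappa_group_terms",
]

P_FLOOR = 1e-300  # p = 0 is clamped here before -log10


@dataclass
class GeneSetCollection:
    """Named gene sets plus optional descriptions (GMT-compatible)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    @classmethod
    def read_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        desc: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name = fields[0]
            desc[name] = fields[1]
            sets[name] = [g for g in fields[2:] if g]
        return cls(sets=sets, descriptions=desc)

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                fh.write(
                    "\t".join([name, self.descriptions.get(name, ""), *genes]) + "\n"
                )


def rank_genes(de: pd.DataFrame, p_floor: float = P_FLOOR) -> pd.DataFrame:
    """Rank genes by ``sign(log2FC) * -log10(p)``, descending.

    Ties break by |log2FC| (descending) then gene id (ascending), making
    the ordering deterministic.
    """
    p = np.maximum(de["p"].to_numpy(dtype=float), p_floor)
    score = np.sign(de["log2fc"].to_numpy(dtype=float)) * (-np.log10(p))
    out = pd.DataFrame(
        {
            "gene": de.index,
            "score": score,
            "_abs_lfc": np.abs(de["log2fc"].to_numpy(dtype=float)),
        }
    )
    out = out.sort_values(
        ["score", "_abs_lfc", "gene"], ascending=[False, False, True]
    ).drop(columns="_abs_lfc")
    return out.reset_index(drop=True)


def enrichment_score(
    scores: np.ndarray, hit_idx: np.ndarray, weight: float = 1.0
) -> tuple[float, int]:
    """Weighted KS enrichment score for hits at ``hit_idx`` of a ranked list.

    Evaluates the running sum only at its candidate extrema (immediately
    after each hit for the maximum, immediately before for the minimum),
    which is equivalent to the full scan; a tie between equal positive and
    negative extrema resolves to the positive one.  Returns
    ``(ES, leading_edge)`` where leading_edge counts the hits at or before
    the extremum.
    """
    n = len(scores)
    k = len(hit_idx)
    if k == 0 or k == n:
        raise ValueError("gene set must hit a strict, nonempty subset of the list")
    hit_idx = np.sort(np.asarray(hit_idx))
    w = np.abs(scores[hit_idx]) ** weight
    total = w.sum()
    if total <= 0:  # all hit scores are zero: fall back to unweighted steps
        w = np.ones(k)
        total = float(k)
    hit_cum = np.cumsum(w) / total
    miss_before = (hit_idx - np.arange(k)) / (n - k)  # misses strictly before hit j
    after = hit_cum - (hit_idx + 1 - np.arange(1, k + 1)) / (n - k)
    before = np.concatenate([[0.0], hit_cum[:-1]]) - miss_before
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    es_max = after[i_max]
    es_min = before[i_min]
    # positive extremum wins ties (within float tolerance of the rational
    # step sums, so the choice is stable across summation orders)
    if abs(es_max) >= abs(es_min) - 1e-9:
        return float(es_max), i_max + 1
    return float(es_min), i_min


def enrichment_score_reference(
    scores: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0
) -> float:
    """Exhaustive running-sum ES (position-by-position loop); testing oracle."""
    n = len(scores)
    k = int(hit_mask.sum())
    if k == 0 or k == n:
        raise ValueError("gene set must hit a strict, nonempty subset of the list")
    w = np.abs(scores) ** weight
    total = w[hit_mask].sum()
    if total <= 0:
        w = np.ones(n)
        total = float(k)
    running = 0.0
    highest = 0.0
    lowest = 0.0
    for i in range(n):
        if hit_mask[i]:
            running += w[i] / total
        else:
            running -= 1.0 / (n - k)
        highest = max(highest, running)
        lowest = min(lowest, running)
    # same tie rule as the production scorer: positive extremum wins ties
    if abs(highest) >= abs(lowest) - 1e-9:
        return float(highest)
    return float(lowest)


def gsea_preranked(
    ranked: pd.DataFrame,
    collection: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a gene-set collection.

    ``ranked`` is the output of :func:`rank_genes`.  The null distribution
    permutes gene labels (equivalently: random same-size hit sets), the
    empirical p uses same-sign permutations with an add-one guard (so
    ``p >= 1/(n_perm + 1)``), and ``NES = ES / mean(same-sign perm ES)``.
    Sets whose overlap with the ranked universe falls outside
    ``[min_size, max_size]`` are skipped with a warning.
    """
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in collection.sets.items():
        hit_idx = np.array(sorted({pos[g] for g in members if g in pos}), dtype=int)
        k = len(hit_idx)
        if k == 0:
            logger.warning("gene set %r has no overlap with the ranked list", name)
            continue
        if not (min_size <= k <= max_size) or k == n:
            logger.warning(
                "gene set %r skipped by size filter (overlap %d)", name, k
            )
            continue
        es, leading = enrichment_score(scores, hit_idx, weight)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            perm_hits = rng.choice(n, size=k, replace=False)
            perm_es[b], _ = enrichment_score(scores, perm_hits, weight)
        same_sign = perm_es >= 0 if es >= 0 else perm_es <= 0
        n_same = int(same_sign.sum())
        extreme = int((np.abs(perm_es[same_sign]) >= abs(es)).sum())
        p = (extreme + 1) / (n_same + 1)
        denom = np.abs(perm_es[same_sign]).mean() if n_same else np.abs(perm_es).mean()
        nes = es / denom if denom > 0 else np.nan
        rows.append(
            {
                "set": name,
                "size": k,
                "leading_edge": leading,
                "es": es,
                "nes": nes,
                "p": p,
            }
        )
    table = pd.DataFrame(
        rows, columns=["set", "size", "leading_edge", "es", "nes", "p"]
    )
    if len(table):
        table["padj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["padj"] = pd.Series(dtype=float)
    return table


def ora_hypergeometric(
    query,
    collection: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a query gene list.

    Query ids outside the universe are dropped with a warning; set
    memberships are likewise restricted to the universe.  Fold enrichment
    is ``(overlap/n) / (K/N)``.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    query = list(dict.fromkeys(query))
    outside = [g for g in query if g not in uni]
    if outside:
        logger.warning("%d query genes outside the universe dropped", len(outside))
    query_set = {g for g in query if g in uni}
    if not query_set:
        raise ValueError("query is empty after restriction to the universe")
    n_query = len(query_set)
    n_uni = len(uni)
    rows = []
    for name, members in collection.sets.items():
        k_set = len(set(members) & uni)
        if k_set == 0:
            continue
        overlap = len(set(members) & query_set)
        p = float(stats.hypergeom.sf(overlap - 1, n_uni, k_set, n_query))
        fold = (overlap / n_query) / (k_set / n_uni)
        rows.append(
            {
                "set": name,
                "size": k_set,
                "overlap": overlap,
                "fold_enrichment": fold,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows, columns=["set", "size", "overlap", "fold_enrichment", "p"])
    if len(table):
        table["padj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["padj"] = pd.Series(dtype=float)
    return table


def cohen_kappa(member1: np.ndarray, member2: np.ndarray) -> float:
    """Cohen's kappa between two binary membership vectors."""
    v1 = np.asarray(member1, dtype=bool)
    v2 = np.asarray(member2, dtype=bool)
    if v1.shape != v2.shape:
        raise ValueError("membership vectors must have equal length")
    n = len(v1)
    a = float(np.sum(v1 & v2))
    d = float(np.sum(~v1 & ~v2))
    p1, p2 = v1.mean(), v2.mean()
    po = (a + d) / n
    pe = p1 * p2 + (1.0 - p1) * (1.0 - p2)
    if 1.0 - pe < 1e-12:
        return 1.0 if np.array_equal(v1, v2) else 0.0
    return (po - pe) / (1.0 - pe)


def kappa_group_terms(
    result: pd.DataFrame,
    collection: GeneSetCollection,
    universe,
    kappa_cut: float = 0.4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group redundant significant terms by membership agreement.

    Terms of ``result`` with ``p <= alpha`` are linked whenever their
    membership vectors (over the universe) reach ``kappa >= kappa_cut``;
    connected components form the groups.  Each group reports its
    representative (smallest-p member) and the group p-value (best member
    p).  Output order is deterministic and independent of input order.
    """
    sig = result[result["p"] <= alpha].copy()
    if sig.empty:
        return pd.DataFrame(
            columns=["set", "group", "representative", "group_p", "p"]
        )
    universe = list(dict.fromkeys(universe))
    idx = {g: i for i, g in enumerate(universe)}
    names = sorted(sig["set"])
    vectors = {}
    for name in names:
        v = np.zeros(len(universe), dtype=bool)
        for g in collection.sets[name]:
            if g in idx:
                v[idx[g]] = True
        vectors[name] = v
    graph = nx.Graph()
    graph.add_nodes_from(names)
    for i, n1 in enumerate(names):
        for n2 in names[i + 1 :]:
            if cohen_kappa(vectors[n1], vectors[n2]) >= kappa_cut:
                graph.add_edge(n1, n2)
    pmap = sig.set_index("set")["p"].to_dict()
    rows = []
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for gi, comp in enumerate(components, start=1):
        comp = sorted(comp)
        rep = min(comp, key=lambda s: (pmap[s], s))
        group_p = min(pmap[s] for s in comp)
        for name in comp:
            rows.append(
                {
                    "set": name,
                    "group": gi,
                    "representative": rep,
                    "group_p": group_p,
                    "p": pmap[name],
                }
            )
    return pd.DataFrame(rows, columns=["set", "group", "representative", "group_p", "p"])
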