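"""End-to-end orchestration: filter -> screen -> DE -> RIF -> networks -> DK
-> enrichment, with a reproducible JSON manifest.

Every threshold lives once in :class:`PipelineConfig` (defaults match the
printed cutoffs of the motivating analysis: DEG p <= 0.05 & |log2FC| >= 0.5,
RIF |z| >= 2, edge |r| >= 0.99 & p <= 0.05, hub mean + 2 SD, DK |z| >= 1.96,
kappa >= 0.4).  All derived randomness (GSEA permutations) flows from the
single config seed, and the manifest echoes the config plus per-stage row
counts so a run can be reproduced byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffexpr import estimate_dispersion, fit_glm_wald, size_factors
from .enrichment import (
    GeneSetCollection,
    gsea_preranked,
    kappa_group_terms,
    ora_hypergeometric,
    rank_genes,
)
from .networks import (
    build_group_network,
    differential_connectivity,
    exclusive_hubs,
    find_hubs,
)
from .preprocess import covariate_screen, cpm, filter_low_expression, pca_explore
from .regulators import load_tf_list, rif_scores

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "load_counts", "load_samples"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and stage toggles for one pipeline run."""

    counts: str = "counts.tsv"
    metadata: str = "samples.tsv"
    tf_list: str | None = "tf_list.txt"
    gmt: str | None = "modules.gmt"
    outdir: str = "results"
    group_col: str = "group"
    reference: str = "fertile"
    # thresholds (defaults are the printed cutoffs)
    p_cut: float = 0.05
    lfc_cut: float = 0.5
    r_cut: float = 0.99
    edge_p_cut: float = 0.05
    rif_z: float = 2.0
    dk_z: float = 1.96
    hub_sd: float = 2.0
    kappa_cut: float = 0.4
    group_p_cut: float = 0.05
    # preprocessing / screening
    min_count: float = 10.0
    min_total: float = 15.0
    log_prior: float = 0.5
    n_pcs: int = 2
    screen_alpha: float = 0.05
    # enrichment
    gsea_weight: float = 1.0
    n_perm: int = 1000
    min_set_size: int = 5
    max_set_size: int = 500
    # scale control
    pcit_max_genes: int = 2000
    seed: int = 0
    # stage toggles
    run_rif: bool = True
    run_networks: bool = True
    run_enrichment: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("duplicate gene or sample ids in count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return counts.astype("int64")


def load_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage
        self.code = f"E_{stage.upper()}"


def _edges_outputs(net, outdir: Path, label: str) -> dict:
    edges_path = outdir / f"edges_{label}.tsv"
    edges = net.edges.assign(group=net.group)
    edges.to_csv(edges_path, sep="\t", index=False)
    sif_path = outdir / f"edges_{label}.sif"
    with open(sif_path, "w") as fh:
        for row in net.edges.itertuples(index=False):
            fh.write(f"{row.gene_a}\tco\t{row.gene_b}\n")
    return {"edges": edges_path.name, "sif": sif_path.name}


def run_all(config: PipelineConfig) -> dict:
    """Execute every enabled stage; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "rewirenet",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    def record(stage: str, status: str, outputs: dict | None = None, **counts):
        manifest["stages"][stage] = {
            "status": status,
            "outputs": outputs or {},
            "counts": counts,
        }

    # ---- load & filter -------------------------------------------------
    try:
        counts = load_counts(config.counts)
        samples = load_samples(config.metadata)
        filtered = filter_low_expression(
            counts,
            samples,
            min_count=config.min_count,
            min_total=config.min_total,
            group_col=config.group_col,
        )
        filtered.to_csv(outdir / "filtered_counts.tsv", sep="\t")
        record(
            "filter",
            "ok",
            {"filtered_counts": "filtered_counts.tsv"},
            genes_in=len(counts),
            genes_kept=len(filtered),
            samples=counts.shape[1],
        )
    except Exception as err:  # noqa: BLE001 - stage boundary
        raise StageError("filter", err) from err

    # ---- exploratory screen -------------------------------------------
    try:
        logcpm = cpm(filtered, log=True, prior=config.log_prior)
        screen = covariate_screen(
            logcpm, samples, n_pcs=config.n_pcs, alpha=config.screen_alpha
        )
        screen.to_csv(outdir / "covariate_screen.tsv", sep="\t", index=False)
        scores, varfrac = pca_explore(logcpm)
        scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        pd.DataFrame(
            {"component": scores.columns, "var_frac": varfrac}
        ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False)
        selected = screen.loc[screen["selected"], "covariate"].tolist()
        categorical = [
            c
            for c in selected
            if not pd.api.types.is_numeric_dtype(samples[c])
        ]
        record(
            "screen",
            "ok",
            {"covariate_screen": "covariate_screen.tsv", "pca_scores": "pca_scores.tsv"},
            covariates_selected=len(selected),
            pc1_var_pct=round(float(varfrac[0]) * 100, 2),
        )
    except Exception as err:
        raise StageError("screen", err) from err

    # ---- differential expression --------------------------------------
    try:
        factors = size_factors(filtered)
        disp = estimate_dispersion(filtered, factors)
        de = fit_glm_wald(
            filtered,
            factors,
            disp["phi"],
            samples,
            covariates=tuple(categorical),
            group_col=config.group_col,
            reference=config.reference,
            p_cut=config.p_cut,
            lfc_cut=config.lfc_cut,
        )
        de.to_csv(outdir / "de_table.tsv", sep="\t")
        deg_ids = de.index[de["direction"] != "ns"].tolist()
        record(
            "de",
            "ok",
            {"de_table": "de_table.tsv"},
            degs=len(deg_ids),
            up=int((de["direction"] == "up").sum()),
            down=int((de["direction"] == "down").sum()),
        )
    except Exception as err:
        raise StageError("de", err) from err

    group2 = samples.loc[samples[config.group_col] != config.reference, "sample"]
    group1 = samples.loc[samples[config.group_col] == config.reference, "sample"]
    logcpm1, logcpm2 = logcpm[group1], logcpm[group2]

    # ---- regulators -----------------------------------------------------
    tf_ids: list[str] = []
    if config.run_rif and config.tf_list:
        try:
            tf_ids = load_tf_list(config.tf_list, filtered.index)
            if deg_ids:
                rif = rif_scores(
                    logcpm1, logcpm2, tf_ids, deg_ids, z_cut=config.rif_z
                )
                rif.to_csv(outdir / "rif_table.tsv", sep="\t")
                record(
                    "rif",
                    "ok",
                    {"rif_table": "rif_table.tsv"},
                    tfs_tested=len(rif),
                    significant=int(
                        (rif["significant_rif1"] | rif["significant_rif2"]).sum()
                    ),
                )
            else:
                record("rif", "skipped_no_degs")
        except Exception as err:
            raise StageError("rif", err) from err
    else:
        record("rif", "skipped")

    # ---- networks, hubs, differential connectivity ---------------------
    if config.run_networks:
        try:
            universe = logcpm
            # common universe: drop genes flat in either group so both
            # networks cover identical genes (required for DK)
            var1 = universe[group1].var(axis=1)
            var2 = universe[group2].var(axis=1)
            universe = universe.loc[(var1 > 0) & (var2 > 0)]
            if len(universe) > config.pcit_max_genes:
                # cap the correlation universe at the most variable genes
                order = universe.var(axis=1).sort_values(ascending=False)
                universe = universe.loc[
                    sorted(order.index[: config.pcit_max_genes])
                ]
                logger.info(
                    "PCIT universe capped at %d most variable genes",
                    config.pcit_max_genes,
                )
            net1 = build_group_network(
                universe[group1],
                deg_ids,
                tf_ids,
                group="reference",
                r_cut=config.r_cut,
                p_cut=config.edge_p_cut,
            )
            net2 = build_group_network(
                universe[group2],
                deg_ids,
                tf_ids,
                group="contrast",
                r_cut=config.r_cut,
                p_cut=config.edge_p_cut,
            )
            outputs = {}
            outputs.update(
                {f"{k}_reference": v for k, v in _edges_outputs(net1, outdir, "reference").items()}
            )
            outputs.update(
                {f"{k}_contrast": v for k, v in _edges_outputs(net2, outdir, "contrast").items()}
            )
            hub_counts = {}
            hubs1 = hubs2 = []
            if len(net1.edges):
                hubs1, thr1 = find_hubs(net1, n_sd=config.hub_sd)
                (outdir / "hubs_reference.txt").write_text("\n".join(hubs1) + "\n")
                outputs["hubs_reference"] = "hubs_reference.txt"
                hub_counts["hubs_reference"] = len(hubs1)
            if len(net2.edges):
                hubs2, thr2 = find_hubs(net2, n_sd=config.hub_sd)
                (outdir / "hubs_contrast.txt").write_text("\n".join(hubs2) + "\n")
                outputs["hubs_contrast"] = "hubs_contrast.txt"
                hub_counts["hubs_contrast"] = len(hubs2)
            only1, only2, shared = exclusive_hubs(hubs1, hubs2)
            record(
                "networks",
                "ok",
                outputs,
                edges_reference=len(net1.edges),
                edges_contrast=len(net2.edges),
                hubs_exclusive_reference=len(only1),
                hubs_exclusive_contrast=len(only2),
                hubs_shared=len(shared),
                **hub_counts,
            )
        except Exception as err:
            raise StageError("networks", err) from err
        try:
            if len(net1.edges) and len(net2.edges):
                dk = differential_connectivity(net1, net2, z_cut=config.dk_z)
                dk.to_csv(outdir / "dk_table.tsv", sep="\t")
                record(
                    "dk",
                    "ok",
                    {"dk_table": "dk_table.tsv"},
                    nodes=len(dk),
                    significant=int(dk["significant"].sum()),
                    gained_in_contrast=int(
                        (dk["significant"] & (dk["gained_in"] == "contrast")).sum()
                    ),
                )
            else:
                record("dk", "skipped_empty_network")
        except Exception as err:
            raise StageError("dk", err) from err
    else:
        record("networks", "skipped")
        record("dk", "skipped_networks_disabled")
        hubs2, only2 = [], set()

    # ---- enrichment -----------------------------------------------------
    if config.run_enrichment and config.gmt:
        try:
            collection = GeneSetCollection.read_gmt(config.gmt)
            ranked = rank_genes(de)
            gsea = gsea_preranked(
                ranked,
                collection,
                weight=config.gsea_weight,
                n_perm=config.n_perm,
                seed=config.seed,
                min_size=config.min_set_size,
                max_size=config.max_set_size,
            )
            gsea.to_csv(outdir / "gsea.tsv", sep="\t", index=False)
            outputs = {"gsea": "gsea.tsv"}
            counts_kw = {"gsea_sets": len(gsea)}
            universe_ids = filtered.index.tolist()
            if deg_ids:
                ora = ora_hypergeometric(deg_ids, collection, universe_ids)
                ora.to_csv(outdir / "ora_degs.tsv", sep="\t", index=False)
                outputs["ora_degs"] = "ora_degs.tsv"
                groups = kappa_group_terms(
                    ora,
                    collection,
                    universe_ids,
                    kappa_cut=config.kappa_cut,
                    alpha=config.group_p_cut,
                )
                groups.to_csv(outdir / "ora_deg_groups.tsv", sep="\t", index=False)
                outputs["ora_deg_groups"] = "ora_deg_groups.tsv"
                counts_kw["ora_significant"] = int((ora["p"] <= config.group_p_cut).sum())
                counts_kw["ora_groups"] = (
                    int(groups["group"].max()) if len(groups) else 0
                )
            if config.run_networks and only2:
                ora_hubs = ora_hypergeometric(sorted(only2), collection, universe_ids)
                ora_hubs.to_csv(outdir / "ora_hubs.tsv", sep="\t", index=False)
                outputs["ora_hubs"] = "ora_hubs.tsv"
            record("enrichment", "ok", outputs, **counts_kw)
        except Exception as err:
            raise StageError("enrichment", err) from err
    else:
        record("enrichment", "skipped")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest
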