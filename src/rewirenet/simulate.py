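"""Synthetic two-group RNA-seq count generator with planted structure.

Counts are drawn through a Gaussian copula: a latent gene-by-sample normal
matrix carries the desired correlation structure (co-expression modules that
may be present in one group only, i.e. rewired), and each latent value is
mapped through the standard-normal CDF and the negative-binomial quantile
function so the marginals remain NB with a mean--dispersion trend
``phi(mu) = a/mu + b`` typical of bulk tissue replicates.

Planted signal, all recorded in :class:`SimTruth` so recovery can be tested:

* differential expression: a fraction of genes is shifted by ``±lfc_de``
  (log2) in group 2 (the "subfertile" group);
* a location batch effect of ``batch_effect_lfc`` on a subset of genes;
* correlated modules: ``n_modules`` blocks of ``module_size`` genes with
  latent equicorrelation ``rho_shared`` in both groups; the first
  ``n_rewired_modules`` blocks instead use ``rho_rewired`` in group 2 and 0
  in group 1 (rewiring).  The first rewired block is the planted hub module;
* one regulator per rewired module: a member gene that is also emitted in
  the transcription-factor list, so it co-expresses with the module's
  differentially expressed members in group 2 only.

Module membership and the other planted roles are assigned among genes with
baseline mean at least ``min_signal_mean`` counts: signal planted below the
expression filter's detection limit would be discarded before any method
sees it, which is not the situation the downstream analyses address.

All randomness flows from a single ``numpy`` Generator seeded with
``SimConfig.seed``.  Draw order is fixed (gene means, library factors, role
permutation, extra-DE signs, sample covariates, module factors, latent
noise), so outputs are byte-identical across runs for a given config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

__all__ = ["SimConfig", "SimTruth", "simulate_counts", "write_simulation"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic two-group count generator.

    Defaults mirror the motivating study design: 7 vs 5 samples, two sample
    origins (locations), and a desk-scale gene count.
    """

    n_genes: int = 2000
    n_group1: int = 7          # reference group ("fertile")
    n_group2: int = 5          # contrast group ("subfertile")
    frac_de: float = 0.05      # fraction of genes shifted in group 2
    lfc_de: float = 1.0        # |log2 fold change| of planted DE genes
    n_modules: int = 4
    module_size: int = 25
    n_rewired_modules: int = 2  # first modules; block 0 is the hub module
    rho_shared: float = 0.8    # latent equicorrelation, both groups
    rho_rewired: float = 0.9   # latent equicorrelation, group 2 only
    n_tf: int = 100
    batch_effect_lfc: float = 0.5
    frac_batch: float = 0.1
    libsize_meanlog: float = 0.0
    libsize_sdlog: float = 0.15
    mu_meanlog: float = 4.0    # natural-log mean of baseline gene means
    mu_sdlog: float = 1.5
    dispersion_a: float = 3.0  # phi(mu) = a/mu + b
    dispersion_b: float = 0.1
    min_signal_mean: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.module_size <= 0:
            raise ValueError("n_genes and module_size must be positive")
        if self.n_group1 + self.n_group2 < 4:
            raise ValueError("need at least 4 samples in total")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError(
                f"module allocation ({self.n_modules}x{self.module_size}) "
                f"exceeds n_genes={self.n_genes}"
            )
        if not 0 <= self.frac_de < 1 or not 0 <= self.frac_batch < 1:
            raise ValueError("frac_de and frac_batch must lie in [0, 1)")
        for name in ("rho_shared", "rho_rewired"):
            rho = getattr(self, name)
            if not 0 <= rho < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0 <= self.n_rewired_modules <= self.n_modules:
            raise ValueError("n_rewired_modules must be in [0, n_modules]")
        if self.libsize_sdlog < 0 or self.mu_sdlog < 0:
            raise ValueError("log-normal sd parameters must be >= 0")
        if self.dispersion_a < 0 or self.dispersion_b < 0:
            raise ValueError("dispersion trend parameters must be >= 0")
        if self.lfc_de < 0 or self.batch_effect_lfc < 0:
            raise ValueError("effect sizes are magnitudes, must be >= 0")
        if self.n_tf > self.n_genes:
            raise ValueError("n_tf cannot exceed n_genes")


@dataclass
class SimTruth:
    """Ground-truth labels of one simulation.

    ``de_genes`` maps gene id to the sign (+1/-1) of its planted log2 shift
    in group 2.  ``rewired_genes`` covers every member of a rewired module
    (superset of ``hub_module``); both are empty when ``rho_rewired == 0``.
    ``modules`` holds every planted module as a named gene set, usable as a
    GMT collection for enrichment tests.
    """

    de_genes: dict[str, int] = field(default_factory=dict)
    regulator_ids: list[str] = field(default_factory=list)
    rewired_genes: list[str] = field(default_factory=list)
    hub_module: list[str] = field(default_factory=list)
    batch_genes: list[str] = field(default_factory=list)
    modules: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _sample_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n1, n2 = config.n_group1, config.n_group2
    ids = [f"F{i + 1}" for i in range(n1)] + [f"S{i + 1}" for i in range(n2)]
    group = ["fertile"] * n1 + ["subfertile"] * n2
    # locations alternate within each group so they are crossed, not confounded
    location = [f"loc{i % 2 + 1}" for i in range(n1)] + [
        f"loc{i % 2 + 1}" for i in range(n2)
    ]
    weight = np.round(rng.normal(440.0, 35.0, n1 + n2), 1)
    rts = rng.integers(2, 6, n1 + n2)
    return pd.DataFrame(
        {
            "sample": ids,
            "group": group,
            "location": location,
            "weight": weight,
            "rts": rts,
        }
    )


def simulate_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], SimTruth]:
    """Generate one synthetic dataset.

    Returns ``(counts, samples, tf_ids, truth)`` where ``counts`` is an
    integer gene-by-sample DataFrame, ``samples`` the metadata table,
    ``tf_ids`` the emitted transcription-factor list and ``truth`` the
    planted-signal labels.  Deterministic given ``config`` (incl. seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    n_samples = config.n_group1 + config.n_group2
    gene_ids = np.array([f"G{i + 1:05d}" for i in range(n_genes)])

    # 1-2: baseline gene means and per-sample library-size factors
    gene_means = rng.lognormal(config.mu_meanlog, config.mu_sdlog, n_genes)
    lib_factor = rng.lognormal(config.libsize_meanlog, config.libsize_sdlog, n_samples)

    # 3: assign planted roles among adequately expressed genes
    n_module_genes = config.n_modules * config.module_size
    n_extra_tf = max(0, config.n_tf - config.n_rewired_modules)
    n_batch = int(round(config.frac_batch * n_genes))
    eligible = np.flatnonzero(gene_means >= config.min_signal_mean)
    n_de_target = int(round(config.frac_de * n_genes))
    budget = n_module_genes + n_extra_tf + n_batch + n_de_target
    if len(eligible) < budget:
        raise ValueError(
            f"only {len(eligible)} genes exceed min_signal_mean="
            f"{config.min_signal_mean}; {budget} needed for planted roles"
        )
    perm = rng.permutation(eligible)
    modules_idx = [
        perm[m * config.module_size : (m + 1) * config.module_size]
        for m in range(config.n_modules)
    ]
    cursor = n_module_genes
    extra_tf_idx = perm[cursor : cursor + n_extra_tf]
    cursor += n_extra_tf
    batch_idx = perm[cursor : cursor + n_batch]
    cursor += n_batch

    rewired_mods = list(range(config.n_rewired_modules))
    regulator_idx = np.array(
        [modules_idx[m][0] for m in rewired_mods], dtype=int
    )

    # 4: planted DE genes: the non-regulator members of rewired modules
    # (coherent sign per module: hub module up, others down) plus extra
    # genes with random signs, up to round(frac_de * n_genes).
    de_idx: list[int] = []
    de_sign: list[int] = []
    if config.frac_de > 0:
        for m in rewired_mods:
            sign = 1 if m == 0 else -1
            for g in modules_idx[m][1:]:
                de_idx.append(int(g))
                de_sign.append(sign)
        n_extra_de = max(0, n_de_target - len(de_idx))
        extra_de = perm[cursor : cursor + n_extra_de]
        cursor += n_extra_de
        if n_extra_de:
            extra_signs = rng.choice([-1, 1], size=n_extra_de)
            de_idx.extend(int(g) for g in extra_de)
            de_sign.extend(int(s) for s in extra_signs)
    de_idx_arr = np.array(de_idx, dtype=int)
    de_sign_arr = np.array(de_sign, dtype=int)

    # 5-6: sample covariates (weight, RTS) then latent normals
    samples = _sample_table(config, rng)
    group2_mask = (samples["group"] == "subfertile").to_numpy()
    loc2_mask = (samples["location"] == "loc2").to_numpy()

    factors = rng.standard_normal((config.n_modules, n_samples))
    latent = rng.standard_normal((n_genes, n_samples))
    for m in range(config.n_modules):
        if m in rewired_mods:
            rho = np.where(group2_mask, config.rho_rewired, 0.0)
        else:
            rho = np.full(n_samples, config.rho_shared)
        members = modules_idx[m]
        latent[members] = np.sqrt(rho) * factors[m] + np.sqrt(1.0 - rho) * latent[
            members
        ]

    # mean model: baseline x library factor x planted shifts
    mu = gene_means[:, None] * lib_factor[None, :]
    if de_idx_arr.size:
        shift = 2.0 ** (config.lfc_de * de_sign_arr)
        mu[de_idx_arr] = mu[de_idx_arr] * np.where(group2_mask, shift[:, None], 1.0)
    if batch_idx.size and config.batch_effect_lfc > 0:
        mu[batch_idx] = mu[batch_idx] * np.where(
            loc2_mask, 2.0**config.batch_effect_lfc, 1.0
        )

    phi = np.maximum(
        config.dispersion_a / gene_means + config.dispersion_b, 1e-8
    )[:, None]
    u = np.clip(ndtr(latent), 1e-12, 1.0 - 1e-12)
    counts = stats.nbinom.ppf(u, n=1.0 / phi, p=1.0 / (1.0 + phi * mu))
    counts_df = pd.DataFrame(
        counts.astype(np.int64), index=gene_ids, columns=samples["sample"].to_numpy()
    )
    counts_df.index.name = "gene_id"

    structure_on = config.rho_rewired > 0
    truth = SimTruth(
        de_genes={gene_ids[g]: int(s) for g, s in zip(de_idx_arr, de_sign_arr)},
        regulator_ids=[gene_ids[g] for g in regulator_idx] if structure_on else [],
        rewired_genes=sorted(
            gene_ids[g] for m in rewired_mods for g in modules_idx[m]
        )
        if structure_on
        else [],
        hub_module=sorted(gene_ids[g] for g in modules_idx[0])
        if structure_on and rewired_mods
        else [],
        batch_genes=sorted(gene_ids[g] for g in batch_idx),
        modules={
            (
                f"module_{m + 1}_rewired" if m in rewired_mods else f"module_{m + 1}_shared"
            ): sorted(gene_ids[g] for g in modules_idx[m])
            for m in range(config.n_modules)
        },
    )
    tf_ids = sorted(
        {gene_ids[g] for g in regulator_idx} | {gene_ids[g] for g in extra_tf_idx}
    )
    return counts_df, samples, tf_ids, truth


def write_simulation(
    outdir: str | Path,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    tf_ids: list[str],
    truth: SimTruth,
    config: SimConfig | None = None,
) -> dict[str, str]:
    """Write a simulated dataset to ``outdir`` in plain-text formats.

    Emits counts TSV (first column gene id), metadata TSV, TF list (one id
    per line), truth JSON, the planted modules as a GMT collection, and the
    generating config as JSON when given.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "tf_list": outdir / "tf_list.txt",
        "truth": outdir / "truth.json",
        "gmt": outdir / "modules.gmt",
    }
    counts.to_csv(paths["counts"], sep="\t")
    samples.to_csv(paths["samples"], sep="\t", index=False)
    paths["tf_list"].write_text("\n".join(tf_ids) + "\n")
    paths["truth"].write_text(truth.to_json() + "\n")
    with open(paths["gmt"], "w") as fh:
        for name, members in truth.modules.items():
            fh.write("\t".join([name, "planted_module", *members]) + "\n")
    if config is not None:
        paths["config"] = outdir / "sim_config.json"
        paths["config"].write_text(
            json.dumps(dataclasses.asdict(config), indent=1, sort_keys=True) + "\n"
        )
    return {k: str(v) for k, v in paths.items()}
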