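"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes:

* per-gene methylation is beta-distributed; driver and buffered genes
  carry a two-component mixture in tumors (a normal-like state plus an
  aberrant hyper- or hypo-methylated state) while normal tissue and null
  genes draw from the normal-like component only;
* transcript levels are negatively and linearly coupled to methylation
  with Gaussian noise;
* protein levels are likewise coupled for true drivers but completely
  decoupled ("buffered") for buffered genes, reproducing the attenuation
  of transcript-level effects at the proteome;
* each gene's CpG cluster is expanded into several probes sharing the
  cluster beta plus small independent noise, positioned near the gene's
  TSS so probe clustering and TSS mapping are exercised end to end;
* clinical stage is an ordinal variable thresholded from a latent score
  driven by marker genes' expression, tumor size is log-normal around the
  same latent score, and batches are balanced round-robin assignments.

Default cohort: 150 tumors, 30 normals, 10 + 10 hyper/hypo drivers,
20 buffered genes and 60 nulls, aberrant-state weight 0.4 and a
methylation difference of 0.5 between states, expression/protein slopes
of -2 with noise SD 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import BetaMatrix, ClinicalTable, OmicsMatrix

__all__ = ["GeneratorConfig", "Cohort", "generate_cohort", "inject_missing_and_batches"]


@dataclass
class GeneratorConfig:
    n_tumor: int = 150
    n_normal: int = 30
    n_driver_hyper: int = 10
    n_driver_hypo: int = 10
    n_buffered: int = 20
    n_null: int = 60
    aberrant_weight: float = 0.4  # mixing weight of the aberrant state in tumors
    methylation_low: float = 0.2  # normal-like level for hyper genes / aberrant for hypo
    methylation_high: float = 0.7
    concentration: float = 40.0  # alpha + beta of each beta component
    expr_slope: float = -2.0
    prot_slope: float = -2.0
    expr_noise_sd: float = 0.5
    prot_noise_sd: float = 0.5
    expr_intercept: float = 8.0
    prot_intercept: float = 0.0
    probes_per_cluster: int = 3
    probe_noise_sd: float = 0.02
    n_batches: int = 2
    marker_fraction: float = 0.5  # fraction of driver genes coupled to stage
    n_stage_levels: int = 4
    stage_noise_sd: float = 0.5
    n_chromosomes: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.aberrant_weight < 1:
            raise ValueError("aberrant_weight must lie in (0, 1)")
        for m in (self.methylation_low, self.methylation_high):
            if not 0 < m < 1:
                raise ValueError("methylation means must lie in (0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if min(self.n_tumor, self.n_normal) < 2:
            raise ValueError("need at least 2 tumor and 2 normal samples")
        if self.probes_per_cluster < 1:
            raise ValueError("probes_per_cluster must be >= 1")

    @property
    def n_genes(self) -> int:
        return self.n_driver_hyper + self.n_driver_hypo + self.n_buffered + self.n_null


@dataclass
class Cohort:
    """One simulated cohort with its ground truth."""

    meth_tumor: BetaMatrix  # probe level
    meth_normal: BetaMatrix
    cluster_tumor: BetaMatrix  # gene-level cluster profiles (latent betas)
    cluster_normal: BetaMatrix
    expr: OmicsMatrix
    prot: OmicsMatrix
    clinical: ClinicalTable
    truth: pd.DataFrame  # per-gene class / parameters / marker flag
    manifest: pd.DataFrame  # probe -> chromosome, position
    annotation: pd.DataFrame  # gene -> chromosome, tss, strand
    cluster_genes: dict[str, str] = field(default_factory=dict)


def _beta_draw(rng, mean: float, conc: float, size) -> np.ndarray:
    return rng.beta(mean * conc, (1.0 - mean) * conc, size=size)


def generate_cohort(config: GeneratorConfig | None = None, seed: int = 0) -> Cohort:
    """Generate a full multi-omics cohort; deterministic per seed."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)

    classes = (
        ["driver_hyper"] * cfg.n_driver_hyper
        + ["driver_hypo"] * cfg.n_driver_hypo
        + ["buffered"] * cfg.n_buffered
        + ["null"] * cfg.n_null
    )
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    tumor_ids = [f"T{i:03d}" for i in range(cfg.n_tumor)]
    normal_ids = [f"N{i:03d}" for i in range(cfg.n_normal)]

    truth_rows = []
    latent_t = np.empty((cfg.n_tumor, cfg.n_genes))
    latent_n = np.empty((cfg.n_normal, cfg.n_genes))
    expr = np.empty_like(latent_t)
    prot = np.empty_like(latent_t)
    driver_seen = 0

    for j, (gene, cls) in enumerate(zip(genes, classes)):
        # buffered genes alternate hyper/hypo aberrations like drivers do
        hyper_like = cls == "driver_hyper" or (cls == "buffered" and j % 2 == 0)
        if cls == "null":
            m0 = m1 = cfg.methylation_low if j % 2 == 0 else cfg.methylation_high
            w = 0.0
        else:
            m0 = cfg.methylation_low if hyper_like else cfg.methylation_high
            m1 = cfg.methylation_high if hyper_like else cfg.methylation_low
            w = cfg.aberrant_weight
        aberrant = rng.random(cfg.n_tumor) < w
        bt = np.where(
            aberrant,
            _beta_draw(rng, m1, cfg.concentration, cfg.n_tumor),
            _beta_draw(rng, m0, cfg.concentration, cfg.n_tumor),
        )
        bn = _beta_draw(rng, m0, cfg.concentration, cfg.n_normal)
        latent_t[:, j] = bt
        latent_n[:, j] = bn

        e_slope = 0.0 if cls == "null" else cfg.expr_slope
        p_slope = cfg.prot_slope if cls in ("driver_hyper", "driver_hypo") else 0.0
        expr[:, j] = (
            cfg.expr_intercept + e_slope * bt
            + rng.normal(0.0, cfg.expr_noise_sd, cfg.n_tumor)
        )
        prot[:, j] = (
            cfg.prot_intercept + p_slope * bt
            + rng.normal(0.0, cfg.prot_noise_sd, cfg.n_tumor)
        )
        # spread marker flags evenly across hyper and hypo drivers
        is_marker = False
        if cls.startswith("driver"):
            driver_seen += 1
            is_marker = int(driver_seen * cfg.marker_fraction) > int(
                (driver_seen - 1) * cfg.marker_fraction
            )
        truth_rows.append(
            {
                "gene_id": gene,
                "gene_class": cls,
                "mean_normal": m0,
                "mean_aberrant": m1,
                "weight_aberrant": w,
                "expr_slope": e_slope,
                "prot_slope": p_slope,
                "marker": is_marker,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")

    # probe-level expansion and genome layout
    probe_rows = []
    ann_rows = []
    probe_t = {}
    probe_n = {}
    cluster_genes = {}
    for j, gene in enumerate(genes):
        chrom = f"chr{j % cfg.n_chromosomes + 1}"
        tss = 100_000 * (j // cfg.n_chromosomes + 1)
        strand = "+" if j % 2 == 0 else "-"
        ann_rows.append(
            {"gene_id": gene, "chromosome": chrom, "tss": tss, "strand": strand}
        )
        cluster_genes[f"{gene}_cl"] = gene
        for p in range(cfg.probes_per_cluster):
            pid = f"cg{j:04d}_{p}"
            probe_rows.append(
                {"probe_id": pid, "chromosome": chrom, "position": tss + 50 * p}
            )
            noise_t = rng.normal(0.0, cfg.probe_noise_sd, cfg.n_tumor)
            noise_n = rng.normal(0.0, cfg.probe_noise_sd, cfg.n_normal)
            probe_t[pid] = np.clip(latent_t[:, j] + noise_t, 1e-4, 1 - 1e-4)
            probe_n[pid] = np.clip(latent_n[:, j] + noise_n, 1e-4, 1 - 1e-4)
    manifest = pd.DataFrame(probe_rows).set_index("probe_id")
    annotation = pd.DataFrame(ann_rows).set_index("gene_id")

    # clinical covariates from a marker-driven latent progression score
    marker_idx = [j for j, g in enumerate(genes) if truth.loc[g, "marker"]]
    if marker_idx:
        Z = expr[:, marker_idx]
        Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
        # tumor suppressors (hyper) lose expression with progression
        orient = np.array(
            [-1.0 if classes[j] == "driver_hyper" else 1.0 for j in marker_idx]
        )
        score = (Z * orient).mean(axis=1)
    else:
        score = np.zeros(cfg.n_tumor)
    score = score + rng.normal(0.0, cfg.stage_noise_sd, cfg.n_tumor)
    qs = np.quantile(score, np.linspace(0, 1, cfg.n_stage_levels + 1)[1:-1])
    stage = 1 + np.searchsorted(qs, score)
    size = 2.0 * np.exp(0.25 * score + rng.normal(0.0, 0.35, cfg.n_tumor))
    grade = 1 + np.searchsorted(
        np.quantile(score, [1 / 3, 2 / 3]),
        score + rng.normal(0.0, cfg.stage_noise_sd, cfg.n_tumor),
    )
    subtype = np.where(score >= np.median(score), "subtype_B", "subtype_A")
    clinical = ClinicalTable(
        table=pd.DataFrame(
            {
                "stage": stage,
                "tumor_size": size,
                "grade": grade,
                "subtype": subtype,
            },
            index=pd.Index(tumor_ids, name="sample_id"),
        ),
        column_types={
            "stage": "ordinal",
            "tumor_size": "continuous",
            "grade": "ordinal",
            "subtype": "categorical",
        },
    )

    batches_t = pd.Series(
        [f"batch{i % cfg.n_batches}" for i in range(cfg.n_tumor)], index=tumor_ids
    )
    batches_n = pd.Series(
        [f"batch{i % cfg.n_batches}" for i in range(cfg.n_normal)], index=normal_ids
    )
    cluster_cols = [f"{g}_cl" for g in genes]
    return Cohort(
        meth_tumor=BetaMatrix(
            pd.DataFrame(probe_t, index=tumor_ids),
            tissue=pd.Series("tumor", index=tumor_ids),
            batch=batches_t,
        ),
        meth_normal=BetaMatrix(
            pd.DataFrame(probe_n, index=normal_ids),
            tissue=pd.Series("normal", index=normal_ids),
            batch=batches_n,
        ),
        cluster_tumor=BetaMatrix(
            pd.DataFrame(latent_t, index=tumor_ids, columns=cluster_cols),
            tissue=pd.Series("tumor", index=tumor_ids),
            batch=batches_t,
        ),
        cluster_normal=BetaMatrix(
            pd.DataFrame(latent_n, index=normal_ids, columns=cluster_cols),
            tissue=pd.Series("normal", index=normal_ids),
            batch=batches_n,
        ),
        expr=OmicsMatrix(
            pd.DataFrame(expr, index=tumor_ids, columns=genes), kind="expression"
        ),
        prot=OmicsMatrix(
            pd.DataFrame(prot, index=tumor_ids, columns=genes), kind="protein"
        ),
        clinical=clinical,
        truth=truth,
        manifest=manifest,
        annotation=annotation,
        cluster_genes=cluster_genes,
    )


def inject_missing_and_batches(
    m: BetaMatrix | OmicsMatrix,
    missing_rate: float = 0.0,
    batch_shift: float = 0.0,
    batch: pd.Series | None = None,
    seed: int = 0,
):
    """Perturb a matrix with MCAR missingness and additive balanced batch
    shifts; returns (perturbed matrix, missing mask) so imputation and
    correction error can be measured against the retained truth.

    Batch b (of B) receives the centered offset
    ``batch_shift * (b - (B - 1) / 2)``, so equal-size batches leave
    per-feature grand means unchanged.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    df = m.values.copy()
    if batch is None and isinstance(m, BetaMatrix):
        batch = m.batch
    if batch_shift != 0.0:
        if batch is None:
            raise ValueError("batch labels required to apply a batch shift")
        levels = sorted(pd.Series(batch).unique())
        offsets = {
            b: batch_shift * (i - (len(levels) - 1) / 2.0)
            for i, b in enumerate(levels)
        }
        shift = pd.Series(batch).reindex(df.index).map(offsets).to_numpy()
        df = df.add(shift, axis=0)
        if isinstance(m, BetaMatrix):
            df = df.clip(1e-4, 1 - 1e-4)
    mask = pd.DataFrame(
        rng.random(df.shape) < missing_rate, index=df.index, columns=df.columns
    )
    if mask.all(axis=0).any():
        raise ValueError("missing_rate would empty an entire feature; lower it")
    df = df.mask(mask)
    return m.with_values(df), mask
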