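"""Dimensionality reduction of CpG probes into co-methylated clusters.

Probes are clustered per chromosome by complete-linkage hierarchical
clustering on the correlation distance 1 - Pearson r, with the tree cut at
height 1 - min_corr (default 0.6).  Complete linkage at that height
guarantees every within-cluster pairwise correlation is at least min_corr,
which implies the weaker average-correlation criterion; the average is
still asserted on every output cluster.  Each cluster is summarized by the
per-sample mean beta over its member probes and mapped to the gene with
the nearest transcription start site, so one gene may own many clusters
but each cluster maps to exactly one gene (cis effects only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data_io import BetaMatrix, DataError

__all__ = ["CpGCluster", "cluster_probes", "map_cluster_to_gene", "cluster_profiles"]

log = logging.getLogger(__name__)


@dataclass
class CpGCluster:
    cluster_id: str
    chromosome: str
    probe_ids: list[str]
    position: int  # median member-probe position (representative coordinate)
    profile: pd.Series  # per-sample mean beta over member probes
    gene_id: str | None = None


def _probe_correlation(X: np.ndarray) -> np.ndarray:
    """Pearson correlation between probe columns; constant probes are
    treated as uncorrelatable (r = 0, i.e. distance 1)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X.T)
    corr = np.atleast_2d(corr)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def cluster_probes(
    m: BetaMatrix,
    manifest: pd.DataFrame,
    min_corr: float = 0.4,
) -> list[CpGCluster]:
    """Partition probes into co-methylated clusters, one chromosome at a
    time (clusters cannot span chromosomes).

    ``manifest`` is indexed by probe id with columns chromosome and
    position.  Constant probes get singleton clusters with a warning.
    The output partition is invariant to probe input order: probes are
    sorted by (chromosome, position, probe id) before clustering.
    """
    if m.values.shape[0] < 2:
        raise DataError("probe clustering needs at least 2 samples")
    missing = [p for p in m.probe_ids if p not in manifest.index]
    if missing:
        raise DataError(f"probe(s) missing from manifest: {missing[:5]}")
    if m.values.isna().to_numpy().any():
        raise DataError("impute missing betas before clustering probes")

    clusters: list[CpGCluster] = []
    man = manifest.loc[m.probe_ids]
    for chrom in sorted(man["chromosome"].unique()):
        probes = man.index[man["chromosome"] == chrom]
        order = np.lexsort((probes, man.loc[probes, "position"].to_numpy()))
        probes = list(np.asarray(probes)[order])
        X = m.values[probes].to_numpy(dtype=float)
        if len(probes) == 1:
            labels = np.array([1])
        else:
            corr = _probe_correlation(X)
            if np.any(np.std(X, axis=0) == 0):
                n_const = int(np.sum(np.std(X, axis=0) == 0))
                log.warning(
                    "%d constant probe(s) on %s become singleton clusters",
                    n_const, chrom,
                )
            dist = np.clip(1.0 - corr, 0.0, 2.0)
            np.fill_diagonal(dist, 0.0)
            Z = linkage(squareform(dist, checks=False), method="complete")
            labels = fcluster(Z, t=1.0 - min_corr, criterion="distance")
        for lab in np.unique(labels):
            members = [p for p, l in zip(probes, labels) if l == lab]
            pos = int(np.median(man.loc[members, "position"].to_numpy()))
            profile = m.values[members].mean(axis=1)
            clusters.append(
                CpGCluster(
                    cluster_id="",  # assigned after global ordering below
                    chromosome=chrom,
                    probe_ids=members,
                    position=pos,
                    profile=profile,
                )
            )
    clusters.sort(key=lambda c: (c.chromosome, c.position, c.probe_ids[0]))
    for i, c in enumerate(clusters):
        c.cluster_id = f"{c.chromosome}:cl{i:05d}"

    _assert_cluster_correlation(m, clusters, min_corr)
    return clusters


def _assert_cluster_correlation(
    m: BetaMatrix, clusters: list[CpGCluster], min_corr: float
) -> None:
    """Post-condition: mean pairwise Pearson r within every multi-probe
    cluster reaches the cut threshold."""
    for c in clusters:
        if len(c.probe_ids) < 2:
            continue
        corr = _probe_correlation(m.values[c.probe_ids].to_numpy(dtype=float))
        iu = np.triu_indices(len(c.probe_ids), k=1)
        mean_r = float(corr[iu].mean())
        if mean_r < min_corr - 1e-9:
            raise AssertionError(
                f"cluster {c.cluster_id} mean pairwise r {mean_r:.3f} < {min_corr}"
            )


def map_cluster_to_gene(cluster: CpGCluster, annotation: pd.DataFrame) -> str | None:
    """Assign the gene whose TSS is closest (absolute genomic distance) to
    the cluster's representative position.  Equidistant TSSs break toward
    the lexicographically smallest gene id.  Returns None (unmapped) when
    the chromosome carries no annotated gene."""
    ann = annotation[annotation["chromosome"] == cluster.chromosome]
    if ann.empty:
        log.info("cluster %s unmapped: no gene on %s", cluster.cluster_id, cluster.chromosome)
        cluster.gene_id = None
        return None
    dist = (ann["tss"] - cluster.position).abs()
    best = dist.min()
    candidates = sorted(dist.index[dist == best])
    if len(candidates) > 1:
        log.info(
            "cluster %s equidistant to %s; choosing %s",
            cluster.cluster_id, candidates, candidates[0],
        )
    cluster.gene_id = candidates[0]
    return cluster.gene_id


def cluster_profiles(
    clusters: list[CpGCluster],
    tissue: pd.Series | None = None,
    batch: pd.Series | None = None,
) -> tuple[BetaMatrix, dict[str, str | None]]:
    """Assemble cluster summary profiles into a samples x clusters
    BetaMatrix plus the cluster-to-gene mapping (mapped clusters only keep
    a gene id; unmapped ones carry None and are excluded downstream)."""
    if not clusters:
        raise DataError("no clusters supplied")
    values = pd.DataFrame({c.cluster_id: c.profile for c in clusters})
    genes = {c.cluster_id: c.gene_id for c in clusters}
    return BetaMatrix(values=values, tissue=tissue, batch=batch), genes
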