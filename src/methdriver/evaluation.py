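"""Downstream evaluation: consensus clustering of the DM-value matrix,
cluster-covariate association tests and tumor-progression-marker
enrichment.

Consensus clustering follows the bootstrap k-means recipe: for each K,
``n_boot`` subsamples of ceil(0.8 n) samples are clustered with k-means
(Euclidean distance), and consensus(i, j) is the fraction of subsamples
containing both i and j in which they land in the same cluster.  Final
labels come from average-linkage hierarchical clustering of
1 - consensus cut at K.  Cluster stability is summarized by the PAC score
(proportion of ambiguous classification: consensus entries strictly
inside (0.1, 0.9), lower is more stable) and by intra/inter cluster
consensus means on a 0-100 scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency, kruskal
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats import spearmanr
from sklearn.cluster import KMeans

from .core import bh_fdr
from .data_io import ClinicalTable, DataError, OmicsMatrix

__all__ = [
    "ConsensusK",
    "ConsensusResult",
    "MarkerEnrichment",
    "consensus_cluster",
    "pac_score",
    "intra_inter_consensus",
    "associate_clusters",
    "tumor_marker_enrichment",
    "fisher_exact",
    "gene_set_enrichment",
    "plot_consensus_heatmap",
]

log = logging.getLogger(__name__)


@dataclass
class ConsensusK:
    k: int
    consensus: pd.DataFrame  # samples x samples, entries in [0, 1] (NaN = never co-sampled)
    labels: pd.Series  # final cluster label per sample (1..K)
    pac: float
    intra: float  # percentage scale, 0-100
    inter: float


@dataclass
class ConsensusResult:
    per_k: dict[int, ConsensusK]

    def summary(self) -> pd.DataFrame:
        rows = [
            {"K": k, "Intra": r.intra, "Inter": r.inter, "PAC": r.pac}
            for k, r in sorted(self.per_k.items())
        ]
        return pd.DataFrame(rows)

    def best_k(self) -> int:
        """K with the lowest PAC (most stable clustering)."""
        return min(self.per_k, key=lambda k: self.per_k[k].pac)


def pac_score(consensus, lower: float = 0.1, upper: float = 0.9) -> float:
    """Fraction of off-diagonal upper-triangle consensus entries strictly
    inside (lower, upper); invariant to sample permutation."""
    C = np.asarray(
        consensus.values if isinstance(consensus, pd.DataFrame) else consensus,
        dtype=float,
    )
    iu = np.triu_indices(C.shape[0], k=1)
    vals = C[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(np.mean((vals > lower) & (vals < upper)))


def intra_inter_consensus(consensus, labels) -> tuple[float, float]:
    """Mean consensus among same-cluster pairs and among different-cluster
    pairs, both on a 0-100 scale.  Singleton clusters contribute no intra
    pairs; NaN (never co-sampled) entries are excluded."""
    C = np.asarray(
        consensus.values if isinstance(consensus, pd.DataFrame) else consensus,
        dtype=float,
    )
    lab = np.asarray(labels)
    if len(np.unique(lab)) < 2:
        raise DataError("inter-cluster consensus needs at least 2 clusters")
    iu, ju = np.triu_indices(C.shape[0], k=1)
    vals = C[iu, ju]
    same = lab[iu] == lab[ju]
    ok = np.isfinite(vals)
    intra_vals = vals[same & ok]
    inter_vals = vals[~same & ok]
    intra = float(intra_vals.mean() * 100) if intra_vals.size else float("nan")
    inter = float(inter_vals.mean() * 100) if inter_vals.size else float("nan")
    return intra, inter


def consensus_cluster(
    dm,
    k_range=range(2, 7),
    n_boot: int = 500,
    subsample_frac: float = 0.8,
    seed: int = 0,
    n_init: int = 10,
) -> ConsensusResult:
    """Bootstrap k-means consensus clustering of a samples x features
    DM-value matrix."""
    if isinstance(dm, pd.DataFrame):
        X = dm.to_numpy(dtype=float)
        index = dm.index
    else:
        X = np.asarray(dm, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    n = X.shape[0]
    if n < 10 or X.shape[1] < 2:
        raise DataError("consensus clustering needs >= 10 samples and >= 2 features")
    size = math.ceil(subsample_frac * n)
    rng = np.random.default_rng(seed)
    per_k: dict[int, ConsensusK] = {}
    for K in k_range:
        co_clustered = np.zeros((n, n))
        co_sampled = np.zeros((n, n))
        for _ in range(n_boot):
            idx = rng.choice(n, size=size, replace=False)
            km = KMeans(
                n_clusters=K,
                n_init=n_init,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X[idx])
            same = km.labels_[:, None] == km.labels_[None, :]
            co_sampled[np.ix_(idx, idx)] += 1.0
            co_clustered[np.ix_(idx, idx)] += same
        never = co_sampled == 0
        if never[np.triu_indices(n, k=1)].any():
            log.warning(
                "consensus K=%d: %d sample pairs never co-sampled (excluded)",
                K, int(never[np.triu_indices(n, k=1)].sum()),
            )
        with np.errstate(invalid="ignore"):
            C = np.where(never, np.nan, co_clustered / np.where(never, 1.0, co_sampled))
        np.fill_diagonal(C, 1.0)
        D = 1.0 - np.where(np.isnan(C), 0.5, C)  # neutral distance for unseen pairs
        D = (D + D.T) / 2.0
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method="average")
        labels = fcluster(Z, t=K, criterion="maxclust")
        consensus = pd.DataFrame(C, index=index, columns=index)
        lab = pd.Series(labels, index=index)
        intra, inter = intra_inter_consensus(consensus, labels)
        per_k[K] = ConsensusK(
            k=K,
            consensus=consensus,
            labels=lab,
            pac=pac_score(consensus),
            intra=intra,
            inter=inter,
        )
    return ConsensusResult(per_k=per_k)


# --------------------------------------------------------------------------
# cluster-covariate association


def associate_clusters(
    labels: pd.Series,
    clinical: ClinicalTable,
    correct: bool = False,
) -> pd.DataFrame:
    """Test each declared clinical feature against the cluster labels:
    chi-squared on the contingency table for categorical features,
    Kruskal-Wallis across clusters for ordinal/continuous ones.  Missing
    clinical values are dropped per feature; optional BH correction across
    features."""
    rows = []
    common = labels.index.intersection(clinical.table.index)
    lab = labels.loc[common]
    for col, typ in clinical.column_types.items():
        vals = clinical.table.loc[common, col]
        ok = vals.notna()
        v, l = vals[ok], lab[ok]
        row = {"feature": col, "type": typ, "test": None, "statistic": np.nan,
               "p_value": np.nan, "note": None}
        if v.nunique() < 2:
            row["note"] = "single_level_untestable"
        elif typ == "categorical":
            table = pd.crosstab(l, v)
            res = chi2_contingency(table.to_numpy())
            row.update(test="chi2", statistic=float(res.statistic),
                       p_value=float(res.pvalue))
        else:  # ordinal / continuous
            groups = [v[l == g].to_numpy(dtype=float) for g in np.unique(l)]
            groups = [g for g in groups if g.size > 0]
            if len(groups) < 2:
                row["note"] = "fewer_than_two_clusters"
            else:
                stat, p = kruskal(*groups)
                row.update(test="kruskal", statistic=float(stat), p_value=float(p))
        rows.append(row)
    out = pd.DataFrame(rows)
    if correct and out["p_value"].notna().any():
        mask = out["p_value"].notna()
        out.loc[mask, "q_value"] = bh_fdr(out.loc[mask, "p_value"].to_numpy())
    return out


# --------------------------------------------------------------------------
# enrichment statistics


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns (odds_ratio, p).  The p-value sums hypergeometric
    probabilities no larger than the observed table's (the conventional
    probability-mass rule); the odds ratio is (a*d)/(b*c), NaN when a
    zero cell makes it undefined.  Any zero margin gives p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("fisher_exact expects a 2x2 table of non-negative integers")
    a, b, c, d = t.ravel()
    if min(a + b, c + d, a + c, b + d) == 0:
        odds = (a * d) / (b * c) if b * c > 0 else float("nan")
        return odds, 1.0
    res = _scipy_fisher(t.astype(int), alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return float(odds), float(res.pvalue)


@dataclass
class MarkerEnrichment:
    markers: list[str]
    overlap: list[str]
    n_markers: int
    n_drivers: int
    n_background: int
    odds_ratio: float
    p_value: float
    marker_table: pd.DataFrame | None = None
    note: str | None = None


def tumor_marker_enrichment(
    expr: OmicsMatrix,
    clinical_values: pd.Series,
    drivers: set[str],
    background: set[str],
    directions: dict[str, str] | None = None,
    p_cut: float = 0.05,
    var_quantile: float = 0.5,
) -> MarkerEnrichment:
    """Enrichment of the driver list for putative tumor-progression
    markers.

    For every background gene, expression is Spearman-correlated with an
    ordinal (stage) or continuous (size) clinical variable over samples
    with both measurements.  Markers are genes with p < ``p_cut`` whose
    expression variance sits in the top half across background genes and,
    when the gene's methylation direction is known, whose correlation sign
    matches it: hyper-methylated genes (candidate tumor suppressors) must
    correlate negatively with progression, hypo-methylated genes
    (candidate oncogenes) positively.  Enrichment of drivers for markers
    over the background is a Fisher exact test.
    """
    drivers = set(drivers)
    background = set(background)
    if not drivers <= background:
        raise ValueError("drivers must be a subset of the background gene set")
    genes = [g for g in expr.gene_ids if g in background]
    if not genes:
        raise DataError("no background genes present in the expression matrix")
    clin = pd.Series(clinical_values).dropna()
    common = expr.values.index.intersection(clin.index)
    rows = []
    for g in genes:
        e = expr.values.loc[common, g]
        ok = e.notna()
        rho, p = np.nan, np.nan
        if ok.sum() >= 3 and e[ok].nunique() > 1 and clin[common][ok].nunique() > 1:
            rho, p = spearmanr(e[ok], clin[common][ok])
        rows.append(
            {
                "gene_id": g,
                "rho": float(rho),
                "p_value": float(p),
                "variance": float(expr.values[g].var(skipna=True)),
            }
        )
    tab = pd.DataFrame(rows).set_index("gene_id")
    var_floor = tab["variance"].quantile(var_quantile)
    is_marker = (tab["p_value"] < p_cut) & (tab["variance"] >= var_floor)
    if directions:
        for g in tab.index:
            if not is_marker[g] or g not in directions:
                continue
            want = directions[g]
            if want == "hyper" and not tab.loc[g, "rho"] < 0:
                is_marker[g] = False
            elif want == "hypo" and not tab.loc[g, "rho"] > 0:
                is_marker[g] = False
    markers = set(tab.index[is_marker])
    overlap = markers & drivers
    note = None
    if not markers or not drivers:
        odds, p = float("nan"), 1.0
        note = "empty marker or driver set; odds undefined"
    else:
        a = len(overlap)
        b = len(drivers - markers)
        c = len(markers - drivers)
        d = len(background - markers - drivers)
        odds, p = fisher_exact([[a, b], [c, d]])
    return MarkerEnrichment(
        markers=sorted(markers),
        overlap=sorted(overlap),
        n_markers=len(markers),
        n_drivers=len(drivers),
        n_background=len(background),
        odds_ratio=odds,
        p_value=p,
        marker_table=tab,
        note=note,
    )


def gene_set_enrichment(
    query: set[str],
    term_sets: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """Generic Fisher-exact over-representation of ``query`` in each named
    gene set, restricted to ``background``, with BH correction across
    terms.  Terms with no background overlap are skipped."""
    query = set(query) & set(background)
    rows = []
    for name, tset in term_sets.items():
        tset = set(tset) & set(background)
        if not tset:
            continue
        a = len(query & tset)
        b = len(query - tset)
        c = len(tset - query)
        d = len(background - query - tset)
        odds, p = fisher_exact([[a, b], [c, d]])
        rows.append(
            {
                "term": name,
                "n_term": len(tset),
                "n_overlap": a,
                "overlap_genes": ",".join(sorted(query & tset)),
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out


def plot_consensus_heatmap(result: ConsensusK, path) -> None:
    """Plain consensus heatmap (samples ordered by final label)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = result.labels.sort_values(kind="stable").index
    C = result.consensus.loc[order, order]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(C.to_numpy(), cmap="Blues", vmin=0, vmax=1, interpolation="nearest")
    ax.set_title(f"Consensus matrix, K = {result.k} (PAC = {result.pac:.3f})")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="consensus")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
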