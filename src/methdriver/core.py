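"""Driver-gene identification from methylation states.

Three steps per CpG cluster:

1. fit a Beta mixture to the tumor methylation profile (``mixture``
   module) — each component is a methylation state;
2. compare every state to normal tissue: its DM value (differential
   methylation) is the component mean minus the mean normal beta, tested
   by a two-sided Wilcoxon rank-sum of the state's member betas against
   the normal betas, with Benjamini-Hochberg q-values pooled over all
   (cluster, state) tests in the run.  A state is flagged differential
   when q <= 0.05 and |DM| >= 0.10 (the 0.10 floor reflects array
   platform sensitivity);
3. functional filter: ordinary least squares of the downstream layer
   (gene expression in GE mode, protein abundance in PA mode) on the
   cluster's per-sample beta over matched samples.  A cluster passes when
   the slope is negative (promoter methylation should silence), R-squared
   exceeds 0.05 and the regression q-value (BH-pooled per layer) is at
   most 0.01.

A gene is a driver when at least one of its clusters has a flagged state
and passes the functional filter.  The run also emits the DM-value
matrix: per driver cluster, each tumor sample carries the DM value of its
assigned state if that state is flagged, otherwise 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress, mannwhitneyu, rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

from .data_io import BetaMatrix, DataError, OmicsMatrix, align_samples
from .mixture import BetaMixtureModel, fit_beta_mixture

__all__ = [
    "MethylationState",
    "FunctionalFit",
    "DriverRecord",
    "MethylMixResult",
    "ComparisonSummary",
    "rank_sum_test",
    "bh_fdr",
    "call_differential",
    "functional_filter",
    "run_methylmix",
    "compare_lists",
]


# --------------------------------------------------------------------------
# statistical primitives


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration when min(n, m) <= 8 and there are no ties;
    otherwise the normal approximation with tie correction and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test needs two non-empty samples")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return 1.0
    ties = np.unique(combined).size < combined.size
    if min(x.size, y.size) <= 8 and not ties:
        return float(mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    # U statistic; a perfectly central U is unambiguous under either method
    ranks = rankdata(combined)
    u = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)
    if u == x.size * y.size / 2.0:
        return 1.0
    return float(
        mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
    )


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# step 2: differential state calling


@dataclass
class MethylationState:
    """One Beta-mixture component compared against normal tissue."""

    component: int
    mu: float
    dm_value: float
    n_samples: int
    p_value: float = float("nan")
    q_value: float = float("nan")
    tested: bool = False
    flagged: bool = False


def call_differential(
    model: BetaMixtureModel,
    tumor_betas,
    normal_betas,
    q_cut: float = 0.05,
    dm_min: float = 0.10,
    min_component_n: int = 3,
    pool: bool = True,
) -> list[MethylationState]:
    """Compare each methylation state to normal tissue.

    DM value = component mean minus mean normal beta.  States with at
    least ``min_component_n`` assigned tumor samples are rank-sum tested
    against the normal betas; smaller states are reported untested.  When
    ``pool`` is true, q-values are BH-corrected across this model's
    states; `run_methylmix` instead pools across all clusters in the run.
    """
    tumor = np.asarray(tumor_betas, dtype=float)
    normal = np.asarray(normal_betas, dtype=float)
    if normal.size == 0:
        raise DataError("differential calling is impossible without normal samples")
    normal_mean = float(normal.mean())
    states: list[MethylationState] = []
    for k in range(model.n_components):
        members = tumor[model.assignments == k]
        st = MethylationState(
            component=k,
            mu=float(model.means[k]),
            dm_value=float(model.means[k] - normal_mean),
            n_samples=int(members.size),
        )
        if members.size >= min_component_n:
            st.p_value = rank_sum_test(members, normal)
            st.tested = True
        states.append(st)
    if pool:
        flag_states(states, q_cut=q_cut, dm_min=dm_min)
    return states


def flag_states(
    states: list[MethylationState], q_cut: float = 0.05, dm_min: float = 0.10
) -> None:
    """BH-correct the supplied collection of states in place and flag
    those with q <= q_cut and |DM| >= dm_min."""
    tested = [s for s in states if s.tested]
    if tested:
        qvals = bh_fdr([s.p_value for s in tested])
        for s, q in zip(tested, qvals):
            s.q_value = float(q)
    for s in states:
        s.flagged = bool(
            s.tested and s.q_value <= q_cut and abs(s.dm_value) >= dm_min
        )


# --------------------------------------------------------------------------
# step 3: functional filter


@dataclass
class FunctionalFit:
    """OLS of a downstream layer on cluster methylation."""

    slope: float = float("nan")
    intercept: float = float("nan")
    r_squared: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")
    n: int = 0
    passed: bool = False
    reason: str | None = None


def functional_filter(
    meth_profile,
    downstream,
    min_samples: int = 10,
) -> FunctionalFit:
    """Regress downstream values on per-sample cluster betas.

    Returns slope, R-squared and the regression p-value; the pass/fail
    decision happens after q-values are pooled (see ``evaluate_fit``).
    Zero-variance methylation is not testable.
    """
    x = np.asarray(meth_profile, dtype=float)
    y = np.asarray(downstream, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < min_samples:
        return FunctionalFit(n=int(x.size), reason="too_few_matched_samples")
    if np.ptp(x) == 0:
        return FunctionalFit(n=int(x.size), reason="zero_variance_methylation")
    res = linregress(x, y)
    return FunctionalFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def evaluate_fit(
    fit: FunctionalFit, r2_min: float = 0.05, q_max: float = 0.01
) -> bool:
    """Apply the negative-slope / R-squared / q-value rule to a fit whose
    q-value has been pooled."""
    fit.passed = bool(
        np.isfinite(fit.slope)
        and fit.slope < 0
        and fit.r_squared > r2_min
        and np.isfinite(fit.q_value)
        and fit.q_value <= q_max
    )
    return fit.passed


# --------------------------------------------------------------------------
# the full per-cohort run


@dataclass
class DriverRecord:
    """Per (gene, cluster) outcome of steps 1-3."""

    gene_id: str
    cluster_id: str
    model: BetaMixtureModel
    states: list[MethylationState]
    fit: FunctionalFit
    is_driver: bool = False
    direction: str | None = None  # hyper / hypo / mixed among flagged states


@dataclass
class MethylMixResult:
    mode: str  # "GE" or "PA"
    records: list[DriverRecord]
    driver_genes: list[str]
    dm_matrix: pd.DataFrame  # tumor samples x driver clusters
    params: dict = field(default_factory=dict)

    def records_frame(self) -> pd.DataFrame:
        """Flat per-(gene, cluster, state) table for export."""
        rows = []
        for r in self.records:
            for s in r.states:
                rows.append(
                    {
                        "gene_id": r.gene_id,
                        "cluster_id": r.cluster_id,
                        "n_components": r.model.n_components,
                        "component": s.component,
                        "state_mean": s.mu,
                        "state_n": s.n_samples,
                        "dm_value": s.dm_value,
                        "dm_p": s.p_value,
                        "dm_q": s.q_value,
                        "flagged": s.flagged,
                        "slope": r.fit.slope,
                        "r_squared": r.fit.r_squared,
                        "reg_p": r.fit.p_value,
                        "reg_q": r.fit.q_value,
                        "functional": r.fit.passed,
                        "is_driver": r.is_driver,
                        "direction": r.direction,
                    }
                )
        return pd.DataFrame(rows)


def _direction(states: list[MethylationState]) -> str | None:
    signs = {np.sign(s.dm_value) for s in states if s.flagged}
    if not signs:
        return None
    if signs == {1.0}:
        return "hyper"
    if signs == {-1.0}:
        return "hypo"
    return "mixed"


def fit_cohort_mixtures(
    meth_tumor: BetaMatrix,
    cluster_ids: list[str],
    seed: int = 0,
    k_max: int = 3,
    n_restarts: int = 5,
) -> dict[str, BetaMixtureModel]:
    """Fit the per-cluster Beta mixtures of a cohort (step 1 only).

    The fits depend only on tumor methylation, so a GE run and a PA run
    on the same cohort can share them; `run_methylmix` accepts the result
    through its ``models`` argument.
    """
    seeds = np.random.SeedSequence(seed).spawn(len(cluster_ids))
    return {
        c: fit_beta_mixture(
            meth_tumor.values[c].to_numpy(dtype=float),
            k_max=k_max,
            seed=child,
            n_restarts=n_restarts,
        )
        for c, child in zip(cluster_ids, seeds)
    }


def run_methylmix(
    meth_tumor: BetaMatrix,
    meth_normal: BetaMatrix,
    downstream: OmicsMatrix,
    cluster_genes: dict[str, str | None],
    mode: str = "GE",
    seed: int = 0,
    k_max: int = 3,
    n_restarts: int = 5,
    q_diff: float = 0.05,
    dm_min: float = 0.10,
    r2_min: float = 0.05,
    q_reg: float = 0.01,
    min_samples_regression: int = 10,
    models: dict[str, BetaMixtureModel] | None = None,
) -> MethylMixResult:
    """Execute steps 1-3 over every mapped cluster of a cohort.

    ``meth_tumor``/``meth_normal`` hold per-sample cluster summary betas
    (samples x clusters); ``cluster_genes`` maps cluster ids to their
    nearest-TSS gene (None = unmapped, skipped).  Mixture fitting uses all
    tumor methylation samples; the regression uses only samples matched
    with the downstream matrix.  Deterministic given ``seed``, and
    independent of ``mode`` except for the downstream matrix itself.
    """
    mode = mode.upper()
    if mode not in ("GE", "PA"):
        raise ValueError("mode must be 'GE' or 'PA'")
    clusters = [c for c in meth_tumor.probe_ids if cluster_genes.get(c)]
    if not clusters:
        raise DataError("no gene-mapped clusters to analyze")
    matched = align_samples(meth_tumor, downstream)
    if models is None:
        models = fit_cohort_mixtures(
            meth_tumor, clusters, seed=seed, k_max=k_max, n_restarts=n_restarts
        )

    records: list[DriverRecord] = []
    for c in clusters:
        gene = cluster_genes[c]
        xt = meth_tumor.values[c].to_numpy(dtype=float)
        if c not in meth_normal.values.columns:
            continue
        xn = meth_normal.values[c].to_numpy(dtype=float)
        model = models[c]
        states = call_differential(
            model, xt, xn, q_cut=q_diff, dm_min=dm_min, pool=False
        )
        if gene in downstream.values.columns:
            fit = functional_filter(
                meth_tumor.values.loc[matched, c],
                downstream.values.loc[matched, gene],
                min_samples=min_samples_regression,
            )
        else:
            fit = FunctionalFit(reason="gene_absent_from_downstream_layer")
        records.append(DriverRecord(gene, c, model, states, fit))

    # pool q-values across the whole run, then decide
    flag_states([s for r in records for s in r.states], q_cut=q_diff, dm_min=dm_min)
    fitted = [r.fit for r in records if np.isfinite(r.fit.p_value)]
    if fitted:
        for fit, q in zip(fitted, bh_fdr([f.p_value for f in fitted])):
            fit.q_value = float(q)
    for r in records:
        evaluate_fit(r.fit, r2_min=r2_min, q_max=q_reg)
        r.direction = _direction(r.states)
        r.is_driver = r.fit.passed and any(s.flagged for s in r.states)

    driver_records = [r for r in records if r.is_driver]
    driver_genes = sorted({r.gene_id for r in driver_records})
    dm = pd.DataFrame(index=meth_tumor.values.index)
    for r in driver_records:
        dms = np.array(
            [s.dm_value if s.flagged else 0.0 for s in r.states], dtype=float
        )
        dm[r.cluster_id] = dms[r.model.assignments]
    return MethylMixResult(
        mode=mode,
        records=records,
        driver_genes=driver_genes,
        dm_matrix=dm,
        params={
            "seed": seed,
            "k_max": k_max,
            "n_restarts": n_restarts,
            "q_diff": q_diff,
            "dm_min": dm_min,
            "r2_min": r2_min,
            "q_reg": q_reg,
            "n_matched_samples": len(matched),
        },
    )


# --------------------------------------------------------------------------
# GE vs PA comparison


@dataclass
class ComparisonSummary:
    shared: list[str]
    unique_ge: list[str]
    unique_pa: list[str]
    containment_pa_in_ge: float  # fraction of PA genes also found by GE
    gene_rho: pd.Series | None = None  # per-gene mRNA-protein Spearman rho
    mean_rho: float = float("nan")


def compare_lists(
    ge: MethylMixResult,
    pa: MethylMixResult,
    expr: OmicsMatrix | None = None,
    prot: OmicsMatrix | None = None,
) -> ComparisonSummary:
    """Overlap of the GE and PA driver lists plus, when both downstream
    matrices are supplied, the per-gene Spearman correlation between
    expression and protein abundance over matched samples."""
    ge_set, pa_set = set(ge.driver_genes), set(pa.driver_genes)
    shared = sorted(ge_set & pa_set)
    summary = ComparisonSummary(
        shared=shared,
        unique_ge=sorted(ge_set - pa_set),
        unique_pa=sorted(pa_set - ge_set),
        containment_pa_in_ge=(len(shared) / len(pa_set)) if pa_set else float("nan"),
    )
    if expr is not None and prot is not None:
        matched = align_samples(expr, prot)
        genes = [g for g in expr.gene_ids if g in set(prot.gene_ids)]
        rho = {}
        for g in genes:
            e = expr.values.loc[matched, g]
            p = prot.values.loc[matched, g]
            ok = e.notna() & p.notna()
            if ok.sum() >= 3 and e[ok].nunique() > 1 and p[ok].nunique() > 1:
                rho[g] = float(spearmanr(e[ok], p[ok]).statistic)
        summary.gene_rho = pd.Series(rho, dtype=float)
        if rho:
            summary.mean_rho = float(summary.gene_rho.mean())
    return summary
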