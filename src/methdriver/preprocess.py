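"""Cohort preprocessing: missingness filters, 15-NN imputation, protein
sample quality control and label-free normalization.

The filtering thresholds are strict inequalities: a CpG feature is dropped
when *more than* 10% of its entries are missing, a protein sample when
*more than* 75% of its measurements are missing.  Imputation replaces each
missing cell with the mean of that sample's value in the k nearest
features, where nearness is Euclidean distance over co-observed samples
rescaled to the full sample count.  Protein QC follows the
standard-deviation / two-component Gaussian mixture screen used for
LC-MS/MS cohorts: the component of samples with the higher mean SD is
treated as degraded and removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.impute import KNNImputer
from sklearn.mixture import GaussianMixture

from .data_io import BetaMatrix, DataError, OmicsMatrix

__all__ = [
    "QCReport",
    "filter_missing_features",
    "filter_missing_samples",
    "knn_impute",
    "protein_sample_qc",
    "quantile_normalize_log2",
    "batch_correct",
    "replace_nonfinite",
]

log = logging.getLogger(__name__)

Matrix = BetaMatrix | OmicsMatrix


@dataclass
class QCReport:
    """Outcome of the protein sample-degradation screen."""

    sample_sd: pd.Series
    assignment: pd.Series  # "good" / "poor" per sample
    removed_samples: list[str]
    component_means: tuple[float, float] | None
    warning: str | None = None
    thresholds: dict = field(default_factory=dict)


def filter_missing_features(m: Matrix, max_missing_frac: float = 0.10) -> Matrix:
    """Drop features whose missing fraction is strictly above the cutoff."""
    if not 0 <= max_missing_frac < 1:
        raise ValueError("max_missing_frac must be in [0, 1)")
    frac = m.values.isna().mean(axis=0)
    keep = frac.index[frac.to_numpy() <= max_missing_frac]
    if len(keep) == 0:
        raise DataError("all features exceed the missingness cutoff")
    dropped = m.values.shape[1] - len(keep)
    if dropped:
        log.info("filter_missing_features: removed %d/%d features", dropped, m.values.shape[1])
    return m.with_values(m.values[keep])


def filter_missing_samples(m: Matrix, max_missing_frac: float = 0.75) -> Matrix:
    """Drop samples whose missing fraction is strictly above the cutoff."""
    if not 0 <= max_missing_frac < 1:
        raise ValueError("max_missing_frac must be in [0, 1)")
    frac = m.values.isna().mean(axis=1)
    keep = frac.index[frac.to_numpy() <= max_missing_frac]
    if len(keep) == 0:
        raise DataError("all samples exceed the missingness cutoff")
    dropped = m.values.shape[0] - len(keep)
    if dropped:
        log.info("filter_missing_samples: removed %d/%d samples", dropped, m.values.shape[0])
    return m.with_values(m.values.loc[keep])


def knn_impute(m: Matrix, k: int = 15) -> Matrix:
    """Impute missing cells from the k nearest features.

    Neighbors are other features (the expression-imputation convention);
    distance is Euclidean over co-observed samples, rescaled by the number
    of samples.  Observed cells are never altered, and imputed beta values
    are clamped to [0, 1].
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = m.values
    if not df.isna().to_numpy().any():
        return m.with_values(df.copy())
    if df.isna().all(axis=0).any():
        bad = df.columns[df.isna().all(axis=0)][0]
        raise DataError(
            f"feature {bad!r} has no observed values; filter it before imputing"
        )
    n_features = df.shape[1]
    imputer = KNNImputer(n_neighbors=min(k, max(n_features - 1, 1)), weights="uniform")
    # transpose: rows become features so neighbors are found among features
    filled = imputer.fit_transform(df.to_numpy(dtype=float).T).T
    out = pd.DataFrame(filled, index=df.index, columns=df.columns)
    out = out.where(df.isna(), df)  # paranoia: observed cells unchanged
    if isinstance(m, BetaMatrix):
        out = out.clip(0.0, 1.0)
    return m.with_values(out)


def protein_sample_qc(raw: OmicsMatrix, seed: int = 0) -> QCReport:
    """Screen non-normalized protein samples for degradation.

    Computes each sample's standard deviation across genes
    (pairwise-complete), fits a one-dimensional two-component Gaussian
    mixture by EM, and marks the higher-mean component as poor quality.
    If a single component describes the SDs better (BIC) or the two
    component means are indistinguishable, no samples are removed.
    """
    if raw.values.shape[0] < 4:
        raise DataError("protein QC needs at least 4 samples")
    sd = raw.values.std(axis=1, skipna=True, ddof=1)
    if sd.isna().any():
        raise DataError("sample(s) with <2 observed proteins; filter first")
    good = pd.Series("good", index=sd.index)
    if np.ptp(sd.to_numpy(dtype=float)) < 1e-12:
        return QCReport(
            sd, good, [], None,
            warning="all sample SDs identical; no samples removed",
        )
    # fit on sorted values so the outcome is invariant to sample order
    x = np.sort(sd.to_numpy(dtype=float))[:, None]
    try:
        gm1 = GaussianMixture(1, random_state=seed).fit(x)
        gm2 = GaussianMixture(
            2, n_init=10, random_state=seed, reg_covar=1e-10
        ).fit(x)
    except Exception as exc:  # degenerate EM
        return QCReport(sd, good, [], None, warning=f"EM failure: {exc}")
    means = gm2.means_.ravel()
    if gm1.bic(x) <= gm2.bic(x):
        return QCReport(
            sd, good, [], tuple(np.sort(means)),
            warning="one component preferred by BIC; no samples removed",
        )
    if abs(means[0] - means[1]) < 1e-6:
        return QCReport(
            sd, good, [], tuple(np.sort(means)),
            warning="degenerate component means; no samples removed",
        )
    poor_comp = int(np.argmax(means))
    labels = gm2.predict(sd.to_numpy(dtype=float)[:, None])
    if len(np.unique(labels)) < 2:
        return QCReport(
            sd, good, [], tuple(np.sort(means)),
            warning="mixture collapsed to one occupied component; no samples removed",
        )
    assignment = pd.Series(
        np.where(labels == poor_comp, "poor", "good"), index=sd.index
    )
    removed = list(assignment.index[assignment == "poor"])
    log.info("protein_sample_qc: removing %d poor-quality samples", len(removed))
    return QCReport(
        sd,
        assignment,
        removed,
        (float(np.min(means)), float(np.max(means))),
        thresholds={"n_components": 2, "rule": "higher-mean component removed"},
    )


def quantile_normalize_log2(raw: OmicsMatrix, pseudocount: float = 1.0) -> OmicsMatrix:
    """Quantile-normalize label-free counts across samples, then log2.

    Classical quantile normalization: every sample's order statistics are
    replaced by the mean order statistics over samples (ties receive the
    average of their reference values), making per-sample distributions
    identical up to ties.  A configurable pseudocount guards the log.
    """
    X = raw.values.to_numpy(dtype=float)
    if np.nanmin(X) < 0:
        raise DataError("quantile normalization expects non-negative counts")
    n_samples, n_genes = X.shape
    grid = np.linspace(0.0, 1.0, n_genes)
    # reference distribution: mean of each sample's empirical quantile function
    ref_rows = np.empty((n_samples, n_genes))
    for i in range(n_samples):
        obs = np.sort(X[i][~np.isnan(X[i])])
        if obs.size == 0:
            raise DataError("sample with no observed values")
        ref_rows[i] = np.interp(grid, np.linspace(0.0, 1.0, obs.size), obs)
    reference = ref_rows.mean(axis=0)
    out = np.full_like(X, np.nan)
    for i in range(n_samples):
        mask = ~np.isnan(X[i])
        m_obs = int(mask.sum())
        ranks = rankdata(X[i][mask], method="average")
        p = (ranks - 1.0) / max(m_obs - 1, 1)
        out[i, mask] = np.interp(p, grid, reference)
    normed = pd.DataFrame(
        np.log2(out + pseudocount), index=raw.values.index, columns=raw.values.columns
    )
    return raw.with_values(normed)


def replace_nonfinite(m: OmicsMatrix, low_value: float | None = None) -> OmicsMatrix:
    """Replace -inf/inf left by log transforms with a non-zero low value
    (default: 1e-3 of the smallest positive finite entry)."""
    X = m.values.to_numpy(dtype=float)
    finite = X[np.isfinite(X)]
    if low_value is None:
        pos = finite[finite > 0]
        low_value = 1e-3 * (pos.min() if pos.size else 1.0)
    X = np.where(np.isfinite(X) | np.isnan(X), X, low_value)
    return m.with_values(pd.DataFrame(X, index=m.values.index, columns=m.values.columns))


def batch_correct(
    m: Matrix,
    batch: pd.Series | None = None,
    method: str | Callable[[pd.DataFrame, pd.Series], pd.DataFrame] = "standardize",
    allow_singleton: bool = False,
) -> Matrix:
    """Equalize per-feature batch means (and scales) while preserving the
    grand mean.

    The shipped reference method is a per-batch location/scale
    standardization; empirical-Bayes batch correction (e.g. ComBat) can be
    plugged in as a callable with the same matrix-in/matrix-out contract.
    """
    df = m.values
    if batch is None:
        if not isinstance(m, BetaMatrix):
            raise ValueError("batch labels required for this matrix type")
        batch = m.batch
    batch = pd.Series(batch).reindex(df.index)
    if batch.isna().any():
        raise DataError("batch label missing for some samples")
    counts = batch.value_counts()
    if len(counts) == 1:
        return m.with_values(df.copy())
    if (counts < 2).any() and not allow_singleton:
        raise DataError(
            f"singleton batch(es) {list(counts.index[counts < 2])}; "
            "pass allow_singleton=True to keep them uncorrected"
        )
    if callable(method):
        return m.with_values(method(df, batch))
    if method != "standardize":
        raise ValueError(f"unknown batch correction method {method!r}")
    X = df.to_numpy(dtype=float)
    grand_mean = np.nanmean(X, axis=0)
    grand_sd = np.nanstd(X, axis=0, ddof=1)
    out = np.array(X)
    for b in counts.index:
        rows = (batch == b).to_numpy()
        if rows.sum() < 2:
            continue
        mb = np.nanmean(X[rows], axis=0)
        sb = np.nanstd(X[rows], axis=0, ddof=1)
        scale = np.where((sb > 0) & (grand_sd > 0), grand_sd / np.where(sb > 0, sb, 1.0), 1.0)
        out[rows] = (X[rows] - mb) * scale + grand_mean
    corrected = pd.DataFrame(out, index=df.index, columns=df.columns)
    if isinstance(m, BetaMatrix):
        corrected = corrected.clip(0.0, 1.0)
    return m.with_values(corrected)
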