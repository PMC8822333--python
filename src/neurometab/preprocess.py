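"""LC-MS feature-table cleaning cascade.

Order is fixed: replicate-CV filter -> sample replicate-correlation filter ->
median summarization -> ComBat batch correction (on summarized log2 values,
missing cells excluded from estimation) -> group-wise missingness filter with
half-minimum imputation -> log2 transform + quantile normalization.

Thresholds default to the reference pipeline's values: CV < 0.75 to keep a
feature, replicate Pearson r >= 0.7 to keep a sample, < 20% missing in at
least one diagnosis group to keep (and impute) a feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    NumericDomainError,
)
from .synthetic import RawFeatureTable


@dataclass
class CleanFeatureTable:
    """Feature x sample log2 quantile-normalized intensities plus QC log."""

    intensities: pd.DataFrame          # features x samples, no missing
    qc_log: pd.DataFrame               # per-feature flags and counts
    dropped_samples: list[str] = field(default_factory=list)
    mz: pd.Series | None = None
    rt: pd.Series | None = None

    @property
    def matrix(self) -> np.ndarray:
        return self.intensities.to_numpy()


def _replicate_cv(raw: RawFeatureTable) -> np.ndarray:
    """Median across samples of within-triplicate CV (sd/mean, ddof=1).

    Samples with fewer than two non-missing replicates do not contribute.
    """
    x = raw.intensities
    n_ok = np.sum(~np.isnan(x), axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(x, axis=2, ddof=1)
        mean = np.nanmean(x, axis=2)
        cv = np.where((n_ok >= 2) & (mean > 0), sd / mean, np.nan)
        med = np.nanmedian(cv, axis=1)
    return med


def filter_replicate_cv(
    raw: RawFeatureTable, cv_max: float = 0.75
) -> tuple[RawFeatureTable, pd.DataFrame]:
    """Drop features whose median within-replicate CV is >= cv_max."""
    if not (cv_max > 0 and np.isfinite(cv_max)):
        raise ConfigurationError("cv_max must be a positive finite fraction")
    med_cv = _replicate_cv(raw)
    keep = ~(med_cv >= cv_max)  # NaN medians (no usable sample) kept here
    log = pd.DataFrame(
        {"median_cv": med_cv, "dropped_cv": ~keep},
        index=pd.Index(raw.feature_ids, name="feature_id"),
    )
    return raw.subset_features(keep), log


def filter_sample_replicate_corr(
    raw: RawFeatureTable, r_min: float = 0.7
) -> tuple[RawFeatureTable, list[str]]:
    """Drop samples whose minimum pairwise replicate Pearson r is < r_min.

    Correlations are computed across features on pairwise-complete values.
    """
    x = raw.intensities
    if raw.n_features < 3:
        raise DegenerateInputError("need >= 3 features to correlate replicates")
    keep, dropped = [], []
    for j in range(raw.n_samples):
        rs = []
        for a in range(3):
            for b in range(a + 1, 3):
                u, v = x[:, j, a], x[:, j, b]
                ok = ~(np.isnan(u) | np.isnan(v))
                if ok.sum() < 3:
                    rs.append(np.nan)
                    continue
                uu, vv = u[ok], v[ok]
                if uu.std() == 0 or vv.std() == 0:
                    rs.append(np.nan)
                    continue
                rs.append(float(np.corrcoef(uu, vv)[0, 1]))
        min_r = np.nanmin(rs) if not np.all(np.isnan(rs)) else np.nan
        if np.isnan(min_r) or min_r >= r_min:
            keep.append(j)
        else:
            dropped.append(raw.samples[j])
    return raw.subset_samples(np.array(keep, dtype=int)), dropped


def summarize_replicates(raw: RawFeatureTable) -> pd.DataFrame:
    """Median of non-missing replicates; missing unless >= 2 are present."""
    x = raw.intensities
    n_ok = np.sum(~np.isnan(x), axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(x, axis=2)
    med = np.where(n_ok >= 2, med, np.nan)
    return pd.DataFrame(
        med,
        index=pd.Index(raw.feature_ids, name="feature_id"),
        columns=raw.samples,
    )


def combat_correct(table: pd.DataFrame, batches: np.ndarray) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch correction.

    Operates on log-scale feature x sample values; missing cells are excluded
    from estimation and remain missing afterwards. Per-feature batch means
    and variances are shrunk toward pooled priors (normal prior on the
    standardized location effect, inverse-gamma on the scale factor, both fit
    by method of moments) and removed; grand feature means are preserved.
    A single batch is returned unchanged.
    """
    x = table.to_numpy(dtype=float)
    batches = np.asarray(batches)
    if batches.shape[0] != x.shape[1]:
        raise ConfigurationError("batch labels do not match sample count")
    levels = np.unique(batches)
    if levels.size == 1:
        return table.copy()
    for b in levels:
        if np.sum(batches == b) < 2:
            raise DegenerateInputError(f"batch {b!r} has fewer than 2 samples")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        grand = np.nanmean(x, axis=1)
        resid = x - grand[:, None]
        pooled_var = np.nanvar(resid, axis=1, ddof=1)
    pooled_var = np.where(pooled_var <= 0, 1e-12, pooled_var)
    z = resid / np.sqrt(pooled_var)[:, None]

    adjusted = z.copy()
    for b in levels:
        cols = batches == b
        zb = z[:, cols]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gamma_hat = np.nanmean(zb, axis=1)               # per-feature location
            delta_hat = np.nanvar(zb, axis=1, ddof=1)        # per-feature scale
        gamma_hat = np.where(np.isnan(gamma_hat), 0.0, gamma_hat)
        delta_hat = np.where(np.isnan(delta_hat) | (delta_hat <= 0), 1.0, delta_hat)

        # EB priors by method of moments across features
        g_bar = float(np.mean(gamma_hat))
        t2 = float(np.var(gamma_hat, ddof=1))
        d_bar = float(np.mean(delta_hat))
        s2 = float(np.var(delta_hat, ddof=1))
        # inverse-gamma moments
        lam = (d_bar**2 + 2 * s2) / s2 if s2 > 0 else 1e6
        theta = (d_bar**3 + d_bar * s2) / s2 if s2 > 0 else d_bar * 1e6

        nb = np.sum(~np.isnan(zb), axis=1).astype(float)
        nb = np.maximum(nb, 1.0)
        if t2 > 0:
            gamma_star = (nb * t2 * gamma_hat + delta_hat * g_bar) / (nb * t2 + delta_hat)
        else:
            gamma_star = np.full_like(gamma_hat, g_bar)
        sse = np.nansum((zb - gamma_star[:, None]) ** 2, axis=1)
        delta_star = (theta + 0.5 * sse) / (nb / 2.0 + lam - 1.0)
        delta_star = np.where(delta_star <= 0, 1.0, delta_star)

        adjusted[:, cols] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = adjusted * np.sqrt(pooled_var)[:, None] + grand[:, None]
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def filter_and_impute_missing(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    miss_max: float = 0.20,
    require_both_groups: bool = False,
    global_half_min: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-aware missingness filter with half-minimum imputation.

    A feature is retained iff its missing fraction is < ``miss_max`` in at
    least one diagnosis group (or in both, with ``require_both_groups``).
    Missing cells of retained features are set to half the feature's minimum
    observed intensity (or half the global table minimum with
    ``global_half_min``). Works on the raw intensity scale.
    """
    if not (0.0 < miss_max <= 1.0):
        raise ConfigurationError("miss_max must lie in (0, 1]")
    diag = meta.loc[table.columns, "diagnosis"]
    groups = [g for g in ("MCI", "CN") if (diag == g).any()]
    if len(groups) < 2:
        raise DegenerateInputError("both diagnosis groups must be non-empty")
    x = table.to_numpy(dtype=float)
    miss_frac = {}
    for g in groups:
        cols = (diag == g).to_numpy()
        miss_frac[g] = np.isnan(x[:, cols]).mean(axis=1)
    below = np.stack([miss_frac[g] < miss_max for g in groups], axis=0)
    keep = below.all(axis=0) if require_both_groups else below.any(axis=0)

    kept = x[keep]
    n_missing = np.isnan(kept).sum(axis=1)
    if global_half_min:
        fill = np.full(kept.shape[0], np.nanmin(kept) / 2.0)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fill = np.nanmin(kept, axis=1) / 2.0
    rows, cols = np.nonzero(np.isnan(kept))
    kept[rows, cols] = fill[rows]

    log = pd.DataFrame(
        {
            "miss_frac_mci": miss_frac.get("MCI", np.full(x.shape[0], np.nan)),
            "miss_frac_cn": miss_frac.get("CN", np.full(x.shape[0], np.nan)),
            "dropped_missing": ~keep,
            "n_imputed": 0,
        },
        index=table.index,
    )
    log.loc[table.index[keep], "n_imputed"] = n_missing
    out = pd.DataFrame(kept, index=table.index[keep], columns=table.columns)
    return out, log


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Force all samples to share a distribution: each column's sorted values
    are replaced by the across-sample mean of order statistics; ties receive
    the mean of their tied ranks' reference values."""
    x = table.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise NumericDomainError("quantile normalization requires complete data")
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        col = x[:, j]
        # average reference values over tied ranks
        sorted_vals = col[order[:, j]]
        vals = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            vals[i : k + 1] = ref[i : k + 1].mean()
            i = k + 1
        out[order[:, j], j] = vals
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def log2_quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """log2 transform followed by quantile normalization across samples."""
    x = table.to_numpy(dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise NumericDomainError("all intensities must be positive and finite")
    return quantile_normalize(pd.DataFrame(np.log2(x), index=table.index, columns=table.columns))


def preprocess(
    raw: RawFeatureTable,
    meta: pd.DataFrame,
    cv_max: float = 0.75,
    r_min: float = 0.7,
    miss_max: float = 0.20,
    require_both_groups: bool = False,
    global_half_min: bool = False,
) -> CleanFeatureTable:
    """Run the full cascade and return the clean table with its QC log."""
    filtered, cv_log = filter_replicate_cv(raw, cv_max=cv_max)
    filtered, dropped_samples = filter_sample_replicate_corr(filtered, r_min=r_min)
    summarized = summarize_replicates(filtered)

    # ComBat on the log2 scale with missing cells excluded, then back
    log_table = pd.DataFrame(
        np.log2(summarized.to_numpy()),
        index=summarized.index,
        columns=summarized.columns,
    )
    corrected_log = combat_correct(log_table, filtered.sample_batches)
    corrected = pd.DataFrame(
        np.exp2(corrected_log.to_numpy()),
        index=corrected_log.index,
        columns=corrected_log.columns,
    )

    imputed, miss_log = filter_and_impute_missing(
        corrected,
        meta,
        miss_max=miss_max,
        require_both_groups=require_both_groups,
        global_half_min=global_half_min,
    )
    clean = log2_quantile_normalize(imputed)

    qc = cv_log.join(miss_log, how="left")
    qc["dropped_missing"] = (
        qc["dropped_missing"].astype("boolean").fillna(False).astype(bool)
    )
    qc["n_imputed"] = qc["n_imputed"].fillna(0).astype(int)
    qc["retained"] = False
    qc.loc[clean.index, "retained"] = True

    id_pos = {f: i for i, f in enumerate(raw.feature_ids)}
    kept_idx = [id_pos[f] for f in clean.index]
    return CleanFeatureTable(
        intensities=clean,
        qc_log=qc,
        dropped_samples=dropped_samples,
        mz=pd.Series(raw.mz[kept_idx], index=clean.index, name="mz"),
        rt=pd.Series(raw.rt[kept_idx], index=clean.index, name="time"),
    )


class MetabolomicsPreprocessor:
    """Estimator-style wrapper over :func:`preprocess`.

    Parameters mirror the cascade thresholds; ``fit_transform(raw, meta)``
    returns the :class:`CleanFeatureTable` and stores the QC log on the
    instance (``qc_log_``, ``dropped_samples_``).
    """

    def __init__(
        self,
        cv_max: float = 0.75,
        r_min: float = 0.7,
        miss_max: float = 0.20,
        require_both_groups: bool = False,
        global_half_min: bool = False,
    ) -> None:
        self.cv_max = cv_max
        self.r_min = r_min
        self.miss_max = miss_max
        self.require_both_groups = require_both_groups
        self.global_half_min = global_half_min

    def get_params(self, deep: bool = True) -> dict:
        return {
            "cv_max": self.cv_max,
            "r_min": self.r_min,
            "miss_max": self.miss_max,
            "require_both_groups": self.require_both_groups,
            "global_half_min": self.global_half_min,
        }

    def set_params(self, **params) -> "MetabolomicsPreprocessor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ConfigurationError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_transform(
        self, raw: RawFeatureTable, meta: pd.DataFrame
    ) -> CleanFeatureTable:
        clean = preprocess(raw, meta, **self.get_params())
        self.qc_log_ = clean.qc_log
        self.dropped_samples_ = clean.dropped_samples
        return clean
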