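"""Probe quality filtration, transformation, outlier masking and
low-variability filtering.

The stage order is fixed: flagged-probe removal -> natural-log transform
with per-sample median centering -> per-probe outlier masking -> sparse
probe removal -> k-means low-variance filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

MUSCLE_COLUMN = "muscle"
SAMPLE_COLUMN = "sample_id"


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity matrix with missingness and quality flags.

    ``values`` uses NaN for missing entries; ``flags`` is a boolean matrix
    of the same shape; ``scale`` is either ``"raw"`` or ``"ln"`` and must
    transition raw -> ln exactly once (enforced by :func:`log_median_center`).
    """

    values: pd.DataFrame
    flags: pd.DataFrame | None = None
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if self.flags.shape != self.values.shape:
            raise ValueError("flags must match values shape")
        if self.scale == "raw":
            if (self.values.values[~np.isnan(self.values.values)] < 0).any():
                raise ValueError("negative raw intensities")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_probes(self, probes) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[probes], flags=self.flags.loc[probes])


@dataclass
class QcReport:
    probes_in: int = 0
    probes_removed_by_flags: int = 0
    probes_removed_by_missingness: int = 0
    probes_removed_by_variability: int = 0
    outlier_spots_masked: int = 0
    probes_remaining: int = 0

    def reconciles(self) -> bool:
        removed = (
            self.probes_removed_by_flags
            + self.probes_removed_by_missingness
            + self.probes_removed_by_variability
        )
        return self.probes_in - removed == self.probes_remaining

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _muscle_groups(m: ExpressionMatrix, meta: pd.DataFrame) -> dict[str, list[str]]:
    meta = meta.set_index(SAMPLE_COLUMN) if SAMPLE_COLUMN in meta.columns else meta
    missing = [s for s in m.samples if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata/muscle label: {missing[:5]}")
    groups: dict[str, list[str]] = {}
    for s in m.samples:
        groups.setdefault(str(meta.loc[s, MUSCLE_COLUMN]), []).append(s)
    return groups


def filter_flagged_probes(
    m: ExpressionMatrix, meta: pd.DataFrame, max_flag_fraction: float = 0.5
) -> ExpressionMatrix:
    """Drop probes flagged in strictly more than *max_flag_fraction* of the
    spots of at least one muscle group; survivors are returned unchanged."""
    groups = _muscle_groups(m, meta)
    drop = pd.Series(False, index=m.probes)
    for samples in groups.values():
        frac = m.flags[samples].mean(axis=1)
        drop |= frac > max_flag_fraction
    return m.subset_probes(m.probes[~drop.values])


def log_median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Natural-log transform then subtract each sample's median.

    Flagged spots are set missing here (they are excluded from every later
    statistic), so medians are computed over clean spots only.
    """
    if m.scale != "raw":
        raise ValueError("log_median_center expects a raw-scale matrix")
    vals = m.values.where(~m.flags)
    arr = vals.values
    bad = np.asarray((arr <= 0) & ~np.isnan(arr))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"nonpositive intensity at probe {m.probes[i]!r}, sample {m.samples[j]!r}"
        )
    logged = np.log(arr)
    centered = logged - np.nanmedian(logged, axis=0, keepdims=True)
    out = pd.DataFrame(centered, index=m.probes, columns=m.samples)
    return ExpressionMatrix(out, m.flags.copy(), scale="ln")


def mask_probe_outliers(
    m: ExpressionMatrix, k_sd: float = 3.0
) -> tuple[ExpressionMatrix, int]:
    """Mask entries deviating from their probe mean by more than ``k_sd``
    standard deviations (mean/SD estimated once, outlier included)."""
    if m.scale != "ln":
        raise ValueError("mask_probe_outliers expects an ln-scale matrix")
    arr = m.values.values.copy()
    n_obs = (~np.isnan(arr)).sum(axis=1)
    skipped = m.probes[n_obs < 3]
    if len(skipped):
        warnings.warn(f"{len(skipped)} probes with <3 observations skipped in outlier masking")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=1, keepdims=True)
        sd = np.nanstd(arr, axis=1, keepdims=True, ddof=1)
    eligible = (n_obs >= 3)[:, None]
    outlier = eligible & (np.abs(arr - mean) > k_sd * sd) & ~np.isnan(arr)
    n_masked = int(outlier.sum())
    arr[outlier] = np.nan
    out = pd.DataFrame(arr, index=m.probes, columns=m.samples)
    return ExpressionMatrix(out, m.flags.copy(), scale="ln"), n_masked


def drop_sparse_probes(
    m: ExpressionMatrix, meta: pd.DataFrame, max_bad_fraction: float = 0.5
) -> ExpressionMatrix:
    """Drop probes whose missing (flagged or outlier-masked) fraction exceeds
    *max_bad_fraction* in at least one muscle group."""
    groups = _muscle_groups(m, meta)
    drop = pd.Series(False, index=m.probes)
    for samples in groups.values():
        bad = m.values[samples].isna() | m.flags[samples]
        drop |= bad.mean(axis=1) > max_bad_fraction
    return m.subset_probes(m.probes[~drop.values])


def variance_filter_kmeans(
    m: ExpressionMatrix, k: int = 3, seed: int = 0, n_init: int = 10
) -> tuple[ExpressionMatrix, pd.Index]:
    """Remove the lowest-variability probe cluster.

    Per-probe variances (non-missing entries) are clustered by 1-D k-means
    on the natural-log variance; probes in the cluster with the smallest
    center are filtered out. Returns the filtered matrix and the removed
    probe index.
    """
    if k < 2:
        raise ValueError("k must be >= 2 (k=1 would remove every probe)")
    if len(m.probes) < k:
        raise ValueError(f"need at least {k} probes for k-means with k={k}")
    variances = m.values.var(axis=1, ddof=1, skipna=True)
    if variances.isna().any():
        variances = variances.fillna(0.0)
    if np.allclose(variances, variances.iloc[0]):
        warnings.warn("all probe variances equal; variance filter removed nothing")
        return m, m.probes[:0]
    x = np.log(np.maximum(variances.values, np.finfo(float).tiny)).reshape(-1, 1)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    low = int(np.argmin(km.cluster_centers_.ravel()))
    removed = m.probes[km.labels_ == low]
    return m.subset_probes(m.probes[km.labels_ != low]), removed


def run_qc(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    max_flag_fraction: float = 0.5,
    k_sd: float = 3.0,
    kmeans_k: int = 3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, QcReport]:
    """Full QC pipeline in the fixed stage order."""
    report = QcReport(probes_in=len(m.probes))
    m1 = filter_flagged_probes(m, meta, max_flag_fraction)
    report.probes_removed_by_flags = report.probes_in - len(m1.probes)
    m2 = log_median_center(m1)
    m3, n_masked = mask_probe_outliers(m2, k_sd)
    report.outlier_spots_masked = n_masked
    m4 = drop_sparse_probes(m3, meta)
    report.probes_removed_by_missingness = len(m3.probes) - len(m4.probes)
    m5, removed = variance_filter_kmeans(m4, k=kmeans_k, seed=seed)
    report.probes_removed_by_variability = len(removed)
    report.probes_remaining = len(m5.probes)
    assert report.reconciles()
    return m5, report
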