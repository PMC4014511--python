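"""Per-probe fixed-effects linear modelling of muscle contrast.

Each probe's centered ln expression is modelled as

    Y = Sex + SlaughterBatch + HybridizationBatch(within Sire)
        + CarcassWeight + Muscle + E

by ordinary least squares. Nuisance effects are screened at ``p < 0.2``
(single backward pass); the muscle effect is always retained. Muscle
p-values are Benjamini-Hochberg adjusted across probes, adjusted
(least-squares) means per muscle give the fold change and direction, and
probe calls are collapsed to genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MUSCLE = "muscle"

DEFAULT_EFFECTS = ("sex", "slaughter_batch", "hyb_within_sire", MUSCLE)
DEFAULT_COVARIATES = ("carcass_weight",)


@dataclass(frozen=True)
class DesignSpec:
    """Model structure: categorical effects, covariates, forced effects.

    The nested hybridization-batch-within-sire effect must be supplied as a
    single pre-combined column (e.g. ``"1/3"`` for sire family 1, batch 3)
    so its levels are never pooled across sire families; see
    :func:`combine_nested`.
    """

    categorical: tuple[str, ...] = DEFAULT_EFFECTS
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    forced: frozenset = frozenset({MUSCLE})

    def __post_init__(self) -> None:
        if MUSCLE not in self.categorical:
            raise ValueError("the muscle effect must be part of the model")
        if not self.forced <= set(self.categorical) | set(self.covariates):
            raise ValueError("forced effects must be model effects")

    @property
    def effects(self) -> tuple[str, ...]:
        return self.categorical + self.covariates


def combine_nested(meta: pd.DataFrame, outer: str = "sire", inner: str = "hyb_batch",
                   name: str = "hyb_within_sire") -> pd.DataFrame:
    """Add a nested-factor column combining *inner* within *outer*."""
    meta = meta.copy()
    meta[name] = meta[outer].astype(str) + "/" + meta[inner].astype(str)
    return meta


class _DesignBuilder:
    """Treatment-coded design matrices and equal-weight prediction rows."""

    def __init__(self, meta: pd.DataFrame, spec: DesignSpec):
        self.spec = spec
        self.meta = meta
        self.levels = {
            eff: sorted(meta[eff].astype(str).unique()) for eff in spec.categorical
        }
        self.cov_means = {cov: float(meta[cov].mean()) for cov in spec.covariates}

    def build(self, effects: set[str], rows: pd.DataFrame | None = None):
        """Return (X, colmap) for the retained *effects* subset.

        colmap maps each effect name to the list of its column indices in X.
        """
        rows = self.meta if rows is None else rows
        cols: list[np.ndarray] = [np.ones(len(rows))]
        colmap: dict[str, list[int]] = {}
        idx = 1
        for eff in self.spec.categorical:
            if eff not in effects:
                continue
            vals = rows[eff].astype(str).values
            colmap[eff] = []
            for level in self.levels[eff][1:]:
                cols.append((vals == level).astype(float))
                colmap[eff].append(idx)
                idx += 1
        for cov in self.spec.covariates:
            if cov not in effects:
                continue
            cols.append(rows[cov].astype(float).values)
            colmap[cov] = [idx]
            idx += 1
        return np.column_stack(cols), colmap

    def mean_row(self, effects: set[str], muscle_level: str) -> np.ndarray:
        """Prediction row for one muscle level: factor levels averaged with
        equal weight, covariates at their sample means."""
        row = [1.0]
        for eff in self.spec.categorical:
            if eff not in effects:
                continue
            levels = self.levels[eff]
            for level in levels[1:]:
                if eff == MUSCLE:
                    row.append(1.0 if level == muscle_level else 0.0)
                else:
                    row.append(1.0 / len(levels))
        for cov in self.spec.covariates:
            if cov in effects:
                row.append(self.cov_means[cov])
        return np.array(row)


def _ols(X: np.ndarray, Y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sse = np.einsum("ij,ij->j", resid, resid)
    return beta, sse, int(rank), resid


def _partial_f_p(X, Y, colmap, sse_full, rank_full, tol=1e-10):
    """Per-effect p-values from partial F-tests (drop-one model comparison)."""
    n = X.shape[0]
    df_resid = n - rank_full
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    pvals = {}
    scale = np.maximum(np.abs(Y).max(axis=0), 1.0) ** 2
    for eff, cols in colmap.items():
        keep = [j for j in range(X.shape[1]) if j not in cols]
        _, sse_r, rank_r, _ = _ols(X[:, keep], Y)
        df1 = rank_full - rank_r
        if df1 == 0:  # effect fully aliased: no information, never retained
            pvals[eff] = np.ones(Y.shape[1])
            continue
        delta = np.maximum(sse_r - sse_full, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (delta / df1) / (sse_full / df_resid)
        # zero-residual probes: exact fit => p=0 if the effect explains
        # anything, p=1 if dropping it changes nothing
        degenerate = sse_full <= tol * scale
        p = stats.f.sf(f, df1, df_resid)
        p = np.where(degenerate & (delta > tol * scale), 0.0, p)
        p = np.where(degenerate & (delta <= tol * scale), 1.0, p)
        pvals[eff] = p
    return pvals


def fit_probe_model(y: np.ndarray, meta: pd.DataFrame, spec: DesignSpec | None = None,
                    effects: set[str] | None = None):
    """Fit one probe's OLS model; returns (coefficients, effect p-values, residuals).

    Effect p-values come from partial F-tests of dropping each effect from
    the model.
    """
    spec = spec or DesignSpec()
    effects = set(spec.effects) if effects is None else effects
    builder = _DesignBuilder(meta, spec)
    X, colmap = builder.build(effects)
    Y = np.asarray(y, float).reshape(-1, 1)
    beta, sse, rank, resid = _ols(X, Y)
    pvals = {e: float(p[0]) for e, p in _partial_f_p(X, Y, colmap, sse, rank).items()}
    return beta.ravel(), pvals, resid.ravel()


def select_effects(pvals: dict[str, float], spec: DesignSpec,
                   alpha_keep: float = 0.2) -> set[str]:
    """Single backward pass: keep effects with p < alpha_keep plus forced ones."""
    kept = {e for e, p in pvals.items() if p < alpha_keep}
    return kept | set(spec.forced)


def adjusted_means(beta: np.ndarray, builder: _DesignBuilder,
                   effects: set[str]) -> dict[str, float]:
    """Least-squares means per muscle level for a fitted coefficient vector."""
    return {
        lvl: float(builder.mean_row(effects, lvl) @ beta)
        for lvl in builder.levels[MUSCLE]
    }


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(pvals, float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def fold_change(mean_lm: float, mean_sm: float,
                labels: tuple[str, str] = ("LM", "SM")) -> tuple[float, str | None]:
    """Fold change (ratio of the greater to the lesser adjusted mean on the
    anti-log scale) and direction (label of the greater mean).

    An exact tie gives FC 1 and direction ``None``.
    """
    if mean_lm == mean_sm:
        return 1.0, None
    fc = float(np.exp(abs(mean_lm - mean_sm)))
    return fc, labels[0] if mean_lm > mean_sm else labels[1]


def call_de(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Probes with BH-adjusted muscle p <= alpha (inclusive)."""
    return results[results["padj"] <= alpha]


def de_analyze(values: pd.DataFrame, meta: pd.DataFrame,
               spec: DesignSpec | None = None, alpha_keep: float = 0.2,
               alpha_de: float = 0.05) -> pd.DataFrame:
    """Full per-probe analysis: fit, effect screening, refit, BH, FC.

    *values* is a probe x sample matrix of centered ln expression (NaN =
    missing). Returns a DataFrame indexed by probe with per-effect
    p-values, muscle p, adjusted p, adjusted means, FC, direction, the
    retained-effect set and the DE flag. Probes that cannot be fitted
    (rank deficiency beyond aliasing, too few observations) are skipped
    with a diagnostic column.
    """
    spec = spec or DesignSpec()
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    meta = meta.loc[values.columns]
    builder = _DesignBuilder(meta, spec)
    muscle_levels = builder.levels[MUSCLE]
    if len(muscle_levels) != 2:
        raise ValueError("the muscle factor must have exactly two levels")

    arr = values.values
    complete = ~np.isnan(arr).any(axis=1)
    full_effects = set(spec.effects)

    records: dict[str, dict] = {}

    def _finish(probe_ids, Y, rows_meta, rows_builder):
        """Screen effects on the full model, refit per retained set."""
        X, colmap = rows_builder.build(full_effects, rows_meta)
        beta, sse, rank, _ = _ols(X, Y)
        pv = _partial_f_p(X, Y, colmap, sse, rank)
        groups: dict[frozenset, list[int]] = {}
        for j in range(Y.shape[1]):
            kept = frozenset(select_effects({e: pv[e][j] for e in pv}, spec, alpha_keep))
            groups.setdefault(kept, []).append(j)
        for kept, idxs in groups.items():
            Xr, cmr = rows_builder.build(set(kept), rows_meta)
            b, sse_r, rank_r, _ = _ols(Xr, Y[:, idxs])
            mp = _partial_f_p(Xr, Y[:, idxs], {MUSCLE: cmr[MUSCLE]}, sse_r, rank_r)[MUSCLE]
            row_a = rows_builder.mean_row(set(kept), muscle_levels[0])
            row_b = rows_builder.mean_row(set(kept), muscle_levels[1])
            means_a, means_b = row_a @ b, row_b @ b
            for pos, j in enumerate(idxs):
                records[probe_ids[j]] = {
                    **{f"p_{e}": pv[e][j] for e in pv},
                    "muscle_p": mp[pos],
                    f"mean_{muscle_levels[0]}": means_a[pos],
                    f"mean_{muscle_levels[1]}": means_b[pos],
                    "retained_effects": ";".join(sorted(kept)),
                }

    if complete.any():
        ids = list(values.index[complete])
        _finish(ids, arr[complete].T, meta, builder)

    skipped = []
    for probe in values.index[~complete]:
        y = values.loc[probe]
        obs = y.notna().values
        sub_meta = meta.loc[y.index[obs]]
        if sub_meta[MUSCLE].astype(str).nunique() < 2:
            skipped.append(probe)
            continue
        sub_builder = _DesignBuilder(sub_meta, spec)
        try:
            _finish([probe], y.values[obs].reshape(-1, 1), sub_meta, sub_builder)
        except (ValueError, np.linalg.LinAlgError):
            skipped.append(probe)
    if skipped:
        warnings.warn(f"{len(skipped)} probes skipped (unfittable model)")

    res = pd.DataFrame.from_dict(records, orient="index").loc[
        [p for p in values.index if p in records]
    ]
    res.index.name = "probe_id"
    res["padj"] = bh_adjust(res["muscle_p"].values)
    la, lb = muscle_levels
    fc_dir = [fold_change(a, b, (la, lb))
              for a, b in zip(res[f"mean_{la}"], res[f"mean_{lb}"])]
    res["fc"] = [f for f, _ in fc_dir]
    res["direction"] = [d for _, d in fc_dir]
    res["tie"] = res["direction"].isna()
    res["de"] = res["padj"] <= alpha_de
    return res


def collapse_to_genes(de_probes: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Collapse significant probe calls to one row per annotated gene.

    The representative FC is the maximum-FC significant probe; genes whose
    significant probes disagree in direction are flagged (``conflict``)
    and should be excluded from downstream functional lists. Probes
    without a gene mapping are dropped.
    """
    pm = probe_map.set_index("probe_id")["gene_id"]
    de = de_probes[de_probes.index.isin(pm.index)].copy()
    de["gene_id"] = pm.loc[de.index].values
    de = de[de["direction"].notna()]
    rows = []
    for gene, grp in de.groupby("gene_id", sort=True):
        best = grp["fc"].idxmax()
        rows.append({
            "gene_id": gene,
            "probe_ids": ";".join(sorted(grp.index)),
            "n_probes": len(grp),
            "fc": float(grp.loc[best, "fc"]),
            "direction": grp.loc[best, "direction"],
            "padj": float(grp["padj"].min()),
            "conflict": grp["direction"].nunique() > 1,
        })
    out = pd.DataFrame(rows, columns=["gene_id", "probe_ids", "n_probes", "fc",
                                      "direction", "padj", "conflict"])
    return out.set_index("gene_id")


def relevance_filter(calls: pd.DataFrame, min_fc: float = 1.5) -> pd.DataFrame:
    """Keep non-conflicting gene calls with FC strictly above *min_fc*."""
    return calls[(calls["fc"] > min_fc) & ~calls["conflict"]]
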