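"""qPCR validation arm: efficiency handling, geNorm reference stability,
normalization factors, normalized expression, muscle comparison and
concordance with the microarray calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample_id", "muscle", "assay", "role", "ct", "efficiency"]


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency from a calibration-curve slope: E = 10^(-1/slope)."""
    if slope >= 0:
        raise ValueError("calibration slope must be negative")
    return float(10.0 ** (-1.0 / slope))


def relative_quantity(ct: float, ct_calibrator: float, e: float):
    """q = E^-(Ct - Ct_calibrator); the calibrator's own quantity is 1."""
    return np.asarray(e, float) ** -(np.asarray(ct, float) - ct_calibrator)


def collapse_triplicates(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate Ct values per (sample, assay)."""
    keys = [c for c in ("sample_id", "muscle", "assay", "role", "efficiency")
            if c in ct_table.columns]
    return ct_table.groupby(keys, as_index=False, sort=True)["ct"].mean()


def genorm_stability(ref_quantities: pd.DataFrame) -> pd.DataFrame:
    """geNorm M-values with stepwise exclusion ranking.

    *ref_quantities* is a sample x reference matrix of relative quantities.
    M_j is the mean over the other references k of the SD over samples of
    log2(q_j / q_k). The least stable (max M) reference is excluded and M
    recomputed until two remain; ranking 1 is most stable (the final pair
    shares rank 1).
    """
    if (ref_quantities.values <= 0).any():
        raise ValueError("relative quantities must be positive")
    refs = list(ref_quantities.columns)
    if len(refs) < 2:
        raise ValueError("geNorm needs at least two reference genes")

    logq = np.log2(ref_quantities)

    def m_values(cols: list[str]) -> pd.Series:
        m = {}
        for j in cols:
            sds = [logq[j].sub(logq[k]).std(ddof=1) for k in cols if k != j]
            m[j] = float(np.mean(sds))
        return pd.Series(m)

    initial_m = m_values(refs)
    remaining = list(refs)
    rank: dict[str, int] = {}
    while len(remaining) > 2:
        m = m_values(remaining)
        worst = m.idxmax()
        rank[worst] = len(remaining)
        remaining.remove(worst)
    for r in remaining:
        rank[r] = 1
    return pd.DataFrame({"m": initial_m, "rank": pd.Series(rank)}).sort_values(
        ["rank", "m"]
    )


def normalization_factor(selected_ref_quantities: pd.DataFrame) -> pd.Series:
    """Per-sample NF = geometric mean of the selected references' quantities."""
    if (selected_ref_quantities.values <= 0).any():
        raise ValueError("relative quantities must be positive")
    nf = np.exp(np.log(selected_ref_quantities).mean(axis=1))
    nf.name = "nf"
    return nf


def normalized_expression(ct, ct_calibrator, e, nf):
    """N_exp = E^-(Ct - Ct_calibrator) / NF."""
    return relative_quantity(ct, ct_calibrator, e) / np.asarray(nf, float)


def quantities_from_ct(ct_table: pd.DataFrame,
                       calibrator_sample: str = "calibrator") -> pd.DataFrame:
    """Sample x assay matrix of efficiency-corrected relative quantities.

    The calibrator row (a pooled sample) defines q = 1 per assay and is
    removed from the output.
    """
    collapsed = collapse_triplicates(ct_table)
    wide = collapsed.pivot(index="sample_id", columns="assay", values="ct")
    eff = collapsed.groupby("assay")["efficiency"].first()
    if calibrator_sample not in wide.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent from Ct table")
    cal = wide.loc[calibrator_sample]
    q = eff.values[None, :] ** -(wide - cal).values
    out = pd.DataFrame(q, index=wide.index, columns=wide.columns)
    return out.drop(index=calibrator_sample)


def muscle_compare(nexp: pd.DataFrame, meta: pd.DataFrame,
                   equal_var: bool = True) -> pd.DataFrame:
    """Per-assay two-sided t-test between muscles on normalized expression.

    *nexp* is a sample x assay matrix; *meta* maps sample_id -> muscle.
    Pooled-variance (Student) by default; Welch with ``equal_var=False``.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    muscles = sorted(meta.loc[nexp.index, "muscle"].astype(str).unique())
    if len(muscles) != 2:
        raise ValueError("need exactly two muscle groups")
    a, b = muscles
    in_a = meta.loc[nexp.index, "muscle"].astype(str) == a
    rows = []
    for assay in nexp.columns:
        xa, xb = nexp.loc[in_a.values, assay], nexp.loc[~in_a.values, assay]
        t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
        ma, mb = float(xa.mean()), float(xb.mean())
        if ma == mb:
            fc, direction = 1.0, None
        else:
            fc = max(ma, mb) / min(ma, mb)
            direction = a if ma > mb else b
        rows.append({"assay": assay, f"mean_{a}": ma, f"mean_{b}": mb,
                     "t": float(t), "p": float(p), "fc": fc, "direction": direction})
    return pd.DataFrame(rows).set_index("assay")


def concordance(qpcr_calls: pd.DataFrame, microarray_calls: pd.DataFrame,
                assay_to_gene: dict[str, str] | None = None) -> pd.DataFrame:
    """Direction agreement between qPCR assays and microarray gene calls.

    Returns one row per shared assay/gene with both directions, both FCs
    and a match flag; ``.attrs['fraction_concordant']`` carries the summary.
    """
    mapping = assay_to_gene or {a: a for a in qpcr_calls.index}
    rows = []
    for assay, gene in mapping.items():
        if assay not in qpcr_calls.index or gene not in microarray_calls.index:
            continue
        qd = qpcr_calls.loc[assay, "direction"]
        md = microarray_calls.loc[gene, "direction"]
        rows.append({"assay": assay, "gene_id": gene,
                     "qpcr_direction": qd, "array_direction": md,
                     "qpcr_fc": float(qpcr_calls.loc[assay, "fc"]),
                     "array_fc": float(microarray_calls.loc[gene, "fc"]),
                     "match": qd == md})
    if not rows:
        raise ValueError("no shared assays between qPCR and microarray calls")
    out = pd.DataFrame(rows).set_index("assay")
    out.attrs["fraction_concordant"] = float(out["match"].mean())
    return out
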