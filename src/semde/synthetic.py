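"""Synthetic fixtures with the statistical structure the pipeline assumes.

Generates (i) a probe x sample intensity matrix following the downstream
linear model run forward — paired muscles per animal, sex / slaughter-batch
/ nested hybridization-batch effects, a carcass-weight slope and a planted
per-gene muscle effect; (ii) a rooted ontology with planted functional
modules and gene annotations; (iii) a Ct table for the qPCR arm. Ground
truth is recorded for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ontology import AnnotationSet, GoDag
from .qc import ExpressionMatrix

MUSCLES = ("LM", "SM")


@dataclass
class SimulationConfig:
    n_animals_per_muscle: int = 90
    n_probes: int = 1200
    n_genes: int = 1000
    redundancy_rate: float = 0.15       # fraction of genes with >1 probe
    prop_de: float = 0.3
    fc_log_mean: float = -1.1           # log of |ln FC|: median FC ~ 1.4
    fc_log_sd: float = 0.8
    fc_min: float = 1.1
    fc_max: float = 15.0
    noise_sd: float = 0.25
    sex_effect: float = 0.1
    slaughter_effect: float = 0.1
    hyb_batch_sd: float = 0.05
    weight_slope: float = 0.002
    within_animal_sd: float = 0.0       # shared animal effect across muscles
    flag_prob: float = 0.01
    base_mean: float = 8.0
    base_sd: float = 1.0
    # ontology / annotation structure
    n_modules: int = 5
    terms_per_module: int = 8
    module_purity: float = 1.0
    annotations_per_gene: int = 3
    part_of_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals_per_muscle < 4:
            raise ValueError("need at least 4 animals per muscle (model unidentifiable)")
        for name in ("n_probes", "n_genes", "n_modules", "terms_per_module",
                     "annotations_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("redundancy_rate", "prop_de", "flag_prob", "module_purity",
                     "part_of_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_probes < self.n_genes:
            raise ValueError("need at least one probe per gene")
        if not 1.0 < self.fc_min <= self.fc_max:
            raise ValueError("fold-change bounds must satisfy 1 < fc_min <= fc_max")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticTruth:
    genes: pd.DataFrame        # gene_id, direction (LM/SM/None), fc, module
    probe_map: pd.DataFrame    # probe_id, gene_id

    def de_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["direction"].notna()]


def _truncated_log_fc(rng, size, cfg: SimulationConfig) -> np.ndarray:
    """|ln FC| ~ lognormal, rejection-truncated to [ln fc_min, ln fc_max]."""
    lo, hi = np.log(cfg.fc_min), np.log(cfg.fc_max)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(cfg.fc_log_mean, cfg.fc_log_sd, size=2 * (size - filled) + 8)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def _make_metadata(cfg: SimulationConfig, rng) -> pd.DataFrame:
    n = cfg.n_animals_per_muscle
    n_fam1 = max(2, round(n * 41 / 90))
    sire = np.where(np.arange(n) < n_fam1, "1", "2")
    n_hyb = {"1": min(9, n_fam1), "2": min(11, n - n_fam1)}
    hyb = np.empty(n, dtype=object)
    for fam in ("1", "2"):
        idx = np.flatnonzero(sire == fam)
        hyb[idx] = [f"b{j % n_hyb[fam] + 1}" for j in range(len(idx))]
    sex = np.where(np.arange(n) % 2 == 0, "F", "M")
    slaughter = np.where((np.arange(n) // 2) % 2 == 0, "summer", "winter")
    weight = rng.normal(90.0, 7.0, size=n)
    rows = []
    for muscle in MUSCLES:
        for i in range(n):
            rows.append({
                "sample_id": f"A{i:03d}_{muscle}", "animal": f"A{i:03d}",
                "muscle": muscle, "sex": sex[i], "slaughter_batch": slaughter[i],
                "sire": sire[i], "hyb_batch": hyb[i],
                "carcass_weight": round(float(weight[i]), 2),
            })
    return pd.DataFrame(rows)


def _plant_genes(cfg: SimulationConfig, rng) -> pd.DataFrame:
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    n_de = int(round(cfg.prop_de * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    direction = np.full(cfg.n_genes, None, dtype=object)
    direction[de_idx] = rng.choice(MUSCLES, size=n_de)
    fc = np.ones(cfg.n_genes)
    fc[de_idx] = np.exp(_truncated_log_fc(rng, n_de, cfg))
    base = rng.normal(cfg.base_mean, cfg.base_sd, size=cfg.n_genes)
    return pd.DataFrame({"gene_id": gene_ids, "direction": direction,
                         "fc": fc, "base": base}).set_index("gene_id")


def _probe_map(cfg: SimulationConfig, rng) -> pd.DataFrame:
    """One probe per gene, extra probes distributed over a redundant subset."""
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    owners = list(gene_ids)
    extra = cfg.n_probes - cfg.n_genes
    n_redundant = max(1, int(round(cfg.redundancy_rate * cfg.n_genes))) if extra else 0
    if extra:
        redundant = rng.choice(gene_ids, size=min(n_redundant, cfg.n_genes),
                               replace=False)
        owners += [redundant[i % len(redundant)] for i in range(extra)]
    return pd.DataFrame({
        "probe_id": [f"P{i:05d}" for i in range(cfg.n_probes)],
        "gene_id": owners,
    })


def generate_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Forward-simulate the array experiment.

    Returns a raw-scale :class:`ExpressionMatrix` (2 x n_animals columns,
    paired per animal), the sample metadata table and the recorded truth.
    """
    rng = np.random.default_rng(cfg.seed)
    meta = _make_metadata(cfg, rng)
    genes = _plant_genes(cfg, rng)
    pmap = _probe_map(cfg, rng)

    n_samples = len(meta)
    n_genes = cfg.n_genes
    # Nuisance effects are per-gene coefficients (the per-probe model run
    # forward): magnitudes centered on the configured effect size with a
    # random sign, so they survive per-sample median centering.
    def per_gene_coef(scale: float) -> np.ndarray:
        if scale == 0.0:
            return np.zeros(n_genes)
        sign_g = rng.choice([-1.0, 1.0], size=n_genes)
        return sign_g * scale * (1.0 + 0.25 * rng.normal(size=n_genes))

    sex_coef = per_gene_coef(cfg.sex_effect)
    slaughter_coef = per_gene_coef(cfg.slaughter_effect)
    weight_coef = per_gene_coef(cfg.weight_slope)
    hyb_levels = sorted((meta["sire"] + "/" + meta["hyb_batch"]).unique())
    hyb_coef = rng.normal(0, cfg.hyb_batch_sd, size=(n_genes, len(hyb_levels))) \
        if cfg.hyb_batch_sd > 0 else np.zeros((n_genes, len(hyb_levels)))

    is_m = (meta["sex"] == "M").values.astype(float)
    is_winter = (meta["slaughter_batch"] == "winter").values.astype(float)
    hyb_idx = pd.Categorical(meta["sire"] + "/" + meta["hyb_batch"],
                             categories=hyb_levels).codes
    weight_c = (meta["carcass_weight"] - meta["carcass_weight"].mean()).values

    sample_eff = np.zeros(n_samples)
    if cfg.within_animal_sd > 0:
        animal_eff = dict(zip(sorted(meta["animal"].unique()),
                              rng.normal(0, cfg.within_animal_sd,
                                         meta["animal"].nunique())))
        sample_eff += [animal_eff[a] for a in meta["animal"]]

    half_fc = 0.5 * np.log(genes["fc"].values)
    sign = np.where(genes["direction"].values == "LM", 1.0,
                    np.where(genes["direction"].values == "SM", -1.0, 0.0))
    muscle_sign = np.where(meta["muscle"] == "LM", 1.0, -1.0)

    gene_pos = {g: i for i, g in enumerate(genes.index)}
    probe_gene = np.array([gene_pos[g] for g in pmap["gene_id"]])

    gene_terms = (sex_coef[:, None] * is_m[None, :]
                  + slaughter_coef[:, None] * is_winter[None, :]
                  + hyb_coef[:, hyb_idx]
                  + weight_coef[:, None] * weight_c[None, :])
    ln_y = (genes["base"].values[probe_gene][:, None]
            + (sign * half_fc)[probe_gene][:, None] * muscle_sign[None, :]
            + gene_terms[probe_gene, :]
            + sample_eff[None, :])
    if cfg.noise_sd > 0:
        ln_y = ln_y + rng.normal(0, cfg.noise_sd, size=ln_y.shape)

    values = pd.DataFrame(np.exp(ln_y), index=pmap["probe_id"].values,
                          columns=meta["sample_id"].values)
    flags = pd.DataFrame(rng.random(ln_y.shape) < cfg.flag_prob,
                         index=values.index, columns=values.columns)

    truth_genes = genes.drop(columns="base").copy()
    truth_genes["module"] = pd.NA
    truth = SyntheticTruth(truth_genes, pmap)
    return ExpressionMatrix(values, flags, scale="raw"), meta, truth


def generate_go_dag(cfg: SimulationConfig,
                    truth: SyntheticTruth | None = None,
                    genes: list[str] | None = None) -> tuple[GoDag, AnnotationSet]:
    """Build a rooted DAG with *n_modules* disjoint subtrees and annotate
    genes (predominantly, per ``module_purity``) within their module.

    Module labels are written back into ``truth.genes['module']`` when a
    truth object is supplied.
    """
    if cfg.n_modules < 2:
        raise ValueError("need at least 2 functional modules")
    rng = np.random.default_rng(cfg.seed + 1)
    if genes is None:
        if truth is not None:
            genes = list(truth.genes.index)
        else:
            genes = [f"G{i:05d}" for i in range(cfg.n_genes)]

    dag = GoDag()
    root = "GO:0000000"
    dag.add_term(root, "root")
    module_terms: dict[int, list[str]] = {}
    tid = 1
    for m in range(cfg.n_modules):
        head = f"GO:{tid:07d}"
        tid += 1
        dag.add_term(head, f"module_{m}_head")
        dag.add_edge(head, root, "is_a")
        terms = [head]
        for _ in range(cfg.terms_per_module - 1):
            t = f"GO:{tid:07d}"
            tid += 1
            dag.add_term(t, f"module_{m}_term")
            parent = terms[int(rng.integers(len(terms)))]
            rel = "part_of" if rng.random() < cfg.part_of_prob else "is_a"
            dag.add_edge(t, parent, rel)
            terms.append(t)
        module_terms[m] = terms
    dag.validate()

    modules = rng.integers(cfg.n_modules, size=len(genes))
    annots = AnnotationSet()
    for g, m in zip(genes, modules):
        own = module_terms[int(m)]
        for j in range(cfg.annotations_per_gene):
            if j > 0 and rng.random() >= cfg.module_purity:
                other = int(rng.choice([x for x in range(cfg.n_modules) if x != m]))
                pool = module_terms[other]
            else:
                pool = own  # first annotation always from the home module
            annots.annotate(g, pool[int(rng.integers(len(pool)))])

    if truth is not None:
        truth.genes.loc[genes, "module"] = modules
    return dag, annots


def generate_qpcr(cfg: SimulationConfig, truth: SyntheticTruth,
                  n_targets: int = 7, n_refs: int = 3, n_animals: int = 8,
                  efficiency: float = 2.0, noise_sd: float | None = None,
                  ref_noise_sds: list[float] | None = None,
                  loading_sd: float = 0.1, n_replicates: int = 3) -> pd.DataFrame:
    """Ct table for target and reference assays over paired muscle samples.

    Targets are the highest-FC planted DE genes; reference assays get
    per-reference noise (``ref_noise_sds``, ascending by default) on top of
    a shared per-sample loading effect, so their stability ranking is
    known. A pooled calibrator sample is included.
    """
    if n_refs < 2:
        raise ValueError("geNorm needs at least two reference genes")
    de = truth.de_genes().sort_values("fc", ascending=False)
    if len(de) < n_targets:
        raise ValueError(f"only {len(de)} DE genes available for {n_targets} targets")
    rng = np.random.default_rng(cfg.seed + 2)
    noise_sd = cfg.noise_sd if noise_sd is None else noise_sd
    if ref_noise_sds is None:
        ref_noise_sds = [0.02 * j for j in range(n_refs)]
    if len(ref_noise_sds) != n_refs:
        raise ValueError("need one noise SD per reference assay")

    targets = list(de.index[:n_targets])
    refs = [f"REF{j + 1}" for j in range(n_refs)]
    animals = [f"A{i:03d}" for i in range(min(n_animals, cfg.n_animals_per_muscle))]
    samples = [(f"{a}_{m}", m) for a in animals for m in MUSCLES]
    loading = rng.normal(0, loading_sd, size=len(samples))

    rows = []
    ln_e = np.log(efficiency)
    lnq: dict[str, np.ndarray] = {}
    for gene in targets:
        half = 0.5 * np.log(truth.genes.loc[gene, "fc"])
        s = 1.0 if truth.genes.loc[gene, "direction"] == "LM" else -1.0
        msign = np.array([1.0 if m == "LM" else -1.0 for _, m in samples])
        lnq[gene] = s * half * msign + loading + rng.normal(0, noise_sd, len(samples))
    for j, ref in enumerate(refs):
        lnq[ref] = loading + rng.normal(0, ref_noise_sds[j], len(samples))

    for assay, role in [(t, "target") for t in targets] + [(r, "ref") for r in refs]:
        q = np.exp(lnq[assay])
        ct = 25.0 - lnq[assay] / ln_e
        ct_cal = 25.0 - np.log(q.mean()) / ln_e  # pooled calibrator
        for (sid, muscle), c in zip(samples, ct):
            for rep in range(1, n_replicates + 1):
                rows.append({"sample_id": sid, "muscle": muscle, "assay": assay,
                             "role": role, "replicate": rep, "ct": float(c),
                             "efficiency": efficiency})
        for rep in range(1, n_replicates + 1):
            rows.append({"sample_id": "calibrator", "muscle": "pool",
                         "assay": assay, "role": role, "replicate": rep,
                         "ct": float(ct_cal), "efficiency": efficiency})
    return pd.DataFrame(rows)


def write_run_manifest(cfg: SimulationConfig, path: str | Path, **extra) -> None:
    payload = dataclasses.asdict(cfg)
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
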