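"""Plain-text (TSV) readers and writers for all pipeline tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .qc import ExpressionMatrix


def write_expression(m: ExpressionMatrix, expr_path, flags_path=None) -> None:
    df = m.values.copy()
    df.index.name = "probe_id"
    df.to_csv(expr_path, sep="\t")
    if flags_path is not None:
        fl = m.flags.astype(int)
        fl.index.name = "probe_id"
        fl.to_csv(flags_path, sep="\t")


def read_expression(expr_path, flags_path=None, scale: str = "raw") -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    flags = None
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t", index_col=0).astype(bool)
    return ExpressionMatrix(values, flags, scale=scale)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_similarity(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns.name = None
    return df


def read_gene_sets(path) -> dict[str, set[str]]:
    """Gene-set TSV: set_id <tab> name <tab> member gene ids (remaining columns)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gene_sets(sets: dict[str, set[str]], path,
                    names: dict[str, str] | None = None) -> None:
    names = names or {}
    with open(path, "w") as fh:
        for sid in sorted(sets):
            members = "\t".join(sorted(sets[sid]))
            fh.write(f"{sid}\t{names.get(sid, sid)}\t{members}\n")


def validate_inputs(expr: pd.DataFrame, meta: pd.DataFrame,
                    probe_map: pd.DataFrame | None = None,
                    annotations: pd.DataFrame | None = None) -> list[str]:
    """Cross-reference ids between tables; returns a list of findings.

    Entries prefixed ``ERROR`` are fatal (duplicated probes, samples
    without metadata); ``WARN`` entries are informational (orphan ids).
    """
    findings: list[str] = []
    if expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique()[:5]
        findings.append(f"ERROR duplicated probe ids: {list(dupes)}")
    meta_ids = set(meta["sample_id"]) if "sample_id" in meta.columns else set(meta.index)
    missing = [s for s in expr.columns if s not in meta_ids]
    if missing:
        findings.append(f"ERROR samples without metadata: {missing[:5]}")
    if probe_map is not None:
        unmapped = set(expr.index) - set(probe_map["probe_id"])
        if unmapped:
            findings.append(f"WARN {len(unmapped)} probes without gene mapping")
        orphans = set(probe_map["probe_id"]) - set(expr.index)
        if orphans:
            findings.append(f"WARN {len(orphans)} mapped probes absent from matrix")
        if annotations is not None:
            known = set(probe_map["gene_id"])
            ghost = set(annotations["gene_id"]) - known
            if ghost:
                findings.append(f"WARN {len(ghost)} annotated genes absent from probe map")
    return findings
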