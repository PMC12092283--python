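"""Readers and writers for the plain-text interchange formats.

Expression: TSV with genes as rows, first column ``gene_id``, remaining
columns one per sample.  Metadata: TSV with sample_id, patient_id, arm,
visit, pct_cortex.  Gene sets: GMT (name, description, then genes,
tab-separated).  Injury marker tables: TSV with gene, cell_state,
state_class.  Ground truth and run manifests: JSON.  Configs: YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .containers import CellProfilePanel, ExpressionMatrix, GeneSet, GeneSetLibrary, ScoreTable, validate_meta


def read_expression(expr_path, meta_path) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.index.name = "gene_id"
    meta = read_metadata(meta_path)
    return ExpressionMatrix(values, meta)


def write_expression(em: ExpressionMatrix, expr_path, meta_path) -> None:
    em.values.rename_axis("gene_id").to_csv(expr_path, sep="\t", float_format="%.17g")
    write_metadata(em.meta, meta_path)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str}).set_index("sample_id")
    return validate_meta(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path) -> GeneSetLibrary:
    lib = GeneSetLibrary()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        lib.add(GeneSet(name=name, genes=genes, provenance=desc))
    return lib


def write_gmt(lib: GeneSetLibrary, path) -> None:
    lines = []
    for s in lib:
        desc = s.provenance.replace("\t", " ").replace("\n", " ") or "na"
        lines.append("\t".join([s.name, desc, *s.genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cell_profiles(path) -> CellProfilePanel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CellProfilePanel(df)


def write_cell_profiles(panel: CellProfilePanel, path) -> None:
    panel.profiles.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.17g")


def read_marker_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene", "cell_state", "state_class"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    if df.duplicated(subset=["gene", "cell_state"]).any():
        raise ValueError("duplicate (gene, cell_state) rows in marker table")
    return df


def write_marker_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_score_table(path, meta_path) -> ScoreTable:
    scores = pd.read_csv(path, sep="\t", index_col=0)
    meta = read_metadata(meta_path)
    return ScoreTable(scores, meta)


def write_score_table(table: ScoreTable, path) -> None:
    out = table.meta.join(table.scores)
    out.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.17g")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def write_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
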