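"""Reading and writing the pipeline's plain-text formats.

Expression matrices are genes x samples TSV with a YAML sidecar recording the
centering flag and batch map; gene sets are GMT; regulatory tables are the
TRRUST dialect (TF, target, mode, reference); everything else is headed TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .containers import (
    ACTIVATION,
    ExpressionMatrix,
    FractionTable,
    GeneSet,
    ProbeMatrix,
    RegulatoryNetwork,
)
from .errors import DataError, ParseError


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_expression(path, m: ExpressionMatrix) -> None:
    path = Path(path)
    m.values.to_csv(path, sep="\t", index_label="gene")
    meta = {
        "centered": bool(m.centered),
        "batch": None if m.batch is None else {str(k): str(v) for k, v in m.batch.items()},
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def read_expression(path) -> ExpressionMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    centered, batch = False, None
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        centered = bool(meta.get("centered", False))
        if meta.get("batch"):
            batch = pd.Series(meta["batch"])
    return ExpressionMatrix(values, centered=centered, batch=batch)


def read_probe_matrix(values_path, map_path) -> ProbeMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    mapping = pd.read_csv(map_path, sep="\t", header=None, names=["probe", "gene"])
    return ProbeMatrix(values, dict(zip(mapping["probe"], mapping["gene"])))


def read_gmt(path) -> dict[str, GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT rows need name, description, genes")
            name = fields[0]
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ParseError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets[name] = GeneSet(name, members)
    if not sets:
        raise DataError(f"{path}: no gene sets found")
    return sets


def write_gmt(path, gene_sets: list[GeneSet], description: str = "") -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.members)]) + "\n")


def write_trrust(path, net: RegulatoryNetwork) -> None:
    df = net.edges.copy()
    df["mode"] = df["mode"].map({ACTIVATION: "Activation", -1: "Repression"})
    df["reference"] = "synthetic"
    df.to_csv(path, sep="\t", header=False, index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("os_event", "rfs_event"):
        if col in df.columns and not set(df[col].dropna().unique()).issubset({0, 1}):
            raise DataError(f"{path}: {col} must be 0/1")
    return df


def write_clinical(path, clinical: pd.DataFrame) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample")


def read_fractions(values_path, lineage_path=None) -> FractionTable:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    if lineage_path is not None:
        lin = pd.read_csv(
            lineage_path, sep="\t", header=None, names=["cell_type", "lineage"]
        )
        lineage = pd.Series(lin["lineage"].values, index=lin["cell_type"])
    else:
        lineage = pd.Series("other", index=values.columns)
    return FractionTable(values, lineage=lineage)


def write_fractions(path, fractions: FractionTable, lineage_path=None) -> None:
    fractions.values.to_csv(path, sep="\t", index_label="sample")
    if lineage_path is not None:
        fractions.lineage.to_csv(lineage_path, sep="\t", header=False)


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_labels(path, labels: pd.DataFrame) -> None:
    labels.to_csv(path, sep="\t", index_label="sample")
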