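"""File-format adapters: expression TSV/CSV, metadata CSV, GMT, GraphML.

Gene identifiers are opaque strings throughout. All writers are
deterministic (sorted keys, fixed float formatting left to pandas) so
re-running a stage with identical inputs reproduces identical bytes.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import RegionExpression, ValidationError


class ParseError(ValidationError):
    """Malformed input file; the message carries the offending line number."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples table; first column gene id, header sample ids."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index.name = None
    dup = np.flatnonzero(df.index.duplicated())
    if dup.size:
        raise ParseError(f"{path}: duplicate gene id at line {int(dup[0]) + 2}")
    if df.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate sample id in header")
    try:
        df = df.astype(float)
    except ValueError as err:
        raise ParseError(f"{path}: non-numeric expression value ({err})") from err
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata CSV indexed by sample id."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicate sample id in metadata")
    for col in ("individual_id", "CERAD"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}'")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_region(expr_path: str | Path, meta_path: str | Path, region_id: str) -> RegionExpression:
    expr = read_expression(expr_path)
    meta = read_metadata(meta_path)
    meta = meta.loc[[s for s in expr.columns if s in meta.index]]
    return RegionExpression(region_id=region_id, expr=expr, sample_meta=meta)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: set name, description ('na' accepted), then gene ids."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name '{name}'")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sets[name]]) + "\n")


def read_biotypes(path: str | Path) -> dict[str, str]:
    """Two-column gene -> biotype TSV (no header required)."""
    path = Path(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            out[fields[0]] = fields[1]
    return out


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def extract_biotypes_from_gtf(path: str | Path) -> dict[str, str]:
    """Minimal GENCODE-attribute extractor: gene id -> gene biotype.

    Reads only ``gene`` feature lines of a GTF and pulls ``gene_id`` and
    ``gene_type`` (falling back to ``gene_biotype``) from the attribute
    column. Full GTF parsing is intentionally out of scope.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            gene_id = attrs.get("gene_id")
            biotype = attrs.get("gene_type") or attrs.get("gene_biotype")
            if gene_id and biotype:
                out[gene_id] = biotype
    return out


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
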