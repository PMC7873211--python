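"""File I/O for outcome tables, count matrices, group maps, GMT gene
sets, and Mapper graphs.

All tabular output is TSV with a single header row and floats at 10
significant digits; every file written here is re-parseable by the
matching reader in this module.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OutcomeMatrix
from .mapper import MapperGraph

logger = logging.getLogger(__name__)

NA_TOKENS = ("", "NA", "NaN", "nan")
FLOAT_FMT = "%.10g"
DEFAULT_METADATA_COLUMNS = ("arm", "dose", "severity")


def read_outcome_table(path, metadata_columns=DEFAULT_METADATA_COLUMNS,
                       id_column: str | None = None) -> OutcomeMatrix:
    """Read a subjects-by-outcomes CSV/TSV.

    The first column (or ``id_column``) holds subject ids; columns named
    in ``metadata_columns`` are split off as metadata; every remaining
    column must be numeric, with empty cells or "NA" marking missing
    values.  Duplicate subject ids and non-numeric outcome cells are
    errors naming the offending row/column.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    idc = id_column or raw.columns[0]
    if idc not in raw.columns:
        raise ValueError(f"id column {idc!r} not in file")
    ids = raw[idc]
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate subject ids: {dups}")
    raw = raw.set_index(idc)
    meta_cols = [c for c in metadata_columns if c in raw.columns]
    metadata = raw[meta_cols].copy()
    if "dose" in metadata.columns:
        metadata["dose"] = pd.to_numeric(metadata["dose"], errors="coerce")
    if "severity" in metadata.columns:
        metadata["severity"] = pd.to_numeric(metadata["severity"], errors="coerce")
    outcome_cols = [c for c in raw.columns if c not in meta_cols]
    data = {}
    for col in outcome_cols:
        vals = []
        for rid, cell in raw[col].items():
            cell = cell.strip()
            if cell in NA_TOKENS:
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} in outcome column {col!r}, row {rid!r}"
                ) from None
        data[col] = vals
    outcomes = pd.DataFrame(data, index=raw.index)
    logger.info("read %d subjects, %d outcomes, %d metadata columns",
                outcomes.shape[0], outcomes.shape[1], len(meta_cols))
    return OutcomeMatrix(outcomes=outcomes, metadata=metadata)


def write_outcome_table(om: OutcomeMatrix, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.concat([om.metadata, om.outcomes], axis=1)
    df.index.name = "subject_id"
    df.to_csv(path, sep=sep, float_format=FLOAT_FMT, na_rep="NA")


def read_counts(path) -> pd.DataFrame:
    """Genes-by-samples TSV of non-negative integer counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate gene ids")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or (arr < 0).any():
        raise ValueError("counts must be non-negative numbers")
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.index.name = counts.index.name or "gene"
    counts.to_csv(path, sep="\t")


def read_groups(path, counts: pd.DataFrame | None = None) -> pd.Series:
    """Two-column sample->group TSV; order-independent.

    When ``counts`` is given, sample ids must match its columns exactly;
    mismatches are reported by name.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("groups file needs two columns: sample, group")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    if s.index.has_duplicates:
        raise ValueError("duplicate sample ids in groups file")
    if counts is not None:
        missing = sorted(set(counts.columns) - set(s.index))
        extra = sorted(set(s.index) - set(counts.columns))
        if missing or extra:
            raise ValueError(
                f"sample mismatch between counts and groups; "
                f"missing from groups: {missing}; not in counts: {extra}"
            )
        s = s.reindex(counts.columns)
    return s


def write_groups(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path, universe=None) -> dict:
    """Standard GMT: set name, description, then tab-separated gene ids.

    When ``universe`` is given, sets are intersected with it and sets
    left empty are dropped with a warning.
    """
    sets = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {line_no}")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if universe is not None:
                genes = [g for g in genes if g in universe]
                if not genes:
                    logger.warning("GMT set %r empty after filtering; dropped", name)
                    continue
            sets[name] = set(genes)
    return sets


def write_graph(graph: MapperGraph, base_path) -> tuple[Path, Path]:
    """Write a Mapper graph as GraphML (node size + overlays, edge
    shared-member counts) and as JSON with full member lists."""
    import networkx as nx

    base = Path(base_path)
    g = nx.Graph()
    for n in graph.nodes:
        attrs = {"size": len(n["members"]),
                 "members": ";".join(n["members"]),
                 "bin": "_".join(map(str, n["bin"]))}
        for var, vals in graph.overlays.items():
            attrs[f"overlay_{var}"] = float(vals[n["id"]])
        g.add_node(n["id"], **attrs)
    for e in graph.edges:
        g.add_edge(e["source"], e["target"], shared=int(e["shared"]))
    graphml = base.with_suffix(".graphml")
    nx.write_graphml(g, graphml)
    payload = {
        "nodes": [
            {
                "id": n["id"],
                "members": list(n["members"]),
                "bin": list(n["bin"]),
            }
            for n in graph.nodes
        ],
        "edges": [
            {"source": e["source"], "target": e["target"], "shared": int(e["shared"])}
            for e in graph.edges
        ],
        "overlays": {
            var: {k: float(v) for k, v in vals.items()}
            for var, vals in graph.overlays.items()
        },
    }
    jsonp = base.with_suffix(".json")
    jsonp.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return graphml, jsonp


def read_graph_json(path) -> MapperGraph:
    payload = json.loads(Path(path).read_text())
    nodes = [
        {"id": n["id"], "members": list(n["members"]), "bin": tuple(n["bin"])}
        for n in payload["nodes"]
    ]
    return MapperGraph(nodes=nodes, edges=list(payload["edges"]),
                       overlays=payload.get("overlays", {}))


def read_intensity_image(path) -> np.ndarray:
    """Grayscale PNG/TIFF as a float intensity matrix (for
    immunoreactive-area quantification)."""
    from PIL import Image

    with Image.open(path) as img:
        return np.asarray(img.convert("F"), dtype=float)


def write_table(df: pd.DataFrame, path, index_name: str | None = None) -> None:
    df = df.copy()
    if index_name:
        df.index.name = index_name
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, na_rep="NA")
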