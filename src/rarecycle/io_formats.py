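"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* OTU tables: TSV (canonical interchange; OTU rows x sample columns with an
  optional trailing ``taxonomy`` column) and BIOM 2.1 HDF5 (read-only, via a
  minimal h5py reader since the format is a fixed HDF5 layout).
* Nutrient tables: CSV with a documented alias list for header names.
* Co-occurrence networks: GraphML, GEXF and a plain edge-list TSV (with a
  companion ``*.nodes.tsv`` so module ids survive the round trip).

All readers validate invariants on entry and all write/read pairs are
round-trip stable.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .tables import (
    MNC_VARIABLES,
    NUTRIENT_VARIABLES,
    NutrientTable,
    OTUTable,
    TableFormatError,
)

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_nutrient_table",
    "write_nutrient_table",
    "read_biom",
    "write_network",
    "read_network",
]


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

def _resolve_crop(sample_ids, crop) -> pd.Series:
    if crop is None:
        return pd.Series("unknown", index=sample_ids)
    if isinstance(crop, pd.Series):
        return crop.reindex(sample_ids)
    return pd.Series({s: crop.get(s) for s in sample_ids})


def read_otu_table(path, format: str = "tsv", crop=None) -> OTUTable:
    """Read an OTU count table and return the validated samples x OTUs form.

    Parameters
    ----------
    path
        Input file.
    format
        ``"tsv"`` (OTU-by-sample matrix, header row of sample ids, first
        column OTU ids, optional trailing ``taxonomy`` column) or ``"biom"``
        (BIOM 2.1 HDF5).
    crop
        Optional mapping/Series sample id -> crop label. When given, it also
        disambiguates orientation: the axis whose labels match the mapping is
        taken as the sample axis. Without it samples default to ``"unknown"``.
    """
    if format == "biom":
        return read_biom(path, crop=crop)
    if format != "tsv":
        raise ValueError(f"unknown OTU table format: {format!r}")

    df = pd.read_csv(path, sep="\t", header=0, index_col=0, comment=None)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    taxonomy = None
    tax_cols = [c for c in df.columns if c.lower() == "taxonomy"]
    if tax_cols:
        taxonomy = df[tax_cols[0]].astype(str)
        df = df.drop(columns=tax_cols)
    else:
        warnings.warn("no taxonomy column found; OTUs set to 'unclassified'")

    # Canonical TSV orientation is OTU rows x sample columns; transpose to
    # samples x OTUs. If a crop mapping identifies the other axis as samples,
    # flip instead.
    counts = df.T
    if crop is not None:
        keys = set(crop.index) if isinstance(crop, pd.Series) else set(crop)
        row_hits = len(keys & set(df.index))
        col_hits = len(keys & set(df.columns))
        if row_hits > col_hits:
            if taxonomy is not None:
                raise TableFormatError(
                    "taxonomy column present but rows match sample metadata"
                )
            counts = df

    try:
        counts = counts.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"non-numeric counts in {path}: {exc}") from exc

    return OTUTable(
        counts=counts,
        crop=_resolve_crop(counts.index, crop),
        taxonomy=taxonomy,
    )


def write_otu_table(table: OTUTable, path) -> Path:
    """Write the canonical OTU TSV (OTU rows, sample columns, taxonomy last)."""
    path = Path(path)
    out = table.counts.T.copy()
    out.insert(len(out.columns), "taxonomy", table.taxonomy)
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")
    return path


def read_biom(path, crop=None) -> OTUTable:
    """Read a BIOM 2.1 HDF5 table (observation-major CSR layout)."""
    import h5py

    with h5py.File(path, "r") as f:
        obs_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["sample/ids"][:]]
        data = f["observation/matrix/data"][:]
        indices = f["observation/matrix/indices"][:]
        indptr = f["observation/matrix/indptr"][:]
        matrix = np.zeros((len(obs_ids), len(sample_ids)))
        for i in range(len(obs_ids)):
            cols = indices[indptr[i]:indptr[i + 1]]
            matrix[i, cols] = data[indptr[i]:indptr[i + 1]]
        taxonomy = None
        if "observation/metadata/taxonomy" in f:
            raw = f["observation/metadata/taxonomy"][:]
            lineage = []
            for row in raw:
                if isinstance(row, bytes):
                    lineage.append(row.decode())
                else:
                    lineage.append(";".join(x.decode() if isinstance(x, bytes) else str(x) for x in np.atleast_1d(row)))
            taxonomy = pd.Series(lineage, index=obs_ids)
        else:
            warnings.warn("BIOM file has no taxonomy metadata; using 'unclassified'")

    counts = pd.DataFrame(matrix.T, index=sample_ids, columns=obs_ids)
    return OTUTable(counts=counts, crop=_resolve_crop(sample_ids, crop), taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# Nutrient tables
# ---------------------------------------------------------------------------

def _normalize_header(name: str) -> str:
    """Collapse a header to a comparable token: drop units, signs, case."""
    name = re.sub(r"\(.*?\)", "", name)           # strip unit parentheticals
    name = re.sub(r"[\s\.\-_+‰%]|−", "", name)    # strip separators and signs
    return name.lower()


#: Documented alias tokens (normalized) for each canonical column.
_NUTRIENT_ALIASES = {
    "ph": "pH", "salt": "salt", "salinity": "salt", "ec": "salt",
    "bd": "BD", "bulkdensity": "BD", "swc": "SWC", "soilwatercontent": "SWC",
    "nh4n": "NH4_N", "ammoniumn": "NH4_N", "no3n": "NO3_N", "nitraten": "NO3_N",
    "olsenp": "Olsen_P", "availp": "Olsen_P", "availk": "Avail_K",
    "availablek": "Avail_K", "an": "AN", "availablen": "AN",
    "tp": "TP", "tk": "TK", "tn": "TN", "soc": "SOC",
}


def read_nutrient_table(path) -> NutrientTable:
    """Read a per-sample nutrient CSV into the canonical 13-variable table.

    The first column is the sample id; a ``crop`` column is required; the
    remaining headers are matched case-insensitively through the alias list
    (e.g. ``"NO3--N (mg kg-1)"`` -> ``NO3_N``).
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)

    crop = None
    rename = {}
    for col in df.columns:
        token = _normalize_header(str(col))
        if token == "crop":
            crop = df[col].astype(str)
            continue
        if token in _NUTRIENT_ALIASES:
            rename[col] = _NUTRIENT_ALIASES[token]
    data = df[list(rename)].rename(columns=rename)

    for var in MNC_VARIABLES:
        if var not in data.columns:
            raise TableFormatError(f"missing MNC variable {var}")
    if crop is None:
        raise TableFormatError("nutrient CSV must contain a 'crop' column")
    return NutrientTable(data=data, crop=crop)


def write_nutrient_table(table: NutrientTable, path) -> Path:
    path = Path(path)
    out = table.data.copy()
    out.insert(0, "crop", table.crop)
    out.index.name = "sample_id"
    out.to_csv(path)
    return path


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def _network_to_igraph(net) -> ig.Graph:
    from .network import CooccurrenceNetwork  # local import, avoids cycle

    assert isinstance(net, CooccurrenceNetwork)
    g = ig.Graph()
    g.add_vertices(len(net.nodes))
    g.vs["name"] = list(net.nodes)
    g.vs["module"] = [int(net.modules.get(n, -1)) for n in net.nodes]
    degree = net.degree()
    g.vs["degree"] = [int(degree[n]) for n in net.nodes]
    index = {n: i for i, n in enumerate(net.nodes)}
    g.add_edges([(index[a], index[b]) for a, b, _, _ in net.edges])
    g.es["r"] = [float(r) for _, _, r, _ in net.edges]
    g.es["p"] = [float(p) for _, _, _, p in net.edges]
    g.es["weight"] = [abs(float(r)) for _, _, r, _ in net.edges]
    return g


def write_network(net, path, format: str = "graphml") -> Path:
    """Export a co-occurrence network to a Gephi-readable file.

    Nodes carry OTU id, module id and degree; edges carry the signed
    correlation ``r``, its ``p`` value and ``weight = |r|``.
    """
    path = Path(path)
    if format == "graphml":
        _network_to_igraph(net).write_graphml(str(path))
    elif format == "gexf":
        nx.write_gexf(_to_networkx(net), str(path))
    elif format == "edge_tsv":
        edges = pd.DataFrame(net.edges, columns=["otu_a", "otu_b", "r", "p"])
        edges.to_csv(path, sep="\t", index=False)
        degree = net.degree()
        nodes = pd.DataFrame(
            {
                "otu_id": list(net.nodes),
                "module": [int(net.modules.get(n, -1)) for n in net.nodes],
                "degree": [int(degree[n]) for n in net.nodes],
            }
        )
        nodes.to_csv(path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format: {format!r}")
    return path


def _to_networkx(net) -> nx.Graph:
    g = nx.Graph()
    degree = net.degree()
    for n in net.nodes:
        g.add_node(str(n), module=int(net.modules.get(n, -1)), degree=int(degree[n]))
    for a, b, r, p in net.edges:
        g.add_edge(str(a), str(b), r=float(r), p=float(p), weight=abs(float(r)))
    return g


def read_network(path, format: str = "graphml"):
    """Re-import a network written by :func:`write_network`."""
    from .network import CooccurrenceNetwork

    path = Path(path)
    if format == "graphml":
        g = ig.Graph.Read_GraphML(str(path))
        nodes = [str(v["name"]) for v in g.vs]
        modules = {str(v["name"]): int(v["module"]) for v in g.vs}
        edges = [
            (nodes[e.source], nodes[e.target], float(e["r"]), float(e["p"]))
            for e in g.es
        ]
    elif format == "gexf":
        g = nx.read_gexf(str(path))
        nodes = list(g.nodes)
        modules = {n: int(g.nodes[n].get("module", -1)) for n in nodes}
        edges = [(a, b, float(d["r"]), float(d["p"])) for a, b, d in g.edges(data=True)]
    elif format == "edge_tsv":
        edges_df = pd.read_csv(path, sep="\t")
        nodes_df = pd.read_csv(path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t")
        nodes = [str(n) for n in nodes_df["otu_id"]]
        modules = dict(zip(nodes, nodes_df["module"].astype(int)))
        edges = [
            (str(a), str(b), float(r), float(p))
            for a, b, r, p in edges_df.itertuples(index=False)
        ]
    else:
        raise ValueError(f"unknown network format: {format!r}")

    return CooccurrenceNetwork.from_edges(nodes=nodes, edges=edges, modules=modules)
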