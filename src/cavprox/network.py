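"""Interactome network assembly and over-representation testing.

Protein–protein edges are consumed from file exports only (BioGRID
tab-separated, STRING link export, or a two-column literature list);
there are no live database queries. Evidence filters follow the
published interactome construction: BioGRID edges whose experimental
system is a non-physical method (Affinity Capture-RNA, Protein-RNA,
Proximity Label-MS) are discarded, and STRING edges require a combined
confidence strictly above 0.4.

Over-representation of user-supplied gene sets (GMT) in a query list
is scored with the hypergeometric upper tail P(X >= k) against a
stated universe, BH-adjusted across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .diffenrich import bh_adjust
from .proteomics import InputError

SOURCES = ("biogrid", "string", "literature")

DEFAULT_EXCLUDED_METHODS = frozenset(
    {"Affinity Capture-RNA", "Protein-RNA", "Proximity Label-MS"}
)
DEFAULT_MIN_CONFIDENCE = 0.4

EDGE_COLUMNS = ["protein_a", "protein_b", "source", "evidence_method", "confidence"]


def _normalise(x: str) -> str:
    return str(x).strip().upper()


def _canonical_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Uppercase ids, order endpoints, drop self-loops and duplicates."""
    a = df["protein_a"].map(_normalise)
    b = df["protein_b"].map(_normalise)
    lo, hi = a.where(a <= b, b), b.where(a <= b, a)
    out = df.assign(protein_a=lo, protein_b=hi)
    out = out[out["protein_a"] != out["protein_b"]]
    return out.drop_duplicates(subset=["protein_a", "protein_b"]).reset_index(drop=True)


def load_edge_table(path: str | Path, source: str) -> pd.DataFrame:
    """Load a protein–protein edge table in one of three dialects.

    ``source``: "biogrid" (columns "Official Symbol Interactor A/B",
    "Experimental System"), "string" (protein1, protein2,
    combined_score on the 0–1000 scale), or "literature" (first two
    tab-separated columns are the interactors).

    Returns a canonical undirected edge frame with columns
    protein_a, protein_b, source, evidence_method, confidence.
    """
    if source not in SOURCES:
        raise InputError(f"unknown edge source {source!r}; expected one of {SOURCES}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if source == "biogrid":
        try:
            out = pd.DataFrame(
                {
                    "protein_a": df["Official Symbol Interactor A"],
                    "protein_b": df["Official Symbol Interactor B"],
                    "evidence_method": df["Experimental System"],
                }
            )
        except KeyError as exc:
            raise InputError(f"not a BioGRID export: missing column {exc}")
        out["confidence"] = float("nan")
    elif source == "string":
        try:
            out = pd.DataFrame(
                {
                    "protein_a": df["protein1"],
                    "protein_b": df["protein2"],
                    "confidence": pd.to_numeric(df["combined_score"]) / 1000.0,
                }
            )
        except KeyError as exc:
            raise InputError(f"not a STRING export: missing column {exc}")
        out["evidence_method"] = "string_combined"
    else:
        if df.shape[1] < 2:
            raise InputError("literature list needs two columns")
        out = pd.DataFrame(
            {
                "protein_a": df.iloc[:, 0],
                "protein_b": df.iloc[:, 1],
                "evidence_method": "literature",
                "confidence": float("nan"),
            }
        )
    out["source"] = source
    return _canonical_pairs(out)[EDGE_COLUMNS]


@dataclass(frozen=True)
class EdgeFilterRules:
    excluded_methods: frozenset[str] = DEFAULT_EXCLUDED_METHODS
    min_confidence: float = DEFAULT_MIN_CONFIDENCE  # strict: keep > this


def filter_edges(
    edges: pd.DataFrame, rules: EdgeFilterRules = EdgeFilterRules()
) -> pd.DataFrame:
    """Apply per-source evidence filters; never adds edges, idempotent.

    BioGRID: rows whose evidence_method is excluded are dropped.
    STRING: rows with confidence <= min_confidence are dropped.
    Literature edges always pass.
    """
    keep = pd.Series(True, index=edges.index)
    is_biogrid = edges["source"] == "biogrid"
    keep &= ~(is_biogrid & edges["evidence_method"].isin(rules.excluded_methods))
    is_string = edges["source"] == "string"
    keep &= ~(is_string & ~(edges["confidence"] > rules.min_confidence))
    return edges[keep].reset_index(drop=True)


def build_network(
    node_set: Iterable[str],
    *edge_tables: pd.DataFrame,
    node_attributes: Mapping[str, Mapping[str, object]] | None = None,
) -> nx.Graph:
    """Restrict pooled edges to a node set and merge multi-source edges.

    Nodes are the (normalised) node_set — e.g. the co-recovered
    proteins; edges require both endpoints inside it. The same pair
    reported by several sources becomes one edge whose ``sources``
    attribute is the provenance union; ``style`` is "solid" if any
    database source supports it and "dotted" for literature-only
    edges. ``node_attributes`` (e.g. interactome category per protein)
    are attached to nodes.
    """
    nodes = sorted({_normalise(n) for n in node_set})
    if not nodes:
        raise InputError("node_set is empty")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for table in edge_tables:
        for _, row in _canonical_pairs(table).iterrows():
            a, b = row["protein_a"], row["protein_b"]
            if a not in g or b not in g:
                continue
            if g.has_edge(a, b):
                g[a][b]["sources"] = sorted(
                    set(g[a][b]["sources"]) | {row["source"]}
                )
            else:
                g.add_edge(a, b, sources=[row["source"]])
    for a, b, data in g.edges(data=True):
        data["style"] = (
            "solid" if set(data["sources"]) & {"biogrid", "string"} else "dotted"
        )
    if node_attributes:
        for node, attrs in node_attributes.items():
            key = _normalise(node)
            if key in g:
                g.nodes[key].update(attrs)
    return g


def write_network(g: nx.Graph, graphml_path: str | Path, tsv_path: str | Path) -> None:
    """Export as GraphML plus an edge-list TSV with provenance."""
    g_out = g.copy()
    for _, _, data in g_out.edges(data=True):
        data["sources"] = ",".join(data["sources"])
    nx.write_graphml(g_out, graphml_path)
    rows = [
        {
            "protein_a": a,
            "protein_b": b,
            "sources": data["sources"],
            "style": data["style"],
        }
        for a, b, data in g_out.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "sources", "style"]).to_csv(
        tsv_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene sets and over-representation


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file: set_id -> (description, unique member list)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InputError(f"malformed GMT line: {line[:60]!r}")
        set_id, desc, *members = parts
        seen: list[str] = []
        for m in members:
            mn = _normalise(m)
            if mn and mn not in seen:
                seen.append(mn)
        sets[set_id] = (desc, seen)
    return sets


def overrepresentation_test(
    query: Iterable[str],
    gene_sets: Mapping[str, tuple[str, Sequence[str]]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in the query.

    With universe size N, set size K (after intersecting the set with
    the universe), query size n and overlap k, the p-value is the
    upper tail P(X >= k) of Hypergeometric(N, K, n); q is the BH
    adjustment across sets. The query must be a subset of the
    universe — the natural universe is the detected proteome (all
    proteins surviving the replicate-presence filter), which avoids
    abundance bias relative to a whole-genome background.
    """
    uni = {_normalise(u) for u in universe}
    q = {_normalise(x) for x in query}
    stray = q - uni
    if stray:
        raise InputError(f"query proteins outside the universe: {sorted(stray)[:5]}")
    n, N = len(q), len(uni)
    rows = []
    for set_id, (name, members) in gene_sets.items():
        mem = {_normalise(m) for m in members} & uni
        K = len(mem)
        k = len(mem & q)
        # P(X >= k); survival function is P(X > k-1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set_id": set_id,
                "name": name,
                "overlap_k": k,
                "set_size_K": K,
                "query_size_n": n,
                "universe_size_N": N,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_id",
            "name",
            "overlap_k",
            "set_size_K",
            "query_size_n",
            "universe_size_N",
            "p",
        ],
    )
    out["q"] = bh_adjust(out["p"]) if len(out) else out["p"]
    return out
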