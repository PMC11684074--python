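"""Edge-table ingestion and network assembly.

Protein-protein interaction (PPI) networks are handled as simple undirected
:class:`networkx.Graph` objects over gene-symbol nodes.  Per-edge interaction
confidences (probabilities in ``[0, 1]``) are stored in the ``confidence``
edge attribute; they are used only for thresholding, ranking and reporting —
all downstream computation treats the graph as binary and unweighted.

Node identity is an exact, case-sensitive gene-symbol string match.  Symbol
harmonization (aliases, capitalisation, species mapping) is the caller's job.

Two edge-table dialects are read:

``generic``
    Tab-separated with a header ``node_a<TAB>node_b[<TAB>score]``; scores in
    ``[0, 1]``, defaulting to 1.0 when the column is absent.
``string_links``
    The STRING *protein links* export: whitespace-separated columns
    ``protein1 protein2 combined_score`` with integer scores in 0-1000,
    rescaled here to ``[0, 1]`` by division by 1000.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

DIALECTS = ("generic", "string_links")

__all__ = [
    "DIALECTS",
    "read_edge_table",
    "build_network",
    "merge_networks",
    "expand_network",
    "write_network",
    "read_network",
]


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    """Drop self-loops and duplicate undirected pairs, canonicalising order."""
    n0 = len(df)
    df = df[df["node_a"] != df["node_b"]].copy()
    n_loops = n0 - len(df)
    swap = df["node_a"] > df["node_b"]
    df.loc[swap, ["node_a", "node_b"]] = df.loc[swap, ["node_b", "node_a"]].values
    n1 = len(df)
    df = df.drop_duplicates(subset=["node_a", "node_b"], keep="first")
    n_dups = n1 - len(df)
    if n_loops or n_dups:
        logger.info("dropped %d self-loop row(s) and %d duplicate pair(s)", n_loops, n_dups)
    return df.reset_index(drop=True)


def read_edge_table(path: str | Path, dialect: str = "generic") -> pd.DataFrame:
    """Read an interaction edge table into a canonical DataFrame.

    Parameters
    ----------
    path
        TSV file (``generic``) or whitespace-separated STRING protein-links
        export (``string_links``).
    dialect
        One of :data:`DIALECTS`.

    Returns
    -------
    pandas.DataFrame
        Columns ``node_a, node_b, score`` with scores in ``[0, 1]``,
        self-loops and duplicate undirected pairs removed (counts logged).
        The dialect is recorded in ``df.attrs["dialect"]``.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "generic":
        raw = pd.read_csv(path, sep="\t", dtype=str)
        required = {"node_a", "node_b"}
        if not required.issubset(raw.columns):
            raise ValueError(
                f"{path}: generic dialect requires header columns node_a, node_b "
                f"(found {list(raw.columns)})"
            )
        if "score" in raw.columns:
            score = pd.to_numeric(raw["score"], errors="coerce")
        else:
            score = pd.Series(1.0, index=raw.index)
        score = score.astype(float)
        bad = score.isna() | (score < 0) | (score > 1) | raw["node_a"].isna() | raw["node_b"].isna()
        if bad.any():
            # +2: one for the header, one for 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{path}: malformed row at line {line}")
        df = pd.DataFrame(
            {"node_a": raw["node_a"], "node_b": raw["node_b"], "score": score}
        )
    else:  # string_links
        raw = pd.read_csv(path, sep=r"\s+", dtype=str)
        required = {"protein1", "protein2", "combined_score"}
        if not required.issubset(raw.columns):
            raise ValueError(
                f"{path}: string_links dialect requires columns protein1, protein2, "
                f"combined_score (found {list(raw.columns)})"
            )
        score = pd.to_numeric(raw["combined_score"], errors="coerce")
        bad = score.isna() | (score < 0) | (score > 1000) | raw["protein1"].isna() | raw["protein2"].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{path}: malformed row at line {line}")
        df = pd.DataFrame(
            {
                "node_a": raw["protein1"],
                "node_b": raw["protein2"],
                "score": score.astype(float) / 1000.0,
            }
        )
    df = _canonical(df)
    df.attrs["dialect"] = dialect
    return df


def build_network(edges: pd.DataFrame, min_score: float | None = 0.7) -> nx.Graph:
    """Assemble a simple undirected network from an edge table.

    Rows with ``score`` strictly greater than ``min_score`` are retained
    (matching the strict ``>0.7`` high-confidence convention for STRING
    scores); the node set is the union of retained endpoints.  Pass
    ``min_score=None`` to keep every row.
    """
    if min_score is not None and not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score must be in [0, 1], got {min_score}")
    net = nx.Graph()
    kept = edges if min_score is None else edges[edges["score"] > min_score]
    for a, b, s in kept[["node_a", "node_b", "score"]].itertuples(index=False):
        net.add_edge(a, b, confidence=float(s))
    if net.number_of_edges() == 0:
        logger.warning("no edges admitted at min_score=%s; empty network", min_score)
    return net


def merge_networks(base: nx.Graph, extra: pd.DataFrame, min_score: float = 0.7) -> nx.Graph:
    """Union of ``base`` with the thresholded edges of ``extra``.

    Existing edge confidences are preserved; incoming duplicates are ignored.
    The node set grows only by endpoints of admitted new edges.
    """
    net = base.copy()
    kept = extra[extra["score"] > min_score]
    added = 0
    for a, b, s in kept[["node_a", "node_b", "score"]].itertuples(index=False):
        if not net.has_edge(a, b):
            net.add_edge(a, b, confidence=float(s))
            added += 1
    logger.info("merge added %d edge(s)", added)
    return net


def expand_network(
    base: nx.Graph,
    pool: pd.DataFrame,
    n_add: int,
    min_score: float = 0.7,
) -> nx.Graph:
    """Grow ``base`` by ``n_add`` external nodes ranked by connectivity.

    One ranking pass per added node: every external node appearing in the
    (thresholded) ``pool`` is scored by (number of admitted edges into the
    current network, summed edge confidence, lexicographic symbol as the
    final deterministic tie-break) and the top node is admitted together
    with all its admitted edges.  Edges among newly admitted nodes are
    picked up on subsequent passes because each pass ranks against the
    *current* (already grown) network.
    """
    if n_add < 0:
        raise ValueError("n_add must be >= 0")
    net = base.copy()
    admitted = pool[pool["score"] > min_score][["node_a", "node_b", "score"]]
    for step in range(n_add):
        current = set(net.nodes)
        links: dict[str, int] = {}
        conf: dict[str, float] = {}
        for a, b, s in admitted.itertuples(index=False):
            for x, other in ((a, b), (b, a)):
                if x not in current and other in current:
                    links[x] = links.get(x, 0) + 1
                    conf[x] = conf.get(x, 0.0) + float(s)
        if not links:
            logger.warning(
                "pool exhausted after %d of %d addition(s); returning partial expansion",
                step,
                n_add,
            )
            break
        best = min(links, key=lambda x: (-links[x], -conf[x], x))
        for a, b, s in admitted.itertuples(index=False):
            if best in (a, b):
                other = b if a == best else a
                if other in current and not net.has_edge(a, b):
                    net.add_edge(a, b, confidence=float(s))
    return net


def write_network(net: nx.Graph, path: str | Path) -> None:
    """Write a network as a sorted generic edge TSV (deterministic bytes).

    Isolated nodes are not representable in an edge list and are dropped
    with a warning.
    """
    isolated = [n for n in net.nodes if net.degree(n) == 0]
    if isolated:
        logger.warning("%d isolated node(s) not written to edge list", len(isolated))
    rows = sorted(
        (min(a, b), max(a, b), float(d.get("confidence", 1.0)))
        for a, b, d in net.edges(data=True)
    )
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_network(path: str | Path) -> nx.Graph:
    """Read a network written by :func:`write_network` (all edges kept)."""
    return build_network(read_edge_table(path, "generic"), min_score=None)


def node_tags(net: nx.Graph, node: str) -> set:
    """The tag set of a node (empty if untagged)."""
    return net.nodes[node].get("tags", set())


def tagged_nodes(net: nx.Graph, tag: str) -> set:
    """All nodes carrying ``tag``."""
    return {n for n, d in net.nodes(data=True) if tag in d.get("tags", set())}
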