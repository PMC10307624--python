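"""Phosphoprotein interaction-network assembly and functional enrichment.

Proteins whose phosphorylation state changed (>= 1 site under the FDR
threshold in >= 1 timepoint) form the core node set; edges come from a
combined-score association table and are kept when the score strictly
exceeds the threshold (default 0.4). Up to ten functionally related
expansion nodes are added by summed above-threshold edge score. Functional
enrichment is an upper-tail hypergeometric test with BH correction,
followed by greedy redundancy pruning at Jaccard >= 0.5.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .quant import bh_adjust

EDGE_COLUMNS = ["protein_a", "protein_b", "score"]


def _validate_edges(edges: pd.DataFrame) -> pd.DataFrame:
    missing = set(EDGE_COLUMNS) - set(edges.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    scores = edges["score"].astype(float)
    if scores.isna().any() or (scores < 0).any() or (scores > 1).any():
        raise ValueError("edge scores must lie in [0, 1]")
    return edges.assign(score=scores)


def build_network(
    core_proteins: set[str] | list[str],
    edges: pd.DataFrame,
    threshold: float = 0.4,
) -> nx.Graph:
    """Induced network on the core proteins, keeping edges with score
    strictly greater than ``threshold``; isolated core proteins stay as
    nodes since they carry phosphorylation states. Self-loops are ignored;
    duplicate edges keep the highest score.
    """
    edges = _validate_edges(edges)
    g = nx.Graph()
    core = sorted(set(core_proteins))
    for p in core:
        g.add_node(p, core=True)
    core_set = set(core)
    for a, b, s in edges[EDGE_COLUMNS].itertuples(index=False):
        if a == b or a not in core_set or b not in core_set:
            continue
        if s > threshold and (not g.has_edge(a, b) or g[a][b]["score"] < s):
            g.add_edge(a, b, score=float(s))
    return g


def expand_network(
    network: nx.Graph,
    edges: pd.DataFrame,
    threshold: float = 0.4,
    max_added: int = 10,
) -> nx.Graph:
    """Add up to ``max_added`` functionally related non-core nodes.

    Candidates are ranked by the sum of their above-threshold edge scores
    to the current nodes; ties break lexicographically. Added nodes are
    flagged ``core=False``; existing nodes and edges are never removed.
    Qualifying edges among the enlarged node set are then attached.
    """
    edges = _validate_edges(edges)
    g = network.copy()
    current = set(g.nodes)
    strength: dict[str, float] = {}
    for a, b, s in edges[EDGE_COLUMNS].itertuples(index=False):
        if a == b or s <= threshold:
            continue
        if a in current and b not in current:
            strength[b] = strength.get(b, 0.0) + s
        elif b in current and a not in current:
            strength[a] = strength.get(a, 0.0) + s
    ranked = sorted(strength.items(), key=lambda kv: (-kv[1], kv[0]))
    added = [name for name, _ in ranked[:max_added]]
    for name in added:
        g.add_node(name, core=False)
    allowed = current | set(added)
    for a, b, s in edges[EDGE_COLUMNS].itertuples(index=False):
        if a == b or s <= threshold or a not in allowed or b not in allowed:
            continue
        if not g.has_edge(a, b) or g[a][b]["score"] < s:
            g.add_edge(a, b, score=float(s))
    return g


def hypergeom_enrichment(
    query: set[str],
    terms: dict[str, set[str]],
    universe: set[str],
    fdr_threshold: float | None = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` against ``terms``.

    p = P(X >= k) for X ~ Hypergeom(N=|universe|, K=|term ∩ universe|,
    n=|query|). Terms with zero overlap are skipped; BH correction runs
    across tested terms; rows are filtered at ``fdr_threshold`` (None
    disables filtering). The overlap gene set is kept for redundancy
    pruning.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError("query must be contained in the universe")
    N, n = len(universe), len(query)
    rows = []
    for term in sorted(terms):
        members = set(terms[term]) & universe
        overlap = members & query
        k, K = len(overlap), len(members)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "overlap": ";".join(sorted(overlap)),
            }
        )
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p", "overlap"])
    if out.empty:
        out["fdr"] = pd.Series(dtype=float)
        return out
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    if fdr_threshold is not None:
        out = out[out["fdr"] < fdr_threshold]
    return out.sort_values(["fdr", "p", "term"]).reset_index(drop=True)


def remove_redundant_terms(results: pd.DataFrame, cutoff: float = 0.5) -> pd.DataFrame:
    """Greedy redundancy pruning on enrichment results.

    Iterating by ascending FDR, a term is dropped when the Jaccard
    similarity of its overlap gene set with any already-kept term is >=
    ``cutoff``. Kept terms therefore have pairwise Jaccard < cutoff.
    """
    if results.empty:
        return results.copy()
    ordered = results.sort_values(["fdr", "p", "term"]).reset_index(drop=True)
    kept_sets: list[set[str]] = []
    keep_rows = []
    for _, row in ordered.iterrows():
        members = set(row["overlap"].split(";")) if row["overlap"] else set()
        redundant = False
        for prev in kept_sets:
            union = members | prev
            if union and len(members & prev) / len(union) >= cutoff:
                redundant = True
                break
        if not redundant:
            kept_sets.append(members)
            keep_rows.append(row)
    return pd.DataFrame(keep_rows).reset_index(drop=True)


def attach_phospho_states(
    network: nx.Graph,
    site_stats: pd.DataFrame,
    ligand: str,
    timepoints: list[str],
    alpha: float = 0.05,
) -> nx.Graph:
    """Annotate each node with one phosphorylation state per timepoint.

    The state is the signed log2FC of the node's significant site
    (adjusted p < alpha) with the largest \\|FC\\| at that timepoint, or
    None when no site qualifies — the per-timepoint ring display.
    """
    g = network.copy()
    df = site_stats[
        (site_stats["condition"] == ligand)
        & site_stats["adj_p"].notna()
        & (site_stats["adj_p"] < alpha)
        & np.isfinite(site_stats["log2fc"])
    ].copy()
    df["protein"] = df["site_key"].str.split("_").str[0]
    for node in g.nodes:
        states: dict[str, float | None] = {}
        sub = df[df["protein"] == node]
        for tp in timepoints:
            rows = sub[sub["timepoint"].astype(str) == str(tp)]
            if rows.empty:
                states[str(tp)] = None
            else:
                best = rows.loc[rows["log2fc"].abs().idxmax()]
                states[str(tp)] = float(best["log2fc"])
        g.nodes[node]["states"] = states
    return g


def network_to_json(network: nx.Graph) -> dict:
    """Deterministic node-link representation (sorted nodes and edges)."""
    nodes = [
        {"id": n, **{k: v for k, v in sorted(network.nodes[n].items())}}
        for n in sorted(network.nodes)
    ]
    edge_rows = []
    for a, b in network.edges:
        a, b = sorted((a, b))
        edge_rows.append({"source": a, "target": b, "score": network[a][b]["score"]})
    edge_rows.sort(key=lambda e: (e["source"], e["target"]))
    return {"nodes": nodes, "edges": edge_rows}


def write_network(network: nx.Graph, json_path: str | Path, edges_path: str | Path) -> None:
    """Write node-link JSON plus a TSV edge list (proteinA, proteinB, score)."""
    data = network_to_json(network)
    Path(json_path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")
    pd.DataFrame(
        [(e["source"], e["target"], e["score"]) for e in data["edges"]],
        columns=EDGE_COLUMNS,
    ).to_csv(edges_path, sep="\t", index=False)


def read_edge_table(path: str | Path) -> pd.DataFrame:
    return _validate_edges(pd.read_csv(path, sep="\t"))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read term -> gene-set annotation in GMT (term, description, genes...)."""
    terms: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        terms[parts[0]] = set(parts[2:])
    return terms


def write_gmt(terms: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([term, description] + sorted(terms[term])) for term in sorted(terms)
    ]
    Path(path).write_text("\n".join(lines) + "\n")
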