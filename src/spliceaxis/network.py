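"""Splicing-factor / AS-event correlation networks.

Undirected bipartite networks: splicing-factor genes and AS events are
nodes; an edge connects a pair whose Spearman correlation (SF log2(TPM+1)
expression vs event PSI, pairwise-complete samples) exceeds ``rho_min`` in
absolute value.  Node attributes carry the comparison's log2FC (SF nodes)
and dPSI (event nodes) when provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .events import PsiMatrix
from .io import ExpressionMatrix, SpliceaxisError

logger = logging.getLogger(__name__)

RHO_MIN_DEFAULT = 0.3
N_MIN_DEFAULT = 10


@dataclass(frozen=True)
class CorrelationEdge:
    sf_gene: str
    event_id: str
    rho: float
    n: int
    subgroup: str


def build_network(
    sf_expr: ExpressionMatrix,
    psi: PsiMatrix,
    samples: Sequence[str] | None = None,
    rho_min: float = RHO_MIN_DEFAULT,
    n_min: int = N_MIN_DEFAULT,
    subgroup: str = "",
    sf_log2fc: Mapping[str, float] | None = None,
    event_dpsi: Mapping[str, float] | None = None,
) -> nx.Graph:
    """All |Spearman rho| > rho_min SF-event edges over the given samples.

    Pairs with constant expression or PSI, or fewer than ``n_min`` paired
    non-missing samples, are skipped (logged).
    """
    if not len(sf_expr.data.index):
        raise SpliceaxisError("build_network: empty splicing-factor list")
    expr = sf_expr.data if samples is None else sf_expr.data[list(samples)]
    psi_df = psi.data if samples is None else psi.data[list(samples)]
    log2 = np.log2(expr + 1.0)
    graph = nx.Graph(subgroup=subgroup)
    skipped = 0
    for sf in log2.index:
        x_full = log2.loc[sf]
        for event_id in psi_df.index:
            y_full = psi_df.loc[event_id]
            mask = x_full.notna() & y_full.notna()
            n = int(mask.sum())
            if n < n_min:
                skipped += 1
                continue
            x = x_full[mask].to_numpy()
            y = y_full[mask].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                skipped += 1
                continue
            rho = float(stats.spearmanr(x, y).statistic)
            if abs(rho) > rho_min:
                graph.add_node(sf, kind="sf", log2fc=(sf_log2fc or {}).get(sf))
                graph.add_node(
                    event_id, kind="event", dpsi=(event_dpsi or {}).get(event_id)
                )
                graph.add_edge(sf, event_id, rho=rho, n=n)
    logger.info(
        "build_network[%s]: %d edges (%d pairs skipped)",
        subgroup,
        graph.number_of_edges(),
        skipped,
    )
    return graph


def edge_set(graph: nx.Graph) -> set[tuple[str, str]]:
    """Canonical (sf_gene, event_id) pairs of a network."""
    out = set()
    for u, v in graph.edges:
        if graph.nodes[u].get("kind") == "sf":
            out.add((u, v))
        else:
            out.add((v, u))
    return out


def network_consistency(networks: Sequence[nx.Graph]) -> pd.DataFrame:
    """Edges shared across networks, with per-network rho and sign agreement.

    Returns one row per edge present in >= 2 networks; ``n_networks`` counts
    where it appears, ``in_all`` marks the fully shared set.
    """
    if len(networks) < 2:
        raise SpliceaxisError("network_consistency: need >= 2 networks")
    names = [g.graph.get("subgroup") or f"net{i}" for i, g in enumerate(networks)]
    sets = [edge_set(g) for g in networks]
    union = set().union(*sets)
    rows = []
    for sf, event_id in sorted(union):
        rhos = {}
        for name, g in zip(names, networks):
            if g.has_edge(sf, event_id):
                rhos[name] = g.edges[sf, event_id]["rho"]
        if len(rhos) < 2:
            continue
        signs = {np.sign(r) for r in rhos.values()}
        row = {
            "sf_gene": sf,
            "event_id": event_id,
            "n_networks": len(rhos),
            "in_all": len(rhos) == len(networks),
            "sign_consistent": len(signs) == 1,
        }
        for name in names:
            row[f"rho_{name}"] = rhos.get(name)
        rows.append(row)
    return pd.DataFrame(rows)


def export_network(graph: nx.Graph, outdir: str | Path, prefix: str = "network") -> None:
    """Cytoscape-compatible node and edge TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        [
            {
                "node": n,
                "kind": d.get("kind"),
                "log2fc": d.get("log2fc"),
                "dpsi": d.get("dpsi"),
            }
            for n, d in sorted(graph.nodes(data=True))
        ]
    )
    edges = pd.DataFrame(
        [
            {
                "source": sf,
                "target": ev,
                "interaction": "correlates",
                "rho": graph.edges[sf, ev]["rho"],
                "n": graph.edges[sf, ev]["n"],
            }
            for sf, ev in sorted(edge_set(graph))
        ]
    )
    nodes.to_csv(outdir / f"{prefix}_nodes.tsv", sep="\t", index=False, na_rep="NA")
    edges.to_csv(outdir / f"{prefix}_edges.tsv", sep="\t", index=False, na_rep="NA")
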