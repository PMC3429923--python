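"""Pairwise epistasis inference by the remove-one importance scan.

A forest captures interactions without naming them. To name them, each of
the top-k SNPs is removed in turn and the forest refit: if SNP i and SNP j
interact, dropping j shifts the importance of i. The shift's sign carries
the direction — importance of i *falling* when j is removed means the pair
contributes jointly (synergistic epistasis); importance *rising* means j
was masking i (antagonistic, or disruptive, epistasis).

The scan is replicated with fresh forest seeds; per ordered pair (i, j) the
replicate-level importance changes are tested against zero with a paired
one-sample t-test, and q-values control the false-discovery rate over all
k(k-1) ordered pairs. An undirected network edge is kept when either
direction is significant; its weight is the absolute mean importance change
of the more significant direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .forest import RFConfig, derive_seed, fit_rf
from .io import GenotypeMatrix
from .stats import one_sample_t, storey_qvalue

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionEdge",
    "InteractionNetwork",
    "interaction_scan",
    "test_interactions",
    "export_network",
    "read_edge_table",
]


@dataclass
class InteractionEdge:
    """One ordered pair: importance change of snp_i when snp_j is removed.

    ``delta_per_rep[r]`` = importance of i in the forest without j minus the
    importance of i in that replicate's baseline forest (same seed family),
    in percent-of-OOB-MSE units. A negative mean marks synergy, a positive
    mean antagonism.
    """

    snp_i: str
    snp_j: str
    delta_per_rep: np.ndarray
    baseline_importance: float  # mean baseline importance of snp_i over reps
    t_stat: float = np.nan
    p_value: float = np.nan
    q_value: float = np.nan

    def __post_init__(self) -> None:
        if self.snp_i == self.snp_j:
            raise ValueError("an edge cannot connect a SNP to itself")
        self.delta_per_rep = np.asarray(self.delta_per_rep, dtype=float)

    @property
    def mean_delta(self) -> float:
        return float(np.mean(self.delta_per_rep))

    @property
    def direction(self) -> str:
        if self.mean_delta < 0:
            return "synergistic"
        if self.mean_delta > 0:
            return "antagonistic"
        return "none"


@dataclass
class InteractionNetwork:
    """Undirected epistasis network over the top-k SNPs.

    ``graph`` is a networkx Graph whose nodes carry baseline importance and
    whose edges carry weight (|mean_delta|), direction, t, p, q and — after
    LD annotation — ld_p/ld_q. ``ordered_pairs`` keeps the full directed
    test table for inspection of asymmetry; ``discordant`` lists pairs whose
    two directions were both significant but disagreed in sign (reported,
    excluded from the graph).
    """

    graph: nx.Graph
    ordered_pairs: pd.DataFrame
    discordant: list[tuple[str, str]]
    alpha: float

    @property
    def edges(self) -> list[tuple[str, str, dict]]:
        return [(u, v, dict(d)) for u, v, d in self.graph.edges(data=True)]


def interaction_scan(
    X_top,
    y,
    replicates: int = 5,
    config: RFConfig | None = None,
    snp_ids=None,
) -> list[InteractionEdge]:
    """Remove-one importance scan over all ordered SNP pairs of a top set.

    Per replicate r a baseline forest on all k SNPs is fit first; then, for
    each SNP j, a forest on the remaining k-1 SNPs. The importance change of
    every remaining SNP i relative to the *same replicate's* baseline forms
    the paired sample later tested against zero. Yields k(k-1) ordered
    pairs, each with ``replicates`` deltas.
    """
    config = config or RFConfig()
    if isinstance(X_top, GenotypeMatrix):
        ids = list(X_top.snp_ids)
        X32 = np.ascontiguousarray(X_top.values, dtype=np.float32)
    else:
        X32 = np.ascontiguousarray(np.asarray(X_top), dtype=np.float32)
        ids = list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(X32.shape[1])]
    k = X32.shape[1]
    if k < 3:
        raise ValueError("interaction scan needs at least 3 SNPs")
    if replicates < 2:
        raise ValueError("need at least 2 replicates for a t-test")
    if k > 50:
        warnings.warn(
            f"interaction scan over k={k} SNPs fits {replicates * (k + 1)} forests",
            stacklevel=2,
        )

    # deltas[r, i, j]: change of importance of SNP i when SNP j is removed
    deltas = np.full((replicates, k, k), np.nan)
    base_imp = np.zeros((replicates, k))
    for r in range(replicates):
        cfg = RFConfig(config.n_trees, config.mtry,
                       derive_seed(config.seed, "epi-base", r), config.min_node_size)
        base_imp[r] = fit_rf(X32, y, cfg).importance
        for j in range(k):
            keep = [c for c in range(k) if c != j]
            cfg_j = RFConfig(config.n_trees, config.mtry,
                             derive_seed(config.seed, "epi-drop", r, j),
                             config.min_node_size)
            f = fit_rf(np.ascontiguousarray(X32[:, keep]), y, cfg_j)
            deltas[r, keep, j] = f.importance - base_imp[r, keep]
        logger.info("interaction scan replicate %d/%d done", r + 1, replicates)

    edges = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            edges.append(
                InteractionEdge(
                    snp_i=ids[i],
                    snp_j=ids[j],
                    delta_per_rep=deltas[:, i, j],
                    baseline_importance=float(base_imp[:, i].mean()),
                )
            )
    return edges


def test_interactions(edges: list[InteractionEdge], alpha: float = 0.05) -> InteractionNetwork:
    """t-test every ordered pair, FDR-adjust, and build the undirected network.

    Each pair's replicate deltas are tested with a two-sided one-sample
    t-test (df = R-1); q-values are computed over all ordered pairs. An
    undirected edge (i, j) enters the network iff min(q_ij, q_ji) < alpha,
    taking direction and weight from the more significant ordered pair.
    Pairs significant in both directions with opposite signs are flagged
    discordant and left out of the graph.
    """
    if not edges:
        raise ValueError("no edges to test")
    for e in edges:
        e.t_stat, e.p_value = one_sample_t(e.delta_per_rep)
    qres = storey_qvalue([e.p_value for e in edges])
    for e, q in zip(edges, qres.q_values):
        e.q_value = float(q)

    by_pair = {(e.snp_i, e.snp_j): e for e in edges}
    graph = nx.Graph()
    for e in edges:
        if not graph.has_node(e.snp_i):
            graph.add_node(e.snp_i, importance=e.baseline_importance)
    discordant: list[tuple[str, str]] = []
    seen = set()
    for e in edges:
        key = tuple(sorted((e.snp_i, e.snp_j)))
        if key in seen:
            continue
        seen.add(key)
        fwd = by_pair[(key[0], key[1])]
        rev = by_pair[(key[1], key[0])]
        best = min(fwd, rev, key=lambda x: (x.q_value, x.p_value, x.snp_i))
        if best.q_value >= alpha:
            continue
        other = rev if best is fwd else fwd
        if other.q_value < alpha and np.sign(other.mean_delta) != np.sign(best.mean_delta):
            discordant.append(key)
            logger.warning("discordant interaction signs for pair %s", key)
            continue
        graph.add_edge(
            key[0],
            key[1],
            weight=abs(best.mean_delta),
            direction=best.direction,
            mean_delta=best.mean_delta,
            t=best.t_stat,
            p=best.p_value,
            q=best.q_value,
            source=best.snp_i,
            removed=best.snp_j,
        )

    table = pd.DataFrame(
        {
            "snp_i": [e.snp_i for e in edges],
            "snp_j": [e.snp_j for e in edges],
            "mean_delta": [e.mean_delta for e in edges],
            "direction": [e.direction for e in edges],
            "t": [e.t_stat for e in edges],
            "p": [e.p_value for e in edges],
            "q": [e.q_value for e in edges],
        }
    )
    return InteractionNetwork(graph=graph, ordered_pairs=table,
                              discordant=discordant, alpha=alpha)


_EDGE_COLUMNS = ["snp_i", "snp_j", "weight", "direction", "mean_delta",
                 "t", "p", "q", "ld_p", "ld_q", "ld_significant"]

_SIF_RELATION = {"synergistic": "synergy", "antagonistic": "antagonism"}


def export_network(net: InteractionNetwork, out_dir) -> dict[str, "Path"]:
    """Write the network as a Cytoscape-importable edge-list TSV and SIF file.

    ``edges.tsv`` has one row per undirected edge with its statistics (and
    LD columns if annotated); ``network.sif`` encodes each edge as
    "snpA synergy|antagonism snpB". An empty network yields a header-only
    TSV and an empty SIF.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for u, v, d in sorted(net.graph.edges(data=True)):
        rows.append(
            {
                "snp_i": u,
                "snp_j": v,
                "weight": d["weight"],
                "direction": d["direction"],
                "mean_delta": d["mean_delta"],
                "t": d["t"],
                "p": d["p"],
                "q": d["q"],
                "ld_p": d.get("ld_p", ""),
                "ld_q": d.get("ld_q", ""),
                "ld_significant": d.get("ld_significant", ""),
            }
        )
    edges_path = out / "edges.tsv"
    pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(edges_path, sep="\t", index=False)

    sif_path = out / "network.sif"
    with open(sif_path, "w") as fh:
        for u, v, d in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{_SIF_RELATION[d['direction']]}\t{v}\n")

    pairs_path = out / "ordered_pairs.tsv"
    net.ordered_pairs.to_csv(pairs_path, sep="\t", index=False)
    return {"edges": edges_path, "sif": sif_path, "ordered_pairs": pairs_path}


def read_edge_table(path) -> pd.DataFrame:
    """Read back an exported edges.tsv (round-trip helper)."""
    return pd.read_csv(path, sep="\t")
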