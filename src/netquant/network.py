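"""Transcript interaction network: construction from domain–domain
interactions, graph statistics, randomization, and the co-expression
overlap analysis.

Two isoforms of *different* genes are connected when their protein products
carry a pair of interacting Pfam domains.  Interactions inferred from 3D
structures are trusted directly; computationally predicted interactions are
kept only when the corresponding gene pair is also supported by a
protein–protein interaction.  Within-gene (self) interactions are never
included: the model only exploits positive co-expression between isoforms
of different genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.stats import chi2_contingency

from .catalog import TranscriptCatalog

__all__ = [
    "TranscriptNetwork",
    "build_transcript_network",
    "network_statistics",
    "randomize_network",
    "coexpression_overlap",
    "pathway_comembership_summary",
]

log = logging.getLogger(__name__)

STRUCTURAL = "structural"
PREDICTED_TIERS = ("predicted_high", "predicted_medium")


@dataclass
class TranscriptNetwork:
    """Symmetric binary adjacency over a catalog's transcripts.

    ``edges`` is an (E, 2) int array with u < v, sorted lexicographically.
    ``provenance`` optionally tags each edge ``structural`` or ``predicted``.
    """

    catalog: TranscriptCatalog
    edges: np.ndarray
    provenance: list[str] | None = None
    neighbors: list[np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        e = np.sort(e, axis=1)
        if e.size:
            if e.min() < 0 or e.max() >= self.catalog.n_transcripts:
                raise ValueError("edge endpoint outside catalog")
            if np.any(e[:, 0] == e[:, 1]):
                raise ValueError("self-loop in edge list")
            tg = self.catalog.tx_gene
            if np.any(tg[e[:, 0]] == tg[e[:, 1]]):
                raise ValueError("within-gene edge in transcript network")
        order = np.lexsort((e[:, 1], e[:, 0]))
        e = e[order]
        if e.size and np.any(np.all(e[1:] == e[:-1], axis=1)):
            raise ValueError("duplicate edge in edge list")
        self.edges = e
        nbrs: list[list[int]] = [[] for _ in range(self.catalog.n_transcripts)]
        for u, v in e:
            nbrs[u].append(v)
            nbrs[v].append(u)
        self.neighbors = [np.array(sorted(x), dtype=np.int64) for x in nbrs]

    @property
    def n_nodes(self) -> int:
        return self.catalog.n_transcripts

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(n) for n in self.neighbors], dtype=np.int64)

    def adjacency(self) -> sp.csr_matrix:
        n = self.n_nodes
        if not self.n_edges:
            return sp.csr_matrix((n, n), dtype=bool)
        u, v = self.edges[:, 0], self.edges[:, 1]
        rows = np.concatenate([u, v])
        cols = np.concatenate([v, u])
        data = np.ones(rows.size, dtype=bool)
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def gene_neighbors(self, gene: int) -> list[np.ndarray]:
        """Neighbor arrays of each transcript of ``gene`` (local order)."""
        sl = self.catalog.gene_slices[gene]
        return [self.neighbors[j] for j in range(sl.start, sl.stop)]


def _dedupe_cross_gene(
    pairs: list[tuple[int, int]], catalog: TranscriptCatalog
) -> tuple[np.ndarray, int]:
    """Canonicalize pairs; drop within-gene ones; return (edges, n_dropped)."""
    seen: set[tuple[int, int]] = set()
    dropped = 0
    for u, v in pairs:
        if u == v or catalog.tx_gene[u] == catalog.tx_gene[v]:
            dropped += 1
            continue
        seen.add((min(u, v), max(u, v)))
    if not seen:
        return np.zeros((0, 2), dtype=np.int64), dropped
    return np.array(sorted(seen), dtype=np.int64), dropped


def build_transcript_network(
    annot: dict[str, set[tuple[str, float]]],
    ddi: dict[frozenset[str], str],
    catalog: TranscriptCatalog,
    evalue_cutoff: float = 1e-5,
    ppi_pairs: set[frozenset[str]] | None = None,
) -> TranscriptNetwork:
    """Join per-transcript domain hits through a domain–domain interaction
    table into a transcript network.

    Parameters
    ----------
    annot : mapping transcript_id -> set of (domain_id, e-value)
        Domain hits; hits with e-value above ``evalue_cutoff`` are ignored.
    ddi : mapping frozenset({domain_a, domain_b}) -> tier
        Tier is ``structural``, ``predicted_high`` or ``predicted_medium``.
    ppi_pairs : optional set of frozenset({gene_a, gene_b})
        Gene-level protein–protein interactions.  Edges supported only by
        predicted-tier interactions are kept just when the gene pair is in
        this set; when omitted, predicted tiers are excluded entirely.

    Self (within-gene) pairs are never emitted.
    """
    if not annot or all(not v for v in annot.values()):
        log.warning("empty domain annotation: returning an empty network")
        return TranscriptNetwork(catalog, np.zeros((0, 2), dtype=np.int64))

    # transcript -> filtered domain set
    domains: dict[int, frozenset[str]] = {}
    for tid, hits in annot.items():
        j = catalog.tx_index.get(tid)
        if j is None:
            continue
        kept = frozenset(d for d, ev in hits if ev <= evalue_cutoff)
        if kept:
            domains[j] = kept

    # domain -> transcripts carrying it
    carriers: dict[str, list[int]] = {}
    for j, ds in domains.items():
        for d in ds:
            carriers.setdefault(d, []).append(j)

    edge_tier: dict[tuple[int, int], bool] = {}  # pair -> has structural support
    for pair, tier in ddi.items():
        ab = sorted(pair)
        d1, d2 = (ab[0], ab[-1]) if len(ab) > 1 else (ab[0], ab[0])
        for u in carriers.get(d1, ()):
            for v in carriers.get(d2, ()):
                if u == v or catalog.tx_gene[u] == catalog.tx_gene[v]:
                    continue
                key = (min(u, v), max(u, v))
                structural = tier == STRUCTURAL
                edge_tier[key] = edge_tier.get(key, False) or structural

    edges: list[tuple[int, int]] = []
    provenance: list[str] = []
    for (u, v), structural in sorted(edge_tier.items()):
        if structural:
            edges.append((u, v))
            provenance.append("structure-based")
        else:
            if ppi_pairs is None:
                continue
            gpair = frozenset(
                (
                    catalog.genes[catalog.tx_gene[u]].gene_id,
                    catalog.genes[catalog.tx_gene[v]].gene_id,
                )
            )
            if gpair in ppi_pairs:
                edges.append((u, v))
                provenance.append("predicted")
    arr = (
        np.array(edges, dtype=np.int64)
        if edges
        else np.zeros((0, 2), dtype=np.int64)
    )
    return TranscriptNetwork(catalog, arr, provenance=provenance)


def network_statistics(
    net: TranscriptNetwork, include_expensive: bool = True
) -> dict:
    """Node/edge counts and topology summaries.

    density is the percentage of realized unordered pairs, E / (V(V-1)/2);
    avg_neighbors is 2E/V; diameter is measured on the largest connected
    component; the average clustering coefficient counts degree-<2 nodes as
    0.  With ``include_expensive=False`` diameter and clustering are skipped
    (returned as None), which is useful on very large graphs.
    """
    v = net.n_nodes
    if v == 0:
        raise ValueError("network has no nodes")
    e = net.n_edges
    stats = {
        "n_nodes": v,
        "n_edges": e,
        "density_pct": 100.0 * e / (v * (v - 1) / 2) if v > 1 else 0.0,
        "avg_neighbors": 2.0 * e / v,
        "diameter": None,
        "avg_clustering": None,
    }
    if include_expensive and e:
        g = net.to_networkx()
        largest = max(nx.connected_components(g), key=len)
        stats["diameter"] = nx.diameter(g.subgraph(largest))
        stats["avg_clustering"] = nx.average_clustering(g)
    return stats


def _sample_cross_gene_edges(
    n_edges: int,
    catalog: TranscriptCatalog,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> np.ndarray:
    """Draw ``n_edges`` distinct cross-gene pairs uniformly (rejection)."""
    n = catalog.n_transcripts
    chosen: set[tuple[int, int]] = set()
    for _ in range(max_tries):
        need = n_edges - len(chosen)
        if need <= 0:
            break
        u = rng.integers(0, n, size=2 * need + 16)
        v = rng.integers(0, n, size=2 * need + 16)
        ok = (u != v) & (catalog.tx_gene[u] != catalog.tx_gene[v])
        for a, b in zip(u[ok], v[ok]):
            chosen.add((min(a, b), max(a, b)))
            if len(chosen) >= n_edges:
                break
    if len(chosen) < n_edges:
        raise RuntimeError(
            f"could not draw {n_edges} distinct cross-gene edges "
            f"(graph too dense?)"
        )
    return np.array(sorted(chosen), dtype=np.int64)[:n_edges]


def randomize_network(
    net: TranscriptNetwork,
    mode: str,
    fraction: float | None = None,
    seed: int = 0,
) -> TranscriptNetwork:
    """Null / ablated versions of a network.

    - ``permute_labels``: relabel nodes by a uniform random permutation
      (degree multiset and edge count preserved).  A relabelling that maps
      an edge inside one gene is repaired by re-assigning the colliding
      label, keeping E exact.
    - ``shuffle_edges``: redraw E edges uniformly among cross-gene pairs.
    - ``remove_fraction``: delete floor(fraction * E) edges uniformly.
    """
    rng = np.random.default_rng(seed)
    catalog = net.catalog
    if mode == "remove_fraction":
        if fraction is None or not 0.0 <= fraction <= 1.0:
            raise ValueError("remove_fraction needs fraction in [0, 1]")
        e = net.n_edges
        n_remove = int(np.floor(fraction * e))
        keep = np.ones(e, dtype=bool)
        keep[rng.choice(e, size=n_remove, replace=False)] = False
        return TranscriptNetwork(catalog, net.edges[keep])
    if mode == "shuffle_edges":
        return TranscriptNetwork(
            catalog, _sample_cross_gene_edges(net.n_edges, catalog, rng)
        )
    if mode == "permute_labels":
        n = catalog.n_transcripts
        perm = rng.permutation(n)
        tg = catalog.tx_gene
        for _ in range(100 * max(net.n_edges, 1)):
            mapped = perm[net.edges]
            bad = tg[mapped[:, 0]] == tg[mapped[:, 1]]
            if not bad.any():
                break
            # swap one colliding label with a random other label
            u = int(net.edges[np.flatnonzero(bad)[0], 0])
            w = int(rng.integers(0, n))
            perm[u], perm[w] = perm[w], perm[u]
        else:  # pragma: no cover - pathological catalogs only
            raise RuntimeError("could not repair within-gene collisions")
        return TranscriptNetwork(catalog, perm[net.edges])
    raise ValueError(f"unknown randomization mode {mode!r}")


def coexpression_overlap(
    expr,
    net: TranscriptNetwork,
    bin_size: int = 1000,
    max_distance: int = 1,
    head_bins: int = 10,
) -> dict:
    """Overlap between co-expression ranking and network proximity.

    Pearson correlation is computed for every cross-gene transcript pair
    from the transcripts x samples table ``expr`` (a DataFrame indexed by
    transcript_id, or an array aligned to the catalog).  Pairs are sorted by
    correlation descending (ties broken by transcript-id pair) and grouped
    into bins of ``bin_size``; within each bin the pairs that are network
    neighbors (``max_distance=1``) or connected by a path of length <= 2
    (``max_distance=2``) are counted.  A 2x2 chi-square test (no continuity
    correction) compares connectedness in the first ``head_bins`` bins
    against the rest.

    Returns a dict with ``bin_counts``, ``n_pairs``, ``n_connected_pairs``,
    ``n_excluded_constant``, ``chi2``, ``p_value`` (``None`` when the test
    is degenerate).
    """
    import pandas as pd

    catalog = net.catalog
    if isinstance(expr, pd.DataFrame):
        mat = np.full((catalog.n_transcripts, expr.shape[1]), np.nan)
        for tid, row in expr.iterrows():
            j = catalog.tx_index.get(tid)
            if j is not None:
                mat[j] = row.to_numpy(dtype=float)
        have = ~np.isnan(mat).any(axis=1)
    else:
        mat = np.asarray(expr, dtype=float)
        if mat.shape[0] != catalog.n_transcripts:
            raise ValueError("expression rows do not match catalog transcripts")
        have = np.ones(mat.shape[0], dtype=bool)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples for correlation")

    sd = mat.std(axis=1)
    constant = have & (sd == 0)
    usable = have & (sd > 0)
    n_excluded = int(constant.sum())
    if n_excluded:
        log.warning(
            "%d constant expression rows excluded from correlation", n_excluded
        )

    if max_distance == 1:
        adj = net.adjacency()
        connected = adj
    elif max_distance == 2:
        adj = net.adjacency()
        two = (adj @ adj).astype(bool) + adj
        connected = two
    else:
        raise ValueError("max_distance must be 1 or 2")

    centered = mat - mat.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    norm[norm == 0] = np.nan
    corr = (centered @ centered.T) / np.outer(norm, norm)

    idx = np.flatnonzero(usable)
    tg = catalog.tx_gene
    pairs: list[tuple[float, str, str, bool]] = []
    conn = connected.toarray() if sp.issparse(connected) else np.asarray(connected)
    for a_pos, u in enumerate(idx):
        for v in idx[a_pos + 1 :]:
            if tg[u] == tg[v]:
                continue
            tid_u, tid_v = catalog.transcript_ids[u], catalog.transcript_ids[v]
            key = (tid_u, tid_v) if tid_u < tid_v else (tid_v, tid_u)
            pairs.append((float(corr[u, v]), key[0], key[1], bool(conn[u, v])))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    n_pairs = len(pairs)
    flags = np.array([p[3] for p in pairs], dtype=bool)
    n_bins = int(np.ceil(n_pairs / bin_size)) if n_pairs else 0
    bin_counts = np.array(
        [int(flags[b * bin_size : (b + 1) * bin_size].sum()) for b in range(n_bins)]
    )

    chi2 = p_value = None
    if net.n_edges == 0 or n_pairs == 0:
        log.warning("empty network or no pairs: chi-square test skipped")
    else:
        head = min(head_bins * bin_size, n_pairs)
        a = int(flags[:head].sum())
        b = head - a
        c = int(flags[head:].sum())
        d = (n_pairs - head) - c
        table = np.array([[a, b], [c, d]])
        if np.all(table.sum(axis=0) > 0) and np.all(table.sum(axis=1) > 0):
            chi2_val, p, _, _ = chi2_contingency(table, correction=False)
            chi2, p_value = float(chi2_val), float(p)
        else:
            log.warning("degenerate contingency table: chi-square test skipped")

    return {
        "bin_counts": bin_counts,
        "n_pairs": n_pairs,
        "n_connected_pairs": int(flags.sum()),
        "n_excluded_constant": n_excluded,
        "chi2": chi2,
        "p_value": p_value,
    }


def pathway_comembership_summary(
    n_genes: int,
    n_comember_pairs: int,
    n_ddi_comember: int,
    n_ddi_noncomember: int,
) -> dict:
    """Summary arithmetic for pathway co-membership vs. DDI coverage.

    Gene pairs here use the ordered-pair-with-self denominator V^2 (the
    convention of pathway co-membership tallies), unlike the unordered
    V(V-1)/2 used for network density.  Returns the co-member percentage,
    the complementary non-co-member pair count and percentage, the share of
    DDIs falling on co-member pairs, and the resulting fold enrichment.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    total_pairs = n_genes * n_genes
    if n_comember_pairs > total_pairs:
        raise ValueError("more co-member pairs than gene pairs")
    noncomember_pairs = total_pairs - n_comember_pairs
    total_ddi = n_ddi_comember + n_ddi_noncomember
    comember_pct = 100.0 * n_comember_pairs / total_pairs
    ddi_cover_pct = 100.0 * n_ddi_comember / total_ddi if total_ddi else 0.0
    # enrichment: DDI rate on co-member pairs over rate on non-co-member pairs
    rate_in = n_ddi_comember / n_comember_pairs if n_comember_pairs else 0.0
    rate_out = (
        n_ddi_noncomember / noncomember_pairs if noncomember_pairs else np.inf
    )
    return {
        "comember_pct": comember_pct,
        "noncomember_pairs": noncomember_pairs,
        "noncomember_pct": 100.0 - comember_pct,
        "ddi_comember_coverage_pct": ddi_cover_pct,
        "fold_enrichment": rate_in / rate_out if rate_out else np.inf,
    }
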