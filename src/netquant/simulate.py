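"""Synthetic data with the statistical structure the joint model assumes.

The generator produces (1) a catalog of genes whose isoforms share exon
segments, so read ambiguity genuinely exists; (2) a random cross-gene
transcript network; (3) a ground-truth expression profile in which gene
totals are Poisson, within-gene isoform shares follow a heavy-tailed power
law with multiplicative Gaussian noise, and a sequential neighbor-average
pass couples the expression of network neighbors; and (4) reads sampled
from transcripts in proportion to expression times effective length, with
compatibility determined by the shared-segment structure.

Read sampling is performed at the level of exact sufficient statistics:
reads are multinomial over transcripts (probability proportional to
pi * (l - l_r + 1)) and, within a transcript, start positions are uniform,
so the count of reads whose covered segment run is constant is multinomial
over the run's start-position interval lengths.  Sampling those multinomial
counts directly is distributionally identical to drawing individual reads
and collapsing them, and orders of magnitude faster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .catalog import Gene, Transcript, TranscriptCatalog
from .compat import (
    CompatibilityMatrix,
    GeneCompat,
    empty_gene_compat,
    sampling_probability,
)
from .network import TranscriptNetwork, _sample_cross_gene_edges

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "synthetic_catalog",
    "random_transcript_network",
    "simulate_truth",
    "simulate_reads",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the ground-truth generator.

    poisson_mean: mean of the per-gene total expression (read-scale).
    power_exponent: tail exponent gamma of the initial isoform shares.
    noise_sd: Gaussian noise, as a fraction of the initial value.
    neighbor_weight: weight w of the neighbor-average term in the
        sequential coupling pass; 0 disconnects truth from the network.
        The default 1.0 adds each transcript's neighbor-average expression
        to its initial expression once.
    """

    poisson_mean: float = 500.0
    power_exponent: float = 1.5
    noise_sd: float = 0.1
    neighbor_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.poisson_mean < 0 or self.noise_sd < 0 or self.neighbor_weight < 0:
            raise ValueError("simulation parameters must be non-negative")
        if self.power_exponent <= 1.0:
            raise ValueError("power_exponent must exceed 1")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset, aligned to the catalog."""

    catalog: TranscriptCatalog
    pi_true: np.ndarray  # reads-per-base expression per transcript
    proportions: np.ndarray  # within-gene read-origin proportions
    gene_totals: np.ndarray  # per-gene total expression (read scale)
    params: SimulationParams
    seed: int

    def __post_init__(self) -> None:
        for sl in self.catalog.gene_slices:
            s = self.proportions[sl].sum()
            if not np.isclose(s, 1.0):
                raise ValueError("per-gene proportions must sum to 1")
        if np.any(self.pi_true < 0):
            raise ValueError("expressions must be non-negative")


def synthetic_catalog(
    n_genes: int,
    seed: int,
    min_segments: int = 3,
    max_segments: int = 10,
    isoform_probs: tuple[float, ...] = (0.2, 0.3, 0.3, 0.2),
    segment_length_range: tuple[int, int] = (100, 300),
    min_transcript_length: int = 200,
    duplicate_prob: float = 0.4,
) -> TranscriptCatalog:
    """Generate genes as chains of exon segments with isoforms that are
    contiguous segment runs all containing a common anchor segment, so
    every isoform pair of a gene overlaps and ambiguous reads exist
    whenever a gene has several isoforms.

    With probability ``duplicate_prob`` an additional isoform reuses an
    existing isoform's segment window.  Such structurally identical
    isoforms are indistinguishable at the read level — the situation of
    annotation catalogs where isoforms differ only in features invisible
    to short-read alignment — and their within-gene proportions can only
    be resolved by outside information such as a network prior.
    """
    rng = np.random.default_rng(seed)
    genes = []
    for gi in range(n_genes):
        n_seg = int(rng.integers(min_segments, max_segments + 1))
        seg_lens = tuple(
            int(x)
            for x in rng.integers(
                segment_length_range[0], segment_length_range[1] + 1, size=n_seg
            )
        )
        n_iso = int(rng.choice(np.arange(1, len(isoform_probs) + 1),
                               p=isoform_probs))
        anchor = int(rng.integers(0, n_seg))
        windows: list[tuple[int, int]] = []
        for _ in range(200):
            if len(windows) >= n_iso:
                break
            if windows and rng.random() < duplicate_prob:
                windows.append(windows[int(rng.integers(0, len(windows)))])
                continue
            a = int(rng.integers(0, anchor + 1))
            b = int(rng.integers(anchor + 1, n_seg + 1))
            if sum(seg_lens[a:b]) >= min_transcript_length:
                windows.append((a, b))
        txs = tuple(
            Transcript(
                transcript_id=f"G{gi:04d}.T{ti}",
                length=sum(seg_lens[a:b]),
                segments=(a, b),
            )
            for ti, (a, b) in enumerate(sorted(windows))
        )
        genes.append(
            Gene(gene_id=f"G{gi:04d}", transcripts=txs, segment_lengths=seg_lens)
        )
    return TranscriptCatalog(genes)


def random_transcript_network(
    catalog: TranscriptCatalog, avg_degree: float, seed: int
) -> TranscriptNetwork:
    """Uniform random cross-gene network with ~avg_degree neighbors/node."""
    rng = np.random.default_rng(seed)
    n_edges = int(round(avg_degree * catalog.n_transcripts / 2))
    edges = _sample_cross_gene_edges(n_edges, catalog, rng)
    return TranscriptNetwork(catalog, edges)


def simulate_truth(
    catalog: TranscriptCatalog,
    net: TranscriptNetwork,
    params: SimulationParams = SimulationParams(),
    seed: int = 0,
) -> SimulationTruth:
    """Draw a network-correlated ground-truth expression profile.

    Gene totals (read scale) are Poisson(poisson_mean).  Each gene's total
    is split over its isoforms by normalized Pareto(gamma - 1) draws,
    perturbed by multiplicative Gaussian noise (sd = noise_sd of the value)
    and truncated at zero; dividing by transcript length turns these into
    initial reads-per-base expressions.  A single sequential pass over
    transcripts in catalog order then adds neighbor_weight times the mean
    per-base expression of each transcript's network neighbors
    (already-updated neighbors contribute their updated value), planting
    positive co-expression along edges in exactly the unit the model's
    prior propagates.  Final within-gene read-origin proportions are
    proportional to expression times length.
    """
    rng = np.random.default_rng(seed)
    n_tx = catalog.n_transcripts
    gene_totals = rng.poisson(params.poisson_mean, size=catalog.n_genes).astype(
        float
    )
    pi = np.zeros(n_tx)
    lengths = catalog.lengths.astype(float)
    for i, sl in enumerate(catalog.gene_slices):
        k = sl.stop - sl.start
        shares = 1.0 + rng.pareto(params.power_exponent - 1.0, size=k)
        shares /= shares.sum()
        init = gene_totals[i] * shares
        init *= 1.0 + params.noise_sd * rng.standard_normal(k)
        pi[sl] = np.maximum(init, 0.0) / lengths[sl]

    if params.neighbor_weight > 0 and net.n_edges:
        for t in range(n_tx):
            nbrs = net.neighbors[t]
            if nbrs.size:
                pi[t] += params.neighbor_weight * pi[nbrs].mean()

    proportions = np.zeros(n_tx)
    counts = pi * lengths
    for i, sl in enumerate(catalog.gene_slices):
        total = counts[sl].sum()
        if total > 0:
            proportions[sl] = counts[sl] / total
        else:
            proportions[sl] = 1.0 / (sl.stop - sl.start)
    return SimulationTruth(
        catalog=catalog,
        pi_true=pi,
        proportions=proportions,
        gene_totals=np.array(
            [counts[sl].sum() for sl in catalog.gene_slices]
        ),
        params=params,
        seed=seed,
    )


def _window_runs(
    seg_lens: tuple[int, ...], tx_range: tuple[int, int], l_r: int
) -> list[tuple[int, int, int]]:
    """For a transcript spanning gene segments [a, b), list the maximal
    intervals of read start positions over which the covered segment run is
    constant, as (n_starts, first_seg, last_seg) with absolute segment ids.
    """
    a, b = tx_range
    lens = seg_lens[a:b]
    length = sum(lens)
    n_pos = length - l_r + 1
    if n_pos <= 0:
        return []
    cum = np.concatenate([[0], np.cumsum(lens)])  # local boundaries
    # breakpoints: starts where the first or last covered segment changes
    points = {0, n_pos}
    for c in cum[1:-1]:
        if 0 < c < n_pos:
            points.add(int(c))  # first segment changes at start = c
        t = int(c) - l_r + 1  # last segment changes here
        if 0 < t < n_pos:
            points.add(t)
    bounds = sorted(points)
    runs = []
    for s0, s1 in zip(bounds[:-1], bounds[1:]):
        first = int(np.searchsorted(cum, s0, side="right")) - 1
        last = int(np.searchsorted(cum, s0 + l_r - 1, side="right")) - 1
        runs.append((s1 - s0, a + first, a + last))
    return runs


def simulate_reads(
    truth: SimulationTruth,
    catalog: TranscriptCatalog,
    n_reads: int,
    l_r: int = 76,
    seed: int = 0,
) -> CompatibilityMatrix:
    """Sample reads and return their per-gene equivalence classes.

    A read picks a transcript with probability proportional to
    pi_true * (l - l_r + 1) (transcripts shorter than the read are never
    picked), then a uniform start position.  Its compatible set is every
    same-gene isoform whose segment run contains the covered window; q is
    1/(l_u - l_r + 1) for each compatible isoform u.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    eff = np.maximum(catalog.lengths - l_r + 1, 0).astype(float)
    weights = truth.pi_true * eff
    total_w = weights.sum()
    if total_w <= 0:
        raise ValueError("no transcript can emit reads at this read length")
    tx_counts = rng.multinomial(n_reads, weights / total_w)

    # per gene: {(first_seg, last_seg) window run -> count}
    gene_classes: list[dict[tuple[int, int], int]] = [
        {} for _ in range(catalog.n_genes)
    ]
    for t in np.flatnonzero(tx_counts):
        gi = int(catalog.tx_gene[t])
        gene = catalog.genes[gi]
        if gene.segment_lengths is None:
            raise ValueError(
                f"gene {gene.gene_id!r} lacks segment structure; use a "
                "synthetic catalog"
            )
        local = t - catalog.gene_slices[gi].start
        tx = gene.transcripts[local]
        runs = _window_runs(gene.segment_lengths, tx.segments, l_r)
        sizes = np.array([r[0] for r in runs], dtype=float)
        run_counts = rng.multinomial(int(tx_counts[t]), sizes / sizes.sum())
        cls = gene_classes[gi]
        for (n_start, first, last), c in zip(runs, run_counts):
            if c:
                key = (first, last)
                cls[key] = cls.get(key, 0) + int(c)

    genes: list[GeneCompat] = []
    for gi, cls in enumerate(gene_classes):
        sl = catalog.gene_slices[gi]
        k = sl.stop - sl.start
        if not cls:
            genes.append(empty_gene_compat(k))
            continue
        gene = catalog.genes[gi]
        # merge window runs with identical compatible sets into one class
        merged: dict[frozenset[int], int] = {}
        for (first, last), c in cls.items():
            compatible = frozenset(
                kk
                for kk, tx in enumerate(gene.transcripts)
                if tx.segments[0] <= first and tx.segments[1] > last
            )
            merged[compatible] = merged.get(compatible, 0) + c
        keys = sorted(merged, key=sorted)
        counts = np.array([merged[key] for key in keys], dtype=float)
        q = np.zeros((len(keys), k))
        for e, members in enumerate(keys):
            for kk in members:
                q[e, kk] = sampling_probability(
                    int(catalog.lengths[sl.start + kk]), l_r
                )
        genes.append(GeneCompat(counts=counts, q=q))
    return CompatibilityMatrix(catalog=catalog, genes=genes)


def evaluate_recovery(
    pi_est: np.ndarray,
    truth: SimulationTruth,
    net: TranscriptNetwork | None = None,
    subset: str = "all_multi_isoform",
) -> float:
    """Pearson correlation between log2(pi + 1) of estimate and truth.

    Estimated expressions are rescaled so their total matches the truth's
    before the log transform (the two profiles live on the read scales of
    the fit and of the generator respectively; total-expression matching
    puts them on one scale without affecting within-profile structure).

    subset:
      - ``all_multi_isoform``: transcripts of genes with >= 2 isoforms;
      - ``different_neighbor_isoforms``: transcripts of multi-isoform genes
        whose isoforms have non-identical neighbor sets in ``net``.
    """
    catalog = truth.catalog
    pi_est = np.asarray(pi_est, dtype=float)
    if pi_est.shape != truth.pi_true.shape:
        raise ValueError("estimate and truth cover different catalogs")
    multi = np.array(
        [sl.stop - sl.start > 1 for sl in catalog.gene_slices]
    )[catalog.tx_gene]
    if subset == "all_multi_isoform":
        mask = multi
    elif subset == "different_neighbor_isoforms":
        if net is None:
            raise ValueError("this subset requires the network")
        mask = np.zeros(catalog.n_transcripts, dtype=bool)
        for i, sl in enumerate(catalog.gene_slices):
            if sl.stop - sl.start < 2:
                continue
            nbr_sets = {
                frozenset(net.neighbors[t].tolist())
                for t in range(sl.start, sl.stop)
            }
            if len(nbr_sets) > 1:
                mask[sl] = True
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if not mask.any():
        raise ValueError(f"subset {subset!r} is empty for this catalog")

    est = pi_est.copy()
    if est.sum() > 0:
        est *= truth.pi_true.sum() / est.sum()
    x = np.log2(est[mask] + 1.0)
    y = np.log2(truth.pi_true[mask] + 1.0)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: constant vector in subset")
    r, _ = pearsonr(x, y)
    return float(r)
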