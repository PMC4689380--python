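"""Read–transcript compatibility with per-transcript sampling probabilities.

Reads aligned to a gene are collapsed into *equivalence classes*: all reads
compatible with the same set of isoforms (and the same sampling-probability
vector) form one class with a multiplicity.  The per-gene likelihood over
classes, sum_e c_e * log(sum_k p_k q_ek), is identical to the per-read
product, so classes are sufficient statistics for the model.

The sampling probability of a read of length ``l_r`` from a transcript of
length ``l`` is uniform over start positions, q = 1 / (l - l_r + 1); a
transcript shorter than the read cannot emit it (q = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .catalog import TranscriptCatalog

__all__ = [
    "sampling_probability",
    "GeneCompat",
    "CompatibilityMatrix",
    "compat_from_alignments",
]

log = logging.getLogger(__name__)


def sampling_probability(l_ik: int, l_r: int) -> float:
    """Per-start-position probability of drawing a read of length ``l_r``
    from a transcript of length ``l_ik``.

    Returns ``1 / (l_ik - l_r + 1)``, or 0 when the transcript is shorter
    than the read (the natural limit of the formula, which is undefined
    there).
    """
    if l_ik < 1 or l_r < 1:
        raise ValueError(f"lengths must be positive, got l_ik={l_ik}, l_r={l_r}")
    if l_ik < l_r:
        return 0.0
    return 1.0 / (l_ik - l_r + 1)


@dataclass
class GeneCompat:
    """Equivalence classes of one gene.

    ``counts`` has shape (E,); ``q`` has shape (E, K) over the gene's local
    transcript order, with 0 marking incompatibility.  ``n_reads`` is the
    total aligned read count |r_i| = counts.sum().
    """

    counts: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.q = np.atleast_2d(np.asarray(self.q, dtype=np.float64))
        if self.counts.ndim != 1 or self.q.shape[0] != self.counts.shape[0]:
            raise ValueError("counts and q shapes disagree")
        if np.any(self.counts < 1):
            raise ValueError("class counts must be >= 1")
        if not np.all(np.isfinite(self.q)) or np.any(self.q < 0):
            raise ValueError("q values must be finite and non-negative")
        if self.counts.size and np.any(self.q.sum(axis=1) <= 0):
            raise ValueError("every class needs at least one compatible transcript")

    @property
    def n_reads(self) -> float:
        return float(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return int(self.counts.size)


@dataclass
class CompatibilityMatrix:
    """Per-gene equivalence classes aligned to a catalog."""

    catalog: TranscriptCatalog
    genes: list[GeneCompat] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.genes) != self.catalog.n_genes:
            raise ValueError(
                f"expected {self.catalog.n_genes} gene slices, got {len(self.genes)}"
            )
        for i, gc in enumerate(self.genes):
            k = self.catalog.gene_slices[i].stop - self.catalog.gene_slices[i].start
            if gc.q.size and gc.q.shape[1] != k:
                raise ValueError(
                    f"gene {self.catalog.genes[i].gene_id!r}: q has "
                    f"{gc.q.shape[1]} columns, catalog has {k} transcripts"
                )

    @property
    def read_counts(self) -> np.ndarray:
        """|r_i| per gene."""
        return np.array([g.n_reads for g in self.genes])

    @property
    def total_reads(self) -> float:
        return float(self.read_counts.sum())


def empty_gene_compat(n_transcripts: int) -> GeneCompat:
    return GeneCompat(
        counts=np.zeros(0), q=np.zeros((0, n_transcripts))
    )


def compat_from_alignments(
    path: str,
    catalog: TranscriptCatalog,
    l_r: int,
    multimap_policy: str = "primary_only",
) -> CompatibilityMatrix:
    """Build a compatibility matrix from SAM/BAM alignments against
    transcript sequences.

    Each read contributes q = sampling_probability(l_t, l_r) for every
    transcript it aligns to.  Reads hitting transcripts of several genes are
    resolved by ``multimap_policy``:

    - ``primary_only``: the read is assigned to the gene of its primary
      alignment; alignments to other genes are dropped.
    - ``split_by_loci``: the read appears in every gene hit, with q divided
      by the number of distinct gene loci.

    Reads aligned to no catalog transcript are dropped with a logged count.
    """
    import pysam

    if multimap_policy not in ("primary_only", "split_by_loci"):
        raise ValueError(f"unknown multimap_policy {multimap_policy!r}")

    # read name -> list of (tx_index, is_primary)
    hits: dict[str, list[tuple[int, bool]]] = {}
    n_unknown = 0
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            ref = aln.reference_name
            j = catalog.tx_index.get(ref)
            if j is None:
                n_unknown += 1
                continue
            primary = not (aln.is_secondary or aln.is_supplementary)
            hits.setdefault(aln.query_name, []).append((j, primary))
    if n_unknown:
        log.warning("%d alignments to unknown transcripts dropped", n_unknown)

    # per gene: {class key -> count}; key = (frozenset local tx, divisor)
    classes: list[dict[tuple[frozenset[int], int], int]] = [
        {} for _ in range(catalog.n_genes)
    ]
    n_no_target = 0
    for _name, alns in hits.items():
        txs = sorted({j for j, _ in alns})
        gene_loci = sorted({int(catalog.tx_gene[j]) for j in txs})
        if multimap_policy == "primary_only":
            primaries = [j for j, p in alns if p]
            if not primaries:
                n_no_target += 1
                continue
            g = int(catalog.tx_gene[primaries[0]])
            keep = [j for j in txs if catalog.tx_gene[j] == g]
            targets = [(g, keep, 1)]
        else:
            divisor = len(gene_loci)
            targets = [
                (g, [j for j in txs if catalog.tx_gene[j] == g], divisor)
                for g in gene_loci
            ]
        for g, keep, divisor in targets:
            start = catalog.gene_slices[g].start
            key = (frozenset(j - start for j in keep), divisor)
            classes[g][key] = classes[g].get(key, 0) + 1
    if n_no_target:
        log.warning("%d reads without a primary alignment dropped", n_no_target)

    genes: list[GeneCompat] = []
    for g, cls in enumerate(classes):
        sl = catalog.gene_slices[g]
        k = sl.stop - sl.start
        if not cls:
            genes.append(empty_gene_compat(k))
            continue
        keys = sorted(cls, key=lambda key: (sorted(key[0]), key[1]))
        counts = np.array([cls[key] for key in keys], dtype=np.float64)
        q = np.zeros((len(keys), k))
        for e, (members, divisor) in enumerate(keys):
            for kk in members:
                q[e, kk] = (
                    sampling_probability(int(catalog.lengths[sl.start + kk]), l_r)
                    / divisor
                )
        # a transcript shorter than the read has q = 0; drop empty classes
        keep_rows = q.sum(axis=1) > 0
        genes.append(GeneCompat(counts=counts[keep_rows], q=q[keep_rows]))
    return CompatibilityMatrix(catalog=catalog, genes=genes)
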