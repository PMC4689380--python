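"""Transcript catalog: the indexing backbone for genes and their isoforms.

A catalog fixes a deterministic global ordering of genes and, within each
gene, of transcripts (both lexicographic by identifier).  Every other
container in the package — compatibility matrices, networks, results,
simulation truths — is indexed against a catalog, so that transcript ``k``
of gene ``i`` means the same thing everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Transcript", "Gene", "TranscriptCatalog"]


@dataclass(frozen=True)
class Transcript:
    """One isoform: an identifier, a length in nucleotides, and (optionally,
    for simulated catalogs) the contiguous run of gene segments it is spliced
    from, as a half-open ``(start, stop)`` index range into the gene's
    segment chain."""

    transcript_id: str
    length: int
    segments: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(
                f"transcript {self.transcript_id!r} has non-positive length "
                f"{self.length}"
            )


@dataclass(frozen=True)
class Gene:
    """A gene and its ordered isoforms.  ``segment_lengths`` carries the
    synthetic exon-segment chain used by the read simulator; it is ``None``
    for catalogs read from plain annotation files."""

    gene_id: str
    transcripts: tuple[Transcript, ...]
    segment_lengths: tuple[int, ...] | None = None


@dataclass
class TranscriptCatalog:
    """Ordered genes and transcripts with flat index arrays.

    Attributes
    ----------
    genes : list of Gene
        In canonical (lexicographic by gene_id) order.
    transcript_ids : list of str
        Global transcript order: genes in order, transcripts within gene in
        order.  Index into this list is the *global transcript index*.
    lengths : ndarray of int
        Transcript lengths aligned to ``transcript_ids``.
    tx_gene : ndarray of int
        Gene index of each transcript.
    gene_slices : list of slice
        Per gene, the slice of the global transcript arrays it occupies.
    """

    genes: list[Gene]
    transcript_ids: list[str] = field(init=False)
    lengths: np.ndarray = field(init=False)
    tx_gene: np.ndarray = field(init=False)
    gene_slices: list[slice] = field(init=False)
    tx_index: dict[str, int] = field(init=False)
    gene_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.genes = sorted(
            (
                Gene(
                    g.gene_id,
                    tuple(sorted(g.transcripts, key=lambda t: t.transcript_id)),
                    g.segment_lengths,
                )
                for g in self.genes
            ),
            key=lambda g: g.gene_id,
        )
        ids: list[str] = []
        lengths: list[int] = []
        tx_gene: list[int] = []
        slices: list[slice] = []
        for i, g in enumerate(self.genes):
            start = len(ids)
            for t in g.transcripts:
                ids.append(t.transcript_id)
                lengths.append(t.length)
                tx_gene.append(i)
            slices.append(slice(start, len(ids)))
        dup = _first_duplicate(ids)
        if dup is not None:
            raise ValueError(f"duplicate transcript_id {dup!r} in catalog")
        self.transcript_ids = ids
        self.lengths = np.asarray(lengths, dtype=np.int64)
        self.tx_gene = np.asarray(tx_gene, dtype=np.int64)
        self.gene_slices = slices
        self.tx_index = {t: j for j, t in enumerate(ids)}
        self.gene_index = {g.gene_id: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def gene_of(self, transcript_id: str) -> str:
        return self.genes[self.tx_gene[self.tx_index[transcript_id]]].gene_id

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TranscriptCatalog({self.n_genes} genes, "
            f"{self.n_transcripts} transcripts)"
        )


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None
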