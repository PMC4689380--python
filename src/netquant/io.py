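"""Readers and writers for the on-disk artifacts.

The canonical exchange formats are plain TSVs: a transcript catalog
(gene_id, transcript_id, length), a compatibility table (gene_id, class_id,
count, transcript_id, q — one row per class–transcript pair), a network
edge list (two transcript_id columns), and the result table.  GTF and
SAM/BAM are supported as convenience importers for the catalog and the
compatibility matrix respectively.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .catalog import Gene, Transcript, TranscriptCatalog
from .compat import CompatibilityMatrix, GeneCompat, empty_gene_compat
from .network import TranscriptNetwork

__all__ = [
    "read_catalog",
    "read_network_edges",
    "write_network_edges",
    "read_compat_table",
    "write_compat_table",
    "write_result",
    "read_result",
]

log = logging.getLogger(__name__)


def read_catalog(path: str, format: str = "tsv") -> TranscriptCatalog:
    """Read a transcript catalog from TSV or GTF.

    TSV needs a header with gene_id, transcript_id, length.  For GTF,
    transcript lengths are the sum of exon spans (1-based inclusive
    coordinates, strand ignored).  Ordering is canonicalized to
    lexicographic by (gene_id, transcript_id) either way.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "transcript_id": str})
        missing = {"gene_id", "transcript_id", "length"} - set(df.columns)
        if missing:
            raise ValueError(f"catalog TSV missing columns: {sorted(missing)}")
        return _catalog_from_table(df)
    if format == "gtf":
        return _catalog_from_gtf(path)
    raise ValueError(f"unknown catalog format {format!r}")


def _catalog_from_table(df: pd.DataFrame) -> TranscriptCatalog:
    owners = df.groupby("transcript_id")["gene_id"].nunique()
    shared = owners[owners > 1]
    if len(shared):
        raise ValueError(
            f"transcript {shared.index[0]!r} listed under multiple genes"
        )
    dup = df.duplicated(subset=["transcript_id"])
    if dup.any():
        raise ValueError(
            f"duplicate transcript_id {df.loc[dup, 'transcript_id'].iloc[0]!r}"
        )
    genes = []
    for gid, grp in df.groupby("gene_id"):
        txs = tuple(
            Transcript(transcript_id=row.transcript_id, length=int(row.length))
            for row in grp.itertuples()
        )
        genes.append(Gene(gene_id=str(gid), transcripts=txs))
    return TranscriptCatalog(genes)


def _catalog_from_gtf(path: str) -> TranscriptCatalog:
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    lengths: dict[str, int] = {}
    gene_of: dict[str, str] = {}
    for exon in db.features_of_type("exon"):
        tid = exon.attributes["transcript_id"][0]
        gid = exon.attributes["gene_id"][0]
        if tid in gene_of and gene_of[tid] != gid:
            raise ValueError(f"transcript {tid!r} listed under multiple genes")
        gene_of[tid] = gid
        lengths[tid] = lengths.get(tid, 0) + (exon.end - exon.start + 1)
    rows = pd.DataFrame(
        {
            "gene_id": [gene_of[t] for t in lengths],
            "transcript_id": list(lengths),
            "length": list(lengths.values()),
        }
    )
    if rows.empty:
        raise ValueError("GTF contains no exon features")
    return _catalog_from_table(rows)


def read_network_edges(path: str, catalog: TranscriptCatalog) -> TranscriptNetwork:
    """Read a two-column transcript-id edge list.

    Within-gene pairs, pairs naming unknown transcripts, self pairs and
    duplicates are dropped (with logged counts).  An empty file yields an
    empty network with a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["a", "b"])
    if df.empty:
        log.warning("empty edge list %s: returning an empty network", path)
        return TranscriptNetwork(catalog, np.zeros((0, 2), dtype=np.int64))
    n_unknown = n_within = 0
    seen: set[tuple[int, int]] = set()
    for a, b in zip(df["a"], df["b"]):
        u = catalog.tx_index.get(a)
        v = catalog.tx_index.get(b)
        if u is None or v is None:
            n_unknown += 1
            continue
        if u == v or catalog.tx_gene[u] == catalog.tx_gene[v]:
            n_within += 1
            continue
        seen.add((min(u, v), max(u, v)))
    if n_unknown:
        log.warning("%d edges naming unknown transcripts dropped", n_unknown)
    if n_within:
        log.warning("%d within-gene edges dropped", n_within)
    edges = (
        np.array(sorted(seen), dtype=np.int64)
        if seen
        else np.zeros((0, 2), dtype=np.int64)
    )
    return TranscriptNetwork(catalog, edges)


def write_network_edges(net: TranscriptNetwork, path: str) -> None:
    ids = net.catalog.transcript_ids
    with open(path, "w") as fh:
        for u, v in net.edges:
            fh.write(f"{ids[u]}\t{ids[v]}\n")


def read_compat_table(path: str, catalog: TranscriptCatalog) -> CompatibilityMatrix:
    """Read the equivalence-class table (gene_id, class_id, count,
    transcript_id, q).  Genes absent from the table get zero classes."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene_id": str, "class_id": str, "transcript_id": str},
    )
    missing = {"gene_id", "class_id", "count", "transcript_id", "q"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"compat TSV missing columns: {sorted(missing)}")
    per_gene: list[dict] = [dict() for _ in range(catalog.n_genes)]
    for row in df.itertuples():
        gi = catalog.gene_index.get(row.gene_id)
        if gi is None:
            raise ValueError(f"unknown gene_id {row.gene_id!r} in compat table")
        j = catalog.tx_index.get(row.transcript_id)
        if j is None or catalog.tx_gene[j] != gi:
            raise ValueError(
                f"class {row.class_id!r} references transcript "
                f"{row.transcript_id!r} outside gene {row.gene_id!r}"
            )
        if row.count < 1:
            raise ValueError(f"class {row.class_id!r} has count {row.count} < 1")
        if not np.isfinite(row.q) or row.q <= 0:
            raise ValueError(
                f"class {row.class_id!r} has invalid q={row.q} for "
                f"{row.transcript_id!r}"
            )
        local = j - catalog.gene_slices[gi].start
        cls = per_gene[gi].setdefault(row.class_id, {"count": None, "q": {}})
        if cls["count"] is not None and cls["count"] != row.count:
            raise ValueError(f"class {row.class_id!r} has inconsistent counts")
        cls["count"] = row.count
        cls["q"][local] = float(row.q)
    genes = []
    for gi, classes in enumerate(per_gene):
        sl = catalog.gene_slices[gi]
        k = sl.stop - sl.start
        if not classes:
            genes.append(empty_gene_compat(k))
            continue
        keys = sorted(classes)
        counts = np.array([classes[c]["count"] for c in keys], dtype=float)
        q = np.zeros((len(keys), k))
        for e, c in enumerate(keys):
            for local, val in classes[c]["q"].items():
                q[e, local] = val
        genes.append(GeneCompat(counts=counts, q=q))
    return CompatibilityMatrix(catalog=catalog, genes=genes)


def write_compat_table(compat: CompatibilityMatrix, path: str) -> None:
    catalog = compat.catalog
    rows = []
    for gi, gc in enumerate(compat.genes):
        gid = catalog.genes[gi].gene_id
        sl = catalog.gene_slices[gi]
        for e in range(gc.n_classes):
            cid = f"{gid}.c{e}"
            for local in np.flatnonzero(gc.q[e] > 0):
                rows.append(
                    (
                        gid,
                        cid,
                        int(gc.counts[e]),
                        catalog.transcript_ids[sl.start + local],
                        gc.q[e, local],
                    )
                )
    df = pd.DataFrame(
        rows, columns=["gene_id", "class_id", "count", "transcript_id", "q"]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_result(result, path: str) -> None:
    """Write the result table (gene_id, transcript_id, p, rho, pi,
    zero_reads) with 6 significant digits."""
    df = result.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_result(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "transcript_id": str}
    )
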