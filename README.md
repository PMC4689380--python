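# netquant

Network-regularized isoform transcript quantification from RNA-Seq read
alignments.

Short reads rarely identify which isoform of a gene they came from: most
reads fall in exons shared by several isoforms, and some isoform pairs are
indistinguishable at short-read resolution altogether. `netquant`
supplements the read likelihood with biological prior knowledge: isoforms
whose protein products interact through protein domain–domain contacts tend
to be co-expressed, so the expression of a transcript's *network neighbors*
is informative about its own abundance. The package builds a transcript
interaction network from Pfam domain annotations and domain–domain
interaction (DDI) tables, places a Dirichlet prior derived from that
network on every gene's isoform proportions, and estimates all genes
jointly.

## Model

For gene *i* with isoforms *k = 1..K*, reads are modeled as draws from a
mixture with proportions `p_ik` and per-read sampling probabilities
`q_ijk = 1/(l_ik − l_r + 1)`; the per-gene ("uncommitted") log-likelihood
over read equivalence classes *e* with multiplicities `c_e` is

```
ll_i(p) = Σ_e c_e · log Σ_k p_ik q_ek .
```

The network prior gives transcript *ik* a pseudo read count equal to its
length times the mean reads-per-base expression `π` of its neighbors:

```
φ_ik = l_ik · mean{ π_u : u ∈ N(i,k) },      α_ik = λ φ_ik + 1 ,
```

and gene *i*'s proportions get a Dirichlet(α_i) prior. The joint
pseudo-likelihood (product over genes of prior × likelihood, with every φ
computed from the current global state) is maximized by acceptance-guarded
coordinate ascent: per gene, an EM step with fixed φ proposes new
proportions (`p_k ∝ λφ_ik + expected assigned reads`), and the proposal is
kept only if the portion of the joint objective involving that gene
strictly increases. λ = 0 recovers independent per-gene maximum-likelihood
EM. Outputs per transcript: read-origin probability `p`, relative molar
abundance `ρ_ik = (p_ik/l_ik)/Σ(p/l)`, and expression
`π_ik = |r_i| p_ik / l_ik` (reads per base).

## Worked example

```python
import numpy as np
from netquant import (Gene, Transcript, TranscriptCatalog,
                      CompatibilityMatrix, GeneCompat,
                      TranscriptNetwork, NetworkTranscriptModel)

catalog = TranscriptCatalog([
    Gene("A", (Transcript("a1", 1000), Transcript("a2", 1000))),
    Gene("B", (Transcript("b1", 1000), Transcript("b2", 1000))),
])
q = 1 / (1000 - 76 + 1)                      # 76-nt reads
compat = CompatibilityMatrix(catalog, [
    GeneCompat(counts=[9, 1], q=[[q, 0], [0, q]]),   # A: unique reads 9:1
    GeneCompat(counts=[10],   q=[[q, q]]),           # B: fully ambiguous
])
net = TranscriptNetwork(catalog, np.array([[0, 2]]))  # edge a1 - b1

base = NetworkTranscriptModel(compat, net, lam=0.1).fit_base()
res  = NetworkTranscriptModel(compat, net, lam=0.1).fit(seed=0)
print("base p:", np.round(base.p, 3))
print("net  p:", np.round(res.p, 3))
print(res.summary())
```

prints

```
base p: [0.9 0.1 0.5 0.5]
net  p: [0.909 0.091 1.    0.   ]
Network-regularized transcript quantification
==============================================
genes                 2
transcripts           4
lambda                0.1
outer rounds          3
gene updates          6 accepted / 0 rejected
final pseudo-loglik   -138.607098
wall time             0.00 s
```

Gene B's reads are completely ambiguous, so the per-gene baseline can only
report 0.5/0.5. The joint model sees that `b1` interacts with the highly
expressed `a1` and resolves the tie toward `b1`; gene A's well-identified
9:1 split moves only marginally (0.900 → 0.909, the prior adds ≈1 pseudo
read).

## Command line

```
netquant simulate  --genes 100 --reads 200000 --seed 1 --out-prefix sim
netquant quantify  --catalog sim.catalog.tsv --compat sim.compat.tsv \
                   --network sim.network.tsv --lambda 0.1 --out res.tsv
netquant netstats  --catalog sim.catalog.tsv --network sim.network.tsv
netquant build-net --catalog cat.tsv --domains pfam.tsv --ddi ddi.tsv \
                   --ppi ppi.tsv --out edges.tsv
netquant coexpr    --catalog cat.tsv --network edges.tsv --expr expr.tsv
```

Canonical formats are plain TSVs (catalog, equivalence-class table, edge
list, result table); GTF catalogs and SAM/BAM alignments against
transcript sequences are supported as importers.

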