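# Methods

## Model

Each gene *i* has isoforms *k = 1..|T_i|* with lengths `l_ik`. A read of
length `l_r` aligned to gene *i* is modeled as generated by isoform *k*
with probability `p_ik` (Σ_k p_ik = 1) and, given the isoform, sampled
uniformly over its `l_ik − l_r + 1` start positions, so
`q = 1/(l_ik − l_r + 1)` per compatible isoform (`q = 0` when
`l_ik < l_r`, the natural limit of the formula). Reads with the same
compatible-isoform set and q-vector are collapsed into equivalence classes
with multiplicities; the class form of the likelihood is exactly the
per-read product, so classes are sufficient statistics.

The uncommitted per-gene log-likelihood is
`ll_i(p) = Σ_e c_e log Σ_k p_ik q_ek`. It is concave but typically has
plateaus: a class compatible with several isoforms constrains only a
weighted sum of their proportions, and isoforms with identical
compatibility signatures are not identifiable from reads at all.

The network prior addresses exactly this unidentifiability. With a
transcript interaction network S (binary, symmetric, no within-gene
edges), the prior read count of transcript *ik* is its length times the
mean reads-per-base expression of its neighbors,
`φ_ik = l_ik · mean(π_u, u ∈ N(i,k))` with `π_u = |r_g| p_u / l_u`, and
gene *i*'s proportions receive a Dirichlet prior with
`α_ik = λ φ_ik + 1`. Transcripts without neighbors get `φ = 0`, i.e. a
flat prior. Genes without reads have `π = 0` everywhere and therefore
contribute nothing to their neighbors' priors.

## Optimization

The joint pseudo-likelihood — the product over genes of Dirichlet prior
density times read likelihood, with all φ computed from the current global
state — is maximized by coordinate ascent over genes in fixed catalog
order. Per gene: (1) φ_i is computed from the current state; (2) EM with
the prior held fixed proposes new proportions, iterating the soft
assignment `a_ek = p_k q_ek / Σ_k p_k q_ek` and the closed-form update
`p_k ∝ λφ_ik + Σ_e c_e a_ek` from the gene's current proportions until
`max|Δp| < 1e-8` (at most 1000 iterations); (3) the proposal is accepted
only if the *local acceptance objective* strictly increases. That
objective contains every term of the joint pseudo-log-likelihood that
depends on the gene's proportions: its own prior and likelihood, plus the
prior terms (log-normalizer and λφ·log p) of all neighbor genes, whose φ
change with the candidate through π. Ties keep the old value. Because the
remaining terms are unchanged, each accepted step increases the joint
objective by exactly the local difference, so the trace of the joint
pseudo-log-likelihood at acceptance events is non-decreasing by
construction; the trace is maintained incrementally from these local
differences and re-checked against a from-scratch evaluation in the tests.

The EM proposal maximizes the gene's prior × likelihood with φ fixed — it
does not see the neighbor-prior feedback terms, which enter only through
the acceptance guard. The ascent's fixed point can therefore differ
slightly from the exact joint maximizer (the two-gene example in the test
suite quantifies this); this is inherent to the algorithm, not a
tolerance issue.

The outer loop stops when the largest per-transcript proportion change
over a full round falls below 1e-6 (default) or after 100 rounds. On the
simulated 100-gene datasets convergence takes 5–7 rounds.

Numerical choices: all comparisons in log space; Dirichlet normalizers via
log-gamma; `log p` floored at 1e-12 inside logarithms only (stored
proportions may be exactly zero — plateau corners are legitimate);
mixture probabilities floored at 1e-300 inside EM to avoid division by
zero; incremental neighbor-expression sums clamped at 0 against floating
round-off. Initialization is per-gene base EM by default (deterministic);
`uniform` and seeded `random` (flat Dirichlet) are available. λ defaults
to 0.1.

## Parameters

| parameter | default | meaning |
|---|---|---|
| λ | 0.1 | prior weight; pseudo-counts λφ against aligned reads. 0 = independent per-gene EM |
| outer tol | 1e-6 | max per-transcript proportion change per round |
| inner tol | 1e-8 | per-gene EM stopping rule |
| max rounds | 100 | outer-loop cap (warning on non-convergence) |
| l_r | 76 nt | read length used for q and the simulator |

The ratio of prior to data is scale-free in sequencing depth: both λφ and
the assigned read counts grow linearly with depth, so λ compares the
neighbor-mean expression against the gene's own — λ ≈ 1 weighs them
equally, which in our simulations over-weights the prior (see
Limitations).

## Network construction and statistics

Transcripts are annotated with Pfam domains (hits filtered at e-value ≤
1e-5); two transcripts of *different* genes are connected when any of
their domain pairs appears in the DDI table. Structure-derived DDIs are
used directly; computationally predicted DDIs (high/medium confidence)
support an edge only when the gene pair is also present in a
protein–protein-interaction table, and are excluded entirely when no PPI
table is supplied. Within-gene edges are never created: the model only
exploits positive co-expression between isoforms of different genes.

Graph statistics follow the field's reporting conventions: density is
E/(V(V−1)/2) as a percentage; average neighbors 2E/V; diameter on the
largest connected component; mean local clustering with degree-<2 nodes
counted as 0. Pathway co-membership tallies use the ordered-with-self
denominator V² — both conventions are implemented where each analysis
needs them. Randomizations: label permutation (degree multiset and E
preserved; collisions that would create a within-gene edge are repaired by
transposing the offending label with a random one), uniform edge
resampling among cross-gene pairs, and uniform edge removal. The
co-expression overlap analysis ranks all cross-gene transcript pairs by
Pearson correlation (ties broken by transcript-id pair; constant rows
excluded with a logged count), counts network-linked pairs per bin
(distance 1, or ≤ 2 via the boolean square of the adjacency), and
compares the first bins against the rest with a 2×2 chi-square test
without continuity correction (the canonical large-sample choice).

## Synthetic data generator

The generator produces the statistical structure the model assumes, so
that joint estimation is testable end to end without external data.

**Catalog.** Each gene is a chain of 3–10 exon segments (100–300 nt).
Isoforms are contiguous segment windows all containing a common anchor
segment, so every isoform pair overlaps and ambiguous reads always exist;
isoform count per gene is 1–4 (mean 2.5). With probability 0.4 an
additional isoform reuses an existing window, creating structurally
identical isoforms — indistinguishable at read level, as is common for
annotated isoforms that differ only in features invisible to short-read
exon/junction evidence. This unidentifiable mass is precisely the regime
where outside information matters.

**Truth.** Gene totals are Poisson(μ = 500) on a read scale. Within-gene
shares come from normalized Pareto draws (tail exponent γ = 1.5) with
multiplicative Gaussian noise (σ = 0.1), truncated at zero, and are
converted to reads-per-base by dividing by length. A single sequential
pass over transcripts in catalog order then adds w = 1 times the mean
per-base expression of each transcript's network neighbors
(already-updated neighbors contribute updated values). Coupling on the
per-base scale matters: it plants the co-expression signal in exactly the
unit the model's prior propagates. Read-origin proportions are
proportional to expression × length.

**Network.** Uniform random cross-gene edges at an average degree of 27
neighbors per transcript, matching the average neighbor count of the
smaller reference DDI transcript network — the quantity the prior
mechanism actually averages over. (At ~250 transcripts this makes the
graph denser in percentage terms than that network; degree, not density, is what the
prior and the ablation experiments depend on.)

**Reads.** A read picks a transcript with probability ∝ π · (l − l_r + 1)
and a uniform start. Sampling is performed at the level of exact
sufficient statistics — multinomial over transcripts, then multinomial
over the start-position runs within which the covered segment window is
constant — which is distributionally identical to drawing reads one at a
time and collapsing them, and much faster. Compatibility of a window with
an isoform is exact containment of the covered segment run. No sequencing
errors, positional bias, or fragment-length model; paired ends are not
modeled (each mate would be an independent read).

**Recovery metric.** Pearson correlation between log2(π + 1) of estimate
and truth over multi-isoform transcripts (or the subset whose isoforms
have different neighbor sets). The estimated profile is rescaled to the
truth's total expression first; the two otherwise live on different read
scales, and the rescaling is applied identically to every method.

What passing these simulations does *not* show about real data: the reads
here follow the model exactly (no bias, no misalignment), the planted
network signal is exactly the model's prior unit, and the
unidentifiable-isoform mass is controlled by one knob. Real improvements
depend on how well DDI neighborhoods track true co-expression.

## Study sizes used in tests

The recovery study runs 10 replicate datasets of 100 genes
(~250 transcripts, 200 000 reads, 27 mean neighbors), three prior weights
λ ∈ {0.01, 0.1, 1}, 20 label-permuted null networks, and edge removal at
10/20/90 % — sizes chosen so the whole study completes in about two
minutes on one CPU while keeping per-gene depth (~2 000 reads) high
enough that the baseline is strong.

## Known limitations

- **λ ≈ 1 over-weights the prior here.** With the deterministic
  uniform-init per-gene baseline (which sits at the best blind point of
  every likelihood plateau) and truth that adds the neighbor mean once,
  a prior weighted comparably to the read evidence double-counts the
  coupling and degrades well-identified genes; in our simulations only
  λ ≲ 0.1 improves mean recovery.
- **Sparse priors on exact plateaus produce corner solutions.** For
  structurally identical isoforms the posterior mode with
  α = (1 + λφ, 1) lies on the simplex boundary; when heavy edge ablation
  leaves a single noisy neighbor, whole genes can be driven to (1, 0)
  allocations that are worse than the uniform split. Robustness to edge
  loss holds for light ablation (≤ 20 %) but not in the near-empty
  regime.
- Multi-locus reads are resolved by primary alignment (or optional
  q-splitting across loci); there is no iterative cross-gene
  reassignment.
- Point estimates only; no uncertainty quantification.
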