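# Methods

This note records the models, conventions and design choices behind
`splicemap`, in the spirit of a statistical methods appendix.

## Phylogenetic covariance and the GLS association test

Under Brownian motion on a rooted tree with branch lengths, trait
covariance between two species equals the rate times their shared path
length from the root, and variance equals the root-to-leaf distance. The
covariance builder (`phylo.tree_covariance`) implements exactly this; it
accepts polytomies literally and zero-length branches (which produce tied
rows — a warning is raised and the GLS layer ridge-regularizes by
`1e-8 · tr(Σ)/n` only when the Cholesky factorization actually fails).
Unrooted trees are rejected: both the covariance and Dollo parsimony are
defined relative to a root, and rooting via outgroups is an upstream task.

The GLS fit uses Cholesky whitening: with `Σ = LLᵀ`, regress `L⁻¹y` on
`L⁻¹X` by least squares. Coefficients are invariant to scaling `Σ` by any
positive constant (the residual variance absorbs it), so the branch-length
units of the input tree never matter for inference. Collinear designs are
rejected with the offending column named. No Pagel-λ or other covariance
transform is applied: the raw tree covariance is the model.

### Bootstrap replicates and Rubin pooling

Phenotypes arrive with B bootstrap replicates (default 100) obtained by
resampling each species' conserved introns. Each replicate is fitted
separately and the fits are pooled like multiple-imputation estimates:
pooled estimate `Q̄` = mean; total variance `T = W + (1 + 1/m)B` with `W`
the mean squared SE and `B` the between-replicate variance; degrees of
freedom by the Barnard–Rubin small-sample formula using the GLS residual
df (`n − p`) as the complete-data df. Since the replicate fits share the
design and covariance, the scan whitens once per genotype and solves all
replicates as a multi-RHS least-squares problem.

A property of this scheme worth knowing: measurement noise enters both
the per-replicate residual variance (hence `W`) and the between-replicate
variance `B`, so it is counted twice and pooled p values become
conservative as the replicate spread grows relative to the Brownian
signal. At the defaults (replicate SD 3% of the between-species trait SD,
the intron-rich regime) the measured null rejection rate at p < 0.05 is
≈ 0.04, and it converges to 0.05 exactly as the replicate noise goes to
zero. For species with very few introns the test loses power but does not
become anticonservative.

BH correction is applied once across all orthogroups of a scan; the
per-residue scan is corrected separately across alignment columns —
mirroring the two analyses' separate hypothesis families.

## Genotypes

Orthogroup presence/absence comes from an Orthofinder-style TSV (presence
= non-empty cell; gene counts retained). The Dollo filter keeps
orthogroups present in ≥ 5 species with ≥ 2 independent losses: under a
single gain at the MRCA of the present species and irreversible loss, the
minimum loss count is the number of maximal all-absent subtrees below the
gain node, which the implementation counts directly (and which matches
exhaustive enumeration over all single-gain histories in the tests). The
two-loss floor prevents an association from being driven by one clade.

Per-residue genotypes score each aligned ortholog residue against a
consensus row with BLOSUM62 and standardize per column. Gaps and
ambiguous residues (X/B/Z) are treated as missing — not penalized —
because a penalty would conflate ortholog absence with divergence; the
species simply drops out of that column's test. Zero-variance columns are
dropped. Standardization uses the population SD (ddof = 0); GLS inference
is scale-invariant, so this convention cannot affect p values.

## Splice-site phenotypes

Ratio phenotypes are `log2((count_num + 0.5)/(count_den + 0.5))`.
The log scale makes the quantity signed and symmetric (A:U = −U:A —
computed as a difference of logs so the antisymmetry is exact in floating
point), and the 0.5 pseudocount keeps it finite for species with few
introns. The acceptor −3 C/U phenotype reuses the identical code path on
the acceptor window's −3 column.

The per-species donor PSSM is `log2((count + 0.5)/(n + 2))` over
positions −3..−1 and +3..+7; no background normalization is applied
because any per-position additive constant cancels in the rank
correlation of score sums (asserted exactly in the tests on
dyadic-rational matrices). Sites containing N at a scored position are
excluded from both PSSM construction and scoring. U5/6ρ is the Spearman
correlation of per-site U5 (−3..−1) and U6 (+3..+7) sums, with a
bootstrap CI that recomputes the PSSM inside every resample; constant
score vectors yield NaN with a warning rather than an arbitrary value.

The ±0.2 threshold used elsewhere to discretize +4 preference is
interpreted on the log2 scale and kept configurable.

## Conserved-intron filter

An intron maps to the alignment column of its host residue (counting
non-gap characters); "frame" is interpreted as intron phase (0/1/2 bases
of the interrupted codon 5' of the intron). A phase-0 intron sits between
codons and its residue index refers to the preceding complete residue.
Introns are conserved when ≥ 2 *distinct species* share the same
(column, phase) within an orthogroup — paralogs of one species do not
count. Orthogroups averaging more than 2 orthologs per species are
skipped (configurable, default on). The filter is idempotent and
order-independent; both are tested.

Extraction from genome FASTA + GFF3 infers introns between consecutive
CDS segments, with coordinates treated as 1-based inclusive, cumulative
coding length giving residue index `(c−1) // 3` and phase `c mod 3`, and
windows reverse-complemented on the minus strand (padded with N at contig
ends).

## Ancestral reconstruction

Sankoff parsimony runs over all compositions of (A, C, G, T) fractions on
a 0.05 grid (1,771 states) with an L1 transition cost; the cost of the
cited prior method is not restated anywhere accessible, so the metric is
configurable (L1 default, L2 available). L1 costs are computed in integer
grid units so parsimony ties are exact, and ties are broken toward the
lexicographically smallest state tuple, making the reconstruction fully
deterministic. Leaf fractions are snapped to the grid by largest-remainder
rounding, which preserves the sum-to-one constraint that plain rounding
can break.

Continuous-trait ancestral states are joint maximum-likelihood estimates
under Brownian motion: for any rate, the ML internal states minimize
`Σ_edges (x_parent − x_child)²/t`, a sparse linear (resistor-network)
problem whose root solution equals the GLS phylogenetic mean. Variances
are the conditional variances of internal states given the tips, scaled
by the ML rate estimated from the tips. Traitgram tables join node times
(root-to-node distance) with these estimates, tips carrying their
observed values.

## Domain segmentation

Residue pairs with both pLDDT > 70 and symmetrized PAE < 5 Å are joined
with weight 1/PAE (PAE floored at 0.2 Å so near-zero errors do not
produce unbounded weights; directional PAE is averaged because the
provider's orientation convention is not reliable). Greedy modularity
maximization with deterministic node ordering partitions the graph;
communities under 20 residues are discarded and their residues reported
as unassigned, as are all low-confidence residues (which never acquire
edges). Structure superposition and TM-score clustering of the resulting
domains are out of scope; the module emits residue ranges for external
tools.

## Synthetic data generator

The generator produces every input the pipeline reads, with known ground
truth, under one seed (all generators are bit-reproducible):

- **Tree**: Yule (pure-birth) via dendropy, made strictly ultrametric,
  tip edges extended past the last birth event so no terminal branch is
  zero, and rescaled to unit height — the standard convention in
  comparative-method simulations, under which a Brownian rate of 1 means
  unit trait variance at the tips and branch lengths read as fractions of
  total time. A birth–death model was considered and rejected: extinction
  adds nothing to what the tests measure.
- **Genotypes**: loss on each branch with probability
  `1 − exp(−rate · length)`, irreversible. The default rate (0.4 per unit
  height) leaves ~70% of species with the gene, matching the presence
  fractions of the splicing factors this kind of study focuses on, and
  typically produces several independent losses.
- **Phenotypes**: `y = β₀ + β·g + ε`, `ε ~ N(0, σ²Σ)` with σ² = 1 and
  β = 1 by default. Measured estimates add i.i.d. noise (SD 0.03, a few
  percent of the between-species spread, emulating log-ratio sampling
  error in intron-rich species) and replicates scatter around the
  estimate with the same SD, as intron bootstrap replicates do.
- **Introns**: toy orthogroups from a mutated ancestral protein
  (substitutions and deletions only, so alignment columns are ancestor
  coordinates); conserved introns occupy shared (column, phase) slots,
  spurious introns occupy slots private to one species, so expected
  filter outcomes are exact. Donor windows are GT at +1+2 with
  `P(+4 = A) = logistic(base + shift·g)` and the rest of the +4 mass on
  T, so the measured log2 A:U ratio has expectation `(base + shift·g)/ln 2`.
- **Confidence**: planted block-diagonal PAE with uniform jitter and a
  low-pLDDT tail.

What the generator does *not* emulate: indels requiring real alignment,
rate variation among lineages, per-species intron-count heterogeneity
over orders of magnitude, correlated loss of interacting factors, and
non-Brownian trait evolution. Passing tests therefore demonstrate
correctness of the machinery and calibration under the stated model, not
robustness to violations of it.

## Problem sizes and numerical choices

The test-bench study uses 150 species, 100 bootstrap replicates, 50 null
orthogroups and 200–1,000 simulated tests per statistical check — sizes
at which the full suite runs in about a minute on a laptop core while
keeping Monte-Carlo error well below the asserted tolerances. Oracle
comparisons use exhaustive enumeration at small n (≤ 8 leaves for Dollo,
≤ 5 leaves / 35 states for Sankoff) where brute force is exact.
Degenerate cases are handled explicitly: exact linear fits report
σ̂² = 0 and p = 1 for null coefficients; all-absent genotypes,
single-tip trees, empty confidence graphs and all-N columns raise or
return empty results with warnings rather than silently proceeding.
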