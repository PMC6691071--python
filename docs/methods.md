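# Methods and conventions

This note records the statistical conventions, default parameters, and
numerical choices baked into `ecosig`, including the points where the
underlying methods admit more than one reasonable reading and which one
this package implements.

## Tetranucleotide signatures (`ecosig.signatures`)

- **Counting.** 1-nt sliding window over the forward strand plus the full
  reverse complement of the sequence; per-word counts from the two strands
  are summed. No junction windows are created between the strands.
  Windows containing `N` are skipped; other IUPAC ambiguity codes are
  rejected at parse time.
- **Expectation and variance (maximal-order Markov).** For word
  `w = n1n2n3n4`:
  `E = N(n1n2n3)·N(n2n3n4)/N(n2n3)`,
  `var = E·(N(n2n3)−N(n1n2n3))·(N(n2n3)−N(n2n3n4))/N(n2n3)²`,
  `Z = (N(w)−E)/sqrt(var)`. Cells with `E = 0` or `var = 0` are set to
  `Z = 0` (no evidence either way).
- **Exact strand symmetry.** `Z(w)` and `Z(revcomp(w))` are mathematically
  equal, but naive evaluation produces last-bit floating-point differences
  because the multiplications associate differently. Both cells of a
  `(w, revcomp(w))` pair are therefore assigned the value computed for the
  lexicographically smaller word, making the symmetry bitwise exact.
- Minimum sequence length is 4 (one window); profiles always span all 256
  cells.

## Comparative analyses (`ecosig.comparative`)

- **Distances.** Euclidean distance between Z-profiles is the default for
  ordination, ANOSIM, and trees. Pearson dissimilarity is provided with
  two conventions: `one_minus_r` (`d = 1 − r`, default) and `half`
  (`d = (1 − r)/2`). The choice is a flag because the literature uses both.
- **nMDS.** Kruskal stress-1, `sqrt(Σ(d_ij − d̂_ij)² / Σ d_ij²)`, with
  disparities `d̂` from isotonic regression on the rank-ordered condensed
  distances and configurations updated by the Guttman transform (SMACOF).
  Default 1000 starts: start 0 is classical (Torgerson) scaling; starts
  1..k−1 are random with per-start seeds derived as
  `default_rng([seed, start])`. A start converges when the stress-1
  improvement drops below 1e-7 (300-iteration cap). The best start wins;
  ties go to the lowest start index, which makes best-of-10 a strict
  prefix of best-of-1000 and the stress therefore monotone in the number
  of starts. An in-module SMACOF loop is used rather than
  `sklearn.manifold.smacof` because the latter's convergence criterion is
  relative raw stress and effectively never triggers at tight tolerances,
  making 1000-start runs impractically slow; `sklearn` is retained in the
  test suite as an independent oracle (our stress is required to match or
  beat it).
- **ANOSIM.** `R = (r̄_between − r̄_within)/(M/2)` on mid-ranks of the
  condensed distances, `M = n(n−1)/2`. Significance by label permutation
  with the add-one estimator `p = (1 + #{R_perm ≥ R_obs})/(1 + n_perms)`,
  default 999 permutations. R is invariant under any monotone transform of
  the distances (rank-based), which the tests verify.
- **Neighbor joining.** Saitou–Nei Q-criterion; ties broken by the
  row-major smallest `(i, j)` pair. Negative branch lengths are clamped to
  zero with the deficit moved to the sister branch, preserving path
  lengths. The result is unrooted (trifurcating root). Exact on additive
  matrices.
- **Bootstrap and consensus.** Bootstrap replicates resample the 256
  signature columns with replacement, recompute the distance matrix, and
  rebuild the NJ tree; default 500 replicates. The majority-rule consensus
  keeps bipartitions present in strictly more than 50% of trees, annotated
  with support percentages. Branch lengths on the consensus (a convention
  this package had to pick): internal edges take the mean length over the
  trees containing that bipartition, pendant edges the mean over all
  trees. Newick output quotes names containing metacharacters (including
  underscores, which unquoted Newick readers fold to spaces).

## Ecogenomic profiling (`ecosig.ecogenomics`)

- **Input.** 12- or 13-column tab-separated hit tables (the standard
  tabular search output, optionally with query length as column 13).
  Query coverage is computed as `100·aln_length/query_length`; when a
  13th column is absent, query lengths must be supplied separately, and
  hits with unknown lengths are reported by query ID. Coverage from
  alignment length (not subject-coordinate span) is one of the dialect
  choices this package fixes.
- **Validity profiles.** `METAGENOME` (identity ≥ 35%, coverage ≥ 50%,
  e ≤ 1e-5), `PHAGE_GENOME_AFFILIATION` (identity ≥ 35%, alignment ≥ 25,
  e ≤ 1e-5), `HOST_GENUS_AFFILIATION` (e ≤ 1e-3), `ANNOTATION`
  (identity ≥ 20%, e ≤ 1e-5). All thresholds inclusive on the kept side.
- **Abundance.** Hits/Mb = valid hits / dataset size in Mb, with sizes
  taken from the dataset manifest (authoritative). Cumulative abundance
  per phage is the exact sum of its ORFs' Hits/Mb values.
- **Affiliation.** Top hit by bit score; ties broken by smaller e-value,
  then lexicographically smaller subject ID (deterministic).
- **Habitat comparison.** Kruskal–Wallis across habitat classes
  (`ENV, HGUT, HORAL, HBODY, HGV, UTV`), followed by Dunn's z-tests with
  tie correction; p-values adjusted by Bonferroni (default) or Holm.
  Habitats with fewer than two datasets are excluded with a warning.
  All-identical values yield `H = 0, p = 1` rather than an error.

## Synthetic data (`ecosig.synthetic`)

What the generator emulates: genomes whose compositional signal is an
order-3 Markov structure — the weakest signal the tetranucleotide Z-score
is designed to detect, since Z measures exactly the deviation beyond what
2-/3-mer composition predicts. Phage genomes are drawn from their host's
model directly (not by mutating host sequence): the analysis measures
composition, not homology, and this isolates the assumption under test.

What it does **not** emulate: genes, codon structure, GC skew, repeats,
horizontal transfer mosaicism, or read-level artifacts. Hit tables are
Poisson counts with planted rates, not alignments.

- **Host-model construction.** Each host is an independent random model
  (transition rows from a symmetric Dirichlet; default concentration 1.0)
  mixed with the uniform i.i.d. chain. The mixing weight is calibrated
  per host, by bisection, so that every host has the same *model-implied
  signature amplitude* — the asymptotic `||Z||/sqrt(L)`, computed
  analytically from the model's stationary 4-, 3-, and 2-mer frequencies
  (reverse-complement-symmetrized, same standardization as the signature).
  The common amplitude equals `divergence_between_hosts` times the
  smallest raw-draw amplitude, so divergence 0 gives identical (uniform)
  hosts and larger divergence gives stronger, farther-apart compositions.
  Equal amplitude matters because signature norms grow with both amplitude
  and genome length: without calibration, a host model whose Dirichlet
  draw is accidentally bland attracts every phage in a Euclidean
  comparison for reasons unrelated to host-of-origin signal. Amplitude is
  monotone in the uniform-mixture weight (it starts at zero), which makes
  the bisection well-posed; mixing toward a skewed shared base instead is
  non-monotone (deviations cancel mid-mixture) and was rejected.
- **Defaults.** Hosts 2 Mb, phages 40 kb — realistic replicon scales that
  keep a full panel in seconds. The optional migrant phage is generated
  from host 0's model but labelled as infecting host 1; at divergence
  ≥ 0.5 its signature points back to host 0 (the recent-host-switch
  scenario the method is meant to expose).
- **Determinism.** Every generator is a pure function of (params, seed);
  seeds fan out through `SeedSequence` so records are independent.

## Pipeline (`ecosig.pipeline`, `ecosig.cli`)

- Stage seeds derive from the master seed as
  `sha256("{seed}:{stage}") mod 2³¹−1`, so stages are decoupled and runs
  are byte-identical for identical configs (`run_manifest.json` records
  SHA-256 checksums of every output).
- Stages degrade independently: with too few sequences for ordination or
  trees, the signature table is still written and the failing stages are
  recorded in `stage_errors` rather than aborting the run.

## Problem sizes

Default analysis sizes (1000 nMDS starts, 500 bootstrap replicates, 999
permutations) are the package's own choices of robust defaults; all are
configurable. The full test suite runs in ~1.5 minutes; the acceptance
script in ~1–2 minutes on one CPU.
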