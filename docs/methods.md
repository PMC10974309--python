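# Methods

This note records the models and procedures implemented in `evesurveyor`,
the parameters that matter, and the choices made where the design was
genuinely open. No empirical number stated here is asserted anywhere except
where the test suite or `scripts/acceptance.py` computes it.

## Translated homology discovery

The search is a seeded, ungapped, six-frame translated alignment — the
classical tblastn architecture reduced to its ungapped core:

- Each contig is translated in frames +1..+3 (forward strand) and −1..−3
  (reverse complement); codons containing N become X; stop codons are kept
  as `*` and score −4 against everything, so extensions may cross the stop
  codons that degraded EVEs accumulate. Each residue carries a map back to
  its 1-based inclusive forward-strand nucleotide interval.
- Seeds are exact 3-mer matches whose BLOSUM62 self-score is ≥ 11; each
  seed is extended without gaps in both directions under x-drop 20.
- Significance uses Karlin–Altschul statistics with the published ungapped
  BLOSUM62 constants λ = 0.318, K = 0.13: `bit = (λS − ln K)/ln 2`,
  `E = m·n·2^(−bit)` with m the summed query length and n the summed
  six-frame translated length (a deliberately simple search space — the
  product of totals, no per-pair edge correction). HSPs with E ≥ 1e−5 are
  discarded; the threshold matches the BlastN criterion used for the
  genome comparison this pipeline emulates.
- Same-contig, same-strand HSPs within 100 nt (tunable) merge into loci by
  union of intervals; opposite-strand HSPs never merge, which is what keeps
  two overlapping insertions in opposite transcriptional orientations —
  the NcP1.1/NcP1.2 configuration — as distinct loci.
- Context: a locus is INTRONIC only if fully contained in one intron
  (the gap between consecutive exons of one transcript), EXONIC if it
  intersects any exon (so junction-straddling loci are EXONIC), else
  INTERGENIC. Relative orientation compares locus strand with the host
  gene strand.

Gapped extension is omitted: planted-element recovery at the divergences of
interest (≤ 35 % amino-acid) does not require it, and ungapped HSPs keep
the E-value theory exact. The per-diagonal optimal ungapped segment is used
as an independent oracle in tests (Kadane scan over every frame/diagonal);
the x-drop extension attains the oracle score on planted instances. The
x-drop heuristic can in principle truncate at an internal score drop
deeper than 20 (≈ six consecutive worst-case mismatches); this is invisible
at the divergences simulated.

Coordinates are 1-based inclusive everywhere in memory and in TSV output;
only the BED6 export converts to 0-based half-open. `locus_span_length`
implements the span convention used for published supercontig coordinates:
`|a − b| + 1`, minus orientation when the pair is descending.

## Synthetic data

The generator's job is to reproduce the *study conditions*, not sequencing
realism:

- **Genome**: i.i.d. bases at a configurable GC content (default 0.40),
  gene models laid out left-to-right (`gene → mRNA → exon`, GFF3, 1-based)
  with configurable exon/intron geometry.
- **Insertions**: a contiguous fragment of a (supplied or generated) viral
  protein is reverse-translated with a fixed most-frequent-codon table
  (determinism over realism), degraded by mutating a fraction of codons to
  random different sense codons (`aa_divergence` — measured in codon edits,
  so the realized amino-acid divergence is slightly lower through synonymous
  edits), optionally adding stop codons and single-base frameshifts, then
  written over an equal-length window centred in the target intron / exon /
  intergenic segment. Replacement (rather than splice-in) keeps every
  gene-model coordinate fixed and makes "fragment longer than the available
  region" a real, testable error. Orientation is applied relative to the
  host gene strand.
- **Small RNA**: reads sampled from the planted locus with a configured
  length distribution (piRNA-like default peaks over 24–29 nt; degradation
  default is uniform 15–35 nt at 40 reads; siRNA-like 20–22 nt), strand
  fraction, and per-position sampling weights (hotspot windows weighted
  10×). `u_bias` is the *exact* probability that the 5′ base is U/T: the
  first base is set to T with that probability and to a non-T base
  otherwise. This makes the null of the 5′-U test exactly 0.25 regardless
  of genome composition, at the cost of ≤ 1 planted mismatch per read
  (within the aligner's tolerance). Qualities are constant Q40, Phred+33.
  Background reads are drawn uniformly from the non-EVE genome on random
  strands to exercise aligner specificity.
- **Panels**: per-sample DNA contains the EVE-bearing region (± 60 bp
  flank) iff the sample carries the element; cDNA contains the
  EVE-spanning transcript segment iff it transcribes it; transcription
  without carriage is rejected. Every compartment carries a neutral decoy
  fragment so PCR-negative samples are non-empty.

What the generator does **not** emulate: transposable-element landscapes,
non-uniform base quality or realistic error profiles, splice isoforms,
exosomal packaging, population genetic structure. Passing tests therefore
demonstrate correctness of the decision chain under its stated assumptions,
not performance on real libraries — in particular the 100-read depth
threshold cannot be calibrated here for real, merged public libraries.

### Hotspot detection vs. hotspot simulation

Hotspots are called as maximal runs (≥ 10 nt) of pooled coverage ≥ 5× the
mean nonzero coverage. Both the 10× sampling multiplier and the 5× rule are
declared defaults. They interact: on a short locus whose background is
fully covered, total coverage mass fixes the mean, and read-length smearing
dilutes the peak, so a 10×-weighted window tops out below the 5× threshold.
Detection is therefore verified on concentrated coverage (most of the locus
near zero — the discontinuous pattern real piRNA loci show), and the
profile classifier deliberately does not depend on hotspot calls.

## Small-RNA profiling and classification

Filtering follows the standard small-RNA recipe: optional 3′-adapter
trimming first (leftmost suffix match of ≥ 6 nt against the adapter prefix,
≤ 1 mismatch per 10 nt of overlap), then removal in fixed order — mean
Phred < 20, ambiguous bases, < 15 nt, > 35 nt — with each read attributed
to exactly one reason. "Low Phred quality" is interpreted as *mean* read
quality (the criterion's min/mean choice is not standard); it is a config
field. Phred+64-looking input (decoded qualities > 45) is rejected with an
explicit error.

Alignment reports every end-to-end placement with ≤ 1 mismatch (no indels)
on either strand; under the default ALL_BEST rule only each read's
minimal-mismatch stratum is kept and placements share weight 1/k. A
sliding-window byte comparison is used; a brute-force scan oracle checks it
on randomized instances.

The profile accumulates weighted size histograms per strand, 5′-base counts
(the read's first *sequenced* base), per-base coverage, and the Gini
coefficient of pooled coverage. Classification thresholds operationalize
qualitative criteria and are all tunable:

| parameter | default | role |
|---|---|---|
| `min_reads` | 100 | depth below which only DEGRADATION/INSUFFICIENT are possible |
| `pirna_len_lo/hi` | 24/29 | piRNA size class |
| `min_pirna_fraction` | 0.5 | majority rule for the size class |
| `min_strand_fraction` | 0.8 | single-strandedness for piRNA calls |
| `sirna_len_lo/hi` | 20/22 | siRNA size class (both-strand signature) |

The 5′-U enrichment test is an exact one-sided binomial test of the 5′-T
count among 24–29 nt reads against p₀ = 0.25, with fractional weights
rounded to integers; zero piRNA-class reads yield the sentinel
(u undefined, p = 1). Its type-I error and power are verified by simulation
through the read generator (1000 null replicates at n = 500; power at
5′-U probability 0.8). Ping-pong (secondary piRNA) signatures are out of
scope: the profile of interest here is primary-piRNA production only.

## Phylogenetics

The JTT replacement process is a time-reversible CTMC built from the
published exchangeabilities and frequencies: `Q_ij = S_ij π_j`, diagonal
set to −row sums, normalized so −Σ π_i Q_ii = 1 (branch lengths in expected
substitutions per site). `P(t) = exp(Qt)` is computed once per branch from
the eigendecomposition of the symmetrized matrix
`diag(√π) Q diag(1/√π)`; tiny negative entries are clamped and rows
renormalized. Note the spectral gap: JTT's slowest mode decays as
`exp(−0.41 t)`, so rows of P(t) approach π only at t ≳ 20.

- **Distances**: pairwise deletion of gap columns, then 1-D bounded
  maximization of Σ log(π_a P_ab(t)) on t ∈ [1e−6, 10]; saturated pairs
  return the bound.
- **Starting tree**: Saitou–Nei NJ or BioNJ (variance-weighted reduction
  with λ clamped to [0, 1]); the two coincide on additive matrices, which
  tests exploit. Negative branch lengths are clamped to zero; Q-criterion
  ties break on the smallest index pair.
- **Likelihood**: Felsenstein pruning over compressed site patterns with
  per-node rescaling; gaps and unknown residues are missing data (partial
  likelihood of ones). Verified against exhaustive internal-state
  enumeration on small trees and against the re-rooting invariance implied
  by reversibility.
- **Branch lengths**: round-robin bounded 1-D maximization per branch until
  a sweep improves the log-likelihood by < 1e−6 (max 100 sweeps); monotone
  because a move is only accepted when it improves.

Topology search stops at the NJ/BioNJ topology: no NNI/SPR rearrangements,
no rate heterogeneity (+G), no bootstrap. For the data sizes this package
targets (a handful of short nucleocapsid fragments) the distance topology
with ML branch lengths is the defensible core; the original 11-taxon
alignment behind the published −1932.07 log-likelihood is not printed
anywhere and is therefore explicitly not a reproduction target — the
correctness claims are the property tests above, plus branch-length
recovery within ±0.05 on JTT-simulated 1000-site alignments.

## In-silico PCR survey

A primer anneals where it matches with ≤ 1 mismatch overall and no
mismatch in its 3′-terminal 3 bases (polymerase extension is blocked by a
3′ mismatch); N never matches. An amplicon is a plus-strand site of one
primer and a downstream minus-strand site of the other with 3′ ends facing,
product ≤ 3000 bp; product length spans the outer 5′ ends inclusive. These
stringencies are declared surrogates for real PCR specificity and are
tunable. A compartment (DNA or cDNA) scores POSITIVE on ≥ 1 amplicon,
NEGATIVE on none, ND when not provided — mirroring surveys where only one
nucleic acid could be extracted from a specimen.

Summaries exclude ND from denominators and report an internal consistency
check (`only_A + both ≤ A_positive`, totals ≤ n_samples) rather than
asserting any fixed published totals, since the published counts for this
kind of survey are not always internally consistent.

## Problem sizes and numerical conventions

Simulated genomes in the tests are 12–35 kb with 1–2 planted loci of
60–100 aa — large enough that E-values discriminate planted signal from the
best random diagonal by > 40 orders of magnitude, small enough for
brute-force oracles to run alongside every stochastic check. Read-level
checks use 40–10,000 reads per library; phylogenetic recovery uses 4–7
taxa and 300–1000 sites. All randomness flows through
`numpy.random.default_rng` seeds carried in configs; identical configs
produce byte-identical output files (fixed iteration orders, fixed float
formats, sorted JSON keys).

Known limitations, beyond those noted above: the aligner is O(loci ×
reads) and meant for locus panels, not genome-wide mapping; the survey does
not model primer thermodynamics; the discovery module's E-values assume
ungapped statistics and a single composite search space.
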