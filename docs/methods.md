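# Methods

`mtsirna` implements the computational arm of a transgene-regulation design
strategy: endogenous male-tissue-specific siRNAs (mts-siRNAs) are discovered
from multi-tissue small RNA sequencing, a transcript region densely covered by
their recognition sites is chosen as a target element, the element is placed
between a transgene's stop codon and 3'UTR, and tissue- and sequence-specific
cleavage of the resulting mRNA is verified from 5'RACE products. Because the
real inputs (proprietary germplasm, sequencing libraries, transformation
events) are not reproducible at desk scale, the package ships a synthetic-data
generator with planted ground truth, and validation is framed as recovery of
that truth.

## Discovery model

**Catalog.** Libraries are collapsed to distinct sequences with redundant read
counts, length-filtered to 18–26 nt (the operational definition of an
mts-siRNA), and normalised to TPM = count / denominator × 10⁶. The default
denominator is the post-filter library total: the comparison universe is the
18–26-nt population itself. The pre-filter total remains selectable
(`denominator_policy="raw"`) and is retained on every filtered library.
Sequences are stored in the DNA alphabet (U→T) so one alphabet serves
matching; reads containing N are discarded because ambiguous bases have no
place in exact/near-exact matching semantics.

**Specificity rule.** There is no canonical formula for "primarily expressed
in tassel", so the package states one explicitly: a sequence is called mts
when its maximum TPM over tassel libraries is ≥ `tau_min` (default 40, the
lower end of the abundance range these siRNAs show) *and* its maximum TPM over
every other library is ≤ max(`leak_abs`=1 TPM, `leak_frac`=0.05 × tassel max).
Enrichment is reported as tassel max / (other max + 0.1 TPM); the pseudocount
avoids division by zero and is small against the 40-TPM floor. The microarray
cross-check is a two-sided Welch t on log2(signal+1), target replicates vs all
pooled others, significant at raw p < 0.05 with the target mean higher;
Benjamini–Hochberg correction is available but off by default, matching the
uncorrected convention of the assay being emulated.

**Matching.** Placements are full-length, ungapped, ≤ `max_mm` substitutions
(default 1, configurable to 2): siRNA–target pairing is highly specific, and
gapped alignment would blur cleavage-site coordinates. The matcher is
seed-and-verify over an exact k-mer index with pigeonhole seeding: the query
is cut into `max_mm`+1 segments, one of which must be exact in any valid
placement, so looking up the k-mer at each segment start is complete whenever
k ≤ ⌊L/(max_mm+1)⌋. The default k=8 satisfies this bound for the shortest
(18-nt) queries at max_mm=1; `map_sirna` refuses k values that would break
completeness rather than silently missing hits. A brute-force sliding-window
scanner with identical semantics is kept as an independent oracle and the two
are required to agree on randomized instances. Minus-strand hits (siRNA
complementary to the transcript) are recorded at the matched window's
coordinates. Internally all coordinates are 0-based half-open; serialisers
emit 1-based inclusive.

**Clustering.** The coverage profile accumulates each hit's tassel TPM over
its footprint, per strand, with distinct-hit counters. Candidate regions are
fixed-width sliding windows (default W=201 nt, the width of the element this
workflow historically selected) scored by the number of distinct siRNAs whose
site is *fully contained* — an intact recognition site is required to direct
cleavage, and integer scores make windows comparable. Selection is greedy
best-first with overlap suppression; ties prefer larger TPM mass, then the
leftmost start. `min_distinct` defaults to 5 ("multiple" sites, made
explicit and configurable).

## Cassette design and screens

`assemble_cassette` concatenates CDS (must end TAA/TAG/TGA) + target element +
non-empty 3'UTR and records feature coordinates. Three screens gate a design:

* **miRNA sites** — ungapped antiparallel alignment of each known miRNA
  against every offset of the element; penalty = mismatches × 1 + G:U wobbles
  × 0.5, doubled over miRNA positions 2–13; a site is called at penalty ≤ 4.
  This is the widely used plant miRNA-target convention, encoded explicitly
  because the screen it reproduces named no rule. A clean element has zero
  calls.
* **Conservation** — global pairwise alignment (match +1, mismatch −1, gap
  open −2, extend −0.5; Biopython `PairwiseAligner`); identity = identical
  columns / alignment columns, pass at ≥ 0.90. With variants carrying exactly
  round(0.08×313)=25 substitutions the expected identity is 288/313 ≈ 92.0%.
* **Transitivity** — the computational analogue of probing a small RNA blot
  with everything except the target element: every library sequence is mapped
  against the cassette transcript and hits overlapping the element interval
  are discarded; any surviving match is evidence of secondary siRNA
  production. This is an analogue of the molecular assay, not a claim of
  equivalence; the report says which interval was excluded.

## 5'RACE cleavage mapping

Trimming removes an exact vector prefix, the adaptor (≤ 1 mismatch, at the
read start), then the maximal run of ≥ 3 C (the terminal-transferase tail);
shorter C runs are genuine sequence. Reads lacking the adaptor are rejected
but pass their sequence through unchanged, which makes trimming idempotent on
the sequence component. The insert is placed full-length, ungapped, ≤ 1
substitution; the position of its first base is the inferred cleavage site.
Reads with ≥ 2 equally good placements are excluded as ambiguous (and
counted) rather than randomly assigned. Sites with ≥ `min_support` (default
2) reads are called, classified against the target element, and the design is
"sequence-specific" only when no supported site falls outside it. The
report's `product_size` column (transcript length − position) reproduces the
expected cleaved-product sizes as a derived quantity.

## Synthetic data: what it emulates and what it does not

The generator plants a cluster of 18–26-nt siRNAs (length weights peaked at
21/22/24 nt, both strands, overlaps allowed) inside a chosen 201-nt region of
a random 1826-nt donor transcript, within a panel of 15 organ/stage libraries
(tassel at three stages). Per-siRNA tassel abundance targets are drawn
log-uniformly from [40, 2660] TPM; realised counts are Poisson, resampled
(then clamped) into the window so that edge-of-window targets still satisfy
the specificity floor — without truncation a 40-TPM siRNA realises below the
floor about half the time and planted-truth recovery would not be a property
of a correct pipeline. Two planted siRNAs are anchored at the region
boundaries so the cluster spans its region; otherwise the densest 201-nt
window is underdetermined by the unused margin and no correct selector could
guarantee ≥ 95% overlap with the planted interval. Background reads are
independent uniform random sequences, deduplicated within a library (each has
count 1) and resampled on collision with planted sequences, so ground truth
stays exact. Non-target libraries receive planted siRNAs at
`background_rate` (0 = no leak).

RACE reads are adaptor + poly(C) (8–14 C) + transcript suffix, with a fixed
synthetic 60-nt vector prefix on a configurable fraction; the adaptor and
vector are package-defined constants (labelled synthetic), chosen so the
adaptor does not end in C. The generator refuses cleavage positions whose
first transcript base is C: maximal-run trimming would eat genuine leading Cs
and shift the inferred site, a real ambiguity of terminal-transferase RACE
that the exact-recovery contract deliberately avoids rather than models.
Germplasm variants carry exactly round(divergence × length) substitutions, so
screened identity is analytically known.

Not modelled: sequencing error, PCR duplicates, adapter dimers, RNA secondary
structure, genuine tissue-specific background populations shared across
libraries. Passing the planted-truth criteria therefore demonstrates that the
pipeline's logic is correct and self-consistent under its stated model — not
that the thresholds are optimal for noisy real libraries.

## Problem sizes and numerics

Scientific defaults match the emulated study: 15 libraries of 10⁶ reads,
30-siRNA cluster, [40, 2660] TPM, 1826-nt donor, 201-nt element, 31 germplasm
amplicons of 313 nt at 8% divergence. The test suite and
`scripts/acceptance.py` run the same study design at 40,000 (tests partly
30,000) reads per library — the package's chosen benchmark size, which keeps
the 20-seed recovery study to about a minute while preserving every
threshold's meaning: the depth floor of 25,000 reads guarantees the 40-TPM
floor is at least one read, and at 40,000 reads a singleton background read is
25 TPM, safely below `tau_min`. All randomness flows from one master seed via
`numpy.random.SeedSequence` spawning, so a fixed config yields byte-identical
reports (output paths are excluded from report parameter blocks for exactly
this reason).

## Known limitations

* The specificity rule uses per-library maxima, not replicate-aware
  statistics; the microarray t-test is the replicate-aware counterpart.
* `find_windows` is a greedy selector; it guarantees the top window has the
  global maximum score but the full non-overlapping set is greedy-optimal,
  not globally optimal.
* The transitivity screen shares the matcher's ≤ 1-substitution semantics;
  probes in the molecular assay it mirrors tolerate more divergence.
* Cleavage sites coinciding with a C, or inserts that multi-map, are excluded
  by design; real degradome analyses must model both.
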