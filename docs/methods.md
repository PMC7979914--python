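# Methods

## Scope and data model

`ablib` implements the sequence-analysis side of antibody display-library
characterisation: read QC, germline V/J assignment, hierarchical
clonotyping, diversity estimation, degenerate-primer specificity analysis
and CDR biophysics. Wet-lab stages (B-cell capture, PCR assembly, display
selections, IgG reformatting) and full IgBLAST feature parity are out of
scope. Reads are treated as single, already-merged amplicon sequences; no
paired-end assembly, adapter trimming, UMI consensus building or indel-aware
alignment is performed.

The packaged germline reference (`data/germline_synthetic.*`) is a
**synthetic** curated set: 12 heavy V genes spanning families IGHV1–IGHV6,
6 heavy J genes, 6 kappa V / 5 kappa J, and 5 lambda V / 4 lambda J genes.
Each V gene is 291 nt — FR1 [0,78), CDR1 [78,99), FR2 [99,150), CDR2
[150,174), FR3 [174,288), then the conserved 2nd-Cys anchor codon — and
begins with an 18 nt region compatible with its family's degenerate forward
primer. Family members share a common body with ~6% per-gene divergence and
a minimum pairwise distance of 8 nt, so error-free reads are always
unambiguously assignable. J genes are 36 nt starting at their Trp/Phe anchor.
The reverse-primer panel (`primers_reverse_synthetic.tsv`) is likewise
synthetic, derived from the packaged J genes; it exists to carry the
amplification combinatorics (12 × 4 heavy PCRs, 12 × 2 scFv assembly pools).
The forward panel and the developability class map transcribe published
primer/classification tables; where a table's column assignment was
ambiguous, genes were classified from the accompanying text and the Tiller
developability criteria, and the map should be treated as a curated fixture,
not an authority.

## Synthetic repertoire generator

The generator emulates the statistical structure the analysis assumes:

- **Clonal abundance**: clone copy numbers are Zipf(α), default α = 2.5,
  truncated at `max_clone_frac` (default 1%) of the clone count. The
  truncation reflects the observed behaviour of real display libraries,
  where even the most dominant clonotype holds on the order of 1% of reads;
  an untruncated Zipf tail at this α routinely puts >5% of reads on one
  clone. At the defaults ~75% of clones are singletons, consistent with the
  58–72% per-pool singleton fractions reported for single-donor libraries.
- **V/J usage**: V genes are drawn by family weight (uniform within family),
  J genes by per-gene weight. Chain presets encode the documented J mixing
  proportions (heavy J1/J2 5%, J3 10%, J4/J5 60%, J6 25%; kappa J1–J5
  29/26/10/26/9%; lambda J1 21%, J2+J3 77%, J7 2%).
- **CDR3 length**: a discretized normal (heavy median 14 aa, σ 3.73; kappa
  9/1.23; lambda 11/1.45) truncated to the observed 3–42 aa range.
- **Junction model**: the CDR3 is a uniformly random stop-free codon string
  inserted between the V and J anchors. No D-gene bookkeeping, P/N-nucleotide
  modelling or positional amino-acid bias: downstream analyses never consume
  D calls, but this means CDR3 composition statistics (charge/GRAVY medians)
  reflect uniform codon usage, not natural repertoire bias, and tests assert
  only structural properties of those statistics.
- **Non-productive clones**: a configurable fraction (heavy default 11%,
  light 16%, matching reported ORF productivities of 89%/84%) receive either
  a frameshifted junction or an in-junction stop codon, with equal
  probability.
- **Sequencing error**: substitutions only, at a per-base rate (no indels or
  chimeras, matching the dominant Illumina error mode). Per-base qualities
  come from a two-regime model — 90% of reads draw from {Q40, Q38, Q30} and
  10% from a degraded {Q12, Q25, Q38} mix — so both quality filters have
  non-trivial work.
- **Determinism**: all randomness flows from one integer seed through a
  `numpy` `default_rng`; no global RNG state is touched.

What passing tests on this generator do *not* show: robustness to indels,
chimeric reads, primer-dimer artefacts, real germline allelic variation, or
natural CDR3 composition bias.

## Read QC

Two Phred criteria are exposed: `fraction_threshold` (pass iff ≥
`min_fraction` of bases have Q ≥ `min_q`; default Q25/90%, the pipeline
default) and `lower_quartile` (pass iff the nearest-rank 25th percentile of
base qualities ≥ `min_q`, e.g. Q37). Nearest-rank (type-1) percentiles are
used because they are unambiguous for short reads. Empty reads are rejected
and counted separately. The filter is idempotent and monotone in `min_q`.

## Germline assignment

The aligner is deliberately simple: ungapped comparison (match +1, mismatch
−1) of the read prefix against each V gene over a small window of candidate
offsets (default 0–2), and of the read 3′ end against each J gene. This is
adequate because the simulator produces substitution-only errors; a banded
gapped mode is a known limitation for indel-bearing data. Ties break on
higher identity, then lexicographic gene name.

Two filters gate the call: an e-value-like statistic
`K·m·n·exp(−λ·S)` with fixed constants λ = 1.33, K = 0.621 (threshold
1e-12 by default, 1e-14 available), and nucleotide identity ≥ 90% computed
over the framework and CDR1/2 positions of the V alignment only — the CDR3
junction never contributes. V identity of an error-free read is exactly 1.0.

CDR1/2 are read off the V alignment through the germline region bounds;
CDR3 is the translation of read nucleotides strictly between the V 2nd-Cys
codon and the J Trp/Phe codon (IMGT convention, anchors excluded). A read is
productive iff the junction length is a codon multiple and the assembled
V..J translation is stop-free. Output follows AIRR Rearrangement column
conventions (`junction_aa` carries the anchor-free CDR3; coordinates are
0-based half-open internally).

## Clonotyping

Keys observed ≥2 times each seed a clonotype. Singletons are compared only
against abundant keys of equal length (Hamming distance is undefined across
lengths); a singleton within `h` of any abundant key is absorbed into the
highest-count candidate (ties lexicographic), otherwise it survives as a
true singleton. Singletons are never merged with one another, which makes
the result order-independent. `h = 0` reduces to exact uniqueness;
`abundance_only` drops singletons entirely (the N ≥ 2 criterion). Read
counts are conserved for all Hamming criteria; for `abundance_only` the
count of dropped singletons is reported alongside the table. Neighbour
search is a length-bucketed vectorised scan — adequate at the table sizes
this package targets (≤10⁵ unique keys); the semantics, not the index
structure, are the contract, and a brute-force all-pairs oracle verifies
equivalence in the tests. Levenshtein distances (for pairwise CDR profile
comparisons) are delegated to `edlib`.

## Diversity

Hill numbers use the closed form with the entropy limit at q = 1 (the closed
form is singular there). Accumulation curves subsample reads without
replacement (rarefaction convention) and clonotype each subsample at the
requested criterion; the replicate-averaged curve is fitted by least squares
to S(n) = S_max(1 − e^(−n/τ)) with initialization S_max ← 1.1 × max S_obs,
τ ← n at half-max, parameter tolerance 1e-8, ≤500 evaluations, and
S_max bounded below by max S_obs. Non-convergence returns a flagged result
rather than raising. Note that rarefaction curves of duplicated datasets do
*not* superpose at equal sampling fractions (hypergeometric coverage rises
with per-key copy number); the tests therefore validate subsampling against
the exact hypergeometric rarefaction expectation instead. Chao-type
estimators and extrapolation beyond the fitted model are out of scope.

## Primer analysis

`iupac_hamming` counts positions whose IUPAC nucleotide sets are disjoint:
degenerate positions match any member base (K vs G is a match). The metric
is symmetric with a zero diagonal but deliberately violates the triangle
inequality (K matches both G and C-complementary sets that do not match each
other); nothing downstream assumes metricity. Ward clustering implements the
Lance–Williams minimum-variance recurrence on squared distances with
deterministic lexicographic tie-breaking; the default cut is at the largest
merge-height gap *below the root merge* (the root gap is always largest and
carries no cluster structure). On tie-free data the criterion heights equal
the squared heights of SciPy's Ward linkage, which serves as the independent
cross-check in tests. The amplification-prediction model (capture ∝
abundance × exp(−W), W the mismatch count with the three 3′-terminal
positions weighted 3×) is a qualitative explanatory device — the 3′ weight
is a design choice exposed in the API, not a fitted thermodynamic quantity.

## Biophysics

Net charge sums Henderson–Hasselbalch fractional charges of ionizable side
chains on the Lehninger pK scale (D 3.65, E 4.25, C 8.18, Y 10.07, H 6.00,
K 10.53, R 12.48) at pH 7 by default. Histidine is included (excluding it
would misstate near-neutral medians); terminal groups are excluded by
default because a CDR is an internal peptide of the chain — both choices are
config-overridable. GRAVY is the plain Kyte–Doolittle mean, cross-checked
against Biopython's implementation. Length summaries report the median,
sample standard deviation (n−1) and nearest-rank 10/90% quantiles. V/J
pairing matrices are read-fraction tables over V family × J gene;
developability summaries can weight primer pools equally before pooling,
mirroring equimolar pool mixing ahead of sequencing.

## Pipeline and problem sizes

The `report` pipeline stamps every artifact with a config hash and the seed;
identical config + seed reproduce identical outputs. Default problem sizes
(thousands of clones, tens of thousands of reads) were chosen as the scale
at which every statistical behaviour of interest — singleton dominance,
J-usage recovery within design-corrected binomial error, accumulation-curve
saturation for oversampled light chains — is already resolved; all analyses
scale linearly in read count. For read-weighted proportions the sampling
tolerance uses the design-effect-corrected effective sample size
n_eff = (Σc)²/Σc², because reads are cluster-sampled by clone and the naive
binomial tolerance at the read count would be anti-conservative.

## Known limitations

- No indel/chimera error models; the aligner is ungapped.
- The synthetic germline set cannot detect allele-level mis-assignment.
- Junction sequences have uniform codon usage; absolute charge/GRAVY medians
  of synthetic repertoires are not comparable to natural ones.
- The primer capture model is qualitative; no ΔG/Tm annealing thermodynamics.
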