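# ablib — antibody display-library NGS analysis

`ablib` analyses deep-sequencing data from in vitro antibody display
libraries (phage/yeast scFv repertoires) and answers the questions a library
builder asks of an NGS run: how many distinct antibodies does the library
really contain, how is that diversity distributed over clones, germline
scaffolds and primer pools, and what are its biophysical characteristics?
It is aimed at antibody engineers and repertoire bioinformaticians, and
ships a synthetic repertoire generator so every stage is testable without
access to proprietary sequencing data.

## What it computes

**Clonotyping.** Reads are quality-filtered (Phred fraction or lower-quartile
criteria), assigned germline V/J genes with an e-value-like and ≥90%
framework/CDR1–2 identity filter, and clustered into clonotypes keyed by the
CDR3 amino-acid sequence (optionally merged CDR1+CDR3, or CDR3 + germline
call). Clustering is hierarchical with abundance filtering plus
Hamming-distance singleton rescue: sequences seen ≥2 times each seed a
clonotype, and a singleton is kept as a "true singleton" only if it lies more
than a Hamming distance *h* (0–3) from every abundant sequence of equal
length, where

d<sup>HD</sup>(i, j) = Σ<sub>k</sub> [y<sub>i,k</sub> ≠ y<sub>j,k</sub>].

**Diversity.** Clone-count tables are summarised by Hill numbers
<sup>q</sup>D = (Σ<sub>i</sub> p<sub>i</sub><sup>q</sup>)<sup>1/(1−q)</sup>
(q = 0 richness, q = 1 exponential Shannon entropy, q = 2 inverse Simpson),
and by rarefaction species-accumulation curves whose asymptote is estimated
with a negative exponential model S(n) = S<sub>max</sub>(1 − e<sup>−n/τ</sup>).
Heavy × light combinatorial totals are per-criterion products of the
per-chain values.

**Primer specificity.** Degenerate (IUPAC) primer panels are compared with a
set-intersection Hamming distance, clustered with Ward's minimum-variance
agglomeration, and annotated pools are summarised as on-/off-target
amplification rates with per-primer read-count normalisation.

**Biophysics.** CDR net charge (Henderson–Hasselbalch on the Lehninger pK
scale at pH 7), GRAVY hydropathy (Kyte–Doolittle), length distributions, V/J
pairing matrices and germline developability-class summaries.

## Worked example

Simulate a small heavy-chain library, filter, annotate and clonotype it:

```bash
$ ablib simulate --chain heavy --n-clones 2000 --n-reads 4000 --seed 11 \
      --out reads.fastq --truth truth.tsv
wrote 4000 reads from 2000 clones to reads.fastq

$ ablib qc reads.fastq --out filtered.fastq
{"reads_in": 4000, "reads_passed": 3618, "failed_quality": 382, "failed_empty": 0}

$ ablib annotate filtered.fastq --chain heavy --out ann.tsv
annotated 3618 reads -> ann.tsv

$ ablib clonotype ann.tsv --criterion 1 --out ct.tsv
1335 clonotypes at hamming_1 -> ct.tsv

$ ablib diversity ct.tsv
{"q0": 1335.0, "q1": 903.0439598924457, "q2": 564.2725492454787}
```

The QC line shows the 10% of simulated reads drawn from the degraded quality
regime being removed. After annotation, hierarchical clonotyping at Hamming 1
collapses 3618 productive reads into 1335 clonotypes; the Hill spectrum
(richness 1335, effective Shannon diversity 903, effective Simpson diversity
564) quantifies how unevenly reads are spread over those clonotypes — the
decline from q0 to q2 reflects the heavy-tailed clone-abundance structure.

Clustering the packaged 12-primer IGHV panel reproduces the three
cross-family specificity groups that explain observed off-target
amplification:

```bash
$ ablib primers
{"k": 3, "clusters": [["IGHV1a", "IGHV1b", "IGHV1c", "IGHV1d", "IGHV3a",
"IGHV3b", "IGHV3c", "IGHV5a"], ["IGHV2a", "IGHV2b"], ["IGHV4", "IGHV6a"]]}
```

`ablib report` runs the whole pipeline (simulation or FASTQ input → QC →
annotation → clonotype/diversity grid → dominance, biophysics) and writes a
JSON/TSV bundle stamped with the config hash and seed.

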