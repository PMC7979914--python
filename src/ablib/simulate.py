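"""Synthetic repertoire generator.

Emulates the statistical structure of a single-donor antibody phage library:
power-law (Zipf) clonal abundance dominated by singletons, V-family usage set
by the primer pools, J usage at the mixing proportions used during library
construction, CDR3 lengths from a discretized truncated normal, and
substitution-only sequencing error with a two-regime per-base Phred model.

All randomness flows from one integer seed through a named generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .resources import GermlineReference

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in _STOPS]

CDR3_LEN_RANGE = (3, 42)

# J mixing proportions used when the amplicon pools were combined
HEAVY_J_WEIGHTS = {"IGHJ1": 0.025, "IGHJ2": 0.025, "IGHJ3": 0.10,
                   "IGHJ4": 0.30, "IGHJ5": 0.30, "IGHJ6": 0.25}
KAPPA_J_WEIGHTS = {"IGKJ1": 0.29, "IGKJ2": 0.26, "IGKJ3": 0.10,
                   "IGKJ4": 0.26, "IGKJ5": 0.09}
LAMBDA_J_WEIGHTS = {"IGLJ1": 0.21, "IGLJ2": 0.385, "IGLJ3": 0.385,
                    "IGLJ7": 0.02}

HEAVY_V_WEIGHTS = {"IGHV1": 0.25, "IGHV2": 0.05, "IGHV3": 0.40,
                   "IGHV4": 0.15, "IGHV5": 0.10, "IGHV6": 0.05}
KAPPA_V_WEIGHTS = {"IGKV1": 0.70, "IGKV3": 0.30}
LAMBDA_V_WEIGHTS = {"IGLV1": 0.40, "IGLV2": 0.30, "IGLV3": 0.30}

# chain -> (v_weights, j_weights, cdr3 median, cdr3 sigma, nonproductive)
_CHAIN_DEFAULTS = {
    "heavy": (HEAVY_V_WEIGHTS, HEAVY_J_WEIGHTS, 14, 3.73, 0.11),
    "kappa": (KAPPA_V_WEIGHTS, KAPPA_J_WEIGHTS, 9, 1.23, 0.16),
    "lambda": (LAMBDA_V_WEIGHTS, LAMBDA_J_WEIGHTS, 11, 1.45, 0.16),
}


@dataclass(frozen=True)
class RepertoireSpec:
    """Generative conditions for one chain's clone population."""

    chain: str
    n_clones: int
    v_weights: Mapping[str, float]
    j_weights: Mapping[str, float]
    abundance_alpha: float = 2.5
    cdr3_len_median: int = 14
    cdr3_len_sigma: float = 3.73
    nonproductive_frac: float = 0.11
    max_clone_frac: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.abundance_alpha <= 1:
            raise ValueError("abundance_alpha must exceed 1")
        if self.cdr3_len_median < CDR3_LEN_RANGE[0]:
            raise ValueError("cdr3_len_median below the shortest observed CDR3 length")
        if self.cdr3_len_sigma <= 0:
            raise ValueError("cdr3_len_sigma must be positive")
        for name, weights in (("v_weights", self.v_weights), ("j_weights", self.j_weights)):
            total = sum(weights.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} sum to {total}, expected 1")


def chain_spec(chain: str, n_clones: int, seed: int = 0, **overrides) -> RepertoireSpec:
    """RepertoireSpec preset with the library's stated conditions for a chain."""
    v_w, j_w, med, sigma, nonprod = _CHAIN_DEFAULTS[chain]
    spec = RepertoireSpec(
        chain=chain, n_clones=n_clones, v_weights=dict(v_w), j_weights=dict(j_w),
        cdr3_len_median=med, cdr3_len_sigma=sigma, nonproductive_frac=nonprod,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


@dataclass(frozen=True)
class SyntheticClone:
    clone_id: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str  # empty for non-productive clones
    full_nt: str
    true_count: int
    productive: bool


@dataclass
class ReadRecord:
    read_id: str
    nt_sequence: str
    phred: np.ndarray  # per-base integer quality, same length as sequence
    source_clone_id: str

    def __post_init__(self) -> None:
        if len(self.phred) != len(self.nt_sequence):
            raise ValueError("phred length must match sequence length")


def _sample_counts(rng: np.random.Generator, spec: RepertoireSpec) -> np.ndarray:
    """Zipf clone copy numbers, truncated so no clone can dominate the pool.

    The cap (``max_clone_frac`` of the clone count) mirrors the observed
    behaviour of the library, where even the most abundant clonotype held
    about 1% of reads.
    """
    counts = rng.zipf(spec.abundance_alpha, size=spec.n_clones)
    cmax = max(10, int(spec.max_clone_frac * spec.n_clones))
    return np.minimum(counts, cmax).astype(np.int64)


def _sample_cdr3_lengths(rng: np.random.Generator, spec: RepertoireSpec) -> np.ndarray:
    raw = np.rint(rng.normal(spec.cdr3_len_median, spec.cdr3_len_sigma, spec.n_clones))
    return np.clip(raw, *CDR3_LEN_RANGE).astype(int)


def _junction(rng: np.random.Generator, n_aa: int, productive: bool) -> str:
    codons = [(_SENSE_CODONS[i]) for i in rng.integers(0, len(_SENSE_CODONS), n_aa)]
    if not productive:
        if rng.random() < 0.5:  # frameshift
            extra = rng.integers(1, 3)
            tail = "".join("ACGT"[i] for i in rng.integers(0, 4, extra))
            return "".join(codons) + tail
        stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
        codons[rng.integers(0, n_aa)] = stop
    return "".join(codons)


def generate_repertoire(spec: RepertoireSpec, reference: GermlineReference) -> list[SyntheticClone]:
    """Draw ground-truth clones: V by family weight, J by gene weight, random
    in-frame junction sized to hit the target CDR3 length distribution."""
    rng = np.random.default_rng(spec.seed)
    fams = reference.families(spec.chain, "V")
    for fam in spec.v_weights:
        if fam not in fams:
            raise ValueError(f"v_weights references unknown family {fam!r}")
    for j in spec.j_weights:
        if j not in reference or reference[j].segment != "J":
            raise ValueError(f"j_weights references unknown J gene {j!r}")

    fam_names = sorted(spec.v_weights)
    fam_p = np.array([spec.v_weights[f] for f in fam_names])
    j_names = sorted(spec.j_weights)
    j_p = np.array([spec.j_weights[j] for j in j_names])

    fam_idx = rng.choice(len(fam_names), size=spec.n_clones, p=fam_p / fam_p.sum())
    j_idx = rng.choice(len(j_names), size=spec.n_clones, p=j_p / j_p.sum())
    counts = _sample_counts(rng, spec)
    lengths = _sample_cdr3_lengths(rng, spec)
    productive = rng.random(spec.n_clones) >= spec.nonproductive_frac

    clones = []
    for i in range(spec.n_clones):
        fam_genes = fams[fam_names[fam_idx[i]]]
        v = fam_genes[rng.integers(0, len(fam_genes))]
        j = reference[j_names[j_idx[i]]]
        cdr3_nt = _junction(rng, int(lengths[i]), bool(productive[i]))
        cdr3_aa = str(Seq(cdr3_nt).translate()) if productive[i] else ""
        clones.append(
            SyntheticClone(
                clone_id=f"{spec.chain}_clone_{i:06d}",
                v_gene=v.name,
                j_gene=j.name,
                cdr3_nt=cdr3_nt,
                cdr3_aa=cdr3_aa,
                full_nt=v.nt_sequence + cdr3_nt + j.nt_sequence[j.anchor:],
                true_count=int(counts[i]),
                productive=bool(productive[i]),
            )
        )
    return clones


def true_richness(clones: Sequence[SyntheticClone], key: str = "cdr3_aa") -> int:
    """Ground-truth clonotype richness: distinct productive CDR3 keys."""
    return len({getattr(c, key) for c in clones if c.productive})


@dataclass(frozen=True)
class PhredModel:
    """Two-regime per-base quality model: most reads high quality, a fraction
    of reads degraded so both printed quality filters discriminate."""

    bad_read_frac: float = 0.10
    good_qs: tuple[int, ...] = (40, 38, 30)
    good_p: tuple[float, ...] = (0.85, 0.10, 0.05)
    bad_qs: tuple[int, ...] = (12, 25, 38)
    bad_p: tuple[float, ...] = (0.70, 0.20, 0.10)

    def sample(self, rng: np.random.Generator, length: int) -> np.ndarray:
        if rng.random() < self.bad_read_frac:
            return rng.choice(self.bad_qs, size=length, p=self.bad_p)
        return rng.choice(self.good_qs, size=length, p=self.good_p)


def simulate_reads(
    clones: Sequence[SyntheticClone],
    n_reads: int,
    sub_rate: float = 0.0,
    phred_model: PhredModel | None = None,
    seed: int = 0,
) -> list[ReadRecord]:
    """Sample reads from clones proportionally to ``true_count`` and apply
    substitution-only errors at ``sub_rate`` per base."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    counts = np.array([c.true_count for c in clones], dtype=float)
    if counts.sum() <= 0:
        raise ValueError("total clone count must be positive")
    phred_model = phred_model or PhredModel()
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(clones), size=n_reads, p=counts / counts.sum())

    reads = []
    for r, ci in enumerate(picks):
        clone = clones[ci]
        seq_arr = np.frombuffer(clone.full_nt.encode(), dtype=np.uint8).copy()
        if sub_rate > 0:
            n_err = rng.binomial(len(seq_arr), sub_rate)
            if n_err:
                pos = rng.choice(len(seq_arr), size=n_err, replace=False)
                # substitute with one of the three other bases
                shift = rng.integers(1, 4, size=n_err)
                base_idx = np.searchsorted(_BASES, seq_arr[pos])
                seq_arr[pos] = _BASES[(base_idx + shift) % 4]
        reads.append(
            ReadRecord(
                read_id=f"read_{r:08d}",
                nt_sequence=seq_arr.tobytes().decode(),
                phred=phred_model.sample(rng, len(seq_arr)),
                source_clone_id=clone.clone_id,
            )
        )
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(int(q) + 33) for q in read.phred)
            fh.write(f"@{read.read_id}\n{read.nt_sequence}\n+\n{qual}\n")


def write_truth(
    reads: Iterable[ReadRecord], clones: Sequence[SyntheticClone], path: str | Path
) -> None:
    """Ground-truth map: read_id, clone_id, v_gene, j_gene, cdr3_aa."""
    by_id = {c.clone_id: c for c in clones}
    with open(path, "w") as fh:
        fh.write("read_id\tclone_id\tv_gene\tj_gene\tcdr3_aa\n")
        for read in reads:
            c = by_id[read.source_clone_id]
            fh.write(f"{read.read_id}\t{c.clone_id}\t{c.v_gene}\t{c.j_gene}\t{c.cdr3_aa}\n")


def effective_sample_size(clones: Sequence[SyntheticClone]) -> float:
    """Design-effect effective n for read-weighted proportions: (Σc)²/Σc²."""
    c = np.array([cl.true_count for cl in clones], dtype=float)
    return float(c.sum() ** 2 / (c ** 2).sum())
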