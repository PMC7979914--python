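"""Hierarchical clonotyping with Hamming-distance singleton rescue.

Sequences observed at least twice (abundant keys) each seed a clonotype.
A singleton is absorbed into an abundant clonotype when some abundant key of
equal length lies within Hamming distance ``h``; otherwise it survives as a
"true singleton" clonotype.  Hamming distance is defined only between
equal-length strings, so a length mismatch means the singleton can never be
absorbed.  Singletons are never merged with other singletons, which makes the
result independent of input order.

Three key schemes are supported: the CDR3 amino-acid sequence, the merged
CDR1+CDR3 string, and a (germline, CDR3) composite where distance is computed
on the CDR3 part and germline equality is required for merging.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .annotate import Annotation

SCHEMES = ("cdr3", "merged", "germline")
CRITERIA = ("hamming_0", "hamming_1", "hamming_2", "hamming_3", "abundance_only")
_SEP = "|"


def hamming(a: str, b: str) -> int:
    """Number of mismatched positions; defined only at equal length."""
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b)["editDistance"]


def make_key(annotation: Annotation, scheme: str = "cdr3") -> str:
    """Clonotype key for a productive, filter-passing annotation."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown key scheme {scheme!r}")
    if not annotation.cdr3_aa:
        raise ValueError("annotation has no CDR3")
    if scheme == "cdr3":
        return annotation.cdr3_aa
    if scheme == "merged":
        return f"{annotation.cdr1_aa or ''}{_SEP}{annotation.cdr3_aa}"
    return f"{annotation.v_gene}{_SEP}{annotation.cdr3_aa}"


def _split_key(key: str, scheme: str) -> tuple[str, str]:
    """(grouping label, string the Hamming criterion applies to)."""
    if scheme == "germline":
        gene, _, cdr3 = key.partition(_SEP)
        return gene, cdr3
    return "", key


@dataclass(frozen=True)
class Clonotype:
    representative: str
    members: tuple[str, ...]
    count: int


@dataclass
class ClonotypeTable:
    clonotypes: list[Clonotype]
    criterion: str
    key_scheme: str
    dropped_singletons: int = 0  # reads discarded by the N>=2 criterion

    def __len__(self) -> int:
        return len(self.clonotypes)

    @property
    def counts(self) -> dict[str, int]:
        return {c.representative: c.count for c in self.clonotypes}

    @property
    def total_reads(self) -> int:
        return sum(c.count for c in self.clonotypes)

    @property
    def keys(self) -> set[str]:
        return {c.representative for c in self.clonotypes}


def _absorb_bucket(
    singles: list[str], abund: list[str], counts: Mapping[str, int], h: int
) -> dict[str, str | None]:
    """Map each singleton key to its absorbing abundant key (or None).

    All keys in a bucket share grouping label and length.  The absorber is the
    abundant key within distance ``h`` with the highest count, ties broken
    lexicographically.
    """
    length = len(singles[0])
    s_arr = np.frombuffer("".join(singles).encode(), dtype=np.uint8).reshape(len(singles), length)
    a_arr = np.frombuffer("".join(abund).encode(), dtype=np.uint8).reshape(len(abund), length)
    dist = (s_arr[:, None, :] != a_arr[None, :, :]).sum(axis=2)
    order = sorted(range(len(abund)), key=lambda i: (-counts[abund[i]], abund[i]))
    out: dict[str, str | None] = {}
    for si, s in enumerate(singles):
        hit = next((abund[i] for i in order if dist[si, i] <= h), None)
        out[s] = hit
    return out


def hierarchical_clonotype(
    table: Mapping[str, int] | Iterable[tuple[str, int]],
    criterion: str | int = 1,
    scheme: str = "cdr3",
) -> ClonotypeTable:
    """Cluster a key -> read-count table under one criterion.

    ``criterion`` is 0..3 (Hamming threshold for singleton rescue) or
    ``"abundance_only"`` (drop all singletons, the N>=2 rows).
    """
    counts = dict(table)
    if any(c < 1 for c in counts.values()):
        raise ValueError("counts must be >= 1")
    if criterion == "abundance_only":
        clonotypes = [
            Clonotype(k, (k,), c) for k, c in sorted(counts.items()) if c >= 2
        ]
        dropped = sum(1 for c in counts.values() if c == 1)
        return ClonotypeTable(clonotypes, "abundance_only", scheme, dropped)

    h = int(criterion)
    if not 0 <= h <= 3:
        raise ValueError("Hamming criterion must be in 0..3")

    members: dict[str, list[str]] = {k: [k] for k, c in counts.items() if c >= 2}
    totals: dict[str, int] = {k: c for k, c in counts.items() if c >= 2}
    singles = sorted(k for k, c in counts.items() if c == 1)

    if h == 0 or not members:
        # nothing can be absorbed: every unique key is its own clonotype
        for k in singles:
            members[k], totals[k] = [k], 1
    else:
        buckets: dict[tuple[str, int], tuple[list[str], list[str]]] = {}
        for k in singles:
            label, s = _split_key(k, scheme)
            buckets.setdefault((label, len(s)), ([], []))[0].append(k)
        for k in totals:
            label, s = _split_key(k, scheme)
            key = (label, len(s))
            if key in buckets:
                buckets[key][1].append(k)
        for (_, _), (bucket_singles, bucket_abund) in sorted(buckets.items()):
            if bucket_abund:
                sub = _absorb_bucket(
                    [_split_key(k, scheme)[1] for k in bucket_singles],
                    [_split_key(k, scheme)[1] for k in bucket_abund],
                    {_split_key(k, scheme)[1]: totals[k] for k in bucket_abund},
                    h,
                )
                back = {_split_key(k, scheme)[1]: k for k in bucket_abund}
            else:
                sub, back = {}, {}
            for k in bucket_singles:
                hit = sub.get(_split_key(k, scheme)[1])
                if hit is None:
                    members[k], totals[k] = [k], 1
                else:
                    full = back[hit]
                    members[full].append(k)
                    totals[full] += 1

    clonotypes = [
        Clonotype(rep, tuple(sorted(mem)), totals[rep])
        for rep, mem in sorted(members.items())
    ]
    return ClonotypeTable(clonotypes, f"hamming_{h}", scheme)


def counts_from_annotations(
    annotations: Iterable[Annotation], scheme: str = "cdr3"
) -> Counter[str]:
    """Key -> read count over productive, filter-passing annotations."""
    out: Counter[str] = Counter()
    for a in annotations:
        if a.pass_filter and a.productive and a.cdr3_aa:
            out[make_key(a, scheme)] += 1
    return out


def clonal_dominance(table: ClonotypeTable) -> float:
    """Share of reads held by the most abundant clonotype."""
    if not table.clonotypes:
        raise ValueError("empty clonotype table")
    return max(c.count for c in table.clonotypes) / table.total_reads


@dataclass
class RankCurve:
    cumulative: np.ndarray  # cumulative read fraction by descending-count rank
    clones_to_half: int
    copy_number_spectrum: dict[int, float]  # count -> fraction of clonotypes


def cumulative_rank(table: ClonotypeTable) -> RankCurve:
    if not table.clonotypes:
        raise ValueError("empty clonotype table")
    counts = np.array(sorted((c.count for c in table.clonotypes), reverse=True), dtype=float)
    cum = np.cumsum(counts) / counts.sum()
    clones_to_half = int(np.searchsorted(cum, 0.5) + 1)
    spectrum = Counter(int(c) for c in counts)
    n = len(counts)
    return RankCurve(
        cumulative=cum,
        clones_to_half=clones_to_half,
        copy_number_spectrum={k: v / n for k, v in sorted(spectrum.items())},
    )


@dataclass(frozen=True)
class OverlapReport:
    jaccard: float
    share_a_in_b: float
    share_b_in_a: float


def overlap(a: ClonotypeTable, b: ClonotypeTable) -> OverlapReport:
    """Exact-key clonotype overlap between two tables."""
    ka, kb = a.keys, b.keys
    union = ka | kb
    inter = ka & kb
    return OverlapReport(
        jaccard=len(inter) / len(union) if union else 0.0,
        share_a_in_b=len(inter) / len(ka) if ka else 0.0,
        share_b_in_a=len(inter) / len(kb) if kb else 0.0,
    )
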