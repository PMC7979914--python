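"""Degenerate-primer specificity analysis.

Distances between degenerate primers are IUPAC-aware: a position matches when
the two characters' nucleotide sets intersect (a primer K anneals to either G
or T).  This set-intersection metric is symmetric with zero diagonal but does
NOT satisfy the triangle inequality.  Primer 5' regions are clustered with
Ward's minimum-variance agglomeration (Lance-Williams recurrence on squared
distances), and on-/off-target amplification is summarised from pipeline
annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import Annotation
from .resources import IUPAC_SETS, GermlineReference, PrimerRecord


def iupac_hamming(a: str, b: str) -> int:
    """Mismatch count with degenerate-set matching; equal lengths required."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    try:
        return sum(1 for x, y in zip(a, b) if not (IUPAC_SETS[x] & IUPAC_SETS[y]))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r}") from exc


def distance_matrix(primers: Sequence[PrimerRecord]) -> pd.DataFrame:
    labels = [p.primer_id for p in primers]
    n = len(primers)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = iupac_hamming(primers[i].sequence, primers[j].sequence)
    return pd.DataFrame(mat, index=labels, columns=labels)


@dataclass
class WardResult:
    merges: list[tuple[frozenset[str], float]]  # (merged member set, criterion height)
    labels: dict[str, int]  # primer_id -> cluster id at the chosen cut
    k: int

    def clusters(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for name, lab in self.labels.items():
            out.setdefault(lab, set()).add(name)
        return [out[k] for k in sorted(out)]


def ward_cluster(primers: Sequence[PrimerRecord], k: int | None = None) -> WardResult:
    """Agglomerative Ward clustering of primer sequences.

    Merge order is deterministic: ties on the minimum-variance criterion break
    on the lexicographically smallest member names.  The cut is at the
    requested ``k``, or at the largest merge-height gap below the root merge
    (the root gap is always the largest and carries no structure).
    """
    if len(primers) < 2:
        raise ValueError("need at least 2 primers")
    if len({len(p.sequence) for p in primers}) != 1:
        raise ValueError("primer sequences must have equal length")
    dm = distance_matrix(primers)
    names = list(dm.index)
    n = len(names)

    # Lance-Williams ward.D on squared distances
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dm.iat[i, j]) ** 2
    active: dict[int, tuple[frozenset[str], int]] = {
        i: (frozenset([names[i]]), 1) for i in range(n)
    }
    get = lambda a, b: d[(a, b) if a < b else (b, a)]
    merges: list[tuple[frozenset[str], float]] = []
    snapshots: list[list[frozenset[str]]] = []
    nxt = n
    while len(active) > 1:
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if b <= a:
                    continue
                v = get(a, b)
                tie = tuple(sorted([min(active[a][0]), min(active[b][0])]))
                if best is None or (v, tie) < (best[0], best[3]):
                    best = (v, a, b, tie)
        v, a, b, _ = best
        na, nb = active[a][1], active[b][1]
        merged = active[a][0] | active[b][0]
        for c in list(active):
            if c in (a, b):
                continue
            nc = active[c][1]
            d[(min(c, nxt), max(c, nxt))] = (
                (na + nc) * get(a, c) + (nb + nc) * get(b, c) - nc * v
            ) / (na + nb + nc)
        del active[a], active[b]
        active[nxt] = (merged, na + nb)
        merges.append((merged, v))
        snapshots.append([active[i][0] for i in sorted(active)])
        nxt += 1

    heights = np.array([h for _, h in merges])
    if k is None:
        gaps = np.diff(heights)
        k = n - (int(np.argmax(gaps[:-1])) + 1) if len(gaps) > 1 else 2
    if not 1 <= k <= n:
        raise ValueError(f"cut k={k} outside 1..{n}")
    if k == n:
        clusters = [frozenset([nm]) for nm in names]
    else:
        clusters = snapshots[n - 1 - k]
    labels: dict[str, int] = {}
    for ci, members in enumerate(sorted(clusters, key=min)):
        for nm in members:
            labels[nm] = ci
    return WardResult(merges=merges, labels=labels, k=k)


@dataclass
class OnTargetReport:
    primer_id: str
    family_level_fraction: float
    gene_level_fraction: float | None
    off_target_families: dict[str, float]  # histogram over all families, sums to 1


def on_target_rate(annotations: Sequence[Annotation], primer: PrimerRecord) -> OnTargetReport:
    """On-/off-target amplification for one primer pool's annotated reads."""
    calls = [(a.v_family, a.v_gene) for a in annotations if a.pass_filter and a.v_family]
    if not calls:
        raise ValueError(f"no passing annotations for primer {primer.primer_id}")
    n = len(calls)
    fam_counts: dict[str, int] = {}
    for fam, _ in calls:
        fam_counts[fam] = fam_counts.get(fam, 0) + 1
    family_frac = fam_counts.get(primer.intended_family, 0) / n
    gene_frac = None
    if primer.intended_genes:
        targets = set(primer.intended_genes)
        gene_frac = sum(1 for _, g in calls if g in targets) / n
    return OnTargetReport(
        primer_id=primer.primer_id,
        family_level_fraction=family_frac,
        gene_level_fraction=gene_frac,
        off_target_families={f: c / n for f, c in sorted(fam_counts.items())},
    )


def normalize_by_primer(pools: Mapping[str, Mapping[str, float]]) -> dict[str, float]:
    """Pool per-primer count tables with equal total weight per pool.

    Relative proportions within each pool are preserved; every pool
    contributes 1/``n_pools`` of the combined weight.
    """
    pools = {k: dict(v) for k, v in pools.items() if v}
    if not pools:
        raise ValueError("need at least one non-empty pool")
    combined: dict[str, float] = {}
    for counts in pools.values():
        total = sum(counts.values())
        for key, c in counts.items():
            combined[key] = combined.get(key, 0.0) + c / total / len(pools)
    return combined


def primer_match_simulation(
    reference: GermlineReference,
    panel: Sequence[PrimerRecord],
    abundance: Mapping[str, float] | None = None,
    decay: float = 1.0,
    three_prime_len: int = 3,
    three_prime_weight: float = 3.0,
) -> pd.DataFrame:
    """Predicted capture of each germline gene by each primer.

    A qualitative explanatory model: capture weight of gene g by primer p is
    proportional to abundance(g) x exp(-decay x W(p, g)), where W is the
    IUPAC mismatch count over the gene's 5' primer-binding region with the
    terminal ``three_prime_len`` positions weighted ``three_prime_weight``-fold
    (3' mismatches block extension).  Rows are normalised to 1.
    """
    genes = [g for g in reference if g.segment == "V"]
    if abundance is None:
        abundance = {g.name: 1.0 for g in genes}
    weights = np.ones(len(panel[0].sequence)) if panel else None
    rows = {}
    for p in panel:
        L = len(p.sequence)
        w = np.ones(L)
        w[L - three_prime_len:] = three_prime_weight
        scores = {}
        for g in genes:
            region = g.nt_sequence[:L]
            mism = np.array([
                0.0 if IUPAC_SETS[x] & IUPAC_SETS[y] else 1.0
                for x, y in zip(p.sequence, region)
            ])
            scores[g.name] = abundance.get(g.name, 0.0) * np.exp(-decay * float((mism * w).sum()))
        total = sum(scores.values())
        rows[p.primer_id] = {k: (v / total if total > 0 else 0.0) for k, v in scores.items()}
    return pd.DataFrame(rows).T.fillna(0.0)
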