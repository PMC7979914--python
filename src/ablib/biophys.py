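"""Sequence-level biophysical profiling of CDRs.

Net charge follows Henderson-Hasselbalch fractional ionisation on the
Lehninger pK scale at a given pH: positive groups (K, R, H) contribute
+1/(1+10^(pH-pK)), negative groups (D, E, C, Y) contribute -1/(1+10^(pK-pH)).
Terminal groups are excluded by default because a CDR is an internal segment
of the chain.  Hydrophobicity is the GRAVY index: the arithmetic mean of
Kyte-Doolittle hydropathy values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import Annotation
from .resources import (
    DEVELOPABILITY_CLASSES,
    ScaleTable,
    classify_developability,
    kyte_doolittle,
    lehninger_pk,
)

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


def net_charge(
    seq: str,
    ph: float = 7.0,
    pk_scale: ScaleTable | None = None,
    include_termini: bool = False,
) -> float:
    """Signed sum of fractional side-chain charges at the given pH."""
    if bad := set(seq) - _STANDARD:
        raise ValueError(f"non-standard residues {sorted(bad)}")
    scale = pk_scale or lehninger_pk()
    groups = [r for r in seq if r in scale]
    if include_termini and seq:
        groups += ["Nterm", "Cterm"]
    charge = 0.0
    for g in groups:
        pk, sign = scale.values[g], scale.signs[g]
        if sign > 0:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pk))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pk - ph))
    return charge


def gravy(seq: str, scale: ScaleTable | None = None) -> float:
    """Grand average of hydropathy; negative values are hydrophilic."""
    if not seq:
        raise ValueError("empty sequence")
    if bad := set(seq) - _STANDARD:
        raise ValueError(f"non-standard residues {sorted(bad)}")
    scale = scale or kyte_doolittle()
    return float(np.mean([scale[r] for r in seq]))


@dataclass(frozen=True)
class BiophysProfile:
    key: str
    length: int
    net_charge: float
    gravy: float
    v_gene: str | None = None
    j_gene: str | None = None
    developability: str = "unclassified"


def profile_annotations(
    annotations: Iterable[Annotation],
    dmap: Mapping[str, str] | None = None,
    ph: float = 7.0,
) -> list[BiophysProfile]:
    """CDR3 biophysics for productive, filter-passing annotations."""
    pk = lehninger_pk()
    kd = kyte_doolittle()
    out = []
    for a in annotations:
        if not (a.pass_filter and a.productive and a.cdr3_aa):
            continue
        out.append(
            BiophysProfile(
                key=a.cdr3_aa,
                length=len(a.cdr3_aa),
                net_charge=net_charge(a.cdr3_aa, ph, pk),
                gravy=gravy(a.cdr3_aa, kd),
                v_gene=a.v_gene,
                j_gene=a.j_gene,
                developability=classify_developability(a.v_gene, dmap) if dmap and a.v_gene else "unclassified",
            )
        )
    return out


def _nearest_rank(values: np.ndarray, q: float) -> float:
    ordered = np.sort(values)
    rank = max(1, int(np.ceil(q * len(ordered))))
    return float(ordered[rank - 1])


def length_distribution(
    profiles: Sequence[BiophysProfile] | Sequence[int],
    stratify: bool = False,
) -> pd.DataFrame:
    """Median / sample sigma / 10-90% nearest-rank quantiles of CDR3 length,
    optionally per (V family, J gene) stratum."""
    if profiles and isinstance(profiles[0], BiophysProfile):
        frame = pd.DataFrame(
            {
                "length": [p.length for p in profiles],
                "v_family": [(p.v_gene or "?")[:5] for p in profiles],
                "j_gene": [p.j_gene or "?" for p in profiles],
            }
        )
    else:
        frame = pd.DataFrame({"length": list(profiles), "v_family": "all", "j_gene": "all"})
    if (frame["length"] < 1).any():
        raise ValueError("lengths must be >= 1")

    def summarize(g: pd.Series) -> pd.Series:
        arr = g.to_numpy(dtype=float)
        return pd.Series({
            "n": len(arr),
            "median": float(np.median(arr)),
            "sigma": float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0,
            "q10": _nearest_rank(arr, 0.10),
            "q90": _nearest_rank(arr, 0.90),
        })

    if stratify:
        return frame.groupby(["v_family", "j_gene"])["length"].apply(summarize).unstack().reset_index()
    return summarize(frame["length"]).to_frame().T


def vj_pairing_matrix(profiles: Sequence[BiophysProfile]) -> pd.DataFrame:
    """Read fractions over V family x J gene; entries sum to 1."""
    if not profiles:
        raise ValueError("no profiles")
    frame = pd.DataFrame(
        {
            "v_family": [(p.v_gene or "?")[:5] for p in profiles],
            "j_gene": [p.j_gene or "?" for p in profiles],
        }
    )
    mat = pd.crosstab(frame["v_family"], frame["j_gene"])
    return mat / mat.to_numpy().sum()


def developability_summary(
    profiles: Sequence[BiophysProfile],
    pool_weights: Mapping[str, Sequence[BiophysProfile]] | None = None,
) -> dict[str, float]:
    """Class fractions over reads; with ``pool_weights`` (primer pool ->
    profiles), each pool contributes equal weight before pooling."""
    if pool_weights:
        pools = {k: v for k, v in pool_weights.items() if v}
        if not pools:
            raise ValueError("all pools empty")
        fracs = {c: 0.0 for c in DEVELOPABILITY_CLASSES}
        for members in pools.values():
            n = len(members)
            for p in members:
                fracs[p.developability] += 1.0 / n / len(pools)
        return fracs
    if not profiles:
        raise ValueError("no profiles")
    fracs = {c: 0.0 for c in DEVELOPABILITY_CLASSES}
    for p in profiles:
        fracs[p.developability] += 1.0 / len(profiles)
    return fracs


def pairwise_levenshtein_profile(keys: Sequence[str], max_pairs: int = 200_000,
                                 seed: int = 0) -> np.ndarray:
    """Distribution of pairwise edit distances among unique keys (subsampled
    uniformly when the number of pairs exceeds ``max_pairs``)."""
    from .clonotype import levenshtein

    uniq = sorted(set(keys))
    n = len(uniq)
    n_pairs = n * (n - 1) // 2
    rng = np.random.default_rng(seed)
    if n_pairs <= max_pairs:
        return np.array([
            levenshtein(uniq[i], uniq[j]) for i in range(n) for j in range(i + 1, n)
        ])
    out = np.empty(max_pairs, dtype=int)
    for t in range(max_pairs):
        i, j = rng.choice(n, size=2, replace=False)
        out[t] = levenshtein(uniq[i], uniq[j])
    return out
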