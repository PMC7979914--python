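"""Packaged reference data: germline V/J genes, primer panels, developability
classes, and physicochemical scale tables.

The germline set is a small synthetic-but-realistic curated reference (files
named ``*_synthetic*``) covering every V family addressed by the packaged
primer panels; it is representative, not an authoritative IMGT snapshot.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources as _ilr
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

DEVELOPABILITY_CLASSES = (
    "desirable",
    "common_in_natural",
    "neutral",
    "poorly_developable",
    "unclassified",
)

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"), "K": frozenset("GT"),
    "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_REGION_NAMES = ("FR1", "CDR1", "FR2", "CDR2", "FR3")


def _data_path(name: str) -> Path:
    return Path(str(_ilr.files("ablib").joinpath("data", name)))


@dataclass(frozen=True)
class GermlineGene:
    """A reference V or J gene segment.

    ``cdr_bounds`` holds 0-based half-open nucleotide intervals for
    FR1, CDR1, FR2, CDR2 and FR3 (V genes only).  ``anchor`` is the index of
    the conserved CDR3-flanking codon: the 2nd-Cys for V genes, the J-Trp/Phe
    for J genes.
    """

    name: str
    family: str
    chain: str  # heavy | kappa | lambda
    segment: str  # V | J
    nt_sequence: str
    anchor: int
    cdr_bounds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.name.startswith(self.family):
            raise ValueError(f"{self.name}: family {self.family} is not a name prefix")
        if self.chain not in ("heavy", "kappa", "lambda"):
            raise ValueError(f"{self.name}: bad chain {self.chain!r}")
        if self.segment not in ("V", "J"):
            raise ValueError(f"{self.name}: bad segment {self.segment!r}")
        if set(self.nt_sequence) - set("ACGT"):
            raise ValueError(f"{self.name}: non-ACGT characters in sequence")
        anchor_aa = str(Seq(self.nt_sequence[self.anchor:self.anchor + 3]).translate())
        expected = "C" if self.segment == "V" else "WF"
        if anchor_aa not in expected:
            raise ValueError(
                f"{self.name}: anchor codon translates to {anchor_aa!r}, expected one of {expected!r}"
            )
        if self.segment == "V":
            if len(self.cdr_bounds) != 5:
                raise ValueError(f"{self.name}: V gene needs 5 region intervals")
            prev = 0
            for (start, end), region in zip(self.cdr_bounds, _REGION_NAMES):
                if not (prev <= start < end <= len(self.nt_sequence)):
                    raise ValueError(f"{self.name}: bad {region} bounds [{start},{end})")
                if (end - start) % 3:
                    raise ValueError(f"{self.name}: {region} length not a codon multiple")
                prev = end

    @property
    def regions(self) -> dict[str, tuple[int, int]]:
        return dict(zip(_REGION_NAMES, self.cdr_bounds))


class GermlineReference:
    """Validated collection of germline genes with simple lookups."""

    def __init__(self, genes: Iterable[GermlineGene]):
        self.genes = list(genes)
        self._by_name: dict[str, GermlineGene] = {}
        for g in self.genes:
            if g.name in self._by_name:
                raise ValueError(f"duplicate germline gene name {g.name}")
            self._by_name[g.name] = g

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, name: str) -> GermlineGene:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def select(self, chain: str | None = None, segment: str | None = None) -> list[GermlineGene]:
        out = self.genes
        if chain is not None:
            out = [g for g in out if g.chain == chain]
        if segment is not None:
            out = [g for g in out if g.segment == segment]
        return out

    def families(self, chain: str, segment: str = "V") -> dict[str, list[GermlineGene]]:
        fams: dict[str, list[GermlineGene]] = {}
        for g in self.select(chain, segment):
            fams.setdefault(g.family, []).append(g)
        return fams


@dataclass(frozen=True)
class PrimerRecord:
    primer_id: str
    sequence: str
    intended_family: str
    intended_genes: tuple[str, ...] = ()
    orientation: str = "forward"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"{self.primer_id}: non-IUPAC characters {sorted(bad)}")
        if self.orientation == "forward" and self.sequence and len(self.sequence) != 18:
            raise ValueError(f"{self.primer_id}: forward V primers are 18 nt")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"{self.primer_id}: bad orientation {self.orientation!r}")


def load_germline_reference(
    fasta_path: str | Path | None = None,
    meta_path: str | Path | None = None,
) -> GermlineReference:
    """Load a germline V/J reference from FASTA plus a metadata table.

    Defaults to the packaged synthetic reference.  Every FASTA id must have a
    metadata row; the metadata carries family, chain, segment, the 0-based
    half-open FR/CDR nucleotide bounds (comma-separated, V genes) and the
    anchor-codon index.
    """
    fasta_path = _data_path("germline_synthetic.fasta") if fasta_path is None else Path(fasta_path)
    meta_path = _data_path("germline_synthetic.tsv") if meta_path is None else Path(meta_path)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    meta_by_name = {row["name"]: row for _, row in meta.iterrows()}
    genes = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        row = meta_by_name.get(record.id)
        if row is None:
            raise ValueError(f"germline FASTA entry {record.id!r} has no metadata row")
        bounds: tuple[tuple[int, int], ...] = ()
        if row["cdr_bounds"]:
            flat = [int(x) for x in row["cdr_bounds"].split(",")]
            bounds = tuple(zip(flat[::2], flat[1::2]))
        genes.append(
            GermlineGene(
                name=record.id,
                family=row["family"],
                chain=row["chain"],
                segment=row["segment"],
                nt_sequence=str(record.seq).upper(),
                anchor=int(row["anchor"]),
                cdr_bounds=bounds,
            )
        )
    return GermlineReference(genes)


def load_primer_panel(
    path: str | Path | None = None,
    orientation: str | None = "forward",
    chain_prefix: str | None = None,
) -> list[PrimerRecord]:
    """Load a primer panel TSV (id, sequence, intended family/genes, orientation).

    With no path, the packaged forward panel is loaded; ``chain_prefix``
    (e.g. ``"IGHV"``) restricts to one locus.
    """
    if path is None:
        path = _data_path(
            "primers_forward.tsv" if orientation != "reverse" else "primers_reverse_synthetic.tsv"
        )
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"primer_id", "sequence", "intended_family"}
    if missing := required - set(table.columns):
        raise ValueError(f"primer panel missing columns {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        rec = PrimerRecord(
            primer_id=row["primer_id"],
            sequence=row["sequence"].upper(),
            intended_family=row["intended_family"],
            intended_genes=tuple(g for g in row.get("intended_genes", "").split(",") if g),
            orientation=row.get("orientation", "forward") or "forward",
        )
        if orientation is not None and rec.orientation != orientation:
            continue
        if chain_prefix is not None and not rec.intended_family.startswith(chain_prefix):
            continue
        records.append(rec)
    return records


_DASHES = "‐‑‒–—−"


def normalize_gene_name(name: str, locus: str | None = None) -> str:
    """Canonicalize a gene identifier to IMGT style with ASCII hyphens.

    Printed tables abbreviate ``IGHV3-23`` as ``3-23`` (with assorted dash
    glyphs); ``locus`` supplies the missing prefix in that case.
    """
    s = name.strip()
    for d in _DASHES:
        s = s.replace(d, "-")
    s = re.sub(r"\s+", "", s)
    if locus and not s.upper().startswith("IG"):
        s = locus + s
    # strip leading zeros in numeric parts: 1-02 -> 1-2
    prefix = re.match(r"^(IG[HKL][VJ])(.*)$", s, re.IGNORECASE)
    if prefix:
        head, tail = prefix.group(1).upper(), prefix.group(2)
    else:
        head, tail = "", s
    parts = tail.split("-")
    parts = [p.lstrip("0") or "0" if p.isdigit() else p for p in parts]
    return head + "-".join(parts)


def load_developability_map(path: str | Path | None = None) -> dict[str, str]:
    """gene -> developability class; genes absent from the map are unclassified."""
    path = _data_path("developability.tsv") if path is None else Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    dmap: dict[str, str] = {}
    for _, row in table.iterrows():
        gene = normalize_gene_name(row["gene"])
        cls = row["class"]
        if cls not in DEVELOPABILITY_CLASSES:
            raise ValueError(f"unknown developability class {cls!r} for {gene}")
        if gene in dmap and dmap[gene] != cls:
            raise ValueError(f"gene {gene} mapped to two classes")
        dmap[gene] = cls
    return dmap


def classify_developability(gene: str, dmap: Mapping[str, str]) -> str:
    return dmap.get(normalize_gene_name(gene), "unclassified")


@dataclass(frozen=True)
class ScaleTable:
    """Per-residue numeric scale (hydropathy values or pK/sign pairs)."""

    name: str
    values: Mapping[str, float]
    signs: Mapping[str, int] = field(default_factory=dict)

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def __contains__(self, residue: str) -> bool:
        return residue in self.values


def load_scale_table(path: str | Path, name: str | None = None) -> ScaleTable:
    table = pd.read_csv(path, sep="\t")
    key = table.columns[0]
    if "sign" in table.columns:
        values = dict(zip(table[key], table["pk"].astype(float)))
        signs = dict(zip(table[key], table["sign"].astype(int)))
    else:
        values = dict(zip(table[key], table["value"].astype(float)))
        signs = {}
    return ScaleTable(name=name or Path(path).stem, values=values, signs=signs)


def kyte_doolittle() -> ScaleTable:
    """Kyte-Doolittle hydropathy scale over the 20 standard residues."""
    scale = load_scale_table(_data_path("kyte_doolittle.tsv"), "kyte_doolittle")
    missing = set("ACDEFGHIKLMNPQRSTVWY") - set(scale.values)
    if missing:
        raise ValueError(f"hydropathy scale missing residues {sorted(missing)}")
    return scale


def lehninger_pk() -> ScaleTable:
    """Lehninger side-chain and terminal pK values with charge signs."""
    return load_scale_table(_data_path("lehninger_pk.tsv"), "lehninger_pk")


def enumerate_pcr_combinations(
    forward: Iterable[PrimerRecord], reverse: Iterable[PrimerRecord]
) -> list[tuple[str, str]]:
    """All forward x reverse primer pairings used in the amplification scheme."""
    return [(f.primer_id, r.primer_id) for f in forward for r in reverse]


def enumerate_scfv_pools(heavy_forward: Iterable[PrimerRecord], light_pools: Iterable[str]) -> list[tuple[str, str]]:
    """scFv assembly pools: each heavy-primer amplicon x each pooled light repertoire."""
    return [(f.primer_id, pool) for f in heavy_forward for pool in light_pools]
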