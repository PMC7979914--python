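"""End-to-end orchestration: reads (simulated or from FASTQ) -> QC ->
germline annotation -> clonotype/diversity grid -> dominance, primer and
biophysics reports.

Every artifact is stamped with the config hash and seed; identical config and
seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotate as _annotate
from . import biophys as _biophys
from . import clonotype as _clonotype
from . import diversity as _diversity
from . import qc as _qc
from . import simulate as _simulate
from .resources import load_developability_map, load_germline_reference

CRITERIA = (0, 1, 2, 3, "abundance_only")
_CRIT_LABELS = ("hamming_0", "hamming_1", "hamming_2", "hamming_3", "abundance_only")


@dataclass
class PipelineConfig:
    chain: str = "heavy"
    outdir: str = "ablib_out"
    seed: int = 0
    # input: either a FASTQ path or synthetic generation parameters
    reads_fastq: str | None = None
    n_clones: int = 5000
    n_reads: int = 10000
    sub_rate: float = 0.002
    # stage settings
    qc_mode: str = "fraction_threshold"
    qc_min_q: int = 25
    qc_min_fraction: float = 0.90
    evalue_max: float = _annotate.EVALUE_DEFAULT
    identity_min: float = 0.90
    h_list: tuple[int, ...] = (0, 1, 2, 3)
    schemes: tuple[str, ...] = ("cdr3", "merged")
    estimate_richness: bool = True
    accumulation_reps: int = 2
    germline_fasta: str | None = None
    germline_meta: str | None = None

    def __post_init__(self) -> None:
        if not set(self.h_list) <= {0, 1, 2, 3}:
            raise ValueError("h_list must be a subset of {0,1,2,3}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("h_list", "schemes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def diversity_grid(
    annotations: Sequence[_annotate.Annotation],
    criteria: Sequence[int | str],
    estimate: bool = True,
    n_reps: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Table-style diversity grid: one row per clustering criterion, columns
    for unique CDR1, unique CDR3 (measured and estimated) and merged CDR1+3."""
    usable = [a for a in annotations if a.pass_filter and a.productive and a.cdr3_aa]
    cdr1_keys = [a.cdr1_aa for a in usable if a.cdr1_aa]
    cdr3_keys = [a.cdr3_aa for a in usable]
    merged_keys = [_clonotype.make_key(a, "merged") for a in usable if a.cdr1_aa]

    rows = []
    for criterion in criteria:
        label = criterion if criterion == "abundance_only" else f"hamming_{int(criterion)}"
        row: dict[str, object] = {"criterion": label, "reads": len(usable)}
        for label, keys, scheme in (
            ("unique_cdr1", cdr1_keys, "cdr3"),
            ("unique_cdr3", cdr3_keys, "cdr3"),
            ("cdr1_3_total", merged_keys, "merged"),
        ):
            if keys:
                table = _clonotype.hierarchical_clonotype(
                    pd.Series(keys).value_counts().to_dict(), criterion, scheme
                )
                row[label] = len(table)
            else:
                row[label] = 0
        if estimate and cdr3_keys:
            grid = np.unique(
                np.geomspace(max(10, len(cdr3_keys) // 50), len(cdr3_keys), 8).astype(int)
            )
            curve = _diversity.accumulation_curve(
                cdr3_keys, grid, criterion, "cdr3", n_reps, seed
            )
            row["cdr3_estimate"] = _diversity.fit_negative_exponential(curve).s_max
        else:
            row["cdr3_estimate"] = float("nan")
        rows.append(row)
    cols = ["criterion", "reads", "unique_cdr1", "unique_cdr3", "cdr3_estimate", "cdr1_3_total"]
    return pd.DataFrame(rows)[cols]


def combined_diversity(heavy_grid: pd.DataFrame, light_grid: pd.DataFrame) -> pd.DataFrame:
    """Combinatorial heavy x light totals: lox recombination pairs the two
    chains freely, so the combined diversity at each criterion is the product
    of the per-chain values."""
    h = heavy_grid.set_index("criterion")
    l = light_grid.set_index("criterion")
    common = [c for c in h.index if c in set(l.index)]
    cols = ["unique_cdr1", "unique_cdr3", "cdr3_estimate", "cdr1_3_total"]
    out = pd.DataFrame(
        {col: [float(h.at[c, col]) * float(l.at[c, col]) for c in common] for col in cols},
        index=pd.Index(common, name="criterion"),
    )
    return out.reset_index()


def j_usage_recovery(
    chain: str,
    j_genes: Sequence[str],
    n_clones: int = 20000,
    n_reads: int = 20000,
    seed: int = 1,
) -> dict:
    """Generate error-free reads at the chain's stated J mixing weights,
    annotate them, and measure the read-weighted share of ``j_genes``.

    Returns the measured percentage, the expected percentage from the mixing
    weights, and the design-effect-corrected binomial tolerance (reads are
    cluster-sampled by clone, so the effective n is (Σc)²/Σc²).
    """
    reference = load_germline_reference()
    spec = _simulate.chain_spec(chain, n_clones, seed=seed)
    clones = _simulate.generate_repertoire(spec, reference)
    reads = _simulate.simulate_reads(clones, n_reads, sub_rate=0.0, seed=seed + 1)
    annotations = _annotate.annotate_reads(reads, reference, chain)
    called = [a for a in annotations if a.pass_filter and a.j_gene]
    share = sum(a.j_gene in set(j_genes) for a in called) / len(called)
    expected = sum(spec.j_weights[j] for j in j_genes)
    n_eff = min(_simulate.effective_sample_size(clones), float(len(called)))
    tol = 3.0 * float(np.sqrt(expected * (1 - expected) / n_eff))
    return {
        "percent": 100.0 * share,
        "expected_percent": 100.0 * expected,
        "tolerance_percent": 100.0 * tol,
        "n_reads": len(called),
        "n_eff": n_eff,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full per-chain pipeline; returns the report bundle dict and
    writes artifacts under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "chain": cfg.chain}
    reference = load_germline_reference(cfg.germline_fasta, cfg.germline_meta)

    # stage 1: reads
    clones = None
    if cfg.reads_fastq:
        reads = _qc.read_fastq(cfg.reads_fastq)
    else:
        spec = _simulate.chain_spec(cfg.chain, cfg.n_clones, seed=cfg.seed)
        clones = _simulate.generate_repertoire(spec, reference)
        reads = _simulate.simulate_reads(
            clones, cfg.n_reads, cfg.sub_rate, seed=cfg.seed + 1
        )

    # stage 2: QC
    qc_cfg = _qc.QCConfig(cfg.qc_mode, cfg.qc_min_q, cfg.qc_min_fraction)
    passed, qc_stats = _qc.filter_by_phred(reads, qc_cfg)

    # stage 3: annotation
    ann_cfg = _annotate.AnnotateConfig(cfg.evalue_max, cfg.identity_min)
    annotations = _annotate.annotate_reads(passed, reference, cfg.chain, ann_cfg)
    _annotate.write_airr(annotations, outdir / "annotations.airr.tsv")

    # stage 4: clonotyping + diversity grid
    criteria = [*(h for h in (0, 1, 2, 3) if h in cfg.h_list), "abundance_only"]
    grid = diversity_grid(
        annotations, criteria, cfg.estimate_richness, cfg.accumulation_reps, cfg.seed
    )
    grid.to_csv(outdir / "diversity_grid.tsv", sep="\t", index=False)

    # stage 5: dominance / rank
    usable_counts = _clonotype.counts_from_annotations(annotations, "cdr3")
    dominance = {}
    if usable_counts:
        table = _clonotype.hierarchical_clonotype(usable_counts, 1, "cdr3")
        rank = _clonotype.cumulative_rank(table)
        dominance = {
            "clonal_dominance": _clonotype.clonal_dominance(table),
            "clones_to_half": rank.clones_to_half,
            "singleton_fraction": rank.copy_number_spectrum.get(1, 0.0),
        }

    # stage 6: biophysics
    dmap = load_developability_map()
    profiles = _biophys.profile_annotations(annotations, dmap)
    bio = {}
    if profiles:
        lengths = _biophys.length_distribution(profiles)
        bio = {
            "cdr3_length": lengths.iloc[0].to_dict(),
            "net_charge_median": float(np.median([p.net_charge for p in profiles])),
            "gravy_median": float(np.median([p.gravy for p in profiles])),
            "developability": _biophys.developability_summary(profiles),
        }
        _biophys.vj_pairing_matrix(profiles).to_csv(outdir / "vj_pairing.tsv", sep="\t")

    report = {
        **stamp,
        "qc": qc_stats.as_dict(),
        "annotation": {
            "reads_annotated": len(annotations),
            "pass_filter": sum(a.pass_filter for a in annotations),
            "productivity": (
                _annotate.productivity(annotations)
                if any(a.v_gene and a.j_gene for a in annotations) else None
            ),
        },
        "diversity_grid": grid.to_dict(orient="records"),
        "dominance": dominance,
        "biophysics": bio,
    }
    if clones is not None:
        report["ground_truth"] = {
            "n_clones": len(clones),
            "true_richness": _simulate.true_richness(clones),
        }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
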