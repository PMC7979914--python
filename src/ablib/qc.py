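"""Phred quality filtering of reads ahead of germline annotation.

Two criteria are exposed: a fraction threshold (at least ``min_fraction`` of
bases at Q >= ``min_q``; the pipeline default, Q>=25 over 90% of bases) and a
lower-quartile rule (25th percentile of base qualities >= ``min_q``, e.g. 37).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .simulate import ReadRecord


@dataclass(frozen=True)
class QCConfig:
    mode: str = "fraction_threshold"  # or "lower_quartile"
    min_q: int = 25
    min_fraction: float = 0.90

    def __post_init__(self) -> None:
        if self.mode not in ("fraction_threshold", "lower_quartile"):
            raise ValueError(f"unknown QC mode {self.mode!r}")
        if not 0 <= self.min_q <= 41:
            raise ValueError("min_q must be in [0, 41]")
        if self.mode == "fraction_threshold" and not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")


@dataclass
class QCStats:
    reads_in: int = 0
    reads_passed: int = 0
    failed_quality: int = 0
    failed_empty: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "reads_in": self.reads_in,
            "reads_passed": self.reads_passed,
            "failed_quality": self.failed_quality,
            "failed_empty": self.failed_empty,
        }


def _lower_quartile(phred: np.ndarray) -> int:
    """Nearest-rank (type-1) 25th percentile; unambiguous for short reads."""
    ordered = np.sort(phred)
    rank = max(1, int(np.ceil(0.25 * len(ordered))))
    return int(ordered[rank - 1])


def read_passes(read: ReadRecord, cfg: QCConfig) -> bool:
    phred = np.asarray(read.phred)
    if phred.size == 0:
        return False
    if cfg.mode == "fraction_threshold":
        return (phred >= cfg.min_q).sum() / phred.size >= cfg.min_fraction
    return _lower_quartile(phred) >= cfg.min_q


def filter_by_phred(
    reads: Iterable[ReadRecord], cfg: QCConfig | None = None
) -> tuple[list[ReadRecord], QCStats]:
    """Split a read stream into passing reads and attrition statistics."""
    cfg = cfg or QCConfig()
    stats = QCStats()
    passed: list[ReadRecord] = []
    for read in reads:
        stats.reads_in += 1
        if len(read.nt_sequence) == 0:
            stats.failed_empty += 1
            continue
        if read_passes(read, cfg):
            stats.reads_passed += 1
            passed.append(read)
        else:
            stats.failed_quality += 1
    return passed, stats


def read_fastq(path: str | Path) -> list[ReadRecord]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            ReadRecord(
                read_id=rec.id,
                nt_sequence=str(rec.seq),
                phred=np.array(rec.letter_annotations["phred_quality"], dtype=int),
                source_clone_id="",
            )
        )
    return reads
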