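"""Motif database (MDB) construction.

Short contiguous motifs (1–6 residues) are harvested from the training
sequences with sliding windows.  Each motif is assigned a class by
majority vote over the classes of the sequences its occurrences came
from (a sequence is class 1 when its phenotype is at or above the
threshold, class 0 otherwise) and a phenotype value equal to the mean
phenotype over the occurrences counted in the winning class.  These
(value, class) pairs are the elementary quantities against which regex
rule weights are trained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .datasets import PeptideDataset

logger = logging.getLogger(__name__)

#: Windows used when harvesting motifs from a sequence (single AAs
#: included — they feed per-residue composition analyses).
DEFAULT_WINDOW_SIZES = range(1, 7)
#: Windows retained in the motif database itself: 2-6 residues.  Single
#: residues are deliberately excluded — a database of single AAs would
#: hand every one-character pattern (plain letters, bracket classes) a
#: large trained weight while carrying almost no motif information.
MDB_WINDOW_SIZES = range(2, 7)


@dataclass
class MotifRecord:
    motif: str
    cest_value: float
    class_label: int
    count_class1: int
    count_class0: int

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("motif must be non-empty")
        if self.class_label not in (0, 1):
            raise ValueError(f"class_label must be 0 or 1, got {self.class_label}")
        if self.count_class1 < 0 or self.count_class0 < 0:
            raise ValueError("occurrence counts must be non-negative")
        if self.count_class1 == 0 and self.count_class0 == 0:
            raise ValueError("a motif record needs at least one occurrence")


@dataclass
class MotifDatabase:
    """Exact-string map motif → :class:`MotifRecord` plus the threshold."""

    records: dict[str, MotifRecord] = field(default_factory=dict)
    threshold: float = 12.5
    n_sequences: int = 0
    window_sizes: tuple[int, ...] = tuple(DEFAULT_WINDOW_SIZES)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, motif: str) -> bool:
        return motif in self.records

    def __iter__(self) -> Iterator[MotifRecord]:
        return iter(self.records.values())

    def lookup(self, motif: str) -> MotifRecord | None:
        """Exact lookup; ``None`` for unknown motifs (including any motif
        longer than the largest extraction window)."""
        return self.records.get(motif)

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            [
                {
                    "motif": r.motif,
                    "class": r.class_label,
                    "cest_value": r.cest_value,
                    "count1": r.count_class1,
                    "count0": r.count_class0,
                }
                for r in sorted(self.records.values(), key=lambda r: r.motif)
            ]
        )
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, threshold: float = 12.5) -> "MotifDatabase":
        frame = pd.read_csv(path, sep="\t")
        records = {
            str(row["motif"]): MotifRecord(
                str(row["motif"]), float(row["cest_value"]), int(row["class"]),
                int(row["count1"]), int(row["count0"]),
            )
            for _, row in frame.iterrows()
        }
        sizes = tuple(sorted({len(m) for m in records})) or tuple(MDB_WINDOW_SIZES)
        return cls(records, threshold=threshold, window_sizes=sizes)


def extract_motifs(
    sequence: str, sizes: Iterable[int] = DEFAULT_WINDOW_SIZES
) -> list[tuple[str, int]]:
    """All sliding-window substrings of ``sequence`` for each window size.

    Returns ``(motif, start)`` pairs, windows left to right within each
    size, 0-based positions.  A window size larger than the sequence
    contributes nothing.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    out: list[tuple[str, int]] = []
    for w in sizes:
        if w < 1:
            raise ValueError(f"window size must be >= 1, got {w}")
        for start in range(len(sequence) - w + 1):
            out.append((sequence[start : start + w], start))
    return out


def build_motif_db(
    train: PeptideDataset,
    threshold: float = 12.5,
    sizes: Iterable[int] = MDB_WINDOW_SIZES,
) -> MotifDatabase:
    """Build the motif database from a labeled training set.

    Class assignment of a sequence: phenotype >= ``threshold`` → class 1
    (the threshold itself — the gold-standard K12 value of 12.5 — counts
    as positive), else class 0.  Per unique motif, window occurrences are
    counted per class; the majority class wins (ties go to class 0) and
    the motif value is the mean phenotype over the *occurrences* counted
    in the winning class, which makes the build order-invariant.
    """
    sizes = tuple(sizes)
    # occurrence tallies: motif -> [count0, count1, phen_sum0, phen_sum1]
    tally: dict[str, list[float]] = {}
    for i, pep in enumerate(train):
        if pep.phenotype is None:
            raise ValueError(f"record {i} ({pep.sequence}) has no phenotype")
        cls = 1 if pep.phenotype >= threshold else 0
        for motif, _pos in extract_motifs(pep.sequence, sizes):
            t = tally.setdefault(motif, [0, 0, 0.0, 0.0])
            t[cls] += 1
            t[2 + cls] += pep.phenotype

    records: dict[str, MotifRecord] = {}
    for motif, (c0, c1, s0, s1) in tally.items():
        label = 1 if c1 > c0 else 0
        mean = (s1 / c1) if label == 1 else (s0 / c0)
        records[motif] = MotifRecord(motif, mean, label, int(c1), int(c0))
    logger.info(
        "motif database: %d motifs from %d sequences (windows %s)",
        len(records), len(train), sizes,
    )
    return MotifDatabase(
        records, threshold=threshold, n_sequences=len(train), window_sizes=sizes
    )
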