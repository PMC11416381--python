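"""Peptide datasets and dataset-level statistics.

The phenotype modelled throughout this package is a CEST-MRI contrast
readout (MTR_asym, in percent, measured at +3.6 ppm — the amide-proton
offset), but nothing in this module is specific to that assay: a dataset
is simply a list of short amino-acid sequences, each optionally paired
with one real-valued phenotype.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class DatasetFormatError(ValueError):
    """Raised when a dataset file cannot be interpreted."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains non-canonical residues."""


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with an optional phenotype value.

    Parameters
    ----------
    sequence
        Uppercase string over the 20 canonical one-letter codes.
    phenotype
        Real-valued phenotype (here: MTR_asym %, at 3.6 ppm), or ``None``
        for unlabeled peptides (e.g. candidate libraries).
    """

    sequence: str
    phenotype: float | None = None

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.phenotype is not None and not math.isfinite(self.phenotype):
            raise ValueError(
                f"phenotype of {self.sequence!r} is not finite: {self.phenotype}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(sequence: str, row: int | None = None) -> None:
    """Raise :class:`SequenceValidationError` unless ``sequence`` is a
    non-empty uppercase string over the canonical 20-letter alphabet."""
    if not sequence:
        raise SequenceValidationError(
            f"empty sequence{f' at row {row}' if row is not None else ''}"
        )
    for ch in sequence:
        if ch not in _AA_SET:
            where = f" at row {row}" if row is not None else ""
            raise SequenceValidationError(
                f"non-amino-acid character {ch!r} in sequence {sequence!r}{where}"
            )


@dataclass
class PeptideDataset:
    """An ordered collection of :class:`Peptide` records.

    ``splits``, when present, assigns each record a ``"train"`` or
    ``"test"`` label (a partition).  ``provenance`` is a free-text note
    carried through I/O for bookkeeping.
    """

    peptides: list[Peptide] = field(default_factory=list)
    splits: list[str] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.splits is not None and len(self.splits) != len(self.peptides):
            raise ValueError("splits must label every record")
        dupes = [s for s, c in Counter(p.sequence for p in self.peptides).items() if c > 1]
        if dupes:
            logger.warning("dataset contains duplicate sequences: %s", dupes[:5])

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i: int) -> Peptide:
        return self.peptides[i]

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    @property
    def phenotypes(self) -> np.ndarray:
        """Phenotypes as a float array; raises if any record is unlabeled."""
        vals = []
        for i, p in enumerate(self.peptides):
            if p.phenotype is None:
                raise ValueError(f"record {i} ({p.sequence}) has no phenotype")
            vals.append(p.phenotype)
        return np.asarray(vals, dtype=float)

    def subset(self, indices: Sequence[int], provenance: str = "") -> "PeptideDataset":
        return PeptideDataset(
            [self.peptides[i] for i in indices],
            provenance=provenance or self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": self.sequences,
                "cest": [p.phenotype for p in self.peptides],
            }
        )

    def to_csv(self, path: str | Path, dialect: str = "csv") -> None:
        sep = {"csv": ",", "tsv": "\t"}[dialect]
        self.to_frame().to_csv(path, sep=sep, index=False)


def read_dataset(path: str | Path, dialect: str = "csv") -> PeptideDataset:
    """Read a peptide table (``sequence`` column, optional ``cest`` column).

    Extra columns are ignored (logged).  FASTA files are accepted for
    unlabeled libraries when the filename ends in ``.fa``/``.fasta``.
    """
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta"}:
        peptides = [Peptide(str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        if not peptides:
            logger.warning("no sequences found in %s", path)
        return PeptideDataset(peptides, provenance=str(path))

    if dialect not in {"csv", "tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    try:
        frame = pd.read_csv(path, sep=sep, dtype={"sequence": str})
    except pd.errors.EmptyDataError:
        raise DatasetFormatError(f"{path}: no header row found") from None
    if "sequence" not in frame.columns:
        raise DatasetFormatError(f"{path}: missing required column 'sequence'")
    extra = [c for c in frame.columns if c not in ("sequence", "cest")]
    if extra:
        logger.info("%s: ignoring extra columns %s", path, extra)
    if frame.empty:
        logger.warning("%s: empty data section", path)

    peptides = []
    for row, rec in enumerate(frame.itertuples(index=False)):
        seq = getattr(rec, "sequence")
        if not isinstance(seq, str):
            raise DatasetFormatError(f"{path}: missing sequence at row {row}")
        validate_sequence(seq, row=row)
        phen = getattr(rec, "cest", None) if "cest" in frame.columns else None
        if phen is not None and (isinstance(phen, float) and math.isnan(phen)):
            phen = None
        peptides.append(Peptide(seq, None if phen is None else float(phen)))
    return PeptideDataset(peptides, provenance=str(path))


def split_dataset(
    ds: PeptideDataset, train_fraction: float, seed: int
) -> tuple[PeptideDataset, PeptideDataset]:
    """Randomly partition ``ds`` into train/test subsets.

    The train size is ``ceil(train_fraction * n)`` so that an 80% split of
    158 records yields the conventional 127/31 partition.  Reproducible
    for a fixed ``seed``; record order within each subset follows the
    original dataset order.
    """
    if not 0 < train_fraction <= 1:
        raise ValueError(f"train_fraction must be in (0, 1], got {train_fraction}")
    if len(ds) == 0:
        raise ValueError("cannot split an empty dataset")
    n = len(ds)
    n_train = int(math.ceil(train_fraction * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = sorted(order[:n_train].tolist())
    test_idx = sorted(order[n_train:].tolist())
    return (
        ds.subset(train_idx, provenance=f"{ds.provenance}[train]"),
        ds.subset(test_idx, provenance=f"{ds.provenance}[test]"),
    )


def percent_identity(a: str, b: str) -> float:
    """Position-by-position percent identity of two unaligned sequences.

    Matches are counted left-anchored over the shared prefix length and
    divided by the length of the *longer* sequence, so identity between
    sequences of unequal length is bounded below 100.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * matches / max(len(a), len(b))


def identity_distribution(
    ds: PeptideDataset, bin_width: float = 10.0, cutoff: float = 50.0
) -> dict:
    """Histogram of all pairwise percent identities.

    Bins are ``[i, i + bin_width)`` with the final bin closed at 100 so a
    pair of identical sequences lands in the top bin.  Returns bin edges,
    the fraction of pairs per bin, and the fraction of pairs strictly
    above ``cutoff``.
    """
    n = len(ds)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    seqs = ds.sequences
    idents = np.array(
        [percent_identity(seqs[i], seqs[j]) for i in range(n) for j in range(i + 1, n)]
    )
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    edges[-1] = 100.0
    counts, _ = np.histogram(idents, bins=edges)
    # np.histogram already treats the last bin as closed on the right.
    fractions = counts / idents.size
    return {
        "bin_edges": edges,
        "fractions": fractions,
        "n_pairs": int(idents.size),
        "identities": idents,
        "cutoff": cutoff,
        "fraction_above_cutoff": float(np.mean(idents > cutoff)),
    }


def aa_frequencies(ds: PeptideDataset) -> dict[str, float]:
    """Relative frequency of each canonical residue over all sequences."""
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    counts = Counter()
    for p in ds:
        counts.update(p.sequence)
    total = sum(counts.values())
    return {aa: counts.get(aa, 0) / total for aa in AMINO_ACIDS}


def mtr_asym(s_neg: float, s_pos: float, s0: float) -> float:
    """Magnetization-transfer-ratio asymmetry (S(−Δ) − S(+Δ)) / S0.

    Utility for turning z-spectral amplitudes at ±Δ ppm into the CEST
    contrast phenotype used throughout the package (multiply by 100 for
    percent units).
    """
    if s0 <= 0:
        raise ValueError(f"reference signal must be positive, got {s0}")
    return (s_neg - s_pos) / s0


@dataclass(frozen=True)
class HydropathyScale:
    """Per-residue hydrophilicity contributions (positive = hydrophilic).

    Exactly one value per canonical amino acid.  The packaged default,
    :func:`wimley_white_interface`, is the Wimley–White water→POPC
    bilayer-interface transfer free-energy scale (kcal/mol) with charged
    side chains for D, E, K, R and neutral histidine; with this sign
    convention a positive sum over a peptide indicates water solubility.
    """

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != _AA_SET:
            missing = _AA_SET - keys
            extra = keys - _AA_SET
            raise ValueError(
                f"scale must cover exactly the 20 canonical AAs "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    def __contains__(self, aa: str) -> bool:
        return aa in self.values

    @classmethod
    def from_file(cls, path: str | Path) -> "HydropathyScale":
        """Load a two-column (``aa``, ``value``) CSV/TSV scale file."""
        frame = pd.read_csv(path, sep=None, engine="python")
        frame.columns = [c.strip().lower() for c in frame.columns]
        if not {"aa", "value"} <= set(frame.columns):
            raise DatasetFormatError(f"{path}: expected columns 'aa' and 'value'")
        return cls({str(r.aa).strip().upper(): float(r.value) for r in frame.itertuples()})


#: Wimley & White interface scale, hydrophilicity sign convention
#: (water → POPC interface ΔG, kcal/mol; D−, E−, K+, R+, neutral H).
_WW_INTERFACE = {
    "A": 0.17, "R": 0.81, "N": 0.42, "D": 1.23, "C": -0.24,
    "Q": 0.58, "E": 2.02, "G": 0.01, "H": 0.17, "I": -0.31,
    "L": -0.56, "K": 0.99, "M": -0.23, "F": -1.13, "P": 0.45,
    "S": 0.13, "T": 0.14, "W": -1.85, "Y": -0.94, "V": 0.07,
}


def wimley_white_interface() -> HydropathyScale:
    """The default hydrophilicity scale (see :class:`HydropathyScale`)."""
    return HydropathyScale(dict(_WW_INTERFACE))
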