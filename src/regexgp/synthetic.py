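"""Synthetic peptide datasets with planted, known structure.

The generator emulates the statistical shape of the CEST peptide study
data — 10–13-mers over the 20-letter alphabet, a composition enriched
in K/R/S/T, phenotypes in roughly 0–20 with a meaningful class boundary
at 12.5, and mostly <10–20% pairwise identity — while making the
sequence→phenotype map exactly known: the phenotype is a clamped
additive function of planted motif occurrence counts plus Gaussian
noise.  Every pipeline stage (motif database, weight training, the
evolutionary search, directed evolution) can therefore be tested for
*recovery* of planted structure without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .datasets import AMINO_ACIDS, Peptide, PeptideDataset, validate_sequence
from .model import Model, Rule


@dataclass(frozen=True)
class PlantedEffectTable:
    """Additive ground-truth phenotype model.

    phenotype(seq) = clamp(baseline + Σ_m effect[m] · count(m in seq)
    + Normal(0, noise_sd)), with overlapping occurrences counted (the
    same convention the motif database uses).
    """

    effects: Mapping[str, float]
    baseline: float = 6.0
    noise_sd: float = 1.0
    clamp: tuple[float, float] = (0.0, 25.0)

    def __post_init__(self) -> None:
        for motif in self.effects:
            validate_sequence(motif)
            if not 1 <= len(motif) <= 6:
                raise ValueError(f"planted motif {motif!r} must be 1-6 residues")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def phenotype(self, sequence: str, noise: float = 0.0) -> float:
        lo, hi = self.clamp
        value = self.baseline + noise
        for motif, effect in self.effects.items():
            value += effect * count_occurrences(sequence, motif)
        return float(min(max(value, lo), hi))


def count_occurrences(sequence: str, motif: str) -> int:
    """Occurrences of ``motif`` in ``sequence``, overlapping included."""
    return sum(
        1
        for start in range(len(sequence) - len(motif) + 1)
        if sequence[start : start + len(motif)] == motif
    )


def default_profile() -> PlantedEffectTable:
    """The default emulation profile: a handful of planted di-residue
    motifs with effects sized so phenotypes spread over ~0–20 and a
    sizeable minority (~15–20%) of sequences clear the 12.5 class
    boundary — the boundary has to separate real classes for the motif
    database and weight training to be exercised meaningfully."""
    return PlantedEffectTable(
        effects={"KK": 5.0, "SK": 4.0, "QS": 3.0, "EE": -4.0},
        baseline=8.0,
        noise_sd=1.0,
        clamp=(0.0, 25.0),
    )


def single_motif_profile(
    motif: str = "KS", effect: float = 8.0, noise_sd: float = 1.0
) -> PlantedEffectTable:
    """A profile with one dominant planted motif, for recovery tests.

    ``KS`` is the default because both residues are common under the
    default composition bias, so the motif occurs in a workable
    fraction (~15–20%) of generated sequences.
    """
    return PlantedEffectTable(
        effects={motif: effect}, baseline=6.0, noise_sd=noise_sd, clamp=(0.0, 25.0)
    )


#: Residue-sampling weights qualitatively mirroring the study data:
#: enriched K/R/S/T (and W), depleted aromatic hydrophobics.
DEFAULT_COMPOSITION = {
    **{aa: 1.0 for aa in AMINO_ACIDS},
    "K": 3.0, "R": 2.2, "S": 2.2, "T": 2.0, "W": 1.5, "Y": 0.5, "F": 0.5,
}


def generate_dataset(
    n: int,
    effects: PlantedEffectTable | None = None,
    rng: np.random.Generator | int | None = None,
    length_range: tuple[int, int] = (10, 13),
    composition: Mapping[str, float] | None = None,
) -> PeptideDataset:
    """Draw ``n`` peptides residue-wise from the composition distribution
    and label them with the planted-effect phenotype.  Fully reproducible
    given a seed or seeded generator."""
    if n < 1:
        raise ValueError("n must be >= 1")
    effects = effects if effects is not None else default_profile()
    rng = np.random.default_rng(rng)
    composition = composition or DEFAULT_COMPOSITION
    letters = list(AMINO_ACIDS)
    probs = np.array([composition.get(aa, 0.0) for aa in letters], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("composition weights must have positive mass")
    probs = probs / probs.sum()

    lo, hi = length_range
    peptides = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        noise = float(rng.normal(0.0, effects.noise_sd)) if effects.noise_sd else 0.0
        peptides.append(Peptide(seq, effects.phenotype(seq, noise)))
    return PeptideDataset(peptides, provenance=f"synthetic(n={n})")


def motif_enrichment(peptides: Iterable[str], motif: str) -> float:
    """Fraction of peptides containing ``motif`` as a substring."""
    if not motif:
        raise ValueError("motif must be non-empty")
    peptides = list(peptides)
    if not peptides:
        return 0.0
    return sum(motif in p for p in peptides) / len(peptides)


def fixture_model() -> Model:
    """A small hand-written model with exactly known scores, shared by
    the test suite: K-runs are strongly positive, acidic residues
    penalized, the QS motif mildly positive."""
    return Model(
        [
            Rule(0, pattern="K+", weight=3.0),
            Rule(1, pattern="[ED]", weight=-2.0),
            Rule(2, pattern="QS", weight=1.5),
        ]
    )
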