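"""Composition vectors, Shannon complexity, Kyte-Doolittle hydropathy, set fractions.

Complexity is the natural-log Shannon entropy of the amino-acid frequency
distribution (range 0 to ln 20, about 3.0). Plug-in frequencies are used with
0*ln 0 = 0; no pseudocounts or finite-sample corrections are applied.
Rounding for comparison against published values is never done here.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import AMINO_ACIDS, ProteinRecord

#: Kyte & Doolittle hydropathy scale (original 1982 values), one entry per residue.
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Fraction above which a residue counts as "highly enriched" in heatmaps.
ENRICHMENT_THRESHOLD = 0.15

MAX_ENTROPY = math.log(20)


@dataclass(frozen=True)
class CompositionProfile:
    """Per-residue fractions of one sequence (all 20 amino acids, zeros included)."""

    fractions: Mapping[str, float]
    length: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        if any(not 0.0 <= f <= 1.0 for f in self.fractions.values()):
            raise ValueError("fractions must lie in [0, 1]")

    def as_vector(self) -> np.ndarray:
        """Fractions in canonical ``AMINO_ACIDS`` column order."""
        return np.array([self.fractions[a] for a in AMINO_ACIDS])


@dataclass(frozen=True)
class ComplexityScore:
    entropy: float  # natural-log units

    def __post_init__(self) -> None:
        if not -1e-12 <= self.entropy <= MAX_ENTROPY + 1e-12:
            raise ValueError(f"entropy {self.entropy} outside [0, ln 20]")


@dataclass(frozen=True)
class HydropathyScore:
    mean_hydropathy: float  # Kyte-Doolittle units

    def __post_init__(self) -> None:
        if not -4.5 - 1e-12 <= self.mean_hydropathy <= 4.5 + 1e-12:
            raise ValueError(f"mean hydropathy {self.mean_hydropathy} outside scale range")


def aa_composition(record: ProteinRecord) -> CompositionProfile:
    """fractions = counts / length over all 20 amino acids."""
    counts = Counter(record.sequence)
    n = len(record.sequence)
    return CompositionProfile({a: counts.get(a, 0) / n for a in AMINO_ACIDS}, n)


def composition_matrix(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """Sequences x 20 composition matrix with an enrichment flag column.

    Row index is the record id; the final ``enriched_gt_15pct`` column lists
    residues whose fraction exceeds :data:`ENRICHMENT_THRESHOLD` (empty string
    if none), matching the "dark red" heatmap category.
    """
    if not records:
        raise ValueError("composition_matrix requires at least one record")
    rows = [aa_composition(r).as_vector() for r in records]
    df = pd.DataFrame(rows, index=[r.id for r in records], columns=list(AMINO_ACIDS))
    df["enriched_gt_15pct"] = [
        ",".join(a for a in AMINO_ACIDS if row[AMINO_ACIDS.index(a)] > ENRICHMENT_THRESHOLD)
        for row in rows
    ]
    return df


def shannon_complexity(record: ProteinRecord) -> ComplexityScore:
    """Natural-log Shannon entropy of the composition, -sum p ln p over p > 0."""
    profile = aa_composition(record)
    entropy = -sum(p * math.log(p) for p in profile.fractions.values() if p > 0)
    return ComplexityScore(max(entropy, 0.0))


def mean_hydropathy(record: ProteinRecord) -> HydropathyScore:
    """Arithmetic mean of Kyte-Doolittle values over all residues."""
    values = [KYTE_DOOLITTLE[c] for c in record.sequence]
    return HydropathyScore(sum(values) / len(values))


def fraction_of_set(record: ProteinRecord, residue_set: Iterable[str]) -> float:
    """(count of residues in ``residue_set``) / length."""
    members = frozenset(residue_set)
    if not members:
        raise ValueError("residue_set must be non-empty")
    unknown = members - frozenset(AMINO_ACIDS)
    if unknown:
        raise ValueError(f"unknown residues in set: {sorted(unknown)}")
    return sum(1 for c in record.sequence if c in members) / len(record.sequence)


def composition_percent_difference(
    query: CompositionProfile, reference: CompositionProfile
) -> np.ndarray:
    """Signed 20-vector of 100 * (query - reference), positive = query enriched.

    Column order follows ``AMINO_ACIDS``.
    """
    return 100.0 * (query.as_vector() - reference.as_vector())
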