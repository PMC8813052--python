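"""Seeded generators for synthetic sequences, proteomes, and kappa ladders.

Everything here is a pure function of (config, seed). The synthetic proteome
emulates the shape of real pipeline input: proteins assembled from alternating
ordered/disordered blocks with distinct composition profiles, plus noisy
indicator disorder tracks with known ground-truth boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import charge_patterning as cp
from .composition_metrics import CompositionProfile
from .disorder_segmentation import DisorderTrack
from .sequence_io import AMINO_ACIDS, ProteinRecord, Region

# Ordered blocks enrich branched hydrophobics and deplete charge; disordered
# blocks do the opposite. Magnitudes are test-harness choices, not claims.
_ORDERED_WEIGHTS = {
    "A": 8, "C": 2, "D": 4, "E": 4, "F": 5, "G": 6, "H": 2, "I": 8, "K": 4,
    "L": 11, "M": 3, "N": 4, "P": 3, "Q": 3, "R": 4, "S": 6, "T": 5, "V": 9,
    "W": 2, "Y": 4,
}
_DISORDERED_WEIGHTS = {
    "A": 7, "C": 1, "D": 7, "E": 10, "F": 2, "G": 7, "H": 2, "I": 3, "K": 9,
    "L": 5, "M": 2, "N": 4, "P": 8, "Q": 5, "R": 7, "S": 10, "T": 6, "V": 4,
    "W": 1, "Y": 2,
}


def _profile(weights: Mapping[str, float]) -> CompositionProfile:
    total = sum(weights.values())
    return CompositionProfile({a: weights[a] / total for a in AMINO_ACIDS}, 0)


ORDERED_PROFILE = _profile(_ORDERED_WEIGHTS)
DISORDERED_PROFILE = _profile(_DISORDERED_WEIGHTS)


def sample_sequence(
    profile: CompositionProfile, length: int, seed: int | np.random.Generator
) -> ProteinRecord:
    """i.i.d. residues drawn from the profile; reproducible given the seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    probs = profile.as_vector()
    if (probs < 0).any():
        raise ValueError("degenerate profile with negative mass")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    letters = rng.choice(list(AMINO_ACIDS), size=length, p=probs / probs.sum())
    return ProteinRecord(f"synth_{length}", "".join(letters))


@dataclass(frozen=True)
class SyntheticProteomeConfig:
    n_proteins: int = 100
    blocks_per_protein: tuple[int, int] = (2, 5)  # inclusive range
    block_length_range: tuple[int, int] = (120, 300)  # inclusive range
    ordered_profile: CompositionProfile = ORDERED_PROFILE
    disordered_profile: CompositionProfile = DISORDERED_PROFILE
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_proteome(
    config: SyntheticProteomeConfig,
) -> tuple[list[ProteinRecord], list[DisorderTrack], list[Region]]:
    """Proteins built from labeled blocks, plus noisy indicator disorder tracks.

    Returns (records, tracks, ground-truth regions). Disorder scores are the
    block indicator (1 = disordered) with additive Gaussian noise clipped to
    [0, 1].
    """
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    tracks: list[DisorderTrack] = []
    truth: list[Region] = []
    for p in range(config.n_proteins):
        pid = f"synth{p:04d}"
        n_blocks = int(rng.integers(config.blocks_per_protein[0], config.blocks_per_protein[1] + 1))
        start_disordered = bool(rng.integers(0, 2))
        seq_parts: list[str] = []
        scores = np.empty(0)
        pos = 1
        for b in range(n_blocks):
            disordered = (b % 2 == 0) == start_disordered
            length = int(
                rng.integers(config.block_length_range[0], config.block_length_range[1] + 1)
            )
            profile = config.disordered_profile if disordered else config.ordered_profile
            seq_parts.append(sample_sequence(profile, length, rng).sequence)
            scores = np.concatenate([scores, np.full(length, 1.0 if disordered else 0.0)])
            truth.append(
                Region(pid, pos, pos + length - 1, "disordered" if disordered else "ordered")
            )
            pos += length
        noisy = np.clip(scores + rng.normal(0.0, config.noise_sd, size=scores.size), 0.0, 1.0)
        records.append(ProteinRecord(pid, "".join(seq_parts)))
        tracks.append(DisorderTrack(pid, tuple(float(s) for s in noisy)))
    return records, tracks, truth


@dataclass(frozen=True)
class KappaLadderSpec:
    composition: str  # fixed multiset of residues, given as a sequence string
    n_steps: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        q = cp.charge_vector(self.composition)
        if not ((q > 0).any() and (q < 0).any()):
            raise ValueError("ladder composition needs both charge signs")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


def _alternating_start(composition: str) -> str:
    """Maximally alternating arrangement: charges interleaved by sign, neutral
    residues spread evenly between them."""
    pos = [c for c in composition if cp.classify_charge(c) > 0]
    neg = [c for c in composition if cp.classify_charge(c) < 0]
    neu = [c for c in composition if cp.classify_charge(c) == 0]
    charged: list[str] = []
    a, b = (pos, neg) if len(pos) >= len(neg) else (neg, pos)
    ia = ib = 0
    for k in range(len(pos) + len(neg)):
        if ia * len(b) <= ib * len(a) and ia < len(a) or ib >= len(b):
            charged.append(a[ia])
            ia += 1
        else:
            charged.append(b[ib])
            ib += 1
    L = len(composition)
    n_charged = len(charged)
    slots = set()
    for i in range(n_charged):
        s = int(round((i + 0.5) * L / n_charged - 0.5))
        while s in slots:
            s += 1
        slots.add(s)
    out: list[str | None] = [None] * L
    it_c = iter(charged)
    for s in sorted(slots):
        out[s] = next(it_c)
    it_n = iter(neu)
    for i in range(L):
        if out[i] is None:
            out[i] = next(it_n)
    return "".join(out)  # type: ignore[arg-type]


def kappa_ladder(spec: KappaLadderSpec) -> list[ProteinRecord]:
    """Permutations of one multiset ordered from well-mixed to segregated.

    Starts from a maximally alternating arrangement and hill-climbs with
    seeded swap moves accepted only when kappa strictly increases; snapshots
    are taken at n_steps evenly spaced points of the accepted-move history,
    so kappa is non-decreasing along the returned list by construction.
    """
    rng = np.random.default_rng(spec.seed)
    chars = list(_alternating_start(spec.composition))
    L = len(chars)
    q = np.array([cp.classify_charge(c) for c in chars], dtype=np.int8)
    n_pos = int((q > 0).sum())
    n_neg = int((q < 0).sum())
    dmax = {g: cp.delta_max(n_pos, n_neg, L - n_pos - n_neg, g) for g in cp.KAPPA_BLOB_SIZES}

    def kappa_of(qv: np.ndarray) -> float:
        return float(np.mean([cp._delta(qv, g) / dmax[g] for g in cp.KAPPA_BLOB_SIZES]))

    history = ["".join(chars)]
    current = kappa_of(q)
    rejections = 0
    while rejections < 400:
        i, j = rng.integers(0, L, size=2)
        if q[i] == q[j]:
            rejections += 1
            continue
        q[i], q[j] = q[j], q[i]
        candidate = kappa_of(q)
        if candidate > current + 1e-12:
            chars[i], chars[j] = chars[j], chars[i]
            current = candidate
            history.append("".join(chars))
            rejections = 0
        else:
            q[i], q[j] = q[j], q[i]
            rejections += 1
    idx = np.linspace(0, len(history) - 1, num=min(spec.n_steps, len(history)))
    records = []
    for rank, h in enumerate(sorted(set(int(round(i)) for i in idx))):
        records.append(ProteinRecord(f"ladder{rank:02d}", history[h]))
    return records
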