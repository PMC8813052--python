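"""Sliding-window tracks, hydrophobic run-length partitioning, and CDK motif scans.

Windows are reported by their 1-based start position and tracks carry no edge
padding, so a track over a length-L sequence with window w has L - w + 1
values. Threshold comparisons on fraction tracks use exact rational
arithmetic (integer counts over the window size) to avoid float pitfalls at
values like 3/5.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Literal, Mapping

import numpy as np

from .charge_patterning import charge_vector
from .sequence_io import ProteinRecord

BRANCHED_HYDROPHOBICS = frozenset("LIV")

#: CDK consensus patterns: minimal [S/T]P; full [S/T]PX[R/K].
CDK_MINIMAL = re.compile(r"(?=([ST]P))")
CDK_FULL = re.compile(r"[ST]P.[RK]")

RUN_CLASSES = ("1", "2", "3+")


@dataclass(frozen=True)
class WindowTrack:
    protein_id: str
    window_size: int
    values: tuple[float, ...]
    start_positions: tuple[int, ...]  # 1-based start of each window
    counts: tuple[int, ...] | None = None  # integer numerators for fraction tracks

    def __post_init__(self) -> None:
        if len(self.values) != len(self.start_positions):
            raise ValueError("values and start_positions must align")

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self) -> str:
        lines = ["start\tvalue"]
        lines += [f"{p}\t{v:.6g}" for p, v in zip(self.start_positions, self.values)]
        return "\n".join(lines) + "\n"


def _starts(n_windows: int) -> tuple[int, ...]:
    return tuple(range(1, n_windows + 1))


def ncpr_track(record: ProteinRecord | str, window: int = 5) -> WindowTrack:
    """Net charge per residue over a sliding window (no padding)."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    if len(seq) < window:
        raise ValueError(f"sequence shorter than window {window}")
    q = charge_vector(seq).astype(float)
    vals = np.convolve(q, np.ones(window), "valid") / window
    return WindowTrack(
        protein_id=getattr(record, "id", "?"),
        window_size=window,
        values=tuple(float(v) for v in vals),
        start_positions=_starts(len(vals)),
    )


def fraction_track(
    record: ProteinRecord | str,
    residue_set: Iterable[str] = BRANCHED_HYDROPHOBICS,
    window: int = 5,
) -> WindowTrack:
    """Fraction of window residues belonging to ``residue_set``."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    members = frozenset(residue_set)
    if not members:
        raise ValueError("residue_set must be non-empty")
    if len(seq) < window:
        raise ValueError(f"sequence shorter than window {window}")
    indicator = np.array([1 if c in members else 0 for c in seq])
    counts = np.convolve(indicator, np.ones(window, dtype=int), "valid")
    return WindowTrack(
        protein_id=getattr(record, "id", "?"),
        window_size=window,
        values=tuple(int(c) / window for c in counts),
        start_positions=_starts(len(counts)),
        counts=tuple(int(c) for c in counts),
    )


def count_windows_at_or_above(track: WindowTrack, threshold: float) -> int:
    """Number of windows with value >= threshold.

    For fraction tracks (integer counts available) the comparison is exact:
    count/window >= threshold as rationals, with the threshold taken at its
    decimal-literal value (``0.6`` means 3/5, not the nearest binary float).
    """
    if track.counts is not None:
        thr = Fraction(str(threshold))
        return sum(1 for c in track.counts if Fraction(c, track.window_size) >= thr)
    return int(sum(1 for v in track.values if v >= threshold))


def merged_regions_at_or_above(track: WindowTrack, threshold: float) -> list[tuple[int, int]]:
    """Threshold-exceeding windows merged wherever their residue spans overlap.

    Returns 1-based inclusive (start, end) spans covering the union of each
    overlapping group of qualifying windows; this is the "distinct peak
    region" count as opposed to the raw overlapping-window count.
    """
    if track.counts is not None:
        thr = Fraction(str(threshold))
        hits = [Fraction(c, track.window_size) >= thr for c in track.counts]
    else:
        hits = [v >= threshold for v in track.values]
    spans = [
        (start, start + track.window_size - 1)
        for start, hit in zip(track.start_positions, hits)
        if hit
    ]
    regions: list[tuple[int, int]] = []
    for start, end in spans:
        if regions and start <= regions[-1][1]:
            regions[-1] = (regions[-1][0], max(regions[-1][1], end))
        else:
            regions.append((start, end))
    return regions


@dataclass(frozen=True)
class RunPartition:
    """Residue-weighted partition of set-residues by maximal-run length class."""

    counts: Mapping[str, int]  # run-length class -> residues in that class
    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total > 0 and abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def total_residues(self) -> int:
        return sum(self.counts.values())


def run_length_partition(
    record: ProteinRecord | str, residue_set: Iterable[str] = BRANCHED_HYDROPHOBICS
) -> RunPartition:
    """Attribute each set-residue to its maximal run's length class (1, 2, 3+)."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    members = frozenset(residue_set)
    pattern = re.compile("[" + "".join(sorted(members)) + "]+")
    counts = {c: 0 for c in RUN_CLASSES}
    for match in pattern.finditer(seq):
        n = len(match.group())
        key = "3+" if n >= 3 else str(n)
        counts[key] += n
    total = sum(counts.values())
    fractions = {c: (counts[c] / total if total else 0.0) for c in RUN_CLASSES}
    return RunPartition(counts=counts, fractions=fractions)


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    position: int  # 1-based start of the matched text
    kind: Literal["full", "minimal"]
    matched_text: str


def scan_cdk_sites(record: ProteinRecord | str) -> list[MotifHit]:
    """All CDK consensus sites, overlapping hits included.

    Every [S/T]P occurrence yields one hit; hits whose 4-residue extension
    matches [S/T]PX[R/K] are labeled ``full`` (matched_text is then the
    4-mer), the rest ``minimal`` (matched_text is the 2-mer).
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    pid = getattr(record, "id", "?")
    hits: list[MotifHit] = []
    for m in CDK_MINIMAL.finditer(seq):
        start = m.start()
        quad = seq[start : start + 4]
        if len(quad) == 4 and CDK_FULL.fullmatch(quad):
            hits.append(MotifHit(pid, start + 1, "full", quad))
        else:
            hits.append(MotifHit(pid, start + 1, "minimal", seq[start : start + 2]))
    return hits
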