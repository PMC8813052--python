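"""Proteome-scale disorder pipeline: smooth score tracks, segment, summarize.

Disorder scores come from an external predictor through tabular files (the
package never shells out to a predictor); a deterministic charge/hydropathy
surrogate is provided so the pipeline can be exercised without one.

Conventions: residues with smoothed score >= threshold are disordered;
maximal same-label runs strictly longer than ``min_length`` are emitted and
shorter runs are dropped (not merged). "Longer than N" is strict throughout.
Quantiles use linear interpolation between order statistics (numpy default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from . import composition_metrics as cm
from .charge_patterning import charge_vector
from .sequence_io import AMINO_ACIDS, ProteinRecord, Region

DISORDER_THRESHOLD = 0.5
SMOOTHING_WINDOW = 20
COMPLEXITY_MIN_LENGTH = 150  # strict lower bound for complexity summaries
FEATURE_MIN_LENGTH = 100  # strict lower bound for composition/hydropathy/LIV


@dataclass(frozen=True)
class DisorderTrack:
    """Per-residue disorder propensity scores in [0, 1] for one protein."""

    protein_id: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        if arr.size == 0:
            raise ValueError("empty disorder track")
        if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
            raise ValueError("disorder scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class DisorderSegment:
    """A labeled contiguous region with its per-segment sequence statistics."""

    region: Region
    mean_score: float
    composition: cm.CompositionProfile
    hydropathy: float
    complexity: float
    fraction_liv: float

    def __post_init__(self) -> None:
        if self.region.label not in ("ordered", "disordered"):
            raise ValueError("segment label must be ordered or disordered")

    @property
    def length(self) -> int:
        return self.region.length


def smooth_track(track: DisorderTrack, window: int = SMOOTHING_WINDOW) -> DisorderTrack:
    """Centered moving average with truncated edges; output length = input length.

    For even windows the span is right-heavy: position i averages scores over
    [i - (window-1)//2, i + window//2], intersected with the track.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    scores = np.asarray(track.scores, dtype=float)
    n = len(scores)
    if window > n:
        import warnings

        warnings.warn(
            f"smoothing window {window} exceeds track length {n}; using the global mean"
        )
    left = (window - 1) // 2
    right = window // 2
    cs = np.concatenate(([0.0], np.cumsum(scores)))
    lo = np.clip(np.arange(n) - left, 0, n)
    hi = np.clip(np.arange(n) + right + 1, 0, n)
    smoothed = (cs[hi] - cs[lo]) / (hi - lo)
    return DisorderTrack(track.protein_id, tuple(float(v) for v in smoothed))


def segment_track(
    record: ProteinRecord,
    smoothed: DisorderTrack,
    threshold: float = DISORDER_THRESHOLD,
    min_length: int = FEATURE_MIN_LENGTH,
) -> list[DisorderSegment]:
    """Split a protein into maximal ordered/disordered runs longer than min_length."""
    if len(smoothed) != len(record.sequence):
        raise ValueError(
            f"track length {len(smoothed)} does not match sequence length "
            f"{len(record.sequence)} for {record.id!r}"
        )
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    labels = np.asarray(smoothed.scores) >= threshold
    segments: list[DisorderSegment] = []
    start = 0
    n = len(labels)
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            if i - start > min_length:
                segments.append(
                    _build_segment(record, smoothed, start + 1, i, bool(labels[start]))
                )
            start = i
    return segments


def _build_segment(
    record: ProteinRecord, track: DisorderTrack, start: int, end: int, disordered: bool
) -> DisorderSegment:
    sub = ProteinRecord(f"{record.id}_{start}-{end}", record.sequence[start - 1 : end])
    return DisorderSegment(
        region=Region(record.id, start, end, "disordered" if disordered else "ordered"),
        mean_score=float(np.mean(track.scores[start - 1 : end])),
        composition=cm.aa_composition(sub),
        hydropathy=cm.mean_hydropathy(sub).mean_hydropathy,
        complexity=cm.shannon_complexity(sub).entropy,
        fraction_liv=cm.fraction_of_set(sub, "LIV"),
    )


def _distribution_summary(values: Sequence[float]) -> dict[str, float | None]:
    if not values:
        return {"n": 0, "median": None, "q1": None, "q3": None, "skewness": None}
    arr = np.asarray(values, dtype=float)
    return {
        "n": int(arr.size),
        "median": float(np.median(arr)),
        "q1": float(np.quantile(arr, 0.25)),
        "q3": float(np.quantile(arr, 0.75)),
        "skewness": float(stats.skew(arr)) if arr.size > 2 else None,
    }


@dataclass(frozen=True)
class ProteomeSummary:
    """Per-class segment counts and metric distributions at the two length cutoffs."""

    per_class: Mapping[str, dict]
    complexity_min_length: int = COMPLEXITY_MIN_LENGTH
    feature_min_length: int = FEATURE_MIN_LENGTH

    def to_json(self) -> str:
        return json.dumps(
            {
                "complexity_min_length": self.complexity_min_length,
                "feature_min_length": self.feature_min_length,
                "per_class": {k: v for k, v in self.per_class.items()},
            },
            indent=2,
        )


def summarize_proteome(
    segments: Iterable[DisorderSegment],
    complexity_min_length: int = COMPLEXITY_MIN_LENGTH,
    feature_min_length: int = FEATURE_MIN_LENGTH,
) -> ProteomeSummary:
    """Two-cutoff summary: complexity over segments > 150 aa, sequence features
    (hydropathy, fraction-LIV, mean composition) over segments > 100 aa.

    The per-class mean composition is the residue-weighted mean of segment
    composition vectors.
    """
    segments = list(segments)
    per_class: dict[str, dict] = {}
    for label in ("ordered", "disordered"):
        members = [s for s in segments if s.region.label == label]
        long_c = [s for s in members if s.length > complexity_min_length]
        long_f = [s for s in members if s.length > feature_min_length]
        if long_f:
            weights = np.array([s.length for s in long_f], dtype=float)
            comp_rows = np.stack([s.composition.as_vector() for s in long_f])
            mean_comp = (comp_rows * weights[:, None]).sum(axis=0) / weights.sum()
            mean_composition = {a: float(v) for a, v in zip(AMINO_ACIDS, mean_comp)}
        else:
            mean_composition = None
        per_class[label] = {
            "segment_count": len(members),
            "count_gt_complexity_cutoff": len(long_c),
            "count_gt_feature_cutoff": len(long_f),
            "complexity": _distribution_summary([s.complexity for s in long_c]),
            "hydropathy": _distribution_summary([s.hydropathy for s in long_f]),
            "fraction_liv": _distribution_summary([s.fraction_liv for s in long_f]),
            "mean_composition": mean_composition,
        }
    return ProteomeSummary(per_class, complexity_min_length, feature_min_length)


def percentile_of(value: float, distribution: Sequence[float]) -> float:
    """Fraction of distribution values <= value, times 100."""
    dist = list(distribution)
    if not dist:
        raise ValueError("empty distribution")
    return 100.0 * sum(1 for v in dist if v <= value) / len(dist)


def surrogate_disorder_scores(record: ProteinRecord, window: int = 21) -> DisorderTrack:
    """Deterministic stand-in predictor: charged/low-hydropathy windows score
    high, hydrophobic windows score low.

    score_i = clip(0.5 - h_i/9 + 0.6*(f_i - 0.25), 0, 1) where h_i is the
    truncated-window mean Kyte-Doolittle hydropathy and f_i the local FCR.
    Not a disorder predictor; a documented heuristic for pipeline tests.
    """
    seq = record.sequence
    h = np.array([cm.KYTE_DOOLITTLE[c] for c in seq], dtype=float)
    f = (charge_vector(seq) != 0).astype(float)
    n = len(seq)
    left = (window - 1) // 2
    right = window // 2
    lo = np.clip(np.arange(n) - left, 0, n)
    hi = np.clip(np.arange(n) + right + 1, 0, n)
    csh = np.concatenate(([0.0], np.cumsum(h)))
    csf = np.concatenate(([0.0], np.cumsum(f)))
    mh = (csh[hi] - csh[lo]) / (hi - lo)
    mf = (csf[hi] - csf[lo]) / (hi - lo)
    scores = np.clip(0.5 - mh / 9.0 + 0.6 * (mf - 0.25), 0.0, 1.0)
    return DisorderTrack(record.id, tuple(float(s) for s in scores))


# ---------------------------------------------------------------------------
# Tabular score I/O: two-column per-protein files (position, score) or a
# combined three-column file (protein_id, position, score). Header optional.
# ---------------------------------------------------------------------------

def read_scores_tsv(path: str | Path, protein_id: str | None = None) -> dict[str, DisorderTrack]:
    """Read disorder scores from TSV; returns protein_id -> DisorderTrack.

    Two-column files require ``protein_id``; three-column files ignore it.
    Positions must be 1..L contiguous per protein.
    """
    rows: list[tuple[str, int, float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        try:
            if len(parts) == 2:
                if protein_id is None:
                    raise ValueError(
                        f"{path}: two-column score file needs an explicit protein_id"
                    )
                rows.append((protein_id, int(parts[0]), float(parts[1])))
            elif len(parts) >= 3:
                rows.append((parts[0], int(parts[1]), float(parts[2])))
            else:
                raise ValueError(f"{path}: malformed line {line!r}")
        except ValueError as exc:
            if "malformed" in str(exc) or "needs an explicit" in str(exc):
                raise
            continue  # header line
    tracks: dict[str, DisorderTrack] = {}
    by_protein: dict[str, list[tuple[int, float]]] = {}
    for pid, pos, score in rows:
        by_protein.setdefault(pid, []).append((pos, score))
    for pid, pairs in by_protein.items():
        pairs.sort()
        positions = [p for p, _ in pairs]
        if positions != list(range(1, len(positions) + 1)):
            raise ValueError(f"{path}: positions for {pid!r} are not contiguous from 1")
        tracks[pid] = DisorderTrack(pid, tuple(s for _, s in pairs))
    return tracks


def write_scores_tsv(tracks: Iterable[DisorderTrack], path: str | Path) -> None:
    """Write tracks as a combined three-column TSV (protein_id, position, score)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tscore\n")
        for track in tracks:
            for i, s in enumerate(track.scores, start=1):
                fh.write(f"{track.protein_id}\t{i}\t{s:.6g}\n")


def segments_to_tsv(segments: Iterable[DisorderSegment]) -> str:
    """BED-like TSV (1-based inclusive) with per-segment metric columns."""
    lines = [
        "protein_id\tstart\tend\tlabel\tlength\tmean_score\tcomplexity\thydropathy\tfraction_liv"
    ]
    for s in segments:
        r = s.region
        lines.append(
            f"{r.protein_id}\t{r.start}\t{r.end}\t{r.label}\t{r.length}\t"
            f"{s.mean_score:.4f}\t{s.complexity:.4f}\t{s.hydropathy:.4f}\t{s.fraction_liv:.4f}"
        )
    return "\n".join(lines) + "\n"
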