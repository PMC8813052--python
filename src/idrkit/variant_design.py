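"""Composition-preserving sequence variant designers and dotplot verification.

All designers return a :class:`DesignResult` whose report documents the
verification metrics relevant to the design kind (composition preservation,
kappa before/after, dotplot match count against the parent).

Dotplots score ungapped windows under BLOSUM62 (the dotmatcher default
protein matrix lineage); a match is a window pair whose summed substitution
score meets the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from Bio.Align import substitution_matrices

from . import charge_patterning as cp
from .composition_metrics import aa_composition
from .sequence_io import ProteinRecord, Region

DOTPLOT_WINDOW = 15
DOTPLOT_THRESHOLD = 32

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62_INDEX = {c: i for i, c in enumerate(_BLOSUM62.alphabet)}
_B62 = np.array(_BLOSUM62)


@dataclass(frozen=True)
class DotplotResult:
    window: int
    threshold: int
    matrix_name: str
    matches: tuple[tuple[int, int], ...]  # 1-based window starts (pos_in_a, pos_in_b)

    @property
    def match_count(self) -> int:
        return len(self.matches)


@dataclass(frozen=True)
class DesignResult:
    variant: ProteinRecord
    parent_id: str
    design_kind: Literal["scramble", "uniform_charge", "substitute", "delete"]
    seed: int | None
    report: dict


def window_score(a: str, b: str) -> float:
    """Summed BLOSUM62 score of two equal-length ungapped windows."""
    if len(a) != len(b):
        raise ValueError("windows must have equal length")
    return float(sum(_B62[_B62_INDEX[x], _B62_INDEX[y]] for x, y in zip(a, b)))


def dotplot(
    a: ProteinRecord,
    b: ProteinRecord,
    window: int = DOTPLOT_WINDOW,
    threshold: int = DOTPLOT_THRESHOLD,
) -> DotplotResult:
    """All window-pair matches scoring >= threshold under BLOSUM62."""
    if len(a.sequence) < window or len(b.sequence) < window:
        raise ValueError(f"both sequences must be at least {window} residues")
    ca = np.array([_B62_INDEX[c] for c in a.sequence])
    cb = np.array([_B62_INDEX[c] for c in b.sequence])
    S = _B62[ca[:, None], cb[None, :]]
    ra = len(ca) - window + 1
    rb = len(cb) - window + 1
    W = np.zeros((ra, rb))
    for k in range(window):
        W += S[k : k + ra, k : k + rb]
    ii, jj = np.nonzero(W >= threshold)
    matches = tuple((int(i) + 1, int(j) + 1) for i, j in zip(ii, jj))
    return DotplotResult(window, threshold, "BLOSUM62", matches)


def _kappa_or_none(seq: str) -> float | None:
    try:
        return cp.kappa(seq)
    except (cp.KappaUndefinedError, ValueError):
        return None


def _base_report(parent: ProteinRecord, variant_seq: str, with_dotplot: bool) -> dict:
    report: dict = {
        "composition_identical": sorted(parent.sequence) == sorted(variant_seq),
        "kappa_before": _kappa_or_none(parent.sequence),
        "kappa_after": _kappa_or_none(variant_seq),
    }
    if with_dotplot:
        report["dotplot_match_count_vs_parent"] = dotplot(
            parent, ProteinRecord(parent.id + "_tmp", variant_seq)
        ).match_count
    return report


def scramble(record: ProteinRecord, seed: int, verify_dotplot: bool = True) -> DesignResult:
    """Uniform random permutation of the residues (seeded Fisher-Yates)."""
    rng = np.random.default_rng(seed)
    residues = np.array(list(record.sequence))
    variant_seq = "".join(rng.permutation(residues))
    return DesignResult(
        variant=ProteinRecord(f"{record.id}_scramble_s{seed}", variant_seq),
        parent_id=record.id,
        design_kind="scramble",
        seed=seed,
        report=_base_report(record, variant_seq, verify_dotplot),
    )


def _even_charge_placement(seq: str, rng: np.random.Generator) -> list[str]:
    """Place charged residues at evenly spaced indices with alternating signs.

    Relative order within each residue class (positive, negative, neutral) is
    preserved so the result is an exact multiset permutation.
    """
    pos = [c for c in seq if cp.classify_charge(c) > 0]
    neg = [c for c in seq if cp.classify_charge(c) < 0]
    neu = [c for c in seq if cp.classify_charge(c) == 0]
    n_charged = len(pos) + len(neg)
    L = len(seq)
    slots = sorted({int(round((i + 0.5) * L / n_charged - 0.5)) for i in range(n_charged)})
    while len(slots) < n_charged:  # rounding collisions at short lengths
        extra = next(i for i in range(L) if i not in set(slots))
        slots = sorted(set(slots) | {extra})
    # Bresenham-style alternation so the denser sign never clumps.
    signs: list[int] = []
    np_, nm = len(pos), len(neg)
    ap = am = 0
    for k in range(n_charged):
        if (ap + 1) * nm <= (am + 1) * np_ and ap < np_ or am >= nm:
            signs.append(1)
            ap += 1
        else:
            signs.append(-1)
            am += 1
    out: list[str | None] = [None] * L
    pi = ni = 0
    for slot, sign in zip(slots, signs):
        if sign > 0:
            out[slot] = pos[pi]
            pi += 1
        else:
            out[slot] = neg[ni]
            ni += 1
    it = iter(neu)
    for i in range(L):
        if out[i] is None:
            out[i] = next(it)
    return out  # type: ignore[return-value]


def design_uniform_charge(
    record: ProteinRecord,
    target_kappa: float = 0.07,
    seed: int = 0,
    max_iter: int = 20000,
) -> DesignResult:
    """Composition-preserving redistribution of charged residues toward low kappa.

    Charged residues are first placed at evenly spaced positions with
    alternating signs, then refined by seeded swap moves (charged-charged and
    charged-neutral) accepted only when kappa decreases. Stops at
    kappa <= target_kappa or after max_iter proposals; an unreached target is
    flagged in the report, never raised.
    """
    q0 = cp.charge_vector(record.sequence)
    if not ((q0 > 0).any() and (q0 < 0).any()):
        raise cp.KappaUndefinedError("uniform-charge design needs both charge signs")
    rng = np.random.default_rng(seed)
    chars = _even_charge_placement(record.sequence, rng)
    L = len(chars)
    q = np.array([cp.classify_charge(c) for c in chars], dtype=np.int8)
    n_pos = int((q > 0).sum())
    n_neg = int((q < 0).sum())
    dmax = {g: cp.delta_max(n_pos, n_neg, L - n_pos - n_neg, g) for g in cp.KAPPA_BLOB_SIZES}

    def kappa_of(qv: np.ndarray) -> float:
        return float(np.mean([cp._delta(qv, g) / dmax[g] for g in cp.KAPPA_BLOB_SIZES]))

    current = kappa_of(q)
    kappa_init = current
    iterations = 0
    while current > target_kappa and iterations < max_iter:
        iterations += 1
        i, j = rng.integers(0, L, size=2)
        if q[i] == q[j]:
            continue
        q[i], q[j] = q[j], q[i]
        candidate = kappa_of(q)
        if candidate < current:
            chars[i], chars[j] = chars[j], chars[i]
            current = candidate
        else:
            q[i], q[j] = q[j], q[i]
    variant_seq = "".join(chars)
    report = _base_report(record, variant_seq, with_dotplot=False)
    report.update(
        kappa_initial_placement=kappa_init,
        kappa_achieved=current,
        target_kappa=target_kappa,
        target_reached=current <= target_kappa,
        swap_proposals=iterations,
    )
    return DesignResult(
        variant=ProteinRecord(f"{record.id}_uniform_s{seed}", variant_seq),
        parent_id=record.id,
        design_kind="uniform_charge",
        seed=seed,
        report=report,
    )


def substitute(
    record: ProteinRecord,
    from_set: Iterable[str],
    to_residue: str,
    fraction: float = 1.0,
    region: Region | None = None,
) -> DesignResult:
    """Replace a left-to-right selection of ``from_set`` residues by ``to_residue``.

    fraction 1.0 replaces every occurrence; fraction f selects occurrence k
    (0-based) whenever floor(k*f) advances past floor((k-1)*f) - for f = 0.5
    this is every second occurrence starting from the first.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    members = frozenset(from_set)
    lo = region.start - 1 if region else 0
    hi = region.end if region else len(record.sequence)
    if hi > len(record.sequence):
        raise ValueError("region exceeds sequence length")
    occurrences = [i for i in range(lo, hi) if record.sequence[i] in members]
    if not occurrences:
        import warnings

        warnings.warn(
            f"no {''.join(sorted(members))} residues in the targeted region of {record.id!r}"
        )
    selected = [
        occurrences[k]
        for k in range(len(occurrences))
        if k == 0 or int(k * fraction) > int((k - 1) * fraction)
    ]
    chars = list(record.sequence)
    for i in selected:
        chars[i] = to_residue
    variant_seq = "".join(chars)
    label = f"{''.join(sorted(members))}to{to_residue}"
    return DesignResult(
        variant=ProteinRecord(f"{record.id}_{label}_{fraction:g}", variant_seq),
        parent_id=record.id,
        design_kind="substitute",
        seed=None,
        report={
            "n_targeted": len(selected),
            "n_occurrences": len(occurrences),
            "positions_changed": [i + 1 for i in selected if record.sequence[i] != to_residue],
            "composition_identical": sorted(record.sequence) == sorted(variant_seq),
        },
    )


def delete_region(record: ProteinRecord, region: Region) -> DesignResult:
    """Remove the inclusive 1-based region from the sequence."""
    if region.end > len(record.sequence):
        raise ValueError("region exceeds sequence length")
    variant_seq = record.sequence[: region.start - 1] + record.sequence[region.end :]
    if not variant_seq:
        raise ValueError("deletion would remove the entire sequence")
    return DesignResult(
        variant=ProteinRecord(f"{record.id}_del{region.start}-{region.end}", variant_seq),
        parent_id=record.id,
        design_kind="delete",
        seed=None,
        report={"deleted_length": region.length, "remaining_length": len(variant_seq)},
    )
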