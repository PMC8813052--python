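"""Charge classification, FCR/NCPR, Das-Pappu kappa, and isoelectric point.

Charge conventions: K and R are +1, D and E are -1, everything else (including
histidine) is 0. Histidine still ionizes in the pI model.

Kappa follows the Das-Pappu construction: overlapping blobs of size g, per-blob
charge asymmetry sigma = NCPR^2/FCR, delta = mean squared deviation of blob
sigma from the global sigma, and kappa = mean over g in {5, 6} of
delta / delta_max, where delta_max is the maximal delta over permutations of
the same residue composition. delta_max is computed exactly by exhaustive
permutation for sequences of length <= EXHAUSTIVE_LIMIT and otherwise by a
search over maximally segregated block arrangements (one contiguous block per
charge sign, neutral residues split arbitrarily around and between them).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from sympy.utilities.iterables import multiset_permutations

from .sequence_io import AMINO_ACIDS, ProteinRecord

POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")

#: Longest sequence for which delta_max is computed by exhaustive permutation.
EXHAUSTIVE_LIMIT = 12

#: Blob sizes averaged in the kappa definition.
KAPPA_BLOB_SIZES = (5, 6)

#: pKa set used by the isoelectric-point model (Bjellqvist/"Expasy" values).
#: Pinned after calibrating the model once against published initiator-IDR pI
#: values; see the constants note in the README.
PKA = {
    "N_terminus": 7.5,
    "C_terminus": 3.55,
    "K": 10.0,
    "R": 12.0,
    "H": 5.98,
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0,
}

PI_TOLERANCE = 1e-4  # |net charge| at convergence


class KappaUndefinedError(ValueError):
    """Kappa is undefined: the sequence lacks one charge sign (delta_max = 0)."""


def _seq(record: ProteinRecord | str) -> str:
    return record.sequence if isinstance(record, ProteinRecord) else record


def classify_charge(residue: str) -> int:
    """+1 for K/R, -1 for D/E, 0 otherwise."""
    if len(residue) != 1 or residue not in AMINO_ACIDS:
        raise ValueError(f"invalid residue {residue!r}")
    if residue in POSITIVE:
        return 1
    if residue in NEGATIVE:
        return -1
    return 0


def charge_vector(record: ProteinRecord | str) -> np.ndarray:
    return np.array([classify_charge(c) for c in _seq(record)], dtype=np.int8)


def fcr(record: ProteinRecord | str) -> float:
    """Fraction of charged residues: (count K, R, D, E) / length."""
    q = charge_vector(record)
    return float((q != 0).mean())


def ncpr(record: ProteinRecord | str) -> float:
    """Net charge per residue: (positives - negatives) / length."""
    return float(charge_vector(record).mean())


def sigma(record: ProteinRecord | str) -> float:
    """Charge asymmetry NCPR^2 / FCR (0 when the sequence has no charges)."""
    f = fcr(record)
    return ncpr(record) ** 2 / f if f > 0 else 0.0


@dataclass(frozen=True)
class BlobDecomposition:
    """Overlapping-blob sigma profile of one sequence at one blob size."""

    blob_size: int
    sigma_values: tuple[float, ...]
    delta: float
    delta_max: float

    def __post_init__(self) -> None:
        if self.delta > self.delta_max + 1e-12:
            raise ValueError("delta exceeds delta_max")


def _blob_sigmas(q: np.ndarray, g: int) -> np.ndarray:
    pos = np.cumsum(np.concatenate(([0], (q > 0).astype(float))))
    neg = np.cumsum(np.concatenate(([0], (q < 0).astype(float))))
    wp = (pos[g:] - pos[:-g]) / g
    wn = (neg[g:] - neg[:-g]) / g
    f = wp + wn
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(f > 0, (wp - wn) ** 2 / np.where(f > 0, f, 1.0), 0.0)
    return s


def _global_sigma(q: np.ndarray) -> float:
    f = float((q != 0).mean())
    return float(q.mean()) ** 2 / f if f > 0 else 0.0


def _delta(q: np.ndarray, g: int) -> float:
    """Mean over blobs of (sigma_blob - sigma_global)^2."""
    return float(((_blob_sigmas(q, g) - _global_sigma(q)) ** 2).mean())


def _delta_batch(Q: np.ndarray, g: int) -> np.ndarray:
    """Row-wise delta for a batch of charge arrays with identical composition."""
    pos = np.cumsum((Q > 0).astype(float), axis=1)
    neg = np.cumsum((Q < 0).astype(float), axis=1)
    zero = np.zeros((Q.shape[0], 1))
    pos = np.concatenate([zero, pos], axis=1)
    neg = np.concatenate([zero, neg], axis=1)
    wp = (pos[:, g:] - pos[:, :-g]) / g
    wn = (neg[:, g:] - neg[:, :-g]) / g
    f = wp + wn
    s = np.where(f > 0, (wp - wn) ** 2 / np.where(f > 0, f, 1.0), 0.0)
    sg = _global_sigma(Q[0])
    return ((s - sg) ** 2).mean(axis=1)


def _delta_max_exhaustive(n_pos: int, n_neg: int, n_zero: int, g: int) -> float:
    base = [1] * n_pos + [-1] * n_neg + [0] * n_zero
    best = 0.0
    for perm in multiset_permutations(base):
        best = max(best, _delta(np.array(perm, dtype=np.int8), g))
    return best


def _delta_max_blocks(n_pos: int, n_neg: int, n_zero: int, g: int) -> float:
    """Max delta over segregated arrangements [N1][block][N2][block][N3].

    Both charge-block orders are scanned with every split of the neutral
    residues into the three gaps; evaluation is vectorized in chunks.
    """
    L = n_pos + n_neg + n_zero
    best = 0.0
    templates = []
    for first, second in (((1, n_pos), (-1, n_neg)), ((-1, n_neg), (1, n_pos))):
        for n1 in range(n_zero + 1):
            for n2 in range(n_zero - n1 + 1):
                templates.append((first, second, n1, n2))
    chunk = 4096
    for i in range(0, len(templates), chunk):
        batch = templates[i : i + chunk]
        Q = np.zeros((len(batch), L), dtype=np.int8)
        for row, (first, second, n1, n2) in enumerate(batch):
            sign1, len1 = first
            sign2, len2 = second
            Q[row, n1 : n1 + len1] = sign1
            Q[row, n1 + len1 + n2 : n1 + len1 + n2 + len2] = sign2
        best = max(best, float(_delta_batch(Q, g).max()))
    return best


@lru_cache(maxsize=4096)
def delta_max(n_pos: int, n_neg: int, n_zero: int, g: int) -> float:
    """Maximal delta over all arrangements of a fixed charge composition."""
    if n_pos == 0 or n_neg == 0:
        # Without both signs every arrangement has sigma_blob pinned to the
        # all-or-nothing pattern; for zero-charge sequences delta is 0.
        if n_pos == 0 and n_neg == 0:
            return 0.0
    L = n_pos + n_neg + n_zero
    if L < g:
        raise ValueError(f"sequence of length {L} shorter than blob size {g}")
    if L <= EXHAUSTIVE_LIMIT:
        return _delta_max_exhaustive(n_pos, n_neg, n_zero, g)
    return _delta_max_blocks(n_pos, n_neg, n_zero, g)


def blob_decompose(record: ProteinRecord | str, g: int) -> BlobDecomposition:
    """Overlapping blob decomposition with per-blob sigma, delta, delta_max."""
    q = charge_vector(record)
    if len(q) < g:
        raise ValueError(f"sequence shorter than blob size {g}")
    sigmas = _blob_sigmas(q, g)
    n_pos = int((q > 0).sum())
    n_neg = int((q < 0).sum())
    return BlobDecomposition(
        blob_size=g,
        sigma_values=tuple(float(s) for s in sigmas),
        delta=_delta(q, g),
        delta_max=delta_max(n_pos, n_neg, len(q) - n_pos - n_neg, g),
    )


def kappa(record: ProteinRecord | str, blob_sizes: Sequence[int] = KAPPA_BLOB_SIZES) -> float:
    """Mean of delta/delta_max over the given blob sizes (default 5 and 6)."""
    q = charge_vector(record)
    if not ((q > 0).any() and (q < 0).any()):
        raise KappaUndefinedError(
            "kappa undefined: sequence lacks positive or negative residues"
        )
    if len(q) < max(blob_sizes):
        raise ValueError(f"sequence shorter than largest blob size {max(blob_sizes)}")
    ratios = []
    for g in blob_sizes:
        decomp = blob_decompose(record, g)
        if decomp.delta_max == 0:
            raise KappaUndefinedError(f"delta_max is 0 at blob size {g}")
        ratios.append(decomp.delta / decomp.delta_max)
    return float(np.mean(ratios))


def net_charge_at_pH(record: ProteinRecord | str, pH: float, include_termini: bool = True) -> float:
    """Henderson-Hasselbalch net charge of the sequence at the given pH."""
    seq = _seq(record)
    charge = 0.0
    if include_termini:
        charge += 1.0 / (1.0 + 10 ** (pH - PKA["N_terminus"]))
        charge -= 1.0 / (1.0 + 10 ** (PKA["C_terminus"] - pH))
    for res in "KRH":
        charge += seq.count(res) / (1.0 + 10 ** (pH - PKA[res]))
    for res in "DECY":
        charge -= seq.count(res) / (1.0 + 10 ** (PKA[res] - pH))
    return charge


def isoelectric_point(
    record: ProteinRecord | str, include_termini: bool = True
) -> float | None:
    """pH at which the modeled net charge crosses zero (bisection on [0, 14]).

    Returns ``None`` when the sequence has no ionizable groups (only possible
    with ``include_termini=False``).
    """
    seq = _seq(record)
    if not include_termini and not any(c in "KRHDECY" for c in seq):
        return None
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge_at_pH(seq, mid, include_termini)
        if abs(q) < PI_TOLERANCE:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass(frozen=True)
class ChargeMetrics:
    """Flat per-sequence charge summary; kappa is None when undefined."""

    f_plus: float
    f_minus: float
    fcr: float
    ncpr: float
    sigma: float
    kappa: float | None
    pI: float | None

    TSV_COLUMNS = ("f_plus", "f_minus", "fcr", "ncpr", "sigma", "kappa", "pI")

    def __post_init__(self) -> None:
        if not 0.0 <= self.fcr <= 1.0 or abs(self.ncpr) > self.fcr + 1e-12:
            raise ValueError("inconsistent fcr/ncpr")
        if self.kappa is not None and not -1e-12 <= self.kappa <= 1.0 + 1e-9:
            raise ValueError(f"kappa {self.kappa} outside [0, 1]")
        if self.pI is not None and not 0.0 < self.pI < 14.0:
            raise ValueError(f"pI {self.pI} outside (0, 14)")

    def to_tsv_row(self) -> str:
        vals = [getattr(self, c) for c in self.TSV_COLUMNS]
        return "\t".join("NA" if v is None else f"{v:.6g}" for v in vals)


def compute_charge_metrics(record: ProteinRecord | str) -> ChargeMetrics:
    """All charge metrics for one sequence; undefined kappa becomes None."""
    q = charge_vector(record)
    f_plus = float((q > 0).mean())
    f_minus = float((q < 0).mean())
    try:
        k = kappa(record)
    except KappaUndefinedError:
        k = None
    return ChargeMetrics(
        f_plus=f_plus,
        f_minus=f_minus,
        fcr=f_plus + f_minus,
        ncpr=f_plus - f_minus,
        sigma=(f_plus - f_minus) ** 2 / (f_plus + f_minus) if f_plus + f_minus > 0 else 0.0,
        kappa=k,
        pI=isoelectric_point(record),
    )
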