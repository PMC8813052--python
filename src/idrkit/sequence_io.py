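"""Protein sequence records, FASTA I/O, region extraction, and packaged constructs.

Coordinates are 1-based and inclusive at every public boundary. Sequences are
restricted to the 20 standard one-letter amino-acid codes; lowercase input is
uppercased and a single terminal ``*`` (stop) is stripped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

FIXTURE_FASTA = "cdt1_constructs.fasta"
FIXTURE_MANIFEST = "cdt1_constructs.tsv"


class SequenceValidationError(ValueError):
    """A sequence contains characters outside the 20-letter alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus a validated amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be non-empty and whitespace-free: {self.id!r}")
        if not self.sequence:
            raise SequenceValidationError(f"record {self.id!r} has an empty sequence")
        bad = sorted(set(self.sequence) - _AA_SET)
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r} contains non-amino-acid characters: {', '.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive interval on a named protein."""

    protein_id: str
    start: int
    end: int
    label: Literal["ordered", "disordered", "unlabeled"] = "unlabeled"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region coordinates {self.start}-{self.end}")
        if self.label not in ("ordered", "disordered", "unlabeled"):
            raise ValueError(f"unknown region label {self.label!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def clean_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase ``raw`` and strip a single terminal stop character.

    Raises :class:`SequenceValidationError` for any remaining character
    outside the 20-letter alphabet.
    """
    seq = raw.strip().upper()
    if seq.endswith("*"):
        warnings.warn(f"record {record_id!r}: stripped terminal '*' stop character")
        seq = seq[:-1]
    bad = sorted(set(seq) - _AA_SET)
    if bad:
        raise SequenceValidationError(
            f"record {record_id!r} contains non-amino-acid characters: {', '.join(bad)}"
        )
    return seq


def read_fasta(path: str | Path, on_invalid: str = "raise") -> list[ProteinRecord]:
    """Read a multi-record FASTA file into validated :class:`ProteinRecord` s.

    Parameters
    ----------
    path:
        FASTA file (wrapped or unwrapped lines).
    on_invalid:
        ``"raise"`` aborts on the first record failing alphabet validation;
        ``"skip"`` drops invalid records with a warning naming each one.
    """
    if on_invalid not in ("raise", "skip"):
        raise ValueError("on_invalid must be 'raise' or 'skip'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(ProteinRecord(entry.id, clean_sequence(str(entry.seq), entry.id)))
        except SequenceValidationError:
            if on_invalid == "raise":
                raise
            warnings.warn(f"skipping invalid record {entry.id!r}")
    if not records:
        raise ValueError(f"no valid FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to ``path`` in FASTA format with ``width``-column wrapping."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqs)


def extract_region(record: ProteinRecord, region: Region) -> ProteinRecord:
    """Return the inclusive 1-based slice of ``record`` as a new record.

    The new id is suffixed with the coordinates, e.g. ``Cdt1_1-297``.
    """
    if region.end > len(record.sequence):
        raise ValueError(
            f"region {region.start}-{region.end} exceeds length {len(record.sequence)} "
            f"of record {record.id!r}"
        )
    return ProteinRecord(
        f"{record.id}_{region.start}-{region.end}",
        record.sequence[region.start - 1 : region.end],
    )


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("idrkit").joinpath("data", name)))


def fixture_manifest() -> dict[str, dict[str, str]]:
    """Name -> {length, description} for every packaged construct."""
    manifest: dict[str, dict[str, str]] = {}
    lines = _fixture_path(FIXTURE_MANIFEST).read_text().splitlines()
    for line in lines[1:]:
        name, length, description = line.split("\t")
        manifest[name] = {"length": length, "description": description}
    return manifest


def load_fixtures() -> dict[str, ProteinRecord]:
    """All packaged Cdt1 construct sequences, keyed by construct name."""
    return {r.id: r for r in read_fasta(_fixture_path(FIXTURE_FASTA))}


def load_fixture(name: str) -> ProteinRecord:
    """Return one packaged construct by name (e.g. ``"WT"``, ``"ScrIDR"``)."""
    fixtures = load_fixtures()
    if name not in fixtures:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {', '.join(sorted(fixtures))}"
        )
    return fixtures[name]


FIXTURE_NAMES = (
    "WT",
    "PheToLeu",
    "PheToAla",
    "Uniform",
    "Del1_100",
    "Del101_200",
    "Del201_297",
    "DelCoiledCoil",
    "ScrIDR",
    "IleLeu05",
    "IleLeu10",
)
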