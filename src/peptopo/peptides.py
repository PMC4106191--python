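"""Peptide sequence model, bundled fixture peptides, and salt-bridge ("ion-lock") variants.

Positions are 1-based everywhere. An ion-lock is a Glu(-)/Lys(+) pair spaced
four residues apart along the sequence (the classic i, i+4 helical spacing);
``IonLockSpec`` carries one or more such pairs plus an ``engaged`` flag that
downstream hydropathy scoring interprets as close-range (engaged) versus
long-range (disengaged) bridge geometry.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

MIN_LENGTH = 10
MAX_LENGTH = 60


class PeptideError(ValueError):
    """Invalid peptide sequence or ion-lock specification."""


class FixtureError(RuntimeError):
    """Bundled fixture table is missing or garbled."""


@dataclass(frozen=True)
class Peptide:
    """A short peptide with a validated 1-letter amino-acid sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = sorted(set(seq) - STANDARD_AA)
        if bad:
            raise PeptideError(
                f"{self.id!r}: non-standard residue code(s) {''.join(bad)!r}"
            )
        if not MIN_LENGTH <= len(seq) <= MAX_LENGTH:
            raise PeptideError(
                f"{self.id!r}: length {len(seq)} outside supported range "
                f"[{MIN_LENGTH}, {MAX_LENGTH}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise PeptideError(
                f"position {position} out of bounds for {self.id!r} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class IonLockSpec:
    """One or more (anion_position, cation_position) Glu/Lys pairs, i +/- 4 apart."""

    pairs: tuple[tuple[int, int], ...]
    engaged: bool = True

    def __post_init__(self) -> None:
        pairs = tuple((int(a), int(c)) for a, c in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        if not pairs:
            raise PeptideError("IonLockSpec requires at least one pair")
        seen: set[int] = set()
        for anion, cation in pairs:
            if abs(cation - anion) != 4:
                raise PeptideError(
                    f"pair ({anion}, {cation}): spacing must be exactly 4 residues"
                )
            if anion < 1 or cation < 1:
                raise PeptideError(f"pair ({anion}, {cation}): positions are 1-based")
            if {anion, cation} & seen:
                raise PeptideError("ion-lock pairs must not share positions")
            seen.update((anion, cation))

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(p for pair in self.pairs for p in pair)

    def label(self) -> str:
        tags = "; ".join(f"E{a}/K{c}" for a, c in self.pairs)
        return f"({tags})"

    def validate_for(self, peptide: Peptide) -> None:
        """Check that every position is in bounds for *peptide*."""
        n = len(peptide)
        for anion, cation in self.pairs:
            if anion > n or cation > n:
                raise PeptideError(
                    f"pair ({anion}, {cation}) out of bounds for {peptide.id!r} "
                    f"(length {n})"
                )


def apply_ion_lock(peptide: Peptide, spec: IonLockSpec) -> Peptide:
    """Substitute Glu at each anion position and Lys at each cation position.

    Returns a new peptide; exactly two residues change per pair (unless the
    positions already hold E/K, in which case the substitution is idempotent).
    """
    spec.validate_for(peptide)
    residues = list(peptide.sequence)
    for anion, cation in spec.pairs:
        residues[anion - 1] = "E"
        residues[cation - 1] = "K"
    return replace(
        peptide,
        id=f"{peptide.id} {spec.label()}",
        sequence="".join(residues),
        description=(peptide.description + " with ion-lock " + spec.label()).strip(),
    )


def _fixture_path():
    return resources.files("peptopo.data").joinpath("fixtures.tsv")


def load_fixtures() -> dict[str, Peptide]:
    """Load the bundled peptide table (sequences transcribed at build time).

    Returns a mapping from peptide id to :class:`Peptide`. Raises
    :class:`FixtureError` if the bundled table is missing or malformed.
    """
    try:
        text = _fixture_path().read_text(encoding="utf-8")
    except (FileNotFoundError, OSError) as exc:  # pragma: no cover
        raise FixtureError(f"fixture table unavailable: {exc}") from exc
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    if not rows or set(rows[0]) < {"id", "sequence", "description"}:
        raise FixtureError("fixture table is garbled: expected id/sequence/description columns")
    peptides: dict[str, Peptide] = {}
    for row in rows:
        try:
            pep = Peptide(row["id"], row["sequence"], row["description"])
        except (KeyError, PeptideError) as exc:
            raise FixtureError(f"bad fixture row {row!r}: {exc}") from exc
        peptides[pep.id] = pep
    return peptides


def get_fixture(name: str) -> Peptide:
    """Look up a single bundled peptide by id."""
    peptides = load_fixtures()
    try:
        return peptides[name]
    except KeyError:
        known = ", ".join(sorted(peptides))
        raise KeyError(f"unknown peptide {name!r}; bundled ids: {known}") from None


# Fixture ids contain spaces, which plain FASTA would split into id + description.
# Headers are therefore written as "id | description" and split back on read, so
# write -> read round-trips both fields exactly.
_HEADER_SEP = " | "


def read_fasta(path: str | Path) -> list[Peptide]:
    """Read peptides from a FASTA file; sequences are upper-cased and validated."""
    path = Path(path)
    peptides = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise PeptideError(f"{path}: malformed FASTA: {exc}") from exc
    if not records and path.read_text().strip():
        raise PeptideError(f"{path}: no FASTA records parsed")
    for rec in records:
        header = rec.description or rec.id
        pid, sep, desc = header.partition(_HEADER_SEP)
        peptides.append(Peptide(pid, str(rec.seq), desc if sep else ""))
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in peptides:
            header = p.id + (_HEADER_SEP + p.description if p.description else "")
            fh.write(f">{header}\n{p.sequence}\n")
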