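"""Pairwise beta-sheet pairing-energy scanning and aggregation profiling.

Scores candidate strand pairings between two equal-length sequence segments
with a pluggable pairwise energy table (parallel and antiparallel sets; more
negative = more stable), enumerates and ranks all pairings between two
sequences (including interpeptide self-pairing), and classifies amyloid
propensity against a strict energy threshold. The real published propensity
tables are external inputs; the bundled toy table exists purely so the
machinery is testable and is labelled as such.

Salt bridges are deliberately *not* modelled here: charged substitutions enter
the scores only through their per-residue table entries.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

AMYLOID_THRESHOLD = -29.0

Orientation = Literal["parallel", "antiparallel"]

_AA = "ACDEFGHIKLMNPQRSTVWY"


class PairingError(ValueError):
    pass


@dataclass(frozen=True)
class PairingEnergyTable:
    """Pairwise facing-residue energies for parallel and antiparallel sheets."""

    parallel: dict[tuple[str, str], float]
    antiparallel: dict[tuple[str, str], float]
    source: str = "unspecified"

    def __post_init__(self) -> None:
        needed = {(a, b) for a in _AA for b in _AA}
        for label, table in (("parallel", self.parallel), ("antiparallel", self.antiparallel)):
            missing = needed - set(table)
            if missing:
                raise PairingError(
                    f"{self.source}: {label} table missing {len(missing)} residue pairs"
                )
        asym = [
            (a, b) for (a, b) in self.antiparallel
            if abs(self.antiparallel[(a, b)] - self.antiparallel[(b, a)]) > 1e-9
        ]
        if asym:
            raise PairingError(f"{self.source}: antiparallel table not symmetric, e.g. {asym[0]}")

    def energy(self, a: str, b: str, orientation: Orientation) -> float:
        table = self.parallel if orientation == "parallel" else self.antiparallel
        return table[(a, b)]


def toy_table() -> PairingEnergyTable:
    """TOY table for tests/demos only — favors identical facing residues.

    Not trained on any structure database; do not use for real predictions.
    """
    par = {(a, b): (-1.0 if a == b else 0.2) for a in _AA for b in _AA}
    anti = {(a, b): (-0.5 if a == b else 0.3) for a in _AA for b in _AA}
    return PairingEnergyTable(par, anti, source="toy-identity")


def load_table(path: str | Path) -> PairingEnergyTable:
    """Load a table from TSV columns: residue_a, residue_b, orientation, energy."""
    par: dict[tuple[str, str], float] = {}
    anti: dict[tuple[str, str], float] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = (row["residue_a"].strip().upper(), row["residue_b"].strip().upper())
            orient = row["orientation"].strip().lower()
            if orient == "parallel":
                par[key] = float(row["energy"])
            elif orient == "antiparallel":
                anti[key] = float(row["energy"])
            else:
                raise PairingError(f"{path}: unknown orientation {orient!r}")
    return PairingEnergyTable(par, anti, source=str(path))


def save_table(table: PairingEnergyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("residue_a\tresidue_b\torientation\tenergy\n")
        for orient, entries in (("parallel", table.parallel), ("antiparallel", table.antiparallel)):
            for (a, b), e in sorted(entries.items()):
                fh.write(f"{a}\t{b}\t{orient}\t{e}\n")


@dataclass(frozen=True)
class PairingResult:
    """One scored strand pairing; segments are 1-based inclusive (start, end)."""

    segment_a: tuple[int, int]
    segment_b: tuple[int, int]
    orientation: Orientation
    energy: float

    @property
    def length(self) -> int:
        return self.segment_a[1] - self.segment_a[0] + 1

    @property
    def register(self) -> int:
        """Offset of segment_b start relative to segment_a start."""
        return self.segment_b[0] - self.segment_a[0]


def score_pairing(
    seq_a: str,
    seq_b: str,
    seg_a: tuple[int, int],
    seg_b: tuple[int, int],
    orientation: Orientation,
    table: PairingEnergyTable,
) -> float:
    """Energy of one pairing: sum of facing-residue table entries.

    In a parallel pairing position i of seg_a faces position i of seg_b; in an
    antiparallel pairing it faces position L-1-i.
    """
    la = seg_a[1] - seg_a[0] + 1
    lb = seg_b[1] - seg_b[0] + 1
    if la != lb:
        raise PairingError(f"segments must have equal length (got {la} and {lb})")
    if la < 1:
        raise PairingError("empty segment")
    if seg_a[0] < 1 or seg_a[1] > len(seq_a) or seg_b[0] < 1 or seg_b[1] > len(seq_b):
        raise PairingError("segment out of sequence bounds")
    a = seq_a[seg_a[0] - 1: seg_a[1]]
    b = seq_b[seg_b[0] - 1: seg_b[1]]
    if orientation == "antiparallel":
        b = b[::-1]
    return sum(table.energy(x, y, orientation) for x, y in zip(a, b))


def enumerate_pairings(
    seq_a: str,
    seq_b: str,
    table: PairingEnergyTable,
    min_len: int = 2,
    max_results: int = 100,
) -> list[PairingResult]:
    """All equal-length segment pairings in both orientations, ranked by energy.

    Ranking is ascending by energy, then smaller seg_a start, then parallel
    before antiparallel, then smaller seg_b start, then shorter segment.
    ``seq_b == seq_a`` scans interpeptide self-pairings (in-register pairs
    included). Truncated to *max_results*.
    """
    if min_len < 2:
        raise PairingError("min_len must be >= 2")
    if max_results < 1:
        raise PairingError("max_results must be >= 1")
    results: list[PairingResult] = []
    max_len = min(len(seq_a), len(seq_b))
    for length in range(min_len, max_len + 1):
        for sa in range(1, len(seq_a) - length + 2):
            seg_a = (sa, sa + length - 1)
            for sb in range(1, len(seq_b) - length + 2):
                seg_b = (sb, sb + length - 1)
                for orientation in ("parallel", "antiparallel"):
                    energy = score_pairing(seq_a, seq_b, seg_a, seg_b, orientation, table)
                    results.append(PairingResult(seg_a, seg_b, orientation, energy))
    results.sort(
        key=lambda r: (
            r.energy,
            r.segment_a[0],
            0 if r.orientation == "parallel" else 1,
            r.segment_b[0],
            r.length,
        )
    )
    return results[:max_results]


def classify_amyloid(best_energy: float, threshold: float = AMYLOID_THRESHOLD) -> bool:
    """True iff the best pairing energy is strictly below the threshold."""
    return best_energy < threshold


def aggregation_profile(
    seq: str,
    table: PairingEnergyTable,
    min_len: int = 2,
    max_results: int = 100,
) -> list[float]:
    """Per-residue propensity: minimum energy among top-ranked self-pairings
    whose seg_a covers the residue; 0.0 where no ranked pairing covers it.
    """
    profile = [0.0] * len(seq)
    if min_len > len(seq):
        return profile
    covered = [False] * len(seq)
    for res in enumerate_pairings(seq, seq, table, min_len=min_len, max_results=max_results):
        for pos in range(res.segment_a[0] - 1, res.segment_a[1]):
            if not covered[pos] or res.energy < profile[pos]:
                profile[pos] = res.energy
                covered[pos] = True
    return profile
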