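"""Per-peptide orchestration: run every analysis stage with available inputs,
emit a combined report table plus a hydropathy-vs-pairing-energy table.

Stages with missing inputs are skipped and logged; a stage error is recorded
on that peptide's report and the pipeline continues for the others.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal, Optional

import pandas as pd
import yaml

from . import beta_pairing, ftir, hdx, hydropathy, orientation
from .peptides import IonLockSpec, Peptide, load_fixtures, read_fasta

logger = logging.getLogger(__name__)

SPAN_THRESHOLD_RESIDUES = 17   # minimum helix length for a bilayer-spanning call
TILT_THRESHOLD_DEG = 30.0      # maximum tilt for a bilayer-spanning call
HELIX_FRACTION_FLOOR = 0.33    # below this, the peptide is called not-helical

Topology = Literal["transmembrane", "single-leaflet", "not-helical"]


@dataclass
class PeptideReport:
    peptide_id: str
    sequence: str
    fractions: Optional[ftir.StructureFractions] = None
    helix_residues: Optional[float] = None
    orientation: Optional[orientation.OrientationResult] = None
    exchange: Optional[hdx.ExchangeFit] = None
    unexchanged_residues: Optional[float] = None
    hydropathy_engaged: Optional[tuple[int, int, float]] = None
    hydropathy_disengaged: Optional[tuple[int, int, float]] = None
    best_pairing_energy: Optional[float] = None
    amyloid: Optional[bool] = None
    topology: Optional[Topology] = None
    errors: dict[str, str] = field(default_factory=dict)

    def to_row(self) -> dict[str, Any]:
        row: dict[str, Any] = {"peptide": self.peptide_id, "length": len(self.sequence)}
        if self.fractions is not None:
            for k, v in self.fractions.as_dict().items():
                row[f"pct_{k}"] = round(100.0 * v, 1)
        row["helix_residues"] = self.helix_residues
        if self.orientation is not None:
            row["dichroic_ratio"] = round(self.orientation.dichroic_ratio, 3)
            row["max_tilt_deg"] = round(self.orientation.theta_max_deg, 1)
        if self.exchange is not None:
            row["hdx_plateau_pct"] = round(self.exchange.plateau, 1)
            row["unexchanged_residues"] = self.unexchanged_residues
        if self.hydropathy_engaged is not None:
            row["hydropathy_engaged_kcal"] = round(self.hydropathy_engaged[2], 2)
        if self.hydropathy_disengaged is not None:
            row["hydropathy_kcal"] = round(self.hydropathy_disengaged[2], 2)
            row["hydropathy_segment"] = (
                f"{self.hydropathy_disengaged[0]}-{self.hydropathy_disengaged[1]}"
            )
        if self.best_pairing_energy is not None:
            row["pairing_energy"] = round(self.best_pairing_energy, 2)
            row["amyloid"] = self.amyloid
        row["topology"] = self.topology
        if self.errors:
            row["errors"] = "; ".join(f"{k}: {v}" for k, v in sorted(self.errors.items()))
        return row


def call_topology(
    report: PeptideReport,
    span_threshold: int = SPAN_THRESHOLD_RESIDUES,
    tilt_threshold_deg: float = TILT_THRESHOLD_DEG,
    helix_fraction_floor: float = HELIX_FRACTION_FLOOR,
) -> Topology:
    """Topology decision from helix length, helix fraction, and (optional) tilt."""
    if report.helix_residues is None:
        raise ValueError("topology call requires a helix residue count")
    if report.fractions is not None and report.fractions.helix < helix_fraction_floor:
        return "not-helical"
    tilt_ok = (
        report.orientation is None
        or report.orientation.theta_max_deg <= tilt_threshold_deg
    )
    if report.helix_residues >= span_threshold and tilt_ok:
        return "transmembrane"
    return "single-leaflet"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _resolve_peptides(config: dict) -> list[tuple[Peptide, dict]]:
    fixtures = load_fixtures()
    entries = config.get("peptides", [])
    resolved = []
    for entry in entries:
        if isinstance(entry, str):
            entry = {"id": entry}
        pid = entry["id"]
        if "sequence" in entry:
            pep = Peptide(pid, entry["sequence"], entry.get("description", ""))
        elif "fasta" in entry:
            matches = [p for p in read_fasta(entry["fasta"]) if p.id == pid]
            if not matches:
                raise KeyError(f"{pid!r} not found in {entry['fasta']}")
            pep = matches[0]
        else:
            pep = fixtures[pid]
        resolved.append((pep, entry))
    return resolved


def run_pipeline(config: dict | str | Path) -> tuple[list[PeptideReport], pd.DataFrame]:
    """Execute all stages for every configured peptide.

    ``config`` is a mapping (or path to a YAML file) with a ``peptides`` list;
    each entry names a bundled fixture id or supplies ``sequence``/``fasta``,
    plus optional per-stage inputs: ``spectrum`` (+ ``reference``),
    ``polarized`` ({parallel, perpendicular} spectrum paths), ``hdx_series``
    (TSV path), ``lock`` ("anion:cation" or a list of those). Thresholds and
    the hydropathy window are config-exposed.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    window = int(config.get("window", hydropathy.DEFAULT_WINDOW))
    span_threshold = int(config.get("span_threshold", SPAN_THRESHOLD_RESIDUES))
    tilt_threshold = float(config.get("tilt_threshold_deg", TILT_THRESHOLD_DEG))
    helix_floor = float(config.get("helix_fraction_floor", HELIX_FRACTION_FLOOR))
    scale = hydropathy.load_scale(config.get("scale"))
    if config.get("pairing_table"):
        table = beta_pairing.load_table(config["pairing_table"])
    else:
        table = beta_pairing.toy_table()
    min_len = int(config.get("pairing_min_len", 4))

    reports: list[PeptideReport] = []
    for pep, entry in _resolve_peptides(config):
        report = PeptideReport(peptide_id=pep.id, sequence=pep.sequence)
        locks = _parse_locks(entry.get("lock"))

        _run_stage(report, "hydropathy", _stage_hydropathy, pep, scale, window, locks)
        _run_stage(report, "beta_pairing", _stage_pairing, pep, table, min_len)
        if entry.get("spectrum"):
            _run_stage(report, "ftir", _stage_ftir, pep, entry)
        else:
            logger.info("peptide %s: no spectrum input; skipping FTIR stage", pep.id)
        if entry.get("polarized"):
            _run_stage(report, "orientation", _stage_orientation, entry)
        if entry.get("hdx_series"):
            _run_stage(report, "hdx", _stage_hdx, pep, entry)
        if report.helix_residues is not None:
            _run_stage(
                report, "topology",
                lambda rep: setattr(
                    rep, "topology",
                    call_topology(rep, span_threshold, tilt_threshold, helix_floor),
                ),
            )
        reports.append(report)

    table_df = pd.DataFrame([r.to_row() for r in reports])
    return reports, table_df


def _run_stage(report: PeptideReport, name: str, fn, *args) -> None:
    try:
        fn(report, *args)
    except Exception as exc:
        logger.warning("peptide %s: stage %s failed: %s", report.peptide_id, name, exc)
        report.errors[name] = str(exc)


def _parse_locks(raw) -> Optional[IonLockSpec]:
    if raw is None:
        return None
    items = raw if isinstance(raw, list) else [raw]
    pairs = []
    for item in items:
        anion, _, cation = str(item).partition(":")
        pairs.append((int(anion), int(cation)))
    return IonLockSpec(tuple(pairs))


def _stage_hydropathy(report, pep, scale, window, locks) -> None:
    if locks is not None:
        engaged = hydropathy.window_hydropathy(
            pep, scale, window, IonLockSpec(locks.pairs, engaged=True)
        )
        report.hydropathy_engaged = hydropathy.best_transmembrane_segment(engaged)
        disengaged = hydropathy.window_hydropathy(
            pep, scale, window, IonLockSpec(locks.pairs, engaged=False)
        )
    else:
        disengaged = hydropathy.window_hydropathy(pep, scale, window)
    report.hydropathy_disengaged = hydropathy.best_transmembrane_segment(disengaged)


def _stage_pairing(report, pep, table, min_len) -> None:
    ranked = beta_pairing.enumerate_pairings(
        pep.sequence, pep.sequence, table, min_len=min_len, max_results=100
    )
    if ranked:
        report.best_pairing_energy = ranked[0].energy
        report.amyloid = beta_pairing.classify_amyloid(ranked[0].energy)


def _stage_ftir(report, pep, entry) -> None:
    spectrum = ftir.read_spectrum(entry["spectrum"])
    logger.info(
        "peptide %s: spectrum %s sha=%s", pep.id, entry["spectrum"],
        _sha256(Path(entry["spectrum"])),
    )
    if entry.get("reference"):
        spectrum = ftir.subtract_reference(
            spectrum, ftir.read_spectrum(entry["reference"]),
            scale=float(entry.get("reference_scale", 1.0)),
        )
    bands, _ = ftir.fit_bands_auto(spectrum)
    report.fractions = ftir.assign_fractions(bands)
    report.helix_residues = ftir.helix_residue_count(report.fractions.helix, len(pep))


def _stage_orientation(report, entry) -> None:
    pol = entry["polarized"]
    pair = orientation.PolarizedPair(
        spectrum_parallel=ftir.read_spectrum(pol["parallel"]),
        spectrum_perpendicular=ftir.read_spectrum(pol["perpendicular"]),
    )
    report.orientation = orientation.analyze_pair(pair)


def _stage_hdx(report, pep, entry) -> None:
    series = hdx.read_series(entry["hdx_series"])
    times, curve = hdx.percent_unexchanged(series)
    fit = hdx.fit_exchange(times, curve, n_components=int(entry.get("hdx_components", 2)))
    report.exchange = fit
    if report.fractions is not None:
        _, reported = hdx.unexchanged_helix_residues(
            fit.plateau, report.fractions.helix, len(pep)
        )
        report.unexchanged_residues = reported


def hydropathy_vs_pairing_table(reports: list[PeptideReport]) -> pd.DataFrame:
    """Two-axis table mirroring a hydropathy (kcal/mol) vs pairing-energy plane."""
    rows = []
    for r in reports:
        rows.append(
            {
                "peptide": r.peptide_id,
                "hydropathy_kcal": None if r.hydropathy_disengaged is None
                else round(r.hydropathy_disengaged[2], 2),
                "hydropathy_engaged_kcal": None if r.hydropathy_engaged is None
                else round(r.hydropathy_engaged[2], 2),
                "pairing_energy": r.best_pairing_energy,
            }
        )
    return pd.DataFrame(rows)
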