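"""Reading and writing instrument scan exports.

The export dialect is a documented JSON format defined by this project
(see ``schema/scan_export.json``): one file per scan, holding scan metadata,
the three raw beam spectra (2048 channels each) and the 42-element
concentration table.  Concentrations below the limit of detection are
flagged and carry no numeric value — the reader never invents zeros.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

__all__ = [
    "ScanMetadata",
    "BeamSpectrum",
    "ConcentrationRecord",
    "ScanRecord",
    "ExportFormatError",
    "read_export",
    "write_export",
    "ingest_directory",
    "records_to_long_table",
    "N_CHANNELS",
    "N_ELEMENTS",
]

logger = logging.getLogger(__name__)

N_CHANNELS = 2048
N_ELEMENTS = 42
STATES = ("thawed", "dried", "natural")


class ExportFormatError(ValueError):
    """A scan export failed schema validation."""


class ScanMetadata(BaseModel):
    model_config = ConfigDict(extra="forbid")

    export_id: str
    specimen_id: str
    taxon: str
    location: str
    state: str
    dwell_time_s: float = Field(gt=0)
    backed: bool
    replicate: int = Field(ge=1)
    instrument_method: str = "GeoChem3-like"
    timestamp: str = "1970-01-01T00:00:00"

    @field_validator("state")
    @classmethod
    def _state_known(cls, v: str) -> str:
        if v not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {v!r}")
        return v


class BeamSpectrum(BaseModel):
    model_config = ConfigDict(extra="forbid")

    beam_index: int = Field(ge=1, le=3)
    beam_energy_kev: float = Field(gt=0)
    live_time_s: float = Field(gt=0)
    gain_kev_per_channel: float = Field(gt=0)
    offset_kev: float = 0.0
    counts: List[int]

    @model_validator(mode="after")
    def _check_counts(self) -> "BeamSpectrum":
        if len(self.counts) != N_CHANNELS:
            raise ValueError(
                f"beam {self.beam_index}: expected {N_CHANNELS} channels, got {len(self.counts)}"
            )
        if any(c < 0 for c in self.counts):
            raise ValueError(f"beam {self.beam_index}: negative counts")
        return self


class ConcentrationRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    element: str
    below_lod: bool = False
    concentration_pct: Optional[float] = None
    error_1sigma_pct: Optional[float] = None

    @model_validator(mode="after")
    def _check_values(self) -> "ConcentrationRecord":
        if not self.below_lod:
            if self.concentration_pct is None:
                raise ValueError(f"{self.element}: concentration missing but not below LOD")
            if self.concentration_pct < 0:
                raise ValueError(f"{self.element}: concentration must be >= 0")
        if self.error_1sigma_pct is not None and self.error_1sigma_pct < 0:
            raise ValueError(f"{self.element}: 1-sigma error must be >= 0")
        return self


class ScanRecord(BaseModel):
    """One instrument scan: metadata + three beam spectra + 42 concentrations."""

    model_config = ConfigDict(extra="forbid")

    metadata: ScanMetadata
    spectra: List[BeamSpectrum]
    concentrations: List[ConcentrationRecord]

    @model_validator(mode="after")
    def _check_structure(self) -> "ScanRecord":
        if len(self.spectra) != 3:
            raise ValueError(f"expected 3 beam spectra, got {len(self.spectra)}")
        if sorted(s.beam_index for s in self.spectra) != [1, 2, 3]:
            raise ValueError("beam indices must be exactly {1, 2, 3}")
        energies = [s.beam_energy_kev for s in self.spectra]
        if len(set(energies)) != 3:
            raise ValueError("beam energies must be distinct")
        if len(self.concentrations) != N_ELEMENTS:
            raise ValueError(
                f"expected {N_ELEMENTS} concentration records, got {len(self.concentrations)}"
            )
        elements = [c.element for c in self.concentrations]
        dupes = {e for e in elements if elements.count(e) > 1}
        if dupes:
            raise ValueError(f"duplicate element(s): {sorted(dupes)}")
        return self

    def spectrum_for_beam_energy(self, beam_energy_kev: float) -> BeamSpectrum:
        for s in self.spectra:
            if s.beam_energy_kev == beam_energy_kev:
                return s
        raise KeyError(f"no beam at {beam_energy_kev} keV")


def read_export(path) -> ScanRecord:
    """Parse and validate one JSON scan export."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ExportFormatError(f"{path.name}: not valid JSON ({exc})") from exc
    try:
        return ScanRecord.model_validate(payload)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ExportFormatError(f"{path.name}: field {loc!r}: {first['msg']}") from exc


def write_export(record: ScanRecord, path) -> Path:
    """Write a scan export with canonical field ordering.

    write_export(read_export(p)) reproduces byte-identical files for files
    written by this function.
    """
    path = Path(path)
    path.write_text(record.model_dump_json(indent=1) + "\n")
    return path


def records_to_long_table(records: Sequence[ScanRecord]) -> pd.DataFrame:
    """Tidy long table: one row per (export, element), sorted by (export_id, element)."""
    rows = []
    for rec in records:
        m = rec.metadata
        for c in rec.concentrations:
            rows.append(
                {
                    "export_id": m.export_id,
                    "specimen_id": m.specimen_id,
                    "taxon": m.taxon,
                    "location": m.location,
                    "state": m.state,
                    "dwell_time_s": m.dwell_time_s,
                    "backed": m.backed,
                    "replicate": m.replicate,
                    "element": c.element,
                    "concentration_pct": c.concentration_pct,
                    "error_1sigma_pct": c.error_1sigma_pct,
                    "below_lod": c.below_lod,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["export_id", "element"], kind="mergesort").reset_index(drop=True)


def ingest_directory(directory, out_csv=None):
    """Read every ``*.json`` export in a directory.

    Returns (records, long_table, skipped_files).  Invalid files are logged
    and skipped; zero valid exports is an error.  Output content is
    independent of directory listing order.
    """
    directory = Path(directory)
    records: list[ScanRecord] = []
    skipped: list[str] = []
    for path in sorted(directory.glob("*.json")):
        try:
            records.append(read_export(path))
        except ExportFormatError as exc:
            logger.warning("skipping invalid export %s: %s", path.name, exc)
            skipped.append(path.name)
    if not records:
        raise ExportFormatError(f"no valid scan exports found in {directory}")
    records.sort(key=lambda r: r.metadata.export_id)
    table = records_to_long_table(records)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return records, table, skipped
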