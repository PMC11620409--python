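"""Element presence screening via diagnostic characteristic peaks.

An element reported by the instrument is only trusted if its diagnostic
Ka1 and Kbeta peaks are actually visible in the net (baseline-subtracted)
spectra of the longest, 80 s scans.  Presence is operationalised as a
Currie-style signal-to-noise criterion: snr = net / sqrt(max(baseline, 1))
over a window of +/- 1.5 x FWHM around the line energy, present when
snr >= threshold (default 3) and the net sum is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_vanta import ScanRecord
from .lines import ElementLineTable, default_line_table
from .simulate import select_beam
from .spectra import DEFAULT_RESOLUTION, ProcessedSpectrum, fwhm_kev, process_spectrum, window_counts

__all__ = [
    "PeakCheckResult",
    "diagnostic_peak_check",
    "validate_panel",
    "PanelResult",
    "apply_lod_filter",
]

logger = logging.getLogger(__name__)

#: Lines below this energy are unobservable on a field instrument (air-path
#: and detector-window absorption) and are treated as absent in screening.
MIN_DETECTABLE_KEV = 1.0


@dataclass(frozen=True)
class PeakCheckResult:
    """Outcome of one diagnostic-line check in one processed spectrum."""

    element: str
    line_label: str
    centre_energy: float
    net_sum: float
    baseline_sum: float
    snr: float
    present: bool


def _check_line(processed: ProcessedSpectrum, element: str, line,
                snr_threshold: float, resolution) -> PeakCheckResult:
    half_width = 1.5 * float(fwhm_kev(line.energy_kev, resolution))
    e0, e1 = float(processed.energy[0]), float(processed.energy[-1])
    if not e0 <= line.energy_kev <= e1:
        raise ValueError(
            f"{element} {line.line_label} at {line.energy_kev} keV outside axis [{e0}, {e1}]"
        )
    net, base = window_counts(processed, line.energy_kev, half_width)
    snr = net / np.sqrt(max(base, 1.0))
    return PeakCheckResult(
        element=element,
        line_label=line.line_label,
        centre_energy=line.energy_kev,
        net_sum=net,
        baseline_sum=base,
        snr=float(snr),
        present=bool(snr >= snr_threshold and net > 0),
    )


def diagnostic_peak_check(
    processed: "ProcessedSpectrum | Mapping[float, ProcessedSpectrum]",
    element: str,
    lines: ElementLineTable,
    snr_threshold: float = 3.0,
    resolution=DEFAULT_RESOLUTION,
) -> list[PeakCheckResult]:
    """Check the element's Ka1 and Kbeta diagnostic peaks.

    `processed` is either one ProcessedSpectrum or a mapping of beam energy
    (keV) -> ProcessedSpectrum; with a mapping, each line is checked in the
    beam that best excites it.  Raises if the element is missing from the
    line table or a line energy lies outside the spectrum axis.
    """
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be > 0")
    ka1, kb = lines.diagnostic_lines(element)
    results = []
    for line in (ka1, kb):
        if isinstance(processed, ProcessedSpectrum):
            spec = processed
        else:
            beam = select_beam(line.energy_kev, sorted(processed))
            if beam is None:
                raise ValueError(
                    f"{element} {line.line_label}: no beam excites {line.energy_kev} keV"
                )
            spec = processed[beam]
        results.append(_check_line(spec, element, line, snr_threshold, resolution))
    return results


@dataclass(frozen=True)
class PanelResult:
    retained: tuple[str, ...]
    excluded: tuple[str, ...]
    evidence: pd.DataFrame  # one row per (scan, element, line)


def _process_record(record: ScanRecord, resolution,
                    sigma_channels: float = 2.0) -> dict[float, ProcessedSpectrum]:
    out = {}
    for s in record.spectra:
        out[s.beam_energy_kev] = process_spectrum(
            s.counts, s.gain_kev_per_channel, s.offset_kev,
            sigma_channels=sigma_channels, resolution=resolution,
        )
    return out


def validate_panel(
    records: Sequence[ScanRecord],
    lines: ElementLineTable | None = None,
    snr_threshold: float = 3.0,
    taxon: str | None = None,
    panel: Sequence[str] | None = None,
    exclude_if_absent_fraction: float = 1.0,
    dwell_time_s: float = 80.0,
    resolution=DEFAULT_RESOLUTION,
    sigma_channels: float = 6.4,
) -> PanelResult:
    """Screen the element panel against the taxon's longest scans.

    Uses the 80 s scans in the thawed state (natural for taxa never thawed,
    e.g. feathers).  An element is excluded when either diagnostic line is
    absent in at least `exclude_if_absent_fraction` of those scans (default
    1.0: absent in all of them).  Diagnostic lines that no beam can excite,
    or that fall beyond the energy axis, count as absent.
    """
    lines = lines or default_line_table()
    panel = tuple(panel) if panel is not None else lines.elements()
    scans = [
        r for r in records
        if r.metadata.dwell_time_s == dwell_time_s
        and r.metadata.state in ("thawed", "natural")
        and (taxon is None or r.metadata.taxon == taxon)
    ]
    if not scans:
        raise ValueError(f"no {dwell_time_s:g} s scans available for panel validation")

    evidence_rows = []
    absent_frac: dict[str, dict[str, float]] = {}
    processed = [_process_record(r, resolution, sigma_channels) for r in scans]
    for element in panel:
        ka1, kb = lines.diagnostic_lines(element)
        per_line_absent = {ka1.line_label: 0, kb.line_label: 0}
        for record, by_beam in zip(scans, processed):
            for line in (ka1, kb):
                beam = select_beam(line.energy_kev, sorted(by_beam))
                axis_max = float(next(iter(by_beam.values())).energy[-1])
                if beam is None or not MIN_DETECTABLE_KEV <= line.energy_kev <= axis_max:
                    res = PeakCheckResult(
                        element, line.line_label, line.energy_kev, 0.0, 0.0, 0.0, False
                    )
                else:
                    res = _check_line(by_beam[beam], element, line, snr_threshold, resolution)
                if not res.present:
                    per_line_absent[line.line_label] += 1
                evidence_rows.append(
                    {
                        "export_id": record.metadata.export_id,
                        "element": element,
                        "line_label": res.line_label,
                        "centre_energy_kev": res.centre_energy,
                        "net_sum": res.net_sum,
                        "baseline_sum": res.baseline_sum,
                        "snr": res.snr,
                        "present": res.present,
                    }
                )
        absent_frac[element] = {
            lab: count / len(scans) for lab, count in per_line_absent.items()
        }

    excluded = tuple(
        e for e in panel
        if any(f >= exclude_if_absent_fraction for f in absent_frac[e].values())
    )
    retained = tuple(e for e in panel if e not in excluded)
    return PanelResult(retained=retained, excluded=excluded, evidence=pd.DataFrame(evidence_rows))


def apply_lod_filter(
    table: pd.DataFrame,
    group_col: str,
    min_detects_per_group: int = 3,
    value_col: str = "concentration_pct",
) -> pd.DataFrame:
    """Blank below-LOD values and drop under-detected elements.

    Below-LOD entries become missing values.  An element is dropped from the
    comparison keyed by `group_col` when any level of that column has fewer
    than `min_detects_per_group` detected values for the element.
    """
    df = table.copy()
    df.loc[df["below_lod"].astype(bool), value_col] = np.nan
    detects = (
        df[df[value_col].notna()]
        .groupby(["element", group_col], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    levels = df[group_col].unique()
    keep = []
    for element in df["element"].unique():
        counts = detects.loc[element] if element in detects.index else None
        ok = counts is not None and all(
            counts.get(level, 0) >= min_detects_per_group for level in levels
        )
        if ok:
            keep.append(element)
        else:
            logger.info("dropping %s from %s comparison (insufficient detects)",
                        element, group_col)
    return df[df["element"].isin(keep)].reset_index(drop=True)
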