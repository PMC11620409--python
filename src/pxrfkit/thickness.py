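"""Infinite-thickness QC from tungsten anode L-lines.

A sample thick and dense enough to contain the beam ("infinite thickness")
returns the same tube-scatter signature whether or not a silica block sits
behind it; a thin sample lets primary radiation reach the backing, inflating
the scattered tungsten L-lines.  The test compares net W Lalpha1/Lbeta1
window counts, normalised by total net counts, between backed and unbacked
scans: the site passes when the relative difference is within a threshold
(default 0.10) for every assessed line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_vanta import ScanRecord
from .lines import ElementLineTable, default_line_table
from .spectra import DEFAULT_RESOLUTION, ProcessedSpectrum, fwhm_kev, process_spectrum, window_counts

__all__ = [
    "ThicknessVerdict",
    "tungsten_window",
    "infinite_thickness_test",
    "thickness_verdicts",
]

W_LINES = ("La1", "Lb1")
#: The 50 keV beam best excites tungsten L scatter.
DEFAULT_BEAM_KEV = 50.0


@dataclass(frozen=True)
class ThicknessVerdict:
    """Backed-vs-unbacked comparison for one W line at one scan site."""

    specimen_id: str
    location: str
    state: str
    line_label: str
    normalised_backed: float
    normalised_unbacked: float
    rel_diff: float
    threshold: float
    met: bool  # shared across the site's assessed lines


def tungsten_window(
    processed: ProcessedSpectrum,
    lines: ElementLineTable | None = None,
    resolution=DEFAULT_RESOLUTION,
) -> dict[str, float]:
    """Net W Lalpha1/Lbeta1 window sums divided by total net counts.

    Normalisation by the spectrum's own total makes the measure invariant
    to dwell time and source intensity.
    """
    lines = lines or default_line_table()
    total = float(processed.net.sum())
    if total <= 0:
        raise ValueError("total net counts must be > 0")
    out = {}
    for label in W_LINES:
        line = lines.get("W", label)
        half_width = 1.5 * float(fwhm_kev(line.energy_kev, resolution))
        net, _ = window_counts(processed, line.energy_kev, half_width)
        out[label] = net / total
    return out


def _mean_windows(records: Iterable[ScanRecord], beam_kev: float,
                  lines, resolution) -> dict[str, float]:
    sums: dict[str, list[float]] = {lab: [] for lab in W_LINES}
    for rec in records:
        s = rec.spectrum_for_beam_energy(beam_kev)
        processed = process_spectrum(
            s.counts, s.gain_kev_per_channel, s.offset_kev, resolution=resolution
        )
        for lab, v in tungsten_window(processed, lines, resolution).items():
            sums[lab].append(v)
    return {lab: float(np.mean(v)) for lab, v in sums.items()}


def _rel_diff(b: float, u: float) -> float:
    if b < 0 or u < 0 or b + u <= 0:
        raise ValueError("window counts must be non-negative with a positive sum")
    return abs(b - u) / ((b + u) / 2.0)


def infinite_thickness_test(
    backed: "ScanRecord | Sequence[ScanRecord]",
    unbacked: "ScanRecord | Sequence[ScanRecord]",
    threshold: float = 0.10,
    lines: ElementLineTable | None = None,
    beam_kev: float = DEFAULT_BEAM_KEV,
    resolution=DEFAULT_RESOLUTION,
) -> list[ThicknessVerdict]:
    """Verdict for one scan site from matched backed/unbacked scans.

    Accepts single records or replicate lists (replicate-averaged windows).
    The two sides must agree on specimen, location, state and dwell time.
    """
    lines = lines or default_line_table()
    backed_list = [backed] if isinstance(backed, ScanRecord) else list(backed)
    unbacked_list = [unbacked] if isinstance(unbacked, ScanRecord) else list(unbacked)
    if not backed_list or not unbacked_list:
        raise ValueError("both backed and unbacked records are required")
    ref_b, ref_u = backed_list[0].metadata, unbacked_list[0].metadata
    mismatched = [
        f for f in ("specimen_id", "location", "state", "dwell_time_s")
        if getattr(ref_b, f) != getattr(ref_u, f)
    ]
    if mismatched:
        raise ValueError(f"backed/unbacked metadata mismatch on: {mismatched}")

    win_b = _mean_windows(backed_list, beam_kev, lines, resolution)
    win_u = _mean_windows(unbacked_list, beam_kev, lines, resolution)
    diffs = {lab: _rel_diff(win_b[lab], win_u[lab]) for lab in W_LINES}
    met = all(d <= threshold for d in diffs.values())
    return [
        ThicknessVerdict(
            specimen_id=ref_b.specimen_id,
            location=ref_b.location,
            state=ref_b.state,
            line_label=lab,
            normalised_backed=win_b[lab],
            normalised_unbacked=win_u[lab],
            rel_diff=diffs[lab],
            threshold=threshold,
            met=met,
        )
        for lab in W_LINES
    ]


def thickness_verdicts(
    records: Sequence[ScanRecord],
    threshold: float = 0.10,
    lines: ElementLineTable | None = None,
    beam_kev: float = DEFAULT_BEAM_KEV,
    resolution=DEFAULT_RESOLUTION,
) -> pd.DataFrame:
    """Study-level driver: one verdict per (specimen, location, state).

    Replicates and dwell times are pooled — the normalised window is dwell-
    invariant in expectation, so averaging across dwells just adds precision.
    """
    lines = lines or default_line_table()
    groups: dict[tuple, dict[bool, list[ScanRecord]]] = {}
    for rec in records:
        m = rec.metadata
        key = (m.specimen_id, m.location, m.state)
        groups.setdefault(key, {True: [], False: []})[m.backed].append(rec)

    rows = []
    for (specimen, location, state), sides in sorted(groups.items()):
        if not sides[True] or not sides[False]:
            continue  # unpaired site: no verdict possible
        win_b = _mean_windows(sides[True], beam_kev, lines, resolution)
        win_u = _mean_windows(sides[False], beam_kev, lines, resolution)
        diffs = {lab: _rel_diff(win_b[lab], win_u[lab]) for lab in W_LINES}
        met = all(d <= threshold for d in diffs.values())
        for lab in W_LINES:
            rows.append(
                {
                    "specimen_id": specimen,
                    "location": location,
                    "state": state,
                    "line_label": lab,
                    "normalised_backed": win_b[lab],
                    "normalised_unbacked": win_u[lab],
                    "rel_diff": diffs[lab],
                    "threshold": threshold,
                    "met": met,
                }
            )
    if not rows:
        raise ValueError("no backed/unbacked scan pairs found")
    return pd.DataFrame(rows)
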