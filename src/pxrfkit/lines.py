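"""Characteristic X-ray emission line reference table.

Energies (keV) of the principal K- and L-shell emission lines for the
42-element panel reported by the instrument's geochemistry method, plus the
tungsten anode lines used for thickness QC.  Values are standard transition
energies rounded to the eV; relative intensities are nominal emission-line
ratios (strongest line of the element = 1.0) adequate for window placement
and forward simulation, not for fundamental-parameters quantification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = [
    "ElementLine",
    "ElementLineTable",
    "ATOMIC_NUMBER",
    "PANEL_42",
    "RETAINED_20",
    "EXCLUDED_22",
    "default_line_table",
]

# Relative intensities used when building the default table.
_REL = {"Ka1": 1.0, "Kb1": 0.15, "Kb2": 0.04, "La1": 0.50, "Lb1": 0.45}

# Canonical ordering of line labels by energy within one element.
_LINE_ORDER = ("La1", "Lb1", "Ka1", "Kb1", "Kb2")


@dataclass(frozen=True)
class ElementLine:
    """One characteristic emission line of one element."""

    element: str
    line_label: str  # one of Ka1, Kb1, Kb2, La1, Lb1
    energy_kev: float
    relative_intensity: float

    def __post_init__(self) -> None:
        if self.energy_kev <= 0:
            raise ValueError(f"{self.element} {self.line_label}: energy must be > 0")
        if not 0 < self.relative_intensity <= 1.0:
            raise ValueError(
                f"{self.element} {self.line_label}: relative intensity must be in (0, 1]"
            )
        if self.line_label not in _LINE_ORDER:
            raise ValueError(f"unknown line label {self.line_label!r}")


# element -> (Z, {label: energy_kev})
# K energies: Ka1/Kb1 for all; Kb2 included where it is a resolved line
# (Z >= 33).  L energies included for the lanthanides and heavy metals whose
# K lines exceed the instrument's 40.94 keV axis.
_LINE_DATA: dict[str, tuple[int, dict[str, float]]] = {
    "Ne": (10, {"Ka1": 0.849, "Kb1": 0.858}),
    "Mg": (12, {"Ka1": 1.254, "Kb1": 1.302}),
    "Al": (13, {"Ka1": 1.487, "Kb1": 1.557}),
    "Si": (14, {"Ka1": 1.740, "Kb1": 1.836}),
    "P": (15, {"Ka1": 2.014, "Kb1": 2.139}),
    "S": (16, {"Ka1": 2.308, "Kb1": 2.464}),
    "Cl": (17, {"Ka1": 2.622, "Kb1": 2.816}),
    "K": (19, {"Ka1": 3.314, "Kb1": 3.590}),
    "Ca": (20, {"Ka1": 3.692, "Kb1": 4.013}),
    "Ti": (22, {"Ka1": 4.511, "Kb1": 4.932}),
    "V": (23, {"Ka1": 4.952, "Kb1": 5.427}),
    "Cr": (24, {"Ka1": 5.415, "Kb1": 5.947}),
    "Mn": (25, {"Ka1": 5.899, "Kb1": 6.490}),
    "Fe": (26, {"Ka1": 6.404, "Kb1": 7.058}),
    "Co": (27, {"Ka1": 6.930, "Kb1": 7.649}),
    "Ni": (28, {"Ka1": 7.478, "Kb1": 8.265}),
    "Cu": (29, {"Ka1": 8.048, "Kb1": 8.905}),
    "Zn": (30, {"Ka1": 8.639, "Kb1": 9.572}),
    "As": (33, {"Ka1": 10.544, "Kb1": 11.726, "Kb2": 11.864}),
    "Se": (34, {"Ka1": 11.222, "Kb1": 12.496, "Kb2": 12.652}),
    "Br": (35, {"Ka1": 11.924, "Kb1": 13.291, "Kb2": 13.470}),
    "Rb": (37, {"Ka1": 13.395, "Kb1": 14.961, "Kb2": 15.185}),
    "Sr": (38, {"Ka1": 14.165, "Kb1": 15.835, "Kb2": 16.085}),
    "Y": (39, {"Ka1": 14.958, "Kb1": 16.738, "Kb2": 17.015}),
    "Zr": (40, {"Ka1": 15.775, "Kb1": 17.668, "Kb2": 17.970}),
    "Nb": (41, {"Ka1": 16.615, "Kb1": 18.622, "Kb2": 18.953}),
    "Mo": (42, {"Ka1": 17.479, "Kb1": 19.608, "Kb2": 19.965}),
    "Pd": (46, {"Ka1": 21.177, "Kb1": 23.819, "Kb2": 24.299}),
    "Ag": (47, {"Ka1": 22.163, "Kb1": 24.942, "Kb2": 25.456}),
    "In": (49, {"Ka1": 24.210, "Kb1": 27.276, "Kb2": 27.861}),
    "Sb": (51, {"Ka1": 26.359, "Kb1": 29.726, "Kb2": 30.393}),
    "Te": (52, {"Ka1": 27.472, "Kb1": 30.996, "Kb2": 31.700}),
    "La": (57, {"La1": 4.651, "Lb1": 5.042, "Ka1": 33.442, "Kb1": 37.801, "Kb2": 38.730}),
    "Ce": (58, {"La1": 4.840, "Lb1": 5.262, "Ka1": 34.719, "Kb1": 39.257, "Kb2": 40.233}),
    "Ta": (73, {"La1": 8.146, "Lb1": 9.343, "Ka1": 57.532, "Kb1": 65.223, "Kb2": 66.990}),
    "W": (74, {"La1": 8.398, "Lb1": 9.672, "Ka1": 59.318, "Kb1": 67.244, "Kb2": 69.100}),
    "Pt": (78, {"La1": 9.442, "Lb1": 11.071, "Ka1": 66.832, "Kb1": 75.748, "Kb2": 77.850}),
    "Au": (79, {"La1": 9.713, "Lb1": 11.442, "Ka1": 68.804, "Kb1": 77.984, "Kb2": 80.150}),
    "Pb": (82, {"La1": 10.552, "Lb1": 12.614, "Ka1": 74.969, "Kb1": 84.936, "Kb2": 87.320}),
    "Bi": (83, {"La1": 10.839, "Lb1": 13.024, "Ka1": 77.108, "Kb1": 87.343, "Kb2": 89.830}),
    "Th": (90, {"La1": 12.969, "Lb1": 16.202, "Ka1": 93.350, "Kb1": 105.609, "Kb2": 108.640}),
    "U": (92, {"La1": 13.615, "Lb1": 17.220, "Ka1": 98.439, "Kb1": 111.300, "Kb2": 114.530}),
}

ATOMIC_NUMBER: dict[str, int] = {el: z for el, (z, _) in _LINE_DATA.items()}

#: The full panel the instrument reports, in atomic-number order.
PANEL_42: tuple[str, ...] = tuple(sorted(_LINE_DATA, key=ATOMIC_NUMBER.get))

#: Biologically plausible elements retained after diagnostic-peak screening.
RETAINED_20: tuple[str, ...] = (
    "Mg", "Al", "P", "S", "Cl", "K", "Ca", "Ti", "Mn", "Fe",
    "Ni", "Cu", "Zn", "As", "Se", "Br", "Rb", "Sr", "Zr", "Mo",
)

#: Non-biological / undetectable complement of the panel.
EXCLUDED_22: tuple[str, ...] = tuple(e for e in PANEL_42 if e not in RETAINED_20)


class ElementLineTable:
    """Lookup of characteristic lines keyed by element and line label.

    Enforces, per element, the physical energy ordering
    La1 < Lb1 < Ka1 < Kb1 < Kb2 over whichever of those lines are present.
    """

    def __init__(self, lines: Mapping[str, Mapping[str, ElementLine]]):
        self._lines = {el: dict(d) for el, d in lines.items()}
        for el, d in self._lines.items():
            present = [d[lab].energy_kev for lab in _LINE_ORDER if lab in d]
            if any(b <= a for a, b in zip(present, present[1:])):
                raise ValueError(f"line energies for {el} violate La1<Lb1<Ka1<Kb1<Kb2")

    def elements(self) -> tuple[str, ...]:
        return tuple(self._lines)

    def has_line(self, element: str, label: str) -> bool:
        return label in self._lines.get(element, ())

    def get(self, element: str, label: str) -> ElementLine:
        try:
            return self._lines[element][label]
        except KeyError:
            raise KeyError(f"no {label} line tabulated for element {element!r}") from None

    def lines_of(self, element: str) -> tuple[ElementLine, ...]:
        if element not in self._lines:
            raise KeyError(f"element {element!r} not in line table")
        d = self._lines[element]
        return tuple(d[lab] for lab in _LINE_ORDER if lab in d)

    def __iter__(self) -> Iterator[ElementLine]:
        for el in self._lines:
            yield from self.lines_of(el)

    def diagnostic_lines(self, element: str) -> tuple[ElementLine, ElementLine]:
        """The (Ka1, Kbeta) pair used for presence screening.

        Kb2 is used where tabulated as a resolved line; for lighter elements
        the Kb complex is not resolvable at SDD resolution and Kb1 stands in
        for the complex centroid.
        """
        ka1 = self.get(element, "Ka1")
        kb = self.get(element, "Kb2") if self.has_line(element, "Kb2") else self.get(element, "Kb1")
        return ka1, kb


def default_line_table() -> ElementLineTable:
    """Build the packaged 42-element line table."""
    table: dict[str, dict[str, ElementLine]] = {}
    for el, (_z, lines) in _LINE_DATA.items():
        table[el] = {
            lab: ElementLine(el, lab, e, _REL[lab]) for lab, e in lines.items()
        }
    return ElementLineTable(table)
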