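"""Reference tables for the 14-element PTE survey panel.

Per-element constants used throughout the pipeline: Hakanson toxic-response
factors ``Tr``, locally derived geochemical background concentrations ``B``
(10 uncontaminated foothill topsoils, same parent material and analytical
protocol as the survey), Italian regulatory screening concentrations for
residential (``CSC_A``) and industrial/commercial (``CSC_B``) land use,
analytical detection limits, and external baseline medians used for
enrichment-factor context (FOREGS European topsoil, GEMAS European
agricultural Ap horizon, Italian agricultural soil).

All concentrations are in ug/g (mg/kg) dry weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Canonical ordered 14-element panel.
ELEMENTS: tuple[str, ...] = (
    "As", "Cd", "Co", "Cr", "Cu", "Hg", "Mn",
    "Ni", "Pb", "Sb", "Sn", "Tl", "V", "Zn",
)

#: Chalcophile (sulphide-ore affine) elements carried by the industrial plume.
CHALCOPHILE: tuple[str, ...] = ("As", "Cd", "Cu", "Pb", "Zn", "Hg", "Sb", "Sn")

#: Lithogenic elements with mafic/ultramafic (ophiolitic) affinity.
LITHOGENIC: tuple[str, ...] = ("Cr", "Ni", "V", "Co", "Mn")

# Hakanson toxic-response factors; Sn has no published value and is assigned 1
# by analogy with other low-toxicity lithophile metals.
_TR = {
    "Sb": 7.0, "As": 10.0, "Cd": 30.0, "Co": 5.0, "Cr": 2.0, "Mn": 1.0,
    "Hg": 40.0, "Ni": 5.0, "Pb": 5.0, "Cu": 5.0, "Tl": 1.0, "V": 2.0,
    "Zn": 1.0, "Sn": 1.0,
}

# Local background concentrations (ug/g).
_B = {
    "Sb": 0.50, "As": 8.85, "Cd": 0.16, "Co": 8.00, "Cr": 42.6, "Mn": 601.0,
    "Hg": 0.10, "Ni": 25.2, "Pb": 13.9, "Cu": 18.1, "Sn": 1.65, "Tl": 0.19,
    "V": 26.2, "Zn": 50.9,
}

# Italian screening concentrations (D.Lgs. 152/2006); Mn has no statutory value.
_CSC_A = {
    "As": 20.0, "Cd": 2.0, "Co": 20.0, "Cr": 150.0, "Cu": 120.0, "Hg": 1.0,
    "Ni": 120.0, "Pb": 100.0, "Sb": 10.0, "Sn": 1.0, "Tl": 1.0, "V": 90.0,
    "Zn": 150.0,
}
_CSC_B = {
    "As": 50.0, "Cd": 15.0, "Co": 250.0, "Cr": 800.0, "Cu": 600.0, "Hg": 5.0,
    "Ni": 800.0, "Pb": 1000.0, "Sb": 30.0, "Sn": 350.0, "Tl": 10.0, "V": 250.0,
    "Zn": 1500.0,
}

# Analytical detection limits (ug/g); elements not listed were always quantified.
_DL = {"Cd": 0.10, "Hg": 0.10, "Sb": 0.50, "Tl": 0.10}

# Published descriptive statistics of the study survey (ug/g); usable as
# worked-example inputs (e.g. cohort enrichment against the GEMAS medians).
STUDY_SUMMARY: dict[str, dict[str, float]] = {
    "average": {
        "As": 33.8, "Cd": 0.33, "Co": 9.46, "Cr": 35.7, "Cu": 27.9,
        "Hg": 0.11, "Mn": 752.0, "Ni": 25.9, "Pb": 29.4, "Sb": 0.54,
        "Sn": 1.99, "Tl": 0.18, "V": 25.5, "Zn": 129.0,
    },
    "sd": {
        "As": 35.5, "Cd": 0.40, "Co": 4.66, "Cr": 14.9, "Cu": 18.6,
        "Hg": 0.02, "Mn": 786.0, "Ni": 6.21, "Pb": 20.8, "Sb": 0.05,
        "Sn": 0.63, "Tl": 0.07, "V": 5.99, "Zn": 163.0,
    },
    "median": {
        "As": 20.7, "Cd": 0.22, "Co": 8.43, "Cr": 32.3, "Cu": 23.3,
        "Hg": 0.11, "Mn": 659.0, "Ni": 26.2, "Pb": 21.2, "Sb": 0.50,
        "Sn": 1.95, "Tl": 0.18, "V": 26.0, "Zn": 83.7,
    },
    "max": {
        "As": 211.0, "Cd": 2.52, "Co": 36.4, "Cr": 101.0, "Cu": 111.0,
        "Hg": 0.16, "Mn": 5581.0, "Ni": 42.1, "Pb": 87.5, "Sb": 0.60,
        "Sn": 4.80, "Tl": 0.39, "V": 50.2, "Zn": 1066.0,
    },
}

# External baseline medians (ug/g) for enrichment-factor context.
_BASELINES = {
    # FOREGS European topsoil, 0-25 cm
    "european_topsoil": {
        "As": 7.03, "Cd": 0.15, "Co": 7.78, "Cr": 60.0, "Cu": 13.0,
        "Hg": 0.037, "Mn": 382.0, "Ni": 18.0, "Pb": 22.6, "Sb": 0.60,
        "Sn": 3.00, "Tl": 0.66, "V": 60.4, "Zn": 52.0,
    },
    # GEMAS European agricultural soil, Ap horizon 0-20 cm
    "european_agricultural": {
        "As": 5.50, "Cd": 0.18, "Co": 7.50, "Cr": 20.0, "Cu": 15.0,
        "Hg": 0.030, "Mn": 445.0, "Ni": 15.0, "Pb": 16.0, "Sb": 0.23,
        "Sn": 0.72, "Tl": 0.12, "V": 25.0, "Zn": 45.0,
    },
    # Italian agricultural soil, Ap horizon 0-20 cm
    "italian_agricultural": {
        "As": 7.56, "Cd": 0.26, "Co": 11.8, "Cr": 33.6, "Cu": 32.0,
        "Hg": 0.033, "Mn": 664.0, "Ni": 31.5, "Pb": 22.1, "Sb": 0.32,
        "Sn": 1.03, "Tl": 0.18, "V": 34.2, "Zn": 61.7,
    },
}


@dataclass(frozen=True)
class ReferenceTables:
    """Per-element reference constants for risk assessment and screening.

    Attributes
    ----------
    Tr : dict
        Hakanson toxic-response factor per element (dimensionless, >= 1).
    B : dict
        Local background concentration per element (ug/g, > 0).
    CSC_A, CSC_B : dict
        Italian screening concentrations for residential and
        industrial/commercial use; an element absent from the dict
        (Mn) has no statutory value.
    DL : dict
        Detection limit per element (ug/g); absent means never censored.
    baselines : dict
        ``{source_name: {element: median}}`` external baseline medians.
    """

    Tr: dict[str, float] = field(default_factory=lambda: dict(_TR))
    B: dict[str, float] = field(default_factory=lambda: dict(_B))
    CSC_A: dict[str, float] = field(default_factory=lambda: dict(_CSC_A))
    CSC_B: dict[str, float] = field(default_factory=lambda: dict(_CSC_B))
    DL: dict[str, float] = field(default_factory=lambda: dict(_DL))
    baselines: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _BASELINES.items()}
    )

    def __post_init__(self) -> None:
        for el, t in self.Tr.items():
            if t < 1:
                raise ValueError(f"Tr[{el}] = {t} < 1")
        for el, b in self.B.items():
            if b <= 0:
                raise ValueError(f"background B[{el}] = {b} must be > 0")
        for el in self.CSC_A:
            if el in self.CSC_B and self.CSC_B[el] < self.CSC_A[el]:
                raise ValueError(f"CSC_B[{el}] < CSC_A[{el}]")

    def replace(self, **overrides: dict) -> "ReferenceTables":
        """Return a copy with selected tables overridden entry-by-entry."""
        new = {
            name: dict(getattr(self, name))
            for name in ("Tr", "B", "CSC_A", "CSC_B", "DL")
        }
        baselines = {k: dict(v) for k, v in self.baselines.items()}
        for name, table in overrides.items():
            if name == "baselines":
                for src, row in table.items():
                    baselines.setdefault(src, {}).update(row)
            elif name in new:
                new[name].update(table)
            else:
                raise KeyError(f"unknown reference table {name!r}")
        return ReferenceTables(baselines=baselines, **new)

    def to_frame(self) -> pd.DataFrame:
        """Element-by-constant DataFrame (NaN where undefined)."""
        rows = {}
        for name in ("Tr", "B", "CSC_A", "CSC_B", "DL"):
            rows[name] = getattr(self, name)
        for src, row in self.baselines.items():
            rows[src] = row
        return pd.DataFrame(rows).reindex(list(ELEMENTS))


def default_references() -> ReferenceTables:
    """Return the packaged study reference tables."""
    return ReferenceTables()
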