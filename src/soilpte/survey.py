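"""Survey data model and CSV I/O.

A survey is a site-by-element table of topsoil concentrations with planar
projected coordinates, elevation and a land-use class per site. Values below
the analytical detection limit are *censored*: they are stored at the limit
itself with a boolean flag, and each downstream stage applies its own
substitution policy (see :mod:`soilpte.compositional`).

CSV dialect: UTF-8, "." decimal, one header row with columns
``site,x,y,elevation,land_use`` followed by one column per element.
A censored cell is written as ``<LIMIT`` (e.g. ``<0.5``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .references import ELEMENTS

LAND_USES = ("agricultural", "industrial", "urban", "other")
META_COLUMNS = ("site", "x", "y", "elevation", "land_use")


class SurveySchemaError(ValueError):
    """Raised when a survey file violates the column contract."""


@dataclass
class SurveyTable:
    """Validated site-by-element concentration table.

    Attributes
    ----------
    data : pandas.DataFrame
        One row per site with columns ``site, x, y, elevation, land_use``
        and one float column per element (ug/g). Censored cells hold the
        detection limit.
    censored : pandas.DataFrame
        Boolean site-by-element frame, True where the stored value is a
        detection limit rather than a measurement.
    """

    data: pd.DataFrame
    censored: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise SurveySchemaError(f"missing mandatory column(s): {missing}")
        self.data = self.data.reset_index(drop=True)
        elements = self.elements
        if not elements:
            raise SurveySchemaError("no element columns found")
        if self.censored is None:
            self.censored = pd.DataFrame(
                False, index=self.data.index, columns=elements
            )
        self.censored = self.censored.reindex(
            index=self.data.index, columns=elements, fill_value=False
        ).astype(bool)
        if self.data["site"].duplicated().any():
            dups = self.data.loc[self.data["site"].duplicated(), "site"].tolist()
            raise ValueError(f"duplicate site ids: {dups}")
        xy = self.data[["x", "y"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise ValueError("non-finite coordinates")
        bad_use = set(self.data["land_use"]) - set(LAND_USES)
        if bad_use:
            raise ValueError(f"unknown land-use class(es): {sorted(bad_use)}")
        conc = self.data[elements].to_numpy(float)
        uncensored_bad = (conc <= 0) & ~self.censored.to_numpy()
        if uncensored_bad.any() or not np.isfinite(conc).all():
            i, j = np.argwhere(uncensored_bad | ~np.isfinite(conc))[0]
            raise ValueError(
                f"non-positive or non-finite concentration at site "
                f"{self.data['site'].iloc[i]!r}, element {elements[j]!r}"
            )

    @property
    def elements(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def n_sites(self) -> int:
        return len(self.data)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of projected x/y in metres."""
        return self.data[["x", "y"]].to_numpy(float)

    def concentrations(self) -> pd.DataFrame:
        """Site-by-element concentration frame (censored cells at DL)."""
        out = self.data[self.elements].astype(float).copy()
        out.index = self.data["site"]
        return out

    def censoring_rate(self) -> pd.Series:
        """Fraction of sites censored, per element."""
        return self.censored.mean(axis=0)

    def subset_elements(self, elements: list[str]) -> "SurveyTable":
        keep = list(META_COLUMNS) + list(elements)
        return SurveyTable(
            self.data[keep].copy(), self.censored[list(elements)].copy()
        )


def read_survey(path, elements: list[str] | None = None) -> SurveyTable:
    """Read a survey CSV, flagging ``<DL`` sentinel cells as censored.

    Parameters
    ----------
    path : str or file-like
        CSV with the documented column dialect.
    elements : list of str, optional
        Restrict/validate the element panel; defaults to every non-meta
        column in file order.
    """
    raw = pd.read_csv(path, dtype=str).rename(columns=str.strip)
    missing = [c for c in META_COLUMNS if c not in raw.columns]
    if missing:
        raise SurveySchemaError(f"missing mandatory column(s): {missing}")
    element_cols = [c for c in raw.columns if c not in META_COLUMNS]
    if elements is not None:
        absent = [e for e in elements if e not in element_cols]
        if absent:
            raise SurveySchemaError(f"element column(s) not in file: {absent}")
        element_cols = list(elements)

    data = pd.DataFrame({"site": raw["site"].astype(str).str.strip()})
    # float() parses exactly (correctly rounded), so read/write round-trips
    for c in ("x", "y", "elevation"):
        data[c] = raw[c].map(float)
    data["land_use"] = raw["land_use"].astype(str).str.strip().str.lower()

    censored = pd.DataFrame(False, index=raw.index, columns=element_cols)
    for el in element_cols:
        cells = raw[el].astype(str).str.strip()
        below = cells.str.startswith("<")
        censored[el] = below
        data[el] = cells.where(~below, cells.str.lstrip("<")).map(float)
    return SurveyTable(data, censored)


def write_survey(table: SurveyTable, path) -> None:
    """Write a survey CSV; censored cells are serialised as ``<DL``."""
    out = table.data.copy()
    for c in ("x", "y", "elevation"):
        out[c] = out[c].map(lambda v: repr(float(v)))
    for el in table.elements:
        col = out[el].map(lambda v: repr(float(v)))  # shortest round-trip
        flagged = table.censored[el].to_numpy()
        out[el] = np.where(flagged, "<" + col, col)
    out.to_csv(path, index=False)


def make_survey(
    site_ids,
    coords: np.ndarray,
    elevation,
    land_use,
    conc: pd.DataFrame,
    censored: pd.DataFrame | None = None,
) -> SurveyTable:
    """Assemble a :class:`SurveyTable` from arrays (used by the simulator)."""
    data = pd.DataFrame(
        {
            "site": list(site_ids),
            "x": np.asarray(coords)[:, 0],
            "y": np.asarray(coords)[:, 1],
            "elevation": np.asarray(elevation, float),
            "land_use": list(land_use),
        }
    )
    for el in conc.columns:
        data[el] = np.asarray(conc[el], float)
    return SurveyTable(data, censored)


def default_panel() -> list[str]:
    """The canonical ordered 14-element panel."""
    return list(ELEMENTS)
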