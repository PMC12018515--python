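"""Packaged reference morphometrics of the insula and model comparison.

The constants are literature-averaged anatomical measurements (mm unless
noted) packaged verbatim as reference data.  They are not mutually
consistent with the ellipsoid model — e.g. the reference volume
(1200 mm^3) is about half the ellipsoid's analytic volume and the
midline distance (15.6 mm) differs from the model centre's |x0| = 40 mm
— so the comparison report is purely descriptive: it pairs model-derived
quantities with the reference constants and reports ratios and absolute
differences, never a pass/fail verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

from .geometry import EllipsoidModel

__all__ = ["ReferenceMorphometrics", "REFERENCE", "compare_morphometrics"]


@dataclass(frozen=True)
class ReferenceMorphometrics:
    """Literature-averaged insular morphometrics (mm; area mm^2; volume mm^3)."""

    diameter: float = 35.5
    length: float = 40.2
    width: float = 20.8
    thickness: float = 4.3
    distance_to_midline: float = 15.6
    surface_area: float = 240.7
    volume: float = 1200.0
    anterior_distance: float = 10.5
    posterior_distance: float = 12.3
    superior_distance: float = 8.7
    inferior_distance: float = 11.2

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


REFERENCE = ReferenceMorphometrics()


def compare_morphometrics(
    ellipsoid: EllipsoidModel, reference: ReferenceMorphometrics = REFERENCE
) -> pd.DataFrame:
    """Pair model-derived quantities with the reference constants.

    Rows: mediolateral extent (2a) vs width, anteroposterior extent (2b)
    vs length, |x0| vs distance to midline, analytic volume vs reference
    volume, and the Thomsen surface-area approximation vs the reference
    area.  ``ratio`` is model / reference.
    """
    ext_x, ext_y, _ = ellipsoid.extents()
    rows = [
        ("width_mediolateral", ext_x, reference.width, "full mediolateral extent 2a vs reference width"),
        ("length_anteroposterior", ext_y, reference.length, "full anteroposterior extent 2b vs reference length"),
        ("distance_to_midline", abs(ellipsoid.center[0]), reference.distance_to_midline, "|x0| of the model centre vs reference midline distance"),
        ("volume", ellipsoid.volume(), reference.volume, "analytic ellipsoid volume (4/3)pi*a*b*c vs reference volume"),
        ("surface_area", ellipsoid.surface_area(), reference.surface_area, "approximate ellipsoid area (Thomsen formula) vs reference area"),
    ]
    df = pd.DataFrame(rows, columns=["measurement", "model", "reference", "note"])
    df["ratio"] = df["model"] / df["reference"]
    df["abs_difference"] = (df["model"] - df["reference"]).abs()
    return df[["measurement", "model", "reference", "ratio", "abs_difference", "note"]]
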