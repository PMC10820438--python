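"""Water-contact-angle arithmetic: coating-induced wettability alteration
and SDS-rinse resilience.

Conventions (fixed by matching published reports): wettability
alteration is expressed relative to the *blank* surface and reported as
a reduction when the coated angle is lower (hydrophobic surface made
wetter) or an increase when higher (hydrophilic surface made less
wettable); rinse resilience is the magnitude of the post-rinse change
relative to the *coated* (pre-rinse) angle, with the direction retained
as a flag. Percentages are rounded half-up to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import List, Literal, Optional

import pandas as pd

__all__ = [
    "WcaMeasurement",
    "PercentChange",
    "wettability_alteration",
    "rinse_resilience",
    "read_wca_table",
    "wca_report",
]


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class WcaMeasurement:
    """One contact-angle measurement (replicate mean)."""

    surface: Literal["teflon", "mica"]
    condition: Literal["blank", "coated", "coated_rinsed"]
    protein: Optional[str]
    mean_deg: float
    sd_deg: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_deg <= 180.0:
            raise ValueError(f"contact angle {self.mean_deg} outside [0, 180]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class PercentChange:
    """A percent change with its direction."""

    percent: float
    direction: Literal["reduced", "increase", "unchanged"]

    @property
    def signed(self) -> float:
        return -self.percent if self.direction == "reduced" else self.percent


def wettability_alteration(blank: float, coated: float) -> PercentChange:
    """Coating-induced wettability change relative to the blank angle.

    100*(blank - coated)/blank when the angle dropped (reported as
    "reduced"), 100*(coated - blank)/blank when it rose ("increase").
    """
    if blank <= 0:
        raise ValueError(f"blank angle must be positive, got {blank}")
    if coated == blank:
        return PercentChange(0.0, "unchanged")
    if coated < blank:
        return PercentChange(_round2(100.0 * (blank - coated) / blank), "reduced")
    return PercentChange(_round2(100.0 * (coated - blank) / blank), "increase")


def rinse_resilience(coated: float, rinsed: float) -> PercentChange:
    """Post-rinse change magnitude relative to the pre-rinse coated angle.

    100*|rinsed - coated|/coated; a small value means the coating layer
    survived the hot-SDS rinse.
    """
    if coated <= 0:
        raise ValueError(f"coated angle must be positive, got {coated}")
    if rinsed == coated:
        return PercentChange(0.0, "unchanged")
    direction = "reduced" if rinsed < coated else "increase"
    return PercentChange(_round2(100.0 * abs(rinsed - coated) / coated), direction)


def read_wca_table(path: str | Path) -> List[WcaMeasurement]:
    """Read a measurement TSV (surface, condition, protein, mean, sd, n)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        protein = getattr(row, "protein", None)
        if pd.isna(protein) or protein == "":
            protein = None
        out.append(
            WcaMeasurement(
                surface=row.surface,
                condition=row.condition,
                protein=protein,
                mean_deg=float(row.mean),
                sd_deg=float(getattr(row, "sd", 0.0)),
                n=int(getattr(row, "n", 1)),
            )
        )
    return out


def wca_report(measurements: List[WcaMeasurement]) -> pd.DataFrame:
    """Alteration and resilience percentages per (protein, surface).

    Requires one blank measurement per surface; proteins with a coated
    measurement get a wettability-alteration row, and those with a
    rinsed measurement additionally get a rinse-resilience row.
    Denominators: alteration vs the blank angle, resilience vs the
    coated angle.
    """
    blanks = {
        m.surface: m for m in measurements if m.condition == "blank"
    }
    rows = []
    proteins = sorted({m.protein for m in measurements if m.protein})
    for protein in proteins:
        for surface in ("teflon", "mica"):
            coated = next(
                (
                    m
                    for m in measurements
                    if m.protein == protein
                    and m.surface == surface
                    and m.condition == "coated"
                ),
                None,
            )
            if coated is None:
                continue
            if surface not in blanks:
                raise ValueError(f"no blank measurement for surface {surface!r}")
            alt = wettability_alteration(blanks[surface].mean_deg, coated.mean_deg)
            rows.append(
                {
                    "protein": protein,
                    "surface": surface,
                    "quantity": "wettability_alteration_vs_blank",
                    "percent": alt.percent,
                    "direction": alt.direction,
                }
            )
            rinsed = next(
                (
                    m
                    for m in measurements
                    if m.protein == protein
                    and m.surface == surface
                    and m.condition == "coated_rinsed"
                ),
                None,
            )
            if rinsed is not None:
                res = rinse_resilience(coated.mean_deg, rinsed.mean_deg)
                rows.append(
                    {
                        "protein": protein,
                        "surface": surface,
                        "quantity": "rinse_resilience_vs_coated",
                        "percent": res.percent,
                        "direction": res.direction,
                    }
                )
    return pd.DataFrame(rows)
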