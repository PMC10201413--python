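"""Michaelis-Menten fitting of single-nucleotide incorporation kinetics.

Velocities (%incor/min) at a dilution series of triphosphate concentrations
are fit to v = Vmax c / (Km + c) by nonlinear least squares; the efficiency
of incorporation is reported as the second-order constant Vmax/Km in
%.min^-1.M^-1 (concentrations are in uM, hence the 10^6 factor).  Signals
below a configurable floor are reported as not detectable (n.d.) rather than
fit to noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class KineticsDataset:
    concentrations: np.ndarray  # uM
    velocities: np.ndarray  # %incor/min
    label: str = ""
    fractions: np.ndarray | None = None  # underlying extended-primer fractions

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.concentrations.shape != self.velocities.shape:
            raise ValueError("concentrations and velocities must align")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be strictly positive")
        if (self.velocities < 0).any():
            raise ValueError("velocities must be non-negative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "KineticsDataset":
        return cls(
            df["concentration_uM"].to_numpy(),
            df["velocity_pct_per_min"].to_numpy(),
            label=label or str(df.get("label", pd.Series(["sample"])).iloc[0]),
        )

    def linear_range_violations(self, limit: float = 0.20) -> np.ndarray:
        """Flag points whose underlying extended-primer fraction breaks the
        <20% linear-range rule (flagged, never silently dropped)."""
        if self.fractions is None:
            return np.zeros_like(self.velocities, dtype=bool)
        return np.asarray(self.fractions) >= limit


@dataclass(frozen=True)
class KineticsFit:
    vmax: float | None
    km: float | None
    vmax_se: float | None
    km_se: float | None
    second_order: float | None  # %.min^-1.M^-1
    detectable: bool
    label: str = ""

    def summary_row(self) -> dict:
        if not self.detectable:
            return {"label": self.label, "vmax": "n.d.", "km": "n.d.", "second_order": "n.d."}
        return {
            "label": self.label,
            "vmax": self.vmax,
            "km": self.km,
            "second_order": self.second_order,
        }


def michaelis_menten(c, vmax, km):
    return vmax * c / (km + c)


def second_order_constant(vmax: float, km_uM: float) -> float:
    """Vmax/Km after uM -> M conversion (x 10^6)."""
    return vmax / km_uM * 1e6


def fit_michaelis_menten(
    data: KineticsDataset,
    nd_floor: float = 0.5,
    weighting: str | None = None,
) -> KineticsFit:
    """Nonlinear least-squares Michaelis-Menten fit.

    Initialisation: Vmax0 = max(v), Km0 = concentration nearest half-Vmax0.
    ``weighting='1/v'`` optionally weights residuals by the inverse velocity.
    Non-convergence or a maximum velocity below ``nd_floor`` yields a
    non-detectable result (n.d.).
    """
    c, v = data.concentrations, data.velocities
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    nd = KineticsFit(None, None, None, None, None, False, data.label)
    if not (v > 0).any() or v.max() < nd_floor:
        return nd
    vmax0 = float(v.max())
    km0 = float(c[np.argmin(np.abs(v - vmax0 / 2))])
    sigma = None
    if weighting == "1/v":
        sigma = np.where(v > 0, v, v[v > 0].min())
    try:
        popt, pcov = curve_fit(
            michaelis_menten, c, v, p0=[vmax0, max(km0, 1e-6)], sigma=sigma,
            maxfev=10_000, xtol=1e-10, ftol=1e-12,
        )
    except RuntimeError:
        return nd
    vmax, km = float(popt[0]), float(popt[1])
    if vmax <= 0 or km <= 0:
        return nd
    se = np.sqrt(np.diag(pcov))
    return KineticsFit(
        vmax=vmax,
        km=km,
        vmax_se=float(se[0]),
        km_se=float(se[1]),
        second_order=second_order_constant(vmax, km),
        detectable=True,
        label=data.label,
    )


def incorporation_fraction(extended: float, unextended: float) -> float:
    """Fraction of primer extended, from band intensities."""
    if extended < 0 or unextended < 0:
        raise ValueError("band intensities must be non-negative")
    total = extended + unextended
    if total == 0:
        raise ValueError("both band intensities are zero")
    return extended / total


def incorporation_velocity(extended: float, unextended: float, minutes: float) -> float:
    """Extension fraction per minute (%incor/min when multiplied by 100)."""
    if minutes <= 0:
        raise ValueError("time must be positive")
    return incorporation_fraction(extended, unextended) / minutes
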