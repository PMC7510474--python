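"""Observation model for the ratiometric NADPH sensor (iNap) and its inverse.

The sensor reports NADPH occupancy through the ratio R of 515 nm emission
under 415 nm versus 488 nm excitation.  Because the 488 nm channel responds
to pH, the mitochondrial readout is normalized to a binding-dead control
sensor, giving the effective readout R' = R_sensor / R_control.  A one-site
binding equilibrium links R' to concentration:

    Y_model = NADPH / (Kd + NADPH)          (bound fraction)
    Y_exp   = (R' - R'_min) / (R'_max - R'_min)

Equating the two and inverting yields NADPH = Kd * Y / (1 - Y).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from mitonadph.errors import CalibrationError, PreconditionError

logger = logging.getLogger(__name__)

#: iNap3 dissociation constant for NADPH (uM), from in vitro characterisation.
DEFAULT_KD = 25.2

#: Reference basal mitochondrial NADPH concentration (uM), the mean over
#: single-cell calibrated readouts reported for HeLa cells.
BASAL_NADPH_UM = 41.8


@dataclass
class SensorCalibration:
    """Span calibration of the effective readout.

    ``r_min`` is the readout at NADPH depletion (obtained experimentally by
    saturating DAAO stimulation), ``r_max`` at sensor saturation (digitonin
    permeabilisation plus excess NADPH).  The study does not print the two
    numbers; the defaults are synthetic calibration constants in normalized
    units, placed so that the documented mean cellular readout maps to the
    41.8 uM basal estimate with the iNap3 Kd.
    """

    kd: float = DEFAULT_KD
    r_min: float = 0.4
    r_max: float = 1.6

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise CalibrationError("kd must be positive")
        if not self.r_max > self.r_min > 0:
            raise CalibrationError(
                f"calibration requires r_max > r_min > 0, got r_min={self.r_min}, r_max={self.r_max}"
            )

    @property
    def span(self) -> float:
        return self.r_max - self.r_min


@dataclass
class ReadoutSeries:
    """A normalized effective-readout time course with per-point SEM."""

    times_min: np.ndarray
    r_prime: np.ndarray
    sem: np.ndarray
    n_cells: int
    condition_mm: float
    normalized: bool = True

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.r_prime = np.asarray(self.r_prime, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (self.times_min.shape == self.r_prime.shape == self.sem.shape):
            raise PreconditionError("times, r_prime and sem must have equal length")
        if self.times_min[0] != 0:
            raise PreconditionError("readout series must start at t = 0")
        if np.any(self.r_prime <= 0):
            raise PreconditionError("readout values must be positive")
        if np.any(self.sem < 0):
            raise PreconditionError("SEM values must be non-negative")

    def normalize(self) -> "ReadoutSeries":
        """Divide the series (and SEM) by its t = 0 value."""
        r0 = self.r_prime[0]
        return ReadoutSeries(
            times_min=self.times_min,
            r_prime=self.r_prime / r0,
            sem=self.sem / r0,
            n_cells=self.n_cells,
            condition_mm=self.condition_mm,
            normalized=True,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times_min,
                "r_prime": self.r_prime,
                "sem": self.sem,
                "n_cells": self.n_cells,
                "condition_mM": self.condition_mm,
                "normalized": self.normalized,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReadoutSeries":
        required = {"time_min", "r_prime", "sem", "n_cells", "condition_mM", "normalized"}
        missing = required - set(df.columns)
        if missing:
            raise PreconditionError(f"readout table missing columns: {sorted(missing)}")
        df = df.sort_values("time_min")
        return cls(
            times_min=df["time_min"].to_numpy(),
            r_prime=df["r_prime"].to_numpy(),
            sem=df["sem"].to_numpy(),
            n_cells=int(df["n_cells"].iloc[0]),
            condition_mm=float(df["condition_mM"].iloc[0]),
            normalized=bool(df["normalized"].iloc[0]),
        )


def read_readout_csv(path) -> list[ReadoutSeries]:
    """Read a readout CSV (one or more conditions) into ReadoutSeries objects."""
    df = pd.read_csv(path)
    return [
        ReadoutSeries.from_frame(group)
        for _, group in df.groupby("condition_mM", sort=True)
    ]


def write_readout_csv(series: Sequence[ReadoutSeries], path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# elementary readout algebra
# ---------------------------------------------------------------------------

def fluorescence_ratio(f_415, f_488):
    """R = F(em 515, ex 415) / F(em 515, ex 488) after background subtraction."""
    f_415 = np.asarray(f_415, dtype=float)
    f_488 = np.asarray(f_488, dtype=float)
    if np.any(f_415 <= 0) or np.any(f_488 <= 0):
        raise PreconditionError(
            "fluorescence intensities must be positive (background oversubtraction?)"
        )
    return f_415 / f_488


def effective_readout(r_inap, r_inapc, normalize: bool = False):
    """R' = R_sensor / R_control; optionally normalized to the first element."""
    r_inap = np.asarray(r_inap, dtype=float)
    r_inapc = np.asarray(r_inapc, dtype=float)
    if np.any(r_inapc <= 0):
        raise PreconditionError("control sensor ratio must be positive")
    r_prime = r_inap / r_inapc
    if normalize:
        r_prime = r_prime / r_prime.flat[0]
    return r_prime


def y_model(nadph, kd: float = DEFAULT_KD):
    """Bound fraction NADPH/(Kd + NADPH) in [0, 1); strictly increasing."""
    nadph = np.asarray(nadph, dtype=float)
    if np.any(nadph < 0):
        raise PreconditionError("NADPH concentration must be non-negative")
    if kd <= 0:
        raise CalibrationError("kd must be positive")
    return nadph / (kd + nadph)


def y_exp(r_prime, cal: SensorCalibration, clip: bool = True):
    """Fraction of the calibrated readout span, clipped to [0, 1] with a warning."""
    r_prime = np.asarray(r_prime, dtype=float)
    y = (r_prime - cal.r_min) / cal.span
    if clip:
        n_out = int(np.sum((y < 0) | (y > 1)))
        if n_out:
            logger.warning(
                "readout outside calibration span: clipping %d of %d points to [0, 1]",
                n_out,
                y.size,
            )
        y = np.clip(y, 0.0, 1.0)
    return y


def readout_of_concentration(nadph, cal: SensorCalibration):
    """Forward observation map: concentration -> effective readout R'."""
    return cal.r_min + cal.span * y_model(nadph, cal.kd)


def concentration_from_readout(r_prime, cal: SensorCalibration):
    """Invert the observation map: R' -> NADPH (uM).

    The bound fraction must lie strictly inside (0, 1); a readout at or
    beyond the calibration limits has no finite concentration.
    """
    r_prime = np.asarray(r_prime, dtype=float)
    y = (r_prime - cal.r_min) / cal.span
    if np.any(y >= 1):
        raise CalibrationError("readout at or beyond saturation (Y >= 1)")
    if np.any(y <= 0):
        raise CalibrationError("readout at or below depletion (Y <= 0)")
    return cal.kd * y / (1.0 - y)
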