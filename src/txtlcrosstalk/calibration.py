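"""Linear fluorescence-to-concentration calibration."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["CalibrationCurve", "apply_calibration"]


@dataclass(frozen=True)
class CalibrationCurve:
    """value_nM = slope * fluorescence + intercept for one readout."""

    slope: float
    intercept: float = 0.0
    readout: str = "sfGFP"

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be > 0")

    def inverse(self, conc):
        return (np.asarray(conc, dtype=float) - self.intercept) / self.slope


def apply_calibration(raw, curve: CalibrationCurve) -> np.ndarray:
    """Elementwise linear conversion of arbitrary units to nM.

    Negative resulting concentrations are flagged with a warning but not
    clipped (they carry information about baseline subtraction).
    """
    out = np.asarray(raw, dtype=float) * curve.slope + curve.intercept
    n_neg = int(np.sum(out < 0))
    if n_neg:
        warnings.warn(
            f"calibration produced {n_neg} negative concentration(s) for {curve.readout!r}"
        )
    return out
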