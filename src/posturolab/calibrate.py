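"""COP-regression calibration of angular COM sway.

In quasi-static stance the center of pressure coincides with the vertical
projection of the whole-body center of mass, so an ordinary least-squares
regression of COP on hip and shoulder marker translations during a slow
two-joint movement yields coefficients that convert marker data to COM
translation in dynamic trials.  The angular COM sway follows from the COM
height: ``com_angle = arcsin(com_translation / com_height)`` (the exact
inverse map is used rather than the small-angle ratio; the difference is
negligible below 5 degrees but the choice is fixed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import statsmodels.api as sm

from .simulate import SwayRecording

__all__ = [
    "CalibrationModel",
    "CollinearMarkersError",
    "fit_calibration",
    "apply_calibration",
]


class CollinearMarkersError(ValueError):
    """Hip and shoulder channels are (numerically) collinear."""


@dataclass
class CalibrationModel:
    """Fitted marker -> COM-translation map.

    ``com_translation = intercept + coef_hip * hip_x + coef_shoulder * shoulder_x``
    """

    coef_hip: float
    coef_shoulder: float
    intercept: float
    com_height: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.com_height <= 0:
            raise ValueError("com_height must be positive")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_calibration(rec: SwayRecording, com_height: float) -> CalibrationModel:
    """Fit the COP regression on a quasi-static recording.

    OLS of ``cop_x`` on ``(hip_x, shoulder_x)`` with an intercept.  Requires
    at least 30 s of data and genuinely two-dimensional marker motion (some
    hip bending); collinear markers raise :class:`CollinearMarkersError`.
    """
    if rec.duration < 30.0:
        raise ValueError(
            f"calibration recording too short ({rec.duration:.1f} s < 30 s)"
        )
    X = np.column_stack([rec.hip_x, rec.shoulder_x])
    Xc = X - X.mean(axis=0)
    # rank / conditioning of the centered design decides identifiability
    sv = np.linalg.svd(Xc, compute_uv=False)
    if sv[-1] < 1e-10 * max(sv[0], 1e-30):
        raise CollinearMarkersError(
            "hip and shoulder translations are collinear; the two "
            "coefficients are not identifiable - repeat the calibration with "
            "more hip (trunk-bending) movement"
        )
    fit = sm.OLS(rec.cop_x, sm.add_constant(X)).fit()
    return CalibrationModel(
        coef_hip=float(fit.params[1]),
        coef_shoulder=float(fit.params[2]),
        intercept=float(fit.params[0]),
        com_height=float(com_height),
        r_squared=min(float(fit.rsquared), 1.0),
    )


def apply_calibration(model: CalibrationModel, rec: SwayRecording) -> np.ndarray:
    """Convert marker translations to the angular COM sway trace (deg)."""
    com_t = (
        model.intercept
        + model.coef_hip * rec.hip_x
        + model.coef_shoulder * rec.shoulder_x
    )
    if np.any(np.abs(com_t) > model.com_height):
        raise ValueError(
            "non-physical COM translation exceeding the COM height "
            f"(max |t| = {np.max(np.abs(com_t)):.3f} m > {model.com_height:.3f} m)"
        )
    return np.rad2deg(np.arcsin(com_t / model.com_height))
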