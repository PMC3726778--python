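"""Curve-vs-data scoring: analytic scale factor and reduced chi-square.

The scale mu minimizing chi^2 has the closed form

    mu = sum(I_m I_e / s^2) / sum(I_m^2 / s^2)

and the reported statistic is the reduced chi-square with K-1 degrees of
freedom (the scale being the single fitted parameter); the convention is
configurable.  Curves must share a q grid exactly — there is no silent
interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FitError, GridMismatchError
from .saxs import ScatteringCurve, debye_intensity
from .topology import BeadModel


@dataclass
class FitResult:
    chi2: float
    scale: float
    n_points: int
    residuals: np.ndarray = field(repr=False)
    model_label: str = ""

    def to_dict(self) -> dict:
        return {"model_label": self.model_label, "chi2": self.chi2,
                "scale": self.scale, "n_points": self.n_points}

    def write_report(self, path: str | Path,
                     model_curve: ScatteringCurve | None = None,
                     data_curve: ScatteringCurve | None = None) -> None:
        """Write a JSON report plus, when curves are given, a 4-column
        residual table (q, I_data, scaled I_model, residual)."""
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")
        if model_curve is not None and data_curve is not None:
            table = path.with_suffix(".residuals.tsv")
            with open(table, "w") as fh:
                fh.write("q\tI_data\tI_model_scaled\tresidual\n")
                for i in range(self.n_points):
                    fh.write(f"{data_curve.q[i]:.8e}\t{data_curve.intensity[i]:.8e}\t"
                             f"{self.scale * model_curve.intensity[i]:.8e}\t"
                             f"{self.residuals[i]:.8e}\n")


def _check_compatible(model_curve: ScatteringCurve,
                      data_curve: ScatteringCurve) -> None:
    if len(model_curve) != len(data_curve) or not np.allclose(
            model_curve.q, data_curve.q, rtol=1e-9, atol=1e-12):
        raise GridMismatchError(
            "model and data curves do not share a q grid; generate the model "
            "curve on the data grid (no interpolation is performed)")
    if data_curve.sigma is None:
        raise FitError("data curve lacks uncertainties (sigma)")


def optimal_scale(model_curve: ScatteringCurve,
                  data_curve: ScatteringCurve) -> float:
    """Analytic least-squares multiplicative scale of model onto data."""
    _check_compatible(model_curve, data_curve)
    s2 = data_curve.sigma**2
    num = np.sum(model_curve.intensity * data_curve.intensity / s2)
    den = np.sum(model_curve.intensity**2 / s2)
    if den <= 0:
        raise FitError("model curve has no intensity to scale")
    return float(num / den)


def chi_squared(model_curve: ScatteringCurve, data_curve: ScatteringCurve,
                dof_convention: str = "K-1") -> FitResult:
    """Reduced chi-square of the optimally scaled model against the data."""
    mu = optimal_scale(model_curve, data_curve)
    residuals = (mu * model_curve.intensity - data_curve.intensity) / data_curve.sigma
    k = len(data_curve)
    dof = k - 1 if dof_convention == "K-1" else k
    if dof < 1:
        raise FitError("not enough points for a reduced chi-square")
    chi2 = float(np.sum(residuals**2) / dof)
    return FitResult(chi2=chi2, scale=mu, n_points=k, residuals=residuals,
                     model_label=model_curve.label)


def fit_rigid_model(model: BeadModel, data_curve: ScatteringCurve,
                    label: str = "rigid model",
                    method: str = "auto") -> FitResult:
    """Fit a single rigid bead model to the data: Debye curve evaluated on
    the data's grid, then optimally scaled reduced chi-square."""
    model_curve = debye_intensity(model, data_curve.q, method=method, label=label)
    return chi_squared(model_curve, data_curve)
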