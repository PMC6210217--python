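"""iRT calibration: a per-sample linear map from library iRT to observed RT.

iRT is a sample-independent retention-time coordinate; each sample's standards
(16 spiked peptides in the emulated design) anchor a least-squares line
RT = slope·iRT + intercept with iterative 3-sigma outlier rejection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class CalibrationError(ValueError):
    pass


class IrtRegressor(BaseEstimator, RegressorMixin):
    """Least-squares iRT→RT line with iterative outlier rejection.

    Parameters
    ----------
    min_standards : int
        Minimum surviving calibration points; fewer raises CalibrationError.
    max_rounds : int
        Outlier-rejection rounds; each drops points with residuals beyond
        ``sigma_cut`` times the residual SD and refits.
    sigma_cut : float
        Residual cut in units of residual standard deviation.

    Attributes
    ----------
    slope_ : float          minutes per iRT unit
    intercept_ : float      minutes
    residual_sd_ : float    minutes
    n_standards_ : int      points supplied
    outliers_removed_ : int points rejected
    """

    def __init__(self, min_standards: int = 3, max_rounds: int = 2, sigma_cut: float = 3.0):
        self.min_standards = min_standards
        self.max_rounds = max_rounds
        self.sigma_cut = sigma_cut

    def fit(self, X, y):
        irt = np.asarray(X, dtype=float).reshape(-1)
        rt = np.asarray(y, dtype=float).reshape(-1)
        if len(irt) != len(rt):
            raise CalibrationError("iRT and RT arrays must have equal length")
        if len(irt) < self.min_standards:
            raise CalibrationError(
                f"need at least {self.min_standards} calibration standards, got {len(irt)}"
            )
        keep = np.ones(len(irt), dtype=bool)
        slope = intercept = sd = 0.0
        for round_no in range(self.max_rounds + 1):
            slope, intercept = np.polyfit(irt[keep], rt[keep], 1)
            resid = rt - (slope * irt + intercept)
            sd = float(np.std(resid[keep], ddof=2)) if keep.sum() > 2 else 0.0
            if round_no == self.max_rounds or sd < 1e-9:
                break  # converged (or an exact fit: nothing left to reject)
            new_keep = keep & (np.abs(resid) <= self.sigma_cut * sd)
            if new_keep.sum() < self.min_standards or new_keep.sum() == keep.sum():
                break
            keep = new_keep
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.residual_sd_ = sd
        self.n_standards_ = len(irt)
        self.outliers_removed_ = int((~keep).sum())
        self.inlier_mask_ = keep
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        irt = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * irt + self.intercept_


def fit_irt(observed: list[tuple[float, float]], min_standards: int = 3) -> IrtRegressor:
    """Fit a calibration line from (iRT, RT-minutes) pairs."""
    arr = np.asarray(observed, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < min_standards:
        raise CalibrationError(f"need at least {min_standards} calibration standards")
    return IrtRegressor(min_standards=min_standards).fit(arr[:, 0], arr[:, 1])


def predict_rt(model: IrtRegressor, irt: float) -> float:
    return float(model.predict(np.array([irt]))[0])
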