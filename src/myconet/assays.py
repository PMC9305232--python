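"""Copy-number-to-biomass calibration and nutrient-transfer efficiency.

qPCR reports total marker copy numbers per sample; a per-strain linear
regression of dry biomass (mg) on copy number, built from reference
subsamples in the 0.5–5 mg range, converts field measurements to biomass.

Network transfer efficiency for a replicate is the quantum-dot-apatite
fluorescence recovered in the whole focal root divided by the focal
extraradical hyphal biomass, i.e. the sum of fungal biomass in the focal
compartment and focal-strain biomass in the central (fungus-only)
compartment — fluorescence units per mg.  Fluorescence units are relative;
no absolute phosphorus conversion is attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CalibrationModel",
    "CopyNumberCalibration",
    "fit_calibration",
    "copies_to_biomass",
    "transfer_efficiency",
    "EFFICIENCY_COLUMNS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted per-strain linear map from qPCR copy number to dry biomass."""

    strain: str
    slope: float  # mg per copy
    intercept: float  # mg
    r_squared: float
    n_samples: int


class CopyNumberCalibration(RegressorMixin, BaseEstimator):
    """OLS calibration of dry biomass (mg) on qPCR copy number.

    Parameters
    ----------
    fit_intercept : bool
        Free intercept (default) or regression through the origin.

    Attributes
    ----------
    slope_ : float
        mg of biomass per copy.
    intercept_ : float
        mg; 0.0 when ``fit_intercept=False``.
    r_squared_ : float
    n_samples_ : int
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("copy_number and biomass arrays must align")
        if x.size < 2:
            raise ValueError("need >=2 calibration samples")
        if np.ptp(x) == 0:
            raise ValueError("copy numbers are all identical; slope is undefined")
        if np.any(x < 0):
            raise ValueError("copy numbers must be non-negative")
        design = sm.add_constant(x) if self.fit_intercept else x[:, None]
        res = sm.OLS(y, design).fit()
        if self.fit_intercept:
            self.intercept_, self.slope_ = float(res.params[0]), float(res.params[1])
        else:
            self.intercept_, self.slope_ = 0.0, float(res.params[0])
        self.r_squared_ = float(res.rsquared)
        self.n_samples_ = int(x.size)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * x + self.intercept_

    def to_model(self, strain: str = "") -> CalibrationModel:
        return CalibrationModel(strain, self.slope_, self.intercept_, self.r_squared_, self.n_samples_)


def fit_calibration(
    samples: pd.DataFrame,
    per_strain: bool = True,
    fit_intercept: bool = True,
) -> tuple[list[CalibrationModel], dict[str, str]]:
    """Fit biomass ~ copy-number regressions from a calibration table.

    ``samples`` needs columns ``strain``, ``copy_number``, ``biomass_mg``
    (``strain`` optional when ``per_strain=False``).  Groups that cannot be
    fitted (fewer than two samples, zero-variance copy numbers) are reported
    in the returned failure map; the remaining groups are still fitted.
    """
    required = {"copy_number", "biomass_mg"} | ({"strain"} if per_strain else set())
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"calibration table is missing columns: {sorted(missing)}")
    if np.any(samples["biomass_mg"].to_numpy(dtype=float) <= 0):
        raise ValueError("biomass_mg must be positive for calibration samples")

    groups = samples.groupby("strain", sort=True) if per_strain else [("all", samples)]
    models: list[CalibrationModel] = []
    failures: dict[str, str] = {}
    for strain, grp in groups:
        try:
            est = CopyNumberCalibration(fit_intercept=fit_intercept).fit(
                grp["copy_number"], grp["biomass_mg"]
            )
        except ValueError as exc:
            failures[str(strain)] = str(exc)
            logger.warning("calibration for strain %s not fitted: %s", strain, exc)
            continue
        models.append(est.to_model(str(strain)))
    return models, failures


def copies_to_biomass(model: CalibrationModel, copy_number: float | np.ndarray) -> np.ndarray:
    """Predict dry biomass (mg) from copy number; negatives clamp to 0.

    A clamped prediction (possible with a negative fitted intercept at low
    copy numbers) is flagged with a warning.
    """
    copies = np.asarray(copy_number, dtype=float)
    if np.any(copies < 0):
        raise ValueError("copy_number must be non-negative")
    pred = model.slope * copies + model.intercept
    if np.any(pred < 0):
        warnings.warn(
            f"{int(np.sum(pred < 0))} biomass prediction(s) below 0 mg clamped to 0 "
            f"(strain {model.strain or '?'})",
            stacklevel=2,
        )
        pred = np.maximum(pred, 0.0)
    return pred if pred.ndim else float(pred)


EFFICIENCY_COLUMNS = (
    "replicate_id",
    "qd_signal_focal_root",
    "biomass_focal_comp_mg",
    "biomass_focal_in_central_mg",
)


def transfer_efficiency(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate transfer efficiency: QD signal per mg of focal hyphae.

    efficiency = qd_signal_focal_root /
                 (biomass_focal_comp_mg + biomass_focal_in_central_mg)

    Returns ``(result, excluded)``: replicates whose denominator is zero are
    moved to ``excluded`` (with the reason) rather than producing infinities.

    Raises
    ------
    ValueError
        If required columns are missing (named in the message) or any
        biomass component is negative.
    """
    missing = set(EFFICIENCY_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"efficiency table is missing columns: {sorted(missing)}")
    df = records.copy()
    comp = df["biomass_focal_comp_mg"].to_numpy(dtype=float)
    central = df["biomass_focal_in_central_mg"].to_numpy(dtype=float)
    if np.any(comp < 0) or np.any(central < 0):
        raise ValueError("biomass components must be non-negative")
    denom = comp + central
    bad = denom == 0
    excluded = df.loc[bad].copy()
    if bad.any():
        excluded["exclusion_reason"] = "zero focal hyphal biomass (denominator)"
        logger.warning("excluded %d replicate(s) with zero denominator", int(bad.sum()))
    kept = df.loc[~bad].copy()
    kept["efficiency"] = kept["qd_signal_focal_root"].to_numpy(dtype=float) / denom[~bad]
    return kept, excluded
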