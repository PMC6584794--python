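"""Predicted-vs-observed yield agreement statistics.

Model validation compares session yields predicted from topography against
yields measured when the same sessions are machine-"played back" on an
emissions system, over repeated trials.  Agreement is summarised by:

* ``m`` — the slope of the best-fit line through the origin, regressing
  observed on predicted (``m = Σ ŷ·y / Σ ŷ²``).  m → 1 is the ideal 1:1 line.
  Reported as the headline slope because it measures calibration against the
  identity line; the ordinary least-squares slope and intercept are reported
  alongside.
* Pearson's correlation coefficient ``r``.
* ``R²`` — the coefficient of determination of the OLS line with intercept
  (equal to r² for simple linear regression).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .emissions import NicotineMassRatioModel, TpmConcentrationModel
from .errors import DomainError, StructuralError
from .topography import Session
from .yields import predict_session_yield

__all__ = [
    "AgreementReport",
    "compare_yields",
    "run_validation",
    "read_observed_yields",
    "write_observed_yields",
    "OBSERVED_HEADER",
]

OBSERVED_HEADER = ("session_id", "replicate", "y_tpm_mg", "y_nic_mg")


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between predicted and observed yields over n paired trials."""

    slope_through_origin: float
    slope_ols: float
    intercept_ols: float
    pearson_r: float
    r_squared: float
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "m": self.slope_through_origin,
            "slope_ols": self.slope_ols,
            "intercept_ols": self.intercept_ols,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "n_pairs": self.n_pairs,
        }


def compare_yields(
    predicted: Sequence[float] | np.ndarray,
    observed: Sequence[float] | np.ndarray | None = None,
) -> AgreementReport:
    """Agreement statistics for paired (predicted, observed) yields.

    Accepts either two parallel arrays or a single iterable of
    ``(predicted, observed)`` pairs.  Requires at least 3 finite,
    non-negative pairs and non-degenerate predictions (a spread of predicted
    values is needed for a correlation to exist).
    """
    if observed is None:
        pairs = np.asarray(list(predicted), dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise DomainError("expected (n, 2) array of (predicted, observed) pairs")
        pred, obs = pairs[:, 0], pairs[:, 1]
    else:
        pred = np.asarray(predicted, dtype=float).ravel()
        obs = np.asarray(observed, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise DomainError("predicted and observed must have equal length")
    n = pred.size
    if n < 3:
        raise DomainError(f"need at least 3 pairs, got {n}")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(obs))):
        raise DomainError("non-finite yields in comparison")
    if np.any(pred < 0) or np.any(obs < 0):
        raise DomainError("yields must be non-negative")
    if np.ptp(pred) == 0:
        raise DomainError("degenerate comparison: all predicted yields are equal")

    m = float(pred @ obs / (pred @ pred))
    px = pred - pred.mean()
    oy = obs - obs.mean()
    sxx = float(px @ px)
    syy = float(oy @ oy)
    sxy = float(px @ oy)
    slope = sxy / sxx
    intercept = float(obs.mean() - slope * pred.mean())
    if syy == 0:
        r = 0.0  # observed constant: no linear association to measure
        r2 = 0.0
    else:
        r = sxy / np.sqrt(sxx * syy)
        resid = obs - (intercept + slope * pred)
        r2 = 1.0 - float(resid @ resid) / syy
    return AgreementReport(
        slope_through_origin=m,
        slope_ols=float(slope),
        intercept_ols=intercept,
        pearson_r=float(r),
        r_squared=float(r2),
        n_pairs=int(n),
    )


def run_validation(
    sessions: Iterable[Session],
    tpm: TpmConcentrationModel,
    nic: NicotineMassRatioModel | None,
    observed: pd.DataFrame,
) -> tuple[Mapping[str, AgreementReport], pd.DataFrame]:
    """Pair per-session predictions with repeated observed playback yields.

    Predictions are computed once per session (they are deterministic) and
    paired against every observed replicate of that session.  ``observed``
    must have one row per (session_id, replicate) with columns
    ``session_id, replicate, y_tpm_mg[, y_nic_mg]``; sessions without
    observations (or observations without a session) are an error listing
    the gaps.

    Returns ``(reports, table)`` where ``reports`` maps ``"tpm"`` (and
    ``"nic"`` when available on both sides) to an :class:`AgreementReport`,
    and ``table`` is the paired per-trial DataFrame.
    """
    sessions = list(sessions)
    required = {"session_id", "replicate", "y_tpm_mg"}
    if not required <= set(observed.columns):
        raise StructuralError(
            f"observed table missing columns {sorted(required - set(observed.columns))}"
        )
    dup = observed.duplicated(subset=["session_id", "replicate"])
    if dup.any():
        raise StructuralError(
            f"duplicate (session_id, replicate) rows in observed table: "
            f"{observed.loc[dup, ['session_id', 'replicate']].to_records(index=False).tolist()}"
        )

    pred_ids = [s.session_id for s in sessions]
    obs_ids = set(observed["session_id"].astype(str))
    missing_obs = sorted(set(pred_ids) - obs_ids)
    missing_sess = sorted(obs_ids - set(pred_ids))
    if missing_obs or missing_sess:
        raise StructuralError(
            "validation pairing gaps: "
            f"sessions without observations {missing_obs}; "
            f"observations without sessions {missing_sess}"
        )

    predictions = {
        s.session_id: predict_session_yield(s, tpm, nic, per_puff=False) for s in sessions
    }
    table = observed.copy()
    table["session_id"] = table["session_id"].astype(str)
    table["pred_y_tpm_mg"] = table["session_id"].map(
        {k: v.y_tpm for k, v in predictions.items()}
    )
    have_nic = nic is not None and "y_nic_mg" in table.columns and table["y_nic_mg"].notna().all()
    if have_nic:
        table["pred_y_nic_mg"] = table["session_id"].map(
            {k: v.y_nic for k, v in predictions.items()}
        )

    reports: dict[str, AgreementReport] = {
        "tpm": compare_yields(table["pred_y_tpm_mg"], table["y_tpm_mg"])
    }
    if have_nic:
        reports["nic"] = compare_yields(table["pred_y_nic_mg"], table["y_nic_mg"])
    return reports, table


def read_observed_yields(path: str | os.PathLike) -> pd.DataFrame:
    """Read an observed-yield CSV (``session_id,replicate,y_tpm_mg[,y_nic_mg]``)."""
    df = pd.read_csv(path)
    missing = {"session_id", "replicate", "y_tpm_mg"} - set(df.columns)
    if missing:
        raise StructuralError(f"{path}: missing required columns {sorted(missing)}")
    return df


def write_observed_yields(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)
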