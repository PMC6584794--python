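"""Empirical emissions models for an e-cigarette / e-liquid pairing.

Two regressions relate machine-puffed emissions measurements to puffing
behaviour:

* **TPM concentration surface** — the log of the total-particulate-matter
  concentration ``C_TPM`` [mg/mL] is modelled as a quadratic-in-log surface of
  puff flow rate ``q`` [mL/s] and duration ``d`` [s]::

      ln C = b1 + b2·ln(q) + b3·d + b4·(ln q)² + b5·ln(d/1000) + b6·(q·d)

  The ``ln(d/1000)`` regressor is kept literally in that form (rather than the
  mathematically equivalent ``ln d`` with a shifted intercept) so that fitted
  intercepts are comparable with published coefficient tables for this model.

* **Nicotine mass ratio** — the ratio ``f_NIC`` [mg/mg] of nicotine mass to
  TPM mass on the filter pad, modelled as linear in flow rate::

      f = β1 + β2·q

Both are fit by ordinary least squares.  The OLS core here is solved by QR
factorisation (the correlated basis {ln q, (ln q)², q·d} is poorly conditioned
for normal equations) and reports the standard diagnostic set: per-coefficient
standard errors, t statistics and two-sided p values (t distribution, n−p
degrees of freedom), R², adjusted R², and RMSE = √(SSR/(n−p)) on the response
scale.

The estimators follow the scikit-learn protocol (``fit``/``predict``,
fitted attributes with trailing underscores) and compose with sklearn
pipelines; ``fit_tpm_model`` / ``fit_nic_model`` are convenience wrappers
operating directly on :class:`EmissionsTrial` records.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DomainError, SingularDesignError, StructuralError

__all__ = [
    "EmissionsTrial",
    "FitReport",
    "TpmConcentrationModel",
    "NicotineMassRatioModel",
    "tpm_design_row",
    "ols_fit",
    "fit_tpm_model",
    "fit_nic_model",
    "predict_ctpm",
    "predict_fnic",
    "read_trials",
    "write_trials",
    "save_model",
    "load_model",
    "TPM_DESIGN_COLUMNS",
    "TRIALS_HEADER",
]

TPM_DESIGN_COLUMNS = ("intercept", "ln_q", "d", "ln_q_sq", "ln_d_over_1000", "q_d")
NIC_DESIGN_COLUMNS = ("intercept", "q")

TRIALS_HEADER = (
    "condition_id",
    "q_ml_s",
    "d_s",
    "n_puffs",
    "total_volume_ml",
    "tpm_mass_mg",
    "nicotine_mass_mg",
)


@dataclass(frozen=True)
class EmissionsTrial:
    """One machine-puffed emissions trial at a fixed flow condition.

    ``q`` and ``d`` are the observed mean puff flow rate [mL/s] and duration
    [s]; ``total_volume`` [mL] is the cumulative aerosol volume drawn over
    ``n_puffs`` repeated puffs; ``tpm_mass`` [mg] is the particulate mass
    captured on the filter pad, and ``nicotine_mass`` [mg] (optional) the
    nicotine recovered from the same pad.
    """

    condition_id: str
    q: float
    d: float
    n_puffs: int
    total_volume: float
    tpm_mass: float
    nicotine_mass: float | None = None

    def __post_init__(self) -> None:
        if not (self.q > 0 and self.d > 0):
            raise StructuralError(
                f"trial {self.condition_id!r}: q and d must be positive "
                f"(q={self.q!r}, d={self.d!r})"
            )
        if not self.total_volume > 0:
            raise StructuralError(
                f"trial {self.condition_id!r}: total_volume must be positive"
            )
        if self.tpm_mass < 0:
            raise StructuralError(f"trial {self.condition_id!r}: tpm_mass must be >= 0")

    @property
    def c_tpm(self) -> float:
        """Observed TPM concentration, mass on pad per aerosol volume [mg/mL]."""
        return self.tpm_mass / self.total_volume

    @property
    def f_nic(self) -> float | None:
        """Observed nicotine mass ratio [mg/mg], or None when not assayed."""
        if self.nicotine_mass is None:
            return None
        if self.tpm_mass <= 0:
            raise DomainError(
                f"trial {self.condition_id!r}: f_nic undefined with zero TPM mass"
            )
        return self.nicotine_mass / self.tpm_mass


# ---------------------------------------------------------------------------
# OLS with diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitReport:
    """Ordinary-least-squares diagnostic report.

    Per-coefficient estimates, standard errors, t statistics (estimate / SE)
    and two-sided p values from the t distribution with n−p degrees of
    freedom, plus R², adjusted R² and residual RMSE on the response scale.
    ``extra`` carries model-specific additions (e.g. a back-transformed RMSE).
    """

    coef_names: tuple[str, ...]
    estimates: np.ndarray
    std_errors: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    r_squared: float
    adj_r_squared: float
    rmse: float
    n_obs: int
    n_params: int
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table in the conventional Estimate/SE/tStat/pValue layout."""
        return pd.DataFrame(
            {
                "Estimate": self.estimates,
                "Std. Error": self.std_errors,
                "tStat": self.t_stats,
                "pValue": self.p_values,
            },
            index=list(self.coef_names),
        )

    def __str__(self) -> str:
        table = self.to_frame().to_string(float_format=lambda x: f"{x:.6f}")
        lines = [
            table,
            f"R-squared: {self.r_squared:.6f}   Adjusted R-squared: {self.adj_r_squared:.6f}",
            f"RMSE: {self.rmse:.6g}   n_obs: {self.n_obs}   n_params: {self.n_params}",
        ]
        for key, val in self.extra.items():
            lines.append(f"{key}: {val:.6g}" if isinstance(val, float) else f"{key}: {val}")
        return "\n".join(lines)


def adjusted_r_squared(r_squared: float, n_obs: int, n_params: int) -> float:
    """adj R² = 1 − (1 − R²)(n − 1)/(n − p)."""
    if n_obs <= n_params:
        raise DomainError("adjusted R² requires n_obs > n_params")
    return 1.0 - (1.0 - r_squared) * (n_obs - 1) / (n_obs - n_params)


def ols_fit(
    X: np.ndarray,
    y: np.ndarray,
    coef_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, FitReport]:
    """Fit ``y = X b`` by QR-based ordinary least squares with diagnostics.

    Requires more rows than columns and a full-column-rank design; rank
    deficiency raises :class:`SingularDesignError` naming the collinear
    columns.  An exact (zero-residual) fit is handled by reporting zero
    standard errors with infinite t statistics and an ``exact_fit`` flag in
    ``extra`` rather than dividing by zero.

    R² is the centred coefficient of determination, which assumes the model
    spans an intercept (true for both models in this package).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise DomainError("X must be a 2-D design matrix")
    n, p = X.shape
    if y.shape[0] != n:
        raise DomainError(f"X has {n} rows but y has {y.shape[0]} entries")
    if n <= p:
        raise DomainError(f"need more observations than parameters (n={n}, p={p})")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise DomainError("non-finite values in regression inputs")
    if coef_names is None:
        coef_names = tuple(f"x{i}" for i in range(p))
    else:
        coef_names = tuple(coef_names)
        if len(coef_names) != p:
            raise DomainError("coef_names length does not match design columns")

    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    bad = diag <= np.finfo(float).eps * n * scale
    if bad.any():
        names = [coef_names[i] for i in np.flatnonzero(bad)]
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear column(s): {names}"
        )

    beta = linalg.solve_triangular(R, Q.T @ y)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    dof = n - p
    # an exact (interpolating) fit leaves only rounding noise in the residual
    exact = ssr <= (np.finfo(float).eps * n * max(1.0, float(np.linalg.norm(y)))) ** 2
    sigma2 = 0.0 if exact else ssr / dof
    Rinv = linalg.solve_triangular(R, np.eye(p))
    xtx_inv_diag = np.sum(Rinv * Rinv, axis=1)
    se = np.sqrt(sigma2 * xtx_inv_diag)

    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if exact else (1.0 - ssr / sst if sst > 0 else 1.0)
    adj_r2 = adjusted_r_squared(r2, n, p)
    rmse = float(np.sqrt(sigma2))

    extra: dict = {}
    if exact:
        extra["exact_fit"] = True
        t = np.where(beta == 0, 0.0, np.sign(beta) * np.inf)
        pvals = np.zeros(p)
    else:
        t = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    report = FitReport(
        coef_names=coef_names,
        estimates=beta,
        std_errors=se,
        t_stats=t,
        p_values=pvals,
        r_squared=r2,
        adj_r_squared=adj_r2,
        rmse=rmse,
        n_obs=n,
        n_params=p,
        extra=extra,
    )
    return beta, report


# ---------------------------------------------------------------------------
# Design rows
# ---------------------------------------------------------------------------

def tpm_design_row(q, d) -> np.ndarray:
    """Regressor row(s) ``[1, ln q, d, (ln q)², ln(d/1000), q·d]``.

    Natural logarithms throughout; ``q`` in mL/s and ``d`` in seconds, both
    strictly positive.  Scalars give a (6,) vector; equal-length arrays give
    an (n, 6) matrix.
    """
    q = np.asarray(q, dtype=float)
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(q)) or not np.all(np.isfinite(d)):
        raise DomainError("q and d must be finite")
    if np.any(q <= 0) or np.any(d <= 0):
        raise DomainError("q and d must be strictly positive")
    lnq = np.log(q)
    row = np.stack(
        [np.ones_like(lnq), lnq, d, lnq**2, np.log(d / 1000.0), q * d],
        axis=-1,
    )
    return row


def _nic_design(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)) or np.any(q < 0):
        raise DomainError("q must be finite and non-negative")
    return np.stack([np.ones_like(q), q], axis=-1)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class TpmConcentrationModel(RegressorMixin, BaseEstimator):
    """Quadratic-in-log TPM concentration surface Ĉ(q, d), fit by OLS.

    ``fit`` takes ``X`` of shape (n, 2) with columns ``[q, d]`` (mL/s, s) and
    ``y`` the observed concentrations ``C_TPM`` [mg/mL]; the regression is of
    ``ln y`` on the six-term design row, and ``predict`` returns
    ``exp(b · row(q, d))``, which is strictly positive for any valid input.

    Fitted attributes
    -----------------
    coef_ : (6,) ndarray — b1…b6.
    report_ : :class:`FitReport` with RMSE on the ln(mg/mL) scale; the
        back-transformed natural-scale residual RMSE [mg/mL] is in
        ``report_.extra["rmse_natural_scale"]``.
    q_range_, d_range_ : fitted design envelope (min, max); predictions
        outside it are legitimate but flagged as extrapolation by the yield
        layer.
    """

    coef_: np.ndarray
    report_: FitReport
    q_range_: tuple[float, float]
    d_range_: tuple[float, float]
    n_features_in_: int

    def fit(self, X, y):
        q, d = _split_qd(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != q.shape[0]:
            raise DomainError("X and y have different lengths")
        if np.any(y <= 0) or not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~(y > 0) | ~np.isfinite(y))[0])
            raise DomainError(
                f"concentrations must be positive and finite to fit on the ln scale "
                f"(offending observation index {bad})"
            )
        design = tpm_design_row(q, d)
        lny = np.log(y)
        coef, report = ols_fit(design, lny, TPM_DESIGN_COLUMNS)
        fitted_nat = np.exp(design @ coef)
        resid_nat = y - fitted_nat
        dof = report.n_obs - report.n_params
        report.extra["rmse_natural_scale"] = float(np.sqrt(resid_nat @ resid_nat / dof))
        report.extra["response"] = "ln(C_TPM [mg/mL])"
        self.coef_ = coef
        self.report_ = report
        self.q_range_ = (float(q.min()), float(q.max()))
        self.d_range_ = (float(d.min()), float(d.max()))
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted concentration Ĉ_TPM [mg/mL] for rows of (q, d)."""
        self._check_fitted()
        q, d = _split_qd(X)
        return np.exp(tpm_design_row(q, d) @ self.coef_)

    def predict_log(self, X) -> np.ndarray:
        """ln Ĉ_TPM — the regression's response scale."""
        self._check_fitted()
        q, d = _split_qd(X)
        return tpm_design_row(q, d) @ self.coef_

    def predict_one(self, q: float, d: float) -> float:
        """Scalar convenience form of :meth:`predict`."""
        self._check_fitted()
        return float(np.exp(tpm_design_row(q, d) @ self.coef_))

    def in_envelope(self, q, d) -> np.ndarray:
        """True where (q, d) lies inside the fitted design envelope."""
        self._check_fitted()
        q = np.asarray(q, dtype=float)
        d = np.asarray(d, dtype=float)
        if self.q_range_ is None or self.d_range_ is None:
            return np.ones(np.broadcast(q, d).shape, dtype=bool)
        return (
            (q >= self.q_range_[0])
            & (q <= self.q_range_[1])
            & (d >= self.d_range_[0])
            & (d <= self.d_range_[1])
        )

    @classmethod
    def from_coefficients(
        cls,
        b: Sequence[float],
        q_range: tuple[float, float] | None = None,
        d_range: tuple[float, float] | None = None,
    ) -> "TpmConcentrationModel":
        """Build an already-fitted surface from known coefficients b1…b6."""
        b = np.asarray(b, dtype=float)
        if b.shape != (6,):
            raise DomainError(f"expected 6 coefficients, got shape {b.shape}")
        if not np.all(np.isfinite(b)):
            raise DomainError("coefficients must be finite")
        model = cls()
        model.coef_ = b
        model.q_range_ = q_range
        model.d_range_ = d_range
        model.n_features_in_ = 2
        return model

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise StructuralError("model is not fitted; call fit() or from_coefficients()")

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "coef_")


class NicotineMassRatioModel(RegressorMixin, BaseEstimator):
    """Linear nicotine mass-ratio model f̂(q) = β1 + β2·q, fit by OLS.

    ``fit`` takes ``X`` of shape (n, 1) (or (n,)) holding flow rates ``q``
    [mL/s] and ``y`` the observed pad mass ratios ``f_NIC`` [mg/mg].
    Predictions falling outside (0, 1) are physically meaningless and are
    reported via a warning (not clipped).
    """

    coef_: np.ndarray
    report_: FitReport
    n_features_in_: int

    def fit(self, X, y):
        q = _as_flow_column(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != q.shape[0]:
            raise DomainError("X and y have different lengths")
        if not np.all(np.isfinite(y)):
            raise DomainError("non-finite mass ratios in y")
        coef, report = ols_fit(_nic_design(q), y, NIC_DESIGN_COLUMNS)
        report.extra["response"] = "f_NIC [mg/mg]"
        self.coef_ = coef
        self.report_ = report
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted mass ratio f̂_NIC [mg/mg]; warns if outside (0, 1)."""
        self._check_fitted()
        q = _as_flow_column(X)
        f = _nic_design(q) @ self.coef_
        if np.any((f <= 0) | (f >= 1)):
            warnings.warn(
                "predicted nicotine mass ratio outside (0, 1); the linear model is "
                "being evaluated far from its calibration range",
                RuntimeWarning,
                stacklevel=2,
            )
        return f

    def predict_one(self, q: float) -> float:
        return float(self.predict(np.asarray([q]))[0])

    @classmethod
    def from_coefficients(cls, beta: Sequence[float]) -> "NicotineMassRatioModel":
        """Build an already-fitted model from known coefficients (β1, β2)."""
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (2,):
            raise DomainError(f"expected 2 coefficients, got shape {beta.shape}")
        if not np.all(np.isfinite(beta)):
            raise DomainError("coefficients must be finite")
        model = cls()
        model.coef_ = beta
        model.n_features_in_ = 1
        return model

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise StructuralError("model is not fitted; call fit() or from_coefficients()")

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "coef_")


def _split_qd(X) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        if X.shape[0] != 2:
            raise DomainError("1-D X must be a single (q, d) pair")
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != 2:
        raise DomainError(f"X must have two columns (q, d); got shape {X.shape}")
    return X[:, 0], X[:, 1]


def _as_flow_column(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise DomainError(f"X must be a single flow-rate column; got shape {X.shape}")
        X = X[:, 0]
    if X.ndim != 1:
        raise DomainError(f"X must be 1-D or (n, 1); got shape {X.shape}")
    return X


# ---------------------------------------------------------------------------
# Trial-level wrappers
# ---------------------------------------------------------------------------

def fit_tpm_model(
    trials: Iterable[EmissionsTrial],
) -> tuple[TpmConcentrationModel, FitReport]:
    """Fit the TPM surface to a table of emissions trials.

    Regresses ln(C_TPM) = ln(tpm_mass / total_volume) on the six-term design
    row at each trial's (q, d).  Requires at least 7 trials and positive
    concentrations; a trial with non-positive TPM mass is named in the error.
    """
    trials = list(trials)
    if len(trials) < 7:
        raise DomainError(
            f"need at least 7 trials to fit the 6-parameter surface, got {len(trials)}"
        )
    for t in trials:
        if t.tpm_mass <= 0:
            raise DomainError(
                f"trial {t.condition_id!r}: non-positive TPM mass; cannot fit ln C"
            )
    X = np.array([[t.q, t.d] for t in trials])
    y = np.array([t.c_tpm for t in trials])
    model = TpmConcentrationModel().fit(X, y)
    return model, model.report_


def fit_nic_model(
    trials: Iterable[EmissionsTrial],
) -> tuple[NicotineMassRatioModel, FitReport]:
    """Fit the nicotine mass-ratio line to trials that carry a nicotine assay.

    Only trials with ``nicotine_mass`` present enter the regression (in the
    reference protocol these are the constant-puff-volume screening trials).
    Requires at least 3 such trials.
    """
    assayed = [t for t in trials if t.nicotine_mass is not None]
    if len(assayed) < 3:
        raise DomainError(
            f"need at least 3 trials with nicotine mass to fit f_NIC, got {len(assayed)}"
        )
    q = np.array([t.q for t in assayed])
    f = np.array([t.f_nic for t in assayed])
    model = NicotineMassRatioModel().fit(q, f)
    return model, model.report_


def predict_ctpm(model: TpmConcentrationModel, q: float, d: float) -> float:
    """Ĉ_TPM(q, d) [mg/mL] — scalar wrapper over :meth:`TpmConcentrationModel.predict`."""
    return model.predict_one(q, d)


def predict_fnic(model: NicotineMassRatioModel, q: float) -> float:
    """f̂_NIC(q) [mg/mg] — scalar wrapper over :meth:`NicotineMassRatioModel.predict`."""
    return model.predict_one(q)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trials(path: str | os.PathLike) -> list[EmissionsTrial]:
    """Read an emissions-trial CSV (see :data:`TRIALS_HEADER` for the dialect)."""
    df = pd.read_csv(path)
    missing = set(TRIALS_HEADER[:-1]) - set(df.columns)
    if missing:
        raise StructuralError(f"{path}: missing required columns {sorted(missing)}")
    has_nic = "nicotine_mass_mg" in df.columns
    trials = []
    for _, row in df.iterrows():
        nic = row["nicotine_mass_mg"] if has_nic else None
        if nic is not None and pd.isna(nic):
            nic = None
        trials.append(
            EmissionsTrial(
                condition_id=str(row["condition_id"]),
                q=float(row["q_ml_s"]),
                d=float(row["d_s"]),
                n_puffs=int(row["n_puffs"]),
                total_volume=float(row["total_volume_ml"]),
                tpm_mass=float(row["tpm_mass_mg"]),
                nicotine_mass=None if nic is None else float(nic),
            )
        )
    return trials


def write_trials(trials: Iterable[EmissionsTrial], path: str | os.PathLike) -> None:
    """Write emissions trials in the canonical CSV dialect."""
    df = pd.DataFrame(
        [
            {
                "condition_id": t.condition_id,
                "q_ml_s": t.q,
                "d_s": t.d,
                "n_puffs": t.n_puffs,
                "total_volume_ml": t.total_volume,
                "tpm_mass_mg": t.tpm_mass,
                "nicotine_mass_mg": t.nicotine_mass,
            }
            for t in trials
        ],
        columns=list(TRIALS_HEADER),
    )
    df.to_csv(path, index=False)


def save_model(
    path: str | os.PathLike,
    tpm: TpmConcentrationModel,
    nic: NicotineMassRatioModel | None = None,
    meta: dict | None = None,
) -> None:
    """Serialise fitted models to the package's JSON model format."""
    payload: dict = {"tpm": {"b": np.asarray(tpm.coef_).tolist()}}
    if getattr(tpm, "q_range_", None) is not None:
        payload["tpm"]["q_range"] = list(tpm.q_range_)
    if getattr(tpm, "d_range_", None) is not None:
        payload["tpm"]["d_range"] = list(tpm.d_range_)
    if nic is not None:
        payload["nic"] = {"beta": np.asarray(nic.coef_).tolist()}
    payload["meta"] = meta or {}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_model(
    path: str | os.PathLike,
) -> tuple[TpmConcentrationModel, NicotineMassRatioModel | None, dict]:
    """Load a model JSON written by :func:`save_model` (or the packaged reference)."""
    with open(path) as fh:
        payload = json.load(fh)
    if "tpm" not in payload or "b" not in payload["tpm"]:
        raise StructuralError(f"{path}: model JSON lacks tpm coefficients")
    tpm_block = payload["tpm"]
    tpm = TpmConcentrationModel.from_coefficients(
        tpm_block["b"],
        q_range=tuple(tpm_block["q_range"]) if "q_range" in tpm_block else None,
        d_range=tuple(tpm_block["d_range"]) if "d_range" in tpm_block else None,
    )
    nic = None
    if "nic" in payload and payload["nic"] is not None:
        nic = NicotineMassRatioModel.from_coefficients(payload["nic"]["beta"])
    return tpm, nic, payload.get("meta", {})
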