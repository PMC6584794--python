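"""Synthetic data generators for every stage of the pipeline.

Three generators mirror the laboratory workflow the emissions models assume,
so the whole pipeline can be exercised end-to-end from a single seed:

* :func:`generate_design` — a design of experiments for machine-puffed
  emissions trials: a *screening* arm in which flow rate and duration vary
  inversely at nominally constant puff volume, plus a *full* grid spanning
  the (q, d) envelope.  Defaults: 34 conditions (10 screening + 24 grid),
  6 replicate trials each, session volumes targeted at 740 mL within
  [522, 1000] mL.
* :func:`simulate_emissions` — inverts the emissions models as the
  data-generating process: ln C_TPM ~ Normal(surface, σ_ln) per trial, and a
  truncated-normal nicotine mass ratio on the screening trials (nicotine is
  assayed only on the screening arm, as in the reference protocol).
* :func:`simulate_session` — a heterogeneous puffing session: lognormal puff
  durations, flow rates and inter-puff intervals, rendered to a flow trace as
  smoothed trapezoid pulses, returned together with the ground-truth session.
* :func:`simulate_observed_yields` — stands in for playback measurements:
  observed yield = predicted yield × lognormal multiplicative noise.

Lognormal puff-metric distributions are a stand-in: the empirical family of
natural-environment durations and flows is not established, but the metrics
are positive and right-skewed, which the lognormal captures.

Reproducibility: every generator derives its bit stream from a root seed via
a component-specific spawn key, so the same seed can drive independent stages
without their streams colliding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .emissions import EmissionsTrial, NicotineMassRatioModel, TpmConcentrationModel
from .errors import DomainError
from .topography import FlowTrace, Puff, Session

__all__ = [
    "DesignSpec",
    "DesignCondition",
    "SessionSpec",
    "generate_design",
    "design_to_frame",
    "simulate_emissions",
    "simulate_session",
    "simulate_observed_yields",
    "session_spec_from_targets",
    "EXEMPLAR_SESSION_TARGETS",
]

# Component spawn keys for seed fan-out.
_KEY_EMISSIONS = 1
_KEY_SESSION = 2
_KEY_OBSERVED = 3


def _rng(seed: int | None, key: int) -> np.random.Generator:
    """Substream generator: one root seed, independent per-component streams."""
    ss = np.random.SeedSequence(entropy=0 if seed is None else int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Emissions design of experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Design of experiments for machine-puffed emissions trials.

    The default envelope — q in [12, 65] mL/s, d in [1.0, 4.4] s — spans the
    session-mean behaviour observed for vape-pen users in the natural
    environment; the screening arm holds puff volume at ~55 mL, a typical
    single-draw volume in that envelope.  ``target_session_volume`` sets the
    per-trial cumulative aerosol volume (the number of repeated puffs per
    trial is chosen to approach it within ``session_volume_range``).
    """

    n_conditions: int = 34
    reps_per_condition: int = 6
    q_range: tuple[float, float] = (12.0, 65.0)
    d_range: tuple[float, float] = (1.0, 4.4)
    target_session_volume: float = 740.0
    session_volume_range: tuple[float, float] = (522.0, 1000.0)
    screening_fraction: float = 10 / 34
    screening_puff_volume: float = 55.0

    def __post_init__(self) -> None:
        if self.n_conditions < 2 or self.reps_per_condition < 1:
            raise DomainError("need at least 2 conditions and 1 rep")
        if not (0 < self.q_range[0] < self.q_range[1]):
            raise DomainError(f"invalid q_range {self.q_range}")
        if not (0 < self.d_range[0] < self.d_range[1]):
            raise DomainError(f"invalid d_range {self.d_range}")
        if not (0 <= self.screening_fraction <= 1):
            raise DomainError("screening_fraction must be in [0, 1]")
        lo, hi = self.session_volume_range
        if not (0 < lo <= self.target_session_volume <= hi):
            raise DomainError("target_session_volume must lie in session_volume_range")

    @property
    def n_screening(self) -> int:
        return int(round(self.n_conditions * self.screening_fraction))


@dataclass(frozen=True)
class DesignCondition:
    """One flow condition: (q, d) and the repeated-puff count per trial."""

    condition_id: str
    q: float
    d: float
    n_puffs: int
    screening: bool

    @property
    def session_volume(self) -> float:
        """Cumulative aerosol volume per trial [mL] = n_puffs · q · d."""
        return self.n_puffs * self.q * self.d


def generate_design(
    spec: DesignSpec | None = None, seed: int | None = None
) -> list[DesignCondition]:
    """Lay out the emissions design of experiments.

    The screening arm places conditions log-uniformly in q with
    ``d = screening_puff_volume / q`` (constant puff volume by construction);
    the full arm is a regular q × d grid.  ``seed`` is accepted for interface
    symmetry with the stochastic generators but the default layout is
    deterministic.  Raises if no repeated-puff count can land the trial
    volume inside ``session_volume_range``.
    """
    spec = spec or DesignSpec()
    n_s = spec.n_screening
    n_f = spec.n_conditions - n_s
    conditions: list[DesignCondition] = []

    if n_s:
        v0 = spec.screening_puff_volume
        q_lo = max(spec.q_range[0], v0 / spec.d_range[1])
        q_hi = min(spec.q_range[1], v0 / spec.d_range[0])
        if not q_lo < q_hi:
            raise DomainError(
                "screening arm infeasible: constant puff volume "
                f"{v0} mL does not fit inside the (q, d) envelope"
            )
        for i, q in enumerate(np.geomspace(q_lo, q_hi, n_s), start=1):
            d = v0 / q
            conditions.append(
                DesignCondition(
                    condition_id=f"S{i:02d}",
                    q=float(q),
                    d=float(d),
                    n_puffs=_choose_n_puffs(q * d, spec),
                    screening=True,
                )
            )

    if n_f:
        n_d = max(1, int(math.floor(math.sqrt(n_f))))
        while n_f % n_d:
            n_d -= 1
        n_q = n_f // n_d
        qs = np.linspace(spec.q_range[0], spec.q_range[1], n_q)
        ds = np.linspace(spec.d_range[0], spec.d_range[1], n_d)
        i = 1
        for d in ds:
            for q in qs:
                conditions.append(
                    DesignCondition(
                        condition_id=f"F{i:02d}",
                        q=float(q),
                        d=float(d),
                        n_puffs=_choose_n_puffs(q * d, spec),
                        screening=False,
                    )
                )
                i += 1
    return conditions


def _choose_n_puffs(puff_volume: float, spec: DesignSpec) -> int:
    """Repeated-puff count bringing n·v closest to the target session volume."""
    lo, hi = spec.session_volume_range
    n_max = int(math.ceil(hi / puff_volume))
    best = None
    for n in range(1, n_max + 1):
        vol = n * puff_volume
        if lo <= vol <= hi:
            err = abs(vol - spec.target_session_volume)
            if best is None or err < best[0]:
                best = (err, n)
    if best is None:
        raise DomainError(
            f"no repeated-puff count lands a {puff_volume:g} mL puff inside "
            f"the session volume range [{lo:g}, {hi:g}] mL"
        )
    return best[1]


def design_to_frame(conditions: Iterable[DesignCondition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition_id": c.condition_id,
                "q_ml_s": c.q,
                "d_s": c.d,
                "n_puffs": c.n_puffs,
                "session_volume_ml": c.session_volume,
                "screening": c.screening,
            }
            for c in conditions
        ]
    )


def simulate_emissions(
    conditions: Sequence[DesignCondition],
    tpm: TpmConcentrationModel,
    nic: NicotineMassRatioModel | None = None,
    noise_ln_sd: float = 0.15,
    noise_f_sd: float = 0.0025,
    n_reps: int = 6,
    seed: int | None = 0,
    nicotine_on: str = "screening",
) -> list[EmissionsTrial]:
    """Generate replicate emissions trials from the models' own surfaces.

    Per trial: ``ln C ~ Normal(ln Ĉ(q, d), noise_ln_sd)``, TPM mass =
    C × session volume; on nicotine-assayed trials the pad mass ratio is
    drawn truncated-normal on (0, 1) around f̂(q) with sd ``noise_f_sd`` and
    nicotine mass = f × TPM mass.  ``nicotine_on`` selects which trials carry
    the assay: ``"screening"`` (default, matching the reference protocol),
    ``"all"`` or ``"none"``.  Deterministic per (conditions, seed).
    """
    if noise_ln_sd < 0 or noise_f_sd < 0:
        raise DomainError("noise scales must be non-negative")
    if nicotine_on not in ("screening", "all", "none"):
        raise DomainError(f"nicotine_on must be screening/all/none, got {nicotine_on!r}")
    rng = _rng(seed, _KEY_EMISSIONS)
    trials: list[EmissionsTrial] = []
    for cond in conditions:
        ln_mean = float(np.log(tpm.predict_one(cond.q, cond.d)))
        f_mean = nic.predict_one(cond.q) if nic is not None else None
        for rep in range(1, n_reps + 1):
            ln_c = rng.normal(ln_mean, noise_ln_sd) if noise_ln_sd else ln_mean
            volume = cond.session_volume
            tpm_mass = math.exp(ln_c) * volume
            nic_mass = None
            assay = nicotine_on == "all" or (nicotine_on == "screening" and cond.screening)
            if assay and f_mean is not None:
                if noise_f_sd:
                    a, b = (0.0 - f_mean) / noise_f_sd, (1.0 - f_mean) / noise_f_sd
                    f = float(
                        stats.truncnorm.rvs(a, b, loc=f_mean, scale=noise_f_sd, random_state=rng)
                    )
                else:
                    f = f_mean
                nic_mass = f * tpm_mass
            trials.append(
                EmissionsTrial(
                    condition_id=f"{cond.condition_id}-r{rep}",
                    q=cond.q,
                    d=cond.d,
                    n_puffs=cond.n_puffs,
                    total_volume=volume,
                    tpm_mass=tpm_mass,
                    nicotine_mass=nic_mass,
                )
            )
    return trials


# ---------------------------------------------------------------------------
# Topography sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionSpec:
    """Distributional spec for one heterogeneous puffing session.

    ``duration_dist``, ``flow_dist`` and ``interval_dist`` are (mean, sigma)
    parameters of lognormal distributions *in log space*; use
    :func:`session_spec_from_targets` to build a spec from natural-scale
    session means.  ``sampling_rate`` [Hz] and ``rise_time`` [s] control the
    rendered trace: each puff is a symmetric trapezoid pulse whose area
    equals the puff volume exactly.
    """

    n_puffs: int = 12
    duration_dist: tuple[float, float] = (math.log(2.0), 0.30)
    flow_dist: tuple[float, float] = (math.log(30.0), 0.30)
    interval_dist: tuple[float, float] = (math.log(20.0), 0.50)
    sampling_rate: float = 100.0
    rise_time: float = 0.1
    session_id: str = "SYN"
    participant_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_puffs < 1:
            raise DomainError("a session needs at least one puff")
        for name in ("duration_dist", "flow_dist", "interval_dist"):
            mu, sd = getattr(self, name)
            if not (np.isfinite(mu) and sd >= 0):
                raise DomainError(f"invalid {name}: {(mu, sd)}")
        if self.sampling_rate <= 0 or self.rise_time < 0:
            raise DomainError("sampling_rate must be positive and rise_time >= 0")


def session_spec_from_targets(
    mean_duration: float,
    mean_flow: float,
    total_volume: float,
    cv: float = 0.25,
    session_id: str = "SYN",
    participant_id: str = "",
    seed: int | None = None,
) -> SessionSpec:
    """Build a :class:`SessionSpec` whose draws match natural-scale session means.

    The puff count is ``round(total_volume / (mean_duration × mean_flow))``
    and each lognormal is parameterised so its *mean* (not median) equals the
    target, with coefficient of variation ``cv``.
    """
    if min(mean_duration, mean_flow, total_volume) <= 0:
        raise DomainError("session targets must be positive")
    n = max(1, int(round(total_volume / (mean_duration * mean_flow))))
    sigma = math.sqrt(math.log(1 + cv**2))

    def _params(mean: float) -> tuple[float, float]:
        return (math.log(mean) - sigma**2 / 2, sigma)

    return SessionSpec(
        n_puffs=n,
        duration_dist=_params(mean_duration),
        flow_dist=_params(mean_flow),
        interval_dist=_params(20.0),
        session_id=session_id,
        participant_id=participant_id,
        seed=seed,
    )


#: Seven exemplar natural-environment session profiles used as generator
#: targets: (mean puff duration [s], mean puff flow [mL/s], session volume
#: [mL]).  These are synthetic stand-ins patterned on published exemplar
#: vape-pen sessions; the printed source table is typographically ambiguous,
#: so the values adopted here are representative of the behaviour range, not
#: authoritative measurements.
EXEMPLAR_SESSION_TARGETS: dict[str, tuple[float, float, float]] = {
    "OS3-01": (1.2, 50.6, 1007.0),
    "OS3-06": (1.2, 18.4, 830.0),
    "OS3-10": (3.0, 16.1, 503.0),
    "OS3-12": (1.2, 30.8, 1004.0),
    "OS3-14": (1.2, 16.7, 748.0),
    "OS3-26": (2.3, 30.4, 605.0),
    "OS3-28": (4.4, 62.6, 360.0),
}


def exemplar_session_specs(cv: float = 0.2) -> list[SessionSpec]:
    """Specs for the seven exemplar validation sessions."""
    return [
        session_spec_from_targets(d, q, v, cv=cv, session_id=sid, participant_id=sid.split("-")[1])
        for sid, (d, q, v) in EXEMPLAR_SESSION_TARGETS.items()
    ]


def simulate_session(
    spec: SessionSpec | None = None, seed: int | None = None
) -> tuple[Session, FlowTrace]:
    """Draw a heterogeneous session and render it as a sampled flow trace.

    Puff durations, flow rates and inter-puff intervals are lognormal draws
    (durations floored at 0.3 s and grid-aligned; flows floored at 2 mL/s so
    every puff clears the default detection threshold; intervals floored at
    1 s, so consecutive pulses can never overlap).  Each puff is rendered as
    a symmetric trapezoid with rise/fall ``spec.rise_time`` whose plateau is
    scaled so the pulse area equals the puff volume q·d exactly; pulse
    breakpoints are aligned to the sampling grid so trapezoidal integration
    of the rendered trace is exact.

    Returns the ground-truth :class:`Session` and the rendered
    :class:`FlowTrace` (1 s of quiet lead-in/lead-out).
    """
    spec = spec or SessionSpec()
    if seed is None:
        seed = spec.seed
    rng = _rng(seed, _KEY_SESSION)
    dt = 1.0 / spec.sampling_rate
    rise = round(spec.rise_time / dt) * dt

    mu_d, sd_d = spec.duration_dist
    mu_q, sd_q = spec.flow_dist
    mu_i, sd_i = spec.interval_dist
    n = spec.n_puffs
    d = np.maximum(rng.lognormal(mu_d, sd_d, n), max(0.3, 2 * rise + 2 * dt))
    d = np.round(d / dt) * dt
    q = np.maximum(rng.lognormal(mu_q, sd_q, n), 2.0)
    gaps = np.maximum(rng.lognormal(mu_i, sd_i, n - 1), 1.0) if n > 1 else np.array([])

    starts = np.empty(n)
    t = 1.0
    for i in range(n):
        starts[i] = round(t / dt) * dt
        t = starts[i] + d[i] + (gaps[i] if i < n - 1 else 0.0)

    total_t = starts[-1] + d[-1] + 1.0
    time = np.arange(0.0, total_t + dt / 2, dt)
    flow = np.zeros_like(time)
    for s, di, qi in zip(starts, d, q):
        h = qi * di / (di - rise) if di > rise else qi
        # breakpoints of the trapezoid, all on the sampling grid
        tp = np.array([s, s + rise, s + di - rise, s + di])
        fp = np.array([0.0, h, h, 0.0])
        i0 = int(round(s / dt))
        i1 = int(round((s + di) / dt))
        seg = np.interp(time[i0 : i1 + 1], tp, fp)
        flow[i0 : i1 + 1] = np.maximum(flow[i0 : i1 + 1], seg)

    puffs = tuple(
        Puff(start=float(s), duration=float(di), volume=float(qi * di))
        for s, di, qi in zip(starts, d, q)
    )
    session = Session(
        puffs=puffs, session_id=spec.session_id, participant_id=spec.participant_id
    )
    trace = FlowTrace(
        time,
        flow,
        meta={
            "session_id": spec.session_id,
            "participant_id": spec.participant_id,
            "sampling_rate_hz": spec.sampling_rate,
        },
    )
    return session, trace


# ---------------------------------------------------------------------------
# Observed playback yields
# ---------------------------------------------------------------------------

def simulate_observed_yields(
    sessions: Sequence[Session],
    tpm: TpmConcentrationModel,
    nic: NicotineMassRatioModel | None = None,
    n_reps: int = 6,
    obs_noise_cv: float = 0.2,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Replicate "playback" yield measurements around model predictions.

    For each session and replicate, observed = predicted × LogNormal(0, cv),
    with independent multipliers for the TPM and nicotine channels (the two
    are measured by different assays).  ``cv = 0`` reproduces the predictions
    exactly.
    """
    if obs_noise_cv < 0:
        raise DomainError("obs_noise_cv must be >= 0")
    from .yields import predict_session_yield  # local import: avoids cycle

    rng = _rng(seed, _KEY_OBSERVED)
    rows = []
    for session in sessions:
        sy = predict_session_yield(session, tpm, nic, per_puff=False)
        for rep in range(1, n_reps + 1):
            mult_t = rng.lognormal(0.0, obs_noise_cv) if obs_noise_cv else 1.0
            mult_n = rng.lognormal(0.0, obs_noise_cv) if obs_noise_cv else 1.0
            rows.append(
                {
                    "session_id": session.session_id,
                    "replicate": rep,
                    "y_tpm_mg": sy.y_tpm * mult_t,
                    "y_nic_mg": sy.y_nic * mult_n if sy.y_nic is not None else None,
                }
            )
    return pd.DataFrame(rows, columns=["session_id", "replicate", "y_tpm_mg", "y_nic_mg"])
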