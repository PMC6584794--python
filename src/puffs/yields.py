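"""Per-session yield prediction: mass delivered to the mouth over a session.

The continuous-time definition of a constituent yield is the integral of
(mass ratio × TPM concentration × flow rate) over the session.  Because the
emissions models are calibrated per puff at a puff's mean flow rate ``q`` and
duration ``d``, the integral is discretised puff-by-puff, holding Ĉ and f̂
constant within a puff::

    Ŷ_TPM = Σ_n Ĉ(q_n, d_n) · v_n
    Ŷ_NIC = Σ_n f̂(q_n) · Ĉ(q_n, d_n) · v_n

with ``v_n = q_n·d_n`` the puff volume.  Two entry points are provided:
:func:`predict_session_yield` for already-detected puffs, and
:func:`integrate_yield_trace` which runs puff detection on a raw flow trace
first — the two agree exactly on traces whose puffs are cleanly detected.

Puffs falling outside the model's fitted (q, d) design envelope are still
evaluated but flagged as extrapolations in the per-puff breakdown.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .emissions import NicotineMassRatioModel, TpmConcentrationModel
from .errors import DomainError
from .topography import (
    DEFAULT_MIN_DURATION,
    DEFAULT_MIN_GAP,
    DEFAULT_THRESHOLD,
    FlowTrace,
    Session,
    detect_puffs,
)

__all__ = ["PuffYield", "SessionYield", "predict_session_yield", "integrate_yield_trace"]


@dataclass(frozen=True)
class PuffYield:
    """Per-puff model evaluation: inputs, predictions, and mass contributions."""

    index: int
    q: float
    d: float
    volume: float
    c_tpm: float
    f_nic: float | None
    tpm_mg: float
    nic_mg: float | None
    extrapolated: bool


@dataclass(frozen=True)
class SessionYield:
    """Predicted (or observed) session totals: Y_TPM and Y_NIC in mg."""

    y_tpm: float
    y_nic: float | None
    session_id: str = ""
    per_puff: tuple[PuffYield, ...] | None = None
    n_extrapolated: int = 0

    def to_dict(self) -> dict:
        out = {
            "session_id": self.session_id,
            "y_tpm_mg": self.y_tpm,
            "y_nic_mg": self.y_nic,
            "n_extrapolated": self.n_extrapolated,
        }
        if self.per_puff is not None:
            out["per_puff"] = [
                {
                    "index": p.index,
                    "q_ml_s": p.q,
                    "d_s": p.d,
                    "volume_ml": p.volume,
                    "c_tpm_mg_ml": p.c_tpm,
                    "f_nic_mg_mg": p.f_nic,
                    "tpm_mg": p.tpm_mg,
                    "nic_mg": p.nic_mg,
                    "extrapolated": p.extrapolated,
                }
                for p in self.per_puff
            ]
        return out

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def predict_session_yield(
    session: Session,
    tpm: TpmConcentrationModel,
    nic: NicotineMassRatioModel | None = None,
    per_puff: bool = True,
) -> SessionYield:
    """Sum per-puff TPM (and optionally nicotine) contributions over a session.

    Each puff contributes Ĉ(q, d)·v mg of TPM and f̂(q)·Ĉ(q, d)·v mg of
    nicotine.  A domain failure in model evaluation is re-raised naming the
    offending puff.  ``y_nic`` is None when no nicotine model is supplied.
    """
    rows: list[PuffYield] = []
    y_tpm = 0.0
    y_nic = 0.0 if nic is not None else None
    n_extrap = 0
    for i, p in enumerate(session.puffs):
        try:
            c = tpm.predict_one(p.mean_flow, p.duration)
            f = nic.predict_one(p.mean_flow) if nic is not None else None
        except DomainError as exc:
            raise DomainError(
                f"session {session.session_id!r}, puff {i} "
                f"(q={p.mean_flow:g}, d={p.duration:g}): {exc}"
            ) from None
        extrap = not bool(np.all(tpm.in_envelope(p.mean_flow, p.duration)))
        n_extrap += extrap
        tpm_mg = c * p.volume
        nic_mg = f * tpm_mg if f is not None else None
        y_tpm += tpm_mg
        if nic_mg is not None:
            y_nic += nic_mg
        if per_puff:
            rows.append(
                PuffYield(
                    index=i,
                    q=p.mean_flow,
                    d=p.duration,
                    volume=p.volume,
                    c_tpm=c,
                    f_nic=f,
                    tpm_mg=tpm_mg,
                    nic_mg=nic_mg,
                    extrapolated=extrap,
                )
            )
    return SessionYield(
        y_tpm=y_tpm,
        y_nic=y_nic,
        session_id=session.session_id,
        per_puff=tuple(rows) if per_puff else None,
        n_extrapolated=n_extrap,
    )


def integrate_yield_trace(
    trace: FlowTrace,
    tpm: TpmConcentrationModel,
    nic: NicotineMassRatioModel | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    min_duration: float = DEFAULT_MIN_DURATION,
    min_gap: float = DEFAULT_MIN_GAP,
    per_puff: bool = True,
) -> SessionYield:
    """Detect puffs in a raw trace, then evaluate the per-puff yield sums.

    A trace with no detectable puffs (e.g. all-zero flow) yields zero mass.
    """
    puffs = detect_puffs(trace, threshold=threshold, min_duration=min_duration, min_gap=min_gap)
    session_id = str(trace.meta.get("session_id", ""))
    if not puffs:
        return SessionYield(
            y_tpm=0.0,
            y_nic=0.0 if nic is not None else None,
            session_id=session_id,
            per_puff=() if per_puff else None,
        )
    session = Session(
        puffs=tuple(puffs),
        session_id=session_id,
        participant_id=str(trace.meta.get("participant_id", "")),
    )
    return predict_session_yield(session, tpm, nic, per_puff=per_puff)
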