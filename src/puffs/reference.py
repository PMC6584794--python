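"""Packaged reference emissions model.

The package ships one fitted coefficient set — a TPM concentration surface
and a nicotine mass-ratio line for a specific pen-style e-cigarette and
tobacco-flavoured e-liquid (1.8% nicotine, 50:50 PG/VG) — so yield prediction
works out of the box.  The coefficients are device- and consumable-specific:
they characterise that pairing only and must be refit for any other product.

The JSON payload is checksum-verified on load to guard against a corrupted
installation.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

from .emissions import NicotineMassRatioModel, TpmConcentrationModel
from .errors import StructuralError

__all__ = ["load_reference_model", "load_reference_info", "REFERENCE_SHA256"]

_RESOURCE = "reference_model.json"
REFERENCE_SHA256 = "2ceb25bf6f4b6ebacd9fdaa33d8778aa0b101008b0e6e1689c069895fab8fc60"


def _read_bytes() -> bytes:
    return resources.files("puffs.data").joinpath(_RESOURCE).read_bytes()


def load_reference_info() -> dict:
    """Full reference payload: coefficients, printed diagnostics, metadata."""
    raw = _read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != REFERENCE_SHA256:
        raise StructuralError(
            f"packaged reference model is corrupted: sha256 {digest} != {REFERENCE_SHA256}"
        )
    return json.loads(raw)


def load_reference_model() -> tuple[TpmConcentrationModel, NicotineMassRatioModel]:
    """The packaged TPM surface and nicotine mass-ratio models, ready to predict."""
    payload = load_reference_info()
    tpm = TpmConcentrationModel.from_coefficients(
        payload["tpm"]["b"],
        q_range=tuple(payload["tpm"]["q_range"]),
        d_range=tuple(payload["tpm"]["d_range"]),
    )
    nic = NicotineMassRatioModel.from_coefficients(payload["nic"]["beta"])
    return tpm, nic
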