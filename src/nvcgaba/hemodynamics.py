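"""Balloon hemodynamics: radius -> blood flow -> HbR/HbT/HbO traces.

The arteriolar radius trace is converted to normalized cerebral blood flow
by a Poiseuille closure (flow ~ radius^4) and fed into the classic venous
balloon model (normalized volume v and deoxyhemoglobin content q, both 1 at
baseline). Fractional hemoglobin changes are then:

* d_hbr = q - 1
* d_hbt from the flow closure (CBF * HbR / CMRO, normalized so the baseline
  change is zero), or optionally the standard balloon volume closure v - 1
* d_hbo = d_hbt - d_hbr, enforcing HbT = HbO + HbR exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrationFailureError, InvalidParameterError
from .params import BalloonParams

__all__ = [
    "BalloonState",
    "HemoTrace",
    "cbf_from_radius",
    "oxygen_extraction",
    "balloon_rhs",
    "cmro_from_activity",
    "hb_outputs",
]


@dataclass
class BalloonState:
    """Normalized venous blood volume and deoxyhemoglobin content (1,1 at rest)."""

    volume: float
    dhb: float


@dataclass
class HemoTrace:
    """Simulated hemoglobin trace: fractional changes on a uniform time grid."""

    t: np.ndarray  # ms
    d_hbo: np.ndarray
    d_hbr: np.ndarray
    d_hbt: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_ms": self.t, "d_hbo": self.d_hbo,
            "d_hbr": self.d_hbr, "d_hbt": self.d_hbt,
        })

    def to_csv(self, path: str | Path, metadata: dict | None = None) -> None:
        """Write the trace as CSV; optional JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if metadata is not None:
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(metadata, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "HemoTrace":
        df = pd.read_csv(path)
        return cls(t=df["t_ms"].to_numpy(float),
                   d_hbo=df["d_hbo"].to_numpy(float),
                   d_hbr=df["d_hbr"].to_numpy(float),
                   d_hbt=df["d_hbt"].to_numpy(float))


def cbf_from_radius(radius: float | np.ndarray) -> float | np.ndarray:
    """Normalized blood flow from the radius ratio (Poiseuille: radius^4)."""
    return radius ** 4


def oxygen_extraction(f_in: float, e0: float) -> float:
    """Flow-dependent O2 extraction fraction E(f) = 1 - (1 - E0)^(1/f)."""
    return 1.0 - (1.0 - e0) ** (1.0 / f_in)


def balloon_rhs(b: BalloonState, f_in: float, p: BalloonParams) -> tuple[float, float]:
    """Time derivatives (dv/dt, dq/dt) of the venous balloon, per ms.

    Outflow follows the Grubb power law f_out = v**(1/alpha_g); the
    deoxyhemoglobin balance uses the flow-dependent extraction fraction.
    (1, 1) is a fixed point at baseline inflow 1.
    """
    if b.volume <= 0:
        raise IntegrationFailureError(
            "balloon volume became non-positive",
            state_dump={"volume": b.volume, "dhb": b.dhb, "f_in": f_in})
    f_out = b.volume ** (1.0 / p.alpha_g)
    dv = (f_in - f_out) / p.tau
    dq = (f_in * oxygen_extraction(f_in, p.e0) / p.e0
          - b.dhb * f_out / b.volume) / p.tau
    return dv, dq


def cmro_from_activity(activity: float, gain: float) -> float:
    """Normalized metabolic rate: 1 + gain * activity (activity is the
    stimulus indicator smoothed by a first-order lag)."""
    if activity < 0:
        raise InvalidParameterError("activity must be >= 0")
    return 1.0 + gain * activity


def hb_outputs(q, cbf, cmro, closure: str = "flow", volume=None):
    """Fractional hemoglobin changes from balloon state and flow.

    Works elementwise on arrays. ``d_hbr = q - 1``; total hemoglobin uses
    either the flow closure ``cbf*q/cmro - 1`` (default) or the balloon
    volume closure ``volume - 1``. HbO is defined by conservation and the
    returned d_hbt is re-derived as ``d_hbo + d_hbr`` so the identity
    HbT = HbO + HbR holds bit-exactly on every sample.

    Returns ``(d_hbr, d_hbt, d_hbo)``.
    """
    q = np.asarray(q, dtype=float)
    cbf = np.asarray(cbf, dtype=float)
    cmro = np.asarray(cmro, dtype=float)
    if np.any(cmro <= 0):
        raise InvalidParameterError("cmro must be > 0")
    d_hbr = q - 1.0
    if closure == "volume":
        if volume is None:
            raise InvalidParameterError("volume closure requires the volume trace")
        d_hbt_raw = np.asarray(volume, dtype=float) - 1.0
    else:
        d_hbt_raw = cbf * q / cmro - 1.0
    d_hbo = d_hbt_raw - d_hbr
    d_hbt = d_hbo + d_hbr  # re-summed so conservation is exact in floats
    return d_hbr, d_hbt, d_hbo


def balloon_steady_state(f_in: float, p: BalloonParams) -> tuple[float, float]:
    """Closed-form steady state (v, q) under constant inflow ``f_in``."""
    v = f_in ** p.alpha_g
    q = v * oxygen_extraction(f_in, p.e0) / p.e0
    return v, q
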