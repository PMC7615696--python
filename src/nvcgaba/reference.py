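"""Synthetic reference hemoglobin traces and trace-comparison metrics.

The experimental 2D-OIS traces this model is compared against are not
published as numeric data, so this module generates SYNTHETIC stand-ins
with the qualitative morphology described for each condition:

* whisker: positive HbT/HbO lobe with a smaller negative HbR lobe
  (functional hyperemia);
* optogenetic, no drug: an early HbR increase with a concomitant HbO/HbT
  dip (NPY-led constriction) followed by a dilation lobe once NPY decays;
* optogenetic, L-NAME: constriction-dominated, predominantly negative HbT.

Templates are differences of gamma-density kernels; across-trial
variability is seeded Gaussian noise averaged over pseudo-trials. These
traces exist to exercise the comparison tooling and qualitative checks —
they are not experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .errors import ComparisonError, InvalidParameterError, InvalidProtocolError
from .hemodynamics import HemoTrace
from .protocol import CONDITIONS

__all__ = ["ReferenceTrace", "make_reference", "compare_traces"]

#: fixture timing constants (ms): hemodynamic onset lag and kernel peaks
ONSET_LAG = 300.0
N_TRIALS = 12


@dataclass
class ReferenceTrace:
    """Across-trial mean +/- s.d. reference trace (synthetic)."""

    t: np.ndarray
    mean_d_hbo: np.ndarray
    mean_d_hbr: np.ndarray
    mean_d_hbt: np.ndarray
    sd_d_hbo: np.ndarray
    sd_d_hbr: np.ndarray
    sd_d_hbt: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "t_ms": self.t,
            "mean_d_hbo": self.mean_d_hbo, "mean_d_hbr": self.mean_d_hbr,
            "mean_d_hbt": self.mean_d_hbt,
            "sd_d_hbo": self.sd_d_hbo, "sd_d_hbr": self.sd_d_hbr,
            "sd_d_hbt": self.sd_d_hbt,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceTrace":
        df = pd.read_csv(path)
        return cls(*(df[c].to_numpy(float) for c in (
            "t_ms", "mean_d_hbo", "mean_d_hbr", "mean_d_hbt",
            "sd_d_hbo", "sd_d_hbr", "sd_d_hbt")))


def _kernel(t: np.ndarray, t0: float, peak_ms: float, shape: float = 4.0) -> np.ndarray:
    """Gamma-density lobe, peak-normalized to 1, zero before onset."""
    scale = peak_ms / (shape - 1.0)
    x = np.clip(t - t0 - ONSET_LAG, 0.0, None)
    k = gamma_dist.pdf(x, a=shape, scale=scale)
    peak = gamma_dist.pdf((shape - 1.0) * scale, a=shape, scale=scale)
    return k / peak


def _templates(condition: str, lname: bool, t: np.ndarray, t0: float):
    """HbO and HbR mean templates per condition (HbT is their sum)."""
    if condition == "whisker":
        hbo = 0.10 * _kernel(t, t0, 1800.0)
        hbr = -0.04 * _kernel(t, t0, 2300.0)
    elif not lname:
        # early constriction lobe then slower dilation lobe
        early_o = -0.04 * _kernel(t, t0, 700.0, shape=3.0)
        late_o = 0.07 * _kernel(t, t0 + 900.0, 2200.0)
        hbo = early_o + late_o
        hbr = 0.02 * _kernel(t, t0, 700.0, shape=3.0) - 0.03 * _kernel(
            t, t0 + 900.0, 2500.0)
    else:
        hbo = -0.07 * _kernel(t, t0, 1500.0)
        hbr = 0.025 * _kernel(t, t0, 1200.0, shape=3.0)
    return hbo, hbr


def make_reference(condition: str, lname: bool = False, seed: int = 0,
                   noise_sd: float = 0.005, t0: float = 2000.0,
                   t_end: float = 22000.0, dt: float = 10.0) -> ReferenceTrace:
    """Deterministic synthetic reference trace for one condition.

    The mean is a fixed gamma-difference template; ``noise_sd`` Gaussian
    trial noise (fraction-change units) is added independently to HbO and
    HbR of each of 12 pseudo-trials, and the across-trial mean and s.d. are
    returned. HbT = HbO + HbR is enforced per trial by construction.
    """
    if condition not in CONDITIONS:
        raise InvalidProtocolError(f"unknown condition {condition!r}")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    t = np.arange(0.0, t_end + 0.5 * dt, dt)
    hbo, hbr = _templates(condition, lname, t, t0)
    rng = np.random.default_rng(seed)
    trials_o = hbo + rng.normal(0.0, noise_sd, size=(N_TRIALS, t.size)) if noise_sd else np.tile(hbo, (N_TRIALS, 1))
    trials_r = hbr + rng.normal(0.0, noise_sd, size=(N_TRIALS, t.size)) if noise_sd else np.tile(hbr, (N_TRIALS, 1))
    trials_t = trials_o + trials_r
    return ReferenceTrace(
        t=t,
        mean_d_hbo=trials_o.mean(axis=0),
        mean_d_hbr=trials_r.mean(axis=0),
        mean_d_hbt=trials_o.mean(axis=0) + trials_r.mean(axis=0),
        sd_d_hbo=trials_o.std(axis=0, ddof=1) if noise_sd else np.zeros_like(t),
        sd_d_hbr=trials_r.std(axis=0, ddof=1) if noise_sd else np.zeros_like(t),
        sd_d_hbt=trials_t.std(axis=0, ddof=1) if noise_sd else np.zeros_like(t),
    )


def _channel_metrics(t, sim, mean, sd) -> dict[str, float]:
    rmse = float(np.sqrt(np.mean((sim - mean) ** 2)))
    i_sim = int(np.argmax(np.abs(sim)))
    i_ref = int(np.argmax(np.abs(mean)))
    within = np.abs(sim - mean) <= sd
    return {
        "rmse": rmse,
        "peak_amplitude_error": float(sim[i_sim] - mean[i_ref]),
        "peak_time_error_ms": float(t[i_sim] - t[i_ref]),
        "band_coverage": float(np.mean(within)),
    }


def compare_traces(sim: HemoTrace, ref: ReferenceTrace) -> dict[str, dict[str, float]]:
    """Per-channel comparison metrics between a simulation and a reference.

    The simulated trace is linearly interpolated onto the overlapping part
    of the reference grid. Returns, per channel, RMSE, peak-amplitude
    error, peak-time error and band coverage (fraction of samples with
    |sim - mean| <= s.d.).
    """
    lo = max(sim.t[0], ref.t[0])
    hi = min(sim.t[-1], ref.t[-1])
    if hi <= lo:
        raise ComparisonError("simulated and reference time ranges do not overlap")
    mask = (ref.t >= lo) & (ref.t <= hi)
    t = ref.t[mask]
    out: dict[str, dict[str, float]] = {}
    for name, s, m, sd in [
        ("d_hbo", sim.d_hbo, ref.mean_d_hbo[mask], ref.sd_d_hbo[mask]),
        ("d_hbr", sim.d_hbr, ref.mean_d_hbr[mask], ref.sd_d_hbr[mask]),
        ("d_hbt", sim.d_hbt, ref.mean_d_hbt[mask], ref.sd_d_hbt[mask]),
    ]:
        s_interp = np.interp(t, sim.t, s)
        out[name] = _channel_metrics(t, s_interp, m, sd)
    return out
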