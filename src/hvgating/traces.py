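"""Per-sweep measurements on current traces.

Turns raw sweep families into the per-voltage quantities the gating
analysis consumes: the step current I_STEP, the instantaneous tail
current I_TAIL obtained by extrapolating a mono-exponential fit back to
the moment of the voltage change, the tail-current reversal potential,
and the apparent activation threshold V_THR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from lmfit import Model

from .errors import FitFailureError, NoBracketError, NotActivatedError
from .simulate import SweepSet
from .thermo import RecordingConditions

__all__ = [
    "IVTable",
    "ExpFitResult",
    "measure_i_step",
    "fit_tail_exponential",
    "measure_sweep_set",
    "estimate_erev_from_tails",
    "estimate_vthr",
]

IV_COLUMNS = ["v_step", "i_step", "i_tail", "i_tail_tau", "g_step"]


@dataclass
class IVTable:
    """Per-voltage measurements for one sweep family.

    ``frame`` holds one row per step voltage with columns v_step (mV),
    i_step (pA), i_tail (pA, instantaneous), i_tail_tau (ms) and g_step
    (nS; NaN until filled by the conductance transform). ``provenance``
    records measurement windows, the tail voltage and any flagged rows.
    """

    frame: pd.DataFrame
    conditions: Optional[RecordingConditions] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in IV_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"IVTable frame missing columns: {missing}")
        self.frame = self.frame.reset_index(drop=True)

    def copy(self) -> "IVTable":
        return IVTable(self.frame.copy(), self.conditions, dict(self.provenance))

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        side = {"provenance": self.provenance}
        if self.conditions is not None:
            side["conditions"] = {
                "ph_i": self.conditions.ph_i,
                "ph_o": self.conditions.ph_o,
                "temperature": self.conditions.temperature,
            }
        path.with_suffix(".json").write_text(json.dumps(side, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "IVTable":
        path = Path(path)
        frame = pd.read_csv(path)
        conditions, provenance = None, {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            side = json.loads(sidecar.read_text())
            provenance = side.get("provenance", {})
            if "conditions" in side:
                conditions = RecordingConditions(**side["conditions"])
        return cls(frame, conditions, provenance)


def measure_i_step(
    time: np.ndarray,
    current: np.ndarray,
    window: tuple,
    policy: str = "peak",
) -> float:
    """Current during the test step, in pA.

    ``window`` is the (start, end) of the step epoch in ms. Policy "peak"
    (default) returns the signed sample of largest magnitude; "steady"
    returns the mean over the final 10% of the window.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    t0, t1 = window
    mask = (time >= t0) & (time < t1)
    if not mask.any():
        raise ValueError("empty measurement window")
    seg = current[mask]
    if policy == "peak":
        return float(seg[np.argmax(np.abs(seg))])
    if policy == "steady":
        tw = time[mask]
        steady = tw >= t1 - 0.1 * (t1 - t0)
        return float(seg[steady].mean())
    raise ValueError(f"unknown policy {policy!r}")


@dataclass(frozen=True)
class ExpFitResult:
    """Mono-exponential tail fit I(t) = i0 + amplitude * exp(-(t - t_onset)/tau)."""

    i0: float  # pA, plateau after decay
    amplitude: float  # pA
    tau: float  # ms
    rss: float  # pA^2
    window: tuple  # (ms, ms)
    at_bounds: bool = False

    @property
    def i_tail(self) -> float:
        """Instantaneous tail current: fit value extrapolated to the voltage change."""
        return self.i0 + self.amplitude


def _exp_model(t, i0, amplitude, tau, t_onset):
    return i0 + amplitude * np.exp(-(t - t_onset) / tau)


def fit_tail_exponential(
    time: np.ndarray,
    current: np.ndarray,
    tail_onset: float,
    fit_window: Optional[tuple] = None,
) -> ExpFitResult:
    """Fit the tail decay to a single exponential and extrapolate to onset.

    The default window starts two samples after ``tail_onset`` (skipping
    the instantaneous jump sample) and ends at five times an initial tau
    guess taken from the 1/e decay point of the windowed data.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    dt = float(np.median(np.diff(time)))

    if fit_window is None:
        start = tail_onset + 2.0 * dt
        post = (time >= start)
        seg_t, seg_i = time[post], current[post]
        i_end = seg_i[-1]
        drop = np.abs(seg_i - i_end)
        if drop[0] > 0:
            below = np.nonzero(drop <= drop[0] / np.e)[0]
            tau_guess = (seg_t[below[0]] - seg_t[0]) if len(below) else (seg_t[-1] - seg_t[0]) / 3
            tau_guess = max(tau_guess, dt)
        else:
            tau_guess = max((seg_t[-1] - seg_t[0]) / 3, dt)
        fit_window = (start, min(time[-1] + dt, start + 5.0 * tau_guess))

    t0, t1 = fit_window
    mask = (time >= t0) & (time <= t1)
    seg_t, seg_i = time[mask], current[mask]
    if len(seg_t) < 5:
        raise ValueError("tail fit window must contain at least 5 samples")

    i0_guess = float(seg_i[-1])
    a_guess = float(seg_i[0] - seg_i[-1])
    tau_guess = max((t1 - t0) / 3.0, dt)
    span = seg_t[-1] - tail_onset

    model = Model(_exp_model, independent_vars=["t"])
    params = model.make_params(
        i0=i0_guess,
        amplitude=a_guess,
        tau=dict(value=tau_guess, min=dt / 10.0, max=100.0 * span),
        t_onset=dict(value=tail_onset, vary=False),
    )
    result = model.fit(seg_i, params, t=seg_t)
    if not result.success:
        raise FitFailureError(
            "tail exponential fit did not converge",
            details={"message": result.message, "residual_rms": float(np.sqrt(np.mean(result.residual**2)))},
        )
    tau = float(result.params["tau"].value)
    at_bounds = bool(
        np.isclose(tau, result.params["tau"].min) or np.isclose(tau, result.params["tau"].max)
    )
    return ExpFitResult(
        i0=float(result.params["i0"].value),
        amplitude=float(result.params["amplitude"].value),
        tau=tau,
        rss=float(np.sum(result.residual**2)),
        window=(float(t0), float(t1)),
        at_bounds=at_bounds,
    )


def measure_sweep_set(
    sweeps: SweepSet,
    i_step_policy: str = "peak",
    tail_fit_window: Optional[tuple] = None,
) -> IVTable:
    """Build an IV table (I_STEP, instantaneous I_TAIL, tail tau) from a sweep family."""
    if sweeps.varied != "step":
        raise ValueError("measure_sweep_set expects a step-varying sweep family")
    p = sweeps.protocol
    step_window = (p.step_onset, p.tail_onset)
    rows = []
    for v, trace in zip(sweeps.sweep_voltages, sweeps.currents):
        i_step = measure_i_step(sweeps.time, trace, step_window, policy=i_step_policy)
        tail = fit_tail_exponential(sweeps.time, trace, p.tail_onset, tail_fit_window)
        rows.append(
            {"v_step": v, "i_step": i_step, "i_tail": tail.i_tail, "i_tail_tau": tail.tau, "g_step": np.nan}
        )
    frame = pd.DataFrame(rows, columns=IV_COLUMNS)
    prov = {
        "i_step_policy": i_step_policy,
        "step_window_ms": list(step_window),
        "v_tail": p.v_tail,
    }
    return IVTable(frame, sweeps.conditions, prov)


def estimate_erev_from_tails(sweeps: SweepSet, use_linear_fit: bool = False) -> float:
    """Reversal potential from instantaneous tail currents vs tail voltage, in mV.

    Requires a reversal protocol (fixed activating step, varying tail
    voltage) whose tail voltages bracket the zero crossing. By default the
    crossing is interpolated linearly between the bracketing points;
    ``use_linear_fit`` instead takes the root of an ordinary least-squares
    line through all points.
    """
    if sweeps.varied != "tail":
        raise ValueError("estimate_erev_from_tails expects a tail-varying sweep family")
    p = sweeps.protocol
    v_tails = sweeps.sweep_voltages
    order = np.argsort(v_tails)
    v_tails = v_tails[order]
    i_tails = np.array(
        [
            fit_tail_exponential(sweeps.time, sweeps.currents[k], p.tail_onset).i_tail
            for k in order
        ]
    )
    signs = np.sign(i_tails)
    crossings = np.nonzero(np.diff(signs) != 0)[0]
    if len(crossings) == 0:
        raise NoBracketError("tail currents do not change sign over the tail-voltage range")
    if use_linear_fit:
        slope, intercept = np.polyfit(v_tails, i_tails, 1)
        return float(-intercept / slope)
    k = crossings[0]
    v0, v1 = v_tails[k], v_tails[k + 1]
    i0, i1 = i_tails[k], i_tails[k + 1]
    return float(v0 - i0 * (v1 - v0) / (i1 - i0))


def estimate_vthr(
    iv: IVTable,
    baseline_sd: float = 0.0,
    k: float = 3.0,
    f: float = 0.02,
) -> float:
    """Apparent activation threshold V_THR from leak-subtracted tail currents.

    Operational surrogate for threshold-by-eye: the smallest step voltage
    at which |i_tail| exceeds max(k * baseline_sd, f * max|i_tail|) and
    stays above it at every more positive voltage. Defaults k = 3 noise
    SDs and f = 2% of the maximal tail amplitude.
    """
    frame = iv.frame.sort_values("v_step")
    v = frame["v_step"].to_numpy(dtype=float)
    y = np.abs(frame["i_tail"].to_numpy(dtype=float))
    if len(v) < 2:
        raise ValueError("need at least two voltages to estimate a threshold")
    thr = max(k * baseline_sd, f * float(np.max(y)))
    above = y > thr
    if not above.any():
        raise NotActivatedError("tail currents never exceed the detection threshold")
    # smallest voltage from which the criterion holds persistently
    idx = None
    for i in range(len(v)):
        if above[i:].all():
            idx = i
            break
    if idx is None:
        raise NotActivatedError("tail currents do not remain above threshold")
    return float(v[idx])
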