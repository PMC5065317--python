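"""Synthetic whole-cell voltage-clamp simulator.

Generates families of current sweeps for step protocols from a
two-conductance + leak model of a proton-conducting voltage-sensor
domain:

* a depolarization-activated "aqueous" conductance (AQ) that opens when
  the sensor reaches its activated state,
* an optional hyperpolarization-activated "shuttle" conductance (SH)
  carried by a histidine at the first S4 arginine, open at rest,
* an ohmic leak.

Each gated conductance follows two-state Hodgkin-Huxley-style kinetics:
the gating variable m relaxes mono-exponentially toward the steady-state
open probability p_inf(V), a Boltzmann function of voltage whose midpoint
shifts with extracellular pH (about -40 mV per pH_o unit). The current is

    I(t) = sum_gated g_max * m(t) * (1 - b(V)) * (V - E_H) + g_leak * (V - E_leak)

with E_H the Nernst proton reversal potential and b(V) an optional
instantaneous voltage-dependent block applied to outward current only
(the tethered-arginine open-channel block phenotype).

Units: mV, ms, nS, pA throughout (pA = nS * mV).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import yaml

from .thermo import RecordingConditions, proton_reversal

__all__ = [
    "Polarity",
    "BlockSpec",
    "ConductanceSpec",
    "VoltageStepProtocol",
    "SweepSet",
    "open_probability",
    "simulate_sweep_set",
    "simulate_reversal_sweeps",
    "reference_parameter_sets",
    "write_sweep_set",
    "read_sweep_set",
    "load_protocol",
    "load_parameter_descriptor",
]

Polarity = Literal["depolarization", "hyperpolarization"]

#: Reference extracellular pH at which v_half values are quoted.
PH_O_REFERENCE = 6.5


@dataclass(frozen=True)
class BlockSpec:
    """Instantaneous voltage-dependent block of outward current.

    The block fraction rises sigmoidally with depolarization,

        b(V) = max_block_fraction / (1 + exp(-(V - v_block_half)/k_block)),

    and is applied only when the unblocked gated current would be
    outward; relief on hyperpolarization is instantaneous (no state
    variable).
    """

    v_block_half: float  # mV
    k_block: float  # mV, > 0
    max_block_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.k_block <= 0:
            raise ValueError("k_block must be positive")
        if not 0.0 <= self.max_block_fraction <= 1.0:
            raise ValueError("max_block_fraction must lie in [0, 1]")

    def fraction(self, v: np.ndarray | float) -> np.ndarray | float:
        return self.max_block_fraction / (
            1.0 + np.exp(-(np.asarray(v, dtype=float) - self.v_block_half) / self.k_block)
        )


@dataclass(frozen=True)
class ConductanceSpec:
    """One membrane conductance: gated (Boltzmann + exponential kinetics) or ohmic.

    ``g_max`` lumps channel number and unitary conductance (G = N*gamma*P_open).
    ``slope_dx`` is always stored positive; gating direction is carried by
    ``polarity`` ("depolarization" = opens on depolarization, rising sigmoid;
    "hyperpolarization" = opens on hyperpolarization, falling sigmoid).
    ``ph_shift_slope`` moves ``v_half`` with extracellular pH relative to the
    reference pH_o of 6.5 (default -40 mV per pH_o unit).
    """

    label: str
    g_max: float  # nS
    v_half: float = 0.0  # mV, at pH_o = PH_O_REFERENCE
    slope_dx: float = 25.0  # mV, > 0
    polarity: Polarity = "depolarization"
    tau_act: float = 10.0  # ms
    tau_deact: float = 10.0  # ms
    ph_shift_slope: float = -40.0  # mV per pH_o unit
    block: Optional[BlockSpec] = None
    is_ohmic: bool = False
    e_leak: float = 0.0  # mV, reversal of the ohmic component

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")
        if not self.is_ohmic:
            if self.slope_dx <= 0:
                raise ValueError("slope_dx must be positive")
            if self.tau_act <= 0 or self.tau_deact <= 0:
                raise ValueError("time constants must be positive")
            if self.polarity not in ("depolarization", "hyperpolarization"):
                raise ValueError(f"unknown polarity {self.polarity!r}")

    def effective_v_half(self, ph_o: float) -> float:
        """Midpoint shifted by the extracellular-pH rule."""
        return self.v_half + self.ph_shift_slope * (ph_o - PH_O_REFERENCE)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ConductanceSpec":
        d = dict(d)
        if d.get("block") is not None:
            d["block"] = BlockSpec(**d["block"])
        return cls(**d)


def open_probability(spec: ConductanceSpec, v: np.ndarray | float, ph_o: float) -> np.ndarray | float:
    """Steady-state open probability p_inf(V) of a gated conductance.

    Boltzmann of the form 1/(1 + exp(s*(V - V_eff)/dx)) with s = +1 for
    hyperpolarization-activated and s = -1 for depolarization-activated
    gating; V_eff is the pH_o-shifted midpoint. Raises for ohmic specs.
    """
    if spec.is_ohmic:
        raise ValueError("open_probability is undefined for an ohmic conductance")
    s = 1.0 if spec.polarity == "hyperpolarization" else -1.0
    v_eff = spec.effective_v_half(ph_o)
    x = s * (np.asarray(v, dtype=float) - v_eff) / spec.slope_dx
    # clip to avoid overflow in exp for extreme voltages
    return 1.0 / (1.0 + np.exp(np.clip(x, -700.0, 700.0)))


@dataclass(frozen=True)
class VoltageStepProtocol:
    """Three-epoch step protocol: hold -> test step -> tail step.

    Times in ms, voltages in mV. ``pre_step_baseline`` is the stretch of
    holding potential recorded before the test step.
    """

    v_hold: float
    step_voltages: tuple
    step_duration: float
    v_tail: float
    tail_duration: float
    sample_interval: float
    pre_step_baseline: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "step_voltages", tuple(float(v) for v in self.step_voltages))
        if len(self.step_voltages) == 0:
            raise ValueError("step_voltages must be non-empty")
        for name in ("step_duration", "tail_duration", "sample_interval", "pre_step_baseline"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        min_dur = min(self.step_duration, self.tail_duration, self.pre_step_baseline)
        if self.sample_interval > min_dur / 10.0:
            raise ValueError(
                "sample_interval must be at most one tenth of the shortest epoch"
            )

    @property
    def step_onset(self) -> float:
        return self.pre_step_baseline

    @property
    def tail_onset(self) -> float:
        return self.pre_step_baseline + self.step_duration

    @property
    def total_duration(self) -> float:
        return self.pre_step_baseline + self.step_duration + self.tail_duration

    def time_base(self) -> np.ndarray:
        n = int(round(self.total_duration / self.sample_interval))
        return np.arange(n) * self.sample_interval

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageStepProtocol":
        d = dict(d)
        if "step_range" in d:
            lo, hi, inc = d.pop("step_range")
            d["step_voltages"] = np.arange(lo, hi + inc / 2, inc).tolist()
        return cls(**d)


@dataclass
class SweepSet:
    """A family of simulated (or imported) current sweeps on a shared time base.

    ``currents`` has shape (n_sweeps, n_samples). ``sweep_voltages`` holds
    the voltage that varies between sweeps: the test-step voltage for the
    standard protocol (``varied == "step"``) or the tail voltage for
    reversal-potential protocols (``varied == "tail"``).
    """

    protocol: VoltageStepProtocol
    conditions: RecordingConditions
    time: np.ndarray
    currents: np.ndarray
    sweep_voltages: np.ndarray
    varied: str = "step"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.currents = np.atleast_2d(np.asarray(self.currents, dtype=float))
        self.sweep_voltages = np.asarray(self.sweep_voltages, dtype=float)
        if self.currents.shape != (len(self.sweep_voltages), len(self.time)):
            raise ValueError("currents must be (n_sweeps, n_samples)")

    @property
    def n_sweeps(self) -> int:
        return self.currents.shape[0]


def _epoch_voltages(protocol: VoltageStepProtocol, v_step: float, v_tail: float):
    """(onset_ms, voltage) per epoch, in order."""
    return [
        (0.0, protocol.v_hold),
        (protocol.step_onset, v_step),
        (protocol.tail_onset, v_tail),
    ]


def _simulate_single_sweep(
    specs: Sequence[ConductanceSpec],
    protocol: VoltageStepProtocol,
    conditions: RecordingConditions,
    v_step: float,
    v_tail: float,
    e_h: float,
) -> np.ndarray:
    t = protocol.time_base()
    i_total = np.zeros_like(t)
    epochs = _epoch_voltages(protocol, v_step, v_tail)
    bounds = [e[0] for e in epochs] + [protocol.total_duration]

    for spec in specs:
        if spec.is_ohmic:
            for k, (t0, v) in enumerate(epochs):
                mask = (t >= t0) & (t < bounds[k + 1])
                i_total[mask] += spec.g_max * (v - spec.e_leak)
            continue

        # gated: exact exponential relaxation within each constant-voltage epoch
        m = np.empty_like(t)
        m_start = float(open_probability(spec, protocol.v_hold, conditions.ph_o))
        for k, (t0, v) in enumerate(epochs):
            mask = (t >= t0) & (t < bounds[k + 1])
            p_inf = float(open_probability(spec, v, conditions.ph_o))
            tau = spec.tau_act if p_inf > m_start else spec.tau_deact
            m[mask] = p_inf + (m_start - p_inf) * np.exp(-(t[mask] - t0) / tau)
            # carry state to the start of the next epoch
            t_next = bounds[k + 1]
            m_start = p_inf + (m_start - p_inf) * np.exp(-(t_next - t0) / tau)

            i_gated = spec.g_max * m[mask] * (v - e_h)
            if spec.block is not None:
                b = spec.block.fraction(v)
                i_gated = np.where(i_gated > 0, i_gated * (1.0 - b), i_gated)
            i_total[mask] += i_gated
    return i_total


def _check_sampling(specs: Sequence[ConductanceSpec], dt: float) -> None:
    taus = [
        tau
        for s in specs
        if not s.is_ohmic
        for tau in (s.tau_act, s.tau_deact)
    ]
    if taus and dt > min(taus) / 5.0:
        warnings.warn(
            f"sample interval {dt} ms is coarse relative to the fastest "
            f"time constant {min(taus)} ms; kinetics will be poorly resolved",
            stacklevel=3,
        )


def simulate_sweep_set(
    specs: Sequence[ConductanceSpec],
    protocol: VoltageStepProtocol,
    conditions: RecordingConditions,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> SweepSet:
    """Simulate one sweep per test-step voltage in the protocol.

    Gating variables start from steady state at the holding potential and
    relax exponentially toward p_inf(V) in each epoch with tau_act (when
    p_inf increased) or tau_deact (otherwise); the per-sample update is the
    exact exponential solution, so the result has no integration-step
    error. ``noise_sd`` adds seeded white Gaussian noise in pA; zero gives
    deterministic output.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    _check_sampling(specs, protocol.sample_interval)
    e_h = proton_reversal(conditions)
    t = protocol.time_base()
    currents = np.stack(
        [
            _simulate_single_sweep(specs, protocol, conditions, v_step, protocol.v_tail, e_h)
            for v_step in protocol.step_voltages
        ]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        currents = currents + rng.normal(0.0, noise_sd, size=currents.shape)
    meta = {
        "specs": [s.to_dict() for s in specs],
        "noise_sd": noise_sd,
        "seed": seed,
        "e_h_mV": e_h,
    }
    return SweepSet(
        protocol=protocol,
        conditions=conditions,
        time=t,
        currents=currents,
        sweep_voltages=np.asarray(protocol.step_voltages),
        varied="step",
        metadata=meta,
    )


def simulate_reversal_sweeps(
    specs: Sequence[ConductanceSpec],
    protocol: VoltageStepProtocol,
    conditions: RecordingConditions,
    tail_voltages: Sequence[float],
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> SweepSet:
    """Reversal-potential protocol: fixed activating step, varying tail voltage.

    Uses the first (and only permitted) entry of ``protocol.step_voltages``
    as the activating step and produces one sweep per tail voltage.
    """
    if len(protocol.step_voltages) != 1:
        raise ValueError("reversal protocol requires exactly one activating step voltage")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    _check_sampling(specs, protocol.sample_interval)
    e_h = proton_reversal(conditions)
    v_step = protocol.step_voltages[0]
    t = protocol.time_base()
    currents = np.stack(
        [
            _simulate_single_sweep(specs, protocol, conditions, v_step, v_tail, e_h)
            for v_tail in tail_voltages
        ]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        currents = currents + rng.normal(0.0, noise_sd, size=currents.shape)
    meta = {
        "specs": [s.to_dict() for s in specs],
        "noise_sd": noise_sd,
        "seed": seed,
        "e_h_mV": e_h,
        "v_step": v_step,
    }
    return SweepSet(
        protocol=protocol,
        conditions=conditions,
        time=t,
        currents=currents,
        sweep_voltages=np.asarray(list(tail_voltages), dtype=float),
        varied="tail",
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# reference parameter sets


def reference_parameter_sets() -> dict:
    """Ready-made model parameter sets for the channel variants analysed here.

    Keys: "R1H", "R1H-N4R", "D185A-R1H", "D185H-R1H", "WT". Values are
    (list of ConductanceSpec, RecordingConditions) at symmetric pH 6.5.

    The SH conductance uses the constrained-fit parameters (g_max 4.6 nS,
    v_half -189 mV, dx 42.1); the AQ conductance uses the leak-subtracted
    fit (g_max 22.2 nS, v_half +29.4 mV, dx 24.9). Leak is 1.5 nS. The
    D185 variants shift the AQ midpoint by +65 / +105 mV; the N4R variant
    adds near-complete instantaneous block of outward AQ current; the
    WT-like set is a single, slower AQ conductance with its midpoint +32 mV
    positive to the R1H value (the observed activation shift between the
    two backgrounds).
    """
    cond = RecordingConditions(ph_i=6.5, ph_o=6.5)
    leak = ConductanceSpec(label="LEAK", g_max=1.5, is_ohmic=True)
    sh = ConductanceSpec(
        label="SH",
        g_max=4.6,
        v_half=-189.0,
        slope_dx=42.1,
        polarity="hyperpolarization",
        tau_act=5.0,
        tau_deact=3.0,
    )
    aq = ConductanceSpec(
        label="AQ",
        g_max=22.2,
        v_half=29.4,
        slope_dx=24.9,
        polarity="depolarization",
        tau_act=20.0,
        tau_deact=10.0,
    )
    block = BlockSpec(v_block_half=-80.0, k_block=15.0, max_block_fraction=0.998)
    aq_blocked = ConductanceSpec(
        label="AQ",
        g_max=22.2,
        v_half=29.4,
        slope_dx=24.9,
        polarity="depolarization",
        tau_act=20.0,
        tau_deact=10.0,
        block=block,
    )
    aq_d185a = ConductanceSpec(
        label="AQ",
        g_max=22.2,
        v_half=29.4 + 65.0,
        slope_dx=24.9,
        polarity="depolarization",
        tau_act=20.0,
        tau_deact=10.0,
    )
    aq_d185h = ConductanceSpec(
        label="AQ",
        g_max=22.2,
        v_half=29.4 + 105.0,
        slope_dx=24.9,
        polarity="depolarization",
        tau_act=20.0,
        tau_deact=10.0,
    )
    aq_wt = ConductanceSpec(
        label="AQ",
        g_max=22.2,
        v_half=29.4 + 32.0,
        slope_dx=24.9,
        polarity="depolarization",
        tau_act=100.0,
        tau_deact=50.0,
    )
    return {
        "R1H": ([sh, aq, leak], cond),
        "R1H-N4R": ([sh, aq_blocked, leak], cond),
        "D185A-R1H": ([sh, aq_d185a, leak], cond),
        "D185H-R1H": ([sh, aq_d185h, leak], cond),
        "WT": ([aq_wt, leak], cond),
    }


# ---------------------------------------------------------------------------
# CSV + JSON round-trip


def write_sweep_set(sweeps: SweepSet, prefix: str | Path) -> tuple:
    """Write a sweep set to ``<prefix>.csv`` + ``<prefix>.json``.

    CSV columns: time_ms, then one current_pA column per sweep, headed by
    the sweep's varying voltage. Values are written with 17 significant
    digits so the round-trip reproduces the float64 data bit-exactly.
    """
    prefix = Path(prefix)
    csv_path = prefix.parent / (prefix.name + ".csv")
    json_path = prefix.parent / (prefix.name + ".json")
    header = "time_ms," + ",".join(f"i_pA_{v:g}" for v in sweeps.sweep_voltages)
    data = np.column_stack([sweeps.time, sweeps.currents.T])
    np.savetxt(csv_path, data, delimiter=",", header=header, comments="", fmt="%.17g")
    sidecar = {
        "protocol": sweeps.protocol.to_dict(),
        "conditions": asdict(sweeps.conditions),
        "sweep_voltages": sweeps.sweep_voltages.tolist(),
        "varied": sweeps.varied,
        "metadata": sweeps.metadata,
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return csv_path, json_path


def read_sweep_set(prefix: str | Path) -> SweepSet:
    """Read a sweep set written by :func:`write_sweep_set`."""
    prefix = Path(prefix)
    sidecar = json.loads((prefix.parent / (prefix.name + ".json")).read_text())
    data = np.loadtxt(prefix.parent / (prefix.name + ".csv"), delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    return SweepSet(
        protocol=VoltageStepProtocol.from_dict(sidecar["protocol"]),
        conditions=RecordingConditions(**sidecar["conditions"]),
        time=data[:, 0],
        currents=data[:, 1:].T,
        sweep_voltages=np.asarray(sidecar["sweep_voltages"], dtype=float),
        varied=sidecar.get("varied", "step"),
        metadata=sidecar.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# descriptor files


def _load_structured(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def load_protocol(path: str | Path) -> VoltageStepProtocol:
    """Load a step protocol from a JSON or YAML descriptor.

    Keys mirror :class:`VoltageStepProtocol`; ``step_range: [lo, hi, inc]``
    may replace an explicit ``step_voltages`` list.
    """
    return VoltageStepProtocol.from_dict(_load_structured(path))


def load_parameter_descriptor(path: str | Path):
    """Load (specs, conditions) from a JSON/YAML model descriptor.

    Schema: ``{"conditions": {ph_i, ph_o, temperature?},
    "conductances": [{label, g_max, ...}, ...]}``.
    """
    d = _load_structured(path)
    if "conductances" not in d or "conditions" not in d:
        raise ValueError("descriptor must contain 'conditions' and 'conductances'")
    specs = [ConductanceSpec.from_dict(c) for c in d["conductances"]]
    cond = RecordingConditions(**d["conditions"])
    return specs, cond
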