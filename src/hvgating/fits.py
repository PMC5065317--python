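"""Conductance transforms and gating-curve fits.

The analytical core of the package: the conductance transform
G = I/(V - E_rev), linear leak estimation and subtraction, Boltzmann fits
of conductance- and tail-current-voltage relations (with parameter
constraints and shared-parameter joint fits), numerical differentiation
of G-V relations, the derivative-Gaussian midpoint estimator, apparent
gating valence, ordinary linear/Pearson fits, and the decomposition of a
U-shaped G-V relation into two opposite-polarity Boltzmann components.

Boltzmann convention: the slope factor dx is always positive and
polarity carries the gating direction,

    y(V) = y_min + (y_max - y_min) / (1 + exp(s*(V - V_half)/dx)),

with s = +1 for hyperpolarization-activated (falling sigmoid) and
s = -1 for depolarization-activated (rising sigmoid) gating.

The derivative of a G-V relation is fit to an area-amplitude Gaussian,

    dG/dV = baseline + (A / (omega*sqrt(pi/2))) * exp(-2*(V - V_peak)^2 / omega^2),

whose center V_peak estimates V_half even when the G-V curve never
reaches saturation inside the recorded voltage range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import lmfit
from scipy import stats

from .errors import FitFailureError, UndefinedPointError
from .thermo import thermal_voltage, DEFAULT_TEMPERATURE_K
from .traces import IVTable

__all__ = [
    "BoltzmannFit",
    "GaussianFit",
    "LinearFit",
    "LeakEstimate",
    "boltzmann",
    "conductance_from_current",
    "fill_g_step",
    "estimate_leak",
    "subtract_leak",
    "fit_boltzmann",
    "fit_boltzmann_shared",
    "numeric_derivative",
    "gaussian_peak",
    "fit_gaussian_peak",
    "gating_valence",
    "fit_line",
    "decompose_two_conductances",
    "normalize_at",
]


def _polarity_sign(polarity: str) -> float:
    if polarity == "hyperpolarization":
        return 1.0
    if polarity == "depolarization":
        return -1.0
    raise ValueError(f"unknown polarity {polarity!r}")


def boltzmann(v, v_half, slope_dx, y_max, y_min, polarity="depolarization"):
    """Boltzmann sigmoid with explicit polarity (dx > 0 convention)."""
    s = _polarity_sign(polarity)
    x = np.clip(s * (np.asarray(v, dtype=float) - v_half) / slope_dx, -700, 700)
    return y_min + (y_max - y_min) / (1.0 + np.exp(x))


def gaussian_peak(v, baseline, area_a, width_omega, v_peak):
    """Area-amplitude Gaussian used for dG/dV-V fits."""
    v = np.asarray(v, dtype=float)
    amp = area_a / (width_omega * np.sqrt(np.pi / 2.0))
    return baseline + amp * np.exp(-2.0 * (v - v_peak) ** 2 / width_omega**2)


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class BoltzmannFit:
    v_half: float  # mV
    slope_dx: float  # mV
    y_max: float
    y_min: float
    polarity: str
    constraints: tuple = ()
    rss: float = float("nan")
    n_points: int = 0
    flags: tuple = ()

    def predict(self, v):
        return boltzmann(v, self.v_half, self.slope_dx, self.y_max, self.y_min, self.polarity)

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        return (
            f"Boltzmann ({self.polarity}): V_0.5 = {self.v_half:.1f} mV, "
            f"dx = {self.slope_dx:.1f}, max = {self.y_max:.3g}, min = {self.y_min:.3g}"
        )


@dataclass(frozen=True)
class GaussianFit:
    baseline: float
    area_a: float
    width_omega: float  # mV
    v_peak: float  # mV
    window: tuple
    constraints: tuple = ()
    rss: float = float("nan")
    n_points: int = 0
    flags: tuple = ()

    def predict(self, v):
        return gaussian_peak(v, self.baseline, self.area_a, self.width_omega, self.v_peak)

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        return (
            f"Gaussian: A = {self.area_a:.3g}, omega = {self.width_omega:.1f}, "
            f"V_PEAK = {self.v_peak:+.1f} mV"
        )


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    pearson_r: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LeakEstimate:
    g_leak: float  # nS
    i_offset: float  # pA
    window: tuple  # (mV, mV)

    def current(self, v):
        return self.g_leak * np.asarray(v, dtype=float) + self.i_offset


# ---------------------------------------------------------------------------
# conductance transform and leak handling


def conductance_from_current(i: float, v: float, e_rev: float, guard_mv: float = 1.0) -> float:
    """Chord conductance G = I/(V - E_rev) in nS (I in pA, V in mV).

    Voltages within ``guard_mv`` of the reversal potential are undefined
    points: the 0/0 limit cannot be evaluated from a single measurement,
    so an :class:`UndefinedPointError` is raised rather than a value
    fabricated.
    """
    if abs(v - e_rev) < guard_mv:
        raise UndefinedPointError(
            f"V = {v} mV lies within {guard_mv} mV of E_rev = {e_rev} mV"
        )
    return i / (v - e_rev)


def fill_g_step(iv: IVTable, e_rev: float, guard_mv: float = 1.0) -> IVTable:
    """Return a copy of the IV table with the g_step column computed.

    Rows whose step voltage falls inside the guard band around E_rev are
    left as NaN and recorded in provenance["undefined_rows"].
    """
    out = iv.copy()
    v = out.frame["v_step"].to_numpy(dtype=float)
    i = out.frame["i_step"].to_numpy(dtype=float)
    defined = np.abs(v - e_rev) >= guard_mv
    g = np.full_like(v, np.nan)
    g[defined] = i[defined] / (v[defined] - e_rev)
    out.frame["g_step"] = g
    out.provenance["e_rev_mV"] = float(e_rev)
    out.provenance["undefined_rows"] = v[~defined].tolist()
    return out


def estimate_leak(iv: IVTable, window: tuple = (0.0, 50.0)) -> LeakEstimate:
    """Ohmic leak from an OLS line through (V, I_STEP) inside a voltage window.

    The default window (0 to +50 mV) targets the plateau where both gated
    conductances are near their minima, so the I-V relation there is the
    leak line; its slope is G_LEAK in nS.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError("leak window must be non-degenerate")
    frame = iv.frame
    mask = (frame["v_step"] >= lo) & (frame["v_step"] <= hi)
    if mask.sum() < 2:
        raise ValueError("need at least 2 points inside the leak window")
    v = frame.loc[mask, "v_step"].to_numpy(dtype=float)
    i = frame.loc[mask, "i_step"].to_numpy(dtype=float)
    res = stats.linregress(v, i)
    return LeakEstimate(g_leak=float(res.slope), i_offset=float(res.intercept), window=(lo, hi))


def subtract_leak(iv: IVTable, leak: LeakEstimate) -> IVTable:
    """Subtract the linear leak from an IV table (original left unchanged).

    i_step loses the leak line evaluated at the step voltage; g_step loses
    the constant g_leak. Tail sweeps sit at a single fixed tail potential,
    so when the table records its tail voltage the constant leak current
    at that potential is removed from i_tail as well.
    """
    out = iv.copy()
    v = out.frame["v_step"].to_numpy(dtype=float)
    out.frame["i_step"] = out.frame["i_step"] - leak.current(v)
    out.frame["g_step"] = out.frame["g_step"] - leak.g_leak
    v_tail = out.provenance.get("v_tail")
    if v_tail is not None:
        out.frame["i_tail"] = out.frame["i_tail"] - leak.current(v_tail)
    out.provenance["leak_subtracted"] = {
        "g_leak_nS": leak.g_leak,
        "i_offset_pA": leak.i_offset,
        "window_mV": list(leak.window),
    }
    return out


# ---------------------------------------------------------------------------
# Boltzmann fitting


_BOLTZ_NAMES = ("v_half", "slope_dx", "y_max", "y_min")


def _boltz_params(v, y, polarity, constraints) -> lmfit.Parameters:
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    constraints = constraints or {}
    span = float(v.max() - v.min())
    y_max0 = float(y.max())
    y_min0 = float(y.min())
    mid = 0.5 * (y_max0 + y_min0)
    v_half0 = float(v[np.argmin(np.abs(y - mid))])
    params = lmfit.Parameters()
    params.add("v_half", value=constraints.get("v_half", v_half0))
    params.add("slope_dx", value=constraints.get("slope_dx", max(span / 6.0, 1.0)), min=1e-3)
    params.add("y_max", value=constraints.get("y_max", y_max0))
    params.add("y_min", value=constraints.get("y_min", y_min0))
    for name in constraints:
        if name not in _BOLTZ_NAMES:
            raise ValueError(f"unknown constrainable parameter {name!r}")
        params[name].set(value=constraints[name], vary=False)
    return params


def fit_boltzmann(
    v: Sequence[float],
    y: Sequence[float],
    polarity: str = "depolarization",
    constraints: Optional[dict] = None,
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a G-V or I_TAIL-V relation.

    ``constraints`` maps any of v_half, slope_dx, y_max, y_min to a value
    that is held exactly during the fit (e.g. constraining V_half to a
    derivative-Gaussian V_peak estimate). Requires more points than free
    parameters.
    """
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(v) & np.isfinite(y)
    v, y = v[ok], y[ok]
    constraints = constraints or {}
    n_free = 4 - len(constraints)
    if len(v) < max(n_free, 1):
        raise ValueError(f"need at least {n_free} points for {n_free} free parameters")
    params = _boltz_params(v, y, polarity, constraints)

    def residual(p):
        return boltzmann(v, p["v_half"], p["slope_dx"], p["y_max"], p["y_min"], polarity) - y

    result = lmfit.minimize(residual, params, method="least_squares")
    if not result.success:
        raise FitFailureError("Boltzmann fit did not converge", details={"message": result.message})
    flags = []
    if result.covar is None and n_free > 0:
        flags.append("ill-conditioned")
    amp = abs(result.params["y_max"].value - result.params["y_min"].value)
    if amp < 1e-9 * max(1.0, float(np.abs(y).max())):
        flags.append("flat")
    return BoltzmannFit(
        v_half=float(result.params["v_half"].value),
        slope_dx=float(result.params["slope_dx"].value),
        y_max=float(result.params["y_max"].value),
        y_min=float(result.params["y_min"].value),
        polarity=polarity,
        constraints=tuple(sorted(constraints)),
        rss=float(np.sum(result.residual**2)),
        n_points=len(v),
        flags=tuple(flags),
    )


def fit_boltzmann_shared(
    datasets: Sequence[tuple],
    polarity: str = "depolarization",
    shared: Sequence[str] = ("slope_dx",),
    constraints: Optional[dict] = None,
) -> list:
    """Joint Boltzmann fit of several datasets with shared parameters.

    ``datasets`` is a sequence of (v, y) pairs; parameters named in
    ``shared`` take a single common value across all datasets (e.g. a
    shared slope factor across pH conditions), the rest vary per dataset.
    ``constraints`` fixes shared parameters exactly.
    """
    shared = tuple(shared)
    constraints = constraints or {}
    for name in shared:
        if name not in _BOLTZ_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
    arrays = [(np.asarray(v, dtype=float), np.asarray(y, dtype=float)) for v, y in datasets]

    params = lmfit.Parameters()
    for name in shared:
        inits = [_boltz_params(v, y, polarity, {})[name].value for v, y in arrays]
        kw = {"min": 1e-3} if name == "slope_dx" else {}
        params.add(f"shared_{name}", value=float(np.mean(inits)), **kw)
        if name in constraints:
            params[f"shared_{name}"].set(value=constraints[name], vary=False)
    for k, (v, y) in enumerate(arrays):
        local = _boltz_params(v, y, polarity, {})
        for name in _BOLTZ_NAMES:
            if name in shared:
                continue
            p = local[name]
            params.add(f"{name}_{k}", value=p.value, min=p.min, max=p.max)

    def get(p, name, k):
        return p[f"shared_{name}"] if name in shared else p[f"{name}_{k}"]

    def residual(p):
        res = []
        for k, (v, y) in enumerate(arrays):
            res.append(
                boltzmann(
                    v,
                    get(p, "v_half", k),
                    get(p, "slope_dx", k),
                    get(p, "y_max", k),
                    get(p, "y_min", k),
                    polarity,
                )
                - y
            )
        return np.concatenate(res)

    result = lmfit.minimize(residual, params, method="least_squares")
    if not result.success:
        raise FitFailureError("joint Boltzmann fit did not converge", details={"message": result.message})
    fits = []
    for k, (v, y) in enumerate(arrays):
        pred = boltzmann(
            v,
            get(result.params, "v_half", k).value,
            get(result.params, "slope_dx", k).value,
            get(result.params, "y_max", k).value,
            get(result.params, "y_min", k).value,
            polarity,
        )
        fits.append(
            BoltzmannFit(
                v_half=float(get(result.params, "v_half", k).value),
                slope_dx=float(get(result.params, "slope_dx", k).value),
                y_max=float(get(result.params, "y_max", k).value),
                y_min=float(get(result.params, "y_min", k).value),
                polarity=polarity,
                constraints=tuple(f"shared:{s}" for s in shared)
                + tuple(sorted(constraints)),
                rss=float(np.sum((pred - y) ** 2)),
                n_points=len(v),
            )
        )
    return fits


# ---------------------------------------------------------------------------
# derivative + Gaussian peak


def numeric_derivative(v: Sequence[float], g: Sequence[float]) -> np.ndarray:
    """dG/dV at the measurement voltages.

    Second-order central differences at interior points (with proper
    weights on nonuniform grids) and one-sided differences at the ends.
    Voltages must be strictly increasing.
    """
    v = np.asarray(v, dtype=float)
    g = np.asarray(g, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 points to differentiate")
    if np.any(np.diff(v) <= 0):
        raise ValueError("voltages must be strictly increasing (no duplicates)")
    return np.gradient(g, v)


def fit_gaussian_peak(
    v: Sequence[float],
    dgdv: Sequence[float],
    window: Optional[tuple] = None,
    fixed_omega: Optional[float] = None,
    direction: Optional[str] = None,
    fixed_baseline: Optional[float] = None,
) -> GaussianFit:
    """Gaussian fit of a dG/dV-V relation; the fitted center is V_peak.

    ``window`` restricts the fit to a voltage range (fits are always
    windowed deliberately: legends state their windows and truncation
    changes the estimate). ``fixed_omega`` holds the width exactly, for
    constrained fits that borrow omega from a better-determined dataset.
    ``direction`` ("up" or "down") forces a positive bump or negative
    trough; by default it is inferred from the data (a rising G-V relation
    has a positive derivative peak, a falling one a negative trough).
    ``fixed_baseline`` pins the offset term (0 is appropriate for
    leak-subtracted derivatives, whose plateaus are flat).
    """
    v = np.asarray(v, dtype=float)
    dgdv = np.asarray(dgdv, dtype=float)
    if window is None:
        window = (float(v.min()), float(v.max()))
    lo, hi = window
    mask = (v >= lo) & (v <= hi) & np.isfinite(dgdv)
    vw, yw = v[mask], dgdv[mask]
    if len(vw) < 5:
        raise ValueError("need at least 5 points inside the fit window")

    # the peak may be a positive bump or a negative trough (falling G-V
    # relations have negative dG/dV); the window edges anchor the baseline
    if direction is None:
        edge = 0.5 * (yw[0] + yw[-1])
        direction = "up" if float(np.max(yw)) - edge >= edge - float(np.min(yw)) else "down"
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    omega0 = fixed_omega if fixed_omega is not None else max((hi - lo) / 3.0, 1.0)
    if direction == "up":
        base0 = float(np.min(yw))
        vpeak0 = float(vw[np.argmax(yw)])
        area0 = float(np.trapezoid(yw - base0, vw))
    else:
        base0 = float(np.max(yw))
        vpeak0 = float(vw[np.argmin(yw)])
        area0 = float(np.trapezoid(yw - base0, vw))

    span = hi - lo
    params = lmfit.Parameters()
    params.add("baseline", value=base0)
    # the area's sign is the peak direction; bounding it prevents the
    # optimiser from flipping a trough into a bump on truncated data
    if direction == "up":
        params.add("area_a", value=area0 if area0 > 0 else 1.0, min=0.0)
    else:
        params.add("area_a", value=area0 if area0 < 0 else -1.0, max=0.0)
    params.add("width_omega", value=omega0, min=1e-2)
    params.add("v_peak", value=vpeak0, min=lo - span, max=hi + span)
    constraints = []
    if fixed_omega is not None:
        params["width_omega"].set(value=float(fixed_omega), vary=False)
        constraints.append("width_omega")
    if fixed_baseline is not None:
        params["baseline"].set(value=float(fixed_baseline), vary=False)
        constraints.append("baseline")

    def residual(p):
        return gaussian_peak(vw, p["baseline"], p["area_a"], p["width_omega"], p["v_peak"]) - yw

    result = lmfit.minimize(residual, params, method="least_squares")
    flags = []
    if not result.success:
        flags.append("non-convergent")
    v_peak = float(result.params["v_peak"].value)
    omega = float(result.params["width_omega"].value)
    if not (lo - omega <= v_peak <= hi + omega):
        flags.append("peak-outside-window")
    return GaussianFit(
        baseline=float(result.params["baseline"].value),
        area_a=float(result.params["area_a"].value),
        width_omega=omega,
        v_peak=v_peak,
        window=(float(lo), float(hi)),
        constraints=tuple(constraints),
        rss=float(np.sum(result.residual**2)),
        n_points=len(vw),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# scalars and lines


def gating_valence(slope_dx: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Apparent gating valence z_G = (RT/F)/dx, in elementary charges."""
    if slope_dx <= 0:
        raise ValueError("slope_dx must be positive")
    return thermal_voltage(temperature) / slope_dx


def fit_line(xs: Sequence[float], ys: Sequence[float]) -> LinearFit:
    """Ordinary least-squares line with the Pearson correlation coefficient."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(xs) == 0:
        raise ValueError("x values have zero variance")
    res = stats.linregress(xs, ys)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept), pearson_r=float(res.rvalue))


# ---------------------------------------------------------------------------
# two-conductance decomposition


def decompose_two_conductances(
    v: Sequence[float],
    g: Sequence[float],
    init: Optional[dict] = None,
    n_starts: int = 5,
    seed: int = 0,
) -> tuple:
    """Decompose a leak-subtracted U-shaped G-V relation into two Boltzmanns.

    Fits G(V) = G_sh_max * B_down(V; vh_sh, dx_sh) + G_aq_max * B_up(V; vh_aq, dx_aq)
    where B_down is hyperpolarization-activated (falling) and B_up is
    depolarization-activated (rising). The optimiser runs ``n_starts``
    seeded, jittered starts and keeps the best solution; components are
    identified by polarity, which breaks the labelling tie. Returns
    (sh_fit, aq_fit, ratio g_aq_max/g_sh_max); a component whose maximal
    conductance collapses toward zero is flagged "collapsed".
    """
    v = np.asarray(v, dtype=float)
    g = np.asarray(g, dtype=float)
    ok = np.isfinite(v) & np.isfinite(g)
    v, g = v[ok], g[ok]
    if len(v) < 7:
        raise ValueError("need at least 7 points for a six-parameter decomposition")
    span = float(v.max() - v.min())
    g_top = float(np.max(g))
    init = dict(init or {})
    defaults = {
        "g_sh_max": max(float(g[0] - g.min()), 1e-3),
        "vh_sh": float(v.min() + 0.25 * span),
        "dx_sh": 35.0,
        "g_aq_max": max(float(g[-1] - g.min()), 1e-3),
        "vh_aq": float(v.min() + 0.75 * span),
        "dx_aq": 25.0,
    }
    defaults.update(init)

    def model(p):
        down = boltzmann(v, p["vh_sh"], p["dx_sh"], p["g_sh_max"], 0.0, "hyperpolarization")
        up = boltzmann(v, p["vh_aq"], p["dx_aq"], p["g_aq_max"], 0.0, "depolarization")
        return down + up

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(n_starts, 1)):
        params = lmfit.Parameters()
        jitter = 1.0 if start == 0 else float(np.exp(rng.normal(0.0, 0.3)))
        vh_jit = 0.0 if start == 0 else float(rng.normal(0.0, 0.1 * span))
        params.add("g_sh_max", value=defaults["g_sh_max"] * jitter, min=0.0)
        params.add("vh_sh", value=defaults["vh_sh"] + vh_jit)
        params.add("dx_sh", value=defaults["dx_sh"] * jitter, min=1.0, max=300.0)
        params.add("g_aq_max", value=defaults["g_aq_max"] * jitter, min=0.0)
        params.add("vh_aq", value=defaults["vh_aq"] - vh_jit)
        params.add("dx_aq", value=defaults["dx_aq"] * jitter, min=1.0, max=300.0)
        try:
            result = lmfit.minimize(lambda p: model(p) - g, params, method="least_squares")
        except Exception:
            continue
        rss = float(np.sum(result.residual**2))
        if result.success and (best is None or rss < best[0]):
            best = (rss, result)
    if best is None:
        raise FitFailureError("two-conductance decomposition did not converge")
    rss, result = best
    p = result.params

    def component_fit(g_max, vh, dx, polarity):
        flags = ("collapsed",) if g_max < 5e-3 * max(g_top, 1e-9) else ()
        return BoltzmannFit(
            v_half=float(vh),
            slope_dx=float(dx),
            y_max=float(g_max),
            y_min=0.0,
            polarity=polarity,
            rss=rss,
            n_points=len(v),
            flags=flags,
        )

    sh_fit = component_fit(p["g_sh_max"].value, p["vh_sh"].value, p["dx_sh"].value, "hyperpolarization")
    aq_fit = component_fit(p["g_aq_max"].value, p["vh_aq"].value, p["dx_aq"].value, "depolarization")
    ratio = float(aq_fit.y_max / sh_fit.y_max) if sh_fit.y_max > 0 else float("inf")
    return sh_fit, aq_fit, ratio


def normalize_at(v: Sequence[float], y: Sequence[float], v_ref: float) -> np.ndarray:
    """Normalize a relation to its (interpolated) amplitude at a reference voltage."""
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    ref = float(np.interp(v_ref, v, y))
    if ref == 0:
        raise ValueError(f"amplitude at {v_ref} mV is zero; cannot normalize")
    return y / ref


def fits_to_json(fits: dict, path) -> None:
    """Serialize a mapping of fit results (any of the dataclasses above) to JSON."""
    payload = {k: f.to_dict() if hasattr(f, "to_dict") else f for k, f in fits.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def fits_to_frame(fits: dict) -> pd.DataFrame:
    """Flat one-row-per-fit summary table."""
    rows = []
    for name, f in fits.items():
        d = f.to_dict() if hasattr(f, "to_dict") else dict(f)
        d = {k: (list(vv) if isinstance(vv, tuple) else vv) for k, vv in d.items()}
        rows.append({"name": name, **d})
    return pd.DataFrame(rows)
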