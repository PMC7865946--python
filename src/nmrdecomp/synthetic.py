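"""Ground-truth synthetic NMR fixtures.

Real multi-component ssNMR series (cellulose degradation time courses,
polymer ¹H spectra, property tables) are emulated as sums of exponentially
decaying complex sinusoids — Lorentzian lines with per-component T2* — plus
complex Gaussian noise:

    s(t) = sum_j a_j exp(i phi_j) exp(i 2 pi f_j t) exp(-t / T2*_j) + noise

The degradation scenario produces a 16-sample series over 0-120 h in which
three spectral components (a fast-decaying "cellulose-like", an intermediate
"protein-like" and a slow-decaying "lipid-like" set of lines, i.e. T2*
ordering cellulose < protein < lipid) wax and wane with smooth kinetics, a
catabolic-product table follows first-order chain kinetics A -> B -> C, and
pseudo-thermal properties are deterministic functions of composition.  Every
generator returns its ground truth so recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import FID, PropertyTable

__all__ = [
    "LineSpec",
    "Component",
    "DegradationScenario",
    "make_fid",
    "make_degradation_series",
    "make_product_table",
    "make_property_table",
    "default_degradation_scenario",
    "amplitude_curve",
]


@dataclass
class LineSpec:
    """One Lorentzian line: frequency (Hz), amplitude (a.u.), T2* (s), phase (rad)."""

    frequency: float
    amplitude: float = 1.0
    t2_star: float = 0.01
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not self.t2_star > 0:
            raise ValueError("t2_star must be > 0")


def amplitude_curve(kind: str, **params) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth non-negative amplitude-vs-time laws for degradation kinetics.

    ``exp_decay`` (consumed substrate), ``logistic_rise`` (accumulating
    product), ``bell`` (transient intermediate).  Times in hours.
    """
    if kind == "exp_decay":
        tau = params.get("tau", 40.0)
        return lambda t: np.exp(-np.asarray(t, float) / tau)
    if kind == "logistic_rise":
        t0, width = params.get("t0", 60.0), params.get("width", 15.0)
        return lambda t: 1.0 / (1.0 + np.exp(-(np.asarray(t, float) - t0) / width))
    if kind == "bell":
        t0, width = params.get("t0", 50.0), params.get("width", 25.0)
        return lambda t: np.exp(-((np.asarray(t, float) - t0) ** 2) / (2 * width**2))
    raise ValueError(f"unknown amplitude curve {kind!r}")


@dataclass
class Component:
    """A named set of lines sharing one amplitude-vs-time law."""

    name: str
    lines: List[LineSpec]
    curve: str = "exp_decay"
    curve_params: Dict[str, float] = field(default_factory=dict)
    base_amplitude: float = 1.0

    def amplitudes(self, times_h: np.ndarray) -> np.ndarray:
        vals = self.base_amplitude * amplitude_curve(self.curve, **self.curve_params)(times_h)
        if (vals < 0).any():
            raise ValueError(f"component {self.name!r}: negative amplitude in span")
        return vals


@dataclass
class DegradationScenario:
    """Multi-sample degradation series layout: 16 timepoints over 0-120 h by default."""

    components: List[Component]
    n_timepoints: int = 16
    time_span: Tuple[float, float] = (0.0, 120.0)
    noise_sd: float = 0.01
    seed: int = 2021

    def times(self) -> np.ndarray:
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        return np.linspace(*self.time_span, self.n_timepoints)


def make_fid(
    lines: Sequence[LineSpec],
    n_points: int = 4096,
    dwell_time: float = 1e-4,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    label: str = "",
) -> FID:
    """Synthesize a complex FID from Lorentzian line specs plus complex noise."""
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    nyquist = 0.5 / dwell_time
    for i, ln in enumerate(lines):
        if abs(ln.frequency) >= nyquist:
            raise ValueError(
                f"line {i} at {ln.frequency} Hz aliases: |f| must be < Nyquist {nyquist} Hz"
            )
    t = np.arange(n_points) * dwell_time
    sig = np.zeros(n_points, dtype=complex)
    for ln in lines:
        sig += (
            ln.amplitude
            * np.exp(1j * ln.phase)
            * np.exp(2j * np.pi * ln.frequency * t)
            * np.exp(-t / ln.t2_star)
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + noise_sd * (rng.standard_normal(n_points) + 1j * rng.standard_normal(n_points))
    return FID(sig, dwell_time=dwell_time, label=label)


def default_degradation_scenario(noise_sd: float = 0.01, seed: int = 2021) -> DegradationScenario:
    """Three-component cellulose-degradation analogue.

    T2* ordering encodes the physics: rigid crystalline cellulose decays
    fastest (broad lines), mobile lipids slowest (narrow lines).
    """
    cellulose = Component(
        "cellulose",
        lines=[LineSpec(-6000.0, 1.0, 0.005), LineSpec(-4500.0, 0.7, 0.005)],
        curve="exp_decay",
        curve_params={"tau": 40.0},
        base_amplitude=1.0,
    )
    protein = Component(
        "protein",
        lines=[LineSpec(-1000.0, 0.6, 0.015), LineSpec(500.0, 1.0, 0.015), LineSpec(2000.0, 0.5, 0.015)],
        curve="bell",
        curve_params={"t0": 50.0, "width": 25.0},
        base_amplitude=0.8,
    )
    lipid = Component(
        "lipid",
        lines=[LineSpec(5000.0, 1.0, 0.05), LineSpec(7000.0, 0.6, 0.05)],
        curve="logistic_rise",
        curve_params={"t0": 60.0, "width": 15.0},
        base_amplitude=0.9,
    )
    return DegradationScenario(
        components=[cellulose, protein, lipid], noise_sd=noise_sd, seed=seed
    )


def make_degradation_series(
    scenario: Optional[DegradationScenario] = None,
    n_points: int = 2048,
    dwell_time: float = 5e-5,
) -> Tuple[List[FID], Dict]:
    """One FID per timepoint plus ground truth.

    Returns ``(fids, truth)`` where ``truth`` holds the composition table
    (timepoints x components DataFrame of amplitude multipliers), sampling
    times in hours, and each component's LineSpecs for reference spectra.
    """
    scenario = scenario or default_degradation_scenario()
    times_h = scenario.times()
    comp_amp = {c.name: c.amplitudes(times_h) for c in scenario.components}
    rng = np.random.default_rng(scenario.seed)
    fids = []
    for i, th in enumerate(times_h):
        lines = []
        for comp in scenario.components:
            a = comp_amp[comp.name][i]
            lines.extend(
                LineSpec(ln.frequency, a * ln.amplitude, ln.t2_star, ln.phase)
                for ln in comp.lines
            )
        fid = make_fid(
            lines,
            n_points=n_points,
            dwell_time=dwell_time,
            noise_sd=scenario.noise_sd,
            seed=int(rng.integers(2**31)),
            label=f"t={th:.1f}h",
        )
        fids.append(fid)
    truth = {
        "composition": pd.DataFrame(comp_amp, index=[f"t={t:.1f}h" for t in times_h]),
        "times_h": times_h,
        "components": {c.name: c.lines for c in scenario.components},
        "scenario": scenario,
    }
    return fids, truth


def make_product_table(
    times_h: np.ndarray,
    k1: float = 1.0 / 25.0,
    k2: float = 1.0 / 45.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> PropertyTable:
    """Catabolic-product intensities from first-order chain kinetics A -> B -> C.

    A ("propionate"-like) is consumed monotonically, B ("acetate"-like) is the
    transient intermediate and C ("CO2"-like) the accumulating end product,
    so B and C are single-valued functions of A over the sampled window.
    Intensities are in scaled (a.u.) units.
    """
    t = np.asarray(times_h, dtype=float)
    A = np.exp(-k1 * t)
    if abs(k2 - k1) < 1e-12:
        B = k1 * t * np.exp(-k1 * t)
    else:
        B = k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    C = 1.0 - A - B
    values = np.column_stack([A, B, C])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(values + noise_sd * rng.standard_normal(values.shape), 0.0, None)
    ids = [f"t={x:.1f}h" for x in t]
    return PropertyTable(ids, ["propionate", "acetate", "co2"], values)


_DEFAULT_PROPERTY_FUNCS = {
    # pseudo-thermal properties (deg C) as linear maps of component fractions;
    # more mobile (lipid-rich) compositions give lower Tg, as in plasticized polymers
    "Tg": lambda f: 60.0 - 30.0 * f.get("lipid", 0.0) + 10.0 * f.get("cellulose", 0.0),
    "Tm": lambda f: 150.0 + 40.0 * f.get("cellulose", 0.0) - 20.0 * f.get("protein", 0.0),
    "Td": lambda f: 300.0 + 50.0 * f.get("cellulose", 0.0) + 20.0 * f.get("lipid", 0.0),
}


def make_property_table(
    truth: Dict,
    property_funcs: Optional[Dict[str, Callable]] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> PropertyTable:
    """Properties as deterministic functions of per-sample composition fractions.

    Each function receives a dict of component fractions (composition row
    normalized to sum 1) and returns one property value; optional Gaussian
    noise on top.
    """
    funcs = property_funcs or _DEFAULT_PROPERTY_FUNCS
    comp = truth["composition"]
    frac = comp.div(comp.sum(axis=1), axis=0)
    names = list(funcs)
    values = np.array(
        [[funcs[name](row.to_dict()) for name in names] for _, row in frac.iterrows()],
        dtype=float,
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + noise_sd * rng.standard_normal(values.shape)
    return PropertyTable(list(comp.index), names, values)
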