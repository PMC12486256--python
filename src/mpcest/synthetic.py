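"""Synthetic glucoCEST inputs: digital phantoms and dynamic DGE experiments.

Everything downstream of the scanner is generated here: per-tube or
per-frame Z-spectra from the Bloch-McConnell simulator, multi-echo readout
decay, and seeded Rician/Gaussian noise, together with the ground truth
(concentration, T2, noiseless signals) needed for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from mpcest import bmc
from mpcest.bmc import R2EX_GLUCOSE_7T, SaturationPulse, ZSpectrum, glucose_pool, t2_from_glucose
from mpcest.dge import DgeSeries, mtr_asym
from mpcest.presets import DGE_OFFSETS_PPM, Preset, default_pulse, get_preset
from mpcest.relaxometry import EchoTrain, MultiEchoStack

__all__ = [
    "PHANTOM_CONCENTRATIONS_MM",
    "TubeSpec",
    "PhantomSpec",
    "DynamicProtocol",
    "make_uptake_curve",
    "conc_for_t2_drop",
    "simulate_dge_experiment",
    "dge_series_from_signals",
    "make_phantom",
    "add_noise",
]

#: Phantom tube concentrations (mM).
PHANTOM_CONCENTRATIONS_MM = (10.0, 50.0, 100.0, 150.0, 230.0, 310.0)


def add_noise(
    data: np.ndarray, sigma: float, kind: str, rng: np.random.Generator
) -> np.ndarray:
    """Seeded magnitude noise: Rician (default) or additive Gaussian."""
    if sigma <= 0 or kind is None or kind == "none":
        return data
    if kind == "rician":
        return np.sqrt(
            (data + rng.normal(0.0, sigma, data.shape)) ** 2
            + rng.normal(0.0, sigma, data.shape) ** 2
        )
    if kind == "gaussian":
        return np.abs(data + rng.normal(0.0, sigma, data.shape))
    raise ValueError(f"unknown noise model {kind!r}")


# ---------------------------------------------------------------------------
# uptake dynamics
# ---------------------------------------------------------------------------


def make_uptake_curve(
    time: np.ndarray,
    infusion_start: float,
    plateau: float,
    shape: str = "sigmoid",
    tau: float = 300.0,
    peak_overshoot: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Smooth glucose concentration curve (mM) over the acquisition.

    Zero before ``infusion_start``; ``sigmoid`` rises monotonically to
    ``plateau`` with time constant ``tau``; ``gamma`` rises to
    ``peak_overshoot * plateau`` and settles back toward the plateau.
    Deterministic given its parameters (``seed`` is accepted for interface
    uniformity only).
    """
    if plateau < 0:
        raise ValueError("plateau concentration must be >= 0")
    time = np.asarray(time, dtype=float)
    t = np.clip(time - infusion_start, 0.0, None)
    if shape == "sigmoid":
        curve = plateau * np.tanh(t / tau)
    elif shape == "gamma":
        # gamma-variate transient relaxing onto the plateau
        x = t / tau
        overshoot = max(peak_overshoot - 1.0, 0.0)
        curve = plateau * (1.0 - np.exp(-x)) + plateau * overshoot * x * np.exp(1.0 - x)
    else:
        raise ValueError(f"unknown uptake shape {shape!r}")
    return np.where(time >= infusion_start, curve, 0.0)


def drift_curve(
    time: np.ndarray,
    amplitude: float,
    seed: int,
    periods: tuple = (900.0, 1500.0),
) -> np.ndarray:
    """Slow glucose-independent T2 drift (ms): seeded sum of sinusoids.

    Models physiological T2 fluctuations (perfusion, temperature) that are
    not driven by glucose; peak excursion equals ``amplitude``.
    """
    time = np.asarray(time, dtype=float)
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, len(periods))
    weights = rng.uniform(0.5, 1.0, len(periods))
    curve = np.zeros_like(time)
    for w, p, ph in zip(weights, periods, phases):
        curve += w * np.sin(2.0 * np.pi * time / p + ph)
    peak = np.max(np.abs(curve))
    return amplitude * curve / peak if peak > 0 else curve


def conc_for_t2_drop(t2_start_ms: float, t2_end_ms: float, r2ex: float = R2EX_GLUCOSE_7T) -> float:
    """Glucose concentration (mM) producing a given T2 drop via R2 relaxivity."""
    if t2_end_ms > t2_start_ms:
        raise ValueError("t2_end must not exceed t2_start")
    return (1000.0 / t2_end_ms - 1000.0 / t2_start_ms) / r2ex


@dataclass
class DynamicProtocol:
    """Dynamic DGE acquisition schedule with coupled glucose/T2 time courses.

    ``t2_curve`` is the glucose-coupled water T2 derived from ``conc_curve``
    through the transverse relaxivity; ``t2_drift`` is an optional additive
    T2 component independent of glucose (physiological drift), so the
    simulated water T2 is ``t2_curve + t2_drift``.
    """

    n_frames: int = 60
    n_baseline: int = 10
    frame_interval: float = 45.0
    t2_baseline: float = 47.5
    conc_curve: np.ndarray | None = None
    t2_drift: np.ndarray | None = None
    r2ex: float = R2EX_GLUCOSE_7T
    offsets: tuple = DGE_OFFSETS_PPM
    echo_train: EchoTrain = field(default_factory=EchoTrain)
    noise: str = "none"
    snr: float = 50.0
    seed: int = 0
    t2_curve: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.conc_curve is None:
            self.conc_curve = make_uptake_curve(
                self.time, self.infusion_start, plateau=0.0
            )
        self.conc_curve = np.asarray(self.conc_curve, dtype=float)
        if self.conc_curve.size != self.n_frames:
            raise ValueError("conc_curve length must equal n_frames")
        if np.any(self.conc_curve[: self.n_baseline] != 0.0):
            raise ValueError("conc_curve must be zero over baseline frames")
        if np.any(self.conc_curve < 0):
            raise ValueError("conc_curve must be non-negative")
        if self.t2_drift is None:
            self.t2_drift = np.zeros(self.n_frames)
        self.t2_drift = np.asarray(self.t2_drift, dtype=float)
        if self.t2_drift.size != self.n_frames:
            raise ValueError("t2_drift length must equal n_frames")
        self.t2_curve = np.array(
            [t2_from_glucose(self.t2_baseline, c, self.r2ex) for c in self.conc_curve]
        )

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def infusion_start(self) -> float:
        return self.n_baseline * self.frame_interval

    @property
    def baseline_idx(self) -> np.ndarray:
        return np.arange(self.n_baseline)

    @property
    def t2_total(self) -> np.ndarray:
        return self.t2_curve + self.t2_drift


# ---------------------------------------------------------------------------
# dynamic experiment
# ---------------------------------------------------------------------------


def _disc_mask(grid: tuple[int, int], frac: float = 0.4) -> np.ndarray:
    ny, nx = grid
    yy, xx = np.mgrid[0:ny, 0:nx]
    return (yy - (ny - 1) / 2) ** 2 + (xx - (nx - 1) / 2) ** 2 <= (frac * min(ny, nx)) ** 2


def simulate_dge_experiment(
    protocol: DynamicProtocol,
    tissue: Preset | str = "tumor",
    grid: tuple[int, int] | None = (16, 16),
    pd0: float = 1000.0,
    pulse: SaturationPulse | None = None,
) -> dict:
    """Simulate a dynamic multi-echo, multi-offset glucoCEST experiment.

    Per frame, normalized Z-spectrum signals are computed with the
    Bloch-McConnell propagator using the frame's glucose fraction and total
    water T2; echo-train images are synthesized with ``exp(-TE/T2)`` decay
    and seeded noise. With ``grid=None`` only the noiseless ground truth is
    returned (signal-level simulation).

    Returns a dict with ``truth`` (time, conc, t2, noiseless signals) and,
    when imaging, ``stack`` (saturated, axes row/col/echo/offset/time) and
    ``s0_stack`` (unsaturated, singleton offset axis).
    """
    if isinstance(tissue, str):
        tissue = get_preset(tissue)
    if pulse is None:
        pulse = default_pulse()
    offsets = np.asarray(protocol.offsets, dtype=float)
    n_off, n_t = offsets.size, protocol.n_frames
    t2_total = protocol.t2_total

    signal = np.empty((n_off, n_t))
    for it in range(n_t):
        pools = tissue.pools(protocol.conc_curve[it], t2_total[it])
        signal[:, it] = bmc.bmc_propagate(pools, pulse, offsets).signal

    truth = {
        "time": protocol.time,
        "conc": protocol.conc_curve.copy(),
        "t2": t2_total.copy(),
        "t2_coupled": protocol.t2_curve.copy(),
        "offsets": offsets.copy(),
        "signal": signal,
        "baseline_idx": protocol.baseline_idx,
    }
    if grid is None:
        return {"truth": truth}

    rng = np.random.default_rng(protocol.seed)
    mask = _disc_mask(grid)
    pd_map = np.where(mask, pd0, 0.0)
    te = protocol.echo_train.te  # ms
    decay = np.exp(-te[:, None] / t2_total[None, :])  # (ne, nt)

    sat = (
        pd_map[:, :, None, None, None]
        * signal[None, None, None, :, :]
        * decay[None, None, :, None, :]
    )
    s0 = pd_map[:, :, None, None, None] * decay[None, None, :, None, :]
    sigma = pd0 * np.exp(-te[0] / protocol.t2_baseline) / protocol.snr
    if protocol.noise != "none":
        sat = add_noise(sat, sigma, protocol.noise, rng)
        s0 = add_noise(s0, sigma, protocol.noise, rng)

    stack = MultiEchoStack(
        sat, protocol.echo_train, offsets=offsets, time=protocol.time, mask=mask
    )
    s0_stack = MultiEchoStack(
        s0, protocol.echo_train, offsets=None, time=protocol.time, mask=mask
    )
    return {"stack": stack, "s0_stack": s0_stack, "truth": truth, "roi": mask}


def dge_series_from_signals(
    signal: np.ndarray,
    offsets: np.ndarray,
    time: np.ndarray,
    baseline_idx: np.ndarray,
    offset: float = 1.2,
) -> DgeSeries:
    """Build a DGE series (signal at +offset plus per-frame MTR_asym).

    ``signal`` has axes (offset, time); signals are assumed normalized.
    """
    offsets = np.asarray(offsets, dtype=float)
    n_t = signal.shape[1]
    s_plus = np.empty(n_t)
    asym = np.empty(n_t)
    for it in range(n_t):
        z = ZSpectrum(offsets, signal[:, it])
        s_plus[it] = z.at(offset)
        asym[it] = mtr_asym(z, offset)
    return DgeSeries(
        time=time, signal=s_plus, baseline_idx=baseline_idx, offset=offset, mtr_asym=asym
    )


# ---------------------------------------------------------------------------
# digital phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TubeSpec:
    """One glucose tube: center (row, col), radius (px), contents."""

    center: tuple[float, float]
    radius: float
    conc: float
    t2: float = 100.0  # Gd-shortened baseline T2 (ms), before the glucose term
    pd: float = 1000.0


@dataclass
class PhantomSpec:
    """Digital multi-tube glucose phantom on a rectangular grid."""

    tubes: list[TubeSpec] = field(default_factory=list)
    grid: tuple[int, int] = (64, 64)
    water_t1: float = 0.35
    glucose_k_ex: float = 4000.0

    def __post_init__(self) -> None:
        if not self.tubes:
            self.tubes = self._default_tubes()
        for i, a in enumerate(self.tubes):
            for b in self.tubes[i + 1 :]:
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius + b.radius:
                    raise ValueError("phantom tubes overlap")

    def _default_tubes(self) -> list[TubeSpec]:
        ny, nx = self.grid
        radius = min(ny, nx) / 8.0
        centers = [
            (ny * 0.25, nx * 0.2),
            (ny * 0.25, nx * 0.5),
            (ny * 0.25, nx * 0.8),
            (ny * 0.75, nx * 0.2),
            (ny * 0.75, nx * 0.5),
            (ny * 0.75, nx * 0.8),
        ]
        return [
            TubeSpec(c, radius * 0.9, conc)
            for c, conc in zip(centers, PHANTOM_CONCENTRATIONS_MM)
        ]

    def tube_masks(self) -> list[np.ndarray]:
        ny, nx = self.grid
        yy, xx = np.mgrid[0:ny, 0:nx]
        return [
            (yy - t.center[0]) ** 2 + (xx - t.center[1]) ** 2 <= t.radius**2
            for t in self.tubes
        ]


def make_phantom(
    spec: PhantomSpec,
    pulse: SaturationPulse | None = None,
    offsets: Sequence[float] | None = None,
    echo_train: EchoTrain | None = None,
    noise: str = "none",
    snr: float = 50.0,
    seed: int = 0,
    readout_exchange: float = 0.04,
) -> dict:
    """Simulate multi-echo, multi-offset images of a glucose tube phantom.

    Each tube gets a water+glucose two-pool Z-spectrum with its own T2
    (Gd-shortened baseline plus the glucose relaxivity term). The apparent
    transverse rate during the echo train is weakly coupled to the residual
    water saturation, ``R2_app = R2 * (1 + readout_exchange * (1 - S))``,
    which broadens Z-spectra read from late echoes relative to the fitted
    saturation-weighted PD amplitude.

    Returns ``stack`` (row, col, echo, offset), ``s0_stack`` (unsaturated,
    singleton offset axis), per-tube ``masks`` and ground-truth spectra.
    """
    if pulse is None:
        pulse = default_pulse()
    if offsets is None:
        offsets = np.arange(-5.0, 5.0001, 0.2)
    offsets = np.asarray(offsets, dtype=float)
    if echo_train is None:
        echo_train = EchoTrain()
    rng = np.random.default_rng(seed)
    masks = spec.tube_masks()
    te = echo_train.te
    ny, nx = spec.grid
    ne, n_off = te.size, offsets.size

    sat = np.zeros((ny, nx, ne, n_off))
    s0 = np.zeros((ny, nx, ne, 1))
    spectra, tube_t2 = [], []
    for tube, mask in zip(spec.tubes, masks):
        t2_ms = t2_from_glucose(tube.t2, tube.conc)
        tube_t2.append(t2_ms)
        pools = [
            bmc.ExchangePool("water", 0.0, 1.0, 0.0, 1.0 / spec.water_t1, 1000.0 / t2_ms),
            glucose_pool(tube.conc, k_ex=spec.glucose_k_ex),
        ]
        z = bmc.bmc_propagate(pools, pulse, offsets)
        spectra.append(z)
        r2_app = (1.0 / t2_ms) * (1.0 + readout_exchange * (1.0 - z.signal))  # 1/ms
        decay = np.exp(-te[:, None] * r2_app[None, :])  # (ne, n_off)
        sat[mask] = tube.pd * z.signal[None, :] * decay[None, :, :]
        s0[mask] = tube.pd * np.exp(-te / t2_ms)[None, :, None]

    sigma = float(np.mean([t.pd for t in spec.tubes])) * np.exp(
        -te[0] / np.mean(tube_t2)
    ) / snr
    if noise != "none":
        sat = add_noise(sat, sigma, noise, rng)
        s0 = add_noise(s0, sigma, noise, rng)

    stack = MultiEchoStack(sat, echo_train, offsets=offsets)
    s0_stack = MultiEchoStack(s0, echo_train, offsets=None)
    return {
        "stack": stack,
        "s0_stack": s0_stack,
        "masks": masks,
        "truth": {
            "offsets": offsets,
            "spectra": spectra,
            "tube_t2_ms": np.asarray(tube_t2),
            "conc": np.asarray([t.conc for t in spec.tubes]),
        },
    }
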