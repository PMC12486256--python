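"""Voxel-wise mono-exponential T2 / saturation-weighted PD mapping.

Each voxel of a multi-echo magnitude stack follows ``S(TE) = PD *
exp(-TE / T2)``; the amplitude is the saturation-weighted proton density
(the post-saturation magnetization before readout decay). Fitting is
vectorized across voxels: a log-linear weighted least-squares solution,
optionally refined by damped Gauss-Newton iterations in signal space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from mpcest.bmc import ZSpectrum

__all__ = [
    "EchoTrain",
    "MultiEchoStack",
    "ParameterMaps",
    "fit_t2_pd",
    "fit_monoexp",
    "default_mask",
    "pd_zspectrum",
    "spectrum_fwhm",
]

#: Acquisition default: 5 echoes, 25 ms spacing.
DEFAULT_N_ECHOES = 5
DEFAULT_SPACING_MS = 25.0

#: Voxels whose first-echo intensity falls below this fraction of the
#: image's 99th percentile are excluded from fitting (noise floor).
MASK_FRACTION = 0.05


@dataclass(frozen=True)
class EchoTrain:
    """Echo-time vector of the multi-echo readout (ms).

    ``te_eff`` defaults to integer multiples of the spacing; arbitrary
    user-supplied vectors are accepted (they must be strictly increasing).
    """

    n_echoes: int = DEFAULT_N_ECHOES
    spacing: float = DEFAULT_SPACING_MS
    te_eff: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.te_eff is None:
            object.__setattr__(
                self,
                "te_eff",
                tuple((i + 1) * self.spacing for i in range(self.n_echoes)),
            )
        else:
            object.__setattr__(self, "te_eff", tuple(float(t) for t in self.te_eff))
        if len(self.te_eff) != self.n_echoes:
            raise ValueError("te_eff length must equal n_echoes")
        if np.any(np.diff(self.te_eff) <= 0):
            raise ValueError("te_eff must be strictly increasing")

    @property
    def te(self) -> np.ndarray:
        return np.asarray(self.te_eff, dtype=float)


@dataclass
class MultiEchoStack:
    """Magnitude image stack indexed ``(row, col, echo[, offset, time])``."""

    data: np.ndarray
    echo_train: EchoTrain
    offsets: np.ndarray | None = None
    time: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim < 3:
            raise ValueError(
                "stack must have at least (row, col, echo) axes; echo axis missing"
            )
        if self.data.shape[2] != self.echo_train.n_echoes:
            raise ValueError(
                f"echo axis has length {self.data.shape[2]}, expected "
                f"{self.echo_train.n_echoes}"
            )
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")
        if self.offsets is not None:
            self.offsets = np.asarray(self.offsets, dtype=float)
            if self.data.ndim < 4 or self.data.shape[3] != self.offsets.size:
                raise ValueError("offset axis length does not match offsets metadata")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            if self.data.ndim < 5 or self.data.shape[4] != self.time.size:
                raise ValueError("time axis length does not match time metadata")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValueError("mask shape must match the spatial grid")

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class ParameterMaps:
    """Fitted saturation-weighted PD and T2 (ms) with per-voxel fit quality."""

    pd: np.ndarray
    t2: np.ndarray
    fit_quality: np.ndarray
    mask: np.ndarray


def default_mask(first_echo: np.ndarray, fraction: float = MASK_FRACTION) -> np.ndarray:
    """Noise-floor mask: keep voxels above ``fraction`` of the 99th percentile."""
    threshold = fraction * np.nanpercentile(first_echo, 99)
    return np.asarray(first_echo, dtype=float) > threshold


def _loglinear(y: np.ndarray, te: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted log-linear solution; returns (amplitude, decay rate 1/ms)."""
    ly = np.where(w > 0, np.log(np.where(y > 0, y, 1.0)), 0.0)
    sw = w.sum(axis=-1)
    swt = (w * te).sum(axis=-1)
    swtt = (w * te * te).sum(axis=-1)
    swy = (w * ly).sum(axis=-1)
    swty = (w * te * ly).sum(axis=-1)
    det = sw * swtt - swt * swt
    det = np.where(det > 0, det, np.nan)
    slope = (sw * swty - swt * swy) / det
    intercept = (swtt * swy - swt * swty) / det
    rate = np.clip(-slope, 1e-8, None)
    return np.exp(intercept), rate


def fit_monoexp(
    y: np.ndarray,
    te: np.ndarray,
    method: str = "nonlinear",
    weights: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``A * exp(-te * r)`` voxel-wise over the trailing axis of ``y``.

    Returns ``(amplitude, rate, r_squared, valid)``. Echo samples that are
    non-positive or non-finite are excluded per voxel; voxels with fewer
    than two usable samples are flagged invalid. The nonlinear mode is a
    damped Gauss-Newton refinement initialized from the log-linear fit.
    """
    if method not in ("log-linear", "nonlinear"):
        raise ValueError(f"unknown method {method!r}")
    y = np.asarray(y, dtype=float)
    te = np.asarray(te, dtype=float)
    if te.size < 2:
        raise ValueError("at least two echoes required")
    w = np.isfinite(y) & (y > 0)
    w = w.astype(float)
    if weights is not None:
        w = w * np.asarray(weights, dtype=float)
    valid = (w > 0).sum(axis=-1) >= 2

    amp, rate = _loglinear(y, te, w)
    valid &= np.isfinite(amp) & np.isfinite(rate)

    if method == "nonlinear":
        a = np.where(valid, amp, 1.0)
        r = np.where(valid, rate, 1e-3)
        yw = np.where(w > 0, y, 0.0)
        for _ in range(max_iter):
            e = np.exp(-te * r[..., None])
            model = a[..., None] * e
            res = np.where(w > 0, model - yw, 0.0)
            # jacobian columns d/dA = e, d/dr = -A te e
            j1 = w * e
            j2 = w * (-a[..., None] * te * e)
            g11 = (j1 * j1).sum(axis=-1)
            g12 = (j1 * j2).sum(axis=-1)
            g22 = (j2 * j2).sum(axis=-1) + 1e-300
            b1 = (j1 * res).sum(axis=-1)
            b2 = (j2 * res).sum(axis=-1)
            det = g11 * g22 - g12 * g12
            det = np.where(np.abs(det) > 0, det, np.nan)
            da = -(g22 * b1 - g12 * b2) / det
            dr = -(g11 * b2 - g12 * b1) / det
            da = np.where(np.isfinite(da), da, 0.0)
            dr = np.where(np.isfinite(dr), dr, 0.0)
            # damped update keeping the decay rate positive
            new_r = np.clip(r + dr, 0.1 * r, 10.0 * r)
            new_a = np.clip(a + da, 0.0, None)
            step = np.maximum(
                np.abs(new_a - a) / np.maximum(np.abs(a), 1e-30),
                np.abs(new_r - r) / np.maximum(np.abs(r), 1e-30),
            )
            a, r = new_a, new_r
            if np.nanmax(np.where(valid, step, 0.0)) < tol:
                break
        amp, rate = a, r

    e = np.exp(-te * rate[..., None])
    model = amp[..., None] * e
    res2 = (w * (model - np.where(w > 0, y, 0.0)) ** 2).sum(axis=-1)
    mean = (w * y).sum(axis=-1) / np.maximum(w.sum(axis=-1), 1.0)
    tot = (w * (np.where(w > 0, y, 0.0) - mean[..., None]) ** 2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tot > 0, 1.0 - res2 / tot, np.where(res2 <= 1e-20, 1.0, 0.0))
    r2 = np.clip(r2, 0.0, 1.0)
    return amp, rate, r2, valid


def fit_t2_pd(
    stack: MultiEchoStack,
    method: str = "nonlinear",
    mask: np.ndarray | None = None,
) -> ParameterMaps:
    """Fit PD and T2 maps from a multi-echo stack.

    Extra trailing axes (offset, time) are fitted independently and carried
    through to the output maps. The returned T2 is in milliseconds.
    """
    data = np.moveaxis(stack.data, 2, -1)  # (..., echo) last
    if mask is None:
        mask = stack.mask
    if mask is None:
        first = stack.data[:, :, 0, ...]
        # pool all extra axes when deriving the noise-floor threshold
        mask = default_mask(first.reshape(stack.grid + (-1,)).max(axis=-1))
    amp, rate, r2, valid = fit_monoexp(data, stack.echo_train.te, method=method)
    full_mask = valid & mask.reshape(mask.shape + (1,) * (data.ndim - 3))
    if not np.any(full_mask):
        raise ValueError("no valid voxels to fit")
    t2 = np.where(full_mask, 1.0 / rate, np.nan)
    pd = np.where(full_mask, amp, np.nan)
    return ParameterMaps(pd=pd, t2=t2, fit_quality=r2, mask=full_mask)


def pd_zspectrum(
    maps_per_offset: Sequence[ParameterMaps],
    unsaturated: ParameterMaps,
    offsets: Sequence[float],
    roi: np.ndarray | None = None,
):
    """Normalized Z-spectrum from per-offset PD maps.

    ``S(offset) = PD_sat(offset) / PD_unsat`` per voxel. With ``roi`` given,
    voxel PDs are averaged within the mask before the ratio is taken and a
    single :class:`~mpcest.bmc.ZSpectrum` is returned; otherwise a
    ``(row, col, n_offsets)`` signal array is returned with invalid voxels
    set to NaN.
    """
    offsets = np.asarray(offsets, dtype=float)
    if len(maps_per_offset) != offsets.size:
        raise ValueError("one ParameterMaps per offset required")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool) & unsaturated.mask
        denom = float(np.nanmean(unsaturated.pd[roi]))
        if not np.isfinite(denom) or denom <= 0:
            raise ValueError("invalid unsaturated reference in ROI")
        sig = np.array(
            [float(np.nanmean(m.pd[roi & m.mask])) / denom for m in maps_per_offset]
        )
        return ZSpectrum(offsets, sig)
    denom = np.where(unsaturated.mask & (unsaturated.pd > 0), unsaturated.pd, np.nan)
    out = np.stack([m.pd / denom for m in maps_per_offset], axis=-1)
    return out


def spectrum_fwhm(z: ZSpectrum) -> float:
    """Full width at half maximum of the Z-spectrum saturation dip (ppm).

    The dip depth is measured between the spectrum minimum and the
    far-offset baseline (mean of the two edge samples); crossings of the
    half-depth level are located by linear interpolation on each side.
    """
    asc = z.ascending
    s = asc.signal
    x = asc.offsets
    if s.size < 3:
        raise ValueError("spectrum too short to measure a width")
    i_min = int(np.argmin(s))
    baseline = 0.5 * (s[0] + s[-1])
    depth = baseline - s[i_min]
    if i_min in (0, s.size - 1) or depth <= 0 or np.isclose(depth, 0.0):
        raise ValueError("no saturation dip bracketed by the offset grid")
    half = s[i_min] + 0.5 * depth

    def crossing(idx: np.ndarray) -> float | None:
        # first crossing of the half level walking away from the minimum
        for a, b in zip(idx[:-1], idx[1:]):
            if (s[a] - half) * (s[b] - half) <= 0 and s[a] != s[b]:
                t = (half - s[a]) / (s[b] - s[a])
                return float(x[a] + t * (x[b] - x[a]))
        return None

    left = crossing(np.arange(i_min, -1, -1))
    right = crossing(np.arange(i_min, s.size))
    if left is None or right is None:
        raise ValueError("half-depth level not crossed on both sides of the dip")
    return abs(right - left)
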