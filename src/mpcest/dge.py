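"""Dynamic glucose-enhanced (DGE) signal quantification.

Normalized signals are saturation-to-baseline ratios ``S = Z / Z0``. Two
quantification modes are supported:

* single-offset DGE: ``dge(t) = 100 * (S_baseline - S(t)) / S_baseline``,
  so glucose uptake (more saturation, lower S) is positive;
* MTR_asym DGE: ``dge_asym(t) = 100 * (MTR_asym(t) - baseline MTR_asym)``
  with ``MTR_asym = S(-offset) - S(+offset)`` on the normalized spectrum.

Both are referenced to the mean over the pre-injection baseline frames, so
the baseline average of either metric is zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from mpcest.bmc import ZSpectrum

__all__ = [
    "DgeSeries",
    "MrsQuant",
    "normalize",
    "single_offset_dge",
    "mtr_asym",
    "mtr_asym_dge",
    "mrs_delta_glc",
    "DEFAULT_DGE_OFFSET_PPM",
]

#: Quantification offset on the glucose (downfield) side.
DEFAULT_DGE_OFFSET_PPM = 1.2

#: Methyl (tCr, 3 protons) to glucose H2-H6 (5 protons) ratio.
MRS_PROTON_RATIO = 3.0 / 5.0


@dataclass
class DgeSeries:
    """Per-timepoint normalized signals and derived DGE metrics.

    ``signal`` holds the normalized saturated signal at the quantification
    offset; ``mtr_asym`` (if set) the per-timepoint asymmetry. ``dge`` and
    ``dge_asym`` are filled by :func:`single_offset_dge` and
    :func:`mtr_asym_dge` (percent units).
    """

    time: np.ndarray
    signal: np.ndarray
    baseline_idx: np.ndarray
    offset: float = DEFAULT_DGE_OFFSET_PPM
    mtr_asym: np.ndarray | None = None
    dge: np.ndarray | None = None
    dge_asym: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.baseline_idx = np.asarray(self.baseline_idx, dtype=int)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if self.baseline_idx.size == 0:
            raise ValueError("baseline_idx must be non-empty")
        if self.baseline_idx.min() < 0 or self.baseline_idx.max() >= self.time.size:
            raise ValueError("baseline_idx out of range")
        post = np.setdiff1d(np.arange(self.time.size), self.baseline_idx)
        if post.size and post.min() < self.baseline_idx.max():
            # baseline frames must precede every post-injection frame
            if np.any(post < self.baseline_idx.min()):
                raise ValueError("baseline frames must precede post-injection frames")
        if self.mtr_asym is not None:
            self.mtr_asym = np.asarray(self.mtr_asym, dtype=float)
            if self.mtr_asym.shape != self.time.shape:
                raise ValueError("mtr_asym must match the time axis")

    @property
    def n_frames(self) -> int:
        return int(self.time.size)


def normalize(saturated: np.ndarray, unsaturated: np.ndarray) -> np.ndarray:
    """Saturation-to-baseline ratio ``S = Z / Z0``; invalid where Z0 <= 0."""
    saturated = np.asarray(saturated, dtype=float)
    unsaturated = np.asarray(unsaturated, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = saturated / unsaturated
    return np.where(unsaturated > 0, s, np.nan)


def single_offset_dge(series: DgeSeries) -> DgeSeries:
    """Fill ``dge``: percent signal drop relative to the baseline mean.

    NaN signals propagate to NaN timepoints; the baseline mean uses only
    finite baseline samples and must contain at least one.
    """
    base = series.signal[series.baseline_idx]
    base = base[np.isfinite(base)]
    if base.size == 0:
        raise ValueError("no finite baseline signal available")
    s_baseline = float(base.mean())
    if s_baseline <= 0:
        raise ValueError("baseline signal must be positive")
    dge = 100.0 * (s_baseline - series.signal) / s_baseline
    return replace(series, dge=dge)


def mtr_asym(z: ZSpectrum, offset: float = DEFAULT_DGE_OFFSET_PPM) -> float:
    """Z-spectrum asymmetry ``S(-offset) - S(+offset)``.

    Spectra are already normalized, so the asymmetry is a plain difference;
    off-grid offsets are linearly interpolated.
    """
    if offset <= 0:
        raise ValueError("asymmetry offset must be positive")
    return z.at(-offset) - z.at(+offset)


def mtr_asym_dge(series: DgeSeries) -> DgeSeries:
    """Fill ``dge_asym``: percent change of MTR_asym from its baseline mean."""
    if series.mtr_asym is None:
        raise ValueError("series has no per-timepoint MTR_asym")
    base = series.mtr_asym[series.baseline_idx]
    base = base[np.isfinite(base)]
    if base.size == 0:
        raise ValueError("no finite baseline MTR_asym available")
    dge_asym = 100.0 * (series.mtr_asym - float(base.mean()))
    return replace(series, dge_asym=dge_asym)


@dataclass(frozen=True)
class MrsQuant:
    """Difference-spectrum glucose quantification against total creatine."""

    ratio: float
    tcr_conc: float
    proton_ratio: float = MRS_PROTON_RATIO

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("area ratio must be >= 0")
        if self.tcr_conc <= 0:
            raise ValueError("tCr concentration must be > 0")


def mrs_delta_glc(q: MrsQuant) -> float:
    """Glucose concentration change (mM): ``(3/5) * R_Glc/tCr * [tCr]``."""
    return q.proton_ratio * q.ratio * q.tcr_conc
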