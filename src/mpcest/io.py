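"""File formats: NIfTI stacks with JSON sidecars, CSV tables, model JSON.

Conventions: NIfTI axes are ordered (row, col, echo[, offset, time]) and a
sidecar ``<name>.json`` carries ``te_ms`` plus optional ``offsets_ppm`` and
``time_s``; CSV files are comma-separated with '.' decimals and '#'-prefixed
metadata lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from mpcest.bmc import ZSpectrum
from mpcest.correction import CorrectionModel, DynamicT2
from mpcest.dge import DgeSeries
from mpcest.relaxometry import EchoTrain, MultiEchoStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_zspectrum",
    "read_zspectrum",
    "write_series",
    "read_series",
    "write_model",
    "read_model",
    "write_dynamic_t2",
    "read_dynamic_t2",
    "write_run_config",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_stack(path: str | Path, stack: MultiEchoStack) -> Path:
    """Write a stack as NIfTI plus JSON sidecar; returns the image path."""
    path = Path(path)
    if not (path.name.endswith(".nii") or path.name.endswith(".nii.gz")):
        path = path.with_suffix(".nii")
    nib.save(nib.Nifti1Image(stack.data, affine=np.eye(4)), str(path))
    meta: dict = {"te_ms": list(stack.echo_train.te)}
    if stack.offsets is not None:
        meta["offsets_ppm"] = stack.offsets.tolist()
    if stack.time is not None:
        meta["time_s"] = stack.time.tolist()
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path) -> MultiEchoStack:
    """Read a NIfTI stack, validating metadata against the array shape."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "te_ms" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks required key 'te_ms'")
    data = np.asarray(nib.load(str(path)).get_fdata())
    if data.ndim < 3:
        raise ValueError(
            f"{path}: expected (row, col, echo[, offset, time]) axes, "
            f"got {data.ndim}-D data (echo axis missing)"
        )
    te = meta["te_ms"]
    if data.shape[2] != len(te):
        raise ValueError(
            f"{path}: echo axis length {data.shape[2]} does not match "
            f"{len(te)} te_ms entries"
        )
    train = EchoTrain(n_echoes=len(te), spacing=float(te[0]), te_eff=tuple(te))
    offsets = meta.get("offsets_ppm")
    time = meta.get("time_s")
    return MultiEchoStack(
        data,
        train,
        offsets=np.asarray(offsets, dtype=float) if offsets is not None else None,
        time=np.asarray(time, dtype=float) if time is not None else None,
    )


def write_zspectrum(path: str | Path, z: ZSpectrum, meta: dict | None = None) -> None:
    lines = [f"# {k}: {v}" for k, v in (meta or {}).items()]
    lines.append("offset_ppm,signal")
    lines += [f"{float(o)!r},{float(s)!r}" for o, s in zip(z.offsets, z.signal)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_zspectrum(path: str | Path) -> ZSpectrum:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return ZSpectrum(df["offset_ppm"].to_numpy(), df["signal"].to_numpy())


_SERIES_COLUMNS = {
    "signal": "S",
    "dge": "dge_pct",
    "mtr_asym": "mtr_asym",
    "dge_asym": "dge_asym_pct",
}


def write_series(path: str | Path, series: DgeSeries, extra: dict | None = None) -> None:
    """DGE time course as CSV (time_s, offset_ppm, S, dge_pct, ...)."""
    out = {"time_s": series.time, "offset_ppm": np.full(series.n_frames, series.offset)}
    for attr, col in _SERIES_COLUMNS.items():
        val = getattr(series, attr)
        if val is not None:
            out[col] = val
    for col, val in (extra or {}).items():
        out[col] = val
    header = f"# n_baseline: {series.baseline_idx.size}\n"
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(out).to_csv(fh, index=False)


def read_series(path: str | Path) -> DgeSeries:
    n_baseline = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "n_baseline" in line:
                n_baseline = int(line.split(":")[1])
            if not line.startswith("#"):
                break
    if n_baseline is None:
        raise ValueError(f"{path}: missing '# n_baseline:' metadata line")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    series = DgeSeries(
        time=df["time_s"].to_numpy(),
        signal=df["S"].to_numpy(),
        baseline_idx=np.arange(n_baseline),
        offset=float(df["offset_ppm"].iloc[0]),
        mtr_asym=df["mtr_asym"].to_numpy() if "mtr_asym" in df else None,
    )
    if "dge_pct" in df:
        series.dge = df["dge_pct"].to_numpy()
    if "dge_asym_pct" in df:
        series.dge_asym = df["dge_asym_pct"].to_numpy()
    return series


def write_dynamic_t2(path: str | Path, t2: DynamicT2) -> None:
    header = f"# n_baseline: {t2.baseline_idx.size}\n"
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame({"time_s": t2.time, "t2_ms": t2.t2}).to_csv(fh, index=False)


def read_dynamic_t2(path: str | Path) -> DynamicT2:
    n_baseline = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "n_baseline" in line:
                n_baseline = int(line.split(":")[1])
            if not line.startswith("#"):
                break
    if n_baseline is None:
        raise ValueError(f"{path}: missing '# n_baseline:' metadata line")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return DynamicT2(
        time=df["time_s"].to_numpy(),
        t2=df["t2_ms"].to_numpy(),
        baseline_idx=np.arange(n_baseline),
    )


def write_model(path: str | Path, model: CorrectionModel, seed: int | None = None) -> None:
    from mpcest import __version__

    payload = model.to_dict()
    payload["version"] = __version__
    if seed is not None:
        payload["seed"] = seed
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model(path: str | Path) -> CorrectionModel:
    return CorrectionModel.from_dict(json.loads(Path(path).read_text()))


def write_run_config(out_dir: str | Path, config: dict) -> Path:
    """Persist the resolved run configuration next to the outputs."""
    from mpcest import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_config.yaml"
    path.write_text(yaml.safe_dump({"version": __version__, **config}, sort_keys=True))
    return path
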