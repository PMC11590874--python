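"""Two-distance fNIRS artifact reduction.

A wearable probe measures total-hemoglobin change at two source-detector
separations: ~1 cm (shallow; scalp and systemic physiology only) and
~3 cm (deep; cortex plus the same shallow components).  The neural
component is extracted in two steps, in order:

1. linear detrending of each channel (removes slow drift);
2. short-channel regression of the deep channel on the shallow channel,

      x_deep = a0 + a1 * x_shallow + x_neural,

   keeping the OLS residual as the neural signal and (a0, a1, r^2) as
   fit metadata.

The residual is exactly orthogonal to the shallow regressor and to the
constant, so repeating the operation is a no-op.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FnirsRecording",
    "NeuralSignal",
    "linear_detrend",
    "dual_regression",
    "read_fnirs_csv",
    "write_neural_csv",
]


@dataclass(frozen=True)
class FnirsRecording:
    """One participant's two-channel recording (total-Hb change, mM*mm)."""

    shallow: np.ndarray
    deep: np.ndarray
    fs: float
    probe_side: str = "left"

    def __post_init__(self) -> None:
        shallow = np.asarray(self.shallow, dtype=float)
        deep = np.asarray(self.deep, dtype=float)
        if shallow.shape != deep.shape or shallow.ndim != 1:
            raise ValueError(
                f"shallow/deep must be 1-D and equal length, got {shallow.shape} vs {deep.shape}"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.probe_side not in ("left", "right"):
            raise ValueError(f"probe_side must be 'left' or 'right', got {self.probe_side!r}")
        object.__setattr__(self, "shallow", shallow)
        object.__setattr__(self, "deep", deep)

    def __len__(self) -> int:
        return len(self.deep)


@dataclass(frozen=True)
class NeuralSignal:
    """Residual neural series after detrending and short-channel regression."""

    values: np.ndarray
    fs: float
    a0: float = 0.0
    a1: float = 0.0
    r_squared: float = 0.0
    degenerate_shallow: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


def linear_detrend(series: np.ndarray) -> np.ndarray:
    """Residual after least-squares removal of an intercept + linear trend.

    The output has zero mean and zero correlation with the sample index.
    A constant or too-short series yields an all-zero residual with a
    warning (the fit is degenerate but the drift-free content is nil).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(x) < 3 or np.ptp(x) == 0:
        warnings.warn("degenerate detrend (constant or <3 samples); returning zeros")
        return np.zeros_like(x)
    t = np.arange(len(x), dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ coef


def dual_regression(rec: FnirsRecording, detrend: bool = True) -> NeuralSignal:
    """Short-channel regression of the deep channel on the shallow channel.

    Both channels are linearly detrended first (skip with
    ``detrend=False`` for pre-detrended input), then deep is regressed
    on shallow by OLS with intercept; the residual is the neural signal.
    A zero-variance shallow channel cannot serve as a regressor: the
    detrended deep channel is returned unchanged with
    ``degenerate_shallow=True``.
    """
    if detrend:
        shallow = linear_detrend(rec.shallow) if np.ptp(rec.shallow) > 0 else np.zeros(len(rec))
        deep = linear_detrend(rec.deep)
    else:
        shallow, deep = rec.shallow.astype(float), rec.deep.astype(float)
    if np.ptp(shallow) == 0:
        return NeuralSignal(values=deep, fs=rec.fs, a0=float(deep.mean()), a1=0.0,
                            r_squared=0.0, degenerate_shallow=True)
    design = np.column_stack([np.ones_like(shallow), shallow])
    coef, *_ = np.linalg.lstsq(design, deep, rcond=None)
    resid = deep - design @ coef
    ss_tot = float(((deep - deep.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return NeuralSignal(values=resid, fs=rec.fs, a0=float(coef[0]), a1=float(coef[1]),
                        r_squared=r2)


FNIRS_COLUMNS = ["dyad_id", "participant_id", "probe_side", "t_s", "shallow", "deep"]


def read_fnirs_csv(path: "str | Path") -> dict:
    """Read a two-channel recording file.

    Returns ``{(participant_id, probe_side): FnirsRecording}``; the
    sampling rate is inferred from the time stamps.
    """
    df = pd.read_csv(path)
    missing = [c for c in FNIRS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fNIRS file {path} missing columns {missing}")
    out: dict = {}
    for (pid, side), group in df.groupby(["participant_id", "probe_side"], sort=True):
        group = group.sort_values("t_s")
        t = group["t_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"participant {pid!r}/{side}: too few samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"participant {pid!r}/{side}: non-uniform sampling")
        out[(pid, side)] = FnirsRecording(
            shallow=group["shallow"].to_numpy(),
            deep=group["deep"].to_numpy(),
            fs=1.0 / dt[0],
            probe_side=side,
        )
    return out


def write_fnirs_csv(path: "str | Path", dyad_id, participant_id, rec: FnirsRecording) -> None:
    pd.DataFrame(
        {
            "dyad_id": dyad_id,
            "participant_id": participant_id,
            "probe_side": rec.probe_side,
            "t_s": np.arange(len(rec)) / rec.fs,
            "shallow": rec.shallow,
            "deep": rec.deep,
        }
    ).to_csv(path, index=False)


def write_neural_csv(path: "str | Path", dyad_id, participant_id, sig: NeuralSignal) -> None:
    """Write a cleaned neural series, with fit metadata in a JSON sidecar."""
    path = Path(path)
    pd.DataFrame(
        {
            "dyad_id": dyad_id,
            "participant_id": participant_id,
            "t_s": np.arange(len(sig)) / sig.fs,
            "neural": sig.values,
        }
    ).to_csv(path, index=False)
    meta = {
        "dyad_id": str(dyad_id),
        "participant_id": str(participant_id),
        "fs_hz": sig.fs,
        "a0": sig.a0,
        "a1": sig.a1,
        "r_squared": sig.r_squared,
        "degenerate_shallow": sig.degenerate_shallow,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
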