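"""Per-second behavior codes and the Duchenne-smiling-with-gaze index.

Facial behavior is coded second by second over the analysis window
(by default the final 300 s of conversation before the game): each
second carries a binary Duchenne-smile code (orbicularis-oculi
involvement, AU 6 + 12) and a binary gaze code (1 = looking at the
partner).  Smiling-with-gaze is the conjunction of the two codes; its
proportion of the observation time, averaged over the two members of a
dyad, is the dyadic index used downstream.

Inter-coder reliability is an intraclass correlation from the two-way
ANOVA mean-squares decomposition, computed per doubly-coded clip and
averaged across clips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CodeSeries",
    "SmileGazeIndex",
    "combine_smile_gaze",
    "proportion",
    "dyad_index",
    "icc_reliability",
    "read_behavior_csv",
    "write_behavior_csv",
]


@dataclass(frozen=True)
class CodeSeries:
    """A binary presence/absence code, one entry per second."""

    values: np.ndarray
    duration_s: int = 300

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=int)
        if values.ndim != 1:
            raise ValueError("code series must be one-dimensional")
        if len(values) != self.duration_s:
            raise ValueError(
                f"series length {len(values)} does not match duration {self.duration_s} s"
            )
        if not np.isin(values, (0, 1)).all():
            raise ValueError("code series entries must be 0 or 1")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.duration_s


@dataclass(frozen=True)
class SmileGazeIndex:
    """Per-participant and dyad-mean smiling-with-gaze proportions."""

    p_a: float
    p_b: float
    dyad_mean: float = field(init=False)

    def __post_init__(self) -> None:
        for p in (self.p_a, self.p_b):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion {p} outside [0, 1]")
        object.__setattr__(self, "dyad_mean", (self.p_a + self.p_b) / 2.0)


def combine_smile_gaze(smile: CodeSeries, gaze: CodeSeries) -> CodeSeries:
    """Element-wise AND: 1 only in seconds with both a Duchenne smile and gaze."""
    if smile.duration_s != gaze.duration_s:
        raise ValueError(
            f"cannot align smile ({smile.duration_s} s) with gaze ({gaze.duration_s} s)"
        )
    return CodeSeries(values=smile.values & gaze.values, duration_s=smile.duration_s)


def proportion(series: CodeSeries) -> float:
    """Fraction of observed seconds in which the code was present."""
    if series.duration_s == 0:
        raise ValueError("cannot take the proportion of an empty series")
    return float(series.values.sum() / series.duration_s)


def dyad_index(p_a: float, p_b: float) -> SmileGazeIndex:
    """Dyadic index: arithmetic mean of the two members' proportions."""
    return SmileGazeIndex(p_a=p_a, p_b=p_b)


def _mean_squares(data: np.ndarray) -> tuple[float, float, float, float]:
    """Two-way ANOVA mean squares for an n-subject x k-rater table.

    Returns (MSR, MSC, MSE, MSW): rows (subjects), columns (raters),
    residual, and within-subject mean squares.
    """
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_total - ss_rows) / (n * (k - 1))
    return msr, msc, mse, msw


def _icc_single(data: np.ndarray, variant: str) -> float:
    n, k = data.shape
    if n < 2:
        raise ValueError("ICC requires at least 2 subjects")
    if np.ptp(data) == 0:
        raise ValueError("ICC undefined: all codes identical (zero variance)")
    msr, msc, mse, msw = _mean_squares(data)
    if variant == "icc1":
        denom = msr + (k - 1) * msw
        value = (msr - msw) / denom
    elif variant == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        value = (msr - mse) / denom
    elif variant == "icc3":
        denom = msr + (k - 1) * mse
        value = (msr - mse) / denom
    else:
        raise ValueError(f"unknown ICC variant {variant!r}; expected icc1, icc2 or icc3")
    if denom <= 0:
        raise ValueError("ICC undefined: non-positive denominator (zero variance)")
    return float(value)


def icc_reliability(
    coder1: "Sequence[CodeSeries] | CodeSeries",
    coder2: "Sequence[CodeSeries] | CodeSeries",
    variant: str = "icc2",
) -> float:
    """Inter-coder reliability of paired codings of the same clips.

    Each clip's seconds are the ANOVA subjects and the two coders the
    raters; the default variant is ICC(2,1), the two-way random-effects,
    single-rater, absolute-agreement coefficient

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).

    The per-clip coefficients are averaged pairwise across clips.
    ``variant`` may also be ``icc1`` (one-way random) or ``icc3``
    (two-way mixed, consistency).
    """
    if isinstance(coder1, CodeSeries):
        coder1 = [coder1]
    if isinstance(coder2, CodeSeries):
        coder2 = [coder2]
    if len(coder1) != len(coder2):
        raise ValueError(
            f"coders rated different numbers of clips: {len(coder1)} vs {len(coder2)}"
        )
    if not coder1:
        raise ValueError("no clips to assess reliability on")
    iccs = []
    for clip_a, clip_b in zip(coder1, coder2):
        if clip_a.duration_s != clip_b.duration_s:
            raise ValueError("paired codings must cover the same clip duration")
        data = np.column_stack([clip_a.values, clip_b.values]).astype(float)
        iccs.append(_icc_single(data, variant))
    return float(np.mean(iccs))


BEHAVIOR_COLUMNS = ["dyad_id", "participant_id", "second", "smile", "gaze", "coder_id"]


def read_behavior_csv(
    path: "str | Path",
    window_s: int = 300,
    coder_id: "str | int | None" = None,
) -> dict:
    """Read per-second smile/gaze codes, slicing the last ``window_s`` seconds.

    Recordings may cover the full conversation (e.g. 600 s); the analysis
    window is the final ``window_s`` seconds directly before the game.
    Returns ``{participant_id: (smile CodeSeries, gaze CodeSeries)}``.
    """
    df = pd.read_csv(path)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"behavior file {path} missing columns {missing}")
    if coder_id is not None:
        df = df[df["coder_id"] == coder_id]
    out: dict = {}
    for pid, group in df.groupby("participant_id", sort=True):
        group = group.sort_values("second")
        total = len(group)
        if total < window_s:
            raise ValueError(
                f"participant {pid!r}: {total} coded seconds < window of {window_s} s"
            )
        tail = group.iloc[total - window_s :]
        out[pid] = (
            CodeSeries(tail["smile"].to_numpy(), duration_s=window_s),
            CodeSeries(tail["gaze"].to_numpy(), duration_s=window_s),
        )
    return out


def write_behavior_csv(
    path: "str | Path",
    dyad_id,
    participant_id,
    smile: CodeSeries,
    gaze: CodeSeries,
    coder_id="c1",
) -> None:
    pd.DataFrame(
        {
            "dyad_id": dyad_id,
            "participant_id": participant_id,
            "second": np.arange(smile.duration_s),
            "smile": smile.values,
            "gaze": gaze.values,
            "coder_id": coder_id,
        }
    ).to_csv(path, index=False)


def smile_gaze_dyad_index(
    member_codes: Iterable[tuple[CodeSeries, CodeSeries]],
) -> SmileGazeIndex:
    """Dyadic smiling-with-gaze index from both members' (smile, gaze) codes."""
    props = [proportion(combine_smile_gaze(smile, gaze)) for smile, gaze in member_codes]
    if len(props) != 2:
        raise ValueError(f"a dyad needs exactly 2 members, got {len(props)}")
    return dyad_index(props[0], props[1])
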