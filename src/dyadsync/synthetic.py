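"""Seeded synthetic dyad cohorts with the structure the analysis assumes.

No public dataset accompanies this kind of dyadic hyperscanning design,
so every pipeline stage is exercised on simulated cohorts built from a
single seeded generator.  Per dyad ``d``:

* a latent trait ``x_d ~ N(0, 1)`` (cooperativeness);
* latent mediators and outcome follow a linear structural model on the
  standardized scale, ``m1 = b_xm1 x + e1`` (smiling-with-gaze
  propensity), ``m2 = b_xm2 x + e2`` (synchrony propensity),
  ``y = b_xy x + b_m1y m1 + b_m2y m2 + ey`` with residual variances
  chosen so every latent has unit variance;
* pre- and post-conversation offers are a clamped, quantized affine map
  of ``x`` (resp. ``y``) plus per-participant noise;
* smile and gaze codes are two-state Markov chains (bouts, not i.i.d.
  coin flips) whose stationary ON-probability increases with ``m1``
  through a logistic link;
* each member's neural series mixes a dyad-shared band-limited
  component (0.04-0.06 Hz by default) with idiosyncratic 1/f-like
  noise; the mixing weight grows with the ``coupling`` parameter and,
  through ``m2``, varies across dyads (coupling = 0 means no shared
  signal at all);
* the measured channels add a shallow systemic signal, a linear trend
  and the short-channel contamination ``deep = a0 + a1 shallow +
  neural + trend``.

The per-dyad latents are retained as ground truth for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from dyadsync.behavior import CodeSeries, write_behavior_csv
from dyadsync.fnirs import FnirsRecording
from dyadsync.pd_game import ENDOWMENT

__all__ = ["CohortConfig", "DyadRecord", "SyntheticCohort", "generate_cohort", "write_cohort", "read_manifest"]


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults mirror the study conditions.

    45 dyads, 36 of them with usable fNIRS; 600 s conversations sampled
    at 10 Hz with the final 300 s as the analysis window; structural
    effects (standardized): trait -> behavior 0.64, trait -> smiling
    0.35, all synchrony paths 0.
    """

    n_dyads: int = 45
    n_fnirs_dyads: int = 36
    fs_hz: float = 10.0
    conversation_s: int = 600
    coding_window_s: int = 300
    # structural paths (standardized scale)
    beta_xy: float = 0.64
    beta_xm1: float = 0.35
    beta_xm2: float = 0.0
    beta_m1y: float = 0.0
    beta_m2y: float = 0.0
    # neural coupling
    coupling: float = 0.3
    coupling_latent_slope: float = 0.4
    shared_band_hz: tuple = (0.04, 0.06)
    neural_sd: float = 0.02
    shallow_sd: float = 0.05
    trend_sd: float = 0.03
    a0_range: tuple = (-0.02, 0.02)
    a1_range: tuple = (0.8, 1.2)
    include_right_probe: bool = True
    # offers
    offer_step: int = 10
    offer_noise_sd: float = 0.15
    # behavior codes
    smile_base_rate: float = 0.15
    gaze_base_rate: float = 0.65
    smile_latent_slope: float = 0.9
    gaze_latent_slope: float = 0.4
    smile_dwell_s: float = 3.0
    gaze_dwell_s: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_fnirs_dyads <= self.n_dyads:
            raise ValueError("need 0 < n_fnirs_dyads <= n_dyads")
        if self.coding_window_s > self.conversation_s:
            raise ValueError("coding window cannot exceed the conversation length")
        for name in ("coupling", "smile_base_rate", "gaze_base_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.shared_band_hz
        if not 0 < lo < hi <= self.fs_hz / 2:
            raise ValueError(f"shared band {self.shared_band_hz} invalid for fs {self.fs_hz}")
        if self.y_resid_var() < 0:
            raise ValueError(
                "structural betas imply outcome variance > 1; reduce the path coefficients"
            )

    def y_resid_var(self) -> float:
        """Residual variance keeping the latent outcome at unit variance."""
        b_xy, b1, b2 = self.beta_xy, self.beta_m1y, self.beta_m2y
        # path tracing: cov(x, m1) = beta_xm1, cov(x, m2) = beta_xm2, cov(m1, m2)
        c_xm1, c_xm2 = self.beta_xm1, self.beta_xm2
        c_m1m2 = self.beta_xm1 * self.beta_xm2
        var = (
            b_xy**2 + b1**2 + b2**2
            + 2 * (b_xy * b1 * c_xm1 + b_xy * b2 * c_xm2 + b1 * b2 * c_m1m2)
        )
        return 1.0 - var


@dataclass
class DyadRecord:
    """One dyad's complete raw material for the pipeline."""

    dyad_id: str
    participant_ids: tuple
    offers_pre: tuple
    offers_post: tuple
    smile: "dict[str, CodeSeries]"
    gaze: "dict[str, CodeSeries]"
    fnirs: "dict[tuple, FnirsRecording]"  # (participant_id, probe_side) -> recording

    @property
    def has_fnirs(self) -> bool:
        return bool(self.fnirs)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    dyads: "list[DyadRecord]"
    latents: pd.DataFrame  # dyad_id, x, m1, m2, y, coupling

    def __len__(self) -> int:
        return len(self.dyads)


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def _markov_chain(rng: np.random.Generator, n: int, p_on: float, dwell_on_s: float) -> np.ndarray:
    """Binary bout series with stationary ON-probability p_on and mean ON dwell."""
    p_on = float(np.clip(p_on, 0.01, 0.99))
    q_off = min(1.0, 1.0 / dwell_on_s)  # P(ON -> OFF)
    q_on = min(1.0, p_on * q_off / (1.0 - p_on))  # P(OFF -> ON)
    out = np.empty(n, dtype=int)
    state = int(rng.random() < p_on)
    u = rng.random(n)
    for t in range(n):
        out[t] = state
        if state == 1:
            state = 0 if u[t] < q_off else 1
        else:
            state = 1 if u[t] < q_on else 0
    return out


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: tuple) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (Hz) via FFT masking."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} contains no Fourier bins at n={n}, fs={fs}")
    x = np.fft.irfft(spec * mask, n)
    return x / x.std()


def _pink_noise(rng: np.random.Generator, n: int, fs: float, floor_hz: float = 0.01) -> np.ndarray:
    """Unit-variance 1/f-flavored noise (amplitude ~ 1/sqrt(f + floor))."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = 1.0 / np.sqrt(freqs + floor_hz)
    amp[0] = 0.0
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) * amp
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _offers(rng: np.random.Generator, latent: float, cfg: CohortConfig) -> tuple:
    """Two clamped, quantized offers mapped from a dyad-level latent."""
    out = []
    for _ in range(2):
        z = latent + cfg.offer_noise_sd * rng.standard_normal()
        raw = ENDOWMENT / 2 + (ENDOWMENT / 4) * z
        step = cfg.offer_step
        out.append(int(np.clip(np.round(raw / step) * step, 0, ENDOWMENT)))
    return tuple(out)


def generate_cohort(config: CohortConfig = CohortConfig()) -> SyntheticCohort:
    """Generate a full cohort; deterministic for a given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_sec = cfg.conversation_s
    n_samp = int(round(cfg.conversation_s * cfg.fs_hz))
    ey_sd = float(np.sqrt(cfg.y_resid_var()))
    e1_sd = float(np.sqrt(max(0.0, 1.0 - cfg.beta_xm1**2)))
    e2_sd = float(np.sqrt(max(0.0, 1.0 - cfg.beta_xm2**2)))

    dyads: list[DyadRecord] = []
    latent_rows = []
    for d in range(cfg.n_dyads):
        dyad_id = f"D{d + 1:03d}"
        pids = (f"{dyad_id}A", f"{dyad_id}B")
        x = rng.standard_normal()
        m1 = cfg.beta_xm1 * x + e1_sd * rng.standard_normal()
        m2 = cfg.beta_xm2 * x + e2_sd * rng.standard_normal()
        y = cfg.beta_xy * x + cfg.beta_m1y * m1 + cfg.beta_m2y * m2 + ey_sd * rng.standard_normal()

        offers_pre = _offers(rng, x, cfg)
        offers_post = _offers(rng, y, cfg)

        smile: dict = {}
        gaze: dict = {}
        for pid in pids:
            p_smile = _sigmoid(
                np.log(cfg.smile_base_rate / (1 - cfg.smile_base_rate))
                + cfg.smile_latent_slope * m1
            )
            p_gaze = _sigmoid(
                np.log(cfg.gaze_base_rate / (1 - cfg.gaze_base_rate))
                + cfg.gaze_latent_slope * m1
            )
            smile[pid] = CodeSeries(
                _markov_chain(rng, n_sec, p_smile, cfg.smile_dwell_s), duration_s=n_sec
            )
            gaze[pid] = CodeSeries(
                _markov_chain(rng, n_sec, p_gaze, cfg.gaze_dwell_s), duration_s=n_sec
            )

        coupling_d = 0.0
        fnirs: dict = {}
        if d < cfg.n_fnirs_dyads:
            coupling_d = float(
                np.clip(cfg.coupling * max(0.0, 1.0 + cfg.coupling_latent_slope * m2), 0.0, 0.95)
            )
            shared = _band_noise(rng, n_samp, cfg.fs_hz, cfg.shared_band_hz)
            for pid in pids:
                sides = ("left", "right") if cfg.include_right_probe else ("left",)
                for side in sides:
                    idio = _pink_noise(rng, n_samp, cfg.fs_hz)
                    if side == "left" and coupling_d > 0:
                        neural = (
                            np.sqrt(coupling_d) * shared + np.sqrt(1 - coupling_d) * idio
                        )
                    else:
                        neural = idio
                    neural = cfg.neural_sd * neural
                    drift = cfg.shallow_sd * _pink_noise(rng, n_samp, cfg.fs_hz, floor_hz=0.002)
                    shallow = drift + cfg.trend_sd * rng.standard_normal() * np.linspace(
                        -1, 1, n_samp
                    )
                    a0 = rng.uniform(*cfg.a0_range)
                    a1 = rng.uniform(*cfg.a1_range)
                    trend = cfg.trend_sd * rng.standard_normal() * np.linspace(-1, 1, n_samp)
                    deep = a0 + a1 * shallow + neural + trend
                    fnirs[(pid, side)] = FnirsRecording(
                        shallow=shallow, deep=deep, fs=cfg.fs_hz, probe_side=side
                    )

        dyads.append(
            DyadRecord(
                dyad_id=dyad_id,
                participant_ids=pids,
                offers_pre=offers_pre,
                offers_post=offers_post,
                smile=smile,
                gaze=gaze,
                fnirs=fnirs,
            )
        )
        latent_rows.append(
            dict(dyad_id=dyad_id, x=x, m1=m1, m2=m2, y=y, coupling=coupling_d)
        )

    return SyntheticCohort(config=cfg, dyads=dyads, latents=pd.DataFrame(latent_rows))


def cohort_offers_frame(cohort: SyntheticCohort) -> pd.DataFrame:
    rows = []
    for rec in cohort.dyads:
        for session, offers in (("pre", rec.offers_pre), ("post", rec.offers_post)):
            for pid, amount in zip(rec.participant_ids, offers):
                rows.append(
                    dict(dyad_id=rec.dyad_id, participant_id=pid, session=session,
                         offer_jpy=amount)
                )
    return pd.DataFrame(rows)


def write_cohort(cohort: SyntheticCohort, directory: "str | Path") -> "list[Path]":
    """Emit the CSV dialects the reader modules consume, plus a manifest.

    Layout: ``offers.csv``; per participant ``behavior_<pid>.csv`` and,
    for dyads with fNIRS, ``fnirs_<pid>.csv``; ``manifest.json`` records
    the config (including the seed) and the file list.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    offers_path = directory / "offers.csv"
    cohort_offers_frame(cohort).to_csv(offers_path, index=False)
    written.append(offers_path)

    for rec in cohort.dyads:
        for pid in rec.participant_ids:
            bpath = directory / f"behavior_{pid}.csv"
            write_behavior_csv(bpath, rec.dyad_id, pid, rec.smile[pid], rec.gaze[pid])
            written.append(bpath)
        if rec.has_fnirs:
            for pid in rec.participant_ids:
                fpath = directory / f"fnirs_{pid}.csv"
                frames = []
                for (p, side), frec in sorted(rec.fnirs.items()):
                    if p != pid:
                        continue
                    frames.append(
                        pd.DataFrame(
                            {
                                "dyad_id": rec.dyad_id,
                                "participant_id": pid,
                                "probe_side": side,
                                "t_s": np.arange(len(frec)) / frec.fs,
                                "shallow": frec.shallow,
                                "deep": frec.deep,
                            }
                        )
                    )
                pd.concat(frames, ignore_index=True).to_csv(fpath, index=False)
                written.append(fpath)

    manifest = {
        "config": dataclasses.asdict(cohort.config),
        "files": sorted(p.name for p in written),
        "n_dyads": len(cohort),
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(mpath)
    return written


def read_manifest(directory: "str | Path") -> dict:
    return json.loads((Path(directory) / "manifest.json").read_text())
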