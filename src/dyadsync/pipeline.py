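"""End-to-end orchestration: simulate/load -> preprocess -> score -> IBS -> inference.

The stages mirror the study flow: dyads play the exchange game toward a
stranger (cooperativeness), converse for 10 minutes while behavior and
two-channel fNIRS are recorded, then play toward the partner
(cooperative behavior).  Analysis uses the final coding window of the
conversation throughout.  Outputs are plain CSV/JSON and are
byte-identical across reruns with the same configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import dyadsync.behavior as behavior
import dyadsync.fnirs as fnirs
import dyadsync.pd_game as pd_game
import dyadsync.synthetic as synthetic
import dyadsync.coherence as wtc
from dyadsync.inference import DEFAULT_PATHS, fit_path_model, mediate_bootstrap

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "scale_comparison", "load_run_config"]

log = logging.getLogger("dyadsync")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    mode: str = "synthetic"  # "synthetic" or "files"
    input_dir: "str | None" = None
    out_dir: str = "dyadsync_out"
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    wavelet: wtc.WaveletParams = field(default_factory=wtc.WaveletParams)
    alpha: float = 0.05
    n_boot: int = 1000
    n_perm: int = 180
    seed: int = 0
    exclude_coi: bool = True
    make_plot: bool = True
    # override automatic POI identification with a fixed period band (s)
    poi_band_s: "tuple | None" = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.mode == "files" and not self.input_dir:
            raise ValueError("files mode requires input_dir")


@dataclass
class PipelineResult:
    dyad_table: pd.DataFrame
    comparison: "wtc.ScaleComparisonTable | None"
    pois: "list[wtc.POI]"
    mediation: object
    path_fit: object
    exclusions: "dict[str, int]"
    periods_s: "np.ndarray | None" = None


def _to_native(obj):
    if isinstance(obj, dict):
        return {k: _to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_native(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_native(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def scale_comparison(
    signals: "dict[str, np.ndarray]",
    dyad_of: "dict[str, str]",
    fs: float,
    params: wtc.WaveletParams,
    n_perm: int,
    seed: int,
    window_s: "tuple | None" = None,
    alpha: float = 0.05,
    exclude_coi: bool = True,
    decimate: int = 4,
):
    """Genuine-vs-permuted per-period comparison over a set of cleaned signals.

    ``signals`` maps participant id to a cleaned neural series (all of
    one length at rate ``fs``); ``dyad_of`` maps participant id to dyad
    id.  Returns ``(table, pois, genuine_by_dyad, periods)`` where
    ``genuine_by_dyad`` maps dyad id to its per-period time-averaged
    coherence vector.
    """
    by_dyad: dict = {}
    for pid, dyad in dyad_of.items():
        by_dyad.setdefault(dyad, []).append(pid)
    genuine_pairs = []
    for dyad, pids in sorted(by_dyad.items()):
        if len(pids) != 2:
            raise ValueError(f"dyad {dyad!r} has {len(pids)} members with signals")
        genuine_pairs.append(tuple(sorted(pids)))
    participants = sorted((pid, dyad) for pid, dyad in dyad_of.items())
    perm_pairs = wtc.build_permutated_dyads(participants, n_perm, seed)

    results = wtc.smoothed_cross_spectra(
        {pid: np.asarray(sig, dtype=float) for pid, sig in signals.items()},
        genuine_pairs + perm_pairs,
        fs,
        params,
        decimate=decimate,
    )
    periods = results[genuine_pairs[0]].periods_s
    genuine_by_dyad = {}
    genuine_rows, perm_rows = [], []
    for pair in genuine_pairs:
        vec = wtc.time_avg_coherence(results[pair], window_s, exclude_coi=exclude_coi)
        genuine_rows.append(vec)
        genuine_by_dyad[dyad_of[pair[0]]] = vec
    for pair in perm_pairs:
        perm_rows.append(
            wtc.time_avg_coherence(results[pair], window_s, exclude_coi=exclude_coi)
        )
    table = wtc.compare_scales(
        np.array(genuine_rows), np.array(perm_rows), periods, alpha=alpha
    )
    pois = wtc.identify_poi(table, alpha=alpha)
    return table, pois, genuine_by_dyad, periods


def _select_poi(pois: "list[wtc.POI]", table: "wtc.ScaleComparisonTable") -> "wtc.POI | None":
    """When several POIs emerge, use the one with the smallest mean q."""
    if not pois:
        return None
    if len(pois) == 1:
        return pois[0]
    df = table.table
    best, best_q = None, np.inf
    for poi in pois:
        sel = df["period_s"].isin(poi.member_periods)
        mean_q = float(df.loc[sel, "q"].mean())
        if mean_q < best_q:
            best, best_q = poi, mean_q
    return best


def _load_cohort_from_files(input_dir: Path, cfg: RunConfig) -> synthetic.SyntheticCohort:
    """Reconstruct a cohort from the CSV layout ``write_cohort`` emits."""
    manifest = synthetic.read_manifest(input_dir)
    ccfg_dict = manifest["config"]
    for key in ("shared_band_hz", "a0_range", "a1_range"):
        ccfg_dict[key] = tuple(ccfg_dict[key])
    ccfg = synthetic.CohortConfig(**ccfg_dict)
    offers = pd_game.read_offers_csv(input_dir / "offers.csv")
    dyads = []
    for dyad_id, group in offers.groupby("dyad_id", sort=True):
        pids = tuple(sorted(group["participant_id"].unique()))
        pre = tuple(
            int(group[(group.session == "pre") & (group.participant_id == p)].offer_jpy.iloc[0])
            for p in pids
        )
        post = tuple(
            int(group[(group.session == "post") & (group.participant_id == p)].offer_jpy.iloc[0])
            for p in pids
        )
        smile, gaze, fn = {}, {}, {}
        for pid in pids:
            codes = behavior.read_behavior_csv(
                input_dir / f"behavior_{pid}.csv", window_s=ccfg.conversation_s
            )
            smile[pid], gaze[pid] = codes[pid]
            fpath = input_dir / f"fnirs_{pid}.csv"
            if fpath.exists():
                for (p, side), rec in fnirs.read_fnirs_csv(fpath).items():
                    fn[(p, side)] = rec
        dyads.append(
            synthetic.DyadRecord(
                dyad_id=dyad_id, participant_ids=pids, offers_pre=pre,
                offers_post=post, smile=smile, gaze=gaze, fnirs=fn,
            )
        )
    return synthetic.SyntheticCohort(config=ccfg, dyads=dyads, latents=pd.DataFrame())


def _behavior_window(series: behavior.CodeSeries, window_s: int) -> behavior.CodeSeries:
    if series.duration_s < window_s:
        raise ValueError(f"coded series ({series.duration_s} s) shorter than window {window_s} s")
    return behavior.CodeSeries(series.values[-window_s:], duration_s=window_s)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write the report bundle to ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")

    # --- stage 1: obtain the cohort -------------------------------------
    if config.mode == "synthetic":
        cohort = synthetic.generate_cohort(config.cohort)
    else:
        cohort = _load_cohort_from_files(Path(config.input_dir), config)
    ccfg = cohort.config
    n_input = len(cohort)
    log.info("stage simulate/load: %d dyads (seed %s)", n_input, ccfg.seed)

    # --- stage 2: fNIRS preprocessing (left probe feeds IBS) ------------
    neural: dict = {}
    dyad_of: dict = {}
    for rec in cohort.dyads:
        if not rec.has_fnirs:
            continue
        for pid in rec.participant_ids:
            key = (pid, "left")
            if key not in rec.fnirs:
                raise ValueError(f"dyad {rec.dyad_id}: participant {pid} lacks a left probe")
            neural[pid] = fnirs.dual_regression(rec.fnirs[key]).values
            dyad_of[pid] = rec.dyad_id
    n_fnirs = len({d for d in dyad_of.values()})
    log.info("stage preprocess: %d dyads with fNIRS, %d excluded", n_fnirs, n_input - n_fnirs)

    # --- stage 3: behavioral scoring and game indices -------------------
    rows = []
    for rec in cohort.dyads:
        props = []
        for pid in rec.participant_ids:
            smile = _behavior_window(rec.smile[pid], ccfg.coding_window_s)
            gaze = _behavior_window(rec.gaze[pid], ccfg.coding_window_s)
            props.append(behavior.proportion(behavior.combine_smile_gaze(smile, gaze)))
        idx = behavior.dyad_index(props[0], props[1])
        rows.append(
            dict(
                dyad_id=rec.dyad_id,
                cooperativeness=pd_game.coop_index(*rec.offers_pre).value,
                smile_gaze=idx.dyad_mean,
                ibs=np.nan,
                coop_behavior=pd_game.coop_index(*rec.offers_post).value,
            )
        )
    dyad_table = pd.DataFrame(rows)

    # --- stage 4: coherence, POI, IBS ------------------------------------
    comparison, pois, periods = None, [], None
    if dyad_of:
        window = (
            float(ccfg.conversation_s - ccfg.coding_window_s),
            float(ccfg.conversation_s),
        )
        comparison, pois, genuine_by_dyad, periods = scale_comparison(
            neural,
            dyad_of,
            ccfg.fs_hz,
            config.wavelet,
            config.n_perm,
            config.seed,
            window_s=window,
            alpha=config.alpha,
            exclude_coi=config.exclude_coi,
        )
        if config.poi_band_s is not None:
            lo, hi = config.poi_band_s
            members = periods[(periods >= lo) & (periods <= hi)]
            poi = wtc.POI(float(members[0]), float(members[-1]), members) if len(members) else None
        else:
            poi = _select_poi(pois, comparison)
        if poi is not None:
            ibs_values = {
                dyad: wtc.ibs_index(vec, periods, poi).value
                for dyad, vec in genuine_by_dyad.items()
            }
            dyad_table["ibs"] = dyad_table["dyad_id"].map(ibs_values)
            log.info(
                "stage ibs: POI %.2f-%.2f s (%d periods)",
                poi.period_lo_s, poi.period_hi_s, len(poi.member_periods),
            )
        else:
            log.info("stage ibs: no POI at alpha=%.2f; IBS left missing", config.alpha)

    # --- stage 5: mediation (smiling-with-gaze mediator, all dyads) -----
    mediation = mediate_bootstrap(
        dyad_table["cooperativeness"].to_numpy(),
        dyad_table["smile_gaze"].to_numpy(),
        dyad_table["coop_behavior"].to_numpy(),
        n_boot=config.n_boot,
        seed=config.seed,
    )

    # --- stage 6: path analysis (complete cases) ------------------------
    path_fit = None
    if dyad_table["ibs"].notna().sum() > len(DEFAULT_PATHS):
        path_fit = fit_path_model(dyad_table, DEFAULT_PATHS)

    exclusions = {
        "n_input": n_input,
        "n_fnirs": n_fnirs,
        "n_excluded_fnirs": n_input - n_fnirs,
        "n_path_complete": int(dyad_table.dropna().shape[0]),
    }

    _write_report(out_dir, config, dyad_table, comparison, pois, mediation, path_fit,
                  exclusions, periods)
    return PipelineResult(
        dyad_table=dyad_table, comparison=comparison, pois=pois, mediation=mediation,
        path_fit=path_fit, exclusions=exclusions, periods_s=periods,
    )


def _write_report(out_dir, config, dyad_table, comparison, pois, mediation, path_fit,
                  exclusions, periods) -> None:
    dyad_table.to_csv(out_dir / "dyad_table.csv", index=False)
    mediation.to_frame().to_csv(out_dir / "mediation.csv", index=False)
    if comparison is not None:
        comparison.to_csv(out_dir / "scale_comparison.csv")
    poi_payload = {
        "alpha": config.alpha,
        "pois": [
            dict(period_lo_s=p.period_lo_s, period_hi_s=p.period_hi_s,
                 member_periods=list(p.member_periods))
            for p in pois
        ],
        "ibs_by_dyad": {
            str(r.dyad_id): (None if pd.isna(r.ibs) else float(r.ibs))
            for r in dyad_table.itertuples()
        },
    }
    (out_dir / "poi_ibs.json").write_text(json.dumps(_to_native(poi_payload), indent=2, sort_keys=True))

    if path_fit is not None:
        payload = {
            "paths": path_fit.paths.to_dict(orient="records"),
            "r_squared": path_fit.r_squared,
            "chi2": path_fit.chi2,
            "df": path_fit.df,
            "p_fit": path_fit.p_fit,
            "cfi": path_fit.cfi,
            "srmr": path_fit.srmr,
            "n": path_fit.n,
            "good_fit": path_fit.good_fit(),
        }
        (out_dir / "path_model.json").write_text(json.dumps(_to_native(payload), indent=2, sort_keys=True))

    cfg_dict = dataclasses.asdict(config)
    # paths vary across reruns; the scientific configuration must not
    for volatile in ("out_dir", "input_dir"):
        cfg_dict.pop(volatile, None)
    cfg_dict["cohort"] = dataclasses.asdict(config.cohort)
    cfg_dict["wavelet"] = dataclasses.asdict(config.wavelet)
    run_log = {"config": _to_native(cfg_dict), "exclusions": exclusions}
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))

    if config.make_plot and comparison is not None:
        _plot_comparison(out_dir / "coherence_by_period.png", comparison, pois)


def _plot_comparison(path, comparison, pois) -> None:
    """Mean +/- SEM coherence per period for genuine vs permuted pairs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = comparison.table
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df["period_s"], df["mean_genuine"], label="genuine dyads", color="tab:red")
    ax.plot(df["period_s"], df["mean_permutated"], label="permuted dyads", color="tab:gray")
    for poi in pois:
        ax.axvspan(poi.period_lo_s, poi.period_hi_s, alpha=0.2, color="tab:orange")
    ax.set_xscale("log", base=2)
    ax.set_xlabel("Fourier period (s)")
    ax.set_ylabel("time-averaged coherence")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def load_run_config(path: "str | Path") -> RunConfig:
    """Build a RunConfig from a YAML file with optional nested sections."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_kwargs = raw.pop("cohort", {})
    for key in ("shared_band_hz", "a0_range", "a1_range"):
        if key in cohort_kwargs:
            cohort_kwargs[key] = tuple(cohort_kwargs[key])
    wavelet_kwargs = raw.pop("wavelet", {})
    if "period_range_s" in wavelet_kwargs:
        wavelet_kwargs["period_range_s"] = tuple(wavelet_kwargs["period_range_s"])
    if "poi_band_s" in raw and raw["poi_band_s"] is not None:
        raw["poi_band_s"] = tuple(raw["poi_band_s"])
    return RunConfig(
        cohort=synthetic.CohortConfig(**cohort_kwargs),
        wavelet=wtc.WaveletParams(**wavelet_kwargs),
        **raw,
    )
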