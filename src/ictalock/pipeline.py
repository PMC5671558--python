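"""End-to-end pipeline: detect episodes, classify phase-locking, compute
firing statistics and pairwise synchrony, optionally analyze Ca2+ traces,
and write a tidy report bundle.

Per-unit or per-pair precondition failures (too few events, insufficient
ictal data, ...) are recorded as exclusions with reasons and the run
continues; the run fails only on invalid inputs or configuration. A
manifest (config + seed + package version) is written so any run can be
replayed exactly: two runs with the same manifest produce byte-identical
result files.
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .calcium import detect_ca_events, event_frequency_contrast
from .config import PipelineConfig
from .gswd import detect_gswds, ictal_intervals, interictal_intervals
from .modulation import analyze_modulation
from .synchrony import bootstrap_z, compare_periods, cross_correlogram, is_synchronous
from .trains import CS, SS, check_isolation, firing_stats, validate_purkinje

log = logging.getLogger("ictalock")


def _seed(cfg: PipelineConfig, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, *key])


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis chain described by ``config``.

    ``config.paths`` must provide ``ecog`` and ``spikes``; ``traces`` is
    optional. Results are written to ``out_dir`` (default
    ``config.paths['out']``) and also returned as a dict of DataFrames and
    summaries.
    """
    paths = config.paths
    for req in ("ecog", "spikes"):
        if req not in paths:
            raise ValueError(f"config.paths must include {req!r}")
    out = Path(out_dir if out_dir is not None else paths.get("out", "ictalock_out"))
    out.mkdir(parents=True, exist_ok=True)

    exclusions: list[dict] = []
    ecog = io.read_ecog(paths["ecog"])
    episodes = detect_gswds(
        ecog,
        channel=config.ecog_channel,
        mad_k=config.mad_k,
        band=config.band,
        min_episode=config.min_episode,
        merge_gap=config.merge_gap,
    )
    io.write_episodes(episodes, out / "episodes.json")
    span = (0.0, ecog.duration)
    ict = ictal_intervals(episodes)
    inter = interictal_intervals(episodes, span, config.guard)
    log.info("detected %d episodes (%.1f s ictal)", len(episodes), sum(e - s for s, e in ict))

    trains = io.read_spikes(paths["spikes"], duration=ecog.duration)

    stats_rows, mod_rows = [], []
    for u, tr in enumerate(trains):
        check_isolation(tr, config.min_isolation)
        val = validate_purkinje(tr, config.cf_pause_min)
        if not val.valid:
            exclusions.append({"unit": tr.unit_id, "stage": "identification",
                               "reason": val.reason or "median CF pause below 10 ms"})
        for period, ivs in (("ictal", ict), ("interictal", inter)):
            fs = firing_stats(tr, ivs, config.burst_span)
            for stat, value in fs.to_dict().items():
                stats_rows.append((tr.unit_id, period, stat, value))
        for li, label in enumerate((CS, SS)):
            try:
                res = analyze_modulation(
                    tr.select(label), episodes, label, tr.unit_id,
                    n_shuffles=config.n_shuffles, seed=_seed(config, 1, u, li),
                    bin_width=config.bin_width, window=config.psth_window,
                    band=config.band, z_crit=config.z_crit,
                    min_total_ictal=config.min_total_ictal,
                )
            except ValueError as err:
                exclusions.append({"unit": tr.unit_id, "stage": f"modulation/{label}",
                                   "reason": str(err)})
                continue
            mod_rows.append((tr.unit_id, label, res.amplitude, res.dominant_freq,
                             res.mean_power_6_9, res.z_amplitude, res.z_power,
                             res.modulated, res.phase_deg, res.reason))

    stats_df = pd.DataFrame(stats_rows, columns=["unit_id", "period", "statistic", "value"])
    stats_df.to_csv(out / "firing_stats.csv", index=False, float_format=io.FLOAT_FMT)
    mod_df = pd.DataFrame(
        mod_rows,
        columns=["unit_id", "label", "amplitude", "dominant_freq", "mean_power_6_9",
                 "z_amplitude", "z_power", "modulated", "phase_deg", "reason"],
    )
    mod_df.to_csv(out / "modulation.csv", index=False, float_format=io.FLOAT_FMT)

    sync_rows = []
    comparisons: dict[str, dict] = {}
    for label in (CS, SS):
        per_period: dict[str, list] = {"ictal": [], "interictal": []}
        for pi, (a, b) in enumerate(itertools.combinations(trains, 2)):
            results = {}
            for period, ivs in (("ictal", ict), ("interictal", inter)):
                min_ev = config.min_ictal_cs if (label == CS and period == "ictal") else None
                try:
                    ccg = cross_correlogram(
                        a.select(label), b.select(label), ivs,
                        bin_width=config.bin_width, max_lag=config.max_lag,
                        period=period, pair=(a.unit_id, b.unit_id), min_events=min_ev,
                    )
                    ccg = bootstrap_z(a.select(label), b.select(label), ivs, ccg,
                                      n_boot=config.n_boot,
                                      seed=_seed(config, 2, pi, label == SS,
                                                 period == "ictal"))
                except ValueError as err:
                    exclusions.append({"pair": f"{a.unit_id}-{b.unit_id}",
                                       "stage": f"synchrony/{label}/{period}",
                                       "reason": str(err)})
                    results = {}
                    break
                results[period] = ccg
            if len(results) < 2:
                continue
            for period, ccg in results.items():
                per_period[period].append(ccg)
                sync_rows.append(
                    (f"{a.unit_id}-{b.unit_id}", label, period,
                     ccg.peak_lag * 1e3, ccg.peak_amp,
                     ccg.z_near_zero(config.zero_tol),
                     is_synchronous(ccg, config.zero_tol, config.z_crit))
                )
        if len(per_period["ictal"]) >= 1:
            cmp = compare_periods(per_period["ictal"], per_period["interictal"],
                                  config.zero_tol, config.z_crit)
            comparisons[label] = {
                "n_pairs": len(cmp.pair_ids),
                "frac_synchronous_ictal": cmp.frac_synchronous_ictal,
                "frac_synchronous_interictal": cmp.frac_synchronous_interictal,
                "p_lag": cmp.p_lag, "p_amp": cmp.p_amp,
                "t_lag": cmp.t_lag, "t_amp": cmp.t_amp,
            }
    sync_df = pd.DataFrame(
        sync_rows,
        columns=["pair_id", "label", "period", "peak_lag_ms", "peak_amp",
                 "z_at_zero", "synchronous"],
    )
    sync_df.to_csv(out / "synchrony_pairs.csv", index=False, float_format=io.FLOAT_FMT)

    ca_summary = None
    if "traces" in paths:
        traces = io.read_traces(paths["traces"])
        events = {}
        ev_rows = []
        for trc in traces:
            ev = detect_ca_events(trc, k=config.ca_k,
                                  baseline_window=config.ca_baseline_window,
                                  baseline_pct=config.ca_baseline_pct,
                                  decay_tau=config.ca_decay_tau)
            events[trc.roi_id] = ev
            ev_rows.extend((t, trc.roi_id) for t in ev.event_times)
        pd.DataFrame(ev_rows, columns=["time_s", "roi_id"]).to_csv(
            out / "calcium_events.csv", index=False, float_format=io.FLOAT_FMT)
        contrast = event_frequency_contrast(events, episodes, span, config.guard)
        ca_summary = {
            "n_rois": len(contrast.roi_ids),
            "mean_rate_ictal": (float(np.mean(contrast.rate_ictal))
                                if len(contrast.roi_ids) else None),
            "mean_rate_interictal": (float(np.mean(contrast.rate_interictal))
                                     if len(contrast.roi_ids) else None),
            "mean_diff": contrast.mean_diff,
            "t": contrast.t, "p": contrast.p,
            "excluded": contrast.excluded,
        }

    summary = {
        "n_episodes": len(episodes),
        "total_ictal_s": float(sum(e - s for s, e in ict)),
        "n_units": len(trains),
        "n_modulated": {
            lab: int(((mod_df["label"] == lab) & mod_df["modulated"]).sum())
            for lab in (CS, SS)
        },
        "synchrony": comparisons,
        "calcium": ca_summary,
        "exclusions": exclusions,
    }
    io.write_json(summary, out / "summary.json")
    manifest = {"config": config.to_dict(), "version": __version__}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {"episodes": episodes, "firing_stats": stats_df, "modulation": mod_df,
            "synchrony": sync_df, "summary": summary}


def replay_manifest(manifest_path: str | Path, out_dir: str | Path) -> dict:
    """Re-run a pipeline exactly as described by a previously written manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    config = PipelineConfig.from_dict(manifest["config"])
    return run_pipeline(config, out_dir)
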