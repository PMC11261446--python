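"""Pipeline stages tying the library together for a configured run.

Each stage reads and writes only files under the run's output
directory; the CLI in :mod:`perspire.cli` is a thin wrapper over these
functions. Stage order: simulate → segment → track → analyze → report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaporation, io, synthetic, tracking, uncertainty
from .config import RunConfig
from .evaporation import FLUX_SI_TO_PHYS
from .imaging import FrameStack, normalize_stack, segment_frame, stabilize_stack, wet_area_series
from .physics import saturation_vapor_concentration

log = logging.getLogger("perspire")

__all__ = [
    "run_simulate",
    "run_segment",
    "run_track",
    "run_analyze",
    "run_report",
    "run_all",
]


def _outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _log_run(cfg: RunConfig, stage: str) -> None:
    import perspire

    log.info(
        "stage=%s seed=%d config_hash=%s version=%s",
        stage,
        cfg.seed,
        cfg.config_hash(),
        perspire.__version__,
    )


def run_simulate(cfg: RunConfig) -> dict:
    """Generate the synthetic experiment: video, truth and probe record."""
    _log_run(cfg, "simulate")
    out = _outdir(cfg)
    sim = cfg.simulation
    scenes = []
    h_ms = []
    base = dataclasses.replace(cfg.scene, seed=cfg.seed)
    if sim.kind in ("dropwise", "two_mode"):
        drop_cfg = dataclasses.replace(
            base,
            onset_ramp_s=base.onset_ramp_s or base.duration_s,
            film_thickness_map=None,
        )
        scenes.append(synthetic.simulate_dropwise_dynamics(drop_cfg))
        h_ms.append(sim.h_m_dropwise)
    if sim.kind in ("filmwise", "two_mode"):
        film_cfg = dataclasses.replace(
            base,
            seed=base.seed + 1,
            film_thickness_map=base.film_thickness_map or (0.3e-3, 0.8e-3, 1.5e-3),
        )
        scenes.append(synthetic.simulate_filmwise_scene(film_cfg))
        h_ms.append(sim.h_m_filmwise)

    stacks = [synthetic.render_mwir(tr) for tr in scenes]
    frames = np.concatenate([s.frames for s in stacks])
    stack = FrameStack(
        frames,
        base.frame_rate,
        base.pixel_pitch_um,
        metadata={"synthetic": True, "seed": cfg.seed, "kind": sim.kind},
    )
    io.write_frame_stack(stack, out / "stack.tif")

    # truth tables over the concatenated time base
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    offset = 0
    truth_rows, flux_parts, time_parts = [], [], []
    c_sat = saturation_vapor_concentration(cfg.analysis.surface_temperature_c)
    for truth, h_m in zip(scenes, h_ms):
        n = truth.omega.size
        t = (np.arange(n) + offset) / base.frame_rate
        flux = truth.omega * h_m * c_sat * FLUX_SI_TO_PHYS
        flux = np.clip(
            flux * (1 + rng.normal(0, sim.flux_noise_frac, n)), 0, None
        )
        ev = truth.events.copy()
        ev["start_frame"] += offset
        ev["end_frame"] += offset
        truth_rows.append(ev)
        df = pd.DataFrame(
            {"time_s": t, "omega_true": truth.omega, "wet_area_cm2": truth.wet_area_cm2}
        )
        time_parts.append(df)
        flux_parts.append(flux)
        offset += n
    pd.concat(truth_rows, ignore_index=True).to_csv(
        out / "truth_events.csv", index=False, float_format="%.6g"
    )
    truth_wet = pd.concat(time_parts, ignore_index=True)
    truth_wet.to_csv(out / "truth_wet.csv", index=False, float_format="%.6g")

    probe_df = synthetic.simulate_probe_signal(
        truth_wet["time_s"].to_numpy(), np.concatenate(flux_parts), cfg.probe
    )
    probe_df.to_csv(out / "probe.csv", index=False, float_format="%.6g")
    return {"stack": out / "stack.tif", "probe": out / "probe.csv"}


def run_segment(cfg: RunConfig) -> dict:
    """Stabilize and segment the run's frame stack into wet masks."""
    _log_run(cfg, "segment")
    out = _outdir(cfg)
    stack = io.read_frame_stack(out / "stack.tif")
    stabilized, offsets = stabilize_stack(stack)
    frames01 = normalize_stack(stabilized.frames)
    masks = np.empty(frames01.shape, dtype=bool)
    for i in range(frames01.shape[0]):
        params = cfg.window_params(i / stack.frame_rate)
        masks[i] = segment_frame(frames01[i], params)
    io.write_masks(masks, out / "masks.tif", stack.pixel_pitch_um, stack.frame_rate)
    np.savetxt(out / "stabilization_offsets.csv", offsets, delimiter=",",
               header="dy_px,dx_px", comments="")
    h, w = masks.shape[1:]
    total = h * w * (stack.pixel_pitch_um * 1e-4) ** 2
    series = wet_area_series(masks, stack.pixel_pitch_um, total, stack.frame_rate)
    io.write_wet_series(series, out / "wet_series.csv")
    return {"masks": out / "masks.tif", "wet_series": out / "wet_series.csv"}


def run_track(cfg: RunConfig) -> dict:
    """Extract droplet events and summary statistics from the masks."""
    _log_run(cfg, "track")
    out = _outdir(cfg)
    masks, meta = io.read_masks(out / "masks.tif")
    pitch = meta["pixel_pitch_um"]
    rate = meta["frame_rate"]
    events = tracking.extract_events(
        masks, pitch, rate, min_frames=cfg.tracking.min_frames
    )
    io.write_events(tracking.events_to_frame(events), out / "events.csv")
    summary: dict = {"n_events": len(events)}
    if events:
        counts = tracking.active_count_series(events, masks.shape[0])
        wet = pd.read_csv(out / "wet_series.csv")
        try:
            slope, intercept = tracking.fit_area_vs_count(
                wet["wet_area_cm2"].to_numpy() * 100.0, counts
            )
            summary["area_vs_count_slope_mm2"] = slope
            summary["area_vs_count_intercept_mm2"] = intercept
        except ValueError:
            pass
        dist = tracking.distribution_summary(events)
        summary["p95_max_diameter_mm"] = dist.percentile(95)
        summary["median_duration_s"] = dist.percentile(50, "duration")
        periods = tracking.cycle_period_estimate(
            events, rate, cfg.tracking.cluster_radius_mm
        )
        summary["mean_cycle_period_s"] = periods["mean_period_s"]
        summary["n_pores"] = periods["n_pores"]
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return {"events": out / "events.csv", "summary": out / "summary.json"}


def _detect_flow_steps(flow: np.ndarray) -> list:
    """Indices where the recorded flow rate changes value."""
    return [int(i) for i in np.flatnonzero(np.diff(flow) != 0) + 1]


def run_analyze(cfg: RunConfig) -> dict:
    """Evaporation-rate, mass-transfer and uncertainty analysis."""
    _log_run(cfg, "analyze")
    out = _outdir(cfg)
    probe, _ = io.read_probe_csv(out / "probe.csv")
    wet = pd.read_csv(out / "wet_series.csv")
    series = evaporation.evaporation_series(
        probe["time_s"].to_numpy() / 60.0,
        probe["flow_lpm"].to_numpy(),
        probe["cout_gm3"].to_numpy(),
        probe["cin_gm3"].to_numpy() if "cin_gm3" in probe else 0.0,
        total_area_cm2=cfg.analysis.total_area_cm2,
    )
    t_probe = probe["time_s"].to_numpy()
    omega = np.interp(t_probe, wet["time_s"].to_numpy(), wet["omega"].to_numpy())
    if cfg.analysis.filter_omega_with_probe_response:
        omega = evaporation.cascade_lag_filter(
            t_probe,
            omega,
            cfg.probe.capsule_mixing_time_constant_s,
            cfg.probe.probe_time_constant_s,
        )

    results: dict = {
        "total_area_cm2": cfg.analysis.total_area_cm2,
        "has_negative_rate": series.has_negative_rate,
    }
    if cfg.analysis.mode_windows:
        windows = {
            mode: (t_probe >= lo) & (t_probe < hi)
            for mode, (lo, hi) in cfg.analysis.mode_windows.items()
        }
        fits, ratio = evaporation.fit_mode_slopes(
            series.flux_mg_min_cm2,
            omega,
            windows,
            surface_temperature=cfg.analysis.surface_temperature_c,
        )
        results["mode_fits"] = {
            m: {"slope_mg_min_cm2": f.slope, "intercept": f.intercept,
                "h_m_m_s": f.h_m, "r_value": f.r_value, "n_points": f.n_points}
            for m, f in fits.items()
        }
        results["h_m_ratio_dropwise_over_filmwise"] = ratio

    flow = probe["flow_lpm"].to_numpy()
    decays = []
    for idx in _detect_flow_steps(flow):
        nxt = flow[idx:]
        seg_end = idx + (np.flatnonzero(np.diff(nxt) != 0)[0] + 1
                         if np.any(np.diff(nxt) != 0) else nxt.size)
        t_seg = t_probe[idx:seg_end]
        c_seg = probe["cout_gm3"].to_numpy()[idx:seg_end]
        if t_seg.size >= 5:
            fit = evaporation.fit_first_order_decay(t_seg / 60.0, c_seg)
            decays.append(
                {"step_time_s": float(t_probe[idx]),
                 "flow_lpm": float(flow[idx]),
                 "tau_min": fit.time_constant,
                 "identifiable": fit.identifiable}
            )
    results["decay_fits"] = decays

    # quasi-steady tail of the record for the operating-point summaries
    tail = slice(max(series.rate_mg_min.size - 50, 0), None)
    q_tail = float(np.mean(series.flow_lpm[tail]))
    cout_tail = float(np.mean(series.cout_gm3[tail]))
    sigma = float(np.std(series.rate_mg_min[tail], ddof=1))
    budget = uncertainty.build_budget(
        q_tail,
        cout_tail,
        sigma,
        n_replicates=cfg.uncertainty.n_replicates,
        confidence=cfg.uncertainty.confidence,
        u_cout=cfg.uncertainty.u_cout_gm3,
        flow_full_scale=cfg.uncertainty.flow_full_scale_lpm,
    )
    results["uncertainty_budget"] = dataclasses.asdict(budget)

    flux_tail = float(np.mean(series.flux_mg_min_cm2[tail]))
    omega_tail = float(np.mean(omega[tail]))
    if flux_tail > 0 and 0 < omega_tail <= 1:
        results["lewis_equivalent_wind_speed_m_s"] = (
            evaporation.lewis_equivalent_wind_speed(
                flux_tail,
                omega_tail,
                cfg.analysis.surface_temperature_c,
                cfg.analysis.ambient,
                cfg.physics,
            )
        )
    (out / "analysis.json").write_text(json.dumps(results, indent=2, default=float))
    return {"analysis": out / "analysis.json"}


def run_report(cfg: RunConfig) -> dict:
    """Assemble a human-readable markdown report (+ diagnostic plots)."""
    _log_run(cfg, "report")
    out = _outdir(cfg)
    analysis = json.loads((out / "analysis.json").read_text())
    summary = json.loads((out / "summary.json").read_text()) if (
        out / "summary.json"
    ).exists() else {}

    lines = ["# Sweat evaporation analysis report", ""]
    lines.append(f"- seed: {cfg.seed}; config hash: {cfg.config_hash()}")
    if "mode_fits" in analysis:
        lines.append("\n## Mass transfer by sweating mode\n")
        for mode, fit in analysis["mode_fits"].items():
            lines.append(
                f"- {mode}: slope {fit['slope_mg_min_cm2']:.3f} mg·min⁻¹·cm⁻² "
                f"per unit ω → h_m = {fit['h_m_m_s']:.4g} m·s⁻¹ "
                f"(r = {fit['r_value']:.3f}, n = {fit['n_points']})"
            )
        ratio = analysis.get("h_m_ratio_dropwise_over_filmwise")
        if ratio:
            lines.append(f"- slope ratio (dropwise / filmwise): **{ratio:.2f}**")
    if analysis.get("decay_fits"):
        lines.append("\n## Flow-step decay fits\n")
        for d in analysis["decay_fits"]:
            tau = d["tau_min"]
            tau_txt = f"{tau:.2f} min" if d["identifiable"] else "unidentifiable"
            lines.append(
                f"- step at t = {d['step_time_s']:.0f} s to "
                f"{d['flow_lpm']:.2g} L·min⁻¹: τ = {tau_txt}"
            )
    budget = analysis.get("uncertainty_budget")
    if budget:
        lines.append("\n## Uncertainty budget (quasi-steady tail)\n")
        lines.append(
            f"- U_systematic = {budget['u_systematic']:.3g} mg·min⁻¹, "
            f"U_random = {budget['u_random']:.3g} mg·min⁻¹, "
            f"U_total = {budget['u_total']:.3g} mg·min⁻¹"
        )
    if "lewis_equivalent_wind_speed_m_s" in analysis:
        lines.append(
            f"\n- Lewis-analogy equivalent head wind speed: "
            f"{analysis['lewis_equivalent_wind_speed_m_s']:.2f} m·s⁻¹"
        )
    if summary:
        lines.append("\n## Droplet statistics\n")
        for key, val in summary.items():
            lines.append(f"- {key}: {val:.4g}" if isinstance(val, float) else f"- {key}: {val}")
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    _plot_overview(out)
    return {"report": report}


def _plot_overview(out: Path) -> None:
    """Flux-vs-ω and wet-fraction diagnostics as PNG (best effort)."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        probe = pd.read_csv(out / "probe.csv")
        wet = pd.read_csv(out / "wet_series.csv")
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        axes[0].plot(wet["time_s"], wet["omega"])
        axes[0].set(xlabel="time (s)", ylabel="wet fraction ω")
        flux = probe["flow_lpm"] * probe["cout_gm3"]
        omega = np.interp(probe["time_s"], wet["time_s"], wet["omega"])
        axes[1].scatter(omega, flux, s=4, alpha=0.4)
        axes[1].set(xlabel="ω", ylabel="ṁe (mg·min⁻¹)")
        fig.tight_layout()
        fig.savefig(out / "overview.png", dpi=110)
        plt.close(fig)
    except Exception as exc:  # pragma: no cover - plotting is best-effort
        log.warning("overview plot failed: %s", exc)


def run_all(cfg: RunConfig) -> dict:
    """Run every stage in order."""
    paths = {}
    for stage in (run_simulate, run_segment, run_track, run_analyze, run_report):
        paths.update(stage(cfg))
    return paths
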