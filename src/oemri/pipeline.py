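"""End-to-end orchestration of the synthetic-cohort analysis.

``run_full_pipeline`` simulates an imaging cohort of concentric tumor
phantoms, maps PSIC per voxel, measures low-PSIC area fractions,
extracts ROI time curves, simulates matched pO2 probe traces and
histology surrogates, runs the correlation/paired-test layer, simulates
a survival cohort grouped on low-PSIC fraction, and writes every table
(CSV), test result (JSON) and a run manifest to the output directory.
Everything is driven by one seed; two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import RunConfig, write_map
from .phantom import (
    default_phantom_spec,
    generate_histology,
    generate_phantom,
    generate_po2_trace,
    generate_section_fractions,
    generate_survival,
)
from .po2 import pair_psic_po2, summarize_po2
from .psic import (
    DynamicSeries,
    StageTiming,
    classify_regions,
    compute_psic_map,
    extract_time_curve,
    low_psic_fraction,
    place_circular_roi,
)
from .stats import (
    correlate_fraction_histology,
    group_by_fraction,
    km_estimate,
    logrank_test,
    paired_t_test,
    spearman,
)

logger = logging.getLogger("oemri")

__all__ = ["run_full_pipeline", "psic_of_curve", "simulate_survival_cohort"]


def psic_of_curve(curve, timing: StageTiming, smooth_window: int = 1) -> float:
    """PSIC (percent) of a single ROI time curve."""
    series = DynamicSeries(
        data=curve.values[:, None, None], times=curve.times
    )
    pmap = compute_psic_map(series, timing, smooth_window=smooth_window)
    return float(pmap.values[0, 0])


def simulate_survival_cohort(cfg: RunConfig, seed: int):
    """Draw the survival cohort's low-PSIC fractions and records."""
    c = cfg.cohort
    rng = np.random.default_rng(seed)
    fractions: list[float] = []
    for center in c.survival_class_centers:
        draws = rng.normal(center, c.survival_class_sd, size=c.n_per_survival_group)
        fractions.extend(np.clip(draws, 0.01, 0.95))
    records = generate_survival(
        fractions,
        baseline_hazard=c.survival_baseline_hazard,
        beta=c.survival_beta,
        censor_day=c.censor_day,
        seed=int(rng.integers(2**31 - 1)),
    )
    return records


def _subject_rois(spec, truth, analysis):
    """Place the tumor-ROI (active rim) and penumbra-ROI for one phantom."""
    py, px = spec.pixel_size_mm
    active = next(c for c in spec.compartments if c.label == "active_tumor")
    penumbra = next(c for c in spec.compartments if c.label == "penumbra")
    center_mm = active.center_mm
    rois = {}
    for site, comp in (("tumor", active), ("penumbra", penumbra)):
        mid_r = 0.5 * (comp.r_inner_mm + comp.r_outer_mm)
        center_px = (center_mm[0] / py - 0.5, (center_mm[1] + mid_r) / px - 0.5)
        rois[site] = place_circular_roi(
            center_px,
            analysis.roi_volume_mm3,
            spec.pixel_size_mm,
            analysis.slice_thickness_mm,
            truth.label_map.shape,
            roi_id=site,
            kind=site,
        )
    return rois


def run_full_pipeline(cfg: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run the whole synthetic-cohort study; returns the report dict.

    The report mirrors ``tests.json``; all tables land in ``output_dir``.
    """
    t_start = time.perf_counter()
    outdir = Path(output_dir if output_dir is not None else cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timing = cfg.stage_timing()
    analysis = cfg.analysis
    c = cfg.cohort
    seeds = np.random.SeedSequence(cfg.seed).generate_state(6) % (2**31 - 1)
    rng = np.random.default_rng(int(seeds[0]))

    # ------------------------------------------------------------------ imaging
    t0 = time.perf_counter()
    amp_scales = np.linspace(*c.amplitude_scale_range, c.n_imaging)
    penumbra_outer = rng.permutation(
        np.linspace(*c.penumbra_outer_range_mm, c.n_imaging)
    )
    subject_rows = []
    roi_rows = []
    subject_fractions = []
    for i in range(c.n_imaging):
        sid = f"rat{i + 1:02d}"
        spec = default_phantom_spec(
            seed=int((seeds[1] + i) % (2**31 - 1)),
            noise_sigma=1000.0 / c.snr,
            amplitude_scale=float(amp_scales[i]),
            penumbra_outer_mm=float(penumbra_outer[i]),
            frame_interval_s=cfg.frame_interval_s,
            stage_durations_s=cfg.stage_durations_s,
        )
        series, truth = generate_phantom(spec)
        pmap = compute_psic_map(
            series,
            timing,
            smooth_window=analysis.smooth_window,
            epsilon_baseline=analysis.epsilon_baseline,
            threshold=analysis.psic_threshold,
        )
        labels = classify_regions(pmap, truth.tumor_mask)
        frac = low_psic_fraction(pmap, truth.tumor_mask)
        subject_fractions.append((sid, frac))
        high = pmap.values[labels == 2]
        low = pmap.values[labels == 1]
        subject_rows.append(
            {
                "subject_id": sid,
                "n_valid_pixels": int((labels != 0).sum()),
                "low_fraction": frac,
                "mean_psic_high": float(high.mean()) if high.size else float("nan"),
                "mean_psic_low": float(low.mean()) if low.size else float("nan"),
                "true_low_fraction": truth.true_low_fraction,
                "amplitude_scale": float(amp_scales[i]),
            }
        )
        write_map(pmap.values, outdir / f"{sid}_psic.nii.gz", spec.pixel_size_mm)
        write_map(truth.label_map, outdir / f"{sid}_labels.nii.gz", spec.pixel_size_mm)
        for site, roi in _subject_rois(spec, truth, analysis).items():
            curve = extract_time_curve(series, roi)
            roi_rows.append(
                {
                    "subject_id": sid,
                    "site": site,
                    "psic_pct": psic_of_curve(curve, timing, analysis.smooth_window),
                    "n_pixels": len(roi.pixels),
                }
            )
    subjects = pd.DataFrame(subject_rows)
    roi_psics = pd.DataFrame(roi_rows)
    subjects.to_csv(outdir / "subjects.csv", index=False)
    roi_psics.to_csv(outdir / "roi_psic.csv", index=False)
    logger.info(
        "imaging cohort: %d subjects mapped in %.1f s",
        c.n_imaging,
        time.perf_counter() - t0,
    )

    # ------------------------------------------------------------------ pO2
    t0 = time.perf_counter()
    po2_rows = []
    for i in range(min(c.n_po2, c.n_imaging)):
        sid = f"rat{i + 1:02d}"
        spec = default_phantom_spec(amplitude_scale=float(amp_scales[i]))
        for j, site in enumerate(("tumor", "penumbra")):
            label = "active_tumor" if site == "tumor" else "penumbra"
            comp = next(cc for cc in spec.compartments if cc.label == label)
            trace = generate_po2_trace(
                comp,
                timing,
                noise_sd=c.po2_noise_sd,
                seed=int((seeds[2] + 2 * i + j) % (2**31 - 1)),
                site=site,
                subject_id=sid,
            )
            summary = summarize_po2(trace, timing)
            po2_rows.append(
                {
                    "subject_id": sid,
                    "site": site,
                    "po2_pre": summary.po2_pre,
                    "po2_max": summary.po2_max,
                    "delta_po2": summary.delta_po2,
                }
            )
    po2_summaries = pd.DataFrame(po2_rows)
    po2_summaries.to_csv(outdir / "po2_summaries.csv", index=False)
    paired, unmatched = pair_psic_po2(
        roi_psics[["subject_id", "site", "psic_pct"]], po2_summaries
    )
    paired.to_csv(outdir / "po2_paired.csv", index=False)
    rho_po2, p_po2 = spearman(paired["psic_pct"], paired["delta_po2"])
    wide = po2_summaries.pivot(index="subject_id", columns="site", values="delta_po2")
    t_po2, tp_po2, df_po2 = paired_t_test(wide["tumor"], wide["penumbra"])
    logger.info("pO2 analysis: %d paired rows in %.1f s", len(paired),
                time.perf_counter() - t0)

    # ------------------------------------------------------------------ histology
    t0 = time.perf_counter()
    histo = generate_histology(
        roi_psics["psic_pct"].tolist(),
        slope=c.histology_slope,
        intercept=c.histology_intercept,
        dispersion=c.histology_dispersion,
        seed=int(seeds[3]),
    )
    histo_df = roi_psics[["subject_id", "site", "psic_pct"]].copy()
    histo_df["vessel_count"] = [h[1] for h in histo]
    histo_df["glut1_fraction"] = [h[2] for h in histo]
    histo_df.to_csv(outdir / "histology_rois.csv", index=False)
    rho_ves, p_ves = spearman(histo_df["psic_pct"], histo_df["vessel_count"])
    wide_v = histo_df.pivot(index="subject_id", columns="site", values="vessel_count")
    t_ves, tp_ves, df_ves = paired_t_test(wide_v["tumor"], wide_v["penumbra"])
    sections = generate_section_fractions(
        subject_fractions,
        slope=c.section_slope,
        intercept=c.section_intercept,
        noise_sd=c.section_noise_sd,
        seed=int(seeds[4]),
    )
    pd.DataFrame(sections, columns=["subject_id", "histo_fraction"]).to_csv(
        outdir / "section_fractions.csv", index=False
    )
    rho_sec, p_sec, n_sec = correlate_fraction_histology(subject_fractions, sections)
    logger.info("histology surrogates in %.1f s", time.perf_counter() - t0)

    # ------------------------------------------------------------------ survival
    t0 = time.perf_counter()
    records = simulate_survival_cohort(cfg, int(seeds[5]))
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "low_fraction": r.low_fraction,
                "time_days": r.time_days,
                "event": int(r.event),
            }
            for r in records
        ]
    ).to_csv(outdir / "survival_records.csv", index=False)
    groups = group_by_fraction(records, analysis.group_cuts)
    km_rows = []
    medians = {}
    for name in ("low", "medium", "high"):
        curve = km_estimate(groups[name])
        medians[name] = curve.median_days
        for t, s, r in zip(curve.event_times, curve.survival_probs, curve.at_risk):
            km_rows.append(
                {"group": name, "time_days": t, "survival": s, "at_risk": int(r)}
            )
    pd.DataFrame(km_rows).to_csv(outdir / "km_curves.csv", index=False)
    chi2, df_lr, p_lr = logrank_test([groups[g] for g in ("low", "medium", "high")])
    logger.info("survival cohort: %d rats, log-rank p=%.3g in %.1f s",
                len(records), p_lr, time.perf_counter() - t0)

    report = {
        "spearman_psic_delta_po2": {"rho": rho_po2, "p": p_po2, "n": len(paired)},
        "paired_t_delta_po2": {"t": t_po2, "p": tp_po2, "df": df_po2},
        "spearman_psic_vessels": {"rho": rho_ves, "p": p_ves, "n": len(histo_df)},
        "paired_t_vessels": {"t": t_ves, "p": tp_ves, "df": df_ves},
        "spearman_fraction_histology": {"rho": rho_sec, "p": p_sec, "n": n_sec},
        "logrank": {
            "chi2": chi2,
            "df": df_lr,
            "p": p_lr,
            "n_per_group": {g: len(groups[g]) for g in ("low", "medium", "high")},
        },
        "median_survival_days": medians,
        "mean_low_fraction": float(subjects["low_fraction"].mean()),
        "mean_psic_tumor_roi": float(
            roi_psics.loc[roi_psics["site"] == "tumor", "psic_pct"].mean()
        ),
        "mean_psic_penumbra_roi": float(
            roi_psics.loc[roi_psics["site"] == "penumbra", "psic_pct"].mean()
        ),
        "mean_delta_po2_tumor": float(
            po2_summaries.loc[po2_summaries["site"] == "tumor", "delta_po2"].mean()
        ),
        "mean_delta_po2_penumbra": float(
            po2_summaries.loc[po2_summaries["site"] == "penumbra", "delta_po2"].mean()
        ),
    }
    with open(outdir / "tests.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    manifest = {
        "package": "oemri",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.model_dump(mode="json"),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
        "unmatched_po2_rows": int(len(unmatched)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    if cfg.make_figures:
        _make_figures(outdir)
    logger.info("pipeline complete in %.1f s", time.perf_counter() - t_start)
    return report


def _make_figures(outdir: Path) -> None:
    """Static figures: KM curves and the low-fraction distribution."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    km = pd.read_csv(outdir / "km_curves.csv")
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, color in (("low", "tab:blue"), ("medium", "tab:green"), ("high", "tab:red")):
        g = km[km["group"] == name]
        ax.step(
            np.concatenate([[0], g["time_days"]]),
            np.concatenate([[1.0], g["survival"]]),
            where="post",
            label=f"{name} low-PSIC fraction",
            color=color,
        )
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "km_curves.png", dpi=120)
    plt.close(fig)
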