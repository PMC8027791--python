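"""Orchestration: simulate → preprocess → extract → model → report.

Each stage is a plain function over a PipelineConfig; the CLI wraps them.
A dataset directory holds EDF recordings with events sidecars, the design
table, the metabolite table, the config used, and a manifest with SHA-256
checksums of every file.  Analysis writes the feature table, per-measure
mixed-model results (JSON + report-shaped CSV) and grand-average arrays
used by the report stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats, pk, preprocessing, spectral, stats
from .config import PipelineConfig
from .design import BASELINE, DOSE_MG, make_crossover_design
from .simulate import default_block_specs, simulate_recording

logger = logging.getLogger(__name__)

EEG_MEASURE_NAMES = stats.EEG_MEASURES


def _rng_for(seed: int, *stream: int) -> np.random.Generator:
    """Independent deterministic substream for one simulation unit."""
    return np.random.default_rng([seed, *stream])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _prepare_out_dir(out_dir: Path, force: bool) -> None:
    if out_dir.exists() and any(out_dir.iterdir()):
        if not force:
            raise FileExistsError(
                f"{out_dir} exists and is not empty (use --force to overwrite)"
            )
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)


def run_simulate(config: PipelineConfig, out_dir: str | Path,
                 force: bool = False) -> Path:
    """Generate the full crossover dataset on disk.

    Layout: ``design.csv``, ``metabolites.csv``, one EDF + events TSV per
    subject-session-timepoint, ``config.yaml``, and ``manifest.json`` with
    per-file checksums.
    """
    out_dir = Path(out_dir)
    _prepare_out_dir(out_dir, force)
    rng_design = _rng_for(config.seed, 0)
    sessions = make_crossover_design(config.n_subjects, rng_design)
    from .design import design_table

    design_table(sessions).to_csv(out_dir / "design.csv", index=False)

    specs = default_block_specs(config.trials_per_block, config.n_oddball,
                                config.iti, config.rates)
    eeg_tps = (BASELINE, *config.eeg_timepoints)
    met_times = {BASELINE: 0.0}
    met_times.update({tp: float(tp.removeprefix("h"))
                      for tp in config.metabolite_timepoints})

    met_rows = []
    for si, session in enumerate(sessions):
        subj_idx = si // 3
        for ti, tp in enumerate(eeg_tps):
            rng = _rng_for(config.seed, 1, subj_idx, session.visit, ti)
            rec = simulate_recording(
                session, tp, config.effect, specs=specs, fs=config.fs,
                rng=rng, resting_segment_s=config.resting_segment_s,
                n_resting_pairs=config.n_resting_pairs,
            )
            name = f"sub-{session.subject_id}_ses-{session.visit}_tp-{tp}.edf"
            io_formats.write_edf(rec, out_dir / name)
        # metabolite trajectories: one draw per analyte per session
        rng = _rng_for(config.seed, 2, subj_idx, session.visit)
        times = np.array(list(met_times.values()))
        for analyte in pk.ANALYTES:
            series = pk.simulate_metabolite(
                analyte, DOSE_MG[session.dose],
                pk.DEFAULT_ANALYTE_CONFIGS[analyte], times, rng,
            )
            for tp, conc in zip(met_times.keys(), series.concentrations):
                met_rows.append(dict(
                    subject_id=session.subject_id, dose=session.dose,
                    timepoint=tp, analyte=analyte, concentration=conc,
                ))
    pd.DataFrame(met_rows).to_csv(out_dir / "metabolites.csv", index=False)
    config.save(out_dir / "config.yaml")

    manifest = {
        "seed": config.seed,
        "files": {
            p.name: _sha256(p)
            for p in sorted(out_dir.iterdir())
            if p.name != "manifest.json"
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("simulate: %d sessions, %d files", len(sessions),
                len(manifest["files"]))
    return out_dir


def verify_manifest(dataset_dir: Path) -> dict:
    manifest = json.loads((dataset_dir / "manifest.json").read_text())
    missing = [n for n in manifest["files"] if not (dataset_dir / n).exists()]
    if missing:
        raise FileNotFoundError(f"dataset files missing vs manifest: {missing}")
    return manifest


def _session_features(rec_path: Path, config: PipelineConfig) -> dict[str, float]:
    """All EEG measures of one recording: 6 ASSR scores + 2 resting scores."""
    rec = io_formats.read_edf(rec_path)
    rec = preprocessing.bandpass(rec, *config.band)
    rec = preprocessing.average_reference(rec)
    out: dict[str, float] = {}
    for rate in config.rates:
        cond = f"assr{int(rate)}"
        ep = preprocessing.epoch(rec, cond, window=config.epoch_window)
        ep = preprocessing.reject_peak_to_peak(ep, config.reject_uv)
        freqs = np.arange(rate - config.assr_halfband,
                          rate + config.assr_halfband + 0.5, 1.0)
        tfr = spectral.morlet_tfr(ep, freqs, n_cycles=config.n_cycles)
        for measure in ("power", "itpc"):
            score = spectral.assr_score(
                tfr, measure, roi=config.roi,
                window=config.assr_window,
                baseline_window=config.baseline_window,
                power_mode=config.power_mode,
            )
            out[f"{cond}_{measure}"] = score.value
    segments = preprocessing.resting_segments(rec)
    psds = [
        spectral.welch_psd(segs, rec.fs, window_s=config.welch_window_s,
                           channel_labels=rec.channel_labels)
        for segs in segments.values() if segs
    ]
    if psds:
        psd = spectral.combine_psds(psds)
        scores = spectral.resting_scores(psd, roi=config.roi)
        out["resting_gamma_db"] = scores.gamma_db
        out["resting_slope"] = scores.slope
    return out


def run_analyze(dataset_dir: str | Path, out_dir: str | Path,
                config: PipelineConfig | None = None,
                force: bool = False) -> Path:
    """Extract all measures from a dataset and fit the dose models."""
    dataset_dir = Path(dataset_dir)
    out_dir = Path(out_dir)
    _prepare_out_dir(out_dir, force)
    verify_manifest(dataset_dir)
    if config is None:
        config = PipelineConfig.load(dataset_dir / "config.yaml")
    design = pd.read_csv(dataset_dir / "design.csv")

    eeg_tps = (BASELINE, *config.eeg_timepoints)
    feature_rows: list[io_formats.FeatureRow] = []
    for _, sess in design.iterrows():
        values: dict[str, dict[str, float]] = {}
        for tp in eeg_tps:
            name = f"sub-{sess.subject_id}_ses-{sess.visit}_tp-{tp}.edf"
            values[tp] = _session_features(dataset_dir / name, config)
        for measure in values[BASELINE]:
            base_val = values[BASELINE][measure]
            feature_rows.append(io_formats.FeatureRow(
                sess.subject_id, sess.dose, BASELINE, measure, base_val, None
            ))
            for tp in config.eeg_timepoints:
                feature_rows.append(io_formats.FeatureRow(
                    sess.subject_id, sess.dose, tp, measure,
                    values[tp][measure], base_val,
                ))
        logger.info("analyze: features extracted for %s ses-%s",
                    sess.subject_id, sess.visit)

    met = pd.read_csv(dataset_dir / "metabolites.csv")
    for (subject, dose, analyte), grp in met.groupby(
        ["subject_id", "dose", "analyte"]
    ):
        by_tp = grp.set_index("timepoint")["concentration"]
        base_val = float(by_tp[BASELINE])
        feature_rows.append(io_formats.FeatureRow(
            subject, dose, BASELINE, analyte, base_val, None))
        for tp in config.metabolite_timepoints:
            feature_rows.append(io_formats.FeatureRow(
                subject, dose, tp, analyte, float(by_tp[tp]), base_val))

    features = io_formats.feature_frame(feature_rows)
    io_formats.write_feature_table(features, out_dir / "features.csv")

    results = stats.analyze_measures(
        features, time_as_categorical=config.time_as_categorical,
        baseline_centering=config.baseline_centering)
    summary = stats.summarize_results(results)
    stats.write_results(results, summary, out_dir / "results.json",
                        out_dir / "results_table.csv")
    _save_grand_averages(dataset_dir, out_dir, config, design)
    logger.info("analyze: %d measures modelled", len(results))
    return out_dir


def _save_grand_averages(dataset_dir, out_dir, config, design) -> None:
    """Grand-average 40 Hz TFR/ITPC maps and resting PSD per dose, for plots."""
    maps = {}
    for dose, grp in design.groupby("dose"):
        sess = grp.iloc[0]  # representative session keeps this stage cheap
        tp = config.eeg_timepoints[0]
        name = f"sub-{sess.subject_id}_ses-{sess.visit}_tp-{tp}.edf"
        rec = io_formats.read_edf(dataset_dir / name)
        rec = preprocessing.bandpass(rec, *config.band)
        ep = preprocessing.epoch(rec, "assr40", window=config.epoch_window)
        ep = preprocessing.reject_peak_to_peak(ep, config.reject_uv)
        # slowest displayable frequency: the wavelet must fit the epoch and
        # half a wavelet must fit the pre-stimulus baseline window
        duration = config.epoch_window[1] - config.epoch_window[0]
        b_len = config.baseline_window[1] - config.baseline_window[0]
        fmin = int(np.ceil(max(config.n_cycles / duration,
                               config.n_cycles / (2 * b_len))))
        freqs = np.arange(fmin, 61.0, 1.0)
        tfr = spectral.morlet_tfr(ep, freqs, n_cycles=config.n_cycles)
        power = spectral.evoked_power(tfr, config.baseline_window,
                                      mode=config.power_mode)
        coh = spectral.itpc(tfr)
        roi_ix = tfr.channel_index(config.roi)
        segments = preprocessing.resting_segments(rec)
        psds = [spectral.welch_psd(s, rec.fs, config.welch_window_s,
                                   channel_labels=rec.channel_labels)
                for s in segments.values() if s]
        psd = spectral.combine_psds(psds)
        maps[dose] = dict(
            power=power[roi_ix].mean(axis=0), itpc=coh[roi_ix].mean(axis=0),
            freqs=freqs, times=tfr.times,
            psd_freqs=psd.freqs, psd=psd.power[psd.channel_index(config.roi)].mean(axis=0),
        )
    np.savez(out_dir / "grand_averages.npz",
             **{f"{d}_{k}": v for d, m in maps.items() for k, v in m.items()})


def run_report(results_dir: str | Path, out_dir: str | Path | None = None) -> Path:
    """Render figures: hourly trajectories, TFR/ITPC maps, resting PSD."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results_dir = Path(results_dir)
    out_dir = Path(out_dir) if out_dir else results_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    features = io_formats.read_feature_table(results_dir / "features.csv")

    # hourly trajectories relative to baseline, one panel per EEG measure
    eeg = features[features["measure"].isin(EEG_MEASURE_NAMES)]
    measures = sorted(eeg["measure"].unique())
    fig, axes = plt.subplots(2, 4, figsize=(16, 7), squeeze=False)
    for ax, measure in zip(axes.ravel(), measures):
        sub = eeg[(eeg["measure"] == measure) & (eeg["timepoint"] != BASELINE)]
        sub = sub.assign(delta=sub["value"] - sub["baseline_value"])
        for dose in ("placebo", "low", "high"):
            traj = sub[sub["dose"] == dose].groupby("timepoint",
                                                    observed=True)["delta"].mean()
            traj = traj.reindex([t for t in ("h1", "h2", "h3", "h4", "h5")
                                 if t in traj.index])
            ax.plot(traj.index, traj.values, marker="o", label=dose)
        ax.set_title(measure)
        ax.axhline(0, color="k", lw=0.5)
    axes[0, 0].legend()
    fig.suptitle("Change from pretreatment baseline by dose")
    fig.tight_layout()
    fig.savefig(out_dir / "trajectories.png", dpi=120)
    plt.close(fig)

    ga_path = results_dir / "grand_averages.npz"
    if ga_path.exists():
        ga = np.load(ga_path)
        doses = sorted({k.split("_")[0] for k in ga.files})
        fig, axes = plt.subplots(3, len(doses), figsize=(4 * len(doses), 9))
        for j, dose in enumerate(doses):
            freqs, times = ga[f"{dose}_freqs"], ga[f"{dose}_times"]
            for i, kind in enumerate(("power", "itpc")):
                axes[i, j].pcolormesh(times, freqs, ga[f"{dose}_{kind}"],
                                      shading="auto")
                axes[i, j].set_title(f"{dose} 40 Hz {kind}")
            axes[2, j].loglog(ga[f"{dose}_psd_freqs"][1:], ga[f"{dose}_psd"][1:])
            axes[2, j].set_title(f"{dose} resting PSD")
        fig.tight_layout()
        fig.savefig(out_dir / "grand_averages.png", dpi=120)
        plt.close(fig)

    # provenance: name the config checksum the figures derive from
    dataset_cfg = results_dir / "config_checksum.txt"
    summary = {"figures": ["trajectories.png", "grand_averages.png"],
               "config_checksum": dataset_cfg.read_text().strip()
               if dataset_cfg.exists() else None}
    (out_dir / "report.json").write_text(json.dumps(summary, indent=2))
    return out_dir


def run_demo(out_dir: str | Path, seed: int = 0, force: bool = False) -> Path:
    """End-to-end reduced run: simulate, analyze, report in one call."""
    from .config import demo_config

    out_dir = Path(out_dir)
    config = demo_config(seed=seed)
    dataset = run_simulate(config, out_dir / "dataset", force=force)
    results = run_analyze(dataset, out_dir / "results", config=config,
                          force=force)
    checksum = _sha256(dataset / "config.yaml")
    (results / "config_checksum.txt").write_text(checksum)
    run_report(results, out_dir / "report")
    return out_dir
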