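"""End-to-end pipeline runner and report writer.

Ties the stages together: (optionally synthetic) audio + metadata in,
then segmentation -> per-cycle features -> subject aggregation -> cohort
summary, GLM fits with model comparison, prediction grid, PSD200 group
comparisons, risk flags and summary plots. Everything is written as
CSV/JSON/PNG under one output directory and is deterministic under the
configured seed in synthetic mode.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import audio, cohort, features, segmentation, synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_cohort", "round_half_up"]


@dataclass(frozen=True)
class PipelineConfig:
    """One run of the full analysis.

    Exactly one input mode: "synthetic" generates a cohort and its
    waveforms from the seeds below; "wav_dir" reads existing WAV files
    named <subject_id>.wav next to a metadata CSV with columns
    subject_id, dm, ht, event, vintage_years.
    """

    out_dir: str | Path
    mode: str = "synthetic"
    wav_dir: str | Path | None = None
    metadata_csv: str | Path | None = None
    seed: int = 0
    cohort_config: synthetic.CohortConfig | None = None
    acoustics: synthetic.AcousticsConfig | None = None
    coefficients: synthetic.ModelCoefficients | None = None
    seg_config: segmentation.SegmentationConfig = field(
        default_factory=segmentation.SegmentationConfig)
    coding: str = "table4"
    risk_threshold: float = cohort.DEFAULT_RISK_THRESHOLD

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "wav_dir"):
            raise ValueError(f"mode must be 'synthetic' or 'wav_dir', got {self.mode!r}")
        if self.mode == "wav_dir" and (self.wav_dir is None or self.metadata_csv is None):
            raise ValueError("wav_dir mode requires wav_dir and metadata_csv")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 17.05 -> 17.1), as used for all
    displayed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_cohort(profiles: list[synthetic.SubjectProfile]) -> pd.DataFrame:
    """Counts and percentages of each history variable, plus vintage
    mean +/- sd, in the standard cohort-overview layout."""
    if not profiles:
        raise ValueError("no profiles to summarize")
    n = len(profiles)
    rows = []

    def add(variable: str, level: str, count: int) -> None:
        rows.append({"variable": variable, "level": level, "n": count,
                     "percent": round_half_up(100.0 * count / n)})

    n_dm = sum(p.dm for p in profiles)
    n_ht = sum(p.ht for p in profiles)
    n_event = sum(p.event for p in profiles)
    n_ge5 = sum(p.vintage_ge5 for p in profiles)
    add("diabetes_mellitus", "+", n_dm)
    add("diabetes_mellitus", "-", n - n_dm)
    add("hypertension", "+", n_ht)
    add("hypertension", "-", n - n_ht)
    add("event", "+", n_event)
    add("event", "-", n - n_event)
    add("vintage", "<5 years", n - n_ge5)
    add("vintage", ">=5 years", n_ge5)
    df = pd.DataFrame(rows)
    vintages = np.array([p.vintage_years for p in profiles])
    df.attrs["vintage_mean"] = float(vintages.mean())
    df.attrs["vintage_sd"] = float(vintages.std(ddof=1)) if n > 1 else 0.0
    return df


def _load_inputs(config: PipelineConfig, out_dir: Path):
    """Return (profiles, recordings) for either input mode."""
    if config.mode == "synthetic":
        cohort_cfg = config.cohort_config or synthetic.CohortConfig(seed=config.seed)
        acoustics = config.acoustics or synthetic.AcousticsConfig(seed=config.seed)
        audio_dir = out_dir / "audio"
        synthetic.generate_dataset(cohort_cfg, acoustics, config.coefficients, audio_dir)
        wav_dir, metadata_csv = audio_dir, audio_dir / "metadata.csv"
    else:
        wav_dir, metadata_csv = Path(config.wav_dir), Path(config.metadata_csv)

    meta = pd.read_csv(metadata_csv, dtype={"subject_id": str})
    profiles, recordings = [], {}
    for row in meta.itertuples():
        profile = synthetic.SubjectProfile(
            subject_id=row.subject_id, dm=int(row.dm), ht=int(row.ht),
            event=int(row.event), vintage_years=float(row.vintage_years))
        wav_path = Path(wav_dir) / f"{profile.subject_id}.wav"
        if not wav_path.exists():
            raise FileNotFoundError(
                f"no WAV file for subject {profile.subject_id}: expected {wav_path}")
        profiles.append(profile)
        recordings[profile.subject_id] = audio.read_wav(wav_path, profile.subject_id)
    return profiles, recordings


def _extract_subject_features(config: PipelineConfig, profiles, recordings):
    subject_features, findings = [], {}
    for profile in profiles:
        rec = recordings[profile.subject_id]
        found = audio.validate_recording(rec)
        if found:
            findings[profile.subject_id] = found
        try:
            env = segmentation.compute_envelope(rec, config.seg_config)
            segments = segmentation.detect_cycles(env, rec.sample_rate, config.seg_config)
            chosen = segmentation.select_cycles(segments, rec, config=config.seg_config)
            per_cycle = [features.cycle_features(seg.extract(rec), rec.sample_rate)
                         for seg in chosen]
            subject_features.append(features.aggregate_subject(per_cycle, profile.subject_id))
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed for subject {profile.subject_id}: {exc}") from exc
    return subject_features, findings


def _plot_band_means(df: pd.DataFrame, value_col: str, ylabel: str, path: Path) -> None:
    """Mean of value_col per band with 95% CI error bars."""
    g = df.groupby("hz")[value_col]
    mean, sd, n = g.mean(), g.std(ddof=1), g.count()
    half = 1.96 * sd / np.sqrt(n)
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.errorbar(mean.index, mean, yerr=half, fmt="o-", capsize=3, markersize=3)
    ax.set_xlabel("frequency band center (Hz)")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a dict of the in-memory results plus the paths written.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles, recordings = _load_inputs(config, out_dir)
    subject_features, findings = _extract_subject_features(config, profiles, recordings)

    summary = summarize_cohort(profiles)
    summary.to_csv(out_dir / "cohort_summary.csv", index=False)

    feat_rows = []
    for f in subject_features:
        for j, hz in enumerate(features.BAND_CENTERS):
            feat_rows.append({"subject_id": f.subject_id, "hz": int(hz),
                              "tmp": f.tmp_by_band[j], "psd": f.band_psd[j]})
    band_df = pd.DataFrame(feat_rows)
    band_df.to_csv(out_dir / "band_features.csv", index=False)

    by_id = {p.subject_id: p for p in profiles}
    subj_df = pd.DataFrame([{
        "subject_id": f.subject_id, "mf": f.mf, "psd200": f.psd200,
        "n_cycles_used": f.n_cycles_used,
        "dm": by_id[f.subject_id].dm, "ht": by_id[f.subject_id].ht,
        "event": by_id[f.subject_id].event,
        "vintage_ge5": by_id[f.subject_id].vintage_ge5,
        "risk_flag": cohort.flag_risk(f.psd200, config.risk_threshold),
    } for f in subject_features])
    subj_df.to_csv(out_dir / "subject_features.csv", index=False)

    long_table = cohort.build_long_table(subject_features, profiles)
    fit_a = cohort.fit_tmp_glm(long_table, "A")
    fit_b = cohort.fit_tmp_glm(long_table, "B")
    preferred = cohort.compare_models(fit_a, fit_b)
    grid = cohort.predict_tmp_grid(fit_b, coding=config.coding)
    grid.to_csv(out_dir / "tmp_prediction_grid.csv", index=False)

    comparisons = cohort.compare_psd200_by_history(subj_df)
    comp_df = pd.DataFrame([{
        "variable": c.variable,
        "group_neg": c.labels[0], "n_neg": c.n[0], "mean_neg": c.mean[0],
        "sd_neg": c.sd[0], "ci_neg_low": c.ci[0][0], "ci_neg_high": c.ci[0][1],
        "group_pos": c.labels[1], "n_pos": c.n[1], "mean_pos": c.mean[1],
        "sd_pos": c.sd[1], "ci_pos_low": c.ci[1][0], "ci_pos_high": c.ci[1][1],
        "t": c.t, "df": c.df, "p": c.p,
    } for c in comparisons])
    comp_df.to_csv(out_dir / "psd200_comparisons.csv", index=False)

    def fit_payload(fit: cohort.GLMFit) -> dict:
        return {"model": fit.model_label, "aic": fit.aic, "n_obs": fit.n_obs,
                "terms": {t: {"estimate": fit.params[t], "se": fit.bse[t],
                              "ci": list(fit.conf_int[t]), "p": fit.pvalues[t]}
                          for t in fit.terms}}

    results_json = {
        "seed": config.seed,
        "mode": config.mode,
        "n_subjects": len(profiles),
        "validation_findings": findings,
        "model_a": fit_payload(fit_a),
        "model_b": fit_payload(fit_b),
        "preferred_model": preferred,
        "n_dropped_rows": long_table.attrs["n_dropped"],
        "risk_threshold": config.risk_threshold,
        "n_flagged": int(subj_df["risk_flag"].sum()),
    }
    with open(out_dir / "results.json", "w") as fh:
        json.dump(results_json, fh, indent=2)

    _plot_band_means(band_df, "tmp", "mean TMP (% of cycle)", out_dir / "tmp_by_band.png")
    _plot_band_means(band_df, "psd", "mean PSD (power/Hz)", out_dir / "psd_by_band.png")

    return {
        "profiles": profiles,
        "subject_features": subject_features,
        "cohort_summary": summary,
        "long_table": long_table,
        "fit_a": fit_a,
        "fit_b": fit_b,
        "preferred_model": preferred,
        "prediction_grid": grid,
        "comparisons": comparisons,
        "subject_table": subj_df,
        "out_dir": out_dir,
    }
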