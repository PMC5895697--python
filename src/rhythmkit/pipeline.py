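"""End-to-end orchestration: synthesize/load -> preprocess -> cosinor ->
mood PCA -> coherence -> group statistics, with reproducible plain-text
outputs.

Every run writes a manifest echoing the full configuration, seed and
package version, so a run is reproducible bit-for-bit from its manifest.
A participant failing quality rules is logged and skipped, never aborting
the cohort.  All outputs are TSV/CSV/YAML.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rhythmkit import cosinor as _cosinor
from rhythmkit import mood as _mood
from rhythmkit import coherence as _coherence
from rhythmkit import stats as _stats
from rhythmkit import synthetic as _synthetic
from rhythmkit.preprocessing import build_analysis_signals, interpolate_mood
from rhythmkit.synthetic import (
    MINUTES_PER_DAY,
    CohortSpec,
    ParticipantRecording,
    default_group,
    generate_cohort,
    read_cohort,
    write_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

log = logging.getLogger("rhythmkit")

SIGNAL_NAMES = ("activity", "sleep", "hr")


@dataclass
class RunConfig:
    """Pipeline configuration; every field is echoed into the run manifest.

    Either ``input_dir`` (a cohort directory in the package CSV dialect) or
    ``synthesis`` (groups to generate) must be set.  ``synthesis`` is a
    mapping with keys ``days`` and ``groups``: a list of group mappings
    accepting label, n, hr_lag_hours, hr_lag_sd_hours, coupling_negative,
    coupling_irritable, noise_scale.
    """

    out_dir: str = "rhythmkit_run"
    seed: int = 0
    input_dir: str | None = None
    synthesis: dict | None = None
    # preprocessing
    window_hours: float = 6.0
    window_mode: str = "centered"
    max_gap_minutes: int = 60
    # cosinor
    min_coverage: float = 0.75
    phase_method: str = "circular"
    difference_method: str = "of_averages"
    # mood PCA
    pca_standardize: bool = True
    # coherence (Welch)
    segment_hours: float = 24.0
    overlap_fraction: float = 0.5
    window_shape: str = "hann"
    detrend_linear: bool = False
    min_days_frequency: float = 4.0
    truncate_days_frequency: float = 4.0
    # statistics
    alpha: float = 0.05
    n_perm: int = 1000
    storey_lambda: float = 0.5
    vs_zero_method: str = "signed_rank"
    permutation_mode: str = "pointwise"

    def __post_init__(self) -> None:
        if self.input_dir is None and self.synthesis is None:
            raise ValueError("RunConfig needs input_dir or a synthesis block")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _synthesis_spec(cfg: RunConfig) -> CohortSpec:
    syn = dict(cfg.synthesis or {})
    days = int(syn.get("days", 7))
    groups = []
    for g in syn.get("groups", []):
        groups.append(
            default_group(
                label=g["label"],
                n_participants=int(g.get("n", 8)),
                hr_lag_hours=float(g.get("hr_lag_hours", 0.0)),
                hr_lag_sd_hours=float(g.get("hr_lag_sd_hours", 0.0)),
                coupling_negative=float(g.get("coupling_negative", 0.0)),
                coupling_irritable=float(g.get("coupling_irritable", 0.0)),
                noise_scale=float(g.get("noise_scale", 1.0)),
            )
        )
    if not groups:
        raise ValueError("synthesis block must define at least one group")
    return CohortSpec(groups=groups, days=days, seed=cfg.seed)


def validate_inputs(directory) -> dict:
    """Per-participant eligibility report for a cohort directory.

    Time-domain analysis needs >= 1 day of recording; frequency-domain
    (coherence) needs >= 4 days, of which the first 4 are used.  Malformed
    participant directories are itemized, not fatal.
    """
    root = Path(directory)
    if not root.exists():
        raise FileNotFoundError(f"input directory {root} does not exist")
    report: dict = {"participants": {}, "errors": {}}
    for pdir in sorted(p for p in root.iterdir() if p.is_dir()):
        try:
            rec = _synthetic.read_participant(pdir)
        except Exception as exc:  # itemized parse errors
            report["errors"][pdir.name] = str(exc)
            continue
        n_days = rec.n_days
        hr_present = int(np.isfinite(rec.hr).sum())
        entry = {
            "group": rec.group,
            "days": n_days,
            "hr_samples": hr_present,
            "mood_entries": len(rec.mood),
            "time_domain": bool(n_days >= 1 and hr_present > 0),
            "frequency_domain": bool(n_days >= 4 and hr_present > 0),
        }
        if not entry["time_domain"]:
            entry["excluded_reason"] = (
                "no HR data" if hr_present == 0 else "under 1 day of recording"
            )
        report["participants"][pdir.name] = entry
    return report


def _truncate(rec: ParticipantRecording, days: float) -> ParticipantRecording:
    n = int(days * MINUTES_PER_DAY)
    if len(rec.t_min) <= n:
        return rec
    return ParticipantRecording(
        id=rec.id,
        group=rec.group,
        t_min=rec.t_min[:n],
        accel={k: v[:n] for k, v in rec.accel.items()},
        hr=rec.hr[:n],
        mood=[e for e in rec.mood if e.timestamp < n],
        ground_truth=rec.ground_truth,
        diagnostics=rec.diagnostics,
    )


def _fill_remaining(x: np.ndarray) -> np.ndarray:
    """Linearly interpolate every remaining NaN (coherence needs gap-free
    input; every signal is carried at 1-min resolution)."""
    x = np.asarray(x, dtype=float).copy()
    ok = np.isfinite(x)
    if ok.all():
        return x
    if not ok.any():
        raise ValueError("signal has no finite samples")
    idx = np.arange(len(x))
    x[~ok] = np.interp(idx[~ok], idx[ok], x[ok])
    return x


def _mood_component_series(rec, model):
    """Interpolated 1-min series per mood component for one participant."""
    frame = rec.mood_frame()
    scores = _mood.project_mood(frame, model)
    out = {}
    for comp in model.component_labels:
        t_grid, v = interpolate_mood(scores["t_min"], scores[comp])
        out[comp] = (t_grid, v)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all outputs under ``config.out_dir``.

    Returns the run manifest (also written as ``run_manifest.yaml``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __import__("rhythmkit").__version__,
        "config": asdict(config),
        "stages": {},
        "skipped": {},
    }

    # ---- acquire cohort -------------------------------------------------
    if config.synthesis is not None:
        spec = _synthesis_spec(config)
        recordings, cohort_manifest = generate_cohort(spec)
        cohort_dir = out / "cohort"
        write_cohort(recordings, cohort_manifest, cohort_dir)
        manifest["stages"]["synthesize"] = {
            "cohort_dir": str(cohort_dir),
            "n_participants": len(recordings),
        }
        log.info("synthesized %d participants", len(recordings))
    else:
        recordings = read_cohort(config.input_dir)
        manifest["stages"]["load"] = {
            "input_dir": str(config.input_dir),
            "n_participants": len(recordings),
        }

    groups = sorted({r.group for r in recordings})

    # ---- preprocessing --------------------------------------------------
    signals_by_id: dict[str, object] = {}
    for rec in recordings:
        try:
            sig = build_analysis_signals(
                rec,
                window_hours=config.window_hours,
                mode=config.window_mode,
                max_gap_minutes=config.max_gap_minutes,
            )
        except Exception as exc:
            log.warning("preprocessing failed for %s: %s", rec.id, exc)
            manifest["skipped"][rec.id] = f"preprocessing: {exc}"
            continue
        signals_by_id[rec.id] = sig
        pdir = out / "signals" / rec.id
        pdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "t_min": sig.t_min,
                "activity": sig.activity,
                "sleep": sig.sleep,
                "hr": sig.hr,
            }
        ).to_csv(pdir / "signals.csv", index=False, float_format="%.6g")
        with open(pdir / "clean_report.yaml", "w") as fh:
            yaml.safe_dump(asdict(sig.clean_report), fh)
    manifest["stages"]["preprocess"] = {"n_processed": len(signals_by_id)}

    # ---- cosinor --------------------------------------------------------
    summaries: list[_cosinor.DiurnalSummary] = []
    rows = []
    for rec in recordings:
        if rec.id not in signals_by_id:
            continue
        summ = _cosinor.summarize_participant(
            signals_by_id[rec.id],
            participant_id=rec.id,
            group=rec.group,
            min_coverage=config.min_coverage,
            phase_method=config.phase_method,
            difference_method=config.difference_method,
        )
        if not summ.modalities:
            log.warning("no valid days for %s; skipping", rec.id)
            manifest["skipped"][rec.id] = "cosinor: no valid days"
            continue
        summaries.append(summ)
        for m, vals in summ.modalities.items():
            rows.append(
                {
                    "participant": summ.participant_id,
                    "group": summ.group,
                    "modality": m,
                    "avg_phase": vals["avg_phase"],
                    "avg_mesor": vals["avg_mesor"],
                    "avg_amplitude": vals["avg_amplitude"],
                    "n_days": vals["n_days"],
                    "d_hr_act": summ.d_hr_act,
                    "d_hr_slp": summ.d_hr_slp,
                    "d_act_slp": summ.d_act_slp,
                }
            )
    summary_df = pd.DataFrame(rows)
    summary_df.to_csv(out / "diurnal_summary.tsv", sep="\t", index=False, float_format="%.6g")
    manifest["stages"]["cosinor"] = {"n_participants": len(summaries)}

    # figure-ready: group-average sinusoids repeated over two days
    fig_rows = []
    minutes2 = np.arange(2 * MINUTES_PER_DAY)
    for g in groups:
        for m in SIGNAL_NAMES:
            vals = [
                s.modalities[m]
                for s in summaries
                if s.group == g and m in s.modalities
            ]
            if not vals:
                continue
            phase = _cosinor.circular_mean_hours([v["avg_phase"] for v in vals])
            mesor = float(np.mean([v["avg_mesor"] for v in vals]))
            amp = float(np.mean([v["avg_amplitude"] for v in vals]))
            curve = mesor + amp * np.cos(2 * np.pi * (minutes2 / 60.0 - phase) / 24.0)
            fig_rows.append(
                pd.DataFrame(
                    {"group": g, "modality": m, "t_min": minutes2, "value": curve}
                )
            )
    if fig_rows:
        pd.concat(fig_rows, ignore_index=True).to_csv(
            out / "average_sinusoids.csv", index=False, float_format="%.6g"
        )

    # ---- mood PCA -------------------------------------------------------
    pooled = pd.concat(
        [r.mood_frame() for r in recordings if len(r.mood) > 0], ignore_index=True
    )
    model = _mood.fit_mood_pca(pooled, standardize=config.pca_standardize)
    with open(out / "mood_model.yaml", "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=True)
    mood_series: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for rec in recordings:
        if len(rec.mood) < 2:
            manifest["skipped"].setdefault(rec.id, "mood: under 2 entries")
            continue
        scores = _mood.project_mood(rec.mood_frame(), model)
        pdir = out / "signals" / rec.id
        pdir.mkdir(parents=True, exist_ok=True)
        scores.to_csv(pdir / "mood_scores.csv", index=False, float_format="%.6g")
        mood_series[rec.id] = _mood_component_series(rec, model)
    manifest["stages"]["mood"] = {
        "n_entries_pooled": int(len(pooled)),
        "explained_variance": model.explained_variance.tolist(),
    }

    # figure-ready: diurnal mood profiles per group and component
    prof_rows = []
    for g in groups:
        members = {
            rid: series
            for rid, series in mood_series.items()
            if next(r.group for r in recordings if r.id == rid) == g
        }
        if not members:
            continue
        for comp in model.component_labels:
            prof = _mood.average_diurnal_profile(
                {rid: s[comp] for rid, s in members.items()},
                component=comp,
                group=g,
            )
            prof_rows.append(
                pd.DataFrame(
                    {
                        "group": g,
                        "component": comp,
                        "minute_of_day": prof.minutes,
                        "mean": prof.mean,
                        "band": prof.band,
                        "no_prompt": prof.no_prompt_mask.astype(int),
                    }
                )
            )
    if prof_rows:
        pd.concat(prof_rows, ignore_index=True).to_csv(
            out / "mood_profiles.csv", index=False, float_format="%.6g"
        )

    # ---- coherence ------------------------------------------------------
    coh_by_pair: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    coh_freq: np.ndarray | None = None
    n_coh = 0
    for rec in recordings:
        if rec.id not in signals_by_id or rec.id not in mood_series:
            continue
        if rec.n_days < config.min_days_frequency:
            manifest["skipped"].setdefault(
                rec.id, f"coherence: under {config.min_days_frequency} days"
            )
            continue
        trunc = _truncate(rec, config.truncate_days_frequency)
        sig = build_analysis_signals(
            trunc,
            window_hours=config.window_hours,
            mode=config.window_mode,
            max_gap_minutes=config.max_gap_minutes,
        )
        phys = {
            "activity": _fill_remaining(sig.activity),
            "sleep": _fill_remaining(sig.sleep),
            "hr": _fill_remaining(sig.hr),
        }
        series = _mood_component_series(trunc, model)
        frame: dict[str, np.ndarray] = {}
        ok = True
        for sname, x in phys.items():
            for comp in model.component_labels:
                t_grid, v = series[comp]
                lo, hi = int(t_grid[0]), int(t_grid[-1])
                try:
                    spec = _coherence.msc(
                        x[lo : hi + 1],
                        v,
                        segment_hours=config.segment_hours,
                        overlap_fraction=config.overlap_fraction,
                        window_shape=config.window_shape,
                        detrend_linear=config.detrend_linear,
                        pair=(sname, comp),
                        participant_id=rec.id,
                    )
                except ValueError as exc:
                    log.warning("coherence failed for %s (%s-%s): %s", rec.id, sname, comp, exc)
                    manifest["skipped"].setdefault(rec.id, f"coherence: {exc}")
                    ok = False
                    break
                frame[f"{sname}_{comp}"] = spec.C_xy
                coh_freq = spec.freq
            if not ok:
                break
        if not ok:
            continue
        n_coh += 1
        pdir = out / "signals" / rec.id
        pdir.mkdir(parents=True, exist_ok=True)
        coh_df = pd.DataFrame({"freq_cpd": coh_freq, **frame})
        coh_df.to_csv(pdir / "coherence.csv", index=False, float_format="%.6g")
        for key, c in frame.items():
            sname, comp = key.split("_", 1)
            coh_by_pair.setdefault((sname, comp), {})[rec.id] = c
    manifest["stages"]["coherence"] = {"n_participants": n_coh}

    # figure-ready: group-mean coherence per pair
    mean_rows = []
    group_of = {r.id: r.group for r in recordings}
    for (sname, comp), per_pid in sorted(coh_by_pair.items()):
        for g in groups:
            mat = [c for rid, c in per_pid.items() if group_of[rid] == g]
            if not mat:
                continue
            mean_rows.append(
                pd.DataFrame(
                    {
                        "group": g,
                        "signal": sname,
                        "component": comp,
                        "freq_cpd": coh_freq,
                        "coherence": np.mean(mat, axis=0),
                    }
                )
            )
    if mean_rows:
        pd.concat(mean_rows, ignore_index=True).to_csv(
            out / "coherence_mean.csv", index=False, float_format="%.6g"
        )

    # ---- statistics -----------------------------------------------------
    if config.n_perm == 0:
        log.warning("n_perm=0: statistics stage skipped")
        manifest["stages"]["stats"] = {"skipped": "n_perm=0"}
    else:
        table = _table1(summaries, groups, config)
        table.to_csv(out / "table1.tsv", sep="\t", index=False, float_format="%.4g")
        perm_df = _permutation_masks(coh_by_pair, coh_freq, group_of, groups, config)
        if perm_df is not None:
            perm_df.to_csv(out / "permutation_masks.csv", index=False, float_format="%.6g")
        manifest["stages"]["stats"] = {
            "n_table_rows": int(len(table)),
            "n_perm": config.n_perm,
        }

    with open(out / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def _table1(summaries, groups, config: RunConfig) -> pd.DataFrame:
    """Within-group phase-difference tests and between-group comparisons
    (phase / MESOR / amplitude per modality), each family FDR-corrected."""
    rows = []
    diff_fields = {"HR-ACT": "d_hr_act", "HR-SLP": "d_hr_slp", "ACT-SLP": "d_act_slp"}

    vs_zero_p = []
    vs_zero_rows = []
    for quantity, attr in diff_fields.items():
        for g in groups:
            vals = np.asarray(
                [getattr(s, attr) for s in summaries if s.group == g], dtype=float
            )
            vals = vals[np.isfinite(vals)]
            if len(vals) < 5:
                continue
            stat, p = _stats.test_vs_zero(vals, method=config.vs_zero_method)
            vs_zero_rows.append(
                {
                    "family": "within_group_vs_zero",
                    "quantity": quantity,
                    "comparison": g,
                    "mean_1": float(vals.mean()),
                    "sd_1": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "mean_2": float("nan"),
                    "sd_2": float("nan"),
                    "n": len(vals),
                    "statistic": stat,
                    "p_raw": p,
                }
            )
            vs_zero_p.append(p)
    if vs_zero_p:
        q = _stats.storey_fdr(vs_zero_p, lambda_=config.storey_lambda)
        for row, qv in zip(vs_zero_rows, q):
            row["q_fdr"] = float(qv)
    rows.extend(vs_zero_rows)

    between_rows = []
    between_p = []
    measures = ("avg_phase", "avg_mesor", "avg_amplitude")
    for m in SIGNAL_NAMES:
        for measure in measures:
            per_group = {
                g: np.asarray(
                    [
                        s.modalities[m][measure]
                        for s in summaries
                        if s.group == g and m in s.modalities
                    ],
                    dtype=float,
                )
                for g in groups
            }
            for ga, gb in combinations(groups, 2):
                a = per_group[ga][np.isfinite(per_group[ga])]
                b = per_group[gb][np.isfinite(per_group[gb])]
                if len(a) < 3 or len(b) < 3:
                    continue
                stat, p = _stats.pairwise_group_test(a, b)
                between_rows.append(
                    {
                        "family": "between_groups",
                        "quantity": f"{m}.{measure}",
                        "comparison": f"{ga} vs {gb}",
                        "mean_1": float(a.mean()),
                        "sd_1": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
                        "mean_2": float(b.mean()),
                        "sd_2": float(b.std(ddof=1)) if len(b) > 1 else 0.0,
                        "n": len(a) + len(b),
                        "statistic": stat,
                        "p_raw": p,
                    }
                )
                between_p.append(p)
    if between_p:
        q = _stats.storey_fdr(between_p, lambda_=config.storey_lambda)
        for row, qv in zip(between_rows, q):
            row["q_fdr"] = float(qv)
    rows.extend(between_rows)
    return pd.DataFrame(rows)


def _permutation_masks(coh_by_pair, freq, group_of, groups, config: RunConfig):
    if not coh_by_pair or freq is None:
        return None
    out_rows = []
    for pi, ((sname, comp), per_pid) in enumerate(sorted(coh_by_pair.items())):
        for gi, (ga, gb) in enumerate(combinations(groups, 2)):
            a = np.array([c for rid, c in sorted(per_pid.items()) if group_of[rid] == ga])
            b = np.array([c for rid, c in sorted(per_pid.items()) if group_of[rid] == gb])
            if len(a) < 3 or len(b) < 3:
                continue
            seed = int(
                np.random.SeedSequence([config.seed, pi, gi]).generate_state(1)[0]
                % (2**31)
            )
            res = _stats.permutation_coherence_test(
                a,
                b,
                freq=freq,
                n_perm=config.n_perm,
                seed=seed,
                alpha=config.alpha,
                mode=config.permutation_mode,
            )
            out_rows.append(
                pd.DataFrame(
                    {
                        "group_pair": f"{ga} vs {gb}",
                        "signal": sname,
                        "component": comp,
                        "freq_cpd": res.freq,
                        "p_perm": res.p_perm,
                        "significant": res.significant_mask.astype(int),
                    }
                )
            )
    if not out_rows:
        return None
    return pd.concat(out_rows, ignore_index=True)
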