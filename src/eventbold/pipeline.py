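"""End-to-end orchestration: stimuli and observers -> boundaries -> GLM ->
cohort statistics, from a single seeded configuration.

In synthetic mode the pipeline generates keypress logs, consensus boundaries,
a frame sequence with its edge regressor, a cohort with known ground truth,
per-subject forward-modeled ROI BOLD, per-subject GLM fits, and the full set
of cohort statistics.  In files mode the same stages run from TSV/CSV inputs
on disk.  A run is bit-reproducible given (config, seed); every report embeds
the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boundaries import (
    BoundarySet,
    consensus_boundaries,
    hit_rate,
    read_keypress_tsv,
    within_event_timepoints,
    write_boundaries_tsv,
    write_keypress_tsv,
)
from .glm import build_design, contrast_variance, fit_glm, qc_filter
from .stats import (
    age_tertiles,
    anova_tukey,
    ols_regression,
    one_sample_t,
    pearson_corr,
    sex_difference_check,
)
from .boundaries import fisher_z_compare
from .synth import (
    EffectSpec,
    simulate_cohort,
    simulate_frames,
    simulate_keypress_logs,
    simulate_motion,
    simulate_roi_bold,
    substream,
    write_cohort_csv,
    read_cohort_csv,
)
from .visual import edge_regressor, edge_series_from_proportions, read_edge_csv, write_edge_tsv

__all__ = [
    "RoiConfig",
    "RunConfig",
    "run_pipeline",
    "boundary_recovery_rate",
    "null_rejection_rate",
    "DEFAULT_TRUE_BOUNDARIES",
]

# Default ground-truth boundary times (s) for an ~8-minute stimulus:
# 12 boundaries, irregularly spaced, all gaps >= 20 s.
DEFAULT_TRUE_BOUNDARIES = (
    22.0, 65.0, 101.0, 144.0, 175.0, 213.0,
    255.0, 294.0, 330.0, 365.0, 410.0, 448.0,
)

NEUROPSYCH_COLS = ["logmem_imm", "logmem_del", "fluency", "visuospatial", "word_memory"]


@dataclass(frozen=True)
class RoiConfig:
    """Per-ROI generative settings for synthetic runs.

    ``target_age_r`` requests calibration of the between-subject amplitude
    noise so the *measured* adjusted-beta-vs-age correlation lands on the
    target (GLM measurement variance is subtracted from the noise budget);
    alternatively fix ``amplitude_noise_sd`` directly.
    """

    name: str
    base_amplitude: float = 0.12
    age_slope: float = 0.0
    target_age_r: float | None = None
    amplitude_noise_sd: float | None = 0.06
    within_amplitude: float = 0.05
    noise_sd: float = 0.12
    ar1_coef: float = 0.3
    drift_slope: float = 0.0
    edge_coupling: float = 0.0
    behavior_coupling: float = 0.0


def default_rois() -> list[RoiConfig]:
    """The study-condition ROI set: a posterior-hippocampus-like effect ROI
    (age decline targeting r = -0.345, memory coupling), an anterior-
    hippocampus-like control (no age effect), and a visual-cortex-like
    control driven by the edge regressor."""
    return [
        RoiConfig(
            name="phpc",
            base_amplitude=0.167,
            age_slope=-0.00138,
            target_age_r=-0.345,
            amplitude_noise_sd=None,
            behavior_coupling=3.08,
        ),
        RoiConfig(name="ahpc", base_amplitude=0.104, amplitude_noise_sd=0.06),
        RoiConfig(name="vc", base_amplitude=0.06, amplitude_noise_sd=0.05, edge_coupling=0.5),
    ]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML-loadable; hashable for provenance."""

    mode: str = "synthetic"
    seed: int = 0
    tr_s: float = 2.47
    n_tr: int = 193
    duration_s: float = 480.0
    # observer / boundary parameters
    n_observers: int = 16
    true_boundaries: tuple = DEFAULT_TRUE_BOUNDARIES
    jitter_sd: float = 1.0
    miss_p: float = 0.15
    fa_rate: float = 0.005
    window_s: float = 5.0
    min_agreement: float = 0.5
    min_separation_s: float = 6.0
    n_within: int | None = None
    # stimulus parameters
    frame_rate: float = 6.0
    frame_shape: tuple = (32, 32)
    grad_threshold: float = 0.2
    # cohort parameters
    n_subjects: int = 546
    age_range: tuple = (18.0, 88.0)
    rois: list = field(default_factory=default_rois)
    # QC thresholds
    mean_fd_limit: float = 0.5
    max_fd_limit: float = 3.0
    tsnr_sd_limit: float = 2.0
    # statistics options
    compare_rois: tuple = ("phpc", "ahpc")
    regression_outcome: str = "logmem_del"
    # files mode paths
    files: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.tr_s <= 0 or self.n_tr <= 0 or self.duration_s <= 0:
            raise ValueError("tr_s, n_tr and duration_s must be positive")
        if not 0 <= self.miss_p <= 1:
            raise ValueError("miss_p must lie in [0, 1]")
        if not 0 < self.min_agreement <= 1:
            raise ValueError("min_agreement must lie in (0, 1]")
        self.rois = [r if isinstance(r, RoiConfig) else RoiConfig(**r) for r in self.rois]
        self.true_boundaries = tuple(float(t) for t in self.true_boundaries)
        if self.mode == "files":
            for key, path in self.files.items():
                if not os.path.exists(path):
                    raise FileNotFoundError(f"files.{key}: no such path: {path}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rois"] = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else r for r in self.rois]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _frame_schedule(boundaries, duration: float) -> list[dict]:
    """Visual pattern schedule whose content changes at each event boundary."""
    cuts = [0.0, *[float(b) for b in boundaries], duration]
    patterns = [
        {"pattern": "checkerboard", "cell": 8},
        {"pattern": "uniform", "value": 0.5},
        {"pattern": "checkerboard", "cell": 4},
        {"pattern": "vertical_step", "position": 0.5},
    ]
    schedule = []
    for i in range(len(cuts) - 1):
        seg = dict(patterns[i % len(patterns)])
        seg["duration"] = cuts[i + 1] - cuts[i]
        schedule.append(seg)
    return schedule


def _effect_spec(roi: RoiConfig, measurement_var: float, age_sd: float) -> EffectSpec:
    amp_sd = roi.amplitude_noise_sd
    if roi.target_age_r is not None:
        from .synth import amplitude_noise_for_target

        amp_sd = amplitude_noise_for_target(
            roi.target_age_r, roi.age_slope, age_sd, measurement_var
        )
    if amp_sd is None:
        raise ValueError(f"ROI {roi.name}: set target_age_r or amplitude_noise_sd")
    return EffectSpec(
        roi_name=roi.name,
        base_amplitude=roi.base_amplitude,
        age_slope=roi.age_slope,
        amplitude_noise_sd=amp_sd,
        within_amplitude=roi.within_amplitude,
        noise_sd=roi.noise_sd,
        ar1_coef=roi.ar1_coef,
        drift_slope=roi.drift_slope,
        edge_coupling=roi.edge_coupling,
        behavior_coupling=roi.behavior_coupling,
    )


def _true_beta_vector(design, spec: EffectSpec, amplitude: float) -> np.ndarray:
    betas = np.zeros(len(design.names))
    betas[design.names.index("boundary")] = amplitude
    betas[design.names.index("within_event")] = spec.within_amplitude
    betas[design.names.index("edge")] = spec.edge_coupling
    betas[design.names.index("drift")] = spec.drift_slope
    return betas


def _fit_cohort(config, bset, within, edge_per_tr, subjects, specs, truth):
    """Per-subject designs, forward models (synthetic) and GLM fits."""
    rows = []
    truth_idx = truth.set_index("subject_id") if truth is not None else None
    for i, subj in enumerate(subjects):
        motion = simulate_motion(config.n_tr, seed=substream(config.seed, "motion", i))
        design = build_design(
            bset, within, edge_per_tr, motion, config.n_tr, config.tr_s
        )
        row = {"subject_id": subj.subject_id}
        for j, spec in enumerate(specs):
            amp = float(truth_idx.loc[subj.subject_id, f"amp_{spec.roi_name}"])
            ts = simulate_roi_bold(
                design,
                _true_beta_vector(design, spec, amp),
                spec.noise_sd,
                spec.ar1_coef,
                seed=substream(config.seed, "bold", i, j),
                subject_id=subj.subject_id,
                roi_name=spec.roi_name,
            )
            betas = fit_glm(ts, design)
            row[f"boundary_{spec.roi_name}"] = betas.boundary_beta
            row[f"within_{spec.roi_name}"] = betas.within_beta
            row[f"adjusted_{spec.roi_name}"] = betas.adjusted_beta
        rows.append(row)
    return pd.DataFrame(rows)


def _fit_cohort_files(config, bset, within, edge_per_tr, subjects):
    from .glm import RoiTimeSeries

    series_dir = config.files["roi_series_dir"]
    motion_dir = config.files.get("motion_dir")
    rows = []
    for subj in subjects:
        tsv = os.path.join(series_dir, f"{subj.subject_id}.tsv")
        if not os.path.exists(tsv):
            raise FileNotFoundError(f"ROI series not found: {tsv}")
        df = pd.read_csv(tsv, sep="\t")
        motion = None
        if motion_dir:
            mpath = os.path.join(motion_dir, f"{subj.subject_id}.tsv")
            motion = pd.read_csv(mpath, sep="\t").to_numpy(dtype=float)
        design = build_design(bset, within, edge_per_tr, motion, config.n_tr, config.tr_s)
        row = {"subject_id": subj.subject_id}
        for roi in df.columns:
            ts = RoiTimeSeries(
                subject_id=subj.subject_id,
                roi_name=roi,
                values=df[roi].to_numpy(dtype=float),
                tr_s=config.tr_s,
            )
            betas = fit_glm(ts, design)
            row[f"boundary_{roi}"] = betas.boundary_beta
            row[f"within_{roi}"] = betas.within_beta
            row[f"adjusted_{roi}"] = betas.adjusted_beta
        rows.append(row)
    return pd.DataFrame(rows)


def _cohort_statistics(config, cohort_df, roi_names):
    labeled = age_tertiles(cohort_df)
    per_roi = {}
    for roi in roi_names:
        vals = labeled[f"adjusted_{roi}"].to_numpy()
        t, df_t, p_t = one_sample_t(vals)
        corr = pearson_corr(labeled["age"].to_numpy(), vals)
        grp = anova_tukey(vals, labeled["age_group"].to_numpy())
        sex_t, sex_p = sex_difference_check(vals, labeled["sex"].to_numpy())
        per_roi[roi] = {
            "one_sample_t": {"t": t, "df": df_t, "p": p_t},
            "age_corr": {"r": corr.r, "p": corr.p, "n": corr.n},
            "anova": {
                "F": grp.F,
                "df": list(grp.df),
                "p": grp.p,
                "eta_squared": grp.eta_squared,
                "tukey": [dataclasses.asdict(pair) for pair in grp.tukey],
            },
            "sex_difference": {"t": sex_t, "p": sex_p},
        }

    fisher = None
    r1_name, r2_name = config.compare_rois
    if r1_name in roi_names and r2_name in roi_names:
        r1 = per_roi[r1_name]["age_corr"]
        r2 = per_roi[r2_name]["age_corr"]
        z, p = fisher_z_compare(r1["r"], r1["n"], r2["r"], r2["n"])
        fisher = {"rois": [r1_name, r2_name], "z": z, "p": p}

    predictors = pd.DataFrame(
        {
            **{f"adjusted_{roi}": labeled[f"adjusted_{roi}"] for roi in roi_names},
            "motion": labeled["mean_fd"],
            "fluency": labeled["fluency"],
            "visuospatial": labeled["visuospatial"],
            "word_memory": labeled["word_memory"],
            "logmem_imm": labeled["logmem_imm"],
            "age": labeled["age"],
        }
    )
    if config.regression_outcome == "logmem_imm":
        predictors = predictors.drop(columns=["logmem_imm"]).assign(
            logmem_del=labeled["logmem_del"]
        )
    regression = ols_regression(labeled[config.regression_outcome], predictors)
    return labeled, per_roi, fisher, regression


def run_pipeline(config: RunConfig, out_dir: str | None = None) -> dict:
    """Execute the full analysis and return the run report as a dict.

    Stages: observers (synthetic mode) -> consensus boundaries and
    within-event controls -> edge regressor -> QC filter -> per-subject GLMs
    -> cohort statistics.  With ``out_dir``, all tables and the JSON report
    are written there.
    """
    scan_len = config.n_tr * config.tr_s

    # --- boundaries
    if config.mode == "synthetic":
        logs = simulate_keypress_logs(
            config.true_boundaries,
            n_observers=config.n_observers,
            jitter_sd=config.jitter_sd,
            miss_p=config.miss_p,
            fa_rate=config.fa_rate,
            duration=config.duration_s,
            seed=config.seed,
        )
    else:
        if "keypress_tsv" not in config.files:
            raise ValueError("files mode requires files.keypress_tsv")
        logs = read_keypress_tsv(config.files["keypress_tsv"], config.duration_s)
    bset = consensus_boundaries(
        logs, config.window_s, config.min_agreement, config.min_separation_s
    )
    if bset.n_boundaries == 0:
        raise RuntimeError("boundary_consensus stage produced no boundaries")
    observed_hit_rate = hit_rate(logs, bset, config.window_s)
    n_within = config.n_within or bset.n_boundaries
    within = within_event_timepoints(
        bset, scan_len, n_within, config.min_separation_s
    )
    bset = bset.with_within_events(within)

    # --- edge regressor
    if config.mode == "synthetic":
        frames = simulate_frames(
            config.duration_s,
            config.frame_rate,
            _frame_schedule(config.true_boundaries, config.duration_s),
            shape=tuple(config.frame_shape),
            seed=config.seed,
        )
        edge = edge_regressor(frames, config.tr_s, config.n_tr, config.grad_threshold)
    elif "edge_frames_csv" in config.files:
        per_frame = read_edge_csv(config.files["edge_frames_csv"])
        edge = edge_series_from_proportions(
            per_frame, config.frame_rate, config.tr_s, config.n_tr
        )
    else:
        raise ValueError("files mode requires files.edge_frames_csv")

    # --- cohort
    age_sd = (config.age_range[1] - config.age_range[0]) / np.sqrt(12.0)
    if config.mode == "synthetic":
        ref_motion = simulate_motion(config.n_tr, seed=substream(config.seed, "motion_ref"))
        ref_design = build_design(
            bset, within, edge.per_tr, ref_motion, config.n_tr, config.tr_s
        )
        specs = []
        for roi in config.rois:
            mvar = contrast_variance(
                ref_design,
                {"boundary": 1.0, "within_event": -1.0},
                roi.noise_sd,
                roi.ar1_coef,
            )
            specs.append(_effect_spec(roi, mvar, age_sd))
        subjects, truth = simulate_cohort(
            config.n_subjects, config.age_range, specs, seed=config.seed
        )
    else:
        if "cohort_csv" not in config.files:
            raise ValueError("files mode requires files.cohort_csv")
        subjects = read_cohort_csv(config.files["cohort_csv"])
        truth, specs = None, None

    kept, excluded = qc_filter(
        subjects, config.mean_fd_limit, config.max_fd_limit, config.tsnr_sd_limit
    )
    if len(kept) < 3:
        raise RuntimeError("fewer than 3 subjects survive QC")

    # --- per-subject GLMs
    if config.mode == "synthetic":
        betas_df = _fit_cohort(config, bset, within, edge.per_tr, kept, specs, truth)
    else:
        betas_df = _fit_cohort_files(config, bset, within, edge.per_tr, kept)
    roi_names = [c[len("adjusted_"):] for c in betas_df.columns if c.startswith("adjusted_")]

    cohort_df = pd.DataFrame([vars(s) for s in kept]).merge(betas_df, on="subject_id")

    # --- cohort statistics
    labeled, per_roi, fisher, regression = _cohort_statistics(config, cohort_df, roi_names)

    report = {
        "provenance": {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "mode": config.mode,
        },
        "boundaries": {
            "count": bset.n_boundaries,
            "times_s": bset.boundary_times.tolist(),
            "agreement": bset.agreement.tolist(),
            "within_event_times_s": within.tolist(),
            "hit_rate": observed_hit_rate,
        },
        "qc": {
            "n_input": len(subjects),
            "n_kept": len(kept),
            "excluded": [
                {"subject_id": e.subject_id, "reasons": list(e.reasons)} for e in excluded
            ],
        },
        "roi_stats": per_roi,
        "age_corr_comparison": fisher,
        "regression": {
            "outcome": config.regression_outcome,
            "table": {
                name: {
                    "coefficient": float(regression.loc[name, "coefficient"]),
                    "std_error": float(regression.loc[name, "std_error"]),
                    "t": float(regression.loc[name, "t"]),
                    "p": float(regression.loc[name, "p"]),
                }
                for name in regression.index
            },
            "r_squared": regression.attrs["r_squared"],
        },
    }

    if out_dir is not None:
        _write_outputs(out_dir, config, report, bset, within, edge, cohort_df, regression, logs)
    return report


def _write_outputs(out_dir, config, report, bset, within, edge, cohort_df, regression, logs):
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    write_boundaries_tsv(bset, os.path.join(out_dir, "boundaries.tsv"))
    pd.DataFrame({"time_s": within}).to_csv(
        os.path.join(out_dir, "within_event.tsv"), sep="\t", index=False
    )
    write_edge_tsv(edge, os.path.join(out_dir, "edge_per_tr.tsv"))
    cohort_df.to_csv(os.path.join(out_dir, "cohort_betas.csv"), index=False)
    regression.to_csv(os.path.join(out_dir, "regression.csv"))
    write_keypress_tsv(logs, os.path.join(out_dir, "keypresses.tsv"))
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# batch experiments used by the acceptance checks


def boundary_recovery_rate(
    n_seeds: int = 100,
    base_seed: int = 0,
    true_boundaries=DEFAULT_TRUE_BOUNDARIES,
    n_observers: int = 16,
    jitter_sd: float = 1.0,
    miss_p: float = 0.1,
    fa_rate: float = 0.005,
    duration: float = 480.0,
    tolerance_s: float = 1.0,
) -> pd.DataFrame:
    """Per-seed consensus recovery of known boundaries.

    A seed counts as an exact recovery when the consensus finds precisely the
    true boundaries (same count, each within ``tolerance_s``, none spurious).
    """
    truth = np.asarray(true_boundaries, dtype=float)
    rows = []
    for k in range(n_seeds):
        logs = simulate_keypress_logs(
            truth,
            n_observers=n_observers,
            jitter_sd=jitter_sd,
            miss_p=miss_p,
            fa_rate=fa_rate,
            duration=duration,
            seed=base_seed + k,
        )
        bset = consensus_boundaries(logs)
        found = bset.boundary_times
        exact = False
        max_err = np.inf
        if found.size == truth.size:
            max_err = float(np.abs(found - truth).max())
            exact = max_err <= tolerance_s
        rows.append(
            {
                "seed": base_seed + k,
                "n_found": int(found.size),
                "max_error_s": max_err,
                "exact_recovery": exact,
                "min_gap_s": float(np.diff(found).min()) if found.size > 1 else np.inf,
                "min_agreement": float(bset.agreement.min()) if found.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def null_rejection_rate(
    n_cohorts: int = 400,
    n_subjects: int = 50,
    base_seed: int = 0,
    alpha: float = 0.05,
    noise_sd: float = 0.12,
    ar1_coef: float = 0.3,
    edge_coupling: float = 0.8,
    n_tr: int = 193,
    tr_s: float = 2.47,
) -> float:
    """Type-I error of the adjusted-beta one-sample t under the null.

    Cohorts carry visually driven signal (a true edge-regressor beta) but
    zero boundary and within-event amplitude; returns the fraction of
    cohorts whose adjusted-beta t-test rejects at ``alpha``.
    """
    scan_len = n_tr * tr_s
    boundaries = np.asarray(DEFAULT_TRUE_BOUNDARIES)
    boundaries = boundaries[boundaries < scan_len]
    within = within_event_timepoints(boundaries, scan_len, boundaries.size)
    frames = simulate_frames(
        scan_len + tr_s, 6.0, _frame_schedule(boundaries, scan_len + tr_s)
    )
    edge = edge_regressor(frames, tr_s, n_tr)
    spec = EffectSpec(
        roi_name="null",
        base_amplitude=0.0,
        within_amplitude=0.0,
        noise_sd=noise_sd,
        ar1_coef=ar1_coef,
        edge_coupling=edge_coupling,
    )
    rejections = 0
    for c in range(n_cohorts):
        adj = np.empty(n_subjects)
        for i in range(n_subjects):
            motion = simulate_motion(n_tr, seed=substream(base_seed, "null_motion", c, i))
            design = build_design(boundaries, within, edge.per_tr, motion, n_tr, tr_s)
            ts = simulate_roi_bold(
                design,
                _true_beta_vector(design, spec, 0.0),
                spec.noise_sd,
                spec.ar1_coef,
                seed=substream(base_seed, "null_bold", c, i),
            )
            adj[i] = fit_glm(ts, design).adjusted_beta
        _, _, p = one_sample_t(adj)
        rejections += p < alpha
    return rejections / n_cohorts
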