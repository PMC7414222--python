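"""Synthetic observers, stimuli, cohorts, and forward-modeled ROI BOLD.

Everything downstream of raw data acquisition is testable against known
ground truth generated here:

* keypress segmentation logs — each observer reports each true boundary with
  probability 1 - miss_p, Gaussian-jittered, plus Poisson false alarms;
* stimulus frames rendered from simple named patterns (uniform, vertical
  step, checkerboard) so edge density is controlled analytically;
* an adult-lifespan cohort with uniformly distributed ages, motion and tSNR
  summaries, neuropsychological scores, and per-ROI true boundary-response
  amplitudes that decline (or rise) linearly with age;
* ROI BOLD series forward-modeled as design @ true_betas plus stationary
  AR(1) Gaussian noise.

All generators are deterministic given (parameters, seed).  A single run
seed is split into fixed labeled substreams so changing one generator never
perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .boundaries import KeypressLog
from .glm import DesignMatrix, RoiTimeSeries

__all__ = [
    "EffectSpec",
    "SubjectRecord",
    "FrameSequence",
    "simulate_keypress_logs",
    "simulate_frames",
    "simulate_cohort",
    "simulate_roi_bold",
    "simulate_motion",
    "amplitude_noise_for_target",
    "substream",
]


def substream(seed, label: str, *indices: int) -> np.random.Generator:
    """Named child RNG stream of a run seed.

    An already-constructed Generator passes through untouched; an integer
    seed is combined with a CRC32 hash of the label (plus optional integer
    indices, e.g. a subject index) so each (seed, label) pair is an
    independent, reproducible stream.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return np.random.default_rng(
        [int(seed), zlib.crc32(label.encode()), *map(int, indices)]
    )


@dataclass(frozen=True)
class EffectSpec:
    """Generative parameters for one ROI's boundary response.

    Amplitudes are in percent-signal units.  ``base_amplitude`` is the true
    boundary-regressor beta at the age-range midpoint; it declines (or
    rises) by ``age_slope`` per year, with between-subject Gaussian scatter
    ``amplitude_noise_sd``.  ``behavior_coupling`` links the amplitude to
    narrative memory scores (points per unit amplitude deviation).
    ``edge_coupling`` is the true beta on the edge-density regressor, used to
    forward-model boundary-free, visually driven signal.
    """

    roi_name: str
    base_amplitude: float = 0.12
    age_slope: float = 0.0
    amplitude_noise_sd: float = 0.06
    within_amplitude: float = 0.05
    noise_sd: float = 0.12
    ar1_coef: float = 0.3
    drift_slope: float = 0.0
    edge_coupling: float = 0.0
    behavior_coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.amplitude_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if abs(self.ar1_coef) >= 1:
            raise ValueError("|ar1_coef| must be < 1")


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort member: demographics, QC summaries, neuropsych scores."""

    subject_id: str
    age: float
    sex: str
    mean_fd: float
    max_fd: float
    tsnr: float
    logmem_imm: float
    logmem_del: float
    fluency: float
    visuospatial: float
    word_memory: float

    def __post_init__(self) -> None:
        if self.mean_fd < 0:
            raise ValueError("mean_fd must be non-negative")
        if self.max_fd < self.mean_fd:
            raise ValueError("max_fd must be >= mean_fd")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")


@dataclass(frozen=True)
class FrameSequence:
    """Ordered 2-D intensity frames in [0, 1] at a fixed frame rate."""

    frames: np.ndarray
    frame_rate: float
    duration: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if frames.shape[0] != round(self.frame_rate * self.duration):
            raise ValueError("frame count must equal round(frame_rate * duration)")


def simulate_keypress_logs(
    true_boundaries,
    n_observers: int = 16,
    jitter_sd: float = 1.0,
    miss_p: float = 0.15,
    fa_rate: float = 0.005,
    duration: float = 480.0,
    seed=0,
) -> list[KeypressLog]:
    """Simulate observers segmenting a stimulus with known true boundaries.

    Each true boundary is reported with probability 1 - miss_p, jittered by
    N(0, jitter_sd) and clipped to [0, duration]; false alarms arrive as a
    homogeneous Poisson process at fa_rate events/s.
    """
    boundaries = np.asarray(true_boundaries, dtype=float).ravel()
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0 <= miss_p <= 1:
        raise ValueError("miss_p must lie in [0, 1]")
    if fa_rate < 0:
        raise ValueError("fa_rate must be non-negative")
    if boundaries.size and (boundaries.min() < 0 or boundaries.max() > duration):
        raise ValueError("true boundaries must lie within [0, duration]")
    rng = substream(seed, "keypress")
    logs = []
    for i in range(n_observers):
        detected = boundaries[rng.random(boundaries.size) >= miss_p]
        jitter = rng.normal(0.0, jitter_sd, detected.size) if jitter_sd > 0 else 0.0
        presses = np.clip(detected + jitter, 0.0, duration)
        n_fa = rng.poisson(fa_rate * duration)
        presses = np.concatenate([presses, rng.uniform(0.0, duration, n_fa)])
        logs.append(
            KeypressLog(
                observer_id=f"obs{i:02d}",
                press_times=np.sort(presses),
                duration=duration,
            )
        )
    return logs


def _render_pattern(shape: tuple[int, int], spec: dict) -> np.ndarray:
    h, w = shape
    pattern = spec.get("pattern")
    if pattern == "uniform":
        return np.full(shape, float(spec.get("value", 0.5)))
    if pattern == "vertical_step":
        frac = float(spec.get("position", 0.5))
        frame = np.full(shape, float(spec.get("low", 0.0)))
        frame[:, int(round(frac * w)):] = float(spec.get("high", 1.0))
        return frame
    if pattern == "checkerboard":
        cell = int(spec.get("cell", 8))
        if cell < 1:
            raise ValueError("checkerboard cell size must be >= 1")
        rows = (np.arange(h) // cell) % 2
        cols = (np.arange(w) // cell) % 2
        board = (rows[:, None] + cols[None, :]) % 2
        lo, hi = float(spec.get("low", 0.0)), float(spec.get("high", 1.0))
        return lo + (hi - lo) * board
    raise ValueError(f"unknown frame pattern: {pattern!r}")


def simulate_frames(
    duration: float,
    frame_rate: float,
    edge_schedule,
    shape: tuple[int, int] = (32, 32),
    seed=0,
) -> FrameSequence:
    """Render a deterministic frame sequence from a piecewise pattern schedule.

    ``edge_schedule`` is a list of dicts, each with a ``pattern`` name
    (uniform / vertical_step / checkerboard), a ``duration`` in seconds, and
    pattern parameters.  Segments must cover the full duration.
    """
    if duration <= 0 or frame_rate <= 0:
        raise ValueError("duration and frame_rate must be positive")
    if not edge_schedule:
        raise ValueError("edge_schedule must contain at least one segment")
    total = sum(float(seg["duration"]) for seg in edge_schedule)
    if total < duration - 1e-9:
        raise ValueError(
            f"schedule covers {total} s but the sequence lasts {duration} s"
        )
    rendered = [_render_pattern(shape, seg) for seg in edge_schedule]
    ends = np.cumsum([float(seg["duration"]) for seg in edge_schedule])
    n_frames = int(round(frame_rate * duration))
    starts = np.arange(n_frames) / frame_rate
    seg_idx = np.searchsorted(ends, starts, side="right")
    seg_idx = np.minimum(seg_idx, len(rendered) - 1)
    frames = np.stack([rendered[j] for j in seg_idx])
    return FrameSequence(frames=frames, frame_rate=frame_rate, duration=duration)


def amplitude_noise_for_target(
    target_r: float,
    age_slope: float,
    age_sd: float,
    measurement_var: float = 0.0,
) -> float:
    """Between-subject amplitude noise SD hitting a target age correlation.

    By the attenuation identity rho = slope*sigma_age /
    sqrt(slope^2 sigma_age^2 + sigma_amp^2), solves for sigma_amp given the
    target; ``measurement_var`` (the GLM's own contrast sampling variance) is
    subtracted first so the target holds for *measured* betas.
    """
    if not 0 < abs(target_r) < 1:
        raise ValueError("target_r must lie strictly between 0 and 1 in magnitude")
    if age_slope == 0:
        raise ValueError("cannot target a nonzero correlation with age_slope = 0")
    signal = (abs(age_slope) * age_sd) ** 2
    total = signal * (1.0 / target_r**2 - 1.0)
    resid = total - measurement_var
    if resid <= 0:
        raise ValueError(
            "target correlation unattainable: measurement variance "
            f"{measurement_var:.4g} exceeds the total noise budget {total:.4g}"
        )
    return float(np.sqrt(resid))


# Cohort-level constants for memory/neuropsych score generation.  Baselines
# and age slopes follow the Table-1-style group means the generator emulates;
# noise SDs set the marginal age-memory correlations near -0.3.
MEMORY_MODEL = {
    "logmem_imm": {"base": 14.7, "age_slope": -0.061, "coupling_scale": 0.65, "noise_sd": 4.0},
    "logmem_del": {"base": 0.35, "imm_weight": 0.883, "age_slope": -0.0194, "noise_sd": 2.5},
    "fluency": {"base": 11.4, "age_slope": -0.056, "noise_sd": 3.0},
    "visuospatial": {"base": 14.7, "age_slope": -0.035, "noise_sd": 1.3},
    "word_memory": {"base": 21.8, "age_slope": -0.097, "noise_sd": 3.5},
}


def simulate_cohort(
    n: int = 546,
    age_range: tuple[float, float] = (18.0, 88.0),
    effect_specs: list[EffectSpec] | None = None,
    seed=0,
    round_scores: bool = False,
):
    """Simulate an adult-lifespan cohort with known per-ROI amplitudes.

    Returns (subjects, truth): a list of :class:`SubjectRecord` and a
    DataFrame of ground-truth boundary amplitudes (columns ``amp_<roi>``)
    per subject, for recovery testing.

    Memory scores couple to ROI amplitudes through each spec's
    ``behavior_coupling``: delayed narrative recall receives
    coupling x amplitude-deviation directly, immediate recall receives a
    0.65-scaled version, and delayed recall additionally loads on immediate
    recall — mimicking the strong shared variance of the two story-recall
    scores.
    """
    if effect_specs is None or not list(effect_specs):
        raise ValueError("effect_specs must contain at least one EffectSpec")
    if n < 0:
        raise ValueError("n must be non-negative")
    lo, hi = map(float, age_range)
    if hi <= lo:
        raise ValueError("age_range must be increasing")
    rng = substream(seed, "cohort")
    mid = (lo + hi) / 2.0

    ages = rng.uniform(lo, hi, n)
    sexes = np.where(rng.random(n) < 0.5, "F", "M")
    mean_fd = rng.lognormal(np.log(0.093), 0.4, n)
    max_fd = mean_fd * (1.5 + rng.exponential(1.5, n))
    tsnr = rng.uniform(80.0, 120.0, n)

    a_c = ages - mid
    amps = {}
    amp_dev_total = np.zeros(n)  # coupling-weighted amplitude deviations
    for spec in effect_specs:
        amp = (
            spec.base_amplitude
            + spec.age_slope * a_c
            + rng.normal(0.0, spec.amplitude_noise_sd, n)
        )
        amps[spec.roi_name] = amp
        if spec.behavior_coupling:
            amp_dev_total += spec.behavior_coupling * (amp - spec.base_amplitude)

    m = MEMORY_MODEL
    imm = (
        m["logmem_imm"]["base"]
        + m["logmem_imm"]["age_slope"] * a_c
        + m["logmem_imm"]["coupling_scale"] * amp_dev_total
        + rng.normal(0.0, m["logmem_imm"]["noise_sd"], n)
    )
    dele = (
        m["logmem_del"]["base"]
        + m["logmem_del"]["imm_weight"] * imm
        + amp_dev_total
        + m["logmem_del"]["age_slope"] * a_c
        + rng.normal(0.0, m["logmem_del"]["noise_sd"], n)
    )
    others = {
        k: m[k]["base"] + m[k]["age_slope"] * a_c + rng.normal(0.0, m[k]["noise_sd"], n)
        for k in ("fluency", "visuospatial", "word_memory")
    }
    if round_scores:
        imm, dele = np.round(imm), np.round(dele)
        others = {k: np.round(v) for k, v in others.items()}

    subjects = [
        SubjectRecord(
            subject_id=f"sub{i:04d}",
            age=float(ages[i]),
            sex=str(sexes[i]),
            mean_fd=float(mean_fd[i]),
            max_fd=float(max_fd[i]),
            tsnr=float(tsnr[i]),
            logmem_imm=float(imm[i]),
            logmem_del=float(dele[i]),
            fluency=float(others["fluency"][i]),
            visuospatial=float(others["visuospatial"][i]),
            word_memory=float(others["word_memory"][i]),
        )
        for i in range(n)
    ]
    truth = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age": ages,
            **{f"amp_{roi}": amp for roi, amp in amps.items()},
        }
    )
    return subjects, truth


def simulate_motion(
    n_tr: int,
    seed=0,
    scale: float = 0.05,
    smoothness: float = 0.95,
) -> np.ndarray:
    """Six smooth AR(1) motion parameter traces (x, y, z, pitch, roll, yaw)."""
    rng = substream(seed, "motion")
    e = rng.normal(0.0, scale * np.sqrt(1 - smoothness**2), (n_tr, 6))
    x0 = rng.normal(0.0, scale, 6)
    traces = np.empty((n_tr, 6))
    prev = x0
    for t in range(n_tr):
        prev = smoothness * prev + e[t]
        traces[t] = prev
    return traces


def simulate_roi_bold(
    design: DesignMatrix,
    true_betas,
    noise_sd: float,
    ar1_coef: float,
    seed=0,
    subject_id: str = "sim",
    roi_name: str = "roi",
) -> RoiTimeSeries:
    """Forward-model an ROI series: design @ true_betas + AR(1) noise.

    The AR(1) noise is stationary with *marginal* SD ``noise_sd`` (innovation
    SD noise_sd * sqrt(1 - ar1^2)) and lag-1 autocorrelation ``ar1_coef``.
    """
    true_betas = np.asarray(true_betas, dtype=float).ravel()
    if true_betas.size != len(design.names):
        raise ValueError(
            f"true_betas has {true_betas.size} entries but the design has "
            f"{len(design.names)} columns"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if abs(ar1_coef) >= 1:
        raise ValueError("|ar1_coef| must be < 1")
    signal = design.X @ true_betas
    if noise_sd == 0:
        noise = np.zeros(design.n_tr)
    else:
        rng = substream(seed, "bold")
        innov = rng.normal(0.0, noise_sd * np.sqrt(1 - ar1_coef**2), design.n_tr)
        x0 = rng.normal(0.0, noise_sd)
        noise, _ = lfilter([1.0], [1.0, -ar1_coef], innov, zi=[ar1_coef * x0])
    return RoiTimeSeries(
        subject_id=subject_id,
        roi_name=roi_name,
        values=signal + noise,
        tr_s=design.tr_s,
    )


# ---------------------------------------------------------------------------
# tabular I/O


def write_cohort_csv(subjects: list[SubjectRecord], truth: pd.DataFrame, path) -> None:
    """Write the cohort CSV plus a parallel *_truth.csv of true amplitudes."""
    path = str(path)
    pd.DataFrame([vars(s) for s in subjects]).to_csv(path, index=False)
    stem = path[:-4] if path.endswith(".csv") else path
    truth.to_csv(stem + "_truth.csv", index=False)


def read_cohort_csv(path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    fields = [
        "subject_id", "age", "sex", "mean_fd", "max_fd", "tsnr",
        "logmem_imm", "logmem_del", "fluency", "visuospatial", "word_memory",
    ]
    missing = set(fields) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing cohort columns {sorted(missing)}")
    return [
        SubjectRecord(**{f: (str(row[f]) if f in ("subject_id", "sex") else float(row[f])) for f in fields})
        for _, row in df.iterrows()
    ]
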