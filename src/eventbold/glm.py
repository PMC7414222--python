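"""Design matrices and per-subject GLMs for boundary-evoked BOLD activity.

The model regresses an ROI-average percent-signal-change time series on:

* an HRF-convolved impulse regressor at consensus event boundaries,
* an identically modeled regressor at within-event control timepoints,
* the per-TR edge-density regressor (continuous, unconvolved by default),
* six motion parameters and their first differences (12 nuisance columns),
* a mean-centered linear drift and an intercept.

The quantity of interest is the *adjusted* boundary response: the boundary
beta minus the within-event beta, which isolates boundary-specific activity
from overall movie-driven activity levels.  A finite-impulse-response (FIR)
variant estimates the boundary-locked response at each lag without assuming
an HRF shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz
from scipy.stats import gamma as gamma_dist

__all__ = [
    "DesignMatrix",
    "RoiTimeSeries",
    "GlmBetas",
    "FirTimecourse",
    "QcExclusion",
    "canonical_hrf",
    "build_design",
    "fit_glm",
    "adjusted_beta",
    "fit_fir",
    "scale_psc",
    "extract_roi_timeseries",
    "qc_filter",
    "contrast_variance",
]

# double-gamma HRF shape (seconds)
HRF_PEAK_S = 6.0
HRF_UNDERSHOOT_S = 16.0
HRF_RATIO = 6.0

MOTION_NAMES = [f"motion_{i}" for i in range(1, 7)]
MOTION_DERIV_NAMES = [f"motion_{i}_deriv" for i in range(1, 7)]


@dataclass(frozen=True)
class DesignMatrix:
    """TR-gridded GLM design with named columns and HRF metadata."""

    X: np.ndarray
    names: list[str]
    tr_s: float
    n_tr: int
    hrf_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        if X.shape != (self.n_tr, len(self.names)):
            raise ValueError(
                f"design shape {X.shape} does not match n_tr={self.n_tr}, "
                f"{len(self.names)} column names"
            )

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.names)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, tr_s: float) -> "DesignMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(
            X=df.to_numpy(dtype=float),
            names=list(df.columns),
            tr_s=tr_s,
            n_tr=len(df),
        )


@dataclass(frozen=True)
class RoiTimeSeries:
    """Per-subject, per-ROI percent-signal-change series on the TR grid."""

    subject_id: str
    roi_name: str
    values: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in series {self.subject_id}/{self.roi_name}")

    @property
    def n_tr(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class GlmBetas:
    """Fitted GLM coefficients, in percent-signal units per unit regressor."""

    boundary_beta: float
    within_beta: float
    adjusted_beta: float
    nuisance_betas: dict
    residual_sd: float

    def __post_init__(self) -> None:
        if self.adjusted_beta != self.boundary_beta - self.within_beta:
            raise ValueError("adjusted_beta must equal boundary_beta - within_beta")


@dataclass(frozen=True)
class FirTimecourse:
    """Boundary-locked FIR response: one amplitude per TR lag."""

    lags: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=int)
        amps = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "amplitudes", amps)
        if lags.size != amps.size:
            raise ValueError("lags and amplitudes lengths differ")


@dataclass(frozen=True)
class QcExclusion:
    subject_id: str
    reasons: tuple


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Double-gamma hemodynamic response kernel sampled at the TR.

    Peak at ~6 s, undershoot at ~16 s, peak-to-undershoot ratio 6;
    peak-normalized so max(kernel) = 1.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if duration_s < tr_s:
        raise ValueError("duration_s must be at least one TR")
    t = np.arange(0.0, duration_s, tr_s)
    h = gamma_dist.pdf(t, HRF_PEAK_S) - gamma_dist.pdf(t, HRF_UNDERSHOOT_S) / HRF_RATIO
    return h / h.max()


def _impulse_column(event_times, n_tr: int, tr_s: float, kernel: np.ndarray) -> np.ndarray:
    times = np.asarray(event_times, dtype=float).ravel()
    scan_len = n_tr * tr_s
    bad = times[(times < 0) | (times >= scan_len)]
    if bad.size:
        raise ValueError(
            f"event times outside the scan [0, {scan_len:.2f}): {bad.tolist()}"
        )
    impulses = np.zeros(n_tr)
    for t in times:
        impulses[int(t // tr_s)] += 1.0
    return np.convolve(impulses, kernel)[:n_tr]


def build_design(
    boundaries,
    within_points,
    edge: np.ndarray,
    motion: np.ndarray | None,
    n_tr: int,
    tr_s: float = 2.47,
    convolve_edge: bool = False,
    hrf_duration_s: float = 32.0,
) -> DesignMatrix:
    """Assemble the boundary GLM design matrix.

    Events are placed as unit impulses in the TR bin containing each time
    (floor(t/TR), 0-based) and convolved with the canonical HRF.  The edge
    regressor enters unconvolved unless ``convolve_edge``; motion derivative
    columns are first differences with a leading zero; drift is a
    mean-centered linear trend.
    """
    edge = np.asarray(edge, dtype=float).ravel()
    if edge.size != n_tr:
        raise ValueError(f"edge regressor length {edge.size} != n_tr {n_tr}")
    kernel = canonical_hrf(tr_s, hrf_duration_s)
    btimes = (
        boundaries.boundary_times if hasattr(boundaries, "boundary_times") else boundaries
    )
    cols = [
        _impulse_column(btimes, n_tr, tr_s, kernel),
        _impulse_column(within_points, n_tr, tr_s, kernel),
    ]
    names = ["boundary", "within_event"]
    edge_col = np.convolve(edge, kernel)[:n_tr] if convolve_edge else edge
    cols.append(edge_col)
    names.append("edge")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_tr, 6):
            raise ValueError(f"motion must have shape ({n_tr}, 6), got {motion.shape}")
        deriv = np.diff(motion, axis=0, prepend=motion[:1])
        cols.extend(motion.T)
        names.extend(MOTION_NAMES)
        cols.extend(deriv.T)
        names.extend(MOTION_DERIV_NAMES)
    drift = np.arange(n_tr, dtype=float)
    cols.append(drift - drift.mean())
    names.append("drift")
    cols.append(np.ones(n_tr))
    names.append("intercept")
    return DesignMatrix(
        X=np.column_stack(cols),
        names=names,
        tr_s=tr_s,
        n_tr=n_tr,
        hrf_params={
            "peak_s": HRF_PEAK_S,
            "undershoot_s": HRF_UNDERSHOOT_S,
            "ratio": HRF_RATIO,
            "duration_s": hrf_duration_s,
            "convolve_edge": convolve_edge,
        },
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    scale = np.abs(np.diag(R)).max()
    small = np.abs(np.diag(R)) < 1e-10 * max(scale, 1.0)
    return [names[i] for i in np.flatnonzero(small)]


def fit_glm(ts: RoiTimeSeries, design: DesignMatrix) -> GlmBetas:
    """Ordinary least squares fit of a percent-signal series on the design.

    Raises on rank deficiency, naming the collinear columns.  residual_sd
    uses n_tr - rank degrees of freedom.
    """
    y = ts.values
    X = design.X
    if y.size != design.n_tr:
        raise ValueError(
            f"series length {y.size} does not match design n_tr {design.n_tr}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design is rank deficient; collinear columns: {_collinear_columns(X, design.names)}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = y.size - rank
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else float("nan")
    lookup = dict(zip(design.names, beta))
    b, w = float(lookup.pop("boundary")), float(lookup.pop("within_event"))
    return GlmBetas(
        boundary_beta=b,
        within_beta=w,
        adjusted_beta=b - w,
        nuisance_betas={k: float(v) for k, v in lookup.items()},
        residual_sd=residual_sd,
    )


def adjusted_beta(betas: GlmBetas) -> float:
    """Boundary-minus-within-event activity (percent-signal units)."""
    return betas.boundary_beta - betas.within_beta


def fit_fir(
    ts: RoiTimeSeries,
    boundaries,
    lags=range(-2, 9),
    nuisance: np.ndarray | None = None,
    nuisance_names: list[str] | None = None,
) -> FirTimecourse:
    """FIR deconvolution of the boundary-locked response.

    One indicator column per TR lag relative to each boundary, fitted jointly
    with an intercept and any supplied nuisance columns; the lag betas are
    the timecourse amplitudes.
    """
    lags = np.asarray(list(lags), dtype=int)
    if lags.size == 0 or not np.array_equal(np.diff(lags), np.ones(lags.size - 1, int)):
        raise ValueError("lags must be a contiguous integer range")
    btimes = (
        boundaries.boundary_times if hasattr(boundaries, "boundary_times") else boundaries
    )
    btimes = np.asarray(btimes, dtype=float).ravel()
    n = ts.n_tr
    ev = (btimes // ts.tr_s).astype(int)
    cols, names = [], []
    for lag in lags:
        idx = ev + lag
        if idx.min() < 0 or idx.max() >= n:
            raise ValueError(
                f"lag {lag} puts an event indicator outside the scan (0..{n - 1})"
            )
        col = np.zeros(n)
        col[idx] = 1.0
        cols.append(col)
        names.append(f"lag_{lag}")
    cols.append(np.ones(n))
    names.append("intercept")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n:
            nuisance = nuisance.T
        cols.extend(nuisance.T)
        names.extend(
            nuisance_names
            or [f"nuisance_{i}" for i in range(nuisance.shape[1])]
        )
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "FIR design is collinear (overlapping events?); columns: "
            f"{_collinear_columns(X, names)}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, ts.values, rcond=None)
    return FirTimecourse(lags=lags, amplitudes=beta[: lags.size])


def scale_psc(raw: np.ndarray) -> np.ndarray:
    """Convert a raw series to percent signal change about its mean."""
    raw = np.asarray(raw, dtype=float).ravel()
    m = raw.mean()
    if m <= 0:
        raise ValueError(f"series mean must be positive for PSC scaling, got {m}")
    return 100.0 * (raw - m) / m


def extract_roi_timeseries(
    volume4d,
    mask,
    tr_s: float,
    subject_id: str = "",
    roi_name: str = "",
) -> RoiTimeSeries:
    """Mean series over mask voxels, scaled to percent signal change.

    Accepts numpy arrays or nibabel images (anything with ``get_fdata``).
    The volume's last axis is time.
    """
    if hasattr(volume4d, "get_fdata"):
        volume4d = volume4d.get_fdata()
    if hasattr(mask, "get_fdata"):
        mask = mask.get_fdata()
    volume4d = np.asarray(volume4d, dtype=float)
    mask = np.asarray(mask) > 0
    if mask.shape != volume4d.shape[:-1]:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume spatial shape "
            f"{volume4d.shape[:-1]}"
        )
    if not mask.any():
        raise ValueError("ROI mask is empty")
    series = volume4d[mask].mean(axis=0)
    return RoiTimeSeries(
        subject_id=subject_id, roi_name=roi_name, values=scale_psc(series), tr_s=tr_s
    )


def qc_filter(
    cohort,
    mean_fd_limit: float = 0.5,
    max_fd_limit: float = 3.0,
    tsnr_sd_limit: float = 2.0,
):
    """Motion and tSNR quality-control exclusion.

    A subject is excluded if mean framewise displacement *exceeds*
    ``mean_fd_limit`` mm, maximal FD exceeds ``max_fd_limit`` mm, or tSNR
    falls more than ``tsnr_sd_limit`` SDs below the full-cohort mean
    (criterion computed on the input cohort before any exclusion).  Strict
    inequalities throughout.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort is empty")
    tsnrs = np.array([s.tsnr for s in cohort], dtype=float)
    cutoff = tsnrs.mean() - tsnr_sd_limit * tsnrs.std(ddof=1) if len(cohort) > 1 else -np.inf
    kept, excluded = [], []
    for subj in cohort:
        reasons = []
        if subj.mean_fd > mean_fd_limit:
            reasons.append("mean_fd")
        if subj.max_fd > max_fd_limit:
            reasons.append("max_fd")
        if subj.tsnr < cutoff:
            reasons.append("tsnr")
        if reasons:
            excluded.append(QcExclusion(subject_id=subj.subject_id, reasons=tuple(reasons)))
        else:
            kept.append(subj)
    return kept, excluded


def contrast_variance(
    design: DesignMatrix,
    weights: dict,
    noise_sd: float,
    ar1_coef: float = 0.0,
) -> float:
    """Sampling variance of a beta contrast under stationary AR(1) noise.

    Var(c'beta_hat) = c X+ V X+' c' * sigma^2 with V the AR(1) correlation
    matrix (unit marginal variance) and X+ the pseudoinverse of the design.
    Used to calibrate synthetic between-subject amplitude noise against the
    measurement noise the GLM itself adds.
    """
    c = np.zeros(len(design.names))
    for name, w in weights.items():
        c[design.names.index(name)] = w
    a = c @ np.linalg.pinv(design.X)
    V = toeplitz(ar1_coef ** np.arange(design.n_tr))
    return float(noise_sd**2 * a @ V @ a)
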