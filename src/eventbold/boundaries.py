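"""Consensus event boundaries from multi-observer keypress segmentation.

Observers watching a continuous stimulus press a key whenever they feel one
meaningful event ends and another begins.  This module turns a collection of
such keypress logs into a set of consensus event boundaries (timepoints where
at least a configurable fraction of observers agree, within a tolerance
window), builds matched within-event control timepoints, and quantifies how
similarly two groups of observers segment the same stimulus.

The consensus procedure:

1. pool all presses from all observers and sort them;
2. cluster greedily in one dimension — a press joins the current cluster if
   it lies within ``window_s`` of the running cluster mean, otherwise it
   starts a new cluster;
3. each cluster's boundary time is the mean of its member presses, refined
   by a flat-kernel mean-shift: the time is recomputed as the mean of all
   pooled presses within ``window_s`` of the provisional time until stable,
   so stray presses the greedy pass swept in from beyond the window cannot
   bias the group-meaned boundary time;
4. a cluster's *agreement* is the fraction of observers with at least one
   press within ``window_s`` of that time; clusters below ``min_agreement``
   are dropped;
5. boundaries closer than ``min_separation_s`` are resolved by dropping the
   lower-agreement member (ties drop the later one).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

__all__ = [
    "KeypressLog",
    "BoundarySet",
    "AgreementResult",
    "consensus_boundaries",
    "within_event_timepoints",
    "hit_rate",
    "segmentation_agreement",
    "fisher_z_compare",
    "read_keypress_tsv",
    "write_keypress_tsv",
    "write_boundaries_tsv",
]


@dataclass(frozen=True)
class KeypressLog:
    """One observer's boundary keypress times for one stimulus viewing.

    Press times are stored sorted ascending and must lie in [0, duration].
    """

    observer_id: str
    press_times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.sort(np.asarray(self.press_times, dtype=float).ravel())
        object.__setattr__(self, "press_times", times)
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if times.size and (times[0] < 0 or times[-1] > self.duration):
            raise ValueError(
                f"press times of {self.observer_id!r} fall outside "
                f"[0, {self.duration}]"
            )

    @property
    def n_presses(self) -> int:
        return int(self.press_times.size)


@dataclass(frozen=True)
class BoundarySet:
    """Consensus boundaries with per-boundary observer agreement.

    ``within_event_times`` holds matched control timepoints placed far from
    every boundary; it is empty until :func:`within_event_timepoints` is run.
    """

    boundary_times: np.ndarray
    agreement: np.ndarray
    within_event_times: np.ndarray
    window_s: float
    min_agreement: float
    min_separation_s: float

    def __post_init__(self) -> None:
        bt = np.asarray(self.boundary_times, dtype=float).ravel()
        ag = np.asarray(self.agreement, dtype=float).ravel()
        we = np.asarray(self.within_event_times, dtype=float).ravel()
        object.__setattr__(self, "boundary_times", bt)
        object.__setattr__(self, "agreement", ag)
        object.__setattr__(self, "within_event_times", we)
        if bt.size != ag.size:
            raise ValueError("boundary_times and agreement lengths differ")
        if bt.size > 1 and np.any(np.diff(bt) < self.min_separation_s):
            raise ValueError(
                f"boundaries closer than min_separation_s={self.min_separation_s}"
            )
        if ag.size and np.any(ag < self.min_agreement):
            raise ValueError("agreement below min_agreement present")
        if we.size and bt.size:
            d = np.abs(we[:, None] - bt[None, :]).min(axis=1)
            if np.any(d < self.min_separation_s - 1e-9):
                raise ValueError(
                    "within-event timepoint closer than min_separation_s "
                    "to a boundary"
                )

    @property
    def n_boundaries(self) -> int:
        return int(self.boundary_times.size)

    def with_within_events(self, times: np.ndarray) -> "BoundarySet":
        return replace(self, within_event_times=np.asarray(times, dtype=float))


@dataclass(frozen=True)
class AgreementResult:
    """Segmentation-agreement comparison between two observer groups."""

    r_within_a: float
    r_within_b: float
    r_between: float
    z_stats: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)


def consensus_boundaries(
    logs: list[KeypressLog],
    window_s: float = 5.0,
    min_agreement: float = 0.5,
    min_separation_s: float = 6.0,
) -> BoundarySet:
    """Derive consensus event boundaries from multiple observers' presses.

    Parameters
    ----------
    logs
        At least two keypress logs, all with the same stimulus duration.
    window_s
        Agreement window: an observer counts toward a boundary if they have a
        press within this many seconds of the group-meaned boundary time.
    min_agreement
        Minimum fraction of observers that must agree for a boundary to
        survive.
    min_separation_s
        Minimum spacing between surviving boundaries; conflicts drop the
        lower-agreement boundary (ties drop the later one).
    """
    if len(logs) < 2:
        raise ValueError("need at least 2 keypress logs for a consensus")
    durations = {log.duration for log in logs}
    if len(durations) > 1:
        raise ValueError(f"logs have mismatched durations: {sorted(durations)}")

    pooled = np.sort(np.concatenate([log.press_times for log in logs]))
    clusters: list[list[float]] = []
    for t in pooled:
        if clusters and abs(t - float(np.mean(clusters[-1]))) <= window_s:
            clusters[-1].append(t)
        else:
            clusters.append([t])

    def refine(t: float) -> float:
        # flat-kernel mean shift over the pooled presses, then the
        # group mean proper: one boundary estimate per agreeing observer
        # (their nearest press), averaged across observers
        for _ in range(50):
            members = pooled[np.abs(pooled - t) <= window_s]
            new = float(members.mean())
            if abs(new - t) < 1e-9:
                break
            t = new
        estimates = []
        for log in logs:
            if log.press_times.size == 0:
                continue
            nearest = log.press_times[np.argmin(np.abs(log.press_times - t))]
            if abs(nearest - t) <= window_s:
                estimates.append(nearest)
        return float(np.mean(estimates)) if estimates else t

    times = np.array([refine(float(np.mean(c))) for c in clusters])
    # mean shift can merge neighboring clusters onto one mode; deduplicate
    if times.size:
        keep_idx = np.concatenate(([True], np.abs(np.diff(times)) > 1e-6))
        times = times[keep_idx]
    agreement = np.array(
        [
            float(
                np.mean(
                    [
                        log.press_times.size > 0
                        and np.min(np.abs(log.press_times - t)) <= window_s
                        for log in logs
                    ]
                )
            )
            for t in times
        ]
    )
    keep = agreement >= min_agreement
    times, agreement = times[keep], agreement[keep]

    # resolve min-separation conflicts: drop the lower-agreement member
    # (tie -> drop the later one), repeating until none remain
    while times.size > 1:
        gaps = np.diff(times)
        bad = np.flatnonzero(gaps < min_separation_s)
        if bad.size == 0:
            break
        i = int(bad[0])
        drop = i + 1 if agreement[i + 1] <= agreement[i] else i
        times = np.delete(times, drop)
        agreement = np.delete(agreement, drop)

    return BoundarySet(
        boundary_times=times,
        agreement=agreement,
        within_event_times=np.empty(0),
        window_s=window_s,
        min_agreement=min_agreement,
        min_separation_s=min_separation_s,
    )


def within_event_timepoints(
    boundaries,
    duration: float,
    n_points: int,
    min_distance_s: float = 6.0,
) -> np.ndarray:
    """Place control timepoints evenly through the video, away from boundaries.

    Candidates are laid on an even grid (spacing ``duration / n_points``,
    starting at half a spacing — for n_points equal to the boundary count this
    spacing is the average elapsed time between events).  Any candidate closer
    than ``min_distance_s`` to a boundary is shifted to the nearest admissible
    time within its event; candidates whose event has no admissible interior
    are redistributed into the roomiest admissible gaps.  Exactly ``n_points``
    times are returned, all at least ``min_distance_s`` from every boundary.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if duration <= 0:
        raise ValueError("duration must be positive")
    btimes = (
        boundaries.boundary_times
        if isinstance(boundaries, BoundarySet)
        else np.sort(np.asarray(boundaries, dtype=float).ravel())
    )

    # admissible set = [0, duration] minus min_distance_s neighborhoods
    eps = 1e-6
    cuts = [(max(0.0, b - min_distance_s - eps), min(duration, b + min_distance_s + eps)) for b in btimes]
    admissible: list[tuple[float, float]] = []
    lo = 0.0
    for a, b in cuts:
        if a > lo:
            admissible.append((lo, a))
        lo = max(lo, b)
    if lo < duration:
        admissible.append((lo, duration))
    admissible = [(a, b) for a, b in admissible if b > a]
    if not admissible:
        raise ValueError(
            f"within-event timepoints infeasible: no time in [0, {duration}] "
            f"is at least min_distance_s={min_distance_s} from every boundary"
        )

    spacing = duration / n_points
    candidates = (np.arange(n_points) + 0.5) * spacing

    def project(t: float) -> float:
        best, best_d = None, np.inf
        for a, b in admissible:
            p = min(max(t, a), b)
            d = abs(p - t)
            if d < best_d:
                best, best_d = p, d
        return float(best)

    placed = sorted(project(t) for t in candidates)
    # respread duplicates (candidates squeezed onto the same interval edge)
    if len(set(np.round(placed, 9))) < n_points:
        out: list[float] = []
        arr = np.asarray(placed)
        for a, b in admissible:
            k = int(np.sum((arr >= a - 1e-9) & (arr <= b + 1e-9)))
            if k == 0:
                continue
            vals = arr[(arr >= a - 1e-9) & (arr <= b + 1e-9)]
            if len(set(np.round(vals, 9))) == k:
                out.extend(vals.tolist())
            else:
                out.extend((a + (b - a) * (np.arange(k) + 1) / (k + 1)).tolist())
        placed = sorted(out)
    return np.asarray(placed)


def hit_rate(
    logs: list[KeypressLog], boundaries, window_s: float = 5.0
) -> float:
    """Fraction of (observer, boundary) pairs with a press within window_s."""
    btimes = (
        boundaries.boundary_times
        if isinstance(boundaries, BoundarySet)
        else np.asarray(boundaries, dtype=float).ravel()
    )
    if btimes.size == 0:
        raise ValueError("boundary list is empty")
    hits = 0
    for log in logs:
        for b in btimes:
            if log.press_times.size and np.min(np.abs(log.press_times - b)) <= window_s:
                hits += 1
    return hits / (len(logs) * btimes.size)


def _press_vector(log: KeypressLog, bin_s: float, smooth_sd_s: float) -> np.ndarray:
    n_bins = int(np.ceil(log.duration / bin_s))
    vec = np.zeros(n_bins)
    if log.press_times.size:
        idx = np.minimum((log.press_times / bin_s).astype(int), n_bins - 1)
        vec[idx] = 1.0
    return ndimage.gaussian_filter1d(vec, sigma=smooth_sd_s / bin_s)


def _mean_pairwise_r(vecs_a: np.ndarray, vecs_b: np.ndarray | None = None) -> float:
    """Mean Pearson r over within-set pairs (vecs_b None) or cross pairs."""
    rs = []
    if vecs_b is None:
        for i, j in itertools.combinations(range(len(vecs_a)), 2):
            rs.append(_safe_r(vecs_a[i], vecs_a[j]))
    else:
        for va in vecs_a:
            for vb in vecs_b:
                rs.append(_safe_r(va, vb))
    rs = [r for r in rs if np.isfinite(r)]
    if not rs:
        raise ValueError("no pair with nonzero variance; cannot compute agreement")
    return float(np.mean(rs))


def _safe_r(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def segmentation_agreement(
    group_a: list[KeypressLog],
    group_b: list[KeypressLog],
    bin_s: float = 1.0,
    smooth_sd_s: float = 2.0,
) -> AgreementResult:
    """Compare segmentation agreement within and between two observer groups.

    Each log becomes a binary per-bin press vector, Gaussian-smoothed;
    agreement is the mean pairwise Pearson r.  Group sizes serve as the n for
    the Fisher z comparisons (the between-group comparison uses the smaller
    group size).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 logs for within-group r")
    durations = {log.duration for log in group_a + group_b}
    if len(durations) > 1:
        raise ValueError("all logs must share the same duration")

    vecs_a = [_press_vector(log, bin_s, smooth_sd_s) for log in group_a]
    vecs_b = [_press_vector(log, bin_s, smooth_sd_s) for log in group_b]
    r_a = _mean_pairwise_r(vecs_a)
    r_b = _mean_pairwise_r(vecs_b)

    # between-group pairs; a log paired with its own duplicate (same observer,
    # same presses — e.g. the two groups are literally the same sample) is
    # skipped so identical groups give r_between == r_within
    def _key(log: KeypressLog):
        return (log.observer_id, tuple(np.round(log.press_times, 9)))

    keys_a = [_key(log) for log in group_a]
    keys_b = [_key(log) for log in group_b]
    rs = [
        _safe_r(va, vb)
        for va, ka in zip(vecs_a, keys_a)
        for vb, kb in zip(vecs_b, keys_b)
        if ka != kb
    ]
    rs = [r for r in rs if np.isfinite(r)]
    if not rs:
        raise ValueError("no valid between-group pair; cannot compute agreement")
    r_ab = float(np.mean(rs))

    n_a, n_b = len(group_a), len(group_b)
    n_ab = min(n_a, n_b)
    comparisons = {
        "within_a_vs_within_b": (r_a, n_a, r_b, n_b),
        "within_a_vs_between": (r_a, n_a, r_ab, n_ab),
        "within_b_vs_between": (r_b, n_b, r_ab, n_ab),
    }
    z_stats, p_values = {}, {}
    for key, (r1, m1, r2, m2) in comparisons.items():
        if min(m1, m2) > 3 and max(abs(r1), abs(r2)) < 1:
            z, p = fisher_z_compare(r1, m1, r2, m2)
        else:  # too few observers for a normal-theory comparison
            z, p = float("nan"), float("nan")
        z_stats[key] = z
        p_values[key] = p
    return AgreementResult(
        r_within_a=r_a,
        r_within_b=r_b,
        r_between=r_ab,
        z_stats=z_stats,
        p_values=p_values,
    )


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent Pearson correlations via Fisher's r-to-z.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), with a two-sided
    p from the standard normal.  Antisymmetric in its argument pairs.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError(f"|r| must be < 1 for the Fisher transform, got {r}")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError(f"need n > 3 per sample, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# tabular I/O


def read_keypress_tsv(path, duration: float) -> list[KeypressLog]:
    """Read keypress logs from TSV with columns observer_id, press_time_s."""
    df = pd.read_csv(path, sep="\t")
    required = {"observer_id", "press_time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    logs = []
    for obs, grp in df.groupby("observer_id", sort=True):
        logs.append(
            KeypressLog(
                observer_id=str(obs),
                press_times=grp["press_time_s"].to_numpy(dtype=float),
                duration=duration,
            )
        )
    return logs


def write_keypress_tsv(logs: list[KeypressLog], path) -> None:
    rows = [
        {"observer_id": log.observer_id, "press_time_s": t}
        for log in logs
        for t in log.press_times
    ]
    pd.DataFrame(rows, columns=["observer_id", "press_time_s"]).to_csv(
        path, sep="\t", index=False
    )


def write_boundaries_tsv(boundaries: BoundarySet, path) -> None:
    pd.DataFrame(
        {"time_s": boundaries.boundary_times, "agreement": boundaries.agreement}
    ).to_csv(path, sep="\t", index=False)


def write_agreement_json(result: AgreementResult, path) -> None:
    payload = {
        "r_within_a": result.r_within_a,
        "r_within_b": result.r_within_b,
        "r_between": result.r_between,
        "z_stats": result.z_stats,
        "p_values": result.p_values,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
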