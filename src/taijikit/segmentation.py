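"""Temporal segmentation of continuous movement.

A continuous skeleton sequence is cut into movement units at moments of
relative stillness.  The driving signal is the composite motion energy

    E(t) = sum_j w_j ||v_j(t)||^2

with per-joint biomechanical weights w_j.  Key frames are local minima of
the (smoothed, multi-scale) energy curve; a boundary score

    B(t) = alpha dE/dt + beta S(t) + gamma P(t)

combining the energy derivative with spatial-configuration similarity S(t)
and postural stability P(t) gates the candidates.  Candidate segments are
validated against minimum-duration and maximum-velocity rules and labeled
by dynamic time warping against reference templates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from taijikit.skeleton import (
    KinematicDerivatives,
    SkeletonSequence,
    center_of_mass,
    central_velocity,
)

__all__ = [
    "EnergyProfile",
    "BoundaryConfig",
    "Segment",
    "Template",
    "motion_energy",
    "boundary_score",
    "detect_keyframes",
    "dtw_align",
    "segment_sequence",
]


@dataclass(frozen=True)
class EnergyProfile:
    """Per-frame motion energy (m^2/s^2) with the joint weights that built it."""

    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if np.any(v < -1e-12):
            raise ValueError("motion energy must be nonnegative")
        object.__setattr__(self, "values", np.maximum(v, 0.0))
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class BoundaryConfig:
    """Coefficients and validation rules for boundary detection.

    ``alpha, beta, gamma`` weight the boundary score terms; the smoothing /
    multi-scale analysis windows range from ``window_min`` to ``window_max``
    frames; candidate segments must last at least ``min_duration_frames``
    and stay below ``max_velocity`` (m/s peak joint speed).
    """

    alpha: float = 1.0
    beta: float = 0.5
    gamma: float = 0.5
    min_duration_frames: int = 25
    max_velocity: float = 8.0
    window_min: int = 30
    window_max: int = 90
    min_peak_separation: int = 20
    # percentile of smoothed energy below which a minimum counts as stillness
    stillness_percentile: float = 25.0

    def __post_init__(self) -> None:
        if self.window_min > self.window_max:
            raise ValueError("window_min must be <= window_max")
        if self.min_duration_frames < 1:
            raise ValueError("min_duration_frames must be >= 1")
        for name in ("alpha", "beta", "gamma"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class Segment:
    """Half-open frame interval [start, end) with template label and score."""

    start: int
    end: int
    label: str = "unknown"
    dtw_distance: float = float("inf")
    valid: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid segment bounds [{self.start}, {self.end})")
        if self.dtw_distance < 0:
            raise ValueError("dtw_distance must be nonnegative")


@dataclass(frozen=True)
class Template:
    """A canonical movement unit used as a DTW labeling reference."""

    template_id: str
    reference: SkeletonSequence

    def __post_init__(self) -> None:
        if self.reference.n_frames == 0:
            raise ValueError("template reference must be nonempty")


def motion_energy(
    deriv: KinematicDerivatives, weights: np.ndarray
) -> EnergyProfile:
    """Composite motion energy E(t) = sum_j w_j ||v_j(t)||^2."""
    if deriv.velocity is None:
        raise ValueError("motion_energy requires a velocity track")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("joint weights must be nonnegative")
    if w.shape[0] != deriv.velocity.shape[1]:
        raise ValueError("weights length must equal joint count")
    sq_speed = np.sum(deriv.velocity**2, axis=2)  # (T, J)
    return EnergyProfile(values=sq_speed @ w, weights=w)


def _pose_vectors(seq: SkeletonSequence) -> np.ndarray:
    """Root-centered flattened pose per frame, (T, 3J)."""
    root = seq.positions[:, :1, :]
    return (seq.positions - root).reshape(seq.n_frames, -1)


def configuration_similarity(seq: SkeletonSequence, window: int) -> np.ndarray:
    """S(t): cosine similarity of the pose vector to its value ``window`` frames earlier.

    The first ``window`` frames compare to frame 0.  A static pose gives 1
    everywhere.  This is the default spatial-configuration-similarity
    strategy; it is replaceable by passing an explicit signal to
    :func:`boundary_score`.
    """
    pv = _pose_vectors(seq)
    idx = np.maximum(np.arange(seq.n_frames) - window, 0)
    a, b = pv, pv[idx]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    denom = np.where(na * nb > 1e-12, na * nb, 1.0)
    sim = np.sum(a * b, axis=1) / denom
    sim[(na < 1e-12) & (nb < 1e-12)] = 1.0  # two degenerate poses agree
    return sim


def postural_stability(seq: SkeletonSequence) -> np.ndarray:
    """P(t) = exp(-||v_COM(t)||): high when the center of mass is still."""
    masses = np.ones(seq.n_joints)
    com = center_of_mass(seq.positions, masses)  # (T, 3)
    v = np.gradient(com, seq.dt, axis=0)
    return np.exp(-np.linalg.norm(v, axis=1))


def boundary_score(
    energy: EnergyProfile,
    similarity_signal: np.ndarray,
    stability_signal: np.ndarray,
    cfg: BoundaryConfig,
    dt: float = 1.0,
) -> np.ndarray:
    """B(t) = alpha dE/dt + beta S(t) + gamma P(t)."""
    e = energy.values
    s = np.asarray(similarity_signal, dtype=float)
    p = np.asarray(stability_signal, dtype=float)
    if not (len(e) == len(s) == len(p)):
        raise ValueError(
            f"signal length mismatch: E={len(e)}, S={len(s)}, P={len(p)}"
        )
    dedt = np.gradient(e, dt)
    return cfg.alpha * dedt + cfg.beta * s + cfg.gamma * p


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    window = max(int(window), 1)
    kernel = np.ones(window) / window
    # reflect-pad so the average stays centered at the edges
    pad = window // 2
    xp = np.pad(x, (pad, window - 1 - pad), mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def _local_minima_with_plateaus(x: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local minima; plateau keeps its first frame."""
    n = len(x)
    if n == 0:
        return np.array([], dtype=int)
    minima = []
    i = 1
    while i < n - 1:
        if x[i] < x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] > x[i]:
                minima.append(i)  # first frame of the plateau
            i = j + 1
        else:
            i += 1
    # an all-flat profile: keep the first frame of the single plateau
    if not minima and n > 0 and np.all(x == x[0]):
        minima.append(0)
    return np.array(minima, dtype=int)


def detect_keyframes(energy: EnergyProfile, cfg: BoundaryConfig) -> np.ndarray:
    """Key frames: multi-scale local minima of the smoothed energy curve.

    The energy is smoothed with a moving average of ``window_min / 2``
    frames; additional coarser scales up to ``window_max / 2`` contribute
    extra minima (union with de-duplication inside
    ``min_peak_separation``).  Candidates whose smoothed energy exceeds the
    ``stillness_percentile`` of the profile are discarded — only moments of
    relative stillness qualify as boundaries.
    """
    e = energy.values
    if len(e) == 0:
        raise ValueError("energy profile is empty")
    base_window = max(cfg.window_min // 2, 1)
    scales = sorted(
        {base_window, max(cfg.window_max // 4, 1), max(cfg.window_max // 2, 1)}
    )
    base = _smooth(e, base_window)
    candidates: set[int] = set()
    for w in scales:
        sm = _smooth(e, w) if w != base_window else base
        candidates.update(_local_minima_with_plateaus(sm).tolist())
    if not candidates:
        return np.array([], dtype=int)
    gate = np.percentile(base, cfg.stillness_percentile)
    kept = sorted(k for k in candidates if base[k] <= gate + 1e-12)
    # thin: keep the lowest-energy candidate within each separation window
    thinned: list[int] = []
    for k in kept:
        if thinned and k - thinned[-1] < cfg.min_peak_separation:
            if base[k] < base[thinned[-1]]:
                thinned[-1] = k
        else:
            thinned.append(k)
    return np.array(thinned, dtype=int)


def dtw_align(
    segment_seq: SkeletonSequence,
    template: Template,
    band_fraction: float | None = 0.2,
) -> tuple[float, list[tuple[int, int]]]:
    """Dynamic time warping of a segment against a reference template.

    The frame metric is the Euclidean distance between root-centered pose
    vectors.  The cumulative cost is minimized over monotone, contiguous
    paths with matched endpoints and normalized by path length.  A
    Sakoe-Chiba band of ``band_fraction`` of the longer length bounds the
    search; pass ``None`` for the exhaustive dynamic program.
    """
    if segment_seq.n_frames == 0 or template.reference.n_frames == 0:
        raise ValueError("dtw_align requires nonempty sequences")
    a = _pose_vectors(segment_seq)
    b = _pose_vectors(template.reference)
    n, m = len(a), len(b)
    band = max(n, m) if band_fraction is None else max(
        int(np.ceil(band_fraction * max(n, m))), abs(n - m) + 1
    )
    # pairwise frame distances (direct differences: exact zeros for
    # identical frames)
    d = cdist(a, b, metric="euclidean")
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    # anti-diagonal sweep: every dependency of diagonal s lies on s-1 / s-2,
    # so each diagonal vectorizes
    for s in range(2, n + m + 2):
        ilo = max(1, s - m, (s - band + 1) // 2)
        ihi = min(n, s - 1, (s + band) // 2)
        if ilo > ihi:
            continue
        i = np.arange(ilo, ihi + 1)
        j = s - i
        best = np.minimum(
            np.minimum(acc[i - 1, j], acc[i, j - 1]), acc[i - 1, j - 1]
        )
        acc[i, j] = d[i - 1, j - 1] + best
    # backtrack
    path = []
    i, j = n, m
    while i > 0 and j > 0:
        path.append((i - 1, j - 1))
        moves = [
            (acc[i - 1, j - 1], i - 1, j - 1),
            (acc[i - 1, j], i - 1, j),
            (acc[i, j - 1], i, j - 1),
        ]
        _, i, j = min(moves, key=lambda t: t[0])
    path.reverse()
    return float(acc[n, m] / len(path)), path


def segment_sequence(
    seq: SkeletonSequence,
    templates: list[Template],
    cfg: BoundaryConfig,
    joint_weights: np.ndarray | None = None,
) -> list[Segment]:
    """Partition a sequence into labeled movement segments.

    Boundaries come from :func:`detect_keyframes`; the resulting half-open
    segments cover [0, T) without overlap.  Each candidate is validated
    (duration >= ``min_duration_frames``, peak joint speed <=
    ``max_velocity``, non-trivial motion) and, if valid, labeled with the
    nearest template under :func:`dtw_align`.
    """
    T = seq.n_frames
    if T < cfg.window_min:
        warnings.warn(
            f"sequence of {T} frames is shorter than window_min={cfg.window_min}; "
            "returning a single unlabeled segment",
            stacklevel=2,
        )
        return [Segment(start=0, end=T, label="unknown", valid=False)]
    w = (
        np.ones(seq.n_joints)
        if joint_weights is None
        else np.asarray(joint_weights, float)
    )
    deriv = central_velocity(seq)
    energy = motion_energy(deriv, w)
    keyframes = detect_keyframes(energy, cfg)
    bounds = [0] + [int(k) for k in keyframes if 0 < k < T] + [T]
    bounds = sorted(set(bounds))

    speeds = np.linalg.norm(deriv.velocity, axis=2)  # (T, J)
    segments: list[Segment] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        duration_ok = (e - s) >= cfg.min_duration_frames
        peak_speed = float(speeds[s:e].max()) if e > s else 0.0
        velocity_ok = peak_speed <= cfg.max_velocity
        # momentary pauses / pure stillness carry no movement unit
        moving = float(energy.values[s:e].mean()) > 1e-10
        valid = bool(duration_ok and velocity_ok and moving)
        label, dist = "unknown", float("inf")
        if valid and templates:
            sub = seq.slice_frames(s, e)
            scored = [
                (dtw_align(sub, tpl)[0], tpl.template_id) for tpl in templates
            ]
            dist, label = min(scored)
        segments.append(
            Segment(start=s, end=e, label=label, dtw_distance=dist, valid=valid)
        )
    return segments
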