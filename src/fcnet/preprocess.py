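"""ROI-level denoising of BOLD time series.

Operates on region-averaged time series (volumes x regions); voxel-level
steps (slice timing, realignment, spatial normalisation, smoothing) are
assumed to have happened upstream. The pipeline order is:

    discard initial volumes -> motion QC -> nuisance regression
    (intercept + linear trend always; optionally Friston-24 motion
    expansion and global signal) -> temporal band-pass 0.01-0.08 Hz

Head motion enters twice: framewise displacement (FD) summarises it per
volume for quality control and provides the subject-level mean-FD covariate
used in group inference, and the Friston-24 expansion of the six rigid-body
parameters serves as nuisance regressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: radius (mm) of the sphere on which rotations are converted to arc
#: displacement when computing framewise displacement
FD_SPHERE_RADIUS_MM = 50.0

#: motion QC bounds: maximum absolute translation (mm) / rotation (degrees)
QC_MAX_TRANSLATION_MM = 1.5
QC_MAX_ROTATION_DEG = 1.5

DEFAULT_BAND_HZ = (0.01, 0.08)
DEFAULT_N_DISCARD = 10


@dataclass
class RoiTimeSeries:
    """One subject's region-averaged BOLD series.

    values : (n_volumes, n_regions) float array
    region_labels : one label per region column
    tr_seconds : repetition time (sampling interval), seconds
    """

    values: np.ndarray
    region_labels: list[str]
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time-series values must be 2-D (volumes x regions)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time-series values must be finite")
        if self.values.shape[1] != len(self.region_labels):
            raise ValueError(
                f"{self.values.shape[1]} regions but {len(self.region_labels)} labels"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class NuisanceModel:
    """Design matrix of nuisance regressors (one row per volume)."""

    regressors: np.ndarray
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be 2-D")
        if not self.column_names:
            self.column_names = [f"x{i}" for i in range(self.regressors.shape[1])]
        if len(self.column_names) != self.regressors.shape[1]:
            raise ValueError("column_names length must match regressor count")


@dataclass
class QcResult:
    subject_id: str
    passed: bool
    reason: str
    max_translation_mm: float
    max_rotation_deg: float
    mean_fd_mm: float


# ---------------------------------------------------------------------------
# volume discard
# ---------------------------------------------------------------------------

def discard_initial_volumes(
    ts: RoiTimeSeries, n_discard: int = DEFAULT_N_DISCARD
) -> RoiTimeSeries:
    """Drop the first ``n_discard`` volumes (scanner equilibration period)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= ts.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_volumes} volumes"
        )
    return replace(ts, values=ts.values[n_discard:].copy())


# ---------------------------------------------------------------------------
# head motion: framewise displacement and QC
# ---------------------------------------------------------------------------

def _check_motion(motion: np.ndarray) -> np.ndarray:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(
            "motion must be (n_volumes, 6): 3 translations (mm) then "
            "3 rotations (radians)"
        )
    return motion


def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """Per-volume framewise displacement (mm).

    FD(t) = sum_i |d_i(t) - d_i(t-1)| + r * sum_i |a_i(t) - a_i(t-1)|

    with translations ``d`` in mm, rotations ``a`` in radians converted to
    arc displacement on a sphere of radius r = 50 mm. FD of the first
    volume is defined as 0.
    """
    motion = _check_motion(motion)
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    delta = np.abs(np.diff(motion, axis=0))
    fd = delta[:, :3].sum(axis=1) + FD_SPHERE_RADIUS_MM * delta[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def qc_exclude(motion: np.ndarray, subject_id: str = "") -> QcResult:
    """Apply the head-motion exclusion rule.

    A subject fails if the maximum absolute translation exceeds 1.5 mm on
    any axis or the maximum absolute rotation exceeds 1.5 degrees on any
    axis. Rotations are stored in radians and converted at comparison time.
    """
    motion = _check_motion(motion)
    abs_t = np.abs(motion[:, :3])
    abs_r_deg = np.degrees(np.abs(motion[:, 3:]))
    max_t = float(abs_t.max())
    max_r = float(abs_r_deg.max())
    mean_fd = float(framewise_displacement(motion).mean()) if motion.shape[0] >= 2 else 0.0
    reasons = []
    if max_t > QC_MAX_TRANSLATION_MM:
        axis = "xyz"[int(np.unravel_index(abs_t.argmax(), abs_t.shape)[1])]
        reasons.append(
            f"translation {max_t:.3f} mm on axis {axis} exceeds "
            f"{QC_MAX_TRANSLATION_MM} mm"
        )
    if max_r > QC_MAX_ROTATION_DEG:
        axis = ("pitch", "roll", "yaw")[int(np.unravel_index(abs_r_deg.argmax(), abs_r_deg.shape)[1])]
        reasons.append(
            f"rotation {max_r:.3f} deg on axis {axis} exceeds "
            f"{QC_MAX_ROTATION_DEG} deg"
        )
    return QcResult(
        subject_id=subject_id,
        passed=not reasons,
        reason="; ".join(reasons) if reasons else "ok",
        max_translation_mm=max_t,
        max_rotation_deg=max_r,
        mean_fd_mm=mean_fd,
    )


# ---------------------------------------------------------------------------
# nuisance regression
# ---------------------------------------------------------------------------

def friston24(motion: np.ndarray) -> np.ndarray:
    """Friston 24-parameter motion expansion.

    Columns: the 6 rigid-body parameters, their one-volume lags (first row
    zero-padded), and the squares of both sets.
    """
    motion = _check_motion(motion)
    lagged = np.vstack([np.zeros((1, 6)), motion[:-1]])
    return np.hstack([motion, lagged, motion**2, lagged**2])


def build_nuisance_model(
    n_volumes: int,
    motion: np.ndarray | None = None,
    global_signal: np.ndarray | None = None,
    mean_fd: float | None = None,
) -> NuisanceModel:
    """Assemble the nuisance design: intercept + linear trend always, plus
    the Friston-24 motion expansion, the global signal, and optionally a
    constant mean-FD column (exactly collinear with the intercept at the
    subject level, so it is pruned again; kept for interface symmetry with
    group-level use)."""
    cols = [np.ones(n_volumes), np.linspace(-1.0, 1.0, n_volumes)]
    names = ["intercept", "trend"]
    if motion is not None:
        f24 = friston24(motion)
        if f24.shape[0] != n_volumes:
            raise ValueError("motion row count does not match volume count")
        cols.extend(f24.T)
        names.extend([f"friston24_{i}" for i in range(24)])
    if global_signal is not None:
        gs = np.asarray(global_signal, dtype=float).ravel()
        if gs.size != n_volumes:
            raise ValueError("global signal length does not match volume count")
        cols.append(gs)
        names.append("global_signal")
    if mean_fd is not None:
        cols.append(np.full(n_volumes, float(mean_fd)))
        names.append("mean_fd")
    return NuisanceModel(np.column_stack(cols), names)


def global_signal(ts: RoiTimeSeries) -> np.ndarray:
    """Mean over the regional series; stands in for the whole-brain average
    (no voxel data exists at this stage)."""
    return ts.values.mean(axis=1)


def _prune_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedily drop columns that add no rank (exact collinearity)."""
    keep: list[int] = []
    dropped: list[str] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


def regress_nuisance(ts: RoiTimeSeries, model: NuisanceModel) -> RoiTimeSeries:
    """Ordinary-least-squares residualisation of every region on the
    nuisance design. Intercept and linear trend are appended if absent, so
    the output is always detrended."""
    X = model.regressors
    names = list(model.column_names)
    if X.shape[0] != ts.n_volumes:
        raise ValueError(
            f"design has {X.shape[0]} rows but series has {ts.n_volumes} volumes"
        )
    n = ts.n_volumes
    if "intercept" not in names:
        X = np.column_stack([np.ones(n), X])
        names = ["intercept"] + names
    if "trend" not in names:
        X = np.column_stack([X, np.linspace(-1.0, 1.0, n)])
        names = names + ["trend"]
    Xp, kept, dropped = _prune_collinear(X, names)
    if np.linalg.matrix_rank(Xp) < Xp.shape[1]:
        raise ValueError(
            f"nuisance design rank-deficient after pruning {dropped}"
        )
    beta, *_ = np.linalg.lstsq(Xp, ts.values, rcond=None)
    resid = ts.values - Xp @ beta
    return replace(ts, values=resid)


# ---------------------------------------------------------------------------
# temporal filtering
# ---------------------------------------------------------------------------

def bandpass_array(
    values: np.ndarray,
    tr_seconds: float,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
) -> np.ndarray:
    """Ideal (boxcar) frequency-domain band-pass along axis 0.

    The series is demeaned and linearly detrended first, then Fourier
    components with frequency outside ``[low_hz, high_hz]`` are zeroed.
    The DC component is always removed, so the output has ~zero mean.
    """
    values = np.asarray(values, dtype=float)
    nyquist = 0.5 / tr_seconds
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist}"
        )
    n = values.shape[0]
    t = np.linspace(-1.0, 1.0, n)
    x = values - values.mean(axis=0, keepdims=True)
    slope = (t @ x) / (t @ t)
    x = x - np.outer(t, slope)
    spec = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    spec[(freqs < low_hz) | (freqs > high_hz)] = 0.0
    return np.fft.irfft(spec, n=n, axis=0)


def bandpass(
    ts: RoiTimeSeries,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
) -> RoiTimeSeries:
    """Band-pass every regional series to ``[low_hz, high_hz]`` Hz."""
    return replace(ts, values=bandpass_array(ts.values, ts.tr_seconds, low_hz, high_hz))


# ---------------------------------------------------------------------------
# full subject-level pipeline
# ---------------------------------------------------------------------------

def preprocess_subject(
    ts: RoiTimeSeries,
    motion: np.ndarray | None = None,
    n_discard: int = DEFAULT_N_DISCARD,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    use_global_signal: bool = True,
) -> RoiTimeSeries:
    """discard -> nuisance/detrend -> band-pass, with motion rows discarded
    in step with the volumes they describe."""
    ts = discard_initial_volumes(ts, n_discard)
    m = None
    if motion is not None:
        m = _check_motion(motion)
        if m.shape[0] < ts.n_volumes + n_discard:
            raise ValueError("motion has fewer rows than the original series")
        m = m[n_discard : n_discard + ts.n_volumes]
    gs = global_signal(ts) if use_global_signal else None
    model = build_nuisance_model(ts.n_volumes, motion=m, global_signal=gs)
    ts = regress_nuisance(ts, model)
    return bandpass(ts, *band_hz)
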