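"""Fluorescence trace analysis: evoked dF/F0, spontaneous activity, dose-response.

Covers the quantification conventions of in vivo hair-cell Ca2+ imaging:

* evoked responses normalized to a pre-stimulus baseline F0, with per-channel
  activity thresholds (strict ``>``): 0.25 for membrane-localized GCaMP6sCAAX,
  0.05 for the mitochondrial indicators;
* spontaneous recordings baselined to the bottom 15th percentile, a 10 percent
  dF/F0 noise floor, magnitude = suprathreshold integral / frame count, and
  event frequency from thresholded local maxima;
* divisive mono-exponential photobleaching correction with event masking;
* two-channel Pearson correlation;
* mock-control baseline normalization and replicate-stack averaging;
* four-parameter logistic (variable-slope) dose-response fitting for IC50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import optimize, signal
from skimage.registration import phase_cross_correlation

__all__ = [
    "TraceSet",
    "EvokedResult",
    "SpontaneousStats",
    "DoseResponseFit",
    "BaselinePair",
    "register_translation",
    "roi_trace",
    "evoked_dff",
    "dff_map",
    "bleach_correct",
    "spontaneous_stats",
    "pearson_matrix",
    "normalize_to_mock",
    "average_replicate_stacks",
    "fit_4pl",
    "activity_threshold",
]

#: Strict activity thresholds on max dF/F0, per indicator family.
ACTIVITY_THRESHOLDS = {"presynaptic": 0.25, "mitochondrial": 0.05}


@dataclass(frozen=True)
class TraceSet:
    """Per-ROI fluorescence time series.

    ``values`` is a (cells x frames) array of raw fluorescence;
    ``stimulus_windows`` is a list of (start_s, end_s) within the recording.
    """

    values: np.ndarray
    frame_rate: float
    stimulus_windows: tuple = ()
    channel: str = ""
    cell_ids: tuple = ()

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        dur = v.shape[1] / self.frame_rate
        for (a, b) in self.stimulus_windows:
            if not (0 <= a < b <= dur + 1e-9):
                raise ValueError(f"stimulus window ({a}, {b}) outside recording of {dur} s")
        object.__setattr__(self, "values", v)
        ids = self.cell_ids or tuple(range(v.shape[0]))
        object.__setattr__(self, "cell_ids", tuple(ids))

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class EvokedResult:
    """Evoked dF/F0 analysis of one TraceSet (arrays are per cell)."""

    f0: np.ndarray
    dff: np.ndarray  # cells x frames
    peak: np.ndarray
    active: np.ndarray
    threshold_used: float


@dataclass
class SpontaneousStats:
    """Spontaneous-activity statistics of a single bleach-corrected trace."""

    f0: float
    dff: np.ndarray
    magnitude: float  # mean suprathreshold dF/F0 per frame
    frequency: float  # peaks per second
    event_times: np.ndarray


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    hill: float
    ic50: float
    fitted: np.ndarray
    residual_norm: float
    ok: bool = True
    message: str = ""


@dataclass(frozen=True)
class BaselinePair:
    """Pre/post treatment intensity of one neuromast."""

    pre: float
    post: float
    treated: bool = True

    def __post_init__(self):
        if self.pre <= 0:
            raise ValueError("pre-treatment intensity must be positive")

    @property
    def ratio(self) -> float:
        return self.post / self.pre


def activity_threshold(channel: str) -> float:
    """Max-dF/F0 activity threshold for a channel tag.

    Mitochondria-targeted indicators ("mito" in the tag) use 0.05; membrane /
    cytosolic presynaptic indicators use 0.25.
    """
    if "mito" in channel.lower():
        return ACTIVITY_THRESHOLDS["mitochondrial"]
    return ACTIVITY_THRESHOLDS["presynaptic"]


# --------------------------------------------------------------------------
# movie-level operations


def register_translation(movie: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correct integer-pixel translational drift against the first frame.

    Shifts are the estimated (dy, dx) displacement of each frame relative to
    frame 0, found by FFT cross-correlation; frames are shifted back by the
    negated displacement.  Constant frames get shift (0, 0) by tie-break.

    Returns ``(aligned_movie, shifts)`` with shifts of shape (frames, 2).
    """
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise ValueError("movie must be (frames, y, x) with at least 2 frames")
    ref = movie[0]
    shifts = np.zeros((movie.shape[0], 2), dtype=int)
    aligned = movie.copy()
    ref_flat = ref.std() == 0
    for k in range(1, movie.shape[0]):
        frame = movie[k]
        if ref_flat or frame.std() == 0:
            continue
        est, _, _ = phase_cross_correlation(ref, frame, upsample_factor=1)
        disp = -np.round(est).astype(int)  # displacement of frame w.r.t. reference
        shifts[k] = disp
        aligned[k] = ndi.shift(frame, -disp, order=0, mode="nearest")
    return aligned, shifts


def roi_trace(
    movie: np.ndarray,
    center: tuple[float, float],
    diameter: float,
    pixel_size: float,
) -> np.ndarray:
    """Mean intensity inside a circular ROI, per frame.

    ``center`` is (y, x) in micrometres, ``diameter`` in micrometres; a pixel
    belongs to the ROI when its center (index * pixel_size) falls strictly
    inside the circle.  The circle must lie within the image and span at
    least one pixel.
    """
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, y, x)")
    if diameter < pixel_size:
        raise ValueError(f"ROI diameter {diameter} um is smaller than one pixel ({pixel_size} um)")
    ny, nx = movie.shape[1:]
    cy, cx = center
    r = diameter / 2.0
    if cy - r < -pixel_size / 2 or cx - r < -pixel_size / 2:
        raise ValueError("ROI extends outside the image")
    if cy + r > (ny - 0.5) * pixel_size or cx + r > (nx - 0.5) * pixel_size:
        raise ValueError("ROI extends outside the image")
    yy = np.arange(ny) * pixel_size
    xx = np.arange(nx) * pixel_size
    mask = (yy[:, None] - cy) ** 2 + (xx[None, :] - cx) ** 2 <= r**2
    if not mask.any():
        raise ValueError("ROI contains no pixel centers")
    return movie[:, mask].mean(axis=1)


def dff_map(
    movie: np.ndarray,
    prestim_frames: int,
    bin_frames: int = 1,
) -> tuple[np.ndarray, dict]:
    """Spatial dF image series relative to the pre-stimulus baseline image.

    The per-pixel F0 image is the mean of the first ``prestim_frames`` frames;
    every later frame minus F0 gives dF, averaged in non-overlapping bins of
    ``bin_frames``.  Returns the binned dF series and a scaling record
    (global min/max) for color encoding.
    """
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, y, x)")
    if not 0 < prestim_frames < movie.shape[0]:
        raise ValueError("prestim_frames must leave at least one post-baseline frame")
    post = movie.shape[0] - prestim_frames
    if bin_frames < 1 or bin_frames > post:
        raise ValueError(f"bin_frames must be in [1, {post}]")
    f0 = movie[:prestim_frames].mean(axis=0)
    df = movie[prestim_frames:] - f0
    nbins = df.shape[0] // bin_frames
    binned = df[: nbins * bin_frames].reshape(nbins, bin_frames, *df.shape[1:]).mean(axis=1)
    scale = {"min": float(binned.min()), "max": float(binned.max())}
    return binned, scale


# --------------------------------------------------------------------------
# trace-level operations


def evoked_dff(
    traces: TraceSet,
    prestim_window: tuple[float, float],
    threshold: float | None = None,
) -> EvokedResult:
    """Evoked dF/F0 with per-cell baseline and activity classification.

    F0 is the mean raw fluorescence over the pre-stimulus window; the peak is
    the maximum dF/F0 over every frame after that window (stimulus and
    recovery).  A cell is active when its peak strictly exceeds the channel's
    threshold (0.25 presynaptic, 0.05 mitochondrial), or ``threshold`` if
    given.
    """
    t0, t1 = prestim_window
    if traces.stimulus_windows and t1 > min(w[0] for w in traces.stimulus_windows) + 1e-9:
        raise ValueError("pre-stimulus window must end before the first stimulus")
    i0 = int(round(t0 * traces.frame_rate))
    i1 = int(round(t1 * traces.frame_rate))
    if i1 <= i0:
        raise ValueError("empty pre-stimulus window")
    f0 = traces.values[:, i0:i1].mean(axis=1)
    if np.any(f0 <= 0):
        bad = np.where(f0 <= 0)[0]
        raise ValueError(f"non-positive baseline F0 for cells {bad.tolist()}")
    dff = (traces.values - f0[:, None]) / f0[:, None]
    peak = dff[:, i1:].max(axis=1)
    thr = activity_threshold(traces.channel) if threshold is None else float(threshold)
    return EvokedResult(f0=f0, dff=dff, peak=peak, active=peak > thr, threshold_used=thr)


def bleach_correct(
    trace: np.ndarray,
    frame_rate: float = 1.0,
    n_iter: int = 3,
) -> tuple[np.ndarray, dict]:
    """Divisive mono-exponential photobleaching correction.

    Fits ``A * exp(-t / tau) + C`` to the trace, iteratively masking samples
    more than 2 robust standard deviations above the fit (transient events)
    so the baseline decay dominates.  The trace is divided by the fit
    normalized to its value at t = 0, preserving dF/F0 ratios.  Flat traces
    pass through essentially unchanged; on pathological input the correction
    falls back to a no-op and flags it.

    Returns ``(corrected, info)`` where info holds ``tau``, ``ok`` and the
    final event mask.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1 or trace.size < 20:
        raise ValueError("trace must be 1D with at least 20 frames")
    t = np.arange(trace.size) / frame_rate

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    lo = float(trace.min())
    p0 = (max(trace[0] - lo, 1e-6), t[-1] / 2.0, lo)
    bounds = ([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf])
    keep = np.ones(trace.size, dtype=bool)
    popt = None
    try:
        for _ in range(n_iter):
            popt, _ = optimize.curve_fit(
                model, t[keep], trace[keep], p0=p0, bounds=bounds, maxfev=20000
            )
            fit = model(t, *popt)
            resid = trace - fit
            mad = np.median(np.abs(resid[keep] - np.median(resid[keep])))
            sd = 1.4826 * mad if mad > 0 else resid[keep].std()
            if sd == 0:
                break
            new_keep = resid <= 2.0 * sd
            if new_keep.sum() < trace.size // 4 or np.array_equal(new_keep, keep):
                break
            keep = new_keep
            p0 = tuple(popt)
        fit = model(t, *popt)
        if fit[0] <= 0 or np.any(fit <= 0):
            raise RuntimeError("non-positive bleaching fit")
        corrected = trace / (fit / fit[0])
        return corrected, {"tau": float(popt[1]), "ok": True, "event_mask": ~keep}
    except (RuntimeError, ValueError) as exc:
        warnings.warn(f"bleach correction failed ({exc}); returning trace unchanged")
        return trace.copy(), {"tau": np.nan, "ok": False, "event_mask": np.zeros_like(keep)}


def spontaneous_stats(
    trace: np.ndarray,
    frame_rate: float,
    noise_threshold: float = 0.10,
    baseline_percentile: float = 15.0,
    baseline_mode: str = "percentile",
    min_peak_separation: int = 3,
) -> SpontaneousStats:
    """Magnitude and frequency of spontaneous activity in one trace.

    F0 is the bottom 15th percentile of the (bleach-corrected) fluorescence
    values -- by default the percentile value with linear interpolation; set
    ``baseline_mode="mean_lowest"`` to average the lowest 15 percent of
    samples instead.  dF/F0 samples below ``noise_threshold`` are treated as
    noise and zeroed.  Magnitude is the suprathreshold dF/F0 integral (sum)
    divided by the number of frames; frequency is the count of local maxima
    of the thresholded trace (minimum separation ``min_peak_separation``
    frames, minimum prominence ``noise_threshold``) per second.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1 or trace.size == 0:
        raise ValueError("trace must be a non-empty 1D array")
    if baseline_mode == "percentile":
        f0 = float(np.percentile(trace, baseline_percentile))
    elif baseline_mode == "mean_lowest":
        k = max(1, int(np.ceil(trace.size * baseline_percentile / 100.0)))
        f0 = float(np.sort(trace)[:k].mean())
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    if f0 <= 0:
        raise ValueError("baseline F0 must be positive")
    dff = (trace - f0) / f0
    dff = np.where(dff < noise_threshold, 0.0, dff)
    magnitude = float(dff.sum() / trace.size)
    peaks, _ = signal.find_peaks(
        dff, distance=min_peak_separation, prominence=noise_threshold
    )
    duration = trace.size / frame_rate
    return SpontaneousStats(
        f0=f0,
        dff=dff,
        magnitude=magnitude,
        frequency=len(peaks) / duration,
        event_times=peaks / frame_rate,
    )


def pearson_matrix(set_a: TraceSet, set_b: TraceSet) -> np.ndarray:
    """Pearson r for every (cell in A, cell in B) pair.

    Returns an (n_a x n_b) matrix in [-1, 1]; entries involving a
    zero-variance trace are NaN (undefined, flagged rather than zeroed).
    """
    if set_a.n_frames != set_b.n_frames:
        raise ValueError("trace sets must have equal frame counts")
    a = set_a.values
    b = set_b.values
    a_sd = a.std(axis=1)
    b_sd = b.std(axis=1)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    cov = ac @ bc.T / a.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.outer(a_sd, b_sd)
    r[a_sd == 0, :] = np.nan
    r[:, b_sd == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def normalize_to_mock(
    treated: list[BaselinePair], mock: list[BaselinePair]
) -> np.ndarray:
    """Normalize post/pre intensity ratios to mock-treated controls.

    Mock controls imaged in every trial capture photobleaching and drift;
    each treated ratio is divided by the mean mock ratio, so the mock set's
    own mean normalized change is 1 by construction.
    """
    if not mock:
        raise ValueError("mock control set must be non-empty")
    mock_mean = float(np.mean([m.ratio for m in mock]))
    if mock_mean <= 0:
        raise ValueError("mean mock ratio must be positive")
    return np.array([p.ratio / mock_mean for p in treated])


def average_replicate_stacks(intensities) -> float:
    """Arithmetic mean of replicate Z-stack intensities at one time point."""
    vals = np.asarray(list(intensities), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one replicate intensity")
    return float(vals.mean())


# --------------------------------------------------------------------------
# dose-response


def four_param_logistic(d, bottom, top, ic50, hill):
    """4PL inhibition curve; dose 0 maps to the top asymptote."""
    d = np.asarray(d, dtype=np.float64)
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (d / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_4pl(doses, responses) -> DoseResponseFit:
    """Least-squares four-parameter logistic fit with variable slope.

    Initial values come from the data extremes (top = response at the lowest
    dose, bottom = at the highest) and the dose where the response crosses
    their midpoint.  IC50 is fitted in log space to stay positive.  Flat
    responses or non-convergence are reported via ``ok=False`` with a
    message, never silently defaulted.
    """
    d = np.asarray(doses, dtype=np.float64)
    y = np.asarray(responses, dtype=np.float64)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("doses and responses must be 1D arrays of equal length")
    if np.unique(d).size < 4:
        raise ValueError("need at least 4 distinct doses for a 4-parameter fit")
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")

    if np.ptp(y) == 0:
        return DoseResponseFit(
            bottom=float(y[0]), top=float(y[0]), hill=np.nan, ic50=np.nan,
            fitted=y.copy(), residual_norm=0.0, ok=False,
            message="degenerate: all responses equal",
        )

    order = np.argsort(d)
    top0 = float(y[order[0]])
    bot0 = float(y[order[-1]])
    mid = (top0 + bot0) / 2.0
    pos = d > 0
    if pos.any():
        # positive dose whose response is nearest the midpoint crossing
        ic50_0 = float(d[pos][np.argmin(np.abs(y[pos] - mid))])
    else:
        ic50_0 = 1.0

    def model(d, bottom, top, log_ic50, hill):
        return four_param_logistic(d, bottom, top, np.exp(log_ic50), hill)

    try:
        popt, _ = optimize.curve_fit(
            model, d, y,
            p0=(bot0, top0, np.log(max(ic50_0, 1e-6)), 1.0),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return DoseResponseFit(
            bottom=np.nan, top=np.nan, hill=np.nan, ic50=np.nan,
            fitted=np.full_like(y, np.nan), residual_norm=np.nan,
            ok=False, message=f"fit did not converge: {exc}",
        )
    bottom, top, log_ic50, hill = popt
    fitted = model(d, *popt)
    return DoseResponseFit(
        bottom=float(bottom), top=float(top), hill=float(hill),
        ic50=float(np.exp(log_ic50)), fitted=fitted,
        residual_norm=float(np.linalg.norm(y - fitted)),
    )
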