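"""Synthetic phantoms with ground truth for every pipeline stage.

Image phantoms emulate Airyscan-like immunostained neuromast stacks: clusters
of presynaptic ribbon puncta with paired postsynaptic densities offset by a
sampled gap, extrasynaptic aggregates, a third channel (Ca_V_1.3-like)
deposited at ribbon sites, planar background shading, and Poisson + Gaussian
detector noise.  Trace phantoms emulate evoked recordings (fast cytosolic vs
slow mitochondrial kinetics) and 900 s spontaneous recordings with coupled
two-channel events and exponential photobleaching.

Every generator returns the rendered data together with a :class:`GroundTruth`
of true puncta, pairs and events, so recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .puncta import VolumeStack
from .traces import TraceSet

__all__ = [
    "ImagePhantomSpec",
    "TraceSimSpec",
    "ChannelKinetics",
    "GroundTruth",
    "simulate_stack",
    "simulate_evoked_traces",
    "simulate_spontaneous_traces",
    "simulate_dose_response",
    "event_kernel",
]

# half-max footprint of a 2D Gaussian: area = 2*pi*ln(2)*sigma^2
_HALF_MAX_AREA = 2.0 * math.pi * math.log(2.0)


@dataclass
class GroundTruth:
    """True puncta, synapse pairs and trace events of a phantom.

    ``puncta`` columns: id, channel, z_um, y_um, x_um, area_um2,
    total_intensity, synaptic.  ``pairs`` columns: ribbon_id, psd_id, gap_um.
    ``events`` columns: cell, channel, time_s, amplitude.
    """

    puncta: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    events: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class ImagePhantomSpec:
    """Parameters of an immunostain image phantom.

    Defaults approximate a 5 dpf neuromast imaged at Airyscan-like sampling:
    0.05 um lateral / 0.3 um axial voxels, a handful of hair cells with ~3
    ribbons each, ribbon-PSD centroid gaps of 0.15 +/- 0.05 um, projected
    areas straddling the 0.08 / 0.04 um^2 minimum-size filters.
    """

    stack_shape: tuple[int, int, int] = (24, 192, 192)
    voxel_size: tuple[float, float, float] = (0.3, 0.05, 0.05)
    n_cells: int = 4
    ribbons_per_cell: int | tuple[int, int] = 3
    paired_fraction: float = 1.0
    gap_mean: float = 0.15  # um
    gap_sd: float = 0.05
    ribbon_area: tuple[float, float] = (0.10, 0.30)  # um^2
    psd_area: tuple[float, float] = (0.06, 0.20)
    n_extrasynaptic: int = 3
    extrasynaptic_area: tuple[float, float] = (0.02, 0.06)
    peak_intensities: dict = field(
        default_factory=lambda: {"ribbon": 100.0, "psd": 100.0, "extrasynaptic": 60.0}
    )
    intensity_jitter: float = 0.2  # fractional peak variation between puncta
    channel3_coefficient: float = 0.5  # channel-3 AU per unit ribbon peak
    background: tuple[float, float] = (5.0, 5.0)  # constant AU, gradient amplitude AU
    poisson_gain: float = 1.0  # photons per AU; 0 disables shot noise
    gaussian_sd: float = 2.0  # read noise AU; 0 disables
    axial_elongation: float = 3.0  # sigma_z / sigma_lateral
    min_separation: float = 1.0  # um between ribbon centers
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ValueError(f"paired_fraction must be in [0, 1]; got {self.paired_fraction}")
        if any(s <= 0 for s in self.stack_shape):
            raise ValueError(f"stack_shape must be positive; got {self.stack_shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive; got {self.voxel_size}")
        for name in ("ribbon_area", "psd_area", "extrasynaptic_area"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (low, high) range")
        if any(v <= 0 for v in self.peak_intensities.values()):
            raise ValueError("peak_intensities must be positive")
        if self.gap_mean < 0 or self.gap_sd < 0:
            raise ValueError("gap distribution parameters must be non-negative")
        if self.poisson_gain < 0 or self.gaussian_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        # largest blob must fit inside the stack
        sigma = _sigma_from_area(max(self.ribbon_area[1], self.psd_area[1]))
        extent_z = 2 * 3 * sigma * self.axial_elongation
        extent_xy = 2 * 3 * sigma
        nz, ny, nx = self.stack_shape
        vz, vy, vx = self.voxel_size
        if extent_z > nz * vz or extent_xy > ny * vy or extent_xy > nx * vx:
            raise ValueError(
                f"blob extent ({extent_z:.2f} x {extent_xy:.2f} um) exceeds stack "
                f"({nz * vz:.2f} x {ny * vy:.2f} x {nx * vx:.2f} um)"
            )


def _sigma_from_area(area: float) -> float:
    """Lateral Gaussian sigma (um) whose half-max projected footprint has the given area."""
    return math.sqrt(area / _HALF_MAX_AREA)


def _render_blob(vol, center_um, sigma_um, amplitude, voxel_size):
    """Add an anisotropic 3D Gaussian to ``vol`` (in place); returns rendered sum."""
    vz, vy, vx = voxel_size
    sz, sy, sx = sigma_um
    cz, cy, cx = center_um
    # local patch of +/- 4 sigma
    z0 = max(0, int((cz - 4 * sz) / vz))
    z1 = min(vol.shape[0], int((cz + 4 * sz) / vz) + 2)
    y0 = max(0, int((cy - 4 * sy) / vy))
    y1 = min(vol.shape[1], int((cy + 4 * sy) / vy) + 2)
    x0 = max(0, int((cx - 4 * sx) / vx))
    x1 = min(vol.shape[2], int((cx + 4 * sx) / vx) + 2)
    zz = (np.arange(z0, z1) * vz - cz) / sz
    yy = (np.arange(y0, y1) * vy - cy) / sy
    xx = (np.arange(x0, x1) * vx - cx) / sx
    blob = amplitude * np.exp(
        -0.5 * (zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2)
    )
    vol[z0:z1, y0:y1, x0:x1] += blob
    return float(blob.sum())


def _place_centers(spec: ImagePhantomSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Sample ribbon centers (um) with minimum mutual separation, away from borders."""
    nz, ny, nx = spec.stack_shape
    vz, vy, vx = spec.voxel_size
    sigma_max = _sigma_from_area(max(spec.ribbon_area[1], spec.psd_area[1]))
    margin_xy = 3 * sigma_max + spec.gap_mean + 3 * spec.gap_sd
    margin_z = 3 * sigma_max * spec.axial_elongation + spec.gap_mean + 3 * spec.gap_sd
    lo = np.array([margin_z, margin_xy, margin_xy])
    hi = np.array([nz * vz - margin_z, ny * vy - margin_xy, nx * vx - margin_xy])
    if np.any(hi <= lo):
        raise ValueError("stack too small for the requested blob sizes and gaps")
    centers: list[np.ndarray] = []
    # separation in resolution units: axial distance is discounted by the blob
    # elongation so that every placed pair is optically resolvable
    w = np.array([1.0 / spec.axial_elongation, 1.0, 1.0])
    tries = 0
    while len(centers) < n:
        c = lo + rng.random(3) * (hi - lo)
        if all(np.linalg.norm((c - p) * w) >= spec.min_separation for p in centers):
            centers.append(c)
        tries += 1
        if tries > 20000:
            raise ValueError(
                f"could not place {n} puncta with separation {spec.min_separation} um"
            )
    return np.array(centers)


def simulate_stack(
    spec: ImagePhantomSpec,
) -> tuple[dict[str, VolumeStack], GroundTruth]:
    """Render a three-channel image phantom and its ground truth.

    Channels: ``ribbon`` (presynaptic label, including extrasynaptic
    aggregates), ``psd`` (postsynaptic label) and ``channel3`` (deposited at
    ribbon sites with amplitude proportional to the ribbon's).  A fraction
    ``paired_fraction`` of ribbons gets a PSD at the sampled 3D gap in a
    random direction.  The same spec and seed reproduce the output bit for
    bit.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.stack_shape
    vols = {
        "ribbon": np.zeros(spec.stack_shape, dtype=np.float64),
        "psd": np.zeros(spec.stack_shape, dtype=np.float64),
        "channel3": np.zeros(spec.stack_shape, dtype=np.float64),
    }

    if isinstance(spec.ribbons_per_cell, tuple):
        lo, hi = spec.ribbons_per_cell
        per_cell = rng.integers(lo, hi + 1, size=spec.n_cells)
    else:
        per_cell = np.full(spec.n_cells, int(spec.ribbons_per_cell))
    n_ribbons = int(per_cell.sum())
    centers = _place_centers(spec, rng, n_ribbons + spec.n_extrasynaptic)
    ribbon_centers = centers[:n_ribbons]
    extra_centers = centers[n_ribbons:]

    puncta_rows = []
    pair_rows = []
    next_id = 1

    # deterministic paired count: round(fraction * n) ribbons, chosen at random
    n_paired = int(round(spec.paired_fraction * n_ribbons))
    paired = np.zeros(n_ribbons, dtype=bool)
    paired[rng.permutation(n_ribbons)[:n_paired]] = True
    jit = spec.intensity_jitter

    ribbon_ids = []
    for i, c in enumerate(ribbon_centers):
        area = rng.uniform(*spec.ribbon_area)
        sig = _sigma_from_area(area)
        amp = spec.peak_intensities["ribbon"] * (1 + jit * (2 * rng.random() - 1))
        tot = _render_blob(
            vols["ribbon"], c, (sig * spec.axial_elongation, sig, sig), amp, spec.voxel_size
        )
        _render_blob(
            vols["channel3"], c, (sig * spec.axial_elongation, sig, sig),
            spec.channel3_coefficient * amp, spec.voxel_size,
        )
        puncta_rows.append(
            dict(id=next_id, channel="ribbon", z_um=c[0], y_um=c[1], x_um=c[2],
                 area_um2=area, total_intensity=tot, synaptic=bool(paired[i]),
                 peak=amp)
        )
        ribbon_ids.append(next_id)
        next_id += 1

    for i, c in enumerate(ribbon_centers):
        if not paired[i]:
            continue
        gap = max(0.0, rng.normal(spec.gap_mean, spec.gap_sd))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pc = c + gap * direction
        area = rng.uniform(*spec.psd_area)
        sig = _sigma_from_area(area)
        amp = spec.peak_intensities["psd"] * (1 + jit * (2 * rng.random() - 1))
        tot = _render_blob(
            vols["psd"], pc, (sig * spec.axial_elongation, sig, sig), amp, spec.voxel_size
        )
        puncta_rows.append(
            dict(id=next_id, channel="psd", z_um=pc[0], y_um=pc[1], x_um=pc[2],
                 area_um2=area, total_intensity=tot, synaptic=True, peak=amp)
        )
        pair_rows.append(dict(ribbon_id=ribbon_ids[i], psd_id=next_id, gap_um=gap))
        next_id += 1

    for c in extra_centers:
        area = rng.uniform(*spec.extrasynaptic_area)
        sig = _sigma_from_area(area)
        amp = spec.peak_intensities["extrasynaptic"] * (1 + jit * (2 * rng.random() - 1))
        tot = _render_blob(
            vols["ribbon"], c, (sig * spec.axial_elongation, sig, sig), amp, spec.voxel_size
        )
        puncta_rows.append(
            dict(id=next_id, channel="ribbon", z_um=c[0], y_um=c[1], x_um=c[2],
                 area_um2=area, total_intensity=tot, synaptic=False, peak=amp)
        )
        next_id += 1

    const, grad = spec.background
    if const or grad:
        yy = np.linspace(0.0, 1.0, ny)[None, :, None]
        xx = np.linspace(0.0, 1.0, nx)[None, None, :]
        bg = const + grad * 0.5 * (yy + xx)
        for v in vols.values():
            v += bg

    for name, v in vols.items():
        if spec.poisson_gain > 0:
            v = rng.poisson(np.clip(v, 0, None) * spec.poisson_gain) / spec.poisson_gain
        if spec.gaussian_sd > 0:
            v = v + rng.normal(0.0, spec.gaussian_sd, size=v.shape)
        vols[name] = v.astype(np.float64)

    stacks = {
        name: VolumeStack(voxels=v, voxel_size=spec.voxel_size, channel=name)
        for name, v in vols.items()
    }
    truth = GroundTruth(
        puncta=pd.DataFrame(puncta_rows),
        pairs=pd.DataFrame(pair_rows, columns=["ribbon_id", "psd_id", "gap_um"]),
        events=pd.DataFrame(columns=["cell", "channel", "time_s", "amplitude"]),
    )
    return stacks, truth


# --------------------------------------------------------------------------
# traces


@dataclass
class ChannelKinetics:
    """Event kernel kinetics of one indicator channel.

    ``rise_tau`` / ``decay_tau`` are the exponential time constants (s) of
    the difference-of-exponentials kernel; ``plateau`` is the evoked peak
    dF/F0 (the kernel is normalized to a maximum of 1).
    """

    rise_tau: float
    decay_tau: float
    plateau: float = 0.5

    def __post_init__(self):
        if not 0 < self.rise_tau < self.decay_tau:
            raise ValueError("need 0 < rise_tau < decay_tau")
        if self.plateau < 0:
            raise ValueError("plateau must be >= 0")


#: Default kinetics: fast cytosolic/membrane indicator (60 ms rise, return to
#: baseline over ~12 s) vs slow mitochondrial uptake (rise within ~0.6 s,
#: ~5 min return).
DEFAULT_KINETICS = {
    "cyto": ChannelKinetics(rise_tau=0.06, decay_tau=3.0, plateau=0.5),
    "mito": ChannelKinetics(rise_tau=0.6, decay_tau=75.0, plateau=0.5),
}


@dataclass
class TraceSimSpec:
    """Parameters of evoked / spontaneous trace simulation."""

    frame_rate: float = 50.0  # Hz
    duration: float = 30.0  # s
    stimulus_windows: tuple = ((10.0, 12.0),)
    baseline_F: float = 100.0
    kinetics: dict = field(default_factory=lambda: dict(DEFAULT_KINETICS))
    event_rate: float = 0.02  # events/s, spontaneous
    amplitude_mean: float = 0.8  # dF/F0
    amplitude_sd: float = 0.2
    coupling: float = 1.0  # fraction of events shared between channels
    bleach_tau: float = math.inf  # s; inf disables bleaching
    noise_sd: float = 0.0  # AU
    n_cells: int = 4
    event_times: tuple | None = None  # explicit planted times override Poisson
    seed: int = 0

    def validate(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError(f"coupling must be in [0, 1]; got {self.coupling}")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if self.amplitude_mean < 0:
            raise ValueError("amplitude_mean must be >= 0")
        if self.baseline_F <= 0:
            raise ValueError("baseline_F must be positive")
        for (a, b) in self.stimulus_windows:
            if not 0 <= a < b <= self.duration:
                raise ValueError(f"stimulus window ({a}, {b}) outside duration {self.duration}")


def event_kernel(t: np.ndarray, kin: ChannelKinetics) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to a maximum of 1.

    ``k(t) = (exp(-t/decay) - exp(-t/rise)) / k(t_peak)`` for t >= 0, else 0,
    with ``t_peak = rise*decay/(decay-rise) * ln(decay/rise)``.
    """
    tr, td = kin.rise_tau, kin.decay_tau
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    norm = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    t = np.asarray(t, dtype=np.float64)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (np.exp(-t[pos] / td) - np.exp(-t[pos] / tr)) / norm
    return out


def _bleach(t: np.ndarray, tau: float) -> np.ndarray:
    if math.isinf(tau):
        return np.ones_like(t)
    return np.exp(-t / tau)


def simulate_evoked_traces(
    spec: TraceSimSpec,
) -> tuple[dict[str, TraceSet], GroundTruth]:
    """Simulate evoked recordings, one TraceSet per kinetics channel.

    Each stimulus window start triggers the channel's kernel scaled by its
    plateau; the noise-free trace is
    ``baseline_F * (1 + plateau * kernel) * bleach``.  Ground-truth events
    record the planted peak dF/F0 per cell and stimulus.
    """
    spec.validate()
    if not spec.stimulus_windows:
        raise ValueError("evoked simulation needs at least one stimulus window")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(int(round(spec.duration * spec.frame_rate))) / spec.frame_rate
    sets: dict[str, TraceSet] = {}
    ev_rows = []
    for channel, kin in spec.kinetics.items():
        sig = np.zeros_like(t)
        for (start, _end) in spec.stimulus_windows:
            sig += kin.plateau * event_kernel(t - start, kin)
        clean = spec.baseline_F * (1.0 + sig) * _bleach(t, spec.bleach_tau)
        values = np.tile(clean, (spec.n_cells, 1))
        if spec.noise_sd > 0:
            values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
        sets[channel] = TraceSet(
            values=values, frame_rate=spec.frame_rate,
            stimulus_windows=tuple(spec.stimulus_windows), channel=channel,
        )
        for cell in range(spec.n_cells):
            for (start, _end) in spec.stimulus_windows:
                ev_rows.append(
                    dict(cell=cell, channel=channel, time_s=start, amplitude=kin.plateau)
                )
    truth = GroundTruth(events=pd.DataFrame(ev_rows))
    return sets, truth


def _draw_event_times(spec: TraceSimSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.event_times is not None:
        times = np.asarray(spec.event_times, dtype=float)
        if np.any((times < 0) | (times > spec.duration)):
            raise ValueError("event_times must lie within the recording duration")
        return np.sort(times)
    n = rng.poisson(spec.event_rate * spec.duration)
    return np.sort(rng.uniform(0.0, spec.duration, size=n))


def simulate_spontaneous_traces(
    spec: TraceSimSpec,
) -> tuple[dict[str, TraceSet], GroundTruth]:
    """Simulate spontaneous two-channel recordings with coupled events.

    Per cell, a master Poisson event train (rate ``event_rate``) is drawn (or
    taken from ``event_times`` if planted).  Each event appears in both
    channels with probability ``coupling``; otherwise it is assigned to one
    channel at random.  Traces are multiplied by ``exp(-t/bleach_tau)`` and
    Gaussian noise is added last.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(int(round(spec.duration * spec.frame_rate))) / spec.frame_rate
    channels = list(spec.kinetics)
    per_channel = {ch: np.zeros((spec.n_cells, t.size)) for ch in channels}
    ev_rows = []
    for cell in range(spec.n_cells):
        times = _draw_event_times(spec, rng)
        amps = np.clip(
            rng.normal(spec.amplitude_mean, spec.amplitude_sd, size=times.size), 0.0, None
        )
        shared = rng.random(times.size) < spec.coupling
        solo_channel = rng.integers(0, max(len(channels), 1), size=times.size)
        for k, (time, amp) in enumerate(zip(times, amps)):
            targets = channels if shared[k] else [channels[solo_channel[k]]]
            for ch in targets:
                kin = spec.kinetics[ch]
                per_channel[ch][cell] += amp * event_kernel(t - time, kin)
                ev_rows.append(dict(cell=cell, channel=ch, time_s=time, amplitude=amp))
    sets: dict[str, TraceSet] = {}
    bleach = _bleach(t, spec.bleach_tau)
    for ch in channels:
        values = spec.baseline_F * (1.0 + per_channel[ch]) * bleach
        if spec.noise_sd > 0:
            values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
        sets[ch] = TraceSet(values=values, frame_rate=spec.frame_rate, channel=ch)
    truth = GroundTruth(
        events=pd.DataFrame(ev_rows, columns=["cell", "channel", "time_s", "amplitude"])
    )
    return sets, truth


def simulate_dose_response(
    ic50: float,
    hill: float,
    bottom: float,
    top: float,
    doses,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 1,
) -> pd.DataFrame:
    """Dose-response table from a 4PL inhibition curve.

    ``response(d) = bottom + (top - bottom) / (1 + (d/ic50)^hill)`` plus
    optional Gaussian noise; dose 0 yields the top asymptote.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    d = np.asarray(doses, dtype=float)
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(replicates):
        with np.errstate(divide="ignore"):
            resp = bottom + (top - bottom) / (1.0 + np.where(d > 0, (d / ic50) ** hill, 0.0))
        if noise_sd > 0:
            resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
        rows.append(pd.DataFrame({"dose_uM": d, "response": resp}))
    return pd.concat(rows, ignore_index=True)
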