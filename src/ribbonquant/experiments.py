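"""Reference experiments run on synthetic phantoms.

Self-contained, seeded experiments that exercise the whole pipeline at the
study's conditions and score recovery against ground truth.  Used by the
acceptance script and the validation tests.
"""

from __future__ import annotations

import numpy as np

from . import pairing as PR
from . import puncta as P
from . import synthdata as S
from . import traces as T

SPONTANEOUS_FRAME_RATE = 1.0 / 3.0  # Hz -> 300 frames in 900 s
PLANTED_EVENT_TIMES = tuple(50.0 + 90.0 * k for k in range(9))  # 9 events in 900 s


def recovery_spec(seed: int, noisy: bool) -> S.ImagePhantomSpec:
    """Phantom with 50 ground-truth synapses and 10 isolated ribbons.

    The noisy variant applies shot noise at peak SNR 10 (peak intensity 100
    photons at unit gain) plus modest read noise.
    """
    return S.ImagePhantomSpec(
        stack_shape=(24, 256, 256), n_cells=10, ribbons_per_cell=6,
        paired_fraction=50 / 60, n_extrasynaptic=0,
        poisson_gain=(1.0 if noisy else 0.0), gaussian_sd=(2.0 if noisy else 0.0),
        background=(5.0, 5.0), seed=seed,
    )


def segment_channel(stacks, channel: str, min_area: bool = True):
    """Standard per-channel pipeline: background, band-pass (PSD only), segment, filter."""
    bg = P.subtract_background(stacks[channel], radius=50)
    proc = P.bandpass(bg, 6, 20) if channel == "psd" else bg
    _, plist = P.segment_puncta(proc, measure_stack=bg)
    if min_area:
        plist = P.apply_min_area(plist, P.DEFAULT_MIN_AREA[channel])
    return plist


def pairing_recovery(seed: int, noisy: bool) -> dict:
    """Segment + pair a recovery phantom; precision/recall vs ground truth.

    A detected pair is a true positive when its ribbon and PSD centroids each
    identify (by nearest neighbour) the two partners of one ground-truth pair.
    """
    stacks, truth = S.simulate_stack(recovery_spec(seed, noisy))
    ribbons = segment_channel(stacks, "ribbon")
    psds = segment_channel(stacks, "psd")
    pairs, summary = PR.pair_synapses(ribbons, psds)

    gt = truth.puncta.set_index("id")
    gtr = gt[gt.channel == "ribbon"]
    gtp = gt[gt.channel == "psd"]
    gtr_xyz = gtr[["z_um", "y_um", "x_um"]].to_numpy(float)
    gtp_xyz = gtp[["z_um", "y_um", "x_um"]].to_numpy(float)
    rib_pos = {p.id: np.asarray(p.centroid) for p in ribbons}
    psd_pos = {p.id: np.asarray(p.centroid) for p in psds}
    true_pairs = set(zip(truth.pairs.ribbon_id, truth.pairs.psd_id))
    tp = 0
    for pr in pairs:
        rid = gtr.index[np.argmin(np.linalg.norm(gtr_xyz - rib_pos[pr.ribbon_id], axis=1))]
        pid = gtp.index[np.argmin(np.linalg.norm(gtp_xyz - psd_pos[pr.psd_id], axis=1))]
        if (rid, pid) in true_pairs:
            tp += 1
    n_det = len(pairs)
    n_true = len(truth.pairs)
    return {
        "precision": tp / n_det if n_det else 0.0,
        "recall": tp / n_true,
        "n_pairs": n_det,
        "n_true_pairs": n_true,
        "n_unpaired_ribbons": summary.n_unpaired_ribbons,
    }


def spontaneous_spec(seed: int, **kw) -> S.TraceSimSpec:
    base = dict(
        frame_rate=SPONTANEOUS_FRAME_RATE, duration=900.0, stimulus_windows=(),
        n_cells=1, noise_sd=0.0, amplitude_mean=1.0, amplitude_sd=0.0,
        kinetics={"cyto": S.ChannelKinetics(0.06, 3.0)}, seed=seed,
    )
    base.update(kw)
    return S.TraceSimSpec(**base)


def spontaneous_recovery(seed: int) -> dict:
    """Plant 9 high-amplitude events in a 900 s / 0.33 Hz recording; recover
    frequency and magnitude and compare the magnitude with the ground-truth
    suprathreshold integral / 300 frames."""
    spec = spontaneous_spec(seed, event_times=PLANTED_EVENT_TIMES)
    sets, truth = S.simulate_spontaneous_traces(spec)
    ts = sets["cyto"]
    stats = T.spontaneous_stats(ts.values[0], ts.frame_rate)
    # ground-truth magnitude: the planted noise-free dF/F0 signal, thresholded
    kin = spec.kinetics["cyto"]
    sig = np.zeros(ts.n_frames)
    for row in truth.events.itertuples():
        sig += row.amplitude * S.event_kernel(ts.times - row.time_s, kin)
    sig = np.where(sig < 0.10, 0.0, sig)
    return {
        "frequency_hz": stats.frequency,
        "magnitude": stats.magnitude,
        "true_magnitude": float(sig.sum() / ts.n_frames),
        "n_events_true": len(PLANTED_EVENT_TIMES),
    }


def bleach_recovery(seed: int) -> dict:
    """Exponential bleach (tau = 600 s) with 3 planted events: residual
    baseline drift and event-amplitude error after correction."""
    spec = spontaneous_spec(seed, event_times=(150.0, 450.0, 750.0), bleach_tau=600.0)
    sets, _ = S.simulate_spontaneous_traces(spec)
    ts = sets["cyto"]
    corrected, info = T.bleach_correct(ts.values[0], frame_rate=ts.frame_rate)
    baseline = np.percentile(corrected, 15)
    drift = abs(float(corrected[:20].mean() - corrected[-20:].mean())) / baseline
    stats = T.spontaneous_stats(corrected, ts.frame_rate)
    peaks = np.sort(stats.dff[stats.dff > 0])[-3:]
    # the planted events all sample the kernel at the same frame offsets
    kin = spec.kinetics["cyto"]
    offset = (3.0 - 150.0 % 3.0) % 3.0
    true_peak = float(S.event_kernel(np.arange(0.0, 9.0, 3.0) + offset, kin).max())
    amp_err = float(np.abs(peaks - true_peak).max() / true_peak)
    return {"drift": drift, "amplitude_error": amp_err, "tau_fit": info["tau"]}


def ic50_recovery(seed: int) -> dict:
    """4PL fit at the study's doses: noise-free and 20 noisy replicates."""
    doses = [0.0, 0.5, 2.0, 5.0, 10.0]
    clean = S.simulate_dose_response(1.37, 1.0, 0.0, 1.0, doses)
    fit = T.fit_4pl(clean.dose_uM.to_numpy(), clean.response.to_numpy())
    noisy = []
    for rep in range(1, 21):
        df = S.simulate_dose_response(
            1.37, 1.0, 0.0, 1.0, doses, noise_sd=0.02, seed=seed * 1000 + rep
        )
        f = T.fit_4pl(df.dose_uM.to_numpy(), df.response.to_numpy())
        if f.ok:
            noisy.append(f.ic50)
    return {
        "ic50_noise_free": fit.ic50,
        "ic50_noisy_median": float(np.median(noisy)),
        "n_noisy_fits": len(noisy),
    }


def correlation_contract(seed: int) -> dict:
    """Two-channel coupling: r per cell at coupling 1 (noise off) and the
    median |r| at coupling 0 with noise, 180 frames (900 s at 0.2 Hz)."""
    kin = {"a": S.ChannelKinetics(0.06, 4.0), "b": S.ChannelKinetics(0.06, 4.0)}
    coupled = S.TraceSimSpec(
        frame_rate=0.2, duration=900.0, stimulus_windows=(), event_rate=0.02,
        coupling=1.0, noise_sd=0.0, n_cells=6, kinetics=kin, seed=seed,
    )
    sets, _ = S.simulate_spontaneous_traces(coupled)
    r_coupled = np.diag(T.pearson_matrix(sets["a"], sets["b"]))
    uncoupled = S.TraceSimSpec(
        frame_rate=0.2, duration=900.0, stimulus_windows=(), event_rate=0.02,
        coupling=0.0, noise_sd=1.0, n_cells=6, kinetics=kin, seed=seed + 1,
    )
    sets0, _ = S.simulate_spontaneous_traces(uncoupled)
    r0 = np.diag(T.pearson_matrix(sets0["a"], sets0["b"]))
    return {
        "min_coupled_r": float(np.min(r_coupled)),
        "median_abs_uncoupled_r": float(np.median(np.abs(r0))),
        "n_frames": sets0["a"].n_frames,
    }
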