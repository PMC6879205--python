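"""Ribbon--PSD synapse pairing and proximity summaries.

A presynaptic ribbon and a postsynaptic density (PSD) form a complete synapse
when their 3D centroids are closer than the sum of their approximate 2D radii
(radius = sqrt(area / pi) from the max-projection footprint).  Matching is
one-to-one, greedy in ascending distance.  Unpaired ribbon-channel puncta from
an unfiltered segmentation pass are the extrasynaptic Ribeye aggregates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .puncta import Punctum, VolumeStack

__all__ = [
    "SynapsePair",
    "SynapseSummary",
    "pair_radius_threshold",
    "pair_synapses",
    "proximity_summary",
    "roi_channel_intensity",
]


@dataclass(frozen=True)
class SynapsePair:
    ribbon_id: int
    psd_id: int
    distance: float  # um, 3D centroid separation
    threshold: float  # um, radius sum that admitted the pair


@dataclass(frozen=True)
class SynapseSummary:
    n_pairs: int
    n_unpaired_ribbons: int
    n_unpaired_psds: int

    @property
    def n_ribbons(self) -> int:
        return self.n_pairs + self.n_unpaired_ribbons

    @property
    def n_psds(self) -> int:
        return self.n_pairs + self.n_unpaired_psds


def pair_radius_threshold(area_ribbon: float, area_psd: float) -> float:
    """Pairing distance threshold from two projected areas.

    Each punctum is treated as a disc of its projected area; the threshold is
    the sum of the two disc radii:  sqrt(A_ribbon/pi) + sqrt(A_psd/pi).
    """
    if area_ribbon <= 0 or area_psd <= 0:
        raise ValueError("areas must be positive")
    return math.sqrt(area_ribbon / math.pi) + math.sqrt(area_psd / math.pi)


def pair_synapses(
    ribbons: list[Punctum], psds: list[Punctum]
) -> tuple[list[SynapsePair], SynapseSummary]:
    """Match ribbons to PSDs one-to-one by 3D centroid distance.

    Every (ribbon, psd) pair whose Euclidean centroid distance is at most
    the radius-sum threshold for that pair is a candidate; candidates are
    accepted greedily in ascending distance (ties broken by ribbon id then
    psd id), each punctum used at most once.

    Returns the accepted pairs and a count summary; empty inputs yield empty
    pairs with counts reflecting the inputs.
    """
    candidates: list[tuple[float, int, int, float]] = []
    for i, r in enumerate(ribbons):
        rc = np.asarray(r.centroid)
        for j, p in enumerate(psds):
            d = float(np.linalg.norm(rc - np.asarray(p.centroid)))
            thr = pair_radius_threshold(r.area2d, p.area2d)
            if d <= thr:
                candidates.append((d, r.id, p.id, thr, i, j))

    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used_r: set[int] = set()
    used_p: set[int] = set()
    pairs: list[SynapsePair] = []
    for d, rid, pid, thr, i, j in candidates:
        if i in used_r or j in used_p:
            continue
        used_r.add(i)
        used_p.add(j)
        pairs.append(SynapsePair(ribbon_id=rid, psd_id=pid, distance=d, threshold=thr))

    summary = SynapseSummary(
        n_pairs=len(pairs),
        n_unpaired_ribbons=len(ribbons) - len(pairs),
        n_unpaired_psds=len(psds) - len(pairs),
    )
    return pairs, summary


def proximity_summary(distances, cutoff: float = 1.0) -> tuple[int, float]:
    """Percent of distances strictly below ``cutoff`` and their median.

    Returns ``(percent_within, median_within)`` where the percent is rounded
    to the nearest integer and the median is taken over the within-cutoff
    subset only.  Matches the convention of reporting what fraction of
    ribbons have a mitochondrion within 1 um.
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("distances must be non-empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    within = d[d < cutoff]
    percent = int(round(100.0 * within.size / d.size))
    median = float(np.median(within)) if within.size else float("nan")
    return percent, median


def roi_channel_intensity(
    rois: list[Punctum],
    label_volume: np.ndarray,
    stack: VolumeStack,
) -> dict[int, float]:
    """Integrated third-channel intensity inside each ribbon 2D footprint.

    For each ROI punctum, sums the max Z-projection of ``stack`` (e.g. the
    Ca_V_1.3 immunolabel) over the ROI's projected footprint taken from
    ``label_volume``.

    Raises
    ------
    ValueError
        If the label volume and stack shapes disagree, or an ROI id is
        missing from the label volume (named in the message).
    """
    if label_volume.shape != stack.shape:
        raise ValueError(
            f"label volume shape {label_volume.shape} does not match stack {stack.shape}"
        )
    proj = stack.voxels.max(axis=0)
    present = set(int(v) for v in np.unique(label_volume) if v != 0)
    out: dict[int, float] = {}
    for roi in rois:
        if roi.id not in present:
            raise ValueError(f"ROI id {roi.id} not present in label volume")
        fp = (label_volume == roi.id).any(axis=0)
        out[roi.id] = float(proj[fp].sum())
    return out
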