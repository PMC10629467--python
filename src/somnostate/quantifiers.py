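"""Back-fitting and microstate quantifiers: duration, occurrence, GFP.

Grand-mean class maps are fitted back to each epoch: GFP-peak maps get the
class with the highest absolute spatial correlation, and every other sample
inherits the label of its temporally nearest peak. Contiguous same-class
runs form microstate segments; runs touching either epoch edge are
potentially truncated and are discarded from the statistics. Quantifiers
are aggregated per epoch set (interval): mean segment duration (ms), the
frequency of occurrence (appearances per second of analysed signal) and
the mean segment GFP (uV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from somnostate.core import Epoch, EpochSet
from somnostate.microstates import MicrostateSolution, find_gfp_peaks, gfp_curve


class UnlabelableEpoch(Exception):
    """Epoch has no GFP peaks: nothing to back-fit, epoch is skipped."""


@dataclass
class Segment:
    class_index: int
    start: int           # first sample (inclusive)
    stop: int            # last sample (inclusive)
    mean_gfp: float
    truncated: bool

    @property
    def n_samples(self) -> int:
        return self.stop - self.start + 1


@dataclass
class Segmentation:
    labels: np.ndarray
    segments: list[Segment]

    @property
    def retained(self) -> list[Segment]:
        return [s for s in self.segments if not s.truncated]


def backfit(epoch, solution: MicrostateSolution) -> np.ndarray:
    """Per-sample class labels from polarity-blind correlation at GFP peaks.

    Ties between classes break toward the lower class index; samples
    equidistant between two peaks take the earlier peak's label.
    """
    data = epoch.data if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    if solution.n_channels != data.shape[0]:
        raise ValueError("channel count mismatch between epoch and solution")
    peaks = find_gfp_peaks(data)
    if peaks.size == 0:
        raise UnlabelableEpoch("no GFP peaks in epoch")

    peak_maps = data[:, peaks].T
    centred = peak_maps - peak_maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    protos = solution.maps - solution.maps.mean(axis=1, keepdims=True)
    protos = protos / np.linalg.norm(protos, axis=1, keepdims=True)
    corr = np.abs((centred / norms) @ protos.T)
    peak_labels = np.argmax(corr, axis=1)      # argmax takes the lowest index on ties

    # nearest-neighbour interpolation by sample index; earlier peak wins ties
    samples = np.arange(data.shape[1])
    dist = np.abs(samples[:, None] - peaks[None, :])
    nearest = np.argmin(dist, axis=1)          # first minimum = earlier peak
    return peak_labels[nearest]


def segment_and_filter(labels: np.ndarray, epoch) -> Segmentation:
    """Run-length encode labels; flag runs touching either epoch edge as truncated."""
    labels = np.asarray(labels)
    g = gfp_curve(epoch)
    if labels.shape[0] != g.shape[0]:
        raise ValueError("labels do not cover the epoch")
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries - 1, [labels.size - 1]])
    segments = [
        Segment(
            class_index=int(labels[a]),
            start=int(a),
            stop=int(b),
            mean_gfp=float(g[a : b + 1].mean()),
            truncated=(a == 0 or b == labels.size - 1),
        )
        for a, b in zip(starts, stops)
    ]
    return Segmentation(labels=labels, segments=segments)


def compute_quantifiers(
    segmentations: list[Segmentation],
    sampling_rate: float,
    n_classes: int = 4,
    analysed_seconds: float | None = None,
) -> pd.DataFrame:
    """Aggregate per-class quantifiers over the epochs of one set.

    ``analysed_seconds`` defaults to the full labelled duration of all
    epochs (the occurrence denominator deliberately includes the samples of
    discarded truncated segments, keeping the denominator identical across
    classes). A class with no retained segment gets missing duration/GFP —
    not zero, since an unobserved duration is undefined — and occurrence 0.
    """
    if analysed_seconds is None:
        analysed_seconds = sum(s.labels.size for s in segmentations) / sampling_rate
    if analysed_seconds <= 0:
        raise ValueError("no analysed time")
    rows = []
    for c in range(n_classes):
        segs = [seg for s in segmentations for seg in s.retained if seg.class_index == c]
        if segs:
            duration = float(np.mean([seg.n_samples for seg in segs])) * 1000.0 / sampling_rate
            mean_gfp = float(np.mean([seg.mean_gfp for seg in segs]))
        else:
            duration = np.nan
            mean_gfp = np.nan
        rows.append(
            dict(
                class_index=c,
                duration=duration,
                occurrence=len(segs) / analysed_seconds,
                gfp=mean_gfp,
                n_segments=len(segs),
            )
        )
    return pd.DataFrame(rows)


def quantify_set(epoch_set: EpochSet, solution: MicrostateSolution, n_classes: int = 4) -> pd.DataFrame:
    """Back-fit and quantify one interval; returns the per-class table.

    Epochs without GFP peaks are skipped, mirroring how unusable epochs are
    dropped from real recordings.
    """
    segmentations = []
    for epoch in epoch_set.epochs:
        try:
            labels = backfit(epoch, solution)
        except UnlabelableEpoch:
            continue
        segmentations.append(segment_and_filter(labels, epoch))
    if not segmentations:
        raise UnlabelableEpoch(f"no usable epochs in interval of {epoch_set.patient_id}")
    table = compute_quantifiers(
        segmentations, epoch_set.epochs[0].sampling_rate, n_classes=n_classes
    )
    table.insert(0, "patient_id", epoch_set.patient_id)
    table.insert(1, "mean_time", epoch_set.mean_time)
    table.insert(2, "suppression", epoch_set.suppression)
    return table
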