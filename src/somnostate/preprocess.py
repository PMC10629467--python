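"""Preprocessing: band-pass filter, average reference, suppression, intervals.

The analysis band is 2-20 Hz. Filtering is a 4th-order Butterworth band-pass
applied forward-backward (zero phase). Suppression is judged on the filtered
signal as the maximum peak-to-peak amplitude over channels falling below a
10 uV threshold. Epochs are grouped into intervals (epoch sets) of up to 24
epochs of homogeneous suppression status, greedily in time order.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from somnostate.core import Epoch, EpochSet, MultichannelRecording

DEFAULT_BAND = (2.0, 20.0)
SUPPRESSION_THRESHOLD_UV = 10.0
ANALYSIS_SFREQ = 250.0


def _as_array(x) -> np.ndarray:
    if isinstance(x, (MultichannelRecording, Epoch)):
        return x.data
    return np.asarray(x, dtype=float)


def bandpass_filter(recording, low: float = 2.0, high: float = 20.0, order: int = 4):
    """Zero-phase Butterworth band-pass along the time axis.

    Accepts a :class:`MultichannelRecording`, an :class:`Epoch` or a raw
    channels x samples array; returns the same kind of object.
    """
    data = _as_array(recording)
    sfreq = getattr(recording, "sampling_rate", None)
    if sfreq is None:
        raise ValueError("pass a recording/epoch carrying its sampling rate")
    nyq = sfreq / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sfreq, output="sos")
    out = sps.sosfiltfilt(sos, data, axis=-1)
    if isinstance(recording, MultichannelRecording):
        return MultichannelRecording(out, recording.channel_labels, sfreq)
    if isinstance(recording, Epoch):
        return Epoch(out, sfreq, recording.onset_from_induction, recording.suppression)
    return out


def resample(recording: MultichannelRecording, target_sfreq: float = ANALYSIS_SFREQ) -> MultichannelRecording:
    """Polyphase resampling to the analysis rate (anti-aliased)."""
    from fractions import Fraction

    frac = Fraction(target_sfreq / recording.sampling_rate).limit_denominator(1000)
    out = sps.resample_poly(recording.data, frac.numerator, frac.denominator, axis=-1)
    return MultichannelRecording(out, recording.channel_labels, target_sfreq)


def average_reference(epoch):
    """Subtract the per-sample channel mean. Idempotent."""
    data = _as_array(epoch)
    out = data - data.mean(axis=0, keepdims=True)
    if isinstance(epoch, Epoch):
        return Epoch(out, epoch.sampling_rate, epoch.onset_from_induction, epoch.suppression)
    if isinstance(epoch, MultichannelRecording):
        return MultichannelRecording(out, epoch.channel_labels, epoch.sampling_rate)
    return out


def detect_suppression(epoch, threshold: float = SUPPRESSION_THRESHOLD_UV) -> bool:
    """True iff the max over channels of peak-to-peak amplitude is < threshold."""
    data = _as_array(epoch)
    if data.size == 0:
        raise ValueError("empty epoch")
    p2p = data.max(axis=-1) - data.min(axis=-1)
    return bool(p2p.max() < threshold)


def slice_epochs(
    recording: MultichannelRecording,
    onsets_min: list[float],
    epoch_length: float = 2.5,
    induction_min: float = 0.0,
    threshold: float = SUPPRESSION_THRESHOLD_UV,
) -> list[Epoch]:
    """Cut a continuous recording into epochs at the given onsets (minutes).

    Suppression is flagged per epoch from the sliced (already filtered)
    data. Epochs extending past the end of the recording are shortened.
    """
    fs = recording.sampling_rate
    n_len = int(round(epoch_length * fs))
    epochs = []
    for onset in onsets_min:
        start = int(round((onset - induction_min) * 60.0 * fs))
        stop = min(start + n_len, recording.n_samples)
        if stop - start < int(0.2 * fs):
            continue
        data = recording.data[:, start:stop]
        epochs.append(
            Epoch(
                data=data,
                sampling_rate=fs,
                onset_from_induction=onset,
                suppression=detect_suppression(data, threshold),
            )
        )
    return epochs


def assemble_intervals(
    epochs: list[Epoch],
    epochs_per_set: int = 24,
    max_span_min: float = 15.0,
    min_size: int = 2,
    patient_id: str = "",
) -> list[EpochSet]:
    """Group epochs into intervals of homogeneous suppression status.

    Greedy in time order: an open set (one per suppression status) is closed
    when it reaches ``epochs_per_set`` members or when the next epoch of
    that status starts more than ``max_span_min`` minutes after the set's
    first epoch. Sets with fewer than ``min_size`` epochs are dropped —
    statistics on a single epoch are degenerate.
    """
    if not epochs:
        return []
    ordered = sorted(epochs, key=lambda e: e.onset_from_induction)
    open_sets: dict[bool, list[Epoch]] = {False: [], True: []}
    out: list[EpochSet] = []

    def close(status: bool) -> None:
        members = open_sets[status]
        if len(members) >= min_size:
            out.append(EpochSet(epochs=list(members), patient_id=patient_id, suppression=status))
        open_sets[status] = []

    for ep in ordered:
        status = bool(ep.suppression)
        members = open_sets[status]
        if members and (
            len(members) >= epochs_per_set
            or ep.onset_from_induction - members[0].onset_from_induction > max_span_min
        ):
            close(status)
        open_sets[status].append(ep)
    for status in (False, True):
        if open_sets[status]:
            close(status)
    out.sort(key=lambda s: s.mean_time)
    return out


def preprocess_epoch(epoch: Epoch, low: float = 2.0, high: float = 20.0) -> Epoch:
    """Filter to the analysis band, average-reference, and re-flag suppression."""
    filtered = bandpass_filter(epoch, low, high)
    referenced = average_reference(filtered)
    referenced.suppression = detect_suppression(referenced)
    return referenced


def preprocess_set(epoch_set: EpochSet, low: float = 2.0, high: float = 20.0) -> EpochSet:
    """Preprocess every epoch of a set, keeping the set's suppression status."""
    done = []
    for e in epoch_set.epochs:
        f = bandpass_filter(e, low, high)
        f = average_reference(f)
        done.append(f)
    return EpochSet(epochs=done, patient_id=epoch_set.patient_id, suppression=epoch_set.suppression)
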