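"""Shared domain types for the analysis chain."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class SomnostateError(Exception):
    """Base class for package errors."""


class DesignError(SomnostateError):
    """A statistical design is unidentifiable (empty cell, single group...)."""


class DegenerateDataError(SomnostateError):
    """Input carries no usable signal (all-zero epoch, flat map...)."""


@dataclass
class MultichannelRecording:
    """Continuous scalp EEG: a channels x samples potential matrix in microvolts."""

    data: np.ndarray
    channel_labels: tuple[str, ...]
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be channels x samples")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel label count does not match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Epoch:
    """A short analysed EEG segment (canonically 2.5 s).

    ``data`` is channels x samples in microvolts. ``onset_from_induction``
    is the epoch onset in minutes since anaesthesia induction.
    Suppression epochs may be shorter than the canonical length.
    """

    data: np.ndarray
    sampling_rate: float
    onset_from_induction: float
    suppression: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be channels x samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Epoch length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class EpochSet:
    """An interval: up to ``epochs_per_set`` epochs of the same suppression status.

    ``mean_time`` is the arithmetic mean of the member epochs' onsets in
    minutes since induction ('anaesthesia duration' in the trend models).
    """

    epochs: list[Epoch]
    patient_id: str
    suppression: bool

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("an epoch set needs at least one epoch")
        if any(e.suppression != self.suppression for e in self.epochs):
            raise ValueError("mixed suppression status within one epoch set")

    @property
    def mean_time(self) -> float:
        return float(np.mean([e.onset_from_induction for e in self.epochs]))

    @property
    def total_duration(self) -> float:
        """Summed epoch length in seconds."""
        return float(sum(e.duration for e in self.epochs))

    def __len__(self) -> int:
        return len(self.epochs)


@dataclass
class PatientMeta:
    """Per-patient covariates used in the adjusted trend models."""

    patient_id: str
    age: float
    sex: str                # 'female' | 'male'
    mmse_band: str          # '24-27' | '28-29' | '30'
    asa_band: str           # 'I-II' | 'III-IV'
    surgical_site: str      # 'abdomen/thorax' | 'other'
    anaesthetic: str        # 'TIVA' | 'inhalation'
    randomization: str      # 'open' | 'blinded'
    pod: bool = False

    def __post_init__(self) -> None:
        allowed = {
            "sex": {"female", "male"},
            "mmse_band": {"24-27", "28-29", "30"},
            "asa_band": {"I-II", "III-IV"},
            "surgical_site": {"abdomen/thorax", "other"},
            "anaesthetic": {"TIVA", "inhalation"},
            "randomization": {"open", "blinded"},
        }
        for name, values in allowed.items():
            if getattr(self, name) not in values:
                raise ValueError(f"{name}={getattr(self, name)!r} not in {sorted(values)}")
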