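"""Synthetic anaesthesia-EEG cohorts with known ground truth.

The generator emulates the structure of intraoperative multichannel EEG as
analysed downstream: 19-channel, average-referenceable epochs of 2.5 s,
grouped into intervals of up to 24 epochs spaced roughly every 30 min;
microstate-structured topographic dynamics driven by a small set of class
maps; suppression intervals whose peak amplitude stays below the 10 uV
suppression threshold; and group x suppression x time trends injected on
the *generating* parameters (segment duration, amplitude gain, signal-to-
noise ratio, state-occupancy concentration) so that recovery by the
analysis chain is a genuine test.

Within an epoch the signal is a semi-Markov sequence of microstate
segments: segment lengths are gamma-distributed (mean ``mean_state_duration``,
shape ``duration_shape``, truncated at one sample), the active class map is
amplitude-modulated by a carrier oscillation inside the 2-20 Hz analysis
band, and white sensor noise is added at the configured SNR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from somnostate.core import DesignError, Epoch, EpochSet, PatientMeta

#: the four (pod, suppression) cells of the factorial design
CELLS: tuple[tuple[bool, bool], ...] = (
    (False, False), (False, True), (True, False), (True, True),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one epoch / one cohort.

    ``snr`` is the ratio of the template-signal standard deviation to the
    white-noise standard deviation. ``suppression_amplitude`` is the target
    maximum peak-to-peak amplitude (uV) of suppression epochs; it must stay
    below the 10 uV suppression threshold used downstream.
    """

    n_channels: int = 19
    n_classes: int = 4
    sampling_rate: float = 250.0
    epoch_length: float = 2.5
    epochs_per_set: int = 24
    mean_state_duration: float = 100.0   # ms
    duration_shape: float = 2.0          # gamma shape for segment lengths
    carrier_freq: float = 10.0           # Hz
    snr: float = 5.0
    base_amplitude: float = 50.0         # uV scale of the clean signal
    suppression_amplitude: float = 5.0   # uV max peak-to-peak
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_classes <= self.n_channels - 1:
            raise DesignError(
                f"{self.n_classes} average-referenced classes do not fit in "
                f"{self.n_channels} channels (span is n_channels - 1)"
            )
        if self.mean_state_duration <= 0:
            raise ValueError("mean_state_duration must be positive")
        n = self.epoch_length * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_length x sampling_rate must be an integer")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_length * self.sampling_rate))


@dataclass(frozen=True)
class GroupEffects:
    """Per-cell linear drifts of the generating parameters over anaesthesia time.

    Keys are (pod, suppression) tuples. ``duration_slope`` is in
    ms of mean state duration per minute of anaesthesia; ``log_gain_slope``
    and ``log_snr_slope`` are per-minute slopes on the natural log of the
    amplitude gain and of the SNR. Missing cells default to zero.
    ``concentration_slope`` (1/min) drifts the state-occupancy distribution
    toward a single dominant class map, shrinking the effective spatial rank
    of the signal — the generating-parameter counterpart of a declining
    number of uncorrelated processes.
    """

    duration_slope: dict = field(default_factory=dict)
    log_gain_slope: dict = field(default_factory=dict)
    log_snr_slope: dict = field(default_factory=dict)
    concentration_slope: dict = field(default_factory=dict)

    def at(self, which: str, cell: tuple[bool, bool]) -> float:
        return float(getattr(self, which).get(cell, 0.0))

    @staticmethod
    def null() -> "GroupEffects":
        return GroupEffects()


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort."""

    n_patients: int = 20
    pod_fraction: float = 0.29
    intervals_per_patient: int = 6
    suppression_fraction: float = 0.3
    interval_spacing: float = 30.0   # minutes
    group_effects: GroupEffects = field(default_factory=GroupEffects)

    def __post_init__(self) -> None:
        for name in ("pod_fraction", "suppression_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.intervals_per_patient < 2:
            raise DesignError("need >= 2 intervals per patient for a trend")


@dataclass
class GroundTruth:
    """What the generator actually used, for recovery checks."""

    class_maps: np.ndarray                      # (n_classes, n_channels)
    state_sequences: dict                       # (patient, interval, epoch) -> labels
    suppression_flags: dict                     # (patient, interval) -> bool
    group_effects: GroupEffects


@dataclass
class SyntheticCohort:
    patients: list            # list of (PatientMeta, list[EpochSet])
    truth: GroundTruth
    config: SimulationConfig
    spec: CohortSpec


def make_template_maps(n_channels: int, n_classes: int, seed: int) -> np.ndarray:
    """Draw ``n_classes`` average-referenced, unit-norm, mutually orthogonal maps.

    Orthogonality in the average-reference subspace guarantees the pairwise
    spatial correlation bound (|r| = 0) and makes clustering recovery
    well-posed. Raises if the montage cannot span that many maps.
    """
    if not 1 <= n_classes <= n_channels - 1:
        raise DesignError(
            f"cannot place {n_classes} average-referenced maps in "
            f"{n_channels} channels"
        )
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_channels, n_classes))
    g -= g.mean(axis=0, keepdims=True)           # project into AR subspace
    q, r = np.linalg.qr(g)
    q *= np.sign(np.diag(r))                     # deterministic orientation
    maps = q.T
    maps -= maps.mean(axis=1, keepdims=True)     # numerically re-centre
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return maps


def draw_state_sequence(
    n_samples: int,
    sampling_rate: float,
    mean_duration_ms: float,
    shape: float,
    n_classes: int,
    rng: np.random.Generator,
    concentration: float = 0.0,
) -> np.ndarray:
    """Semi-Markov class sequence: gamma segment lengths, no immediate repeats.

    ``concentration`` in [0, 1) tilts the next-state draw toward class 0:
    with that probability the chain (re-)enters the dominant class — which
    may extend its current run — otherwise it moves uniformly to a
    different class. At 0 the chain is the plain no-immediate-repeat walk.
    """
    labels = np.empty(n_samples, dtype=np.int64)
    pos = 0
    current = int(rng.integers(n_classes))
    scale = (mean_duration_ms / 1000.0) / shape
    conc = float(np.clip(concentration, 0.0, 0.95))
    while pos < n_samples:
        seg = max(1, int(round(rng.gamma(shape, scale) * sampling_rate)))
        labels[pos : pos + seg] = current
        pos += seg
        if n_classes > 1:
            if conc > 0.0 and rng.random() < conc:
                current = 0
            else:
                step = int(rng.integers(n_classes - 1))
                current = step if step < current else step + 1
    return labels


def simulate_epoch(
    config: SimulationConfig,
    class_maps: np.ndarray,
    suppression: bool,
    rng: np.random.Generator,
    *,
    onset_from_induction: float = 0.0,
    gain: float = 1.0,
    mean_state_duration: float | None = None,
    snr: float | None = None,
    concentration: float = 0.0,
) -> tuple[Epoch, np.ndarray]:
    """Simulate one epoch; returns the epoch and its generating class sequence.

    Suppression epochs keep the same microstate sequence and are rescaled as
    a whole so the maximum peak-to-peak amplitude across channels equals
    ``config.suppression_amplitude * gain`` (staying below the detection
    threshold); they are also allowed to be shorter than the canonical
    epoch length, as suppression periods in practice often are.
    """
    if class_maps.shape != (config.n_classes, config.n_channels):
        raise ValueError("class_maps shape does not match the configuration")
    mean_ms = config.mean_state_duration if mean_state_duration is None else mean_state_duration
    use_snr = config.snr if snr is None else snr

    n = config.n_samples
    if suppression:
        # suppression epochs are frequently truncated
        n = max(int(round(n * rng.uniform(0.6, 1.0))), int(config.sampling_rate * 0.5))
    labels = draw_state_sequence(
        n, config.sampling_rate, mean_ms, config.duration_shape, config.n_classes, rng,
        concentration=concentration,
    )

    t = np.arange(n) / config.sampling_rate
    # each microstate segment is its own amplitude-modulated wavelet: the
    # carrier phase re-randomizes at topographic transitions, as scalp
    # fields reorganize rather than continue a single global oscillation
    carrier = np.empty(n)
    boundaries = np.concatenate([[0], np.flatnonzero(np.diff(labels)) + 1, [n]])
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        seg_t = np.arange(b - a) / config.sampling_rate
        carrier[a:b] = np.sin(
            2 * np.pi * config.carrier_freq * seg_t + rng.uniform(0, 2 * np.pi)
        )
    envelope = 1.0 + 0.4 * np.sin(2 * np.pi * rng.uniform(0.3, 1.0) * t + rng.uniform(0, 2 * np.pi))
    waveform = config.base_amplitude * carrier * envelope
    clean = class_maps[labels].T * waveform          # (channels, samples)

    signal_sd = float(clean.std())
    noise = rng.normal(0.0, signal_sd / use_snr, size=clean.shape) if np.isfinite(use_snr) else 0.0
    data = gain * (clean + noise)

    if suppression:
        target = config.suppression_amplitude * gain
        p2p = float((data.max(axis=1) - data.min(axis=1)).max())
        if p2p > 0:
            data = data * (target / p2p)

    epoch = Epoch(
        data=data,
        sampling_rate=config.sampling_rate,
        onset_from_induction=onset_from_induction,
        suppression=suppression,
    )
    return epoch, labels


def _draw_meta(pid: str, pod: bool, rng: np.random.Generator) -> PatientMeta:
    """Covariates drawn from distributions matching the study population."""
    return PatientMeta(
        patient_id=pid,
        age=float(np.clip(rng.normal(70.7, 6.5), 60.0, 92.0)),
        sex="female" if rng.random() < 0.40 else "male",
        mmse_band=("24-27", "28-29", "30")[int(rng.choice(3, p=(0.25, 0.40, 0.35)))],
        asa_band="I-II" if rng.random() < 0.48 else "III-IV",
        surgical_site="abdomen/thorax" if rng.random() < 0.34 else "other",
        anaesthetic="TIVA" if rng.random() < 0.36 else "inhalation",
        randomization="open" if rng.random() < 0.5 else "blinded",
        pod=pod,
    )


def simulate_cohort(config: SimulationConfig, spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort; byte-identical for identical seeds.

    POD status is assigned to exactly ``round(pod_fraction * n_patients)``
    randomly chosen patients. Interval mean times are strictly increasing
    within each patient (~``interval_spacing`` apart). Each patient receives
    at least one suppression and one non-suppression interval whenever the
    suppression fraction makes both cells possible, so the factorial design
    stays identifiable.
    """
    root = np.random.default_rng(np.random.SeedSequence(config.seed))
    class_maps = make_template_maps(
        config.n_channels, config.n_classes, seed=int(root.integers(2**31))
    )

    n_pod = int(round(spec.pod_fraction * spec.n_patients))
    pod_flags = np.zeros(spec.n_patients, dtype=bool)
    pod_flags[root.permutation(spec.n_patients)[:n_pod]] = True

    patients = []
    state_sequences: dict = {}
    suppression_flags: dict = {}
    ge = spec.group_effects

    for i in range(spec.n_patients):
        pid = f"P{i:03d}"
        rng = np.random.default_rng(root.integers(2**31))
        meta = _draw_meta(pid, bool(pod_flags[i]), rng)

        m = spec.intervals_per_patient
        supp = rng.random(m) < spec.suppression_fraction
        if 0.0 < spec.suppression_fraction < 1.0:
            if not supp.any():
                supp[int(rng.integers(m))] = True
            if supp.all():
                supp[int(rng.integers(m))] = False

        sets: list[EpochSet] = []
        for j in range(m):
            centre = 15.0 + spec.interval_spacing * j + rng.uniform(-3.0, 3.0)
            cell = (meta.pod, bool(supp[j]))
            mean_ms = max(20.0, config.mean_state_duration + ge.at("duration_slope", cell) * centre)
            gain = float(np.exp(ge.at("log_gain_slope", cell) * centre))
            snr_j = config.snr * float(np.exp(ge.at("log_snr_slope", cell) * centre))
            conc = float(np.clip(ge.at("concentration_slope", cell) * centre, 0.0, 0.95))

            epochs = []
            for k in range(config.epochs_per_set):
                onset = centre + (k - config.epochs_per_set / 2) * config.epoch_length / 60.0
                epoch, seq = simulate_epoch(
                    config, class_maps, bool(supp[j]), rng,
                    onset_from_induction=onset, gain=gain,
                    mean_state_duration=mean_ms, snr=snr_j, concentration=conc,
                )
                epochs.append(epoch)
                state_sequences[(pid, j, k)] = seq
            suppression_flags[(pid, j)] = bool(supp[j])
            sets.append(EpochSet(epochs=epochs, patient_id=pid, suppression=bool(supp[j])))
        patients.append((meta, sets))

    truth = GroundTruth(
        class_maps=class_maps,
        state_sequences=state_sequences,
        suppression_flags=suppression_flags,
        group_effects=ge,
    )
    return SyntheticCohort(patients=patients, truth=truth, config=config, spec=spec)


def cohort_to_disk(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write one EDF file per patient plus ground-truth JSON and a metadata CSV."""
    from somnostate.io import write_edf  # local import to keep synth lightweight

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for meta, sets in cohort.patients:
        data = np.concatenate([e.data for s in sets for e in s.epochs], axis=1)
        write_edf(out / f"{meta.patient_id}.edf", data, cohort.config.sampling_rate)
        rows.append(
            dict(
                patient_id=meta.patient_id, age=round(meta.age, 1), sex=meta.sex,
                mmse_band=meta.mmse_band, asa_band=meta.asa_band,
                surgical_site=meta.surgical_site, anaesthetic=meta.anaesthetic,
                randomization=meta.randomization, pod=int(meta.pod),
            )
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "metadata.csv", index=False)
    sidecar = {
        "class_maps": cohort.truth.class_maps.tolist(),
        "intervals": {
            meta.patient_id: [
                {
                    "mean_time": s.mean_time,
                    "suppression": s.suppression,
                    "epoch_onsets": [e.onset_from_induction for e in s.epochs],
                    "epoch_samples": [e.n_samples for e in s.epochs],
                }
                for s in sets
            ]
            for meta, sets in cohort.patients
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar))


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Convenience: a default configuration with a given seed."""
    return replace(SimulationConfig(seed=seed), **overrides)
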