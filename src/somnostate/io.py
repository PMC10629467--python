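"""File I/O: EDF export/import, HDF5 epoch containers, CSV tables.

Reading EDF goes through MNE. Writing uses a minimal EDF writer implemented
here (ASCII header + 16-bit little-endian data records per the EDF
standard): it supports equal-rate continuous signals, which is all the
synthetic cohort export needs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from somnostate.core import Epoch, MultichannelRecording
from somnostate.montage import CANONICAL_1020, reorder_index


def write_edf(
    path: str | Path,
    data: np.ndarray,
    sampling_rate: float,
    channel_labels: tuple[str, ...] = CANONICAL_1020,
) -> None:
    """Write a channels x samples array (uV) as a standard EDF file.

    Data are stored in 1-second records of 16-bit integers with a symmetric
    physical range; the last record is zero-padded if the signal length is
    not a whole number of records.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    if len(channel_labels) != n_ch:
        raise ValueError("label count does not match channel count")
    spr = int(round(sampling_rate))
    if abs(spr - sampling_rate) > 1e-9:
        raise ValueError("integer sampling rates only")
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data

    absmax = float(np.abs(padded).max())
    absmax = max(absmax, 1e-6)
    phys_min, phys_max = -absmax, absmax
    dig_min, dig_max = -32767, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min) * scale + dig_min).astype("<i2")

    def f(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            f("0", 8), f("X X X X", 80), f("Startdate X X X X", 80),
            f("01.01.00", 8), f("00.00.00", 8),
            f(256 * (1 + n_ch), 8), f("", 44), f(n_rec, 8), f("1", 8), f(n_ch, 4),
        ]
    )
    fields = [
        ("label", 16, channel_labels),
        ("transducer", 80, [""] * n_ch),
        ("dim", 8, ["uV"] * n_ch),
        ("pmin", 8, [f"{phys_min:.6g}"[:8] for _ in range(n_ch)]),
        ("pmax", 8, [f"{phys_max:.6g}"[:8] for _ in range(n_ch)]),
        ("dmin", 8, [str(dig_min)] * n_ch),
        ("dmax", 8, [str(dig_max)] * n_ch),
        ("prefilter", 80, [""] * n_ch),
        ("spr", 8, [str(spr)] * n_ch),
        ("reserved", 32, [""] * n_ch),
    ]
    sig_header = b"".join(
        b"".join(f(v, width) for v in values) for _, width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        # records: for each record, all samples of ch0, then ch1, ...
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path: str | Path, reorder: bool = True) -> MultichannelRecording:
    """Read an EDF recording via MNE, reordered to the canonical 10/20 montage."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE works in volts
    labels = list(raw.ch_names)
    if reorder:
        idx = reorder_index(labels)
        data = data[idx]
        labels = list(CANONICAL_1020)
    return MultichannelRecording(data, tuple(labels), float(raw.info["sfreq"]))


def write_epochs_h5(path: str | Path, epochs: list[Epoch], patient_id: str = "") -> None:
    """Store epoch matrices plus onset/suppression metadata in one HDF5 file."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["patient_id"] = patient_id
        for i, e in enumerate(epochs):
            ds = fh.create_dataset(f"epoch_{i:04d}", data=e.data)
            ds.attrs["sampling_rate"] = e.sampling_rate
            ds.attrs["onset_from_induction"] = e.onset_from_induction
            ds.attrs["suppression"] = e.suppression


def read_epochs_h5(path: str | Path) -> tuple[str, list[Epoch]]:
    import h5py

    epochs = []
    with h5py.File(path, "r") as fh:
        pid = str(fh.attrs.get("patient_id", ""))
        for key in sorted(fh.keys()):
            ds = fh[key]
            epochs.append(
                Epoch(
                    data=ds[()],
                    sampling_rate=float(ds.attrs["sampling_rate"]),
                    onset_from_induction=float(ds.attrs["onset_from_induction"]),
                    suppression=bool(ds.attrs["suppression"]),
                )
            )
    return pid, epochs
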