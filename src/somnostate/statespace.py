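"""Wackermann state space descriptors: sigma, phi, omega.

Each 2.5-s epoch is viewed as a trajectory of the channel vector u(t)
through the k-dimensional sensor space. A spatial principal component
analysis of the channel covariance yields k eigenvalues; the descriptors
are

* sigma — total field variance, the sum of all eigenvalues (uV^2);
* phi   — generalized frequency: the root ratio of derivative power to
          signal power, scaled to Hz (for a multichannel pure sinusoid at
          f Hz it returns f up to discretization error);
* omega — spatial complexity: the antilog of the Shannon entropy of the
          normalized eigenvalue spectrum, a lower-bound estimate of the
          number of uncorrelated generator processes, in [1, k].

The antilog form (not the raw entropy) is what gives omega its stated
1..k range; natural logarithms are used internally, which the antilog
makes immaterial. Eigenvalues below 1e-12 x the largest are clamped to
zero before the entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from somnostate.core import DegenerateDataError, Epoch, EpochSet

EIGENVALUE_CLAMP = 1e-12


@dataclass
class SpatialSpectrum:
    """Eigenvalues (descending, uV^2) and orthonormal eigenvectors of the channel covariance."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns

    @property
    def k(self) -> int:
        return self.eigenvalues.size


def _epoch_data(epoch) -> np.ndarray:
    return epoch.data if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)


def spatial_pca(epoch, allow_degenerate: bool = False) -> SpatialSpectrum:
    """Eigendecomposition of the channel covariance over time.

    Returns exactly k eigenvalue/eigenvector pairs. For average-referenced
    data at least one eigenvalue is ~0 (the reference constraint removes
    one spatial dimension).
    """
    x = _epoch_data(epoch)
    x = x - x.mean(axis=1, keepdims=True)
    if not allow_degenerate and not np.any(x):
        raise DegenerateDataError("all-zero epoch has a degenerate spectrum")
    cov = (x @ x.T) / x.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    return SpatialSpectrum(eigenvalues=vals, eigenvectors=vecs[:, order])


def sigma(spectrum: SpatialSpectrum) -> float:
    """Total variance: sum of all eigenvalues (= trace of the channel covariance)."""
    return float(spectrum.eigenvalues.sum())


def phi(epoch, sampling_rate: float | None = None) -> float:
    """Generalized frequency in Hz of the state space trajectory."""
    x = _epoch_data(epoch)
    if sampling_rate is None:
        if not isinstance(epoch, Epoch):
            raise ValueError("pass sampling_rate for a bare array")
        sampling_rate = epoch.sampling_rate
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    u = x - x.mean(axis=1, keepdims=True)
    power = float(np.sum(u**2))
    if power == 0:
        raise DegenerateDataError("zero-power epoch: phi undefined")
    du = np.diff(u, axis=1) * sampling_rate
    return float(np.sqrt(np.sum(du**2) / power) / (2 * np.pi))


def omega(spectrum: SpatialSpectrum) -> float:
    """Spatial complexity: antilog of the spectral Shannon entropy, in [1, k]."""
    lam = spectrum.eigenvalues.copy()
    if lam.max() <= 0:
        raise DegenerateDataError("all-zero spectrum: omega undefined")
    lam[lam < EIGENVALUE_CLAMP * lam.max()] = 0.0
    p = lam / lam.sum()
    nz = p[p > 0]
    return float(np.exp(-np.sum(nz * np.log(nz))))


def descriptors(epoch, sampling_rate: float | None = None) -> tuple[float, float, float]:
    """(sigma, phi, omega) for one epoch."""
    spec = spatial_pca(epoch)
    return sigma(spec), phi(epoch, sampling_rate), omega(spec)


def average_descriptors(epoch_set: EpochSet) -> pd.Series:
    """Arithmetic mean of sigma, phi, omega over the valid epochs of a set."""
    rows = []
    for e in epoch_set.epochs:
        try:
            rows.append(descriptors(e))
        except DegenerateDataError:
            continue
    if not rows:
        raise DegenerateDataError(f"no valid epochs in interval of {epoch_set.patient_id}")
    arr = np.array(rows)
    return pd.Series(
        {
            "patient_id": epoch_set.patient_id,
            "mean_time": epoch_set.mean_time,
            "suppression": epoch_set.suppression,
            "sigma": arr[:, 0].mean(),
            "phi": arr[:, 1].mean(),
            "omega": arr[:, 2].mean(),
        }
    )
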