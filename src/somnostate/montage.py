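"""Canonical 19-electrode International 10/20 montage.

Channel order is fixed package-wide; recordings read from disk are
reordered by label to match. 2-D positions are schematic top-view
coordinates (x toward the right ear, y toward the nasion, unit head
radius) used for building template topographies — they are not meant
for source analysis.
"""

from __future__ import annotations

import numpy as np

CANONICAL_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: schematic (x, y) positions on the unit disc, same order as CANONICAL_1020
POSITIONS_2D: dict[str, tuple[float, float]] = {
    "Fp1": (-0.309, 0.951), "Fp2": (0.309, 0.951),
    "F7": (-0.809, 0.588), "F3": (-0.425, 0.520), "Fz": (0.0, 0.500),
    "F4": (0.425, 0.520), "F8": (0.809, 0.588),
    "T3": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.809, -0.588), "P3": (-0.425, -0.520), "Pz": (0.0, -0.500),
    "P4": (0.425, -0.520), "T6": (0.809, -0.588),
    "O1": (-0.309, -0.951), "O2": (0.309, -0.951),
}


def positions_array(channels: tuple[str, ...] = CANONICAL_1020) -> np.ndarray:
    """Return an (n_channels, 2) array of schematic positions."""
    return np.array([POSITIONS_2D[ch] for ch in channels], dtype=float)


def reorder_index(labels: list[str]) -> np.ndarray:
    """Index that reorders ``labels`` into the canonical 10/20 order.

    Raises ``KeyError`` if a canonical channel is missing.
    """
    lookup = {lab.lower(): i for i, lab in enumerate(labels)}
    try:
        return np.array([lookup[ch.lower()] for ch in CANONICAL_1020])
    except KeyError as err:  # pragma: no cover - message clarity only
        raise KeyError(f"channel {err} required by the canonical montage") from None
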