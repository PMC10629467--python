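"""Synthetic approximations of the canonical microstate class maps A-D.

The published normative maps are not redistributed here. Instead the four
classes are rebuilt from their well-known qualitative geometry on a
schematic 10/20 layout:

* class A — diagonal gradient from left-posterior to right-frontal,
* class B — mirror diagonal, right-posterior to left-frontal,
* class C — symmetric anterior-negative / posterior-positive gradient,
* class D — fronto-central maximum against the periphery.

Each map is average-referenced and normalized to unit Euclidean norm, so it
can serve as a labelling template for any solution on the same montage.
These are synthetic stand-ins adequate for label assignment and testing,
not normative data.
"""

from __future__ import annotations

import numpy as np

from somnostate.montage import CANONICAL_1020, positions_array

TEMPLATE_LABELS: tuple[str, ...] = ("A", "B", "C", "D")


def _finalize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    return v / np.linalg.norm(v)


def canonical_templates(channels: tuple[str, ...] = CANONICAL_1020) -> np.ndarray:
    """Return a (4, n_channels) array of unit-norm template maps A-D."""
    pos = positions_array(channels)
    x, y = pos[:, 0], pos[:, 1]
    xs = _finalize(x)
    ys = _finalize(y)
    a = _finalize(0.85 * xs + 0.53 * ys)                 # LP- / RF+ diagonal
    b = _finalize(-0.85 * xs + 0.53 * ys)                # RP- / LF+ diagonal
    c = -ys                                              # frontal- / occipital+
    d = _finalize(np.exp(-((x**2 + (y - 0.2) ** 2) / 0.45)))  # fronto-central hill
    return np.vstack([a, b, c, d])
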