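"""Microstate topography analysis: GFP, polarity-blind clustering, labelling.

Global field power (GFP) is the spatial standard deviation of an
average-referenced map. Momentary GFP maxima index the time points of
maximal topographic signal-to-noise; the maps at these peaks are clustered
by a modified k-means that ignores map polarity, the classic formulation in
which the class update is the leading eigenvector of the outer-product sum
of its assigned maps. Group and grand mean maps are built hierarchically
with permutation/polarity alignment, and classes are labelled A-D against
normative-style templates by exhaustive permutation search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from somnostate.core import DegenerateDataError, Epoch

__all__ = [
    "MicrostateSolution",
    "gfp",
    "gfp_curve",
    "find_gfp_peaks",
    "modified_kmeans",
    "explained_variance",
    "align_and_average",
    "label_by_template",
    "spatial_correlation",
]


@dataclass
class MicrostateSolution:
    """A set of unit-norm class maps with fit diagnostics.

    ``maps`` is (n_classes, n_channels). ``labels`` is None until the
    solution has been labelled against templates.
    """

    maps: np.ndarray
    explained_variance: float = np.nan
    labels: tuple[str, ...] | None = None
    template_correlations: np.ndarray | None = None
    degenerate: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_classes(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


def gfp(values: np.ndarray) -> float:
    """Spatial standard deviation of one average-referenced map."""
    v = np.asarray(values, dtype=float)
    return float(np.sqrt(np.mean(v**2)))


def gfp_curve(epoch) -> np.ndarray:
    """Per-sample GFP of a channels x samples array or Epoch."""
    data = epoch.data if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    return np.sqrt(np.mean(data**2, axis=0))


def find_gfp_peaks(epoch) -> np.ndarray:
    """Indices of strict local maxima of the GFP series (interior samples only)."""
    g = gfp_curve(epoch) if not (isinstance(epoch, np.ndarray) and epoch.ndim == 1) else epoch
    if g.size < 3:
        raise ValueError("need at least 3 samples")
    interior = (g[1:-1] > g[:-2]) & (g[1:-1] > g[2:])
    return np.flatnonzero(interior) + 1


def _normalize_rows(maps: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


def _principal_map(maps: np.ndarray) -> np.ndarray:
    """Leading right singular vector of a stack of maps (polarity-safe mean)."""
    _, _, vt = np.linalg.svd(maps, full_matrices=False)
    v = vt[0]
    # orient along the majority polarity of the contributing maps
    if (maps @ v).sum() < 0:
        v = -v
    return v


def modified_kmeans(
    maps: np.ndarray,
    n_classes: int = 4,
    restarts: int = 20,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = None,
) -> MicrostateSolution:
    """Polarity-blind modified k-means over GFP-peak maps.

    Maps are GFP-normalized before clustering so high-amplitude epochs do
    not dominate. Assignment maximizes squared spatial correlation to the
    class map; the update is the first principal eigenvector of the
    assigned maps. The best of ``restarts`` seeded restarts (by explained
    variance) is returned. Classes that end up empty are flagged degenerate.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < n_classes:
        raise ValueError(f"need at least {n_classes} maps to cluster")
    maps = maps - maps.mean(axis=1, keepdims=True)
    normed = _normalize_rows(maps)
    n = normed.shape[0]
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(restarts):
        protos = normed[rng.choice(n, n_classes, replace=False)].copy()
        prev_ev = -np.inf
        assign = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            corr = normed @ protos.T
            new_assign = np.argmax(corr**2, axis=1)
            for c in range(n_classes):
                members = normed[new_assign == c]
                if len(members):
                    protos[c] = _principal_map(members)
                else:  # re-seed an empty class
                    protos[c] = normed[rng.integers(n)]
            ev = float(np.mean(np.max((normed @ protos.T) ** 2, axis=1)))
            if np.array_equal(new_assign, assign) or ev - prev_ev < tol:
                assign = new_assign
                break
            assign, prev_ev = new_assign, ev
        ev = float(np.mean(np.max((normed @ protos.T) ** 2, axis=1)))
        if best is None or ev > best[0]:
            best = (ev, protos.copy(), assign.copy())

    ev, protos, assign = best
    counts = np.bincount(assign, minlength=n_classes)
    return MicrostateSolution(
        maps=_normalize_rows(protos),
        explained_variance=ev,
        degenerate=counts == 0,
    )


def explained_variance(solution: MicrostateSolution, maps: np.ndarray) -> float:
    """Fraction of squared map norm captured by polarity-blind projection."""
    maps = np.asarray(maps, dtype=float)
    maps = maps - maps.mean(axis=1, keepdims=True)
    total = float(np.sum(maps**2))
    if total == 0:
        raise DegenerateDataError("all maps are flat")
    protos = _normalize_rows(solution.maps)
    proj = maps @ protos.T                     # (n, n_classes)
    captured = float(np.sum(np.max(proj**2, axis=1)))
    return captured / total


def spatial_correlation(map1: np.ndarray, map2: np.ndarray, ignore_polarity: bool = False) -> float:
    """Pearson correlation across channels of two maps."""
    a = np.asarray(map1, dtype=float) - np.mean(map1)
    b = np.asarray(map2, dtype=float) - np.mean(map2)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateDataError("zero-variance map has no defined correlation")
    r = float(a @ b / (na * nb))
    return abs(r) if ignore_polarity else r


class IntervalExcluded(Exception):
    """Raised when an averaging step has fewer datasets than required."""


def _best_permutation(maps: np.ndarray, reference: np.ndarray) -> tuple[tuple[int, ...], np.ndarray]:
    """Class permutation and per-class signs maximizing shared variance.

    Exhaustive over all n! permutations (24 for four classes); for each
    candidate pairing the polarity sign is chosen optimally, so the search
    is exact for the polarity-blind criterion.
    """
    k = maps.shape[0]
    corr = _normalize_rows(maps) @ _normalize_rows(reference).T  # (k, k)
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        score = sum(corr[perm[c], c] ** 2 for c in range(k))
        if score > best_score + 1e-12:
            best_perm, best_score = perm, score
    signs = np.array([np.sign(corr[best_perm[c], c]) or 1.0 for c in range(k)])
    return best_perm, signs


def align_and_average(
    solutions: list[MicrostateSolution],
    min_datasets: int = 2,
    n_sweeps: int = 10,
) -> MicrostateSolution:
    """Average class maps across datasets, maximizing within-class shared variance.

    For every input solution a class permutation and a polarity sign are
    chosen to best match the running mean; mean maps are recomputed as
    principal eigenvectors (polarity-safe) and the alignment is iterated
    until stable. Raises :class:`IntervalExcluded` below ``min_datasets``.
    """
    if len(solutions) < min_datasets:
        raise IntervalExcluded(
            f"{len(solutions)} datasets < required {min_datasets}; interval dropped"
        )
    k = solutions[0].n_classes
    if any(s.n_classes != k or s.n_channels != solutions[0].n_channels for s in solutions):
        raise ValueError("solutions differ in shape")

    reference = solutions[0].maps.copy()
    aligned = [s.maps.copy() for s in solutions]
    for _ in range(n_sweeps):
        changed = False
        for i, s in enumerate(solutions):
            perm, signs = _best_permutation(s.maps, reference)
            new = s.maps[list(perm)] * signs[:, None]
            if not np.allclose(new, aligned[i]):
                changed = True
            aligned[i] = new
        stacked = np.stack(aligned)                       # (n, k, ch)
        reference = np.stack([_principal_map(stacked[:, c]) for c in range(k)])
        if not changed:
            break
    mean_maps = _normalize_rows(reference - reference.mean(axis=1, keepdims=True))
    ev = float(
        np.mean([
            np.mean([spatial_correlation(a[c], mean_maps[c], ignore_polarity=True) ** 2
                     for c in range(k)])
            for a in aligned
        ])
    )
    return MicrostateSolution(maps=mean_maps, explained_variance=ev)


def label_by_template(
    solution: MicrostateSolution,
    templates: np.ndarray,
    template_labels: tuple[str, ...] = ("A", "B", "C", "D"),
) -> MicrostateSolution:
    """Label classes by exhaustive one-to-one matching against templates.

    The permutation maximizing the summed absolute spatial correlation wins;
    ties break deterministically toward lexicographic label order (the first
    permutation enumerated). The returned solution has its maps reordered to
    template order with per-class |r| stored.
    """
    templates = np.asarray(templates, dtype=float)
    if templates.shape[1] != solution.n_channels:
        raise ValueError("template channel count does not match solution")
    k = solution.n_classes
    if templates.shape[0] != k:
        raise ValueError("need one template per class")
    corr = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            corr[i, j] = spatial_correlation(solution.maps[i], templates[j], ignore_polarity=True)
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        # perm[j] = index of the solution map assigned to template j
        score = sum(corr[perm[j], j] for j in range(k))
        if score > best_score + 1e-12:
            best_perm, best_score = perm, score
    order = list(best_perm)
    return MicrostateSolution(
        maps=solution.maps[order],
        explained_variance=solution.explained_variance,
        labels=tuple(template_labels[:k]),
        template_correlations=np.array([corr[order[j], j] for j in range(k)]),
    )


def epoch_peak_maps(epoch) -> np.ndarray:
    """Maps at GFP peaks of one epoch, as a (n_peaks, n_channels) array."""
    data = epoch.data if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    peaks = find_gfp_peaks(data)
    return data[:, peaks].T
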