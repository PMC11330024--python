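"""Quantitative summaries of simulated pigmentation patterns.

The published claims about patterns are visual — spot size grows with the
activation drive, spots fuse when degradation drops, activator and
inhibitor peak in the same places, each spot decays from its center.  This
module turns those claims into numbers: strict thresholding at the
visualization level (2 uM by default), connected-component spot labeling
aware of the periodic domain, a fusion index (largest spot / total colored
area), Pearson correlation of the two fields for the in-phase check, and a
ring-wise radial-decay score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "SpotSet",
    "PatternSummary",
    "threshold_mask",
    "relative_threshold",
    "label_spots",
    "pattern_summary",
    "radial_decay_check",
]


@dataclass
class SpotSet:
    """Connected above-threshold components ("spots") of a field.

    label_map : (n, n) int array, 0 = background, labels 1..n_spots.
    areas : cells per spot, indexed label-1.
    centroids : (row, col) mean position per spot (not periodic-aware;
        informational only).
    peaks : per-spot (max_A, (row, col) of the argmax); None if no
        intensity field was supplied.
    """

    label_map: np.ndarray
    areas: np.ndarray
    centroids: list
    peaks: Optional[list] = None

    @property
    def n_spots(self) -> int:
        return len(self.areas)


@dataclass
class PatternSummary:
    """Scalar pattern metrics of one final field pair."""

    n_spots: int
    area_fraction: float
    mean_area: float
    max_area: float
    fusion_index: Optional[float]   # largest spot / total colored area; None if empty
    ah_correlation: float

    def to_dict(self) -> dict:
        return {
            "n_spots": self.n_spots,
            "area_fraction": self.area_fraction,
            "mean_area": self.mean_area,
            "max_area": self.max_area,
            "fusion_index": self.fusion_index,
            "ah_correlation": self.ah_correlation,
        }


def threshold_mask(A: np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask of cells strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return (np.asarray(A) > threshold).astype(int)


def relative_threshold(
    A: np.ndarray, GA_whi: float, GA_pur: float, basic: float = 2.0
) -> float:
    """Deep-layer threshold for piece-wise G_A runs.

    Defined as the GA_whi/GA_pur proportion of the maximum activator
    level, clamped from below at the basic threshold so the deep layer
    always sits above the basic coloring layer.
    """
    A = np.asarray(A)
    if A.size == 0:
        raise ValueError("empty field")
    if not GA_pur > GA_whi > 0:
        raise ValueError(f"need GA_pur > GA_whi > 0, got {GA_pur}, {GA_whi}")
    return max(basic, (GA_whi / GA_pur) * float(A.max()))


def _merge_labels_periodic(labels: np.ndarray, connectivity: int) -> np.ndarray:
    """Union labels that touch across opposite grid edges (torus seams).

    8-connectivity also merges diagonal contacts across the seams,
    including the corner wrap.
    """
    n_labels = labels.max()
    parent = np.arange(n_labels + 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    shifts = [0] if connectivity == 4 else [-1, 0, 1]
    n_cols = labels.shape[1]
    n_rows = labels.shape[0]
    for j in range(n_cols):
        for s in shifts:
            a, b = labels[-1, j], labels[0, (j + s) % n_cols]
            if a and b:
                union(a, b)
    for i in range(n_rows):
        for s in shifts:
            a, b = labels[i, -1], labels[(i + s) % n_rows, 0]
            if a and b:
                union(a, b)
    roots = np.array([find(x) for x in range(n_labels + 1)])
    # Relabel contiguously 1..n.
    uniq = np.unique(roots[1:]) if n_labels else np.array([], dtype=int)
    remap = np.zeros(n_labels + 1, dtype=int)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    return remap[roots[labels]]


def label_spots(
    mask: np.ndarray,
    connectivity: int = 4,
    periodic: bool = True,
    A: Optional[np.ndarray] = None,
) -> SpotSet:
    """Label connected above-threshold components.

    connectivity : 4 (edge neighbors, default) or 8 (include diagonals).
    periodic : merge components touching across opposite grid edges
        (torus topology, matching the solver's boundary condition); with
        8-connectivity diagonal seam contacts merge too.
    A : optional intensity field used to record per-spot peaks.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("label_spots expects a binary 0/1 mask")
    if connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    elif connectivity == 8:
        structure = ndimage.generate_binary_structure(2, 2)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, _ = ndimage.label(mask, structure=structure)
    if periodic and labels.max() > 0:
        labels = _merge_labels_periodic(labels, connectivity)
    n = int(labels.max())
    areas = np.array(
        ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1)),
        dtype=int,
    ) if n else np.array([], dtype=int)
    centroids = ndimage.center_of_mass(mask, labels, range(1, n + 1)) if n else []
    peaks = None
    if A is not None and n:
        A = np.asarray(A)
        peaks = []
        for lab in range(1, n + 1):
            inside = np.where(labels == lab)
            i_best = int(np.argmax(A[inside]))
            loc = (int(inside[0][i_best]), int(inside[1][i_best]))
            peaks.append((float(A[loc]), loc))
    return SpotSet(label_map=labels, areas=areas, centroids=centroids, peaks=peaks)


def pattern_summary(
    A: np.ndarray,
    H: np.ndarray,
    threshold: float = 2.0,
    periodic: bool = True,
    connectivity: int = 4,
) -> PatternSummary:
    """Threshold, label and summarize a final field pair."""
    A = np.asarray(A, dtype=float)
    H = np.asarray(H, dtype=float)
    if A.shape != H.shape:
        raise ValueError(f"shape mismatch: A {A.shape} vs H {H.shape}")
    mask = threshold_mask(A, threshold)
    spots = label_spots(mask, connectivity=connectivity, periodic=periodic, A=A)
    total = int(mask.sum())
    area_fraction = total / mask.size
    if spots.n_spots:
        mean_area = float(np.mean(spots.areas))
        max_area = float(np.max(spots.areas))
        fusion = max_area / total
    else:
        mean_area = 0.0
        max_area = 0.0
        fusion = None
    a, h = A.ravel(), H.ravel()
    if np.std(a) == 0 or np.std(h) == 0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(a, h)[0, 1])
    return PatternSummary(
        n_spots=spots.n_spots,
        area_fraction=area_fraction,
        mean_area=mean_area,
        max_area=max_area,
        fusion_index=fusion,
        ah_correlation=corr,
    )


def radial_decay_check(
    A: np.ndarray, spots: SpotSet, periodic: bool = True
) -> tuple[float, list[float]]:
    """Score how monotonically each spot decays away from its peak.

    For every spot, cells are binned by their (torus) distance from the
    peak cell rounded to the nearest integer ring; the score is the
    fraction of consecutive ring pairs whose mean activator level does not
    increase (ties count as non-increasing).  Returns the median score
    over spots plus per-spot scores.  Spots too small to form two rings
    score 1.0.
    """
    if spots.peaks is None:
        raise ValueError("SpotSet has no peaks; label with the A field")
    A = np.asarray(A, dtype=float)
    n_rows, n_cols = A.shape
    scores: list[float] = []
    for lab in range(1, spots.n_spots + 1):
        _, (pr, pc) = spots.peaks[lab - 1]
        rows, cols = np.where(spots.label_map == lab)
        dr = np.abs(rows - pr)
        dc = np.abs(cols - pc)
        if periodic:
            dr = np.minimum(dr, n_rows - dr)
            dc = np.minimum(dc, n_cols - dc)
        rings = np.rint(np.hypot(dr, dc)).astype(int)
        means = [A[rows[rings == r], cols[rings == r]].mean()
                 for r in range(rings.max() + 1) if np.any(rings == r)]
        if len(means) < 2:
            scores.append(1.0)
            continue
        pairs = len(means) - 1
        ok = sum(1 for a, b in zip(means, means[1:]) if b <= a + 1e-12)
        scores.append(ok / pairs)
    median = float(np.median(scores)) if scores else float("nan")
    return median, scores
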