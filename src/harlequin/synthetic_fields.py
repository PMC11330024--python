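"""Stochastic inputs of the analysis: initial conditions and G_A masks.

The study has no external raw data; its only stochastic ingredients are
(1) the random initial activator field — i.i.d. uniform on [0, 1] per grid
point, with the inhibitor starting at zero — and (2) binary masks marking
where the enhancing solo-LTR (1) versus the repressive full-length
retrotransposon (0) sits for the heterogeneous-G_A scenario.  The published
mask is shown only pictorially, so several generators are offered as
stand-ins plus CSV file input.

All generators are pure functions of (grid, parameters, seed).  Randomness
uses numpy's PCG64 (``np.random.default_rng``); seeds are portable across
platforms and releases.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

__all__ = [
    "random_initial_A",
    "zero_initial_H",
    "make_mask",
    "read_mask",
    "write_mask",
]


def random_initial_A(grid, seed: int) -> np.ndarray:
    """Initial activator field: i.i.d. uniform on [0, 1] per grid point."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(grid.n, grid.n))


def zero_initial_H(grid) -> np.ndarray:
    """Initial inhibitor field: all zeros (its synthesis needs the activator)."""
    return np.zeros((grid.n, grid.n))


def make_mask(
    grid,
    kind: str = "blobs",
    seed: int = 0,
    p: float = 0.5,
    target_fraction: float = 0.5,
    smoothing: float = 4.0,
    blocks: Optional[Sequence[tuple[int, int, int, int]]] = None,
    path: Optional[Union[str, Path]] = None,
) -> np.ndarray:
    """Generate (or load) a binary (n, n) mask.

    Kinds
    -----
    bernoulli : independent cells, P(cell = 1) = ``p``.
    blocks : union of axis-aligned rectangles ``(row0, col0, height, width)``.
    blobs : spatially contiguous patches covering ~``target_fraction`` of
        the grid — seeded white noise smoothed with a periodic Gaussian
        filter of width ``smoothing`` and thresholded at the empirical
        (1 - target_fraction) quantile, so the covered fraction is exact
        up to quantile ties.
    from_file : 0/1 integer CSV at ``path``.
    """
    shape = (grid.n, grid.n)
    if kind == "bernoulli":
        if not 0 <= p <= 1:
            raise ValueError(f"p must be in [0, 1], got {p}")
        rng = np.random.default_rng(seed)
        return (rng.random(shape) < p).astype(int)
    if kind == "blocks":
        if not blocks:
            raise ValueError("blocks kind needs a non-empty rectangle list")
        mask = np.zeros(shape, dtype=int)
        for r0, c0, h, w in blocks:
            mask[r0:r0 + h, c0:c0 + w] = 1
        return mask
    if kind == "blobs":
        if not 0 < target_fraction < 1:
            raise ValueError(
                f"target_fraction must be in (0, 1), got {target_fraction}"
            )
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(noise, sigma=smoothing, mode="wrap")
        cutoff = np.quantile(smooth, 1.0 - target_fraction)
        return (smooth > cutoff).astype(int)
    if kind == "from_file":
        if path is None:
            raise ValueError("from_file kind needs a path")
        return read_mask(path)
    raise ValueError(f"unknown mask kind {kind!r}")


def read_mask(path: Union[str, Path]) -> np.ndarray:
    """Read a 0/1 integer CSV mask (row-major, matching grid convention)."""
    try:
        mask = np.loadtxt(path, delimiter=",", dtype=float)
    except OSError as exc:
        raise ValueError(f"cannot read mask file {path}: {exc}") from exc
    mask = np.atleast_2d(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError(f"mask file {path} contains non-binary values")
    return mask.astype(int)


def write_mask(mask: np.ndarray, path: Union[str, Path]) -> None:
    """Write a binary mask as a 0/1 integer CSV (round-trips byte-exactly)."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    np.savetxt(path, mask.astype(int), fmt="%d", delimiter=",")
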