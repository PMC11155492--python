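"""Spectral photon-counting CT forward model.

A parallel-beam scanner measures photon counts in energy windows along
rays through a 2-D material-fraction image x (nk pixels, nm materials).
The chain is

    y = P x                 per-ray material path lengths (cm), P from
                            exact Siddon ray-pixel intersection lengths
    mean_{w,l} = sum_i S_{wli} exp(-sum_m mu_{mi} y_{lm})
                            expected window counts under the beam
                            spectrum S and attenuation table mu
    C_{w,l} ~ Poisson(mean_{w,l})   independent across windows and rays.

Geometry conventions: image centered at the origin, pixels indexed
row-major 0-based with the material index fastest in any vectorized view;
ray offsets are measured perpendicular to the ray direction, with the
detector extent equal to the image diagonal so every ray family covers
the full support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ImageGrid",
    "ScanGeometry",
    "SpectralModel",
    "AttenuationTable",
    "build_projection_matrix",
    "chord_length",
    "forward_project",
    "path_exponents",
    "window_intensities",
    "expected_counts",
    "simulate_counts",
]

MIN_INTERSECTION_CM = 1e-12  # drop shorter segments as numerical noise


@dataclass(frozen=True)
class ImageGrid:
    """Square pixel grid of physical side ``side_cm`` centered at the origin."""

    nx: int
    ny: int
    side_cm: float = 10.0

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1 or not self.side_cm > 0:
            raise ValueError("invalid image grid")

    @property
    def nk(self) -> int:
        return self.nx * self.ny

    @property
    def pixel_size(self) -> float:
        return self.side_cm / self.nx

    @property
    def pixel_size_y(self) -> float:
        return self.side_cm / self.ny

    def pixel_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of all pixel centers, row-major order."""
        half = self.side_cm / 2.0
        cx = -half + self.pixel_size * (np.arange(self.nx) + 0.5)
        cy = -half + self.pixel_size_y * (np.arange(self.ny) + 0.5)
        ys, xs = np.meshgrid(cy, cx, indexing="ij")
        return xs.ravel(), ys.ravel()


@dataclass(frozen=True)
class ScanGeometry:
    """Parallel-beam scan: evenly spaced angles over [0, 2pi), uniform cells.

    Each ray is parameterized by (angle theta, lateral offset): direction
    ``(cos t, sin t)`` passing through ``offset * (-sin t, cos t)``. Cell
    offsets are the ``n_cells`` midpoints of a detector whose extent
    equals the image diagonal. Rays are indexed angle-major:
    ``l = angle_index * n_cells + cell_index``.
    """

    n_angles: int
    n_cells: int
    grid: ImageGrid

    def __post_init__(self):
        if self.n_angles < 1 or self.n_cells < 1:
            raise ValueError("degenerate scan geometry")

    @property
    def nl(self) -> int:
        return self.n_angles * self.n_cells

    @property
    def angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_angles) / self.n_angles

    @property
    def detector_extent(self) -> float:
        return self.grid.side_cm * np.sqrt(2.0)

    @property
    def offsets(self) -> np.ndarray:
        ext = self.detector_extent
        return ((np.arange(self.n_cells) + 0.5) / self.n_cells - 0.5) * ext

    def rays(self) -> np.ndarray:
        """(nl, 2) array of (theta, offset) pairs, angle-major."""
        th = np.repeat(self.angles, self.n_cells)
        off = np.tile(self.offsets, self.n_angles)
        return np.column_stack([th, off])


@dataclass
class SpectralModel:
    """Incident photon counts per window per energy bin, shared across rays.

    ``S_wi[w, i]`` is the beam density at energy ``energies[i]`` times the
    probability that such a photon is detected in window ``w``; summing
    over windows recovers the beam density, and the grand total is the
    photon budget per ray. ``ray_sensitivity`` (optional, default 1)
    multiplies the spectrum per ray.
    """

    energies: np.ndarray
    S_wi: np.ndarray
    ray_sensitivity: Optional[np.ndarray] = None

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.S_wi = np.asarray(self.S_wi, dtype=float)
        if self.S_wi.ndim != 2 or self.S_wi.shape[1] != self.energies.shape[0]:
            raise ValueError("S_wi must have shape (nw, ni) matching energies")
        if np.any(self.S_wi < 0):
            raise ValueError("S_wi must be nonnegative")

    @property
    def nw(self) -> int:
        return self.S_wi.shape[0]

    @property
    def ni(self) -> int:
        return self.S_wi.shape[1]

    @property
    def total_photons(self) -> float:
        return float(self.S_wi.sum())

    @property
    def beam_density(self) -> np.ndarray:
        return self.S_wi.sum(axis=0)


@dataclass
class AttenuationTable:
    """Linear attenuation coefficients (1/cm) per material per energy."""

    mu: np.ndarray
    energies: np.ndarray
    materials: Tuple[str, ...] = ()

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.mu.ndim != 2 or self.mu.shape[1] != self.energies.shape[0]:
            raise ValueError("mu must have shape (nm, ni) matching energies")
        if np.any(self.mu < 0) or not np.all(np.isfinite(self.mu)):
            raise ValueError("mu must be nonnegative and finite")

    @property
    def nm(self) -> int:
        return self.mu.shape[0]


# ---------------------------------------------------------------------------
# Siddon projection matrix
# ---------------------------------------------------------------------------


def _square_entry_exit(ox, oy, dx, dy, half):
    """Parameter interval of the ray inside [-half, half]^2, or None."""
    smin, smax = -np.inf, np.inf
    for o, d in ((ox, dx), (oy, dy)):
        if abs(d) < 1e-15:
            if abs(o) > half:
                return None
        else:
            s1 = (-half - o) / d
            s2 = (half - o) / d
            if s1 > s2:
                s1, s2 = s2, s1
            smin = max(smin, s1)
            smax = min(smax, s2)
    if smax <= smin:
        return None
    return smin, smax


def chord_length(theta: float, offset: float, side_cm: float) -> float:
    """Length of the ray's chord through the square image support (cm)."""
    dx, dy = np.cos(theta), np.sin(theta)
    ox, oy = -offset * dy, offset * dx
    seg = _square_entry_exit(ox, oy, dx, dy, side_cm / 2.0)
    return 0.0 if seg is None else seg[1] - seg[0]


def build_projection_matrix(grid: ImageGrid, geom: ScanGeometry) -> sp.csr_matrix:
    """Exact ray-pixel intersection lengths as a sparse (nl, nk) matrix.

    Siddon-style: for each ray, the crossing parameters with all vertical
    and horizontal grid lines are merged and sorted; each consecutive
    parameter pair is one pixel traversal whose midpoint identifies the
    pixel and whose parameter gap (times the unit direction) is the
    intersection length in cm. Deterministic; entries below 1e-12 cm are
    dropped.
    """
    half = grid.side_cm / 2.0
    px, py = grid.pixel_size, grid.pixel_size_y
    xlines = -half + px * np.arange(grid.nx + 1)
    ylines = -half + py * np.arange(grid.ny + 1)
    rows, cols, vals = [], [], []
    for l, (theta, offset) in enumerate(geom.rays()):
        dx, dy = np.cos(theta), np.sin(theta)
        ox, oy = -offset * dy, offset * dx
        seg = _square_entry_exit(ox, oy, dx, dy, half)
        if seg is None:
            continue
        smin, smax = seg
        crossings = [np.array([smin, smax])]
        if abs(dx) > 1e-15:
            s = (xlines - ox) / dx
            crossings.append(s[(s > smin) & (s < smax)])
        if abs(dy) > 1e-15:
            s = (ylines - oy) / dy
            crossings.append(s[(s > smin) & (s < smax)])
        s_all = np.unique(np.concatenate(crossings))
        lengths = np.diff(s_all)
        mids = 0.5 * (s_all[:-1] + s_all[1:])
        xm = ox + mids * dx
        ym = oy + mids * dy
        ci = np.clip(((xm + half) / px).astype(int), 0, grid.nx - 1)
        ri = np.clip(((ym + half) / py).astype(int), 0, grid.ny - 1)
        keep = lengths > MIN_INTERSECTION_CM
        k = ri[keep] * grid.nx + ci[keep]
        rows.extend([l] * int(keep.sum()))
        cols.extend(k.tolist())
        vals.extend(lengths[keep].tolist())
    P = sp.coo_matrix(
        (vals, (rows, cols)), shape=(geom.nl, grid.nk), dtype=float
    ).tocsr()
    P.sum_duplicates()
    return P


# ---------------------------------------------------------------------------
# Spectral expected counts
# ---------------------------------------------------------------------------


def forward_project(P: sp.spmatrix, x: np.ndarray) -> np.ndarray:
    """Per-ray material path lengths ``y = P x`` (cm), shape (nl, nm)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or P.shape[1] != x.shape[0]:
        raise ValueError("phantom shape does not match projection matrix")
    return np.asarray(P @ x)


def path_exponents(y: np.ndarray, att: AttenuationTable) -> np.ndarray:
    """Exponent arguments ``t_{li} = -sum_m mu_{mi} y_{lm}``, shape (nl, ni)."""
    return -(np.asarray(y, dtype=float) @ att.mu)


def window_intensities(
    y: np.ndarray, spectrum: SpectralModel, att: AttenuationTable, expfun=np.exp
) -> np.ndarray:
    """``sum_i S_{wli} expfun(t_{li})`` per window and ray, shape (nw, nl).

    ``expfun`` is the true exponential for the physical forward model; the
    reconstruction passes its quadratic-tail surrogate here so that both
    sides share one code path (and agree bitwise wherever the exponent
    arguments are nonpositive).
    """
    t = path_exponents(y, att)
    vals = expfun(t)  # (nl, ni)
    mean = spectrum.S_wi @ vals.T  # (nw, nl)
    if spectrum.ray_sensitivity is not None:
        mean = mean * np.asarray(spectrum.ray_sensitivity, dtype=float)[None, :]
    return mean


def expected_counts(
    y: np.ndarray, spectrum: SpectralModel, att: AttenuationTable
) -> np.ndarray:
    """Poisson means ``sum_i S_{wli} exp(-sum_m mu_{mi} y_{lm})``, shape (nw, nl)."""
    if not np.all(np.isfinite(y)):
        raise ValueError("projected image y must be finite")
    return window_intensities(y, spectrum, att, expfun=np.exp)


def simulate_counts(mean: np.ndarray, seed: int) -> np.ndarray:
    """Independent Poisson draws per (window, ray); reproducible given seed."""
    mean = np.asarray(mean, dtype=float)
    if np.any(mean < 0):
        raise ValueError("Poisson means must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.poisson(mean)
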