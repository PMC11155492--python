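"""Seeded generators for all simulation inputs.

Covers the two study designs exercised by the solver:

* sparse quantile-regression data — i.i.d. standard-normal design, a
  sparse all-ones signal, and heavy-tailed Student-t(5) noise;
* spectral photon-counting CT fixtures — a material-fraction phantom on a
  square grid, an X-ray beam spectrum split into blurry energy windows,
  and embedded synthetic attenuation curves for PMMA, aluminum and
  gadolinium (with the Gd K-edge at 50.2 keV).

The attenuation curves are synthetic parametric stand-ins carrying the
qualitative features the reconstruction exercises (positivity, decay in
energy, Al above PMMA everywhere, a single upward K-edge jump); they are
not physical reference data. Every generator is a pure function of its
arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ct.forward import AttenuationTable, ImageGrid, ScanGeometry, SpectralModel

__all__ = [
    "QrDataset",
    "generate_qr_data",
    "Insert",
    "PhantomSpec",
    "generate_phantom",
    "generate_spectrum",
    "builtin_attenuation",
    "GD_K_EDGE_KEV",
    "CT_MATERIALS",
    "ct_preset",
]

GD_K_EDGE_KEV = 50.2
CT_MATERIALS = ("pmma", "aluminum", "gadolinium")


# ---------------------------------------------------------------------------
# Quantile regression data
# ---------------------------------------------------------------------------


@dataclass
class QrDataset:
    """Design matrix, responses and the sparse ground-truth signal."""

    Phi: np.ndarray
    w: np.ndarray
    x_true: np.ndarray
    noise_kind: str
    seed: int


def generate_qr_data(
    n: int = 2000,
    d: int = 2500,
    s_star: int = 10,
    noise: str = "t5",
    seed: int = 0,
) -> QrDataset:
    """Simulate ``w = Phi x_true + z`` with a sparse all-ones signal.

    ``Phi`` has i.i.d. N(0,1) entries; ``x_true`` equals 1 in its leading
    ``s_star`` coordinates and 0 elsewhere; the noise is i.i.d. Student-t
    with 5 degrees of freedom (heavy-tailed, the regime where quantile
    regression beats least squares), or ``"gaussian"``/``"none"``.
    """
    if not (0 <= s_star <= d) or n < 1 or d < 1:
        raise ValueError("invalid dimensions for quantile-regression data")
    rng = np.random.default_rng(seed)
    Phi = rng.standard_normal((n, d))
    x_true = np.zeros(d)
    x_true[:s_star] = 1.0
    if noise == "t5":
        z = rng.standard_t(5, size=n)
    elif noise == "gaussian":
        z = rng.standard_normal(n)
    elif noise == "none":
        z = np.zeros(n)
    else:
        raise ValueError(f"unknown noise kind {noise!r}")
    w = Phi @ x_true + z
    return QrDataset(Phi=Phi, w=w, x_true=x_true, noise_kind=noise, seed=seed)


# ---------------------------------------------------------------------------
# CT phantom
# ---------------------------------------------------------------------------


@dataclass
class Insert:
    """One phantom feature: a disk or axis-aligned rectangle of a material.

    ``size`` is the radius (disk) or ``(width, height)`` (rectangle), in
    cm. ``mode="replace"`` overwrites the pixel's full material content
    (an insert punched out of the background); ``mode="add"`` adds the
    fraction on top of what is already there.
    """

    shape: str
    center: tuple
    size: object
    material: int
    fraction: float = 1.0
    mode: str = "replace"


@dataclass
class PhantomSpec:
    grid: ImageGrid
    n_materials: int
    inserts: Sequence[Insert] = field(default_factory=list)


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Rasterize inserts by pixel-center membership into an (nk, nm) image.

    Deterministic; raises if any pixel's summed material fraction exceeds 1.
    """
    grid = spec.grid
    xs, ys = grid.pixel_centers()
    x = np.zeros((grid.nk, spec.n_materials))
    for ins in spec.inserts:
        if not 0.0 <= ins.fraction <= 1.0:
            raise ValueError("insert fraction must lie in [0, 1]")
        if not 0 <= ins.material < spec.n_materials:
            raise ValueError("insert material index out of range")
        cx, cy = ins.center
        if ins.shape == "disk":
            mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= float(ins.size) ** 2
        elif ins.shape == "rectangle":
            wdt, hgt = ins.size
            mask = (np.abs(xs - cx) <= wdt / 2.0) & (np.abs(ys - cy) <= hgt / 2.0)
        else:
            raise ValueError(f"unknown insert shape {ins.shape!r}")
        if ins.mode == "replace":
            x[mask, :] = 0.0
            x[mask, ins.material] = ins.fraction
        elif ins.mode == "add":
            x[mask, ins.material] += ins.fraction
        else:
            raise ValueError(f"unknown insert mode {ins.mode!r}")
    sums = x.sum(axis=1)
    if np.any(sums > 1.0 + 1e-12):
        raise ValueError("overlapping inserts push a pixel's material sum above 1")
    if np.any(x < 0) or np.any(x > 1.0 + 1e-12):
        raise ValueError("material fractions must lie in [0, 1]")
    return x


# ---------------------------------------------------------------------------
# Beam spectrum with blurry window responses
# ---------------------------------------------------------------------------


def generate_spectrum(
    ni: int = 60,
    nw: int = 3,
    total_photons: float = 1e6,
    energy_range_keV: tuple = (20.0, 120.0),
    thresholds_keV: Sequence[float] = (50.0, 80.0),
    blur_keV: float = 3.0,
) -> SpectralModel:
    """Smooth unimodal beam density split into logistically blurred windows.

    The density is a Beta-shaped bump over the energy range discretized to
    ``ni`` bin centers and normalized to ``total_photons``; the window
    responses are products of logistic threshold functions that sum to 1
    at every energy, so the per-window intensities ``S_wi`` exactly
    partition the beam density (``blur_keV -> 0`` recovers a hard
    partition).
    """
    lo, hi = energy_range_keV
    thresholds = np.asarray(thresholds_keV, dtype=float)
    if nw != len(thresholds) + 1:
        raise ValueError("need nw == len(thresholds) + 1")
    if np.any(thresholds <= lo) or np.any(thresholds >= hi) or np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing inside the energy range")
    h = (hi - lo) / ni
    energies = lo + h * (np.arange(ni) + 0.5)
    s = (energies - lo) / (hi - lo)
    density = s**2.0 * (1.0 - s) ** 1.5  # bump peaking below mid-range
    density = density / density.sum() * total_photons
    if blur_keV > 0:
        sig = [1.0 / (1.0 + np.exp(-(energies - th) / blur_keV)) for th in thresholds]
    else:
        sig = [(energies >= th).astype(float) for th in thresholds]
    edges = [np.ones(ni)] + sig + [np.zeros(ni)]
    responses = np.stack([edges[w] - edges[w + 1] for w in range(nw)])
    S_wi = responses * density[None, :]
    return SpectralModel(energies=energies, S_wi=S_wi)


# ---------------------------------------------------------------------------
# Synthetic attenuation curves
# ---------------------------------------------------------------------------


def builtin_attenuation(
    materials: Sequence[str], energies: np.ndarray
) -> AttenuationTable:
    """Embedded synthetic attenuation curves (1/cm) at the given energies.

    Smooth, strictly decreasing photoelectric-plus-Compton-shaped curves
    for PMMA (low) and aluminum (higher, above PMMA at every energy), and
    for gadolinium a decreasing curve with a single discontinuous upward
    K-edge jump at 50.2 keV. Synthetic stand-ins, not physical reference
    values.
    """
    energies = np.asarray(energies, dtype=float)
    if np.any(energies <= 0):
        raise ValueError("energies must be positive (keV)")
    rows = []
    # three spectrally distinct shapes: Compton-dominated plastic,
    # photoelectric-dominated metal, dilute K-edge contrast agent
    compton = (60.0 / energies) ** 0.4
    photo = (30.0 / energies) ** 3
    for mat in materials:
        key = mat.lower()
        if key == "pmma":
            mu = 0.18 * compton + 0.30 * photo
        elif key == "aluminum":
            mu = 0.25 * compton + 2.8 * photo
        elif key == "gadolinium":
            below = 0.15 * compton + 1.2 * photo
            above = 0.10 + 2.6 * (GD_K_EDGE_KEV / energies) ** 2.7
            mu = np.where(energies < GD_K_EDGE_KEV, below, above)
        else:
            raise ValueError(f"unknown material {mat!r}")
        rows.append(mu)
    return AttenuationTable(mu=np.stack(rows), energies=energies, materials=tuple(materials))


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------


def _default_phantom_spec(grid: ImageGrid) -> PhantomSpec:
    # PMMA background disk with one aluminum and one gadolinium insert,
    # each punched out of the background.
    return PhantomSpec(
        grid=grid,
        n_materials=3,
        inserts=[
            Insert(shape="disk", center=(0.0, 0.0), size=4.0, material=0, fraction=1.0),
            Insert(shape="disk", center=(-2.0, 0.0), size=1.0, material=1, fraction=1.0),
            Insert(shape="disk", center=(2.0, 0.0), size=1.0, material=2, fraction=1.0),
        ],
    )


def ct_preset(name: str) -> dict:
    """Bundle of grid, geometry, spectrum, attenuation and phantom by name.

    ``"full-scale"``: 25x25 grid on 10 cm, 50 angles x 50 cells, ni=60
    energy bins, 3 windows, 1e6 photons. ``"small"``: 16x16 grid, 24x24
    rays, ni=20, 3 windows, 1e5 photons — the scaled-down setting used by
    the test suite and acceptance checks.
    """
    if name == "full-scale":
        grid = ImageGrid(25, 25, side_cm=10.0)
        geom = ScanGeometry(n_angles=50, n_cells=50, grid=grid)
        spectrum = generate_spectrum(ni=60, nw=3, total_photons=1e6)
    elif name == "small":
        grid = ImageGrid(16, 16, side_cm=10.0)
        geom = ScanGeometry(n_angles=24, n_cells=24, grid=grid)
        spectrum = generate_spectrum(ni=20, nw=3, total_photons=1e5)
    else:
        raise ValueError(f"unknown preset {name!r}")
    att = builtin_attenuation(CT_MATERIALS, spectrum.energies)
    phantom = generate_phantom(_default_phantom_spec(grid))
    return {
        "grid": grid,
        "geometry": geom,
        "spectrum": spectrum,
        "attenuation": att,
        "phantom": phantom,
    }
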