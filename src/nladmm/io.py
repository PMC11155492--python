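"""Plain-text serialization: CSV schemas, MatrixMarket, run configs.

Sparse projection matrices travel as MatrixMarket coordinate files; dense
arrays (phantoms, spectra, attenuation tables, counts, iteration logs) as
CSV with documented headers; run configurations as YAML with a
``schema_version`` field.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import yaml

from .ct.forward import AttenuationTable, SpectralModel

__all__ = [
    "write_projection_matrix",
    "read_projection_matrix",
    "write_phantom",
    "read_phantom",
    "write_spectrum",
    "read_spectrum",
    "write_attenuation",
    "read_attenuation",
    "write_counts",
    "read_counts",
    "write_run_config",
    "read_run_config",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


def write_projection_matrix(path: str, P: sp.spmatrix) -> None:
    sio.mmwrite(path, sp.coo_matrix(P))


def read_projection_matrix(path: str) -> sp.csr_matrix:
    return sio.mmread(path).tocsr()


def write_phantom(path: str, x: np.ndarray, materials: Sequence[str] = ()) -> None:
    """Pixel-by-material fractions; one row per pixel (row-major), one column per material."""
    x = np.asarray(x)
    cols = list(materials) if materials else [f"material_{m}" for m in range(x.shape[1])]
    pd.DataFrame(x, columns=cols).to_csv(path, index_label="pixel")


def read_phantom(path: str) -> np.ndarray:
    return pd.read_csv(path, index_col="pixel").to_numpy(dtype=float)


def write_spectrum(path: str, spectrum: SpectralModel) -> None:
    """Energy (keV) plus per-window incident intensities, one row per energy bin."""
    df = pd.DataFrame({"energy_keV": spectrum.energies})
    for w in range(spectrum.nw):
        df[f"window_{w}"] = spectrum.S_wi[w]
    df.to_csv(path, index=False)


def read_spectrum(path: str) -> SpectralModel:
    df = pd.read_csv(path)
    wcols = [c for c in df.columns if c.startswith("window_")]
    return SpectralModel(
        energies=df["energy_keV"].to_numpy(),
        S_wi=df[wcols].to_numpy().T,
    )


def write_attenuation(path: str, att: AttenuationTable) -> None:
    """Energy (keV) plus attenuation coefficient (1/cm) per material column."""
    cols = list(att.materials) if att.materials else [f"material_{m}" for m in range(att.nm)]
    df = pd.DataFrame({"energy_keV": att.energies})
    for m, name in enumerate(cols):
        df[name] = att.mu[m]
    df.to_csv(path, index=False)


def read_attenuation(path: str) -> AttenuationTable:
    df = pd.read_csv(path)
    mats = tuple(c for c in df.columns if c != "energy_keV")
    return AttenuationTable(
        mu=df[list(mats)].to_numpy().T,
        energies=df["energy_keV"].to_numpy(),
        materials=mats,
    )


def write_counts(path: str, counts: np.ndarray) -> None:
    """Photon counts, one row per energy window, one column per ray."""
    pd.DataFrame(np.asarray(counts)).to_csv(path, index_label="window")


def read_counts(path: str) -> np.ndarray:
    return pd.read_csv(path, index_col="window").to_numpy(dtype=np.int64)


def write_run_config(config: dict, path: str) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **config}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_run_config(path: str) -> dict:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    version = payload.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unknown run-config schema version {version!r}")
    return payload
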