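"""Readers and writers for the pipeline's plain-text formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .regions import ProfileMatrix, Spectrum

__all__ = ["read_spectrum", "write_spectrum", "read_profile_matrix", "write_profile_matrix"]


def read_spectrum(path) -> Spectrum:
    """Read a two-column delimited spectrum (ppm, intensity); '#' comments allowed."""
    text = Path(path).read_text()
    delimiter = "," if ("," in text.splitlines()[0] if text.splitlines() else False) else None
    data = np.loadtxt(path, comments="#", delimiter=delimiter)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    return Spectrum(data[:, 0], data[:, 1])


def write_spectrum(spectrum: Spectrum, path) -> None:
    np.savetxt(
        path,
        np.column_stack([spectrum.ppm, spectrum.intensity]),
        header="ppm intensity",
        fmt="%.6f %.8e",
    )


def write_profile_matrix(pm: ProfileMatrix, matrix_path, metadata_path=None) -> None:
    pm.values.to_csv(matrix_path)
    if metadata_path is not None:
        if pm.metadata is None:
            raise ValueError("profile matrix carries no metadata")
        pm.metadata.to_csv(metadata_path)


def read_profile_matrix(matrix_path, metadata_path=None) -> ProfileMatrix:
    values = pd.read_csv(matrix_path, index_col="sample_id")
    meta = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, index_col="sample_id")
        meta = meta.loc[values.index]
    return ProfileMatrix(values, meta)
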