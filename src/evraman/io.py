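"""Reading and writing spectra, bundles and tabular outputs.

Two interchangeable on-disk forms are supported:

* per-spectrum delimited text files (columns ``channel``,
  ``wavenumber_cm-1``, ``intensity``; ``# key=value`` metadata header) plus a
  ``labels.csv`` table, and
* a single ``.npz`` matrix bundle holding the axis vector, the intensity
  matrix, the metadata table column-by-column and a provenance record.

The ``.npz`` container is written deterministically: identical content gives
identical bytes, which the end-to-end workflow relies on for reproducibility
checks.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import RamanSpectrum, SpectraMatrix


class SpectraIOError(ValueError):
    """Malformed spectra input (non-numeric cell, ragged rows, bad axis...)."""


# -- matrix bundle ------------------------------------------------------------

def save_bundle(m: SpectraMatrix, path: str | Path,
                provenance: dict | None = None) -> Path:
    """Write a SpectraMatrix to a single ``.npz`` bundle."""
    path = Path(path)
    arrays: dict = {
        "wavenumbers": m.wavenumbers,
        "intensities": m.intensities,
        "meta_columns": np.array(list(m.meta.columns), dtype=str),
        "provenance": np.array(
            [json.dumps(provenance or {}, sort_keys=True)], dtype=str
        ),
    }
    for col in m.meta.columns:
        values = m.meta[col].to_numpy()
        if values.dtype == object:
            values = values.astype(str)
        arrays[f"meta_{col}"] = values
    buf = _io.BytesIO()
    np.savez_compressed(buf, **arrays)
    path.write_bytes(buf.getvalue())
    return path


def load_bundle(path: str | Path) -> tuple[SpectraMatrix, dict]:
    """Read a ``.npz`` bundle back into a SpectraMatrix (+ provenance)."""
    with np.load(Path(path), allow_pickle=False) as z:
        wn = z["wavenumbers"]
        X = z["intensities"]
        cols = [str(c) for c in z["meta_columns"]]
        meta = pd.DataFrame({c: z[f"meta_{c}"] for c in cols})
        provenance = json.loads(str(z["provenance"][0]))
    return SpectraMatrix(wn, X, meta), provenance


# -- per-spectrum delimited text ----------------------------------------------

def write_spectrum_text(s: RamanSpectrum, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for key in sorted(s.meta):
            fh.write(f"# {key}={s.meta[key]}\n")
        fh.write("channel\twavenumber_cm-1\tintensity\n")
        for ch, wn, y in zip(s.channels, s.wavenumbers, s.intensities):
            fh.write(f"{int(ch)}\t{wn:.8f}\t{y:.8f}\n")
    return path


def read_spectrum_text(path: str | Path) -> RamanSpectrum:
    path = Path(path)
    meta: dict = {}
    channels, wavenumbers, intensities = [], [], []
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    if body_start < len(lines) and lines[body_start].startswith("channel"):
        body_start += 1
    colnames = ("channel", "wavenumber_cm-1", "intensity")
    for row_no, line in enumerate(lines[body_start:], start=body_start + 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 3:
            raise SpectraIOError(
                f"{path.name}, row {row_no}: expected 3 columns, got {len(parts)}"
            )
        values = []
        for col_no, part in enumerate(parts):
            try:
                values.append(float(part))
            except ValueError:
                raise SpectraIOError(
                    f"{path.name}, row {row_no}, column "
                    f"{colnames[col_no]!r}: non-numeric value {part!r}"
                ) from None
        channels.append(int(values[0]))
        wavenumbers.append(values[1])
        intensities.append(values[2])
    wn = np.asarray(wavenumbers)
    if wn.size < 2 or not np.all(np.diff(wn) > 0):
        raise SpectraIOError(f"{path.name}: wavenumber axis is not "
                             "strictly increasing")
    return RamanSpectrum(np.asarray(channels), wn, np.asarray(intensities), meta)


def write_spectra_dir(m: SpectraMatrix, directory: str | Path) -> Path:
    """Write one text file per spectrum plus a ``labels.csv`` metadata table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(m.n_spectra):
        s = m.spectrum(i)
        write_spectrum_text(s, directory / f"{m.ids[i]}.txt")
    m.meta.to_csv(directory / "labels.csv", index=False)
    return directory


def read_spectra(path: str | Path) -> SpectraMatrix:
    """Read spectra from a bundle file or a per-spectrum directory.

    A directory must contain per-spectrum ``.txt`` files and a ``labels.csv``
    metadata table with an ``id`` column; every id must resolve to a file and
    all spectra must share one axis.
    """
    path = Path(path)
    if path.is_file():
        matrix, _ = load_bundle(path)
        return matrix
    if not path.is_dir():
        raise SpectraIOError(f"{path}: no such bundle file or directory")
    labels_path = path / "labels.csv"
    if not labels_path.exists():
        raise SpectraIOError(f"{path}: missing labels.csv metadata table")
    meta = pd.read_csv(labels_path)
    if "id" not in meta.columns:
        raise SpectraIOError("labels.csv must contain an 'id' column")
    spectra = []
    for sid in meta["id"]:
        f = path / f"{sid}.txt"
        if not f.exists():
            raise SpectraIOError(f"missing spectrum file for id {sid!r}")
        spectra.append(read_spectrum_text(f))
    wn = spectra[0].wavenumbers
    for sid, s in zip(meta["id"], spectra):
        if len(s.wavenumbers) != len(wn) or not np.allclose(s.wavenumbers, wn):
            raise SpectraIOError(f"spectrum {sid!r}: axis differs from the "
                                 "first spectrum")
    X = np.vstack([s.intensities for s in spectra])
    return SpectraMatrix(wn, X, meta)


# -- tabular output with provenance headers -----------------------------------

def write_csv_with_provenance(df: pd.DataFrame, path: str | Path,
                              provenance: dict | None = None,
                              index: bool = False) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in sorted((provenance or {}).items()):
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=index)
    return path
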