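"""In-memory containers for trapped-particle Raman acquisitions.

A single acquisition is a :class:`RamanSpectrum` (CCD channel index, Raman
shift axis in cm^-1, intensity counts plus free-form metadata).  All modeling
operates on a :class:`SpectraMatrix`: an ensemble of spectra aligned on one
shared wavenumber axis with a per-spectrum metadata table (class label,
isolation batch, ground-truth composition where known).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class AxisError(ValueError):
    """Raised when a wavenumber axis is invalid or two axes disagree."""


def _validate_axis(wavenumbers: np.ndarray) -> np.ndarray:
    wn = np.asarray(wavenumbers, dtype=float)
    if wn.ndim != 1 or wn.size < 2:
        raise AxisError("wavenumber axis must be a 1-D array with >= 2 points")
    if not np.all(np.diff(wn) > 0):
        raise AxisError("wavenumber axis must be strictly increasing")
    return wn


@dataclass
class RamanSpectrum:
    """One trapped-particle Raman acquisition."""

    channels: np.ndarray
    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        self.wavenumbers = _validate_axis(self.wavenumbers)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not (len(self.channels) == len(self.wavenumbers) == len(self.intensities)):
            raise AxisError(
                "channels, wavenumbers and intensities must have equal length"
            )

    @property
    def n_channels(self) -> int:
        return len(self.wavenumbers)

    def with_intensities(self, intensities: np.ndarray) -> "RamanSpectrum":
        """Copy of the spectrum with replaced intensities (same axis, same meta)."""
        return RamanSpectrum(
            self.channels.copy(), self.wavenumbers.copy(),
            np.asarray(intensities, dtype=float), dict(self.meta),
        )

    def restrict(self, mask: np.ndarray) -> "RamanSpectrum":
        """Copy restricted to the channels selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        return RamanSpectrum(
            self.channels[mask], self.wavenumbers[mask],
            self.intensities[mask], dict(self.meta),
        )


@dataclass
class ResponseCurve:
    """Relative-intensity correction curve (multiplicative, per wavenumber).

    Derived in practice from a calibrated luminescence standard for the
    excitation wavelength in use; here only the application of the resulting
    correction factors is modeled.
    """

    wavenumbers: np.ndarray
    correction_factor: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = _validate_axis(self.wavenumbers)
        self.correction_factor = np.asarray(self.correction_factor, dtype=float)
        if len(self.correction_factor) != len(self.wavenumbers):
            raise AxisError("correction_factor length must match wavenumbers")
        if np.any(self.correction_factor <= 0):
            raise ValueError("response correction factors must be strictly positive")

    def interpolated(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Correction factors interpolated onto a target axis.

        The curve must cover the full target range; extrapolation is refused.
        """
        wn = np.asarray(wavenumbers, dtype=float)
        if wn.min() < self.wavenumbers[0] or wn.max() > self.wavenumbers[-1]:
            raise AxisError(
                "response curve does not cover the spectrum range "
                f"[{wn.min():.1f}, {wn.max():.1f}] cm^-1"
            )
        return np.interp(wn, self.wavenumbers, self.correction_factor)


@dataclass
class SpectraMatrix:
    """Ensemble of spectra on a shared axis; the unit of all modeling.

    ``meta`` holds one row per spectrum and must contain an ``id`` column;
    ``label`` (class) and ``batch`` (isolation) columns are used by the
    modeling stages when present.  Ground-truth mixing weights from the
    synthetic generator are stored as ``w_<component>`` columns.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavenumbers = _validate_axis(self.wavenumbers)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[1] != len(self.wavenumbers):
            raise AxisError("intensity matrix width must match axis length")
        if not isinstance(self.meta, pd.DataFrame):
            self.meta = pd.DataFrame(self.meta)
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError("metadata table must have one row per spectrum")
        if "id" not in self.meta.columns:
            raise ValueError("metadata table must contain an 'id' column")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    @property
    def ids(self) -> np.ndarray:
        return self.meta["id"].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        if "label" not in self.meta.columns:
            raise KeyError("metadata has no 'label' column")
        return self.meta["label"].to_numpy()

    def spectrum(self, i: int) -> RamanSpectrum:
        """The i-th row as a standalone :class:`RamanSpectrum`."""
        return RamanSpectrum(
            np.arange(self.n_channels), self.wavenumbers.copy(),
            self.intensities[i].copy(), self.meta.iloc[i].to_dict(),
        )

    def select(self, mask: np.ndarray) -> "SpectraMatrix":
        """Row subset (boolean mask or integer indices); order preserved."""
        mask = np.asarray(mask)
        return SpectraMatrix(
            self.wavenumbers.copy(), self.intensities[mask],
            self.meta.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask],
        )

    def restrict_channels(self, mask: np.ndarray) -> "SpectraMatrix":
        mask = np.asarray(mask, dtype=bool)
        return SpectraMatrix(self.wavenumbers[mask], self.intensities[:, mask],
                             self.meta.copy())

    def with_intensities(self, intensities: np.ndarray) -> "SpectraMatrix":
        return SpectraMatrix(self.wavenumbers.copy(),
                             np.asarray(intensities, dtype=float), self.meta.copy())

    def class_means(self) -> "SpectraMatrix":
        """Per-class mean spectra (equal weight per spectrum), one row per class.

        Classes are ordered by first appearance in the metadata table.
        """
        labels = self.labels
        order = pd.unique(labels)
        means = np.vstack([self.intensities[labels == c].mean(axis=0) for c in order])
        meta = pd.DataFrame({"id": order, "label": order})
        return SpectraMatrix(self.wavenumbers.copy(), means, meta)

    def same_axis(self, other: "SpectraMatrix", tol: float = 1e-9) -> bool:
        return (self.n_channels == other.n_channels
                and np.allclose(self.wavenumbers, other.wavenumbers, atol=tol))

    @classmethod
    def from_spectra(cls, spectra: list[RamanSpectrum]) -> "SpectraMatrix":
        """Stack spectra that share one axis into a matrix."""
        if not spectra:
            raise ValueError("cannot build a SpectraMatrix from zero spectra")
        wn = spectra[0].wavenumbers
        for s in spectra[1:]:
            if len(s.wavenumbers) != len(wn) or not np.allclose(s.wavenumbers, wn):
                raise AxisError("all spectra must share one wavenumber axis")
        meta = pd.DataFrame([s.meta for s in spectra])
        if "id" not in meta.columns:
            meta.insert(0, "id", [f"s{i:05d}" for i in range(len(spectra))])
        return cls(wn.copy(), np.vstack([s.intensities for s in spectra]), meta)
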