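"""Dimensional Reduction Arrays (DRAs).

A DRA compresses an ensemble of Raman spectra into a heatmap of mean
intensity per fixed-width wavenumber bin (default block size 50 cm^-1), with
one row per class mean or per individual spectrum.  Because the CCD pixel
axis maps nonlinearly onto Raman shift, the number of channels per bin
varies; cell values are means over the channels actually assigned to each
bin, which corrects for that mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SpectraMatrix

#: Perceptually uniform colormaps accepted by default for rendering.
APPROVED_COLORMAPS = ("viridis", "cividis", "plasma", "inferno", "magma")
#: Rainbow-style maps rejected by default (not perceptually uniform).
REJECTED_COLORMAPS = ("jet", "rainbow", "gist_rainbow", "hsv", "nipy_spectral",
                      "turbo")


@dataclass
class DRAHeatmap:
    """Binned mean-intensity matrix with its bin edges and row labels.

    ``values`` is (n_rows, n_bins); empty bins hold NaN (flagged missing,
    never zero, so they cannot distort the color scale).
    """

    bin_edges: np.ndarray
    rows: list
    values: np.ndarray
    points_per_bin: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{self.bin_edges[i]:.1f}-{self.bin_edges[i + 1]:.1f}"
            for i in range(self.n_bins)
        ]
        return pd.DataFrame(self.values, index=self.rows, columns=cols)


def _bin_edges(lo: float, hi: float, bin_size: float) -> np.ndarray:
    """Half-open bins [edge, edge + bin_size) anchored at lo; a partial final
    bin is kept and closed at hi."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    n_full = int(np.floor((hi - lo) / bin_size + 1e-12))
    edges = lo + bin_size * np.arange(n_full + 1)
    if edges[-1] < hi - 1e-12:
        edges = np.append(edges, hi)
    return edges


def build_dra(
    m: SpectraMatrix,
    bin_size: float = 50.0,
    range: tuple[float, float] | None = None,
    rows: str = "class",
) -> DRAHeatmap:
    """Bin an ensemble into a DRA heatmap.

    ``rows="class"`` first averages spectra within each class (equal weight
    per spectrum) and then averages the class-mean spectrum within each bin;
    ``rows="spectrum"`` keeps one row per spectrum.  Channels are assigned to
    bins by wavenumber value, so points per bin vary with axis nonlinearity.
    """
    lo, hi = range if range is not None else (m.wavenumbers[0], m.wavenumbers[-1])
    edges = _bin_edges(lo, hi, bin_size)

    if rows == "class":
        source = m.class_means()
        row_labels = list(source.ids)
    elif rows == "spectrum":
        source = m
        row_labels = list(m.ids)
    else:
        raise ValueError("rows must be 'class' or 'spectrum'")

    wn = source.wavenumbers
    in_range = (wn >= lo) & (wn <= hi)
    # half-open [e_i, e_{i+1}) with the final bin closed at hi
    bin_of = np.searchsorted(edges, wn, side="right") - 1
    bin_of[wn == hi] = len(edges) - 2

    n_bins = len(edges) - 1
    points = np.zeros(n_bins, dtype=int)
    values = np.full((source.n_spectra, n_bins), np.nan)
    for b in np.arange(n_bins):
        mask = in_range & (bin_of == b)
        points[b] = int(mask.sum())
        if points[b] > 0:
            values[:, b] = source.intensities[:, mask].mean(axis=1)
    return DRAHeatmap(edges, row_labels, values, points)


def subrange_dra(
    m: SpectraMatrix,
    range: tuple[float, float],
    bin_size: float = 50.0,
    rows: str = "class",
) -> DRAHeatmap:
    """DRA restricted to a spectral subrange.

    The color scale of a rendered DRA spans its own min/max cell, so a
    subrange excluding a dominant band (e.g. the strong CH2 bend at
    1442 cm^-1) reveals subtler variation elsewhere.
    """
    lo, hi = range
    if lo < m.wavenumbers[0] - 1e-9 or hi > m.wavenumbers[-1] + 1e-9:
        raise ValueError("subrange must lie within the data range")
    return build_dra(m, bin_size=bin_size, range=(lo, hi), rows=rows)


def render_dra(
    h: DRAHeatmap,
    colormap: str = "viridis",
    out: str | None = None,
    *,
    allow_any_colormap: bool = False,
    missing_color: str = "#b0b0b0",
):
    """Render a DRA heatmap to an image file.

    Only perceptually uniform colormaps are accepted by default; rainbow-style
    maps distort perceived intensity differences and are rejected unless
    ``allow_any_colormap`` is set.  The color scale spans [min cell, max cell]
    and missing cells are drawn in a distinct flat marker color.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not allow_any_colormap and colormap not in APPROVED_COLORMAPS:
        reason = (
            "is a rainbow-style gradient, which is not perceptually uniform"
            if colormap in REJECTED_COLORMAPS
            else "is not in the approved perceptually uniform list"
        )
        raise ValueError(
            f"colormap {colormap!r} {reason}; pick one of {APPROVED_COLORMAPS} "
            "or pass allow_any_colormap=True"
        )

    data = np.ma.masked_invalid(h.values)
    cmap = plt.get_cmap(colormap).copy()
    cmap.set_bad(missing_color)

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.35 * h.n_bins), max(2.0, 0.35 * len(h.rows) + 1.2))
    )
    ycoords = np.arange(len(h.rows) + 1)
    mesh = ax.pcolormesh(h.bin_edges, ycoords, data, cmap=cmap,
                         vmin=data.min(), vmax=data.max())
    ax.set_yticks(ycoords[:-1] + 0.5)
    ax.set_yticklabels([str(r) for r in h.rows])
    ax.invert_yaxis()
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    fig.colorbar(mesh, ax=ax, label="mean intensity")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150, metadata={"Software": None})
        plt.close(fig)
        return out
    return fig
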