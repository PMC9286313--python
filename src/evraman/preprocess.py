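"""Spectral preprocessing chain for trapped-particle Raman ensembles.

Steps, in the order the pipeline applies them:

1. cosmic-spike removal (amplitude + second-difference thresholds, linear
   interpolation over flagged channels),
2. relative-intensity response correction,
3. min/max post-thresholding of whole spectra (background-only traps and
   aggregates),
4. subtraction of a fixed fraction (default 95%) of the averaged PBS
   background,
5. crop to the fingerprint region,
6. asymmetric-least-squares Whittaker baseline subtraction,
7. Savitzky-Golay smoothing (first order, frame 7 by default),
8. normalization by the area under the curve.

Every step exists standalone and the one-call :func:`preprocess_pipeline` /
:class:`RamanPreprocessor` applies them in this order with a per-spectrum
processing log.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal, sparse
from scipy.sparse.linalg import spsolve

from .containers import AxisError, RamanSpectrum, ResponseCurve, SpectraMatrix


class WhittakerConvergenceError(RuntimeError):
    """Asymmetric-weight iteration did not stabilize within max_iter passes."""

    def __init__(self, iterations: int):
        super().__init__(
            f"Whittaker baseline weights did not converge in {iterations} iterations"
        )
        self.iterations = iterations


class DegenerateSpectrumError(ValueError):
    """Raised when an operation would leave no usable channels."""


@dataclass
class PipelineConfig:
    """Parameters of the preprocessing chain.

    Setting ``pbs_fraction`` with a PBS reference supplied enables background
    subtraction; ``crop=None``, ``whittaker_lambda=None``, ``sg_frame=None``
    or the boolean flags disable the corresponding step.  Intensity
    thresholds of ``None`` disable post-thresholding.
    """

    despike: bool = True
    spike_amp_threshold: float = 8.0
    spike_d2_threshold: float = 8.0
    spike_window: int = 9
    pbs_fraction: float = 0.95
    crop: tuple[float, float] | None = (600.0, 1800.0)
    whittaker_lambda: float | None = 1e4
    whittaker_p: float = 1e-4
    whittaker_max_iter: int = 50
    sg_order: int = 1
    sg_frame: int | None = 7
    normalize: bool = True
    min_intensity: float | None = None
    max_intensity: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.pbs_fraction <= 1.0):
            raise ValueError("pbs_fraction must be in (0, 1]")
        if self.sg_frame is not None:
            if self.sg_frame % 2 == 0:
                raise ValueError("sg_frame must be odd")
            if self.sg_frame <= self.sg_order:
                raise ValueError("sg_frame must exceed sg_order")
        if self.crop is not None and not (self.crop[0] < self.crop[1]):
            raise ValueError("crop interval must satisfy lo < hi")
        if self.whittaker_lambda is not None and self.whittaker_lambda <= 0:
            raise ValueError("whittaker_lambda must be > 0")
        if not (0.0 < self.whittaker_p < 1.0):
            raise ValueError("whittaker_p must be in (0, 1)")


# -- cosmic spikes -----------------------------------------------------------

def remove_cosmic_spikes(
    s: RamanSpectrum, cfg: PipelineConfig | None = None
) -> tuple[RamanSpectrum, list[int]]:
    """Flag and interpolate single-channel cosmic spikes.

    A channel is flagged only when both its deviation from a rolling median
    and the magnitude of the local second difference exceed robust-sigma
    multiples; flagged channels are replaced by linear interpolation from the
    nearest unflagged neighbors, all other channels are returned unchanged.
    """
    cfg = cfg or PipelineConfig()
    y = s.intensities
    n = len(y)
    if n < 5:
        raise DegenerateSpectrumError("spike removal needs >= 5 channels")

    med = ndimage.median_filter(y, size=cfg.spike_window, mode="nearest")
    resid = y - med
    # robust scales with a tiny relative floor against exact-zero MAD
    floor = 1e-12 * (np.abs(y).max() + 1.0)
    sigma = max(1.4826 * np.median(np.abs(resid - np.median(resid))), floor)
    d2 = np.zeros(n)
    d2[1:-1] = y[:-2] - 2.0 * y[1:-1] + y[2:]
    sigma_d2 = max(1.4826 * np.median(np.abs(d2 - np.median(d2))), floor)

    flagged = (np.abs(resid) > cfg.spike_amp_threshold * sigma) & (
        np.abs(d2) > cfg.spike_d2_threshold * sigma_d2
    )
    if flagged.all():
        raise DegenerateSpectrumError("all channels flagged as spikes")
    if not flagged.any():
        return s.with_intensities(y.copy()), []

    keep = ~flagged
    cleaned = y.copy()
    cleaned[flagged] = np.interp(
        s.wavenumbers[flagged], s.wavenumbers[keep], y[keep]
    )
    return s.with_intensities(cleaned), [int(i) for i in np.flatnonzero(flagged)]


# -- response correction -----------------------------------------------------

def apply_response_correction(s: RamanSpectrum, c: ResponseCurve) -> RamanSpectrum:
    """Multiply intensities by the interpolated correction factor."""
    factor = c.interpolated(s.wavenumbers)
    if np.any(factor <= 0):
        raise ValueError("response correction factors must be strictly positive")
    return s.with_intensities(s.intensities * factor)


# -- min/max post-thresholding ----------------------------------------------

def threshold_filter(
    m: SpectraMatrix, cfg: PipelineConfig | None = None
) -> tuple[SpectraMatrix, list]:
    """Drop spectra whose maximum intensity falls outside [min, max] bounds.

    Removes background-only traps (max below ``min_intensity``) and
    aggregates (max above ``max_intensity``).  Thresholds are configuration,
    never auto-chosen; ``None`` disables a bound.  Survivor order preserved.
    """
    cfg = cfg or PipelineConfig()
    peak = m.intensities.max(axis=1)
    keep = np.ones(m.n_spectra, dtype=bool)
    if cfg.min_intensity is not None:
        keep &= peak >= cfg.min_intensity
    if cfg.max_intensity is not None:
        keep &= peak <= cfg.max_intensity
    rejected = [m.ids[i] for i in np.flatnonzero(~keep)]
    return m.select(keep), rejected


# -- PBS background subtraction ----------------------------------------------

def subtract_background(
    s: RamanSpectrum, pbs: SpectraMatrix, cfg: PipelineConfig | None = None
) -> RamanSpectrum:
    """Subtract ``pbs_fraction`` x columnwise mean of the PBS reference set.

    Matching of batch / integration-time reference sets is the caller's duty.
    """
    cfg = cfg or PipelineConfig()
    if pbs.n_spectra < 1:
        raise ValueError("PBS reference set is empty")
    if len(pbs.wavenumbers) != len(s.wavenumbers) or not np.allclose(
        pbs.wavenumbers, s.wavenumbers
    ):
        raise AxisError("PBS reference axis does not match spectrum axis")
    mean_pbs = pbs.intensities.mean(axis=0)
    return s.with_intensities(s.intensities - cfg.pbs_fraction * mean_pbs)


# -- fingerprint crop ---------------------------------------------------------

def crop_fingerprint(
    s: RamanSpectrum, cfg: PipelineConfig | None = None
) -> RamanSpectrum:
    """Keep channels with lo <= wavenumber <= hi; metadata preserved."""
    cfg = cfg or PipelineConfig()
    if cfg.crop is None:
        return s
    lo, hi = cfg.crop
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise DegenerateSpectrumError(
            f"crop [{lo}, {hi}] cm^-1 leaves no channels on axis "
            f"[{s.wavenumbers[0]:.1f}, {s.wavenumbers[-1]:.1f}]"
        )
    return s.restrict(mask)


# -- Whittaker baseline -------------------------------------------------------

def _second_difference(n: int) -> sparse.csr_matrix:
    return sparse.diags(
        [1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csr"
    )


def whittaker_baseline(
    y: np.ndarray | RamanSpectrum,
    lam: float = 1e4,
    p: float = 1e-4,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Asymmetric-least-squares Whittaker baseline.

    The baseline z minimizes sum_i w_i (y_i - z_i)^2 + lam * sum (D2 z)^2 with
    asymmetric weights w_i = p where y_i > z_i else (1 - p), iterated until
    the weight pattern stabilizes.  Returns ``(baseline, corrected)`` where
    ``corrected = y - baseline`` (no clipping applied).
    """
    if isinstance(y, RamanSpectrum):
        y = y.intensities
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not lam > 0:
        raise ValueError("lam must be > 0")
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    if n < 3:
        raise DegenerateSpectrumError("Whittaker baseline needs >= 3 channels")

    D = _second_difference(n)
    penalty = (lam * (D.T @ D)).tocsc()
    w = np.ones(n)
    z = y
    seen = {w.tobytes()}
    for _ in range(max_iter):
        A = sparse.diags(w).tocsc() + penalty
        z = spsolve(A, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            return z, y - z
        # the binary weight pattern can enter a limit cycle at channels that
        # straddle the baseline; a repeated pattern means iterating further
        # cannot produce new information, so the current solution is accepted
        if w_new.tobytes() in seen:
            return z, y - z
        seen.add(w_new.tobytes())
        w = w_new
    raise WhittakerConvergenceError(max_iter)


def whittaker_correct(s: RamanSpectrum, lam: float = 1e4, p: float = 1e-4,
                      max_iter: int = 50) -> RamanSpectrum:
    _, corrected = whittaker_baseline(s.intensities, lam, p, max_iter)
    return s.with_intensities(corrected)


# -- Savitzky-Golay smoothing -------------------------------------------------

def savgol_smooth(
    s: RamanSpectrum | np.ndarray, cfg: PipelineConfig | None = None
) -> RamanSpectrum | np.ndarray:
    """Savitzky-Golay smoothing on the channel index.

    Interior channels take the value at the window center of the
    least-squares polynomial over the frame; edges use a symmetrically
    shrunk window (down to a single channel at the boundary, which is left
    unchanged) to avoid padding artifacts.
    """
    cfg = cfg or PipelineConfig()
    frame, order = cfg.sg_frame, cfg.sg_order
    y = s.intensities if isinstance(s, RamanSpectrum) else np.asarray(s, float)
    n = len(y)
    if frame is None:
        return s
    if frame % 2 == 0:
        raise ValueError("sg_frame must be odd")
    if frame <= order:
        raise ValueError("sg_frame must exceed sg_order")
    if frame > n:
        raise ValueError("sg_frame exceeds channel count")

    out = signal.savgol_filter(y, frame, order)
    half = frame // 2
    for i in list(range(half)) + list(range(n - half, n)):
        h = min(i, n - 1 - i)
        if h == 0:
            out[i] = y[i]
            continue
        k = min(order, 2 * h)
        idx = np.arange(i - h, i + h + 1)
        coeffs = np.polynomial.polynomial.polyfit(idx - i, y[idx], k)
        out[i] = coeffs[0]
    if isinstance(s, RamanSpectrum):
        return s.with_intensities(out)
    return out


# -- area normalization -------------------------------------------------------

def normalize_auc(s: RamanSpectrum) -> RamanSpectrum:
    """Divide by the trapezoidal area under the curve on the wavenumber axis.

    The axis may be nonuniform, so the quadrature runs over wavenumbers, not
    channel indices.  Scale-invariant and idempotent.
    """
    area = float(np.trapezoid(s.intensities, s.wavenumbers))
    if area <= 0:
        raise ValueError(f"area under the curve is {area:.3g}; must be > 0")
    return s.with_intensities(s.intensities / area)


# -- full pipeline ------------------------------------------------------------

def _apply_rowwise(m: SpectraMatrix, fn) -> SpectraMatrix:
    rows = [fn(m.spectrum(i)) for i in range(m.n_spectra)]
    wn = rows[0].wavenumbers
    return SpectraMatrix(wn, np.vstack([r.intensities for r in rows]), m.meta)


def preprocess_pipeline(
    m: SpectraMatrix,
    pbs: SpectraMatrix | None = None,
    curve: ResponseCurve | None = None,
    cfg: PipelineConfig | None = None,
) -> tuple[SpectraMatrix, dict]:
    """Apply the full chain in order, returning the processed ensemble and a
    per-spectrum processing log (spike channels, rejected ids, step list)."""
    cfg = cfg or PipelineConfig()
    log: dict = {"steps": [], "spikes": {}, "rejected": [], "errors": {}}

    def step(name):
        log["steps"].append(name)

    out = m
    if cfg.despike:
        step("remove_cosmic_spikes")
        rows = []
        for i in range(out.n_spectra):
            try:
                s, flagged = remove_cosmic_spikes(out.spectrum(i), cfg)
            except Exception as exc:  # re-raise with spectrum id attached
                raise type(exc)(f"spectrum {out.ids[i]}: {exc}") from exc
            if flagged:
                log["spikes"][out.ids[i]] = flagged
            rows.append(s)
        out = SpectraMatrix(out.wavenumbers,
                            np.vstack([r.intensities for r in rows]), out.meta)

    if curve is not None:
        step("apply_response_correction")
        out = _apply_rowwise(out, lambda s: apply_response_correction(s, curve))

    if cfg.min_intensity is not None or cfg.max_intensity is not None:
        step("threshold_filter")
        out, rejected = threshold_filter(out, cfg)
        log["rejected"] = rejected

    if pbs is not None:
        step("subtract_background")
        ref = pbs
        if curve is not None:
            # PBS references are response-corrected identically before averaging
            ref = _apply_rowwise(pbs, lambda s: apply_response_correction(s, curve))
        out = _apply_rowwise(out, lambda s: subtract_background(s, ref, cfg))

    if cfg.crop is not None:
        step("crop_fingerprint")
        lo, hi = cfg.crop
        mask = (out.wavenumbers >= lo) & (out.wavenumbers <= hi)
        if not mask.any():
            raise DegenerateSpectrumError(f"crop [{lo}, {hi}] leaves no channels")
        out = out.restrict_channels(mask)

    if cfg.whittaker_lambda is not None:
        step("whittaker_baseline")
        out = _apply_rowwise(
            out, lambda s: whittaker_correct(
                s, cfg.whittaker_lambda, cfg.whittaker_p, cfg.whittaker_max_iter)
        )

    if cfg.sg_frame is not None:
        step("savgol_smooth")
        out = _apply_rowwise(out, lambda s: savgol_smooth(s, cfg))

    if cfg.normalize:
        step("normalize_auc")
        out = _apply_rowwise(out, normalize_auc)

    return out, log


#: Preprocessing used ahead of entropy-minimization unmixing: the standard
#: batch chain with baseline removal at asymmetry 1e-4 / smoothing 1e4, but
#: no area normalization (unit-length normalization happens in the abundance
#: stage instead).
BTEM_BRANCH_CONFIG = PipelineConfig(
    whittaker_lambda=1e4, whittaker_p=1e-4, sg_frame=7, normalize=False
)


class RamanPreprocessor:
    """Estimator-style wrapper over :func:`preprocess_pipeline`.

    ``fit`` stores the PBS reference and response curve; ``transform`` runs
    the chain on a :class:`SpectraMatrix`.  Follows the scikit-learn
    get_params/set_params protocol so it can sit in composite workflows,
    though it transforms ensembles rather than bare arrays.
    """

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "RamanPreprocessor":
        for k, v in params.items():
            if k == "config":
                self.config = v
            elif hasattr(self.config, k):
                self.config = replace(self.config, **{k: v})
            else:
                raise ValueError(f"unknown parameter {k!r}")
        return self

    def fit(self, pbs: SpectraMatrix | None = None,
            curve: ResponseCurve | None = None) -> "RamanPreprocessor":
        self.pbs_ = pbs
        self.curve_ = curve
        return self

    def transform(self, m: SpectraMatrix) -> SpectraMatrix:
        if not hasattr(self, "pbs_"):
            self.fit()
        out, self.log_ = preprocess_pipeline(m, self.pbs_, self.curve_, self.config)
        return out
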