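"""Synthetic single-EV Raman spectrum generator.

Emulates the statistical structure of trapped-particle EV spectra in the
fingerprint region: each extracellular vesicle is a convex mixture of four
biomolecular component spectra (protein, nucleic acid, phosphatidylcholine-
like lipid, sphingomyelin-like lipid) built from literature band assignments,
sitting on a smooth baseline plus a PBS/water background, read out through a
mildly nonlinear CCD-pixel -> wavenumber axis with signal-dependent (shot-
like) noise and occasional single-channel cosmic spikes.

Class profiles control the mean composition: noncancer-like profiles carry
relatively more nucleic acid and less total lipid than cancer-like profiles,
the ordering that drives the downstream classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RamanSpectrum, ResponseCurve, SpectraMatrix

#: Canonical component order used for weight vectors throughout the package.
COMPONENT_ORDER = (
    "protein",
    "nucleic_acid",
    "phosphatidylcholine_like",
    "sphingomyelin_like",
)


@dataclass(frozen=True)
class BandSpec:
    """One Raman band: center (cm^-1), FWHM (cm^-1), relative height, label."""

    center: float
    width: float = 12.0
    height: float = 1.0
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band at {self.center} cm^-1: width must be > 0")
        if self.height < 0:
            raise ValueError(f"band at {self.center} cm^-1: height must be >= 0")


@dataclass(frozen=True)
class AxisMap:
    """Monotone CCD pixel -> wavenumber map.

    The default map is mildly quadratic, so channel spacing in cm^-1 varies
    across the detector — the situation wavenumber-binned visualizations must
    correct for.
    """

    n_channels: int = 1024
    lo: float = 600.0
    hi: float = 1800.0
    curvature: float = 0.10

    def wavenumbers(self) -> np.ndarray:
        u = np.linspace(0.0, 1.0, self.n_channels)
        f = (u + self.curvature * u**2) / (1.0 + self.curvature)
        return self.lo + (self.hi - self.lo) * f

    @property
    def range(self) -> tuple[float, float]:
        return (self.lo, self.hi)


@dataclass
class ComponentTruth:
    """Ground-truth pure-component spectrum (non-negative, unit L2 norm)."""

    name: str
    bands: tuple[BandSpec, ...]
    spectrum: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.spectrum, dtype=float)
        if np.any(s < 0):
            raise ValueError(f"component {self.name}: spectrum must be non-negative")
        n = np.linalg.norm(s)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"component {self.name}: spectrum must be unit length")
        self.spectrum = s


@dataclass
class ClassProfile:
    """Mean composition and acquisition statistics for one EV class.

    ``mean_weights`` follows :data:`COMPONENT_ORDER`.  ``weight_dispersion``
    is the Dirichlet concentration: per-EV weights are drawn from
    Dirichlet(dispersion * mean_weights), so larger values give tighter
    compositional distributions (``inf`` pins every EV at the mean).
    """

    class_name: str
    mean_weights: tuple[float, float, float, float]
    weight_dispersion: float = 1000.0
    snr: float = 60.0
    spike_rate: float = 0.05
    acquisition_time: float = 10.0

    def __post_init__(self) -> None:
        w = np.asarray(self.mean_weights, dtype=float)
        if len(w) != len(COMPONENT_ORDER):
            raise ValueError("mean_weights must have one entry per component")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mean_weights must be non-negative and sum to 1")
        if not self.snr > 0:
            raise ValueError("snr must be > 0")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        self.mean_weights = tuple(float(x) for x in w)


# Band tables per component.  Centers follow standard EV Raman assignments
# (phenylalanine 1004, CH2 bend of lipids 1442, DNA ring breathing 723, the
# 989 cm^-1 marker of sphingomyelin-like species, ...).  Relative heights are
# generator choices giving mutually distinguishable spectra.
_BAND_TABLES: dict[str, tuple[tuple[float, float, str], ...]] = {
    "protein": (
        (845.0, 0.50, "tyrosine, glycans"),
        (884.0, 0.45, "tyrosine, glycans"),
        (1004.0, 1.00, "phenylalanine"),
        (1128.0, 0.40, "C-N stretch proteins"),
        (1256.0, 0.70, "amide-III proteins"),
        (1337.0, 0.60, "amide-III proteins"),
    ),
    "nucleic_acid": (
        (723.0, 1.00, "DNA ring breathing modes"),
        (1084.0, 0.80, "PO2 stretch DNA backbone"),
        (1185.0, 0.50, "cytosine, guanine"),
        (1337.0, 0.55, "DNA ring breathing modes"),
        (1354.0, 0.50, "guanine"),
        (1371.0, 0.45, "DNA ring breathing modes"),
    ),
    "phosphatidylcholine_like": (
        (1064.0, 0.55, "C-C stretch lipids"),
        (1295.0, 0.65, "CH2 twist lipids"),
        (1399.0, 0.35, "C=O stretch, CH2 lipids"),
        (1442.0, 1.00, "CH2 bend lipids"),
    ),
    "sphingomyelin_like": (
        (989.0, 1.00, "sphingomyelin marker"),
        (1064.0, 0.45, "C-C stretch lipids"),
        (1295.0, 0.40, "CH2 twist lipids"),
        (1442.0, 0.75, "CH2 bend lipids"),
    ),
}

#: Default class profiles: noncancer-like EVs carry more nucleic acid and
#: less total lipid (PC + SM) than cancer-like EVs.
DEFAULT_PROFILES: tuple[ClassProfile, ...] = (
    ClassProfile("noncancer", (0.35, 0.30, 0.25, 0.10)),
    ClassProfile("cancer", (0.30, 0.15, 0.40, 0.15)),
)


def pseudo_voigt(x: np.ndarray, center: float, fwhm: float,
                 eta: float = 0.5) -> np.ndarray:
    """Pseudo-Voigt profile with unit peak height.

    ``eta`` is the Lorentzian fraction; 0.5 is a typical condensed-phase
    Raman lineshape.
    """
    gamma = fwhm / 2.0
    lor = gamma**2 / ((x - center) ** 2 + gamma**2)
    gau = np.exp(-4.0 * math.log(2.0) * (x - center) ** 2 / fwhm**2)
    return eta * lor + (1.0 - eta) * gau


def make_component_truths(axis: AxisMap | None = None,
                          fwhm: float = 12.0) -> list[ComponentTruth]:
    """Build the four ground-truth component spectra on a given axis.

    Raises ``ValueError`` naming the offending band if the axis range does
    not contain every required band center.
    """
    axis = axis or AxisMap()
    wn = axis.wavenumbers()
    truths = []
    for name in COMPONENT_ORDER:
        bands = tuple(
            BandSpec(center=c, width=fwhm, height=h, assignment=a)
            for c, h, a in _BAND_TABLES[name]
        )
        for b in bands:
            if not (wn[0] <= b.center <= wn[-1]):
                raise ValueError(
                    f"axis range [{wn[0]:.1f}, {wn[-1]:.1f}] cm^-1 excludes the "
                    f"{name} band at {b.center:.0f} cm^-1 ({b.assignment})"
                )
        s = np.zeros_like(wn)
        for b in bands:
            s += b.height * pseudo_voigt(wn, b.center, b.width)
        s /= np.linalg.norm(s)
        truths.append(ComponentTruth(name=name, bands=bands, spectrum=s))
    return truths


def pbs_template(axis: AxisMap, amplitude: float = 120.0) -> np.ndarray:
    """PBS/water background template: broad water bending band plus a weak
    phosphate feature on a gentle pedestal.  No biomolecular fingerprint bands.
    """
    wn = axis.wavenumbers()
    shape = (0.25
             + pseudo_voigt(wn, 1640.0, 180.0, eta=0.3)
             + 0.25 * pseudo_voigt(wn, 980.0, 90.0, eta=0.3))
    return amplitude * shape


def make_response_curve(axis: AxisMap, strength: float = 0.4) -> ResponseCurve:
    """Smooth synthetic relative-intensity correction curve (>0 everywhere)."""
    wn = axis.wavenumbers()
    u = (wn - wn[0]) / (wn[-1] - wn[0])
    factor = 1.0 - strength / 2.0 + strength * u**2
    return ResponseCurve(wn, factor)


def _baseline(wn: np.ndarray, amplitude: float,
              rng: np.random.Generator) -> np.ndarray:
    """Smooth per-spectrum baseline drift: jittered low-order polynomial."""
    if amplitude == 0:
        return np.zeros_like(wn)
    u = (wn - wn[0]) / (wn[-1] - wn[0])
    p0 = 1.0 * (1.0 + 0.2 * rng.standard_normal())
    p1 = -0.4 * (1.0 + 0.3 * rng.standard_normal())
    p2 = 0.20 * (1.0 + 0.3 * rng.standard_normal())
    base = amplitude * (p0 + p1 * u + p2 * u**2)
    return np.clip(base, 0.0, None)


def generate_ev_spectrum(
    profile: ClassProfile,
    truths: list[ComponentTruth],
    axis: AxisMap,
    seed: int,
    *,
    scale: float = 400.0,
    baseline_amplitude: float = 150.0,
    pbs: np.ndarray | None = None,
    response: ResponseCurve | None = None,
    scale_jitter: float = 0.15,
) -> RamanSpectrum:
    """Simulate one trapped-EV acquisition.

    The signal is ``scale`` x (Dirichlet-perturbed convex combination of the
    component truths); a smooth baseline, the PBS background, heteroscedastic
    Gaussian noise (variance affine in the total count level, approximating
    shot noise) and Poisson-count cosmic spikes of amplitude >= 20x the local
    noise sigma are added on top.  The realized mixing weights are recorded in
    the metadata.  A fixed seed gives byte-identical output.
    """
    names = [t.name for t in truths]
    if list(names) != list(COMPONENT_ORDER):
        raise ValueError("truths must cover all components in canonical order")
    rng = np.random.default_rng(seed)
    wn = axis.wavenumbers()

    mean_w = np.asarray(profile.mean_weights, dtype=float)
    if math.isinf(profile.weight_dispersion):
        w = mean_w.copy()
    else:
        alpha = np.maximum(profile.weight_dispersion * mean_w, 1e-12)
        w = rng.dirichlet(alpha)

    amp = scale * math.exp(scale_jitter * rng.standard_normal()) \
        if scale_jitter > 0 else scale
    signal = amp * sum(wi * t.spectrum for wi, t in zip(w, truths))
    base = _baseline(wn, baseline_amplitude, rng)
    background = base + (pbs if pbs is not None else 0.0)
    total = signal + background

    peak = float(signal.max()) if signal.max() > 0 else amp
    sigma_max = peak / profile.snr
    if math.isinf(profile.snr):
        sigma = np.zeros_like(wn)
        noisy = total.copy()
    else:
        ref = float(total.max())
        # variance affine in the local count level (shot-noise approximation)
        sigma = sigma_max * np.sqrt((0.1 * ref + total) / (1.1 * ref))
        noisy = total + sigma * rng.standard_normal(len(wn))

    n_spikes = rng.poisson(profile.spike_rate)
    spike_channels = []
    if n_spikes > 0:
        spike_channels = sorted(rng.choice(len(wn), size=n_spikes, replace=False))
        for ch in spike_channels:
            local_sigma = sigma[ch] if sigma[ch] > 0 else max(peak, 1.0) * 1e-3
            noisy[ch] += (20.0 + rng.exponential(30.0)) * local_sigma

    if response is not None:
        # the instrument's relative response attenuates the recorded counts;
        # preprocessing multiplies by the correction factor to undo it
        noisy = noisy / response.interpolated(wn)

    meta = {
        "label": profile.class_name,
        "acquisition_time": profile.acquisition_time,
        "n_spikes": int(n_spikes),
        "scale": amp,
    }
    meta.update({f"w_{n}": float(wi) for n, wi in zip(COMPONENT_ORDER, w)})
    return RamanSpectrum(np.arange(len(wn)), wn, noisy, meta)


@dataclass
class SimConfig:
    """Configuration of one simulated acquisition batch."""

    classes: tuple[ClassProfile, ...] = DEFAULT_PROFILES
    axis: AxisMap = field(default_factory=AxisMap)
    n_per_class: int = 100
    seed: int = 0
    baseline_amplitude: float = 150.0
    pbs_amplitude: float = 120.0
    scale: float = 400.0
    batch: str = "I"
    use_response: bool = False

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not self.classes:
            raise ValueError("at least one class profile is required")
        names = [p.class_name for p in self.classes]
        if len(set(names)) != len(names):
            raise ValueError(f"class name collision in profiles: {names}")

    def pbs_background(self) -> np.ndarray:
        return pbs_template(self.axis, self.pbs_amplitude)


def _child_seed(*keys: int) -> int:
    """Deterministic 31-bit child seed from integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def generate_dataset(
    config: SimConfig,
    truths: list[ComponentTruth] | None = None,
) -> SpectraMatrix:
    """Simulate ``n_per_class`` spectra per class on a shared axis.

    Labels, isolation batch and realized ground-truth weights are attached to
    the metadata table.  Distinct batches with identical profiles are obtained
    by distinct ``seed`` (and ``batch`` label) values.
    """
    truths = truths if truths is not None else make_component_truths(config.axis)
    pbs = config.pbs_background()
    response = make_response_curve(config.axis) if config.use_response else None
    spectra = []
    for ci, profile in enumerate(config.classes):
        for si in range(config.n_per_class):
            s = generate_ev_spectrum(
                profile, truths, config.axis,
                _child_seed(config.seed, ci, si),
                scale=config.scale,
                baseline_amplitude=config.baseline_amplitude,
                pbs=pbs, response=response,
            )
            s.meta["id"] = f"{config.batch}-{profile.class_name}-{si:05d}"
            s.meta["batch"] = config.batch
            spectra.append(s)
    return SpectraMatrix.from_spectra(spectra)


def generate_pbs_reference(
    axis: AxisMap,
    n: int,
    seed: int,
    *,
    amplitude: float = 120.0,
    noise_sigma: float = 4.0,
    batch: str = "I",
) -> SpectraMatrix:
    """``n`` noisy realizations of the PBS background (no biomolecular bands)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    template = pbs_template(axis, amplitude)
    wn = axis.wavenumbers()
    X = template[None, :] + noise_sigma * rng.standard_normal((n, len(wn)))
    meta = pd.DataFrame({
        "id": [f"pbs-{batch}-{i:05d}" for i in range(n)],
        "label": ["PBS"] * n,
        "batch": [batch] * n,
    })
    return SpectraMatrix(wn, X, meta)
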