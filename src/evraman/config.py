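"""Run configuration: one structured-text (YAML) document driving the whole
workflow, with strict schema validation (unknown keys rejected) and a single
master seed from which every stage derives its own seed by stable hashing of
the stage name."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocess import PipelineConfig
from .synth import ClassProfile, DEFAULT_PROFILES, AxisMap


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


def _from_mapping(cls, mapping: dict, context: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**mapping)


@dataclass
class SimulateSection:
    n_per_class: int = 100
    n_batches: int = 2
    classes: list | None = None  # list of ClassProfile mappings; None = defaults
    n_channels: int = 1024
    range: tuple[float, float] = (600.0, 1800.0)
    snr: float | None = None
    weight_dispersion: float | None = None
    spike_rate: float | None = None
    pbs_n: int = 200
    use_response: bool = True

    def profiles(self) -> tuple[ClassProfile, ...]:
        if self.classes is None:
            base = DEFAULT_PROFILES
        else:
            base = tuple(
                _from_mapping(ClassProfile, dict(c), "simulate.classes")
                for c in self.classes
            )
        out = []
        for p in base:
            kwargs = {}
            if self.snr is not None:
                kwargs["snr"] = self.snr
            if self.weight_dispersion is not None:
                kwargs["weight_dispersion"] = self.weight_dispersion
            if self.spike_rate is not None:
                kwargs["spike_rate"] = self.spike_rate
            out.append(dataclasses.replace(p, **kwargs) if kwargs else p)
        return tuple(out)

    def axis(self) -> AxisMap:
        return AxisMap(n_channels=self.n_channels,
                       lo=self.range[0], hi=self.range[1])


@dataclass
class InputsSection:
    """Alternative to simulation: pre-acquired bundles on disk."""

    spectra: list = field(default_factory=list)  # one bundle path per batch
    pbs: str | None = None
    response: str | None = None


@dataclass
class DRASection:
    bin_size: float = 50.0
    range: tuple[float, float] | None = None
    per_spectrum: bool = False
    colormap: str = "viridis"


@dataclass
class PLSDASection:
    n_components: int = 3
    splits: int = 10
    exclude_outliers: bool = True
    confidence: float = 0.95


@dataclass
class BTEMSection:
    k: int = 10
    k_nucleic: int = 25
    n_restarts: int = 10
    epochs: int = 200
    moves_per_epoch: int = 50
    targets: list | None = None  # [[name, lo, hi], ...]; None = defaults


@dataclass
class RunConfig:
    """Complete, validated configuration of one end-to-end run."""

    seed: int = 0
    simulate: SimulateSection | None = field(default_factory=SimulateSection)
    inputs: InputsSection | None = None
    preprocess: PipelineConfig = field(default_factory=PipelineConfig)
    dra: DRASection = field(default_factory=DRASection)
    plsda: PLSDASection = field(default_factory=PLSDASection)
    btem: BTEMSection = field(default_factory=BTEMSection)

    def __post_init__(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ConfigError("either 'simulate' or 'inputs' must be provided")
        if self.simulate is None and self.inputs is not None:
            if not self.inputs.spectra:
                raise ConfigError("inputs.spectra must list at least one bundle")
            if self.inputs.pbs is None and self.preprocess.pbs_fraction > 0:
                raise ConfigError(
                    "PBS background subtraction is enabled but inputs.pbs "
                    "names no PBS reference bundle"
                )

    def stage_seed(self, stage: str) -> int:
        """Deterministic 31-bit per-stage seed from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration document."""
        blob = json.dumps(to_dict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [to_dict(x) for x in obj]
    return obj


_SECTION_TYPES = {
    "simulate": SimulateSection,
    "inputs": InputsSection,
    "preprocess": PipelineConfig,
    "dra": DRASection,
    "plsda": PLSDASection,
    "btem": BTEMSection,
}


def config_from_dict(doc: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError("configuration document must be a mapping")
    allowed = {"seed"} | set(_SECTION_TYPES)
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    kwargs: dict = {"seed": int(doc.get("seed", 0))}
    for name, cls in _SECTION_TYPES.items():
        if name in doc:
            section = doc[name]
            if section is None:
                kwargs[name] = None
                continue
            section = dict(section)
            for key in ("range", "crop"):
                if key in section and section[key] is not None:
                    section[key] = tuple(section[key])
            kwargs[name] = _from_mapping(cls, section, name)
        elif name == "inputs":
            kwargs[name] = None
    try:
        return RunConfig(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc or {})


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(to_dict(config), fh, sort_keys=True)
    return path
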