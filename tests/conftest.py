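"""Shared fixtures: synthetic study datasets computed once per session."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import evraman as ev
from evraman.abundance import unit_normalize
from evraman.btem import BandTargetEntropyMinimizer
from evraman.preprocess import BTEM_BRANCH_CONFIG, PipelineConfig, \
    preprocess_pipeline

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def axis():
    return ev.AxisMap()


@pytest.fixture(scope="session")
def truths(axis):
    return ev.make_component_truths(axis)


@pytest.fixture(scope="session")
def truths_cropped(axis, truths):
    """Component truths restricted to the fingerprint crop, re-normalized."""
    wn = axis.wavenumbers()
    mask = (wn >= 600.0) & (wn <= 1800.0)
    out = {}
    for t in truths:
        s = t.spectrum[mask]
        out[t.name] = s / np.linalg.norm(s)
    return out


@pytest.fixture(scope="session")
def pbs_reference(axis):
    return ev.generate_pbs_reference(axis, 200, seed=5)


@pytest.fixture(scope="session")
def two_class_batches(axis, pbs_reference):
    """The default two-class study: 300 spectra/class in each of two
    isolation batches, preprocessed with the standard chain."""
    b1 = ev.generate_dataset(ev.SimConfig(n_per_class=300, seed=101, batch="I"))
    b2 = ev.generate_dataset(ev.SimConfig(n_per_class=300, seed=202, batch="II"))
    cfg = PipelineConfig()
    p1, _ = preprocess_pipeline(b1, pbs_reference, None, cfg)
    p2, _ = preprocess_pipeline(b2, pbs_reference, None, cfg)
    return {"raw1": b1, "raw2": b2, "proc1": p1, "proc2": p2}


@pytest.fixture(scope="session")
def two_pp_report(pbs_reference):
    """CV report for two classes differing by 0.02 in one mean weight."""
    from evraman.plsda import cross_validate
    profiles = (
        ev.ClassProfile("base", (0.32, 0.28, 0.25, 0.15)),
        ev.ClassProfile("shifted", (0.30, 0.30, 0.25, 0.15)),
    )
    m = ev.generate_dataset(
        ev.SimConfig(classes=profiles, n_per_class=300, seed=31))
    proc, _ = preprocess_pipeline(m, pbs_reference, None, PipelineConfig())
    return cross_validate(proc.intensities, proc.labels, n_lv=3, splits=10)


DEMO_CONFIG = {
    "seed": 7,
    "simulate": {"n_per_class": 60, "n_batches": 2, "pbs_n": 100},
    "plsda": {"n_components": 3, "splits": 10},
    "btem": {"n_restarts": 2, "epochs": 40, "moves_per_epoch": 20},
}


@pytest.fixture(scope="session")
def demo_runs(tmp_path_factory):
    """The demo workflow executed twice from one configuration."""
    from evraman.config import config_from_dict
    from evraman.workflow import run_workflow
    root = tmp_path_factory.mktemp("workflow")
    manifests = [
        run_workflow(config_from_dict(dict(DEMO_CONFIG)), root / f"run{i}")
        for i in (1, 2)
    ]
    return root, manifests


@pytest.fixture(scope="session")
def btem_study(axis, pbs_reference):
    """Pooled unmixing study: 600 spectra/class, batch-preprocessed with the
    entropy-minimization branch, unit-normalized, and fitted."""
    raw = ev.generate_dataset(ev.SimConfig(n_per_class=600, seed=11, batch="I"))
    pooled, _ = preprocess_pipeline(raw, pbs_reference, None, BTEM_BRANCH_CONFIG)
    pooled = unit_normalize(pooled)
    unmixer = BandTargetEntropyMinimizer(seed=11).fit(pooled)
    return {"raw": raw, "pooled": pooled, "unmixer": unmixer}
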