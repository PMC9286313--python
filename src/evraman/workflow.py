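"""End-to-end workflow: simulate (or ingest) -> preprocess -> DRA -> PLS-DA
(fit on batch 1, predict batch 2) -> entropy-minimization unmixing ->
convex-mixing abundances.

Every artifact written carries the configuration hash and stage seed in its
header or provenance record, and a ``manifest.json`` maps every output file
to its SHA-256 hash; reruns of the same configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import abundance as ab
from . import dra as dra_mod
from . import io as io_mod
from . import plsda as plsda_mod
from .btem import DEFAULT_TARGETS, BandTargetEntropyMinimizer, SAConfig
from .config import RunConfig
from .preprocess import BTEM_BRANCH_CONFIG, RamanPreprocessor
from .synth import (SimConfig, generate_dataset, generate_pbs_reference,
                    make_response_curve)


class StageError(RuntimeError):
    """A workflow stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_workflow(config: RunConfig, out_root: str | Path) -> dict:
    """Execute the full pipeline, returning a manifest of artifacts."""
    out = Path(out_root)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    artifacts: list[Path] = []

    def provenance(stage: str) -> dict:
        return {"config_hash": chash, "stage": stage,
                "stage_seed": config.stage_seed(stage)}

    # -- simulate or ingest --------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        axis = sim.axis()
        profiles = sim.profiles()
        batches = []
        batch_names = [chr(ord("I"))] if sim.n_batches == 1 else [
            "I" * (i + 1) for i in range(sim.n_batches)
        ]
        for i, bname in enumerate(batch_names):
            cfg = SimConfig(
                classes=profiles, axis=axis, n_per_class=sim.n_per_class,
                seed=config.stage_seed(f"simulate-{bname}"), batch=bname,
                use_response=sim.use_response,
            )
            batches.append(generate_dataset(cfg))
        pbs = generate_pbs_reference(
            axis, sim.pbs_n, config.stage_seed("simulate-pbs"))
        curve = make_response_curve(axis) if sim.use_response else None
        for bname, matrix in zip(batch_names, batches):
            p = out / f"spectra_batch_{bname}.npz"
            io_mod.save_bundle(matrix, p, provenance("simulate"))
            artifacts.append(p)
        p = out / "pbs_reference.npz"
        io_mod.save_bundle(pbs, p, provenance("simulate"))
        artifacts.append(p)
    else:
        try:
            batches = [io_mod.read_spectra(p) for p in config.inputs.spectra]
            pbs = (io_mod.read_spectra(config.inputs.pbs)
                   if config.inputs.pbs else None)
        except Exception as exc:
            raise StageError("ingest", str(exc)) from exc
        curve = None

    # -- preprocess ----------------------------------------------------------
    try:
        pre = RamanPreprocessor(config.preprocess).fit(pbs, curve)
        processed = [pre.transform(b) for b in batches]
    except Exception as exc:
        raise StageError("preprocess", str(exc)) from exc
    for matrix, original in zip(processed, batches):
        bname = original.meta["batch"].iloc[0] if "batch" in original.meta else "I"
        p = out / f"processed_batch_{bname}.npz"
        io_mod.save_bundle(matrix, p, provenance("preprocess"))
        artifacts.append(p)

    # -- DRA -----------------------------------------------------------------
    try:
        heatmap = dra_mod.build_dra(
            processed[0], bin_size=config.dra.bin_size,
            range=config.dra.range,
            rows="spectrum" if config.dra.per_spectrum else "class",
        )
        p = out / "dra.csv"
        io_mod.write_csv_with_provenance(
            heatmap.to_frame(), p, provenance("dra"), index=True)
        artifacts.append(p)
        p = out / "dra.png"
        dra_mod.render_dra(heatmap, config.dra.colormap, p)
        artifacts.append(p)
    except Exception as exc:
        raise StageError("dra", str(exc)) from exc

    # -- PLS-DA --------------------------------------------------------------
    try:
        train = processed[0]
        X, y = train.intensities, train.labels
        model = plsda_mod.PLSDAClassifier(
            n_components=config.plsda.n_components,
            confidence=config.plsda.confidence,
        ).fit(X, y)
        excluded: list = []
        if config.plsda.exclude_outliers:
            model, keep, _ = plsda_mod.exclude_outliers(model, X, y)
            excluded = [i for i in train.ids[~keep]]
            X, y = X[keep], y[keep]
        cv = plsda_mod.cross_validate(
            X, y, n_lv=config.plsda.n_components, splits=config.plsda.splits)
        cv.excluded_ids = excluded
        reports = {"cross_validation": cv}
        if len(processed) > 1:
            test = processed[1]
            reports["prediction"] = plsda_mod.predict_report(
                model, test.intensities, test.labels)
        for name, report in reports.items():
            p = out / f"plsda_{name}.csv"
            io_mod.write_csv_with_provenance(
                report.summary_frame(), p, provenance("plsda"), index=True)
            artifacts.append(p)
        pseudo = pd.DataFrame(
            model.x_loadings_, index=train.wavenumbers,
            columns=[f"LV{a + 1}" for a in range(model.n_components)])
        p = out / "plsda_pseudospectra.csv"
        io_mod.write_csv_with_provenance(pseudo, p, provenance("plsda"),
                                         index=True)
        artifacts.append(p)
        p = out / "plsda_scores.png"
        plsda_mod.plot_scores(model, X, y, p)
        artifacts.append(p)
    except Exception as exc:
        raise StageError("plsda", str(exc)) from exc

    # -- BTEM ----------------------------------------------------------------
    try:
        pooled_raw = batches[0]
        btem_pre = RamanPreprocessor(BTEM_BRANCH_CONFIG).fit(pbs, curve)
        pooled = ab.unit_normalize(btem_pre.transform(pooled_raw))
        targets = (DEFAULT_TARGETS if config.btem.targets is None
                   else tuple((n, lo, hi) for n, lo, hi in config.btem.targets))
        unmixer = BandTargetEntropyMinimizer(
            targets=targets, k=config.btem.k, k_nucleic=config.btem.k_nucleic,
            n_restarts=config.btem.n_restarts,
            seed=config.stage_seed("btem"),
            sa_config=SAConfig(epochs=config.btem.epochs,
                               moves_per_epoch=config.btem.moves_per_epoch),
        ).fit(pooled)
        comp_df = pd.DataFrame(
            {c.name: c.spectrum for c in unmixer.components_},
            index=pooled.wavenumbers)
        p = out / "btem_components.csv"
        io_mod.write_csv_with_provenance(comp_df, p, provenance("btem"),
                                         index=True)
        artifacts.append(p)
        meta = {c.name: {"entropy": c.entropy, "k": c.k,
                         "restarts": [r["objective"] for r in c.restarts_log]}
                for c in unmixer.components_}
        p = out / "btem_metadata.json"
        p.write_text(json.dumps(
            {"provenance": provenance("btem"), "components": meta},
            indent=2, sort_keys=True))
        artifacts.append(p)
    except Exception as exc:
        raise StageError("btem", str(exc)) from exc

    # -- abundances ----------------------------------------------------------
    try:
        profiles = ab.fit_abundances(pooled, unmixer.components_)
        names = unmixer.component_names_
        pf = ab.profiles_frame(profiles, names)
        p = out / "abundances.csv"
        io_mod.write_csv_with_provenance(pf, p, provenance("abundance"))
        artifacts.append(p)
        summary = ab.summarize_composition(profiles, names)
        p = out / "composition_summary.csv"
        io_mod.write_csv_with_provenance(
            summary.means, p, provenance("abundance"), index=True)
        artifacts.append(p)
        p = out / "composition.png"
        ab.plot_composition(summary, profiles, p)
        artifacts.append(p)
    except Exception as exc:
        raise StageError("abundance", str(exc)) from exc

    manifest = {
        "config_hash": chash,
        "files": {a.name: _sha256(a) for a in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
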