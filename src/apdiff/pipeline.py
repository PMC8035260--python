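"""End-to-end orchestration: scan -> differences -> training -> evaluation
-> drug validation, with scale presets and a reproducibility manifest.

Presets fix every free parameter:

* ``full``    — step 0.01 (1,980 variants), 10 beats at CL 1,000 ms.
* ``reduced`` — step 0.05 (380 variants), 10 beats; desk-scale run that
  preserves the classification result qualitatively.
* ``fixture`` — step 0.25 (60 variants), 3 beats; test-suite scale.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .ap_features import apd_statistics, difference_dataset, measure_apd
from .cell_model import StimulusProtocol
from .classifier import MLPConfig, split_dataset, train, predict
from .drug_block import (
    evaluate_drug_dataset,
    generate_drug_dataset,
    load_drug_table,
    sample_drug_params,
)
from .metrics import evaluate
from .scan_generator import build_grid, generate_library

__all__ = ["RunConfig", "PipelineResult", "run_full_pipeline", "PRESETS"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Fully determined pipeline configuration."""

    preset: str = "reduced"
    grid_step: float = 0.05
    grid_lo: float = 0.01
    grid_hi: float = 1.99
    n_beats: int = 10
    cycle_length: float = 1000.0
    stimulus_amplitude: float = -80.0
    stimulus_duration: float = 1.0
    stimulus_onset: float = 50.0
    sample_interval: float = 2.0
    dt: float = 0.02
    seed: int = 0
    hidden_units: int = 130
    learning_rate: float = 0.001
    epochs: int = 500
    batch_size: int = 32
    split_fraction: float = 0.8
    run_drugs: bool = True
    drug_table: str | None = None      # CSV path; None = bundled synthetic
    n_boot: int = 2000
    n_draw: int = 10
    out_dir: str | None = None

    def protocol(self) -> StimulusProtocol:
        return StimulusProtocol(amplitude=self.stimulus_amplitude,
                                duration=self.stimulus_duration,
                                cycle_length=self.cycle_length,
                                n_beats=self.n_beats,
                                onset=self.stimulus_onset)

    def mlp_config(self) -> MLPConfig:
        return MLPConfig(hidden_units=self.hidden_units,
                         learning_rate=self.learning_rate,
                         epochs=self.epochs, batch_size=self.batch_size,
                         seed=self.seed, split_fraction=self.split_fraction)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


PRESETS: dict[str, dict] = {
    "full": {"grid_step": 0.01, "n_beats": 10},
    "reduced": {"grid_step": 0.05, "n_beats": 10},
    "fixture": {"grid_step": 0.25, "n_beats": 3},
}


def make_config(preset: str = "reduced", **overrides) -> RunConfig:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    kwargs = {"preset": preset, **PRESETS[preset], **overrides}
    return RunConfig(**kwargs)


@dataclass
class PipelineResult:
    config: RunConfig
    library: object
    apd_table: list
    model: object
    report: object
    drug_report: object | None
    manifest: dict


def run_full_pipeline(config: RunConfig,
                      progress: bool = False) -> PipelineResult:
    """Run every stage; deterministic given ``config.seed``.

    Artifacts (library HDF5, APD CSV, model weights, JSON reports,
    manifest) are written under ``config.out_dir`` when set.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    protocol = config.protocol()

    stage = "scan"
    try:
        grid = build_grid(config.grid_step, config.grid_lo, config.grid_hi)
        log.info("scan: %d conditions", len(grid))
        library = generate_library(
            grid, protocol, sample_interval=config.sample_interval,
            dt=config.dt, step=config.grid_step,
            out_path=(out / "library.h5") if out else None,
            progress=progress)
        if library.failures:
            log.warning("scan: %d failed conditions", len(library.failures))

        stage = "features"
        apd_table = apd_statistics(library)
        X, y = difference_dataset(library)
        if out is not None:
            import pandas as pd
            pd.DataFrame([asdict(r) for r in apd_table]).to_csv(
                out / "apd_statistics.csv", index=False)

        stage = "training"
        mlp = config.mlp_config()
        train_set, test_set = split_dataset((X, y), mlp)
        model = train(train_set, mlp)
        if out is not None:
            model.save(out / "model.npz")

        stage = "evaluation"
        proba, pred = predict(model, (test_set[0], None))
        report = evaluate(test_set[1], pred, proba)
        if out is not None:
            report.save(out / "report.json")

        drug_report = None
        if config.run_drugs:
            stage = "drug_validation"
            base_table = (load_drug_table(config.drug_table)
                          if config.drug_table else None)
            names = (sorted(base_table["drug"].unique()) if base_table is not None
                     else ["ibutilide", "dofetilide", "diltiazem"])
            specs = [sample_drug_params(n, base_table, config.n_boot,
                                        config.n_draw,
                                        seed=config.seed + 101 + i)
                     for i, n in enumerate(names)]
            dataset = generate_drug_dataset(
                specs, protocol, standard=library.standard,
                sample_interval=config.sample_interval, dt=config.dt)
            drug_report = evaluate_drug_dataset(model, dataset)
            if out is not None:
                drug_report.save(out / "drug_report.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_conditions": len(library),
        "n_failures": len(library.failures),
        "standard_apd90_ms": measure_apd(library.standard),
        "macro_f1": report.macro_f1,
        "accuracy": report.accuracy,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    if drug_report is not None:
        manifest["drug_macro_stats"] = {
            "accuracy": drug_report.accuracy,
        }
    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(config=config, library=library, apd_table=apd_table,
                          model=model, report=report,
                          drug_report=drug_report, manifest=manifest)
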