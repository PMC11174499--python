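"""One-command reproducible run: generate -> preprocess -> kinetics -> fit -> report.

A :class:`RunConfig` (YAML/JSON document) fixes every stage; all
randomness flows from its single seed, so two runs with the same config
produce identical artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import chemometrics, evaluate, kinetics, preprocess, simulate, spectra

log = logging.getLogger("ramantsd")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    generator: simulate.GeneratorConfig | None = None
    manifest: str | None = None  # alternative input: real spectra on disk
    window: tuple = (315.0, 1800.0)
    baseline: preprocess.BaselineParams = field(default_factory=preprocess.BaselineParams)
    outlier_k: float = 3.0
    models: chemometrics.TSDStudyConfig = field(default_factory=chemometrics.TSDStudyConfig)
    kinetic_bands: tuple = ((890.0, 8.0), (1369.0, 8.0), (1577.0, 8.0))
    seed: int = 0
    output_dir: str = "tsd_run"

    def to_dict(self) -> dict:
        import dataclasses

        return {
            "generator": (
                simulate.config_to_dict(self.generator) if self.generator else None
            ),
            "manifest": self.manifest,
            "window": list(self.window),
            "baseline": dataclasses.asdict(self.baseline),
            "outlier_k": self.outlier_k,
            "models": {
                "plsda_lv": self.models.plsda_lv,
                "plsr_lv": self.models.plsr_lv,
                "cv_splits": self.models.cv_splits,
                "class_boundary": list(self.models.class_boundary),
                "log_time": self.models.log_time,
            },
            "kinetic_bands": [list(b) for b in self.kinetic_bands],
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        models = doc.get("models", {})
        cfg = cls(
            generator=(
                simulate.config_from_dict(doc["generator"]) if doc.get("generator") else None
            ),
            manifest=doc.get("manifest"),
            window=tuple(doc.get("window", (315.0, 1800.0))),
            baseline=preprocess.BaselineParams(**doc.get("baseline", {})),
            outlier_k=float(doc.get("outlier_k", 3.0)),
            models=chemometrics.TSDStudyConfig(
                plsda_lv=int(models.get("plsda_lv", 3)),
                plsr_lv=int(models.get("plsr_lv", 5)),
                cv_splits=int(models.get("cv_splits", 10)),
                class_boundary=tuple(models.get("class_boundary", (72.0, 96.0))),
                log_time=bool(models.get("log_time", False)),
            ),
            kinetic_bands=tuple(tuple(b) for b in doc.get("kinetic_bands",
                                                          ((890.0, 8.0), (1369.0, 8.0), (1577.0, 8.0)))),
            seed=int(doc.get("seed", 0)),
            output_dir=str(doc.get("output_dir", "tsd_run")),
        )
        return cfg

    @classmethod
    def default(cls, seed: int = 0, output_dir: str = "tsd_run") -> "RunConfig":
        gen = simulate.default_config(seed=seed)
        return cls(generator=gen, seed=seed, output_dir=output_dir)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def run_pipeline(config: RunConfig, write_artifacts: bool = True):
    """Execute all stages; returns ``(EvaluationReport, kinetics_table, results)``.

    Any stage error aborts with a stage-labeled message; partial outputs
    are retained next to a FAILED marker file.
    """
    out_dir = Path(config.output_dir)
    if write_artifacts:
        out_dir.mkdir(parents=True, exist_ok=True)
    digest = evaluate.config_digest(config.to_dict())
    stage = "setup"
    try:
        stage = "generate/load"
        t0 = time.perf_counter()
        if config.manifest is not None:
            dataset = spectra.read_dataset(config.manifest)
            log.info("loaded %d spectra from manifest %s", len(dataset), config.manifest)
        else:
            if config.generator is None:
                raise ValueError("config needs either a generator or a manifest")
            gen = config.generator
            dataset = simulate.generate_dataset(gen)
            log.info(
                "generated %d spectra (%d donors x %d hours x %d spots), seed=%d",
                len(dataset), len(gen.donors), len(gen.schedule),
                gen.spots_per_map, gen.seed,
            )
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "preprocess"
        t0 = time.perf_counter()
        processed, prep_report = preprocess.preprocess_dataset(
            dataset, window=config.window, baseline_params=config.baseline,
            outlier_k=config.outlier_k,
        )
        log.info(
            "preprocessed %d spectra, removed %d outliers (%s) in %.2fs",
            prep_report.n_input, prep_report.n_removed_outliers,
            prep_report.removed_ids, time.perf_counter() - t0,
        )

        stage = "kinetics"
        t0 = time.perf_counter()
        kin_table = kinetics.kinetics_report(processed, config.kinetic_bands)
        log.info("fit %d kinetic bands in %.2fs", len(kin_table), time.perf_counter() - t0)

        stage = "fit"
        t0 = time.perf_counter()
        donors = processed.donors
        if len(donors) < 2:
            raise ValueError("need two donors (calibration + external validation)")
        train = processed.select(donor_id=donors[0])
        test = processed.select(donor_id=donors[1])
        log.info(
            "calibration donor %s: %d spectra; external donor %s: %d spectra",
            donors[0], len(train), donors[1], len(test),
        )
        results = chemometrics.TSDStudy(train, test, config.models).fit()
        log.info("models fit in %.2fs", time.perf_counter() - t0)

        stage = "report"
        report = evaluate.evaluate_study(results)
        report.config_hash = digest
        report.seed = config.seed
        report.schedule = sorted(float(h) for h in set(results.hour_true["external"]))
        if write_artifacts:
            written = evaluate.render_report(report, out_dir, results=results)
            kin_path = out_dir / "kinetics_table.csv"
            kin_table.to_csv(kin_path, index=False)
            written.append(kin_path)
            prep_path = out_dir / "preprocess_report.json"
            with open(prep_path, "w") as fh:
                json.dump(
                    {
                        "n_input": prep_report.n_input,
                        "n_removed_outliers": prep_report.n_removed_outliers,
                        "removed_ids": prep_report.removed_ids,
                        "window": list(prep_report.window),
                        "config_hash": digest,
                        "seed": config.seed,
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
            written.append(prep_path)
            config.to_yaml(out_dir / "config.yaml")
            log.info("wrote %d artifacts to %s", len(written) + 1, out_dir)
        return report, kin_table, results
    except Exception as exc:
        if write_artifacts:
            out_dir.mkdir(parents=True, exist_ok=True)
            (out_dir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
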