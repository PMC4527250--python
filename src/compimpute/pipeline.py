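"""End-to-end orchestration: simulate -> QC -> mask -> impute -> evaluate -> relate.

One :class:`ExperimentConfig` (JSON/YAML-compatible) drives the whole run and
produces a results grid with one row per scenario x panel (CR %, allelic R²,
mask size, fallback fraction) plus per-animal breakdowns and the
relatedness regression.  A single mandatory top-level seed feeds every
stage through deterministically derived sub-seeds, so identical config +
seed yields a byte-identical grid.  Intermediate artifacts (VCFs, mask
indices, per-animal CR tables) are persisted so any grid cell can be
re-derived by calling the evaluation functions directly on them.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataio, evaluate, imputer, panels, qc, relate, simdata
from .dataio import DataValidationError

log = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Configuration of a full imputation-strategy experiment."""

    seed: int
    simulation: simdata.SimulationConfig | None = None
    input_vcf: str | None = None
    input_samples: str | None = None
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    panel_ladder: list | None = None      # None -> full density ladder
    scenarios: tuple = ("S1",)
    scheme: imputer.WindowScheme = field(default_factory=imputer.WindowScheme)
    freq_source: str = "all_samples"
    regression_panels: tuple = ()         # panels to regress CR on relatedness
    output_dir: str = "results"
    persist_artifacts: bool = True

    def __post_init__(self) -> None:
        for s in self.scenarios:
            if s not in panels.SCENARIO_NAMES:
                raise DataValidationError(
                    f"config requests undefined scenario {s!r}")
        if self.simulation is None and self.input_vcf is None:
            raise DataValidationError(
                "config needs either a simulation block or input paths")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "seed" not in d:
            raise DataValidationError("config requires a top-level seed")
        sim = d.pop("simulation", None)
        if sim is not None:
            sim.setdefault("seed", d["seed"])
            sim = simdata.SimulationConfig.from_dict(sim)
        thr = qc.QCThresholds(**d.pop("qc_thresholds", {}))
        scheme_d = d.pop("scheme", {})
        if "lengths" in scheme_d:
            scheme_d["lengths"] = tuple(scheme_d["lengths"])
        scheme = imputer.WindowScheme(**scheme_d)
        return cls(seed=int(d.pop("seed")), simulation=sim,
                   qc_thresholds=thr, scheme=scheme,
                   scenarios=tuple(d.pop("scenarios", ("S1",))),
                   regression_panels=tuple(d.pop("regression_panels", ())),
                   **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        text = Path(path).read_text()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass
class ExperimentResult:
    grid: pd.DataFrame
    per_animal: pd.DataFrame
    regressions: pd.DataFrame
    qc_report: qc.QCReport
    scenarios: dict
    grm: relate.GRM
    output_dir: Path


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full pipeline; see module docstring."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- data ----------------------------------------------------------
    if config.simulation is not None:
        sim = simdata.simulate_dataset(config.simulation)
        truth, observed = sim.truth, sim.observed
        samples, mmap = sim.samples, sim.marker_map
    else:
        observed, mmap = dataio.read_genotypes(config.input_vcf)
        samples = dataio.read_sample_table(config.input_samples)
        truth = observed  # user data: the HD file is the truth to mask
        sim = None

    # ---- QC (on the observed matrix; truth subset identically) ---------
    try:
        observed_f, mmap_f, report = qc.apply_qc(observed, mmap,
                                                 config.qc_thresholds)
    except DataValidationError as exc:
        raise DataValidationError(f"stage qc: {exc}") from exc
    kept_markers = mmap.indices_of(mmap_f.marker_ids)
    kept_samples = truth.sample_index(observed_f.sample_ids)
    truth_f = truth.subset(sample_idx=kept_samples, marker_idx=kept_markers)
    samples_f = dataio.SampleTable(
        samples.table[samples.table["sample_id"].isin(observed_f.sample_ids)])
    if config.persist_artifacts:
        report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        dataio.write_marker_map(mmap_f, outdir / "markers_postqc.tsv")
        dataio.write_sample_table(samples_f, outdir / "samples_postqc.tsv")

    # ---- relationships -------------------------------------------------
    grm = relate.compute_grm(observed_f, freq_source=config.freq_source)

    # ---- panels --------------------------------------------------------
    if config.panel_ladder is None:
        ladder = panels.make_density_ladder(mmap_f)
    else:
        ladder = [panels.make_synthetic_panel(mmap_f, int(n), name=str(name))
                  for name, n in config.panel_ladder]

    # ---- scenario x panel grid ----------------------------------------
    grid_rows = []
    animal_rows = []
    reg_rows = []
    scen_objs = {}
    for sname in config.scenarios:
        try:
            scen = panels.build_scenario(samples_f, sname)
        except DataValidationError as exc:
            raise DataValidationError(f"stage scenario {sname}: {exc}") from exc
        scen_objs[sname] = scen
        maxrel = relate.max_relationship(grm, scen)
        for panel in ladder:
            cell = f"{sname}_{panel.name}"
            masked = panels.mask_to_panel(truth_f, mmap_f, panel,
                                          scen.target_ids, scen.reference_ids)
            library = imputer.build_library(masked.reference, mmap_f,
                                            masked.panel)
            result = imputer.impute_dataset(masked, mmap_f, config.scheme,
                                            library=library)
            metrics = evaluate.accuracy_report(result, masked.truth_targets,
                                               mmap_f)
            grid_rows.append({"scenario": sname, "panel": panel.name,
                              "panel_size": len(panel),
                              "n_reference": len(scen.reference_ids),
                              "n_target": len(scen.target_ids),
                              "mask_size": metrics["n_masked"],
                              "cr_percent": metrics["cr_percent"],
                              "allelic_r2": metrics["allelic_r2"],
                              "fallback_fraction": metrics["fallback_fraction"]})
            per_animal = evaluate.concordance_rate(
                masked.truth_targets, result.best_guess, result.mask,
                sample_ids=masked.target_ids, by="animal")
            per_animal.insert(0, "panel", panel.name)
            per_animal.insert(0, "scenario", sname)
            pa = per_animal.merge(maxrel, left_on="cell", right_on="target_id")
            animal_rows.append(pa)
            if panel.name in config.regression_panels:
                reg = relate.regress_cr_on_relationship(
                    pa["concordance"].to_numpy(),
                    pa["max_relationship"].to_numpy())
                reg_rows.append({"scenario": sname, "panel": panel.name,
                                 "intercept": reg.coefficients[0],
                                 "linear": reg.coefficients[1],
                                 "quadratic": reg.coefficients[2],
                                 "linear_pvalue": reg.linear_pvalue})
            if config.persist_artifacts:
                dataio.write_genotypes(masked.target, mmap_f,
                                       outdir / f"{cell}_target_masked.vcf")
                truth_gm = dataio.GenotypeMatrix(masked.target_ids,
                                                 masked.truth_targets)
                dataio.write_genotypes(truth_gm, mmap_f,
                                       outdir / f"{cell}_target_truth.vcf")
                imputed_gm = dataio.GenotypeMatrix(masked.target_ids,
                                                   result.best_guess)
                dataio.write_genotypes(imputed_gm, mmap_f,
                                       outdir / f"{cell}_imputed.vcf",
                                       dosages=result.dosage)
                pa.drop(columns=["target_id"]).to_csv(
                    outdir / f"{cell}_per_animal.tsv", sep="\t", index=False,
                    float_format="%.6f")
            log.info("cell %s: CR %.2f%%, R2 %s", cell, metrics["cr_percent"],
                     f"{metrics['allelic_r2']:.4f}"
                     if np.isfinite(metrics["allelic_r2"]) else "undef")

    grid = pd.DataFrame(grid_rows)
    per_animal_all = (pd.concat(animal_rows, ignore_index=True)
                      .drop(columns=["target_id"]))
    regressions = pd.DataFrame(
        reg_rows, columns=["scenario", "panel", "intercept", "linear",
                           "quadratic", "linear_pvalue"])
    grid.to_csv(outdir / "results_grid.tsv", sep="\t", index=False,
                float_format="%.6f")
    if config.persist_artifacts:
        per_animal_all.to_csv(outdir / "per_animal_cr.tsv", sep="\t",
                              index=False, float_format="%.6f")
        if len(regressions):
            regressions.to_csv(outdir / "relatedness_regressions.tsv",
                               sep="\t", index=False, float_format="%.6f")
    log.info("experiment finished in %.1f s (wall clock; logged only)",
             time.time() - t0)
    return ExperimentResult(grid, per_animal_all, regressions, report,
                            scen_objs, grm, outdir)
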