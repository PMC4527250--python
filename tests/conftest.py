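"""Shared fixtures: tiny hand-built datasets and one heavy seeded simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import compimpute as ci

SEED = 20250927


def spread_strata(group, sex, n, years):
    base, rem = divmod(n, len(years))
    return [(group, sex, y, base + (1 if i < rem else 0))
            for i, y in enumerate(years) if base + (1 if i < rem else 0)]


def make_sample_table(rows):
    """rows: (sample_id, sex, birth_year, group[, sire, dam])"""
    recs = []
    for r in rows:
        recs.append({"sample_id": r[0], "sex": r[1], "birth_year": r[2],
                     "genetic_group": r[3],
                     "sire_id": r[4] if len(r) > 4 else None,
                     "dam_id": r[5] if len(r) > 5 else None})
    return ci.SampleTable(pd.DataFrame(recs))


@pytest.fixture(scope="session")
def tiny_map():
    """10 markers on two chromosomes."""
    return ci.MarkerMap(pd.DataFrame({
        "marker_id": [f"m{i}" for i in range(10)],
        "chromosome": ["1"] * 5 + ["2"] * 5,
        "position_bp": [1000 * (i % 5 + 1) for i in range(10)],
        "position_cm": [float(i % 5 + 1) for i in range(10)],
        "allele_a": ["A"] * 10,
        "allele_b": ["B"] * 10,
    }))


@pytest.fixture(scope="session")
def ladder_run():
    """One seeded simulation at study scale plus the full density ladder.

    5 chromosomes x 4,000 markers; a year-split with 300 reference and 60
    target animals (2005-born targets half paternal half-sibs of the
    reference, half from sires/dams used for 2005 only).  Shared by the
    density-monotonicity and relatedness-effect checks.
    """
    pre = list(range(1999, 2005))
    strata = (spread_strata("CANCHIM", "M", 100, pre)
              + spread_strata("CANCHIM", "F", 115, pre)
              + spread_strata("MA", "M", 55, pre)
              + spread_strata("MA", "F", 30, pre)
              + [("CANCHIM", "M", 2005, 20), ("CANCHIM", "F", 2005, 20),
                 ("MA", "M", 2005, 10), ("MA", "F", 2005, 10)])
    cfg = ci.SimulationConfig(design=ci.PedigreeDesign(cohort=tuple(strata)),
                              seed=SEED)
    sim = ci.simulate_dataset(cfg)
    observed, mmap, _ = ci.apply_qc(sim.observed, sim.marker_map)
    kept = sim.marker_map.indices_of(mmap.marker_ids)
    ksam = sim.truth.sample_index(observed.sample_ids)
    truth = sim.truth.subset(sample_idx=ksam, marker_idx=kept)
    samples = ci.SampleTable(sim.samples.table[
        sim.samples.table["sample_id"].isin(observed.sample_ids)])
    scen = ci.build_scenario(samples, "S1")
    reference_ids = scen.reference_ids[:300]
    target_ids = scen.target_ids[:60]
    grm = ci.compute_grm(observed)
    maxrel = grm.submatrix(target_ids, reference_ids).max(axis=1)

    rows = []
    for panel in ci.make_density_ladder(mmap):
        masked = ci.mask_to_panel(truth, mmap, panel, target_ids, reference_ids)
        library = ci.build_library(masked.reference, mmap, panel)
        result = ci.impute_dataset(masked, mmap, library=library)
        metrics = ci.accuracy_report(result, masked.truth_targets, mmap)
        per_animal = ci.concordance_rate(masked.truth_targets,
                                         result.best_guess, result.mask,
                                         sample_ids=target_ids, by="animal")
        rows.append({"panel": panel.name, "size": len(panel), **metrics,
                     "per_animal": per_animal})
    return {"rows": rows, "maxrel": maxrel, "observed": observed,
            "truth": truth, "mmap": mmap, "samples": samples,
            "reference_ids": reference_ids, "target_ids": target_ids}
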