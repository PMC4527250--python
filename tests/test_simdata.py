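"""Simulator correctness: divergence model, pedigree rules, gene drop, noise."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import compimpute as ci
from compimpute.dataio import MISSING, DataValidationError


# ---------------------------------------------------------------------------
# Ancestral frequencies
# ---------------------------------------------------------------------------


def test_zero_divergence_limit():
    """As fst -> 0, both population frequencies collapse onto the base."""
    model = ci.AncestralModel(n_chromosomes=1, markers_per_chromosome=2000,
                              fst=1e-5)
    base, p1, p2 = ci.simulate_ancestral_frequencies(model, seed=3)
    assert np.max(np.abs(p1 - base)) < 0.05
    assert np.max(np.abs(p2 - base)) < 0.05


def test_fst_recovered_by_moment_estimator():
    """A Weir-style moment estimator on 2e4 markers recovers fst 0.15 +-0.02.

    Under the Balding-Nichols draw, E[(p_k - p)^2] = fst * p(1-p), so the
    ratio-of-sums estimator over markers is consistent for fst.
    """
    model = ci.AncestralModel(fst=0.15)  # 5 x 4000 markers
    base, p1, p2 = ci.simulate_ancestral_frequencies(model, seed=11)
    num = ((p1 - base) ** 2 + (p2 - base) ** 2) / 2.0
    fst_hat = num.sum() / (base * (1 - base)).sum()
    assert abs(fst_hat - 0.15) < 0.02


def test_frequency_draws_deterministic_under_seed():
    model = ci.AncestralModel(n_chromosomes=1, markers_per_chromosome=100)
    a = ci.simulate_ancestral_frequencies(model, seed=5)
    b = ci.simulate_ancestral_frequencies(model, seed=5)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)


def test_invalid_fst_rejected():
    with pytest.raises(DataValidationError, match="fst"):
        ci.AncestralModel(fst=1.5)


# ---------------------------------------------------------------------------
# Pedigree construction
# ---------------------------------------------------------------------------


def expected_ancestry(ped):
    t = ped.table
    anc = {}
    for r in t.itertuples(index=False):
        if r.group == "CHAROLAIS":
            anc[r.id] = 1.0
        elif r.group == "ZEBU":
            anc[r.id] = 0.0
        else:
            anc[r.id] = (anc[r.sire] + anc[r.dam]) / 2.0
    return anc


def test_crossing_rules_reach_expected_ancestry():
    """F1 = 1/2, Canchim = 5/8, MA = 21/32 Charolais, exactly by pedigree."""
    ped = ci.build_pedigree(ci.PedigreeDesign(), seed=0)
    anc = expected_ancestry(ped)
    t = ped.table
    by_group = lambda g: [anc[i] for i in t.loc[t["group"] == g, "id"]]
    assert set(by_group("F1")) == {0.5}
    assert set(by_group("CANCHIM")) == {0.625}
    assert set(by_group("MA")) == {21 / 32}
    assert abs(21 / 32 - 0.65625) == 0.0


def test_default_cohort_matches_design_counts():
    ped = ci.build_pedigree(ci.PedigreeDesign(), seed=0)
    st = ped.sample_table().table
    counts = st["genetic_group"].value_counts().to_dict()
    assert counts == {"CANCHIM": 283, "MA": 112, "CHAROLAIS": 1}
    assert st["birth_year"].between(1990, 2005).all()
    assert set(st["sex"]) == {"M", "F"}


def test_pedigree_without_founders_rejected():
    with pytest.raises(DataValidationError, match="founder"):
        ci.PedigreeDesign(n_charolais_sires=0)


def test_single_known_parent_rejected():
    df = pd.DataFrame([
        dict(id="f", sire=None, dam=None, sex="M", birth_year=1990,
             group="CHAROLAIS", population="TAURINE", genotyped=False),
        dict(id="x", sire="f", dam=None, sex="F", birth_year=1995,
             group="F1", population=None, genotyped=False)])
    with pytest.raises(DataValidationError, match="both parents"):
        ci.Pedigree(df)


# ---------------------------------------------------------------------------
# Gene drop
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_drop():
    model = ci.AncestralModel(n_chromosomes=2, markers_per_chromosome=500)
    mmap = ci.make_marker_map(model)
    _, p1, p2 = ci.simulate_ancestral_frequencies(model, seed=7)
    ped = ci.build_pedigree(ci.PedigreeDesign(), seed=7)
    drop = ci.gene_drop(ped, (p1, p2), mmap, seed=7)
    return ped, drop, (p1, p2), mmap


def test_founder_genotypes_in_hardy_weinberg(small_drop):
    """Founder-only genotype frequencies agree with HWE at the pop freqs."""
    model = ci.AncestralModel(n_chromosomes=1, markers_per_chromosome=300)
    mmap = ci.make_marker_map(model)
    _, p1, p2 = ci.simulate_ancestral_frequencies(model, seed=9)
    ped = ci.founders_only_pedigree(400)
    drop = ci.gene_drop(ped, (p1, p2), mmap, seed=9)
    g = drop.genotypes.genotypes
    n = g.shape[0]
    pvals = []
    for j in range(mmap.n_markers):
        p = p1[j]
        exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        obs = np.array([(g[:, j] == k).sum() for k in (0, 1, 2)])
        keep = exp > 1e-9
        chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        pvals.append(stats.chi2.sf(chi2, df=keep.sum() - 1))
    # uniform p-values: only a few percent should dip below 0.01
    assert np.mean(np.asarray(pvals) < 0.01) < 0.05


def test_offspring_alleles_come_from_parents(small_drop):
    ped, drop, _, _ = small_drop
    gm = drop.genotypes
    pos = {s: i for i, s in enumerate(gm.sample_ids)}
    t = ped.table
    nonf = t[t["sire"].notna()].sample(20, random_state=0)
    for r in nonf.itertuples(index=False):
        child = gm.phase[pos[r.id]]
        for hap, parent in ((0, r.sire), (1, r.dam)):
            pa = gm.phase[pos[parent]]
            ok = (child[:, hap] == pa[:, 0]) | (child[:, hap] == pa[:, 1])
            assert ok.all()


def test_mendelian_consistency_everywhere(small_drop):
    ped, drop, _, _ = small_drop
    gm = drop.genotypes
    pos = {s: i for i, s in enumerate(gm.sample_ids)}
    g = gm.genotypes.astype(np.int16)
    for r in ped.table.itertuples(index=False):
        if pd.isna(r.sire):
            continue
        c, s, d = g[pos[r.id]], g[pos[r.sire]], g[pos[r.dam]]
        # child must receive one allele from each parent
        lo = (s > 1).astype(int) + (d > 1).astype(int)
        hi = 2 - (s < 1).astype(int) - (d < 1).astype(int)
        assert ((c >= lo) & (c <= hi)).all()


def test_realized_canchim_ancestry_tracks_five_eighths():
    """Origin-tracked Charolais ancestry of Canchim ~ 0.625 at 2e4 markers."""
    sim = ci.simulate_dataset(ci.SimulationConfig(seed=2))
    ca = [s for s in sim.samples.sample_ids if s.startswith("CANCHIM")]
    realized = sim.ancestry[ca].mean()
    assert abs(realized - 0.625) < 0.03


def test_gene_drop_deterministic(small_drop):
    ped, drop, freqs, mmap = small_drop
    again = ci.gene_drop(ped, freqs, mmap, seed=7)
    np.testing.assert_array_equal(drop.genotypes.genotypes,
                                  again.genotypes.genotypes)
    np.testing.assert_array_equal(drop.hap_origins, again.hap_origins)


# ---------------------------------------------------------------------------
# Genotyping noise
# ---------------------------------------------------------------------------


def test_zero_noise_is_identity(small_drop):
    _, drop, _, _ = small_drop
    gm = drop.genotypes
    out = ci.apply_genotyping_noise(gm, 0.0, 0.0, seed=1)
    np.testing.assert_array_equal(out.genotypes, gm.genotypes)
    np.testing.assert_array_equal(out.phase, gm.phase)


def test_missing_rate_binomial():
    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, size=(100, 1000)).astype(np.int8)
    gm = ci.GenotypeMatrix([f"s{i}" for i in range(100)], g)
    out = ci.apply_genotyping_noise(gm, 0.05, 0.0, seed=4)
    frac = (out.genotypes == MISSING).mean()
    assert abs(frac - 0.05) < 0.005


def test_errors_change_code_and_strip_phase(small_drop):
    _, drop, _, _ = small_drop
    gm = drop.genotypes
    out = ci.apply_genotyping_noise(gm, 0.0, 0.2, seed=5)
    changed = out.genotypes != gm.genotypes
    assert 0.1 < changed.mean() < 0.3
    assert (out.genotypes[changed] != MISSING).all()
    assert (out.phase[changed] == MISSING).all()
    # unchanged entries keep phase
    assert (out.phase[~changed] == gm.phase[~changed]).all()


def test_noise_deterministic_and_rates_validated(small_drop):
    _, drop, _, _ = small_drop
    gm = drop.genotypes
    a = ci.apply_genotyping_noise(gm, 0.02, 0.01, seed=6)
    b = ci.apply_genotyping_noise(gm, 0.02, 0.01, seed=6)
    np.testing.assert_array_equal(a.genotypes, b.genotypes)
    with pytest.raises(DataValidationError):
        ci.apply_genotyping_noise(gm, 1.0, 0.0, seed=0)
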