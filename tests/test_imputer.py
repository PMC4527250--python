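"""Window-matching imputer vs exhaustive pair enumeration, plus limit cases."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import compimpute as ci
from compimpute.dataio import MISSING, DataValidationError
from compimpute.imputer import (SOURCE_FALLBACK, SOURCE_MATCH,
                                best_guess_from_dosage)

from test_panels import line_map


def phased_matrix(haps, ids=None):
    """Build a phased GenotypeMatrix from an (2R, M) 0/1 haplotype array."""
    haps = np.asarray(haps, dtype=np.int8)
    n = haps.shape[0] // 2
    phase = np.stack([haps[0::2], haps[1::2]], axis=2)
    g = phase.sum(axis=2).astype(np.int8)
    return ci.GenotypeMatrix(ids or [f"r{i}" for i in range(n)], g, phase)


# ---------------------------------------------------------------------------
# Independent oracle: plain-python re-derivation of the window contract
# ---------------------------------------------------------------------------


def naive_impute(target, haps, typed_idx, n_markers, scheme):
    """Brute-force single-chromosome imputation by full pair enumeration.

    Loops every window, every ordered haplotype pair (i <= j), counts
    mismatches site by site, measures exact-match runs by expansion, and
    accumulates run-length-weighted votes — no shared code with the
    implementation beyond the contract itself.
    """
    typed_idx = list(typed_idx)
    n_typed = len(typed_idx)
    H = np.asarray(haps)
    votes = {m: [0.0, 0.0] for m in range(n_markers)}
    for L in scheme.lengths:
        if L > n_typed:
            continue
        step = max(1, int(round(L * (1 - scheme.overlap))))
        starts = list(range(0, n_typed - L + 1, step))
        if starts[-1] != n_typed - L:
            starts.append(n_typed - L)
        for s0 in starts:
            sites = typed_idx[s0:s0 + L]
            g_w = [int(target[m]) for m in sites]
            valid = [g != MISSING for g in g_w]
            n_valid = sum(valid)
            if n_valid == 0:
                continue
            k_allowed = int(np.floor(scheme.mismatch_tol * n_valid))
            lo = 0 if s0 == 0 else sites[0]
            hi = n_markers - 1 if s0 + L == n_typed else sites[-1]
            for i in range(H.shape[0]):
                for j in range(i, H.shape[0]):
                    match = [not valid[s]
                             or H[i, sites[s]] + H[j, sites[s]] == g_w[s]
                             for s in range(L)]
                    mism = sum(1 for s in range(L) if valid[s] and not match[s])
                    if mism > k_allowed:
                        continue

                    def runlen(s):
                        if not match[s]:
                            return 0
                        a = s
                        while a > 0 and match[a - 1]:
                            a -= 1
                        b = s
                        while b < L - 1 and match[b + 1]:
                            b += 1
                        return b - a + 1

                    if max(runlen(s) for s in range(L)) < scheme.min_match:
                        continue
                    for m in range(lo, hi + 1):
                        gap = np.searchsorted(sites, m, side="left")
                        w = 0.0
                        if gap >= 1 and match[gap - 1]:
                            w = runlen(gap - 1)
                        if gap <= L - 1 and match[gap]:
                            w = max(w, runlen(gap))
                        if w > 0:
                            votes[m][0] += w * (H[i, m] + H[j, m])
                            votes[m][1] += w
    p_ref = H.mean(axis=0)
    dosage = np.empty(n_markers)
    source = np.empty(n_markers, dtype=int)
    for m in range(n_markers):
        if target[m] != MISSING:
            dosage[m], source[m] = float(target[m]), 0
        elif votes[m][1] > 0:
            dosage[m], source[m] = votes[m][0] / votes[m][1], 1
        else:
            dosage[m], source[m] = 2 * p_ref[m], 2
    return dosage, source


def run_both(haps, target, n_markers, scheme):
    mmap = line_map(n_markers)
    ref = phased_matrix(haps)
    typed = sorted(np.flatnonzero(np.asarray(target) != MISSING))
    panel = ci.PanelManifest("p", [f"m{i}" for i in typed])
    lib = ci.build_library(ref, mmap, panel)
    dosage, best, source = ci.impute_target(np.asarray(target, dtype=np.int8),
                                            lib, scheme)
    d2, s2 = naive_impute(target, np.asarray(haps), typed, n_markers, scheme)
    return dosage, source, d2, s2


def test_window_output_equals_pair_enumeration_oracle():
    """<= 12 haplotypes, <= 30 markers: exact agreement with brute force."""
    rng = np.random.default_rng(42)
    scheme = ci.WindowScheme(lengths=(8, 4), overlap=0.5, min_match=3,
                             mismatch_tol=0.05)
    for trial in range(25):
        n_hap = rng.integers(4, 13)
        n_markers = rng.integers(12, 31)
        haps = rng.integers(0, 2, size=(n_hap if n_hap % 2 == 0 else n_hap + 1,
                                        n_markers))
        typed = np.sort(rng.choice(n_markers, size=rng.integers(8, n_markers),
                                   replace=False))
        target = np.full(n_markers, MISSING, dtype=np.int8)
        # target drawn from two random library haplotypes, so matches exist
        a, b = rng.integers(0, haps.shape[0], size=2)
        target[typed] = haps[a, typed] + haps[b, typed]
        dosage, source, d2, s2 = run_both(haps, target, n_markers, scheme)
        np.testing.assert_allclose(dosage, d2, atol=1e-12,
                                   err_msg=f"trial {trial}")
        np.testing.assert_array_equal(source, s2)


def test_printed_toy_has_unique_compatible_pair():
    """4 haplotypes 00110/00111/11000/11001 typed at sites {1,2,5}: the only
    pair matching target genotypes (0,0,2) is (h2,h2), so the untyped sites
    3,4 must impute to homozygous-B."""
    haps = np.array([[0, 0, 1, 1, 0],
                     [0, 0, 1, 1, 1],
                     [1, 1, 0, 0, 0],
                     [1, 1, 0, 0, 1]])
    target = np.array([0, MISSING, MISSING, MISSING, 2], dtype=np.int8)
    target[1] = 0
    scheme = ci.WindowScheme(lengths=(3,), overlap=0.5, min_match=3,
                             mismatch_tol=0.0)
    dosage, source, d2, s2 = run_both(haps, target, 5, scheme)
    assert dosage[2] == 2.0 and dosage[3] == 2.0
    np.testing.assert_allclose(dosage, d2, atol=1e-12)
    assert best_guess_from_dosage(dosage[[2, 3]]).tolist() == [2, 2]


# ---------------------------------------------------------------------------
# Library
# ---------------------------------------------------------------------------


def test_library_counts_and_consistency():
    rng = np.random.default_rng(1)
    haps = rng.integers(0, 2, size=(4, 20))
    ref = phased_matrix(haps)
    mmap = line_map(20)
    panel = ci.PanelManifest("p", [f"m{i}" for i in range(0, 20, 2)])
    lib = ci.build_library(ref, mmap, panel)
    assert lib.n_haplotypes == 4  # 2 samples -> 4 haplotypes
    np.testing.assert_array_equal(lib.haplotypes[0::2] + lib.haplotypes[1::2],
                                  ref.genotypes)
    again = ci.build_library(ref, mmap, panel)
    np.testing.assert_array_equal(lib.haplotypes, again.haplotypes)


def test_unphased_reference_rejected():
    rng = np.random.default_rng(2)
    g = rng.integers(0, 3, size=(3, 10)).astype(np.int8)
    ref = ci.GenotypeMatrix(["a", "b", "c"], g)
    panel = ci.PanelManifest("p", ["m0"])
    with pytest.raises(DataValidationError, match="phased reference"):
        ci.build_library(ref, line_map(10), panel)


def test_library_repairs_are_counted():
    rng = np.random.default_rng(3)
    haps = rng.integers(0, 2, size=(6, 15))
    ref = phased_matrix(haps)
    ref.genotypes[0, 3] = MISSING
    ref.phase[0, 3] = MISSING
    ref.phase[1, 5] = MISSING  # unphased but called
    lib = ci.build_library(ref, line_map(15),
                           ci.PanelManifest("p", ["m0", "m7", "m14"]))
    assert lib.n_filled == 2
    assert set(np.unique(lib.haplotypes)) <= {0, 1}


# ---------------------------------------------------------------------------
# Limit behaviours
# ---------------------------------------------------------------------------


def test_perfect_template_limit_small():
    """Target equal to a reference sample imputes its genotype exactly."""
    rng = np.random.default_rng(4)
    haps = rng.integers(0, 2, size=(20, 60))
    ref = phased_matrix(haps)
    mmap = line_map(60)
    typed = list(range(0, 60, 3))
    panel = ci.PanelManifest("p", [f"m{i}" for i in typed])
    lib = ci.build_library(ref, mmap, panel)
    scheme = ci.WindowScheme(lengths=(20, 10), overlap=0.5, min_match=10,
                             mismatch_tol=0.0)
    truth = ref.genotypes[0]
    target = np.full(60, MISSING, dtype=np.int8)
    target[typed] = truth[typed]
    dosage, best, source = ci.impute_target(target, lib, scheme)
    assert (source[target == MISSING] == SOURCE_MATCH).all()
    np.testing.assert_array_equal(best, truth)


def test_disabled_matching_falls_back_to_frequency():
    """min_match above every window length leaves only 2 p_B dosages."""
    rng = np.random.default_rng(5)
    haps = rng.integers(0, 2, size=(30, 40))
    ref = phased_matrix(haps)
    mmap = line_map(40)
    typed = list(range(0, 40, 2))
    panel = ci.PanelManifest("p", [f"m{i}" for i in typed])
    lib = ci.build_library(ref, mmap, panel)
    scheme = ci.WindowScheme(lengths=(10,), min_match=99)
    target = np.full(40, MISSING, dtype=np.int8)
    target[typed] = (haps[0] + haps[1])[typed]
    dosage, best, source = ci.impute_target(target, lib, scheme)
    hidden = target == MISSING
    assert (source[hidden] == SOURCE_FALLBACK).all()
    np.testing.assert_allclose(dosage[hidden], 2 * lib.p_b[hidden], atol=1e-12)


def test_typed_genotypes_never_modified():
    rng = np.random.default_rng(6)
    haps = rng.integers(0, 2, size=(10, 30))
    ref = phased_matrix(haps)
    mmap = line_map(30)
    typed = list(range(0, 30, 2))
    panel = ci.PanelManifest("p", [f"m{i}" for i in typed])
    lib = ci.build_library(ref, mmap, panel)
    target = np.full(30, MISSING, dtype=np.int8)
    target[typed] = rng.integers(0, 3, size=len(typed))
    dosage, best, _ = ci.impute_target(target, lib, ci.WindowScheme((8,), 0.5,
                                                                    4, 0.1))
    np.testing.assert_array_equal(best[typed], target[typed])
    np.testing.assert_array_equal(dosage[typed], target[typed].astype(float))


def test_chromosome_without_typed_markers_all_fallback():
    rng = np.random.default_rng(7)
    haps = rng.integers(0, 2, size=(8, 10))
    ref = phased_matrix(haps)
    mmap = ci.MarkerMap(pd.DataFrame({
        "marker_id": [f"m{i}" for i in range(10)],
        "chromosome": ["1"] * 5 + ["2"] * 5,
        "position_bp": list(range(1, 6)) * 2,
        "position_cm": [float(i) for i in range(1, 6)] * 2,
        "allele_a": "A", "allele_b": "B"}))
    panel = ci.PanelManifest("p", ["m0", "m2", "m4"])  # chrom 2 untyped
    lib = ci.build_library(ref, mmap, panel)
    target = np.full(10, MISSING, dtype=np.int8)
    target[[0, 2, 4]] = (haps[0] + haps[1])[[0, 2, 4]]
    _, _, source = ci.impute_target(target, lib, ci.WindowScheme((3,), 0.5, 1,
                                                                 0.0))
    assert (source[5:] == SOURCE_FALLBACK).all()


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.floats(0.0, 2.0))
def test_best_guess_is_binomial_argmax_with_small_code_ties(d):
    p = d / 2.0
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2]
    expected = int(np.flatnonzero(np.isclose(probs, max(probs)))[0])
    assert int(best_guess_from_dosage(np.array([d]))[0]) == expected


def test_window_scheme_validation():
    with pytest.raises(DataValidationError):
        ci.WindowScheme(lengths=(100, 200))
    with pytest.raises(DataValidationError):
        ci.WindowScheme(overlap=1.0)
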