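"""Imputation accuracy metrics and adjacent-marker LD.

Two criteria score imputation against the retained truth of masked entries:

* concordance rate (CR): the fraction of masked genotypes whose imputed
  best guess equals the true genotype — reported overall and broken down
  per chromosome / animal / marker (the overall value is always the pooled
  fraction, never a mean of group means);
* allelic R²: the squared Pearson correlation between the allele dosage of
  the most likely imputed genotype and the true allele dosage, computed per
  marker across target animals and averaged over markers where it is
  defined (pooled across entries as an option).  It penalises
  frequency-driven lucky guesses and therefore typically sits below CR.

Cells or markers with no scoreable entries (or zero variance) are flagged
undefined and excluded with a logged count — never reported as zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dataio import MISSING, DataValidationError, GenotypeMatrix, MarkerMap

log = logging.getLogger(__name__)


def _check_aligned(truth: np.ndarray, imputed: np.ndarray,
                   mask: np.ndarray) -> None:
    if truth.shape != imputed.shape or truth.shape != mask.shape:
        raise DataValidationError(
            f"misaligned arrays: truth {truth.shape}, imputed {imputed.shape}, "
            f"mask {mask.shape}")


def concordance_rate(truth: np.ndarray, imputed: np.ndarray, mask: np.ndarray,
                     marker_map: MarkerMap | None = None,
                     sample_ids=None, by: str = "overall") -> pd.DataFrame:
    """Exact-match fraction over masked, truth-called entries.

    ``by`` is one of overall / chromosome / animal / marker.  Returns a frame
    with columns cell, n_entries, n_correct, concordance; empty cells carry
    NaN concordance.
    """
    truth = np.asarray(truth)
    imputed = np.asarray(imputed)
    mask = np.asarray(mask, dtype=bool)
    _check_aligned(truth, imputed, mask)
    score = mask & (truth != MISSING)
    correct = score & (imputed == truth)

    def row(cell, sc, co):
        n = int(sc.sum())
        return (cell, n, int(co.sum()), co.sum() / n if n else np.nan)

    if by == "overall":
        rows = [row("overall", score, correct)]
    elif by == "animal":
        ids = sample_ids if sample_ids is not None else range(truth.shape[0])
        rows = [row(s, score[i], correct[i]) for i, s in enumerate(ids)]
    elif by == "marker":
        rows = [row(m, score[:, j], correct[:, j])
                for j, m in enumerate(
                    marker_map.marker_ids if marker_map is not None
                    else range(truth.shape[1]))]
    elif by == "chromosome":
        if marker_map is None:
            raise DataValidationError("per-chromosome CR needs a marker map")
        rows = []
        for chrom in marker_map.chromosomes:
            idx = marker_map.chrom_indices(chrom)
            rows.append(row(chrom, score[:, idx], correct[:, idx]))
    else:
        raise DataValidationError(f"unknown grouping {by!r}")
    out = pd.DataFrame(rows, columns=["cell", "n_entries", "n_correct",
                                      "concordance"])
    n_empty = int(out["n_entries"].eq(0).sum())
    if n_empty:
        log.info("concordance by %s: %d empty cell(s) excluded", by, n_empty)
    return out


def allelic_r2(truth: np.ndarray, imputed: np.ndarray, mask: np.ndarray,
               per_marker: bool = True) -> tuple[float, int]:
    """Squared Pearson correlation of true vs imputed allele dosages.

    ``per_marker=True`` (default): r² per marker across target animals,
    averaged over markers with defined values; ``False``: pooled across all
    masked entries.  Returns (value, n_undefined_markers); value is NaN when
    nothing is defined.
    """
    truth = np.asarray(truth, dtype=float)
    imputed = np.asarray(imputed, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    _check_aligned(truth, imputed, mask)
    score = mask & (truth != MISSING)
    if not per_marker:
        t, m = truth[score], imputed[score]
        if len(t) < 2 or t.std() == 0 or m.std() == 0:
            return float("nan"), 1
        return float(np.corrcoef(t, m)[0, 1] ** 2), 0
    vals = []
    n_undef = 0
    for j in range(truth.shape[1]):
        sc = score[:, j]
        if sc.sum() < 2:
            if sc.any():
                n_undef += 1
            continue
        t, m = truth[sc, j], imputed[sc, j]
        if t.std() == 0 or m.std() == 0:
            n_undef += 1
            continue
        vals.append(np.corrcoef(t, m)[0, 1] ** 2)
    if n_undef:
        log.info("allelic R2: %d marker(s) undefined (zero variance), excluded",
                 n_undef)
    return (float(np.mean(vals)) if vals else float("nan")), n_undef


def accuracy_report(result, truth_targets: np.ndarray,
                    marker_map: MarkerMap) -> dict:
    """Headline metrics for one imputation run (CR %, allelic R², sizes)."""
    cr = concordance_rate(truth_targets, result.best_guess, result.mask)
    r2, n_undef = allelic_r2(truth_targets, result.best_guess, result.mask)
    cr_val = float(cr.loc[0, "concordance"])
    if np.isfinite(r2) and r2 > cr_val:
        log.warning("allelic R2 (%.4f) exceeds concordance (%.4f); unusual "
                    "but not impossible", r2, cr_val)
    return {
        "concordance": cr_val,
        "cr_percent": 100.0 * cr_val,
        "allelic_r2": r2,
        "n_masked": int(result.mask.sum()),
        "n_scored": int(cr.loc[0, "n_entries"]),
        "n_r2_undefined_markers": n_undef,
        "fallback_fraction": result.fallback_fraction,
    }


def adjacent_ld_r2(matrix: GenotypeMatrix, marker_map: MarkerMap,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Composite LD (genotype-correlation r²) between adjacent markers.

    For each physically adjacent marker pair on a chromosome, r² is the
    squared Pearson correlation of genotype codes across samples with both
    calls present.  Returns (per-chromosome means, per-pair table); pairs
    with zero variance are undefined and excluded from the means.
    """
    g = matrix.genotypes
    pair_rows = []
    chrom_rows = []
    for chrom in marker_map.chromosomes:
        idx = marker_map.chrom_indices(chrom)
        vals = []
        for a, b in zip(idx[:-1], idx[1:]):
            ga, gb = g[:, a], g[:, b]
            both = (ga != MISSING) & (gb != MISSING)
            r2 = np.nan
            if both.sum() >= 2:
                x, y = ga[both].astype(float), gb[both].astype(float)
                if x.std() > 0 and y.std() > 0:
                    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
            pair_rows.append((chrom, marker_map.marker_ids[a],
                              marker_map.marker_ids[b], int(both.sum()), r2))
            if np.isfinite(r2):
                vals.append(r2)
        chrom_rows.append((chrom, len(idx) - 1, len(vals),
                           float(np.mean(vals)) if vals else np.nan))
    pairs = pd.DataFrame(pair_rows, columns=["chromosome", "marker_a",
                                             "marker_b", "n_samples", "r2"])
    chroms = pd.DataFrame(chrom_rows, columns=["chromosome", "n_pairs",
                                               "n_defined", "mean_r2"])
    return chroms, pairs
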