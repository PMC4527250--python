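"""Marker and sample quality control.

The cascade runs in a fixed, reported order: (1) non-autosomal or
unknown-position markers, (2) SNP call rate < 0.90, (3) Hardy-Weinberg exact
test p < 1e-6, (4) heterozygosity > 0.85, (5) MAF < 0.0025, then (6) sample
call rate < 0.90 computed on the surviving markers.  Every stage's removals
are counted in a :class:`QCReport`.

A 2p(1-p) expected heterozygosity is bounded by 0.5, so a "heterozygosity
above 0.85" filter can only bite on *observed* heterozygosity (the usual
paralog-artifact screen); that is the default, with the literal expected-het
variant behind ``het_filter_mode='expected'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .dataio import (MISSING, DataValidationError, GenotypeMatrix, MarkerMap)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults follow common HD bovine practice."""

    snp_call_rate_min: float = 0.90
    hwe_p_min: float = 1e-6
    het_max: float = 0.85
    maf_min: float = 0.0025
    sample_call_rate_min: float = 0.90
    het_filter_mode: str = "observed"   # or "expected"

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "hwe_p_min", "het_max", "maf_min",
                     "sample_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataValidationError(f"{name} must be in [0,1], got {v}")
        if self.het_filter_mode not in ("observed", "expected"):
            raise DataValidationError(
                f"het_filter_mode must be observed|expected, got {self.het_filter_mode}")


@dataclass
class QCReport:
    """Per-stage removal accounting; removed + remaining = input counts."""

    n_markers_in: int
    n_samples_in: int
    marker_removals: list[tuple[str, int]] = field(default_factory=list)
    n_samples_removed: int = 0
    removed_sample_ids: list[str] = field(default_factory=list)

    @property
    def n_markers_out(self) -> int:
        return self.n_markers_in - sum(n for _, n in self.marker_removals)

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.n_samples_removed

    def to_frame(self) -> pd.DataFrame:
        rows = [("input_markers", self.n_markers_in)]
        rows += [(f"removed_{name}", n) for name, n in self.marker_removals]
        rows += [("remaining_markers", self.n_markers_out),
                 ("input_samples", self.n_samples_in),
                 ("removed_sample_call_rate", self.n_samples_removed),
                 ("remaining_samples", self.n_samples_out)]
        return pd.DataFrame(rows, columns=["stage", "count"])


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts: enumerates every heterozygote
    count compatible with them, and sums the probabilities of configurations
    no more probable than the observed one (two-sided, Fisher-style).
    Returns p in (0, 1].
    """
    for n in (n_aa, n_ab, n_bb):
        if n < 0:
            raise DataValidationError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise DataValidationError("all genotype counts are zero")
    nb = n_ab + 2 * n_bb          # B-allele count
    na = 2 * n - nb
    k_max = min(na, nb)
    ks = np.arange(k_max % 2, k_max + 1, 2)  # parity fixed by allele counts
    # log P(n_ab = k | n, nb) up to a constant:
    #   n! / (naa! nab! nbb!) * 2^nab with naa=(na-k)/2, nbb=(nb-k)/2
    logp = (ks * np.log(2.0) - gammaln((na - ks) / 2 + 1)
            - gammaln(ks + 1.0) - gammaln((nb - ks) / 2 + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(ks, n_ab)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_exact_test_many(n_aa: np.ndarray, n_ab: np.ndarray,
                        n_bb: np.ndarray) -> np.ndarray:
    """Vectorized wrapper over :func:`hwe_exact_test` (per-marker loop)."""
    out = np.ones(len(n_aa))
    for i, (a, h, b) in enumerate(zip(n_aa, n_ab, n_bb)):
        if a + h + b > 0:
            out[i] = hwe_exact_test(int(a), int(h), int(b))
        else:
            out[i] = np.nan
    return out


# ---------------------------------------------------------------------------
# Marker statistics
# ---------------------------------------------------------------------------


def marker_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker call rate, allele-B frequency, MAF and heterozygosities.

    Markers with no non-missing call get NaN statistics (they are flagged
    undefined and will fail the call-rate filter).
    """
    if matrix.n_markers == 0 or matrix.n_samples == 0:
        raise DataValidationError("empty genotype matrix")
    g = matrix.genotypes
    called = g != MISSING
    n_called = called.sum(axis=0)
    n_aa = ((g == 0) & called).sum(axis=0)
    n_ab = (g == 1).sum(axis=0)
    n_bb = (g == 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        call_rate = n_called / matrix.n_samples
        p_b = np.where(n_called > 0, (n_ab + 2 * n_bb) / (2 * n_called), np.nan)
        maf = np.minimum(p_b, 1 - p_b)
        obs_het = np.where(n_called > 0, n_ab / n_called, np.nan)
        exp_het = 2 * p_b * (1 - p_b)
    return pd.DataFrame({
        "n_called": n_called, "call_rate": call_rate, "p_b": p_b, "maf": maf,
        "obs_het": obs_het, "exp_het": exp_het,
        "n_aa": n_aa, "n_ab": n_ab, "n_bb": n_bb,
    })


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

_STAGES = ("non_autosomal_or_unplaced", "snp_call_rate", "hwe", "heterozygosity",
           "maf")


def apply_qc(matrix: GenotypeMatrix, marker_map: MarkerMap,
             thresholds: QCThresholds = QCThresholds(),
             ) -> tuple[GenotypeMatrix, MarkerMap, QCReport]:
    """Run the full QC cascade, returning the filtered data plus a report."""
    if matrix.n_markers != marker_map.n_markers:
        raise DataValidationError("matrix / marker map size mismatch")
    report = QCReport(matrix.n_markers, matrix.n_samples)
    alive = np.ones(matrix.n_markers, dtype=bool)

    def remove(stage: str, fail: np.ndarray) -> None:
        fail = fail & alive
        report.marker_removals.append((stage, int(fail.sum())))
        alive[fail] = False

    remove("non_autosomal_or_unplaced", ~marker_map.is_autosomal())

    stats = marker_stats(matrix)
    call_rate = stats["call_rate"].to_numpy()
    undefined = stats["n_called"].to_numpy() == 0
    remove("snp_call_rate",
           (call_rate < thresholds.snp_call_rate_min) | undefined)

    # HWE only on markers still alive (the expensive stage)
    hwe_fail = np.zeros(matrix.n_markers, dtype=bool)
    idx = np.flatnonzero(alive)
    if len(idx):
        p = hwe_exact_test_many(stats["n_aa"].to_numpy()[idx],
                                stats["n_ab"].to_numpy()[idx],
                                stats["n_bb"].to_numpy()[idx])
        hwe_fail[idx] = p < thresholds.hwe_p_min
    remove("hwe", hwe_fail)

    het = stats["obs_het" if thresholds.het_filter_mode == "observed"
                else "exp_het"].to_numpy()
    remove("heterozygosity", het > thresholds.het_max)
    remove("maf", stats["maf"].to_numpy() < thresholds.maf_min)

    marker_idx = np.flatnonzero(alive)
    filtered = matrix.subset(marker_idx=marker_idx)
    fmap = marker_map.subset(marker_idx)

    sample_cr = (filtered.genotypes != MISSING).mean(axis=1) \
        if filtered.n_markers else np.zeros(filtered.n_samples)
    keep = sample_cr >= thresholds.sample_call_rate_min
    report.n_samples_removed = int((~keep).sum())
    report.removed_sample_ids = [s for s, k in zip(filtered.sample_ids, keep)
                                 if not k]
    if report.n_samples_removed:
        filtered = filtered.subset(sample_idx=np.flatnonzero(keep))
        log.info("QC removed %d sample(s) below call rate %.2f",
                 report.n_samples_removed, thresholds.sample_call_rate_min)
    return filtered, fmap, report
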