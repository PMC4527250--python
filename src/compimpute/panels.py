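"""Low/medium-density panel emulation and reference/target scenarios.

Low-density genotyping is emulated by masking: target animals keep only the
markers present in a panel manifest, everything else becomes missing while
the truth is retained for scoring.  Synthetic panels follow the commercial
density ladder (3K, 6K, 9K, 20K, 50K, 75K, 80K chips), with each size
rescaled to the working high-density marker count.

Seven reference/target scenarios partition the cohort by birth year, genetic
group and sex; the rules reproduce the study-design bookkeeping exactly when
the metadata mirrors it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataio import (MISSING, DataValidationError, GenotypeMatrix, MarkerMap,
                     PanelManifest, SampleTable)

log = logging.getLogger(__name__)

#: post-QC marker counts of the commercial low/medium-density chips on the
#: ~617k-SNP bovine HD panel; used as the density ladder, rescaled to the
#: working HD marker count.
STUDY_PANEL_SIZES = {
    "3K": 2341,
    "6K": 6280,
    "GGP9K": 7548,
    "GGP20Ki": 14305,
    "50K": 38802,
    "GGP75Ki": 50038,
    "GGP80K": 67143,
}
STUDY_HD_SIZE = 616565

SCENARIO_NAMES = ("S1", "S2", "S3", "S4", "S5", "S6", "S7")


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------


def make_synthetic_panel(marker_map: MarkerMap, n_markers: int,
                         strategy: str = "uniform_spacing", seed=None,
                         name: str = "panel") -> PanelManifest:
    """Select ``n_markers`` from the map.

    ``uniform_spacing`` (default, approximating commercial chip design)
    allocates markers to chromosomes proportionally and picks them at
    centred, approximately equal intervals; ``random`` samples without
    replacement under ``seed``.
    """
    total = marker_map.n_markers
    if not 1 <= n_markers <= total:
        raise DataValidationError(
            f"n_markers must be in [1, {total}], got {n_markers}")
    ids = marker_map.marker_ids
    if strategy == "random":
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(total, size=n_markers, replace=False))
        return PanelManifest(name, list(ids[pick]))
    if strategy != "uniform_spacing":
        raise DataValidationError(f"unknown panel strategy {strategy!r}")
    chroms = marker_map.chromosomes
    sizes = np.array([len(marker_map.chrom_indices(c)) for c in chroms])
    # proportional allocation, largest remainder
    quota = n_markers * sizes / total
    alloc = np.floor(quota).astype(int)
    rem = n_markers - alloc.sum()
    order = np.argsort(-(quota - alloc))
    alloc[order[:rem]] += 1
    alloc = np.minimum(alloc, sizes)
    short = n_markers - alloc.sum()
    while short > 0:  # spill-over if a chromosome saturated
        for i in np.argsort(alloc - sizes):
            if short and alloc[i] < sizes[i]:
                alloc[i] += 1
                short -= 1
    picked: list[str] = []
    for c, k in zip(chroms, alloc):
        if k == 0:
            continue
        idx = marker_map.chrom_indices(c)
        sel = np.floor((np.arange(k) + 0.5) * len(idx) / k).astype(int)
        picked.extend(ids[idx[sel]])
    return PanelManifest(name, picked)


def make_density_ladder(marker_map: MarkerMap, strategy: str = "uniform_spacing",
                        seed=None) -> list[PanelManifest]:
    """The 7-panel commercial density ladder rescaled to this marker map."""
    scale = marker_map.n_markers / STUDY_HD_SIZE
    panels = []
    for label, size in STUDY_PANEL_SIZES.items():
        n = max(1, min(marker_map.n_markers, round(size * scale)))
        panels.append(make_synthetic_panel(marker_map, n, strategy=strategy,
                                           seed=seed, name=label))
    return panels


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """A named reference/target sample partition."""

    name: str
    reference_ids: list[str]
    target_ids: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        ref, tgt = set(self.reference_ids), set(self.target_ids)
        if not ref or not tgt:
            raise DataValidationError(
                f"scenario {self.name}: empty reference or target")
        if ref & tgt:
            raise DataValidationError(
                f"scenario {self.name}: reference and target overlap "
                f"({len(ref & tgt)} samples)")


def build_scenario(samples: SampleTable, name: str,
                   include_charolais_sires: bool = True,
                   split_year: int = 2005) -> Scenario:
    """Build one of the seven standard reference/target partitions.

    Rules (CH = Charolais sires, CA = Canchim, MA = the MA genetic group;
    "old" = born before ``split_year``, "young" = born in it):

    ======  =============================================  =================
    name    reference                                       target
    ======  =============================================  =================
    S1      all old (CH included)                           all young
    S2      all CA                                          all MA
    S3      all MA                                          all CA
    S4      all CA + old MA                                 young MA
    S5      all MA + old CA                                 young CA
    S6      all males (CH included)                         all females
    S7      males + old females (CH included)               young females
    ======  =============================================  =================

    In S4/S5 the group supplying the target enters the reference only with
    its older animals, so reference and target never overlap; Charolais
    sires appear only in the year/sex-based references.
    """
    if name not in SCENARIO_NAMES:
        raise DataValidationError(
            f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    t = samples.table
    grp = t["genetic_group"]
    in_cohort = grp.isin(("CANCHIM", "MA"))
    is_ch = (grp == "CHAROLAIS") & include_charolais_sires
    old = t["birth_year"] < split_year
    young = t["birth_year"] == split_year
    male = t["sex"] == "M"

    def ids(mask) -> list[str]:
        return t.loc[mask, "sample_id"].tolist()

    if name == "S1":
        ref, tgt = (in_cohort & old) | (is_ch & old), in_cohort & young
        desc = f"reference born before {split_year}; target born {split_year}"
    elif name == "S2":
        ref, tgt = grp == "CANCHIM", grp == "MA"
        desc = "reference all Canchim; target all MA"
    elif name == "S3":
        ref, tgt = grp == "MA", grp == "CANCHIM"
        desc = "reference all MA; target all Canchim"
    elif name == "S4":
        ref = (grp == "CANCHIM") | ((grp == "MA") & old)
        tgt = (grp == "MA") & young
        desc = f"reference Canchim + MA born before {split_year}; target MA born {split_year}"
    elif name == "S5":
        ref = (grp == "MA") | ((grp == "CANCHIM") & old)
        tgt = (grp == "CANCHIM") & young
        desc = f"reference MA + Canchim born before {split_year}; target Canchim born {split_year}"
    elif name == "S6":
        ref, tgt = (in_cohort | is_ch) & male, in_cohort & ~male
        desc = "reference all males; target all females"
    else:  # S7
        ref = ((in_cohort | is_ch) & male) | (in_cohort & ~male & old)
        tgt = in_cohort & ~male & young
        desc = f"reference males + females born before {split_year}; target females born {split_year}"
    try:
        return Scenario(name, ids(ref), ids(tgt), desc)
    except DataValidationError as exc:
        raise DataValidationError(f"{exc} under rule: {desc}") from None


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------


@dataclass
class MaskedDataset:
    """Reference at HD plus targets masked down to a panel.

    ``mask`` is a boolean (n_targets, n_markers) array marking hidden
    entries; the truth for every hidden entry is kept in ``truth_targets``.
    Target rows are treated as unphased (phase removed).
    """

    panel: PanelManifest
    reference: GenotypeMatrix
    target: GenotypeMatrix
    mask: np.ndarray
    truth_targets: np.ndarray
    panel_marker_idx: np.ndarray
    reference_ids: list[str]
    target_ids: list[str]

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


def mask_to_panel(truth: GenotypeMatrix, marker_map: MarkerMap,
                  panel: PanelManifest, target_ids,
                  reference_ids=None) -> MaskedDataset:
    """Hide all non-panel markers in the target samples.

    Reference rows are untouched at HD (bit-exact); target rows keep only
    the panel-typed markers and lose phase.
    """
    panel_idx, _ = panel.resolve(marker_map, on_missing="error")
    target_ids = list(target_ids)
    tgt_idx = truth.sample_index(target_ids)
    if reference_ids is None:
        reference_ids = [s for s in truth.sample_ids if s not in set(target_ids)]
    else:
        reference_ids = list(reference_ids)
        if set(reference_ids) & set(target_ids):
            raise DataValidationError("reference and target samples overlap")
    ref_idx = truth.sample_index(reference_ids)

    reference = truth.subset(sample_idx=ref_idx)
    truth_targets = truth.genotypes[tgt_idx].copy()
    masked = truth_targets.copy()
    hide = np.ones(truth.n_markers, dtype=bool)
    hide[panel_idx] = False
    masked[:, hide] = MISSING
    mask = np.broadcast_to(hide, masked.shape).copy()
    target = GenotypeMatrix(target_ids, masked, None)
    log.info("panel %s: masked %d entries (%d targets x %d hidden markers)",
             panel.name, int(mask.sum()), len(target_ids), int(hide.sum()))
    return MaskedDataset(panel, reference, target, mask, truth_targets,
                         panel_idx, reference_ids, target_ids)
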