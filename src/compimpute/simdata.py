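"""Synthetic composite-breed cattle populations.

Emulates the structure of a Canchim/MA breeding programme: two divergent
ancestral populations (taurine-like Charolais, indicine-like Zebu) whose
allele frequencies are drawn under a Balding-Nichols divergence model, a
grading-up crossing pedigree producing Canchim (expected 5/8 Charolais) and
MA (Charolais sire x Canchim-Zebu dam, expected 21/32 = 0.65625 Charolais),
half-sib family structure over birth years 1999-2005, gene dropping with
Haldane (no-interference) recombination on a cM map, and genotyping
missingness/error.

Founder-haplotype origins are tracked through the gene drop, so realized
(not just expected) breed ancestry is available for every individual.
All randomness flows through explicit seeds; there is no global state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import (MISSING, DataValidationError, GenotypeMatrix, MarkerMap,
                     SampleTable)

log = logging.getLogger(__name__)

TAURINE, INDICINE = 0, 1  # ancestral population codes


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Ancestral model and marker map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AncestralModel:
    """Two ancestral populations diverged from a common base.

    ``fst`` controls divergence (Balding-Nichols Beta draws around a base
    frequency uniform on ``(freq_low, freq_high)``).  The default 0.15 is on
    the taurine-indicine scale.  The map is laid out at 1 cM/Mb with
    ``chrom_length_cm`` per chromosome.
    """

    n_chromosomes: int = 5
    markers_per_chromosome: int = 4000
    fst: float = 0.15
    chrom_length_cm: float = 100.0
    freq_low: float = 0.05
    freq_high: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise DataValidationError(f"fst must be in (0,1), got {self.fst}")
        if not 0.0 < self.freq_low < self.freq_high < 1.0:
            raise DataValidationError("frequency bounds must satisfy 0<lo<hi<1")
        if self.n_chromosomes < 1 or self.markers_per_chromosome < 1:
            raise DataValidationError("need at least one chromosome and marker")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome


def make_marker_map(model: AncestralModel) -> MarkerMap:
    """Evenly spaced markers, 1 cM/Mb, chromosomes labelled "1", "2", ..."""
    m = model.markers_per_chromosome
    length_bp = int(model.chrom_length_cm * 1e6)
    pos = np.floor((np.arange(m) + 0.5) * length_bp / m).astype(np.int64) + 1
    rows = []
    for c in range(1, model.n_chromosomes + 1):
        for j in range(m):
            rows.append((f"snp_{c}_{j + 1}", str(c), pos[j], pos[j] / 1e6, "A", "B"))
    return MarkerMap(pd.DataFrame(
        rows, columns=["marker_id", "chromosome", "position_bp", "position_cm",
                       "allele_a", "allele_b"]))


def simulate_ancestral_frequencies(model: AncestralModel,
                                   seed) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-marker base and two diverged population frequencies.

    Balding-Nichols: each population frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F),
    so E[p_k] = p and Var[p_k] = F p (1-p).  Returns (base, taurine, indicine).
    """
    rng = _rng(seed)
    p = rng.uniform(model.freq_low, model.freq_high, size=model.n_markers)
    theta = (1.0 - model.fst) / model.fst
    a, b = p * theta, (1.0 - p) * theta
    p_tau = rng.beta(a, b)
    p_ind = rng.beta(a, b)
    eps = 1e-9
    return p, np.clip(p_tau, eps, 1 - eps), np.clip(p_ind, eps, 1 - eps)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """Individuals in topological order (parents precede offspring).

    Columns: id, sire, dam (None for founders), sex, birth_year, group,
    population (founders only: TAURINE/INDICINE), expected_charolais,
    genotyped.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        seen: dict[str, int] = {}
        for i, row in enumerate(t.itertuples(index=False)):
            if row.id in seen:
                raise DataValidationError(f"duplicate pedigree id {row.id}")
            has_sire, has_dam = not pd.isna(row.sire), not pd.isna(row.dam)
            if has_sire != has_dam:
                raise DataValidationError(
                    f"{row.id}: both parents must be known or both unknown")
            if has_sire:
                for par in (row.sire, row.dam):
                    if par not in seen:
                        raise DataValidationError(
                            f"{row.id}: parent {par} not defined earlier "
                            "(pedigree must be topologically ordered/acyclic)")
                    if t.at[seen[par], "birth_year"] >= row.birth_year:
                        raise DataValidationError(
                            f"{row.id}: parent {par} not born before offspring")
            seen[row.id] = i
        self.table = t
        self._pos = seen

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    @property
    def founder_mask(self) -> np.ndarray:
        return self.table["sire"].isna().to_numpy()

    def genotyped_ids(self) -> list[str]:
        return self.table.loc[self.table["genotyped"], "id"].tolist()

    def sample_table(self) -> SampleTable:
        """Metadata table for the genotyped individuals."""
        t = self.table[self.table["genotyped"]]
        return SampleTable(pd.DataFrame({
            "sample_id": t["id"],
            "sex": t["sex"],
            "birth_year": t["birth_year"],
            "genetic_group": t["group"],
            "sire_id": t["sire"],
            "dam_id": t["dam"],
        }))


@dataclass(frozen=True)
class PedigreeDesign:
    """Counts shaping the crossing pedigree.

    ``cohort`` lists (group, sex, birth_year, count) strata for the genotyped
    cohort (CANCHIM / MA).  Grading-up path: F1 = Charolais x Zebu;
    3/4 = Charolais x F1; base Canchim = 3/4 x F1 (5/8 Charolais); cohort
    Canchim = Canchim x Canchim; MA = Charolais x (Canchim x Zebu).

    2005-born animals are split between sires already producing earlier
    offspring (paternal half-sibs of the reference cohort) and sires used for
    2005 only (``fresh_target_fraction``), giving a relatedness gradient
    between target and reference animals.
    """

    n_charolais_sires: int = 15
    n_zebu_dams: int = 60
    n_f1_dams: int = 60
    n_34_sires: int = 20
    n_canchim_sires: int = 20
    n_canchim_dams: int = 100
    n_cz_dams: int = 40
    cohort: tuple = ()
    fresh_target_fraction: float = 0.5
    n_canchim_ref_sires: int = 12
    n_ma_ref_sires: int = 8
    genotype_charolais_sire: bool = True

    def __post_init__(self) -> None:
        if self.n_charolais_sires < 1 or self.n_zebu_dams < 1:
            raise DataValidationError("need at least one founder of each breed")
        if not self.cohort:
            object.__setattr__(self, "cohort", tuple(study_cohort_strata()))


def _spread(count: int, years: Sequence[int]) -> list[tuple[int, int]]:
    """Distribute ``count`` over ``years`` as evenly as possible."""
    base, rem = divmod(count, len(years))
    return [(y, base + (1 if i < rem else 0)) for i, y in enumerate(years)]


def study_cohort_strata() -> list[tuple[str, str, int, int]]:
    """Default cohort strata: 283 Canchim + 112 MA, both sexes, 1999-2005.

    The joint (group, sex, birth-year) layout is consistent with every
    reference/target split of the seven evaluation scenarios.
    """
    pre = list(range(1999, 2005))
    strata: list[tuple[str, str, int, int]] = []
    for group, sex, n_pre, n_2005 in (
            ("CANCHIM", "M", 84, 44), ("CANCHIM", "F", 100, 55),
            ("MA", "M", 45, 18), ("MA", "F", 23, 26)):
        strata += [(group, sex, y, n) for y, n in _spread(n_pre, pre) if n]
        strata.append((group, sex, 2005, n_2005))
    return strata


def build_pedigree(design: PedigreeDesign, seed) -> Pedigree:
    """Construct the crossing pedigree implementing the grading-up scheme."""
    rng = _rng(seed)
    rows: list[dict] = []

    def add(id_, sire, dam, sex, year, group, pop=None, genotyped=False,
            anc=None) -> str:
        if anc is None:
            anc = (anc_of[sire] + anc_of[dam]) / 2.0
        anc_of[id_] = anc
        rows.append(dict(id=id_, sire=sire, dam=dam, sex=sex, birth_year=year,
                         group=group, population=pop, genotyped=genotyped))
        return id_

    anc_of: dict[str, float] = {}
    ch_sires = [f"CH_S{i + 1:03d}" for i in range(design.n_charolais_sires)]
    for i, s in enumerate(ch_sires):
        add(s, None, None, "M", 1990, "CHAROLAIS", "TAURINE",
            genotyped=design.genotype_charolais_sire and i == 0, anc=1.0)
    zb_dams = [add(f"ZB_D{i + 1:03d}", None, None, "F", 1990, "ZEBU",
                   "INDICINE", anc=0.0) for i in range(design.n_zebu_dams)]

    def cross(prefix, n, sires, dams, sex, year, group):
        out = []
        for i in range(n):
            out.append(add(f"{prefix}{i + 1:03d}", sires[i % len(sires)],
                           dams[rng.integers(len(dams))], sex, year, group))
        return out

    f1_dams = cross("F1_D", design.n_f1_dams, ch_sires, zb_dams, "F", 1992, "F1")
    g34_sires = cross("G34_S", design.n_34_sires, ch_sires, f1_dams, "M", 1994,
                      "CROSS_3_4")
    ca_sires = cross("CA_S", design.n_canchim_sires, g34_sires, f1_dams, "M",
                     1996, "CANCHIM")
    ca_dams = cross("CA_D", design.n_canchim_dams, g34_sires, f1_dams, "F",
                    1996, "CANCHIM")
    cz_dams = cross("CZ_D", design.n_cz_dams, ca_sires, zb_dams, "F", 1997,
                    "CANCHIM_X_ZEBU")

    # cohort sire pools: "ref" sires serve every year; "fresh" sires only 2005
    ca_ref = ca_sires[:design.n_canchim_ref_sires]
    ca_fresh = ca_sires[design.n_canchim_ref_sires:] or ca_ref
    ma_ref = ch_sires[:design.n_ma_ref_sires]
    ma_fresh = ch_sires[design.n_ma_ref_sires:] or ma_ref
    half = len(ca_dams) // 2
    pools = {
        "CANCHIM": dict(ref_s=ca_ref, fresh_s=ca_fresh,
                        ref_d=ca_dams[:half] or ca_dams,
                        fresh_d=ca_dams[half:] or ca_dams),
        "MA": dict(ref_s=ma_ref, fresh_s=ma_fresh,
                   ref_d=cz_dams[: len(cz_dams) // 2] or cz_dams,
                   fresh_d=cz_dams[len(cz_dams) // 2:] or cz_dams),
    }
    counters = {"CANCHIM": 0, "MA": 0}
    for group, sex, year, count in design.cohort:
        if group not in pools:
            raise DataValidationError(f"cohort group {group} not supported")
        p = pools[group]
        n_fresh = (round(count * design.fresh_target_fraction)
                   if year == 2005 else 0)
        for j in range(count):
            counters[group] += 1
            fresh = j < n_fresh
            sires = p["fresh_s"] if fresh else p["ref_s"]
            dams = p["fresh_d"] if fresh else p["ref_d"]
            add(f"{group}_{counters[group]:04d}",
                sires[counters[group] % len(sires)],
                dams[rng.integers(len(dams))], sex, year, group, genotyped=True)
    return Pedigree(pd.DataFrame(rows))


def founders_only_pedigree(n_taurine: int, n_indicine: int = 0) -> Pedigree:
    """Unrelated founders with no offspring (zero-generation pedigree)."""
    rows = []
    for i in range(n_taurine):
        rows.append(dict(id=f"TAU_{i + 1:04d}", sire=None, dam=None,
                         sex="M" if i % 2 else "F", birth_year=1990,
                         group="CHAROLAIS", population="TAURINE", genotyped=True))
    for i in range(n_indicine):
        rows.append(dict(id=f"IND_{i + 1:04d}", sire=None, dam=None,
                         sex="M" if i % 2 else "F", birth_year=1990,
                         group="ZEBU", population="INDICINE", genotyped=True))
    return Pedigree(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------


@dataclass
class GeneDropResult:
    """Phased genotypes for all pedigree members plus origin tracking.

    ``hap_origins`` holds, per individual, the founder-haplotype slot id for
    every (haplotype, marker); ``founder_population`` maps slot -> ancestral
    population, so realized breed ancestry is ``taurine_ancestry``.
    """

    genotypes: GenotypeMatrix          # all pedigree individuals, phased
    hap_origins: np.ndarray            # (n_ind, 2, n_markers) int32 slot ids
    founder_population: np.ndarray     # (2 * n_founders,) {TAURINE, INDICINE}

    def taurine_ancestry(self) -> pd.Series:
        """Realized fraction of marker-haplotypes of taurine founder origin."""
        is_tau = (self.founder_population == TAURINE)
        frac = is_tau[self.hap_origins].mean(axis=(1, 2))
        return pd.Series(frac, index=self.genotypes.sample_ids)


def _meiosis(parent_haps: np.ndarray, mmap: MarkerMap, chrom_slices,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete: Haldane crossovers, Poisson(L/100) per chromosome."""
    gamete = np.empty(parent_haps.shape[1], dtype=parent_haps.dtype)
    for sl, cm in chrom_slices:
        length = cm[-1] - cm[0] if len(cm) > 1 else 0.0
        n_x = rng.poisson(length / 100.0)
        cuts = np.sort(rng.uniform(cm[0], cm[0] + length, size=n_x))
        start = rng.integers(2)
        which = (start + np.searchsorted(cuts, cm, side="right")) % 2
        gamete[sl] = np.where(which == 0, parent_haps[0, sl], parent_haps[1, sl])
    return gamete


def gene_drop(pedigree: Pedigree, freqs: tuple[np.ndarray, np.ndarray],
              marker_map: MarkerMap, seed) -> GeneDropResult:
    """Drop founder haplotypes through the pedigree with recombination.

    Founder haplotypes are drawn marker-independently from their population's
    frequencies (taurine, indicine); non-founders inherit recombinant parental
    haplotypes.  Output is fully phased and Mendelian-consistent.
    """
    rng = _rng(seed)
    p_tau, p_ind = freqs
    n_markers = marker_map.n_markers
    if len(p_tau) != n_markers or len(p_ind) != n_markers:
        raise DataValidationError("frequency vectors do not match the marker map")
    t = pedigree.table
    n_ind = len(t)
    chrom_slices = []
    for chrom in marker_map.chromosomes:
        idx = marker_map.chrom_indices(chrom)
        sl = slice(idx[0], idx[-1] + 1)
        chrom_slices.append((sl, marker_map.table["position_cm"].to_numpy()[sl]))

    founders = t[t["sire"].isna()]
    n_f = len(founders)
    founder_pop = np.empty(2 * n_f, dtype=np.int8)
    founder_alleles = np.empty((2 * n_f, n_markers), dtype=np.int8)
    slot_of: dict[str, int] = {}
    for k, row in enumerate(founders.itertuples(index=False)):
        if row.population not in ("TAURINE", "INDICINE"):
            raise DataValidationError(
                f"founder {row.id} has no ancestral population assignment")
        pop = TAURINE if row.population == "TAURINE" else INDICINE
        p = p_tau if pop == TAURINE else p_ind
        for h in (0, 1):
            slot = 2 * k + h
            founder_pop[slot] = pop
            founder_alleles[slot] = (rng.random(n_markers) < p).astype(np.int8)
        slot_of[row.id] = 2 * k

    origins = np.empty((n_ind, 2, n_markers), dtype=np.int32)
    pos = pedigree._pos
    for i, row in enumerate(t.itertuples(index=False)):
        if pd.isna(row.sire):
            base = slot_of[row.id]
            origins[i, 0] = base
            origins[i, 1] = base + 1
        else:
            origins[i, 0] = _meiosis(origins[pos[row.sire]], marker_map,
                                     chrom_slices, rng)
            origins[i, 1] = _meiosis(origins[pos[row.dam]], marker_map,
                                     chrom_slices, rng)

    alleles = founder_alleles[origins, np.arange(n_markers)[None, None, :]]
    phase = np.moveaxis(alleles, 1, 2)  # (n_ind, n_markers, 2)
    genotypes = phase.sum(axis=2).astype(np.int8)
    gm = GenotypeMatrix(t["id"].tolist(), genotypes, phase.astype(np.int8))
    return GeneDropResult(gm, origins, founder_pop)


# ---------------------------------------------------------------------------
# Genotyping noise
# ---------------------------------------------------------------------------


def apply_genotyping_noise(matrix: GenotypeMatrix, missing_rate: float,
                           error_rate: float, seed) -> GenotypeMatrix:
    """Independently drop calls and perturb surviving calls.

    Each entry is set missing with ``missing_rate``; each surviving non-missing
    entry is replaced by one of the two other genotype codes (uniformly) with
    ``error_rate``.  Phase is removed for affected entries.
    """
    for name, r in (("missing_rate", missing_rate), ("error_rate", error_rate)):
        if not 0.0 <= r < 1.0:
            raise DataValidationError(f"{name} must be in [0,1), got {r}")
    rng = _rng(seed)
    out = matrix.copy()
    g = out.genotypes
    drop = rng.random(g.shape) < missing_rate
    flip = (rng.random(g.shape) < error_rate) & ~drop & (g != MISSING)
    # perturb to a *different* valid code: shift by 1 or 2 mod 3
    shift = rng.integers(1, 3, size=g.shape).astype(np.int8)
    g[flip] = (g[flip] + shift[flip]) % 3
    g[drop] = MISSING
    if out.phase is not None:
        out.phase[drop | flip] = MISSING
    out.genotypes = g
    return GenotypeMatrix(out.sample_ids, g, out.phase)


# ---------------------------------------------------------------------------
# One-call simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to simulate a dataset reproducibly."""

    model: AncestralModel = field(default_factory=AncestralModel)
    design: PedigreeDesign = field(default_factory=PedigreeDesign)
    missing_rate: float = 0.002
    error_rate: float = 0.001
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        model = AncestralModel(**d.get("model", {}))
        design = PedigreeDesign(**{k: (tuple(map(tuple, v)) if k == "cohort" else v)
                                   for k, v in d.get("design", {}).items()})
        return cls(model=model, design=design,
                   missing_rate=d.get("missing_rate", 0.002),
                   error_rate=d.get("error_rate", 0.001),
                   seed=int(d["seed"]))


@dataclass
class SimulatedDataset:
    """Truth and observed genotypes for the genotyped cohort."""

    truth: GenotypeMatrix            # phased, error-free
    observed: GenotypeMatrix         # after genotyping noise
    samples: SampleTable
    marker_map: MarkerMap
    pedigree: Pedigree
    ancestry: pd.Series              # realized taurine fraction, all pedigree ids
    frequencies: tuple[np.ndarray, np.ndarray, np.ndarray]  # base, tau, ind


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate frequencies, pedigree, gene drop and noise in one pass."""
    ss = np.random.SeedSequence(config.seed)
    s_freq, s_ped, s_drop, s_noise = ss.spawn(4)
    mmap = make_marker_map(config.model)
    base, p_tau, p_ind = simulate_ancestral_frequencies(
        config.model, np.random.default_rng(s_freq))
    ped = build_pedigree(config.design, np.random.default_rng(s_ped))
    drop = gene_drop(ped, (p_tau, p_ind), mmap, np.random.default_rng(s_drop))
    ancestry = drop.taurine_ancestry()
    geno_ids = ped.genotyped_ids()
    idx = drop.genotypes.sample_index(geno_ids)
    truth = drop.genotypes.subset(sample_idx=idx)
    observed = apply_genotyping_noise(truth, config.missing_rate,
                                      config.error_rate,
                                      np.random.default_rng(s_noise))
    log.info("simulated %d genotyped samples x %d markers (%d pedigree members)",
             truth.n_samples, truth.n_markers, len(ped.table))
    return SimulatedDataset(truth, observed, ped.sample_table(), mmap, ped,
                            ancestry, (base, p_tau, p_ind))
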