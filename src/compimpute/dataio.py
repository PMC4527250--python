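"""On-disk representations: VCF genotypes, sample/marker TSV tables, panel manifests.

Genotype codes count copies of allele B (the VCF ALT allele): 0 = AA, 1 = AB,
2 = BB, :data:`MISSING` = no call.  This keeps the genotype matrix directly
usable as the incidence matrix of the VanRaden genomic relationship (where row
entries are ``code - 2 p_i``).

Reading goes through cyvcf2 (htslib); writing emits plain VCF 4.2 text.  Only
bi-allelic SNPs are supported: anything else is an error, never a silent skip,
so datasets cannot drift.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: genotype / allele code for a missing call
MISSING: int = -1

#: recognised sample sexes
SEXES = ("M", "F")

#: recognised genetic groups.  CHAROLAIS/ZEBU are the founder breeds, F1,
#: CROSS_3_4 (3/4 Charolais) and CANCHIM_X_ZEBU are the intermediate crossing
#: generations of the grading-up scheme, CANCHIM (expected 5/8 Charolais) and
#: MA (Charolais sire x Canchim-Zebu dam, expected 21/32 Charolais) are the
#: genotyped composite groups.
GENETIC_GROUPS = (
    "CHAROLAIS",
    "ZEBU",
    "F1",
    "CROSS_3_4",
    "CANCHIM_X_ZEBU",
    "CANCHIM",
    "MA",
)


class DataValidationError(ValueError):
    """Input violates a structural invariant."""


class VcfParseError(DataValidationError):
    """A VCF record could not be parsed or is unsupported."""


def _norm_chrom(label: str) -> str:
    return re.sub(r"^chr", "", str(label), flags=re.IGNORECASE)


# ---------------------------------------------------------------------------
# MarkerMap
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Per-marker chromosome, 1-based bp position, cM position and alleles.

    ``table`` columns: marker_id, chromosome, position_bp, position_cm,
    allele_a, allele_b.  Marker order is file order; within a chromosome the
    bp positions must be strictly increasing and the cM positions
    non-decreasing.
    """

    table: pd.DataFrame

    REQUIRED = ("marker_id", "chromosome", "position_bp", "position_cm",
                "allele_a", "allele_b")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise DataValidationError(f"marker map missing columns: {missing}")
        t = t.reset_index(drop=True).copy()
        t["marker_id"] = t["marker_id"].astype(str)
        t["chromosome"] = t["chromosome"].map(_norm_chrom)
        t["position_bp"] = t["position_bp"].astype(np.int64)
        t["position_cm"] = t["position_cm"].astype(float)
        if t["marker_id"].duplicated().any():
            dups = t.loc[t["marker_id"].duplicated(), "marker_id"].tolist()[:5]
            raise DataValidationError(f"duplicate marker ids, e.g. {dups}")
        for chrom, sub in t.groupby("chromosome", sort=False):
            bp = sub["position_bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise DataValidationError(
                    f"bp positions not strictly increasing on chromosome {chrom}")
            cm = sub["position_cm"].to_numpy()
            if np.any(np.diff(cm) < 0):
                raise DataValidationError(
                    f"cM positions decreasing on chromosome {chrom}")
            if np.any(cm < 0):
                raise DataValidationError(
                    f"negative cM position on chromosome {chrom}")
        if (t["position_bp"] < 1).any():
            raise DataValidationError("bp positions must be 1-based positive")
        self.table = t
        self._index = pd.Index(t["marker_id"])

    # -- accessors ---------------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in file order."""
        return list(dict.fromkeys(self.table["chromosome"]))

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Marker indices (file order) belonging to ``chrom``."""
        return np.flatnonzero(
            (self.table["chromosome"] == _norm_chrom(chrom)).to_numpy())

    def indices_of(self, marker_ids: Iterable[str]) -> np.ndarray:
        idx = self._index.get_indexer(list(marker_ids))
        if (idx < 0).any():
            bad = [m for m, i in zip(marker_ids, idx) if i < 0][:10]
            raise DataValidationError(f"unknown marker ids: {bad}")
        return idx

    def is_autosomal(self) -> np.ndarray:
        """Boolean mask of markers on an autosome with a known position."""
        chrom_ok = self.table["chromosome"].str.fullmatch(r"[0-9]+").to_numpy()
        pos_ok = (self.table["position_bp"].to_numpy() >= 1)
        return chrom_ok & pos_ok

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.asarray(indices)].reset_index(drop=True))


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x markers allele-B counts, optionally with a phased pair.

    ``genotypes``: int8 array (n_samples, n_markers) in {0,1,2,MISSING}.
    ``phase``: optional int8 array (n_samples, n_markers, 2) in {0,1,MISSING};
    wherever both haplotype alleles are present their sum equals the genotype.
    """

    sample_ids: list[str]
    genotypes: np.ndarray
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataValidationError("duplicate sample ids")
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 2 or g.shape[0] != len(self.sample_ids):
            raise DataValidationError(
                f"genotype matrix shape {g.shape} does not match "
                f"{len(self.sample_ids)} samples")
        valid = np.isin(g, (0, 1, 2, MISSING))
        if not valid.all():
            raise DataValidationError("genotype codes outside {0,1,2,missing}")
        self.genotypes = g
        if self.phase is not None:
            ph = np.asarray(self.phase, dtype=np.int8)
            if ph.shape != g.shape + (2,):
                raise DataValidationError("phase array shape mismatch")
            both = (ph >= 0).all(axis=2)
            s = ph[..., 0].astype(np.int16) + ph[..., 1]
            if np.any(both & (g >= 0) & (s != g)):
                raise DataValidationError("phase pair does not sum to genotype")
            self.phase = ph

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise DataValidationError(f"unknown sample id {exc}") from None

    def subset(self, sample_idx: np.ndarray | None = None,
               marker_idx: np.ndarray | None = None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        ph = None if self.phase is None else self.phase[np.ix_(si, mi)]
        return GenotypeMatrix([self.sample_ids[i] for i in si],
                              self.genotypes[np.ix_(si, mi)], ph)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.sample_ids), self.genotypes.copy(),
                              None if self.phase is None else self.phase.copy())

    def drop_phase(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.sample_ids), self.genotypes.copy(), None)


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """Sample metadata: id, sex, birth year, genetic group, sire, dam."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "sex", "birth_year", "genetic_group")

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise DataValidationError(f"sample table missing columns: {missing}")
        t["sample_id"] = t["sample_id"].astype(str)
        if t["sample_id"].duplicated().any():
            raise DataValidationError("duplicate sample ids in sample table")
        bad_sex = ~t["sex"].isin(SEXES)
        if bad_sex.any():
            raise DataValidationError(
                f"unknown sex token(s): {sorted(t.loc[bad_sex, 'sex'].unique())}")
        bad_grp = ~t["genetic_group"].isin(GENETIC_GROUPS)
        if bad_grp.any():
            raise DataValidationError(
                "unknown genetic group(s): "
                f"{sorted(t.loc[bad_grp, 'genetic_group'].unique())}")
        t["birth_year"] = t["birth_year"].astype(int)
        for col in ("sire_id", "dam_id"):
            if col not in t.columns:
                t[col] = None
            t[col] = t[col].map(
                lambda v: None if v is None or (isinstance(v, float) and np.isnan(v))
                or str(v) in ("", "0", "NA", "nan", "None") else str(v))
        known = set(t["sample_id"])
        external = {p for p in pd.concat([t["sire_id"], t["dam_id"]]).dropna()
                    if p not in known}
        if external:
            log.info("sample table: %d parent id(s) not present in the table "
                     "(treated as ungenotyped founders)", len(external))
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def subset_ids(self, **conditions) -> list[str]:
        """Sample ids matching equality/callable conditions on columns."""
        mask = np.ones(len(self.table), dtype=bool)
        for col, cond in conditions.items():
            vals = self.table[col]
            mask &= vals.map(cond).to_numpy() if callable(cond) else (vals == cond).to_numpy()
        return self.table.loc[mask, "sample_id"].tolist()


# ---------------------------------------------------------------------------
# PanelManifest
# ---------------------------------------------------------------------------


@dataclass
class PanelManifest:
    """A named set of marker ids defining a (low-density) genotyping panel.

    Order is preserved for reproducible output; ids are unique.
    """

    name: str
    marker_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [str(m) for m in self.marker_ids]
        if not ids:
            raise DataValidationError(f"panel {self.name!r} is empty")
        seen: dict[str, None] = {}
        dups = 0
        for m in ids:
            if m in seen:
                dups += 1
            seen[m] = None
        if dups:
            log.warning("panel %s: collapsed %d duplicate marker id(s)",
                        self.name, dups)
        self.marker_ids = list(seen)

    def __len__(self) -> int:
        return len(self.marker_ids)

    def resolve(self, marker_map: MarkerMap,
                on_missing: str = "error") -> tuple[np.ndarray, list[str]]:
        """Map panel ids to marker-map indices (sorted to map order).

        Unresolvable ids are reported: ``on_missing='error'`` raises naming
        them, ``'report'`` returns them in the second element.
        """
        idx = marker_map._index.get_indexer(self.marker_ids)
        missing = [m for m, i in zip(self.marker_ids, idx) if i < 0]
        if missing and on_missing == "error":
            raise DataValidationError(
                f"panel {self.name}: {len(missing)} marker id(s) not in the "
                f"marker map, e.g. {missing[:10]}")
        if missing:
            log.warning("panel %s: %d unresolvable marker id(s)",
                        self.name, len(missing))
        return np.sort(idx[idx >= 0]), missing


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_genotypes(vcf_path: str | Path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a bi-allelic SNP VCF into a genotype matrix plus marker map.

    Phased records ("|") populate the phase array; unphased records populate
    the genotype only; missing calls become :data:`MISSING`.  Multi-allelic or
    non-SNP records are a hard error naming the marker.  A ``CM`` INFO field
    supplies the genetic position; absent that, 1 cM/Mb is assumed.
    """
    from cyvcf2 import VCF

    path = Path(vcf_path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib-level failure
        raise VcfParseError(f"{path}: cannot open as VCF ({exc})") from exc
    samples = list(vcf.samples)
    genos: list[np.ndarray] = []
    phases: list[np.ndarray] = []
    rows = []
    any_phase = False
    recno = 0
    try:
        for var in vcf:
            recno += 1
            if len(var.ALT) != 1:
                raise VcfParseError(
                    f"{path} record {recno} ({var.ID or var.CHROM}:{var.POS}): "
                    "multi-allelic site; only bi-allelic SNPs are supported")
            if len(var.REF) != 1 or len(var.ALT[0]) != 1:
                raise VcfParseError(
                    f"{path} record {recno} ({var.ID or var.CHROM}:{var.POS}): "
                    "not a SNP; only bi-allelic SNPs are supported")
            arr = var.genotype.array()  # (n, 3): allele0, allele1, phased
            a0 = arr[:, 0].astype(np.int16)
            a1 = arr[:, 1].astype(np.int16)
            phased = arr[:, 2].astype(bool)
            called = (a0 >= 0) & (a1 >= 0)
            g = np.where(called, a0 + a1, MISSING).astype(np.int8)
            ph = np.full((len(samples), 2), MISSING, dtype=np.int8)
            use = called & phased
            ph[use, 0] = a0[use]
            ph[use, 1] = a1[use]
            any_phase = any_phase or bool(use.any())
            genos.append(g)
            phases.append(ph)
            cm = var.INFO.get("CM")
            rows.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS,
                         float(cm) if cm is not None else var.POS / 1e6,
                         var.REF, var.ALT[0]))
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"{path} record {recno + 1}: parse error ({exc})") from exc
    if not rows:
        raise VcfParseError(f"{path}: no variant records")
    mmap = MarkerMap(pd.DataFrame(rows, columns=list(MarkerMap.REQUIRED)))
    g = np.stack(genos, axis=1)
    ph = np.stack(phases, axis=1) if any_phase else None
    return GenotypeMatrix(samples, g, ph), mmap


_GT_UNPHASED = np.array(["./.", "0/0", "0/1", "1/1"], dtype=object)
_GT_PHASED = np.array([["0|0", "0|1"], ["1|0", "1|1"]], dtype=object)


def write_genotypes(matrix: GenotypeMatrix, marker_map: MarkerMap,
                    path: str | Path, dosages: np.ndarray | None = None) -> None:
    """Write a VCF 4.2 file; phase is preserved, missing entries become ./. .

    ``dosages`` (same shape as the genotype matrix) adds a DS FORMAT field
    with the imputed allele-B dosage.
    """
    if matrix.n_markers != marker_map.n_markers:
        raise DataValidationError(
            f"matrix has {matrix.n_markers} markers, map has {marker_map.n_markers}")
    if dosages is not None and dosages.shape != matrix.genotypes.shape:
        raise DataValidationError("dosage array shape mismatch")
    g = matrix.genotypes
    gt = _GT_UNPHASED[g.astype(np.int16) + 1]
    if matrix.phase is not None:
        ph = matrix.phase
        ok = (ph[..., 0] >= 0) & (ph[..., 1] >= 0)
        gt = gt.copy()
        gt[ok] = _GT_PHASED[ph[..., 0][ok], ph[..., 1][ok]]
    if dosages is not None:
        ds = np.char.mod("%.4f", np.asarray(dosages, dtype=float))
        gt = np.char.add(np.char.add(gt.astype(str), ":"), ds).astype(object)
    t = marker_map.table
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=compimpute\n")
        for chrom in marker_map.chromosomes:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,'
                 'Description="Genetic map position in cM">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dosages is not None:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Imputed allele-B dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        fmt = "GT:DS" if dosages is not None else "GT"
        chroms = t["chromosome"].to_numpy()
        poss = t["position_bp"].to_numpy()
        ids = t["marker_id"].to_numpy()
        refs = t["allele_a"].to_numpy()
        alts = t["allele_b"].to_numpy()
        cms = t["position_cm"].to_numpy()
        for m in range(marker_map.n_markers):
            fh.write(f"{chroms[m]}\t{poss[m]}\t{ids[m]}\t{refs[m]}\t{alts[m]}"
                     f"\t.\t.\tCM={cms[m]:.6f}\t{fmt}\t")
            fh.write("\t".join(gt[:, m]))
            fh.write("\n")


# ---------------------------------------------------------------------------
# TSV / manifest I/O
# ---------------------------------------------------------------------------


def read_marker_map(path: str | Path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))


def write_marker_map(marker_map: MarkerMap, path: str | Path) -> None:
    marker_map.table.to_csv(path, sep="\t", index=False)


def read_sample_table(path: str | Path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                                          "sire_id": str,
                                                          "dam_id": str}))


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.table.to_csv(path, sep="\t", index=False)


def read_panel_manifest(path: str | Path, name: str | None = None) -> PanelManifest:
    """One marker id per line; blank lines and #-comments ignored."""
    path = Path(path)
    ids = [line.strip() for line in path.read_text().splitlines()
           if line.strip() and not line.lstrip().startswith("#")]
    return PanelManifest(name or path.stem, ids)


def write_panel_manifest(panel: PanelManifest, path: str | Path) -> None:
    Path(path).write_text("\n".join(panel.marker_ids) + "\n")
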