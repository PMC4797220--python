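"""Data containers, file I/O, SNP/animal quality control and phenotype encoding.

The mapping pipeline works on a phased haplotype panel aligned to a marker
map, a pedigree, and per-animal diagnostic records.  Diagnostic evidence is
converted into the quantitative phenotype vector **y** of the mixed model:
disease-free animals are coded 1.0, progeny-confirmed carriers 2.0 and
pathologically confirmed affected animals 3.0, with interpolated codes
(2.25/2.5/2.75) for clinically diagnosed animals whose status is supported
only by pedigree evidence of carrier ancestors.

SNP quality control applies, in order: per-SNP missingness, Mendelian
(paternity) conflict rate over checkable parent-offspring pairs, missing map
position, observed heterozygosity, and off-target chromosome.  Animals with
genotyping call rate below 0.95 are flagged but never removed.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Per-SNP chromosome, physical (1-based bp) and genetic (Morgan) position.

    Attributes
    ----------
    ids : list of str
        SNP identifiers, in map order.
    chrom : ndarray of str
        Chromosome of each SNP.
    bp : ndarray of int
        1-based physical positions, strictly increasing within a chromosome.
    morgans : ndarray of float
        Genetic positions in Morgans, non-decreasing within a chromosome.
    """

    ids: list
    chrom: np.ndarray
    bp: np.ndarray
    morgans: np.ndarray

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.morgans = np.asarray(self.morgans, dtype=float)
        for c in np.unique(self.chrom):
            sel = self.chrom == c
            if not np.all(np.diff(self.bp[sel]) > 0):
                raise ValueError(f"bp positions not strictly increasing on {c}")
            if not np.all(np.diff(self.morgans[sel]) >= 0):
                raise ValueError(f"genetic positions decreasing on {c}")

    @property
    def n_snps(self) -> int:
        return len(self.ids)

    def subset(self, idx) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap([self.ids[i] for i in idx], self.chrom[idx],
                         self.bp[idx], self.morgans[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "chrom": self.chrom,
                             "bp": self.bp, "morgans": self.morgans})


@dataclass
class HaplotypePanel:
    """Phased (or unphased) allele matrix with two haplotype rows per animal.

    Rows ``2j`` and ``2j+1`` hold the two haplotypes of animal ``j``.  For
    phased data row ``2j`` is the maternally and ``2j+1`` the paternally
    inherited haplotype where that is known.  Alleles are 0/1 with
    ``MISSING`` (-1) for no-calls.
    """

    animals: list
    alleles: np.ndarray
    phased: bool = True

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] % 2 != 0:
            raise ValueError("allele matrix must be 2*n_animals x n_snps")
        if self.alleles.shape[0] != 2 * len(self.animals):
            raise ValueError("row count does not match animal count")

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def genotypes(self) -> np.ndarray:
        """Collapse haplotypes to 0/1/2 genotype dosage; MISSING if either allele is."""
        a = self.alleles[0::2].astype(np.int16)
        b = self.alleles[1::2].astype(np.int16)
        g = a + b
        g[(a == MISSING) | (b == MISSING)] = MISSING
        return g

    def subset_animals(self, ids) -> "HaplotypePanel":
        pos = {a: i for i, a in enumerate(self.animals)}
        idx = [pos[i] for i in ids]
        rows = np.array([[2 * i, 2 * i + 1] for i in idx]).ravel()
        return HaplotypePanel(list(ids), self.alleles[rows], self.phased)

    def subset_snps(self, idx) -> "HaplotypePanel":
        return HaplotypePanel(self.animals, self.alleles[:, np.asarray(idx)],
                              self.phased)


class Diagnosis(enum.Enum):
    FREE = "free"
    CARRIER_PROGENY = "carrier_progeny"
    AFFECTED_PATH = "affected_path"
    AFFECTED_CLINICAL = "affected_clinical"


class CarrierEvidence(enum.Enum):
    """Pedigree evidence classes for clinically-diagnosed-only animals."""

    BOTH_SIDES_WITHIN_2 = "both_sides_within_2"
    GAP_3PLUS_GENERATIONS = "gap_3plus_generations"
    SINGLE_OFFICIAL_CARRIER = "single_official_carrier"
    MISSING_PEDIGREE = "missing_pedigree"


@dataclass
class StatusRecord:
    animal_id: str
    diagnosis: Diagnosis
    carrier_ancestor_evidence: CarrierEvidence | None = None

    def __post_init__(self):
        if isinstance(self.diagnosis, str):
            self.diagnosis = Diagnosis(self.diagnosis)
        if isinstance(self.carrier_ancestor_evidence, str):
            self.carrier_ancestor_evidence = CarrierEvidence(
                self.carrier_ancestor_evidence)
        clinical = self.diagnosis is Diagnosis.AFFECTED_CLINICAL
        if clinical and self.carrier_ancestor_evidence is None:
            raise ValueError(
                f"{self.animal_id}: clinical diagnosis requires ancestor evidence")
        if not clinical and self.carrier_ancestor_evidence is not None:
            raise ValueError(
                f"{self.animal_id}: ancestor evidence only valid for clinical diagnosis")


@dataclass
class PhenotypeVector:
    animals: list
    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        allowed = {1.0, 2.0, 2.25, 2.5, 2.75, 3.0}
        bad = set(np.unique(self.y)) - allowed
        if bad:
            raise ValueError(f"invalid phenotype codes {sorted(bad)}")


@dataclass
class QcReport:
    kept_snps: list
    dropped: pd.DataFrame       # columns: snp_id, reason
    flagged_animals: pd.DataFrame  # columns: animal_id, call_rate (all animals)

    DROP_REASONS = ("missingness", "paternity_conflict", "no_map_position",
                    "low_heterozygosity", "off_target_chrom")


@dataclass
class QcConfig:
    max_missing_rate: float = 0.05
    paternity_conflict_rate: float = 0.01
    min_heterozygosity: float = 0.05
    min_call_rate: float = 0.95


# ---------------------------------------------------------------------------
# Phenotype encoding
# ---------------------------------------------------------------------------

_CLINICAL_CODES = {
    CarrierEvidence.BOTH_SIDES_WITHIN_2: 2.75,
    CarrierEvidence.GAP_3PLUS_GENERATIONS: 2.5,
    CarrierEvidence.SINGLE_OFFICIAL_CARRIER: 2.25,
    CarrierEvidence.MISSING_PEDIGREE: 2.0,
}

_DIAGNOSIS_CODES = {
    Diagnosis.FREE: 1.0,
    Diagnosis.CARRIER_PROGENY: 2.0,
    Diagnosis.AFFECTED_PATH: 3.0,
}


def encode_phenotypes(status: list[StatusRecord]) -> PhenotypeVector:
    """Encode diagnostic records into the quantitative phenotype vector y.

    free -> 1.0; progeny-confirmed carrier -> 2.0; pathologically confirmed
    affected -> 3.0.  Clinically diagnosed animals receive interpolated
    values by pedigree evidence: carriers on both pedigree sides within two
    generations -> 2.75, a gap of three or more generations -> 2.5, a single
    official carrier -> 2.25, missing pedigree -> 2.0.
    """
    ys = []
    for rec in status:
        if rec.diagnosis is Diagnosis.AFFECTED_CLINICAL:
            ys.append(_CLINICAL_CODES[rec.carrier_ancestor_evidence])
        elif rec.diagnosis in _DIAGNOSIS_CODES:
            ys.append(_DIAGNOSIS_CODES[rec.diagnosis])
        else:  # pragma: no cover - enum exhausts this
            raise ValueError(f"unknown diagnosis {rec.diagnosis}")
    return PhenotypeVector([r.animal_id for r in status], np.array(ys))


# ---------------------------------------------------------------------------
# SNP / animal quality control
# ---------------------------------------------------------------------------


def _mendel_conflicts(geno: np.ndarray, animals: list, pedigree: pd.DataFrame):
    """Per-SNP Mendelian conflict counts and checkable-comparison counts.

    Uses parent-offspring pair exclusions (parent and child opposite
    homozygotes) plus the trio check that two homozygous parents determine
    the offspring genotype.
    """
    pos = {a: i for i, a in enumerate(animals)}
    m = geno.shape[1]
    conflicts = np.zeros(m, dtype=np.int64)
    checkable = np.zeros(m, dtype=np.int64)
    for _, row in pedigree.iterrows():
        child = row["animal_id"]
        if child not in pos:
            continue
        gc = geno[pos[child]]
        parents = []
        for col in ("sire_id", "dam_id"):
            p = row.get(col, "0")
            if p in (0, "0", None, "") or (isinstance(p, float) and np.isnan(p)):
                continue
            if p not in pos:
                logger.warning("pedigree parent %s not genotyped; pair skipped", p)
                continue
            parents.append(geno[pos[p]])
        for gp in parents:
            ok = (gc != MISSING) & (gp != MISSING)
            checkable += ok
            conflicts += ok & (((gc == 0) & (gp == 2)) | ((gc == 2) & (gp == 0)))
        if len(parents) == 2:
            gs, gd = parents
            ok = (gc != MISSING) & (gs != MISSING) & (gd != MISSING)
            both_hom = ok & (gs != 1) & (gd != 1)
            expected = (gs + gd) // 2
            checkable += both_hom
            conflicts += both_hom & (gc != expected)
    return conflicts, checkable


def filter_snps(panel, marker_map: MarkerMap, pedigree: pd.DataFrame | None,
                target_chrom: str, cfg: QcConfig | None = None,
                snp_ids: list | None = None) -> QcReport:
    """Apply SNP exclusion criteria and report animal call rates.

    Criteria, in precedence order (a SNP receives the first applicable
    reason): (1) missingness above ``cfg.max_missing_rate``; (2) Mendelian
    conflict rate over checkable parent-offspring comparisons above
    ``cfg.paternity_conflict_rate``; (3) no/ambiguous map position; (4)
    observed heterozygosity below ``cfg.min_heterozygosity``; (5) chromosome
    other than ``target_chrom``.  Animals below ``cfg.min_call_rate`` are
    flagged, never removed.

    Parameters
    ----------
    panel : HaplotypePanel or ndarray
        Haplotype panel, or an (n_animals x n_snps) genotype dosage matrix.
    snp_ids : optional
        SNP identifiers when ``panel`` is a raw genotype matrix; defaults to
        the marker-map ids (which must then cover every column).
    """
    cfg = cfg or QcConfig()
    if isinstance(panel, HaplotypePanel):
        geno = panel.genotypes()
        animals = panel.animals
    else:
        geno = np.asarray(panel)
        animals = [f"A{i}" for i in range(geno.shape[0])]
    if geno.size == 0:
        raise ValueError("empty genotype input")
    n, m = geno.shape
    if snp_ids is None:
        if marker_map.n_snps < m:
            raise ValueError("snp_ids required when map does not cover input")
        snp_ids = list(marker_map.ids[:m])
    map_index = {s: i for i, s in enumerate(marker_map.ids)}

    miss_rate = (geno == MISSING).mean(axis=0)
    nonmiss = (geno != MISSING).sum(axis=0)
    het = np.divide((geno == 1).sum(axis=0), nonmiss,
                    out=np.zeros(m), where=nonmiss > 0)
    if pedigree is not None and len(pedigree):
        conf, checkable = _mendel_conflicts(geno, animals, pedigree)
        conf_rate = np.divide(conf, checkable, out=np.zeros(m, dtype=float),
                              where=checkable > 0)
    else:
        conf_rate = np.zeros(m)

    kept, dropped = [], []
    for j, sid in enumerate(snp_ids):
        in_map = sid in map_index
        if miss_rate[j] > cfg.max_missing_rate:
            dropped.append((sid, "missingness"))
        elif conf_rate[j] > cfg.paternity_conflict_rate:
            dropped.append((sid, "paternity_conflict"))
        elif not in_map:
            dropped.append((sid, "no_map_position"))
        elif het[j] < cfg.min_heterozygosity:
            dropped.append((sid, "low_heterozygosity"))
        elif str(marker_map.chrom[map_index[sid]]) != str(target_chrom):
            dropped.append((sid, "off_target_chrom"))
        else:
            kept.append(sid)

    call_rate = (geno != MISSING).mean(axis=1)
    flagged = pd.DataFrame({"animal_id": animals, "call_rate": call_rate,
                            "flagged": call_rate < cfg.min_call_rate})
    n_flag = int(flagged["flagged"].sum())
    if n_flag:
        logger.info("%d animals below call rate %.2f (flagged, not removed)",
                    n_flag, cfg.min_call_rate)
    return QcReport(kept, pd.DataFrame(dropped, columns=["snp_id", "reason"]),
                    flagged)


# ---------------------------------------------------------------------------
# Trio phasing utility
# ---------------------------------------------------------------------------


def trio_phase(geno: np.ndarray, animals: list,
               pedigree: pd.DataFrame | None = None,
               window: int = 10) -> HaplotypePanel:
    """Phase biallelic genotypes by Mendelian transmission plus greedy extension.

    Heterozygous sites are resolved where a genotyped homozygous parent
    forces the transmitted allele; leftover heterozygotes are phased by
    greedy extension against the most frequent compatible local haplotype in
    a ``window``-SNP neighbourhood; remaining missing alleles are imputed to
    the major allele.  Row order per animal is (maternal, paternal).
    Deterministic given input order.  This is a convenience stand-in for a
    proper HMM phaser; the pipeline's contract is phased input.
    """
    geno = np.asarray(geno, dtype=np.int16).copy()
    n, m = geno.shape
    pos = {a: i for i, a in enumerate(animals)}
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    if pedigree is not None:
        for _, row in pedigree.iterrows():
            c = row["animal_id"]
            if c not in pos:
                continue
            for col, arr in (("sire_id", sire), ("dam_id", dam)):
                p = row.get(col, "0")
                if p not in (0, "0", None, "") and p in pos:
                    arr[pos[c]] = pos[p]

    # Mendelian-inconsistent trio sites -> offspring set missing
    n_incons = 0
    for i in range(n):
        if sire[i] < 0 or dam[i] < 0:
            continue
        gs, gd, gc = geno[sire[i]], geno[dam[i]], geno[i]
        ok = (gc != MISSING) & (gs != MISSING) & (gd != MISSING)
        bad = ok & (gs != 1) & (gd != 1) & (gc != (gs + gd) // 2)
        bad |= ((gc != MISSING) & (gs != MISSING)
                & (((gc == 0) & (gs == 2)) | ((gc == 2) & (gs == 0))))
        bad |= ((gc != MISSING) & (gd != MISSING)
                & (((gc == 0) & (gd == 2)) | ((gc == 2) & (gd == 0))))
        n_incons += int(bad.sum())
        geno[i, bad] = MISSING
    if n_incons:
        logger.warning("%d Mendelian-inconsistent sites set missing", n_incons)

    hap = np.full((2 * n, m), MISSING, dtype=np.int8)
    mat, pat = hap[0::2], hap[1::2]
    hom = (geno == 0) | (geno == 2)
    mat[hom] = (geno[hom] // 2).astype(np.int8)
    pat[hom] = (geno[hom] // 2).astype(np.int8)

    # transmission at het sites with an informative (homozygous) parent
    for i in range(n):
        het = geno[i] == 1
        if dam[i] >= 0:
            gd = geno[dam[i]]
            inf = het & ((gd == 0) | (gd == 2))
            mat[i, inf] = (gd[inf] // 2).astype(np.int8)
            pat[i, inf] = 1 - mat[i, inf]
        if sire[i] >= 0:
            gs = geno[sire[i]]
            inf = het & ((gs == 0) | (gs == 2)) & (mat[i] == MISSING)
            pat[i, inf] = (gs[inf] // 2).astype(np.int8)
            mat[i, inf] = 1 - pat[i, inf]

    # greedy local-frequency phasing for leftover heterozygotes
    half = window // 2
    for i in range(n):
        unresolved = np.flatnonzero((geno[i] == 1) & (mat[i] == MISSING))
        for s in unresolved:
            lo, hi = max(0, s - half), min(m, s + half)
            score = np.zeros(2)
            for cand in (0, 1):
                for h, a in ((mat, cand), (pat, 1 - cand)):
                    ref = hap[:, lo:hi]
                    probe = h[i, lo:hi].copy()
                    probe[s - lo] = a
                    known = probe != MISSING
                    if known.sum() == 0:
                        continue
                    match = ((ref[:, known] == probe[known]).all(axis=1)
                             & (ref[:, known] != MISSING).all(axis=1))
                    score[cand] += match.sum()
            cand = 0 if score[0] >= score[1] else 1
            mat[i, s] = cand
            pat[i, s] = 1 - cand

    # impute remaining missing alleles to the major allele
    for j in range(m):
        col = hap[:, j]
        miss = col == MISSING
        if miss.any():
            known = col[~miss]
            major = 1 if known.size and known.mean() > 0.5 else 0
            col[miss] = major
    return HaplotypePanel(list(animals), hap, phased=True)


# ---------------------------------------------------------------------------
# PLINK-style and TSV I/O
# ---------------------------------------------------------------------------


def write_ped_map(panel: HaplotypePanel, marker_map: MarkerMap, prefix: str,
                  pedigree: pd.DataFrame | None = None) -> None:
    """Write space-separated PLINK-style .ped/.map (alleles 1/2, 0 missing)."""
    par = {}
    if pedigree is not None:
        for _, row in pedigree.iterrows():
            par[row["animal_id"]] = (row.get("sire_id", "0"), row.get("dam_id", "0"))
    with open(prefix + ".ped", "w") as fh:
        for i, animal in enumerate(panel.animals):
            s, d = par.get(animal, ("0", "0"))
            a = panel.alleles[2 * i].astype(np.int16) + 1
            b = panel.alleles[2 * i + 1].astype(np.int16) + 1
            a[a == 0] = 0  # MISSING (-1) + 1 -> 0 already
            pairs = np.empty(2 * panel.n_snps, dtype=np.int16)
            pairs[0::2], pairs[1::2] = a, b
            fh.write(f"FAM {animal} {s} {d} 0 -9 "
                     + " ".join(map(str, pairs)) + "\n")
    with open(prefix + ".map", "w") as fh:
        for sid, c, bp, mo in zip(marker_map.ids, marker_map.chrom,
                                  marker_map.bp, marker_map.morgans):
            fh.write(f"{c} {sid} {100 * mo:.6f} {bp}\n")


def read_ped_map(prefix: str, phased: bool = True):
    """Read PLINK-style text .ped/.map written by :func:`write_ped_map`."""
    rows = []
    with open(prefix + ".map") as fh:
        for line in fh:
            c, sid, cm, bp = line.split()
            rows.append((sid, c, int(bp), float(cm) / 100.0))
    mm = MarkerMap([r[0] for r in rows], [r[1] for r in rows],
                   [r[2] for r in rows], [r[3] for r in rows])
    animals, haps, peds = [], [], []
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            animals.append(parts[1])
            peds.append((parts[1], parts[2], parts[3]))
            al = np.array(parts[6:], dtype=np.int16) - 1
            haps.append(al[0::2])
            haps.append(al[1::2])
    panel = HaplotypePanel(animals, np.array(haps, dtype=np.int8), phased)
    pedigree = pd.DataFrame(peds, columns=["animal_id", "sire_id", "dam_id"])
    return panel, mm, pedigree


def write_pedigree(pedigree: pd.DataFrame, path: str) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str).fillna("0")


def write_status(records: list[StatusRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("animal_id\tdiagnosis\tcarrier_ancestor_evidence\n")
        for r in records:
            ev = r.carrier_ancestor_evidence.value if r.carrier_ancestor_evidence else ""
            fh.write(f"{r.animal_id}\t{r.diagnosis.value}\t{ev}\n")


def read_status(path: str) -> list[StatusRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        ev = row["carrier_ancestor_evidence"] or None
        out.append(StatusRecord(row["animal_id"], row["diagnosis"], ev))
    return out
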