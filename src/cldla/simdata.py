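"""Gene-dropping simulator for pedigreed SNP haplotypes with a planted
recessive disease locus.

Founder haplotypes are drawn with independent per-SNP allele frequencies;
linkage disequilibrium then arises purely from transmitting founder
chromosomes through a multi-generation pedigree with crossovers placed by a
Poisson process on the genetic map (Haldane model, no interference).  The
deleterious allele is placed on one (configurable) founder haplotype, so
every affected animal is homozygous for a segment of that founder
chromosome around the locus and every carrier is heterozygous for it --
the structure a young recessive mutation leaves in a closed breed.

Each transmitted haplotype carries a per-locus founder-segment label, which
makes identity-by-descent exactly verifiable and yields the true shared
disease-haplotype interval used as ground truth by the mapping tests.

The study sample drawn from the final generation follows the case/carrier/
control composition of a typical recessive-disease mapping design (default
40 affected + 3 phenocopies, 31 progeny-confirmed carriers and 86 free
animals, 160 in total).  Phenocopies are animals without the mutation that
are nevertheless labelled clinically affected, mirroring historically
misdiagnosed cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import (MISSING, CarrierEvidence, Diagnosis, HaplotypePanel,
                    MarkerMap, StatusRecord)
from .variantmonitor import VariantTable

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study conditions of the simulated mapping design.

    ``study_composition`` counts animals by true disease-locus genotype:
    affected (two copies), carrier (one copy), free (none).  Phenocopies
    are drawn in addition, from zero-copy animals, and labelled affected.
    ``carrier_fraction`` is the share of each intermediate generation bred
    to carry one copy, keeping the mutation segregating the way popular
    carrier sires did historically.
    """

    n_founders: int = 50
    n_generations: int = 6
    n_snps: int = 2000
    chrom_length_bp: int = 120_000_000
    cm_per_mb: float = 1.0
    disease_bp: int = 60_000_000
    carrier_founder_count: int = 1
    study_composition: dict = field(
        default_factory=lambda: {"affected": 40, "carrier": 31, "free": 86})
    missing_rate: float = 0.01
    phenocopy_count: int = 3
    trio_fraction: float = 0.2
    seed: int = 0
    chrom: str = "4"
    carrier_fraction: float = 0.15
    # whether carriers' non-disease gametes enter the random-mating pool
    mix_carrier_kinship: bool = False
    # share of true affected animals with clinical-only records (no
    # pathological confirmation); they receive interpolated phenotype
    # codes, emulating diagnostic uncertainty of historical cases
    clinical_affected_fraction: float = 0.0
    n_background_variants: int = 500
    n_outside_concordant: int = 1

    def validate(self):
        for k in ("affected", "carrier", "free"):
            if self.study_composition.get(k, 0) < 0:
                raise ValueError(f"negative study count for {k}")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0,1)")
        if not (1 <= self.carrier_founder_count <= self.n_founders):
            raise ValueError("carrier_founder_count out of range")
        if not (0 <= self.trio_fraction <= 1):
            raise ValueError("trio_fraction must be in [0,1]")


@dataclass
class SimOutput:
    haplotypes: HaplotypePanel          # panel with missingness applied
    map: MarkerMap
    pedigree: pd.DataFrame              # animal_id, sire_id, dam_id ('0' unknown)
    truth: pd.DataFrame                 # animal_id, copies, is_phenocopy, in_study
    status_records: list
    variant_table: VariantTable | None
    # ground truth, unmasked
    truth_haplotypes: HaplotypePanel = None
    labels: np.ndarray = None           # founder-segment label per SNP, 2n x m
    disease_alleles: np.ndarray = None  # allele at the disease locus per haplotype
    disease_labels: np.ndarray = None   # founder label at the disease locus
    mutant_labels: frozenset = None     # founder haplotype labels bearing the mutation
    shared_interval_bp: tuple = None    # (lo, hi) true shared-haplotype interval
    config: SimConfig = None

    def _study(self):
        t = self.truth
        return t[t.in_study]

    def carriers(self):
        t = self._study()
        return list(t.loc[(t.copies == 1) & ~t.is_phenocopy, "animal_id"])

    def affected(self):
        t = self._study()
        return list(t.loc[t.copies == 2, "animal_id"])

    def free(self):
        t = self._study()
        return list(t.loc[(t.copies == 0) & ~t.is_phenocopy, "animal_id"])

    def phenocopies(self):
        t = self._study()
        return list(t.loc[t.is_phenocopy, "animal_id"])

    def study_animals(self):
        return list(self._study()["animal_id"])


def _sample_positions(rng, n, length):
    """n distinct 1-based positions, uniform on [1, length]."""
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 10))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


class _Indiv:
    __slots__ = ("id", "sire", "dam", "alleles", "labels")

    def __init__(self, id, sire, dam, alleles, labels):
        self.id, self.sire, self.dam = id, sire, dam
        self.alleles, self.labels = alleles, labels

    def copies(self, d_idx):
        return int(self.alleles[0][d_idx] + self.alleles[1][d_idx])


def _gamete(parent: _Indiv, morgans: np.ndarray, rng):
    """One meiosis: Poisson crossovers on the genetic map, no interference."""
    span = morgans[-1] - morgans[0]
    n_x = rng.poisson(span) if span > 0 else 0
    start = int(rng.integers(2))
    if n_x == 0:
        return parent.alleles[start].copy(), parent.labels[start].copy()
    xpts = np.sort(rng.uniform(morgans[0], morgans[-1], n_x))
    phase = (start + np.searchsorted(xpts, morgans, side="right")) % 2
    al = np.where(phase == 0, parent.alleles[0], parent.alleles[1])
    lb = np.where(phase == 0, parent.labels[0], parent.labels[1])
    return al.astype(np.int8), lb.astype(np.int32)


def _gamete_with_allele(parent, morgans, d_idx, want, rng, max_tries=400):
    """Rejection-sample a gamete that carries (want=1) the disease allele."""
    for _ in range(max_tries):
        al, lb = _gamete(parent, morgans, rng)
        if al[d_idx] == want:
            return al, lb
    raise RuntimeError("gamete rejection sampling failed")


def simulate_population(cfg: SimConfig) -> SimOutput:
    """Run the gene-dropping simulation and assemble the study dataset.

    Panel rows per animal are ordered (maternal, paternal).  All randomness
    derives from ``cfg.seed`` via independent sub-streams, so outputs are
    bit-reproducible.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    s_map, s_founder, s_drop, s_sample, s_miss, s_var = ss.spawn(6)
    rng_map = np.random.default_rng(s_map)
    rng_f = np.random.default_rng(s_founder)
    rng = np.random.default_rng(s_drop)
    rng_s = np.random.default_rng(s_sample)
    rng_m = np.random.default_rng(s_miss)

    # --- marker map and locus grid (SNPs + the disease pseudo-locus) ---
    snp_bp = _sample_positions(rng_map, cfg.n_snps, cfg.chrom_length_bp)
    if not (snp_bp[0] < cfg.disease_bp < snp_bp[-1]):
        raise ValueError("disease_bp must lie strictly between first and last SNP")
    if cfg.disease_bp in snp_bp:
        snp_bp[np.searchsorted(snp_bp, cfg.disease_bp)] += 1
        snp_bp = np.sort(snp_bp)
    loci_bp = np.sort(np.append(snp_bp, cfg.disease_bp))
    d_idx = int(np.searchsorted(loci_bp, cfg.disease_bp))
    snp_idx = np.delete(np.arange(loci_bp.size), d_idx)
    morgans = loci_bp * cfg.cm_per_mb / 1e8  # bp -> Morgans, uniform map
    mm = MarkerMap([f"snp{i:05d}" for i in range(cfg.n_snps)],
                   [cfg.chrom] * cfg.n_snps, loci_bp[snp_idx],
                   morgans[snp_idx])

    # --- founders ---
    freqs = rng_f.uniform(0.05, 0.95, loci_bp.size)
    founders = []
    for f in range(cfg.n_founders):
        al = [(rng_f.random(loci_bp.size) < freqs).astype(np.int8)
              for _ in range(2)]
        for a in al:
            a[d_idx] = 0
        lb = [np.full(loci_bp.size, 2 * f + h, dtype=np.int32)
              for h in range(2)]
        founders.append(_Indiv(f"F{f:03d}", "0", "0", al, lb))
    mutant_labels = set()
    for f in range(cfg.carrier_founder_count):
        founders[f].alleles[0][d_idx] = 1
        mutant_labels.add(2 * f)

    comp = cfg.study_composition
    n_study = (comp.get("affected", 0) + comp.get("carrier", 0)
               + comp.get("free", 0) + cfg.phenocopy_count)
    gen_size = max(cfg.n_founders, n_study + 40)
    carrier_target = max(4, int(round(cfg.carrier_fraction * gen_size)))

    # --- gene dropping ---
    prev, penult = founders, []
    counter = 0

    def breed(kind, g, carriers_prev, others_prev):
        nonlocal counter
        counter += 1
        cid = f"G{g}_{counter:04d}"
        try:
            if kind == "affected":
                if len(carriers_prev) < 2:
                    raise ValueError(
                        "composition unreachable: fewer than two carrier "
                        "parents available for affected class")
                i, j = rng.choice(len(carriers_prev), 2, replace=False)
                sire, dam = carriers_prev[i], carriers_prev[j]
                am, lm = _gamete_with_allele(dam, morgans, d_idx, 1, rng)
                ap, lp = _gamete_with_allele(sire, morgans, d_idx, 1, rng)
            elif kind == "carrier":
                if not carriers_prev or not others_prev:
                    raise ValueError(
                        "composition unreachable: carrier or non-carrier "
                        "parents missing for carrier class")
                sire = carriers_prev[int(rng.integers(len(carriers_prev)))]
                dam = others_prev[int(rng.integers(len(others_prev)))]
                am, lm = _gamete(dam, morgans, rng)
                ap, lp = _gamete_with_allele(sire, morgans, d_idx, 1, rng)
            else:
                # random matings; with kinship mixing enabled, carrier
                # parents contribute their non-disease-bearing gametes so
                # carrier kinship spreads into the control pool
                pool = prev if cfg.mix_carrier_kinship else others_prev
                if len(pool) < 2:
                    raise ValueError(
                        "composition unreachable: fewer than two parents "
                        "available for random matings")
                i, j = rng.choice(len(pool), 2, replace=False)
                sire, dam = pool[i], pool[j]
                am, lm = _gamete_with_allele(dam, morgans, d_idx, 0, rng) \
                    if dam.copies(d_idx) else _gamete(dam, morgans, rng)
                ap, lp = _gamete_with_allele(sire, morgans, d_idx, 0, rng) \
                    if sire.copies(d_idx) else _gamete(sire, morgans, rng)
        except RuntimeError as e:  # pragma: no cover
            raise ValueError(f"composition unreachable: {e}") from e
        return _Indiv(cid, sire.id, dam.id, [am, ap], [lm, lp])

    for g in range(1, cfg.n_generations + 1):
        carriers_prev = [p for p in prev if p.copies(d_idx) >= 1]
        others_prev = [p for p in prev if p.copies(d_idx) == 0]
        final = g == cfg.n_generations
        cur = []
        if final:
            for _ in range(comp.get("affected", 0)):
                cur.append(breed("affected", g, carriers_prev, others_prev))
            for _ in range(comp.get("carrier", 0)):
                cur.append(breed("carrier", g, carriers_prev, others_prev))
        while len(cur) < gen_size:
            cur.append(breed("random", g, carriers_prev, others_prev))
        if not final:
            # top up carriers so the mutation neither fixes nor dies out
            n_car = sum(1 for ind in cur if ind.copies(d_idx) >= 1)
            deficit = carrier_target - n_car
            if deficit > 0:
                replaceable = [k for k, ind in enumerate(cur)
                               if ind.copies(d_idx) == 0]
                for k in replaceable[-deficit:]:
                    cur[k] = breed("carrier", g, carriers_prev, others_prev)
        penult, prev = prev, cur

    # --- draw the study sample from the final generation ---
    pool = prev if cfg.n_generations > 0 else founders
    by_copies = {0: [], 1: [], 2: []}
    for ind in pool:
        by_copies[ind.copies(d_idx)].append(ind)
    for lst in by_copies.values():
        rng_s.shuffle(lst)

    def take(cls, n, kind):
        if len(by_copies[cls]) < n:
            raise ValueError(
                f"composition unreachable: need {n} {kind} animals, "
                f"only {len(by_copies[cls])} available")
        out, by_copies[cls][:n] = by_copies[cls][:n], []
        return out

    affected = take(2, comp.get("affected", 0), "affected")
    carriers = take(1, comp.get("carrier", 0), "carrier")
    free = take(0, comp.get("free", 0), "free")
    phenocopies = take(0, cfg.phenocopy_count, "phenocopy (zero-copy)")
    study = affected + carriers + free + phenocopies

    # trio parents: genotyped parents for a fraction of the study animals
    parent_by_id = {ind.id: ind for ind in penult}
    trio_parents = []
    trio_child_ids = set()
    if cfg.trio_fraction > 0 and cfg.n_generations > 0:
        n_trio = int(round(cfg.trio_fraction * len(study)))
        chosen = rng_s.choice(len(study), size=min(n_trio, len(study)),
                              replace=False)
        seen = {ind.id for ind in study}
        for ci in sorted(chosen):
            child = study[ci]
            trio_child_ids.add(child.id)
            for pid in (child.sire, child.dam):
                if pid in parent_by_id and pid not in seen:
                    trio_parents.append(parent_by_id[pid])
                    seen.add(pid)

    # diagnostic records: most affected are pathologically confirmed, a
    # share carries clinical-only records with interpolated codes
    n_clin = int(round(cfg.clinical_affected_fraction * len(affected)))
    clin_ids = {ind.id for ind in
                (rng_s.choice(affected, n_clin, replace=False)
                 if n_clin else [])}
    evidence_classes = [CarrierEvidence.BOTH_SIDES_WITHIN_2,
                        CarrierEvidence.GAP_3PLUS_GENERATIONS,
                        CarrierEvidence.SINGLE_OFFICIAL_CARRIER]
    clin_evidence = {aid: evidence_classes[int(rng_s.integers(3))]
                     for aid in clin_ids}

    panel_inds = study + trio_parents
    return _assemble(cfg, mm, loci_bp, morgans, d_idx, snp_idx, panel_inds,
                     set(i.id for i in study), trio_child_ids,
                     affected, carriers, phenocopies, mutant_labels,
                     clin_evidence, rng_m, s_var)


def _assemble(cfg, mm, loci_bp, morgans, d_idx, snp_idx, panel_inds,
              study_ids, trio_child_ids, affected, carriers, phenocopies,
              mutant_labels, clin_evidence, rng_m, s_var):
    n = len(panel_inds)
    H = np.empty((2 * n, loci_bp.size), dtype=np.int8)
    L = np.empty((2 * n, loci_bp.size), dtype=np.int32)
    panel_id_set = {ind.id for ind in panel_inds}
    ped_rows, truth_rows, status = [], [], []
    aff_ids = {i.id for i in affected}
    car_ids = {i.id for i in carriers}
    pheno_ids = {i.id for i in phenocopies}
    for j, ind in enumerate(panel_inds):
        H[2 * j], H[2 * j + 1] = ind.alleles[0], ind.alleles[1]
        L[2 * j], L[2 * j + 1] = ind.labels[0], ind.labels[1]
        # parents outside the genotyped panel are recorded as unknown
        sire = ind.sire if ind.sire in panel_id_set else "0"
        dam = ind.dam if ind.dam in panel_id_set else "0"
        ped_rows.append((ind.id, sire, dam))
        truth_rows.append((ind.id, ind.copies(d_idx), ind.id in pheno_ids,
                           ind.id in study_ids))
        if ind.id not in study_ids:
            continue
        if ind.id in aff_ids:
            if ind.id in clin_evidence:
                status.append(StatusRecord(ind.id, Diagnosis.AFFECTED_CLINICAL,
                                           clin_evidence[ind.id]))
            else:
                status.append(StatusRecord(ind.id, Diagnosis.AFFECTED_PATH))
        elif ind.id in car_ids:
            status.append(StatusRecord(ind.id, Diagnosis.CARRIER_PROGENY))
        elif ind.id in pheno_ids:
            status.append(StatusRecord(ind.id, Diagnosis.AFFECTED_CLINICAL,
                                       CarrierEvidence.SINGLE_OFFICIAL_CARRIER))
        else:
            status.append(StatusRecord(ind.id, Diagnosis.FREE))

    animals = [ind.id for ind in panel_inds]
    snpH, snpL = H[:, snp_idx], L[:, snp_idx]
    truth_panel = HaplotypePanel(animals, snpH.copy(), phased=True)

    masked = snpH.copy()
    if cfg.missing_rate > 0:
        mask = rng_m.random((n, cfg.n_snps)) < cfg.missing_rate
        masked[np.repeat(mask, 2, axis=0)] = MISSING
    panel = HaplotypePanel(animals, masked, phased=True)

    truth = pd.DataFrame(truth_rows, columns=["animal_id", "copies",
                                              "is_phenocopy", "in_study"])
    pedigree = pd.DataFrame(ped_rows,
                            columns=["animal_id", "sire_id", "dam_id"])
    disease_alleles = H[:, d_idx].copy()
    disease_labels = L[:, d_idx].copy()
    shared = _shared_interval(snpL, disease_labels, disease_alleles,
                              mm.bp, loci_bp[d_idx])
    sim = SimOutput(haplotypes=panel, map=mm, pedigree=pedigree, truth=truth,
                    status_records=status, variant_table=None,
                    truth_haplotypes=truth_panel, labels=snpL,
                    disease_alleles=disease_alleles,
                    disease_labels=disease_labels,
                    mutant_labels=frozenset(mutant_labels),
                    shared_interval_bp=shared, config=cfg)
    if len(sim.carriers()) >= 2:
        region = shared
        if not np.any((mm.bp >= region[0]) & (mm.bp <= region[1])):
            # degenerate truth interval: widen to the flanking SNPs
            left = int(np.searchsorted(mm.bp, cfg.disease_bp)) - 1
            region = (int(mm.bp[max(left, 0)]),
                      int(mm.bp[min(left + 1, mm.bp.size - 1)]))
        sim.variant_table = make_variant_table(
            sim, region=region, n_background=cfg.n_background_variants,
            n_outside_concordant=cfg.n_outside_concordant,
            seed=int(np.random.default_rng(s_var).integers(2 ** 31)))
    return sim


def _shared_interval(snp_labels, disease_labels, disease_alleles, bp,
                     disease_bp):
    """Intersection, over all mutation-bearing haplotypes, of the
    founder-segment run around the disease locus.  Returned as a closed bp
    interval on the SNP grid; degenerate at the locus if empty."""
    hap_rows = np.flatnonzero(disease_alleles == 1)
    if hap_rows.size == 0:
        return (int(disease_bp), int(disease_bp))
    left = int(np.searchsorted(bp, disease_bp)) - 1
    lo_idx, hi_idx = 0, bp.size - 1
    for r in hap_rows:
        lab, row = disease_labels[r], snp_labels[r]
        i = left
        while i >= 0 and row[i] == lab:
            i -= 1
        lo_idx = max(lo_idx, i + 1)
        i = left + 1
        while i < bp.size and row[i] == lab:
            i += 1
        hi_idx = min(hi_idx, i - 1)
    if lo_idx > hi_idx:
        return (int(disease_bp), int(disease_bp))
    # the IBD segment physically straddles the locus even when no SNP of
    # the run falls on one side of it
    return (int(min(bp[lo_idx], disease_bp)),
            int(max(bp[hi_idx], disease_bp)))


def make_variant_table(sim: SimOutput, region: tuple, n_background: int,
                       n_outside_concordant: int, seed: int,
                       include_affected: bool = False) -> VariantTable:
    """Build a region-restricted sequence-variant table for concordance tests.

    The table emulates a deep resequencing panel genotyped at every variant
    in a candidate region: (a) the causal variant at the disease locus,
    whose alternative allele sits exactly on the mutation-bearing
    haplotypes; (b) ``n_background`` variants whose alleles are planted on
    founder haplotypes and propagated through the simulated mosaic, hence
    in LD with local SNPs but not (except by rare chance) concordant with
    carrier status; (c) ``n_outside_concordant`` variants outside
    ``region`` that are perfectly concordant with carrier/affected status.

    By default the genotyped subset is the designated carriers plus the
    zero-copy animals (free and phenocopies), mirroring a resequencing
    panel of known carriers and population controls without affected
    animals among them.
    """
    lo, hi = int(region[0]), int(region[1])
    cfg = sim.config
    bp = sim.map.bp
    if lo > bp[-1] or hi < bp[0]:
        raise ValueError("region does not overlap the simulated chromosome")
    if not np.any((bp >= lo) & (bp <= hi)):
        raise ValueError("region contains no SNP anchors")
    carriers = sim.carriers()
    if len(carriers) < 2:
        raise ValueError("need at least 2 carriers for a variant table")
    animals = carriers + (sim.affected() if include_affected else []) \
        + sim.free() + sim.phenocopies()
    pos_in_panel = {a: i for i, a in enumerate(sim.haplotypes.animals)}
    idx = np.array([pos_in_panel[a] for a in animals])
    copies = (sim.truth.set_index("animal_id")
              .loc[animals, "copies"].to_numpy())

    rng = np.random.default_rng(seed)
    n_founder_haps = 2 * cfg.n_founders
    records = [(cfg.disease_bp, copies.astype(np.int8), True, "SNP")]

    if n_background > 0:
        positions = rng.integers(lo, hi + 1, size=n_background)
        anchor = np.clip(np.searchsorted(bp, positions), 0, bp.size - 1)
        hap_rows = np.array([[2 * i, 2 * i + 1] for i in idx]).ravel()
        mut = np.array(sorted(sim.mutant_labels))
        non_mut = np.array([l for l in range(n_founder_haps)
                            if l not in sim.mutant_labels])
        noncarrier_rows = np.array(
            [[2 * i, 2 * i + 1] for i, c in zip(idx, copies) if c == 0]
        ).ravel()
        for pos_v, a_idx in zip(positions, anchor):
            f = rng.uniform(0.05, 0.95)
            founder_allele = (rng.random(n_founder_haps) < f).astype(np.int8)
            # Standing variants on the ancestral haplotype predate the
            # mutation, so mutation-free copies of that haplotype in the
            # control panel carry them too (the reason deep control
            # panels leave only the causal mutation concordant): never
            # leave the alternative allele private to the mutant branch.
            carried_by_mut = founder_allele[mut].any()
            carried_by_noncarrier = founder_allele[
                sim.labels[noncarrier_rows, a_idx]].any()
            if carried_by_mut and not carried_by_noncarrier:
                present = np.unique(sim.labels[noncarrier_rows, a_idx])
                candidates = present[~np.isin(present, mut)]
                if candidates.size == 0:
                    candidates = non_mut
                founder_allele[candidates[rng.integers(candidates.size)]] = 1
            hap_al = founder_allele[sim.labels[hap_rows, a_idx]]
            g = hap_al[0::2] + hap_al[1::2]
            vtype = "indel" if rng.random() < 0.05 else "SNP"
            records.append((int(pos_v), g.astype(np.int8), False, vtype))

    for _ in range(n_outside_concordant):
        if hi + 2000 < cfg.chrom_length_bp:
            pos_v = int(rng.integers(hi + 1000,
                                     min(cfg.chrom_length_bp, hi + 2_000_000)))
        else:
            pos_v = int(rng.integers(1, lo))
        records.append((pos_v, copies.astype(np.int8), False, "SNP"))

    # resolve position collisions deterministically, then sort
    seen, final = set(), []
    for pos_v, g, causal, vtype in sorted(records, key=lambda r: r[0]):
        while pos_v in seen:
            pos_v += 1
        seen.add(pos_v)
        final.append((pos_v, g, causal, vtype))
    final.sort(key=lambda r: r[0])

    meta = pd.DataFrame({
        "chrom": cfg.chrom,
        "pos": [r[0] for r in final],
        "id": [f"var{i:06d}" for i in range(len(final))],
        "ref": "A",
        "alt": ["AT" if r[3] == "indel" else "G" for r in final],
        "vtype": [r[3] for r in final],
        "is_causal": [r[2] for r in final],
    })
    geno = np.stack([r[1] for r in final])
    return VariantTable(meta, geno, list(animals))
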