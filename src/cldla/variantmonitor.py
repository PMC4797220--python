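"""Carrier-concordance filtering of sequence variants and population
monitoring of a candidate causal allele.

Given a variant table over a resequencing panel that contains a set of
known heterozygous carriers, a variant is *concordant* with carrier status
when every known carrier is heterozygous and every other genotyped animal
is homozygous for the reference allele.  Restricting candidates to the
interval of extended homozygosity first and then filtering for concordance
is what reduces tens of thousands of regional variants to a single
candidate causal mutation.

The monitoring side converts per-stratum genotype counts (e.g. by birth
year) into allele frequencies and a Hardy-Weinberg carrier-mating risk:
for allele frequency q the carrier frequency is 2q(1-q) and the chance
that a random mating produces an affected offspring is (2q(1-q))^2 / 4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GT_MISSING = -1
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2


@dataclass
class VariantTable:
    """Biallelic variants with per-animal genotype dosages.

    ``meta`` holds one row per variant (chrom, pos, id, ref, alt, vtype);
    ``genotypes`` is an (n_variants x n_animals) int matrix coded
    0=hom-ref, 1=het, 2=hom-alt, -1=missing.  Positions must be sorted.
    """

    meta: pd.DataFrame
    genotypes: np.ndarray
    animals: list

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.meta), len(self.animals)):
            raise ValueError("genotype matrix shape mismatch")
        if not self.meta["pos"].is_monotonic_increasing:
            raise ValueError("variant positions must be sorted")

    @property
    def n_variants(self) -> int:
        return len(self.meta)

    def subset(self, row_mask) -> "VariantTable":
        return VariantTable(self.meta[row_mask].reset_index(drop=True),
                            self.genotypes[np.asarray(row_mask)],
                            self.animals)

    # ------------------------------------------------------------------
    # VCF 4.2 I/O
    # ------------------------------------------------------------------
    def to_vcf(self, path: str) -> None:
        import pysam
        header = pysam.VariantHeader()
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        for c in pd.unique(self.meta["chrom"]):
            header.contigs.add(str(c))
        for a in self.animals:
            header.add_sample(str(a))
        gt_map = {GT_HOM_REF: (0, 0), GT_HET: (0, 1), GT_HOM_ALT: (1, 1),
                  GT_MISSING: (None, None)}
        with pysam.VariantFile(path, "w", header=header) as out:
            for i, row in self.meta.iterrows():
                rec = out.new_record(contig=str(row["chrom"]),
                                     start=int(row["pos"]) - 1,
                                     stop=int(row["pos"]) - 1 + len(row["ref"]),
                                     alleles=(row["ref"], row["alt"]),
                                     id=row["id"])
                for j, a in enumerate(self.animals):
                    rec.samples[str(a)]["GT"] = gt_map[int(self.genotypes[i, j])]
                    rec.samples[str(a)].phased = False
                out.write(rec)

    @classmethod
    def from_vcf(cls, path: str) -> "VariantTable":
        import pysam
        rows, genos = [], []
        with pysam.VariantFile(path) as vcf:
            animals = list(vcf.header.samples)
            for rec in vcf:
                if rec.alts is None or len(rec.alts) != 1:
                    raise ValueError(
                        f"{rec.chrom}:{rec.pos}: only biallelic records "
                        "supported (split multi-allelics upstream)")
                vtype = ("SNP" if len(rec.ref) == 1 and len(rec.alts[0]) == 1
                         else "indel")
                rows.append((rec.chrom, rec.pos, rec.id or ".",
                             rec.ref, rec.alts[0], vtype))
                g = []
                for a in animals:
                    gt = rec.samples[a]["GT"]
                    if gt is None or None in gt:
                        g.append(GT_MISSING)
                    else:
                        g.append(int(sum(gt)))
                genos.append(g)
        meta = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref",
                                           "alt", "vtype"])
        return cls(meta, np.array(genos, dtype=np.int8), animals)


@dataclass
class ConcordanceResult:
    kept: pd.DataFrame          # metadata rows of fully concordant variants
    near_misses: pd.DataFrame   # variant id, n_violations, violating_animals
    mode: str
    n_missing_compatible: int = 0


def concordance_filter(variants: VariantTable, carrier_ids,
                       region: tuple, mode: str = "lenient",
                       max_violations: int = 2,
                       chrom: str | None = None) -> ConcordanceResult:
    """Keep region variants where carriers are het and all others hom-ref.

    Missing genotypes in non-carriers are violations in ``strict`` mode and
    compatible (but counted) in ``lenient`` mode; a variant with any
    missing carrier genotype is excluded in both modes.  Variants with at
    most ``max_violations`` violating animals are reported as near misses.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    carrier_ids = list(carrier_ids)
    if not carrier_ids:
        raise ValueError("carrier_ids must be nonempty")
    missing_carriers = set(carrier_ids) - set(variants.animals)
    if missing_carriers:
        raise ValueError(f"unknown carrier ids: {sorted(missing_carriers)}")
    lo, hi = int(region[0]), int(region[1])
    if lo > hi:
        raise ValueError("empty region")
    in_region = (variants.meta["pos"] >= lo) & (variants.meta["pos"] <= hi)
    if chrom is not None:
        in_region &= variants.meta["chrom"].astype(str) == str(chrom)
    vt = variants.subset(in_region.to_numpy())

    is_carrier = np.array([a in set(carrier_ids) for a in vt.animals])
    g = vt.genotypes
    carrier_g = g[:, is_carrier]
    other_g = g[:, ~is_carrier]
    other_ids = [a for a in vt.animals if a not in set(carrier_ids)]

    carrier_missing = (carrier_g == GT_MISSING).any(axis=1)
    carrier_bad = (carrier_g != GT_HET) & (carrier_g != GT_MISSING)
    if mode == "strict":
        other_bad = other_g != GT_HOM_REF
        n_missing_ok = 0
    else:
        other_bad = (other_g != GT_HOM_REF) & (other_g != GT_MISSING)
        n_missing_ok = int(((other_g == GT_MISSING).sum()))
        if n_missing_ok:
            logger.info("lenient mode: %d missing non-carrier genotypes "
                        "treated as compatible", n_missing_ok)
    n_viol = carrier_bad.sum(axis=1) + other_bad.sum(axis=1)
    keep = (n_viol == 0) & ~carrier_missing

    near_rows = []
    near = (~keep) & (n_viol <= max_violations)
    for i in np.flatnonzero(near):
        viol = [vt.animals[j] for j in np.flatnonzero(is_carrier)[
            np.flatnonzero(carrier_bad[i])]]
        viol += [other_ids[j] for j in np.flatnonzero(other_bad[i])]
        if carrier_missing[i]:
            viol.append("<missing carrier genotype>")
        near_rows.append((vt.meta.loc[i, "id"], int(n_viol[i]),
                          ",".join(map(str, viol))))
    kept = vt.meta[keep].reset_index(drop=True)
    near_df = pd.DataFrame(near_rows, columns=["variant_id", "n_violations",
                                               "violating_animals"])
    return ConcordanceResult(kept, near_df, mode, n_missing_ok)


def allele_frequency(rows) -> pd.DataFrame:
    """Per-stratum and pooled alternative-allele frequencies in percent.

    ``rows`` is an iterable of (stratum, n_genotyped, n_het, n_hom_alt) or a
    DataFrame with those columns.  Frequencies are (n_het + 2 n_hom_alt) /
    (2 n_genotyped), computed in exact rational arithmetic and rounded to
    two decimals on the percent scale.  Strata with no genotyped animals
    are skipped with a warning.
    """
    if isinstance(rows, pd.DataFrame):
        it = [(r["stratum"], r["n_genotyped"], r["n_het"],
               r.get("n_hom_alt", 0)) for _, r in rows.iterrows()]
    else:
        it = [tuple(r) if len(r) == 4 else (*r, 0) for r in rows]
    out = []
    tot_n = tot_h = tot_a = 0
    for stratum, n, h, a in it:
        if min(n, h, a) < 0 or h + a > n:
            raise ValueError(f"invalid counts in stratum {stratum}")
        if n == 0:
            logger.warning("stratum %s has no genotyped animals; skipped",
                           stratum)
            continue
        freq = Fraction(h + 2 * a, 2 * n)
        out.append((str(stratum), n, h, a,
                    round(float(100 * freq), 2)))
        tot_n, tot_h, tot_a = tot_n + n, tot_h + h, tot_a + a
    if tot_n:
        freq = Fraction(tot_h + 2 * tot_a, 2 * tot_n)
        out.append(("pooled", tot_n, tot_h, tot_a,
                    round(float(100 * freq), 2)))
    return pd.DataFrame(out, columns=["stratum", "n_genotyped", "n_het",
                                      "n_hom_alt", "allele_freq_percent"])


def mating_risk(q: float) -> tuple[float, float]:
    """Carrier frequency and affected-offspring risk under Hardy-Weinberg.

    Returns ``(2q(1-q), (2q(1-q))^2 / 4)``: the probability that a random
    animal is a carrier, and the probability that a random mating pairs two
    carriers and produces an affected offspring.
    """
    if not (0 <= q <= 1):
        raise ValueError("allele frequency must be in [0,1]")
    carrier = 2 * q * (1 - q)
    return carrier, carrier ** 2 / 4
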