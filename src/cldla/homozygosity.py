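"""Case-control homozygosity mapping and common disease-haplotype
extraction for a recessive locus.

A run is a maximal stretch of consecutive SNPs at which every case animal
is homozygous for one identical allele per SNP.  Runs are scored by how
improbable the shared homozygosity is in controls,

    score = sum_i -log10( max(f_i, eps) ),    eps = 1 / (2 n_controls + 2),

where f_i is the control frequency of the shared allele: long runs of
alleles rare in controls score highest.  The scoring is this package's
documented stand-in for published case-control autozygosity scores and
preserves their intent.

Phenocopies -- clinically diagnosed animals without the mutation -- break
the causal run and can make homozygosity mapping fail outright;
:func:`drop_incompatible_cases` ranks case animals by their
incompatibility with the best candidate shared segment so phenocopies can
be flagged for diagnostic review.

On phased data, :func:`common_haplotype` extends outward from an anchor
position the maximal interval over which all affected animals are
homozygous for one identical haplotype and every obligate carrier still
carries at least one copy of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import HaplotypePanel, MarkerMap, MISSING

logger = logging.getLogger(__name__)


@dataclass
class HomozygosityRun:
    start_bp: int
    end_bp: int
    n_snps: int
    shared_alleles: np.ndarray          # 0/1 allele per SNP of the run
    score: float
    snp_span: tuple = None              # (first_idx, last_idx) on the map
    incompatible_animals: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_snps < 1 or self.score < 0 or self.start_bp > self.end_bp:
            raise ValueError("invalid homozygosity run")


def _case_shared(cases: np.ndarray):
    """Columns where every case is homozygous for one identical allele.

    Returns (valid mask, shared allele per column).  Missing case
    genotypes invalidate the column, terminating runs through it.
    """
    hom = (cases == 0) | (cases == 2)
    all_hom = hom.all(axis=0)
    same = (cases == cases[0]).all(axis=0)
    valid = all_hom & same
    shared = np.where(valid, cases[0] // 2, -1)
    return valid, shared


def _control_freq(controls: np.ndarray, shared: np.ndarray):
    """Frequency of the shared allele among control alleles, per column."""
    nonmiss = controls != MISSING
    alt_count = np.where(nonmiss, controls, 0).sum(axis=0)
    total = 2 * nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_alt = np.where(total > 0, alt_count / np.maximum(total, 1), 0.0)
    return np.where(shared == 1, f_alt, 1.0 - f_alt)


def asshom_scan(cases: np.ndarray, controls: np.ndarray,
                marker_map: MarkerMap) -> list[HomozygosityRun]:
    """Ranked case-homozygosity runs scored against control frequencies.

    ``cases`` and ``controls`` are genotype dosage matrices (animals x
    SNPs, 0/1/2, -1 missing) over the same SNP set as ``marker_map``.
    """
    cases = np.asarray(cases)
    controls = np.asarray(controls)
    if cases.shape[1] != controls.shape[1]:
        raise ValueError("case and control SNP sets differ")
    if cases.shape[0] < 2 or controls.shape[0] < 1:
        raise ValueError("need >= 2 cases and >= 1 control")
    n_controls = controls.shape[0]
    eps = 1.0 / (2 * n_controls + 2)
    valid, shared = _case_shared(cases)
    f = _control_freq(controls, shared)
    contrib = -np.log10(np.maximum(f, eps))

    runs = []
    j = 0
    m = cases.shape[1]
    while j < m:
        if not valid[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and valid[k + 1]:
            k += 1
        runs.append(HomozygosityRun(
            start_bp=int(marker_map.bp[j]), end_bp=int(marker_map.bp[k]),
            n_snps=k - j + 1, shared_alleles=shared[j:k + 1].astype(np.int8),
            score=float(contrib[j:k + 1].sum()), snp_span=(j, k)))
        j = k + 1
    runs.sort(key=lambda r: -r.score)
    return runs


def _top_score(cases, controls, marker_map):
    runs = asshom_scan(cases, controls, marker_map)
    return runs[0].score if runs else 0.0


def _relaxed_top_run(cases, controls, marker_map, k):
    """Best-scoring run when up to ``k`` case animals may be ignored.

    A column is a quorum column when at least n_cases - k cases are
    homozygous for the column's majority case allele; a run is a maximal
    quorum stretch whose union of breaking animals has size <= k.  Used to
    locate the candidate shared segment that a few phenocopies disrupt.
    """
    n_cases, m = cases.shape
    hom0 = cases == 0
    hom2 = cases == 2
    n0, n2 = hom0.sum(axis=0), hom2.sum(axis=0)
    shared = np.where(n2 >= n0, 1, 0)
    support = np.where(shared == 1, n2, n0)
    quorum = support >= n_cases - k
    breaker = np.where(shared[None, :] == 1, ~hom2, ~hom0)  # per-animal breaks
    f = _control_freq(np.asarray(controls), shared)
    eps = 1.0 / (2 * controls.shape[0] + 2)
    contrib = -np.log10(np.maximum(f, eps))

    best = None
    j = 0
    while j < m:
        if not quorum[j]:
            j += 1
            continue
        # grow greedily while the union of breakers stays within k
        broken = set(np.flatnonzero(breaker[:, j]))
        end = j
        score = contrib[j]
        while end + 1 < m and quorum[end + 1]:
            cand = broken | set(np.flatnonzero(breaker[:, end + 1]))
            if len(cand) > k:
                break
            broken = cand
            end += 1
            score += contrib[end]
        if best is None or score > best[0]:
            best = (score, j, end, broken)
        j = end + 1
    return best


def drop_incompatible_cases(cases: np.ndarray, controls: np.ndarray,
                            marker_map: MarkerMap, k: int,
                            shortlist_size: int | None = None) -> pd.DataFrame:
    """Rank case animals whose exclusion most improves homozygosity mapping.

    Candidates are shortlisted by their incompatibility with the best
    quorum-relaxed run (up to ``k`` breakers allowed) and their
    leave-one-out gain in the top run score; every subset of up to ``k``
    shortlisted animals is then scored by the top run obtained when the
    subset is excluded, and the members of the best subset are reported,
    ranked by how many SNPs of that winning run each one breaks.  The
    result is the set of phenocopy-review candidates.
    """
    cases = np.asarray(cases)
    n_cases = cases.shape[0]
    if n_cases < 3:
        raise ValueError("need at least 3 cases")
    cols = ["case_index", "n_mismatch_top_run", "loo_gain"]
    if k == 0:
        return pd.DataFrame(columns=cols)
    k = min(k, n_cases - 2)
    base = _top_score(cases, controls, marker_map)
    loo = np.array([
        _top_score(np.delete(cases, i, axis=0), controls, marker_map) - base
        for i in range(n_cases)])
    mism = np.zeros(n_cases, dtype=int)
    best = _relaxed_top_run(cases, controls, marker_map, k)
    if best is not None:
        _, j, end, _ = best
        n0 = (cases[:, j:end + 1] == 0).sum(axis=0)
        n2 = (cases[:, j:end + 1] == 2).sum(axis=0)
        shared_g = np.where(n2 >= n0, 2, 0)
        mism = (cases[:, j:end + 1] != shared_g[None, :]).sum(axis=1)

    m = shortlist_size or min(n_cases, 2 * k + 2)
    order = np.lexsort((-loo, -mism))
    shortlist = list(order[:m])
    best_subset, best_score = None, -np.inf
    from itertools import combinations
    for subset in combinations(shortlist, k):
        score = _top_score(np.delete(cases, list(subset), axis=0),
                           controls, marker_map)
        if score > best_score:
            best_score, best_subset = score, subset
    # rank winners by their breakage of the winning run
    kept = np.delete(cases, list(best_subset), axis=0)
    runs = asshom_scan(kept, controls, marker_map)
    rank_mism = mism.copy()
    if runs:
        j, end = runs[0].snp_span
        n0 = (cases[:, j:end + 1] == 0).sum(axis=0)
        n2 = (cases[:, j:end + 1] == 2).sum(axis=0)
        shared_g = np.where(n2 >= n0, 2, 0)
        rank_mism = (cases[:, j:end + 1] != shared_g[None, :]).sum(axis=1)
    rows = sorted(best_subset,
                  key=lambda i: (-rank_mism[i], -loo[i]))
    df = pd.DataFrame({"case_index": rows,
                       "n_mismatch_top_run": [int(rank_mism[i])
                                              for i in rows],
                       "loo_gain": [float(loo[i]) for i in rows]})
    return df


@dataclass
class CommonHaplotype:
    start_bp: int
    end_bp: int
    n_snps: int
    alleles: np.ndarray
    carriers_with_one_copy: list
    snp_span: tuple = None
    carrier_copy_counts: dict = field(default_factory=dict)


def common_haplotype(affected: HaplotypePanel, carriers: HaplotypePanel,
                     marker_map: MarkerMap, anchor_bp: int,
                     exact_one_copy: bool = False) -> CommonHaplotype:
    """Maximal interval of one haplotype homozygous in affecteds and
    carried (at least once; exactly once with ``exact_one_copy``) by every
    carrier, grown outward from the SNP nearest ``anchor_bp``.
    """
    if not (affected.phased and carriers.phased):
        raise ValueError("phased panels required")
    bp = marker_map.bp
    if not (bp[0] <= anchor_bp <= bp[-1]):
        raise ValueError("anchor_bp outside map range")
    anchor = int(np.argmin(np.abs(bp - anchor_bp)))
    aff = affected.alleles
    car = carriers.alleles
    m = marker_map.n_snps

    def consensus(j):
        """Shared allele at SNP j if all affected are homozygous-identical."""
        col = aff[:, j]
        if np.any(col == MISSING):
            return None
        if not np.all(col == col[0]):
            return None
        geno = col.reshape(-1, 2)
        if np.any(geno[:, 0] != geno[:, 1]):
            return None
        return int(col[0])

    a0 = consensus(anchor)
    if a0 is None:
        bad = np.flatnonzero((aff[:, anchor] != aff[0, anchor])
                             | (aff[:, anchor] == MISSING))
        who = affected.animals[bad[0] // 2] if bad.size else affected.animals[0]
        raise ValueError(f"no common haplotype at the anchor SNP: "
                         f"affected animal {who} violates homozygosity")
    # which carrier haplotypes still match the shared haplotype
    match = car[:, anchor] == a0
    if not _carriers_ok(match, exact_one_copy):
        who = carriers.animals[int(np.flatnonzero(
            ~_per_animal_ok(match, exact_one_copy))[0])]
        raise ValueError(f"no common haplotype at the anchor SNP: "
                         f"carrier {who} has no matching haplotype")

    # grow outward; a carrier haplotype must match the whole interval, so
    # one match state is threaded through both directions (left first)
    alleles = {anchor: a0}
    lo = hi = anchor
    cur_match = match.copy()
    for direction in (-1, +1):
        j = anchor + direction
        while 0 <= j < m:
            a = consensus(j)
            if a is None:
                break
            new_match = cur_match & (car[:, j] == a)
            if not _carriers_ok(new_match, exact_one_copy):
                break
            cur_match = new_match
            alleles[j] = a
            if direction < 0:
                lo = j
            else:
                hi = j
            j += direction
    counts = cur_match.reshape(-1, 2).sum(axis=1)
    with_copy = [a for a, c in zip(carriers.animals, counts) if c >= 1]
    return CommonHaplotype(
        start_bp=int(bp[lo]), end_bp=int(bp[hi]), n_snps=hi - lo + 1,
        alleles=np.array([alleles[j] for j in range(lo, hi + 1)],
                         dtype=np.int8),
        carriers_with_one_copy=with_copy, snp_span=(lo, hi),
        carrier_copy_counts=dict(zip(carriers.animals, map(int, counts))))


def _per_animal_ok(match, exact_one):
    per = match.reshape(-1, 2).sum(axis=1)
    return per == 1 if exact_one else per >= 1


def _carriers_ok(match, exact_one):
    return bool(np.all(_per_animal_ok(match, exact_one)))
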