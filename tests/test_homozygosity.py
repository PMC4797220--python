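"""Case-control homozygosity runs, phenocopy diagnostics and common
disease-haplotype extraction."""

import numpy as np
import pytest

from cldla import (HaplotypePanel, MarkerMap, asshom_scan, common_haplotype,
                   drop_incompatible_cases)
from cldla.io_qc import MISSING


def _map(n, start=1000, step=1000):
    bp = np.arange(start, start + n * step, step)
    return MarkerMap([f"s{i}" for i in range(n)], ["4"] * n, bp, bp / 1e8)


class TestAsshomScan:
    def test_hand_computed_run_score(self):
        # 3 cases homozygous (for the reference allele) at SNPs 2-4 with
        # control frequencies of the shared allele 0.5, 0.1, 0.5:
        # score = -log10(0.5) - log10(0.1) - log10(0.5) = 1.602
        cases = np.array([
            [1, 0, 0, 0, 1],
            [1, 0, 0, 0, 0],
            [0, 0, 0, 0, 1]])
        # 5 controls -> 10 alleles; shared allele is ref (dosage of ref
        # alleles = 10 - alt): freq 0.5 -> alt 5; 0.1 -> alt 9; 0.5 -> alt 5
        controls = np.array([
            [1, 2, 2, 1, 1],
            [1, 1, 2, 1, 0],
            [0, 1, 2, 1, 1],
            [1, 1, 2, 1, 2],
            [1, 0, 1, 1, 1]])
        runs = asshom_scan(cases, controls, _map(5))
        top = runs[0]
        assert (top.snp_span, top.n_snps) == ((1, 3), 3)
        assert top.score == pytest.approx(
            -np.log10(0.5) - np.log10(0.1) - np.log10(0.5), abs=1e-12)

    def test_no_shared_homozygosity_gives_empty_list(self):
        cases = np.array([[1, 1], [0, 2]])
        controls = np.array([[0, 0]])
        assert asshom_scan(cases, controls, _map(2)) == []

    def test_allele_absent_in_controls_is_clamped(self):
        cases = np.array([[2], [2]])
        controls = np.array([[0], [0], [0]])
        runs = asshom_scan(cases, controls, _map(1))
        eps = 1.0 / (2 * 3 + 2)
        assert runs[0].score == pytest.approx(-np.log10(eps))
        assert np.isfinite(runs[0].score)

    def test_missing_case_genotype_terminates_run(self):
        cases = np.array([[0, MISSING, 0], [0, 0, 0]])
        controls = np.array([[1, 1, 1]])
        runs = asshom_scan(cases, controls, _map(3))
        spans = sorted(r.snp_span for r in runs)
        assert spans == [(0, 0), (2, 2)]

    def test_invariant_to_case_and_control_order(self, rng):
        cases = rng.integers(0, 3, size=(5, 30))
        controls = rng.integers(0, 3, size=(8, 30))
        mm = _map(30)
        base = [(r.snp_span, r.score) for r in asshom_scan(cases, controls, mm)]
        perm = [(r.snp_span, r.score) for r in asshom_scan(
            cases[rng.permutation(5)], controls[rng.permutation(8)], mm)]
        assert base == perm

    def test_input_validation(self):
        with pytest.raises(ValueError):
            asshom_scan(np.zeros((1, 3)), np.zeros((2, 3)), _map(3))
        with pytest.raises(ValueError):
            asshom_scan(np.zeros((2, 3)), np.zeros((2, 4)), _map(3))


class TestDropIncompatibleCases:
    def test_zero_budget_gives_empty_table(self, rng):
        cases = rng.integers(0, 3, size=(4, 20))
        controls = rng.integers(0, 3, size=(4, 20))
        assert drop_incompatible_cases(cases, controls, _map(20), 0).empty

    def test_planted_phenocopies_rank_top(self, tiny_sim):
        sim = tiny_sim
        panel = sim.truth_haplotypes
        g = panel.genotypes()
        order = {a: i for i, a in enumerate(panel.animals)}
        case_ids = sim.affected() + sim.phenocopies()
        cases = g[[order[a] for a in case_ids]]
        controls = g[[order[a] for a in sim.free()]]
        diag = drop_incompatible_cases(cases, controls, sim.map, k=2)
        flagged = {case_ids[i] for i in diag.case_index}
        assert flagged == set(sim.phenocopies())

    def test_gains_are_nonnegative(self, rng):
        cases = rng.integers(0, 3, size=(6, 40))
        controls = rng.integers(0, 3, size=(6, 40))
        diag = drop_incompatible_cases(cases, controls, _map(40), k=3)
        assert (diag.loo_gain >= -1e-12).all()


def _phased(rows):
    rows = np.asarray(rows, dtype=np.int8)
    return HaplotypePanel([f"A{i}" for i in range(rows.shape[0] // 2)], rows)


class TestCommonHaplotype:
    def test_whole_map_when_everything_matches(self):
        aff = _phased([[0, 1, 0]] * 4)           # 2 animals, homozygous 0,1,0
        car = _phased([[0, 1, 0], [1, 0, 1]] * 2)
        mm = _map(3)
        hap = common_haplotype(aff, car, mm, anchor_bp=2000)
        assert (hap.start_bp, hap.end_bp, hap.n_snps) == (1000, 3000, 3)
        assert list(hap.alleles) == [0, 1, 0]
        assert set(hap.carriers_with_one_copy) == {"A0", "A1"}

    def test_heterozygous_affected_stops_extension(self):
        aff = _phased([[0, 1, 0], [0, 1, 1]])    # het at SNP 3
        car = _phased([[0, 1, 0], [1, 0, 1]])
        hap = common_haplotype(aff, car, _map(3), anchor_bp=2000)
        assert hap.snp_span == (0, 1)

    def test_carrier_without_copy_at_anchor_is_an_error(self):
        aff = _phased([[0, 0]] * 2)
        car = _phased([[1, 1], [1, 1]])
        with pytest.raises(ValueError, match="carrier"):
            common_haplotype(aff, car, _map(2), anchor_bp=1000)

    def test_exact_one_copy_flag(self):
        aff = _phased([[0, 0]] * 2)
        car = _phased([[0, 0], [0, 0]])          # carrier homozygous for it
        hap = common_haplotype(aff, car, _map(2), anchor_bp=1000)
        assert hap.carrier_copy_counts["A0"] == 2
        with pytest.raises(ValueError):
            common_haplotype(aff, car, _map(2), anchor_bp=1000,
                             exact_one_copy=True)

    def test_interval_brackets_locus_and_tracks_truth(self, tiny_sim):
        sim = tiny_sim
        order = {a: i for i, a in enumerate(sim.haplotypes.animals)}
        aff = sim.truth_haplotypes.subset_animals(sim.affected())
        car = sim.truth_haplotypes.subset_animals(sim.carriers())
        hap = common_haplotype(aff, car, sim.map, sim.config.disease_bp)
        assert hap.start_bp <= sim.config.disease_bp <= hap.end_bp
        # the interval must span the descent-truth interval; identity by
        # state can overhang it by a few markers at each end
        lo, hi = sim.shared_interval_bp
        bp = sim.map.bp
        lo_i = int(np.searchsorted(bp, lo))
        hi_i = int(np.searchsorted(bp, hi, side="right")) - 1
        assert hap.snp_span[0] <= lo_i
        assert hap.snp_span[1] >= hi_i
        assert hap.snp_span[0] >= lo_i - 5
        assert hap.snp_span[1] <= hi_i + 5
        assert set(hap.carriers_with_one_copy) == set(sim.carriers())

    def test_removing_a_carrier_never_shrinks_interval(self, tiny_sim):
        sim = tiny_sim
        aff = sim.truth_haplotypes.subset_animals(sim.affected())
        carriers = sim.carriers()
        car = sim.truth_haplotypes.subset_animals(carriers)
        full = common_haplotype(aff, car, sim.map, sim.config.disease_bp)
        fewer = sim.truth_haplotypes.subset_animals(carriers[1:])
        sub = common_haplotype(aff, fewer, sim.map, sim.config.disease_bp)
        assert sub.start_bp <= full.start_bp
        assert sub.end_bp >= full.end_bp

    def test_top_run_and_common_haplotype_overlap_locus(self):
        from cldla import SimConfig, simulate_population
        from conftest import TINY_KW
        hits = 0
        for seed in (21, 22, 23):
            kw = dict(TINY_KW, phenocopy_count=0, missing_rate=0.0)
            sim = simulate_population(SimConfig(seed=seed, **kw))
            panel = sim.truth_haplotypes
            order = {a: i for i, a in enumerate(panel.animals)}
            g = panel.genotypes()
            cases = g[[order[a] for a in sim.affected()]]
            controls = g[[order[a] for a in sim.free()]]
            runs = asshom_scan(cases, controls, sim.map)
            top = runs[0]
            hap = common_haplotype(
                panel.subset_animals(sim.affected()),
                panel.subset_animals(sim.carriers()), sim.map,
                sim.config.disease_bp)
            d = sim.config.disease_bp
            if (top.start_bp <= d <= top.end_bp
                    and hap.start_bp <= d <= hap.end_bp):
                hits += 1
        assert hits >= 2
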