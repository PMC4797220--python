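"""Windowing, the locus-IBD closed form against independent evaluation,
and the DRM conversion against a brute-force four-term loop."""

import math

import numpy as np
import pytest

from cldla import (HaplotypePanel, IbdParams, MarkerMap, drm_from_locibd,
                   locibd_matrix, locibd_pair, make_windows)


def _map(bp, chrom="4", cm_per_mb=1.0):
    bp = np.asarray(bp)
    return MarkerMap([f"s{i}" for i in range(len(bp))], [chrom] * len(bp),
                     bp, bp * cm_per_mb / 1e8)


class TestWindows:
    def test_window_count(self):
        mm = _map(np.arange(1, 101) * 1000)
        assert len(make_windows(mm, size=40)) == 100 - 40 + 1

    def test_midpoint_between_central_snps(self):
        bp = np.arange(1, 41) * 1000
        bp[19], bp[20] = 100_000, 100_100   # keep increasing
        bp = np.sort(bp)
        mm = _map(bp)
        w = make_windows(mm, size=40)[0]
        assert w.midpoint_bp == (int(bp[19]) + int(bp[20])) // 2
        assert w.midpoint_morgans == pytest.approx(
            (mm.morgans[19] + mm.morgans[20]) / 2)

    def test_exactly_forty_snps_gives_one_window(self):
        mm = _map(np.arange(1, 41) * 500)
        assert len(make_windows(mm, size=40)) == 1

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            make_windows(_map(np.arange(1, 40) * 500), size=40)


class TestLocibdPair:
    def test_no_ibs_evidence_returns_prior(self):
        bp = np.arange(1, 41) * 1000
        mm = _map(bp)
        w = make_windows(mm, size=40)[0]
        a = np.zeros(40, dtype=np.int8)
        b = a.copy()
        b[19] = 1   # mismatch immediately left of midpoint
        b[20] = 1   # and immediately right
        params = IbdParams()
        p = locibd_pair(a, b, w, mm, np.full(40, 0.5), params)
        assert p == pytest.approx(params.phi, abs=1e-15)

    def test_symmetry(self, rng):
        bp = np.arange(1, 41) * 2000
        mm = _map(bp)
        w = make_windows(mm, size=40)[0]
        f = rng.uniform(0.1, 0.9, 40)
        for _ in range(10):
            a = (rng.random(40) < 0.5).astype(np.int8)
            b = (rng.random(40) < 0.5).astype(np.int8)
            assert locibd_pair(a, b, w, mm, f, IbdParams()) == \
                locibd_pair(b, a, w, mm, f, IbdParams())

    def test_closed_form_hand_substitution(self):
        # one IBS marker each side with h = 0.5 and d = 0.001 Morgans total
        spacing = 50_000           # 0.0005 M per interval at 1 cM/Mb
        bp = np.arange(1, 41) * spacing
        mm = _map(bp)
        w = make_windows(mm, size=40)[0]
        a = np.zeros(40, dtype=np.int8)
        b = np.ones(40, dtype=np.int8)
        b[19] = b[20] = 0          # IBS exactly at the two central SNPs
        f = np.full(40, 0.5)       # h_i = 0.5
        params = IbdParams(ne=100, t=10)
        phi = 1 - (1 - 1 / 200) ** 10
        d = (w.midpoint_morgans - mm.morgans[19]) \
            + (mm.morgans[20] - w.midpoint_morgans)
        assert d == pytest.approx(0.0005, rel=1e-9)
        s = math.exp(-2 * 10 * d)
        c = 0.5 * 0.5
        expected = phi * s / (phi * s + (1 - phi) * c)
        got = locibd_pair(a, b, w, mm, f, params)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_allele_rejected(self):
        bp = np.arange(1, 41) * 1000
        mm = _map(bp)
        w = make_windows(mm, size=40)[0]
        a = np.zeros(40, dtype=np.int8)
        b = a.copy()
        b[5] = -1
        with pytest.raises(ValueError, match="missing"):
            locibd_pair(a, b, w, mm, np.full(40, 0.5), IbdParams())

    def test_monotone_in_run_length_when_ibs_is_informative(self):
        # equal spacing, h < exp(-2 T delta): each added IBS marker must
        # increase the IBD probability
        spacing_m = 1e-6
        bp = (np.arange(1, 41) * spacing_m * 1e8).astype(int)
        mm = _map(bp)
        w = make_windows(mm, size=40)[0]
        f = np.full(40, 0.5)
        params = IbdParams(ne=100, t=10)
        assert 0.5 < math.exp(-2 * params.t * spacing_m)
        last = -1.0
        a = np.zeros(40, dtype=np.int8)
        for run in range(0, 21):
            b = np.ones(40, dtype=np.int8)
            if run > 0:
                b[20 - run:20 + run] = 0
            p = locibd_pair(a, b, w, mm, f, params)
            assert p > last
            last = p


class TestLocibdMatrix:
    def _panel(self, rng, n_animals=6, n_snps=40):
        alleles = (rng.random((2 * n_animals, n_snps)) < 0.5).astype(np.int8)
        return HaplotypePanel([f"A{i}" for i in range(n_animals)], alleles)

    def test_matrix_equals_pairwise_oracle(self, rng):
        panel = self._panel(rng)
        mm = _map(np.arange(1, 41) * 3000)
        w = make_windows(mm, size=40)[0]
        f = rng.uniform(0.2, 0.8, 40)
        params = IbdParams()
        m = locibd_matrix(panel, w, mm, params, freqs=f).values
        H = 2 * panel.n_animals
        for i in range(H):
            for j in range(H):
                if i == j:
                    assert m[i, j] == 1.0
                else:
                    expected = locibd_pair(panel.alleles[i],
                                           panel.alleles[j], w, mm, f,
                                           params)
                    assert m[i, j] == pytest.approx(expected, abs=1e-12)

    def test_shape_symmetry_and_range(self, rng):
        panel = self._panel(rng, n_animals=2)
        mm = _map(np.arange(1, 41) * 3000)
        w = make_windows(mm, size=40)[0]
        m = locibd_matrix(panel, w, mm, IbdParams()).values
        assert m.shape == (4, 4)
        assert np.allclose(m, m.T)
        assert np.all((m >= 0) & (m <= 1))
        assert np.allclose(np.diag(m), 1.0)

    def test_duplicated_animals_give_equal_blocks(self, rng):
        panel = self._panel(rng, n_animals=3)
        dup = HaplotypePanel(panel.animals + [a + "b" for a in panel.animals],
                             np.vstack([panel.alleles, panel.alleles]))
        mm = _map(np.arange(1, 41) * 3000)
        w = make_windows(mm, size=40)[0]
        f = np.full(40, 0.5)
        m = locibd_matrix(dup, w, mm, IbdParams(), freqs=f).values
        H = 6
        off = m[:H, H:]
        np.testing.assert_allclose(off, off.T, atol=1e-12)
        np.testing.assert_allclose(m[:H, :H][~np.eye(H, dtype=bool)],
                                   m[H:, H:][~np.eye(H, dtype=bool)],
                                   atol=1e-12)

    def test_ibd_pairs_score_higher_at_disease_window(self, tiny_sim):
        sim = tiny_sim
        mm = sim.map
        ws = make_windows(mm, size=40)
        mid = np.array([w.midpoint_bp for w in ws])
        w = ws[int(np.argmin(np.abs(mid - sim.config.disease_bp)))]
        panel = sim.truth_haplotypes
        m = locibd_matrix(panel, w, mm, IbdParams()).values
        d_idx_lab = sim.disease_labels
        mut = sim.disease_alleles == 1
        ibd_mask = np.outer(mut, mut)
        np.fill_diagonal(ibd_mask, False)
        non_mask = np.outer(mut, ~mut)
        assert m[ibd_mask].mean() > m[non_mask].mean()


class TestDrm:
    def test_identity_locibd_gives_identity_drm(self):
        d = drm_from_locibd(np.eye(8))
        assert np.allclose(d.values, np.eye(4))

    def test_autozygous_animal_has_diagonal_two(self):
        m = np.eye(4)
        m[0, 1] = m[1, 0] = 1.0
        d = drm_from_locibd(m, repair=False)
        assert d.values[0, 0] == pytest.approx(2.0)
        assert d.values[1, 1] == pytest.approx(1.0)

    def test_matches_four_term_loop(self, rng):
        n = 4
        m = rng.uniform(0, 1, size=(2 * n, 2 * n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        d = drm_from_locibd(m, repair=False).values
        for j in range(n):
            for k in range(n):
                if j == k:
                    expected = 1 + m[2 * j, 2 * j + 1]
                else:
                    expected = 0.5 * (m[2 * j, 2 * k] + m[2 * j, 2 * k + 1]
                                      + m[2 * j + 1, 2 * k]
                                      + m[2 * j + 1, 2 * k + 1])
                assert d[j, k] == pytest.approx(expected, abs=1e-12)

    def test_repair_enforces_minimum_eigenvalue(self, rng):
        m = rng.uniform(0.4, 1.0, size=(8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        d = drm_from_locibd(m, repair=True)
        assert np.linalg.eigvalsh(d.values)[0] >= 1e-6 - 1e-12

    def test_symmetric_with_diagonal_at_least_one(self, tiny_sim):
        mm = tiny_sim.map
        w = make_windows(mm, size=40)[10]
        m = locibd_matrix(tiny_sim.truth_haplotypes, w, mm, IbdParams())
        d = drm_from_locibd(m).values
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) >= 1.0 - 1e-12)

    def test_odd_row_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            drm_from_locibd(np.eye(5))
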