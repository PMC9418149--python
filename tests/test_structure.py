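"""Pairwise PhiST, AMOVA decomposition and PCoA."""

import numpy as np
import pandas as pd
import pytest

import matriline as m
from conftest import make_alns, random_state_strings
from oracles import hand_amova


def popmap_for(alns, pops):
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in alns],
            "population": pops,
            "region": [""] * len(alns),
        }
    )


class TestAmova:
    def test_three_population_toy_matches_hand_computed_components(self):
        rng = np.random.default_rng(4)
        seqs = random_state_strings(rng, 15, 25, alphabet="AC")
        alns = make_alns(seqs)
        pops = ["P1"] * 5 + ["P2"] * 5 + ["P3"] * 5
        layout = {"G1": ["P1", "P2"], "G2": ["P3"]}
        res = m.amova(alns, popmap_for(alns, pops), layout=layout, n_perm=0)
        d2, _ = m.pairwise_differences(alns)
        sa, sb, sc, ss = hand_amova(
            d2.astype(float), pops, {"P1": "G1", "P2": "G1", "P3": "G2"}
        )
        assert res.sigma2[0] == pytest.approx(sa, abs=1e-9)
        assert res.sigma2[1] == pytest.approx(sb, abs=1e-9)
        assert res.sigma2[2] == pytest.approx(sc, abs=1e-9)
        assert res.ss == pytest.approx(ss, abs=1e-9)

    def test_unequal_sizes_match_hand_computation(self):
        rng = np.random.default_rng(9)
        sizes = [3, 6, 4, 5]
        seqs = random_state_strings(rng, sum(sizes), 30, alphabet="ACG")
        alns = make_alns(seqs)
        pops = sum([[f"P{k}"] * s for k, s in enumerate(sizes)], [])
        layout = {"G1": ["P0", "P1", "P2"], "G2": ["P3"]}
        res = m.amova(alns, popmap_for(alns, pops), layout=layout, n_perm=0)
        sa, sb, sc, _ = hand_amova(
            m.pairwise_differences(alns)[0].astype(float),
            pops,
            {"P0": "G1", "P1": "G1", "P2": "G1", "P3": "G2"},
        )
        for got, want in zip(res.sigma2, (sa, sb, sc)):
            assert got == pytest.approx(want, abs=1e-9)

    def test_identical_population_multisets_have_no_among_variance(self):
        block = ["AAAA", "AAAT", "AATT"]
        alns = make_alns(block * 3)
        pops = ["P1"] * 3 + ["P2"] * 3 + ["P3"] * 3
        res = m.amova(alns, popmap_for(alns, pops), n_perm=200, seed=0)
        assert res.percentages[2] > 95.0  # within-population dominates
        assert res.p_phi_st > 0.05

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        seqs = random_state_strings(rng, 12, 20, alphabet="AC")
        alns = make_alns(seqs)
        pops = ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4
        res = m.amova(alns, popmap_for(alns, pops), n_perm=0)
        assert sum(res.percentages) == pytest.approx(100.0, abs=0.01)

    def test_single_population_rejected(self):
        alns = make_alns(["AAAA", "AAAT", "AATT"])
        with pytest.raises(ValueError, match="two populations"):
            m.amova(alns, popmap_for(alns, ["P"] * 3), n_perm=0)


class TestPairwiseFst:
    def test_equals_two_population_amova_phi_st(self):
        rng = np.random.default_rng(6)
        seqs = random_state_strings(rng, 14, 30, alphabet="AC")
        alns = make_alns(seqs)
        pops = ["P1"] * 6 + ["P2"] * 8
        popmap = popmap_for(alns, pops)
        fst = m.pairwise_fst(alns, popmap, n_perm=0)
        am = m.amova(alns, popmap, n_perm=0)
        assert fst.matrix[0, 1] == pytest.approx(am.phi_st, abs=1e-12)

    def test_panmictic_pool_gives_near_zero(self):
        rng = np.random.default_rng(13)
        pool = random_state_strings(rng, 8, 40, alphabet="AC")
        draws = [pool[i] for i in rng.integers(0, 8, size=40)]
        alns = make_alns(draws)
        pops = ["P1"] * 20 + ["P2"] * 20
        fst = m.pairwise_fst(alns, popmap_for(alns, pops), n_perm=500, seed=3)
        assert abs(fst.matrix[0, 1]) < 0.05
        assert fst.p_matrix[0, 1] > 0.05

    def test_fixed_differences_give_one(self):
        alns = make_alns(["AAAA"] * 5 + ["TTAA"] * 5)
        fst = m.pairwise_fst(alns, popmap_for(alns, ["P1"] * 5 + ["P2"] * 5), n_perm=100, seed=1)
        assert fst.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert fst.p_matrix[0, 1] < 0.05

    def test_small_population_excluded_with_record(self):
        alns = make_alns(["AAAA", "AAAT", "TTAA", "TTAT", "GGGG"])
        fst = m.pairwise_fst(
            alns, popmap_for(alns, ["P1", "P1", "P2", "P2", "P3"]), n_perm=0
        )
        assert fst.excluded == ("P3",)
        assert fst.populations == ["P1", "P2"]

    def test_label_order_invariance_and_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        seqs = random_state_strings(rng, 18, 25, alphabet="ACG")
        alns = make_alns(seqs)
        pops = ["B"] * 6 + ["A"] * 6 + ["C"] * 6
        popmap = popmap_for(alns, pops)
        f1 = m.pairwise_fst(alns, popmap, n_perm=300, seed=5)
        f2 = m.pairwise_fst(alns, popmap, n_perm=300, seed=5)
        assert np.array_equal(f1.matrix, f2.matrix)
        assert np.array_equal(f1.p_matrix, f2.p_matrix)
        # reorder input sequences: PhiST values for the same pair match
        order = list(rng.permutation(18))
        f3 = m.pairwise_fst([alns[i] for i in order], popmap, n_perm=0)
        for pa in ("A", "B", "C"):
            for pb in ("A", "B", "C"):
                if pa >= pb:
                    continue
                v1 = f1.matrix[f1.populations.index(pa), f1.populations.index(pb)]
                v3 = f3.matrix[f3.populations.index(pa), f3.populations.index(pb)]
                assert v1 == pytest.approx(v3, abs=1e-12)

    def test_phist_increases_with_divergence(self, ref, tree):
        """Island-model check: generator-imposed between-deme divergence
        ranks identically with the estimated PhiST."""
        from matriline.simulate import aligned_from_sequences

        levels = [1, 2, 4, 7, 11]
        values = []
        for lvl in levels:
            reps = []
            for r in range(3):
                spec = m.SimSpec(
                    reference=ref,
                    demes=[
                        m.DemeSpec("P1", "x", 12, {"ROOT": 1.0}),
                        m.DemeSpec("P2", "x", 12, {"ROOT": 1.0}),
                    ],
                    theta_within=2.0,
                    divergence_extra=lvl,
                    seed=100 * lvl + r,
                )
                seqs, popmap, _ = m.generate_dataset(spec, tree)
                alns = aligned_from_sequences(seqs)
                reps.append(m.pairwise_fst(alns, popmap, n_perm=0).matrix[0, 1])
            values.append(np.mean(reps))
        assert values == sorted(values)


class TestPcoa:
    def test_recovers_planted_euclidean_configuration(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [1.5, 1.5]])
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = m.pcoa_from_fst(D)
        C = res.coordinates
        D_rec = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
        assert np.allclose(D_rec, D, atol=1e-9)

    def test_percent_variation_sums_to_100(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = m.pcoa_from_fst(D)
        assert res.percent_variation.sum() == pytest.approx(100.0, abs=1e-9)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()  # descending order

    def test_matches_skbio_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(7, 4))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ours = m.pcoa_from_fst(D)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D))
        lam_ours = ours.eigenvalues[ours.eigenvalues > 1e-9]
        lam_theirs = np.array(theirs.eigvals)
        lam_theirs = lam_theirs[lam_theirs > 1e-9]
        assert np.allclose(np.sort(lam_ours)[::-1], np.sort(lam_theirs)[::-1], atol=1e-8)

    def test_degenerate_all_zero_matrix_flagged(self):
        res = m.pcoa_from_fst(np.zeros((4, 4)))
        assert res.degenerate

    def test_too_few_populations_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            m.pcoa_from_fst(np.zeros((2, 2)))
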