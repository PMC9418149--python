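"""Synthetic data generator and truth verification."""

import numpy as np
import pytest

import matriline as m
from matriline.simulate import aligned_from_sequences


class TestFounders:
    def test_v_founder_differs_exactly_at_published_motifs(self, ref, tree, founders):
        diffs = {
            f"{ref.sequence[i]}{i + 1}{founders['V'][i]}"
            for i in range(ref.length)
            if founders["V"][i] != ref.sequence[i]
        }
        assert diffs == {"A281G", "T355C", "C363T"}

    def test_root_founder_is_reference(self, ref, founders):
        assert founders["ROOT"] == ref.sequence

    def test_d1b_founder_round_trips_through_pipeline(self, ref, tree, founders):
        rec = m.SequenceRecord("x", founders["D1b"], "p")
        aln = m.anchor_to_reference(rec, ref)
        vs = m.call_substitutions(aln, ref)
        assert m.classify(vs, tree).haplogroup == "D1b"

    def test_conflicting_motifs_on_path_rejected(self, ref):
        cfg = [
            {"name": "r", "parent": None, "motifs": ["A281G"]},
            {"name": "x", "parent": "r", "motifs": ["A281C"]},
        ]
        t = m.load_motif_tree(cfg)
        with pytest.raises(ValueError, match="conflicting"):
            m.make_founders(t, ref)


class TestGenerateDataset:
    def test_zero_theta_single_haplogroup_is_monomorphic(self, ref, tree):
        spec = m.SimSpec(
            reference=ref,
            demes=[m.DemeSpec("P1", "x", 8, {"V": 1.0})],
            theta_within=0.0,
            seed=1,
        )
        seqs, popmap, truth = m.generate_dataset(spec, tree)
        alns = aligned_from_sequences(seqs)
        part = m.collapse_haplotypes(alns)
        assert part.Ht == 1
        hd, _ = m.haplotype_diversity(part)
        pi, _ = m.nucleotide_diversity(alns)
        assert hd == 0.0 and pi == 0.0

    def test_fixed_demes_force_phist_one_and_single_edge_network(self, ref, tree):
        spec = m.SimSpec(
            reference=ref,
            demes=[
                m.DemeSpec("P1", "x", 6, {"V": 1.0}),
                m.DemeSpec("P2", "y", 6, {"D1b": 1.0}),
            ],
            theta_within=0.0,
            seed=2,
        )
        seqs, popmap, _ = m.generate_dataset(spec, tree)
        alns = aligned_from_sequences(seqs)
        fst = m.pairwise_fst(alns, popmap, n_perm=100, seed=0)
        assert fst.matrix[0, 1] == pytest.approx(1.0)
        part = m.collapse_haplotypes(alns)
        net = m.add_median_vectors(part)
        # V and D1b founders share A281G; k = symmetric difference of paths
        k = len(
            tree.cumulative["V"].symmetric_difference(tree.cumulative["D1b"])
        )
        assert net.graph.number_of_edges() >= 1
        assert m.mutation_steps(net, "Hap_1", "Hap_2") == k

    def test_composition_respected_exactly(self, ref, tree):
        spec = m.SimSpec(
            reference=ref,
            demes=[m.DemeSpec("P1", "x", 10, {"D1b": 0.4, "V": 0.6})],
            theta_within=1.0,
            seed=3,
        )
        _, _, truth = m.generate_dataset(spec, tree)
        counts = {}
        for hg in truth.true_haplogroup.values():
            counts[hg] = counts.get(hg, 0) + 1
        assert counts == {"D1b": 4, "V": 6}

    def test_bit_reproducible_given_seed(self, ref, tree):
        spec = m.SimSpec(
            reference=ref,
            demes=[m.DemeSpec("P1", "x", 10, {"V": 0.5, "A": 0.5})],
            theta_within=2.0,
            migration_share=0.0,
            seed=9,
        )
        s1, p1, t1 = m.generate_dataset(spec, tree)
        s2, p2, t2 = m.generate_dataset(spec, tree)
        assert s1 == s2
        assert t1.substitutions == t2.substitutions

    def test_mutations_avoid_diagnostic_positions(self, ref, tree):
        spec = m.SimSpec(
            reference=ref,
            demes=[m.DemeSpec("P1", "x", 20, {"V2": 1.0})],
            theta_within=5.0,
            divergence_extra=3,
            seed=4,
        )
        _, _, truth = m.generate_dataset(spec, tree)
        diagnostic = {
            m.parse_token(t).position for node in tree.nodes.values() for t in node.motifs
        }
        assert not (set(truth.positions_used) & diagnostic)

    def test_theta_too_large_for_frame_raises(self, tree):
        tiny = m.ReferenceFrame("toy", "ACGTACGTACGT")
        t = m.load_motif_tree([{"name": "r", "parent": None, "motifs": []}])
        spec = m.SimSpec(
            reference=tiny,
            demes=[m.DemeSpec("P1", "x", 30, {"r": 1.0})],
            theta_within=200.0,
            seed=5,
        )
        with pytest.raises(ValueError, match="exhausted|exceed"):
            m.generate_dataset(spec, t)

    def test_migration_copies_sequences_across_demes(self, ref, tree):
        spec = m.SimSpec(
            reference=ref,
            demes=[
                m.DemeSpec("P1", "x", 25, {"V": 1.0}),
                m.DemeSpec("P2", "y", 25, {"A": 1.0}),
            ],
            theta_within=1.0,
            migration_share=0.3,
            seed=6,
        )
        seqs, popmap, truth = m.generate_dataset(spec, tree)
        assert truth.copied_from  # some migrants at 30% share of 50 samples
        for sid, src in truth.copied_from.items():
            assert seqs[sid] == seqs[src]
            assert truth.deme_of[sid] != truth.deme_of[src]

    def test_mean_pi_tracks_theta_over_replicates(self, ref, tree):
        """Downstream per-site pi across replicate generations matches
        theta / L_eff within Monte-Carlo error."""
        theta, n = 2.0, 12
        pis = []
        for seed in range(100):
            spec = m.SimSpec(
                reference=ref,
                demes=[m.DemeSpec("P1", "x", n, {"ROOT": 1.0})],
                theta_within=theta,
                seed=seed,
            )
            seqs, _, _ = m.generate_dataset(spec, tree)
            alns = aligned_from_sequences(seqs)
            pi, _ = m.nucleotide_diversity(alns)
            pis.append(pi * ref.length)  # back to per-locus scale
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - theta) < 3 * se


class TestVerifyTruth:
    def _run(self, spec, tree, ref):
        seqs, popmap, truth = m.generate_dataset(spec, tree)
        alns = aligned_from_sequences(seqs)
        variant_sets = [m.call_substitutions(a, ref) for a in alns]
        classifications = {
            vs.sample_id: m.classify(vs, tree).haplogroup for vs in variant_sets
        }
        part = m.collapse_haplotypes(alns)
        return seqs, truth, classifications, part

    def test_noise_free_run_is_perfect(self, ref, tree):
        spec = m.SimSpec(
            reference=ref,
            demes=[
                m.DemeSpec("P1", "x", 15, {"V": 0.4, "D1b": 0.6}),
                m.DemeSpec("P2", "y", 15, {"A": 0.5, "D2": 0.5}),
            ],
            theta_within=2.0,
            migration_share=0.1,
            seed=7,
        )
        seqs, truth, classifications, part = self._run(spec, tree, ref)
        report = m.verify_truth(classifications, part.labels(), seqs, truth)
        assert report.classifier_accuracy == 1.0
        assert report.rand_index == 1.0

    def test_injected_back_mutation_is_detected(self, ref, tree):
        spec = m.SimSpec(
            reference=ref,
            demes=[m.DemeSpec("P1", "x", 10, {"D1b": 1.0})],
            theta_within=1.0,
            seed=8,
        )
        seqs, popmap, truth = m.generate_dataset(spec, tree)
        victim = sorted(seqs)[0]
        s = list(seqs[victim])
        s[280] = "A"  # revert the CDV diagnostic A281G
        seqs[victim] = "".join(s)
        alns = aligned_from_sequences(seqs)
        classifications = {
            a.sample_id: m.classify(m.call_substitutions(a, ref), tree).haplogroup
            for a in alns
        }
        part = m.collapse_haplotypes(alns)
        report = m.verify_truth(classifications, part.labels(), seqs, truth)
        assert report.misclassified == (victim,)
        assert classifications[victim] == "ROOT"  # fallback ancestor

    def test_shuffled_popmap_destroys_structure(self, ref, tree):
        spec = m.SimSpec(
            reference=ref,
            demes=[
                m.DemeSpec("P1", "x", 15, {"V": 1.0}),
                m.DemeSpec("P2", "y", 15, {"D1b": 1.0}),
            ],
            theta_within=1.0,
            seed=10,
        )
        seqs, popmap, _ = m.generate_dataset(spec, tree)
        alns = aligned_from_sequences(seqs)
        rng = np.random.default_rng(0)
        shuffled = popmap.copy()
        shuffled["population"] = rng.permutation(shuffled["population"].to_numpy())
        fst_true = m.pairwise_fst(alns, popmap, n_perm=200, seed=1)
        fst_shuf = m.pairwise_fst(alns, shuffled, n_perm=200, seed=1)
        assert fst_true.matrix[0, 1] > 0.5
        assert abs(fst_shuf.matrix[0, 1]) < 0.2
        assert fst_shuf.p_matrix[0, 1] > 0.05
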