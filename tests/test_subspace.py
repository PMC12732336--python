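"""Genome Subspace fitting, vertex volumes, overfitting, intersections."""

import numpy as np
import pandas as pd
import pytest

from genesimplex import (GeneMatrix, GenomeSubspaceResults, VolumeEstimate,
                         amino_acid_summary, build_vocabulary, contains,
                         embed_records, fit_subspace, intersect_subspaces,
                         make_profile, overfitting_ratio, perturb_profile,
                         sample_genome, vertex, vertex_invariance,
                         vertex_volume, volume_curve)


def manual_model(weights, offset, level="nucleotide", organism="o"):
    return GenomeSubspaceResults(
        organism=organism, vocab_level=level,
        weights=np.asarray(weights, dtype=float), offset=float(offset),
        nu=0.1, n_train=100)


class TestFitSubspace:
    def test_nu_point_one_keeps_at_least_ninety_percent(self, matrix_a):
        """The design point: nu = 0.1 targets a subspace holding >= 90% of
        the 1000 training genes (small solver slack allowed)."""
        model = fit_subspace(matrix_a, nu=0.1)
        assert model.inside_fraction(matrix_a) >= 0.88

    def test_nu_half_keeps_about_half(self, matrix_a):
        model = fit_subspace(matrix_a, nu=0.5)
        assert abs(model.inside_fraction(matrix_a) - 0.5) < 0.03

    def test_nu_controls_outside_fraction(self, matrix_a):
        for nu in (0.1, 0.3, 0.5):
            model = fit_subspace(matrix_a, nu=nu)
            assert model.outside_fraction(matrix_a) <= nu + 0.03

    def test_identical_training_points_are_inside(self, nt_vocab):
        X = np.tile([0.1, 0.2, 0.3, 0.4], (20, 1))
        m = GeneMatrix("o", nt_vocab, X, [f"g{i}" for i in range(20)])
        model = fit_subspace(m, nu=0.1)
        assert model.contains(X[0])

    def test_invalid_nu_and_small_n_rejected(self, matrix_a, nt_vocab):
        with pytest.raises(ValueError):
            fit_subspace(matrix_a, nu=1.5)
        tiny = GeneMatrix("o", nt_vocab, np.full((5, 4), 0.25),
                          [f"g{i}" for i in range(5)])
        with pytest.raises(ValueError):
            fit_subspace(tiny, nu=0.1)

    def test_json_round_trip(self, matrix_a):
        model = fit_subspace(matrix_a, nu=0.1)
        back = GenomeSubspaceResults.from_json(model.to_json())
        np.testing.assert_allclose(back.weights, model.weights)
        assert back.offset == model.offset
        assert back.organism == model.organism


class TestContains:
    def test_boundary_counts_as_inside(self):
        model = manual_model([1, 0, 0, 0], offset=0.25)
        assert model.contains(np.array([0.25, 0.25, 0.25, 0.25]))

    def test_agrees_with_direct_linear_evaluation(self, matrix_a):
        model = fit_subspace(matrix_a, nu=0.1)
        rng = np.random.default_rng(0)
        pts = rng.dirichlet(np.ones(61), size=100)
        for p in pts:
            direct = float(model.weights @ p) - model.offset >= 0
            assert contains(model, p) == direct

    def test_dimension_mismatch(self, matrix_a):
        model = fit_subspace(matrix_a, nu=0.1)
        with pytest.raises(ValueError):
            model.contains(np.array([0.5, 0.5]))


def brute_force_vertex_count(model, vocab):
    inside = set()
    for token in vocab.tokens:
        if contains(model, vertex(vocab, token)):
            inside.add(token)
    return inside


class TestVertexVolume:
    def test_half_space_containing_whole_simplex(self, nt_vocab):
        est = vertex_volume(manual_model([1, 1, 1, 1], offset=0.5), nt_vocab)
        assert est.n_vertices_inside == est.n_total == 4

    def test_half_space_excluding_whole_simplex(self, nt_vocab):
        est = vertex_volume(manual_model([-1, -1, -1, -1], 0.5), nt_vocab)
        assert est.n_vertices_inside == 0

    def test_matches_brute_force_enumeration(self, matrix_a, codon_vocab):
        model = fit_subspace(matrix_a, nu=0.1)
        est = vertex_volume(model, codon_vocab)
        brute = brute_force_vertex_count(model, codon_vocab)
        assert est.vertex_tokens == frozenset(brute)
        assert est.n_vertices_inside == len(brute)

    def test_bit_reproducible(self, matrix_a, codon_vocab):
        m1 = fit_subspace(matrix_a, nu=0.1)
        m2 = fit_subspace(matrix_a, nu=0.1)
        assert vertex_volume(m1, codon_vocab) == vertex_volume(m2, codon_vocab)


class TestOverfittingRatio:
    def test_self_validation_gives_ratio_one(self, matrix_a):
        """Scoring the training set itself makes validation loss equal
        training loss: ratio exactly 1."""
        model = fit_subspace(matrix_a, nu=0.1)
        tl = model.outside_fraction(matrix_a)
        vl = model.outside_fraction(matrix_a)
        assert vl / tl == 1.0

    def test_ratio_is_mean_of_swapped_ratios(self, matrix_a):
        res = overfitting_ratio(matrix_a, nu=0.1, seed=4)
        expected = np.mean([v / t for v, t in
                            zip(res.validation_losses, res.training_losses)])
        assert res.ratio == pytest.approx(expected)
        assert all(0 <= x <= 1 for x in
                   res.training_losses + res.validation_losses)

    def test_iid_data_ratio_near_one(self, matrix_a):
        res = overfitting_ratio(matrix_a, nu=0.1, seed=4)
        assert 0.8 <= res.ratio <= 1.25

    def test_divergent_validation_inflates_ratio(self, profile_a,
                                                 codon_vocab):
        """Validation genes from strongly diverged profiles fall outside
        the fitted half-space far more often than training genes do.  Any
        single diverged cloud can land wholly on the inside of the
        unbounded half-space, so the direction is asserted on the mean
        over several diverged profiles."""
        m_near = embed_records(sample_genome(profile_a, 200, 97),
                               codon_vocab, "near")
        model = fit_subspace(m_near, nu=0.1)
        tl = model.outside_fraction(m_near)
        vls = []
        for s in range(99, 105):
            far = perturb_profile(profile_a, 2.0, s, label="far")
            m_far = embed_records(sample_genome(far, 200, s + 1000),
                                  codon_vocab, "far")
            vls.append(model.outside_fraction(m_far))
        assert np.mean(vls) / max(tl, 0.1) > 1.0

    def test_too_few_genes(self, nt_vocab):
        m = GeneMatrix("o", nt_vocab, np.full((10, 4), 0.25),
                       [f"g{i}" for i in range(10)])
        with pytest.raises(ValueError):
            overfitting_ratio(m, seed=0)


class TestVolumeCurve:
    def test_two_fractions_volume_weakly_increasing(self, matrix_a,
                                                    codon_vocab):
        df = volume_curve(matrix_a, codon_vocab, [0.5, 0.9])
        assert len(df) == 2
        assert df["n_vertices_inside"].iloc[1] >= \
            df["n_vertices_inside"].iloc[0]

    def test_single_fraction_reproduces_fit_subspace(self, matrix_a,
                                                     codon_vocab):
        df = volume_curve(matrix_a, codon_vocab, [0.9])
        model = fit_subspace(matrix_a, nu=0.1)
        est = vertex_volume(model, codon_vocab)
        assert df["n_vertices_inside"].iloc[0] == est.n_vertices_inside
        assert df["nu"].iloc[0] == pytest.approx(0.1)
        assert df["achieved_inside_fraction"].iloc[0] == pytest.approx(
            model.inside_fraction(matrix_a))

    def test_achieved_fractions_nested(self, matrix_a, codon_vocab):
        df = volume_curve(matrix_a, codon_vocab, [0.5, 0.7, 0.9])
        achieved = df["achieved_inside_fraction"].to_numpy()
        assert (np.diff(achieved) >= -0.02).all()

    def test_curve_is_nonlinear(self, matrix_a_pair, pair_vocab):
        """Uneven gene density: equal fraction increments give unequal
        volume increments (resolved at codon-pair scale, where the vertex
        count is fine-grained enough to register the change)."""
        df = volume_curve(matrix_a_pair, pair_vocab, [0.5, 0.7, 0.9])
        v = df["n_vertices_inside"].to_numpy()
        assert abs((v[1] - v[0]) - (v[2] - v[1])) > 0

    def test_empty_fraction_list(self, matrix_a, codon_vocab):
        with pytest.raises(ValueError):
            volume_curve(matrix_a, codon_vocab, [])


class TestVertexInvariance:
    def test_repeated_fraction_fully_invariant(self, matrix_a, codon_vocab):
        assert vertex_invariance(matrix_a, codon_vocab, [0.9, 0.9]) == 1.0

    def test_agrees_with_set_algebra_recomputation(self, matrix_a,
                                                   codon_vocab):
        fracs = [0.5, 0.7, 0.9]
        inv = vertex_invariance(matrix_a, codon_vocab, fracs)
        sets = []
        for f in fracs:
            model = fit_subspace(matrix_a, nu=1 - f)
            sets.append(vertex_volume(model, codon_vocab).vertex_tokens)
        always_in = frozenset.intersection(*sets)
        never_in = frozenset(codon_vocab.tokens) - frozenset().union(*sets)
        expected = (len(always_in) + len(never_in)) / codon_vocab.n
        assert inv == pytest.approx(expected)

    def test_needs_two_fractions(self, matrix_a, codon_vocab):
        with pytest.raises(ValueError):
            vertex_invariance(matrix_a, codon_vocab, [0.9])


def estimate(organism, tokens, level="codon", n_total=61):
    return VolumeEstimate(organism=organism, level=level,
                          n_vertices_inside=len(tokens), n_total=n_total,
                          vertex_tokens=frozenset(tokens))


class TestIntersectSubspaces:
    def test_identical_sets_all_shared(self):
        toks = {"GAA", "GAG", "GCT"}
        df = intersect_subspaces([estimate("a", toks), estimate("b", toks)])
        excl = df[df["exclusive"]]
        only_a = excl[excl["organisms"].apply(lambda o: o == ("a",))]
        both = excl[excl["organisms"].apply(lambda o: o == ("a", "b"))]
        assert only_a["count"].iloc[0] == 0
        assert both["count"].iloc[0] == 3

    def test_disjoint_sets_share_nothing(self):
        df = intersect_subspaces([estimate("a", {"GAA"}),
                                  estimate("b", {"GCT"})])
        shared = df[~df["exclusive"]]
        assert shared["count"].iloc[0] == 0

    def test_four_organisms_match_brute_force_set_algebra(self):
        rng = np.random.default_rng(8)
        vocab = build_vocabulary("codon")
        sets = {}
        for org in "abcd":
            k = rng.integers(5, 25)
            sets[org] = set(rng.choice(vocab.tokens, size=k, replace=False))
        df = intersect_subspaces([estimate(o, s) for o, s in sets.items()])
        excl = df[df["exclusive"]]
        for _, row in excl.iterrows():
            subset = set(row["organisms"])
            expected = set.intersection(*(sets[o] for o in subset))
            for o in sets:
                if o not in subset:
                    expected -= sets[o]
            assert row["count"] == len(expected)
            assert set(row["tokens"]) == expected
        # exclusive regions partition the union
        assert excl["count"].sum() == len(set().union(*sets.values()))

    def test_mixed_levels_rejected(self):
        with pytest.raises(ValueError):
            intersect_subspaces([estimate("a", {"GAA"}),
                                 estimate("b", {"GAAGAA"},
                                          level="codon_pair", n_total=3721)])


class TestAminoAcidSummary:
    def test_glutamate_codons(self):
        s = amino_acid_summary(estimate("o", {"GAA", "GAG"}))
        assert s.to_dict() == {"E": 2}

    def test_empty_inside_set(self):
        s = amino_acid_summary(estimate("o", set()))
        assert len(s) == 0

    def test_matches_brute_force_translation(self, matrix_a, codon_vocab):
        from Bio.Seq import Seq
        model = fit_subspace(matrix_a, nu=0.1)
        est = vertex_volume(model, codon_vocab)
        s = amino_acid_summary(est)
        assert len(s) <= 20
        expected = {}
        for codon in est.vertex_tokens:
            aa = str(Seq(codon).translate())
            expected[aa] = expected.get(aa, 0) + 1
        assert s.to_dict() == expected

    def test_codon_pair_maps_both_codons(self):
        est = estimate("o", {"GAAGCT"}, level="codon_pair", n_total=3721)
        s = amino_acid_summary(est)
        assert s.to_dict() == {"A": 1, "E": 1}

    def test_nucleotide_level_is_usage_error(self):
        est = VolumeEstimate("o", "nucleotide", 1, 4, frozenset({"A"}))
        with pytest.raises(ValueError):
            amino_acid_summary(est)
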