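"""Tests for model scoring, permutation tests, repeat scoring, distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trnacode as tc
from trnacode.io import FastaRecord
from trnacode.synthetic import MutationConfig, mutate_sequence
from trnacode.trna_compare import INSERTION, segment_sequence

SLS17 = "CCGGGUUAAAAACCCGG"


class TestSegmentSequence:
    def test_identity_mapping_on_core(self, type1_model):
        assignment = segment_sequence(type1_model.core, type1_model)
        assert len(assignment.labels) == 75
        assert INSERTION not in assignment.labels
        assert assignment.aligned_pairs == tuple((i, i) for i in range(75))

    def test_single_insertion_labelled(self, type1_model):
        core = type1_model.core
        query = core[:40] + "A" + core[40:]  # 76 nt
        assignment = segment_sequence(query, type1_model)
        assert assignment.labels.count(INSERTION) == 1
        assert len(assignment.aligned_pairs) == 75

    def test_type_mismatch_length_error(self, type1_model, type2_model):
        with pytest.raises(ValueError, match="type"):
            segment_sequence(type2_model.core, type1_model)

    def test_segment_labels_follow_model_layout(self, type1_model):
        assignment = segment_sequence(type1_model.core, type1_model)
        assert assignment.labels[0] == "acc5"
        assert assignment.labels[7] == "dloop"
        assert assignment.labels[29] == "acloop"
        assert assignment.labels[46] == "vloop"
        assert assignment.labels[-1] == "acc3"


class TestIdentityToPri:
    def test_self_identity(self, type1_model):
        profile = tc.identity_to_pri(type1_model.core, type1_model)
        assert profile.overall == 1.0
        assert all(v == 1.0 for v in profile.per_segment.values())
        assert profile.aligned_length == 75

    def test_fifteen_substitutions(self, type1_model):
        core = list(type1_model.core)
        swap = {"A": "C", "C": "A", "G": "U", "U": "G"}
        for i in range(0, 75, 5):  # 15 evenly spread positions
            core[i] = swap[core[i]]
        profile = tc.identity_to_pri("".join(core), type1_model)
        assert profile.overall == pytest.approx((75 - 15) / 75)

    def test_overall_is_weighted_mean_of_segments(self, type1_model):
        query = mutate_sequence(
            type1_model.core, MutationConfig(substitution_rate=0.2, seed=5)
        )
        profile = tc.identity_to_pri(query, type1_model)
        seg_counts = {
            s.name: len(s.sequence) for s in type1_model.segments
        }
        weighted = sum(
            profile.per_segment[name] * seg_counts[name]
            for name in profile.per_segment
        ) / sum(seg_counts[n] for n in profile.per_segment)
        assert profile.overall == pytest.approx(weighted)

    def test_random_composition_matched_background(self, type1_model):
        """Mean identity of shuffled cores matches the closed-form
        expectation for a uniform random permutation: sum_b (n_b / n)^2
        (the image of each position is marginally uniform over all n)."""
        core = type1_model.core
        n = len(core)
        counts = {b: core.count(b) for b in "ACGU"}
        expected = sum(c * c for c in counts.values()) / (n * n)
        rng = np.random.default_rng(42)
        draws = 300
        chars = np.array(list(core))
        mean_identity = np.mean(
            [
                tc.identity_to_pri(
                    "".join(chars[rng.permutation(n)]), type1_model
                ).overall
                for _ in range(draws)
            ]
        )
        # binomial-ish sampling error bound (3 sigma, sd < 0.5/sqrt(n) per draw)
        assert mean_identity == pytest.approx(expected, abs=3 * 0.06 / np.sqrt(draws))

    def test_monotone_decay_on_mutation_ladder(self, type1_model):
        """Mean identity is non-increasing in the substitution rate."""
        rates = [0.0, 0.05, 0.1, 0.2, 0.4]
        means = []
        for rate in rates:
            config = MutationConfig(substitution_rate=rate, seed=7)
            rng = np.random.default_rng(11)
            identities = [
                tc.identity_to_pri(
                    mutate_sequence(type1_model.core, config, rng=rng), type1_model
                ).overall
                for _ in range(30)
            ]
            means.append(float(np.mean(identities)))
        assert means[0] == 1.0
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestLoopHomologyTest:
    def test_identical_sequences(self):
        result = tc.loop_homology_test(SLS17, SLS17, n_perm=999, seed=0)
        assert result.statistic == 1.0
        assert result.p_value == pytest.approx(1 / 1000)

    def test_model_stem_loop_stems_identical(self, type1_model):
        a = type1_model.segment("acloop").sequence
        b = type1_model.segment("tloop").sequence
        result = tc.loop_homology_test(a, b, n_perm=999, seed=0)
        assert result.statistic == 1.0

    def test_zero_match_reversal(self):
        seq_a = "AAAACCCCGGGGUUUU"
        seq_b = seq_a[::-1]
        assert sum(x == y for x, y in zip(seq_a, seq_b)) == 0
        result = tc.loop_homology_test(seq_a, seq_b, n_perm=499, seed=3)
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            tc.loop_homology_test("ACGU", "ACG", n_perm=99, seed=0)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            tc.loop_homology_test("ACGU", "ACGU", n_perm=50, seed=0)

    def test_reproducible_under_seed(self):
        a = tc.loop_homology_test(SLS17, SLS17[::-1], n_perm=199, seed=9)
        b = tc.loop_homology_test(SLS17, SLS17[::-1], n_perm=199, seed=9)
        assert a == b

    def test_p_value_super_uniform_under_null(self):
        """Empirical check over 500 simulated nulls: P(p <= alpha) should
        not exceed alpha (beyond Monte Carlo error) when seq_b is a random
        shuffle of seq_a."""
        rng = np.random.default_rng(2024)
        chars = list(SLS17)
        p_values = []
        for k in range(500):
            shuffled = "".join(rng.permutation(chars))
            p_values.append(
                tc.loop_homology_test(SLS17, shuffled, n_perm=199, seed=k).p_value
            )
        p = np.array(p_values)
        for alpha in (0.05, 0.1, 0.25):
            margin = 3 * np.sqrt(alpha * (1 - alpha) / 500)
            assert np.mean(p <= alpha) <= alpha + margin


class TestRepeatScore:
    def test_uagcc_repeat_is_perfect(self):
        assert tc.repeat_score("UAGCCUAGCCUAGCCUA", "UAGCC") == 1.0

    def test_gcg_repeat_is_perfect(self):
        assert tc.repeat_score("GCGGCGG", "GCG") == 1.0

    def test_polya_against_gcg_brute_force(self):
        # exhaustive oracle: all 3 phases of GCG against AAAAAAA match nowhere
        seq = "AAAAAAA"
        motif = "GCG"
        phases = [
            sum(seq[i] == motif[(i + p) % 3] for i in range(len(seq))) / len(seq)
            for p in range(3)
        ]
        assert max(phases) == 0.0
        assert tc.repeat_score(seq, motif) == 0.0

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            tc.repeat_score("ACGU", "")

    @settings(max_examples=50)
    @given(
        st.text(alphabet="ACGU", min_size=1, max_size=30),
        st.text(alphabet="ACGU", min_size=1, max_size=6),
        st.integers(min_value=0, max_value=5),
    )
    def test_invariant_to_motif_rotation(self, seq, motif, k):
        rotated = motif[k % len(motif) :] + motif[: k % len(motif)]
        assert tc.repeat_score(seq, motif) == pytest.approx(
            tc.repeat_score(seq, rotated)
        )


class TestTrnaomeDistance:
    def test_identical_records_distance_zero(self):
        records = [FastaRecord("a", SLS17), FastaRecord("b", SLS17)]
        frame, nearest = tc.trnaome_distance(records)
        assert frame.loc["a", "b"] == 0.0
        assert nearest == {"a": "b", "b": "a"}

    def test_symmetry_and_zero_diagonal(self, type1_model):
        rng = np.random.default_rng(0)
        config = MutationConfig(substitution_rate=0.15, seed=0)
        records = [
            FastaRecord(f"r{i}", mutate_sequence(type1_model.core, config, rng=rng))
            for i in range(5)
        ]
        frame, _ = tc.trnaome_distance(records)
        assert np.allclose(frame.values, frame.values.T)
        assert np.allclose(np.diag(frame.values), 0.0)

    def test_duplicate_ids_rejected(self):
        records = [FastaRecord("a", SLS17), FastaRecord("a", SLS17)]
        with pytest.raises(ValueError, match="duplicate"):
            tc.trnaome_distance(records)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            tc.trnaome_distance([FastaRecord("a", SLS17)])

    def test_shared_parent_mutual_nearest_neighbors(self, type1_model):
        """Two records mutated from a common parent are mutual nearest
        neighbors against a backdrop of more divergent records (verified by
        exhaustive pairwise identity via the distance matrix itself)."""
        parent = mutate_sequence(
            type1_model.core, MutationConfig(substitution_rate=0.1, seed=21)
        )
        child_cfg = MutationConfig(substitution_rate=0.03, seed=0)
        rng = np.random.default_rng(22)
        records = [
            FastaRecord("child1", mutate_sequence(parent, child_cfg, rng=rng)),
            FastaRecord("child2", mutate_sequence(parent, child_cfg, rng=rng)),
        ]
        far_cfg = MutationConfig(substitution_rate=0.35, seed=0)
        records += [
            FastaRecord(f"far{i}", mutate_sequence(type1_model.core, far_cfg, rng=rng))
            for i in range(4)
        ]
        _, nearest = tc.trnaome_distance(records)
        assert nearest["child1"] == "child2"
        assert nearest["child2"] == "child1"

    def test_nearest_tie_breaks_lexicographically(self):
        records = [
            FastaRecord("z", SLS17),
            FastaRecord("b", SLS17),
            FastaRecord("a", SLS17),
        ]
        _, nearest = tc.trnaome_distance(records)
        assert nearest["z"] == "a"
        assert nearest["a"] == "b"
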