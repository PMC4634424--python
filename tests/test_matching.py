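import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somtraj.matching import (
    ClassificationResult,
    TemplateLibrary,
    build_template,
    classify,
    lcs_multi,
    lcs_pair,
    similarity,
)
from somtraj.trajmap import PostureSequence, TrajectoryMap, collapse_repetitions, encode, render_trajectory_map


def is_subsequence(sub, seq):
    it = iter(seq)
    return all(any(s == t for t in it) for s in sub)


def exhaustive_lcs_length(seqs):
    """Oracle: enumerate all subsequences of the shortest input."""
    shortest = min(seqs, key=len)
    others = [s for s in seqs if s is not shortest]
    best = 0
    for r in range(len(shortest), 0, -1):
        for comb in itertools.combinations(shortest, r):
            if all(is_subsequence(comb, o) for o in seqs):
                return r
    return best


class TestLcsPair:
    def test_worked_example(self):
        a = PostureSequence([6, 1, 2, 1, 6])
        b = PostureSequence([6, 2, 1, 6])
        out = lcs_pair(a, b)
        assert out.symbols == [6, 2, 1, 6]

    def test_identical_sequences(self):
        a = PostureSequence([4, 2, 7, 1])
        assert lcs_pair(a, a).symbols == [4, 2, 7, 1]

    def test_disjoint_alphabets(self):
        out = lcs_pair(PostureSequence([1, 2, 3]), PostureSequence([4, 5]))
        assert out.symbols == []

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.integers(1, 5), max_size=8),
        st.lists(st.integers(1, 5), max_size=8),
    )
    def test_against_exhaustive_oracle(self, a, b):
        out = lcs_pair(PostureSequence(a), PostureSequence(b))
        assert is_subsequence(out.symbols, a)
        assert is_subsequence(out.symbols, b)
        if a and b:
            assert len(out.symbols) == exhaustive_lcs_length([a, b])


class TestLcsMulti:
    def test_table_trajectory_1(self):
        rows = [
            PostureSequence([6, 1, 2, 1, 6]),
            PostureSequence([6, 1, 2, 9, 2, 1, 3, 6]),
            PostureSequence([6, 2, 1, 6]),
            PostureSequence([6, 5, 4, 2, 1, 6]),
        ]
        assert lcs_multi(rows).symbols == [6, 2, 1, 6]

    def test_table_trajectory_3(self):
        rows = [
            PostureSequence([6, 1, 3, 6]),
            PostureSequence([6, 1, 5, 3, 6]),
            PostureSequence([6, 5, 1, 5, 3, 6]),
            PostureSequence([6, 1, 6]),
        ]
        assert lcs_multi(rows).symbols == [6, 1, 6]

    def test_single_input_returned(self):
        assert lcs_multi([PostureSequence([3, 1, 4])]).symbols == [3, 1, 4]

    def test_guards(self):
        many = [PostureSequence([1])] * 7
        with pytest.raises(ValueError, match="pairwise"):
            lcs_multi(many)
        long = [PostureSequence([1] * 65), PostureSequence([1] * 65)]
        with pytest.raises(ValueError, match="pairwise"):
            lcs_multi(long)

    def test_random_against_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = rng.integers(2, 5)
            seqs = [
                list(rng.integers(1, 6, size=rng.integers(1, 9))) for _ in range(k)
            ]
            out = lcs_multi([PostureSequence(s) for s in seqs]).symbols
            for s in seqs:
                assert is_subsequence(out, s)
            assert len(out) == exhaustive_lcs_length(seqs)

    def test_pairwise_agreement_on_two_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = list(rng.integers(1, 5, size=7))
            b = list(rng.integers(1, 5, size=7))
            assert len(lcs_multi([PostureSequence(a), PostureSequence(b)]).symbols) == len(
                lcs_pair(PostureSequence(a), PostureSequence(b)).symbols
            )


class TestBuildTemplate:
    def test_identical_instances(self, trained_pmap, cohort, cohort_features):
        feats = cohort_features[0]
        entry = build_template(trained_pmap, "x", [feats, feats, feats])
        expected = collapse_repetitions(encode(trained_pmap, feats))
        assert entry.sequence.symbols == expected.symbols

    def test_template_is_subsequence_of_instances(
        self, trained_pmap, cohort, cohort_features
    ):
        by_label = {}
        for rec, feats in zip(cohort, cohort_features):
            by_label.setdefault(rec.label, []).append(feats)
        label, instances = next(iter(by_label.items()))
        entry = build_template(trained_pmap, label, instances[:5])
        for feats in instances[:5]:
            collapsed = collapse_repetitions(encode(trained_pmap, feats)).symbols
            assert is_subsequence(entry.sequence.symbols, collapsed)

    def test_map_consistent_with_sequence(self, trained_pmap, trained_library):
        for entry in trained_library.entries.values():
            rebuilt = render_trajectory_map(trained_pmap, entry.sequence)
            assert np.array_equal(rebuilt.image, entry.map.image)

    def test_empty_instances_error(self, trained_pmap):
        with pytest.raises(ValueError):
            build_template(trained_pmap, "x", [])


def make_map(image):
    return TrajectoryMap(image=np.asarray(image, dtype=np.uint8))


class TestSimilarity:
    def test_self_similarity_is_one(self):
        p = make_map([[0, 50], [200, 255]])
        assert similarity(p, p) == pytest.approx(1.0, abs=1e-12)

    def test_inverted_is_minus_one(self):
        p = make_map([[0, 50], [200, 255]])
        q = make_map(255 - p.image)
        assert similarity(p, q) == pytest.approx(-1.0, abs=1e-12)

    def test_orthogonal_centered_patterns(self):
        p = make_map([[0, 0], [255, 255]])
        t = make_map([[0, 255], [0, 255]])
        assert similarity(p, t) == pytest.approx(0.0, abs=1e-12)

    def test_constant_image_error(self):
        p = make_map([[5, 5], [5, 5]])
        q = make_map([[0, 1], [2, 3]])
        with pytest.raises(ValueError, match="constant"):
            similarity(p, q)

    def test_shape_mismatch_error(self):
        with pytest.raises(ValueError):
            similarity(make_map([[0, 1]]), make_map([[0], [1]]))

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a = make_map(rng.integers(0, 256, size=(5, 5)))
            b = make_map(rng.integers(0, 256, size=(5, 5)))
            s = similarity(a, b)
            assert -1.0 <= s <= 1.0
            assert similarity(b, a) == pytest.approx(s, abs=1e-12)

    def test_affine_intensity_invariance(self):
        # positive affine rescaling of either image leaves S unchanged
        rng = np.random.default_rng(3)
        for _ in range(200):
            a = rng.integers(0, 256, size=(6, 6)).astype(float)
            b = rng.integers(0, 256, size=(6, 6)).astype(float)
            s0 = similarity(TrajectoryMap(image=a), TrajectoryMap(image=b))
            scale, offset = rng.uniform(0.1, 3.0), rng.uniform(-50, 50)
            s1 = similarity(TrajectoryMap(image=scale * a + offset), TrajectoryMap(image=b))
            assert s1 == pytest.approx(s0, abs=1e-9)


class TestClassify:
    def test_own_template_scores_one(self, trained_library):
        label, entry = next(iter(sorted(trained_library.entries.items())))
        result = classify(entry.map, trained_library)
        assert result.label == label
        assert result.score == pytest.approx(1.0, abs=1e-12)
        assert not result.rejected

    def test_all_templates_recognized(self, trained_library):
        for label, entry in trained_library.entries.items():
            result = classify(entry.map, trained_library)
            assert result.label == label

    def test_rejection_below_threshold(self, trained_pmap, trained_library):
        # a map visiting every basin in reverse-ish order shares little with
        # any single template; force rejection with a strict threshold
        strict = TemplateLibrary(threshold=0.999)
        for e in trained_library.entries.values():
            strict.add(e)
        weird = np.array(trained_library.entries[
            sorted(trained_library.entries)[0]
        ].map.image)
        weird = (255 - weird).astype(np.uint8)  # inverted: anti-correlated
        result = classify(TrajectoryMap(image=weird), strict)
        assert result.rejected
        assert result.label is None
        assert result.score < 0.999

    def test_tie_breaks_lexicographically(self):
        img = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        lib = TemplateLibrary(threshold=0.0)
        tmap = TrajectoryMap(image=img)
        from somtraj.matching import TemplateEntry

        lib.add(TemplateEntry("b", PostureSequence([1], collapsed=True), tmap))
        lib.add(TemplateEntry("a", PostureSequence([1], collapsed=True), tmap))
        result = classify(TrajectoryMap(image=img), lib)
        assert result.label == "a"

    def test_empty_library_error(self):
        with pytest.raises(ValueError):
            classify(make_map([[0, 1], [2, 3]]), TemplateLibrary())


class TestLibrarySerialization:
    def test_json_round_trip(self, trained_library, tmp_path):
        path = tmp_path / "lib.json"
        trained_library.to_json(path)
        back = TemplateLibrary.from_json(path)
        assert back.threshold == trained_library.threshold
        assert set(back.entries) == set(trained_library.entries)
        for label in back.entries:
            a, b = back.entries[label], trained_library.entries[label]
            assert a.sequence.symbols == b.sequence.symbols
            assert np.array_equal(a.map.image, b.map.image)
            assert a.map.appearance == b.map.appearance
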