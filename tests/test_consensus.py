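import numpy as np
import pytest

from alertminer.alert_filtering import AlertSet
from alertminer.alert_scoring import ScoredAlert
from alertminer.chem_io import PatternCatalogue
from alertminer.consensus import (
    NormalizedAlert,
    build_benchmark,
    compare_to_reference,
    consolidate,
    normalize,
    pairwise_overlap,
)
from alertminer.fragment_mining import AlertSupport, FragmentKey


def alert_set(patterns, strategy, igs=None):
    igs = igs or [0.1] * len(patterns)
    return AlertSet(
        endpoint="demo",
        strategy=strategy,
        alerts=[
            ScoredAlert(
                key=FragmentKey(p, strategy),
                support=AlertSupport(10, 9),
                pr=0.9,
                cr=0.1,
                ig=ig,
                p_value=0.01,
            )
            for p, ig in zip(patterns, igs)
        ],
    )


BENZENE = "c1ccccc1"
PHENOL = "Oc1ccccc1"
ANILINE = "Nc1ccccc1"
NITROBENZENE = "O=[N+]([O-])c1ccccc1"


class TestNormalize:
    def test_explicit_h_aromatic_form_canonicalizes_to_aniline(self):
        got = normalize("[cH]1[cH][cH][cH][cH]c1[NH2]")
        assert got.canonical == normalize(ANILINE).canonical

    def test_idempotent_on_canonical_smiles(self):
        once = normalize(BENZENE)
        twice = normalize(once.canonical)
        assert once.canonical == twice.canonical

    def test_atom_maps_stripped(self):
        assert normalize("[C:1][O:2]").canonical == normalize("CO").canonical

    def test_unparseable_pattern_rejected(self):
        with pytest.raises(ValueError):
            normalize("((((")


class TestConsolidate:
    def norm(self, pattern, source):
        return normalize(pattern, sources={source})

    def test_inclusion_collapses_to_simpler(self):
        out = consolidate([self.norm(PHENOL, "a"), self.norm(BENZENE, "b")])
        assert [a.canonical for a in out] == [normalize(BENZENE).canonical]
        assert out[0].sources == {"a", "b"}

    def test_disjoint_patterns_unchanged(self):
        out = consolidate([self.norm("CCO", "a"), self.norm("c1ccncc1", "b")])
        assert len(out) == 2

    def test_chain_reaches_fixed_point(self):
        # CC < CCC < CCCC: the whole chain collapses to the smallest
        out = consolidate([self.norm("CCCC", "a"), self.norm("CCC", "b"), self.norm("CC", "c")])
        assert [a.canonical for a in out] == ["CC"]
        assert out[0].sources == {"a", "b", "c"}

    def test_order_independence(self):
        pats = [PHENOL, BENZENE, "CCO", "OCCO", ANILINE]
        base = consolidate([self.norm(p, f"s{i}") for i, p in enumerate(pats)])
        rng = np.random.default_rng(1)
        for _ in range(4):
            order = rng.permutation(len(pats))
            shuffled = consolidate([self.norm(pats[i], f"s{i}") for i in order])
            assert {a.canonical for a in shuffled} == {a.canonical for a in base}


class TestBenchmark:
    def test_small_set_excluded_shared_pattern_kept(self):
        shared = [f"{'C' * k}O" for k in range(1, 21)]  # 20 distinct alcohols? no inclusions...
        # use genuinely inclusion-free patterns: substituted pyridines etc.
        big_a = alert_set([BENZENE] + [f"C{i % 2 * 'C'}N{'C' * i}" for i in range(25)], "alpha")
        big_b = alert_set([BENZENE] + [f"O=C(N{'C' * i})C" for i in range(25)], "beta")
        small = alert_set([BENZENE], "gamma")  # 1 alert < 20 -> excluded
        result = build_benchmark({"alpha": big_a, "beta": big_b, "gamma": small})
        assert result.included_strategies == ["alpha", "beta"]
        assert result.excluded_strategies == ["gamma"]
        assert normalize(BENZENE).canonical in {a.canonical for a in result.benchmark}

    def test_no_shared_pattern_empty_benchmark(self):
        a = alert_set([f"C{'C' * i}O" for i in range(20)], "alpha")
        b = alert_set([f"N{'C' * i}N" for i in range(20)], "beta")
        result = build_benchmark({"alpha": a, "beta": b}, min_set_size=5)
        # alcohols and diamines may still include one another within a set,
        # but across sets nothing is identical
        assert result.benchmark == [] or all(
            a.sources >= {"alpha", "beta"} for a in result.benchmark
        )

    def test_all_excluded_is_flagged_not_error(self):
        result = build_benchmark({"alpha": alert_set([BENZENE], "alpha")})
        assert result.benchmark == []
        assert result.note is not None

    def test_annotated_variants_consolidate_into_benchmark(self):
        # three strategies emit the same nitrobenzene chemistry with
        # different decorations; the benchmark holds one consolidated form
        variants = {
            "alpha": alert_set([NITROBENZENE], "alpha"),
            "beta": alert_set(["[cH]1[cH][cH][cH][cH]c1[N+](=O)[O-]"], "beta"),
            "gamma": alert_set(["O=[N+]([O-])c1[cH][cH][cH][cH][cH]1"], "gamma"),
        }
        result = build_benchmark(variants, min_set_size=1)
        assert len(result.benchmark) == 1
        assert result.benchmark[0].sources == {"alpha", "beta", "gamma"}

    def test_benchmark_subset_of_each_included_strategy(self, circular_alerts):
        sets = {
            "circular": circular_alerts,
            "copy": AlertSet(
                endpoint=circular_alerts.endpoint,
                strategy="copy",
                alerts=list(circular_alerts.alerts),
            ),
        }
        result = build_benchmark(sets, min_set_size=1)
        from alertminer.consensus import _normalized_set, consolidate as cons

        for s in result.included_strategies:
            canon = {a.canonical for a in cons(_normalized_set(sets[s]))}
            assert {a.canonical for a in result.benchmark} <= canon


class TestPairwiseOverlap:
    def test_identical_sets(self):
        pats = ["CCO", "c1ccncc1", ANILINE]
        sets = {"a": alert_set(pats, "a"), "b": alert_set(pats, "b")}
        matrix, strategies = pairwise_overlap(sets)
        n = len(consolidate([normalize(p, {"x"}) for p in pats]))
        assert matrix[0, 1] == matrix[1, 0] == n
        assert matrix[0, 0] == matrix[1, 1] == n

    def test_disjoint_sets(self):
        sets = {"a": alert_set(["CCO"], "a"), "b": alert_set(["c1ccncc1"], "b")}
        matrix, _ = pairwise_overlap(sets)
        assert matrix[0, 1] == 0

    def test_hand_counted_three_set_fixture(self):
        # a: {CCO, benzene, aniline}; b: {CCO, benzene}; c: {aniline, pyridine}
        # no inclusion relations within any set after normalization
        sets = {
            "a": alert_set(["CCO", BENZENE, "c1ccncc1"], "a"),
            "b": alert_set(["CCO", BENZENE], "b"),
            "c": alert_set(["c1ccncc1", "CCS"], "c"),
        }
        matrix, strategies = pairwise_overlap(sets)
        assert strategies == ["a", "b", "c"]
        expected = np.array([[3, 2, 1], [2, 2, 0], [1, 0, 2]])
        assert np.array_equal(matrix, expected)
        assert np.array_equal(matrix, matrix.T)


class TestReferenceComparison:
    def test_reference_containing_everything(self):
        alerts = alert_set(["CCO", BENZENE], "a", igs=[0.3, 0.2])
        ref = PatternCatalogue("ref", ["CCO", BENZENE])
        report = compare_to_reference(alerts, ref, k=10)
        assert report.overlap_count == 2

    def test_empty_reference(self):
        alerts = alert_set(["CCO"], "a")
        report = compare_to_reference(alerts, PatternCatalogue("ref", []), k=10)
        assert report.overlap_count == 0
        assert report.unmatched == ["CCO"]

    def test_inclusion_counts_as_overlap(self):
        # mined aniline vs reference benzene: aniline contains the reference ring
        alerts = alert_set([ANILINE], "a")
        ref = PatternCatalogue("ref", [BENZENE])
        report = compare_to_reference(alerts, ref, k=10)
        assert report.overlap_count == 1
        assert report.matched[0][1] == "contains"

    def test_top_k_limits_comparison(self):
        alerts = alert_set(["CCO", "CCS", ANILINE], "a", igs=[0.3, 0.2, 0.1])
        ref = PatternCatalogue("ref", [ANILINE])
        report = compare_to_reference(alerts, ref, k=2)
        # aniline ranks third, outside k=2; the top two are unrelated to the reference
        assert report.overlap_count == 0
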