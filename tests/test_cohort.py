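import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvcohort import cohort
from cnvcohort.consensus import breakpoints_match
from cnvcohort.models import CNVCall, ConsensusSet, GenomeBuild, SampleRecord

from conftest import make_call


def cset(sample, calls):
    return ConsensusSet(sample, calls, [True] * len(calls))


def record(sid, breed):
    return SampleRecord(sid, breed, 1000, 101, 99.0, 95.0)


class TestClusterCalls:
    def test_identical_calls_share_one_cluster(self):
        a = cset("S1", [make_call(sample="S1")])
        b = cset("S2", [make_call(sample="S2")])
        (cl,) = cohort.cluster_calls([a, b])
        assert cl.sharing_count == 2

    def test_separation_beyond_tolerance_splits(self):
        a = cset("S1", [make_call(sample="S1", start=1000, end=2000)])
        b = cset("S2", [make_call(sample="S2", start=1150, end=2150)])
        clusters = cohort.cluster_calls([a, b], tol=100)
        assert len(clusters) == 2

    def test_partition_preserves_member_multiset(self):
        rng = np.random.default_rng(1)
        csets = []
        for s in ("S1", "S2", "S3"):
            calls = []
            for _ in range(30):
                start = int(rng.integers(1, 100_000))
                calls.append(CNVCall(s, "1", start, start + 500, "DUP", "read_depth"))
            csets.append(cset(s, calls))
        clusters = cohort.cluster_calls(csets)
        members = sorted(
            (s, c.chrom, c.start, c.end) for cl in clusters for s, c in cl.members
        )
        inputs = sorted((cs.sample_id, c.chrom, c.start, c.end) for cs in csets for c in cs.calls)
        assert members == inputs
        for cl in clusters:
            assert all(breakpoints_match(cl.representative, c, 100) for _, c in cl.members)

    def test_greedy_equals_transitive_closure_when_separated(self):
        # pairwise distances either <= tol or > 2*tol: the two rules coincide
        def transitive_closure(calls, tol):
            n = len(calls)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    if breakpoints_match(calls[i][1], calls[j][1], tol):
                        parent[find(i)] = find(j)
            groups = {}
            for i in range(n):
                groups.setdefault(find(i), []).append(calls[i])
            return {frozenset((s, c.start, c.end) for s, c in g) for g in groups.values()}

        rng = np.random.default_rng(2)
        for trial in range(1000):
            anchors = rng.integers(1, 50_000, size=rng.integers(1, 6)) * 1000
            calls = []
            for k in range(int(rng.integers(2, 21))):
                anchor = int(rng.choice(anchors))
                ds, de = int(rng.integers(-50, 51)), int(rng.integers(-50, 51))
                calls.append(
                    (f"S{k}", CNVCall(f"S{k}", "1", anchor + ds, anchor + 2000 + de, "DUP", "read_depth"))
                )
            csets_ = [cset(s, [c]) for s, c in calls]
            greedy = {
                frozenset((s, c.start, c.end) for s, c in cl.members)
                for cl in cohort.cluster_calls(csets_, tol=100)
            }
            assert greedy == transitive_closure(calls, 100)


class TestSharingStatistics:
    def test_singleton_fraction_all_singletons(self):
        clusters = cohort.cluster_calls(
            [cset("S1", [make_call(sample="S1", start=s, end=s + 500) for s in (1000, 9000)])]
        )
        assert cohort.singleton_fraction(clusters, "DUP") == 100.0

    def test_singleton_fraction_undefined_without_clusters(self):
        with pytest.raises(ValueError, match="undefined"):
            cohort.singleton_fraction([], "DUP")

    def test_most_common_ordering_and_truncation(self):
        csets = [
            cset(s, [make_call(sample=s, start=1000, end=2000)]) for s in ("S1", "S2", "S3", "S4", "S5")
        ]
        csets += [cset(s, [make_call(sample=s, start=9000, end=9900)]) for s in ("S6", "S7", "S8")]
        clusters = cohort.cluster_calls(csets)
        top = cohort.most_common(clusters, "DUP", n=20)
        assert [c.sharing_count for c in top] == [5, 3]
        assert cohort.most_common(clusters, "DUP", n=1)[0].sharing_count == 5

    def test_most_common_tie_breaks_to_earlier_coordinates(self):
        csets = [
            cset("S1", [make_call(sample="S1", start=5000, end=6000)]),
            cset("S2", [make_call(sample="S2", start=1000, end=2000)]),
        ]
        clusters = cohort.cluster_calls(csets)
        top = cohort.most_common(clusters, "DUP", n=1)
        assert top[0].representative.start == 1000

    @pytest.mark.parametrize(
        "n,size,expected",
        [(10, 48, 20.83), (23, 48, 47.92), (5, 16, 31.25), (7, 19, 36.84), (6, 30, 20.00), (6, 20, 30.00), (10, 20, 50.00)],
    )
    def test_sharing_percent_two_decimals(self, n, size, expected):
        assert cohort.sharing_percent(n, size) == expected


class TestBreedSpecific:
    def _fixture(self):
        manifest = [record("B1", "BSW"), record("B2", "BSW"), record("F1", "FLV"), record("F2", "FLV")]
        return manifest

    def test_two_same_breed_carriers_no_leak(self):
        manifest = self._fixture()
        csets = [
            cset("B1", [make_call(sample="B1", start=1000, end=2000)]),
            cset("B2", [make_call(sample="B2", start=1050, end=2050)]),
            cset("F1", [make_call(sample="F1", start=50_000, end=51_000)]),
        ]
        clusters = cohort.cluster_calls(csets)
        specific = cohort.breed_specific(clusters, manifest, breeds_considered=["BSW", "FLV"])
        assert [(s.breed, s.cluster.sharing_count) for s in specific] == [("BSW", 2)]

    def test_cross_breed_member_disqualifies(self):
        manifest = self._fixture()
        csets = [
            cset("B1", [make_call(sample="B1", start=1000, end=2000)]),
            cset("B2", [make_call(sample="B2", start=1050, end=2050)]),
            cset("F1", [make_call(sample="F1", start=1020, end=2020)]),
        ]
        clusters = cohort.cluster_calls(csets)
        assert cohort.breed_specific(clusters, manifest, breeds_considered=["BSW", "FLV"]) == []

    def test_neighbouring_cluster_match_disqualifies(self):
        # the other breed's call lands in a different cluster but still
        # matches this cluster's representative within tolerance
        manifest = self._fixture()
        csets = [
            cset("F2", [make_call(sample="F2", start=820, end=1820)]),
            cset("F1", [make_call(sample="F1", start=920, end=1920)]),
            cset("B1", [make_call(sample="B1", start=1010, end=2010)]),
            cset("B2", [make_call(sample="B2", start=1010, end=2010)]),
        ]
        clusters = cohort.cluster_calls(csets, tol=100)
        # F1 joined the cluster founded at 820 but still matches the BSW
        # representative at 1010 within tolerance
        assert len(clusters) == 2
        specific = cohort.breed_specific(clusters, manifest, breeds_considered=["BSW", "FLV"])
        assert [s.breed for s in specific] == ["FLV"]

    def test_sample_missing_from_manifest_is_error(self):
        csets = [cset("B1", [make_call(sample="B1")]), cset("B2", [make_call(sample="B2")])]
        clusters = cohort.cluster_calls(csets)
        with pytest.raises(KeyError, match="B2"):
            cohort.breed_specific(clusters, [record("B1", "BSW")])

    def test_breed_specific_sets_disjoint_across_breeds(self, small_cohort, toy_build):
        from cnvcohort import consensus as cns, qc

        cfg = small_cohort.config
        kept, _ = qc.filter_samples(small_cohort.manifest, cfg.build)
        csets = [
            cns.build_consensus(
                cns.filter_by_length(small_cohort.rd_calls[s.sample_id]),
                cns.filter_by_length(small_cohort.sr_calls[s.sample_id]),
            )
            for s in kept
        ]
        clusters = cohort.cluster_calls(csets, manifest=kept, validated_only=False)
        specific = cohort.breed_specific(clusters, kept)
        seen = set()
        for s in specific:
            key = id(s.cluster)
            assert key not in seen
            seen.add(key)
            assert set(s.cluster.breed_counts) == {s.breed}

    def test_breed_specific_percent(self):
        manifest = self._fixture()
        csets = [
            cset("B1", [make_call(sample="B1", start=1000, end=2000)]),
            cset("B2", [make_call(sample="B2", start=1050, end=2050)]),
            cset("B1", [make_call(sample="B1", start=70_000, end=71_000)]),
            cset("F1", [make_call(sample="F1", start=70_000, end=71_000)]),
        ]
        clusters = cohort.cluster_calls(csets)
        specific = cohort.breed_specific(clusters, manifest, breeds_considered=["BSW", "FLV"])
        pct = cohort.breed_specific_percent(specific, clusters, "BSW", "DUP")
        assert pct == pytest.approx(50.0)  # 1 specific of 2 BSW-observed clusters
        assert cohort.breed_specific_percent([], clusters, "FLV", "DUP") == 0.0


class TestGenomeCovered:
    def test_single_interval(self):
        build = GenomeBuild("t", {"1": 100_000})
        cs = cset("S1", [CNVCall("S1", "1", 1001, 2000, "DEL", "read_depth")])
        assert cohort.genome_covered_pct(cs, build, "DEL") == pytest.approx(1.0)

    def test_duplicate_intervals_counted_once(self):
        build = GenomeBuild("t", {"1": 100_000})
        call = CNVCall("S1", "1", 1001, 2000, "DEL", "read_depth")
        one = cohort.genome_covered_pct(cset("S1", [call]), build, "DEL")
        two = cohort.genome_covered_pct(cset("S1", [call, call]), build, "DEL")
        assert one == two

    def test_call_beyond_chromosome_end_is_error(self):
        build = GenomeBuild("t", {"1": 1_500})
        cs = cset("S1", [CNVCall("S1", "1", 1000, 2000, "DEL", "read_depth")])
        with pytest.raises(ValueError, match="beyond"):
            cohort.genome_covered_pct(cs, build, "DEL")

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(1, 5_000), st.integers(0, 2_000)),
            min_size=1,
            max_size=30,
        )
    )
    def test_union_never_exceeds_sum(self, spans):
        intervals = [(s, s + l) for s, l in spans]
        union = cohort.union_length(intervals)
        total = sum(e - s + 1 for s, e in intervals)
        assert 0 < union <= total
        assert union >= max(e - s + 1 for s, e in intervals)
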