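"""Cross-sample pooling and the pooled read-support cutoff."""

import pytest

from intronseek.annotation import AnnotationModel, Transcript
from intronseek.conservation import (
    NoQualifyingCutoff,
    SupportEntry,
    SupportProfile,
    aggregate_junctions,
    build_support_profiles,
    select_read_cutoff,
)
from intronseek.junctions import SpliceJunction


def J(start, reads, length=20, sample=""):
    return SpliceJunction("c", start, start + length - 1, "+",
                          unique_reads=reads, sample_id=sample)


class TestAggregate:
    def test_pooled_counts_and_sample_number(self):
        reps = {
            "s1": ([J(100, 5)], [J(100, 2)]),
            "s2": ([J(100, 9)], []),
            "s3": ([], [J(100, 0)]),
            "s4": ([J(900, 3)], [J(900, 3)]),
        }
        cutoffs = {s: 4 for s in reps}
        agg = aggregate_junctions(reps, cutoffs)
        entry = agg[("c", 100, 119, "+")]
        # detected where >= cutoff in some replicate: s1 and s2
        assert entry.samples_detected == 2
        # pooled reads sum every observation, sub-cutoff included
        assert entry.total_unique_reads == 16
        # junction never reaching any cutoff is dropped entirely
        assert ("c", 900, 919, "+") not in agg

    def test_respects_per_sample_cutoffs(self):
        reps = {"s1": ([J(100, 5)], []), "s2": ([J(100, 5)], [])}
        agg = aggregate_junctions(reps, {"s1": 4, "s2": 6})
        assert agg[("c", 100, 119, "+")].samples_detected == 1


class TestProfiles:
    def _annotation(self):
        # one transcript with a single annotated long intron [1000, 1200)
        tx = Transcript("t", "g", "c", "+", [(800, 1000), (1200, 1400)])
        return AnnotationModel([tx])

    def test_split_by_length_and_annotation(self):
        agg = {
            ("c", 101, 130, "+"): SupportEntry("c", 101, 130, "+", 3, 50),
            ("c", 1001, 1200, "+"): SupportEntry("c", 1001, 1200, "+", 9, 300),
            ("c", 2001, 2200, "+"): SupportEntry("c", 2001, 2200, "+", 2, 30),
        }
        pools = build_support_profiles(agg, self._annotation())
        assert [e.length for e in pools["short"].entries] == [30]
        assert [e.start for e in pools["long_annotated"].entries] == [1001]
        assert [e.start for e in pools["long_unannotated"].entries] == [2001]

    def test_short_keys_restriction(self):
        agg = {
            ("c", 101, 130, "+"): SupportEntry("c", 101, 130, "+", 3, 50),
            ("c", 301, 330, "+"): SupportEntry("c", 301, 330, "+", 3, 50),
        }
        pools = build_support_profiles(
            agg, self._annotation(), short_keys=[("c", 101, 130, "+")]
        )
        assert len(pools["short"].entries) == 1

    def test_distribution_sums_to_one(self):
        prof = SupportProfile(
            [SupportEntry("c", 1, 20, "+", s, 10) for s in (1, 1, 3, 5)]
        )
        dist = prof.distribution()
        assert sum(dist.values()) == pytest.approx(1.0)
        assert dist[1] == 0.5


class TestSelectReadCutoff:
    @staticmethod
    def _profiles(short_samples_reads, long_samples):
        short = SupportProfile(
            [SupportEntry("c", i + 1, i + 30, "+", s, r)
             for i, (s, r) in enumerate(short_samples_reads)]
        )
        long_u = SupportProfile(
            [SupportEntry("c", 5000 + i, 5100 + i, "+", s, 99)
             for i, s in enumerate(long_samples)]
        )
        return short, long_u

    def test_short_pool_dominating_immediately(self):
        short, long_u = self._profiles([(5, 10), (6, 20)], [1, 2, 1])
        cutoff, table = select_read_cutoff(short, long_u)
        assert cutoff == 1
        assert table[0][1] == 2

    def test_crossing_at_higher_cutoff(self):
        # low-support single-sample noise drags the mean below the long pool
        # until the cutoff removes it
        members = [(1, r) for r in (3, 3, 4, 5)] * 4 + [(8, 50), (9, 60)]
        short, long_u = self._profiles(members, [2, 2, 2, 2])
        cutoff, table = select_read_cutoff(short, long_u)
        # mean samples: (16*1 + 8 + 9)/18 = 1.83 < 2 until the cutoff drops
        # the reads<4 singles, leaving (8*1 + 17)/10 = 2.5 > 2
        assert cutoff == 4
        # kept pool size is non-increasing in the cutoff
        sizes = [row[1] for row in table]
        assert sizes == sorted(sizes, reverse=True)

    def test_all_single_sample_never_qualifies(self):
        short, long_u = self._profiles([(1, 10), (1, 20)], [2, 3])
        with pytest.raises(NoQualifyingCutoff) as exc:
            select_read_cutoff(short, long_u)
        assert len(exc.value.table) > 0

    def test_restricted_mean_non_decreasing_on_synthetic(self, default_dataset):
        from intronseek.pipeline import run_pipeline

        ds = default_dataset
        res = run_pipeline(ds.junctions, ds.genome, ds.annotation)
        means = [row[2] for row in res.cutoff_table]
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))


def test_planted_conservation_structure(default_dataset, default_result):
    """Annotated long introns sit in every sample, noise in one; the chosen
    pooled cutoff keeps the planted multi-sample short introns."""
    profiles = default_result.profiles
    n = default_dataset.config.n_datasets
    annot = profiles["long_annotated"].distribution()
    assert max(annot, key=annot.get) == n
    unannot = profiles["long_unannotated"].mean_samples()
    assert unannot < profiles["long_annotated"].mean_samples()
    assert default_result.read_cutoff <= 7
    true_keys = {
        t.key for t in default_dataset.truth_by_class("true_short_intron")
    }
    final_keys = {r.key for r in default_result.records}
    assert true_keys <= final_keys
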