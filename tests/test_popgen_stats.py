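"""Summary statistics and genetic distances against brute-force oracles."""

import itertools

import numpy as np
import pytest

from coalabc.errors import InsufficientDataError, UndefinedStatisticError
from coalabc.popgen_stats import (
    mean_pairwise_differences,
    net_between_group_distance,
    observed_stat_vector,
    pairwise_fst,
    pairwise_p_distance,
    segregating_sites,
    stat_vector_names,
)
from coalabc.sequence_data import MultiLocusDataset, SampleRecord

from conftest import make_alignment, random_alignment


# ---------------------------------------------------------------------------
# brute-force oracles: plain double loops, no numpy


def bf_p_distance(a, b):
    comp = diff = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            comp += 1
            diff += x != y
    return None if comp == 0 else diff / comp


def bf_segregating(seqs):
    s = 0
    for col in zip(*seqs):
        if len({c for c in col if c in "ACGT"}) >= 2:
            s += 1
    return s


def bf_mean_pairwise(seqs):
    tot = npair = 0
    for a, b in itertools.combinations(seqs, 2):
        npair += 1
        tot += sum(
            1 for x, y in zip(a, b) if x in "ACGT" and y in "ACGT" and x != y
        )
    return tot / npair


def bf_between(px, py):
    tot = 0
    for a in px:
        for b in py:
            tot += sum(
                1 for x, y in zip(a, b) if x in "ACGT" and y in "ACGT" and x != y
            )
    return tot / (len(px) * len(py))


def bf_net_distance(gx, gy):
    between = sum(bf_p_distance(a, b) for a in gx for b in gy) / (len(gx) * len(gy))
    def within(g):
        pairs = list(itertools.combinations(g, 2))
        if not pairs:
            return 0.0
        return sum(bf_p_distance(a, b) for a, b in pairs) / len(pairs)
    return between - (within(gx) + within(gy)) / 2


def bf_fst(px, py):
    pi_b = bf_between(px, py)
    pi_w = (bf_mean_pairwise(px) + bf_mean_pairwise(py)) / 2
    return 1 - pi_w / pi_b


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGA", 0.25),
            ("ACGT", "ACGT", 0.0),
            ("ACRT", "ATGT", 1 / 3),  # R excluded pairwise
            ("ACGT", "NCGT", 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_p_distance(a, b) == pytest.approx(expected)

    def test_no_comparable_sites_signalled(self):
        with pytest.raises(UndefinedStatisticError):
            pairwise_p_distance("NNNN", "ACGT")


class TestNetDistance:
    def test_fixed_difference(self):
        assert net_between_group_distance(
            ["AAAA", "AAAA"], ["AATT", "AATT"]
        ) == pytest.approx(0.5)

    def test_duplicated_group_matches_brute_force(self):
        # literal duplicates: between-mean includes self-pairs at distance 0,
        # so the net distance is negative — exactly what the formula yields
        g = ["AAAA", "AATT"]
        got = net_between_group_distance(g, list(g))
        assert got == pytest.approx(bf_net_distance(g, list(g)))
        assert got == pytest.approx(-0.25)

    def test_same_distribution_near_zero(self, rng):
        # two independent samples from one pool: net distance ~ 0
        pool = random_alignment(rng, 16, 400)
        got = net_between_group_distance(pool[:8], pool[8:])
        assert got == pytest.approx(0.0, abs=0.02)

    def test_empty_group(self):
        with pytest.raises(ValueError):
            net_between_group_distance([], ["AAAA"])

    def test_singleton_groups(self):
        assert net_between_group_distance(["AAAA"], ["AATT"]) == pytest.approx(0.5)


class TestWithinPopStats:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["ACGT", "ACGT"], 0),
            (["AAAA", "AAAT", "AATT"], 2),
        ],
    )
    def test_segregating_examples(self, seqs, expected):
        assert segregating_sites(seqs) == expected

    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["AAAA", "AAAT"], 1.0),
            (["AAAA", "AAAA", "AAAA"], 0.0),
        ],
    )
    def test_pi_examples(self, seqs, expected):
        assert mean_pairwise_differences(seqs) == pytest.approx(expected)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            segregating_sites(["ACGT"])
        with pytest.raises(InsufficientDataError):
            mean_pairwise_differences(["ACGT"])


class TestFst:
    def test_same_source_population_near_zero(self, rng):
        # two independent samples from one pool: no differentiation
        pool = random_alignment(rng, 16, 400)
        assert pairwise_fst(pool[:8], pool[8:]) == pytest.approx(0.0, abs=0.05)

    def test_fixed_differences_give_one(self):
        assert pairwise_fst(["AATT", "AATT"], ["AAAA", "AAAA"]) == 1.0

    def test_monomorphic_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pairwise_fst(["AAAA", "AAAA"], ["AAAA", "AAAA"])


def test_statistics_match_brute_force_on_random_alignments(rng):
    """Exact equality with double-loop oracles on 50 random small alignments."""
    for _ in range(50):
        n = int(rng.integers(4, 9))
        length = int(rng.integers(30, 61))
        seqs = random_alignment(rng, n, length, p_missing=0.05, p_ambig=0.05)
        half = n // 2
        px, py = seqs[:half], seqs[half:]
        assert segregating_sites(seqs) == bf_segregating(seqs)
        assert mean_pairwise_differences(seqs) == bf_mean_pairwise(seqs)
        assert pairwise_p_distance(seqs[0], seqs[1]) == bf_p_distance(
            seqs[0], seqs[1]
        )
        assert net_between_group_distance(px, py) == pytest.approx(
            bf_net_distance(px, py), abs=1e-12
        )
        try:
            got = pairwise_fst(px, py)
        except UndefinedStatisticError:
            assert bf_between(px, py) == 0.0
        else:
            assert got == pytest.approx(
                np.clip(bf_fst(px, py), -1, 1), abs=1e-12
            )


class TestObservedStatVector:
    def test_dimension_bookkeeping(self, tiny_dataset):
        sv = observed_stat_vector(tiny_dataset)
        assert sv.values.size == 13
        assert sv.names == stat_vector_names()

    def test_undifferentiated_populations_fst_near_zero(self, rng):
        # three taxa drawn from one pool carry no differentiation signal
        pool = random_alignment(rng, 12, 400)
        ids = [f"s{i}" for i in range(12)]
        taxa = ["albiceps"] * 4 + ["chilensis"] * 4 + ["pallatangae"] * 4
        samples = [SampleRecord(i, t) for i, t in zip(ids, taxa)]
        ds = MultiLocusDataset(samples, [make_alignment(pool, ids=ids)])
        sv = observed_stat_vector(ds).as_series()
        for name in sv.index:
            if name.startswith("fst_"):
                assert sv[name] == pytest.approx(0.0, abs=0.05)

    def test_mito_is_single_locus_passthrough(self, tiny_dataset):
        sv = observed_stat_vector(tiny_dataset, marker_set="mitochondrial")
        mt = tiny_dataset.loci[1]
        alb = tiny_dataset.taxon_rows(mt, "albiceps")
        assert sv.as_series()["S_albiceps"] == segregating_sites(alb)
        assert sv.as_series()["pi_albiceps"] == mean_pairwise_differences(alb)

    def test_invariant_under_sample_relabeling(self, rng):
        seqs = random_alignment(rng, 6, 100)
        taxa = ["albiceps"] * 2 + ["chilensis"] * 2 + ["pallatangae"] * 2
        ids = [f"s{i}" for i in range(6)]
        samples = [SampleRecord(i, t) for i, t in zip(ids, taxa)]
        aln = make_alignment(seqs, ids=ids)
        base = observed_stat_vector(MultiLocusDataset(samples, [aln])).values
        # swap labels within albiceps
        swapped = dict(zip(ids, seqs))
        swapped["s0"], swapped["s1"] = swapped["s1"], swapped["s0"]
        aln2 = make_alignment([swapped[i] for i in ids], ids=ids)
        again = observed_stat_vector(MultiLocusDataset(samples, [aln2])).values
        assert np.array_equal(base, again)

    def test_population_missing_errors(self, tiny_dataset):
        with pytest.raises(InsufficientDataError):
            observed_stat_vector(
                tiny_dataset, pops=("albiceps", "chilensis", "other")
            )

    def test_monomorphic_dataset_all_zero(self):
        ids = [f"s{i}" for i in range(6)]
        taxa = ["albiceps"] * 2 + ["chilensis"] * 2 + ["pallatangae"] * 2
        samples = [SampleRecord(i, t) for i, t in zip(ids, taxa)]
        aln = make_alignment(["AAAA"] * 6, ids=ids)
        sv = observed_stat_vector(MultiLocusDataset(samples, [aln]))
        assert np.all(sv.values == 0.0)
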