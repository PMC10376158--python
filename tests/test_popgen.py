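"""Frequency reports, difference counts and K2P distances."""

import math

import numpy as np
import pytest

from beehap.model import HaplotypeCall, LocusSequence
from beehap.popgen import (
    k2p_distance,
    k2p_from_proportions,
    k2p_pair,
    p_distance_pair,
    pairwise_differences,
    summarize,
)
from beehap.synthetic_locus import MutationSpec, build_canonical, mutate


def _call(sample_id, lineage, haplogroup="X", haplotype="Xa"):
    return HaplotypeCall(
        sample_id=sample_id,
        lineage=lineage,
        haplogroup=haplogroup,
        haplotype=haplotype,
        novelty=False,
        n_diffs_to_nearest=0,
        nearest_known=haplotype,
    )


def test_lineage_shares_round_half_up():
    calls = [_call(f"c{i}", "C_or_O") for i in range(71)] + [
        _call(f"m{i}", "M") for i in range(198)
    ]
    report = summarize(calls)
    assert report.n == 269
    assert report.lineage_percent == {"C_or_O": 26.4, "M": 73.6}
    assert abs(sum(report.lineage_percent.values()) - 100.0) <= 0.1


def test_single_sample_is_hundred_percent():
    report = summarize([_call("s1", "M")])
    assert report.lineage_percent == {"M": 100.0}


def test_summarize_matches_direct_counting_oracle():
    rng = np.random.default_rng(2)
    lineages = rng.choice(["C_or_O", "M", "A"], size=100)
    calls = [_call(f"s{i}", lin) for i, lin in enumerate(lineages)]
    report = summarize(calls)
    for lin in set(lineages):
        expected = int(np.sum(lineages == lin))
        assert report.lineage_counts[lin] == expected
        assert report.lineage_percent[lin] == round(100 * expected / 100, 1)


def test_summarize_is_permutation_invariant():
    calls = [_call(f"s{i}", lin) for i, lin in enumerate(["M", "C_or_O", "M"])]
    assert summarize(calls).to_dict() == summarize(calls[::-1]).to_dict()


def test_summarize_sheet_mismatch_lists_offenders():
    calls = [_call("s1", "M"), _call("s2", "M")]
    with pytest.raises(ValueError, match="s3"):
        summarize(calls, {"s1": "r1", "s3": "r1"})


def test_summarize_per_region_breakdown():
    calls = [_call("s1", "M"), _call("s2", "C_or_O"), _call("s3", "M")]
    report = summarize(calls, {"s1": "north", "s2": "south", "s3": "north"})
    assert report.region_lineage_counts == {
        "north": {"M": 2},
        "south": {"C_or_O": 1},
    }


def test_pairwise_differences_identity_and_symmetry():
    seqs = [
        LocusSequence("a", "ACGTACGTAC"),
        LocusSequence("b", "ACGTACGTAC"),
        LocusSequence("c", "ACGAACGTAC"),
    ]
    dm = pairwise_differences(seqs)
    assert dm.get("a", "b") == 0
    assert dm.get("a", "c") == dm.get("c", "a") == 1


def test_four_substitutions_plus_deletion_count_five(library):
    # analog of sister haplotypes separated by 4 substitutions and a 1 bp
    # deletion: the contiguous gap counts as one event, total 5
    base = build_canonical("M4'", library=library)
    subs = []
    for pos in (650, 700, 750, 800):
        subs.append((pos, "C" if base.sequence[pos] != "C" else "G"))
    mut, _ = mutate(
        base, MutationSpec(substitutions=tuple(subs), indels=((860, 1),))
    )
    dm = pairwise_differences([base, LocusSequence("m4h", mut.sequence)])
    assert dm.get("M4'", "m4h") == 5


def test_differences_match_bruteforce_on_substitution_pairs():
    # for equal-length sequences differing only by substitutions, the event
    # count must equal the direct Hamming count
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(50, 200))
        a = "".join(rng.choice(list("ACGT"), size=n))
        b = list(a)
        k = int(rng.integers(0, 6))
        pos = rng.choice(n, size=k, replace=False)
        for p in pos:
            b[p] = str(rng.choice([x for x in "ACGT" if x != b[p]]))
        b = "".join(b)
        dm = pairwise_differences([LocusSequence("a", a), LocusSequence("b", b)])
        assert dm.get("a", "b") == sum(x != y for x, y in zip(a, b))


def test_k2p_identical_is_zero():
    assert k2p_pair("ACGT" * 25, "ACGT" * 25) == 0.0


def test_k2p_one_transition_closed_form():
    a = "ACGT" * 25
    b = "GCGT" + "ACGT" * 24  # A->G transition at the first column
    expected = -0.5 * math.log((1 - 2 * 0.01 - 0.0) * math.sqrt(1.0))
    assert abs(k2p_pair(a, b) - expected) < 1e-9
    assert abs(expected - 0.010101) < 5e-7


def test_k2p_mixed_changes_closed_form():
    a = "ACGT" * 25
    b = list(a)
    b[0] = "G"   # transition
    b[5] = "T"   # C->T transition
    b[10] = "T"  # G->T transversion
    b = "".join(b)
    p, q = 2 / 100, 1 / 100
    expected = -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q))
    assert abs(k2p_pair(a, b) - expected) < 1e-9


def test_k2p_dominates_p_distance():
    rng = np.random.default_rng(4)
    for _ in range(25):
        a = "".join(rng.choice(list("ACGT"), size=200))
        b = list(a)
        for p in rng.choice(200, size=int(rng.integers(1, 40)), replace=False):
            b[p] = str(rng.choice([x for x in "ACGT" if x != b[p]]))
        b = "".join(b)
        d = k2p_pair(a, b)
        if not math.isnan(d):
            assert d >= p_distance_pair(a, b) - 1e-12


def test_k2p_saturation_flagged_not_raised():
    a = "A" * 60
    b = "G" * 60  # all transitions: argument of the log is non-positive
    seqs = [LocusSequence("a", a), LocusSequence("b", b)]
    dm = k2p_distance(seqs)
    assert math.isnan(dm.get("a", "b"))
    assert dm.undefined == (("a", "b"),)
    assert math.isnan(k2p_from_proportions(0.5, 0.0))


def test_distance_matrix_export(tmp_path):
    seqs = [LocusSequence("a", "ACGT"), LocusSequence("b", "ACGA")]
    dm = pairwise_differences(seqs)
    dm.to_tsv(tmp_path / "d.tsv")
    dm.to_phylip(tmp_path / "d.phy")
    assert (tmp_path / "d.tsv").read_text().startswith("label\t")
    assert (tmp_path / "d.phy").read_text().splitlines()[0] == "2"
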