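"""Haplogroup rules, haplotype matching, nomenclature proposals."""

import pytest

from beehap.annotate import annotate
from beehap.classify import (
    HAPLOGROUP_RULES,
    InconsistencyError,
    ReferenceDB,
    ReferenceRecord,
    assign_haplogroup,
    default_reference_db,
    match_haplotype,
    propose_name,
)
from beehap.digest import digest
from beehap.model import FragmentProfile
from beehap.synthetic_locus import (
    CANONICAL_RECIPES,
    MutationSpec,
    build_canonical,
    mutate,
)


def _profile(fragments):
    cuts = []
    acc = 0
    for f in fragments[:-1]:
        acc += f
        cuts.append(acc)
    return FragmentProfile(tuple(fragments), tuple(cuts))


def test_rule_table_contents():
    table = {r.haplogroup: (r.profile, r.allele) for r in HAPLOGROUP_RULES}
    assert table["C1"] == ((47, 41, 64, 420), "Q")
    assert table["C2"] == ((47, 40, 64, 420), "Q")
    assert table["C3"] == ((47, 40, 63, 420), "Q")
    assert table["C4"] == ((47, 39, 64, 420), "Q")
    assert table["M4"] == ((142, 65, 131, 65, 422), "PQQ")
    assert table["M17"] == ((142, 66, 131, 65, 422), "PQQ")
    assert table["M7"] == ((47, 95, 65, 131, 65, 422), "PQQ")
    assert table["M4'"] == ((142, 65, 131, 65, 131, 65, 421), "PQQQ")


@pytest.mark.parametrize("name", sorted(CANONICAL_RECIPES))
def test_roundtrip_haplogroup_assignment(name, canonicals, library):
    rec = canonicals[name]
    assignment = assign_haplogroup(digest(rec), annotate(rec, library=library))
    assert assignment.status == "MATCHED"
    assert assignment.haplogroup == CANONICAL_RECIPES[name]["haplogroup"]


def test_c4_profile_matches():
    assert assign_haplogroup(_profile([47, 39, 64, 420])).haplogroup == "C4"


def test_novel_profile_carries_key():
    # six-fragment profile reported for a misnamed GenBank M4 record
    a = assign_haplogroup(_profile([100, 65, 130, 65, 29, 289]))
    assert a.status == "NOVEL"
    assert a.haplogroup == "NOVEL_PROFILE"
    assert a.profile_key == "100/65/130/65/29/289"


def test_profile_allele_contradiction(canonicals, library):
    q_structure = annotate(canonicals["C2"], library=library)  # allele Q
    with pytest.raises(InconsistencyError):
        assign_haplogroup(_profile([142, 65, 131, 65, 422]), q_structure)


def test_relaxed_tolerance_reports_ambiguity_sets():
    a = assign_haplogroup(_profile([142, 65, 131, 65, 422]), tolerance=1)
    assert a.status == "AMBIGUOUS"
    assert a.haplogroups == ("M17", "M4")
    c = assign_haplogroup(_profile([47, 40, 64, 420]), tolerance=1)
    assert c.status == "AMBIGUOUS"
    assert set(c.haplogroups) == {"C1", "C2", "C3", "C4"}


def test_exact_match_is_known(canonicals, refdb, library):
    call = match_haplotype(canonicals["C2"], refdb, library=library)
    assert call.haplotype == "C2"
    assert not call.novelty
    assert call.n_diffs_to_nearest == 0
    assert call.lineage == "C_or_O"


def test_single_substitution_yields_novel_neighbor(canonicals, refdb, library):
    mut, _ = mutate(
        canonicals["C2"], MutationSpec(substitutions=((200, "G") if canonicals["C2"].sequence[200] != "G" else (200, "C"),))
    )
    call = match_haplotype(mut, refdb, library=library)
    assert call.novelty
    assert call.nearest_known == "C2"
    assert call.n_diffs_to_nearest == 1
    assert call.haplotype == "C2a"  # next free suffix in the shipped DB


def test_difference_counts_to_reference(library, refdb):
    # analogs of sister haplotypes two and one substitution from a reference
    base = build_canonical("M4'", library=library)
    db = ReferenceDB(
        [ReferenceRecord("M4g'", "M4'", "M", base.sequence)], version="test"
    )
    two, _ = mutate(base, MutationSpec(substitutions=((700, "C") if base.sequence[700] != "C" else (700, "G"), (750, "C") if base.sequence[750] != "C" else (750, "G"))))
    one, _ = mutate(base, MutationSpec(substitutions=(((720, "C") if base.sequence[720] != "C" else (720, "G")),)))
    call_two = match_haplotype(two, db, library=library)
    call_one = match_haplotype(one, db, library=library)
    assert (call_two.n_diffs_to_nearest, call_one.n_diffs_to_nearest) == (2, 1)
    assert call_two.nearest_known == call_one.nearest_known == "M4g'"
    assert call_one.haplotype == "M4h'"  # prime carried through proposals


def test_empty_haplogroup_gives_none_nearest(canonicals, library):
    db = ReferenceDB([], version="empty")
    call = match_haplotype(canonicals["C2"], db, library=library)
    assert call.novelty
    assert call.nearest_known == "NONE"
    assert call.haplotype == "C2a"


def _site_neutral_variant(seq: str, i: int) -> str:
    # distinct single-substitution variants deep in the COII filler
    pos = 450 + i
    base = "C" if seq[pos] != "C" else "G"
    return seq[:pos] + base + seq[pos + 1 :]


def test_propose_name_conventions(library):
    seq_m17 = build_canonical("M17", library=library).sequence
    db = ReferenceDB(
        [
            ReferenceRecord(f"M17{c}", "M17", "M", _site_neutral_variant(seq_m17, i))
            for i, c in enumerate("jklmnopqrstu")
        ],
        version="t",
    )
    assert propose_name("M17", db) == "M17v"
    seq_c2 = build_canonical("C2", library=library).sequence
    db2 = ReferenceDB(
        [
            ReferenceRecord("C2i", "C2", "C_or_O", seq_c2),
            ReferenceRecord("C2i1", "C2", "C_or_O", _site_neutral_variant(seq_c2, 1)),
        ],
        version="t",
    )
    assert propose_name("C2", db2) == "C2i2"
    assert propose_name("C4", ReferenceDB([], version="t")) == "C4a"


def test_db_validation_rejects_contradicting_record(library):
    # a sequence digesting to the C2 profile declared as M17 must be refused
    seq = build_canonical("C2", library=library).sequence
    with pytest.raises(ValueError, match="contradicts"):
        ReferenceDB([ReferenceRecord("M17x", "M17", "M", seq)])


def test_db_rejects_duplicate_names(library):
    seq = build_canonical("C2", library=library).sequence
    with pytest.raises(ValueError, match="duplicate"):
        ReferenceDB(
            [
                ReferenceRecord("C2", "C2", "C_or_O", seq),
                ReferenceRecord("C2", "C2", "C_or_O", seq),
            ]
        )


def test_db_tsv_roundtrip(tmp_path, refdb):
    path = tmp_path / "db.tsv"
    refdb.to_tsv(path)
    loaded = ReferenceDB.from_tsv(path)
    assert loaded.names == refdb.names
    assert loaded.records == refdb.records


def test_site_neutral_mutation_keeps_haplogroup(canonicals, library):
    import numpy as np

    from beehap.synthetic_locus import random_site_neutral_substitutions

    rng = np.random.default_rng(8)
    for name in sorted(CANONICAL_RECIPES):
        rec = canonicals[name]
        mut, _ = mutate(rec, random_site_neutral_substitutions(rec, 3, rng))
        assignment = assign_haplogroup(digest(mut))
        assert assignment.haplogroup == CANONICAL_RECIPES[name]["haplogroup"]
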