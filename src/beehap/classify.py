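"""Haplogroup and haplotype classification.

A haplogroup is the set of haplotypes sharing one DraI fragment profile
(e.g. every sequence cutting to 47/40/64/420 is haplogroup C2); a haplotype
is a unique sequence within a haplogroup, named by letter suffix.  Profile
matching is exact by default: haplogroups M4 and M17 differ by a single base
(65 vs 66 bp in the second fragment), so any tolerance must report ambiguity
sets instead of picking a winner.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

from ._align import diff_pair
from .annotate import annotate, call_lineage
from .digest import digest, profile_key
from .model import (
    LINEAGE_C_OR_O,
    LINEAGE_M,
    AlleleStructure,
    FragmentProfile,
    HaplotypeCall,
    LocusSequence,
)
from .synthetic_locus import build_canonical, canonical_names, normalize_name
from .templates import TemplateLibrary, default_templates

NOVEL_PROFILE = "NOVEL_PROFILE"


@dataclass(frozen=True)
class HaplogroupRule:
    haplogroup: str
    profile: tuple[int, ...]
    allele: str


#: The published profile -> haplogroup rule table.
HAPLOGROUP_RULES: tuple[HaplogroupRule, ...] = (
    HaplogroupRule("C1", (47, 41, 64, 420), "Q"),
    HaplogroupRule("C2", (47, 40, 64, 420), "Q"),
    HaplogroupRule("C3", (47, 40, 63, 420), "Q"),
    HaplogroupRule("C4", (47, 39, 64, 420), "Q"),
    HaplogroupRule("M4", (142, 65, 131, 65, 422), "PQQ"),
    HaplogroupRule("M17", (142, 66, 131, 65, 422), "PQQ"),
    HaplogroupRule("M7", (47, 95, 65, 131, 65, 422), "PQQ"),
    HaplogroupRule("M4'", (142, 65, 131, 65, 131, 65, 421), "PQQQ"),
)


class InconsistencyError(ValueError):
    """Profile and allele architecture contradict each other."""


@dataclass(frozen=True)
class HaplogroupAssignment:
    status: str  # MATCHED | NOVEL | AMBIGUOUS
    haplogroups: tuple[str, ...]
    profile_key: str

    @property
    def haplogroup(self) -> str:
        if self.status == "MATCHED":
            return self.haplogroups[0]
        if self.status == "NOVEL":
            return NOVEL_PROFILE
        return "AMBIGUOUS:" + "|".join(self.haplogroups)


def assign_haplogroup(
    profile: FragmentProfile,
    structure: AlleleStructure | None = None,
    tolerance: int = 0,
) -> HaplogroupAssignment:
    """Match a fragment profile against the haplogroup rule table.

    ``tolerance`` is a per-fragment +/- bp allowance (0 = exact, the
    default).  In relaxed mode every matching haplogroup is reported; the
    caller decides.  A profile matching no rule is NOVEL (carrying its
    profile key so new haplogroups, like C4 in the original survey, can be
    registered).
    """
    fragments = profile.fragments
    matches = []
    for rule in HAPLOGROUP_RULES:
        if len(rule.profile) != len(fragments):
            continue
        if all(abs(a - b) <= tolerance for a, b in zip(rule.profile, fragments)):
            matches.append(rule)
    if structure is not None and structure.resolved:
        for rule in matches:
            if rule.allele != structure.allele_string:
                raise InconsistencyError(
                    f"profile {profile_key(profile)} implies haplogroup "
                    f"{rule.haplogroup} (allele {rule.allele}) but the "
                    f"annotated allele is {structure.allele_string}"
                )
    key = profile_key(profile)
    if not matches:
        return HaplogroupAssignment("NOVEL", (), key)
    if len(matches) == 1:
        return HaplogroupAssignment("MATCHED", (matches[0].haplogroup,), key)
    return HaplogroupAssignment(
        "AMBIGUOUS", tuple(sorted(r.haplogroup for r in matches)), key
    )


@dataclass(frozen=True)
class ReferenceRecord:
    name: str
    haplogroup: str
    lineage: str
    sequence: str


class ReferenceDB:
    """Known-haplotype database: name, haplogroup, lineage, sequence.

    Every record whose haplogroup appears in the rule table is validated at
    load: its sequence must digest to exactly that haplogroup's profile.
    """

    def __init__(self, records: list[ReferenceRecord], version: str = "user"):
        names = [r.name for r in records]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate haplotype names in reference DB: {dupes}")
        rules = {r.haplogroup: r.profile for r in HAPLOGROUP_RULES}
        for rec in records:
            if rec.haplogroup in rules:
                observed = digest(rec.sequence.upper()).fragments
                if observed != rules[rec.haplogroup]:
                    raise ValueError(
                        f"reference record {rec.name}: digest "
                        f"{profile_key(observed)} contradicts declared "
                        f"haplogroup {rec.haplogroup} "
                        f"({profile_key(rules[rec.haplogroup])})"
                    )
        self.records = list(records)
        self.version = version

    def __len__(self) -> int:
        return len(self.records)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def in_haplogroup(self, haplogroup: str) -> list[ReferenceRecord]:
        return [r for r in self.records if r.haplogroup == haplogroup]

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path, version: str | None = None) -> "ReferenceDB":
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                name, haplogroup, lineage, sequence = line.split("\t")
                if name == "name":
                    continue  # header
                records.append(
                    ReferenceRecord(
                        normalize_name(name),
                        normalize_name(haplogroup),
                        lineage,
                        sequence.upper(),
                    )
                )
        return cls(records, version=version or Path(path).name)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\thaplogroup\tlineage\tsequence\n")
            for r in self.records:
                fh.write(f"{r.name}\t{r.haplogroup}\t{r.lineage}\t{r.sequence}\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceDB":
        with open(path) as fh:
            payload = json.load(fh)
        records = [
            ReferenceRecord(
                normalize_name(r["name"]),
                normalize_name(r["haplogroup"]),
                r["lineage"],
                r["sequence"].upper(),
            )
            for r in payload["records"]
        ]
        return cls(records, version=payload.get("version", "user"))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "records": [
                {
                    "name": r.name,
                    "haplogroup": r.haplogroup,
                    "lineage": r.lineage,
                    "sequence": r.sequence,
                }
                for r in self.records
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def default_reference_db(library: TemplateLibrary | None = None) -> ReferenceDB:
    """The shipped DB: the eight canonical synthetic haplotype sequences."""
    library = library or default_templates()
    records = []
    from .synthetic_locus import CANONICAL_RECIPES

    for name in canonical_names():
        rec = build_canonical(name, library=library)
        meta = CANONICAL_RECIPES[name]
        records.append(
            ReferenceRecord(
                name=name,
                haplogroup=meta["haplogroup"],
                lineage=meta["lineage"],
                sequence=rec.sequence,
            )
        )
    return ReferenceDB(records, version=f"synthetic-canonical-{library.version}")


_SUFFIX_RE = re.compile(r"^([a-z]?)(\d*)$")


def propose_name(haplogroup: str, db: ReferenceDB) -> str:
    """Propose the next nomenclature-compliant haplotype name.

    Convention: single-letter suffixes a-z; a letter's digit series (C2i,
    C2i1, C2i2, ...) is continued when the most advanced existing suffix has
    a digit; primes on M' haplogroups trail the suffix (M4k' after M4j').
    """
    haplogroup = normalize_name(haplogroup)
    prime = "'" if haplogroup.endswith("'") else ""
    stem = haplogroup.rstrip("'")
    suffixes = []
    for name in db.names:
        if name.endswith("'") != bool(prime):
            continue  # M4 and M4' are distinct haplogroup series
        name = name.rstrip("'")
        if not name.startswith(stem):
            continue
        m = _SUFFIX_RE.match(name[len(stem) :])
        if m:
            letter, num = m.group(1), m.group(2)
            suffixes.append((letter, int(num) if num else 0))
    existing = {f"{l}{n if n else ''}" for l, n in suffixes}

    def render(letter: str, num: int) -> str:
        return f"{stem}{letter}{num if num else ''}{prime}"

    lettered = [s for s in suffixes if s[0]]
    if not lettered:
        letter, num = "a", 0
    else:
        letter, num = max(lettered)
        if num > 0:
            num += 1
        elif letter < "z":
            letter, num = chr(ord(letter) + 1), 0
        else:
            num = 1
    while f"{letter}{num if num else ''}" in existing:
        num += 1
    return render(letter, num)


def match_haplotype(
    seq: LocusSequence,
    db: ReferenceDB,
    library: TemplateLibrary | None = None,
    tolerance: int = 0,
) -> HaplotypeCall:
    """Full per-sample call: lineage, haplogroup, haplotype name, novelty.

    Exact sequence equality against same-haplogroup references gives a known
    haplotype; otherwise the sample is novel and its distance (substitutions
    plus indel events, from a global alignment) to the nearest known
    haplotype is reported, along with a nomenclature-compliant proposed name.
    """
    library = library or default_templates()
    structure = annotate(seq, library=library)
    lineage = call_lineage(structure).lineage
    profile = digest(seq)
    assignment = assign_haplogroup(
        profile, structure if structure.resolved else None, tolerance=tolerance
    )
    haplogroup = assignment.haplogroup

    candidates = (
        db.in_haplogroup(haplogroup) if assignment.status == "MATCHED" else []
    )
    for rec in candidates:
        if rec.sequence == seq.sequence:
            return HaplotypeCall(
                sample_id=seq.sample_id,
                lineage=lineage,
                haplogroup=haplogroup,
                haplotype=rec.name,
                novelty=False,
                n_diffs_to_nearest=0,
                nearest_known=rec.name,
            )
    if not candidates:
        proposed = (
            propose_name(haplogroup, db)
            if assignment.status == "MATCHED"
            else f"NOVEL:{assignment.profile_key}"
        )
        return HaplotypeCall(
            sample_id=seq.sample_id,
            lineage=lineage,
            haplogroup=haplogroup,
            haplotype=proposed,
            novelty=True,
            n_diffs_to_nearest=-1,
            nearest_known="NONE",
        )
    diffs = [
        (diff_pair(seq.sequence, rec.sequence).n_events, rec.name)
        for rec in candidates
    ]
    n_diffs, nearest = min(diffs)
    return HaplotypeCall(
        sample_id=seq.sample_id,
        lineage=lineage,
        haplogroup=haplogroup,
        haplotype=propose_name(haplogroup, db),
        novelty=True,
        n_diffs_to_nearest=n_diffs,
        nearest_known=nearest,
    )
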