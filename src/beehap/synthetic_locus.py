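"""Deterministic generator of canonical and mutated tRNAleu-COII amplicons.

Canonical haplotypes are assembled from the element templates in
:mod:`beehap.templates` by concatenation plus small declared edits (the
1 bp indels that distinguish, e.g., C1/C3/C4 from C2, and the substitution
that creates the intra-P DraI site of M7).  Every build is verified against
its expected DraI cut list, so a generated sequence can never carry an
undeclared site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .digest import DRAI_SITE, digest, find_sites, profile_key
from .model import LINEAGE_C_OR_O, LINEAGE_M, LocusSequence
from .templates import TemplateLibrary, default_templates

_PRIME_CHARS = {"′": "'", "ʹ": "'"}


def normalize_name(name: str) -> str:
    """Map typographic primes (M4′) to the ASCII apostrophe (M4')."""
    for prime, ascii_ in _PRIME_CHARS.items():
        name = name.replace(prime, ascii_)
    return name


@dataclass(frozen=True)
class AlleleSpec:
    """Request for one synthetic allele.

    Either ``haplotype_label`` names a supported canonical haplotype, or
    ``target_profile`` gives an explicit fragment-length profile, or
    ``p_form``/``q_count`` describe an arbitrary element architecture.
    """

    haplotype_label: str = ""
    p_form: str | None = None
    q_count: int | None = None
    target_profile: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.q_count is not None and not 1 <= self.q_count <= 3:
            raise ValueError("q_count must be in {1, 2, 3} for canonical alleles")


@dataclass(frozen=True)
class MutationSpec:
    """Explicit edits: substitutions (position, base) and indels.

    An indel is ``(position, insert-string)`` (inserted before ``position``)
    or ``(position, deletion-length)``.  All positions refer to the input
    sequence; substitutions are applied first, then indels right-to-left.
    """

    substitutions: tuple[tuple[int, str], ...] = ()
    indels: tuple[tuple[int, str | int], ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class MutationReport:
    profile_before: tuple[int, ...]
    profile_after: tuple[int, ...]
    site_set_changed: bool
    n_sites_before: int
    n_sites_after: int


class MutationResult(NamedTuple):
    sequence: LocusSequence
    report: MutationReport


# recipe = ordered (template_variant, edits); an edit is ("ins", pos, str),
# ("del", pos, len) or ("sub", pos, base), applied to a copy of the template.
_C = "COII"
_T = "tRNAleu"
CANONICAL_RECIPES: dict[str, dict] = {
    "C1": {
        "haplogroup": "C1",
        "lineage": LINEAGE_C_OR_O,
        "recipe": [(_T, ()), ("Q_C", (("ins", 20, "G"),)), (_C, ())],
    },
    "C2": {
        "haplogroup": "C2",
        "lineage": LINEAGE_C_OR_O,
        "recipe": [(_T, ()), ("Q_C", ()), (_C, ())],
    },
    "C3": {
        "haplogroup": "C3",
        "lineage": LINEAGE_C_OR_O,
        "recipe": [(_T, ()), ("Q_C", (("del", 70, 1),)), (_C, ())],
    },
    "C4a": {
        "haplogroup": "C4",
        "lineage": LINEAGE_C_OR_O,
        "recipe": [(_T, ()), ("Q_C", (("del", 20, 1),)), (_C, ())],
    },
    "M4": {
        "haplogroup": "M4",
        "lineage": LINEAGE_M,
        "recipe": [(_T, ()), ("P", ()), ("Q_M", ()), ("Q_M", ()), (_C, ())],
    },
    "M7": {
        "haplogroup": "M7",
        "lineage": LINEAGE_M,
        # the substitution completes the intra-P near-site TTTAAT -> TTTAAA
        "recipe": [
            (_T, ()),
            ("P", (("sub", 9, "A"),)),
            ("Q_M", ()),
            ("Q_M", ()),
            (_C, ()),
        ],
    },
    "M17": {
        "haplogroup": "M17",
        "lineage": LINEAGE_M,
        "recipe": [
            (_T, ()),
            ("P", ()),
            ("Q_M", (("ins", 70, "G"),)),
            ("Q_M", ()),
            (_C, ()),
        ],
    },
    "M4'": {
        "haplogroup": "M4'",
        "lineage": LINEAGE_M,
        "recipe": [
            (_T, ()),
            ("P", ()),
            ("Q_M", ()),
            ("Q_M", ()),
            ("Q_M", ()),
            (_C, (("del", 100, 1),)),
        ],
    },
}

#: Published DraI fragment profiles for the canonical haplotypes.
CANONICAL_PROFILES: dict[str, tuple[int, ...]] = {
    "C1": (47, 41, 64, 420),
    "C2": (47, 40, 64, 420),
    "C3": (47, 40, 63, 420),
    "C4a": (47, 39, 64, 420),
    "M4": (142, 65, 131, 65, 422),
    "M7": (47, 95, 65, 131, 65, 422),
    "M17": (142, 66, 131, 65, 422),
    "M4'": (142, 65, 131, 65, 131, 65, 421),
}


def canonical_names() -> tuple[str, ...]:
    return tuple(CANONICAL_RECIPES)


def _apply_element_edits(sequence: str, edits) -> str:
    for op in edits:
        if op[0] == "sub":
            _, pos, base = op
            sequence = sequence[:pos] + base + sequence[pos + 1 :]
        elif op[0] == "ins":
            _, pos, insert = op
            sequence = sequence[:pos] + insert + sequence[pos:]
        elif op[0] == "del":
            _, pos, length = op
            sequence = sequence[:pos] + sequence[pos + length :]
        else:  # pragma: no cover - recipe table is static
            raise ValueError(f"unknown edit op {op!r}")
    return sequence


def _assemble(recipe, library: TemplateLibrary) -> tuple[str, tuple[int, ...]]:
    """Concatenate edited elements; return sequence and expected cut list."""
    parts: list[str] = []
    cuts: list[int] = []
    offset = 0
    for variant, edits in recipe:
        seq = _apply_element_edits(library[variant].sequence, edits)
        for s in find_sites(seq):
            cuts.append(offset + s + 3)
        parts.append(seq)
        offset += len(seq)
    return "".join(parts), tuple(cuts)


def build_canonical(
    spec: AlleleSpec | str,
    library: TemplateLibrary | None = None,
    seed: int = 1,
    sample_id: str | None = None,
) -> LocusSequence:
    """Build one canonical (or explicitly specified) amplicon.

    ``spec`` may be a canonical haplotype name (C1, C2, C3, C4a, M4, M7,
    M17, M4'), an :class:`AlleleSpec` with a ``target_profile``, or an
    :class:`AlleleSpec` describing a p-form / Q-count architecture.
    Repeated calls with the same seed are byte-identical.
    """
    if isinstance(spec, str):
        spec = AlleleSpec(haplotype_label=normalize_name(spec))
    label = normalize_name(spec.haplotype_label)

    if spec.target_profile is not None:
        return build_from_profile(
            spec.target_profile, seed=seed, sample_id=sample_id or label or "profile"
        )

    library = library or default_templates(seed)
    if label:
        if label not in CANONICAL_RECIPES:
            raise ValueError(
                f"unsupported canonical haplotype {label!r}; "
                f"supported: {', '.join(canonical_names())}"
            )
        recipe = CANONICAL_RECIPES[label]["recipe"]
    else:
        if spec.q_count is None:
            raise ValueError("AlleleSpec needs a label, target_profile or q_count")
        q_variant = "Q_C" if spec.p_form in (None, "ABSENT") else "Q_M"
        recipe = [(_T, ())]
        if spec.p_form not in (None, "ABSENT"):
            recipe.append((spec.p_form, ()))
        recipe.extend([(q_variant, ())] * spec.q_count)
        recipe.append((_C, ()))

    sequence, expected_cuts = _assemble(recipe, library)
    prof = digest(sequence)
    if prof.site_positions != expected_cuts:  # pragma: no cover - by design
        raise AssertionError(
            f"{label or spec}: designed cuts {expected_cuts}, "
            f"observed {prof.site_positions}"
        )
    if label and prof.fragments != CANONICAL_PROFILES[label]:
        raise AssertionError(  # pragma: no cover - by design
            f"{label}: expected profile {CANONICAL_PROFILES[label]}, "
            f"got {prof.fragments}"
        )
    return LocusSequence(
        sample_id=sample_id or (label or "allele"),
        sequence=sequence,
        haplotype=label or None,
    )


def build_from_profile(
    profile: Iterable[int], seed: int = 1, sample_id: str = "profile"
) -> LocusSequence:
    """Build a sequence whose DraI digest equals ``profile`` exactly.

    Fragments are joined so each internal boundary reads TTT^AAA; filler is
    rejection-sampled so no other TTTAAA occurs.
    """
    fragments = tuple(int(f) for f in profile)
    if not fragments:
        raise ValueError("profile must contain at least one fragment")
    rng = np.random.default_rng(seed)
    n = len(fragments)
    for i, length in enumerate(fragments):
        lo = 1 if n == 1 else (6 if 0 < i < n - 1 else 3)
        if length < lo:
            raise ValueError(
                f"unsatisfiable profile: fragment {i} ({length} bp) is shorter "
                f"than the embedded mandatory motif ({lo} bp minimum)"
            )
    bases: list[str] = []
    for i, length in enumerate(fragments):
        head = "AAA" if i > 0 else ""
        tail = "TTT" if i < n - 1 else ""
        filler = rng.choice(list("ACGT"), size=length - len(head) - len(tail))
        bases.extend([head, *filler, tail])
    seq = list("".join(bases))
    cuts = np.cumsum(fragments[:-1])
    designed = {int(c) - 3 for c in cuts}
    protected = {b for s in designed for b in range(s, s + len(DRAI_SITE))}
    while True:
        accidental = [i for i in find_sites("".join(seq)) if i not in designed]
        if not accidental:
            break
        window = [
            j
            for j in range(accidental[0], accidental[0] + len(DRAI_SITE))
            if j not in protected
        ]
        seq[window[-1]] = str(rng.choice(list("CG")))
    out = LocusSequence(sample_id=sample_id, sequence="".join(seq))
    assert digest(out).fragments == fragments
    return out


def _site_windows(sequence: str) -> list[tuple[int, int]]:
    return [(s, s + len(DRAI_SITE)) for s in find_sites(sequence)]


def mutate(
    seq: LocusSequence, m: MutationSpec, allow_site_edits: bool = False
) -> MutationResult:
    """Apply an explicit edit set; flag any change to the DraI site set.

    Edits that touch an existing TTTAAA site raise unless
    ``allow_site_edits`` is set, preventing silent profile changes.
    """
    sequence = seq.sequence
    windows = _site_windows(sequence)

    def _in_site(lo: int, hi: int) -> bool:
        return any(lo < e and hi > s for s, e in windows)

    for pos, base in m.substitutions:
        if not 0 <= pos < len(sequence):
            raise ValueError(f"substitution position {pos} out of bounds")
        if base not in "ACGTN":
            raise ValueError(f"invalid substitution base {base!r}")
        if not allow_site_edits and _in_site(pos, pos + 1):
            raise ValueError(
                f"substitution at {pos} falls inside a DraI site; "
                "pass allow_site_edits=True to override"
            )
    for pos, edit in m.indels:
        span = (pos, pos + edit) if isinstance(edit, int) else (pos, pos)
        if not 0 <= pos <= len(sequence):
            raise ValueError(f"indel position {pos} out of bounds")
        if isinstance(edit, int) and pos + edit > len(sequence):
            raise ValueError(f"deletion at {pos} extends past sequence end")
        touches = _in_site(*span) if isinstance(edit, int) else _in_site(pos - 1, pos + 1)
        if not allow_site_edits and touches:
            raise ValueError(
                f"indel at {pos} falls inside a DraI site; "
                "pass allow_site_edits=True to override"
            )

    before = digest(sequence)
    edited = list(sequence)
    for pos, base in m.substitutions:
        edited[pos] = base
    out = "".join(edited)
    for pos, edit in sorted(m.indels, key=lambda x: x[0], reverse=True):
        if isinstance(edit, int):
            out = out[:pos] + out[pos + edit :]
        else:
            out = out[:pos] + edit + out[pos:]
    after = digest(out)
    report = MutationReport(
        profile_before=before.fragments,
        profile_after=after.fragments,
        site_set_changed=before.site_positions != after.site_positions,
        n_sites_before=before.n_sites,
        n_sites_after=after.n_sites,
    )
    mutated = LocusSequence(
        sample_id=seq.sample_id, sequence=out, region=seq.region
    )
    return MutationResult(mutated, report)


def random_site_neutral_substitutions(
    seq: LocusSequence, n: int, rng: np.random.Generator
) -> MutationSpec:
    """Draw ``n`` substitutions guaranteed not to touch or create any site.

    Positions avoid existing TTTAAA windows; replacement bases are C/G, which
    can never complete a new recognition site.
    """
    windows = {b for s in find_sites(seq.sequence) for b in range(s, s + 6)}
    candidates = [i for i in range(len(seq.sequence)) if i not in windows]
    positions = rng.choice(len(candidates), size=n, replace=False)
    subs = []
    for idx in sorted(int(p) for p in positions):
        pos = candidates[idx]
        cur = seq.sequence[pos]
        new = "G" if cur in "CAT" else "C"
        subs.append((pos, new))
    return MutationSpec(substitutions=tuple(subs))


DEFAULT_REGIONS = tuple(f"region-{i:02d}" for i in range(1, 20))


def simulate_population(
    freqs: dict[str, int],
    seed: int = 1,
    library: TemplateLibrary | None = None,
    regions: Iterable[str] = DEFAULT_REGIONS,
) -> list[LocusSequence]:
    """Simulate a typed population: ``freqs`` maps haplotype name to count.

    Emits exactly ``sum(freqs.values())`` records; each record carries its
    true haplotype label and a round-robin region assignment.  The study this
    emulates sampled 269 colonies from 19 regions.
    """
    if any(c < 0 for c in freqs.values()):
        raise ValueError("haplotype counts must be >= 0")
    library = library or default_templates(seed)
    regions = tuple(regions)
    base = {
        normalize_name(name): build_canonical(name, library=library)
        for name in freqs
    }
    total = sum(freqs.values())
    width = max(4, len(str(total)))
    records: list[LocusSequence] = []
    i = 0
    for name, count in freqs.items():
        canon = base[normalize_name(name)]
        for _ in range(count):
            records.append(
                LocusSequence(
                    sample_id=f"S{i + 1:0{width}d}",
                    sequence=canon.sequence,
                    region=regions[i % len(regions)] if regions else None,
                    haplotype=canon.haplotype,
                )
            )
            i += 1
    return records


def truth_table(records: Iterable[LocusSequence]) -> dict[str, str]:
    """Hidden truth mapping sample_id -> true haplotype, for recovery tests."""
    return {r.sample_id: r.haplotype or "" for r in records}
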