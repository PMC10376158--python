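"""Structural annotation of tRNAleu-COII amplicons.

The locus is tiled left to right with element templates: the partial tRNAleu
gene, an optional P element (best-scoring variant among P0/P/P1/P2, or
absent), a maximal tandem array of Q repeats, and the partial COII gene.
Each assignment requires >= 90% identity to a template; anything less yields
an UNRESOLVED structure with diagnostics rather than a silent guess.

The evolutionary lineage follows from the architecture alone: the C and O
lineages lack the P element and carry a single Q; lineage M carries P(Q)1-n;
lineage A carries the P0 (13 bp insert) or P1 (15 bp deletion) form; lineage
Y carries the P2 form (18 bp deletion).
"""

from __future__ import annotations

import edlib

from ._align import align_pair
from .model import (
    LINEAGE_A,
    LINEAGE_C_OR_O,
    LINEAGE_M,
    LINEAGE_UNRESOLVED,
    LINEAGE_Y,
    AlleleStructure,
    LineageCall,
    LocusSequence,
)
from .templates import COII_PART, Q, TRNALEU_PART, TemplateLibrary, default_templates

IDENTITY_THRESHOLD = 0.90
P_VARIANTS = ("P0", "P", "P1", "P2")

C_OR_O_CAVEAT = (
    "architecture lacks the P element with a single Q repeat; this marker "
    "cannot separate the C from the O evolutionary lineage"
)

#: Nominal allele lengths resolvable on an 8% polyacrylamide gel.
GEL_ALLELE_LENGTHS = {"Q": 571, "PQQ": 825, "PQQQ": 1020}
GEL_WINDOW = 25  # +/- bp, mirrors ~600/800/1000 bp gel resolution
GEL_CAVEAT = (
    "length prescreen only: A- and Y-lineage alleles can have the same "
    "fragment size as M-lineage alleles"
)


def _best_prefix(template: str, target: str) -> tuple[float, int]:
    """Identity and consumed target length for template-vs-prefix alignment."""
    if not target:
        return 0.0, 0
    res = edlib.align(template, target, mode="SHW", task="locations")
    end = res["locations"][-1][1]
    identity = 1.0 - res["editDistance"] / len(template)
    return identity, end + 1


def annotate(
    seq: LocusSequence,
    library: TemplateLibrary | None = None,
    identity_threshold: float = IDENTITY_THRESHOLD,
) -> AlleleStructure:
    """Parse one amplicon into element spans and an allele string."""
    library = library or default_templates()
    s = seq.sequence
    spans: list[tuple[str, int, int]] = []
    pos = 0

    trna = library.by_kind(TRNALEU_PART)[0]
    identity, consumed = _best_prefix(trna.sequence, s)
    if identity < identity_threshold:
        return AlleleStructure.unresolved(
            f"tRNAleu segment identity {identity:.2f} below "
            f"{identity_threshold:.2f} threshold"
        )
    spans.append((TRNALEU_PART, 0, consumed))
    pos = consumed

    # P element: candidates are P0/P/P1/P2 and ABSENT.  Variants are close
    # truncations of one another, so each candidate is scored jointly: its
    # own edit distance plus the distance of the best Q repeat starting
    # right after it.  The candidate explaining the most context wins.
    q_templates = library.by_kind(Q)

    def _best_q(rest: str) -> tuple[float, int, int]:
        best = (0.0, 0, 10**9)  # identity, consumed, distance
        for t in q_templates:
            identity, consumed = _best_prefix(t.sequence, rest)
            dist = round((1.0 - identity) * len(t.sequence))
            if identity > best[0]:
                best = (identity, consumed, dist)
        return best

    candidates = []  # (total_distance, variant, p_identity, p_consumed)
    _, _, q_dist_absent = _best_q(s[pos:])
    candidates.append((q_dist_absent, "ABSENT", 1.0, 0))
    for variant in P_VARIANTS:
        template = library[variant].sequence
        identity, consumed = _best_prefix(template, s[pos:])
        p_dist = round((1.0 - identity) * len(template))
        _, _, q_dist = _best_q(s[pos + consumed :])
        candidates.append((p_dist + q_dist, variant, identity, consumed))
    _, p_form, p_identity, p_consumed = min(
        candidates, key=lambda c: (c[0], c[1])
    )
    if p_form != "ABSENT":
        if p_identity < identity_threshold:
            return AlleleStructure.unresolved(
                f"best P-variant ({p_form}) identity {p_identity:.2f} below "
                f"{identity_threshold:.2f} threshold"
            )
        spans.append((p_form, pos, pos + p_consumed))
        pos += p_consumed

    # Maximal tandem Q array, counted by template tiling.
    q_count = 0
    while True:
        best_q, best_consumed = 0.0, 0
        for t in q_templates:
            identity, consumed = _best_prefix(t.sequence, s[pos:])
            if identity > best_q:
                best_q, best_consumed = identity, consumed
        if best_q < identity_threshold:
            break
        q_count += 1
        spans.append((Q, pos, pos + best_consumed))
        pos += best_consumed
    if q_count == 0:
        return AlleleStructure.unresolved(
            f"no Q repeat found at offset {pos} (best identity {best_q:.2f})"
        )

    # The COII segment must account for the entire remainder.
    coii = library.by_kind(COII_PART)[0]
    remainder = s[pos:]
    if not remainder:
        return AlleleStructure.unresolved("sequence ends before the COII segment")
    res = edlib.align(coii.sequence, remainder, mode="NW", task="distance")
    identity = 1.0 - res["editDistance"] / max(len(coii.sequence), len(remainder))
    if identity < identity_threshold:
        return AlleleStructure.unresolved(
            f"COII segment identity {identity:.2f} below "
            f"{identity_threshold:.2f} threshold"
        )
    spans.append((COII_PART, pos, len(s)))

    allele = ("" if p_form == "ABSENT" else p_form) + "Q" * q_count
    return AlleleStructure(
        p_form=p_form,
        q_count=q_count,
        allele_string=allele,
        element_spans=tuple(spans),
    )


def call_lineage(structure: AlleleStructure) -> LineageCall:
    """Map an allele architecture to its evolutionary lineage."""
    if not structure.resolved:
        return LineageCall(
            LINEAGE_UNRESOLVED,
            f"structure unresolved: {structure.diagnostics}",
        )
    if structure.p_form == "ABSENT":
        if structure.q_count == 1:
            return LineageCall(LINEAGE_C_OR_O, C_OR_O_CAVEAT)
        return LineageCall(
            LINEAGE_UNRESOLVED,
            f"P element absent but q_count={structure.q_count}; no described "
            "lineage matches this architecture",
        )
    if structure.p_form == "P":
        return LineageCall(LINEAGE_M, "P element present: P(Q)1-n architecture")
    if structure.p_form in ("P0", "P1"):
        return LineageCall(
            LINEAGE_A,
            f"{structure.p_form} form of the P element (African-lineage marker)",
        )
    if structure.p_form == "P2":
        return LineageCall(
            LINEAGE_Y, "P2 form (18 bp deletion) of the P element"
        )
    return LineageCall(LINEAGE_UNRESOLVED, f"unknown P form {structure.p_form}")


def length_based_prescreen(seq_length: int) -> tuple[str, str]:
    """Coarse allele guess from amplicon length alone (gel-style screen).

    Returns ``(allele_or_UNKNOWN, caveat)``; nearest canonical allele length
    within +/- 25 bp, else UNKNOWN.
    """
    if seq_length <= 0:
        raise ValueError("sequence length must be positive")
    best = min(
        GEL_ALLELE_LENGTHS.items(), key=lambda kv: abs(kv[1] - seq_length)
    )
    if abs(best[1] - seq_length) <= GEL_WINDOW:
        return best[0], GEL_CAVEAT
    return "UNKNOWN", GEL_CAVEAT


def describe_p_variant(
    variant: str, library: TemplateLibrary | None = None
) -> dict:
    """Recover, by alignment against P, what distinguishes a P variant.

    Returns ``{"variant", "kind", "length", "sequence"}`` where kind is
    ``insertion`` or ``deletion`` relative to the plain P element.
    """
    library = library or default_templates()
    if variant == "P":
        return {"variant": "P", "kind": "reference", "length": 0, "sequence": ""}
    if variant not in P_VARIANTS:
        raise ValueError(f"unknown P variant {variant!r}")
    row_var, row_p = align_pair(
        library[variant].sequence, library["P"].sequence
    )
    ins = []  # bases present in the variant but not in P
    dels = []  # bases present in P but not in the variant
    for x, y in zip(row_var, row_p):
        if y == "-":
            ins.append(x)
        elif x == "-":
            dels.append(y)
    if ins and not dels:
        return {
            "variant": variant,
            "kind": "insertion",
            "length": len(ins),
            "sequence": "".join(ins),
        }
    if dels and not ins:
        return {
            "variant": variant,
            "kind": "deletion",
            "length": len(dels),
            "sequence": "".join(dels),
        }
    return {
        "variant": variant,
        "kind": "complex",
        "length": len(ins) + len(dels),
        "sequence": "",
    }
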