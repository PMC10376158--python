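"""Core record types shared across the typing pipeline.

The locus under study is the non-coding mtDNA region between the tRNA-leucine
gene and the cytochrome-oxidase-II gene of *Apis mellifera* (the COI-COII or
tRNAleu-COII intergenic locus).  Its architecture — a partial tRNAleu segment,
an optional P element (forms P0/P/P1/P2), a tandem array of Q repeats, and a
partial COII segment — together with the positions of DraI (TTTAAA)
recognition sites defines the maternal evolutionary lineage and haplogroup of
a colony.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGTN")

#: Evolutionary lineage labels.  The DraI test cannot separate the East
#: European (C) from the West/Central Asian (O) lineage, hence the joint key.
LINEAGE_A = "A"
LINEAGE_M = "M"
LINEAGE_C_OR_O = "C_or_O"
LINEAGE_Y = "Y"
LINEAGE_UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class LocusSequence:
    """One tRNAleu-COII amplicon (primer-to-primer, linear, 5'->3')."""

    sample_id: str
    sequence: str
    region: str | None = None
    haplotype: str | None = None  # ground-truth label, when known

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.sample_id}: empty sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.sample_id}: invalid characters {sorted(bad)} "
                "(alphabet is A/C/G/T/N)"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentProfile:
    """Ordered DraI fragment lengths for one amplicon.

    ``site_positions`` are cut coordinates (0-based, between the third and
    fourth base of each TTTAAA site); ``fragments`` are the 5'->3' lengths
    between consecutive cuts.
    """

    fragments: tuple[int, ...]
    site_positions: tuple[int, ...]
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.fragments) != len(self.site_positions) + 1:
            raise ValueError("len(fragments) must equal n_sites + 1")
        if any(f < 1 for f in self.fragments):
            raise ValueError("all fragments must be >= 1 bp")

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    @property
    def total_length(self) -> int:
        return sum(self.fragments)


# Allowed P-element annotations.  ABSENT marks the C/O-lineage architecture.
P_FORMS = ("ABSENT", "P0", "P", "P1", "P2")


@dataclass(frozen=True)
class AlleleStructure:
    """Parsed element architecture of one amplicon.

    ``element_spans`` are ``(element_name, start, end)`` triples in 0-based,
    half-open coordinates; when the structure is resolved they are contiguous
    and cover the full sequence.
    """

    p_form: str
    q_count: int
    allele_string: str
    element_spans: tuple[tuple[str, int, int], ...]
    resolved: bool = True
    diagnostics: str = ""

    @classmethod
    def unresolved(cls, diagnostics: str) -> "AlleleStructure":
        return cls(
            p_form="UNRESOLVED",
            q_count=0,
            allele_string="UNRESOLVED",
            element_spans=(),
            resolved=False,
            diagnostics=diagnostics,
        )


@dataclass(frozen=True)
class LineageCall:
    lineage: str
    rationale: str


@dataclass(frozen=True)
class HaplotypeCall:
    """Final per-sample call: lineage, haplogroup, haplotype name, novelty."""

    sample_id: str
    lineage: str
    haplogroup: str
    haplotype: str
    novelty: bool
    n_diffs_to_nearest: int
    nearest_known: str

    def __post_init__(self) -> None:
        if not self.novelty and self.n_diffs_to_nearest != 0:
            raise ValueError("known haplotype must have zero differences")
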