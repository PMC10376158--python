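"""Synthetic element templates for the tRNAleu-COII locus.

The published record gives allele totals (Q = 571 bp, PQQ = 825 bp,
PQQQ = 1020 bp) and DraI fragment profiles, but not the element boundary
sequences themselves.  The geometry used here is derived from those numbers:

* the spacing between homologous DraI cuts in consecutive Q copies of the
  M-lineage alleles (142/207 vs 338/403) fixes the tandem Q unit at 196 bp;
* Q = 571 bp with a 40 bp tRNAleu part and a 196 bp Q repeat leaves a
  335 bp COII part;
* PQQ = 825 bp then leaves 825 − 40 − 2·196 − 335 = 58 bp for the P element.

P-variant landmarks follow the published descriptions: P0 carries the 13 bp
insert AAACAAAATATAA at the P 5' end; P1 and P2 are P with 15 bp and 18 bp
deletions, taken from the P 3' end by convention (the true offsets are not
published).  The C-lineage and M-lineage Q repeats are distinct sequence
variants (their DraI sites sit at different offsets), as the printed C and M
profiles require.

Filler bases are pseudorandom from a stated seed (default 1) and are
rejection-sampled so that TTTAAA occurs only at declared sites; template
edges are forced to C/G so concatenation can never create a site across an
element junction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .digest import DRAI_SITE, find_sites

# Element kind names
TRNALEU_PART = "TRNALEU_PART"
COII_PART = "COII_PART"
Q = "Q"

# Geometry (bp) — see module docstring for the derivation.
TRNALEU_LEN = 40
P_LEN = 58
Q_LEN = 196
COII_LEN = 335

P0_INSERT = "AAACAAAATATAA"  # 13 bp, at the P 5' end
P1_DELETION = 15  # bp removed from the P 3' end
P2_DELETION = 18  # bp removed from the P 3' end

#: DraI site start offsets within each Q variant.
QC_SITES = (4, 44, 108)  # C/O-lineage Q repeat (three sites)
QM_SITES = (41, 106)  # M-lineage Q repeat (two sites)

#: P carries a near-site TTTAAT here; one substitution turns it into a true
#: DraI site (the M7 architecture has a cut inside the P element).
P_NEAR_SITE_AT = 4
P_NEAR_SITE = "TTTAAT"

_CG = np.array(list("CG"))
_ACGT = np.array(list("ACGT"))


@dataclass(frozen=True)
class ElementTemplate:
    """One locus building block with its declared DraI sites."""

    name: str  # element kind: TRNALEU_PART, P0, P, P1, P2, Q, COII_PART
    variant: str  # concrete template id, e.g. "Q_C", "Q_M", "P0"
    sequence: str
    drai_sites: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        found = tuple(find_sites(self.sequence))
        if found != self.drai_sites:
            raise ValueError(
                f"template {self.variant}: found DraI sites {found}, "
                f"declared {self.drai_sites}"
            )


def _sample_filler(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_ACGT, size=n))


def _repair_accidental_sites(
    bases: list[str], protected: set[int], rng: np.random.Generator
) -> None:
    """Destroy every TTTAAA outside protected windows by a C/G substitution."""
    while True:
        seq = "".join(bases)
        accidental = [i for i in find_sites(seq) if i not in protected]
        if not accidental:
            return
        window = range(accidental[0], accidental[0] + len(DRAI_SITE))
        editable = [j for j in window if j not in _protected_bases(protected)]
        if not editable:  # cannot happen with non-overlapping designs
            raise RuntimeError("accidental DraI site inside protected window")
        bases[editable[-1]] = str(rng.choice(_CG))


def _protected_bases(site_starts: set[int]) -> set[int]:
    out: set[int] = set()
    for s in site_starts:
        out.update(range(s, s + len(DRAI_SITE)))
    return out


def _build_template(
    rng: np.random.Generator,
    name: str,
    variant: str,
    length: int,
    sites: tuple[int, ...] = (),
    near_sites: tuple[int, ...] = (),
    force_cg: tuple[int, ...] = (),
) -> ElementTemplate:
    bases = _sample_filler(rng, length)
    stamped: set[int] = set(sites)
    for s in sites:
        bases[s : s + len(DRAI_SITE)] = list(DRAI_SITE)
    for s in near_sites:
        bases[s : s + len(P_NEAR_SITE)] = list(P_NEAR_SITE)
    # Template edges must be C/G so junctions can never complete a TTTAAA.
    for pos in {0, length - 1, *force_cg}:
        if pos not in _protected_bases(stamped) and not any(
            ns <= pos < ns + len(P_NEAR_SITE) for ns in near_sites
        ):
            bases[pos] = str(rng.choice(_CG))
    _repair_accidental_sites(bases, stamped, rng)
    return ElementTemplate(
        name=name, variant=variant, sequence="".join(bases), drai_sites=sites
    )


class TemplateLibrary:
    """The set of element templates defining one synthetic locus 'genome'."""

    def __init__(self, templates: dict[str, ElementTemplate], seed: int):
        self.templates = templates
        self.seed = seed
        self.version = f"synthetic-templates-seed{seed}"

    def __getitem__(self, variant: str) -> ElementTemplate:
        return self.templates[variant]

    def by_kind(self, kind: str) -> list[ElementTemplate]:
        return [t for t in self.templates.values() if t.name == kind]

    def to_dir(self, path: str | Path) -> None:
        """Ship the library as FASTA plus a JSON manifest of declared sites."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "templates.fasta", "w") as fh:
            for t in self.templates.values():
                fh.write(f">{t.variant}\n{t.sequence}\n")
        manifest = {
            "seed": self.seed,
            "version": self.version,
            "elements": [
                {
                    "variant": t.variant,
                    "name": t.name,
                    "length": t.length,
                    "drai_sites": list(t.drai_sites),
                }
                for t in self.templates.values()
            ],
        }
        with open(path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dir(cls, path: str | Path) -> "TemplateLibrary":
        path = Path(path)
        with open(path / "manifest.json") as fh:
            manifest = json.load(fh)
        seqs: dict[str, str] = {}
        header = None
        chunks: list[str] = []
        with open(path / "templates.fasta") as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if header is not None:
                        seqs[header] = "".join(chunks)
                    header, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
        if header is not None:
            seqs[header] = "".join(chunks)
        templates = {
            e["variant"]: ElementTemplate(
                name=e["name"],
                variant=e["variant"],
                sequence=seqs[e["variant"]],
                drai_sites=tuple(e["drai_sites"]),
            )
            for e in manifest["elements"]
        }
        return cls(templates, seed=manifest["seed"])


def build_default_templates(seed: int = 1) -> TemplateLibrary:
    """Deterministically build the full template set from one seed."""
    rng = np.random.default_rng(seed)
    templates: dict[str, ElementTemplate] = {}

    templates["tRNAleu"] = _build_template(
        rng, TRNALEU_PART, "tRNAleu", TRNALEU_LEN
    )

    # P: force C/G where the P1/P2 3'-truncations end, so the derived
    # variants keep safe junction edges.
    p = _build_template(
        rng,
        "P",
        "P",
        P_LEN,
        near_sites=(P_NEAR_SITE_AT,),
        force_cg=(P_LEN - P1_DELETION - 1, P_LEN - P2_DELETION - 1),
    )
    templates["P"] = p
    templates["P0"] = ElementTemplate(
        name="P0", variant="P0", sequence=P0_INSERT + p.sequence
    )
    templates["P1"] = ElementTemplate(
        name="P1", variant="P1", sequence=p.sequence[: P_LEN - P1_DELETION]
    )
    templates["P2"] = ElementTemplate(
        name="P2", variant="P2", sequence=p.sequence[: P_LEN - P2_DELETION]
    )

    # Two Q sequence variants: the C/O-lineage repeat (three DraI sites) and
    # the M-lineage repeat (two).  Interior C/G anchors guard the positions
    # where canonical indel edits are applied (see synthetic_locus).
    templates["Q_C"] = _build_template(
        rng, Q, "Q_C", Q_LEN, sites=QC_SITES, force_cg=(21, 71)
    )
    templates["Q_M"] = _build_template(
        rng, Q, "Q_M", Q_LEN, sites=QM_SITES, force_cg=(71,)
    )

    templates["COII"] = _build_template(
        rng, COII_PART, "COII", COII_LEN, force_cg=(101,)
    )

    # Structural invariants of the published P-variant landmarks.
    assert templates["P0"].length - templates["P"].length == len(P0_INSERT)
    assert templates["P"].length - templates["P1"].length == P1_DELETION
    assert templates["P"].length - templates["P2"].length == P2_DELETION
    return TemplateLibrary(templates, seed=seed)


_DEFAULT_CACHE: dict[int, TemplateLibrary] = {}


def default_templates(seed: int = 1) -> TemplateLibrary:
    """Cached accessor for the deterministic default library."""
    if seed not in _DEFAULT_CACHE:
        _DEFAULT_CACHE[seed] = build_default_templates(seed)
    return _DEFAULT_CACHE[seed]
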