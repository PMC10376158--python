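"""In-silico DraI digestion of tRNAleu-COII amplicons.

DraI recognizes TTTAAA and cuts bluntly between the third and fourth base
(TTT^AAA).  The site is its own reverse complement, so scanning the plus
strand is sufficient; it also cannot overlap itself, so a left-to-right scan
finds every site exactly once.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .model import FragmentProfile, LocusSequence

DRAI_SITE = "TTTAAA"
CUT_OFFSET = 3  # blunt cut TTT^AAA


def find_sites(sequence: str) -> list[int]:
    """Start offsets of every exact TTTAAA occurrence, left to right."""
    sites = []
    i = sequence.find(DRAI_SITE)
    while i != -1:
        sites.append(i)
        i = sequence.find(DRAI_SITE, i + 1)
    return sites


def _ambiguous_windows(sequence: str) -> list[int]:
    """Windows where an N prevents deciding whether a DraI site is present."""
    hits = []
    for i in range(len(sequence) - len(DRAI_SITE) + 1):
        window = sequence[i : i + len(DRAI_SITE)]
        if "N" in window and all(
            c == p or c == "N" for c, p in zip(window, DRAI_SITE)
        ):
            hits.append(i)
    return hits


def digest(seq: LocusSequence | str) -> FragmentProfile:
    """Digest one amplicon, returning ordered fragment lengths 5'->3'.

    An N inside a window that could form TTTAAA yields no cut there but an
    ``ambiguous DraI site`` warning on the returned profile.
    """
    sequence = seq.sequence if isinstance(seq, LocusSequence) else seq.upper()
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    cuts = [i + CUT_OFFSET for i in find_sites(sequence)]
    bounds = [0, *cuts, len(sequence)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    warnings = tuple(
        f"ambiguous DraI site at offset {i} (N within recognition window)"
        for i in _ambiguous_windows(sequence)
    )
    return FragmentProfile(
        fragments=fragments, site_positions=tuple(cuts), warnings=warnings
    )


def profile_key(profile: FragmentProfile | Iterable[int]) -> str:
    """Canonical slash-joined rendering, e.g. ``47/40/64/420``."""
    fragments = (
        profile.fragments
        if isinstance(profile, FragmentProfile)
        else tuple(profile)
    )
    return "/".join(str(f) for f in fragments)


def parse_profile_key(key: str) -> tuple[int, ...]:
    """Inverse of :func:`profile_key`."""
    try:
        fragments = tuple(int(part) for part in key.split("/"))
    except ValueError as exc:
        raise ValueError(f"malformed profile key {key!r}") from exc
    if not fragments or any(f < 1 for f in fragments):
        raise ValueError(f"malformed profile key {key!r}")
    return fragments


def digest_table(seqs: Iterable[LocusSequence]) -> pd.DataFrame:
    """Per-sample digest summary (sample_id, length, n_sites, profile_key)."""
    rows = []
    for seq in seqs:
        prof = digest(seq)
        rows.append(
            {
                "sample_id": seq.sample_id,
                "length": prof.total_length,
                "n_sites": prof.n_sites,
                "profile_key": profile_key(prof),
                "warnings": ";".join(prof.warnings),
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "length", "n_sites", "profile_key", "warnings"]
    )
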