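"""Shared pairwise-alignment configuration and difference counting.

One global aligner parameterization (affine gaps, open 10 / extend 1, free
end gaps) is used everywhere column-level alignments matter: haplotype
difference counts, K2P distances and P-variant indel recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    # free end gaps: haplotypes may differ by whole tandem-repeat copies
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Bio.Align attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER = make_aligner()


@dataclass(frozen=True)
class GapRun:
    """One contiguous indel event in a pairwise alignment."""

    row: int  # 0 = gap in first sequence (insertion), 1 = gap in second
    column: int
    length: int
    bases: str  # the bases present on the ungapped row


@dataclass(frozen=True)
class PairwiseDiff:
    n_substitutions: int
    gap_runs: tuple[GapRun, ...]

    @property
    def n_events(self) -> int:
        """Substitutions plus indel events (a contiguous gap counts once)."""
        return self.n_substitutions + len(self.gap_runs)


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Best global alignment of two sequences as gapped row strings."""
    alignment = _ALIGNER.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def diff_pair(a: str, b: str) -> PairwiseDiff:
    """Count substitutions and contiguous indel events between two sequences."""
    if a == b:
        return PairwiseDiff(0, ())
    row_a, row_b = align_pair(a, b)
    n_subs = 0
    runs: list[GapRun] = []
    open_run: list | None = None  # [row, column, length, bases]
    for col, (x, y) in enumerate(zip(row_a, row_b)):
        if x == "-" or y == "-":
            row = 0 if x == "-" else 1
            base = y if x == "-" else x
            if open_run is not None and open_run[0] == row:
                open_run[2] += 1
                open_run[3] += base
            else:
                if open_run is not None:
                    runs.append(GapRun(*open_run))
                open_run = [row, col, 1, base]
        else:
            if open_run is not None:
                runs.append(GapRun(*open_run))
                open_run = None
            if x != y:
                n_subs += 1
    if open_run is not None:
        runs.append(GapRun(*open_run))
    return PairwiseDiff(n_subs, tuple(runs))
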