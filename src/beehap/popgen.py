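"""Frequency reports and pairwise distances over classified samples.

Percentages are rendered half-up to one decimal (so 71/269 C-lineage and
198/269 M-lineage colonies print as 26.4% and 73.6%).  Pairwise differences
count substitutions plus indel events — a contiguous gap run counts once, so
"four substitutions and a deletion of one nucleotide" is five differences.
K2P is the Kimura two-parameter distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q))
with P and Q the transition and transversion proportions over ungapped
aligned columns.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._align import align_pair, diff_pair
from .model import HaplotypeCall, LocusSequence

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _percent(count: int, total: int) -> float:
    pct = Decimal(count) / Decimal(total) * Decimal(100)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FrequencyReport:
    n: int
    haplotype_counts: dict[str, int]
    haplogroup_counts: dict[str, int]
    lineage_counts: dict[str, int]
    lineage_percent: dict[str, float]
    region_lineage_counts: dict[str, dict[str, int]] | None = None

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "haplotype_counts": dict(sorted(self.haplotype_counts.items())),
            "haplogroup_counts": dict(sorted(self.haplogroup_counts.items())),
            "lineage_counts": dict(sorted(self.lineage_counts.items())),
            "lineage_percent": dict(sorted(self.lineage_percent.items())),
        }
        if self.region_lineage_counts is not None:
            out["region_lineage_counts"] = {
                k: dict(sorted(v.items()))
                for k, v in sorted(self.region_lineage_counts.items())
            }
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def summarize(
    calls: Iterable[HaplotypeCall],
    sheet: Mapping[str, str] | pd.DataFrame | None = None,
) -> FrequencyReport:
    """Tabulate haplotype/haplogroup/lineage frequencies from calls.

    ``sheet`` optionally maps sample_id -> region (or is a DataFrame with
    those columns); sample ids in the sheet must match the calls exactly.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no calls to summarize")
    regions: dict[str, str] | None = None
    if sheet is not None:
        if isinstance(sheet, pd.DataFrame):
            regions = dict(zip(sheet["sample_id"], sheet["region"]))
        else:
            regions = dict(sheet)
        call_ids = {c.sample_id for c in calls}
        missing = sorted(call_ids.symmetric_difference(regions))
        if missing:
            raise ValueError(
                "sample sheet does not match calls; offending ids: "
                + ", ".join(missing)
            )
    n = len(calls)
    lineage_counts = Counter(c.lineage for c in calls)
    report = FrequencyReport(
        n=n,
        haplotype_counts=dict(Counter(c.haplotype for c in calls)),
        haplogroup_counts=dict(Counter(c.haplogroup for c in calls)),
        lineage_counts=dict(lineage_counts),
        lineage_percent={k: _percent(v, n) for k, v in lineage_counts.items()},
        region_lineage_counts=(
            {
                region: dict(
                    Counter(
                        c.lineage for c in calls if regions[c.sample_id] == region
                    )
                )
                for region in sorted(set(regions.values()))
            }
            if regions is not None
            else None
        ),
    )
    return report


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray
    metric: str
    undefined: tuple[tuple[str, str], ...] = ()  # saturated K2P pairs

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="label")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                cells = " ".join(f"{x:.6f}" for x in row)
                fh.write(f"{label:<10s} {cells}\n")


def _as_pairs(seqs: list[LocusSequence]) -> list[tuple[str, str]]:
    labels = [s.sample_id for s in seqs]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate sample ids in distance computation")
    return labels


def pairwise_differences(seqs: list[LocusSequence]) -> DistanceMatrix:
    """Counts of substitutions + indel events for every pair."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    labels = _as_pairs(seqs)
    n = len(seqs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = diff_pair(seqs[i].sequence, seqs[j].sequence).n_events
            values[i, j] = values[j, i] = d
    return DistanceMatrix(tuple(labels), values, metric="difference_count")


def k2p_from_proportions(p: float, q: float) -> float:
    """Kimura two-parameter distance from transition/transversion fractions."""
    arg = (1.0 - 2.0 * p - q) * math.sqrt(1.0 - 2.0 * q)
    if arg <= 0.0:
        return float("nan")
    return -0.5 * math.log(arg)


def k2p_pair(a: str, b: str) -> float:
    """K2P distance for one pair; gap and N columns are excluded."""
    if a == b:
        return 0.0
    row_a, row_b = align_pair(a, b)
    n = transitions = transversions = 0
    for x, y in zip(row_a, row_b):
        if x in "-N" or y in "-N":
            continue
        n += 1
        if x != y:
            if frozenset((x, y)) in TRANSITIONS:
                transitions += 1
            else:
                transversions += 1
    if n == 0:
        return float("nan")
    return k2p_from_proportions(transitions / n, transversions / n)


def k2p_distance(seqs: list[LocusSequence]) -> DistanceMatrix:
    """K2P distance matrix (substitutions/site); saturated pairs are flagged
    as undefined (NaN), not raised."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    labels = _as_pairs(seqs)
    n = len(seqs)
    values = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_pair(seqs[i].sequence, seqs[j].sequence)
            values[i, j] = values[j, i] = d
            if math.isnan(d):
                undefined.append((labels[i], labels[j]))
    return DistanceMatrix(
        tuple(labels), values, metric="K2P", undefined=tuple(undefined)
    )


def p_distance_pair(a: str, b: str) -> float:
    """Raw proportion of differing ungapped columns (for sanity checks)."""
    if a == b:
        return 0.0
    row_a, row_b = align_pair(a, b)
    n = diff = 0
    for x, y in zip(row_a, row_b):
        if x in "-N" or y in "-N":
            continue
        n += 1
        diff += x != y
    return diff / n if n else float("nan")
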