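"""File formats: FASTA, sample sheets, provenance-stamped TSV/JSON.

FASTA is read through Bio.SeqIO (wrapped or unwrapped, mixed case; record
ids up to the first whitespace; duplicate ids rejected).  TSV outputs are
UTF-8, tab-separated, '.' decimal; the typographic prime in M4′ is
serialized as the ASCII apostrophe (M4').
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import LocusSequence
from .synthetic_locus import normalize_name

FASTA_WRAP = 70


def read_fasta(path: str | Path) -> list[LocusSequence]:
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(LocusSequence(sample_id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Iterable[LocusSequence], path: str | Path) -> Path:
    path = Path(path)
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.sample_id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(seqrecords)
    return path


def write_sample_sheet(
    records: Iterable[LocusSequence], path: str | Path, with_truth: bool = True
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if with_truth:
            fh.write("sample_id\tregion\ttrue_haplotype\n")
        else:
            fh.write("sample_id\tregion\n")
        for r in records:
            cols = [r.sample_id, r.region or ""]
            if with_truth:
                cols.append(normalize_name(r.haplotype or ""))
            fh.write("\t".join(cols) + "\n")
    return path


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    if "sample_id" not in df.columns:
        raise ValueError(f"sample sheet {path} lacks a sample_id column")
    return df


def provenance_header(provenance: Mapping[str, object]) -> str:
    items = " ".join(f"{k}={v}" for k, v in sorted(provenance.items()))
    return f"# {items}\n"


def write_tsv(
    df: pd.DataFrame, path: str | Path, provenance: Mapping[str, object]
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(provenance))
        df.to_csv(fh, sep="\t", index=False)
    return path


def write_json(
    payload: dict, path: str | Path, provenance: Mapping[str, object]
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(
            {"provenance": dict(sorted(provenance.items())), **payload},
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return path
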