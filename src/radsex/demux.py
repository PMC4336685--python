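"""Demultiplex 90-nt RAD reads by inline 8-nt barcode.

A read is assigned to an individual iff its first 8 nt match that
individual's MID and the next five bases are the residual EcoRI motif
``AATTC``; the barcode is then stripped, leaving the 82-nt RAD tag read.
Everything else is counted in a discard log by reason.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .samples import Individual, validate_mids
from .simulate import AFTER_CUT, MID_LENGTH, READ_LENGTH, TAG_LENGTH

DISCARD_REASONS = (
    "unknown_barcode",
    "bad_restriction_site",
    "contains_N",
    "wrong_length",
)


@dataclass
class DemuxResult:
    """Per-individual 82-nt reads plus the accounting needed for audits."""

    reads: dict[str, list[str]]
    counts: pd.Series  # assigned reads per individual
    discards: Counter  # reason -> count
    total: int

    @property
    def assigned(self) -> int:
        return int(self.counts.sum())


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _near_matches(prefix: str, mids: dict[str, str]) -> list[str]:
    """Individuals whose MID is within Hamming distance 1 of ``prefix``."""
    hits = []
    for mid, ind in mids.items():
        if sum(a != b for a, b in zip(prefix, mid)) <= 1:
            hits.append(ind)
    return hits


def demultiplex(
    fastq_path: str | Path,
    sample_sheet: list[Individual],
    barcode_mismatch: int = 0,
) -> DemuxResult:
    """Assign reads to individuals and strip barcodes.

    barcode_mismatch=0 requires an exact MID match; 1 rescues reads whose
    barcode is a unique single-mismatch neighbour of exactly one MID
    (ambiguous rescues are discarded as unknown_barcode).
    """
    if barcode_mismatch not in (0, 1):
        raise ValueError("barcode_mismatch must be 0 or 1")
    validate_mids(sample_sheet)
    mid_to_ind = {i.mid: i.individual_id for i in sample_sheet}

    reads: dict[str, list[str]] = {i.individual_id: [] for i in sample_sheet}
    discards: Counter = Counter()
    total = 0

    with _open_maybe_gzip(fastq_path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                total += 1
                seq = str(rec.seq).upper()
                if len(seq) != READ_LENGTH:
                    discards["wrong_length"] += 1
                    continue
                if "N" in seq:
                    discards["contains_N"] += 1
                    continue
                prefix = seq[:MID_LENGTH]
                ind = mid_to_ind.get(prefix)
                if ind is None and barcode_mismatch == 1:
                    near = _near_matches(prefix, mid_to_ind)
                    if len(near) == 1:
                        ind = near[0]
                if ind is None:
                    discards["unknown_barcode"] += 1
                    continue
                tag = seq[MID_LENGTH:]
                if not tag.startswith(AFTER_CUT):
                    discards["bad_restriction_site"] += 1
                    continue
                assert len(tag) == TAG_LENGTH
                reads[ind].append(tag)
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record near record {total + 1}: {exc}"
            ) from exc

    counts = pd.Series(
        {i.individual_id: len(reads[i.individual_id]) for i in sample_sheet},
        name="assigned_reads",
    )
    assert int(counts.sum()) + sum(discards.values()) == total
    return DemuxResult(reads=reads, counts=counts, discards=discards, total=total)


def write_demuxed(result: DemuxResult, outdir: str | Path) -> None:
    """One FASTA per individual plus a TSV discard log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ind, seqs in result.reads.items():
        with open(outdir / f"{ind}.fasta", "w") as fh:
            for k, s in enumerate(seqs):
                fh.write(f">{ind}_{k}\n{s}\n")
    log = pd.DataFrame(
        [(r, result.discards.get(r, 0)) for r in DISCARD_REASONS],
        columns=["reason", "count"],
    )
    log.to_csv(outdir / "discards.tsv", sep="\t", index=False)
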