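"""Sequence and table I/O plus read quality control.

Reads enter the pipeline as FASTA or FASTQ (Phred+33); everything tabular
(cluster tables, depth histograms, genotype calls) is tab-separated text with
a single ``#``-prefixed header line, so outputs stay diff-able and
test-friendly.

Quality control mirrors the standard RAD pre-processing: discard reads with
ambiguous basecalls, too many low-quality positions, or a missing restriction
site at the read start; optionally head-trim to a fixed length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class FormatError(ValueError):
    """A sequence or table file could not be parsed."""


class QCConfigError(ValueError):
    """The QC policy is inconsistent with the input (e.g. quality filter on FASTA)."""


@dataclass
class ReadRecord:
    """One sequencing read.

    ``qualities`` holds per-base Phred scores and is ``None`` for FASTA input.
    """

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"read {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: {len(self.qualities)} quality values for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QCPolicy:
    """Read-discard rules, applied in the order N -> quality -> motif.

    Defaults follow common RAD practice: no ambiguous basecalls, at most 5
    positions below Q10, restriction-site motif required at the read start
    when set.
    """

    max_n_bases: int = 0
    low_quality_score: int | None = 10
    max_low_quality_positions: int = 5
    required_site_motif: str | None = None
    trim_length: int | None = None

    def __post_init__(self) -> None:
        if self.max_n_bases < 0 or self.max_low_quality_positions < 0:
            raise QCConfigError("QC thresholds must be non-negative")
        if self.trim_length is not None and self.trim_length <= 0:
            raise QCConfigError("trim_length must be positive")


def _detect_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("fasta", "fastq"):
            raise FormatError(f"unknown sequence format {fmt!r} (expected fasta or fastq)")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    raise FormatError(f"cannot infer format from {path!r}; pass format='fasta'|'fastq'")


def read_sequences(path: str | Path, format: str | None = None) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` objects from a FASTA/FASTQ file in file order.

    Nucleotides are uppercased; record IDs are preserved. Malformed records
    raise :class:`FormatError` naming the offending record.
    """
    fmt = _detect_format(path, format)
    index = 0
    try:
        for rec in SeqIO.parse(str(path), fmt):
            index += 1
            quals = None
            if fmt == "fastq":
                quals = list(rec.letter_annotations["phred_quality"])
            yield ReadRecord(id=rec.id, sequence=str(rec.seq).upper(), qualities=quals)
    except ValueError as exc:  # Biopython's parse error
        raise FormatError(f"{path}: record {index + 1}: {exc}") from exc


def write_sequences(records: Iterable[ReadRecord], path: str | Path,
                    format: str | None = None, default_quality: int = 40) -> int:
    """Write records as FASTA or FASTQ; returns the number written.

    Records lacking qualities get a uniform ``default_quality`` when writing
    FASTQ.
    """
    fmt = _detect_format(path, format)
    n = 0

    def _to_seqrecord(r: ReadRecord) -> SeqRecord:
        sr = SeqRecord(Seq(r.sequence), id=r.id, description="")
        if fmt == "fastq":
            quals = r.qualities if r.qualities is not None else [default_quality] * len(r)
            sr.letter_annotations["phred_quality"] = quals
        return sr

    with open(path, "w") as fh:
        for r in records:
            SeqIO.write(_to_seqrecord(r), fh, fmt)
            n += 1
    return n


def apply_qc(reads: Iterable[ReadRecord], policy: QCPolicy) -> tuple[list[ReadRecord], dict[str, int]]:
    """Filter reads by the policy; return kept reads and per-reason discard counts.

    A read is tested against the rules in a fixed order (ambiguous bases,
    low-quality positions, restriction-site motif) and reported under the
    first rule it fails, so ``kept + sum(report) == input`` always holds.
    Kept reads are head-trimmed to ``trim_length`` when set.
    """
    kept: list[ReadRecord] = []
    report: Counter[str] = Counter(n_bases=0, low_quality=0, no_site=0)
    for read in reads:
        if read.sequence.count("N") > policy.max_n_bases:
            report["n_bases"] += 1
            continue
        if policy.low_quality_score is not None:
            if read.qualities is None:
                raise QCConfigError(
                    "quality filter enabled but read has no qualities (FASTA input); "
                    "set low_quality_score=None"
                )
            n_low = sum(q < policy.low_quality_score for q in read.qualities)
            if n_low > policy.max_low_quality_positions:
                report["low_quality"] += 1
                continue
        if policy.required_site_motif is not None:
            if not read.sequence.startswith(policy.required_site_motif):
                report["no_site"] += 1
                continue
        if policy.trim_length is not None and len(read) > policy.trim_length:
            read = ReadRecord(
                id=read.id,
                sequence=read.sequence[: policy.trim_length],
                qualities=None if read.qualities is None else read.qualities[: policy.trim_length],
            )
        kept.append(read)
    return kept, dict(report)


# ---------------------------------------------------------------------------
# Tabular formats (TSV with one '#'-prefixed header line)
# ---------------------------------------------------------------------------

def _write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise FormatError(f"{path}: missing '#'-prefixed header line")
    names = first[1:].rstrip("\n").split("\t")
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=1, header=None, names=names)
    return df


def write_cluster_table(clusters, path: str | Path) -> None:
    """Write clusters as TSV: cluster_id, depth, consensus, then per-position A:C:G:T counts."""
    def rows():
        for c in clusters:
            pos_cols = [":".join(str(int(v)) for v in c.counts[p]) for p in range(c.length)]
            yield [c.cluster_id, c.depth, c.consensus, *pos_cols]

    first = next(iter(clusters), None)
    length = first.length if first is not None else 0
    header = ["cluster_id", "depth", "consensus", *[f"pos{p}" for p in range(length)]]
    _write_tsv(path, header, rows())


def read_cluster_table(path: str | Path):
    """Read a cluster table TSV back into :class:`radml.clustering.ReadCluster` objects.

    Member read IDs are not stored in the table and come back empty.
    """
    from .clustering import ReadCluster

    df = _read_tsv(path)
    clusters = []
    pos_cols = [c for c in df.columns if c.startswith("pos")]
    for _, row in df.iterrows():
        counts = np.array(
            [[int(v) for v in str(row[c]).split(":")] for c in pos_cols], dtype=np.int64
        )
        clusters.append(
            ReadCluster(
                cluster_id=int(row["cluster_id"]),
                member_read_ids=[],
                counts=counts,
                consensus=str(row["consensus"]),
                depth=int(row["depth"]),
            )
        )
    return clusters


def write_depth_histogram(depths: Sequence[int], path: str | Path) -> None:
    """Write a depth histogram TSV (columns: depth, n_clusters)."""
    vals, cnts = np.unique(np.asarray(depths, dtype=np.int64), return_counts=True)
    _write_tsv(path, ["depth", "n_clusters"], zip(vals.tolist(), cnts.tolist()))


def read_depth_histogram(path: str | Path) -> np.ndarray:
    """Read a depth histogram TSV and expand it back to a depth vector."""
    df = _read_tsv(path)
    return np.repeat(df["depth"].to_numpy(np.int64), df["n_clusters"].to_numpy(np.int64))


CALLS_COLUMNS = ["cluster_id", "position", "category", "allele1", "allele2",
                 "post_hom", "post_het", "post_und"]


def write_calls(calls_rows: Iterable[Sequence], path: str | Path) -> None:
    """Write genotype calls TSV; each row follows :data:`CALLS_COLUMNS`.

    Posteriors are printed with 6 significant digits.
    """
    def fmt(row):
        out = list(row[:5])
        out += [f"{float(x):.6g}" for x in row[5:8]]
        return out

    _write_tsv(path, CALLS_COLUMNS, (fmt(r) for r in calls_rows))


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a calls TSV into a DataFrame with :data:`CALLS_COLUMNS`."""
    df = _read_tsv(path)
    df["position"] = df["position"].astype(int)
    return df
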