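"""Readers and writers for the formats the pipeline touches.

All nucleotide sequences are normalized to an uppercase DNA alphabet at
parse time (``U`` -> ``T``), so downstream matching operates on a single
alphabet regardless of whether references were supplied as RNA or DNA.
FASTQ quality strings are interpreted as Sanger-encoded (Phred+33).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

RNA_CLASSES = ("miRNA", "tRNA", "rRNA", "mRNA", "piRNA", "other")

_NORMALIZE = str.maketrans("acgtunU", "ACGTTNT")


def normalize_seq(seq: str) -> str:
    """Uppercase a nucleotide string and convert U to T."""
    return seq.translate(_NORMALIZE)


@dataclass
class Read:
    """A single sequencing read: identifier, sequence, per-base qualities."""

    read_id: str
    seq: str
    qual: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceLibrary:
    """An ordered, named set of reference sequences of one sncRNA class.

    ``entries`` preserves FASTA input order; feature ids must be unique
    within a library. Optional per-feature metadata (e.g. the canonical
    mature interval of a miRNA entry carrying genomic flanks) lives in
    ``metadata`` keyed by feature id.
    """

    name: str
    rna_class: str
    entries: list[tuple[str, str]]
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {self.rna_class!r}")
        ids = [fid for fid, _ in self.entries]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate feature id {dup!r} in library {self.name!r}")
        for fid, s in self.entries:
            if not s:
                raise ValueError(f"empty sequence for feature {fid!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def sequence(self, feature_id: str) -> str:
        for fid, s in self.entries:
            if fid == feature_id:
                return s
        raise KeyError(feature_id)


@dataclass
class CountTable:
    """A feature x sample matrix of non-negative read counts.

    ``features`` is an ordered list of ``(feature_id, rna_class)`` pairs;
    ``counts`` has one row per feature and one column per sample. Raw
    tables are integer-valued; normalized tables may be real-valued.
    """

    features: list[tuple[str, str]]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative count in table")
        ids = [f for f, _ in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in count table")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names in count table")

    @property
    def feature_ids(self) -> list[str]:
        return [f for f, _ in self.features]

    def column(self, sample: str) -> np.ndarray:
        try:
            j = self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.samples)
        df.insert(0, "rna_class", [c for _, c in self.features])
        df.insert(0, "feature_id", self.feature_ids)
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.features == other.features
            and self.samples == other.samples
            and np.array_equal(self.counts, other.counts)
        )


class FastqParseError(ValueError):
    """Raised on malformed FASTQ input; message names the offending line."""


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream Reads from a (optionally gzipped) Sanger-encoded FASTQ file.

    Records are validated as they are read: a missing ``@`` / ``+`` marker,
    a sequence/quality length mismatch, or a truncated final record raises
    :class:`FastqParseError` naming the line number.
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(f"line {lineno}: expected '@', got {header[:20]!r}")
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqParseError(f"line {lineno}: truncated FASTQ record")
            lineno += 3
            seq = seq.rstrip("\n")
            qual = qual.rstrip("\n")
            if not plus.startswith("+"):
                raise FastqParseError(f"line {lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"line {lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield Read(
                read_id=(header[1:].split() or [""])[0],
                seq=normalize_seq(seq),
                qual=[ord(c) - 33 for c in qual],
            )


def write_fastq(reads, path: str | Path) -> int:
    """Write Reads as Sanger-encoded FASTQ; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in reads:
            q = "".join(chr(min(x, 93) + 33) for x in r.qual)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{q}\n")
            n += 1
    return n


def read_fasta(path: str | Path, rna_class: str, name: str | None = None) -> ReferenceLibrary:
    """Load one reference FASTA into a :class:`ReferenceLibrary`.

    The header token up to the first whitespace is the feature id. A
    ``canonical=START-END`` token elsewhere in the header marks the mature
    interval (0-based, half-open) of an entry that carries genomic flanks;
    it is stored in the library metadata for isomiR classification.
    """
    path = Path(path)
    entries: list[tuple[str, str]] = []
    metadata: dict[str, dict] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            fid = record.id
            seq = normalize_seq(str(record.seq))
            entries.append((fid, seq))
            for token in record.description.split()[1:]:
                if token.startswith("canonical="):
                    lo, hi = token[len("canonical="):].split("-")
                    metadata[fid] = {"canonical": (int(lo), int(hi))}
    if not entries:
        raise ValueError(f"empty FASTA file: {path}")
    return ReferenceLibrary(
        name=name or path.stem, rna_class=rna_class, entries=entries, metadata=metadata
    )


def write_fasta(library: ReferenceLibrary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for fid, seq in library.entries:
            meta = library.metadata.get(fid)
            if meta and "canonical" in meta:
                lo, hi = meta["canonical"]
                fh.write(f">{fid} canonical={lo}-{hi}\n")
            else:
                fh.write(f">{fid}\n")
            fh.write(seq + "\n")


# Count-table dialect: tab-separated; columns feature_id, rna_class, then one
# column per sample; '#'-prefixed lines are comments.

def write_count_table(table: CountTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("feature_id\trna_class\t" + "\t".join(table.samples) + "\n")
        integral = np.all(table.counts == np.round(table.counts))
        for (fid, cls), row in zip(table.features, table.counts):
            if integral:
                vals = "\t".join(str(int(v)) for v in row)
            else:
                vals = "\t".join(format(v, ".10g") for v in row)
            fh.write(f"{fid}\t{cls}\t{vals}\n")


def read_count_table(path: str | Path) -> CountTable:
    """Read the TSV count-table dialect; negative or non-numeric cells error."""
    features: list[tuple[str, str]] = []
    rows: list[list[float]] = []
    samples: list[str] | None = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if samples is None:
                if parts[:2] != ["feature_id", "rna_class"]:
                    raise ValueError(
                        f"line {lineno}: expected header starting "
                        "'feature_id\\trna_class', got " + repr(parts[:2])
                    )
                samples = parts[2:]
                continue
            if len(parts) != 2 + len(samples):
                raise ValueError(f"line {lineno}: expected {2 + len(samples)} columns")
            try:
                vals = [float(v) for v in parts[2:]]
            except ValueError:
                raise ValueError(f"line {lineno}: non-numeric count") from None
            if any(v < 0 for v in vals):
                raise ValueError(f"line {lineno}: negative count")
            features.append((parts[0], parts[1]))
            rows.append(vals)
    if samples is None:
        raise ValueError(f"empty count table: {path}")
    counts = np.array(rows, dtype=float) if rows else np.empty((0, len(samples)))
    return CountTable(features=features, samples=samples, counts=counts)
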