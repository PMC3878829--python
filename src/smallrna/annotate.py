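"""Hierarchical sncRNA annotation: map collapsed reads against ordered
reference libraries in a first-match cascade, count per feature, classify
miRNA reads into isomiR categories, and report unassigned reads.

The cascade mirrors the column structure of a per-class read-count summary
(miRNA, tRNA, rRNA, mRNA, piRNA, other): a sequence is tested against the
libraries in priority order and assigned, with its full multiplicity, to
the first library in which it has at least one hit; it is never tested
against later libraries. This first-match rule is what limits cross-mapping
between classes (e.g. a miRNA-identical read is never counted as a piRNA).

Matching is substitution-only (Hamming): a read hits a reference if it
occurs as a substring with at most ``m`` mismatches. 'N' bases never match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core_io import CountTable, ReferenceLibrary

DEFAULT_MISMATCHES: dict[str, int] = {
    "miRNA": 0,
    "tRNA": 1,
    "rRNA": 1,
    "mRNA": 1,
    "piRNA": 0,
    "other": 1,
}

ISOMIR_CLASSES = ("canonical", "5p_shift", "3p_shift", "both_shift", "not_applicable")

# base encoding: read 'N' (5) never equals reference 'N' (4)
_REF_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_QUERY_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 5}


@dataclass
class CascadeConfig:
    """Ordered libraries plus per-library mismatch allowances."""

    libraries: list[ReferenceLibrary]
    max_mismatches: Mapping[str, int] | int = field(default_factory=lambda: dict(DEFAULT_MISMATCHES))

    def __post_init__(self) -> None:
        if not self.libraries:
            raise ValueError("cascade requires at least one reference library")

    def mismatches_for(self, library: ReferenceLibrary) -> int:
        if isinstance(self.max_mismatches, int):
            return self.max_mismatches
        return self.max_mismatches.get(library.rna_class, 0)


@dataclass
class AnnotationAssignment:
    seq: str
    multiplicity: int
    rna_class: str
    feature_id: str
    start_offset: int
    mismatches: int
    isomir_class: str = "not_applicable"


@dataclass
class AnnotationSummary:
    """Per-class read totals; classes plus unassigned partition the input."""

    class_totals: dict[str, int]
    unassigned: int
    total: int

    def validate(self) -> None:
        assert sum(self.class_totals.values()) + self.unassigned == self.total

    def to_tsv(self, sample: str = "sample") -> str:
        classes = list(self.class_totals)
        header = "sample\ttotal_reads\t" + "\t".join(f"{c}_reads" for c in classes) + "\tunassigned"
        vals = [sample, str(self.total)] + [str(self.class_totals[c]) for c in classes]
        vals.append(str(self.unassigned))
        return header + "\n" + "\t".join(vals) + "\n"


class MismatchIndex:
    """Substring index over one library supporting Hamming-distance queries.

    Seed-and-verify: a query allowed ``m`` substitutions is split into
    ``m + 1`` chunks, at least one of which must match a reference exactly
    (pigeonhole; 'N' never matches, so a chunk containing 'N' can never be
    the exact one and is skipped). Exact chunk occurrences are located via
    per-length substring hash tables built lazily over the concatenated
    references, and each candidate placement is verified by a full
    mismatch count. Windows crossing reference boundaries are rejected by
    coordinate arithmetic.
    """

    def __init__(self, library: ReferenceLibrary):
        if not library.entries:
            raise ValueError(f"empty library {library.name!r}")
        self.library = library
        seqs = [s for _, s in library.entries]
        self._text = "".join(seqs)
        # recode to small ints so 'N' semantics are explicit
        raw = np.frombuffer(self._text.encode("ascii"), dtype=np.uint8)
        coded = np.full(raw.size, 4, dtype=np.int8)
        for base, code in _REF_CODE.items():
            coded[raw == ord(base)] = code
        self._coded = coded
        lengths = np.array([len(s) for s in seqs])
        self._starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        self._ends = np.cumsum(lengths)
        self._max_len = int(lengths.max())
        self._substr_cache: dict[int, dict[str, list[int]]] = {}

    def _substring_positions(self, length: int) -> dict[str, list[int]]:
        cached = self._substr_cache.get(length)
        if cached is not None:
            return cached
        table: dict[str, list[int]] = {}
        text = self._text
        for start, end in zip(self._starts, self._ends):
            for p in range(int(start), int(end) - length + 1):
                table.setdefault(text[p : p + length], []).append(p)
        self._substr_cache[length] = table
        return table

    def query(self, seq: str, max_mismatches: int) -> list[tuple[int, int, int]]:
        """All occurrences of ``seq`` with <= max_mismatches substitutions.

        Returns (entry_index, start_offset, mismatches) tuples; 'N' in
        either read or reference counts as a mismatch.
        """
        k = len(seq)
        if k == 0 or k > self._max_len or k <= max_mismatches:
            return []
        n_chunks = max_mismatches + 1
        bounds = np.linspace(0, k, n_chunks + 1).astype(int)
        candidates: set[int] = set()
        for c_start, c_end in zip(bounds[:-1], bounds[1:]):
            chunk = seq[c_start:c_end]
            if "N" in chunk:
                continue
            for p in self._substring_positions(c_end - c_start).get(chunk, ()):
                g = p - c_start
                if g >= 0:
                    candidates.add(g)
        if not candidates:
            return []
        q = np.array([_QUERY_CODE.get(b, 5) for b in seq], dtype=np.int8)
        out = []
        for g in sorted(candidates):
            entry = int(np.searchsorted(self._starts, g, side="right")) - 1
            if g + k > self._ends[entry]:
                continue
            mm = int((self._coded[g : g + k] != q).sum())
            if mm <= max_mismatches:
                out.append((entry, int(g - self._starts[entry]), mm))
        return out


def build_index(library: ReferenceLibrary) -> MismatchIndex:
    return MismatchIndex(library)


def map_read(seq: str, index: MismatchIndex, max_mismatches: int) -> list[tuple[str, int, int]]:
    """All hits of a read in a library, sorted by (mismatches, entry order,
    start offset); empty list when the read maps nowhere."""
    hits = index.query(seq, max_mismatches)
    hits.sort(key=lambda h: (h[2], h[0], h[1]))
    return [(index.library.entries[e][0], off, mm) for e, off, mm in hits]


def classify_isomir(
    seq: str,
    start_offset: int,
    reference_seq: str,
    canonical: tuple[int, int] | None = None,
) -> str:
    """Classify a miRNA-mapped read by 5'/3' end position vs the canonical
    mature sequence.

    ``canonical`` is the mature interval within the reference entry
    (0-based, half-open) when the entry carries genomic flanks; without it
    the whole entry is the mature sequence. A read identical to the
    canonical sequence is canonical; a read whose 5' (only) or 3' (only)
    end position differs is a 5p/3p shift; anything else is both_shift.
    """
    lo, hi = canonical if canonical is not None else (0, len(reference_seq))
    read_lo = start_offset
    read_hi = start_offset + len(seq)
    if read_lo == lo and read_hi == hi and seq == reference_seq[lo:hi]:
        return "canonical"
    if read_lo == lo and read_hi != hi:
        return "3p_shift"
    if read_lo != lo and read_hi == hi:
        return "5p_shift"
    return "both_shift"


def cascade_annotate(
    collapsed: Mapping[str, int],
    config: CascadeConfig,
    sample: str = "sample",
) -> tuple[CountTable, list[AnnotationAssignment], AnnotationSummary]:
    """Assign collapsed reads through the library cascade.

    Returns the per-feature count table (one column, named ``sample``), the
    per-sequence assignments, and the per-class summary. Multi-mapping
    within a library is resolved to the single best hit under map_read's
    ordering; counts stay integral.
    """
    indexes = [build_index(lib) for lib in config.libraries]
    assignments: list[AnnotationAssignment] = []
    feature_counts: dict[tuple[str, str], int] = {}
    class_totals: dict[str, int] = {lib.rna_class: 0 for lib in config.libraries}
    unassigned = 0
    total = 0

    for seq, mult in collapsed.items():
        total += mult
        assigned = False
        for lib, index in zip(config.libraries, indexes):
            hits = map_read(seq, index, config.mismatches_for(lib))
            if not hits:
                continue
            feature_id, offset, mm = hits[0]
            isomir = "not_applicable"
            if lib.rna_class == "miRNA":
                ref_seq = lib.sequence(feature_id)
                canonical = lib.metadata.get(feature_id, {}).get("canonical")
                isomir = classify_isomir(seq, offset, ref_seq, canonical)
            assignments.append(
                AnnotationAssignment(
                    seq=seq,
                    multiplicity=mult,
                    rna_class=lib.rna_class,
                    feature_id=feature_id,
                    start_offset=offset,
                    mismatches=mm,
                    isomir_class=isomir,
                )
            )
            key = (feature_id, lib.rna_class)
            feature_counts[key] = feature_counts.get(key, 0) + mult
            class_totals[lib.rna_class] += mult
            assigned = True
            break
        if not assigned:
            unassigned += mult

    # feature rows in library order so output is deterministic
    features: list[tuple[str, str]] = []
    counts: list[int] = []
    for lib in config.libraries:
        for fid, _ in lib.entries:
            key = (fid, lib.rna_class)
            if key in feature_counts:
                features.append(key)
                counts.append(feature_counts[key])
    table = CountTable(
        features=features,
        samples=[sample],
        counts=np.array(counts, dtype=float).reshape(-1, 1),
    )
    summary = AnnotationSummary(class_totals=class_totals, unassigned=unassigned, total=total)
    summary.validate()
    return table, assignments, summary


def merge_count_tables(tables: list[CountTable]) -> CountTable:
    """Outer-join single-sample tables into one multi-sample table (absent
    features get count 0)."""
    if not tables:
        raise ValueError("no tables to merge")
    features: list[tuple[str, str]] = []
    seen = set()
    for t in tables:
        for f in t.features:
            if f not in seen:
                seen.add(f)
                features.append(f)
    samples = [s for t in tables for s in t.samples]
    counts = np.zeros((len(features), len(samples)))
    row = {f: i for i, f in enumerate(features)}
    j = 0
    for t in tables:
        for f, r in zip(t.features, t.counts):
            counts[row[f], j : j + len(t.samples)] = r
        j += len(t.samples)
    return CountTable(features=features, samples=samples, counts=counts)
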