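"""Read pre-processing: 3' adapter cleavage, quality and length filtering,
read collapsing, and read-length distribution reporting.

Adapter matching is error-tolerant semi-global alignment, following the
semantics of standard 3'-adapter trimmers: a candidate match is either the
full adapter occurring inside the read, or a prefix of the adapter hanging
off the read's 3' end. Errors are unit-cost edits (substitutions and
indels); a candidate matching ``L`` adapter bases with ``E`` errors is
admissible iff ``L >= min_overlap`` and ``E <= floor(error_rate * L)``.
Everything from the match start to the end of the read is removed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .core_io import Read

DEFAULT_MIN_LENGTH = 15
DEFAULT_MIN_QUALITY = 20
DEFAULT_ERROR_RATE = 0.1
DEFAULT_MIN_OVERLAP = 3


@dataclass
class AdapterSpec:
    """3' adapter search parameters.

    Multiple adapters are searched jointly per read; ties between equally
    good matches are broken by 5'-most start, then adapter list order.
    """

    adapters: list[str]
    max_error_rate: float = DEFAULT_ERROR_RATE
    min_overlap: int = DEFAULT_MIN_OVERLAP

    def __post_init__(self) -> None:
        if not self.adapters:
            raise ValueError("at least one adapter sequence required")
        for a in self.adapters:
            if not a or set(a) - set("ACGT"):
                raise ValueError(f"adapter must be a non-empty ACGT string: {a!r}")
        if not 0 <= self.max_error_rate < 1:
            raise ValueError("max_error_rate must be in [0, 1)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass
class TrimResult:
    read: Read
    adapter_found: bool
    trimmed_bases: int = 0
    errors_in_match: int = 0


@dataclass
class PreprocessReport:
    """Per-sample accounting: input reads partition exactly into kept,
    discarded-short and discarded-low-quality; the length histogram covers
    kept (post-trimming) reads only."""

    n_input: int = 0
    n_kept: int = 0
    n_discarded_short: int = 0
    n_discarded_quality: int = 0
    length_histogram: Counter = field(default_factory=Counter)

    def validate(self) -> None:
        assert self.n_input == self.n_kept + self.n_discarded_short + self.n_discarded_quality
        assert sum(self.length_histogram.values()) == self.n_kept

    def to_tsv(self) -> str:
        lines = [
            f"# n_input\t{self.n_input}",
            f"# n_kept\t{self.n_kept}",
            f"# n_discarded_short\t{self.n_discarded_short}",
            f"# n_discarded_quality\t{self.n_discarded_quality}",
            "length\tcount",
        ]
        for length in sorted(self.length_histogram):
            lines.append(f"{length}\t{self.length_histogram[length]}")
        return "\n".join(lines) + "\n"


def _exact_candidates(seq: str, adapter: str, min_overlap: int) -> int | None:
    """5'-most start of any zero-error candidate, or None.

    Zero-error candidates are exact internal occurrences of the whole
    adapter and exact adapter prefixes (length >= min_overlap) flush with
    the read's 3' end. Zero errors are always admissible, so when one
    exists the search reduces to picking the leftmost.
    """
    best: int | None = None
    if len(adapter) >= min_overlap:
        pos = seq.find(adapter)
        if pos != -1:
            best = pos
    n = len(seq)
    max_l = min(len(adapter) - 1, n)
    for length in range(max_l, min_overlap - 1, -1):
        start = n - length
        if (best is None or start < best) and seq.endswith(adapter[:length], start):
            best = start
        elif best is not None and start >= best:
            break
    return best


def _align_adapter(seq: str, adapter: str, error_rate: float, min_overlap: int):
    """Best admissible semi-global match of ``adapter`` in ``seq``.

    Returns ``(errors, start)`` minimizing errors then start, or None.
    The DP computes, for every adapter prefix length i and read position j,
    the minimum edit distance of ``adapter[:i]`` vs ``read[s:j]`` over all
    starts s, together with the smallest s achieving it; candidate cells
    are (i == len(adapter), any j) for internal matches and
    (i >= min_overlap, j == len(read)) for matches running off the 3' end.
    """
    n, m = len(seq), len(adapter)
    # cost[j], start[j] for current adapter prefix row
    cost = [0] * (n + 1)
    start = list(range(n + 1))
    best: tuple[int, int] | None = None

    def consider(e: int, s: int, matched_len: int) -> None:
        nonlocal best
        if matched_len >= min_overlap and e <= int(error_rate * matched_len):
            if best is None or (e, s) < best:
                best = (e, s)

    for i in range(1, m + 1):
        a = adapter[i - 1]
        prev_cost, prev_start = cost, start
        cost = [i] + [0] * n
        start = [0] * (n + 1)
        for j in range(1, n + 1):
            # diagonal: match/mismatch ('N' mismatches everything)
            c = prev_cost[j - 1] + (0 if seq[j - 1] == a and a != "N" and seq[j - 1] != "N" else 1)
            s = prev_start[j - 1]
            # up: adapter base unmatched (deletion in read)
            cu, su = prev_cost[j] + 1, prev_start[j]
            if (cu, su) < (c, s):
                c, s = cu, su
            # left: extra read base inside the match (insertion)
            cl, sl = cost[j - 1] + 1, start[j - 1]
            if (cl, sl) < (c, s):
                c, s = cl, sl
            cost[j], start[j] = c, s
        if i == m:
            for j in range(n + 1):
                consider(cost[j], start[j], m)
        elif i >= min_overlap:
            consider(cost[n], start[n], i)
    return best


def trim_adapter(read: Read, spec: AdapterSpec) -> TrimResult:
    """Remove the best-matching 3' adapter occurrence from a read.

    Among admissible candidates over all adapters the winner has minimal
    error count, then 5'-most start, then earliest adapter in list order;
    the read is cut at the match start and the quality string truncated in
    lockstep. No admissible match leaves the read unchanged.
    """
    best: tuple[int, int, int] | None = None  # (errors, start, adapter_index)
    for k, adapter in enumerate(spec.adapters):
        exact = _exact_candidates(read.seq, adapter, spec.min_overlap)
        if exact is not None:
            cand = (0, exact, k)
        else:
            if spec.max_error_rate == 0:
                continue
            hit = _align_adapter(read.seq, adapter, spec.max_error_rate, spec.min_overlap)
            if hit is None:
                continue
            cand = (hit[0], hit[1], k)
        if best is None or cand < best:
            best = cand
    if best is None:
        return TrimResult(read=read, adapter_found=False)
    errors, cut, _ = best
    return TrimResult(
        read=Read(read.read_id, read.seq[:cut], list(read.qual[:cut])),
        adapter_found=True,
        trimmed_bases=len(read.seq) - cut,
        errors_in_match=errors,
    )


def quality_filter(read: Read, min_mean_q: int = DEFAULT_MIN_QUALITY) -> bool:
    """Keep a read iff its mean base quality is >= the threshold (inclusive)."""
    if len(read.qual) == 0:
        return False
    return sum(read.qual) / len(read.qual) >= min_mean_q


def length_filter(read: Read, min_len: int = DEFAULT_MIN_LENGTH) -> bool:
    """Keep a read iff it is at least ``min_len`` nucleotides long."""
    return len(read) >= min_len


def collapse_reads(reads: Iterable[Read | str]) -> Counter:
    """Collapse reads to a sequence -> multiplicity map."""
    counts: Counter = Counter()
    for r in reads:
        counts[r if isinstance(r, str) else r.seq] += 1
    return counts


def length_distribution(reads: Iterable[Read | str]) -> Counter:
    """Histogram of read lengths."""
    hist: Counter = Counter()
    for r in reads:
        hist[len(r)] += 1
    return hist


def preprocess_reads(
    reads: Iterable[Read],
    spec: AdapterSpec,
    min_len: int = DEFAULT_MIN_LENGTH,
    min_mean_q: int = DEFAULT_MIN_QUALITY,
) -> tuple[Iterator[Read], PreprocessReport]:
    """Trim + filter a read stream; returns (kept reads, report).

    The report is filled in as the returned iterator is consumed.
    """
    report = PreprocessReport()

    def gen() -> Iterator[Read]:
        for read in reads:
            report.n_input += 1
            trimmed = trim_adapter(read, spec).read
            if not length_filter(trimmed, min_len):
                report.n_discarded_short += 1
                continue
            if not quality_filter(trimmed, min_mean_q):
                report.n_discarded_quality += 1
                continue
            report.n_kept += 1
            report.length_histogram[len(trimmed)] += 1
            yield trimmed

    return gen(), report


def run_preprocess(
    in_fastq: str | Path,
    out_fastq: str | Path,
    spec: AdapterSpec,
    min_len: int = DEFAULT_MIN_LENGTH,
    min_mean_q: int = DEFAULT_MIN_QUALITY,
    report_path: str | Path | None = None,
) -> PreprocessReport:
    """File-to-file trimming driver used by the CLI."""
    from .core_io import read_fastq, write_fastq

    kept, report = preprocess_reads(read_fastq(in_fastq), spec, min_len, min_mean_q)
    write_fastq(kept, out_fastq)
    report.validate()
    if report_path is not None:
        Path(report_path).write_text(report.to_tsv(), encoding="utf-8")
    return report
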