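"""Synthetic small-RNA-seq data with known ground truth.

The generator emulates a single-end small RNA sequencing library: each
read is a sncRNA fragment (a whole mature miRNA or piRNA, or a fragment of
a longer tRNA/rRNA/mRNA/other reference) followed by the 3' sequencing
adapter, truncated to the machine read length, with independent per-base
substitution errors. Reads are drawn from a configurable class composition
(defaults shaped like a miRNA-dominated library: the majority of inserts
are ~22 nt miRNAs, with a piRNA shoulder at 26-31 nt) plus a fraction of
unassignable background reads of uniform random sequence, which exercise
the "reads not assigned" path of the annotation cascade.

All randomness flows from one integer seed; the same profile and seed
reproduce byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import CountTable, Read, ReferenceLibrary

# Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

DEFAULT_CLASS_FRACTIONS = {
    # miRNA-dominated composition; the remainder (0.25) is unassignable
    # background standing in for genomic/degradation reads
    "miRNA": 0.55,
    "tRNA": 0.01,
    "rRNA": 0.03,
    "mRNA": 0.10,
    "piRNA": 0.01,
    "other": 0.05,
}

DEFAULT_FEATURES_PER_CLASS = {
    # library sizes on the order of what a deeply sequenced breast-cancer
    # cell line yields: ~450 mature miRNAs, tens of tRNA/piRNA species,
    # a few rRNAs, a few hundred mRNA fragments
    "miRNA": 450,
    "tRNA": 50,
    "rRNA": 4,
    "mRNA": 300,
    "piRNA": 80,
    "other": 20,
}

# reference lengths typical of each class (scaled-down rRNA/mRNA)
_REF_LENGTHS = {"tRNA": (70, 80), "rRNA": (120, 160), "mRNA": (150, 250),
                "piRNA": (26, 31), "other": (80, 120)}

DEFAULT_MATURE_LENGTHS = {20: 0.10, 21: 0.20, 22: 0.50, 23: 0.15, 24: 0.05}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimProfile:
    """Study conditions for one simulated library."""

    rng_seed: int = 0
    n_reads: int = 50_000
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    features_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FEATURES_PER_CLASS)
    )
    adapter: str = DEFAULT_ADAPTER
    read_error_rate: float = 0.001
    read_length: int = 40
    mature_length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MATURE_LENGTHS)
    )
    abundance_sigma: float = 1.0  # log-normal spread of feature abundances

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if total > 1 + 1e-9:
            raise ValueError("class fractions must sum to <= 1")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be >= 0")
        if not 0 <= self.read_error_rate <= 0.2:
            raise ValueError("read_error_rate must be in [0, 0.2]")

    @property
    def background_fraction(self) -> float:
        return max(0.0, 1.0 - sum(self.class_fractions.values()))


@dataclass
class GroundTruth:
    """True per-read and per-feature composition of a simulated FASTQ."""

    read_assignments: list[tuple[str, str, str]]  # (read_id, class, feature or "")
    feature_counts: dict[tuple[str, str], int]  # (feature_id, class) -> count
    n_background: int
    condition_effects: dict[str, float]

    def validate(self, n_reads: int) -> None:
        assert sum(self.feature_counts.values()) + self.n_background == n_reads


def _rng(profile: SimProfile, stream: int) -> np.random.Generator:
    return np.random.default_rng([profile.rng_seed & 0x7FFFFFFF, stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def _hamming_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    return sum(1 for i in range(n) if a[i] != b[i])


def simulate_references(profile: SimProfile) -> dict[str, ReferenceLibrary]:
    """Random reference libraries with class-typical lengths.

    miRNAs are rejection-sampled so every pair differs at >= 3 positions
    over their common prefix, keeping cascade assignment unambiguous at
    mismatch allowances <= 1.
    """
    rng = _rng(profile, 1)
    libraries: dict[str, ReferenceLibrary] = {}
    mature_lengths = sorted(profile.mature_length_distribution)
    mature_probs = np.array([profile.mature_length_distribution[k] for k in mature_lengths])
    mature_probs = mature_probs / mature_probs.sum()

    for cls, n in profile.features_per_class.items():
        if n <= 0:
            continue
        entries: list[tuple[str, str]] = []
        seqs: list[str] = []
        while len(entries) < n:
            if cls == "miRNA":
                length = int(rng.choice(mature_lengths, p=mature_probs))
            else:
                lo, hi = _REF_LENGTHS[cls]
                length = int(rng.integers(lo, hi + 1))
            seq = _random_seq(rng, length)
            if cls == "miRNA" and any(_hamming_prefix(seq, s) < 3 for s in seqs):
                continue
            if seq in seqs:
                continue
            seqs.append(seq)
            entries.append((f"sim-{cls}-{len(entries) + 1:03d}", seq))
        libraries[cls] = ReferenceLibrary(name=f"sim_{cls}", rna_class=cls, entries=entries)
    return libraries


def simulate_abundances(
    profile: SimProfile, libraries: Mapping[str, ReferenceLibrary]
) -> dict[str, dict[str, float]]:
    """Log-normal relative abundances per class (normalized to sum to 1)."""
    rng = _rng(profile, 2)
    abundances: dict[str, dict[str, float]] = {}
    for cls, lib in libraries.items():
        w = rng.lognormal(mean=0.0, sigma=profile.abundance_sigma, size=len(lib.entries))
        w = w / w.sum()
        abundances[cls] = {fid: float(x) for (fid, _), x in zip(lib.entries, w)}
    return abundances


def _feature_probs(
    profile: SimProfile,
    abundances: Mapping[str, Mapping[str, float]],
    condition_effects: Mapping[str, float],
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Flatten (class fraction x feature abundance x effect multiplier) into
    one probability vector over (feature, class) plus a background slot."""
    keys: list[tuple[str, str]] = []
    w: list[float] = []
    for cls, frac in profile.class_fractions.items():
        if cls not in abundances or frac <= 0:
            continue
        for fid, ab in abundances[cls].items():
            keys.append((fid, cls))
            w.append(frac * ab * condition_effects.get(fid, 1.0))
    keys.append(("", "background"))
    w.append(profile.background_fraction)
    probs = np.asarray(w)
    return keys, probs / probs.sum()


def simulate_reads(
    profile: SimProfile,
    libraries: Mapping[str, ReferenceLibrary],
    abundances: Mapping[str, Mapping[str, float]] | None = None,
    condition_effects: Mapping[str, float] | None = None,
    sample_name: str = "sim",
    stream: int = 3,
) -> tuple[list[Read], GroundTruth]:
    """Draw a full synthetic FASTQ library plus its ground truth.

    ``condition_effects`` multiplies the expected abundance of selected
    features (e.g. ``{"sim-miRNA-001": 4.0}``) before renormalization,
    emulating differential expression between conditions; pass a distinct
    ``stream`` per sample so conditions are independent draws.
    """
    if abundances is None:
        abundances = simulate_abundances(profile, libraries)
    condition_effects = dict(condition_effects or {})
    rng = _rng(profile, stream)
    keys, probs = _feature_probs(profile, abundances, condition_effects)
    seq_by_key = {
        (fid, cls): seq
        for cls, lib in libraries.items()
        for fid, seq in lib.entries
    }
    choice = rng.choice(len(keys), size=profile.n_reads, p=probs)

    reads: list[Read] = []
    assignments: list[tuple[str, str, str]] = []
    feature_counts: dict[tuple[str, str], int] = {}
    n_background = 0
    for i, ki in enumerate(choice):
        fid, cls = keys[ki]
        if cls == "background":
            insert = _random_seq(rng, int(rng.integers(18, 31)))
            n_background += 1
        elif cls in ("miRNA", "piRNA"):
            insert = seq_by_key[(fid, cls)]
        else:
            ref = seq_by_key[(fid, cls)]
            frag_len = int(rng.integers(18, 33))
            start = int(rng.integers(0, len(ref) - frag_len + 1))
            insert = ref[start : start + frag_len]
        if cls != "background":
            feature_counts[(fid, cls)] = feature_counts.get((fid, cls), 0) + 1
        seq = (insert + profile.adapter)[: profile.read_length]
        if profile.read_error_rate > 0:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            hit = np.nonzero(rng.random(arr.size) < profile.read_error_rate)[0]
            for p in hit:
                arr[p] = _BASES[(np.searchsorted(_BASES, arr[p]) + int(rng.integers(1, 4))) % 4]
            seq = bytes(arr).decode("ascii")
        qual = rng.integers(32, 41, size=len(seq)).tolist()
        read_id = f"{sample_name}:{i + 1}"
        reads.append(Read(read_id=read_id, seq=seq, qual=qual))
        assignments.append((read_id, cls, fid))
    truth = GroundTruth(
        read_assignments=assignments,
        feature_counts=feature_counts,
        n_background=n_background,
        condition_effects=condition_effects,
    )
    truth.validate(profile.n_reads)
    return reads, truth


def pick_condition_effects(
    profile: SimProfile,
    library: ReferenceLibrary,
    fraction: float = 0.1,
    fold: float = 4.0,
) -> dict[str, float]:
    """Mark a deterministic fraction of a library's features as perturbed,
    half up (x fold) and half down (/ fold)."""
    rng = _rng(profile, 4)
    ids = [fid for fid, _ in library.entries]
    n = max(1, round(fraction * len(ids)))
    chosen = list(rng.choice(ids, size=n, replace=False))
    effects: dict[str, float] = {}
    for i, fid in enumerate(chosen):
        effects[fid] = fold if i % 2 == 0 else 1.0 / fold
    return effects


def simulate_count_table(
    profile: SimProfile,
    libraries: Mapping[str, ReferenceLibrary],
    abundances: Mapping[str, Mapping[str, float]] | None = None,
    condition_effects: Mapping[str, float] | None = None,
    sample_names: Sequence[str] = ("test", "control"),
    effects_apply_to: str = "test",
) -> CountTable:
    """Draw per-feature counts directly (no reads): one multinomial draw of
    ``n_reads`` assigned reads per sample, with condition effects applied to
    the designated sample only. Background is excluded — this is the table
    the annotation stage would produce, without the sequencing detour."""
    if abundances is None:
        abundances = simulate_abundances(profile, libraries)
    condition_effects = dict(condition_effects or {})
    features: list[tuple[str, str]] = []
    base_w: list[float] = []
    for cls, lib in libraries.items():
        frac = profile.class_fractions.get(cls, 0.0)
        if frac <= 0:
            continue
        for fid, _ in lib.entries:
            features.append((fid, cls))
            base_w.append(frac * abundances[cls][fid])
    cols = []
    for s_idx, sample in enumerate(sample_names):
        rng = _rng(profile, 10 + s_idx)
        w = np.asarray(base_w, dtype=float)
        if sample == effects_apply_to:
            mult = np.array([condition_effects.get(fid, 1.0) for fid, _ in features])
            w = w * mult
        cols.append(rng.multinomial(profile.n_reads, w / w.sum()))
    return CountTable(
        features=features,
        samples=list(sample_names),
        counts=np.column_stack(cols).astype(float),
    )
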