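"""Independent brute-force oracles used to validate the optimized
implementations. Each oracle is a direct transcription of the operation's
definition — full enumeration, exact arithmetic where possible — and shares
no code with the library paths it checks."""

from __future__ import annotations

from fractions import Fraction
from math import comb


def levenshtein_table(a: str, b: str) -> list[list[int]]:
    """Full unit-cost edit-distance DP table; dp[i][j] is the distance
    between a[:i] and b[:j]. 'N' mismatches everything."""
    la, lb = len(a), len(b)
    dp = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        dp[i][0] = i
    for j in range(lb + 1):
        dp[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            same = a[i - 1] == b[j - 1] and a[i - 1] != "N" and b[j - 1] != "N"
            dp[i][j] = min(
                dp[i - 1][j - 1] + (0 if same else 1),
                dp[i - 1][j] + 1,
                dp[i][j - 1] + 1,
            )
    return dp


def trim_oracle(seq: str, adapters: list[str], error_rate: float, min_overlap: int):
    """Enumerate every (adapter, start, matched-length) candidate.

    A candidate is the full adapter aligned to any read substring
    read[s:t], or an adapter prefix of length L < len(adapter) aligned to
    the read suffix read[s:]; it is admissible iff the matched adapter
    length L satisfies L >= min_overlap and its edit distance E satisfies
    E <= floor(error_rate * L). Returns the winning (errors, start,
    adapter_index) under (min errors, 5'-most start, adapter order), or
    None when nothing is admissible.
    """
    n = len(seq)
    best = None
    for k, adapter in enumerate(adapters):
        m = len(adapter)
        for s in range(n + 1):
            dp = levenshtein_table(adapter, seq[s:])
            if m >= min_overlap:
                allowed = int(error_rate * m)
                for t in range(s, n + 1):
                    e = dp[m][t - s]
                    if e <= allowed:
                        cand = (e, s, k)
                        if best is None or cand < best:
                            best = cand
            for length in range(min_overlap, m):
                e = dp[length][n - s]
                if e <= int(error_rate * length):
                    cand = (e, s, k)
                    if best is None or cand < best:
                        best = cand
    return best


def hamming_scan_oracle(seq: str, references: list[tuple[str, str]], max_mm: int):
    """All (feature_id, offset, mismatches) occurrences of seq as a
    substring of any reference with <= max_mm substitutions, by scanning
    every position of every reference. 'N' never matches."""
    hits = []
    k = len(seq)
    for entry_idx, (fid, ref) in enumerate(references):
        for start in range(len(ref) - k + 1):
            mm = sum(
                1
                for i in range(k)
                if seq[i] != ref[start + i] or seq[i] == "N" or ref[start + i] == "N"
            )
            if mm <= max_mm:
                hits.append((entry_idx, fid, start, mm))
    hits.sort(key=lambda h: (h[3], h[0], h[2]))
    return [(fid, start, mm) for _, fid, start, mm in hits]


def fisher_two_sided_oracle(a: int, b: int, n_test: int, n_control: int) -> float:
    """Two-sided Fisher p by exact rational hypergeometric enumeration.

    With margins fixed, the table is determined by the count x drawn from
    the test column; P(x) = C(n_test, x) C(n_control, n-x) / C(N, n). The
    two-sided p sums P(x) over all x whose probability does not exceed the
    observed table's. All arithmetic is exact (fractions), so ties are
    compared exactly.
    """
    n = a + b
    total = comb(n_test + n_control, n)
    pmf = {}
    for x in range(max(0, n - n_control), min(n, n_test) + 1):
        pmf[x] = Fraction(comb(n_test, x) * comb(n_control, n - x), total)
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


def bh_oracle(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up by direct definition."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_from_end in range(n, 0, -1):
        i = order[rank_from_end - 1]
        val = min(1.0, pvalues[i] * n / rank_from_end)
        running_min = min(running_min, val)
        adjusted[i] = running_min
    return adjusted


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def seed_sites_oracle(utr: str, mirna: str):
    """Naive three-motif scan with subsumption.

    Builds the 8mer / 7mer-m8 / 7mer-A1 motifs from the miRNA seed by
    hand, scans every UTR position for each, then drops matches subsumed
    by a stronger type at the same locus: a 7mer-m8 at p is subsumed by an
    8mer at p, a 7mer-A1 at p by an 8mer at p-1. Returns (start, type,
    matched substring) triples sorted by (start, type).
    """
    m8 = _rc(mirna[1:8])
    motif_8mer = m8 + "A"
    motif_a1 = _rc(mirna[1:7]) + "A"
    eight = {p for p in range(len(utr) - 7) if utr[p : p + 8] == motif_8mer}
    m7m8 = {p for p in range(len(utr) - 6) if utr[p : p + 7] == m8}
    a1 = {p for p in range(len(utr) - 6) if utr[p : p + 7] == motif_a1}
    sites = [(p, "8mer", utr[p : p + 8]) for p in eight]
    sites += [(p, "7mer-m8", utr[p : p + 7]) for p in m7m8 if p not in eight]
    sites += [(p, "7mer-A1", utr[p : p + 7]) for p in a1 if p - 1 not in eight]
    return sorted(sites)
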