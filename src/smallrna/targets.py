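"""Seed-based miRNA target prediction on 3'UTR sequences.

A miRNA recognizes its targets mainly through its seed, nucleotides 2-8
from the 5' end. The three canonical site types on the mRNA sense strand
are, in decreasing strength:

* 8mer     — reverse complement of seed nt 2-8, followed by an A
* 7mer-m8  — reverse complement of seed nt 2-8
* 7mer-A1  — reverse complement of seed nt 2-7, followed by an A

(The A opposite miRNA position 1 is recognized directly, not by pairing.)
Every seed-match locus in the UTR is reported once with the strongest
applicable type. Scanning is strand-faithful: only the supplied sense
strand is searched.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import ReferenceLibrary

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeedMatchParams:
    site_types: tuple[str, ...] = SITE_TYPES
    min_sites_per_utr: int = 1

    def __post_init__(self) -> None:
        if not self.site_types:
            raise ValueError("at least one site type required")
        unknown = set(self.site_types) - set(SITE_TYPES)
        if unknown:
            raise ValueError(f"unknown site types: {sorted(unknown)}")
        if self.min_sites_per_utr < 1:
            raise ValueError("min_sites_per_utr must be >= 1")


@dataclass
class SeedSite:
    utr_id: str
    mirna_id: str
    site_type: str
    start: int  # 0-based position of the site's 5'-most base on the UTR
    site_seq: str


def seed(mirna_seq: str) -> str:
    """Seed sequence: nucleotides 2-8 (1-based) of the mature miRNA."""
    if len(mirna_seq) < 8:
        raise ValueError(f"miRNA too short for a seed (need >= 8 nt): {mirna_seq!r}")
    return mirna_seq[1:8]


def site_motifs(mirna_seq: str) -> dict[str, str]:
    """The three canonical target-site motifs for a mature miRNA."""
    s = seed(mirna_seq)  # nt 2-8
    m8 = _revcomp(s)  # 7 nt
    return {
        "8mer": m8 + "A",
        "7mer-m8": m8,
        "7mer-A1": _revcomp(mirna_seq[1:7]) + "A",
    }


def find_seed_sites(
    utr_seq: str, mirna_seq: str, mirna_id: str = "", utr_id: str = "",
    params: SeedMatchParams | None = None,
) -> list[SeedSite]:
    """All seed-match sites of one miRNA in one UTR, 5' to 3'.

    Each locus — an occurrence of the 6-nt core complementary to seed nt
    2-7 — is reported once with the strongest applicable type
    (8mer > 7mer-m8 > 7mer-A1); a core with neither the m8 match nor the
    A1 anchor (a bare 6mer) is not reported. 'N' never matches.
    """
    params = params or SeedMatchParams()
    seed(mirna_seq)  # validates length
    utr = utr_seq.upper()
    core = _revcomp(mirna_seq[1:7])  # complements seed nt 2-7
    m8_base = _revcomp(mirna_seq[7])  # UTR base pairing miRNA nt 8
    if "N" in core or "N" in m8_base:
        return []
    sites: list[SeedSite] = []
    wanted = set(params.site_types)
    p = utr.find(core)
    while p != -1:
        has_m8 = p >= 1 and utr[p - 1] == m8_base
        has_a1 = p + 6 < len(utr) and utr[p + 6] == "A"
        if has_m8 and has_a1:
            stype, start, length = "8mer", p - 1, 8
        elif has_m8:
            stype, start, length = "7mer-m8", p - 1, 7
        elif has_a1:
            stype, start, length = "7mer-A1", p, 7
        else:
            stype = None
        if stype is not None and stype in wanted:
            sites.append(
                SeedSite(
                    utr_id=utr_id,
                    mirna_id=mirna_id,
                    site_type=stype,
                    start=start,
                    site_seq=utr[start : start + length],
                )
            )
        p = utr.find(core, p + 1)
    return sites


def predict_targets(
    mirnas: ReferenceLibrary,
    utrs: ReferenceLibrary,
    params: SeedMatchParams | None = None,
) -> pd.DataFrame:
    """Scan every (miRNA, UTR) pair for seed sites.

    Returns one row per pair with at least ``min_sites_per_utr`` sites:
    per-type site counts, total, and semicolon-joined ``type@start``
    coordinates; sorted by miRNA (library order) then descending total.
    """
    params = params or SeedMatchParams()
    if not mirnas.entries or not utrs.entries:
        raise ValueError("both libraries must be non-empty")
    rows = []
    site_lists: dict[tuple[str, str], list[SeedSite]] = {}
    for order, (mid, mseq) in enumerate(mirnas.entries):
        for uid, useq in utrs.entries:
            sites = find_seed_sites(useq, mseq, mirna_id=mid, utr_id=uid, params=params)
            if len(sites) < params.min_sites_per_utr:
                continue
            site_lists[(mid, uid)] = sites
            by_type = {t: sum(1 for s in sites if s.site_type == t) for t in SITE_TYPES}
            rows.append(
                {
                    "mirna_id": mid,
                    "utr_id": uid,
                    "n_8mer": by_type["8mer"],
                    "n_7mer_m8": by_type["7mer-m8"],
                    "n_7mer_A1": by_type["7mer-A1"],
                    "total": len(sites),
                    "sites": ";".join(f"{s.site_type}@{s.start}" for s in sites),
                    "_order": order,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["mirna_id", "utr_id", "n_8mer", "n_7mer_m8", "n_7mer_A1", "total", "sites", "_order"],
    )
    df = df.sort_values(["_order", "total"], ascending=[True, False], kind="stable")
    df = df.drop(columns="_order").reset_index(drop=True)
    df.attrs["site_lists"] = site_lists
    return df
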