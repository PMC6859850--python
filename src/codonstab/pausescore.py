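"""Codon-level ribosomal-site occupancy and pause scores from footprint reads.

In 28–30 nt ribosome-protected fragments the A, P, and E sites occupy read
positions 17–19, 14–16, and 11–13 (1-based), so with a fixed 5' end the three
site codons are consecutive CDS codons (i, i-1, i-2). A read contributes to a
site table only if that site starts in-frame and lies fully inside the CDS;
otherwise it is rejected (and counted). The pause score of a codon is its
observed site frequency divided by its expected frequency under the null that
ribosomes are spread evenly over the translated pool: each gene's codon
frequency weighted by the gene's share of in-frame (A-site-accepted) reads.
High scores mark long dwell times, i.e. slow decoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._genetic_code import (AA_TO_CODONS, ALL_CODONS, AMINO_ACIDS, CODON_TO_AA)
from .codonstats import codon_frequencies
from .io_formats import FootprintTable

#: 0-based offset of each site's first nucleotide from the read 5' end
SITE_OFFSETS = {"A": 16, "P": 13, "E": 10}

REJECT = None


@dataclass
class SiteOccupancy:
    """Observed codon counts/frequencies in one ribosomal site."""

    site: str
    obs_counts: pd.Series  # over 64 codons, integer counts
    obs_freq: pd.Series    # over 64 codons; empty Series when no reads used
    n_reads_used: int
    n_reads_rejected: int


@dataclass
class PauseScoreTable:
    """Observed/expected enrichment per codon in one site."""

    site: str
    score: pd.Series          # over 64 codons; NaN where expected == 0
    expected_freq: pd.Series  # over 64 codons
    aa_score: pd.Series       # over the 20 standard amino acids

    def to_frame(self, obs: SiteOccupancy | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "codon": self.score.index,
            "amino_acid": [CODON_TO_AA.get(c, "*") for c in self.score.index],
            "expected_freq": self.expected_freq.to_numpy(),
            "score": self.score.to_numpy(),
        })
        if obs is not None and len(obs.obs_freq):
            df.insert(2, "obs_freq", obs.obs_freq.reindex(self.score.index).to_numpy())
        return df


def assign_site_codon(five_prime_pos: int, cds_length: int, site: str):
    """Codon index of a read's A/P/E site, or REJECT (None).

    The site starts at ``five_prime_pos + offset`` (A: +16, P: +13, E: +10,
    0-based); it is accepted iff that start is a multiple of 3 (in-frame) and
    the full site lies inside the CDS.
    """
    start = five_prime_pos + SITE_OFFSETS[site]
    if start % 3 != 0 or start + 3 > cds_length or five_prime_pos < 0:
        return REJECT
    return start // 3


def _site_codons(fp: FootprintTable, cds_set: dict[str, str], site: str):
    """All accepted site codons as a list of codon strings, plus reject count."""
    offset = SITE_OFFSETS[site]
    codons: list[str] = []
    n_rejected = 0
    unknown = set(fp.reads["transcript_id"]) - set(cds_set)
    if unknown:
        raise ValueError(f"footprints reference unknown transcripts: {sorted(unknown)[:5]}")
    for tid, sub in fp.reads.groupby("transcript_id", sort=True):
        seq = cds_set[tid]
        n = len(seq)
        starts = sub["five_prime_pos"].to_numpy(dtype=np.int64) + offset
        ok = (starts % 3 == 0) & (starts + 3 <= n) & (starts >= 0)
        n_rejected += int((~ok).sum())
        for s in starts[ok]:
            codons.append(seq[s:s + 3])
    return codons, n_rejected


def observed_occupancy(fp: FootprintTable, cds_set: dict[str, str], site: str) -> SiteOccupancy:
    """Count codons in one ribosomal site over the accepted reads."""
    codons, n_rejected = _site_codons(fp, cds_set, site)
    counts = pd.Series(0, index=list(ALL_CODONS), dtype=np.int64)
    if codons:
        vc = pd.Series(codons).value_counts()
        counts.loc[vc.index] = vc.to_numpy()
    n_used = int(counts.sum())
    freq = counts / n_used if n_used > 0 else pd.Series(dtype=float)
    return SiteOccupancy(site=site, obs_counts=counts, obs_freq=freq,
                         n_reads_used=n_used, n_reads_rejected=n_rejected)


def expected_frequencies(fp: FootprintTable, cds_set: dict[str, str]) -> pd.Series:
    """Abundance-weighted null codon frequencies.

    expected(c) = sum over genes g of w_g * f_g(c), where f_g is the codon
    frequency vector of g's CDS (stop codons counted) and w_g is g's share of
    in-frame A-site-accepted 28–30 nt reads. One consistent weighting is used
    for all three site tables. Zero accepted reads is an error.
    """
    offset = SITE_OFFSETS["A"]
    weights: dict[str, int] = {}
    for tid, sub in fp.reads.groupby("transcript_id", sort=True):
        n = len(cds_set[tid])
        starts = sub["five_prime_pos"].to_numpy(dtype=np.int64) + offset
        ok = (starts % 3 == 0) & (starts + 3 <= n) & (starts >= 0)
        if ok.any():
            weights[tid] = int(ok.sum())
    total = sum(weights.values())
    if total == 0:
        raise ValueError("no in-frame accepted reads; expected frequencies undefined")
    expected = pd.Series(0.0, index=list(ALL_CODONS))
    for tid, w in weights.items():
        expected += (w / total) * codon_frequencies(cds_set[tid])
    return expected


def pause_scores(obs: SiteOccupancy, expected: pd.Series) -> PauseScoreTable:
    """Observed/expected ratio per codon (stop codons included).

    Codons with zero expected frequency get NaN. Amino-acid scores are the
    arithmetic mean of the member codon scores (NaN members omitted).
    """
    if not len(obs.obs_freq):
        of = pd.Series(0.0, index=list(ALL_CODONS))
    else:
        of = obs.obs_freq.reindex(list(ALL_CODONS)).fillna(0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = of / expected
    score[expected <= 0] = np.nan
    aa = {}
    for a in AMINO_ACIDS:
        member = score.loc[list(AA_TO_CODONS[a])].dropna()
        aa[a] = float(member.mean()) if len(member) else float("nan")
    return PauseScoreTable(site=obs.site, score=score, expected_freq=expected,
                           aa_score=pd.Series(aa, index=list(AMINO_ACIDS)))


def tertile_groups(scores: pd.Series) -> dict[str, list[str]]:
    """Split codons into three near-equal groups by descending score.

    Returns {"slow": ..., "neutral": ..., "fast": ...}: "slow" holds the
    highest scores (longest dwell). Sizes differ by at most one, with earlier
    groups taking the extra (61 codons -> 21/20/20). Ties, and the all-equal
    degenerate case, are broken by codon lexicographic order, so the grouping
    is deterministic and independent of input order.
    """
    s = scores.dropna()
    order = sorted(s.index, key=lambda c: (-s[c], c))
    parts = np.array_split(np.asarray(order, dtype=object), 3)
    return {"slow": list(parts[0]), "neutral": list(parts[1]), "fast": list(parts[2])}
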