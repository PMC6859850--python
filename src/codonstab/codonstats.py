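"""Codon usage, codon/amino-acid stability coefficients, and frameshift controls.

The codon stability coefficient (CSC) of a codon is the Spearman rank
correlation, across a transcript set, between the codon's frequency in each
CDS and the transcript's half-life. The amino-acid stabilization coefficient
(AASC) is the arithmetic mean of the CSCs of an amino acid's synonymous
codons. Frameshift controls recompute codon frequencies after shifting the
reading frame by +1 or +2 nucleotides; a translation-dependent signal should
degrade under the shift.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._genetic_code import (AA_TO_CODONS, ALL_CODONS, AMINO_ACIDS, CODON_TO_AA,
                            SENSE_CODONS)

__all__ = [
    "codon_frequencies", "frequency_table", "spearman", "compute_csc",
    "compute_aasc", "fisher_r_to_z", "csc_null_band", "CSCTable", "AASCTable",
]


def codon_frequencies(cds: str, frameshift: int = 0) -> pd.Series:
    """Codon frequencies of a CDS, optionally after a +1/+2 frameshift.

    Frequencies are fractions of the codons counted (stop codons are counted
    in the denominator). The frameshift controls remove, from a CDS of length
    n, the 1-based positions {1, n-2, n-1} for +1 and {1, 2, n-1} for +2, so
    the remaining n-3 nucleotides re-chunk into out-of-frame codons.

    Returns a Series over all 64 codons summing to 1.
    """
    seq = cds.upper()
    n = len(seq)
    if n % 3 != 0:
        raise ValueError(f"CDS length {n} not divisible by 3")
    if n < 6:
        raise ValueError("CDS shorter than 2 codons")
    if frameshift == 0:
        s = seq
    elif frameshift == 1:
        s = seq[1:n - 3] + seq[n - 1]
    elif frameshift == 2:
        s = seq[2:n - 2] + seq[n - 1]
    else:
        raise ValueError("frameshift must be 0, 1, or 2")
    codons = [s[i:i + 3] for i in range(0, len(s), 3)]
    counts = Counter(codons)
    total = len(codons)
    freq = pd.Series(
        [counts.get(c, 0) / total for c in ALL_CODONS],
        index=list(ALL_CODONS), dtype=float,
    )
    return freq


def frequency_table(cds_set: dict[str, str], frameshift: int = 0) -> pd.DataFrame:
    """Per-transcript codon frequency vectors (transcripts x 64 codons).

    Transcripts whose length is not divisible by 3 are skipped with a warning.
    """
    rows, index, skipped = [], [], []
    for tid, seq in cds_set.items():
        if len(seq) % 3 != 0:
            skipped.append(tid)
            continue
        rows.append(codon_frequencies(seq, frameshift).to_numpy())
        index.append(tid)
    if skipped:
        warnings.warn(f"skipped {len(skipped)} transcript(s) with length % 3 != 0")
    return pd.DataFrame(np.asarray(rows), index=index, columns=list(ALL_CODONS))


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    NaN pairs are dropped; fewer than 3 complete pairs is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete (non-NA) pairs")
    return float(sps.spearmanr(x[ok], y[ok]).statistic)


@dataclass
class CSCTable:
    """Per-codon stability coefficients over the 61 sense codons."""

    csc: pd.Series
    n_transcripts: int

    def __post_init__(self) -> None:
        assert list(self.csc.index) == list(SENSE_CODONS)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "codon": self.csc.index,
            "amino_acid": [CODON_TO_AA[c] for c in self.csc.index],
            "csc": self.csc.to_numpy(),
            "n": self.n_transcripts,
        })


@dataclass
class AASCTable:
    aasc: pd.Series  # indexed by the 20 standard one-letter amino acids


def _rank_columns(mat: np.ndarray) -> np.ndarray:
    return sps.rankdata(mat, axis=0, method="average")


def compute_csc(freqs: pd.DataFrame, half_lives: pd.Series,
                min_transcripts: int = 20) -> CSCTable:
    """Spearman correlation of each sense codon's frequency with half-life.

    ``freqs`` is a transcripts x codons frequency table; ``half_lives`` is
    indexed by transcript id (NaN half-lives dropped pairwise — frequency
    vectors carry no NaN, so this is a row subset). Stop codons are excluded
    from the output. Codons with zero frequency variance get NaN with a
    warning. Implemented as Pearson correlation of average-ranked columns,
    cross-checkable against a per-codon scipy.stats.spearmanr.
    """
    hl = half_lives.dropna()
    common = freqs.index.intersection(hl.index)
    if len(common) < 3:
        raise ValueError("need at least 3 transcripts with half-lives")
    if len(common) < min_transcripts:
        warnings.warn(f"only {len(common)} transcripts with half-lives "
                      f"(recommended >= {min_transcripts})")
    F = freqs.loc[common, list(SENSE_CODONS)].to_numpy(dtype=float)
    y = hl.loc[common].to_numpy(dtype=float)

    rF = _rank_columns(F)
    ry = sps.rankdata(y, method="average")
    rF = rF - rF.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rF ** 2).sum(axis=0) * (ry ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rF * ry[:, None]).sum(axis=0) / denom
    zero_var = denom == 0
    if zero_var.any():
        bad = [SENSE_CODONS[i] for i in np.flatnonzero(zero_var)]
        warnings.warn(f"zero-variance codon frequency, CSC set to NA: {bad}")
        r[zero_var] = np.nan
    return CSCTable(csc=pd.Series(r, index=list(SENSE_CODONS)),
                    n_transcripts=len(common))


def compute_aasc(csc: CSCTable) -> AASCTable:
    """Arithmetic mean of CSCs over each amino acid's codons (NaN omitted)."""
    vals = {}
    for aa in AMINO_ACIDS:
        member = csc.csc.loc[list(AA_TO_CODONS[aa])].dropna()
        vals[aa] = float(member.mean()) if len(member) else float("nan")
    return AASCTable(aasc=pd.Series(vals, index=list(AMINO_ACIDS)))


def fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent correlations by Fisher's r-to-z transformation.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); the two-sided
    p-value comes from the standard normal.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ValueError("|r| must be < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("n must exceed 3")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def csc_null_band(freqs: pd.DataFrame, half_lives: pd.Series, *,
                  n_permutations: int = 200, level: float = 0.95,
                  seed: int = 0) -> pd.DataFrame:
    """Permutation null band for CSC values.

    Half-lives are permuted across transcripts ``n_permutations`` times and
    the per-codon CSC recomputed each time; returns a DataFrame indexed by
    sense codon with columns ``lo`` and ``hi`` (the central ``level`` band).
    """
    hl = half_lives.dropna()
    common = freqs.index.intersection(hl.index)
    F = freqs.loc[common, list(SENSE_CODONS)].to_numpy(dtype=float)
    y = hl.loc[common].to_numpy(dtype=float)
    rF = _rank_columns(F)
    rF = rF - rF.mean(axis=0)
    ry0 = sps.rankdata(y, method="average")
    rng = np.random.default_rng(seed)
    ssF = (rF ** 2).sum(axis=0)

    null = np.empty((n_permutations, len(SENSE_CODONS)))
    for i in range(n_permutations):
        ry = rng.permutation(ry0)
        ry = ry - ry.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            null[i] = (rF * ry[:, None]).sum(axis=0) / np.sqrt(ssF * (ry ** 2).sum())
    alpha = (1.0 - level) / 2.0
    lo = np.nanquantile(null, alpha, axis=0)
    hi = np.nanquantile(null, 1.0 - alpha, axis=0)
    return pd.DataFrame({"lo": lo, "hi": hi}, index=list(SENSE_CODONS))
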