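"""ORF-level covariates: length, windowed secondary structure, miRNA seed
sites, and AU-rich elements, with distribution comparisons against half-life.

Secondary structure is scored per 100-nt window (windows start every 3 nt)
and the minimum over windows is kept. The energy function is pluggable: the
default is a deterministic base-pairing surrogate, minus the maximum number
of nested complementary pairs (Watson-Crick plus G:U wobble, minimum hairpin
loop of 3 nt) found by dynamic programming. An adapter for a thermodynamic
folding engine (ViennaRNA's RNAfold) is provided for users who want physical
minimum-free-energy values; both are interchangeable through ``energy_fn``.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from ._genetic_code import reverse_complement
from .stats import TestResult, ks_test

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


@njit(cache=False)
def _max_pairs(enc: np.ndarray, min_loop: int) -> int:  # pragma: no cover - jitted
    n = enc.shape[0]
    M = np.zeros((n, n), dtype=np.int32)
    for d in range(min_loop + 1, n):
        for i in range(n - d):
            j = i + d
            best = M[i + 1, j]
            if M[i, j - 1] > best:
                best = M[i, j - 1]
            a, b = enc[i], enc[j]
            paired = (a + b == 3 and a != b) or (a == 1 and b == 2) or \
                     (a == 2 and b == 1) or (a == 2 and b == 3) or (a == 3 and b == 2)
            if paired and M[i + 1, j - 1] + 1 > best:
                best = M[i + 1, j - 1] + 1
            for k in range(i + 1, j):
                v = M[i, k] + M[k + 1, j]
                if v > best:
                    best = v
            M[i, j] = best
    return int(M[0, n - 1])


def pairing_energy(seq: str, min_loop: int = 3) -> float:
    """Default surrogate energy: -(max nested complementary base pairs).

    Pairs are A:T(U), G:C, and G:U wobble; hairpin loops shorter than
    ``min_loop`` nt are forbidden. Lower (more negative) = more structured;
    an unpairable sequence scores 0.
    """
    enc = np.array([_ENCODE.get(b, 4) for b in seq.upper()], dtype=np.int8)
    if len(enc) < min_loop + 2:
        return 0.0
    return -float(_max_pairs(enc, min_loop))


def rnafold_energy(seq: str) -> float:
    """Adapter: thermodynamic MFE (kcal/mol) from the RNAfold command line.

    Satisfies the same contract as :func:`pairing_energy` (str -> real, lower
    = more structured). Requires ViennaRNA's ``RNAfold`` on PATH.
    """
    if shutil.which("RNAfold") is None:
        raise RuntimeError("RNAfold not found on PATH")
    out = subprocess.run(["RNAfold", "--noPS"], input=seq + "\n", text=True,
                         capture_output=True, check=True).stdout
    # last line: "....structure.... (-12.30)"
    tail = out.strip().splitlines()[-1]
    return float(tail[tail.rindex("(") + 1:tail.rindex(")")])


def sliding_windows(cds: str, window: int = 100, step: int = 3) -> list[str]:
    """Subsequences of length ``window`` starting every ``step`` nt.

    Window count is floor((len - window)/step) + 1; a CDS shorter than the
    window is an error.
    """
    if len(cds) < window:
        raise ValueError(f"CDS length {len(cds)} shorter than window {window}")
    return [cds[i:i + window] for i in range(0, len(cds) - window + 1, step)]


def min_window_energy(cds: str, energy_fn=None, window: int = 100, step: int = 3) -> float:
    """Minimum of ``energy_fn`` over all sliding windows (default surrogate)."""
    fn = energy_fn or pairing_energy
    return min(fn(w) for w in sliding_windows(cds, window, step))


def scan_mirna_sites(seq: str, seeds: list[str]) -> dict[str, bool]:
    """7mer-m8 seed-site scan.

    Each seed is the 7-mer at miRNA positions 2–8 (5'->3'); a site is the
    exact reverse-complement match in the target sequence. Returns a flag per
    seed; an empty seed list yields an empty dict.
    """
    s = seq.upper().replace("U", "T")
    out: dict[str, bool] = {}
    for seed in seeds:
        if len(seed) != 7:
            raise ValueError(f"seed {seed!r} is not a 7-mer")
        out[seed] = reverse_complement(seed.upper()) in s
    return out


def detect_are(seq: str, motif: str = "ATTTA", min_count: int = 1) -> bool:
    """AU-rich element flag: >= ``min_count`` (overlapping) motif occurrences."""
    s = seq.upper().replace("U", "T")
    count = start = 0
    while True:
        idx = s.find(motif, start)
        if idx < 0:
            break
        count += 1
        start = idx + 1
    return count >= min_count


def group_compare(hl_with, hl_without) -> TestResult:
    """Two-sample KS test of half-lives with vs without a feature."""
    return ks_test(hl_with, hl_without)


@dataclass
class FeatureTable:
    table: pd.DataFrame  # transcript_id, orf_length_nt, min_window_energy, has_are, seed flags


def feature_table(cds_set: dict[str, str], seeds: list[str] | None = None,
                  energy_fn=None, window: int = 100, step: int = 3) -> FeatureTable:
    """Compute the ORF covariates for every transcript long enough to window."""
    seeds = seeds or []
    rows = []
    for tid, seq in cds_set.items():
        row = {
            "transcript_id": tid,
            "orf_length_nt": len(seq),
            "min_window_energy": (min_window_energy(seq, energy_fn, window, step)
                                  if len(seq) >= window else np.nan),
            "has_are": detect_are(seq),
        }
        for seed, flag in scan_mirna_sites(seq, seeds).items():
            row[f"site_{seed}"] = flag
        rows.append(row)
    return FeatureTable(table=pd.DataFrame(rows).set_index("transcript_id", drop=False))
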