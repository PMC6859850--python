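"""Half-life estimation from approach-to-equilibrium labeling time courses.

During continuous 4SU labeling the labeled abundance of a transcript follows
bounded growth, ``y(t) = y_eq * (1 - exp(k*t))`` with decay constant
``k <= 0`` (1/h), and the half-life is ``HL = ln(2)/|k|``. Counts are first
normalized per sample to the total of the labeled *D. melanogaster* spike-in
rows, filtered on raw counts (>=1 read at every time point, >=5 reads at some
time point), and then fit per transcript by weighted (1/y) nonlinear least
squares with box constraints ``y_eq >= 0``, ``k <= 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io_formats import TimeCourseCounts

#: a fit whose rate is closer to zero than this is declared non-converged
K_CONVERGENCE_BOUND = -1e-9

#: half-lives above this (hours) are flagged as long-lived (reported uncapped)
LONG_HALFLIFE_H = 100.0


@dataclass
class DecayFit:
    """Result of a bounded-growth fit for one transcript.

    ``k`` carries the non-positive sign convention (decay constants are
    reported as k <= 0); ``half_life`` is ln(2)/|k| in hours, or NaN when the
    fit did not converge.
    """

    transcript_id: str
    y_eq: float
    k: float
    half_life: float
    converged: bool
    n_timepoints_used: int

    @property
    def long_halflife(self) -> bool:
        return bool(np.isfinite(self.half_life) and self.half_life > LONG_HALFLIFE_H)


def spike_normalize(tc: TimeCourseCounts) -> pd.DataFrame:
    """Divide each sample's counts by its total labeled-spike (fly) reads.

    Spike rows (fly and yeast) are excluded from the returned matrix. A
    sample with zero fly-spike reads is an error naming that sample.
    """
    dmel = [r for r in tc.counts.index if r.startswith("spike_dmel|")]
    if not dmel:
        raise ValueError("no spike_dmel| rows present; cannot spike-normalize")
    totals = tc.counts.loc[dmel].sum(axis=0).astype(float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero D. melanogaster spike total in sample(s): {list(zero.index)}")
    return tc.human_counts().astype(float).div(totals, axis=1)


def filter_timecourse(tc: TimeCourseCounts, cell_line: str | None = None,
                      min_reads_each: int = 1, min_reads_any: int = 5
                      ) -> tuple[list[str], list[str]]:
    """Raw-count expression filter applied before fitting.

    A transcript is kept iff over the labeled time points of the cell line it
    has at least ``min_reads_each`` reads at *every* time point and at least
    ``min_reads_any`` reads at *some* time point. Spike rows are ignored.

    Returns (kept_ids, dropped_ids).
    """
    samples = tc.labeled_samples(cell_line).index
    counts = tc.human_counts()[list(samples)]
    keep = (counts.min(axis=1) >= min_reads_each) & (counts.max(axis=1) >= min_reads_any)
    return list(counts.index[keep]), list(counts.index[~keep])


def _model(t: np.ndarray, y_eq: float, k: float) -> np.ndarray:
    return y_eq * (1.0 - np.exp(k * t))


def fit_bounded_growth(times, y, *, transcript_id: str = "",
                       xtol: float = 1e-12, max_nfev: int = 200) -> DecayFit:
    """Fit ``y(t) = y_eq * (1 - exp(k t))`` by weighted nonlinear least squares.

    Weights are 1/y(t); start values are ``y_eq = max(y)``, ``k = -0.5``; box
    constraints are ``y_eq in [0, inf)`` and ``k in (-inf, 0]`` (trust-region
    reflective solver). Non-convergence — solver failure or a fitted rate at
    the k = 0 bound — yields ``converged=False`` and a NaN half-life.

    Series containing non-positive values are rejected (the 1/y weights are
    undefined there; the upstream raw-count filter guarantees positivity).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and y must be 1-D arrays of equal length")
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(y <= 0):
        raise ValueError("non-positive normalized counts: 1/y weights undefined")

    sw = 1.0 / np.sqrt(y)  # sqrt of the 1/y weights

    def resid(p):
        return sw * (y - _model(t, p[0], p[1]))

    def jac(p):
        e = np.exp(p[1] * t)
        return np.column_stack([-sw * (1.0 - e), sw * p[0] * t * e])

    x0 = np.array([float(np.max(y)), -0.5])
    try:
        sol = least_squares(resid, x0, jac=jac, bounds=([0.0, -np.inf], [np.inf, 0.0]),
                            method="trf", xtol=xtol, ftol=xtol, gtol=xtol,
                            max_nfev=max_nfev)
        ok = sol.success
        y_eq, k = float(sol.x[0]), float(sol.x[1])
    except Exception:
        ok, y_eq, k = False, float("nan"), float("nan")

    converged = bool(ok and k < K_CONVERGENCE_BOUND)
    return DecayFit(
        transcript_id=transcript_id,
        y_eq=y_eq,
        k=k,
        half_life=half_life(k) if converged else float("nan"),
        converged=converged,
        n_timepoints_used=len(t),
    )


def half_life(k: float) -> float:
    """ln(2)/|k| in hours for k < 0; NaN for k = 0 (no decay, undefined)."""
    if not np.isfinite(k) or k >= 0.0:
        return float("nan")
    return math.log(2.0) / abs(k)


def combine_replicates(half_lives) -> float:
    """Arithmetic mean of the non-NaN replicate half-lives; NaN if all NaN."""
    vals = np.asarray(half_lives, dtype=float)
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if len(vals) else float("nan")


def weighted_sse(times, y, y_eq: float, k: float) -> float:
    """The objective the fitter minimizes: sum over t of (y - model)^2 / y."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    r = y - _model(t, y_eq, k)
    return float(np.sum(r * r / y))


def fit_halflives(tc: TimeCourseCounts, cell_line: str | None = None,
                  min_reads_each: int = 1, min_reads_any: int = 5) -> pd.DataFrame:
    """Filter, spike-normalize, and fit every transcript of one cell line.

    Returns a DataFrame with columns transcript_id, cell_line, y_eq, k,
    half_life_h, converged, n_timepoints, indexed by transcript_id.
    """
    meta = tc.labeled_samples(cell_line)
    if cell_line is None:
        lines = meta["cell_line"].unique()
        if len(lines) != 1:
            raise ValueError("multiple cell lines present; pass cell_line explicitly")
        cell_line = str(lines[0])
    kept, _dropped = filter_timecourse(tc, cell_line, min_reads_each, min_reads_any)
    norm = spike_normalize(tc)[list(meta.index)]
    times = meta["timepoint_h"].to_numpy(dtype=float)

    rows = []
    for tid in kept:
        fit = fit_bounded_growth(times, norm.loc[tid].to_numpy(), transcript_id=tid)
        rows.append({
            "transcript_id": tid,
            "cell_line": cell_line,
            "y_eq": fit.y_eq,
            "k": fit.k,
            "half_life_h": fit.half_life,
            "converged": fit.converged,
            "n_timepoints": fit.n_timepoints_used,
        })
    out = pd.DataFrame(rows, columns=["transcript_id", "cell_line", "y_eq", "k",
                                      "half_life_h", "converged", "n_timepoints"])
    return out.set_index("transcript_id", drop=False)
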