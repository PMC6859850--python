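"""Transcript classification from steady-state libraries of paired cell lines.

Each pooled reporter line expresses one pool of ORFeome clones. Because reads
cannot distinguish a reporter transcript from its endogenous counterpart, a
transcript is called "orfeome" in a line only when it is in that line's pool
*and* clearly over-expressed there relative to the paired line: its
library-size-normalized steady-state count must exceed 3x the paired line's
and exceed 4 reads (both strict inequalities). Pool members failing either
threshold are "excluded"; transcripts in neither line's pool are "endogenous".
Transcripts present only in the *paired* line's pool are also "excluded" from
the endogenous set, since their reads may be reporter-derived.
"""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd

LABELS = ("orfeome", "endogenous", "excluded")


def library_size_normalize(steady_counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample by (mean library total / its library total).

    Keeps values on a read-count scale so absolute-count thresholds (e.g.
    "> 4 reads") stay meaningful. An all-zero sample is an error.
    """
    totals = steady_counts.sum(axis=0).astype(float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return steady_counts.astype(float).mul(totals.mean() / totals, axis=1)


def classify_orfeome(norm_self: pd.Series, norm_paired: pd.Series,
                     pool_self: Iterable[str], pool_paired: Iterable[str] = (),
                     *, cell_line: str = "", fold: float = 3.0,
                     min_norm: float = 4.0) -> pd.DataFrame:
    """Label every transcript for one cell line.

    Parameters
    ----------
    norm_self, norm_paired
        Library-size-normalized steady-state counts in this line and the
        matched line (aligned on transcript id; missing = 0).
    pool_self, pool_paired
        Transcript ids infected into this line / the paired line. Transcripts
        present in the counts but absent from both registries are treated as
        not in any pool (endogenous).

    Returns
    -------
    DataFrame indexed by transcript_id with columns transcript_id, cell_line,
    label, norm_count_self, norm_count_paired. Every transcript receives
    exactly one label.
    """
    pool_self = set(pool_self)
    pool_paired = set(pool_paired)
    ids = norm_self.index.union(norm_paired.index)
    ns = norm_self.reindex(ids, fill_value=0.0).astype(float)
    np_ = norm_paired.reindex(ids, fill_value=0.0).astype(float)

    labels = []
    for tid in ids:
        if tid in pool_self:
            passed = (ns[tid] > fold * np_[tid]) and (ns[tid] > min_norm)
            labels.append("orfeome" if passed else "excluded")
        elif tid in pool_paired:
            labels.append("excluded")
        else:
            labels.append("endogenous")

    return pd.DataFrame({
        "transcript_id": ids,
        "cell_line": cell_line,
        "label": labels,
        "norm_count_self": ns.to_numpy(),
        "norm_count_paired": np_.to_numpy(),
    }, index=ids)


def classify_lines(steady_counts: pd.DataFrame, pools: dict[str, Iterable[str]],
                   line_self: str, line_paired: str, *, fold: float = 3.0,
                   min_norm: float = 4.0, normalize: bool = True) -> pd.DataFrame:
    """Normalize a two-line steady-state table and classify for ``line_self``."""
    norm = library_size_normalize(steady_counts) if normalize else steady_counts.astype(float)
    return classify_orfeome(
        norm[line_self], norm[line_paired],
        pools.get(line_self, ()), pools.get(line_paired, ()),
        cell_line=line_self, fold=fold, min_norm=min_norm,
    )


def read_pool_registry(path) -> dict[str, set[str]]:
    """Read a TSV of (transcript_id, pool_id) into pool_id -> set of ids."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"transcript_id", "pool_id"} <= set(df.columns):
        raise ValueError("pool registry needs columns transcript_id, pool_id")
    return {pid: set(sub["transcript_id"]) for pid, sub in df.groupby("pool_id")}
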