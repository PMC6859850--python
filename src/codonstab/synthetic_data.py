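"""Ground-truth synthetic data emulating the statistical structure the
analysis assumes.

The generator plants a known codon-composition -> decay coupling and known
codon dwell times, then emits the observables the pipeline consumes:

* CDS sequences: ATG + codons drawn i.i.d. from a per-transcript
  Dirichlet-perturbed global codon usage (so codon frequencies vary across
  transcripts, which is what gives the stability coefficients a signal) + one
  stop codon, with no internal in-frame stop.
* decay constants: log k_i = alpha + beta * sum_c f_i(c) w_c + eps_i with
  Gaussian eps and latent per-codon stability weights w_c ~ N(0, 1). With the
  convention that positive w_c stabilizes, beta is negative; setting
  ``codon_r2`` calibrates |beta| so the codon term explains that fraction of
  var(log k).
* labeling time courses: expected labeled count y_eq_i * (1 - exp(-k_i t))
  scaled to the sample depth, plus constant-expectation labeled fly
  (``spike_dmel|``) and unlabeled yeast (``spike_scer|``) spike-in rows, with
  optional Poisson count noise.
* ribosome footprints: 28–30 nt reads whose A-site codon is sampled with
  probability proportional to transcript abundance times the codon's dwell
  multiplier, the 5' end placed so the sampled codon occupies read positions
  17–19.

Everything is deterministic given the seed: each stage draws from its own
generator spawned from ``(seed, stage_tag)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._genetic_code import ALL_CODONS, SENSE_CODONS, STOP_CODONS
from .codonstats import codon_frequencies
from .io_formats import FootprintTable, TimeCourseCounts

_STAGE = {"transcriptome": 1, "timecourse": 2, "footprints": 3, "steady": 4}

POOL_LABELS = ("pool_A", "pool_B", "none")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror the measured experiment: six labeled time points at
    1, 2, 4, 8, 12, 24 h, a 10% (w/w) labeled fly spike and a matching
    unlabeled yeast spike, a median endogenous-like half-life of 8 h, and
    codon dwell multipliers log-uniform in [0.5, 2].
    """

    n_transcripts: int = 200
    length_range: tuple[int, int] = (100, 300)     # codons, incl. start + stop
    timepoints: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
    depth: float = 2_000_000.0                     # expected total counts/sample
    noise_model: str = "poisson"                   # {"none", "poisson"}
    beta: float = 0.0                              # codon->log k coupling
    codon_r2: float | None = None                  # overrides beta when set
    seed: int = 0
    # generator shape parameters (see docs/methods.md for rationale)
    alpha_log_k: float = math.log(math.log(2.0) / 8.0)  # median HL 8 h
    log_k_noise_sd: float = 0.35
    usage_concentration: float = 40.0              # Dirichlet kappa across transcripts
    abundance_sd: float = 1.0                      # lognormal sd of expression
    spike_fraction: float = 0.10                   # labeled fly spike share of depth
    scer_fraction: float = 0.10                    # unlabeled yeast spike share
    n_spike_rows: int = 8                          # rows per spike species
    dwell_log_range: tuple[float, float] = (0.5, 2.0)
    dwell_stability_coupling: float = 0.0          # Spearman-scale w vs -log d link
    stop_pause: float = 1.0                        # dwell multiplier of stop codons
    hl_range: tuple[float, float] | None = None    # optional clip of true HL (h)
    cell_line: str = "simline"

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be positive")
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ValueError("length_range min must be >= 10 codons (start + stop "
                             "+ body must fit) and max >= min")
        tp = np.asarray(self.timepoints, dtype=float)
        if len(tp) < 1 or np.any(tp <= 0) or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing and positive")
        if self.noise_model not in {"none", "poisson"}:
            raise ValueError("noise_model must be 'none' or 'poisson'")
        if self.codon_r2 is not None and not (0.0 <= self.codon_r2 < 1.0):
            raise ValueError("codon_r2 must be in [0, 1)")
        if not (0.0 <= self.spike_fraction < 1.0):
            raise ValueError("spike_fraction must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Latent generating quantities the pipeline tries to recover.

    ``table`` is indexed by transcript id with columns k_true (1/h, stored as
    magnitude), y_eq_true (expected steady-state count), abundance (sums to
    1), pool_label. ``codon_weights`` holds the latent stability weight of
    each sense codon; ``dwell_multipliers`` the relative A-site dwell of every
    codon (stop codons included, strictly positive).
    """

    table: pd.DataFrame
    codon_weights: pd.Series
    dwell_multipliers: pd.Series

    def __post_init__(self) -> None:
        if (self.table["k_true"] <= 0).any():
            raise ValueError("k_true must be positive (stored as magnitude)")
        if abs(float(self.table["abundance"].sum()) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        if (self.dwell_multipliers <= 0).any():
            raise ValueError("dwell multipliers must be strictly positive")
        missing_w = set(SENSE_CODONS) - set(self.codon_weights.index)
        missing_d = set(SENSE_CODONS) - set(self.dwell_multipliers.index)
        if missing_w or missing_d:
            raise ValueError("every sense codon needs a weight and a dwell multiplier")

    @property
    def half_life_true(self) -> pd.Series:
        return np.log(2.0) / self.table["k_true"]


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STAGE[stage]])


# ---------------------------------------------------------------------------
# transcriptome + truth
# ---------------------------------------------------------------------------

def simulate_transcriptome(config: SimulationConfig) -> tuple[dict[str, str], SyntheticTruth]:
    """Generate CDS sequences and the latent truth they were drawn from."""
    rng = _rng(config, "transcriptome")
    n = config.n_transcripts
    ids = [f"tx{i:05d}" for i in range(n)]

    # codon-level latents
    w = rng.standard_normal(len(SENSE_CODONS))
    lo, hi = config.dwell_log_range
    rho = config.dwell_stability_coupling
    u = rng.standard_normal(len(SENSE_CODONS))
    v = -rho * w + math.sqrt(max(0.0, 1.0 - rho * rho)) * u
    if hi > lo:
        # Gaussian copula onto a log-uniform marginal in [lo, hi]
        q = sps.norm.cdf(v)
        dwell = np.exp(math.log(lo) + q * (math.log(hi) - math.log(lo)))
    else:
        dwell = np.full(len(SENSE_CODONS), float(lo))
    codon_weights = pd.Series(w, index=list(SENSE_CODONS))
    dwell_mult = pd.Series(
        np.concatenate([dwell, np.full(len(STOP_CODONS), config.stop_pause)]),
        index=list(SENSE_CODONS) + list(STOP_CODONS),
    ).reindex(list(ALL_CODONS))

    # per-transcript codon usage: Dirichlet perturbation of a global usage
    global_usage = rng.dirichlet(np.full(len(SENSE_CODONS), 5.0))
    usages = rng.dirichlet(config.usage_concentration * len(SENSE_CODONS) *
                           global_usage + 1e-3, size=n)

    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, size=n)
    sense = np.asarray(SENSE_CODONS, dtype=object)
    stops = np.asarray(STOP_CODONS, dtype=object)
    cds_set: dict[str, str] = {}
    scores = np.empty(n)
    for i, tid in enumerate(ids):
        body = rng.choice(sense, size=int(lengths[i]) - 2, p=usages[i])
        stop = rng.choice(stops)
        seq = "ATG" + "".join(body) + str(stop)
        cds_set[tid] = seq
        f = codon_frequencies(seq)
        scores[i] = float(f.loc[list(SENSE_CODONS)].to_numpy() @ w)

    # codon composition -> decay coupling on log k
    if config.codon_r2 is not None:
        if config.codon_r2 == 0.0 or np.std(scores) == 0.0:
            beta = 0.0
        else:
            beta = -math.sqrt(config.codon_r2 / (1.0 - config.codon_r2)) * \
                config.log_k_noise_sd / float(np.std(scores))
    else:
        beta = config.beta
    eps = rng.normal(0.0, config.log_k_noise_sd, size=n) if config.log_k_noise_sd > 0 \
        else np.zeros(n)
    log_k = config.alpha_log_k + beta * (scores - scores.mean()) + eps
    k_true = np.exp(log_k)
    if config.hl_range is not None:
        hl_lo, hl_hi = config.hl_range
        k_true = np.clip(k_true, math.log(2.0) / hl_hi, math.log(2.0) / hl_lo)

    abundance = rng.lognormal(0.0, config.abundance_sd, size=n)
    abundance = abundance / abundance.sum()
    human_share = 1.0 - config.spike_fraction - config.scer_fraction
    y_eq_true = config.depth * human_share * abundance

    pool = rng.choice(np.asarray(POOL_LABELS, dtype=object), size=n, p=(0.4, 0.4, 0.2))
    table = pd.DataFrame({
        "k_true": k_true,
        "y_eq_true": y_eq_true,
        "abundance": abundance,
        "codon_score": scores,
        "pool_label": pool,
    }, index=pd.Index(ids, name="transcript_id"))
    truth = SyntheticTruth(table=table, codon_weights=codon_weights,
                           dwell_multipliers=dwell_mult)
    return cds_set, truth


def truth_from_halflives(half_lives_h, depth: float = 2e6,
                         spike_fraction: float = 0.10,
                         scer_fraction: float = 0.10,
                         abundance=None) -> SyntheticTruth:
    """Construct a truth table directly from prescribed half-lives.

    Convenience for kinetics benchmarks where the decay constants should tile
    a range deterministically instead of arising from the codon model. Codon
    weights and dwell multipliers are set to the neutral values (0 and 1).
    """
    hl = np.asarray(half_lives_h, dtype=float)
    if np.any(hl <= 0):
        raise ValueError("half-lives must be positive")
    n = len(hl)
    ids = [f"tx{i:05d}" for i in range(n)]
    a = np.full(n, 1.0 / n) if abundance is None else np.asarray(abundance, float)
    a = a / a.sum()
    table = pd.DataFrame({
        "k_true": math.log(2.0) / hl,
        "y_eq_true": depth * (1.0 - spike_fraction - scer_fraction) * a,
        "abundance": a,
        "codon_score": 0.0,
        "pool_label": "none",
    }, index=pd.Index(ids, name="transcript_id"))
    return SyntheticTruth(
        table=table,
        codon_weights=pd.Series(0.0, index=list(SENSE_CODONS)),
        dwell_multipliers=pd.Series(1.0, index=list(ALL_CODONS)),
    )


# ---------------------------------------------------------------------------
# labeling time course
# ---------------------------------------------------------------------------

def _format_tp(t: float) -> str:
    return f"{t:g}".replace(".", "p")


def simulate_timecourse(truth: SyntheticTruth, config: SimulationConfig) -> TimeCourseCounts:
    """Emit the labeled time-course count matrix with spike-in rows.

    Expected labeled human counts follow bounded growth; fly and yeast spike
    rows have constant expected totals per sample (``spike_fraction`` /
    ``scer_fraction`` of depth). With ``noise_model="poisson"`` counts are
    Poisson draws; with ``"none"`` the matrix holds the exact expected values
    (fractional, for noise-free recovery benchmarks).
    """
    rng = _rng(config, "timecourse")
    times = np.asarray(config.timepoints, dtype=float)
    sample_ids = [f"{config.cell_line}_t{_format_tp(t)}h" for t in times]

    k = truth.table["k_true"].to_numpy()
    y_eq = truth.table["y_eq_true"].to_numpy()
    mu_human = y_eq[:, None] * (1.0 - np.exp(-np.outer(k, times)))

    n_rows = config.n_spike_rows
    dmel_ids = [f"spike_dmel|{i:02d}" for i in range(n_rows)]
    scer_ids = [f"spike_scer|{i:02d}" for i in range(n_rows)]
    mu_dmel = np.full((n_rows, len(times)), config.depth * config.spike_fraction / n_rows)
    mu_scer = np.full((n_rows, len(times)), config.depth * config.scer_fraction / n_rows)

    mu = np.vstack([mu_human, mu_dmel, mu_scer])
    index = list(truth.table.index) + dmel_ids + scer_ids
    if config.noise_model == "poisson":
        values = rng.poisson(mu).astype(np.int64)
    else:
        values = mu
    counts = pd.DataFrame(values, index=index, columns=sample_ids)
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "cell_line": config.cell_line,
        "timepoint_h": times,
        "treatment": "none",
    }).set_index("sample_id", drop=False)
    return TimeCourseCounts(counts=counts, sample_meta=meta)


# ---------------------------------------------------------------------------
# ribosome footprints
# ---------------------------------------------------------------------------

READ_LENGTHS = np.array([28, 29, 30], dtype=np.int64)
_A_OFFSET = 16  # A site at read positions 17-19 (1-based)


def simulate_footprints(cds_set: dict[str, str], truth: SyntheticTruth,
                        n_reads: int, config: SimulationConfig,
                        allow_stop_site: bool = False) -> FootprintTable:
    """Sample footprint reads with dwell-weighted A-site codon occupancy.

    The A-site codon (transcript g, codon index i) is drawn with probability
    proportional to abundance_g * dwell(codon at i) over all placeable
    positions; read length is uniform on {28, 29, 30} and the 5' end is
    ``3*i - 16`` so the codon sits at read positions 17–19. By default reads
    are kept fully inside the CDS; with ``allow_stop_site=True`` the 3' end
    may overhang (terminating-ribosome footprints), letting the A site reach
    the stop codon. Codon positions that cannot host a read (near the CDS
    ends) are excluded up front; their number is recorded in
    ``n_positions_skipped`` on the returned table.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = _rng(config, "footprints")
    dwell = truth.dwell_multipliers
    abundance = truth.table["abundance"]

    tx_arr: list[str] = []
    fp_arr: list[int] = []
    wt_arr: list[float] = []
    n_skipped = 0
    for tid in truth.table.index:
        seq = cds_set[tid]
        L = len(seq)
        n_codons = L // 3
        ci_min = int(math.ceil(_A_OFFSET / 3))  # first codon with 5' end >= 0
        if allow_stop_site:
            ci_max = n_codons - 1
        else:
            ci_max = (L - int(READ_LENGTHS.max()) + _A_OFFSET) // 3
        n_skipped += n_codons - max(0, ci_max - ci_min + 1)
        if ci_max < ci_min:
            continue
        a = float(abundance[tid])
        for ci in range(ci_min, ci_max + 1):
            codon = seq[3 * ci:3 * ci + 3]
            tx_arr.append(tid)
            fp_arr.append(3 * ci - _A_OFFSET)
            wt_arr.append(a * float(dwell[codon]))
    if not tx_arr:
        raise ValueError("no placeable footprint positions (transcripts too short)")

    p = np.asarray(wt_arr)
    p = p / p.sum()
    idx = rng.choice(len(p), size=n_reads, p=p)
    lengths = rng.choice(READ_LENGTHS, size=n_reads)
    reads = pd.DataFrame({
        "transcript_id": np.asarray(tx_arr, dtype=object)[idx],
        "five_prime_pos": np.asarray(fp_arr, dtype=np.int64)[idx],
        "read_length": lengths,
    })
    table = FootprintTable(reads=reads)
    table.n_positions_skipped = n_skipped  # type: ignore[attr-defined]
    return table


# ---------------------------------------------------------------------------
# steady-state libraries with a planted classification design
# ---------------------------------------------------------------------------

def simulate_steady_state(truth: SyntheticTruth, config: SimulationConfig,
                          *, fail_fold_fraction: float = 0.15,
                          fail_min_fraction: float = 0.10,
                          fold: float = 3.0, min_norm: float = 4.0
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-line steady-state counts with planted pass/fail reporter status.

    Pool members of each line are planted as "pass" (over-expressed in their
    own line beyond both thresholds), "fail_fold" (expressed within ``fold``x
    of the paired line), or "fail_min" (at or below ``min_norm`` normalized
    reads). Library totals of the two lines are equalized with a filler row,
    so library-size normalization is the identity and the planted arithmetic
    is exact. Three deterministic boundary transcripts (exactly at the fold
    and minimum-count thresholds) are always included.

    Returns (counts [transcripts x {line_A, line_B}], expected labels per
    line as a DataFrame with columns label_line_A, label_line_B).
    """
    rng = _rng(config, "steady")
    ids = list(truth.table.index)
    pool = truth.table["pool_label"]
    counts = pd.DataFrame(0.0, index=ids, columns=["line_A", "line_B"])
    expected = pd.DataFrame("endogenous", index=ids,
                            columns=["label_line_A", "label_line_B"])

    for tid in ids:
        lab = pool[tid]
        if lab == "none":
            level = rng.uniform(20.0, 200.0)
            counts.loc[tid] = [level, level]
            # expected stays endogenous in both lines
            continue
        self_col, other_col = ("line_A", "line_B") if lab == "pool_A" else ("line_B", "line_A")
        self_lab, other_lab = (("label_line_A", "label_line_B") if lab == "pool_A"
                               else ("label_line_B", "label_line_A"))
        u = rng.uniform()
        if u < fail_fold_fraction:
            hi = rng.uniform(10.0, 100.0)
            counts.loc[tid, self_col] = hi
            counts.loc[tid, other_col] = hi / 2.0      # within fold threshold
            expected.loc[tid, self_lab] = "excluded"
        elif u < fail_fold_fraction + fail_min_fraction:
            counts.loc[tid, self_col] = rng.uniform(0.0, min_norm)  # <= 4 reads
            counts.loc[tid, other_col] = 0.0
            expected.loc[tid, self_lab] = "excluded"
        else:
            hi = rng.uniform(2.0 * min_norm, 200.0)
            counts.loc[tid, self_col] = hi
            counts.loc[tid, other_col] = hi / (2.0 * fold)  # comfortably past fold
            expected.loc[tid, self_lab] = "orfeome"
        expected.loc[tid, other_lab] = "excluded"  # member of the paired pool

    # deterministic boundary cases in line A's pool
    boundary = pd.DataFrame(
        {"line_A": [min_norm * 2.5, 3.0 * fold, min_norm],
         "line_B": [2.0, 3.0, 0.0]},
        index=["bnd_pass", "bnd_fold", "bnd_min"],
    )
    counts = pd.concat([counts, boundary])
    expected = pd.concat([expected, pd.DataFrame(
        {"label_line_A": ["orfeome", "excluded", "excluded"],
         "label_line_B": ["excluded", "excluded", "excluded"]},
        index=boundary.index)])

    # equalize library totals so normalization is the identity
    totals = counts.sum(axis=0)
    filler = float(totals.max() + 100.0)
    counts.loc["tx_filler"] = [filler - totals["line_A"], filler - totals["line_B"]]
    expected.loc["tx_filler"] = ["endogenous", "endogenous"]
    return counts, expected


def planted_pools(truth: SyntheticTruth) -> dict[str, set[str]]:
    """Pool registries matching :func:`simulate_steady_state`."""
    pool = truth.table["pool_label"]
    pools = {
        "line_A": set(pool.index[pool == "pool_A"]) | {"bnd_pass", "bnd_fold", "bnd_min"},
        "line_B": set(pool.index[pool == "pool_B"]),
    }
    return pools


def depth_for_median_count(target_median: float, config: SimulationConfig) -> float:
    """Depth giving the requested median expected steady-state human count.

    Uses the lognormal abundance model: the median transcript abundance is
    approximately exp(-sd^2/2)/n of the total, so depth scales accordingly.
    """
    human_share = 1.0 - config.spike_fraction - config.scer_fraction
    med_abundance = math.exp(-config.abundance_sd ** 2 / 2.0) / config.n_transcripts
    return target_median / (human_share * med_abundance)
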