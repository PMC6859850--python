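"""Readers and writers for the tabular and sequence formats used by the pipeline.

All tables are TSV: header line, tab delimiter, UTF-8, ``NA`` for missing
values. Writers may prepend ``#``-prefixed provenance comment lines, which
every reader skips. Footprints are expressed in transcript (CDS) coordinates,
0-based: a transcriptome SAM record with RNAME=transcript and 1-based POS maps
to ``five_prime_pos = POS - 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: read lengths retained for ribosome-footprint analyses (nt)
FOOTPRINT_LENGTHS = (28, 29, 30)

#: row-id prefixes marking spike-in rows in count tables
SPIKE_PREFIXES = ("spike_dmel|", "spike_scer|")

_NA = "NA"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read CDS records from a FASTA file.

    Sequences are uppercased. Raises on duplicate ids or an empty file;
    warns (does not error) when a sequence length is not divisible by 3.

    Returns
    -------
    dict mapping record id to uppercase DNA sequence, in file order.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"record {rec.id!r}: non-DNA characters {sorted(bad)}")
        if len(seq) % 3 != 0:
            warnings.warn(f"record {rec.id!r}: length {len(seq)} not divisible by 3")
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    """Write one uppercase-DNA record per transcript."""
    SeqIO.write(
        (SeqRecord(Seq(seq.upper()), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# generic TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[_NA],
                       keep_default_na=False, **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, *, index: bool = False,
              provenance: list[str] | None = None) -> None:
    """Write a DataFrame in the package's fixed TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in provenance or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep=_NA)


# ---------------------------------------------------------------------------
# sample sheets and time-course count tables
# ---------------------------------------------------------------------------

SAMPLESHEET_COLUMNS = ("sample_id", "cell_line", "timepoint_h", "treatment")


def read_samplesheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet (YAML list-of-dicts or TSV) into a DataFrame.

    Columns: sample_id, cell_line, timepoint_h (hours, or "steady_state"),
    treatment. Indexed by sample_id.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path, encoding="utf-8") as fh:
            rows = yaml.safe_load(fh)
        meta = pd.DataFrame(rows)
    else:
        meta = _read_tsv(path)
    missing = set(SAMPLESHEET_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("sample sheet contains duplicate sample_id values")
    return meta.set_index("sample_id", drop=False)


def write_samplesheet(meta: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        rows = meta.reset_index(drop=True).to_dict(orient="records")
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(rows, fh, sort_keys=False)
    else:
        write_tsv(meta.reset_index(drop=True), path)


@dataclass
class TimeCourseCounts:
    """A transcript x sample count matrix from a metabolic-labeling time course.

    ``counts`` rows include exogenous spike-in transcripts (row ids prefixed
    ``spike_dmel|`` for the labeled fly spike and ``spike_scer|`` for the
    unlabeled yeast QC spike). ``sample_meta`` is indexed by sample id with
    columns cell_line, timepoint_h (hours or "steady_state"), treatment.

    Counts are integer read counts on disk; in-memory matrices of expected
    (fractional) counts from noise-free simulations are also accepted.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if (np.asarray(self.counts.values, dtype=float) < 0).any():
            raise ValueError("negative counts")

    @property
    def spike_rows(self) -> list[str]:
        """Row ids of all spike-in rows (fly and yeast)."""
        return [r for r in self.counts.index if r.startswith(SPIKE_PREFIXES)]

    @property
    def human_rows(self) -> list[str]:
        return [r for r in self.counts.index if not r.startswith(SPIKE_PREFIXES)]

    def human_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.human_rows]

    def labeled_samples(self, cell_line: str | None = None) -> pd.DataFrame:
        """Metadata of labeled (numeric-timepoint) samples, sorted by time."""
        meta = self.sample_meta
        tp = pd.to_numeric(meta["timepoint_h"], errors="coerce")
        sel = tp.notna()
        if cell_line is not None:
            sel &= meta["cell_line"] == cell_line
        out = meta[sel].copy()
        out["timepoint_h"] = tp[sel]
        return out.sort_values("timepoint_h")

    def validate_timepoint_coverage(self, min_timepoints: int = 4) -> None:
        for line, meta in self.labeled_samples().groupby("cell_line"):
            n = meta["timepoint_h"].nunique()
            if n < min_timepoints:
                raise ValueError(
                    f"cell line {line!r} has only {n} distinct labeled time points "
                    f"(need >= {min_timepoints})"
                )


def read_timecourse(counts_path: str | Path, samplesheet_path: str | Path) -> TimeCourseCounts:
    """Read a count table plus sample sheet into a validated TimeCourseCounts.

    The first column of the count table holds transcript ids; remaining
    columns are samples and must all appear in the sample sheet. Counts must
    be non-negative integers.
    """
    raw = _read_tsv(counts_path)
    raw = raw.set_index(raw.columns[0])
    meta = read_samplesheet(samplesheet_path)
    missing = set(raw.columns) - set(meta.index)
    if missing:
        raise ValueError(f"count columns absent from sample sheet: {sorted(missing)}")
    values = raw.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values in count table")
    if (values < 0).any():
        raise ValueError("negative counts in count table")
    if not np.array_equal(values, np.floor(values)):
        raise ValueError("non-integer counts in count table")
    counts = pd.DataFrame(values.astype(np.int64), index=raw.index, columns=raw.columns)
    tc = TimeCourseCounts(counts=counts, sample_meta=meta.loc[list(raw.columns)])
    tc.validate_timepoint_coverage()
    return tc


def write_timecourse(tc: TimeCourseCounts, counts_path: str | Path,
                     samplesheet_path: str | Path | None = None,
                     provenance: list[str] | None = None) -> None:
    df = tc.counts.copy()
    df.index.name = "transcript_id"
    write_tsv(df, counts_path, index=True, provenance=provenance)
    if samplesheet_path is not None:
        write_samplesheet(tc.sample_meta, samplesheet_path)


# ---------------------------------------------------------------------------
# footprint tables
# ---------------------------------------------------------------------------

@dataclass
class FootprintTable:
    """Ribosome-footprint reads in CDS coordinates.

    Columns: transcript_id, five_prime_pos (0-based offset of the read 5' end
    within the CDS), read_length (nt, in {28, 29, 30}). Reads from terminating
    ribosomes may extend past the CDS 3' end; downstream site assignment
    requires the ribosomal site itself to lie inside the CDS.
    """

    reads: pd.DataFrame
    n_rejected: int = 0

    COLUMNS = ("transcript_id", "five_prime_pos", "read_length")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.reads.columns)
        if missing:
            raise ValueError(f"footprint table missing columns: {sorted(missing)}")
        self.reads = self.reads.loc[:, list(self.COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.reads)


def read_footprints(path: str | Path) -> FootprintTable:
    """Read a footprint TSV, rejecting (with a warning and a count) rows whose
    read_length is outside {28, 29, 30} or whose five_prime_pos is negative."""
    df = _read_tsv(path, dtype={"transcript_id": str})
    missing = set(FootprintTable.COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"footprint table missing columns: {sorted(missing)}")
    ok = df["read_length"].isin(FOOTPRINT_LENGTHS) & (df["five_prime_pos"] >= 0)
    n_rej = int((~ok).sum())
    if n_rej:
        warnings.warn(f"rejected {n_rej} footprint rows (bad read_length or position)")
    kept = df[ok].copy()
    kept["five_prime_pos"] = kept["five_prime_pos"].astype(np.int64)
    kept["read_length"] = kept["read_length"].astype(np.int64)
    return FootprintTable(reads=kept, n_rejected=n_rej)


def write_footprints(fp: FootprintTable, path: str | Path,
                     provenance: list[str] | None = None) -> None:
    write_tsv(fp.reads, path, provenance=provenance)


# ---------------------------------------------------------------------------
# truth tables (synthetic ground truth)
# ---------------------------------------------------------------------------

def write_truth_tables(truth, prefix: str | Path) -> None:
    """Write a SyntheticTruth as ``<prefix>.transcripts.tsv`` and
    ``<prefix>.codons.tsv`` (latent per-codon weights and dwell multipliers)."""
    prefix = str(prefix)
    tx = truth.table.copy()
    tx.index.name = "transcript_id"
    write_tsv(tx, prefix + ".transcripts.tsv", index=True)
    codons = pd.DataFrame({
        "codon_weight": truth.codon_weights,
        "dwell_multiplier": truth.dwell_multipliers,
    })
    codons.index.name = "codon"
    write_tsv(codons, prefix + ".codons.tsv", index=True)


def read_truth_tables(prefix: str | Path):
    """Round-trip counterpart of :func:`write_truth_tables`."""
    from .synthetic_data import SyntheticTruth

    prefix = str(prefix)
    tx = _read_tsv(prefix + ".transcripts.tsv").set_index("transcript_id")
    codons = _read_tsv(prefix + ".codons.tsv").set_index("codon")
    return SyntheticTruth(
        table=tx,
        codon_weights=codons["codon_weight"].dropna(),
        dwell_multipliers=codons["dwell_multiplier"],
    )
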