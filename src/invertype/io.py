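"""Tab-separated input/output for the pipeline's tabular data.

All tables use 1-based, fully-closed genomic coordinates (the pileup
convention).  Schemas:

``panel``
    ``inversion_id  chrom  pos  allele_A  allele_B`` — one row per
    inversion-diagnostic biallelic site.  ``allele_A`` tags the reference
    (ancestral-arrangement) haplotype, ``allele_B`` the alternative
    (inverted) haplotype.

``frequencies``
    ``population  inversion_id  freq_B`` — frequency of haplotype B in each
    candidate population, one row per (population, inversion) pair.

``observations``
    ``specimen  chrom  pos  base  dist5  dist3  read_len`` — one row per
    read overlapping a panel site.  ``dist5``/``dist3`` are the distances
    (in bases, 0-based) of the site from the 5' and 3' ends of the read;
    ``dist5 + dist3 == read_len - 1``.

``truth``
    ``specimen  population  inversion_id  genotype  true_cal_age`` —
    simulation ground truth.

``dates``
    ``specimen  c14_age  sigma  delta_r  sigma_delta_r`` — uncalibrated
    radiocarbon determinations with their reservoir offsets.

Producing an observations table from aligned reads: for every read in a BAM
that overlaps a panel site, record the read base at the site, its distance
from each read end, and the read length — e.g. via ``pysam``'s
``get_aligned_pairs`` or by post-processing ``samtools mpileup`` output
(mpileup alone does not report per-base distances from the read termini, so
a BAM-level pass is required).  BAM parsing is deliberately not a dependency
of this package; see :func:`observations_from_bam`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

PathLike = Union[str, Path]

VALID_BASES = frozenset("ACGT")

PANEL_COLUMNS = ["inversion_id", "chrom", "pos", "allele_A", "allele_B"]
FREQ_COLUMNS = ["population", "inversion_id", "freq_B"]
OBS_COLUMNS = ["specimen", "chrom", "pos", "base", "dist5", "dist3", "read_len"]
TRUTH_COLUMNS = ["specimen", "population", "inversion_id", "genotype", "true_cal_age"]
DATES_COLUMNS = ["specimen", "c14_age", "sigma", "delta_r", "sigma_delta_r"]
CALLS_COLUMNS = [
    "specimen", "inversion_id", "p_AA", "p_AB", "p_BB",
    "hard_call", "n_sites_used", "n_reads_used",
]


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns {missing}")


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check SNP-panel invariants; returns the (unmodified) frame."""
    _require_columns(panel, PANEL_COLUMNS, "panel")
    if len(panel) == 0:
        raise ValueError("panel has no sites")
    bad = ~(panel["allele_A"].isin(VALID_BASES) & panel["allele_B"].isin(VALID_BASES))
    if bad.any():
        raise ValueError("panel contains invalid allele characters")
    if (panel["allele_A"] == panel["allele_B"]).any():
        raise ValueError("panel sites must have two distinct alleles")
    if (panel["pos"] < 1).any():
        raise ValueError("panel positions are 1-based and must be >= 1")
    if panel.duplicated(subset=["inversion_id", "chrom", "pos"]).any():
        raise ValueError("duplicate (chrom, pos) within an inversion")
    return panel


def validate_frequencies(freqs: pd.DataFrame) -> pd.DataFrame:
    _require_columns(freqs, FREQ_COLUMNS, "frequency")
    if freqs.duplicated(subset=["population", "inversion_id"]).any():
        raise ValueError("duplicate (population, inversion) pair in frequency table")
    f = freqs["freq_B"]
    if ((f < 0) | (f > 1)).any():
        raise ValueError("freq_B values must lie in [0, 1]")
    return freqs


def validate_observations(obs: pd.DataFrame) -> pd.DataFrame:
    _require_columns(obs, OBS_COLUMNS, "observations")
    if len(obs) == 0:
        return obs
    if not obs["base"].isin(VALID_BASES).all():
        raise ValueError("observations contain invalid base characters")
    if ((obs["dist5"] < 0) | (obs["dist3"] < 0) | (obs["read_len"] < 1)).any():
        raise ValueError("negative distances or non-positive read length")
    if ((obs["dist5"] + obs["dist3"]) != (obs["read_len"] - 1)).any():
        raise ValueError("dist5 + dist3 must equal read_len - 1")
    return obs


def validate_dates(dates: pd.DataFrame) -> pd.DataFrame:
    _require_columns(dates, DATES_COLUMNS, "dates")
    if (dates["sigma"] <= 0).any():
        raise ValueError("measurement sigma must be positive")
    if (dates["sigma_delta_r"] < 0).any():
        raise ValueError("sigma_delta_r must be non-negative")
    return dates


def read_panel(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"inversion_id": str, "chrom": str,
                                            "allele_A": str, "allele_B": str})
    return validate_panel(df)


def read_frequencies(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"population": str, "inversion_id": str})
    return validate_frequencies(df)


def read_observations(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"specimen": str, "chrom": str, "base": str},
    )
    return validate_observations(df)


def read_truth(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"specimen": str, "population": str,
                                            "inversion_id": str, "genotype": str})
    _require_columns(df, TRUTH_COLUMNS, "truth")
    return df


def read_dates(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"specimen": str})
    return validate_dates(df)


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    """Write any pipeline table as TSV (header, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def observations_from_bam(*args, **kwargs):  # pragma: no cover - documented stub
    """Stub: extract panel-site observations from an indexed BAM.

    Not implemented here to keep alignment-format parsing out of the core
    dependency set.  With ``pysam`` installed the conversion is::

        for site in panel: for each read in bam.fetch(chrom, pos-1, pos):
            find the query offset q aligned to pos (get_aligned_pairs),
            emit (specimen, chrom, pos, read.query_sequence[q],
                  dist5=q, dist3=read.query_length-1-q,
                  read_len=read.query_length)

    (swap dist5/dist3 for reverse-strand reads).
    """
    raise NotImplementedError(
        "BAM conversion is intentionally not bundled; see the docstring for "
        "the pysam recipe that produces the observations TSV."
    )
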