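"""Stage 2: transcript-locus peak calling against a knockout control.

Per canonical transcript, IP coverage (RPM, no mean scaling) is divided
by knockout coverage plus a global pseudocount of 5; positions in the
bottom 3% of cumulative IP signal at the locus are set to fold 1.
Candidate peaks are maximal runs of more than 20 consecutive positions
exceeding twofold enrichment with mean IP RPM above 10. Significance is
a one-sided Poisson test on the IP read count overlapping the run, with
expected count taken from the (pseudocounted) knockout read count scaled
by the library-size ratio; q-values are Benjamini-Hochberg across all
candidate peaks of a condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import (
    CoverageTrack,
    ReadInterval,
    coverage_from_reads,
    group_by_reference,
    rpm_normalize,
)
from .enrichment import low_signal_mask
from .params import PipelineParams

PEAK_COLUMNS = [
    "locus",
    "start_1based",
    "end_1based",
    "length",
    "mean_fold",
    "mean_rpm",
    "observed",
    "lam",
    "p",
    "q",
]


@dataclass(frozen=True)
class Peak:
    """A called interval, 1-based inclusive on the transcript."""

    locus: str
    start: int
    end: int
    mean_fold: float
    mean_rpm: float
    observed: int
    lam: float
    p: float
    q: float


def ko_fold_track(
    ip_rpm: CoverageTrack,
    ko_rpm: CoverageTrack,
    global_pc: float,
    low_signal_fraction: float = 0.0,
) -> np.ndarray:
    """fold[i] = ip[i] / (ko[i] + global_pc), low-signal positions -> 1.

    The low-signal filter is the per-locus 3% cumulative-coverage rule
    applied to the IP RPM track.
    """
    if ip_rpm.length != ko_rpm.length:
        raise ValueError(f"length mismatch: ip {ip_rpm.length} vs ko {ko_rpm.length}")
    if global_pc <= 0:
        raise ValueError("global pseudocount must be > 0")
    fold = ip_rpm.counts / (ko_rpm.counts + global_pc)
    if low_signal_fraction > 0:
        fold[low_signal_mask(ip_rpm, low_signal_fraction)] = 1.0
    return fold


def candidate_runs(
    fold: np.ndarray, ip_rpm: np.ndarray, params: PipelineParams
) -> list[tuple[int, int]]:
    """Maximal runs of fold > peak_min_fold, kept when longer than 20 nt
    and mean IP RPM over the run exceeds peak_min_rpm.

    Returns 0-based half-open (start, end) intervals. Both thresholds
    are strict: a run of exactly 20 positions, or fold exactly at the
    cutoff, does not qualify.
    """
    fold = np.asarray(fold, float)
    ip_rpm = np.asarray(ip_rpm, float)
    if fold.size != ip_rpm.size:
        raise ValueError("fold and ip_rpm must have equal length")
    qualifying = fold > params.peak_min_fold
    padded = np.concatenate(([False], qualifying, [False])).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    runs = []
    for s, e in zip(starts, ends):
        if e - s >= params.peak_min_run and ip_rpm[s:e].mean() > params.peak_min_rpm:
            runs.append((int(s), int(e)))
    return runs


def poisson_upper_p(observed: int, lam: float) -> float:
    """One-sided upper-tail Poisson p-value, P(X >= observed)."""
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, lam))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q for the i-th smallest p is min over ranks j >= i of p_(j) * n / j,
    capped at 1. Ties are handled by a stable sort; tied p-values always
    receive identical q-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * (n / np.arange(1, n + 1))
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def _count_overlapping(reads: Sequence[ReadInterval], start: int, end: int) -> int:
    """Number of reads overlapping 0-based half-open [start, end)."""
    return sum(1 for r in reads if r.start < end and r.end > start)


def peak_statistics(
    run: tuple[int, int],
    ip_reads: Sequence[ReadInterval],
    ko_reads: Sequence[ReadInterval],
    ip_lib: float,
    ko_lib: float,
    global_pc: float,
) -> tuple[int, float]:
    """Observed IP read count over a run and its Poisson expectation.

    lambda = (knockout reads overlapping the run + global pseudocount)
    scaled by the IP/knockout library-size ratio. Read counts, not
    coverage sums, keep the Poisson variance assumption: summing
    coverage would inflate dispersion by roughly the read length.
    """
    if ko_lib <= 0:
        raise ValueError("knockout library size must be > 0")
    if ip_lib <= 0:
        raise ValueError("IP library size must be > 0")
    start, end = run
    observed = _count_overlapping(ip_reads, start, end)
    ko_count = _count_overlapping(ko_reads, start, end)
    lam = (ko_count + global_pc) * ip_lib / ko_lib
    return observed, lam


def call_peaks(
    ip_reads: Mapping[str, Sequence[ReadInterval]] | Sequence[ReadInterval],
    ko_reads: Mapping[str, Sequence[ReadInterval]] | Sequence[ReadInterval],
    ip_lib: float,
    ko_lib: float,
    transcripts: pd.DataFrame,
    params: PipelineParams | None = None,
    *,
    count_mode: str = "reads",
) -> pd.DataFrame:
    """Call peaks over every canonical transcript of one condition.

    Reads may be supplied as a flat list or pre-grouped by reference.
    ``transcripts`` is the annotation table (gene_id, transcript_id,
    canonical, strand, len_5utr, len_cds, len_3utr); only canonical
    entries are scanned. ``count_mode`` selects the Poisson count
    definition: "reads" (default; reads overlapping the run) or
    "coverage" (rounded coverage sums, for comparison only).

    Returns a peak table sorted by (q, locus, start), coordinates
    1-based inclusive, with every row satisfying the strict fold / RPM /
    length thresholds.
    """
    params = params or PipelineParams()
    if count_mode not in ("reads", "coverage"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    if ko_lib <= 0:
        raise ValueError("missing or empty knockout sample")
    ip_reads_by_ref = ip_reads if hasattr(ip_reads, "get") else group_by_reference(ip_reads)
    ko_reads_by_ref = ko_reads if hasattr(ko_reads, "get") else group_by_reference(ko_reads)

    rows: list[dict] = []
    canonical = transcripts[transcripts["canonical"] == 1]
    for _, tx in canonical.iterrows():
        tx_id = tx["transcript_id"]
        length = int(tx["len_5utr"] + tx["len_cds"] + tx["len_3utr"])
        ip_reads = list(ip_reads_by_ref.get(tx_id, ()))
        ko_reads = list(ko_reads_by_ref.get(tx_id, ()))
        ip_rpm = rpm_normalize(
            coverage_from_reads(ip_reads, length, library_size=ip_lib)
            if ip_reads
            else CoverageTrack(tx_id, np.zeros(length), ip_lib)
        )
        ko_rpm = rpm_normalize(
            coverage_from_reads(ko_reads, length, library_size=ko_lib)
            if ko_reads
            else CoverageTrack(tx_id, np.zeros(length), ko_lib)
        )
        fold = ko_fold_track(ip_rpm, ko_rpm, params.global_pseudocount, params.low_signal_fraction)
        for start, end in candidate_runs(fold, ip_rpm.counts, params):
            if count_mode == "reads":
                observed, lam = peak_statistics(
                    (start, end), ip_reads, ko_reads, ip_lib, ko_lib, params.global_pseudocount
                )
            else:
                raw_ip = coverage_from_reads(ip_reads, length, library_size=ip_lib)
                raw_ko = coverage_from_reads(ko_reads, length, library_size=ko_lib)
                observed = int(round(raw_ip.counts[start:end].sum()))
                lam = (raw_ko.counts[start:end].sum() + params.global_pseudocount) * ip_lib / ko_lib
            rows.append(
                {
                    "locus": tx_id,
                    "start_1based": start + 1,
                    "end_1based": end,
                    "length": end - start,
                    "mean_fold": fold[start:end].mean(),
                    "mean_rpm": ip_rpm.counts[start:end].mean(),
                    "observed": observed,
                    "lam": lam,
                    "p": poisson_upper_p(observed, lam),
                }
            )
    peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS[:-1])
    peaks["q"] = bh_adjust(peaks["p"].to_numpy()) if len(peaks) else np.array([])
    peaks = peaks.sort_values(["q", "locus", "start_1based"], kind="mergesort").reset_index(
        drop=True
    )
    return peaks


def significant_peaks(peaks: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Rows with q below the FDR threshold."""
    return peaks[peaks["q"] < fdr].reset_index(drop=True)


def peaks_to_bed(peaks: pd.DataFrame) -> str:
    """Significant-peak table as BED6 text (0-based half-open)."""
    lines = []
    for i, row in peaks.iterrows():
        lines.append(
            f"{row['locus']}\t{row['start_1based'] - 1}\t{row['end_1based']}\t"
            f"peak{i}\t{min(1000, int(-10 * np.log10(max(row['q'], 1e-300))))}\t+"
        )
    return "\n".join(lines) + ("\n" if lines else "")
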