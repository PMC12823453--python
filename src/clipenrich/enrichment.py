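"""Stage 1: control-normalized per-nucleotide fold enrichment on rRNA.

The track answers "how much more CLIP signal does the IP sample carry at
this nucleotide than a non-binding truncation control?". Both samples
are RPM-normalized, mean-scaled over the reference, and divided
position-wise with a pseudocount in the denominator equal to the 0.1
percentile of the control coverage. Positions holding the bottom 3% of
cumulative IP coverage are masked (fold forced to 1), and the track is
smoothed with a centered rolling mean of window 10 for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, rpm_normalize
from .params import PipelineParams, RegionAnnotation


@dataclass
class EnrichmentTrack:
    """Per-position fold enrichment with its low-signal mask.

    ``fold`` is the unsmoothed ratio (masked positions exactly 1);
    ``smoothed`` is its rolling mean. ``mask`` is True where the
    position was removed by the cumulative low-signal filter.
    """

    reference_name: str
    fold: np.ndarray
    mask: np.ndarray
    smoothed: np.ndarray

    def __post_init__(self) -> None:
        self.fold = np.asarray(self.fold, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.smoothed = np.asarray(self.smoothed, dtype=float)
        if not (self.fold.size == self.mask.size == self.smoothed.size):
            raise ValueError("fold, mask and smoothed must have equal length")
        if np.any(self.fold < 0):
            raise ValueError("fold enrichment must be >= 0")
        if not np.all(self.fold[self.mask] == 1.0):
            raise ValueError("masked positions must have fold exactly 1")

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready table with 1-based positions."""
        return pd.DataFrame(
            {
                "pos_1based": np.arange(1, self.fold.size + 1),
                "fold": self.fold,
                "masked": self.mask.astype(int),
                "smoothed": self.smoothed,
            }
        )


def mean_scale(track: CoverageTrack) -> CoverageTrack:
    """Divide an RPM track by its mean so the regional mean is 1."""
    if track.units != "rpm":
        raise ValueError(f"mean_scale expects rpm units, got {track.units!r}")
    m = track.counts.mean()
    if m == 0:
        raise ValueError("all-zero track: cannot mean-scale")
    from dataclasses import replace

    return replace(track, counts=track.counts / m, units="mean_scaled")


def pseudocount_from_quantile(control: np.ndarray | CoverageTrack, q: float) -> float:
    """Denominator pseudocount: the q-quantile of the control coverage.

    Uses linear-interpolation quantiles (the common "type 7" default).
    A sparse control can make the 0.1 percentile exactly 0, which would
    defeat the divide-by-zero protection, so 0 falls back to the
    smallest strictly positive value, and an all-zero control to 1.
    """
    values = control.counts if isinstance(control, CoverageTrack) else np.asarray(control, float)
    if values.size == 0:
        raise ValueError("empty control track")
    pc = float(np.quantile(values, q))
    if pc > 0:
        return pc
    positive = values[values > 0]
    if positive.size:
        warnings.warn(
            f"{q:g}-quantile pseudocount is 0; falling back to smallest positive value",
            stacklevel=2,
        )
        return float(positive.min())
    warnings.warn("all-zero control; pseudocount falls back to 1", stacklevel=2)
    return 1.0


def fold_enrichment(
    ip: np.ndarray | CoverageTrack, control: np.ndarray | CoverageTrack, pc: float
) -> np.ndarray:
    """fold[i] = ip[i] / (control[i] + pc)."""
    a = ip.counts if isinstance(ip, CoverageTrack) else np.asarray(ip, float)
    b = control.counts if isinstance(control, CoverageTrack) else np.asarray(control, float)
    if a.size != b.size:
        raise ValueError(f"length mismatch: ip {a.size} vs control {b.size}")
    if pc <= 0:
        raise ValueError("pseudocount must be > 0")
    return a / (b + pc)


def low_signal_mask(signal: np.ndarray | CoverageTrack, fraction: float) -> np.ndarray:
    """Mask positions holding the bottom ``fraction`` of cumulative signal.

    Positions are sorted by ascending signal (ties by ascending index)
    and the maximal prefix whose cumulative sum is strictly below
    ``fraction`` x total is masked. Masked folds are later set to 1.
    """
    values = signal.counts if isinstance(signal, CoverageTrack) else np.asarray(signal, float)
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    mask = np.zeros(values.size, dtype=bool)
    if fraction == 0.0 or values.size == 0:
        return mask
    order = np.lexsort((np.arange(values.size), values))  # value asc, index asc
    cumulative = np.cumsum(values[order])
    keep = cumulative < fraction * values.sum()
    mask[order[keep]] = True
    return mask


def rolling_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean; the window shrinks at the edges.

    Position i averages indices [i - ceil(w/2) + 1, i + floor(w/2)]
    intersected with the valid range, so even windows extend one
    position further to the right.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        return v.copy()
    cs = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - int(np.ceil(window / 2)) + 1)
    hi = np.minimum(n, idx + window // 2 + 1)
    return (cs[hi] - cs[lo]) / (hi - lo)


def rrna_enrichment_pipeline(
    ip_raw: CoverageTrack,
    control_raw: CoverageTrack,
    params: PipelineParams | None = None,
    annotation: RegionAnnotation | None = None,
) -> tuple[EnrichmentTrack, pd.DataFrame]:
    """Raw IP + truncation-control tracks -> smoothed enrichment track.

    Steps: RPM-normalize both; mean-scale both over the reference;
    pseudocount from the control's 0.1 percentile; position-wise ratio;
    low-signal mask computed on the IP RPM track; masked fold set to 1;
    rolling-average smoothing. The summary table reports max and mean of
    the raw and smoothed fold per annotated region (1-based inclusive
    coordinates).
    """
    params = params or PipelineParams()
    annotation = annotation or RegionAnnotation()
    if ip_raw.length != control_raw.length:
        raise ValueError(
            f"length mismatch: ip {ip_raw.length} vs control {control_raw.length}"
        )
    annotation.validate_against(ip_raw.length)

    ip_rpm = rpm_normalize(ip_raw)
    control_rpm = rpm_normalize(control_raw)
    ip_ms = mean_scale(ip_rpm)
    control_ms = mean_scale(control_rpm)
    pc = pseudocount_from_quantile(control_ms, params.pseudocount_quantile)
    fold = fold_enrichment(ip_ms, control_ms, pc)
    mask = low_signal_mask(ip_rpm, params.low_signal_fraction)
    fold[mask] = 1.0
    smoothed = rolling_average(fold, params.rrna_smooth_window)
    track = EnrichmentTrack(ip_raw.reference_name, fold, mask, smoothed)

    rows = []
    for name, (start1, end1) in annotation.items():
        sl = slice(start1 - 1, end1)
        rows.append(
            {
                "region": name,
                "start_1based": start1,
                "end_1based": end1,
                "max_fold": fold[sl].max(),
                "mean_fold": fold[sl].mean(),
                "max_smoothed": smoothed[sl].max(),
                "mean_smoothed": smoothed[sl].mean(),
            }
        )
    return track, pd.DataFrame(rows)


def average_enrichment(tracks: list[EnrichmentTrack]) -> np.ndarray:
    """Mean smoothed fold across replicate tracks (fold computed per
    replicate first, then averaged)."""
    if not tracks:
        raise ValueError("no tracks to average")
    return np.mean([t.smoothed for t in tracks], axis=0)
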