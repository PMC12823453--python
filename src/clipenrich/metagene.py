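"""Stage 3: region-scaled metagene profiles normalized to a knockout.

Each retained transcript's 5'UTR, CDS and 3'UTR coverage is linearly
interpolated onto 100 standardized positions per region and the three
regions concatenated into a 300-position axis (0-100 5'UTR, 100-200 CDS,
200-300 3'UTR). Profiles are averaged over transcripts with equal
weight, divided by the knockout profile position-wise, and smoothed with
a rolling mean of window 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .enrichment import pseudocount_from_quantile, rolling_average
from .params import PipelineParams

N_BINS = 300


@dataclass(frozen=True)
class TranscriptModel:
    """Region extents of one transcript, 5' to 3' in nt."""

    gene_id: str
    transcript_id: str
    canonical: bool
    strand: str
    len_5utr: int
    len_cds: int
    len_3utr: int

    def __post_init__(self) -> None:
        if self.len_cds < 1:
            raise ValueError(f"{self.transcript_id}: CDS length must be >= 1")
        if self.len_5utr < 0 or self.len_3utr < 0:
            raise ValueError(f"{self.transcript_id}: UTR lengths must be >= 0")

    @property
    def length(self) -> int:
        return self.len_5utr + self.len_cds + self.len_3utr


def models_from_annotation(annotation: pd.DataFrame) -> list[TranscriptModel]:
    return [
        TranscriptModel(
            r["gene_id"],
            r["transcript_id"],
            bool(r["canonical"]),
            r["strand"],
            int(r["len_5utr"]),
            int(r["len_cds"]),
            int(r["len_3utr"]),
        )
        for _, r in annotation.iterrows()
    ]


def filter_transcripts(
    models: Sequence[TranscriptModel], min_cds: int = 300
) -> list[TranscriptModel]:
    """Keep canonical transcripts with CDS >= min_cds nt.

    A gene with two canonical transcripts is an annotation defect and
    raises.
    """
    kept = [m for m in models if m.canonical and m.len_cds >= min_cds]
    genes = [m.gene_id for m in kept]
    dupes = {g for g in genes if genes.count(g) > 1}
    if dupes:
        raise ValueError(f"multiple canonical transcripts for gene(s): {sorted(dupes)}")
    return kept


def scale_region_linear(values: np.ndarray, nbins: int = 100) -> np.ndarray:
    """Resample one region onto nbins positions by linear interpolation.

    Samples nbins points evenly spaced over [0, L-1] (both endpoints
    included); L == nbins returns the input unchanged and L == 1
    broadcasts the single value.
    """
    v = np.asarray(values, dtype=float)
    L = v.size
    if L == 0:
        raise ValueError("empty region cannot be scaled")
    if L == nbins:
        return v.copy()
    if L == 1:
        return np.full(nbins, v[0])
    return np.interp(np.linspace(0.0, L - 1, nbins), np.arange(L), v)


def transcript_profile(
    coverage: CoverageTrack | np.ndarray,
    model: TranscriptModel,
    nbins_per_region: int = 100,
) -> np.ndarray:
    """Split one transcript's coverage by region and scale to 300 bins.

    Minus-strand coverage must be reversed to 5'->3' upstream. A
    zero-length UTR contributes zero bins with a warning; a zero-length
    CDS is rejected by the model itself.
    """
    v = coverage.counts if isinstance(coverage, CoverageTrack) else np.asarray(coverage, float)
    if v.size != model.length:
        raise ValueError(
            f"{model.transcript_id}: coverage length {v.size} != transcript length {model.length}"
        )
    bounds = (model.len_5utr, model.len_5utr + model.len_cds)
    regions = [v[: bounds[0]], v[bounds[0] : bounds[1]], v[bounds[1] :]]
    scaled = []
    for name, region in zip(("5utr", "cds", "3utr"), regions):
        if region.size == 0:
            warnings.warn(
                f"{model.transcript_id}: empty {name}; its bins are set to 0", stacklevel=2
            )
            scaled.append(np.zeros(nbins_per_region))
        else:
            scaled.append(scale_region_linear(region, nbins_per_region))
    return np.concatenate(scaled)


def metagene_profile(
    coverage_by_tx: Mapping[str, CoverageTrack | np.ndarray],
    models: Sequence[TranscriptModel],
    nbins_per_region: int = 100,
) -> np.ndarray:
    """Unweighted per-bin mean of transcript profiles.

    ``models`` should already be filtered (canonical, CDS length);
    every model must have coverage in ``coverage_by_tx``.
    """
    if not models:
        raise ValueError("no transcripts retained for the metagene")
    profiles = [
        transcript_profile(coverage_by_tx[m.transcript_id], m, nbins_per_region) for m in models
    ]
    return np.mean(profiles, axis=0)


def normalize_and_smooth(
    profile: np.ndarray,
    ko_profile: np.ndarray,
    window: int = 5,
    eps: float | None = None,
) -> np.ndarray:
    """Knockout-normalized, smoothed metagene ratio.

    ratio[b] = profile[b] / (ko_profile[b] + eps), then a centered
    rolling mean. ``eps`` defaults to the same 0.1-percentile
    pseudocount rule used on the rRNA track, applied to the knockout
    profile, so the divide-by-zero policy is consistent across stages.
    """
    profile = np.asarray(profile, float)
    ko_profile = np.asarray(ko_profile, float)
    if profile.size != ko_profile.size:
        raise ValueError("profile and knockout profile must have equal length")
    if eps is None:
        eps = pseudocount_from_quantile(ko_profile, PipelineParams().pseudocount_quantile)
    ratio = profile / (ko_profile + eps)
    return rolling_average(ratio, window)


def profile_frame(
    raw: np.ndarray, ratio_smoothed: np.ndarray, nbins_per_region: int = 100
) -> pd.DataFrame:
    """TSV-ready metagene table with region labels per bin."""
    n = raw.size
    region = np.repeat(["5utr", "cds", "3utr"], nbins_per_region)[:n]
    return pd.DataFrame(
        {"bin": np.arange(n), "region": region, "raw_mean": raw, "smoothed_ratio": ratio_smoothed}
    )
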