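"""Pipeline constants and named rRNA regions.

Every numeric constant used by the three analysis stages lives in
:class:`PipelineParams` so a run can be reproduced from a single record.
The defaults encode the published analysis settings: a 0.1-percentile
pseudocount for the truncation-control denominator, a 3% cumulative
low-signal filter, rolling-average windows of 10 (rRNA track) and 5
(metagene), a global pseudocount of 5 for knockout normalization, and
peak thresholds of >2-fold enrichment over runs longer than 20 nt with
mean coverage above 10 reads per million.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class PipelineParams:
    """Validated record of every tunable constant in the pipeline.

    Attributes
    ----------
    pseudocount_quantile:
        Quantile of the control coverage used as the denominator
        pseudocount on the rRNA track (0.001 = the 0.1 percentile).
    low_signal_fraction:
        Positions holding the bottom ``low_signal_fraction`` of
        cumulative coverage are masked and forced to fold 1.
    rrna_smooth_window:
        Rolling-average window for the rRNA enrichment track.
    global_pseudocount:
        Constant added to knockout coverage/counts in peak calling.
    peak_min_fold:
        Strict lower bound on per-position fold enrichment inside a
        candidate peak (positions must exceed this value).
    peak_min_run:
        Minimum run length in nt for a candidate peak ("more than 20"
        qualifying positions, hence 21).
    peak_min_rpm:
        Strict lower bound on the mean IP reads-per-million over a run.
    metagene_bins_per_region:
        Standardized positions per transcript region (5'UTR/CDS/3'UTR).
    metagene_min_cds:
        Minimum CDS length (nt) for a transcript to enter the metagene.
    metagene_smooth_window:
        Rolling-average window for the metagene ratio profile.
    fdr_threshold:
        Benjamini-Hochberg q-value cutoff for significant peaks.
    """

    pseudocount_quantile: float = 0.001
    low_signal_fraction: float = 0.03
    rrna_smooth_window: int = 10
    global_pseudocount: float = 5.0
    peak_min_fold: float = 2.0
    peak_min_run: int = 21
    peak_min_rpm: float = 10.0
    metagene_bins_per_region: int = 100
    metagene_min_cds: int = 300
    metagene_smooth_window: int = 5
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.pseudocount_quantile < 1.0:
            raise ValueError(
                f"pseudocount_quantile must be in (0, 1), got {self.pseudocount_quantile}"
            )
        if not 0.0 <= self.low_signal_fraction < 1.0:
            raise ValueError(
                f"low_signal_fraction must be in [0, 1), got {self.low_signal_fraction}"
            )
        for name in (
            "rrna_smooth_window",
            "global_pseudocount",
            "peak_min_fold",
            "peak_min_run",
            "peak_min_rpm",
            "metagene_bins_per_region",
            "metagene_min_cds",
            "metagene_smooth_window",
            "fdr_threshold",
        ):
            value = getattr(self, name)
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.peak_min_run < 1:
            raise ValueError("peak_min_run must be >= 1")

    @classmethod
    def from_dict(cls, overrides: dict) -> "PipelineParams":
        """Build params from a mapping, rejecting unknown keys."""
        known = {f.name for f in fields(cls)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**overrides)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class RegionAnnotation:
    """Named 1-based inclusive intervals on an rRNA reference.

    Defaults mark the two 18S expansion-segment footprints: ES7
    (bases 1117-1195) and ES6b/c (bases 710-766).
    """

    regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"ES7": (1117, 1195), "ES6b/c": (710, 766)}
    )

    def __post_init__(self) -> None:
        for name, (start, end) in self.regions.items():
            if not 1 <= start <= end:
                raise ValueError(f"region {name!r}: need 1 <= start <= end, got {start}..{end}")

    def validate_against(self, reference_length: int) -> None:
        for name, (_, end) in self.regions.items():
            if end > reference_length:
                raise ValueError(
                    f"region {name!r} ends at {end}, beyond reference length {reference_length}"
                )

    def items(self):
        return self.regions.items()
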