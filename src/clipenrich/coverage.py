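"""Coverage tracks and interval I/O.

Internal coordinates are 0-based half-open throughout; user-facing rRNA
positions are reported 1-based inclusive (conversion is centralized in
:func:`to_one_based` / :func:`from_one_based`). Coverage uses depth
semantics: every position a read spans is counted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: legal unit transitions for a CoverageTrack
_UNIT_ORDER = ("raw", "rpm", "mean_scaled")


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based inclusive (start, end)."""
    return start0 + 1, end0


def from_one_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive (start, end) -> 0-based half-open [start, end)."""
    return start1 - 1, end1


@dataclass(frozen=True)
class ReadInterval:
    """One deduplicated read alignment on a single reference."""

    reference: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")


@dataclass
class CoverageTrack:
    """Per-position read depth over one reference.

    ``library_size`` is the total deduplicated read count of the whole
    sample (not just reads on this reference), so RPM reflects
    sequencing depth. ``units`` walks raw -> rpm -> mean_scaled only.
    """

    reference_name: str
    counts: np.ndarray
    library_size: float
    units: str = "raw"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.units not in _UNIT_ORDER:
            raise ValueError(f"unknown units {self.units!r}")
        if self.library_size < 0:
            raise ValueError("library_size must be >= 0")

    def __len__(self) -> int:
        return self.counts.size

    @property
    def length(self) -> int:
        return self.counts.size


def coverage_from_reads(
    reads: Iterable[ReadInterval], reference_length: int, *, library_size: float | None = None
) -> CoverageTrack:
    """Build a raw depth track: counts[i] = number of reads spanning i.

    ``library_size`` defaults to the number of reads supplied, which is
    correct for single-reference simulations; pass the sample's total
    when reads span several references.
    """
    delta = np.zeros(reference_length + 1)
    n = 0
    name = ""
    for r in reads:
        if n == 0:
            name = r.reference
        elif r.reference != name:
            raise ValueError(f"mixed references: {name!r} vs {r.reference!r}")
        if r.end > reference_length:
            raise ValueError(
                f"read [{r.start}, {r.end}) beyond reference length {reference_length}"
            )
        delta[r.start] += 1
        delta[r.end] -= 1
        n += 1
    counts = np.cumsum(delta[:-1])
    return CoverageTrack(
        reference_name=name,
        counts=counts,
        library_size=float(n if library_size is None else library_size),
        units="raw",
    )


def group_by_reference(reads: Iterable[ReadInterval]) -> dict[str, list[ReadInterval]]:
    """Split a flat read list into per-reference lists."""
    out: dict[str, list[ReadInterval]] = {}
    for r in reads:
        out.setdefault(r.reference, []).append(r)
    return out


def rpm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Scale raw counts to reads per million of library size."""
    if track.units != "raw":
        raise ValueError(f"rpm_normalize expects raw counts, got units={track.units!r}")
    if track.library_size == 0:
        raise ValueError("empty library: cannot RPM-normalize library_size 0")
    return replace(track, counts=track.counts / track.library_size * 1e6, units="rpm")


# ---------------------------------------------------------------------------
# BED / bedGraph I/O
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[ReadInterval]:
    """Parse a BED file (>= 3 columns) into read intervals."""
    reads: list[ReadInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = parts[5] if len(parts) >= 6 else "+"
            try:
                reads.append(ReadInterval(parts[0], start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return reads


def write_bed(reads: Sequence[ReadInterval], path: str | Path) -> None:
    """Write intervals as BED6 with sequential read names."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.reference}\t{r.start}\t{r.end}\tr{i}\t0\t{r.strand}\n")


def read_bedgraph(
    path: str | Path, *, library_size: float, reference_length: int | None = None
) -> CoverageTrack:
    """Parse a dense bedGraph into a raw coverage track.

    The file must cover a single reference; gaps are zero-filled.
    ``library_size`` is supplied separately (sidecar manifest) because
    bedGraph carries no sample-level metadata.
    """
    segments: list[tuple[int, int, float]] = []
    name = None
    max_end = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 bedGraph columns, got {len(parts)}"
                )
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph fields") from exc
            if name is None:
                name = parts[0]
            elif parts[0] != name:
                raise ValueError(f"{path}:{lineno}: multiple references in one track")
            if not 0 <= start < end:
                raise ValueError(f"{path}:{lineno}: need 0 <= start < end")
            if reference_length is not None and end > reference_length:
                raise ValueError(
                    f"{path}:{lineno}: interval ends at {end}, beyond declared length "
                    f"{reference_length}"
                )
            segments.append((start, end, value))
            max_end = max(max_end, end)
    length = reference_length if reference_length is not None else max_end
    counts = np.zeros(length)
    for start, end, value in segments:
        counts[start:end] = value
    return CoverageTrack(name or "", counts, float(library_size), units="raw")


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as run-length-encoded bedGraph (one line per run)."""
    counts = track.counts
    with open(path, "w") as fh:
        if counts.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(counts)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [counts.size]))
        for s, e in zip(starts, ends):
            fh.write(f"{track.reference_name}\t{s}\t{e}\t{counts[s]:g}\n")


# ---------------------------------------------------------------------------
# Sample manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["sample", "role", "condition", "path", "library_size"]
SAMPLE_ROLES = {"ip", "truncation_control", "knockout"}


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest TSV (sample, role, condition, path, library_size)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "role": str, "condition": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing column(s): {sorted(missing)}")
    bad_roles = set(df["role"]) - SAMPLE_ROLES
    if bad_roles:
        raise ValueError(f"manifest {path} has unknown role(s): {sorted(bad_roles)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)
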