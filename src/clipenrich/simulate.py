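"""Synthetic CLIP experiments with planted footprints.

The generator emits deduplicated single-end read intervals on transcript
coordinates, mimicking the statistical structure of a CLIP experiment:
a uniform background of read starts, multiplicative rate enrichment
inside planted footprint intervals (IP samples only, in the footprint's
active conditions), library-size differences between samples, and flat
background in truncation-control and knockout samples. Read starts are
allocated by a single multinomial draw of the exact library size over
per-position rates, so RPM normalization is exactly invertible in tests.

Outputs are BED6 intervals plus a JSON truth record carrying the planted
footprints and expected per-position rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .coverage import ReadInterval

SAMPLE_ROLES = ("ip", "truncation_control", "knockout")
CONDITIONS = ("untreated", "treated")

#: human 18S rRNA length in nt — the default single-reference coordinate system
DEFAULT_18S_LENGTH = 1869


@dataclass(frozen=True)
class Footprint:
    """A planted protein-contact region with multiplicative enrichment.

    Coordinates are 1-based inclusive on the reference. ``condition_set``
    names the simulated conditions in which IP samples carry the
    enrichment; control-role samples never do.
    """

    start: int
    end: int
    fold: float
    condition_set: frozenset[str] = frozenset(CONDITIONS)

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"footprint {self.start}..{self.end}: need 1 <= start <= end")
        if self.fold < 0:
            raise ValueError(f"footprint {self.start}..{self.end}: fold must be >= 0")
        object.__setattr__(self, "condition_set", frozenset(self.condition_set))
        unknown = self.condition_set - set(CONDITIONS)
        if unknown:
            raise ValueError(f"footprint {self.start}..{self.end}: unknown condition(s) {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "start": self.start,
            "end": self.end,
            "fold": self.fold,
            "condition_set": sorted(self.condition_set),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Footprint":
        return cls(d["start"], d["end"], d["fold"], frozenset(d["condition_set"]))


@dataclass(frozen=True)
class SampleSpec:
    name: str
    role: str
    condition: str = "untreated"

    def __post_init__(self) -> None:
        if self.role not in SAMPLE_ROLES:
            raise ValueError(f"sample {self.name!r}: unknown role {self.role!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"sample {self.name!r}: unknown condition {self.condition!r}")


@dataclass
class SimulationConfig:
    """Full description of one synthetic CLIP experiment.

    ``background_rate`` is the expected read starts per nt per million
    library reads; only its ratio to footprint-enriched rates matters
    because the exact library size is allocated multinomially.
    ``read_length`` is either a fixed nt length or a (min, max) tuple
    sampled uniformly per read.
    """

    reference_name: str = "18S"
    reference_length: int = DEFAULT_18S_LENGTH
    background_rate: float = 1.0
    footprints: list[Footprint] = field(default_factory=list)
    library_sizes: dict[str, int] = field(default_factory=dict)
    read_length: int | tuple[int, int] = 30
    seed: int = 0
    samples: list[SampleSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.reference_length < 1:
            raise ValueError("reference_length must be >= 1")
        if self.background_rate < 0:
            raise ValueError(f"negative background rate {self.background_rate}")
        for fp in self.footprints:
            if fp.end > self.reference_length:
                raise ValueError(
                    f"footprint {fp.start}..{fp.end} outside reference "
                    f"{self.reference_name!r} of length {self.reference_length}"
                )
        for name, size in self.library_sizes.items():
            if size < 0:
                raise ValueError(f"sample {name!r}: library size must be >= 0")
        for s in self.samples:
            if s.name not in self.library_sizes:
                raise ValueError(f"sample {s.name!r} has no library size")

    def to_dict(self) -> dict:
        return {
            "reference_name": self.reference_name,
            "reference_length": self.reference_length,
            "background_rate": self.background_rate,
            "footprints": [fp.to_dict() for fp in self.footprints],
            "library_sizes": dict(self.library_sizes),
            "read_length": list(self.read_length)
            if isinstance(self.read_length, tuple)
            else self.read_length,
            "seed": self.seed,
            "samples": [
                {"name": s.name, "role": s.role, "condition": s.condition} for s in self.samples
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["footprints"] = [Footprint.from_dict(f) for f in d.get("footprints", [])]
        d["samples"] = [SampleSpec(**s) for s in d.get("samples", [])]
        rl = d.get("read_length", 30)
        if isinstance(rl, (list, tuple)):
            d["read_length"] = (int(rl[0]), int(rl[1]))
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth for one simulation: planted footprints, expected
    per-position read-start counts per sample, and the generator config."""

    config: dict
    sample_footprints: dict[str, list[dict]]
    expected_rates: dict[str, dict[str, list[float]]]  # sample -> reference -> rates

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "config": self.config,
                "sample_footprints": self.sample_footprints,
                "expected_rates": self.expected_rates,
            },
            indent=1,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "TruthRecord":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(d["config"], d["sample_footprints"], d["expected_rates"])


def _sample_rates(config: SimulationConfig, sample: SampleSpec, length: int | None = None,
                  footprints: Sequence[Footprint] | None = None) -> np.ndarray:
    """Per-position relative read-start rates for one sample."""
    L = config.reference_length if length is None else length
    rates = np.full(L, config.background_rate)
    if sample.role == "ip":
        for fp in config.footprints if footprints is None else footprints:
            if sample.condition in fp.condition_set:
                rates[fp.start - 1 : fp.end] *= fp.fold
    return rates


def _draw_reads(
    rng: np.random.Generator,
    rates: np.ndarray,
    n_reads: int,
    reference: str,
    length: int,
    read_length: int | tuple[int, int],
) -> list[ReadInterval]:
    """Multinomial allocation of exactly n_reads starts over rates."""
    total = rates.sum()
    if total <= 0:
        if n_reads > 0:
            raise ValueError("all-zero rates with a nonzero library size")
        return []
    starts_per_pos = rng.multinomial(n_reads, rates / total)
    starts = np.repeat(np.arange(length), starts_per_pos)
    if isinstance(read_length, tuple):
        lens = rng.integers(read_length[0], read_length[1] + 1, size=starts.size)
    else:
        lens = np.full(starts.size, read_length)
    ends = np.minimum(starts + lens, length)
    return [ReadInterval(reference, int(s), int(e)) for s, e in zip(starts, ends)]


def simulate_rrna_experiment(
    config: SimulationConfig,
) -> tuple[dict[str, list[ReadInterval]], TruthRecord]:
    """Simulate read sets over a single rRNA-like reference.

    Returns a mapping sample name -> sorted read intervals, plus the
    truth record. Identical config (including seed) gives identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    reads_by_sample: dict[str, list[ReadInterval]] = {}
    expected: dict[str, dict[str, list[float]]] = {}
    sample_fps: dict[str, list[dict]] = {}
    for sample in config.samples:
        rates = _sample_rates(config, sample)
        n = config.library_sizes[sample.name]
        reads = _draw_reads(
            rng, rates, n, config.reference_name, config.reference_length, config.read_length
        )
        reads_by_sample[sample.name] = reads
        total = rates.sum()
        expected[sample.name] = {
            config.reference_name: (n * rates / total if total > 0 else rates).tolist()
        }
        sample_fps[sample.name] = [
            fp.to_dict()
            for fp in config.footprints
            if sample.role == "ip" and sample.condition in fp.condition_set
        ]
    truth = TruthRecord(config.to_dict(), sample_fps, expected)
    return reads_by_sample, truth


# ---------------------------------------------------------------------------
# Transcriptome simulation
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "gene_id",
    "transcript_id",
    "canonical",
    "strand",
    "len_5utr",
    "len_cds",
    "len_3utr",
]


def default_length_sampler(rng: np.random.Generator) -> tuple[int, int, int]:
    """Realistic-ish transcript region lengths (nt): 5'UTR, CDS, 3'UTR."""
    u5 = int(rng.integers(50, 201))
    cds = int(rng.integers(300, 1201))
    u3 = int(rng.integers(100, 501))
    return u5, cds, u3


def simulate_transcriptome_experiment(
    config: SimulationConfig,
    n_genes: int,
    utr_cds_lengths: Callable[[np.random.Generator], tuple[int, int, int]] | None = None,
    *,
    cds_footprint: Footprint | None = None,
    n_decoys: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[ReadInterval]], TruthRecord]:
    """Simulate a multi-transcript CLIP experiment.

    One canonical transcript is emitted per gene (references named by
    transcript id), with region lengths drawn from ``utr_cds_lengths``.
    ``cds_footprint``, if given, is planted in every gene's CDS at the
    footprint's CDS-relative coordinates (1-based within the CDS) for IP
    samples in the footprint's active conditions; knockout and
    truncation samples see background only. ``n_decoys`` adds
    non-canonical annotation entries (no reads) to exercise the
    canonical-transcript filter downstream.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    sampler = utr_cds_lengths or default_length_sampler
    rng = np.random.default_rng(config.seed)

    rows = []
    tx_lengths: dict[str, int] = {}
    tx_footprints: dict[str, list[Footprint]] = {}
    for g in range(n_genes):
        u5, cds, u3 = sampler(rng)
        if cds <= 0:
            raise ValueError(f"gene g{g}: CDS length must be >= 1, got {cds}")
        tx = f"g{g}.t1"
        rows.append([f"g{g}", tx, 1, "+", u5, cds, u3])
        tx_lengths[tx] = u5 + cds + u3
        fps = []
        if cds_footprint is not None:
            if cds_footprint.end > cds:
                raise ValueError(
                    f"footprint {cds_footprint.start}..{cds_footprint.end} outside CDS "
                    f"of length {cds} (gene g{g})"
                )
            fps.append(
                Footprint(
                    u5 + cds_footprint.start,
                    u5 + cds_footprint.end,
                    cds_footprint.fold,
                    cds_footprint.condition_set,
                )
            )
        tx_footprints[tx] = fps
    for d in range(n_decoys):
        g = d % n_genes
        u5, cds, u3 = sampler(rng)
        rows.append([f"g{g}", f"g{g}.decoy{d}", 0, "+", u5, cds, u3])
    annotation = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)

    tx_ids = sorted(tx_lengths)
    offsets = np.cumsum([0] + [tx_lengths[t] for t in tx_ids])
    total_len = int(offsets[-1])

    reads_by_sample: dict[str, list[ReadInterval]] = {}
    expected: dict[str, dict[str, list[float]]] = {}
    sample_fps: dict[str, list[dict]] = {}
    for sample in config.samples:
        concat = np.empty(total_len)
        for i, tx in enumerate(tx_ids):
            concat[offsets[i] : offsets[i + 1]] = _sample_rates(
                config, sample, length=tx_lengths[tx], footprints=tx_footprints[tx]
            )
        n = config.library_sizes[sample.name]
        total = concat.sum()
        starts_per_pos = rng.multinomial(n, concat / total) if total > 0 else np.zeros(total_len, int)
        reads: list[ReadInterval] = []
        for i, tx in enumerate(tx_ids):
            seg = starts_per_pos[offsets[i] : offsets[i + 1]]
            starts = np.repeat(np.arange(tx_lengths[tx]), seg)
            if isinstance(config.read_length, tuple):
                lens = rng.integers(
                    config.read_length[0], config.read_length[1] + 1, size=starts.size
                )
            else:
                lens = np.full(starts.size, config.read_length)
            ends = np.minimum(starts + lens, tx_lengths[tx])
            reads.extend(ReadInterval(tx, int(s), int(e)) for s, e in zip(starts, ends))
        reads_by_sample[sample.name] = reads
        expected[sample.name] = {
            tx: (n * concat[offsets[i] : offsets[i + 1]] / total).tolist()
            for i, tx in enumerate(tx_ids)
        } if total > 0 else {tx: [0.0] * tx_lengths[tx] for tx in tx_ids}
        sample_fps[sample.name] = [
            {"reference": tx, **fp.to_dict()}
            for tx, fps in sorted(tx_footprints.items())
            for fp in fps
            if sample.role == "ip" and sample.condition in fp.condition_set
        ]
    truth = TruthRecord(config.to_dict(), sample_fps, expected)
    return annotation, reads_by_sample, truth


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "transcript_id": str, "strand": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation {path} missing column(s): {sorted(missing)}")
    return df
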