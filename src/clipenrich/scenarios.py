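"""Reference synthetic scenarios emulating the CLIP study design.

These builders pin down one set of realistic conditions per analysis
stage so demos, tests and reproduction scripts all run the same
experiment. Choices, briefly:

* Footprints mirror the two 18S expansion-segment contacts: ES7 (bases
  1117-1195) enriched threefold in both conditions, ES6b/c (bases
  710-766) threefold in the treated condition only.
* The truncation control does not bind ribosomes, so its rRNA coverage
  is sparse relative to the IP samples (2,000 vs 50,000 reads on 18S).
* Reads are a fixed 10 nt: RNase-trimmed CLIP fragments are short, and
  short spans keep coverage closely proportional to the crosslink-start
  rate, so planted truth intervals remain the right unit of comparison
  (span smearing extends apparent coverage by at most read_length - 1 nt
  3' of a footprint).
"""

from __future__ import annotations

import numpy as np

from .simulate import Footprint, SampleSpec, SimulationConfig

ES7 = Footprint(1117, 1195, 3.0, frozenset({"untreated", "treated"}))
ES6BC = Footprint(710, 766, 3.0, frozenset({"treated"}))

READ_LENGTH = 10


def rrna_scenario(seed: int) -> SimulationConfig:
    """Two IP conditions plus a non-binding truncation control on 18S."""
    return SimulationConfig(
        reference_name="18S",
        footprints=[ES7, ES6BC],
        library_sizes={"ip_untreated": 50_000, "ip_treated": 50_000, "trunc": 2_000},
        read_length=READ_LENGTH,
        seed=seed,
        samples=[
            SampleSpec("ip_untreated", "ip", "untreated"),
            SampleSpec("ip_treated", "ip", "treated"),
            SampleSpec("trunc", "truncation_control", "untreated"),
        ],
    )


def _fixed_lengths(rng: np.random.Generator) -> tuple[int, int, int]:
    return 100, 600, 200


def transcriptome_null_scenario(seed: int) -> tuple[SimulationConfig, dict]:
    """One gene, no footprint: the peak caller should stay silent."""
    config = SimulationConfig(
        library_sizes={"ip": 5_000, "ko": 5_000},
        read_length=READ_LENGTH,
        seed=seed,
        samples=[SampleSpec("ip", "ip", "treated"), SampleSpec("ko", "knockout", "treated")],
    )
    return config, {"n_genes": 1, "utr_cds_lengths": _fixed_lengths}


PEAK_FOOTPRINT = Footprint(101, 140, 4.0, frozenset({"treated"}))  # CDS-relative, width 40


def transcriptome_peak_scenario(seed: int) -> tuple[SimulationConfig, dict]:
    """One gene with a fourfold, 40-nt footprint planted in the CDS."""
    config = SimulationConfig(
        library_sizes={"ip": 20_000, "ko": 20_000},
        read_length=READ_LENGTH,
        seed=seed,
        samples=[SampleSpec("ip", "ip", "treated"), SampleSpec("ko", "knockout", "treated")],
    )
    return config, {
        "n_genes": 1,
        "utr_cds_lengths": _fixed_lengths,
        "cds_footprint": PEAK_FOOTPRINT,
    }


METAGENE_FOOTPRINT = Footprint(150, 250, 4.0, frozenset({"treated"}))


def metagene_scenario(seed: int) -> tuple[SimulationConfig, dict]:
    """Ten genes with a CDS-restricted footprint; knockout is background."""
    config = SimulationConfig(
        library_sizes={"ip": 20_000, "ko": 20_000},
        read_length=READ_LENGTH,
        seed=seed,
        samples=[SampleSpec("ip", "ip", "treated"), SampleSpec("ko", "knockout", "treated")],
    )
    return config, {"n_genes": 10, "cds_footprint": METAGENE_FOOTPRINT}
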