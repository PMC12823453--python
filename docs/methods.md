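# Methods

## Scope and model

The package analyses deduplicated CLIP-seq alignments as interval sets
on single-reference coordinates (an rRNA, or one transcript per locus).
All statements below concern the three analysis stages and the
synthetic-data generator; upstream steps (UMI extraction, trimming,
alignment, deduplication) are out of scope and assumed done.

Coverage uses depth semantics: every position a read spans is counted.
Internally all coordinates are 0-based half-open; user-facing rRNA and
peak coordinates are 1-based inclusive, with the conversion centralized
in `coverage.to_one_based` / `from_one_based`.

## Stage 1 — rRNA fold enrichment

Given raw IP and truncation-control tracks with their sample library
sizes:

1. RPM-normalize both (`counts / library_size × 10⁶`). `library_size`
   is the sample's total deduplicated read count, supplied in the
   manifest, so RPM reflects sequencing depth, not reads-on-reference.
2. Mean-scale both over the reference (divide by the track mean). This
   removes the remaining depth difference, so only coverage *shape*
   matters downstream.
3. Pseudocount ε = the 0.001 quantile of the mean-scaled control,
   computed with linear-interpolation ("type 7") quantiles. If that
   quantile is exactly 0 (sparse controls), ε falls back to the smallest
   strictly positive value, and to 1 if the control is all-zero; both
   fallbacks warn. The pseudocount is computed after mean scaling so it
   shares units with the ratio's denominator.
4. fold_i = ip_i / (control_i + ε).
5. Low-signal mask: sort positions by ascending IP RPM (ties by
   ascending index) and mask the maximal prefix whose cumulative signal
   is strictly below 3% of the total. The filter runs on the IP track —
   the signal being plotted — and masked positions are set to fold 1
   *before* smoothing.
6. Smooth with a centered rolling mean, window 10. Position *i* averages
   indices [i − ⌈w/2⌉ + 1, i + ⌊w/2⌋] intersected with the track, so an
   even window extends one position further right and edge windows
   shrink rather than pad. Smoothing is presentation-layer: the
   per-region summary reports both raw and smoothed maxima/means.

When replicates exist, fold is computed per replicate and the smoothed
tracks averaged (`enrichment.average_enrichment`); replicate shading is
not implemented.

## Stage 2 — peak calling against the knockout

Per canonical transcript: fold_i = ip_rpm_i / (ko_rpm_i + 5), with no
mean scaling; the same 3% cumulative filter is applied per locus on IP
RPM and filtered positions are set to fold 1. Candidate peaks are
maximal runs of consecutive positions with fold strictly greater than 2,
kept when the run exceeds 20 nt (≥ 21) and its mean per-position IP RPM
strictly exceeds 10. All three thresholds are strict; a sliding-window
variant was considered and rejected in favour of maximal runs, the
simplest deterministic reading.

Significance: observed = IP reads overlapping the run, and
λ = (KO reads overlapping the run + 5) × N_IP / N_KO, tested one-sided
(P(X ≥ observed)). Read counts rather than coverage sums keep the
Poisson variance assumption — summing per-position coverage would count
each read up to read-length times and over-disperse the statistic by
roughly that factor. A `count_mode="coverage"` flag exposes the
coverage-sum variant for comparison only. Benjamini–Hochberg q-values
are computed across all candidate peaks of a condition (the conservative
choice of test family), implemented as the standard step-up
q_(i) = min_{j≥i} p_(j)·(n/j) capped at 1; the test suite cross-checks
it against statsmodels and against a loop-based oracle.

## Stage 3 — metagene

Canonical transcripts with CDS ≥ 300 nt are retained (two canonical
transcripts for one gene is treated as an annotation defect and raises).
Each region is resampled to 100 bins by sampling `linspace(0, L−1, 100)`
with linear interpolation — endpoints included, so a region of exactly
100 nt is reproduced unchanged and a 1-nt region broadcasts. Profiles
are unweighted means over transcripts (no expression weighting: the
fixed-length alignment across genes implies equal weight), the IP/KO
ratio is taken bin-wise with ε from the same 0.1-percentile rule applied
to the knockout profile (no pseudocount is prescribed for this stage;
reusing the rule keeps one divide-by-zero policy), and smoothed with
window 5. Region boundaries on the standardized axis are half-open:
[0,100) 5′UTR, [100,200) CDS, [200,300) 3′UTR. Empty UTRs contribute
zero bins with a warning; an empty CDS is an error.

## Synthetic-data generator

The generator emulates the statistical structure of the CLIP design:
uniform background read-start rates over an 18S-length reference
(default 1869 nt), multiplicative rate enrichment inside planted
footprints (IP samples only, in the footprint's active conditions),
library-size differences between samples, and flat background in
truncation-control and knockout samples. Read starts are allocated with
a single multinomial draw of the exact library size over per-position
rates, so per-sample totals are exact and RPM normalization is exactly
invertible in tests. Reads are single-end, plus-strand, fixed or
uniform-length, clipped at the reference end; UMI duplication is not
simulated (outputs represent post-dedup reads).

### Reference scenarios and their defaults

`clipenrich.scenarios` pins one set of conditions per stage, chosen from
closed-form expected-coverage calculations before any empirical tuning:

- **Footprints**: ES7 (1117–1195) threefold in both conditions, ES6b/c
  (710–766) threefold in the treated condition only — the two
  expansion-segment contacts of the study design; fourfold, 40-nt
  (peaks) and fourfold, 101-nt (metagene) CDS footprints for the
  transcript stages.
- **Control sparsity**: the truncation control is a *non-binding*
  construct, so its rRNA coverage is sparse by design — 2,000 reads on
  18S versus 50,000 for the IP samples. This matters quantitatively: the
  denominator pseudocount is the 0.1-percentile of the control, and for
  a deep, flat control that percentile approaches the typical
  mean-scaled value (≈ 0.85), capping the achievable fold of a threefold
  footprint near 1.5. A sparse control (per-position coverage ~10×)
  keeps the percentile near 0.1–0.2, as in real data where control
  tracks span orders of magnitude.
- **Read length 10 nt** (5 nt in the coverage-ratio recovery test).
  RNase-digested CLIP fragments are short, and short spans keep coverage
  nearly proportional to the crosslink-start rate: a footprint's
  apparent coverage extends at most read_length − 1 nt 3′ of its end, so
  called peaks line up with planted truth intervals. With 30-nt reads
  the same geometry extends every called peak ~20 nt rightward — a real
  property of coverage-based peak calling worth remembering when
  interpreting peak boundaries on real data.
- **Background rate 1.0** (uniform): only the ratio of enriched to
  background rates matters under multinomial allocation.
- **Library sizes** for transcript scenarios: 5,000 reads per sample for
  the null (enough depth that candidate runs are reachable in principle)
  and 20,000 for planted-footprint recovery.

### What the generator does not emulate

Real rRNA background is highly structured (secondary-structure and
ligation biases), reads have variable length and sequencing errors, and
crosslink sites have nucleotide preferences; none of this is simulated.
Passing tests therefore demonstrate that the implementation computes the
defined statistics correctly and recovers planted signal under the
stated noise model — not that the thresholds are optimal for any
particular real library.

## Numerical choices and degenerate inputs

- Quantiles: numpy's default linear interpolation throughout.
- Low-signal filter: strict `<` against fraction × total; a tie at the
  threshold is kept, ties in signal break by position index.
- Rolling mean: window 1 is the identity; even windows are right-heavy
  as defined above.
- Poisson p: `scipy.stats.poisson.sf(observed − 1, λ)`; observed = 0
  returns exactly 1; λ ≤ 0 is an error.
- Empty peak tables BH-adjust to empty; peaks sort by (q, locus, start)
  with a stable sort for deterministic output.
- All-zero tracks: mean-scaling errors; RPM of an empty library errors;
  an all-zero control track yields pseudocount 1 with a warning.

## Problem sizes

Validation runs use 20 seeds for the rRNA and metagene recovery checks,
100 seeds for the peak-caller null, and 20 for planted-peak recovery,
with the library sizes above — small enough to run anywhere in seconds
while leaving the statistical margins (e.g. planted Jaccard ≈ 0.80
against a 0.6 bound) wide.

## Known limitations

- Single-reference, single-end, plus-strand intervals only; no BAM/CIGAR
  or splice handling (minus-strand transcripts must be reversed to 5′→3′
  upstream of the metagene).
- The rRNA stage reports no significance measure — it is a descriptive
  fold track.
- The Poisson model ignores overdispersion between biological
  replicates; q-values are exact only under the within-sample Poisson
  assumption.
- Peak boundaries inherit read-span smearing (see read-length note
  above).
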