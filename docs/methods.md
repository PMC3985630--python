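# Methods

## The mapping model

A methyltransferase-directed mapping experiment reduces, for analysis
purposes, to three coupled models.

**Reference map.** An enzyme's duplex recognition site set on a genome is
defined by forward-strand occurrences of its motif string(s). A
self-reverse-complementary motif (`TCGA`, `TCTAGA`) is found on both
strands by a single forward scan, so one forward occurrence is one duplex
site. M.FokI's two domains read `GGATG` and `CATCC` — mutual reverse
complements — so a forward occurrence of either string is one duplex site,
recorded with the strand of the `GGATG` reading. Overlapping occurrences
are all counted (each is an independent methylation target), `N` never
matches, and coordinates are 0-based half-open (BED). *Star* sites are all
Hamming-distance-1 variants of each motif string; because the reverse
complement of a variant of one string is a variant of the partner string,
the same forward-scan closure argument covers both strands. The reported
site position is the motif's forward-strand start: the ≤5 bp offset of the
methylated adenine is far below both the 50 bp match tolerance and the
~360 bp mean site spacing, so it is carried as metadata only. Reference
maps exclude star sites unless explicitly requested.

**Combing geometry.** Combed DNA is over-stretched to `c ≈ 1.59 ± 0.03`
times its B-DNA contour length (rise 0.34 nm/bp), so a genome position x
on a molecule with origin o maps to `(x − o) · 0.34 · c` nm from the
molecule end (mirrored with probability 1/2 for deposition orientation).
The stretch is drawn once per molecule from a normal truncated at ±3 sd.
The quoted ±0.03 is a spread over measured molecules and the literature
does not resolve whether it is inter- or intra-molecule; per-molecule
variation is assumed here because it reproduces the observed <200 bp
standard deviation of a 10 kb distance, and a dataset-global stretch mode
is provided in the aligner for the other reading.

**Label statistics.** Each site in a molecule is labelled independently
with probability `p_label` (default 0.70, the coupling efficiency of the
click reaction). False positives — non-specific labels from surface dyes,
non-covalent binding, or off-target enzyme activity — are modelled as a
uniform Poisson process along the molecule; the default rate is derived at
run time as `0.5 · p_label · (site density)` so that false positives are
one third of all labels, the level reported for these experiments.
Localization error is Gaussian in nm (sd 10 nm, an imaging quantity), and
copper-mediated cleavage during labelling is a Poisson number of uniform
breaks per molecule, with presets calibrated so the intact fraction
matches the gel-based protection levels (20% for TBTA in 40% DMSO, 33% for
THPTA in 20% DMSO, 80% for a 10:1 THPTA excess — the last stated only as
"majority protected" and fixed here at 0.80).

## Bleaching-analysis localization

Labels sit well below the diffraction limit (~360 bp ≈ 194 nm at 1.59×
stretch, PSF sigma 130 nm here), so single frames cannot separate them. In
a photobleaching movie each fluorophore emits at a constant rate until a
single-step, geometrically distributed bleaching time; the difference of
consecutive frames around one bleaching event contains that fluorophore
alone. The implementation renders such movies (Poisson shot noise,
constant background) as its own fixture generator, differences consecutive
frames, detects candidates as local maxima of the matched-filtered
(Gaussian-smoothed, sigma = PSF sigma) difference frame above a
configurable photon threshold, refines each by least-squares 2D Gaussian
fitting with the PSF width held fixed (free: centre, photon count,
background), and projects the accumulated 2D localizations onto the first
principal component of their scatter — the molecule backbone — shifting
the minimum projection to zero. Precision is estimated as
`sigma_psf/sqrt(N)` (the photon-limited Thompson term; pixelation and
background corrections are deliberately omitted at these photon budgets).
Two simultaneous bleaching events in one interval are not resolved —
consecutive-frame pairing is the method's resolution limit — and the
backbone's mirror ambiguity is left to the aligner's orientation search.
End-to-end, scheduled (collision-free) bleaching recovers every label with
RMS 1D error within 2·√2 of the Thompson bound, the √2 reflecting the
doubled shot-noise variance of a frame difference.

## Alignment

Each trace is placed by exhaustive grid search: stretch factor
`s ∈ [0.60, 0.65]` step 0.002 (bp per 0.34 nm; 1/1.59 ≈ 0.629), shift on a
25 bp grid over the genome, both orientations. A placement's score is the
number of labels within 50 bp of their nearest reference site
(many-to-one matching is allowed — with ~360 bp site spacing versus 50 bp
tolerance, contention is negligible and Hungarian assignment would be
overkill), with smaller RMS residual and then smaller shift as
deterministic tie-breaks. Count-first scoring is robust to the ~1/3 false
positives that would dominate a pure least-squares objective. Grid steps
are half the 50 bp match bin. Genomes are treated as linear; molecules
with fewer than 5 labels are rejected with an explicit status rather than
guessed.

Because stretch is quantized, shift alone is not identifiable to one grid
step: a one-step stretch error rescales a 30 kb molecule by ~60 bp and the
count-optimal shift compensates by half of that. Recovery against
simulation ground truth is therefore scored at the molecule midpoint,
where the two grid dimensions decouple; "recovered" means correct
orientation, midpoint within one 25 bp step, stretch within one 0.002
step. Under the default study conditions (14 molecules of 23–36 kb,
p = 0.7, 1/3 false positives, 10 nm noise) ≥95% of molecules recover their
true placement; the residual misses are dominated by molecules whose true
stretch draw falls outside the searched window (1/1.59 ± 3 sd spans
0.595–0.667, slightly wider than the conventional 0.60–0.65 search range).

## Map statistics

Aligned label positions are accumulated in 50 bp genome bins, per molecule
and as a dataset consensus. The summary statistics are:

* `pct_matched_data` — matched labels over all labels (identical, by
  construction, to the alignment records' totals). Its complement is the
  false-positive fraction. A bin-based match variant ("same or adjacent
  50 bp bin", admitting up to ~100 bp) is available separately since both
  definitions appear in practice; the distance-based 50 bp rule is the
  default.
* `pct_matched_reference` — reference sites receiving ≥1 matched label,
  over reference sites *inside the union of fitted molecule intervals*.
  Molecules covering ~3/4 of a genome cannot testify about the rest, and a
  whole-genome denominator would be unattainable by construction.
* `labelling_efficiency_pct` — mean labels per molecule over the mean
  in-silico site count within each fitted interval. This mirrors the
  headline arithmetic used with real cohorts (e.g. 60 labels per ~30 kb
  molecule against 3/4 of 111 sites ≈ 72%, quoted as ~70%), which counts
  every localized fluorophore in the numerator; on data with false
  positives it therefore reads ~1.5 × p_label, and estimator validation
  is done with false positives disabled, where it recovers p_label to
  within sampling error.
* Star screening — consensus bins with count ≥ 4 and no canonical site
  within 50 bp are annotated with the nearest one-base-off star site.
  The threshold is set where the uniform false-positive background
  (~0.5 labels/bin at cohort-scale coverage) has a Poisson tail of ~0.2%,
  leaving ~1–2 chance flags per genome.

## What the synthetic data does and does not emulate

The generator reproduces the *statistical* structure of a mapping
experiment — site density (planted-site genomes carry an exact site count,
e.g. 111 `TCGA` sites on 39,937 bp, at uniform random positions),
labelling efficiency, false-positive load, stretch variability,
localization noise, fragmentation, orientation. It does not emulate
sequence-dependent labelling bias, dye photophysics beyond single-step
bleaching, non-uniform stretching within a molecule, combing surface
effects, or clustered (non-uniform) false positives. Passing recovery
tests on these data therefore validates the pipeline's inference under the
declared noise model, not its robustness to structured artefacts in real
images; the localization stage's movie renderer is likewise an idealized
forward model, not an instrument simulation.

## Numerical and design choices

* All randomness derives from one integer seed via named, CRC-keyed
  substreams (`stage_rng`), so runs are reproducible byte-for-byte while
  stages stay independent.
* Problem sizes in tests and the acceptance script — 14-molecule cohorts,
  20 seeds, 10⁴-molecule fragmentation batches, 12-label movies — are the
  cohort scale of the emulated experiments, which also keeps every check
  fast enough for routine runs.
* Ties in the placement search resolve deterministically (count, then RMS,
  then smaller shift, then forward orientation and smaller stretch by
  iteration order).
* Localization candidates that fail to converge in the Gaussian fit are
  dropped with a log entry rather than propagated.
* Simulated label positions perturbed past a molecule end are clipped to
  the measured extent, as they would be in segmentation of real images.
* The per-molecule length default (uniform 23–36 kb) matches the selected
  long-molecule cohorts of the emulated experiments; fragmentation-driven
  sampling is available where molecule length should instead follow the
  cleavage statistics.

## Known limitations

* The placement objective (count, then RMS) is this package's definition;
  the original analyses describe only an "optimal overlap" criterion.
* No significance model: a placement is reported even when its match count
  could plausibly arise by chance (relevant for sparse maps like M.XbaI
  with 3 sites, where `min_labels` already rejects most traces).
* Star-site annotation is a screen, not a test; with ~15 one-base variants
  per motif string a star site lies within ~1 kb of most genome positions,
  so an annotation is meaningful only for bins that already show recurrent
  unexplained labels.
* The real-genome site-count check requires the user to supply the
  bacteriophage T7 sequence (GenBank NC_001604); it is not redistributed.
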