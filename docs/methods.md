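# Methods

## The problem

Histone N-terminal tails carry combinations of post-translational marks
whose joint occurrence — not just their individual levels — governs
reader recruitment and chromatin state. Middle-down MS keeps those
combinations intact by analyzing the whole GluC-cleaved tail (H3 1–50,
released by cleavage after E50, 0 missed cleavages) and fragmenting it
with ETD, which yields c and z• ions while preserving labile marks.
Metabolic labeling adds the time axis: heavy K/R labels the protein
sequence (old vs newly synthesized tails), and heavy methionine feeds
¹³CD₃ methyls through SAM into newly catalyzed methylations (old vs new
marks). This package implements the full data-analysis chain for such
experiments plus a synthetic-data generator that serves as its ground
truth.

## Mass model

Monoisotopic residue masses and isotope deltas come from the NIST tables
shipped with pyteomics. Frozen derived constants (Da):

| quantity | value | note |
|---|---|---|
| methylation unit (CH₂) | 14.015650 | per methyl |
| trimethyl delta | 42.046950 | 3×CH₂ |
| acetyl delta (C₂H₂O) | 42.010565 | 0.036385 below me3 |
| heavy methyl (¹³CD₃ − CH₃) | 4.022185 | (¹³C−¹²C) + 3(²H−¹H) |
| heavy K (¹³C₆,¹⁵N₂) | 8.014199 | |
| heavy R (¹³C₆,¹⁵N₄) | 10.008269 | |
| c-ion offset | +17.026549 | prefix + NH₃ |
| z•-ion offset | +1.991841 | suffix + (H₂O + H − NH₃) |

For every split i of an n-residue tail, c_i + z•_(n−i) − M = 1.007825 Da
regardless of marks and labels — a useful internal consistency check that
the test suite asserts on random proteoforms. The H3 1–50 sequence
contains 8 K and 7 R, so the full heavy-KR shift is
8×8.0142 + 7×10.0083 = 134.17 Da (16.77 m/z at 8+), which is what
separates the two sequence channels on the precursor axis.

A mark is written `K27me2:1` — residue, parent-protein site (1-based,
K4…K36 numbering), kind, and after the colon the number of heavy methyl
groups; the suffix is omitted when all methyls are light. Site-ascending
concatenation of tokens is the canonical proteoform ID used in every
table. Allowed kinds per residue are configurable; the default is
me1/me2 on K and R, me3 and ac on K only. Heavy-methyl experiments on
tails containing methionine are rejected by default (the sequence itself
would be heavy) unless explicitly overridden; H3 1–50 contains no M.

## Search

Spectra are handled as deconvoluted neutral monoisotopic masses
(Xtract-style); charge exists only at I/O boundaries. Candidate
generation is composition-first: solve for the totals (methyl units a,
acetyls b, heavy methyls c) with
a·14.015650 + b·42.010565 + c·4.022185 inside the precursor window
(default ±2.1 Da, wide enough to absorb deconvolution and isotope-pick
errors), then place them on the modifiable sites and distribute the heavy
methyls over the placed marks. Enumeration is exact and deterministic
(fewest mods, then notation); exceeding the candidate cap raises an error
advising tighter rules rather than truncating silently. One label channel
is active per experiment, matching how these labeling workflows are run;
with both channels enabled a +134 Da precursor window additionally admits
hypermethylated light-channel isobars and the space can exceed the cap.

Fragment matching is greedy: for each theoretical ion the most intense
unused peak within 0.01 Da (configurable; ppm mode available) is taken,
one peak per ion series. The score is the mean of the matched-ion
fraction and the matched-intensity fraction, in [0,1]; ties break toward
fewer modifications, then notation — determinism over cleverness, since
on deconvoluted data the true form separates cleanly.

### Localization filter

An accepted identification must localize every modification
unambiguously. For each mod, the rival placements are all candidates
within 0.05 Da of the assignment's mass (the isobaric window; this covers
both exact isobars and the me3/ac near-isobar at 8+) that do not carry
that same mod. The assignment is accepted only if *every* such rival is
excluded by at least one matched discriminating ion — an ion whose
theoretical mass differs between assignment and rival by more than
1e-4 Da — with mass error within 30 ppm. Peptides that cannot be pinned
down this way are discarded as ambiguous, which is what keeps
trimethylation (42.047) from being mistaken for acetylation (42.011).

Two ion-set notions coexist and are deliberately distinct:

* *exclusion evidence* (filter): ions discriminating against at least
  one rival; every rival needs one. Requiring instead a single ion that
  differs from **all** rivals simultaneously would make localization
  impossible whenever rivals flank the site on both sides, which is the
  normal situation on a 9-site tail.
* *member-specific ions* (quantification): ions differing from **every**
  other co-isolated member. Only these carry signal attributable to one
  member alone, so only these drive the FIRR split.

## FIRR quantification

Imperfect chromatography leaves isobaric proteoforms mixed in single
MS/MS spectra. After the top identification, candidates with evidence in
the residual spectrum (peaks the winner left unexplained) are filtered in
full; the accepted set forms the co-isolation group. The group's summed
matched fragment intensity is split in proportion to each member's mean
member-specific ion intensity — exact on noise-free data, since each
specific ion then carries exactly that member's share of the base signal.
Members with no specific signal receive share zero with a logged warning
and are dropped from the quant table: such "phantom" placements arise
because the union ladder of the true members can fully contain an
intermediate placement's ladder.

**Known limitation.** Splitting by member-specific ions requires each
member to *have* specific ions. A nested single-site trio (e.g. K9me2 /
K14me2 / K27me2 co-isolated) violates this: every c ion covering the
middle site also covers the N-terminal one and every z ion covering it
also covers the C-terminal one, so the middle member is invisible to
single-ion reasoning and its signal is reassigned to the flanking
members. Trios in which a multi-mark form bridges sites
(K9me2 / K14me1K18me1 / K27me2) are fully identifiable and are recovered
to 1e-9. Two-member groups always split exactly.

Relative abundance divides each proteoform's (summed) intensity by the
total of all forms sharing its tail within one label channel and sample;
light and heavy tails are distinct sequences, so channels normalize
separately by default (a pooled mode exists). Proteoforms seen in only
one replicate are kept; no imputation.

## Analytics

* `single_ptm_abundance`: summed relative abundance of every
  combinatorial form carrying a mark. The bare token (`K27me2`) means the
  fully light mark; `K27me2:1` a specific heavy count; `K27me2:*`
  aggregates over h. The remainder to 1 is the unmodified state.
* `heavy_fraction`: summed abundance of forms with at least one heavy
  methyl — the turnover readout of pulse labeling.
* `hybrid_marks`: marks with 0 < h < k, ranked by abundance. Fully heavy
  marks are excluded because they are indistinguishable from whole-mark
  turnover; hybrids prove a site retained part of its pre-label state
  while gaining new methyls.
* `interplay`: I(a,b) = log₂(F_ab / (F_a·F_b)), positive when two marks
  co-occur above chance, negative when they avoid each other. The log
  base-2 form is used so "positive/negative" maps onto
  enrichment/exclusion; mutually exclusive pairs (F_ab = 0) return a
  flagged NaN sentinel instead of −∞ so ranked outputs stay sortable.
  No multiple-testing correction is applied; raw scores are reported.
* `replicate_correlation`: Pearson r with two-tailed p from
  t = r√((n−2)/(1−r²)) on n−2 df (scipy.stats.pearsonr); zero-variance
  inputs return flagged NaNs.
* `cv_by_mark`: sd/mean (sample sd) of single-mark abundances across
  replicates, with grouping by site or kind.
* `compare_single_mark_tables`: least-squares slope through the origin
  plus Pearson r on shared marks — the cross-method (e.g. middle-down vs
  bottom-up) comparison.

## Synthetic data

The generator emulates what the instrument delivers after deconvolution,
not the instrument itself. Per isobaric group of the configured mixture
it emits one spectrum whose peaks are the exact c/z• ladders, each ion at
(base intensity × member proportion), shared ions accumulating. Noise is
layered on top, all seed-deterministic:

* multiplicative log-normal intensity noise, parameterized by CV
  (mean-preserving; σ² = ln(1+CV²));
* Bernoulli peak dropout (missing ions);
* Gaussian mass jitter in ppm.

Fragment base intensities are uniform across ions — real ETD intensity
profiles are uneven, but a flat profile is the simplest model that
exercises ratio-based splitting; consequences for real data are limited
to the noise statistics of FIRR, not its expectation. Not modeled:
chromatographic elution, isotope envelopes, charge-state distributions.
Passing tests therefore demonstrate correctness of the inference given
deconvoluted peak lists, not robustness to deconvolution artifacts.

Incomplete heavy-KR incorporation — long sequences hardly reach 100%
labeling — is modeled exactly: each K/R site heavy independently with
probability p (default 0.95, a realistic incorporation level after
several passages), giving a product-of-binomials pmf over (heavy-site
count, mass shift); mean shift is p × full shift by linearity.

The EMT-style time course models methyl turnover as a first-order
replacement process: each methyl group present on a tail is heavy with
probability 1 − e^(−λt), so a k-methyl mark carries Binomial(k, q) heavy
methyls. Tails are sampled (default n = 10,000 per time point) with
independent per-site mark marginals chosen once as a realistic H3
steady state (K9/K27/K36 heavily methylated, K14/K18/K23
acetylation-prone, sparse K4/R8/R26). Default rates λ = 0.5/day
(non-confluent) and λ = 0.22/day (confluent, contact-inhibited) place the
simulated day-1/day-2 heavy fractions in the ~80/95% and ~55/85% ranges
characteristic of fast- vs slow-growing cultures; with a single
exponential both days cannot be matched to arbitrary targets
simultaneously, and no per-site rate heterogeneity is modeled.

## Numerical choices

* Ion-mass distinctness threshold 1e-4 Da (theoretical ladders are exact;
  the threshold only guards float noise while staying far below the
  0.0364 Da me3/ac gap).
* Candidate cap 200,000 with a hard error, never truncation.
* Peak ties in matching break toward smaller mass error, then lower peak
  index; candidate ties toward fewer mods, then notation — every stage is
  deterministic given inputs and seed.
* TSV output is UTF-8, LF, '.' decimal, stably sorted; MGF masses print
  at 6 decimals, making writers byte-reproducible.
* Degenerate inputs fail loudly: zero total intensity, zero-variance
  correlation vectors, mean-zero CVs and zero light intensity in channel
  ratios return flagged NaNs or raise, as documented per function.

## Test and simulation sizes

Problem sizes were chosen to make the checks decisive while keeping the
whole suite fast: exhaustive-oracle comparison over 1000 random precursor
windows on 6–8 residue tails (where exhaustive enumeration is feasible);
500 noiseless toy-tail searches plus 20 full H3 1–50 searches for
soundness; 100 noise seeds (CV 10%, dropout 5%) for FIRR recovery; 200
deletion cases for the localization filter; 10⁵ sampled tails for
interplay-under-independence; 10⁴ tails per time point for the turnover
analogue.
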