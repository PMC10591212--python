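# Methods

## Problem and model

ZooMS assigns a taxon to a collagen-bearing sample from the masses of its
tryptic collagen type I peptides. Teleost fish carry three distinct COL1
chains (COL1a1a, COL1a2, COL1a1b), each a Gly-X-Y triplet-repeat protein;
inter-species substitutions at X/Y positions shift the [M+H]+ of the tryptic
peptides that span them. The package models the full chain of inference:
chain sequences → located tryptic peptides → modification-state mass ladders
→ species-discriminating markers → matches against picked MALDI-TOF peaks →
a per-sample call → cohort composition.

All masses are monoisotopic and singly protonated (MALDI convention; no
multiply charged species, no isotope envelopes, no adducts). Residue masses
come from the standard monoisotopic table (via pyteomics); water is
18.010565 Da and the proton 1.007276 Da. Modifications are counted, never
site-localised, because MALDI cannot localise them: hydroxylation
(+15.994915 Da, P/K), deamidation (+0.984016 Da, N/Q), oxidation
(+15.994915 Da, M). Default enumeration caps are 3/0/0; hydroxylation
dominates collagen ladders, and deamidation/oxidation are opt-in.

Coordinates are 1-based inclusive, numbered within the *mature* chain
(propeptides removed). Mature bounds are explicit annotations supplied with
the sequences; the package does not predict propeptide cleavage. Peptide
names are positional (`chain start`, e.g. `COL1a2 568`), so homologous
peptides share a name across species.

## Digestion

Trypsin cleaves after K/R, suppressed before proline by default; a flag
permits K/R-P cleavage because one published grouper marker begins with
proline, implying such a cleavage in the observed data. Missed cleavages
join up to `max_missed_cleavages` (default 2) adjacent fragments; length
bounds default to 6–60 residues. These defaults span the published marker
peptides (12–33 residues, several with one internal K or R). The digest is
deterministic and is property-tested against an independent brute-force
enumeration of adjacent-fragment joins.

## Marker discovery and diagnosticity

Peptides are paired across species positionally — same chain, same mature
start and end — which is valid under the package's gap-free assumption
(collagen chains are highly conserved; length mismatches are end-padded with
`X` and excluded from comparison rather than aligned). A pairing becomes a
marker when sequences differ between at least two species or the presence
pattern differs; a variant carried by exactly one species is flagged
species-specific.

Because identification sees masses, not sequences, species-specificity of a
sequence is necessary but not sufficient: a variant's mass state is
*diagnostic* only if no species outside the variant's presence set can
produce a peak near it. Isolation is checked per mass state against the
complete enumerated fingerprint of every other species — conserved peptides
included, not just panel members — at the matching tolerance plus a guard
band (default 0.2 + 0.05 Da). The guard band covers observation error
(calibration residual, centroiding): a foreign peak whose theoretical
separation is barely above the matching tolerance can otherwise drift into
the match window. Variants with no isolated state are retained but demoted
to supporting-only evidence, mirroring how empirically isobaric markers are
to be used only in combination. Isobaric collisions across the panel are
additionally reported pairwise (`isobaric_conflicts`).

The bundled grouper panel transcribes the published table verbatim —
including per-species evidence levels (MALDI-visible vs LC-MS/MS-only),
isobaric-visibility annotations, and the `COL1a2 568` row whose printed mass
(1319.6) lies ~17 Da below the computed [M+H]+ of its printed sequence. That
row is carried as an annotated anomaly with its diagnostic flag cleared; the
package does not force agreement. The printed masses mix theoretical and
calibrated-observed values at 1–2 decimals, so the validation tolerance
against them is ±0.25 Da.

## Spectrum processing

The preprocessing contract is fixed and explicit (the conventional GUI
tools' "default settings" are not recoverable, so reproducibility is tied to
these parameters): rolling-minimum baseline over a window of 5% of the m/z
span, linearised by a moving average and subtracted with flooring at zero;
Savitzky-Golay smoothing (7 points, order 2). Noise is the sigma-scaled MAD
(x1.4826) in 100 Da segments, linearly interpolated per point; the same
segments provide a local median. A peak is a local maximum whose height
*above the local median* exceeds `snr_threshold` times the local noise — the
median term matters because a minimum-tracking baseline leaves the noise
floor a few sigma above zero, and a raw intensity/noise ratio would pass the
entire floor at threshold 3. Apexes are refined by three-point parabolic
interpolation (recovering a Gaussian center to <0.05 Da at ~3 points per
FWHM). Sparse stick input is auto-detected by point spacing and bypasses
profile preprocessing. All steps are translation-equivariant by
construction, and thresholds in the conventional 3.0–5.0 range give
monotonically nested peak sets.

## Identification rules

Matching tests every MALDI-visible panel mass state against the picked peaks
and keeps the nearest peak within tolerance (default 0.2 Da, Da or ppm
modes; MALDI with external calibration). LC-MS/MS-only markers are excluded
unless explicitly relaxed. Calls are conservative: a species call requires
exactly one species with at least `min_specific` (default 1) matched
diagnostic species-specific variants and zero specific matches for any other
species; conflicting specific evidence yields indeterminate rather than a
majority vote; two or more shared-marker matches without specific support
yield a genus-level call. A variant matched only at non-isolated
(isobaric-prone) states contributes shared support at most.

The end-to-end `identify_sample` pipeline picks peaks at S/N 5.0 — the
stringent end of the conventional range — because the automated pipeline has
no manual-inspection step and a single spurious peak landing on a foreign
diagnostic mass triggers the conflict rule; collagen peptide peaks sit one
to two orders of magnitude above either threshold, so sensitivity is
unaffected.

## Synthetic data

The generator enforces collagen-likeness by construction rather than
learning it: glycine at every third mature position, proline-rich X/Y draws
(P probability 0.30), K/R at density 0.11 among X/Y positions (a
collagen-realistic K+R frequency giving mean tryptic fragments of ~14
residues), 340 triplets per chain, short propeptides (30 N-terminal, 15
C-terminal) to exercise mature-bounds handling. Four species derive from one
ancestral chain set by per-position substitutions at rate 0.008, drawn from
a pool excluding G, K, R; substitutions also never touch the proline that
guards a K/R-P bond nor introduce one there. This keeps tryptic spans
homologous across species, which is what makes the marker-recovery check an
exact set-equality oracle: the discovered panel must contain precisely the
digested peptides overlapping recorded substitution sites. The cost is that
the generator does not model indels, convergent substitutions at K/R sites,
or cleavage-pattern divergence — passing tests say nothing about those.

Spectra are simulated on a uniform grid (0.05 Da step, 800–3600 m/z):
Gaussian peaks of 0.3 Da FWHM at the drawn hydroxylation state of each
peptide (binomial per proline, probability 0.30, capped at the enumeration
cap), log-normal intensities (mu 4.0, sigma 0.5), an exponentially decaying
baseline (amplitude 20, decay 700 Da), additive Gaussian noise (sd 0.5), a
+5 ppm calibration shift, 0.01 Da per-peak jitter, and Poisson spurious
peaks at 0.01 per 100 Da with ~20-fold weaker intensities. These defaults
describe a clean, externally calibrated reflector-mode acquisition of
well-preserved collagen; degradation is modelled by per-peptide peak dropout.
Real MALDI data differ in ways the model ignores (isotope envelopes,
detector saturation, chemical background structure, mass-dependent
resolution), so classification accuracies measured here characterise the
pipeline's logic, not field performance.

Every per-peptide random quantity is drawn unconditionally and dropout is
applied as a threshold on a pre-drawn uniform deviate, so cohorts sharing a
seed but differing in dropout are coupled (common random numbers): the
degraded cohort is exactly the clean cohort with a monotonically growing set
of peaks removed. This turns the accuracy-versus-dropout monotonicity check
into a near-sure comparison instead of a noisy one.

## Phylogeny stand-in

The tree component is a sanity check on inter-species collagen variation,
not model-based phylogenetics: p-distances over concatenated mature chains
(positions with `X` in either sequence excluded; an error if nothing is
comparable), neighbor joining (scikit-bio, negative branch estimates clamped
to zero), and a column-resampling bootstrap (default B=100; a configurable
knob, deliberately far below publication-grade replicate counts) whose
supports annotate the full-data tree's splits and survive newick
round-trips. NJ provably recovers additive matrices, which the tests
exercise on random 4–8-taxon trees.

## Problem sizes and numerical choices

Test and acceptance runs use the generator defaults above with cohorts of
100 spectra per species per condition (clean plus dropout 0.4 and 0.8),
chosen to keep the whole suite a desk-scale computation while leaving the
binomial noise on a 400-sample accuracy estimate near one percentage point.
Ties in tolerance matching are broken by smallest absolute delta; mass
arithmetic is exact floating-point summation with no rounding before
comparison; digests and the generator are fully deterministic given their
seeds, and identification is deterministic given its inputs.

## Known limitations

- Evidence levels (MALDI-visible vs LC-MS/MS-only) are input annotations on
  empirical panels, not predicted; discovered panels default to
  MALDI-visible.
- Coverage percentages for empirical chains depend on the raw MS data and
  exact mature bounds, which are not shipped; the coverage statistic is
  exercised on constructed fixtures.
- The species-count bookkeeping of the published panel (22 biomarkers across
  23 printed rows; per-species specific-marker counts) is preserved verbatim
  rather than resolved; counting conventions are left to the user.
- No semi-tryptic termini beyond the single proline-start case; no replicate
  merging beyond peak-list union; no instrument calibration.
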