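# Methods

`iresact` implements the quantitative layer of a set of IRES-activity
assays: smFISH isoform colocalization, circRNA-reporter flow cytometry,
Ct-based qPCR workflows, polysome gradient distributions, and 5' UTR
sequence features. Each analysis route is paired with a synthetic-data
generator that plants a known ground truth, so every pipeline can be
validated by parameter recovery rather than by eye.

## smFISH isoform quantification

**Model.** Each diffraction-limited punctum is a single mRNA molecule. A CDS
probe detects all isoforms of the transcript; an IRES probe detects only the
long 5' UTR isoform. A CDS spot whose pixel mask shares at least
`min_overlap_px` pixels (default 1) with an IRES spot is called a
long-isoform molecule; otherwise short. "Partial overlap" is deliberately the
weakest mask criterion — one shared pixel — because the two probes label the
same physical molecule and any positive overlap is evidence of coincidence;
the threshold is exposed for sensitivity analysis. A CDS spot is counted once
however many IRES spots it touches, while one IRES spot may support several
CDS spots. IRES spots with no CDS partner are reported as a QC count
(biologically they should be near zero).

**Spot detection.** A pixel is foreground when its intensity exceeds the
local median by `k` local MADs, both computed in a square sliding window
(defaults: window 15 px, k = 5) with symmetric boundary reflection.
8-connected foreground components with area in [2, 200] px become spots; the
area ceiling rejects merged blobs in lieu of watershed splitting. Centroids
are intensity-weighted using the positive part of (intensity − local
median), which is also the integrated spot intensity. The median/MAD
statistic was chosen over mean/SD for robustness in spot-dense
neighbourhoods; the detector is validated by exact equivalence to an
independent per-pixel threshold plus hand flood-fill oracle on random
images, and by planted-fraction recovery, not by tuning to any particular
dataset.

**Pooling.** Counts from all images of one embryo are pooled before the
proportion is formed (images contribute by molecule count, not equally);
region summaries are mean ± SD of the per-embryo proportions. Embryos with
zero CDS spots are excluded and flagged.

**Generator.** Spots are isotropic 2D Gaussians (σ = 1.2 px, a standard
diffraction-limited approximation) with log-normal amplitudes (median 800
above a constant background of 100, log-SD 0.25) and additive Gaussian noise
(SD 5); Poisson noise is omitted as the planted SNR makes it immaterial to
the classification decision. Spot centers are rejection-sampled with an 8 px
minimum separation on a 192×192 px frame with ~40 spots per image — round
values standing in for unspecified acquisition settings, recorded in the
truth sidecar. The planted colocalized count is `round(long_fraction ·
n_spots)` exactly; IRES partners are displaced ≤ 1 px from their CDS
centers so masks overlap under any reasonable threshold. Presets encode the
biology: `somite` plants a long fraction of 0.80, `neural_tube` 0.20. What
the generator does not emulate: tissue autofluorescence gradients, optical
aberrations, 3D defocus, or probe off-target binding beyond a uniform low
false-spot density in the negative-control channel — so recovery results
demonstrate correctness of the counting rules, not robustness to every
imaging artifact.

## Reporter flow cytometry

**Gating.** The chain is QC → viable → singlet → mRuby+ with masks nested by
construction. QC excludes flagged events and (when acquisition timestamps
exist) whole time bins whose event rate deviates from the run median by more
than 3× in either direction — the signature of a clog. The viable gate is a
robust ellipse on (log10 FSC-A, log10 SSC-A): center at the medians,
semi-axes 4 scaled MADs, plus a debris floor at 25% of median FSC-A. The
singlet gate keeps events whose FSC-H/FSC-A ratio is within 12% of the
viable-population median (doublets sit near half). These data-driven gates
replace manual polygons so runs are reproducible; every constant lives in
`GateParams`. The mRuby+ threshold is the 99.9th percentile of the control's
viable-singlet mRuby; the control may be untransfected cells or the empty
vector (both supported — the original cutoff is unstated, and the synthetic
presets use untransfected cells because the empty vector is itself
mRuby-positive).

**Activity.** The readout is the median EGFP of the mRuby+ subfraction
(MFI). Folds are each replicate MFI divided by the mean empty-vector MFI, so
the reference averages exactly 1 and all folds are invariant to a common
rescaling of the fluorescence axis. Construct-vs-reference comparisons use a
Welch two-tailed t-test on replicate folds ("unpaired t-test" with the
unequal-variance correction; the pooled-variance variant would give slightly
smaller p for equal ns), with tiers ns/*/**/***/**** at
0.05/0.01/0.001/0.0001.

**Generator.** Populations are log-normal: viable singlets at FSC 1e5/SSC
5e4 (CV 0.25), debris at 10% of that, doublets with FSC-A ≈ 2·FSC-H.
Transfected cells carry mRuby 2e4 vs autofluorescence 50, and EGFP =
200 · activity_fold (CV 0.35); because the median of a log-normal noise
factor is 1, MFI recovers the planted fold without bias. A clog window
compresses inter-event intervals 10-fold and flags the events. Spectral
spillover and compensation are out of scope. Preset folds (1, 1.2, 4.5, 13)
span the range the reporter resolves between an empty vector and a strong
viral IRES.

## qPCR workflows

**Ct model (generator).** Ct = 20 − log(quantity)/log(efficiency) +
N(0, σ_Ct), with quantity in pg; the anchor "1 pg ⇒ Ct 20" is arbitrary but
fixed. RNase R treatment divides linear-class (and reference) quantities by
`rnaser_linear_decay` and circular-class quantities by `rnaser_circ_decay`;
no-RT samples retain a 2⁻¹⁰ leak (ΔCt 10 at efficiency 2). Nonpositive
quantities emit "undetermined" (NaN) Cts — never imputed, except for the
documented ceiling fallback in the no-RT check (Ct 40).

**Analysis.** Relative levels are 2^(−ΔCt) against a reference amplicon
(Nupl1 or actin — which housekeeping gene applies is configuration, as both
appear in practice). Replicates aggregate as the arithmetic mean of Cts,
i.e. the geometric mean of linear levels, which is the natural scale for an
exponential assay. RNase R enrichment is level(+R)/level(−R) per amplicon
class; the circ/linear ratio then equals d_lin/d_circ exactly at zero noise,
independent of the reference's own decay — the closed-form identity the
tests assert. Standard curves are OLS of Ct on log10(quantity) (≥ 3 distinct
points; efficiency = 10^(−1/slope), warned outside [1.8, 2.1]); absolute
quantification inverts the line and flags extrapolation beyond the fitted
range. Polysome distributions normalize each fraction's Ct to the spike-in
RNA added in equal amount per fraction (cancelling recovery differences —
the generator plants a per-fraction log-normal recovery factor precisely so
the tests can confirm the cancellation), convert to linear levels and
renormalize to sum to 1 across fractions; a ten-fraction gradient maps onto
the five canonical portions (free, 40S/60S, 80S, light polysome, heavy
polysome).

## Sequence features

Inverse controls are reverse complements with orientation flipped; length
and GC content are invariant (property-tested), which is what makes them
composition-matched controls. The uAUG scanner defines the main start codon
to begin immediately after the last UTR base: distance = UTR length −
offset, frame = distance mod 3 (0 = in-frame), and a uAUG is a uORF when the
first in-frame stop lies fully within the UTR; a uAUG without an in-UTR stop
is an "overlapping uORF" whose reading frame runs into the main start.
Transcript intervals are 1-based inclusive (the convention of public
transcript records) with nested, pairwise-disjoint exclusions; image
coordinates elsewhere in the package are 0-based (row, col). RNA-style
sequences (U) are normalized to DNA (T) on input.

## Numerical choices and degenerate inputs

- All randomness flows through one `numpy.random.default_rng(seed)` per
  generator call; no global state. Identical truth ⇒ byte-identical output.
- Median convention: mean-of-middle for even counts (NumPy default).
- A constant image yields zero spots (local MAD is 0 and the strict `>`
  comparison fails); an empty gate mask makes the MFI undefined and raises
  rather than returning a silent 0.
- Spot placement rejects configurations that cannot satisfy the minimum
  separation within a bounded number of attempts rather than degrading
  silently.
- The extrapolation check in `absolute_quantify` uses a 1e-9 relative guard
  so standards at the curve boundary are not spuriously flagged.

## Problem sizes

Default validation sizes are chosen as the smallest cohorts at which the
recovery targets are statistically comfortable: smFISH cohorts of 3 embryos
× 5 images × ~40 spots (≥ 500 CDS spots per condition) for ±0.03 recovery
of the planted long fraction; 20,000 events × 3 replicates per construct for
±10% recovery of activity folds; 100 simulated dilution series at Ct noise
0.2 for the <15% median-error bound on absolute quantification.

## Known limitations

- No cell segmentation or transcript-per-cell assignment; proportions are
  per-image and per-embryo only.
- No watershed splitting of merged spots; at high spot density the area
  ceiling discards merged blobs, biasing counts low in both channels.
- Gating assumes log-normal-ish unimodal scatter; heavily skewed or
  multimodal viable populations would need manual gates.
- The Ct model is a single-efficiency exponential with additive cycle
  noise; it does not simulate amplification curves, melt behaviour, or
  primer-dimer artifacts.
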