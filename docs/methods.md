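# Methods

## Model

**Spectrum representation.** A centroided spectrum is a set of peaks
(µ(k), ι(k)). Intensities are normalised to sum to one before any kernel
evaluation, giving every spectrum probability semantics; duplicate masses
are merged by intensity summation at parse time. Each peak is modelled as
a 2-D Gaussian centred at its measured (mass, intensity) with covariance
diag(σ²ₘ, σ²ᵢ) shared by all peaks — the widths express measurement
uncertainty, not peak shape. The spectrum is the uniform mixture of its
peak Gaussians (weight 1/l per peak). The mixture weights are a modelling
choice of this package: uniform weights make the mixture a proper density
and produce the 1/(l·l′) prefactor in the kernel.

**Probability product kernel.** The kernel between two spectra is the
integral of the product of their mixture densities. For Gaussians with
shared diagonal covariance the peak-pair integral is closed-form,
N(p₁ − p₂; 0, 2Σ) = exp(−Δm²/4σ²ₘ − Δι²/4σ²ᵢ) / (4π σₘ σᵢ); the kernel is
the mean of these integrals over all peak pairs. Variants:

* *peaks* — fragment peaks as measured;
* *mloss* — pseudo-peaks at (µ_prec − µ, ι), the neutral losses.
  Fragments heavier than the precursor give negative losses; these
  indicate adduct/isotope contamination above the assumed precursor and
  are dropped with a warning rather than reflected.
* *diff* — pseudo-peaks at all pairwise differences (µⱼ − µᵢ, ιᵢ·ιⱼ) for
  i < j. The intensity coordinate of a difference is not canonically
  defined; the product ιᵢ·ιⱼ is used because it is symmetric in the
  contributing peaks and damps pairs involving noise peaks. This variant
  has quadratically more pseudo-peaks and requires ≥ 2 peaks.

Each variant is cosine-normalised, K̃ = K(x,y)/√(K(x,x)K(y,y)), before
summation with unit weights. Normalisation is this package's choice: raw
values scale with 1/(σₘσᵢ) and with peak counts, and normalising makes
variant sums comparable and gives the Gram matrix a constant diagonal.
Default combination: peaks + mloss. Mathematically the kernel is strictly
positive; in double precision, values for spectra with no peaks within a
few σ of each other underflow to exactly 0, which downstream code
tolerates.

**Kernel parameters.** σₘ defaults to 0.01 Da (high-resolution
instruments; 0.5 Da is the suggested nominal-mass setting) and σᵢ to 0.05
(relative units after sum-to-one normalisation). Both can be estimated
from replicate spectra: peaks are greedily matched across replicates
within a 0.5 Da tolerance and the pooled within-cluster variances floored
at σₘ ≥ 1e-4 Da, σᵢ ≥ 1e-3 give the estimates. The floors keep the peak
model non-degenerate on noise-free (e.g. synthetic) replicates.

**Per-bit SVMs.** Fingerprints are 528 ±1 bits (FP3 55, FP4 307, MACCS
166, concatenated in that frozen order and computed with OpenBabel; a
schema hash over the bit names guards model/database agreement). Bits
constant across the training molecules are masked from training and
scoring but retain their constant for reporting. Each effective bit gets
an independent soft-margin kernel SVM; a bias term is included (standard
soft-margin form) even though the bare kernel expansion can be written
without one. A zero decision value maps to +1 — an explicit, documented
tie rule. Bits whose training labels are single-class become constant
predictors rather than being dropped, keeping the bit vector length
stable across folds.

**Cost selection and reliability.** C is chosen per bit from
{2⁻⁵ … 2¹⁰} by inner molecule-grouped cross-validation (5 inner folds by
default, shrinking to the group count; accuracy ties break toward the
smaller C). Outer 10-fold molecule-grouped CV yields the reliability
scores wⱼ: plain held-out accuracy of bit j (not balanced accuracy; on
imbalanced bits a constant predictor can earn a deceptively high wⱼ, which
the Poisson-binomial score then correctly treats as weak evidence only
when wⱼ is near the majority rate). Fold assignment shuffles molecules
with a seed and deals them largest-first onto the lightest fold, which
keeps per-fold spectrum counts within one molecule's spectrum count of
each other while guaranteeing that no molecule ever spans folds.

**Scoring and ranking.** Candidates within |Δmass| ≤ mass·ppm·1e-6 of
the estimated neutral mass are scored by the factorised Poisson-binomial
log-likelihood: log wⱼ per agreeing bit, log(1 − wⱼ) per disagreeing bit,
over effective bits only. Reliabilities are clipped into
[1e-6, 1 − 1e-6] so no bit is infinitely informative; scores live in log
space because products over hundreds of bits underflow. Ties are real
(molecules sharing a fingerprint share a score) and break by ascending
molecule id, making rankings deterministic.

**Exact mass estimation.** From an MS1 spectrum, the most abundant peak
(ties → lowest mass, favouring the monoisotopic peak) is the precursor;
the neutral mass removes a proton (1.007276466 Da) in positive mode or
adds one in negative mode. Only [M+H]⁺/[M−H]⁻ are assumed; other adducts
(e.g. [M+Na]⁺, [M+2H]⁺) occur in practice and are the caller's
responsibility via the explicit exact-mass input.

**Isotope patterns.** An element with r isotopes contributes
C(l+r−1, r−1) isotopologues for l atoms, with multinomial abundances;
the molecular pattern convolves element patterns (order-independent),
merging entries within 1e-4 Da (high-resolution regime) by
abundance-weighted mean mass and pruning below 1e-5 relative abundance
before renormalising. The embedded isotope table covers C, H, N, O, P, S,
Na, Cl, K; carbon is fixed at 98.890 % ¹²C / 1.110 % ¹³C and the other
elements use the IUPAC values of the same era, so simulated envelopes are
internally consistent. The table is overridable per call. MS1 matching
converts the pattern to an [M±H] spectrum (sum-to-one intensities,
matching the MS2 convention) and evaluates the cosine-normalised *peaks*
kernel with a dedicated MS1 σₘ (default 0.01 Da, configurable separately
from the MS2 value). Rank fusion supports average-rank, min-rank, and
rerank (isotope score first, fingerprint score breaking isotope ties); the
aggregated list's score column stores the sort key so it stays
non-increasing.

## Synthetic worlds

The generator plants a characteristic fragment mass per fingerprint bit
(spread over 60–250 Da, below every precursor); a molecule with bit j set
emits a peak near that mass in each of its spectra. Difficulty knobs:
Gaussian mass jitter (default 0.002 Da), multiplicative intensity noise
(log-normal, sd 0.2), uninformative noise peaks (3 per spectrum, 55–260
Da), and per-energy random retention of planted peaks (probability 0.8
across 3 simulated collision energies). Molecules carry real CHO formulas
(C18–30) whose monoisotopic masses are the database exact masses, so the
isotope engine works on the same worlds. Per-bit +1 fractions are forced
into [0.2, 0.8] so every bit survives the effective-bit mask, and an
option forces all fingerprints distinct for retrieval experiments. All
sampling flows through one seeded generator; equal seeds give
bit-identical worlds.

What the toy worlds do **not** emulate: real fragmentation chemistry
(peaks are independent given bits, with no neutral-loss structure or
rearrangements), correlated fingerprint bits, mass-dependent measurement
error, adduct/isotope contamination of MS2 spectra, and database-scale
candidate lists. Passing tests therefore demonstrate the correctness and
qualitative behaviour of the machinery (kernel math, CV hygiene, score
coherence, rank recovery, pooling benefit), not identification rates on
real libraries.

## Evaluation experiments and problem sizes

The shipped experiments (`specfp.experiments`, reused by
`scripts/acceptance.py`) run at desk scale, chosen so the full suite
executes in minutes on one CPU:

* retrieval recovery: 200 unique-fingerprint candidates, 20 bits,
  200 corruption replicates per reliability level w ∈ {0.6, 0.8, 0.95, 1};
* learning curve: 100 molecules × 2 energies, 20 bits, 10 outer folds,
  nested training fractions 20/60/100 %, C-grid {2⁻², 1, 2²} with 3 inner
  folds;
* energy pooling: 40 molecules × 3 energies, 5 seeds, one fifth of the
  molecules held out.

The reduced C-grid in the experiments trades a slightly coarser cost
search for speed; the estimator default remains the full 2⁻⁵…2¹⁰ grid.

## Numerical choices and degenerate inputs

* Quadrature cross-checks of the closed-form integral run in
  standardised coordinates (u = m/σₘ), keeping the integrand
  well-conditioned for sharp peak models.
* Gram PSD tolerance: minimum eigenvalue ≥ −1e-9 · trace/n.
* Empty mass windows are valid results (empty ranking, exit 0 in the
  CLI); empty spectra, all-zero intensities, single-class training
  labels, unknown elements and schema mismatches raise explicit errors.
* Tanimoto similarity of two all-absent fingerprints is defined as 1
  (identical empty key sets) and logged.
* Model bundles contain no timestamps; retraining with equal seeds is
  byte-identical.

## Known limitations

* Fingerprint bits are treated as independent in both learning and
  scoring; correlated substructure keys violate this and the
  Poisson-binomial score has no dependency correction.
* Reliability scores are in-library CV accuracies; they transfer poorly
  to queries far outside the training molecules' chemical space.
* Only singly-charged protonated/deprotonated species are modelled; no
  multimers, multiply-charged ions or fine isotopic structure.
* The MassBank dialect parser targets the record subset documented in
  `specfp.spectra`; profile data, mzML and centroiding are out of scope.
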