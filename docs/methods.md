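# Methods

This note documents the models, defaults, and design choices behind
`ugimem`, in the order data flows through the pipeline.

## Library enumeration and masses

A Ugi product's formula is the elementwise sum of its four reagents'
formulas minus H₂O; its monoisotopic mass M is the sum of per-element
counts times the most-abundant-isotope masses from a pinned IUPAC table
(`elements.py`). Pinning the table (rather than depending on an external
mass library) makes every computed mass bit-reproducible across
environments. Enumeration order is frozen — nested loops
amine → aldehyde → acid → isocyanide, amine slowest — so library index
*i* always denotes the same product; indices are 1-based in all
user-facing I/O.

The packaged reagent table (5 amines, 5 aldehydes, 12 Boc-protected
acids, 5 isocyanides) yields 1500 products with M between ~449 and
~733 Da, most in the 500–700 Da window. Adduct m/z values subtract the
electron mass (appropriate at FT-ICR mass accuracy; a flag disables this
for coarse matching), giving the ordering [M+H]⁺ < [M+Na]⁺ < [M+K]⁺.

**Isotopes.** Envelopes use a carbon-binomial model only: the M+k peak
has relative abundance C(n_C, k)·(p/q)ᵏ with p = 0.0107 and offsets of
k × 1.00335 Da. This is accurate for CHNO molecules; the library's few
S- and Cl-containing products (methionine-derived acids,
4-chlorobenzylamine) additionally have ³⁴S/³⁷Cl satellites that the
model ignores. For peak *detection* this is immaterial — the M+0 and
M+1 positions used by the readout are unaffected — so full isotopologue
convolution was deliberately left out.

**Mass collisions and subset selection.** `mass_collisions` partitions
products into groups whose masses agree within a ppm tolerance
(transitive closure; verified against an all-pairs oracle in the tests).
The packaged library contains exact formula twins (e.g.
Boc-*N*-Me-Val + ethyl isocyanoacetate vs Boc-β-homoleucine + methyl
isocyanoacetate condense to the same formula), which single-peak readout
cannot distinguish even noiselessly. Direct-mapped data plates therefore
draw their compound subset with `select_compound_subset`, a greedy scan
that accepts a product only if all of its H/Na/K adduct peaks and ¹³C
satellites stay > 2× the lookup tolerance away from every already
reserved peak (including the reference calibrant). Sparse mappings use
the plain leading subset: their error correction absorbs degeneracy.

## Sparse constant-weight code

Data blocks of b bits map to K = 2ᵇ codewords of length n and weight w
(default n = 512, w = 32, b = 16). Construction is seeded uniform
constant-weight sampling with a greedy repair loop: verify the minimum
pairwise distance exactly, resample one member of every violating pair,
repeat (10 rounds max, then fail loudly reporting the best achieved
distance). For the default geometry random sampling is comfortably
inside the Gilbert–Varshamov regime — two random weight-32 subsets of
512 positions overlap by 2 on average, giving typical distances near 60
— so the d_min = 36 target is reached essentially immediately; the cost
is the verification, not the construction. The codebook interface is a
plain (K, n) binary array, so a structured construction can be swapped
in without touching the codec.

Verification packs codewords into uint64 lanes and scans the upper
triangle in 64-row blocks with XOR + `np.bitwise_count`, ~2 minutes for
the 2.1 × 10⁹ pairs of the default codebook on one CPU. Decoding is
exact nearest-codeword search (same packed popcount); ties resolve to
the smallest data value and raise an explicit ambiguity flag, because a
silent arbitrary choice would be untestable. Pad bits are zeros, with
the count stored in the presence-matrix metadata and stripped on decode.
Block values are MSB-first, assigned to codewords in construction order.

The symmetric channel simulation corrupts every matrix cell
independently at rate p (or exactly k flips per row), then decodes. At
exactly 17 flips per row under a d_min ≥ 36 codebook the decoded BER is
identically zero (guarantee); well beyond the radius most rows still
decode correctly because a corrupted word remains far closer to its own
codeword (distance ≈ n·p + w-ish) than to any other (≈ 2w − 2·overlap).

## Spectrum simulation

`specsim` generates plate spectra on a uniform m/z grid (default
0.001 Da over 300–1000, matching the sub-0.001 Da peak-width regime of
FT-ICR) rather than event lists — simpler, and adequate for a readout
that only ever takes window maxima. Per spot:

* every present, non-failed compound contributes Gaussian peaks at its
  H/Na/K adduct positions with FWHM = m/R (R = 1.3 × 10⁵ default) and
  carbon-binomial isotope satellites;
* adduct intensity ratios default to Na : H : K = 1 : 0.3 : 0.2
  (sodiated-dominant); these are free parameters — no acceptance result
  depends on their exact values;
* per-compound, per-spot amplitudes are lognormal (median 300 a.u.,
  log-sd 0.8) divided by (mixture size)^0.5, a stand-in for competitive
  ionization;
* with probability 0.15 a compound carries a correlated reagent-complex
  satellite at M + (its amine's mass), sodiated, at 30 % of the product
  amplitude — the kind of "non-intuitive identifier" multi-peak models
  can exploit;
* a fixed, seeded set of 200 matrix-background peaks is shared across
  spots (HCCA-like chemical noise), plus a truncated-Gaussian baseline
  (mean 10, sd 2);
* each spot's m/z axis is scaled by a random offset (Gaussian, sd 3 ppm)
  — exactly the error a one-point calibrant can undo; higher-order mass
  error is out of scope;
* the reference calibrant (neutral mass 450.2 Da) is spiked into every
  spot.

Reaction failure is a **library-level** Bernoulli mask (default rate
0.10, consistent with a ~90 % validated-library yield): a failed well
emits no product peaks anywhere on the plate. Because data plates are
dispensed from library wells that already passed validation, end-to-end
data-recovery experiments run with failures disabled for the selected
subset; the failure rate instead manifests in the library-validation
workflow, where the detected fraction comes out ≈ 0.90.

Everything is driven by a single `numpy` generator seeded from
`SimParams.seed`: identical (matrix, params, seed) give byte-identical
spectra. What the simulator does *not* model: physical ionization,
laser-shot statistics, detector transients, true HCCA cluster chemistry,
or instrument drift — so passing tests demonstrate the correctness of
the codec/readout logic under the stated statistical structure, not
instrument-grade performance.

## Readout

**Calibration** finds the intensity apex within ±50 ppm of the reference
m/z; if it clears the clipped background by SNR ≥ 5 the m/z axis is
divided by (1 + offset·10⁻⁶). A spot without a usable calibrant raises a
flagged calibration error rather than passing silently. Calibrating an
already calibrated spectrum changes it by less than the grid step.

**Background** is estimated by iterative one-sided 3σ clipping (clip
values above μ + 3σ, re-estimate, to convergence or 10 passes). Chosen
for robustness and determinism; the method tag is stored so a
median/MAD alternative can be swapped in. A zero-variance background
(noise-free simulation, missing spot) raises a degenerate-background
error at the API level; the pipeline's matrix transform passes such rows
through unscaled, since intensities over an exactly-zero background
already behave like SNR values.

**SNR transform** is (I − μ)/σ per spot, making classifier inputs
scale-free across spots (raw-intensity mode exists behind the
`kind` field). Peak lookup takes the maximum value within ±15 ppm
(≈ 2 × FWHM at R = 1.3 × 10⁵) of the target m/z; configurable.

**Single-peak detection** thresholds each compound's sodiated-peak SNR.
Thresholds come from exact ROC curves (candidate thresholds are
midpoints between sorted unique scores plus ±∞ sentinels; counts are
exact at each), minimizing √(FPR² + (1 − TPR)²); ties prefer the larger
threshold (fewer false positives). Data plates use per-compound
thresholds learned from the labeled training region; library validation
uses one global threshold over all (well, product) pairs, with
mass-degenerate partners of the expected product booked as TP/FN, never
FP.

**Multi-peak detection** fits one model per compound on the labeled 30 %
of spots (seeded uniform split — exact per-compound stratification is
not simultaneously achievable across 32+ label columns; compounds that
come out single-class in training fall back to a flagged constant
predictor). Features are SNR-matrix columns that survive a noise-floor
prune (mean SNR ≥ 3, at most 20,000 columns). Logistic models take the
top-64 columns by |AUROC − 0.5| — ranking by distance from chance keeps
anti-correlated (suppression) features usable — capped at half the
training-set size: on small desk-scale plates (~40 training spots) the
full 64-feature selection overfits the ranking step, while plates at
full 1536-spot scale retain all 64. Random forests (300 trees, unlimited
depth) skip the AUROC refinement since they select features internally.

## Plate geometry and pipelines

Plates are 32 × 48 = 1536 spots, row-major (A1…AF48), mixture index =
spot index. Transfer lists contain one 2.5 nL record per presence-matrix
"1" plus one 30 nL matrix record per spot, and reject any spot over
200 nL. Each 4 μL library well supports 1600 ≥ 1000 dispenses. A
`RunConfig` (JSON-serializable) pins every knob and seed, so any run is
reproducible bit-for-bit; missing spectra decode as all-absent rows with
a per-row flag, leaving sparse correction a chance to rescue them.

## Problem sizes used in tests and the acceptance script

The test suite exercises the codec at the full paper operating point
(n = 512, w = 32, K = 2¹⁶, exact verification of ~2.1 × 10⁹ pairwise
distances; channel trials at exactly 17 flips per mixture). End-to-end
plate experiments use a 64 × 64-bit payload on 128 mixtures of a
32-compound subset with the m/z grid restricted to 430–800 Da — the
window actually occupied by the subset's adducts — which keeps a full
write/simulate/read cycle at a few seconds without changing any
per-peak physics. Library validation is exercised on a 100-well
one-product-per-well plate.

## Known limitations

* Carbon-only isotope model (no S/Cl satellites).
* Single-point multiplicative mass calibration only.
* The simulator's adduct ratios, suppression exponent, and
  complex-formation rate are plausible defaults, not fitted to
  instrument data.
* Single-peak readout cannot separate exact-mass twins; this is handled
  by subset selection (direct mapping) or error correction (sparse
  mapping), and multi-peak models can separate them only when correlated
  secondary features exist.
* Soft-decision decoding from intensities is out of scope; decoding
  consumes hard presence calls.
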