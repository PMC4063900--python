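# Methods

This note records the models, conventions, numerical choices and known
limitations behind `oligoims`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Mass model and conventions

A peptide's elemental composition is the sum of its residue compositions
plus one water; residue compositions, atomic masses and isotope abundances
come from the NIST tables shipped with pyteomics. Average masses are
abundance-weighted over isotopes; monoisotopic masses use the most abundant
isotope of each element. A tyrosine–tyrosine cross-link is modeled purely
as the loss of two hydrogen atoms per bond (−2.016 Da average, −2 Da
nominal); no positional bookkeeping is done because mass is the only
observable the analysis uses. An n-mer with k bonds requires k ≤ n − 1 (a
connected network of n chains) and k indexes total bonds, so a "mixed"
trimer — one covalent dimer plus a non-covalently bound monomer — is
simply (n = 3, k = 1).

Two m/z conventions are implemented. `physical` uses the proton mass
(1.00728 Da) as the charge carrier and is the default everywhere. `nominal`
uses exactly 1.000 Da; it exists because the published species table this
package reproduces is internally consistent only under
M = z·(m/z) − z·1.000, to ±0.01 Da across 50 of its 52 printed mass cells.
The two remaining cells (both in the 7+ trimer block) deviate by 0.28 and
0.04 Da; the first is a typo in the source — its own printed mass shift
matches the m/z-derived mass, not the printed one — and the second is
last-digit rounding of the printed m/z. The tests assert exactly this
behavior rather than excluding the rows silently. The inferred bond count
is convention-independent: the carrier term cancels in ΔM at fixed z.

## Isotopic distributions

Per-element isotope patterns (natural abundances) are convolved by binary
exponentiation, tracking per-nominal-peak abundance and abundance-weighted
mass moment, then aggregated by neutron count: each output peak is the
centroid of all isotopologues sharing a nominal mass, which is what an
instrument that resolves the ~1.0033/z envelope spacing but not the
fine structure records. `prune_below` (default 1e-4 fractional abundance)
drops negligible peaks and renormalizes; internal tails are trimmed at
≤1e-15 so pruning never distorts retained abundances. The test oracle is a
deliberately naive atom-by-atom polynomial product kept independent of the
production path; the two agree to total-variation distance < 1e-9 on the
full Aβ1-40 composition (comparisons exclude abundances below 1e-12, where
double-precision underflow dominates both computations).

## Synthetic 2D spectra

Each species contributes a separable product of Gaussians: the isotope
envelope mapped to m/z at its charge (σ_mz default 0.02 Th — a simulator
parameter, not a measured instrument resolution) times a sum of Gaussian
drift components (compact/extended conformers). Peaks are normalized as
densities, so the grid-summed intensity of a noise-free spectrum equals the
sum of scenario intensities — asserted to 0.1 % in tests. Noise is additive
Gaussian with standard deviation expressed as a fraction of the spectrum
maximum, clipped at zero; Poisson statistics, detector saturation and
T-wave transport physics are out of scope. Default grid steps are 0.02 Th
and 0.05 ms, which resolve envelope spacings to z ≈ 10 and the 6–17 ms
drift range of interest. Rendering is bit-reproducible under a fixed seed.
What passing simulator-based tests show is that the analysis chain inverts
this generative model; real spectra add baseline drift, tailing peak
shapes, envelope overlap and intensity-dependent noise that the generator
deliberately omits.

## Envelope assignment

Peak picking sums the gated drift rows, takes local maxima above a relative
threshold (default 0.05 of the window maximum), and refines each apex by
3-point parabolic interpolation; peaks closer than one grid step merge —
the documented resolution limit. Charge is the z ∈ 1..z_max (default 12)
whose 1.0033/z best matches the *median* adjacent spacing — the median
tolerates one missed or merged isotopologue, a mean would not — accepted
only within 20 % relative deviation, ties toward smaller z. Species
assignment minimizes |M − (n·M_mono − 2k·m_H)| over n ≤ n_max, k ≤ n − 1
(ties toward smaller k) and fails informatively beyond the tolerance
(default 1.0 Da). Assignment uses average masses, matching how average m/z
is read off an unresolved-fine-structure envelope; a monoisotopic mode
exists but is off by default. Peak-picking thresholds are
simulator-validated choices, not published values.

## Cross-link inference

ΔM = M_after − M_before per (n, z); k = round(−ΔM/2) clamped at ≥ 0;
residual |ΔM + 2k| beyond the matching tolerance (default 0.5 Da, bracketing
the 0.2–0.35 Da residuals typical of the tabulated pairs) reports k as
unassigned (mass loss) or as k = 0 with a "no cross-link evidence" flag
(mass gain). When a charge state exists only after the reaction, the
before-reference mass is taken from the same order's other charge states —
the neutral mass is z-independent — and the report row keeps its
before-columns empty, mirroring how such species are tabulated.

## CCS calibration

The T-wave relation Ω = c·q·t_D^X is empirical; (c, X) are fitted to
calibrant triples (q, t_D, Ω_ref). Initialization is the ordinary
least-squares line ln(Ω/q) = ln c + X·ln t_D — exact for noise-free data —
followed by bounded nonlinear refinement (0 < X < 2) minimizing *relative*
residuals Σ((Ω − c·q·t_D^X)/Ω)². Relative weighting is deliberate:
calibrant reference uncertainty is multiplicative, and an absolute-error
objective lets the largest cross-sections dominate and measurably inflates
the exponent variance (the simulation study in the tests: 15 calibrants,
1 % multiplicative noise, 100 seeds — the relative objective recovers X
within ±0.02 in ≥ 95 runs, the absolute one does not). Reference Ω values
for the usual protein standards are instrument-protocol data and are not
packaged; calibrants come from a user CSV, and the demo uses synthetic
calibrants drawn from (c = 53.1, X = 0.652) — the published parameters for
the dataset this package reproduces. Conversions outside the calibrated
drift range ([6, 17] ms in the demo) are flagged `in_range=False`, not
refused. No reduced-mass or per-charge correction beyond the explicit q
factor is applied.

## Shared-center drift decomposition

Profiles of one species under two conditions are fit jointly by Gaussians
whose centers are common to both conditions; widths are tied as well by
default (`tie_widths=False` relaxes this — the stricter reading of
"same set of curves" is the default). Amplitudes are free per condition and
non-negative. The solver uses variable projection: seeded multi-start
(default 10 starts) bounded least squares over centers and widths, with the
amplitudes of every condition solved exactly by NNLS at each step. Each
condition's residuals are scaled by its profile maximum so the conditions
weigh equally regardless of total intensity. Components are reported in
center order with per-condition *area* fractions (amplitude × width ×
√(2π), normalized); a condition with zero total area has undefined (NaN)
fractions. `n_components='auto'` picks the smallest n whose BIC-style score
(N·ln(RSS/N) + p·ln N, RSS floored so near-perfect fits tie) is within 1 %
of the best over 1..n_max; a fit with pooled R² < 0.2 or centers closer
than a component width is flagged ill-conditioned. Degenerate inputs:
identical profiles recover equal amplitudes; a single component reduces to
moment matching; pure noise selects one component and flags it.

The published supplementary fit this mirrors reports only that amplitudes
alone changed between conditions; its numeric amplitude table is not
available, so the tests validate parameter recovery on simulated pairs
(including the halve/double scenario at SNR 50, recovered within 5 %)
rather than reproducing specific published amplitudes.

## Pipeline

The pipeline (YAML config; `run` subcommand) renders per-window before and
after spectra, assigns each configured envelope, matches species, attaches
cross-sections, and decomposes flagged windows, writing every stage's
outputs plus a structured log (stage, parameters, SHA-256 of outputs) to
the run directory; two runs with the same seed are byte-identical. Before
decomposition the extracted drift profile has its median subtracted and is
clipped at zero: summing zero-truncated noise over a window's m/z rows
leaves a positive pedestal that would otherwise bias widths and fractions.
Per-window sub-seeds derive deterministically from the run seed.

## Problem sizes

Tests and the acceptance script run on deliberately small problems chosen
to exercise every code path: single-window spectra of a few hundred × ~100
grid points, the full z ≤ 10 × n ≤ 3 charge-inference grid, 100-seed
calibration studies, and drift profiles of 161 samples. The complete suite
runs in a few seconds on one CPU.

## Known limitations

- Gaussian peak shapes in both dimensions; no Lorentzian tails, baseline
  drift or saturation.
- Windows and drift gates are analyst-specified; there is no untargeted
  whole-spectrum deconvolution or joint fitting of overlapping envelopes.
- Cross-link chemistry is mass-only (−2 H per bond); no Tyr-position or
  topology tracking, no other modifications, no reaction kinetics.
- The charge-carrier conventions are exactly two (proton, 1.000 Da);
  adducts other than protons are not modeled.
- mzML/vendor-format ingestion is out of scope; spectra enter as the TSV
  dialect documented in `synthetic_spectra`.
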