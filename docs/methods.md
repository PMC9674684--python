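# Methods

## Observable model

A deuteron in an oriented anisotropic phase yields a symmetric doublet at
center ± Δν/2. The splitting is tied to the C–D bond order parameter by

    Δν = (3/2) · χ · |S_CD| · f

with χ the quadrupolar coupling constant (default 167 kHz, typical for
aliphatic C–D) and f a geometric factor for the director orientation
relative to the magnetic field: 1 when parallel, ½ when perpendicular.
SDS/1-decanol mimetic phases orient with the director perpendicular to B₀,
so f = ½ is the default; both χ and f are configurable everywhere the
conversion appears. Experimental splittings are magnitudes, so predictions
report |Δν| and the sign of S_CD is not recoverable from a splitting alone.

The order parameter itself is the plain time-and-bond average of
P₂(cos θ) over the trajectory, with the director fixed to laboratory z (the
bilayer normal). Instantaneous-normal estimation is intentionally out of
scope. Standard errors come from 5 contiguous block averages (default),
which absorbs slow orientational correlation better than a per-frame
variance.

For a CD₃ label spinning fast about its C–C axis, the deuteron order
parameter is the axis order parameter scaled by P₂(cos 109.47°) = −1/3
exactly. `methyl_axis_scd` provides this second route; on a fast-rotor
fixture the two routes agree to the Monte-Carlo error, and that equivalence
is asserted in the tests.

## Spectra

Spectra are uniformly sampled intensity traces over an axis defined by point
count and spectral width; the default fixture axis (32768 points, 43.1 kHz)
reproduces the 1.32 Hz/point digital resolution of the acquisition setup the
package targets. Synthetic lines are height-normalised Lorentzians (the
usual liquid-crystal line shape; Gaussian behind a flag).

Doublet detection:

- the trace is lightly smoothed (5-point Hann) before peak picking;
- the noise floor is 1.4826 × MAD of the outer 10 % of the axis, where no
  doublet sits — robust to signal near center;
- local maxima above `min_snr` × floor (also used as a prominence bound) are
  refined to sub-bin positions as the midpoint of the half-maximum
  crossings. The apex of a broad Lorentzian is flat, so a 3-point parabola
  there is noise-dominated; the half-height flanks are steep, giving
  position errors well under one bin at 1 % noise;
- peaks are paired when mirror-symmetric about the axis center within a
  tolerance (default 3 axis spacings); ambiguous pairings resolve by closest
  amplitude and are logged; unpaired peaks are returned as warnings, never
  silently merged. Doublets are reported outermost first.

Residual-doublet identification normalises both spectra to unit maximum
(the comparison is between profiles, not absolute intensities) and matches
doublets by splitting within twice the pairing tolerance, since each of the
two detections carries up to a bin of error. Exactly one unmatched doublet
is demanded; anything else raises an ambiguity error listing candidates.

## Splitting prediction and bimodality

Fragments that toggle between two long-lived average orientations show two
splittings. `predict_splitting_set` detects this on the per-frame P₂ series
with an exact 1-D two-means split (sorted scan minimising within-class sum
of squares — deterministic, no iterative clustering), declaring two states
when both clusters hold ≥ 20 % of frames *and* the cluster means are
separated by more than twice the summed within-cluster standard deviations.
The weight rule alone would split any unimodal series; the separation rule
is what makes the test meaningful. Two-valued fragments are listed largest
splitting first; ordering is irrelevant downstream because RMSRD matching
is assignment-based.

## RMSRD and the configuration search

For each fragment, predicted and experimental splittings are matched by the
minimum-cost one-to-one assignment on the relative deviation |(p − e)/e|
(at most two entries per side, solved exactly). Experimental splittings
left unmatched contribute a relative deviation of 1.0, so a missing doublet
can never improve a score. RMSRD is 100 × the root mean square over all
experimental entries; the denominator is always the experimental value.
RMSRD is unbounded above (a prediction many times the experimental value
deviates by more than 100 %).

Candidates are drawn uniformly on the sphere (uniform in cos tilt), uniform
in azimuth and depth, each with a derived seed. Evaluation is sequential
with deterministic ordering so the stop-at-first-acceptable rule (default
threshold 50 %) is reproducible; the full evaluated set is always returned
ranked by RMSRD with seed tie-breaks. Trajectories come from an injected
provider; the repository never launches an MD engine. No multiplicity
control is applied across candidates — the score ranks, it does not test.

A practical conditioning note: a fragment whose bond sits near the magic
angle (54.74°) has a near-zero splitting, and relative deviations against
it blow up. The planted-truth test geometries therefore keep every
fragment's polar angle away from the magic angle — as a real labelling
scheme would, since a vanishing splitting is unobservable anyway.

## Umbrella sampling and WHAM

Window centers are placed at every multiple of the spacing (default 0.2 nm,
i.e. 2.0 Å) crossed by a pull trajectory. Window count is treated as data,
not a constant. The WHAM self-consistency

    P(ξ) = Σᵢ nᵢ(ξ) / Σᵢ Nᵢ exp[(Fᵢ − wᵢ(ξ))/kT],
    Fᵢ = −kT ln Σ_ξ P(ξ) exp(−wᵢ(ξ)/kT)

is iterated on 200 uniform half-open bins (default) until the largest
window free-energy change is below 1e−6 kT or 10⁵ iterations, both logged;
non-convergence warns with the final residual and still returns the
profile. Temperature defaults to 310.15 K (37 °C) and must be uniform
across a window set. The profile is reported in kJ/mol, gauge-fixed to zero
minimum; empty bins carry +inf, never fabricated values. Uncertainties are
optional bootstrap resamples of each window's series.

Connectivity is checked at the window level: windows form a graph with
edges where histograms share an occupied bin, and more than one component
raises an error listing the gaps. (Bin-level contiguity would false-alarm
on a single stray sample.) `detect_poor_sampling` flags consecutive-window
pairs whose normalised histograms share less than 5 % mass — the cue to add
windows there. `endpoint_symmetry` compares count-weighted mean free
energies over the two margins, so sparsely visited tail bins do not
dominate; a translocation with no driving force should show zero
difference within sampling error.

## Membrane metrics

RDFs are 3-D with periodic minimum image and exact spherical-shell
normalisation (4/3 π (r₊³ − r₋³)), so a uniform fluid gives g = 1 without
the 4πr²Δr small-bin bias; r_max may not exceed half the smallest box
length; self-pairs are excluded when selections overlap. Slab-corrected
RDFs are out of scope.

The α-helix count re-implements the Kabsch–Sander hydrogen-bond criterion
so tests run hermetically: an i→i+4 bond is accepted when
E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol < −0.5 kcal/mol,
with missing amide hydrogens rebuilt at 1.01 Å along the direction opposing
the bisector of C(prev)→N and CA→N. Two consecutive accepted bonds mark the
four bracketed residues helical; only the α class is assigned (3₁₀/π,
sheets and turns are out of scope). On an ideal 13-residue helix the count
matches an established DSSP implementation exactly (asserted in a test).

Depth is the unsigned |z_COM − z_bilayer| with the bilayer center defined
as the mean z of designated bilayer atoms (or 0 for pre-centered systems);
masses default to unity and are configurable. The helix-versus-depth
profile bins per-frame counts by COM depth; empty bins report zero
occupancy and NaN statistics.

## Synthetic generators

Every generator records its analytic ground truth alongside the data and
derives all randomness from an explicit seed (identical parameters →
identical bytes).

- **Cone**: bond directions uniform on a spherical cap via inverse-CDF in
  cos θ (exact, unlike rejection sampling); closed-form
  S = ½ cos θ₀ (1 + cos θ₀), cross-checked in tests by numerical cap
  integration.
- **Methyl rotor**: three deuterons at the tetrahedral angle about a tilted
  axis with uniform random phase per frame (the fast-spin limit, making the
  two averaging routes exactly equivalent in expectation).
- **Two-state**: geometric dwell times between two tilted wobble cones; the
  azimuthally averaged per-state order parameter is exactly
  P₂(cos tilt) × S_cone by the spherical-harmonic addition theorem.
- **Placement**: each labelled fragment owns an axis at a fixed offset to
  the peptide axis; tilting moves every offset rigidly. Azimuth and depth
  deliberately leave the observable unchanged, exactly as in the real
  experiment, which is blind to both — so the search can only recover tilt,
  and tests assert exactly that.
- **Umbrella**: samples drawn by inverse-CDF on a 10⁴-point grid of the
  biased Boltzmann density — the target distribution is hit exactly (up to
  grid resolution) with zero autocorrelation, so WHAM tests probe WHAM, not
  a sampler. The stair-shaped test potential (adsorption well, two
  ascending steps, descent to equal endpoint energies) is a monotone PCHIP
  interpolant through fixed knots.
- **Helix**: backbone built by natural-extension (NeRF) placement with
  standard bond geometry; frayed termini use extended dihedrals.
- **Point cloud / spectra**: uniform periodic ideal gas; doublet spectra on
  the instrument axis.

What these fixtures do *not* emulate: force-field energetics, solvent and
lipid structure, autocorrelated sampling, baseline/phase artifacts in
spectra, and finite acquisition effects. Passing tests therefore
demonstrate the correctness of the estimators and solvers on data whose
generating process is known — not the fidelity of any force field or the
attainability of a given RMSRD on real spectra.

## Problem sizes and statistical margins

Order-parameter recovery uses 10⁵ frames per cone (Monte-Carlo error
≈ 10⁻³, against a 0.02 assertion band). WHAM recovery uses 30 windows ×
10⁴ samples (harmonic, 0.1 nm spacing, k = 1000 kJ mol⁻¹ nm⁻²) and 31
windows × 5·10³ (stair, 0.2 nm spacing, k = 500): spring constants and
spacings were chosen once so neighbour histogram overlap sits comfortably
above the 5 % poor-sampling threshold, and drops far below it when a
window is removed. Ideal-gas RDFs use 4 × 5000 points with 0.04 nm bins so
per-bin shot noise (~1 %) stays well inside the 5 % flatness band —
pair-count fluctuations are correlated across pairs sharing a point, so
the naive Poisson estimate understates the noise and the margin is sized
accordingly.

## Known limitations

- The direction of comparison is fixed: simulated S_CD is converted to
  splittings and compared in splitting space; the inverse mapping is not
  unique when fragments are bimodal.
- The two-means bimodality rule cannot distinguish two states from one
  strongly non-Gaussian state with matching first moments; dwell-time
  analysis is not implemented.
- WHAM uncertainties are bootstrap-only; no autocorrelation correction is
  applied (the exact-sampling fixtures have none by construction).
- The selection mini-language covers resname/name/resid/chain with and/or
  — no parentheses, wildcards or distance-based selections.
- PDB I/O inherits the format's 3-decimal Å precision (10⁻⁴ nm).
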