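# qsplit

Quadrupolar-splitting analysis for membrane-embedded peptides: from
oriented-sample ²H-NMR doublets and MD trajectories to an equilibrium
membrane-bound configuration, and from umbrella-sampling windows to the
translocation free-energy profile.

## The problem

Hydrophobic cell-penetrating peptides (the 13-residue peptide PLILLRLLRGQFC
is the motivating case) cross lipid bilayers passively, but their structure
inside the membrane is hard to see: it is dynamic, so crystallographic
snapshots miss it. Selective deuterium labelling offers a handle. A C–D bond
in an oriented anisotropic phase (e.g. an SDS/1-decanol membrane mimetic that
aligns in the magnetic field) produces a doublet whose separation — the
quadrupolar splitting Δν — reports the bond's orientational order parameter

    S_CD = ⟨ (3 cos²θ − 1) / 2 ⟩,      Δν = (3/2) χ |S_CD| f,

where θ is the angle between the bond and the director (the bilayer normal),
χ ≈ 167 kHz is the aliphatic C–D quadrupolar coupling constant, and
f ∈ {1, ½} accounts for the director's orientation relative to the field
(½ for the perpendicular-orienting SDS phase). Measuring Δν for several
labelled side chains and asking which rigid placement of the peptide
(tilt, azimuth, insertion depth) reproduces them all pins down the
equilibrium structure *including its dynamics*.

`qsplit` implements that pipeline:

- **spectra** — model/synthesize doublet spectra, detect and pair symmetric
  doublets, add spectra, identify the residual doublet present only in a
  fully labelled sample (how an unassigned fragment's splitting is isolated),
  and compute splitting shifts between samples.
- **order_params** — S_CD from trajectories, CD₃ fast-rotor averaging
  (S_CD = −S_axis/3), conversion to splittings, and bimodality-aware
  per-fragment prediction (a fragment living in two long-lived orientations
  shows two splittings).
- **structure_fit** — the RMSRD score (root-mean-square relative deviation
  between predicted and experimental splittings, in %), random candidate
  placements uniform on the sphere, and the accept/rank search loop
  (default accept threshold 50 %).
- **pmf_wham** — umbrella-window bookkeeping (centers every 2.0 Å along a
  pull), self-consistent WHAM reconstruction of the potential of mean force
  at 310.15 K, poor-sampling diagnostics, and endpoint-symmetry checks.
- **membrane_metrics** — periodic minimum-image RDFs, a hermetic
  Kabsch–Sander α-helix assignment (helical residue count vs. membrane
  depth), and center-of-mass depth series.
- **fixtures** — synthetic generators with closed-form ground truth (cone
  wobble, methyl rotors, two-state dynamics, ideal helices, exact Boltzmann
  umbrella samples, ideal-gas point clouds, doublet spectra).

Production MD is *not* run here: trajectories are consumed, and candidate
placements are realised through an injectable provider.

## Worked example

```python
import numpy as np
from qsplit import SplittingSet, CandidateConfiguration, compute_scd, \
    scd_to_splitting, generate_candidates, search
from qsplit.fixtures import make_cone_trajectory, make_placement_trajectory, \
    placement_provider

# An order parameter from a trajectory: a C-D bond wobbling in a 60 degree
# cone about the bilayer normal has S = cos(60)*(1+cos(60))/2 = 0.375.
fx = make_cone_trajectory(60.0, n_frames=100_000, seed=1)
est = compute_scd(fx.trajectory, fx.selections[0])
print(f"S_CD = {est.s_cd:.4f}  ->  {scd_to_splitting(est.s_cd)/1e3:.2f} kHz")

# A configuration search against five labelled leucines.
offsets = {"Leu-2": 0.0, "Leu-4": 13.0, "Leu-5": 30.0, "Leu-7": 55.0, "Leu-8": 75.0}
planted = make_placement_trajectory(35.0, offsets, seed=42)
experimental = SplittingSet({k: (v,) for k, v in planted.truth["splittings"].items()})
candidates = [CandidateConfiguration(35.0, 0.0, -1.8, seed=0)] + \
    generate_candidates(20, seed=7)
ranked = search(candidates, placement_provider(offsets), planted.selections,
                experimental)
best = ranked[0]
print(f"best: tilt {best.tilt:.1f} deg, RMSRD {best.rmsrd:.1f} %")
```

prints

```
S_CD = 0.3750  ->  46.97 kHz
best: tilt 35.0 deg, RMSRD 1.4 %
```

The recovered order parameter matches the closed form to the fourth decimal,
and the planted placement wins the search with an RMSRD far below the 50 %
accept threshold while the 20 random decoys score worse.

The same machinery is scriptable from the shell through a single entry
point: `qsplit gen-fixture ...`, `qsplit spectra-analyze`, `qsplit scd`,
`qsplit fit-config`, `qsplit wham`, `qsplit rdf`, `qsplit helix-profile`,
`qsplit depth` (see `qsplit --help`).

## Documentation

`docs/methods.md` describes the models, the numerical choices (WHAM
iteration and tolerances, peak refinement, bimodality detection), what the
synthetic generators do and do not emulate, and known limitations.
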