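# Methods

## Molecular model

A pentitol is represented as an explicit 22-atom graph
(C1-C5, O1-O5, seven C-H hydrogens including the prochiral methylene
pairs H1R/H1S and H5R/H5S, five hydroxyl hydrogens HO1-HO5) with a
stereochemistry map giving the Fischer-projection side (d/l) of the OH
at C2, C3 and C4.  Conformers are realized in Cartesian space by
sequential natural-extension-reference-frame (NeRF) placement from
idealized internal coordinates; crystal-quality bond lengths and angles
are not redetermined, standard values stand in for them and are exposed
in `GeometryParams`:

| parameter | default | unit |
|---|---|---|
| C-C bond | 1.53 | Å |
| C-O bond | 1.43 | Å |
| O-H bond | 0.97 | Å |
| C-H bond | 1.09 | Å |
| C-C-C angle | 112.0 | deg |
| all other angles | 109.5 | deg |

With these values the all-trans chain has C1-C5 = 4·1.53·sin(56°) =
5.07 Å, matching the printed 5.1 Å of extended d-arabitol crystals to
the printed precision; rebuilding every deposited conformer from its
printed dihedrals reproduces the printed C1-C5 distances within 0.22 Å
(the acceptance rows within ±0.1/±0.15 Å).  Dihedrals follow the IUPAC
sign convention and live in (−180°, 180°].

### Stereochemistry conventions

The Fischer d/l → 3D mapping was calibrated geometrically (matching
configurations at C2/C4 give parallel 1,3 C-O bonds in the extended
chain — the steric clash behind Jeffrey's bent/extended rule) and
absolutely (the built structures carry the CIP descriptors
d-arabitol 2R,4R; l-arabitol 2S,4S; ribitol 2R,3s,4S; xylitol 2R,3r,4S,
verified against RDKit's CIP labeller in the test suite).

Two conventions deserve explicit notice because the meso compounds
(ribitol, xylitol) make them easy to trip over:

* **Chain numbering.**  A meso pentitol can be numbered from either end;
  the two choices negate every backbone torsion and swap the prochiral
  labels.  The built-in topologies number the meso chains from the end
  that makes C2 Fischer-'l', which is the frame in which the published
  rotamer analyses of these compounds are stated.  d-Arabitol keeps its
  standard numbering (C1 = the former aldehyde carbon of d-arabinose).
* **Prochiral naming.**  The atoms named H1R/H1S (H5R/H5S) follow the
  stereospecific assignment convention of the alditol solution-NMR
  literature: H1R sits at torsion φ1 − 120° from the terminal oxygen.
  Applying CIP software to the idealized geometries labels the two
  positions the other way around (deuterating the atom named H1R makes
  C1 an S centre).  Both facts are pinned in
  `tests/test_stereochemistry.py`.  The naming choice is empirical: it
  is the unique convention under which the published φ1 populations of
  all three alditols are reproduced from the published couplings
  (forward-model errors ≈ 0.1 Hz); with strict-CIP naming none of the
  published rows is recovered.  Since the two methylene shifts of
  d-arabitol are degenerate (3.66/3.66 ppm), the experimental
  distinction rests on spectral simulation, and conventions in this
  literature predate routine CIP software.

## Coupling prediction and inversion

Per-state couplings are evaluated on conformers built with the site
dihedral at exactly 180°/−60°/+60° (ideal staggered states, no libration
averaging).  For ³J(H,H) the Haasnoot-de Leeuw-Altona equation is used
with the substituent-count-specific coefficient sets (2-substituted:
13.70, −0.73, 0, 0.56, −2.47, 16.9; 3-substituted: 13.22, −0.99, 0,
0.87, −2.46, 19.9; 4-substituted: 13.24, −0.91, 0, 0.53, −2.41, 15.5),
Huggins electronegativity differences (O 1.30, C 0.40 vs H) attenuated
by β-substituents with factor 0.14.  The orientation signs ξ are read
off the 3D fragment: a substituent whose torsion to the far coupled
proton is −120° from the H-H torsion gets ξ = +1 (this reproduces the
classic observation that an electronegative substituent antiperiplanar
to the coupled proton suppresses the gauche coupling).  For ³J(C,H) a
single cosine form A·cos²θ + B·cosθ + C is used along the C-C-C-H path
with defaults (8.06, −0.87, 0.47); the lower-amplitude carbohydrate
parameterization (5.7, −0.6, 0.5) is selectable, but the default was
chosen because a printed C,H coupling of 10.0 Hz in the xylitol data
exceeds the low-amplitude curve's maximum (6.8 Hz).  All parameters live
in a versioned key-value file (`pentitol/data/karplus_params.txt`) and
can be overridden per call or per CLI invocation.

The inversion solves min ‖Mp − J‖² on the probability simplex by exact
enumeration of the simplex faces (KKT system per face), so boundary
solutions come out exactly 0 — consistent with printed populations like
64:36:0 — and ties break toward trans.  The forward model
(`forward_couplings`) and a 0.001-step grid search over the simplex act
as independent oracles in the tests; the round trip is the identity to
10⁻⁶ on the simplex interior.

### Fidelity to the published populations — and a documented limit

With the conventions above, the three published φ1 rows are reproduced
from the published couplings to within 2 points (63:36:1 vs 64:36:0;
55:19:26 vs 57:17:26; 58:23:20 vs 59:21:19).  The two published φ2 rows
are **not** reproduced, and provably cannot be under this model class:

* For ribitol, the printed row is 2:46:52 with J(H2,H3) = 6.50 Hz.  In
  the H2-C2-C3-H3 fragment the HLA gauche coupling is ≤ ~5.2 Hz for
  every orientation-sign combination, so any ~98% gauche mixture
  averages below ~5.3 Hz — the printed row cannot forward-generate the
  printed coupling under ideal staggered states (any Karplus
  parameterization with a normal gauche/anti contrast gives the same
  bound).
* For xylitol, matching the printed 55:45:0 to both observables would
  require the H2 offset around the C2-C3 bond to vanish modulo 120°,
  which tetrahedral geometry forbids.

These rows also disagree with the study's own MD (which puts ribitol φ2
at ~72% trans, where this package's inversion gives 60%), and the C,H
couplings entering them carry the original data's strong-coupling error
flag.  The package therefore reports its faithful result for φ2
(ribitol 60:23:16, xylitol 26:28:46) rather than fitting the table.

## Trajectory statistics

Rotamer binning uses the three-state partition trans: angle < −120° or
> 120°; gauche−: −120° ≤ angle < 0°; gauche+: 0° ≤ angle ≤ 120° (the
boundaries follow the strict inequalities of the source convention;
angles are wrapped, never rejected).  Joint probabilities, transition
counts and per-dihedral populations all reduce to this single
classification, shared with the crystal survey.  Chain shape is labelled
from the C1-C5 distance with hysteresis thresholds (bent ≤ 4.7 Å,
extended ≥ 4.9 Å by default, CLI-exposed): a flip is a bent↔extended
change, with intermediate frames neither triggering nor resetting it,
because a single-threshold rule would count boundary chatter as
conformational events.  RMSD superposes each frame on the reference by
the Kabsch algorithm over all atoms (a no-fit mode exists); an iterative
rotation-vector optimizer serves as the independent oracle in tests.

Hydrogen bonds are detected per frame over all 20 directed hydroxyl
pairs by the three geometric criteria (O···O ≤ 3.4 Å; angle at the donor
oxygen between O-H and O→O ≤ 30°; angle at the hydrogen > 120°), with no
pairs excluded — vicinal 1,2-pairs are tested like any other.  An oxygen
counts once per frame in the per-oxygen frequency if it participates in
any bond as donor or acceptor (the alternative — once per bond — is a
documented choice point; per-frame counting keeps the frequency a
probability).  Reporting cutoffs of 10% and 20% are provided.

## Synthetic data

The generators replace instrument and MD-engine output with analytically
known ground truth:

* **Rotamer jumps.**  Each backbone dihedral follows an independent
  discrete-state Markov chain: with probability *r* per frame (default
  0.1) the state is resampled from the target stationary law, which
  makes that law exact by construction.  Libration noise is a truncated
  Gaussian (default σ = 10°, capped at 40°) confined to the state's
  classification bin, so the planted state sequence always equals the
  classified sequence and population tests are exact rather than
  statistical.  Frames are realized in Cartesian space through the
  builder; everything is bit-reproducible given the seed.  Deliberately
  not modelled: correlated φ2/φ3 motion, continuous barrier crossings,
  solvent friction — so agreement of planted-recovery tests says the
  analysis code is correct, not that real alditol dynamics look like
  this.
* **Planted hydrogen bonds.**  For a scheduled set of donor→acceptor
  pairs a backbone is chosen from a small conformer library (including
  curled doubly-gauche chains for terminal contacts), the donor hydroxyl
  torsion is grid-searched to point the hydrogen at the acceptor, and
  every unscheduled hydroxyl is oriented to violate the donor-angle
  criterion towards all oxygens in range.  Each engineered frame is
  verified by re-detection before use; infeasible requests raise.
* **EXSY.**  Two-site longitudinal magnetization exchange is solved
  exactly with the matrix exponential of the relaxation-exchange matrix
  (forward rate k_ex, backward rate from detailed balance, default equal
  populations and R₁ = 1 s⁻¹ per site).  cross/diagonal → k_ex·t as
  t → 0; the initial-rate estimator's bias grows with the window and
  stays below 10% for k_ex·t ≤ 0.2, which the tests assert against the
  exact solution.  The mixing-time grid defaults to the experimental
  3-24 ms in 3 ms steps.

## Estimators

The EXSY rate is the through-origin least-squares slope of
cross/diagonal versus mixing time over a user-chosen window (weighted
when volume uncertainties are supplied).  The phrase "build-up of the
diagonal over the cross peak" admits an inverted reading; it is
physically non-linear at short times, so the ratio convention defaults
to cross/diagonal with the alternative behind a flag.  Temperature
coefficients are the ordinary least-squares slope of shift (ppb) against
temperature; the magnitude is reported, with the raw sign kept
separately, matching how such coefficients are quoted.

## Problem sizes

Defaults were chosen so the whole suite runs on a laptop core: 10⁵-frame
trajectories for population-recovery checks (±2-point tolerance),
100-200 frames for exact hydrogen-bond recovery, 1000 simplex points for
round-trip identity, 8-point mixing-time grids for EXSY.

## Known limitations

* Idealized internal coordinates: rebuilt C1-C5 distances carry a
  ±0.15 Å documented tolerance against crystal values.
* Rigid three-state rotamer model: no libration averaging of couplings,
  no Boltzmann weighting; populations of strongly librating systems will
  differ from ensemble-averaged treatments.
* The φ2 inversion depends on an error-flagged C,H coupling and on the
  choice of C,H Karplus parameterization (±5-point effect).
* The Karplus coefficient sets are literature reconstructions; the
  source publications for this data did not print the coefficients they
  used.
* Hydrogen-bond analysis treats only intramolecular solute pairs; water
  is skipped on input and never modelled.
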