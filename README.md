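# pentitol

Conformational analysis of acyclic five-carbon sugar alcohols (ribitol,
d-arabitol, l-arabitol, xylitol).

Acyclic polyols are flexible: their backbone conformation is set by four
rotatable C-C dihedrals, φ1 (O1-C1-C2-C3), φ2 (C1-C2-C3-C4),
φ3 (C2-C3-C4-C5) and φ4 (C3-C4-C5-O5), each hopping between three
staggered rotamers — trans (180°), gauche− (−60°) and gauche+ (+60°).
Ribitol in particular is a building block of the O-mannose glycan on
α-dystroglycan, where its flexibility matters for ligand recognition.
This package implements the analyses used to characterize that
flexibility from experiment and simulation:

* **Rotamer populations from NMR.**  An observed vicinal coupling is the
  population-weighted average over the three rotamers, so with per-state
  couplings J<sub>s</sub> predicted by generalized Karplus equations the
  populations *p* solve

      min ‖M p − J_obs‖²   s.t.  p ≥ 0, Σp = 1

  ³J(H,H) uses the Haasnoot–de Leeuw–Altona equation
  J = P₁cos²φ + P₂cosφ + P₃ + Σᵢ Δχᵢ[P₄ + P₅cos²(ξᵢφ + P₆|Δχᵢ|)]
  with substituent electronegativity and orientation corrections;
  ³J(C,H) uses a cosine Karplus form A·cos²θ + B·cosθ + C.  All coupling-path
  dihedrals and orientation signs ξ are measured on idealized 3D rotamer
  conformers built by the package — no offsets are hardcoded.
* **Crystal-conformer survey.**  Deposited conformers are binned into the
  three rotamer states, joint φ2/φ3 patterns counted, and end-to-end
  C1-C5 distances recomputed from idealized internal coordinates;
  Jeffrey's rule (extended chain when the C2 and C4 configurations
  differ, bent when they match) is applied from the stereochemistry.
* **Trajectory statistics.**  Dihedral time series, state populations,
  joint probabilities, transition counts, extended/bent flip detection on
  the C1-C5 distance, all-atom Kabsch RMSD, and geometric hydrogen-bond
  detection (O···O ≤ 3.4 Å, H-O<sub>d</sub>-O<sub>a</sub> angle ≤ 30°,
  O<sub>d</sub>-H-O<sub>a</sub> angle > 120°) with per-oxygen bonding
  frequencies.
* **Hydroxyl-proton exchange.**  EXSY initial-rate estimation
  (cross/diagonal ∝ k<sub>ex</sub>·t<sub>m</sub>) and chemical-shift
  temperature coefficients (ppb·K⁻¹).
* **Synthetic data with exact ground truth** replacing spectrometer and
  MD-engine output: Markov rotamer-jump trajectories realized in
  Cartesian space, frames with planted hydrogen bonds, matrix-exponential
  two-site EXSY curves, and forward-modelled coupling sets.

## Worked example

```pycon
>>> from pentitol import AlditolTopology, CouplingSet, phi_populations
>>> cs = CouplingSet("ribitol", {"3J(H1R,H2)": 3.00, "3J(H1S,H2)": 7.20})
>>> phi_populations("ribitol", "phi1", cs).percentages()
(63, 36, 1)
```

The two prochiral H1-H2 couplings of ribitol invert to a φ1 rotamer
distribution of 63% trans, 36% gauche− and 1% gauche+ — the backbone
spends most of its time anti, with a substantial single-gauche
population, matching the published solution-NMR analysis of ribitol
(64:36:0) to within a point.  The same call with d-arabitol's couplings
(5.00, 7.55 Hz) gives (55, 19, 26), and xylitol's (4.5, 7.5 Hz) gives
(58, 23, 20).

From the shell:

```sh
$ pentitol survey --molecule xylitol
45 records for xylitol
  phi2=gauche+  phi3=trans    n=33
  phi2=trans    phi3=gauche+  n=12
```

— the 45 deposited xylitol conformers fall into exactly the two
mirror-related bent patterns, consistent with Jeffrey's rule for a
molecule whose C2 and C4 configurations match.

The numbered scripts under `analysis/` run the full study: crystal
survey, coupling inversion for all molecules and sites, desk-scale
rotamer-jump dynamics, hydrogen-bond recovery, and exchange-rate
estimation.  Each prints its findings and writes tables under
`results/`.

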