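# Methods

## Scope and model

`glysaxs` decides between folded and unfolded conformations of
two-strand glycan hairpins by comparing SAXS intensities predicted from
explicit-solvent atomistic ensembles with a 1D experimental curve. The
package covers three layers: ensemble generation/analytics, intensity
prediction, and curve analysis; it does not run molecular dynamics —
ensembles are either read from multi-model PDB files or produced by the
synthetic generator described below.

## Scattering model

For a configuration of atoms with positions rᵢ and X-ray form factors
fᵢ(q), the orientationally averaged intensity is

    I(q) = ⟨ |Σᵢ fᵢ(q) exp(i q u·rᵢ)|² ⟩_u ,

averaged over scattering directions u on the unit sphere and then over
frames of the ensemble. Two routes are implemented:

* **Debye sum** (`debye_intensity`): the analytically exact
  orientational average, I(q) = Σᵢⱼ fᵢfⱼ sin(qr_ij)/(qr_ij), O(N²) per
  frame. It is the oracle against which the numerical route is tested.
* **Direction quadrature** (`orientational_intensity`): |A(q,u)|²
  averaged over a deterministic Fibonacci (golden-spiral) point set of
  directions. The point set is seedless, so results are reproducible
  and convergence can be checked simply by doubling the count. Default
  400 directions; on solute-sized systems (≲ 50 Å) the error at
  q ≤ 0.5 Å⁻¹ is well below 1% already at a few hundred directions and
  shrinks monotonically with the count.

On a *uniform* q grid the quadrature route uses a phase-recurrence fast
path: exp(iq_k u·r) is built multiplicatively from exp(iq₀ u·r) and
exp(iΔq u·r), replacing one complex exponential per (atom, direction,
q) with one complex multiply. Non-uniform (e.g. logarithmic) grids use
direct evaluation; both paths agree to ~1e-8 relative.

Form factors use the standard international-tables four-Gaussian-plus-
constant parameterization for H, C, N, O, shipped as a JSON data file;
f(0) equals the electron number to < 0.1 e⁻. Hydrogens are explicit —
there is no implicit-H merging.

## Solvation envelope and buffer subtraction

The envelope is the union, over all frames of a window, of points
within a fixed distance (default 7 Å) of any solute atom, voxelized at
0.5 Å (volume error < 3% on 7 Å features; both the distance and voxel
size are configurable, and a per-frame envelope option exists). The
buffer-subtracted ("excess") ensemble intensity is

    I(q) = ⟨|A(q)|²⟩_solute-system − ⟨|B(q)|²⟩_solvent-system ,

where A sums the solute plus those water molecules whose oxygen lies
inside the envelope, and B sums the in-envelope molecules of a
pure-solvent ensemble. The estimator is the plain difference of the two
ensemble means. It is exact in the mean; reduced-variance estimators
can be swapped in behind the same function signature. Water molecules
are recognized by atom name (OW/HW1/HW2). Solute atoms outside the
envelope are an error (the envelope must come from the same window);
differing frame counts between the two systems only warn, since the
two means are estimated independently.

## Synthetic ensembles

The generator emulates the two conformational regimes rather than any
force field:

* Residues are idealized pyranose-like templates — a planar hexagonal
  C₅O ring of circumradius 1.5 Å plus one exocyclic O4 (C4–O4 1.4 Å) —
  seven atoms per residue. Two strands of n residues (5.15 Å rise per
  residue, the anhydroglucose repeat) are joined by a three-residue
  turn; alternate residues are flipped 180° about the chain axis as in
  cellulose.
* The **end-to-end distance** between the terminal O4 atoms of the two
  strands is controlled by the strand opening angle. Folded frames are
  held in [3, 10] Å, unfolded in [10, 25] Å; a target distance is drawn
  0.6 Å inside the admissible range and the built frame is rejected and
  resampled (≤ 100 attempts) if jitter pushed it outside. Torsional
  jitter (default σ = 8°) rotates each ring about its chain axis —
  which leaves the terminal O4 invariant by construction — and a
  positional jitter of σ = 0.05 + 0.02·(torsion jitter) Å perturbs all
  atoms, so extreme jitter makes the range genuinely unattainable and
  triggers the documented failure path.
* **Hydration water** is placed on a randomly offset cubic lattice of
  spacing ρ^(−1/3) (bulk ρ = 0.0334 molecules/Å³, the standard ambient
  number density), jittered by ±0.3 lattice units, kept only inside the
  envelope and beyond a 1.8 Å contact distance from solute atoms, and
  expanded into rigid 3-site molecules (O–H 0.9572 Å, H–O–H 104.52°)
  with uniformly random orientations. Realized density matches the
  request within ~10% on envelopes ≥ 10⁴ Å³.
* One top-level seed expands into per-frame sub-seeds
  (`default_rng([seed, frame])`), so reproducibility is bit-exact and
  independent of evaluation order.

What the generator does *not* emulate: force-field energetics, realistic
sugar puckers and exocyclic rotamers, solvent structuring beyond bulk
density, or the kinetics connecting the two states. Passing tests
therefore demonstrate the correctness of the analysis chain on
ensembles with the stated geometric statistics, not the physics of any
particular hairpin.

The MD frame-saving interval is not fixed by the problem; it is exposed
as `frame_interval` (default 1 ps) and only affects reported durations.

## Trajectory analytics

* Rg uses electron weighting by default (what SAXS senses); mass and
  uniform weighting are available for comparison with MD conventions.
* Window classification labels each frame fc ([3, 10] Å), ufc
  ([10, 25] Å) or neither, and reports maximal same-label runs of at
  least `min_frames` (default 1000, echoing the ≥ 1000-consecutive-frame
  ensembles used for intensity averaging). Frames in neither range break
  windows, keeping them conformationally pure. The two default ranges
  share the endpoint 10 Å: ranges may share an endpoint (a frame exactly
  there counts as fc, the first range checked); interval overlap is
  rejected.
* Dihedrals follow the standard signed convention (cis = 0°, atan2 on
  bond-plane normals), values in (−180°, 180°]. Both glycosidic torsion
  conventions — heavy-atom (Φ: O5′–C1′–On–Cn, Ψ: C1′–On–Cn–Cn−1) and
  hydrogen-based (Φ: H1′–C1′–O4–C4, Ψ: C1′–O4–C4–H4) — are supported by
  passing the corresponding atom selections; the convention is tagged in
  the output.
* Ramachandran densities are normalized 2D histograms on (−180°, 180°]²
  (bin width must divide 360°); the mode is the center of the
  highest-count bin, ties broken toward the smallest (Φ, Ψ).
* Hydrogen bonds use the common geometric criteria d(D···A) ≤ 3.5 Å and
  ∠(D–H···A) ≥ 150°, both configurable; a hydrogen farther than 1.2 Å
  from its donor yields a warning in the record, not a failure.

## Curve analysis

* **Guinier**: weighted least squares of ln I vs q² on a fixed window,
  default q² ∈ [0.008, 0.06] Å⁻² (σ-weighted when uncertainties exist,
  unweighted otherwise); Rg = √(−3·slope). The fit is flagged when
  qmax·Rg ≥ 1.3. An optional self-consistent mode (`qmax_rg_limit`)
  shrinks the window until qmax·Rg meets the limit; for strongly
  elongated particles the fixed wide window systematically
  underestimates Rg (by ~10% for a 26×3 Å cylinder, where the window
  reaches qRg ≈ 1.9), so the limited mode is preferred when absolute Rg
  accuracy matters.
* **Kratky**: q²I(q); the peak is the first grid maximum (optional
  moving-average smoothing, off by default). For Gaussian decay the
  analytic peak is √3/Rg.
* **Rod model**: L = √(12Rg² − 6R²) at default cross-section radius
  R = 3 Å, defined for Rg > R/√2; lengths are reported raw and rounded
  to the nearest Å, and AGU counts as round(L/5.15) together with the
  raw ratio so callers can flag poor fits. Note the arithmetic is
  molecule-agnostic: Rg = 8.8 Å gives L ≈ 29.6 → 30 Å (ratio 5.7 AGU,
  a poor rod fit) and Rg = 7.9 Å gives L ≈ 26.4 → 26 Å (5 AGU).
* **Model-to-experiment fit**: the model is linearly interpolated onto
  the experimental grid over the q overlap (models are smooth,
  experiments noisy; no extrapolation) and an affine (scale + offset)
  weighted least-squares fit minimizes Σ((s·I_m + c − I_e)/σ)². χ² is
  computed on the full overlap; the reduced χ² over 0.16–0.4 Å⁻¹ —
  where folded and unfolded conformers separate most — is reported
  alongside as a diagnostic band. The verdict is the χ² minimum across
  candidate models.
* Curve files are 2–3 column whitespace text with `#` comments; q may
  be flagged as nm⁻¹ (divided by 10) or auto-detected (nm⁻¹ assumed
  when max q > 2, since SAXS data rarely exceed 2 Å⁻¹).

## Pipeline defaults and problem sizes

`run_pipeline` defaults mirror the analysis conditions: 7 Å envelope,
fc/ufc ranges [3, 10]/[10, 25] Å, ≥ 1000-frame windows, q grid
0.01–0.5 Å⁻¹ (100 points), 400 quadrature directions, bulk water
density. The test suite and the acceptance script exercise the
end-to-end discrimination at desk scale — 200-frame ensembles,
~120 solute atoms (7 residues per strand), a thin 3 Å hydration shell,
64 directions, 50 solvent-only frames, a linear 60-point q grid —
sizes chosen so a full verdict run completes in seconds while keeping
every stage (solvation, envelope, subtraction, fitting) active. Under
these conditions the χ² of the true conformer beats the alternative by
an order of magnitude in the median.

Every run writes a manifest (full config, package and numpy versions)
sufficient to reproduce all outputs bit-identically; any stage failure
aborts with the stage name and leaves a `FAILED` marker next to the
partial outputs.

## Known limitations

* The plain difference estimator for buffer subtraction has higher
  variance than the reduced-variance schemes used by dedicated
  explicit-solvent SAXS codes; averaging over enough frames compensates.
* No WAXS fidelity (q > 1 Å⁻¹): the form-factor table and envelope
  treatment target the small-angle regime.
* PDB round-trips quantize coordinates at 10⁻³ Å and do not carry frame
  times; times are rebuilt from a frame interval on read.
* No P(r) inversion, ab initio shape reconstruction, or ensemble
  reweighting; the verdict is a discrete model comparison.
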