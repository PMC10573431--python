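# Methods

## Scope and model

`opreact` covers the desk-scale, post-processing stages of an in-silico
fluoride-reactivation study of organophosphate (OP) adducts. It does not run
molecular dynamics, docking searches or semiempirical SCF calculations; it
consumes their outputs (structures, multi-model trajectories, pose tables,
partial charges) and produces the derived quantities on which adducts are
compared:

1. **Probe placement.** Reactivation proceeds by in-line nucleophilic attack
   of F⁻ on the tetrahedral phosphorus. The probe is placed on the line of
   the P=O (phosphoryl) bond, *anti* to the phosphoryl oxygen, at a fixed
   distance from P (default 2.0 Å). Anti placement is the only collinear
   orientation that puts the ion in the solvent-accessible gorge rather than
   inside the P=O bond, and matches the backside-attack geometry of the
   presumed trigonal-bipyramidal transition state. The construction is exact
   vector arithmetic and is equivariant under rigid motions.

2. **Productive-conformation filter.** A pose is geometrically capable of
   reaction when the attacking atom (Ser/Tyr O or His/Lys N, or F⁻) lies
   within the attack cutoff (default 4.0 Å, boundary inclusive) of the
   attacked atom (P, or the methylene C for His/Lys chemistry). Pose-table
   rows whose distance is the sentinel `not found` are treated as having no
   productive conformation and are dropped by the filter.

3. **Trajectory read-outs.** From a distance time series d(t):
   * *interval mean* — arithmetic mean over frames with t0 ≤ t ≤ t1. Frames
     are weighted equally (fixed-step MD output is assumed), so for a clean
     split the mean over a union of intervals is the frame-count-weighted
     mean of the parts.
   * *residence time* — the time of the last frame of the *initial*
     contiguous run with d ≤ cutoff; 0 if the first frame is already
     outside. Re-entries earn no credit, because "remains in the productive
     position, then moves away" describes first escape; they are reported
     separately as a list of runs (`productive_runs`).
   * *hydration count* — number of distinct water molecules whose oxygen is
     within the hydration cutoff of the ion in a frame. Waters are
     recognised by residue name (HOH/WAT/SOL, configurable).

4. **Electrostatic barrier score.** With semiempirical partial charges q_P,
   q_Oγ, q_F and the distances r(P–Oγ) (the covalent bond, ~1.69 Å) and
   r(P–F) (the productive separation) the screened Coulomb pair energies are

       E_el(i,j) = k·q_i·q_j / (ε·r_ij),  k = 332.0637 kcal·Å·mol⁻¹·e⁻².

   The barrier proxy is ΔE_el = E_el(P–F) − E_el(P–Oγ). The sign convention
   is fixed so that the score is positive for physically meaningful records
   (P positive, O/F negative, the bound Oγ closer to P than the probe):
   it is the attraction deficit that must be overcome to swap the partners.
   Lower ΔE_el → easier reactivation. The model deliberately neglects van
   der Waals terms and assumes the covalent P–O/P–F bond energies are
   adduct-independent, so *differences between adducts* are meaningful but
   absolute barrier heights are not.

5. **Ranking.** Adducts are ordered by ascending score under either
   criterion — mean P–F distance (molecular-mechanics view: charges are
   conformation-independent, so only the distance discriminates) or ΔE_el
   (semiempirical view). The order is a pure function of the data: stable
   ascending sort with lexicographic adduct-id tie-break (the packaged
   mean-distance table contains one exact tie, 3.52 Å).

6. **Thermodynamics.** K_d = exp(ΔG/RT) against the 1 M standard state,
   R = 1.98720425×10⁻³ kcal·mol⁻¹·K⁻¹, T = 298.15 K by default ("room
   temperature" is not defined more precisely anywhere in the workflow;
   293–300 K all give ~7 μM for ΔG = −7 kcal/mol to one significant figure).

7. **Structural grouping.** Over the controlled substituent vocabulary of
   the studied adducts: group I — massive R2 carrying an electronegative
   atom (N-(CH3)2, O-C2H5); group II — R1 branched at the first carbon,
   CH(X)–X′ (isopropyl, cyclohexyl, pinacolyl); group III — less branched
   R1 (O–CH2–Y) with R2 = CH3; R2 = C2H5 is transitional; an aromatic R1
   (the CBDP adduct) is special. The classifier rejects tokens outside the
   vocabulary rather than guessing at general SMILES.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| placement distance | 2.0 | Å | manual-docking convention for the probe: short enough to be "pre-bond", long enough to minimise cleanly |
| attack cutoff | 4.0 | Å | productive-conformation criterion; inclusive ("does not exceed") |
| dielectric ε | 4 | — | calibrated: screened Coulomb with ε = 4 reproduces the packaged published pair energies to < 0.025 kcal/mol across all 11 adducts (vacuum ε = 1 overshoots 4×); a common effective value for buried protein interiors |
| hydration cutoff | 3.5 | Å | ion–water-oxygen first-shell boundary for F⁻; no criterion is stated with the published visual counts, so this literature default is configurable |
| H-bond criteria | 3.5 Å / 120° | Å, deg | donor–acceptor distance and donor–H–acceptor angle; common literature defaults, configurable |
| temperature | 298.15 | K | standard room temperature |

All distances are in Å, times in ps, energies in kcal/mol, charges in
elementary units, angles in degrees, throughout.

## Synthetic data: what it emulates and what it does not

The generators provide inputs with known ground truth:

* `make_active_site` plants exact geometry — P–Oγ 1.69 Å (the typical bond
  length in the reference records), P=O 1.48 Å, tetrahedral substituents, a
  protonated His with its Nε–H pointed at the ion, near waters uniformly at
  2.5–3.2 Å from the ion and far waters at 5.5–8 Å, optionally a linear
  water→Oγ hydrogen bond.
* `make_trajectory` moves only the ion: its P-distance follows a
  mean-reverting AR(1) process (autocorrelation φ = 0.8, stationary s.d. =
  `tether_sd`) around `tether_mean` with isotropic angular jitter; past
  `escape_time` the radial mean grows at `post_escape_drift` and is capped
  at `max_radius`. Defaults (10 ps frames, 1000 frames ≙ 10 ns, tether 3.2
  ± 0.15 Å, escape at 1300 ps, drift 0.1 Å/ps, cap 70 Å) mirror the
  phenomenology of the reference simulations: a fluoride tethered in the
  2.9–3.6 Å band for 1–8 ns that then leaves the gorge and ends up tens of
  Å away. The fast drift makes the escape front sharp relative to the frame
  spacing, so the planted escape time is recoverable to within one frame.
* `make_adduct_records` draws charges/distances uniformly inside the
  published ranges (q_P ∈ [2.2, 2.4] e, q_Oγ ∈ [−0.65, −0.54] e, q_F ∈
  [−0.76, −0.70] e, r(P–Oγ) ∈ [1.68, 1.70] Å, r(P–F) ∈ [2.7, 4.0] Å). Over
  these ranges the P–Oγ attraction always exceeds the P–F attraction, so
  ΔE_el is provably positive for every sample.

These are statistical emulations, not physics: no water or protein dynamics,
no force field, no periodic boundary conditions, no correlation between
substituent structure and the sampled charges. Passing tests therefore
demonstrate that the *analysis operations* recover planted truth — residence
times to one frame, tether means to within sampling error, hydration counts
exactly — not that the physical simulations themselves are reproduced. The
published MD-derived numbers (mean distances, hydration levels, ΔE_el
values for the albumin Tyr150 adducts) ship as packaged reference tables;
only the screened-Coulomb energies are recomputable from first inputs, and
the test suite recomputes them all.

Every generator is a pure function of its parameters and a mandatory seed.

## Numerical choices

* Coincident P and phosphoryl O (norm < 1e-9 Å) is a geometry error, not a
  silent NaN; likewise H coincident with donor/acceptor in the H-bond test.
* Collinearity of the placed probe holds to a cross-product norm < 1e-6 Å²;
  the placement distance is exact to 1e-9 Å (limited only by float
  arithmetic). PDB round-trips are exact to the format's 1e-3 Å coordinate
  precision.
* Recomputed screened-Coulomb energies are asserted within 0.05 kcal/mol of
  the packaged reference values: charges are printed to 3 decimals, which
  bounds the reconstruction error (observed maximum ≈ 0.023 kcal/mol).
* Record validation enforces sign conventions (q_P > 0, q_Oγ < 0, q_F < 0,
  r(P–Oγ) ∈ (1.0, 2.5) Å) because the barrier score is meaningless
  otherwise; a `validate=False` override admits exploratory records.
* Adduct tables with a stable-interval ambiguity (different analyses of the
  same trajectory may use different 1 ns windows) are handled by making the
  interval an explicit per-adduct parameter (`RunConfig.intervals`) rather
  than hard-coding a resolution.

## Test problem sizes

The statistical acceptance test uses 50 replicate trajectories of 300
frames (10 ps spacing, escape planted at 1300 ps) — large enough that the
AR(1)-corrected 3-standard-error band for the interval mean is ~0.12 Å and
the residence estimate is frame-exact in almost every replicate, small
enough to run in seconds. The convergence test for the generator itself
uses a single 2000-frame run.

## Known limitations

* The barrier score is electrostatics-only; aging (dealkylation to the
  reactivation-resistant P(O)O⁻ species), spontaneous hydrolysis and
  adduct-formation efficiency are outside the model, and they are exactly
  the mechanisms invoked when ranking disagrees with in vitro data.
* The MM criterion carries no charge information at all; it cannot separate
  stereoisomers whose geometry differs mainly in charge distribution.
* Trajectories are assumed pre-imaged (no periodic-boundary handling) and
  fixed-step.
* Albumin adduct scores cannot be recomputed from packaged inputs (their
  underlying charges are not published) and are provided as reference
  values only.
* The classifier is defined only over the controlled substituent vocabulary
  of the studied adduct set, by design.
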