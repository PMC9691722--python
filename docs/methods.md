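# Methods

This note documents the models implemented in `tcrspec`, their assumptions,
the defaults and why they were chosen, and what the synthetic-data tests do
and do not demonstrate.

## Steady-state SPR (module `affinity`)

**Model.** Equilibrium 1:1 binding: `R_eq(C) = RU_max · C / (K_D + C)`.
Inputs are blank-corrected steady-state responses; kinetic analysis, drift
and bulk-refractive-index correction are out of scope. Duplicate injections
are concatenated and fit as one dataset.

**Fitting.** Least squares over `(log10 K_D, log10 RU_max)` —
the log parameterization enforces positivity and conditions the problem
across concentration decades. Initialization: `RU_max⁰ = 1.1 · max(R)` and
`K_D⁰` the concentration at half of `RU_max⁰`, interpolated on the sorted
titration; this is robust for monotone saturation data. With a share group,
all titrations are fit globally with one common RU_max and one K_D each;
pooling is the standard way to stabilize RU_max when individual titrations
do not reach saturation. Parameter errors are 1σ values from the
residual-variance-scaled covariance `(JᵀJ)⁻¹s²`. A response exceeding twice
the fitted RU_max raises a warning (surface calibration suspect);
non-convergence raises an error with the optimizer's diagnostics.

**Single-point assay.** With a peptide-independent reference surface of
known `(K_D,ref, RU_max,ref)`, the analyte concentration follows from
inverting the Langmuir model, `C = K_D,ref·R/(RU_max,ref − R)`, valid only
for `0 < R < RU_max,ref` (saturated or non-binding signals are errors, not
numbers). The TCR-surface K_D then follows from the same inversion,
`K_D = C·(RU_max − R)/R`. Both surfaces are assumed to be at equilibrium at
the read-out time.

**Units and constants.** K_D in molar on the 1 M standard state;
`ΔG° = RT ln K_D` with `R = 1.9872e-3 kcal/(mol·K)`; default
`T = 298.15 K` (experiments at 25 °C). ΔΔG° is taken relative to the
*mean* of the wild-type replicate measurements; positive means weaker.

**Error propagation** is first-order (delta method) with independent input
errors; no higher-order scheme is attempted because the input errors in
practice are ≲20 % where the linearization is adequate. A useful identity:
the ΔG° error equals `RT·(σ_K/K_D)`, so a 10 % K_D error is ≈0.06 kcal/mol.

## Specificity fingerprint (modules `fingerprint`, `distribution`, `proteome`)

**Percent-response PWM.** A complete positional-scanning library gives
`ΔG°(i, a)` for 7 varied positions × 20 amino acids (anchors p2/p9 fixed).
Cells are rescaled to

    percent(i, a) = 100 · (ΔG°_weakest − ΔG°(i, a)) / (ΔG°_weakest − ΔG°_strongest)

so the strongest binder maps to 100 and the weakest to 0. The orientation
is a deliberate design choice: it is the one under which the score is an
increasing measure of binding strength, the native peptide sits at 1, and
the score→affinity exponential maps high scores to strong affinities. The
opposite orientation (strongest → 0, as the rescaling formula is sometimes
written) is available as `orientation="literal"` for auditing; it inverts
the scale and is not meaningful downstream.

**Scoring.** `s(p) = Σᵢ percent(i, pᵢ)/N` over the varied positions, where
`N = Σᵢ percent(i, wtᵢ)`. Because the normalization factor is accumulated
in the same (ascending-position) order as the score sum, `s(WT) = 1.0`
*exactly*, not merely to rounding — the tests assert `== 1.0`. Anchor
positions contribute nothing; a widened p2 set (e.g. {M, L}) changes only
motif admission, not the score. By default the PWM keeps each position's
own measured native cell; `wt_cell_policy="replicate-mean"` substitutes the
cross-replicate WT mean into the seven native cells instead (either way the
WT score is exactly 1).

**Score → affinity.** `K_D(s) = exp(s·ΔG°_WT/RT) = K_D,WT^s`, anchored at
`s=0 → 1 M` and `s=1 → K_D,WT`. ΔG°_WT defaults to the mean of the library's
WT replicates but is an explicit parameter: the anchor is an empirical
calibration, and `anchor_dg_wt(score, kd)` derives it from any known
(score, K_D) pair — e.g. anchoring 5 mM at s = 0.5 implies
K_D,WT = (5·10⁻³)² M = 25 μM.

**Exact counting.** The score is additive over positions, so the exact
count of the 20⁷ = 1.28·10⁹ peptides per 0.01-wide score bin is obtained
without enumeration: all 20⁴ partial sums of the first four varied
positions and all 20³ of the last three are formed, one side is sorted, and
pairs below each bin edge are counted by binary search
(`O(A⁴ log A⁴)` ≈ milliseconds). Logo matrices use the same machinery: the
count of band peptides with residue *a* at position *i* is the number of
assignments of the other six positions whose partial sum falls in the band
shifted by `percent(i, a)`.

**Numerical determinism.** Partial sums accumulate in ascending position
order. Bins are left-closed/right-open and thresholds inclusive, with an
absolute snap-to-edge guard of 10⁻⁹ in score units: a score within the
guard below an edge is assigned to the upper bin. This makes the binning
insensitive to the (≈10⁻¹³) float-association differences between the
split-sum and left-to-right evaluations, which the reduced-alphabet
brute-force tests confirm bin-for-bin. The guard would misassign only a
score genuinely within 10⁻⁹ of an edge, which has measure zero for
measured inputs. "Deciles" are score-scale bands of width 0.1 (the top two
deciles are scores ≥ 0.8), not population deciles — the top bands hold
≈0.1 % of the space, so population deciles would be a different object.
Scores may exceed 1 when some cell is stronger than the native one.

**Proteome scan.** Sequences are uppercased; 9-mer windows must have p9
equal to the fixed anchor and p2 in the allowed set (default {M, L},
leucine being tolerated in the HLA-A2 B pocket); windows containing
B/J/O/U/X/Z are skipped. Both the occurrence list and the deduplicated
unique-peptide count are reported, since either may be the quantity of
interest. Peptide positions are 1-based (p1–p9); window offsets 0-based.

## DSF (module `dsf`)

T_m is the temperature at the global maximum of the first derivative
(central differences) of the melt curve, after a centered moving average
(default window 5 points) — the standard read-out for SYPRO-orange melts on
a 25–95 °C, 1 °C grid. The maximum is searched over an interior window
excluding 2 points per end; a maximum on the window edge sets an
`edge-peak` flag. Ties break to the lowest temperature. A transition is
declared absent when the derivative peak fails to rise above the median
derivative by more than 5 % of the derivative range — this rejects flat and
strictly linear signals and falling sigmoids analyzed without the
`inverted` option (for dyes that quench on unfolding). Smoothing and edge
handling are this package's defaults, documented here rather than asserted
as anyone else's convention. Two-state thermodynamic fitting (ΔH, van 't
Hoff) is out of scope; the derivative rule biases T_m by ≲ the grid spacing
for asymmetric transitions.

## Docking geometry (module `geometry`)

Conventions (validated against constructed fixtures and rigid-motion
invariance; the two published worked examples serve as calibration when the
structure files are supplied):

* **Groove frame.** Least-squares plane of the groove Cα atoms (class I
  default: heavy-chain residues 1–180, author numbering, inclusive);
  normal oriented toward the TCR; x = in-plane projection of the peptide
  Cα principal axis oriented N→C; y = z × x.
* **Crossing angle.** Angle in [0, 180]° between the in-plane projections
  of the Vα→Vβ disulfide-centroid line and the peptide axis. The disulfide
  centroid is the midpoint of the two Sγ atoms of the closest CYS pair
  (≤3 Å) inside the annotated V-domain range, falling back to the Cα
  midpoint when Sγ atoms are absent.
* **COM angle.** Same construction with the line joining the Vα and Vβ
  geometric centers (all non-hydrogen atoms, unit masses — element
  weighting moves descriptors by ≪0.1 Å, and no published convention
  mandates it).
* **Polar descriptors.** r = |COM(Vα∪Vβ) − COM(groove Cα)|; ϕ = angle of
  that displacement from the plane normal; θ = its in-plane azimuth
  (atan2, (−180, 180]); θ is reported as 0 when the TCR sits exactly above
  the groove center (azimuth undefined). Docking polarity is reported
  separately as a boolean Vα-over-α2 test (is the Vα center closer to the
  α2-helix Cα centroid, default residues 138–180, than Vβ is).
* **Contacts.** All cross-group non-hydrogen atom pairs within the cutoff
  (default 4.0 Å), aggregated per residue pair, via a k-d tree; the test
  suite checks exact agreement with the O(n²) oracle.
* **SASA.** Shrake–Rupley with probe 1.4 Å, Bondi-style van der Waals radii
  by element, and a deterministic golden-spiral point set (default 960
  points/atom; 240 vs 960 differ <2 % on test structures). Unknown elements
  are errors naming the atom.
* **CDR3.** From the conserved second framework cysteine through the Phe/Trp
  of the J-region [FW]G.G motif, inclusive of both, with an explicit
  boundary override. Length statistics report the sample mean and SD, the
  z-score of a query length, the normal upper-tail percent P(X ≥ query),
  and the empirical fraction — the normal tail is meaningful because
  repertoire CDR3β length distributions are approximately normal.

Structure files are read with gemmi: first model only, hydrogens and waters
dropped, altloc blank/'A' retained, author residue numbering kept as-is.

## Synthetic data (module `synth`)

The generators define the conditions under which the pipeline is tested:

* **Scan library.** Wild-type K_D 25 μM (ΔG° ≈ −6.28 kcal/mol).
  Substitution penalties ΔΔG° are drawn per position class: highly specific
  positions 3–6 from Normal(2.5, 1.0²) kcal/mol and tolerant positions
  1, 7, 8 from Normal(0.3, 0.3²), both truncated below at −0.2 kcal/mol so
  no variant substantially improves binding; native cells are exactly 0
  before noise. Measurement noise is Gaussian with SD 0.04 kcal/mol, the
  scale of a well-calibrated SPR free energy. These choices emulate the
  qualitative landscape of a TCR with a specific central core and tolerant
  termini and a mean library-wide weakening of ≈2 kcal/mol.
* **SPR observations.** Analyte concentrations Normal(14, 4²) μM (truncated
  at 1.4 μM), the scale of UV-exchange yields; responses from the Langmuir
  model on both surfaces plus Gaussian RU noise.
* **Melt curves.** Linear baseline plus a logistic transition; the
  noise-free derivative peaks exactly at T_m, so on-grid melting points are
  recovered exactly.
* **Geometry fixtures.** Pseudo-atom complexes built directly in the groove
  frame: a symmetric planar Cα grid (groove), a straight peptide trace, and
  two mirror-symmetric V-domain clouds whose disulfide and COM axes realize
  the requested crossing/COM angles and whose midpoint realizes (θ, ϕ, r)
  exactly.

All generators consume a single `numpy` `default_rng(seed)` per call and
never touch global state; fixed seeds give byte-identical outputs.

**What the synthetic tests do not show.** The generated library is exactly
position-additive, so passing tests cannot validate the additivity
assumption itself against real couplings between peptide positions (the
fingerprint model ignores them by construction, as it does peptide lengths
other than 9 and class II ligands). Melt curves are ideal two-state;
geometry fixtures are not protein folds and exercise the descriptor
definitions, not structure parsing corner cases. Real-data properties
(instrument drift, exchange failures, electron-density ambiguity) are out
of scope.

## Problem sizes and tolerances in the test suite

Simulation-based checks use 100 seeds (titration bias, shared-vs-independent
RMSE, DSF recovery), 50 seeds for library landscape statistics, and 4-letter
alphabets (4⁷ = 16,384 peptides) for brute-force enumeration against the
exact counter — sizes at which the Monte-Carlo assertions are stable and the
whole suite runs in seconds. Angle fixtures are asserted to 0.5°, rigid-
motion invariance to 10⁻⁶, noise-free fits to 10⁻⁶ relative, and exact
identities (WT score, counts, roundtrips) to equality.

## Known limitations

* The fingerprint is a strictly additive model; epistasis between peptide
  positions is invisible to it.
* The single-point assay inherits the reference-surface calibration;
  accuracy degrades for very weak binders (response near 0) and near
  saturation, which the admissible-range errors make explicit.
* The crossing-angle and polar conventions are calibrated to constructed
  fixtures and the published worked examples within ±3°; other published
  pipelines may differ by small systematic amounts depending on atom sets
  and projection choices.
* The derivative-maximum T_m is a proxy, not a thermodynamic fit.
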