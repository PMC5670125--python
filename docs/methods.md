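# Methods

## Ensemble model and estimators

### Input model

Conformational ensembles are ordered frames sharing one topology, read from
multi-model PDB files (coordinates in Å, 1-based residue numbers, PDB chain
ids). The package analyses ensembles; it does not generate physical
trajectories — frames may come from an MD engine, normal-mode sampling, or
the built-in synthetic generator.

### Superposition, RMSD, RMSF

Rigid superposition is the least-squares Kabsch fit (proper rotation,
det = +1), computed with `scipy.spatial.transform.Rotation.align_vectors`.
Subsets of fewer than 3 atoms, or collinear subsets, are rejected (the
rotation is not unique there).

RMSD series superpose each frame independently onto the reference on the
chosen selection (default Cα — the same selection the DF analysis uses, so
the two views of rigidity are directly comparable).

The RMSF reference is the *iterated mean structure*: frames are superposed
onto the current mean, the mean is recomputed, and the loop repeats until
the mean moves < 1e-6 Å (cap 100 iterations; convergence is typically 2–4
passes). This is a deterministic, convergent realisation of "fluctuations
about equilibrium positions". No mass weighting is applied; on a Cα-only
selection weights would be uniform anyway. Superposition is whole-selection
by default; per-monomer profiles can be obtained by slicing the selection,
but note that the whole-selection fit absorbs the 6 rigid degrees of freedom,
so with N atoms the measured mean-square fluctuation of an isotropic
Gaussian ensemble is biased low by roughly a factor (1 − 2/N); at the
package's default problem sizes (N ≥ 100) this is within the Monte-Carlo
noise of the tests.

Variant comparison: per-residue RMSF values of corresponding residues in the
different monomers are averaged (chains must carry identical residue index
sets), then subtracted position-wise. In the difference profile the fraction
of *strictly* negative positions is reported (ties count as non-negative),
plus a 20-bin histogram.

### Distance fluctuations (DF)

DF_ij = ⟨(d_ij − ⟨d_ij⟩)²⟩, the plain time variance of the Cα–Cα distance,
in Å². Choices:

- **Population variance** (1/F), not sample variance: the defining bracket
  is a time average, and the estimator is compared against an independent
  per-pair double-loop oracle for exact equality.
- **No superposition**: distances are invariant under per-frame rigid
  motions, so superposing first would only add a hidden free choice. The
  invariance is verified to 1e-9 Å² against the same fluctuation
  realisation with random per-frame rotations/translations applied.
- **Two-pass accumulation** (mean first, then squared deviations): a rigid
  trajectory yields zeros at ~1e-30 Å² instead of the ~1e-13 Å²
  cancellation error of a sum-of-squares shortcut.

Block summaries report mean/median DF within and between user-supplied
residue blocks; the variant difference reports the fraction of residue
pairs with negative ΔDF. Raw values only — no thresholding or colour-scale
decisions are baked in.

### Hydrogen bonds

Detection is geometric: donor–acceptor heavy-atom distance ≤ 3.5 Å and
D–H···A angle ≥ 135° by default (common MD-analysis convention; both
configurable, since conventions differ). Donor/acceptor flags come from
standard residue chemistry (backbone amide N and carbonyl O; side-chain
N/O per residue), with hydrogens assigned to the nearest N/O within 1.25 Å —
name-convention-free, so it tolerates the several H-naming schemes found in
PDB files. Donors require a hydrogen actually present in the input; a
hydrogen-free ensemble yields a warning and no donors. Equivalent donor
hydrogens (e.g. NH₃⁺) are collapsed to one record per donor-heavy/acceptor
pair, counting each frame once, so records are residue-level bonds keyed by
explicit atom names. Persistence = % of frames detected (1 decimal);
default reporting threshold 15%, chosen below the smallest persistence
worth tabulating in practice (~16%). Loosening either cutoff can only grow
the per-frame detection set, so persistences are monotone in the criteria
(property-tested).

## Synthetic-data generator

The generator produces the *statistical structure* the estimators assume,
not physical dynamics:

- **Block trajectories**: frame t = R_t·(x + s·(a_b(t) + e_i(t))) + T_t,
  with a_b an isotropic Gaussian displacement shared within block b (sd
  σ_block per coordinate), e_i independent per residue (sd σ_local), s the
  variant amplitude scale, and (R_t, T_t) optional random rigid motion.
  Displacements are frame-independent (white): the estimators are pure
  ensemble averages, for which autocorrelation changes only the effective
  sample size, not expectations. Defaults σ_block = 0.5 Å, σ_local = 0.3 Å
  on a 4-chain, 30-residue-per-chain helical Cα trace — fluctuation
  amplitudes and a block structure of the magnitude seen in stable globular
  oligomers. The rigidified variant is s < 1 (ground truth: RMSF scales
  with s, DF with s²). Rigid motion draws come from a separate RNG stream,
  so toggling it preserves the fluctuation realisation — that is what makes
  the invariance tests exact rather than statistical.
- **H-bond series**: a 5-atom N–H···O system that satisfies the default
  criteria (2.9 Å, 170°) in each frame independently with probability p,
  else places the acceptor at 5.5 Å. Persistence estimates are binomial,
  and are tested as such.
- **Melting/inactivation curves**: exact two-state logistics (rising
  unfolded fraction or falling % activity) plus optional Gaussian noise;
  default grids 25–95 °C at 0.5 °C (melting) and 37–70 °C at 1 °C
  (inactivation), matching standard assay protocols.
- **Kinetics**: v(S) = kcat·E0·S/(Km+S) with multiplicative noise
  (constant CV, the error structure typical of activity assays). Defaults
  Km = 0.89 mM, kcat = 59.77 s⁻¹ — wild-type asparaginase-like constants.
  E0 in mg is converted to nmol via an explicit monomer mass (default
  34 590 Da); all derived quantities (kcat, specific activity) are exact
  functions of that choice, so it is a parameter, not a constant.

What the generator does **not** emulate: temporal correlation, anisotropic
or multi-well dynamics, solvent, side-chain chemistry beyond donor/acceptor
placement, baseline drift or post-peak dye quenching beyond a simple
plateau, outliers. Passing tests therefore demonstrate estimator
correctness under the assumed statistical model, not robustness to every
artefact of real assays.

## Curve descriptors

**Normalisation** (melting): baseline = mean of the lowest-temperature 10%
of points; plateau = maximum of a 3-point moving average (robust to the
fluorescence drop after the unfolding peak that hydrophobic dyes show);
y′ = (y − baseline)/(plateau − baseline), clipped to [0, 1.05]. A curve
whose plateau is indistinguishable from its baseline is rejected ("no
transition"). The operator is the identity on a curve whose baseline window
is exactly 0 and plateau exactly 1.

**Unfolding fit**: least-squares logistic 1/(1+exp((Tm−T)/k)) (scipy
`curve_fit`; initial Tm from the interpolated 0.5 crossing, k from the
0.25–0.75 span). Reported: T0.5 = Tm (2 dp), max slope = 25/k %/°C (the
analytic maximum derivative of the percentage curve — the identity
max_slope·k = 25 is asserted post-fit), onset = the fitted 5% crossing
Tm − k·ln 19, clipped to the observed range. The onset is computed
analytically from the fitted parameters rather than as the first grid point
with f ≥ 0.05: the continuous definition is grid-independent,
shift-equivariant, and satisfies onset − Tm = −k·ln 19 exactly, where grid
quantisation would make the reported integer flip on exact crossings. The
5% threshold is a convention (no standard definition of "initial unfolding
temperature" exists); it is recorded in the fit metadata. If the nonlinear
fit fails, the midpoint falls back to monotone linear interpolation.

**Inactivation fit**: decreasing logistic 100/(1+exp((T−T50)/k)) with the
plateau pinned at 100% (residual activity is defined relative to the
untreated control). Inputs that are plainly not percentages (max > 150 or
all < 1) are rejected. The two-state logistic is an assumption for both
curves — the assays define no model — and is flagged in the fit metadata.

**Michaelis–Menten**: `curve_fit` on v = Vmax·S/(Km+S); initial guesses
Vmax = 1.05·max(v) and Km = the interpolated substrate at half the plateau
guess. Standard errors from the fit covariance; the efficiency SE is
first-order propagated. Non-convergence and non-positive estimates raise
structured errors. Data confined far above Km leave Km weakly identified;
the reported covariance SE then exceeds 50% of the estimate, in agreement
with a profile-likelihood scan (tested).

## Masses

Average masses use a pinned table of amino-acid residue masses (IUPAC 1997
average atomic weights, as tabulated by ExPASy) plus one water
(18.0153 Da); the test suite cross-checks against pyteomics. Matching of a
deconvoluted intact mass considers **N-terminal truncations only** (the
degradation under study is exclusively N-terminal); default tolerance 5 Da
absolute, with a relative mode (e.g. 0.02%, typical of linear ion-trap
intact-mass accuracy). Reproducing a tagged construct's absolute masses
requires the actual construct sequence (tag and linker included) as input.

## Problem sizes and determinism

All analyses are exercised on a 120-residue (4 × 30) synthetic tetramer.
Estimator-recovery tests use 2 000 frames (ΔRMSF/DF sign recovery), 5 000
frames (RMSF closed form, H-bond binomial checks) or 20-seed replication;
the full suite runs in about a minute on one core. Every random draw flows
from an explicit integer seed (NumPy `default_rng`/`SeedSequence`); equal
seeds give bit-identical outputs, and CLI reports embed the version, a
config hash and input checksums.

## Known limitations

- Cα-level geometry only in the synthetic structures; the H-bond toy system
  is minimal by design.
- The DF matrix is reported raw; no community/spectral decomposition.
- Two-state logistic descriptors cannot represent multi-transition melts.
- No binary trajectory formats (DCD/XTC); multi-model PDB is the canonical
  ensemble format, chosen to keep inputs text-based and dependency-light.
- Whole-selection superposition is the only RMSF mode wired into the CLI.
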