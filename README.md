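# rigidiscope

Comparative **rigidity and stability analysis** for protein variants.

When a point mutation stabilises an enzyme — the motivating case is a
single-residue variant of the homotetrameric *E. coli* type II
L-asparaginase whose flexible active-site loop is a protease target — the
evidence typically comes from several independent measurements: molecular
ensembles (is the mutant less mobile?), thermal assays (does it unfold and
inactivate at higher temperature?), kinetics (is catalysis unchanged?) and
intact-mass spectrometry (where is the wild-type being clipped?).
`rigidiscope` implements the full analysis chain for all of these, plus a
seeded synthetic-data generator so every estimator can be validated against
known ground truth.

## What it computes

**Ensemble rigidity** (input: multi-model PDB, one MODEL per conformation)

- RMSD time series after least-squares (Kabsch) superposition,
  RMSD(t) = √(1/N Σᵢ ‖rᵢ(t) − rᵢ^ref‖²) on a Cα selection.
- Per-residue RMSF about the iterated mean structure,
  RMSFᵢ = √⟨‖rᵢ − ⟨rᵢ⟩‖²⟩, averaged over corresponding residues of the
  monomers, and the difference profile ΔRMSFᵢ = RMSFᵢ(variant) − RMSFᵢ(WT):
  predominantly negative values indicate rigidification.
- The distance-fluctuation (DF) coordination matrix,
  DFᵢⱼ = ⟨(dᵢⱼ − ⟨dᵢⱼ⟩)²⟩ with dᵢⱼ the Cα–Cα distance — invariant under
  rigid motions, so no superposition is needed; low DF = coordinated
  (mutually rigid) residue pair. Computed tetramer-wide or per monomer,
  with block summaries and variant-difference statistics.
- Geometric H-bond persistence: a donor–H–acceptor triplet counts in a
  frame when the donor–acceptor distance ≤ 3.5 Å and the D–H···A angle
  ≥ 135° (configurable); persistence is the % of frames detected.

**Stability curves** (input: 2-column CSV)

- Thermal-shift melting curves are normalised to unfolded fraction and fit
  with a two-state logistic f(T) = 1/(1 + e^{(Tm−T)/k}): reports the
  midpoint T0.5, the maximum unfolding slope 25/k %/°C, and the onset
  (5%-unfolded) temperature Tm − k·ln 19.
- Thermal inactivation: decreasing logistic A(T) = 100/(1 + e^{(T−T50)/k});
  midpoint = T50, the temperature of 50% residual activity.

**Kinetics and masses**

- Michaelis–Menten fits v = Vmax·S/(Km+S): Km (mM), kcat (s⁻¹, from the
  enzyme amount in nmol), specific activity (U/mg, 1 U = 1 µmol·min⁻¹) and
  efficiency kcat/Km (mM⁻¹·s⁻¹), with standard errors.
- Average protein masses and matching of deconvoluted intact masses to
  N-terminal cleavage sites (e.g. limited proteolysis of the flexible loop).

## Worked example

Generate a "wild-type" ensemble and a rigidified "mutant" (all fluctuation
amplitudes scaled by 0.8), then compare them:

```bash
rigidiscope simulate --kind trajectory --out wt.pdb  --seed 1 --n-frames 400 --scale 1.0
rigidiscope simulate --kind trajectory --out mut.pdb --seed 2 --n-frames 400 --scale 0.8
rigidiscope compare --traj-mut mut.pdb --traj-wt wt.pdb --out compare.json
# INFO rigidiscope: ΔRMSF negative fraction 1.000, DF negative fraction 1.000; wrote compare.json
```

`compare.json` then contains (abridged):

```
delta_rmsf.summary.fraction_negative = 1.0      # every residue is less mobile
delta_rmsf.summary.median_delta      = -0.160   # Å, median RMSF decrease
df_difference_summary = {fraction_negative: 1.0, mean_delta: -0.203, n_pairs: 7140}
verdict_rigidified = true
```

Every residue position has lower RMSF and every residue pair has lower
distance fluctuation in the mutant — exactly the ground truth built into the
generator (RMSF scales with the amplitude factor 0.8, DF with 0.8² = 0.64).

A thermal-shift curve with a 62.04 °C midpoint and logistic scale 4.72 °C:

```bash
rigidiscope simulate --kind melting --midpoint 62.04 --steepness 4.72 --out melt.csv
rigidiscope thermal --melting melt.csv --out melt_fit.json
# INFO rigidiscope: T0.5 = 62.04 degC; wrote melt_fit.json
```

reports `T0_5_degC: 62.04`, `max_slope_pct_per_degC: 5.3` (= 25/4.72) and
`onset_degC: 48.2` (= Tm − k·ln 19): the fit recovers the generator's
descriptors exactly on noiseless data.

Real multi-model PDB ensembles (e.g. downloaded entries such as 5MQ5 or
3ECA, or snapshots exported from an MD engine) can be passed to the same
commands; nothing in the analysis depends on the synthetic generator.

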