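# koffkit

Tools for modeling protein–ligand binding kinetics from equilibrium
structures: per-residue interaction-energy featurization, descriptor
pretreatment, and regression of dissociation rate constants
(pkoff = −log10 koff) with a Bayesian neural network and seven baseline
regressors, evaluated by a ranked 4:1 split and leave-one-out
cross-validation.

## What it does

1. **complex_io** — reads energy-minimized protein–ligand complexes
   (PDB ATOM/HETATM subset, ligand identified by residue name, default
   `LIG`) plus a per-atom parameter sidecar (partial charge, LJ Rmin/2,
   well depth) in CSV or JSON; also matrix/dataset CSV I/O and a
   fixture-quality element-rule parameterizer.
2. **energetics** — decomposes the intermolecular nonbonded energy into
   per-residue van der Waals (AMBER-style LJ, Lorentz–Berthelot combining)
   and electrostatic (Coulomb with uniform dielectric, default 4) terms and
   assembles the N × 2·n_p descriptor matrix (vdW block, then
   electrostatic block, residue-ordered).
3. **pretreatment** — the fixed four-step sequence: positive energies
   truncated to zero → columns with sample std below a threshold removed →
   optional standardization → PCA (SVD, deterministic sign convention).
   Statistics are frozen from training rows only.
4. **models** — a mean-field variational BNN (pure NumPy: closed-form KL,
   local reparameterization, Adam on the negative ELBO, learnable Gaussian
   noise, 95% posterior-predictive intervals) plus PLSR, Bayesian ridge,
   GPR, PCR, random forest, SVR and gradient boosting behind one
   fit/predict contract (the boosting kind is registered as `xgboost` and
   backed by scikit-learn's `GradientBoostingRegressor`).
5. **evaluation** — ranked every-fifth-sample split (sort ascending by
   pkoff, 1-based positions 5, 10, … to test), LOO-CV with per-fold
   pretreatment refits, the 12 statistical indicators
   (R²/Q²cv, MAE, RMSE, Pearson r on train/cv/test), and multi-model
   comparison reports.
6. **dataset_analysis** — pkoff-vs-pKd linearity fit (OLS slope α′,
   intercept β′, R²), fingerprint chemical-space PCA, label-distribution
   summaries.
7. **synthetic** — deterministic toy complexes (shared protein scaffold,
   clash-free ligand placement) with planted descriptor→pkoff relations,
   so the full pipeline is testable without external data.

## CLI

```bash
koffkit simulate  --seed 5 --out-dir fixtures/            # synthetic PDB + sidecar + labels
koffkit featurize --complexes fixtures/complexes --params fixtures/params --out X.csv
koffkit pretreat  --matrix X.csv --out scores.csv --save-fitted fitted.json
koffkit train     --scores scores.csv --labels fixtures/labels.csv --model bnn --out model.json
koffkit evaluate  --matrix X.csv --labels fixtures/labels.csv --models bnn,plsr --report report.csv
koffkit bep       --labels fixtures/labels.csv --out bep.json
koffkit qc        --labels fixtures/labels.csv --smiles smiles.csv --out qc.json
koffkit pipeline  --config run.toml --out-dir out/        # end to end, with manifest
```

Configuration is TOML; a single `--seed` fans out deterministically to
per-stage seeds, so identical inputs reproduce identical outputs.

Example pipeline config:

```toml
seed = 3
[paths]
complexes = "fixtures/complexes"
params = "fixtures/params"
labels = "fixtures/labels.csv"
[pretreatment]
n_components = 3
[[models]]
kind = "bnn"
[[models]]
kind = "plsr"
```

## Notes

- The BNN is implemented in-repo with hand-coded backpropagation; all
  baselines are backed by scikit-learn.
- Real kinetic datasets are external inputs; nothing in the test suite or
  acceptance path depends on them.
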