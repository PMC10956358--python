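# qsarkit

Tested building blocks for a small-molecule inhibitor-discovery analysis:
QSAR model building with a full validation battery, virtual-screening
early-recognition metrics, MM/GBSA component bookkeeping, MD trajectory
statistics, and rule-based drug-likeness filters — plus seeded synthetic-data
generators so every stage runs offline.

## What's inside

| Module | Purpose |
| --- | --- |
| `qsarkit.core_data` | Compound/dataset types, IC50→pIC50 conversion, train/test splitting, CSV I/O |
| `qsarkit.mlr` | OLS multiple linear regression; R², adjusted R², MSE/RMSE/MAE, F, s, BIC |
| `qsarkit.validation` | LOOCV Q², Golbraikh–Tropsha external criteria, Y-randomization (cRp²), leverage applicability domain with Williams table |
| `qsarkit.ann` | Small sigmoid-hidden-layer regressor (conjugate-gradient training, seeded init, z-scoring) |
| `qsarkit.screening` | ROC AUC, BEDROC/RIE (Truchon–Bayly), enrichment factors, accumulation curve/AUAC, actives-at-decoy-fraction |
| `qsarkit.mmgbsa` | MM/GBSA per-frame component tables, means ± sd, ΔG_gas/ΔG_solv/total identities |
| `qsarkit.traj` | Kabsch superposition, RMSD/RMSF/RoG, H-bond counting, Shrake–Rupley SASA, coordinate PCA, 2-D free-energy landscapes; multi-frame XYZ / multi-model PDB I/O |
| `qsarkit.druglikeness` | Lipinski, Ghose, Veber, Egan, Muegge filters over property tables |
| `qsarkit.synthetic` | Seeded generators for QSAR tables, ranked screens, trajectories, MM/GBSA frames |
| `qsarkit.cli` | `qsarkit` command with one subcommand per stage |

## CLI

```bash
# synthetic 28-compound dataset with a 23/5 split, then fit + validate
qsarkit simulate qsar --seed 7 --out qsar.csv
qsarkit qsar-fit --data qsar.csv --model-out model.json
qsarkit qsar-validate --data qsar.csv --out report.json   # LOOCV + external criteria
qsarkit ydrand --data qsar.csv --n-perm 10 --seed 1
qsarkit domain --data qsar.csv --williams-out williams.csv
qsarkit domain --k 4 --n 24                               # h* only
qsarkit ann --data qsar.csv --hidden 3 --seed 0

# screening metrics on a ranked list (id,score,active)
qsarkit simulate screen --seed 1 --separation 3 --out screen.csv
qsarkit screen-metrics screen.csv --alpha 160.9 --ef 0.01,0.05,0.2

# MM/GBSA totals and trajectory statistics
qsarkit simulate mmgbsa --seed 1 --out frames.csv && qsarkit mmgbsa-total frames.csv
qsarkit simulate traj --seed 1 --out t.xyz --ref-out ref.xyz
qsarkit traj rmsd --traj t.xyz --ref ref.xyz --out rmsd.csv
qsarkit traj fel --traj t.xyz --bins 40 --out fel.csv

# drug-likeness verdicts
qsarkit druglikeness props.csv --rules lipinski,veber,egan
```

A YAML file passed as `qsarkit --config cfg.yaml <subcommand>` supplies
per-subcommand default options; explicit flags win.

## Conventions worth knowing

- pIC50 = 9 − log10(IC50 in nM); activity labels use a strict `pIC50 > 6.5`.
- H-bond distance criterion defaults to H···A < 3.5 Å (`distance_mode`
  switches to the conventional donor–acceptor reading); the angle window is
  |∠DHA − 180°| ≤ 30°.
- Leverage uses the intercept-augmented design, so training leverages sum to
  k + 1 and h* = 3(k+1)/n.
- cRp² = R·√(R² − mean permuted R²), clamped at 0 with a warning flag when the
  radicand is negative.
- Free-energy landscapes are reported in kcal/mol with k_B·T at 310 K by
  default; empty bins are NaN, the occupied minimum is exactly 0.
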