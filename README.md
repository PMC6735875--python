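# scarconcord

Concordance analysis between MRI-derived ventricular scar and
electroanatomic substrate on endocardial surface meshes.

## The problem

In ventricular tachycardia substrate assessment, two independent views of
myocardial scar must be reconciled: the **structural** view from late
gadolinium enhancement (LGE) MRI, where scar retains contrast and appears
hyper-intense, and the **electrophysiological** view from catheter-based
electroanatomic mapping (EAM), where scar shows low bipolar voltage and
slow conduction. `scarconcord` implements the full analysis chain that
quantifies their agreement on a per-vertex ("nodal") basis:

1. **FWHM scar segmentation** — within the LV wall mask, voxels with
   intensity above half the maximum wall intensity are labelled scar.
2. **Rigid registration** — a landmark (Kabsch/Procrustes) fit aligns the
   image frame to the mapping frame, with optional iterative-closest-point
   (ICP) refinement of the scar point cloud against the endocardial mesh.
3. **Voxel-to-node mapping** — each scar voxel centre is assigned to its
   nearest mesh vertex, yielding a binary LGE scar map on the shell.
4. **Map interpolation** — electrogram samples fix Dirichlet values at
   their nearest vertices; remaining vertices solve the discrete Laplace
   equation on the vertex–edge graph (each unknown equals the mean of its
   neighbours), reproducing the relaxation colour interpolation of
   clinical mapping platforms.
5. **Concordance and diagnostics** — Sørensen–Dice coefficients between
   the binarized voltage map and the LGE map across voltage thresholds,
   plus confusion statistics (Se/Sp/PPV/NPV) and ROC/AUC for voltage- and
   stimulus-to-QRS-based scar detection, with the LGE map as the gold
   standard.

With `A` the voltage-abnormal vertex set (bipolar voltage < threshold,
conventionally 1.5 mV) and `B` the LGE scar vertex set:

```
DSC_scar   = 2|A ∩ B| / (|A| + |B|)
DSC_normal = 2|Aᶜ ∩ Bᶜ| / (|Aᶜ| + |Bᶜ|)
DSC_total  = (2|A ∩ B| + 2|Aᶜ ∩ Bᶜ|) / 2N      (= nodal agreement fraction)
```

Because no raw animal data are distributed, the package ships a seeded
**synthetic LV phantom**: an ellipsoidal half-shell wall with a transmural
antero-septal scar sector, class-conditional log-normal bipolar voltages,
truncated-Gaussian S-QRS delays with capture failure inside scar, and a
known rigid misalignment between the image and mapping frames — so every
stage can be validated against analytic ground truth.

## Worked example

```python
from scarconcord import PhantomConfig, run_phantom_study

res = run_phantom_study(PhantomConfig(seed=1))
rep = res.report
con = rep["concordance"]
print(f"DSC @ 1.5 mV: total {con['dsc_total']:.3f}, "
      f"scar {con['dsc_scar']:.3f}, normal {con['dsc_normal']:.3f}")
vd = rep["voltage_diagnostics"]
print(f"voltage vs LGE: sens {vd['sensitivity']:.2f}, "
      f"spec {vd['specificity']:.2f}, AUC {vd['auc']:.3f}")
```

prints

```
DSC @ 1.5 mV: total 0.962, scar 0.843, normal 0.978
voltage vs LGE: sens 0.85, spec 0.95, AUC 0.954
```

Reading: after segmenting the phantom's LGE volume, recovering the frame
transform from noisy landmarks (here to 0.6° / 0.8 mm) and projecting scar
onto the 2987-vertex shell, 96.2% of vertices agree between the low-voltage
map and the LGE map at the 1.5 mV cut-off; scar-class overlap is 0.843.
Classifying each of the 445 electrograms by its own voltage against its
vertex's LGE label gives sensitivity 0.85 and specificity 0.95 — close to
the class-conditional log-normal tail probabilities (0.90 / 0.97) that the
voltage model implies, the residual being boundary-vertex transfer error.

The same pipeline is scriptable from the shell:

```sh
scarconcord run --out demo_run --seed 1
scarconcord report --run-dir demo_run
scarconcord dice --voltage-map demo_run/voltage_map.csv --scar-map demo_run/lge_node_map.csv
```

Subcommands `phantom`, `segment`, `register`, `map`, `dice`, `roc`, `run`,
`report` operate on NIfTI volumes, PLY meshes and documented CSV tables, so
real data in the same formats drop in for the synthetic inputs.

## Layout

- `scarconcord.phantom` — synthetic LV generator (geometry, electrics, landmarks)
- `scarconcord.segmentation` — FWHM thresholding, scar point clouds
- `scarconcord.transforms` / `scarconcord.registration` — rigid fits, ICP, nearest-node mapping
- `scarconcord.eam` — nodal map assembly, Laplace interpolation, S-QRS classification
- `scarconcord.concordance` — Dice coefficients and threshold sweeps
- `scarconcord.diagnostics` — confusion statistics, ROC/AUC
- `scarconcord.pipeline` / `scarconcord.cli` — orchestration, YAML config, I/O

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
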