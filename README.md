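# ke4dflow

Ventricular and cavopulmonary **kinetic-energy (KE) quantification from 4D
phase-contrast MRI**, built for studying single-ventricle (Fontan)
circulation against healthy controls.

In a Fontan circulation one functional ventricle drives the systemic
circulation while venous blood reaches the lungs passively, so ventricular
*filling* — diastole — is the limiting step. 4D PC-MRI measures the
three-directional blood velocity in every voxel over the cardiac cycle;
summing each voxel's kinetic energy

&nbsp;&nbsp;&nbsp;&nbsp;KE = ½ m v²,&nbsp;&nbsp; m = V<sub>voxel</sub> · ρ,&nbsp;&nbsp; ρ = 1.05 g/cm³

over the segmented ventricle (or a Fontan-pathway vessel segment) yields a
KE–time curve whose systolic and diastolic peaks, their ratio, a possible
late (atrial) peak, and a possible diastolic *plateau* characterize the
hemodynamics. KE is indexed to stroke volume (mJ/ml), body surface area
(mJ/m²) or cardiac index to compare subjects of different size.

The package implements the full measurement chain for analysts working in
Python:

* **`ke4dflow.io`** — data model (velocity field + per-phase label masks +
  JSON metadata sidecar) and NIfTI-based storage;
* **`ke4dflow.phantom`** — synthetic phantoms with exact ground truth:
  plug flow, Poiseuille pipe, a parameterized single-ventricle phantom
  (systolic-dominant / diastolic-dominant / plateau KE patterns),
  corruption injectors (eddy-current velocity planes, venc aliasing,
  noise) and a two-group cohort simulator;
* **`ke4dflow.preprocess`** — temporal phase unwrapping, first-order
  polynomial eddy-current compensation fitted to stationary tissue, and
  periodic temporal reconstruction to the analysis phase count (40);
* **`ke4dflow.kinetic_energy`** — voxel and ROI KE, cycle landmarks from
  the ventricular volume curve, peak/fusion/plateau analysis, pattern
  classification, indexing;
* **`ke4dflow.hemodynamics`** — EDV/ESV/SV/EF, through-plane flow and
  effective stroke volume, cardiac output/index, aortopulmonary-collateral
  (APC) flow with the >25%-of-SV significance rule, vessel cross-sections;
* **`ke4dflow.stats`** — exact Mann–Whitney U (enumeration-backed),
  Pearson correlation, Cohen's kappa, interobserver variability, cohort
  summary tables with small-subgroup test suppression;
* **`ke4dflow.pipeline`** / **`ke4dflow` CLI** — configuration-driven,
  seed-reproducible subject and cohort runs.

## Worked example

```python
import ke4dflow as k
from ke4dflow.pipeline import measure_subject

fld, masks, truth = k.make_ventricle_phantom("diastolic_dominant",
                                             n_phases=20, seed=7)
result = measure_subject(fld, masks)   # preprocess -> KE -> hemodynamics
peaks, rec = result["peaks"]["ventricle"], result["record"]
print(peaks.systolic_peak[0], peaks.early_diastolic_peak[0], peaks.sd_ratio)
print(rec.ke_pattern, rec.peak_systolic_ke_sv, rec.peak_diastolic_ke_sv)
```

prints

```
1.3459191846939558 2.020685143925457 0.6660707081160223
diastolic_dominant 0.021940518790655256 0.032940224698837006
```

— a 1.35 mJ systolic and 2.02 mJ early-diastolic KE peak, a
systole/diastole ratio of 0.67 (< 1, hence the diastolic-dominant pattern
of a short-outflow left ventricle), and peak KE/SV of 0.022 / 0.033 mJ/ml,
the scale observed in Fontan patients with left-ventricular morphology.

The `examples/` directory holds one short narrative script per
capability (analytic phantoms, preprocessing recovery, KE patterns,
cohort statistics, collateral flow); each prints what it computes and
what the numbers mean. The same chain is scriptable from the shell:

```bash
ke4dflow synth ventricle --pattern plateau --out scratch/demo --seed 1
ke4dflow run-cohort --n-per-group 8 --seed 12 --out scratch/cohort
```

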