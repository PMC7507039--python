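# vesselperm

Quantitative analysis tools for combined high-resolution vessel-wall MRI
(HR-MRI) and dynamic contrast-enhanced MRI (DCE-MRI) studies of
intracranial artery stenosis — the setting where a clinician needs to know
*why* a middle cerebral artery is narrowed (vasculitis vs atherosclerosis
vs moyamoya disease) and *whether* the blood–brain barrier downstream of
the stenosis is leaking.

The package implements three things:

1. **DCE-MRI permeability mapping.** Variable-flip-angle (VFA) T1 mapping
   from spoiled gradient-echo (SPGR) data, conversion of the dynamic
   signal to contrast-agent concentration, input-function handling
   (venous-sinus extraction or a population curve), and voxelwise fitting
   of the **extended Tofts model**

   &nbsp;&nbsp;&nbsp;&nbsp;
   C<sub>t</sub>(t) = V<sub>p</sub>·C<sub>p</sub>(t) + K<sup>trans</sup>
   ∫₀ᵗ C<sub>p</sub>(τ)·exp(−k<sub>ep</sub>(t−τ)) dτ,
   &nbsp; k<sub>ep</sub> = K<sup>trans</sup>/V<sub>e</sub>,

   yielding K<sup>trans</sup> (1/min), V<sub>e</sub>, V<sub>p</sub> maps and
   lesion-vs-mirror ROI statistics. The default solver is the closed-form
   linear least-squares reformulation; a bounded nonlinear fit is available
   as an independent cross-check.
2. **Vessel-wall morphometry.** Lumen area (LA), vessel area (VA) and wall
   area (WA = VA − LA) from cross-section label images by pixel counting;
   stenosis degree (1 − LA/LA<sub>ref</sub>)×100 with mild/moderate/severe/
   occlusion grading and focal/segmental/full-length extent classification.
3. **Small-cohort statistics.** Normality-gated two-sample comparisons
   (Shapiro–Wilk → pooled/Welch t or Wilcoxon rank-sum, with Levene's
   test), Pearson chi-square without continuity correction, Fisher's exact
   test, Spearman correlation, and a dispatcher that mirrors the standard
   SPSS-style workflow for aetiology-group tables.

Because no patient data are distributed, a fully seeded synthetic module
generates every input with known ground truth: SPGR phantoms whose
dynamic signals follow the extended Tofts forward model, annular vessel
cross-sections with known areas, and a 36-patient cohort table whose
group sizes, risk-factor counts and stage-by-stenosis cells match the
study the defaults are drawn from, exactly.

## Worked example

```python
import numpy as np
from vesselperm import (
    ExtendedToftsModel, VFAT1Model, extract_aif,
    generate_phantom, roi_ktrans_stats, signal_to_concentration,
)

# phantom with a leaky lesion (Ktrans 0.098 /min), its contralateral
# mirror (0.003 /min), background tissue and a venous sinus
ph = generate_phantom(seed=1, grid_shape=(12, 12, 2), snr=50.0)

t1 = VFAT1Model(ph.vfa).fit()                      # VFA T1 mapping
conc, qc = signal_to_concentration(ph.dynamic, t1, ph.protocol)
aif, n = extract_aif(conc, ph.sinus_mask, ph.protocol.hematocrit)

tissue = ~ph.sinus_mask
fit = ExtendedToftsModel(conc.conc[tissue], aif).fit()
print(fit.summary())

kmap = np.full(ph.labels.shape, np.nan)
kmap[tissue] = fit.ktrans
s = roi_ktrans_stats(kmap, ph.labels == 1, ph.labels == 2)
print(f"lesion {s.lesion_mean:.4f} /min, mirror {s.mirror_mean:.4f} /min")
```

Output:

```
Extended Tofts fit results
==========================
method:          linear
voxels:          216
flagged/clipped: 99
Ktrans mean:     0.0344 1/min
Ktrans sd:       0.0459 1/min
Ve mean:         0.0833
Vp mean:         0.0137
RSS total:       0.3452
lesion 0.0990 /min, mirror 0.0035 /min
```

The lesion ROI recovers its generating permeability (0.098 /min, the
acute-infarct group mean) and the mirror ROI its low control value
(0.003 /min); the map-wide mean is diluted by the non-enhancing
background region, whose no-exchange voxels fit at K^trans ≈ 0 and are
frequently flagged (clipped at a bound) under noise.

The same chain is available from the shell:

```bash
vesselperm run --seed 1 --out results/demo       # full pipeline + report
vesselperm simulate cohort --seed 1 --out cohort.csv
vesselperm stats --cohort cohort.csv --variable smoking --out stats.csv
```

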