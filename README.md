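# octdr

Early detection of diabetic retinopathy (DR) from macular 3D-OCT volumes,
for researchers building and validating OCT texture-analysis pipelines.
A volume is a stack of K grayscale B-scans (K = 5, mid scan through the
fovea) in which the retina shows 12 layers (NFL … RPE). The pipeline:

1. **Segmentation** — a labeled mid scan acts as a patient-specific atlas:
   each neighboring scan is densely registered to its labeled neighbor and
   every pixel takes the label with the highest incidence among
   intensity-similar pixels (|Δg| ≤ τ) in an expanding window around its
   correspondence.
2. **Features** — per layer *l* and co-occurrence offset *i* (the 8
   in-plane unit/diagonal offsets), the gray-pair distribution F_i is
   tallied inside the layer and averaged across B-scans; the analytical
   Gibbs potentials of a pairwise Markov–Gibbs random field are

       V_i(q,s) = ρ_i · (F_i(q,s) − f_i(q) f_i(s)),   f_i(q) = Σ_s F_i(q,s)

   Each pixel's Gibbs energy sums the potentials of its in-layer cliques,
   and the nine deciles E(10)…E(90) of the layer's energy CDF form its
   descriptor.
3. **Diagnosis** — twelve feed-forward networks (9 → 20 tanh → 10 tanh →
   2 softmax, per-sample SGD backprop) classify each layer; a majority
   vote over the 12 layer decisions gives the subject-level diagnosis.

Because clinical OCT datasets of this kind are private, the package
includes a seeded synthetic phantom: a 12-layer retina with foveal dip and
speckle-like texture where the two classes differ only in *second-order*
spatial statistics (matched first-order histograms), so every stage is
testable end to end. See `docs/methods.md` for the model details and
design choices.

## Worked example

```python
import numpy as np
from octdr import phantom, propagation, mgrf

params = phantom.PhantomParams()                      # 128 x 256 x 5, Q = 32
volume, truth = phantom.generate_phantom_volume("DR", params, seed=7)

# propagate the ground-truth mid-scan labels through the stack
seg = propagation.propagate_volume(volume, truth.labels[volume.mid_index])
band = truth.labels > 0
print(f"retina-band agreement: {(seg.labels[band] == truth.labels[band]).mean():.3f}")

features = mgrf.extract_volume_features(volume, seg, class_label="DR")
print(features[["layer", "d10", "d50", "d90"]].head(6).to_string(index=False))
```

```
retina-band agreement: 0.988
 layer      d10      d50      d90
     1 0.036540 0.133317 0.240714
     2 0.038839 0.128145 0.240146
     3 0.038671 0.131264 0.235596
     4 0.037563 0.131119 0.236331
     5 0.017586 0.110747 0.222934
     6 0.021627 0.113692 0.221808
```

98.8 % of retina-band pixels keep their true layer after propagation from
the mid scan alone. The decile rows are each layer's Gibbs-energy CDF
summary — the DR effect lives in layers 5–6 (OPL/ONL), whose energy
distribution is visibly shifted low relative to the unaffected layers; the
per-layer networks learn exactly this shift while first-order histograms
carry no class signal.

The same pipeline is available from the shell:

```bash
octdr phantom  --seed 0 --out cohort/ --n-healthy 20 --n-dr 20
octdr segment  --volume cohort/h000_volume.tif --mid-labels cohort/h000_labels.tif --out seg.tif
octdr features --volume cohort/h000_volume.tif --labels seg.tif --out features.csv
octdr evaluate --manifest cohort/manifest.csv --k 5 --seed 0 --out eval/
```

`evaluate` writes a 13-row report (12 layers + majority vote) with
accuracy/sensitivity/specificity and per-layer ROC/AUC CSVs.

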