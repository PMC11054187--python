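# mdbind

Trajectory-based decoding of inhibitor binding to bromodomains (and other
single-chain receptors): residue-contact-map deep learning with gradient
saliency, PCA free-energy landscapes, standard structural metrics,
hydrogen-bond occupancy, and MM-GBSA-style binding free-energy bookkeeping
with per-residue decomposition.

## Who this is for

Computational chemists and structural bioinformaticians who have conformational
ensembles of a receptor in several ligation states (e.g. from molecular
dynamics) and want to answer three questions:

1. **Which internal contacts distinguish the ligation states?**  Each frame is
   turned into an N x N binary residue contact map (Cα–Cα distance ≤ 4.5 Å),
   encoded as a grayscale image, and a small 2D CNN is trained to classify the
   states.  Vanilla-gradient saliency — |∂(class score)/∂pixel| — masked by the
   contact map of the most populated structural cluster, then aggregated over
   structural-domain pairs (helices, loops), names the discriminative contacts.
2. **How do the free-energy surfaces differ?**  PCA of superposed Cα
   coordinates (covariance C = ⟨(q − ⟨q⟩)(q − ⟨q⟩)ᵀ⟩) gives collective modes;
   projections onto PC1/PC2 are Boltzmann-inverted, G = −k_BT ln(P/P_max),
   into a free-energy landscape whose basins are detected and assigned
   representative frames.
3. **What holds the ligand in place?**  Single-trajectory MM-GBSA bookkeeping:
   ΔG_bind = ΔH − TΔS with ΔH = ΔE_ele + ΔE_vdW + ΔG_gb + ΔG_surf
   (Still-form pairwise generalized Born; ΔG_surf = γ·ΔSASA with
   γ = 0.0072 kcal mol⁻¹ Å⁻²), per-residue decomposition with a 0.8 kcal/mol
   key-residue threshold, hydrogen bonds by the <3.5 Å / >120° criterion
   with per-frame occupancy, and a Schlitter quasi-harmonic entropy bound.

Because real MD trajectories are bulky and slow to produce, the package ships
a first-class synthetic generator: K-class Cα-chain ensembles whose classes
differ by *planted* residue contacts (planted pairs ≤ 4.0 Å, all other
non-neighbor pairs > 5.5 Å, Gaussian noise about each reference), so every
stage of the pipeline has exact ground truth to recover.

## Worked example

```python
import numpy as np
from mdbind import (default_benchmark_spec, generate_class_ensembles,
                    contact_maps, ImageDataset, split_train_val,
                    CNNSpec, build_model, train_classifier,
                    most_populated_representative,
                    vanilla_gradient_saliency, mask_and_aggregate)

spec = default_benchmark_spec(n_residues=40, frames_per_class=300,
                              noise_sigma=0.3, seed=0)
ensembles, truth = generate_class_ensembles(spec)

images = np.concatenate([contact_maps(e).maps for e in ensembles]).astype(float)
labels = np.repeat(np.arange(3), 300)
ds = split_train_val(ImageDataset(images=images, labels=labels), 0.8, seed=0)

model = build_model(CNNSpec(n_input=40, n_classes=3, seed=0))
result = train_classifier(model, ds, seed=0, early_stop_accuracy=0.99)
print(f"validation accuracy {result.accuracy:.2f}% "
      f"after {result.epochs_run} epoch(s)")

rep_frame, rep_map = most_populated_representative(ensembles[0])
sal = vanilla_gradient_saliency(model, rep_map.astype(float), target=0)
sal = mask_and_aggregate(sal, rep_map, spec.domains)
print(sal.domain_table.head(3).to_string(index=False))
print("planted contact of class 0:", truth.discriminative_pairs[0])
```

Output:

```
validation accuracy 99.44% after 1 epoch(s)
domain_a domain_b  attribution
      D1       D3     0.882419
      D3       D3     0.341740
      D4       D4     0.282429
planted contact of class 0: [(5, 25)]
```

Class 0's planted contact is residue pair (5, 25), which lives in the domain
pair (D1, D3) — exactly the top-ranked saliency entry.  The per-class
validation accuracy and the confusion matrix live on `result`; the masked
saliency map itself is `sal.masked`.

The same stages are exposed as a CLI (`mdbind run --seed 0 --out-dir run/`,
or individually `simulate`, `featurize`, `train`, `attribute`, `metrics`,
`pca`, `fel`, `gbsa`, `report`), writing plain-text artifacts and a manifest
with checksums and seeds.

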