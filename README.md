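# lcnflow

Predicting bone's surface mechanoresponse from load-induced fluid flow
through the osteocyte lacunocanalicular network (LCN).

Osteocytes sit in lacunae connected by sub-micrometre canaliculi; cyclic
loading of the bone matrix pumps interstitial fluid through this network,
and the resulting flow is a leading candidate for the stimulus that tells
osteoblasts and osteoclasts where to form or resorb bone. `lcnflow`
implements the full computational chain needed to test that hypothesis on
whole cortical cross-sections:

1. **Image → network.** Confocal stacks of stained porosity are
   thresholded, segmented into canaliculi / lacunae / vascular channels,
   and skeletonized into a graph (`lcnflow.imaging`).
2. **Strain-rate sources.** A beam-bending surrogate of axial tibial
   loading (or an imported FE voxel table) supplies the volumetric strain
   rate ε̇_vol at every node (`lcnflow.strain`). A node of pore volume
   `V_i` contributes a fluid source `f_i = −V_i · ε̇_vol,i`: compression
   expels fluid.
3. **Circuit-theory flow.** Kirchhoff's first law plus Darcy's law in
   every canaliculus give a sparse graph-Laplacian system
   `AᵀCA·p = f` with `A` the directed edge–node incidence matrix and
   `C_jj = k_p·A_cs/(µ·l_j)` the edge conductances; surface and vascular
   nodes are pressure-0 sinks. Flows `q_j = C_jj·Δp_j` and mean
   velocities `v_j = q_j/A_cs` follow (`lcnflow.flow`).
4. **Surface predictor.** Both cortical surfaces are discretized into
   180 wedges of 2°; per wedge the predictor is the exponentially
   distance-weighted mean

   `P_w = (Σ_j w_j l_j)⁻¹ Σ_j |v_j| l_j w_j`, `w_j = exp(−r_j/R)`,

   with `r_j` the distance of canaliculus `j` to the surface and
   `R ≈ 15 µm` the decay length; profiles are smoothed with a circular
   30° triangular moving average, affinely calibrated to measured
   (re)modeling thickness and scored with the RMSE over the 180 wedges
   (`lcnflow.predictor`).
5. **Synthetic data.** Seeded generators produce annular cross-sections
   with heterogeneous canalicular density (target Ca.Dn 0.27 µm/µm³, a
   depleted angular band, vascular channels inside it), confocal-like
   image stacks, and sine-wave-like remodeling responses driven by the
   flow predictor itself, so every stage is testable without any
   download (`lcnflow.synthetic`).

## Worked example

```python
import numpy as np
from lcnflow import SyntheticSpec, synthetic_experiment, r_sensitivity
from lcnflow.synthetic import score_experiment

spec = SyntheticSpec(seed=3, outer_radius=100, inner_radius=70,
                     slab_thickness=20, n_lacunae=40, n_vascular=3)
exp = synthetic_experiment(spec)          # generate + solve + respond
print(exp.network.n_nodes, exp.network.n_edges)
res = score_experiment(exp)
print(res["flow"]["rmse"], res["strain"]["rmse"])
tab = r_sensitivity(exp.solution, exp.assignment, exp.measured,
                    [5, 10, 15, 20, 30])
print(tab.to_string(index=False))
```

prints

```
11627 27705
{'endocortical': 5.004967910215465, 'periosteal': 4.834937034474643}
{'endocortical': 12.120265013455768, 'periosteal': 13.488953458981674}
 R_um  rmse_um
  5.0 5.583300
 10.0 4.981141
 15.0 4.919952
 20.0 4.939990
 30.0 4.999132
```

The synthetic animal's measured response was generated from the flow
predictor at R = 15 µm plus 5 µm of per-wedge noise. The calibrated flow
predictor recovers the response down to the noise floor (RMSE ≈ 5 µm)
while the strain-only predictor, blind to the network architecture,
stays at 12–13 µm; the R parameter study finds its minimum at the
generating decay length.

A command-line interface mirrors the stages
(`lcnflow simulate | segment | network | density | solve | predict | run`),
e.g.

```bash
lcnflow network image.tif net.graphml --threshold 100 --voxel-size 0.37
lcnflow run --seed 1 --out results/run1
```

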