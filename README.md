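# lungmotion

Quantification of diaphragm and chest-wall mechanics from dynamic 3D lung
segmentations.

Diaphragm weakness (as in neuromuscular disease) can hide behind normal
spirometry because the rib-cage muscles compensate. Given a time-resolved 3D
lung segmentation of a breathing maneuver — a binary mask at full expiration
plus a displacement field tracking the lung surface over T frames —
`lungmotion` separates the contribution of the diaphragm from that of the
chest wall and computes a per-lung feature set that discriminates
diaphragm-weak from healthy breathing patterns.

The package is aimed at medical image-analysis researchers working with
dynamic (4D) MRI or CT of the thorax. It does **not** perform image
registration itself: the deformation field is an input.

## Method

1. **Surface extraction.** The full-expiration mask is meshed into a
   watertight triangle surface (vertices V, triangles F, outward normals)
   and propagated through all frames with the displacement field, so every
   surface point is traceable through the maneuver.
2. **Anatomical partitioning.** The surface is split into *costal*
   (chest-wall), *medial* (mediastinal/cardiac) and *diaphragmatic* regions:
   a watershed on the maximal principal curvature κ_max oversegments the
   mesh into patches bounded by surface ridges; patches close to the convex
   hull (≥ ¼ of triangles within 10 mm) are merged into the costal surface
   (it is the only large convex region); the rest is divided by a seeded
   random walker on the triangle-adjacency graph with edge weights
   `w_ij = exp(−d_ij²)`, `d_ij = w₁‖p_i−p_j‖ + w₂‖n_i−n_j‖ + w₃ f(κ_ij)`,
   where `f(κ) = 5κ for κ ≥ 0, |κ| otherwise` emphasizes convex ridges.
   Seeds come from anatomy: the most posterior patch is diaphragmatic; the
   most superior patch and patches occluded from a viewpoint below the lung
   are medial; the walker is iterated with additional random seeds until the
   partition changes by < 3%.
3. **Motion features.** Per lung:
   - **B1–B6** — residual volume V(T); vital capacity V(1)−V(T); volume
     ratio V(1)/V(T); cranio-caudal (CC) and antero-posterior (AP) size
     ratios; their quotient B6 = B4/B5.
   - **A1–A3** — volumes displaced by the diaphragmatic (D) and costal (C)
     surfaces: each triangle sweeps a signed prism between consecutive
     frames (`ΔV_D^t = Σ_{f∈D} V(prism)`, summed over t); the diaphragm
     contribution is A3 = ΔV_D/(ΔV_D+ΔV_C). By construction the sum over a
     *closed* surface telescopes exactly to V(t)−V(t+1).
   - **A4/A5** — maximum cranial excursion of diaphragm triangles
     (area-weighted mean; posterior−anterior contrast across the
     mid-coronal plane, right lung).
   - **A6/A7** — sagittal-plane orientation of the diaphragm dome (angle of
     the caudal normal, positive for a backwards-tilted dome) at full
     inspiration, and its largest signed change between the 10% and 90%
     volume-change time points.
4. **Visualization & statistics.** 2D unfolded-box excursion maps (bottom =
   diaphragm, sides = costal parts), ASE/MARE agreement metrics between
   time-series measurements, two-sided Wilcoxon rank-sum group comparisons
   and a significance-masked Pearson correlation matrix.

A synthetic dynamic lung phantom (`lungmotion.phantom`) with an analytically
invertible deformation provides ground truth for every step: labels, volume
and size curves, excursion and orientation schedules.

## Worked example

Run the whole chain on the control-like phantom (large dome excursion, dome
tilt 20°→5° during exhalation):

```python
from lungmotion import phantom as ph
from lungmotion.pipeline import run_phantom_pipeline

res = run_phantom_pipeline(ph.control_like(0))
print(res["diaphragm_label_agreement"])   # 0.917
print(res["features"]["A4"], res["features"]["A6"], res["features"]["A7"])
```

Output of the full feature table (measured vs the phantom's analytic truth):

```
diaphragm-label agreement vs analytic truth: 0.917
B3  measured    1.274   analytic    1.274     volume ratio TLC/RV
B6  measured    1.105   analytic    1.121     CC/AP expansion ratio (>1: dome-driven)
A4  measured   20.698   analytic   20.586     mean CC diaphragm excursion [mm]
A5  measured   20.248   analytic   24.149     posterior−anterior excursion [mm]
A6  measured   20.153   analytic   20.000     dome orientation at full insp. [°]
A7  measured  -15.197   analytic  -15.000     max orientation change [°]
```

The measured A4/A6/A7 recover the generator's built-in maneuver parameters
(descent 20 mm, tilt 20°→5°); A5 > 0 reflects the posterior-dominant
excursion of a healthy diaphragm. The patient-like phantom flips the
pattern: A5 ≤ 0, A3 < 0.2, B6 < 1. Note that A1–A3 in this listing use the
*measured* partition; imperfect costal boundaries on the desk-scale phantom
leak into the swept-volume split, which is why the kinematics recovery tests
evaluate A1–A3 with the analytic labels.

The same steps are available from the shell:

```bash
lungmotion phantom   --out work/ --condition control --seed 0
lungmotion partition --mesh work/reference.stl --out work/labeled.ply
lungmotion features  --labels work/labeled.ply --field work/trajectories.npy \
                     --out work/features.csv
lungmotion unfold    --labels work/labeled.ply --field work/trajectories.npy \
                     --out work/map.csv
lungmotion evaluate  --features cohort.csv --out summary.csv
```

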