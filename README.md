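# myodyn

Dynamic muscle MRI analysis for electrically stimulated contraction:
strain-tensor mapping from phase-contrast velocity fields, sigmoid-derived
contraction dynamics, EPG dictionary water-T2 / fat-fraction relaxometry,
Dixon fat–water separation, and cohort-level biomarker statistics.

## The problem

Quantitative MRI biomarkers of neuromuscular disease have mostly targeted
*structure*: fat replacement (fat fraction, FF) and water distribution
(water T2, wT2). Muscles can, however, lose contractile *function* before
any structural change is visible. Dynamic MRI during neuromuscular
electrical stimulation (NMES) makes contraction itself measurable: a
periodic stimulus (750 ms contraction + 750 ms release) synchronizes a 3-D
phase-contrast acquisition that encodes tissue velocity (Venc 15 cm/s) in
the calf throughout the cycle.

`myodyn` implements the full analysis chain from those velocity fields to
per-muscle biomarkers and group statistics, together with synthetic
phantoms that provide analytic ground truth for every stage.

## The model

**Strain mapping.** Velocities v(x, t) are integrated into a displacement
field with a forward/backward temporal blend that pins u(0) = u(T) = 0 and
exactly cancels constant velocity offsets:

    u(t) = (1 − t/T)·∫₀ᵗ v dτ  +  (t/T)·(−∫ₜᵀ v dτ)

Spatial gradients ∇u come from a separable 3-D Savitzky–Golay derivative
filter (local least-squares polynomial fit; default window 5, order 2),
and the Green–Lagrange strain tensor is

    E = ½ (F^T F − I),   F = I + ∇u,

which is invariant under rigid rotation (the infinitesimal tensor
ε = ½(∇u + ∇uᵀ) is available for comparison). The largest positive
eigenvalue λ₁ of E — the maximal local lengthening — is averaged over each
muscle between the two NMES electrode centers, and the resulting time
curve is fitted per phase with a logistic

    s(t) = b + A / (1 + exp(∓k (t − t₀)))

whose steepness k is the **buildup rate** (rising phase) or **release
rate** (falling phase); the plateau b + A is the cycle's **strain**.

**Relaxometry.** wT2 and FF are fitted from a 17-echo multi-echo spin-echo
stack by matching each voxel against a dictionary of dual-compartment
(muscle water + fat) signals simulated with the extended phase graph (EPG)
formalism, which accounts for stimulated echoes from the flip-angle
distribution across the slice; fat T2 is calibrated per subject from
subcutaneous fat. An independent FF estimate comes from 6-echo Dixon
gradient-echo data via multi-peak fat–water least squares with a
region-growing fieldmap prior.

**Statistics.** Per muscle and variable, groups are summarized as
median (IQR) and compared by standardized logistic regression: group
(patient = 1) on the z-scored variable; exp(slope) is the odds ratio per
SD, with 95% profile-likelihood confidence intervals (an unbounded profile
endpoint under quasi-separation is reported as undefined). Dynamic and
structural biomarkers are related by Spearman correlation.

## Worked example

```python
import numpy as np
from myodyn import synthetic, strain, dynamics
from myodyn.io import RoiMask

# phantom calf, +20% stretch along x / −5% transverse at peak contraction
geom = synthetic.make_phantom_geometry((32, 32, 48), (2.3, 2.3, 2.5))
model = synthetic.DeformationModel(
    amplitude_tensor=np.diag([0.2, -0.05, -0.05]))
times = np.arange(32) * model.cycle_duration / 32
truth = synthetic.analytic_displacement(geom, model, times)
vel, _ = synthetic.velocities_from_displacement(
    truth.displacement, noise_sd=0.3, seed=0)   # cm/s noise

u = strain.integrate_velocity(vel)
grad = strain.spatial_gradient_sg(u, window=5, poly_order=2)
E = strain.strain_tensor(grad, convention="green_lagrange",
                         frame_times=u.frame_times)
P = strain.principal_strains(E)
curve = strain.roi_strain_curve(P, RoiMask(label_volume=geom.label_volume),
                                label=1,  # soleus
                                electrode_centers=geom.electrode_centers)
m = dynamics.dynamic_metrics(curve)
print(f"peak ROI-mean lambda1 : {curve.values.max():.3f}")
print(f"fitted strain (b + A) : {m.strain:.3f}")
print(f"buildup rate          : {m.buildup_rate_s:.1f} 1/s")
print(f"release rate          : {m.release_rate_s:.1f} 1/s")
```

prints

```
peak ROI-mean lambda1 : 0.171
fitted strain (b + A) : 0.174
buildup rate          : 12.9 1/s
release rate          : 13.8 1/s
```

The ROI mean (0.17) sits below the interior ground truth λ₁ = 0.22 because
the whole-muscle average includes the tapered displacement rim at the
muscle boundary; restricted to the untapered interior the pipeline
recovers 0.22 within ~1%. The fitted rates recover the generator's
steepness (15 s⁻¹) to within the distortion introduced by the rim and the
velocity noise.

The same chain is available from the shell:

```sh
myodyn simulate phantom --out phantom/ --seed 1
myodyn strain --vel-x phantom/vel_x.nii.gz --vel-y phantom/vel_y.nii.gz \
    --vel-z phantom/vel_z.nii.gz --sidecar phantom/vel.json \
    --mask phantom/mask.nii.gz --out strain_out/
myodyn fit-dynamics --curves strain_out/curves.csv --out metrics.csv
myodyn simulate cohort --out subjects.csv --seed 1
myodyn stats --table subjects.csv --out stats_out/
```

`myodyn stats` also reads externally deposited subject tables; map foreign
column names with a YAML config (`column_map:`).

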