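# spinepinn

Hybrid finite-element / physics-informed neural-network estimation of
lumbar-spine material properties, exercised end to end on synthetic
vertebra–disc phantoms.

## The problem

Patient-specific spine simulations need tissue material properties that
cannot be measured directly: the Young's modulus and Poisson's ratio of
vertebral bone and of the intervertebral discs (IVDs), plus the bulk and
shear moduli and densities they imply. This package implements the inverse
route: simulate axial compression of a lumbar segment with candidate
properties, record the mechanical response (reaction force, displacements,
stresses, strains), and train a network to invert response → properties,
with the physics of isotropic elasticity built into the training loss.
An iterative feedback loop between the forward simulation and the learned
inverse then calibrates the properties of a specimen from its observed
response.

It is aimed at computational-biomechanics researchers who want a
self-contained, fully synthetic testbed for this identification strategy —
no CT data, segmentation models, or commercial FE solvers required.

## The model

**Forward model.** A conforming linear-tetrahedron FE model of an L1–L5-like
stack: five vertebra regions and four disc regions sharing interface nodes
(tied contact), the bottom endplate fully constrained, a prescribed axial
displacement (0.2–2.8 mm) on the top endplate. Both tissues are linear
elastic isotropic; a one-term incompressible Ogden law is available at
constitutive level for disc nonlinearity studies, and Hounsfield-unit
helpers implement the empirical CT bands (cortical +700…+2000 HU,
cancellous +100…+300 HU) and the relations E(MPa) = a·HUᵇ,
ρ(kg/m³) = c + d·HU.

**Inverse model.** An MLP maps the 16 response features
(F_ext; u_x,u_y,u_z; σ_x,σ_y,σ_z,σ_xy,σ_yz,σ_xz; ε_x,…,ε_xz) to the 10
targets (E, ν, k, μ, ρ for bone and disc). The loss augments the data
misfit with soft isotropic-consistency penalties,

    L(θ) = (1/N) Σᵢ ‖N(xᵢ;θ) − yᵢ‖²
           + λ₁ · mean|k̂ − Ê/(3(1−2ν̂))| + λ₂ · mean|μ̂ − Ê/(2(1+ν̂))|,

evaluated per tissue on de-normalized (physical-unit) predictions.

**Calibration loop.** Writing f for the FE simulation and f⁻¹ for the
network, the loop is seeded by predicting from the observed response and
iterates re-simulation + damped residual correction; the error obeys
e_{n+1} = A e_n and converges while the spectral radius ρ(A) < 1, which the
package estimates empirically from successive step/error norms.

## Worked example

`examples/05_hybrid_calibration.py` runs the whole study at coarse mesh
resolution — build the phantom, generate a 406-row training table
(29 material draws × 14 load magnitudes), train the [64-32-16] network,
fine-tune it on an enlarged 672-row set, then calibrate against a synthetic
specimen with known ground truth:

```
network: test accuracy 96.06% -> 97.39% after fine-tuning on the enlarged set

loop: converged=True in 8 iterations, step contraction ~0.66
quantity            truth    recovered   rel err
E_bone           20.562 GPa     22.457 GPa     9.2%
E_disc            3.051 MPa      2.991 MPa     2.0%
nu_bone           0.121   -      0.206   -    70.9%
nu_disc           0.471   -      0.471   -     0.0%
```

The loop converged in 8 iterations with an empirical contraction factor of
~0.66 per step; both Young's moduli are recovered within 10% (bone Poisson's
ratio is the weakly identifiable quantity — this truth sits near the edge of
the sampled range). The other examples cover phantom generation and
endplate annotation (`01`), a single FE solve and its 16 features (`02`),
dataset construction (`03`), and the physics-penalty ablation (`04`).

The same stages are scriptable from a shell:

```bash
spinepinn phantom build --config cfg.yaml --out mesh.vtk
spinepinn dataset build --config cfg.yaml --mesh mesh.vtk --out data.csv
spinepinn pinn train --config cfg.yaml --data data.csv --out model.json
spinepinn calibrate run --mesh mesh.vtk --model model.json --out report.json
spinepinn all --config cfg.yaml        # full pipeline into a results bundle
```

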