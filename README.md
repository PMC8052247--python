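# rhinoflow

Virtual nasal-surgery planning from CT-like volumes: simulate inhalation
through a segmented airway with a lattice-Boltzmann solver, locate the flow
constrictions that cause obstructed breathing, and iteratively widen the
airway there until the obstruction criterion clears — reporting the tissue
**resection volume** a surgeon would have to remove to achieve the same
effect.

## Who this is for

Researchers in computational rhinology / upper-airway CFD who want an
automated, reproducible pipeline from a Hounsfield-unit volume to a
quantitative surgical plan, without meshing. Because clinical CT series are
rarely shareable, the package ships a phantom generator that produces
CT-like volumes (air ≈ −1000 HU in tissue ≈ +40 HU) with known channel
geometry, constrictions and septum-like deviations, so every stage is
testable end to end.

## Method

1. **Segmentation** — isotropic resampling, thresholding at −300 HU and
   26-connected region growing from a seed inside the airway. Two
   artificial boundary bodies are attached: a sphere over the nostrils
   (ambient-pressure inlet) and a cuboid at the nasopharynx (velocity
   outlet drawing the inhalation flow rate).
2. **Flow** — D3Q19 lattice-Boltzmann BGK solver with a Smagorinsky
   large-eddy closure (c_s = 0.14), halfway bounce-back walls, and
   physical↔lattice unit mapping chosen from a lattice-Mach cap and the
   stable relaxation-time range. Pressure in Pa is
   p = (ρ_lat − 1)·c_s,lat²·(Δx/Δt)²·ρ_air with c_s,lat² = 1/3.
3. **Streamline analysis** — seeds uniform in the inlet sphere, adaptive
   RK45 integration in arc-length parameterization, trilinear sampling of
   pressure. A **high-pressure-gradient region (HPGR)** is a streamline
   segment with dp/dl at or below a critical threshold; detections are
   deduplicated on a coarse voxel binning. The surgery criterion is
   **≥ 25 HPGRs at −1.1 Pa/mm**; the full sweep over [−5, 0] Pa/mm in 0.1
   steps is also computed.
4. **Virtual surgery** — each selected HPGR founds a 10 mm optimization
   cube and a growing region of interest (ROI, +0.468 mm per axis per
   iteration). Per iteration the airway wall inside each ROI moves outward
   by one voxel layer (Laplacian edge detection), the flow is re-solved
   (warm-started), HPGRs are re-detected, and the loop stops when fewer
   than 5 remain in all ROIs. The resection volume is the Boolean
   difference between the final and initial airway masks.
5. **Verification & outcome metrics** — Richardson extrapolation / grid
   convergence index (GCI) for mesh independence, surface-averaged
   pressures, the pressure-drop ratio
   ΔΠ = (Δp_pre − Δp_virtual)/(Δp_pre − Δp_post), cross-sectional area
   profiles A(d), and the area ratio ΔA = A_virtual/A_post.

## Worked example

Run the miniature constricted-phantom study (a 48 mm channel with a 50%
stenosis, 60 ml/s inhalation):

```python
from rhinoflow.config import tiny_phantom_config
from rhinoflow.pipeline import run_pipeline

summary = run_pipeline(tiny_phantom_config(), "runs/demo")
print(summary)
```

which prints (exactly, runs are bit-reproducible):

```
{'criterion_met': True, 'hpgr_count': 179, 'dp_pre_pa': -4.6991075113326755,
 'developed': True, 'resection_volume_mm3': 6481.0, 'iterations': 1,
 'converged': True, 'dp_virtual_pa': -0.6057003495804995}
```

Reading: the obstructed phantom shows 179 HPGR bins at −1.1 Pa/mm (≥ 25 →
surgery indicated) and a nostril-to-nasopharynx pressure drop of −4.7 Pa.
One optimization iteration widens the throat, removing 6481 mm³ of virtual
tissue, after which no HPGRs remain and the pressure drop falls to −0.6 Pa.
The run directory contains every artifact (masks and fields as NIfTI,
streamlines/HPGRs as CSV and legacy VTK, Δp trace, sweep curve, provenance
and a checksum manifest).

The same pipeline is scriptable from the shell:

```bash
rhinoflow pipeline --run-dir runs/demo          # shipped desk-scale config
rhinoflow select --run-dir runs/demo --indices 0,3,7
rhinoflow gci --f 100.1 100.4 101.6 --r 2
```

The `gci` command prints the three-grid convergence report
(`p_order 2.0, f0 100.0, mi 0.997` for this constructed second-order
series).

## Limitations

The phantom geometry is idealized (circular ducts, cosine stenoses); no
anatomical constraints (mucosa, septum integrity, surgical accessibility)
are modelled, and desk-scale runs use a reduced flow rate to stay in the
flow regime the coarse lattice resolves. See `docs/methods.md` for the
model details, parameter defaults and numerical choices.
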