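# retquant

Quantification pipeline for longitudinal retinal imaging and spatial-memory
studies in mice: optical coherence tomography (OCT) layer-thickness
zonation around the optic nerve head (ONH), SNR-gated OCT angiography
(OCTA) vessel density in the three retinal vascular plexuses, Morris water
maze (MWM) trajectory metrics, and the longitudinal and correlation
statistics that link retinal structure to spatial memory.

It is written for preclinical imaging groups who quantify murine retinal
phenotypes (e.g. in Alzheimer-model cohorts of transgenic animals and
littermate controls) and want every stage of that quantification to be
exercisable — and testable — on synthetic data with known ground truth.
The package therefore ships a first-class synthetic-data module: layered
retinal phantom volumes with repeated B-scans, a depolarizing RPE band,
vessels of known area density and radially varying SNR; swim trajectories
from a parameterised memory/thigmotaxis model; and longitudinal cohorts
with configurable group effects and a configurable correlation between
inner nuclear layer (INL) thickness and memory ability.

## What it computes

**Layer analysis.** Volumes are flattened with respect to the retinal
pigment epithelium (RPE), located through its depolarizing signature in
the auxiliary polarization channel. Seven boundary surfaces (ILM, the five
inner interfaces, posterior RPE) are segmented by a gradient band search;
en-face thickness maps are built for the six sublayers (RNFL/GCL, IPL,
INL, OPL, PRC, RPE), the inner and outer complexes (IRL = RNFL/GCL + IPL +
INL, ORL = OPL + PRC + RPE) and the total retina, and summarised in a
200–600 µm annulus around the ONH, split into four sectors by the field
diagonals.

**OCTA density.** Motion contrast between the five repeated B-scans is an
amplitude decorrelation `D = 1 − ⟨corr(A_i, A_{i+1})⟩` over adjacent
repeat pairs. The decorrelation volume is max-projected over the SVP, ICP
and DCP slabs; binarization combines a 10× noise-floor signal gate with
Frangi-vesselness-seeded reconstruction of the flow mask; a 10-pixel
border is zeroed and a disc around the ONH is cut out. The field is split
into quadrants × 100 µm rings, zones whose SNR falls below the plexus gate
(20× for SVP/ICP, 15× for DCP) are excluded, and the area density is
`100 · positives / (positives + negatives)` over the included zones.

**MWM metrics.** Latency to the platform, distance traversed, floating and
thigmotaxis fractions on training days; quadrant abidance and target-zone
crossings on the probe day.

**Statistics.** Mixed-intercepts (random intercept per animal) models of
any retinal parameter against group × week with estimated-marginal-means
contrasts (no multiplicity correction, mirroring an exploratory design);
unpaired t-tests, chance-level tests (25 % abidance, 1.5 crossings) and
Cohen's *d* for the probe day; Pearson correlation with R² = r², MSE and
the analytic power of the correlation test via the Fisher *z*
approximation, `power = Φ(atanh ρ √(n−3) − z₁₋α/₂) + Φ(−atanh ρ √(n−3) −
z₁₋α/₂)`; and the retina–behaviour correlation orchestration (eyes
averaged per mouse, six group splits).

## Worked example

```python
from retquant import synthetic_data as syn, layer_analysis as la, octa_density as od
from retquant import stats_pipeline as sp

cfg = syn.PhantomConfig(n_fast=256, n_slow=200, n_depth=224, seed=1, snr_falloff=0.0)
vol, truth = syn.generate_phantom(cfg)

flat = la.flatten_volume(vol)
surfaces = la.segment_layers(flat.volume, onh_center_um=truth.onh_center_um)
maps = la.thickness_maps(surfaces)
total = la.annulus_sector_average(maps["TOTAL"])
print(f"total retinal thickness (200-600 um annulus): {total.overall_mean_um:.1f} um")
for sector, mean in total.sector_mean_um.items():
    print(f"  {sector:<9s} {mean:.1f} um")

decorr = od.compute_octa(flat.volume)
densities = od.vessel_density_pipeline(decorr, flat.volume, surfaces,
                                       onh_center_um=truth.onh_center_um)
for plexus, res in densities.items():
    print(f"{plexus} vessel density: {res.density_pct:.1f}% "
          f"(ground truth {truth.vessel_density[plexus] * 100:.1f}%)")

print(f"power of r-test at rho=0.87, n=8: {sp.pearson_power(0.87, 8, 0.05):.2f}")
```

prints

```
total retinal thickness (200-600 um annulus): 222.7 um
  superior  221.8 um
  nasal     223.1 um
  inferior  222.6 um
  temporal  223.2 um
SVP vessel density: 20.6% (ground truth 20.0%)
ICP vessel density: 9.0% (ground truth 9.0%)
DCP vessel density: 11.0% (ground truth 12.0%)
power of r-test at rho=0.87, n=8: 0.85
```

The phantom was generated with a total retinal thickness of ~223 µm and
plexus densities of 20 / 9 / 12 %; the pipeline recovers the thickness to
within one axial pixel (1.5 µm) and each density to within two percentage
points. The 0.85 is the analytic power of a two-sided Pearson test for a
true correlation of 0.87 observed in eight animals.

A command-line interface mirrors the library:

```bash
retquant simulate phantom --seed 7 --out phantom_dir
retquant layers --in phantom_dir/phantom.h5 --onh-x 500 --onh-y 500 --out layers_dir
retquant octa   --in phantom_dir/phantom.h5 --onh-x 500 --onh-y 500 --out octa_dir
retquant simulate mwm --seed 7 --out swims
retquant mwm --traj-dir swims --pool swims/pool.yaml --out metrics.csv
```

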