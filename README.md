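# doct — dynamic OCT analysis of tumor spheroids

`doct` is a Python implementation of the 3D dynamic optical coherence
tomography (D-OCT) analysis used for label-free drug-response assessment of
in-vitro tumor spheroids. Standard OCT resolves a spheroid's structure but
not whether its cells are alive; D-OCT adds that contrast by scanning each
B-scan location repeatedly and analyzing the temporal fluctuations of the
speckle signal, which sub-resolution intracellular motion decorrelates.
The package is aimed at researchers building or validating D-OCT processing
chains: it covers the scan-timing model, the per-voxel dynamics metrics,
pseudo-color image composition, spheroid segmentation with volumetric
read-outs, group statistics — and a synthetic dynamic-speckle phantom that
provides ground truth for end-to-end validation, since no public instrument
data accompanies the method.

## The metrics

For each voxel, N repeated frames of dB-scaled intensity
I_dB(x,z,t_i) are acquired at intervals Δt (N = 32, Δt = 204.8 ms in the
standard protocol). Two complementary quantities are computed:

**LIV** (logarithmic intensity variance, dB²) — the magnitude of the
fluctuations:

    LIV(x,z) = (1/N) Σ_{i=0}^{N-1} [ I_dB(x,z,t_i) − ⟨I_dB(x,z)⟩_t ]²

**OCDS** (OCT correlation decay speed, ms⁻¹) — the speed of the
fluctuations: the temporal autocorrelation ρ_A(τ_i; x, z) of the dB
intensity is estimated at integer-lag delays τ_i = iΔt (Pearson correlation
of the overlapping subsequences), and OCDS is the negated slope of an
ordinary-least-squares line fitted over a delay window — [204.8, 1228.8] ms
for the late variant OCDS_l, [12.8, 64] ms (high-density single-location
protocol, N = 350, Δt = 12.8 ms) for the early variant OCDS_e.

Low LIV and low OCDS_l mark the necrotic core of a spheroid; the necrotic
cell ratio is the fraction of segmented spheroid voxels whose metric falls
below a cutoff (3 dB² for LIV, 2 × 10⁻⁴ ms⁻¹ for OCDS_l).

## Worked example

Simulate a control spheroid phantom (low-dynamics necrotic core, 22% of the
spheroid volume, inside a high-dynamics viable rim, above a bright
well-plate slab), run the full pipeline, and quantify it:

```python
import doct

spec = doct.scenario_library("mcf7_control", seed=7)
volume, labels = doct.generate_phantom(spec)        # linear intensity (y, t, z, x)
maps = doct.compute_dynamics_volume(doct.to_db(volume))
mask = doct.segment_spheroid(
    maps.mean_intensity_db, threshold_db=-10.0,
    voxel_volume_mm3=spec.protocol.voxel_volume_mm3,
)
print(doct.quantify_spheroid(mask, maps).as_dict())
```

prints

```
{'volume_mm3': 0.092096, 'mean_liv_db2': 20.11, 'mean_ocdsl_ms_inv': 0.000382,
 'necrotic_ratio_liv': 0.209, 'necrotic_ratio_ocdsl': 0.310}
```

The segmented volume (0.092 mm³, 11512 voxels) matches the constructed
spheroid exactly, and the LIV-based necrotic cell ratio (0.209) recovers the
ground-truth core fraction of the phantom (0.221): core voxels fluctuate
weakly (LIV ≈ 2 dB², below the 3 dB² cutoff) while rim voxels are nearly
fully developed dynamic speckle (LIV ≈ 25 dB²).

The same chain is available from the shell:

```sh
doct simulate --scenario mcf7_control --seed 7 --out phantom.h5
doct info phantom.h5                      # timing summary of the protocol
doct compute phantom.h5 --metrics liv,ocdsl --out maps.h5
doct render maps.h5 --metric liv --plane en_face --index mid --out liv.png
doct quantify maps.h5 --threshold-db -10
```

The rendered PNG uses the HSV composition of the method: hue = metric
(red = low, green = high), value = mean OCT intensity, saturation = 1.

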