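# swmpam

Spatial-weight-matrix (SWM) reconstruction for MEMS-scanned
optical-resolution photoacoustic microscopy (OR-PAM).

## The problem

OR-PAM builds volumetric images from laser-induced ultrasound: a MEMS
mirror raster-scans a focused spot and a single unfocused sensor records
one time-resolved A-line per position. Two system effects degrade the
stacked volume:

* the nonlinear tilt-angle-versus-voltage response of the MEMS mirror
  (worst near the turning points of each B-scan) warps the lateral grid, so
  maximum-amplitude-projection (MAP) images are geometrically distorted;
* the Airy-disk spot (12.5 um) is larger than the scan step (4 x 6 um) and
  the large, close sensor integrates overlapping wavefronts, blurring the
  volume laterally and axially.

Both effects are properties of the *system*, not the sample. This package
implements the three-layer stored operator that inverts them for a fixed
configuration, following the forward model

```
I' = (((I + N1) (*) K_laser) . M_map + N2)        (acquisition)
I^ = (((I' + N) (*) K_denoise) . M_map^-1) (/) K_laser   (reconstruction)
```

where `M_map` is the location-mapping matrix (the integral of the mirror
velocity), `K_laser` the spot point-spread kernel, and `N1`, `N2` the
source- and sensor-side noise. The three layers are:

1. **Denoise** — per-A-line baseline-offset correction
   (`offset = mean(A[n_st..n_nd])`) followed by a 3x3 locally adaptive
   Wiener filter driven by a local PSNR estimate.
2. **Registration** — a grid resolution chart turns distortion correction
   into knowledge-based registration: an ordinal-valued Markov random field
   labels the chart foreground, Harris-Stephens corners (with adaptive
   non-maximal suppression and Sobel two-direction verification) are
   matched to the reference chart, and a polynomial/projective/local
   weighted-mean transform `M_map^-1` is fitted and accepted once the
   normalized mutual information (NMI) of the warped chart exceeds
   `epsilon = 0.48`.
3. **3-D deconvolution** — a modified delay-and-sum over a fixed
   deconvolution region (enlarged Airy-disk top face, 1.05 mm height):
   `p0(r) = sum_{m in Phi} W_m |dp/dd| cos(theta_m) / d_m`, with `Phi` the
   iso-time wavefront set and `W_m` weights proportional to the average
   signal in the region; a 3x3 guided filter (guide = the
   pre-deconvolution image) restores the edges.

Quality is quantified by joint-histogram mutual information / NMI
(`I(A,B) = H(A) + H(B) - H(A;B)`, NMI = `I / sqrt(H(A) H(B))`) and PSNR.

Because no public MOR-PAM acquisitions exist, the package ships a
first-class forward simulator (grid/ring charts, vessel phantoms, nonlinear
scan maps, PSF blur, noise, baseline drift) and validates the
reconstruction end-to-end against known ground truth.

## Worked example

```
$ swmpam swm demo --seed 42
{
  "n_pairs": 100,
  "chart_nmi_initial": 0.2454,
  "chart_nmi_final": 0.7381,
  "chart_nmi_ratio": 3.008,
  "interior_displacement_error_px": 0.2598,
  "nmi_map_raw": 0.0774,
  "nmi_map_reconstructed": 0.3247,
  "psnr_registered_db": 28.28,
  "psnr_reconstructed_db": 34.17,
  "psnr_gain_percent": 20.8
}
```

(Values abridged; the command prints the full JSON.) The demo simulates a
200 x 200 x 48 chart acquisition and a vessel-phantom acquisition through
the same electrothermal scan distortion (nonlinearity 0.3), builds the SWM
from the chart and applies it to the phantom. Reading the numbers: 100
chart corner pairs were matched automatically; registering the chart raised
its binary-histogram NMI from 0.245 to 0.738 (3.0x, above the 0.48
acceptance threshold); the fitted transform deviates from the true inverse
scan map by 0.26 px on average over the interior; reconstruction raised the
MAP-image NMI against ground truth from 0.077 to 0.325 and the
deconvolution layer added 5.9 dB PSNR (+21 %) over registration alone.

The same pieces are available as a library:

```python
import numpy as np
from swmpam import (ScanGeometry, NoiseModel, make_grid_chart,
                    make_laser_kernel, make_vessel_phantom, mems_distortion,
                    simulate_acquisition, build_swm, apply_swm)

geom = ScanGeometry(scan_area_mm=(0.8, 1.2))          # 200 x 200 at 4/6 um
kernel = make_laser_kernel(airy_um=12.5)
dist = mems_distortion(200, nonlinearity=0.3, kind="electrothermal")
chart = make_grid_chart(200, 200, pitch_px=20, line_width_px=2)

chart_truth = np.zeros((200, 200, 48))
chart_truth[:, :, 24] = chart.pixels.T
chart_acq = simulate_acquisition(chart_truth, kernel, dist,
                                 NoiseModel(sigma2=0.01, seed=0), geom)
swm, diag = build_swm(chart_acq, chart, geom)          # layers 1-3

vol = simulate_acquisition(make_vessel_phantom(200, seed=1), kernel, dist,
                           NoiseModel(sigma2=0.01, seed=2), geom)
recon = apply_swm(vol, swm)                            # baseline -> Wiener
                                                       # -> warp -> DAS -> guided
```

CLI subcommands mirror the layers: `simulate`, `preproc`, `features`,
`register`, `deconv`, `metrics`, and `swm build/apply/demo`. Geometry files
are YAML with the defaults

```yaml
step_fast_um: 4.0        # MEMS step sizes
step_slow_um: 6.0
scan_area_mm: [1.20, 0.80]
sensor_radius_mm: 3.50
sensor_distance_mm: 8.80
sound_speed_m_s: 1540.0
sample_rate_hz: 5.0e7
pulse_rate_hz: 1.0e4
```

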