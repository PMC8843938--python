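# meercbct

Multi-energy element-resolved cone-beam CT (CBCT): simulation and joint
reconstruction of kVp-switching scans for low-concentration iodine
contrast imaging.

Iodine contrast is hard to see in conventional CBCT used for radiotherapy
image guidance. One route to better detectability is spectral imaging on an
unmodified scanner: cycle the tube voltage view-by-view through 80/100/120
kVp in a single rotation, and reconstruct all channels *jointly* with a
physics model that ties the per-kVp attenuation images to the electron
density and elemental composition (H, O, iodine) of each voxel. This
package implements that framework end to end for digital-phantom studies:

* fan-beam scan geometry, exact Siddon projector, equiangular fan-beam FBP;
* filtered x-ray spectra, embedded elemental attenuation tables, the
  empirical per-channel attenuation model and its scanner calibration;
* an elemental-composition dictionary of soft tissues plus pure iodine;
* a nine-insert iodine phantom and a polyenergetic, Poisson-noise,
  water-precorrected kVp-switching scan simulator;
* the convex joint reconstruction model and its nested-ADMM solver, the
  single-energy (beta = 0) iterative baseline, and recovery of the electron
  density, composition, and iodine-concentration maps;
* ROI metrics (contrast enhancement, CNR, concentration error), a
  parameter-sensitivity sweep, an end-to-end study driver, and a CLI.

## The model

With `F = [f_1 .. f_N]` the per-channel attenuation images, `B` the
kVp-tagged projection data, `P` the (per-channel) projection matrix, `W` a
tight frame (`W^T W = I`), `Lambda` the dictionary's elemental rows and
`A = Lambda K + K_EC` its calibrated spectral responses, the reconstruction
solves the convex problem

    min_{F, X >= 0}  1/2 ||P F - B||_F^2 + beta/2 ||F - X A||_F^2
                     + alpha1 sum_i ||W f_i||_1 + alpha2 sum_j ||x_j||_1

by nested ADMM, then recovers the relative electron density
`rho = diag(X 1)`, dictionary weights `V = rho^-1 X`, composition
`lambda = V Lambda`, and the iodine density map in mg/ml. Defaults follow
the tuned operating point `beta = 50`, `alpha1 = 1.0`, `alpha2 = 0.001`
with 40 outer iterations. See `docs/methods.md` for the science,
numerical choices, and limitations.

## Worked example

```python
import numpy as np
from meercbct import *
from meercbct.simulate import AcquisitionProtocol
from meercbct.metrics import default_rois, concentration_error

geom = ScanGeometry(n_views=600, image_shape=(256, 256), pixel_size=0.1)  # cm
phantom = build_insert_phantom(geom)          # 20 cm water cylinder, 9 inserts
protocol = AcquisitionProtocol(rng_seed=1)    # 80/100/120 kVp, 1.4/0.8/0.5 mAs
spectra = protocol.spectra()
cal = calibrate_from_spectra(spectra)

sino = simulate_kvp_switching_scan(phantom, protocol, geom, spectra=spectra)
dictionary = build_dictionary()
km = compute_K_matrices(dictionary, cal.params)
result = meer_reconstruct(sino, dictionary, km)

maps = recover_decomposition(result.X, dictionary)
iodine = maps.iodine_mg_per_ml.reshape(phantom.shape)
rois = default_rois(phantom)
errs, mean_err, _ = concentration_error(
    iodine, phantom.insert_iodine_mg_per_ml(), rois
)
print(f"mean relative iodine-concentration error: {100 * mean_err:.1f}%")
print("per-insert estimates (mg/ml):",
      np.round([iodine[rois.insert_mask(i, phantom.shape)].mean()
                for i in range(8)], 2))
```

Output (seed 1):

```
mean relative iodine-concentration error: 20.0%
per-insert estimates (mg/ml): [ 0.1   1.42  1.95  3.01  3.97  5.71  9.01 17.96]
```

against ground truth `[0.175, 0.875, 1.75, 2.625, 3.5, 5.25, 8.75, 17.5]`
mg/ml - within ~3-15% from 1% stock dilution upward, with the
characteristic deviation at the lowest concentrations where the spectral
noise floor and the dictionary's trace-iodine ambiguity dominate.

The same study from the shell:

```bash
meercbct reproduce-sim-study --seed 1 --outdir out/   # scans, recons, metrics.csv
meercbct sweep --parameter alpha2 --values 1e-4,1e-3,1e-2 --outdir out/
```

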