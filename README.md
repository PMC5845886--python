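# viscade

Filter-cascade models of early visual processing, in pure scientific
Python.  The package simulates retinal ganglion cells, direction-selective
units and V1-like cells as cascades of 3D spatio-temporal linear filters,
recursive (IIR) filters, static nonlinearities, contrast gain control and
leaky integrate-and-fire spike generation — and fits any trainable
parameter (or a stimulus parameter) to data with gradient-based
optimization.

## Layout

| module               | contents |
|----------------------|----------|
| `viscade.signals`    | `VideoTensor` (axes `batch, channel, time, x, y`), the `Layer`/`Parameter`/state contract, chunked streaming (`run_chunked`), `resample` |
| `viscade.filters`    | dense `Conv3D`, recursive `TemporalIIR` / `ExponentialSmooth` / `RecursiveGaussian2D` (4th-order Deriche), the `SoftConvBank` hybrid, pointwise nonlinearities |
| `viscade.retina`     | OPL center–surround stage, bipolar shunting gain control, ganglion static nonlinearity, LIF spiking; VirtualRetina-dialect XML / JSON configuration |
| `viscade.cascade`    | LN / LNSN / LNSNF / LNFSNF / LNFDSNF cascades, direction-selective kernels and tuning curves, JSON cascade specs |
| `viscade.stimuli`    | seeded generators: chirp, moving gratings, checkerboard flicker, moving bars, Gaussian noise, Poisson event trains, the letter-raster receptive field |
| `viscade.fitting`    | MSE loss, analytic parameter gradients + finite-difference oracle, optimizers (SGD / momentum / Adam / L-BFGS), error-curve scans, pairwise Hessians, stimulus optimization, fraction of variance explained |
| `viscade.io` / `viscade.cli` | npy / HDF5 / image-sequence I/O, CSV spike lists, the `viscade` command |

Gradients are analytic (reverse mode for convolutions and pointwise maps,
exact forward sensitivities for recursive filters and the gain-control
integrator) and are checked against central finite differences throughout
the test suite; no autodiff framework is required.

## CLI

```sh
# generate a drifting grating
viscade stimulus grating --shape 20 20 --dt 0.001 --frames 500 \
    --direction 0 --speed 10 --sf 0.1 --contrast 0.5 --out g.npy

# run the retina cascade (XML or JSON config), chunked, seeded
viscade run --config retina.xml --input g.npy --output out.h5 --chunk 100 --seed 0

# fit a cascade model to input/target pairs
viscade fit --model cascade.json --input x.npy --target y.npy \
    --method quasi_newton_limited_memory --steps 3 --out fit.h5

# direction-tuning curve of a DS kernel
viscade tuning --direction 45 --n-directions 16 --out tuning.csv

# per-stage fraction of variance explained between two configs
viscade compare --config-a a.xml --config-b b.xml --input g.npy
```

Exit codes: 0 success, 1 runtime error, 2 usage error.

## Configuration

Retina models are configured from a VirtualRetina-dialect XML subset; the
attribute-to-field mapping ships as data in
`src/viscade/data/vr_attribute_map.json` (unrecognized attributes warn and
are ignored; radially-varying-blur attributes are explicitly unsupported).
An equivalent nested-JSON config is accepted via `viscade.retina.load_retina_json`.
Default parameter magnitudes are chosen to keep the bipolar potential
within roughly [-1, 1] for unit-contrast stimuli at low temporal frequency
(`lambda_opl = 10`, `g_leak = 10`); see the dataclass defaults in
`viscade.retina` for the documented reference values.
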