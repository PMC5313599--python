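# localroi

Interior-tomography reconstruction with a known subregion: correct the
cupping artifact of a padded-FBP local reconstruction by fitting the
low-frequency reconstruction error in a coarse multi-resolution Gaussian
blob basis.

## The problem

In local (interior) tomography the detector covers only a region of interest
(ROI) inside a larger object, so every parallel-beam projection is truncated.
The interior problem is not uniquely solvable from the truncated data alone:
reconstructions obtained by extrapolating each sinogram row with its edge
values and applying filtered backprojection ("padded FBP") recover mid and
high frequencies well, but carry a smooth low-frequency radial bias — the
*cupping* artifact.  If the attenuation values are known a priori on some
subregion Ω of the ROI (for instance an air pocket), the interior problem
becomes solvable, and the bias can be removed.

## The method

Let `x0` be the padded-FBP reconstruction of the ROI (N² pixels), zero-
extended to `x̃0` on a larger support (N2² pixels, N2 > N), `P̃` the
parallel-beam projector on that support and `C` the crop to the N measured
detector columns.  The correction term is expanded in truncated Gaussian
blobs `G c` — per-band lattices with spacing `s = 0.65 σ`, the standard
deviation doubling from the ROI disk outwards — and the coefficients solve
the quadratic problem

```
min_c  ‖ C P̃ G c − f ‖²  +  β ‖ (G c)|_Ω − (u0 − x0|_Ω) ‖² ,    f = d − P x0
```

by conjugate gradient on the normal equations.  Because the blobs are
isolated points convolved with a Gaussian, `C P̃ G` is applied as a sparse
CSR *point-projector* (one look-up-table entry per blob and angle) followed
by 1-D Gaussian convolutions of the sinogram rows; its adjoint is the exact
transpose (CSC triple, same kernels).  The corrected reconstruction is
`x = C̃(x̃0 + G ĉ)`.  With a few hundred coefficients instead of N2² pixel
unknowns, 200 CG iterations suffice where exact pixel-domain solvers need
thousands.

## Worked example

```sh
localroi simulate --size 512 --roi 272 --angles 800 --out setup.h5
localroi reconstruct --setup setup.h5 --sigma0 18.7 --iters 200 --out recon.h5
```

which prints (the σ0 here yields N_g = 736 basis functions):

```
PSNR padded FBP: 16.28 dB
PSNR corrected:  35.05 dB
N_g=736, iterations=200 -> recon.h5
```

The first number is the quality of the padded-FBP reconstruction over the
ROI disk (peak = maximum of the ground truth on the disk); the cupping bias
dominates its error.  The corrected reconstruction removes the bias — an
18.8 dB improvement — while the known-zone constraint pins the mean value
inside Ω (residual bias below 0.1 % of the FBP bias there).

`localroi benchmark --table rows.json --out report.json --plot-dir plots/`
runs a list of such configurations (tuning σ0 by bisection to hit a target
basis size) and writes machine-readable results plus line-profile plots.

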