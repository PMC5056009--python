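# sparsesense

Sparsity-regularised parallel-MRI (SparseSENSE) reconstruction with
accelerated forward-backward operator-splitting solvers, plus a synthetic
multi-coil acquisition simulator so the whole stack runs at desk scale with
no scanner data.

## The problem

Partially parallel imaging accelerates MRI by undersampling k-space and
using the spatial sensitivity profiles of a receiver-coil array to undo the
resulting aliasing; compressed sensing adds a sparsity prior so the
acceleration can exceed what the coil count alone supports.  Combining the
two gives the SparseSENSE model

```
min_x  ||D x||_1  +  (λ/2) ||A x − y||_2²,        x ∈ ℂⁿ
```

where `y` is the measured multi-coil k-space, `A = [F_p S_1; …; F_p S_k]`
is the SENSE encoding operator (pointwise coil sensitivities `S_j` followed
by the partial Fourier transform `F_p`), and `D` is a sparsifying transform
— here isotropic total variation (TV) or a special second-order total
generalized variation (TGV²) built from second differences.  `||Dx||_1` is
the isotropic group ℓ1 norm and λ weights data consistency.

## The solvers

Both terms are handled by operator splitting with Barzilai-Borwein (BB)
stepsizes `δ = ||A Δx||² / ||Δx||²`, so no linear system involving
`AᴴA` or `DᵀD` is ever inverted and `D` may be completely general:

* **FBOSS** — forward-backward operator splitting shrinkage: a gradient
  step on the data term, a groupwise soft-thresholding (the prox of the
  group ℓ1 norm), and a dual update.
* **FBOSP** — the same scheme with the dual step written as a groupwise
  projection onto the unit ball — the prox of the conjugate norm.  By the
  Moreau decomposition `v = prox_γφ(v) + γ prox_{φ*/γ}(v/γ)` the two
  produce identical iterate sequences.
* **BOS** — Bregman operator splitting baseline; its x-update solves
  `(ρ DᵀD + λδ I) x = rhs` by FFT and therefore requires periodic-TV.
* **AM** — alternating-minimisation baseline with its published stepsize
  schedules `τ_k = 0.2 + 0.08k`, `θ_k = (0.5 − 5/(15+k))/τ_k`.

All iterations stop when the relative change `||x^k − x^{k−1}|| / ||x^k||`
falls below ε (default 5·10⁻⁵).

## Worked example

```python
import sparsesense as ss

# synthetic study: 128x128 Shepp-Logan at 8-bit amplitude, 8 normalised
# coils, 4-fold variable-density undersampling, 30 dB k-space SNR
ds = ss.make_dataset(ny=128, nx=128, ncoils=8, factor=4, snr_db=30.0, seed=0)

model = ss.SparseSenseModel.from_dataset(ds, lam=1e3, reg="tv")
res = model.fit(method="fboss", gamma=1.0, eps=5e-5, max_iter=500)
print(res.summary())
```

prints

```
SparseSENSE reconstruction results
============================================
method                fboss
grid                  128 x 128
coils                 8
regulariser           tv (periodic)
lam                   1000
gamma                 1
iterations            84
converged             True
final objective       1.39753e+07
final rel. change     4.736e-05
elapsed seconds       2.815
relative error        1.3409e-01
PSNR (dB)             -73.31
============================================
```

The solver terminates after 84 iterations; the relative error of 0.134
against the sum-of-squares reference reflects the 30 dB noise passing
through the weakly regularised inversion (noiseless data reconstruct to
relative error 8·10⁻⁴ with the same settings; at 40–50 dB the error drops
to 0.03–0.05).  The PSNR row uses the package's default formula
`20·log10(255/||x−x*||²)`, which is large and negative for big error
norms; pass `formula="standard"` to `sparsesense.psnr` for the
conventional RMSE-based value (≈ 29.5 dB here).

The same model can be fitted with `method="fbosp"` (identical results),
`"bos"` or `"am"` for baselines, or with `reg="tgv2"` for second-order
regularisation.  A `click` CLI wraps the library:

```
sparsesense simulate --config sim.yaml -o data.h5
sparsesense recon    --config run.yaml -i data.h5 -o outdir
sparsesense compare  -i data.h5 --algos fboss,fbosp,bos,am -o outdir
```

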