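# diracfit

Off-the-grid sparse spike reconstruction for fluorescence microscopy and
related Poisson inverse problems.

Point sources (single fluorescent molecules, beads, vesicle exit sites) are
modelled as a discrete measure μ = Σᵢ aᵢ δ_{xᵢ} with **continuous**
positions — no reconstruction grid — observed through a Gaussian point
spread function Φ with background b under photon-counting (Poisson) noise.
`diracfit` recovers positions and amplitudes by solving the variational
problem over measures

    min_μ  f(Φμ) + λ |μ|(Ω)   (+ non-negativity),

where |μ|(Ω) = Σ|aᵢ| is the total-variation norm (the continuous analogue
of the ℓ¹ penalty) and the data term f is either the Kullback–Leibler
divergence D_KL(Φμ + b, y) matched to Poisson statistics, or the classical
½‖Φμ + b − y‖² of the Gaussian-noise BLASSO, kept as a built-in baseline.

The solver is the Sliding Frank–Wolfe algorithm: one spike is inserted per
iteration at the maximiser of the dual certificate η = −Φ*∇f(Φμ)/λ, the
amplitudes are re-estimated under the ℓ¹ penalty, and a sliding step
jointly refines amplitudes and positions off the grid.  The regularisation
parameter is chosen automatically by an algorithmic homotopy: starting from
λ₁ = γ‖η(1, μ₀)‖∞, λ is decreased by λ_{t+1} = λ_t‖η(λ_t, μ̂_t)‖∞/(1+c)
until the data residual falls below a noise-calibrated target σ_target,
which can be estimated blindly from a pure-background region of the image.
Ground-truth generators, Poisson/Gaussian acquisition simulators and
spike-space metrics (tolerance-radius Jaccard index, position/amplitude
RMSE) reproduce the standard 1D/2D/3D simulation protocols.

See `docs/methods.md` for the full model, solver and parameter account.

## Worked example

Simulate a 1D phantom (6 spikes on [0,1], Gaussian PSF σ = 0.07, background
0.01, Poisson noise), reconstruct it with the Poisson model and automatic
λ selection, and score the result:

```
$ diracfit simulate --scenario sim1d --seed 5 --out-dir run
wrote 6-spike phantom and (64,) acquisition to run

$ diracfit solve --input run/acquisition.tif --model kl --psf-sigma 0.07 \
    --background 0.01 --sigma-target 0.05 --out-dir run/rec
recovered 5 spikes -> run/rec/spikes.csv

$ diracfit evaluate run/ground_truth.csv run/rec/spikes.csv --delta 0.05
 tp  fp  fn  jaccard   rmse_x   rmse_a  delta
  5   0   1 0.833333 0.006205 0.416734   0.05
```

Five of the six spikes are matched within the 0.05 tolerance radius
(Jaccard 0.83) with a mean localisation error of 0.006 — well below the
pixel size of 1/64 — and no false positives.  The missed spike sits closer
than the tolerance radius to a brighter neighbour, the classic
resolution-limit failure mode, which also inflates the amplitude RMSE
(the pair's mass is absorbed by one recovered spike).  The same library
API is available in Python
(`diracfit.homotopy_solve`, `diracfit.sfw_solve`, …), and
`diracfit benchmark` runs the replicated two-model comparison.

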