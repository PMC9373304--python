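# bleachdmd

Dynamic mode decomposition (DMD) of photobleaching kinetics in
fluorescence time-lapse microscopy.

## The problem

Under continuous illumination every fluorophore bleaches, and different
species bleach at different rates. A *bleach stack* — a movie acquired
at constant frame interval Δt — therefore carries kinetic information
that single frames do not: two regions with identical intensity but
different bleach rates are inseparable by any intensity threshold, yet
trivially separable by their decay. This matters in practice when a
probe's emission overlaps cellular autofluorescence, or when two
probes share a spectral band. `bleachdmd` is for microscopists and
image analysts who want to segment images by bleaching kinetics,
denoise bleach stacks, or unmix spectrally indistinguishable
fluorophores — without fitting a parametric decay model to every
pixel, although a pixel-wise fitter is included as the classical
comparator.

## The method

Each frame is flattened row-major into a column vector; the columns
form the space–time matrix **X** ∈ ℝ^(n×m) (n pixels, m frames). DMD
finds the best-fit linear transfer operator *A* between consecutive
snapshots, x_{k+1} = A x_k, via the truncated SVD of the time-shifted
matrix X₁ = UΣV*:

    A′ = U′* X₂ V′ Σ′⁻¹,   A′W = WΛ,   Φ = X₂ V′ Σ′⁻¹ W

The columns φ_j of Φ are the *dynamic modes* (spatial weight maps), the
eigenvalues λ_j their discrete-time dynamics, and ω_j = log(λ_j)/Δt the
continuous rates: Re ω_j is a bleach rate, Im ω_j an oscillation
frequency (e.g. specimen drift). The stack is reconstructed as

    x_k = Σ_j φ_j λ_j^(k−1) b_j

with amplitudes b solving Φb = x₁ in least squares. The truncation
rank is chosen by the median-based optimal singular-value hard
threshold, or fixed by the user. Thresholding a decaying mode's weight
map (Otsu, Isodata, Li, Yen, Mean, Minimum, Triangle or multi-Otsu, via
scikit-image) segments the pixels that follow that mode's kinetics;
restricting the reconstruction to a subset of modes isolates one
fluorophore species. The comparator fits
I(t) = A·exp(−(t/τ)^h) + C per pixel (h ≡ 1 for mono-exponential).

## Worked example

```python
from bleachdmd import SimConfig, simulate_stack, fit_dmd, evaluate_modes

stack, truth = simulate_stack(SimConfig(seed=0))   # 160x120, 100 frames
model = fit_dmd(stack)                             # rank chosen automatically
print(model.rank, model.omegas.real.round(4))
```

prints

```
3 [-0.01   -0.053  -0.1568]
```

— the stack contains three kinetic components (rank 3) bleaching at
0.010, 0.053 and 0.157 s⁻¹, matching the simulated rate constants
0.01 / 0.05 / 0.15 s⁻¹ of the rectangle, circle and ellipse (the two
faster rates are slightly biased because DMD describes every pixel as a
sum of all three modes rather than fitting each region separately).
Continuing,

```python
table = evaluate_modes(model, truth.masks, methods=("minimum", "otsu"))
print(table[table.method == "minimum"][["region", "jaccard", "dice"]].round(3))
```

```
      region  jaccard  dice
0  rectangle      1.0   1.0
2     circle      1.0   1.0
4    ellipse      1.0   1.0
```

Minimum-thresholding each mode-weight map segments its region pixel-
perfectly (Jaccard = Dice = 1.000) even though all three regions start
at the same intensity. The scripts in `examples/` walk through
simulation and decomposition, kinetic segmentation, pixel-wise rate
fitting, and two-fluorophore unmixing, each printing the numbers it
computes.

A thin CLI wraps the same functions:

```bash
bleachdmd simulate --seed 0 --out stack.tif
bleachdmd decompose stack.tif --dt 1.0 --rank auto --out model/
bleachdmd run --out results/ --seed 0
```

## Layout

- `src/bleachdmd/simulate.py` — seeded synthetic bleach stacks with ground truth
- `src/bleachdmd/dmd.py` — exact DMD, rank selection, continuous eigenvalues
- `src/bleachdmd/modes.py` — reconstruction, mode maps, grouping, overlays
- `src/bleachdmd/segmentation.py` — histogram thresholding, Jaccard/Dice
- `src/bleachdmd/pixelfit.py` — per-pixel mono/stretched exponential fitting
- `src/bleachdmd/io.py`, `pipeline.py`, `cli.py` — TIFF I/O, orchestration, CLI
- `docs/methods.md` — models, assumptions, numerical choices, limitations
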