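# printfid

Print-fidelity toolkit for extrusion bioprinting of shear-thinning inks
(e.g. gelatin/siloxane hybrid hydrogels). It answers, in one package, the
questions a bioprinting lab iterates on: *what strand will this nozzle and
pressure produce, how faithful is the printed scaffold to its CAD design,
and which printing parameters should I use next?*

Four components, usable separately or as a pipeline:

- **Extrusion model** (`printfid.extrusion`) — fits Ostwald–de Waele
  rheology `eta = K * gamma_dot^(n-1)` and predicts flow rate
  `Q = V_ext * pi R^2`, maximum velocity `V_max = V_ext (3n+1)/n`,
  generalized Hagen–Poiseuille pressure/velocity/consistency relations,
  and the deposited strand diameter `D_f = 4 W_n V_ext / (n V_max)`
  (= bore for a Newtonian ink, die swell for n < 1).
- **Fidelity scoring** (`printfid.fidelity`) — preprocesses scaffold
  images (grayscale, Gaussian, Otsu, resize to 128 x 128), computes
  windowed SSIM, dimensional similarity
  `SD = 100 - (|L-L_o|+|W-W_o|)/max(L_o,W_o) * 100`, aggregate similarity
  `SA = (SSIM% + SD)/2`, and a caliper-style manual similarity
  `100 - mean(E_L, E_W, E_FD)`.
- **CNN classifier** (`printfid.classifier`) — a four-block 32/64/128/256
  convolutional network (NumPy implementation in `printfid.nn`) that
  labels prints High/Low fidelity, trained incrementally with early
  stopping, and maps the best predicted print back to its printing
  parameters through the experiment matrix.
- **Factorial DoE** (`printfid.doe`) — the 2 x 5 x 5 design over nozzle
  gauge, pressure and velocity; centered polynomial OLS
  (`FactorialModel.from_dataframe(...).fit()` returning a results object
  with `params`, `pvalues`, `summary()`, `prune(alpha=0.01)`); main
  effects, response-surface grids, and MAE/MSE/Pearson comparison
  statistics. Two literal reference surfaces ship as `eq19` (diameter) and
  `eq20` (similarity).

A synthetic-data module (`printfid.synthgen`) renders grid-scaffold images
with known ground truth (strand width, defects, dimensional bias), samples
power-law flow curves, and simulates DoE response tables, so the whole
pipeline runs and is tested without any external data.

## Worked example

```python
>>> import printfid as pf
>>> from printfid import extrusion as ex, synthgen as sg

# 1. Fit rheology and predict the strand from a 25G nozzle
>>> curve = sg.generate_rheology(n=0.4, K=120.0, noise_sigma=0.05, seed=1)
>>> fit = ex.fit_power_law(curve)
>>> print(fit.summary())
Power-law (Ostwald-de Waele) fit
  n  (flow-behavior index) : 0.394669
  K  (consistency, Pa*s^n) : 120.34
  R^2 (log-log OLS)        : 0.9990
  shear-rate window (1/s)  : [0.1, 100]
>>> noz = ex.NozzleGeometry.from_gauge(25)
>>> round(ex.filament_diameter(noz, v_ext=25.0, n=fit.n), 4)
0.4579

# 2. Score a rendered print against the 10 x 10 mm CAD target
>>> img, truth = sg.render_mesh(sg.MeshRenderSpec(defect_rate=0.1, seed=3))
>>> ref, _ = sg.render_mesh(sg.MeshRenderSpec())
>>> scores = pf.score_print(img, ref, sg.DEFAULT_CAD)
>>> round(scores.sa, 1), round(scores.manual_similarity, 1)
(96.9, 100.0)

# 3. Fit and prune the factorial surface on simulated responses
>>> from printfid import doe
>>> runs = sg.generate_doe_responses(doe.FactorialDesign(replicates=2),
...                                  sg.surface_truth("eq19", 0.01), seed=1)
>>> res = doe.FactorialModel.from_dataframe(runs, "filament_diameter_mm").fit()
>>> pruned, trace = res.prune(alpha=0.01)
>>> pruned.terms
('A', 'B', 'C', 'AB', 'AC')
>>> round(pruned.predict(27, 180, 15), 4)
0.5483
```

The fitted `n` ≈ 0.4 recovers the generator's shear-thinning index; the
0.46 mm strand prediction shows die swell beyond the 0.250 mm bore; the
damaged print scores SA ≈ 97% (SSIM penalizes the broken strands while
the outer dimensions stay at CAD, so the manual caliper-style score stays
at 100); and the pruned factorial model retains exactly the five-term
surface used to simulate the data, predicting a 0.548 mm strand for the
27G nozzle at the design-center pressure and speed.

A command-line interface mirrors the library:

```bash
printfid simulate --out study/ --n 400 --seed 7
printfid extrude --rheology study/rheology.csv --nozzle 25G --pressure 170 --velocity 25 --temp 32
printfid score --image study/images/img-0000.png --scale 0.05 --cad 10x10x0.25
printfid doe fit --matrix study/experiment_matrix.csv --response filament_diameter_mm
printfid doe predict --model eq19 --A 27 --B 170 --C 25
```

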