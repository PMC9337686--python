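# actin2nucleus

In-silico nucleus prediction from actin-filament images, with the
statistics to show the prediction is not luck.

Adherent cells anchor and reposition their nucleus through the actin
cytoskeleton, and nuclear mispositioning marks several disorders — but
the "spaghetti" arrangement of stress fibers resists conventional
parameterization.  `actin2nucleus` takes the generative route: train an
image-to-image translator to paint the nucleus channel of a fluorescence
image pair from the actin channel alone, segment the generated and real
nuclei, match them, and ask how often the generated nucleus lands within
one nuclear radius (r = 4 µm) of the real one compared with random
placement.  The package is aimed at mechanobiology and bioimage-analysis
groups who want the full chain — simulation, training, segmentation,
matching, statistics — runnable and testable on one CPU with no external
data: a built-in generator produces paired tiles in which the nucleus
position is a known deterministic function of the fiber arrangement
(the intensity-weighted centroid of fiber midpoints), so recovery can be
measured against exact ground truth.

The pieces, in the field's standard notation:

- **Translator** G: CNN encoder → transformer (z′ₗ = MSA(LN(zₗ₋₁)) + zₗ₋₁,
  zₗ = MLP(LN(z′ₗ)) + z′ₗ over tokens z₀ = [x₁; …; x_N] + E_pos) → CNN
  decoder with multi-resolution outputs, plus a discriminator D
  downsampling to 4×4.
- **Losses**: pixel-weighted reconstruction
  L_rec = α‖M ⊙ (I_out − I_gt)‖₁ + ‖(1−M) ⊙ (I_out − I_gt)‖₁ with α = 10
  (M = binary nucleus mask), and the minimax adversarial loss
  min_G max_D E[log D(I_gt)] + E[log(1 − D(G(I_in)))].
- **Evaluation**: Otsu binarization, connected components with a 50-px
  minimum area, bounding-box IoU ("overlap ratio") matching, centroid
  Euclidean distances, Error(%) = |N_GT − N_Gen| / N_GT × 100.
- **Statistics**: random-placement nulls p = πr²/L² (image level) or the
  erosion-restricted cell-mask ratio (cell level); Binomial(n, p) tails
  in log10 via extended-precision summation; Clopper–Pearson and Wilson
  score 95% confidence intervals.

## Worked example

Simulate 60 paired tiles (64 px ≙ 52.5 µm, 3 cells each), train the
desk-scale translator for 600 iterations, generate nuclei for the
held-out 20%, and run the full evaluation:

```bash
actin2nucleus run --out runs/demo --seed 1 --n-tiles 60 --iterations 600
```

which prints

```
4um: 35/36 matched (97.2%)
1um: 32/36 matched (88.9%)
```

meaning: on the 12 held-out tiles the real images contained 35 nuclei and
the translator generated 36 detectable nuclei (count error 2.9%); 35 of
the generated nuclei lie within 4 µm of their matched real counterpart.
`runs/demo/statistics.json` holds the full analysis, e.g. for the 4 µm
threshold:

- matched fraction 0.972, Wilson 95% CI [0.858, 0.995],
  Clopper–Pearson [0.855, 0.999];
- image-level null p = πr²/L² = 0.0182 for r = 4 µm, L = 52.5 µm;
- one-sided exact binomial tail log₁₀ P(X ≥ 35) = −59.3 — the matched
  fraction is 53× the random-placement probability, and the hypothesis
  that placement is random is untenable.

`runs/demo/` also contains the simulated dataset (`data/` with
`scenes.json` ground truth), the model checkpoint and per-iteration loss
log, per-image detection records (`records_*.csv`), the match table
(`matches.csv`), and image-quality metrics (`metrics.json`: here mean
ℓ₁ 0.026, PSNR 20.8 dB, SSIM 0.864 against the real nucleus channel).

Every step is also available as its own subcommand
(`simulate | train | predict | detect | match | stats | metrics`) and as
library functions (`actin2nucleus.synthetic`, `.nn`, `.detection`,
`.matching`, `.placement`, `.metrics`).

At published-study scale the same statistics module reproduces the
headline numbers from their counts: a Wilson 95% interval of 71.0 ± 1.0%
for 5785/8151 nuclei matched at 4 µm, 28.6 ± 1.0% for 2328/8151 at 1 µm,
and a 1-in-505 (≈ "1 in 500") random-placement probability for r = 4 µm
in a 159.41 µm image.

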