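# venomshift

Mode and tempo of ontogenetic shifts in compositional venom phenotypes.

Many snakes remodel their venom as they grow — juvenile venoms give way to
adult ones — but a single "juvenile vs. adult" size cutoff silently assumes
the change is sudden. Serial sampling of the *same* individual over years
lets one ask the sharper question: does venom composition drift gradually,
or switch discretely, and over how many days? `venomshift` implements the
full analysis for longitudinal HPLC peak tables (samples × peak relative
abundances with collection dates and body sizes), together with a
ground-truthed simulator so every stage can be exercised and validated
without access to a colony of rattlesnakes.

It is a library: the public face is the importable API plus the short
narrative scripts in `examples/`.

## The statistics

Venom composition lives on the simplex, so all analysis runs in Aitchison
geometry. For a composition x with D parts and geometric mean g(x):

- **clr** (centered log-ratio): clr(x)ᵢ = ln(xᵢ / g(x));
  **ilr** projects clr onto an orthonormal (Helmert-type) basis of the
  zero-sum hyperplane; **Aitchison distance** d(x, y) = ‖clr(x) − clr(y)‖₂.
- Zeros are replaced multiplicatively: zeros → δ, nonzero parts in a row
  with Z zeros scaled by (1 − Zδ).
- **Ontogeny test**: PERMANOVA of the ilr-transformed composition on day of
  study as a *continuous* predictor; pseudo-F from the least-squares
  projection (equivalent to the Gower-centered distance formulation for
  Euclidean coordinates), p from 10,000 predictor permutations with the +1
  correction — so the smallest reportable p is 1/10001 ≈ 9.9 × 10⁻⁵.
  Designs with n ≤ 7 are enumerated exhaustively.
- **Trajectory**: each sample's Aitchison distance from the juvenile
  baseline (closed geometric mean of the three earliest samples), scaled by
  its own mean, is fit with a line and with a 3-parameter logistic
  d(t) = A / (1 + exp((t₀ − t)/s)); models compete on
  AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1).
- **Tempo**: days to cover 90% of the asymptotic change at the maximum
  (inflection-point) rate A/(4s): tempo = 0.9A / (A/4s) = **3.6·s**. A
  sigmoid-preferred shift is **discrete** when tempo < 244 days (one
  April–November active season), otherwise **gradual**; a linear-preferred
  fit is gradual by definition.
- **Per-peak scan**: the same competition on every peak's clr abundance
  (centered on its juvenile reference, amplitude free in sign), tallied
  into mode counts, proportion shifting and percent gradual.
- **Venom space**: peaks binned into eleven fixed retention-time windows
  (R1: 10–20 min … R11: 110–125 min) to make individuals comparable, then
  non-metric MDS (Kruskal stress-1) of pairwise Aitchison distances.
- Companions: testosterone series preparation (duplicate averaging,
  non-detects at the 0.001 ng/mL detection limit, ln transform) with
  distance-on-ln-T regression and a collinearity guard; diet records binned
  into four equal-width body-size classes with adjacent-class chi-square
  contrasts.

## Worked example

`python examples/ontogeny_trajectory.py` simulates one snake sampled every
~12 weeks for 3.3 years whose venom carries a single fast-switching peak
(logistic scale 40 days, i.e. a true tempo of 144 days), then runs the
trajectory analysis:

```
day  scaled distance from juvenile baseline
    0   0.046
   85   0.044
  170   0.054
  255   0.062
  340   0.059
  425   0.235
  510   0.980
  595   1.567
  680   1.680
  765   1.693
  850   1.714
  935   1.699
 1020   1.733
 1105   1.703
 1190   1.731

linear fit : AICc   -25.60  R2 0.82  p 3.1e-06
sigmoid fit: AICc   -94.53  R2 1.00  p 7.1e-18  scale 41.2 d
mode: sigmoid_discrete   tempo: 148 days (< 244-day active season -> discrete)
```

The distance series sits near zero while the venom is juvenile, switches
around day 500, and plateaus at the adult (terminal) phenotype. The
logistic wins the AICc competition decisively and its fitted scale (41.2
days vs. 40 simulated) gives a tempo of 3.6 × 41.2 ≈ 148 days — faster
than one active season, so the shift is called discrete. The other
examples cover the PERMANOVA and time-vs-size comparison, the per-peak
scan, the shared NMDS venom space, the hormone regression, the diet
contrasts, and the file-based end-to-end pipeline (`full_report.py`).

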