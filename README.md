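# rootplates

Quantification pipeline for cereal seedling root growth in soil-plate
(rhizobox-style) assays under controlled water deficit.

Wheat seedlings grown against the transparent wall of a soil-filled plate
are photographed on days 0, 1 and 2 after transplant into well-watered
(WW) or PEG-osmoticum water-stressed (WS, e.g. 20 % PEG-8000 ≈ −0.65 MPa)
plates. Roots and shoot are traced in the images (e.g. with the SmartRoot
ImageJ plugin) and exported as CSV tables of labelled lengths. `rootplates`
is the quantification layer downstream of tracing: it merges and validates
the exports, applies the replicate-accounting rules the assay needs, fits
per-structure treatment contrasts, and renders the standard figures.

## What it computes

**Replicate accounting.** Wheat has up to 5–6 seminal roots; roots 1–3 and
the coleoptile (shoot) are present from transplant, roots 4–5 emerge later.
Each seedling × structure × day cell is scored

- *measured* — a usable traced length;
- *occluded* — present but not measurable in that photograph (excluded
  from the mean and from *n* without touching any other structure);
- *absent* — a late root (4–6) that has not emerged: length 0, counted
  toward *n*.

A missing record for roots 1–3/shoot means occlusion; for roots 4–6 it
means absence, unless the root was traced with an `_NA` suffix
(present-but-hidden → occluded). A sixth root enters plots and statistics
only when more than 3 of the 24 seedlings ever show one.

**Treatment contrasts.** Per structure, length is modelled as a linear
mixed-effects ANOVA

&nbsp;&nbsp;&nbsp;&nbsp;`length ~ condition × day,  (1 | plate) + (1 | seedling:plate)`

with day categorical and WS − WW contrasts at each timepoint
(Satterthwaite-style between-within degrees of freedom; singular fits drop
the seedling, then the plate term, deterministically). Points with
p < α (default 0.05) are flagged significant.

**Figures.** *Root plots* — stacked bars laid out like the seedling (roots
down, shoot up), each bar = day-0 baseline + day 0→1 + day 1→2 growth.
*Difference plots* — one facet per structure, WS − WW at each day with SE
bars, significant points black, others gray. Both exported as vector PDF.

**Simulator.** A synthetic experiment generator reproduces the full design
(2 conditions × 3 plates × 8 seedlings, days 0/1/2, emergence delays,
day-1 occlusion with edge-weighted odds, plate/seedling random intercepts,
truncated Gaussian noise) and writes SmartRoot-style CSV file sets, so the
whole pipeline is testable without photographs.

## Worked example

```sh
rootplates simulate --seed 3 --out sim3
rootplates analyze sim3 --out out3
```

prints `analysis complete: 10 significant structure × day contrasts` and
writes combined CSVs, compiled long tables, `summary.csv`,
`differences.csv`, a three-panel `report.pdf` (WW root plot, WS root plot,
difference plot) and a JSON run log of every rule application. The same
analysis from Python:

```python
import rootplates as rp
from rootplates import compile as cmod, stats

tables, _ = rp.simulate_tables(seed=1)
ww = cmod.compile_condition(*tables["WW"])
ws = cmod.compile_condition(*tables["WS"])
print(stats.fit_structure_model(ww, ws, "root1").summary())
```

```
Water-stress contrast model — structure: root1
  formula: length_mm ~ C(condition, Treatment('WW')) * C(day)
  random terms kept: plate+seedling
  contrast df (between-within): 46
  n obs: 142, alpha: 0.05

  day   WS-WW (mm)       SE          p
    0       0.2091   0.3739     0.5787
    1      -5.8726   0.3759  5.133e-20
    2     -10.8080   0.3739  3.839e-31
```

Read: at transplant (day 0) WS and WW seedlings are at the same stage
(+0.21 mm, p ≈ 0.58 — gray point); by 24 h root 1 is 5.9 mm shorter under
−0.65 MPa stress and 10.8 mm shorter by 48 h (black points). `n obs` is
142 rather than 144 because two day-1 tracings were occluded and excluded.

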