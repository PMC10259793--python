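# hyphamorph

Quantitative morphometry for budding bacteria that reproduce through
**hyphae** — thin polar cell extensions at whose tip the daughter cell (bud)
forms, as in *Rhodomicrobium* and related Hyphomicrobiaceae. The package
measures how straight or buckled these hyphae are, where along the cell
fluorescent signals sit, and whether strains differ — the measurements a
microscopist needs when a cytoskeletal mutant turns straight hyphae into
kinked ones.

## The deformity statistic d_h

A hypha is summarized by the turn angles along its medial axis: the
*junction angle* between the mother cell's long axis and the initial hypha
direction, and the deflection α of every *kink*. The hyphal deformity is
the mean sine of all measured angles,

```
d_h = ( sin(junction) + Σᵢ sin(αᵢ) ) / N ,   N = 1 + number of kinks
```

so a straight, collinearly emerging hypha scores 0 and heavily buckled ones
approach 1. Because sin(180° − α) = sin(α), the score is identical whether
angles are read as interior angles or as deflections. Only cells with an
initiated or finished bud and exactly one unbranched hypha are scored —
budding marks the stage at which hyphal growth has completed, and branched
cells are excluded (with a logged reason, never silently).

The pipeline around the statistic:

* **tracing** — label masks (any segmenter) → topological skeleton with
  local width from the distance transform → body / hypha / bud partition and
  growth-stage classification (`no_hypha`, `hypha_no_bud`, `budding`);
* **kink detection** — Douglas–Peucker simplification (default tolerance
  0.1 µm) followed by a deflection threshold (default 10°);
* **demographs** — per-cell fluorescence profiles, min–max normalized,
  pole-aligned and stacked by cell length, per stage group;
* **peak-to-tip distances** — arc distance from the hyphal tip to the
  (smoothed) profile maximum per channel, e.g. a terminal cell-wall label
  versus a subterminally localizing protein fusion;
* **group statistics** — D'Agostino–Pearson normality screen,
  tie-corrected Kruskal–Wallis comparison, significance labels
  (\*\*\*\* < 0.0001, \*\*\* < 0.001, \*\* < 0.01, \* < 0.1, n.s.);
* **synthetic data** — a ground-truthed generator (half-normal kink angles,
  Poisson kink counts, PSF blur, shot + read noise) so every stage is
  testable without micrographs.

## Worked example

Score two synthetic populations — a straight "wild-type-like" phenotype
(kink-angle spread σ = 5°) and a buckled "mutant-like" one (σ = 40°) — and
compare them:

```python
from hyphamorph.config import RunConfig
from hyphamorph.pipeline import run_deformity
from hyphamorph.simulate import PhenotypeSpec, generate_cells

groups = {}
for name, sigma, seed in (("WT-like", 5, 11), ("bacA-mutant-like", 40, 12)):
    spec = PhenotypeSpec(name=name, n_cells=100,
                         deflection_sigma_deg=sigma, seed=seed)
    groups[name] = generate_cells(spec)[0]

deform, comparison, excluded = run_deformity(groups, RunConfig())
print(comparison.summary())
```

prints

```
d_h: Kruskal-Wallis H = 149.3, p = 2.52e-34 (****)
  WT-like: n = 100, mean = 0.08318, SD = 0.06284
  bacA-mutant-like: n = 100, mean = 0.5726, SD = 0.1499
```

— the straight population sits near d_h ≈ 0.08 (mostly the sine of a small
emergence angle), the buckled one near 0.57, and the rank test flags the
contrast at the strongest label. The same analysis runs from the shell:

```
hyphamorph simulate --name wt  --sigma-deg 5  --n-cells 100 --seed 11 --out out/wt
hyphamorph simulate --name mut --sigma-deg 40 --n-cells 100 --seed 12 --out out/mut
hyphamorph deformity --traces wt=out/wt/wt_traces.csv \
                     --traces mut=out/mut/mut_traces.csv --out out/deformity
```

which writes the per-cell `deformity.csv`, an exclusion log, the comparison
report and a swarm plot. `trace`, `demograph`, `peaks` and `compare`
subcommands cover the remaining stages; every run writes its effective
configuration and a manifest for exact replay.

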