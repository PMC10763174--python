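# delphistats

Consensus analysis for multi-round expert-panel rating studies using the
RAND/UCLA appropriateness method.

Structured consensus studies (Delphi panels, appropriateness panels) ask a
panel of experts to score items — typically clinical scenarios or candidate
quality indicators — on a 9-point scale where 1–3 means *inappropriate*
(harms outweigh benefits), 4–6 *uncertain/equivocal* and 7–9 *appropriate*.
After each round the panel sees aggregated feedback and re-rates the items,
often with some rewordings and some panellist attrition. The analytical
question is always the same: **did the panel reach consensus on each item,
and in which direction?** `delphistats` implements the standard statistics
for that question, the bookkeeping for multi-round studies (item lineage,
convergence, category cross-tabulation), and a synthetic panel generator so
pipelines can be tested without access to raw ratings, which are rarely
shared.

## The statistic

For each item the panel's ratings are reduced to the median and the 30th
and 70th percentiles (P₃₀, P₇₀). Disagreement is measured by the
**disagreement index**

```
DI = IPR / IPRAS
IPR   = P70 − P30                    (interpercentile range)
IPRCP = (P30 + P70) / 2              (central point of the IPR)
AI    = |5 − IPRCP|                  (asymmetry index)
IPRAS = 2.35 + 1.5 · AI              (IPR adjusted for symmetry)
```

A panel whose central mass sits away from the scale midpoint is allowed a
wider spread before being called split; a symmetric full-spread panel
(P₃₀ = 1, P₇₀ = 9) attains the maximal DI = 8/2.35 ≈ 3.404. If DI < 1 the
panel agrees, and the median places the item in a band: median < 3.5 →
*agreement on inappropriateness* (label `A/IA`), median > 6.5 → agreement on
appropriateness (`A/A`), otherwise agreement on equivocality (`Neutral`).
DI ≥ 1 is `Disagreement`. Percentile interpolation, the DI threshold, the
band edges and the IPRAS constants are all configurable.

## Worked example

```python
import delphistats as ds

# one item: nine panellists, scores clustered low
s = ds.summarize_item([1, 2, 2, 2, 2, 2, 3, 3, 5], item_id="demo")
print(s.median, round(s.di, 3), ds.classify(s).label)
# 2.0 0.094 A/IA

# a full synthetic two-round study with the shape of a real panel:
# 24 panellists x 20 items in round 1, ~19 panellists re-rating the
# originals plus 13 reworded items in round 2
study = ds.simulate_study(ds.SimulationConfig(seed=1))
res = ds.ConsensusModel(study).fit()
print(res.summary())
```

The summary header printed by the last line:

```
Appropriateness consensus analysis
==================================
dimension: appropriateness
percentiles: 30%/70% (linear); DI threshold: 1; IPRAS = 2.35 + 1.5*AI
round 1: 20 items, 20 with agreement (A/IA: 15, Neutral: 5)
round 2: 33 items, 33 with agreement (A/IA: 28, Neutral: 5)
```

i.e. every item reached consensus, 15 of the 20 round-1 items were judged
inappropriate and 5 equivocal — the simulator's default item archetypes —
and in round 2 many of the equivocal rewordings converged to
inappropriateness. `res.transitions()` returns the band-transition matrix
and per-item detail; `res.modified_transitions()` isolates the effect of
rewording by comparing each modified item against its parent within the
same round; `res.crosstab()` tallies agreement-on-inappropriateness by item
category.

The same pipeline runs from the shell:

```
delphistats simulate --seed 1 --out run/
delphistats summarize --ratings run/synthetic_ratings.csv \
    --lineage run/synthetic_lineage.csv --out run/ --format md
delphistats compare --ratings run/synthetic_ratings.csv \
    --lineage run/synthetic_lineage.csv --out run/
```

Every command writes a `manifest.json` (command, config hash, seed,
inputs, outputs, version); identical config and seed give identical
numeric outputs.

## Bundled reference tables

`delphistats.datasets` ships the printed per-item summary tables of a
published two-round e-Delphi study on opioid prescribing-safety indicators
(20 original scenarios, 13 round-2 rewordings, panels of 24 and 19), which
serve as a real-world desk check for the classification, convergence and
cross-tabulation machinery. The study's raw ratings are not public, and its
printed DI values were computed from unrounded percentiles, so only the
classification-level results — not the exact DI values — are recomputable
from the printed numbers.

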