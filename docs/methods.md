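# Methods

## The consensus model

`delphistats` analyses multi-round expert-panel rating studies in the
RAND/UCLA appropriateness tradition. The data are integer scores on a
9-point scale, one per panellist × item × round × rating dimension
(appropriateness, and optionally feasibility). The analysis is
distribution-free: each item's ratings are summarised by the sample
median and the 30th/70th percentiles, and consensus is judged from the
disagreement index

DI = IPR / IPRAS, with IPR = P₇₀ − P₃₀, IPRCP = (P₃₀ + P₇₀)/2,
AI = |5 − IPRCP| and IPRAS = 2.35 + 1.5·AI.

The IPRAS term encodes the method's key assumption: a panel whose
central opinion sits at an extreme of the scale (AI large) is granted a
wider interpercentile range before being called split, because scale
compression near the ends inflates apparent spread. DI < 1 is
agreement; the median then assigns the band (inappropriate /
equivocal / appropriate). The statistic is a *rule*, not an estimator
with sampling theory attached; the simulator below is how we
characterise its operating behaviour.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| percentile fractions | 0.30 / 0.70 | the conventional appropriateness-method pair |
| interpolation | `linear` | sorted-sample interpolation at 1-based position (n−1)q+1; `nearest_rank` (⌈nq⌉-th order statistic) and `weibull` ((n+1)q position) available |
| DI threshold | 1.0 | DI below ⇒ agreement; **DI exactly 1 counts as disagreement** (the agreement rule is stated strictly as DI < 1, so the boundary goes to the conservative side) |
| band edges | 3.5 / 6.5 on the median | medians can be half-integers; 2.5 is inappropriate, 4.5 equivocal, and the exact edges 3.5/6.5 fall to equivocal (conservative: an item is only in/appropriate if its median is clearly inside the band) |
| IPRAS constants | 2.35, 1.5 | from the appropriateness-method manual; overridable for sensitivity analyses |

Source studies rarely state their percentile interpolation rule. The
`linear` default is the most common convention (numpy/spreadsheets),
and the alternatives let users match other software; classification
results at panel sizes ≥ ~15 are insensitive to the choice in all the
cases we test, because percentiles of concentrated integer samples land
on integers regardless.

All computation runs at full floating precision. Display rounding
(median/percentiles to one decimal only when non-integer, DI to three
decimals, half-even) happens exclusively in the reporting layer.

## Multi-round bookkeeping

Later rounds relate to earlier ones through an item lineage
(`identical` / `modified` / `split`). Two comparisons are computed:

* **between rounds** — an item rated in both rounds is compared with
  itself; the transition of interest is agreement-on-equivocality
  converging to agreement-on-inappropriateness after feedback;
* **rewording effect** — a modified or split child is compared against
  its parent's classification *in the same round*, isolating what the
  rewording changed. This is also the "before" state used when a child
  appears in a between-round table and its parent was re-rated, since
  the child inherits the parent's full rating history.

Split children each compare against the shared parent; splitting never
alters the parent's own classification. Items rated in only one round
are reported with a null transition rather than dropped. The category
cross-tabulation counts agreement-on-a-band (by default
inappropriateness) per item category per round; category totals always
sum to the study-wide count.

The bundled published tables contain one internal anomaly we preserve
verbatim: one round-1 row prints a median of 4 with an
inappropriateness label (our rule classifies a median-4 agreement item
as equivocal), and another prints a median below its 30th percentile.
Tests document the first as the single printed-label exception;
convergence counts therefore use the study's printed round-1 labels as
the round-1 state, which reproduces its reported bookkeeping exactly.

## The synthetic panel generator

The generator emulates the structure the analysis assumes, with
defaults matching the design shape of the bundled study: 24 panellists
and 20 items in round 1; independent per-panellist attrition 5/24
(expected round-2 panel 19); 13 derived round-2 items (one split pair
plus 11 modified rewordings, children inheriting the parent archetype);
and 15 tight low-score items (consensus, μ=2, σ=1 — reproducing printed
medians of 2 with DI ≈ 0.2) against 5 broader mid-scale items
(consensus, μ=5, σ=1.2 — medians 4–5, DI ≈ 0.5–0.7).

Item archetypes:

* **consensus** — ratings are a normal draw at (μ, σ), rounded to the
  nearest integer and clamped to [1, 9]; σ = 0 is the point-mass limit.
* **polarized** — the panel splits between two poles; `mix` is the
  *realized panel composition* (round(mix·n) panellists at the first
  pole), not a per-draw probability. A polarized archetype therefore
  always *is* polarized: with a Bernoulli mixture a nominally 50/50
  panel of 24 lands 17+ panellists in one camp about 6% of the time and
  stops being a split panel at all, which would make the archetype an
  unreliable test bed for the disagreement rule. Each camp member's
  rating is drawn at its pole with spread σ (default 1).
* **uniform** — equiprobable scores 1–9, the no-structure reference.

Round-2 ratings are drawn fresh from the archetype and then, with
probability `feedback_shift` (default 0.3), moved exactly one scale
step toward the parent item's round-1 median, never crossing it — a
deliberately mild rendering of documented Delphi convergence that
leaves round-1 structure dominant. A single seed drives a hierarchical
`SeedSequence` stream (study → round → item), so enlarging the design
never perturbs existing items' draws.

What the generator does **not** emulate: intra-panellist correlation
across items (hawks/doves severity offsets), item-order or fatigue
effects, missing individual ratings, and any dependence of attrition on
a panellist's opinions. Passing tests on synthetic panels therefore
demonstrate that the pipeline recovers the structure it assumes, not
that real panels satisfy those assumptions.

## Operating characteristics

`recovery_experiment` measures, per (archetype, panel size): the
probability of agreement, the accuracy of the recovered band against
the archetype's true band, and the mean DI, each with Monte-Carlo
standard errors. Panels sharing an archetype use common random numbers
across sizes (the size-n panel is a prefix of the largest one), so
accuracy comparisons across n are positively coupled. Reference
behaviour at the defaults, computed by the test suite and
`scripts/acceptance.py`: degenerate consensus items (σ=0) are
classified perfectly at any n; 50/50 polarized 1-vs-9 panels of 24 are
flagged as disagreement in effectively all of 10,000 replicates; a
uniform panel of 24 agrees far less often than a tight consensus panel;
and band accuracy for μ=2, σ=2 consensus items rises monotonically over
n ∈ {6, 12, 24, 48} (≈ 0.92 → 1.00 at 2,000 replicates).

Problem sizes in the tests and the acceptance script (exhaustive oracle
comparison over all rating multisets up to size 6, ≈ 5,000 cases;
10,000 replicates for the polarized reference rate; 200 seeds for the
attrition check) were chosen to pin each property with comfortable
Monte-Carlo margins while keeping the default suite fast.

## Numerical and degenerate-input choices

* Empty rating sets raise `EmptyPanelError` everywhere (no silent NaN).
* Percentile fractions are restricted to the open interval (0, 1);
  inverted percentile pairs raise `DomainError`.
* A unanimous panel has IPR = 0 and hence DI = 0 exactly.
* Missing individual ratings are allowed and simply absent — per-item n
  is the count of present records; no imputation is ever performed.
* Duplicate (panellist, round, item, dimension) keys, out-of-range or
  non-integer scores, and round-2 panellists unseen in round 1 (unless
  explicitly allowed) are hard validation errors with row references.
* Panellist identifiers are treated as opaque and never surface in
  rendered reports (panels are anonymous by design).

## Known limitations

Only the DI-based consensus rule is implemented — not the older
frequency-in-extreme-thirds disagreement definitions. The exact DI
values printed in the bundled study tables are not recomputable because
the published percentiles are rounded (two printed rows share identical
percentile pairs yet different DIs); the package's desk checks
therefore target the classification level, where the printed numbers
are self-consistent. Feasibility ratings are carried as a second
dimension but given no bespoke statistics; the same consensus rule
applies.
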