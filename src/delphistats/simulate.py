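"""Synthetic multi-round panel generator.

Real appropriateness-panel ratings are rarely shareable, so the
simulator produces studies with the same statistical structure the
analysis assumes: a fixed panel rating every item on the 1-9 scale in
round 1, attrition before round 2, re-rating of the original items plus
a set of modified/split rewordings, and a mild pull of round-2 ratings
toward the round-1 medians (the documented feedback effect of Delphi
rounds).

Items follow one of three archetypes:

* ``consensus`` — scores cluster around a location ``mu`` with spread
  ``sigma`` (a truncated, discretised bell);
* ``polarized`` — the panel splits into two camps at ``poles``; ``mix``
  is the fraction of the panel in the first camp;
* ``uniform`` — scores equiprobable over 1-9 (no opinion structure).

A single integer seed drives a hierarchical random stream (study ->
item -> panellist), so adding items never perturbs the draws of
existing items.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .data import RATING_COLUMNS, ItemLineage, RatingStudy
from .errors import ConfigError
from .stats import (
    DEFAULT_CONFIG,
    PERCENTILE_METHODS,
    ClassificationConfig,
    band_of,
)

ARCHETYPE_KINDS = ("consensus", "polarized", "uniform")


@dataclass(frozen=True)
class ItemArchetype:
    """Generating distribution of one item's panel opinion.

    ``location``/``dispersion`` parameterise the consensus bell (and
    the per-pole spread of a polarized item); ``poles``/``mix`` only
    apply to polarized items.  ``dispersion = 0`` collapses to a point
    mass at the rounded location.
    """

    kind: str = "consensus"
    location: float = 5.0
    dispersion: float = 1.0
    poles: tuple[float, float] = (1.0, 9.0)
    mix: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ARCHETYPE_KINDS:
            raise ConfigError(f"unknown archetype kind {self.kind!r}")
        if not (1.0 <= self.location <= 9.0):
            raise ConfigError("archetype location must lie on the 1-9 scale")
        if self.dispersion < 0:
            raise ConfigError("archetype dispersion must be >= 0")
        if not (0.0 <= self.mix <= 1.0):
            raise ConfigError("archetype mix must lie in [0, 1]")
        if not all(1.0 <= p <= 9.0 for p in self.poles):
            raise ConfigError("archetype poles must lie on the 1-9 scale")

    def true_band(self, config: ClassificationConfig = DEFAULT_CONFIG) -> str:
        """Band implied by the archetype's theoretical median."""
        if self.kind == "consensus":
            centre = self.location
        elif self.kind == "uniform":
            centre = 5.0
        else:  # polarized: median sits at the majority pole, or between equal camps
            if self.mix > 0.5:
                centre = self.poles[0]
            elif self.mix < 0.5:
                centre = self.poles[1]
            else:
                centre = (self.poles[0] + self.poles[1]) / 2.0
        return band_of(centre, config)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Sample ``n`` integer ratings from this archetype."""
        return _draw_matrix(self, rng, 1, n)[0]


def _clip_round(values: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(values), 1, 9).astype(int)


def _draw_matrix(arch: ItemArchetype, rng: np.random.Generator, reps: int, n: int) -> np.ndarray:
    """(reps, n) integer rating draws; rows are independent panels."""
    if n < 1:
        raise ConfigError("panel size must be >= 1")
    if arch.kind == "uniform":
        return rng.integers(1, 10, size=(reps, n))
    if arch.kind == "consensus":
        if arch.dispersion == 0:
            return np.full((reps, n), _clip_round(np.array([arch.location]))[0])
        return _clip_round(rng.normal(arch.location, arch.dispersion, size=(reps, n)))
    # polarized: mix is realized panel composition — round(mix*n) panellists
    # sit at the first pole, the rest at the second; camp membership is
    # shuffled so no panellist slot is systematically extreme.
    n_first = int(round(arch.mix * n))
    locs = np.empty((reps, n))
    locs[:, :n_first] = arch.poles[0]
    locs[:, n_first:] = arch.poles[1]
    locs = rng.permuted(locs, axis=1)
    if arch.dispersion == 0:
        return _clip_round(locs)
    return _clip_round(rng.normal(locs, arch.dispersion))


# ---------------------------------------------------------------------------
# study-level configuration
# ---------------------------------------------------------------------------

#: archetype used for feasibility ratings when enabled: broad, undecided
FEASIBILITY_ARCHETYPE = ItemArchetype(kind="consensus", location=5.0, dispersion=2.0)


def default_archetypes(
    n_items: int = 20,
    n_inappropriate: int = 15,
) -> dict[str, ItemArchetype]:
    """Archetype map emulating a two-band appropriateness panel.

    The first ``n_inappropriate`` items are tight low-score consensus
    items (mu 2, sigma 1 — the pattern behind printed medians of 2 with
    DI around 0.2); the remainder are broader mid-scale items (mu 5,
    sigma 1.2 — equivocal medians 4-5 with DI around 0.5).
    """
    out: dict[str, ItemArchetype] = {}
    for i in range(1, n_items + 1):
        if i <= n_inappropriate:
            out[f"S{i:02d}"] = ItemArchetype("consensus", location=2.0, dispersion=1.0)
        else:
            out[f"S{i:02d}"] = ItemArchetype("consensus", location=5.0, dispersion=1.2)
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic two-round panel study.

    Defaults mirror the design shape of a published two-round
    prescribing-indicator panel: 24 panellists rating 20 items in round
    1; attrition 5/24 so the expected round-2 panel is 19; 13
    later-round items derived from the originals (11 modified wordings
    plus one item split in two); and a feedback shift making each
    retained panellist move one scale step toward the round-1 median
    with probability 0.3.
    """

    n_panellists_round1: int = 24
    n_items_round1: int = 20
    n_modified_items: int = 13
    attrition: float = 5.0 / 24.0
    feedback_shift: float = 0.3
    archetypes: Mapping[str, ItemArchetype] | None = None
    rate_feasibility: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_panellists_round1 < 1 or self.n_items_round1 < 1:
            raise ConfigError("panel and item counts must be positive")
        if self.n_modified_items < 0:
            raise ConfigError("n_modified_items must be >= 0")
        if not (0.0 <= self.attrition <= 1.0):
            raise ConfigError("attrition must be a probability in [0, 1]")
        if not (0.0 <= self.feedback_shift <= 1.0):
            raise ConfigError("feedback_shift must be a probability in [0, 1]")
        if self.archetypes is not None:
            if len(self.archetypes) != self.n_items_round1:
                raise ConfigError(
                    "archetype map must cover exactly the round-1 items "
                    f"({len(self.archetypes)} given, {self.n_items_round1} needed)"
                )

    def resolved_archetypes(self) -> dict[str, ItemArchetype]:
        if self.archetypes is not None:
            return dict(self.archetypes)
        n_inapp = max(0, self.n_items_round1 - max(0, self.n_items_round1 // 4))
        if self.n_items_round1 == 20:
            n_inapp = 15
        return default_archetypes(self.n_items_round1, n_inapp)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a config from YAML/JSON; archetypes given as per-item mappings."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"simulation config {path!r} must be a mapping")
        arch = raw.pop("archetypes", None)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown simulation config key(s) {sorted(unknown)}")
        if arch is not None:
            parsed = {}
            for item_id, spec_dict in arch.items():
                if not isinstance(spec_dict, dict):
                    raise ConfigError(f"archetype for {item_id!r} must be a mapping")
                if "poles" in spec_dict:
                    spec_dict = {**spec_dict, "poles": tuple(spec_dict["poles"])}
                parsed[str(item_id)] = ItemArchetype(**spec_dict)
            raw["archetypes"] = parsed
        return cls(**raw)


def _item_stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def default_lineage(config: SimulationConfig) -> list[ItemLineage]:
    """Lineage for the derived round-2 items.

    With ``k`` derived items: the first original item is split into two
    children (``*a``/``*b``) and the following ``k - 2`` originals each
    get one modified child (``*m``); with ``k < 2`` only modified
    children are produced.
    """
    k = config.n_modified_items
    originals = [f"S{i:02d}" for i in range(1, config.n_items_round1 + 1)]
    lineage: list[ItemLineage] = []
    if k >= 2:
        parent = originals[0]
        lineage.append(ItemLineage(parent + "a", parent, "split"))
        lineage.append(ItemLineage(parent + "b", parent, "split"))
        remaining = k - 2
        pool = originals[1:]
    else:
        remaining = k
        pool = originals
    if remaining > len(pool):
        raise ConfigError(
            f"cannot derive {k} items from {config.n_items_round1} originals "
            "with one modification per parent"
        )
    for parent in pool[:remaining]:
        lineage.append(ItemLineage(parent + "m", parent, "modified"))
    return lineage


def simulate_study(config: SimulationConfig) -> RatingStudy:
    """Generate a deterministic two-round synthetic rating study.

    Round 1: every panellist rates every original item from its
    archetype.  Between rounds each panellist independently drops out
    with probability ``attrition``.  Round 2: retained panellists
    re-rate the originals and rate the derived items (which inherit the
    parent archetype); each fresh draw then moves one scale step toward
    the parent item's round-1 median with probability
    ``feedback_shift``, never crossing it.
    """
    archetypes = config.resolved_archetypes()
    originals = list(archetypes)
    panellists = [f"P{i:02d}" for i in range(1, config.n_panellists_round1 + 1)]

    roster_rng = _item_stream(config.seed, 0)
    dropped = roster_rng.random(len(panellists)) < config.attrition
    retained = [p for p, d in zip(panellists, dropped) if not d]
    if not retained:  # keep at least one rater so round 2 exists
        retained = [panellists[0]]

    rows: list[tuple] = []
    round1_median: dict[str, float] = {}

    for idx, item_id in enumerate(originals):
        rng = _item_stream(config.seed, 1, idx)
        scores = archetypes[item_id].draw(rng, len(panellists))
        round1_median[item_id] = float(np.median(scores))
        rows += [
            (p, 1, item_id, "appropriateness", int(s))
            for p, s in zip(panellists, scores)
        ]

    lineage = default_lineage(config) if config.n_modified_items else []
    round2_items = originals + [ln.child_item_id for ln in lineage]
    parent = {ln.child_item_id: ln.parent_item_id for ln in lineage}

    for idx, item_id in enumerate(round2_items):
        src = parent.get(item_id, item_id)
        arch = archetypes[src]
        rng = _item_stream(config.seed, 2, idx)
        scores = arch.draw(rng, len(retained)).astype(float)
        med = round1_median[src]
        shift_mask = rng.random(len(retained)) < config.feedback_shift
        step = np.sign(med - scores)
        far_enough = np.abs(med - scores) >= 1.0
        scores = scores + step * (shift_mask & far_enough)
        rows += [
            (p, 2, item_id, "appropriateness", int(s))
            for p, s in zip(retained, scores)
        ]
        if config.rate_feasibility:
            feas = FEASIBILITY_ARCHETYPE.draw(
                _item_stream(config.seed, 3, idx), len(retained)
            )
            rows += [
                (p, 2, item_id, "feasibility", int(s))
                for p, s in zip(retained, feas)
            ]

    data = pd.DataFrame(rows, columns=RATING_COLUMNS)
    items = pd.DataFrame(
        {
            "item_id": round2_items,
            "text": [
                f"synthetic {archetypes[parent.get(i, i)].kind} item" for i in round2_items
            ],
            "category_id": [archetypes[parent.get(i, i)].true_band() for i in round2_items],
        }
    )
    return RatingStudy(data, items=items, lineage=lineage)


# ---------------------------------------------------------------------------
# operating characteristics
# ---------------------------------------------------------------------------

def _vector_summaries(
    draws: np.ndarray, config: ClassificationConfig
) -> pd.DataFrame:
    """Vectorised per-row (panel) median/DI/band over a (reps, n) matrix."""
    method = PERCENTILE_METHODS[config.method]
    med = np.median(draws, axis=1)
    p_lo = np.quantile(draws, config.q_low, axis=1, method=method)
    p_hi = np.quantile(draws, config.q_high, axis=1, method=method)
    ipr = p_hi - p_lo
    iprcp = (p_lo + p_hi) / 2.0
    ipras = config.ipras_intercept + config.ipras_slope * np.abs(5.0 - iprcp)
    di = ipr / ipras
    bands = np.where(
        med < config.band_low_edge,
        "inappropriate",
        np.where(med > config.band_high_edge, "appropriate", "equivocal"),
    )
    return pd.DataFrame({"median": med, "di": di, "band": bands})


def recovery_experiment(
    config_grid: Sequence[tuple[ItemArchetype, int]],
    replicates: int = 1000,
    seed: int = 0,
    config: ClassificationConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Monte-Carlo operating characteristics of the consensus rule.

    ``config_grid`` is a sequence of ``(archetype, panel size)`` pairs.
    For each pair the experiment simulates ``replicates`` independent
    panels, runs the summary/classification pipeline, and reports the
    probability of agreement (DI below threshold), the accuracy of the
    median band against the archetype's true band, and the mean DI,
    each with its Monte-Carlo standard error.

    Panels sharing an archetype use common random numbers across panel
    sizes (the size-``n`` panel is the first ``n`` columns of the
    largest panel drawn), so operating characteristics compared across
    ``n`` are positively coupled.
    """
    if len(config_grid) == 0:
        raise ConfigError("recovery experiment needs a non-empty config grid")
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")

    # group grid entries by archetype for common-random-number draws
    unique: list[ItemArchetype] = []
    for arch, _ in config_grid:
        if arch not in unique:
            unique.append(arch)

    draws_cache: dict[int, np.ndarray] = {}
    for ai, arch in enumerate(unique):
        n_max = max(n for a, n in config_grid if a == arch)
        rng = _item_stream(seed, 4, ai)
        draws_cache[ai] = _draw_matrix(arch, rng, replicates, n_max)

    rows = []
    for arch, n in config_grid:
        ai = unique.index(arch)
        sub = _vector_summaries(draws_cache[ai][:, :n], config)
        agree = (sub["di"] < config.di_threshold).to_numpy()
        correct = (sub["band"] == arch.true_band(config)).to_numpy()
        p_agree = float(agree.mean())
        acc = float(correct.mean())
        rows.append(
            {
                "kind": arch.kind,
                "location": arch.location,
                "dispersion": arch.dispersion,
                "n": n,
                "true_band": arch.true_band(config),
                "p_agreement": p_agree,
                "p_agreement_se": math.sqrt(p_agree * (1 - p_agree) / replicates),
                "band_accuracy": acc,
                "band_accuracy_se": math.sqrt(acc * (1 - acc) / replicates),
                "mean_di": float(sub["di"].mean()),
                "mean_di_se": float(sub["di"].std(ddof=1) / math.sqrt(replicates))
                if replicates > 1
                else 0.0,
                "replicates": replicates,
            }
        )
    return pd.DataFrame(rows)
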