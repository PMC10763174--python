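"""Model/Results facade over the consensus-analysis pipeline.

`ConsensusModel` holds the data and configuration; `fit()` runs the
per-item appropriateness statistics and returns a `ConsensusResults`
carrying summaries, classifications and the derived round-to-round
analyses::

    model = ConsensusModel.from_csv("ratings.csv", categories="cats.csv")
    res = model.fit()
    print(res.summary())
    matrix, comparisons = res.transitions()
    res.crosstab()
"""

from __future__ import annotations

import io
from collections.abc import Iterable

import pandas as pd

from . import rounds as rounds_mod
from .data import (
    ItemLineage,
    RatingStudy,
    read_categories,
    read_lineage,
    read_ratings,
)
from .errors import MappingError
from .reporting import fmt_di, fmt_score, render_item_table
from .stats import (
    AGREEMENT,
    DEFAULT_CONFIG,
    Classification,
    ClassificationConfig,
    ItemSummary,
    classify,
    summarize_study,
)


class ConsensusModel:
    """An appropriateness-method consensus analysis of a rating study.

    Parameters
    ----------
    study
        Validated :class:`~delphistats.data.RatingStudy`.
    config
        :class:`~delphistats.stats.ClassificationConfig`; defaults to
        the standard 30th/70th-percentile, DI-threshold-1 rule.
    categories
        Optional item-category map (``item_id, category_id[,
        category_label]``) enabling :meth:`ConsensusResults.crosstab`.
    """

    def __init__(
        self,
        study: RatingStudy,
        config: ClassificationConfig = DEFAULT_CONFIG,
        categories: pd.DataFrame | None = None,
    ) -> None:
        self.study = study
        self.config = config
        self.categories = categories

    @classmethod
    def from_csv(
        cls,
        ratings,
        lineage=None,
        categories=None,
        config: ClassificationConfig = DEFAULT_CONFIG,
        schema=None,
        **study_kwargs,
    ) -> "ConsensusModel":
        """Build a model from the CSV/TSV interchange files."""
        lineage_list: Iterable[ItemLineage] = read_lineage(lineage) if lineage is not None else ()
        cat = read_categories(categories) if categories is not None else None
        study = read_ratings(ratings, schema=schema, lineage=lineage_list, **study_kwargs)
        return cls(study, config=config, categories=cat)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        lineage: Iterable[ItemLineage] = (),
        categories: pd.DataFrame | None = None,
        config: ClassificationConfig = DEFAULT_CONFIG,
        **study_kwargs,
    ) -> "ConsensusModel":
        """Build a model from an in-memory tidy rating table."""
        study = RatingStudy(data, lineage=lineage, **study_kwargs)
        return cls(study, config=config, categories=categories)

    def fit(self, dimension: str = "appropriateness") -> "ConsensusResults":
        """Compute every per-item summary and classification."""
        summaries = summarize_study(self.study, dimension=dimension, config=self.config)
        classifications = {
            key: classify(summ, config=self.config) for key, summ in summaries.items()
        }
        return ConsensusResults(self, dimension, summaries, classifications)


class ConsensusResults:
    """Fitted consensus statistics with round-linkage analyses attached."""

    def __init__(
        self,
        model: ConsensusModel,
        dimension: str,
        summaries: dict[tuple[str, int], ItemSummary],
        classifications: dict[tuple[str, int], Classification],
    ) -> None:
        self.model = model
        self.config = model.config
        self.dimension = dimension
        self.summaries = summaries
        self.classifications = classifications

    # -- tabular views -------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """Tidy per-(item, round) statistics table at full precision."""
        rows = []
        for (item, rnd), s in sorted(self.summaries.items()):
            c = self.classifications[(item, rnd)]
            rows.append(
                {
                    "item_id": item,
                    "round": rnd,
                    "dimension": s.dimension,
                    "n": s.n,
                    "median": s.median,
                    "p_low": s.p_low,
                    "p_high": s.p_high,
                    "ipr": s.ipr,
                    "ipras": s.ipras,
                    "di": s.di,
                    "bin_low": s.bins[0],
                    "bin_mid": s.bins[1],
                    "bin_high": s.bins[2],
                    "agreement": c.agreement,
                    "band": c.band,
                    "label": c.label,
                }
            )
        return pd.DataFrame(rows)

    def label_counts(self, round_index: int) -> pd.Series:
        """Consensus-label tally for one round."""
        labels = [
            c.label for (i, r), c in self.classifications.items() if r == round_index
        ]
        return pd.Series(labels, dtype=object).value_counts()

    # -- round linkage -------------------------------------------------
    def transitions(self, round_before: int = 1, round_after: int = 2):
        """Band-transition matrix and per-item comparisons between rounds."""
        di = {k: s.di for k, s in self.summaries.items()}
        return rounds_mod.transition_table(
            self.classifications,
            round_before=round_before,
            round_after=round_after,
            lineage=self.model.study.lineage,
            di=di,
        )

    def modified_transitions(self, round_index: int = 2):
        """Transitions of reworded items against their unmodified parents."""
        di = {k: s.di for k, s in self.summaries.items()}
        return rounds_mod.modified_transitions(
            self.classifications,
            self.model.study.lineage,
            round_index=round_index,
            di=di,
        )

    def crosstab(self, agreement_band: str = "inappropriate") -> pd.DataFrame:
        """Per-category agreement counts (requires a category map)."""
        cats = self.model.categories
        if cats is None:
            cats = self.model.study.items.rename(columns={"category_id": "category_id"})
            cats = cats[cats["category_id"] != ""][["item_id", "category_id"]]
            if cats.empty:
                raise MappingError(
                    "no category map supplied and the study's item table has no categories"
                )
            cats = cats.assign(category_label=cats["category_id"])
        return rounds_mod.category_crosstab(
            self.classifications, cats, agreement_band=agreement_band
        )

    # -- presentation --------------------------------------------------
    def report(self, fmt: str = "md") -> str:
        """Conventional per-item table, rounds side by side."""
        _, comparisons = self.transitions() if len(self.rounds) > 1 else (None, [])
        converged = rounds_mod.converged_items(comparisons)
        return render_item_table(
            self.summaries,
            self.classifications,
            lineage=self.model.study.lineage,
            converged=converged,
            fmt=fmt,
        )

    @property
    def rounds(self) -> list[int]:
        return sorted({r for _, r in self.summaries})

    def summary(self) -> str:
        """Human-readable overview: rule settings, per-round tallies, items."""
        cfg = self.config
        buf = io.StringIO()
        buf.write("Appropriateness consensus analysis\n")
        buf.write("==================================\n")
        buf.write(f"dimension: {self.dimension}\n")
        buf.write(
            f"percentiles: {cfg.q_low:.0%}/{cfg.q_high:.0%} ({cfg.method}); "
            f"DI threshold: {fmt_score(cfg.di_threshold)}; "
            f"IPRAS = {cfg.ipras_intercept} + {cfg.ipras_slope}*AI\n"
        )
        for r in self.rounds:
            n_items = sum(1 for (_, rr) in self.summaries if rr == r)
            agree = sum(
                1
                for (i, rr), c in self.classifications.items()
                if rr == r and c.agreement == AGREEMENT
            )
            tally = ", ".join(f"{k}: {v}" for k, v in self.label_counts(r).items())
            buf.write(f"round {r}: {n_items} items, {agree} with agreement ({tally})\n")
        buf.write("\n")
        frame = self.frame
        cols = ["item_id", "round", "n", "median", "p_low", "p_high", "di", "label"]
        show = frame[cols].copy()
        for c in ("median", "p_low", "p_high"):
            show[c] = show[c].map(fmt_score)
        show["di"] = show["di"].map(fmt_di)
        buf.write(show.to_string(index=False))
        buf.write("\n")
        return buf.getvalue()
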