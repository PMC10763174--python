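"""Multi-round linkage: convergence between rounds and category cross-tabs.

Two comparisons matter in a two-round appropriateness panel:

* **between rounds** — the same item rated in round 1 and round 2; the
  interesting transition is agreement-on-equivocality converging to
  agreement-on-inappropriateness after panellists see the round-1
  feedback;
* **within the later round** — a modified or split wording compared
  against its parent's classification *in the same round*, which shows
  whether the rewording itself moved the panel.

Both produce the same row shape (:class:`RoundComparison`) and a 3x3
band-transition count matrix.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import pandas as pd

from .data import ItemLineage, RatingStudy
from .errors import LinkageError, MappingError
from .stats import AGREEMENT, BANDS, Classification

#: row order/columns of the per-item comparison table
COMPARISON_COLUMNS = [
    "item_id", "parent_id", "band_before", "band_after",
    "di_before", "di_after", "converged",
]


@dataclass(frozen=True)
class RoundComparison:
    """Classification of one item against its parent's earlier classification."""

    item_id: str
    parent_id: str
    class_before: Classification
    class_after: Classification
    di_before: float | None = None
    di_after: float | None = None

    @property
    def transition(self) -> tuple[str, str]:
        return (self.class_before.band, self.class_after.band)

    @property
    def converged_to_inappropriate(self) -> bool:
        """Equivocal consensus that became inappropriate consensus."""
        return (
            self.class_before.agreement == AGREEMENT
            and self.class_after.agreement == AGREEMENT
            and self.class_before.band == "equivocal"
            and self.class_after.band == "inappropriate"
        )


def _lookup(classifications: Mapping, item_id: str, round_index: int) -> Classification:
    try:
        return classifications[(item_id, round_index)]
    except KeyError:
        raise LinkageError(
            f"no classification for item {item_id!r} in round {round_index}"
        ) from None


def transition_table(
    classifications: Mapping[tuple[str, int], Classification],
    round_before: int = 1,
    round_after: int = 2,
    lineage: Iterable[ItemLineage] = (),
    di: Mapping[tuple[str, int], float] | None = None,
) -> tuple[pd.DataFrame, list[RoundComparison]]:
    """Band-transition counts between two rounds, plus per-item detail.

    ``classifications`` maps ``(item_id, round_index)`` to a
    :class:`~delphistats.stats.Classification`.  Items classified in
    both rounds compare against themselves.  Lineage children (modified
    or split rewordings) compare against their parent's classification
    *in the same round* when the parent was also rated there — the
    rewording, not the round, is then the thing being assessed — and
    fall back to the parent's ``round_before`` classification
    otherwise.  Split children each compare against the shared parent.
    Items with no counterpart in the other round get a null transition
    row rather than being dropped.

    Returns a ``(matrix, comparisons)`` pair: a 3x3 DataFrame of band
    transition counts (rows = band before, columns = band after) and the
    per-item :class:`RoundComparison` list.
    """
    parent_of = {ln.child_item_id: ln.parent_item_id for ln in lineage}
    after_items = sorted({i for (i, r) in classifications if r == round_after})
    di = di or {}

    comparisons: list[RoundComparison] = []
    null_rows: list[str] = []
    for item in after_items:
        parent = parent_of.get(item, item)
        if parent != item and (parent, round_after) in classifications:
            # modified wording compared against its parent within the round
            before = classifications[(parent, round_after)]
            before_key = (parent, round_after)
        elif (parent, round_before) in classifications:
            before = classifications[(parent, round_before)]
            before_key = (parent, round_before)
        elif parent == item:
            null_rows.append(item)
            continue
        else:
            raise LinkageError(
                f"item {item!r} links to parent {parent!r}, which has no "
                f"classification in round {round_before} or {round_after}"
            )
        comparisons.append(
            RoundComparison(
                item_id=item,
                parent_id=parent,
                class_before=before,
                class_after=_lookup(classifications, item, round_after),
                di_before=di.get(before_key),
                di_after=di.get((item, round_after)),
            )
        )

    matrix = pd.DataFrame(0, index=list(BANDS), columns=list(BANDS), dtype=int)
    for comp in comparisons:
        b, a = comp.transition
        if b in matrix.index and a in matrix.columns:
            matrix.loc[b, a] += 1
    return matrix, ComparisonList(comparisons, null_items=null_rows)


class ComparisonList(list):
    """List of :class:`RoundComparison` rows.

    ``frame`` renders the list as the fixed-column tidy table; items
    rated in only one round appear there with a null transition rather
    than being dropped.
    """

    def __init__(self, comparisons, null_items: Iterable[str] = ()):
        super().__init__(comparisons)
        self.null_items = list(null_items)

    @property
    def frame(self) -> pd.DataFrame:
        return comparisons_frame(self, null_items=self.null_items)


def comparisons_frame(
    comparisons: Iterable[RoundComparison],
    null_items: Iterable[str] = (),
) -> pd.DataFrame:
    """Tidy per-item comparison table (fixed column names)."""
    rows = [
        {
            "item_id": c.item_id,
            "parent_id": c.parent_id,
            "band_before": c.class_before.band,
            "band_after": c.class_after.band,
            "di_before": c.di_before,
            "di_after": c.di_after,
            "converged": c.converged_to_inappropriate,
        }
        for c in comparisons
    ]
    rows += [
        {
            "item_id": i, "parent_id": i, "band_before": None, "band_after": None,
            "di_before": None, "di_after": None, "converged": False,
        }
        for i in null_items
    ]
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)


def modified_transitions(
    classifications: Mapping[tuple[str, int], Classification],
    lineage: Iterable[ItemLineage],
    round_index: int = 2,
    di: Mapping[tuple[str, int], float] | None = None,
) -> tuple[pd.DataFrame, "ComparisonList"]:
    """Transitions of modified/split rewordings against their parents.

    Restricted to lineage children: each child's classification in
    ``round_index`` is compared against its parent's classification in
    the same round, showing what the rewording alone changed.  Children
    whose parent has no classification in that round (e.g. a split
    replacing its parent outright) are reported as null transitions.
    """
    di = di or {}
    comparisons: list[RoundComparison] = []
    null_rows: list[str] = []
    for ln in lineage:
        child = ln.child_item_id
        after = _lookup(classifications, child, round_index)
        if (ln.parent_item_id, round_index) not in classifications:
            null_rows.append(child)
            continue
        before = classifications[(ln.parent_item_id, round_index)]
        comparisons.append(
            RoundComparison(
                item_id=child,
                parent_id=ln.parent_item_id,
                class_before=before,
                class_after=after,
                di_before=di.get((ln.parent_item_id, round_index)),
                di_after=di.get((child, round_index)),
            )
        )
    matrix = pd.DataFrame(0, index=list(BANDS), columns=list(BANDS), dtype=int)
    for comp in comparisons:
        b, a = comp.transition
        matrix.loc[b, a] += 1
    return matrix, ComparisonList(comparisons, null_items=null_rows)


def converged_items(comparisons: Iterable[RoundComparison]) -> list[str]:
    """Item ids whose consensus converged from equivocal to inappropriate."""
    return [c.item_id for c in comparisons if c.converged_to_inappropriate]


def category_crosstab(
    classifications: Mapping[tuple[str, int], Classification],
    category_map: pd.DataFrame,
    agreement_band: str = "inappropriate",
) -> pd.DataFrame:
    """Per-category, per-round counts of agreement on a band.

    With the default band this reproduces the "number of items the
    panel agreed were inappropriate" (A/IA) tally by prescribing-problem
    category.  ``category_map`` has columns ``item_id, category_id[,
    category_label]``; every classified item must appear in it.
    """
    cat = category_map.set_index("item_id")
    rounds = sorted({r for (_, r) in classifications})
    counts: dict[str, dict[int, int]] = {}
    labels: dict[str, str] = {}
    for cid, sub in category_map.groupby("category_id", sort=False):
        counts[cid] = {r: 0 for r in rounds}
        labels[cid] = sub["category_label"].iloc[0] if "category_label" in sub else cid
    for (item, round_index), cls in classifications.items():
        if item not in cat.index:
            raise MappingError(f"item {item!r} has no entry in the category map")
        if cls.agreement == AGREEMENT and cls.band == agreement_band:
            counts[cat.loc[item, "category_id"]][round_index] += 1
    out = pd.DataFrame(
        [
            {"category_id": cid, "category_label": labels[cid],
             **{f"round{r}": counts[cid][r] for r in rounds}}
            for cid in counts
        ]
    )
    return out
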