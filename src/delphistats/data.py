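"""Data model and IO for multi-round expert-panel rating studies.

A rating study is a tidy table of integer scores: one row per
panellist x round x item x rating dimension, scores on the 9-point
appropriateness scale (1-3 inappropriate, 4-6 uncertain, 7-9
appropriate).  Two rating dimensions occur in appropriateness panels:
``appropriateness`` itself and, typically in a later round,
``feasibility`` of using the item in practice.

The canonical interchange format is delimiter-separated text with
columns ``panellist_id, round, item_id, dimension, rating`` (the
``dimension`` column may be omitted and defaults to appropriateness).
Item lineage — which later-round items are modified or split versions
of earlier items — and the item-category map travel in separate CSVs.
"""

from __future__ import annotations

import io
import os
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyPanelError,
    LinkageError,
    SchemaError,
    ValidationError,
)

DIMENSIONS = ("appropriateness", "feasibility")
LINEAGE_RELATIONS = ("identical", "modified", "split")

#: canonical column order of the tidy rating table
RATING_COLUMNS = ["panellist_id", "round", "item_id", "dimension", "rating"]


@dataclass(frozen=True)
class RatingRecord:
    """One panellist's integer score for one item in one round.

    ``rating`` is an integer on the 1-9 scale; the key
    ``(panellist_id, round, item_id, dimension)`` is unique within a
    study.
    """

    panellist_id: str
    round: int
    item_id: str
    dimension: str
    rating: int


@dataclass(frozen=True)
class ItemLineage:
    """Links a later-round item to the item it was derived from.

    ``relation`` is ``identical`` (re-rated unchanged), ``modified``
    (reworded) or ``split`` (one parent divided into several children).
    """

    child_item_id: str
    parent_item_id: str
    relation: str

    def __post_init__(self) -> None:
        if self.relation not in LINEAGE_RELATIONS:
            raise LinkageError(
                f"unknown lineage relation {self.relation!r} for item "
                f"{self.child_item_id!r}; expected one of {LINEAGE_RELATIONS}"
            )


class RatingStudy:
    """A validated multi-round panel rating study.

    Parameters
    ----------
    data
        Tidy DataFrame with columns ``panellist_id, round, item_id,
        dimension, rating``.
    items
        Optional item descriptor table (``item_id``, ``text``,
        ``category_id``).  Items present in ``data`` but absent here are
        added with empty descriptors.
    lineage
        Iterable of :class:`ItemLineage` linking later-round items to
        their parents.
    allow_new_panellists
        Whether a panellist may appear in round ``r+1`` without having
        rated in round ``r``.  Appropriateness panels keep a fixed
        panel with attrition only, so the default is ``False``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        items: pd.DataFrame | None = None,
        lineage: Iterable[ItemLineage] = (),
        allow_new_panellists: bool = False,
    ) -> None:
        self.data = _validate_ratings(data)
        self.lineage = validate_lineage(list(lineage))
        self.allow_new_panellists = allow_new_panellists
        self.items = _build_item_table(self.data, items)
        self._check_rosters()

    # -- derived views -------------------------------------------------
    @property
    def rounds(self) -> list[int]:
        return sorted(self.data["round"].unique())

    def roster(self, round_index: int) -> list[str]:
        """Panellists who contributed at least one rating in a round."""
        mask = self.data["round"] == round_index
        return sorted(self.data.loc[mask, "panellist_id"].unique())

    def item_ids(self, round_index: int | None = None) -> list[str]:
        if round_index is None:
            return sorted(self.data["item_id"].unique())
        mask = self.data["round"] == round_index
        return sorted(self.data.loc[mask, "item_id"].unique())

    @property
    def records(self) -> list[RatingRecord]:
        return [
            RatingRecord(r.panellist_id, int(r.round), r.item_id, r.dimension, int(r.rating))
            for r in self.data.itertuples(index=False)
        ]

    def ratings(self, item_id: str, round_index: int, dimension: str = "appropriateness") -> np.ndarray:
        """Integer scores for one item/round/dimension, order unspecified."""
        mask = (
            (self.data["item_id"] == item_id)
            & (self.data["round"] == round_index)
            & (self.data["dimension"] == dimension)
        )
        return self.data.loc[mask, "rating"].to_numpy()

    def parent_of(self, item_id: str) -> str:
        """Parent item id under the lineage; items without an entry are their own parent."""
        for ln in self.lineage:
            if ln.child_item_id == item_id:
                return ln.parent_item_id
        return item_id

    # -- IO ------------------------------------------------------------
    def to_csv(self, path: str | os.PathLike | io.TextIOBase, sep: str = ",") -> None:
        df = self.data.copy()
        self_sorted = df.sort_values(RATING_COLUMNS, kind="stable")
        self_sorted.to_csv(path, sep=sep, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        rounds = ", ".join(
            f"round {r}: {len(self.roster(r))} panellists x {len(self.item_ids(r))} items"
            for r in self.rounds
        )
        return f"<RatingStudy {len(self.data)} ratings ({rounds})>"

    def _check_rosters(self) -> None:
        if self.allow_new_panellists:
            return
        rounds = self.rounds
        for earlier, later in zip(rounds, rounds[1:]):
            new = set(self.roster(later)) - set(self.roster(earlier))
            if new:
                raise ValidationError(
                    f"panellists {sorted(new)} appear in round {later} but not "
                    f"round {earlier}; pass allow_new_panellists=True to permit late additions"
                )


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def _validate_ratings(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RATING_COLUMNS if c not in df.columns and c != "dimension"]
    if missing:
        raise SchemaError(f"rating table is missing required column(s) {missing}")
    df = df.copy()
    if "dimension" not in df.columns:
        df["dimension"] = "appropriateness"
    df = df[RATING_COLUMNS]

    bad_dim = sorted(set(df["dimension"].unique()) - set(DIMENSIONS))
    if bad_dim:
        raise ValidationError(f"unknown rating dimension(s) {bad_dim}; expected {DIMENSIONS}")

    for col, kind in (("rating", "rating"), ("round", "round index")):
        numeric = pd.to_numeric(df[col], errors="coerce")
        nonint = df.index[numeric.isna() | (numeric != numeric.round())]
        if len(nonint):
            row = nonint[0]
            raise ValidationError(
                f"non-integer {kind} {df.loc[row, col]!r} at row {row}"
            )
        df[col] = numeric.astype(int)

    out = df.index[(df["rating"] < 1) | (df["rating"] > 9)]
    if len(out):
        row = out[0]
        raise ValidationError(
            f"rating {df.loc[row, 'rating']} out of range [1, 9] at row {row}"
        )
    if (df["round"] < 1).any():
        row = df.index[df["round"] < 1][0]
        raise ValidationError(f"round index must be >= 1 (row {row})")

    df["panellist_id"] = df["panellist_id"].astype(str)
    df["item_id"] = df["item_id"].astype(str)

    key = ["panellist_id", "round", "item_id", "dimension"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        rows = list(df.index[dup][:2])
        k = df.loc[rows[0], key].tolist()
        raise ValidationError(
            f"duplicate rating for key {tuple(k)} at rows {rows[0]} and {rows[1]}"
        )
    return df.reset_index(drop=True)


def _build_item_table(data: pd.DataFrame, items: pd.DataFrame | None) -> pd.DataFrame:
    rated = pd.DataFrame({"item_id": sorted(data["item_id"].unique())})
    if items is None:
        items = rated.assign(text="", category_id="")
    else:
        items = items.copy()
        if "item_id" not in items.columns:
            raise SchemaError("item table is missing required column(s) ['item_id']")
        items["item_id"] = items["item_id"].astype(str)
        for col in ("text", "category_id"):
            if col not in items.columns:
                items[col] = ""
        unknown = set(rated["item_id"]) - set(items["item_id"])
        if unknown:
            extra = pd.DataFrame({"item_id": sorted(unknown), "text": "", "category_id": ""})
            items = pd.concat([items, extra], ignore_index=True)
    return items[["item_id", "text", "category_id"]].reset_index(drop=True)


def validate_lineage(lineage: Sequence[ItemLineage]) -> list[ItemLineage]:
    """Check that every child has one parent and the graph is acyclic.

    ``split`` relations must come in groups: at least two children
    sharing a parent.
    """
    parents: dict[str, str] = {}
    for ln in lineage:
        if ln.child_item_id in parents:
            raise LinkageError(
                f"item {ln.child_item_id!r} has more than one parent in the lineage"
            )
        parents[ln.child_item_id] = ln.parent_item_id

    # acyclicity: follow parent chains, which must terminate
    for child in parents:
        seen = {child}
        cur = child
        while cur in parents:
            cur = parents[cur]
            if cur in seen:
                raise LinkageError(f"lineage cycle detected through item {child!r}")
            seen.add(cur)

    split_children: dict[str, int] = {}
    for ln in lineage:
        if ln.relation == "split":
            split_children[ln.parent_item_id] = split_children.get(ln.parent_item_id, 0) + 1
    lonely = [p for p, k in split_children.items() if k < 2]
    if lonely:
        raise LinkageError(
            f"split parent(s) {lonely} have fewer than two split children"
        )
    return list(lineage)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DEFAULT_SCHEMA = {c: c for c in RATING_COLUMNS}


def _read_table(source, sep: str | None = None) -> pd.DataFrame:
    """Read CSV/TSV, autodetecting the delimiter from the extension."""
    if sep is None:
        name = getattr(source, "name", source)
        sep = "\t" if str(name).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(source, sep=sep, dtype=str)


def read_ratings(
    source,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
    lineage: Iterable[ItemLineage] = (),
    items: pd.DataFrame | None = None,
    allow_new_panellists: bool = False,
) -> RatingStudy:
    """Read a tidy rating table into a validated :class:`RatingStudy`.

    ``schema`` maps canonical column names (``panellist_id``, ``round``,
    ``item_id``, ``dimension``, ``rating``) to the names used in the
    file; unmapped columns are expected under their canonical names.
    Row order in the file never affects a downstream statistic.
    """
    df = _read_table(source, sep=sep)
    mapping = dict(_DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(RATING_COLUMNS)
        if unknown:
            raise SchemaError(f"schema maps unknown canonical column(s) {sorted(unknown)}")
        mapping.update(schema)
    for canonical, actual in mapping.items():
        if canonical == "dimension" and actual not in df.columns:
            continue  # optional column
        if actual not in df.columns:
            raise SchemaError(
                f"required column {actual!r} (for {canonical!r}) not found in input; "
                f"available columns: {list(df.columns)}"
            )
    renamed = df.rename(columns={v: k for k, v in mapping.items()})
    return RatingStudy(
        renamed, items=items, lineage=lineage, allow_new_panellists=allow_new_panellists
    )


def read_wide_ratings(
    source,
    round_index: int,
    dimension: str = "appropriateness",
    id_column: str = "panellist_id",
    sep: str | None = None,
    **study_kwargs,
) -> RatingStudy:
    """Convenience importer for wide-format exports (one column per item).

    Survey platforms commonly export one row per panellist with one
    column per item; this melts such a table into the tidy format for a
    single round and dimension.  Empty cells are treated as skipped
    items and dropped.
    """
    df = _read_table(source, sep=sep)
    if id_column not in df.columns:
        raise SchemaError(f"required column {id_column!r} not found in input")
    long = df.melt(id_vars=[id_column], var_name="item_id", value_name="rating")
    long = long.dropna(subset=["rating"])
    long = long.rename(columns={id_column: "panellist_id"})
    long["round"] = round_index
    long["dimension"] = dimension
    return RatingStudy(long[RATING_COLUMNS], **study_kwargs)


def read_lineage(source, sep: str | None = None) -> list[ItemLineage]:
    """Read a lineage CSV with columns ``child_id, parent_id, relation``."""
    df = _read_table(source, sep=sep)
    required = ["child_id", "parent_id", "relation"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"lineage table is missing required column(s) {missing}")
    lineage = [
        ItemLineage(str(r.child_id), str(r.parent_id), str(r.relation))
        for r in df.itertuples(index=False)
    ]
    return validate_lineage(lineage)


def read_categories(source, sep: str | None = None) -> pd.DataFrame:
    """Read an item-category map (``item_id, category_id[, category_label]``)."""
    df = _read_table(source, sep=sep)
    required = ["item_id", "category_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"category table is missing required column(s) {missing}")
    if "category_label" not in df.columns:
        df["category_label"] = df["category_id"]
    dup = df.duplicated(subset=["item_id"], keep=False)
    if dup.any():
        raise ValidationError(
            f"item(s) {sorted(df.loc[dup, 'item_id'].unique())} mapped to more than one category"
        )
    return df[["item_id", "category_id", "category_label"]].astype(str)


# ---------------------------------------------------------------------------
# elementary statistics on raw scores
# ---------------------------------------------------------------------------

def bin_counts(ratings: Iterable[int]) -> tuple[int, int, int]:
    """Counts of ratings falling in the 1-3, 4-6 and 7-9 scale regions.

    These are the three interpretive regions of the 9-point
    appropriateness scale (inappropriate / uncertain / appropriate) and
    are reported alongside the median and disagreement index.
    """
    arr = np.asarray(list(ratings))
    if arr.size == 0:
        raise EmptyPanelError("cannot bin an empty set of ratings")
    if np.any((arr < 1) | (arr > 9)):
        raise ValidationError("ratings outside [1, 9] cannot be binned")
    low = int(np.count_nonzero(arr <= 3))
    high = int(np.count_nonzero(arr >= 7))
    mid = int(arr.size - low - high)
    return (low, mid, high)
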