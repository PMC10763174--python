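"""Render per-item and study-level results in the conventional table shapes.

The canonical appropriateness-study row reads

    2 (2, 2) | 19 0 0 | A/IA (0.203)

i.e. median (P30, P70), the 1-3/4-6/7-9 rating counts, and the
consensus label with the disagreement index.  Display rounding happens
only here: DI to three decimals (half-even), medians and percentiles to
one decimal and only when non-integer.  All renderings are
deterministic byte-for-byte given the same inputs.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Mapping

import pandas as pd

from .data import ItemLineage
from .stats import Classification, ItemSummary

FORMATS = ("csv", "tsv", "md")


def fmt_score(x: float) -> str:
    """Scale value at display precision: integer, else one decimal."""
    return str(int(x)) if float(x) == int(x) else f"{float(x):.1f}"


def fmt_di(x: float) -> str:
    """Disagreement index at three decimals (round-half-even)."""
    return f"{float(x):.3f}"


def summary_cell(summary: ItemSummary, cls: Classification) -> str:
    """One item-round rendered in the conventional row shape."""
    b1, b2, b3 = summary.bins
    return (
        f"{fmt_score(summary.median)} ({fmt_score(summary.p_low)}, "
        f"{fmt_score(summary.p_high)}) | {b1} {b2} {b3} | "
        f"{cls.label} ({fmt_di(summary.di)})"
    )


def _ordered_items(
    item_rounds: Iterable[tuple[str, int]],
    lineage: Iterable[ItemLineage],
) -> list[str]:
    """Items sorted with lineage children as sub-rows after their parent."""
    items = sorted({i for i, _ in item_rounds})
    parent = {ln.child_item_id: ln.parent_item_id for ln in lineage}
    roots = [i for i in items if i not in parent]
    order: list[str] = []
    for root in roots:
        order.append(root)
        order.extend(c for c in items if parent.get(c) == root)
    order.extend(i for i in items if i not in order)  # orphans, defensively
    return order


def build_item_report(
    summaries: Mapping[tuple[str, int], ItemSummary],
    classifications: Mapping[tuple[str, int], Classification],
    lineage: Iterable[ItemLineage] = (),
    converged: Iterable[str] = (),
) -> pd.DataFrame:
    """One row per item, rounds side by side, children under parents."""
    rounds = sorted({r for _, r in summaries})
    converged = set(converged)
    rows = []
    for item in _ordered_items(summaries.keys(), lineage):
        row: dict[str, object] = {"item_id": item}
        for r in rounds:
            key = (item, r)
            row[f"round{r}"] = (
                summary_cell(summaries[key], classifications[key])
                if key in summaries
                else ""
            )
        row["converged"] = "*" if item in converged else ""
        rows.append(row)
    return pd.DataFrame(rows)


def _emit(frame: pd.DataFrame, fmt: str) -> str:
    if fmt not in FORMATS:
        raise ValueError(f"unknown output format {fmt!r}; expected one of {FORMATS}")
    if fmt in ("csv", "tsv"):
        buf = io.StringIO()
        frame.to_csv(buf, sep="," if fmt == "csv" else "\t", index=False)
        return buf.getvalue()
    return _markdown_grid(frame)


def _markdown_grid(frame: pd.DataFrame) -> str:
    cols = [str(c) for c in frame.columns]
    cells = [[("" if pd.isna(v) else str(v)) for v in row] for row in frame.itertuples(index=False)]
    widths = [
        max(len(cols[j]), *(len(r[j]) for r in cells)) if cells else len(cols[j])
        for j in range(len(cols))
    ]
    def line(values):
        return "| " + " | ".join(v.ljust(w) for v, w in zip(values, widths)) + " |"
    out = [line(cols), "| " + " | ".join("-" * w for w in widths) + " |"]
    out += [line(r) for r in cells]
    return "\n".join(out) + "\n"


def render_item_table(
    summaries: Mapping[tuple[str, int], ItemSummary],
    classifications: Mapping[tuple[str, int], Classification],
    lineage: Iterable[ItemLineage] = (),
    converged: Iterable[str] = (),
    fmt: str = "md",
) -> str:
    """Delimited or grid rendering of the per-item consensus table."""
    return _emit(build_item_report(summaries, classifications, lineage, converged), fmt)


def render_crosstab(crosstab: pd.DataFrame, fmt: str = "md") -> str:
    """Render a category cross-tabulation; counts survive a parse round-trip."""
    return _emit(crosstab, fmt)


def parse_crosstab(text: str, fmt: str = "csv") -> pd.DataFrame:
    """Parse a rendered csv/tsv crosstab back to its numeric form."""
    if fmt not in ("csv", "tsv"):
        raise ValueError("parse-back is supported for delimited formats only")
    return pd.read_csv(io.StringIO(text), sep="," if fmt == "csv" else "\t")


def output_name(study: str, round_index: int, dimension: str, fmt: str) -> str:
    """Conventional artifact file name ``<study>_round<k>_<dimension>.<ext>``."""
    return f"{study}_round{round_index}_{dimension}.{fmt}"
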