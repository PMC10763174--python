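"""Bundled reference data: the opioid-prescribing e-Delphi consensus tables.

A published two-round e-Delphi study on opioid prescribing-safety
indicators (24 UK panellists in round 1 rating 20 scenarios, 19 in
round 2 re-rating them plus 13 modified/split rewordings) reports only
its per-item summary statistics — median, 30th/70th percentiles, bin
counts, consensus label and disagreement index — not the raw ratings.
Those printed summaries are bundled here as inputs for desk-checking
the classification, convergence and cross-tabulation machinery against
a real study.

Item ids ``1``-``20`` are the original scenarios; ``<k>m`` is the
round-2 modified rewording of scenario ``k``; ``9a``/``9b`` are the two
halves of the split scenario 9 (SSRI/SNRI vs MAOI co-prescription).
The printed DI values were computed by the study authors from
unrounded percentiles, so they are not exactly recomputable from the
rounded percentile pairs printed alongside them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data import ItemLineage, read_categories, read_lineage
from .stats import Classification


def _path(name: str):
    return resources.files(__package__) / "datasets" / name


def load_summaries() -> pd.DataFrame:
    """Published per-item summary rows for both rounds.

    Columns: ``item_id, round, variant, median, p_low, p_high,
    bin_low, bin_mid, bin_high, label, di, modified, converged``.
    ``variant`` is ``original`` or ``modified``; ``converged`` marks the
    items the study flagged as converging to agreement-on-
    inappropriateness (between rounds for originals, relative to the
    unmodified parent for rewordings).
    """
    with resources.as_file(_path("opioid_delphi_summaries.csv")) as p:
        df = pd.read_csv(p, dtype={"item_id": str})
    df["modified"] = df["modified"].astype(bool)
    df["converged"] = df["converged"].astype(bool)
    return df


def load_lineage() -> list[ItemLineage]:
    """Lineage of the 13 round-2 rewordings (11 modified, 1 split pair)."""
    with resources.as_file(_path("opioid_delphi_lineage.csv")) as p:
        return read_lineage(p)


def load_categories() -> pd.DataFrame:
    """Prescribing-problem category for each of the 20 original scenarios."""
    with resources.as_file(_path("opioid_delphi_categories.csv")) as p:
        return read_categories(p)


def load_study_shape_config():
    """The bundled simulation config mirroring the study's design shape."""
    from .simulate import SimulationConfig

    with resources.as_file(_path("study_shape.yaml")) as p:
        return SimulationConfig.from_file(p)


def printed_classifications(
    variant: str | None = None,
) -> dict[tuple[str, int], Classification]:
    """The study's printed consensus labels, parsed per (item, round)."""
    df = load_summaries()
    if variant is not None:
        df = df[df["variant"] == variant]
    return {
        (r.item_id, int(r.round)): Classification.from_label(r.label)
        for r in df.itertuples(index=False)
    }
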