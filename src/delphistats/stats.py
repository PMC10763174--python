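"""RAND/UCLA appropriateness statistics.

For each item the panel's scores (integers 1-9) are reduced to the
median and the 30th/70th percentiles.  Disagreement is judged with the
disagreement index

    DI = IPR / IPRAS

where ``IPR = P70 - P30`` is the interpercentile range and

    IPRAS = 2.35 + 1.5 * AI,      AI = |5 - IPRCP|,
    IPRCP = (P30 + P70) / 2

is the interpercentile range adjusted for symmetry: a rating
distribution whose central mass sits away from the scale midpoint is
allowed a wider IPR before the panel is called split.  ``DI < 1``
denotes agreement; the median then places the item in the
inappropriate (1-3), equivocal (4-6) or appropriate (7-9) band.

All computation runs at full floating precision; rounding happens only
in :mod:`delphistats.reporting`.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass
import numpy as np
import yaml

from .data import bin_counts
from .errors import ConfigError, DomainError, EmptyPanelError, ValidationError

#: scale midpoint of the 1-9 appropriateness scale
SCALE_MIDPOINT = 5.0

#: names accepted for the percentile interpolation rule, mapped to the
#: corresponding numpy.quantile method.  "linear" interpolates at
#: 1-based position (n-1)q + 1, "nearest_rank" takes the ceil(nq)-th
#: order statistic, "weibull" interpolates at position (n+1)q.
PERCENTILE_METHODS: dict[str, str] = {
    "linear": "linear",
    "nearest_rank": "inverted_cdf",
    "weibull": "weibull",
}

AGREEMENT = "agreement"
DISAGREEMENT = "disagreement"
BANDS = ("inappropriate", "equivocal", "appropriate")


@dataclass(frozen=True)
class ClassificationConfig:
    """Tunable constants of the consensus rule.

    The defaults reproduce the standard appropriateness-method
    convention: 30th/70th percentiles, linear interpolation, DI
    threshold 1, band edges at 3.5 and 6.5 on the median, IPRAS
    constants 2.35 and 1.5.
    """

    q_low: float = 0.30
    q_high: float = 0.70
    method: str = "linear"
    di_threshold: float = 1.0
    band_low_edge: float = 3.5
    band_high_edge: float = 6.5
    ipras_intercept: float = 2.35
    ipras_slope: float = 1.5

    def __post_init__(self) -> None:
        if not (0.0 < self.q_low < 1.0 and 0.0 < self.q_high < 1.0):
            raise ConfigError("percentile fractions must lie strictly in (0, 1)")
        if self.q_low > self.q_high:
            raise ConfigError("q_low must not exceed q_high")
        if self.method not in PERCENTILE_METHODS:
            raise ConfigError(
                f"unknown percentile method {self.method!r}; "
                f"expected one of {sorted(PERCENTILE_METHODS)}"
            )
        if self.di_threshold <= 0:
            raise ConfigError("di_threshold must be positive")
        if not (self.band_low_edge < self.band_high_edge):
            raise ConfigError("band_low_edge must be below band_high_edge")

    @classmethod
    def from_file(cls, path) -> "ClassificationConfig":
        """Load overrides from a YAML/JSON mapping (unknown keys rejected)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"classification config {path!r} must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown classification config key(s) {sorted(unknown)}")
        return cls(**raw)


DEFAULT_CONFIG = ClassificationConfig()


@dataclass(frozen=True)
class ItemSummary:
    """Per-item, per-round statistics block."""

    item_id: str
    round: int
    dimension: str
    n: int
    median: float
    p_low: float
    p_high: float
    ipr: float
    iprcp: float
    ai: float
    ipras: float
    di: float
    bins: tuple[int, int, int]


@dataclass(frozen=True)
class Classification:
    """Consensus verdict for one item: agreement status x median band."""

    agreement: str
    band: str
    label: str

    @classmethod
    def from_label(cls, label: str) -> "Classification":
        """Parse a printed consensus label (``A/IA``, ``Neutral``, ``A/A``,
        ``Disagreement``) back into a Classification."""
        key = label.strip()
        table = {
            "A/IA": (AGREEMENT, "inappropriate"),
            "Neutral": (AGREEMENT, "equivocal"),
            "A/A": (AGREEMENT, "appropriate"),
            "Disagreement": (DISAGREEMENT, ""),
        }
        if key not in table:
            raise ValidationError(f"unrecognised consensus label {label!r}")
        agreement, band = table[key]
        return cls(agreement, band, key)


def percentile(
    scores: Iterable[int],
    q: float,
    method: str = "linear",
) -> float:
    """Sample percentile of a set of panel scores.

    ``q`` is a fraction strictly inside (0, 1).  The default rule
    interpolates linearly at 1-based position ``(n-1)q + 1`` of the
    sorted sample (the common spreadsheet/numpy convention); see
    :data:`PERCENTILE_METHODS` for alternatives.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise EmptyPanelError("cannot take a percentile of an empty panel")
    if not (0.0 < q < 1.0):
        raise DomainError(f"percentile fraction must lie in (0, 1), got {q}")
    if method not in PERCENTILE_METHODS:
        raise ConfigError(
            f"unknown percentile method {method!r}; expected one of {sorted(PERCENTILE_METHODS)}"
        )
    return float(np.quantile(arr, q, method=PERCENTILE_METHODS[method]))


def disagreement_index(
    p_low: float,
    p_high: float,
    config: ClassificationConfig = DEFAULT_CONFIG,
) -> tuple[float, float, float, float, float]:
    """Disagreement-index decomposition from a percentile pair.

    Returns ``(ipr, iprcp, ai, ipras, di)``.  ``di = ipr / ipras`` with
    ``ipras = intercept + slope * |midpoint - iprcp|``; with the default
    constants a perfectly symmetric full-spread panel (P30=1, P70=9)
    reaches the maximal DI of 8/2.35.
    """
    if p_low > p_high:
        raise DomainError(f"p_low ({p_low}) exceeds p_high ({p_high})")
    ipr = p_high - p_low
    iprcp = (p_low + p_high) / 2.0
    ai = abs(SCALE_MIDPOINT - iprcp)
    ipras = config.ipras_intercept + config.ipras_slope * ai
    di = ipr / ipras
    return (ipr, iprcp, ai, ipras, di)


def summarize_item(
    ratings: Iterable[int],
    item_id: str = "",
    round_index: int = 1,
    dimension: str = "appropriateness",
    config: ClassificationConfig = DEFAULT_CONFIG,
) -> ItemSummary:
    """Full statistics block (median, percentiles, DI, bin counts) for one item."""
    arr = np.asarray(list(ratings), dtype=float)
    if arr.size == 0:
        raise EmptyPanelError(f"no ratings for item {item_id!r}")
    med = float(np.median(arr))
    p_lo = percentile(arr, config.q_low, config.method)
    p_hi = percentile(arr, config.q_high, config.method)
    ipr, iprcp, ai, ipras, di = disagreement_index(p_lo, p_hi, config)
    return ItemSummary(
        item_id=item_id,
        round=round_index,
        dimension=dimension,
        n=int(arr.size),
        median=med,
        p_low=p_lo,
        p_high=p_hi,
        ipr=ipr,
        iprcp=iprcp,
        ai=ai,
        ipras=ipras,
        di=di,
        bins=bin_counts(arr.astype(int)),
    )


def band_of(median: float, config: ClassificationConfig = DEFAULT_CONFIG) -> str:
    """Appropriateness band of a median score.

    Medians can be half-integers; a median strictly below 3.5 is
    inappropriate, strictly above 6.5 appropriate, anything else
    (including exactly 3.5 or 6.5) equivocal.
    """
    if median < config.band_low_edge:
        return "inappropriate"
    if median > config.band_high_edge:
        return "appropriate"
    return "equivocal"


def classify(
    summary: ItemSummary | None = None,
    *,
    median: float | None = None,
    di: float | None = None,
    config: ClassificationConfig = DEFAULT_CONFIG,
) -> Classification:
    """Consensus classification from a summary or a bare (median, DI) pair.

    DI below the threshold (default 1) means the panel agrees; the
    median then selects the band.  DI exactly at the threshold counts
    as disagreement.  Labels follow the appropriateness-study
    convention: ``A/IA`` agreement-on-inappropriateness, ``Neutral``
    agreement-on-equivocality, ``A/A`` agreement-on-appropriateness,
    ``Disagreement`` otherwise.
    """
    if summary is not None:
        median, di = summary.median, summary.di
    if median is None or di is None:
        raise DomainError("classify needs either a summary or both median= and di=")
    if di >= config.di_threshold:
        return Classification(DISAGREEMENT, band_of(median, config), "Disagreement")
    band = band_of(median, config)
    label = {"inappropriate": "A/IA", "equivocal": "Neutral", "appropriate": "A/A"}[band]
    return Classification(AGREEMENT, band, label)


def summarize_study(
    study,
    dimension: str = "appropriateness",
    config: ClassificationConfig = DEFAULT_CONFIG,
) -> dict[tuple[str, int], ItemSummary]:
    """Summaries for every (item, round) with ratings on a dimension."""
    out: dict[tuple[str, int], ItemSummary] = {}
    for round_index in study.rounds:
        for item_id in study.item_ids(round_index):
            scores = study.ratings(item_id, round_index, dimension)
            if scores.size == 0:
                continue
            out[(item_id, round_index)] = summarize_item(
                scores, item_id=item_id, round_index=round_index,
                dimension=dimension, config=config,
            )
    return out
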