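"""Evaluation metrics: coverage, expression reduction, label statistics and
the duplicate-identification histogram.

Reduction is computed as 1 - (distinct normalized expressions / distinct raw
expressions among successfully normalized inputs); distinctness of raw
expressions is string identity of (type, subject tokens, object tokens),
while normalized expressions fold a relationship and its inverse twin into
one.  This convention is ours: the source material reports the metric
without printing a formula.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import asdict, dataclass
from typing import Iterable, Optional, Sequence

from .normalize import NormalizationOutcome, RawRelationship
from .ontology import Ontology

DEFAULT_BINS: tuple[tuple[int, Optional[int]], ...] = ((2, 5), (5, 10), (10, None))


class UndefinedMetricError(ValueError):
    """The metric is undefined on this input (e.g. empty denominator)."""


@dataclass
class MetricsReport:
    n_entity_types: int
    n_roles: int
    labels_per_entity_type: float
    labels_per_role: float
    reduction: float
    coverage: float
    duplicate_histogram: dict[str, int]

    def to_dict(self) -> dict:
        return asdict(self)


def coverage(raws: Sequence[RawRelationship], outcome: NormalizationOutcome) -> float:
    """Fraction of raw relationships successfully normalized."""
    if len(raws) == 0:
        raise UndefinedMetricError("coverage is undefined on empty input")
    return len(outcome.normalized_sources) / len(raws)


def reduction(raws: Sequence[RawRelationship], outcome: NormalizationOutcome) -> float:
    if not outcome.normalized_sources:
        raise UndefinedMetricError("reduction is undefined with zero normalized inputs")
    distinct_in = len({raw.surface_key() for raw in outcome.normalized_sources})
    distinct_out = outcome.n_expressions
    return 1.0 - distinct_out / distinct_in


def label_stats(onto: Ontology) -> tuple[float, float]:
    """Arithmetic mean label-set size (preferred + alternatives) per entity
    type and per role."""
    if not onto.entity_types or not onto.roles:
        raise UndefinedMetricError("label statistics need at least one type and one role")
    per_type = sum(len(et.labels) for et in onto.entity_types.values()) / len(
        onto.entity_types
    )
    per_role = sum(len(r.labels) for r in onto.roles.values()) / len(onto.roles)
    return per_type, per_role


def _bin_label(lo: int, hi: Optional[int]) -> str:
    return f"{lo}<=n<{hi}" if hi is not None else f"n>={lo}"


def histogram_from_multiplicities(
    multiplicities: Iterable[int],
    bins: Sequence[tuple[int, Optional[int]]] = DEFAULT_BINS,
) -> dict[str, int]:
    out = {_bin_label(lo, hi): 0 for lo, hi in bins}
    for m in multiplicities:
        for lo, hi in bins:
            if m >= lo and (hi is None or m < hi):
                out[_bin_label(lo, hi)] += 1
                break
    return out


def duplicate_histogram(
    data,
    bins: Sequence[tuple[int, Optional[int]]] = DEFAULT_BINS,
    count_records: bool = False,
) -> dict[str, int]:
    """Histogram of equivalence-class multiplicities.

    ``data`` is either a sequence of raw relationships (equivalence = exact
    string identity of type/subject/object) or a NormalizationOutcome
    (equivalence = identity of the normalized expression).  By default each
    class counts once per bin; ``count_records`` switches to counting the
    records inside the classes.
    """
    if isinstance(data, NormalizationOutcome):
        counts = Counter(data.expression_counts)
    else:
        counts = Counter(raw.surface_key() for raw in data)
    if count_records:
        out = {_bin_label(lo, hi): 0 for lo, hi in bins}
        for m in counts.values():
            for lo, hi in bins:
                if m >= lo and (hi is None or m < hi):
                    out[_bin_label(lo, hi)] += m
                    break
        return out
    return histogram_from_multiplicities(counts.values(), bins)


def metrics_report(
    raws: Sequence[RawRelationship],
    outcome: NormalizationOutcome,
    onto: Ontology,
) -> MetricsReport:
    per_type, per_role = label_stats(onto)
    return MetricsReport(
        n_entity_types=len(onto.entity_types),
        n_roles=len(onto.roles),
        labels_per_entity_type=per_type,
        labels_per_role=per_role,
        reduction=reduction(raws, outcome),
        coverage=coverage(raws, outcome),
        duplicate_histogram=duplicate_histogram(outcome),
    )
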