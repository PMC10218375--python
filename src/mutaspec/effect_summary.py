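"""Gene-effect summaries from annotator output.

Annotated variants carry a genomic region (intergenic, up/downstream,
exon, intron, ...), an impact level (MODIFIER / LOW / MODERATE / HIGH) and,
for coding substitutions, a functional class (missense / nonsense /
silent).  Summaries restrict region comparisons between mutagen groups to
the *commonly affected regions* — region labels observed in every group —
and always report the share of effects that restriction retains, so the
comparison is auditable.  Counting is annotation-level: a variant annotated
against several genes contributes one count per annotation.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .exceptions import ConfigurationError
from .variant_io import IMPACT_LEVELS, AnnotationRecord

__all__ = [
    "EffectSummary",
    "common_regions",
    "region_proportions",
    "impact_level_counts",
    "functional_class_counts",
    "functional_class_ratio",
    "summarize_effects",
]


@dataclass
class EffectSummary:
    """Region / impact / functional-class tallies for one group."""

    group_label: str = ""
    zygosity_scope: str = ""
    region_counts: dict[str, int] = field(default_factory=dict)
    impact_counts: dict[str, int] = field(default_factory=dict)
    class_counts: dict[str, int] = field(default_factory=dict)
    common_region_share: float = float("nan")


def _region_counter(records: Iterable[AnnotationRecord]) -> Counter:
    return Counter(r.region for r in records)


def common_regions(region_sets: Mapping[str, Iterable[str]]) -> set[str]:
    """Region labels observed (nonzero) in every group.

    With an empty intersection the union is returned with a warning rather
    than silently dropping all effects.
    """
    if len(region_sets) < 2:
        raise ConfigurationError("need >= 2 groups to intersect regions")
    sets = [set(labels) for labels in region_sets.values()]
    shared = set.intersection(*sets)
    if not shared:
        warnings.warn(
            "no region label is shared by all groups; falling back to the union",
            stacklevel=2,
        )
        return set.union(*sets)
    return shared


def region_proportions(region_counts: Mapping[str, int], regions: Iterable[str] | None = None) -> dict[str, float]:
    """Percentage of effects per region, restricted to ``regions`` if given."""
    if regions is not None:
        region_counts = {r: region_counts.get(r, 0) for r in regions}
    total = sum(region_counts.values())
    if total == 0:
        raise ConfigurationError("no effects in the selected regions")
    return {r: 100.0 * n / total for r, n in sorted(region_counts.items())}


def impact_level_counts(records: Iterable[AnnotationRecord]) -> dict[str, int]:
    """Counts per impact level (all four levels always present)."""
    counter = Counter(r.impact for r in records)
    return {level: counter.get(level, 0) for level in IMPACT_LEVELS}


def functional_class_counts(records: Iterable[AnnotationRecord]) -> dict[str, int]:
    counter = Counter(
        r.functional_class for r in records if r.functional_class != "none"
    )
    return {c: counter.get(c, 0) for c in ("missense", "nonsense", "silent")}


def functional_class_ratio(class_counts: Mapping[str, int]) -> float:
    """Missense-to-silent ratio; ``inf`` flags a zero silent count."""
    silent = class_counts.get("silent", 0)
    missense = class_counts.get("missense", 0)
    if silent == 0:
        return float("inf") if missense else float("nan")
    return missense / silent


def summarize_effects(
    groups: Mapping[str, Sequence[AnnotationRecord]],
    zygosity_scope: str = "",
) -> dict[str, EffectSummary]:
    """Per-group effect summaries with region counts restricted to the
    commonly affected regions; the retained share is recorded per group."""
    if not groups:
        raise ConfigurationError("no annotation groups supplied")
    counters = {g: _region_counter(records) for g, records in groups.items()}
    if len(groups) >= 2:
        shared = common_regions({g: c.keys() for g, c in counters.items()})
    else:
        shared = set(next(iter(counters.values())).keys())
    out: dict[str, EffectSummary] = {}
    for group, records in groups.items():
        counter = counters[group]
        total = sum(counter.values())
        restricted = {r: counter.get(r, 0) for r in sorted(shared)}
        share = 100.0 * sum(restricted.values()) / total if total else float("nan")
        out[group] = EffectSummary(
            group_label=group,
            zygosity_scope=zygosity_scope,
            region_counts=restricted,
            impact_counts=impact_level_counts(records),
            class_counts=functional_class_counts(records),
            common_region_share=share,
        )
    return out
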