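"""Mutation-spectrum classification, summaries and cross-mutagen tests.

Retained mutations fall into four top-level categories — single-base
substitutions (SBS), small insertions/deletions (INDEL, length change <= 50
bp), multinucleotide variants (MNV, merged adjacent substitutions) and
structural variants (> 50 bp: DEL_SV, DUP_SV, or breakends BND_SV).  This
module tabulates category counts per mutagen group and per line, the
transition/transversion ratio (with MNV constituents excluded), length-class
breakdowns, genotype-group fractions, and the chi-squared / Student's t
comparisons between mutagens.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DataError, InapplicableTestError
from .pipeline import LineMutationSet, Mnv

__all__ = [
    "CATEGORIES",
    "SpectrumSummary",
    "classify_variant",
    "ts_tv_counts",
    "ts_tv_ratio",
    "length_class_breakdown",
    "aggregate",
    "homozygous_fraction",
    "category_proportion",
    "sv_proportion",
    "chi_squared_test",
    "two_sample_t_test",
    "significance_label",
    "phenotype_proportions",
    "error_band",
]

CATEGORIES = (
    "SBS",
    "INDEL_deletion",
    "INDEL_insertion",
    "MNV",
    "DEL_SV",
    "DUP_SV",
    "BND_SV",
)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def classify_variant(call) -> str:
    """Assign one of the seven spectrum categories to a call.

    Equal-length single-base alleles are SBS; equal-length multi-base
    alleles (and merged runs) are MNV; a length change of at most 50 bp is
    an INDEL (deletion when the reference is longer); symbolic/breakend
    records keep their SV sub-type.
    """
    if isinstance(call, Mnv):
        return "MNV"
    if call.sv_type is not None:
        return call.sv_type
    lr, la = len(call.ref), len(call.alt)
    if lr == la == 1:
        return "SBS"
    if lr == la:
        return "MNV"
    if abs(lr - la) <= 50:
        return "INDEL_deletion" if lr > la else "INDEL_insertion"
    raise DataError(
        f"unclassifiable allele pair {call.ref!r}>{call.alt!r} "
        f"(length change > 50 bp without SV type)"
    )


def _indel_length(call) -> int:
    return abs(len(call.ref) - len(call.alt))


# ---------------------------------------------------------------------------
# Ts/Tv
# ---------------------------------------------------------------------------


def ts_tv_counts(sbs_calls: Iterable) -> tuple[int, int]:
    """Count transitions (A<->G, C<->T) and transversions."""
    ts = tv = 0
    for call in sbs_calls:
        pair = (call.ref.upper(), call.alt.upper())
        if pair in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    return ts, tv


def ts_tv_ratio(sbs_calls: Iterable) -> float:
    """Transition/transversion ratio over standalone SBSs.

    Constituents of merged MNVs must already be excluded (they never count).
    Returns ``inf`` when there are transitions but no transversions and
    ``nan`` for an empty input — both flag an undefined ratio.
    """
    ts, tv = ts_tv_counts(sbs_calls)
    if tv == 0:
        return float("inf") if ts else float("nan")
    return ts / tv


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass
class SpectrumSummary:
    """Category counts (and sub-classifications) for a group of lines."""

    group_label: str
    zygosity_scope: str
    counts: dict[str, int] = field(default_factory=dict)
    sub_counts: dict[str, int] = field(default_factory=dict)
    per_line: dict[str, Counter] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], group_label: str = "", zygosity_scope: str = "") -> "SpectrumSummary":
        unknown = set(counts) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories {sorted(unknown)}")
        full = {c: int(counts.get(c, 0)) for c in CATEGORIES}
        return cls(group_label=group_label, zygosity_scope=zygosity_scope, counts=full)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def proportions(self) -> dict[str, float]:
        """Per-category percentage of the summary total."""
        total = self.total
        if total == 0:
            raise ConfigurationError("empty summary has no proportions")
        return {c: 100.0 * n / total for c, n in self.counts.items()}


def length_class_breakdown(events: Sequence) -> dict[str, int]:
    """Split INDELs at 1 bp vs >= 2 bp and MNVs at 2 bp vs >= 3 bp."""
    out = {
        "deletion_1bp": 0,
        "deletion_ge2bp": 0,
        "insertion_1bp": 0,
        "insertion_ge2bp": 0,
        "mnv_2bp": 0,
        "mnv_ge3bp": 0,
    }
    for ev in events:
        category = ev.category or classify_variant(ev)
        if category == "MNV":
            length = ev.length if isinstance(ev, Mnv) else len(ev.ref)
            out["mnv_2bp" if length == 2 else "mnv_ge3bp"] += 1
        elif category == "INDEL_deletion":
            out["deletion_1bp" if _indel_length(ev) == 1 else "deletion_ge2bp"] += 1
        elif category == "INDEL_insertion":
            out["insertion_1bp" if _indel_length(ev) == 1 else "insertion_ge2bp"] += 1
    return out


def aggregate(
    line_sets: Sequence[LineMutationSet],
    zygosity_scope: str = "homozygous+heterozygous",
    group_label: str = "",
) -> SpectrumSummary:
    """Sum category counts over lines within one zygosity scope.

    ``zygosity_scope`` is ``"homozygous"`` or ``"homozygous+heterozygous"``.
    The result is independent of line order.
    """
    if not line_sets:
        raise ConfigurationError("cannot aggregate an empty group")
    counts: Counter = Counter({c: 0 for c in CATEGORIES})
    per_line: dict[str, Counter] = {}
    scoped_events: list = []
    for ls in line_sets:
        events = ls.by_zygosity(zygosity_scope)
        line_counter: Counter = Counter()
        for ev in events:
            category = ev.category or classify_variant(ev)
            counts[category] += 1
            line_counter[category] += 1
        per_line[ls.sample_id] = line_counter
        scoped_events.extend(events)
    sub = length_class_breakdown(scoped_events)
    ts, tv = ts_tv_counts(
        [e for e in scoped_events if not isinstance(e, Mnv) and (e.category or classify_variant(e)) == "SBS"]
    )
    sub["ts"] = ts
    sub["tv"] = tv
    return SpectrumSummary(
        group_label=group_label,
        zygosity_scope=zygosity_scope,
        counts=dict(counts),
        sub_counts=sub,
        per_line=per_line,
    )


def homozygous_fraction(summary_homo: SpectrumSummary, summary_all: SpectrumSummary) -> float:
    """Percentage of all (hom + het) variants that are homozygous."""
    if summary_all.total == 0:
        raise ConfigurationError("zero denominator: empty combined summary")
    return 100.0 * summary_homo.total / summary_all.total


def category_proportion(summary: SpectrumSummary, category: str) -> float:
    """Percentage of the summary total in one category (``"SV"`` pools
    DEL_SV + DUP_SV + BND_SV; ``"INDEL"`` pools both directions)."""
    if summary.total == 0:
        raise ConfigurationError("empty summary")
    if category == "SV":
        n = sum(summary.counts.get(c, 0) for c in ("DEL_SV", "DUP_SV", "BND_SV"))
    elif category == "INDEL":
        n = sum(summary.counts.get(c, 0) for c in ("INDEL_deletion", "INDEL_insertion"))
    else:
        n = summary.counts.get(category, 0)
    return 100.0 * n / summary.total


def sv_proportion(summary: SpectrumSummary) -> float:
    return category_proportion(summary, "SV")


# ---------------------------------------------------------------------------
# statistical tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    df: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    @property
    def label(self) -> str:
        return significance_label(self.p_value)


def significance_label(p: float) -> str:
    """Figure-legend convention: N.S. (p >= 0.05), *, **, ***."""
    if p >= 0.05:
        return "N.S."
    if p >= 0.01:
        return "*"
    if p >= 0.001:
        return "**"
    return "***"


def chi_squared_test(contingency) -> ChiSquaredResult:
    """Pearson chi-squared on an r x c count table (no continuity
    correction), df = (r-1)(c-1), significance threshold 0.05."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.min() < 0:
        raise InapplicableTestError("contingency must be a non-negative 2-d table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InapplicableTestError("zero marginal: expected counts undefined")
    statistic, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquaredResult(statistic=float(statistic), df=int(df), p_value=float(p))


def two_sample_t_test(values_a: Sequence[float], values_b: Sequence[float], welch: bool = False) -> TTestResult:
    """Two-sample Student's t (pooled variance by default; Welch by flag)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InapplicableTestError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise InapplicableTestError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    else:
        df = a.size + b.size - 2
    return TTestResult(statistic=float(res.statistic), df=float(df), p_value=float(res.pvalue))


# ---------------------------------------------------------------------------
# phenotype tables and error bands
# ---------------------------------------------------------------------------


def phenotype_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-class percentages of screened phenotypic mutant families.

    ``table`` has phenotype classes as the index and one column of family
    counts per mutagen; each cell becomes ``100 * count / column total``
    (full precision — round for display).
    """
    totals = table.sum(axis=0)
    if (totals <= 0).any():
        raise ConfigurationError("every mutagen column needs a positive total")
    return 100.0 * table / totals


def error_band(values: Sequence[float]) -> tuple[float, float]:
    """Mean and half-width ``1.97 * sample SD`` (the reporting convention
    used for replicate measurements here)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ConfigurationError("need >= 2 values for an error band")
    return float(arr.mean()), float(1.97 * arr.std(ddof=1))
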