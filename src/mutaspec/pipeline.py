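"""Filtering raw per-line variant calls down to induced-mutation sets.

A mutagenized line's call set contains, besides true induced mutations,
pre-existing background polymorphisms (present in the unirradiated control
individuals), artefacts shared across independent lines, and low-quality
calls.  The pipeline removes these in sequence:

1. quality filter (``qual >= min_qual``; calls lacking a quality are kept
   but flagged),
2. control subtraction — any key present in every control (CK) call set is
   background, not induced,
3. shared-line exclusion — a key seen in two or more independent M3 lines
   cannot be an independent induction event and is removed everywhere,
4. zygosity labelling — small variants by allele frequency (AF >= 0.75
   homozygous, 0.25 <= AF < 0.75 heterozygous, below 0.25 discarded as
   unreliable), SVs by genotype string (no zero allele: homozygous; exactly
   one zero: heterozygous),
5. MNV merging — runs of single-base substitutions at strictly consecutive
   positions become one multinucleotide variant; constituents are excluded
   from later Ts/Tv arithmetic,
6. scaffold filtering — SVs touching an unassembled-scaffold name on either
   locus are set aside.

Every removal is tallied per stage in :class:`LineMutationSet.provenance`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .exceptions import ConfigurationError, DataError, FieldValidationError
from .variant_io import VariantCall, variant_key

__all__ = [
    "Mnv",
    "LineMutationSet",
    "classify_zygosity_small",
    "classify_zygosity_sv",
    "filter_quality",
    "subtract_control",
    "exclude_shared",
    "merge_mnv",
    "filter_scaffold_svs",
    "process_line",
    "run_cohort",
]

HOMOZYGOUS_AF = 0.75  # AF >= 0.75: homozygous (rule stated with >=)
HETEROZYGOUS_AF = 0.25  # 0.25 <= AF < 0.75: heterozygous; below: discarded
DEFAULT_MIN_QUAL = 20.0


@dataclass(frozen=True)
class Mnv:
    """A multinucleotide variant merged from >= 2 adjacent substitutions.

    ``af`` is the mean constituent AF and ``zygosity`` the class of that
    mean, so the label is independent of constituent order.
    """

    sample_id: str
    chrom: str
    start_pos: int
    ref_run: str
    alt_run: str
    af: float
    zygosity: str
    constituent_positions: tuple[int, ...]
    category: str = "MNV"

    @property
    def length(self) -> int:
        return len(self.constituent_positions)

    @property
    def end_pos(self) -> int:
        return self.start_pos + self.length - 1

    def key(self) -> tuple:
        return (self.chrom, self.start_pos, self.ref_run, self.alt_run)


@dataclass
class LineMutationSet:
    """Retained, zygosity- and category-labelled calls for one line.

    ``calls`` holds :class:`VariantCall` (SBS/INDEL/SV) and :class:`Mnv`
    events; ``provenance`` maps each filter stage to the number of raw calls
    it removed.  MNV merging is not a removal: constituents are conserved
    inside their Mnv.
    """

    sample_id: str
    calls: list = field(default_factory=list)
    provenance: dict[str, int] = field(default_factory=dict)
    flagged_missing_qual: int = 0
    raw_count: int = 0

    @property
    def retained_raw_equivalents(self) -> int:
        """Retained events counted in raw-call units (MNVs expand)."""
        return sum(e.length if isinstance(e, Mnv) else 1 for e in self.calls)

    def provenance_consistent(self) -> bool:
        return self.raw_count - sum(self.provenance.values()) == self.retained_raw_equivalents

    def by_zygosity(self, scope: str) -> list:
        if scope == "homozygous":
            wanted = {"homozygous"}
        elif scope in ("homozygous+heterozygous", "all"):
            wanted = {"homozygous", "heterozygous"}
        else:
            raise ConfigurationError(f"unknown zygosity scope {scope!r}")
        return [c for c in self.calls if c.zygosity in wanted]


# ---------------------------------------------------------------------------
# zygosity
# ---------------------------------------------------------------------------


def classify_zygosity_small(af: float) -> str:
    """Classify a small variant by allele frequency.

    Returns ``homozygous`` (AF >= 0.75), ``heterozygous`` (0.25 <= AF <
    0.75) or ``discard`` (AF < 0.25, too low to trust).  The 0.75 boundary
    belongs to the homozygous class because that rule is stated inclusively.
    """
    if not 0.0 <= af <= 1.0:
        raise FieldValidationError(f"AF must lie in [0, 1], got {af}")
    if af >= HOMOZYGOUS_AF:
        return "homozygous"
    if af >= HETEROZYGOUS_AF:
        return "heterozygous"
    return "discard"


def classify_zygosity_sv(gt: str) -> str:
    """Classify an SV by its diploid genotype string.

    ``0/1`` (exactly one zero allele) is heterozygous, ``1/1`` (no zero)
    homozygous, ``0/0`` reference, and any missing allele gives unknown.
    """
    if gt is None:
        return "unknown"
    alleles = gt.replace("|", "/").split("/")
    if len(alleles) != 2:
        raise FieldValidationError(f"genotype {gt!r} is not diploid")
    if "." in alleles:
        return "unknown"
    try:
        values = [int(a) for a in alleles]
    except ValueError as exc:
        raise FieldValidationError(f"unparseable genotype {gt!r}") from exc
    zeros = sum(v == 0 for v in values)
    if zeros == 2:
        return "reference"
    if zeros == 1:
        return "heterozygous"
    return "homozygous"


# ---------------------------------------------------------------------------
# key-set filters
# ---------------------------------------------------------------------------


def _sv_keys_match(key_a: tuple, key_b: tuple, tolerance: int) -> bool:
    if key_a[0] != key_b[0]:
        return False
    if key_a[0] == "BND_SV":
        return (
            key_a[1] == key_b[1]
            and key_a[3] == key_b[3]
            and abs(key_a[2] - key_b[2]) <= tolerance
            and abs(key_a[4] - key_b[4]) <= tolerance
        )
    return (
        key_a[1] == key_b[1]
        and abs(key_a[2] - key_b[2]) <= tolerance
        and abs(key_a[3] - key_b[3]) <= tolerance
    )


def _key_in(key: tuple, key_set: set, tolerance: int) -> bool:
    if tolerance == 0 or not isinstance(key[0], str) or key[0] not in ("DEL_SV", "DUP_SV", "BND_SV"):
        if key in key_set:
            return True
        if tolerance == 0:
            return False
    return any(
        _sv_keys_match(key, other, tolerance)
        for other in key_set
        if other[0] == key[0]
    )


def filter_quality(calls: Sequence[VariantCall], min_qual: float = DEFAULT_MIN_QUAL):
    """Drop calls with ``qual < min_qual``; keep and flag calls lacking qual.

    Returns ``(retained, removed, n_flagged)``.
    """
    retained, removed = [], []
    n_flagged = 0
    for call in calls:
        if call.qual is None:
            n_flagged += 1
            call.notes = call.notes + ("missing_qual",)
            retained.append(call)
        elif call.qual >= min_qual:
            retained.append(call)
        else:
            removed.append(call)
    return retained, removed, n_flagged


def subtract_control(
    line_calls: Sequence[VariantCall],
    control_call_sets: Sequence[Sequence[VariantCall]],
    mode: str = "intersection",
    sv_tolerance: int = 0,
):
    """Remove background variants present in the control individuals.

    A key is background when it appears in **every** control call set
    (``mode="intersection"``, the default: variants common between the CK
    individuals) or in **any** control set (``mode="union"``, stricter).
    Returns ``(retained, removed)``.
    """
    if not control_call_sets:
        raise ConfigurationError("at least one control call set is required")
    if mode not in ("intersection", "union"):
        raise ConfigurationError(f"unknown control mode {mode!r}")
    key_sets = [{variant_key(c) for c in cs} for cs in control_call_sets]
    background = set.intersection(*key_sets) if mode == "intersection" else set.union(*key_sets)
    retained, removed = [], []
    for call in line_calls:
        if _key_in(variant_key(call), background, sv_tolerance):
            removed.append(call)
        else:
            retained.append(call)
    return retained, removed


def exclude_shared(
    all_line_sets: Mapping[str, Sequence[VariantCall]],
    min_lines: int = 2,
    sv_tolerance: int = 0,
) -> dict[str, tuple[list, list]]:
    """Remove keys detected in ``min_lines`` or more distinct lines.

    Independent induction events are private to a line, so recurrence across
    lines marks a shared artefact or residual background.  Returns
    ``{sample_id: (retained, removed)}``.
    """
    if min_lines < 2:
        raise ConfigurationError("min_lines must be >= 2")
    if len(all_line_sets) < 2:
        raise ConfigurationError("need at least two lines")
    occurrences: dict[tuple, set[str]] = {}
    for sample, calls in all_line_sets.items():
        for key in {variant_key(c) for c in calls}:
            occurrences.setdefault(key, set()).add(sample)
    if sv_tolerance > 0:
        shared = set()
        keys = list(occurrences)
        for i, ka in enumerate(keys):
            lines = set(occurrences[ka])
            if isinstance(ka[0], str) and ka[0] in ("DEL_SV", "DUP_SV", "BND_SV"):
                for kb in keys:
                    if kb is not ka and _sv_keys_match(ka, kb, sv_tolerance):
                        lines |= occurrences[kb]
            if len(lines) >= min_lines:
                shared.add(ka)
    else:
        shared = {k for k, lines in occurrences.items() if len(lines) >= min_lines}
    out: dict[str, tuple[list, list]] = {}
    for sample, calls in all_line_sets.items():
        retained = [c for c in calls if variant_key(c) not in shared]
        removed = [c for c in calls if variant_key(c) in shared]
        out[sample] = (retained, removed)
    return out


# ---------------------------------------------------------------------------
# MNV merging and scaffold filtering
# ---------------------------------------------------------------------------


def merge_mnv(sbs_calls: Sequence[VariantCall]) -> tuple[list[Mnv], list[VariantCall]]:
    """Merge maximal runs of strictly consecutive SBSs into MNVs.

    Input must be single-base substitutions for one line.  Runs of length
    >= 2 at positions ``pos, pos+1, ...`` on one chromosome become one
    :class:`Mnv`; singletons are returned unchanged.  Constituent SBSs are
    therefore absent from the returned SBS list and never enter Ts/Tv
    arithmetic.  Duplicate positions raise :class:`DataError`.
    """
    ordered = sorted(sbs_calls, key=lambda c: (c.chrom, c.pos))
    for a, b in zip(ordered, ordered[1:]):
        if a.chrom == b.chrom and a.pos == b.pos:
            raise DataError(f"duplicate SBS position {a.chrom}:{a.pos}")
    mnvs: list[Mnv] = []
    singles: list[VariantCall] = []
    run: list[VariantCall] = []

    def flush(run: list[VariantCall]) -> None:
        if len(run) >= 2:
            afs = [c.af for c in run if c.af is not None]
            mean_af = sum(afs) / len(afs) if afs else 1.0
            mnvs.append(
                Mnv(
                    sample_id=run[0].sample_id,
                    chrom=run[0].chrom,
                    start_pos=run[0].pos,
                    ref_run="".join(c.ref for c in run),
                    alt_run="".join(c.alt for c in run),
                    af=mean_af,
                    zygosity=classify_zygosity_small(mean_af),
                    constituent_positions=tuple(c.pos for c in run),
                )
            )
        elif run:
            singles.append(run[0])

    for call in ordered:
        if run and call.chrom == run[-1].chrom and call.pos == run[-1].pos + 1:
            run.append(call)
        else:
            flush(run)
            run = [call]
    flush(run)
    return mnvs, singles


def filter_scaffold_svs(
    sv_calls: Sequence[VariantCall], chromosome_names: Iterable[str]
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition SVs into (on-chromosome, scaffold-related).

    An SV is scaffold-related when either its anchor locus or, for
    breakends, its mate locus lies on a name outside the assembled
    chromosome set.
    """
    names = set(chromosome_names)
    if not names:
        raise ConfigurationError("chromosome name set is empty")
    retained, filtered = [], []
    for call in sv_calls:
        loci = [call.chrom]
        if call.mate_chrom is not None:
            loci.append(call.mate_chrom)
        (retained if all(l in names for l in loci) else filtered).append(call)
    return retained, filtered


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _label_and_assemble(
    sample_id: str,
    calls: Sequence[VariantCall],
    chromosome_names: Iterable[str] | None,
    provenance: dict[str, int],
    raw_count: int,
    n_flagged: int,
) -> LineMutationSet:
    from .spectrum_stats import classify_variant  # late import: no cycle at runtime

    small, svs = [], []
    n_low_af = n_nonvariant = 0
    for call in calls:
        if call.is_sv:
            call.zygosity = classify_zygosity_sv(call.gt)
            if call.zygosity in ("reference", "unknown"):
                n_nonvariant += 1
            else:
                svs.append(call)
        else:
            call.zygosity = classify_zygosity_small(call.af)
            if call.zygosity == "discard":
                n_low_af += 1
            else:
                small.append(call)
    provenance["low_af"] = n_low_af
    provenance["sv_nonvariant_gt"] = n_nonvariant

    if chromosome_names is not None:
        svs, scaffold = filter_scaffold_svs(svs, chromosome_names)
        provenance["scaffold_sv"] = len(scaffold)
    else:
        provenance["scaffold_sv"] = 0

    sbs = [c for c in small if len(c.ref) == 1 == len(c.alt)]
    others = [c for c in small if not (len(c.ref) == 1 == len(c.alt))]
    mnvs, sbs_single = merge_mnv(sbs)

    events: list = []
    for call in sbs_single + others + svs:
        call.category = classify_variant(call)
        events.append(call)
    events.extend(mnvs)
    return LineMutationSet(
        sample_id=sample_id,
        calls=events,
        provenance=provenance,
        flagged_missing_qual=n_flagged,
        raw_count=raw_count,
    )


def process_line(
    line_calls: Sequence[VariantCall],
    control_call_sets: Sequence[Sequence[VariantCall]],
    chromosome_names: Iterable[str] | None = None,
    min_qual: float = DEFAULT_MIN_QUAL,
    control_mode: str = "intersection",
    sample_id: str | None = None,
) -> LineMutationSet:
    """Run the single-line stages (no cross-line exclusion) for one line."""
    raw = len(line_calls)
    sample = sample_id or (line_calls[0].sample_id if line_calls else "line")
    provenance: dict[str, int] = {}
    calls, removed_q, n_flagged = filter_quality(list(line_calls), min_qual)
    provenance["low_quality"] = len(removed_q)
    calls, removed_c = subtract_control(calls, control_call_sets, mode=control_mode)
    provenance["control_shared"] = len(removed_c)
    provenance["line_shared"] = 0
    return _label_and_assemble(sample, calls, chromosome_names, provenance, raw, n_flagged)


def run_cohort(
    lines: Mapping[str, Sequence[VariantCall]],
    controls: Sequence[Sequence[VariantCall]],
    chromosome_names: Iterable[str] | None = None,
    min_qual: float = DEFAULT_MIN_QUAL,
    control_mode: str = "intersection",
    min_shared_lines: int = 2,
    sv_tolerance: int = 0,
) -> dict[str, LineMutationSet]:
    """Full multi-line pipeline: quality, control, cross-line, labelling.

    ``lines`` maps sample id to raw calls; ``controls`` is the list of CK
    call sets.  Cross-line exclusion spans all supplied lines.
    """
    staged: dict[str, list] = {}
    provenances: dict[str, dict[str, int]] = {}
    raw_counts: dict[str, int] = {}
    flagged: dict[str, int] = {}
    for sample, calls in lines.items():
        raw_counts[sample] = len(calls)
        prov: dict[str, int] = {}
        kept, removed_q, n_flag = filter_quality(list(calls), min_qual)
        prov["low_quality"] = len(removed_q)
        kept, removed_c = subtract_control(
            kept, controls, mode=control_mode, sv_tolerance=sv_tolerance
        )
        prov["control_shared"] = len(removed_c)
        staged[sample] = kept
        provenances[sample] = prov
        flagged[sample] = n_flag
    if len(staged) >= 2:
        for sample, (kept, removed_s) in exclude_shared(
            staged, min_lines=min_shared_lines, sv_tolerance=sv_tolerance
        ).items():
            provenances[sample]["line_shared"] = len(removed_s)
            staged[sample] = kept
    else:
        for sample in staged:
            provenances[sample]["line_shared"] = 0
    return {
        sample: _label_and_assemble(
            sample,
            staged[sample],
            chromosome_names,
            provenances[sample],
            raw_counts[sample],
            flagged[sample],
        )
        for sample in staged
    }
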