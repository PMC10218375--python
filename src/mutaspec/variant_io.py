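"""Reading and writing the constrained variant and annotation formats.

The pipeline consumes a narrow slice of VCF 4.x: per-sample allele
frequency (FORMAT/AF, with INFO/AF as fallback) for small variants, and
SVTYPE/END/GT (plus MATEID for breakend pairs) for structural variants.
Records are mapped onto :class:`VariantCall`, validated constructively, and
breakend mates are joined into a single call.  Gene-effect annotations
(region, impact level, functional class — the output layer of a SnpEff-style
annotator) arrive as delimited text or ANN-style pipe fields and map onto
:class:`AnnotationRecord`.

Coordinates are 1-based throughout (VCF convention); an SV interval is
``[pos, sv_end]`` with length ``sv_end - pos``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
import pysam

from .exceptions import FieldValidationError, VcfFormatError

__all__ = [
    "VariantCall",
    "AnnotationRecord",
    "SV_TYPES",
    "IMPACT_LEVELS",
    "read_vcf_subset",
    "write_vcf",
    "read_annotations",
    "write_report",
    "read_report",
    "variant_key",
]

SV_TYPES = ("DEL_SV", "DUP_SV", "BND_SV")
IMPACT_LEVELS = ("MODIFIER", "LOW", "MODERATE", "HIGH")

#: region labels the annotator is known to emit; others are kept but flagged
KNOWN_REGIONS = frozenset(
    {
        "intergenic",
        "downstream",
        "upstream",
        "exon",
        "intron",
        "exon_duplication",
        "splice",
        "utr_5",
        "utr_3",
    }
)

FUNCTIONAL_CLASSES = ("missense", "nonsense", "silent", "none")

_BASES = frozenset("ACGTN")
_BND_MATE_RE = re.compile(r"[\[\]]([^:\[\]]+):(\d+)[\[\]]")

#: SnpEff ANN annotation terms -> (region label, functional class)
_ANN_TERM_MAP = {
    "intergenic_region": ("intergenic", "none"),
    "downstream_gene_variant": ("downstream", "none"),
    "upstream_gene_variant": ("upstream", "none"),
    "intron_variant": ("intron", "none"),
    "missense_variant": ("exon", "missense"),
    "stop_gained": ("exon", "nonsense"),
    "synonymous_variant": ("exon", "silent"),
    "exon_variant": ("exon", "none"),
    "duplication": ("exon_duplication", "none"),
    "exon_loss_variant": ("exon", "none"),
    "splice_region_variant": ("splice", "none"),
}


@dataclass
class VariantCall:
    """One called variant for one sample.

    Small variants carry base-string alleles and an allele frequency;
    structural variants carry ``sv_type`` plus an end position (DEL_SV /
    DUP_SV) or a mate locus (BND_SV) and a diploid genotype string.
    ``zygosity`` and ``category`` are filled in by the pipeline.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    af: float | None = None
    gt: str | None = None
    sv_type: str | None = None
    sv_end: int | None = None
    mate_chrom: str | None = None
    mate_pos: int | None = None
    zygosity: str | None = None
    category: str | None = None
    notes: tuple[str, ...] = ()

    def validate(self) -> "VariantCall":
        """Check field-level invariants; return self for chaining."""
        if self.pos < 1:
            raise FieldValidationError(f"pos must be >= 1, got {self.pos}")
        if self.sv_type is None:
            for name, allele in (("ref", self.ref), ("alt", self.alt)):
                if not allele or set(allele.upper()) - _BASES:
                    raise FieldValidationError(
                        f"small-variant {name} must be a base string, got {allele!r}"
                    )
            if abs(len(self.ref) - len(self.alt)) > 50:
                raise FieldValidationError(
                    f"small-variant length change exceeds 50 bp at "
                    f"{self.chrom}:{self.pos}"
                )
            if self.af is not None and not 0.0 <= self.af <= 1.0:
                raise FieldValidationError(f"AF must lie in [0, 1], got {self.af}")
        elif self.sv_type in ("DEL_SV", "DUP_SV"):
            if self.sv_end is None or self.sv_end <= self.pos:
                raise FieldValidationError(
                    f"{self.sv_type} at {self.chrom}:{self.pos} needs sv_end > pos"
                )
            if self.sv_end - self.pos < 50:
                raise FieldValidationError(
                    f"{self.sv_type} at {self.chrom}:{self.pos} is "
                    f"{self.sv_end - self.pos} bp; SVs must span >= 50 bp"
                )
        elif self.sv_type == "BND_SV":
            if self.mate_chrom is None or self.mate_pos is None:
                raise FieldValidationError(
                    f"BND_SV at {self.chrom}:{self.pos} lacks a mate locus"
                )
        else:
            raise FieldValidationError(f"unknown sv_type {self.sv_type!r}")
        return self

    def key(self) -> tuple:
        return variant_key(self)

    @property
    def is_sv(self) -> bool:
        return self.sv_type is not None


def variant_key(call) -> tuple:
    """Cross-sample equality key.

    Small variants: ``(chrom, pos, ref, alt)``.  Extent SVs:
    ``(sv_type, chrom, pos, sv_end)``.  Breakends:
    ``(sv_type, chrom, pos, mate_chrom, mate_pos)``.
    """
    sv_type = getattr(call, "sv_type", None)
    if sv_type is None:
        return (call.chrom, call.pos, call.ref, call.alt)
    if sv_type == "BND_SV":
        return (sv_type, call.chrom, call.pos, call.mate_chrom, call.mate_pos)
    return (sv_type, call.chrom, call.pos, call.sv_end)


@dataclass
class AnnotationRecord:
    """One predicted gene effect for one variant in one sample."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    region: str
    impact: str
    functional_class: str = "none"
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_LEVELS:
            raise FieldValidationError(
                f"unknown impact level {self.impact!r}; expected one of "
                f"{IMPACT_LEVELS}"
            )
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise FieldValidationError(
                f"unknown functional class {self.functional_class!r}"
            )
        if self.region not in KNOWN_REGIONS:
            self.flagged = True

    @property
    def variant_key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# VCF subset reading
# ---------------------------------------------------------------------------


def _format_gt(gt_tuple) -> str | None:
    if gt_tuple is None or all(a is None for a in gt_tuple):
        return None
    return "/".join("." if a is None else str(a) for a in gt_tuple)


def _scalar(value, index: int = 0):
    if isinstance(value, (tuple, list)):
        return value[index] if index < len(value) else None
    return value


def _parse_bnd_mate(alt: str) -> tuple[str, int] | None:
    m = _BND_MATE_RE.search(alt)
    if m is None:
        return None
    return m.group(1), int(m.group(2))


def read_vcf_subset(path, sample_id: str) -> list[VariantCall]:
    """Read the VCF subset for one sample into validated calls.

    Small variants require an allele frequency (per-sample FORMAT/AF
    preferred, INFO/AF fallback); symbolic/breakend records require SVTYPE
    and, for DEL/DUP, an END.  Reciprocal breakend mates (MATEID) are joined
    into a single BND_SV call anchored at the lexicographically first locus.
    Validation failures raise :class:`FieldValidationError` naming the file
    line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"{path}: malformed VCF: {exc}") from exc
    with vcf:
        if sample_id not in list(vcf.header.samples):
            raise FieldValidationError(
                f"{path}: sample {sample_id!r} absent from header"
            )
        n_header = str(vcf.header).count("\n")
        calls: list[VariantCall] = []
        bnd: dict[str, tuple[VariantCall, str | None]] = {}
        for idx, rec in enumerate(vcf):
            line_no = n_header + 1 + idx
            try:
                calls_here, bnd_here = _convert_record(rec, sample_id)
            except FieldValidationError as exc:
                raise FieldValidationError(f"{path} line {line_no}: {exc}") from exc
            calls.extend(calls_here)
            for rec_id, (call, mate_id) in bnd_here.items():
                bnd[rec_id] = (call, mate_id)
    calls.extend(_join_breakends(bnd))
    return calls


def _convert_record(rec, sample_id: str):
    """Map one pysam record to calls; split multi-allelic sites."""
    sv_type_raw = rec.info.get("SVTYPE") if "SVTYPE" in rec.info else None
    sample = rec.samples[sample_id]
    calls: list[VariantCall] = []
    bnd: dict[str, tuple[VariantCall, str | None]] = {}
    alts = rec.alts or ()
    for i, alt in enumerate(alts):
        common = dict(
            sample_id=sample_id,
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alt=alt,
            qual=None if rec.qual is None else float(rec.qual),
            gt=_format_gt(sample.get("GT")),
        )
        if sv_type_raw is not None or alt.startswith("<") or _BND_MATE_RE.search(alt):
            sv = _scalar(sv_type_raw) or ("BND" if _BND_MATE_RE.search(alt) else None)
            if sv == "BND":
                mate = _parse_bnd_mate(alt)
                call = VariantCall(
                    **common,
                    sv_type="BND_SV",
                    mate_chrom=mate[0] if mate else None,
                    mate_pos=mate[1] if mate else None,
                ).validate()
                mate_id = _scalar(rec.info.get("MATEID")) if "MATEID" in rec.info else None
                if rec.id is not None:
                    bnd[rec.id] = (call, mate_id)
                else:
                    calls.append(call)
            elif sv in ("DEL", "DUP"):
                call = VariantCall(
                    **common, sv_type=f"{sv}_SV", sv_end=int(rec.stop)
                ).validate()
                calls.append(call)
            else:
                raise FieldValidationError(f"unsupported SVTYPE {sv!r}")
        else:
            af = None
            if "AF" in sample:
                af = _scalar(sample.get("AF"), i)
            if af is None and "AF" in rec.info:
                af = _scalar(rec.info.get("AF"), i)
            if af is None:
                raise FieldValidationError(
                    f"small variant {rec.chrom}:{rec.pos} {rec.ref}>{alt} "
                    "has no AF in FORMAT or INFO"
                )
            calls.append(VariantCall(**common, af=float(af)).validate())
    return calls, bnd


def _join_breakends(bnd: dict) -> list[VariantCall]:
    """Collapse reciprocal MATEID pairs to one call each."""
    joined: list[VariantCall] = []
    consumed: set[str] = set()
    for rec_id, (call, mate_id) in sorted(bnd.items()):
        if rec_id in consumed:
            continue
        if mate_id is not None and mate_id in bnd:
            mate_call, _ = bnd[mate_id]
            consumed.update({rec_id, mate_id})
            first, second = sorted(
                (call, mate_call), key=lambda c: (c.chrom, c.pos)
            )
            joined.append(
                replace(
                    first,
                    mate_chrom=second.chrom,
                    mate_pos=second.pos,
                ).validate()
            )
        else:
            consumed.add(rec_id)
            joined.append(call)
    return joined


# ---------------------------------------------------------------------------
# VCF subset writing (plain-text emission; pysam round-trips it on read)
# ---------------------------------------------------------------------------

_VCF_META = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=MATEID,Number=.,Type=String,Description="ID of mate breakend">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
"""


def write_vcf(calls: Sequence[VariantCall], path, sample_id: str, contigs: dict[str, int] | None = None) -> None:
    """Write calls for one sample as a sorted plain-text VCF.

    Breakend calls are expanded back into reciprocal MATEID pairs.  Contig
    lengths default to the largest coordinate seen per name, padded.
    """
    if contigs is None:
        contigs = {}
        for c in calls:
            for name, p in ((c.chrom, c.sv_end or c.pos), (c.mate_chrom, c.mate_pos)):
                if name is not None:
                    contigs[name] = max(contigs.get(name, 0), int(p) + 10_000)
    lines = [_VCF_META.rstrip("\n")]
    for name in sorted(contigs):
        lines.append(f"##contig=<ID={name},length={contigs[name]}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    rows: list[tuple] = []
    bnd_n = 0
    for call in calls:
        qual = "." if call.qual is None else f"{call.qual:g}"
        gt = call.gt or "./."
        if call.sv_type is None:
            fmt, sample_col = "GT:AF", f"{gt}:{call.af:g}"
            rows.append((call.chrom, call.pos, ".", call.ref, call.alt, qual, "PASS", ".", fmt, sample_col))
        elif call.sv_type in ("DEL_SV", "DUP_SV"):
            svt = call.sv_type[:3]
            info = f"SVTYPE={svt};END={call.sv_end}"
            rows.append((call.chrom, call.pos, ".", "N", f"<{svt}>", qual, "PASS", info, "GT", gt))
        else:
            bnd_n += 1
            id_a, id_b = f"bnd_{bnd_n}a", f"bnd_{bnd_n}b"
            alt_a = f"N[{call.mate_chrom}:{call.mate_pos}["
            alt_b = f"N]{call.chrom}:{call.pos}]"
            rows.append((call.chrom, call.pos, id_a, "N", alt_a, qual, "PASS", f"SVTYPE=BND;MATEID={id_b}", "GT", gt))
            rows.append((call.mate_chrom, call.mate_pos, id_b, "N", alt_b, qual, "PASS", f"SVTYPE=BND;MATEID={id_a}", "GT", gt))
    rows.sort(key=lambda r: (r[0], r[1], r[3], r[4]))
    for r in rows:
        lines.append("\t".join(str(x) for x in r))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# annotation records
# ---------------------------------------------------------------------------


def _record_from_ann(sample_id, chrom, pos, ref, alt, ann_field: str) -> AnnotationRecord:
    parts = ann_field.split("|")
    if len(parts) < 3:
        raise FieldValidationError(
            f"ANN field needs >= 3 pipe-separated sub-fields, got {ann_field!r}"
        )
    term, impact = parts[1], parts[2]
    region, functional_class = _ANN_TERM_MAP.get(term, (term, "none"))
    return AnnotationRecord(
        sample_id=sample_id,
        chrom=chrom,
        pos=int(pos),
        ref=ref,
        alt=alt,
        region=region,
        impact=impact,
        functional_class=functional_class,
    )


def read_annotations(path, sep: str = "\t") -> list[AnnotationRecord]:
    """Read annotation records from delimited text.

    Two layouts are accepted: explicit columns
    ``sample_id, chrom, pos, ref, alt, region, impact[, functional_class]``,
    or an ``ann`` column holding a SnpEff-style pipe-delimited field from
    which region, impact and functional class are extracted.
    """
    df = pd.read_csv(path, sep=sep, dtype={"chrom": str})
    required = {"sample_id", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise FieldValidationError(f"{path}: missing columns {sorted(missing)}")
    records: list[AnnotationRecord] = []
    if "ann" in df.columns:
        for row in df.itertuples(index=False):
            records.append(
                _record_from_ann(row.sample_id, row.chrom, row.pos, row.ref, row.alt, row.ann)
            )
    elif {"region", "impact"} <= set(df.columns):
        has_class = "functional_class" in df.columns
        for row in df.itertuples(index=False):
            records.append(
                AnnotationRecord(
                    sample_id=row.sample_id,
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    region=row.region,
                    impact=row.impact,
                    functional_class=(row.functional_class if has_class else "none"),
                )
            )
    else:
        raise FieldValidationError(
            f"{path}: need either region/impact columns or an ann column"
        )
    return records


# ---------------------------------------------------------------------------
# generic TSV reports
# ---------------------------------------------------------------------------


def write_report(table: pd.DataFrame, path) -> None:
    """Write a DataFrame as a TSV with deterministic row order.

    Rows are sorted by all columns (stable) so repeated runs are
    byte-identical; the column order is preserved as given.
    """
    df = table.copy()
    if len(df.columns) and len(df):
        df = df.sort_values(by=list(df.columns), kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
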