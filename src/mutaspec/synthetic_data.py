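"""Synthetic study inputs with known ground truth.

Emulates the data layout of a two-mutagen soybean mutagenesis experiment:
binomially noised dose-response observations on a single-hit multitarget
curve, per-line variant call sets for two cohorts of M3 mutant lines plus
two unirradiated control (CK) individuals, and annotator output for the
retained variants.  Every generated record is logged in a ground-truth
table (origin, intended zygosity, category), so each pipeline filter can be
audited against exactly the records planted for it.

Defaults mirror the study conditions: 16 lines per mutagen, per-line
expected category counts equal to the published group totals divided by 16,
homozygous fractions of 0.2051 (carbon) and 0.3706 (gamma), a 20 x 1 Mb
chromosome model plus unassembled scaffold names, and dose grids of
40-180 Gy (carbon) / 100-400 Gy (gamma) with ~20 seeds per dose point.
All draws come from one ``numpy.random.Generator``; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import DoseResponseObservation, shmt_rate
from .exceptions import ConfigurationError
from .variant_io import VariantCall, AnnotationRecord, write_vcf

__all__ = [
    "SimulationConfig",
    "GroupProfile",
    "SimulatedCohort",
    "carbon_profile",
    "gamma_profile",
    "default_genome",
    "ENDPOINT_TRUTH",
    "DOSE_GRIDS",
    "simulate_dose_response",
    "simulate_mutant_lines",
    "simulate_annotations",
    "write_cohort",
]

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: generating (d0 Gy, m) per mutagen/endpoint, chosen so the implied
#: shoulder and 50%-effect doses match the published readouts
#: (e.g. carbon survival: Dq = 64.2 * ln 6 = 115 Gy, D50 ~ 142 Gy).
ENDPOINT_TRUTH: dict[tuple[str, str], tuple[float, float]] = {
    ("carbon", "survival"): (64.2, 6.0),
    ("gamma", "survival"): (88.1, 49.0),
    ("carbon", "fertility"): (26.6, 45.0),
    ("gamma", "fertility"): (69.1, 45.0),
}

#: absorbed-dose grids (Gy), control included
DOSE_GRIDS: dict[str, tuple[float, ...]] = {
    "carbon": (0.0, 40.0, 60.0, 80.0, 100.0, 120.0, 150.0, 180.0),
    "gamma": (0.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0, 400.0),
}

#: replicate dishes per dose point (carbon, gamma)
REPLICATES = {"carbon": 5, "gamma": 3}

REGION_FREQS = {
    "intergenic": 0.40,
    "downstream": 0.22,
    "upstream": 0.18,
    "intron": 0.11,
    "exon": 0.06,
    "exon_duplication": 0.03,
}
IMPACT_FREQS = {"MODIFIER": 0.945, "LOW": 0.01, "MODERATE": 0.03, "HIGH": 0.015}
CLASS_FREQS = {"missense": 0.72, "nonsense": 0.04, "silent": 0.24}


def default_genome(n_chromosomes: int = 20, chrom_length: int = 1_000_000) -> dict[str, int]:
    """Desk-scale genome model: 20 chromosomes named like the soybean
    assembly (Gm01..Gm20)."""
    return {f"Gm{i:02d}": chrom_length for i in range(1, n_chromosomes + 1)}


@dataclass(frozen=True)
class GroupProfile:
    """Per-line expected mutation counts and zygosity mix for one mutagen."""

    label: str
    n_lines: int = 16
    sbs: float = 0.0
    deletions: float = 0.0
    insertions: float = 0.0
    mnv: float = 0.0
    del_sv: float = 0.0
    dup_sv: float = 0.0
    bnd_sv: float = 0.0
    hom_fraction: float = 0.25
    ts_probability: float = 0.6
    indel_1bp_prob: float = 0.6
    mnv_length_probs: tuple[tuple[int, float], ...] = ((2, 0.70), (3, 0.20), (4, 0.07), (5, 0.03))

    def scaled(self, scale: float) -> "GroupProfile":
        """Scale expected per-line counts (sampling-design knob for small
        test runs; the zygosity mix is untouched)."""
        return replace(
            self,
            sbs=self.sbs * scale,
            deletions=self.deletions * scale,
            insertions=self.insertions * scale,
            mnv=self.mnv * scale,
            del_sv=self.del_sv * scale,
            dup_sv=self.dup_sv * scale,
            bnd_sv=self.bnd_sv * scale,
        )


def carbon_profile(scale: float = 1.0, n_lines: int = 16) -> GroupProfile:
    """Carbon-ion cohort: published hom+het group totals over 16 lines,
    homozygous fraction 20.51%."""
    return GroupProfile(
        label="carbon",
        n_lines=n_lines,
        sbs=5677 / 16,
        deletions=1892 / 16,
        insertions=1379 / 16,
        mnv=139 / 16,
        del_sv=43 / 16,
        dup_sv=77 / 16,
        bnd_sv=488 / 16,
        hom_fraction=0.2051,
    ).scaled(scale)


def gamma_profile(scale: float = 1.0, n_lines: int = 16) -> GroupProfile:
    """Gamma-ray cohort: published hom+het group totals over 16 lines,
    homozygous fraction 37.06%."""
    return GroupProfile(
        label="gamma",
        n_lines=n_lines,
        sbs=8947 / 16,
        deletions=2619 / 16,
        insertions=1819 / 16,
        mnv=283 / 16,
        del_sv=40 / 16,
        dup_sv=71 / 16,
        bnd_sv=464 / 16,
        hom_fraction=0.3706,
    ).scaled(scale)


@dataclass
class SimulationConfig:
    """Cohort-simulation settings shared by both mutagen groups."""

    seed: int = 0
    chromosomes: dict[str, int] = field(default_factory=default_genome)
    scaffolds: tuple[str, ...] = tuple(f"scaffold_{i}" for i in range(1, 11))
    scaffold_length: int = 100_000
    n_ck_shared: int = 50
    n_ck_private: int = 20
    n_crossline_shared: int = 20
    n_low_quality: int = 5
    scaffold_fraction: float = 0.4
    hom_af_range: tuple[float, float] = (0.9, 1.0)
    het_af_range: tuple[float, float] = (0.35, 0.65)
    adversarial_af: bool = False
    qual_range: tuple[float, float] = (30.0, 60.0)
    low_qual_range: tuple[float, float] = (2.0, 10.0)

    def validate(self) -> "SimulationConfig":
        if not self.chromosomes:
            raise ConfigurationError("genome model needs >= 1 chromosome")
        for name in ("n_ck_shared", "n_crossline_shared", "n_low_quality"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 <= self.scaffold_fraction <= 1.0:
            raise ConfigurationError("scaffold_fraction must lie in [0, 1]")
        return self


@dataclass
class SimulatedCohort:
    """Generated call sets plus the ground-truth ledger."""

    lines: dict[str, list[VariantCall]]
    controls: list[list[VariantCall]]
    truth: pd.DataFrame
    config: SimulationConfig
    profiles: tuple[GroupProfile, ...]

    def group_samples(self, label: str) -> list[str]:
        return sorted(s for s in self.lines if s.startswith(label))


# ---------------------------------------------------------------------------
# dose response
# ---------------------------------------------------------------------------


def simulate_dose_response(
    doses: Sequence[float],
    d0: float,
    m: float,
    n_units: int = 20,
    n_replicates: int = 5,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[list[DoseResponseObservation], dict]:
    """Binomially noised observations on an SHMT curve.

    Per dose and replicate, ``n_effect ~ Binomial(n_units, rate(dose))``;
    one observation per dose-replicate pair is returned (the fitter averages
    replicates).  The truth record carries the generating parameters.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_units <= 0 or n_replicates <= 0:
        raise ConfigurationError("n_units and n_replicates must be positive")
    observations: list[DoseResponseObservation] = []
    for dose in doses:
        rate = shmt_rate(float(dose), d0, m)
        for _ in range(n_replicates):
            n_effect = int(rng.binomial(n_units, rate))
            observations.append(
                DoseResponseObservation(dose=float(dose), n_total=n_units, n_effect=n_effect)
            )
    truth = {
        "d0": d0,
        "m": m,
        "dq": d0 * float(np.log(m)),
        "n_units": n_units,
        "n_replicates": n_replicates,
    }
    return observations, truth


# ---------------------------------------------------------------------------
# variant cohorts
# ---------------------------------------------------------------------------


class _LocusPool:
    """Collision-free locus sampler over the genome model.

    A guard base on each side of every drawn span prevents accidental
    adjacency (which would create unplanned MNV runs).  The pool is shared
    across lines so induced keys are cohort-unique by construction.
    """

    def __init__(self, chromosomes: Mapping[str, int], rng: np.random.Generator):
        self.names = sorted(chromosomes)
        self.lengths = np.array([chromosomes[n] for n in self.names], dtype=float)
        self.weights = self.lengths / self.lengths.sum()
        self.rng = rng
        self.used: dict[str, set[int]] = {n: set() for n in self.names}

    def draw(self, span: int = 1) -> tuple[str, int]:
        for _ in range(10_000):
            idx = int(self.rng.choice(len(self.names), p=self.weights))
            chrom = self.names[idx]
            limit = int(self.lengths[idx]) - span - 1
            if limit < 2:
                continue
            pos = int(self.rng.integers(2, limit))
            window = range(pos - 1, pos + span + 1)
            if any(p in self.used[chrom] for p in window):
                continue
            self.used[chrom].update(range(pos, pos + span))
            return chrom, pos
        raise ConfigurationError("genome too small for the requested counts")


def _draw_af(cfg: SimulationConfig, zygosity: str, rng: np.random.Generator) -> float:
    if cfg.adversarial_af:
        # sample near the classification boundaries to stress the rules
        if zygosity == "homozygous":
            return float(rng.uniform(0.75, 0.80))
        return float(rng.uniform(0.25, 0.30) if rng.random() < 0.5 else rng.uniform(0.70, 0.7499))
    lo, hi = cfg.hom_af_range if zygosity == "homozygous" else cfg.het_af_range
    return float(rng.uniform(lo, hi))


def _draw_zygosity(hom_fraction: float, rng: np.random.Generator) -> str:
    return "homozygous" if rng.random() < hom_fraction else "heterozygous"


def _random_sbs_alleles(ts_probability: float, rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[int(rng.integers(4))]
    if rng.random() < ts_probability:
        return ref, _TRANSITION[ref]
    choices = [b for b in _BASES if b != ref and b != _TRANSITION[ref]]
    return ref, choices[int(rng.integers(2))]


def _new_truth_row(call: VariantCall, category: str, zygosity: str, origin: str, length: int) -> dict:
    return {
        "sample_id": call.sample_id,
        "chrom": call.chrom,
        "pos": call.pos,
        "ref": call.ref,
        "alt": call.alt,
        "sv_type": call.sv_type or "",
        "sv_end": call.sv_end or 0,
        "mate_chrom": call.mate_chrom or "",
        "mate_pos": call.mate_pos or 0,
        "category": category,
        "zygosity": zygosity,
        "origin": origin,
        "length": length,
    }


def simulate_mutant_lines(
    config: SimulationConfig,
    profiles: Sequence[GroupProfile],
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """Generate per-line call sets, CK controls and the ground-truth table.

    Per line, category counts are Poisson around the profile expectations;
    loci are uniform on the genome model; AFs come from the
    zygosity-specific windows; planted MNVs are emitted as runs of adjacent
    SBS calls; the configured fraction of SV loci lands on scaffold names.
    CK-shared background keys go into both controls and every line;
    cross-line keys are planted in exactly two lines each; low-quality
    decoys get sub-threshold quality values.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool = _LocusPool(config.chromosomes, rng)
    scaffold_names = list(config.scaffolds)
    lines: dict[str, list[VariantCall]] = {}
    truth_rows: list[dict] = []

    def qual(low: bool = False) -> float:
        lo, hi = config.low_qual_range if low else config.qual_range
        return float(np.round(rng.uniform(lo, hi), 1))

    def scaffold_locus() -> tuple[str, int]:
        name = scaffold_names[int(rng.integers(len(scaffold_names)))]
        return name, int(rng.integers(100, config.scaffold_length - 100))

    for profile in profiles:
        for line_idx in range(1, profile.n_lines + 1):
            sample = f"{profile.label}_{line_idx:02d}"
            calls: list[VariantCall] = []

            def add_small(origin: str, category: str, ref: str, alt: str, chrom: str, pos: int, zygosity: str, af: float, q: float, length: int) -> None:
                call = VariantCall(
                    sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    qual=q, af=af,
                ).validate()
                calls.append(call)
                truth_rows.append(_new_truth_row(call, category, zygosity, origin, length))

            # --- standalone SBS ---
            for _ in range(int(rng.poisson(profile.sbs))):
                chrom, pos = pool.draw(1)
                ref, alt = _random_sbs_alleles(profile.ts_probability, rng)
                zyg = _draw_zygosity(profile.hom_fraction, rng)
                add_small("induced", "SBS", ref, alt, chrom, pos, zyg, _draw_af(config, zyg, rng), qual(), 1)

            # --- MNV runs: emitted as adjacent SBS calls ---
            run_lengths = [l for l, _ in profile.mnv_length_probs]
            run_probs = [p for _, p in profile.mnv_length_probs]
            for _ in range(int(rng.poisson(profile.mnv))):
                length = int(rng.choice(run_lengths, p=run_probs))
                chrom, pos = pool.draw(length)
                zyg = _draw_zygosity(profile.hom_fraction, rng)
                af = _draw_af(config, zyg, rng)
                q = qual()
                for offset in range(length):
                    ref, alt = _random_sbs_alleles(profile.ts_probability, rng)
                    call = VariantCall(
                        sample_id=sample, chrom=chrom, pos=pos + offset,
                        ref=ref, alt=alt, qual=q, af=af,
                    ).validate()
                    calls.append(call)
                truth_rows.append(
                    {
                        "sample_id": sample, "chrom": chrom, "pos": pos,
                        "ref": "", "alt": "", "sv_type": "", "sv_end": 0,
                        "mate_chrom": "", "mate_pos": 0, "category": "MNV",
                        "zygosity": zyg, "origin": "induced", "length": length,
                    }
                )

            # --- INDELs ---
            for n_expected, category in (
                (profile.deletions, "INDEL_deletion"),
                (profile.insertions, "INDEL_insertion"),
            ):
                for _ in range(int(rng.poisson(n_expected))):
                    length = 1 if rng.random() < profile.indel_1bp_prob else int(rng.integers(2, 11))
                    chrom, pos = pool.draw(length + 1)
                    anchor = _BASES[int(rng.integers(4))]
                    run = "".join(_BASES[int(b)] for b in rng.integers(0, 4, length))
                    if category == "INDEL_deletion":
                        ref, alt = anchor + run, anchor
                    else:
                        ref, alt = anchor, anchor + run
                    zyg = _draw_zygosity(profile.hom_fraction, rng)
                    add_small("induced", category, ref, alt, chrom, pos, zyg, _draw_af(config, zyg, rng), qual(), length)

            # --- extent SVs ---
            # profile SV expectations are retained (on-chromosome) counts;
            # inflate the planted number so the scaffold router removes its
            # share without shrinking the retained spectrum
            sv_inflation = (
                1.0 / (1.0 - config.scaffold_fraction)
                if config.scaffold_fraction < 1.0
                else 1.0
            )
            for n_expected, sv_type in ((profile.del_sv, "DEL_SV"), (profile.dup_sv, "DUP_SV")):
                for _ in range(int(rng.poisson(n_expected * sv_inflation))):
                    span = int(rng.integers(100, 5001))
                    on_scaffold = rng.random() < config.scaffold_fraction
                    if on_scaffold:
                        chrom, pos = scaffold_locus()
                    else:
                        chrom, pos = pool.draw(2)
                    zyg = _draw_zygosity(profile.hom_fraction, rng)
                    call = VariantCall(
                        sample_id=sample, chrom=chrom, pos=pos, ref="N",
                        alt=f"<{sv_type[:3]}>", qual=qual(),
                        gt="1/1" if zyg == "homozygous" else "0/1",
                        sv_type=sv_type, sv_end=pos + span,
                    ).validate()
                    calls.append(call)
                    truth_rows.append(
                        _new_truth_row(call, sv_type, zyg, "induced_scaffold" if on_scaffold else "induced", span)
                    )

            # --- breakends ---
            for _ in range(int(rng.poisson(profile.bnd_sv * sv_inflation))):
                chrom, pos = pool.draw(2)
                if rng.random() < config.scaffold_fraction:
                    mate_chrom, mate_pos = scaffold_locus()
                    origin = "induced_scaffold"
                else:
                    mate_chrom, mate_pos = pool.draw(2)
                    origin = "induced"
                zyg = _draw_zygosity(profile.hom_fraction, rng)
                call = VariantCall(
                    sample_id=sample, chrom=chrom, pos=pos, ref="N",
                    alt=f"N[{mate_chrom}:{mate_pos}[", qual=qual(),
                    gt="1/1" if zyg == "homozygous" else "0/1",
                    sv_type="BND_SV", mate_chrom=mate_chrom, mate_pos=mate_pos,
                ).validate()
                calls.append(call)
                truth_rows.append(_new_truth_row(call, "BND_SV", zyg, origin, 0))

            # --- low-quality decoys ---
            for _ in range(config.n_low_quality):
                chrom, pos = pool.draw(1)
                ref, alt = _random_sbs_alleles(profile.ts_probability, rng)
                zyg = _draw_zygosity(profile.hom_fraction, rng)
                add_small("low_quality", "SBS", ref, alt, chrom, pos, zyg, _draw_af(config, zyg, rng), qual(low=True), 1)

            lines[sample] = calls

    sample_names = sorted(lines)

    # --- CK-shared background: in both controls and every line ---
    controls: list[list[VariantCall]] = [[], []]
    for _ in range(config.n_ck_shared):
        chrom, pos = pool.draw(1)
        ref, alt = _random_sbs_alleles(0.6, rng)
        zyg = _draw_zygosity(0.5, rng)
        af = _draw_af(config, zyg, rng)
        for ck_idx, ck in enumerate(controls, start=1):
            ck.append(
                VariantCall(sample_id=f"CK{ck_idx}", chrom=chrom, pos=pos, ref=ref, alt=alt, qual=45.0, af=af).validate()
            )
        for sample in sample_names:
            call = VariantCall(sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt, qual=45.0, af=af).validate()
            lines[sample].append(call)
            truth_rows.append(_new_truth_row(call, "SBS", zyg, "ck_shared", 1))

    # --- CK-private noise (harmless under intersection subtraction) ---
    for ck_idx, ck in enumerate(controls):
        for _ in range(config.n_ck_private):
            chrom, pos = pool.draw(1)
            ref, alt = _random_sbs_alleles(0.6, rng)
            ck.append(
                VariantCall(sample_id=f"CK{ck_idx + 1}", chrom=chrom, pos=pos, ref=ref, alt=alt, qual=45.0, af=float(rng.uniform(0.35, 0.65))).validate()
            )

    # --- cross-line shared artefacts: planted in exactly two lines ---
    if config.n_crossline_shared and len(sample_names) >= 2:
        for _ in range(config.n_crossline_shared):
            chrom, pos = pool.draw(1)
            ref, alt = _random_sbs_alleles(0.6, rng)
            zyg = _draw_zygosity(0.5, rng)
            af = _draw_af(config, zyg, rng)
            pair = rng.choice(len(sample_names), size=2, replace=False)
            for idx in pair:
                sample = sample_names[int(idx)]
                call = VariantCall(sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt, qual=45.0, af=af).validate()
                lines[sample].append(call)
                truth_rows.append(_new_truth_row(call, "SBS", zyg, "crossline_shared", 1))

    truth = pd.DataFrame(truth_rows).sort_values(
        ["sample_id", "chrom", "pos", "ref", "alt"], kind="stable"
    ).reset_index(drop=True)
    return SimulatedCohort(
        lines=lines, controls=controls, truth=truth, config=config, profiles=tuple(profiles)
    )


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def _check_freqs(name: str, freqs: Mapping[str, float]) -> tuple[list[str], list[float]]:
    labels = sorted(freqs)
    probs = [freqs[l] for l in labels]
    if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} frequencies must be non-negative and sum to 1")
    return labels, probs


def simulate_annotations(
    variants: pd.DataFrame,
    region_freqs: Mapping[str, float] = REGION_FREQS,
    impact_freqs: Mapping[str, float] = IMPACT_FREQS,
    class_freqs: Mapping[str, float] = CLASS_FREQS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[AnnotationRecord]:
    """Assign region/impact/class to variants by categorical draws.

    ``variants`` needs columns sample_id, chrom, pos, ref, alt.  The
    functional class is drawn only for single-base substitutions landing in
    an exon; everything else gets class ``none``, matching how an annotator
    restricts codon-level calls to coding SBSs.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    region_labels, region_p = _check_freqs("region", region_freqs)
    impact_labels, impact_p = _check_freqs("impact", impact_freqs)
    class_labels, class_p = _check_freqs("class", class_freqs)
    records: list[AnnotationRecord] = []
    for row in variants.itertuples(index=False):
        region = region_labels[int(rng.choice(len(region_labels), p=region_p))]
        impact = impact_labels[int(rng.choice(len(impact_labels), p=impact_p))]
        ref, alt = str(row.ref), str(row.alt)
        if region == "exon" and len(ref) == 1 == len(alt):
            f_class = class_labels[int(rng.choice(len(class_labels), p=class_p))]
        else:
            f_class = "none"
        records.append(
            AnnotationRecord(
                sample_id=row.sample_id,
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=ref,
                alt=alt,
                region=region,
                impact=impact,
                functional_class=f_class,
            )
        )
    return records


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict[str, Path]:
    """Write per-line and control VCFs plus the ground-truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = dict(cohort.config.chromosomes)
    for name in cohort.config.scaffolds:
        contigs[name] = cohort.config.scaffold_length
    paths: dict[str, Path] = {}
    for sample in sorted(cohort.lines):
        path = out / f"{sample}.vcf"
        write_vcf(cohort.lines[sample], path, sample, contigs)
        paths[sample] = path
    for i, ck in enumerate(cohort.controls, start=1):
        path = out / f"CK{i}.vcf"
        write_vcf(ck, path, f"CK{i}", contigs)
        paths[f"CK{i}"] = path
    truth_path = out / "ground_truth.tsv"
    cohort.truth.to_csv(truth_path, sep="\t", index=False)
    paths["ground_truth"] = truth_path
    return paths
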