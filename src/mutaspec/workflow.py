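"""End-to-end orchestration: simulate, fit, filter, summarize, report.

``run_full_analysis`` wires the stages together over synthetic study
inputs and writes plain TSV/JSON reports plus a run manifest.  The
manifest records the command parameters, seed, config hash, input
checksums and per-stage record counts; rerunning from the same manifest
settings reproduces every output byte for byte (no timestamps enter the
reports).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dose_response import ShmtCurve, rbe
from .effect_summary import functional_class_ratio, region_proportions, summarize_effects
from .pipeline import run_cohort
from .spectrum_stats import (
    CATEGORIES,
    aggregate,
    chi_squared_test,
    homozygous_fraction,
    sv_proportion,
)
from .synthetic_data import (
    DOSE_GRIDS,
    ENDPOINT_TRUTH,
    REPLICATES,
    SimulationConfig,
    carbon_profile,
    gamma_profile,
    simulate_annotations,
    simulate_dose_response,
    simulate_mutant_lines,
    write_cohort,
)
from .variant_io import write_report

__all__ = ["RunManifest", "run_full_analysis"]

logger = logging.getLogger("mutaspec")


def _stage(name: str) -> None:
    logger.info("[%s] running", name)


@dataclass
class RunManifest:
    """Everything needed to re-run a full analysis identically."""

    command: str
    seed: int
    config: dict
    package_version: str = __version__
    config_hash: str = ""
    input_checksums: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        payload = json.dumps(self.config, sort_keys=True).encode()
        self.config_hash = hashlib.sha256(payload).hexdigest()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), sort_keys=True, indent=2) + "\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(
    out_dir,
    seed: int = 0,
    scale: float = 1.0,
    n_lines: int = 16,
    write_vcfs: bool = False,
) -> dict:
    """Run every stage on synthetic study inputs and write reports.

    ``scale`` multiplies the per-line expected mutation counts (1.0 keeps
    the published study magnitudes); ``n_lines`` is the cohort size per
    mutagen.  Returns the collected results dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage_counts: dict = {}
    checksums: dict = {}

    # --- dose-response stage -------------------------------------------
    _stage("dose-response")
    rng = np.random.default_rng(seed)
    fits: dict[tuple[str, str], ShmtCurve] = {}
    dose_rows = []
    for (mutagen, endpoint), (d0, m) in sorted(ENDPOINT_TRUTH.items()):
        obs, truth = simulate_dose_response(
            DOSE_GRIDS[mutagen], d0, m,
            n_units=20, n_replicates=REPLICATES[mutagen], rng=rng,
        )
        dose = [o.dose for o in obs]
        rate = [o.rate for o in obs]
        model = ShmtCurve().fit(dose, rate)
        fits[(mutagen, endpoint)] = model
        dose_rows.append(
            {
                "mutagen": mutagen,
                "endpoint": endpoint,
                "d0": round(model.d0_, 3),
                "m": round(model.m_, 3),
                "dq": round(model.dq_, 2),
                "d50": round(model.dose_at_rate(0.5), 2),
                "r_squared": round(model.r_squared_, 4),
                "true_dq": round(truth["dq"], 2),
            }
        )
    dose_df = pd.DataFrame(dose_rows)
    write_report(dose_df, out / "dose_response.tsv")
    checksums["dose_response.tsv"] = _checksum(out / "dose_response.tsv")
    stage_counts["dose_response_fits"] = len(dose_rows)
    results["dose_response"] = dose_df

    rbe_rows = []
    for endpoint in ("survival", "fertility"):
        ref = fits[("gamma", endpoint)]
        test = fits[("carbon", endpoint)]
        rbe_rows.append(
            {
                "endpoint": f"{endpoint}_dq",
                "reference_dose": round(ref.dq_, 1),
                "test_dose": round(test.dq_, 1),
                "rbe": rbe(ref.dq_, test.dq_).rounded,
            }
        )
        rbe_rows.append(
            {
                "endpoint": f"{endpoint}_d50",
                "reference_dose": round(ref.dose_at_rate(0.5), 1),
                "test_dose": round(test.dose_at_rate(0.5), 1),
                "rbe": rbe(ref.dose_at_rate(0.5), test.dose_at_rate(0.5)).rounded,
            }
        )
    rbe_df = pd.DataFrame(rbe_rows)
    write_report(rbe_df, out / "rbe.tsv")
    checksums["rbe.tsv"] = _checksum(out / "rbe.tsv")
    results["rbe"] = rbe_df

    # --- cohort simulation + pipeline ----------------------------------
    _stage("simulate-cohort")
    config = SimulationConfig(seed=seed)
    cohort = simulate_mutant_lines(
        config,
        [carbon_profile(scale, n_lines), gamma_profile(scale, n_lines)],
        rng=rng,
    )
    if write_vcfs:
        for name, path in write_cohort(cohort, out / "vcf").items():
            checksums[f"vcf/{Path(path).name}"] = _checksum(Path(path))
    stage_counts["raw_calls"] = sum(len(c) for c in cohort.lines.values())

    _stage("pipeline")
    chrom_names = set(config.chromosomes)
    line_sets = run_cohort(cohort.lines, cohort.controls, chromosome_names=chrom_names)
    stage_counts["retained_events"] = sum(len(ls.calls) for ls in line_sets.values())

    # --- spectrum summaries --------------------------------------------
    _stage("spectrum")
    spectra = {}
    spectrum_rows = []
    for label in ("carbon", "gamma"):
        group = [line_sets[s] for s in sorted(line_sets) if s.startswith(label)]
        for scope in ("homozygous", "homozygous+heterozygous"):
            summary = aggregate(group, scope, group_label=label)
            spectra[(label, scope)] = summary
            row = {"group": label, "scope": scope, "total": summary.total}
            row.update({c: summary.counts[c] for c in CATEGORIES})
            row["sv_pct"] = round(sv_proportion(summary), 2)
            spectrum_rows.append(row)
    for label in ("carbon", "gamma"):
        homo = spectra[(label, "homozygous")]
        both = spectra[(label, "homozygous+heterozygous")]
        results[f"homozygous_fraction_{label}"] = homozygous_fraction(homo, both)
    spectrum_df = pd.DataFrame(spectrum_rows)
    write_report(spectrum_df, out / "spectrum.tsv")
    checksums["spectrum.tsv"] = _checksum(out / "spectrum.tsv")
    results["spectrum"] = spectrum_df

    table = [
        [spectra[(label, "homozygous+heterozygous")].counts[c] for c in CATEGORIES]
        for label in ("carbon", "gamma")
    ]
    # drop all-zero categories so expected counts stay positive
    keep = [i for i in range(len(CATEGORIES)) if any(row[i] for row in table)]
    chi = chi_squared_test([[row[i] for i in keep] for row in table])
    results["category_chi_squared"] = {
        "statistic": chi.statistic,
        "df": chi.df,
        "p_value": chi.p_value,
        "significant": chi.significant,
    }

    # --- annotations + effects -----------------------------------------
    _stage("effects")
    retained = cohort.truth[cohort.truth["origin"] == "induced"]
    annotations = simulate_annotations(retained, rng=rng)
    groups = {
        label: [a for a in annotations if a.sample_id.startswith(label)]
        for label in ("carbon", "gamma")
    }
    effect_summaries = summarize_effects(groups)
    effect_rows = []
    for label, summary in sorted(effect_summaries.items()):
        props = region_proportions(summary.region_counts)
        effect_rows.append(
            {
                "group": label,
                "common_region_share": round(summary.common_region_share, 2),
                "intergenic_pct": round(props.get("intergenic", 0.0), 2),
                "missense_silent_ratio": (
                    round(functional_class_ratio(summary.class_counts), 2)
                ),
                **{f"impact_{k.lower()}": v for k, v in summary.impact_counts.items()},
            }
        )
    effects_df = pd.DataFrame(effect_rows)
    write_report(effects_df, out / "effects.tsv")
    checksums["effects.tsv"] = _checksum(out / "effects.tsv")
    results["effects"] = effects_df

    # --- provenance + manifest -----------------------------------------
    prov_rows = []
    for sample in sorted(line_sets):
        row = {"sample_id": sample, "raw": line_sets[sample].raw_count}
        row.update(line_sets[sample].provenance)
        prov_rows.append(row)
    prov_df = pd.DataFrame(prov_rows)
    write_report(prov_df, out / "provenance.tsv")
    checksums["provenance.tsv"] = _checksum(out / "provenance.tsv")

    summary_json = {
        "homozygous_fraction_carbon": round(results["homozygous_fraction_carbon"], 2),
        "homozygous_fraction_gamma": round(results["homozygous_fraction_gamma"], 2),
        "category_chi_squared": {
            k: (round(v, 6) if isinstance(v, float) else v)
            for k, v in results["category_chi_squared"].items()
        },
    }
    (out / "summary.json").write_text(json.dumps(summary_json, sort_keys=True, indent=2) + "\n")
    checksums["summary.json"] = _checksum(out / "summary.json")

    manifest = RunManifest(
        command="run-all",
        seed=seed,
        config={"scale": scale, "n_lines": n_lines, "write_vcfs": write_vcfs},
        input_checksums=checksums,
        stage_counts=stage_counts,
    )
    manifest.write(out / "manifest.json")
    results["manifest"] = manifest
    results["line_sets"] = line_sets
    results["cohort"] = cohort
    return results


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
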