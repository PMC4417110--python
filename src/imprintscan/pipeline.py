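"""End-to-end orchestration: reads -> QC'd clones -> allelic profile -> calls.

``process_sample`` is the per-sample core shared by the command-line stages:
align, call methylation, compute conversion QC, filter, deduplicate, assign
alleles.  ``run_preset_pipeline`` runs a whole simulated imprint-timing study
(sperm + oocyte + somatic samples) and writes every intermediate table, so a
fixed seed and configuration reproduce byte-identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as iomod
from .alleles import AllelicMethylationProfile, DmrCall, classify_dmr
from .bisulfite import AlignParams, Amplicon, BisulfiteClone, build_clones, deduplicate, filter_clones
from .config import RunConfig
from .lollipop import render_lollipop
from .origin import GameteCall, classify_germline_origin, gamete_state
from .synthetic import (
    DEFAULT_NOISE,
    PRESETS,
    NoiseProfile,
    default_amplicon,
    preset_scenarios,
    simulate_clones,
)

logger = logging.getLogger("imprintscan")


@dataclass
class SampleResult:
    """Per-sample accounting of the clone-processing chain."""

    sample_id: str
    clones: list[BisulfiteClone]  # unique, QC-passed, allele-assigned
    rejected: list[tuple[str, str]]  # (clone_id, reason)
    n_input: int
    profile: AllelicMethylationProfile | None = None
    dmr_call: DmrCall | None = None
    gamete_call: GameteCall | None = None


def align_params(config: RunConfig) -> AlignParams:
    return AlignParams(
        min_read_length=config.min_read_length,
        identity_floor=config.identity_floor,
    )


def process_sample(
    reads: Sequence[tuple[str, str]],
    sample_id: str,
    amplicon: Amplicon,
    config: RunConfig = RunConfig(),
    split_alleles: bool = True,
) -> SampleResult:
    """Align, QC-filter and deduplicate one sample's clone reads.

    With ``split_alleles`` (and a usable SNP on the amplicon) the surviving
    unique clones are partitioned by allele and the DMR status classified;
    gamete samples typically skip the split and are summarized pooled.
    """
    clones, rejected = build_clones(reads, sample_id, amplicon, align_params(config))
    min_called = max(1, int(round(config.min_called_fraction * amplicon.n_cpg)))
    kept, qc_rejected = filter_clones(
        clones, min_efficiency=config.min_efficiency, min_called_cpgs=min_called
    )
    rejected = rejected + [(c.clone_id, reason) for c, reason in qc_rejected]
    unique = deduplicate(kept)
    result = SampleResult(sample_id, unique, rejected, n_input=len(reads))
    logger.info(
        "%s: %d reads, %d rejected, %d unique clones",
        sample_id, len(reads), len(rejected), len(unique),
    )
    if split_alleles:
        result.profile = AllelicMethylationProfile.from_clones(
            unique, amplicon, sample_id=sample_id, assign=bool(amplicon.usable_snps())
        )
        result.dmr_call = classify_dmr(
            result.profile, hi=config.dmr_hi, lo=config.dmr_lo,
            min_clones=config.dmr_min_clones,
        )
    else:
        result.gamete_call = gamete_state(
            unique, hi=config.gamete_hi, lo=config.gamete_lo,
            min_clones=config.gamete_min_clones,
            partial_lo=config.partial_lo, partial_hi=config.partial_hi,
        )
    return result


def classify_locus(
    sperm: SampleResult, oocyte: SampleResult, somatic: SampleResult, locus: str = ""
):
    """Combine processed gamete and somatic samples into an origin call."""
    notes = [
        f"{name}: {r.gamete_call.contamination_note}"
        for name, r in (("sperm", sperm), ("oocyte", oocyte))
        if r.gamete_call and r.gamete_call.contamination_note
    ]
    return classify_germline_origin(
        sperm.gamete_call.state,
        oocyte.gamete_call.state,
        somatic.dmr_call.status,
        locus=locus,
        contamination_note="; ".join(notes),
    )


def run_preset_pipeline(
    preset_name: str,
    out_dir: str | Path,
    config: RunConfig = RunConfig(),
    noise: NoiseProfile = DEFAULT_NOISE,
    n_molecules: int = 30,
    write_outputs: bool = True,
):
    """Simulate one imprint-timing preset and run the full analysis chain.

    Writes (when ``write_outputs``): amplicon FASTA + sidecar, per-sample
    clone FASTA, ground-truth TSV, clone table, rejected table, profile TSV,
    lollipop text, a DMR-status JSON and the origin-call TSV, all embedding
    the configuration hash.  Returns the origin call and sample results.
    """
    if preset_name not in PRESETS:
        raise ValueError(f"unknown preset {preset_name!r}; choose from {sorted(PRESETS)}")
    out_dir = Path(out_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
    amplicon = default_amplicon(seed=config.seed)
    scenarios = preset_scenarios(
        preset_name, seed=config.seed, noise=noise, n_molecules=n_molecules
    )
    results: dict[str, SampleResult] = {}
    for sample, scenario in scenarios.items():
        reads, truth = simulate_clones(amplicon, scenario)
        result = process_sample(
            reads, scenario.scenario_id, amplicon, config,
            split_alleles=(sample == "somatic"),
        )
        results[sample] = result
        if write_outputs:
            iomod.write_fasta(reads, out_dir / f"{sample}.clones.fasta")
            iomod.write_tsv(truth, out_dir / f"{sample}.truth.tsv", config.config_hash)
            iomod.write_tsv(
                iomod.clone_table(result.clones),
                out_dir / f"{sample}.clone_table.tsv",
                config.config_hash,
            )
            iomod.write_tsv(
                pd.DataFrame(result.rejected, columns=["clone_id", "reason"]),
                out_dir / f"{sample}.rejected.tsv",
                config.config_hash,
            )
    origin = classify_locus(
        results["sperm"], results["oocyte"], results["somatic"], locus=preset_name
    )
    if write_outputs:
        iomod.write_amplicon(amplicon, out_dir / "amplicon.fasta")
        somatic = results["somatic"]
        iomod.write_tsv(
            iomod.profile_table(somatic.profile),
            out_dir / "somatic.profile.tsv",
            config.config_hash,
        )
        (out_dir / "somatic.lollipop.txt").write_text(render_lollipop(somatic.profile))
        (out_dir / "dmr_status.json").write_text(
            json.dumps(
                {
                    "sample_id": somatic.sample_id,
                    "status": somatic.dmr_call.status,
                    "phased": somatic.dmr_call.phased,
                    "allele_means": somatic.dmr_call.allele_means,
                    "config_hash": config.config_hash,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        origin_df = pd.DataFrame(
            [
                dict(
                    locus=origin.locus,
                    sperm_state=origin.sperm_state,
                    oocyte_state=origin.oocyte_state,
                    somatic_status=origin.somatic_status,
                    origin=origin.origin,
                    reason=origin.reason,
                    contamination_note=origin.contamination_note,
                )
            ]
        )
        iomod.write_tsv(origin_df, out_dir / "origin_calls.tsv", config.config_hash)
        config.save(out_dir / "run_config.json")
    return origin, results
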