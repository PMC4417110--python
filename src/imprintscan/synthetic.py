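"""Synthetic bisulfite clone-sequencing data with known ground truth.

Emulates the structure of a locus-specific imprinting study: short PCR
amplicons (a few hundred bp, 10–30 CpGs, at least one heterozygous non-C/T
SNP), clone sets of tens of capillary reads per sample drawn from two parental
epialleles, per-molecule bisulfite conversion failure, sequencing error, PCR
duplication, and optional somatic-cell contamination of gamete samples.

Every emitted read is paired with a ground-truth row (source allele, true
per-CpG methylation states, duplicate-of pointer, contaminant flag) so the
full analysis chain can be validated end to end.

Conventions: the maternal chromosome carries each SNP's reference allele and
the paternal chromosome the alternate allele, so the allele labels recovered
downstream (A = reference, B = alternate) map deterministically onto truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bisulfite import Amplicon, Snp, StrandMode, snp_pair_collapses

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one simulated clone-sequencing sample.

    ``maternal_meth_prob``/``paternal_meth_prob`` are the per-CpG methylation
    probabilities of the two parental epialleles.  In a gamete sample both are
    set to the gamete's level (all molecules of one germline carry the same
    imprint state regardless of which chromosome they bear).

    Noise model: ``conversion_failure_rate`` is the probability a non-CpG
    cytosine is NOT converted (and an unmethylated CpG cytosine is retained);
    ``inappropriate_conversion_rate`` the probability a methylated CpG
    converts anyway; ``seq_error_rate`` a per-base substitution probability
    applied last; ``pcr_duplicate_rate`` the fraction of emitted clones that
    are exact resampled copies of earlier reads; ``contamination_fraction``
    the fraction of molecules drawn from a contaminant epiallele pair (e.g.
    somatic cells in a gamete preparation).
    """

    scenario_id: str
    maternal_meth_prob: float
    paternal_meth_prob: float
    conversion_failure_rate: float = 0.01
    inappropriate_conversion_rate: float = 0.0
    seq_error_rate: float = 0.002
    n_molecules: int = 30
    pcr_duplicate_rate: float = 0.0
    contamination_fraction: float = 0.0
    contaminant_maternal_prob: float = 1.0
    contaminant_paternal_prob: float = 0.0
    maternal_fraction: float = 0.5
    blocky: bool = False
    end_trim_max: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in (
            "maternal_meth_prob",
            "paternal_meth_prob",
            "conversion_failure_rate",
            "inappropriate_conversion_rate",
            "seq_error_rate",
            "contaminant_maternal_prob",
            "contaminant_paternal_prob",
            "maternal_fraction",
        ):
            _check_prob(name, getattr(self, name))
        if not (0.0 <= self.pcr_duplicate_rate < 1.0):
            raise ValueError("pcr_duplicate_rate must be in [0, 1)")
        if not (0.0 <= self.contamination_fraction < 1.0):
            raise ValueError("contamination_fraction must be in [0, 1)")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.end_trim_max < 0:
            raise ValueError("end_trim_max must be >= 0")


@dataclass(frozen=True)
class ImprintPreset:
    """Gamete and somatic methylation levels for one imprint-timing group."""

    name: str
    sperm_meth: float
    oocyte_meth: float
    somatic_maternal: float
    somatic_paternal: float
    expected_origin: str


#: Methylation levels of a methylated / unmethylated epiallele in the presets.
#: Near-all-or-none rather than exactly 1/0: real clone sets show sporadic
#: discordant CpGs within otherwise uniform epialleles, so distinct molecules
#: rarely produce byte-identical patterns.
METH_LEVEL = 0.98
UNMETH_LEVEL = 0.02

#: The three germline imprint-timing groups: methylation acquired in the male
#: germline, in the female germline, or only after fertilization (gametes both
#: unmethylated, somatic tissue differentially methylated).
PRESETS: dict[str, ImprintPreset] = {
    "paternal-germline": ImprintPreset(
        "paternal-germline", METH_LEVEL, UNMETH_LEVEL, UNMETH_LEVEL, METH_LEVEL,
        "paternal_germline",
    ),
    "maternal-germline": ImprintPreset(
        "maternal-germline", UNMETH_LEVEL, METH_LEVEL, METH_LEVEL, UNMETH_LEVEL,
        "maternal_germline",
    ),
    "delayed-maternal": ImprintPreset(
        "delayed-maternal", UNMETH_LEVEL, UNMETH_LEVEL, METH_LEVEL, UNMETH_LEVEL,
        "post_fertilization_maternal",
    ),
}


@dataclass(frozen=True)
class NoiseProfile:
    """Shared noise settings applied to every sample of a preset run."""

    conversion_failure_rate: float = 0.01
    inappropriate_conversion_rate: float = 0.0
    seq_error_rate: float = 0.002
    pcr_duplicate_rate: float = 0.1
    gamete_contamination: float = 0.04


ZERO_NOISE = NoiseProfile(0.0, 0.0, 0.0, 0.0, 0.0)
DEFAULT_NOISE = NoiseProfile()


def preset_scenarios(
    preset: ImprintPreset | str,
    seed: int = 0,
    noise: NoiseProfile = DEFAULT_NOISE,
    n_molecules: int = 30,
) -> dict[str, SimulationScenario]:
    """Sperm, oocyte and somatic sample scenarios for one imprint group.

    Gamete samples put both parental epialleles at the gamete's methylation
    level; their contaminant epiallele pair is the preset's somatic state, so
    contamination of an unmethylated gamete sample introduces partially or
    fully methylated clones, as somatic carry-over would.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    common = dict(
        conversion_failure_rate=noise.conversion_failure_rate,
        inappropriate_conversion_rate=noise.inappropriate_conversion_rate,
        seq_error_rate=noise.seq_error_rate,
        pcr_duplicate_rate=noise.pcr_duplicate_rate,
        n_molecules=n_molecules,
        contaminant_maternal_prob=preset.somatic_maternal,
        contaminant_paternal_prob=preset.somatic_paternal,
    )
    return {
        "sperm": SimulationScenario(
            scenario_id=f"{preset.name}-sperm",
            maternal_meth_prob=preset.sperm_meth,
            paternal_meth_prob=preset.sperm_meth,
            contamination_fraction=noise.gamete_contamination,
            seed=seed * 3 + 0,
            **common,
        ),
        "oocyte": SimulationScenario(
            scenario_id=f"{preset.name}-oocyte",
            maternal_meth_prob=preset.oocyte_meth,
            paternal_meth_prob=preset.oocyte_meth,
            contamination_fraction=noise.gamete_contamination,
            seed=seed * 3 + 1,
            **common,
        ),
        "somatic": SimulationScenario(
            scenario_id=f"{preset.name}-somatic",
            maternal_meth_prob=preset.somatic_maternal,
            paternal_meth_prob=preset.somatic_paternal,
            contamination_fraction=0.0,
            seed=seed * 3 + 2,
            **common,
        ),
    }


def make_amplicon(
    length: int,
    n_cpg: int,
    snp_spec: Sequence[tuple[int, tuple[str, str]]],
    gc_content: float = 0.45,
    seed: int = 0,
    amplicon_id: str | None = None,
    strand_mode: StrandMode = "top",
    allow_collapsing_snps: bool = False,
) -> Amplicon:
    """Construct a random amplicon with exactly ``n_cpg`` CpGs and the given SNPs.

    SNP allele pairs that collapse under bisulfite conversion (C/T on the top
    strand, G/A on the bottom) are rejected unless ``allow_collapsing_snps``
    is set, since allele assignment in converted reads requires a non-C/T
    polymorphism; if accepted they are flagged unusable.
    """
    if length < 50:
        raise ValueError("length must be >= 50")
    if n_cpg < 1:
        raise ValueError("n_cpg must be >= 1")
    _check_prob("gc_content", gc_content)
    snp_offsets = [o for o, _ in snp_spec]
    if len(set(snp_offsets)) != len(snp_offsets):
        raise ValueError("duplicate SNP offsets")
    for o, (a, b) in snp_spec:
        if not (1 <= o < length - 1):
            raise ValueError(f"SNP offset {o} must be inside (0, {length - 1})")
        if a == b or not {a, b} <= set("ACGT"):
            raise ValueError(f"invalid allele pair {a}/{b}")
        if snp_pair_collapses(a, b, strand_mode) and not allow_collapsing_snps:
            raise ValueError(
                f"allele pair {a}/{b} at offset {o} collapses under bisulfite "
                f"conversion ({strand_mode} strand); allele assignment needs a "
                "non-C/T SNP (set allow_collapsing_snps to keep it, flagged unusable)"
            )
    # candidate CpG starts: >=3 apart from each other, >=2 from any SNP, off the ends
    forbidden = {q for o in snp_offsets for q in range(o - 1, o + 2)}
    candidates = [p for p in range(2, length - 3) if not ({p, p + 1} & forbidden)]
    rng = np.random.default_rng(seed)
    rng.shuffle(candidates)
    cpg_positions: list[int] = []
    for p in candidates:
        if all(abs(p - q) >= 3 for q in cpg_positions):
            cpg_positions.append(p)
            if len(cpg_positions) == n_cpg:
                break
    if len(cpg_positions) < n_cpg:
        raise ValueError(
            f"cannot place {n_cpg} CpGs in {length} bp around {len(snp_spec)} SNPs: "
            "CpG starts need >=3 bp separation and >=2 bp clearance from SNPs"
        )
    cpg_positions.sort()

    # background sequence with the requested GC content and no CpG dinucleotides
    p_each = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    bases = "ACGT"
    seq = []
    for i in range(length):
        b = bases[rng.choice(4, p=p_each)]
        if seq and seq[-1] == "C" and b == "G":
            b = "A"
        seq.append(b)
    for p in cpg_positions:
        seq[p], seq[p + 1] = "C", "G"
    for o, (ref, _alt) in snp_spec:
        seq[o] = ref
    # neither allele may create or sit in a CpG context
    for o, (ref, alt) in snp_spec:
        if "G" in (ref, alt) and seq[o - 1] == "C":
            seq[o - 1] = "A"
        if "C" in (ref, alt) and seq[o + 1] == "G":
            seq[o + 1] = "T"
    # scrub accidental CpGs introduced by SNP/CpG placement edits
    recorded = set(cpg_positions)
    snp_set = set(snp_offsets)
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in recorded:
            j = i if i not in snp_set else i + 1
            if j in snp_set:  # both members are SNPs; cannot happen with clearance
                raise ValueError("unresolvable CpG at SNP pair")
            seq[j] = "T" if j == i else "A"
    sequence = "".join(seq)
    assert sequence.count("CG") == n_cpg, "CpG placement failed"
    snps = tuple(Snp.make(o, ref, alt, strand_mode) for o, (ref, alt) in snp_spec)
    return Amplicon(
        amplicon_id=amplicon_id or f"amplicon-L{length}-cpg{n_cpg}-s{seed}",
        sequence=sequence,
        cpg_positions=tuple(cpg_positions),
        snps=snps,
        strand_mode=strand_mode,
    )


def default_amplicon(seed: int = 0, length: int = 160, n_cpg: int = 12) -> Amplicon:
    """A study-scale amplicon with one usable A/G SNP, for presets and demos."""
    return make_amplicon(
        length=length,
        n_cpg=n_cpg,
        snp_spec=[(length // 2, ("A", "G"))],
        seed=seed,
    )


def _bisulfite_read(
    amplicon: Amplicon,
    allele: str,
    meth_states: np.ndarray,
    conversion_failure: float,
    inappropriate_conversion: float,
    seq_error: float,
    rng: np.random.Generator,
) -> str:
    seq = list(amplicon.sequence)
    # SNP base by allele: maternal carries ref, paternal carries alt
    for s in amplicon.snps:
        seq[s.offset] = s.ref_allele if allele == "maternal" else s.alt_allele
    top = amplicon.strand_mode == "top"
    convertible, converted_to = ("C", "T") if top else ("G", "A")
    cpg_site = set(amplicon.cpg_positions) if top else {p + 1 for p in amplicon.cpg_positions}
    cpg_index = {o: i for i, o in enumerate(sorted(cpg_site))}
    for i, b in enumerate(seq):
        if b != convertible:
            continue
        if i in cpg_site:
            if meth_states[cpg_index[i]]:
                if rng.random() < inappropriate_conversion:
                    seq[i] = converted_to
            else:
                if rng.random() >= conversion_failure:
                    seq[i] = converted_to
        else:
            if rng.random() >= conversion_failure:
                seq[i] = converted_to
    # substitution errors last
    if seq_error > 0:
        for i in range(len(seq)):
            if rng.random() < seq_error:
                seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    return "".join(seq)


def simulate_clones(
    amplicon: Amplicon, scenario: SimulationScenario
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate a clone set; returns ((clone_id, read) pairs, ground truth).

    Each molecule draws a parental allele, a contaminant flag, then per-CpG
    methylation states from the allele's probability (a single draw shared by
    all CpGs in ``blocky`` mode).  The read applies bisulfite conversion with
    the scenario's failure rates, sets SNP bases by allele, and adds
    substitution errors last; up to ``end_trim_max`` bases are then clipped
    from each end, emulating variable capillary read boundaries.  After the first read, each emitted clone is an
    exact copy of a uniformly chosen earlier read with probability
    ``pcr_duplicate_rate``; emission stops once ``n_molecules`` distinct
    molecules are out, so the read count is ``n_molecules`` plus duplicates.

    Ground-truth columns: clone_id, allele, dup_of (empty for originals),
    contaminant, meth_string ('1'/'0' per CpG, in amplicon CpG order).
    """
    rng = np.random.default_rng(scenario.seed)
    n_cpg = amplicon.n_cpg
    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    originals_emitted = 0
    i = 0
    while originals_emitted < scenario.n_molecules:
        clone_id = f"{scenario.scenario_id}|clone{i:03d}"
        if reads and rng.random() < scenario.pcr_duplicate_rate:
            src = int(rng.integers(len(reads)))
            reads.append((clone_id, reads[src][1]))
            parent = truth_rows[src]
            truth_rows.append(
                {
                    "clone_id": clone_id,
                    "allele": parent["allele"],
                    "dup_of": reads[src][0],
                    "contaminant": parent["contaminant"],
                    "meth_string": parent["meth_string"],
                }
            )
        else:
            contaminant = rng.random() < scenario.contamination_fraction
            allele = "maternal" if rng.random() < scenario.maternal_fraction else "paternal"
            if contaminant:
                p = (
                    scenario.contaminant_maternal_prob
                    if allele == "maternal"
                    else scenario.contaminant_paternal_prob
                )
            else:
                p = (
                    scenario.maternal_meth_prob
                    if allele == "maternal"
                    else scenario.paternal_meth_prob
                )
            if scenario.blocky:
                meth = np.full(n_cpg, rng.random() < p)
            else:
                meth = rng.random(n_cpg) < p
            read = _bisulfite_read(
                amplicon,
                allele,
                meth,
                scenario.conversion_failure_rate,
                scenario.inappropriate_conversion_rate,
                scenario.seq_error_rate,
                rng,
            )
            if scenario.end_trim_max > 0:
                # capillary reads start/end at slightly different points
                # (primer trimming, base-call quality clipping)
                t5 = int(rng.integers(0, scenario.end_trim_max + 1))
                t3 = int(rng.integers(0, scenario.end_trim_max + 1))
                read = read[t5 : len(read) - t3 if t3 else len(read)]
            reads.append((clone_id, read))
            truth_rows.append(
                {
                    "clone_id": clone_id,
                    "allele": allele,
                    "dup_of": "",
                    "contaminant": contaminant,
                    "meth_string": "".join("1" if m else "0" for m in meth),
                }
            )
            originals_emitted += 1
        i += 1
    truth = pd.DataFrame(
        truth_rows, columns=["clone_id", "allele", "dup_of", "contaminant", "meth_string"]
    )
    return reads, truth


def simulate_pyro(
    true_fraction: float,
    sd: float,
    n_replicates: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Pyrosequencing allele-quantification noise model.

    Replicate measurements are truncated-normal around the true allele
    fraction, bounded to [0, 1] (AQ-mode outputs are percentages of a bounded
    signal).  ``sd = 0`` returns the true fraction exactly.
    """
    _check_prob("true_fraction", true_fraction)
    _check_prob("sd", sd)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if sd == 0:
        return np.full(n_replicates, true_fraction)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = (0.0 - true_fraction) / sd
    b = (1.0 - true_fraction) / sd
    return stats.truncnorm.rvs(
        a, b, loc=true_fraction, scale=sd, size=n_replicates, random_state=rng
    )
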