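"""Allele assignment of bisulfite clones and DMR classification.

Because the animals are outbred, a heterozygous SNP inside the amplicon lets
each clone be tied to one of the two chromosomes — provided the SNP survives
bisulfite conversion: a C/T polymorphism (top strand; G/A bottom) is useless
because the unmethylated C allele also reads as T.  With clones partitioned
by allele, a differentially methylated region (DMR) shows one allele
hypermethylated and the other hypomethylated.

Without pedigrees the parental origin of each allele cannot be established;
alleles are labeled A (reference base) and B (alternate).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .bisulfite import (
    METHYLATED,
    MISSING,
    UNMETHYLATED,
    Amplicon,
    BisulfiteClone,
    expected_read_base,
    snp_pair_collapses,
)

ALLELES = ("A", "B", "unassigned")


@dataclass(frozen=True)
class CandidateSnp:
    """A biallelic split observed across aligned clones at one offset."""

    offset: int
    base_a: str
    base_b: str
    n_a: int
    n_b: int
    usable_for_bisulfite: bool


def discover_snps(
    clones: Sequence[BisulfiteClone],
    amplicon: Amplicon,
    min_clones_per_allele: int = 2,
) -> list[CandidateSnp]:
    """Find offsets where unique clones split into exactly two bases.

    Splits at CpG dinucleotides, and C/T splits (top strand; G/A bottom), are
    reported but flagged unusable: they are indistinguishable from methylation
    state or conversion failure.  A recurrently unconverted non-CpG cytosine
    therefore shows up as an (unusable) C/T candidate rather than vanishing.
    """
    if len(clones) < 2 * min_clones_per_allele:
        raise ValueError(
            f"need >= {2 * min_clones_per_allele} unique clones to split two alleles"
        )
    cpg_footprint = {q for p in amplicon.cpg_positions for q in (p, p + 1)}
    out: list[CandidateSnp] = []
    for offset in range(len(amplicon.sequence)):
        counts = Counter()
        for c in clones:
            b = c.alignment.read_bases[offset]
            if b in {"A", "C", "G", "T"}:
                counts[b] += 1
        if len(counts) != 2:
            continue
        (b1, n1), (b2, n2) = counts.most_common()
        if min(n1, n2) < min_clones_per_allele:
            continue
        usable = offset not in cpg_footprint and not snp_pair_collapses(
            b1, b2, amplicon.strand_mode
        )
        out.append(CandidateSnp(offset, b1, b2, n1, n2, usable))
    return out


class UninformativeSampleError(ValueError):
    """Raised when an amplicon carries no SNP usable for allele assignment."""


def assign_allele(clone: BisulfiteClone, amplicon: Amplicon) -> str:
    """Assign a clone to allele A (reference base) or B (alternate) at usable SNPs.

    Each usable SNP votes by comparing the aligned read base with the
    conversion-adjusted expectation for either allele; majority wins, ties or
    no votes (gaps, sequencing errors) give ``unassigned``.
    """
    usable = amplicon.usable_snps()
    if not usable:
        raise UninformativeSampleError(
            f"amplicon {amplicon.amplicon_id} has no SNP usable for bisulfite "
            "allele assignment (uninformative_sample)"
        )
    votes = Counter()
    for s in usable:
        b = clone.alignment.read_bases[s.offset]
        if b == expected_read_base(s.ref_allele, amplicon.strand_mode):
            votes["A"] += 1
        elif b == expected_read_base(s.alt_allele, amplicon.strand_mode):
            votes["B"] += 1
    if not votes:
        return "unassigned"
    top = votes.most_common()
    if len(top) == 2 and top[0][1] == top[1][1]:
        return "unassigned"
    return top[0][0]


def assign_alleles(clones: Iterable[BisulfiteClone], amplicon: Amplicon) -> list[BisulfiteClone]:
    """Assign every clone in place; returns the same list for chaining."""
    clones = list(clones)
    for c in clones:
        c.allele = assign_allele(c, amplicon)
    return clones


@dataclass
class AllelicMethylationProfile:
    """Per-allele × per-CpG methylation summary of one sample's unique clones."""

    amplicon_id: str
    sample_id: str
    n_cpg: int
    clones_by_allele: dict[str, list[BisulfiteClone]]
    has_usable_snp: bool = True
    dmr_status: str | None = None

    @classmethod
    def from_clones(
        cls,
        clones: Sequence[BisulfiteClone],
        amplicon: Amplicon,
        sample_id: str | None = None,
        assign: bool = True,
    ) -> "AllelicMethylationProfile":
        clones = list(clones)
        has_snp = bool(amplicon.usable_snps())
        if assign and has_snp:
            assign_alleles(clones, amplicon)
        by_allele: dict[str, list[BisulfiteClone]] = {a: [] for a in ALLELES}
        for c in clones:
            by_allele[c.allele if has_snp else "unassigned"].append(c)
        return cls(
            amplicon_id=amplicon.amplicon_id,
            sample_id=sample_id or (clones[0].sample_id if clones else ""),
            n_cpg=amplicon.n_cpg,
            clones_by_allele=by_allele,
            has_usable_snp=has_snp,
        )

    @property
    def all_clones(self) -> list[BisulfiteClone]:
        return [c for a in ALLELES for c in self.clones_by_allele[a]]

    def clone_count(self, allele: str) -> int:
        return len(self.clones_by_allele[allele])

    def counts(self, allele: str) -> np.ndarray:
        """(n_cpg, 3) array of methylated / unmethylated / missing counts."""
        out = np.zeros((self.n_cpg, 3), dtype=int)
        for c in self.clones_by_allele[allele]:
            for i, call in enumerate(c.cpg_calls):
                col = {METHYLATED: 0, UNMETHYLATED: 1, MISSING: 2}[call]
                out[i, col] += 1
        return out

    def mean_methylation(self, allele: str) -> float:
        """Pooled mean over called CpGs of the allele's clones (nan if none)."""
        counts = self.counts(allele)
        meth, unmeth = counts[:, 0].sum(), counts[:, 1].sum()
        if meth + unmeth == 0:
            return float("nan")
        return meth / (meth + unmeth)

    def pooled_mean(self) -> float:
        meth = unmeth = 0
        for a in ALLELES:
            counts = self.counts(a)
            meth += counts[:, 0].sum()
            unmeth += counts[:, 1].sum()
        if meth + unmeth == 0:
            return float("nan")
        return meth / (meth + unmeth)


@dataclass(frozen=True)
class DmrCall:
    """Outcome of DMR classification for one sample × amplicon."""

    status: str  # differential | hypermethylated | hypomethylated | intermediate | insufficient_data
    phased: bool
    allele_means: dict = field(default_factory=dict)
    note: str = ""


def classify_dmr(
    profile: AllelicMethylationProfile,
    hi: float = 0.75,
    lo: float = 0.25,
    min_clones: int = 3,
) -> DmrCall:
    """Classify DMR status from per-allele methylation means.

    Differential when one allele's mean is >= ``hi`` and the other's <= ``lo``;
    hypermethylated/hypomethylated when both sit on the same side; otherwise
    intermediate.  With no usable SNP an unphased fallback inspects the
    per-clone mean-methylation histogram: a bimodal pattern with >= 25% of
    clones above ``hi`` and >= 25% below ``lo`` is called differential
    (unphased), else the pooled mean decides.  Fewer clones than required
    yields ``insufficient_data`` rather than a silent call.
    """
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("thresholds must satisfy 0 <= lo < hi <= 1")

    def finish(status: str, phased: bool, means: dict, note: str = "") -> DmrCall:
        profile.dmr_status = status
        return DmrCall(status, phased, means, note)

    if profile.has_usable_snp:
        n_a, n_b = profile.clone_count("A"), profile.clone_count("B")
        if min(n_a, n_b) < min_clones:
            return finish(
                "insufficient_data",
                True,
                {},
                f"need >= {min_clones} clones per allele, have A={n_a}, B={n_b}",
            )
        mean_a = profile.mean_methylation("A")
        mean_b = profile.mean_methylation("B")
        means = {"A": mean_a, "B": mean_b}
        if (mean_a >= hi and mean_b <= lo) or (mean_b >= hi and mean_a <= lo):
            return finish("differential", True, means)
        if mean_a >= hi and mean_b >= hi:
            return finish("hypermethylated", True, means)
        if mean_a <= lo and mean_b <= lo:
            return finish("hypomethylated", True, means)
        return finish("intermediate", True, means)

    clones = [c for c in profile.all_clones if not math.isnan(c.mean_methylation)]
    if len(clones) < 2 * min_clones:
        return finish(
            "insufficient_data",
            False,
            {},
            f"unphased fallback needs >= {2 * min_clones} clones, have {len(clones)}",
        )
    per_clone = np.array([c.mean_methylation for c in clones])
    frac_hi = float(np.mean(per_clone >= hi))
    frac_lo = float(np.mean(per_clone <= lo))
    pooled = profile.pooled_mean()
    means = {"pooled": pooled}
    if frac_hi >= 0.25 and frac_lo >= 0.25:
        return finish(
            "differential", False, means,
            f"bimodal clone histogram: {frac_hi:.0%} >= {hi}, {frac_lo:.0%} <= {lo}",
        )
    if pooled >= hi:
        return finish("hypermethylated", False, means)
    if pooled <= lo:
        return finish("hypomethylated", False, means)
    return finish("intermediate", False, means)
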