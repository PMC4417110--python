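"""Bisulfite clone processing: reference conversion, alignment, methylation calls, QC.

Cloned bisulfite-PCR products are capillary-sequenced one molecule at a time;
each clone therefore reports the methylation pattern of a single chromosome
(an epiallele).  Processing a clone set means (i) aligning every read to the
*in silico* bisulfite-converted amplicon reference, treating each CpG cytosine
as a two-way ambiguous position since its read base depends on methylation,
(ii) calling methylated/unmethylated/missing per CpG, (iii) scoring bisulfite
conversion efficiency from non-CpG cytosines (assumed unmethylated, so any
retained C is a conversion failure), and (iv) collapsing byte-identical reads,
which are taken to be PCR duplicates of the same molecule rather than
independent chromosomes.

Coordinates are 0-based half-open internally; human-readable reports are
1-based inclusive.
"""

from __future__ import annotations

import functools
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import reverse_complement

StrandMode = Literal["top", "bottom"]

#: per-CpG call symbols used throughout (also in TSV meth strings)
METHYLATED = "1"
UNMETHYLATED = "0"
MISSING = "."

_DNA = set("ACGT")

#: ambiguity codes used in the converted reference (IUPAC)
AMBIG_TOP = "Y"  # C or T — a CpG cytosine on the top strand
AMBIG_BOTTOM = "R"  # G or A — a CpG guanine read from the bottom strand

_ALPHABET = "ACGTYR"


class UnmappableReadError(ValueError):
    """Raised when a read's best alignment falls below the identity floor."""

    def __init__(self, message: str, score: float | None = None, identity: float | None = None):
        super().__init__(message)
        self.score = score
        self.identity = identity


@dataclass(frozen=True)
class Snp:
    """A known single-nucleotide polymorphism inside the amplicon.

    ``usable_for_bisulfite`` is False exactly when the allele pair collapses
    under bisulfite conversion: C/T on the top strand (unmethylated C reads as
    T) or G/A on the bottom strand.
    """

    offset: int
    ref_allele: str
    alt_allele: str
    usable_for_bisulfite: bool

    @staticmethod
    def make(offset: int, ref_allele: str, alt_allele: str, strand_mode: StrandMode = "top") -> "Snp":
        return Snp(offset, ref_allele, alt_allele,
                   usable_for_bisulfite=not snp_pair_collapses(ref_allele, alt_allele, strand_mode))


def snp_pair_collapses(a: str, b: str, strand_mode: StrandMode) -> bool:
    """True when the allele pair is indistinguishable after conversion."""
    pair = {a.upper(), b.upper()}
    return pair == {"C", "T"} if strand_mode == "top" else pair == {"G", "A"}


def expected_read_base(allele_base: str, strand_mode: StrandMode) -> str:
    """Base a SNP allele is expected to show in a fully converted read.

    Non-CpG cytosines convert (C->T on top; G->A as read on the bottom
    strand), so a C allele at a non-CpG SNP is observed as T.
    """
    b = allele_base.upper()
    if strand_mode == "top" and b == "C":
        return "T"
    if strand_mode == "bottom" and b == "G":
        return "A"
    return b


@dataclass(frozen=True)
class Amplicon:
    """A bisulfite-PCR amplicon reference with annotated CpGs and SNPs.

    ``cpg_positions`` are offsets of the C of each CpG dinucleotide.  This is
    the coordinate frame for every downstream call.
    """

    amplicon_id: str
    sequence: str
    cpg_positions: tuple[int, ...]
    snps: tuple[Snp, ...] = ()
    strand_mode: StrandMode = "top"

    def __post_init__(self):
        seq = self.sequence
        if not set(seq) <= _DNA:
            bad = sorted(set(seq) - _DNA)
            raise ValueError(f"amplicon sequence contains non-ACGT characters: {bad}")
        object.__setattr__(self, "cpg_positions", tuple(sorted(self.cpg_positions)))
        for p in self.cpg_positions:
            if seq[p : p + 2] != "CG":
                raise ValueError(f"cpg_position {p} is not a CpG dinucleotide (found {seq[p:p+2]!r})")
        cpg_footprint = {q for p in self.cpg_positions for q in (p, p + 1)}
        offsets = [s.offset for s in self.snps]
        if len(set(offsets)) != len(offsets):
            raise ValueError("duplicate SNP offsets")
        object.__setattr__(self, "snps", tuple(sorted(self.snps, key=lambda s: s.offset)))
        for s in self.snps:
            if not (0 <= s.offset < len(seq)):
                raise ValueError(f"SNP offset {s.offset} outside sequence")
            if s.offset in cpg_footprint:
                raise ValueError(f"SNP offset {s.offset} coincides with a CpG dinucleotide")
            expect = not snp_pair_collapses(s.ref_allele, s.alt_allele, self.strand_mode)
            if s.usable_for_bisulfite != expect:
                raise ValueError(
                    f"SNP at {s.offset}: usable_for_bisulfite must be {expect} for "
                    f"{s.ref_allele}/{s.alt_allele} in {self.strand_mode} mode"
                )

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    def usable_snps(self) -> tuple[Snp, ...]:
        return tuple(s for s in self.snps if s.usable_for_bisulfite)

    def non_cpg_c_positions(self) -> tuple[int, ...]:
        """Offsets informative for conversion QC (non-CpG C; bottom: non-CpG G)."""
        base = "C" if self.strand_mode == "top" else "G"
        skip = (
            set(self.cpg_positions)
            if self.strand_mode == "top"
            else {p + 1 for p in self.cpg_positions}
        )
        return tuple(i for i, b in enumerate(self.sequence) if b == base and i not in skip)


def in_silico_convert(sequence: str, strand_mode: StrandMode = "top") -> tuple[str, frozenset[int]]:
    """Bisulfite-convert a reference sequence in silico.

    Top strand: every non-CpG C becomes T; each CpG C becomes ambiguous
    ({C,T}, since its fate depends on methylation).  Bottom strand is the
    mirror read in top-strand coordinates: non-CpG G becomes A, CpG G becomes
    {G,A}.  Returns the converted string (ambiguous offsets left as the
    original base) and the set of ambiguous offsets.
    """
    bad = [i for i, b in enumerate(sequence) if b not in _DNA]
    if bad:
        raise ValueError(f"non-ACGT character at offset {bad[0]}")
    out = list(sequence)
    ambiguous = set()
    if strand_mode == "top":
        for i, b in enumerate(sequence):
            if b != "C":
                continue
            if sequence[i + 1 : i + 2] == "G":
                ambiguous.add(i)
            else:
                out[i] = "T"
    else:
        for i, b in enumerate(sequence):
            if b != "G":
                continue
            if i > 0 and sequence[i - 1] == "C":
                ambiguous.add(i)
            else:
                out[i] = "A"
    return "".join(out), frozenset(ambiguous)


def ambiguous_reference(amplicon: Amplicon) -> str:
    """Converted reference with IUPAC ambiguity codes at CpG positions."""
    converted, ambiguous = in_silico_convert(amplicon.sequence, amplicon.strand_mode)
    code = AMBIG_TOP if amplicon.strand_mode == "top" else AMBIG_BOTTOM
    out = list(converted)
    for i in ambiguous:
        out[i] = code
    return "".join(out)


@dataclass(frozen=True)
class AlignParams:
    """Scoring for read-vs-converted-reference alignment.

    Global alignment with free end gaps; an internal gap of length L costs
    ``gap_open + (L - 1) * gap_extend``.  At ambiguous reference positions
    both bases of the pair score as a match.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    min_read_length: int = 30
    identity_floor: float = 0.80


@functools.lru_cache(maxsize=8)
def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    n = len(_ALPHABET)
    m = np.full((n, n), params.mismatch)
    np.fill_diagonal(m, params.match)
    idx = {c: i for i, c in enumerate(_ALPHABET)}
    for a, b in (("Y", "C"), ("Y", "T"), ("R", "G"), ("R", "A")):
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = params.match
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.Array(_ALPHABET, dims=2, data=m)
    aligner.mode = "global"
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _matches(ref_char: str, read_char: str) -> bool:
    if ref_char == AMBIG_TOP:
        return read_char in "CT"
    if ref_char == AMBIG_BOTTOM:
        return read_char in "GA"
    return ref_char == read_char


@dataclass(frozen=True)
class AlignmentResult:
    """A read placed on the amplicon coordinate frame.

    ``read_bases[i]`` is the read base aligned to reference offset ``i``,
    ``'-'`` for an internal deletion, or ``''`` where the read does not cover
    the reference (free end gaps).
    """

    score: float
    orientation: Literal["forward", "reverse"]
    identity: float
    read_bases: tuple[str, ...]

    def covered(self, offset: int) -> bool:
        return self.read_bases[offset] not in ("", "-")


def alignment_score(read: str, amplicon: Amplicon, params: AlignParams = AlignParams()) -> float:
    """Score of the best forward-orientation alignment (no traceback)."""
    return _aligner(params).score(ambiguous_reference(amplicon), read)


def score_read(converted_ref: str, read: str, params: AlignParams = AlignParams()) -> float:
    """Score a read against a converted reference string (may contain Y/R)."""
    return _aligner(params).score(converted_ref, read)


def align_clone(
    read: str,
    amplicon: Amplicon,
    params: AlignParams = AlignParams(),
    check_identity: bool = True,
) -> AlignmentResult:
    """Align a clone read to the converted reference, trying both orientations.

    Raises :class:`UnmappableReadError` when the best alignment's identity over
    aligned columns falls below ``params.identity_floor``.
    """
    read = read.upper()
    if not set(read) <= _DNA:
        bad = sorted(set(read) - _DNA)
        raise ValueError(f"read contains non-ACGT characters: {bad}")
    if len(read) < params.min_read_length:
        raise ValueError(f"read shorter than {params.min_read_length} bp")
    ref = ambiguous_reference(amplicon)
    aligner = _aligner(params)
    rc = reverse_complement(read)
    score_fwd = aligner.score(ref, read)
    score_rev = aligner.score(ref, rc)
    if score_rev > score_fwd:
        orientation, oriented, best = "reverse", rc, score_rev
    else:
        orientation, oriented, best = "forward", read, score_fwd
    aln = aligner.align(ref, oriented)[0]
    tblocks, qblocks = aln.aligned
    read_bases = [""] * len(ref)
    for (ts, te), (qs, _qe) in zip(tblocks, qblocks):
        for k in range(te - ts):
            read_bases[ts + k] = oriented[qs + k]
    if len(tblocks):
        lo, hi = int(tblocks[0][0]), int(tblocks[-1][1])
        for i in range(lo, hi):
            if read_bases[i] == "":
                read_bases[i] = "-"
    covered = [i for i in range(len(ref)) if read_bases[i] not in ("", "-")]
    n_match = sum(_matches(ref[i], read_bases[i]) for i in covered)
    identity = n_match / len(covered) if covered else 0.0
    result = AlignmentResult(best, orientation, identity, tuple(read_bases))
    if check_identity and identity < params.identity_floor:
        raise UnmappableReadError(
            f"best alignment identity {identity:.2f} below floor {params.identity_floor:.2f}",
            score=best,
            identity=identity,
        )
    return result


def call_methylation(alignment: AlignmentResult, amplicon: Amplicon) -> str:
    """Per-CpG methylation string: '1' methylated, '0' unmethylated, '.' missing.

    Top strand: C at the CpG cytosine means the methyl group blocked
    conversion; T means it converted (unmethylated).  Bottom strand reads the
    CpG guanine: G methylated, A unmethylated.  Gaps and unexpected bases are
    missing.
    """
    calls = []
    if amplicon.strand_mode == "top":
        offsets, meth_base, unmeth_base = amplicon.cpg_positions, "C", "T"
    else:
        offsets = tuple(p + 1 for p in amplicon.cpg_positions)
        meth_base, unmeth_base = "G", "A"
    for o in offsets:
        b = alignment.read_bases[o]
        if b == meth_base:
            calls.append(METHYLATED)
        elif b == unmeth_base:
            calls.append(UNMETHYLATED)
        else:
            calls.append(MISSING)
    return "".join(calls)


def conversion_efficiency(alignment: AlignmentResult, amplicon: Amplicon) -> float | None:
    """Fraction of covered non-CpG cytosines that converted.

    Computed as ``1 - unconverted / total`` over non-CpG reference cytosines
    covered by the read (gapped and uncovered positions excluded from both
    counts).  Returns None when no informative position is covered: the
    statistic is then undefined, not zero.
    """
    retained_base = "C" if amplicon.strand_mode == "top" else "G"
    total = 0
    unconverted = 0
    for o in amplicon.non_cpg_c_positions():
        if not alignment.covered(o):
            continue
        total += 1
        if alignment.read_bases[o] == retained_base:
            unconverted += 1
    if total == 0:
        return None
    return 1.0 - unconverted / total


@dataclass
class BisulfiteClone:
    """One cloned bisulfite read with its calls and QC statistics."""

    clone_id: str
    sample_id: str
    raw_sequence: str
    alignment: AlignmentResult | None = None
    cpg_calls: str = ""
    conversion_efficiency: float | None = None
    multiplicity: int = 1
    allele: str = "unassigned"

    @property
    def n_called(self) -> int:
        return sum(c != MISSING for c in self.cpg_calls)

    @property
    def mean_methylation(self) -> float:
        """Fraction of called CpGs methylated (nan when nothing called)."""
        n = self.n_called
        if n == 0:
            return float("nan")
        return self.cpg_calls.count(METHYLATED) / n


def build_clone(
    clone_id: str,
    sample_id: str,
    read: str,
    amplicon: Amplicon,
    params: AlignParams = AlignParams(),
) -> BisulfiteClone:
    """Align one read and attach methylation calls and conversion QC."""
    aln = align_clone(read, amplicon, params)
    return BisulfiteClone(
        clone_id=clone_id,
        sample_id=sample_id,
        raw_sequence=read.upper(),
        alignment=aln,
        cpg_calls=call_methylation(aln, amplicon),
        conversion_efficiency=conversion_efficiency(aln, amplicon),
    )


def build_clones(
    reads: Sequence[tuple[str, str]],
    sample_id: str,
    amplicon: Amplicon,
    params: AlignParams = AlignParams(),
) -> tuple[list[BisulfiteClone], list[tuple[str, str]]]:
    """Process (clone_id, sequence) pairs; returns (clones, rejected).

    Rejected entries are (clone_id, reason) with reasons ``unmappable`` and
    ``too_short``.
    """
    clones: list[BisulfiteClone] = []
    rejected: list[tuple[str, str]] = []
    for clone_id, read in reads:
        try:
            clones.append(build_clone(clone_id, sample_id, read, amplicon, params))
        except UnmappableReadError:
            rejected.append((clone_id, "unmappable"))
        except ValueError as exc:
            if "shorter" in str(exc):
                rejected.append((clone_id, "too_short"))
            else:
                raise
    return clones, rejected


def filter_clones(
    clones: Iterable[BisulfiteClone],
    min_efficiency: float | None = 0.95,
    min_called_cpgs: int | None = None,
    n_cpg: int | None = None,
) -> tuple[list[BisulfiteClone], list[tuple[BisulfiteClone, str]]]:
    """QC filter: conversion efficiency and number of called CpGs.

    ``min_called_cpgs`` defaults to half the amplicon's CpG count (pass
    ``n_cpg``).  Pass ``min_efficiency=None`` to opt out of the conversion
    filter.  Clones whose efficiency is undefined (no informative position
    covered) are not filtered on efficiency.  Rejections carry reasons
    ``low_conversion`` or ``few_cpg_calls``.
    """
    clones = list(clones)
    if min_called_cpgs is None:
        if n_cpg is None:
            n_cpg = max((len(c.cpg_calls) for c in clones), default=0)
        min_called_cpgs = (n_cpg + 1) // 2
    kept, rejected = [], []
    for c in clones:
        if (
            min_efficiency is not None
            and c.conversion_efficiency is not None
            and c.conversion_efficiency < min_efficiency
        ):
            rejected.append((c, "low_conversion"))
        elif c.n_called < min_called_cpgs:
            rejected.append((c, "few_cpg_calls"))
        else:
            kept.append(c)
    return kept, rejected


def deduplicate(clones: Iterable[BisulfiteClone]) -> list[BisulfiteClone]:
    """Collapse byte-identical reads into one representative per group.

    Identical sequences among separately picked clones are taken to be
    nonindependent PCR amplificates of the same molecule; one representative
    (lexicographically smallest clone_id) is kept and its ``multiplicity`` is
    the group's total multiplicity.  Idempotent; total multiplicity is
    conserved.  Output sorted by clone_id.
    """
    groups: dict[str, list[BisulfiteClone]] = defaultdict(list)
    for c in clones:
        groups[c.raw_sequence].append(c)
    out = []
    for members in groups.values():
        rep = min(members, key=lambda c: c.clone_id)
        out.append(replace(rep, multiplicity=sum(m.multiplicity for m in members)))
    return sorted(out, key=lambda c: c.clone_id)
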