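"""Three-tier allelic-expression calling from cDNA SNP assays.

A transcribed SNP heterozygous in genomic DNA makes an individual informative:
the minor-allele fraction of its cDNA signal (pyrosequencing in
allele-quantification mode, or relative capillary peak heights) measures how
biased expression is.  Calls fall into three tiers — complete monoallelic,
preferential monoallelic, biallelic — and per-gene, per-tissue summaries give
the percentage of informative samples in each tier.  Individuals homozygous
at the assay SNP are uninformative and excluded from percentages.

Tissue codes: (C) cerebellum, (T) testes, (P) pancreas, (K) kidney,
(L) liver, (M) muscle, (UC) umbilical cord, (PL) placenta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

TISSUE_CODES = ("C", "T", "P", "K", "L", "M", "UC", "PL")

CATEGORIES = ("complete_monoallelic", "preferential_monoallelic", "biallelic", "uninformative")
MONOALLELIC = {"complete_monoallelic", "preferential_monoallelic"}

#: default tier thresholds on the minor allele fraction (<= semantics).
#: Not taken from any measured calibration: chosen so that typical AQ noise
#: (~5 percentage points) cannot promote a truly silent allele past the
#: complete-monoallelic tier.
T_COMPLETE = 0.10
T_BIALLELIC = 0.35


class NoSignalError(ValueError):
    """Both peaks are zero — no allelic signal to quantify."""


def peak_allele_fraction(peak_height_ref: float, peak_height_alt: float) -> float:
    """Minor allele fraction from two capillary peak heights."""
    if peak_height_ref < 0 or peak_height_alt < 0:
        raise ValueError("peak heights must be nonnegative")
    total = peak_height_ref + peak_height_alt
    if total == 0:
        raise NoSignalError("no_signal: both peak heights are zero")
    return min(peak_height_ref, peak_height_alt) / total


def fold_minor(fraction: float) -> float:
    """Fold an allele fraction onto the minor-allele scale [0, 0.5]."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"allele fraction {fraction} outside [0, 1]")
    return min(fraction, 1.0 - fraction)


def classify_expression(
    minor_fraction: float,
    t_complete: float = T_COMPLETE,
    t_biallelic: float = T_BIALLELIC,
) -> str:
    """Three-tier call from the minor allele fraction (folded if needed).

    <= ``t_complete``: complete monoallelic; <= ``t_biallelic``: preferential
    monoallelic; above: biallelic.  Monotone in the minor fraction.
    """
    if not (0.0 <= t_complete < t_biallelic <= 0.5):
        raise ValueError("need 0 <= t_complete < t_biallelic <= 0.5")
    f = fold_minor(minor_fraction)
    if f <= t_complete:
        return "complete_monoallelic"
    if f <= t_biallelic:
        return "preferential_monoallelic"
    return "biallelic"


@dataclass(frozen=True)
class ExpressionCall:
    """One gene × tissue × individual allelic-expression measurement."""

    gene: str
    tissue: str
    individual: str
    snp_id: str
    allele_fraction: float  # minor fraction, <= 0.5 (nan when uninformative)
    method: Literal["pyro_AQ", "capillary_peaks"]
    informative: bool
    category: str

    def __post_init__(self):
        if self.informative != (self.category != "uninformative"):
            raise ValueError("category must be uninformative iff not informative")


def make_call(
    gene: str,
    tissue: str,
    individual: str,
    snp_id: str,
    method: Literal["pyro_AQ", "capillary_peaks"],
    informative: bool,
    allele_fraction: float | None = None,
    peak_ref: float | None = None,
    peak_alt: float | None = None,
    t_complete: float = T_COMPLETE,
    t_biallelic: float = T_BIALLELIC,
) -> ExpressionCall:
    """Build a call from either an AQ fraction or two peak heights.

    ``informative`` reflects the genomic-DNA genotype at the assay SNP;
    uninformative individuals get no fraction and no tier.
    """
    if not informative:
        return ExpressionCall(
            gene, tissue, individual, snp_id, float("nan"), method, False, "uninformative"
        )
    if method == "capillary_peaks":
        if peak_ref is None or peak_alt is None:
            raise ValueError("capillary_peaks requires peak_ref and peak_alt")
        f = peak_allele_fraction(peak_ref, peak_alt)
    else:
        if allele_fraction is None:
            raise ValueError("pyro_AQ requires allele_fraction")
        f = fold_minor(allele_fraction)
    return ExpressionCall(
        gene, tissue, individual, snp_id, f, method,
        True, classify_expression(f, t_complete, t_biallelic),
    )


def summarize_gene(calls: Iterable[ExpressionCall]) -> pd.DataFrame:
    """Per-tissue summary of one gene's calls (bar-chart style).

    Columns: tissue, n (informative), n_uninformative, pct_biallelic,
    pct_monoallelic (split into pct_complete + pct_preferential), and a
    ``polymorphic`` flag set when a tissue contains both biallelic and
    monoallelic informative individuals — imprinting present in some
    individuals and absent in others.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no calls supplied")
    genes = {c.gene for c in calls}
    if len(genes) != 1:
        raise ValueError(f"summarize_gene expects one gene, got {sorted(genes)}")
    rows = []
    tissues = sorted({c.tissue for c in calls})
    # keep the canonical panel order where applicable
    tissues.sort(key=lambda t: TISSUE_CODES.index(t) if t in TISSUE_CODES else len(TISSUE_CODES))
    for tissue in tissues:
        sub = [c for c in calls if c.tissue == tissue]
        informative = [c for c in sub if c.informative]
        n = len(informative)
        n_unk = len(sub) - n
        if n == 0:
            rows.append(
                dict(tissue=tissue, n=0, n_uninformative=n_unk, pct_biallelic=float("nan"),
                     pct_monoallelic=float("nan"), pct_complete=float("nan"),
                     pct_preferential=float("nan"), polymorphic=False)
            )
            continue
        n_bi = sum(c.category == "biallelic" for c in informative)
        n_comp = sum(c.category == "complete_monoallelic" for c in informative)
        n_pref = sum(c.category == "preferential_monoallelic" for c in informative)
        rows.append(
            dict(
                tissue=tissue,
                n=n,
                n_uninformative=n_unk,
                pct_biallelic=100.0 * n_bi / n,
                pct_monoallelic=100.0 * (n_comp + n_pref) / n,
                pct_complete=100.0 * n_comp / n,
                pct_preferential=100.0 * n_pref / n,
                polymorphic=n_bi > 0 and (n_comp + n_pref) > 0,
            )
        )
    return pd.DataFrame(rows)
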