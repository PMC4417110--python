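"""Germline imprint-timing classification and acquisition trajectories.

A somatic DMR can acquire its differential methylation in either germline or
only after fertilization.  Comparing sperm and oocyte clone profiles with the
somatic DMR status separates three groups: paternal germline imprints (sperm
methylated, oocyte not), maternal germline imprints (oocyte methylated, sperm
not), and delayed maternal imprints (both gametes unmethylated yet the
somatic region differential — methylation must arise post-fertilization on
the maternal allele, assuming the somatic differential is maternal as at the
orthologous rodent loci).

Gamete clone sets are pooled (no allele split needed: all molecules of one
germline share the imprint state) and summarized by their mean CpG
methylation, plus a clone-level breakdown so that a few partially methylated
clones in an otherwise unmethylated sample — rare somatic-cell contamination
or germline epimutation — stay visible instead of vanishing into the mean.

Stage-wise trajectories normalize absolute methylation per developmental
stage to its level at a reference stage (typically ICM/blastocyst, where
acquisition is complete).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bisulfite import BisulfiteClone

GAMETE_STATES = ("methylated", "unmethylated", "intermediate", "missing")
ORIGINS = (
    "paternal_germline",
    "maternal_germline",
    "post_fertilization_maternal",
    "not_imprint_like",
    "indeterminate",
)

#: clone-level bands: a clone is "partial" when its fraction of methylated
#: called CpGs lies strictly between these bounds; a single sporadic CpG on a
#: typical amplicon does not flip a clone out of the full/empty bands.
PARTIAL_LO = 0.10
PARTIAL_HI = 0.90


@dataclass(frozen=True)
class GameteCall:
    """Pooled methylation state of one gamete clone set."""

    state: str
    mean_methylation: float
    n_clones: int
    frac_fully_methylated: float
    frac_partial: float
    frac_unmethylated: float
    contamination_note: str = ""


def gamete_state(
    clones: Sequence[BisulfiteClone],
    hi: float = 0.8,
    lo: float = 0.2,
    min_clones: int = 5,
    partial_lo: float = PARTIAL_LO,
    partial_hi: float = PARTIAL_HI,
) -> GameteCall:
    """Call a gamete sample methylated / unmethylated / intermediate.

    Uses the pooled mean over called CpGs of unique clones; fewer than
    ``min_clones`` clones yields state ``missing``.  Clones are additionally
    binned as fully methylated (>= ``partial_hi``), partial, or unmethylated
    (<= ``partial_lo``); discordant clones in an otherwise clean sample raise
    a contamination note.
    """
    usable = [c for c in clones if not math.isnan(c.mean_methylation)]
    n = len(usable)
    if n < min_clones:
        return GameteCall("missing", float("nan"), n, float("nan"), float("nan"), float("nan"),
                          f"only {n} usable clones (< {min_clones})")
    meth = sum(c.cpg_calls.count("1") for c in usable)
    unmeth = sum(c.cpg_calls.count("0") for c in usable)
    mean = meth / (meth + unmeth)
    per_clone = np.array([c.mean_methylation for c in usable])
    frac_full = float(np.mean(per_clone >= partial_hi))
    frac_partial = float(np.mean((per_clone > partial_lo) & (per_clone < partial_hi)))
    frac_unmeth = float(np.mean(per_clone <= partial_lo))
    if mean >= hi:
        state = "methylated"
        discordant = int(round((frac_partial + frac_unmeth) * n))
    elif mean <= lo:
        state = "unmethylated"
        discordant = int(round((frac_partial + frac_full) * n))
    else:
        state = "intermediate"
        discordant = 0
    note = ""
    if discordant:
        note = (
            f"{discordant}/{n} clones discordant with the {state} call — "
            "possible somatic-cell contamination or epimutation"
        )
    return GameteCall(state, mean, n, frac_full, frac_partial, frac_unmeth, note)


@dataclass(frozen=True)
class ImprintOriginCall:
    """Combined gamete + somatic evidence for one locus."""

    locus: str
    sperm_state: str
    oocyte_state: str
    somatic_status: str
    origin: str
    reason: str = ""
    contamination_note: str = ""


def classify_germline_origin(
    sperm_state: str,
    oocyte_state: str,
    somatic_status: str,
    locus: str = "",
    contamination_note: str = "",
) -> ImprintOriginCall:
    """Decision table over gamete states and somatic DMR status.

    sperm methylated + oocyte unmethylated + somatic differential
    -> paternal_germline; the mirror -> maternal_germline; both gametes
    unmethylated with a somatic differential -> post_fertilization_maternal
    (delayed acquisition); somatic not differential -> not_imprint_like.
    Intermediate or missing inputs give ``indeterminate`` naming the field —
    a value, never an exception, so the table is total over its inputs.
    """

    def call(origin: str, reason: str = "") -> ImprintOriginCall:
        return ImprintOriginCall(
            locus, sperm_state, oocyte_state, somatic_status, origin, reason, contamination_note
        )

    for name, state in (("sperm_state", sperm_state), ("oocyte_state", oocyte_state)):
        if state not in ("methylated", "unmethylated"):
            return call("indeterminate", f"{name} is {state}")
    if somatic_status == "insufficient_data":
        return call("indeterminate", "somatic_status is insufficient_data")
    if somatic_status != "differential":
        return call("not_imprint_like", f"somatic_status is {somatic_status}")
    if sperm_state == "methylated" and oocyte_state == "unmethylated":
        return call("paternal_germline")
    if sperm_state == "unmethylated" and oocyte_state == "methylated":
        return call("maternal_germline")
    if sperm_state == "unmethylated" and oocyte_state == "unmethylated":
        return call("post_fertilization_maternal")
    return call("indeterminate", "both gametes methylated with a somatic differential")


@dataclass(frozen=True)
class StageTrajectory:
    """Absolute and reference-normalized methylation across developmental stages."""

    locus: str
    stages: tuple[str, ...]
    absolute: tuple[float, ...]
    relative: tuple[float, ...]  # percent of reference-stage level; nan if undefined
    reference_stage: str
    relative_defined: bool
    monotone_acquisition: bool


def acquisition_trajectory(
    stage_table: Mapping[str, float] | pd.DataFrame,
    reference_stage: str,
    locus: str = "",
    stage_order: Sequence[str] | None = None,
    tolerance: float = 0.05,
) -> StageTrajectory:
    """Normalize a per-stage methylation series to a reference stage.

    ``relative[s] = 100 * absolute[s] / absolute[reference]``; when the
    reference level is zero the relative series is undefined (all-nan,
    flagged).  The monotone-acquisition flag is True when absolute
    methylation is non-decreasing from the first stage through the reference
    stage, allowing dips up to ``tolerance`` — the shape of gradual
    post-fertilization acquisition completed by the reference stage.
    """
    if isinstance(stage_table, pd.DataFrame):
        if not {"stage", "absolute_methylation"} <= set(stage_table.columns):
            raise ValueError("stage table needs 'stage' and 'absolute_methylation' columns")
        series = dict(zip(stage_table["stage"], stage_table["absolute_methylation"]))
    else:
        series = dict(stage_table)
    if len(series) < 2:
        raise ValueError("need at least two stages")
    if reference_stage not in series:
        raise ValueError(f"reference stage {reference_stage!r} not in table")
    stages = tuple(stage_order) if stage_order is not None else tuple(series)
    if set(stages) != set(series):
        raise ValueError("stage_order must list exactly the table's stages")
    absolute = tuple(float(series[s]) for s in stages)
    for s, v in zip(stages, absolute):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"absolute methylation at {s!r} outside [0, 1]: {v}")
    ref = series[reference_stage]
    if ref > 0:
        relative = tuple(100.0 * v / ref for v in absolute)
        defined = True
    else:
        relative = tuple(float("nan") for _ in absolute)
        defined = False
    ref_idx = stages.index(reference_stage)
    pre = absolute[: ref_idx + 1]
    monotone = all(b >= a - tolerance for a, b in zip(pre, pre[1:]))
    return StageTrajectory(locus, stages, absolute, relative, reference_stage, defined, monotone)
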