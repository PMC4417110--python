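"""Lollipop diagrams: one row per unique clone, one circle per CpG.

Filled circle = methylated, open circle = unmethylated, dash = no call.
Collapsed PCR duplicates show their multiplicity beside the row.  Row order
is deterministic: allele group (A, B, unassigned), then descending methylated
count, then clone_id.
"""

from __future__ import annotations

from typing import Literal

from .alleles import ALLELES, AllelicMethylationProfile
from .bisulfite import METHYLATED, MISSING, UNMETHYLATED, BisulfiteClone

GLYPHS = {METHYLATED: "●", UNMETHYLATED: "○", MISSING: "-"}


def _ordered(profile: AllelicMethylationProfile) -> list[tuple[str, list[BisulfiteClone]]]:
    groups = []
    for allele in ALLELES:
        clones = sorted(
            profile.clones_by_allele[allele],
            key=lambda c: (-c.cpg_calls.count(METHYLATED), c.clone_id),
        )
        if clones:
            groups.append((allele, clones))
    return groups


def clone_row(clone: BisulfiteClone) -> str:
    row = "".join(GLYPHS[c] for c in clone.cpg_calls)
    if clone.multiplicity > 1:
        row += f" ×{clone.multiplicity}"
    return row


def render_lollipop(
    profile: AllelicMethylationProfile, format: Literal["text", "svg"] = "text"
) -> str:
    if format == "text":
        return _render_text(profile)
    if format == "svg":
        return _render_svg(profile)
    raise ValueError(f"unknown format {format!r}")


def _render_text(profile: AllelicMethylationProfile) -> str:
    lines = [f"# {profile.sample_id} / {profile.amplicon_id}"]
    for allele, clones in _ordered(profile):
        lines.append(f"allele {allele} (n={len(clones)}):")
        for c in clones:
            lines.append(f"  {clone_row(c)}  {c.clone_id}")
    if profile.dmr_status:
        lines.append(f"status: {profile.dmr_status}")
    return "\n".join(lines) + "\n"


def _render_svg(profile: AllelicMethylationProfile) -> str:
    cell, r, left, top = 16, 5, 120, 30
    y = top
    elements: list[str] = [
        f'<text x="4" y="16" font-family="monospace" font-size="12">'
        f"{profile.sample_id} / {profile.amplicon_id}</text>"
    ]
    for allele, clones in _ordered(profile):
        y += cell
        elements.append(
            f'<text x="4" y="{y}" font-family="monospace" font-size="11">'
            f"allele {allele} (n={len(clones)})</text>"
        )
        for c in clones:
            y += cell
            cy = y - r
            for i, call in enumerate(c.cpg_calls):
                cx = left + i * cell
                if call == METHYLATED:
                    elements.append(f'<circle cx="{cx}" cy="{cy}" r="{r}" fill="black"/>')
                elif call == UNMETHYLATED:
                    elements.append(
                        f'<circle cx="{cx}" cy="{cy}" r="{r}" fill="white" stroke="black"/>'
                    )
                else:
                    elements.append(
                        f'<line x1="{cx - r}" y1="{cy}" x2="{cx + r}" y2="{cy}" stroke="black"/>'
                    )
            if c.multiplicity > 1:
                elements.append(
                    f'<text x="{left + len(c.cpg_calls) * cell + 4}" y="{y - 1}" '
                    f'font-family="monospace" font-size="11">×{c.multiplicity}</text>'
                )
    width = left + profile.n_cpg * cell + 60
    height = y + cell
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">\n'
        + "\n".join(elements)
        + "\n</svg>\n"
    )
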