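"""File formats: FASTA clones, amplicon JSON sidecars, TSV tables.

Clone FASTA headers follow ``sample|clone{i}``; the part before the first
``|`` is the sample id and the full header is the clone id.  All TSV outputs
start with a ``# config: <hash>`` comment line; read them back with
``comment='#'``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bisulfite import Amplicon, BisulfiteClone, Snp


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_clone_fasta(path: str | Path) -> tuple[str, list[tuple[str, str]]]:
    """Read clones; returns (sample_id, [(clone_id, sequence), ...])."""
    records = read_fasta(path)
    if not records:
        raise ValueError(f"no records in {path}")
    samples = {name.split("|")[0] for name, _ in records}
    if len(samples) != 1:
        raise ValueError(f"clone FASTA mixes samples: {sorted(samples)}")
    return samples.pop(), records


def write_amplicon(amplicon: Amplicon, fasta_path: str | Path) -> Path:
    """Write amplicon FASTA plus its JSON sidecar; returns the sidecar path."""
    fasta_path = Path(fasta_path)
    write_fasta([(amplicon.amplicon_id, amplicon.sequence)], fasta_path)
    sidecar = fasta_path.with_suffix(".json")
    payload = {
        "amplicon_id": amplicon.amplicon_id,
        "strand_mode": amplicon.strand_mode,
        "cpg_positions": list(amplicon.cpg_positions),
        "snps": [
            {"offset": s.offset, "ref_allele": s.ref_allele, "alt_allele": s.alt_allele}
            for s in amplicon.snps
        ],
    }
    sidecar.write_text(json.dumps(payload, indent=2) + "\n")
    return sidecar


def read_amplicon(fasta_path: str | Path, sidecar_path: str | Path | None = None) -> Amplicon:
    """Read an amplicon from FASTA + JSON sidecar (default: same stem, .json)."""
    fasta_path = Path(fasta_path)
    sidecar = Path(sidecar_path) if sidecar_path else fasta_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"amplicon sidecar not found: {sidecar} (expected next to {fasta_path})"
        )
    records = read_fasta(fasta_path)
    if len(records) != 1:
        raise ValueError(f"amplicon FASTA must hold one record, found {len(records)}")
    name, sequence = records[0]
    meta = json.loads(sidecar.read_text())
    strand_mode = meta.get("strand_mode", "top")
    snps = tuple(
        Snp.make(s["offset"], s["ref_allele"], s["alt_allele"], strand_mode)
        for s in meta.get("snps", [])
    )
    return Amplicon(
        amplicon_id=meta.get("amplicon_id", name),
        sequence=sequence,
        cpg_positions=tuple(meta["cpg_positions"]),
        snps=snps,
        strand_mode=strand_mode,
    )


def write_tsv(df: pd.DataFrame, path: str | Path, config_hash: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def clone_table(clones: Sequence[BisulfiteClone]) -> pd.DataFrame:
    """Per-clone report table (1-based human-readable coordinates elsewhere)."""
    rows = []
    for c in clones:
        rows.append(
            dict(
                clone_id=c.clone_id,
                sample_id=c.sample_id,
                orientation=c.alignment.orientation if c.alignment else "",
                score=c.alignment.score if c.alignment else float("nan"),
                efficiency=(
                    c.conversion_efficiency
                    if c.conversion_efficiency is not None
                    else float("nan")
                ),
                n_called=c.n_called,
                meth_string=c.cpg_calls,
                multiplicity=c.multiplicity,
                allele=c.allele,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "clone_id", "sample_id", "orientation", "score", "efficiency",
            "n_called", "meth_string", "multiplicity", "allele",
        ],
    )


def profile_table(profile) -> pd.DataFrame:
    """Long-format per-allele per-CpG counts for an allelic profile."""
    rows = []
    for allele in ("A", "B", "unassigned"):
        counts = profile.counts(allele)
        for i in range(profile.n_cpg):
            rows.append(
                dict(
                    allele=allele,
                    cpg_index=i + 1,  # 1-based in reports
                    meth=int(counts[i, 0]),
                    unmeth=int(counts[i, 1]),
                    missing=int(counts[i, 2]),
                )
            )
    return pd.DataFrame(rows)
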