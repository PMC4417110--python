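"""Independent brute-force oracles used only by the test suite.

The alignment oracle is a plain Gotoh dynamic program written without
reference to the package's aligner: free end gaps (leading/trailing gaps cost
zero), affine internal gaps costing ``gap_open + (L - 1) * gap_extend``, and
ambiguity codes Y (matches C/T) and R (matches G/A) in the reference.
"""

from __future__ import annotations

import numpy as np

_AMBIG = {"Y": "CT", "R": "GA"}


def gotoh_score(
    ref: str,
    read: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal global-with-free-end-gaps affine alignment score."""
    n, m = len(ref), len(read)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in read (reference consumed)
    Y = np.full((n + 1, m + 1), NEG)  # gap in reference (read consumed)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0  # free leading gap in read
    for j in range(1, m + 1):
        Y[0, j] = 0.0  # free leading gap in reference
    for i in range(1, n + 1):
        rc = ref[i - 1]
        for j in range(1, m + 1):
            qc = read[j - 1]
            s = match if (qc == rc or qc in _AMBIG.get(rc, "")) else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    best = NEG
    for j in range(m + 1):  # free trailing gap in reference row
        best = max(best, M[n, j], X[n, j], Y[n, j])
    for i in range(n + 1):  # free trailing gap in read column
        best = max(best, M[i, m], X[i, m], Y[i, m])
    return float(best)


def random_bisulfite_read(rng: np.random.Generator, max_len: int = 40) -> tuple[str, str]:
    """A toy (reference, read) pair shaped like bisulfite data.

    The reference is random DNA; the read is its conversion with random
    methylation at CpGs, plus mutations, indels and end trims, so alignments
    exercise matches, ambiguity, mismatches and gaps.
    """
    n = int(rng.integers(10, max_len + 1))
    ref = "".join(rng.choice(list("ACGT"), size=n))
    read = []
    for i, b in enumerate(ref):
        if b == "C":
            if ref[i + 1 : i + 2] == "G" and rng.random() < 0.5:
                read.append("C")  # methylated CpG retained
            else:
                read.append("T")
        else:
            read.append(b)
    read = list("".join(read))
    for i in range(len(read)):  # sprinkle mismatches
        if rng.random() < 0.05:
            read[i] = str(rng.choice(list("ACGT")))
    if len(read) > 12 and rng.random() < 0.3:  # deletion
        start = int(rng.integers(0, len(read) - 3))
        del read[start : start + int(rng.integers(1, 4))]
    if rng.random() < 0.3:  # insertion
        pos = int(rng.integers(0, len(read)))
        read.insert(pos, str(rng.choice(list("ACGT"))))
    t5, t3 = int(rng.integers(0, 4)), int(rng.integers(0, 4))
    read = read[t5 : len(read) - t3 if t3 else len(read)]
    return ref, "".join(read)
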