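"""Codon state space for the bacterial genetic code (translation table 11).

All codon-model code in the package works on the 61 sense codons; the
three stop codons (TAA, TAG, TGA) are excluded from the state space.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[11]

NUCS = "TCAG"
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product(NUCS, repeat=3)) if c not in STOP_CODONS
)
assert len(CODONS) == 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AA_OF = {c: _TABLE.forward_table[c] for c in CODONS}

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """True when the single-nucleotide change a<->b is a transition."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def _pair_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Static structure of single-nucleotide codon changes.

    Returns (single_diff, transition, synonymous) boolean 61x61 arrays;
    single_diff is False on the diagonal and for multi-nucleotide changes.
    """
    n = len(CODONS)
    single = np.zeros((n, n), dtype=bool)
    ts = np.zeros((n, n), dtype=bool)
    syn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            ts[i, j] = is_transition(*diffs[0])
            syn[i, j] = AA_OF[ci] == AA_OF[cj]
    return single, ts, syn


SINGLE_DIFF, TRANSITION, SYNONYMOUS = _pair_structure()


def translate(cds: str) -> str:
    """Translate an in-frame CDS of sense codons."""
    if len(cds) % 3:
        raise ValueError("CDS length not a multiple of 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at position {i}")
        aas.append(AA_OF[codon])
    return "".join(aas)


def f3x4_frequencies(sequences) -> np.ndarray:
    """F3x4 codon frequencies from positional nucleotide counts.

    Nucleotide frequencies are tallied separately at each codon position
    over all ungapped codons of the supplied sequences; the frequency of
    a codon is the product over its three positions, renormalised over
    the 61 sense codons.
    """
    counts = {p: dict.fromkeys(NUCS, 0.0) for p in range(3)}
    for seq in sequences:
        s = seq.upper()
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i : i + 3]
            if codon in CODON_INDEX:
                for p, nuc in enumerate(codon):
                    counts[p][nuc] += 1.0
    pos = []
    for p in range(3):
        tot = sum(counts[p].values())
        if tot == 0:
            raise ValueError("no countable codons in input sequences")
        pos.append({n: c / tot for n, c in counts[p].items()})
    freqs = np.array([pos[0][c[0]] * pos[1][c[1]] * pos[2][c[2]] for c in CODONS])
    return freqs / freqs.sum()
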