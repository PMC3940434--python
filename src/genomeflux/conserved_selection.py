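"""Conserved-ortholog selection and codon-aware alignment preparation.

Families for the concatenated species-tree alignment are chosen by two
filters: the smallest mean pairwise dN/dS (strong purifying selection)
among families whose mean synonymous rate dS lies between the first and
third quartiles (moderate, informative divergence).  Protein alignments
are mapped back onto their coding sequences codon by codon, noisy
regions are masked (gap-heavy columns removed, short blocks dropped),
alignments are concatenated with a partition map, and a neighbor-joining
tree on Poisson-corrected protein distances provides the starting
topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import LabeledTree

__all__ = [
    "MaskedAlignment",
    "select_conserved_families",
    "map_protein_alignment_to_codons",
    "mask_alignment",
    "concatenate_alignments",
    "nj_tree",
]


def select_conserved_families(
    rates: pd.DataFrame, k: int = 100, boundary_inclusive: bool = True
) -> list[str]:
    """Pick the k most conserved families with moderate synonymous rates.

    ``rates`` must be indexed by family id with columns ``mean_dnds``
    and ``mean_ds``.  Quartiles of mean dS are computed over all
    families with linear interpolation; families whose mean dS lies in
    [Q1, Q3] (boundaries inclusive by default) are ranked by ascending
    mean dN/dS, ties broken by family id, and the first k returned.
    """
    if not {"mean_dnds", "mean_ds"}.issubset(rates.columns):
        raise ValueError("rates needs columns mean_dnds and mean_ds")
    ds = rates["mean_ds"].to_numpy(dtype=float)
    q1, q3 = np.percentile(ds[np.isfinite(ds)], [25, 75])
    if boundary_inclusive:
        eligible = rates[(rates["mean_ds"] >= q1) & (rates["mean_ds"] <= q3)]
    else:
        eligible = rates[(rates["mean_ds"] > q1) & (rates["mean_ds"] < q3)]
    ranked = eligible.loc[eligible.index.sort_values()].sort_values("mean_dnds", kind="mergesort")
    ids = list(ranked.index[:k])
    if len(ids) < k:
        warnings.warn(f"only {len(ids)} of {k} requested families are eligible", stacklevel=2)
    return ids


def map_protein_alignment_to_codons(
    protein_alignment: dict[str, str], cds: dict[str, str]
) -> dict[str, str]:
    """Map an aligned protein back onto its CDS, codon by codon.

    For each taxon the ungapped protein length times three must equal
    the CDS length (stop codon excluded); each residue column becomes
    the corresponding codon triplet and each gap becomes ``---``.
    """
    from ._codes import translate

    out = {}
    for taxon, prot in protein_alignment.items():
        if taxon not in cds:
            raise ValueError(f"no CDS for taxon {taxon!r}")
        seq = cds[taxon].upper()
        translate(seq)  # raises on internal stops / bad length
        ungapped = prot.replace("-", "")
        if len(ungapped) * 3 != len(seq):
            raise ValueError(
                f"taxon {taxon!r}: protein length {len(ungapped)} x 3 != CDS length {len(seq)}"
            )
        codons = []
        pos = 0
        for residue in prot:
            if residue == "-":
                codons.append("---")
            else:
                codons.append(seq[pos : pos + 3])
                pos += 3
        out[taxon] = "".join(codons)
    return out


@dataclass
class MaskedAlignment:
    """Masked alignment with the index map back to original columns."""

    sequences: dict[str, str]
    kept_columns: list[int]
    blocks: list[tuple[int, int]]  # [start, end) ranges in original coordinates


def mask_alignment(
    alignment: dict[str, str], min_block: int = 10, max_gap_fraction: float = 0.5
) -> MaskedAlignment:
    """Drop gap-heavy columns and blocks shorter than ``min_block``.

    A column is invalid when its gap fraction exceeds
    ``max_gap_fraction``; maximal runs of valid columns shorter than
    ``min_block`` are removed entirely; the surviving blocks are
    concatenated in order.
    """
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment is not rectangular")
    (ncol,) = lengths
    taxa = list(alignment)
    arr = np.array([list(alignment[t]) for t in taxa])
    gap_frac = (arr == "-").mean(axis=0)
    valid = gap_frac <= max_gap_fraction
    blocks = []
    start = None
    for i in range(ncol + 1):
        ok = i < ncol and valid[i]
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= min_block:
                blocks.append((start, i))
            start = None
    kept = [c for s, e in blocks for c in range(s, e)]
    sequences = {t: "".join(alignment[t][c] for c in kept) for t in taxa}
    return MaskedAlignment(sequences=sequences, kept_columns=kept, blocks=blocks)


def concatenate_alignments(
    alignments: dict[str, dict[str, str]], family_order: list[str] | None = None
) -> tuple[dict[str, str], pd.DataFrame]:
    """Column-wise concatenation in a fixed family order.

    Returns the concatenated alignment and a partition map with each
    family's 1-based inclusive column range.  Every alignment must
    cover the same taxon set; no automatic gap-filling.
    """
    if family_order is None:
        family_order = sorted(alignments)
    taxa = None
    parts = []
    rows = []
    pos = 0
    for fam in family_order:
        aln = alignments[fam]
        if taxa is None:
            taxa = sorted(aln)
        elif sorted(aln) != taxa:
            missing = set(taxa) ^ set(aln)
            raise ValueError(f"taxon set mismatch in family {fam!r}: {sorted(missing)}")
        (ncol,) = {len(s) for s in aln.values()}
        parts.append(aln)
        rows.append({"family": fam, "start": pos + 1, "end": pos + ncol})
        pos += ncol
    concat = {t: "".join(p[t] for p in parts) for t in (taxa or [])}
    return concat, pd.DataFrame(rows)


def _poisson_distance(a: str, b: str) -> float:
    shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not shared:
        raise ValueError("no shared ungapped columns")
    p = sum(x != y for x, y in shared) / len(shared)
    if p >= 1.0:
        raise ValueError("saturated distance (p >= 1)")
    return -float(np.log(1.0 - p))


def nj_tree(alignment: dict[str, str]) -> LabeledTree:
    """Neighbor-joining tree on Poisson-corrected protein distances.

    Distances are d = -ln(1 - p) over shared ungapped columns.  Joins
    follow the standard NJ criterion with ties broken by lexicographic
    taxon-pair order; negative branch lengths are clamped to zero.
    """
    taxa = sorted(alignment)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    import skbio

    n = len(taxa)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _poisson_distance(alignment[taxa[i]], alignment[taxa[j]])
    sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm, ids=taxa))
    tree = LabeledTree.from_newick(str(sk_tree).strip())
    for node in tree.nodes.values():
        if node.length < 0:
            node.length = 0.0
    return tree
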