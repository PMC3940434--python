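"""Genome-specific codon usage tables and the Codon Adaptation Index.

A reference set of highly expressed genes (ribosomal proteins in the
intended use) defines, per amino acid, the relative adaptedness
w = (codon fraction) / (max fraction among synonyms) of every sense
codon.  The CAI of a gene is the geometric mean of w over its codons,
excluding Met, Trp and stop codons whose single-codon families carry no
information.  Zero-count sense codons receive a 0.5 pseudocount before
weights so CAI stays positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._codes import AA_OF, CODONS, STOP_CODONS

__all__ = ["CodonUsageTable", "build_usage_table", "cai", "CAIResult", "cai_group_compare"]

_SINGLE_CODON_AAS = {aa for aa in set(AA_OF.values()) if sum(1 for c in CODONS if AA_OF[c] == aa) == 1}
# amino acids encoded by a single codon (Met, Trp in the standard code)


@dataclass
class CodonUsageTable:
    """Per-codon counts, per-amino-acid fractions, and weights w."""

    counts: dict[str, float]
    fraction: dict[str, float]
    weight: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c, "amino_acid": AA_OF[c], "count": self.counts[c],
                "fraction": self.fraction[c], "weight": self.weight[c],
            }
            for c in CODONS
        ]
        return pd.DataFrame(rows)

    def write_cusp(self, path) -> None:
        """cusp-style text table: codon, aa, fraction, freq/1000, count."""
        total = sum(self.counts.values())
        with open(path, "w") as fh:
            fh.write("#Codon AA Fraction Frequency Number\n")
            for c in CODONS:
                per1000 = 1000.0 * self.counts[c] / total if total else 0.0
                fh.write(f"{c} {AA_OF[c]} {self.fraction[c]:.3f} {per1000:.3f} {int(self.counts[c])}\n")

    @classmethod
    def read_cusp(cls, path, pseudocount: float = 0.5) -> "CodonUsageTable":
        """Rebuild a table from a cusp-style file (counts column)."""
        counts = dict.fromkeys(CODONS, 0.0)
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                codon, _aa, _frac, _freq, number = line.split()
                if codon in counts:
                    counts[codon] = float(number)
        if not any(counts.values()):
            raise ValueError(f"no codon counts in {path}")
        return build_usage_table(["".join(c * int(n) for c, n in counts.items())], pseudocount)


def build_usage_table(reference_genes, pseudocount: float = 0.5) -> CodonUsageTable:
    """Codon usage table from a reference CDS set.

    Codons are tallied over all in-frame reference genes (stop codons
    ignored); zero-count sense codons get ``pseudocount`` on the
    frequency-per-1000 scale (so the table is invariant to duplicating
    the reference set) before the per-amino-acid fractions and
    Sharp & Li relative adaptedness weights
    w = fraction / max synonymous fraction are formed.
    """
    genes = list(reference_genes)
    if not genes:
        raise ValueError("empty reference set")
    counts = dict.fromkeys(CODONS, 0.0)
    for gene in genes:
        s = gene.upper()
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i : i + 3]
            if codon in counts:
                counts[codon] += 1.0
            elif codon not in STOP_CODONS and "-" not in codon:
                raise ValueError(f"unrecognised codon {codon!r}")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("reference set contains no sense codons")
    per_mille = {c: 1000.0 * n / total for c, n in counts.items()}
    adjusted = {c: (x if x > 0 else pseudocount) for c, x in per_mille.items()}
    fraction = {}
    weight = {}
    for aa in sorted(set(AA_OF.values())):
        fam = [c for c in CODONS if AA_OF[c] == aa]
        tot = sum(adjusted[c] for c in fam)
        top = max(adjusted[c] for c in fam)
        for c in fam:
            fraction[c] = adjusted[c] / tot
            weight[c] = adjusted[c] / top
    return CodonUsageTable(counts=counts, fraction=fraction, weight=weight)


@dataclass
class CAIResult:
    gene: str
    cai: float
    n_codons: int


def cai(gene_cds: str, table: CodonUsageTable, gene_id: str = "", include_single_codon_aas: bool = False) -> CAIResult:
    """Codon Adaptation Index: geometric mean of w over counted codons.

    Codons for single-codon amino acids (Met, Trp) and stop codons are
    excluded by default; ``include_single_codon_aas`` keeps them for
    strict compatibility with tools that count every sense codon.
    """
    s = gene_cds.upper()
    log_sum = 0.0
    n = 0
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        if codon not in table.weight:
            continue
        if not include_single_codon_aas and AA_OF[codon] in _SINGLE_CODON_AAS:
            continue
        log_sum += math.log(table.weight[codon])
        n += 1
    if n == 0:
        raise ValueError("gene has no countable codons")
    return CAIResult(gene=gene_id, cai=math.exp(log_sum / n), n_codons=n)


def cai_group_compare(
    lost_genes: dict[str, str],
    retained_genes: dict[str, str],
    table: CodonUsageTable,
    sided: str = "two",
):
    """Table-style CAI comparison of Lost vs Retained gene groups.

    Computes each group's CAI mean, sd and n and a two-sample t-test
    p-value (Welch).  Returns (summary dict, per-gene DataFrame); the
    test is skipped with a flag when either group is a singleton.
    """
    from .stats_report import t_test

    if not lost_genes or not retained_genes:
        raise ValueError("both groups must be non-empty")
    rows = []
    for group, genes in (("lost", lost_genes), ("retained", retained_genes)):
        for gid, seq in genes.items():
            rows.append({"group": group, "gene": gid, "cai": cai(seq, table, gid).cai})
    frame = pd.DataFrame(rows)
    lost = frame.loc[frame["group"] == "lost", "cai"].to_numpy()
    ret = frame.loc[frame["group"] == "retained", "cai"].to_numpy()
    out = {
        "lost_n": len(lost), "lost_mean": float(lost.mean()),
        "lost_sd": float(lost.std(ddof=1)) if len(lost) > 1 else float("nan"),
        "retained_n": len(ret), "retained_mean": float(ret.mean()),
        "retained_sd": float(ret.std(ddof=1)) if len(ret) > 1 else float("nan"),
        "test_skipped": len(lost) < 2 or len(ret) < 2,
    }
    if not out["test_skipped"]:
        res = t_test(lost, ret, sided=sided)
        out["p_value"] = res.p_value
        out["statistic"] = res.statistic
    return out, frame
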