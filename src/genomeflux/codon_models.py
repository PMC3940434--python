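"""Codon substitution models: pairwise dN/dS and GY94 branch models.

Two layers live here.  The counting layer estimates pairwise rates of
synonymous (dS) and non-synonymous (dN) substitution per site, either
with the transparent equal-weight NG86 scheme or with a YN00-style
iteration that weights site classification by the transition/transversion
rate ratio kappa and corrects distances with transitions and
transversions distinguished.  The likelihood layer implements the
Goldman-Yang (GY94) codon model with branch classes sharing a dN/dS
ratio omega: Felsenstein pruning over the 61 sense-codon states,
maximum-likelihood fitting of kappa, per-class omega and branch lengths,
and likelihood-ratio / AIC model comparison.

Branch lengths are measured in expected substitutions per codon; each
class's rate matrix is scaled so that one unit of branch length equals
one expected substitution per codon at that class's parameters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from ._codes import (
    AA_OF,
    CODON_INDEX,
    CODONS,
    SINGLE_DIFF,
    STOP_CODONS,
    SYNONYMOUS,
    TRANSITION,
    f3x4_frequencies,
    is_transition,
)
from .trees import LabeledTree

__all__ = [
    "CodonAlignment",
    "PairwiseRates",
    "ng86_pairwise",
    "yn00_hky_pairwise",
    "gy94_rate_matrix",
    "branch_model_loglik",
    "CodonBranchModel",
    "BranchModelResults",
    "fit_branch_model",
    "ModelComparison",
    "compare_models",
    "per_genome_dn_to_outgroup",
]

GAP_CODON = "---"


# ---------------------------------------------------------------------------
# alignment container
# ---------------------------------------------------------------------------


class CodonAlignment:
    """In-frame codon alignment; gaps are whole-codon ``---``."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences differ in length")
        (length,) = lengths
        if length % 3:
            raise ValueError("alignment length not a multiple of 3")
        self.sequences = {t: s.upper() for t, s in sequences.items()}
        self.n_codons = length // 3
        for taxon, seq in self.sequences.items():
            for i in range(0, length, 3):
                codon = seq[i : i + 3]
                if codon in STOP_CODONS:
                    raise ValueError(f"internal stop codon in {taxon!r} at codon {i // 3}")

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    def codons(self, taxon: str) -> list[str]:
        s = self.sequences[taxon]
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def subset(self, taxa) -> "CodonAlignment":
        return CodonAlignment({t: self.sequences[t] for t in taxa})

    def codes(self, taxa=None) -> np.ndarray:
        """Codon-index matrix (taxa x sites); -1 marks gaps/ambiguity."""
        taxa = list(taxa) if taxa is not None else self.taxa
        out = np.empty((len(taxa), self.n_codons), dtype=np.int64)
        for r, t in enumerate(taxa):
            out[r] = [CODON_INDEX.get(c, -1) for c in self.codons(t)]
        return out

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon, seq in self.sequences.items():
                fh.write(f">{taxon}\n{seq}\n")


# ---------------------------------------------------------------------------
# pairwise counting estimators
# ---------------------------------------------------------------------------


@dataclass
class PairwiseRates:
    """Pairwise substitution-rate estimates per site class."""

    dn: float
    ds: float
    omega: float | None
    s_sites: float
    n_sites: float
    method: str
    saturated: bool = False
    converged: bool = True
    kappa: float | None = None


def _site_counts(codon: str, kappa: float = 1.0) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts for one codon.

    Each codon position contributes one site, split by the fraction of
    possible single-nucleotide changes (weighted kappa for transitions,
    stop-codon changes excluded) that are synonymous.
    """
    syn = 0.0
    for p in range(3):
        w_tot = w_syn = 0.0
        for nuc in "TCAG":
            if nuc == codon[p]:
                continue
            alt = codon[:p] + nuc + codon[p + 1 :]
            if alt in STOP_CODONS:
                continue
            w = kappa if is_transition(codon[p], nuc) else 1.0
            w_tot += w
            if AA_OF[alt] == AA_OF[codon]:
                w_syn += w
        if w_tot > 0:
            syn += w_syn / w_tot
    return syn, 3.0 - syn


def _path_differences(a: str, b: str) -> np.ndarray:
    """Average substitution counts between two codons over minimal paths.

    Returns a length-4 vector (syn-ts, syn-tv, nonsyn-ts, nonsyn-tv)
    averaged over all orderings of the differing positions; paths that
    pass through a stop codon are excluded (all orderings are used if
    every path is blocked).
    """
    diff_pos = [p for p in range(3) if a[p] != b[p]]
    if not diff_pos:
        return np.zeros(4)

    def walk(order):
        counts = np.zeros(4)
        cur = a
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                return None
            ts = is_transition(cur[p], b[p])
            syn = AA_OF[cur] == AA_OF[nxt]
            counts[(0 if syn else 2) + (0 if ts else 1)] += 1
            cur = nxt
        return counts

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:  # every route crosses a stop; fall back to direct tally
        valid = []
        for order in itertools.permutations(diff_pos):
            counts = np.zeros(4)
            cur = a
            for p in order:
                nxt = cur[:p] + b[p] + cur[p + 1 :]
                ts = is_transition(cur[p], b[p])
                syn = nxt not in STOP_CODONS and cur not in STOP_CODONS and AA_OF.get(cur) == AA_OF.get(nxt)
                counts[(0 if syn else 2) + (0 if ts else 1)] += 1
                cur = nxt
            valid.append(counts)
    return np.mean(valid, axis=0)


def _paired_codons(a: str, b: str) -> list[tuple[str, str]]:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("length not a multiple of 3")
    pairs = []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3].upper(), b[i : i + 3].upper()
        if ca in CODON_INDEX and cb in CODON_INDEX:
            pairs.append((ca, cb))
    return pairs


def ng86_pairwise(a: str, b: str) -> PairwiseRates:
    """NG86 pairwise dN/dS with Jukes-Cantor correction.

    Sites are counted per codon position with equal weight on every
    non-stop change and averaged over the two sequences; differences are
    averaged over all minimal substitution paths between differing
    codons; proportions are corrected with d = -3/4 ln(1 - 4p/3).
    """
    pairs = _paired_codons(a, b)
    if not pairs:
        raise ValueError("no comparable (ungapped) codons")
    s_sites = n_sites = 0.0
    diffs = np.zeros(4)
    for ca, cb in pairs:
        sa, na = _site_counts(ca)
        sb, nb = _site_counts(cb)
        s_sites += (sa + sb) / 2
        n_sites += (na + nb) / 2
        diffs += _path_differences(ca, cb)
    sd, nd = diffs[0] + diffs[1], diffs[2] + diffs[3]

    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * math.log(1 - 4 * p / 3)

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds, dn = jc(ps), jc(pn)
    if ds is None or dn is None:
        return PairwiseRates(
            dn=float("nan"), ds=float("nan"), omega=None,
            s_sites=s_sites, n_sites=n_sites, method="NG86", saturated=True,
        )
    omega = dn / ds if ds > 0 else None
    return PairwiseRates(dn=dn, ds=ds, omega=omega, s_sites=s_sites, n_sites=n_sites, method="NG86")


def _k80_distance(p: float, q: float) -> tuple[float | None, float | None, float | None]:
    """Two-parameter distance and ts/tv rate components.

    Returns (d, a, b) with a the transition and b the per-type
    transversion component; None when the log arguments are non-positive
    (saturation).
    """
    w1 = 1 - 2 * p - q
    w2 = 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return None, None, None
    a = -0.5 * math.log(w1) + 0.25 * math.log(w2)
    b = -0.25 * math.log(w2)
    return a + 2 * b, a, b


_FOURFOLD = {c for c in CODONS if all(c[:2] + n in CODON_INDEX and AA_OF[c[:2] + n] == AA_OF[c] for n in "TCAG")}


def _kappa_from_degenerate_sites(pairs) -> float | None:
    """kappa from fourfold-degenerate and non-degenerate positions.

    Transition/transversion proportions are tallied at third positions of
    codons fourfold-degenerate in both sequences and at non-degenerate
    positions (where any change is non-synonymous); each yields a K80
    kappa estimate and the two are combined weighted by site counts.
    """
    counts = {"four": [0, 0, 0], "zero": [0, 0, 0]}  # [sites, ts, tv]
    for ca, cb in pairs:
        if ca in _FOURFOLD and cb in _FOURFOLD and ca[:2] == cb[:2]:
            counts["four"][0] += 1
            if ca[2] != cb[2]:
                counts["four"][1 if is_transition(ca[2], cb[2]) else 2] += 1
        for p in range(3):
            # non-degenerate: every non-stop change at this position is non-synonymous
            def nondeg(c):
                return all(
                    AA_OF[c[:p] + n + c[p + 1 :]] != AA_OF[c]
                    for n in "TCAG"
                    if n != c[p] and (c[:p] + n + c[p + 1 :]) in CODON_INDEX
                )

            if nondeg(ca) and nondeg(cb):
                counts["zero"][0] += 1
                if ca[p] != cb[p]:
                    counts["zero"][1 if is_transition(ca[p], cb[p]) else 2] += 1
    est, weights = [], []
    for sites, ts, tv in counts.values():
        if sites == 0:
            continue
        _, a, b = _k80_distance(ts / sites, tv / sites)
        if a is None or b is None or b <= 0 or a <= 0:
            continue
        est.append(a / b)
        weights.append(sites)
    if not est:
        return None
    return float(np.average(est, weights=weights))


def yn00_hky_pairwise(a: str, b: str, max_iter: int = 100, tol: float = 1e-8) -> PairwiseRates:
    """YN00-style pairwise dN/dS with kappa-weighted sites.

    Site classification weights transitions by kappa; synonymous and
    non-synonymous distances are corrected with transitions and
    transversions distinguished (two-parameter correction); kappa is
    estimated from fourfold-degenerate and non-degenerate positions and
    the whole scheme is iterated until kappa, dN and dS move by less
    than ``tol``.
    """
    pairs = _paired_codons(a, b)
    if not pairs:
        raise ValueError("no comparable (ungapped) codons")
    kappa_sites = _kappa_from_degenerate_sites(pairs)
    kappa = kappa_sites if kappa_sites is not None else 2.0
    diffs = np.zeros(4)
    for ca, cb in pairs:
        diffs += _path_differences(ca, cb)
    syn_ts, syn_tv, non_ts, non_tv = diffs

    prev = (float("inf"),) * 3
    dn = ds = 0.0
    converged = False
    s_sites = n_sites = 0.0
    for _ in range(max_iter):
        s_sites = n_sites = 0.0
        for ca, cb in pairs:
            sa, na = _site_counts(ca, kappa)
            sb, nb = _site_counts(cb, kappa)
            s_sites += (sa + sb) / 2
            n_sites += (na + nb) / 2
        ds, _, _ = _k80_distance(syn_ts / s_sites, syn_tv / s_sites) if s_sites > 0 else (0.0, 0, 0)
        dn, _, _ = _k80_distance(non_ts / n_sites, non_tv / n_sites) if n_sites > 0 else (0.0, 0, 0)
        if ds is None or dn is None:
            return PairwiseRates(
                dn=float("nan"), ds=float("nan"), omega=None, s_sites=s_sites,
                n_sites=n_sites, method="YN00-HKY", saturated=True, kappa=kappa,
            )
        new_kappa = _kappa_from_degenerate_sites(pairs)
        if new_kappa is not None:
            kappa = new_kappa
        cur = (kappa, dn, ds)
        if max(abs(x - y) for x, y in zip(cur, prev)) < tol:
            converged = True
            break
        prev = cur
    omega = dn / ds if ds > 0 else None
    return PairwiseRates(
        dn=dn, ds=ds, omega=omega, s_sites=s_sites, n_sites=n_sites,
        method="YN00-HKY", converged=converged, kappa=kappa,
    )


# ---------------------------------------------------------------------------
# GY94 rate matrix and transition probabilities
# ---------------------------------------------------------------------------


def gy94_rate_matrix(kappa: float, omega: float, codon_freqs: np.ndarray, scale: bool = True) -> np.ndarray:
    """GY94 instantaneous rate matrix over the 61 sense codons.

    q(i->j) is zero for multi-nucleotide changes, proportional to
    pi_j for a synonymous transversion, kappa*pi_j for a synonymous
    transition, and multiplied by omega when the change is
    non-synonymous.  When ``scale`` is true the matrix is normalised so
    the expected substitution rate is one per codon per unit time.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    freqs = np.asarray(codon_freqs, dtype=float)
    if freqs.shape != (61,) or abs(freqs.sum() - 1) > 1e-8 or (freqs < 0).any():
        raise ValueError("codon_freqs must be 61 non-negative values summing to 1")
    q = np.where(SINGLE_DIFF, freqs[None, :], 0.0)
    q = np.where(SINGLE_DIFF & TRANSITION, q * kappa, q)
    q = np.where(SINGLE_DIFF & ~SYNONYMOUS, q * omega, q)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale:
        rate = -(freqs * np.diag(q)).sum()
        if rate > 0:
            q /= rate
    return q


class _EigQ:
    """Eigendecomposition of a reversible Q for fast matrix exponentials."""

    def __init__(self, q: np.ndarray, freqs: np.ndarray):
        d = np.sqrt(np.maximum(freqs, 1e-300))
        sym = (q * d[:, None]) / d[None, :]
        lam, u = np.linalg.eigh((sym + sym.T) / 2)
        self.lam = lam
        self.left = u / d[:, None]  # P(t) = left @ diag(exp(lam t)) @ right
        self.right = (u * d[:, None]).T

    def expm(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.lam * t)) @ self.right
        return np.maximum(p, 0.0)


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------


def _compress_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, weights = np.unique(codes, axis=1, return_counts=True)
    return patterns, weights.astype(float)


class _PruningEngine:
    """Site-pattern-compressed pruning over a labeled tree."""

    def __init__(self, alignment: CodonAlignment, tree: LabeledTree, class_of_label: dict[str, str]):
        self.tree = tree
        leaf_names = tree.leaf_names()
        missing = set(leaf_names) - set(alignment.taxa)
        if missing:
            raise ValueError(f"taxa missing from alignment: {sorted(missing)}")
        codes = alignment.codes(leaf_names)
        self.patterns, self.weights = _compress_patterns(codes)
        self.n_sites = alignment.n_codons
        self.leaf_row = {name: r for r, name in enumerate(leaf_names)}
        self.postorder = tree.postorder()
        self.edges = [n for n in self.postorder if n.parent is not None]
        self.edge_class: dict[int, str] = {}
        for e in self.edges:
            if e.label is None or e.label not in class_of_label:
                raise ValueError(f"branch label {e.label!r} not mapped to an omega class")
            self.edge_class[e.id] = class_of_label[e.label]
        self.classes = sorted(set(self.edge_class.values()))
        npat = self.patterns.shape[1]
        self._leaf_partial: dict[int, np.ndarray] = {}
        for node in self.postorder:
            if node.is_leaf:
                col = self.patterns[self.leaf_row[node.name]]
                part = np.zeros((npat, 61))
                ok = col >= 0
                part[ok, col[ok]] = 1.0
                part[~ok, :] = 1.0  # gap codon: missing data
                self._leaf_partial[node.id] = part

    def class_eigs(self, kappa: float, omegas: dict[str, float], freqs: np.ndarray) -> dict[str, _EigQ]:
        return {c: _EigQ(gy94_rate_matrix(kappa, omegas[c], freqs), freqs) for c in self.classes}

    def _edge_p(self, eigs, node, lengths) -> np.ndarray:
        return eigs[self.edge_class[node.id]].expm(lengths[node.id])

    def down_partials(self, eigs, lengths):
        """Post-order conditional likelihoods with per-site log scaling."""
        npat = self.patterns.shape[1]
        down: dict[int, np.ndarray] = {}
        scale: dict[int, np.ndarray] = {}
        for node in self.postorder:
            if node.is_leaf:
                down[node.id] = self._leaf_partial[node.id]
                scale[node.id] = np.zeros(npat)
                continue
            part = np.ones((npat, 61))
            sc = np.zeros(npat)
            for cid in node.children:
                child = self.tree.nodes[cid]
                p = self._edge_p(eigs, child, lengths)
                part = part * (down[cid] @ p.T)
                sc = sc + scale[cid]
            m = part.max(axis=1)
            m[m == 0] = 1.0
            down[node.id] = part / m[:, None]
            scale[node.id] = sc + np.log(m)
        return down, scale

    def loglik(self, kappa: float, omegas: dict[str, float], lengths: dict[int, float], freqs: np.ndarray) -> float:
        eigs = self.class_eigs(kappa, omegas, freqs)
        down, scale = self.down_partials(eigs, lengths)
        root = self.tree.root
        site = down[root] @ freqs
        return float(np.dot(self.weights, np.log(site) + scale[root]))

    def edge_coefficients(self, eigs, lengths, freqs):
        """Per-edge spectral coefficients for 1-D branch-length profiles.

        For edge e between parent u and child v the site likelihood as a
        function of t is ``sum_k C[s, k] * exp(lam_k * t)`` (up to the
        returned per-site log scale), computed from the down partial of v
        and the out partial of u with the other subtrees folded in.
        """
        down, dscale = self.down_partials(eigs, lengths)
        npat = self.patterns.shape[1]
        out = {self.tree.root: np.tile(freqs, (npat, 1))}
        oscale = {self.tree.root: np.zeros(npat)}
        coef: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for node in self.tree.preorder():
            if node.is_leaf:
                continue
            contrib = {}
            for cid in node.children:
                child = self.tree.nodes[cid]
                p = self._edge_p(eigs, child, lengths)
                contrib[cid] = down[cid] @ p.T
            for cid in node.children:
                child = self.tree.nodes[cid]
                w = out[node.id].copy()
                sc = oscale[node.id].copy()
                for other in node.children:
                    if other != cid:
                        w = w * contrib[other]
                        sc = sc + dscale[other]
                m = w.max(axis=1)
                m[m == 0] = 1.0
                w /= m[:, None]
                sc = sc + np.log(m)
                eig = eigs[self.edge_class[cid]]
                a = w @ eig.left
                b = down[cid] @ eig.right.T
                coef[cid] = (a * b, eig.lam, sc + dscale[cid])
                p = self._edge_p(eigs, child, lengths)
                out[cid] = w @ p
                oscale[cid] = sc
        return coef

    def edge_loglik(self, coef_entry, t: float) -> float:
        c, lam, sc = coef_entry
        site = c @ np.exp(lam * t)
        site = np.maximum(site, 1e-300)
        return float(np.dot(self.weights, np.log(site) + sc))


def branch_model_loglik(
    alignment: CodonAlignment,
    tree: LabeledTree,
    class_of_label: dict[str, str],
    kappa: float,
    omegas: dict[str, float],
    codon_freqs: np.ndarray | None = None,
    branch_lengths: dict[int, float] | None = None,
) -> float:
    """Log-likelihood of a GY94 branch model by Felsenstein pruning.

    Gap codons contribute partial likelihood one over all states; the
    root carries the equilibrium codon frequencies.  Branch lengths are
    taken from the tree unless overridden.
    """
    if codon_freqs is None:
        codon_freqs = f3x4_frequencies(alignment.sequences.values())
    engine = _PruningEngine(alignment, tree, class_of_label)
    if branch_lengths is None:
        branch_lengths = {e.id: e.length for e in engine.edges}
    return engine.loglik(kappa, omegas, branch_lengths, codon_freqs)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

OMEGA_BOUNDS = (1e-6, 20.0)
KAPPA_BOUNDS = (0.1, 50.0)
LENGTH_BOUNDS = (1e-8, 50.0)


@dataclass
class BranchModelResults:
    """ML estimates for one GY94 branch model.

    Carries the fitted transition/transversion ratio kappa, one dN/dS
    ratio per branch class, per-edge branch lengths (expected
    substitutions per codon), the log-likelihood and the parameter count
    NP = 1 (kappa) + #omega classes + #branch lengths (+9 for the F3x4
    frequencies when ``count_freq_params`` was requested).
    """

    model: str
    class_of_label: dict[str, str]
    kappa: float
    omegas: dict[str, float]
    branch_lengths: dict[int, float]
    lnl: float
    np: int
    codon_freqs: np.ndarray
    converged: bool
    n_codons: int
    n_patterns: int
    identifiable: bool = True
    history: list[float] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2 * self.np - 2 * self.lnl

    def compare(self, null: "BranchModelResults") -> "ModelComparison":
        return compare_models(null, self)

    def summary(self) -> str:
        lines = [
            f"GY94 branch model: {self.model}",
            f"  lnL = {self.lnl:.4f}   NP = {self.np}   AIC = {self.aic:.4f}",
            f"  kappa = {self.kappa:.4f}   converged = {self.converged}",
            f"  codons = {self.n_codons} ({self.n_patterns} patterns)",
            "  omega (dN/dS) by branch class:",
        ]
        for cls in sorted(self.omegas):
            lines.append(f"    {cls:<16s} {self.omegas[cls]:.4f}")
        tot = sum(self.branch_lengths.values())
        lines.append(f"  tree length = {tot:.4f} substitutions/codon over {len(self.branch_lengths)} branches")
        return "\n".join(lines)


class CodonBranchModel:
    """GY94 codon model with branch classes sharing a dN/dS ratio.

    Parameters
    ----------
    alignment : CodonAlignment
    tree : LabeledTree
        Every edge must carry a class label mapped by ``branch_classes``.
    branch_classes : dict
        branch label -> omega-class name.  A one-ratio model maps every
        label to one class; a free-ratio model gives each branch its own.
    codon_freqs : array or None
        Equilibrium frequencies; default F3x4 computed from the data.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: LabeledTree,
        branch_classes: dict[str, str],
        codon_freqs: np.ndarray | None = None,
    ):
        self.alignment = alignment
        self.tree = tree
        self.branch_classes = dict(branch_classes)
        if codon_freqs is None:
            codon_freqs = f3x4_frequencies(alignment.sequences.values())
        freqs = np.maximum(np.asarray(codon_freqs, dtype=float), 1e-10)
        self.codon_freqs = freqs / freqs.sum()
        self.engine = _PruningEngine(alignment, tree, self.branch_classes)
        self.classes = self.engine.classes

    def loglik(self, kappa, omegas, branch_lengths=None) -> float:
        if branch_lengths is None:
            branch_lengths = {e.id: e.length for e in self.engine.edges}
        return self.engine.loglik(kappa, omegas, branch_lengths, self.codon_freqs)

    # -- optimisation --------------------------------------------------

    def _opt_scalar(self, fun, bounds, x0, f0=None):
        """Bounded 1-D maximisation in log space; never moves downhill."""
        lo, hi = np.log(bounds[0]), np.log(bounds[1])
        res = minimize_scalar(lambda z: fun(float(np.exp(z))), bounds=(lo, hi), method="bounded", options={"xatol": 1e-4})
        f0 = fun(x0) if f0 is None else f0
        if -res.fun > -f0:
            return float(np.exp(res.x)), -res.fun
        return x0, -f0

    def _cycle(self, kappa, omegas, lengths, current, free_classes=None):
        eng = self.engine
        if free_classes is None:
            free_classes = self.classes

        def neg_kappa(k):
            return -eng.loglik(k, omegas, lengths, self.codon_freqs)

        kappa, current = self._opt_scalar(neg_kappa, KAPPA_BOUNDS, kappa, f0=-current)
        for cls in free_classes:
            def neg_omega(w, cls=cls):
                trial = dict(omegas, **{cls: w})
                return -eng.loglik(kappa, trial, lengths, self.codon_freqs)

            omegas[cls], current = self._opt_scalar(neg_omega, OMEGA_BOUNDS, omegas[cls], f0=-current)
        # branch lengths: 1-D spectral profiles from shared partials,
        # updated jointly with step damping toward the previous vector
        eigs = eng.class_eigs(kappa, omegas, self.codon_freqs)
        coef = eng.edge_coefficients(eigs, lengths, self.codon_freqs)
        proposal = dict(lengths)
        for e in eng.edges:
            res = minimize_scalar(
                lambda t, eid=e.id: -eng.edge_loglik(coef[eid], t),
                bounds=LENGTH_BOUNDS, method="bounded", options={"xatol": 1e-9},
            )
            if -res.fun >= eng.edge_loglik(coef[e.id], lengths[e.id]):
                proposal[e.id] = float(res.x)
        for _ in range(8):
            lnl = eng.loglik(kappa, omegas, proposal, self.codon_freqs)
            if lnl >= current:
                return kappa, omegas, proposal, lnl
            proposal = {k: 0.5 * (proposal[k] + lengths[k]) for k in proposal}
        return kappa, omegas, lengths, current

    def fit(
        self,
        start: dict | None = None,
        n_starts: int = 3,
        tol: float = 1e-6,
        max_cycles: int = 60,
        warmup_cycles: int = 2,
        seed: int = 0,
        count_freq_params: bool = False,
        fixed_omegas: dict[str, float] | None = None,
        model_name: str = "branch-model",
    ) -> BranchModelResults:
        """Maximise the likelihood by coordinate ascent.

        Several fixed-seed starts are each run for ``warmup_cycles``
        cycles; the best is continued until the lnL improvement per
        cycle falls below ``tol``.  An explicit ``start`` (dict with
        kappa / omegas / branch_lengths) replaces the first default
        start.  ``fixed_omegas`` pins named classes at given values
        (e.g. a neutral omega = 1 null); they are excluded from both
        the optimisation and the parameter count.
        """
        eng = self.engine
        rng = np.random.default_rng(seed)
        fixed_omegas = dict(fixed_omegas or {})
        unknown = set(fixed_omegas) - set(self.classes)
        if unknown:
            raise ValueError(f"fixed_omegas names unknown class(es): {sorted(unknown)}")
        free_classes = [c for c in self.classes if c not in fixed_omegas]
        n_unique = len({tuple(self.alignment.sequences[t]) for t in self.alignment.taxa})
        starts = []
        for i in range(max(1, n_starts)):
            if i == 0 and start is not None:
                starts.append(
                    (
                        start.get("kappa", 2.0),
                        dict(start.get("omegas", dict.fromkeys(self.classes, 0.2))),
                        dict(start.get("branch_lengths", {e.id: max(e.length, 0.02) for e in eng.edges})),
                    )
                )
            else:
                kappa0 = float(np.exp(rng.uniform(np.log(1.2), np.log(6.0))))
                om0 = float(np.exp(rng.uniform(np.log(0.02), np.log(1.0))))
                t0 = float(np.exp(rng.uniform(np.log(0.02), np.log(0.3))))
                starts.append((kappa0, dict.fromkeys(self.classes, om0), dict.fromkeys([e.id for e in eng.edges], t0)))
        for _, omegas, _ in starts:
            omegas.update(fixed_omegas)

        warm = []
        for kappa, omegas, lengths in starts:
            current = eng.loglik(kappa, omegas, lengths, self.codon_freqs)
            for _ in range(warmup_cycles):
                kappa, omegas, lengths, current = self._cycle(kappa, omegas, lengths, current, free_classes)
            warm.append((current, kappa, omegas, lengths))
        current, kappa, omegas, lengths = max(warm, key=lambda w: w[0])

        history = [current]
        converged = False
        for _ in range(max_cycles):
            kappa, omegas, lengths, new = self._cycle(kappa, omegas, lengths, current, free_classes)
            history.append(new)
            if new - current < tol:
                converged = True
                current = new
                break
            current = new

        n_params = 1 + len(free_classes) + len(eng.edges) + (9 if count_freq_params else 0)
        return BranchModelResults(
            model=model_name,
            class_of_label=dict(self.branch_classes),
            kappa=kappa,
            omegas=dict(omegas),
            branch_lengths=dict(lengths),
            lnl=current,
            np=n_params,
            codon_freqs=self.codon_freqs,
            converged=converged,
            n_codons=self.alignment.n_codons,
            n_patterns=eng.patterns.shape[1],
            identifiable=n_unique > 1,
            history=history,
        )


def fit_branch_model(
    alignment: CodonAlignment,
    tree: LabeledTree,
    class_of_label: dict[str, str],
    **options,
) -> BranchModelResults:
    """Functional wrapper: build a :class:`CodonBranchModel` and fit it."""
    freqs = options.pop("codon_freqs", None)
    return CodonBranchModel(alignment, tree, class_of_label, codon_freqs=freqs).fit(**options)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


@dataclass
class ModelComparison:
    """LRT and AIC comparison of two branch-model fits.

    ``delta_aic`` = AIC(alternative) - AIC(null), i.e. AIC of the first
    model named in a "alt vs. null" comparison minus AIC of the second;
    negative values favour the alternative.
    """

    null_name: str
    alt_name: str
    lrt: float
    df: int
    p_value: float | None
    aic_null: float
    aic_alt: float
    delta_aic: float
    nested: bool
    better: str

    def summary(self) -> str:
        p = "-" if self.p_value is None else f"{self.p_value:.3g}"
        return (
            f"{self.alt_name} vs. {self.null_name}: "
            f"2dlnL = {self.lrt:.2f}, df = {self.df}, P = {p}, "
            f"dAIC = {self.delta_aic:.2f}, better = {self.better}"
        )


def _np_lnl(fit) -> tuple[int, float, str]:
    """Accept BranchModelResults, (NP, lnL) or (NP, lnL, name)."""
    if isinstance(fit, BranchModelResults):
        return fit.np, fit.lnl, fit.model
    if len(fit) == 3:
        n_params, lnl, name = fit
        return int(n_params), float(lnl), str(name)
    n_params, lnl = fit
    return int(n_params), float(lnl), f"NP={n_params}"

def compare_models(null, alt, alpha: float = 0.05, require_lrt: bool = False) -> ModelComparison:
    """Compare a null and an alternative branch-model fit.

    Accepts :class:`BranchModelResults` or plain ``(NP, lnL)`` pairs.
    Nested comparisons (df > 0) are decided by the likelihood-ratio test
    against a chi-square with df = NP difference; otherwise by AIC.
    """
    np0, lnl0, name0 = _np_lnl(null)
    np1, lnl1, name1 = _np_lnl(alt)
    lrt = 2.0 * (lnl1 - lnl0)
    df = np1 - np0
    aic0 = 2 * np0 - 2 * lnl0
    aic1 = 2 * np1 - 2 * lnl1
    nested = df > 0
    if require_lrt and not nested:
        raise ValueError("LRT requires a positive df; use the AIC verdict instead")
    if nested:
        p = float(chi2.sf(max(lrt, 0.0), df))
        better = name1 if p < alpha else name0
    else:
        p = None
        better = name1 if aic1 < aic0 else name0
    return ModelComparison(
        null_name=name0, alt_name=name1, lrt=lrt, df=df, p_value=p,
        aic_null=aic0, aic_alt=aic1, delta_aic=aic1 - aic0, nested=nested, better=better,
    )


# ---------------------------------------------------------------------------
# per-genome dN against a common outgroup
# ---------------------------------------------------------------------------


def per_genome_dn_to_outgroup(
    alignments: dict[str, CodonAlignment],
    outgroup: str,
    groups: dict[str, str] | None = None,
):
    """dN of every in-group taxon against one outgroup, per family.

    Returns a DataFrame with one row per (family, taxon) and, when a
    taxon -> group labelling is supplied, a per-group summary DataFrame
    (n, mean, sd, median of dN) for ecotype comparisons.
    """
    import pandas as pd

    rows = []
    for family, aln in alignments.items():
        if outgroup not in aln.sequences:
            raise ValueError(f"outgroup {outgroup!r} missing from family {family!r}")
        ref = aln.sequences[outgroup]
        for taxon in aln.taxa:
            if taxon == outgroup:
                continue
            rates = yn00_hky_pairwise(aln.sequences[taxon], ref)
            rows.append(
                {
                    "family": family, "taxon": taxon, "dn": rates.dn, "ds": rates.ds,
                    "omega": rates.omega, "saturated": rates.saturated,
                }
            )
    table = pd.DataFrame(rows)
    if groups is None:
        return table
    table["group"] = table["taxon"].map(groups)
    summary = (
        table.dropna(subset=["dn"])
        .groupby("group")["dn"]
        .agg(n="count", mean="mean", sd="std", median="median")
        .reset_index()
    )
    return table, summary
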