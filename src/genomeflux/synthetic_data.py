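"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the structure of the 18-genome marine
picocyanobacteria study: a 15-taxon tree (12 Prochlorococcus, 2 sister
Synechococcus, 1 outgroup) with nine labeled ancestral branches;
gene-content histories with heavy early loss; codon alignments evolved
under branch-class-specific dN/dS; genome-specific codon usage bias; and
noisy BLAST-style bit-score hit tables.  Everything is bit-reproducible
given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codes import CODONS
from .codon_models import CodonAlignment, _EigQ, gy94_rate_matrix
from .trees import LabeledTree

__all__ = [
    "study_topology",
    "INGROUP_TAXA",
    "OUTGROUP_TAXON",
    "FIVE_RATIO_OMEGAS",
    "branch_model_classes",
    "GeneContentTruth",
    "simulate_gene_content",
    "CodonSimTruth",
    "simulate_codon_alignment",
    "simulate_hit_table",
]

OUTGROUP_TAXON = "RCC307"
SYN_TAXA = ("WH8102", "WH7803")
HL_TAXA = ("MED4", "MIT9515", "AS9601", "MIT9301", "MIT9215", "MIT9312")
INGROUP_TAXA = (
    "MED4", "MIT9515", "AS9601", "MIT9301", "MIT9215", "MIT9312",
    "NATL1A", "NATL2A", "SS120", "MIT9211", "MIT9303", "MIT9313",
    "WH8102", "WH7803",
)

#: ML dN/dS estimates of the selected five-ratio branch model, used as
#: simulation truth: Synechococcus background, the deep branch after the
#: MIT9303-clade split, the MIT9303 clade, the HL stem branch, and the
#: Prochlorococcus background.
FIVE_RATIO_OMEGAS = {
    "w_syn": 0.226,
    "w_anc2": 0.001,
    "w_9303": 0.106,
    "w_anc4": 0.118,
    "w_bg": 0.076,
}


def study_topology(branch_length: float = 0.1) -> LabeledTree:
    """The fixed 15-taxon topology with labeled ancestral branches.

    Returns an unrooted (trifurcating-root) binary tree whose nine
    internal ancestral branches carry labels ``anc1`` .. ``anc9``:
    anc1 = Prochlorococcus stem, anc2 = post-MIT9303-split backbone,
    anc3 = NATL+HL backbone, anc4 = HL stem, anc5 = MED4+MIT9515 stem,
    anc6 = MIT9303-clade stem, anc7 = SS120-clade stem, anc8 = NATL stem,
    anc9 = stem of the 4-taxon HL subclade.  Remaining edges are tagged
    by side (``syn``) or clade (``mit9303_clade``, ``ss120_clade``,
    ``natl_clade``, ``hl_clade``).  All branch lengths are set to
    ``branch_length``.
    """
    bl = branch_length
    t = LabeledTree()
    a = t.add_node()  # trifurcation adjacent to the outgroup
    t.add_node("RCC307", a, bl, "syn")
    s = t.add_node(None, a, bl, "syn")
    t.add_node("WH8102", s, bl, "syn")
    t.add_node("WH7803", s, bl, "syn")
    p = t.add_node(None, a, bl, "anc1")
    m3 = t.add_node(None, p, bl, "anc6")
    t.add_node("MIT9303", m3, bl, "mit9303_clade")
    t.add_node("MIT9313", m3, bl, "mit9303_clade")
    q = t.add_node(None, p, bl, "anc2")
    ss = t.add_node(None, q, bl, "anc7")
    t.add_node("SS120", ss, bl, "ss120_clade")
    t.add_node("MIT9211", ss, bl, "ss120_clade")
    r = t.add_node(None, q, bl, "anc3")
    natl = t.add_node(None, r, bl, "anc8")
    t.add_node("NATL1A", natl, bl, "natl_clade")
    t.add_node("NATL2A", natl, bl, "natl_clade")
    h = t.add_node(None, r, bl, "anc4")
    mm = t.add_node(None, h, bl, "anc5")
    t.add_node("MED4", mm, bl, "hl_clade")
    t.add_node("MIT9515", mm, bl, "hl_clade")
    k = t.add_node(None, h, bl, "anc9")
    t.add_node("MIT9312", k, bl, "hl_clade")
    k2 = t.add_node(None, k, bl, "hl_clade")
    t.add_node("MIT9215", k2, bl, "hl_clade")
    k3 = t.add_node(None, k2, bl, "hl_clade")
    t.add_node("MIT9301", k3, bl, "hl_clade")
    t.add_node("AS9601", k3, bl, "hl_clade")
    return t


_ALL_LABELS = (
    "syn", "anc1", "anc2", "anc3", "anc4", "anc5", "anc6", "anc7", "anc8",
    "anc9", "mit9303_clade", "ss120_clade", "natl_clade", "hl_clade",
)
_HL_ALL = ("anc5", "anc9", "hl_clade")


def branch_model_classes() -> dict[str, dict[str, str]]:
    """Branch-label -> omega-class maps of the nested ratio models.

    Mirrors the reduced branch-model family used for hypothesis testing
    on this topology: one-ratio, the two two-ratio, four three-ratio,
    three four-ratio variants and the selected five-ratio model.
    """

    def build(*groups):
        out = {}
        for i, labels in enumerate(groups):
            for lab in labels:
                out.setdefault(lab, f"w{i + 1}")
        for lab in _ALL_LABELS:
            out.setdefault(lab, f"w{len(groups) + 1}")
        return out

    return {
        "one-ratio": dict.fromkeys(_ALL_LABELS, "w1"),
        "2-1": build(("syn",)),
        "2-2": build(("syn", "anc1")),
        "3-1": build(("syn",), ("anc2",)),
        "3-2": build(("syn",), ("anc2", "anc7", "ss120_clade")),
        "3-3": build(("syn",), ("anc2", "anc3", "anc8", "natl_clade")),
        "3-4": build(("syn",), ("anc2", "anc3", "anc4") + _HL_ALL),
        "4-1-1": build(("syn",), ("anc2",), ("anc4",)),
        "4-1-2": build(("syn",), ("anc2",), ("anc4",) + _HL_ALL),
        "4-2": build(("syn",), ("anc2",), ("anc6", "mit9303_clade")),
        "5": build(("syn",), ("anc2",), ("anc6", "mit9303_clade"), ("anc4",)),
        "free": {lab: f"w_{lab}" for lab in _ALL_LABELS},
    }


def five_ratio_truth_omegas() -> dict[str, float]:
    """omega per class of the "5" class map, at the selected-model values."""
    classes = branch_model_classes()["5"]
    by_class = {
        classes["syn"]: FIVE_RATIO_OMEGAS["w_syn"],
        classes["anc2"]: FIVE_RATIO_OMEGAS["w_anc2"],
        classes["anc6"]: FIVE_RATIO_OMEGAS["w_9303"],
        classes["anc4"]: FIVE_RATIO_OMEGAS["w_anc4"],
        classes["anc1"]: FIVE_RATIO_OMEGAS["w_bg"],
    }
    return by_class


# ---------------------------------------------------------------------------
# gene-content simulation
# ---------------------------------------------------------------------------


@dataclass
class GeneContentTruth:
    """Ground-truth gene-content history on a rooted tree.

    ``states_per_node`` maps node id -> {family: copy number}; ``events``
    is the per-branch ledger of (child node id, family, delta).
    """

    tree: LabeledTree
    states_per_node: dict[int, dict[str, int]]
    events: list[tuple[int, str, int]]
    gain_rate: float
    loss_rate: float

    @property
    def families(self) -> list[str]:
        fams = set()
        for states in self.states_per_node.values():
            fams.update(states)
        return sorted(fams)

    def leaf_matrix(self) -> pd.DataFrame:
        """Families x genomes copy-number matrix at the leaves."""
        leaves = self.tree.leaves()
        fams = self.families
        data = {
            leaf.name: [self.states_per_node[leaf.id].get(f, 0) for f in fams] for leaf in leaves
        }
        return pd.DataFrame(data, index=fams)

    def flux_by_branch(self) -> pd.DataFrame:
        rows = {}
        for child, _fam, delta in self.events:
            rec = rows.setdefault(child, {"gains": 0, "losses": 0})
            if delta > 0:
                rec["gains"] += delta
            else:
                rec["losses"] -= delta
        tree = self.tree
        return pd.DataFrame(
            [
                {
                    "node": nid,
                    "label": tree.nodes[nid].label,
                    "gains": rec["gains"],
                    "losses": rec["losses"],
                }
                for nid, rec in sorted(rows.items())
            ]
        )


def simulate_gene_content(
    tree: LabeledTree,
    root_size: int,
    gain_rate: float,
    loss_rate: float,
    seed: int,
    duplication_rate: float = 0.0,
) -> GeneContentTruth:
    """Evolve gene content along a rooted tree with known event ledger.

    Families evolve independently.  On a branch of length t each
    existing copy is lost with probability 1 - exp(-loss_rate * t) and
    duplicated with probability 1 - exp(-duplication_rate * t); gains
    arrive as a Poisson count with mean gain_rate * t and always found
    new families (a lost family is never re-gained), which keeps
    parsimony reconstruction identifiable.
    """
    if not tree.is_rooted:
        raise ValueError("tree must be rooted; root it at the outgroup leaf first (rooted_at_outgroup)")
    if root_size < 1 or gain_rate < 0 or loss_rate < 0 or duplication_rate < 0:
        raise ValueError("root_size must be >= 1 and rates non-negative")
    rng = np.random.default_rng(seed)
    fam_counter = root_size
    width = 6
    root_states = {f"fam{idx:0{width}d}": 1 for idx in range(root_size)}
    states: dict[int, dict[str, int]] = {tree.root: root_states}
    events: list[tuple[int, str, int]] = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_states = states[node.parent]
        t = node.length
        p_loss = 1.0 - np.exp(-loss_rate * t)
        p_dup = 1.0 - np.exp(-duplication_rate * t)
        here: dict[str, int] = {}
        for fam in sorted(parent_states):
            copies = parent_states[fam]
            if copies == 0:
                here[fam] = 0
                continue
            lost = int(rng.binomial(copies, p_loss))
            dup = int(rng.binomial(copies - lost, p_dup)) if p_dup > 0 else 0
            new = copies - lost + dup
            here[fam] = new
            if new != copies:
                events.append((node.id, fam, new - copies))
        n_gain = int(rng.poisson(gain_rate * t))
        for _ in range(n_gain):
            fam = f"fam{fam_counter:0{width}d}"
            fam_counter += 1
            here[fam] = 1
            events.append((node.id, fam, 1))
        states[node.id] = here
    return GeneContentTruth(tree, states, events, gain_rate, loss_rate)


# ---------------------------------------------------------------------------
# codon-alignment simulation
# ---------------------------------------------------------------------------


@dataclass
class CodonSimTruth:
    """Parameters of a GY94 branch-class simulation."""

    tree: LabeledTree
    kappa: float
    omega_by_class: dict[str, float]  # branch label -> omega
    codon_freqs: np.ndarray
    n_codons: int
    seed: int

    def __post_init__(self) -> None:
        freqs = np.asarray(self.codon_freqs, dtype=float)
        if freqs.shape != (61,):
            raise ValueError("codon_freqs must have 61 entries (sense codons only)")
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError("codon_freqs must sum to 1 within 1e-12")
        if any(w <= 0 for w in self.omega_by_class.values()):
            raise ValueError("every class omega must be > 0")
        self.codon_freqs = freqs


def simulate_codon_alignment(truth: CodonSimTruth) -> tuple[CodonAlignment, pd.DataFrame]:
    """Evolve codon sequences site-independently under GY94.

    The root sequence is drawn from the equilibrium frequencies and each
    branch applies the exact matrix-exponential transition probabilities
    of its class's scaled rate matrix, so a branch length of t yields t
    expected substitutions per codon.  Returns the gap-free leaf
    alignment and a per-branch table of sites whose codon differs
    between parent and child (observable changes).
    """
    tree = truth.tree
    rng = np.random.default_rng(truth.seed)
    labels = set(tree.branch_labels())
    missing = labels - set(truth.omega_by_class)
    if missing:
        raise ValueError(f"branch label(s) {sorted(missing)} missing from omega_by_class")
    eigs = {
        lab: _EigQ(gy94_rate_matrix(truth.kappa, w, truth.codon_freqs), truth.codon_freqs)
        for lab, w in truth.omega_by_class.items()
    }
    n = truth.n_codons
    state: dict[int, np.ndarray] = {tree.root: rng.choice(61, size=n, p=truth.codon_freqs)}
    changes = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent = state[node.parent]
        if node.length == 0:
            child = parent.copy()
        else:
            p = eigs[node.label].expm(node.length)
            p = p / p.sum(axis=1, keepdims=True)
            cum = np.cumsum(p, axis=1)
            u = rng.random(n)
            child = np.empty(n, dtype=np.int64)
            for s in np.unique(parent):
                mask = parent == s
                child[mask] = np.searchsorted(cum[s], u[mask], side="right")
            child = np.minimum(child, 60)
        state[node.id] = child
        changes.append(
            {"node": node.id, "label": node.label, "changed_sites": int((child != parent).sum())}
        )
    codon_arr = np.array(CODONS)
    seqs = {leaf.name: "".join(codon_arr[state[leaf.id]]) for leaf in tree.leaves()}
    return CodonAlignment(seqs), pd.DataFrame(changes)


# ---------------------------------------------------------------------------
# hit-table simulation
# ---------------------------------------------------------------------------


def simulate_hit_table(
    genomes: dict[str, dict[str, list[str]]],
    score_in=(120.0, 15.0),
    score_out=(60.0, 10.0),
    seed: int = 0,
    noise: float = 0.0,
    outgroup_genome: str = "OUTGROUP",
    outgroup_presence: dict[str, bool] | None = None,
    bit_score_min: float = 40.0,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """BLAST-outfmt-6-style hit rows with known ortholog families.

    ``genomes`` maps family -> genome -> gene list.  True orthologs get
    in-group scores drawn from ``score_in`` (mean, sd), truncated above
    the bit-score cutoff; out-group evidence hits use ``score_out``.
    With probability ``noise`` a query's top hit in a genome is swapped
    to a random gene of another family, creating inconsistent sets.
    Within-genome hits among co-family paralogs are emitted so paralog
    validation has per-genome blastp evidence.  Returns the hit table
    and the per-family outgroup-evidence flags.
    """
    rng = np.random.default_rng(seed)
    genome_ids = sorted({g for fam in genomes.values() for g in fam})
    genes_by_genome = {
        g: sorted(
            {(fam, gene) for fam, members in genomes.items() for gene in members.get(g, [])}
        )
        for g in genome_ids
    }

    def draw(dist, size=1):
        mean, sd = dist
        return rng.normal(mean, sd, size=size)

    rows = []
    flags: dict[str, bool] = {}
    if outgroup_presence is None:
        outgroup_presence = dict.fromkeys(genomes, True)
    for fam in sorted(genomes):
        members = genomes[fam]
        for qg in sorted(members):
            for query in members[qg]:
                for sg in sorted(members):
                    if sg == qg:
                        # within-genome paralog evidence
                        for subject in members[sg]:
                            if subject != query:
                                score = float(np.clip(draw(score_in)[0], bit_score_min + 1, None))
                                rows.append((query, qg, subject, sg, score))
                        continue
                    for rank, subject in enumerate(sorted(members[sg])):
                        score = float(np.clip(draw(score_in)[0] - 5.0 * rank, bit_score_min + 1, None))
                        if rank == 0 and noise > 0 and rng.random() < noise:
                            others = [x for x in genes_by_genome[sg] if x[0] != fam]
                            if others:
                                _, subject = others[rng.integers(len(others))]
                        rows.append((query, qg, subject, sg, score))
                if outgroup_presence.get(fam, False):
                    # evidence must clear the cutoff for the flag to be recoverable
                    score = float(np.clip(draw(score_out)[0], bit_score_min + 0.5, None))
                    rows.append((query, qg, f"{outgroup_genome}|{fam}", outgroup_genome, score))
        flags[fam] = bool(outgroup_presence.get(fam, False))
    table = pd.DataFrame(rows, columns=["query", "query_genome", "subject", "subject_genome", "bit_score"])
    return table, flags
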