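"""Ancestral gene-content reconstruction and per-branch gain/loss flux.

Gene states (copy numbers, 0 = absent) are reconstructed at every
internal node of a rooted tree by two methods assuming a single rate of
change between any two states: unordered-state parsimony (Sankoff with a
uniform unit cost matrix, returning the full most-parsimonious state set
per node) and a k-state equal-rates Markov (Mk) maximum-likelihood model
with marginal ancestral probabilities.  Root-ambiguous families are kept
only with out-group evidence; families ambiguous at an internal node are
excluded from downstream analyses.  Branch flux counts copy-number-
weighted gains and losses between consecutive nodes, and the ancestor-
derived ortholog universe is partitioned into Lost and Retained groups
per labeled branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .trees import LabeledTree

__all__ = [
    "AncestralStates",
    "FluxSummary",
    "LostRetainedPartition",
    "sankoff_parsimony",
    "mk_ml_reconstruction",
    "resolve_root",
    "compute_flux",
    "partition_lost_retained",
    "AncestralContentModel",
    "AncestralContentResults",
]

AMBIGUOUS = None  # sentinel for an unassigned state

_INF = float("inf")


@dataclass
class AncestralStates:
    """Per-node, per-family reconstruction results.

    ``mpr`` holds the most-parsimonious state set per node (parsimony);
    ``marginal`` the ML marginal probability vector over the family's
    state space; ``assigned`` the final state, with ``None`` marking an
    ambiguous node.
    """

    tree: LabeledTree
    families: list[str]
    method: str
    state_space: dict[str, int]  # family -> max state (space is 0..max)
    mpr: dict[str, dict[int, frozenset[int]]] = field(default_factory=dict)
    marginal: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)
    assigned: dict[str, dict[int, int | None]] = field(default_factory=dict)
    cost: dict[str, int] = field(default_factory=dict)
    rate: float | None = None

    def ambiguous_nodes(self, family: str) -> list[int]:
        return [n for n, s in self.assigned[family].items() if s is AMBIGUOUS]


def _check_leaves(matrix: pd.DataFrame, tree: LabeledTree) -> None:
    missing = [leaf.name for leaf in tree.leaves() if leaf.name not in matrix.columns]
    if missing:
        raise ValueError(f"leaf genome(s) missing from matrix columns: {missing}")


def _prepare_tree(tree: LabeledTree, outgroup: str | None) -> LabeledTree:
    if tree.is_rooted:
        return tree
    if outgroup is None:
        raise ValueError("unrooted tree: supply the outgroup leaf name to root on")
    return tree.rooted_at_outgroup(outgroup)


def sankoff_parsimony(
    matrix: pd.DataFrame, tree: LabeledTree, outgroup: str | None = None
) -> AncestralStates:
    """Sankoff parsimony with uniform unit cost between distinct states.

    The state space per family is {0, ..., max observed copy number}.
    Bottom-up cost vectors give the minimal total change count; the full
    MPR state set per node is recovered with a top-down pass: a state
    belongs to the set when some most-parsimonious labeling uses it.
    The final assignment is the MPR state where unique, ambiguous
    otherwise.
    """
    tree = _prepare_tree(tree, outgroup)
    _check_leaves(matrix, tree)
    post = tree.postorder()
    pre = tree.preorder()
    res = AncestralStates(tree=tree, families=list(matrix.index), method="parsimony", state_space={})
    for family, row in matrix.iterrows():
        kmax = int(row.max())
        k = kmax + 1
        res.state_space[family] = kmax
        down: dict[int, np.ndarray] = {}
        for node in post:
            if node.is_leaf:
                vec = np.full(k, _INF)
                vec[int(row[node.name])] = 0.0
            else:
                vec = np.zeros(k)
                for cid in node.children:
                    child = down[cid]
                    vec += np.minimum(child, child.min() + 1.0)
            down[node.id] = vec
        total = down[tree.root].min()
        # top-down: up[v][s] = best cost of the rest of the tree with v = s
        up: dict[int, np.ndarray] = {tree.root: np.zeros(k)}
        for node in pre:
            for cid in node.children:
                rest = up[node.id].copy()
                for other in node.children:
                    if other != cid:
                        ov = down[other]
                        rest += np.minimum(ov, ov.min() + 1.0)
                child = np.minimum(rest, rest.min() + 1.0)
                up[cid] = child
        mpr = {}
        assigned = {}
        for node in post:
            score = down[node.id] + up[node.id]
            states = frozenset(int(s) for s in np.flatnonzero(score <= total + 1e-9))
            mpr[node.id] = states
            assigned[node.id] = int(next(iter(states))) if len(states) == 1 else AMBIGUOUS
        res.mpr[family] = mpr
        res.assigned[family] = assigned
        res.cost[family] = int(round(total))
    return res


def _mk_transition(k: int, rate: float, t: float) -> np.ndarray:
    """Equal-rates k-state transition matrix: off-diagonal rate ``rate``."""
    e = np.exp(-k * rate * t)
    p = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(p, (1.0 + (k - 1) * e) / k)
    return p


def _mk_loglik_family(row, tree, post, rate: float, k: int) -> float:
    down = {}
    for node in post:
        if node.is_leaf:
            vec = np.zeros(k)
            vec[int(row[node.name])] = 1.0
        else:
            vec = np.ones(k)
            for cid in node.children:
                p = _mk_transition(k, rate, tree.nodes[cid].length)
                vec = vec * (p @ down[cid])
        down[node.id] = vec
    return float(np.log(max(down[tree.root].sum() / k, 1e-300)))


def mk_ml_reconstruction(
    matrix: pd.DataFrame,
    tree: LabeledTree,
    rate: float | str = "estimate",
    outgroup: str | None = None,
    support_threshold: float = 2.0,
    unit_lengths: bool = False,
) -> AncestralStates:
    """Mk (equal-rates, uniform stationary) ML ancestral reconstruction.

    The likelihood is computed by pruning; marginal ancestral
    probabilities use the re-rooting (up/down) decomposition.  With
    ``rate="estimate"`` a single change rate shared by all families is
    fitted by bounded 1-D maximum likelihood.  A node is assigned its
    best state only when its marginal log-likelihood beats the
    runner-up by at least ``support_threshold`` log units.
    """
    tree = _prepare_tree(tree, outgroup)
    _check_leaves(matrix, tree)
    work = tree.copy()
    if unit_lengths:
        for n in work.nodes.values():
            if n.parent is not None:
                n.length = 1.0
    post = work.postorder()
    pre = work.preorder()
    kk = {family: int(row.max()) + 1 for family, row in matrix.iterrows()}

    def total_neg_loglik(log_rate: float) -> float:
        r = float(np.exp(log_rate))
        return -sum(
            _mk_loglik_family(row, work, post, r, max(kk[family], 2))
            for family, row in matrix.iterrows()
        )

    if rate == "estimate":
        opt = minimize_scalar(total_neg_loglik, bounds=(np.log(1e-4), np.log(100.0)), method="bounded")
        fitted_rate = float(np.exp(opt.x))
    else:
        fitted_rate = float(rate)

    res = AncestralStates(
        tree=work, families=list(matrix.index), method="ml",
        state_space={f: k - 1 for f, k in kk.items()}, rate=fitted_rate,
    )
    for family, row in matrix.iterrows():
        k = max(kk[family], 2)
        down: dict[int, np.ndarray] = {}
        for node in post:
            if node.is_leaf:
                vec = np.zeros(k)
                vec[int(row[node.name])] = 1.0
            else:
                vec = np.ones(k)
                for cid in node.children:
                    p = _mk_transition(k, fitted_rate, work.nodes[cid].length)
                    vec = vec * (p @ down[cid])
            m = vec.max()
            down[node.id] = vec / m if m > 0 else vec
        up: dict[int, np.ndarray] = {work.root: np.full(k, 1.0 / k)}
        marginal = {}
        assigned = {}
        for node in pre:
            for cid in node.children:
                w = up[node.id].copy()
                for other in node.children:
                    if other != cid:
                        p = _mk_transition(k, fitted_rate, work.nodes[other].length)
                        w = w * (p @ down[other])
                p = _mk_transition(k, fitted_rate, work.nodes[cid].length)
                vec = w @ p
                m = vec.max()
                up[cid] = vec / m if m > 0 else vec
        for node in post:
            joint = down[node.id] * up[node.id]
            tot = joint.sum()
            prob = joint / tot if tot > 0 else np.full(k, 1.0 / k)
            marginal[node.id] = prob
            order = np.argsort(prob)[::-1]
            best, second = order[0], (order[1] if k > 1 else order[0])
            logs = np.log(np.maximum(prob, 1e-300))
            if k == 1 or logs[best] - logs[second] >= support_threshold:
                assigned[node.id] = int(best)
            else:
                assigned[node.id] = AMBIGUOUS
        res.marginal[family] = marginal
        res.assigned[family] = assigned
        # MPR-compatible view for the root rule: states within threshold
        res.mpr[family] = {
            nid: frozenset(
                int(s)
                for s in range(k)
                if np.log(max(marginal[nid][s], 1e-300)) >= np.log(max(marginal[nid].max(), 1e-300)) - support_threshold
            )
            for nid in marginal
        }
    return res


def resolve_root(
    states: AncestralStates, outgroup_evidence: dict[str, bool]
) -> tuple[dict[str, int], set[str]]:
    """Final root content under the out-group evidence rule.

    Unambiguous root states are kept as-is.  A family ambiguous at the
    root is kept (at the smallest positive state in its MPR set) only
    when it has out-group evidence, else absent.  Families ambiguous at
    any non-root internal node are excluded from downstream analyses.
    """
    root = states.tree.root
    root_content: dict[str, int] = {}
    excluded: set[str] = set()
    for family in states.families:
        assigned = states.assigned[family]
        for nid, s in assigned.items():
            node = states.tree.nodes[nid]
            if s is AMBIGUOUS and not node.is_leaf and nid != root:
                excluded.add(family)
                break
        root_state = assigned[root]
        if root_state is not AMBIGUOUS:
            root_content[family] = int(root_state)
            continue
        mpr = states.mpr[family][root]
        positive = sorted(s for s in mpr if s > 0)
        if outgroup_evidence.get(family, False) and positive:
            root_content[family] = positive[0]
            assigned[root] = positive[0]
        else:
            root_content[family] = 0
            assigned[root] = 0
    return root_content, excluded


@dataclass
class FluxSummary:
    """Per-branch gene gains and losses with per-family deltas."""

    per_branch: pd.DataFrame  # node, label, gains, losses
    deltas: dict[int, dict[str, int]]  # node -> family -> delta
    weighted: bool

    def branch_row(self, label: str) -> pd.Series:
        hit = self.per_branch[self.per_branch["label"] == label]
        if hit.empty:
            raise KeyError(f"no branch labeled {label!r}")
        return hit.iloc[0]


def compute_flux(
    states: AncestralStates,
    included: set[str] | None = None,
    weighted: bool = True,
) -> FluxSummary:
    """Per-branch flux from assigned states of consecutive nodes.

    delta = child state - parent state per family; gains accumulate
    positive deltas and losses negative ones, copy-number-weighted by
    default (a 2 -> 0 drop counts two losses) or per-event with
    ``weighted=False``.
    """
    tree = states.tree
    families = [f for f in states.families if included is None or f in included]
    deltas: dict[int, dict[str, int]] = {}
    rows = []
    for node in tree.postorder():
        if node.parent is None:
            continue
        gains = losses = 0
        d: dict[str, int] = {}
        for family in families:
            child = states.assigned[family].get(node.id)
            parent = states.assigned[family].get(node.parent)
            if child is AMBIGUOUS or parent is AMBIGUOUS or child is None or parent is None:
                continue
            delta = int(child) - int(parent)
            if delta:
                d[family] = delta
                if weighted:
                    gains += max(delta, 0)
                    losses += max(-delta, 0)
                else:
                    gains += delta > 0
                    losses += delta < 0
        deltas[node.id] = d
        rows.append({"node": node.id, "label": node.label, "gains": gains, "losses": losses})
    return FluxSummary(per_branch=pd.DataFrame(rows), deltas=deltas, weighted=weighted)


def leaf_flux_totals(states: AncestralStates, flux: FluxSummary, root_content: dict[str, int]) -> pd.DataFrame:
    """Per-genome cumulative flux from the root along each leaf path.

    One row per leaf: total gene losses and gains summed over the
    root-to-leaf path, the root gene count, and the leaf's own count.
    """
    tree = states.tree
    rows = []
    root_genes = sum(1 for v in root_content.values() if v > 0)
    leaves = tree.leaves()
    core_genes = sum(
        1
        for f in states.families
        if all((states.assigned[f].get(leaf.id) or 0) > 0 for leaf in leaves)
    )
    for leaf in tree.leaves():
        path = tree.path_to_root(leaf.id)
        loss = gain = 0
        for node in path[:-1]:
            d = flux.deltas.get(node.id, {})
            for delta in d.values():
                if delta > 0:
                    gain += delta if flux.weighted else 1
                else:
                    loss += -delta if flux.weighted else 1
        leaf_total = sum(
            max(states.assigned[f].get(leaf.id) or 0, 0) for f in states.families
        )
        rows.append(
            {
                "genome": leaf.name, "total_genes": leaf_total, "core_genes": core_genes,
                "root_genes": root_genes, "total_loss": loss, "total_gain": gain,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LostRetainedPartition:
    """Lost vs Retained split of the ancestor-derived ortholog universe."""

    branch: str
    lost: list[str]
    retained: list[str]

    def summary(self, metric: dict[str, float] | None = None) -> dict:
        out = {"branch": self.branch, "lost_n": len(self.lost), "retained_n": len(self.retained)}
        if metric is not None:
            for name, fams in (("lost", self.lost), ("retained", self.retained)):
                vals = [metric[f] for f in fams if f in metric and np.isfinite(metric[f])]
                out[f"{name}_mean"] = float(np.mean(vals)) if vals else np.nan
                out[f"{name}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        return out


def partition_lost_retained(
    root_content: dict[str, int],
    matrix: pd.DataFrame,
    states: AncestralStates,
    reference_genomes: list[str],
    target_genomes: list[str] | None = None,
    branch_labels: list[str] | None = None,
    excluded: set[str] | None = None,
) -> tuple[list[str], dict[str, LostRetainedPartition]]:
    """ASO universe and per-branch Lost/Retained partitions.

    The ancestor-derived ortholog universe contains families present at
    the root and present in every reference genome.  On each labeled
    ancestral branch, Lost = families whose state drops to 0 on that
    branch; Retained = families still present in the descendant node.
    The ``"terminal"`` partition splits the universe into families
    absent from every target genome versus present in all of them.
    """
    missing = [g for g in reference_genomes if g not in matrix.columns]
    if missing:
        raise ValueError(f"reference genome(s) not in matrix: {missing}")
    excluded = excluded or set()
    tree = states.tree
    if target_genomes is None:
        target_genomes = [g for g in matrix.columns if g not in reference_genomes]
    aso = sorted(
        f
        for f, s in root_content.items()
        if s > 0 and f not in excluded and f in matrix.index and (matrix.loc[f, reference_genomes] > 0).all()
    )
    if branch_labels is None:
        branch_labels = sorted(
            {e.label for e in tree.edges() if e.label and not tree.nodes[e.id].is_leaf}
        )
    partitions: dict[str, LostRetainedPartition] = {}
    for label in branch_labels:
        nodes = [e for e in tree.edges() if e.label == label]
        if not nodes:
            continue
        node = nodes[0]
        lost, retained = [], []
        for f in aso:
            child = states.assigned[f].get(node.id)
            parent = states.assigned[f].get(node.parent)
            if child is AMBIGUOUS or parent is AMBIGUOUS:
                continue
            if parent and not child:
                lost.append(f)
            elif child:
                retained.append(f)
        partitions[label] = LostRetainedPartition(branch=label, lost=lost, retained=retained)
    term_lost = [f for f in aso if (matrix.loc[f, target_genomes] == 0).all()]
    term_ret = [f for f in aso if (matrix.loc[f, target_genomes] > 0).all()]
    partitions["terminal"] = LostRetainedPartition(branch="terminal", lost=term_lost, retained=term_ret)
    return aso, partitions


# ---------------------------------------------------------------------------
# model/results wrapper
# ---------------------------------------------------------------------------


class AncestralContentModel:
    """Gene-content reconstruction model over a state matrix and tree."""

    def __init__(self, matrix: pd.DataFrame, tree: LabeledTree, outgroup: str | None = None):
        self.matrix = matrix
        self.tree = _prepare_tree(tree, outgroup)
        _check_leaves(matrix, self.tree)

    def fit(
        self,
        method: str = "parsimony",
        rate: float | str = "estimate",
        outgroup_evidence: dict[str, bool] | None = None,
        weighted_flux: bool = True,
    ) -> "AncestralContentResults":
        if method == "parsimony":
            states = sankoff_parsimony(self.matrix, self.tree)
        elif method == "ml":
            states = mk_ml_reconstruction(self.matrix, self.tree, rate=rate)
        else:
            raise ValueError(f"unknown method {method!r}")
        root_content, excluded = resolve_root(states, outgroup_evidence or {})
        included = set(states.families) - excluded
        flux = compute_flux(states, included=included, weighted=weighted_flux)
        return AncestralContentResults(
            model=self, states=states, root_content=root_content,
            excluded=excluded, flux=flux,
        )


@dataclass
class AncestralContentResults:
    """Reconstruction output: states, resolved root, per-branch flux."""

    model: AncestralContentModel
    states: AncestralStates
    root_content: dict[str, int]
    excluded: set[str]
    flux: FluxSummary

    @property
    def root_gene_count(self) -> int:
        return sum(1 for f, s in self.root_content.items() if s > 0 and f not in self.excluded)

    def leaf_totals(self) -> pd.DataFrame:
        return leaf_flux_totals(self.states, self.flux, self.root_content)

    def partitions(self, reference_genomes, **kw):
        return partition_lost_retained(
            self.root_content, self.model.matrix, self.states,
            reference_genomes, excluded=self.excluded, **kw,
        )

    def summary(self) -> str:
        fx = self.flux.per_branch
        lines = [
            f"Ancestral gene-content reconstruction ({self.states.method})",
            f"  families: {len(self.states.families)}  excluded (ambiguous): {len(self.excluded)}",
            f"  root gene count: {self.root_gene_count}",
            f"  total gains: {int(fx['gains'].sum())}  total losses: {int(fx['losses'].sum())}",
        ]
        if self.states.rate is not None:
            lines.insert(1, f"  fitted change rate: {self.states.rate:.4g} per unit branch length")
        labeled = fx[fx["label"].notna()]
        for _, row in labeled.iterrows():
            lines.append(f"    {str(row['label']):<14s} +{int(row['gains']):>5d} / -{int(row['losses']):>5d}")
        return "\n".join(lines)
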