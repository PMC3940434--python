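"""Ortholog-table construction from per-genome BLAST hit lists.

The procedure builds, for every query gene, a ranked in-group top-hit
list (one best subject per genome, kept only when it outscores every
out-group hit for that query), then assembles candidate ortholog sets
and classifies them: a set is *consistent* when every member genome's
own top-hit list reproduces exactly the same set; the remaining,
overlapping candidate sets are resolved into *consensus* sets by
majority rule, with paralogs accepted only when the same set is
nominated at least twice and each paralog is confirmed by its own
genome's hit evidence.  The result feeds a families x genomes
copy-number matrix (0 = absent) used for ancestral reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "TopHits",
    "OrthologSet",
    "build_top_hit_lists",
    "assemble_ortholog_sets",
    "validate_paralogs",
    "resolve_consensus_sets",
    "build_gene_state_matrix",
    "read_hit_table",
    "write_gene_state_matrix",
]

HIT_COLUMNS = ["query", "query_genome", "subject", "subject_genome", "bit_score"]


@dataclass
class TopHits:
    """Per-query ranked in-group hits and out-group evidence flags."""

    best: dict[str, dict[str, str]]  # query gene -> {genome: best subject}
    genome_of: dict[str, str]  # gene -> genome
    outgroup_evidence: dict[str, bool]  # query gene -> any out-group hit >= cutoff
    within_genome: dict[str, set[str]] = field(default_factory=dict)  # query -> same-genome subjects


@dataclass
class OrthologSet:
    """One gene family: per genome an ordered gene list.

    The first gene per genome is the ortholog; any further entries are
    validated paralogs.  ``status`` is "consistent" or "consensus".
    """

    family: str
    members: dict[str, list[str]]
    status: str

    def genes(self) -> set[str]:
        return {g for genes in self.members.values() for g in genes}

    def orthologs(self) -> frozenset[str]:
        return frozenset(genes[0] for genes in self.members.values() if genes)


def read_hit_table(path, columns=None) -> pd.DataFrame:
    """Read a BLAST outfmt-6-style TSV.

    ``columns`` maps the five required fields (query, query_genome,
    subject, subject_genome, bit_score) to column names or 0-based
    indices of the file; by default the first file columns are taken in
    that order.  Gene ids of the form ``genome|gene`` supply the genome
    fields when the file has only query/subject/bit_score columns.
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    if columns is None:
        if raw.shape[1] >= 5:
            columns = dict(zip(HIT_COLUMNS, range(5)))
        else:
            columns = {"query": 0, "subject": 1, "bit_score": raw.shape[1] - 1}
    out = pd.DataFrame({name: raw[idx] for name, idx in columns.items()})
    for side in ("query", "subject"):
        if f"{side}_genome" not in out:
            out[f"{side}_genome"] = out[side].str.split("|").str[0]
    out["bit_score"] = out["bit_score"].astype(float)
    return out[HIT_COLUMNS]


def build_top_hit_lists(
    hits: pd.DataFrame,
    ingroup: set[str],
    outgroup: set[str],
    bit_score_min: float = 40.0,
    strict_superior: bool = True,
) -> TopHits:
    """Ranked in-group top-hit list per query, with out-group screening.

    Hits below ``bit_score_min`` are dropped.  For each query at most one
    subject per in-group genome is kept (highest score; ties broken by
    gene id), and only when its score exceeds the query's best out-group
    score (strictly by default).  The evidence flag is true when any
    out-group hit at or above the cutoff exists for the query.
    """
    ingroup, outgroup = set(ingroup), set(outgroup)
    known = ingroup | outgroup
    seen = set(hits["query_genome"]) | set(hits["subject_genome"])
    unknown = sorted(seen - known)
    if unknown:
        raise ValueError(f"genome id(s) not classified as in-group or out-group: {unknown}")

    hits = hits[hits["bit_score"] >= bit_score_min]
    genome_of = {}
    for col, gcol in (("query", "query_genome"), ("subject", "subject_genome")):
        genome_of.update(dict(zip(hits[col], hits[gcol])))

    best: dict[str, dict[str, str]] = {}
    outflag: dict[str, bool] = {}
    within: dict[str, set[str]] = {}
    best_out: dict[str, float] = {}
    out_rows = hits[hits["subject_genome"].isin(outgroup)]
    for q, grp in out_rows.groupby("query"):
        best_out[q] = float(grp["bit_score"].max())
        outflag[q] = True

    in_rows = hits[hits["subject_genome"].isin(ingroup)]
    for q, grp in in_rows.groupby("query"):
        qg = genome_of[q]
        cutoff = best_out.get(q, float("-inf"))
        lists: dict[str, tuple[float, str]] = {}
        for _, row in grp.iterrows():
            sg, subj, score = row["subject_genome"], row["subject"], row["bit_score"]
            if sg == qg:
                within.setdefault(q, set()).add(subj)
                continue
            ok = score > cutoff if strict_superior else score >= cutoff
            if not ok:
                continue
            cur = lists.get(sg)
            if cur is None or score > cur[0] or (score == cur[0] and subj < cur[1]):
                lists[sg] = (score, subj)
        best[q] = {sg: subj for sg, (score, subj) in lists.items()}
        outflag.setdefault(q, False)
    for q in outflag:
        best.setdefault(q, {})
        outflag.setdefault(q, False)
    return TopHits(best=best, genome_of=genome_of, outgroup_evidence=outflag, within_genome=within)


def _candidate_set(query: str, top: TopHits) -> frozenset[str]:
    return frozenset([query, *top.best.get(query, {}).values()])


def assemble_ortholog_sets(top: TopHits) -> tuple[list[frozenset[str]], list[list[frozenset[str]]]]:
    """Split candidate sets into consistent sets and inconsistent groups.

    A candidate set (a query's top-hit list plus the query itself) is
    consistent when every member's own candidate set is identical.
    Inconsistent candidate sets are grouped by shared membership
    (connected components) for consensus resolution.
    """
    consistent: set[frozenset[str]] = set()
    inconsistent: list[frozenset[str]] = []
    for query in sorted(top.best):
        cand = _candidate_set(query, top)
        if len(cand) < 2:
            continue
        if all(_candidate_set(m, top) == cand for m in cand):
            consistent.add(cand)
        else:
            inconsistent.append(cand)
    # group inconsistent sets by shared genes (union-find over genes)
    parent: dict[str, str] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for cand in inconsistent:
        genes = sorted(cand)
        for g in genes[1:]:
            union(genes[0], g)
    groups: dict[str, list[frozenset[str]]] = {}
    for cand in inconsistent:
        groups.setdefault(find(sorted(cand)[0]), []).append(cand)
    ordered = [sorted(v, key=sorted) for _, v in sorted(groups.items())]
    return sorted(consistent, key=sorted), ordered


def validate_paralogs(
    candidate: frozenset[str],
    nominations: int,
    top: TopHits,
) -> bool:
    """Accept a candidate paralog set under the two evidence criteria.

    (1) the identical set must have been reported at least twice, and
    (2) every paralog must be confirmed by its own genome's within-genome
    hit evidence (each paralog pair connected by a same-genome hit).
    """
    if nominations < 2:
        return False
    by_genome: dict[str, list[str]] = {}
    for gene in candidate:
        by_genome.setdefault(top.genome_of.get(gene, gene.split("|")[0]), []).append(gene)
    for genes in by_genome.values():
        if len(genes) < 2:
            continue
        for a in genes:
            for b in genes:
                if a != b and b not in top.within_genome.get(a, set()) and a not in top.within_genome.get(b, set()):
                    return False
    return True


def resolve_consensus_sets(
    groups: list[list[frozenset[str]]],
    top: TopHits,
    scores: dict[str, float] | None = None,
) -> list[OrthologSet]:
    """Majority-rule consensus orthologs from inconsistent set groups.

    Within each group the gene most frequently nominated per genome
    becomes the consensus ortholog; ties are broken by highest total bit
    score (when supplied) then lexicographic gene id.  Non-consensus
    genes are appended as paralogs only when the validation criteria
    hold for the full candidate set they came from.
    """
    scores = scores or {}
    out = []
    for gi, group in enumerate(groups):
        votes: dict[str, dict[str, int]] = {}
        for cand in group:
            for gene in cand:
                genome = top.genome_of.get(gene, gene.split("|")[0])
                votes.setdefault(genome, {}).setdefault(gene, 0)
                votes[genome][gene] += 1
        members: dict[str, list[str]] = {}
        for genome, tally in votes.items():
            winner = min(tally, key=lambda g: (-tally[g], -scores.get(g, 0.0), g))
            members[genome] = [winner]
        # validated paralogs from sets nominated >= twice
        counts: dict[frozenset[str], int] = {}
        for cand in group:
            counts[cand] = counts.get(cand, 0) + 1
        for cand, n in sorted(counts.items(), key=lambda kv: sorted(kv[0])):
            if validate_paralogs(cand, n, top):
                for gene in sorted(cand):
                    genome = top.genome_of.get(gene, gene.split("|")[0])
                    if gene not in members.setdefault(genome, []):
                        members[genome].append(gene)
        out.append(OrthologSet(family=f"consensus{gi:04d}", members=members, status="consensus"))
    return out


def _consistent_to_sets(consistent, top: TopHits, paralog_candidates=None) -> list[OrthologSet]:
    sets = []
    for fi, cand in enumerate(consistent):
        members: dict[str, list[str]] = {}
        for gene in sorted(cand):
            genome = top.genome_of.get(gene, gene.split("|")[0])
            members.setdefault(genome, []).append(gene)
        sets.append(OrthologSet(family=f"fam{fi:04d}", members=members, status="consistent"))
    return sets


def build_ortholog_table(top: TopHits, scores: dict[str, float] | None = None):
    """Full table procedure: consistent sets, then consensus resolution."""
    consistent, groups = assemble_ortholog_sets(top)
    consistent_sets = _consistent_to_sets(consistent, top)
    # attach validated paralogs that overlap a consistent set
    claimed = {g for s in consistent_sets for g in s.genes()}
    leftover_groups = []
    for group in groups:
        overlapping = [c for c in group if c & claimed]
        counts: dict[frozenset[str], int] = {}
        for cand in overlapping:
            counts[cand] = counts.get(cand, 0) + 1
        for cand, n in counts.items():
            if not validate_paralogs(cand, n, top):
                continue
            for s in consistent_sets:
                if cand & s.genes():
                    for gene in sorted(cand - s.genes()):
                        genome = top.genome_of.get(gene, gene.split("|")[0])
                        s.members.setdefault(genome, []).append(gene)
                    break
        rest = [c for c in group if not (c & claimed)]
        if rest:
            leftover_groups.append(rest)
    consensus_sets = resolve_consensus_sets(leftover_groups, top, scores)
    return consistent_sets, consensus_sets


def build_gene_state_matrix(
    ortholog_sets: list[OrthologSet],
    genomes: list[str],
    all_genes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Families x genomes copy-number matrix (0 = absent).

    Each cell counts the family's members (ortholog + validated
    paralogs) in that genome.  Genes assigned to no family become
    singleton families so gene gains stay countable; a gene assigned to
    two families is an error.
    """
    assigned: dict[str, str] = {}
    for s in ortholog_sets:
        for gene in s.genes():
            if gene in assigned and assigned[gene] != s.family:
                raise ValueError(f"gene {gene!r} assigned to families {assigned[gene]!r} and {s.family!r}")
            assigned[gene] = s.family
    rows = {}
    for s in ortholog_sets:
        rows[s.family] = {g: len(s.members.get(g, [])) for g in genomes}
    if all_genes:
        singletons = sorted(g for g in all_genes if g not in assigned)
        for gene in singletons:
            genome = all_genes[gene]
            if genome not in genomes:
                continue
            fam = f"singleton|{gene}"
            rows[fam] = dict.fromkeys(genomes, 0)
            rows[fam][genome] = 1
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=genomes).fillna(0).astype(int)
    return matrix.sort_index()


def write_gene_state_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="family")
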