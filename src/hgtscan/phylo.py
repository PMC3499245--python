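"""Phylogenetic verification of foreign calls.

Foreign transcripts with at least one significant metazoan hit are verified
on support-annotated trees.  "Clade" is read in the unrooted sense: one side
of an internal edge; supports live on edges.  Each focal transcript is
assigned to one of five groups:

1. monophyletic with Metazoa (or only metazoan hits in the search);
2. monophyly with Metazoa cannot be strongly rejected;
3. too few sequences to define a meaningful clade;
4. monophyly with Metazoa strongly rejected;
5. monophyletic with a single non-metazoan taxon.

"Strongly" means an edge support at or above a configurable threshold
``s_min`` (default 0.75; a calibration helper fits it against recorded
classifications).  An absent support never satisfies a >= s_min test.

The neighbour-joining bootstrap tree builder here is a lightweight stand-in
used to exercise the classifier on synthetic data; it is not a
maximum-likelihood method and carries no substitution model.
"""

from __future__ import annotations

import io as _io
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np

from hgtscan.taxa import FOREIGN_TAXA, METAZOA

GAP_CHARS = frozenset("-.")


class DegenerateAlignmentError(ValueError):
    """Trimming removed every column."""


class TooFewSequencesError(ValueError):
    """Fewer than four sequences: no meaningful unrooted tree."""


def trim_alignment(rows: Sequence[str]) -> list[str]:
    """Drop alignment columns where only one sequence has a residue.

    Columns with exactly one non-gap character are removed; relative column
    order is preserved.  Raises if nothing remains.
    """
    if len(rows) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("ragged alignment")
    keep = [
        j for j in range(ncol)
        if sum(r[j] not in GAP_CHARS for r in rows) != 1
    ]
    if not keep:
        raise DegenerateAlignmentError("all columns removed by trimming")
    return ["".join(r[j] for j in keep) for r in rows]


@dataclass
class PhyloAssessment:
    """Monophyly supports for one focal transcript plus its group verdict."""

    transcript_id: str
    supports: dict[str, float | None] = field(default_factory=dict)
    focal_supports: dict[str, float | None] = field(default_factory=dict)
    separation_support: float | None = None
    n_nonfocal_leaves: int = 0
    n_taxa_present: int = 0
    only_metazoan_hits: bool = False
    group: int | None = None
    s_min: float | None = None


def _edge_sides(tree: dendropy.Tree) -> list[tuple[frozenset[str], float | None]]:
    """All (leaf-set-on-one-side, support) pairs, one per tree edge.

    Each edge is reported once, by the leaf set of its head-node subtree;
    callers test a target set against both the side and its complement.
    """
    sides = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        leaves = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        sides.append((leaves, getattr(node, "support", None)))
    return sides


def _best_support(candidates: Iterable[float | None]) -> tuple[bool, float | None]:
    """(exists, best numeric support or None) over matching edges."""
    found = False
    best: float | None = None
    for s in candidates:
        found = True
        if s is not None and (best is None or s > best):
            best = s
    return found, best


def extract_monophyly_supports(
    tree: dendropy.Tree,
    focal_leaf: str,
    taxon_of: Callable[[str], str] | Mapping[str, str],
) -> PhyloAssessment:
    """Extract per-taxon monophyly supports for a focal leaf.

    For each taxon tau with at least one (non-focal) leaf, reports
    (a) the support of the best edge with exactly the tau leaves on one side
    (tau monophyly) and (b) the best edge with exactly {focal} + tau leaves
    on one side (focal-with-tau monophyly), evaluated on bipartitions of the
    unrooted tree; absent when no such edge exists or the matching edges
    carry no support.  Also records the best support of an edge separating
    the focal leaf from every metazoan leaf (the group-4 evidence).
    """
    if not callable(taxon_of):
        mapping = dict(taxon_of)
        taxon_of = mapping.__getitem__
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if focal_leaf not in labels:
        raise ValueError(f"focal leaf {focal_leaf!r} not in tree")
    all_leaves = frozenset(labels)
    nonfocal = all_leaves - {focal_leaf}
    by_taxon: dict[str, set[str]] = {}
    for leaf in nonfocal:
        by_taxon.setdefault(taxon_of(leaf), set()).add(leaf)

    sides = _edge_sides(tree)

    def matches(target: frozenset[str]):
        # a rooted Newick splits one unrooted edge into two root edges with
        # separate labels; the label as written annotates the clade beneath
        # it, so direct side matches take precedence over complements
        direct = [s for side, s in sides if side == target]
        if direct:
            return direct
        return [s for side, s in sides if (all_leaves - side) == target]

    assessment = PhyloAssessment(
        transcript_id=focal_leaf,
        n_nonfocal_leaves=len(nonfocal),
        n_taxa_present=len(by_taxon),
    )
    for taxon, leaves in by_taxon.items():
        target = frozenset(leaves)
        found, best = _best_support(matches(target))
        assessment.supports[taxon] = best if found else None
        found_f, best_f = _best_support(matches(target | {focal_leaf}))
        assessment.focal_supports[taxon] = best_f if found_f else None
    met_leaves = by_taxon.get(METAZOA, set())
    if met_leaves:
        # edges whose focal side excludes every metazoan leaf
        seps = []
        for side, support in sides:
            focal_side = side if focal_leaf in side else (all_leaves - side)
            if focal_side != all_leaves and not (focal_side & met_leaves):
                seps.append(support)
        _, assessment.separation_support = _best_support(seps)
    return assessment


def assign_group(
    assessment: PhyloAssessment,
    s_min: float = 0.75,
    min_nonfocal: int = 3,
) -> int:
    """Assign the five-group verdict; precedence 1, 3, 5, 4, 2.

    Group 5 (monophyly with one specific non-metazoan taxon) takes priority
    over the weaker group-4 statement (metazoan monophyly rejected); both
    require edge support >= s_min.  Absent supports never pass the test.
    """

    def ok(s: float | None) -> bool:
        return s is not None and s >= s_min

    group = None
    if assessment.only_metazoan_hits or ok(assessment.focal_supports.get(METAZOA)):
        group = 1
    elif (assessment.n_nonfocal_leaves < min_nonfocal
          or assessment.n_taxa_present < 2):
        group = 3
    elif any(ok(assessment.focal_supports.get(t)) for t in FOREIGN_TAXA):
        group = 5
    elif ok(assessment.separation_support):
        group = 4
    else:
        group = 2
    assessment.group = group
    assessment.s_min = s_min
    return group


def summarize_groups(
    assessments: Sequence[PhyloAssessment],
    n_without_metazoan: int = 0,
) -> dict:
    """Counts and percentages per group, plus the verified-foreign tally.

    ``n_without_metazoan`` is the number of foreign transcripts excluded from
    tree building because they had no significant metazoan hit; those count
    as verified foreign alongside groups 4 and 5.
    """
    counts = Counter(a.group for a in assessments)
    total = len(assessments)
    g45 = counts.get(4, 0) + counts.get(5, 0)
    combined_total = total + n_without_metazoan
    return {
        "counts": {g: counts.get(g, 0) for g in range(1, 6)},
        "percent": {
            g: 100.0 * counts.get(g, 0) / total if total else 0.0
            for g in range(1, 6)
        },
        "total": total,
        "verified_rate": g45 / total if total else 0.0,
        "combined_verified": g45 + n_without_metazoan,
        "combined_verified_rate": (
            (g45 + n_without_metazoan) / combined_total if combined_total else 0.0
        ),
    }


def calibrate_s_min(
    assessments: Sequence[PhyloAssessment],
    recorded_groups: Sequence[int],
    grid: Sequence[float] = tuple(np.round(np.arange(0.5, 1.0, 0.01), 2)),
    min_nonfocal: int = 3,
) -> float:
    """Fit s_min by maximising agreement with recorded group assignments."""
    best = (-1, 0.75)
    for s in grid:
        agree = sum(
            assign_group(a, s_min=s, min_nonfocal=min_nonfocal) == g
            for a, g in zip(assessments, recorded_groups)
        )
        if agree > best[0]:
            best = (agree, s)
    return best[1]


# ---------------------------------------------------------------------------
# Distance-tree stand-in (synthetic-test use only)

def _p_distance(a: str, b: str) -> float:
    diffs = comp = 0
    for x, y in zip(a, b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        comp += 1
        diffs += x != y
    return diffs / comp if comp else 0.75


def _nj_from_matrix(labels: Sequence[str], dm: np.ndarray) -> dendropy.Tree:
    # Biopython's NJ is a deterministic pure-python implementation
    from Bio import Phylo
    from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

    lower = [[float(dm[i, j]) for j in range(i + 1)] for i in range(len(labels))]
    bio_tree = DistanceTreeConstructor().nj(DistanceMatrix(list(labels), lower))
    for clade in bio_tree.find_clades():
        if not clade.is_terminal():
            clade.name = None  # drop Inner1.. labels
    buf = _io.StringIO()
    Phylo.write(bio_tree, buf, "newick")
    return dendropy.Tree.get(
        data=buf.getvalue(), schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )


def _bipartitions(tree: dendropy.Tree, anchor: str) -> set[frozenset[str]]:
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for side, _ in _edge_sides(tree):
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue  # trivial
        canon = side if anchor not in side else all_leaves - side
        out.add(canon)
    return out


def build_support_tree(
    sequences: Mapping[str, str],
    bootstrap_n: int = 100,
    rng: np.random.Generator | int | None = None,
) -> dendropy.Tree:
    """Neighbour-joining tree on pairwise p-distances with bootstrap supports.

    A deliberately simple stand-in for likelihood tree inference, used to
    exercise the downstream classifier on synthetic alignments.  Supports are
    bootstrap proportions in [0, 1] on internal edges; ``bootstrap_n = 0``
    leaves supports absent.  Deterministic under a fixed seed.
    """
    labels = sorted(sequences)
    if len(labels) < 4:
        raise TooFewSequencesError(
            f"need >= 4 sequences for an informative unrooted tree, got {len(labels)}"
        )
    rng = np.random.default_rng(rng)
    aln = np.array([list(sequences[l]) for l in labels])
    n = len(labels)

    def matrix(cols: np.ndarray) -> np.ndarray:
        dm = np.zeros((n, n))
        rows = ["".join(cols[i]) for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = _p_distance(rows[i], rows[j])
        return dm

    tree = _nj_from_matrix(labels, matrix(aln))
    anchor = labels[0]
    if bootstrap_n > 0:
        ncol = aln.shape[1]
        counts: Counter[frozenset[str]] = Counter()
        for _ in range(bootstrap_n):
            idx = rng.integers(0, ncol, size=ncol)
            boot = _nj_from_matrix(labels, matrix(aln[:, idx]))
            counts.update(_bipartitions(boot, anchor))
        all_leaves = frozenset(labels)
        for node in tree.preorder_node_iter():
            node.support = None
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            canon = side if anchor not in side else all_leaves - side
            node.support = counts.get(canon, 0) / bootstrap_n
    else:
        for node in tree.preorder_node_iter():
            node.support = None
    return tree
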