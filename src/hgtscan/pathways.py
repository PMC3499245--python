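"""EC assignment, six-colour coding, and pathway enrichment.

Transcripts are assigned the EC number(s) of their best EC-annotated match,
tagged by their HGT category (from the Swiss-Prot-style index h_S), and each
EC is coloured by the set of categories observed for it:

    {metazoan} -> green          {foreign} -> red       {indeterminate} -> grey
    {metazoan, foreign} or {metazoan, foreign, indeterminate} -> orange
    {foreign, indeterminate} -> pink      {metazoan, indeterminate} -> light-green

Foreign-contributing ECs (red, pink, orange) are then tested for pathway
over-representation with a hypergeometric upper tail against the universe of
ECs present in the dataset, with Benjamini-Hochberg correction across
pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from hgtscan.io import validate_ec

#: Colours with a foreign contribution, per the enrichment definition.
FOREIGN_COLORS = frozenset({"red", "pink", "orange"})

_COLOR_MAP = {
    frozenset({"metazoan"}): "green",
    frozenset({"foreign"}): "red",
    frozenset({"indeterminate"}): "grey",
    frozenset({"metazoan", "foreign"}): "orange",
    frozenset({"metazoan", "foreign", "indeterminate"}): "orange",
    frozenset({"foreign", "indeterminate"}): "pink",
    frozenset({"metazoan", "indeterminate"}): "light-green",
}


@dataclass(frozen=True)
class ECCall:
    """One transcript's EC assignment, tagged by HGT category."""

    transcript_id: str
    ec: str
    category: str


@dataclass
class PathwayResult:
    """Enrichment outcome for one pathway."""

    pathway_id: str
    name: str
    ecs_by_color: dict[str, int]
    k: int   # pathway ECs with foreign contribution
    n: int   # pathway ECs present in the universe
    K: int   # universe ECs with foreign contribution
    N: int   # universe size
    p: float
    q: float = float("nan")


def assign_ec(
    hits: pd.DataFrame,
    subject_ec: Mapping[str, Sequence[str]],
    categories: Mapping[str, str],
    eps: float = 1e-5,
    policy: str = "first-annotated",
) -> tuple[list[ECCall], dict]:
    """EC call(s) per transcript from its best EC-annotated match.

    ``hits`` is a hit table (qseqid, sseqid, bitscore, evalue); only hits
    with E <= eps count.  Under the default "first-annotated" policy the
    best-bitscore hit *among annotated subjects* provides the EC(s) — i.e.
    the first row after filtering to annotated matches; under
    "best-overall" an unannotated best hit drops the transcript.  Subjects
    carrying several ECs contribute all of them.  Returns the calls plus a
    tally of excluded transcripts and the fraction of foreign transcripts
    with an EC.
    """
    if policy not in ("first-annotated", "best-overall"):
        raise ValueError("policy must be 'first-annotated' or 'best-overall'")
    if subject_ec is None:
        raise ValueError("subject -> EC map required")
    calls: list[ECCall] = []
    n_unannotated = 0
    annotated_tids = set()
    sig = hits[hits["evalue"] <= eps]
    for tid, sub in sig.groupby("qseqid", sort=True):
        tid = str(tid)
        sub = sub.sort_values(["bitscore", "evalue"], ascending=[False, True],
                              kind="mergesort")
        chosen = None
        for r in sub.itertuples(index=False):
            ecs = subject_ec.get(str(r.sseqid))
            if ecs:
                chosen = ecs
                break
            if policy == "best-overall":
                break
        if not chosen:
            n_unannotated += 1
            continue
        annotated_tids.add(tid)
        cat = categories.get(tid)
        if cat is None:
            continue
        for ec in chosen:
            calls.append(ECCall(tid, validate_ec(ec), cat))
    foreign_ids = {t for t, c in categories.items() if c == "foreign"}
    n_foreign_annotated = len(annotated_tids & foreign_ids)
    stats = {
        "n_annotated": len(annotated_tids),
        "n_unannotated": n_unannotated,
        "foreign_annotated_fraction": (
            n_foreign_annotated / len(foreign_ids) if foreign_ids else 0.0
        ),
    }
    return calls, stats


def color_ec(calls: Sequence[ECCall]) -> dict[str, str]:
    """Colour every EC by the set of categories observed for it."""
    by_ec: dict[str, set[str]] = {}
    for call in calls:
        by_ec.setdefault(call.ec, set()).add(call.category)
    colors = {}
    for ec, cats in by_ec.items():
        if not cats:
            raise ValueError(f"EC {ec} has an empty category set")
        try:
            colors[ec] = _COLOR_MAP[frozenset(cats)]
        except KeyError:
            raise ValueError(f"unrecognised category set {cats!r} for EC {ec}") from None
    return colors


def enrich_pathways(
    colors: Mapping[str, str],
    pathway_map: Mapping[str, tuple[str, frozenset[str]]],
    alpha: float = 0.05,
) -> list[PathwayResult]:
    """Hypergeometric upper-tail enrichment of foreign-contributing ECs.

    Universe: the N unique ECs present in the dataset, of which K carry a
    foreign contribution (red, pink or orange).  Per pathway: n = pathway
    ECs in the universe, k = of those, foreign-contributing;
    p = P(X >= k), X ~ Hypergeometric(N, K, n); q = Benjamini-Hochberg over
    all tested pathways.  Pathways with n = 0 are excluded from testing.
    """
    universe = set(colors)
    foreign_set = {ec for ec, c in colors.items() if c in FOREIGN_COLORS}
    N, K = len(universe), len(foreign_set)
    results = []
    for pid, (name, ecs) in sorted(pathway_map.items()):
        present = ecs & universe
        n = len(present)
        if n == 0:
            continue
        k = len(present & foreign_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        by_color: dict[str, int] = {}
        for ec in present:
            by_color[colors[ec]] = by_color.get(colors[ec], 0) + 1
        results.append(PathwayResult(pid, name, by_color, k, n, K, N, min(p, 1.0)))
    if results:
        qs = multipletests([r.p for r in results], alpha=alpha, method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


def summarize_enzymes(
    calls: Sequence[ECCall],
    categories: Mapping[str, str],
    colors: Mapping[str, str] | None = None,
) -> dict:
    """Headline enzyme fractions.

    Reports the fraction of foreign transcripts with an EC call, and of the
    EC universe: the share only assigned to foreign transcripts (red), the
    share shared between foreign and metazoan (orange), and their sum — the
    total enzyme activities with a foreign contribution.
    """
    colors = color_ec(calls) if colors is None else colors
    foreign_ids = {t for t, c in categories.items() if c == "foreign"}
    annotated_foreign = {c.transcript_id for c in calls} & foreign_ids
    n_ec = len(colors)
    counts = {}
    for color in ("green", "red", "grey", "orange", "pink", "light-green"):
        counts[color] = sum(1 for c in colors.values() if c == color)
    foreign_only = counts["red"]
    shared = counts["orange"]
    contributing = counts["red"] + counts["pink"] + counts["orange"]
    return {
        "n_ec": n_ec,
        "color_counts": counts,
        "foreign_annotated_fraction": (
            len(annotated_foreign) / len(foreign_ids) if foreign_ids else 0.0
        ),
        "foreign_only_fraction": foreign_only / n_ec if n_ec else 0.0,
        "foreign_shared_fraction": shared / n_ec if n_ec else 0.0,
        "foreign_contribution_fraction": contributing / n_ec if n_ec else 0.0,
    }


def pathway_frame(results: Sequence[PathwayResult]) -> pd.DataFrame:
    """Per-pathway table sorted by q then p (Table-2 style)."""
    df = pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in results],
            "name": [r.name for r in results],
            "foreign_ec": [r.k for r in results],
            "total_ec": [r.n for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
        }
    )
    return df.sort_values(["q", "p", "pathway_id"], kind="mergesort").reset_index(drop=True)
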