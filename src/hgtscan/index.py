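"""HGT index computation and transcript classification.

Per transcript, homology hits against six taxon partitions are distilled into
a :class:`HitProfile` (best bitscore and minimum E-value per taxon, with the
top-k hits retained for audit).  The HGT index is

    h = max_tau S_tau  -  S_Metazoa        (tau over non-metazoan taxa)

with an absent side contributing 0 bits, so a transcript with no metazoan hit
at all gets h equal to its best non-metazoan bitscore.  Bitscores are
independent of database size, which is why h is preferred to the E-value
based alien index; the alien index is computed alongside for comparison.

Categories: foreign (h >= theta, default 30), metazoan (h <= 0),
indeterminate (0 < h < theta).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from hgtscan.taxa import FOREIGN_TAXA, METAZOA, TAXA, normalize_taxon

#: Default E-value cut defining the matched set.
DEFAULT_EPSILON = 1e-5
#: Default foreignness threshold on h, in bits.
DEFAULT_THETA = 30.0
#: Clamp constant in the alien-index formula.
DEFAULT_AI_CONSTANT = 1e-200

Category = Literal["metazoan", "indeterminate", "foreign"]


@dataclass
class HitProfile:
    """Per-transcript, per-taxon summary of homology hits.

    ``hits`` maps taxon -> list of (bitscore, evalue) pairs sorted best first
    (descending bitscore, ties by ascending E-value); at most ``top_k`` are
    retained per taxon.
    """

    transcript_id: str
    length: float | None = None
    hits: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def best_bitscore(self, taxon: str, epsilon: float | None = None) -> float | None:
        """Best bitscore for a taxon, or None if the taxon has no hit.

        With ``epsilon`` given, only hits with E <= epsilon count: the
        stricter-cut reanalysis recomputes bests from the retained hits
        rather than merely re-filtering transcripts.
        """
        rows = self.hits.get(taxon)
        if not rows:
            return None
        if epsilon is not None:
            rows = [r for r in rows if r[1] <= epsilon]
            if not rows:
                return None
        return max(r[0] for r in rows)

    def min_evalue(self, taxon: str) -> float | None:
        rows = self.hits.get(taxon)
        if not rows:
            return None
        return min(r[1] for r in rows)

    @property
    def taxa_with_hits(self) -> list[str]:
        return [t for t in TAXA if self.hits.get(t)]

    def has_any_hit(self) -> bool:
        return any(self.hits.get(t) for t in TAXA)


@dataclass
class HGTRecord:
    """Classification outcome for one transcript."""

    transcript_id: str
    h: float
    alien_index: float
    category: Category
    best_nonmetazoan_taxon: str | None
    has_significant_metazoan: bool
    database_tag: str = "U"
    length: float | None = None


class ProfileError(ValueError):
    """Contract violation on a hit profile."""


def build_profiles(
    hits: pd.DataFrame | Iterable,
    top_k: int = 5,
    epsilon: float = DEFAULT_EPSILON,
    lengths: Mapping[str, float] | None = None,
) -> tuple[list[HitProfile], int]:
    """Distil raw hits into per-transcript profiles and apply the matched-set filter.

    Parameters
    ----------
    hits
        DataFrame with columns (qseqid, taxon, bitscore, evalue) at least, or
        an iterable of objects with those attributes.
    top_k
        Hits retained per transcript and taxon (by descending bitscore,
        ties by ascending E-value).
    epsilon
        A transcript is retained only if its minimum E-value across all taxa
        is <= epsilon; excluded transcripts are tallied.
    lengths
        Optional transcript length lookup (bp), recorded on the profiles.

    Returns
    -------
    (profiles, n_excluded)
        Profiles of the matched set and the count of excluded transcripts.
    """
    if not isinstance(hits, pd.DataFrame):
        hits = pd.DataFrame(
            [
                (h.query_id, h.taxon, h.bitscore, h.evalue)
                for h in hits
            ],
            columns=["qseqid", "taxon", "bitscore", "evalue"],
        )
    profiles: list[HitProfile] = []
    n_excluded = 0
    if hits.empty:
        return profiles, 0
    hits = hits.copy()
    hits["taxon"] = hits["taxon"].map(normalize_taxon)
    hits = hits.sort_values(
        ["qseqid", "taxon", "bitscore", "evalue"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    topk = hits.groupby(["qseqid", "taxon"], sort=False).head(top_k)
    for tid, sub in topk.groupby("qseqid", sort=True):
        prof = HitProfile(
            transcript_id=str(tid),
            length=None if lengths is None else lengths.get(str(tid)),
            hits={
                taxon: list(zip(g["bitscore"].tolist(), g["evalue"].tolist()))
                for taxon, g in sub.groupby("taxon", sort=False)
            },
        )
        best_e = min(r[1] for rows in prof.hits.values() for r in rows)
        if best_e <= epsilon:
            profiles.append(prof)
        else:
            n_excluded += 1
    return profiles, n_excluded


def compute_h(profile: HitProfile, epsilon: float | None = None) -> float:
    """HGT index: best non-metazoan bitscore minus best metazoan bitscore.

    An absent side contributes 0 bits.  With ``epsilon`` set, per-taxon bests
    are recomputed using only hits with E <= epsilon.
    """
    if not profile.has_any_hit():
        raise ProfileError(f"profile {profile.transcript_id} has no hits")
    s_non = [
        s
        for t in FOREIGN_TAXA
        if (s := profile.best_bitscore(t, epsilon)) is not None
    ]
    s_met = profile.best_bitscore(METAZOA, epsilon)
    return (max(s_non) if s_non else 0.0) - (s_met if s_met is not None else 0.0)


def compute_alien_index(profile: HitProfile, c: float = DEFAULT_AI_CONSTANT) -> float:
    """Alien index: ln(E_Metazoa + c) - ln(E_best-non-metazoan + c).

    An absent E-value is treated as 1 (no evidence); the constant ``c``
    prevents the index diverging for E = 0.  Positive values indicate a
    foreign origin.
    """
    e_met = profile.min_evalue(METAZOA)
    e_non = [e for t in FOREIGN_TAXA if (e := profile.min_evalue(t)) is not None]
    e_met = 1.0 if e_met is None else e_met
    e_best_non = min(e_non) if e_non else 1.0
    if e_met < 0 or e_best_non < 0:
        raise ValueError("negative E-value")
    return math.log(e_met + c) - math.log(e_best_non + c)


def classify(h: float, theta: float = DEFAULT_THETA) -> Category:
    """Map an h value to its category; the h = theta boundary is foreign."""
    if not math.isfinite(h):
        raise ValueError("h must be finite")
    if h >= theta:
        return "foreign"
    if h <= 0:
        return "metazoan"
    return "indeterminate"


def attribute_source_taxon(
    profile: HitProfile, epsilon: float | None = None
) -> str | None:
    """Non-metazoan taxon with the maximal bitscore.

    Ties broken by lowest E-value, then by the fixed taxon order of
    :data:`hgtscan.taxa.FOREIGN_TAXA`.  Returns None when no non-metazoan
    taxon has a hit.
    """
    candidates = []
    for i, t in enumerate(FOREIGN_TAXA):
        s = profile.best_bitscore(t, epsilon)
        if s is None:
            continue
        rows = profile.hits[t]
        if epsilon is not None:
            rows = [r for r in rows if r[1] <= epsilon]
        e = min(r[1] for r in rows if r[0] == s)
        candidates.append((-s, e, i, t))
    if not candidates:
        return None
    return min(candidates)[3]


def evaluate_profiles(
    profiles: Sequence[HitProfile],
    theta: float = DEFAULT_THETA,
    epsilon: float = DEFAULT_EPSILON,
    database_tag: str = "U",
    ai_constant: float = DEFAULT_AI_CONSTANT,
) -> list[HGTRecord]:
    """Compute h, alien index and category for every profile.

    ``has_significant_metazoan`` is True when the metazoan minimum E-value is
    <= epsilon.
    """
    records = []
    for p in profiles:
        h = compute_h(p)
        cat = classify(h, theta)
        e_met = p.min_evalue(METAZOA)
        records.append(
            HGTRecord(
                transcript_id=p.transcript_id,
                h=h,
                alien_index=compute_alien_index(p, ai_constant),
                category=cat,
                best_nonmetazoan_taxon=attribute_source_taxon(p),
                has_significant_metazoan=e_met is not None and e_met <= epsilon,
                database_tag=database_tag,
                length=p.length,
            )
        )
    return records


@dataclass
class DatasetSummary:
    """Headline counts for one dataset at one threshold."""

    matched: int
    foreign: int
    foreign_fraction: float
    foreign_without_metazoan: int
    foreign_without_metazoan_fraction: float
    source_composition: dict[str, float]
    reanalysis: dict[float, tuple[int, int, float]] = field(default_factory=dict)
    """epsilon -> (matched, foreign, foreign fraction) with bests recomputed
    from hits passing the stricter cut."""


def summarize(
    records: Sequence[HGTRecord],
    profiles: Sequence[HitProfile],
    theta: float = DEFAULT_THETA,
    epsilon: float = DEFAULT_EPSILON,
    alt_epsilons: Sequence[float] = (1e-10, 1e-15),
) -> DatasetSummary:
    """Dataset-wide summary: foreign fraction, no-metazoan fraction, source mix,
    and the same at stricter E-value cuts.

    At a stricter cut, per-taxon bests are recomputed using only hits passing
    that cut (not merely re-filtering the matched set), transcripts with no
    remaining hit drop out of the matched set, and h is re-derived.
    """
    foreign = [r for r in records if r.category == "foreign"]
    n_no_met = sum(1 for r in foreign if not r.has_significant_metazoan)
    comp = Counter(
        r.best_nonmetazoan_taxon for r in foreign if r.best_nonmetazoan_taxon
    )
    total_attr = sum(comp.values())
    summary = DatasetSummary(
        matched=len(records),
        foreign=len(foreign),
        foreign_fraction=len(foreign) / len(records) if records else 0.0,
        foreign_without_metazoan=n_no_met,
        foreign_without_metazoan_fraction=n_no_met / len(foreign) if foreign else 0.0,
        source_composition={
            t: comp.get(t, 0) / total_attr if total_attr else 0.0
            for t in FOREIGN_TAXA
        },
    )
    for eps in alt_epsilons:
        n_matched = 0
        n_foreign = 0
        for p in profiles:
            bests = [
                s for t in TAXA if (s := p.best_bitscore(t, epsilon=eps)) is not None
            ]
            if not bests:
                continue
            n_matched += 1
            if compute_h(p, epsilon=eps) >= theta:
                n_foreign += 1
        summary.reanalysis[eps] = (
            n_matched,
            n_foreign,
            n_foreign / n_matched if n_matched else 0.0,
        )
    return summary


def crossref_gene_set(
    records: Sequence[HGTRecord],
    reference_hits: pd.DataFrame,
    epsilons: Sequence[float] = (1e-5, 1e-10, 1e-15),
) -> dict[float, tuple[float, float]]:
    """Fraction of foreign and of metazoan transcripts matching a reference gene set.

    ``reference_hits`` is a hit table (qseqid, evalue at least) of transcripts
    against an arbitrary reference set, e.g. known nuclear mitochondrial
    genes.  For each cut, returns (fraction of foreign transcripts with any
    reference match at E <= cut, same for metazoan transcripts).
    """
    out = {}
    foreign_ids = {r.transcript_id for r in records if r.category == "foreign"}
    met_ids = {r.transcript_id for r in records if r.category == "metazoan"}
    for eps in epsilons:
        if reference_hits.empty:
            out[eps] = (0.0, 0.0)
            continue
        matched = set(
            reference_hits.loc[reference_hits["evalue"] <= eps, "qseqid"].astype(str)
        )
        out[eps] = (
            len(foreign_ids & matched) / len(foreign_ids) if foreign_ids else 0.0,
            len(met_ids & matched) / len(met_ids) if met_ids else 0.0,
        )
    return out


def records_frame(records: Sequence[HGTRecord]) -> pd.DataFrame:
    """Records as a tidy DataFrame (one row per transcript)."""
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "length": [r.length for r in records],
            "h": [r.h for r in records],
            "alien_index": [r.alien_index for r in records],
            "category": [r.category for r in records],
            "source_taxon": [r.best_nonmetazoan_taxon for r in records],
            "has_significant_metazoan": [r.has_significant_metazoan for r in records],
            "database_tag": [r.database_tag for r in records],
        }
    )
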