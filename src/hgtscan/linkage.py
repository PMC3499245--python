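"""Transcript-to-genome alignment chaining and co-localisation.

To rule out contamination as the source of foreign transcripts, each
transcript's genome alignments are chained under four rules and the covered
fraction of the transcript computed.  Processing is in descending bitscore
(ties: ascending E-value, then ascending transcript start); a match is
accepted iff

1. E-value <= eps (default 1e-3);
2. its transcript interval overlaps no previously accepted match;
3. its alignment is longer than L_min bp (default 40, strict: a minimum
   exon length);
4. it lies on the same genomic contig as a previously accepted match, OR
   both it and some previously accepted match lie within D_end bp
   (default 1000, inclusive) of their contigs' ends (a maximum intron
   length constraint).  The first accepted match is exempt.

Covered bp is the sum of accepted transcript-interval lengths, divided by
transcript length.  A transcript is "on" a contig if an accepted match lies
on it; contigs carrying a foreign transcript are then scanned for metazoan
co-residents or foreign co-residents of a different source taxon.

Intervals are 0-based half-open internally; tabular inputs are 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomeMatch:
    """One transcript-vs-genome alignment (0-based half-open intervals)."""

    transcript_id: str
    contig_id: str
    t_start: int
    t_end: int
    c_start: int
    c_end: int
    strand: int
    evalue: float
    bitscore: float

    @property
    def alignment_length(self) -> int:
        return self.t_end - self.t_start


@dataclass
class CoverageResult:
    """Accepted chain and covered fraction for one transcript."""

    transcript_id: str
    transcript_length: int
    accepted: list[GenomeMatch] = field(default_factory=list)
    covered_bp: int = 0

    @property
    def coverage_fraction(self) -> float:
        return self.covered_bp / self.transcript_length if self.transcript_length else 0.0

    @property
    def contigs_on(self) -> frozenset[str]:
        return frozenset(m.contig_id for m in self.accepted)


def matches_from_frame(df: pd.DataFrame) -> list[GenomeMatch]:
    """Build matches from a 12-column hit table (1-based inclusive coords).

    Query = transcript, subject = genomic contig.  Minus-strand subject
    coordinates (sstart > send) are normalised with strand recorded.
    """
    out = []
    for r in df.itertuples(index=False):
        qs, qe = int(r.qstart), int(r.qend)
        if qs > qe:
            qs, qe = qe, qs
        ss, se = int(r.sstart), int(r.send)
        strand = 1
        if ss > se:
            ss, se = se, ss
            strand = -1
        out.append(
            GenomeMatch(str(r.qseqid), str(r.sseqid), qs - 1, qe, ss - 1, se,
                        strand, float(r.evalue), float(r.bitscore))
        )
    return out


class ContigLengthError(KeyError):
    """Contig length needed for the end-distance rule but unknown."""


def _near_end(m: GenomeMatch, contig_lengths: Mapping[str, int], d_end: int) -> bool:
    try:
        clen = contig_lengths[m.contig_id]
    except KeyError:
        raise ContigLengthError(
            f"length of contig {m.contig_id!r} unknown but needed for the "
            f"end-distance rule"
        ) from None
    # nearer contig end to nearer alignment end, inclusive
    return min(m.c_start, clen - m.c_end) <= d_end


def select_alignment_chain(
    matches: Sequence[GenomeMatch],
    transcript_length: int,
    contig_lengths: Mapping[str, int] | None = None,
    eps: float = 1e-3,
    l_min: int = 40,
    d_end: int = 1000,
    overlap_on: str = "transcript",
) -> CoverageResult:
    """Greedy chain selection under the four acceptance rules.

    The result is invariant to input row order: matches are sorted
    internally by descending bitscore, then ascending E-value, then
    ascending transcript start.  ``overlap_on`` selects whether rule 2 tests
    transcript ("transcript", default) or genomic ("genome") intervals.
    """
    if overlap_on not in ("transcript", "genome"):
        raise ValueError("overlap_on must be 'transcript' or 'genome'")
    tids = {m.transcript_id for m in matches}
    if len(tids) > 1:
        raise ValueError(f"matches span multiple transcripts: {sorted(tids)}")
    ordered = sorted(matches, key=lambda m: (-m.bitscore, m.evalue, m.t_start))
    tid = ordered[0].transcript_id if ordered else ""
    result = CoverageResult(tid, transcript_length)
    accepted: list[GenomeMatch] = []
    for m in ordered:
        if m.evalue > eps:
            continue
        if overlap_on == "transcript":
            clash = any(m.t_start < a.t_end and a.t_start < m.t_end for a in accepted)
        else:
            clash = any(
                a.contig_id == m.contig_id
                and m.c_start < a.c_end and a.c_start < m.c_end
                for a in accepted
            )
        if clash:
            continue
        if m.alignment_length <= l_min:
            continue
        if accepted:
            same_contig = any(a.contig_id == m.contig_id for a in accepted)
            if not same_contig:
                if contig_lengths is None:
                    raise ContigLengthError(
                        "contig lengths required for the end-distance rule"
                    )
                if not (_near_end(m, contig_lengths, d_end)
                        and any(_near_end(a, contig_lengths, d_end) for a in accepted)):
                    continue
        accepted.append(m)
    accepted.sort(key=lambda m: m.t_start)
    result.accepted = accepted
    result.covered_bp = sum(m.alignment_length for m in accepted)
    return result


def chain_all(
    df: pd.DataFrame,
    transcript_lengths: Mapping[str, int],
    contig_lengths: Mapping[str, int] | None = None,
    **kwargs,
) -> dict[str, CoverageResult]:
    """Run chain selection per transcript over a full alignment table.

    Transcripts with a known length but no alignment rows get an empty
    (zero-coverage) result.
    """
    results: dict[str, CoverageResult] = {
        tid: CoverageResult(tid, length)
        for tid, length in transcript_lengths.items()
    }
    if not df.empty:
        for tid, sub in df.groupby("qseqid", sort=False):
            tid = str(tid)
            if tid not in transcript_lengths:
                raise KeyError(f"transcript {tid!r} has alignments but no length")
            results[tid] = select_alignment_chain(
                matches_from_frame(sub), transcript_lengths[tid],
                contig_lengths, **kwargs,
            )
    return results


def coverage_histogram(
    results: Mapping[str, CoverageResult],
    categories: Mapping[str, str] | None = None,
    bins: np.ndarray | None = None,
    cut: float = 0.5,
) -> dict:
    """Histogram of coverage fractions and the fraction strictly above a cut.

    With ``categories`` (transcript -> category) the histogram and the
    above-cut fraction are also stratified per category.  The cut is a
    strict inequality (> cut).
    """
    bins = np.linspace(0, 1, 21) if bins is None else np.asarray(bins)
    fracs = {tid: r.coverage_fraction for tid, r in results.items()}

    def stats(tids):
        vals = np.array([fracs[t] for t in tids])
        if vals.size == 0:
            return {"n": 0, "counts": np.zeros(len(bins) - 1, int),
                    "fraction_above_cut": 0.0}
        counts, _ = np.histogram(vals, bins=bins)
        return {
            "n": int(vals.size),
            "counts": counts,
            "fraction_above_cut": float(np.mean(vals > cut)),
        }

    out = {"bins": bins, "cut": cut, "all": stats(list(fracs))}
    if categories is not None:
        by_cat: dict[str, list[str]] = {}
        for tid in fracs:
            if tid in categories:
                by_cat.setdefault(categories[tid], []).append(tid)
        out["by_category"] = {cat: stats(tids) for cat, tids in sorted(by_cat.items())}
    return out


def colocalization_report(
    results: Mapping[str, CoverageResult],
    categories: Mapping[str, str],
    source_taxa: Mapping[str, str | None],
) -> dict:
    """Per-contig co-residence counts and the global co-localisation fraction.

    For each contig carrying at least one foreign transcript, counts the
    metazoan transcripts on it and the foreign transcripts of a different
    source taxon.  The global fraction is the share of foreign transcripts
    sharing a contig with a metazoan transcript or a foreign transcript of
    another taxon — the signature that rules out contamination.
    """
    on_contig: dict[str, list[str]] = {}
    for tid, r in results.items():
        for contig in r.contigs_on:
            on_contig.setdefault(contig, []).append(tid)

    per_contig = {}
    colocated: set[str] = set()
    foreign_placed = [
        tid for tid, r in results.items()
        if categories.get(tid) == "foreign" and r.contigs_on
    ]
    for contig, tids in on_contig.items():
        foreign_here = [t for t in tids if categories.get(t) == "foreign"]
        if not foreign_here:
            continue
        met_here = [t for t in tids if categories.get(t) == "metazoan"]
        for f in foreign_here:
            n_other_taxon = sum(
                1 for g in foreign_here
                if g != f and source_taxa.get(g) != source_taxa.get(f)
            )
            if met_here or n_other_taxon:
                colocated.add(f)
        per_contig[contig] = {
            "n_foreign": len(foreign_here),
            "n_metazoan": len(met_here),
            "n_foreign_other_taxon": len(
                {source_taxa.get(t) for t in foreign_here}
            ) - 1 if foreign_here else 0,
        }
    return {
        "per_contig": per_contig,
        "n_foreign_placed": len(foreign_placed),
        "n_colocated": len(colocated),
        "colocalization_fraction": (
            len(colocated) / len(foreign_placed) if foreign_placed else 0.0
        ),
    }
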