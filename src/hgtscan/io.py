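"""Readers and writers for the standard input formats.

Handles 12-column tabular homology-search results (the de-facto tabular
output of local alignment search tools), FASTA transcript files, per-taxon
summary tables, Newick trees with branch supports, and pathway -> EC maps.
All text readers transparently accept gzip-compressed files.

Coordinate conventions: external files are 1-based inclusive; internal
intervals are 0-based half-open.
"""

from __future__ import annotations

import csv
import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

from hgtscan.taxa import TAXA, TaxonError, normalize_taxon

logger = logging.getLogger(__name__)

#: Column names of the 12-column tabular hit format.
HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class FormatError(ValueError):
    """Malformed input file."""


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


@dataclass
class RawHit:
    """One row of a tabular homology-search result, taxon-labelled."""

    query_id: str
    subject_id: str
    taxon: str
    percent_identity: float
    alignment_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float


def read_hits(path: str | Path, taxon: str | None = None) -> Iterator[RawHit]:
    """Stream hits from a 12-column tabular file.

    ``taxon`` labels every row; when None, a 13th column must carry the
    taxon label per row.  Query coordinates are normalised ascending;
    minus-strand subject coordinates are retained as given.  Rows with
    unparseable numeric fields are rejected and logged with their line
    number.
    """
    n = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            expected = 12 if taxon is not None else 13
            if len(fields) != expected:
                raise FormatError(
                    f"{path}: line {lineno}: expected {expected} tab-separated "
                    f"columns, found {len(fields)}"
                )
            row_taxon = normalize_taxon(taxon if taxon is not None else fields[12])
            try:
                pident = float(fields[2])
                length = int(fields[3])
                qs, qe = int(fields[6]), int(fields[7])
                ss, se = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError:
                logger.warning("%s: line %d: unparseable numeric field; row rejected",
                               path, lineno)
                continue
            if qs > qe:
                qs, qe = qe, qs
            yield RawHit(fields[0], fields[1], row_taxon, pident, length,
                         qs, qe, ss, se, evalue, bitscore)
            n += 1
    if n == 0:
        logger.warning("%s: no hits read", path)


def read_hits_frame(
    paths: Mapping[str, str | Path] | str | Path,
    taxon: str | None = None,
) -> pd.DataFrame:
    """Read one taxon-labelled file, or a {taxon: path} mapping of per-taxon
    files, into a DataFrame with :data:`HIT_COLUMNS` plus ``taxon``."""
    if isinstance(paths, (str, Path)):
        items = [(taxon, paths)]
    else:
        items = list(paths.items())
    frames = []
    for tax, path in items:
        rows = [
            (h.query_id, h.subject_id, h.percent_identity, h.alignment_length,
             0, 0, h.q_start, h.q_end, h.s_start, h.s_end, h.evalue, h.bitscore,
             h.taxon)
            for h in read_hits(path, taxon=tax)
        ]
        frames.append(pd.DataFrame(rows, columns=list(HIT_COLUMNS) + ["taxon"]))
    if not frames:
        return pd.DataFrame(columns=list(HIT_COLUMNS) + ["taxon"])
    return pd.concat(frames, ignore_index=True)


def write_hits_frame(df: pd.DataFrame, path: str | Path,
                     with_taxon_column: bool = True) -> None:
    """Write a hit DataFrame in the 12-column format (+ optional taxon column)."""
    cols = list(HIT_COLUMNS) + (["taxon"] if with_taxon_column else [])
    df.loc[:, cols].to_csv(path, sep="\t", header=False, index=False)


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    """Transcript lengths (bp) keyed by sequence id."""
    with _open_text(path) as fh:
        return {rec.id: len(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


# ---------------------------------------------------------------------------
# Summary tables (per-taxon best-hit exports)

@dataclass
class SummaryRow:
    """One transcript row of a per-taxon summary table.

    ``best`` maps taxon -> (max bitscore, min E-value); taxa without a hit
    are absent from the map (never stored as bitscore 0, so downstream rules
    can distinguish "no metazoan hit" from "weak metazoan hit").
    """

    transcript_id: str
    length: float | None = None
    best: dict[str, tuple[float, float]] = field(default_factory=dict)
    supports: dict[str, float] = field(default_factory=dict)
    focal_supports: dict[str, float] = field(default_factory=dict)
    recorded_h: float | None = None
    recorded_alien_index: float | None = None
    recorded_classification: str | None = None


#: Default column-name templates of the summary-table dialect; ``{taxon}``
#: is substituted with each canonical taxon name (case-insensitive match,
#: spelling variants accepted).
DEFAULT_DIALECT = {
    "transcript_id": "transcript_id",
    "length": "length",
    "bitscore": "{taxon}_bitscore",
    "evalue": "{taxon}_evalue",
    "support": "{taxon}_support",
    "focal_support": "{taxon}_focal_support",
    "h": "h",
    "alien_index": "alien_index",
    "classification": "classification",
}


def _find_column(columns: Sequence[str], name: str) -> str | None:
    # case-insensitive, spelling-variant-tolerant lookup
    wanted = name.lower()
    variants = {wanted}
    if "archaea" in wanted:
        variants.add(wanted.replace("archaea", "archea"))
    for col in columns:
        if col.lower() in variants:
            return col
    return None


def read_summary_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> list[SummaryRow]:
    """Read a per-taxon summary table (TSV/CSV export of a supplementary table).

    The dialect maps logical fields to column-name templates (see
    :data:`DEFAULT_DIALECT`).  Absent cells become "no hit"; rows with no
    taxon pair at all are dropped.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep=sep)
    id_col = _find_column(df.columns, dialect["transcript_id"])
    if id_col is None:
        raise FormatError(
            f"{path}: missing transcript id column "
            f"(expected {dialect['transcript_id']!r}); found {list(df.columns)}"
        )
    len_col = _find_column(df.columns, dialect["length"])
    taxon_cols = {}
    for taxon in TAXA:
        cols = {
            key: _find_column(df.columns, dialect[key].format(taxon=taxon))
            for key in ("bitscore", "evalue", "support", "focal_support")
        }
        taxon_cols[taxon] = cols
    if not any(c["bitscore"] for c in taxon_cols.values()):
        raise FormatError(
            f"{path}: no per-taxon bitscore columns found; expected columns "
            f"like {dialect['bitscore'].format(taxon=TAXA[0])!r}"
        )
    h_col = _find_column(df.columns, dialect["h"])
    ai_col = _find_column(df.columns, dialect["alien_index"])
    cls_col = _find_column(df.columns, dialect["classification"])

    rows = []
    for _, r in df.iterrows():
        row = SummaryRow(transcript_id=str(r[id_col]))
        if len_col is not None and pd.notna(r[len_col]):
            row.length = float(r[len_col])
        for taxon, cols in taxon_cols.items():
            if cols["bitscore"] is None:
                continue
            s = r[cols["bitscore"]]
            e = r[cols["evalue"]] if cols["evalue"] is not None else None
            if pd.notna(s):
                row.best[taxon] = (
                    float(s),
                    float(e) if e is not None and pd.notna(e) else 1.0,
                )
            if cols["support"] is not None and pd.notna(r[cols["support"]]):
                row.supports[taxon] = float(r[cols["support"]])
            if cols["focal_support"] is not None and pd.notna(r[cols["focal_support"]]):
                row.focal_supports[taxon] = float(r[cols["focal_support"]])
        if h_col is not None and pd.notna(r[h_col]):
            row.recorded_h = float(r[h_col])
        if ai_col is not None and pd.notna(r[ai_col]):
            row.recorded_alien_index = float(r[ai_col])
        if cls_col is not None and pd.notna(r[cls_col]):
            row.recorded_classification = str(r[cls_col])
        if row.best:
            rows.append(row)
    return rows


def profiles_from_summary(rows: Sequence[SummaryRow]):
    """Convert summary rows into :class:`~hgtscan.index.HitProfile` objects
    (one pseudo-hit per taxon, carrying the recorded best pair)."""
    from hgtscan.index import HitProfile

    return [
        HitProfile(
            transcript_id=row.transcript_id,
            length=row.length,
            hits={t: [(s, e)] for t, (s, e) in row.best.items()},
        )
        for row in rows
    ]


# ---------------------------------------------------------------------------
# Trees

def read_newick_supports(path_or_string: str | Path) -> dendropy.Tree:
    """Parse a Newick tree whose internal-node labels are branch supports.

    Numeric internal labels are stored as ``edge.head_node.support`` (float);
    unlabelled internal edges get support None ("absent", distinct from 0).
    """
    src = str(path_or_string)
    kwargs = dict(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if src.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=src, **kwargs)
    else:
        with _open_text(path_or_string) as fh:
            tree = dendropy.Tree.get(file=fh, **kwargs)
    for node in tree:
        support = None
        if not node.is_leaf() and node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        node.support = support
    return tree


def write_newick_supports(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree with node ``support`` attributes back as internal labels."""
    for node in tree:
        if not node.is_leaf() and getattr(node, "support", None) is not None:
            node.label = repr(node.support)
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, unquoted_underscores=True)


# ---------------------------------------------------------------------------
# Pathway / EC maps

_EC_RE = re.compile(r"^\d+\.(?:\d+|-)\.(?:\d+|-)\.(?:n?\d+|-)$")


def validate_ec(ec: str) -> str:
    """Validate an EC number: four dot-separated fields, trailing dashes allowed."""
    ec = ec.strip()
    if not _EC_RE.match(ec):
        raise FormatError(f"malformed EC number {ec!r}")
    fields = ec.split(".")
    seen_dash = False
    for f in fields[1:]:
        if f == "-":
            seen_dash = True
        elif seen_dash:
            raise FormatError(f"malformed EC number {ec!r}: non-trailing dash")
    return ec


def read_pathway_map(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a TSV of (pathway_id, pathway_name, ec) into
    pathway_id -> (name, EC set); duplicate rows are collapsed."""
    pathways: dict[str, tuple[str, set[str]]] = {}
    with _open_text(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 3:
                raise FormatError(
                    f"{path}: expected 3 columns (pathway_id, name, ec), got {row!r}"
                )
            pid, name, ec = row
            ec = validate_ec(ec)
            if pid in pathways:
                pathways[pid][1].add(ec)
            else:
                pathways[pid] = (name, {ec})
    return {pid: (name, frozenset(ecs)) for pid, (name, ecs) in pathways.items()}


def write_pathway_map(
    pathways: Mapping[str, tuple[str, frozenset[str]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for pid in sorted(pathways):
            name, ecs = pathways[pid]
            for ec in sorted(ecs):
                w.writerow([pid, name, ec])


def read_contig_lengths(path: str | Path) -> dict[str, int]:
    """TSV of (contig_id, length in bp)."""
    lengths = {}
    with _open_text(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            lengths[row[0]] = int(row[1])
    return lengths
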