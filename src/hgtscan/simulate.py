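"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the statistical structure of a taxon-partitioned
homology search over a transcriptome with a known foreign fraction:

* per-transcript best-hit bitscores per taxon follow a linear
  bits-per-aligned-bp model, S = rate * L + Normal(0, sd), with the
  own-lineage rate above the cross-lineage rate, so the HGT index scales
  with length the way real bitscores do;
* E-values are derived from bitscores through E = (m*n) * 2**(-S) with a
  fixed effective search-space size, keeping E and S consistent as in
  Karlin-Altschul statistics;
* transcript lengths are lognormal, calibrated to a short-read assembly
  (median ~341 bp, mean ~445 bp), truncated to the observed contig range;
* trees nest each foreign focal transcript inside its true source clade
  with Beta-distributed supports, with a controllable misleading-tree rate;
* the synthetic genome places transcripts as exon-split alignment chains on
  contigs, withholds placement for contaminants, and co-locates foreign
  with metazoan genes at a controllable rate;
* EC annotations follow a global null except in spiked pathways, which
  receive an elevated share of foreign-only enzymes.

One integer seed drives all four generators through independent substreams,
so outputs are bit-for-bit reproducible and component-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from hgtscan.io import HIT_COLUMNS
from hgtscan.taxa import FOREIGN_TAXA, METAZOA

#: Default donor-taxon mix (Eubacteria, Archaea, Fungi, Plantae, OtherEukaryotes),
#: mirroring the observed source composition of foreign transcripts.
DEFAULT_TAXON_MIX = (0.59, 0.01, 0.23, 0.06, 0.11)

_STREAMS = {"hits": 0, "trees": 1, "genome": 2, "ec": 3, "fasta": 4}


class ParameterError(ValueError):
    """Invalid simulation parameter."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic study.

    Score model: bitscore = rate * length + Normal(0, score_sd), with
    ``mu_own`` bits/bp for the own-lineage taxon and ``mu_cross`` for the
    others; E = search_space * 2**(-S).
    """

    n_transcripts: int = 5000
    foreign_fraction: float = 0.10
    taxon_mix: tuple[float, ...] = DEFAULT_TAXON_MIX
    length_log_mean: float = float(np.log(341.0))
    length_log_sd: float = 0.73
    length_range: tuple[int, int] = (118, 3674)
    mu_own: float = 0.6
    mu_cross: float = 0.3
    score_sd: float = 2.0
    search_space: float = 4e9
    dropout: float = 0.3
    support_alpha: float = 8.0
    support_beta: float = 2.0
    misleading_rate: float = 0.02
    contamination_rate: float = 0.10
    colocalization_rate: float = 0.80
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.foreign_fraction <= 1.0:
            raise ParameterError("foreign_fraction must lie in [0, 1]")
        mix = np.asarray(self.taxon_mix, dtype=float)
        if mix.size != len(FOREIGN_TAXA) or np.any(mix < 0):
            raise ParameterError(
                f"taxon_mix must be {len(FOREIGN_TAXA)} nonnegative weights"
            )
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ParameterError("taxon_mix must sum to 1")
        if not self.mu_own > self.mu_cross > 0:
            raise ParameterError("score model requires mu_own > mu_cross > 0")
        for name in ("dropout", "misleading_rate", "contamination_rate",
                     "colocalization_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.n_transcripts < 1:
            raise ParameterError("n_transcripts must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible substream for one generator component."""
        return np.random.default_rng([self.seed % (2**31), _STREAMS[stream]])

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=seed)


@dataclass
class TruthTable:
    """Ground truth of one simulated study."""

    origins: dict[str, str] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)
    placed: dict[str, bool] = field(default_factory=dict)
    spiked_pathways: set[str] = field(default_factory=set)

    @property
    def foreign_ids(self) -> list[str]:
        return [t for t, o in self.origins.items() if o != METAZOA]

    @property
    def metazoan_ids(self) -> list[str]:
        return [t for t, o in self.origins.items() if o == METAZOA]

    def categories(self) -> dict[str, str]:
        """True category per transcript (no indeterminate class in truth)."""
        return {
            t: ("foreign" if o != METAZOA else "metazoan")
            for t, o in self.origins.items()
        }


def _evalue(bitscore: np.ndarray, search_space: float) -> np.ndarray:
    # E = (m*n) * 2^-S; exponent in log-space to avoid premature overflow
    with np.errstate(over="ignore", under="ignore"):
        return search_space * np.exp2(-np.asarray(bitscore, dtype=float))


def generate_hit_table(params: SimParams) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate the taxon-partitioned hit table and its ground truth.

    Each transcript gets up to five hits for its own-lineage taxon and, with
    probability 1 - dropout, for each cross-lineage taxon; successive hits
    decay below the taxon's best score.  Deterministic under a fixed seed.
    """
    rng = params.rng("hits")
    n = params.n_transcripts
    tids = [f"tr{i:06d}" for i in range(n)]
    lengths = np.exp(
        rng.normal(params.length_log_mean, params.length_log_sd, size=n)
    )
    lengths = np.clip(np.round(lengths), *params.length_range).astype(int)
    is_foreign = rng.random(n) < params.foreign_fraction
    donor_idx = rng.choice(len(FOREIGN_TAXA), size=n, p=np.asarray(params.taxon_mix))
    origins = np.where(
        is_foreign, np.array(FOREIGN_TAXA, dtype=object)[donor_idx], METAZOA
    )

    truth = TruthTable(
        origins=dict(zip(tids, origins)),
        lengths=dict(zip(tids, lengths.tolist())),
    )
    # genomic placement: contaminants only among foreign transcripts
    contaminant = is_foreign & (rng.random(n) < params.contamination_rate)
    truth.placed = dict(zip(tids, (~contaminant).tolist()))

    rows = []
    taxa = (METAZOA,) + FOREIGN_TAXA
    for i, tid in enumerate(tids):
        L = int(lengths[i])
        own = origins[i]
        for taxon in taxa:
            if taxon == own:
                rate = params.mu_own
            else:
                if rng.random() < params.dropout:
                    continue
                rate = params.mu_cross
            n_hits = int(rng.integers(1, 6))
            best = rate * L + rng.normal(0.0, params.score_sd)
            # subsequent hits decay below the best one
            decays = np.concatenate(
                [[0.0], np.cumsum(rng.exponential(0.05 * best + 1.0, n_hits - 1))]
            )
            scores = np.maximum(best - decays, 25.0)
            evals = _evalue(scores, params.search_space)
            for j in range(n_hits):
                rows.append((
                    tid,
                    f"{taxon[:3].lower()}|{i}|{j}",
                    round(float(rng.uniform(35, 98)), 1),
                    max(L // 3, 20),
                    0, 0,
                    1, L, 1, max(L // 3, 20),
                    float(evals[j]),
                    round(float(scores[j]), 1),
                    taxon,
                ))
    table = pd.DataFrame(rows, columns=list(HIT_COLUMNS) + ["taxon"])
    return table, truth


def taxon_of_leaf(label: str) -> str:
    """Taxon of a simulated tree leaf (labels are '<taxon>|<k>')."""
    return label.split("|", 1)[0]


def generate_trees(
    truth: TruthTable,
    params: SimParams,
    transcripts: Sequence[str] | None = None,
    n_group3: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Newick trees with supports for foreign transcripts, plus a support table.

    Each focal transcript is nested inside its true source-taxon clade with
    Beta(support_alpha, support_beta) supports; with probability
    ``misleading_rate`` the focal leaf is regrafted into the metazoan clade
    instead.  The first ``n_group3`` trees are generated with only two
    non-focal leaves (too few for a meaningful clade).  Returns
    {transcript_id: newick} plus a per-taxon support table with columns
    (transcript_id, taxon, support, focal_support, misleading).
    """
    rng = params.rng("trees")
    if transcripts is None:
        transcripts = truth.foreign_ids
    trees: dict[str, str] = {}
    records = []

    def beta() -> float:
        return round(float(rng.beta(params.support_alpha, params.support_beta)), 3)

    for idx, tid in enumerate(transcripts):
        origin = truth.origins[tid]
        if origin == METAZOA:
            continue
        if idx < n_group3:
            # deliberately undersampled tree: two non-focal leaves
            newick = f"(({METAZOA}|0:1,{tid}:1):1,{origin}|0:1);"
            trees[tid] = newick
            records.append((tid, origin, None, None, False))
            continue
        misleading = bool(rng.random() < params.misleading_rate)
        s_origin, s_focal, s_met = beta(), beta(), beta()
        others = [t for t in FOREIGN_TAXA if t != origin]
        extra = str(rng.choice(others))
        s_extra = beta()
        o1, o2 = f"{origin}|0", f"{origin}|1"
        m1, m2 = f"{METAZOA}|0", f"{METAZOA}|1"
        x1, x2 = f"{extra}|0", f"{extra}|1"
        if not misleading:
            # focal nested in its true source clade
            newick = (
                f"((({o1}:1,{o2}:1){s_origin}:1,{tid}:1){s_focal}:1,"
                f"({m1}:1,{m2}:1){s_met}:1,({x1}:1,{x2}:1){s_extra}:1);"
            )
        else:
            # focal regrafted into the metazoan clade
            newick = (
                f"((({m1}:1,{m2}:1){s_met}:1,{tid}:1){s_focal}:1,"
                f"({o1}:1,{o2}:1){s_origin}:1,({x1}:1,{x2}:1){s_extra}:1);"
            )
        trees[tid] = newick
        with_taxon = METAZOA if misleading else origin
        for taxon, s_mono in ((origin, s_origin), (METAZOA, s_met), (extra, s_extra)):
            records.append((
                tid, taxon,
                s_mono,
                s_focal if taxon == with_taxon else None,
                misleading,
            ))
    table = pd.DataFrame(
        records,
        columns=["transcript_id", "taxon", "support", "focal_support", "misleading"],
    )
    return trees, table


def generate_genome(
    truth: TruthTable,
    params: SimParams,
    two_contig_rate: float = 0.05,
) -> tuple[dict[str, int], pd.DataFrame, dict[str, dict]]:
    """Synthetic draft genome: contig lengths, alignment table, linkage truth.

    Placed transcripts are split into 1-5 exon-like segments (each >= 41 bp)
    tiling the whole transcript, separated by intron gaps on the contig;
    contaminants get no rows.  A placed foreign transcript shares its contig
    with a metazoan transcript with probability ``colocalization_rate``;
    with probability ``two_contig_rate`` a multi-exon transcript is split
    across two contigs with the break-side segments within 1000 bp of the
    contig ends (exercising the maximum-intron rule).
    """
    rng = params.rng("genome")
    contig_lengths: dict[str, int] = {}
    rows: list[tuple] = []
    linkage_truth: dict[str, dict] = {}
    n_contigs = 0

    def new_contig() -> str:
        nonlocal n_contigs
        n_contigs += 1
        return f"ctg{n_contigs:05d}"

    def split_exons(L: int) -> list[int]:
        # partition L into k parts, each at least 41 bp (strictly > 40)
        k_max = max(1, min(5, L // 41))
        k = int(rng.integers(1, k_max + 1))
        if k == 1:
            return [L]
        extra = L - 41 * k
        cuts = np.sort(rng.integers(0, extra + 1, size=k - 1))
        parts = np.diff(np.concatenate([[0], cuts, [extra]])) + 41
        return [int(p) for p in parts]

    def lay_out(tid: str, contigs: list[tuple[str, int]], exons: list[int],
                split_at: int | None) -> None:
        """Place exons on one contig, or across two with terminal segments
        near the break ends.  ``contigs`` entries are (id, current offset)."""
        t_pos = 0
        placements: list[tuple[str, int, int, int, int]] = []
        for e_idx, ex in enumerate(exons):
            which = 0 if split_at is None or e_idx < split_at else 1
            cid, offset = contigs[which]
            c_start = offset
            placements.append((cid, t_pos + 1, t_pos + ex, c_start + 1, c_start + ex))
            contigs[which] = (cid, c_start + ex + int(rng.integers(50, 501)))
            t_pos += ex
        for cid, ts, te, cs, ce in placements:
            exon_len = te - ts + 1
            score = round(2.0 * exon_len, 1)
            rows.append((tid, cid, round(float(rng.uniform(97, 100)), 1), exon_len,
                         0, 0, ts, te, cs, ce, 1e-30, score))

    # pair placed foreign transcripts with metazoan co-residents
    placed_foreign = [t for t in truth.foreign_ids if truth.placed[t]]
    placed_met = [t for t in truth.metazoan_ids if truth.placed.get(t, True)]
    rng.shuffle(placed_foreign)
    met_pool = list(placed_met)
    rng.shuffle(met_pool)

    plan: list[tuple[list[str], bool]] = []  # (transcripts on one contig group, coloc)
    for tid in placed_foreign:
        if met_pool and rng.random() < params.colocalization_rate:
            plan.append(([tid, met_pool.pop()], True))
        else:
            plan.append(([tid], False))
    for tid in met_pool:
        plan.append(([tid], False))

    for group, coloc in plan:
        use_two = (
            not coloc
            and rng.random() < two_contig_rate
            and truth.lengths[group[0]] >= 82
        )
        margin = int(rng.integers(200, 1001))
        if use_two:
            # one exon per contig, each within 1000 bp of its contig's
            # break-side end, exercising the maximum-intron rule
            tid = group[0]
            L = truth.lengths[tid]
            cut = int(rng.integers(41, L - 40))
            exons = [cut, L - cut]
            cid_a, cid_b = new_contig(), new_contig()
            # exon 1 ends just short of contig A's end; exon 2 starts just
            # after contig B's start
            a_start = min(margin, 900)
            contig_lengths[cid_a] = a_start + exons[0] + int(rng.integers(50, 500))
            b_start = int(rng.integers(50, 900))
            contig_state = [(cid_a, a_start), (cid_b, b_start)]
            lay_out(tid, contig_state, exons, split_at=1)
            contig_lengths[cid_b] = contig_state[1][1] + 3000
            linkage_truth[tid] = {
                "coverage": 1.0,
                "contigs": {cid_a, cid_b},
                "colocated": False,
            }
            continue
        cid_a = new_contig()
        offset = margin
        for tid in group:
            exons = split_exons(truth.lengths[tid])
            contig_state = [(cid_a, offset)]
            lay_out(tid, contig_state, exons, split_at=None)
            offset = contig_state[0][1] + int(rng.integers(500, 1500))
            linkage_truth[tid] = {
                "coverage": 1.0,
                "contigs": {cid_a},
                "colocated": coloc,
            }
        contig_lengths[cid_a] = offset + margin

    for tid, placed in truth.placed.items():
        if not placed:
            linkage_truth[tid] = {"coverage": 0.0, "contigs": set(), "colocated": False}

    table = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return contig_lengths, table, linkage_truth


def generate_pathway_map(
    rng: np.random.Generator | int | None = None,
    n_pathways: int = 20,
    ecs_per_pathway: tuple[int, int] = (6, 14),
) -> dict[str, tuple[str, frozenset[str]]]:
    """A random pathway -> EC map with disjoint EC memberships."""
    rng = np.random.default_rng(rng)
    pathways = {}
    counter = 0
    for p in range(n_pathways):
        n_ec = int(rng.integers(*ecs_per_pathway))
        ecs = set()
        for _ in range(n_ec):
            counter += 1
            ecs.add(f"{int(rng.integers(1, 7))}.{int(rng.integers(1, 20))}."
                    f"{int(rng.integers(1, 30))}.{counter}")
        pathways[f"path{p:03d}"] = (f"Pathway {p}", frozenset(ecs))
    return pathways


def generate_ec_annotations(
    truth: TruthTable,
    pathway_map: Mapping[str, tuple[str, frozenset[str]]],
    spike: Iterable[str] = (),
    params: SimParams | None = None,
    spike_share: float = 0.9,
    calls_per_ec: tuple[int, int] = (1, 3),
) -> pd.DataFrame:
    """EC call table with optional spiked-in enriched pathways.

    Under the null every EC draws its transcripts uniformly from the whole
    transcriptome, so its category mix follows the global foreign fraction;
    ECs of spiked pathways draw each transcript from the foreign pool with
    probability ``spike_share`` instead.  Returns a table with columns
    (transcript_id, ec, category); deterministic under the shared seed.
    """
    params = params or SimParams()
    spike = set(spike)
    unknown = spike - set(pathway_map)
    if unknown:
        raise ParameterError(f"spiked pathways absent from map: {sorted(unknown)}")
    rng = params.rng("ec")
    spiked_ecs = set()
    for pid in spike:
        spiked_ecs |= set(pathway_map[pid][1])
    truth.spiked_pathways = spike

    all_ids = list(truth.origins)
    foreign_ids = truth.foreign_ids
    cats = truth.categories()
    rows = []
    all_ecs = sorted({ec for _, ecs in pathway_map.values() for ec in ecs})
    for ec in all_ecs:
        m = int(rng.integers(calls_per_ec[0], calls_per_ec[1] + 1))
        for _ in range(m):
            if ec in spiked_ecs and foreign_ids and rng.random() < spike_share:
                tid = str(rng.choice(foreign_ids))
            else:
                tid = str(rng.choice(all_ids))
            rows.append((tid, ec, cats[tid]))
    return pd.DataFrame(rows, columns=["transcript_id", "ec", "category"]).drop_duplicates(
        ignore_index=True
    )


def random_fasta(truth: TruthTable, params: SimParams) -> str:
    """Dummy transcript sequences (IDs match the tables; composition is random)."""
    rng = params.rng("fasta")
    parts = []
    bases = np.array(list("ACGT"))
    for tid in truth.origins:
        seq = "".join(rng.choice(bases, size=truth.lengths[tid]))
        parts.append(f">{tid}\n{seq}\n")
    return "".join(parts)


def write_simulation(
    out_dir: str | Path,
    params: SimParams,
    spike: Iterable[str] = (),
    pathway_map: Mapping[str, tuple[str, frozenset[str]]] | None = None,
) -> dict[str, Path]:
    """Run all four generators and write their outputs under ``out_dir``."""
    from hgtscan.io import write_hits_frame, write_pathway_map

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hits, truth = generate_hit_table(params)
    trees, support_table = generate_trees(truth, params)
    contig_lengths, alignments, _ = generate_genome(truth, params)
    if pathway_map is None:
        pathway_map = generate_pathway_map(params.rng("ec").integers(2**31))
    ec_calls = generate_ec_annotations(truth, pathway_map, spike, params)

    paths = {}
    paths["hits"] = out / "hits.tsv"
    write_hits_frame(hits, paths["hits"])
    paths["truth"] = out / "truth.tsv"
    pd.DataFrame(
        {
            "transcript_id": list(truth.origins),
            "origin": list(truth.origins.values()),
            "length": [truth.lengths[t] for t in truth.origins],
            "placed": [truth.placed[t] for t in truth.origins],
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    paths["trees"] = out / "trees.nwk"
    with open(paths["trees"], "w") as fh:
        for tid in sorted(trees):
            fh.write(trees[tid] + "\n")
    paths["supports"] = out / "supports.tsv"
    support_table.to_csv(paths["supports"], sep="\t", index=False)
    paths["contigs"] = out / "contig_lengths.tsv"
    pd.Series(contig_lengths).rename_axis("contig_id").rename("length").to_csv(
        paths["contigs"], sep="\t", header=False
    )
    paths["alignments"] = out / "genome_alignments.tsv"
    alignments.to_csv(paths["alignments"], sep="\t", header=False, index=False)
    paths["pathways"] = out / "pathway_map.tsv"
    write_pathway_map(pathway_map, paths["pathways"])
    paths["ec_calls"] = out / "ec_calls.tsv"
    ec_calls.to_csv(paths["ec_calls"], sep="\t", index=False)
    paths["fasta"] = out / "transcripts.fasta"
    paths["fasta"].write_text(random_fasta(truth, params))
    return paths
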