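"""Chromatin-state assignment and state-transition enrichment.

Given histone-mark interval tracks (BED, one file per mark per sample
group) and a gene model, each gene in each sample group receives one of
four chromatin states -- ``active``, ``poised``, ``repressed`` or
``no_signal`` -- from an ordered, user-overridable rule table evaluated on
which marks overlap the gene's promoter, gene body and (optional) enhancer
regions.  Comparing two sample groups yields state-transition groups, e.g.
(poised -> active); genes sharing a transition form the edges of a
transition graph, and each edge is subjected to over-representation
analysis against a gene-set collection.

Coordinates are BED-style throughout: 0-based, half-open.
"""

from __future__ import annotations

import bisect
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .enrich import EnrichmentRecord, adjust_records, ora
from .geneset import GeneSetCollection, harmonize

logger = logging.getLogger(__name__)

STATES = ("active", "poised", "repressed", "no_signal")

#: Histone marks the default rule table understands.
DEFAULT_MARKS = frozenset({"H3K4me3", "H3K9me3", "H3K27ac", "H3K27me3", "H3K36me3"})

#: Promoter window around the TSS (upstream, downstream), in bp.
DEFAULT_PROMOTER_UP = 2000
DEFAULT_PROMOTER_DOWN = 500

Interval = tuple[str, int, int]


# ---------------------------------------------------------------------------
# BED input


class BedFormatError(ValueError):
    pass


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort intervals and merge any that overlap or abut within a chromosome."""
    merged: list[Interval] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def read_bed(path: str | Path) -> list[Interval]:
    """Read the first three columns of a BED file as merged intervals.

    Extra columns are ignored; ``track``/``browser``/comment lines are
    skipped.  Chromosome names are not checked against any reference.
    """
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedFormatError(f"{path}: line {lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise BedFormatError(
                    f"{path}: line {lineno}: start {start} >= end {end} (0-based half-open)"
                )
            intervals.append((chrom, start, end))
    return merge_intervals(intervals)


class _IntervalIndex:
    """Overlap queries against merged, sorted intervals via bisect."""

    def __init__(self, intervals: Iterable[Interval]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, start, end in merge_intervals(intervals):
            starts, ends = self._by_chrom.setdefault(chrom, ([], []))
            starts.append(start)
            ends.append(end)

    def overlaps(self, chrom: str, start: int, end: int, min_bp: int = 1) -> bool:
        if chrom not in self._by_chrom or start >= end:
            return False
        starts, ends = self._by_chrom[chrom]
        # candidate intervals are those starting before `end`
        i = bisect.bisect_left(starts, end)
        for j in range(i - 1, -1, -1):
            ov = min(end, ends[j]) - max(start, starts[j])
            if ov >= min_bp:
                return True
            if ends[j] <= start:
                break  # merged intervals are disjoint; earlier ones end even sooner
        return False


# ---------------------------------------------------------------------------
# Gene model


@dataclass
class GeneModel:
    """Gene coordinates used to derive promoter/body/enhancer regions.

    ``tss``/``tes`` are 0-based; on the minus strand tss > tes is typical.
    Enhancers are optional half-open intervals anywhere in the genome.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    enhancers: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.tss == self.tes:
            raise ValueError(f"{self.gene_id}: tss == tes")
        for chrom, start, end in self.enhancers:
            if start >= end:
                raise ValueError(f"{self.gene_id}: malformed enhancer ({chrom},{start},{end})")


def gene_regions(
    gene: GeneModel,
    promoter_up: int = DEFAULT_PROMOTER_UP,
    promoter_down: int = DEFAULT_PROMOTER_DOWN,
) -> dict[str, list[Interval]]:
    """Promoter, gene-body and enhancer intervals for one gene.

    The promoter spans ``promoter_up`` bp upstream to ``promoter_down`` bp
    downstream of the TSS in transcription direction (mirrored on the minus
    strand) and is clipped at coordinate 0.  The body spans TSS to TES.
    """
    if promoter_up < 0 or promoter_down < 0:
        raise ValueError("promoter window sizes must be >= 0")
    if gene.strand == "+":
        p_start, p_end = gene.tss - promoter_up, gene.tss + promoter_down
    else:
        p_start, p_end = gene.tss - promoter_down, gene.tss + promoter_up
    p_start = max(0, p_start)
    regions: dict[str, list[Interval]] = {
        "promoter": [(gene.chrom, p_start, p_end)] if p_start < p_end else [],
        "body": [(gene.chrom, min(gene.tss, gene.tes), max(gene.tss, gene.tes))],
    }
    if gene.enhancers:
        regions["enhancer"] = list(gene.enhancers)
    return regions


def read_gene_model(path: str | Path) -> list[GeneModel]:
    """Read a 6-column gene model TSV.

    Columns: gene_id, chrom, strand, tss, tes, enhancers (semicolon-joined
    ``chrom:start-end`` entries, may be empty).  A header line starting with
    ``gene_id`` is tolerated.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("gene_id"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}: line {lineno}: expected >= 5 columns")
            enhancers: list[Interval] = []
            if len(fields) >= 6 and fields[5].strip():
                for token in fields[5].split(";"):
                    chrom, span = token.split(":")
                    start, end = span.split("-")
                    enhancers.append((chrom, int(start), int(end)))
            genes.append(
                GeneModel(
                    gene_id=fields[0].strip(),
                    chrom=fields[1].strip(),
                    strand=fields[2].strip(),
                    tss=int(fields[3]),
                    tes=int(fields[4]),
                    enhancers=enhancers,
                )
            )
    return genes


def write_gene_model(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\ttes\tenhancers\n")
        for g in genes:
            enh = ";".join(f"{c}:{s}-{e}" for c, s, e in g.enhancers)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tes}\t{enh}\n")


# ---------------------------------------------------------------------------
# Mark tracks and the rule table


@dataclass
class MarkTrack:
    """One histone mark's peak intervals for one sample group."""

    mark_name: str
    sample_group: str
    intervals: list[Interval]

    def __post_init__(self) -> None:
        self._index = _IntervalIndex(self.intervals)

    def overlaps(self, chrom: str, start: int, end: int, min_bp: int = 1) -> bool:
        return self._index.overlaps(chrom, start, end, min_bp)


@dataclass(frozen=True)
class Rule:
    """One rule of the state-assignment table, in conjunctive normal form.

    ``requires`` is a list of clauses; each clause is a tuple of
    ``(region, mark)`` alternatives.  The rule fires when every clause has
    at least one alternative whose mark is present in that region.  An
    empty ``requires`` always fires (the fall-through rule).
    """

    state: str
    requires: tuple[tuple[tuple[str, str], ...], ...] = ()

    def matches(self, evidence: Mapping[str, frozenset[str]]) -> bool:
        return all(
            any(mark in evidence.get(region, frozenset()) for region, mark in clause)
            for clause in self.requires
        )


def default_rule_table() -> list[Rule]:
    """The ordered default rule table (first match wins).

    Encodes the canonical bivalent/active/repressed logic of the five
    default marks: a promoter with both H3K4me3 and H3K27me3 is poised
    (bivalent); H3K4me3 with activating evidence (promoter/enhancer
    H3K27ac or transcribed-body H3K36me3), or alone, is active; repressive
    marks without H3K4me3 mean repressed; anything else is no_signal.
    Enhancer evidence can only add to "active"; a gene without enhancer
    annotation is never penalized for it.
    """
    return [
        Rule("poised", ((("promoter", "H3K4me3"),), (("promoter", "H3K27me3"),))),
        Rule(
            "active",
            (
                (("promoter", "H3K4me3"),),
                (("promoter", "H3K27ac"), ("enhancer", "H3K27ac"), ("body", "H3K36me3")),
            ),
        ),
        Rule("active", ((("promoter", "H3K4me3"),),)),
        Rule(
            "repressed",
            (
                (
                    ("promoter", "H3K27me3"),
                    ("body", "H3K27me3"),
                    ("promoter", "H3K9me3"),
                    ("body", "H3K9me3"),
                ),
            ),
        ),
        Rule("no_signal"),
    ]


def rules_from_config(spec: Sequence[Mapping]) -> list[Rule]:
    """Build a rule table from a YAML/JSON-friendly list of dicts.

    Each entry: ``{"state": ..., "requires": [[["promoter", "H3K4me3"], ...], ...]}``.
    """
    rules = []
    for entry in spec:
        if entry["state"] not in STATES:
            raise ValueError(f"unknown state {entry['state']!r}")
        requires = tuple(
            tuple((region, mark) for region, mark in clause) for clause in entry.get("requires", [])
        )
        rules.append(Rule(entry["state"], requires))
    return rules


@dataclass
class ChromatinCall:
    """The chromatin state assigned to one gene in one sample group."""

    gene_id: str
    sample_group: str
    state: str
    evidence: dict[str, frozenset[str]] = field(default_factory=dict)


def assign_state(
    gene: GeneModel,
    tracks: Sequence[MarkTrack],
    rules: Sequence[Rule] | None = None,
    promoter_up: int = DEFAULT_PROMOTER_UP,
    promoter_down: int = DEFAULT_PROMOTER_DOWN,
    min_overlap_bp: int = 1,
    vocabulary: frozenset[str] = DEFAULT_MARKS,
) -> ChromatinCall:
    """Assign one chromatin state to ``gene`` from one group's mark tracks.

    A mark is "present" in a region iff any of its intervals overlaps the
    region by at least ``min_overlap_bp``.  The first matching rule in the
    ordered table decides the state; the default table ends in a
    fall-through ``no_signal`` rule, so assignment is total.
    """
    if rules is None:
        rules = default_rule_table()
    groups = {t.sample_group for t in tracks}
    if len(groups) > 1:
        raise ValueError(f"tracks span multiple sample groups: {sorted(groups)}")
    for t in tracks:
        if t.mark_name not in vocabulary:
            raise ValueError(f"unknown mark {t.mark_name!r}; declared vocabulary: {sorted(vocabulary)}")

    regions = gene_regions(gene, promoter_up, promoter_down)
    evidence: dict[str, frozenset[str]] = {}
    for region, intervals in regions.items():
        present = frozenset(
            t.mark_name
            for t in tracks
            if any(t.overlaps(c, s, e, min_overlap_bp) for c, s, e in intervals)
        )
        evidence[region] = present

    for rule in rules:
        if rule.matches(evidence):
            state = rule.state
            break
    else:  # a table without a fall-through rule
        state = "no_signal"
    group = tracks[0].sample_group if tracks else ""
    return ChromatinCall(gene_id=gene.gene_id, sample_group=group, state=state, evidence=evidence)


def assign_states(
    genes: Sequence[GeneModel], tracks: Sequence[MarkTrack], **kwargs
) -> list[ChromatinCall]:
    return [assign_state(g, tracks, **kwargs) for g in genes]


# ---------------------------------------------------------------------------
# Transition graph


@dataclass
class TransitionGraph:
    """State-transition groups between two sample groups.

    Vertices are (sample_group, state) pairs with gene counts; each edge
    (state in group 1 -> state in group 2) carries its member genes, with
    weight = member count.
    """

    group1: str
    group2: str
    vertex_counts: dict[tuple[str, str], int]  # (group, state) -> count
    edges: dict[tuple[str, str], list[str]]  # (state1, state2) -> members

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(g for members in self.edges.values() for g in members)

    def edge_weight(self, state1: str, state2: str) -> int:
        return len(self.edges.get((state1, state2), []))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "groups": [self.group1, self.group2],
            "vertices": [
                {"group": g, "state": s, "count": c}
                for (g, s), c in sorted(self.vertex_counts.items())
            ],
            "edges": [
                {
                    "from_state": s1,
                    "to_state": s2,
                    "weight": len(members),
                    "members": sorted(members),
                }
                for (s1, s2), members in sorted(self.edges.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def transitions(
    calls_g1: Sequence[ChromatinCall], calls_g2: Sequence[ChromatinCall]
) -> TransitionGraph:
    """Build the transition graph from two groups' chromatin calls.

    Both call lists must cover exactly the same gene universe; an
    asymmetric gene set is an error listing the offending genes.
    """
    m1 = {c.gene_id: c for c in calls_g1}
    m2 = {c.gene_id: c for c in calls_g2}
    if len(m1) != len(calls_g1) or len(m2) != len(calls_g2):
        raise ValueError("duplicate gene_id within a call list")
    asym = sorted(set(m1) ^ set(m2))
    if asym:
        raise ValueError(f"genes present in only one group: {asym[:10]}" + ("..." if len(asym) > 10 else ""))

    g1 = calls_g1[0].sample_group if calls_g1 else "group1"
    g2 = calls_g2[0].sample_group if calls_g2 else "group2"
    vertex_counts: dict[tuple[str, str], int] = {}
    edges: dict[tuple[str, str], list[str]] = {}
    for gene_id in m1:
        s1, s2 = m1[gene_id].state, m2[gene_id].state
        vertex_counts[(g1, s1)] = vertex_counts.get((g1, s1), 0) + 1
        vertex_counts[(g2, s2)] = vertex_counts.get((g2, s2), 0) + 1
        edges.setdefault((s1, s2), []).append(gene_id)
    for members in edges.values():
        members.sort()
    return TransitionGraph(group1=g1, group2=g2, vertex_counts=vertex_counts, edges=edges)


def enrich_transitions(
    graph: TransitionGraph,
    coll: GeneSetCollection,
    correction: str = "bh",
    min_edge_size: int = 2,
) -> dict[tuple[str, str], list[EnrichmentRecord]]:
    """Over-representation analysis for every transition group.

    The background universe is the full set of genes with calls; the
    collection is harmonized to it first.  Within each edge, p-values are
    corrected across categories.  Edges smaller than ``min_edge_size`` are
    skipped with a warning (ORA on a single gene is uninformative).
    """
    universe = graph.universe
    coll = harmonize(coll, universe)
    results: dict[tuple[str, str], list[EnrichmentRecord]] = {}
    for edge, members in sorted(graph.edges.items()):
        if len(members) < min_edge_size:
            logger.warning("transition %s->%s has %d member(s); skipped", *edge, len(members))
            continue
        records = [
            ora(members, coll.members(cid), universe, direction="over",
                category_id=cid, name=coll.display_name(cid))
            for cid in coll.categories
        ]
        records.sort(key=lambda r: (r.p_raw, r.category_id))
        results[edge] = adjust_records(records, method=correction)
    return results


def write_calls_tsv(calls: Iterable[ChromatinCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgroup\tstate\n")
        for c in calls:
            fh.write(f"{c.gene_id}\t{c.sample_group}\t{c.state}\n")
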