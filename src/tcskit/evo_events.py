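"""Inference of evolutionary events from clusters, foci and architectures.

Events are read off the comparative tables rather than reconciled on a
tree: a two-genome comparison cannot polarise gain versus loss, so records
state which genomes differ and how.  Event types:

* ``SINGLETON``       — protein with no orthologue in the compared genome;
* ``DUPLICATION``     — one genome contributes ≥2 cluster members, every
  other genome ≤1 (detail distinguishes local vs distal copies);
* ``ORG_CHANGE``      — members sit in foci of different category/notation;
* ``ARCH_CHANGE``     — differing R/T/H architecture strings;
* ``FAMILY_CHANGE``   — differing RR output-domain families;
* ``SIZE_CHANGE``     — member lengths span more than 100 aa;
* ``PSEUDOGENE``      — pseudogene and intact members coexist;
* ``HGT_CANDIDATE``   — singleton whose best non-self reference homolog is
  labelled outside the focal clade;
* ``RELOCATION``      — orthologue pair off every collinear dot-plot run.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

from Bio import SeqIO

from .focus_builder import Focus
from .genome_io import GenomeBundle, ProteinRecord
from .ortho_cluster import OrthoCluster, pairwise_similarity
from .tcs_classify import TCSProtein
from .util import round_half_away

__all__ = [
    "EventType",
    "EventRecord",
    "SyntenyPoint",
    "EventFrequencyTable",
    "ReferenceSeq",
    "read_reference",
    "detect_singletons",
    "detect_duplications",
    "detect_changes",
    "flag_hgt",
    "dotplot_points",
    "detect_relocations",
    "event_frequency_table",
]


class EventType(Enum):
    SINGLETON = "SINGLETON"
    DUPLICATION = "DUPLICATION"
    ORG_CHANGE = "ORG_CHANGE"
    ARCH_CHANGE = "ARCH_CHANGE"
    FAMILY_CHANGE = "FAMILY_CHANGE"
    SIZE_CHANGE = "SIZE_CHANGE"
    PSEUDOGENE = "PSEUDOGENE"
    HGT_CANDIDATE = "HGT_CANDIDATE"
    RELOCATION = "RELOCATION"


@dataclass(frozen=True)
class EventRecord:
    """One inferred evolutionary change."""

    event_type: EventType
    genomes: tuple[str, ...]
    cluster_id: Optional[str] = None
    loci: tuple[str, ...] = ()
    detail: tuple[tuple[str, str], ...] = ()

    def detail_dict(self) -> dict[str, str]:
        return dict(self.detail)


@dataclass
class SyntenyPoint:
    """One orthologue pair positioned by gene-order rank in two genomes."""

    a_rank: int
    b_rank: int
    a_id: str
    b_id: str
    segment_id: Optional[int] = None
    outlier: bool = False


@dataclass(frozen=True)
class EventFrequencyTable:
    """Per-event-type affected/comparable cluster counts and percentages."""

    rows: tuple[tuple[EventType, int, int, float], ...]

    def percentage(self, event_type: EventType) -> float:
        for et, _, _, pct in self.rows:
            if et is event_type:
                return pct
        raise KeyError(event_type)


@dataclass(frozen=True)
class ReferenceSeq:
    """A labelled homolog used for horizontal-transfer calls."""

    seq_id: str
    label: str
    sequence: str


def read_reference(path: str | Path) -> list[ReferenceSeq]:
    """Read a reference FASTA whose headers carry ``label=<clade>``."""
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        label = None
        for tok in rec.description.split():
            if tok.startswith("label="):
                label = tok[len("label="):]
        if label is None:
            raise ValueError(f"reference record {rec.id} lacks a label= field")
        out.append(ReferenceSeq(rec.id, label, str(rec.seq)))
    return out


def _pair_clusters(
    clusters: Sequence[OrthoCluster], genome_a: str, genome_b: str
) -> list[OrthoCluster]:
    kept = []
    for cl in clusters:
        members = [(g, p) for g, p in cl.members if g in (genome_a, genome_b)]
        if members:
            kept.append(
                OrthoCluster(cl.cluster_id, members, cl.representative, cl.tier, cl.flags)
            )
    return kept


def detect_singletons(
    clusters: Sequence[OrthoCluster], genome_a: str, genome_b: str
) -> list[EventRecord]:
    """One SINGLETON per protein lacking any orthologue in the other genome."""
    events = []
    for cl in _pair_clusters(clusters, genome_a, genome_b):
        present = cl.genomes()
        if len(present) == 1:
            (only,) = present
            for g, pid in cl.members:
                events.append(
                    EventRecord(
                        EventType.SINGLETON,
                        genomes=(only,),
                        cluster_id=cl.cluster_id,
                        loci=(pid,),
                    )
                )
    return events


def _ranks_by_protein(bundle: GenomeBundle) -> dict[str, int]:
    return {g.protein_id: g.rank for g in bundle.genes if g.protein_id is not None}


def detect_duplications(
    clusters: Sequence[OrthoCluster],
    bundles: Optional[Mapping[str, GenomeBundle]] = None,
    local_rank_gap: int = 5,
) -> list[EventRecord]:
    """Lineage-specific duplications: one genome with ≥2 members, rest ≤1.

    When bundles are supplied the detail marks the copies ``local`` (minimum
    rank gap ≤ ``local_rank_gap``) or ``distal``.
    """
    events = []
    ranks = {g: _ranks_by_protein(b) for g, b in (bundles or {}).items()}
    for cl in clusters:
        mult = cl.multiplicity()
        dupl = [g for g, v in mult.items() if v >= 2]
        if len(dupl) != 1 or any(v > 1 for g, v in mult.items() if g != dupl[0]):
            continue
        genome = dupl[0]
        pids = tuple(pid for g, pid in cl.members if g == genome)
        detail = []
        if genome in ranks:
            rs = sorted(ranks[genome][pid] for pid in pids if pid in ranks[genome])
            if len(rs) >= 2:
                min_gap = min(b - a for a, b in zip(rs, rs[1:]))
                detail.append(("placement", "local" if min_gap <= local_rank_gap else "distal"))
        events.append(
            EventRecord(
                EventType.DUPLICATION,
                genomes=(genome,),
                cluster_id=cl.cluster_id,
                loci=pids,
                detail=tuple(detail),
            )
        )
    return events


def detect_changes(
    clusters: Sequence[OrthoCluster],
    bundles: Mapping[str, GenomeBundle],
    tcs: Mapping[str, Mapping[str, TCSProtein]],
    foci: Mapping[str, Sequence[Focus]],
    size_diff_aa: int = 100,
) -> list[EventRecord]:
    """Per multi-member cluster, one record per change type observed."""
    notation_of: dict[tuple[str, str], str] = {}
    category_of: dict[tuple[str, str], str] = {}
    for genome_id, genome_foci in foci.items():
        for f in genome_foci:
            for pid in f.member_protein_ids:
                notation_of[(genome_id, pid)] = f.notation
                category_of[(genome_id, pid)] = f.category.value

    pseudo_of: dict[tuple[str, str], bool] = {}
    for genome_id, bundle in bundles.items():
        for g in bundle.genes:
            if g.protein_id is not None:
                pseudo_of[(genome_id, g.protein_id)] = g.pseudogene

    events = []
    for cl in clusters:
        if len(cl.members) < 2:
            continue
        genomes = tuple(sorted(cl.genomes()))
        loci = tuple(pid for _, pid in cl.members)

        def emit(et: EventType, **detail: str) -> None:
            events.append(
                EventRecord(
                    et,
                    genomes=genomes,
                    cluster_id=cl.cluster_id,
                    loci=loci,
                    detail=tuple(sorted(detail.items())),
                )
            )

        notations = {notation_of.get((g, p)) for g, p in cl.members}
        categories = {category_of.get((g, p)) for g, p in cl.members}
        if len(notations) > 1 or len(categories) > 1:
            emit(
                EventType.ORG_CHANGE,
                notations="|".join(sorted(str(x) for x in notations)),
            )
        archs = {tcs[g][p].architecture for g, p in cl.members}
        if len(archs) > 1:
            emit(EventType.ARCH_CHANGE, architectures="|".join(sorted(archs)))
        families = {
            tcs[g][p].rr_family
            for g, p in cl.members
            if tcs[g][p].rr_family is not None
        }
        if len(families) > 1:
            emit(EventType.FAMILY_CHANGE, families="|".join(sorted(families)))
        lengths = [bundles[g].proteins[p].length for g, p in cl.members]
        if max(lengths) - min(lengths) > size_diff_aa:
            emit(EventType.SIZE_CHANGE, delta=str(max(lengths) - min(lengths)))
        pseudo = {pseudo_of.get((g, p), False) for g, p in cl.members}
        if pseudo == {True, False}:
            emit(EventType.PSEUDOGENE)
    return events


def flag_hgt(
    singletons: Sequence[EventRecord],
    bundles: Mapping[str, GenomeBundle],
    reference: Sequence[ReferenceSeq],
    focal_clade: str,
) -> list[EventRecord]:
    """Flag singletons whose best non-self reference hit is outside the clade.

    Conservative on ties: if any top-scoring reference hit carries the focal
    clade label, the singleton is not flagged.
    """
    events = []
    for ev in singletons:
        if ev.event_type is not EventType.SINGLETON:
            raise ValueError("flag_hgt expects SINGLETON events")
        (genome,) = ev.genomes
        (pid,) = ev.loci
        prot = bundles[genome].proteins[pid]
        best_sim = -1.0
        best_labels: set[str] = set()
        for ref in reference:
            if ref.seq_id == pid:
                continue
            sim = pairwise_similarity(
                prot, ProteinRecord.make(ref.seq_id, ref.sequence)
            ).similarity
            if sim > best_sim:
                best_sim, best_labels = sim, {ref.label}
            elif sim == best_sim:
                best_labels.add(ref.label)
        if best_labels and focal_clade not in best_labels:
            events.append(
                EventRecord(
                    EventType.HGT_CANDIDATE,
                    genomes=ev.genomes,
                    cluster_id=ev.cluster_id,
                    loci=ev.loci,
                    detail=(
                        ("best_labels", "|".join(sorted(best_labels))),
                        ("best_similarity", f"{best_sim:.3f}"),
                    ),
                )
            )
    return events


def dotplot_points(
    clusters: Sequence[OrthoCluster],
    bundles: Mapping[str, GenomeBundle],
    genome_a: str,
    genome_b: str,
) -> list[SyntenyPoint]:
    """One point per 1:1 orthologue pair, positioned by gene-order rank."""
    ranks_a = _ranks_by_protein(bundles[genome_a])
    ranks_b = _ranks_by_protein(bundles[genome_b])
    points = []
    for cl in _pair_clusters(clusters, genome_a, genome_b):
        mult = cl.multiplicity()
        if mult.get(genome_a) == 1 and mult.get(genome_b) == 1:
            pid_a = next(p for g, p in cl.members if g == genome_a)
            pid_b = next(p for g, p in cl.members if g == genome_b)
            points.append(
                SyntenyPoint(ranks_a[pid_a], ranks_b[pid_b], pid_a, pid_b)
            )
    points.sort(key=lambda p: p.a_rank)
    return points


def detect_relocations(
    points: Sequence[SyntenyPoint],
    min_segment: int = 3,
    max_rank_step: int = 25,
) -> list[EventRecord]:
    """Flag points outside every collinear run of at least ``min_segment``.

    Points (sorted by first-genome rank) are chained greedily into runs:
    consecutive points extend a run when both rank steps are at most
    ``max_rank_step`` and the second-genome direction (+1 or -1) is
    consistent within the run.  Segment ids and outlier flags are written
    back onto the points.
    """
    ordered = sorted(points, key=lambda p: p.a_rank)
    runs: list[list[SyntenyPoint]] = []
    direction = 0
    for p in ordered:
        if runs:
            prev = runs[-1][-1]
            da = p.a_rank - prev.a_rank
            db = p.b_rank - prev.b_rank
            ok = 0 < da <= max_rank_step and 0 < abs(db) <= max_rank_step
            if ok and len(runs[-1]) == 1:
                direction = 1 if db > 0 else -1
            elif ok:
                ok = (db > 0) == (direction > 0)
            if ok:
                runs[-1].append(p)
                continue
        runs.append([p])
        direction = 0

    events = []
    for seg_id, run in enumerate(runs):
        keep = len(run) >= min_segment
        for p in run:
            p.segment_id = seg_id if keep else None
            p.outlier = not keep
            if not keep:
                events.append(
                    EventRecord(
                        EventType.RELOCATION,
                        genomes=(),
                        loci=(p.a_id, p.b_id),
                        detail=(("a_rank", str(p.a_rank)), ("b_rank", str(p.b_rank))),
                    )
                )
    return events


def event_frequency_table(
    events: Sequence[EventRecord], clusters: Sequence[OrthoCluster]
) -> EventFrequencyTable:
    """Percentage of comparable clusters affected by each event type.

    The denominator is the number of multi-member clusters, except for
    SINGLETON events where every cluster is comparable.  RELOCATION events
    carry no cluster id and are counted per event.
    """
    n_total = len(clusters)
    n_multi = sum(1 for cl in clusters if len(cl.members) > 1)
    rows = []
    for et in EventType:
        of_type = [e for e in events if e.event_type is et]
        cited = {e.cluster_id for e in of_type if e.cluster_id is not None}
        numerator = len(cited) if cited or not of_type else len(of_type)
        denominator = n_total if et is EventType.SINGLETON else n_multi
        pct = round_half_away(100.0 * numerator / denominator) if denominator else 0.0
        rows.append((et, numerator, denominator, pct))
    return EventFrequencyTable(rows=tuple(rows))
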