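"""Genomic foci of TCS genes and per-genome organisation statistics.

A *focus* is a maximal same-strand run of TCS genes in which consecutive
members are separated by at most one intervening non-TCS gene.  Its notation
joins the members' R/T/H architecture strings with commas, in transcription
order.  Foci are categorised:

* ``ORPHAN``  — a single gene carrying exactly one TCS domain;
* ``PAIRED``  — the focus's TCS domains are exactly one transmitter and one
  receiver (a lone hybrid gene, or an HK/RR gene pair);
* ``COMPLEX`` — anything else.

A focus (or a single protein) is *intricate* when it carries at least two
receiver and at least two transmitter domains.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

from .genome_io import GeneRecord, GenomeBundle
from .tcs_classify import TCSProtein
from .util import round_half_away

__all__ = [
    "FocusCategory",
    "Focus",
    "GenomeStats",
    "build_foci",
    "focus_notation",
    "classify_focus",
    "detect_intricate",
    "genome_summary",
    "cohort_summary",
]


class FocusCategory(Enum):
    ORPHAN = "ORPHAN"
    PAIRED = "PAIRED"
    COMPLEX = "COMPLEX"


@dataclass(frozen=True)
class Focus:
    """One maximal unidirectional run of TCS genes."""

    genome_id: str
    contig: str
    member_locus_tags: tuple[str, ...]
    member_protein_ids: tuple[str, ...]
    strand: str
    notation: str
    category: FocusCategory
    intricate: bool
    at_contig_edge: bool = False  # flank condition met only via a contig end

    def __len__(self) -> int:
        return len(self.member_locus_tags)


@dataclass
class GenomeStats:
    """One row of the per-genome summary table.

    Organisation percentages are ``None`` for incomplete genomes.  The same
    type doubles as the cohort mean row, in which case count fields hold
    (rounded) means rather than integers.
    """

    genome_id: str
    n_tcs: float
    n_hk: float
    n_hybrid: float
    n_pp: float
    n_rr: float
    pct_hybrid: Optional[float] = None
    pct_tm_hk: Optional[float] = None
    pct_orphan: Optional[float] = None
    pct_paired: Optional[float] = None
    pct_complex: Optional[float] = None
    n_intricate_foci: Optional[float] = None
    flags: tuple[str, ...] = ()


def _is_tcs_gene(g: GeneRecord, tcs: Mapping[str, TCSProtein]) -> bool:
    return g.protein_id is not None and g.protein_id in tcs and tcs[g.protein_id].is_tcs


def focus_notation(
    member_genes: Sequence[GeneRecord], tcs: Mapping[str, TCSProtein]
) -> str:
    """Comma-joined member architectures, in transcription order.

    ``member_genes`` are in genomic order; for '-'-strand foci transcription
    runs right-to-left so member order is reversed.  Within-protein domain
    order is always the protein's own N→C order.  Intervening non-TCS genes
    are not represented.
    """
    ordered = list(member_genes)
    if ordered and ordered[0].strand == "-":
        ordered = ordered[::-1]
    return ",".join(tcs[g.protein_id].architecture for g in ordered)


def classify_focus(notation: str) -> FocusCategory:
    """Categorise a focus from its notation string."""
    genes = notation.split(",")
    if len(genes) == 1 and len(genes[0]) == 1:
        return FocusCategory.ORPHAN
    symbols = sorted(notation.replace(",", ""))
    if symbols == ["R", "T"]:
        return FocusCategory.PAIRED
    return FocusCategory.COMPLEX


def detect_intricate(notation: str) -> bool:
    """True iff the focus carries ≥2 receiver and ≥2 transmitter domains."""
    return notation.count("R") >= 2 and notation.count("T") >= 2


def _make_focus(
    genome_id: str,
    contig: str,
    members: Sequence[GeneRecord],
    tcs: Mapping[str, TCSProtein],
    at_edge: bool,
) -> Focus:
    notation = focus_notation(members, tcs)
    return Focus(
        genome_id=genome_id,
        contig=contig,
        member_locus_tags=tuple(g.locus_tag for g in members),
        member_protein_ids=tuple(g.protein_id for g in members),
        strand=members[0].strand,
        notation=notation,
        category=classify_focus(notation),
        intricate=detect_intricate(notation),
        at_contig_edge=at_edge,
    )


def build_foci(
    genome: GenomeBundle, tcs: Mapping[str, TCSProtein], max_intervening: int = 1
) -> list[Focus]:
    """Partition a genome's TCS genes into foci.

    A focus is terminated by a strand change, by more than ``max_intervening``
    consecutive non-TCS genes, or by a contig end.  Every TCS gene belongs to
    exactly one focus.  Contig ends satisfy the flanking condition trivially;
    such foci are flagged ``at_contig_edge``.
    """
    foci: list[Focus] = []
    for contig, genes in genome.genes_by_contig().items():
        n_genes = len(genes)
        members: list[GeneRecord] = []
        gap = 0  # non-TCS genes since the last member

        def close() -> None:
            if members:
                at_edge = members[0].rank < 2 or members[-1].rank > n_genes - 3
                foci.append(_make_focus(genome.genome_id, contig, members, tcs, at_edge))

        for g in genes:
            if _is_tcs_gene(g, tcs):
                if members and (g.strand != members[0].strand or gap > max_intervening):
                    close()
                    members = []
                members.append(g)
                gap = 0
            else:
                gap += 1
        close()
    return foci


def genome_summary(
    genome: GenomeBundle,
    tcs: Mapping[str, TCSProtein],
    foci: Sequence[Focus],
) -> GenomeStats:
    """Compute the per-genome summary row.

    Percentages are rounded to one decimal, halves away from zero.
    Organisation percentages are gene-weighted (fraction of TCS genes sitting
    in foci of each category) and suppressed for incomplete genomes.
    """
    from .tcs_classify import TCSClass

    gene_pids = [
        g.protein_id for g in genome.genes if _is_tcs_gene(g, tcs)
    ]
    classes = [tcs[pid].tcs_class for pid in gene_pids]
    n_hk = sum(c is TCSClass.HK for c in classes)
    n_hybrid = sum(c is TCSClass.HYBRID_HK for c in classes)
    n_pp = sum(c is TCSClass.PP for c in classes)
    n_rr = sum(c is TCSClass.RR for c in classes)
    n_tcs = len(gene_pids)

    flags: list[str] = []
    n_kinase = n_hk + n_hybrid
    if n_kinase:
        pct_hybrid = round_half_away(100.0 * n_hybrid / n_kinase)
        n_tm = sum(
            tcs[pid].has_tm
            for pid in gene_pids
            if tcs[pid].tcs_class in (TCSClass.HK, TCSClass.HYBRID_HK)
        )
        pct_tm_hk = round_half_away(100.0 * n_tm / n_kinase)
    else:
        pct_hybrid = 0.0
        pct_tm_hk = 0.0
        flags.append("pct-hk-undefined")

    pct_orphan = pct_paired = pct_complex = None
    if genome.complete:
        if n_tcs:
            weights = {cat: 0 for cat in FocusCategory}
            for f in foci:
                weights[f.category] += len(f)
            pct_orphan = round_half_away(100.0 * weights[FocusCategory.ORPHAN] / n_tcs)
            pct_paired = round_half_away(100.0 * weights[FocusCategory.PAIRED] / n_tcs)
            pct_complex = round_half_away(100.0 * weights[FocusCategory.COMPLEX] / n_tcs)
        else:
            pct_orphan = pct_paired = pct_complex = 0.0
            flags.append("pct-organisation-undefined")

    return GenomeStats(
        genome_id=genome.genome_id,
        n_tcs=n_tcs,
        n_hk=n_hk,
        n_hybrid=n_hybrid,
        n_pp=n_pp,
        n_rr=n_rr,
        pct_hybrid=pct_hybrid,
        pct_tm_hk=pct_tm_hk,
        pct_orphan=pct_orphan,
        pct_paired=pct_paired,
        pct_complex=pct_complex,
        n_intricate_foci=sum(f.intricate for f in foci) if genome.complete else None,
        flags=tuple(flags),
    )


def cohort_summary(stats: Sequence[GenomeStats], genome_id: str = "mean") -> GenomeStats:
    """Arithmetic column means over a cohort, skipping not-available entries.

    Every value (including counts) is rounded to one decimal, halves away
    from zero.  Raises ``ValueError`` on empty input.
    """
    if not stats:
        raise ValueError("cohort_summary requires at least one genome")

    def mean_of(values: list[Optional[float]]) -> Optional[float]:
        present = [v for v in values if v is not None]
        if not present:
            return None
        return round_half_away(sum(present) / len(present))

    fields = [
        "n_tcs",
        "n_hk",
        "n_hybrid",
        "n_pp",
        "n_rr",
        "pct_hybrid",
        "pct_tm_hk",
        "pct_orphan",
        "pct_paired",
        "pct_complex",
        "n_intricate_foci",
    ]
    means = {f: mean_of([getattr(s, f) for s in stats]) for f in fields}
    return GenomeStats(genome_id=genome_id, flags=("mean",), **means)
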