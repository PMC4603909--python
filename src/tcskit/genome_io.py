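"""Data model and on-disk format for per-genome annotation bundles.

A bundle directory holds four plain-text files::

    proteins.faa   protein sequences (FASTA, 60-column wrap)
    genes.tsv      locus_tag, contig, rank, strand, start, end, pseudogene, protein_id
    domains.tsv    protein_id, kind, subtype, start, end
    ssu.fna        16S rRNA gene sequence (FASTA, optional)
    meta.json      genome_id and completeness flag (optional; defaults applied)

All tables are UTF-8, tab-separated, with a header row and ``.`` for absent
values.  Gene coordinates are 1-based inclusive nucleotide positions, domain
coordinates are 1-based inclusive residue positions, and the gene-order
``rank`` is a 0-based index within each contig.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DOMAIN_KINDS",
    "GeneRecord",
    "DomainHit",
    "ProteinRecord",
    "GenomeBundle",
    "Issue",
    "BundleLoadError",
    "BundleValidationError",
    "read_bundle",
    "write_bundle",
    "validate_bundle",
]

#: Closed set of recognised domain annotation kinds.
DOMAIN_KINDS = frozenset(
    {"receiver", "transmitter", "phosphoacceptor", "input", "output", "TM"}
)

_ABSENT = "."

_GENE_COLUMNS = [
    "locus_tag",
    "contig",
    "rank",
    "strand",
    "start",
    "end",
    "pseudogene",
    "protein_id",
]
_DOMAIN_COLUMNS = ["protein_id", "kind", "subtype", "start", "end"]


class BundleLoadError(Exception):
    """A bundle file is missing or cannot be parsed."""


class BundleValidationError(Exception):
    """A bundle violates the data-model invariants."""

    def __init__(self, issues: list["Issue"]):
        self.issues = issues
        super().__init__(
            "invalid bundle: " + "; ".join(f"{i.code} at {i.location}" for i in issues)
        )


class Issue(NamedTuple):
    """One machine-readable validation finding."""

    code: str
    location: str
    detail: str = ""


@dataclass(frozen=True)
class DomainHit:
    """One annotated domain region within a protein."""

    protein_id: str
    kind: str
    subtype: Optional[str]
    start: int  # 1-based inclusive residue
    end: int


@dataclass(frozen=True)
class GeneRecord:
    """One gene in a genome's gene-order table."""

    locus_tag: str
    contig: str
    rank: int  # 0-based order index within contig
    strand: str  # '+' or '-'
    start: int  # 1-based inclusive nucleotide
    end: int
    pseudogene: bool = False
    protein_id: Optional[str] = None


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence together with its ordered domain annotation."""

    protein_id: str
    sequence: str
    domains: tuple[DomainHit, ...] = ()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @staticmethod
    def make(protein_id: str, sequence: str, domains: Iterable[DomainHit] = ()) -> "ProteinRecord":
        """Build a record with domains normalised to (start, end, kind) order."""
        ordered = tuple(sorted(domains, key=lambda d: (d.start, d.end, d.kind)))
        return ProteinRecord(protein_id, sequence, ordered)


@dataclass
class GenomeBundle:
    """One genome's genes, proteins and (optionally) 16S sequence."""

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    proteins: dict[str, ProteinRecord] = field(default_factory=dict)
    ssu_rrna: Optional[str] = None
    complete: bool = True

    def genes_by_contig(self) -> dict[str, list[GeneRecord]]:
        """Genes grouped per contig, sorted by rank."""
        out: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            out.setdefault(g.contig, []).append(g)
        for contig in out:
            out[contig].sort(key=lambda g: g.rank)
        return out


# ---------------------------------------------------------------------------
# validation

_FATAL_ON_READ = frozenset(
    {"dangling-protein-id", "duplicate-locus-tag", "unknown-domain-kind"}
)


def validate_bundle(bundle: GenomeBundle) -> list[Issue]:
    """Check every data-model invariant; return [] iff the bundle is valid."""
    issues: list[Issue] = []

    seen_tags: set[str] = set()
    for g in bundle.genes:
        if g.locus_tag in seen_tags:
            issues.append(Issue("duplicate-locus-tag", g.locus_tag))
        seen_tags.add(g.locus_tag)
        if g.strand not in ("+", "-"):
            issues.append(Issue("bad-strand", g.locus_tag, g.strand))
        if g.start > g.end:
            issues.append(Issue("coord-inverted", g.locus_tag, f"{g.start}>{g.end}"))
        if g.protein_id is not None and g.protein_id not in bundle.proteins:
            issues.append(Issue("dangling-protein-id", g.locus_tag, g.protein_id))

    for contig, genes in bundle.genes_by_contig().items():
        ranks = [g.rank for g in genes]
        if ranks != list(range(len(ranks))):
            issues.append(
                Issue("rank-not-consecutive", contig, f"ranks={sorted(ranks)}")
            )
        by_coord = sorted(genes, key=lambda g: (g.start, g.locus_tag))
        if [g.locus_tag for g in by_coord] != [g.locus_tag for g in genes]:
            issues.append(Issue("rank-order-mismatch", contig))

    for pid, p in bundle.proteins.items():
        if pid != p.protein_id:
            issues.append(Issue("protein-id-mismatch", pid, p.protein_id))
        prev_start = 0
        for d in p.domains:
            if d.protein_id != pid:
                issues.append(Issue("domain-protein-mismatch", pid, d.protein_id))
            if d.kind not in DOMAIN_KINDS:
                issues.append(Issue("unknown-domain-kind", pid, d.kind))
            if not (1 <= d.start <= d.end):
                issues.append(Issue("domain-coord-inverted", pid, f"{d.start}>{d.end}"))
            elif d.end > p.length:
                issues.append(
                    Issue("domain-out-of-range", pid, f"end={d.end}>len={p.length}")
                )
            if d.start < prev_start:
                issues.append(Issue("domain-unsorted", pid))
            prev_start = d.start

    if bundle.ssu_rrna is not None and not bundle.ssu_rrna:
        issues.append(Issue("empty-ssu", bundle.genome_id))

    return issues


# ---------------------------------------------------------------------------
# readers / writers


def _require(path: Path) -> Path:
    if not path.exists():
        raise BundleLoadError(f"missing bundle file: {path}")
    return path


def _parse_int(value: str, where: str) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise BundleLoadError(f"bad integer {value!r} in {where}") from exc


def read_bundle(dir_path: str | Path) -> GenomeBundle:
    """Load and cross-validate a bundle directory.

    Raises :class:`BundleLoadError` for missing/unparseable files and
    :class:`BundleValidationError` when the loaded tables violate the data
    model (dangling protein ids, duplicate locus tags, unknown domain kinds,
    or any other invariant).
    """
    root = Path(dir_path)
    if not root.is_dir():
        raise BundleLoadError(f"not a bundle directory: {root}")

    meta_path = root / "meta.json"
    genome_id = root.name
    complete = True
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        genome_id = meta.get("genome_id", genome_id)
        complete = bool(meta.get("complete", True))

    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(_require(root / "proteins.faa"), "fasta"):
        sequences[rec.id] = str(rec.seq)

    domains_by_protein: dict[str, list[DomainHit]] = {}
    with open(_require(root / "domains.tsv"), newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _DOMAIN_COLUMNS:
            raise BundleLoadError(f"bad header in {root / 'domains.tsv'}")
        for row in reader:
            hit = DomainHit(
                protein_id=row["protein_id"],
                kind=row["kind"],
                subtype=None if row["subtype"] == _ABSENT else row["subtype"],
                start=_parse_int(row["start"], "domains.tsv"),
                end=_parse_int(row["end"], "domains.tsv"),
            )
            domains_by_protein.setdefault(hit.protein_id, []).append(hit)

    dangling_domains = sorted(set(domains_by_protein) - set(sequences))
    if dangling_domains:
        raise BundleValidationError(
            [Issue("dangling-protein-id", "domains.tsv", pid) for pid in dangling_domains]
        )

    proteins = {
        pid: ProteinRecord.make(pid, seq, domains_by_protein.get(pid, ()))
        for pid, seq in sequences.items()
    }

    genes: list[GeneRecord] = []
    with open(_require(root / "genes.tsv"), newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _GENE_COLUMNS:
            raise BundleLoadError(f"bad header in {root / 'genes.tsv'}")
        for row in reader:
            genes.append(
                GeneRecord(
                    locus_tag=row["locus_tag"],
                    contig=row["contig"],
                    rank=_parse_int(row["rank"], "genes.tsv"),
                    strand=row["strand"],
                    start=_parse_int(row["start"], "genes.tsv"),
                    end=_parse_int(row["end"], "genes.tsv"),
                    pseudogene=row["pseudogene"] == "1",
                    protein_id=None if row["protein_id"] == _ABSENT else row["protein_id"],
                )
            )

    ssu_path = root / "ssu.fna"
    ssu = None
    if ssu_path.exists():
        records = list(SeqIO.parse(ssu_path, "fasta"))
        if records:
            ssu = str(records[0].seq)

    bundle = GenomeBundle(genome_id, genes, proteins, ssu, complete)
    issues = validate_bundle(bundle)
    if issues:
        raise BundleValidationError(issues)
    return bundle


def write_bundle(bundle: GenomeBundle, dir_path: str | Path) -> Path:
    """Write a bundle directory; inverse of :func:`read_bundle`."""
    root = Path(dir_path)
    root.mkdir(parents=True, exist_ok=True)

    records = [
        SeqRecord(Seq(p.sequence), id=pid, description="")
        for pid, p in sorted(bundle.proteins.items())
    ]
    SeqIO.write(records, root / "proteins.faa", "fasta")

    with open(root / "genes.tsv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_GENE_COLUMNS)
        for g in bundle.genes:
            writer.writerow(
                [
                    g.locus_tag,
                    g.contig,
                    g.rank,
                    g.strand,
                    g.start,
                    g.end,
                    "1" if g.pseudogene else "0",
                    g.protein_id if g.protein_id is not None else _ABSENT,
                ]
            )

    with open(root / "domains.tsv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_DOMAIN_COLUMNS)
        for pid, p in sorted(bundle.proteins.items()):
            for d in p.domains:
                writer.writerow(
                    [pid, d.kind, d.subtype if d.subtype is not None else _ABSENT, d.start, d.end]
                )

    if bundle.ssu_rrna is not None:
        SeqIO.write(
            [SeqRecord(Seq(bundle.ssu_rrna), id=f"{bundle.genome_id}_16S", description="")],
            root / "ssu.fna",
            "fasta",
        )

    (root / "meta.json").write_text(
        json.dumps({"genome_id": bundle.genome_id, "complete": bundle.complete}) + "\n"
    )
    return root
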