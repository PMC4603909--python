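"""Genome simulator with planted evolutionary events and an exact truth log.

An ancestral single-contig genome is generated with background genes and TCS
foci drawn from a configurable organisation mix, then evolved along a tree.
Structural events (gene/focus loss, duplication, HGT insertion, domain
gain/loss, frameshift pseudogenisation, size indels, block inversions) are
sampled as Poisson processes with expectation ``rate x branch length``;
sequences accumulate per-site substitutions at the branch-length rate (16S)
and a scaled rate (TCS proteins).  Domain annotations are bookkept exactly
through every edit, so tip bundles always validate.

Every gene carries an *origin* id.  The ancestor's genes are their own
origins; a duplicate appends ``.dN`` to its parent's origin and an acquired
gene gets a fresh ``hgt...`` origin, so genes sharing a root origin (the id
up to the first ``.``) form one orthologue family.  The
:class:`TruthLog` records all applied events, the per-tip locus→origin map
and per-tip focus notations — the oracle against which event detection is
scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import dendropy
import numpy as np

from .focus_builder import build_foci
from .genome_io import DomainHit, GeneRecord, GenomeBundle, ProteinRecord
from .tcs_classify import classify_protein
from .evo_events import ReferenceSeq

__all__ = [
    "SimulationConfig",
    "TruthEvent",
    "TruthLog",
    "simulate_ancestor",
    "evolve_along_tree",
    "make_reference",
    "make_distance_regimes",
    "FOCAL_CLADE",
    "FOREIGN_CLADE",
]

FOCAL_CLADE = "focal"
FOREIGN_CLADE = "other-order"

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NT = np.array(list("ACGT"))
_RR_FAMILIES = ("NtrC", "OmpR", "LytTR", "NarL", "CheY")
_SENSORS = ("PAS", "GAF", "HAMP", "Cache")

_DOMAIN_LEN = {"receiver": 120, "transmitter": 220, "phosphoacceptor": 90,
               "output": 100, "input": 110}
_LINKER = 20

_COMPLEX_TEMPLATES = (("T", "R", "R"), ("T", "T", "R"), ("RT", "T"), ("H", "R"))
_INTRICATE_TEMPLATES = (("TRTR",), ("RT", "RT"), ("T", "R", "T", "R"))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulation; every field has a reproducible default.

    Event rates are per gene (or per focus, for ``focus_loss_rate``; per
    genome for ``hgt_rate``) per unit branch length, so with 16S-scale
    branch lengths the interesting regimes use numerically large rates.
    ``inversion_prob`` is a per-branch probability (branches of zero length
    evolve nothing).
    """

    seed: int
    tree: str = "(A:0.005,B:0.005);"
    n_background_genes: int = 60
    n_tcs_foci: int = 12
    focus_mix: tuple[float, float, float, float] = (0.25, 0.40, 0.25, 0.10)
    gene_loss_rate: float = 0.0
    focus_loss_rate: float = 0.0
    duplication_rate: float = 0.0
    local_dup_prob: float = 0.5
    hgt_rate: float = 0.0
    domain_gain_rate: float = 0.0
    domain_loss_rate: float = 0.0
    frameshift_rate: float = 0.0
    size_indel_rate: float = 0.0
    size_indel_mean_aa: float = 150.0
    inversion_prob: float = 0.0
    protein_rate_scale: float = 1.0
    ssu_length: int = 1500

    def validate(self) -> None:
        rates = (
            self.gene_loss_rate, self.focus_loss_rate, self.duplication_rate,
            self.hgt_rate, self.domain_gain_rate, self.domain_loss_rate,
            self.frameshift_rate, self.size_indel_rate,
        )
        if any(r < 0 for r in rates):
            raise ValueError("event rates must be non-negative")
        if not 0 <= self.inversion_prob <= 1 or not 0 <= self.local_dup_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.focus_mix) - 1.0) > 1e-9:
            raise ValueError("focus_mix fractions must sum to 1")
        if self.n_background_genes < 2 * (self.n_tcs_foci + 1):
            raise ValueError("need >=2 background genes per focus flank")


@dataclass(frozen=True)
class TruthEvent:
    branch: str  # label of the child node of the branch
    event_type: str
    origins: tuple[str, ...]
    detail: tuple[tuple[str, str], ...] = ()


@dataclass
class TruthLog:
    """Machine-readable record of everything the simulator did."""

    events: list[TruthEvent] = field(default_factory=list)
    #: per tip: locus_tag -> origin id (TCS genes only)
    origins: dict[str, dict[str, str]] = field(default_factory=dict)
    #: per tip: locus_tag -> focus notation of the gene's focus
    notations: dict[str, dict[str, str]] = field(default_factory=dict)
    #: per tip: node labels on the root-to-tip path (excluding the root)
    paths: dict[str, list[str]] = field(default_factory=dict)
    n_ancestral_tcs: int = 0

    def root_origin_families(self, tip: str) -> dict[str, list[str]]:
        """Group a tip's TCS locus tags by root origin (orthologue family)."""
        fams: dict[str, list[str]] = {}
        for tag, origin in self.origins[tip].items():
            fams.setdefault(origin.split(".")[0], []).append(tag)
        return fams

    def to_json(self) -> str:
        return json.dumps(
            {
                "events": [
                    {
                        "branch": e.branch,
                        "event_type": e.event_type,
                        "origins": list(e.origins),
                        "detail": dict(e.detail),
                    }
                    for e in self.events
                ],
                "origins": self.origins,
                "notations": self.notations,
                "paths": self.paths,
                "n_ancestral_tcs": self.n_ancestral_tcs,
            },
            indent=1,
        )

    @staticmethod
    def from_json(text: str) -> "TruthLog":
        raw = json.loads(text)
        return TruthLog(
            events=[
                TruthEvent(
                    branch=e["branch"],
                    event_type=e["event_type"],
                    origins=tuple(e["origins"]),
                    detail=tuple(sorted(e["detail"].items())),
                )
                for e in raw["events"]
            ],
            origins=raw["origins"],
            notations=raw["notations"],
            paths=raw["paths"],
            n_ancestral_tcs=raw["n_ancestral_tcs"],
        )


# ---------------------------------------------------------------------------
# internal mutable gene representation


@dataclass
class _SimGene:
    origin: str
    is_tcs: bool
    strand: str
    sequence: str
    domains: list[tuple[str, Optional[str], int, int]]  # kind, subtype, start, end
    pseudogene: bool = False

    def copy(self) -> "_SimGene":
        return _SimGene(
            self.origin, self.is_tcs, self.strand, self.sequence,
            [tuple(d) for d in self.domains], self.pseudogene,
        )


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _build_protein(
    rng: np.random.Generator, arch: str, with_output: bool, with_input: bool
) -> _SimGene:
    """Construct one TCS gene whose R/T/H architecture equals ``arch``."""
    kinds = {"R": "receiver", "T": "transmitter", "H": "phosphoacceptor"}
    domains: list[tuple[str, Optional[str], int, int]] = []
    pos = 1 + _LINKER
    if with_input:
        domains.append(("input", str(rng.choice(_SENSORS)), pos, pos + _DOMAIN_LEN["input"] - 1))
        pos += _DOMAIN_LEN["input"] + _LINKER
        if rng.random() < 0.5:
            domains.append(("TM", None, 2, 20))  # inside the N-terminal linker
    for sym in arch:
        kind = kinds[sym]
        domains.append((kind, None, pos, pos + _DOMAIN_LEN[kind] - 1))
        pos += _DOMAIN_LEN[kind] + _LINKER
    if with_output:
        domains.append(("output", str(rng.choice(_RR_FAMILIES)), pos, pos + _DOMAIN_LEN["output"] - 1))
        pos += _DOMAIN_LEN["output"] + _LINKER
    length = pos + 10
    return _SimGene(
        origin="",
        is_tcs=True,
        strand="+",
        sequence=_rand_seq(rng, length),
        domains=domains,
    )


def _background_gene(rng: np.random.Generator) -> _SimGene:
    return _SimGene(
        origin="",
        is_tcs=False,
        strand="+" if rng.random() < 0.5 else "-",
        sequence=_rand_seq(rng, int(rng.integers(120, 400))),
        domains=[],
    )


def _focus_genes(rng: np.random.Generator, category: str) -> list[_SimGene]:
    if category == "orphan":
        sym = str(rng.choice(["R", "T", "H"]))
        template = (sym,)
    elif category == "paired":
        template = ("RT",) if rng.random() < 0.5 else ("T", "R")
    elif category == "complex":
        template = _COMPLEX_TEMPLATES[int(rng.integers(len(_COMPLEX_TEMPLATES)))]
    elif category == "intricate":
        template = _INTRICATE_TEMPLATES[int(rng.integers(len(_INTRICATE_TEMPLATES)))]
    else:
        raise ValueError(category)
    strand = "+" if rng.random() < 0.5 else "-"
    genes = []
    for arch in template:
        with_output = arch == "R"
        with_input = arch.endswith("T") and rng.random() < 0.7
        g = _build_protein(rng, arch, with_output, with_input)
        g.strand = strand
        genes.append(g)
    if strand == "-":
        genes = genes[::-1]  # templates are written in transcription order
    return genes


def _mix_counts(mix: tuple[float, ...], n: int) -> list[int]:
    raw = [f * n for f in mix]
    counts = [int(x) for x in raw]
    remainders = sorted(
        range(len(mix)), key=lambda i: (raw[i] - counts[i]), reverse=True
    )
    for i in range(n - sum(counts)):
        counts[remainders[i % len(mix)]] += 1
    return counts


def _freeze(
    genes: list[_SimGene], genome_id: str, ssu: Optional[str], complete: bool = True
) -> tuple[GenomeBundle, dict[str, str]]:
    """Turn a gene list into a validated bundle; returns (bundle, tag→origin)."""
    records = []
    proteins = {}
    origin_of: dict[str, str] = {}
    pos = 1
    for i, g in enumerate(genes):
        tag = f"{genome_id}_{i:05d}"
        gene_len = 3 * (len(g.sequence) + 1)
        records.append(
            GeneRecord(
                locus_tag=tag,
                contig="chr",
                rank=i,
                strand=g.strand,
                start=pos,
                end=pos + gene_len - 1,
                pseudogene=g.pseudogene,
                protein_id=tag,
            )
        )
        pos += gene_len + 150
        proteins[tag] = ProteinRecord.make(
            tag,
            g.sequence,
            [DomainHit(tag, k, s, a, b) for (k, s, a, b) in g.domains],
        )
        if g.is_tcs:
            origin_of[tag] = g.origin
    bundle = GenomeBundle(genome_id, records, proteins, ssu, complete)
    return bundle, origin_of


def _genes_from_bundle(bundle: GenomeBundle) -> list[_SimGene]:
    genes = []
    for g in sorted(bundle.genes, key=lambda x: x.rank):
        p = bundle.proteins[g.protein_id]
        tcs = classify_protein(p).is_tcs
        genes.append(
            _SimGene(
                origin=g.locus_tag,
                is_tcs=tcs,
                strand=g.strand,
                sequence=p.sequence,
                domains=[(d.kind, d.subtype, d.start, d.end) for d in p.domains],
                pseudogene=g.pseudogene,
            )
        )
    return genes


def simulate_ancestor(cfg: SimulationConfig) -> GenomeBundle:
    """Generate the ancestral genome: background genes with TCS foci planted
    in the configured organisation mix, plus a random 16S sequence.

    Deterministic given ``cfg.seed``; each focus is flanked by at least two
    background genes so the planted categories survive focus construction.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])

    categories = []
    for cat, count in zip(("orphan", "paired", "complex", "intricate"),
                          _mix_counts(cfg.focus_mix, cfg.n_tcs_foci)):
        categories.extend([cat] * count)

    n_slots = cfg.n_tcs_foci + 1
    extra = cfg.n_background_genes - 2 * n_slots
    extras = rng.multinomial(extra, np.full(n_slots, 1.0 / n_slots)) if extra else np.zeros(n_slots, dtype=int)

    genes: list[_SimGene] = []
    for i, cat in enumerate(categories):
        genes.extend(_background_gene(rng) for _ in range(2 + int(extras[i])))
        genes.extend(_focus_genes(rng, cat))
    genes.extend(_background_gene(rng) for _ in range(2 + int(extras[-1])))

    for i, g in enumerate(genes):
        g.origin = f"ancestor_{i:05d}"  # matches the frozen locus tag

    ssu = "".join(rng.choice(_NT, size=cfg.ssu_length))
    bundle, _ = _freeze(genes, "ancestor", ssu)
    return bundle


def _foreign_pool(cfg: SimulationConfig) -> list[_SimGene]:
    rng = np.random.default_rng([cfg.seed, 1])
    pool = []
    for i in range(40):
        arch = str(rng.choice(["T", "R", "RT"]))
        g = _build_protein(rng, arch, with_output=arch == "R", with_input=False)
        g.origin = f"hgt{i:03d}"
        pool.append(g)
    return pool


def make_reference(ancestor: GenomeBundle, cfg: SimulationConfig) -> list[ReferenceSeq]:
    """Labelled homolog set: ancestral TCS proteins (focal clade) plus the
    foreign pool that HGT insertions are drawn from (other-order)."""
    refs = []
    for pid in sorted(ancestor.proteins):
        p = ancestor.proteins[pid]
        if classify_protein(p).is_tcs:
            refs.append(ReferenceSeq(f"ref_{pid}", FOCAL_CLADE, p.sequence))
    for g in _foreign_pool(cfg):
        refs.append(ReferenceSeq(f"ref_{g.origin}", FOREIGN_CLADE, g.sequence))
    return refs


# --- per-branch mutation machinery -----------------------------------------


def _mutate_seq(rng: np.random.Generator, seq: str, p: float, alphabet: np.ndarray) -> str:
    if p <= 0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < p
    if hit.any():
        # draw replacements distinct from the current letter
        repl = rng.choice(alphabet, size=int(hit.sum()))
        cur = arr[hit]
        clash = repl == cur
        while clash.any():
            repl[clash] = rng.choice(alphabet, size=int(clash.sum()))
            clash = repl == cur
        arr[hit] = repl
    return "".join(arr)


def _tcs_indices(genes: list[_SimGene]) -> list[int]:
    return [i for i, g in enumerate(genes) if g.is_tcs]


def _safe_insert_positions(genes: list[_SimGene]) -> list[int]:
    """Insertion indices at least two genes away from any TCS gene."""
    n = len(genes)
    ok = []
    for j in range(n + 1):
        window = genes[max(0, j - 2): min(n, j + 2)]
        if not any(g.is_tcs for g in window):
            ok.append(j)
    return ok or [n]


def _shift_domains(gene: _SimGene, from_pos: int, delta: int) -> None:
    gene.domains = [
        (k, s, a + delta if a >= from_pos else a, b + delta if b >= from_pos else b)
        for (k, s, a, b) in gene.domains
    ]


def _tail_start(gene: _SimGene) -> int:
    return max((b for (_, _, _, b) in gene.domains), default=0) + 1


def _apply_branch(
    genes: list[_SimGene],
    ssu: str,
    length: float,
    branch_label: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    log: TruthLog,
    counters: dict[str, int],
) -> tuple[list[_SimGene], str]:
    genes = [g.copy() for g in genes]

    def record(event_type: str, origins: tuple[str, ...], **detail: str) -> None:
        log.events.append(
            TruthEvent(branch_label, event_type, origins, tuple(sorted(detail.items())))
        )

    def poisson(rate: float, n_units: int) -> int:
        lam = rate * length * n_units
        return int(rng.poisson(lam)) if lam > 0 else 0

    tcs0 = _tcs_indices(genes)
    n_tcs0 = len(tcs0)

    # inversion: pivot a block roughly centred on the chromosome midpoint;
    # zero-length branches evolve nothing
    if cfg.inversion_prob > 0 and length > 0 and rng.random() < cfg.inversion_prob:
        n = len(genes)
        half = int(rng.integers(max(2, n // 6), max(3, n // 3)))
        centre = n // 2 + int(rng.integers(-n // 10, n // 10 + 1))
        lo, hi = max(0, centre - half), min(n, centre + half)
        block = genes[lo:hi][::-1]
        for g in block:
            g.strand = "+" if g.strand == "-" else "-"
        genes[lo:hi] = block
        record("inversion", tuple(g.origin for g in block if g.is_tcs),
               span=f"{lo}:{hi}")

    # whole-focus loss
    if cfg.focus_loss_rate > 0:
        bundle, _ = _freeze(genes, "tmp", None)
        tcs_map = {pid: classify_protein(p) for pid, p in bundle.proteins.items()}
        foci = build_foci(bundle, tcs_map)
        k = poisson(cfg.focus_loss_rate, len(foci))
        if k:
            chosen = rng.choice(len(foci), size=min(k, len(foci)), replace=False)
            doomed_tags = {
                tag for fi in chosen for tag in foci[int(fi)].member_locus_tags
            }
            doomed = {
                i for i, g in enumerate(genes)
                if g.is_tcs and f"tmp_{i:05d}" in doomed_tags
            }
            record(
                "focus_loss",
                tuple(genes[i].origin for i in sorted(doomed)),
                n=str(len(doomed)),
            )
            genes = [g for i, g in enumerate(genes) if i not in doomed]

    # individual gene loss
    k = poisson(cfg.gene_loss_rate, n_tcs0)
    tcs_now = _tcs_indices(genes)
    if k and tcs_now:
        chosen = rng.choice(len(tcs_now), size=min(k, len(tcs_now)), replace=False)
        doomed = {tcs_now[int(i)] for i in chosen}
        for i in sorted(doomed):
            record("gene_loss", (genes[i].origin,))
        genes = [g for i, g in enumerate(genes) if i not in doomed]

    # duplication
    k = poisson(cfg.duplication_rate, n_tcs0)
    for _ in range(k):
        tcs_now = _tcs_indices(genes)
        if not tcs_now:
            break
        src = tcs_now[int(rng.integers(len(tcs_now)))]
        src_origin = genes[src].origin
        copy = genes[src].copy()
        counters["dup"] += 1
        copy.origin = f"{src_origin}.d{counters['dup']}"
        local = rng.random() < cfg.local_dup_prob
        if local:
            genes.insert(src + 1, copy)
        else:
            pos = _safe_insert_positions(genes)
            genes.insert(int(rng.choice(pos)), copy)
        record(
            "duplication",
            (src_origin, copy.origin),
            placement="local" if local else "distal",
        )

    # horizontal acquisition from the foreign pool
    k = poisson(cfg.hgt_rate, 1)
    pool = counters["pool"]
    for _ in range(k):
        if not pool:
            break
        new = pool.pop(0).copy()
        counters["hgt"] += 1
        pos = _safe_insert_positions(genes)
        genes.insert(int(rng.choice(pos)), new)
        record("hgt_insertion", (new.origin,))

    # domain gain (appended receiver at the C-terminus)
    k = poisson(cfg.domain_gain_rate, n_tcs0)
    for _ in range(k):
        tcs_now = _tcs_indices(genes)
        if not tcs_now:
            break
        g = genes[tcs_now[int(rng.integers(len(tcs_now)))]]
        start = len(g.sequence) + _LINKER + 1
        dlen = _DOMAIN_LEN["receiver"]
        g.sequence += _rand_seq(rng, _LINKER + dlen + 10)
        g.domains.append(("receiver", None, start, start + dlen - 1))
        record("domain_gain", (g.origin,), kind="receiver")

    # domain loss (never the last remaining TCS domain)
    k = poisson(cfg.domain_loss_rate, n_tcs0)
    for _ in range(k):
        candidates = []
        for i in _tcs_indices(genes):
            g = genes[i]
            tcs_doms = [
                j for j, (kind, _, _, _) in enumerate(g.domains)
                if kind in ("receiver", "transmitter", "phosphoacceptor")
            ]
            removable = tcs_doms if len(tcs_doms) > 1 else []
            removable += [
                j for j, (kind, _, _, _) in enumerate(g.domains) if kind == "output"
            ]
            for j in removable:
                candidates.append((i, j))
        if not candidates:
            break
        i, j = candidates[int(rng.integers(len(candidates)))]
        g = genes[i]
        kind, _, a, b = g.domains[j]
        g.sequence = g.sequence[: a - 1] + g.sequence[b:]
        del g.domains[j]
        _shift_domains(g, a, -(b - a + 1))
        record("domain_loss", (g.origin,), kind=kind)

    # frameshift -> pseudogene, architecture truncated between TCS domains
    tcs_kinds = ("receiver", "transmitter", "phosphoacceptor")
    k = poisson(cfg.frameshift_rate, n_tcs0)
    for _ in range(k):
        candidates = []
        for i in _tcs_indices(genes):
            g = genes[i]
            if g.pseudogene:
                continue
            ordered = sorted(g.domains, key=lambda d: d[2])
            tcs_pos = [j for j, d in enumerate(ordered) if d[0] in tcs_kinds]
            if len(tcs_pos) >= 2:
                # cut points keeping >=1 and dropping >=1 TCS domain
                cuts = [j + 1 for j in tcs_pos[:-1]]
                candidates.append((i, ordered, cuts))
        if not candidates:
            break
        i, ordered, cuts = candidates[int(rng.integers(len(candidates)))]
        g = genes[i]
        cut_after = cuts[int(rng.integers(len(cuts)))]
        keep = ordered[:cut_after]
        new_len = max(b for (_, _, _, b) in keep) + 5
        g.domains = keep
        g.sequence = g.sequence[:new_len]
        g.pseudogene = True
        record("frameshift_pseudogene", (g.origin,), kept=str(cut_after))

    # size indel in the unannotated C-terminal tail
    k = poisson(cfg.size_indel_rate, n_tcs0)
    for _ in range(k):
        tcs_now = _tcs_indices(genes)
        if not tcs_now:
            break
        g = genes[tcs_now[int(rng.integers(len(tcs_now)))]]
        size = max(1, int(rng.normal(cfg.size_indel_mean_aa, cfg.size_indel_mean_aa / 10)))
        tail = len(g.sequence) - _tail_start(g)
        if rng.random() < 0.5 and tail > size:
            g.sequence = g.sequence[: len(g.sequence) - size]
            delta = -size
        else:
            g.sequence += _rand_seq(rng, size)
            delta = size
        record("size_indel", (g.origin,), delta=str(delta))

    # substitutions: 16S at the branch-length rate, TCS proteins scaled
    ssu = _mutate_seq(rng, ssu, length, _NT)
    p_prot = length * cfg.protein_rate_scale
    for g in genes:
        if g.is_tcs:
            g.sequence = _mutate_seq(rng, g.sequence, p_prot, _AA)

    return genes, ssu


def evolve_along_tree(
    ancestor: GenomeBundle, cfg: SimulationConfig
) -> tuple[dict[str, GenomeBundle], TruthLog]:
    """Evolve the ancestor along ``cfg.tree``; returns tip bundles + truth.

    Tip genomes are re-ranked and re-coordinated after structural edits and
    always satisfy the bundle invariants.  Deterministic given the config.
    """
    cfg.validate()
    tree = dendropy.Tree.get(data=cfg.tree, schema="newick", preserve_underscores=True)
    rng = np.random.default_rng([cfg.seed, 2])
    log = TruthLog()
    counters = {"dup": 0, "hgt": 0, "pool": _foreign_pool(cfg)}

    root_genes = _genes_from_bundle(ancestor)
    log.n_ancestral_tcs = sum(g.is_tcs for g in root_genes)

    label_counter = [0]
    bundles: dict[str, GenomeBundle] = {}

    def label_of(node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        if node.label is None:
            label_counter[0] += 1
            node.label = f"n{label_counter[0]}"
        return node.label

    def walk(node, genes: list[_SimGene], ssu: str, path: list[str]) -> None:
        for child in node.child_nodes():
            lbl = label_of(child)
            blen = child.edge.length or 0.0
            child_genes, child_ssu = _apply_branch(
                genes, ssu, blen, lbl, cfg, rng, log, counters
            )
            child_path = path + [lbl]
            if child.is_leaf():
                bundle, origin_of = _freeze(child_genes, lbl, child_ssu)
                bundles[lbl] = bundle
                log.origins[lbl] = origin_of
                log.paths[lbl] = child_path
                tcs_map = {
                    pid: classify_protein(p) for pid, p in bundle.proteins.items()
                }
                notations = {}
                for f in build_foci(bundle, tcs_map):
                    for tag in f.member_locus_tags:
                        notations[tag] = f.notation
                log.notations[lbl] = notations
            else:
                walk(child, child_genes, child_ssu, child_path)

    walk(tree.seed_node, root_genes, ancestor.ssu_rrna or "", [])
    return bundles, log


def make_distance_regimes(
    template: SimulationConfig,
    scales: tuple[float, float, float, float] = (0.005, 0.02, 0.045, 0.09),
) -> list[SimulationConfig]:
    """Four two-tip configs whose expected 16S p-distances occupy disjoint,
    increasing ranges (genus < family < sub-order < order).

    Raises ``ValueError`` for degenerate (non-increasing) scale sets.
    """
    if len(scales) != 4 or any(
        b <= a for a, b in zip(scales, scales[1:])
    ) or scales[0] <= 0:
        raise ValueError("regime scales must be positive and strictly increasing")
    return [
        replace(template, tree=f"(A:{s},B:{s});", seed=template.seed + 1000 * i)
        for i, s in enumerate(scales)
    ]
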