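"""End-to-end pipeline: classify → foci → stats → cluster → distance → events.

Every output table is written with a provenance header line (package
version, config hash, seed) and is byte-stable across reruns of the same
configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .evo_events import (
    EventRecord,
    detect_changes,
    detect_duplications,
    detect_relocations,
    detect_singletons,
    dotplot_points,
    event_frequency_table,
    flag_hgt,
    read_reference,
)
from .focus_builder import Focus, build_foci, cohort_summary, genome_summary
from .genome_io import GenomeBundle, read_bundle
from .ortho_cluster import (
    OrthoCluster,
    flag_clusters,
    orthology_fraction,
    two_tier_cluster,
)
from .phylo_distance import (
    MultipleAlignment,
    bootstrap_support,
    discretise_distances,
    fit_exponential,
    nj_tree,
    p_distance_matrix,
)
from .tcs_classify import classify_protein

log = logging.getLogger("tcskit")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_table"]


@dataclass
class PipelineConfig:
    bundle_dirs: list[str]
    out_dir: str
    high: float = 0.90
    low: float = 0.30
    size_diff_aa: int = 100
    min_segment: int = 3
    max_rank_step: int = 25
    k_bands: int = 4
    bootstrap: int = 0
    seed: int = 0
    reference: Optional[str] = None
    focal_clade: str = "focal"

    def digest(self) -> str:
        return hashlib.md5(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    out_dir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    stats: list = field(default_factory=list)
    clusters: list[OrthoCluster] = field(default_factory=list)
    events: list[EventRecord] = field(default_factory=list)


def write_table(
    path: Path, header: Sequence[str], rows: Sequence[Sequence], provenance: str
) -> Path:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance + "\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


def _fmt(x) -> str:
    return "." if x is None else (f"{x:g}" if isinstance(x, float) else str(x))


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage on the configured bundles; returns paths + objects.

    Comparative stages (clustering, distances, events) require at least two
    genome bundles; with a single bundle only the per-genome stages run.
    """
    if not cfg.bundle_dirs:
        raise ValueError("need at least 1 genome bundle")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = f"# tcskit {__version__} config={cfg.digest()} seed={cfg.seed}"
    result = PipelineResult(out_dir=out)

    bundles: dict[str, GenomeBundle] = {}
    for d in cfg.bundle_dirs:
        b = read_bundle(d)
        bundles[b.genome_id] = b
    log.info("loaded %d bundles: %s", len(bundles), ",".join(sorted(bundles)))

    # classification
    tcs = {
        gid: {pid: classify_protein(p) for pid, p in b.proteins.items()}
        for gid, b in bundles.items()
    }
    rows = [
        (gid, pid, t.tcs_class.value, t.architecture or ".", t.n_receiver,
         t.n_transmitter, t.n_phosphoacceptor, _fmt(t.rr_family), int(t.has_tm))
        for gid in sorted(bundles)
        for pid, t in sorted(tcs[gid].items())
        if t.is_tcs
    ]
    result.tables["classify"] = write_table(
        out / "tcs_proteins.tsv",
        ["genome", "protein_id", "class", "architecture", "n_receiver",
         "n_transmitter", "n_phosphoacceptor", "rr_family", "has_tm"],
        rows, prov,
    )
    log.info("classified %d TCS proteins", len(rows))

    # foci + stats
    foci: dict[str, list[Focus]] = {
        gid: build_foci(b, tcs[gid]) for gid, b in bundles.items()
    }
    rows = [
        (gid, i, ";".join(f.member_locus_tags), f.strand, f.notation,
         f.category.value, int(f.intricate), int(f.at_contig_edge))
        for gid in sorted(bundles)
        for i, f in enumerate(foci[gid])
    ]
    result.tables["foci"] = write_table(
        out / "foci.tsv",
        ["genome", "focus", "members", "strand", "notation", "category",
         "intricate", "at_contig_edge"],
        rows, prov,
    )

    stats = [genome_summary(bundles[g], tcs[g], foci[g]) for g in sorted(bundles)]
    stat_rows = stats + ([cohort_summary(stats)] if stats else [])
    result.stats = stat_rows
    result.tables["stats"] = write_table(
        out / "stats.tsv",
        ["genome", "n_tcs", "n_hk", "n_hybrid", "n_pp", "n_rr", "pct_hybrid",
         "pct_tm_hk", "pct_orphan", "pct_paired", "pct_complex",
         "n_intricate_foci"],
        [
            (s.genome_id, _fmt(s.n_tcs), _fmt(s.n_hk), _fmt(s.n_hybrid),
             _fmt(s.n_pp), _fmt(s.n_rr), _fmt(s.pct_hybrid), _fmt(s.pct_tm_hk),
             _fmt(s.pct_orphan), _fmt(s.pct_paired), _fmt(s.pct_complex),
             _fmt(s.n_intricate_foci))
            for s in stat_rows
        ],
        prov,
    )
    log.info("built %d foci", sum(len(v) for v in foci.values()))

    if len(bundles) < 2:
        log.info("single genome: comparative stages skipped")
        return result

    # clustering over all TCS proteins
    pool = [
        (gid, bundles[gid].proteins[pid])
        for gid in sorted(bundles)
        for pid, t in sorted(tcs[gid].items())
        if t.is_tcs
    ]
    clusters = flag_clusters(
        two_tier_cluster(pool, cfg.high, cfg.low),
        bundles, tcs, foci, cfg.size_diff_aa,
    )
    result.clusters = clusters
    result.tables["clusters"] = write_table(
        out / "clusters.tsv",
        ["cluster_id", "tier", "genome", "protein_id", "representative", "flags"],
        [
            (cl.cluster_id, f"{cl.tier:g}", g, pid, cl.representative,
             ";".join(sorted(cl.flags)) or ".")
            for cl in clusters
            for g, pid in cl.members
        ],
        prov,
    )
    log.info("%d clusters", len(clusters))

    # 16S distances and tree
    ssu_taxa = [g for g in sorted(bundles) if bundles[g].ssu_rrna]
    dm = None
    if len(ssu_taxa) >= 2:
        lengths = {len(bundles[g].ssu_rrna) for g in ssu_taxa}
        if len(lengths) != 1:
            raise ValueError(
                "16S sequences differ in length; supply a pre-computed alignment"
            )
        aln = MultipleAlignment(
            tuple(ssu_taxa), tuple(bundles[g].ssu_rrna for g in ssu_taxa)
        )
        dm = p_distance_matrix(aln)
        result.tables["distances"] = write_table(
            out / "distances.tsv",
            ["a", "b", "p_distance"],
            [
                (a, b, f"{dm.get(a, b):.6g}")
                for a, b in combinations(ssu_taxa, 2)
            ],
            prov,
        )
        if len(ssu_taxa) >= 3:
            tree = nj_tree(dm)
            support = (
                bootstrap_support(aln, cfg.bootstrap, cfg.seed)
                if cfg.bootstrap
                else None
            )
            (out / "tree.nwk").write_text(tree.to_newick(support) + "\n")
            result.tables["tree"] = out / "tree.nwk"
        pair_d = [((a, b), dm.get(a, b)) for a, b in combinations(ssu_taxa, 2)]
        distinct = len({v for _, v in pair_d})
        if distinct >= cfg.k_bands:
            bands = discretise_distances(pair_d, cfg.k_bands)
            result.tables["bands"] = write_table(
                out / "bands.tsv",
                ["a", "b", "band"],
                [(a, b, band) for (a, b), band in sorted(bands.assignment.items())],
                prov,
            )

    # events per genome pair
    reference = read_reference(cfg.reference) if cfg.reference else None
    all_events: list[EventRecord] = []
    dot_rows = []
    decay_points = []
    for a, b in combinations(sorted(bundles), 2):
        singles = detect_singletons(clusters, a, b)
        all_events += singles
        if reference:
            all_events += flag_hgt(singles, bundles, reference, cfg.focal_clade)
        points = dotplot_points(clusters, bundles, a, b)
        all_events += detect_relocations(points, cfg.min_segment, cfg.max_rank_step)
        dot_rows += [
            (a, b, p.a_rank, p.b_rank, p.a_id, p.b_id,
             _fmt(p.segment_id), int(p.outlier))
            for p in points
        ]
        if dm is not None and a in ssu_taxa and b in ssu_taxa:
            decay_points.append(((a, b), dm.get(a, b), orthology_fraction(clusters, a, b)))
    all_events += detect_duplications(clusters, bundles)
    all_events += detect_changes(clusters, bundles, tcs, foci, cfg.size_diff_aa)
    result.events = all_events

    result.tables["events"] = write_table(
        out / "events.tsv",
        ["event_type", "genomes", "cluster_id", "loci", "detail"],
        [
            (e.event_type.value, ";".join(e.genomes) or ".", _fmt(e.cluster_id),
             ";".join(e.loci) or ".",
             ";".join(f"{k}={v}" for k, v in e.detail) or ".")
            for e in all_events
        ],
        prov,
    )
    freq = event_frequency_table(all_events, clusters)
    result.tables["freq"] = write_table(
        out / "freq.tsv",
        ["event_type", "numerator", "denominator", "percentage"],
        [(et.value, n, d, f"{p:g}") for et, n, d, p in freq.rows],
        prov,
    )
    result.tables["dotplot"] = write_table(
        out / "dotplot.tsv",
        ["genome_a", "genome_b", "a_rank", "b_rank", "a_id", "b_id",
         "segment", "outlier"],
        dot_rows, prov,
    )
    if decay_points:
        fit_row = []
        positive = [(d, y) for _, d, y in decay_points if y > 0]
        if len(positive) >= 2 and len({d for d, _ in positive}) >= 2:
            a_fit, b_fit, resid = fit_exponential(positive)
            fit_row = [("FIT", f"{a_fit:.6g}", f"{b_fit:.6g}", f"{resid:.3g}")]
        result.tables["decay"] = write_table(
            out / "decay.tsv",
            ["pair", "p_distance", "orthology_fraction", "extra"],
            [
                (f"{a}|{b}", f"{d:.6g}", f"{y:.6g}", ".")
                for (a, b), d, y in decay_points
            ] + fit_row,
            prov,
        )
    log.info("%d events", len(all_events))
    return result
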