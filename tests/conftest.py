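"""Shared fixtures and bundle-construction helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from tcskit.genome_io import DomainHit, GeneRecord, GenomeBundle, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"

DOMAIN_LEN = {
    "receiver": 120,
    "transmitter": 220,
    "phosphoacceptor": 90,
    "output": 100,
    "input": 110,
}
SYMBOL_KIND = {"R": "receiver", "T": "transmitter", "H": "phosphoacceptor"}


def rand_protein_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def protein_from_arch(
    pid: str,
    arch: str,
    rng: np.random.Generator,
    rr_family: str | None = None,
    has_tm: bool = False,
    extra_tail: int = 0,
) -> ProteinRecord:
    """Build a protein whose R/T/H architecture is exactly ``arch``."""
    domains = []
    pos = 25
    if has_tm:
        domains.append(DomainHit(pid, "TM", None, 2, 21))
    for sym in arch:
        kind = SYMBOL_KIND[sym]
        domains.append(DomainHit(pid, kind, None, pos, pos + DOMAIN_LEN[kind] - 1))
        pos += DOMAIN_LEN[kind] + 15
    if rr_family is not None:
        domains.append(DomainHit(pid, "output", rr_family, pos, pos + 99))
        pos += 115
    seq = rand_protein_seq(rng, pos + 10 + extra_tail)
    return ProteinRecord.make(pid, seq, domains)


def bundle_from_layout(
    genome_id: str,
    layout: list[tuple[str, str | None] | tuple[str, str | None, dict]],
    seed: int = 0,
    ssu: str | None = None,
    complete: bool = True,
) -> GenomeBundle:
    """Build a single-contig bundle from ``[(strand, arch-or-None, opts?)]``.

    ``arch=None`` plants a background (non-TCS) gene.  Options per gene:
    ``rr_family``, ``has_tm``, ``pseudogene``, ``extra_tail``.
    """
    rng = np.random.default_rng(seed)
    genes, proteins = [], {}
    pos = 1
    for i, entry in enumerate(layout):
        strand, arch = entry[0], entry[1]
        opts = entry[2] if len(entry) > 2 else {}
        pid = f"{genome_id}_p{i:04d}"
        if arch is None:
            prot = ProteinRecord.make(pid, rand_protein_seq(rng, 200))
        else:
            prot = protein_from_arch(
                pid,
                arch,
                rng,
                rr_family=opts.get("rr_family"),
                has_tm=opts.get("has_tm", False),
                extra_tail=opts.get("extra_tail", 0),
            )
        glen = 3 * (prot.length + 1)
        genes.append(
            GeneRecord(
                locus_tag=f"{genome_id}_g{i:04d}",
                contig="chr",
                rank=i,
                strand=strand,
                start=pos,
                end=pos + glen - 1,
                pseudogene=opts.get("pseudogene", False),
                protein_id=pid,
            )
        )
        proteins[pid] = prot
        pos += glen + 100
    return GenomeBundle(genome_id, genes, proteins, ssu, complete)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_bundle():
    """Background, T(+), R(+), background, background: one paired focus."""
    return bundle_from_layout(
        "gx",
        [("+", None), ("+", "T"), ("+", "R", {"rr_family": "OmpR"}),
         ("-", None), ("+", None)],
    )


def all_notations(max_domains: int = 4) -> list[str]:
    """Every R/T/H notation string with up to ``max_domains`` domains."""
    out = []
    for total in range(1, max_domains + 1):
        for symbols in itertools.product("RTH", repeat=total):
            # all ways to split the symbol run into consecutive genes
            for cuts in itertools.product([False, True], repeat=total - 1):
                genes, cur = [], [symbols[0]]
                for sym, cut in zip(symbols[1:], cuts):
                    if cut:
                        genes.append("".join(cur))
                        cur = [sym]
                    else:
                        cur.append(sym)
                genes.append("".join(cur))
                out.append(",".join(genes))
    return sorted(set(out))
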