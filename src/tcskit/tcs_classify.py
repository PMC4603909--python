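"""Classification of two-component-system (TCS) proteins from domain content.

A protein's TCS character is read off its annotated domains:

* ``transmitter`` (T) — the kinase core.  Input data may carry transmitters
  pre-merged, or split into a phosphoacceptor region followed by an
  ATPase-type region; :func:`transmitter_from_parts` normalises the latter.
* ``receiver`` (R) — the phospho-accepting regulatory domain.
* ``phosphoacceptor`` (H) — an isolated HisKA/Hpt-like domain.

Classes: a histidine kinase (HK) has at least one transmitter; a hybrid
kinase additionally has at least one receiver; a response regulator (RR)
has receivers but no transmitter; a phosphotransfer protein (PP) has only
phosphoacceptor TCS domains.  The architecture string lists the protein's
R/T/H domains in N→C order.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome_io import DomainHit, ProteinRecord

__all__ = [
    "TCSClass",
    "TCSProtein",
    "transmitter_from_parts",
    "classify_protein",
    "composition_matrix",
    "T_BANDS",
    "R_BANDS",
]

#: Default maximum residue gap between a phosphoacceptor and the ATPase
#: region that together constitute a transmitter.
DEFAULT_MERGE_GAP = 200

_SYMBOL = {"receiver": "R", "transmitter": "T", "phosphoacceptor": "H"}

#: Row labels (transmitter-count bands) of the composition matrix.
T_BANDS = ("0T", "1T", "2+T")
#: Column labels (receiver-count bands) of the composition matrix.
R_BANDS = ("0R", "1R", "2R", "3R", "4+R")


class TCSClass(Enum):
    HK = "HK"
    HYBRID_HK = "HYBRID_HK"
    RR = "RR"
    PP = "PP"
    NONE = "NONE"


@dataclass(frozen=True)
class TCSProtein:
    """A protein's TCS classification and R/T/H architecture."""

    protein_id: str
    tcs_class: TCSClass
    architecture: str
    n_receiver: int
    n_transmitter: int
    n_phosphoacceptor: int
    rr_family: Optional[str] = None
    has_tm: bool = False

    @property
    def is_tcs(self) -> bool:
        return self.tcs_class is not TCSClass.NONE


def _is_atpase_input(hit: DomainHit) -> bool:
    return hit.kind == "input" and hit.subtype is not None and "atpase" in hit.subtype.lower()


def transmitter_from_parts(
    domains: Sequence[DomainHit], max_gap: int = DEFAULT_MERGE_GAP
) -> list[DomainHit]:
    """Merge phosphoacceptor + ATPase-region pairs into transmitter hits.

    Each phosphoacceptor hit whose next annotated domain is an ATPase-type
    input region starting within ``max_gap`` residues is replaced by a single
    transmitter hit spanning both.  Unpaired phosphoacceptors are left as-is,
    and already-merged transmitters pass through unchanged (idempotent).
    """
    ordered = sorted(domains, key=lambda d: (d.start, d.end, d.kind))
    out: list[DomainHit] = []
    i = 0
    while i < len(ordered):
        d = ordered[i]
        nxt = ordered[i + 1] if i + 1 < len(ordered) else None
        if (
            d.kind == "phosphoacceptor"
            and nxt is not None
            and _is_atpase_input(nxt)
            and nxt.start - d.end <= max_gap
        ):
            out.append(DomainHit(d.protein_id, "transmitter", None, d.start, nxt.end))
            i += 2
        else:
            out.append(d)
            i += 1
    return out


def classify_protein(
    p: ProteinRecord, merge_gap: int = DEFAULT_MERGE_GAP
) -> TCSProtein:
    """Classify one protein and compute its architecture string.

    Total over all inputs: proteins with no receiver/transmitter/
    phosphoacceptor domain classify as ``NONE``.
    """
    domains = transmitter_from_parts(p.domains, max_gap=merge_gap)

    arch = "".join(_SYMBOL[d.kind] for d in domains if d.kind in _SYMBOL)
    n_r = arch.count("R")
    n_t = arch.count("T")
    n_h = arch.count("H")

    if n_t >= 1 and n_r >= 1:
        cls = TCSClass.HYBRID_HK
    elif n_t >= 1:
        cls = TCSClass.HK
    elif n_r >= 1:
        cls = TCSClass.RR
    elif n_h >= 1:
        cls = TCSClass.PP
    else:
        cls = TCSClass.NONE

    rr_family = None
    if n_r >= 1:
        for d in domains:
            if d.kind == "output":
                rr_family = d.subtype
                break

    return TCSProtein(
        protein_id=p.protein_id,
        tcs_class=cls,
        architecture=arch,
        n_receiver=n_r,
        n_transmitter=n_t,
        n_phosphoacceptor=n_h,
        rr_family=rr_family,
        has_tm=any(d.kind == "TM" for d in domains),
    )


def _t_band(n: int) -> int:
    return min(n, 2)


def _r_band(n: int) -> int:
    return min(n, 4)


def composition_matrix(proteins: Iterable[TCSProtein]) -> np.ndarray:
    """Count classified TCS proteins by (transmitter band, receiver band).

    Rows are :data:`T_BANDS` (0, 1, 2+ transmitters); columns :data:`R_BANDS`
    (0, 1, 2, 3, 4+ receivers).  The (0T, 0R) cell counts PP-only proteins;
    ``NONE`` proteins are excluded.
    """
    m = np.zeros((len(T_BANDS), len(R_BANDS)), dtype=int)
    for p in proteins:
        if p.is_tcs:
            m[_t_band(p.n_transmitter), _r_band(p.n_receiver)] += 1
    return m
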