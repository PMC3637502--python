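"""Complementarity-penalty target prediction for plant miRNAs.

Plant miRNAs bind their mRNA targets with perfect or near-perfect
complementarity, so candidate sites are found by scoring every
mature-length window on the sense strand of each unigene against the mature
aligned antiparallel: Watson-Crick pairs cost 0, G:U wobbles 0.5, any other
apposition 1.0.  Windows whose summed penalty stays within a budget
(default 4.0, the standard EST-complementarity cutoff) are reported, with
overlapping same-miRNA windows collapsed to the best one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._sequtils import dna_to_rna
from .io_formats import MatureMirna, SequenceRecord

MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
DEFAULT_MAX_PENALTY = 4.0

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

_BASES = "ACGU"
_B_INDEX = {b: i for i, b in enumerate(_BASES + "N")}
# penalty[mature_base, site_base(transcribed)]
_PENALTY = np.full((5, 5), MISMATCH_PENALTY)
for (m, t) in _WC:
    _PENALTY[_B_INDEX[m], _B_INDEX[t]] = 0.0
for (m, t) in _WOBBLE:
    _PENALTY[_B_INDEX[m], _B_INDEX[t]] = WOBBLE_PENALTY
_PENALTY[_B_INDEX["N"], :] = MISMATCH_PENALTY
_PENALTY[:, _B_INDEX["N"]] = MISMATCH_PENALTY


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    unigene_id: str
    site_start: int  # 1-based on the unigene, inclusive
    site_end: int
    penalty: float
    alignment: str = ""


def pair_penalty(mature_base: str, site_base_rna: str) -> float:
    """Penalty of apposing one mature base to one (transcribed) target base."""
    return float(_PENALTY[_B_INDEX[mature_base], _B_INDEX[site_base_rna]])


def score_site(mirna: MatureMirna | str, site: str) -> float:
    """Penalty of a mature miRNA against an equal-length DNA site window.

    The site (mRNA sense, 5'->3') is transcribed and apposed antiparallel to
    the mature: mature position i faces site position L-1-i.
    """
    mseq = mirna.seq if isinstance(mirna, MatureMirna) else mirna
    if len(mseq) != len(site):
        raise ValueError(f"site length {len(site)} != mature length {len(mseq)}")
    site_rna = dna_to_rna(site.upper())
    total = 0.0
    L = len(mseq)
    for i, mb in enumerate(mseq):
        total += pair_penalty(mb, site_rna[L - 1 - i])
    return total


def render_alignment(mirna: MatureMirna | str, site: str) -> str:
    """Text alignment, mature 3'->5' over the site 5'->3'."""
    mseq = mirna.seq if isinstance(mirna, MatureMirna) else mirna
    site_rna = dna_to_rna(site.upper())
    mid = []
    for i, sb in enumerate(site_rna):
        mb = mseq[len(mseq) - 1 - i]
        if (mb, sb) in _WC:
            mid.append("|")
        elif (mb, sb) in _WOBBLE:
            mid.append("o")
        else:
            mid.append(" ")
    return (
        f"miRNA  3' {mseq[::-1]} 5'\n"
        f"          {''.join(mid)}\n"
        f"target 5' {site_rna} 3'"
    )


def _window_penalties(mature: MatureMirna, unigene: SequenceRecord) -> np.ndarray:
    """Penalty of every mature-length window of a unigene (vectorized)."""
    L = mature.length
    codes = np.array(
        [_B_INDEX[b] for b in dna_to_rna(unigene.seq)], dtype=np.intp
    )
    if codes.size < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    m_rev = np.array([_B_INDEX[b] for b in mature.seq[::-1]], dtype=np.intp)
    return _PENALTY[m_rev[None, :], windows].sum(axis=1)


def find_targets(
    mirnas: Sequence[MatureMirna],
    unigenes: Sequence[SequenceRecord],
    max_penalty: float = DEFAULT_MAX_PENALTY,
    with_alignment: bool = True,
) -> list[TargetHit]:
    """Scan unigene sense strands for target sites within the penalty budget.

    Overlapping hits of one miRNA on one unigene are collapsed to the
    minimum-penalty window (ties: leftmost).  Hits are sorted by
    (mirna_id, unigene_id, site_start).
    """
    if not mirnas or not unigenes:
        raise ValueError("mirnas and unigenes must be non-empty")
    hits: list[TargetHit] = []
    for mir in mirnas:
        L = mir.length
        for uni in unigenes:
            pens = _window_penalties(mir, uni)
            keep = np.nonzero(pens <= max_penalty)[0]
            if keep.size == 0:
                continue
            # collapse overlapping windows: greedy cluster sweep left to right
            clusters: list[list[int]] = []
            for off in keep:
                if clusters and off <= clusters[-1][-1] + L - 1:
                    clusters[-1].append(int(off))
                else:
                    clusters.append([int(off)])
            for cluster in clusters:
                best = min(cluster, key=lambda o: (pens[o], o))
                site = uni.seq[best : best + L]
                hits.append(
                    TargetHit(
                        mirna_id=mir.id,
                        unigene_id=uni.id,
                        site_start=best + 1,
                        site_end=best + L,
                        penalty=float(pens[best]),
                        alignment=render_alignment(mir, site) if with_alignment else "",
                    )
                )
    hits.sort(key=lambda h: (h.mirna_id, h.unigene_id, h.site_start))
    return hits
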