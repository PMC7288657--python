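"""SNP-targeting guide-RNA enumeration and filtering.

Candidates are every 19-base protospacer followed by an SpCas9 NGG PAM on
either strand of a screening window around the target SNP.  Filters mirror
a practical screening design: GC fraction within [10%, 80%] (boundaries
kept) and blunt-cut site within 10 nt of the SNP.  A naive exhaustive
Hamming-distance scan over a genome stands in for dedicated off-target
predictors; it counts NGG-adjacent protospacer matches with up to two
mismatches (no bulges, no scoring model).

Coordinates are 0-based internally; the blunt Cas9 cut falls between the
3rd and 4th nucleotide 5' of the PAM, and ``cut_pos`` records the base
immediately 5' of the scission on the candidate's own strand.  These
conventions are fixed and stated in the TSV output header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

__all__ = [
    "GuideCandidate",
    "enumerate_candidates",
    "gc_filter",
    "cut_distance_filter",
    "count_offtargets",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer/PAM hit near a target SNP.

    ``protospacer`` and ``pam`` are given on the candidate's strand;
    window-frame coordinates (``protospacer_start``, ``cut_pos``) are
    always in forward-strand space.
    """

    protospacer: str
    pam: str
    strand: str  # '+' or '-'
    protospacer_start: int  # 0-based window offset (forward-strand frame)
    cut_pos: int  # 0-based; base immediately 5' of the blunt scission
    gc_fraction: float
    snp_distance: int

    def __post_init__(self) -> None:
        if self.pam[1:3] != "GG":
            raise ValueError("PAM must match NGG on the candidate strand")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def enumerate_candidates(
    window: str,
    snp_pos: int,
    protospacer_len: int = 19,
) -> list[GuideCandidate]:
    """Enumerate all protospacer+NGG candidates on both strands of a window.

    ``snp_pos`` is the 0-based offset of the target SNP inside the window.
    Reverse-strand hits are reported in forward-window coordinates with
    strand '-'.  Candidates whose span contains an ambiguous base are
    excluded with a logged reason.  Output order is deterministic: by
    protospacer start, then strand ('+' before '-').
    """
    window = window.upper()
    L = len(window)
    if not 0 <= snp_pos < L:
        raise ValueError("snp_pos must lie inside the window")
    if protospacer_len < 1:
        raise ValueError("protospacer_len must be positive")
    out: list[GuideCandidate] = []

    for start in range(0, L - protospacer_len - 2):
        proto = window[start : start + protospacer_len]
        pam = window[start + protospacer_len : start + protospacer_len + 3]
        if pam[1:3] == "GG":
            span = proto + pam
            if not set(span) <= _VALID:
                logger.info("skipping + candidate at %d: ambiguous base in span", start)
                continue
            # scission between the 3rd and 4th nt 5' of the PAM
            cut = start + protospacer_len - 4
            out.append(
                GuideCandidate(
                    protospacer=proto,
                    pam=pam,
                    strand="+",
                    protospacer_start=start,
                    cut_pos=cut,
                    gc_fraction=_gc(proto),
                    snp_distance=abs(cut - snp_pos),
                )
            )

    # minus strand: PAM appears as CCN in the forward frame, protospacer 3' of it
    for i in range(0, L - protospacer_len - 2):
        if window[i : i + 2] == "CC":
            span = window[i : i + 3 + protospacer_len]
            if len(span) < 3 + protospacer_len:
                continue
            if not set(span) <= _VALID:
                logger.info("skipping - candidate at %d: ambiguous base in span", i)
                continue
            proto_fwd = window[i + 3 : i + 3 + protospacer_len]
            # on the minus strand, 5' of the scission means the larger
            # forward-frame index
            cut = i + 6
            out.append(
                GuideCandidate(
                    protospacer=reverse_complement(proto_fwd),
                    pam=reverse_complement(window[i : i + 3]),
                    strand="-",
                    protospacer_start=i + 3,
                    cut_pos=cut,
                    gc_fraction=_gc(proto_fwd),
                    snp_distance=abs(cut - snp_pos),
                )
            )

    out.sort(key=lambda c: (c.protospacer_start, 0 if c.strand == "+" else 1))
    return out


def gc_filter(
    cands: list[GuideCandidate], low: float = 0.10, high: float = 0.80
) -> list[GuideCandidate]:
    """Keep candidates with ``low <= gc_fraction <= high``.

    The semantics are strict readings of "over 80%" and "less than 10%"
    being removed, so both boundary values survive.
    """
    return [c for c in cands if low <= c.gc_fraction <= high]


def cut_distance_filter(
    cands: list[GuideCandidate], snp_pos: int, max_dist: int = 10
) -> list[GuideCandidate]:
    """Keep candidates whose cut site is not more than ``max_dist`` nt from
    the SNP (distance recomputed against ``snp_pos`` in the window frame)."""
    return [c for c in cands if abs(c.cut_pos - snp_pos) <= max_dist]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def count_offtargets(
    cand: GuideCandidate | str,
    genome,
    max_mismatch: int = 2,
) -> dict[int, int]:
    """Count NGG-adjacent protospacer matches at Hamming distance 0..max_mismatch.

    ``genome`` is a sequence, an iterable of sequences, or a mapping
    ``name -> sequence``; both strands of every sequence are scanned
    exhaustively.  The on-target site (if present) is included in the
    0-mismatch count.  Bulges and non-NGG PAMs are not considered.
    """
    proto = cand.protospacer if isinstance(cand, GuideCandidate) else str(cand)
    proto = proto.upper()
    n = len(proto)
    if isinstance(genome, str):
        seqs = [genome]
    elif hasattr(genome, "values") and not isinstance(genome, (list, tuple)):
        seqs = list(genome.values())
    else:
        seqs = list(genome)
    counts = {k: 0 for k in range(max_mismatch + 1)}
    for seq in seqs:
        seq = str(seq).upper()
        for s in (seq, reverse_complement(seq)):
            for i in range(0, len(s) - n - 2):
                if s[i + n + 1 : i + n + 3] != "GG":
                    continue
                d = _hamming(proto, s[i : i + n])
                if d <= max_mismatch:
                    counts[d] += 1
    return counts
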