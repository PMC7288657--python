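"""Hard-filter cascade for RNA-seq variant calls and clone-divergence summaries.

RNA-seq variant calling has a high false-positive rate (reverse
transcriptase errors, allele-specific expression), so called SNVs pass a
cascade of hard filters before clones are compared: dense SNP clusters are
excluded, low-depth calls dropped, calls must be consistent between the two
biological replicates of a clone, and only exonic polymorphisms count.
Every stage only removes calls, is deterministic and is independent of
input record order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

__all__ = [
    "VariantCall",
    "filter_snp_clusters",
    "filter_depth",
    "replicate_consistent",
    "exonic_only",
    "clone_divergence",
    "merge_intervals",
]


@dataclass(frozen=True)
class VariantCall:
    """A called single-nucleotide variant (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int = 0
    replicate_id: str | None = None
    exonic: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _sorted_calls(calls: list[VariantCall]) -> list[VariantCall]:
    keys = [(c.chrom, c.pos) for c in calls]
    if keys != sorted(keys):
        warnings.warn("calls were not sorted by (chrom, pos); sorting internally",
                      stacklevel=3)
        return sorted(calls, key=lambda c: (c.chrom, c.pos))
    return list(calls)


def filter_snp_clusters(
    calls: list[VariantCall], cluster_size: int = 3, window: int = 35
) -> list[VariantCall]:
    """Remove every SNV belonging to a dense cluster.

    A cluster is any run of ``cluster_size`` consecutive SNVs (per
    chromosome) whose first and last positions span at most ``window``
    bases (``pos_last - pos_first <= window``).  All members of any such
    run are removed.  Indels bypass this filter.
    """
    calls = _sorted_calls(calls)
    snvs = [c for c in calls if c.is_snv]
    doomed: set[int] = set()
    by_chrom: dict[str, list[VariantCall]] = {}
    for c in snvs:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom_calls in by_chrom.values():
        pos = [c.pos for c in chrom_calls]
        for i in range(len(pos) - cluster_size + 1):
            j = i + cluster_size - 1
            if pos[j] - pos[i] <= window:
                for k in range(i, j + 1):
                    doomed.add(id(chrom_calls[k]))
    return [c for c in calls if id(c) not in doomed]


def filter_depth(calls: list[VariantCall], min_depth: int = 50) -> list[VariantCall]:
    """Keep calls with read depth >= ``min_depth`` (the boundary is kept)."""
    return [c for c in calls if c.depth >= min_depth]


def replicate_consistent(
    calls_rep1: list[VariantCall], calls_rep2: list[VariantCall]
) -> list[VariantCall]:
    """Site-level intersection of two biological replicates of one clone.

    Calls are matched on (chrom, pos, ref, alt); the surviving call carries
    the minimum of the two depths.
    """
    second = {c.key: c for c in calls_rep2}
    out = []
    for c in calls_rep1:
        other = second.get(c.key)
        if other is not None:
            out.append(replace(c, depth=min(c.depth, other.depth), replicate_id=None))
    return out


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/touching half-open intervals."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def exonic_only(
    calls: list[VariantCall], exon_intervals: dict[str, list[tuple[int, int]]]
) -> list[VariantCall]:
    """Keep calls falling inside an exon.

    ``exon_intervals`` maps chromosome to half-open 0-based ``(start, end)``
    intervals (BED convention); overlapping intervals are merged first.  A
    1-based call position ``pos`` is exonic when ``start <= pos - 1 < end``
    for some interval.
    """
    merged = {chrom: merge_intervals(ivs) for chrom, ivs in exon_intervals.items()}
    out = []
    for c in calls:
        for start, end in merged.get(c.chrom, ()):
            if start <= c.pos - 1 < end:
                out.append(c)
                break
    return out


def clone_divergence(
    clone_calls: list[VariantCall],
    consensus_calls: list[VariantCall],
    n_sites_assessed: int,
) -> tuple[int, float]:
    """Count sites where a clone differs from the bulk consensus.

    The count is the symmetric difference on (chrom, pos, ref, alt); the
    fraction is reported as a percentage rounded to 2 decimals of
    ``count / n_sites_assessed``.
    """
    if n_sites_assessed <= 0:
        raise ValueError("n_sites_assessed must be positive")
    diff = {c.key for c in clone_calls} ^ {c.key for c in consensus_calls}
    count = len(diff)
    if count > n_sites_assessed:
        raise ValueError("more differing sites than sites assessed")
    return count, round(100.0 * count / n_sites_assessed, 2)
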