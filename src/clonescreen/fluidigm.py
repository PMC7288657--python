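"""Fluidigm-style qRT-PCR processing: Ct transform, QC filters, batch
adjustment and clone-vs-control comparisons.

Raw cycle-threshold (Ct) values from a 48x48 nanoscale chip are transformed
to ``max(0, 30 - Ct)`` so that each unit increment represents, in theory, a
doubling of initial transcript abundance and 0 means unexpressed.  QC then
removes samples with too many unexpressed probes and probes detected in too
few samples (in that order), a per-batch location-scale adjustment removes
the fresh/frozen offset and standardises every probe to mean 0, sd 1, and
edited clones are compared to negative controls with per-probe two-sample
t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "ct_to_expression",
    "filter_samples",
    "filter_probes",
    "adjust_batch",
    "compare_to_control",
    "average_technical_replicates",
]


@dataclass
class ExpressionMatrix:
    """Samples x probes expression values with aligned metadata.

    ``values`` rows are samples, columns probes.  ``sample_meta`` (indexed
    like the rows) typically carries ``batch``, ``clone``, ``guide``,
    ``target`` and a boolean ``control`` flag; ``probe_meta`` (indexed like
    the columns) may flag housekeeping probes.  Metadata alignment is
    enforced; either table may be None.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    probe_meta: pd.DataFrame | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.sample_meta is not None and not self.values.index.equals(
            self.sample_meta.index
        ):
            raise ValueError("sample_meta index must match the value rows")
        if self.probe_meta is not None and not self.values.columns.equals(
            self.probe_meta.index
        ):
            raise ValueError("probe_meta index must match the value columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def subset(self, samples=None, probes=None) -> "ExpressionMatrix":
        v = self.values
        sm, pm = self.sample_meta, self.probe_meta
        if samples is not None:
            v = v.loc[samples]
            sm = sm.loc[samples] if sm is not None else None
        if probes is not None:
            v = v[probes]
            pm = pm.loc[probes] if pm is not None else None
        return ExpressionMatrix(v, sm, pm, standardized=self.standardized)


def ct_to_expression(
    ct_matrix: pd.DataFrame,
    sample_meta: pd.DataFrame | None = None,
    probe_meta: pd.DataFrame | None = None,
    max_cycles: int = 30,
) -> ExpressionMatrix:
    """Transform Ct values to the 30-Ct expression scale.

    Each value becomes ``max(0, max_cycles - Ct)``; reactions at or beyond
    the cycle ceiling, and missing reactions (NaN), become 0 (unexpressed).
    Negative Ct values are rejected.
    """
    ct = ct_matrix.astype(float)
    if (ct.to_numpy() < 0).any():
        raise ValueError("negative Ct values are not meaningful")
    expr = (max_cycles - ct).clip(lower=0.0).fillna(0.0)
    return ExpressionMatrix(expr, sample_meta, probe_meta)


def filter_samples(m: ExpressionMatrix, max_unexpressed: int = 40) -> ExpressionMatrix:
    """Drop samples with strictly more than ``max_unexpressed`` zero-valued
    probes ("unexpressed" = exactly 0 on the 30-Ct scale).  Survivor order
    is preserved."""
    zeros = (m.values == 0).sum(axis=1)
    keep = m.values.index[zeros <= max_unexpressed]
    if len(keep) == 0:
        warnings.warn("sample filter removed every sample", stacklevel=2)
    return m.subset(samples=keep)


def filter_probes(m: ExpressionMatrix, min_samples: int = 5) -> ExpressionMatrix:
    """Drop probes expressed (nonzero) in fewer than ``min_samples`` samples."""
    expressed = (m.values != 0).sum(axis=0)
    keep = m.values.columns[expressed >= min_samples]
    dropped = m.values.columns.difference(keep)
    if (
        len(dropped)
        and m.probe_meta is not None
        and "housekeeping" in m.probe_meta.columns
        and m.probe_meta.loc[dropped, "housekeeping"].any()
    ):
        warnings.warn("probe filter removed housekeeping probes", stacklevel=2)
    return m.subset(probes=keep)


def adjust_batch(m: ExpressionMatrix, batch_labels=None) -> ExpressionMatrix:
    """Remove a batch offset and standardise each probe to mean 0, sd 1.

    Per probe, each batch's values are centred on the batch mean and
    divided by the batch sd (a location-scale adjustment), after which the
    probe is re-standardised across all samples.  Batches with a single
    sample are rejected.  When the batches are identical in distribution
    the result equals plain per-probe standardisation.
    """
    if batch_labels is None:
        if m.sample_meta is None or "batch" not in m.sample_meta.columns:
            raise ValueError("batch labels required (argument or sample_meta['batch'])")
        batch_labels = m.sample_meta["batch"]
    batch = pd.Series(np.asarray(batch_labels), index=m.values.index)
    counts = batch.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"batches with a single sample cannot be adjusted: {bad}")

    adj = m.values.copy()
    for _, idx in adj.groupby(batch).groups.items():
        block = adj.loc[idx]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1).replace(0.0, 1.0)
        adj.loc[idx] = (block - mu) / sd
    mu = adj.mean(axis=0)
    sd = adj.std(axis=0, ddof=1).replace(0.0, 1.0)
    out = (adj - mu) / sd
    return ExpressionMatrix(out, m.sample_meta, m.probe_meta, standardized=True)


def compare_to_control(
    m: ExpressionMatrix,
    probe: str,
    control_samples,
    group_samples,
) -> tuple[float, float]:
    """Two-sided two-sample t-test of one probe: edited group vs controls.

    Returns ``(difference of means, p-value)``; the significance star
    convention downstream is p < 0.05.  Exact ties with zero variance in
    both groups yield p = 1 with a warning.
    """
    x = m.values.loc[list(group_samples), probe].to_numpy(dtype=float)
    y = m.values.loc[list(control_samples), probe].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    est = float(x.mean() - y.mean())
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        warnings.warn("degenerate (constant) groups; p set by exact-tie rule", stacklevel=2)
        return est, 1.0 if est == 0 else 0.0
    t, p = stats.ttest_ind(x, y)
    return est, float(p)


def average_technical_replicates(
    tidy: pd.DataFrame,
    sample_col: str = "sample",
    probe_col: str = "probe",
    value_col: str = "ct",
) -> pd.DataFrame:
    """Average technical replicate reactions per (sample, probe).

    Applied before QC when replicate structure is present; each returned
    datum is the mean of the replicate Ct reactions.
    """
    out = tidy.groupby([sample_col, probe_col], sort=False)[value_col].mean().unstack(probe_col)
    out.index.name = None
    out.columns.name = None
    return out
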