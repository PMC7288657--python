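"""Synthetic-data generators for every pipeline stage.

All generators are deterministic given a seed and never emit values outside
their declared ranges.  Four kinds of fixtures are produced:

* mixed-model expression measurements with guide/clone/batch/replicate
  structure (:func:`simulate_experiment`);
* 48x48 Fluidigm-like Ct chips with a fresh/frozen batch shift
  (:func:`simulate_chip`);
* small genomes with one annotated SNP for guide design
  (:func:`simulate_genome_with_snp`);
* toy variant-call sets for the hard-filter cascade
  (:func:`simulate_variant_calls`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ExperimentDesign

__all__ = [
    "simulate_experiment",
    "simulate_measurement_arrays",
    "ChipSpec",
    "simulate_chip",
    "simulate_genome_with_snp",
    "simulate_variant_calls",
]

MEASUREMENT_COLUMNS = ["guide", "clone", "batch", "replicate", "value"]


def simulate_measurement_arrays(
    design: ExperimentDesign, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_sims`` independent experiments as a ``(n_sims, n_clones,
    replicates)`` array of expression values in sdu.

    The value of measurement k of clone j (belonging to guide g, batch b) is

        effect_sdu * 1[g causal] + clone_j + batch_b + eps_jk

    with ``clone_j ~ N(0, sigma_clone^2)`` drawn once per clone,
    ``batch_b ~ N(0, sigma_batch^2)`` once per batch and
    ``eps ~ N(0, sigma_resid^2)`` per measurement.  This vectorised kernel
    is the workhorse of the Monte Carlo power engine;
    :func:`simulate_experiment` wraps it for a single labelled dataset.
    """
    guides, batches = design.clone_table()
    C, r = design.n_clones, design.replicates
    causal = np.isin(guides, list(design.causal_guides))

    values = rng.normal(0.0, design.sigma_resid, size=(n_sims, C, r))
    if design.sigma_clone > 0:
        values += rng.normal(0.0, design.sigma_clone, size=(n_sims, C))[:, :, None]
    if design.sigma_batch > 0:
        batch_eff = rng.normal(0.0, design.sigma_batch, size=(n_sims, design.n_batches))
        values += batch_eff[:, batches][:, :, None]
    values += np.where(causal, design.effect_sdu, 0.0)[None, :, None]
    return values


def simulate_experiment(design: ExperimentDesign, seed: int) -> pd.DataFrame:
    """Simulate one experiment as tidy labelled measurements.

    Returns a DataFrame with columns ``guide, clone, batch, replicate,
    value`` -- one row per (clone, replicate), clone ids unique across
    guides.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(seed)
    values = simulate_measurement_arrays(design, 1, rng)[0]
    guides, batches = design.clone_table()
    C, r = design.n_clones, design.replicates
    return pd.DataFrame(
        {
            "guide": np.repeat(guides, r),
            "clone": np.repeat(np.arange(C), r),
            "batch": np.repeat(batches, r),
            "replicate": np.tile(np.arange(r), C),
            "value": values.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# Fluidigm-like chips
# ---------------------------------------------------------------------------


@dataclass
class ChipSpec:
    """Specification of a simulated nanoscale qRT-PCR chip.

    Defaults emulate the 48x48 chip of the screening experiment: 2304
    assays, 30 amplification cycles, half the samples from fresh cells and
    half from a frozen aliquot with an additive Ct offset, and a bimodal
    abundance profile (a minority of probes near the detection floor).
    """

    n_samples: int = 48
    n_probes: int = 48
    max_cycles: int = 30
    batch_labels: tuple[str, str] = ("fresh", "frozen")
    batch_shift: float = 2.0  # additive Ct offset applied to the second batch
    probe_means: np.ndarray | None = None  # per-probe mean Ct; drawn if None
    probe_sds: np.ndarray | float = 1.0
    dropout_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_probes < 1:
            raise ValueError("chip must have >= 2 samples and >= 1 probe")
        if not 0 <= self.dropout_fraction <= 1:
            raise ValueError("dropout_fraction must be in [0, 1]")
        if self.max_cycles <= 0:
            raise ValueError("max_cycles must be positive")

    @property
    def n_assays(self) -> int:
        return self.n_samples * self.n_probes


def simulate_chip(spec: ChipSpec, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a raw Ct matrix plus sample metadata.

    Returns ``(ct, sample_meta)`` where ``ct`` is samples x probes (values
    in ``[0, max_cycles + 10]``; dropout cells encoded as ``Ct >=
    max_cycles``) and ``sample_meta`` carries the batch label per sample.
    """
    rng = np.random.default_rng(seed)
    S, P = spec.n_samples, spec.n_probes

    if spec.probe_means is None:
        # ~1/4 of probes sit near the detection floor -> bimodal 30-Ct profile
        low = rng.random(P) < 0.25
        means = np.where(
            low,
            rng.normal(spec.max_cycles - 3.0, 1.5, P),
            rng.normal(spec.max_cycles / 2.0, 3.0, P),
        )
    else:
        means = np.asarray(spec.probe_means, dtype=float)
        if means.shape != (P,):
            raise ValueError("probe_means must have one entry per probe")
    sds = np.broadcast_to(np.asarray(spec.probe_sds, dtype=float), (P,))

    ct = rng.normal(means, sds, size=(S, P))
    half = S // 2
    batch = np.array([spec.batch_labels[0]] * half + [spec.batch_labels[1]] * (S - half))
    ct[half:] += spec.batch_shift
    if spec.dropout_fraction > 0:
        drop = rng.random((S, P)) < spec.dropout_fraction
        ct[drop] = spec.max_cycles + 5.0
    ct = np.clip(ct, 0.0, spec.max_cycles + 10.0)

    samples = [f"S{i:02d}" for i in range(S)]
    probes = [f"P{j:02d}" for j in range(P)]
    ct_df = pd.DataFrame(ct, index=samples, columns=probes)
    meta = pd.DataFrame({"batch": batch}, index=samples)
    return ct_df, meta


# ---------------------------------------------------------------------------
# Toy genomes and variant calls
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_genome_with_snp(
    length: int,
    snp_offset: int,
    seed: int,
    pam_offsets: tuple[int, ...] = (),
    chrom: str = "chrSim",
) -> tuple[str, dict]:
    """Generate an uppercase A/C/G/T sequence with one annotated SNP.

    ``snp_offset`` is 0-based.  ``pam_offsets`` optionally plants NGG PAMs:
    for each offset p, bases p+1 and p+2 are set to ``GG`` so that an NGG
    motif starts at p on the forward strand.

    Returns ``(sequence, snp_record)`` where the record carries ``chrom``,
    0-based ``pos0``, 1-based ``pos`` (VCF convention), ``ref`` and ``alt``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= snp_offset < length:
        raise ValueError("snp_offset must lie inside the sequence")
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length)
    for p in pam_offsets:
        if not 0 <= p + 2 < length:
            raise ValueError(f"PAM at offset {p} does not fit in the sequence")
        seq[p + 1] = "G"
        seq[p + 2] = "G"
    ref = seq[snp_offset]
    alt = rng.choice(_BASES[_BASES != ref])
    record = {
        "chrom": chrom,
        "pos0": int(snp_offset),
        "pos": int(snp_offset) + 1,
        "ref": str(ref),
        "alt": str(alt),
    }
    return "".join(seq), record


def simulate_variant_calls(
    n_calls: int,
    seed: int,
    chrom: str = "chrSim",
    span: int = 100_000,
    depth_range: tuple[int, int] = (1, 200),
) -> list:
    """Draw a toy set of SNV calls with random positions and depths.

    Positions are unique and returned sorted; ref/alt are distinct bases.
    Intended as a fixture generator for the hard-filter cascade.
    """
    from .variants import VariantCall

    if n_calls > span:
        raise ValueError("cannot place more unique calls than positions")
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, span + 1), size=n_calls, replace=False))
    refs = rng.choice(_BASES, size=n_calls)
    alts = np.array(
        [rng.choice(_BASES[_BASES != r]) for r in refs]
    )
    depths = rng.integers(depth_range[0], depth_range[1] + 1, size=n_calls)
    exonic = rng.random(n_calls) < 0.5
    return [
        VariantCall(
            chrom=chrom,
            pos=int(p),
            ref=str(r),
            alt=str(a),
            depth=int(d),
            exonic=bool(e),
        )
        for p, r, a, d, e in zip(pos, refs, alts, depths, exonic)
    ]
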