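"""Experiment designs and power-study scenarios for single-clone CRISPR screens.

The experimental unit is a single-cell clone carrying a CRISPR-Cas9 edit at
one candidate SNP (one "guide").  An experiment targets ``n_guides`` SNPs in
one credible interval, expands one or more clones per guide, and measures
expression of the target gene in ``replicates`` technical replicates per
clone.  Effect sizes are expressed in standard deviation units (sdu): the
residual standard deviation of a single measurement is fixed at 1, so a
1-sdu effect corresponds roughly to an eQTL explaining 10% of expression
variance.

Variance components beyond the residual:

* ``sigma_clone`` -- clone-to-clone variability (genetic background drift,
  growth differences), a random intercept per clone.
* ``sigma_batch`` -- shared processing shifts (e.g. clones grown at
  different times), a random intercept per batch; guides are assigned to
  batches in contiguous blocks (guides 0-4 to batch 0, 5-9 to batch 1 in
  the canonical two-batch design).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = ["ExperimentDesign", "Scenario", "SCENARIOS", "EFFECT_GRID"]

#: Canonical effect-size grid: 0 to 2 sdu in 0.1 steps (21 points).
EFFECT_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 2.0001, 0.1), 1))


@dataclass(frozen=True)
class ExperimentDesign:
    """A simulated CRISPR-clone experiment.

    Parameters
    ----------
    n_guides
        Number of guide RNAs (targeted SNPs), default 10.
    causal_guides
        Indices of guides whose edit truly shifts expression.  Must be a
        non-empty subset of ``range(n_guides)`` whenever ``effect_sdu > 0``.
    clones_per_guide
        Either a single count applied to every guide or a mapping
        ``guide index -> clone count``.
    n_batches
        Number of processing batches; guides are split into contiguous
        blocks of equal size.
    replicates
        Technical replicates per clone (>= 2).
    effect_sdu
        Fixed shift added to every measurement of a causal guide's clones.
    sigma_clone, sigma_batch
        Standard deviations of the clone and batch random intercepts (sdu).
    sigma_resid
        Residual standard deviation; fixed at 1.0 so effects are literally
        in sdu.
    """

    n_guides: int = 10
    causal_guides: frozenset[int] = frozenset({0})
    clones_per_guide: int | Mapping[int, int] = 1
    n_batches: int = 1
    replicates: int = 8
    effect_sdu: float = 0.0
    sigma_clone: float = 0.0
    sigma_batch: float = 0.0
    sigma_resid: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "causal_guides", frozenset(self.causal_guides))
        if self.n_guides < 2:
            raise ValueError("need at least 2 guides to form a contrast")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.n_batches < 1 or self.n_guides % self.n_batches:
            raise ValueError("n_batches must divide n_guides")
        for name in ("sigma_clone", "sigma_batch", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.causal_guides <= set(range(self.n_guides)):
            raise ValueError("causal_guides must be a subset of guide indices")
        if self.effect_sdu != 0 and not self.causal_guides:
            raise ValueError("an effect > 0 requires a non-empty causal set")
        if self.effect_sdu < 0:
            raise ValueError("effect_sdu must be >= 0")
        if min(self.clones_of(g) for g in range(self.n_guides)) < 1:
            raise ValueError("every guide needs at least one clone")

    # ----- derived structure -------------------------------------------------

    def clones_of(self, guide: int) -> int:
        if isinstance(self.clones_per_guide, Mapping):
            return int(self.clones_per_guide.get(guide, 1))
        return int(self.clones_per_guide)

    @property
    def n_clones(self) -> int:
        return sum(self.clones_of(g) for g in range(self.n_guides))

    @property
    def n_measurements(self) -> int:
        return self.n_clones * self.replicates

    def batch_of_guide(self, guide: int) -> int:
        return guide * self.n_batches // self.n_guides

    def clone_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Return per-clone ``(guide_index, batch_index)`` arrays.

        Clone ids are the positions in these arrays and are unique across
        guides.
        """
        guides = np.repeat(
            np.arange(self.n_guides),
            [self.clones_of(g) for g in range(self.n_guides)],
        )
        batches = np.array([self.batch_of_guide(g) for g in guides])
        return guides, batches

    @property
    def has_random_effects(self) -> bool:
        return self.sigma_clone > 0 or self.sigma_batch > 0

    @property
    def has_clone_replication(self) -> bool:
        """True when at least one guide is represented by >= 2 clones."""
        return self.n_clones > self.n_guides

    def with_(self, **kw) -> "ExperimentDesign":
        return replace(self, **kw)


@dataclass(frozen=True)
class Scenario:
    """One of the five canonical power-study scenarios.

    A scenario is a template: calling :meth:`design` binds the grid effect
    size and the replicate level.
    """

    label: str
    sigma_clone: float = 0.0
    sigma_batch: float = 0.0
    n_batches: int = 1
    causal_guides: frozenset[int] = frozenset({0})
    causal_clones: int = 1  # clones representing each causal guide
    description: str = ""

    def design(self, effect_sdu: float, replicates: int, n_guides: int = 10) -> ExperimentDesign:
        clones: int | dict[int, int] = 1
        if self.causal_clones != 1:
            clones = {g: self.causal_clones for g in self.causal_guides}
        return ExperimentDesign(
            n_guides=n_guides,
            causal_guides=self.causal_guides,
            clones_per_guide=clones,
            n_batches=self.n_batches,
            replicates=replicates,
            effect_sdu=effect_sdu,
            sigma_clone=self.sigma_clone,
            sigma_batch=self.sigma_batch,
        )


#: The five scenarios, keyed both by panel letter and by name.
SCENARIOS: dict[str, Scenario] = {}


def _register(letter: str, scenario: Scenario) -> None:
    SCENARIOS[letter] = scenario
    SCENARIOS[scenario.label] = scenario


_register("a", Scenario(
    "baseline",
    description="10 clones, one causal guide, no clone or batch variance",
))
_register("b", Scenario(
    "clone_effects", sigma_clone=0.2,
    description="0.2-sdu random clone effects among the ten clones",
))
_register("c", Scenario(
    "clone_plus_batch", sigma_clone=0.2, sigma_batch=0.2, n_batches=2,
    description="clone effects plus a 0.2-sdu batch effect over two batches of 5 guides",
))
_register("d", Scenario(
    "duplicate_causal_clones", sigma_clone=0.2, causal_clones=2,
    description="causal variant represented by two clones, clone effects 0.2 sdu",
))
_register("e", Scenario(
    "three_causal", sigma_clone=0.2, causal_guides=frozenset({0, 1, 2}),
    description="three causal guides each carrying the grid effect, clone effects 0.2 sdu",
))
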