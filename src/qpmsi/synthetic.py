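"""Synthetic sib-family genotypes and correlated multi-trait BLUEs.

Real candidate populations in breeding programs have two features the
selection indices exercise: block-structured relatedness (full-sib
families share half their genome on average, so the GRM has elevated
within-family blocks) and inter-trait genetic correlation.  The
generator produces both:

* **Markers** — per family, two founder parents are drawn with dosages
  ``Binomial(2, q_m)`` at each biallelic locus (``q_m`` uniform over a
  configurable frequency window); each offspring receives one gamete
  from each parent by per-locus Mendelian sampling (a parent with
  dosage ``d`` transmits the alternate allele with probability
  ``d/2``).  Loci are unlinked.
* **Traits** — marker effects are drawn with a target inter-trait
  correlation matrix, genetic values are the scaled-marker cross
  product with those effects, and independent Gaussian noise is mixed
  in so the genetic component explains a fraction ``h2`` of each
  trait's variance (a heritability-like signal fraction).  Output
  traits are returned on arbitrary raw scales (nonzero means, unequal
  SDs) so the standardization step is genuinely exercised; traits
  flagged ``lower_is_better`` are emitted with inverted polarity so
  the favorable direction matches the flag.

One global seed drives everything; per-stage sub-streams are spawned
deterministically from it, so a dataset is a pure function of
``(config, seed)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidConfig, NonPSDCorrelation
from .grm import MarkerMatrix
from .preprocess import Direction, TraitTable, _check_directions

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one synthetic dataset.

    Parameters
    ----------
    n_families, family_size
        ``n = n_families * family_size`` offspring genotypes.
    p_markers
        Number of unlinked biallelic loci.
    allele_freq_range
        Founder allele-frequency window; keep it away from 0 and 1 to
        avoid monomorphic loci in small samples.
    trait_corr
        Target ``p0 x p0`` genetic correlation matrix (symmetric PSD,
        unit diagonal).
    h2
        Per-trait signal fraction in [0, 1]; 0 means pure noise, 1 a
        fully genetic trait.
    directions
        Per-trait improvement direction flags.
    seed
        Master seed; all randomness derives from it.
    """

    n_families: int = 5
    family_size: int = 10
    p_markers: int = 500
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    trait_corr: np.ndarray = field(default_factory=lambda: np.eye(4))
    h2: tuple[float, ...] = ()
    directions: tuple[Direction, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 1 or self.family_size < 1:
            raise InvalidConfig("n_families and family_size must be >= 1")
        if self.n_families * self.family_size < 2:
            raise InvalidConfig("need at least two genotypes in total")
        if self.p_markers < 1:
            raise InvalidConfig("p_markers must be >= 1")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise InvalidConfig("allele_freq_range must satisfy 0 < lo <= hi < 1")
        C = np.asarray(self.trait_corr, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise InvalidConfig("trait_corr must be square")
        if not np.allclose(C, C.T, atol=1e-9):
            raise InvalidConfig("trait_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-9):
            raise InvalidConfig("trait_corr must have unit diagonal")
        if np.linalg.eigvalsh(C)[0] < -1e-8:
            raise NonPSDCorrelation("trait_corr is not positive semidefinite")
        object.__setattr__(self, "trait_corr", C)
        p0 = C.shape[0]
        h2 = self.h2 or (0.5,) * p0
        h2 = tuple(float(h) for h in h2)
        if len(h2) != p0:
            raise InvalidConfig(f"{len(h2)} h2 values for {p0} trait(s)")
        if any(not (0.0 <= h <= 1.0) for h in h2):
            raise InvalidConfig("each h2 must lie in [0, 1]")
        object.__setattr__(self, "h2", h2)
        directions = self.directions or ("higher_is_better",) * p0
        object.__setattr__(self, "directions", _check_directions(directions, p0))

    @property
    def n(self) -> int:
        return self.n_families * self.family_size

    @property
    def p0(self) -> int:
        return self.trait_corr.shape[0]


@dataclass(frozen=True)
class SyntheticDataset:
    """Markers, traits and the true family labels of one simulated population."""

    markers: MarkerMatrix
    traits: TraitTable
    true_family: tuple[int, ...]


def _spawn(seed: int, stage: int) -> np.random.Generator:
    child = np.random.SeedSequence(seed).spawn(stage + 1)[stage]
    return np.random.default_rng(child)


def _draw_family_block(
    rng: np.random.Generator, q: np.ndarray, family_size: int
) -> np.ndarray:
    """Dosages of one full-sib family at loci with founder frequencies q."""
    parents = rng.binomial(2, q, size=(2, q.size)).astype(float)
    gametes_a = rng.binomial(1, np.broadcast_to(parents[0] / 2.0, (family_size, q.size)))
    gametes_b = rng.binomial(1, np.broadcast_to(parents[1] / 2.0, (family_size, q.size)))
    return (gametes_a + gametes_b).astype(float)


def simulate_markers(config: SimulationConfig) -> tuple[MarkerMatrix, tuple[int, ...]]:
    """Generate family-structured dosages and the true family labels.

    Full sibs share parents, so within-family relatedness in the
    derived GRM exceeds between-family relatedness.  Loci that come out
    monomorphic in the realized sample (possible by chance at small n)
    are redrawn, with a logged note, so downstream GRM construction
    never trips over zero-variance columns.
    """
    rng = _spawn(config.seed, 0)
    n, p = config.n, config.p_markers
    lo, hi = config.allele_freq_range

    q = rng.uniform(lo, hi, size=p)
    blocks = []
    fam_rngs = [np.random.default_rng(s) for s in
                np.random.SeedSequence(config.seed).spawn(config.n_families + 2)[2:]]
    for f in range(config.n_families):
        blocks.append(_draw_family_block(fam_rngs[f], q, config.family_size))
    X = np.vstack(blocks)

    for attempt in range(50):
        mono = X.std(axis=0) == 0.0
        if not mono.any():
            break
        cols = np.flatnonzero(mono)
        logger.info("redrawing %d monomorphic locus/loci (attempt %d)", cols.size, attempt + 1)
        q_new = rng.uniform(lo, hi, size=cols.size)
        for f in range(config.n_families):
            rows = slice(f * config.family_size, (f + 1) * config.family_size)
            X[rows, cols] = _draw_family_block(fam_rngs[f], q_new, config.family_size)[:, :]
    else:
        raise InvalidConfig(
            "could not generate a polymorphic marker set; widen allele_freq_range "
            "or increase the population size"
        )

    ids = tuple(f"F{f:03d}_I{i:03d}" for f in range(config.n_families)
                for i in range(config.family_size))
    names = tuple(f"M{m:05d}" for m in range(p))
    labels = tuple(f for f in range(config.n_families) for _ in range(config.family_size))
    return MarkerMatrix(ids, X, names), labels


def simulate_traits(markers: MarkerMatrix, config: SimulationConfig) -> TraitTable:
    """Generate raw multi-trait BLUEs with marker-driven genetic values.

    Marker effects for the ``p0`` traits are drawn jointly normal with
    covariance ``trait_corr``, so the genetic values inherit that
    inter-trait correlation.  Each trait mixes its (unit-scaled)
    genetic value with independent noise as
    ``sqrt(h2) * g + sqrt(1 - h2) * e``, then maps to an arbitrary raw
    scale.  ``lower_is_better`` traits are emitted sign-flipped so
    genetically superior genotypes have *low* raw values, as the flag
    promises.
    """
    rng = _spawn(config.seed, 1)
    X = markers.dosages
    n, p = X.shape
    p0 = config.p0

    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise InvalidConfig("marker matrix contains monomorphic loci")
    W = (X - X.mean(axis=0)) / sd

    # effect rows ~ N(0, trait_corr) -> genetic values inherit the correlation
    eigval, eigvec = np.linalg.eigh(config.trait_corr)
    L = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    B = rng.standard_normal((p, p0)) @ L.T
    g = W @ B
    g_sd = g.std(axis=0, ddof=1)
    g_sd[g_sd == 0] = 1.0
    g = g / g_sd

    e = rng.standard_normal((n, p0))
    h2 = np.asarray(config.h2)
    scores = np.sqrt(h2) * g + np.sqrt(1.0 - h2) * e

    # arbitrary raw trait scales (units differ per trait on purpose)
    scales = 1.0 + np.arange(p0, dtype=float)
    offsets = 10.0 * (1.0 + np.arange(p0, dtype=float))
    signs = np.where(np.array(config.directions) == "lower_is_better", -1.0, 1.0)
    raw = offsets + scales * signs * scores

    names = tuple(f"T{j + 1}" for j in range(p0))
    return TraitTable(markers.genotype_ids, raw, names, config.directions)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Markers + traits + family labels from one config/seed pair."""
    markers, labels = simulate_markers(config)
    traits = simulate_traits(markers, config)
    return SyntheticDataset(markers=markers, traits=traits, true_family=labels)
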