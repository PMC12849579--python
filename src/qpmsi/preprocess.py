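"""Trait standardization and gain-threshold construction.

Raw per-trait breeding values (BLUEs) arrive on trait-specific scales.
Before they can be combined into a single selection index each trait is
z-scored, ``y_ji = (BLUE_ji - mu_j) / sigma_j``, and traits for which
*lower* values are agronomically favorable (disease score, excessive
height, ...) are sign-flipped so that larger standardized scores always
mean better genotypes.  The per-trait minimum-gain constraint thresholds
are ``l_j = R_j * s / 100`` where ``R_j`` is the desired minimum gain for
trait ``j`` expressed as a percent and ``s`` is the number of genotypes
to be selected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import (
    InvalidSize,
    LengthMismatch,
    MissingValue,
    NegativeGain,
    ZeroVarianceTrait,
)

logger = logging.getLogger(__name__)

Direction = Literal["higher_is_better", "lower_is_better"]

_DIRECTIONS = ("higher_is_better", "lower_is_better")


def _check_directions(directions: Sequence[str], p0: int) -> tuple[str, ...]:
    directions = tuple(directions)
    if len(directions) != p0:
        raise LengthMismatch(
            f"{len(directions)} direction flags for {p0} trait(s)"
        )
    bad = [d for d in directions if d not in _DIRECTIONS]
    if bad:
        raise ValueError(f"unknown direction flag(s): {bad}; expected one of {_DIRECTIONS}")
    return directions


@dataclass(frozen=True)
class TraitTable:
    """Raw multi-trait BLUEs for ``n`` genotypes by ``p0`` traits.

    Parameters
    ----------
    genotype_ids
        Unique, ordered genotype identifiers (length ``n``).
    values
        ``n x p0`` array of raw breeding values in trait units.
    trait_names
        Trait column labels (length ``p0``).
    directions
        Per-trait flag, ``"higher_is_better"`` or ``"lower_is_better"``.
    """

    genotype_ids: tuple[str, ...]
    values: np.ndarray
    trait_names: tuple[str, ...]
    directions: tuple[Direction, ...] = field(default=())

    def __post_init__(self):
        ids = tuple(str(g) for g in self.genotype_ids)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array (genotypes x traits)")
        n, p0 = values.shape
        if n < 2:
            raise ValueError("need at least two genotypes")
        if p0 < 1:
            raise ValueError("need at least one trait")
        if len(ids) != n:
            raise LengthMismatch(f"{len(ids)} genotype ids for {n} rows")
        if len(set(ids)) != n:
            raise ValueError("genotype ids must be unique")
        names = tuple(str(t) for t in self.trait_names)
        if len(names) != p0:
            raise LengthMismatch(f"{len(names)} trait names for {p0} columns")
        directions = self.directions or ("higher_is_better",) * p0
        directions = _check_directions(directions, p0)
        object.__setattr__(self, "genotype_ids", ids)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "trait_names", names)
        object.__setattr__(self, "directions", directions)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p0(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class StandardizedTraits:
    """Standardized (and possibly direction-adjusted) trait scores.

    Each column of ``y`` is a z-score of the source trait: mean 0, unit
    standard deviation, dimensionless.  Row order matches the source
    table.
    """

    genotype_ids: tuple[str, ...]
    y: np.ndarray
    trait_names: tuple[str, ...]

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "genotype_ids", tuple(str(g) for g in self.genotype_ids))
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "trait_names", tuple(str(t) for t in self.trait_names))
        if y.shape[0] != len(self.genotype_ids):
            raise LengthMismatch("genotype ids do not match score rows")
        if y.shape[1] != len(self.trait_names):
            raise LengthMismatch("trait names do not match score columns")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p0(self) -> int:
        return self.y.shape[1]


@dataclass(frozen=True)
class GainThresholds:
    """Per-trait minimum-gain settings.

    ``R`` holds the desired minimum gains as percents in [0, 100];
    ``l`` the corresponding constraint right-hand sides on the
    standardized scale, ``l_j = R_j * s / 100``.
    """

    R: np.ndarray
    l: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float))
        object.__setattr__(self, "l", np.asarray(self.l, dtype=float))
        if self.R.shape != self.l.shape:
            raise LengthMismatch("R and l must have equal length")


def standardize_traits(
    raw: TraitTable,
    *,
    ddof: int = 1,
    on_missing: Literal["error", "drop"] = "error",
) -> StandardizedTraits:
    """Z-score every trait column of a raw BLUE table.

    Parameters
    ----------
    raw
        The raw trait table.
    ddof
        Delta degrees of freedom for the standard deviation; 1 (the
        default) gives the sample SD, 0 the population SD.
    on_missing
        ``"error"`` (default) raises :class:`MissingValue` on any
        non-finite cell; ``"drop"`` removes the offending genotypes with
        a logged warning.

    Returns
    -------
    StandardizedTraits
        Scores ``(value - column mean) / column SD``, row order
        preserved (minus dropped rows under ``on_missing="drop"``).

    Raises
    ------
    ZeroVarianceTrait
        If any column's SD is zero (names the offending traits).
    MissingValue
        Non-finite cell under the default policy.
    """
    values = raw.values
    ids = raw.genotype_ids
    finite = np.isfinite(values)
    if not finite.all():
        if on_missing == "error":
            bad = np.argwhere(~finite)
            i, j = bad[0]
            raise MissingValue(
                f"{(~finite).sum()} non-finite cell(s); first at genotype "
                f"{ids[i]!r}, trait {raw.trait_names[j]!r}"
            )
        keep = finite.all(axis=1)
        dropped = [ids[i] for i in np.flatnonzero(~keep)]
        logger.warning(
            "dropping %d genotype(s) with missing trait values: %s",
            len(dropped), dropped,
        )
        warnings.warn(
            f"dropped {len(dropped)} genotype(s) with missing trait values",
            stacklevel=2,
        )
        values = values[keep]
        ids = tuple(g for g, k in zip(ids, keep) if k)
        if values.shape[0] < 2:
            raise ValueError("fewer than two genotypes remain after dropping missing rows")

    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    zero = sd == 0.0
    if zero.any():
        raise ZeroVarianceTrait([raw.trait_names[j] for j in np.flatnonzero(zero)])
    return StandardizedTraits(ids, (values - mu) / sd, raw.trait_names)


def adjust_direction(
    z: StandardizedTraits, directions: Sequence[Direction]
) -> StandardizedTraits:
    """Negate columns whose trait improves downward.

    After adjustment higher standardized scores always reflect more
    favorable breeding values, so a single maximization objective treats
    all traits uniformly.  Applying the same flags twice restores the
    original scores (the operation is an involution).
    """
    directions = _check_directions(directions, z.p0)
    signs = np.where(np.array(directions) == "lower_is_better", -1.0, 1.0)
    return StandardizedTraits(z.genotype_ids, z.y * signs, z.trait_names)


def standardize_and_adjust(
    raw: TraitTable,
    *,
    ddof: int = 1,
    on_missing: Literal["error", "drop"] = "error",
) -> StandardizedTraits:
    """Convenience: z-score then apply the table's own direction flags."""
    z = standardize_traits(raw, ddof=ddof, on_missing=on_missing)
    return adjust_direction(z, raw.directions)


def gain_thresholds(
    R: Sequence[float], s: int, *, n: int | None = None
) -> GainThresholds:
    """Convert minimum-gain percents into constraint thresholds.

    ``l_j = R_j * s / 100`` expresses the requirement that the *sum* of
    selected standardized scores for trait ``j`` reach at least
    ``R_j`` percent of the selection size.  ``R_j = 0`` gives the base
    situation ``l_j = 0`` (the sum must merely be non-negative).

    Parameters
    ----------
    R
        Per-trait minimum gains, percents, all ``>= 0``.
    s
        Selection size, ``>= 1`` (and ``<= n`` when ``n`` is given).
    n
        Optional population size for the upper bound check on ``s``.
    """
    R_arr = np.asarray(list(R), dtype=float)
    if R_arr.ndim != 1:
        raise ValueError("R must be one-dimensional")
    if (R_arr < 0).any():
        raise NegativeGain(f"negative minimum gain(s): {R_arr[R_arr < 0].tolist()}")
    s = int(s)
    if s < 1:
        raise InvalidSize(f"selection size s={s} must be >= 1")
    if n is not None and s > n:
        raise InvalidSize(f"selection size s={s} exceeds population size n={n}")
    return GainThresholds(R=R_arr, l=R_arr * s / 100.0)
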