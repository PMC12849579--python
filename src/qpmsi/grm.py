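"""Genomic relationship matrix (GRM) construction and validation.

The GRM summarizes realized genetic relatedness between genotypes from
marker dosages.  Two scalings are offered:

``column_standardize`` (default)
    Each marker column is centered and scaled to unit sample SD, giving
    the scaled matrix ``W``; the GRM is ``G = W W^T / p`` with ``p`` the
    marker count.  Under this scaling ``trace(G) = n - 1`` and every row
    of ``G`` sums to zero.

``vanraden_freq``
    VanRaden's method 1: columns are centered by twice the observed
    allele frequency ``2 p_hat_j`` and the cross-product is divided by
    ``2 * sum_j p_hat_j (1 - p_hat_j)``.  Requires 0/1/2 dosage coding.

Both produce a symmetric positive semidefinite Gram matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import (
    AsymmetricMatrix,
    DimensionError,
    IDMismatch,
    LengthMismatch,
    MonomorphicMarker,
)

logger = logging.getLogger(__name__)

Scaling = Literal["column_standardize", "vanraden_freq"]


@dataclass(frozen=True)
class MarkerMatrix:
    """Allele dosages for ``n`` genotypes at ``p`` markers.

    Any numeric additive coding is accepted (0/1/2 or -1/0/1); the
    offset is removed by centering.
    """

    genotype_ids: tuple[str, ...]
    dosages: np.ndarray
    marker_names: tuple[str, ...]

    def __post_init__(self):
        dosages = np.asarray(self.dosages, dtype=float)
        ids = tuple(str(g) for g in self.genotype_ids)
        if dosages.ndim != 2:
            raise DimensionError("dosages must be 2-D (genotypes x markers)")
        n, p = dosages.shape
        if n < 2 or p < 1:
            raise DimensionError(f"need n >= 2 genotypes and p >= 1 markers, got {n} x {p}")
        if not np.isfinite(dosages).all():
            raise ValueError("dosages must be finite")
        if len(ids) != n:
            raise LengthMismatch(f"{len(ids)} genotype ids for {n} rows")
        if len(set(ids)) != n:
            raise ValueError("genotype ids must be unique")
        names = tuple(str(m) for m in self.marker_names)
        if len(names) != p:
            raise LengthMismatch(f"{len(names)} marker names for {p} columns")
        object.__setattr__(self, "genotype_ids", ids)
        object.__setattr__(self, "dosages", dosages)
        object.__setattr__(self, "marker_names", names)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]


@dataclass(frozen=True)
class RelationshipMatrix:
    """Symmetric ``n x n`` genomic relationship matrix with genotype ids."""

    genotype_ids: tuple[str, ...]
    G: np.ndarray

    def __post_init__(self):
        G = np.asarray(self.G, dtype=float)
        ids = tuple(str(g) for g in self.genotype_ids)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise DimensionError("G must be square")
        if len(ids) != G.shape[0]:
            raise LengthMismatch(f"{len(ids)} ids for a {G.shape[0]}-square matrix")
        object.__setattr__(self, "genotype_ids", ids)
        object.__setattr__(self, "G", G)

    @property
    def n(self) -> int:
        return self.G.shape[0]

    def submatrix(self, indices: Sequence[int]) -> np.ndarray:
        idx = np.asarray(indices, dtype=int)
        return self.G[np.ix_(idx, idx)]


def compute_grm(
    markers: MarkerMatrix,
    scaling: Scaling = "column_standardize",
    *,
    on_monomorphic: Literal["error", "drop"] = "error",
) -> RelationshipMatrix:
    """Build the GRM from a marker matrix.

    Parameters
    ----------
    markers
        Dosage matrix.
    scaling
        ``"column_standardize"`` (default): per-column z-scores with
        sample SD, then ``W W^T / p``.  ``"vanraden_freq"``: VanRaden
        method 1 with allele-frequency centering (requires dosages in
        [0, 2]).
    on_monomorphic
        Under ``column_standardize`` a zero-variance marker column cannot
        be scaled.  ``"error"`` (default) raises
        :class:`MonomorphicMarker`; ``"drop"`` removes those columns with
        a warning (this changes ``p`` and hence the scale of ``G``).
    """
    X = markers.dosages
    names = markers.marker_names
    if scaling == "column_standardize":
        sd = X.std(axis=0, ddof=1)
        mono = sd == 0.0
        if mono.any():
            if on_monomorphic == "error":
                raise MonomorphicMarker([names[j] for j in np.flatnonzero(mono)])
            dropped = [names[j] for j in np.flatnonzero(mono)]
            logger.warning("dropping %d monomorphic marker(s)", len(dropped))
            warnings.warn(
                f"dropped {len(dropped)} monomorphic marker(s); p changes from "
                f"{X.shape[1]} to {X.shape[1] - len(dropped)}",
                stacklevel=2,
            )
            keep = ~mono
            X, sd = X[:, keep], sd[keep]
            if X.shape[1] == 0:
                raise DimensionError("all markers monomorphic")
        W = (X - X.mean(axis=0)) / sd
        G = W @ W.T / W.shape[1]
    elif scaling == "vanraden_freq":
        if X.min() < 0.0 or X.max() > 2.0:
            raise ValueError("vanraden_freq scaling requires dosages coded in [0, 2]")
        p_hat = X.mean(axis=0) / 2.0
        het = 2.0 * np.sum(p_hat * (1.0 - p_hat))
        if het == 0.0:
            raise MonomorphicMarker(list(names))
        Z = X - 2.0 * p_hat
        G = Z @ Z.T / het
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    G = (G + G.T) / 2.0  # kill rounding asymmetry from the matmul
    return RelationshipMatrix(markers.genotype_ids, G)


def validate_grm(
    ids: Sequence[str],
    G: np.ndarray,
    *,
    id_order: Sequence[str] | None = None,
    asym_tol: float = 1e-6,
    psd_warn: float = -1e-4,
    psd_tol: float = -1e-8,
) -> RelationshipMatrix:
    """Validate (and optionally reorder) a precomputed relationship matrix.

    Symmetrizes via ``(G + G^T)/2`` when the largest asymmetry is within
    ``asym_tol``, errors beyond that.  A smallest eigenvalue in
    ``[psd_warn, psd_tol)`` draws a warning (numerical PSD violation);
    below ``psd_warn`` it errors.  When ``id_order`` is given, rows and
    columns are permuted to that order.

    Raises
    ------
    AsymmetricMatrix
        Asymmetry beyond ``asym_tol``.
    IDMismatch
        ``id_order`` is not a permutation of the matrix ids.
    """
    rm = RelationshipMatrix(tuple(ids), np.asarray(G, dtype=float))
    G = rm.G
    asym = np.abs(G - G.T).max()
    if asym > asym_tol:
        raise AsymmetricMatrix(f"max |G - G^T| = {asym:.3g} exceeds tolerance {asym_tol:g}")
    G = (G + G.T) / 2.0
    min_eig = float(np.linalg.eigvalsh(G)[0])
    if min_eig < psd_warn:
        raise ValueError(
            f"relationship matrix is not positive semidefinite (min eigenvalue {min_eig:.3g})"
        )
    if min_eig < psd_tol:
        warnings.warn(
            f"relationship matrix is near-singular indefinite: min eigenvalue {min_eig:.3g}",
            stacklevel=2,
        )
    out_ids = rm.genotype_ids
    if id_order is not None:
        id_order = tuple(str(g) for g in id_order)
        if set(id_order) != set(out_ids) or len(id_order) != len(out_ids):
            missing = set(id_order) - set(out_ids)
            extra = set(out_ids) - set(id_order)
            raise IDMismatch(f"id sets differ; missing from G: {sorted(missing)}, "
                             f"absent from requested order: {sorted(extra)}")
        pos = {g: i for i, g in enumerate(out_ids)}
        perm = np.array([pos[g] for g in id_order])
        G = G[np.ix_(perm, perm)]
        out_ids = id_order
    return RelationshipMatrix(out_ids, G)
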