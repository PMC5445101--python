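"""Genotype containers and genomic relationship matrices.

Genotypes are held as an allele-count matrix ``A`` (lines x markers, entries in
{0, 1, 2} counting the minor allele).  The centered and scaled matrix ``W`` has
columns ``w_i = (a_i - 2 p_i) / sqrt(2 p_i (1 - p_i))`` where ``p_i`` is the
minor allele frequency, and the genomic relationship matrix (GRM) is
``G = W W' / m``.  Fully inbred panels (e.g. DGRP-like lines) carry only
homozygous calls 0/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Drosophila-style circular chromosome order (2L -> ... -> X, wrapping).
DEFAULT_CHROM_ORDER = ("2L", "2R", "3L", "3R", "4", "X")

# Relative eigenvalue cutoff for every generalized inverse of G / WW'.
EIG_REL_TOL = 1e-8


def minor_allele_frequencies(A: np.ndarray) -> np.ndarray:
    """Per-marker frequency of the counted allele, mean(a_i) / 2."""
    return np.asarray(A, dtype=float).mean(axis=0) / 2.0


def centered_scaled(A: np.ndarray, p: np.ndarray | None = None) -> np.ndarray:
    """Centered and scaled genotype matrix W with columns (a_i - 2p_i)/sqrt(2p_i(1-p_i))."""
    A = np.asarray(A, dtype=float)
    if p is None:
        p = minor_allele_frequencies(A)
    denom = np.sqrt(2.0 * p * (1.0 - p))
    if np.any(denom <= 0):
        raise ValueError("monomorphic marker (p = 0 or 1); remove at QC before scaling")
    return (A - 2.0 * p) / denom


@dataclass
class GenotypeData:
    """Allele-count genotypes with a marker map.

    Parameters
    ----------
    line_ids : array-like of str
        Identifiers of the n lines (rows of ``A``).
    marker_ids : array-like of str
        Identifiers of the m markers (columns of ``A``).
    chrom, pos : array-like
        Per-marker chromosome label and base-pair coordinate.
    A : ndarray (n, m)
        Allele counts in {0, 1, 2} of the minor allele.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    A: np.ndarray
    _p: np.ndarray | None = field(default=None, repr=False)
    _W: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids)
        self.marker_ids = np.asarray(self.marker_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos)
        self.A = np.asarray(self.A)
        n, m = self.A.shape
        if len(self.line_ids) != n:
            raise ValueError("line_ids length does not match A rows")
        if not (len(self.marker_ids) == len(self.chrom) == len(self.pos) == m):
            raise ValueError("marker annotation length does not match A columns")

    @property
    def n_lines(self) -> int:
        return self.A.shape[0]

    @property
    def n_markers(self) -> int:
        return self.A.shape[1]

    @property
    def p(self) -> np.ndarray:
        """Minor allele frequencies; coding is flipped on access if any p > 0.5."""
        if self._p is None:
            p = minor_allele_frequencies(self.A)
            flip = p > 0.5
            if np.any(flip):
                self.A = self.A.copy()
                self.A[:, flip] = 2 - self.A[:, flip]
                p = np.where(flip, 1.0 - p, p)
            self._p = p
        return self._p

    @property
    def W(self) -> np.ndarray:
        """Centered/scaled matrix; cached (float64, n x m)."""
        if self._W is None:
            self._W = centered_scaled(self.A, self.p)
        return self._W

    def sort_markers(self, chrom_order: tuple[str, ...] | None = None) -> "GenotypeData":
        """Return a copy sorted by (chromosome order, position).

        ``chrom_order`` is an explicit list; chromosomes absent from it sort
        after the listed ones, alphabetically.
        """
        order = list(chrom_order) if chrom_order is not None else list(DEFAULT_CHROM_ORDER)
        rank = {c: i for i, c in enumerate(order)}
        extras = sorted(set(map(str, self.chrom)) - set(order))
        rank.update({c: len(order) + i for i, c in enumerate(extras)})
        key = np.array([rank[str(c)] for c in self.chrom])
        idx = np.lexsort((self.pos, key))
        return self.take_markers(idx)

    def take_markers(self, idx: np.ndarray) -> "GenotypeData":
        """Subset/reorder markers (returns a new object; caches dropped)."""
        idx = np.asarray(idx)
        return GenotypeData(
            line_ids=self.line_ids,
            marker_ids=self.marker_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            A=self.A[:, idx],
        )


@dataclass
class GRM:
    """Genomic relationship matrix G = W_s W_s' / m_s over a marker subset."""

    G: np.ndarray
    m_used: int
    marker_subset: np.ndarray | None = None
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def mean_diag(self) -> float:
        """Average diagonal of G (~2 for fully inbred panels under HW scaling).

        The per-line genomic variance implied by g ~ N(0, G s2) is
        ``mean_diag * s2``; heritabilities and simulated variance splits are
        expressed on that per-line scale so that a stated h2 refers to the
        realized phenotypic variance decomposition.
        """
        return float(self.G.diagonal().mean())

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition G = U diag(d) U', cached, eigenvalues ascending."""
        if self._eig is None:
            d, U = np.linalg.eigh(self.G)
            self._eig = (d, U)
        return self._eig

    def eig_nonnull(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenpairs above the relative cutoff EIG_REL_TOL * lambda_max."""
        d, U = self.eig()
        cut = EIG_REL_TOL * max(d[-1], 0.0)
        keep = d > cut
        return d[keep], U[:, keep]

    def pinv(self) -> np.ndarray:
        """Eigen-based pseudo-inverse with the package-wide relative cutoff."""
        d, U = self.eig_nonnull()
        return (U / d) @ U.T


def build_grm(genotypes: GenotypeData, marker_subset: np.ndarray | None = None) -> GRM:
    """G = W_s W_s' / m_s over ``marker_subset`` (all markers by default).

    Column-centering of W forces G row sums to zero; G is symmetric PSD up to
    round-off.
    """
    if marker_subset is not None:
        marker_subset = np.asarray(marker_subset)
        if marker_subset.size == 0:
            raise ValueError("empty marker subset")
        if marker_subset.min() < 0 or marker_subset.max() >= genotypes.n_markers:
            raise ValueError("marker subset index out of range")
        Ws = genotypes.W[:, marker_subset]
    else:
        Ws = genotypes.W
    m = Ws.shape[1]
    G = (Ws @ Ws.T) / m
    G = 0.5 * (G + G.T)
    return GRM(G=G, m_used=m, marker_subset=marker_subset)


def complement_grm(full: GRM, feature: GRM) -> GRM:
    """GRM of the markers outside a feature, from the full and feature GRMs.

    Uses m G = m_f G_f + m_r G_r, avoiding a second pass over W.
    """
    m_r = full.m_used - feature.m_used
    if m_r <= 0:
        raise ValueError("feature covers all markers; complement GRM is empty")
    G_r = (full.m_used * full.G - feature.m_used * feature.G) / m_r
    subset = None
    if feature.marker_subset is not None:
        base = (
            np.arange(full.m_used)
            if full.marker_subset is None
            else np.asarray(full.marker_subset)
        )
        subset = base[~np.isin(base, feature.marker_subset)]
    return GRM(G=0.5 * (G_r + G_r.T), m_used=m_r, marker_subset=subset)
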