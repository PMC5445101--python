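"""Competitive-null inference by circular genome rotation or random marker sets.

The competitive null asks whether a feature's set statistic exceeds that of a
random marker set of the same size.  Because every statistic here is a sum of
per-marker contributions, one engine serves all tests: the genome is treated
as circular (chromosomes concatenated in map order, wrapping), the vector of
per-marker contributions is rotated by a random offset, and the feature
statistic is recomputed at the feature's original positions.  Rotation
preserves the multiset of contributions and the local correlation structure
among them while breaking their association with the feature.  Alternatively
the null draws a fresh random marker set of the feature's size.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = ["NullEngine", "circular_permute", "empirical_pvalue", "random_set_null"]


def circular_permute(contribs: np.ndarray, offset: int) -> np.ndarray:
    """Rotate per-marker contributions by ``offset`` along the circular genome.

    Element j of the output is element ((j - offset) mod m) of the input, so
    the statistic originally at the first marker moves to position offset.
    """
    m = len(contribs)
    if not 0 <= offset < m:
        raise ValueError("offset must lie in [0, m)")
    return np.roll(contribs, offset)


def empirical_pvalue(observed: float, null_draws: np.ndarray, *, add_one: bool = True,
                     strict: bool = False) -> float:
    """One-tailed empirical p: proportion of null draws at or above observed.

    With ``add_one`` (default) the estimator is (#{T >= T_obs} + 1)/(n + 1),
    strictly positive; ``add_one=False`` reproduces the raw proportion (which
    can be zero, reported in tables as "< 1/n").  ``strict`` counts only
    draws strictly larger than observed.
    """
    null_draws = np.asarray(null_draws)
    n = null_draws.size
    hits = int((null_draws > observed).sum() if strict else (null_draws >= observed).sum())
    if add_one:
        return (hits + 1) / (n + 1)
    return hits / n


def _feature_key(feature_idx: np.ndarray) -> int:
    """Stable per-feature stream key so features get distinct offsets."""
    return zlib.crc32(np.ascontiguousarray(np.sort(feature_idx), dtype=np.int64).tobytes())


@dataclass
class NullEngine:
    """Configuration + sampler for the competitive null.

    mode : 'circular' (genome rotation) or 'random_sets' (fresh marker sets)
    domain : optional boolean mask restricting the null to a marker subset
        (e.g. genic markers only); the feature must lie inside the domain.
    n_perm : number of permutations (>= 100; empirical p unstable below).
    seed : master seed; per-feature streams are derived deterministically.
    """

    n_perm: int = 10_000
    mode: str = "circular"
    seed: int = 0
    domain: np.ndarray | None = None

    def _rng(self, key: int | None) -> np.random.Generator:
        return np.random.default_rng([self.seed & 0x7FFFFFFF, (key or 0) & 0xFFFFFFFF])

    def draws(self, contribs: np.ndarray, feature_idx: np.ndarray,
              key: int | None = None) -> np.ndarray:
        """Null statistics (sums of contributions) for one feature.

        ``contribs`` may be a (m,) vector or a (k, m) stack of contribution
        vectors sharing the same rotations (one gather serves k statistics);
        the result is (n_perm,) or (k, n_perm) accordingly.
        """
        if self.n_perm < 100:
            raise ValueError("n_perm < 100 gives unstable empirical p-values")
        contribs = np.asarray(contribs, dtype=float)
        was_1d = contribs.ndim == 1
        contribs = np.atleast_2d(contribs)
        feature_idx = np.asarray(feature_idx)
        if key is None:
            key = _feature_key(feature_idx)
        if self.domain is not None:
            sub = np.flatnonzero(self.domain)
            pos_map = -np.ones(contribs.shape[1], dtype=np.int64)
            pos_map[sub] = np.arange(sub.size)
            fpos = pos_map[feature_idx]
            if np.any(fpos < 0):
                raise ValueError("feature contains markers outside the null domain")
            contribs = contribs[:, sub]
            feature_idx = fpos
        m = contribs.shape[1]
        rng = self._rng(key)
        if self.mode == "circular":
            offsets = rng.integers(1, m + 1, size=self.n_perm) % m
            out = _rotated_sums(contribs, feature_idx, offsets)
        elif self.mode == "random_sets":
            out = random_set_null(contribs, feature_idx.size, self.n_perm, rng)
        else:
            raise ValueError(f"unknown null mode {self.mode!r}")
        return out[0] if was_1d else out

    def pvalue(self, observed: float, contribs: np.ndarray, feature_idx: np.ndarray,
               key: int | None = None, **kw) -> tuple[float, np.ndarray]:
        draws = self.draws(contribs, feature_idx, key=key)
        return empirical_pvalue(observed, draws, **kw), draws


def _rotated_sums(contribs: np.ndarray, feature_idx: np.ndarray,
                  offsets: np.ndarray) -> np.ndarray:
    """Feature sums under rotation offsets, chunked to bound memory.

    ``contribs`` is (k, m); returns (k, n_offsets).
    """
    k, m = contribs.shape
    out = np.empty((k, offsets.size))
    chunk = max(1, int(2e7 / max(feature_idx.size, 1)))
    for a in range(0, offsets.size, chunk):
        off = offsets[a : a + chunk, None]
        pos = (feature_idx[None, :] - off) % m
        out[:, a : a + chunk] = contribs[:, pos].sum(axis=2)
    return out


def random_set_null(contribs: np.ndarray, m_f: int, n_perm: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Null draws by sampling m_f markers without replacement per draw."""
    contribs = np.asarray(contribs, dtype=float)
    was_1d = contribs.ndim == 1
    contribs = np.atleast_2d(contribs)
    k, m = contribs.shape
    if m_f > m:
        raise ValueError("feature size exceeds null domain size")
    out = np.empty((k, n_perm))
    for i in range(n_perm):
        pick = rng.choice(m, size=m_f, replace=False)
        out[:, i] = contribs[:, pick].sum(axis=1)
    return out[0] if was_1d else out
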