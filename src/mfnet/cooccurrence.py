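"""Probabilistic species-trait cooccurrence and Jaccard association strength.

Each species is reduced to the set of trait modalities it possesses
(fuzzy affinity above a threshold).  For a pair of species holding
``n_a`` and ``n_b`` of the ``N`` modalities, the number of shared
modalities under random, independent assignment follows a hypergeometric
distribution:

    P(share exactly j) = C(n_a, j) C(N - n_a, n_b - j) / C(N, n_b)

A pair shares traits significantly when the upper tail P(share >= q_obs)
falls below alpha (positive associations only).  The strength of a
significant association is Jaccard's coefficient
JC = q / (n_a + n_b - q).

Probabilities are computed from exact integer binomial coefficients — no
Monte Carlo, no log-gamma rounding beyond the final float division.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FuzzyTraitTable, ValidationError

logger = logging.getLogger("mfnet")


@dataclass
class BinaryTraitMatrix:
    """Presence/absence view of a fuzzy trait table.

    ``N`` is the total modality count, ``n_i`` the per-species number of
    possessed modalities.  Species possessing no modality are flagged and
    excluded from pairwise testing, not errors.
    """

    species_ids: list[str]
    modality_ids: list[str]
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if not np.isin(self.cells, (0, 1)).all():
            raise ValidationError("binary trait matrix must contain only 0/1")
        self.cells = self.cells.astype(np.int8)

    @property
    def N(self) -> int:
        return len(self.modality_ids)

    @property
    def n_i(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def flagged_empty(self) -> list[str]:
        return [s for s, n in zip(self.species_ids, self.n_i) if n == 0]

    def row(self, species: str) -> np.ndarray:
        try:
            i = self.species_ids.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None
        return self.cells[i]


@dataclass
class PairAssociation:
    """Cooccurrence statistics for one unordered species pair."""

    species_a: str
    species_b: str
    q: int                 # observed shared modalities
    expected: float        # n_a * n_b / N
    p_lt: float            # P(share <= q) under the hypergeometric model
    p_gt: float            # P(share >= q)
    jaccard: float
    significant: bool      # positive association: p_gt < alpha


def binarize(traits: FuzzyTraitTable, threshold: float = 0.0) -> BinaryTraitMatrix:
    """Convert fuzzy affinities to presence/absence: cell = 1 iff score > threshold."""
    if threshold < 0:
        raise ValidationError("binarize threshold must be >= 0")
    cells = (traits.scores > threshold).astype(np.int8)
    out = BinaryTraitMatrix(list(traits.species_ids), list(traits.modality_ids), cells)
    for s in out.flagged_empty:
        logger.warning("species %s has no modality above threshold %g; "
                       "excluded from cooccurrence analysis", s, threshold)
    return out


def pair_probabilities(N: int, n_a: int, n_b: int, q: int) -> tuple[float, float, float]:
    """Exact hypergeometric sharing probabilities ``(p_exact, p_lt, p_gt)``.

    ``p_lt`` = P(share <= q), ``p_gt`` = P(share >= q); hence
    p_lt + p_gt = 1 + p_exact.
    """
    if not (0 <= n_a <= N and 0 <= n_b <= N):
        raise ValidationError(f"need 0 <= n_a, n_b <= N, got N={N}, n_a={n_a}, n_b={n_b}")
    q_min = max(0, n_a + n_b - N)
    q_max = min(n_a, n_b)
    if not (q_min <= q <= q_max):
        raise ValidationError(
            f"infeasible overlap q={q} for N={N}, n_a={n_a}, n_b={n_b} "
            f"(feasible range [{q_min}, {q_max}])"
        )
    denom = comb(N, n_b)
    counts = [comb(n_a, j) * comb(N - n_a, n_b - j) for j in range(q_min, q_max + 1)]
    k = q - q_min
    p_exact = counts[k] / denom
    p_lt = sum(counts[: k + 1]) / denom
    p_gt = sum(counts[k:]) / denom
    return p_exact, p_lt, p_gt


def jaccard(bin: BinaryTraitMatrix, a: str, b: str) -> float:
    """Jaccard coefficient of two species' modality sets: q / (n_a + n_b - q)."""
    ra, rb = bin.row(a), bin.row(b)
    na, nb = int(ra.sum()), int(rb.sum())
    if na + nb == 0:
        raise ValidationError(f"both species {a!r} and {b!r} possess no modalities")
    q = int((ra & rb).sum())
    return q / (na + nb - q)


def cooccurrence_scan(
    bin: BinaryTraitMatrix,
    alpha: float = 0.05,
    min_expected: float = 1.0,
    fdr: bool = False,
) -> list[PairAssociation]:
    """Test every usable species pair for positive trait cooccurrence.

    Pairs with expected sharing below ``min_expected`` are not tested
    (removed before any correction).  ``fdr=True`` applies a
    Benjamini–Hochberg correction to the upper-tail p-values before the
    alpha cut; the default reports raw significant pairs.  Output is one
    record per retained unordered pair, sorted lexicographically.
    """
    usable = [s for s, n in zip(bin.species_ids, bin.n_i) if n > 0]
    if len(usable) < 2:
        raise ValidationError("need at least 2 species with nonzero traits")
    N = bin.N
    n_of = dict(zip(bin.species_ids, (int(n) for n in bin.n_i)))
    out: list[PairAssociation] = []
    ordered = sorted(usable)
    for i, a in enumerate(ordered):
        ra = bin.row(a)
        for b in ordered[i + 1:]:
            rb = bin.row(b)
            na, nb = n_of[a], n_of[b]
            expected = na * nb / N
            if expected < min_expected:
                continue
            q = int((ra & rb).sum())
            _, p_lt, p_gt = pair_probabilities(N, na, nb, q)
            out.append(PairAssociation(
                species_a=a, species_b=b, q=q, expected=expected,
                p_lt=p_lt, p_gt=p_gt,
                jaccard=q / (na + nb - q),
                significant=bool(p_gt < alpha),
            ))
    if fdr and out:
        adj = stats.false_discovery_control([r.p_gt for r in out], method="bh")
        for r, p in zip(out, adj):
            r.significant = bool(p < alpha)
    return out


def scan_to_frame(assocs: Iterable[PairAssociation]) -> pd.DataFrame:
    """Tabulate scan results for CSV export."""
    return pd.DataFrame(
        [(r.species_a, r.species_b, r.q, r.expected, r.p_lt, r.p_gt,
          r.jaccard, r.significant) for r in assocs],
        columns=["species_a", "species_b", "q", "expected", "p_lt", "p_gt",
                 "jaccard", "significant"],
    )
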