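"""Tolerance-matched cosine similarity between clonal profiles.

Two repertoires are compared the way MS/MS spectra often are: clones are
paired across profiles when their masses agree within an absolute
tolerance (default 1.5 Da), the paired intensities form two vectors, and
the score is the cosine of the angle between them — 1 for identical
profiles, 0 when no clone of one lies within tolerance of any clone of
the other.  Profiles are first reduced to their top-N most intense clones
(default 100); intensities enter the score untransformed.

Pairing is greedy one-to-one nearest-mass matching: candidate pairs within
tolerance are sorted by ascending mass difference (ties by the smaller,
then larger, member mass, which makes the matching symmetric in its
arguments) and accepted while both members are unmatched.  Unmatched
clones contribute one-sided entries, penalizing the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clones import ClonalProfile, top_n

__all__ = ["SimilarityMatrix", "align_peaks", "cosine_score", "similarity_matrix"]


@dataclass
class SimilarityMatrix:
    """Square, symmetric matrix of pairwise cosine scores in [0, 1]."""

    sample_ids: list[str]
    scores: np.ndarray

    def validate(self) -> None:
        n = len(self.sample_ids)
        if self.scores.shape != (n, n):
            raise ValueError("scores shape does not match sample_ids")
        if not np.allclose(self.scores, self.scores.T):
            raise ValueError("similarity matrix is not symmetric")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("scores outside [0, 1]")


def align_peaks(a: ClonalProfile, b: ClonalProfile,
                tolerance: float) -> tuple[np.ndarray, np.ndarray]:
    """Pair clones across two (already top-N-reduced) profiles.

    Returns two equal-length non-negative intensity vectors: matched pairs
    contribute ``(ia, ib)``, unmatched clones ``(ia, 0)`` or ``(0, ib)``.
    """
    pairs = []
    for i, ca in enumerate(a.clones):
        for j, cb in enumerate(b.clones):
            delta = abs(ca.mass - cb.mass)
            if delta <= tolerance:
                lo, hi = sorted((ca.mass, cb.mass))
                pairs.append((delta, lo, hi, i, j))
    pairs.sort()
    matched_a = set()
    matched_b = set()
    u: list[float] = []
    v: list[float] = []
    for _delta, _lo, _hi, i, j in pairs:
        if i in matched_a or j in matched_b:
            continue
        matched_a.add(i)
        matched_b.add(j)
        u.append(a.clones[i].intensity)
        v.append(b.clones[j].intensity)
    for i, ca in enumerate(a.clones):
        if i not in matched_a:
            u.append(ca.intensity)
            v.append(0.0)
    for j, cb in enumerate(b.clones):
        if j not in matched_b:
            u.append(0.0)
            v.append(cb.intensity)
    return np.asarray(u, dtype=np.float64), np.asarray(v, dtype=np.float64)


def cosine_score(a: ClonalProfile, b: ClonalProfile,
                 tolerance: float = 1.5, n: int = 100) -> float:
    """Cosine similarity of two clonal profiles in [0, 1].

    Both profiles are reduced to their ``n`` most intense clones before
    matching with the given mass ``tolerance`` (Da).  An empty or all-zero
    side scores 0 by convention.  Two profiles whose aligned vectors are
    identical score exactly 1.
    """
    ra, rb = top_n(a, n), top_n(b, n)
    u, v = align_peaks(ra, rb, tolerance)
    if u.size == 0:
        return 0.0
    # norms are computed from each reduced profile in its own (canonical)
    # clone order rather than from the aligned vectors: the aligned vectors
    # interleave zero-partner entries at argument-order-dependent positions,
    # which perturbs blocked floating-point summation by an ulp and would
    # break the exact symmetry score(a,b) == score(b,a)
    ia = np.array([c.intensity for c in ra.clones])
    ib = np.array([c.intensity for c in rb.clones])
    nu = float(np.dot(ia, ia))
    nv = float(np.dot(ib, ib))
    if nu <= 0.0 or nv <= 0.0:
        return 0.0
    if np.array_equal(u, v):
        return 1.0
    score = float(np.dot(u, v)) / (np.sqrt(nu) * np.sqrt(nv))
    return float(min(max(score, 0.0), 1.0))


def similarity_matrix(profiles: Sequence[ClonalProfile],
                      tolerance: float = 1.5, n: int = 100) -> SimilarityMatrix:
    """All pairwise cosine scores; symmetric with a unit diagonal."""
    if not profiles:
        raise ValueError("need at least one profile")
    k = len(profiles)
    scores = np.zeros((k, k))
    for i in range(k):
        scores[i, i] = cosine_score(profiles[i], profiles[i], tolerance, n)
        for j in range(i + 1, k):
            s = cosine_score(profiles[i], profiles[j], tolerance, n)
            scores[i, j] = scores[j, i] = s
    return SimilarityMatrix(sample_ids=[p.sample_id for p in profiles], scores=scores)
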