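"""Cross-slice clone assembly.

Each retention-time slice of the run yields an independent list of
deconvoluted mass peaks.  A clonal Fab species elutes over several
consecutive slices, so the same underlying clone appears as a short train
of peaks with nearly identical masses.  This module collapses those trains
into a deduplicated clone list — the per-sample antibody repertoire
profile — using a relative (ppm) mass tolerance and an optional retention
time gap limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .deconvolve import MassPeak

__all__ = ["Clone", "ClonalProfile", "merge_slices", "top_n"]


@dataclass(frozen=True)
class Clone:
    """A unique Fab species: one (mass, retention time) pair with intensity.

    Attributes
    ----------
    clone_id : int
        1-based rank after sorting by descending intensity.
    mass : float
        Intensity-weighted mean mass (Da) of the merged per-slice peaks.
    rt : float
        Retention time (min) of the most intense contributing slice.
    intensity : float
        Apex intensity: the maximum over contributing slice peaks.
    n_slices : int
        Number of slices that contributed a peak to this clone.
    slice_index : int
        Index of the apex slice (provenance; used for same-slice exclusion
        when a clone list is re-merged).
    """

    clone_id: int
    mass: float
    rt: float
    intensity: float
    n_slices: int
    slice_index: int = -1


@dataclass
class ClonalProfile:
    """Per-sample clone list, sorted by descending intensity."""

    sample_id: str
    clones: list[Clone] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clones)

    def masses(self):
        return [c.mass for c in self.clones]

    def intensities(self):
        return [c.intensity for c in self.clones]

    def validate(self) -> None:
        ids = [c.clone_id for c in self.clones]
        if len(ids) != len(set(ids)):
            raise ValueError("clone_ids are not unique")
        for prev, cur in zip(self.clones, self.clones[1:]):
            if cur.intensity > prev.intensity:
                raise ValueError("clones are not sorted by descending intensity")
        for c in self.clones:
            if c.intensity < 0:
                raise ValueError(f"clone {c.clone_id}: negative intensity")
            if c.n_slices < 1:
                raise ValueError(f"clone {c.clone_id}: n_slices < 1")


def _ppm(a: float, b: float) -> float:
    return abs(a - b) / b * 1e6


class _Cluster:
    __slots__ = ("members", "_wsum", "_msum")

    def __init__(self, seed: "MassPeak"):
        self.members: list = [seed]
        self._wsum = seed.intensity
        self._msum = seed.intensity * seed.mass

    @property
    def mean_mass(self) -> float:
        if self._wsum > 0:
            return self._msum / self._wsum
        return sum(p.mass for p in self.members) / len(self.members)

    def slices(self) -> set:
        return {p.slice_index for p in self.members}

    def absorb(self, peak: "MassPeak") -> None:
        self.members.append(peak)
        self._wsum += peak.intensity
        self._msum += peak.intensity * peak.mass


def merge_slices(
    peaks: Iterable["MassPeak"],
    merge_ppm: float,
    merge_max_rt_gap: float = math.inf,
    sample_id: str = "sample",
) -> ClonalProfile:
    """Merge per-slice mass peaks into a deduplicated clonal profile.

    Greedy intensity-ordered clustering: the most intense unassigned peak
    seeds a cluster, which then absorbs every unassigned peak that lies
    within ``merge_ppm`` of the running intensity-weighted mean mass and
    within ``merge_max_rt_gap`` minutes of the cluster's nearest member —
    except peaks from a slice already represented in the cluster, since
    two masses resolved within one deconvoluted slice are distinct species
    by construction.  Ties in intensity are broken by lower mass, then
    lower slice index, which makes the procedure deterministic.

    Each cluster becomes one :class:`Clone`: its mass is the
    intensity-weighted mean of its members, its intensity the apex
    (maximum) member intensity, and its retention time that apex member's
    slice RT.
    """
    if merge_ppm <= 0:
        raise ValueError("merge_ppm must be > 0")
    order = sorted(peaks, key=lambda p: (-p.intensity, p.mass, p.slice_index))
    assigned = [False] * len(order)
    clones: list[Clone] = []
    for seed_i, seed in enumerate(order):
        if assigned[seed_i]:
            continue
        assigned[seed_i] = True
        cluster = _Cluster(seed)
        used_slices = {seed.slice_index}
        changed = True
        while changed:
            changed = False
            mean = cluster.mean_mass
            for j in range(seed_i + 1, len(order)):
                if assigned[j]:
                    continue
                p = order[j]
                if p.slice_index in used_slices:
                    continue
                if _ppm(p.mass, mean) > merge_ppm:
                    continue
                if math.isfinite(merge_max_rt_gap):
                    gap = min(abs(p.slice_rt - m.slice_rt) for m in cluster.members)
                    if gap > merge_max_rt_gap:
                        continue
                assigned[j] = True
                cluster.absorb(p)
                used_slices.add(p.slice_index)
                mean = cluster.mean_mass
                changed = True
        apex = min(
            cluster.members,
            key=lambda p: (-p.intensity, p.mass, p.slice_index),
        )
        clones.append(
            Clone(
                clone_id=0,
                mass=cluster.mean_mass,
                rt=apex.slice_rt,
                intensity=apex.intensity,
                n_slices=len(cluster.members),
                slice_index=apex.slice_index,
            )
        )
    clones.sort(key=lambda c: (-c.intensity, c.mass))
    clones = [replace(c, clone_id=i + 1) for i, c in enumerate(clones)]
    return ClonalProfile(sample_id=sample_id, clones=clones)


def top_n(profile: ClonalProfile, n: int) -> ClonalProfile:
    """Keep the ``n`` most intense clones (all, if fewer).

    Ties in intensity at the cutoff are broken in favour of the lower mass.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    kept = sorted(profile.clones, key=lambda c: (-c.intensity, c.mass))[:n]
    return ClonalProfile(
        sample_id=profile.sample_id,
        clones=kept,
        provenance=dict(profile.provenance),
    )
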