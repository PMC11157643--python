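"""Independent oracles used by the test suite.

These deliberately avoid the package's solver/clustering code paths: the
deconvolution oracle scores candidate masses by brute-force charge
summation of the observed spectrum, and the clustering checker verifies
partition validity from the definition.
"""

from __future__ import annotations

import numpy as np


def charge_summation_mass(spectrum, config) -> float:
    """Brute-force zero-charge mass estimate.

    For every grid mass, sum the observed intensity interpolated at
    ``(M + z*m_p)/z`` over all charges in the configured range; read the
    peak of that score as the centroid of the contiguous region above half
    its apex (raw argmax is unstable because the profile peaks are sampled
    below Nyquist, giving the score a jittery ~1 Da flat top).
    """
    n = int(round((config.mass_high - config.mass_low) / config.mass_spacing)) + 1
    masses = config.mass_low + config.mass_spacing * np.arange(n)
    score = np.zeros_like(masses)
    for z in range(config.charge_min, config.charge_max + 1):
        pos = (masses + z * config.proton_mass) / z
        score += np.interp(pos, spectrum.mz, spectrum.intensity, left=0.0, right=0.0)
    i = int(np.argmax(score))
    thr = 0.5 * score[i]
    lo = i
    while lo > 0 and score[lo - 1] > thr:
        lo -= 1
    hi = i
    while hi < score.size - 1 and score[hi + 1] > thr:
        hi += 1
    seg = score[lo:hi + 1] - thr
    return float((masses[lo:hi + 1] * seg).sum() / seg.sum())


def slice_windows_by_enumeration(roi_start, roi_end, width, overlap):
    """Enumerate slice windows directly from the definition."""
    stride = width - overlap
    out = []
    k = 0
    while True:
        start = roi_start + k * stride
        end = start + width
        out.append((start, min(end, roi_end)))
        if end >= roi_end - 1e-9:
            break
        k += 1
    return out


def check_clone_partition(peaks, profile, merge_ppm, merge_max_rt_gap) -> None:
    """Assert the emitted clone list is a valid partition of the input peaks.

    Checks, from the clustering definition: every peak is accounted for
    exactly once; every clone's mass is the intensity-weighted mean of its
    members; each member lies within ``merge_ppm`` of that mean; members
    come from distinct slices; the members form an RT chain with no nearest
    gap above ``merge_max_rt_gap``; clone intensity is the member maximum.
    """
    import math

    remaining = sorted(
        ((p.mass, p.intensity, p.slice_index, p.slice_rt) for p in peaks))
    assigned_total = 0
    for clone in profile.clones:
        members = _recover_members(remaining, clone, merge_ppm)
        assert members, f"clone {clone.clone_id}: no matching members found"
        assigned_total += len(members)
        w = sum(m[1] for m in members)
        if w > 0:
            mean = sum(m[0] * m[1] for m in members) / w
        else:
            mean = sum(m[0] for m in members) / len(members)
        assert abs(mean - clone.mass) < 1e-6
        slices = [m[2] for m in members]
        assert len(slices) == len(set(slices)), "duplicate slice in one clone"
        assert clone.n_slices == len(members)
        assert clone.intensity == max(m[1] for m in members)
        for m in members:
            assert abs(m[0] - mean) / mean * 1e6 <= merge_ppm + 1e-6
        if math.isfinite(merge_max_rt_gap) and len(members) > 1:
            for m in members:
                gap = min(abs(m[3] - o[3]) for o in members if o is not m)
                assert gap <= merge_max_rt_gap + 1e-9
    assert assigned_total == len(list(peaks)), "peaks lost or duplicated"


def _recover_members(remaining, clone, merge_ppm):
    """Greedily pull the peaks belonging to a clone out of ``remaining``.

    Membership is recovered by mass proximity to the clone mass; works for
    the well-separated random fixtures these checks run on.
    """
    members = [m for m in remaining
               if abs(m[0] - clone.mass) / clone.mass * 1e6 <= merge_ppm + 1e-6]
    chosen = []
    seen_slices = set()
    for m in sorted(members, key=lambda m: abs(m[0] - clone.mass)):
        if m[2] in seen_slices:
            continue
        if len(chosen) == clone.n_slices:
            break
        chosen.append(m)
        seen_slices.add(m[2])
    for m in chosen:
        remaining.remove(m)
    return chosen
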