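"""Analysis of a reconstructed free-energy profile: Gaussian smoothing,
detection of the alternating minima/maxima (the profile's singularities),
smoothed and point-to-point barrier heights, ξ zones and per-singularity
membership bands.

When exactly five singularities are found they are labelled P1, M1, P2, M2,
P3 in ξ order (minima P, maxima M); otherwise generic ``min#``/``max#``
labels are used.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .wham import FreeEnergyProfile

__all__ = [
    "Singularity",
    "SingularitySet",
    "smooth_profile",
    "detect_singularities",
    "barrier_heights",
    "pointwise_barriers",
    "zone_filter",
    "singularity_band",
]


class ProfileAnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class Singularity:
    kind: str  # "min" or "max"
    xi: float
    F: float


@dataclass
class SingularitySet:
    """Alternating minima/maxima of a profile, with detection provenance."""

    singularities: list[Singularity]
    bandwidth: float | None = None
    prominence: float | None = None

    def __iter__(self):
        return iter(self.singularities)

    def __len__(self):
        return len(self.singularities)

    def __getitem__(self, i):
        return self.singularities[i]

    def labels(self) -> list[str]:
        """P1..P3/M1..M2 labels when the canonical five are present."""
        sings = self.singularities
        if len(sings) == 5 and [s.kind for s in sings] == \
                ["min", "max", "min", "max", "min"]:
            return ["P1", "M1", "P2", "M2", "P3"]
        out, nmin, nmax = [], 0, 0
        for s in sings:
            if s.kind == "min":
                nmin += 1
                out.append(f"min{nmin}")
            else:
                nmax += 1
                out.append(f"max{nmax}")
        return out

    def minima(self) -> list[Singularity]:
        return [s for s in self.singularities if s.kind == "min"]

    def maxima(self) -> list[Singularity]:
        return [s for s in self.singularities if s.kind == "max"]


def smooth_profile(profile: FreeEnergyProfile,
                   bandwidth: float = 0.05) -> FreeEnergyProfile:
    """Gaussian-kernel local average of the defined bins (σ = ``bandwidth`` Å).

    Undefined bins contribute nothing and remain undefined; the kernel is
    renormalized over the defined bins, so gaps do not bleed values.
    """
    if bandwidth <= 0:
        raise ProfileAnalysisError("bandwidth must be > 0")
    mask = profile.defined_mask
    if mask.sum() < 3:
        raise ProfileAnalysisError("need at least 3 defined bins to smooth")
    x = profile.xi_grid[mask]
    f = profile.F[mask]
    with np.errstate(under="ignore"):
        w = np.exp(-0.5 * ((x[:, None] - x[None, :]) / bandwidth) ** 2)
    fs = (w @ f) / w.sum(axis=1)
    out = np.full_like(profile.F, np.nan)
    out[mask] = fs
    return FreeEnergyProfile(xi_grid=profile.xi_grid.copy(), F=out,
                             defined_mask=mask.copy(),
                             window_offsets=profile.window_offsets)


def _raw_extrema(x: np.ndarray, f: np.ndarray) -> list[tuple[str, int]]:
    """Interior strict extrema by sign change of discrete differences.

    Plateaus resolve to their lowest-ξ bin.  First and last points are never
    extrema.
    """
    d = np.diff(f)
    sign = np.sign(d)
    # Carry the last nonzero slope sign across flat stretches.
    carried = sign.copy()
    for i in range(1, len(carried)):
        if carried[i] == 0:
            carried[i] = carried[i - 1]
    out = []
    prev = carried[0]
    for i in range(1, len(carried)):
        s = carried[i]
        if s != 0 and prev != 0 and s != prev:
            # The extremum bin: the first index of the plateau that ended
            # at position i (lowest ξ wins ties).
            j = i
            while j > 0 and sign[j - 1] == 0:
                j -= 1
            out.append(("max" if prev > 0 else "min", j))
        if s != 0:
            prev = s
    return out


def _enforce_alternation(cand: list[tuple[str, int]],
                         f: np.ndarray) -> list[tuple[str, int]]:
    """Drop the weaker of any same-kind adjacent pair until kinds alternate."""
    changed = True
    cand = list(cand)
    while changed:
        changed = False
        for i in range(len(cand) - 1):
            k1, j1 = cand[i]
            k2, j2 = cand[i + 1]
            if k1 == k2:
                if k1 == "max":
                    weaker = i if f[j1] < f[j2] else i + 1
                else:
                    weaker = i if f[j1] > f[j2] else i + 1
                del cand[weaker]
                changed = True
                break
    return cand


def detect_singularities(profile: FreeEnergyProfile,
                         prominence: float = 0.2) -> SingularitySet:
    """Find the alternating local extrema of a (smoothed) profile.

    Candidates are interior sign-change extrema of the defined bins; an
    extremum is kept only if it differs from both flanking opposite extrema
    (profile end values serve as virtual flanks) by at least ``prominence``
    kcal/mol.  The weakest offender is removed first and same-kind neighbours
    re-merged, so raising the prominence can only shrink the set.
    """
    mask = profile.defined_mask
    x = profile.xi_grid[mask]
    f = profile.F[mask]
    if len(f) < 3:
        return SingularitySet([], prominence=prominence)

    cand = _enforce_alternation(_raw_extrema(x, f), f)

    def depths(c):
        """Min |ΔF| of each extremum to its flanking opposite values."""
        out = []
        for i, (kind, j) in enumerate(c):
            left = f[c[i - 1][1]] if i > 0 else f[0]
            right = f[c[i + 1][1]] if i < len(c) - 1 else f[-1]
            out.append(min(abs(f[j] - left), abs(f[j] - right)))
        return out

    while cand:
        d = depths(cand)
        i_weak = int(np.argmin(d))
        if d[i_weak] >= prominence:
            break
        del cand[i_weak]
        cand = _enforce_alternation(cand, f)

    sings = [Singularity(kind, float(x[j]), float(f[j])) for kind, j in cand]
    return SingularitySet(sings, prominence=prominence)


def barrier_heights(sing: SingularitySet) -> list[tuple[str, str, float]]:
    """For each maximum, the forward barrier F(max) − F(preceding minimum).

    Returns (from-minimum label, over-maximum label, height) in ξ order;
    maxima with no preceding minimum are skipped.  Invariant under adding a
    constant to the profile.
    """
    labels = sing.labels()
    out = []
    prev_min: tuple[str, Singularity] | None = None
    for label, s in zip(labels, sing):
        if s.kind == "min":
            prev_min = (label, s)
        elif prev_min is not None:
            out.append((prev_min[0], label, s.F - prev_min[1].F))
    return out


def pointwise_barriers(raw: FreeEnergyProfile, sing: SingularitySet,
                       half_window: float = 0.1) -> list[tuple[str, str, float]]:
    """Point-to-point barriers on the unsmoothed profile.

    For each min→max pair of ``sing``: the maximum raw F within
    ``half_window`` Å of the maximum's position minus the minimum raw F
    within ``half_window`` of the preceding minimum's position.
    """
    mask = raw.defined_mask
    x = raw.xi_grid[mask]
    f = raw.F[mask]

    def window_vals(center):
        sel = np.abs(x - center) <= half_window
        if not sel.any():
            raise ProfileAnalysisError(
                f"no defined bins within {half_window} Å of ξ = {center}")
        return f[sel]

    labels = sing.labels()
    out = []
    prev_min = None
    for label, s in zip(labels, sing):
        if s.kind == "min":
            prev_min = (label, s)
        elif prev_min is not None:
            lo = float(window_vals(prev_min[1].xi).min())
            hi = float(window_vals(s.xi).max())
            out.append((prev_min[0], label, hi - lo))
    return out


def _get_xi(record) -> float:
    if isinstance(record, (int, float, np.floating)):
        return float(record)
    if isinstance(record, dict):
        return float(record["xi"])
    return float(record.xi)


def zone_filter(records: Sequence, center: float, width: float = 0.4) -> list:
    """Records whose ξ lies within the zone |ξ − center| ≤ width/2.

    Accepts plain numbers, dicts with an ``xi`` key, or objects with an
    ``xi`` attribute.
    """
    if width <= 0:
        raise ProfileAnalysisError("zone width must be > 0")
    half = 0.5 * width
    return [r for r in records if abs(_get_xi(r) - center) <= half]


def singularity_band(profile: FreeEnergyProfile, sing: Singularity,
                     delta_F: float = 0.5) -> tuple[float, float]:
    """Maximal contiguous ξ interval around ``sing`` where
    |F − F(singularity)| ≤ delta_F (the membership band of the singularity)."""
    mask = profile.defined_mask
    x = profile.xi_grid[mask]
    f = profile.F[mask]
    j = int(np.argmin(np.abs(x - sing.xi)))
    inside = np.abs(f - f[j]) <= delta_F
    lo = j
    while lo > 0 and inside[lo - 1]:
        lo -= 1
    hi = j
    while hi < len(f) - 1 and inside[hi + 1]:
        hi += 1
    return float(x[lo]), float(x[hi])
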