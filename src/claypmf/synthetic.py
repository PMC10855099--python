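"""Synthetic study conditions: analytic reference free-energy profile,
biased 1-D sampling of the reaction coordinate, the 19-window umbrella
protocol, and toy 3-D snapshots with prescribed descriptor values.

The reference profile is an analytic stand-in for the desorption free-energy
surface: a C¹ curve interpolating the five printed singularities
P1 (3.41 Å, 0), M1 (3.88 Å, 1.5), P2 (4.24 Å, 0), M2 (5.35 Å, 11.5) and
P3 (5.56 Å, 11.0 kcal/mol), rising linearly beyond the last minimum and as a
steep repulsive wall below the first.  Biased sampling on this surface plus
the printed window protocol gives a desk-scale data set whose WHAM
reconstruction can be checked against a known ground truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .constants import DEFAULT_TEMPERATURE, kbt
from .geometry import AtomRecord, Snapshot, build_cell

__all__ = [
    "ReferenceProfile",
    "WindowSpec",
    "WindowSamples",
    "reference_profile_builder",
    "bias_potential",
    "sample_window",
    "make_window_table",
    "toy_snapshot",
    "DEFAULT_ANCHORS",
    "DEFAULT_TAIL_TARGET",
]


class SyntheticError(ValueError):
    """Invalid generator prescription."""


#: Printed singularity anchors (ξ in Å, F in kcal/mol): P1, M1, P2, M2, P3.
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (3.41, 0.0),
    (3.88, 1.5),
    (4.24, 0.0),
    (5.35, 11.5),
    (5.56, 11.0),
)

#: Default normalization point of the rising tail: F_ref ≈ 15 kcal/mol at the
#: outermost window center.  The free energy beyond the last minimum is a
#: model choice, not a measured quantity.
DEFAULT_TAIL_TARGET = (8.920, 15.0)

#: Left-wall slope (kcal/mol/Å): short-range surface repulsion below P1.
DEFAULT_LEFT_SLOPE = 20.0


class ReferenceProfile:
    """Analytic 1-D free-energy surface F_ref(ξ) with C¹ continuity.

    Between anchors: cubic Hermite segments with zero slope at every anchor
    (monotone between consecutive anchors, so no spurious extrema).

    Left of the first anchor: a repulsive wall, quadratic with the curvature
    of the first interior segment until the slope reaches
    ``tail_slope_left``, linear beyond (zero slope at the anchor itself).
    An explicit ``tail_width`` overrides the curvature-matched width.

    Right of the last anchor the profile rises in three C¹ pieces: a
    quadratic whose curvature matches the adjacent interior segment (width
    ``tail_match_width``), a concave blend (width ``tail_blend_width``)
    bringing the slope down to the asymptotic ``tail_slope``, then a straight
    line.  Matching the well curvature on both sides keeps kernel smoothing
    from displacing the last minimum.  If ``tail_slope`` is None it is solved
    so that F_ref passes through ``tail_target`` = (ξ*, F*).
    """

    def __init__(self, anchors, tail_slope: float | None = None,
                 tail_slope_left: float = DEFAULT_LEFT_SLOPE,
                 tail_width: float | None = None,
                 tail_match_width: float = 0.15,
                 tail_blend_width: float = 0.35,
                 tail_target: tuple[float, float] = DEFAULT_TAIL_TARGET):
        anchors = [(float(x), float(f)) for x, f in anchors]
        if len(anchors) < 2:
            raise SyntheticError("need at least two anchors")
        xs = np.array([x for x, _ in anchors])
        if not np.all(np.diff(xs) > 0):
            raise SyntheticError("anchor ξ values must be strictly increasing")
        if tail_slope_left <= 0:
            raise SyntheticError("left tail slope must be positive")
        if tail_width is not None and tail_width <= 0:
            raise SyntheticError("tail_width must be positive")
        if tail_match_width <= 0 or tail_blend_width <= 0:
            raise SyntheticError("tail widths must be positive")
        self.anchors = anchors
        self.tail_slope_left = float(tail_slope_left)
        h0 = anchors[1][0] - anchors[0][0]
        left_curv = max(6.0 * abs(anchors[1][1] - anchors[0][1]) / h0 ** 2, 1.0)
        if tail_width is None:
            tail_width = tail_slope_left / left_curv
        self.tail_width = float(tail_width)
        self.tail_match_width = float(tail_match_width)
        self.tail_blend_width = float(tail_blend_width)
        fs = np.array([f for _, f in anchors])
        self._x0, self._x1 = xs[0], xs[-1]
        self._f0, self._f1 = fs[0], fs[-1]
        self._spline = CubicHermiteSpline(xs, fs, np.zeros_like(fs))

        # Curvature of a zero-slope Hermite segment at its end: 6|ΔF|/h².
        h = xs[-1] - xs[-2]
        self._tail_curv = max(6.0 * abs(fs[-1] - fs[-2]) / h ** 2, 1.0)
        w1, w2 = self.tail_match_width, self.tail_blend_width
        b = self._tail_curv
        if tail_slope is None:
            xt, ft = tail_target
            run = xt - self._x1
            if run <= w1 + w2:
                raise SyntheticError(
                    "tail target lies inside the curvature-matched blend; "
                    "pass tail_slope explicitly")
            # F at the end of the two blend pieces, as a function of s:
            #   F1 + b w1²/2 + (b w1 + s) w2 / 2 + s (run - w1 - w2) = Ft
            num = ft - self._f1 - 0.5 * b * w1 ** 2 - 0.5 * b * w1 * w2
            den = 0.5 * w2 + run - w1 - w2
            tail_slope = num / den
            if tail_slope <= 0:
                raise SyntheticError(
                    f"tail target {tail_target} needs a non-positive slope; "
                    "choose a higher target or pass tail_slope explicitly")
        if tail_slope <= 0:
            raise SyntheticError("tail_slope must be positive")
        self.tail_slope = float(tail_slope)

    def _right_tail(self, d: np.ndarray) -> np.ndarray:
        """Rise above the last anchor as a function of d = ξ − ξ_last ≥ 0."""
        b, s = self._tail_curv, self.tail_slope
        w1, w2 = self.tail_match_width, self.tail_blend_width
        s1 = b * w1          # slope at the end of the matched piece
        f1 = 0.5 * b * w1 ** 2
        f2 = f1 + 0.5 * (s1 + s) * w2
        d2 = d - w1
        d3 = d - w1 - w2
        blend = f1 + s1 * d2 - 0.5 * (s1 - s) * d2 ** 2 / w2
        return np.where(d <= w1, 0.5 * b * d ** 2,
                        np.where(d <= w1 + w2, blend, f2 + s * d3))

    def _right_tail_deriv(self, d: np.ndarray) -> np.ndarray:
        b, s = self._tail_curv, self.tail_slope
        w1, w2 = self.tail_match_width, self.tail_blend_width
        s1 = b * w1
        return np.where(d <= w1, b * d,
                        np.where(d <= w1 + w2,
                                 s1 - (s1 - s) * (d - w1) / w2, s))

    def _left_tail(self, d: np.ndarray) -> np.ndarray:
        """Repulsive wall below the first anchor, d = ξ_first − ξ ≥ 0."""
        w, s = self.tail_width, self.tail_slope_left
        return np.where(d < w, 0.5 * s * d * d / w, s * (d - 0.5 * w))

    def _left_tail_deriv(self, d: np.ndarray) -> np.ndarray:
        w, s = self.tail_width, self.tail_slope_left
        return np.where(d < w, s * d / w, s)

    def free_energy(self, xi):
        """F_ref(ξ) in kcal/mol; accepts scalars or arrays."""
        xi = np.asarray(xi, dtype=float)
        out = self._spline(np.clip(xi, self._x0, self._x1))
        left = xi < self._x0
        right = xi > self._x1
        if np.any(left):
            out = np.where(left, self._f0 + self._left_tail(self._x0 - xi), out)
        if np.any(right):
            out = np.where(right, self._f1 + self._right_tail(xi - self._x1),
                           out)
        return out if out.ndim else float(out)

    __call__ = free_energy

    def derivative(self, xi):
        """dF_ref/dξ in kcal/mol/Å."""
        xi = np.asarray(xi, dtype=float)
        out = self._spline.derivative()(np.clip(xi, self._x0, self._x1))
        left = xi < self._x0
        right = xi > self._x1
        if np.any(left):
            out = np.where(left, -self._left_tail_deriv(self._x0 - xi), out)
        if np.any(right):
            out = np.where(right, self._right_tail_deriv(xi - self._x1), out)
        return out if out.ndim else float(out)


def reference_profile_builder(anchors=None, tail_slope: float | None = None,
                              tail_slope_left: float = DEFAULT_LEFT_SLOPE,
                              **tail_kwargs) -> ReferenceProfile:
    """Build a :class:`ReferenceProfile`; defaults are the printed anchors
    and a tail normalized through ``DEFAULT_TAIL_TARGET``."""
    if anchors is None:
        anchors = DEFAULT_ANCHORS
    return ReferenceProfile(anchors, tail_slope, tail_slope_left, **tail_kwargs)


@dataclass(frozen=True)
class WindowSpec:
    """One umbrella window: restraint center ξᵢ (Å), harmonic constant
    kᵢ (kcal/mol/Å²) and nominal duration tᵢ (ps)."""

    index: int
    xi: float
    k: float
    t_ps: float

    def __post_init__(self):
        if not self.k > 0:
            raise SyntheticError(f"window {self.index}: k must be > 0")
        if not self.t_ps > 0:
            raise SyntheticError(f"window {self.index}: t must be > 0")


def bias_potential(xi, window: WindowSpec):
    """Harmonic umbrella bias V(ξ) = ½ kᵢ (ξ − ξᵢ)² in kcal/mol."""
    xi = np.asarray(xi, dtype=float)
    v = 0.5 * window.k * (xi - window.xi) ** 2
    return v if v.ndim else float(v)


#: The 19-window umbrella protocol (index, ξᵢ/Å, kᵢ/kcal·mol⁻¹·Å⁻², tᵢ/ps).
#: Three centers (3.805, 5.421, 7.832) are duplicated with different k.
_WINDOW_TABLE = (
    (1, 3.583, 28.6, 13),
    (2, 3.628, 14.3, 16),
    (3, 3.805, 57.1, 4),
    (4, 3.805, 28.6, 9),
    (5, 4.157, 14.3, 12),
    (6, 4.486, 14.3, 14),
    (7, 5.216, 14.3, 12),
    (8, 5.421, 57.1, 5),
    (9, 5.421, 28.6, 7),
    (10, 5.615, 28.6, 13),
    (11, 5.745, 14.3, 14),
    (12, 6.274, 14.3, 12),
    (13, 6.803, 14.3, 14),
    (14, 7.332, 14.3, 14),
    (15, 7.832, 57.1, 4),
    (16, 7.832, 28.6, 10),
    (17, 7.861, 14.3, 12),
    (18, 8.391, 14.3, 12),
    (19, 8.920, 14.3, 12),
)


def make_window_table() -> list[WindowSpec]:
    """The 19 printed umbrella windows, duplicated centers included."""
    return [WindowSpec(i, xi, k, t) for i, xi, k, t in _WINDOW_TABLE]


@dataclass
class WindowSamples:
    """Reaction-coordinate samples of one biased window."""

    spec: WindowSpec
    xi: np.ndarray
    seed: int
    burn_in: int
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.xi = np.asarray(self.xi, dtype=float)
        if self.xi.size == 0:
            raise SyntheticError("empty sample series")


def _dense_table(profile: ReferenceProfile, lo: float, hi: float,
                 dx: float = 1e-3):
    """Tabulate F_ref on [lo, hi] for fast linear interpolation in the chain.

    With dx = 1e-3 Å the interpolation error is O(dx²·F'') ≲ 1e-5 kcal/mol,
    far below thermal noise.
    """
    n = int(math.ceil((hi - lo) / dx)) + 1
    grid = lo + dx * np.arange(n + 1)
    return grid[0], dx, profile.free_energy(grid)


def sample_window(profile: ReferenceProfile, window: WindowSpec, n: int,
                  burn_in: int | None = None, step: float = 0.3,
                  seed: int = 0, temperature: float = DEFAULT_TEMPERATURE,
                  method: str = "metropolis", dt: float = 5e-3) -> WindowSamples:
    """Sample ξ from the biased density ∝ exp(−[F_ref(ξ) + V(ξ)] / kBT).

    ``metropolis`` (default): Metropolis Monte Carlo with symmetric uniform
    proposals of half-width ``step`` (Å), started at the window center.
    ``langevin``: overdamped Langevin (Euler–Maruyama, time step ``dt``) on
    the same biased surface; produces autocorrelated series for diagnostics.
    The first ``burn_in`` samples (default 5 % of ``n``) are discarded;
    everything is reproducible from ``seed``.
    """
    if n <= 0:
        raise SyntheticError("n must be > 0")
    if step <= 0:
        raise SyntheticError("step must be > 0")
    if burn_in is None:
        burn_in = n // 20
    if burn_in < 0:
        raise SyntheticError("burn_in must be >= 0")
    beta = 1.0 / kbt(temperature)
    k, c = window.k, window.xi

    # Generous tabulation range: the bias confines the chain near the center.
    anchor_lo = profile.anchors[0][0]
    anchor_hi = profile.anchors[-1][0]
    lo = min(anchor_lo, c) - 4.0
    hi = max(anchor_hi, c) + 4.0
    x0, dx, table = _dense_table(profile, lo, hi)
    inv_dx = 1.0 / dx
    tmax = len(table) - 2

    rng = np.random.default_rng(seed)
    total = burn_in + n
    out = np.empty(n)

    if method == "metropolis":
        props = rng.uniform(-step, step, size=total)
        urand = rng.random(total)
        tab = table.tolist()  # python-list indexing is faster in the loop
        x = float(c)
        t = (x - x0) * inv_dx
        j = int(t)
        u_cur = tab[j] + (tab[j + 1] - tab[j]) * (t - j)  # + 0 bias at center
        exp = math.exp
        for i in range(total):
            xp = x + props[i]
            t = (xp - x0) * inv_dx
            j = int(t)
            if j < 0 or j > tmax:  # pragma: no cover - outside tabulated range
                up = float(profile.free_energy(xp)) + 0.5 * k * (xp - c) ** 2
            else:
                up = tab[j] + (tab[j + 1] - tab[j]) * (t - j) \
                    + 0.5 * k * (xp - c) ** 2
            du = up - u_cur
            if du <= 0.0 or urand[i] < exp(-beta * du):
                x = xp
                u_cur = up
            if i >= burn_in:
                out[i - burn_in] = x
    elif method == "langevin":
        # Overdamped dynamics: dx = -beta*D*U'(x)*dt + sqrt(2*D*dt)*eta with
        # unit diffusion constant D; the stationary density is the same.
        noise = rng.standard_normal(total) * math.sqrt(2.0 * dt)
        x = float(c)
        for i in range(total):
            grad = float(profile.derivative(x)) + k * (x - c)
            x = x - beta * grad * dt + noise[i]
            if i >= burn_in:
                out[i - burn_in] = x
    else:
        raise SyntheticError(f"unknown sampling method {method!r}")

    return WindowSamples(spec=window, xi=out, seed=seed, burn_in=burn_in,
                         temperature=temperature)


# ---------------------------------------------------------------------------
# Toy snapshots with prescribed descriptor values
# ---------------------------------------------------------------------------

#: Local in-plane coordinates (Å) of the rigid planar adsorbate proxy,
#: Cl at the origin and the ring N3 across the ring along +x.  Only the
#: named atoms enter descriptor definitions; the generic ring atoms give the
#: proxy a molecule-like mass distribution and hydration footprint.
_ATRAZINE_LOCAL = (
    ("Cl", "Cl", (0.00, 0.00)),
    ("N", "N3", (2.60, 0.00)),
    ("N", "N1", (1.25, 1.15)),
    ("C", "C2", (0.70, -1.20)),
    ("C", "C4", (2.10, -1.25)),
    ("C", "C6", (1.05, 0.05)),
    ("C", "Ce", (4.30, 1.40)),
    ("C", "Ci", (4.30, -1.40)),
)

_TOY_CATION_CUTOFF = 3.0
_TOY_ATRA_CUTOFF = 3.5


def _fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (deterministic golden-spiral set)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def toy_snapshot(theta_target: float, hs_atra: int, hs_ca1: int,
                 hs_ca2: int, shared: int, xi_target: float,
                 seed: int = 0) -> Snapshot:
    """Build a snapshot whose descriptors equal the prescription.

    A flat Ob sheet sits at z = 0; a rigid planar adsorbate proxy is tilted
    so the ghost-atom angle θ equals ``theta_target`` (deg) and translated so
    its center of mass sits ``xi_target`` Å above the sheet; water oxygens
    are placed inside/outside the hydration cutoffs (3.0 Å cation, 3.5 Å
    adsorbate heavy atoms) so the sphere sizes and the Atra∩Ca1 overlap are
    exactly ``hs_atra``, ``hs_ca1``, ``hs_ca2`` and ``shared``; Ca2 waters
    are disjoint from both other spheres.

    Raises :class:`SyntheticError` for infeasible prescriptions.
    """
    for name, v in (("hs_atra", hs_atra), ("hs_ca1", hs_ca1),
                    ("hs_ca2", hs_ca2), ("shared", shared)):
        if v < 0:
            raise SyntheticError(f"{name} must be >= 0")
    if shared > min(hs_atra, hs_ca1):
        raise SyntheticError("shared waters cannot exceed min(hs_atra, hs_ca1)")
    if not -90.0 <= theta_target <= 90.0:
        raise SyntheticError("theta_target must lie in [-90, 90] degrees")

    rng = np.random.default_rng(seed)
    cell = build_cell(30.0, 30.0, 40.0, 90.0, 90.0, 90.0)
    atoms: list[AtomRecord] = []

    # Basal-oxygen sheet at z = 0 (5 x 5 grid around the adsorbate).
    for ix in range(5):
        for iy in range(5):
            atoms.append(AtomRecord("O", "Ob",
                                    (6.0 + 3.0 * ix, 6.0 + 3.0 * iy, 0.0)))
    surf_indices = list(range(len(atoms)))

    # Adsorbate proxy: tilt the plane about the y axis through Cl so that
    # z_N3 - z_Cl = d*sin(theta) while the xy separation is d*cos(theta).
    th = math.radians(theta_target)
    origin = np.array([12.0, 12.0, 0.0])
    atra_start = len(atoms)
    for element, label, (lx, ly) in _ATRAZINE_LOCAL:
        pos = origin + np.array([lx * math.cos(th), ly, lx * math.sin(th)])
        atoms.append(AtomRecord(element, f"atrazine:{label}", pos))
    atra_atoms = atoms[atra_start:]
    masses = np.array([at.mass for at in atra_atoms])
    com_z = float(np.dot(masses, [at.position[2] for at in atra_atoms])
                  / masses.sum())
    dz = xi_target - com_z
    for at in atra_atoms:
        at.position = at.position + np.array([0.0, 0.0, dz])
    heavy = np.array([at.position for at in atra_atoms])

    n1 = next(at.position for at in atra_atoms if at.role == "atrazine:N1")
    centroid = heavy.mean(axis=0)
    away = n1 - centroid
    away[2] = 0.0
    away /= np.linalg.norm(away)
    ca1_pos = n1 + 2.411 * away
    atoms.append(AtomRecord("Ca", "Ca1", ca1_pos))
    ca2_pos = np.array([24.0, 24.0, 0.6])
    atoms.append(AtomRecord("Ca", "Ca2", ca2_pos))

    waters: list[np.ndarray] = []

    def _dist_to_heavy(p):
        return float(np.min(np.linalg.norm(heavy - p, axis=1)))

    # Shared waters: inside both the Ca1 3.0 Å and the adsorbate 3.5 Å shell.
    u = (ca1_pos - n1) / np.linalg.norm(ca1_pos - n1)
    v = np.array([0.0, 0.0, 1.0])
    v = v - np.dot(v, u) * u
    v /= np.linalg.norm(v)
    phis = [0.0]
    for m in range(1, shared + 1):
        phis.extend([0.22 * m, -0.22 * m])
    placed = 0
    for phi in phis:
        if placed == shared:
            break
        p = n1 + 3.3 * (math.cos(phi) * u + math.sin(phi) * v)
        if (np.linalg.norm(p - ca1_pos) <= _TOY_CATION_CUTOFF
                and _dist_to_heavy(p) <= _TOY_ATRA_CUTOFF
                and np.linalg.norm(p - ca2_pos) > _TOY_CATION_CUTOFF + 0.5):
            waters.append(p)
            placed += 1
    if placed < shared:
        raise SyntheticError(
            f"could not place {shared} shared waters (placed {placed})")

    # Ca1-only waters: within 3.0 Å of Ca1 but beyond 3.5 Å of every
    # adsorbate heavy atom.
    need = hs_ca1 - shared
    placed = 0
    for r in (2.6, 2.9):
        for d in _fibonacci_directions(64):
            if placed == need:
                break
            p = ca1_pos + r * d
            if (_dist_to_heavy(p) > _TOY_ATRA_CUTOFF + 0.15
                    and np.linalg.norm(p - ca2_pos) > _TOY_CATION_CUTOFF + 0.5):
                waters.append(p)
                placed += 1
        if placed == need:
            break
    if placed < need:
        raise SyntheticError(
            f"could not place {need} Ca1-only waters (placed {placed})")

    # Adsorbate-only waters: within 3.5 Å of some heavy atom, outside both
    # cation shells.
    need = hs_atra - shared
    placed = 0
    anchors = [at.position for at in atra_atoms]
    for radius in (3.1, 2.6, 3.35):
        for anchor in anchors:
            for d in _fibonacci_directions(48):
                if placed == need:
                    break
                p = anchor + radius * d + rng.uniform(-0.04, 0.04, size=3)
                if not _dist_to_heavy(p) <= _TOY_ATRA_CUTOFF - 0.05:
                    continue
                if np.linalg.norm(p - ca1_pos) <= _TOY_CATION_CUTOFF + 0.15:
                    continue
                if np.linalg.norm(p - ca2_pos) <= _TOY_CATION_CUTOFF + 0.5:
                    continue
                if waters and min(np.linalg.norm(np.array(waters) - p, axis=1)) < 0.35:
                    continue
                waters.append(p)
                placed += 1
            if placed == need:
                break
        if placed == need:
            break
    if placed < need:
        raise SyntheticError(
            f"could not place {need} adsorbate-only waters (placed {placed})")

    # Ca2 waters: around the far cation, automatically disjoint.
    placed = 0
    for r in (2.5, 2.8):
        for d in _fibonacci_directions(32):
            if placed == hs_ca2:
                break
            p = ca2_pos + r * d
            if (_dist_to_heavy(p) > _TOY_ATRA_CUTOFF + 0.5
                    and np.linalg.norm(p - ca1_pos) > _TOY_CATION_CUTOFF + 0.5):
                waters.append(p)
                placed += 1
        if placed == hs_ca2:
            break
    if placed < hs_ca2:
        raise SyntheticError(
            f"could not place {hs_ca2} Ca2 waters (placed {placed})")

    for p in waters:
        atoms.append(AtomRecord("O", "Ow", p))

    return Snapshot(cell=cell, atoms=atoms, time=0.0,
                    surf_indices=surf_indices)
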