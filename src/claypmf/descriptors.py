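"""Per-snapshot structural descriptors of the adsorbate/clay system.

Quantities follow the conventions of the desorption analysis:

* reaction coordinate ξ — Cartesian z distance between the adsorbate's
  center of mass and the basal-oxygen surface plane;
* tilt angle θ — signed angle at the Cl vertex between Cl→X and Cl→N3,
  with the ghost atom X = (x_N3, y_N3, z_Cl); positive when N3 sits higher
  than Cl, so θ ≈ 0 means the triazine ring lies parallel to the surface;
* hydration spheres — water oxygens within a cutoff of an entity
  (3.0 Å for the cations; 3.5 Å default from any adsorbate heavy atom);
* named distances — cation–adsorbate and atom–surface separations
  (minimum-image for 3-D pairs, signed z offset for –surf ones).

Hydrogen atoms never enter distance criteria.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (GeometryError, Snapshot, center_of_mass,
                       min_image_distance, surface_z)

__all__ = [
    "HydrationReport",
    "DescriptorRecord",
    "reaction_coordinate",
    "theta_angle",
    "hydration_sphere",
    "hydration_report",
    "named_distances",
    "normalized_distribution",
    "summary_table",
    "describe_snapshot",
    "DISTANCE_NAMES",
]

#: Cutoff (Å) for a water oxygen to belong to a cation's first shell.
CATION_CUTOFF = 3.0
#: Default cutoff (Å) from any adsorbate heavy atom (not fixed by the study
#: conditions; configurable everywhere it is used).
ATRA_CUTOFF = 3.5

#: Fixed column order of the named distances.
DISTANCE_NAMES = ("Ca1-N1", "Ca1-Cl", "Ca1-Ca2", "Ce-surf", "Ci-surf",
                  "Cl-surf", "Ca1-surf", "Ca2-surf")


@dataclass
class HydrationReport:
    """First hydration spheres (sets of water-oxygen atom indices) of the
    adsorbate, Ca1 and Ca2, with their overlap and union counts."""

    hs_atra: frozenset[int]
    hs_ca1: frozenset[int]
    hs_ca2: frozenset[int]

    @property
    def shared_atra_ca1(self) -> int:
        """|HS_Atra ∩ HS_Ca1| — waters common to adsorbate and Ca1."""
        return len(self.hs_atra & self.hs_ca1)

    @property
    def hs_atra_ca1(self) -> int:
        """|HS_Atra ∪ HS_Ca1| — hydration of the adsorbate–Ca1 entity."""
        return len(self.hs_atra | self.hs_ca1)

    @property
    def hs_tot(self) -> int:
        """|HS_Atra ∪ HS_Ca1 ∪ HS_Ca2|."""
        return len(self.hs_atra | self.hs_ca1 | self.hs_ca2)

    @property
    def ca1_subset_of_atra(self) -> bool:
        """True in the regime where HS_Ca1 is contained in HS_Atra."""
        return self.hs_ca1 <= self.hs_atra


@dataclass
class DescriptorRecord:
    """All descriptors of one snapshot."""

    xi: float
    theta: float
    distances: dict[str, float]
    hydration: HydrationReport
    time: float = 0.0


def reaction_coordinate(snapshot: Snapshot) -> float:
    """ξ = z(adsorbate center of mass) − z(surface plane), in Å."""
    atra = snapshot.atrazine_atoms(heavy_only=False)
    if not atra:
        raise GeometryError("snapshot has no atrazine atoms")
    return float(center_of_mass(atra)[2]) - surface_z(snapshot)


def theta_angle(snapshot: Snapshot) -> float:
    """Signed tilt angle θ (deg) of the triazine ring.

    θ = sign(z_N3 − z_Cl) × angle(X–Cl–N3) with X = (x_N3, y_N3, z_Cl).
    If N3 lies exactly above/below Cl the angle is ±90° by the sign rule;
    coincident Cl and N3 is an error.
    """
    cl = snapshot.single_atom("atrazine:Cl").position
    n3 = snapshot.single_atom("atrazine:N3").position
    dxy = math.hypot(n3[0] - cl[0], n3[1] - cl[1])
    dz = n3[2] - cl[2]
    if dxy == 0.0 and dz == 0.0:
        raise GeometryError("Cl and N3 coincide; θ undefined")
    return math.degrees(math.atan2(dz, dxy))


def hydration_sphere(snapshot: Snapshot, entity: str,
                     cutoff: float | None = None) -> frozenset[int]:
    """Water-oxygen indices within ``cutoff`` of ``entity``.

    ``entity`` is "Ca1", "Ca2" (distance to the cation, default cutoff
    3.0 Å) or "Atra" (distance to the nearest adsorbate heavy atom, default
    cutoff 3.5 Å).  Distances are minimum-image.
    """
    if entity in ("Ca1", "Ca2"):
        if cutoff is None:
            cutoff = CATION_CUTOFF
        refs = [snapshot.single_atom(entity).position]
    elif entity == "Atra":
        if cutoff is None:
            cutoff = ATRA_CUTOFF
        refs = [at.position for at in snapshot.atrazine_atoms(heavy_only=True)]
        if not refs:
            raise GeometryError("snapshot has no atrazine heavy atoms")
    else:
        raise GeometryError(f"unknown hydration entity {entity!r}")
    if cutoff <= 0:
        raise GeometryError("cutoff must be > 0")
    cell = snapshot.cell
    members = []
    for i in snapshot.water_oxygen_indices():
        p = snapshot.atoms[i].position
        if any(min_image_distance(p, r, cell) <= cutoff for r in refs):
            members.append(i)
    return frozenset(members)


def hydration_report(snapshot: Snapshot, cation_cutoff: float = CATION_CUTOFF,
                     atra_cutoff: float = ATRA_CUTOFF) -> HydrationReport:
    """First hydration spheres of the adsorbate, Ca1 and Ca2."""
    return HydrationReport(
        hs_atra=hydration_sphere(snapshot, "Atra", atra_cutoff),
        hs_ca1=hydration_sphere(snapshot, "Ca1", cation_cutoff),
        hs_ca2=hydration_sphere(snapshot, "Ca2", cation_cutoff),
    )


def named_distances(snapshot: Snapshot) -> dict[str, float]:
    """The fixed set of reported distances (Å).

    Ca1–N1, Ca1–Cl and Ca1–Ca2 are minimum-image 3-D distances; the –surf
    entries are the signed z offset of the atom from the surface plane.
    """
    cell = snapshot.cell
    surf = surface_z(snapshot)

    def pos(role: str) -> np.ndarray:
        try:
            return snapshot.single_atom(role).position
        except GeometryError:
            raise GeometryError(f"named distance needs atom {role!r}") from None

    ca1 = pos("Ca1")
    ca2 = pos("Ca2")
    return {
        "Ca1-N1": min_image_distance(ca1, pos("atrazine:N1"), cell),
        "Ca1-Cl": min_image_distance(ca1, pos("atrazine:Cl"), cell),
        "Ca1-Ca2": min_image_distance(ca1, ca2, cell),
        "Ce-surf": float(pos("atrazine:Ce")[2]) - surf,
        "Ci-surf": float(pos("atrazine:Ci")[2]) - surf,
        "Cl-surf": float(pos("atrazine:Cl")[2]) - surf,
        "Ca1-surf": float(ca1[2]) - surf,
        "Ca2-surf": float(ca2[2]) - surf,
    }


def normalized_distribution(values, n_bins: int,
                            range: tuple[float, float] | None = None):
    """Unit-area histogram (bin centers, densities); Σ density·Δ = 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise GeometryError("cannot histogram an empty value list")
    density, edges = np.histogram(values, bins=n_bins, range=range,
                                  density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def describe_snapshot(snapshot: Snapshot, cation_cutoff: float = CATION_CUTOFF,
                      atra_cutoff: float = ATRA_CUTOFF) -> DescriptorRecord:
    """Compute every descriptor of one snapshot."""
    return DescriptorRecord(
        xi=reaction_coordinate(snapshot),
        theta=theta_angle(snapshot),
        distances=named_distances(snapshot),
        hydration=hydration_report(snapshot, cation_cutoff, atra_cutoff),
        time=snapshot.time,
    )


def summary_table(records: dict[str, list[DescriptorRecord]]) -> pd.DataFrame:
    """Per-group summary in the layout of the study's report tables.

    ``records`` maps a group label (a singularity or ξ zone) to the records
    the caller assigned to it.  Columns: mean θ, mean named distances, the
    hydration-sphere means, the shared/union counts, and MIN/MAX/MEAN of the
    adsorbate sphere size.  Empty groups are reported as a warning and
    skipped.
    """
    rows = {}
    for label, recs in records.items():
        if not recs:
            warnings.warn(f"group {label!r} is empty; row omitted")
            continue
        row = {
            "n": len(recs),
            "theta_mean": float(np.mean([r.theta for r in recs])),
        }
        for name in DISTANCE_NAMES:
            row[f"{name}_mean"] = float(
                np.mean([r.distances[name] for r in recs]))
        hs_atra = [len(r.hydration.hs_atra) for r in recs]
        row.update({
            "HStot_mean": float(np.mean([r.hydration.hs_tot for r in recs])),
            "HSAtraCa1_mean": float(
                np.mean([r.hydration.hs_atra_ca1 for r in recs])),
            "shared_mean": float(
                np.mean([r.hydration.shared_atra_ca1 for r in recs])),
            "HSAtra_mean": float(np.mean(hs_atra)),
            "HSAtra_min": int(np.min(hs_atra)),
            "HSAtra_max": int(np.max(hs_atra)),
            "HSCa1_mean": float(
                np.mean([len(r.hydration.hs_ca1) for r in recs])),
            "HSCa2_mean": float(
                np.mean([len(r.hydration.hs_ca2) for r in recs])),
        })
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index")
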