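"""File formats and run configuration.

Everything on disk is plain text: tab-separated values with '.' decimals
and '#' comment lines, COLVAR-like two-column ξ series, extended-XYZ
snapshots paired with a JSON role map, and a YAML run configuration.
Writers format floats with ``repr``-precision so that a fixed config and
seed reproduce every file byte-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constants import DEFAULT_TEMPERATURE
from .geometry import AtomRecord, Snapshot, TriclinicCell, build_cell
from .profile_analysis import SingularitySet
from .synthetic import WindowSamples, WindowSpec
from .wham import FreeEnergyProfile

__all__ = [
    "RunConfig",
    "FormatError",
    "read_window_table", "write_window_table",
    "read_xi_series", "write_xi_series",
    "read_profile", "write_profile",
    "write_window_offsets", "write_overlap_matrix",
    "write_singularity_report", "write_barrier_report",
    "read_snapshot", "write_snapshot",
]

_WINDOW_HEADER = "i\txi_A\tk_kcal_mol_A2\tt_ps"


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass
class RunConfig:
    """All tunables of the pipeline, defaulting to the study conditions:
    350 K, 1000 WHAM bins, 1e-6 kcal/mol WHAM precision, 3.0 Å cation
    hydration cutoff, 0.4 Å-wide ξ zones at 6.0/7.0/8.0 Å."""

    temperature: float = DEFAULT_TEMPERATURE
    n_bins: int = 1000
    wham_tol: float = 1e-6
    wham_max_iter: int = 200_000
    bandwidth: float = 0.05
    prominence: float = 0.2
    band_delta_f: float = 0.5
    pointwise_half_window: float = 0.1
    n_samples: int = 200_000
    burn_in: int | None = None  # None -> 5 % of n_samples
    step: float = 0.3
    base_seed: int = 42
    cation_cutoff: float = 3.0
    atra_cutoff: float = 3.5
    zone_centers: tuple[float, ...] = (6.0, 7.0, 8.0)
    zone_width: float = 0.4
    overlap_threshold: float = 0.05
    #: bins with fewer aggregate counts are dropped before smoothing and
    #: singularity detection (their free energy is sampling noise)
    min_bin_count: int = 100

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["zone_centers"] = list(self.zone_centers)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "zone_centers" in data:
            data["zone_centers"] = tuple(data["zone_centers"])
        return cls(**data)

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logs."""
        data = dataclasses.asdict(self)
        data["zone_centers"] = list(self.zone_centers)
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _fmt(x: float) -> str:
    return repr(float(x))


# -- window tables ----------------------------------------------------------

def write_window_table(windows: list[WindowSpec], path: str | Path) -> None:
    lines = [_WINDOW_HEADER]
    for w in windows:
        lines.append(f"{w.index}\t{_fmt(w.xi)}\t{_fmt(w.k)}\t{_fmt(w.t_ps)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_window_table(path: str | Path) -> list[WindowSpec]:
    """Parse a TSV window table (header ``i  xi_A  k_kcal_mol_A2  t_ps``)."""
    out = []
    lines = Path(path).read_text().splitlines()
    body = [(n, ln) for n, ln in enumerate(lines, 1)
            if ln.strip() and not ln.lstrip().startswith("#")]
    if not body:
        raise FormatError(f"{path}: empty window table")
    first_n, first = body[0]
    if first.strip() != _WINDOW_HEADER.strip():
        raise FormatError(
            f"{path}:{first_n}: expected header {_WINDOW_HEADER!r}")
    for n, ln in body[1:]:
        parts = ln.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{n}: expected 4 tab-separated fields")
        try:
            idx = int(parts[0])
            xi, k, t = (float(p) for p in parts[1:])
        except ValueError:
            raise FormatError(f"{path}:{n}: non-numeric field") from None
        if k <= 0 or t <= 0:
            raise FormatError(f"{path}:{n}: k and t must be positive")
        out.append(WindowSpec(idx, xi, k, t))
    if not out:
        raise FormatError(f"{path}: window table has no data rows")
    return out


# -- ξ series (COLVAR-like) -------------------------------------------------

def write_xi_series(samples: WindowSamples, path: str | Path) -> None:
    lines = [
        f"# window {samples.spec.index}  xi_i={_fmt(samples.spec.xi)}"
        f"  k={_fmt(samples.spec.k)}  seed={samples.seed}"
        f"  burn_in={samples.burn_in}  T={_fmt(samples.temperature)}",
        "# time_index\txi_A",
    ]
    lines.extend(f"{i}\t{_fmt(x)}" for i, x in enumerate(samples.xi))
    Path(path).write_text("\n".join(lines) + "\n")


def read_xi_series(path: str | Path) -> np.ndarray:
    """Ordered ξ values from a two-column ``time_index  xi`` text file."""
    vals = []
    for n, ln in enumerate(Path(path).read_text().splitlines(), 1):
        s = ln.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) < 2:
            raise FormatError(f"{path}:{n}: expected two columns")
        try:
            vals.append(float(parts[1]))
        except ValueError:
            raise FormatError(f"{path}:{n}: non-numeric token {parts[1]!r}") \
                from None
    return np.array(vals)


# -- profiles and reports ---------------------------------------------------

def write_profile(profile: FreeEnergyProfile, path: str | Path) -> None:
    lines = ["xi_A\tF_kcal_mol\tdefined"]
    for x, f, d in zip(profile.xi_grid, profile.F, profile.defined_mask):
        lines.append(f"{_fmt(x)}\t{_fmt(f) if d else 'nan'}\t{int(d)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> FreeEnergyProfile:
    xs, fs, ds = [], [], []
    lines = Path(path).read_text().splitlines()
    for n, ln in enumerate(lines, 1):
        s = ln.strip()
        if not s or s.startswith("#") or s.startswith("xi_A"):
            continue
        parts = s.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{n}: expected 3 columns")
        xs.append(float(parts[0]))
        fs.append(float(parts[1]))
        ds.append(bool(int(parts[2])))
    return FreeEnergyProfile(xi_grid=np.array(xs), F=np.array(fs),
                             defined_mask=np.array(ds))


def write_window_offsets(profile: FreeEnergyProfile,
                         windows: list[WindowSpec], path: str | Path) -> None:
    lines = ["i\tf_kcal_mol"]
    for w, f in zip(windows, profile.window_offsets):
        lines.append(f"{w.index}\t{_fmt(f)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_overlap_matrix(ovl: np.ndarray, path: str | Path) -> None:
    lines = ["\t".join(_fmt(v) for v in row) for row in ovl]
    Path(path).write_text("\n".join(lines) + "\n")


def write_singularity_report(sing: SingularitySet, path: str | Path) -> None:
    lines = ["label\tkind\txi_A\tF_kcal_mol"]
    for label, s in zip(sing.labels(), sing):
        lines.append(f"{label}\t{s.kind}\t{_fmt(s.xi)}\t{_fmt(s.F)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_barrier_report(smoothed: list[tuple[str, str, float]],
                         pointwise: list[tuple[str, str, float]],
                         path: str | Path) -> None:
    """Barriers as TSV ``from  over  height_smoothed  height_pointwise``."""
    pw = {(a, b): h for a, b, h in pointwise}
    lines = ["from\tover\theight_smoothed\theight_pointwise"]
    for a, b, h in smoothed:
        hp = pw.get((a, b))
        lines.append(f"{a}\t{b}\t{_fmt(h)}\t{_fmt(hp) if hp is not None else 'nan'}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- snapshots (XYZ + JSON role map) ---------------------------------------

def write_snapshot(snapshot: Snapshot, xyz_path: str | Path,
                   roles_path: str | Path) -> None:
    """Write a snapshot as standard XYZ plus a JSON sidecar holding the
    cell parameters, the atom-index → role map and the surf indices."""
    lines = [str(len(snapshot.atoms)),
             f"t={_fmt(snapshot.time)} ps"]
    for at in snapshot.atoms:
        x, y, z = at.position
        lines.append(f"{at.element} {_fmt(x)} {_fmt(y)} {_fmt(z)}")
    Path(xyz_path).write_text("\n".join(lines) + "\n")
    c = snapshot.cell
    sidecar = {
        "cell": {"a": c.a, "b": c.b, "c": c.c,
                 "alpha": c.alpha, "beta": c.beta, "gamma": c.gamma},
        "roles": {str(i): at.role for i, at in enumerate(snapshot.atoms)},
        "surf": (list(snapshot.surf_indices)
                 if snapshot.surf_indices is not None else None),
        "time_ps": snapshot.time,
    }
    Path(roles_path).write_text(json.dumps(sidecar, indent=1) + "\n")


def read_snapshot(xyz_path: str | Path, roles_path: str | Path) -> Snapshot:
    """Read an XYZ file and its JSON role map back into a snapshot.

    Positions are used as written; no periodic unwrapping is applied, so
    molecules must be stored in one connected image.
    """
    lines = Path(xyz_path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{xyz_path}: empty file")
    try:
        n_atoms = int(lines[0].strip())
    except ValueError:
        raise FormatError(f"{xyz_path}:1: expected atom count") from None
    if len(lines) < n_atoms + 2:
        raise FormatError(f"{xyz_path}: truncated (expected {n_atoms} atoms)")
    sidecar = json.loads(Path(roles_path).read_text())
    cell_p = sidecar["cell"]
    cell = build_cell(cell_p["a"], cell_p["b"], cell_p["c"],
                      cell_p["alpha"], cell_p["beta"], cell_p["gamma"])
    roles = sidecar["roles"]
    atoms = []
    for i in range(n_atoms):
        parts = lines[i + 2].split()
        if len(parts) < 4:
            raise FormatError(f"{xyz_path}:{i + 3}: expected 'El x y z'")
        try:
            pos = [float(p) for p in parts[1:4]]
        except ValueError:
            raise FormatError(f"{xyz_path}:{i + 3}: non-numeric coordinate") \
                from None
        atoms.append(AtomRecord(parts[0], roles[str(i)], pos))
    return Snapshot(cell=cell, atoms=atoms,
                    time=float(sidecar.get("time_ps", 0.0)),
                    surf_indices=sidecar.get("surf"))
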