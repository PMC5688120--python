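"""Featurization of coordinate trajectories and kinase order parameters.

Turns Cartesian trajectories into feature matrices (dihedrals, contact
distances) and computes the structural order parameters used to follow
kinase activation: activation-loop / P-loop / R-spine / DFG RMSDs relative
to a double-helical inactive reference, and the two regulatory salt-bridge
distances (Glu439–Arg468 and Glu445–Lys430, author numbering).

Coordinates are in Å and times in ns throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "CoordinateTrajectory",
    "FeatureTrajectory",
    "OrderParameterSpec",
    "Normalizer",
    "compute_dihedrals",
    "dihedral_angle",
    "compute_min_heavy_distances",
    "superpose_rmsd",
    "kabsch",
    "atom_pair_distance",
    "order_parameter_panel",
    "moving_average",
    "normalize_features",
]

_HYDROGEN = {"H", "D"}

# gamma-position side-chain atoms accepted as the fourth chi1 atom
_CHI1_GAMMA = ("CG", "CG1", "OG", "OG1", "SG", "CD", "SD")


@dataclass
class Topology:
    """Per-atom table: name, element, residue name, residue number (author
    numbering), heavy-atom flag. (residue number, atom name) pairs are unique."""

    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"name", "element", "res_name", "res_seq"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise ValueError(f"topology table missing columns: {sorted(missing)}")
        if "heavy" not in self.atoms.columns:
            self.atoms = self.atoms.assign(
                heavy=~self.atoms["element"].str.upper().isin(_HYDROGEN)
            )
        dup = self.atoms.duplicated(subset=["res_seq", "name"])
        if dup.any():
            bad = self.atoms.loc[dup, ["res_seq", "name"]].values.tolist()
            raise ValueError(f"duplicate (residue, atom name) pairs: {bad[:5]}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def res_seqs(self) -> np.ndarray:
        return np.unique(self.atoms["res_seq"].to_numpy())

    def atom_index(self, res_seq: int, name: str) -> int:
        sel = (self.atoms["res_seq"] == res_seq) & (self.atoms["name"] == name)
        idx = np.flatnonzero(sel.to_numpy())
        if idx.size == 0:
            raise KeyError(f"atom {name!r} of residue {res_seq} not in topology")
        return int(idx[0])

    def has_atom(self, res_seq: int, name: str) -> bool:
        sel = (self.atoms["res_seq"] == res_seq) & (self.atoms["name"] == name)
        return bool(sel.any())

    def heavy_indices(self, res_seqs) -> np.ndarray:
        res_seqs = np.atleast_1d(np.asarray(res_seqs))
        mask = self.atoms["res_seq"].isin(res_seqs) & self.atoms["heavy"]
        return np.flatnonzero(mask.to_numpy())

    def to_mdtraj(self):
        """Build an mdtraj Topology carrying the same names and numbering."""
        import mdtraj as md

        top = md.Topology()
        chain = top.add_chain()
        residue = None
        last_seq = None
        for row in self.atoms.itertuples(index=False):
            if residue is None or row.res_seq != last_seq:
                residue = top.add_residue(row.res_name, chain, resSeq=int(row.res_seq))
                last_seq = row.res_seq
            element = md.element.Element.getBySymbol(row.element.capitalize())
            top.add_atom(row.name, element, residue)
        return top

    @classmethod
    def from_mdtraj(cls, top) -> "Topology":
        records = [
            {
                "name": a.name,
                "element": a.element.symbol.upper(),
                "res_name": a.residue.name,
                "res_seq": a.residue.resSeq,
            }
            for a in top.atoms
        ]
        return cls(pd.DataFrame.from_records(records))


@dataclass
class CoordinateTrajectory:
    """Cartesian frames (time × atom × 3, Å) with a fixed frame interval."""

    xyz: np.ndarray
    dt: float
    topology: Topology

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (n_frames, n_atoms, 3)")
        if self.xyz.shape[1] != self.topology.n_atoms:
            raise ValueError("atom count does not match topology")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    def to_mdtraj(self):
        import mdtraj as md

        # mdtraj stores nm; our canonical unit is Å
        return md.Trajectory(self.xyz / 10.0, self.topology.to_mdtraj())

    @classmethod
    def from_mdtraj(cls, traj, dt: float) -> "CoordinateTrajectory":
        return cls(traj.xyz * 10.0, dt, Topology.from_mdtraj(traj.topology))


@dataclass
class FeatureTrajectory:
    """Time × feature matrix with named columns and a fixed frame interval."""

    values: np.ndarray
    dt: float
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_frames, n_features)")
        if not self.names:
            self.names = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.names) != self.values.shape[1]:
            raise ValueError("feature name count must match column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle(s) in (−π, π] for points of shape (..., 3).

    Praxeolitic atan2 formulation; stable for near-degenerate geometries.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.arctan2(y, x)
    # convention: torsion of the textbook trans arrangement is +π, not −π
    return np.where(np.isclose(ang, -np.pi), np.pi, ang)


def _torsion_quads(top: Topology, which) -> tuple[list[tuple[int, int, int, int]], list[str]]:
    quads: list[tuple[int, int, int, int]] = []
    names: list[str] = []
    seqs = top.res_seqs
    seq_set = set(int(s) for s in seqs)
    for s in seqs:
        s = int(s)
        if "phi" in which and (s - 1) in seq_set:
            try:
                q = (top.atom_index(s - 1, "C"), top.atom_index(s, "N"),
                     top.atom_index(s, "CA"), top.atom_index(s, "C"))
                quads.append(q)
                names.append(f"phi_{s}")
            except KeyError:
                pass
        if "psi" in which and (s + 1) in seq_set:
            try:
                q = (top.atom_index(s, "N"), top.atom_index(s, "CA"),
                     top.atom_index(s, "C"), top.atom_index(s + 1, "N"))
                quads.append(q)
                names.append(f"psi_{s}")
            except KeyError:
                pass
        if "chi1" in which:
            gamma = next((g for g in _CHI1_GAMMA if top.has_atom(s, g)), None)
            if gamma is not None and all(top.has_atom(s, a) for a in ("N", "CA", "CB")):
                quads.append((top.atom_index(s, "N"), top.atom_index(s, "CA"),
                              top.atom_index(s, "CB"), top.atom_index(s, gamma)))
                names.append(f"chi1_{s}")
    return quads, names


def compute_dihedrals(
    traj: CoordinateTrajectory,
    which=("phi", "psi", "chi1"),
    dihedral_atoms=None,
) -> FeatureTrajectory:
    """Backbone/side-chain torsions emitted as (sin, cos) pairs per angle.

    ``which`` selects torsion families discovered from the topology (residues
    missing the needed atoms are skipped, as at chain termini). Alternatively
    ``dihedral_atoms`` gives explicit quads of (res_seq, atom_name); any
    missing atom raises a KeyError naming the residue.
    """
    if dihedral_atoms is not None:
        quads, names = [], []
        for i, quad in enumerate(dihedral_atoms):
            idx = tuple(traj.topology.atom_index(r, a) for r, a in quad)
            quads.append(idx)
            names.append(f"torsion_{i}")
    else:
        quads, names = _torsion_quads(traj.topology, which)
    if not quads:
        raise ValueError("no resolvable torsions in topology")
    q = np.asarray(quads)
    ang = dihedral_angle(
        traj.xyz[:, q[:, 0]], traj.xyz[:, q[:, 1]],
        traj.xyz[:, q[:, 2]], traj.xyz[:, q[:, 3]],
    )  # (T, n_torsions)
    values = np.empty((traj.n_frames, 2 * ang.shape[1]))
    values[:, 0::2] = np.sin(ang)
    values[:, 1::2] = np.cos(ang)
    colnames = []
    for n in names:
        colnames.extend([f"{n}_sin", f"{n}_cos"])
    return FeatureTrajectory(values, traj.dt, colnames)


def compute_min_heavy_distances(traj: CoordinateTrajectory, residue_pairs) -> FeatureTrajectory:
    """Per-frame minimum heavy-atom distance (Å) for each residue pair."""
    cols = []
    names = []
    for ra, rb in residue_pairs:
        ia = traj.topology.heavy_indices(ra)
        ib = traj.topology.heavy_indices(rb)
        if ia.size == 0 or ib.size == 0:
            raise ValueError(f"residue pair ({ra}, {rb}) has no heavy atoms")
        diff = traj.xyz[:, ia, None, :] - traj.xyz[:, None, ib, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1))
        cols.append(d.reshape(traj.n_frames, -1).min(axis=1))
        names.append(f"mindist_{ra}_{rb}")
    return FeatureTrajectory(np.column_stack(cols), traj.dt, names)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing ‖mobile@R + t − target‖.

    Standard SVD solution with the determinant correction for proper rotations.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, 1.0, d])
    rot = u @ s @ vt
    return rot, tc - mc @ rot


def superpose_rmsd(
    traj: CoordinateTrajectory,
    reference: np.ndarray,
    selection: np.ndarray,
    fit: bool = True,
    fit_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) over ``selection`` against a reference frame.

    With ``fit`` the mobile frame is first rigid-body superposed onto the
    reference; the fit uses ``fit_selection`` if given, else the measured
    selection itself.
    """
    reference = np.asarray(reference, dtype=float)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty atom selection")
    if reference.shape[0] != traj.xyz.shape[1]:
        raise ValueError("reference atom count mismatch")
    fit_sel = selection if fit_selection is None else np.asarray(fit_selection, dtype=int)
    out = np.empty(traj.n_frames)
    ref_sel = reference[selection]
    for i in range(traj.n_frames):
        frame = traj.xyz[i]
        if fit:
            rot, trans = kabsch(frame[fit_sel], reference[fit_sel])
            moved = frame[selection] @ rot + trans
        else:
            moved = frame[selection]
        diff = moved - ref_sel
        out[i] = np.sqrt(np.mean(np.sum(diff * diff, axis=1)))
    return out


def atom_pair_distance(traj: CoordinateTrajectory, pair) -> np.ndarray:
    """Per-frame Euclidean distance (Å) between two named atoms."""
    (ra, na), (rb, nb) = pair
    ia = traj.topology.atom_index(ra, na)
    ib = traj.topology.atom_index(rb, nb)
    diff = traj.xyz[:, ia, :] - traj.xyz[:, ib, :]
    return np.linalg.norm(diff, axis=1)


@dataclass
class OrderParameterSpec:
    """Atom selections for the kinase switch panel (author residue numbering).

    Defaults follow the BTK catalytic domain: A-loop 539–559, DFG 539–541,
    P-loop 410–415, R-spine {540, 449, 519, 460}; salt bridges Glu439(CD)–
    Arg468(CZ) and Glu445(CD)–Lys430(NZ). RMSDs are taken relative to
    ``reference`` (a double-helical inactive frame).
    """

    reference: np.ndarray
    aloop: tuple[int, int] = (539, 559)
    dfg: tuple[int, int] = (539, 541)
    ploop: tuple[int, int] = (410, 415)
    rspine: tuple[int, ...] = (540, 449, 519, 460)
    salt_bridge_1: tuple = ((439, "CD"), (468, "CZ"))  # Glu439–Arg468
    salt_bridge_2: tuple = ((445, "CD"), (430, "NZ"))  # Glu445–Lys430
    fit_on_selection: bool = True


def order_parameter_panel(traj: CoordinateTrajectory, spec: OrderParameterSpec) -> FeatureTrajectory:
    """Kinase-switch panel: A-loop/P-loop/R-spine/DFG RMSDs and the two
    regulatory salt-bridge distances, one named column each."""
    top = traj.topology

    def _range_sel(lo, hi):
        return top.heavy_indices(np.arange(lo, hi + 1))

    cols = {
        "aloop_rmsd": superpose_rmsd(traj, spec.reference, _range_sel(*spec.aloop), fit=spec.fit_on_selection),
        "r468_e439_dist": atom_pair_distance(traj, spec.salt_bridge_1),
        "k430_e445_dist": atom_pair_distance(traj, spec.salt_bridge_2),
        "ploop_rmsd": superpose_rmsd(traj, spec.reference, _range_sel(*spec.ploop), fit=spec.fit_on_selection),
        "rspine_rmsd": superpose_rmsd(traj, spec.reference, top.heavy_indices(list(spec.rspine)), fit=spec.fit_on_selection),
        "dfg_rmsd": superpose_rmsd(traj, spec.reference, _range_sel(*spec.dfg), fit=spec.fit_on_selection),
    }
    names = list(cols)
    return FeatureTrajectory(np.column_stack([cols[n] for n in names]), traj.dt, names)


def moving_average(series, window: int) -> np.ndarray:
    """Trailing mean over ``window`` frames; the first window−1 entries are
    averaged over the available prefix."""
    series = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be ≥ 1")
    if window > series.shape[0]:
        raise ValueError("window exceeds series length")
    c = np.concatenate([[0.0], np.cumsum(series)])
    out = np.empty_like(series)
    n = series.shape[0]
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - window, 0)
    out = (c[idx] - c[lo]) / (idx - lo)
    return out


@dataclass
class Normalizer:
    """Per-feature z-scoring parameters pooled over a trajectory set."""

    mean: np.ndarray
    scale: np.ndarray
    constant: np.ndarray  # flags features with zero pooled variance

    def transform(self, traj: FeatureTrajectory) -> FeatureTrajectory:
        vals = (traj.values - self.mean) / self.scale
        return FeatureTrajectory(vals, traj.dt, list(traj.names))


def normalize_features(trajs) -> tuple[list[FeatureTrajectory], Normalizer]:
    """Pooled per-feature z-scoring. Zero-variance features get scale 1 and
    are flagged rather than divided by zero."""
    trajs = list(trajs)
    if not trajs:
        raise ValueError("no trajectories given")
    x = np.concatenate([t.values for t in trajs], axis=0)
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    constant = var <= 1e-15 * max(1.0, float(var.max(initial=0.0)))
    scale = np.where(constant, 1.0, np.sqrt(var))
    norm = Normalizer(mean, scale, constant)
    return [norm.transform(t) for t in trajs], norm
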