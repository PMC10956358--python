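"""Trajectory statistics: superposition, RMSD, RMSF, radius of gyration,
hydrogen-bond counting, SASA, coordinate PCA, and free-energy landscapes.

Coordinates are in angstroms, masses in amu, energies in kcal/mol.

Conventions
-----------
* RMSD is mass-weighted by default and computed after a weighted Kabsch fit.
* RMSF aligns frames to an iteratively refined mean structure (two passes).
* The H-bond distance criterion applies to the hydrogen...acceptor distance
  as written (< 3.5 A); ``distance_mode="donor-acceptor"`` switches to the
  conventional D...A reading.  The angle window 150-210 degrees is applied as
  ``|angle - 180| <= 30`` since three-point angles fold at 180.
* SASA is a Shrake-Rupley estimate on a deterministic golden-spiral point set.
* Free-energy landscape: ``dG = -kB*T*(ln P - ln Pmax)`` with kB in
  kcal/mol/K and empty bins masked as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "FESGrid",
    "BONDI_RADII",
    "KB_KCAL",
    "superpose",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
    "hbond_count",
    "sasa",
    "pca_coords",
    "fel_grid",
    "read_xyz",
    "write_xyz",
    "read_pdb_models",
    "write_pdb_models",
]

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/(mol*K)

# Bondi (1964) van der Waals radii, angstroms
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904,
}


@dataclass
class Trajectory:
    """frames x atoms x 3 coordinates with per-atom masses and metadata."""

    coords: np.ndarray
    masses: np.ndarray | None = None
    elements: list[str] | None = None
    times_ns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.masses is None:
            if self.elements is not None:
                self.masses = np.array([_MASSES.get(e, 12.0) for e in self.elements])
            else:
                self.masses = np.ones(self.coords.shape[1])
        self.masses = np.asarray(self.masses, dtype=float)
        if len(self.masses) != self.coords.shape[1]:
            raise ValueError("masses length must equal atom count")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# Superposition (weighted Kabsch)


def superpose(mobile, reference, weights=None):
    """Optimal weighted rigid fit of ``mobile`` onto ``reference``.

    Returns ``(rotation (3x3, det=+1), translation (3,), fitted coords)`` with
    ``fitted = mobile @ R.T + t``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms to superpose")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    A = mobile - mc
    B = reference - rc
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("degenerate (collinear) atom configuration")
    H = (w[:, None] * A).T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    fitted = mobile @ R.T + t
    return R, t, fitted


# ---------------------------------------------------------------------------
# Per-frame metrics


def _weighted_rmsd(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    d2 = np.sum((a - b) ** 2, axis=1)
    return math.sqrt(float(np.sum(w * d2) / np.sum(w)))


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    mass_weighted: bool = True,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD to the reference, optionally after a weighted fit."""
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.n_atoms, 3):
        raise ValueError("reference atom count must match the trajectory")
    w = traj.masses if mass_weighted else np.ones(traj.n_atoms)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        if fit:
            _, _, frame = superpose(frame, reference, weights=w)
        out[f] = _weighted_rmsd(frame, reference, w)
    return out


def _aligned_coords(traj: Trajectory, align_first: bool, passes: int = 2) -> np.ndarray:
    coords = traj.coords
    if not align_first:
        return coords
    # iterative mean-structure alignment
    mean = coords.mean(axis=0)
    for _ in range(passes):
        aligned = np.empty_like(coords)
        for f in range(coords.shape[0]):
            _, _, aligned[f] = superpose(coords[f], mean, weights=traj.masses)
        mean = aligned.mean(axis=0)
        coords = aligned
    return coords


def rmsf(traj: Trajectory, align_first: bool = True) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-averaged position."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    coords = _aligned_coords(traj, align_first)
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


def radius_of_gyration(traj: Trajectory) -> np.ndarray:
    """Per-frame mass-weighted radius of gyration."""
    m = traj.masses
    com = (traj.coords * m[None, :, None]).sum(axis=1) / m.sum()
    d2 = np.sum((traj.coords - com[:, None, :]) ** 2, axis=2)
    return np.sqrt((d2 * m[None, :]).sum(axis=1) / m.sum())


# ---------------------------------------------------------------------------
# Hydrogen bonds


def hbond_count(
    traj: Trajectory,
    donors,
    hydrogens,
    acceptors,
    dist_cutoff: float = 3.5,
    angle_tol_deg: float = 30.0,
    distance_mode: str = "hydrogen-acceptor",
):
    """Count hydrogen bonds per frame and report per-triple occupancy.

    ``donors`` and ``hydrogens`` are parallel index lists defining covalent
    D-H pairs; ``acceptors`` is an index list.  A bond is counted when the
    chosen distance is below ``dist_cutoff`` and the D-H...A angle is within
    ``angle_tol_deg`` of 180 degrees.
    """
    donors = list(donors)
    hydrogens = list(hydrogens)
    acceptors = list(acceptors)
    if len(donors) != len(hydrogens):
        raise ValueError("every hydrogen needs a donor assignment (parallel lists)")
    if distance_mode not in ("hydrogen-acceptor", "donor-acceptor"):
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    counts = np.zeros(traj.n_frames, dtype=int)
    bonded_frames: dict[tuple[int, int, int], int] = {}
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        for d, h in zip(donors, hydrogens):
            for a in acceptors:
                if a == d or a == h:
                    continue
                dist_vec = xyz[a] - (xyz[h] if distance_mode == "hydrogen-acceptor" else xyz[d])
                if np.linalg.norm(dist_vec) >= dist_cutoff:
                    continue
                v1 = xyz[d] - xyz[h]
                v2 = xyz[a] - xyz[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                if abs(angle - 180.0) <= angle_tol_deg:
                    counts[f] += 1
                    bonded_frames[(d, h, a)] = bonded_frames.get((d, h, a), 0) + 1
    occupancy = {
        triple: nf / traj.n_frames for triple, nf in sorted(bonded_frames.items())
    }
    return counts, occupancy


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    frame: np.ndarray,
    radii,
    probe: float = 1.4,
    n_sphere_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area (total, per-atom) in A^2."""
    frame = np.asarray(frame, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 3:
        raise ValueError("frame must be (atoms, 3)")
    if len(radii) != frame.shape[0]:
        raise ValueError("need one radius per atom")
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("radii must be positive and finite")
    sphere = _sphere_points(n_sphere_points)
    expanded = radii + probe
    n_atoms = frame.shape[0]
    per_atom = np.zeros(n_atoms)
    for i in range(n_atoms):
        pts = frame[i] + expanded[i] * sphere
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in range(n_atoms):
            if j == i:
                continue
            # skip atoms too far away to occlude
            if np.linalg.norm(frame[j] - frame[i]) > expanded[i] + expanded[j]:
                continue
            d2 = np.sum((pts - frame[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        per_atom[i] = (
            4.0 * math.pi * expanded[i] ** 2 * accessible.sum() / n_sphere_points
        )
    return float(per_atom.sum()), per_atom


# ---------------------------------------------------------------------------
# Coordinate PCA


def pca_coords(traj: Trajectory, align_first: bool = True, n_components: int | None = None):
    """PCA of aligned, mean-centered coordinates.

    Returns ``(eigenvalues desc, eigenvectors (3*atoms, n_components),
    projections (frames, n_components))``.  Eigenvalues use the ddof=1
    covariance normalization, so their sum equals the total coordinate
    variance.
    """
    if traj.n_frames < 3:
        raise ValueError("PCA needs at least 3 frames")
    coords = _aligned_coords(traj, align_first)
    flat = coords.reshape(traj.n_frames, -1)
    centered = flat - flat.mean(axis=0)
    max_comp = min(centered.shape)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(f"cannot extract {n_components} components from {max_comp}")
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = S**2 / (traj.n_frames - 1)
    projections = U * S
    return (
        eigvals[:n_components],
        Vt[:n_components].T,
        projections[:, :n_components],
    )


# ---------------------------------------------------------------------------
# Free-energy landscape


@dataclass
class FESGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    prob: np.ndarray       # (nx, ny), sums to 1
    delta_g: np.ndarray    # (nx, ny), NaN on empty bins; occupied min is 0
    temperature_K: float
    kT: float = field(init=False)

    def __post_init__(self) -> None:
        self.kT = KB_KCAL * self.temperature_K


def fel_grid(x, y, temperature_K: float = 310.0, bins: int = 50) -> FESGrid:
    """2-D free-energy landscape ``dG = -kB*T*(ln P - ln Pmax)`` in kcal/mol."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("order-parameter series must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("order parameter is constant; landscape undefined")
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=bins)
    prob = counts / counts.sum()
    pmax = prob.max()
    log_p = np.full_like(prob, np.nan)
    np.log(prob, out=log_p, where=prob > 0)
    delta_g = -KB_KCAL * temperature_K * (log_p - math.log(pmax))
    return FESGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        prob=prob,
        delta_g=delta_g,
        temperature_K=temperature_K,
    )


# ---------------------------------------------------------------------------
# Plain-text trajectory I/O


def write_xyz(traj: Trajectory, path) -> None:
    """Multi-frame XYZ; elements default to carbon when unknown."""
    elements = traj.elements or ["C"] * traj.n_atoms
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\nframe {f}\n")
            for e, (xx, yy, zz) in zip(elements, traj.coords[f]):
                fh.write(f"{e} {xx:.10f} {yy:.10f} {zz:.10f}\n")


def read_xyz(path, masses=None) -> Trajectory:
    frames = []
    elements: list[str] | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError("truncated XYZ frame")
        frame_elems, xyz = [], []
        for line in block:
            parts = line.split()
            frame_elems.append(parts[0])
            xyz.append([float(p) for p in parts[1:4]])
        if elements is None:
            elements = frame_elems
        frames.append(xyz)
        i += 2 + n
    if not frames:
        raise ValueError("no frames found in XYZ file")
    return Trajectory(coords=np.array(frames), masses=masses, elements=elements)


def write_pdb_models(traj: Trajectory, path) -> None:
    """Minimal multi-model PDB writer (ATOM records only)."""
    elements = traj.elements or ["C"] * traj.n_atoms
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:>4}\n")
            for i, (e, (xx, yy, zz)) in enumerate(zip(elements, traj.coords[f])):
                fh.write(
                    f"ATOM  {i + 1:>5} {e:<4}MOL A   1    "
                    f"{xx:8.3f}{yy:8.3f}{zz:8.3f}  1.00  0.00          {e:>2}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb_models(path, masses=None) -> Trajectory:
    frames: list[list[list[float]]] = []
    current: list[list[float]] = []
    elements: list[str] = []
    first_model = True
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                current.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
                if first_model:
                    elem = line[76:78].strip() or line[12:16].strip()[:1]
                    elements.append(elem)
            elif rec == "ENDMDL":
                frames.append(current)
                current = []
                first_model = False
    if current:
        frames.append(current)
    if not frames or not frames[0]:
        raise ValueError("no coordinates found in PDB file")
    return Trajectory(coords=np.array(frames), masses=masses, elements=elements)
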