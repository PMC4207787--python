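"""Grid-probe cavity detection and druggability descriptors.

A transparent stand-in for grid/Difference-of-Gaussians pocket scanners:
the structure is embedded in a cubic grid, cells inside the van der Waals
volume are protein, remaining cells are probed for burial along 26 scan
directions, and face-connected buried components become pockets.  Each
pocket gets geometric descriptors (volume, exposed surface, lipophilic
surface fraction, depth below bulk solvent) and a logistic druggability
score in [0, 1].  The score is a fixed, documented formula — deliberately
not a trained model — so the triage role (keep pockets scoring above a
floor, near a target residue) is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structio import Structure

__all__ = [
    "VDW_RADII",
    "DruggabilityWeights",
    "PocketGrid",
    "Pocket",
    "detect_pockets",
    "pocket_descriptors",
    "druggability_score",
    "pockets_near_residue",
    "analyze_pockets",
]

# Bondi-style van der Waals radii (Angstrom), by element symbol.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW = 1.70

PROBE_RADIUS = 1.4  # water-probe radius, Angstrom
APOLAR_BOND_CUTOFF = 1.9  # C/S bonded to N/O within this distance -> polar
LINING_CUTOFF = 4.0  # residue within this distance of a cavity cell lines it

# the 26 grid scan directions: all nonzero offsets in {-1,0,1}^3
SCAN_DIRECTIONS = [
    (i, j, k)
    for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]

_FACE_NEIGHBORS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                   (0, -1, 0), (0, 0, 1), (0, 0, -1)]


@dataclass(frozen=True)
class DruggabilityWeights:
    """Logistic weights for the druggability score.

    score = logistic(w0 + w_volume * min(V, 1500)/1500
                        + w_lipo * lipo_surface/surface
                        + w_depth * min(depth, 10)/10)

    All slope weights are positive so the score is monotone increasing in
    each normalized descriptor.
    """

    w0: float = -4.5
    w_volume: float = 3.0
    w_lipo: float = 2.0
    w_depth: float = 3.0


@dataclass
class PocketGrid:
    """The detection grid shared by all pockets of one structure."""

    origin: np.ndarray
    spacing: float
    protein: np.ndarray  # bool, cells inside vdW volume
    solvent: np.ndarray  # bool, bulk-exposed cells
    depth: np.ndarray    # Angstrom distance of each cell to bulk solvent

    def cell_centers(self, cells: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(cells, dtype=float) + 0.5) * self.spacing


@dataclass
class Pocket:
    """One face-connected cavity with its descriptors."""

    cells: np.ndarray  # (n_cells, 3) integer grid indices
    grid: PocketGrid
    volume: float  # A^3 = n_cells * spacing^3
    surface: float = float("nan")  # A^2, exposed cavity faces
    lipo_surface: float = float("nan")  # A^2, faces lined by apolar atoms
    depth: float = float("nan")  # A, max cell distance to bulk solvent
    druggability: float = float("nan")
    lining_residues: list[tuple[str, int]] = field(default_factory=list)
    distance_to_target: float = float("nan")

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]


def _vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def _shift(mask: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """mask shifted so out[c] = mask[c + d] (False beyond the boundary)."""
    out = np.zeros_like(mask)
    src = []
    dst = []
    for axis, step in enumerate(d):
        n = mask.shape[axis]
        if step == 1:
            src.append(slice(1, n))
            dst.append(slice(0, n - 1))
        elif step == -1:
            src.append(slice(0, n - 1))
            dst.append(slice(1, n))
        else:
            src.append(slice(None))
            dst.append(slice(None))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _burial_counts(protein: np.ndarray) -> np.ndarray:
    """For each cell, in how many of the 26 scan directions a protein cell
    lies somewhere strictly beyond it."""
    counts = np.zeros(protein.shape, dtype=np.int8)
    n_steps = max(protein.shape)
    for d in SCAN_DIRECTIONS:
        covered = np.zeros_like(protein)
        for _ in range(n_steps):
            new = _shift(covered | protein, d)
            if np.array_equal(new, covered):
                break
            covered = new
        counts += covered
    return counts


def _apolar_atom_flags(s: Structure) -> np.ndarray:
    """C/S atoms with no N/O neighbour within bonding distance are apolar."""
    elements = np.char.upper(s.elements.astype(str))
    carbonish = np.isin(elements, ("C", "S"))
    polar_partner = np.isin(elements, ("N", "O"))
    flags = carbonish.copy()
    if polar_partner.any() and carbonish.any():
        tree = cKDTree(s.coords[polar_partner])
        d, _ = tree.query(s.coords[carbonish], k=1)
        flags[np.flatnonzero(carbonish)[d <= APOLAR_BOND_CUTOFF]] = False
    return flags


def detect_pockets(
    s: Structure,
    spacing: float = 1.0,
    burial_threshold: int = 16,
    probe_radius: float = PROBE_RADIUS,
    min_volume: float = 30.0,
    max_probe_reach: float = 8.0,
) -> list[Pocket]:
    """Detect candidate cavities on a structure.

    Cavity cells are outside the protein van der Waals volume, within
    *max_probe_reach* of the molecular surface, and see protein in at least
    *burial_threshold* of the 26 scan directions.  Face-connected components
    smaller than *min_volume* (A^3) are discarded; the rest are returned
    sorted by volume, largest first.
    """
    if len(s) == 0:
        raise ValueError("empty structure")
    if not 0.5 <= spacing <= 1.5:
        raise ValueError("spacing must be in [0.5, 1.5] Angstrom")
    coords = s.coords
    radii = np.array([_vdw_radius(e) for e in s.elements])
    margin = radii.max() + 2 * probe_radius + 2 * spacing
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    dims = np.ceil((hi - lo) / spacing).astype(int)
    protein = np.zeros(tuple(dims), dtype=bool)
    # stamp each atom's vdW sphere into the grid via a local sub-box
    for xyz, r in zip(coords, radii):
        ilo = np.floor((xyz - r - lo) / spacing).astype(int)
        ihi = np.ceil((xyz + r - lo) / spacing).astype(int)
        ilo = np.clip(ilo, 0, dims - 1)
        ihi = np.clip(ihi, 0, dims - 1)
        ranges = [np.arange(a, b + 1) for a, b in zip(ilo, ihi)]
        gx, gy, gz = np.meshgrid(*ranges, indexing="ij")
        centers = lo + (np.stack([gx, gy, gz], axis=-1) + 0.5) * spacing
        inside = np.sum((centers - xyz) ** 2, axis=-1) <= r * r
        protein[gx[inside], gy[inside], gz[inside]] = True

    burial = _burial_counts(protein)
    buried = (~protein) & (burial >= burial_threshold)
    solvent = (~protein) & ~buried
    # probe reach: candidate cell centers must be near the molecular surface
    cand = np.argwhere(buried)
    if cand.size:
        tree = cKDTree(coords)
        centers = lo + (cand + 0.5) * spacing
        d, idx = tree.query(centers, k=1)
        reach = d - radii[idx]
        far = reach > max_probe_reach
        buried[tuple(cand[far].T)] = False

    depth_cells = ndimage.distance_transform_edt(~solvent)
    grid = PocketGrid(origin=lo, spacing=spacing, protein=protein,
                      solvent=solvent, depth=depth_cells * spacing)

    labeled, n_comp = ndimage.label(
        buried, structure=ndimage.generate_binary_structure(3, 1))
    pockets = []
    for comp in range(1, n_comp + 1):
        cells = np.argwhere(labeled == comp)
        volume = cells.shape[0] * spacing**3
        if volume < min_volume:
            continue
        pockets.append(Pocket(cells=cells, grid=grid, volume=volume))
    pockets.sort(key=lambda p: -p.volume)
    return pockets


def pocket_descriptors(p: Pocket, s: Structure) -> Pocket:
    """Fill in surface, lipophilic surface, depth and lining residues.

    Surface counts exposed cavity-cell faces; a face is lipophilic when its
    nearest protein atom is an apolar carbon or sulfur.  Lining residues
    have any atom within 4 A of a cavity cell center.  Returns *p* updated
    in place (and also for chaining).
    """
    grid = p.grid
    spacing = grid.spacing
    mask = np.zeros(grid.protein.shape, dtype=bool)
    mask[tuple(p.cells.T)] = True
    apolar = _apolar_atom_flags(s)
    tree = cKDTree(s.coords)

    n_faces = 0
    n_lipo = 0
    face_centers = []
    for d in _FACE_NEIGHBORS:
        exposed = mask & ~_shift(mask, d)
        cells = np.argwhere(exposed)
        if cells.size == 0:
            continue
        n_faces += cells.shape[0]
        fc = grid.origin + (cells + 0.5) * spacing + 0.5 * spacing * np.array(d)
        face_centers.append(fc)
    if face_centers:
        fc = np.concatenate(face_centers)
        _, nearest = tree.query(fc, k=1)
        n_lipo = int(np.sum(apolar[nearest]))
    p.surface = n_faces * spacing**2
    p.lipo_surface = n_lipo * spacing**2
    p.depth = float(grid.depth[tuple(p.cells.T)].max())

    centers = grid.cell_centers(p.cells)
    near = tree.query_ball_point(centers, LINING_CUTOFF)
    atom_ids = sorted({a for lst in near for a in lst})
    seen: dict[tuple[str, int], None] = {}
    for a in atom_ids:
        seen.setdefault((str(s.chain_ids[a]), int(s.res_seqs[a])))
    p.lining_residues = list(seen)
    return p


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def druggability_score(
    p: Pocket, weights: DruggabilityWeights = DruggabilityWeights()
) -> float:
    """Logistic druggability score in (0, 1) from normalized descriptors.

    Monotone increasing in capped volume, lipophilic surface fraction and
    capped depth.  This is a transparent fixed formula, not a trained
    classifier: absolute values are not comparable to SVM-based scorers,
    only the [0, 1] range and the triage role are shared.
    """
    if not np.isfinite(p.surface):
        raise ValueError("descriptors not computed; call pocket_descriptors")
    if p.surface <= 0:
        raise ValueError("pocket has zero surface")
    x = (weights.w0
         + weights.w_volume * min(p.volume, 1500.0) / 1500.0
         + weights.w_lipo * (p.lipo_surface / p.surface)
         + weights.w_depth * min(p.depth, 10.0) / 10.0)
    score = float(_logistic(x))
    p.druggability = score
    return score


def pockets_near_residue(
    pockets: list[Pocket],
    s: Structure,
    chain: str,
    res_seq: int,
    max_dist: float,
    min_score: float | None = None,
) -> list[Pocket]:
    """Pockets whose closest cavity cell lies within *max_dist* Angstrom of
    any atom of the given residue (e.g. the mutation site), optionally also
    above a druggability floor.  Each kept pocket is annotated with its
    distance to the residue."""
    res_mask = (s.chain_ids.astype(str) == chain) & (s.res_seqs == res_seq)
    if not res_mask.any():
        raise KeyError(f"residue {chain}:{res_seq} not found")
    res_tree = cKDTree(s.coords[res_mask])
    kept = []
    for p in pockets:
        centers = p.grid.cell_centers(p.cells)
        d, _ = res_tree.query(centers, k=1)
        dist = float(d.min())
        if dist <= max_dist:
            p.distance_to_target = dist
            if min_score is None or (np.isfinite(p.druggability)
                                     and p.druggability >= min_score):
                kept.append(p)
    return kept


def analyze_pockets(
    s: Structure,
    spacing: float = 1.0,
    burial_threshold: int = 16,
    weights: DruggabilityWeights = DruggabilityWeights(),
    **kwargs,
) -> list[Pocket]:
    """Detect pockets and compute all descriptors and scores in one call."""
    pockets = detect_pockets(s, spacing=spacing,
                             burial_threshold=burial_threshold, **kwargs)
    for p in pockets:
        pocket_descriptors(p, s)
        druggability_score(p, weights)
    return pockets
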