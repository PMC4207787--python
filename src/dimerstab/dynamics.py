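"""Superposition, RMSD/RMSF and B-factor conversion for ensemble validation.

Before pockets are hunted on trajectory snapshots the ensemble is sanity
checked the classical way: backbone RMSD against the iterative mean
structure, per-residue C-alpha RMSF, and comparison of the derived pseudo
B-factors (B = 8*pi^2/3 * RMSF^2) with crystallographic ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import AtomSelection, Ensemble, Structure

__all__ = [
    "SuperpositionResult",
    "FluctuationProfile",
    "DegenerateGeometryError",
    "kabsch_superpose",
    "apply_superposition",
    "rmsd",
    "average_structure",
    "rmsf",
    "rmsf_to_bfactor",
]

B_FACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0


class DegenerateGeometryError(ValueError):
    """Fewer than 3 atoms, or a collinear point set: no unique rotation."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation/translation and the residual RMSD (Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclass(frozen=True)
class FluctuationProfile:
    """Per-atom RMSF (Angstrom) over the selected atoms, with metadata."""

    indices: np.ndarray
    rmsf: np.ndarray

    @property
    def pseudo_bfactor(self) -> np.ndarray:
        return rmsf_to_bfactor(self.rmsf)


def _coords(x, sel: AtomSelection | None) -> np.ndarray:
    arr = x.coords if isinstance(x, Structure) else np.asarray(x, dtype=float)
    if sel is not None:
        arr = arr[sel.indices]
    return arr


def kabsch_superpose(
    mobile, reference, sel: AtomSelection | None = None
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition (Kabsch, via SVD).

    Returns the proper rotation (det = +1) and translation mapping *mobile*
    onto *reference*, with the post-fit RMSD over the selected atoms.
    """
    a = _coords(mobile, sel)
    b = _coords(reference, sel)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 atoms to superpose")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinearity: second singular value of the centered set vanishes
    if np.linalg.svd(a0, compute_uv=False)[1] < 1e-9:
        raise DegenerateGeometryError("selected atoms are collinear")
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cb - rot @ ca
    fitted = a @ rot.T + trans
    val = float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=val)


def apply_superposition(coords: np.ndarray, sup: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ sup.rotation.T + sup.translation


def rmsd(a, b, sel: AtomSelection | None = None, superpose: bool = False) -> float:
    """Root-mean-square deviation (Angstrom) over *sel*, optionally after an
    optimal superposition over the same selection."""
    xa = _coords(a, sel)
    xb = _coords(b, sel)
    if xa.shape != xb.shape:
        raise ValueError(f"coordinate shape mismatch {xa.shape} vs {xb.shape}")
    if superpose:
        return kabsch_superpose(xa, xb).rmsd
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def average_structure(
    e: Ensemble,
    sel: AtomSelection | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> Structure:
    """Iterative mean structure: superpose every frame onto the running mean
    (seeded by the first frame) until the mean moves less than *tol* Angstrom.

    The superposition fit uses *sel* (default: all atoms); the mean is taken
    over all atoms.  The result carries label ``"ave"``.
    """
    if e.n_frames < 2:
        raise ValueError("need at least 2 frames to average")
    frames = e.coords.copy()
    ref = frames[0]
    for _ in range(max_iter):
        fitted = np.empty_like(frames)
        for i in range(frames.shape[0]):
            sup = kabsch_superpose(frames[i][sel.indices] if sel else frames[i],
                                   ref[sel.indices] if sel else ref)
            fitted[i] = apply_superposition(frames[i], sup)
        mean = fitted.mean(axis=0)
        shift = float(np.max(np.linalg.norm(mean - ref, axis=1)))
        ref = mean
        frames = fitted
        if shift <= tol:
            break
    return e.topology.with_coords(ref, label="ave")


def rmsf(e: Ensemble, sel: AtomSelection | None = None) -> FluctuationProfile:
    """Per-atom root-mean-square fluctuation about the time-mean position,
    after superposing each frame onto the iterative average structure."""
    if e.n_frames < 2:
        raise ValueError("RMSF is undefined for a single frame")
    avg = average_structure(e, sel=sel)
    ref = avg.coords[sel.indices] if sel else avg.coords
    n = e.n_frames
    sel_idx = sel.indices if sel else np.arange(len(e.topology))
    fitted = np.empty((n, sel_idx.size, 3))
    for i in range(n):
        sup = kabsch_superpose(e.coords[i][sel_idx], ref)
        fitted[i] = apply_superposition(e.coords[i][sel_idx], sup)
    mean_pos = fitted.mean(axis=0)
    dev2 = np.sum((fitted - mean_pos) ** 2, axis=2)
    return FluctuationProfile(indices=sel_idx, rmsf=np.sqrt(dev2.mean(axis=0)))


def rmsf_to_bfactor(value) -> np.ndarray | float:
    """Convert RMSF (Angstrom) to an isotropic B-factor: B = (8*pi^2/3)*RMSF^2."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("RMSF must be nonnegative")
    out = B_FACTOR_PREFACTOR * arr**2
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out
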