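"""Rigid and relaxed binding free-energy protocols over energy trajectories.

Two bookkeeping schemes estimate the stabilisation a bound ligand confers
on the dimer, both averaging the last 20 snapshots (1 ps apart) of a
production run:

* rigid (single-trajectory): ddG = <E(complex) - E(dimer) - E(ligand)>
  where the dimer and ligand energies are evaluated on geometries
  extracted from the very same complex snapshots;
* relaxed (separate-trajectory): ddG = <E(complex)> - <E_r(dimer)> -
  <E_r(ligand)> with the dimer and ligand sampled in their own independent
  runs, so relaxation (and implicitly entropy) of the free species is
  included.

Candidates are kept when either estimate is better (more negative) than a
threshold, -20 kcal/mol by default.  A fully specified toy pair potential
(Lennard-Jones plus distance-dependent-dielectric Coulomb) makes the whole
protocol exercisable without a molecular-mechanics engine; it claims no
force-field equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EnergyTrajectory",
    "BindingEnergyResult",
    "COULOMB_CONSTANT",
    "toy_energy",
    "ddg_rigid",
    "ddg_relaxed",
    "select_candidates",
    "read_energy_tables",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 20  # snapshots averaged, anchored at the trajectory end
COULOMB_CONSTANT = 332.06  # kcal*A/(mol*e^2)

ROLES = ("complex", "receptor", "ligand")
SOURCES = ("extracted", "independent")


@dataclass
class EnergyTrajectory:
    """Per-snapshot potential energies (kcal/mol) for one species."""

    role: str
    source: str
    energies: np.ndarray
    timestep_ps: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1:
            raise ValueError("energies must be a 1-D array")
        if not np.all(np.isfinite(e)):
            raise ValueError("energies must be finite")
        self.energies = e

    def __len__(self) -> int:
        return self.energies.size


@dataclass(frozen=True)
class BindingEnergyResult:
    compound_id: str
    ddg_rigid: float
    ddg_relaxed: float
    n_snapshots_averaged: int = DEFAULT_WINDOW

    @property
    def best(self) -> float:
        return min(self.ddg_rigid, self.ddg_relaxed)


def toy_energy(
    coords: np.ndarray,
    epsilon: np.ndarray,
    sigma: np.ndarray,
    charge: np.ndarray,
) -> float:
    """Pairwise toy potential (kcal/mol), no cutoff:

    E = sum_pairs 4*eps_ij*((sig_ij/r)^12 - (sig_ij/r)^6)
        + 332.06 * q_i*q_j / (4 * r^2)

    with Lorentz-Berthelot combining (geometric epsilon, arithmetic sigma)
    and the distance-dependent dielectric eps(r) = 4r.
    """
    x = np.asarray(coords, dtype=float)
    eps = np.asarray(epsilon, dtype=float)
    sig = np.asarray(sigma, dtype=float)
    q = np.asarray(charge, dtype=float)
    n = x.shape[0]
    if not (eps.size == sig.size == q.size == n):
        raise ValueError("parameter arrays must match the atom count")
    iu, ju = np.triu_indices(n, k=1)
    r = np.linalg.norm(x[iu] - x[ju], axis=1)
    if np.any(r == 0):
        raise ValueError("coincident atoms: pair distance of zero")
    eps_ij = np.sqrt(eps[iu] * eps[ju])
    sig_ij = 0.5 * (sig[iu] + sig[ju])
    sr6 = (sig_ij / r) ** 6
    lj = 4.0 * eps_ij * (sr6**2 - sr6)
    coul = COULOMB_CONSTANT * q[iu] * q[ju] / (4.0 * r**2)
    return float(np.sum(lj + coul))


def _check_window(t: EnergyTrajectory, window: int) -> None:
    if len(t) < window:
        raise ValueError(
            f"{t.role} trajectory has {len(t)} snapshots, need >= {window}")


def ddg_rigid(
    complex_t: EnergyTrajectory,
    receptor_t: EnergyTrajectory,
    ligand_t: EnergyTrajectory,
    window: int = DEFAULT_WINDOW,
) -> float:
    """Single-trajectory binding energy: mean over the last *window*
    snapshots of E(complex) - E(receptor) - E(ligand), with the receptor
    and ligand geometries extracted from the same complex snapshots."""
    for t, role in ((complex_t, "complex"), (receptor_t, "receptor"),
                    (ligand_t, "ligand")):
        if t.role != role:
            raise ValueError(f"expected a {role} trajectory, got {t.role}")
    if receptor_t.source != "extracted" or ligand_t.source != "extracted":
        raise ValueError(
            "rigid protocol needs receptor/ligand energies extracted from "
            "the complex snapshots")
    if not (len(complex_t) == len(receptor_t) == len(ligand_t)):
        raise ValueError("extracted trajectories must be snapshot-aligned")
    _check_window(complex_t, window)
    diff = (complex_t.energies - receptor_t.energies - ligand_t.energies)
    return float(np.mean(diff[-window:]))


def ddg_relaxed(
    complex_t: EnergyTrajectory,
    receptor_indep_t: EnergyTrajectory,
    ligand_indep_t: EnergyTrajectory,
    window: int = DEFAULT_WINDOW,
) -> float:
    """Separate-trajectory binding energy: mean(last window of E(complex))
    minus the corresponding means of independent receptor-only and
    ligand-only runs."""
    for t, role in ((complex_t, "complex"), (receptor_indep_t, "receptor"),
                    (ligand_indep_t, "ligand")):
        if t.role != role:
            raise ValueError(f"expected a {role} trajectory, got {t.role}")
    if (receptor_indep_t.source != "independent"
            or ligand_indep_t.source != "independent"):
        raise ValueError(
            "relaxed protocol needs independent receptor/ligand runs")
    for t in (complex_t, receptor_indep_t, ligand_indep_t):
        _check_window(t, window)
    return float(np.mean(complex_t.energies[-window:])
                 - np.mean(receptor_indep_t.energies[-window:])
                 - np.mean(ligand_indep_t.energies[-window:]))


def select_candidates(
    results: list[BindingEnergyResult],
    threshold: float = -20.0,
    max_candidates: int | None = None,
) -> list[BindingEnergyResult]:
    """Keep compounds whose rigid OR relaxed estimate is better (more
    negative) than *threshold*, sorted best-first (ties by id), optionally
    truncated to *max_candidates*."""
    if not results:
        raise ValueError("no binding-energy results to select from")
    kept = [r for r in results if r.best <= threshold]
    kept.sort(key=lambda r: (r.best, r.compound_id))
    if max_candidates is not None:
        kept = kept[:max_candidates]
    return kept


def read_energy_tables(path: str | Path) -> dict[str, dict[tuple[str, str], EnergyTrajectory]]:
    """Read a CSV (compound_id, role, source, snapshot_ps, energy_kcal_mol)
    into per-compound {(role, source): EnergyTrajectory} maps."""
    df = pd.read_csv(path)
    required = {"compound_id", "role", "source", "snapshot_ps",
                "energy_kcal_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"energy CSV missing columns {sorted(missing)}")
    out: dict[str, dict[tuple[str, str], EnergyTrajectory]] = {}
    for (cid, role, source), grp in df.groupby(
            ["compound_id", "role", "source"], sort=True):
        grp = grp.sort_values("snapshot_ps")
        ts = grp["snapshot_ps"].to_numpy()
        dt = float(ts[1] - ts[0]) if ts.size > 1 else 1.0
        out.setdefault(str(cid), {})[(str(role), str(source))] = \
            EnergyTrajectory(role=str(role), source=str(source),
                             energies=grp["energy_kcal_mol"].to_numpy(),
                             timestep_ps=dt)
    return out
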