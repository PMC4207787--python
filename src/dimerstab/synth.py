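"""Synthetic inputs with planted ground truth for every pipeline stage.

Nothing here pretends to be physics or chemistry: the toy dimer is a pair
of idealised backbone helices with an interface groove, the conformational
states are a fixed non-rigid displacement field on the binding-site atoms,
the library descriptors are drawn around the drug-likeness filter windows,
the docking scores share a latent affinity between two engines, and the
energy streams encode an exact planted binding energy plus Gaussian
snapshot noise.  What the generator guarantees instead is (a) full
determinism from one integer seed and (b) known ground truth (state
labels, pass flags, binder ids, true ddG) emitted alongside every
artifact, never consumed by the pipeline under test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import ScoreTable
from .energy import EnergyTrajectory
from .structio import AtomSelection, Ensemble, Structure, write_pdb

__all__ = [
    "SynthSpec",
    "make_toy_dimer",
    "binding_site_selection",
    "make_ensemble",
    "make_library",
    "make_score_tables",
    "make_energy_traj",
    "write_all",
]

# fixed substream keys so each artifact kind has its own reproducible stream
_KEY_DIMER, _KEY_ENSEMBLE, _KEY_LIBRARY, _KEY_SCORES, _KEY_ENERGY = range(1, 6)


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


@dataclass
class SynthSpec:
    """All knobs of the synthetic study conditions.

    Defaults emulate the desk-scale analogue of the real campaign: a
    1500-snapshot ensemble at 1 ps spacing with 8 planted binding-site
    states, a library of 5000 compounds with 10 planted binders, engine
    score conventions in the printed ranges, planted binding energies of
    -25 (binders) / -5 (non-binders) kcal/mol with 2 kcal/mol snapshot
    noise.  State separation (3 A) is ~8x the intra-state thermal spread
    (sigma 0.15 A per coordinate, i.e. ~0.37 A frame-to-frame RMSD) so
    recovery is neither trivial nor flaky.
    """

    seed: int = 1
    # toy dimer / ensemble
    n_residues: int = 60
    k_states: int = 8
    state_amplitude: float = 3.0  # A, min inter-state binding-site RMSD
    thermal_sigma: float = 0.15  # A, i.i.d. per-coordinate noise
    n_snapshots: int = 1500
    timestep_ps: float = 1.0
    interface_cutoff: float = 6.0  # A, defines binding-site residues
    # compound library
    library_size: int = 5000
    violation_fraction: float = 0.25
    # docking scores
    n_binders: int = 10
    binder_latent: float = 6.0
    score_noise: float = 0.5
    conformations: tuple[str, ...] = ("mini", "ave", "706ps")
    # binding energies
    ddg_true_binder: float = -25.0
    ddg_true_nonbinder: float = -5.0
    ddg_noise: float = 2.0
    n_energy_snapshots: int = 60
    relax_receptor: float = 1.5  # kcal/mol lowering in the independent run
    relax_ligand: float = 0.5

    def __post_init__(self) -> None:
        if self.k_states < 1:
            raise ValueError("k_states must be >= 1")
        if self.state_amplitude <= 0 or self.thermal_sigma < 0:
            raise ValueError("amplitudes must be positive")
        if self.n_binders > self.library_size:
            raise ValueError("n_binders cannot exceed library_size")


# -- toy dimer ---------------------------------------------------------------

_HELIX_RISE = 1.5  # A per residue
_HELIX_TURN = np.deg2rad(100.0)
_CHAIN_SEP = 9.0  # A between the two helix axes

# (name, element, radius, phase offset rad, z offset) per backbone atom
_BACKBONE_GEOM = (
    ("N", "N", 1.6, -0.45, -0.8),
    ("CA", "C", 2.3, 0.0, 0.0),
    ("C", "C", 2.0, 0.35, 0.7),
    ("O", "O", 2.2, 0.60, 1.2),
)


def make_toy_dimer(spec: SynthSpec) -> Structure:
    """Two-chain helical backbone dimer with a groove at the interface.

    Chains C and D run parallel, 9 A axis-to-axis, with a 180-degree phase
    offset so the closest backbone atoms face each other across a ~4.5 A
    gap.  Deterministic per seed (the seed only perturbs nothing here; the
    geometry is analytic, so identical specs give identical structures).
    """
    if spec.n_residues < 10:
        raise ValueError("need at least 10 residues per chain")
    serials, names, elements, chains, res_names, res_seqs, coords = \
        [], [], [], [], [], [], []
    serial = 1
    for chain_id, x_off, phase in (("C", 0.0, 0.0), ("D", _CHAIN_SEP, np.pi)):
        for i in range(spec.n_residues):
            theta = i * _HELIX_TURN + phase
            z = i * _HELIX_RISE
            for name, elem, radius, dphase, dz in _BACKBONE_GEOM:
                ang = theta + dphase
                coords.append((x_off + radius * np.cos(ang),
                               radius * np.sin(ang), z + dz))
                serials.append(serial)
                names.append(name)
                elements.append(elem)
                chains.append(chain_id)
                res_names.append("ALA")
                res_seqs.append(i + 1)
                serial += 1
    n = len(serials)
    return Structure(
        serials=np.array(serials), names=np.array(names),
        elements=np.array(elements), chain_ids=np.array(chains),
        res_names=np.array(res_names), res_seqs=np.array(res_seqs),
        coords=np.array(coords, dtype=float),
        b_factors=np.zeros(n), hetero=np.zeros(n, dtype=bool),
        label="toy_dimer",
    )


def binding_site_selection(s: Structure, cutoff: float = 6.0) -> AtomSelection:
    """All atoms of residues having any atom within *cutoff* Angstrom of
    the other chain — the synthetic binding site at the dimer interface."""
    chains = s.chain_ids.astype(str)
    unique = sorted(set(chains))
    if len(unique) != 2:
        raise ValueError("binding site detection expects exactly 2 chains")
    a_mask = chains == unique[0]
    from scipy.spatial import cKDTree
    tree_b = cKDTree(s.coords[~a_mask])
    tree_a = cKDTree(s.coords[a_mask])
    d_a, _ = tree_b.query(s.coords[a_mask], k=1)
    d_b, _ = tree_a.query(s.coords[~a_mask], k=1)
    close = np.zeros(len(s), dtype=bool)
    close[np.flatnonzero(a_mask)[d_a <= cutoff]] = True
    close[np.flatnonzero(~a_mask)[d_b <= cutoff]] = True
    keys = set(zip(chains[close], s.res_seqs[close]))
    mask = np.array([(c, r) in keys for c, r in zip(chains, s.res_seqs)])
    idx = np.flatnonzero(mask)
    return AtomSelection(indices=idx,
                         spec=f"interface residues (cutoff {cutoff} A)")


def _displacement_field(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random per-atom field with the 6 rigid-body modes projected out and
    unit RMS amplitude, so scaling it changes internal geometry that no
    superposition can undo."""
    m = coords.shape[0]
    centered = coords - coords.mean(axis=0)
    u = rng.normal(size=(m, 3))
    # rigid modes: 3 translations + 3 infinitesimal rotations
    modes = []
    for k in range(3):
        t = np.zeros((m, 3))
        t[:, k] = 1.0
        modes.append(t)
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        modes.append(np.cross(np.broadcast_to(axis, (m, 3)), centered))
    flat = u.ravel()
    basis = []
    for mode in modes:
        v = mode.ravel().astype(float)
        for b in basis:
            v = v - (v @ b) * b
        norm = np.linalg.norm(v)
        if norm > 1e-12:
            basis.append(v / norm)
    for b in basis:
        flat = flat - (flat @ b) * b
    u = flat.reshape(m, 3)
    rms = np.sqrt(np.mean(np.sum(u**2, axis=1)))
    return u / rms


def make_ensemble(
    structure: Structure, spec: SynthSpec
) -> tuple[Ensemble, np.ndarray, list[Structure]]:
    """Snapshots = base + per-state binding-site displacement + thermal noise.

    Each of the *k_states* states displaces the binding-site atoms along a
    shared mode-free field with amplitude ``state * state_amplitude``, so
    the binding-site RMSD between any two state references is at least
    *state_amplitude* even after optimal superposition.  State labels are
    balanced and shuffled.  Returns (ensemble, per-frame state labels, the
    k noise-free reference structures).
    """
    rng = _rng(spec.seed, _KEY_ENSEMBLE)
    site = binding_site_selection(structure, spec.interface_cutoff)
    u = _displacement_field(structure.coords[site.indices], rng)
    amplitudes = np.arange(spec.k_states) * spec.state_amplitude
    references = []
    for s_idx, amp in enumerate(amplitudes):
        c = structure.coords.copy()
        c[site.indices] += amp * u
        references.append(structure.with_coords(c, label=f"state{s_idx}"))
    n = spec.n_snapshots
    labels = rng.permutation(np.arange(n) % spec.k_states)
    frames = np.empty((n, len(structure), 3))
    for i in range(n):
        frames[i] = references[labels[i]].coords
    if spec.thermal_sigma > 0:
        frames += rng.normal(scale=spec.thermal_sigma, size=frames.shape)
    ens = Ensemble(topology=structure, coords=frames,
                   timestep_ps=spec.timestep_ps)
    return ens, labels, references


# -- compound library --------------------------------------------------------

# PPI-adapted open intervals, as printed: value must be strictly inside.
_FILTER_WINDOWS = {
    "mw": (100.0, 700.0), "tpsa": (0.0, 160.0), "logp": (-4.0, 6.0),
    "hbd": (0, 5), "hba": (0, 10), "rotb": (0, 15),
}

_SMILES_ATOMS = np.array(list("CCCCCNO"))


def _random_smiles(rng: np.random.Generator) -> str:
    length = int(rng.integers(3, 10))
    chain = "".join(rng.choice(_SMILES_ATOMS, size=length))
    if rng.random() < 0.5:
        chain += "c1ccccc1"
    return chain


def _passes(desc: dict) -> bool:
    return all(lo < desc[k] < hi for k, (lo, hi) in _FILTER_WINDOWS.items())


def make_library(spec: SynthSpec) -> pd.DataFrame:
    """Synthetic compound table with planted filter ground truth.

    Descriptors of passing records are drawn from truncated normals inside
    every open filter window; a *violation_fraction* of records get one
    randomly chosen descriptor pushed outside its window.  Columns: id,
    smiles, the six descriptors, and ``true_pass`` (the planted flag).
    """
    if spec.library_size < 1:
        raise ValueError("library_size must be >= 1")
    rng = _rng(spec.seed, _KEY_LIBRARY)
    n = spec.library_size
    mw = np.clip(rng.normal(400.0, 120.0, n), 100.5, 699.5)
    tpsa = np.clip(rng.normal(80.0, 40.0, n), 0.5, 159.5)
    logp = np.clip(rng.normal(1.5, 2.0, n), -3.9, 5.9)
    hbd = 1 + rng.binomial(3, 0.4, n)
    hba = np.minimum(1 + rng.binomial(8, 0.4, n), 9)
    rotb = np.minimum(1 + rng.binomial(13, 0.35, n), 14)
    table = pd.DataFrame({
        "id": [f"CPD{i:06d}" for i in range(n)],
        "smiles": [_random_smiles(rng) for _ in range(n)],
        "mw": mw, "tpsa": tpsa, "logp": logp,
        "hbd": hbd, "hba": hba, "rotb": rotb,
    })
    n_viol = int(round(spec.violation_fraction * n))
    viol_idx = rng.choice(n, size=n_viol, replace=False)
    descriptors = list(_FILTER_WINDOWS)
    for i in viol_idx:
        name = descriptors[int(rng.integers(len(descriptors)))]
        low_side = bool(rng.random() < 0.5)
        if name == "mw":
            val = rng.uniform(20.0, 99.9) if low_side else rng.uniform(700.1, 1200.0)
        elif name == "tpsa":
            val = 0.0 if low_side else rng.uniform(160.1, 300.0)
        elif name == "logp":
            val = rng.uniform(-8.0, -4.01) if low_side else rng.uniform(6.01, 10.0)
        elif name == "hbd":
            val = 0 if low_side else int(rng.integers(5, 9))
        elif name == "hba":
            val = 0 if low_side else int(rng.integers(10, 15))
        else:  # rotb
            val = 0 if low_side else int(rng.integers(15, 26))
        table.loc[i, name] = val
    table["true_pass"] = [
        _passes(row) for row in table[descriptors].to_dict("records")]
    return table


# -- docking score tables ----------------------------------------------------

def make_score_tables(
    spec: SynthSpec, compound_ids: list[str]
) -> tuple[dict[str, tuple[ScoreTable, ScoreTable]], list[str]]:
    """Two correlated engine score tables per conformation.

    A shared latent affinity drives both engines; planted binders sit in
    the top tail of both.  Engine A ("surflex-like") is higher-is-better
    around [4, 9]; engine B ("vina-like") is lower-is-better around
    [-9, -4].  Returns ({conformation: (table_A, table_B)}, binder ids).
    """
    ids = list(compound_ids)
    if spec.n_binders > len(ids):
        raise ValueError("fewer compounds than planted binders")
    rng = _rng(spec.seed, _KEY_SCORES)
    binder_pos = rng.choice(len(ids), size=spec.n_binders, replace=False)
    binders = sorted(ids[i] for i in binder_pos)
    latent = rng.normal(0.0, 1.0, len(ids))
    latent[binder_pos] = spec.binder_latent + rng.normal(
        0.0, 0.25, spec.n_binders)
    tables = {}
    for conf in spec.conformations:
        va = latent + rng.normal(0.0, spec.score_noise, len(ids))
        vb = latent + rng.normal(0.0, spec.score_noise, len(ids))
        score_a = 6.5 + 0.45 * va
        score_b = -6.5 - 0.45 * vb
        tables[conf] = (
            ScoreTable(engine="engineA", conformation=conf,
                       scores=pd.Series(score_a, index=ids),
                       direction="higher"),
            ScoreTable(engine="engineB", conformation=conf,
                       scores=pd.Series(score_b, index=ids),
                       direction="lower"),
        )
    return tables, binders


# -- energy trajectories -----------------------------------------------------

def make_energy_traj(
    spec: SynthSpec, compound_index: int, ddg_true: float
) -> dict[tuple[str, str], EnergyTrajectory]:
    """Planted-truth energy streams for one compound.

    The complex stream is constructed as receptor + ligand + ddg_true +
    Gaussian noise, so the rigid protocol recovers *ddg_true* exactly at
    zero noise and with estimator SD ``ddg_noise/sqrt(window)`` otherwise.
    Independent receptor/ligand runs are the extracted streams lowered by
    the deterministic relaxation offsets, so relaxed minus rigid equals
    ``relax_receptor + relax_ligand`` exactly.
    """
    rng = _rng(spec.seed, _KEY_ENERGY, int(compound_index))
    n = spec.n_energy_snapshots
    receptor = -5000.0 + rng.normal(0.0, 5.0, n)
    ligand = -50.0 + rng.normal(0.0, 2.0, n)
    noise = rng.normal(0.0, spec.ddg_noise, n) if spec.ddg_noise > 0 \
        else np.zeros(n)
    complex_e = receptor + ligand + ddg_true + noise
    dt = spec.timestep_ps
    return {
        ("complex", "extracted"): EnergyTrajectory(
            "complex", "extracted", complex_e, dt),
        ("receptor", "extracted"): EnergyTrajectory(
            "receptor", "extracted", receptor, dt),
        ("ligand", "extracted"): EnergyTrajectory(
            "ligand", "extracted", ligand, dt),
        ("receptor", "independent"): EnergyTrajectory(
            "receptor", "independent", receptor - spec.relax_receptor, dt),
        ("ligand", "independent"): EnergyTrajectory(
            "ligand", "independent", ligand - spec.relax_ligand, dt),
    }


# -- fixture export ----------------------------------------------------------

def write_all(spec: SynthSpec, outdir: str | Path) -> dict[str, str]:
    """Write every synthetic artifact plus truth side-cars under *outdir*.

    Truth files carry planted labels/flags/ids and are never read by the
    pipeline; they exist for evaluation only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    dimer = make_toy_dimer(spec)
    ens, labels, _ = make_ensemble(dimer, spec)
    p = outdir / "ensemble.pdb"
    write_pdb(ens, p)
    paths["ensemble"] = str(p)
    p = outdir / "truth_state_labels.json"
    p.write_text(json.dumps({"labels": labels.tolist()}))
    paths["truth_states"] = str(p)

    lib = make_library(spec)
    p = outdir / "library.csv"
    lib.drop(columns=["true_pass"]).to_csv(p, index=False)
    paths["library"] = str(p)
    p = outdir / "truth_filter_flags.csv"
    lib[["id", "true_pass"]].to_csv(p, index=False)
    paths["truth_filter"] = str(p)

    kept = lib.loc[lib["true_pass"], "id"].tolist()
    tables, binders = make_score_tables(spec, kept)
    rows = []
    for conf, (ta, tb) in tables.items():
        for t in (ta, tb):
            for cid, sc in t.scores.items():
                rows.append({"engine": t.engine, "conformation": conf,
                             "compound_id": cid, "score": sc,
                             "direction": t.direction})
    p = outdir / "scores.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    paths["scores"] = str(p)
    p = outdir / "truth_binders.json"
    p.write_text(json.dumps({"binders": binders}))
    paths["truth_binders"] = str(p)

    erows = []
    id_index = {cid: i for i, cid in enumerate(lib["id"])}
    for cid in binders[: spec.n_binders]:
        trajs = make_energy_traj(spec, id_index[cid], spec.ddg_true_binder)
        for (role, source), t in trajs.items():
            for k, e in enumerate(t.energies):
                erows.append({"compound_id": cid, "role": role,
                              "source": source,
                              "snapshot_ps": k * t.timestep_ps,
                              "energy_kcal_mol": e})
    p = outdir / "energies.csv"
    pd.DataFrame(erows).to_csv(p, index=False)
    paths["energies"] = str(p)

    p = outdir / "synth_spec.json"
    p.write_text(json.dumps(asdict(spec), default=list, indent=2))
    paths["spec"] = str(p)
    return paths
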