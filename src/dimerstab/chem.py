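"""Descriptors, PPI-adapted drug-likeness filtering, fingerprints and
library clustering.

Protein-protein interface modulators are on average larger and greasier
than classical oral drugs, so the physicochemical filter here uses widened
ranges (MW up to 700, logP up to 6, tPSA up to 160) rather than Lipinski's
rule of five.  All bounds are strictly exclusive.  Similarity work uses a
radius-2 circular fingerprint with pharmacophoric (functional-class) atom
invariants — the open-source analogue of an FCFP-4 — folded to 2048 bits.
Computation is delegated to RDKit; this module owns the record model, the
filter semantics and the two clustering modes (sphere-exclusion diversity
picking at distance 0.3 and single-linkage scaffold grouping at similarity
0.6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator
from rdkit.Chem import rdMolDescriptors

__all__ = [
    "MoleculeRecord",
    "FilterRule",
    "FilterResult",
    "DEFAULT_PPI_RULES",
    "DEFAULT_LIABILITY_SMARTS",
    "MoleculeParseError",
    "compute_descriptors",
    "ppi_druglike_filter",
    "fingerprint",
    "tanimoto",
    "diversity_cluster",
    "scaffold_cluster",
    "liability_flags",
    "bioavailability_radar",
]

FINGERPRINT_BITS = 2048
FINGERPRINT_RADIUS = 2

DESCRIPTOR_NAMES = ("mw", "logp", "tpsa", "hbd", "hba", "rotb")


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass
class MoleculeRecord:
    """One library compound: id, structure and physicochemical profile."""

    id: str
    smiles: str
    mw: float | None = None
    logp: float | None = None
    tpsa: float | None = None
    hbd: int | None = None
    hba: int | None = None
    rotb: int | None = None
    fingerprint: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def descriptor(self, name: str):
        return getattr(self, name)


@dataclass(frozen=True)
class FilterRule:
    """Open interval (lo, hi) a descriptor must fall strictly inside."""

    descriptor: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("rule requires lo < hi")

    def passes(self, value: float) -> bool:
        return self.lo < value < self.hi


# "100< MW <700; 0< tPSA <160; -4< logP <6; 0< HBD <5; 0< HBA <10;
#  0< RotBonds <15" — all bounds exclusive, as printed.
DEFAULT_PPI_RULES = (
    FilterRule("mw", 100.0, 700.0),
    FilterRule("tpsa", 0.0, 160.0),
    FilterRule("logp", -4.0, 6.0),
    FilterRule("hbd", 0, 5),
    FilterRule("hba", 0, 10),
    FilterRule("rotb", 0, 15),
)


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    violations: tuple[str, ...]


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"cannot parse SMILES {smiles!r}")
    return mol


def compute_descriptors(smiles: str, mol_id: str = "") -> MoleculeRecord:
    """Compute MW, Crippen logP, Ertl tPSA, H-bond donor/acceptor counts and
    rotatable bonds for one SMILES."""
    mol = _mol(smiles)
    return MoleculeRecord(
        id=mol_id or smiles,
        smiles=smiles,
        mw=float(Descriptors.MolWt(mol)),
        logp=float(Crippen.MolLogP(mol)),
        tpsa=float(rdMolDescriptors.CalcTPSA(mol)),
        hbd=int(rdMolDescriptors.CalcNumHBD(mol)),
        hba=int(rdMolDescriptors.CalcNumHBA(mol)),
        rotb=int(rdMolDescriptors.CalcNumRotatableBonds(mol)),
    )


def ppi_druglike_filter(
    rec: MoleculeRecord, rules=DEFAULT_PPI_RULES
) -> FilterResult:
    """Pass iff every descriptor lies strictly inside its rule interval.

    A missing descriptor is an error, never a silent pass.  All violated
    rule names are reported, not just the first.
    """
    violations = []
    for rule in rules:
        value = rec.descriptor(rule.descriptor)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(
                f"record {rec.id!r} is missing descriptor {rule.descriptor!r}")
        if not rule.passes(value):
            violations.append(rule.descriptor)
    return FilterResult(passed=not violations, violations=tuple(violations))


_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(
    radius=FINGERPRINT_RADIUS,
    fpSize=FINGERPRINT_BITS,
    atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
)


def fingerprint(smiles: str, nbits: int = FINGERPRINT_BITS) -> np.ndarray:
    """Circular fingerprint (radius 2, pharmacophoric atom invariants) as a
    boolean bit array.  Deterministic and canonical-form invariant."""
    mol = _mol(smiles)
    if nbits == FINGERPRINT_BITS:
        fp = _FP_GEN.GetFingerprint(mol)
    else:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=FINGERPRINT_RADIUS, fpSize=nbits,
            atomInvariantsGenerator=rdFingerprintGenerator
            .GetMorganFeatureAtomInvGen())
        fp = gen.GetFingerprint(mol)
    arr = np.zeros(nbits, dtype=bool)
    arr[list(fp.GetOnBits())] = True
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two equal-length bitsets.

    Two all-zero bitsets are defined as identical (similarity 1).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"bitset length mismatch {a.size} vs {b.size}")
    union = int(np.sum(a | b))
    if union == 0:
        return 1.0
    return float(np.sum(a & b)) / union


def diversity_cluster(
    records: list[MoleculeRecord], max_distance: float = 0.3
) -> tuple[list[str], dict[str, str]]:
    """Sphere-exclusion (leader) diversity clustering.

    Records are processed in descending id order.  A record joins the first
    existing representative within Tanimoto distance <= *max_distance*,
    otherwise it founds a new cluster, so representatives end up pairwise
    more distant than the threshold.  Returns (representative ids, member
    id -> representative id map).
    """
    if not records:
        raise ValueError("empty library")
    for rec in records:
        if rec.fingerprint is None:
            raise ValueError(f"record {rec.id!r} has no fingerprint")
    ordered = sorted(records, key=lambda r: r.id, reverse=True)
    reps: list[MoleculeRecord] = []
    assignment: dict[str, str] = {}
    for rec in ordered:
        home = None
        for rep in reps:
            if 1.0 - tanimoto(rec.fingerprint, rep.fingerprint) <= max_distance:
                home = rep
                break
        if home is None:
            reps.append(rec)
            assignment[rec.id] = rec.id
        else:
            assignment[rec.id] = home.id
    return [r.id for r in reps], assignment


def scaffold_cluster(
    records: list[MoleculeRecord], min_similarity: float = 0.6
) -> list[set[str]]:
    """Single-linkage scaffold grouping: connected components of the graph
    joining record pairs with Tanimoto similarity >= *min_similarity*."""
    n = len(records)
    if n == 0:
        return []
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if tanimoto(records[i].fingerprint,
                        records[j].fingerprint) >= min_similarity:
                parent[find(i)] = find(j)
    comps: dict[int, set[str]] = {}
    for i, rec in enumerate(records):
        comps.setdefault(find(i), set()).add(rec.id)
    return sorted(comps.values(), key=lambda c: sorted(c)[0])


# Minimal reactive/PAINS substructure list — a small documented subset, not
# a full liability catalogue.
DEFAULT_LIABILITY_SMARTS = {
    "reactive_acyl_halide": "[CX3](=O)[F,Cl,Br,I]",
    "reactive_aldehyde": "[CX3H1](=O)[#6]",
    "reactive_michael_acceptor": "[CX3]=[CX3][CX3]=[OX1]",
    "reactive_isocyanate": "[NX2]=[CX2]=[OX1]",
    "reactive_epoxide": "C1OC1",
    "reactive_alkyl_halide": "[CX4;H2][Br,I]",
    "pains_quinone": "O=C1C=CC(=O)C=C1",
    "pains_catechol": "c1ccc(O)c(O)c1",
    "pains_hydrazone": "[NX3][NX2]=[CX3]",
    "pains_nitroaromatic": "c[N+](=O)[O-]",
}


def liability_flags(
    smiles: str, smarts_rules: dict[str, str] = DEFAULT_LIABILITY_SMARTS
) -> list[str]:
    """Names of liability substructures (reactive groups, PAINS-like motifs)
    present in the molecule."""
    mol = _mol(smiles)
    hits = []
    for name, smarts in smarts_rules.items():
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"malformed SMARTS for rule {name!r}: {smarts!r}")
        if mol.HasSubstructMatch(patt):
            hits.append(name)
    return hits


def bioavailability_radar(
    rec: MoleculeRecord, rules=DEFAULT_PPI_RULES
) -> tuple[dict[str, float], bool]:
    """Oral-bioavailability radar: each descriptor mapped to its fractional
    position inside the rule interval ((value - lo)/(hi - lo)).

    The compound polygon lies inside the rule polygon exactly when every
    fraction is strictly between 0 and 1 — the same predicate as
    :func:`ppi_druglike_filter`, rendered geometrically.
    """
    fractions = {}
    for rule in rules:
        value = rec.descriptor(rule.descriptor)
        if value is None:
            raise ValueError(f"missing descriptor {rule.descriptor!r}")
        fractions[rule.descriptor] = (value - rule.lo) / (rule.hi - rule.lo)
    inside = all(0.0 < f < 1.0 for f in fractions.values())
    return fractions, inside
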