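"""Deterministic synthetic SMILES sets for offline evaluation.

Real evaluations use public molecule corpora; these generators stand in
for them with seeded, grammar-built molecule sets so the whole
framework runs and is tested with no external data.  Two generators:

* :func:`generate_smiles_set` — pairwise-distinct molecules drawn from
  a small structural grammar (alkyl chains, benzene-derived and
  heteroaromatic rings, fused/bridged aliphatic rings, heteroatom
  substituents), emitted in randomized atom order so canonicalization
  is a non-trivial rewrite.
* :func:`isomer_like_set` — distinct constitutional isomers sharing one
  molecular formula, emulating retrieval pools where composition alone
  cannot separate molecules.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass

from rdkit import Chem

from .augment import MoleculeRecord, randomize_atom_order

GRAMMAR_VERSION = "1"


class GenerationError(RuntimeError):
    """Raised when the requested set cannot be generated."""


@dataclass(frozen=True)
class FixtureSpec:
    """Size, seed and composition targets for a synthetic molecule set."""

    n_molecules: int
    seed: int
    min_aromatic_frac: float = 0.3
    min_ring_frac: float = 0.5
    min_heteroatom_frac: float = 0.4
    grammar_version: str = GRAMMAR_VERSION


# scaffold SMILES by category; substituents attach at implicit-H positions
_AROMATIC_SCAFFOLDS = [
    "c1ccccc1",          # benzene
    "c1ccncc1",          # pyridine
    "c1ccoc1",           # furan
    "c1ccsc1",           # thiophene
    "c1cc[nH]c1",        # pyrrole
    "c1ccc2ccccc2c1",    # naphthalene
    "c1cnc2ccccc2c1",    # quinoline-like
    "c1ccc2[nH]ccc2c1",  # indole
]
_ALIPHATIC_RING_SCAFFOLDS = [
    "C1CCCCC1",          # cyclohexane
    "C1CCCC1",           # cyclopentane
    "C1CCOC1",           # tetrahydrofuran
    "C1CCNCC1",          # piperidine
    "C1CCOCC1",          # tetrahydropyran
    "C1CCC2CCCCC2C1",    # decalin (fused)
    "C1CC2CCC1C2",       # norbornane (bridged)
    "C1CCSC1",           # tetrahydrothiophene
]
_SUBSTITUENTS = ["C", "CC", "CCC", "C(C)C", "O", "N", "F", "Cl", "Br", "OC", "CO", "C(=O)C"]
_CHAIN_ATOMS = ["C", "C", "C", "C", "N", "O"]  # carbon-weighted

# small embedded list for doctests and quick examples (common molecules)
DOCTEST_SMILES = [
    "CCO",                      # ethanol
    "CC(=O)O",                  # acetic acid
    "c1ccccc1",                 # benzene
    "Cc1ccccc1",                # toluene
    "c1ccncc1",                 # pyridine
    "CC(=O)Oc1ccccc1C(=O)O",    # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # caffeine
    "C1CCCCC1",                 # cyclohexane
    "CC(C)O",                   # isopropanol
    "CCN(CC)CC",                # triethylamine
    "C1CCOC1",                  # tetrahydrofuran
    "Clc1ccccc1",               # chlorobenzene
    "CC(N)C(=O)O",              # alanine
    "c1ccc2ccccc2c1",           # naphthalene
    "CCOC(=O)C",                # ethyl acetate
    "NC(=O)c1ccccc1",           # benzamide
    "OCC(O)CO",                 # glycerol
    "CC(C)(C)O",                # tert-butanol
    "C1CC2CCC1C2",              # norbornane
    "OC1CCCCC1",                # cyclohexanol
]


def _attach_substituent(mol: Chem.Mol, frag_smiles: str, rng: random.Random) -> Chem.Mol | None:
    """Attach a fragment by a single bond at a random H-bearing atom."""
    frag = Chem.MolFromSmiles(frag_smiles)
    sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]
    if not sites:
        return None
    site = rng.choice(sites)
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _random_chain(rng: random.Random) -> Chem.Mol | None:
    """A random acyclic skeleton: atoms attached one by one to any atom
    with a free valence (a random tree)."""
    n_heavy = rng.randint(5, 10)
    mol = Chem.RWMol()
    mol.AddAtom(Chem.Atom("C"))
    free = [_VALENCE["C"]]
    for _ in range(n_heavy - 1):
        symbol = rng.choice(_CHAIN_ATOMS)
        sites = [i for i, f in enumerate(free) if f >= 1]
        if not sites:
            break
        site = rng.choice(sites)
        new_idx = mol.AddAtom(Chem.Atom(symbol))
        free.append(_VALENCE[symbol] - 1)
        free[site] -= 1
        mol.AddBond(site, new_idx, Chem.BondType.SINGLE)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _random_candidate(rng: random.Random) -> Chem.Mol | None:
    roll = rng.random()
    if roll < 0.40:
        mol = Chem.MolFromSmiles(rng.choice(_AROMATIC_SCAFFOLDS))
        n_subs = rng.randint(1, 3)
    elif roll < 0.75:
        mol = Chem.MolFromSmiles(rng.choice(_ALIPHATIC_RING_SCAFFOLDS))
        n_subs = rng.randint(0, 3)
    else:
        mol = _random_chain(rng)
        n_subs = rng.randint(0, 2)
    if mol is None:
        return None
    for _ in range(n_subs):
        nxt = _attach_substituent(mol, rng.choice(_SUBSTITUENTS), rng)
        if nxt is not None:
            mol = nxt
    return mol


def _is_aromatic(mol: Chem.Mol) -> bool:
    return any(a.GetIsAromatic() for a in mol.GetAtoms())


def _has_ring(mol: Chem.Mol) -> bool:
    return mol.GetRingInfo().NumRings() > 0


def _has_heteroatom(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() not in (1, 6) for a in mol.GetAtoms())


def generate_smiles_set(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Generate ``spec.n_molecules`` pairwise-distinct molecules.

    Deterministic for a given spec.  Distinctness is enforced by
    canonical-form dedup; composition targets (aromatic / ring /
    heteroatom fractions) are checked after generation and violation
    raises :class:`GenerationError`.  Records are emitted in randomized
    (non-canonical) atom order.
    """
    if spec.n_molecules < 2:
        raise ValueError("need n >= 2 molecules")
    rng = random.Random(spec.seed)
    seen: set[str] = set()
    canonicals: list[str] = []
    n_arom = n_ring = n_het = 0
    attempts = 0
    max_attempts = 300 * spec.n_molecules
    while len(canonicals) < spec.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not generate {spec.n_molecules} distinct molecules "
                f"in {max_attempts} attempts (got {len(canonicals)})"
            )
        mol = _random_candidate(rng)
        if mol is None or mol.GetNumAtoms() < 5:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        canonicals.append(canon)
        n_arom += _is_aromatic(mol)
        n_ring += _has_ring(mol)
        n_het += _has_heteroatom(mol)

    n = spec.n_molecules
    checks = [
        ("aromatic", n_arom / n, spec.min_aromatic_frac),
        ("ring", n_ring / n, spec.min_ring_frac),
        ("heteroatom", n_het / n, spec.min_heteroatom_frac),
    ]
    unmet = [f"{name} {got:.2f} < {want:.2f}" for name, got, want in checks if got < want]
    if unmet:
        raise GenerationError(f"composition targets unmet: {'; '.join(unmet)}")

    return [
        MoleculeRecord(
            id=f"fx{i:04d}",
            smiles=randomize_atom_order(canon, seed=rng.randrange(2**31)),
        )
        for i, canon in enumerate(canonicals)
    ]


# --- isomer generator ------------------------------------------------------

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "F": 1, "Cl": 1, "Br": 1, "I": 1}
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | dict[str, int]) -> dict[str, int]:
    """Molecular formula string ("C3H8O") or dict to an element-count map."""
    if isinstance(formula, dict):
        return dict(formula)
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def _mol_formula_counts(mol: Chem.Mol) -> dict[str, int]:
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        counts["H"] = counts.get("H", 0) + atom.GetTotalNumHs()
    if counts.get("H") == 0:
        counts.pop("H", None)
    return counts


def _random_isomer(heavy: list[str], extra_unsat: int, rng: random.Random) -> Chem.Mol | None:
    """One random connected structure: a random spanning tree over the
    heavy atoms plus ``extra_unsat`` ring bonds / bond-order increments."""
    order = heavy[:]
    rng.shuffle(order)
    mol = Chem.RWMol()
    free = []
    for sym in order:
        idx = mol.AddAtom(Chem.Atom(sym))
        free.append(_VALENCE[sym])
        if idx > 0:
            parents = [i for i in range(idx) if free[i] >= 1]
            if not parents:
                return None
            p = rng.choice(parents)
            mol.AddBond(p, idx, Chem.BondType.SINGLE)
            free[p] -= 1
            free[idx] -= 1
    for _ in range(extra_unsat):
        choices = []
        n_atoms = mol.GetNumAtoms()
        for i in range(n_atoms):
            for j in range(i + 1, n_atoms):
                if free[i] >= 1 and free[j] >= 1:
                    choices.append((i, j))
        if not choices:
            return None
        i, j = rng.choice(choices)
        bond = mol.GetBondBetweenAtoms(i, j)
        if bond is None:
            mol.AddBond(i, j, Chem.BondType.SINGLE)
        elif bond.GetBondType() == Chem.BondType.SINGLE:
            bond.SetBondType(Chem.BondType.DOUBLE)
        elif bond.GetBondType() == Chem.BondType.DOUBLE:
            bond.SetBondType(Chem.BondType.TRIPLE)
        else:
            return None
        free[i] -= 1
        free[j] -= 1
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def isomer_like_set(
    formula_atoms: str | dict[str, int], n: int, seed: int
) -> list[MoleculeRecord]:
    """``n`` distinct constitutional isomers sharing one molecular formula.

    Structures are built by randomized search (random spanning trees
    over the heavy atoms, plus ring closures / multiple bonds for each
    degree of unsaturation) and kept only when the computed formula
    matches exactly.  Raises :class:`GenerationError` reporting the
    achievable count when fewer than ``n`` isomers are found.
    """
    target = parse_formula(formula_atoms)
    unknown = [el for el in target if el != "H" and el not in _VALENCE]
    if unknown:
        raise ValueError(f"elements outside the generator grammar: {unknown}")
    heavy = [el for el, c in target.items() if el != "H" for _ in range(c)]
    if len(heavy) < 2:
        raise ValueError("need at least two heavy atoms")
    h_target = target.get("H", 0)
    h_tree = sum(_VALENCE[s] for s in heavy) - 2 * (len(heavy) - 1)
    if (h_tree - h_target) % 2 or h_target > h_tree:
        raise GenerationError(
            f"formula {target} is unreachable with single-bond valences"
        )
    extra_unsat = (h_tree - h_target) // 2

    rng = random.Random(seed)
    seen: set[str] = set()
    out: list[str] = []
    attempts, max_attempts = 0, 3000 * n
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        mol = _random_isomer(heavy, extra_unsat, rng)
        if mol is None:
            continue
        if _mol_formula_counts(mol) != {k: v for k, v in target.items() if v}:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
    if len(out) < n:
        raise GenerationError(
            f"only {len(out)} distinct isomers of {formula_atoms!r} found "
            f"(requested {n})"
        )
    return [
        MoleculeRecord(id=f"iso{i:04d}", smiles=smi) for i, smi in enumerate(out)
    ]
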