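"""Identity-preserving SMILES augmentations.

Five rewrites that change the string but never the molecule:

* ``canonical`` — the toolkit's canonical aromatic SMILES.
* ``explicit_hydrogen`` — every atom written in bracket form with its
  hydrogen count spelled out (methane ``C`` becomes ``[CH4]``).
* ``kekulized`` — aromatic rings rewritten with explicit alternating
  single/double bonds instead of lowercase aromatic symbols.
* ``cycle_renumbered`` — ring-closure labels remapped to random numbers
  by a string-level, ring-closure-aware scanner.
* ``random_order`` — the molecule re-written from a seeded random atom
  permutation (a non-canonical traversal).

Every augmented string is verified to encode the same molecule as its
original via canonical-SMILES equality (`same_molecule`).
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field
from enum import Enum

from rdkit import Chem, RDLogger

# parse failures are surfaced as Python exceptions; silence the C++ log spam
RDLogger.DisableLog("rdApp.error")


class SmilesParseError(ValueError):
    """Raised when a string cannot be parsed as a valid molecule."""


class MalformedSmilesError(ValueError):
    """Raised for structurally broken SMILES text (e.g. unbalanced ring labels)."""


class AugmentationError(RuntimeError):
    """Raised when a transformation cannot be applied to a valid molecule."""


class AugmentationKind(str, Enum):
    """The five identity-preserving transformations."""

    CANONICAL = "canonical"
    EXPLICIT_HYDROGEN = "explicit_hydrogen"
    KEKULIZED = "kekulized"
    CYCLE_RENUMBERED = "cycle_renumbered"
    RANDOM_ORDER = "random_order"


@dataclass(frozen=True)
class MoleculeRecord:
    """One original SMILES with a stable identifier."""

    id: str
    smiles: str


@dataclass(frozen=True)
class AugmentedPair:
    """An (original, augmented) SMILES pair — the "synonym" unit.

    ``changed`` records whether the augmented string differs from the
    original *as a string*; ``valid`` records whether identity
    verification (same molecule) passed.  ``seed`` reproduces the pair
    for the stochastic kinds.
    """

    original: MoleculeRecord
    augmented_smiles: str
    kind: AugmentationKind
    seed: int
    changed: bool
    valid: bool


def _mol(smiles: str, side: str = "input") -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"{side} is not a valid SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return the toolkit's default canonical aromatic SMILES.

    Idempotent: re-canonicalizing the output returns it unchanged.
    """
    return Chem.MolToSmiles(_mol(smiles))


def add_explicit_hydrogens(smiles: str) -> str:
    """Write every hydrogen explicitly, all atoms in bracket form.

    ``"C" -> "[CH4]"``, ``"O" -> "[OH2]"``.  Hydrogen counts are spelled
    out inside the brackets rather than appended as separate ``[H]``
    atoms, so the heavy-atom skeleton of the string is preserved while
    its syntax changes substantially.
    """
    return Chem.MolToSmiles(_mol(smiles), allHsExplicit=True)


def kekulize(smiles: str) -> str:
    """Rewrite aromatic rings with explicit alternating single/double bonds.

    The output contains no lowercase aromatic atom symbols.  Raises
    :class:`AugmentationError` for aromatic systems the toolkit cannot
    kekulize (the dataset-level driver turns that into ``valid=False``
    rather than a crash).
    """
    mol = _mol(smiles)
    try:
        out = Chem.MolToSmiles(mol, kekuleSmiles=True)
    except Exception as exc:  # pragma: no cover - rare unkekulizable input
        raise AugmentationError(f"cannot kekulize {smiles!r}: {exc}") from exc
    return out


# --- string-level ring-closure scanner -----------------------------------

def _ring_label_tokens(smiles: str) -> list[tuple[int, int, int]]:
    """Locate ring-closure labels outside bracket atoms.

    Returns ``(start, end, label)`` spans.  Digits inside ``[...]`` are
    isotopes/charges/H-counts and are skipped; ``%nn`` two-digit labels
    are supported.
    """
    tokens: list[tuple[int, int, int]] = []
    i, n = 0, len(smiles)
    while i < n:
        c = smiles[i]
        if c == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise MalformedSmilesError(f"unclosed bracket atom in {smiles!r}")
            i = j + 1
        elif c == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise MalformedSmilesError(f"malformed %nn ring label in {smiles!r}")
            tokens.append((i, i + 3, int(smiles[i + 1 : i + 3])))
            i += 3
        elif c.isdigit():
            tokens.append((i, i + 1, int(c)))
            i += 1
        else:
            i += 1
    return tokens


def _pair_ring_labels(tokens: list[tuple[int, int, int]]) -> list[tuple[int, int]]:
    """Pair ring-closure tokens: open at first occurrence, closed at second.

    A label may be reused after it closes; pairing tracks that.  Returns
    index pairs into ``tokens``; raises on unbalanced labels.
    """
    open_at: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []
    for idx, (_, _, label) in enumerate(tokens):
        if label in open_at:
            pairs.append((open_at.pop(label), idx))
        else:
            open_at[label] = idx
    if open_at:
        labels = sorted(open_at)
        raise MalformedSmilesError(f"unbalanced ring-closure labels {labels}")
    return pairs


def _render_label(label: int) -> str:
    return str(label) if label < 10 else f"%{label:02d}"


def renumber_cycles(smiles: str, seed: int) -> str:
    """Remap every ring-closure label pair to a fresh random label.

    Operates at the string level with a ring-closure-aware scanner, so
    bond symbols preceding a closure (``=1``) and bracket-atom digits
    are untouched.  New labels are assigned injectively from 1..99, so
    concurrently open labels never collide; the single-digit namespace
    1..9 is exhausted first (the conventional rendering), with labels
    >= 10 written ``%nn``.  Molecules without ring closures are
    returned unchanged.
    """
    _mol(smiles)  # precondition: must be a valid molecule
    tokens = _ring_label_tokens(smiles)
    pairs = _pair_ring_labels(tokens)
    if not pairs:
        return smiles
    rng = random.Random(seed)
    single = rng.sample(range(1, 10), k=min(len(pairs), 9))
    multi = rng.sample(range(10, 100), k=max(0, len(pairs) - 9))
    new_labels = single + multi
    replacement: dict[int, str] = {}
    for (open_idx, close_idx), label in zip(pairs, new_labels):
        replacement[open_idx] = replacement[close_idx] = _render_label(label)
    out: list[str] = []
    cursor = 0
    for idx, (start, end, _) in enumerate(tokens):
        out.append(smiles[cursor:start])
        out.append(replacement[idx])
        cursor = end
    out.append(smiles[cursor:])
    result = "".join(out)
    if not same_molecule(smiles, result):  # pragma: no cover - safety net
        raise AugmentationError(f"cycle renumbering altered the molecule: {smiles!r}")
    return result


def randomize_atom_order(smiles: str, seed: int) -> str:
    """Re-write the molecule from a seeded random atom permutation.

    A pure function of ``(smiles, seed)``: the same pair always yields
    the same output, across processes.
    """
    mol = _mol(smiles)
    order = list(range(mol.GetNumAtoms()))
    random.Random(seed).shuffle(order)
    shuffled = Chem.RenumberAtoms(mol, order)
    return Chem.MolToSmiles(shuffled, canonical=False)


def same_molecule(a: str, b: str) -> bool:
    """True iff the two SMILES encode the same molecule.

    Identity is canonical-SMILES equality of the parsed molecules
    (hydrogens normalized by parsing), the package-wide identity oracle.
    """
    ma = _mol(a, side="first argument")
    mb = _mol(b, side="second argument")
    return Chem.MolToSmiles(ma) == Chem.MolToSmiles(mb)


# --- dataset-level driver --------------------------------------------------

@dataclass
class SkipReport:
    """Records which pairs failed augmentation or identity verification."""

    kind: AugmentationKind
    n_total: int = 0
    n_valid: int = 0
    n_changed: int = 0
    failures: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "n_total": self.n_total,
            "n_valid": self.n_valid,
            "n_changed": self.n_changed,
            "failures": self.failures,
        }


def derive_seed(master_seed: int, record_id: str) -> int:
    """Stable per-record seed from (master seed, id), order-independent."""
    digest = hashlib.blake2b(
        f"{master_seed}:{record_id}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _apply(kind: AugmentationKind, smiles: str, seed: int) -> str:
    if kind is AugmentationKind.CANONICAL:
        return canonicalize(smiles)
    if kind is AugmentationKind.EXPLICIT_HYDROGEN:
        return add_explicit_hydrogens(smiles)
    if kind is AugmentationKind.KEKULIZED:
        return kekulize(smiles)
    if kind is AugmentationKind.CYCLE_RENUMBERED:
        return renumber_cycles(smiles, seed)
    if kind is AugmentationKind.RANDOM_ORDER:
        return randomize_atom_order(smiles, seed)
    raise ValueError(f"unknown augmentation kind: {kind!r}")


def augment_dataset(
    records: list[MoleculeRecord],
    kind: AugmentationKind | str,
    master_seed: int,
) -> tuple[list[AugmentedPair], SkipReport]:
    """Apply one augmentation to every record, verifying identity.

    The output is row-aligned with the input: one pair per record, in
    order, so retrieval set sizes match the input size exactly.  Records
    whose augmentation fails are retained with ``valid=False`` and
    listed in the skip report; unchanged outputs are retained with
    ``changed=False``.  Per-record seeds derive from
    ``(master_seed, record.id)``, so results do not depend on dataset
    ordering.
    """
    kind = AugmentationKind(kind)
    if not records:
        raise ValueError("augment_dataset requires a non-empty record list")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record ids: {dupes}")

    report = SkipReport(kind=kind, n_total=len(records))
    pairs: list[AugmentedPair] = []
    for rec in records:
        seed = derive_seed(master_seed, rec.id)
        try:
            aug = _apply(kind, rec.smiles, seed)
            valid = same_molecule(rec.smiles, aug)
            if not valid:
                report.failures.append(
                    {"id": rec.id, "reason": "identity verification failed"}
                )
        except (AugmentationError, SmilesParseError, MalformedSmilesError) as exc:
            aug, valid = rec.smiles, False
            report.failures.append({"id": rec.id, "reason": str(exc)})
        changed = aug != rec.smiles
        report.n_valid += valid
        report.n_changed += changed
        pairs.append(
            AugmentedPair(
                original=rec,
                augmented_smiles=aug,
                kind=kind,
                seed=seed,
                changed=changed,
                valid=valid,
            )
        )
    return pairs, report
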