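"""Reusable control experiments on synthetic molecule sets.

Each function runs one self-contained study used to validate (and
demonstrate) the framework: an identity suite over all augmentations, a
perfect-retrieval positive control, a pure-noise chance control, a
robustness-recovery sweep, and the surface-encoder difficulty ordering
with its matching Levenshtein-ratio profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment import AugmentationKind, augment_dataset
from .encoders import InvariantToyEncoder, NoisySyntheticEncoder, SurfaceToyEncoder
from .fixtures import FixtureSpec, generate_smiles_set
from .retrieval import DistanceKind, evaluate_retrieval
from .string_stats import dataset_string_report

STANDARD_FIXTURE = FixtureSpec(n_molecules=100, seed=1)


def standard_records(n: int = 100, seed: int = 1):
    return generate_smiles_set(FixtureSpec(n_molecules=n, seed=seed))


def identity_suite(n: int = 100, seed: int = 1) -> dict[str, float]:
    """Fraction of valid (identity-verified) pairs per augmentation kind."""
    records = standard_records(n, seed)
    out = {}
    for kind in AugmentationKind:
        pairs, _ = augment_dataset(records, kind, master_seed=seed)
        out[kind.value] = sum(p.valid for p in pairs) / len(pairs)
    return out


def positive_control(n: int = 100, seed: int = 1) -> dict[str, dict[str, float]]:
    """Invariant encoder: every synonym collapses, so retrieval is perfect."""
    records = standard_records(n, seed)
    encoder = InvariantToyEncoder(seed=seed)
    orig = encoder.encode([r.smiles for r in records])
    out = {}
    for kind in AugmentationKind:
        pairs, _ = augment_dataset(records, kind, master_seed=seed)
        aug = encoder.encode([p.augmented_smiles for p in pairs])
        rep = evaluate_retrieval(
            orig.last_layer, aug.last_layer, DistanceKind.EUCLIDEAN_L2
        )
        out[kind.value] = {"acc_at_1": rep.acc_at_1, "mrr": rep.mrr}
    return out


@dataclass
class ChanceControlResult:
    mean_acc_at_1: float
    mean_mrr: float
    n: int
    n_seeds: int
    per_seed_acc: list[float]
    per_seed_mrr: list[float]


def chance_control(
    n: int = 100,
    n_seeds: int = 50,
    fixture_seed: int = 1,
    d: int = 64,
    encoder_seed_base: int = 0,
) -> ChanceControlResult:
    """Pure-noise encoder (rho=0): retrieval ranks are uniform.

    Expected Acc@1 = 1/n and expected MRR = H_n/n.  Originals and
    augmentations are encoded with different salts, as for a model whose
    non-chemical component differs between encoding passes.
    """
    records = standard_records(n, fixture_seed)
    smiles = [r.smiles for r in records]
    pairs, _ = augment_dataset(
        records, AugmentationKind.RANDOM_ORDER, master_seed=fixture_seed
    )
    aug_smiles = [p.augmented_smiles for p in pairs]
    accs, mrrs = [], []
    for s in range(encoder_seed_base, encoder_seed_base + n_seeds):
        enc = NoisySyntheticEncoder(rho=0.0, seed=s, d=d, salt="orig")
        orig = enc.encode(smiles)
        aug = enc.with_salt("aug").encode(aug_smiles)
        rep = evaluate_retrieval(orig.last_layer, aug.last_layer)
        accs.append(rep.acc_at_1)
        mrrs.append(rep.mrr)
    return ChanceControlResult(
        mean_acc_at_1=float(np.mean(accs)),
        mean_mrr=float(np.mean(mrrs)),
        n=n,
        n_seeds=n_seeds,
        per_seed_acc=accs,
        per_seed_mrr=mrrs,
    )


def robustness_sweep(
    rhos=(0.0, 0.25, 0.5, 0.75, 1.0),
    n: int = 100,
    n_seeds: int = 10,
    fixture_seed: int = 1,
    d: int = 64,
    encoder_seed_base: int = 0,
) -> dict[float, float]:
    """Mean Acc@1 as a function of the encoder robustness rho.

    Recovery check: the retrieval metric should increase monotonically
    with the share of molecule-identity signal in the embedding.
    """
    records = standard_records(n, fixture_seed)
    smiles = [r.smiles for r in records]
    pairs, _ = augment_dataset(
        records, AugmentationKind.RANDOM_ORDER, master_seed=fixture_seed
    )
    aug_smiles = [p.augmented_smiles for p in pairs]
    out: dict[float, float] = {}
    for rho in rhos:
        accs = []
        for s in range(encoder_seed_base, encoder_seed_base + n_seeds):
            enc = NoisySyntheticEncoder(rho=rho, seed=s, d=d, salt="orig")
            orig = enc.encode(smiles)
            aug = enc.with_salt("aug").encode(aug_smiles)
            accs.append(evaluate_retrieval(orig.last_layer, aug.last_layer).acc_at_1)
        out[float(rho)] = float(np.mean(accs))
    return out


def difficulty_ordering(n: int = 100, seed: int = 1) -> dict[str, dict[str, float]]:
    """Surface encoder Acc@1 and mean Levenshtein ratio per augmentation.

    The surface baseline keys on raw text, so augmentations that disturb
    more characters are harder: explicit hydrogens hardest, cycle
    renumbering easiest, canonicalization/kekulization in between.
    """
    records = standard_records(n, seed)
    encoder = SurfaceToyEncoder(seed=seed)
    orig = encoder.encode([r.smiles for r in records])
    pairs_by_kind = {}
    out: dict[str, dict[str, float]] = {}
    for kind in AugmentationKind:
        pairs, _ = augment_dataset(records, kind, master_seed=seed)
        pairs_by_kind[kind.value] = pairs
        aug = encoder.encode([p.augmented_smiles for p in pairs])
        rep = evaluate_retrieval(orig.last_layer, aug.last_layer)
        out[kind.value] = {"acc_at_1": rep.acc_at_1, "mrr": rep.mrr}
    stats = dataset_string_report(pairs_by_kind)
    for kind_name, row in stats.rows.items():
        if kind_name in out:
            out[kind_name]["lev_ratio_mean"] = row.ratio_mean
            out[kind_name]["lev_ratio_std"] = row.ratio_std
    return out
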