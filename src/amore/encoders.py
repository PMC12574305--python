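"""Encoder contract and deterministic built-in encoders.

An encoder maps a list of strings to per-layer pooled embedding
matrices (`LayerEmbeddings`).  Three built-ins make the retrieval
framework testable without any model download:

* :class:`InvariantToyEncoder` — embeds the *canonical* form of each
  SMILES, so all synonyms of one molecule collapse to one vector.  A
  positive control: retrieval is perfect by construction.
* :class:`SurfaceToyEncoder` — hashes character n-grams of the raw
  string, so any rewrite shifts the embedding in proportion to how much
  surface text it disturbs.  A non-robust baseline.
* :class:`NoisySyntheticEncoder` — interpolates between the two with a
  robustness parameter ``rho``; a parameter-recovery fixture for the
  metrics (``rho=1`` perfect, ``rho=0`` pure noise, monotone between).

External models are supported through the same contract: any object
with ``encode(strings) -> LayerEmbeddings`` plugs into the evaluation,
and precomputed embedding matrices can be ingested from disk (see
:mod:`amore.cli_io`) so no model code ever needs to run here.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

import numpy as np

from .augment import SmilesParseError, canonicalize


@dataclass
class LayerEmbeddings:
    """Per-layer n x d embedding matrices, row-aligned with the input order.

    Layer 0 is conventionally the initial token-embedding layer of a
    transformer; single-layer encoders just use {0}.
    """

    layers: dict[int, np.ndarray]
    encoder: str = "unknown"
    pooling: str = "mean"
    side: str = "n/a"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("LayerEmbeddings requires at least one layer")
        shapes = {idx: m.shape for idx, m in self.layers.items()}
        ns = {s[0] for s in shapes.values()}
        if len(ns) != 1:
            raise ValueError(f"layers disagree on n: {shapes}")
        for idx, m in self.layers.items():
            if m.ndim != 2 or m.shape[1] < 1:
                raise ValueError(f"layer {idx} is not an n x d matrix: {m.shape}")
            if np.isnan(m).all(axis=1).any():
                raise ValueError(f"layer {idx} contains an all-NaN row")

    @property
    def n(self) -> int:
        return next(iter(self.layers.values())).shape[0]

    @property
    def layer_indices(self) -> list[int]:
        return sorted(self.layers)

    @property
    def last_layer(self) -> np.ndarray:
        return self.layers[max(self.layers)]


def mean_pool(token_vectors, mask) -> np.ndarray:
    """Arithmetic mean of the token vectors where ``mask`` is true.

    The standard pooling rule for turning per-token transformer states
    into one sequence vector; padding positions are masked out.
    """
    vectors = np.asarray(token_vectors, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if vectors.shape[0] != mask.shape[0]:
        raise ValueError(
            f"mask length {mask.shape[0]} != token count {vectors.shape[0]}"
        )
    if not mask.any():
        raise ValueError("empty pooling window: mask selects no positions")
    return vectors[mask].mean(axis=0)


def _hashed_ngram_vector(
    text: str, d: int, seed: int, n_min: int = 1, n_max: int = 3
) -> np.ndarray:
    """Signed hashed bag-of-n-grams, L2-normalized. Process-stable hashing."""
    v = np.zeros(d)
    s = f"^{text}$"
    for n in range(n_min, n_max + 1):
        for i in range(len(s) - n + 1):
            h = hashlib.blake2b(
                f"{seed}|{n}|{s[i:i + n]}".encode(), digest_size=8
            ).digest()
            idx = int.from_bytes(h[:4], "little") % d
            sign = 1.0 if h[4] & 1 else -1.0
            v[idx] += sign
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


class InvariantToyEncoder:
    """Embeds the canonical form of each SMILES: synonyms collapse exactly.

    Because every valid rewrite of a molecule canonicalizes to the same
    string, all its synonyms receive byte-identical rows — the retrieval
    task's positive control.
    """

    n_layers = 1
    pooling = "n/a (string-level hashing)"

    def __init__(self, d: int = 256, seed: int = 0):
        self.d = d
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    @property
    def name(self) -> str:
        return f"invariant(d={self.d},seed={self.seed})"

    def _row(self, smiles: str) -> np.ndarray:
        key = canonicalize(smiles)
        if key not in self._cache:
            self._cache[key] = _hashed_ngram_vector(key, self.d, self.seed)
        return self._cache[key]

    def encode(self, strings: list[str]) -> LayerEmbeddings:
        bad = []
        rows = []
        for s in strings:
            try:
                rows.append(self._row(s))
            except SmilesParseError:
                bad.append(s)
        if bad:
            raise SmilesParseError(f"unparseable SMILES: {bad}")
        return LayerEmbeddings(
            layers={0: np.vstack(rows)}, encoder=self.name, pooling=self.pooling
        )


class SurfaceToyEncoder:
    """Hashes character n-grams of a notation-folded copy of the raw string.

    Keys on the surface layout of the string — atom sequence, branching,
    ring labels, brackets — so rewrites shift the embedding roughly in
    proportion to how much text they disturb.  Before hashing, the one
    purely notational axis of SMILES is folded away: letter case,
    bond-order marks (``= # :``) and aromatic-hydrogen brackets
    (``[nH]`` -> ``n``) — the aromatic vs. Kekulé writings of a ring
    then hash identically.  The encoder stays fully sensitive to atom
    reordering, branch placement, ring-label choice and the bracket
    expansion produced by writing hydrogens explicitly.
    """

    n_layers = 1
    pooling = "n/a (string-level hashing)"
    _DROP = str.maketrans("", "", "=#:")
    _AROMATIC_H = re.compile(r"\[([a-z][a-z]?)H\d?\]")

    def __init__(self, d: int = 256, seed: int = 0):
        self.d = d
        self.seed = seed

    @property
    def name(self) -> str:
        return f"surface(d={self.d},seed={self.seed})"

    def _row(self, text: str) -> np.ndarray:
        stream = self._AROMATIC_H.sub(r"\1", text).lower().translate(self._DROP)
        return _hashed_ngram_vector(stream, self.d, self.seed)

    def encode(self, strings: list[str]) -> LayerEmbeddings:
        if not strings:
            raise ValueError("cannot encode an empty string list")
        rows = np.vstack([self._row(s) for s in strings])
        return LayerEmbeddings(
            layers={0: rows}, encoder=self.name, pooling=self.pooling
        )


class NoisySyntheticEncoder:
    """Mixture of a molecule-identity signal and string-specific noise.

    Each row is ``rho * invariant(molecule) + (1 - rho) * noise``, where
    the noise is a unit Gaussian vector drawn deterministically from
    ``(seed, salt, raw string)``.  ``rho=1`` reproduces the invariant
    encoder; ``rho=0`` is pure noise, under which retrieval ranks are
    uniform.  The ``salt`` distinguishes encoding passes, emulating a
    model whose idiosyncratic (non-chemical) component differs between
    the original and augmented encoding runs.
    """

    n_layers = 1
    pooling = "n/a (synthetic)"

    def __init__(
        self, rho: float, seed: int = 0, d: int = 256, salt: str = ""
    ):
        if not 0.0 <= rho <= 1.0:
            raise ValueError(f"robustness rho must be in [0, 1], got {rho}")
        self.rho = float(rho)
        self.seed = seed
        self.d = d
        self.salt = salt
        self._signal = InvariantToyEncoder(d=d, seed=seed)

    @property
    def name(self) -> str:
        return f"noisy(rho={self.rho},d={self.d},seed={self.seed},salt={self.salt!r})"

    def with_salt(self, salt: str) -> "NoisySyntheticEncoder":
        return NoisySyntheticEncoder(self.rho, seed=self.seed, d=self.d, salt=salt)

    def _noise(self, text: str) -> np.ndarray:
        digest = hashlib.blake2b(
            f"{self.seed}|{self.salt}|{text}".encode(), digest_size=8
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        v = rng.standard_normal(self.d)
        return v / np.linalg.norm(v)

    def encode(self, strings: list[str]) -> LayerEmbeddings:
        signal = self._signal.encode(strings).layers[0]
        noise = np.vstack([self._noise(s) for s in strings])
        rows = self.rho * signal + (1.0 - self.rho) * noise
        return LayerEmbeddings(
            layers={0: rows}, encoder=self.name, pooling=self.pooling
        )


class StackedLayersEncoder:
    """Wraps per-layer encoders into one multi-layer adapter (test harness
    for the layer sweep: e.g. noise at layer 0, signal at layer 1)."""

    def __init__(self, layer_encoders: dict[int, object], name: str = "stacked"):
        self.layer_encoders = dict(layer_encoders)
        self._name = name

    @property
    def name(self) -> str:
        return self._name

    def encode(self, strings: list[str]) -> LayerEmbeddings:
        layers = {
            idx: enc.encode(strings).layers[0]
            for idx, enc in self.layer_encoders.items()
        }
        return LayerEmbeddings(layers=layers, encoder=self._name)
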