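"""Non-hashed binary fingerprints and the dissimilarity measures of the selection filter.

The default scheme is the 167-bit MACCS substructure-key set (non-hashed, so
bit semantics are stable across toolkits). Additional schemes can be
registered; ``composite`` concatenates every registered base scheme.

Two distances are provided:

* :func:`jaccard_distance` on binary vectors;
* :func:`continuous_tanimoto_distance`, the real-valued Tanimoto
  generalization ``1 - x.y / (|x|^2 + |y|^2 - x.y)`` used on (scaled)
  descriptor vectors.

Note on terminology: the similarity family implemented here is
Jaccard/Tanimoto. Rogers–Tanimoto (which also counts matching zeros) is
deliberately NOT implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from .errors import ConfigurationError, SmilesParseError, UndefinedDistanceError
from .io import CompoundRecord


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint plus the label of its scheme."""

    bits: np.ndarray  # uint8 0/1
    scheme: str

    def count(self) -> int:
        return int(self.bits.sum())


def _maccs_bits(mol: Chem.Mol) -> np.ndarray:
    bv = MACCSkeys.GenMACCSKeys(mol)
    return np.frombuffer(bytes(bv.ToBitString(), "ascii"), dtype=np.uint8) - ord("0")


_SCHEMES: dict[str, Callable[[Chem.Mol], np.ndarray]] = {"maccs": _maccs_bits}


def register_scheme(name: str, fn: Callable[[Chem.Mol], np.ndarray]) -> None:
    _SCHEMES[name] = fn


def available_schemes() -> list[str]:
    return sorted(_SCHEMES) + ["composite"]


def compute_fingerprint(record: CompoundRecord, scheme: str = "maccs") -> Fingerprint:
    """Deterministic fingerprint of one record under a registered scheme."""
    if scheme != "composite" and scheme not in _SCHEMES:
        raise ConfigurationError(
            f"unknown fingerprint scheme {scheme!r}; available: {available_schemes()}"
        )
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise SmilesParseError(record.id, record.smiles)
    if scheme == "composite":
        parts = [_SCHEMES[name](mol) for name in sorted(_SCHEMES)]
        bits = np.concatenate(parts)
    else:
        bits = _SCHEMES[scheme](mol)
    return Fingerprint(bits=bits.astype(np.uint8), scheme=scheme)


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - |intersection| / |union| for binary vectors of equal length."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    a = a != 0
    b = b != 0
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise UndefinedDistanceError("Jaccard distance undefined for two all-zero vectors")
    inter = int(np.logical_and(a, b).sum())
    return 1.0 - inter / union


def continuous_tanimoto_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Real-valued Tanimoto distance 1 - x.y / (|x|^2 + |y|^2 - x.y).

    Equals jaccard_distance on 0/1 vectors; 0 iff x == y; symmetric.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    dot = float(x @ y)
    denom = float(x @ x) + float(y @ y) - dot
    if denom == 0.0:
        raise UndefinedDistanceError(
            "continuous Tanimoto distance undefined for two all-zero vectors"
        )
    return 1.0 - dot / denom


def pairwise_continuous_tanimoto(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorized distances from one vector `x` to every row of `Y`."""
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    dots = Y @ x
    denom = float(x @ x) + np.einsum("ij,ij->i", Y, Y) - dots
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(denom != 0.0, dots / denom, np.nan)
    return d


def pairwise_jaccard(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorized Jaccard distances from one binary vector to every row of `Y`."""
    x = np.asarray(x) != 0
    Y = np.asarray(Y) != 0
    inter = (Y & x).sum(axis=1)
    union = (Y | x).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union != 0, inter / union, np.nan)
    return d
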