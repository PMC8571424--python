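"""Assembly of the 150-dimensional per-sequence feature vector.

The vector concatenates six blocks in a fixed, versioned order (trained
models depend on it):

====================  ======  =====================================
block                 length  content
====================  ======  =====================================
seq moments               30  raw/central/Hahn moments of the grid
                              built from the encoded sequence
PRIM moments              30  the same 30 moments of the 20x20 PRIM
RPRIM moments             30  ... of the 20x20 RPRIM
frequency                 20  standard amino-acid counts
AAPIV                     20  summed forward positions
RAAPIV                    20  summed reverse positions
====================  ======  =====================================

PRIM/RPRIM are fed to the moment engine directly as 20x20 grids; their
entries may be negative under the signed-offset convention, which the
moment sums accept.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import positional
from .moments import MOMENT_ORDER_NAMES, moment_descriptor, to_square_matrix
from .sequence_io import STANDARD_AMINO_ACIDS, ProteinSequence, encode_sequence

FEATURE_LENGTH = 150

#: block boundaries within the 150-vector
BLOCK_SLICES = {
    "seq_moments": slice(0, 30),
    "prim_moments": slice(30, 60),
    "rprim_moments": slice(60, 90),
    "frequency": slice(90, 110),
    "aapiv": slice(110, 130),
    "raapiv": slice(130, 150),
}


def _moment_names(prefix: str) -> list[str]:
    fams = [("raw", "G"), ("central", "H"), ("hahn", "E")]
    return [f"{prefix}_{fam}_{sym}{xy}" for fam, sym in fams for xy in MOMENT_ORDER_NAMES]


#: stable, ordered names of the 150 features
FEATURE_NAMES: list[str] = (
    _moment_names("seq")
    + _moment_names("prim")
    + _moment_names("rprim")
    + [f"freq_{aa}" for aa in STANDARD_AMINO_ACIDS]
    + [f"aapiv_{aa}" for aa in STANDARD_AMINO_ACIDS]
    + [f"raapiv_{aa}" for aa in STANDARD_AMINO_ACIDS]
)

assert len(FEATURE_NAMES) == FEATURE_LENGTH


def feature_fingerprint(names: list[str] | None = None) -> str:
    """Short stable digest of the feature-name order; stored with models."""
    names = FEATURE_NAMES if names is None else names
    return hashlib.sha256(",".join(names).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class FeatureVector:
    id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (FEATURE_LENGTH,):
            raise ValueError(
                f"feature vector must have {FEATURE_LENGTH} values, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature values for {self.id!r}")


def extract_features(seq: ProteinSequence) -> FeatureVector:
    """Compute the full 150-value descriptor of one sequence."""
    grid = to_square_matrix(encode_sequence(seq))
    blocks = [
        moment_descriptor(grid).values,
        moment_descriptor(positional.prim(seq).astype(float)).values,
        moment_descriptor(positional.rprim(seq).astype(float)).values,
        positional.frequency_vector(seq).astype(float),
        positional.aapiv(seq).astype(float),
        positional.raapiv(seq).astype(float),
    ]
    return FeatureVector(seq.id, np.concatenate(blocks))


def extract_feature_matrix(
    sequences: list[ProteinSequence],
) -> tuple[np.ndarray, list[str]]:
    """Feature matrix (n x 150) plus ids, in input order."""
    vectors = [extract_features(s) for s in sequences]
    return np.vstack([v.values for v in vectors]), [v.id for v in vectors]


def write_feature_table(vectors: list[FeatureVector], path: str | Path) -> None:
    """CSV with an ``id`` column plus the 150 named feature columns.

    A ``.gz`` suffix produces gzip-compressed output.
    """
    if not vectors:
        raise ValueError("no feature vectors to write")
    df = pd.DataFrame(
        np.vstack([v.values for v in vectors]), columns=FEATURE_NAMES
    )
    df.insert(0, "id", [v.id for v in vectors])
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a feature CSV; returns (matrix, ids, feature names)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError("feature table must have an 'id' column")
    names = [c for c in df.columns if c != "id"]
    return df[names].to_numpy(dtype=float), df["id"].astype(str).tolist(), names
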