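"""Word-embedding tables: GloVe text-format reader and vocabulary alignment.

Pretrained vectors ship as plain text, one ``token v1 v2 ... vD`` line
each.  ``read_glove`` parses such a file; ``build_table`` aligns a vector
map to a :class:`~milsocnet.preprocessing.Vocabulary`, drawing seeded
uniform(-0.05, 0.05) rows for words without a pretrained vector and
keeping the padding row at exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocessing import PAD_ID, Vocabulary

__all__ = ["EmbeddingTable", "read_glove", "build_table"]

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingTable:
    weights: np.ndarray  # (vocab size, dim)
    trainable: bool = True

    def __post_init__(self):
        if not np.isfinite(self.weights).all():
            raise ValueError("embedding table contains non-finite values")
        if not (self.weights[PAD_ID] == 0).all():
            raise ValueError("padding row of the embedding table must be zero")

    @property
    def dim(self) -> int:
        return self.weights.shape[1]

    def embed(self, token_ids: np.ndarray) -> np.ndarray:
        """Row lookup: ids of any shape -> vectors of shape ids.shape + (dim,)."""
        return self.weights[np.asarray(token_ids)]


def read_glove(path, dim: int) -> dict[str, np.ndarray]:
    """Parse a GloVe-format text file into a word -> vector map.

    Lines whose arity does not match ``1 + dim`` (or whose floats fail to
    parse) are skipped with a logged warning.  If the file is non-empty
    but no line parses, that is a dim mismatch and an error.
    """
    vectors: dict[str, np.ndarray] = {}
    n_lines = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n_lines += 1
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                logger.warning(
                    "skipping line %d of %s: expected %d fields, got %d",
                    lineno, path, dim + 1, len(parts),
                )
                continue
            try:
                vec = np.array([float(v) for v in parts[1:]])
            except ValueError:
                logger.warning("skipping line %d of %s: unparseable floats",
                               lineno, path)
                continue
            vectors[parts[0]] = vec
    if n_lines > 0 and not vectors:
        raise ValueError(
            f"no line of {path} has dimension {dim}; wrong --dim or wrong file"
        )
    return vectors


def build_table(
    vocab: Vocabulary,
    vectors: dict[str, np.ndarray],
    dim: int,
    seed: int = 0,
    trainable: bool = True,
) -> EmbeddingTable:
    """Align pretrained vectors to a vocabulary.

    In-vocabulary words take their pretrained rows; everything else
    (including the OOV token) gets an i.i.d. uniform(-0.05, 0.05) row from
    a seeded generator, so two builds with the same seed are identical.
    The padding row is zero.
    """
    rng = np.random.default_rng(seed)
    table = rng.uniform(-0.05, 0.05, size=(len(vocab), dim))
    for token, idx in vocab.token_to_id.items():
        vec = vectors.get(token)
        if vec is not None:
            if vec.shape != (dim,):
                raise ValueError(
                    f"vector for {token!r} has dim {vec.shape[0]}, expected {dim}"
                )
            table[idx] = vec
    table[PAD_ID] = 0.0
    return EmbeddingTable(table, trainable=trainable)
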