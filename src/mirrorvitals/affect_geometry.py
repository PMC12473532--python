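"""Face-analysis geometry and classification primitives.

Covers the cosine-rule alignment angle from eye/reference landmark
distances, prototype classification of caller-supplied embeddings by
cosine similarity or Euclidean distance, and the rolling majority vote
used for age buckets.  A deterministic toy embedder ships for tests; real
CNN embeddings plug in through the same interface.
"""

from __future__ import annotations

import hashlib
import math
from collections import Counter
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ClassificationError, ConfigurationError, GeometryError

#: Default number of rolling samples for the age majority vote.
DEFAULT_VOTES = 30


@dataclass(frozen=True)
class TriangleSides:
    """a: eye-to-eye distance; b, c: each eye to the reference landmark."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        if self.a < 0 or self.b <= 0 or self.c <= 0:
            raise GeometryError(
                f"sides must be positive (a may be 0), got a={self.a}, b={self.b}, c={self.c}"
            )
        if self.b + self.c < self.a or self.a + self.b < self.c or self.a + self.c < self.b:
            raise GeometryError(f"triangle inequality violated for ({self.a}, {self.b}, {self.c})")


def alignment_angle(sides: TriangleSides) -> float:
    """Angle at the reference vertex via the cosine rule, in degrees.

    ``A = arccos((b^2 + c^2 - a^2) / (2 b c)) * 180 / pi``, in [0, 180].
    """
    cos_a = (sides.b ** 2 + sides.c ** 2 - sides.a ** 2) / (2.0 * sides.b * sides.c)
    cos_a = min(1.0, max(-1.0, cos_a))  # clamp rounding at collinear limits
    return math.degrees(math.acos(cos_a))


def sides_from_landmarks(
    left_eye: Sequence[float], right_eye: Sequence[float], reference: Sequence[float]
) -> TriangleSides:
    le = np.asarray(left_eye, dtype=float)
    re = np.asarray(right_eye, dtype=float)
    ref = np.asarray(reference, dtype=float)
    return TriangleSides(
        a=float(np.linalg.norm(le - re)),
        b=float(np.linalg.norm(le - ref)),
        c=float(np.linalg.norm(re - ref)),
    )


@dataclass
class PrototypeSet:
    """Labeled reference vectors, all of one dimension."""

    labels: List[str]
    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if len(self.labels) != len(self.vectors):
            raise ConfigurationError("one label per prototype vector required")
        if len(self.labels) < 1:
            raise ConfigurationError("at least one prototype required")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def classify_cosine(v: np.ndarray, protos: PrototypeSet) -> Tuple[str, float]:
    """Label of the prototype with maximal cosine similarity to ``v``.

    Ties go to the first prototype in declared order.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (protos.dim,):
        raise ClassificationError(f"embedding dim {v.shape} != prototype dim ({protos.dim},)")
    norm_v = np.linalg.norm(v)
    if norm_v == 0:
        raise ClassificationError("zero-norm embedding cannot be classified by cosine")
    norms = np.linalg.norm(protos.vectors, axis=1)
    if np.any(norms == 0):
        raise ClassificationError("zero-norm prototype in cosine mode")
    sims = protos.vectors @ v / (norms * norm_v)
    j = int(np.argmax(sims))  # argmax returns the first maximal index: tie rule
    return protos.labels[j], float(sims[j])


def classify_euclidean(v: np.ndarray, protos: PrototypeSet) -> Tuple[str, float]:
    """Label of the nearest prototype in Euclidean distance (first-wins ties)."""
    v = np.asarray(v, dtype=float)
    if v.shape != (protos.dim,):
        raise ClassificationError(f"embedding dim {v.shape} != prototype dim ({protos.dim},)")
    dists = np.linalg.norm(protos.vectors - v, axis=1)
    j = int(np.argmin(dists))
    return protos.labels[j], float(dists[j])


def majority_vote(
    labels: Sequence[str], n_required: int = DEFAULT_VOTES
) -> Optional[Tuple[str, int, float]]:
    """Most frequent label over the last ``n_required`` entries.

    Returns ``(label, count, count / n_required)``; ``None`` (pending)
    while fewer than ``n_required`` labels have been collected.  Ties are
    broken in favour of the tied label seen most recently.
    """
    if n_required < 1:
        raise ConfigurationError("n_required must be >= 1")
    if len(labels) < n_required:
        return None
    window = list(labels)[-n_required:]
    counts = Counter(window)
    best = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == best}
    for lab in reversed(window):  # most recent occurrence among tied labels wins
        if lab in tied:
            return lab, best, best / n_required
    raise AssertionError("unreachable")


def toy_embedder(label_hint: str, dim: int = 16) -> np.ndarray:
    """Deterministic stand-in for a CNN embedding function.

    Hashes the hint into a unit vector; identical hints give identical
    embeddings, distinct hints are well separated with high probability.
    """
    digest = hashlib.sha256(label_hint.encode("utf-8")).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)
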