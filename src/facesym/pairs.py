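"""Bilateral landmark pairing for the 68-point facial annotation scheme.

The standard 68-point scheme (17 jaw, 10 eyebrow, 9 nose, 12 eye and 20
mouth points) contains 29 bilaterally paired landmarks per hemiface and 10
landmarks on the facial midline.  Asymmetry is measured per pair, so the
pair table is the central bookkeeping object: it fixes which landmark on
the left corresponds to which on the right, the facial region each pair
belongs to, and the 1..29 pair labels used in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PairTable", "default_pair_table", "REGION_COUNTS"]

#: Region name -> number of bilateral pairs in the default 68-point scheme.
REGION_COUNTS = {"face_edge": 8, "eyebrows": 5, "nostrils": 2, "eyes": 6, "mouth": 8}

_DEFAULT_PAIRS: tuple[tuple[int, int, str], ...] = (
    # face edge: jaw pairs, outermost -> innermost
    (0, 16, "face_edge"),
    (1, 15, "face_edge"),
    (2, 14, "face_edge"),
    (3, 13, "face_edge"),
    (4, 12, "face_edge"),
    (5, 11, "face_edge"),
    (6, 10, "face_edge"),
    (7, 9, "face_edge"),
    # eyebrows, outer -> inner
    (17, 26, "eyebrows"),
    (18, 25, "eyebrows"),
    (19, 24, "eyebrows"),
    (20, 23, "eyebrows"),
    (21, 22, "eyebrows"),
    # nostril flares
    (31, 35, "nostrils"),
    (32, 34, "nostrils"),
    # eyes
    (36, 45, "eyes"),
    (37, 44, "eyes"),
    (38, 43, "eyes"),
    (39, 42, "eyes"),
    (40, 47, "eyes"),
    (41, 46, "eyes"),
    # mouth, outer -> inner
    (48, 54, "mouth"),
    (49, 53, "mouth"),
    (50, 52, "mouth"),
    (59, 55, "mouth"),
    (58, 56, "mouth"),
    (60, 64, "mouth"),
    (61, 63, "mouth"),
    (65, 67, "mouth"),
)

_DEFAULT_MIDLINE: tuple[int, ...] = (8, 27, 28, 29, 30, 33, 51, 57, 62, 66)


@dataclass(frozen=True)
class PairTable:
    """Bilateral pairing of an n-landmark scheme.

    Parameters
    ----------
    pairs : list of (right_index, left_index)
        Ordered bilateral pairs; the order defines the pair labels 1..len(pairs).
    midline : tuple of int
        Indices of landmarks on the facial midline.
    regions : tuple of str
        Facial region of each pair, aligned with ``pairs``.
    n_landmarks : int
        Total landmark count of the scheme (pairs cover 2*len(pairs) indices,
        midline the rest).
    """

    pairs: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]
    regions: tuple[str, ...]
    n_landmarks: int = 68
    pair_labels: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        used = [i for p in self.pairs for i in p] + list(self.midline)
        if sorted(used) != list(range(self.n_landmarks)):
            raise ValueError(
                "pair table must partition landmark indices "
                f"0..{self.n_landmarks - 1} exactly"
            )
        if len(self.regions) != len(self.pairs):
            raise ValueError("one region per pair required")
        object.__setattr__(self, "pair_labels", tuple(range(1, len(self.pairs) + 1)))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def right_indices(self) -> np.ndarray:
        """Right-hemiface landmark indices, in pair-label order."""
        return np.array([r for r, _ in self.pairs], dtype=int)

    @property
    def left_indices(self) -> np.ndarray:
        """Left-hemiface landmark indices, in pair-label order."""
        return np.array([l for _, l in self.pairs], dtype=int)

    def swap_permutation(self) -> np.ndarray:
        """Index permutation exchanging each (right, left) pair.

        Applying this permutation to a mirrored landmark array restores the
        standard ordering: the reflected left landmark takes the right
        landmark's slot and vice versa; midline indices are fixed points.
        """
        perm = np.arange(self.n_landmarks)
        for r, l in self.pairs:
            perm[r], perm[l] = l, r
        return perm

    def region_of(self, label: int) -> str:
        """Facial region of pair ``label`` (1-based)."""
        return self.regions[label - 1]


def default_pair_table() -> PairTable:
    """The standard 68-point bilateral pairing.

    29 pairs grouped by facial region (face edge 8, eyebrows 5, nostrils 2,
    eyes 6, mouth 8) plus 10 midline landmarks; the 68 indices are covered
    exactly once.
    """
    return PairTable(
        pairs=tuple((r, l) for r, l, _ in _DEFAULT_PAIRS),
        midline=_DEFAULT_MIDLINE,
        regions=tuple(reg for _, _, reg in _DEFAULT_PAIRS),
        n_landmarks=68,
    )
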