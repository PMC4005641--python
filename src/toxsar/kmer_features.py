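"""k-mer descriptor vectors for short nucleotide sequences.

Every contiguous nucleotide motif of length ``kmin..kmax`` (default
2..5) defines one descriptor position; a sequence is encoded as the
ordered vector of its occurrence counts.  For the default range the
catalogue holds 16 + 64 + 256 + 1024 = 1360 motifs.  Occurrences are
counted with a sliding window, so overlapping matches all count: for a
14-mer the counts over all motifs of one length k always sum to
14 - k + 1 (13, 12, 11, 10 for k = 2..5; 46 in total), a conservation
law the tests lean on.

Ordering is length-major and lexicographic (A < C < G < T) within a
length, giving every motif a fixed, reproducible vector position.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gapmer_data import ALPHABET, Dataset

_BASES = "ACGT"


@dataclass(frozen=True)
class MotifIndex:
    """The ordered catalogue of all motifs of lengths ``kmin..kmax``."""

    kmin: int
    kmax: int
    motifs: tuple[str, ...]

    @property
    def position_of(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.motifs)}

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __contains__(self, motif: str) -> bool:
        return motif in self.position_of

    def index(self, motif: str) -> int:
        return self.position_of[motif]


def enumerate_motifs(kmin: int = 2, kmax: int = 5) -> MotifIndex:
    """Enumerate all A/C/G/T motifs of lengths kmin..kmax in canonical order.

    The catalogue size is sum(4**k for k in kmin..kmax); (2, 5) gives 1360.
    """
    if not 1 <= kmin <= kmax:
        raise ValueError(f"need 1 <= kmin <= kmax, got kmin={kmin}, kmax={kmax}")
    motifs = tuple(
        "".join(p) for k in range(kmin, kmax + 1) for p in product(_BASES, repeat=k)
    )
    return MotifIndex(kmin=kmin, kmax=kmax, motifs=motifs)


def _check_alphabet(seq: str, what: str) -> str:
    seq = str(seq).upper()
    bad = sorted({ch for ch in seq if ch not in ALPHABET})
    if bad:
        raise ValueError(f"{what} contains illegal characters {bad}")
    return seq


def count_occurrences(bases: str, motif: str) -> int:
    """Number of (possibly overlapping) occurrences of ``motif`` in ``bases``.

    Counts starting positions i with ``bases[i:i+len(motif)] == motif``;
    0 when the motif is longer than the sequence.
    """
    bases = _check_alphabet(bases, "sequence")
    motif = _check_alphabet(motif, "motif")
    if not motif:
        raise ValueError("motif must be non-empty")
    k = len(motif)
    return sum(1 for i in range(len(bases) - k + 1) if bases[i : i + k] == motif)


def motif_present(bases: str, motif: str) -> bool:
    """True iff the motif occurs at least once as a contiguous substring."""
    return count_occurrences(bases, motif) > 0


@dataclass
class FeatureMatrix:
    """Per-sequence occurrence-count vectors aligned to a MotifIndex.

    ``X[i, j]`` is the count of motif ``index.motifs[j]`` in sequence
    ``row_ids[i]``; ``y[i]`` is the toxicity label (True/False/None).
    """

    index: MotifIndex
    row_ids: tuple[str, ...]
    X: np.ndarray
    y: tuple[Optional[bool], ...]

    @property
    def p(self) -> int:
        """Number of descriptor columns."""
        return self.X.shape[1]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def presence(self) -> np.ndarray:
        """Boolean presence/absence matrix (counts > 0)."""
        return self.X > 0

    def labeled_mask(self) -> np.ndarray:
        return np.array([lab is not None for lab in self.y], dtype=bool)

    def labels_array(self) -> np.ndarray:
        """Boolean labels for labeled rows only (True = toxic)."""
        return np.array([lab for lab in self.y if lab is not None], dtype=bool)

    def subset_motifs(self, motifs: Sequence[str]) -> "FeatureMatrix":
        """Restrict columns to the given motifs (order as given)."""
        pos = self.index.position_of
        missing = [m for m in motifs if m not in pos]
        if missing:
            raise KeyError(f"motifs not in catalogue: {missing}")
        cols = [pos[m] for m in motifs]
        sub_index = MotifIndex(
            kmin=min(len(m) for m in motifs),
            kmax=max(len(m) for m in motifs),
            motifs=tuple(motifs),
        )
        return FeatureMatrix(
            index=sub_index, row_ids=self.row_ids, X=self.X[:, cols].copy(), y=self.y
        )

    def labeled(self) -> "FeatureMatrix":
        mask = self.labeled_mask()
        return FeatureMatrix(
            index=self.index,
            row_ids=tuple(r for r, keep in zip(self.row_ids, mask) if keep),
            X=self.X[mask],
            y=tuple(lab for lab in self.y if lab is not None),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, index=list(self.row_ids), columns=list(self.index.motifs))
        df.index.name = "id"
        return df


def featurize(
    dataset: Dataset,
    index: Optional[MotifIndex] = None,
    binarize: bool = False,
) -> FeatureMatrix:
    """Encode every record of a dataset as an ordered k-mer count vector.

    Row order follows dataset order; labels are copied through.  With
    ``binarize=True`` counts are clipped to presence/absence (0/1) —
    the count encoding is the default.
    """
    if index is None:
        index = enumerate_motifs(2, 5)
    pos = index.position_of
    n, p = len(dataset), len(index)
    X = np.zeros((n, p), dtype=np.int32)
    for i, rec in enumerate(dataset):
        seq = rec.bases
        L = len(seq)
        for k in range(index.kmin, index.kmax + 1):
            for start in range(L - k + 1):
                j = pos.get(seq[start : start + k])
                if j is not None:
                    X[i, j] += 1
    if binarize:
        X = (X > 0).astype(np.int32)
    return FeatureMatrix(
        index=index,
        row_ids=tuple(rec.id for rec in dataset),
        X=X,
        y=tuple(rec.toxic for rec in dataset),
    )
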