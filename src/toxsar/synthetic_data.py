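"""Synthetic labeled gapmer datasets with planted toxicity motifs.

The generator reproduces the statistical structure of the mouse
tolerability screen the analysis is built for: 51 toxic and 20
non-toxic 14-mer 3-8-3 gapmers, where a configurable fraction
(*penetrance*, default 27/51) of the toxic class carries at least one
planted motif (default TGC and/or TCC) and **no** non-toxic sequence
carries any.  The zero-carrier non-toxic class is a structural feature
of the data, not an approximation, so non-carriers are
rejection-sampled until motif-free.

What the generator does not emulate: real antisense 14-mers are
complementary to transcriptome regions chosen by a design workflow,
with its own composition biases; here non-carrier backgrounds are
i.i.d. letters (uniform by default, configurable per-letter
probabilities to study composition confounding).  Toxic non-carriers
are plain motif-free sequences — no attempt is made to plant the
unidentified "other" motifs that a real toxic class may share.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Optional

import numpy as np
import pandas as pd

from .gapmer_data import ALPHABET, DEFAULT_DESIGN, Dataset, GapmerRecord
from .kmer_features import motif_present

_BASES = "ACGT"


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters (defaults mirror the mouse screen)."""

    n_toxic: int = 51
    n_nontoxic: int = 20
    planted_motifs: tuple[str, ...] = ("TCC", "TGC")
    penetrance: float = 27 / 51
    seq_length: int = 14
    design: tuple[int, int, int] = DEFAULT_DESIGN
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.penetrance <= 1:
            raise ValueError(f"penetrance must be in [0, 1], got {self.penetrance}")
        if self.n_toxic < 0 or self.n_nontoxic < 0:
            raise ValueError("class sizes must be non-negative")
        if sum(self.design) != self.seq_length:
            raise ValueError(
                f"design {self.design} does not sum to seq_length {self.seq_length}"
            )
        motifs = tuple(sorted(m.upper() for m in self.planted_motifs))
        object.__setattr__(self, "planted_motifs", motifs)
        for m in motifs:
            if not m or any(ch not in ALPHABET for ch in m):
                raise ValueError(f"invalid planted motif {m!r}")
            if len(m) > self.seq_length:
                raise ValueError(f"planted motif {m!r} longer than seq_length")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1) > 1e-9:
            raise ValueError("base_composition must be 4 probabilities summing to 1")

    @property
    def n_carriers(self) -> int:
        return ceil(self.penetrance * self.n_toxic)


class GenerationError(RuntimeError):
    """Rejection sampling could not produce a motif-free sequence."""


def _random_sequence(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    letters = rng.choice(list(_BASES), size=spec.seq_length, p=spec.base_composition)
    return "".join(letters)


def _motif_free_sequence(
    rng: np.random.Generator, spec: SyntheticSpec, max_tries: int = 10_000
) -> str:
    for _ in range(max_tries):
        seq = _random_sequence(rng, spec)
        if not any(motif_present(seq, m) for m in spec.planted_motifs):
            return seq
    raise GenerationError(
        f"no motif-free {spec.seq_length}-mer found in {max_tries} draws; "
        f"planted motifs {spec.planted_motifs} are too dense for this length "
        f"or base composition"
    )


def generate(
    spec: SyntheticSpec = SyntheticSpec(), seed: Optional[int] = None
) -> tuple[Dataset, pd.DataFrame]:
    """Draw one labeled dataset plus ground-truth carrier annotations.

    Exactly ``n_toxic`` toxic and ``n_nontoxic`` non-toxic records are
    produced (toxic block first, ids ``tox-001..`` / ``ntx-001..``).  A
    seeded random subset of ceil(penetrance * n_toxic) toxic records
    each receives one planted motif, chosen uniformly, written at a
    uniform valid position into a motif-free background; every other
    record is rejection-sampled until it contains no planted motif.

    Returns the dataset and a truth table with columns id, toxic,
    carrier, planted_motif, planted_position.  Deterministic given
    (spec, seed); ``seed=None`` uses ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    carrier_idx = set(
        rng.choice(spec.n_toxic, size=spec.n_carriers, replace=False).tolist()
    ) if spec.n_toxic else set()

    records: list[GapmerRecord] = []
    truth_rows = []
    for i in range(spec.n_toxic):
        rid = f"tox-{i + 1:03d}"
        background = _motif_free_sequence(rng, spec)
        if i in carrier_idx:
            motif = spec.planted_motifs[rng.integers(0, len(spec.planted_motifs))]
            pos = int(rng.integers(0, spec.seq_length - len(motif) + 1))
            seq = background[:pos] + motif + background[pos + len(motif) :]
            truth_rows.append(
                {"id": rid, "toxic": True, "carrier": True,
                 "planted_motif": motif, "planted_position": pos}
            )
        else:
            seq = background
            truth_rows.append(
                {"id": rid, "toxic": True, "carrier": False,
                 "planted_motif": "", "planted_position": -1}
            )
        records.append(GapmerRecord(id=rid, bases=seq, design=spec.design, toxic=True))

    for i in range(spec.n_nontoxic):
        rid = f"ntx-{i + 1:03d}"
        seq = _motif_free_sequence(rng, spec)
        records.append(GapmerRecord(id=rid, bases=seq, design=spec.design, toxic=False))
        truth_rows.append(
            {"id": rid, "toxic": False, "carrier": False,
             "planted_motif": "", "planted_position": -1}
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["id", "toxic", "carrier", "planted_motif", "planted_position"],
    )
    return Dataset(records), truth


def shuffle_labels(dataset: Dataset, seed: int) -> Dataset:
    """Permute the toxicity labels uniformly, keeping class counts fixed.

    Sequences and record order are untouched; unlabeled records keep
    ``toxic=None``.  This is the null model for calibration checks:
    after shuffling, no motif is genuinely associated with the label.
    """
    rng = np.random.default_rng(seed)
    labeled_idx = [i for i, r in enumerate(dataset) if r.toxic is not None]
    labels = [dataset[i].toxic for i in labeled_idx]
    perm = rng.permutation(len(labels))
    shuffled = [labels[j] for j in perm]
    new_records = []
    it = iter(shuffled)
    for i, rec in enumerate(dataset):
        toxic = next(it) if rec.toxic is not None else None
        new_records.append(
            GapmerRecord(
                id=rec.id, bases=rec.bases, target=rec.target, design=rec.design,
                toxic=toxic, alt_u_per_l=rec.alt_u_per_l, ast_u_per_l=rec.ast_u_per_l,
                lesion_grades=rec.lesion_grades,
            )
        )
    return Dataset(new_records)
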