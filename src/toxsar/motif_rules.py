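"""Motif-presence toxicity rules and sequence-editing utilities.

The screening and forest analysis of 3-8-3 gapmers motivates a very
simple flag: if a sequence contains TGC and/or TCC, predict it
hepatotoxic.  In the originating dataset those two trinucleotides
occurred in 27 of 51 toxic sequences and in none of the 20 non-toxic
ones, independent of position and of LNA placement — so the rule is
pure any-of presence, unweighted and position-free.  The rule is a
flag-raiser, not an oracle: known exceptions exist in both directions
and evaluate_rule reports every mismatch rather than adjudicating it.

The editing utilities reproduce the wet-lab validation moves: write a
motif into a sequence at a chosen position, or remove every occurrence
of a motif by minimal single-base substitutions without creating new
occurrences of forbidden motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .gapmer_data import ALPHABET, DEFAULT_DESIGN, Dataset
from .kmer_features import motif_present
from .rf_model import Confusion

_BASES = "ACGT"

DEFAULT_RULE_MOTIFS = frozenset({"TGC", "TCC"})


@dataclass(frozen=True)
class MotifRule:
    """Any-of presence rule: predict toxic iff any motif occurs."""

    motifs: frozenset[str] = DEFAULT_RULE_MOTIFS

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("a motif rule needs at least one motif")
        object.__setattr__(self, "motifs", frozenset(m.upper() for m in self.motifs))
        for m in self.motifs:
            if not m or any(ch not in ALPHABET for ch in m):
                raise ValueError(f"invalid rule motif {m!r}")


@dataclass(frozen=True)
class RulePrediction:
    toxic: bool
    matches: tuple[tuple[str, int], ...]  # (motif, 0-based start), sorted

    @property
    def matched_motifs(self) -> list[str]:
        return sorted({m for m, _ in self.matches})


def _occurrences(bases: str, motif: str) -> list[int]:
    k = len(motif)
    return [i for i in range(len(bases) - k + 1) if bases[i : i + k] == motif]


def rule_predict(bases: str, rule: MotifRule = MotifRule()) -> RulePrediction:
    """Apply the presence rule to one sequence.

    Returns the predicted label and every (motif, start) match, so the
    caller can see *why* a sequence was flagged.
    """
    bases = str(bases).upper()
    matches = sorted(
        (motif, pos)
        for motif in sorted(rule.motifs)
        for pos in _occurrences(bases, motif)
    )
    return RulePrediction(toxic=bool(matches), matches=tuple(matches))


def evaluate_rule(
    dataset: Dataset, rule: MotifRule = MotifRule()
) -> tuple[Confusion, pd.DataFrame]:
    """Score the rule against known labels.

    Returns the confusion counts (toxic = positive class) and a
    per-sequence agreement table that lists each record's label, the
    rule's verdict, the matched motifs, and whether they agree.
    """
    labeled = dataset.labeled()
    if len(labeled) == 0:
        raise ValueError("evaluate_rule needs at least one labeled record")
    rows = []
    tp = fn = tn = fp = 0
    for rec in labeled:
        pred = rule_predict(rec.bases, rule)
        if rec.toxic and pred.toxic:
            tp += 1
        elif rec.toxic:
            fn += 1
        elif pred.toxic:
            fp += 1
        else:
            tn += 1
        rows.append(
            {
                "id": rec.id,
                "sequence": rec.bases,
                "label_toxic": rec.toxic,
                "rule_toxic": pred.toxic,
                "matched_motifs": ",".join(pred.matched_motifs),
                "agree": pred.toxic == rec.toxic,
            }
        )
    return Confusion(tp=tp, fn=fn, tn=tn, fp=fp), pd.DataFrame(rows)


@dataclass(frozen=True)
class EditReport:
    """Record of a sequence edit: per-position (index, before, after)."""

    original: str
    edited: str
    changes: tuple[tuple[int, str, str], ...]


def introduce_motif(bases: str, motif: str, position: int) -> EditReport:
    """Overwrite the window at ``position`` with ``motif``.

    Length is preserved; introducing a motif already present at that
    position is an identity edit (empty change list).
    """
    bases = str(bases).upper()
    motif = str(motif).upper()
    if any(ch not in ALPHABET for ch in motif) or not motif:
        raise ValueError(f"invalid motif {motif!r}")
    if not 0 <= position <= len(bases) - len(motif):
        raise ValueError(
            f"position {position} out of range for motif of length {len(motif)} "
            f"in a {len(bases)}-mer (valid: 0..{len(bases) - len(motif)})"
        )
    edited = bases[:position] + motif + bases[position + len(motif) :]
    changes = tuple(
        (position + i, bases[position + i], motif[i])
        for i in range(len(motif))
        if bases[position + i] != motif[i]
    )
    return EditReport(original=bases, edited=edited, changes=changes)


@dataclass(frozen=True)
class RemovalResult:
    success: bool
    report: Optional[EditReport]
    message: str


def _new_forbidden(candidate: str, original: str, forbidden: frozenset[str]) -> bool:
    """True if the candidate has a forbidden-motif occurrence at a
    position where the original sequence had none."""
    for m in forbidden:
        orig = set(_occurrences(original, m))
        if any(pos not in orig for pos in _occurrences(candidate, m)):
            return True
    return False


def _edit_positions(seq_len: int, design: tuple[int, int, int]) -> list[int]:
    """All indices ordered gap-first then leftmost (wings afterwards)."""
    w5, g, _ = design
    gap = list(range(w5, min(w5 + g, seq_len)))
    wings = [i for i in range(seq_len) if i not in set(gap)]
    return gap + wings


def remove_motif(
    bases: str,
    motif: str,
    forbidden: Sequence[str] | frozenset[str] = DEFAULT_RULE_MOTIFS,
    design: tuple[int, int, int] = DEFAULT_DESIGN,
    max_edits: int = 6,
) -> RemovalResult:
    """Eliminate every occurrence of ``motif`` by single-base substitutions.

    Finds a minimal set of substitutions (iterative deepening on the
    edit count) such that the result contains no occurrence of
    ``motif`` and no *newly created* occurrence of any motif in
    ``forbidden``.  Among equally small solutions, edits at DNA-gap
    positions are preferred over LNA-wing positions (so the wing
    composition stays intact), ties broken by leftmost position and
    then alphabetic replacement base — fully deterministic.

    A no-op with a warning when the motif is absent; a failure report
    when no edit set within ``max_edits`` satisfies the constraints.
    """
    original = str(bases).upper()
    motif = str(motif).upper()
    forbidden = frozenset(str(m).upper() for m in forbidden) | {motif}
    if not motif_present(original, motif):
        warnings.warn(f"motif {motif!r} not present; nothing to remove", stacklevel=2)
        return RemovalResult(True, EditReport(original, original, ()), "motif absent; no-op")

    pos_order = _edit_positions(len(original), design)

    def offending(seq: str) -> set[int]:
        """Positions covered by a target occurrence or a new forbidden one."""
        cover: set[int] = set()
        for start in _occurrences(seq, motif):
            cover.update(range(start, start + len(motif)))
        for m in forbidden:
            orig = set(_occurrences(original, m))
            for start in _occurrences(seq, m):
                if start not in orig:
                    cover.update(range(start, start + len(m)))
        return cover

    def search(seq: str, editable: list[int], budget: int) -> Optional[str]:
        bad = offending(seq)
        if not bad:
            return seq
        if budget == 0:
            return None
        for pos in editable:
            if pos not in bad:
                continue
            for base in _BASES:
                if base == seq[pos]:
                    continue
                cand = seq[:pos] + base + seq[pos + 1 :]
                hit = search(cand, [q for q in editable if q != pos], budget - 1)
                if hit is not None:
                    return hit
        return None

    for budget in range(1, max_edits + 1):
        solution = search(original, pos_order, budget)
        if solution is not None:
            changes = tuple(
                (i, original[i], solution[i])
                for i in range(len(original))
                if original[i] != solution[i]
            )
            return RemovalResult(
                True,
                EditReport(original=original, edited=solution, changes=changes),
                f"removed {motif} with {len(changes)} substitution(s)",
            )
    return RemovalResult(
        False,
        None,
        f"could not remove {motif!r} within {max_edits} substitutions "
        f"without creating a forbidden motif",
    )
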