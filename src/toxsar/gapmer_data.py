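"""Domain types, validation and I/O for annotated LNA-gapmer sequence sets.

A *gapmer* is a short single-stranded antisense oligonucleotide with a
central DNA core flanked by chemically modified "wings" (here LNA,
locked nucleic acid).  The default design is 3-8-3: three LNA
nucleotides, an eight-nucleotide DNA gap, three LNA nucleotides —
fourteen bases in total.  Each record carries the 5'->3' base sequence,
an optional binary hepatotoxicity label (liver lesions present in a
mouse tolerability study, or not) and optional clinical-chemistry
annotations (serum ALT/AST).

The chemical-modification pattern is deliberately *not* part of the
descriptor-relevant content: all sequences in a study share the same
design, so the design triple is carried as metadata only and never
feeds featurization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGT")
DEFAULT_DESIGN: tuple[int, int, int] = (3, 8, 3)

# accepted spellings for the binary lesion label, lower-cased
_TRUE_LABELS = {"toxic", "yes", "y", "true", "1"}
_FALSE_LABELS = {"non-toxic", "nontoxic", "non_toxic", "no", "n", "false", "0"}
_UNKNOWN_LABELS = {"", "na", "nan", "none", "unknown", "?"}


class GapmerValidationError(ValueError):
    """Raised when one or more sequence records violate their contract.

    Carries the full list of violations so callers see every problem,
    not just the first.
    """

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


def validate_gapmer(bases: str, design: tuple[int, int, int] = DEFAULT_DESIGN) -> list[str]:
    """Check a base string against a gapmer design; return all violations.

    Parameters
    ----------
    bases : str
        5'->3' nucleotide sequence, upper- or lower-case.
    design : (wing5, gap, wing3)
        Non-negative segment lengths; the sequence must have length
        ``wing5 + gap + wing3``.

    Returns
    -------
    list of str
        Empty when the sequence is valid.  Every violated constraint
        contributes one human-readable entry.
    """
    violations: list[str] = []
    if any(w < 0 for w in design):
        violations.append(f"design {design} has a negative segment length")
    expected = sum(design)
    seq = str(bases).upper()
    if len(seq) != expected:
        violations.append(
            f"sequence length {len(seq)} != {expected} required by design {design}"
        )
    bad = sorted({ch for ch in seq if ch not in ALPHABET})
    if bad:
        violations.append(f"illegal characters {bad} (alphabet is A/C/G/T)")
    return violations


def parse_label(value) -> Optional[bool]:
    """Map a file label onto True (toxic), False (non-toxic) or None (unknown)."""
    if value is None or (isinstance(value, bool)):
        return value
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if pd.isna(value):
            return None
        if value in (0, 1):
            return bool(value)
        raise GapmerValidationError([f"unrecognized toxicity label {value!r}"])
    text = str(value).strip().lower()
    if text in _TRUE_LABELS:
        return True
    if text in _FALSE_LABELS:
        return False
    if text in _UNKNOWN_LABELS:
        return None
    raise GapmerValidationError([f"unrecognized toxicity label {value!r}"])


@dataclass
class GapmerRecord:
    """One annotated antisense oligonucleotide.

    Attributes
    ----------
    id : str
        Short unique identifier (e.g. ``"1a"``, ``"4c"``).
    bases : str
        5'->3' base sequence over {A, C, G, T}.
    target : str
        Target gene name, or ``"None"`` for non-targeting controls.
    design : (wing5, gap, wing3)
        LNA wing / DNA gap lengths; metadata only.
    toxic : bool or None
        True = liver lesions observed, False = none, None = unknown
        (e.g. an untested candidate sequence).
    alt_u_per_l, ast_u_per_l : float or None
        Optional serum aminotransferase values, U/L.
    lesion_grades : mapping or None
        Optional free-text map lesion type -> severity grade.
    """

    id: str
    bases: str
    target: str = "None"
    design: tuple[int, int, int] = DEFAULT_DESIGN
    toxic: Optional[bool] = None
    alt_u_per_l: Optional[float] = None
    ast_u_per_l: Optional[float] = None
    lesion_grades: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        self.bases = str(self.bases).upper()
        self.design = tuple(int(w) for w in self.design)  # type: ignore[assignment]
        violations = validate_gapmer(self.bases, self.design)
        for name in ("alt_u_per_l", "ast_u_per_l"):
            v = getattr(self, name)
            if v is not None and v < 0:
                violations.append(f"{name} must be non-negative, got {v}")
        if violations:
            raise GapmerValidationError([f"record {self.id!r}: {v}" for v in violations])

    @property
    def gap_positions(self) -> range:
        """0-based indices of the central DNA gap."""
        w5, g, _ = self.design
        return range(w5, w5 + g)


@dataclass
class Dataset:
    """An ordered collection of gapmer records with unique ids."""

    records: list[GapmerRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dupes = []
        for rec in self.records:
            if rec.id in seen:
                dupes.append(rec.id)
            seen.add(rec.id)
        if dupes:
            raise GapmerValidationError([f"duplicate id {d!r}" for d in dupes])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GapmerRecord]:
        return iter(self.records)

    def __getitem__(self, key):
        if isinstance(key, str):
            for rec in self.records:
                if rec.id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]

    @property
    def n_toxic(self) -> int:
        return sum(1 for r in self.records if r.toxic is True)

    @property
    def n_nontoxic(self) -> int:
        return sum(1 for r in self.records if r.toxic is False)

    def labeled(self) -> "Dataset":
        """Subset with known toxicity labels, order preserved."""
        return Dataset([r for r in self.records if r.toxic is not None])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "id": r.id,
                    "target": r.target,
                    "sequence": r.bases,
                    "design": "-".join(str(w) for w in r.design),
                    "label": {True: "toxic", False: "non-toxic", None: ""}[r.toxic],
                    "alt": r.alt_u_per_l,
                    "ast": r.ast_u_per_l,
                }
            )
        return pd.DataFrame(rows, columns=["id", "target", "sequence", "design", "label", "alt", "ast"])


_COLUMN_ALIASES = {
    "id": {"id", "aso", "name", "compound"},
    "sequence": {"sequence", "seq", "bases", "sequence_5_3"},
    "target": {"target", "gene"},
    "label": {"label", "toxic", "lesions", "liver_lesions", "toxicity"},
    "alt": {"alt", "alt_u_per_l"},
    "ast": {"ast", "ast_u_per_l"},
}


def _resolve_columns(columns: Iterable[str]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for col in columns:
        key = str(col).strip().lower()
        for canonical, aliases in _COLUMN_ALIASES.items():
            if key in aliases and canonical not in mapping:
                mapping[canonical] = col
    return mapping


def _parse_design(text) -> tuple[int, int, int]:
    parts = [int(p) for p in str(text).replace(",", "-").split("-")]
    if len(parts) != 3:
        raise GapmerValidationError([f"design {text!r} is not a wing-gap-wing triple"])
    return tuple(parts)  # type: ignore[return-value]


def read_dataset(
    path: str | Path | IO[str],
    sep: Optional[str] = None,
    design: tuple[int, int, int] = DEFAULT_DESIGN,
) -> Dataset:
    """Read a delimited sequence table into a validated :class:`Dataset`.

    The file must have a header with at least id and sequence columns
    (several alias spellings accepted); target, label, alt, ast and
    design columns are optional.  Labels may be spelled
    toxic/non-toxic, yes/no, true/false or 1/0 in any case; rows with
    blank or unknown labels are retained with ``toxic=None``.

    ``sep=None`` sniffs comma vs tab from the header.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, skipinitialspace=True)
    cols = _resolve_columns(df.columns)
    missing = [c for c in ("id", "sequence") if c not in cols]
    if missing:
        raise GapmerValidationError(
            [f"required column {c!r} not found in header {list(df.columns)}" for c in missing]
        )

    records: list[GapmerRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        rid = str(row[cols["id"]]).strip()
        try:
            rec = GapmerRecord(
                id=rid,
                bases=str(row[cols["sequence"]]).strip(),
                target=str(row[cols["target"]]).strip() if "target" in cols and pd.notna(row[cols["target"]]) else "None",
                design=_parse_design(row[cols["design"]]) if "design" in cols and pd.notna(row.get(cols.get("design"))) else design,
                toxic=parse_label(row[cols["label"]]) if "label" in cols else None,
                alt_u_per_l=float(row[cols["alt"]]) if "alt" in cols and pd.notna(row[cols["alt"]]) and str(row[cols["alt"]]).strip() not in ("", "-") else None,
                ast_u_per_l=float(row[cols["ast"]]) if "ast" in cols and pd.notna(row[cols["ast"]]) and str(row[cols["ast"]]).strip() not in ("", "-") else None,
            )
        except GapmerValidationError as exc:
            errors.extend(f"row {i + 2} ({rid!r}): {v}" for v in exc.violations)
            continue
        records.append(rec)
    if errors:
        raise GapmerValidationError(errors)
    return Dataset(records)


def write_dataset(dataset: Dataset, path: str | Path | IO[str], sep: str = "\t") -> None:
    """Write the normalized dataset table (round-trips through read_dataset)."""
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def write_fasta(dataset: Dataset, path: str | Path | IO[str]) -> None:
    """Write one FASTA record per sequence, record id as header."""
    if len(dataset) == 0:
        warnings.warn("writing FASTA for an empty dataset", stacklevel=2)
    seq_records = [
        SeqRecord(Seq(rec.bases), id=rec.id, description="") for rec in dataset
    ]
    SeqIO.write(seq_records, path, "fasta")


def read_fasta(
    path: str | Path | IO[str],
    design: tuple[int, int, int] = DEFAULT_DESIGN,
) -> Dataset:
    """Read plain FASTA into an unlabeled Dataset (toxic=None throughout)."""
    records = [
        GapmerRecord(id=sr.id, bases=str(sr.seq), design=design)
        for sr in SeqIO.parse(path, "fasta")
    ]
    return Dataset(records)
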