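"""Chi-square association screening of motifs against toxicity labels.

Each motif is reduced to presence/absence per sequence and crossed
with the binary lesion label in a 2x2 contingency table.  The Pearson
chi-square statistic (no continuity correction, 1 df) screens the full
catalogue; motifs with raw p < alpha form the reduced descriptor set
passed to the forest.  Presence — not the occurrence count — drives the
association test, because carrier fractions ("present in 18 of 51
toxic sequences, never in a non-toxic one") are the quantity of
interest; the count vectors are kept for the classifier.

No multiple-testing correction is applied by default (the screen is a
filter, not an inference); Benjamini-Hochberg is available as an
option.  Motifs absent from every sequence (or present in all) have a
degenerate presence margin and are flagged untestable, never selected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gapmer_data import Dataset
from .kmer_features import FeatureMatrix, motif_present

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Motif-presence x toxicity counts.

    a: toxic with motif, b: toxic without, c: non-toxic with,
    d: non-toxic without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_toxic(self) -> int:
        return self.a + self.b

    @property
    def n_nontoxic(self) -> int:
        return self.c + self.d

    @property
    def n_with_motif(self) -> int:
        return self.a + self.c

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class ScreenResult:
    motif: str
    table: ContingencyTable2x2
    chi2: float
    p_value: float
    selected: bool
    testable: bool
    alpha: float


def build_contingency(motif: str, dataset: Dataset) -> ContingencyTable2x2:
    """Cross motif presence with the lesion label over labeled records."""
    labeled = dataset.labeled()
    n_tox = labeled.n_toxic
    n_non = labeled.n_nontoxic
    if n_tox == 0 or n_non == 0:
        raise ValueError(
            "association with toxicity is undefined: dataset must contain "
            f"labeled records of both classes (toxic={n_tox}, non-toxic={n_non})"
        )
    a = sum(1 for r in labeled if r.toxic and motif_present(r.bases, motif))
    c = sum(1 for r in labeled if not r.toxic and motif_present(r.bases, motif))
    return ContingencyTable2x2(a=a, b=n_tox - a, c=c, d=n_non - c)


def chi2_2x2(
    table: ContingencyTable2x2, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, closed form, 1 df.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); with the optional
    Yates correction |ad - bc| is shrunk by n/2 before squaring.  A
    degenerate presence margin (motif in none or in all sequences)
    yields chi2 = 0, p = 1.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    n = a + b + c + d
    if n <= 0:
        raise ValueError("empty contingency table")
    if table.n_toxic == 0 or table.n_nontoxic == 0:
        raise ValueError("both class margins must be positive")
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if continuity_correction:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff**2 / ((a + b) * (c + d) * col1 * col2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def expected_counts(table: ContingencyTable2x2) -> np.ndarray:
    """Expected cell counts under independence (row x column margins / n)."""
    obs = table.as_array()
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value (cross-check utility, not the screen)."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def permutation_pvalue(
    table: ContingencyTable2x2, n_perm: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo label-shuffle p-value for a 2x2 presence table.

    Reconstructs the carrier vector implied by the table, shuffles the
    class labels ``n_perm`` times with fixed class counts, and returns
    (p_hat, standard_error) for P(chi2_perm >= chi2_obs).  Serves as an
    independent check on the chi-square(1 df) tail approximation.
    """
    rng = np.random.default_rng(seed)
    n, n_tox = table.n, table.n_toxic
    carriers = np.zeros(n, dtype=bool)
    carriers[: table.n_with_motif] = True
    chi2_obs, _ = chi2_2x2(table)

    # one shuffled label vector per row; a = carriers among shuffled "toxic"
    labels = np.zeros((n_perm, n), dtype=bool)
    labels[:, :n_tox] = True
    labels = rng.permuted(labels, axis=1)
    a = labels[:, carriers].sum(axis=1).astype(float)
    c = table.n_with_motif - a
    b = n_tox - a
    d = (n - n_tox) - c
    col1, col2 = a + c, b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_perm = n * (a * d - b * c) ** 2 / (n_tox * (n - n_tox) * col1 * col2)
    chi2_perm = np.where((col1 == 0) | (col2 == 0), 0.0, chi2_perm)
    # >= with a small tolerance so the observed table counts itself
    p_hat = float(np.mean(chi2_perm >= chi2_obs - 1e-12))
    se = float(np.sqrt(max(p_hat * (1 - p_hat), 1e-30) / n_perm))
    return p_hat, se


def screen_motifs(
    feature_matrix: FeatureMatrix,
    alpha: float = 0.05,
    continuity_correction: bool = False,
    fdr_method: Optional[str] = None,
) -> list[ScreenResult]:
    """Chi-square screen of every motif in the catalogue.

    Returns one :class:`ScreenResult` per motif in catalogue order.
    Selection uses the raw p < alpha by default; ``fdr_method="bh"``
    switches to Benjamini-Hochberg adjusted p-values.  Untestable
    motifs (degenerate presence margin) are never selected.  A warning
    is logged when any testable motif has an expected cell below 5,
    where the chi-square approximation is rough.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    fm = feature_matrix.labeled()
    y = fm.labels_array()
    n_tox = int(y.sum())
    n_non = int((~y).sum())
    if n_tox == 0 or n_non == 0:
        raise ValueError(
            "screening requires labeled records of both classes "
            f"(toxic={n_tox}, non-toxic={n_non})"
        )
    P = fm.presence()
    a = P[y].sum(axis=0).astype(float)
    c = P[~y].sum(axis=0).astype(float)
    b = n_tox - a
    d = n_non - c
    n = float(n_tox + n_non)
    col1, col2 = a + c, b + d
    testable = (col1 > 0) & (col2 > 0)

    diff = np.abs(a * d - b * c)
    if continuity_correction:
        diff = np.maximum(diff - n / 2.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * diff**2 / (n_tox * n_non * col1 * col2)
    chi2 = np.where(testable, chi2, 0.0)
    p = np.where(testable, stats.chi2.sf(chi2, df=1), 1.0)

    p_eff = p.copy()
    if fdr_method is not None:
        if fdr_method.lower() not in {"bh", "fdr_bh", "benjamini-hochberg"}:
            raise ValueError(f"unknown fdr_method {fdr_method!r}")
        p_eff[testable] = stats.false_discovery_control(p[testable], method="bh")
    selected = testable & (p_eff < alpha)

    # chi-square approximation quality diagnostic
    exp_min = np.minimum.reduce(
        [
            (a + b) * col1 / n,
            (a + b) * col2 / n,
            (c + d) * col1 / n,
            (c + d) * col2 / n,
        ]
    )
    n_small = int(np.sum(testable & (exp_min < 5)))
    if n_small:
        logger.warning(
            "%d testable motifs have an expected cell count < 5; "
            "chi-square p-values are approximate there",
            n_small,
        )

    results = []
    for j, motif in enumerate(fm.index.motifs):
        results.append(
            ScreenResult(
                motif=motif,
                table=ContingencyTable2x2(int(a[j]), int(b[j]), int(c[j]), int(d[j])),
                chi2=float(chi2[j]),
                p_value=float(p[j]),
                selected=bool(selected[j]),
                testable=bool(testable[j]),
                alpha=alpha,
            )
        )
    return results


def selected_motifs(results: Sequence[ScreenResult]) -> list[str]:
    """Motifs passing the screen, in catalogue order."""
    return [r.motif for r in results if r.selected]


def screen_table(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Full screen report: motif, 2x2 counts, chi2, p, selected flag."""
    return pd.DataFrame(
        {
            "motif": [r.motif for r in results],
            "a_toxic_with": [r.table.a for r in results],
            "b_toxic_without": [r.table.b for r in results],
            "c_nontoxic_with": [r.table.c for r in results],
            "d_nontoxic_without": [r.table.d for r in results],
            "chi2": [r.chi2 for r in results],
            "p_value": [r.p_value for r in results],
            "testable": [r.testable for r in results],
            "selected": [r.selected for r in results],
        }
    )


def motif_distribution_table(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Carrier counts per selected motif, strongest association first.

    One row per selected motif with the number of toxic and non-toxic
    carrier sequences, ordered by chi-square descending (ties broken by
    motif string for determinism).
    """
    rows = sorted(
        (r for r in results if r.selected),
        key=lambda r: (-r.chi2, r.motif),
    )
    return pd.DataFrame(
        {
            "motif": [r.motif for r in rows],
            "toxic_with_motif": [r.table.a for r in rows],
            "nontoxic_with_motif": [r.table.c for r in rows],
            "chi2": [r.chi2 for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
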