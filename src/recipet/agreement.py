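"""Inter-rater agreement statistics and the dTTV threshold-sweep analysis.

Two delineation methods (e.g. a human reader and an automated one) yield
two binary progression calls per patient; their concordance is summarised
by a 2x2 confusion matrix, Cohen's chance-corrected kappa with the usual
interpretation bands, raw percent agreement, and Spearman correlation of
the underlying tumour volumes. The threshold sweep asks how prognostic a
simple dTTV dichotomisation is at a grid of cutoffs, with and without the
new-lesion requirement removed — each cutoff row carries a univariate Cox
fit (HR, 95% CI, p, C-index) and, when a second rater is supplied, the
kappa between the two raters' dichotomisations at that cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .recip import DeltaTTV
from .survival import (
    CoxDiagnosticError,
    CoxFit,
    SurvivalRecord,
    UndefinedStatisticError,
    cox_univariate,
)

__all__ = [
    "ConfusionMatrix2x2",
    "KappaResult",
    "SweepRow",
    "KAPPA_BANDS",
    "cohens_kappa",
    "kappa_band",
    "percent_agreement",
    "spearman_corr",
    "exceeds_cutoff",
    "threshold_sweep",
    "DEFAULT_CUTOFFS",
]

DEFAULT_CUTOFFS: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)

# Upper-inclusive interpretation bands for Cohen's kappa.
KAPPA_BANDS: tuple[tuple[float, str], ...] = (
    (0.20, "none-to-slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost-perfect"),
)


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts with rows = rater 1 (non-PD, PD), columns = rater 2.

    ``a`` both non-PD, ``b`` rater-1 non-PD / rater-2 PD, ``c`` rater-1 PD /
    rater-2 non-PD, ``d`` both PD.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.n == 0:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_flags(cls, rater1: Sequence[bool], rater2: Sequence[bool]) -> "ConfusionMatrix2x2":
        if len(rater1) != len(rater2):
            raise ValueError("raters must classify the same cases")
        r1 = np.asarray(rater1, dtype=bool)
        r2 = np.asarray(rater2, dtype=bool)
        return cls(
            a=int((~r1 & ~r2).sum()),
            b=int((~r1 & r2).sum()),
            c=int((r1 & ~r2).sum()),
            d=int((r1 & r2).sum()),
        )


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    band: str


def kappa_band(kappa: float) -> str:
    """Interpretation band; boundaries are inclusive on the upper end."""
    for upper, name in KAPPA_BANDS:
        if kappa <= upper:
            return name
    return KAPPA_BANDS[-1][1]


def cohens_kappa(m: ConfusionMatrix2x2) -> KappaResult:
    """Cohen's kappa = (po - pe)/(1 - pe) for the 2x2 table.

    With degenerate margins (pe = 1, both raters using a single class),
    kappa is 1 when agreement is perfect and undefined otherwise.
    """
    n = m.n
    po = (m.a + m.d) / n
    row1, row2 = (m.a + m.b) / n, (m.c + m.d) / n
    col1, col2 = (m.a + m.c) / n, (m.b + m.d) / n
    pe = row1 * col1 + row2 * col2
    if pe >= 1.0 - 1e-12:
        if po >= 1.0 - 1e-12:
            return KappaResult(1.0, kappa_band(1.0))
        raise UndefinedStatisticError(
            "kappa undefined: degenerate margins with disagreement"
        )
    kappa = (po - pe) / (1.0 - pe)
    return KappaResult(kappa, kappa_band(kappa))


def percent_agreement(m: ConfusionMatrix2x2) -> tuple[float, float | None, float | None]:
    """Overall and row-conditional agreement, in percent.

    Returns (overall, non-PD-row, PD-row); a row conditional is None when
    rater 1 never used that class.
    """
    overall = 100.0 * (m.a + m.d) / m.n
    row_nonpd = 100.0 * m.a / (m.a + m.b) if (m.a + m.b) else None
    row_pd = 100.0 * m.d / (m.c + m.d) if (m.c + m.d) else None
    return overall, row_nonpd, row_pd


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("Spearman correlation undefined for constant input")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def exceeds_cutoff(delta: DeltaTTV, cutoff_pct: float) -> bool:
    """Dichotomise a dTTV at a sweep cutoff.

    Cutoff 0 means "any TTV increase" (strict > 0); positive cutoffs are
    inclusive (>= cutoff). An undefined dTTV (lesions appearing from a
    lesion-free baseline) exceeds every cutoff.
    """
    if delta.undefined_flag:
        return True
    if cutoff_pct == 0:
        return delta.percent > 0.0
    return delta.percent >= cutoff_pct


@dataclass(frozen=True)
class SweepRow:
    cutoff_pct: float
    fit: CoxFit | None
    kappa: float | None
    n_exposed: int
    error: str | None = None


def threshold_sweep(
    deltas: Sequence[DeltaTTV],
    survival: Sequence[SurvivalRecord],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    second_rater_deltas: Sequence[DeltaTTV] | None = None,
) -> list[SweepRow]:
    """Prognostic value of dTTV dichotomisations at each cutoff.

    Per cutoff: exposure = dTTV exceeding the cutoff, a univariate Cox
    fit of that exposure against survival, and kappa between the two
    raters' exposures when a second rater's dTTVs are given. A Cox fit
    failure is recorded on its row without aborting the sweep.
    """
    if len(deltas) != len(survival):
        raise ValueError("need one dTTV per survival record")
    if second_rater_deltas is not None and len(second_rater_deltas) != len(deltas):
        raise ValueError("second rater must cover the same patients")

    rows: list[SweepRow] = []
    for cutoff in cutoffs:
        exposed = [exceeds_cutoff(d, cutoff) for d in deltas]
        records = [
            SurvivalRecord(r.time, r.event, float(e))
            for r, e in zip(survival, exposed)
        ]
        fit: CoxFit | None = None
        error: str | None = None
        try:
            fit = cox_univariate(records)
        except (CoxDiagnosticError, UndefinedStatisticError) as err:
            error = str(err)
        kappa: float | None = None
        if second_rater_deltas is not None:
            exposed2 = [exceeds_cutoff(d, cutoff) for d in second_rater_deltas]
            try:
                kappa = cohens_kappa(
                    ConfusionMatrix2x2.from_flags(exposed, exposed2)
                ).kappa
            except UndefinedStatisticError:
                kappa = None
        rows.append(
            SweepRow(
                cutoff_pct=float(cutoff),
                fit=fit,
                kappa=kappa,
                n_exposed=int(sum(exposed)),
                error=error,
            )
        )
    return rows
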