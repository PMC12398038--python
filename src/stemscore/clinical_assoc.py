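"""2×2 marker-by-clinical-parameter association statistics.

Markers (e.g. an IHC or ELISA readout dichotomized into low/high) are
crossed against binary clinicopathological parameters (stage I+II vs
III+IV, M0 vs M1, …) and tested with the uncorrected Pearson chi-square:

    chi2 = n (ad − bc)^2 / [(a+b)(c+d)(a+c)(b+d)],   df = 1.

No Yates continuity correction and no Fisher exact test are applied, even
at small expected counts: published LUAD marker tables of this layout
report uncorrected chi-square P-values (verifiable from their printed
counts), and the uncorrected statistic is the only one that reproduces
them.  Display P-values are rounded to 3 decimals, half-up, as such tables
print them; full precision is kept in machine-readable output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ClinicalTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "crosstab",
    "chi_square_2x2",
    "association_report",
    "round_half_up",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = clinical levels, cols = marker low/high."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("level1", "level2")
    col_labels: tuple[str, str] = ("low", "high")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValidationError("counts must be nonnegative integers")
        if self.n == 0:
            raise ValidationError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def margins(self) -> dict[str, int]:
        return {
            "row1": self.a + self.b,
            "row2": self.c + self.d,
            "col1": self.a + self.c,
            "col2": self.b + self.d,
        }


def crosstab(
    marker_level: pd.Series, clinical_level: pd.Series
) -> tuple[ContingencyTable2x2, int]:
    """Cross binary marker (low/high) against a binary clinical parameter.

    Samples missing either level are excluded; the count of exclusions is
    returned alongside the table.
    """
    joined = pd.DataFrame({"marker": marker_level, "clinical": clinical_level})
    n_missing = int(joined.isna().any(axis=1).sum())
    joined = joined.dropna()
    if joined.empty:
        raise ValidationError("no samples with both marker and clinical levels")
    if n_missing:
        logger.warning("excluded %d sample(s) with missing levels", n_missing)
    m_levels = sorted(map(str, pd.unique(joined["marker"].astype(str))))
    c_levels = sorted(map(str, pd.unique(joined["clinical"].astype(str))))
    if len(m_levels) > 2 or len(c_levels) > 2:
        raise ValidationError("both variables must be binary")
    # a binary variable observed at one level still defines a (degenerate) table
    m_levels = (m_levels + m_levels)[:2]
    c_levels = (c_levels + c_levels)[:2]
    m = joined["marker"].astype(str)
    c = joined["clinical"].astype(str)
    counts = [
        [int(((c == cl) & (m == ml)).sum()) for ml in m_levels[:2]]
        for cl in c_levels[:2]
    ]
    table = ContingencyTable2x2(
        a=counts[0][0],
        b=counts[0][1],
        c=counts[1][0],
        d=counts[1][1],
        row_labels=(c_levels[0], c_levels[1]),
        col_labels=(m_levels[0], m_levels[1]),
    )
    return table, n_missing


def chi_square_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Uncorrected Pearson chi-square (df = 1) and its upper-tail p."""
    a, b, c, d = table.a, table.b, table.c, table.d
    m = table.margins
    if min(m.values()) == 0:
        raise ValidationError("degenerate margin: chi-square undefined")
    chi2 = table.n * (a * d - b * c) ** 2 / (
        m["row1"] * m["row2"] * m["col1"] * m["col2"]
    )
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def round_half_up(x: float, decimals: int = 3) -> float:
    """Round half away from zero, matching printed-table conventions."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def association_report(
    clinical: ClinicalTable,
    marker_level: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One chi-square row per clinical parameter against the marker levels.

    Returns a frame with the 2×2 counts, chi2, full-precision p, a
    3-decimal display p, and a significance flag at ``alpha``.
    """
    records = []
    for param in clinical.data.columns:
        col = clinical.binary_column(param)
        table, n_missing = crosstab(marker_level, col)
        chi2, p = chi_square_2x2(table)
        records.append(
            {
                "parameter": param,
                "rows": f"{table.row_labels[0]}/{table.row_labels[1]}",
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "n_missing": n_missing,
                "chi2": chi2,
                "p": p,
                "p_display": round_half_up(p, 3),
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(records).set_index("parameter")
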