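"""2x2 contingency analysis of PAV status against gene attributes.

The core question: are presence/absence variants over-represented among
multi-copy genes, tandem-clustered genes, or any curated gene list? The
association is quantified with the df=1 chi-square statistic on the 2x2
table (Yates continuity correction on by default),

    chi2 = N (|ad - bc| - N/2)^2 / [(a+b)(c+d)(a+c)(b+d)],

together with the attribute rates within the PAV and non-PAV columns and
the PAV rate ratio between attribute-positive and attribute-negative
genes (e.g. "multi-copy genes are five times more likely to be PAV").
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (reporting convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def chisq_2x2(table, yates: bool = True) -> tuple[float, float]:
    """Chi-square statistic and p-value for a 2x2 table, df=1.

    ``table`` is [[a, b], [c, d]]. With ``yates=True`` the continuity
    correction N/2 is subtracted from |ad - bc| (floored at zero). A zero
    row or column margin leaves the statistic undefined and raises
    ``ValueError``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table cells must be non-negative")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined: zero row or column margin")
    num = abs(a * d - b * c)
    if yates:
        num = max(0.0, num - n / 2.0)
    chi2 = n * num**2 / np.prod(margins)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass
class ContingencyResult:
    """2x2 table with chi-square test and the field's standard proportions."""

    table: list[list[int]]  # rows: attribute +/-, cols: PAV +/-
    chi2: float
    p_value: float
    yates: bool
    #: attribute rate within the PAV and the non-PAV gene sets (%)
    attr_rate_in_pav: float
    attr_rate_in_nonpav: float
    #: PAV rate within the attribute-positive / -negative gene sets (%)
    pav_rate_in_attr: float
    pav_rate_in_nonattr: float
    rate_ratio: float  # PAV rate attr+ / attr-

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def crosstab(
    pav_genes: set[str], attribute_genes: set[str], universe: set[str],
    yates: bool = True,
) -> ContingencyResult:
    """Build the 2x2 table by set intersection and test for association.

    Rows are attribute +/-, columns PAV +/-. All percentages are reported
    to one decimal, rounded half-up.
    """
    pav_genes, attribute_genes, universe = (
        set(pav_genes), set(attribute_genes), set(universe),
    )
    for name, s in (("pav", pav_genes), ("attribute", attribute_genes)):
        outside = s - universe
        if outside:
            raise ValueError(
                f"{name} gene {sorted(outside)[0]!r} is outside the universe"
            )
    a = len(pav_genes & attribute_genes)  # attr+, PAV+
    b = len(attribute_genes) - a  # attr+, PAV-
    c = len(pav_genes) - a  # attr-, PAV+
    d = len(universe) - a - b - c  # attr-, PAV-
    return contingency_from_counts([[a, b], [c, d]], yates=yates)


def contingency_from_counts(table, yates: bool = True) -> ContingencyResult:
    """Fill a :class:`ContingencyResult` from a ready-made 2x2 table."""
    chi2, p = chisq_2x2(table, yates=yates)
    (a, b), (c, d) = (list(map(int, row)) for row in table)
    pct = lambda num, den: round_half_up(100.0 * num / den, 1) if den else float("nan")
    pav_rate_attr = pct(a, a + b)
    pav_rate_nonattr = pct(c, c + d)
    return ContingencyResult(
        table=[[a, b], [c, d]],
        chi2=chi2,
        p_value=p,
        yates=yates,
        attr_rate_in_pav=pct(a, a + c),
        attr_rate_in_nonpav=pct(b, b + d),
        pav_rate_in_attr=pav_rate_attr,
        pav_rate_in_nonattr=pav_rate_nonattr,
        rate_ratio=(
            float("nan")
            if pav_rate_nonattr == 0
            else (100.0 * a / (a + b)) / (100.0 * c / (c + d))
        ),
    )


def overlap_report(pav_genes: set[str], external_list: set[str]) -> float:
    """Percentage of an external gene list that is PAV: |PAV & list| / |list|."""
    external_list = set(external_list)
    if not external_list:
        raise ValueError("external list is empty")
    return round_half_up(
        100.0 * len(set(pav_genes) & external_list) / len(external_list), 1
    )


def validation_tabulation(records: pd.DataFrame) -> dict:
    """Confirmation rate from PCR-validation records.

    ``records`` needs columns ``gene`` and ``comment``; each distinct gene
    counts once as tested, and counts as refuted when any of its rows marks
    a false PAV. Returns tested / confirmed / false counts and the
    confirmation percentage.
    """
    genes = records["gene"].astype(str)
    false_mask = (
        records["comment"].fillna("").str.strip().str.lower() == "false pav"
    )
    tested = genes.nunique()
    false_genes = set(genes[false_mask])
    confirmed = tested - len(false_genes)
    return {
        "n_tested": int(tested),
        "n_confirmed": int(confirmed),
        "n_false": len(false_genes),
        "confirmation_rate_pct": round_half_up(100.0 * confirmed / tested, 0)
        if tested
        else float("nan"),
    }


def load_pcr_validation() -> pd.DataFrame:
    """Packaged PCR-validation records for 40 candidate PAV genes.

    Columns: gene, kind (p=partial / f=full), variety, gap_size_bp,
    gap_coords, comment. One row per (gene, variety) PCR assay.
    """
    from importlib.resources import files

    path = files("melopav.data").joinpath("pcr_validation.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)
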