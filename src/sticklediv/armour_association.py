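"""Pelvic/dorsal-spine association tests (the hybridization screen).

In a panmictic population polymorphic for both armour traits, pelvic girdle
and dorsal spine phenotypes are expected to vary independently (they are
largely controlled by unlinked genes in extant threespine stickleback).  A
significant association between a complete pelvis (pelvic score exactly 3)
and the fully armoured three-spine state in a mixed sample therefore
indicates restricted interbreeding between the high- and low-armoured forms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact

from .io_model import SpecimenTable

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "dichotomize_armour",
    "fisher_exact_2x2",
    "mixed_armour_frequencies",
]

DICHOTOMY_RULE = "full pelvis := pelvic_score == 3; high spines := dorsal_spine_count == 3"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Dichotomized armour counts.

    ``a``: full pelvis & three spines, ``b``: full pelvis & fewer,
    ``c``: reduced pelvis & three spines, ``d``: reduced pelvis & fewer.
    """

    a: int
    b: int
    c: int
    d: int
    dichotomy_rule: str = DICHOTOMY_RULE

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n < 1:
            raise ValueError("contingency table must contain at least one specimen")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def dichotomize_armour(table: SpecimenTable) -> ContingencyTable2x2:
    """Cross-classify specimens by pelvis (full = score exactly 3) and
    dorsal spines (three vs fewer).

    Specimens missing either armour value are excluded (and counted in a log
    line).  Scores such as 2.6 count as reduced.
    """
    df = table.data
    if df.empty:
        raise ValueError("empty specimen table")
    ps = df["pelvic_score"].to_numpy(dtype=float)
    dsc = df["dorsal_spine_count"].to_numpy(dtype=float)
    scored = ~np.isnan(ps) & ~np.isnan(dsc)
    n_dropped = int((~scored).sum())
    if n_dropped:
        logger.info("dichotomize_armour: %d specimen(s) missing armour values excluded", n_dropped)
    if not scored.any():
        raise ValueError("no specimens with both armour values scored")

    full = np.isclose(ps[scored], 3.0)
    three = np.isclose(dsc[scored], 3.0)
    return ContingencyTable2x2(
        a=int(np.sum(full & three)),
        b=int(np.sum(full & ~three)),
        c=int(np.sum(~full & three)),
        d=int(np.sum(~full & ~three)),
    )


def fisher_exact_2x2(t: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test.

    The two-sided p sums the hypergeometric probabilities (at the observed
    margins) of all tables at least as extreme — i.e. with point probability
    no greater than the observed table's.  Returns ``(p, odds_ratio)`` with
    the sample odds ratio ``(a*d)/(b*c)`` (infinite when only a zero
    denominator cell, NaN when 0/0).  A zero margin gives p = 1 by convention.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)

    margins = (a + b, c + d, a + c, b + d)
    if 0 in margins:
        logger.warning("fisher_exact_2x2: a margin is zero; p = 1 by convention")
        return 1.0, odds

    p = float(fisher_exact(t.as_array(), alternative="two-sided").pvalue)
    return p, odds


def mixed_armour_frequencies(table: SpecimenTable) -> dict[str, float]:
    """Frequencies of the two mixed armour phenotypes.

    Returns the proportion of scored specimens with a full pelvis but fewer
    than three dorsal spines, the proportion with three spines but a reduced
    pelvis, and the number of specimens scored.
    """
    df = table.data
    ps = df["pelvic_score"].to_numpy(dtype=float)
    dsc = df["dorsal_spine_count"].to_numpy(dtype=float)
    scored = ~np.isnan(ps) & ~np.isnan(dsc)
    if not scored.any():
        raise ValueError("no specimens with both armour values scored")
    full = np.isclose(ps[scored], 3.0)
    three = np.isclose(dsc[scored], 3.0)
    n = int(scored.sum())
    return {
        "prop_full_pelvis_reduced_spines": float(np.sum(full & ~three)) / n,
        "prop_three_spines_reduced_pelvis": float(np.sum(~full & three)) / n,
        "n": n,
    }
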