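"""Published summary statistics for the Miocene *Gasterosteus doryssus*
series-K lineage and the British Columbia benthic–limnetic species pairs.

These numbers come from the published study of the Truckee Formation fossil
stickleback sequence that this package's synthetic generator emulates. They
serve two purposes:

* calibration inputs for :mod:`sticklediv.synthetic_data` (trajectory
  endpoints, within-sample noise levels, per-trait sample sizes, per-lake
  divergence magnitudes), and
* cross-check values for the statistical machinery (e.g. the published
  U statistics and effect sizes must satisfy the CLES identity).

The within-sample standard deviations used by the generator are *derived*
here from the published mean difference and common-language effect size under
a normal shift model, because the published pooled-variance column is not
internally consistent with the rank statistics for every trait (it appears to
pool across temporal samples for some rows).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "PublishedTraitRow",
    "KSERIES_TRAIT_TESTS",
    "SPECIES_PAIR_MEAN_D",
    "FOSSIL_BOOT_D_MEAN",
    "FOSSIL_BOOT_D_SD",
    "ARMOUR_TABLE_D4",
    "ARMOUR_TABLE_L_REPLACEMENT",
    "MIXED_ARMOUR_COUNT",
    "MIXED_ARMOUR_TOTAL",
    "MEAN_TRAIT_CORRELATION",
    "N_SIGNIFICANT_TRAITS",
    "GENERATIONS_PER_YEAR",
    "derived_within_sample_sd",
]


@dataclass(frozen=True)
class PublishedTraitRow:
    """One row of the published first-vs-last trait comparison table."""

    code: str
    median_diff: float
    mean_diff: float  # last sample minus first sample, trait units
    pooled_variance: float
    n_first: int
    n_last: int
    u_statistic: float
    p_value: float  # printed to 3 decimals
    cles: float  # printed to 2 decimals


# First-vs-last comparison for the 18-sample fossil series (16 traits).
# Size-corrected lengths carry the ".sc" suffix and are in mm.
KSERIES_TRAIT_TESTS: tuple[PublishedTraitRow, ...] = (
    PublishedTraitRow("mds", -2.00, -1.96, 0.32, 42, 55, 2.50, 0.000, 0.00),
    PublishedTraitRow("lps.sc", -6.85, -6.81, 0.50, 42, 49, 0.00, 0.000, 0.00),
    PublishedTraitRow("tpg.sc", -7.68, -7.85, 135.0, 41, 49, 3.00, 0.000, 0.00),
    PublishedTraitRow("ds1.sc", -5.03, -4.88, 0.61, 31, 50, 0.00, 0.000, 0.00),
    PublishedTraitRow("ds3.sc", -1.46, -1.47, 0.37, 35, 54, 0.00, 0.000, 0.00),
    PublishedTraitRow("ds2.sc", -6.24, -5.93, 1.04, 40, 53, 28.0, 0.000, 0.01),
    PublishedTraitRow("lpt.sc", -1.12, -1.09, 0.39, 41, 47, 46.00, 0.000, 0.02),
    PublishedTraitRow("ect.sc", -1.49, -1.55, 0.82, 32, 46, 92.00, 0.000, 0.06),
    PublishedTraitRow("stl", -12.88, -14.45, 9.49, 43, 55, 318.50, 0.000, 0.13),
    PublishedTraitRow("mcv", -1.00, -1.01, 0.56, 42, 55, 321.00, 0.000, 0.14),
    PublishedTraitRow("mpt", -1.00, -0.77, 0.56, 39, 48, 346.00, 0.000, 0.18),
    PublishedTraitRow("pmx.sc", -0.34, -0.38, 0.33, 37, 41, 339.00, 0.000, 0.22),
    PublishedTraitRow("cle.sc", -0.80, -0.83, 0.78, 13, 31, 92.00, 0.005, 0.23),
    PublishedTraitRow("maf", 0.00, -0.31, 0.65, 43, 52, 840.50, 0.020, 0.38),
    PublishedTraitRow("mdf", 0.00, -0.14, 0.70, 43, 53, 1052.50, 0.473, 0.46),
    PublishedTraitRow("mav", 0.00, -0.02, 0.29, 31, 40, 612.00, 0.857, 0.49),
)

# Mean of the bootstrapped benthic-limnetic d per species-pair lake.
SPECIES_PAIR_MEAN_D: dict[str, float] = {
    "LittleQuarry": 26.9,
    "Enos": 18.6,
    "Paxton": 16.1,
    "Priest": 12.1,
    "Emily": 7.8,
}

# Bootstrap summary of first-vs-last fossil d.
FOSSIL_BOOT_D_MEAN = 19.9
FOSSIL_BOOT_D_SD = 1.3

# Armour contingency tables from samples where high- and low-armoured fish
# co-occur: (full pelvis & 3 spines, full pelvis & <3, reduced & 3, reduced & <3).
ARMOUR_TABLE_D4 = (7, 0, 0, 63)
ARMOUR_TABLE_L_REPLACEMENT = (26, 0, 0, 40)

# Mixed armour phenotypes in the 441 specimens preceding the replacement event.
MIXED_ARMOUR_COUNT = 14  # full pelvis, reduced dorsal spines
MIXED_ARMOUR_TOTAL = 441

# Reported correlated-trait-evolution and significance summaries.
MEAN_TRAIT_CORRELATION = 0.59
N_SIGNIFICANT_TRAITS = 12

# Stratigraphic years per stickleback generation used for unit conversion.
GENERATIONS_PER_YEAR = 0.5  # 2 years per generation

_CLES_CLIP = (0.0025, 0.4975)


def derived_within_sample_sd(row: PublishedTraitRow) -> float:
    """Within-sample s.d. implied by the published mean shift and CLES.

    Under a normal shift model with common s.d. sigma, the probability that a
    random last-sample individual exceeds a random first-sample individual is
    Phi(delta / (sigma * sqrt(2))).  Inverting with the printed CLES (clipped
    away from the 0.00/0.50 printing limits) gives sigma.  For the two rows
    with negligible mean shift the formula reduces to roughly the published
    pooled s.d., which is reassuring.
    """
    cles = min(max(row.cles, _CLES_CLIP[0]), _CLES_CLIP[1])
    z = norm.ppf(1.0 - cles)
    delta = abs(row.mean_diff)
    if delta == 0.0:
        # zero printed shift: fall back on the published variance column
        return math.sqrt(row.pooled_variance)
    return delta / (math.sqrt(2.0) * z)
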