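"""Outlier masking and allometric size correction.

Both steps run before any divergence statistic.  Outliers are screened once
(single pass, no iteration) against the dataset-level pooled mean and s.d. of
each trait — fossils pooled across temporal samples, extant fish pooled
across lakes — and flagged cells are set to missing.

Size correction removes the allometric component of each continuous trait:
a common (fixed) slope ``b`` on standard length with group-level random
intercepts is fitted per trait, and corrected values are
``observed - b * (stl - L_bar)`` with ``L_bar`` the grand mean standard
length, so corrected values stay in mm.  Count traits, which are fixed early
in development, and standard length itself pass through unchanged.  Fossil
and extant datasets are corrected separately (different allometries).  If the
mixed-model fit fails to converge, an ordinary least-squares fit with group
indicator intercepts is used instead (identical point estimates in balanced
designs); the fallback is logged and recorded on the model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .io_model import SpecimenTable

logger = logging.getLogger(__name__)

__all__ = [
    "OutlierFlag",
    "OutlierReport",
    "SizeCorrectionModel",
    "detect_outliers",
    "apply_outlier_mask",
    "fit_size_correction",
    "size_correct",
]

DEFAULT_THRESHOLD_SD = 3.5


@dataclass(frozen=True)
class OutlierFlag:
    specimen_id: str
    trait: str
    value: float
    z_score: float


@dataclass(frozen=True)
class OutlierReport:
    flagged: tuple[OutlierFlag, ...]
    threshold_sd: float
    pooling: str  # "fossil-pooled" | "extant-pooled" | "mixed-pooled"

    def __len__(self) -> int:
        return len(self.flagged)


def detect_outliers(
    table: SpecimenTable, threshold_sd: float = DEFAULT_THRESHOLD_SD
) -> OutlierReport:
    """Flag trait values more than ``threshold_sd`` pooled s.d. from the
    pooled mean.

    The pool is the whole dataset (the table is assumed to hold one dataset);
    the mean and s.d. include the candidate point.  Constant trait columns
    cannot yield flags (s.d. zero) and are logged.  A trait with no values at
    all raises.
    """
    datasets = set(table.data["dataset"].dropna().unique())
    pooling = f"{datasets.pop()}-pooled" if len(datasets) == 1 else "mixed-pooled"

    flags: list[OutlierFlag] = []
    for code in table.registry.codes:
        col = table.data[code].to_numpy(dtype=float)
        present = ~np.isnan(col)
        vals = col[present]
        if vals.size == 0:
            raise ValueError(f"trait {code!r} entirely missing; cannot screen outliers")
        if vals.size < 3:
            logger.warning("trait %s: fewer than 3 values; outlier screen skipped", code)
            continue
        sd = float(np.std(vals, ddof=1))
        if sd == 0.0:
            logger.warning("trait %s is constant; no outliers can be flagged", code)
            continue
        mean = float(np.mean(vals))
        z = (col - mean) / sd
        for idx in np.flatnonzero(present & (np.abs(z) > threshold_sd)):
            flags.append(
                OutlierFlag(
                    specimen_id=str(table.data["specimen_id"].iloc[idx]),
                    trait=code,
                    value=float(col[idx]),
                    z_score=float(z[idx]),
                )
            )
    return OutlierReport(tuple(flags), threshold_sd, pooling)


def apply_outlier_mask(table: SpecimenTable, report: OutlierReport) -> SpecimenTable:
    """Set every flagged cell to missing; all other cells are unchanged.

    Single pass: re-screening the masked table may flag new points, but the
    screen is deliberately not iterated.
    """
    out = table.copy()
    idx_by_id = pd.Series(out.data.index, index=out.data["specimen_id"].astype(str))
    n_masked = 0
    for flag in report.flagged:
        row = idx_by_id[flag.specimen_id]
        if not np.isnan(out.data.at[row, flag.trait]):
            n_masked += 1
        out.data.at[row, flag.trait] = np.nan
    logger.info("outlier mask: %d cell(s) set to missing", n_masked)
    out.provenance = (table.provenance + "; outlier-masked").lstrip("; ")
    return out


@dataclass(frozen=True)
class SizeCorrectionModel:
    """Per-trait common allometric slope with group intercepts."""

    slopes: dict[str, float]  # mm per mm of standard length
    slope_se: dict[str, float]
    intercepts: dict[str, dict[str, float]]
    grand_mean_sl: float  # L_bar, mm
    grouping: str
    traits: tuple[str, ...]
    method_used: dict[str, str] = field(default_factory=dict)  # mixed | ols


def _fit_one_trait(
    y: np.ndarray, stl: np.ndarray, groups: np.ndarray, code: str
) -> tuple[float, float, dict[str, float], str]:
    """Common slope + group intercepts, mixed model with OLS fallback."""
    within_var = (
        pd.DataFrame({"stl": stl, "g": groups}).groupby("g")["stl"].var(ddof=0).fillna(0.0)
    )
    if float(within_var.max()) < 1e-12:
        raise ValueError(
            f"size correction for trait {code!r} is singular: "
            "standard length has no within-group variation"
        )

    exog = sm.add_constant(stl)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("error", RuntimeWarning)
            model = sm.MixedLM(y, exog, groups=groups)
            fit = model.fit(reml=True)
        b = float(fit.fe_params[1])
        se = float(fit.bse_fe[1])
        if not (np.isfinite(b) and np.isfinite(se)):
            raise RuntimeError("non-finite mixed-model estimate")
        base = float(fit.fe_params[0])
        intercepts = {
            str(g): base + float(re.iloc[0] if hasattr(re, "iloc") else re[0])
            for g, re in fit.random_effects.items()
        }
        return b, se, intercepts, "mixed"
    except Exception as err:  # fall back to fixed group intercepts
        logger.info("mixed model for %s fell back to OLS (%s)", code, err)

    dummies = pd.get_dummies(pd.Series(groups), dtype=float)
    X = np.column_stack([stl, dummies.to_numpy()])
    fit = sm.OLS(y, X).fit()
    b = float(fit.params[0])
    se = float(fit.bse[0]) if np.isfinite(fit.bse[0]) else float("nan")
    intercepts = {
        str(g): float(fit.params[i + 1]) for i, g in enumerate(dummies.columns)
    }
    return b, se, intercepts, "ols"


def fit_size_correction(table: SpecimenTable, grouping: str = "group") -> SizeCorrectionModel:
    """Fit the per-trait allometric model on one dataset.

    Records missing either the trait or standard length are excluded from
    that trait's fit.  Requires at least two groups (the intercept structure
    is meaningless otherwise).
    """
    if grouping != "group":
        raise ValueError("grouping by the table's 'group' column is the only supported unit")
    df = table.data
    if df["group"].nunique() < 2:
        raise ValueError("size correction requires at least two groups")
    sl_code = table.registry.size_covariate
    stl_all = df[sl_code].to_numpy(dtype=float)
    if np.isnan(stl_all).all():
        raise ValueError("standard length entirely missing")
    grand_mean = float(np.nanmean(stl_all))

    slopes: dict[str, float] = {}
    slope_se: dict[str, float] = {}
    intercepts: dict[str, dict[str, float]] = {}
    method: dict[str, str] = {}
    traits = table.registry.size_corrected_codes
    for code in traits:
        y_all = df[code].to_numpy(dtype=float)
        keep = ~np.isnan(y_all) & ~np.isnan(stl_all)
        if keep.sum() < 3:
            raise ValueError(f"too few complete cases to size-correct trait {code!r}")
        b, se, icpt, meth = _fit_one_trait(
            y_all[keep], stl_all[keep], df["group"].to_numpy()[keep], code
        )
        slopes[code] = b
        slope_se[code] = se
        intercepts[code] = icpt
        method[code] = meth

    return SizeCorrectionModel(
        slopes=slopes,
        slope_se=slope_se,
        intercepts=intercepts,
        grand_mean_sl=grand_mean,
        grouping=grouping,
        traits=tuple(traits),
        method_used=method,
    )


def size_correct(table: SpecimenTable, model: SizeCorrectionModel) -> SpecimenTable:
    """Apply ``corrected = observed - b * (stl - L_bar)`` to covered traits.

    A record without standard length gets missing corrected values for the
    covered traits; counts and standard length pass through unchanged.
    """
    df = table.data.copy()
    sl_code = table.registry.size_covariate
    stl = df[sl_code].to_numpy(dtype=float)
    adj = stl - model.grand_mean_sl
    for code in model.traits:
        if code not in df.columns:
            raise KeyError(f"model covers trait {code!r} absent from table")
        vals = df[code].to_numpy(dtype=float)
        corrected = vals - model.slopes[code] * adj
        corrected[np.isnan(stl)] = np.nan
        df[code] = corrected
    return SpecimenTable(
        df,
        table.registry,
        provenance=(table.provenance + "; size-corrected").lstrip("; "),
        validate_positive=False,
    )
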