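import numpy as np
import pandas as pd
import pytest

from sticklediv.io_model import META_COLUMNS, SpecimenTable, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def make_table(registry):
    """Factory building a minimal SpecimenTable from per-group trait arrays.

    ``groups`` maps a group label to {trait_code: values}; traits not given
    are left missing (or set to ``fill`` when provided).  Extant dataset by
    default (no age bookkeeping).
    """

    def _make(
        groups: dict[str, dict[str, np.ndarray]],
        dataset: str = "extant",
        ages: dict[str, float] | None = None,
        pelvic: dict[str, np.ndarray] | None = None,
        spines: dict[str, np.ndarray] | None = None,
        validate_positive: bool = True,
        fill: float | None = None,
    ) -> SpecimenTable:
        frames = []
        sid = 0
        for order, (group, traits) in enumerate(groups.items(), start=1):
            n = len(next(iter(traits.values()))) if traits else len((pelvic or {})[group])
            trait_default = np.nan if fill is None else float(fill)
            df = pd.DataFrame({c: np.full(n, np.nan) for c in META_COLUMNS}
                              | {c: np.full(n, trait_default) for c in registry.codes})
            df["specimen_id"] = [f"s{sid + i}" for i in range(n)]
            df["dataset"] = dataset
            df["group"] = group
            if dataset == "fossil":
                df["sample_order"] = float(order)
                df["age_years"] = (ages or {}).get(group, float(order - 1) * 1000.0)
            for code, vals in traits.items():
                df[code] = np.asarray(vals, dtype=float)
            if pelvic is not None:
                df["pelvic_score"] = np.asarray(pelvic[group], dtype=float)
            if spines is not None:
                df["dorsal_spine_count"] = np.asarray(spines[group], dtype=float)
            frames.append(df)
            sid += n
        data = pd.concat(frames, ignore_index=True)
        return SpecimenTable(data, registry, validate_positive=validate_positive)

    return _make


# ---------------------------------------------------------------------------
# independent oracles


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided Fisher p: enumerate every table with the
    observed margins and sum the hypergeometric probabilities of tables no
    more probable than the observed one.  Exact integer arithmetic."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def weight(k: int) -> int:  # numerator of P(a = k)
        return comb(r1, k) * comb(r2, c1 - k)

    w_obs = weight(a)
    total = sum(
        w for k in range(max(0, c1 - r2), min(r1, c1) + 1) if (w := weight(k)) <= w_obs
    )
    return total / denom


def brute_force_u(first: np.ndarray, last: np.ndarray) -> float:
    """Pair-counting U: #{last_j > first_i} + half the ties."""
    u = 0.0
    for x in first:
        for y in last:
            if y > x:
                u += 1.0
            elif y == x:
                u += 0.5
    return u


def exact_rank_permutation_p(first: np.ndarray, last: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    from itertools import combinations

    pooled = np.concatenate([first, last])
    n1 = len(first)
    u_obs = brute_force_u(first, last)
    centre = n1 * len(last) / 2.0
    dev_obs = abs(u_obs - centre)
    idx = range(len(pooled))
    count = 0
    total = 0
    for first_idx in combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(first_idx)] = True
        u = brute_force_u(pooled[mask], pooled[~mask])
        if abs(u - centre) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total
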