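"""Dyadic resampling nulls with percentile confidence intervals.

Two null schemes, both reported with equal-tailed 95% and 99% percentile
intervals over (by default) 10,000 Monte-Carlo iterations:

* within-group: the observed mean for a dyad class (e.g. female-female)
  in one group is compared against means of equally many dyads drawn
  without replacement from *all* dyads of that group, irrespective of
  class — dyads are sampled as units, so an individual may appear in
  several sampled dyads;
* population-level: the observed grand mean (the mean over groups of each
  group's mean same-sex dyadic relatedness) is compared against simulated
  group sets in which each real group is replaced by the same number of
  same-sex individuals drawn from the population-wide pool (draws are
  independent across simulated groups within an iteration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .relatedness import RelatednessMatrix

__all__ = [
    "DyadicMatrix",
    "NullResult",
    "PopulationNullResult",
    "within_group_null",
    "within_group_nulls",
    "population_null",
    "summarize_significance",
]

DYAD_CLASSES = ("FF", "MM", "MF")


def dyad_class(sex_a: str, sex_b: str) -> str:
    key = "".join(sorted(sex_a + sex_b))
    return {"FF": "FF", "MM": "MM", "FM": "MF"}[key]


@dataclass
class DyadicMatrix:
    """Within-group dyadic values with FF/MM/MF class labels.

    Built from any long-format dyadic table (proximity scores or
    relatedness estimates restricted to co-resident dyads).
    """

    table: pd.DataFrame  # id1, id2, group, dyad_class, value

    @classmethod
    def from_long(cls, df: pd.DataFrame, sexes: Mapping[str, str],
                  groups: Mapping[str, str] | None = None,
                  value_col: str = "value") -> "DyadicMatrix":
        rows = []
        for rec in df.itertuples(index=False):
            a, b = rec.id1, rec.id2
            g = getattr(rec, "group", None)
            if g is None and groups is not None:
                if groups.get(a) != groups.get(b):
                    continue
                g = groups.get(a)
            rows.append((a, b, g, dyad_class(sexes[a], sexes[b]),
                         float(getattr(rec, value_col))))
        return cls(pd.DataFrame(rows, columns=["id1", "id2", "group",
                                               "dyad_class", "value"]))

    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def group_values(self, group: str) -> pd.DataFrame:
        return self.table[self.table["group"] == group]


@dataclass
class NullResult:
    """Within-group resampling outcome for one (group, dyad class)."""

    group: str
    dyad_class: str
    observed_mean: float
    n_class_dyads: int
    n_total_dyads: int
    iterations: int
    seed: int | None
    ci95: tuple[float, float]
    ci99: tuple[float, float]
    direction95: str   # above | below | inside
    direction99: str
    degenerate: bool = False

    def significant(self, level: int = 95) -> bool:
        return (self.direction95 if level == 95 else self.direction99) != "inside"


def _direction(observed: float, lo: float, hi: float) -> str:
    if observed > hi:
        return "above"
    if observed < lo:
        return "below"
    return "inside"


def _percentile_cis(sim_means: np.ndarray) -> tuple[tuple, tuple]:
    lo95, hi95 = np.percentile(sim_means, [2.5, 97.5])
    lo99, hi99 = np.percentile(sim_means, [0.5, 99.5])
    return (float(lo95), float(hi95)), (float(lo99), float(hi99))


def within_group_null(matrix: DyadicMatrix, group: str, target_class: str,
                      iterations: int = 10_000,
                      seed: int | None = None) -> NullResult | None:
    """Resample one group's dyads against one dyad class.

    Returns None when the group has no dyad of the target class (the "-"
    cells of the reporting table).  A group with a single dyad yields a
    degenerate interval and is flagged.
    """
    sub = matrix.group_values(group)
    values = sub["value"].to_numpy(dtype=float)
    classes = sub["dyad_class"].to_numpy()
    n_total = len(values)
    mask = classes == target_class
    n_class = int(mask.sum())
    if n_class == 0:
        return None
    observed = float(values[mask].mean())
    rng = np.random.default_rng(seed)
    # each iteration draws n_class distinct dyads (as units) from all dyads
    order = np.argsort(rng.random((iterations, n_total)), axis=1)[:, :n_class]
    sim_means = values[order].mean(axis=1)
    ci95, ci99 = _percentile_cis(sim_means)
    return NullResult(
        group=group, dyad_class=target_class, observed_mean=observed,
        n_class_dyads=n_class, n_total_dyads=n_total, iterations=iterations,
        seed=seed, ci95=ci95, ci99=ci99,
        direction95=_direction(observed, *ci95),
        direction99=_direction(observed, *ci99),
        degenerate=n_total == 1,
    )


def within_group_nulls(matrix: DyadicMatrix, iterations: int = 10_000,
                       seed: int | None = None,
                       classes: Sequence[str] = DYAD_CLASSES) -> list[NullResult]:
    """Run the within-group null for every group and requested dyad class."""
    rng = np.random.default_rng(seed)
    out = []
    for group in matrix.groups():
        for cls in classes:
            sub_seed = None if seed is None else int(rng.integers(2**31 - 1))
            res = within_group_null(matrix, group, cls, iterations, sub_seed)
            if res is not None:
                out.append(res)
    return out


@dataclass
class PopulationNullResult:
    """Population-level resampling outcome for one sex."""

    sex: str
    observed_grand_mean: float
    group_sizes: dict[str, int]
    iterations: int
    seed: int | None
    ci95: tuple[float, float]
    ci99: tuple[float, float]
    direction95: str
    direction99: str


def population_null(rmat: RelatednessMatrix, groups: Mapping[str, str],
                    sexes: Mapping[str, str], sex: str,
                    iterations: int = 10_000, seed: int | None = None,
                    min_group_size: int = 2) -> PopulationNullResult:
    """Compare average within-group same-sex R against random groups.

    The observed statistic is the mean across groups of each group's mean
    same-sex dyadic R.  Each iteration replaces every real group with the
    same number of individuals of that sex drawn without replacement from
    the pooled population, and records the same grand mean.
    """
    pool = sorted(i for i in rmat.ids if sexes.get(i) == sex and i in groups)
    by_group: dict[str, list[str]] = {}
    for i in pool:
        by_group.setdefault(groups[i], []).append(i)
    sizes = {g: len(m) for g, m in sorted(by_group.items())
             if len(m) >= min_group_size}
    if len(sizes) < 2:
        raise ValueError(f"need >= 2 groups with >= {min_group_size} "
                         f"individuals of sex {sex!r}")
    if max(sizes.values()) > len(pool):
        raise ValueError("group larger than the population pool")

    observed = float(np.mean([rmat.submatrix_mean(by_group[g]) for g in sizes]))

    rows = np.array([rmat._row[i] for i in pool])
    R = rmat.r[np.ix_(rows, rows)]
    n_pool = len(pool)
    rng = np.random.default_rng(seed)
    sim = np.empty(iterations)
    triu_cache = {k: np.triu_indices(k, 1) for k in set(sizes.values())}
    for it in range(iterations):
        means = []
        for g, k in sizes.items():
            draw = rng.choice(n_pool, size=k, replace=False)
            sub = R[np.ix_(draw, draw)][triu_cache[k]]
            sub = sub[~np.isnan(sub)]
            means.append(sub.mean() if sub.size else np.nan)
        sim[it] = np.nanmean(means)
    ci95, ci99 = _percentile_cis(sim)
    return PopulationNullResult(
        sex=sex, observed_grand_mean=observed, group_sizes=sizes,
        iterations=iterations, seed=seed, ci95=ci95, ci99=ci99,
        direction95=_direction(observed, *ci95),
        direction99=_direction(observed, *ci99),
    )


def summarize_significance(results: Sequence[NullResult]) -> pd.DataFrame:
    """Tabulate resampling outcomes with significance flags.

    One row per (group, dyad class): observed mean, the four CI bounds,
    and flags at the 95% and 99% confidence levels with direction
    ('*' = outside the 95% interval, '**' = outside the 99% interval).
    """
    rows = []
    for r in results:
        flag = ""
        if r.direction99 != "inside":
            flag = "**"
        elif r.direction95 != "inside":
            flag = "*"
        rows.append({
            "group": r.group, "dyad_class": r.dyad_class,
            "observed_mean": r.observed_mean,
            "n_class_dyads": r.n_class_dyads,
            "ci99_lower": r.ci99[0], "ci95_lower": r.ci95[0],
            "ci95_upper": r.ci95[1], "ci99_upper": r.ci99[1],
            "direction95": r.direction95, "direction99": r.direction99,
            "flag": flag,
        })
    return pd.DataFrame(rows)
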