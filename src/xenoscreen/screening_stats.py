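"""Screen-level statistics: toxicity brackets and group comparisons.

The 48-h dose-survival table (compound x concentration, % survival of
normal larvae) is reduced to LD50 *brackets* — the interval between tested
concentrations within which survival crosses 50% — matching how such
screens report toxicity (">10 uM", "0.5 uM ~ 1 uM"); no interpolation is
performed.  The working concentration for the xenograft assay is the
highest tested concentration at which every compound still shows 100%
survival.

Group effects on proliferation or migration are tested with Student's
(pooled-variance) t-test for two groups and one-way ANOVA followed by
Dunnett's many-to-one comparisons against the untreated control for more,
with mean +/- SEM summaries throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ToxicityTable",
    "LD50Bracket",
    "GroupComparison",
    "ld50_bracket",
    "max_safe_concentration",
    "two_sample_t",
    "anova_dunnett",
    "group_summary",
]


@dataclass
class ToxicityTable:
    """Mean % survival per compound across an increasing concentration grid."""

    compounds: list[str]
    concentrations_um: np.ndarray
    survival_pct: np.ndarray  # shape (n_compounds, n_concentrations)

    def __post_init__(self) -> None:
        self.concentrations_um = np.asarray(self.concentrations_um, dtype=float)
        self.survival_pct = np.asarray(self.survival_pct, dtype=float)
        if np.any(np.diff(self.concentrations_um) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.survival_pct.shape != (len(self.compounds), self.concentrations_um.size):
            raise ValueError("survival_pct shape must be (n_compounds, n_concentrations)")
        if np.any((self.survival_pct < 0) | (self.survival_pct > 100)):
            raise ValueError("survival must lie in [0, 100]")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ToxicityTable":
        """Build from a wide table: first column = compound, remaining column
        names parse as concentrations in µM.  A malformed cell raises an
        error naming the compound and concentration."""
        compounds = df.iloc[:, 0].astype(str).tolist()
        try:
            conc = np.array([float(c) for c in df.columns[1:]])
        except ValueError as e:
            raise ValueError(f"concentration column names must be numeric: {e}") from e
        order = np.argsort(conc)
        values = np.empty((len(compounds), conc.size))
        for i, compound in enumerate(compounds):
            for j, col in enumerate(df.columns[1:]):
                try:
                    values[i, j] = float(df.iloc[i, j + 1])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"invalid survival value at (compound={compound!r}, "
                        f"concentration={col} uM): {df.iloc[i, j + 1]!r}"
                    ) from None
        return cls(compounds, conc[order], values[:, order])

    @classmethod
    def from_csv(cls, path) -> "ToxicityTable":
        return cls.from_dataframe(pd.read_csv(path))

    def row(self, compound: str) -> np.ndarray:
        return self.survival_pct[self.compounds.index(compound)]


@dataclass
class LD50Bracket:
    """Bracketing interval for the median lethal dose of one compound.

    ``lower_um`` is the highest tested concentration with survival >= 50%
    (0 if survival is below 50% already at the lowest dose); ``upper_um`` is
    the lowest tested concentration with survival < 50% (inf if survival
    never drops below 50%, i.e. "LD50 > highest tested").
    """

    compound: str
    lower_um: float
    upper_um: float

    def __post_init__(self) -> None:
        if not self.lower_um < self.upper_um:
            raise ValueError("bracket must satisfy lower < upper")


def ld50_bracket(
    compound: str, concentrations_um, survival_pct, threshold: float = 50.0
) -> LD50Bracket:
    """Bracket the LD50 between tested concentrations at the first crossing.

    Survival that recovers above threshold at a higher dose (non-monotone
    row) triggers a warning; the bracket is still taken from the first
    downward crossing.
    """
    conc = np.asarray(concentrations_um, dtype=float)
    surv = np.asarray(survival_pct, dtype=float)
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    below = surv < threshold
    if not below.any():
        return LD50Bracket(compound, float(conc[-1]), math.inf)
    first = int(np.argmax(below))
    if below[first:].size and not below[first:].all():
        warnings.warn(
            f"{compound}: survival recovers above {threshold}% at a higher dose; "
            "bracketing at the first crossing",
            stacklevel=2,
        )
    lower = float(conc[first - 1]) if first > 0 else 0.0
    return LD50Bracket(compound, lower, float(conc[first]))


def max_safe_concentration(table: ToxicityTable) -> float:
    """Highest tested concentration with 100% survival for every compound.

    This is the automated version of the screen's working-concentration
    choice: the dose at which no compound shows overt toxicity.
    """
    if not table.compounds:
        raise ValueError("toxicity table is empty")
    all_safe = (table.survival_pct == 100.0).all(axis=0)
    if not all_safe.any():
        raise ValueError("no common safe concentration: every tested dose kills for some compound")
    return float(table.concentrations_um[np.nonzero(all_safe)[0].max()])


def two_sample_t(a, b) -> tuple[float, float]:
    """Classic pooled-variance (Student's) two-sample t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def group_summary(values) -> tuple[float, float | None]:
    """Mean and SEM (SD/sqrt(n)); SEM is None for a single observation."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty group")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else None
    return mean, sem


def _stars(p: float) -> str:
    return "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class GroupComparison:
    """One-way ANOVA with Dunnett many-to-one comparisons vs a control.

    ``adjusted_p`` are two-sided family-wise adjusted p-values from the
    equicorrelated multivariate-t distribution of the maximum |t|;
    significance stars mark 0.05 (*) and 0.01 (**).
    """

    groups: dict[str, np.ndarray]
    control: str
    statistic: float  # ANOVA F
    p: float  # ANOVA p
    comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)
    alpha: float = 0.05

    @property
    def means(self) -> dict[str, float]:
        return {g: float(np.mean(v)) for g, v in self.groups.items()}

    @property
    def sems(self) -> dict[str, float | None]:
        return {g: group_summary(v)[1] for g, v in self.groups.items()}

    def summary(self) -> pd.DataFrame:
        """Per-group table: n, mean, SEM, and for non-control groups the
        Dunnett statistic, raw and adjusted p, and significance stars."""
        rows = []
        for g, v in self.groups.items():
            mean, sem = group_summary(v)
            row = {"group": g, "n": len(v), "mean": mean, "sem": sem}
            if g != self.control:
                c = self.comparisons.set_index("group").loc[g]
                row.update(
                    statistic=c["statistic"],
                    p_raw=c["p_raw"],
                    p_adjusted=c["p_adjusted"],
                    significance=c["significance"],
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        head = f"One-way ANOVA: F = {self.statistic:.4g}, p = {self.p:.4g} (control: {self.control})"
        return head + "\n" + self.summary().to_string(index=False)


def anova_dunnett(
    groups: dict[str, "np.ndarray"], control: str, alpha: float = 0.05, seed: int | None = 0
) -> GroupComparison:
    """One-way ANOVA F-test plus Dunnett's test of every group vs control.

    Adjusted p-values come from the multivariate-t distribution of the
    maximum |t_i| (two-sided); raw per-comparison p-values use the same
    pooled error with N - k degrees of freedom.  ``seed`` fixes the
    quasi-random integration of the multivariate-t CDF so repeated calls
    are reproducible.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} not among groups")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if any(v.size < 2 for v in arrays.values()):
        raise ValueError("each group needs n >= 2")
    if all(v.var(ddof=1) == 0 for v in arrays.values()):
        raise ValueError("zero within-group variance in every group")

    f_stat, f_p = stats.f_oneway(*arrays.values())
    treatment_names = [g for g in arrays if g != control]
    res = stats.dunnett(
        *(arrays[g] for g in treatment_names),
        control=arrays[control],
        alternative="two-sided",
        rng=seed,
    )
    n_total = sum(v.size for v in arrays.values())
    df = n_total - len(arrays)
    p_raw = 2.0 * stats.t.sf(np.abs(res.statistic), df)
    # family-wise adjustment can never fall below the per-comparison p
    p_adj = np.maximum(res.pvalue, p_raw)
    comparisons = pd.DataFrame(
        {
            "group": treatment_names,
            "statistic": res.statistic,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "significance": [_stars(p) for p in p_adj],
        }
    )
    return GroupComparison(arrays, control, float(f_stat), float(f_p), comparisons, alpha)
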