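"""Normality-gated group comparisons for colony, densitometry and qPCR tables.

Four comparison families are implemented, each gated the same way: Shapiro-
Wilk is run per group and the parametric branch is taken only if every group
passes at alpha (homoscedasticity is additionally checked with Brown-Forsythe
and reported).

* within-treatment sections: one-way ANOVA + Tukey HSD on all section pairs,
  or Kruskal-Wallis + Dunn on the nonparametric branch;
* treatments vs vehicle: one-way ANOVA + Dunnett against the vehicle control,
  or Kruskal-Wallis + Dunn restricted to vehicle contrasts;
* randomized-block ANOVA (one- or two-factor conditions, biological replicate
  as an additive block) with uncorrected Fisher's LSD on preselected pairs;
* paired expression: ratio paired t test (a paired t on log ratios), or the
  Wilcoxon matched-pairs signed-rank test.

Dunn's z tests are tie-corrected and reported two-sided; by default no
family-wise correction is applied to them (a Bonferroni option exists).
Zero-variance inputs short-circuit to a flagged "no-test" result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stack_io import SECTIONS
from .spatial import ColonyRecord

_MIN_N_SHAPIRO = 3


@dataclass
class StatConfig:
    """Decision-tree settings: significance level and Dunn correction."""

    alpha: float = 0.05
    dunn_correction: str | None = None  # None | "bonferroni"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.dunn_correction not in (None, "bonferroni"):
            raise ValueError(f"unknown dunn_correction {self.dunn_correction!r}")


@dataclass
class Comparison:
    group_a: str
    group_b: str
    estimate: float  # difference (or log-ratio mean) a - b on the test's scale
    statistic: float
    p: float
    p_adjusted: float | None
    method: str

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "estimate": self.estimate,
            "statistic": self.statistic,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "method": self.method,
        }


@dataclass
class StatResult:
    """Outcome of one gated comparison family."""

    family: str
    branch: str  # "parametric" | "nonparametric" | "none"
    normality_ps: Mapping[str, float]
    homoscedasticity_p: float | None
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    comparisons: list[Comparison]
    n_per_group: Mapping[str, int]
    flags: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def comparison(self, a: str, b: str) -> Comparison:
        for c in self.comparisons:
            if {c.group_a, c.group_b} == {a, b}:
                return c
        raise KeyError(f"no comparison between {a!r} and {b!r}")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "branch": self.branch,
            "normality_ps": dict(self.normality_ps),
            "homoscedasticity_p": self.homoscedasticity_p,
            "omnibus_test": self.omnibus_test,
            "omnibus_stat": self.omnibus_stat,
            "omnibus_p": self.omnibus_p,
            "comparisons": [c.to_dict() for c in self.comparisons],
            "n_per_group": dict(self.n_per_group),
            "flags": list(self.flags),
        }

    def to_rows(self) -> list[dict]:
        base = {
            "family": self.family,
            "branch": self.branch,
            "omnibus_test": self.omnibus_test,
            "omnibus_stat": self.omnibus_stat,
            "omnibus_p": self.omnibus_p,
            "homoscedasticity_p": self.homoscedasticity_p,
            "flags": ";".join(self.flags),
        }
        if not self.comparisons:
            return [dict(base, group_a="", group_b="", estimate=np.nan, p=np.nan,
                         p_adjusted=np.nan, method="")]
        return [dict(base, **c.to_dict()) for c in self.comparisons]


# -- gate helpers ----------------------------------------------------------------


def _normality_gate(groups: Mapping[str, np.ndarray], alpha: float):
    """Shapiro-Wilk per group; returns (all_passed, per-group p-values, flags)."""
    ps: dict[str, float] = {}
    flags: list[str] = []
    passed = True
    for name, vals in groups.items():
        if len(vals) < _MIN_N_SHAPIRO or np.ptp(vals) == 0:
            ps[name] = float("nan")
            flags.append(f"normality_untestable:{name}")
            continue
        ps[name] = float(sps.shapiro(vals).pvalue)
        if ps[name] < alpha:
            passed = False
    return passed, ps, flags


def _brown_forsythe(groups: Sequence[np.ndarray]) -> float | None:
    """Levene's test with median centring (Brown-Forsythe)."""
    usable = [g for g in groups if len(g) >= 2]
    if len(usable) < 2 or all(np.ptp(g) == 0 for g in usable):
        return None
    return float(sps.levene(*usable, center="median").pvalue)


def dunn_test(
    groups: Mapping[str, np.ndarray],
    pairs: Sequence[tuple[str, str]],
    correction: str | None = None,
) -> list[Comparison]:
    """Dunn's rank-sum z tests on the given pairs, with tie correction.

    Ranks the pooled data once; for a pair (i, j) the statistic is
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))`` where
    ``T = sum(t^3 - t) / (12 (N - 1))`` corrects for ties.  Two-sided normal
    p-values; Bonferroni over the tested pairs if requested.
    """
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for n in names:
        k = len(groups[n])
        mean_ranks[n] = float(ranks[start:start + k].mean())
        sizes[n] = k
        start += k
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1))) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    out = []
    m = len(pairs)
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        diff = mean_ranks[a] - mean_ranks[b]
        z = diff / se if se > 0 else 0.0
        p = float(2.0 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, p * m) if correction == "bonferroni" else None
        out.append(Comparison(a, b, estimate=diff, statistic=z, p=p,
                              p_adjusted=p_adj, method="dunn"))
    return out


def _no_test_result(family: str, groups: Mapping[str, np.ndarray], flag: str) -> StatResult:
    return StatResult(
        family=family,
        branch="none",
        normality_ps={k: float("nan") for k in groups},
        homoscedasticity_p=None,
        omnibus_test="none",
        omnibus_stat=float("nan"),
        omnibus_p=float("nan"),
        comparisons=[],
        n_per_group={k: len(v) for k, v in groups.items()},
        flags=[flag],
    )


def _records_to_section_groups(records: Sequence[ColonyRecord]) -> dict[str, np.ndarray]:
    groups: dict[str, list[float]] = {}
    for rec in records:
        for sec, val in rec.relative_means.items():
            if np.isfinite(val):
                groups.setdefault(sec, []).append(float(val))
    order = [s for s in SECTIONS if s in groups] + [s for s in groups if s not in SECTIONS]
    return {s: np.asarray(groups[s]) for s in order}


def _coerce_groups(data, group_col: str, value_col: str) -> dict[str, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        return {
            str(g): sub[value_col].to_numpy(dtype=float)
            for g, sub in data.groupby(group_col, sort=False)
        }
    if isinstance(data, Mapping):
        return {str(k): np.asarray(v, dtype=float) for k, v in data.items()}
    return _records_to_section_groups(list(data))


# -- comparison families ----------------------------------------------------------


def compare_sections_within_group(
    records,
    config: StatConfig | None = None,
) -> StatResult:
    """All-pairs section comparison within one treatment and channel.

    Accepts a list of :class:`ColonyRecord` (one treatment/channel), a tidy
    DataFrame with ``section``/``value`` columns, or a mapping section ->
    values.  Normal data: one-way ANOVA omnibus with Tukey HSD on every
    section pair.  Otherwise: Kruskal-Wallis with Dunn's test.  A section
    with no observations is omitted from the pairs and flagged.
    """
    config = config or StatConfig()
    groups = _coerce_groups(records, "section", "value")
    flags = []
    for name in list(groups):
        if len(groups[name]) == 0:
            flags.append(f"section_missing:{name}")
            del groups[name]
    if len(groups) < 2:
        res = _no_test_result("within_treatment_sections", groups, "insufficient_groups")
        res.flags.extend(flags)
        return res
    if any(len(v) < 2 for v in groups.values()):
        res = _no_test_result("within_treatment_sections", groups, "insufficient_n")
        res.flags.extend(flags)
        return res
    if np.ptp(np.concatenate(list(groups.values()))) == 0:
        res = _no_test_result("within_treatment_sections", groups, "zero_variance")
        res.flags.extend(flags)
        return res
    names = list(groups)
    arrays = [groups[n] for n in names]
    passed, norm_ps, gate_flags = _normality_gate(groups, config.alpha)
    bf_p = _brown_forsythe(arrays)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    if passed:
        f = sps.f_oneway(*arrays)
        tk = sps.tukey_hsd(*arrays)
        comps = [
            Comparison(
                a, b,
                estimate=float(np.mean(groups[a]) - np.mean(groups[b])),
                statistic=float(tk.statistic[names.index(a), names.index(b)]),
                p=float(tk.pvalue[names.index(a), names.index(b)]),
                p_adjusted=float(tk.pvalue[names.index(a), names.index(b)]),
                method="tukey_hsd",
            )
            for a, b in pairs
        ]
        branch, test, stat, p = "parametric", "one_way_anova", float(f.statistic), float(f.pvalue)
    else:
        kw = sps.kruskal(*arrays)
        comps = dunn_test(groups, pairs, config.dunn_correction)
        branch, test, stat, p = "nonparametric", "kruskal_wallis", float(kw.statistic), float(kw.pvalue)
    return StatResult(
        family="within_treatment_sections",
        branch=branch,
        normality_ps=norm_ps,
        homoscedasticity_p=bf_p,
        omnibus_test=test,
        omnibus_stat=stat,
        omnibus_p=p,
        comparisons=comps,
        n_per_group={n: len(groups[n]) for n in names},
        flags=flags + gate_flags,
    )


def compare_treatments_vs_vehicle(
    records,
    vehicle_label: str = "vehicle",
    config: StatConfig | None = None,
) -> StatResult:
    """Each treatment against the vehicle control for one section/channel.

    Accepts a tidy DataFrame with ``treatment``/``value`` columns or a
    mapping treatment -> values; a vehicle group must be present along with
    at least one treatment.  Normal data: one-way ANOVA omnibus with
    Dunnett's test (vehicle as control).  Otherwise: Kruskal-Wallis with
    Dunn's test restricted to vehicle contrasts.  Treatment-vs-treatment
    pairs are never reported.
    """
    config = config or StatConfig()
    groups = _coerce_groups(records, "treatment", "value")
    if vehicle_label not in groups:
        raise ValueError(f"missing vehicle group {vehicle_label!r}")
    others = [n for n in groups if n != vehicle_label]
    if not others:
        raise ValueError("vehicle-only input: nothing to compare against")
    if any(len(v) < 2 for v in groups.values()):
        return _no_test_result("treatments_vs_vehicle", groups, "insufficient_n")
    all_vals = np.concatenate(list(groups.values()))
    if np.ptp(all_vals) == 0:
        return _no_test_result("treatments_vs_vehicle", groups, "zero_variance")
    passed, norm_ps, gate_flags = _normality_gate(groups, config.alpha)
    bf_p = _brown_forsythe(list(groups.values()))
    if passed:
        arrays = [groups[n] for n in [vehicle_label] + others]
        f = sps.f_oneway(*arrays)
        dn = sps.dunnett(*[groups[n] for n in others], control=groups[vehicle_label])
        comps = [
            Comparison(
                n, vehicle_label,
                estimate=float(np.mean(groups[n]) - np.mean(groups[vehicle_label])),
                statistic=float(dn.statistic[i]),
                p=float(dn.pvalue[i]),
                p_adjusted=float(dn.pvalue[i]),
                method="dunnett",
            )
            for i, n in enumerate(others)
        ]
        branch, test, stat, p = "parametric", "one_way_anova", float(f.statistic), float(f.pvalue)
    else:
        kw = sps.kruskal(*[groups[n] for n in groups])
        comps = dunn_test(groups, [(n, vehicle_label) for n in others], config.dunn_correction)
        branch, test, stat, p = "nonparametric", "kruskal_wallis", float(kw.statistic), float(kw.pvalue)
    return StatResult(
        family="treatments_vs_vehicle",
        branch=branch,
        normality_ps=norm_ps,
        homoscedasticity_p=bf_p,
        omnibus_test=test,
        omnibus_stat=stat,
        omnibus_p=p,
        comparisons=comps,
        n_per_group={n: len(groups[n]) for n in groups},
        flags=gate_flags,
    )


def blocked_anova_lsd(
    table: pd.DataFrame,
    design: str = "one_way",
    config: StatConfig | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
    response: str = "response",
    condition: str = "condition",
    block: str = "block",
    factors: tuple[str, str] = ("factor_a", "factor_b"),
) -> StatResult:
    """Randomized-block ANOVA with uncorrected Fisher's LSD contrasts.

    The block (biological replicate) enters as an additive factor.  For
    ``design="one_way"`` the table needs ``response``, ``condition`` and
    ``block`` columns; the omnibus F is the condition effect over the
    residual mean square.  For ``design="two_way"`` the two factor columns
    form a factorial condition (main effects plus interaction, block
    additive); a ``condition`` label for LSD purposes is the ``a:b``
    combination, and the omnibus F tests all cell-mean differences jointly.

    LSD tests only the preselected ``pairs`` of condition labels (all pairs
    if omitted) with ``t = (m1 - m2) / sqrt(MSE (1/n1 + 1/n2))`` on the
    residual degrees of freedom, uncorrected.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    config = config or StatConfig()
    df = table.copy()
    if design not in ("one_way", "two_way"):
        raise ValueError(f"design must be 'one_way' or 'two_way', got {design!r}")
    if design == "two_way":
        fa, fb = factors
        for col in (response, fa, fb, block):
            if col not in df.columns:
                raise ValueError(f"two_way table lacks column {col!r}")
        df[condition] = df[fa].astype(str) + ":" + df[fb].astype(str)
    else:
        for col in (response, condition, block):
            if col not in df.columns:
                raise ValueError(f"one_way table lacks column {col!r}")
    levels = list(dict.fromkeys(df[condition]))
    counts = df.groupby(condition)[response].count()
    if (counts == 0).any():
        raise ValueError("a condition is absent from every block")

    groups = {str(l): df.loc[df[condition] == l, response].to_numpy(float) for l in levels}
    if np.ptp(df[response].to_numpy(float)) == 0:
        return _no_test_result("blocked_anova_lsd", groups, "zero_variance")

    df = df.rename(columns={response: "_y", condition: "_cond", block: "_block"})
    if design == "two_way":
        df = df.rename(columns={factors[0]: "_fa", factors[1]: "_fb"})
        model = smf.ols("_y ~ C(_fa) * C(_fb) + C(_block)", data=df).fit()
    else:
        model = smf.ols("_y ~ C(_cond) + C(_block)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    mse = float(anova.loc["Residual", "sum_sq"] / anova.loc["Residual", "df"])
    df_resid = float(anova.loc["Residual", "df"])

    def _effect_f(tbl, row):
        # guard the perfectly-additive degenerate case (0/0): a vanishing
        # effect sum of squares means F = 0, p = 1, whatever the residual
        ss = float(tbl.loc[row, "sum_sq"])
        total = float(tbl["sum_sq"].sum())
        if total <= 0 or ss / total < 1e-12:
            return 0.0, 1.0
        sse, dfe = float(tbl.loc["Residual", "sum_sq"]), float(tbl.loc["Residual", "df"])
        dfn = float(tbl.loc[row, "df"])
        if sse / total < 1e-12:
            return float("inf"), 0.0
        f = (ss / dfn) / (sse / dfe)
        return f, float(sps.f.sf(f, dfn, dfe))

    if design == "one_way":
        omnibus_stat, omnibus_p = _effect_f(anova, "C(_cond)")
    else:
        # joint test of all cell-mean differences (main effects + interaction)
        cell_model = smf.ols("_y ~ C(_cond) + C(_block)", data=df).fit()
        cell_anova = sm.stats.anova_lm(cell_model, typ=2)
        omnibus_stat, omnibus_p = _effect_f(cell_anova, "C(_cond)")

    if pairs is None:
        pairs = [(str(a), str(b)) for i, a in enumerate(levels) for b in levels[i + 1:]]
    comps = []
    for a, b in pairs:
        if a not in groups or b not in groups:
            raise ValueError(f"LSD pair ({a!r}, {b!r}) names an unknown condition")
        ga, gb = groups[a], groups[b]
        se = math.sqrt(mse * (1.0 / len(ga) + 1.0 / len(gb)))
        est = float(ga.mean() - gb.mean())
        if se == 0:
            tstat, p = 0.0, 1.0
        else:
            tstat = est / se
            p = float(2.0 * sps.t.sf(abs(tstat), df_resid))
        comps.append(Comparison(a, b, estimate=est, statistic=tstat, p=p,
                                p_adjusted=None, method="fisher_lsd"))
    return StatResult(
        family="blocked_anova_lsd",
        branch="parametric",
        normality_ps={},
        homoscedasticity_p=None,
        omnibus_test=f"randomized_block_{design}_anova",
        omnibus_stat=omnibus_stat,
        omnibus_p=omnibus_p,
        comparisons=comps,
        n_per_group={n: len(g) for n, g in groups.items()},
        extra={"anova_table": anova, "mse": mse, "df_resid": df_resid},
    )


def paired_expression_test(
    vehicle: Sequence[float],
    treated: Sequence[float],
    config: StatConfig | None = None,
) -> StatResult:
    """Ratio paired t test (or Wilcoxon matched-pairs) on expression values.

    Values must be positive and paired by replicate.  The ratio paired t is
    a one-sample t on ``log(treated / vehicle)``; the gate is Shapiro-Wilk
    on those log-ratios, with the Wilcoxon matched-pairs signed-rank test on
    the nonparametric branch.  All-equal pairs give p = 1 by convention;
    other zero-variance log-ratios are flagged as untestable.
    """
    config = config or StatConfig()
    v = np.asarray(vehicle, dtype=float)
    t = np.asarray(treated, dtype=float)
    if v.shape != t.shape or v.ndim != 1:
        raise ValueError("vehicle and treated must be equal-length 1-D samples")
    if np.any(v <= 0) or np.any(t <= 0):
        raise ValueError("ratio paired test requires positive values (log undefined)")
    logr = np.log(t / v)
    groups = {"log_ratio": logr}
    n = len(logr)
    if np.ptp(logr) == 0:
        res = _no_test_result("paired_expression", groups, "zero_variance")
        if np.allclose(logr, 0.0):
            res.omnibus_test = "ratio_paired_t"
            res.omnibus_p = 1.0
            res.flags.append("identical_pairs")
        return res
    passed, norm_ps, gate_flags = _normality_gate(groups, config.alpha)
    if passed:
        tt = sps.ttest_1samp(logr, 0.0)
        branch, test, stat, p = "parametric", "ratio_paired_t", float(tt.statistic), float(tt.pvalue)
    else:
        w = sps.wilcoxon(logr, alternative="two-sided")
        branch, test, stat, p = "nonparametric", "wilcoxon_matched_pairs", float(w.statistic), float(w.pvalue)
    est = float(np.exp(logr.mean()))  # geometric-mean treated/vehicle ratio
    return StatResult(
        family="paired_expression",
        branch=branch,
        normality_ps=norm_ps,
        homoscedasticity_p=None,
        omnibus_test=test,
        omnibus_stat=stat,
        omnibus_p=p,
        comparisons=[
            Comparison("treated", "vehicle", estimate=est, statistic=stat,
                       p=p, p_adjusted=None, method=test)
        ],
        n_per_group={"pairs": n},
        flags=gate_flags,
    )
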