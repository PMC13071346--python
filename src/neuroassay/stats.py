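"""Assumption-gated statistical comparisons with the study's post-hoc scheme.

The entry point is a plan-then-execute layer: :func:`gate` runs the
assumption checks (Levene's F-type test for homogeneity of variance,
Shapiro–Wilk per group for normality, both at α = 0.05) and routes to one
of the named analysis families

* parametric one-way ANOVA + Dunnett's many-to-one comparisons,
* Brown–Forsythe and Welch ANOVA + Dunnett T3 pairwise comparisons
  (variance heterogeneity),
* Kruskal–Wallis (normality unrecoverable),
* two-way factorial ANOVA with Sidak within-level or Tukey all-pairs
  post hocs,

with log-transformation as the normality remedy tried before giving up on
parametric analysis (the gate order is normality → transform → variance).
When the log route is taken, back-transformed group means are geometric
means of the raw data. A Mauchly/Greenhouse–Geisser sphericity gate is
exposed for repeated-measures designs but is inert for the between-subjects
designs this package targets.

Underlying test mathematics are delegated to scipy/statsmodels/pingouin;
this module contributes the routing, the comparison families, and a
Monte-Carlo calibration harness (:func:`simulate_type1`) that measures
each route's familywise type-I error under its own null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatPlan",
    "StatResult",
    "gate",
    "one_way_dunnett",
    "two_way_factorial",
    "welch_bf_dunnett_t3",
    "kruskal_wallis",
    "analyze_one_way",
    "sphericity_gate",
    "sidak_adjust",
    "simulate_type1",
]

ALPHA = 0.05


def sidak_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Sidak familywise adjustment: 1 − (1 − p)^m, capped at 1."""
    p = np.asarray(p, float)
    m = len(p) if m is None else m
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


@dataclass
class StatPlan:
    """Routing decision plus the assumption-test evidence behind it."""

    design: str
    route: str                      # 'anova' | 'welch-bf' | 'kruskal'
    posthoc: str                    # 'dunnett' | 'dunnett-t3' | 'sidak' | 'tukey' | 'none'
    transform: str = "none"         # 'none' | 'log'
    levene_p: float = np.nan
    shapiro_p: dict = dc_field(default_factory=dict)
    mauchly_p: float | None = None
    alpha: float = ALPHA
    audit: list = dc_field(default_factory=list)


@dataclass
class StatResult:
    """Omnibus and per-comparison outcome of one routed analysis."""

    omnibus: pd.DataFrame           # columns: effect, statistic, df1, df2, p
    comparisons: pd.DataFrame       # columns: comparison, estimate, p_raw, p_adj, method
    route: str
    transform: str = "none"
    group_means: dict | None = None  # back-transformed (geometric) under log
    degenerate: bool = False


def _as_groups(groups) -> dict:
    out = {k: np.asarray(v, float).ravel() for k, v in dict(groups).items()}
    if len(out) < 2:
        raise ValueError("need at least two groups")
    for k, v in out.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    return out


def _normality_ok(groups: dict, alpha: float, audit: list, label: str) -> tuple:
    ps = {}
    ok = True
    for name, vals in groups.items():
        if len(vals) < 3 or np.ptp(vals) == 0:
            audit.append(f"shapiro[{label}] {name}: not computable (n<3 or constant)")
            ps[name] = np.nan
            ok = False
            continue
        p = float(sps.shapiro(vals).pvalue)
        ps[name] = p
        if p < alpha:
            ok = False
    audit.append(f"shapiro[{label}]: " + ("pass" if ok else "fail")
                 + " " + str({k: None if np.isnan(v) else round(v, 4)
                              for k, v in ps.items()}))
    return ok, ps


def gate(groups, design: str = "one-way", alpha: float = ALPHA,
         repeated_measures: bool = False) -> StatPlan:
    """Route a dataset to an analysis family from the assumption checks.

    Order: Shapiro–Wilk normality per group on the raw data; on failure
    the data are log-transformed (possible only when all values are
    positive) and re-tested, and if normality still fails the plan routes
    to Kruskal–Wallis. With normality in hand, Levene's test (F effect
    type, mean-centered, outliers included) decides between the classic
    ANOVA route and the Welch/Brown–Forsythe route with Dunnett T3. The
    sphericity gate applies only to repeated-measures designs.
    """
    groups = _as_groups(groups)
    audit: list = []
    transform = "none"

    ok, ps = _normality_ok(groups, alpha, audit, "raw")
    small_n = any(len(v) < 3 for v in groups.values())
    if small_n:
        warnings.warn("group too small for Shapiro-Wilk; routing to "
                      "nonparametric analysis", stacklevel=2)
        plan = StatPlan(design, "kruskal", "none", "none",
                        shapiro_p=ps, alpha=alpha, audit=audit)
        plan.audit.append("route: kruskal (insufficient n for normality test)")
        return plan
    work = groups
    if not ok:
        if all((v > 0).all() for v in groups.values()):
            logged = {k: np.log(v) for k, v in groups.items()}
            ok2, ps2 = _normality_ok(logged, alpha, audit, "log")
            if ok2:
                transform, work, ps = "log", logged, ps2
                audit.append("transform: log (normality restored)")
        if transform == "none":
            audit.append("route: kruskal (normality not recoverable)")
            return StatPlan(design, "kruskal", "none", "none",
                            shapiro_p=ps, alpha=alpha, audit=audit)

    levene_p = float(sps.levene(*work.values(), center="mean").pvalue)
    audit.append(f"levene[{transform}]: p={levene_p:.4g}")
    if levene_p < alpha:
        audit.append("route: welch-bf (variance heterogeneity)")
        return StatPlan(design, "welch-bf", "dunnett-t3", transform,
                        levene_p, ps, alpha=alpha, audit=audit)

    posthoc = {"one-way": "dunnett", "two-way": "sidak"}.get(design, "dunnett")
    audit.append("route: anova (assumptions met)")
    plan = StatPlan(design, "anova", posthoc, transform, levene_p, ps,
                    alpha=alpha, audit=audit)
    if repeated_measures:
        plan.audit.append("sphericity gate requested; supply wide data to "
                          "sphericity_gate() for Mauchly/Greenhouse-Geisser")
    return plan


def _group_means(groups: dict, transform: str) -> dict:
    if transform == "log":
        return {k: float(np.exp(np.mean(np.log(v)))) for k, v in groups.items()}
    return {k: float(np.mean(v)) for k, v in groups.items()}


def _maybe_log(groups: dict, transform: str) -> dict:
    if transform == "log":
        return {k: np.log(v) for k, v in groups.items()}
    return groups


def one_way_dunnett(groups, control: str, transform: str = "none") -> StatResult:
    """One-way ANOVA omnibus plus Dunnett many-to-one comparisons.

    ``control`` names the reference group (e.g. the 0 mM dose); every
    other group is compared against it with Dunnett's familywise-adjusted
    p-values. All-constant input is flagged degenerate rather than raising.
    """
    raw = _as_groups(groups)
    if control not in raw:
        raise ValueError(f"control group {control!r} not present")
    work = _maybe_log(raw, transform)
    vals = list(work.values())
    k, N = len(vals), sum(len(v) for v in vals)
    if all(np.ptp(v) == 0 for v in vals):
        omnibus = pd.DataFrame([{"effect": "group", "statistic": np.nan,
                                 "df1": k - 1, "df2": N - k, "p": np.nan}])
        return StatResult(omnibus, pd.DataFrame(), "anova", transform,
                          _group_means(raw, transform), degenerate=True)
    F, p = sps.f_oneway(*vals)
    omnibus = pd.DataFrame([{"effect": "group", "statistic": float(F),
                             "df1": k - 1, "df2": N - k, "p": float(p)}])
    treat_names = [g for g in work if g != control]
    res = sps.dunnett(*[work[g] for g in treat_names], control=work[control])
    comp = pd.DataFrame({
        "comparison": [f"{g} vs {control}" for g in treat_names],
        "estimate": [float(np.mean(work[g]) - np.mean(work[control]))
                     for g in treat_names],
        "p_raw": np.nan,
        "p_adj": np.asarray(res.pvalue, float),
        "method": "dunnett",
    })
    return StatResult(omnibus, comp, "anova", transform,
                      _group_means(raw, transform))


def two_way_factorial(data: pd.DataFrame, value: str, factor_a: str,
                      factor_b: str, posthoc: str = "sidak",
                      include_interaction: bool = True) -> StatResult:
    """Two-way factorial ANOVA with Sidak or Tukey post hocs.

    Fits ``value ~ A * B`` (full-effects model with interaction) or the
    additive ``A + B`` model via OLS. Post hocs follow the study's scheme:
    ``"sidak"`` compares levels of A within each level of B using the
    pooled residual error, with Sidak familywise adjustment over the
    whole family; ``"tukey"`` runs Tukey's all-pairs comparison across B
    within each level of A.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    if include_interaction:
        counts = d.groupby(["_a", "_b"])["_y"].size()
        full = len(d["_a"].unique()) * len(d["_b"].unique())
        if len(counts) < full:
            raise ValueError("empty factor cells: interaction model "
                             "cannot be estimated")
        if (counts < 2).all():
            raise ValueError("interaction model needs replicate cells")
        model = smf.ols("_y ~ C(_a) * C(_b)", d).fit()
    else:
        model = smf.ols("_y ~ C(_a) + C(_b)", d).fit()
    table = sm.stats.anova_lm(model, typ=2)
    rename = {"C(_a)": factor_a, "C(_b)": factor_b,
              "C(_a):C(_b)": f"{factor_a}:{factor_b}"}
    omnibus = pd.DataFrame([
        {"effect": rename.get(idx, idx), "statistic": float(row["F"]),
         "df1": float(row["df"]), "df2": float(table.loc["Residual", "df"]),
         "p": float(row["PR(>F)"])}
        for idx, row in table.iterrows() if idx != "Residual"])

    rows = []
    if posthoc == "sidak":
        mse = float(model.mse_resid)
        df_resid = float(model.df_resid)
        cells = d.groupby(["_b", "_a"])["_y"].agg(["mean", "size"])
        for b_level in d["_b"].unique():
            a_levels = sorted(d.loc[d["_b"] == b_level, "_a"].unique())
            for i, a1 in enumerate(a_levels):
                for a2 in a_levels[i + 1:]:
                    m1, n1 = cells.loc[(b_level, a1)]
                    m2, n2 = cells.loc[(b_level, a2)]
                    se = np.sqrt(mse * (1 / n1 + 1 / n2))
                    t = (m1 - m2) / se if se > 0 else np.nan
                    p = 2 * sps.t.sf(abs(t), df_resid) if np.isfinite(t) else np.nan
                    rows.append({"comparison": f"{a1} vs {a2} | {factor_b}={b_level}",
                                 "estimate": float(m1 - m2), "p_raw": p})
        comp = pd.DataFrame(rows)
        if not comp.empty:
            comp["p_adj"] = sidak_adjust(comp["p_raw"].to_numpy())
            comp["method"] = "sidak"
    elif posthoc == "tukey":
        for a_level in d["_a"].unique():
            sub = d[d["_a"] == a_level]
            b_levels = sorted(sub["_b"].unique())
            samples = [sub.loc[sub["_b"] == b, "_y"].to_numpy() for b in b_levels]
            res = sps.tukey_hsd(*samples)
            for i in range(len(b_levels)):
                for j in range(i + 1, len(b_levels)):
                    rows.append({
                        "comparison": f"{b_levels[i]} vs {b_levels[j]} | "
                                      f"{factor_a}={a_level}",
                        "estimate": float(np.mean(samples[i]) - np.mean(samples[j])),
                        "p_raw": np.nan,
                        "p_adj": float(res.pvalue[i, j]),
                        "method": "tukey"})
        comp = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return StatResult(omnibus, comp, "anova")


def _welch_t(x: np.ndarray, y: np.ndarray) -> tuple:
    """Welch t statistic, Satterthwaite df, two-sided p."""
    n1, n2 = len(x), len(y)
    v1, v2 = np.var(x, ddof=1) / n1, np.var(y, ddof=1) / n2
    se2 = v1 + v2
    if se2 == 0:
        return np.nan, np.nan, 1.0
    t = (np.mean(x) - np.mean(y)) / np.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return float(t), float(df), float(2 * sps.t.sf(abs(t), df))


def _brown_forsythe(vals: list) -> tuple:
    """Brown–Forsythe ANOVA for means (heteroscedasticity-robust F*)."""
    k = len(vals)
    n = np.array([len(v) for v in vals], float)
    N = n.sum()
    means = np.array([np.mean(v) for v in vals])
    s2 = np.array([np.var(v, ddof=1) for v in vals])
    grand = np.sum(n * means) / N
    num = np.sum(n * (means - grand) ** 2)
    den_terms = (1 - n / N) * s2
    den = den_terms.sum()
    if den == 0:
        return np.nan, k - 1.0, np.nan, np.nan
    F = num / den
    c = den_terms / den
    df2 = 1.0 / np.sum(c ** 2 / (n - 1))
    return float(F), float(k - 1), float(df2), float(sps.f.sf(F, k - 1, df2))


def welch_bf_dunnett_t3(groups, transform: str = "none") -> StatResult:
    """Welch and Brown–Forsythe ANOVA with Dunnett T3 pairwise comparisons.

    Both heteroscedasticity-robust omnibus statistics are reported. The
    Dunnett T3 family runs all pairwise Welch t-tests with Satterthwaite
    degrees of freedom and adjusts with the studentized-maximum-modulus
    bound evaluated under independence (the Sidak form), which keeps the
    familywise error at or below α under unequal variances.
    """
    raw = _as_groups(groups)
    work = _maybe_log(raw, transform)
    names = list(work)
    vals = [work[g] for g in names]

    import pingouin as pg
    long = pd.DataFrame({
        "y": np.concatenate(vals),
        "g": np.repeat(names, [len(v) for v in vals])})
    welch = pg.welch_anova(data=long, dv="y", between="g").iloc[0]
    bf_F, bf_df1, bf_df2, bf_p = _brown_forsythe(vals)
    omnibus = pd.DataFrame([
        {"effect": "group (Welch)", "statistic": float(welch["F"]),
         "df1": float(welch["ddof1"]), "df2": float(welch["ddof2"]),
         "p": float(welch["p_unc"])},
        {"effect": "group (Brown-Forsythe)", "statistic": bf_F,
         "df1": bf_df1, "df2": bf_df2, "p": bf_p}])

    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t, df, p = _welch_t(work[a], work[b])
            rows.append({"comparison": f"{a} vs {b}",
                         "estimate": float(np.mean(work[a]) - np.mean(work[b])),
                         "p_raw": p})
    comp = pd.DataFrame(rows)
    comp["p_adj"] = sidak_adjust(comp["p_raw"].to_numpy())
    comp["method"] = "dunnett-t3"
    return StatResult(omnibus, comp, "welch-bf", transform,
                      _group_means(raw, transform))


def kruskal_wallis(groups) -> StatResult:
    """Kruskal–Wallis rank test (the nonparametric fallback route)."""
    work = _as_groups(groups)
    vals = list(work.values())
    if all(np.ptp(np.concatenate(vals)) == 0 for _ in (0,)):
        omnibus = pd.DataFrame([{"effect": "group", "statistic": np.nan,
                                 "df1": len(vals) - 1, "df2": np.nan,
                                 "p": np.nan}])
        return StatResult(omnibus, pd.DataFrame(), "kruskal", degenerate=True)
    H, p = sps.kruskal(*vals)
    omnibus = pd.DataFrame([{"effect": "group", "statistic": float(H),
                             "df1": len(vals) - 1, "df2": np.nan,
                             "p": float(p)}])
    return StatResult(omnibus, pd.DataFrame(), "kruskal",
                      group_means={k: float(np.median(v)) for k, v in work.items()})


def analyze_one_way(groups, control: str, alpha: float = ALPHA) -> tuple:
    """Gate a one-way dose design and execute the routed analysis.

    Returns ``(StatPlan, StatResult)``; the plan's audit trail records
    every assumption decision that led to the executed route.
    """
    plan = gate(groups, "one-way", alpha)
    if plan.route == "anova":
        res = one_way_dunnett(groups, control, plan.transform)
    elif plan.route == "welch-bf":
        res = welch_bf_dunnett_t3(groups, plan.transform)
    else:
        res = kruskal_wallis(groups)
    return plan, res


def sphericity_gate(wide: pd.DataFrame, alpha: float = ALPHA) -> dict:
    """Mauchly sphericity check with Greenhouse–Geisser epsilon.

    ``wide`` holds one row per subject and one column per within-subject
    condition. Provided for repeated-measures designs; between-subjects
    analyses never consult it.
    """
    import pingouin as pg
    arr = wide.to_numpy(float)
    spher = pg.sphericity(wide)
    eps = float(pg.epsilon(wide, correction="gg"))
    return {"mauchly_W": float(spher.W), "mauchly_p": float(spher.pval),
            "gg_epsilon": eps, "sphericity_ok": bool(spher.pval >= alpha),
            "n_conditions": arr.shape[1]}


# ---------------------------------------------------------------------------
# Monte-Carlo calibration of each route's familywise type-I error.

def _sim_one_way(rng, route_fn, n_groups=3, n=3, scales=None):
    scales = scales or [1.0] * n_groups
    names = [f"g{i}" for i in range(n_groups)]
    return {nm: rng.normal(0, s, n) for nm, s in zip(names, scales)}


def simulate_type1(route: str, n_sims: int = 2000, seed: int = 0,
                   alpha: float = ALPHA) -> float:
    """Familywise type-I error of one routed family under its own null.

    Routes: ``"one-way-dunnett"`` (3 normal groups, n = 3; reject when any
    Dunnett-adjusted p < α), ``"two-way-interaction"`` (2×3 design, n = 3
    per cell; reject on the interaction F), ``"welch-bf-t3"``
    (heteroscedastic null, SDs 1/1/5, n = 10; reject when any T3-adjusted
    p < α), ``"kruskal"`` (3 groups, n = 6; omnibus rejection). Returns
    the rejection proportion; under a calibrated procedure it should sit
    near α.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        if route == "one-way-dunnett":
            groups = _sim_one_way(rng, None, 3, 3)
            res = one_way_dunnett(groups, "g0")
            rejections += bool((res.comparisons["p_adj"] < alpha).any())
        elif route == "two-way-interaction":
            d = pd.DataFrame({
                "y": rng.normal(size=18),
                "a": np.repeat(["a1", "a2"], 9),
                "b": np.tile(np.repeat(["b1", "b2", "b3"], 3), 2)})
            res = two_way_factorial(d, "y", "a", "b", posthoc="sidak")
            p_int = res.omnibus.loc[res.omnibus["effect"] == "a:b", "p"].iloc[0]
            rejections += bool(p_int < alpha)
        elif route == "welch-bf-t3":
            groups = _sim_one_way(rng, None, 3, 10, scales=[1.0, 1.0, 5.0])
            res = welch_bf_dunnett_t3(groups)
            rejections += bool((res.comparisons["p_adj"] < alpha).any())
        elif route == "kruskal":
            groups = _sim_one_way(rng, None, 3, 6)
            res = kruskal_wallis(groups)
            rejections += bool(res.omnibus["p"].iloc[0] < alpha)
        else:
            raise ValueError(f"unknown route {route!r}")
    return rejections / n_sims
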