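"""Relative quantification of qPCR data by the ΔΔCt method.

A Ct table is a tidy :class:`pandas.DataFrame` with columns

    gene, group, dose_mM, replicate, ct

where ``group`` is the differentiation status (``"UnDiff"`` or ``"Diff"``)
and ``dose_mM`` the ethanol dose. The workflow is

1. :func:`delta_ct` — normalize each target gene to a housekeeping
   (reference) gene, pairing replicates: ΔCt = Ct_target − Ct_reference.
2. :func:`calibrator_means` — pick the calibrator group's mean ΔCt per
   gene, under one of two conventions: ``"within-status"`` (each status
   uses its own 0 mM group) or ``"cross-status"`` (everything is referred
   to the UnDiff 0 mM group).
3. :func:`fold_change` — per replicate, FC = E^(−ΔΔCt) with
   ΔΔCt = ΔCt − mean ΔCt_calibrator and amplification efficiency E
   (default 2, the classic assumption). The group-level fold change is the
   arithmetic mean of per-replicate fold changes; the geometric alternative
   (E^−mean ΔΔCt) is available by flag.

Reference-gene choice among candidates is done by
:func:`normfinder_stability`, a model-based variance-decomposition on the
Ct scale (Ct is already log2 expression up to affine terms): each candidate
gets an intragroup variance and a per-group expression bias, combined into
a stability value; the lowest-stability candidate is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CT_COLUMNS",
    "FoldChangeResult",
    "StabilityResult",
    "delta_ct",
    "calibrator_means",
    "fold_change",
    "relative_expression",
    "normfinder_stability",
]

CT_COLUMNS = ("gene", "group", "dose_mM", "replicate", "ct")

_SAMPLE_KEYS = ["group", "dose_mM", "replicate"]


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks required columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return table


def delta_ct(table: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Normalize target Ct values to a reference gene, replicate-paired.

    Returns a tidy frame with columns ``gene, group, dose_mM, replicate,
    delta_ct``. Target rows whose (group, dose, replicate) has no matching
    reference measurement are dropped with a warning, never imputed.
    """
    _check_table(table)
    ref = table.loc[table["gene"] == reference_gene, _SAMPLE_KEYS + ["ct"]]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    ref = ref.rename(columns={"ct": "ct_ref"})
    targets = table[table["gene"] != reference_gene]
    merged = targets.merge(ref, on=_SAMPLE_KEYS, how="left")
    n_missing = int(merged["ct_ref"].isna().sum())
    if n_missing:
        warnings.warn(
            f"dropped {n_missing} target row(s) with no paired "
            f"{reference_gene} replicate", stacklevel=2)
        merged = merged.dropna(subset=["ct_ref"])
    merged = merged.assign(delta_ct=merged["ct"] - merged["ct_ref"])
    return merged[["gene", "group", "dose_mM", "replicate", "delta_ct"]]


def calibrator_means(dct: pd.DataFrame, convention: str = "within-status",
                     calibrator_dose: float = 0.0,
                     calibrator_group: str = "UnDiff") -> pd.DataFrame:
    """Mean calibrator ΔCt per gene (and per status for ``within-status``).

    ``"within-status"``: each differentiation status is calibrated to its
    own 0 mM group. ``"cross-status"``: every group is calibrated to the
    UnDiff 0 mM mean, so UnDiff 0 mM has fold change 1 by construction.
    """
    if convention not in ("within-status", "cross-status"):
        raise ValueError(f"unknown convention {convention!r}")
    if convention == "within-status":
        cal = dct[dct["dose_mM"] == calibrator_dose]
        out = (cal.groupby(["gene", "group"], as_index=False)["delta_ct"]
               .agg(calibrator_mean_dct="mean", n_calibrator="size"))
    else:
        cal = dct[(dct["dose_mM"] == calibrator_dose)
                  & (dct["group"] == calibrator_group)]
        out = (cal.groupby("gene", as_index=False)["delta_ct"]
               .agg(calibrator_mean_dct="mean", n_calibrator="size"))
    absent = set(dct["gene"]) - set(out["gene"])
    if absent:
        raise ValueError(
            "calibrator group missing for gene(s): " + ", ".join(sorted(absent)))
    if (out["n_calibrator"] < 2).any():
        warnings.warn("calibrator mean based on fewer than 2 replicates "
                      "for some gene(s)", stacklevel=2)
    return out


@dataclass
class FoldChangeResult:
    """Per-replicate and group-level ΔΔCt fold changes.

    ``replicates`` has one row per (gene, group, dose, replicate) with its
    ΔCt, ΔΔCt and fold change; ``groups`` one row per (gene, group, dose)
    with the group fold change and replicate count.
    """

    replicates: pd.DataFrame
    groups: pd.DataFrame
    convention: str
    efficiency: float = 2.0
    group_statistic: str = "mean-fc"


def fold_change(dct: pd.DataFrame, convention: str = "within-status",
                efficiency: float = 2.0,
                group_statistic: str = "mean-fc") -> FoldChangeResult:
    """Compute ΔΔCt fold changes against the convention's calibrator.

    Per replicate, FC = efficiency^(−(ΔCt − calibrator mean ΔCt)). The
    group fold change is the mean of replicate FCs (``"mean-fc"``, matching
    per-replicate points plotted around bar means) or
    efficiency^(−mean ΔΔCt) (``"geometric"``).
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    if group_statistic not in ("mean-fc", "geometric"):
        raise ValueError(f"unknown group statistic {group_statistic!r}")
    cal = calibrator_means(dct, convention)
    keys = ["gene", "group"] if convention == "within-status" else ["gene"]
    merged = dct.merge(cal[keys + ["calibrator_mean_dct"]], on=keys, how="left")
    merged["ddct"] = merged["delta_ct"] - merged["calibrator_mean_dct"]
    merged["fold_change"] = np.power(float(efficiency), -merged["ddct"])
    if group_statistic == "mean-fc":
        groups = (merged.groupby(["gene", "group", "dose_mM"], as_index=False)
                  .agg(fold_change=("fold_change", "mean"),
                       n=("fold_change", "size")))
    else:
        groups = (merged.groupby(["gene", "group", "dose_mM"], as_index=False)
                  .agg(mean_ddct=("ddct", "mean"), n=("ddct", "size")))
        groups["fold_change"] = np.power(float(efficiency), -groups.pop("mean_ddct"))
    cols = ["gene", "group", "dose_mM", "replicate", "delta_ct", "ddct",
            "fold_change"]
    return FoldChangeResult(merged[cols], groups, convention,
                            float(efficiency), group_statistic)


def relative_expression(table: pd.DataFrame, reference: str = "auto",
                        candidates: tuple[str, ...] = ("B-ACTIN", "PGK1", "GAPDH"),
                        convention: str = "within-status",
                        efficiency: float = 2.0,
                        group_statistic: str = "mean-fc") -> FoldChangeResult:
    """End-to-end ΔΔCt pipeline: reference selection, ΔCt, fold change.

    With ``reference="auto"`` the housekeeping gene is chosen among
    ``candidates`` by :func:`normfinder_stability`; otherwise the named
    gene is used directly.
    """
    _check_table(table)
    if reference == "auto":
        present = tuple(g for g in candidates if (table["gene"] == g).any())
        if len(present) < 2:
            raise ValueError("need >=2 candidate housekeeping genes present "
                             "for automatic selection")
        reference = normfinder_stability(table, present).selected_gene
    dct = delta_ct(table, reference)
    return fold_change(dct, convention, efficiency, group_statistic)


@dataclass
class StabilityResult:
    """Outcome of model-based reference-gene stability analysis.

    ``stability`` maps gene → stability value (Ct units; lower is more
    stable); ``intragroup_variance`` and ``intergroup_bias`` expose the
    per-(gene, group) variance components behind it.
    """

    stability: dict[str, float]
    intragroup_variance: pd.DataFrame
    intergroup_bias: pd.DataFrame
    selected_gene: str
    groups: list = field(default_factory=list)


def normfinder_stability(table: pd.DataFrame,
                         candidates: tuple[str, ...],
                         group_cols: tuple[str, ...] = ("group", "dose_mM"),
                         ) -> StabilityResult:
    """Rank candidate reference genes by a variance-decomposition model.

    Works directly on Ct values (already a log2 scale). The model is a
    two-way decomposition per group: Ct = gene-group level + sample
    (template/loading) effect + noise. Sample effects are estimated
    within each group from gene-centered residuals, so group-level
    structure never leaks into them; intragroup variances are deconvolved
    from the centered residuals (the candidate-average subtraction mixes
    a 1/k share of every other gene's noise into each residual, which the
    deconvolution removes). The intergroup expression bias d of each gene
    is the deviation of its group means around its own grand mean, shrunk
    toward zero by the estimated between-group variance component, and
    the stability of gene j is

        rho_j = mean over groups of ( |d_shrunk| + sqrt(var(d_shrunk) + sigma2/n) )

    so a gene is penalized both for differing systematically between
    experimental groups and for noisy replicates. Lowest rho wins; exact
    ties are broken alphabetically with a warning.
    """
    _check_table(table)
    candidates = tuple(sorted(set(candidates)))
    k = len(candidates)
    if k < 2:
        raise ValueError("need at least two candidate genes")
    sub = table[table["gene"].isin(candidates)]
    wide = sub.pivot_table(index=list(group_cols) + ["replicate"],
                           columns="gene", values="ct")
    wide = wide.dropna()
    if wide.empty:
        raise ValueError("no complete samples across all candidates")
    group_index = wide.index.droplevel("replicate")
    groups = list(dict.fromkeys(group_index))
    G = len(groups)
    if G < 2:
        raise ValueError("need at least two experimental groups")

    y = wide[list(candidates)].to_numpy(float)        # samples x genes
    z = y - y.mean(axis=1, keepdims=True)             # gene-centered residuals

    m = np.empty((G, k))       # raw group means per gene
    v = np.empty((G, k))       # within-group variances of centered residuals
    n = np.empty(G)
    for gi, g in enumerate(groups):
        sel = np.asarray(group_index == g)
        if sel.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 complete replicates")
        n[gi] = sel.sum()
        m[gi] = y[sel].mean(axis=0)
        v[gi] = z[sel].var(axis=0, ddof=1)

    # Deconvolve the gene-centering: Var(z_j) = sigma2_j (1 - 2/k) + S/k^2
    # with S the summed sigma2 of the group. For k = 2 the system is
    # singular and the total is split evenly.
    if k >= 3:
        S = v.sum(axis=1, keepdims=True) * k / (k - 1)
        sigma2 = np.clip((v - S / k**2) / (1.0 - 2.0 / k), 0.0, None)
    else:
        sigma2 = 2.0 * v

    d = m - m.mean(axis=0, keepdims=True)             # intergroup bias per gene
    sig_n = sigma2 / n[:, None]
    # Method of moments, per gene, for its between-group variance
    # component: E[sum_g d^2] = (G-1) gamma2_j + (1 - 1/G) sum_g sig_n.
    gamma2 = np.maximum(0.0, ((d ** 2).sum(axis=0)
                              - (1.0 - 1.0 / G) * sig_n.sum(axis=0))
                        / (G - 1))                    # shape (k,)

    denom = gamma2[None, :] + sig_n
    safe = np.where(denom > 0, denom, 1.0)
    shrink = np.where(denom > 0, gamma2[None, :] / safe, 0.0)
    d_shrunk = d * shrink
    var_post = np.where(denom > 0, gamma2[None, :] * sig_n / safe, 0.0)
    rho = (np.abs(d_shrunk) + np.sqrt(var_post + sig_n)).mean(axis=0)

    stability = {g: float(r) for g, r in zip(candidates, rho)}
    order = sorted(stability, key=lambda g: (round(stability[g], 12), g))
    selected = order[0]
    if len(order) > 1 and round(stability[order[0]], 12) == round(
            stability[order[1]], 12):
        warnings.warn(
            f"stability tie between {order[0]} and {order[1]}; "
            "selected alphabetically", stacklevel=2)

    idx = pd.MultiIndex.from_tuples(
        [g if isinstance(g, tuple) else (g,) for g in groups],
        names=list(group_cols))
    intragroup = pd.DataFrame(sigma2, index=idx, columns=list(candidates))
    bias = pd.DataFrame(d, index=idx, columns=list(candidates))
    return StabilityResult(stability, intragroup, bias, selected, groups)
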