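"""Model selection, significance of length changes, loading clusters, and
covariate evaluation around the fitted factor models.

Selection fits every combination of trend count and observation-error
structure, ranks converged fits by AICc and, among fits within two AICc
units, prefers models without an unimportant trend and then models with
fewer parameters.  Significance of a river's length change requires the
95% band of its fitted series to sit entirely above the river mean in at
least one period and entirely below it in at least one other.  Loadings
are clustered by complete linkage with the gap statistic choosing k.
Covariates are evaluated one at a time against the selected base model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from riversync.covariates import CovariateTable
from riversync.dfa import (
    DFAModelSpec,
    DFAResults,
    FittedIntervals,
    R_STRUCTURES,
    fit_dfa,
    fit_dfa_covariate,
)
from riversync.panel import LengthPanel

__all__ = [
    "aicc_threshold",
    "select_model",
    "significant_changes",
    "SignificanceReport",
    "cluster_loadings",
    "ClusterResult",
    "evaluate_covariates",
]


def aicc_threshold(n_series: int) -> float:
    """Conventional improvement threshold for one added covariate.

    A model with one extra covariate costs one parameter per time series,
    so it is conventionally preferred only when its AICc undercuts the
    base model by more than 2 x (number of series).
    """
    if n_series < 1:
        raise ValueError("n_series must be >= 1")
    return 2.0 * n_series


# ---------------------------------------------------------------------------
# model selection


def select_model(
    panel: LengthPanel,
    m_range=range(1, 5),
    structures=R_STRUCTURES,
    spec: DFAModelSpec | None = None,
    unimportant_loading: float = 0.2,
    rotate_winner: bool = True,
) -> tuple[pd.DataFrame, DFAResults]:
    """Grid model selection over trend counts x error structures.

    Fits every combination, drops non-converged fits, ranks by AICc and
    computes Akaike weights over the converged fits.  When two or more
    fits sit within two AICc of the best, models whose varimax-rotated
    loadings contain an unimportant trend (every column-scaled loading of
    some trend below ``unimportant_loading`` in absolute value) are set
    aside first, then the fewest-parameter model wins.  The winner is
    varimax-rotated (when m > 1) before being returned.

    Returns the selection table (one row per fitted model) and the chosen
    fit.
    """
    base = spec or DFAModelSpec()
    fits: list[DFAResults] = []
    rows = []
    for m in m_range:
        for structure in structures:
            this = replace(base, m=m, r_structure=structure, covariates=None)
            fit = fit_dfa(panel, this)
            fits.append(fit)
            rows.append(
                {
                    "m": m,
                    "r_structure": structure,
                    "logLik": fit.loglik,
                    "n_params": fit.n_params,
                    "AICc": fit.AICc,
                    "converged": fit.converged,
                }
            )
    table = pd.DataFrame(rows)
    conv = table[table["converged"]]
    if conv.empty:
        raise RuntimeError("no model converged")
    best_aicc = conv["AICc"].min()
    table["dAICc"] = np.where(table["converged"], table["AICc"] - best_aicc, np.nan)
    rel = np.exp(-0.5 * table.loc[table["converged"], "dAICc"])
    weights = pd.Series(0.0, index=table.index)
    weights[table["converged"]] = rel / rel.sum()
    table["AICc_weight"] = weights
    table = table.sort_values("AICc").reset_index(drop=True)

    candidates = [
        fits[i]
        for i in range(len(fits))
        if fits[i].converged and fits[i].AICc - best_aicc <= 2.0
    ]
    winner = _tie_break(candidates, unimportant_loading)
    if rotate_winner and winner.m > 1:
        winner = winner.rotate()
    return table, winner


def _has_unimportant_trend(fit: DFAResults, threshold: float) -> bool:
    """True when some varimax-rotated trend has all |loadings| below the
    threshold, measured relative to the spread of the full loading matrix
    (so a uniformly tiny column reads as unimportant)."""
    Z = fit.rotate().Z if (fit.m > 1 and not fit.rotated) else fit.Z
    scale = Z.std(ddof=1)
    if scale == 0:
        return True
    scaled = np.abs(Z) / scale
    return bool((scaled.max(axis=0) < threshold).any())


def _tie_break(candidates: list[DFAResults], threshold: float) -> DFAResults:
    if len(candidates) == 1:
        return candidates[0]
    useful = [f for f in candidates if not _has_unimportant_trend(f, threshold)]
    pool = useful or candidates
    return min(pool, key=lambda f: (f.n_params, f.AICc))


# ---------------------------------------------------------------------------
# significance of changes


@dataclass
class RiverChange:
    river: str
    runs: list[tuple[int, int, str]]  # (start_year, end_year, "above"/"below")
    significant: bool
    change_mm: float | None
    change_pct: float | None


@dataclass
class SignificanceReport:
    """Per-river CI-excursion runs and the resulting significance calls."""

    rivers: list[RiverChange]
    level: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "river": r.river,
                    "n_runs": len(r.runs),
                    "significant": r.significant,
                    "change_mm": r.change_mm,
                    "change_pct": r.change_pct,
                }
                for r in self.rivers
            ]
        )

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "rivers": [
                {
                    "river": r.river,
                    "runs": [list(run) for run in r.runs],
                    "significant": r.significant,
                    "change_mm": r.change_mm,
                    "change_pct": r.change_pct,
                }
                for r in self.rivers
            ],
        }


def _maximal_runs(flags: np.ndarray, years: np.ndarray, label: str):
    runs = []
    start = None
    for k, f in enumerate(flags):
        if f and start is None:
            start = k
        elif not f and start is not None:
            runs.append((int(years[start]), int(years[k - 1]), label))
            start = None
    if start is not None:
        runs.append((int(years[start]), int(years[-1]), label))
    return runs


def significant_changes(
    fitted: FittedIntervals,
    river_means: np.ndarray | None = None,
    require_both_signs: bool = True,
) -> SignificanceReport:
    """Flag rivers whose fitted length left the river mean in both directions.

    ``fitted`` must be on the centered scale (zero = river-specific mean);
    a run of years with the CI lower bound above zero is an "above" period,
    upper bound below zero a "below" period.  A river's change is
    significant when at least one period of each sign exists (or, with
    ``require_both_signs=False``, any two excluding-zero periods).  The
    change magnitude is the maximum fitted value inside above-runs minus
    the minimum inside below-runs; the percent change divides by the
    river's raw mean length when ``river_means`` is given.
    """
    fit, lo, hi = fitted.fitted, fitted.lower, fitted.upper
    obs_scale = np.nanmax(np.abs(fit.to_numpy())) if fit.size else 0.0
    # a centered panel's fitted values straddle zero per river; a raw-scale
    # input (all-positive fitted lengths) is a usage error
    if fit.size and (fit.to_numpy() > 0).all() and obs_scale > 100:
        raise ValueError("fitted values look uncentered; fit on a centered panel")
    years = fit.columns.to_numpy()
    out = []
    for i, river in enumerate(fit.index):
        above = _maximal_runs(lo.loc[river].to_numpy() > 0, years, "above")
        below = _maximal_runs(hi.loc[river].to_numpy() < 0, years, "below")
        runs = sorted(above + below)
        if require_both_signs:
            significant = bool(above and below)
        else:
            significant = len(runs) >= 2
        change_mm = change_pct = None
        if above and below:
            f = fit.loc[river]
            peak = max(
                f.loc[s:e].max() for s, e, _ in above
            )
            trough = min(f.loc[s:e].min() for s, e, _ in below)
            change_mm = float(peak - trough)
            if river_means is not None:
                change_pct = float(100.0 * change_mm / river_means[i])
        out.append(RiverChange(str(river), runs, significant, change_mm, change_pct))
    return SignificanceReport(out, fitted.level)


# ---------------------------------------------------------------------------
# clustering of loadings


@dataclass
class ClusterResult:
    linkage: np.ndarray
    optimal_k: int
    gap: np.ndarray
    gap_se: np.ndarray
    labels: np.ndarray          # cluster labels at optimal_k
    newick: str
    merge_heights: pd.DataFrame


def _within_dispersion(dist_sq: np.ndarray, labels: np.ndarray) -> float:
    """Tibshirani W_k = sum_r D_r / (2 n_r) from squared distances."""
    total = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) > 1:
            total += dist_sq[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return total


def _newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def cluster_loadings(
    Z: np.ndarray,
    river_names: list[str] | None = None,
    k_max: int = 6,
    n_reference: int = 100,
    seed: int = 0,
) -> ClusterResult:
    """Complete-linkage clustering of rivers by their trend loadings.

    Loadings are centered and scaled per trend (mean 0, SD 1), distances
    are Euclidean, and the number of clusters is chosen by the gap
    statistic over k = 1..min(k_max, S-1): ``n_reference`` uniform draws
    over the bounding box of the scaled loadings are clustered the same
    way and the smallest k with Gap(k) >= Gap(k+1) - SE(k+1) wins.
    Requires at least two trends.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValueError("clustering needs loadings from more than one trend")
    S = Z.shape[0]
    if river_names is None:
        river_names = [f"river_{i + 1:02d}" for i in range(S)]
    scaled = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)

    link = hierarchy.linkage(scaled, method="complete", metric="euclidean")
    dist_sq = squareform(pdist(scaled)) ** 2

    ks = np.arange(1, min(k_max, S - 1) + 1)
    log_w = np.empty(len(ks))
    for j, k in enumerate(ks):
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
        log_w[j] = np.log(_within_dispersion(dist_sq, labels))

    rng = np.random.default_rng(seed)
    lo, hi = scaled.min(axis=0), scaled.max(axis=0)
    ref_log_w = np.empty((n_reference, len(ks)))
    for b in range(n_reference):
        ref = rng.uniform(lo, hi, size=scaled.shape)
        ref_link = hierarchy.linkage(ref, method="complete", metric="euclidean")
        ref_sq = squareform(pdist(ref)) ** 2
        for j, k in enumerate(ks):
            labels = hierarchy.fcluster(ref_link, t=k, criterion="maxclust")
            ref_log_w[b, j] = np.log(_within_dispersion(ref_sq, labels))

    gap = ref_log_w.mean(axis=0) - log_w
    se = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_reference)

    optimal_k = int(ks[-1])
    for j in range(len(ks) - 1):
        if gap[j] >= gap[j + 1] - se[j + 1]:
            optimal_k = int(ks[j])
            break
    labels = hierarchy.fcluster(link, t=optimal_k, criterion="maxclust")
    merges = pd.DataFrame(link, columns=["left", "right", "height", "size"])
    return ClusterResult(
        linkage=link,
        optimal_k=optimal_k,
        gap=gap,
        gap_se=se,
        labels=labels,
        newick=_newick(link, river_names),
        merge_heights=merges,
    )


# ---------------------------------------------------------------------------
# covariate evaluation


def evaluate_covariates(
    panel: LengthPanel,
    base: DFAResults,
    covariates: CovariateTable,
    names: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Refit the base model once per covariate and rank the improvements.

    Each candidate adds a single centered-and-scaled covariate to the base
    model's trend count and error structure (one coefficient per river).
    The table reports ``dAICc`` relative to the base fit (negative =
    improvement), the log-likelihood, whether the fit improves on both
    criteria (lower AICc and higher log-likelihood), and the conventional
    2 x S reference threshold.  Per-river coefficient tables with 95% CIs
    and significance flags are returned alongside.
    """
    if not covariates.scaled:
        from riversync.covariates import center_scale

        covariates = center_scale(covariates)
    names = names or covariates.names
    spec = DFAModelSpec(
        m=base.m,
        r_structure=base.r_structure,
        max_iter=base.model.spec.max_iter,
        tol=base.model.spec.tol,
        aicc_n=base.model.spec.aicc_n,
    )
    rows = []
    coef_tables: dict[str, pd.DataFrame] = {}
    threshold = aicc_threshold(panel.n_rivers)
    for name in names:
        series = covariates[name].reindex(panel.years)
        if series.isna().any():
            raise ValueError(f"covariate {name!r} incomplete over the panel years")
        fit = fit_dfa_covariate(panel, spec, series.rename(name))
        coef = fit.covariate_table()
        coef_tables[name] = coef
        rows.append(
            {
                "covariate": name,
                "dAICc": fit.AICc - base.AICc,
                "logLik": fit.loglik,
                "improves": bool(fit.AICc < base.AICc and fit.loglik > base.loglik),
                "exceeds_2S_threshold": bool(base.AICc - fit.AICc > threshold),
                "n_significant_rivers": int(coef["significant"].sum()),
                "converged": fit.converged,
            }
        )
    table = (
        pd.DataFrame(rows).sort_values("dAICc").reset_index(drop=True)
    )
    table.attrs["threshold_2S"] = threshold
    return table, coef_tables
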