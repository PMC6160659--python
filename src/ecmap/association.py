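"""Association of cluster-mean centrality with biological/cognitive markers.

Per subject, centrality is averaged inside the significant-cluster mask;
each marker is then related to the cluster mean by simple linear regression
on the whole sample and within each genotype-risk stratum, and the group
effect is assessed with a one-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MarkerFitResult",
    "StratumFit",
    "extract_cluster_means",
    "fit_marker",
    "group_anova",
    "marker_table",
    "MARKERS",
]

MARKERS = ["age", "csf_amyloid", "ngmv", "score_15ot", "tmt_a_s", "tmt_b_s"]


def extract_cluster_means(ec_volumes: np.ndarray, cluster_mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean of each subject's centrality inside the cluster mask.

    ``ec_volumes`` is (n_subjects, x, y, z); returns one scalar per subject.
    """
    vols = np.asarray(ec_volumes, dtype=np.float64)
    if vols.ndim != 4:
        raise ValueError("expected a (n_subjects, x, y, z) stack")
    if cluster_mask.shape != vols.shape[1:]:
        raise ValueError("cluster mask grid does not match the maps")
    if not cluster_mask.any():
        raise ValueError("cluster mask is empty")
    return vols[:, cluster_mask].mean(axis=1)


@dataclass
class StratumFit:
    slope: float
    p_value: float
    r_squared: float
    n: int


@dataclass
class MarkerFitResult:
    """Linear fits of cluster-mean centrality on one marker.

    ``adjusted_p`` is the marker-term p-value in a model that also contains
    the group indicator (the between-genotype column of the marker table);
    with ``interaction`` it is the marker-by-group interaction p instead.
    """

    marker: str
    whole: StratumFit
    by_group: dict[int, StratumFit]
    adjusted_p: float
    adjusted_model: str
    n_dropped: int = 0


def _simple_fit(x: np.ndarray, y: np.ndarray) -> StratumFit:
    if len(x) < 3:
        raise ValueError("need at least 3 observations per fitted stratum")
    if np.std(x) == 0:
        raise ValueError("marker has zero variance in a fitted stratum")
    res = stats.linregress(x, y)
    return StratumFit(
        slope=float(res.slope),
        p_value=float(res.pvalue),
        r_squared=float(res.rvalue**2),
        n=len(x),
    )


def fit_marker(
    cluster_means: np.ndarray,
    marker_values: np.ndarray,
    groups: np.ndarray,
    marker: str = "marker",
    interaction: bool = False,
) -> MarkerFitResult:
    """Regress cluster-mean centrality on a marker, whole-sample and per group.

    Missing marker values are dropped pairwise (the dropped count is
    recorded).  Slope, two-sided p for slope = 0 and R^2 are reported for
    the whole sample and for each genotype stratum.
    """
    ec = np.asarray(cluster_means, dtype=np.float64)
    mk = np.asarray(marker_values, dtype=np.float64)
    g = np.asarray(groups)
    if not (len(ec) == len(mk) == len(g)):
        raise ValueError("cluster means, marker and groups must be aligned")
    ok = np.isfinite(ec) & np.isfinite(mk)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"{marker}: dropped {n_dropped} subjects with missing values")
    ec, mk, g = ec[ok], mk[ok], g[ok]

    whole = _simple_fit(mk, ec)
    by_group: dict[int, StratumFit] = {}
    for lvl in np.unique(g):
        sel = g == lvl
        if sel.sum() < 3:
            warnings.warn(
                f"{marker}: stratum {lvl} has fewer than 3 observations; skipped"
            )
            continue
        by_group[int(lvl)] = _simple_fit(mk[sel], ec[sel])

    # marker effect adjusted for group (optionally the interaction term)
    gz = (g == np.max(g)).astype(float)
    if interaction:
        design = sm.add_constant(np.column_stack([mk, gz, mk * gz]))
        fit = sm.OLS(ec, design).fit()
        adjusted_p = float(fit.pvalues[3])
        model = "marker + group + marker:group"
    else:
        design = sm.add_constant(np.column_stack([mk, gz]))
        fit = sm.OLS(ec, design).fit()
        adjusted_p = float(fit.pvalues[1])
        model = "marker + group"
    return MarkerFitResult(
        marker=marker,
        whole=whole,
        by_group=by_group,
        adjusted_p=adjusted_p,
        adjusted_model=model,
        n_dropped=n_dropped,
    )


def group_anova(cluster_means: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of cluster means by group: (F, p)."""
    ec = np.asarray(cluster_means, dtype=np.float64)
    g = np.asarray(groups)
    levels = np.unique(g)
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    samples = [ec[g == lvl] for lvl in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 members")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def marker_table(
    cluster_means: np.ndarray,
    table: pd.DataFrame,
    markers: list[str] | None = None,
    interaction: bool = False,
) -> pd.DataFrame:
    """Fit every marker and lay the results out as one table.

    Columns mirror the association summary: whole-sample p, group-adjusted
    marker p, and per-stratum slope/p/R^2; a Bonferroni-corrected p column
    is appended as supplementary output (no correction is applied to the
    primary p-values).
    """
    if markers is None:
        markers = [m for m in MARKERS if m in table.columns]
    groups = table["group"].to_numpy()
    rows = []
    for m in markers:
        res = fit_marker(cluster_means, table[m].to_numpy(dtype=np.float64),
                         groups, marker=m, interaction=interaction)
        lo = res.by_group.get(0)
        hi = res.by_group.get(1)
        rows.append(
            {
                "marker": m,
                "p": res.whole.p_value,
                "slope": res.whole.slope,
                "r2": res.whole.r_squared,
                "p_adjusted_for_group": res.adjusted_p,
                "noncarrier_p": lo.p_value if lo else np.nan,
                "noncarrier_r2": lo.r_squared if lo else np.nan,
                "noncarrier_n": lo.n if lo else 0,
                "carrier_p": hi.p_value if hi else np.nan,
                "carrier_r2": hi.r_squared if hi else np.nan,
                "carrier_n": hi.n if hi else 0,
                "n_dropped": res.n_dropped,
            }
        )
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0)
    return df


def plot_marker_fits(cluster_means: np.ndarray, table: pd.DataFrame,
                     out_dir, markers: list[str] | None = None) -> list[str]:
    """Scatter of cluster-mean EC against each marker, colored by group,
    with per-stratum least-squares lines.  Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    if markers is None:
        markers = [m for m in MARKERS if m in table.columns]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ec = np.asarray(cluster_means, dtype=np.float64)
    groups = table["group"].to_numpy()
    paths = []
    for m in markers:
        mk = table[m].to_numpy(dtype=np.float64)
        fig, ax = plt.subplots(figsize=(4, 3))
        for lvl, color, label in [(0, "tab:blue", "noncarrier"),
                                  (1, "tab:red", "carrier")]:
            sel = groups == lvl
            ax.scatter(mk[sel], ec[sel], s=12, color=color, alpha=0.6,
                       label=label)
            if sel.sum() >= 3 and np.std(mk[sel]) > 0:
                coef = np.polyfit(mk[sel], ec[sel], 1)
                xs = np.linspace(mk[sel].min(), mk[sel].max(), 20)
                ax.plot(xs, np.polyval(coef, xs), color=color, lw=1.5)
        ax.set_xlabel(m)
        ax.set_ylabel("cluster-mean EC")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = out / f"fit_{m}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(str(path))
    return paths
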