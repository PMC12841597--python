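"""Per-donor age-prediction residuals and aging-rate synchronization.

The residual ("age acceleration") of a donor in one epigenetic layer is the
mean over that donor's tissues of predicted minus chronological age in
years: over-prediction is positive and reads as "epigenetically older than
the calendar age". Cross-layer synchronization is quantified by pairwise
Spearman correlation of residuals over shared donors; by default residuals
are first residualized against chronological age (ranked), so those
correlations are partial correlations controlling for age. The caloric
restriction comparison contrasts mouse residuals (in months) between diet
groups with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .age_stats import spearman_t_pvalue
from .clocks import donor_level

MONTHS_PER_YEAR = 12.0


def compute_residuals(records: pd.DataFrame) -> pd.DataFrame:
    """One row per donor x layer: residual_years (tissue-averaged predicted
    minus actual age) plus an age-adjusted variant.

    ``residual_adj`` is the residual of an ordinary least-squares fit of
    residual_years on the rank of actual age, computed within each
    (species, layer) group; it is uncorrelated with age by construction, so
    downstream cross-layer correlations are partial correlations given age.
    """
    table = donor_level(records)
    table["residual_years"] = table["predicted_years"] - table["actual_years"]
    adj = np.full(len(table), np.nan)
    for _, idx in table.groupby(["species", "layer"]).groups.items():
        sub = table.loc[idx]
        x = stats.rankdata(sub["actual_years"])
        y = sub["residual_years"].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        adj[table.index.get_indexer(idx)] = y - X @ beta
    table["residual_adj"] = adj
    return table[["donor_id", "layer", "species", "diet", "actual_years",
                  "residual_years", "residual_adj"]]


def layer_sync(table: pd.DataFrame, adjusted: bool = True,
               min_shared: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Layer x layer Spearman correlation of residuals over shared donors.

    Returns (rho matrix, p matrix); p from the Student-t model. Pairs
    sharing fewer than ``min_shared`` donors raise. The matrix is symmetric
    with unit diagonal.
    """
    col = "residual_adj" if adjusted else "residual_years"
    wide = table.pivot(index="donor_id", columns="layer", values=col)
    layers = wide.columns.tolist()
    rho = pd.DataFrame(np.eye(len(layers)), index=layers, columns=layers)
    pval = pd.DataFrame(np.zeros((len(layers), len(layers))), index=layers, columns=layers)
    for i, a in enumerate(layers):
        for b in layers[i + 1:]:
            pair = wide[[a, b]].dropna()
            if len(pair) < min_shared:
                raise ValueError(f"layers {a}/{b} share only {len(pair)} donors "
                                 f"(need >= {min_shared})")
            r, _ = stats.spearmanr(pair[a], pair[b])
            p = float(spearman_t_pvalue(r, len(pair)))
            rho.loc[a, b] = rho.loc[b, a] = float(r)
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def binned_residual_curve(table: pd.DataFrame, layer_x: str, layer_y: str,
                          bin_halfwidth_years: float = 1.0,
                          adjusted: bool = False) -> pd.DataFrame:
    """Mean layer-Y residual among donors with a similar layer-X residual.

    Donors are grouped around integer-year centers (the rounded layer-X
    residuals), each bin collecting donors within +/- ``bin_halfwidth_years``
    of its center; bins with fewer than two donors are dropped. Returns
    columns ``center, mean, se, n``.
    """
    col = "residual_adj" if adjusted else "residual_years"
    wide = table.pivot(index="donor_id", columns="layer", values=col)[[layer_x, layer_y]].dropna()
    x = wide[layer_x].to_numpy(dtype=float)
    y = wide[layer_y].to_numpy(dtype=float)
    rows = []
    for center in np.unique(np.round(x)):
        mask = np.abs(x - center) <= bin_halfwidth_years
        n = int(mask.sum())
        if n < 2:
            continue
        vals = y[mask]
        rows.append({"center": float(center), "mean": float(vals.mean()),
                     "se": float(vals.std(ddof=1) / np.sqrt(n)), "n": n})
    return pd.DataFrame(rows, columns=["center", "mean", "se", "n"])


def cr_comparison(table: pd.DataFrame, layers=("DNAm",),
                  species: str = "mouse") -> dict:
    """Compare age residuals between standard-diet and calorically
    restricted donors.

    Residuals (averaged over the requested layers per donor; pass all
    histone layers for the pooled-histone grouping) are reported in months
    for mice. Returns medians per diet, the median shift (CR minus
    standard), group sizes, and the two-sided Mann-Whitney U p-value.
    """
    sub = table[(table["species"] == species) & table["layer"].isin(list(layers))]
    per_donor = sub.groupby(["donor_id", "diet"], as_index=False)["residual_years"].mean()
    factor = MONTHS_PER_YEAR if species == "mouse" else 1.0
    groups = {diet: g["residual_years"].to_numpy() * factor
              for diet, g in per_donor.groupby("diet")}
    for diet in ("standard", "CR"):
        if diet not in groups or len(groups[diet]) == 0:
            raise ValueError(f"no {diet} donors for layers {list(layers)}")
    p = float(stats.mannwhitneyu(groups["CR"], groups["standard"],
                                 alternative="two-sided").pvalue)
    med_cr = float(np.median(groups["CR"]))
    med_std = float(np.median(groups["standard"]))
    return {
        "layers": list(layers),
        "unit": "months" if species == "mouse" else "years",
        "median_standard": med_std,
        "median_cr": med_cr,
        "median_shift": med_cr - med_std,
        "n_standard": len(groups["standard"]),
        "n_cr": len(groups["CR"]),
        "p": p,
    }
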