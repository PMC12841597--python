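"""Per-gene age associations and cross-layer / cross-species statistics.

Within each {species x layer} stratum, each gene's normalized signal is
correlated with donor age by Spearman's rho; two-sided p-values come from the
t approximation ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on n - 2 degrees of
freedom, with Benjamini-Hochberg q-values per stratum. On top of those
association tables:

* top-k overlap enrichment between layers or species (observed vs expected
  ``k^2 / G`` overlap of the k genes with the strongest unsigned association,
  two-sided binomial test, Bonferroni across tested pairs);
* the crosstalk statistic: the median difference of layer-B associations
  between layer-A's k most age-increasing and k most age-decreasing genes,
  tested by a two-sided Mann-Whitney U;
* direction-based gene-set selection (epigenetically repressed / activated
  with age) and a local hypergeometric gene-set enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gene_matrix import ACTIVATING_MARKS, REPRESSIVE_MARKS, GeneMatrix

#: Unordered pairs among the seven epigenetic layers: Bonferroni family for
#: the crosstalk tests.
N_LAYER_PAIRS = comb(7, 2)


def spearman_t_pvalue(rho: np.ndarray, n) -> np.ndarray:
    """Two-sided p for Spearman rho via the Student-t model on n-2 df.

    |rho| = 1 gives t = inf; the p-value is floored at the smallest positive
    double so it stays in (0, 1].
    """
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rho of two vectors with the t-model p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return 0.0, 1.0
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, float(spearman_t_pvalue(rho, len(x)))


def age_association(matrix: GeneMatrix, species: str | None = None,
                    layer: str | None = None) -> pd.DataFrame:
    """Per-gene Spearman association with chronological age in one stratum.

    Returns a frame indexed by gene with columns ``rho, n, p, q, constant``;
    constant gene columns are flagged and recorded as rho = 0, p = 1.
    Requires at least 4 samples.
    """
    sub = matrix
    if species is not None:
        sub = sub.select_species(species)
    if layer is not None:
        sub = sub.select_layers([layer])
    n = sub.n_samples
    if n < 4:
        raise ValueError(f"stratum has {n} samples; need >= 4 for age association")
    X = sub.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; harmonize before association")
    age_rank = stats.rankdata(sub.samples["age_years"].to_numpy())
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    ar = age_rank - age_rank.mean()
    gr = ranks - ranks.mean(axis=0)
    denom = np.sqrt((ar**2).sum()) * np.sqrt((gr**2).sum(axis=0))
    constant = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(constant, 0.0, (gr * ar[:, None]).sum(axis=0) / np.where(denom == 0, 1, denom))
    rho = np.clip(rho, -1.0, 1.0)
    p = np.where(constant, 1.0, spearman_t_pvalue(rho, n))
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"rho": rho, "n": n, "p": p, "q": np.clip(q, np.finfo(float).tiny, 1.0),
         "constant": constant},
        index=sub.values.columns.rename("gene_id"),
    )


def association_tables(matrix: GeneMatrix) -> dict[tuple[str, str], pd.DataFrame]:
    """Age-association tables for every {species x layer} stratum present."""
    out = {}
    for (sp, layer), _ in matrix.samples.groupby(["species", "layer"], sort=True):
        out[(sp, layer)] = age_association(matrix, species=sp, layer=layer)
    return out


def assoc_vector_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation between two strata's gene-level age associations
    over their shared gene universe."""
    shared = table_a.index.intersection(table_b.index)
    return spearman_with_p(table_a.loc[shared, "rho"], table_b.loc[shared, "rho"])


def _top_k(table: pd.DataFrame, k: int, by: str) -> pd.Index:
    """k top genes; ``by`` is 'abs' (unsigned), 'pos' or 'neg'.

    Ranking ties are broken by ascending gene_id for reproducibility.
    """
    if by == "abs":
        key = table["rho"].abs()
        ascending = False
    elif by == "pos":
        key, ascending = table["rho"], False
    elif by == "neg":
        key, ascending = table["rho"], True
    else:
        raise ValueError(f"unknown ranking {by!r}")
    order = key.sort_index().sort_values(ascending=ascending, kind="stable")
    return order.index[:k]


@dataclass
class EnrichmentResult:
    """Observed vs expected overlap of two top-k gene sets from universe G."""

    pair: tuple
    k_top: int
    universe: int
    observed: int
    expected: float
    fold: float
    p: float
    p_bonf: float


def top_k_overlap_enrichment(table_a: pd.DataFrame, table_b: pd.DataFrame, k: int = 1000,
                             pair: tuple = ("A", "B"), n_tests: int = 1,
                             null: str = "binomial") -> EnrichmentResult:
    """Overlap of the k genes with the strongest unsigned age association.

    expected = k^2 / G; fold = observed / expected. p is a two-sided exact
    binomial with success probability k/G over k trials (``null='hypergeom'``
    switches to the exact hypergeometric two-sided test); ``n_tests`` applies
    a Bonferroni factor.
    """
    shared = table_a.index.intersection(table_b.index)
    G = len(shared)
    if G <= k:
        raise ValueError(f"universe size {G} must exceed k={k}")
    top_a = set(_top_k(table_a.loc[shared], k, "abs"))
    top_b = set(_top_k(table_b.loc[shared], k, "abs"))
    observed = len(top_a & top_b)
    expected = k * k / G
    fold = observed / expected
    if null == "binomial":
        p = stats.binomtest(observed, n=k, p=k / G, alternative="two-sided").pvalue
    elif null == "hypergeom":
        p = hypergeom_two_sided(observed, G, k, k)
    else:
        raise ValueError(f"unknown null {null!r}")
    return EnrichmentResult(pair, k, G, observed, expected, fold,
                            float(p), float(min(1.0, p * n_tests)))


#: Cross-species concordance uses the identical contract.
cross_species_overlap = top_k_overlap_enrichment


def hypergeom_two_sided(observed: int, G: int, K: int, n: int) -> float:
    """Two-sided exact hypergeometric p: total probability of outcomes no
    more likely than the observed one."""
    support = np.arange(max(0, n + K - G), min(n, K) + 1)
    pmf = stats.hypergeom.pmf(support, G, K, n)
    p_obs = stats.hypergeom.pmf(observed, G, K, n)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-12)].sum()))


@dataclass
class CrosstalkResult:
    """Directional coupling of age-related change from layer A to layer B."""

    pair: tuple
    median_diff: float
    p: float
    p_bonf: float
    n_increasing: int
    n_decreasing: int


def crosstalk(table_a: pd.DataFrame, table_b: pd.DataFrame, k: int = 1000,
              pair: tuple = ("A", "B"), n_tests: int = N_LAYER_PAIRS) -> CrosstalkResult:
    """Median difference of layer-B rho between layer-A's k most positively
    and k most negatively age-associated genes, with a two-sided
    Mann-Whitney U test; Bonferroni over ``n_tests`` layer pairs."""
    shared = table_a.index.intersection(table_b.index)
    inc = _top_k(table_a.loc[shared], k, "pos")
    dec = _top_k(table_a.loc[shared], k, "neg")
    rho_inc = table_b.loc[inc, "rho"].to_numpy()
    rho_dec = table_b.loc[dec, "rho"].to_numpy()
    median_diff = float(np.median(rho_inc) - np.median(rho_dec))
    p = float(stats.mannwhitneyu(rho_inc, rho_dec, alternative="two-sided").pvalue)
    return CrosstalkResult(pair, median_diff, p, float(min(1.0, p * n_tests)),
                           len(inc), len(dec))


def significant_fraction(table: pd.DataFrame, q_threshold: float = 0.05) -> float:
    """Fraction of genes whose age association passes BH FDR < q_threshold."""
    return float((table["q"] < q_threshold).mean())


def all_layer_intersection(tables: dict, fdr_levels=(0.05, 0.1, 0.2)) -> pd.Series:
    """Number of genes significant (q < level) in *every* table, per level."""
    counts = {}
    frames = list(tables.values())
    shared = frames[0].index
    for t in frames[1:]:
        shared = shared.intersection(t.index)
    for level in fdr_levels:
        sig = np.ones(len(shared), dtype=bool)
        for t in frames:
            sig &= (t.loc[shared, "q"] < level).to_numpy()
        counts[level] = int(sig.sum())
    return pd.Series(counts, name="n_genes").rename_axis("fdr")


def select_direction_genesets(tables: dict[tuple[str, str], pd.DataFrame], k: int = 1000,
                              repressive=tuple(REPRESSIVE_MARKS),
                              activating=tuple(ACTIVATING_MARKS)) -> tuple[set, set]:
    """Genes with the strongest epigenetic repression / activation with age.

    Repressed-with-age = intersection over every available (species,
    repressive mark) table of its top-k most positively age-associated genes
    and over every (species, activating mark) table of its top-k most
    negatively associated genes. Activated-with-age is the converse.
    """
    repressed: set | None = None
    activated: set | None = None

    def _meet(current, new):
        return set(new) if current is None else current & set(new)

    for (_, layer), table in sorted(tables.items()):
        if layer in repressive:
            repressed = _meet(repressed, _top_k(table, k, "pos"))
            activated = _meet(activated, _top_k(table, k, "neg"))
        elif layer in activating:
            repressed = _meet(repressed, _top_k(table, k, "neg"))
            activated = _meet(activated, _top_k(table, k, "pos"))
    if repressed is None:
        raise ValueError("no recognized repressive/activating layers among tables")
    return repressed, activated


def geneset_enrichment(geneset: set, library: dict[str, set], universe: set) -> pd.DataFrame:
    """One-sided hypergeometric (Fisher exact) enrichment of ``geneset``
    against each term of a named gene-set library.

    Terms overlapping the query in fewer than two genes, or with a
    Benjamini-Hochberg adjusted p >= 0.05, are excluded from the returned
    table.
    """
    query = set(geneset) & set(universe)
    G, n = len(universe), len(query)
    rows = []
    for term, members in library.items():
        K = len(set(members) & set(universe))
        overlap = len(set(members) & query)
        if K == 0:
            continue
        p = float(stats.hypergeom.sf(overlap - 1, G, K, n))
        rows.append((term, overlap, K, p))
    table = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    if table.empty:
        return table.assign(q=pd.Series(dtype=float))
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table = table[(table["overlap"] >= 2) & (table["q"] < 0.05)]
    return table.sort_values("p").reset_index(drop=True)


def read_gmt(path) -> dict[str, set]:
    """Read a gene-set library in GMT format (term, description, genes...)."""
    library = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            library[fields[0]] = set(g for g in fields[2:] if g)
    return library


def pairwise_layer_stats(tables: dict[tuple[str, str], pd.DataFrame], species: str,
                         k: int = 1000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All unordered within-species layer-pair overlap enrichments and all
    ordered crosstalk results, with Bonferroni families sized accordingly."""
    layers = sorted(layer for sp, layer in tables if sp == species)
    pairs = [(a, b) for i, a in enumerate(layers) for b in layers[i + 1:]]
    n_pairs = len(pairs)
    overlap_rows, talk_rows = [], []
    for a, b in pairs:
        res = top_k_overlap_enrichment(tables[(species, a)], tables[(species, b)], k=k,
                                       pair=(a, b), n_tests=n_pairs)
        overlap_rows.append(vars(res))
    for a in layers:
        for b in layers:
            if a == b:
                continue
            res = crosstalk(tables[(species, a)], tables[(species, b)], k=k, pair=(a, b),
                            n_tests=n_pairs)
            talk_rows.append(vars(res))
    return pd.DataFrame(overlap_rows), pd.DataFrame(talk_rows)
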