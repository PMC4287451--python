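"""Per-TE-family enrichment of stress-responsive genes and response attribution.

For every TE family, the distinct *expressed* genes with an insertion near
their TSS are partitioned into up-regulated / down-regulated / non-DE, and
compared with the same partition of a background gene set via

* fold enrichment: the family's up (down) fraction over the background
  up (down) fraction, and
* a multinomial goodness-of-fit test: the probability, under
  Multinomial(n, background proportions), of a log-likelihood-ratio (G)
  statistic at least as extreme as observed.  Exact by full enumeration of
  compositions for small n, seeded Monte Carlo otherwise, with the
  chi-square asymptotic available as a cross-check.

A family is called enriched when it has over ``min_genes`` expressed
associated genes, fold enrichment over ``fe_threshold`` and p below
``p_threshold`` (all strict).  Attribution then asks what fraction of the
up-regulated transcriptome response sits next to an insertion from any
enriched family.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust

__all__ = [
    "build_contingency",
    "fold_enrichment",
    "multinomial_gof_test",
    "family_enrichment_table",
    "call_enriched_families",
    "percent_up",
    "attribute_response",
    "profile_gene_sets",
]

EXACT_ENUMERATION_MAX_N = 60

CLASSES = ("up", "down", "nonDE")


def build_contingency(
    associations: pd.DataFrame,
    contrasts: pd.DataFrame,
    background: str = "expressed_genes",
) -> pd.DataFrame:
    """Per-family observed class counts with background counts.

    A gene counts once per family regardless of its number of insertions;
    genes classified ``not_expressed`` are excluded everywhere.  Background
    modes: ``expressed_genes`` (all expressed genes in the contrast),
    ``all_genes`` (not_expressed genes fold into the non-DE background
    cell) and ``te_associated_genes`` (expressed genes with any TE
    association).
    """
    if background not in ("expressed_genes", "all_genes", "te_associated_genes"):
        raise ValueError(f"unknown background mode {background!r}")
    cls = contrasts.set_index("gene_id")["response_class"]
    shared = set(associations["gene_id"]) & set(cls.index)
    if associations.shape[0] and not shared:
        raise ValueError("associations and contrast summaries share no gene ids")

    if background == "te_associated_genes":
        bg_cls = cls[cls.index.isin(set(associations["gene_id"]))]
    else:
        bg_cls = cls
    bg_counts = bg_cls.value_counts()
    bg_up = int(bg_counts.get("up", 0))
    bg_down = int(bg_counts.get("down", 0))
    bg_nde = int(bg_counts.get("nonDE", 0))
    if background == "all_genes":
        bg_nde += int(bg_counts.get("not_expressed", 0))

    pairs = associations[["family", "gene_id"]].drop_duplicates()
    pairs = pairs[pairs["gene_id"].isin(cls.index)]
    pairs["response_class"] = cls.reindex(pairs["gene_id"]).values
    pairs = pairs[pairs["response_class"] != "not_expressed"]
    tab = (
        pairs.groupby(["family", "response_class"]).size().unstack(fill_value=0)
        .reindex(columns=CLASSES, fill_value=0)
    )
    out = pd.DataFrame(
        {
            "family": tab.index,
            "n_up": tab["up"].astype(int).values,
            "n_down": tab["down"].astype(int).values,
            "n_nde": tab["nonDE"].astype(int).values,
        }
    ).reset_index(drop=True)
    out["n_expressed"] = out[["n_up", "n_down", "n_nde"]].sum(axis=1)
    out["background"] = background
    out["bg_up"], out["bg_down"], out["bg_nde"] = bg_up, bg_down, bg_nde
    return out


def fold_enrichment(
    n_up: int, n_down: int, n_nde: int, bg_up: int, bg_down: int, bg_nde: int
) -> tuple[float, float]:
    """(fe_up, fe_down): family class fractions over background fractions.

    NaN (never a division error) when the family has no expressed genes or
    the background rate for the class is zero.
    """
    n = n_up + n_down + n_nde
    bg_n = bg_up + bg_down + bg_nde
    if n == 0 or bg_n == 0:
        return (np.nan, np.nan)
    fe_up = (n_up / n) / (bg_up / bg_n) if bg_up > 0 else np.nan
    fe_down = (n_down / n) / (bg_down / bg_n) if bg_down > 0 else np.nan
    return (fe_up, fe_down)


def _g_statistic(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Log-likelihood-ratio G = 2 * sum obs*log(obs/exp), 0*log0 := 0.

    Cells with zero expectation but nonzero observation yield +inf.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * (np.log(obs) - np.log(exp)), 0.0)
    return 2.0 * terms.sum(axis=-1)


def _enumerate_compositions(n: int, k: int = 3) -> np.ndarray:
    """All (n+1)(n+2)/2 ordered triples of non-negative ints summing to n."""
    assert k == 3
    i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    mask = i + j <= n
    a, b = i[mask], j[mask]
    return np.column_stack([a, b, n - a - b])


def multinomial_gof_test(
    observed: Sequence[int],
    expected_props: Sequence[float],
    method: str = "auto",
    n_mc: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Goodness-of-fit p-value for observed 3-cell counts vs expected proportions.

    ``method='exact'`` enumerates every composition of n (feasible for the
    small per-family gene counts this analysis sees); ``'monte_carlo'``
    samples ``n_mc`` multinomial draws with a seeded generator and applies
    the add-one estimator; ``'chisq'`` is the asymptotic cross-check.
    ``'auto'`` switches from exact to Monte Carlo above n = 60.
    """
    obs = np.asarray(observed, dtype=int)
    props = np.asarray(expected_props, dtype=float)
    if obs.shape != (3,) or props.shape != (3,):
        raise ValueError("expect 3 observed counts and 3 expected proportions")
    if (obs < 0).any():
        raise ValueError("observed counts must be non-negative")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"expected proportions sum to {props.sum()!r}, not 1")
    if (props < 0).any():
        raise ValueError("expected proportions must be non-negative")
    n = int(obs.sum())
    if n == 0:
        raise ValueError("n_expressed must be positive")

    if method == "auto":
        method = "exact" if n <= EXACT_ENUMERATION_MAX_N else "monte_carlo"
    g_obs = _g_statistic(obs, n * props)
    tol = 1e-9

    if method == "exact":
        comps = _enumerate_compositions(n)
        pmf = stats.multinomial.pmf(comps, n, props)
        g_all = _g_statistic(comps, n * props)
        return float(min(1.0, pmf[g_all >= g_obs - tol].sum()))
    if method == "monte_carlo":
        if rng is None:
            rng = np.random.default_rng(seed)
        draws = rng.multinomial(n, props, size=n_mc)
        g_sim = _g_statistic(draws, n * props)
        return float((1 + np.count_nonzero(g_sim >= g_obs - tol)) / (n_mc + 1))
    if method == "chisq":
        return float(stats.chi2.sf(g_obs, df=2))
    raise ValueError(f"unknown method {method!r}")


def family_enrichment_table(
    contingency: pd.DataFrame,
    method: str = "auto",
    n_mc: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fold enrichments, multinomial p and percent-up for every family row."""
    rng = np.random.default_rng(seed)
    rows = []
    for row in contingency.itertuples(index=False):
        fe_up, fe_down = fold_enrichment(
            row.n_up, row.n_down, row.n_nde, row.bg_up, row.bg_down, row.bg_nde
        )
        bg_n = row.bg_up + row.bg_down + row.bg_nde
        if row.n_expressed > 0 and bg_n > 0:
            props = np.array([row.bg_up, row.bg_down, row.bg_nde], dtype=float) / bg_n
            p = multinomial_gof_test(
                (row.n_up, row.n_down, row.n_nde), props, method=method, n_mc=n_mc, rng=rng
            )
            pct = percent_up(row.n_up, row.n_expressed)
        else:
            p, pct = np.nan, np.nan
        rows.append({"fe_up": fe_up, "fe_down": fe_down, "p_multinomial": p, "pct_up": pct})
    out = pd.concat([contingency.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    out["p_bh"] = bh_adjust(out["p_multinomial"])
    return out


def call_enriched_families(
    results: pd.DataFrame,
    min_genes: int = 10,
    fe_threshold: float = 2.0,
    p_threshold: float = 0.001,
) -> pd.DataFrame:
    """Flag enriched families; every threshold is strict (>, <)."""
    out = results.copy()
    eligible = out["n_expressed"] > min_genes
    sig = out["p_multinomial"] < p_threshold
    out["enriched_up"] = eligible & (out["fe_up"] > fe_threshold) & sig
    out["enriched_down"] = eligible & (out["fe_down"] > fe_threshold) & sig
    return out


def percent_up(n_up: int, n_expressed: int) -> float:
    """Percent of up-regulated genes among expressed TE-associated genes,
    reported to the nearest integer percent; NaN for an empty family."""
    if n_expressed == 0:
        return float("nan")
    return float(int(np.floor(100.0 * n_up / n_expressed + 0.5)))


def attribute_response(
    contrasts: pd.DataFrame,
    associations: pd.DataFrame,
    enriched_families: Iterable[str],
) -> dict:
    """Fraction of the up-regulated response attributable to enriched families.

    Among up-regulated genes (split into activated vs expressed-in-control),
    the proportion carrying at least one insertion of any enriched family in
    the window used to build ``associations``; a gene near two enriched
    families counts once.  The baseline is the same proportion over all
    expressed genes.
    """
    fams = set(enriched_families)
    assoc_genes = set(associations.loc[associations["family"].isin(fams), "gene_id"])
    up = contrasts[contrasts["response_class"] == "up"]
    activated = up[up["activated"]]
    up_expressed = up[~up["activated"]]
    expressed = contrasts[contrasts["response_class"] != "not_expressed"]

    def prop(df: pd.DataFrame) -> float:
        if df.shape[0] == 0:
            return float("nan")
        return float(df["gene_id"].isin(assoc_genes).mean())

    return {
        "n_up": int(up.shape[0]),
        "n_activated": int(activated.shape[0]),
        "prop_up_attributed": prop(up),
        "prop_activated_attributed": prop(activated),
        "prop_up_expressed_attributed": prop(up_expressed),
        "baseline_expressed_prop": prop(expressed),
    }


REQUIRED_ATTRIBUTES = [
    "length", "exon_count", "tissues_expressed", "fgs", "has_paralog", "has_ortholog", "has_go",
]


def profile_gene_sets(
    te_influenced: Iterable[str],
    other_up: Iterable[str],
    attributes: pd.DataFrame,
) -> pd.DataFrame:
    """Compare TE-influenced vs other up-regulated genes on gene attributes.

    ``attributes`` is indexed by gene_id with columns: length (bp),
    exon_count, tissues_expressed, and boolean fgs / has_paralog /
    has_ortholog / has_go.  Returns one summary row per group.
    """
    missing = [c for c in REQUIRED_ATTRIBUTES if c not in attributes.columns]
    if missing:
        raise ValueError(f"attribute table missing column(s): {missing}")
    groups = {"te_influenced": list(te_influenced), "non_te_influenced": list(other_up)}
    rows = []
    for name, ids in groups.items():
        sub = attributes.loc[attributes.index.intersection(ids)]
        rows.append(
            {
                "group": name,
                "n_genes": int(sub.shape[0]),
                "mean_length_bp": float(sub["length"].mean()),
                "mean_exon_number": float(sub["exon_count"].mean()),
                "pct_expressed_gt5_tissues": float(100 * (sub["tissues_expressed"] > 5).mean()),
                "mean_tissues_expressed": float(sub["tissues_expressed"].mean()),
                "pct_fgs": float(100 * sub["fgs"].mean()),
                "pct_with_paralogs": float(100 * sub["has_paralog"].mean()),
                "pct_with_orthologs": float(100 * sub["has_ortholog"].mean()),
                "pct_with_go": float(100 * sub["has_go"].mean()),
            }
        )
    return pd.DataFrame(rows).set_index("group")
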