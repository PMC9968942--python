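"""Relative-abundance summaries, Firmicutes/Bacteroidetes ratios, and
per-taxon intersite Wilcoxon rank-sum tests with multiplicity correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import CountTable, TaxonTable, aggregate_by_rank

logger = logging.getLogger("gutassembly")

_CORRECTIONS = {"bh": "fdr_bh", "fdr_bh": "fdr_bh",
                "bonferroni": "bonferroni", "holm": "holm"}

#: exact rank-sum p-values are used when both sites have at most this many samples
_EXACT_N = 8


def _as_taxon_table(table: CountTable, rank: str | None) -> CountTable:
    if rank is not None and not (isinstance(table, TaxonTable) and table.rank == rank):
        return aggregate_by_rank(table, rank)
    return table


@dataclass
class CompositionSummary:
    """Per-site composition at one rank, with the <threshold 'others' pool."""

    rank: str | None
    threshold: float
    rel_abundance: pd.DataFrame        # taxa x samples, columns sum to 1
    site_mean: pd.DataFrame            # taxa x sites
    site_sd: pd.DataFrame              # taxa x sites
    overall_mean: pd.Series            # pooled over all samples
    displayed_taxa: list               # overall mean >= threshold
    others_by_site: pd.Series          # 1 - sum of displayed taxa, per site
    site_sizes: pd.Series              # samples per site
    site_of_sample: pd.Series          # sample id -> site label


def summarize_composition(
    table: CountTable, rank: str | None = None, threshold: float = 0.01
) -> CompositionSummary:
    """Per-site mean ± SD relative abundance at ``rank``.

    Taxa whose pooled mean relative abundance is below ``threshold``
    (default 1%) are pooled into an "others" bucket per site.
    """
    table = _as_taxon_table(table, rank)
    rel = table.relative_abundance()
    site = table.meta["site"]
    site_mean = rel.T.groupby(site).mean().T
    site_sd = rel.T.groupby(site).std(ddof=1).T
    overall = rel.mean(axis=1)
    displayed = overall.index[overall.to_numpy() >= threshold].tolist()
    others = 1.0 - site_mean.loc[displayed].sum(axis=0)
    sizes = site.value_counts().sort_index()
    rank_label = getattr(table, "rank", None) if rank is None else rank
    return CompositionSummary(
        rank=rank_label, threshold=threshold, rel_abundance=rel,
        site_mean=site_mean, site_sd=site_sd, overall_mean=overall,
        displayed_taxa=displayed, others_by_site=others, site_sizes=sizes,
        site_of_sample=site.copy(),
    )


# ---------------------------------------------------------------------------
# Firmicutes / Bacteroidetes ratio
# ---------------------------------------------------------------------------

@dataclass
class FbRatio:
    """Firmicutes/Bacteroidetes ratios under both common conventions.

    ``per_site`` and ``overall_weighted`` are ratios of mean relative
    abundances (the overall means are sample-size-weighted site means, i.e.
    pooled means). ``per_site_mean_of_ratios`` / ``overall_mean_of_ratios``
    instead average the per-sample F/B ratio. The two conventions are not
    derivable from each other, so both are always reported.
    """

    per_site: dict
    overall_weighted: float
    per_site_mean_of_ratios: dict
    overall_mean_of_ratios: float
    flagged: bool = False  # True when a Bacteroidetes mean of zero forced inf


def weighted_overall_ratio(mean_f: dict, mean_b: dict, n: dict) -> float:
    """Ratio of sample-size-weighted overall means from per-site summary stats.

    Arguments map site -> mean Firmicutes fraction, mean Bacteroidetes
    fraction, and sample count. Useful for checking a published overall F/B
    against published per-site means.
    """
    sites = list(n)
    total = sum(n[s] for s in sites)
    f = sum(n[s] * mean_f[s] for s in sites) / total
    b = sum(n[s] * mean_b[s] for s in sites) / total
    return f / b if b > 0 else float("inf")


def fb_ratio(
    summary: CompositionSummary,
    firmicutes: str = "Firmicutes",
    bacteroidetes: str = "Bacteroidetes",
) -> FbRatio:
    """Firmicutes/Bacteroidetes ratio per site and overall (both conventions)."""
    for name in (firmicutes, bacteroidetes):
        if name not in summary.rel_abundance.index:
            raise KeyError(f"taxon {name!r} not present in the summary")
    mean_f = summary.site_mean.loc[firmicutes]
    mean_b = summary.site_mean.loc[bacteroidetes]
    flagged = bool((mean_b == 0).any())
    if flagged:
        logger.warning("Bacteroidetes mean is zero in some site; ratio is infinite")
    with np.errstate(divide="ignore"):
        per_site = (mean_f / mean_b).to_dict()
        n = summary.site_sizes.to_dict()
        overall = weighted_overall_ratio(mean_f.to_dict(), mean_b.to_dict(), n)

        sample_ratio = (summary.rel_abundance.loc[firmicutes]
                        / summary.rel_abundance.loc[bacteroidetes])
        mean_of_ratios = sample_ratio.groupby(summary.site_of_sample).mean()
    return FbRatio(
        per_site={k: float(v) for k, v in per_site.items()},
        overall_weighted=float(overall),
        per_site_mean_of_ratios={k: float(v) for k, v in mean_of_ratios.items()},
        overall_mean_of_ratios=float(np.mean(sample_ratio.to_numpy())),
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def diff_abundance(
    table: CountTable,
    rank: str | None = None,
    correction: str = "bh",
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per taxon between the two sites.

    Tests run on relative abundances. Exact p-values when both sites have
    <= 8 samples; otherwise the normal approximation with tie correction.
    Multiplicity is corrected across all taxa at the tested rank
    (Benjamini–Hochberg by default; ``bonferroni`` and ``holm`` available).
    Taxa constant across all samples get p = 1 and are flagged.

    Returns a DataFrame indexed by taxon with site means, raw and corrected
    p-values, and the direction of enrichment.
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    table = _as_taxon_table(table, rank)
    sites = sorted(table.meta["site"].unique())
    if len(sites) != 2:
        raise ValueError("diff_abundance needs exactly two sites")
    rel = table.relative_abundance()
    cols_a = table.meta.index[table.meta["site"] == sites[0]]
    cols_b = table.meta.index[table.meta["site"] == sites[1]]
    if min(len(cols_a), len(cols_b)) < 2:
        raise ValueError("each site needs at least two samples")
    x = rel[cols_a].to_numpy()
    y = rel[cols_b].to_numpy()

    constant = np.array([np.ptp(np.concatenate([xi, yi])) == 0
                         for xi, yi in zip(x, y)])
    method = "exact" if max(len(cols_a), len(cols_b)) <= _EXACT_N else "asymptotic"
    pvals = np.ones(rel.shape[0])
    stats_u = np.full(rel.shape[0], np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(rel.shape[0]):
            if constant[i]:
                continue
            res = stats.mannwhitneyu(x[i], y[i], alternative="two-sided",
                                     method=method)
            stats_u[i] = res.statistic
            pvals[i] = min(float(res.pvalue), 1.0)

    _, corrected, _, _ = multipletests(pvals, method=_CORRECTIONS[correction])
    corrected = np.maximum(corrected, pvals)  # corrected p never below raw p
    mean_a, mean_b = x.mean(axis=1), y.mean(axis=1)
    direction = np.where(constant, "none",
                         np.where(mean_a > mean_b, sites[0],
                                  np.where(mean_b > mean_a, sites[1], "none")))
    out = pd.DataFrame({
        f"mean_{sites[0]}": mean_a,
        f"mean_{sites[1]}": mean_b,
        "statistic": stats_u,
        "pvalue": pvals,
        "pvalue_corrected": np.minimum(corrected, 1.0),
        "direction": direction,
        "constant": constant,
    }, index=rel.index)
    out.index.name = rel.index.name or "taxon"
    return out.sort_values("pvalue")
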