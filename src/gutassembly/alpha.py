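"""Per-sample alpha diversity, rarefaction curves, and the intersite
mixed-model comparison.

Indices follow the mothur conventions used throughout mammal-gut 16S work:
Shannon in natural log, inverse Simpson as 1/Σp², bias-corrected Chao1,
the abundance-based coverage estimator (ACE) with the standard rare/abundant
cutoff of 10 reads, and Good's coverage 1 − singletons/reads.

The intersite comparison fits a Gaussian linear mixed model to
log10(index) with site as the fixed factor and social group as a random
intercept, and tests the site effect with a likelihood-ratio test of the
full model against the intercept-only model (both fitted by ML so the
likelihoods are comparable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .tables import CountTable, OtuTable, rarefy

logger = logging.getLogger("gutassembly")

ALPHA_INDICES = ("sobs", "shannon", "invsimpson", "chao1", "ace", "coverage")

_ACE_CUTOFF = 10  # reads; taxa at or below this count as "rare"


def _shannon(counts: np.ndarray, base: float | None = None) -> float:
    p = counts[counts > 0] / counts.sum()
    h = -(p * np.log(p)).sum()
    return h / np.log(base) if base else h


def _invsimpson(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return 1.0 / (p ** 2).sum()


def _chao1(counts: np.ndarray) -> float:
    sobs = int((counts > 0).sum())
    n1 = int((counts == 1).sum())
    n2 = int((counts == 2).sum())
    # bias-corrected form: well defined even when there are no doubletons
    return sobs + n1 * (n1 - 1) / (2.0 * (n2 + 1))


def _ace(counts: np.ndarray) -> float:
    c = counts[counts > 0]
    rare = c[c <= _ACE_CUTOFF]
    s_abund = int((c > _ACE_CUTOFF).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        # every rare taxon is a singleton; the estimator is undefined
        return float("nan")
    sum_i = float((rare * (rare - 1)).sum())
    gamma2 = max(s_rare / c_ace * sum_i / (n_rare * (n_rare - 1.0)) - 1.0, 0.0) \
        if n_rare > 1 else 0.0
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma2


def _coverage(counts: np.ndarray) -> float:
    n1 = int((counts == 1).sum())
    return 1.0 - n1 / counts.sum()


def alpha_indices(table: CountTable, shannon_base: float | None = None) -> pd.DataFrame:
    """Compute all alpha indices; one row per sample.

    Columns: ``sobs`` (observed taxa), ``shannon`` (natural log unless
    ``shannon_base`` given), ``invsimpson``, ``chao1`` (bias-corrected),
    ``ace`` (cutoff 10), ``coverage`` (Good's).
    """
    rows = {}
    for sample in table.sample_ids:
        c = table.counts[sample].to_numpy()
        if c.sum() == 0:
            raise ValueError(f"sample {sample!r} is empty")
        rows[sample] = {
            "sobs": int((c > 0).sum()),
            "shannon": _shannon(c, shannon_base),
            "invsimpson": _invsimpson(c),
            "chao1": _chao1(c),
            "ace": _ace(c),
            "coverage": _coverage(c),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")[list(ALPHA_INDICES)]
    df.index.name = "sample_id"
    return df


# ---------------------------------------------------------------------------
# rarefaction curves
# ---------------------------------------------------------------------------

def expected_sobs(counts: np.ndarray, depth: int) -> float:
    """Analytic E[observed taxa] in a without-replacement subsample of ``depth`` reads.

    Hypergeometric closed form: Σ_i (1 − C(N−N_i, d)/C(N, d)), computed in
    log space for stability.
    """
    c = counts[counts > 0].astype(np.int64)
    N = int(c.sum())
    if depth > N:
        raise ValueError("depth exceeds sample total")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    with np.errstate(invalid="ignore"):
        log_p0 = log_choose(N - c, depth) - log_choose(N, depth)
    p0 = np.where(N - c >= depth, np.exp(log_p0), 0.0)
    return float((1.0 - p0).sum())


def rarefaction_curve(
    table: OtuTable,
    depths: np.ndarray | list,
    statistic: str = "sobs",
    replicates: int = 10,
    seed: int = 0,
    method: str = "subsample",
) -> pd.DataFrame:
    """Mean ``statistic`` at each subsampling depth, per sample.

    ``method='subsample'`` averages Monte-Carlo rarefactions (``replicates``
    draws per depth); ``method='exact'`` uses the hypergeometric closed form
    (``statistic='sobs'`` only), which is exactly monotone in depth.
    Returns a DataFrame indexed by depth with one column per sample.
    """
    depths = [int(d) for d in depths]
    if len(depths) == 0:
        raise ValueError("depth grid is empty")
    if statistic not in ("sobs", "shannon"):
        raise ValueError("statistic must be 'sobs' or 'shannon'")
    min_depth = int(table.depth.min())
    if max(depths) > min_depth:
        raise ValueError(f"depths exceed the shallowest sample ({min_depth} reads)")

    if method == "exact":
        if statistic != "sobs":
            raise ValueError("the analytic curve is available for 'sobs' only")
        data = {
            s: [expected_sobs(table.counts[s].to_numpy(), d) for d in depths]
            for s in table.sample_ids
        }
        return pd.DataFrame(data, index=pd.Index(depths, name="depth"))

    ss = np.random.SeedSequence(seed)
    stat_fn = (lambda c: float((c > 0).sum())) if statistic == "sobs" else _shannon
    acc = {s: np.zeros(len(depths)) for s in table.sample_ids}
    for child in ss.spawn(replicates):
        rng = np.random.default_rng(child)
        for s in table.sample_ids:
            col = table.counts[s].to_numpy()
            for k, d in enumerate(depths):
                sub = rng.multivariate_hypergeometric(col, d)
                acc[s][k] += stat_fn(sub)
    data = {s: acc[s] / replicates for s in table.sample_ids}
    return pd.DataFrame(data, index=pd.Index(depths, name="depth"))


# ---------------------------------------------------------------------------
# intersite comparison: LMM with likelihood-ratio test
# ---------------------------------------------------------------------------

@dataclass
class LmmComparison:
    """Likelihood-ratio comparison of one alpha index between sites."""

    index_name: str
    chi2: float
    df: int
    p_value: float
    fixed_effect_estimate: float  # site effect on the log10 scale
    method: str = "lmm_lrt"  # 'wilcoxon_fallback' when the LMM fit fails


def _lmm_lrt(values: pd.Series, site: pd.Series, group: pd.Series) -> tuple:
    import statsmodels.api as sm

    y = np.log10(values.to_numpy(dtype=float))
    x_full = pd.get_dummies(site, drop_first=True, dtype=float)
    exog_full = np.column_stack([np.ones_like(y), x_full.to_numpy().ravel()])
    exog_null = np.ones((y.size, 1))
    groups = group.to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MixedLM(y, exog_full, groups=groups).fit(reml=False)
        null = sm.MixedLM(y, exog_null, groups=groups).fit(reml=False)
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p, float(full.fe_params[1])


def compare_alpha_lmm(
    alpha: pd.DataFrame,
    meta: pd.DataFrame,
    indices: tuple = ("shannon", "invsimpson", "chao1", "ace"),
) -> list[LmmComparison]:
    """Compare alpha indices between the two sites with an LMM LRT.

    The response is log10(index); site is the fixed factor, social group a
    random intercept; both full and null models are fitted by ML and the
    LRT statistic referred to chi-square with 1 df. If a mixed-model fit
    fails (singular random-effects structure, non-convergence), the result
    falls back to a Wilcoxon rank-sum p-value, flagged via ``method``.
    """
    meta = meta.loc[alpha.index]
    site = meta["site"].astype(str)
    group = meta["social_group"].astype(str)
    if site.nunique() < 2:
        raise ValueError("site must have two observed levels")
    if group.nunique() < 2:
        raise ValueError("need at least two social groups for a random intercept")

    levels = sorted(site.unique())
    results = []
    for name in indices:
        values = alpha[name].astype(float)
        if values.isna().any() or (values <= 0).any():
            logger.warning("index %s has non-positive or missing values; skipped", name)
            continue
        try:
            chi2, p, est = _lmm_lrt(values, site, group)
            results.append(LmmComparison(name, chi2, 1, p, est))
        except Exception as exc:  # singular fit / convergence failure
            logger.warning("LMM failed for %s (%s); Wilcoxon fallback", name, exc)
            a = np.log10(values[site == levels[0]])
            b = np.log10(values[site == levels[1]])
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            results.append(LmmComparison(name, float("nan"), 1, float(p),
                                         float(b.mean() - a.mean()),
                                         method="wilcoxon_fallback"))
    return results


def mean_alpha_over_rounds(
    table: OtuTable, depth: int | None, rounds: int, seed: int
) -> pd.DataFrame:
    """Average alpha indices over repeated independent rarefactions.

    For users who read "leveling twice" as two independent draws whose index
    estimates are averaged; ``rounds=1`` reduces to a single rarefaction.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    frames = []
    for child in np.random.SeedSequence(seed).spawn(rounds):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        frames.append(alpha_indices(rarefy(table, depth, seed=sub_seed)))
    out = sum(frames[1:], frames[0].copy()) / rounds
    return out
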