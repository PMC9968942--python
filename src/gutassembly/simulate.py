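"""Synthetic OTU tables with known ground truth.

Two generators cover the study design end to end:

* :func:`simulate_neutral` — communities assembled *exactly* under the
  Sloan neutral model: each taxon's local relative abundance in each host
  is a Beta(N·m·p_i, N·m·(1−p_i)) draw around its metacommunity abundance
  p_i, so the migration rate ``m`` driving occupancy is known and can be
  compared with the value the fitter recovers.

* :func:`simulate_two_site` — a two-site survey table (default 155 vs 48
  samples across nine social groups, ~3,000 OTUs, uniform depth) with
  Dirichlet–multinomial noise, planted per-taxon site effects on the
  log scale, and group-level random intercepts, so differential-abundance
  calls, mixed-model comparisons and classifier importances can be checked
  against a truth record.

All randomness in a generator flows from the single ``seed`` through
spawned, independent streams, so the draw for one component can never
shift another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import RANKS, OtuTable

# Phylum pool for synthetic lineages, weighted roughly like a folivorous
# primate gut (Firmicutes-dominated, Bacteroidetes second).
_PHYLA = [
    ("Firmicutes", 0.55),
    ("Bacteroidetes", 0.15),
    ("Actinobacteria", 0.08),
    ("Proteobacteria", 0.07),
    ("Campylobacterota", 0.04),
    ("Verrucomicrobiota", 0.03),
    ("Spirochaetota", 0.03),
    ("Desulfobacterota", 0.02),
    ("Cyanobacteria", 0.02),
    ("Fibrobacterota", 0.01),
]


@dataclass
class NeutralSimSpec:
    """Parameters of an exactly-neutral community simulation.

    ``reads_per_sample`` is the local community size N (uniform depth, as
    after rarefaction); ``m`` is the migration probability in (0, 1];
    ``source_abundances`` is the metacommunity relative-abundance vector p
    (defaults to a normalised log-normal with ``lognormal_sigma``, giving
    the long-tailed abundance distribution real 16S tables show).
    """

    n_taxa: int = 3000
    n_samples: int = 100
    reads_per_sample: int = 20000
    m: float = 0.1
    source_abundances: np.ndarray | None = None
    lognormal_sigma: float = 1.5
    count_model: str = "quantize"  # or "multinomial" / "binomial"
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2 or self.n_samples < 1:
            raise ValueError("need at least 2 taxa and 1 sample")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if not (0 < self.m <= 1):
            raise ValueError("migration rate m must be in (0, 1]")
        if self.count_model not in ("quantize", "multinomial", "binomial"):
            raise ValueError("count_model must be 'quantize', 'multinomial' or 'binomial'")
        if self.source_abundances is not None:
            p = np.asarray(self.source_abundances, dtype=float)
            if p.shape != (self.n_taxa,):
                raise ValueError("source_abundances must have length n_taxa")
            if np.any(p <= 0) or not np.isclose(p.sum(), 1.0, atol=1e-12):
                raise ValueError("source_abundances must be positive and sum to 1")
            self.source_abundances = p


@dataclass
class NeutralTruth:
    m: float
    N: int
    Nm: float
    source_abundances: np.ndarray


@dataclass
class TwoSiteSimSpec:
    """Parameters of the two-site Dirichlet–multinomial survey simulation.

    Site B taxon weights are ``base × exp(log_fold_effects)``; each social
    group perturbs every taxon's log-weight by an independent
    N(0, ``group_sd``) intercept; each sample's composition is
    Dirichlet(``dispersion`` × weights) and its counts one multinomial draw
    of ``reads_per_sample`` reads (uniform depth, as after rarefaction).

    Defaults emulate the study design: 155 vs 48 samples, nine social
    groups, ~3,000 taxa. ``dispersion`` (the Dirichlet concentration mass)
    defaults to 50 — strong sample-to-sample compositional noise, typical
    of mammal-gut 16S surveys; ``group_sd`` defaults to 0.3, a moderate
    group-level signature.
    """

    n_taxa: int = 3000
    n_samples_a: int = 155
    n_samples_b: int = 48
    reads_per_sample: int = 20000
    base_abundances: np.ndarray | None = None
    lognormal_sigma: float = 1.5
    log_fold_effects: np.ndarray | None = None
    dispersion: float = 50.0
    group_sd: float = 0.3
    n_groups_a: int = 5
    n_groups_b: int = 4
    site_names: tuple = ("siteA", "siteB")
    seed: int = 0

    def __post_init__(self):
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.group_sd < 0:
            raise ValueError("group_sd must be non-negative")
        if min(self.n_samples_a, self.n_samples_b) < 1:
            raise ValueError("each site needs at least one sample")
        if min(self.n_groups_a, self.n_groups_b) < 1:
            raise ValueError("each site needs at least one group")
        if self.base_abundances is not None:
            p = np.asarray(self.base_abundances, dtype=float)
            if p.shape != (self.n_taxa,):
                raise ValueError("base_abundances must have length n_taxa")
            if np.any(p <= 0):
                raise ValueError("base_abundances must be positive")
            self.base_abundances = p / p.sum()
        if self.log_fold_effects is not None:
            eff = np.asarray(self.log_fold_effects, dtype=float)
            if eff.shape != (self.n_taxa,):
                raise ValueError("log_fold_effects must have length n_taxa")
            if not np.all(np.isfinite(eff)):
                raise ValueError("log_fold_effects must be finite")
            self.log_fold_effects = eff


@dataclass
class TwoSiteTruth:
    base_abundances: np.ndarray
    log_fold_effects: np.ndarray
    affected_taxa: list
    group_log_intercepts: dict
    dispersion: float
    group_sd: float


def _otu_ids(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"OTU{i + 1:0{width}d}" for i in range(n)]


def _synthetic_lineages(ids: Sequence[str], rng: np.random.Generator) -> pd.DataFrame:
    n = len(ids)
    names, probs = zip(*_PHYLA)
    phyla = rng.choice(names, size=n, p=np.asarray(probs) / sum(probs))
    cl = rng.integers(1, 6, n)
    order = rng.integers(1, 11, n)
    fam = rng.integers(1, 31, n)
    gen = rng.integers(1, 9, n)
    families = np.char.add(phyla.astype(str), [f"_fam{k:02d}" for k in fam])
    frame = pd.DataFrame({
        "domain": "Bacteria",
        "phylum": phyla,
        "class": np.char.add(phyla.astype(str), [f"_cl{k}" for k in cl]),
        "order": np.char.add(phyla.astype(str), [f"_ord{k}" for k in order]),
        "family": families,
        "genus": np.char.add(families, [f"_gen{k}" for k in gen]),
    }, index=list(ids))
    return frame[list(RANKS)]


def _source_abundances(n_taxa: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    w = rng.lognormal(mean=0.0, sigma=sigma, size=n_taxa)
    return w / w.sum()


def _quantize_composition(comp: np.ndarray, N: int) -> np.ndarray:
    """Apportion exactly N reads to a simplex composition, respecting the
    1/N detection limit.

    Taxa with relative abundance above 1/N receive ``floor(N·x)`` reads and
    the leftover reads go to the largest fractional parts among those same
    taxa (largest-remainder apportionment). Taxa below the detection limit
    receive no reads, so presence in the table is exactly ``x > 1/N`` — the
    event the Sloan occupancy formula describes.
    """
    target = N * comp
    counts = np.floor(target).astype(np.int64)
    detected = counts >= 1
    remainder = N - int(counts.sum())
    if not detected.any():
        counts[np.argmax(target)] = N
        return counts
    frac = np.where(detected, target - counts, -1.0)
    top = np.argsort(frac)[::-1][:remainder]
    counts[top] += 1
    return counts


def simulate_neutral(spec: NeutralSimSpec) -> tuple[OtuTable, NeutralTruth]:
    """Simulate a community assembled exactly under the Sloan neutral model.

    Returns the OTU table and a truth record holding ``m``, ``N`` and the
    metacommunity abundances. In Sloan's continuous approximation the Beta
    distribution describes the realised composition of the N-individual
    local community itself, so with ``count_model='quantize'`` (default)
    the Beta draws are renormalised to the simplex and deterministically
    apportioned into exactly N reads with presence matching the 1/N
    detection limit — the table is then neutral *as the occupancy model
    sees it*. ``'multinomial'`` instead treats the reads as one
    Multinomial(N, ·) sample of the composition (extra observation noise
    that inflates fitted Nm), and ``'binomial'`` keeps the textbook
    per-taxon Binomial(N, x_ij) form (depth then varies around N).
    """
    ss = np.random.SeedSequence(spec.seed)
    r_src, r_beta, r_counts, r_tax = [np.random.default_rng(c) for c in ss.spawn(4)]

    p = spec.source_abundances
    if p is None:
        p = _source_abundances(spec.n_taxa, spec.lognormal_sigma, r_src)
    N = spec.reads_per_sample
    Nm = N * spec.m
    a, b = Nm * p, Nm * (1.0 - p)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("Beta parameters N*m*p and N*m*(1-p) must be positive")

    x = r_beta.beta(a[:, None], b[:, None], size=(spec.n_taxa, spec.n_samples))
    if spec.count_model == "quantize":
        comp = x / x.sum(axis=0, keepdims=True)
        counts = np.column_stack(
            [_quantize_composition(comp[:, j], N) for j in range(spec.n_samples)]
        )
    elif spec.count_model == "multinomial":
        comp = x / x.sum(axis=0, keepdims=True)
        counts = np.column_stack(
            [r_counts.multinomial(N, comp[:, j]) for j in range(spec.n_samples)]
        )
    else:
        counts = r_counts.binomial(N, x)

    ids = _otu_ids(spec.n_taxa)
    samples = [f"S{j + 1:04d}" for j in range(spec.n_samples)]
    counts_df = pd.DataFrame(counts, index=ids, columns=samples)
    lineages = _synthetic_lineages(ids, r_tax)
    meta = pd.DataFrame({
        "sample_id": samples,
        "site": "siteA",
        "social_group": [f"g{(j % 3) + 1}" for j in range(spec.n_samples)],
    }).set_index("sample_id")
    table = OtuTable(counts_df, lineages, meta)
    return table, NeutralTruth(m=spec.m, N=N, Nm=Nm, source_abundances=p)


def neutral_occurrence_probability(p, N: int, m: float, detection_limit: float | None = None):
    """Closed-form neutral occupancy: P(local abundance > d) for source abundance p.

    This is the survival function of Beta(N·m·p, N·m·(1−p)) at the detection
    limit d (default 1/N) — the analytic curve the simulator's empirical
    occurrence frequencies must follow.
    """
    from scipy.stats import beta as beta_dist

    d = 1.0 / N if detection_limit is None else detection_limit
    p = np.asarray(p, dtype=float)
    return beta_dist.sf(d, N * m * p, N * m * (1.0 - p))


def simulate_two_site(spec: TwoSiteSimSpec) -> tuple[OtuTable, TwoSiteTruth]:
    """Simulate a two-site survey table with planted effects and group structure."""
    ss = np.random.SeedSequence(spec.seed)
    r_src, r_grp, r_dir, r_cnt, r_tax = [np.random.default_rng(c) for c in ss.spawn(5)]

    base = spec.base_abundances
    if base is None:
        base = _source_abundances(spec.n_taxa, spec.lognormal_sigma, r_src)
    effects = spec.log_fold_effects
    if effects is None:
        effects = np.zeros(spec.n_taxa)

    site_a, site_b = spec.site_names
    log_w = {site_a: np.log(base), site_b: np.log(base) + effects}
    if not all(np.all(np.isfinite(v)) for v in log_w.values()):
        raise ValueError("non-finite site weights")

    ids = _otu_ids(spec.n_taxa)
    groups = (
        [(site_a, f"A{g + 1}") for g in range(spec.n_groups_a)]
        + [(site_b, f"B{g + 1}") for g in range(spec.n_groups_b)]
    )
    group_intercepts = {
        g: r_grp.normal(0.0, spec.group_sd, size=spec.n_taxa) if spec.group_sd > 0
        else np.zeros(spec.n_taxa)
        for _, g in groups
    }

    sample_rows, columns = [], []
    counters = {site_a: 0, site_b: 0}
    n_per_site = {site_a: spec.n_samples_a, site_b: spec.n_samples_b}
    groups_per_site = {site_a: [g for s, g in groups if s == site_a],
                       site_b: [g for s, g in groups if s == site_b]}
    for site in (site_a, site_b):
        site_groups = groups_per_site[site]
        for j in range(n_per_site[site]):
            group = site_groups[j % len(site_groups)]
            lw = log_w[site] + group_intercepts[group]
            w = np.exp(lw - lw.max())
            w /= w.sum()
            comp = r_dir.dirichlet(spec.dispersion * w)
            counts = r_cnt.multinomial(spec.reads_per_sample, comp)
            counters[site] += 1
            sid = f"{site}_{counters[site]:03d}"
            columns.append(counts)
            sample_rows.append({"sample_id": sid, "site": site, "social_group": group})

    counts_df = pd.DataFrame(
        np.column_stack(columns), index=ids,
        columns=[r["sample_id"] for r in sample_rows],
    )
    meta = pd.DataFrame(sample_rows).set_index("sample_id")
    lineages = _synthetic_lineages(ids, r_tax)
    table = OtuTable(counts_df, lineages, meta)
    truth = TwoSiteTruth(
        base_abundances=base,
        log_fold_effects=effects,
        affected_taxa=[ids[i] for i in np.nonzero(effects)[0]],
        group_log_intercepts=group_intercepts,
        dispersion=spec.dispersion,
        group_sd=spec.group_sd,
    )
    return table, truth
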