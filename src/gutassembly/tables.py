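"""OTU count tables with taxonomy and per-sample metadata.

The central container is :class:`OtuTable`: a non-negative integer count
matrix oriented **taxa (rows) x samples (columns)**, one taxonomic lineage
per OTU (domain through genus), and one metadata row per sample (``site``
and ``social_group``). Every downstream stage — diversity, ordination,
differential abundance, the neutral community model, the random-forest
classifier — consumes this object or the rank-aggregated
:class:`TaxonTable` derived from it.

All operations document and preserve the taxa-x-samples orientation; there
is no silent transposition anywhere in the package.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("gutassembly")

#: Taxonomic ranks handled by the package, most to least inclusive.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_PREFIX_TO_RANK = {
    "k": "domain",  # QIIME "kingdom" prefix maps onto the domain slot
    "d": "domain",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
}
_RANK_TO_PREFIX = {"domain": "k", "phylum": "p", "class": "c",
                   "order": "o", "family": "f", "genus": "g"}


class LineageParseError(ValueError):
    """A taxonomy string could not be interpreted."""


class TableValidationError(ValueError):
    """An OTU table violated a structural contract."""


def parse_lineage(lineage: str, otu_id: str | None = None) -> dict:
    """Parse a semicolon-delimited lineage string into a rank -> label dict.

    QIIME-style single-letter prefixes (``k__``, ``d__``, ``p__`` ... ``g__``)
    are accepted and stripped; tokens without a recognised prefix are
    assigned positionally. Placeholder labels such as
    ``norank_o__Clostridia_UCG-014`` or ``unclassified_f__X`` are ordinary
    labels and are preserved verbatim — they are never coerced to missing.
    Ranks absent from the string become empty-string placeholders. Tokens
    beyond genus (e.g. species) are ignored.

    Raises :class:`LineageParseError` if the string is empty or the domain
    label is missing.
    """
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        raise LineageParseError(f"missing lineage for OTU {otu_id!r}")
    tokens = [t.strip() for t in str(lineage).split(";")]
    tokens = [t for t in tokens if t != ""] or [""]
    labels = {rank: "" for rank in RANKS}
    position = 0
    for token in tokens:
        if len(token) >= 3 and token[1:3] == "__" and token[0].lower() in _PREFIX_TO_RANK:
            rank = _PREFIX_TO_RANK[token[0].lower()]
            label = token[3:]
            if rank == "genus":
                position = len(RANKS)  # anything after genus is ignored
            else:
                position = RANKS.index(rank) + 1
        else:
            if position >= len(RANKS):
                continue
            rank = RANKS[position]
            label = token
            position += 1
        labels[rank] = label
    if labels["domain"] == "":
        raise LineageParseError(
            f"lineage {lineage!r} for OTU {otu_id!r} has no domain label"
        )
    return labels


def lineage_to_string(labels: Mapping[str, str]) -> str:
    """Serialise a rank -> label mapping back to a prefixed lineage string."""
    return ";".join(f"{_RANK_TO_PREFIX[r]}__{labels.get(r, '')}" for r in RANKS)


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate taxon ids: {dups[:5]}")
    if counts.columns.has_duplicates:
        dups = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate sample ids: {dups[:5]}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise TableValidationError("counts must be numeric")
    if np.any(values < 0):
        raise TableValidationError("counts must be non-negative")
    if not np.allclose(values, np.round(values)):
        bad = counts.index[np.any(values != np.round(values), axis=1)][:5].tolist()
        raise TableValidationError(f"non-integer counts in taxa {bad}")
    return counts.astype(np.int64)


class CountTable:
    """Base container: integer counts (taxa x samples) plus sample metadata.

    All-zero sample columns are dropped at construction with a warning so
    that per-sample quantities (relative abundances, diversity indices) are
    always defined.
    """

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame, *, validate: bool = True):
        counts = pd.DataFrame(counts)
        meta = pd.DataFrame(meta)
        if validate:
            counts = _validate_counts(counts)
            if meta.index.name != "sample_id" and "sample_id" in meta.columns:
                meta = meta.set_index("sample_id")
            missing_cols = [c for c in ("site", "social_group") if c not in meta.columns]
            if missing_cols:
                raise TableValidationError(f"metadata lacks columns {missing_cols}")
            if meta.index.has_duplicates:
                raise TableValidationError("duplicate sample ids in metadata")
            absent = [s for s in counts.columns if s not in meta.index]
            if absent:
                raise TableValidationError(
                    f"samples missing from metadata: {absent}"
                )
            empty = counts.columns[counts.sum(axis=0).to_numpy() == 0].tolist()
            if empty:
                logger.warning("dropping all-zero samples: %s", empty)
                counts = counts.drop(columns=empty)
                if counts.shape[1] == 0:
                    raise TableValidationError("all samples are empty")
            meta = meta.loc[counts.columns, ["site", "social_group"]].copy()
            meta = meta.astype(str)
            meta.index.name = "sample_id"
            counts.columns.name = None
        self.counts = counts
        self.meta = meta

    # -- basic accessors -------------------------------------------------
    @property
    def taxon_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def depth(self) -> pd.Series:
        """Per-sample read totals (column sums)."""
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by per-sample depth; columns sum to 1."""
        return self.counts / self.depth

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{type(self).__name__} {self.n_taxa} taxa x {self.n_samples} samples>"


class OtuTable(CountTable):
    """Counts + lineages + metadata; the pipeline's single source of truth."""

    def __init__(self, counts, lineages: pd.DataFrame, meta, *, validate: bool = True):
        super().__init__(counts, meta, validate=validate)
        lineages = pd.DataFrame(lineages)
        if validate:
            missing = [o for o in self.counts.index if o not in lineages.index]
            if missing:
                raise TableValidationError(
                    f"OTUs missing from taxonomy: {missing[:5]}"
                )
            lineages = lineages.loc[self.counts.index, list(RANKS)].astype(str)
            self.counts.index.name = "otu_id"
            lineages.index.name = "otu_id"
        self.lineages = lineages

    def copy(self) -> "OtuTable":
        return OtuTable(self.counts.copy(), self.lineages.copy(), self.meta.copy(),
                        validate=False)

    # -- lossless round trip ---------------------------------------------
    def to_dir(self, path: str | Path) -> Path:
        """Write counts/taxonomy/metadata TSVs; round-trips losslessly."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.counts.rename_axis("otu_id").to_csv(path / "counts.tsv", sep="\t")
        self.lineages.rename_axis("otu_id").to_csv(path / "taxonomy.tsv", sep="\t")
        self.meta.rename_axis("sample_id").to_csv(path / "metadata.tsv", sep="\t")
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "OtuTable":
        path = Path(path)
        counts = pd.read_csv(path / "counts.tsv", sep="\t", index_col=0)
        lineages = pd.read_csv(path / "taxonomy.tsv", sep="\t", index_col=0,
                               keep_default_na=False, dtype=str)
        meta = pd.read_csv(path / "metadata.tsv", sep="\t", index_col=0, dtype=str)
        counts.columns = counts.columns.astype(str)
        return cls(counts, lineages, meta)


class TaxonTable(CountTable):
    """Counts aggregated to one taxonomic rank (rows indexed by taxon label)."""

    def __init__(self, counts, meta, rank: str, *, validate: bool = True):
        super().__init__(counts, meta, validate=validate)
        self.rank = rank


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a counts TSV (first column = OTU id, header = sample ids).

    Accepts the BIOM-TSV dialect: a leading ``# Constructed from biom file``
    comment line and a header starting with ``#OTU ID``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        second = fh.readline()
    skip = 0
    if first.startswith("#") and "\t" not in first:
        skip = 1
    elif first.startswith("#") and second.startswith("#") and "\t" in second:
        skip = 1  # comment line followed by '#OTU ID' header
    counts = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    counts.index.name = "otu_id"
    return counts


def _read_taxonomy_tsv(path: str | Path) -> pd.Series:
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str,
                      keep_default_na=False)
    if raw.shape[1] < 2:
        raise TableValidationError(f"taxonomy file {path} needs >= 2 columns")
    first_val = raw.iloc[0, 1]
    looks_like_header = ";" not in first_val and "__" not in first_val
    if looks_like_header:
        raw = raw.iloc[1:]
    return pd.Series(raw.iloc[:, 1].values, index=raw.iloc[:, 0].values)


def read_otu_table(counts_path, taxonomy_path, metadata_path) -> OtuTable:
    """Assemble a validated :class:`OtuTable` from three TSV files.

    ``counts``: first column OTU id, header row = sample ids (plain or
    BIOM-TSV dialect). ``taxonomy``: two columns, OTU id and a
    semicolon-delimited lineage (QIIME prefixes accepted). ``metadata``:
    columns ``sample_id``, ``site``, ``social_group``.
    """
    counts = _read_counts_tsv(counts_path)
    tax_strings = _read_taxonomy_tsv(taxonomy_path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise TableValidationError("metadata must contain a 'sample_id' column")
    meta = meta.set_index("sample_id")

    missing_tax = [o for o in counts.index if o not in tax_strings.index]
    if missing_tax:
        raise TableValidationError(f"OTUs missing from taxonomy: {missing_tax[:5]}")
    records = {otu: parse_lineage(tax_strings[otu], otu) for otu in counts.index}
    lineages = pd.DataFrame.from_dict(records, orient="index")[list(RANKS)]
    return OtuTable(counts, lineages, meta)


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def filter_to_domain(table: OtuTable, domain: str = "Bacteria") -> OtuTable:
    """Retain only OTUs whose domain label equals ``domain``.

    Samples that become all-zero are dropped with a warning (handled by the
    table constructor). An empty result is an error.
    """
    keep = table.lineages["domain"] == domain
    if not keep.any():
        raise TableValidationError(f"no OTUs with domain {domain!r}")
    return OtuTable(table.counts.loc[keep.values], table.lineages.loc[keep.values],
                    table.meta)


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Subsample each sample's reads, without replacement, to a common depth.

    Each column is an independent multivariate-hypergeometric draw (leveling
    semantics: reads are removed, never duplicated). ``depth=None`` uses the
    minimum per-sample depth. Reproducible given ``seed``.
    """
    depths = table.depth
    if depth is None:
        depth = int(depths.min())
    depth = int(depth)
    too_shallow = depths.index[depths.to_numpy() < depth].tolist()
    if too_shallow:
        raise TableValidationError(
            f"samples shallower than requested depth {depth}: {too_shallow}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for j, sample in enumerate(table.counts.columns):
        col = table.counts[sample].to_numpy()
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    logger.info("rarefied %d samples to depth %d (seed=%d)", table.n_samples, depth, seed)
    return OtuTable(counts, table.lineages, table.meta)


def aggregate_by_rank(table: OtuTable | TaxonTable, rank: str) -> TaxonTable:
    """Sum counts over taxa sharing the same label at ``rank``.

    Depth is preserved exactly (pure regrouping of reads). Placeholder
    labels are grouped like any other label. Aggregating a
    :class:`TaxonTable` at its own rank is the identity.
    """
    if rank not in ("phylum", "family", "genus"):
        raise ValueError(f"unknown aggregation rank {rank!r}")
    if isinstance(table, TaxonTable):
        if table.rank != rank:
            raise ValueError(
                f"table already aggregated at {table.rank!r}; cannot re-aggregate at {rank!r}"
            )
        return TaxonTable(table.counts.copy(), table.meta, rank, validate=False)
    labels = table.lineages[rank]
    counts = table.counts.groupby(labels.values).sum()
    counts = counts.loc[counts.sum(axis=1).sort_values(ascending=False).index]
    counts.index.name = rank
    return TaxonTable(counts, table.meta, rank, validate=False)


VennCounts = namedtuple("VennCounts", ["shared", "unique_a", "unique_b"])


def venn_counts(taxa_a: Iterable, taxa_b: Iterable) -> VennCounts:
    """Shared / unique-to-A / unique-to-B counts for two taxon sets."""
    a, b = set(taxa_a), set(taxa_b)
    return VennCounts(len(a & b), len(a - b), len(b - a))


def site_taxon_sets(table: CountTable, rank: str | None = None) -> dict:
    """Taxa present (total count > 0) within each site.

    If ``rank`` is given the table is aggregated first; keys are the site
    labels in sorted order.
    """
    if rank is not None:
        table = aggregate_by_rank(table, rank)
    sets = {}
    for site in sorted(table.meta["site"].unique()):
        cols = table.meta.index[table.meta["site"] == site]
        totals = table.counts[cols].sum(axis=1)
        sets[site] = set(totals.index[totals.to_numpy() > 0])
    return sets
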