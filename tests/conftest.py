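import numpy as np
import pandas as pd
import pytest

from gutassembly import OtuTable
from gutassembly.tables import RANKS


def build_table(counts, phyla=None, families=None, sites=None, groups=None,
                domains=None):
    """Hand-build a small OtuTable from a 2-D array of counts."""
    counts = np.asarray(counts)
    n_taxa, n_samples = counts.shape
    otus = [f"OTU{i + 1}" for i in range(n_taxa)]
    samples = [f"S{j + 1}" for j in range(n_samples)]
    phyla = phyla or ["Firmicutes"] * n_taxa
    families = families or [f"fam{i + 1}" for i in range(n_taxa)]
    domains = domains or ["Bacteria"] * n_taxa
    lineages = pd.DataFrame({
        "domain": domains,
        "phylum": phyla,
        "class": ["c"] * n_taxa,
        "order": ["o"] * n_taxa,
        "family": families,
        "genus": [f"gen{i + 1}" for i in range(n_taxa)],
    }, index=otus)[list(RANKS)]
    sites = sites or ["siteA"] * (n_samples // 2) + ["siteB"] * (n_samples - n_samples // 2)
    groups = groups or [f"g{j % 2 + 1}" for j in range(n_samples)]
    meta = pd.DataFrame({"sample_id": samples, "site": sites,
                         "social_group": groups}).set_index("sample_id")
    return OtuTable(pd.DataFrame(counts, index=otus, columns=samples), lineages, meta)


@pytest.fixture
def ten_otu_table():
    """10 OTUs, 3 phyla, 6 samples (3 per site), uniform depth 100."""
    rng = np.random.default_rng(42)
    counts = rng.multinomial(100, np.full(10, 0.1), size=6).T
    phyla = ["Firmicutes"] * 5 + ["Bacteroidetes"] * 3 + ["Actinobacteria"] * 2
    return build_table(counts, phyla=phyla,
                       sites=["siteA"] * 3 + ["siteB"] * 3,
                       groups=["g1", "g1", "g2", "g3", "g3", "g4"])


@pytest.fixture
def toy_tsvs(tmp_path):
    """3-OTU x 2-sample TSV trio with depths 6 and 9."""
    (tmp_path / "counts.tsv").write_text(
        "otu_id\tA\tB\nOTU1\t3\t2\nOTU2\t2\t3\nOTU3\t1\t4\n")
    (tmp_path / "taxonomy.tsv").write_text(
        "OTU1\tk__Bacteria;p__Firmicutes;c__Clostridia;o__Oscillospirales;"
        "f__Oscillospiraceae;g__\n"
        "OTU2\tk__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;"
        "f__Prevotellaceae;g__Prevotella\n"
        "OTU3\td__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridia_UCG-014;"
        "f__norank_o__Clostridia_UCG-014;g__norank_f__norank_o__Clostridia_UCG-014\n")
    (tmp_path / "metadata.tsv").write_text(
        "sample_id\tsite\tsocial_group\nA\tsiteA\tg1\nB\tsiteB\tg2\n")
    return (tmp_path / "counts.tsv", tmp_path / "taxonomy.tsv",
            tmp_path / "metadata.tsv")
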