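# gutassembly

Intersite gut-microbiota analysis from a leveled OTU table: alpha/beta
diversity, differential taxon abundance, Firmicutes/Bacteroidetes ratios,
random-forest site discrimination, and Sloan neutral-community-model
quantification of stochastic vs deterministic community assembly — with a
synthetic-data module that generates tables with known ground truth so the
whole pipeline is testable without any sequencing download.

It is written for microbial ecologists comparing the gut communities of two
host populations (the motivating design: fecal 16S surveys of a primate
species living in habitat fragments of different quality, 155 vs 48 samples
across nine social groups, ~3,000 OTUs after leveling) who want every step
— from the rarefied count table to the community-assembly verdict — in one
seeded, reproducible toolchain.

## The model at the core

Under Sloan's neutral community model, a taxon with metacommunity relative
abundance *p* in a local community of *N* individuals with migration rate
*m* has local relative abundance distributed Beta(*Nmp*, *Nm*(1−*p*)), so
its expected occurrence frequency across hosts is

```
freq(p) = 1 − BetaCDF(d; Nm·p, Nm·(1−p)),      d = 1/N
```

The package estimates the composite *Nm* by bounded nonlinear least squares
of this curve against the observed abundance–occupancy relation, reports
*m = Nm/N*, reads *R²* of the fit as the stochastic share of community
assembly (1 − *R²* deterministic), and partitions taxa by a Wilson-score
95% band around the prediction: taxa above the band are candidates for
positive selection, below for negative selection.

Around that centerpiece sit the standard survey statistics: Shannon /
inverse Simpson / Chao1 / ACE / Good's coverage (mothur conventions), a
Gaussian LMM on log10 indices with site fixed and social group random
(likelihood-ratio tested), Bray–Curtis + PCoA + one-factor PERMANOVA,
per-taxon Wilcoxon rank-sum tests with Benjamini–Hochberg correction, both
F/B ratio conventions, and a 500-tree random forest with Mean-Decrease-Gini
importance ranking, a stratified 70/30 split and repeated 10-fold × 5
cross-validated AUC.

## Worked example

```python
import numpy as np
import gutassembly as ga

# a two-site survey with five ~1%-abundance taxa enriched ~4.5x at site B
rng = np.random.default_rng(0)
base = rng.lognormal(0, 1.5, 400); base /= base.sum()
effects = np.zeros(400)
effects[np.argsort(np.abs(base - 0.01))[:5]] = 1.5

table, truth = ga.simulate_two_site(ga.TwoSiteSimSpec(
    n_taxa=400, n_samples_a=40, n_samples_b=24, reads_per_sample=5000,
    base_abundances=base, log_fold_effects=effects, seed=7))

alpha = ga.alpha_indices(table)
lrt = ga.compare_alpha_lmm(alpha, table.meta, indices=("shannon",))[0]
perm = ga.permanova(ga.bray_curtis(table), table.meta["site"],
                    n_permutations=999, seed=7)
da = ga.diff_abundance(table)
rf = ga.rf_discriminate(table, rank="family", seed=7)
fit = ga.NeutralCommunityModel.from_table(table).fit()
```

which prints (via the obvious `print` calls):

```
shannon LRT: chi2=4.535 df=1 p=0.033
PERMANOVA: F=4.27 R2=0.064 p=0.001
true positives in top 5 hits: 5
RF: held-out AUC=1.000  CV AUC=0.995
Sloan neutral community model
==============================================
taxa (detected)                            378
samples                                     64
community size N                          5000
detection limit d                    2.000e-04
Nm (composite)                          53.950
migration rate m                        0.0108
stochasticity R2                        0.9118
above 95% band                          10.5%
within 95% band                         79.7%
below 95% band                           9.7%
==============================================
```

Reading the numbers: the planted site effect is picked up everywhere — the
site term shifts Shannon diversity (LRT p = 0.033), explains 6.4% of the
Bray–Curtis variance at the permutation floor p = 0.001, the five planted
taxa are exactly the top five BH-corrected rank-sum hits, and the forest
separates the sites perfectly. The NCM fit says assembly in this simulated
community is dominated by the neutral abundance–occupancy relation
(R² = 0.91), with ~80% of taxa inside the 95% neutral band.

The same analyses run from the shell:

```bash
gutassembly simulate two-site --spec spec.json -o sim/
gutassembly ingest --counts counts.tsv --taxonomy tax.tsv --metadata meta.tsv \
    --rarefy-depth min --seed 17 -o table/
gutassembly alpha --table table/ -o out/alpha
gutassembly beta  --table table/ --permutations 999 --seed 7 -o out/beta
gutassembly compare --table table/ --rank phylum --correction bh -o out/comp
gutassembly ncm   --table table/ -o out/ncm
gutassembly rf    --table table/ --rank phylum --seed 11 --trees 500 -o out/rf
gutassembly run   --config config.json -o out/   # full pipeline + report.json
```

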