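# icecore

Analysis pipeline for low-biomass glacier-ice microbiome and virome studies:
in-silico decontamination of 16S amplicon tables against sequenced background
controls, community profiling with permutation statistics, species-level viral
OTU (vOTU) clustering, genus-level viral-cluster categorization, and
three-method in-silico virus–host linkage. A synthetic-data module generates
contamination-structured studies and virome fixtures with known ground truth,
so every stage is testable without sequencing data.

## Who this is for

Microbial ecologists working with ultra-low-biomass samples (glacier ice, ice
cores, cleanroom or atmospheric samples), where reagent and handling
contamination can rival or exceed the genuine signal, and where viral
communities must be characterized from a handful of assembled contigs.

## The core statistics

**R-OTU decontamination.** Background controls (air, sterile artificial ice,
extraction blank, sequencing blank) are sequenced alongside the real samples
and qPCR quantifies each library's 16S rRNA gene copy load. For OTU *o*,
with "absolute" abundance defined per sample as
`abs[s,o] = relabund[s,o] × qpcr_copies[s]`,

```
R-OTU(o) = mean(abs[controls, o]) / mean(abs[ice samples, o])
```

OTUs with `R-OTU > 0.01` are contaminants and are removed; remaining
per-sample proportions are renormalized. Genuine ice taxa score near
`cross-talk × load ratio` (~1e-4 under realistic loads) while contaminants
score near 1, so the 0.01 threshold separates them by orders of magnitude.

**Community statistics.** Rarefaction without replacement (hypergeometric),
major-taxa selection (≥ x% of reads in ≥1 sample), normalized weighted
UniFrac `d(A,B) = Σ l_b |p_A(b) − p_B(b)| / Σ l_b (p_A(b) + p_B(b))`,
PCoA, ANOSIM (999 permutations), and two-tailed Mantel tests — delegated to
scikit-bio behind a table-aware interface.

**vOTU clustering.** Viral contigs ≥10 kb in upstream confidence categories
1/2/4/5 are clustered greedily, longest first: a contig joins a cluster when
it shares ≥95% nucleotide identity with the representative across ≥80% of the
shorter sequence's length; the longest contig seeds each vOTU. Coverage is
normalized to per-gigabase-of-virome. Viral clusters (VCs, ~genera) are
categorized as classified (contain a reference genome), ice-exclusive, or
singleton; novel genera = exclusive VCs + singletons.

**Host linkage.** Three independent in-silico methods: (i) nucleotide
similarity (bit ≥50, E ≤1e-3, ≥70% ANI across ≥2,000 bp of merged aligned
span), (ii) d2* oligonucleotide-frequency dissimilarity ≤0.1 with ≥80%
genus consensus among the 30 nearest hosts, and (iii) CRISPR spacers from
arrays of >2 direct repeats matching vOTU sequences with zero mismatches.

## Worked example

```python
from icecore import AmpliconSimParams, simulate_amplicon_study, decontaminate

params = AmpliconSimParams(n_ice_samples=8, n_controls=4, seed=7)
table, truth = simulate_amplicon_study(params)
result = decontaminate(table, threshold=0.01)

flagged = result.flagged[result.flagged].index
print(f"flagged {len(flagged)}/{len(table.otu_ids)} OTUs as contaminants")
planted = set(truth.contaminant_otu_ids)
print(f"planted contaminants recovered: {len(set(flagged) & planted)}/{len(planted)}")
print(f"max R-OTU among retained OTUs: {result.r_otu[~result.flagged].max():.2e}")
```

prints

```
flagged 30/150 OTUs as contaminants
planted contaminants recovered: 30/30
max R-OTU among retained OTUs: 4.59e-04
```

All 30 planted contaminants are flagged with zero false positives, and the
retained (genuine) OTUs sit more than an order of magnitude below the 0.01
decision threshold. The same pipeline is scriptable from the shell:

```
icecore simulate amplicon --out study/ --seed 7
icecore decontam run --otu study/otu_table.tsv --roles study/roles.tsv \
    --qpcr study/qpcr.tsv --out clean/
```

See `icecore --help` for the community, votu, and hostlink subcommands.

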