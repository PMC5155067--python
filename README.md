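# binquant

Genome-resolved metatranscriptome quantification for microbial communities
degrading lignocellulose under ionic-liquid (IL) stress.

When a thermophilic switchgrass-degrading community is amended with the
pretreatment solvent 1-ethyl-3-methylimidazolium acetate ([C₂mim][OAc]),
community composition, transcription and respiration all shift along the IL
gradient. `binquant` implements the analysis stages downstream of assembly,
binning and read alignment that turn raw tables into genome-resolved
biology:

- **Bin taxonomy** — each genome bin is labelled with the most frequent
  lineage among its genes' closest reference-protein hits, with the averaged
  amino-acid identity (AAI) over the winner-voting genes; unbinned scaffolds
  get a lowest-common-ancestor (LCA) label, with the conventional exclusion
  vocabulary ("eukaryotes", "cellular organisms", "unassigned" are dropped
  from transcript accounting; "unclassified bacteria" stays in).
- **Functional annotation reconciliation** — EC numbers are transferred from
  a reference annotation when a gene maps at ≥95% identity and ≥40%
  coverage; genes are assigned to five enzyme classes (endoglucanase,
  cellulose 1,4-β-cellobiosidase, β-glucosidase, xylanase, acetate kinase)
  only when KEGG Orthology (KO) and EC annotations agree — except for the
  cellobiosidase class, where the EC number alone decides because its KO/EC
  agreement is too low to be trusted. Putative IL-tolerance efflux genes
  (*eilA*, *sugE*, *emrE*, *smvA*, *ykkC*, *ykkD* homologs) are flagged at
  E ≤ 1e−5.
- **Quantification** — RPKM = 10⁹ · count / (gene length · library size);
  genome expression is the sum of member-gene RPKM; top-k transcriber shares
  and per-bin top-gene percentages follow.
- **Ecology** — richness S, Shannon diversity H = −Σ pᵢ ln pᵢ, Pielou's
  evenness J = H / ln S after global singleton removal, and a UPGMA tree of
  samples on Bray–Curtis distances between relative abundance profiles.
- **Respirometry** — CO₂ evolution rate CER(t) = flow · 60 · CO₂-fraction ·
  (44.01/Vₘ) · 1000 / dry mass (mg CO₂ g⁻¹ h⁻¹) and its trapezoidal time
  integral cCER (mg CO₂ g⁻¹ dry matter).
- **Synthetic communities** — a seeded generator plants a multi-phylum bin
  set whose dominants shift from *Proteobacteria* (no IL) to *Firmicutes*
  (high IL), negative-binomial transcript counts with known per-bin
  expression shares, annotation tables with a controlled KO/EC agreement
  rate, OTU tables with planted evenness, and respirometry traces with
  known cCER — so every stage is testable without sequencing data.

## Worked example

```sh
binquant all --outdir run --seed 1
```

simulates a 5-sample community (inoculum + 0/0.5/1/2% IL) and runs every
stage. Selected output:

```
$ head -4 run/quantify/top_share.tsv
sample	top5_share_pct
inoculum	56.0439
IL0	55.2785
IL0.5	50.3787

$ head -3 run/ecology/diversity.tsv
sample	richness	shannon	pielou
inoculum	200	3.0179	0.569596
IL0	200	3.03568	0.572951

$ cat run/respirometry/ccer_summary.tsv
trace	final_ccer_mg_per_g	peak_cer_mg_per_g_h
resp_IL0.5	295.997	2.62534
resp_IL0	298.997	2.65195
resp_IL1	267.997	2.377
resp_IL2	240.997	2.13753
resp_inoculum	298.997	2.65195
```

The top-5 share is the percentage of prokaryotic transcription carried by
the five most-transcribing genome bins in each sample (here ~56% of the
inoculum's transcription, with the unbinned prokaryotic pool kept in the
denominator). Diversity falls along the gradient — evenness drops from ~0.57
(no IL) toward ~0.35 (2% IL) — and cumulative respiration decreases from
~299 to ~241 mg CO₂ g⁻¹ dry matter over the seven-day incubation.
`run/ecology/sample_tree.nwk` holds the Bray–Curtis/UPGMA tree, in which
the two no-IL samples and the two high-IL samples pair up.

Each stage is also available on its own (`binquant taxonomy|annotate|
quantify|ecology|respire`) over your own GFF3/TSV inputs, or as plain
library calls (`binquant.pipeline`).

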