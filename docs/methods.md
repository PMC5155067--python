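# Methods

This note records the models, conventions and numerical choices behind
`binquant`, and what the synthetic-data tests do and do not demonstrate.

## Taxonomy

**Bin voting.** A genome bin's taxonomy is the modal lineage among its
genes' closest reference hits. The vote is cast on the *full* lineage
string (species level when available); reports at a shallower rank truncate
the winner. This matches the species-level calls one gets from best-hit
voting on well-separated bins. The mean AAI averages percent identity over
the winner-voting genes only — genes whose best hit names a different
lineage are treated as misassignments and excluded from the identity
estimate. Ties are broken by higher mean identity among the tied lineages,
then lexicographically; genes without hits do not vote and do not enter the
vote-fraction denominator. A hitless bin is "unassigned" with an absent
(not zero) AAI.

**LCA labels.** Unbinned scaffolds are labelled by the deepest rank shared
by their high-scoring hits. Because the hit tables carry E-values rather
than bit scores, the scoring proxy is −log₁₀ E (floored at 1e−180), and
hits within 10% of the best score participate — the window is configurable
(`lca_top_percent`) since the exact parameters of LCA binning tools vary.
Label vocabulary: an LCA that bottoms out at the Bacteria domain is
"unclassified bacteria" (kept in transcript accounting); an LCA above the
domain rank is "cellular organisms"; a eukaryotic LCA is "eukaryotes"; no
hits is "unassigned". The latter three are excluded from all prokaryotic
totals, as is any bin whose winning lineage is eukaryotic — eukaryotic gene
models are structurally unreliable in this setting and would distort
length-normalised expression.

## Annotation reconciliation

EC transfer requires the best reference hit to reach both thresholds
*inclusively* (≥95% identity, ≥40% coverage — "at least" semantics).
Coverage is interpreted as query coverage; both thresholds are
configurable. Multiple ECs per gene are carried as a set.

Enzyme classification demands a class KO **and** a class EC
(`requires_both`), with one exception: cellulose 1,4-β-cellobiosidase is
decided by EC 3.2.1.91 alone, because KO annotations for this class agree
with the EC far too rarely to be a useful second witness. A gene carrying
one class's KO with another class's EC is never classified — including the
case where the EC belongs to the EC-only class. The five built-in class
definitions are disjoint in both KO and EC space, which
`validate_classes` enforces for user-supplied overrides.

The KO/EC agreement ratio is, per class, the percentage of KO-annotated
genes whose EC agrees; classes with no KO-annotated genes report an absent
value rather than 0%, which would be misleading.

IL-tolerance flagging uses an inclusive E ≤ 1e−5 cutoff over hits against
the six reference efflux/SMR genes; any qualifying hit flags the gene, and
flagged-gene expression sums over all flagged genes (not best-hit-per-
reference), since a community can carry many homologs of one pump.

## Quantification

RPKM = 10⁹ · count / (length_bp · library size). The library size defaults
to the per-sample column sum of gene-assigned counts — the only denominator
reproducible without the original alignments — and can be overridden with
externally measured totals. With the column-sum default, Σ RPKM ·
length_kb = 10⁶ holds exactly per sample, which the tests exploit as a
conservation check.

Aggregation sums member-gene RPKM per group (bin, phylum, enzyme class, or
an `unbinned:<label>` pool); excluded groups (eukaryote bins and the
excluded label vocabulary) stay in the report but out of prokaryotic
totals. The top-k share supports two denominators, both reported: the
default keeps unbinned prokaryotic transcription in the total (phylum-level
plots count it, so the published shares plausibly do too); `binned_only`
restricts to binned genomes. Percent-of-bin for top genes divides by the
bin's own total, not the sample total. Ties at rank k break by group id
for determinism.

## Ecology

Shannon H uses the natural log; the reported (H, S, J) triplets satisfy
J = H / ln S to 2 d.p. only under that convention, which fixes it.
Singletons are OTUs with total count ≤ 1 across the whole dataset (the
common global convention; a per-sample rule would also drop taxa that are
merely rare everywhere at once). Pielou's J is undefined for S < 2 and
reported absent. The sample tree uses Bray–Curtis distances on per-sample
relative abundances with UPGMA (size-weighted average linkage) — the
standard abundance-dendrogram recipe; metric and linkage are configurable.
Zero distances (identical samples) are valid inputs; merge order on ties
follows input order deterministically.

## Respirometry

CER(t) = flow · 60 · CO₂-fraction · (44.01 / Vₘ) · 1000 / dry mass, in
mg CO₂ g⁻¹ h⁻¹. The molar volume defaults to 24.0 L mol⁻¹ (ambient sensor
conditions) and is configurable; an optional baseline column supports inlet
CO₂ subtraction (default zero, clipped at zero after subtraction). cCER is
the trapezoidal integral of CER over the sampled times; the quadrature
error decreases at second order in the step size, verified against a
fine-grid oracle. A single-point trace integrates to zero with a warning.

## Synthetic communities

The generator emulates the study design: five samples (inoculum, 0%, 0.5%,
1%, 2% IL), a 20-bin community over four phyla, and a gradient of dominance
— each sample's five favoured bins hold 60% of its transcription
(`top_share`), with the favoured set sliding from *Proteobacteria*-like
early bins (no IL) to *Firmicutes*-like late bins (high IL) at gradient
positions 0, 0, 0.5, 0.9, 1.0. The last two positions are deliberately
close: the community shift is essentially complete at 1% IL, which makes
the no-IL pair and the high-IL pair each cluster in the coverage tree.

Gene lengths are log-normal (μ=6.8, σ=0.4 on bp; median ≈ 900 bp, floored
at 90 bp). Genes sit ~10 per scaffold; 10% of scaffolds are withheld from
the membership table to form the unbinned pool that exercises the LCA
path. Counts are negative-binomial with mean ∝ depth · bin weight ·
per-gene expression factor · length, dispersion shared across genes
(default 0.1), expression factors log-normal with σ = 0.75 normalised
within each bin. These noise defaults keep the sampling error of a
~250-gene bin total under one percentage point of share, so planted top-5
shares are recoverable within the two-point budget the recovery tests use;
a single gene's count still carries ≈√dispersion ≈ 32% relative noise,
which is why single-gene share checks either use Poisson counts or compare
against count-level arithmetic rather than the planted expectation.

Wrong-lineage noise (probability `taxonomy_noise`) always fakes genus and
species and with probability 0.5 also swaps the phylum-to-family path,
exercising both shallow and deep disagreement in voting and LCA. One
eukaryotic bin is planted to exercise the exclusion rules; one marker gene
is pinned to 12% of its bin's expression. OTU tables plant per-sample
evenness via a mixture of a uniform floor and a steep geometric head, with
the dominant mass solved numerically (Brent) for the target J — the floor
keeps every taxon detectable at the simulated depth, so observed evenness
tracks the planted value instead of being biased upward by an unsampled
rare tail. Five global singletons are appended to exercise the filter.
Respirometry traces use a Γ-like profile c₀·(t/τ)·e^(1−t/τ) (τ = 48 h)
scaled in closed form so the continuous cCER equals the target magnitudes
(299/296/268/241 mg g⁻¹ along the gradient).

All randomness flows from one `numpy` generator seeded explicitly; equal
seeds give byte-identical files, recorded with SHA-256 checksums in a
manifest.

**What passing tests do not show.** The generator plants clean, single-hit
taxonomy and disjoint annotation classes; real communities have chimeric
bins, strain heterogeneity, multi-hit ambiguity, partial annotations and
compositional artefacts that none of these tests probe. Recovery results
certify the arithmetic and the rules, not robustness to real-data mess.

## Problem sizes

The default community (20 bins × ~240 genes × 5 samples, ~5,000 genes) runs
the full pipeline in a few seconds; multi-seed checks (tree topology across
100 seeds) use a 12-bin, ~35-gene/bin configuration. The acceptance script
uses the default size for recovery and shares, n = 500 KO-annotated genes
for the agreement ratio, and 20 seeds for topology.

## Known limitations

- LCA uses an E-value score proxy, not recomputed bit scores; scores from
  heterogeneous search tools are only comparable within one table.
- Library-size normalisation ignores reads mapped outside predicted genes;
  with external totals supplied, the RPKM conservation identity no longer
  holds (by design).
- The distance tree is a sample dendrogram, not a phylogeny; branch
  lengths are cophenetic heights.
- No differential-expression modelling: RPKM comparisons across samples
  inherit library-composition effects.
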