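"""Synthetic community generator with planted ground truth.

Emulates the data layout of a genome-resolved metatranscriptome study of a
thermophilic switchgrass-degrading community along a four-level ionic-liquid
(IL) amendment gradient plus its inoculum: a multi-phylum set of genome
bins whose relative abundance shifts from *Proteobacteria*-dominated (no IL)
to *Firmicutes*-dominated (high IL), genes with log-normal length variation,
per-gene closest-hit records with noisy identities and (optionally) wrong
lineages, KO/EC annotations with a controlled agreement probability,
negative-binomial transcript counts with planted per-bin expression shares,
an OTU table with planted evenness per sample, per-bin coverages, and
respirometry traces whose cumulative CO2 evolution matches the reported
magnitudes (299 / 296 / 268 / 241 mg CO2 per g dry matter at 0/0.5/1/2% IL).

Everything is drawn from one explicitly seeded generator: identical seeds
produce byte-identical files.  No read sequences are simulated — only the
tabular products the pipeline consumes.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from binquant import annotation as ann_mod
from binquant import io as bio
from binquant.io import BestHit, GeneRecord, Lineage
from binquant.respirometry import DEFAULT_MOLAR_VOLUME, RespTrace, compute_cer, write_trace

# toy taxonomy: phylum -> (class, order, family) path stem
_PHYLA = (
    ("Proteobacteria", ("Gammaproteobacteria", "Xanthomonadales", "Xanthomonadaceae")),
    ("Firmicutes", ("Bacilli", "Bacillales", "Bacillaceae")),
    ("Actinobacteria", ("Actinomycetia", "Streptosporangiales", "Streptosporangiaceae")),
    ("Bacteroidetes", ("Sphingobacteriia", "Sphingobacteriales", "Sphingobacteriaceae")),
    ("Chloroflexi", ("Anaerolineae", "Anaerolineales", "Anaerolineaceae")),
    ("Planctomycetes", ("Planctomycetia", "Planctomycetales", "Planctomycetaceae")),
)

_GENERA = ("Thermoger", "Calidimonas", "Fervidibacillus", "Pyrolinea", "Aestuarium",
           "Torridicoccus", "Ustulomyces", "Ardensella")

#: default trace target cCER by gradient position, mg CO2 / g dry matter
_CCER_BY_LEVEL = {0.0: 299.0, 0.005: 296.0, 0.01: 268.0, 0.02: 241.0}


@dataclass
class SimConfig:
    """Knobs of the synthetic community.

    Defaults mirror the study design: five samples (inoculum + 0/0.5/1/2%
    IL), a 20-bin community spanning four phyla whose dominants shift along
    the gradient with the five top bins holding 60% of the transcription,
    gene lengths log-normal around ~900 bp, shared negative-binomial
    dispersion, and a 10% unbinned scaffold pool.
    """

    n_bins: int = 20
    n_phyla: int = 4
    genes_per_bin: tuple[int, int] = (200, 280)
    gene_length_law: tuple[float, float] = (6.8, 0.4)  # log-normal mu, sigma of bp
    n_samples: int = 5
    abundance_profiles: np.ndarray | None = None  # (n_bins, n_samples) weights
    dispersion: float = 0.1
    annotation_consistency: float = 0.9
    taxonomy_noise: float = 0.05
    seed: int = 0
    # community structure
    n_euk_bins: int = 1
    genes_per_scaffold: int = 10
    unbinned_fraction: float = 0.10
    top_share: float = 0.60          # summed weight of the 5 dominant bins
    marker_share: float = 0.12       # planted top-gene share of its bin
    genes_per_class: int = 12        # planted genes per enzyme class
    depth: float | Sequence[float] = 3.0e5  # expected aligned reads per sample
    otu_richness: int = 200
    otu_reads: int = 20000
    otu_evenness: Sequence[float] | None = None  # target Pielou J per sample
    identity_sd: float = 3.0
    expression_sigma: float = 0.75  # log-normal sd of per-gene expression factors

    def __post_init__(self) -> None:
        for name in ("annotation_consistency", "taxonomy_noise", "unbinned_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_bins < 1 or self.n_phyla < 1 or self.n_samples < 2:
            raise ValueError("n_bins, n_phyla >= 1 and n_samples >= 2 required")
        if self.genes_per_bin[0] < 1:
            raise ValueError("a bin must carry at least one gene")
        if not (0.0 < self.top_share < 1.0):
            raise ValueError("top_share must be in (0,1)")
        if self.abundance_profiles is not None:
            w = np.asarray(self.abundance_profiles, dtype=float)
            if w.shape != (self.n_bins, self.n_samples):
                raise ValueError("abundance_profiles must be (n_bins, n_samples)")
            if (w < 0).any() or (w.sum(axis=0) <= 0).any():
                raise ValueError("abundance weights must be >= 0 with a positive "
                                 "total per sample")

    @property
    def sample_names(self) -> list[str]:
        if self.n_samples == 5:
            return ["inoculum", "IL0", "IL0.5", "IL1", "IL2"]
        return [f"S{i}" for i in range(self.n_samples)]

    @property
    def gradient(self) -> np.ndarray:
        """Per-sample position in [0,1] along the IL gradient."""
        if self.n_samples == 5:
            return np.array([0.0, 0.0, 0.5, 0.9, 1.0])
        return np.linspace(0.0, 1.0, self.n_samples)

    @property
    def il_levels(self) -> np.ndarray:
        """Nominal IL mass fraction per sample (used for respirometry targets)."""
        if self.n_samples == 5:
            return np.array([0.0, 0.0, 0.005, 0.01, 0.02])
        return np.linspace(0.0, 0.02, self.n_samples)


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated dataset."""

    bin_lineages: dict[str, Lineage]
    bin_mean_identity: dict[str, float]          # realized mean of hit identities
    gene_to_bin: dict[str, str]
    scaffold_to_bin: dict[str, str]              # includes withheld scaffolds
    unbinned_scaffolds: set[str]
    expression_shares: pd.DataFrame              # expected bin RPKM share x sample
    top5_shares: dict[str, float]                # planted top-5 %, all-prokaryotic denom
    top5_shares_binned: dict[str, float]         # planted top-5 %, binned-only denom
    class_genes: dict[str, set[str]]             # planted enzyme-class gene sets
    ec_truth: dict[str, str]                     # planted transferable ECs
    il_genes: set[str]
    marker: tuple[str, str, float]               # (bin, gene, expected % of bin)
    otu_evenness: dict[str, float]               # planted Pielou J per sample
    ccer_targets: dict[str, float]


# ---------------------------------------------------------------------------
# helpers


def _bin_lineage(phylum_idx: int, bin_idx: int, rng: np.random.Generator) -> Lineage:
    phylum, (cls, order, family) = _PHYLA[phylum_idx % len(_PHYLA)]
    genus = f"{_GENERA[bin_idx % len(_GENERA)]}{bin_idx:03d}"
    species = f"{genus} sp. B{bin_idx:03d}"
    return Lineage(("Bacteria", "Terrabacteria" if phylum in {"Firmicutes", "Actinobacteria"}
                    else "Gracilicutes", phylum, cls, order, family, genus, species))


_EUK_LINEAGE = Lineage(("Eukaryota", "Fungi", "Ascomycota", "Sordariomycetes",
                        "Sordariales", "Chaetomiaceae", "Thermochaetoides",
                        "Thermochaetoides thermophila"))


def _noisy_lineage(true: Lineage, rng: np.random.Generator) -> Lineage:
    """Wrong-lineage noise: always fake genus+species; half the time the
    phylum..family path is swapped for another phylum's."""
    ranks = list(true.ranks)
    k = int(rng.integers(0, 10_000))
    ranks[6] = f"Errans{k:04d}"
    ranks[7] = f"Errans{k:04d} sp."
    if rng.random() < 0.5:
        cur = ranks[2]
        others = [p for p in _PHYLA if p[0] != cur]
        phylum, (cls, order, family) = others[int(rng.integers(0, len(others)))]
        ranks[2:6] = [phylum, cls, order, family]
    return Lineage(tuple(ranks))


def _dominant_sets(config: SimConfig) -> list[list[int]]:
    """Per sample, the indices of the (up to) 5 bins favoured at its gradient
    position — nearest bins by planted niche position, ties by index."""
    b = config.n_bins
    positions = np.arange(b) / max(b - 1, 1)
    out = []
    for g in config.gradient:
        order = np.lexsort((np.arange(b), np.abs(positions - g)))
        out.append(sorted(order[: min(5, b)].tolist()))
    return out


def _default_profiles(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Planted per-bin weights per sample: dominant bins share ``top_share``
    (split 30/25/20/15/10 with jitter), the rest share the remainder."""
    b, s = config.n_bins, config.n_samples
    w = np.zeros((b, s))
    dom_sets = _dominant_sets(config)
    base_split = np.array([0.30, 0.25, 0.20, 0.15, 0.10])
    for j in range(s):
        dom = dom_sets[j]
        split = base_split[: len(dom)] * np.exp(rng.normal(0, 0.08, size=len(dom)))
        split = split / split.sum() * config.top_share
        rest = [i for i in range(b) if i not in dom]
        if rest:
            rw = np.exp(rng.normal(0, 0.10, size=len(rest)))
            rw = rw / rw.sum() * (1.0 - config.top_share)
            w[rest, j] = rw
        else:
            split = split / split.sum()
        w[dom, j] = split
    return w


def _solve_evenness_profile(s: int, target_j: float) -> np.ndarray:
    """Relative abundances over s taxa with Pielou J = target.

    Mixture of a uniform floor and a steep geometric head,
    p_i = (1-m)/s + m * g_i with g_i ∝ exp(-2i); the dominant mass m is
    solved so that J(p) = target.  The floor keeps every taxon detectable at
    realistic sequencing depth, so the evenness of a finite multinomial
    sample stays close to the planted value (a pure geometric series would
    lose its rare tail to sampling and bias the observed J upward).
    """
    head = np.exp(-2.0 * np.arange(s))
    head = head / head.sum()

    def profile(m: float) -> np.ndarray:
        return (1.0 - m) / s + m * head

    def j_of(m: float) -> float:
        p = profile(m)
        return float(-(p * np.log(p)).sum() / math.log(s))

    if target_j >= 1.0:
        return np.full(s, 1.0 / s)
    m_max = 0.92  # keeps the uniform floor >= 8% of reads
    if j_of(m_max) > target_j:
        return profile(m_max)
    m = brentq(lambda m: j_of(m) - target_j, 1e-12, m_max, xtol=1e-12)
    return profile(m)


# ---------------------------------------------------------------------------
# main generator


def generate_community(config: SimConfig, outdir: str | Path) -> SyntheticTruth:
    """Write the full synthetic dataset under ``outdir`` and return its truth.

    Emits: genes.gff, scaffold_bins.tsv, hits.tsv, ko.tsv, ref_ec.tsv,
    ec_hits.tsv, il_hits.tsv, counts.tsv, coverage.tsv, otus.tsv, one
    respirometry trace per sample, and manifest.json with SHA-256 checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    samples = config.sample_names

    # --- bins, lineages, genes, scaffolds -------------------------------
    prok_bins = [f"bin{i:03d}" for i in range(config.n_bins)]
    euk_bins = [f"binE{i:02d}" for i in range(config.n_euk_bins)]
    bin_lineages: dict[str, Lineage] = {}
    for i, b in enumerate(prok_bins):
        bin_lineages[b] = _bin_lineage(i % config.n_phyla, i, rng)
    for b in euk_bins:
        bin_lineages[b] = _EUK_LINEAGE

    genes: list[GeneRecord] = []
    gene_to_bin: dict[str, str] = {}
    scaffold_to_bin: dict[str, str] = {}
    gene_to_scaffold: dict[str, str] = {}
    bin_genes: dict[str, list[str]] = {b: [] for b in bin_lineages}
    mu, sigma = config.gene_length_law
    for b in bin_lineages:
        n_genes = int(rng.integers(config.genes_per_bin[0], config.genes_per_bin[1] + 1))
        lengths = np.maximum(90, np.round(rng.lognormal(mu, sigma, size=n_genes) / 3) * 3)
        n_scaf = max(1, n_genes // config.genes_per_scaffold)
        for gi, ln in enumerate(lengths):
            scaf = f"{b}_scf{gi % n_scaf:04d}"
            gid = f"{b}_g{gi:04d}"
            start = 1 + 2000 * (gi // n_scaf)
            genes.append(GeneRecord(gene_id=gid, scaffold_id=scaf, start=start,
                                    end=start + int(ln) - 1,
                                    strand="+" if rng.random() < 0.5 else "-"))
            gene_to_bin[gid] = b
            gene_to_scaffold[gid] = scaf
            scaffold_to_bin[scaf] = b
            bin_genes[b].append(gid)
    gene_index = {g.gene_id: g for g in genes}

    # withhold scaffolds from the membership table -> unbinned pool
    all_scaffolds = sorted(scaffold_to_bin)
    n_unbinned = int(round(config.unbinned_fraction * len(all_scaffolds)))
    # the marker gene's scaffold must stay binned (see below): reserve index 0
    marker_bin = prok_bins[min(4, config.n_bins - 1)]
    marker_gene = bin_genes[marker_bin][0]
    reserved = gene_to_scaffold[marker_gene]
    pool = [s for s in all_scaffolds if s != reserved]
    unbinned = set(rng.choice(pool, size=min(n_unbinned, len(pool)), replace=False).tolist())

    # --- taxonomy best hits --------------------------------------------
    bin_aai = {b: float(rng.uniform(72, 99)) for b in bin_lineages}
    hits: list[BestHit] = []
    ident_by_bin: dict[str, list[float]] = {b: [] for b in bin_lineages}
    for g in genes:
        b = gene_to_bin[g.gene_id]
        true_lin = bin_lineages[b]
        lin = true_lin
        if config.taxonomy_noise > 0 and rng.random() < config.taxonomy_noise:
            lin = _noisy_lineage(true_lin, rng)
        ident = float(np.clip(rng.normal(bin_aai[b], config.identity_sd), 50.0, 100.0))
        # the planted AAI reference averages the winner-voting genes the
        # pipeline will actually see: binned scaffolds, true-lineage hits
        if lin == true_lin and gene_to_scaffold[g.gene_id] not in unbinned:
            ident_by_bin[b].append(ident)
        hits.append(BestHit(
            gene_id=g.gene_id, subject_id=f"ref_{g.gene_id}",
            lineage=lin, pct_identity=round(ident, 2),
            evalue=float(f"{10 ** -rng.uniform(20, 150):.3e}"),
            query_coverage=round(float(rng.uniform(60, 100)), 2),
            aln_len=g.length // 3,
        ))
    bin_mean_identity = {
        b: round(float(np.mean([round(v, 2) for v in vals])), 10) if vals else float("nan")
        for b, vals in ident_by_bin.items()
    }

    # --- enzyme-class annotations (KO table + EC-transfer inputs) -------
    prok_set = set(prok_bins)
    prok_gene_ids = [g for g in gene_to_bin if gene_to_bin[g] in prok_set]
    rng.shuffle(prok_gene_ids)
    class_defs = ann_mod.BUILTIN_CLASSES
    needed = config.genes_per_class * len(class_defs)
    chosen = prok_gene_ids[:needed]
    ko_rows: list[tuple[str, str]] = []
    ref_ec_rows: list[tuple[str, str]] = []
    ec_hit_rows: list[BestHit] = []
    class_genes: dict[str, set[str]] = {c.name: set() for c in class_defs}
    ec_truth: dict[str, str] = {}
    for ci, cdef in enumerate(class_defs):
        members = chosen[ci * config.genes_per_class:(ci + 1) * config.genes_per_class]
        kos = sorted(cdef.ko_ids)
        for gid in members:
            ko = kos[int(rng.integers(0, len(kos)))]
            ko_rows.append((gid, ko))
            class_genes[cdef.name].add(gid)
            if rng.random() < config.annotation_consistency:
                ec = sorted(cdef.ec_ids)[0]
            else:  # inconsistent: EC drawn from a different class
                others = [d for d in class_defs if d.name != cdef.name]
                ec = sorted(others[int(rng.integers(0, len(others)))].ec_ids)[0]
            ref_id = f"jgi_{gid}"
            ref_ec_rows.append((ref_id, ec))
            ec_truth[gid] = ec
            ec_hit_rows.append(BestHit(
                gene_id=gid, subject_id=ref_id, lineage=Lineage(()),
                pct_identity=round(float(rng.uniform(95.0, 100.0)), 2),
                evalue=1e-50, query_coverage=round(float(rng.uniform(40.0, 100.0)), 2),
                aln_len=200))
    # decoys: below-threshold reference hits that must NOT transfer an EC
    decoys = prok_gene_ids[needed:needed + 20]
    for gid in decoys:
        ref_id = f"jgi_{gid}"
        ref_ec_rows.append((ref_id, "1.1.1.1"))
        ec_hit_rows.append(BestHit(
            gene_id=gid, subject_id=ref_id, lineage=Lineage(()),
            pct_identity=round(float(rng.uniform(60.0, 94.8)), 2),
            evalue=1e-30, query_coverage=round(float(rng.uniform(40.0, 100.0)), 2),
            aln_len=150))

    # --- IL-tolerance homology -----------------------------------------
    il_pool = prok_gene_ids[needed + 20:needed + 20 + 3 * config.n_bins]
    il_genes: set[str] = set()
    il_hit_rows: list[BestHit] = []
    for i, gid in enumerate(il_pool):
        subject = ann_mod.IL_TOLERANCE_GENES[i % len(ann_mod.IL_TOLERANCE_GENES)]
        flagged = i % 3 != 2  # two thirds pass the E-value cutoff
        ev = 10 ** -rng.uniform(6, 40) if flagged else 10 ** -rng.uniform(1, 4.9)
        if flagged:
            il_genes.add(gid)
        il_hit_rows.append(BestHit(
            gene_id=gid, subject_id=subject, lineage=Lineage(()),
            pct_identity=round(float(rng.uniform(30, 90)), 2),
            evalue=float(f"{ev:.3e}"), query_coverage=round(float(rng.uniform(30, 100)), 2),
            aln_len=100))

    # --- expression: planted shares -> negative-binomial counts ---------
    weights = (np.asarray(config.abundance_profiles, dtype=float)
               if config.abundance_profiles is not None
               else _default_profiles(config, rng))
    weights = weights / weights.sum(axis=0, keepdims=True)
    # per-gene expression factors, normalized within each bin
    xfac: dict[str, float] = {}
    for b in bin_lineages:
        e = rng.lognormal(0.0, config.expression_sigma, size=len(bin_genes[b]))
        e = e / e.sum()
        if b == marker_bin and len(e) > 1:
            # pin the marker gene (index 0) to exactly marker_share of its bin
            e[1:] *= (1.0 - config.marker_share) / e[1:].sum()
            e[0] = config.marker_share
        for gid, x in zip(bin_genes[b], e):
            xfac[gid] = float(x)
    depth = np.asarray(config.depth, dtype=float)
    if depth.ndim == 0:
        depth = np.full(config.n_samples, float(depth))
    euk_weight = 0.02  # eukaryote bins transcribe a little in every sample
    gene_ids = [g.gene_id for g in genes]
    mu_mat = np.zeros((len(gene_ids), config.n_samples))
    for gi, gid in enumerate(gene_ids):
        b = gene_to_bin[gid]
        if b in euk_bins:
            wrow = np.full(config.n_samples, euk_weight / max(config.n_euk_bins, 1))
        else:
            wrow = weights[prok_bins.index(b)]
        mu_mat[gi] = depth * wrow * xfac[gid] * (gene_index[gid].length / 1000.0)
    if config.dispersion > 0:
        n_param = 1.0 / config.dispersion
        counts = rng.negative_binomial(n_param, n_param / (n_param + np.maximum(mu_mat, 1e-12)))
    else:
        counts = rng.poisson(np.maximum(mu_mat, 0.0))
    count_df = pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=samples)

    # planted expected bin RPKM shares (prokaryotic denominator)
    exp_shares = pd.DataFrame(weights, index=prok_bins, columns=samples)
    # planted top-5 share restricted to the *binned* portion of each bin
    binned_x = {
        b: sum(xfac[g] for g in bin_genes[b] if gene_to_scaffold[g] not in unbinned)
        for b in prok_bins
    }
    top5: dict[str, float] = {}
    top5_binned: dict[str, float] = {}
    for j, s in enumerate(samples):
        bin_tot = np.array([weights[i, j] * binned_x[b] for i, b in enumerate(prok_bins)])
        top_sum = float(np.sort(bin_tot)[::-1][:5].sum())
        # all-prokaryotic denominator keeps the unbinned pool's transcription
        top5[s] = 100.0 * top_sum / weights[:, j].sum()
        top5_binned[s] = 100.0 * top_sum / float(bin_tot.sum())

    marker_expected = 100.0 * xfac[marker_gene] / binned_x[marker_bin]

    # --- coverage table -------------------------------------------------
    cov = weights * 400.0 * np.exp(rng.normal(0, 0.05, size=weights.shape))
    cov_df = pd.DataFrame(np.round(cov, 3), index=prok_bins, columns=samples)

    # --- OTU table with planted evenness --------------------------------
    if config.otu_evenness is None:
        target_j = 0.57 - (0.57 - 0.35) * config.gradient
    else:
        target_j = np.asarray(config.otu_evenness, dtype=float)
    otu_ids = [f"OTU{i:04d}" for i in range(config.otu_richness)]
    otu = np.zeros((config.otu_richness, config.n_samples), dtype=np.int64)
    planted_j: dict[str, float] = {}
    for j, s in enumerate(samples):
        p = _solve_evenness_profile(config.otu_richness, float(target_j[j]))
        perm = rng.permutation(config.otu_richness)
        otu[perm, j] = rng.multinomial(config.otu_reads, p)
        planted_j[s] = float(target_j[j])
    # add global singletons to exercise the filter
    single = np.zeros((5, config.n_samples), dtype=np.int64)
    for i in range(5):
        single[i, int(rng.integers(0, config.n_samples))] = 1
    otu_df = pd.DataFrame(
        np.vstack([otu, single]),
        index=otu_ids + [f"OTUS{i:02d}" for i in range(5)], columns=samples)

    # --- respirometry traces --------------------------------------------
    ccer_targets: dict[str, float] = {}
    for j, s in enumerate(samples):
        lvl = float(config.il_levels[j])
        target = _CCER_BY_LEVEL.get(round(lvl, 4), 299.0 - (299.0 - 241.0) * config.gradient[j])
        trace = make_planted_trace(target_ccer=target, seed=int(rng.integers(0, 2**31)))
        write_trace(trace, outdir / f"resp_{s}.tsv")
        ccer_targets[s] = target

    # --- write files -----------------------------------------------------
    bio.write_gff(genes, outdir / "genes.gff")
    pd.DataFrame(
        [(s, scaffold_to_bin[s]) for s in all_scaffolds if s not in unbinned],
        columns=["scaffold_id", "bin_id"],
    ).to_csv(outdir / "scaffold_bins.tsv", sep="\t", index=False)
    bio.write_hits(hits, outdir / "hits.tsv")
    pd.DataFrame(sorted(ko_rows), columns=["gene_id", "ko_id"]).to_csv(
        outdir / "ko.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(ref_ec_rows), columns=["ref_id", "ec"]).to_csv(
        outdir / "ref_ec.tsv", sep="\t", index=False)
    bio.write_hits(ec_hit_rows, outdir / "ec_hits.tsv")
    bio.write_hits(il_hit_rows, outdir / "il_hits.tsv")
    bio.write_counts(bio.CountTable(counts=count_df), outdir / "counts.tsv")
    cov_df.rename_axis("bin_id").to_csv(outdir / "coverage.tsv", sep="\t")
    otu_df.rename_axis("otu_id").to_csv(outdir / "otus.tsv", sep="\t")

    files = sorted(p.name for p in outdir.iterdir() if p.suffix in {".tsv", ".gff"})
    manifest = {
        "seed": config.seed,
        "samples": samples,
        "files": {f: hashlib.sha256((outdir / f).read_bytes()).hexdigest() for f in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return SyntheticTruth(
        bin_lineages=bin_lineages,
        bin_mean_identity=bin_mean_identity,
        gene_to_bin=gene_to_bin,
        scaffold_to_bin=scaffold_to_bin,
        unbinned_scaffolds=unbinned,
        expression_shares=exp_shares,
        top5_shares=top5,
        top5_shares_binned=top5_binned,
        class_genes=class_genes,
        ec_truth=ec_truth,
        il_genes=il_genes,
        marker=(marker_bin, marker_gene, marker_expected),
        otu_evenness=planted_j,
        ccer_targets=ccer_targets,
    )


# ---------------------------------------------------------------------------
# respirometry trace synthesis


def default_co2_profile(target_ccer: float, flow: float = 0.2, dry_mass: float = 10.0,
                        molar_volume: float = DEFAULT_MOLAR_VOLUME,
                        tau: float = 48.0, duration: float = 168.0) -> Callable[[np.ndarray], np.ndarray]:
    """CO2-fraction profile c(t) = c0 (t/tau) e^(1 - t/tau) scaled so the CER
    integral over [0, duration] equals ``target_ccer`` exactly (closed form)."""
    u_t = duration / tau
    shape_integral = tau * math.e * (1.0 - (1.0 + u_t) * math.exp(-u_t))
    cer_per_co2 = flow * 60.0 * (44.01 / molar_volume) * 1000.0 / dry_mass
    c0 = target_ccer / (cer_per_co2 * shape_integral)

    def profile(t: np.ndarray) -> np.ndarray:
        u = np.asarray(t, dtype=float) / tau
        return c0 * u * np.exp(1.0 - u)

    return profile


def generate_respirometry(
    flow_profile: float | Callable[[np.ndarray], np.ndarray],
    co2_profile: float | Callable[[np.ndarray], np.ndarray],
    dry_mass: float,
    seed: int = 0,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    molar_volume: float = DEFAULT_MOLAR_VOLUME,
) -> RespTrace:
    """Build a respirometry trace from flow / CO2-fraction profiles.

    Profiles may be constants or callables of the time array (hours).  The
    optional Gaussian noise on the CO2 fraction is seeded; ``noise_sd=0``
    with the same seed reproduces the trace exactly.
    """
    if dry_mass <= 0:
        raise ValueError("dry_mass must be positive")
    t = np.linspace(0.0, 168.0, 337) if times is None else np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    flow = flow_profile(t) if callable(flow_profile) else np.full_like(t, float(flow_profile))
    co2 = co2_profile(t) if callable(co2_profile) else np.full_like(t, float(co2_profile))
    if np.any(np.asarray(flow) < 0):
        raise ValueError("negative flow")
    if np.any((np.asarray(co2) < 0) | (np.asarray(co2) > 1)):
        raise ValueError("co2 fraction outside [0, 1]")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        co2 = np.clip(co2 + rng.normal(0.0, noise_sd, size=t.size), 0.0, 1.0)
    return RespTrace(time=t, co2_fraction=np.round(co2, 10), flow=np.round(flow, 10),
                     dry_mass=dry_mass, molar_volume=molar_volume)


def make_planted_trace(target_ccer: float = 299.0, flow: float = 0.2,
                       dry_mass: float = 10.0, tau: float = 48.0,
                       duration: float = 168.0, n_points: int = 337,
                       seed: int = 0, noise_sd: float = 0.0) -> RespTrace:
    """Seven-day trace whose true (continuous) cCER equals ``target_ccer``."""
    profile = default_co2_profile(target_ccer, flow=flow, dry_mass=dry_mass,
                                  tau=tau, duration=duration)
    times = np.linspace(0.0, duration, n_points)
    return generate_respirometry(flow, profile, dry_mass, seed=seed,
                                 times=times, noise_sd=noise_sd)


__all__ = [
    "SimConfig", "SyntheticTruth", "generate_community", "generate_respirometry",
    "make_planted_trace", "default_co2_profile",
]
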