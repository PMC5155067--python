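"""Stage runners tying the modules into a file-driven pipeline.

Each stage reads its inputs through :mod:`binquant.io`, runs one module, and
writes a TSV report; the CLI wraps these functions one-to-one.  All
thresholds default to the study values (95% identity / 40% coverage for EC
transfer, E <= 1e-5 for IL-tolerance flagging).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from binquant import annotation as ann_mod
from binquant import ecology, io as bio, quantify, respirometry as resp
from binquant import taxonomy as tax_mod
from binquant.taxonomy import EXCLUDED_LABELS

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved thresholds and modes for one run (defaults = study values)."""

    min_identity: float = 95.0
    min_coverage: float = 40.0
    evalue_cutoff: float = 1e-5
    lca_top_percent: float = 10.0
    top_k: int = 5
    library_size_mode: str = "column_sum"   # or "external"
    denominator: str = "all_prokaryotic"    # or "binned_only"
    distance_metric: str = "braycurtis"
    linkage_method: str = "average"
    seed: int = 0

    def dump(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")


def run_taxonomy(gff: Path, scaffold_bins: Path, hits: Path, outdir: Path,
                 config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bin taxonomy voting + LCA labels for unbinned scaffolds.

    Writes ``bin_taxonomy.tsv`` (bin_id, lineage, vote_fraction, mean_aai,
    n_genes, is_eukaryote) and ``scaffold_labels.tsv``.
    """
    outdir.mkdir(parents=True, exist_ok=True)
    genes = bio.read_gff(gff)
    memb = bio.read_scaffold_bins(scaffold_bins)
    best = bio.read_hits(hits)

    by_bin: dict[str, list] = {}
    by_scaffold: dict[str, list] = {}
    for g in genes.values():
        h = best.get(g.gene_id)
        b = memb.get(g.scaffold_id)
        if b is not None:
            if h is not None:
                by_bin.setdefault(b, []).append(h)
        else:
            by_scaffold.setdefault(g.scaffold_id, [])
            if h is not None:
                by_scaffold[g.scaffold_id].append(h)

    bin_rows = []
    for b in sorted(set(memb.values())):
        t = tax_mod.vote_bin_taxonomy(b, by_bin.get(b, []))
        bin_rows.append({
            "bin_id": b, "lineage": t.label,
            "vote_fraction": t.vote_fraction, "mean_aai": t.mean_aai,
            "n_genes": t.n_genes, "is_eukaryote": t.is_eukaryote,
        })
    bin_df = pd.DataFrame(bin_rows)
    bin_df.to_csv(outdir / "bin_taxonomy.tsv", sep="\t", index=False, float_format="%.6g")

    scaf_rows = []
    for s in sorted(by_scaffold):
        lab = tax_mod.lca_assign(s, by_scaffold[s], top_percent=config.lca_top_percent)
        scaf_rows.append({"scaffold_id": s, "label": lab.label,
                          "include": lab.include_in_transcriptomics})
    scaf_df = pd.DataFrame(scaf_rows, columns=["scaffold_id", "label", "include"])
    scaf_df.to_csv(outdir / "scaffold_labels.tsv", sep="\t", index=False)
    return bin_df, scaf_df


def run_annotate(ko: Path, ref_ec: Path, ec_hits: Path, il_hits: Path,
                 outdir: Path, config: PipelineConfig) -> pd.DataFrame:
    """EC transfer, enzyme classification, agreement ratios and IL flags.

    Writes ``gene_annotations.tsv`` and ``ko_ec_agreement.tsv``.
    """
    outdir.mkdir(parents=True, exist_ok=True)
    ko_map: dict[str, set[str]] = {}
    for gene, k in bio.read_gene_map(ko, "gene_id", "ko_id").items():
        ko_map.setdefault(gene, set()).add(k)
    ref_ec_map = bio.read_gene_map(ref_ec, "ref_id", "ec")
    ec_map = ann_mod.transfer_ec(bio.read_hits(ec_hits), ref_ec_map,
                                 min_identity=config.min_identity,
                                 min_coverage=config.min_coverage)
    il_flags = ann_mod.flag_il_tolerance(bio.read_hits(il_hits, best_only=False),
                                         evalue_cutoff=config.evalue_cutoff)
    gene_ids = sorted(set(ko_map) | set(ec_map) | set(il_flags))
    annotations = [
        ann_mod.GeneAnnotation(
            gene_id=g,
            ko_ids=frozenset(ko_map.get(g, ())),
            ec_ids=ec_map.get(g, frozenset()),
            il_tolerance=il_flags.get(g, False),
        )
        for g in gene_ids
    ]
    ann_mod.classify_all(annotations)
    df = pd.DataFrame([
        {"gene_id": a.gene_id,
         "ko_ids": ",".join(sorted(a.ko_ids)),
         "ec_ids": ",".join(sorted(a.ec_ids)),
         "enzyme_class": a.enzyme_class or "",
         "il_tolerance": a.il_tolerance}
        for a in annotations
    ])
    df.to_csv(outdir / "gene_annotations.tsv", sep="\t", index=False)
    agreement = ann_mod.ko_ec_agreement(annotations)
    pd.DataFrame(
        [(c, "" if v is None else f"{v:.4g}") for c, v in agreement.items()],
        columns=["enzyme_class", "ko_ec_agreement_pct"],
    ).to_csv(outdir / "ko_ec_agreement.tsv", sep="\t", index=False)
    return df


def run_quantify(gff: Path, counts: Path, scaffold_bins: Path,
                 bin_taxonomy: Path, scaffold_labels: Path,
                 outdir: Path, config: PipelineConfig,
                 annotations: Path | None = None) -> dict[str, pd.DataFrame]:
    """RPKM, bin/phylum/class aggregation and top-share reports."""
    outdir.mkdir(parents=True, exist_ok=True)
    genes = bio.read_gff(gff)
    table = bio.read_counts(counts)
    memb = bio.read_scaffold_bins(scaffold_bins)
    bin_tax = pd.read_csv(bin_taxonomy, sep="\t").set_index("bin_id")
    scaf_lab = pd.read_csv(scaffold_labels, sep="\t").set_index("scaffold_id")

    rpkm = quantify.compute_rpkm(table, genes)
    rpkm.rename_axis("gene_id").to_csv(outdir / "rpkm.tsv", sep="\t", float_format="%.6g")

    euk_bins = set(bin_tax.index[bin_tax["is_eukaryote"].astype(bool)])
    grouping: dict[str, str] = {}
    for gid, g in genes.items():
        b = memb.get(g.scaffold_id)
        if b is not None:
            grouping[gid] = b
        elif g.scaffold_id in scaf_lab.index:
            label = scaf_lab.loc[g.scaffold_id, "label"]
            grouping[gid] = label if label in EXCLUDED_LABELS else f"unbinned:{label}"
    bin_expr, included = quantify.aggregate(rpkm, grouping, excluded_groups=euk_bins)
    report = bin_expr.copy()
    report.insert(0, "included", included)
    report.rename_axis("group").to_csv(outdir / "bin_expression.tsv", sep="\t",
                                       float_format="%.6g")

    shares = {
        s: quantify.top_k_share(bin_expr, included, s, k=config.top_k,
                                denominator=config.denominator)
        for s in bin_expr.columns
    }
    pd.DataFrame(
        [(s, "" if v is None else f"{v:.4f}") for s, v in shares.items()],
        columns=["sample", f"top{config.top_k}_share_pct"],
    ).to_csv(outdir / "top_share.tsv", sep="\t", index=False)

    out = {"rpkm": rpkm, "bin_expression": bin_expr, "included": included,
           "shares": pd.Series(shares)}

    if annotations is not None:
        ann = pd.read_csv(annotations, sep="\t").fillna("")
        class_map = {r.gene_id: r.enzyme_class for r in ann.itertuples()
                     if r.enzyme_class}
        cls_expr, _ = quantify.aggregate(rpkm, class_map)
        cls_expr = cls_expr.drop(index=[quantify.UNGROUPED], errors="ignore")
        cls_expr.rename_axis("enzyme_class").to_csv(
            outdir / "class_expression.tsv", sep="\t", float_format="%.6g")
        out["class_expression"] = cls_expr
    return out


def run_ecology(otus: Path, coverage: Path, outdir: Path,
                config: PipelineConfig) -> pd.DataFrame:
    """Diversity report from the OTU table and distance tree from coverages."""
    outdir.mkdir(parents=True, exist_ok=True)
    otu = bio.read_table(otus, "otu_id").astype(np.int64)
    report = ecology.diversity_report(otu)
    report.to_csv(outdir / "diversity.tsv", sep="\t", float_format="%.6g")
    cov = bio.read_table(coverage, "bin_id")
    tree = ecology.distance_tree(cov, metric=config.distance_metric,
                                 method=config.linkage_method)
    bio.write_newick(tree, outdir / "sample_tree.nwk")
    return report


def run_respire(traces: list[Path], outdir: Path) -> pd.DataFrame:
    """CER / cCER report over one or more trace files."""
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for path in traces:
        trace = resp.read_trace(path)
        cer = resp.compute_cer(trace)
        rows.append({"trace": Path(path).stem,
                     "final_ccer_mg_per_g": resp.integrate_ccer(cer, trace.time),
                     "peak_cer_mg_per_g_h": float(cer.max())})
        resp.cer_report(trace).to_csv(outdir / f"cer_{Path(path).stem}.tsv",
                                      sep="\t", index=False, float_format="%.6g")
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "ccer_summary.tsv", sep="\t", index=False, float_format="%.6g")
    return df
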