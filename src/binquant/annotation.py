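"""Functional annotation reconciliation.

Covers four operations: transferring EC numbers from a reference annotation
by identity/coverage thresholds, classifying genes into the five
lignocellulolytic/acetate enzyme classes by requiring the KEGG Orthology
(KO) and Enzyme Commission (EC) annotations to agree, measuring the KO/EC
agreement ratio per class, and flagging putative ionic-liquid tolerance
genes (SMR-family efflux pumps and relatives) by homology E-value.

Classification demands both a class KO and the class EC, except for
cellulose 1,4-beta-cellobiosidase where the EC number alone suffices — the
KO annotations for that class agree with the EC too rarely to be trusted.
A gene carrying one class's KO with another class's EC is left unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from binquant.io import BestHit, best_hit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnzymeClassDef:
    """One enzyme class: its KO id set, EC id set, and the dual-match flag."""

    name: str
    ko_ids: frozenset[str]
    ec_ids: frozenset[str]
    requires_both: bool = True


#: The five built-in enzyme classes with their KO and EC definitions.
BUILTIN_CLASSES: tuple[EnzymeClassDef, ...] = (
    EnzymeClassDef("endoglucanase",
                   frozenset({"K01179", "K19356", "K19357", "K20542"}),
                   frozenset({"3.2.1.4"})),
    EnzymeClassDef("cellulose 1,4-beta-cellobiosidase",
                   frozenset({"K01225", "K19668"}),
                   frozenset({"3.2.1.91"}),
                   requires_both=False),
    EnzymeClassDef("beta-glucosidase",
                   frozenset({"K01188", "K05349", "K05350"}),
                   frozenset({"3.2.1.21"})),
    EnzymeClassDef("xylanase",
                   frozenset({"K01181", "K13465"}),
                   frozenset({"3.2.1.8"})),
    EnzymeClassDef("acetate kinase",
                   frozenset({"K00925"}),
                   frozenset({"2.7.2.1"})),
)

#: Reference IL-tolerance gene identifiers (efflux pumps / SMR transporters).
IL_TOLERANCE_GENES: tuple[str, ...] = ("eilA", "sugE", "emrE", "smvA", "ykkC", "ykkD")


@dataclass
class GeneAnnotation:
    """Per-gene annotation state: KO ids, EC ids, IL-tolerance flag, class."""

    gene_id: str
    ko_ids: frozenset[str] = frozenset()
    ec_ids: frozenset[str] = frozenset()
    il_tolerance: bool = False
    enzyme_class: str | None = field(default=None)


def validate_classes(classes: Sequence[EnzymeClassDef]) -> None:
    seen_ko: dict[str, str] = {}
    seen_ec: dict[str, str] = {}
    for c in classes:
        if not c.ec_ids:
            raise ValueError(f"class {c.name!r} has no EC ids")
        if c.requires_both and not c.ko_ids:
            raise ValueError(f"class {c.name!r} requires both but has no KO ids")
        for ko in c.ko_ids:
            if seen_ko.setdefault(ko, c.name) != c.name:
                raise ValueError(f"KO {ko} shared by {seen_ko[ko]!r} and {c.name!r}")
        for ec in c.ec_ids:
            if seen_ec.setdefault(ec, c.name) != c.name:
                raise ValueError(f"EC {ec} shared by {seen_ec[ec]!r} and {c.name!r}")


def transfer_ec(
    query_hits: Mapping[str, Sequence[BestHit]] | Mapping[str, BestHit],
    reference_ec: Mapping[str, str | Iterable[str]],
    min_identity: float = 95.0,
    min_coverage: float = 40.0,
) -> dict[str, frozenset[str]]:
    """Transfer EC numbers from an annotated reference by best-hit similarity.

    A gene receives the EC number(s) of its best reference hit iff
    ``pct_identity >= min_identity`` and ``query_coverage >= min_coverage``
    (both inclusive).  Reference genes without an EC are ignored with a
    debug log.  Returns gene id -> frozenset of EC ids (possibly several,
    set semantics).
    """
    if not (0.0 < min_identity <= 100.0) or not (0.0 < min_coverage <= 100.0):
        raise ValueError("thresholds must be in (0, 100]")
    out: dict[str, frozenset[str]] = {}
    for gene_id, hits in query_hits.items():
        hit = best_hit(hits) if isinstance(hits, (list, tuple)) else hits
        if hit.pct_identity < min_identity or hit.query_coverage < min_coverage:
            continue
        ref = reference_ec.get(hit.subject_id)
        if ref is None:
            logger.debug("reference gene %s has no EC; hit from %s ignored",
                         hit.subject_id, gene_id)
            continue
        ecs = frozenset([ref]) if isinstance(ref, str) else frozenset(ref)
        if ecs:
            out[gene_id] = ecs
    return out


def classify_enzyme(
    ann: GeneAnnotation,
    classes: Sequence[EnzymeClassDef] = BUILTIN_CLASSES,
) -> str | None:
    """Assign a gene to at most one enzyme class by KO/EC consistency.

    For dual-match classes the gene needs a class KO *and* a class EC.  For
    EC-only classes (cellobiosidase) the EC suffices, provided the gene does
    not carry a KO belonging to a different class — inconsistent KO/EC
    combinations are never classified.
    """
    validate_classes(classes)
    candidates: list[str] = []
    for c in classes:
        ko_match = bool(ann.ko_ids & c.ko_ids)
        ec_match = bool(ann.ec_ids & c.ec_ids)
        foreign_ko = any(ann.ko_ids & d.ko_ids for d in classes if d.name != c.name)
        if c.requires_both:
            if ko_match and ec_match:
                candidates.append(c.name)
        else:
            if ec_match and not foreign_ko:
                candidates.append(c.name)
    if len(candidates) == 1:
        return candidates[0]
    if len(candidates) > 1:
        logger.warning("gene %s matches several classes %s; left unclassified",
                       ann.gene_id, candidates)
    return None


def classify_all(
    annotations: Iterable[GeneAnnotation],
    classes: Sequence[EnzymeClassDef] = BUILTIN_CLASSES,
) -> dict[str, str]:
    """Classify a collection; returns gene id -> class name for classified genes."""
    out: dict[str, str] = {}
    for ann in annotations:
        cls = classify_enzyme(ann, classes)
        ann.enzyme_class = cls
        if cls is not None:
            out[ann.gene_id] = cls
    return out


def ko_ec_agreement(
    annotations: Iterable[GeneAnnotation],
    classes: Sequence[EnzymeClassDef] = BUILTIN_CLASSES,
) -> dict[str, float | None]:
    """Percent of KO-annotated genes per class whose EC agrees.

    For each class: 100 x |genes with a class KO and a class EC| /
    |genes with a class KO|.  Classes with no KO-annotated gene report None
    rather than zero.
    """
    anns = list(annotations)
    out: dict[str, float | None] = {}
    for c in classes:
        with_ko = [a for a in anns if a.ko_ids & c.ko_ids]
        if not with_ko:
            out[c.name] = None
            continue
        agree = sum(1 for a in with_ko if a.ec_ids & c.ec_ids)
        out[c.name] = 100.0 * agree / len(with_ko)
    return out


def flag_il_tolerance(
    hits: Mapping[str, Sequence[BestHit]],
    evalue_cutoff: float = 1e-5,
) -> dict[str, bool]:
    """Flag genes homologous to the reference IL-tolerance genes.

    A gene is flagged iff any of its hits against the tolerance-gene set has
    E-value <= cutoff (inclusive boundary).
    """
    return {
        gene_id: any(h.evalue <= evalue_cutoff for h in gene_hits)
        for gene_id, gene_hits in hits.items()
    }


__all__ = [
    "EnzymeClassDef", "GeneAnnotation", "BUILTIN_CLASSES", "IL_TOLERANCE_GENES",
    "transfer_ec", "classify_enzyme", "classify_all", "ko_ec_agreement",
    "flag_il_tolerance", "validate_classes",
]
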