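"""Evidence-graded metabolite annotation and pathway concordance.

Annotation evidence for an unknown feature is combined into a single
category (1 strongest .. 6 weakest) with the matching Metabolomics
Standards Initiative (MSI) identification level:

1. match to an authentic reference standard            -> MSI 1
2. clusters with a standard-validated known compound   -> MSI 1
3. MS/MS spectral-library match                        -> MSI 2
4. MS/MS + RT match to an in-house chemical backbone   -> MSI 3
5. formula/structure prediction (external tool import) -> (not in MSI 2007)
6. m/z database match                                  -> (not in MSI 2007)

Structure/formula predictions and database hits are imported from
user-provided tables; this module is the integration logic only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["EvidenceBundle", "AnnotationRecord", "assign_category", "pathway_concordance"]

logger = logging.getLogger(__name__)

MSI_BY_CATEGORY = {1: 1, 2: 1, 3: 2, 4: 3, 5: None, 6: None}


@dataclass
class EvidenceBundle:
    """All annotation evidence collected for one feature.

    Each non-empty field is a flag with its payload (the identity or class
    the evidence supports); ``predictions`` carries an external structure
    prediction candidate list, strongest first.
    """

    feature: str
    standard_match: str = ""
    cocluster_identity: str = ""
    library_match: str = ""
    backbone_class: str = ""
    predictions: list[str] = field(default_factory=list)
    mz_db_match: str = ""
    gene: str = ""


@dataclass
class AnnotationRecord:
    feature: str
    identity: str = ""
    category: int | None = None
    msi_class: int | None = None
    confidence_note: str = ""
    pathway_concordance: str = "unknown"


def assign_category(evidence: EvidenceBundle) -> AnnotationRecord:
    """Assign the highest-priority applicable annotation category.

    Categories are tried in order 1 > 2 > 3 > 4 > 5 > 6; the winning
    source supplies the identity (or class). Conflicting identities from
    weaker sources are logged, never override. The mapping to MSI classes
    is fixed: categories 1-2 -> MSI 1, 3 -> MSI 2, 4 -> MSI 3.
    """
    sources: list[tuple[int, str, str]] = [
        (1, evidence.standard_match, "authentic standard"),
        (2, evidence.cocluster_identity, "co-clustered known metabolite"),
        (3, evidence.library_match, "spectral library match"),
        (4, evidence.backbone_class, "in-house backbone MS/MS+RT match"),
        (5, evidence.predictions[0] if evidence.predictions else "", "structure prediction"),
        (6, evidence.mz_db_match, "m/z database match"),
    ]
    present = [(cat, ident, note) for cat, ident, note in sources if ident]
    if not present:
        return AnnotationRecord(feature=evidence.feature)
    cat, ident, note = present[0]
    others = {i for _, i, _ in present[1:] if i and i != ident}
    if others:
        logger.info(
            "feature %s: category %d identity %r conflicts with weaker evidence %s",
            evidence.feature, cat, ident, sorted(others),
        )
    n_sources = len(present)
    return AnnotationRecord(
        feature=evidence.feature,
        identity=ident,
        category=cat,
        msi_class=MSI_BY_CATEGORY[cat],
        confidence_note=f"{note}; {n_sources} supporting source(s)",
    )


def pathway_concordance(
    record: AnnotationRecord,
    gene: str,
    pathway_map: pd.DataFrame | dict[str, set[str]],
) -> AnnotationRecord:
    """Check the annotation against the candidate gene's pathways.

    ``pathway_map`` maps gene symbol to the set of metabolite identities
    or classes in its pathways (two-column frame ``gene``/``metabolite``
    or a dict). Concordant when the predicted identity or class intersects
    the gene's set; discordant when the gene is mapped but there is no
    intersection; unknown when the gene is absent or nothing was
    predicted.
    """
    if isinstance(pathway_map, pd.DataFrame):
        mapping: dict[str, set[str]] = {
            g: set(grp["metabolite"]) for g, grp in pathway_map.groupby("gene")
        }
    else:
        mapping = {g: set(v) for g, v in pathway_map.items()}

    if not gene or gene not in mapping or not record.identity:
        record.pathway_concordance = "unknown"
        return record
    targets = {t.lower() for t in mapping[gene]}
    record.pathway_concordance = (
        "concordant" if record.identity.lower() in targets else "discordant"
    )
    return record
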