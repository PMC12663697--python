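"""AP2/ERF family assignment from domain architecture.

Family rules follow the standard domain-count convention for the
superfamily: two AP2 domains define the AP2 family; one AP2 plus one B3
domain defines RAV; a single AP2 domain leaves ERF/DREB/Soloist, which are
indistinguishable from domain counts alone and are labelled ``ERF-like``
unless a labelled reference panel resolves a finer group; genes with no AP2
domain are ``unclassified`` and are filtered from downstream group tables.
Finer groups (DREB-III, ERF-I, Soloist, …) are assigned by the
highest-identity labelled panel sequence meeting the builder's 90/90
identity/coverage thresholds, replacing tree-based classification.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import GeneRecord
from .ogg_builder import BuilderParams, pairwise_score

FAMILIES = ("AP2", "RAV", "ERF-like", "unclassified")


@dataclass(frozen=True)
class DomainAnnotation:
    gene_id: str
    ap2_count: int
    b3_count: int


def assign_family(annotation: DomainAnnotation) -> str:
    """Pure function of (ap2_count, b3_count) → family label."""
    if annotation.ap2_count >= 2:
        return "AP2"
    if annotation.ap2_count == 1 and annotation.b3_count >= 1:
        return "RAV"
    if annotation.ap2_count == 1:
        return "ERF-like"
    return "unclassified"


def assign_group(
    gene: GeneRecord,
    panel: Sequence[tuple[str, str, str]],
    params: BuilderParams | None = None,
) -> tuple[str | None, float]:
    """Nearest-labelled-reference group assignment.

    ``panel`` holds (panel_id, group_label, cds) triples. The group of the
    best-identity panel member passing both thresholds is returned with that
    identity; below threshold the group stays unset. Ties on identity are
    broken by coverage, then panel order.
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    params = params or BuilderParams()
    best_group: str | None = None
    best_key: tuple[float, float] | None = None
    best_identity = 0.0
    for _panel_id, group, cds in panel:
        score = pairwise_score(gene.cds, cds)
        best_identity = max(best_identity, score.identity)
        if score.identity < params.min_identity or score.coverage < params.min_coverage:
            continue
        key = (score.identity, score.coverage)
        if best_key is None or key > best_key:
            best_key = key
            best_group = group
    return best_group, best_identity


def assign_families(
    domains: Mapping[str, tuple[int, int]],
    genes: Mapping[str, GeneRecord] | None = None,
    panel: Sequence[tuple[str, str, str]] | None = None,
    params: BuilderParams | None = None,
) -> list[dict[str, object]]:
    """Family (and optional group) labels for every annotated gene."""
    rows = []
    for gene_id in sorted(domains):
        ap2, b3 = domains[gene_id]
        family = assign_family(DomainAnnotation(gene_id, ap2, b3))
        group = None
        identity = None
        if panel and genes and gene_id in genes and family != "unclassified":
            group, identity = assign_group(genes[gene_id], panel, params)
        rows.append(
            {
                "gene_id": gene_id,
                "family": family,
                "group": group,
                "best_identity": identity,
            }
        )
    return rows


FAMILIES_SCHEMA = {
    "gene_id": "str",
    "family": "str",
    "group": "str",
    "best_identity": "float",
}
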