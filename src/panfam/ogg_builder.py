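"""Iterative construction of orthologous gene groups (OGGs) across accessions.

The builder re-implements the iterative presence/absence scan used to build
pan-gene families: all genes of a seed accession become initial reference
sequences (one group each); every remaining gene is assigned to the best
reference it matches at ≥ min_identity and ≥ min_coverage; whenever genes
remain unassigned, the "most abundant" unassigned sequence of the next
accession in iteration order — the one with the most above-threshold
neighbours among all unassigned sequences — is elected as a new reference,
and assignment repeats. The process terminates because every round either
assigns or promotes at least one gene, and yields a partition of the input.

Sequence comparison is an in-process global alignment with free end gaps
(match +1, mismatch −1, gap open −2, gap extend −0.5) instead of BLASTn;
identity is computed over aligned columns excluding terminal gaps, and
coverage over both sequences (both must pass).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import DatasetManifest, GeneRecord, PanfamError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentScore:
    """Identity/coverage summary of one pairwise alignment.

    identity: identical A/C/G/T columns over aligned columns excluding
    terminal gaps, ×100. Coverage is reported for both sequences (aligned
    non-gap positions over sequence length, ×100); ``coverage`` is the
    stricter of the two. Columns involving N count as mismatches.
    """

    identity: float
    coverage_reference: float
    coverage_query: float
    aligned_columns: int

    @property
    def coverage(self) -> float:
        return min(self.coverage_reference, self.coverage_query)


@dataclass
class OrthologousGeneGroup:
    ogg_id: str
    reference_gene: str
    members: set[str] = field(default_factory=set)
    per_accession_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class BuilderParams:
    min_identity: float = 90.0
    min_coverage: float = 90.0
    accession_order: list[str] | None = None  # default: seed first, then sorted
    seed_accession: str | None = None  # default: first accession of the manifest

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage"):
            value = getattr(self, name)
            if not 0 < value <= 100:
                raise PanfamError(f"{name} must be in (0, 100], got {value}")


def _make_aligner() -> Align.PairwiseAligner:
    # ACGTN matrix with every N pairing scored as a mismatch (N==N included).
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            matrix[a, b] = 1.0 if (a == b and a != "N") else -1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aligner.end_insertion_score = 0.0  # free end gaps on both sequences
    aligner.end_deletion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_score(query: str, reference: str) -> AlignmentScore:
    """Align two CDSs and report identity and reciprocal coverage."""
    if not query or not reference:
        raise PanfamError("cannot align an empty sequence")
    alignment = _ALIGNER.align(reference.upper(), query.upper())[0]
    row_ref, row_qry = str(alignment[0]), str(alignment[1])

    # Terminal gaps are the free-end-gap overhangs before the first and after
    # the last aligned pair; identity is computed over everything in between.
    first_pair = last_pair = None
    for i in range(len(row_ref)):
        if row_ref[i] != "-" and row_qry[i] != "-":
            if first_pair is None:
                first_pair = i
            last_pair = i
    if first_pair is None:
        raise PanfamError("alignment contains no aligned columns")
    columns = range(first_pair, last_pair + 1)

    identical = 0
    aligned_pairs = 0
    for i in columns:
        a, b = row_ref[i], row_qry[i]
        if a != "-" and b != "-":
            aligned_pairs += 1
            if a == b and a != "N":
                identical += 1
    n_columns = len(columns)
    identity = 100.0 * identical / n_columns
    # The window spans every aligned pair, so pair count serves both coverages.
    cov_ref = 100.0 * aligned_pairs / len(reference)
    cov_qry = 100.0 * aligned_pairs / len(query)
    return AlignmentScore(
        identity=identity,
        coverage_reference=cov_ref,
        coverage_query=cov_qry,
        aligned_columns=n_columns,
    )


def _passes(score: AlignmentScore, params: BuilderParams) -> bool:
    return score.identity >= params.min_identity and score.coverage >= params.min_coverage


def assign_batch(
    candidates: Sequence[GeneRecord],
    references: Sequence[tuple[str, str]],
    params: BuilderParams,
) -> tuple[dict[str, str], list[GeneRecord]]:
    """Assign each candidate to its best above-threshold reference.

    A candidate is assigned to the passing reference with the highest
    identity, ties broken by higher coverage, then by lexicographically
    smallest ogg_id; candidates passing no reference are returned unassigned.
    """
    if not references:
        raise PanfamError("assign_batch requires at least one reference")
    assignments: dict[str, str] = {}
    unassigned: list[GeneRecord] = []
    for record in candidates:
        best: tuple[float, float, str] | None = None
        for ogg_id, ref_seq in references:
            score = pairwise_score(record.cds, ref_seq)
            if not _passes(score, params):
                continue
            key = (score.identity, score.coverage, ogg_id)
            if best is None or (key[0], key[1]) > (best[0], best[1]) or (
                (key[0], key[1]) == (best[0], best[1]) and ogg_id < best[2]
            ):
                best = key
        if best is None:
            unassigned.append(record)
        else:
            assignments[record.gene_id] = best[2]
    return assignments, unassigned


def elect_reference(
    unassigned_by_accession: Mapping[str, Sequence[GeneRecord]],
    params: BuilderParams,
) -> GeneRecord:
    """Pick the next reference: the greedy centroid of the next accession.

    Among unassigned genes of the first accession (in ``accession_order``)
    that still holds any, the gene with the greatest number of
    above-threshold neighbours among *all* unassigned genes wins; ties go to
    the longest CDS, then the smallest gene_id.
    """
    order = params.accession_order or sorted(unassigned_by_accession)
    accession = next(
        (a for a in order if unassigned_by_accession.get(a)),
        None,
    )
    if accession is None:
        raise PanfamError("no unassigned genes to elect a reference from")
    candidates = list(unassigned_by_accession[accession])
    pool = [g for genes in unassigned_by_accession.values() for g in genes]

    def neighbor_count(record: GeneRecord) -> int:
        count = 0
        for other in pool:
            if other.gene_id == record.gene_id:
                continue
            if _passes(pairwise_score(other.cds, record.cds), params):
                count += 1
        return count

    return sorted(
        candidates,
        key=lambda g: (-neighbor_count(g), -len(g.cds), g.gene_id),
    )[0]


def build_pan_family(
    manifest: DatasetManifest,
    params: BuilderParams | None = None,
) -> list[OrthologousGeneGroup]:
    """Run the full iterative build; returns a partition of all genes."""
    if len(manifest) == 0:
        raise PanfamError("manifest contains no genes")
    params = params or BuilderParams()
    seed = params.seed_accession or manifest.accessions[0]
    if seed not in manifest.accessions:
        raise PanfamError(f"seed accession {seed!r} not in manifest")
    if params.accession_order is None:
        params = BuilderParams(
            min_identity=params.min_identity,
            min_coverage=params.min_coverage,
            accession_order=[seed] + sorted(a for a in manifest.accessions if a != seed),
            seed_accession=seed,
        )
    logger.info(
        "building pan family: %d genes, %d accessions, identity>=%g coverage>=%g, seed=%s",
        len(manifest), len(manifest.accessions), params.min_identity, params.min_coverage, seed,
    )

    oggs: list[OrthologousGeneGroup] = []
    ref_seqs: dict[str, str] = {}

    def open_ogg(record: GeneRecord) -> OrthologousGeneGroup:
        ogg = OrthologousGeneGroup(
            ogg_id=f"OGG{len(oggs) + 1:05d}",
            reference_gene=record.gene_id,
            members={record.gene_id},
        )
        oggs.append(ogg)
        ref_seqs[ogg.ogg_id] = record.cds
        return ogg

    seed_genes = [g for g in manifest.gene_index.values() if g.accession_id == seed]
    for record in seed_genes:
        open_ogg(record)
    remaining = [g for g in manifest.gene_index.values() if g.accession_id != seed]

    by_id = {o.ogg_id: o for o in oggs}
    # Incremental best-passing-hit per remaining gene; references only
    # accumulate, so each round only the newly opened reference is scored.
    best: dict[str, tuple[float, float, str]] = {}

    def update_best(records: Iterable[GeneRecord], refs: list[tuple[str, str]]) -> None:
        for record in records:
            for ogg_id, seq in refs:
                score = pairwise_score(record.cds, seq)
                if not _passes(score, params):
                    continue
                key = (score.identity, score.coverage, ogg_id)
                prev = best.get(record.gene_id)
                if (
                    prev is None
                    or (key[0], key[1]) > (prev[0], prev[1])
                    or ((key[0], key[1]) == (prev[0], prev[1]) and ogg_id < prev[2])
                ):
                    best[record.gene_id] = key

    update_best(remaining, [(o.ogg_id, ref_seqs[o.ogg_id]) for o in oggs])
    while remaining:
        still = []
        for record in remaining:
            hit = best.get(record.gene_id)
            if hit is None:
                still.append(record)
            else:
                by_id[hit[2]].members.add(record.gene_id)
        remaining = still
        if not remaining:
            break
        grouped: dict[str, list[GeneRecord]] = {}
        for record in remaining:
            grouped.setdefault(record.accession_id, []).append(record)
        new_ref = elect_reference(grouped, params)
        ogg = open_ogg(new_ref)
        by_id[ogg.ogg_id] = ogg
        remaining = [g for g in remaining if g.gene_id != new_ref.gene_id]
        update_best(remaining, [(ogg.ogg_id, ref_seqs[ogg.ogg_id])])

    for ogg in oggs:
        counts: dict[str, int] = {}
        for gid in ogg.members:
            accession = manifest.gene_index[gid].accession_id
            counts[accession] = counts.get(accession, 0) + 1
        ogg.per_accession_counts = counts
    logger.info("built %d OGGs from %d genes", len(oggs), len(manifest))
    return oggs


def occupancy_matrix(
    oggs: Sequence[OrthologousGeneGroup],
    manifest: DatasetManifest,
) -> pd.DataFrame:
    """OGG × accession member-count matrix (row sums are OGG sizes)."""
    matrix = pd.DataFrame(
        0,
        index=[o.ogg_id for o in oggs],
        columns=list(manifest.accessions),
        dtype=int,
    )
    for ogg in oggs:
        for accession, count in ogg.per_accession_counts.items():
            matrix.loc[ogg.ogg_id, accession] = count
    return matrix


def oggs_to_table(oggs: Sequence[OrthologousGeneGroup]) -> list[dict[str, object]]:
    return [
        {
            "ogg_id": o.ogg_id,
            "reference_gene": o.reference_gene,
            "members": ";".join(sorted(o.members)),
        }
        for o in oggs
    ]


OGGS_SCHEMA = {"ogg_id": "str", "reference_gene": "str", "members": "str"}
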