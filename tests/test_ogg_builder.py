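import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from panfam.io_formats import DatasetManifest, GeneRecord, PanfamError
from panfam.ogg_builder import (
    BuilderParams,
    assign_batch,
    build_pan_family,
    elect_reference,
    occupancy_matrix,
    pairwise_score,
)


def _record(gene_id, accession, cds):
    return GeneRecord(gene_id, accession, "pop", cds)


def _manifest(records):
    accessions = sorted({r.accession_id for r in records})
    return DatasetManifest(
        accessions=accessions,
        population_map={a: "pop" for a in accessions},
        gene_index={r.gene_id: r for r in records},
    )


def _mutate(seq, positions, rng=None):
    """Substitute at fixed positions (cycle A->C->G->T->A)."""
    subst = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = subst[out[p]]
    return "".join(out)


# Fixed pseudorandom CDS: repetition-free so alignments have a unique register.
_BASE_RNG = np.random.default_rng(20240917)
BASE = "ATG" + "".join(_BASE_RNG.choice(list("ACGT"), size=294)) + "TAA"


class TestPairwiseScore:
    def test_self_alignment_is_perfect(self):
        score = pairwise_score(BASE, BASE)
        assert score.identity == 100.0
        assert score.coverage == 100.0

    def test_thirty_substitutions_give_90_percent(self):
        query = _mutate(BASE, range(0, 300, 10))
        score = pairwise_score(query, BASE)
        assert score.identity == pytest.approx(90.0)
        assert score.coverage == pytest.approx(100.0)

    def test_truncated_reference_coverage(self):
        # A 250-nt prefix aligned against the full 300-nt sequence: the long
        # side's coverage is 250/300, computable without any aligner.
        score = pairwise_score(BASE[:250], BASE)
        assert score.coverage_reference == pytest.approx(100 * 250 / 300, abs=1e-9)
        assert score.coverage_query == pytest.approx(100.0)
        assert score.coverage < 90.0

    def test_n_bases_count_as_mismatch(self):
        # Ns in the middle cannot be shuffled into free end gaps, so N/N
        # columns stay aligned and score as mismatches.
        seq = BASE[:100] + "NNN" + BASE[103:]
        score = pairwise_score(seq, seq)
        assert score.identity == pytest.approx(100 * 297 / 300)

    def test_empty_sequence_rejected(self):
        with pytest.raises(PanfamError):
            pairwise_score("", BASE)


class TestAssignBatch:
    params = BuilderParams()

    def test_identical_candidate_assigned(self):
        refs = [("OGG1", BASE)]
        cand = [_record("g1", "a2", BASE)]
        assignments, unassigned = assign_batch(cand, refs, self.params)
        assert assignments == {"g1": "OGG1"} and not unassigned

    def test_below_threshold_unassigned(self):
        refs = [("OGG1", BASE)]
        cand = [_record("g1", "a2", _mutate(BASE, range(0, 300, 7)))]  # ~85.7%
        assignments, unassigned = assign_batch(cand, refs, self.params)
        assert not assignments and [r.gene_id for r in unassigned] == ["g1"]

    def test_equal_scores_break_to_smaller_ogg_id(self):
        refs = [("OGG2", BASE), ("OGG1", BASE)]
        cand = [_record("g1", "a2", BASE)]
        assignments, _ = assign_batch(cand, refs, self.params)
        assert assignments["g1"] == "OGG1"


class TestElectReference:
    params = BuilderParams(accession_order=["a1", "a2"])

    def test_single_gene_elected(self):
        gene = _record("g1", "a1", BASE)
        assert elect_reference({"a1": [gene]}, self.params) is gene

    def test_centroid_beats_singleton(self):
        cluster = [
            _record(f"g{i}", "a1", _mutate(BASE, [i]))  # mutually ~99%
            for i in range(3)
        ]
        outlier = _record("g9", "a1", _mutate(BASE, range(0, 300, 5)))  # 80%
        chosen = elect_reference({"a1": cluster + [outlier]}, self.params)
        assert chosen.gene_id in {"g0", "g1", "g2"}

    def test_neighbor_tie_breaks_to_longer_cds(self):
        long_gene = _record("gA", "a1", BASE)
        short_gene = _record("gB", "a1", BASE[:291])
        chosen = elect_reference({"a1": [long_gene, short_gene]}, self.params)
        assert chosen.gene_id == "gA"


def brute_force_build(manifest, params):
    """Oracle: full re-scan of every unassigned gene each round (no caching)."""
    seed = params.seed_accession or manifest.accessions[0]
    order = [seed] + sorted(a for a in manifest.accessions if a != seed)
    params = BuilderParams(params.min_identity, params.min_coverage, order, seed)
    refs = []
    membership = {}
    for g in manifest.gene_index.values():
        if g.accession_id == seed:
            ogg = f"OGG{len(refs) + 1:05d}"
            refs.append((ogg, g.cds))
            membership[g.gene_id] = ogg
    remaining = [g for g in manifest.gene_index.values() if g.accession_id != seed]
    while remaining:
        assignments, unassigned = assign_batch(remaining, refs, params)
        membership.update(assignments)
        remaining = unassigned
        if not remaining:
            break
        grouped = {}
        for g in remaining:
            grouped.setdefault(g.accession_id, []).append(g)
        new_ref = elect_reference(grouped, params)
        ogg = f"OGG{len(refs) + 1:05d}"
        refs.append((ogg, new_ref.cds))
        membership[new_ref.gene_id] = ogg
        remaining = [g for g in remaining if g.gene_id != new_ref.gene_id]
    return membership


def _toy_manifest(rng):
    """3 accessions, 4 well-separated families, some missing members."""
    rng = np.random.default_rng(rng)
    bases = []
    while len(bases) < 4:
        cds = "ATG" + "".join(rng.choice(list("ACGT"), size=96)) + "TAA"
        if all(pairwise_score(cds, b).identity < 75 for b in bases):
            bases.append(cds)
    records = []
    presence = [(0, 1, 2), (0, 1), (1, 2), (0, 2)]
    for fam, (base, accs) in enumerate(zip(bases, presence)):
        for a in accs:
            records.append(
                _record(f"f{fam}_a{a}", f"acc{a}", _mutate(base, [5 + fam, 40 + a]))
            )
    return _manifest(records)


class TestBuildPanFamily:
    def test_singleton_genes_make_singleton_oggs(self):
        rng = np.random.default_rng(0)
        records = []
        seqs = []
        while len(seqs) < 3:
            cds = "ATG" + "".join(rng.choice(list("ACGT"), size=60)) + "TAA"
            if all(pairwise_score(cds, s).identity < 75 for s in seqs):
                seqs.append(cds)
        for i, s in enumerate(seqs):
            records.append(_record(f"g{i}", "a1", s))
        oggs = build_pan_family(_manifest(records))
        assert len(oggs) == 3
        assert all(len(o.members) == 1 for o in oggs)

    def test_empty_manifest_rejected(self):
        with pytest.raises(PanfamError):
            build_pan_family(_manifest([]))

    def test_partition_property(self, scaled_oggs, scaled_manifest):
        seen = set()
        for ogg in scaled_oggs:
            assert ogg.reference_gene in ogg.members
            assert not (ogg.members & seen)
            seen |= ogg.members
        assert seen == set(scaled_manifest.gene_index)

    def test_matches_brute_force_oracle(self):
        manifest = _toy_manifest(3)
        params = BuilderParams()
        oggs = build_pan_family(manifest, params)
        fast = {g: o.ogg_id for o in oggs for g in o.members}
        slow = brute_force_build(manifest, params)
        assert fast == slow

    def test_recovery_ari_is_one(self, scaled_dataset, scaled_oggs):
        dataset, _ = scaled_dataset
        pred = {g: o.ogg_id for o in scaled_oggs for g in o.members}
        genes = sorted(dataset.truth.membership)
        ari = adjusted_rand_score(
            [dataset.truth.membership[g] for g in genes], [pred[g] for g in genes]
        )
        assert ari == 1.0

    def test_threshold_monotonicity(self):
        manifest = _toy_manifest(5)
        n_oggs = [
            len(build_pan_family(manifest, BuilderParams(min_identity=mi)))
            for mi in (80.0, 90.0, 99.5)
        ]
        assert n_oggs == sorted(n_oggs)

    def test_idempotence_on_own_references(self, scaled_oggs, scaled_manifest):
        # Re-assigning every gene to the final reference set must not leave
        # anything unassigned (the loop truly converged).
        refs = [(o.ogg_id, scaled_manifest.gene_index[o.reference_gene].cds) for o in scaled_oggs]
        _, unassigned = assign_batch(
            list(scaled_manifest.gene_index.values()), refs, BuilderParams()
        )
        assert unassigned == []


class TestOccupancyMatrix:
    def test_row_shape_and_counts(self):
        from panfam.ogg_builder import OrthologousGeneGroup

        records = [
            _record("g1", "a1", BASE),
            _record("g2", "a1", _mutate(BASE, [3])),
        ]
        manifest = _manifest(records)
        manifest.accessions = ["a1", "a2"]
        manifest.population_map["a2"] = "pop"
        ogg = OrthologousGeneGroup(
            "OGG00001", "g1", {"g1", "g2"}, {"a1": 2}
        )
        matrix = occupancy_matrix([ogg], manifest)
        assert list(matrix.columns) == ["a1", "a2"]
        assert matrix.iloc[0].tolist() == [2, 0]

    def test_column_sums_equal_accession_gene_counts(self, scaled_oggs, scaled_manifest):
        matrix = occupancy_matrix(scaled_oggs, scaled_manifest)
        for accession in scaled_manifest.accessions:
            n = sum(
                1 for g in scaled_manifest.gene_index.values() if g.accession_id == accession
            )
            assert matrix[accession].sum() == n

    def test_occupancy_matches_truth(self, scaled_dataset, scaled_oggs, scaled_manifest):
        dataset, _ = scaled_dataset
        matrix = occupancy_matrix(scaled_oggs, scaled_manifest)
        occupancy = (matrix > 0).sum(axis=1)
        # map each built OGG to its true OGG through any member
        for ogg in scaled_oggs:
            true_ogg = dataset.truth.membership[next(iter(ogg.members))]
            assert occupancy[ogg.ogg_id] == dataset.truth.occupancy[true_ogg]
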