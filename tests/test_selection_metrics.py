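import math
from itertools import permutations

import numpy as np
import pytest
from Bio.Data import CodonTable

from panfam.io_formats import PanfamError
from panfam.selection_metrics import (
    KaKsEstimate,
    codon_align,
    estimate_pair,
    kaks_significance,
    ng86,
    ogg_pairwise_kaks,
    selection_compare,
)

# ---------------------------------------------------------------------------
# Brute-force NG86 oracle, written directly from the counting definitions.

_CT = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_CT.stop_codons)


def _aa(codon):
    return _CT.forward_table[codon]


def oracle_sites(codon):
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            valid += 1
            if _aa(alt) == _aa(codon):
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def oracle_substitutions(ca, cb):
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0, True
    syn_tot = nonsyn_tot = 0.0
    n_ok = 0
    for order in permutations(diff):
        cur = ca
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_ok += 1
    if n_ok == 0:
        return 0.0, 0.0, False
    return syn_tot / n_ok, nonsyn_tot / n_ok, True


def oracle_ng86(codon_pairs):
    S = N = Sd = Nd = 0.0
    for ca, cb in codon_pairs:
        sd, nd, ok = oracle_substitutions(ca, cb)
        if not ok:
            continue
        sa, na = oracle_sites(ca)
        sb, nb = oracle_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += sd
        Nd += nd
    ps = Sd / S if S else None
    pn = Nd / N if N else None

    def jc(p):
        return None if p is None or p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return S, N, Sd, Nd, jc(ps), jc(pn)


_SENSE = [c for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3)) if c not in _STOPS]


def _random_codon_pairs(rng, n_codons):
    return [
        (_SENSE[rng.integers(61)], _SENSE[rng.integers(61)]) for _ in range(n_codons)
    ]


# ---------------------------------------------------------------------------


class TestCodonAlign:
    def test_identical_cds_no_gaps(self):
        cds = "ATGGCTAAGGATTAA"
        columns = codon_align(cds, cds)
        assert all(a is not None and b is not None for a, b in columns)
        assert len(columns) == 4  # terminal stop stripped

    def test_deleted_codon_yields_one_gap_column(self):
        cds_a = "ATGGCTAAGGATCTTGAGTAA"
        cds_b = "ATGGCTGATCTTGAGTAA"  # AAG removed
        columns = codon_align(cds_a, cds_b)
        gaps = [(a, b) for a, b in columns if a is None or b is None]
        assert len(gaps) == 1 and gaps[0][1] is None
        # degap invariant
        assert "".join(a for a, _ in columns if a) == cds_a[:-3]
        assert "".join(b for _, b in columns if b) == cds_b[:-3]

    def test_synonymous_mutant_alignment_is_gap_free(self):
        cds_a = "ATGGCTAAGGATTAA"
        cds_b = "ATGGCAAAGGACTAA"  # GCT->GCA, GAT->GAC
        columns = codon_align(cds_a, cds_b)
        assert all(a and b for a, b in columns)
        assert sum(a != b for a, b in columns) == 2

    def test_untranslatable_input_rejected(self):
        with pytest.raises(PanfamError):
            codon_align("ATGTAACCC", "ATGCCC")  # internal stop
        with pytest.raises(PanfamError):
            codon_align("ATGC", "ATGCCC")


class TestNg86:
    def test_identical_sequences(self):
        est = estimate_pair("ATGGCTAAGGATTAA", "ATGGCTAAGGATTAA")
        assert est.ka == est.ks == 0.0
        assert est.omega is None  # 0/0

    def test_glycine_triplet_example(self):
        est = ng86(codon_align("GGTGGTGGT", "GGCGGTGGT"))
        assert est.S == pytest.approx(3.0)
        assert est.N_sites == pytest.approx(6.0)
        assert est.Sd == pytest.approx(1.0)
        assert est.Nd == pytest.approx(0.0)
        assert est.ka == 0.0
        assert est.ks == pytest.approx(-0.75 * math.log(1 - 4 / 9), abs=1e-9)

    def test_saturation_guard_single_codon(self):
        est = ng86(codon_align("GGT", "GGC"))
        assert est.ps == pytest.approx(1.0)
        assert est.ks is None and est.omega is None

    def test_site_conservation_and_symmetry(self, rng):
        for _ in range(50):
            pairs = _random_codon_pairs(rng, int(rng.integers(2, 20)))
            fwd = ng86(pairs)
            rev = ng86([(b, a) for a, b in pairs])
            assert fwd.S + fwd.N_sites == pytest.approx(3.0 * fwd.n_columns)
            assert rev.S == pytest.approx(fwd.S)
            assert rev.Sd == pytest.approx(fwd.Sd)
            assert rev.Nd == pytest.approx(fwd.Nd)

    def test_oracle_equivalence_500_random_alignments(self, rng):
        for _ in range(500):
            pairs = _random_codon_pairs(rng, int(rng.integers(1, 31)))
            got = ng86(pairs)
            S, N, Sd, Nd, ks, ka = oracle_ng86(pairs)
            assert got.S == pytest.approx(S, abs=1e-9)
            assert got.N_sites == pytest.approx(N, abs=1e-9)
            assert got.Sd == pytest.approx(Sd, abs=1e-9)
            assert got.Nd == pytest.approx(Nd, abs=1e-9)
            if ks is None:
                assert got.ks is None
            else:
                assert got.ks == pytest.approx(ks, abs=1e-9)
            if ka is None:
                assert got.ka is None
            else:
                assert got.ka == pytest.approx(ka, abs=1e-9)


class TestSignificance:
    def test_no_substitutions_p_one(self):
        est = KaKsEstimate(S=20, N_sites=40, Sd=0, Nd=0, ps=0, pn=0, ka=0, ks=0,
                           omega=None, n_columns=20)
        assert kaks_significance(est) == 1.0

    def test_four_zero_table(self):
        est = KaKsEstimate(S=4, N_sites=4, Sd=4, Nd=0, ps=1, pn=0, ka=None, ks=None,
                           omega=None, n_columns=3)
        assert kaks_significance(est) == pytest.approx(2 / 70, abs=1e-6)

    def test_proportional_rates_near_one(self):
        est = KaKsEstimate(S=100, N_sites=200, Sd=10, Nd=20, ps=0.1, pn=0.1,
                           ka=0.1, ks=0.1, omega=1.0, n_columns=100)
        assert kaks_significance(est) > 0.8


class TestOggPairwise:
    def test_identical_members_all_zero(self):
        members = [(f"g{i}", "ATGGCTAAGGATCTTGAGTAA") for i in range(3)]
        pairs, summary = ogg_pairwise_kaks(members, p_filter=None)
        assert (pairs.ka == 0).all() and (pairs.ks == 0).all()
        assert summary["mean_omega"] is None  # omega undefined at zero divergence

    def test_subsample_reproducible(self, rng):
        from panfam.synthetic_data import mutate_cds, _codon_weights, _sample_ancestral_cds

        anc = _sample_ancestral_cds(rng, 60, _codon_weights(rng, 0.0))
        members = [
            (f"g{i}", mutate_cds(anc, 0.1, 0.05, rng)[0]) for i in range(8)
        ]  # 28 pairs
        pairs_a, _ = ogg_pairwise_kaks(members, max_pairs=10, seed=5, p_filter=None)
        pairs_b, _ = ogg_pairwise_kaks(members, max_pairs=10, seed=5, p_filter=None)
        assert pairs_a.equals(pairs_b)
        assert len(pairs_a) == 10

    def test_single_member_rejected(self):
        with pytest.raises(PanfamError):
            ogg_pairwise_kaks([("g", "ATGTAA")])


class TestSelectionCompare:
    def test_identical_groups_p_one(self):
        result = selection_compare({"a": [0.2, 0.2, 0.2], "b": [0.2, 0.2, 0.2]})
        assert result.p.iloc[0] == 1.0

    def test_constructed_effect_recovered(self, rng):
        core = list(rng.normal(0.1, 0.01, size=12))
        disp = list(rng.normal(0.5, 0.05, size=12))
        result = selection_compare({"core": core, "dispensable": disp})
        row = result.iloc[0]
        assert row.mean_b > row.mean_a
        assert row.p <= 0.05

    def test_undefined_cells_skipped(self):
        result = selection_compare({"a": [None, None], "b": [0.1, 0.2, 0.3]})
        assert len(result) == 0


def test_parameter_recovery_omega_one_fifth(rng):
    """OGG-style parameter recovery: nonsyn/syn pressure 0.2 → mean ω ≈ 0.2."""
    from panfam.synthetic_data import mutate_cds, _codon_weights, _sample_ancestral_cds

    weights = _codon_weights(rng, 0.0)
    omegas = []
    for _ in range(60):
        anc = _sample_ancestral_cds(rng, 200, weights)
        a, _, _ = mutate_cds(anc, 0.25, 0.05, rng)
        b, _, _ = mutate_cds(anc, 0.25, 0.05, rng)
        est = estimate_pair(a, b)
        if est.omega is not None:
            omegas.append(est.omega)
    assert np.mean(omegas) == pytest.approx(0.2, abs=0.05)
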