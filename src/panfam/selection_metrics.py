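"""Codon-aware pairwise alignment and Nei–Gojobori (NG86) Ka/Ks estimation.

The workflow mirrors the ParaAT + KaKs_Calculator combination commonly used
for pan-genome selection scans: each CDS pair is translated, the proteins are
globally aligned (BLOSUM62, gap open −10, extend −1), the alignment is
back-translated so gaps fall on codon boundaries, and Ka/Ks is estimated with
the NG86 counting method — per-codon synonymous/nonsynonymous site fractions
averaged over the two sequences, multi-difference codons averaged over all
mutational pathways with stop-crossing pathways excluded, and Jukes–Cantor
correction of the substitution proportions. ω = Ka/Ks < 1 indicates purifying
selection, ω = 1 neutrality, ω > 1 positive selection.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import fisher_exact

from ._codes import CODON_TO_AA, NONSYN_SITES, STOP_CODONS, SYN_SITES
from .codon_metrics import significance_stars, wilcoxon_rank_sum
from .io_formats import PanfamError

logger = logging.getLogger(__name__)

CodonColumn = tuple[str | None, str | None]
CodonAlignment = list[CodonColumn]


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_PROT_ALIGNER = _protein_aligner()


def _codons_and_protein(cds: str, label: str) -> tuple[list[str], str]:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise PanfamError(f"{label}: CDS length {len(cds)} not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    protein = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise PanfamError(f"{label}: internal stop codon at codon {i + 1}")
        protein.append(CODON_TO_AA.get(codon, "X"))  # N-containing codons -> X
    if not protein:
        raise PanfamError(f"{label}: no codons to align")
    return codons, "".join(protein)


def codon_align(cds_a: str, cds_b: str) -> CodonAlignment:
    """Protein-guided pairwise codon alignment of two in-frame CDSs.

    Returns one column per aligned protein position: (codonA, codonB), with
    None marking a whole-codon gap. Dropping the gaps recovers the inputs
    (minus any terminal stop codon).
    """
    codons_a, prot_a = _codons_and_protein(cds_a, "sequence A")
    codons_b, prot_b = _codons_and_protein(cds_b, "sequence B")
    alignment = _PROT_ALIGNER.align(prot_a, prot_b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    columns: CodonAlignment = []
    i = j = 0
    for a, b in zip(row_a, row_b):
        ca = codons_a[i] if a != "-" else None
        cb = codons_b[j] if b != "-" else None
        if a != "-":
            i += 1
        if b != "-":
            j += 1
        columns.append((ca, cb))
    return columns


@dataclass
class KaKsEstimate:
    """NG86 estimate for one aligned CDS pair.

    ``S`` and ``N_sites`` are synonymous/nonsynonymous site counts (summing
    to 3× the compared codon columns), ``Sd``/``Nd`` the pathway-averaged
    substitution counts. Rates are Jukes–Cantor corrected; ``None`` marks
    saturation (p ≥ 3/4) or an empty denominator, and ``omega`` is defined
    only when both rates are and Ks > 0.
    """

    S: float
    N_sites: float
    Sd: float
    Nd: float
    ps: float | None
    pn: float | None
    ka: float | None
    ks: float | None
    omega: float | None
    n_columns: int
    p_value: float | None = None


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average syn/nonsyn substitution counts over all mutational pathways.

    Pathways passing through a stop codon are excluded and the remainder
    re-weighted equally; if every pathway is blocked the pair contributes
    nothing (callers exclude such columns from site counts too).
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    syn_total = nonsyn_total = 0.0
    n_valid = 0
    for order in permutations(diff):
        current = codon_a
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if not blocked:
            syn_total += syn
            nonsyn_total += nonsyn
            n_valid += 1
    if n_valid == 0:
        raise _BlockedColumn()
    return syn_total / n_valid, nonsyn_total / n_valid


class _BlockedColumn(Exception):
    """All mutational pathways for a codon pair cross a stop codon."""


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86(alignment: CodonAlignment) -> KaKsEstimate:
    """NG86 site and substitution counting over the gap-free codon columns.

    Columns with a gap, an N-containing codon, or (degenerate inputs) a stop
    codon on either side are excluded from both site and substitution counts.
    """
    S = N = Sd = Nd = 0.0
    n_cols = 0
    for codon_a, codon_b in alignment:
        if codon_a is None or codon_b is None:
            continue
        if codon_a not in SYN_SITES or codon_b not in SYN_SITES:
            continue  # N-containing or stop codon
        try:
            syn_d, nonsyn_d = _pathway_counts(codon_a, codon_b)
        except _BlockedColumn:
            continue
        S += (SYN_SITES[codon_a] + SYN_SITES[codon_b]) / 2.0
        N += (NONSYN_SITES[codon_a] + NONSYN_SITES[codon_b]) / 2.0
        Sd += syn_d
        Nd += nonsyn_d
        n_cols += 1
    if n_cols == 0:
        raise PanfamError("no comparable codon columns in alignment")
    ps = Sd / S if S > 0 else None
    pn = Nd / N if N > 0 else None
    ks = _jc_correct(ps) if ps is not None else None
    ka = _jc_correct(pn) if pn is not None else None
    omega = ka / ks if (ka is not None and ks is not None and ks > 0) else None
    return KaKsEstimate(
        S=S, N_sites=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, ka=ka, ks=ks, omega=omega, n_columns=n_cols
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def kaks_significance(estimate: KaKsEstimate) -> float:
    """Two-sided Fisher exact test of substitution excess.

    Tests the 2×2 table [[Sd, S−Sd], [Nd, N−Nd]] (entries rounded half away
    from zero, fractional pathway averages being non-integer). A table with a
    zero margin carries no signal and yields p = 1.
    """
    table = [
        [_round_half_away(estimate.Sd), _round_half_away(estimate.S - estimate.Sd)],
        [_round_half_away(estimate.Nd), _round_half_away(estimate.N_sites - estimate.Nd)],
    ]
    _, p = fisher_exact(table, alternative="two-sided")
    return float(p)


def estimate_pair(cds_a: str, cds_b: str) -> KaKsEstimate:
    """Convenience: codon-align a CDS pair and run NG86 plus significance."""
    estimate = ng86(codon_align(cds_a, cds_b))
    estimate.p_value = kaks_significance(estimate)
    return estimate


def ogg_pairwise_kaks(
    members: Sequence[tuple[str, str]],
    max_pairs: int = 200,
    seed: int = 0,
    p_filter: float | None = 0.01,
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """All-pairs Ka/Ks within one orthologous group.

    ``members`` is a list of (gene_id, cds). When the number of unordered
    pairs exceeds ``max_pairs`` a uniform seeded subsample is used. Per-group
    means are taken over defined estimates, after discarding pairs whose
    Fisher exact p-value is ≥ ``p_filter`` (pass ``p_filter=None`` to keep
    every pair); undefined estimates are counted, never imputed.
    """
    if len(members) < 2:
        raise PanfamError("need at least two members for pairwise Ka/Ks")
    pairs = list(combinations(range(len(members)), 2))
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    rows = []
    for i, j in pairs:
        gid_a, cds_a = members[i]
        gid_b, cds_b = members[j]
        est = estimate_pair(cds_a, cds_b)
        rows.append(
            {
                "gene_a": gid_a,
                "gene_b": gid_b,
                "S": est.S,
                "N": est.N_sites,
                "Sd": est.Sd,
                "Nd": est.Nd,
                "ka": est.ka,
                "ks": est.ks,
                "omega": est.omega,
                "p": est.p_value,
            }
        )
    frame = pd.DataFrame(rows)
    numeric = ["S", "N", "Sd", "Nd", "ka", "ks", "omega", "p"]
    frame[numeric] = frame[numeric].astype(float)  # None -> NaN
    kept = frame if p_filter is None else frame[frame["p"] < p_filter]
    summary: dict[str, float | None] = {}
    for col in ("ka", "ks", "omega"):
        values = kept[col].dropna()
        summary[f"mean_{col}"] = float(values.mean()) if len(values) else None
        summary[f"n_{col}"] = int(len(values))
    summary["n_pairs"] = len(frame)
    summary["n_kept"] = len(kept)
    return frame, summary


def selection_compare(
    values: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Pairwise rank-sum comparisons of Ka/Ks-type values between labels.

    ``values`` maps a label (population, pan-category, subfamily …) to its
    defined estimates. Cells with fewer than two observations are skipped
    with a log entry; the shared Wilcoxon implementation and star convention
    of the codon module are reused.
    """
    rows = []
    labels = sorted(values)
    for a, b in combinations(labels, 2):
        va = [v for v in values[a] if v is not None]
        vb = [v for v in values[b] if v is not None]
        if len(va) < 2 or len(vb) < 2:
            logger.info("skipping comparison %s vs %s (cell with <2 defined values)", a, b)
            continue
        p = wilcoxon_rank_sum(va, vb)
        rows.append(
            {
                "label_a": a,
                "label_b": b,
                "n_a": len(va),
                "n_b": len(vb),
                "mean_a": float(np.mean(va)),
                "mean_b": float(np.mean(vb)),
                "p": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["label_a", "label_b", "n_a", "n_b", "mean_a", "mean_b", "p", "stars"],
    )
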