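"""Codon-usage-bias metrics: RSCU, CAI, Wright's ENC and positional GC.

The metrics quantify how far a coding sequence departs from uniform use of
synonymous codons:

* RSCU — observed count of a codon divided by the count expected if all
  synonyms of its amino acid were used equally.
* CAI — geometric mean of relative-adaptiveness weights (codon frequency
  relative to the optimal synonym in a reference gene set, Sharp & Li);
  1.0 means every scorable codon is the reference-optimal one.
* ENC — Wright's effective number of codons, from 20 (one codon per amino
  acid) to 61 (uniform synonymous usage); lower means stronger bias.
* GC1/GC2/GC3 — G+C percentage at each codon position.

A shared Wilcoxon rank-sum test (exact enumeration for small groups, normal
approximation with tie correction otherwise) serves the population and group
comparisons here and in the selection module.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, mannwhitneyu, rankdata

from ._codes import (
    AA_TO_CODONS,
    CAI_EXCLUDED,
    CODON_TO_AA,
    DEGENERACY,
    DEGENERATE_SENSE_CODONS,
    STOP_CODONS,
)
from .io_formats import ParseError, PanfamError

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 12  # both groups at or below this → exact enumeration


@dataclass
class CodonCounts:
    """Sense-codon counts of one CDS (terminal stop and N-codons excluded)."""

    counts: dict[str, int]
    n_codons: int
    n_skipped: int = 0


def count_codons(cds: str) -> CodonCounts:
    """Tally sense codons of an in-frame CDS.

    The terminal stop codon (if present) is excluded; an internal stop is an
    error; codons containing characters outside A/C/G/T are skipped and
    tallied in ``n_skipped``.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ParseError(f"CDS length {len(cds)} is not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    counts: dict[str, int] = {}
    skipped = 0
    for i, codon in enumerate(codons):
        if set(codon) - set("ACGT"):
            skipped += 1
            continue
        if codon in STOP_CODONS:
            raise ParseError(f"internal stop codon {codon} at codon position {i + 1}")
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(counts=counts, n_codons=sum(counts.values()), n_skipped=skipped)


def rscu(counts: CodonCounts) -> dict[str, float | None]:
    """Relative synonymous codon usage over the 59 degenerate sense codons.

    For an amino acid with k synonymous codons used t times in total,
    RSCU(c) = k·count(c)/t; amino acids with t = 0 yield None. Within each
    amino acid with nonzero usage the defined values average to exactly 1.
    """
    out: dict[str, float | None] = {}
    for aa, codons in AA_TO_CODONS.items():
        k = DEGENERACY[aa]
        if k == 1:
            continue
        total = sum(counts.counts.get(c, 0) for c in codons)
        for c in codons:
            out[c] = k * counts.counts.get(c, 0) / total if total > 0 else None
    assert set(out) == set(DEGENERATE_SENSE_CODONS)
    return out


@dataclass
class ReferenceWeights:
    """Relative adaptiveness w(c) per codon, built from a reference gene set.

    For every amino acid present in the reference, the most frequent synonym
    has w = 1; reference codons with zero count are floored at 0.5/max to
    keep CAI finite (the floor is logged). Amino acids entirely absent from
    the reference have no weights; scoring a gene that uses one raises.
    """

    w: dict[str, float]
    absent_aas: frozenset[str] = field(default_factory=frozenset)


def build_reference_weights(reference: Iterable[CodonCounts]) -> ReferenceWeights:
    pooled: dict[str, int] = {}
    for cc in reference:
        for codon, n in cc.counts.items():
            pooled[codon] = pooled.get(codon, 0) + n
    w: dict[str, float] = {}
    absent: set[str] = set()
    for aa, codons in AA_TO_CODONS.items():
        top = max(pooled.get(c, 0) for c in codons)
        if top == 0:
            absent.add(aa)
            continue
        floored = []
        for c in codons:
            n = pooled.get(c, 0)
            if n == 0:
                w[c] = 0.5 / top
                floored.append(c)
            else:
                w[c] = n / top
        if floored:
            logger.debug("reference weights: floored zero-count codons %s", floored)
    return ReferenceWeights(w=w, absent_aas=frozenset(absent))


def cai(gene: CodonCounts, weights: ReferenceWeights) -> float:
    """Codon adaptation index: geometric mean of w over the gene's codons.

    Met, Trp and stop codons are excluded (single-codon amino acids carry no
    usage signal). Raises when the gene has nothing scorable or uses an
    amino acid absent from the reference.
    """
    log_sum = 0.0
    n = 0
    for codon, count in gene.counts.items():
        if codon in CAI_EXCLUDED:
            continue
        aa = CODON_TO_AA[codon]
        if aa in weights.absent_aas:
            raise PanfamError(
                f"amino acid {aa} required for CAI is absent from the reference set"
            )
        log_sum += count * math.log(weights.w[codon])
        n += count
    if n == 0:
        raise PanfamError("gene has no scorable codons for CAI")
    return math.exp(log_sum / n)


# Wright's degeneracy classes: class size k → amino acids, with the term
# multiplicities of the standard code (9 two-fold, 1 three-fold, 5 four-fold,
# 3 six-fold; Met and Trp contribute the constant 2).
_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _k in DEGENERACY.items():
    if _k > 1:
        _CLASSES.setdefault(_k, ())
        _CLASSES[_k] = _CLASSES[_k] + (_aa,)
_CLASS_WEIGHT = {k: len(aas) for k, aas in _CLASSES.items()}  # {2:9, 3:1, 4:5, 6:3}


def enc(counts: CodonCounts) -> float | None:
    """Wright's effective number of codons, or None when undefined.

    Per amino acid with n ≥ 2 countable codons and synonym proportions p̂,
    the codon homozygosity is F̂ = (n·Σp̂² − 1)/(n − 1); F̄ₖ averages F̂ over
    the k-fold class. ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, clipped at 61.
    A missing 3-fold class is substituted by (F̄₂+F̄₄)/2 and a missing 6-fold
    class by F̄₄ (Wright's fallbacks); if the 2- or 4-fold class itself is
    missing, or any class average is non-positive, the statistic is undefined.
    """
    f_bar: dict[int, float] = {}
    for k, aas in _CLASSES.items():
        f_values = []
        for aa in aas:
            ns = [counts.counts.get(c, 0) for c in AA_TO_CODONS[aa]]
            n = sum(ns)
            if n < 2:
                continue
            sum_p2 = sum((x / n) ** 2 for x in ns)
            f_values.append((n * sum_p2 - 1) / (n - 1))
        if f_values:
            f_bar[k] = float(np.mean(f_values))
    if 2 not in f_bar or 4 not in f_bar:
        return None
    if 3 not in f_bar:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2
    if 6 not in f_bar:
        f_bar[6] = f_bar[4]
    if any(f_bar[k] <= 0 for k in (2, 3, 4, 6)):
        return None
    value = 2.0 + sum(_CLASS_WEIGHT[k] / f_bar[k] for k in (2, 3, 4, 6))
    return min(value, 61.0)


def gc_by_position(cds: str) -> tuple[float, float, float, float]:
    """(gc, gc1, gc2, gc3) percentages over counted codons.

    The terminal stop and codons containing non-ACGT characters are excluded,
    mirroring :func:`count_codons`; gc is the mean of the three positions.
    """
    counted = count_codons(cds)  # validates frame and internal stops
    if counted.n_codons == 0:
        raise ParseError("no countable codons for GC computation")
    gc_pos = [0, 0, 0]
    for codon, n in counted.counts.items():
        for pos in range(3):
            if codon[pos] in "GC":
                gc_pos[pos] += n
    pct = [100.0 * g / counted.n_codons for g in gc_pos]
    return (sum(pct) / 3, pct[0], pct[1], pct[2])


def codon_usage_metrics(
    cds: str, weights: ReferenceWeights | None = None
) -> dict[str, float | None]:
    """All per-gene metrics in one pass (CAI only when weights are given)."""
    counts = count_codons(cds)
    gc, gc1, gc2, gc3 = gc_by_position(cds)
    out: dict[str, float | None] = {
        "cai": cai(counts, weights) if weights is not None else None,
        "enc": enc(counts),
        "gc": gc,
        "gc1": gc1,
        "gc2": gc2,
        "gc3": gc3,
    }
    return out


# ---------------------------------------------------------------------------
# Shared Wilcoxon rank-sum test


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value, shared by all group comparisons.

    When both groups have at most 12 observations the null distribution of
    the rank sum (midranks, so ties are handled) is enumerated exhaustively
    and p = min(1, 2·min(P(W ≤ w), P(W ≥ w))). Larger groups use the
    tie-corrected normal approximation (Mann–Whitney U).
    """
    x = list(x)
    y = list(y)
    if not x or not y:
        raise PanfamError("both groups must be nonempty")
    n1, n2 = len(x), len(y)
    if n1 <= EXACT_WILCOXON_MAX_N and n2 <= EXACT_WILCOXON_MAX_N:
        ranks = rankdata(np.asarray(x + y, dtype=float))
        w_obs = float(ranks[:n1].sum())
        total = 0
        le = 0
        ge = 0
        eps = 1e-9
        for comb in combinations(range(n1 + n2), n1):
            w = float(ranks[list(comb)].sum())
            total += 1
            if w <= w_obs + eps:
                le += 1
            if w >= w_obs - eps:
                ge += 1
        return min(1.0, 2.0 * min(le, ge) / total)
    _, p = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(p)


def significance_stars(p: float | None) -> str:
    """Figure-style annotation: '**' at p ≤ 0.01, '*' at p ≤ 0.05."""
    if p is None:
        return ""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare_groups(
    metric: Mapping[str, float],
    grouping: Mapping[str, tuple[str, str]],
) -> pd.DataFrame:
    """Pairwise population comparisons of a per-gene metric within each group.

    ``grouping`` maps gene_id → (group label, population). For every group,
    all population pairs with at least two observations on both sides are
    tested with the shared rank-sum test; raw and Benjamini–Hochberg-adjusted
    p-values are both reported. Under-populated cells are skipped and logged.
    """
    cells: dict[tuple[str, str], list[float]] = {}
    for gene, value in metric.items():
        if gene not in grouping or value is None:
            continue
        group, pop = grouping[gene]
        cells.setdefault((group, pop), []).append(float(value))

    rows = []
    groups = sorted({g for g, _ in cells})
    for group in groups:
        pops = sorted(p for g, p in cells if g == group)
        for pop_a, pop_b in combinations(pops, 2):
            a = cells[(group, pop_a)]
            b = cells[(group, pop_b)]
            if len(a) < 2 or len(b) < 2:
                logger.info(
                    "skipping %s: %s vs %s (cell with <2 observations)", group, pop_a, pop_b
                )
                continue
            p = wilcoxon_rank_sum(a, b)
            rows.append(
                {
                    "group": group,
                    "population_a": pop_a,
                    "population_b": pop_b,
                    "n_a": len(a),
                    "n_b": len(b),
                    "median_a": float(np.median(a)),
                    "median_b": float(np.median(b)),
                    "p_raw": p,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "group",
            "population_a",
            "population_b",
            "n_a",
            "n_b",
            "median_a",
            "median_b",
            "p_raw",
        ],
    )
    if len(frame):
        frame["p_bh"] = false_discovery_control(frame["p_raw"].to_numpy(), method="bh")
        frame["stars"] = [significance_stars(p) for p in frame["p_raw"]]
    else:
        frame["p_bh"] = []
        frame["stars"] = []
    return frame
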