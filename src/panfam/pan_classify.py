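"""Occupancy-based pan-category classification of orthologous gene groups.

With N accessions, a group's occupancy (number of distinct accessions carrying
at least one member) places it in exactly one category:

* ``core``     — occupancy = N
* ``softcore`` — ceil(0.9·N) ≤ occupancy ≤ N−1
* ``shell``    — floor(0.1·N)+1 ≤ occupancy < ceil(0.9·N)
* ``cloud``    — 2 ≤ occupancy ≤ floor(0.1·N)
* ``private``  — occupancy = 1

At N = 111 this reproduces the familiar 111 / 100–110 / 12–99 / 2–11 bands.
``private`` is this package's explicit label for singleton groups, which the
four-band scheme otherwise leaves undefined; roll-ups count it with cloud as
dispensable.
"""
from __future__ import annotations

from collections import Counter
from typing import Mapping

import pandas as pd
from scipy.stats import fisher_exact

from .io_formats import ConfigError

CATEGORIES = ("core", "softcore", "shell", "cloud", "private")
DISPENSABLE = ("shell", "cloud", "private")
CORE_LIKE = ("core", "softcore")

DEG_STATUSES = ("up", "down", "ns")


def _ceil09(n: int) -> int:
    return (9 * n + 9) // 10


def category_bands(n_accessions: int) -> dict[str, tuple[int, int]]:
    """Inclusive occupancy interval per category; empty bands have lo > hi."""
    if n_accessions < 1:
        raise ConfigError("n_accessions must be >= 1")
    n = n_accessions
    bands = {
        "core": (n, n),
        "softcore": (_ceil09(n), n - 1),
        "shell": (max(n // 10 + 1, 2), _ceil09(n) - 1),
        "cloud": (2, n // 10),
        "private": (1, 1) if n > 1 else (1, 0),
    }
    return bands


def classify_occupancy(occupancy: int, n_accessions: int) -> str:
    """Deterministic category label for one occupancy count."""
    n = n_accessions
    if not 1 <= occupancy <= n:
        raise ConfigError(f"occupancy {occupancy} outside [1, {n}]")
    if occupancy == n:
        return "core"
    if occupancy == 1:
        return "private"
    if occupancy >= _ceil09(n):
        return "softcore"
    if occupancy > n // 10:
        return "shell"
    return "cloud"


def categorize(matrix: pd.DataFrame) -> tuple[dict[str, str], Counter]:
    """Classify every OGG row of an occupancy matrix.

    Parameters
    ----------
    matrix : DataFrame
        OGG × accession member counts (the builder's occupancy matrix).

    Returns
    -------
    (categories, summary)
        Mapping ogg_id → category, and a Counter of per-category totals.
    """
    if matrix.empty:
        raise ConfigError("occupancy matrix is empty")
    n = matrix.shape[1]
    occupancy = (matrix > 0).sum(axis=1)
    categories = {ogg: classify_occupancy(int(occ), n) for ogg, occ in occupancy.items()}
    return categories, Counter(categories.values())


def population_breakdown(
    matrix: pd.DataFrame,
    population_map: Mapping[str, str],
    categories: Mapping[str, str],
) -> pd.DataFrame:
    """Per-population gene counts and proportions per pan-category.

    Returns one row per (population, category) with the gene count, the share
    of that population's genes, and the population's core-like share
    (core + softcore genes over all its genes).
    """
    unknown = sorted(set(matrix.columns) - set(population_map))
    if unknown:
        raise ConfigError(f"accessions without a population label: {unknown}")
    rows = []
    populations = sorted(set(population_map[a] for a in matrix.columns))
    cat_series = pd.Series({ogg: categories[ogg] for ogg in matrix.index})
    for pop in populations:
        cols = [a for a in matrix.columns if population_map[a] == pop]
        per_ogg = matrix[cols].sum(axis=1)
        total = int(per_ogg.sum())
        by_cat = {c: int(per_ogg[cat_series == c].sum()) for c in CATEGORIES}
        core_like = sum(by_cat[c] for c in CORE_LIKE)
        for cat in CATEGORIES:
            rows.append(
                {
                    "population": pop,
                    "category": cat,
                    "n_genes": by_cat[cat],
                    "proportion": by_cat[cat] / total if total else None,
                    "core_like_share": core_like / total if total else None,
                }
            )
    return pd.DataFrame(rows)


def deg_crosstab(
    deg_flags: Mapping[str, tuple[str, str]],
    membership: Mapping[str, str],
    categories: Mapping[str, str],
) -> pd.DataFrame:
    """Cross-tabulate differential-expression flags against pan-categories.

    ``deg_flags`` maps gene_id → (leaf_status, root_status) with statuses in
    {"up", "down", "ns"}; genes absent from the table count as not
    differentially expressed. For each tissue and category the fraction of
    upregulated genes is reported together with a two-sided Fisher exact
    p-value of the category-vs-rest × up-vs-not-up 2×2 table.
    """
    genes = list(membership)
    gene_cat = {g: categories[membership[g]] for g in genes}
    rows = []
    for tissue_idx, tissue in enumerate(("leaf", "root")):
        up = {
            g
            for g in genes
            if g in deg_flags and deg_flags[g][tissue_idx] == "up"
        }
        total_up = len(up)
        total = len(genes)
        for cat in CATEGORIES:
            cat_genes = [g for g in genes if gene_cat[g] == cat]
            n_cat = len(cat_genes)
            n_up = sum(1 for g in cat_genes if g in up)
            if n_cat == 0:
                rows.append(
                    {
                        "tissue": tissue,
                        "category": cat,
                        "n_genes": 0,
                        "n_up": 0,
                        "up_percent": None,
                        "fisher_p": None,
                    }
                )
                continue
            table = [
                [n_up, n_cat - n_up],
                [total_up - n_up, (total - n_cat) - (total_up - n_up)],
            ]
            _, p = fisher_exact(table, alternative="two-sided")
            rows.append(
                {
                    "tissue": tissue,
                    "category": cat,
                    "n_genes": n_cat,
                    "n_up": n_up,
                    "up_percent": 100.0 * n_up / n_cat,
                    "fisher_p": float(p),
                }
            )
    return pd.DataFrame(rows)
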