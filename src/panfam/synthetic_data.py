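"""Synthetic pan-gene-family generator with ground truth.

The generator emulates the structure of a transcription-factor pan-family
survey across resequenced accessions: N accessions split into populations
(default 36 cultivars / 40 landraces / 35 wild, N = 111), a configurable
number of orthologous gene groups whose occupancy is drawn inside the band
of a requested pan-category, per-member divergence controlled by separate
synonymous and nonsynonymous substitution rates, and codon-usage bias
controlled by a single Dirichlet concentration knob. Ancestral sequences are
mutually dissimilar by construction (rejection sampling against the
builder's own identity score), so the orthologous groups are recoverable by
the iterative builder and every downstream stage can be checked against the
emitted truth tables.

Substitutions are introduced codon-wise by a continuous-time process whose
synonymous/nonsynonymous channel rates are proportional to the NG86 site
counts of the current codon, so ``syn_rate`` and ``nonsyn_rate`` are
expected substitutions *per site* of each class and equal rates correspond
to neutral evolution (ω = 1) as NG86 measures it.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from ._codes import (
    AA_TO_CODONS,
    NONSYN_NEIGHBORS,
    NONSYN_SITES,
    STOP_CODONS,
    SYN_NEIGHBORS,
    SYN_SITES,
)
from .io_formats import (
    ConfigError,
    DEG_SCHEMA,
    DOMAINS_SCHEMA,
    GeneRecord,
    POPULATIONS_SCHEMA,
    write_fasta,
    write_table,
)
from .ogg_builder import pairwise_score
from .pan_classify import category_bands, classify_occupancy

# Default pan-category mix: the 18/107/51/49 core/softcore/shell/cloud split
# of a 225-group family, expressed as proportions.
DEFAULT_CATEGORY_MIX = {
    "core": 18 / 225,
    "softcore": 107 / 225,
    "shell": 51 / 225,
    "cloud": 49 / 225,
}

# Family architectures emitted in the domain table: (ap2_count, b3_count).
_FAMILY_DOMAINS = {
    "AP2": (2, 0),
    "RAV": (1, 1),
    "ERF-like": (1, 0),
    "unclassified": (0, 1),
}
_FAMILY_PROBS = {"AP2": 0.12, "RAV": 0.04, "ERF-like": 0.79, "unclassified": 0.05}

# Differential-expression enrichment multipliers per pan-category (core-like
# groups are enriched for drought-responsive genes, shell/cloud are not).
_DEG_BASE_UP = 0.30
_DEG_DOWN = 0.05
_DEG_MULTIPLIER = {"core": 1.5, "softcore": 1.25, "shell": 0.7, "cloud": 0.9, "private": 0.9}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs of the generator (defaults mirror the survey design)."""

    n_accessions: int = 111
    population_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"cultivar": 36, "landrace": 40, "wild": 35}
    )
    n_oggs: int = 225
    category_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    ogg_length_range: tuple[int, int] = (100, 300)  # codons, start/stop excluded
    within_ogg_identity: float = 0.97
    between_ogg_max_identity: float = 0.80
    syn_rate: float = 0.03  # expected synonymous substitutions per synonymous site
    nonsyn_rate: float = 0.01
    codon_bias_strength: float = 1.0  # 0 = uniform synonymous usage
    seed: int = 0

    def validate(self) -> None:
        if sum(self.population_sizes.values()) != self.n_accessions:
            raise ConfigError(
                f"population sizes {dict(self.population_sizes)} do not sum to "
                f"n_accessions={self.n_accessions}"
            )
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("category_mix must sum to 1")
        unknown = set(self.category_mix) - {"core", "softcore", "shell", "cloud", "private"}
        if unknown:
            raise ConfigError(f"unknown pan-categories in category_mix: {sorted(unknown)}")
        if not 0.9 < self.within_ogg_identity <= 1.0:
            raise ConfigError("within_ogg_identity must lie in (0.9, 1.0]")
        if not 0 < self.between_ogg_max_identity < 0.9:
            raise ConfigError("between_ogg_max_identity must lie below 0.9")
        if self.syn_rate < 0 or self.nonsyn_rate < 0:
            raise ConfigError("substitution rates must be non-negative")
        if self.codon_bias_strength < 0:
            raise ConfigError("codon_bias_strength must be >= 0")
        lo, hi = self.ogg_length_range
        if not 1 <= lo <= hi:
            raise ConfigError("ogg_length_range must be a nonempty positive interval")
        bands = category_bands(self.n_accessions)
        for category, proportion in self.category_mix.items():
            if proportion <= 0:
                continue
            lo_b, hi_b = bands[category]
            if lo_b > hi_b:
                raise ConfigError(
                    f"category band {category!r} is empty for n_accessions={self.n_accessions}"
                )


@dataclass
class TruthTables:
    """Ground truth emitted alongside the synthetic dataset."""

    membership: dict[str, str]  # gene_id -> ogg_id
    occupancy: dict[str, int]  # ogg_id -> number of carrying accessions
    category: dict[str, str]  # ogg_id -> pan-category
    domain_counts: dict[str, tuple[int, int]]  # gene_id -> (ap2, b3)
    deg_flags: dict[str, tuple[str, str]]  # gene_id -> (leaf, root) in {up,down,ns}


@dataclass
class SimulatedDataset:
    genes: list[GeneRecord]
    population_map: dict[str, str]  # accession -> population
    truth: TruthTables
    config: SimConfig

    @property
    def accessions(self) -> list[str]:
        return sorted(self.population_map)


def _codon_weights(rng: np.random.Generator, strength: float) -> dict[str, np.ndarray]:
    """Per-amino-acid synonymous codon probabilities.

    strength = 0 gives uniform usage; larger values draw the probabilities
    from an increasingly concentrated Dirichlet (alpha = 1/strength), i.e.
    a stronger random preference for a subset of synonyms.
    """
    weights: dict[str, np.ndarray] = {}
    for aa, codons in AA_TO_CODONS.items():
        k = len(codons)
        if strength == 0 or k == 1:
            weights[aa] = np.full(k, 1.0 / k)
        else:
            weights[aa] = rng.dirichlet(np.full(k, 1.0 / strength))
    return weights


def _sample_ancestral_cds(
    rng: np.random.Generator, n_codons: int, weights: Mapping[str, np.ndarray]
) -> str:
    """ATG + n_codons biased sense codons + TAA, free of internal stops."""
    aas = sorted(AA_TO_CODONS)
    body = []
    for _ in range(n_codons):
        aa = aas[rng.integers(len(aas))]
        codons = AA_TO_CODONS[aa]
        body.append(codons[rng.choice(len(codons), p=weights[aa])])
    return "ATG" + "".join(body) + "TAA"


def mutate_cds(
    ancestral: str,
    syn_rate: float,
    nonsyn_rate: float,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Introduce stop-avoiding substitutions codon-wise.

    Each codon evolves for unit time under a Gillespie process whose total
    synonymous channel rate is ``syn_rate × s(codon)`` and nonsynonymous
    channel rate ``nonsyn_rate × n(codon)``, with s/n the NG86 site counts of
    the *current* codon (recomputed after every jump, so multiple hits
    accumulate realistically). Candidate changes creating stop codons are
    never proposed. Returns (sequence, realized syn count, realized nonsyn
    count); a terminal stop codon is preserved untouched.
    """
    if syn_rate < 0 or nonsyn_rate < 0:
        raise ConfigError("substitution rates must be non-negative")
    if len(ancestral) % 3 != 0:
        raise ConfigError(f"CDS length {len(ancestral)} not a multiple of 3")
    codons = [ancestral[i : i + 3] for i in range(0, len(ancestral), 3)]
    tail = ""
    if codons and codons[-1] in STOP_CODONS:
        tail = codons.pop()
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ConfigError(f"internal stop codon at codon {i + 1}")
    if syn_rate == 0 and nonsyn_rate == 0:
        return ancestral, 0, 0

    n_syn = n_nonsyn = 0
    out = []
    for codon in codons:
        t = 0.0
        current = codon
        while True:
            rate_s = syn_rate * SYN_SITES[current]
            rate_n = nonsyn_rate * NONSYN_SITES[current]
            total = rate_s + rate_n
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= 1.0:
                break
            if rng.random() < rate_s / total:
                nbrs = SYN_NEIGHBORS[current]
                current = nbrs[rng.integers(len(nbrs))][2]
                n_syn += 1
            else:
                nbrs = NONSYN_NEIGHBORS[current]
                current = nbrs[rng.integers(len(nbrs))][2]
                n_nonsyn += 1
        out.append(current)
    return "".join(out) + tail, n_syn, n_nonsyn


def sample_occupancy(
    category: str, n_accessions: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean presence vector whose count lies in the category's band."""
    lo, hi = category_bands(n_accessions)[category]
    if lo > hi:
        raise ConfigError(
            f"category band {category!r} is empty for n_accessions={n_accessions}"
        )
    k = int(rng.integers(lo, hi + 1))
    present = np.zeros(n_accessions, dtype=bool)
    present[rng.choice(n_accessions, size=k, replace=False)] = True
    assert classify_occupancy(k, n_accessions) == category
    return present


def _apportion(mix: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n groups over category proportions."""
    items = sorted(mix.items())
    raw = {c: p * n for c, p in items}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(items, key=lambda cp: (counts[cp[0]] - raw[cp[0]], cp[0]))
    for c, _ in by_remainder[:short]:
        counts[c] += 1
    return counts


def simulate_pan_family(
    config: SimConfig, out_dir: str | Path | None = None
) -> SimulatedDataset:
    """Generate a full synthetic dataset (optionally written to ``out_dir``)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    accessions = []
    population_map = {}
    for pop in sorted(config.population_sizes):
        for i in range(config.population_sizes[pop]):
            accession = f"{pop}{i + 1:03d}"
            accessions.append(accession)
            population_map[accession] = pop
    accessions = sorted(accessions)

    category_counts = _apportion(config.category_mix, config.n_oggs)
    ogg_categories = [c for c in sorted(category_counts) for _ in range(category_counts[c])]

    weights = _codon_weights(rng, config.codon_bias_strength)
    lo, hi = config.ogg_length_range

    ancestrals: list[str] = []
    genes: list[GeneRecord] = []
    truth = TruthTables({}, {}, {}, {}, {})

    for ogg_idx, category in enumerate(ogg_categories):
        ogg_id = f"SIM{ogg_idx + 1:05d}"
        for attempt in range(200):
            n_codons = int(rng.integers(lo, hi + 1))
            cds = _sample_ancestral_cds(rng, n_codons, weights)
            max_ident = 0.0
            for other in ancestrals:
                score = pairwise_score(cds, other)
                max_ident = max(max_ident, score.identity / 100.0)
                if max_ident > config.between_ogg_max_identity:
                    break
            if max_ident <= config.between_ogg_max_identity:
                break
        else:
            raise ConfigError(
                f"could not sample an ancestral CDS for {ogg_id} below "
                f"identity {config.between_ogg_max_identity} in 200 attempts"
            )
        ancestrals.append(cds)

        present = sample_occupancy(category, config.n_accessions, rng)
        carriers = [accessions[i] for i in np.flatnonzero(present)]
        truth.occupancy[ogg_id] = len(carriers)
        truth.category[ogg_id] = category

        family = rng.choice(sorted(_FAMILY_PROBS), p=[_FAMILY_PROBS[f] for f in sorted(_FAMILY_PROBS)])
        domains = _FAMILY_DOMAINS[str(family)]

        up_p = min(_DEG_BASE_UP * _DEG_MULTIPLIER[category], 0.95)
        for accession in carriers:
            gene_id = f"{ogg_id}_{accession}"
            mutated, _, _ = mutate_cds(cds, config.syn_rate, config.nonsyn_rate, rng)
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    accession_id=accession,
                    population=population_map[accession],
                    cds=mutated,
                )
            )
            truth.membership[gene_id] = ogg_id
            truth.domain_counts[gene_id] = domains
            statuses = []
            for _tissue in ("leaf", "root"):
                u = rng.random()
                if u < up_p:
                    statuses.append("up")
                elif u < up_p + _DEG_DOWN:
                    statuses.append("down")
                else:
                    statuses.append("ns")
            truth.deg_flags[gene_id] = (statuses[0], statuses[1])

    dataset = SimulatedDataset(
        genes=genes, population_map=population_map, truth=truth, config=config
    )
    if out_dir is not None:
        write_dataset(dataset, out_dir)
    return dataset


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> None:
    """Write the dataset in the pipeline's on-disk layout (all plain text)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "truth").mkdir(exist_ok=True)

    by_accession: dict[str, list[tuple[str, str]]] = {a: [] for a in dataset.accessions}
    for gene in dataset.genes:
        by_accession[gene.accession_id].append((gene.gene_id, gene.cds))
    for accession, records in by_accession.items():
        write_fasta(records, out_dir / f"{accession}.cds.fa")

    write_table(
        [
            {"accession_id": a, "population": dataset.population_map[a]}
            for a in dataset.accessions
        ],
        POPULATIONS_SCHEMA,
        out_dir / "populations.tsv",
    )
    write_table(
        [
            {"gene_id": g, "ap2_count": d[0], "b3_count": d[1]}
            for g, d in sorted(dataset.truth.domain_counts.items())
        ],
        DOMAINS_SCHEMA,
        out_dir / "domains.tsv",
    )
    write_table(
        [
            {"gene_id": g, "leaf_status": f[0], "root_status": f[1]}
            for g, f in sorted(dataset.truth.deg_flags.items())
        ],
        DEG_SCHEMA,
        out_dir / "deg.tsv",
    )
    write_table(
        [
            {"gene_id": g, "ogg_id": o}
            for g, o in sorted(dataset.truth.membership.items())
        ],
        {"gene_id": "str", "ogg_id": "str"},
        out_dir / "truth" / "membership.tsv",
    )
    write_table(
        [
            {"ogg_id": o, "occupancy": n, "category": dataset.truth.category[o]}
            for o, n in sorted(dataset.truth.occupancy.items())
        ],
        {"ogg_id": "str", "occupancy": "int", "category": "str"},
        out_dir / "truth" / "oggs.tsv",
    )


def scaled_default_config(seed: int = 0) -> SimConfig:
    """Desk-scale variant of the default design: 12 accessions, 30 groups.

    Keeps the identity separation of the full design (within ≈ 0.97 pairwise,
    between ≤ 0.80) while remaining tractable for tests and examples.
    """
    return SimConfig(
        n_accessions=12,
        population_sizes={"cultivar": 4, "landrace": 4, "wild": 4},
        n_oggs=30,
        category_mix={"core": 0.4, "softcore": 0.3, "shell": 0.3},
        ogg_length_range=(80, 160),
        seed=seed,
    )
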