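"""Seedable synthetic observation/query generator and brute-force oracle.

The generator emulates a stream of pharmacogenomics observations of the kind
collected in clinical trials: each record pairs a gene symbol and variant
number with a drug and an outcome, plus flags for a suspected gene-outcome
relation and a serious side effect.  Field values are drawn independently and
uniformly from configurable pools, so duplicate gene-variant-drug
combinations arise naturally once the observation count approaches the pool
product — exactly the regime that separates the per-observation and pooled
storage designs.

:func:`oracle_query` is an independent linear-scan reference used as ground
truth for both contract designs.  It never touches contract storage or the
gas meter and shares no query code with the contract modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    WILDCARD,
    AggregateResult,
    CombinationKey,
    Observation,
    Outcome,
    QueryTriple,
    canonical_variant,
)

_OUTCOMES = (Outcome.IMPROVED, Outcome.UNCHANGED, Outcome.DETERIORATED)


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-stream parameters.

    Pool sizes default to 50 genes x 20 variants x 30 drugs; outcomes are
    drawn with the given weights (uniform by default) and the two flags with
    fixed per-observation probabilities.
    """

    n_observations: int
    n_genes: int = 50
    n_variants: int = 20
    n_drugs: int = 30
    outcome_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    p_suspected: float = 0.3
    p_side_effect: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_observations < 0:
            raise ValueError("n_observations must be non-negative")
        if min(self.n_genes, self.n_variants, self.n_drugs) < 1:
            raise ValueError("pool sizes must be at least 1")
        weights = tuple(float(w) for w in self.outcome_weights)
        if len(weights) != 3 or any(w < 0 for w in weights) or sum(weights) == 0:
            raise ValueError("outcome_weights must be 3 non-negative, not all zero")
        object.__setattr__(self, "outcome_weights", weights)
        for name in ("p_suspected", "p_side_effect"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def gene_pool(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n + 1)]


def variant_pool(n: int) -> list[int]:
    return list(range(1, n + 1))


def drug_pool(n: int) -> list[str]:
    return [f"drug-{i:04d}" for i in range(1, n + 1)]


def _draw_flags_outcomes(rng: np.random.Generator, cfg: GeneratorConfig, n: int):
    weights = np.asarray(cfg.outcome_weights, dtype=float)
    outcome_idx = rng.choice(3, size=n, p=weights / weights.sum())
    suspected = rng.random(n) < cfg.p_suspected
    side_effect = rng.random(n) < cfg.p_side_effect
    return outcome_idx, suspected, side_effect


def generate_observations(cfg: GeneratorConfig) -> list[Observation]:
    """Draw exactly ``cfg.n_observations`` records; identical seeds give
    identical lists."""
    rng = np.random.default_rng(cfg.seed)
    genes = gene_pool(cfg.n_genes)
    variants = variant_pool(cfg.n_variants)
    drugs = drug_pool(cfg.n_drugs)
    n = cfg.n_observations
    gi = rng.integers(0, cfg.n_genes, size=n)
    vi = rng.integers(0, cfg.n_variants, size=n)
    di = rng.integers(0, cfg.n_drugs, size=n)
    outcome_idx, suspected, side_effect = _draw_flags_outcomes(rng, cfg, n)
    return [
        Observation(
            gene=genes[gi[k]],
            variant=variants[vi[k]],
            drug=drugs[di[k]],
            outcome=_OUTCOMES[outcome_idx[k]],
            suspected_relation=bool(suspected[k]),
            serious_side_effect=bool(side_effect[k]),
        )
        for k in range(n)
    ]


def sample_combinations(
    cfg: GeneratorConfig, n_combinations: int, seed: int | None = None
) -> list[tuple[str, int, str]]:
    """Draw ``n_combinations`` distinct gene-variant-drug triples from the
    configured pools (without replacement over the pool product)."""
    total = cfg.n_genes * cfg.n_variants * cfg.n_drugs
    if n_combinations > total:
        raise ValueError(f"cannot draw {n_combinations} distinct triples from {total}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    flat = rng.choice(total, size=n_combinations, replace=False)
    genes = gene_pool(cfg.n_genes)
    variants = variant_pool(cfg.n_variants)
    drugs = drug_pool(cfg.n_drugs)
    out = []
    for f in flat:
        f = int(f)
        g, rem = divmod(f, cfg.n_variants * cfg.n_drugs)
        v, d = divmod(rem, cfg.n_drugs)
        out.append((genes[g], variants[v], drugs[d]))
    return out


def generate_observations_from_combinations(
    combinations: Sequence[tuple[str, int, str]],
    n_observations: int,
    cfg: GeneratorConfig | None = None,
    seed: int | None = None,
) -> list[Observation]:
    """Observation stream confined to a fixed combination pool.

    Every combination appears at least once (so the distinct-combination
    count is exactly ``len(combinations)``); remaining draws are uniform over
    the pool.  Used to grow duplicate multiplicity at constant distinct
    combinations.
    """
    if n_observations < len(combinations):
        raise ValueError("need at least one observation per combination")
    cfg = cfg or GeneratorConfig(n_observations=n_observations)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = n_observations
    idx = np.concatenate(
        [
            np.arange(len(combinations)),
            rng.integers(0, len(combinations), size=n - len(combinations)),
        ]
    )
    rng.shuffle(idx)
    outcome_idx, suspected, side_effect = _draw_flags_outcomes(rng, cfg, n)
    out = []
    for k in range(n):
        gene, variant, drug = combinations[int(idx[k])]
        out.append(
            Observation(
                gene=gene,
                variant=variant,
                drug=drug,
                outcome=_OUTCOMES[outcome_idx[k]],
                suspected_relation=bool(suspected[k]),
                serious_side_effect=bool(side_effect[k]),
            )
        )
    return out


def generate_queries(
    cfg: GeneratorConfig, n_queries: int, n_ands: int, seed: int | None = None
) -> list[QueryTriple]:
    """Random *n_ands*-AND query triples: exactly ``n_ands + 1`` non-wildcard
    fields, positions chosen uniformly, values drawn from the generator
    pools (independently of any particular database, so empty results are
    possible)."""
    if n_ands not in (0, 1, 2):
        raise ValueError("n_ands must be 0, 1 or 2")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genes = gene_pool(cfg.n_genes)
    variants = variant_pool(cfg.n_variants)
    drugs = drug_pool(cfg.n_drugs)
    n_fields = n_ands + 1
    queries = []
    for _ in range(n_queries):
        positions = rng.choice(3, size=n_fields, replace=False)
        gene: str = WILDCARD
        variant: int | str = WILDCARD
        drug: str = WILDCARD
        if 0 in positions:
            gene = genes[rng.integers(0, cfg.n_genes)]
        if 1 in positions:
            variant = int(variants[rng.integers(0, cfg.n_variants)])
        if 2 in positions:
            drug = drugs[rng.integers(0, cfg.n_drugs)]
        queries.append(QueryTriple(gene=gene, variant=variant, drug=drug))
    return queries


# --------------------------------------------------------------------------
# Brute-force oracle.

def _obs_matches(obs: Observation, q: QueryTriple) -> bool:
    if q.gene_specified and obs.gene != q.gene.strip():
        return False
    if q.variant_specified and canonical_variant(obs.variant) != q.variant_key:
        return False
    if q.drug_specified and obs.drug != q.drug.strip():
        return False
    return True


def oracle_query(
    observations: Sequence[Observation], q: QueryTriple
) -> list[AggregateResult]:
    """Reference implementation: linear scan, filter on the non-wildcard
    fields, group by combination in first-occurrence order, count, convert
    to percentages.  Independent of the contract modules and of any storage
    or gas machinery."""
    groups: dict[CombinationKey, list[Observation]] = {}
    for obs in observations:
        if _obs_matches(obs, q):
            groups.setdefault(obs.combination_key, []).append(obs)
    results = []
    for combo, members in groups.items():
        n = len(members)
        side = sum(1 for m in members if m.serious_side_effect)
        susp = sum(1 for m in members if m.suspected_relation)
        imp = sum(1 for m in members if m.outcome is Outcome.IMPROVED)
        det = sum(1 for m in members if m.outcome is Outcome.DETERIORATED)
        unch = sum(1 for m in members if m.outcome is Outcome.UNCHANGED)
        results.append(
            AggregateResult(
                combination=combo,
                n_observations=n,
                side_effect_count=side,
                side_effect_pct=100.0 * side / n,
                suspected_count=susp,
                suspected_pct=100.0 * susp / n,
                improved_count=imp,
                improved_pct=100.0 * imp / n,
                deteriorated_count=det,
                deteriorated_pct=100.0 * det / n,
                unchanged_count=unch,
                unchanged_pct=100.0 * unch / n,
            )
        )
    return results
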