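"""Pooled storage design ("fastQuery").

Instead of one struct per observation, a single :class:`Relation` struct is
kept per unique gene-variant-drug combination and its counters are bumped at
insert time.  A fifth mapping translates the injective combination key to the
relation ID (0 meaning absent, since IDs start at 1).  Queries reuse the same
minimum-array intersection front end as the challenge design but emit results
directly from the stored counters — no pass over an external
unique-combinations array and no per-observation pooling — so query cost
depends only on the number of distinct combinations, not on how many
duplicate observations were ever inserted.

Pooling deliberately discards individual records; the ledger's transaction
log is the only raw record.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    AggregateResult,
    CombinationKey,
    Observation,
    Outcome,
    QueryTriple,
    canonical_variant,
    decode_fixed32,
    encode_fixed32,
)
from .ledger import ContractStorage, GasMeter, GasSchedule

_COUNTER = "counter"
_COMBO_TO_ID = "combo_to_id"  # the fifth mapping
_GENE_IDS = "gene_to_ids"
_VARIANT_IDS = "variant_to_ids"
_DRUG_IDS = "drug_to_ids"
_REL_GENE = "rel.gene"
_REL_VARIANT = "rel.variant"
_REL_DRUG = "rel.drug"
_REL_TOTAL = "rel.total"
_REL_IMPROVED = "rel.improved"
_REL_DETERIORATED = "rel.deteriorated"
_REL_UNCHANGED = "rel.unchanged"
_REL_SUSPECTED = "rel.suspected"
_REL_SIDE_EFFECT = "rel.side_effect"

_GLOBAL = ()

_OUTCOME_MAPPING = {
    Outcome.IMPROVED: _REL_IMPROVED,
    Outcome.DETERIORATED: _REL_DETERIORATED,
    Outcome.UNCHANGED: _REL_UNCHANGED,
}


@dataclass(frozen=True)
class Relation:
    """Pooled per-combination record: total and per-category counts.

    The unchanged count is stored explicitly even though it is derivable from
    total − improved − deteriorated; the extra slot buys symmetric output
    code and a cheap internal consistency check.
    """

    combination: CombinationKey
    total_count: int
    improved_count: int
    deteriorated_count: int
    unchanged_count: int
    suspected_count: int
    side_effect_count: int

    def __post_init__(self):
        if (
            self.improved_count + self.deteriorated_count + self.unchanged_count
            != self.total_count
        ):
            raise ValueError("outcome counts do not sum to total_count")
        if self.suspected_count > self.total_count:
            raise ValueError("suspected_count exceeds total_count")
        if self.side_effect_count > self.total_count:
            raise ValueError("side_effect_count exceeds total_count")


class FastQueryContract:
    """fastQuery design: pooled per-combination structs updated at insert."""

    design_name = "fastquery"

    def __init__(
        self,
        storage: ContractStorage | None = None,
        schedule: GasSchedule | None = None,
    ):
        self.storage = storage or ContractStorage(GasMeter(schedule))

    @property
    def meter(self) -> GasMeter:
        return self.storage.meter

    # ------------------------------------------------------------------ insert
    def insert(self, obs: Observation) -> int:
        """Insert one observation; returns the ID of its (possibly new)
        relation.

        A zero-default lookup in the combination-key mapping decides whether
        the relation exists.  If not, the name fields are recorded, the new
        ID is appended to the three field mappings and the counter advances;
        either way the total, matching-outcome and (conditionally) suspected
        and side-effect counters are incremented.
        """
        st = self.storage
        gene32 = encode_fixed32(obs.gene, "gene")
        variant_str = canonical_variant(obs.variant)
        variant32 = encode_fixed32(variant_str, "variant")
        combo_key = obs.combination_key.storage_key()

        rid = st.load(_COMBO_TO_ID, combo_key)
        if rid == 0:
            raw = st.load(_COUNTER, _GLOBAL)
            rid = raw if raw != 0 else 1
            st.store(_COMBO_TO_ID, combo_key, rid)
            st.store(_REL_GENE, rid, gene32)
            st.store(_REL_VARIANT, rid, variant32)
            st.store(_REL_DRUG, rid, obs.drug)
            st.array_append(_GENE_IDS, obs.gene, rid)
            st.array_append(_VARIANT_IDS, variant_str, rid)
            st.array_append(_DRUG_IDS, obs.drug, rid)
            st.store(_COUNTER, _GLOBAL, rid + 1)

        st.store(_REL_TOTAL, rid, st.load(_REL_TOTAL, rid) + 1)
        outcome_mapping = _OUTCOME_MAPPING[obs.outcome]
        st.store(outcome_mapping, rid, st.load(outcome_mapping, rid) + 1)
        if obs.suspected_relation:
            st.store(_REL_SUSPECTED, rid, st.load(_REL_SUSPECTED, rid) + 1)
        if obs.serious_side_effect:
            st.store(_REL_SIDE_EFFECT, rid, st.load(_REL_SIDE_EFFECT, rid) + 1)
        return rid

    # ------------------------------------------------------------------ query
    def _candidate_ids(self, q: QueryTriple) -> list[int]:
        st = self.storage
        if q.is_full_wildcard:
            raw = st.load(_COUNTER, _GLOBAL)
            n = raw - 1 if raw else 0
            return list(range(1, n + 1))
        arrays = []
        if q.gene_specified:
            arrays.append(st.array_read(_GENE_IDS, q.gene.strip()))
        if q.variant_specified:
            arrays.append(st.array_read(_VARIANT_IDS, q.variant_key))
        if q.drug_specified:
            arrays.append(st.array_read(_DRUG_IDS, q.drug.strip()))
        arrays.sort(key=len)
        shortest, rest = arrays[0], [set(a) for a in arrays[1:]]
        return [i for i in shortest if all(i in s for s in rest)]

    def _read_relation(self, rid: int) -> Relation:
        st = self.storage
        return Relation(
            combination=CombinationKey(
                gene=decode_fixed32(st.load(_REL_GENE, rid, zero=b"\x00" * 32)),
                variant=decode_fixed32(st.load(_REL_VARIANT, rid, zero=b"\x00" * 32)),
                drug=st.load(_REL_DRUG, rid, zero=""),
            ),
            total_count=st.load(_REL_TOTAL, rid),
            improved_count=st.load(_REL_IMPROVED, rid),
            deteriorated_count=st.load(_REL_DETERIORATED, rid),
            unchanged_count=st.load(_REL_UNCHANGED, rid),
            suspected_count=st.load(_REL_SUSPECTED, rid),
            side_effect_count=st.load(_REL_SIDE_EFFECT, rid),
        )

    def query(self, q: QueryTriple) -> list[AggregateResult]:
        """Same intersection front end as the challenge design; each matching
        relation's stored counts convert directly to percentages.  Results
        are ordered by ascending relation ID (first-insertion order of
        combinations).  Read-only."""
        results = []
        for rid in sorted(self._candidate_ids(q)):
            rel = self._read_relation(rid)
            results.append(
                AggregateResult.from_counts(
                    combination=rel.combination,
                    n_observations=rel.total_count,
                    side_effect_count=rel.side_effect_count,
                    suspected_count=rel.suspected_count,
                    improved_count=rel.improved_count,
                    deteriorated_count=rel.deteriorated_count,
                    unchanged_count=rel.unchanged_count,
                )
            )
        return results

    # ----------------------------------------------------------- inspection
    def relation_count(self) -> int:
        raw = self.storage.peek(_COUNTER, _GLOBAL)
        return raw - 1 if raw else 0

    def relation(self, rid: int) -> Relation:
        """Unmetered read of one relation (tests/diagnostics)."""
        st = self.storage
        return Relation(
            combination=CombinationKey(
                gene=decode_fixed32(st.peek(_REL_GENE, rid, zero=b"\x00" * 32)),
                variant=decode_fixed32(st.peek(_REL_VARIANT, rid, zero=b"\x00" * 32)),
                drug=st.peek(_REL_DRUG, rid, zero=""),
            ),
            total_count=st.peek(_REL_TOTAL, rid),
            improved_count=st.peek(_REL_IMPROVED, rid),
            deteriorated_count=st.peek(_REL_DETERIORATED, rid),
            unchanged_count=st.peek(_REL_UNCHANGED, rid),
            suspected_count=st.peek(_REL_SUSPECTED, rid),
            side_effect_count=st.peek(_REL_SIDE_EFFECT, rid),
        )
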