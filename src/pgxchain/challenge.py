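"""Per-observation, index-based multi-mapping storage design ("challenge").

Each observation is stored in its own struct under a unique integer ID, and
three inverted-index mappings (gene, variant, drug -> array of IDs) support
wildcard queries by set intersection.  An append-only array of the unique
gene-variant-drug combinations drives result aggregation: query hits are
pooled per combination and reported as counts and percentages.

IDs start at 1; 0 is reserved as the storage zero value so "absent key"
checks are well defined.  Storage grows with the number of observations, so
query cost grows with duplicates — the pooled design in
:mod:`pgxchain.fastquery` exists to remove exactly that cost.
"""

from __future__ import annotations

from typing import Optional

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

# Storage mapping names.
_COUNTER = "counter"
_COMBO_SEEN = "combo_seen"  # auxiliary membership mapping for unique combos
_COMBOS = "unique_combinations"  # global append-only array
_GENE_IDS = "gene_to_ids"
_VARIANT_IDS = "variant_to_ids"
_DRUG_IDS = "drug_to_ids"
_DB_GENE = "db.gene"
_DB_VARIANT = "db.variant"
_DB_DRUG = "db.drug"
_DB_OUTCOME = "db.outcome"
_DB_SUSPECTED = "db.suspected"
_DB_SIDE_EFFECT = "db.side_effect"

_GLOBAL = ()  # key of the single global unique-combinations array


class ChallengeContract:
    """Challenge design: one struct per observation, intersection queries,
    on-the-fly aggregation over the unique-combinations array."""

    design_name = "challenge"

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
        """Insert one observation; returns its assigned ID.

        Storage effects, in order: the unique-combinations array is extended
        iff the combination is new; the new ID is appended to the three
        field mappings; the observation struct lands in the database mapping;
        the global counter advances by one.  Field validation happens before
        any write, so a rejected observation leaves no partial state.
        """
        st = self.storage
        gene32 = encode_fixed32(obs.gene, "gene")
        variant_str = canonical_variant(obs.variant)
        variant32 = encode_fixed32(variant_str, "variant")
        outcome32 = encode_fixed32(obs.outcome.value, "outcome")
        combo_key = obs.combination_key.storage_key()

        if st.load(_COMBO_SEEN, combo_key) == 0:
            st.array_append(_COMBOS, _GLOBAL, combo_key)
            st.store(_COMBO_SEEN, combo_key, 1)

        raw = st.load(_COUNTER, _GLOBAL)
        ident = raw if raw != 0 else 1

        st.array_append(_GENE_IDS, obs.gene, ident)
        st.array_append(_VARIANT_IDS, variant_str, ident)
        st.array_append(_DRUG_IDS, obs.drug, ident)

        st.store(_DB_GENE, ident, gene32)
        st.store(_DB_VARIANT, ident, variant32)
        st.store(_DB_DRUG, ident, obs.drug)
        st.store(_DB_OUTCOME, ident, outcome32)
        st.store(_DB_SUSPECTED, ident, 1 if obs.suspected_relation else 0)
        st.store(_DB_SIDE_EFFECT, ident, 1 if obs.serious_side_effect else 0)

        st.store(_COUNTER, _GLOBAL, ident + 1)
        return ident

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
        # Loop over the minimum-length array, retaining IDs present in every
        # other specified field's array.
        arrays.sort(key=len)
        shortest, rest = arrays[0], [set(a) for a in arrays[1:]]
        return [i for i in shortest if all(i in s for s in rest)]

    def _read_struct(self, ident: int) -> Observation:
        st = self.storage
        return Observation(
            gene=decode_fixed32(st.load(_DB_GENE, ident, zero=b"\x00" * 32)),
            variant=int(decode_fixed32(st.load(_DB_VARIANT, ident, zero=b"\x00" * 32))),
            drug=st.load(_DB_DRUG, ident, zero=""),
            outcome=Outcome(decode_fixed32(st.load(_DB_OUTCOME, ident, zero=b"\x00" * 32))),
            suspected_relation=bool(st.load(_DB_SUSPECTED, ident)),
            serious_side_effect=bool(st.load(_DB_SIDE_EFFECT, ident)),
        )

    def query(self, q: QueryTriple) -> list[AggregateResult]:
        """Wildcard query: intersect the field ID-arrays, fetch the matching
        structs, and pool them per unique combination.

        Read-only: contract state is untouched.  Results follow the
        first-insertion order of combinations; combinations with no matches
        are omitted.  Tokens other than ``"*"`` are literal values, and an
        absent key simply yields an empty ID array.
        """
        ids = self._candidate_ids(q)
        structs = [(i, self._read_struct(i)) for i in ids]

        # Pool hits by combination (memory-only work; gas is already charged
        # for the storage reads above).
        groups: dict[str, list[Observation]] = {}
        for _, obs in structs:
            groups.setdefault(obs.combination_key.storage_key(), []).append(obs)

        results = []
        for combo_key in self.storage.array_read(_COMBOS, _GLOBAL):
            members = groups.get(combo_key)
            if not members:
                continue
            results.append(_aggregate(members[0].combination_key, members))
        return results

    # ----------------------------------------------------------- inspection
    def observation_count(self) -> int:
        raw = self.storage.peek(_COUNTER, _GLOBAL)
        return raw - 1 if raw else 0

    def unique_combination_count(self) -> int:
        return self.storage.peek((_COMBOS, "len"), _GLOBAL)

    def ids_for_gene(self, gene: str) -> list[int]:
        n = self.storage.peek((_GENE_IDS, "len"), gene)
        return [self.storage.peek((_GENE_IDS, "elem"), (gene, i)) for i in range(n)]


def _aggregate(
    combination: CombinationKey, members: list[Observation]
) -> AggregateResult:
    return AggregateResult.from_counts(
        combination=combination,
        n_observations=len(members),
        side_effect_count=sum(m.serious_side_effect for m in members),
        suspected_count=sum(m.suspected_relation for m in members),
        improved_count=sum(m.outcome is Outcome.IMPROVED for m in members),
        deteriorated_count=sum(m.outcome is Outcome.DETERIORATED for m in members),
        unchanged_count=sum(m.outcome is Outcome.UNCHANGED for m in members),
    )
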