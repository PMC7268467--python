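# Methods

## Data model

An **observation** is one empirical gene-variant-drug data point:

| field | type | storage encoding |
|---|---|---|
| gene | text, ≤ 32 UTF-8 bytes | fixed 32-byte slot, zero-padded |
| variant | integer ≥ 0 | canonical decimal string in a 32-byte slot |
| drug | non-empty text, unbounded | string slot |
| outcome | IMPROVED / UNCHANGED / DETERIORATED | fixed 32-byte slot |
| suspected relation | boolean | 0/1 slot |
| serious side effect | boolean | 0/1 slot |

Short fields use fixed 32-byte slots (the `bytes32` idiom of contract
storage); drug names are kept as unbounded strings because many exceed 32
characters. The variant is canonicalized to its plain decimal form, removing
`"52"` vs `"052"` ambiguity. String matching is exact and case-sensitive
after stripping surrounding whitespace — contract-storage keys compare
byte-for-byte, so no ontology normalization (HGNC/RxNorm) is attempted here;
data producers normalize upstream. Outcome tokens are parsed
case-insensitively and canonicalized to upper case.

The **combination key** for a (gene, variant, drug) triple is the
length-prefixed concatenation `len(gene):gene|len(variant):variant|...`.
Length prefixes make the encoding injective for *any* field contents,
including drug names containing the separator characters; a plain separator
join would not be. A property test drives 10⁴ adversarial random triples
through the encoding and checks for collisions.

One deliberate strictness beyond the table above: the gene must be
non-empty. An empty gene would encode to the all-zero 32-byte slot, which is
precisely the storage "zero value" that absent-key reads return, so allowing
it would make "absent" and "present-but-empty" indistinguishable.

## Storage and gas model

Contract state is a flat set of key-value slots grouped into named mappings.
Semantics follow contract-storage conventions:

* a read of an absent slot returns the zero value and still costs one
  `SLOAD`;
* a write costs `SSTORE_NEW` if the slot previously held the zero value,
  `SSTORE_UPDATE` otherwise;
* a dynamic array occupies a length slot plus one slot per element:
  reading an array of length L costs 1+L `SLOAD`s, appending costs one
  `SLOAD` plus two `SSTORE`s;
* each struct field is its own slot.

Default costs are `SLOAD`=200, `SSTORE_NEW`=20,000, `SSTORE_UPDATE`=5,000
gas, following the Ethereum fee schedule; they are configurable
(`GasSchedule`), and every comparative claim in the test suite (linearity,
ordering, duplicate-independence) holds for any positive constants, because
the claims are about operation *counts*. Gas is additive: the meter's total
is exactly the cost table applied to its counters, and per-transaction
deltas sum to the sequence total — there are no hidden charges. Queries are
metered but never recorded as ledger transactions, since reads change no
state.

The slot granularity (field-per-slot, element-per-slot) is the one modelling
choice with teeth: it makes query gas proportional to the lengths of the
index arrays actually read, which is what separates the two designs. Packing
multiple fields per slot, as a real compiler may do, would rescale constants
without changing any asymptotic comparison.

## The two designs

**Per-observation ("challenge").** Four mappings linked by an integer ID:
`database[id] → struct`, and `gene/variant/drug → [ids]`. IDs start at 1,
reserving 0 as the zero value. Insertion appends the fresh ID to the three
index arrays, writes the six struct fields, extends an append-only
unique-combinations array iff the combination is new, and increments a
global counter. Combination novelty is decided by one read of an auxiliary
membership mapping rather than a scan of the array — a scan would make bulk
insertion quadratic, contradicting the observed linear insertion cost.

Querying fetches the ID array for each specified field, loops over the
shortest, and keeps IDs present in every other specified array ("present in
every specified field's array" — equivalently, the match count equals the
number of fields searched). Matching structs are fetched and pooled per
unique combination into counts and percentages. The pooling pass is
implemented as a single group-by over the hits followed by an iteration of
the unique-combinations array (which fixes the output order to
first-insertion order of combinations); storage reads are identical to the
literal combinations×hits double loop, and the oracle-equivalence property
test pins the semantics.

**Pooled ("fastQuery").** One `Relation` struct per distinct combination —
name fields plus total, improved, deteriorated, unchanged, suspected and
side-effect counts — plus the same three index arrays (now holding relation
IDs, each ID exactly once per array) and a fifth mapping from combination
key to relation ID, with 0 meaning absent. Insertion either creates the
relation (first occurrence) or just increments counters. The unchanged count
is stored even though it is derivable from the others; the extra slot per
relation buys symmetric code and a cheap invariant check. Queries run the
same intersection front end and convert each matching relation's counters to
percentages directly; output is ordered by ascending relation ID, which
coincides with the per-observation design's combination order, so the two
designs' result lists are byte-comparable without re-sorting.

The designs differ where it matters: per-observation storage and 2-AND query
cost grow with the number of raw observations (index arrays hold one entry
per observation), while pooled storage and query cost grow only with the
number of distinct combinations — a finite set, unlike the unbounded stream
of raw observations. Growing duplicate multiplicity 10-fold at fixed
combinations leaves pooled query gas bit-identical and multiplies
per-observation query gas roughly by the duplicate factor.

## Ledger

A minimal hash-linked chain sealed by a single deterministic authority —
the one-authority limit of proof-of-authority consensus, which preserves the
storage and query semantics under study while dropping networking, sealer
rotation and fee markets. Each block stores number, timestamp, previous
block hash, a digest of its canonically-serialized transaction list, and its
own header digest. Verification recomputes everything in ascending order
and reports the lowest inconsistent block; any single-field mutation of any
block is therefore detected and localized (property-tested over random
mutations). The digest is Keccak-256 when a provider is importable,
otherwise SHA-256, and the algorithm name is recorded in the genesis block
and the export header; both digests satisfy the tamper-evidence contract.

Timestamps come from an injectable clock whose default is a constant, so
identical transaction sequences yield bit-identical ledgers; inject
`time.time` for wall-clock stamps. Inserts are batched 200 to a block. The
CLI shows a development-network-style gas limit (4,712,388) and price (100)
as configuration; exceeding the limit logs a warning rather than failing,
as there is no fee market to enforce it.

## Synthetic data

The generator emulates a clinical observation stream: gene, variant and
drug drawn independently and uniformly from pools of 50 genes × 20 variants
× 30 drugs by default, outcomes drawn with configurable weights (uniform by
default), and flags drawn per-observation with `p_suspected` = 0.3 and
`p_side_effect` = 0.2 — plausible adverse-event/suspicion rates for drug
response studies, chosen once for realism rather than fitted to anything.
Duplicate combinations arise naturally as the stream grows toward the pool
product. A second entry point fixes the distinct-combination set exactly
(every combination appears at least once) to study duplicate scaling in
isolation. Query generation picks which of the three fields to specify
uniformly at random and draws values from the pools, independently of any
concrete database, so empty results occur and are part of the contract.

What the generator does *not* emulate: real gene/drug name distributions,
correlated gene-drug co-occurrence, outcome effects that depend on the
combination, or adversarial inputs. Passing tests therefore demonstrate
storage/query correctness and cost scaling, not clinical realism of the
aggregates.

## Benchmarks and problem sizes

The benchmark harness reports storage-operation counts and gas — pure
functions of (design, data, query, cost table) that reproduce bit-for-bit
under fixed seeds — instead of milliseconds or megabytes, which are
hardware- and VM-bound. Each cell inserts a fresh seeded database and runs
100 seeded queries of one class; per-cell totals and result-row counts are
exported as a tidy table (TSV via pandas), with an optional matplotlib plot.

Problem sizes used by the test suite and acceptance script: oracle-agreement
checks at 100 and 1,000 observations (100 queries × {0,1,2} ANDs each);
insertion-linearity sweeps to 1,000 (per-observation design) and 10,000
(pooled) observations; the duplicate-scaling comparison at 50 distinct
combinations with 1,000 vs 10,000 observations; an end-to-end CLI run at
10,000 observations; ledger tamper tests on 50-block chains with 100 random
mutations. These sizes exercise every asymptotic regime of interest while
keeping a full run in seconds.

## Numerical and degenerate-input notes

* Percentages are exact rational multiples `100·count/total` evaluated in
  double precision; the three outcome percentages sum to 100 within 1e-9.
  Full precision lives in the data model; JSON display rounds to 2 decimals.
* Zero-match combinations never appear in results (`n_observations ≥ 1`);
  the empty database returns an empty list for every query, including the
  all-wildcard one.
* Query tokens other than `"*"` are literal values — there is no pattern
  syntax — and an absent key reads as an empty ID array, giving an empty
  intersection.
* Tie-breaking/ordering is always first-insertion order of combinations,
  making outputs deterministic and the two designs directly comparable.
* Observation validation happens before any storage write, so a rejected
  record (overlong gene, negative variant, empty drug) leaves no partial
  state; the CLI additionally parses a whole CSV before touching the ledger.

## Known limitations

* No deletion or update of observations (append-only, by design).
* The pooled design keeps no link from a relation back to its raw
  observations; the ledger's transaction log is the only raw record.
* Single-sealer ledger: no consensus, peers, transaction pool, or block gas
  limit enforcement beyond a warning.
* The storage model is flat key-value; Merkle-Patricia state tries, real
  EVM bytecode costs and calldata/memory gas are out of scope, so gas
  figures are comparable within this model rather than equal to any
  particular client's estimates.
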