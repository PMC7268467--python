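# pgxchain

Blockchain-style storage and querying of pharmacogenomics observations,
with gas-cost accounting and no network.

## The problem

Pharmacogenomics observations — "patients with variant *v* of gene *g*
responded to drug *d* this way" — increasingly inform prescribing decisions,
so the databases that hold them need tamper-evident, high-integrity storage
*and* efficient field-combination queries. Smart-contract storage on a
permissioned Ethereum-style chain offers the integrity, but contract storage
charges **gas** for every storage read (`SLOAD`) and write (`SSTORE`), which
makes the data-structure design the whole game.

`pgxchain` implements and instruments two contract-storage designs for this
workload so their correctness and scaling can be studied reproducibly on a
laptop, with all hardware-dependent quantities (milliseconds, megabytes)
replaced by exact storage-operation counts and their gas totals:

* **challenge** — each observation `(gene, variant, drug, outcome,
  suspected-relation, serious-side-effect)` is stored in its own struct under
  a unique integer ID; three inverted-index mappings (`gene → [ids]`,
  `variant → [ids]`, `drug → [ids]`) support wildcard queries by
  intersecting ID arrays, and results are pooled per unique
  gene-variant-drug combination at query time.
* **fastquery** — one pooled struct per unique gene-variant-drug
  combination, holding total/outcome/flag *counts* that are incremented at
  insert time via a fifth mapping (injective combination key → relation ID).
  Queries use the same intersection front end but read the pooled counters
  directly, so query cost depends on the number of *distinct* combinations,
  not on how many duplicate observations exist.

A query specifies any subset of the three fields (`"*"` = wildcard): a
single field is a *0-AND* query, two fields *1-AND*, all three *2-AND*; the
all-wildcard query returns the entire database as per-combination aggregates
(observation count, plus counts and percentages of side effects, suspected
relations, and improved/unchanged/deteriorated outcomes).

Inserts are batched (200 per block) into a minimal hash-linked ledger sealed
by a single deterministic authority; every block commits to the previous
block's hash, so any single-field tampering is detected and localized. The
gas model charges `SLOAD`=200, `SSTORE`=20,000 (fresh slot) / 5,000
(overwrite) by default and is fully configurable.

## Worked example

The single observation used throughout the docs: gene `CYP3A5`, variant 52,
drug pegloticase, outcome UNCHANGED, suspected relation and serious side
effect both true.

```sh
$ cat one.csv
gene,variant,drug,outcome,relation,sideEffect
CYP3A5,52,pegloticase,UNCHANGED,true,true

$ pgxchain --design fastquery --ledger demo.ledger insert one.csv
rows inserted: 1
blocks appended: 1
total gas: 301800

$ pgxchain --design fastquery --ledger demo.ledger query --gene CYP3A5
[
  {
    "gene": "CYP3A5",
    "variant": "52",
    "drug": "pegloticase",
    "n_observations": 1,
    "side_effect_count": 1,
    "side_effect_pct": 100.0,
    "suspected_count": 1,
    "suspected_pct": 100.0,
    "improved_count": 0,
    "improved_pct": 0.0,
    "deteriorated_count": 0,
    "deteriorated_pct": 0.0,
    "unchanged_count": 1,
    "unchanged_pct": 100.0
  }
]

$ pgxchain --ledger demo.ledger verify
valid: 2 blocks, digest sha256
```

The 301,800 gas is exactly the hand-countable 9 `SLOAD` + 15 fresh `SSTORE`
that a first insert performs in the pooled design (the per-observation
design needs 6 + 16 = 321,200); the query output says all of this
combination's single observation was unchanged, with a serious side effect
and a suspected gene-outcome relation. Other subcommands: `pgxchain gen`
(seeded synthetic CSVs), `pgxchain bench` (the scaling sweep as a TSV
table).

Library use mirrors the CLI:

```python
from pgxchain import FastQueryContract, QueryTriple, parse_observation

contract = FastQueryContract()
contract.insert(parse_observation("CYP3A5,52,pegloticase,UNCHANGED,true,true"))
print(contract.query(QueryTriple(gene="CYP3A5")))
print(contract.meter.total_gas)
```

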