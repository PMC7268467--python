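"""Benchmark harness reporting hardware-independent scaling tables.

Wall-clock, RAM and disk figures are inherently tied to one machine and VM;
the quantities recorded here are instead storage-operation counts and their
gas totals, which are pure functions of (design, data, query, cost table)
and reproduce bit-for-bit under fixed seeds while capturing the same
asymptotic behaviour: linear insertion cost, query cost driven by index
array lengths, and the pooled design's independence from duplicate
multiplicity.

Each benchmark cell inserts a fresh synthetic database of the requested size
and runs a fixed number of seeded random queries (100 by default) of one
query class (0/1/2-AND or full wildcard); inserts are batched 200 per ledger
block.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .challenge import ChallengeContract
from .core import Observation, QueryTriple
from .fastquery import FastQueryContract
from .ledger import GasSchedule, GasUsage
from .synth import GeneratorConfig, generate_observations, generate_queries

DESIGNS = ("challenge", "fastquery")
#: Query classes: number of ANDs, or "full" for the all-wildcard query.
QueryClass = Union[int, str]
FULL_WILDCARD = "full"

#: Ledger batch size used throughout (inserts sealed 200 to a block).
DEFAULT_BATCH_SIZE = 200


@dataclass(frozen=True)
class BenchmarkRecord:
    """One benchmark cell: totals over the cell's operations.

    ``gas_total`` always equals the cost table applied to the op counters;
    for query cells the totals cover ``n_ops`` queries (divide for means).
    """

    design: str
    operation: str  # "insert" | "query"
    n_ands: QueryClass | None  # None for insert cells
    db_size: int
    gas_total: int
    sload_count: int
    sstore_new_count: int
    sstore_update_count: int
    result_rows: int
    n_ops: int

    @property
    def mean_gas(self) -> float:
        return self.gas_total / self.n_ops


def new_contract(design: str, schedule: GasSchedule | None = None):
    if design == "challenge":
        return ChallengeContract(schedule=schedule)
    if design == "fastquery":
        return FastQueryContract(schedule=schedule)
    raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")


def insert_all(contract, observations: Iterable[Observation]) -> GasUsage:
    """Insert a stream of observations, returning the gas used."""
    before = contract.meter.snapshot()
    for obs in observations:
        contract.insert(obs)
    return contract.meter.since(before)


def run_queries(contract, queries: Sequence[QueryTriple]) -> tuple[GasUsage, int]:
    """Run queries, returning (gas used, total result rows)."""
    before = contract.meter.snapshot()
    rows = 0
    for q in queries:
        rows += len(contract.query(q))
    return contract.meter.since(before), rows


def _queries_for_class(
    cfg: GeneratorConfig, n_ands: QueryClass, n_queries: int, seed: int
) -> list[QueryTriple]:
    if n_ands == FULL_WILDCARD:
        return [QueryTriple() for _ in range(n_queries)]
    return generate_queries(cfg, n_queries, int(n_ands), seed=seed)


def run_benchmark(
    designs: Sequence[str] = DESIGNS,
    db_sizes: Sequence[int] = (100, 200, 500, 1000),
    n_ands_list: Sequence[QueryClass] = (0, 1, 2, FULL_WILDCARD),
    cfg: GeneratorConfig | None = None,
    n_queries: int = 100,
    schedule: GasSchedule | None = None,
) -> list[BenchmarkRecord]:
    """Sweep design x database size x query class.

    For each size a fresh synthetic database is generated (same data for
    both designs at the same size) and inserted, recording insertion totals;
    then ``n_queries`` seeded queries per class are run, recording query
    totals.  Query lists are identical across designs for a given (size,
    class) cell.  Rerunning with the same configuration reproduces every
    record bit-for-bit.
    """
    if list(db_sizes) != sorted(db_sizes):
        raise ValueError("db_sizes must be sorted ascending")
    base = cfg or GeneratorConfig(n_observations=0)
    records: list[BenchmarkRecord] = []
    seed_root = np.random.SeedSequence(base.seed)
    for si, size in enumerate(db_sizes):
        data_seed, *query_seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in seed_root.spawn(1 + len(n_ands_list))
        ]
        data_cfg = replace(base, n_observations=size, seed=data_seed + si)
        observations = generate_observations(data_cfg)
        for design in designs:
            contract = new_contract(design, schedule)
            usage = insert_all(contract, observations)
            records.append(
                BenchmarkRecord(
                    design=design,
                    operation="insert",
                    n_ands=None,
                    db_size=size,
                    gas_total=usage.total_gas,
                    sload_count=usage.sload_count,
                    sstore_new_count=usage.sstore_new_count,
                    sstore_update_count=usage.sstore_update_count,
                    result_rows=0,
                    n_ops=size,
                )
            )
            for qi, n_ands in enumerate(n_ands_list):
                queries = _queries_for_class(
                    data_cfg, n_ands, n_queries, seed=query_seeds[qi] + si
                )
                usage, rows = run_queries(contract, queries)
                records.append(
                    BenchmarkRecord(
                        design=design,
                        operation="query",
                        n_ands=n_ands,
                        db_size=size,
                        gas_total=usage.total_gas,
                        sload_count=usage.sload_count,
                        sstore_new_count=usage.sstore_new_count,
                        sstore_update_count=usage.sstore_update_count,
                        result_rows=rows,
                        n_ops=len(queries),
                    )
                )
    return records


def records_to_frame(records: Sequence[BenchmarkRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "design": r.design,
                "operation": r.operation,
                "n_ands": "" if r.n_ands is None else str(r.n_ands),
                "db_size": r.db_size,
                "gas_total": r.gas_total,
                "sload_count": r.sload_count,
                "sstore_new_count": r.sstore_new_count,
                "sstore_update_count": r.sstore_update_count,
                "result_rows": r.result_rows,
                "n_ops": r.n_ops,
                "mean_gas": r.mean_gas,
            }
            for r in records
        ]
    )
    return df


def export_table(records: Sequence[BenchmarkRecord], path, sep: str = "\t") -> None:
    records_to_frame(records).to_csv(path, sep=sep, index=False)


def plot_benchmark(records: Sequence[BenchmarkRecord], path) -> None:
    """Optional scaling plot: mean query gas vs database size per design and
    query class, plus insertion totals."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records_to_frame(records)
    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    ins = df[df.operation == "insert"]
    for design, sub in ins.groupby("design"):
        axes[0].plot(sub.db_size, sub.gas_total, marker="o", label=design)
    axes[0].set(xlabel="database size", ylabel="insert gas total", title="Insertion")
    axes[0].legend()
    qry = df[df.operation == "query"]
    for (design, n_ands), sub in qry.groupby(["design", "n_ands"]):
        axes[1].plot(
            sub.db_size, sub.mean_gas, marker="o", label=f"{design} {n_ands}-AND"
        )
    axes[1].set(
        xlabel="database size", ylabel="mean query gas", title="Querying", yscale="log"
    )
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
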