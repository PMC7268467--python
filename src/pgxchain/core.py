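"""Domain model for pharmacogenomics observations.

An :class:`Observation` is one empirical gene-variant-drug data point with a
clinical outcome and two boolean flags (suspected gene-outcome relation,
serious side effect).  Short text fields (gene symbol, variant number,
outcome) are stored in fixed 32-byte slots, mirroring the ``bytes32`` type of
contract storage; drug names are unbounded text because many exceed 32
characters.

Matching throughout the package is exact and case-sensitive after stripping
surrounding whitespace: keys in contract storage compare byte-for-byte, so
data producers are expected to normalise names upstream.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

FIELD_WIDTH = 32
ZERO32 = bytes(FIELD_WIDTH)

#: Wildcard token in queries.
WILDCARD = "*"

#: Exact CSV header for observation files.
CSV_COLUMNS = ("gene", "variant", "drug", "outcome", "relation", "sideEffect")


class FieldOverflowError(ValueError):
    """A short text field does not fit in its fixed 32-byte slot."""

    def __init__(self, field: str, value: str):
        self.field = field
        self.value = value
        super().__init__(
            f"field {field!r} exceeds {FIELD_WIDTH} bytes after encoding: {value!r}"
        )


class ParseError(ValueError):
    """Malformed record in tabular input; carries row number and column."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        where = []
        if row is not None:
            where.append(f"row {row}")
        if column is not None:
            where.append(f"column {column!r}")
        prefix = f"[{', '.join(where)}] " if where else ""
        super().__init__(prefix + message)


class Outcome(str, enum.Enum):
    """Clinical outcome of a gene-variant-drug observation."""

    IMPROVED = "IMPROVED"
    UNCHANGED = "UNCHANGED"
    DETERIORATED = "DETERIORATED"

    @classmethod
    def parse(cls, token: str) -> "Outcome":
        try:
            return cls(token.strip().upper())
        except ValueError:
            raise ValueError(
                f"outcome must be one of {[o.value for o in cls]}, got {token!r}"
            ) from None


def encode_fixed32(value: str, field: str = "value") -> bytes:
    """Encode *value* (UTF-8) into a fixed 32-byte slot, right-padded with
    zero bytes.

    Raises :class:`FieldOverflowError` naming *field* if the encoding exceeds
    32 bytes.  Round-trips losslessly through :func:`decode_fixed32`.
    """
    raw = value.encode("utf-8")
    if len(raw) > FIELD_WIDTH:
        raise FieldOverflowError(field, value)
    return raw.ljust(FIELD_WIDTH, b"\x00")


def decode_fixed32(raw: bytes) -> str:
    """Inverse of :func:`encode_fixed32`: strip zero padding, decode UTF-8."""
    if len(raw) != FIELD_WIDTH:
        raise ValueError(f"expected {FIELD_WIDTH} bytes, got {len(raw)}")
    return raw.rstrip(b"\x00").decode("utf-8")


def canonical_variant(variant: int) -> str:
    """Canonical decimal-string form of a variant number (no leading zeros)."""
    if not isinstance(variant, int) or isinstance(variant, bool):
        raise TypeError(f"variant must be an integer, got {type(variant).__name__}")
    if variant < 0:
        raise ValueError(f"variant must be non-negative, got {variant}")
    text = str(variant)
    if len(text) > FIELD_WIDTH:
        raise FieldOverflowError("variant", text)
    return text


@dataclass(frozen=True)
class CombinationKey:
    """Injective key for one (gene, variant, drug) combination.

    ``variant`` is held in canonical decimal-string form.  The storage key is
    a length-prefixed concatenation of the three fields, so that no choice of
    separator characters inside a drug (or gene) name can make two distinct
    triples collide.
    """

    gene: str
    variant: str
    drug: str

    def storage_key(self) -> str:
        parts = (self.gene, self.variant, self.drug)
        return "|".join(f"{len(p)}:{p}" for p in parts)


def make_combination_key(gene: str, variant: int, drug: str) -> CombinationKey:
    """Build the canonical, injective :class:`CombinationKey` for a triple.

    Deterministic: identical inputs always yield identical (equal) keys.
    Field validation errors (overflow, negative variant, empty drug)
    propagate.
    """
    gene = gene.strip()
    drug = drug.strip()
    if not gene:
        raise ValueError("gene must be non-empty")
    if not drug:
        raise ValueError("drug must be non-empty")
    encode_fixed32(gene, "gene")
    return CombinationKey(gene=gene, variant=canonical_variant(variant), drug=drug)


@dataclass(frozen=True)
class Observation:
    """One empirical gene-variant-drug data point.

    Invariants enforced at construction: gene and outcome fit in 32 bytes,
    variant is a non-negative integer whose decimal form fits in 32 bytes,
    drug is non-empty (no length cap).
    """

    gene: str
    variant: int
    drug: str
    outcome: Outcome
    suspected_relation: bool
    serious_side_effect: bool

    def __post_init__(self):
        object.__setattr__(self, "gene", self.gene.strip())
        object.__setattr__(self, "drug", self.drug.strip())
        if not self.gene:
            raise ValueError("gene must be non-empty")
        encode_fixed32(self.gene, "gene")
        canonical_variant(self.variant)
        if not self.drug:
            raise ValueError("drug must be non-empty")
        if not isinstance(self.outcome, Outcome):
            raise TypeError("outcome must be an Outcome")
        if not isinstance(self.suspected_relation, bool):
            raise TypeError("suspected_relation must be a bool")
        if not isinstance(self.serious_side_effect, bool):
            raise TypeError("serious_side_effect must be a bool")

    @property
    def combination_key(self) -> CombinationKey:
        return CombinationKey(
            gene=self.gene,
            variant=canonical_variant(self.variant),
            drug=self.drug,
        )

    def to_row(self) -> tuple[str, ...]:
        return (
            self.gene,
            str(self.variant),
            self.drug,
            self.outcome.value,
            "true" if self.suspected_relation else "false",
            "true" if self.serious_side_effect else "false",
        )


@dataclass(frozen=True)
class QueryTriple:
    """Gene/variant/drug query pattern; each field is a value or ``"*"``.

    An *n*-AND query specifies n+1 of the three fields; the all-wildcard
    triple is the full-database query.
    """

    gene: str = WILDCARD
    variant: Union[int, str] = WILDCARD
    drug: str = WILDCARD

    def __post_init__(self):
        if isinstance(self.variant, str):
            if self.variant != WILDCARD:
                # Tolerate numeric strings from CLI plumbing.
                object.__setattr__(self, "variant", int(self.variant))
        if self.variant != WILDCARD:
            canonical_variant(self.variant)

    @property
    def gene_specified(self) -> bool:
        return self.gene != WILDCARD

    @property
    def variant_specified(self) -> bool:
        return self.variant != WILDCARD

    @property
    def drug_specified(self) -> bool:
        return self.drug != WILDCARD

    @property
    def n_specified(self) -> int:
        return sum(
            (self.gene_specified, self.variant_specified, self.drug_specified)
        )

    @property
    def is_full_wildcard(self) -> bool:
        return self.n_specified == 0

    @property
    def n_ands(self) -> int | None:
        """Number of ANDs: specified fields minus one; None for all-wildcard."""
        return self.n_specified - 1 if self.n_specified else None

    @property
    def variant_key(self) -> str:
        """Canonical decimal form used as the variant-mapping key."""
        if not self.variant_specified:
            raise ValueError("variant is a wildcard")
        return canonical_variant(self.variant)  # type: ignore[arg-type]


@dataclass(frozen=True)
class AggregateResult:
    """Per-combination query output: observation count plus counts and
    percentages for side effects, suspected relations and the three outcomes.

    Percentages are held at full precision; rendering rounds to two decimals.
    """

    combination: CombinationKey
    n_observations: int
    side_effect_count: int
    side_effect_pct: float
    suspected_count: int
    suspected_pct: float
    improved_count: int
    improved_pct: float
    deteriorated_count: int
    deteriorated_pct: float
    unchanged_count: int
    unchanged_pct: float

    @classmethod
    def from_counts(
        cls,
        combination: CombinationKey,
        n_observations: int,
        side_effect_count: int,
        suspected_count: int,
        improved_count: int,
        deteriorated_count: int,
        unchanged_count: int,
    ) -> "AggregateResult":
        if n_observations < 1:
            raise ValueError("aggregate requires at least one observation")
        if improved_count + deteriorated_count + unchanged_count != n_observations:
            raise ValueError("outcome counts do not sum to n_observations")

        def pct(c: int) -> float:
            return 100.0 * c / n_observations

        return cls(
            combination=combination,
            n_observations=n_observations,
            side_effect_count=side_effect_count,
            side_effect_pct=pct(side_effect_count),
            suspected_count=suspected_count,
            suspected_pct=pct(suspected_count),
            improved_count=improved_count,
            improved_pct=pct(improved_count),
            deteriorated_count=deteriorated_count,
            deteriorated_pct=pct(deteriorated_count),
            unchanged_count=unchanged_count,
            unchanged_pct=pct(unchanged_count),
        )

    def to_json_dict(self, pct_decimals: int | None = 2) -> dict:
        def fmt(x: float) -> float:
            return round(x, pct_decimals) if pct_decimals is not None else x

        return {
            "gene": self.combination.gene,
            "variant": self.combination.variant,
            "drug": self.combination.drug,
            "n_observations": self.n_observations,
            "side_effect_count": self.side_effect_count,
            "side_effect_pct": fmt(self.side_effect_pct),
            "suspected_count": self.suspected_count,
            "suspected_pct": fmt(self.suspected_pct),
            "improved_count": self.improved_count,
            "improved_pct": fmt(self.improved_pct),
            "deteriorated_count": self.deteriorated_count,
            "deteriorated_pct": fmt(self.deteriorated_pct),
            "unchanged_count": self.unchanged_count,
            "unchanged_pct": fmt(self.unchanged_pct),
        }


_TRUE_TOKENS = {"true", "1", "t", "yes"}
_FALSE_TOKENS = {"false", "0", "f", "no"}


def parse_bool(token: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ValueError(f"boolean must be true/false or 1/0, got {token!r}")


def parse_observation(
    row: Union[str, Sequence[str]], row_number: int | None = None
) -> Observation:
    """Parse one delimited record into a typed :class:`Observation`.

    *row* may be a comma-delimited string or an already-split sequence of the
    six declared columns.  The outcome is parsed case-insensitively; booleans
    accept true/false and 1/0.  Malformed records raise :class:`ParseError`
    carrying the row number and the offending column name.
    """
    if isinstance(row, str):
        row = next(csv.reader(io.StringIO(row)))
    if len(row) != len(CSV_COLUMNS):
        raise ParseError(
            f"expected {len(CSV_COLUMNS)} columns, got {len(row)}", row=row_number
        )
    fields = dict(zip(CSV_COLUMNS, (c.strip() for c in row)))

    def fail(column: str, exc: Exception) -> ParseError:
        return ParseError(str(exc), row=row_number, column=column)

    try:
        variant = int(fields["variant"])
    except ValueError as e:
        raise fail("variant", e) from None
    try:
        outcome = Outcome.parse(fields["outcome"])
    except ValueError as e:
        raise fail("outcome", e) from None
    try:
        suspected = parse_bool(fields["relation"])
    except ValueError as e:
        raise fail("relation", e) from None
    try:
        side_effect = parse_bool(fields["sideEffect"])
    except ValueError as e:
        raise fail("sideEffect", e) from None
    try:
        return Observation(
            gene=fields["gene"],
            variant=variant,
            drug=fields["drug"],
            outcome=outcome,
            suspected_relation=suspected,
            serious_side_effect=side_effect,
        )
    except (ValueError, FieldOverflowError) as e:
        column = getattr(e, "field", None)
        if column is None:
            msg = str(e)
            column = next((c for c in ("gene", "variant", "drug") if c in msg), None)
        raise ParseError(str(e), row=row_number, column=column) from None


def read_observations_csv(path_or_file) -> list[Observation]:
    """Read an observation CSV (header exactly ``gene,variant,drug,outcome,
    relation,sideEffect``); returns the typed observations in file order."""
    if hasattr(path_or_file, "read"):
        return _read_csv_stream(path_or_file)
    with open(path_or_file, newline="", encoding="utf-8") as fh:
        return _read_csv_stream(fh)


def _read_csv_stream(fh) -> list[Observation]:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("empty file: missing header") from None
    if tuple(h.strip() for h in header) != CSV_COLUMNS:
        raise ParseError(
            f"bad header: expected {','.join(CSV_COLUMNS)}, got {','.join(header)}",
            row=1,
        )
    observations = []
    for i, row in enumerate(reader, start=2):
        if not row:
            continue
        observations.append(parse_observation(row, row_number=i))
    return observations


def write_observations_csv(path_or_file, observations: Iterable[Observation]) -> None:
    """Write observations in the declared CSV schema (UTF-8, one per row)."""
    if hasattr(path_or_file, "write"):
        _write_csv_stream(path_or_file, observations)
    else:
        with open(path_or_file, "w", newline="", encoding="utf-8") as fh:
            _write_csv_stream(fh, observations)


def _write_csv_stream(fh, observations: Iterable[Observation]) -> None:
    writer = csv.writer(fh, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for obs in observations:
        writer.writerow(obs.to_row())
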