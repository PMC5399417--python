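"""Categorical dataset container with explicit missing-value semantics.

Clinical repository extracts are tables of nominal attributes plus one
nominal target (e.g. ``Risk1Yr``, ``Cardiac death``), often with scattered
missing cells.  This module holds such tables, reads/writes them as CSV or
ARFF, turns raw numeric columns into categories via user-supplied rules, and
computes the prevalence of a target of interest.

Missing cells are represented by the module-level :data:`MISSING` sentinel,
which is distinct from every category.  Numeric columns are carried as raw
floats until :func:`categorize` is applied; the discovery stage refuses raw
numerics, which forces an explicit, documented categorization step.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import arff as scipy_arff

__all__ = [
    "MISSING",
    "DEFAULT_MISSING_TOKENS",
    "Dataset",
    "Record",
    "TargetSpec",
    "CategorizationRule",
    "Prevalence",
    "read_table",
    "write_table",
    "categorize",
    "prevalence",
    "load_rules",
]


class _MissingType:
    """Singleton marker for an absent cell. Never equal to any category."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _MissingType()

#: Cell contents interpreted as missing when reading tables.
DEFAULT_MISSING_TOKENS = frozenset({"?", "N/A", ""})


@dataclass(frozen=True)
class TargetSpec:
    """The target attribute and the (minority) value of interest t."""

    target_name: str
    positive_value: str


@dataclass(frozen=True)
class Record:
    """One sample: attribute -> category (or MISSING), plus optional label."""

    values: Mapping[str, object]
    target_value: object = None

    def __getitem__(self, attribute: str) -> object:
        return self.values[attribute]


class Dataset:
    """An ordered table of n records over m categorical/numeric attributes.

    Parameters
    ----------
    df
        Table with one column per attribute (object dtype for categorical
        columns holding strings or ``MISSING``; float dtype for raw numeric
        columns holding ``nan`` for missing).
    target_name
        Name of the target column, or ``None`` for unlabeled data.
    domains
        Category domain per categorical column.  Where omitted, the domain is
        the ordered set of observed non-missing values (first-appearance
        order).  ARFF headers supply declared domains that may exceed the
        observed values.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        target_name: str | None = None,
        domains: Mapping[str, Sequence[str]] | None = None,
    ):
        if len(set(df.columns)) != len(df.columns):
            raise ValueError("duplicate attribute names in table")
        if target_name is not None and target_name not in df.columns:
            raise ValueError(f"target attribute {target_name!r} not in table")
        self.df = df.reset_index(drop=True)
        self.target_name = target_name
        self.domains: dict[str, tuple[str, ...]] = {}
        domains = dict(domains or {})
        for col in self.df.columns:
            if self.is_numeric(col):
                continue
            observed = _observed_domain(self.df[col])
            declared = tuple(domains.get(col, ()))
            # union, declared order first
            extra = tuple(v for v in observed if v not in declared)
            self.domains[col] = declared + extra

    # -- basic shape -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def attributes(self) -> list[str]:
        """Predictor attribute names (target excluded)."""
        return [c for c in self.df.columns if c != self.target_name]

    @property
    def m(self) -> int:
        return len(self.attributes)

    def is_numeric(self, attribute: str) -> bool:
        return pd.api.types.is_numeric_dtype(self.df[attribute])

    @property
    def numeric_attributes(self) -> list[str]:
        return [c for c in self.attributes if self.is_numeric(c)]

    # -- record access -----------------------------------------------------

    def record(self, i: int) -> Record:
        row = self.df.iloc[i]
        values = {a: _cell(row[a], self.is_numeric(a)) for a in self.attributes}
        tv = None
        if self.target_name is not None:
            tv = _cell(row[self.target_name], False)
        return Record(values=values, target_value=tv)

    def __iter__(self) -> Iterator[Record]:
        return (self.record(i) for i in range(self.n))

    def __len__(self) -> int:
        return self.n

    # -- target helpers ----------------------------------------------------

    def target_values(self, target: TargetSpec) -> np.ndarray:
        col = self.df[target.target_name]
        if any(v is MISSING for v in col):
            raise ValueError("MISSING target cells are not allowed")
        return col.to_numpy(dtype=object)

    def positive_mask(self, target: TargetSpec) -> np.ndarray:
        return np.array(
            [v == target.positive_value for v in self.target_values(target)], dtype=bool
        )

    def subset(self, indices: Iterable[int]) -> "Dataset":
        sub = self.df.iloc[list(indices)].reset_index(drop=True)
        return Dataset(sub, target_name=self.target_name, domains=self.domains)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        if self.target_name != other.target_name or self.domains != other.domains:
            return False
        if list(self.df.columns) != list(other.df.columns) or self.n != other.n:
            return False
        for col in self.df.columns:
            a, b = self.df[col], other.df[col]
            if self.is_numeric(col) != other.is_numeric(col):
                return False
            if self.is_numeric(col):
                if not np.array_equal(
                    a.to_numpy(float), b.to_numpy(float), equal_nan=True
                ):
                    return False
            elif list(a) != list(b):
                return False
        return True

    def __repr__(self) -> str:
        return (
            f"Dataset(n={self.n}, m={self.m}, target={self.target_name!r})"
        )


def _observed_domain(col: pd.Series) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for v in col:
        if v is not MISSING and not (isinstance(v, float) and math.isnan(v)):
            seen.setdefault(v, None)
    return tuple(seen)


def _cell(v, numeric: bool):
    if numeric:
        return MISSING if (isinstance(v, float) and math.isnan(v)) else v
    return v


# ---------------------------------------------------------------------------
# Readers / writers


def read_table(
    path,
    format: str = "csv",
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    target_name: str | None = None,
) -> Dataset:
    """Read a CSV or ARFF table into a :class:`Dataset`.

    Cells matching any of *missing_tokens* become :data:`MISSING`.  Columns
    whose every non-missing cell parses as a number are kept as raw floats
    (``nan`` for missing) and must be categorized before discovery.  ARFF
    nominal domains are taken from the header, not from observed values.
    """
    missing_tokens = set(missing_tokens)
    if format == "csv":
        return _read_csv(path, missing_tokens, target_name)
    if format == "arff":
        return _read_arff(path, missing_tokens, target_name)
    raise ValueError(f"unknown format {format!r} (expected 'csv' or 'arff')")


def _read_csv(path, missing_tokens, target_name) -> Dataset:
    with open(path, newline="") as fh:
        try:
            rows = list(csv.reader(fh))
        except csv.Error as e:  # pragma: no cover - csv is forgiving
            raise ValueError(f"malformed CSV {path}: {e}") from e
    if not rows:
        raise ValueError(f"{path}: empty file, no header row")
    header, body = rows[0], rows[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate attribute names in header")
    if not body:
        raise ValueError(f"{path}: no data rows")
    for lineno, row in enumerate(body, start=2):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
            )
    cols = {name: [row[j] for row in body] for j, name in enumerate(header)}
    return Dataset(
        _build_frame(cols, missing_tokens), target_name=target_name
    )


def _build_frame(cols: dict[str, list[str]], missing_tokens) -> pd.DataFrame:
    out = {}
    for name, raw in cols.items():
        cells = [MISSING if c.strip() in missing_tokens else c for c in raw]
        present = [c for c in cells if c is not MISSING]
        if present and all(_is_number(c) for c in present):
            out[name] = pd.Series(
                [math.nan if c is MISSING else float(c) for c in cells], dtype=float
            )
        else:
            out[name] = pd.Series(cells, dtype=object)
    return pd.DataFrame(out)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _read_arff(path, missing_tokens, target_name) -> Dataset:
    try:
        data, meta = scipy_arff.loadarff(path)
    except Exception as e:
        raise ValueError(f"malformed ARFF {path}: {e}") from e
    if data.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    names = list(meta.names())
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate attribute names")
    cols: dict[str, pd.Series] = {}
    domains: dict[str, tuple[str, ...]] = {}
    for name in names:
        kind, rng = meta[name]
        if kind == "nominal":
            vals = [v.decode() if isinstance(v, bytes) else v for v in data[name]]
            cells = [MISSING if v in missing_tokens else v for v in vals]
            cols[name] = pd.Series(cells, dtype=object)
            domains[name] = tuple(rng)
        else:
            cols[name] = pd.Series(np.asarray(data[name], dtype=float))
    return Dataset(pd.DataFrame(cols), target_name=target_name, domains=domains)


def write_table(
    dataset: Dataset, path, format: str = "csv", missing_token: str = "?",
    relation: str = "patdisc",
) -> None:
    """Write a Dataset as CSV or ARFF; MISSING cells become *missing_token*.

    ``read_table(write_table(d))`` round-trips the dataset (ARFF carries the
    declared domains; CSV domains are re-derived from observed values).
    """
    if format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(list(dataset.df.columns))
            for _, row in dataset.df.iterrows():
                w.writerow(
                    [
                        missing_token
                        if (v is MISSING or (isinstance(v, float) and math.isnan(v)))
                        else v
                        for v in row
                    ]
                )
        return
    if format == "arff":
        with open(path, "w") as fh:
            fh.write(f"@relation {relation}\n")
            for col in dataset.df.columns:
                if dataset.is_numeric(col):
                    fh.write(f"@attribute {_arff_quote(col)} numeric\n")
                else:
                    dom = ",".join(_arff_quote(v) for v in dataset.domains[col])
                    fh.write(f"@attribute {_arff_quote(col)} {{{dom}}}\n")
            fh.write("@data\n")
            for _, row in dataset.df.iterrows():
                out = []
                for col in dataset.df.columns:
                    v = row[col]
                    if v is MISSING or (isinstance(v, float) and math.isnan(v)):
                        out.append("?")
                    elif dataset.is_numeric(col):
                        out.append(repr(float(v)))
                    else:
                        out.append(_arff_quote(str(v)))
                fh.write(",".join(out) + "\n")
        return
    raise ValueError(f"unknown format {format!r}")


def _arff_quote(token: str) -> str:
    if any(c in token for c in " ,{}%'\"\t"):
        return "'" + token.replace("'", r"\'") + "'"
    return token


# ---------------------------------------------------------------------------
# Categorization


@dataclass(frozen=True)
class CategorizationRule:
    """Turn raw numeric column(s) into a categorical column.

    Three kinds are supported:

    ``bins``
        Ordered ``(label, low, high)`` half-open intervals ``[low, high)``
        over one source column; a value outside every bin is an error, which
        forces the rule set to cover the observed range.
    ``sign``
        ``label_pos`` for values > 0, ``label_nonpos`` for values <= 0 (the
        convention used for sign-categorized gene-expression components).
    ``combine``
        Two source columns, each tested against a half-open interval; the
        output is ``label_true`` when the combination (``all`` or ``any``)
        holds, else ``label_false`` — e.g. deriving a COPD yes/no flag from
        two spirometry measurements.

    Missing inputs always map to MISSING.
    """

    kind: str  # bins | sign | combine
    sources: tuple[str, ...]
    output: str
    bins: tuple[tuple[str, float, float], ...] = ()
    label_pos: str = "pos"
    label_nonpos: str = "nonpos"
    conditions: tuple[tuple[float, float], ...] = ()
    label_true: str = "Yes"
    label_false: str = "No"
    mode: str = "all"
    drop_sources: bool = True

    def __post_init__(self):
        if self.kind not in ("bins", "sign", "combine"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind in ("bins", "sign") and len(self.sources) != 1:
            raise ValueError(f"{self.kind} rule needs exactly one source column")
        if self.kind == "combine" and len(self.sources) != 2:
            raise ValueError("combine rule needs exactly two source columns")
        if self.kind == "bins":
            for label, low, high in self.bins:
                if not low < high:
                    raise ValueError(f"bin {label!r}: need low < high")
            for (_, _, h1), (_, l2, _) in zip(self.bins, self.bins[1:]):
                if l2 < h1:
                    raise ValueError("overlapping bins")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CategorizationRule":
        d = dict(d)
        kind = d.pop("kind")
        sources = d.pop("sources", None) or [d.pop("source")]
        output = d.pop("output")
        kw = {}
        if kind == "bins":
            kw["bins"] = tuple(
                (b["label"], _bound(b.get("low"), -math.inf), _bound(b.get("high"), math.inf))
                for b in d.pop("bins")
            )
        elif kind == "sign":
            kw["label_pos"] = d.pop("label_pos", "pos")
            kw["label_nonpos"] = d.pop("label_nonpos", "nonpos")
        elif kind == "combine":
            kw["conditions"] = tuple(
                (_bound(c.get("low"), -math.inf), _bound(c.get("high"), math.inf))
                for c in d.pop("conditions")
            )
            kw["label_true"] = d.pop("label_true", "Yes")
            kw["label_false"] = d.pop("label_false", "No")
            kw["mode"] = d.pop("mode", "all")
        kw["drop_sources"] = d.pop("drop_sources", True)
        if d:
            raise ValueError(f"unknown rule keys: {sorted(d)}")
        return cls(kind=kind, sources=tuple(sources), output=output, **kw)

    def apply_value(self, *values) -> object:
        if any(v is MISSING or (isinstance(v, float) and math.isnan(v)) for v in values):
            return MISSING
        if self.kind == "sign":
            return self.label_pos if values[0] > 0 else self.label_nonpos
        if self.kind == "bins":
            x = values[0]
            for label, low, high in self.bins:
                if low <= x < high:
                    return label
            raise ValueError(
                f"value {x!r} of {self.sources[0]!r} falls outside every bin of "
                f"rule {self.output!r}"
            )
        checks = [
            low <= x < high for x, (low, high) in zip(values, self.conditions)
        ]
        hit = all(checks) if self.mode == "all" else any(checks)
        return self.label_true if hit else self.label_false


def _bound(v, default):
    return default if v is None else float(v)


def load_rules(path) -> list[CategorizationRule]:
    """Load an ordered categorization rule file (YAML or JSON)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, Mapping):
        doc = doc.get("rules", doc)
    return [CategorizationRule.from_dict(d) for d in doc]


def categorize(dataset: Dataset, rules: Sequence[CategorizationRule]) -> Dataset:
    """Apply rules in order, replacing/augmenting columns; MISSING propagates.

    Already-categorical columns not named by any rule pass through untouched.
    A numeric value outside every bin of its rule raises (rules must be
    complete over the observed range).
    """
    df = dataset.df.copy()
    domains = dict(dataset.domains)
    for rule in rules:
        for src in rule.sources:
            if src not in df.columns:
                raise ValueError(f"rule {rule.output!r}: source {src!r} not in table")
        source_cols = [df[s] for s in rule.sources]
        out = [
            rule.apply_value(*vals) for vals in zip(*[list(c) for c in source_cols])
        ]
        if rule.drop_sources:
            keep = [c for c in df.columns if c not in rule.sources or c == rule.output]
            df = df[keep].copy()
        else:
            df = df.copy()
        df[rule.output] = pd.Series(out, dtype=object)
        for s in rule.sources:
            domains.pop(s, None)
        domains.pop(rule.output, None)
    return Dataset(df, target_name=dataset.target_name, domains=domains)


# ---------------------------------------------------------------------------
# Prevalence


@dataclass(frozen=True)
class Prevalence:
    """#(T=t)/n together with the positive/negative count ratio."""

    prevalence: float
    ratio: float | None  # None when the dataset has no negatives
    n_positive: int
    n_negative: int

    @property
    def ratio_defined(self) -> bool:
        return self.ratio is not None


def prevalence(dataset: Dataset, target: TargetSpec) -> Prevalence:
    """Fraction of records with the target of interest, #(T=t)/n."""
    if dataset.n == 0:
        raise ValueError("empty dataset")
    pos = int(dataset.positive_mask(target).sum())
    neg = dataset.n - pos
    return Prevalence(
        prevalence=pos / dataset.n,
        ratio=(pos / neg) if neg else None,
        n_positive=pos,
        n_negative=neg,
    )
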