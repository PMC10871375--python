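"""Power-set count matrices with small-cell suppression and cross-site merge.

The only artifact a site ever shares is an *aggregate matrix*: for an
ordered set S of discrete study variables, the matrix holds one count for
every observed level combination of every subset T ⊆ S — the data cube over
S — including the empty subset, whose single row is the total cohort size.
The representation is sparse: level combinations observed in no unit are
simply absent, so the row count is far below the 2^n worst case.

Privacy is enforced by small-cell suppression: every row whose count falls
below a threshold (default 10 patients) is removed outright — no masking
value is left behind, because "suppressed" and "zero" must be
indistinguishable to the recipient.  Sites suppress before sharing, and the
coordinating merge re-suppresses the summed matrix with the same threshold.
A consequence, documented rather than hidden: a cell suppressed at one site
contributes nothing to the network total, so merged counts can undercount.
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from fedcube.errors import MergeError, ValidationError

logger = logging.getLogger(__name__)

#: assignment: ((variable, level), ...) ordered by the matrix variable order;
#: the empty tuple is the null set (no variable fixed).
Assignment = tuple[tuple[str, str], ...]

N_MAX_DEFAULT = 10  # hard cap on |S|; the cube has 2^n subsets


@dataclass
class MatrixMetadata:
    """Subscription metadata travelling with every matrix."""

    sites: list[str] = field(default_factory=list)
    study_period: tuple[str, str] = ("", "")
    threshold: int | None = None  # suppression threshold applied, if any
    compiled: str = ""
    variable_descriptions: dict[str, str] = field(default_factory=dict)


@dataclass
class AggregateMatrix:
    variables: list[str]
    rows: dict[Assignment, int]
    metadata: MatrixMetadata = field(default_factory=MatrixMetadata)

    def __post_init__(self) -> None:
        order = {v: i for i, v in enumerate(self.variables)}
        canonical: dict[Assignment, int] = {}
        for a, c in self.rows.items():
            if c < 0:
                raise ValidationError(f"negative count for {a}")
            for v, _ in a:
                if v not in order:
                    raise ValidationError(f"assignment uses unknown variable {v!r}")
            key = tuple(sorted(a, key=lambda kv: order[kv[0]]))
            if key in canonical:
                raise ValidationError(f"duplicate assignment {key}")
            canonical[key] = c
        self.rows = canonical

    # -- access ----------------------------------------------------------

    def canonical(self, mapping: dict[str, str]) -> Assignment:
        order = {v: i for i, v in enumerate(self.variables)}
        return tuple(sorted(((v, str(l)) for v, l in mapping.items()),
                            key=lambda kv: order[kv[0]]))

    def count(self, mapping: dict[str, str]) -> int | None:
        """Count for an assignment, or None when the cell is absent."""
        return self.rows.get(self.canonical(mapping))

    @property
    def total(self) -> int | None:
        """The null-set row: total size of the selected cohort."""
        return self.rows.get(())

    def sorted_rows(self) -> list[tuple[Assignment, int]]:
        """Canonical order: subset size, then variable names, then levels."""
        def key(item):
            a, _ = item
            return (len(a), tuple(v for v, _ in a), tuple(l for _, l in a))
        return sorted(self.rows.items(), key=key)

    # -- serialization ---------------------------------------------------

    def write_csv(self, path: str | Path) -> Path:
        """One column per variable (empty cell = variable not in subset) + cnt;
        metadata lands beside it as ``<stem>.meta.yaml``."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(self.variables + ["cnt"])
            for a, c in self.sorted_rows():
                d = dict(a)
                w.writerow([d.get(v, "") for v in self.variables] + [c])
        meta = {
            "sites": self.metadata.sites,
            "study_period": list(self.metadata.study_period),
            "threshold": self.metadata.threshold,
            "compiled": self.metadata.compiled,
            "variable_descriptions": self.metadata.variable_descriptions,
        }
        with path.with_suffix(".meta.yaml").open("w", encoding="utf-8") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "AggregateMatrix":
        path = Path(path)
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if not header or header[-1] != "cnt":
                raise ValidationError(f"{path}: last column must be 'cnt'")
            variables = header[:-1]
            rows: dict[Assignment, int] = {}
            for raw in reader:
                assignment = tuple((v, cell) for v, cell in zip(variables, raw[:-1]) if cell != "")
                rows[assignment] = int(raw[-1])
        meta_path = path.with_suffix(".meta.yaml")
        metadata = MatrixMetadata()
        if meta_path.exists():
            with meta_path.open(encoding="utf-8") as fh:
                m = yaml.safe_load(fh) or {}
            metadata = MatrixMetadata(
                sites=m.get("sites", []),
                study_period=tuple(m.get("study_period", ["", ""])),
                threshold=m.get("threshold"),
                compiled=m.get("compiled", ""),
                variable_descriptions=m.get("variable_descriptions", {}),
            )
        return cls(variables=variables, rows=rows, metadata=metadata)


def cube_counts(
    cohort: pd.DataFrame,
    variables: list[str],
    metadata: MatrixMetadata | None = None,
    n_max: int = N_MAX_DEFAULT,
) -> AggregateMatrix:
    """Count cohort units for every subset of *variables* (the data cube).

    Sparse by construction: unobserved level combinations are omitted.  The
    null-set row always exists and equals the cohort size.  Columns must
    hold finite discrete labels (no floats) — bin continuous values first.
    """
    if len(variables) > n_max:
        raise ValidationError(
            f"{len(variables)} variables exceed the cap of {n_max}; "
            f"the cube would have 2^{len(variables)} subsets")
    for v in variables:
        if v not in cohort.columns:
            raise ValidationError(f"variable {v!r} missing from cohort columns")
        if len(cohort) and pd.api.types.is_float_dtype(cohort[v]):
            raise ValidationError(f"variable {v!r} is continuous; bin it into discrete levels")
    frame = cohort[variables].astype(str) if variables else cohort.iloc[:, :0]
    order = {v: i for i, v in enumerate(variables)}
    rows: dict[Assignment, int] = {(): len(cohort)}
    for r in range(1, len(variables) + 1):
        for subset in itertools.combinations(variables, r):
            grouped = frame.groupby(list(subset), sort=False).size()
            for levels, count in grouped.items():
                if not isinstance(levels, tuple):
                    levels = (levels,)
                assignment = tuple(sorted(zip(subset, levels), key=lambda kv: order[kv[0]]))
                rows[assignment] = int(count)
    return AggregateMatrix(variables=list(variables), rows=rows,
                           metadata=metadata or MatrixMetadata())


def suppress(matrix: AggregateMatrix, threshold: int = 10) -> AggregateMatrix:
    """Remove every row with fewer than *threshold* units — no masking value.

    The threshold applies uniformly, null-set row included: a cohort smaller
    than the threshold yields an empty matrix with a logged refusal.
    """
    if threshold < 1:
        raise ValidationError("suppression threshold must be >= 1")
    kept = {a: c for a, c in matrix.rows.items() if c >= threshold}
    if () not in kept and () in matrix.rows:
        logger.warning(
            "cohort total %d is below the suppression threshold %d; refusing to emit any cell",
            matrix.rows[()], threshold)
        kept = {}
    return AggregateMatrix(variables=list(matrix.variables), rows=kept,
                           metadata=replace(matrix.metadata, threshold=threshold))


def merge(matrices: list[AggregateMatrix]) -> AggregateMatrix:
    """Sum site matrices cellwise over the union of assignments.

    Inputs must agree on variable list, study period, and suppression
    threshold (push-model federation: each site suppressed before sharing).
    The merged result is re-suppressed with the same threshold; a cell a
    site suppressed locally simply contributes zero.
    """
    if not matrices:
        raise MergeError("nothing to merge")
    first = matrices[0]
    for m in matrices[1:]:
        if m.variables != first.variables:
            raise MergeError(
                f"variable lists diverge: {first.variables} vs {m.variables}")
        if m.metadata.study_period != first.metadata.study_period:
            raise MergeError(
                f"study periods diverge: {first.metadata.study_period} vs "
                f"{m.metadata.study_period}")
        if m.metadata.threshold != first.metadata.threshold:
            raise MergeError(
                f"suppression thresholds diverge: {first.metadata.threshold} vs "
                f"{m.metadata.threshold}")
    rows: dict[Assignment, int] = {}
    sites: list[str] = []
    for m in matrices:
        for a, c in m.rows.items():
            rows[a] = rows.get(a, 0) + c
        for s in m.metadata.sites:
            if s not in sites:
                sites.append(s)
    merged = AggregateMatrix(
        variables=list(first.variables), rows=rows,
        metadata=replace(first.metadata, sites=sites))
    if first.metadata.threshold is not None:
        merged = suppress(merged, first.metadata.threshold)
    return merged
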