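"""Data model and tabular/graph I/O.

The analytical inputs are three flat TSV/CSV tables:

* a **feature table** — samples in rows, features (lipids, cytokines,
  inflammation-gene expression) in columns, non-negative measurements with
  missing cells;
* a **sample metadata table** — patient/control group, matched pair id,
  antipsychotic-medication flag;
* a **feature catalog** — the role of each feature (circulating lipid,
  plasma mediator, gene-expression mediator) plus a display name from which
  lipid class annotations are parsed.

Outputs are a flat edge list, a candidate table and a GraphML network.
Readers validate structural invariants aggressively (unique ids, complete
patient/control pairs) so downstream stages can assume a clean cohort.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .lipids import LipidAnnotation, parse_lipid_name

if TYPE_CHECKING:  # avoid an import cycle; records are defined in .network
    from .network import CandidateRecord, EdgeRecord

ROLES = ("lipid", "mediator_plasma", "mediator_gene")
MEDIATOR_ROLES = frozenset({"mediator_plasma", "mediator_gene"})

#: Tokens read as a missing measurement (case-insensitive), besides the
#: empty cell.
MISSING_TOKENS = frozenset({"", "na", "nan"})


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


class PairingError(ValidationError):
    """Patient/control pairing is incomplete or ambiguous."""


class ParseError(ValidationError):
    """A cell failed to parse, with its location in the message."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CatalogEntry:
    feature_id: str
    role: str
    display_name: str
    lipid_annotation: LipidAnnotation | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r} for {self.feature_id!r}")
        if (self.role == "lipid") != (self.lipid_annotation is not None):
            raise ValidationError(
                f"feature {self.feature_id!r}: lipid_annotation present iff role is lipid"
            )


class FeatureCatalog:
    """Immutable mapping feature_id -> role / display name / lipid class."""

    def __init__(self, entries: Iterable[CatalogEntry]):
        self._entries: dict[str, CatalogEntry] = {}
        for e in entries:
            if e.feature_id in self._entries:
                raise ValidationError(f"duplicate feature id {e.feature_id!r} in catalog")
            self._entries[e.feature_id] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __getitem__(self, feature_id: str) -> CatalogEntry:
        try:
            return self._entries[feature_id]
        except KeyError:
            raise ValidationError(f"feature {feature_id!r} not in catalog") from None

    def role(self, feature_id: str) -> str:
        return self[feature_id].role

    def is_mediator(self, feature_id: str) -> bool:
        return self.role(feature_id) in MEDIATOR_ROLES

    def lipid_class(self, feature_id: str) -> str:
        ann = self[feature_id].lipid_annotation
        return ann.lipid_class if ann is not None else ""

    def edge_kind(self, feature_a: str, feature_b: str) -> str:
        """Classify an edge: mediator-mediator, mediator-lipid or lipid-lipid."""
        n_med = sum(self.is_mediator(f) for f in (feature_a, feature_b))
        return ("lipid-lipid", "mediator-lipid", "mediator-mediator")[n_med]


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    group: str  # "patient" | "control"
    pair_id: str
    antipsychotic_flag: bool = False

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValidationError(
                f"sample {self.sample_id!r}: group must be patient/control, got {self.group!r}"
            )


def validate_pairing(metadata: Sequence[SampleMetadata]) -> dict[str, tuple[str, str]]:
    """Check each pair has exactly one patient and one control.

    Returns ``{pair_id: (patient_sample_id, control_sample_id)}`` ordered by
    first appearance; raises :class:`PairingError` listing offending pairs.
    """
    seen_samples: set[str] = set()
    pairs: dict[str, dict[str, list[str]]] = {}
    for m in metadata:
        if m.sample_id in seen_samples:
            raise ValidationError(f"duplicate sample id {m.sample_id!r}")
        seen_samples.add(m.sample_id)
        pairs.setdefault(m.pair_id, {"patient": [], "control": []})[m.group].append(m.sample_id)
    bad = [
        pid for pid, g in pairs.items() if len(g["patient"]) != 1 or len(g["control"]) != 1
    ]
    if bad:
        raise PairingError(
            "pairs without exactly one patient and one control: " + ", ".join(sorted(bad))
        )
    return {pid: (g["patient"][0], g["control"][0]) for pid, g in pairs.items()}


@dataclass
class FeatureTable:
    """Samples x features matrix; missing measurements are NaN.

    Raw measurements are non-negative in principle, but negative cells are
    retained on read and only zeroed in the explicit cleaning step, so that
    reading a file is a faithful, auditable operation.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray  # float array, shape (n_samples, n_features)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        for kind, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dupes = {i for i in ids if ids.count(i) > 1} if len(set(ids)) != len(ids) else set()
            if dupes:
                raise ValidationError(f"duplicate {kind} ids: {sorted(dupes)}")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(float))

    def subset_features(self, keep: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_ids.index(f) for f in keep]
        return FeatureTable(list(self.sample_ids), list(keep), self.values[:, idx])


# ---------------------------------------------------------------------------
# readers


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_feature_table(path: str | Path, dialect: str | None = None) -> FeatureTable:
    """Read a samples x features table from TSV (default) or CSV.

    First column holds sample ids, the header row feature ids. Cells must
    parse as a real number or one of the missing tokens (empty, ``NA``,
    ``NaN``, case-insensitive). A malformed cell raises :class:`ParseError`
    naming its row and column.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows:
        raise ParseError(f"{path}: empty file")
    feature_ids = [c.strip() for c in rows[0][1:]]
    sample_ids: list[str] = []
    data = np.empty((len(rows) - 1, len(feature_ids)))
    for r, row in enumerate(rows[1:]):
        if len(row) != len(feature_ids) + 1:
            raise ParseError(
                f"{path}: row {r + 2} has {len(row)} fields, expected {len(feature_ids) + 1}"
            )
        sample_ids.append(row[0].strip())
        for c, cell in enumerate(row[1:]):
            tok = cell.strip()
            if tok.lower() in MISSING_TOKENS:
                data[r, c] = np.nan
                continue
            try:
                data[r, c] = float(tok)
            except ValueError:
                raise ParseError(
                    f"{path}: malformed numeric cell {cell!r} at sample "
                    f"{row[0].strip()!r}, feature {feature_ids[c]!r}"
                ) from None
    return FeatureTable(sample_ids, feature_ids, data)


_TRUE_TOKENS = {"true", "1", "yes", "t"}
_FALSE_TOKENS = {"false", "0", "no", "f", ""}


def _parse_flag(token: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ParseError(f"cannot parse boolean flag {token!r}")


def read_metadata(path: str | Path, dialect: str | None = None) -> list[SampleMetadata]:
    """Read sample metadata and verify the patient/control pairing invariant."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str, keep_default_na=False)
    required = {"sample_id", "group", "pair_id", "antipsychotic_flag"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: metadata missing columns {sorted(missing)}")
    metadata = [
        SampleMetadata(
            sample_id=row.sample_id.strip(),
            group=row.group.strip().lower(),
            pair_id=row.pair_id.strip(),
            antipsychotic_flag=_parse_flag(row.antipsychotic_flag),
        )
        for row in df.itertuples()
    ]
    validate_pairing(metadata)
    return metadata


def read_catalog(path: str | Path, dialect: str | None = None) -> FeatureCatalog:
    """Read the feature catalog; lipid annotations are parsed from display names."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str, keep_default_na=False)
    required = {"feature_id", "role", "display_name"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: catalog missing columns {sorted(missing)}")
    entries = []
    for row in df.itertuples():
        role = row.role.strip()
        name = row.display_name.strip()
        ann = parse_lipid_name(name) if role == "lipid" else None
        entries.append(CatalogEntry(row.feature_id.strip(), role, name, ann))
    return FeatureCatalog(entries)


# ---------------------------------------------------------------------------
# writers


def write_feature_table(table: FeatureTable, path: str | Path, dialect: str | None = None) -> None:
    """Write a feature table; missing values become empty cells.

    Floats are written with ``repr`` (shortest round-trip form), so
    write-then-read reproduces the table exactly.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=sep, lineterminator="\n")
        w.writerow(["sample_id", *table.feature_ids])
        for sid, row in zip(table.sample_ids, table.values):
            w.writerow([sid] + ["" if np.isnan(v) else repr(float(v)) for v in row])


def write_metadata(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "group", "pair_id", "antipsychotic_flag"])
        for m in metadata:
            w.writerow([m.sample_id, m.group, m.pair_id, str(m.antipsychotic_flag)])


def write_catalog(catalog: FeatureCatalog, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["feature_id", "role", "display_name"])
        for e in catalog:
            w.writerow([e.feature_id, e.role, e.display_name])


def _edge_sort_key(e) -> tuple:
    # |rho| descending, ties broken lexicographically on the id pair
    return (-abs(e.rho), e.feature_a, e.feature_b)


def write_edge_list(
    edges: Sequence["EdgeRecord"],
    path: str | Path,
    catalog: FeatureCatalog | None = None,
) -> None:
    """Write retained edges as a flat TSV (feature_a, feature_b, rho, nrr, kind).

    Rows are sorted by |rho| descending with lexicographic tie-break, so the
    output is deterministic. If a catalog is given, unknown endpoints raise.
    """
    if catalog is not None:
        for e in edges:
            for f in (e.feature_a, e.feature_b):
                if f not in catalog:
                    raise ValidationError(f"edge endpoint {f!r} not in catalog")
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["feature_a", "feature_b", "rho", "nrr", "kind"])
        for e in sorted(edges, key=_edge_sort_key):
            w.writerow([e.feature_a, e.feature_b, repr(float(e.rho)), repr(float(e.nrr)), e.kind])


def write_candidates(candidates: Sequence["CandidateRecord"], path: str | Path) -> None:
    """Write strong-candidate records (mediator, lipid, rho, nrr, group test)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["mediator", "lipid", "rho", "nrr", "group_difference_p", "significant_group_difference"]
        )
        key = lambda c: (-abs(c.rho), c.mediator, c.lipid)
        for c in sorted(candidates, key=key):
            w.writerow(
                [
                    c.mediator,
                    c.lipid,
                    repr(float(c.rho)),
                    repr(float(c.nrr)),
                    "" if c.group_difference_p is None else repr(float(c.group_difference_p)),
                    "" if c.significant_group_difference is None else str(c.significant_group_difference),
                ]
            )


def read_edge_list(path: str | Path) -> list["EdgeRecord"]:
    """Read back a flat edge-list TSV written by :func:`write_edge_list`."""
    from .network import EdgeRecord  # local import to avoid a cycle

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"feature_a": str, "feature_b": str, "kind": str})
    return [
        EdgeRecord(r.feature_a, r.feature_b, float(r.rho), float(r.nrr), r.kind)
        for r in df.itertuples()
    ]


def read_matrix_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a square feature x feature matrix TSV (ids in header and first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: matrix row and column ids differ")
    return list(map(str, df.columns)), df.to_numpy(float)


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """Serialize the association network (node roles/classes, signed weighted edges)."""
    nx.write_graphml(graph, str(path), encoding="utf-8", prettyprint=True)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
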