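"""Readers and writers for every on-disk artifact of the pipeline.

All tabular artifacts are tab-separated UTF-8 text with a header row — one
dialect, no CSV fallback.  Sample columns of the expression matrix are named
``<group>_r<k>`` with a 1-based replicate index, so the experimental design is
self-describing from the header alone.  Loading is strict: a malformed file is
a hard error, never a silently dropped row.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "ThreeWayDesign",
    "StudyDesign",
    "CandidateSet",
    "load_expression",
    "write_expression",
    "load_design",
    "load_annotations",
    "write_annotations",
    "write_candidate_table",
    "load_candidate_table",
    "DEFAULT_GROUPS",
]

#: The nine sample groups of the default design: four named varieties and the
#: five extreme-phenotype seedling pools.
DEFAULT_GROUPS: dict[str, str] = {
    "Chiquitita": "variety",
    "Picual": "variety",
    "Arbequina": "variety",
    "Arbosana": "variety",
    "SILe": "pool",
    "LILe": "pool",
    "SmaD": "pool",
    "LarD": "pool",
    "ChiCa": "pool",
}


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized linear-scale expression values, genes x (group, replicate).

    ``values`` is an (n_genes, n_columns) float array; ``columns`` holds the
    ordered (group, replicate_index) pairs exactly as read from disk.
    """

    gene_ids: tuple[str, ...]
    columns: tuple[tuple[str, int], ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) == 0:
            raise ValueError("expression matrix has no genes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            for g in self.gene_ids:
                if g in seen:
                    raise ValueError(f"duplicate gene id: {g!r}")
                seen.add(g)
        if self.values.shape != (len(self.gene_ids), len(self.columns)):
            raise ValueError(
                f"value block shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.columns)} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing/non-finite values")
        if np.any(self.values < 0):
            raise ValueError("expression matrix contains negative values")
        for group, n in self.replicate_counts().items():
            if n < 2:
                raise ValueError(f"group {group!r} has {n} replicate column(s); >=2 required")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def groups(self) -> tuple[str, ...]:
        out: list[str] = []
        for g, _ in self.columns:
            if g not in out:
                out.append(g)
        return tuple(out)

    def replicate_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g, _ in self.columns:
            counts[g] = counts.get(g, 0) + 1
        return counts

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of one group, in file order."""
        idx = [i for i, (g, _) in enumerate(self.columns) if g == group]
        if not idx:
            raise KeyError(f"group {group!r} not in matrix (has {self.groups})")
        return np.asarray(idx)

    def group_values(self, group: str) -> np.ndarray:
        """(n_genes, n_replicates) linear values for one group."""
        return self.values[:, self.group_columns(group)]

    def gene_index(self) -> Mapping[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{g}_r{k}" for g, k in self.columns]
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=cols)


@dataclass(frozen=True)
class ThreeWayDesign:
    """One trait's selection rule: a primary contrast between opposite-phenotype
    samples plus a concordance contrast against the reference variety."""

    trait: str
    primary: tuple[str, str]
    concordance: tuple[str, str]


@dataclass(frozen=True)
class StudyDesign:
    groups: dict[str, str]  # name -> role ("variety" | "pool")
    three_way: tuple[ThreeWayDesign, ...] = ()
    alpha: float = 0.05
    fc_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not self.fc_threshold > 1.0:
            raise ValueError(f"fc_threshold must be > 1, got {self.fc_threshold}")
        for role in self.groups.values():
            if role not in ("variety", "pool"):
                raise ValueError(f"unknown group role {role!r}")
        for d in self.three_way:
            for name in (*d.primary, *d.concordance):
                if name not in self.groups:
                    raise ValueError(
                        f"three-way design {d.trait!r} names unknown group {name!r}"
                    )


@dataclass
class CandidateSet:
    """A trait-labelled candidate-gene set from a three-way comparison.

    ``direction`` is 'over' or 'under' relative to the first group of the
    primary contrast; ``fold_change``/``p_value`` carry the primary-contrast
    statistics for reporting.
    """

    trait: str
    gene_ids: tuple[str, ...]
    direction: dict[str, str]
    fold_change: dict[str, float] = field(default_factory=dict)
    p_value: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [g for g in self.gene_ids if g not in self.direction]
        if missing:
            raise ValueError(f"no direction for members: {missing[:5]}")
        bad = {d for d in self.direction.values()} - {"over", "under"}
        if bad:
            raise ValueError(f"invalid directions: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.gene_ids)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def _parse_sample_column(name: str) -> tuple[str, int]:
    group, sep, rep = name.rpartition("_r")
    if not sep or not group:
        raise ValueError(
            f"sample column {name!r} does not follow '<group>_r<k>' naming"
        )
    try:
        k = int(rep)
    except ValueError:
        raise ValueError(
            f"sample column {name!r}: replicate index {rep!r} is not an integer"
        ) from None
    if k < 1:
        raise ValueError(f"sample column {name!r}: replicate index must be 1-based")
    return group, k


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Load a normalized expression matrix from TSV.

    The header must start with ``gene_id`` followed by ``<group>_r<k>`` sample
    columns.  Duplicate gene ids, non-numeric/negative/missing cells and groups
    with fewer than two replicates are hard errors naming the offending cell.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty file, missing header")
        header = header_line.rstrip("\n").split("\t")
        if header[0] != "gene_id":
            raise ValueError(f"{path}: first header field must be 'gene_id', got {header[0]!r}")
        columns = tuple(_parse_sample_column(c) for c in header[1:])
        if not columns:
            raise ValueError(f"{path}: no sample columns")

        gene_ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            gid = fields[0]
            if gid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            vals: list[float] = []
            for j, cell in enumerate(fields[1:], start=1):
                try:
                    v = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in column {header[j]!r}"
                    ) from None
                if not np.isfinite(v):
                    raise ValueError(
                        f"{path}:{lineno}: missing/non-finite value in column {header[j]!r}"
                    )
                if v < 0:
                    raise ValueError(
                        f"{path}:{lineno}: negative value {v} in column {header[j]!r}"
                    )
                vals.append(v)
            gene_ids.append(gid)
            rows.append(vals)

    return ExpressionMatrix(
        gene_ids=tuple(gene_ids),
        columns=columns,
        values=np.asarray(rows, dtype=float),
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path, float_format: str = "%.6g") -> None:
    """Write an expression matrix as TSV (inverse of :func:`load_expression`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        header = ["gene_id"] + [f"{g}_r{k}" for g, k in matrix.columns]
        fh.write("\t".join(header) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(float_format % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

def load_design(path: str | Path) -> StudyDesign:
    """Load a study design from a YAML config.

    Schema::

        groups:                # name -> role, or list of names (role "pool")
          Chiquitita: variety
          SILe: pool
        three_way:
          - trait: internode_length
            primary: [SILe, LILe]
            concordance: [Chiquitita, SILe]
        alpha: 0.05            # optional, default 0.05
        fc_threshold: 2        # optional, default 2
    """
    with Path(path).open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: design config must be a mapping")
    return design_from_dict(raw)


def design_from_dict(raw: dict) -> StudyDesign:
    groups_raw = raw.get("groups")
    if groups_raw is None:
        raise ValueError("design config missing 'groups'")
    if isinstance(groups_raw, dict):
        groups = {str(k): str(v) for k, v in groups_raw.items()}
    else:
        groups = {str(name): "pool" for name in groups_raw}

    three_way: list[ThreeWayDesign] = []
    for entry in raw.get("three_way", []) or []:
        d = ThreeWayDesign(
            trait=str(entry["trait"]),
            primary=(str(entry["primary"][0]), str(entry["primary"][1])),
            concordance=(str(entry["concordance"][0]), str(entry["concordance"][1])),
        )
        three_way.append(d)

    return StudyDesign(
        groups=groups,
        three_way=tuple(three_way),
        alpha=float(raw.get("alpha", 0.05)),
        fc_threshold=float(raw.get("fc_threshold", 2.0)),
    )


def default_design() -> StudyDesign:
    """The study's design: 9 groups and its three trait-wise three-way rules.

    Internode length and trunk diameter contrast the opposite-phenotype pools
    and require concordance between Chiquitita and its like pool; growth habit
    contrasts Chiquitita against Arbosana with concordance against the
    Chiquitita-like-canopy pool.
    """
    return StudyDesign(
        groups=dict(DEFAULT_GROUPS),
        three_way=(
            ThreeWayDesign("internode_length", ("SILe", "LILe"), ("Chiquitita", "SILe")),
            ThreeWayDesign("trunk_diameter", ("SmaD", "LarD"), ("Chiquitita", "SmaD")),
            ThreeWayDesign("growth_habit", ("Chiquitita", "Arbosana"), ("Chiquitita", "ChiCa")),
        ),
    )


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------

def load_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Load a two-column gene->GO TSV into a map of term sets.

    Column 2 holds comma-separated term ids; repeated genes union their terms;
    duplicate (gene, term) pairs collapse.  Malformed lines error with their
    line number.
    """
    out: dict[str, set[str]] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            gid, terms_raw = fields
            terms = {t.strip() for t in terms_raw.split(",") if t.strip()}
            if not terms:
                raise ValueError(f"{path}:{lineno}: no terms for gene {gid!r}")
            out.setdefault(gid, set()).update(terms)
    return {g: frozenset(ts) for g, ts in out.items()}


def write_annotations(annotations: Mapping[str, frozenset[str] | set[str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for gid in sorted(annotations):
            fh.write(f"{gid}\t{','.join(sorted(annotations[gid]))}\n")


# ---------------------------------------------------------------------------
# candidate tables
# ---------------------------------------------------------------------------

_CANDIDATE_HEADER = ["gene_id", "trait", "direction", "fold_change", "p_value"]


def write_candidate_table(sets: Sequence[CandidateSet], path: str | Path) -> None:
    """Write candidate sets as one TSV, rows sorted by (trait, gene_id)."""
    rows = []
    for cs in sets:
        for gid in cs.gene_ids:
            rows.append(
                (
                    gid,
                    cs.trait,
                    cs.direction[gid],
                    cs.fold_change.get(gid, float("nan")),
                    cs.p_value.get(gid, float("nan")),
                )
            )
    rows.sort(key=lambda r: (r[1], r[0]))
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_CANDIDATE_HEADER) + "\n")
        for gid, trait, direction, fc, p in rows:
            fh.write(f"{gid}\t{trait}\t{direction}\t{fc:.6g}\t{p:.6g}\n")


def load_candidate_table(path: str | Path) -> list[CandidateSet]:
    """Reload a candidate TSV into per-trait CandidateSets (trait-sorted)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "trait": str, "direction": str})
    if list(df.columns) != _CANDIDATE_HEADER:
        raise ValueError(f"{path}: unexpected candidate-table header {list(df.columns)}")
    out: list[CandidateSet] = []
    for trait, sub in df.groupby("trait", sort=True):
        out.append(
            CandidateSet(
                trait=str(trait),
                gene_ids=tuple(sub["gene_id"]),
                direction=dict(zip(sub["gene_id"], sub["direction"])),
                fold_change=dict(zip(sub["gene_id"], sub["fold_change"])),
                p_value=dict(zip(sub["gene_id"], sub["p_value"])),
            )
        )
    return out
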