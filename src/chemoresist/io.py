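"""Shared containers and tabular readers/writers.

The canonical on-disk dialect is tab-separated UTF-8 with a header row;
comma-separated files are accepted by passing ``sep=","``. Missing values
are written and read as ``NA``. Readers reject malformed input (ragged
rows, duplicate identifiers, unsigned gene-set tokens) rather than
silently repairing it.

Containers defined here:

* :class:`AnalyteMatrix` — an analyte-by-sample expression matrix with a
  linear/log2 scale flag and optional per-analyte annotations
  (``species``, ``is_phospho``).
* :class:`SignedGeneSet` — a pathway's positive and negative regulators;
  the object behind pathway-activity scoring.
* :class:`RunConfig` — the run-wide parameters (seed, quantile, alpha,
  tumor-inclusion window, edge-confidence floor, hub-degree threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("chemoresist")

LINEAR = "linear"
LOG2 = "log2"
_SCALES = (LINEAR, LOG2)

#: analyte annotation columns recognised as sidecars in matrix files
META_COLUMNS = ("species", "is_phospho")
_SPECIES_VALUES = ("human", "mouse")


class FormatError(ValueError):
    """Raised when an input file does not follow the expected dialect."""


class InvariantError(ValueError):
    """Raised when a container would violate one of its declared invariants."""


# ---------------------------------------------------------------------------
# AnalyteMatrix


@dataclass
class AnalyteMatrix:
    """Analyte-by-sample expression matrix.

    Parameters
    ----------
    values
        DataFrame with analyte ids as the index and sample ids as columns.
        Units are raw intensity when ``scale == "linear"`` and log2 units
        when ``scale == "log2"``. Missing readings are NaN.
    scale
        Either ``"linear"`` (raw, non-negative) or ``"log2"``.
    analyte_meta
        Optional per-analyte annotations; recognised columns are
        ``species`` (``human``/``mouse``) and ``is_phospho`` (bool).
    """

    values: pd.DataFrame
    scale: str
    analyte_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise InvariantError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise InvariantError(f"duplicate analyte id(s): {dups}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise InvariantError(f"duplicate sample id(s): {dups}")
        self.values.index = idx.astype(str)
        self.values.columns = cols.astype(str)
        if self.scale == LINEAR:
            arr = self.values.to_numpy(dtype=float)
            if np.any(arr < 0):  # NaN compares False, so missing cells pass
                raise InvariantError("linear-scale matrix contains negative values")
        if self.analyte_meta is not None:
            unknown = set(self.analyte_meta.columns) - set(META_COLUMNS)
            if unknown:
                raise InvariantError(f"unrecognised analyte_meta column(s): {sorted(unknown)}")
            self.analyte_meta = self.analyte_meta.reindex(self.values.index)
            if "species" in self.analyte_meta:
                bad = self.analyte_meta["species"].dropna()
                bad = bad[~bad.isin(_SPECIES_VALUES)]
                if len(bad):
                    raise InvariantError(f"species must be in {_SPECIES_VALUES}; offending: {sorted(set(bad))}")

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def species(self) -> pd.Series | None:
        """Per-analyte species annotation, or None when unannotated."""
        if self.analyte_meta is None or "species" not in self.analyte_meta:
            return None
        return self.analyte_meta["species"]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "AnalyteMatrix":
        """New matrix with replaced values (and optionally scale); metadata follows the rows."""
        meta = None
        if self.analyte_meta is not None:
            meta = self.analyte_meta.reindex(values.index)
        return AnalyteMatrix(values, self.scale if scale is None else scale, meta)


def _scan_table(path: str | Path, sep: str) -> list[str]:
    """Check rectangularity line by line; return the header fields."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty file")
        fields = header.rstrip("\n").split(sep)
        ncol = len(fields)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            if len(line.rstrip("\n").split(sep)) != ncol:
                raise FormatError(f"{path}: ragged row at line {lineno} (expected {ncol} fields)")
    return fields


def _parse_bool_column(col: pd.Series, name: str) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    out = col.astype("string").str.lower().map(mapping)
    bad = col[col.notna() & out.isna()]
    if len(bad):
        raise FormatError(f"column {name!r}: non-boolean value(s) {sorted(set(bad))}")
    return out.astype("boolean")


def read_matrix(path: str | Path, scale: str, sep: str = "\t") -> AnalyteMatrix:
    """Read a delimited analyte-by-sample matrix.

    First column holds analyte ids, header row holds sample ids. Optional
    sidecar columns named ``species`` / ``is_phospho`` become analyte
    annotations. ``NA`` cells become NaN.
    """
    header = _scan_table(path, sep)
    sample_fields = [h for h in header[1:] if h not in META_COLUMNS]
    dup_samples = {s for s in sample_fields if sample_fields.count(s) > 1}
    if dup_samples:
        raise FormatError(f"{path}: duplicate sample id(s): {sorted(dup_samples)}")

    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=False)
    id_col = df.columns[0]
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dups = sorted(set(ids[ids.duplicated()]))
        raise FormatError(f"{path}: duplicate analyte id(s): {dups}")
    df = df.set_index(pd.Index(ids, name="analyte")).drop(columns=[id_col])

    meta = None
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    if meta_cols:
        meta = df[meta_cols].copy()
        df = df.drop(columns=meta_cols)
        if "is_phospho" in meta:
            meta["is_phospho"] = _parse_bool_column(meta["is_phospho"], "is_phospho")
    try:
        values = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric cell: {exc}") from exc
    return AnalyteMatrix(values, scale=scale, analyte_meta=meta)


def write_matrix(m: AnalyteMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix in the canonical dialect (annotations as sidecar columns)."""
    out = m.values
    if m.analyte_meta is not None:
        out = pd.concat([m.analyte_meta, m.values], axis=1)
    out = out.copy()
    out.index.name = "analyte"
    out.to_csv(path, sep=sep, na_rep="NA")


# ---------------------------------------------------------------------------
# SignedGeneSet


@dataclass
class SignedGeneSet:
    """A pathway's regulators split by sign.

    ``positive`` members push pathway activity up, ``negative`` members
    (e.g. inhibitory phospho-sites such as SRC pY527) push it down. The
    two lists are disjoint, together non-empty, and free of duplicates.
    """

    name: str
    positive: list[str] = field(default_factory=list)
    negative: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positive = [str(g) for g in self.positive]
        self.negative = [str(g) for g in self.negative]
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise InvariantError(f"set {self.name!r}: member(s) in both signs: {sorted(overlap)}")
        if not self.positive and not self.negative:
            raise InvariantError(f"set {self.name!r}: empty member list")
        for sign, members in (("+", self.positive), ("-", self.negative)):
            dups = {g for g in members if members.count(g) > 1}
            if dups:
                raise InvariantError(f"set {self.name!r}: duplicate {sign} member(s): {sorted(dups)}")

    @property
    def members(self) -> list[str]:
        return self.positive + self.negative


def read_signed_sets(path: str | Path) -> list[SignedGeneSet]:
    """Parse a signed gene-set file (one set per line).

    Line format: ``name<TAB>+GENE<TAB>-GENE...`` — a GMT-like dialect
    where every member token carries a ``+`` or ``-`` prefix giving its
    regulator sign. Blank lines and ``#`` comments are skipped.
    """
    path = Path(path)
    sets: list[SignedGeneSet] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            name = parts[0].strip()
            if not name:
                raise FormatError(f"{path}:{lineno}: missing set name")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: set {name!r} has an empty member list")
            positive: list[str] = []
            negative: list[str] = []
            for tok in parts[1:]:
                tok = tok.strip()
                if not tok:
                    continue
                if tok[0] == "+":
                    target = positive
                elif tok[0] == "-":
                    target = negative
                else:
                    raise FormatError(f"{path}:{lineno}: member token {tok!r} lacks a +/- sign prefix")
                member = tok[1:]
                if not member:
                    raise FormatError(f"{path}:{lineno}: bare sign with no member id")
                target.append(member)
            try:
                sets.append(SignedGeneSet(name, positive, negative))
            except InvariantError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return sets


def write_signed_sets(sets: Iterable[SignedGeneSet], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in sets:
            toks = [f"+{g}" for g in s.positive] + [f"-{g}" for g in s.negative]
            fh.write("\t".join([s.name, *toks]) + "\n")


# ---------------------------------------------------------------------------
# RunConfig


@dataclass
class RunConfig:
    """Run-wide parameters shared across pipeline stages.

    Defaults follow the study conventions: 75% expression quantile for
    High/Low stratification, alpha 0.05, tumor inclusion when the
    treatment-start volume lies in (60, 200] mm^3, interaction-edge
    confidence floor 0.9 with hubs defined by degree > 2, and the top
    400 differentially expressed genes feeding the network.
    """

    seed: int = 0
    quantile_q: float = 0.75
    alpha: float = 0.05
    auc_inclusion_window: tuple[float, float] = (60.0, 200.0)
    edge_confidence_min: float = 0.9
    hub_min_degree: int = 2
    top_n_deg: int = 400

    def __post_init__(self) -> None:
        if not 0 < self.quantile_q < 1:
            raise InvariantError(f"quantile_q must be in (0,1), got {self.quantile_q}")
        if not 0 < self.alpha < 1:
            raise InvariantError(f"alpha must be in (0,1), got {self.alpha}")
        lo, hi = self.auc_inclusion_window
        if not lo < hi:
            raise InvariantError(f"inclusion window min must be < max, got ({lo}, {hi}]")
        self.auc_inclusion_window = (float(lo), float(hi))
        if not 0 <= self.edge_confidence_min <= 1:
            raise InvariantError("edge_confidence_min must be in [0,1]")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}: expected a mapping of config keys")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config key(s): {sorted(unknown)}")
        if "auc_inclusion_window" in data:
            data["auc_inclusion_window"] = tuple(data["auc_inclusion_window"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["auc_inclusion_window"] = list(data["auc_inclusion_window"])
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Readers for stage-specific tables (types live with their stages; imported
# lazily here to keep io importable from everywhere without cycles).


def read_survival_table(path: str | Path, sep: str = "\t"):
    """Read a survival table (columns: sample_id, time, event[, group])."""
    from .survival import SurvivalCohort

    _scan_table(path, sep)
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=False)
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s): {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["time"] = pd.to_numeric(df["time"])
    df["event"] = _parse_bool_column(df["event"].astype(str), "event").astype(bool)
    group = None
    if "group" in df.columns:
        group = pd.Series(df["group"].astype(str).to_numpy(), index=df["sample_id"].to_numpy())
    return SurvivalCohort(df[["sample_id", "time", "event"]], group=group)


def write_survival_table(cohort, path: str | Path, sep: str = "\t") -> None:
    df = cohort.records.copy()
    if cohort.group is not None:
        df["group"] = cohort.group.reindex(df["sample_id"]).to_numpy()
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def read_growth_table(path: str | Path, sep: str = ","):
    """Read caliper measurements (animal, arm, day, length_mm, width_mm) into GrowthSeries.

    A ``volume_mm3`` column may replace the caliper pair. Default
    separator is comma, matching typical caliper exports.
    """
    from .growth import GrowthSeries

    _scan_table(path, sep)
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=False)
    need = {"animal", "arm", "day"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s): {sorted(missing)}")
    caliper = {"length_mm", "width_mm"} <= set(df.columns)
    if not caliper and "volume_mm3" not in df.columns:
        raise FormatError(f"{path}: need either length_mm+width_mm or volume_mm3 columns")
    series = []
    for (animal, arm), grp in df.groupby(["animal", "arm"], sort=True):
        grp = grp.sort_values("day")
        if caliper:
            series.append(
                GrowthSeries.from_caliper(
                    str(animal), str(arm),
                    grp["day"].to_numpy(dtype=int),
                    grp["length_mm"].to_numpy(dtype=float),
                    grp["width_mm"].to_numpy(dtype=float),
                )
            )
        else:
            series.append(
                GrowthSeries(str(animal), str(arm),
                             grp["day"].to_numpy(dtype=int),
                             grp["volume_mm3"].to_numpy(dtype=float))
            )
    return series


def write_growth_table(series_list, path: str | Path, sep: str = ",") -> None:
    rows = []
    for s in series_list:
        for day, vol in zip(s.days, s.volumes):
            if s.lengths is not None:
                i = int(np.where(s.days == day)[0][0])
                rows.append({"animal": s.animal_id, "arm": s.arm, "day": int(day),
                             "length_mm": s.lengths[i], "width_mm": s.widths[i]})
            else:
                rows.append({"animal": s.animal_id, "arm": s.arm, "day": int(day),
                             "volume_mm3": vol})
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_edge_list(path: str | Path, sep: str = "\t"):
    """Read a confidence-scored edge list (columns: gene_a, gene_b, confidence)."""
    from .network import EdgeList

    _scan_table(path, sep)
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=False)
    need = {"gene_a", "gene_b", "confidence"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s): {sorted(missing)}")
    df["gene_a"] = df["gene_a"].astype(str)
    df["gene_b"] = df["gene_b"].astype(str)
    df["confidence"] = pd.to_numeric(df["confidence"])
    return EdgeList(df)


def write_edge_list(edges, path: str | Path, sep: str = "\t") -> None:
    edges.edges.to_csv(path, sep=sep, index=False)


def read_deg_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read differential-expression records (columns: gene, lfc, padj)."""
    _scan_table(path, sep)
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=False)
    need = {"gene", "lfc", "padj"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s): {sorted(missing)}")
    df["gene"] = df["gene"].astype(str)
    df["lfc"] = pd.to_numeric(df["lfc"])
    df["padj"] = pd.to_numeric(df["padj"])
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        bad = df.loc[(df["padj"] < 0) | (df["padj"] > 1), "gene"].tolist()
        raise FormatError(f"{path}: padj outside [0,1] for gene(s): {bad}")
    return df
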