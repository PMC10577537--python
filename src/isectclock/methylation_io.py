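"""Reading CpG-level methylation calls and assembling the training feature table.

Bisulfite sequencing reports methylated/unmethylated read counts per cytosine
and per strand. A CpG dinucleotide is symmetric: the plus-strand C at position
``p`` and the minus-strand C at ``p + 1`` interrogate the same site, so counts
from both strands are summed into one strand-collapsed record keyed by the
plus-strand C position (1-based). All coordinates inside the package are
1-based; basis conversion happens only at reader boundaries.

The training feature table keeps only the CpG sites covered by at least
``min_coverage`` reads (after strand collapse) in *every* training sample, so
it contains no missing entries by construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Malformed input file (reports the offending line where known)."""


class MetadataError(ValueError):
    """Sample metadata missing or inconsistent."""


class EmptyTableError(ValueError):
    """No CpG site survived the cross-sample intersection."""


class CpGCoordinate(NamedTuple):
    """Strand-collapsed CpG site: chromosome and 1-based plus-strand C position."""

    chrom: str
    pos: int


@dataclass(frozen=True)
class SiteCall:
    """Read counts at one strand-collapsed CpG site."""

    coord: CpGCoordinate
    meth_reads: int
    unmeth_reads: int

    @property
    def coverage(self) -> int:
        return self.meth_reads + self.unmeth_reads


def methylation_percent(call: SiteCall) -> float:
    """Methylation percentage 100 * meth / (meth + unmeth); requires coverage > 0."""
    cov = call.meth_reads + call.unmeth_reads
    if cov <= 0:
        raise ValueError(
            f"methylation percentage undefined at {call.coord}: zero coverage"
        )
    return 100.0 * call.meth_reads / cov


@dataclass
class MethylationCallSet:
    """One sample's strand-collapsed CpG calls.

    ``data`` is indexed by (chrom, pos) with integer columns ``meth`` and
    ``unmeth``; the index is unique and sorted.
    """

    sample_id: str
    data: pd.DataFrame
    assembly: str = "synthetic"

    def __post_init__(self) -> None:
        if list(self.data.columns) != ["meth", "unmeth"]:
            self.data = self.data[["meth", "unmeth"]]
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ParseError(
                f"duplicate coordinate after strand collapse: {dup} "
                f"(sample {self.sample_id})"
            )
        if len(self.data) and ((self.data["meth"] < 0).any() or (self.data["unmeth"] < 0).any()):
            raise ParseError(f"negative read count in sample {self.sample_id}")
        if not self.data.index.is_monotonic_increasing:
            self.data = self.data.sort_index()

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_calls(
        cls, sample_id: str, calls: Iterable[SiteCall], assembly: str = "synthetic"
    ) -> "MethylationCallSet":
        calls = list(calls)
        idx = pd.MultiIndex.from_tuples(
            [c.coord for c in calls], names=["chrom", "pos"]
        ) if calls else _empty_index()
        data = pd.DataFrame(
            {
                "meth": [c.meth_reads for c in calls],
                "unmeth": [c.unmeth_reads for c in calls],
            },
            index=idx,
            dtype=np.int64,
        )
        return cls(sample_id=sample_id, data=data, assembly=assembly)

    @classmethod
    def from_arrays(
        cls,
        sample_id: str,
        chrom: Sequence[str],
        pos: Sequence[int],
        meth: Sequence[int],
        unmeth: Sequence[int],
        assembly: str = "synthetic",
    ) -> "MethylationCallSet":
        idx = pd.MultiIndex.from_arrays(
            [np.asarray(chrom, dtype=object), np.asarray(pos, dtype=np.int64)],
            names=["chrom", "pos"],
        )
        data = pd.DataFrame(
            {"meth": np.asarray(meth, dtype=np.int64),
             "unmeth": np.asarray(unmeth, dtype=np.int64)},
            index=idx,
        )
        return cls(sample_id=sample_id, data=data, assembly=assembly)

    # -- accessors --------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.data)

    @property
    def coordinates(self) -> pd.MultiIndex:
        return self.data.index

    def coordinate_set(self) -> set[CpGCoordinate]:
        return {CpGCoordinate(c, int(p)) for c, p in self.data.index}

    def get(self, coord: CpGCoordinate) -> SiteCall:
        row = self.data.loc[(coord.chrom, coord.pos)]
        return SiteCall(coord, int(row["meth"]), int(row["unmeth"]))

    def percentages(self) -> pd.Series:
        """Methylation percentage per site (coverage must be positive everywhere)."""
        cov = self.data["meth"] + self.data["unmeth"]
        if (cov <= 0).any():
            bad = self.data.index[cov <= 0][0]
            raise ValueError(f"zero-coverage site {bad} in sample {self.sample_id}")
        return 100.0 * self.data["meth"] / cov

    def filter_coverage(self, min_coverage: int) -> "MethylationCallSet":
        cov = self.data["meth"] + self.data["unmeth"]
        return MethylationCallSet(
            sample_id=self.sample_id,
            data=self.data[cov >= min_coverage].copy(),
            assembly=self.assembly,
        )


def _empty_index() -> pd.MultiIndex:
    return pd.MultiIndex.from_arrays(
        [np.array([], dtype=object), np.array([], dtype=np.int64)],
        names=["chrom", "pos"],
    )


def _normalize_chrom(series: pd.Series) -> pd.Series:
    return series.where(series.str.startswith("chr"), "chr" + series)


# ---------------------------------------------------------------------------
# Bismark-style CpG report reader
# ---------------------------------------------------------------------------

def read_cpg_report(
    path,
    min_coverage: int = 5,
    sample_id: str | None = None,
    assembly: str = "synthetic",
    normalize_chrom: bool = False,
) -> MethylationCallSet:
    """Read a Bismark-style CpG report and strand-collapse it.

    Expected tab-separated columns: chromosome, 1-based position, strand
    (``+``/``-``), methylated count, unmethylated count; any further columns
    (context, trinucleotide) are ignored. A minus-strand record at position
    ``p`` is summed into the plus-strand coordinate ``p - 1`` when a plus
    record exists there, otherwise it is re-keyed to ``p - 1`` on its own.
    Sites whose summed coverage falls below ``min_coverage`` are dropped.
    """
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    name = sample_id if sample_id is not None else _stem(path)
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, dtype=str, comment=None, skip_blank_lines=False
        )
    except pd.errors.EmptyDataError:
        return MethylationCallSet(
            sample_id=name,
            data=pd.DataFrame({"meth": [], "unmeth": []}, index=_empty_index(), dtype=np.int64),
            assembly=assembly,
        )
    if raw.shape[1] < 5:
        raise ParseError(f"{path}: expected >=5 tab-separated columns, got {raw.shape[1]}")
    raw = raw.iloc[:, :5]
    raw.columns = ["chrom", "pos", "strand", "meth", "unmeth"]

    for col in ("pos", "meth", "unmeth"):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | (converted % 1 != 0)
        if bad.any():
            line = int(converted.index[bad][0]) + 1
            raise ParseError(f"{path}: malformed line {line}: non-integer {col!r} field")
        raw[col] = converted.astype(np.int64)
    unknown = ~raw["strand"].isin(["+", "-"])
    if unknown.any():
        line = int(raw.index[unknown][0]) + 1
        raise ParseError(
            f"{path}: malformed line {line}: unknown strand symbol {raw['strand'][unknown].iloc[0]!r}"
        )
    if (raw["meth"] < 0).any() or (raw["unmeth"] < 0).any():
        neg = (raw["meth"] < 0) | (raw["unmeth"] < 0)
        raise ParseError(f"{path}: malformed line {int(raw.index[neg][0]) + 1}: negative count")
    if (raw["pos"] < 1).any():
        line = int(raw.index[raw["pos"] < 1][0]) + 1
        raise ParseError(f"{path}: malformed line {line}: position < 1")
    dup = raw.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        line = int(raw.index[dup][0]) + 1
        raise ParseError(f"{path}: duplicate record for same (chrom, pos, strand) at line {line}")

    if normalize_chrom:
        raw["chrom"] = _normalize_chrom(raw["chrom"])

    # Strand collapse: a minus-strand C belongs to the CpG whose plus-strand C
    # sits one base upstream.
    minus = raw["strand"] == "-"
    if (minus & (raw["pos"] < 2)).any():
        line = int(raw.index[minus & (raw["pos"] < 2)][0]) + 1
        raise ParseError(f"{path}: malformed line {line}: minus-strand record at position 1")
    raw.loc[minus, "pos"] -= 1
    collapsed = raw.groupby(["chrom", "pos"], sort=True)[["meth", "unmeth"]].sum()
    collapsed = collapsed[(collapsed["meth"] + collapsed["unmeth"]) >= min_coverage]
    return MethylationCallSet(sample_id=name, data=collapsed, assembly=assembly)


# ---------------------------------------------------------------------------
# Processed (GEO-style) table reader
# ---------------------------------------------------------------------------

@dataclass
class TableDialect:
    """Column layout of a processed methylation table.

    ``value_kind`` is one of ``"fraction"`` (methylation level in [0, 1] plus a
    coverage column), ``"percent"`` (level in [0, 100] plus coverage), or
    ``"counts"`` (separate methylated/unmethylated count columns).
    ``position_basis`` 0 means positions are 0-based and are shifted to the
    package's 1-based convention on read.
    """

    chrom_col: int = 0
    pos_col: int = 1
    value_kind: str = "fraction"
    value_col: int | None = 2
    coverage_col: int | None = 3
    meth_col: int | None = None
    unmeth_col: int | None = None
    position_basis: int = 1
    sep: str = "\t"
    has_header: bool = False
    normalize_chrom: bool = False

    def __post_init__(self) -> None:
        if self.value_kind not in ("fraction", "percent", "counts"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.position_basis not in (0, 1):
            raise ValueError("position_basis must be 0 or 1")
        if self.value_kind == "counts":
            if self.meth_col is None or self.unmeth_col is None:
                raise ValueError("counts dialect requires meth_col and unmeth_col")
        elif self.value_col is None or self.coverage_col is None:
            raise ValueError(f"{self.value_kind} dialect requires value_col and coverage_col")


def read_processed_table(
    path,
    dialect: TableDialect,
    min_coverage: int = 5,
    sample_id: str | None = None,
    assembly: str = "synthetic",
) -> MethylationCallSet:
    """Read a processed methylation table (already strand-collapsed upstream).

    Fraction/percent dialects reconstruct counts by half-up rounding of
    ``level * coverage``; count dialects use the counts as given. The coverage
    filter is applied exactly as in :func:`read_cpg_report`.
    """
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    name = sample_id if sample_id is not None else _stem(path)
    try:
        raw = pd.read_csv(
            path, sep=dialect.sep, header=0 if dialect.has_header else None, dtype=str
        )
    except pd.errors.EmptyDataError:
        return MethylationCallSet(
            sample_id=name,
            data=pd.DataFrame({"meth": [], "unmeth": []}, index=_empty_index(), dtype=np.int64),
            assembly=assembly,
        )
    needed = [dialect.chrom_col, dialect.pos_col] + (
        [dialect.meth_col, dialect.unmeth_col]
        if dialect.value_kind == "counts"
        else [dialect.value_col, dialect.coverage_col]
    )
    if max(needed) >= raw.shape[1]:
        raise MetadataError(
            f"{path}: dialect references column {max(needed)} but table has {raw.shape[1]} columns"
        )
    offset = 0 if dialect.has_header else 1  # header consumes a file line

    chrom = raw.iloc[:, dialect.chrom_col].astype(str)
    if dialect.normalize_chrom:
        chrom = _normalize_chrom(chrom)
    pos = pd.to_numeric(raw.iloc[:, dialect.pos_col], errors="coerce")
    if pos.isna().any():
        line = int(pos.index[pos.isna()][0]) + 1 + (1 if dialect.has_header else 0)
        raise ParseError(f"{path}: malformed line {line}: non-numeric position")
    pos = pos.astype(np.int64)
    if dialect.position_basis == 0:
        pos = pos + 1
    if (pos < 1).any():
        raise ParseError(f"{path}: position < 1 after basis conversion")

    if dialect.value_kind == "counts":
        meth = pd.to_numeric(raw.iloc[:, dialect.meth_col], errors="raise").astype(np.int64)
        unmeth = pd.to_numeric(raw.iloc[:, dialect.unmeth_col], errors="raise").astype(np.int64)
    else:
        level = pd.to_numeric(raw.iloc[:, dialect.value_col], errors="coerce")
        cov = pd.to_numeric(raw.iloc[:, dialect.coverage_col], errors="coerce")
        if level.isna().any() or cov.isna().any():
            bad = level.isna() | cov.isna()
            raise ParseError(
                f"{path}: malformed line {int(level.index[bad][0]) + 1 + (1 if dialect.has_header else 0)}:"
                " non-numeric methylation level or coverage"
            )
        hi = 1.0 if dialect.value_kind == "fraction" else 100.0
        if ((level < 0) | (level > hi)).any():
            bad = (level < 0) | (level > hi)
            raise ParseError(
                f"{path}: methylation {dialect.value_kind} outside [0, {hi:g}] "
                f"at line {int(level.index[bad][0]) + 1 + (1 if dialect.has_header else 0)}"
            )
        frac = level / hi
        cov = cov.astype(np.int64)
        meth = np.floor(frac * cov + 0.5).astype(np.int64)  # half-up rounding
        unmeth = cov - meth
    data = pd.DataFrame(
        {"meth": meth.to_numpy(), "unmeth": np.asarray(unmeth)},
        index=pd.MultiIndex.from_arrays([chrom.to_numpy(object), pos.to_numpy()],
                                        names=["chrom", "pos"]),
    )
    if data.index.has_duplicates:
        dup = data.index[data.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate record for coordinate {dup}")
    data = data[(data["meth"] + data["unmeth"]) >= min_coverage].sort_index()
    return MethylationCallSet(sample_id=name, data=data, assembly=assembly)


def _stem(path) -> str:
    import os

    if isinstance(path, io.IOBase):
        return "sample"
    base = os.path.basename(str(path))
    for suffix in (".gz", ".txt", ".tsv", ".cov", ".CpG_report"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    return base


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Samples x CpG-sites matrix of methylation percentages with ages.

    ``values`` has one row per sample and one column per site, all entries in
    [0, 100]; every retained site is covered in every sample. ``sites`` is a
    (chrom, pos) MultiIndex sorted by chromosome then position.
    """

    sample_ids: list[str]
    ages: np.ndarray
    sites: pd.MultiIndex
    values: np.ndarray
    group_labels: list[str] | None = None
    assembly: str = "synthetic"

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.ages) != self.values.shape[0] or len(self.sample_ids) != self.values.shape[0]:
            raise MetadataError("ages/sample_ids length must match number of matrix rows")
        if len(self.sites) != self.values.shape[1]:
            raise MetadataError("sites length must match number of matrix columns")
        if (self.ages < 0).any():
            raise MetadataError("negative chronological age")
        if self.values.size and (np.nanmin(self.values) < 0 or np.nanmax(self.values) > 100):
            raise ValueError("methylation percentages must lie in [0, 100]")
        if np.isnan(self.values).any():
            raise ValueError("feature table must not contain missing entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def site_list(self) -> list[CpGCoordinate]:
        return [CpGCoordinate(c, int(p)) for c, p in self.sites]

    # -- persistence -------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV: sample_id, age, group, then one 'chrom:pos' column per site."""
        cols = [f"{c}:{p}" for c, p in self.sites]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "age", self.ages)
        df.insert(2, "group", self.group_labels if self.group_labels is not None else "")
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path, assembly: str = "synthetic") -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        meta_cols = ["sample_id", "age", "group"]
        site_cols = [c for c in df.columns if c not in meta_cols]
        pairs = [c.rsplit(":", 1) for c in site_cols]
        sites = pd.MultiIndex.from_arrays(
            [[c for c, _ in pairs], [int(p) for _, p in pairs]], names=["chrom", "pos"]
        )
        groups = df["group"].astype(str).tolist() if "group" in df else None
        if groups is not None and all(g in ("", "nan") for g in groups):
            groups = None
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            ages=df["age"].to_numpy(float),
            sites=sites,
            values=df[site_cols].to_numpy(float),
            group_labels=groups,
            assembly=assembly,
        )

    def to_npz(self, path) -> None:
        """Compact binary cache (lossless round-trip of the TSV contents)."""
        np.savez_compressed(
            path,
            sample_ids=np.array(self.sample_ids, dtype=object),
            ages=self.ages,
            chroms=np.array([c for c, _ in self.sites], dtype=object),
            poss=np.array([p for _, p in self.sites], dtype=np.int64),
            values=self.values,
            groups=np.array(self.group_labels if self.group_labels else [], dtype=object),
            assembly=np.array([self.assembly], dtype=object),
        )

    @classmethod
    def from_npz(cls, path) -> "FeatureTable":
        with np.load(path, allow_pickle=True) as z:
            groups = z["groups"].tolist() or None
            return cls(
                sample_ids=z["sample_ids"].tolist(),
                ages=z["ages"],
                sites=pd.MultiIndex.from_arrays(
                    [z["chroms"].tolist(), z["poss"]], names=["chrom", "pos"]
                ),
                values=z["values"],
                group_labels=groups,
                assembly=str(z["assembly"][0]),
            )


def build_feature_table(
    callsets: Sequence[MethylationCallSet],
    metadata: Mapping[str, tuple] | pd.DataFrame,
    assembly: str | None = None,
) -> FeatureTable:
    """Assemble the training feature table from coverage-filtered call sets.

    Retains exactly the CpG sites present in *all* call sets (the cross-sample
    intersection), in (chrom, pos) order; rows follow the input call-set order.
    ``metadata`` maps sample_id -> (age, group) or is a DataFrame with columns
    sample_id, age[, group].
    """
    if not callsets:
        raise MetadataError("no call sets given")
    meta = _normalize_metadata(metadata)
    for cs in callsets:
        if cs.sample_id not in meta:
            raise MetadataError(f"sample {cs.sample_id!r} missing from metadata")
        age = meta[cs.sample_id][0]
        if age is None or (isinstance(age, float) and np.isnan(age)) or age < 0:
            raise MetadataError(f"sample {cs.sample_id!r} has invalid age {age!r}")

    common = callsets[0].coordinates
    for cs in callsets[1:]:
        common = common.intersection(cs.coordinates)
    common = common.sort_values()
    if len(common) == 0:
        raise EmptyTableError(
            "no CpG site is covered in every sample; check assemblies and chromosome naming"
        )
    rows = np.empty((len(callsets), len(common)), dtype=float)
    for i, cs in enumerate(callsets):
        sub = cs.data.loc[common]
        cov = (sub["meth"] + sub["unmeth"]).to_numpy(float)
        rows[i] = 100.0 * sub["meth"].to_numpy(float) / cov
    return FeatureTable(
        sample_ids=[cs.sample_id for cs in callsets],
        ages=np.array([meta[cs.sample_id][0] for cs in callsets], dtype=float),
        sites=common,
        values=rows,
        group_labels=[str(meta[cs.sample_id][1]) for cs in callsets],
        assembly=assembly if assembly is not None else callsets[0].assembly,
    )


def _normalize_metadata(metadata) -> dict[str, tuple]:
    if isinstance(metadata, pd.DataFrame):
        if "sample_id" not in metadata or "age" not in metadata:
            raise MetadataError("metadata table needs 'sample_id' and 'age' columns")
        out = {}
        for _, row in metadata.iterrows():
            out[str(row["sample_id"])] = (
                float(row["age"]),
                row.get("group", "") if hasattr(row, "get") else "",
            )
        return out
    out = {}
    for sid, val in metadata.items():
        if isinstance(val, (tuple, list)):
            age = val[0]
            group = val[1] if len(val) > 1 else ""
        else:
            age, group = val, ""
        out[str(sid)] = (age, group)
    return out
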