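"""Coordinate-basis shifts and pluggable assembly-to-assembly position mapping.

Test datasets arrive on various genome assemblies and position conventions;
before a sample can be intersected with the training table its coordinates
must match the training assembly. Two concerns are handled here: (1) a basis
shift for inputs reported 0-based (shift by +1 before mapping), and (2)
re-keying each site through an :class:`AssemblyMap`. Chain-file liftover is
deliberately out of scope — maps are either the identity or an explicit
lookup table, and a caller can plug in any object with the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .methylation_io import CpGCoordinate, MethylationCallSet


class CoordinateError(ValueError):
    """A position left the valid 1-based range."""


class AssemblyMismatchError(ValueError):
    """Call set assembly does not match the map's source assembly."""


class LiftCollisionError(ValueError):
    """Two source sites mapped to the same target coordinate (bad map)."""


class UnmappedSiteError(ValueError):
    """Strict lift policy hit an unmapped site."""


def shift_basis(callset: MethylationCallSet, offset: int) -> MethylationCallSet:
    """Shift every position by ``offset`` (0, +1 or -1); counts are unchanged.

    Used to bring 0-based input coordinates onto the package's 1-based
    convention before any assembly lift.
    """
    if offset not in (0, 1, -1):
        raise ValueError("offset must be one of 0, +1, -1")
    if offset == 0:
        return MethylationCallSet(
            sample_id=callset.sample_id, data=callset.data.copy(), assembly=callset.assembly
        )
    pos = callset.data.index.get_level_values("pos").to_numpy() + offset
    if len(pos) and pos.min() < 1:
        raise CoordinateError(
            f"shift by {offset:+d} pushes a position below 1 in sample {callset.sample_id}"
        )
    idx = pd.MultiIndex.from_arrays(
        [callset.data.index.get_level_values("chrom"), pos], names=["chrom", "pos"]
    )
    data = pd.DataFrame(
        {"meth": callset.data["meth"].to_numpy(), "unmeth": callset.data["unmeth"].to_numpy()},
        index=idx,
    )
    return MethylationCallSet(sample_id=callset.sample_id, data=data, assembly=callset.assembly)


class AssemblyMap:
    """Deterministic (chrom, pos) -> (chrom, pos) position mapping.

    Subclasses implement :meth:`map_position` returning the target coordinate
    or ``None`` for unmapped sites.
    """

    source: str
    target: str

    def map_position(self, chrom: str, pos: int) -> Optional[tuple[str, int]]:
        raise NotImplementedError


class IdentityMap(AssemblyMap):
    """Maps every position to itself (source assembly == target assembly)."""

    def __init__(self, assembly: str):
        self.source = assembly
        self.target = assembly

    def map_position(self, chrom: str, pos: int):
        return (chrom, pos)


class LookupTableMap(AssemblyMap):
    """Explicit position map backed by a table of source/target coordinates."""

    def __init__(self, source: str, target: str, entries: dict[tuple[str, int], tuple[str, int]]):
        self.source = source
        self.target = target
        self._entries = dict(entries)

    @classmethod
    def from_tsv(cls, path, source: str, target: str) -> "LookupTableMap":
        """Load from a TSV with columns source_chrom, source_pos, target_chrom, target_pos."""
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["source_chrom", "source_pos", "target_chrom", "target_pos"],
            dtype={"source_chrom": str, "target_chrom": str},
        )
        entries = {
            (str(r.source_chrom), int(r.source_pos)): (str(r.target_chrom), int(r.target_pos))
            for r in df.itertuples()
        }
        return cls(source=source, target=target, entries=entries)

    def map_position(self, chrom: str, pos: int):
        return self._entries.get((chrom, int(pos)))


@dataclass
class LiftReport:
    """Bookkeeping of one lift: how many sites mapped and how many were dropped."""

    n_input: int
    n_mapped: int
    n_dropped: int


def lift_callset(
    callset: MethylationCallSet,
    assembly_map: AssemblyMap,
    on_unmapped: str = "drop",
) -> tuple[MethylationCallSet, LiftReport]:
    """Re-key every site of ``callset`` through ``assembly_map``.

    Unmapped sites are dropped (``on_unmapped="drop"``, the default) or raise
    (``"strict"``). Two source sites landing on one target coordinate raise
    :class:`LiftCollisionError`, which signals a defective map.
    """
    if on_unmapped not in ("drop", "strict"):
        raise ValueError("on_unmapped must be 'drop' or 'strict'")
    if callset.assembly != assembly_map.source:
        raise AssemblyMismatchError(
            f"call set is on {callset.assembly!r} but map source is {assembly_map.source!r}"
        )
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[int] = []
    unmeths: list[int] = []
    n_dropped = 0
    for (chrom, pos), row in callset.data.iterrows():
        hit = assembly_map.map_position(chrom, int(pos))
        if hit is None:
            if on_unmapped == "strict":
                raise UnmappedSiteError(
                    f"site ({chrom}, {pos}) of sample {callset.sample_id} has no target coordinate"
                )
            n_dropped += 1
            continue
        chroms.append(hit[0])
        poss.append(hit[1])
        meths.append(int(row["meth"]))
        unmeths.append(int(row["unmeth"]))
    idx = pd.MultiIndex.from_arrays(
        [np.array(chroms, dtype=object), np.array(poss, dtype=np.int64)], names=["chrom", "pos"]
    )
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise LiftCollisionError(f"two source sites map to the same target coordinate {dup}")
    out = MethylationCallSet(
        sample_id=callset.sample_id,
        data=pd.DataFrame({"meth": meths, "unmeth": unmeths}, index=idx, dtype=np.int64),
        assembly=assembly_map.target,
    )
    report = LiftReport(n_input=callset.n_sites, n_mapped=len(poss), n_dropped=n_dropped)
    return out, report
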