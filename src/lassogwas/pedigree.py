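"""Pedigree records: individual / sire / dam triples.

A pedigree is the input to the additive relationship matrix and to the
gene-dropping genotype simulator.  Unknown parents are encoded as ``"0"``,
the PLINK convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNKNOWN = "0"


@dataclass
class Pedigree:
    """Individual-sire-dam records, optionally tagged with a generation number.

    Invariants checked by :meth:`validate`: ids are unique, no individual is
    its own parent, and every named parent appears among the ids.
    Topological order (parents before offspring) is *not* required here;
    :func:`sort_pedigree` establishes it.
    """

    ids: list[str]
    sires: list[str]
    dams: list[str]
    generation: list[int] | None = None

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.sires) == len(self.dams)):
            raise ValueError("ids, sires and dams must have equal length")
        if self.generation is not None and len(self.generation) != len(self.ids):
            raise ValueError("generation must match ids in length")

    def __len__(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        seen = set(self.ids)
        if len(seen) != len(self.ids):
            raise ValueError("pedigree ids are not unique")
        for i, s, d in zip(self.ids, self.sires, self.dams):
            if i == s or i == d:
                raise ValueError(f"individual {i!r} listed as its own parent")
            for p in (s, d):
                if p != UNKNOWN and p not in seen:
                    raise ValueError(f"parent {p!r} of {i!r} absent from pedigree")

    def to_frame(self) -> pd.DataFrame:
        cols = {"id": self.ids, "sire": self.sires, "dam": self.dams}
        if self.generation is not None:
            cols["generation"] = self.generation
        return pd.DataFrame(cols)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame()[["id", "sire", "dam"]].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", dtype=str)
        need = {"id", "sire", "dam"}
        if not need.issubset(df.columns):
            raise ValueError(f"pedigree file must have columns {sorted(need)}")
        ped = cls(list(df["id"]), list(df["sire"]), list(df["dam"]))
        ped.validate()
        return ped


def sort_pedigree(ped: Pedigree) -> Pedigree:
    """Topologically sort a pedigree so parents precede offspring.

    Stable: among individuals whose parents are already placed, input order is
    preserved, so an already-sorted pedigree is returned unchanged.  A cycle
    (an individual that is its own ancestor) raises ``ValueError`` naming an
    individual on the cycle.
    """
    ped.validate()
    index = {i: k for k, i in enumerate(ped.ids)}
    placed: set[str] = set()
    order: list[int] = []
    remaining = list(range(len(ped)))
    while remaining:
        progressed = []
        for k in remaining:
            s, d = ped.sires[k], ped.dams[k]
            if (s == UNKNOWN or s in placed) and (d == UNKNOWN or d in placed):
                progressed.append(k)
        if not progressed:
            culprit = ped.ids[remaining[0]]
            raise ValueError(f"pedigree contains a cycle involving {culprit!r}")
        for k in progressed:
            order.append(k)
            placed.add(ped.ids[k])
        remaining = [k for k in remaining if k not in set(progressed)]
    gen = None if ped.generation is None else [ped.generation[k] for k in order]
    return Pedigree(
        [ped.ids[k] for k in order],
        [ped.sires[k] for k in order],
        [ped.dams[k] for k in order],
        gen,
    )


def parent_indices(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Integer sire/dam indices into ``ped.ids`` (-1 for unknown)."""
    index = {i: k for k, i in enumerate(ped.ids)}
    sire = np.array([index.get(s, -1) if s != UNKNOWN else -1 for s in ped.sires])
    dam = np.array([index.get(d, -1) if d != UNKNOWN else -1 for d in ped.dams])
    return sire, dam
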