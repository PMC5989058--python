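"""Observation containers and delimited-text IO.

The unit of every hierarchical fit is one patient: their age, the number of
crypts scored, counts of wholly (WPC) and partially (PPC) populated mutant
crypts, and the list of mutant patch sizes. Transit-amplifying (TA) clone
screens contribute per-tissue-block counts of de novo clones against the
goblet-cell total scored in the block.

On-disk formats are plain TSV:

* cohort:  ``patient  age  crypts  wpc  ppc``
* patches: ``patient  age  patch_size`` (one row per patch)
* TA:      ``patient  block  ta_clones  goblet_cells``
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortObservation",
    "TABlockCounts",
    "cohort_to_frame",
    "frame_to_cohort",
    "read_cohort_tsv",
    "write_cohort_tsv",
    "read_patches_tsv",
    "write_patches_tsv",
    "read_ta_tsv",
    "write_ta_tsv",
]


@dataclass
class CohortObservation:
    """One patient's clone counts.

    ``patch_sizes`` lists the size in crypts of each mutant patch observed
    (a fixed clone that has not undergone fission is a patch of one).
    ``delta`` is the neighbour count per crypt used for the chance-doublet
    correction (6 for hexagonal packing).
    """

    patient: str
    age: float
    crypts: int
    wpc: int
    ppc: int
    patch_sizes: list[int] = field(default_factory=list)
    delta: int = 6

    def __post_init__(self) -> None:
        if not 0 <= self.age <= 110:
            raise ValueError(f"age out of range: {self.age}")
        if self.crypts <= 0:
            raise ValueError("crypts must be positive")
        if self.wpc < 0 or self.ppc < 0 or self.wpc + self.ppc > self.crypts:
            raise ValueError("wpc + ppc must lie in [0, crypts]")
        if any(int(g) < 1 for g in self.patch_sizes):
            raise ValueError("patch sizes must be >= 1")
        self.patch_sizes = [int(g) for g in self.patch_sizes]


@dataclass(frozen=True)
class TABlockCounts:
    """TA-clone count ``k`` against goblet-cell total ``G`` for one block."""

    patient: str
    block: str
    k: int
    G: int

    def __post_init__(self) -> None:
        if self.G <= 0:
            raise ValueError("goblet-cell total must be positive")
        if not 0 <= self.k <= self.G:
            raise ValueError("TA clone count must lie in [0, G]")


def cohort_to_frame(cohort: list[CohortObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient": [o.patient for o in cohort],
            "age": [o.age for o in cohort],
            "crypts": [o.crypts for o in cohort],
            "wpc": [o.wpc for o in cohort],
            "ppc": [o.ppc for o in cohort],
        }
    )


def frame_to_cohort(
    df: pd.DataFrame, patches: pd.DataFrame | None = None, delta: int = 6
) -> list[CohortObservation]:
    sizes: dict[str, list[int]] = {}
    if patches is not None:
        for pat, grp in patches.groupby("patient"):
            sizes[str(pat)] = [int(g) for g in grp["patch_size"]]
    return [
        CohortObservation(
            patient=str(r.patient),
            age=float(r.age),
            crypts=int(r.crypts),
            wpc=int(r.wpc),
            ppc=int(r.ppc),
            patch_sizes=sizes.get(str(r.patient), []),
            delta=delta,
        )
        for r in df.itertuples()
    ]


def write_cohort_tsv(cohort: list[CohortObservation], path) -> None:
    cohort_to_frame(cohort).to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path, patches_path=None, delta: int = 6) -> list[CohortObservation]:
    df = pd.read_csv(path, sep="\t")
    patches = pd.read_csv(patches_path, sep="\t") if patches_path else None
    return frame_to_cohort(df, patches, delta)


def write_patches_tsv(cohort: list[CohortObservation], path) -> None:
    rows = [
        {"patient": o.patient, "age": o.age, "patch_size": g}
        for o in cohort
        for g in o.patch_sizes
    ]
    pd.DataFrame(rows, columns=["patient", "age", "patch_size"]).to_csv(
        path, sep="\t", index=False
    )


def read_patches_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ta_tsv(blocks: list[TABlockCounts], path) -> None:
    pd.DataFrame(
        {
            "patient": [b.patient for b in blocks],
            "block": [b.block for b in blocks],
            "ta_clones": [b.k for b in blocks],
            "goblet_cells": [b.G for b in blocks],
        }
    ).to_csv(path, sep="\t", index=False)


def read_ta_tsv(path) -> list[TABlockCounts]:
    df = pd.read_csv(path, sep="\t")
    return [
        TABlockCounts(str(r.patient), str(r.block), int(r.ta_clones), int(r.goblet_cells))
        for r in df.itertuples()
    ]


def patch_counts(obs: CohortObservation, n_max: int | None = None) -> np.ndarray:
    """Counts of patches by size 1..n_max for one patient."""
    if not obs.patch_sizes:
        return np.zeros(0, dtype=int)
    m = max(obs.patch_sizes)
    n_max = m if n_max is None else max(n_max, m)
    out = np.zeros(n_max, dtype=int)
    for g in obs.patch_sizes:
        out[g - 1] += 1
    return out
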