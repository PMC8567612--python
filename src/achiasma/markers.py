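"""High-confidence discriminant marker selection between two parent strains.

A marker is a biallelic site at which the two (haploid) parents carry
opposite alleles, each supported by deep, near-pure read evidence.  The
default thresholds are at least 10 reads in each parent with more than
90% of reads supporting one allele; a relaxed variant lowers the depth
floor to 3 for low-coverage parents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SampleCall:
    """Per-sample evidence at one site: read depths and an optional GT string."""

    ref_depth: int
    alt_depth: int
    genotype: str | None = None

    def __post_init__(self) -> None:
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("depths must be >= 0")

    @property
    def depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def majority_allele_purity(self) -> float:
        if self.depth == 0:
            return 0.0
        return max(self.ref_depth, self.alt_depth) / self.depth


@dataclass
class SiteCall:
    """One VCF-style record: position is 1-based, as in VCF."""

    chromosome: str
    position: int
    ref: str
    alts: tuple[str, ...]
    samples: dict[str, SampleCall]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("SiteCall positions are 1-based")
        self.alts = tuple(self.alts)


@dataclass
class MarkerTable:
    """Filtered discriminant markers, sorted by (chromosome, position).

    ``table`` columns: ``chrom``, ``pos`` (0-based), ``allele_p1``,
    ``allele_p2``; ``provenance`` records the thresholds used.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    COLUMNS = ("chrom", "pos", "allele_p1", "allele_p2")

    def __post_init__(self) -> None:
        if list(self.table.columns) != list(self.COLUMNS):
            raise ValueError(f"MarkerTable columns must be {self.COLUMNS}")
        if len(self.table):
            if (self.table["allele_p1"] == self.table["allele_p2"]).any():
                raise ValueError("non-discriminant marker in table")
            ordered = self.table.sort_values(["chrom", "pos"], kind="mergesort")
            if not ordered.index.equals(self.table.index):
                self.table = ordered.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def positions(self, chrom: str) -> np.ndarray:
        sub = self.table[self.table["chrom"] == chrom]
        return sub["pos"].to_numpy(dtype=np.int64)

    def alleles(self, chrom: str) -> np.ndarray:
        sub = self.table[self.table["chrom"] == chrom]
        return sub[["allele_p1", "allele_p2"]].to_numpy()

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["pos"] = out["pos"] + 1  # 1-based on disk
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MarkerTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        df["pos"] = df["pos"].astype(np.int64) - 1
        return cls(table=df[list(cls.COLUMNS)])

    @classmethod
    def from_parent_pair(cls, pair) -> "MarkerTable":
        """Ground-truth marker table of a simulated ParentalPair."""
        rows = []
        for chrom, _ in pair.genome.chromosomes:
            pos = pair.positions[chrom]
            alle = pair.alleles[chrom]
            for p, (a1, a2) in zip(pos, alle):
                rows.append((chrom, int(p), a1, a2))
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(table=df, provenance={"source": "simulated-truth"})


def _majority_allele(call: SampleCall, ref: str, alt: str) -> str:
    return ref if call.ref_depth >= call.alt_depth else alt


def select_markers(
    calls: Iterable[SiteCall],
    parents: Sequence[str],
    min_depth: int = 10,
    purity: float = 0.9,
) -> MarkerTable:
    """Keep sites with one alt allele, deep pure evidence, opposite parents.

    A site is retained when it has exactly one alternate allele, each
    parent has depth >= ``min_depth``, each parent's majority allele
    carries strictly more than ``purity`` of its reads, and the two
    parents' majority alleles differ.  Raising either threshold can only
    shrink the retained set.
    """
    if len(parents) != 2:
        raise ValueError("exactly two parent samples required")
    p1, p2 = parents
    rows = []
    n_seen = 0
    for site in calls:
        n_seen += 1
        missing = [p for p in (p1, p2) if p not in site.samples]
        if missing:
            raise ValueError(f"parent sample(s) {missing} absent at "
                             f"{site.chromosome}:{site.position}")
        if len(site.alts) != 1:
            continue
        alt = site.alts[0]
        if len(site.ref) != 1 or len(alt) != 1:
            continue  # indels/MNVs are not markers
        c1, c2 = site.samples[p1], site.samples[p2]
        if c1.depth < min_depth or c2.depth < min_depth:
            continue
        if not (c1.majority_allele_purity > purity and c2.majority_allele_purity > purity):
            continue
        a1 = _majority_allele(c1, site.ref, alt)
        a2 = _majority_allele(c2, site.ref, alt)
        if a1 == a2:
            continue  # non-discriminant
        rows.append((site.chromosome, site.position - 1, a1, a2))
    if not rows:
        logger.info("no sites survived marker filtering (of %d examined)", n_seen)
    df = pd.DataFrame(rows, columns=list(MarkerTable.COLUMNS))
    return MarkerTable(
        table=df,
        provenance={"min_depth": min_depth, "purity": purity,
                    "parents": (p1, p2), "n_sites_examined": n_seen},
    )


def select_markers_relaxed(
    calls: Iterable[SiteCall],
    parents: Sequence[str],
    min_depth: int = 3,
    purity: float = 0.9,
) -> MarkerTable:
    """Marker selection with the reduced-coverage depth floor (default 3)."""
    return select_markers(calls, parents, min_depth=min_depth, purity=purity)
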