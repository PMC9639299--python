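"""Genotype-matrix and marker-map containers.

Genotypes are stored as an individuals x markers ``int8`` array counting
copies of the per-marker counted allele (0/1/2), with ``-1`` for a
missing call.  The marker map carries physical (bp) and genetic (cM)
positions; when a source provides only physical positions the genetic
ones are derived at a constant cM/Mb rate (default 1, i.e. 1 Mb ~ 1 cM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)


class MarkerMap:
    """Ordered marker positions over one or more chromosomes.

    Markers must be grouped by chromosome with strictly increasing bp
    (and non-decreasing cM) within each chromosome.
    """

    def __init__(self, chrom: Sequence, bp: Sequence[int],
                 cM: Optional[Sequence[float]] = None,
                 ids: Optional[Sequence[str]] = None,
                 cm_per_mb: float = 1.0):
        chrom = np.asarray(chrom, dtype=object)
        bp = np.asarray(bp, dtype=np.int64)
        if cM is None:
            if cm_per_mb is None or cm_per_mb <= 0:
                raise ValueError("cM positions absent and no positive cM/Mb rate given")
            cM = bp / 1e6 * cm_per_mb
        cM = np.asarray(cM, dtype=np.float64)
        if not (len(chrom) == len(bp) == len(cM)):
            raise ValueError("chrom/bp/cM length mismatch")
        if np.any(bp < 0) or np.any(cM < 0):
            raise ValueError("negative positions")
        self.table = pd.DataFrame({
            "chrom": chrom,
            "id": ids if ids is not None else [f"snp{i}" for i in range(len(bp))],
            "cM": cM,
            "bp": bp,
        })
        self._slices = self._build_slices()

    def _build_slices(self) -> dict:
        slices = {}
        chrom = self.table["chrom"].to_numpy()
        bp = self.table["bp"].to_numpy()
        cm = self.table["cM"].to_numpy()
        start = 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                c = chrom[start]
                if c in slices:
                    raise ValueError(f"chromosome {c!r} not contiguous in map")
                seg_bp = bp[start:i]
                seg_cm = cm[start:i]
                if np.any(np.diff(seg_bp) <= 0):
                    raise ValueError(f"bp positions not strictly increasing on {c!r}")
                if np.any(np.diff(seg_cm) < 0):
                    raise ValueError(f"cM positions decreasing on {c!r}")
                slices[c] = slice(start, i)
                start = i
        return slices

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list:
        return list(self._slices)

    def chrom_slice(self, chrom) -> slice:
        return self._slices[chrom]

    @property
    def genome_length_mb(self) -> float:
        """Sum over chromosomes of (last - first mapped bp), in Mb."""
        total = 0.0
        bp = self.table["bp"].to_numpy()
        for sl in self._slices.values():
            total += (bp[sl.stop - 1] - bp[sl.start]) / 1e6
        return total

    @property
    def genome_length_morgan(self) -> float:
        total = 0.0
        cm = self.table["cM"].to_numpy()
        for sl in self._slices.values():
            total += (cm[sl.stop - 1] - cm[sl.start]) / 100.0
        return total


@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype calls with an attached marker map."""

    ids: list
    geno: np.ndarray  # int8, -1 missing
    mmap: MarkerMap
    _freq: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.ndim != 2:
            raise ValueError("genotype array must be 2-D")
        if self.geno.shape[0] != len(self.ids):
            raise ValueError("individual count mismatch")
        if self.geno.shape[1] != len(self.mmap):
            raise ValueError("marker count mismatch with map")
        bad = ~np.isin(self.geno, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes outside {-1, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.geno.shape[0]

    @property
    def n_markers(self) -> int:
        return self.geno.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Counted-allele sample frequency per marker over non-missing calls."""
        if self._freq is None:
            g = self.geno
            obs = g >= 0
            n = obs.sum(axis=0)
            with np.errstate(invalid="ignore"):
                self._freq = np.where(obs, g, 0).sum(axis=0) / np.where(n > 0, 2.0 * n, np.nan)
        return self._freq

    @property
    def n_called(self) -> np.ndarray:
        """Number of non-missing calls per marker."""
        return (self.geno >= 0).sum(axis=0)

    def to_minor(self) -> "GenotypeMatrix":
        """Recode so the counted allele is the minor one at every marker.

        Markers already at frequency <= 0.5 are untouched; ties stay as
        coded.  All downstream statistics (homozygosity, VanRaden G, ROH)
        are invariant to this flip; it exists so that PLINK round trips
        are bit-identical.
        """
        p = self.allele_freq
        flip = p > 0.5
        g = self.geno.copy()
        cols = np.flatnonzero(flip)
        sub = g[:, cols]
        sub = np.where(sub >= 0, 2 - sub, sub).astype(np.int8)
        g[:, cols] = sub
        return GenotypeMatrix(list(self.ids), g, self.mmap)

    def subset(self, ids: Sequence) -> "GenotypeMatrix":
        pos = [self.ids.index(i) for i in ids]
        return GenotypeMatrix(list(ids), self.geno[pos], self.mmap)
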