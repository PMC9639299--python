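"""Synthetic pedigrees and linked genotypes with tracked autozygosity.

The generator exists so that every estimator in the package can be
exercised against a known truth: pedigrees are built under explicit
mating policies whose inbreeding trajectories are textbook results, and
genotypes are gene-dropped along those pedigrees marker by marker so the
true autozygous (founder-allele-sharing) segments of every individual are
known exactly.

Model choices (deliberately simple, analytically checkable):

* founder haplotypes in linkage equilibrium, allele frequencies drawn
  from a configurable spectrum;
* recombination by Haldane's model — crossover counts Poisson in the map
  length, positions uniform, no interference;
* physical positions derived from genetic positions at a constant cM/Mb
  rate, so length thresholds agree between simulation and analysis;
* genotyping error as a symmetric state flip (homozygote -> heterozygote,
  heterozygote -> random homozygote), then missingness at a flat rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genome import GenotypeMatrix, MarkerMap
from .pedigree import Pedigree, PedigreeRecord

__all__ = [
    "PedSimConfig", "GenomeSimConfig", "TruthRecord",
    "simulate_pedigree", "simulate_genotypes",
]

POLICIES = ("random", "circular", "full_sib_line", "close_kin")


@dataclass
class PedSimConfig:
    """Multi-generation pedigree simulation settings.

    ``close_kin_prob`` only applies to the ``close_kin`` policy: each
    mating is a full-sib pair with that probability and a random pair
    otherwise (``close_kin`` with probability 0 reproduces ``random``
    draw for draw).  Birth years advance one decade per generation so a
    generation maps onto one 10-year generational interval.
    """

    n_founders: int = 20
    n_generations: int = 3
    progeny_per_mating: int = 2
    mating_policy: str = "random"
    close_kin_prob: float = 0.0
    close_kin_schedule: Optional[list] = None  # per-generation override
    n_matings: Optional[int] = None  # default: n_founders // 2
    seed: int = 0
    base_year: int = 1950

    def __post_init__(self):
        if self.n_founders < 2:
            raise ValueError("need at least two founders")
        if self.n_generations < 1:
            raise ValueError("need at least one generation")
        if self.mating_policy not in POLICIES:
            raise ValueError(f"unknown mating policy {self.mating_policy!r}")
        if self.mating_policy == "full_sib_line" and self.progeny_per_mating < 2:
            raise ValueError("full_sib_line needs progeny_per_mating >= 2")
        if not (0.0 <= self.close_kin_prob <= 1.0):
            raise ValueError("close_kin_prob must be in [0, 1]")
        if self.close_kin_schedule is not None:
            if len(self.close_kin_schedule) != self.n_generations:
                raise ValueError("close_kin_schedule must have one entry per generation")
            if any(not (0.0 <= p <= 1.0) for p in self.close_kin_schedule):
                raise ValueError("schedule probabilities must be in [0, 1]")


def simulate_pedigree(cfg: PedSimConfig) -> Pedigree:
    """Build a pedigree under the configured mating policy."""
    rng = np.random.default_rng(cfg.seed)
    records: list[PedigreeRecord] = []
    females: list[str] = []
    males: list[str] = []
    for k in range(cfg.n_founders):
        sex = "male" if k % 2 == 0 else "female"
        rid = f"F{k}"
        records.append(PedigreeRecord(rid, None, None, cfg.base_year, sex))
        (males if sex == "male" else females).append(rid)

    # family bookkeeping for kin-biased mating: id -> (sire, dam)
    parents_of: dict[str, tuple[str, str]] = {}

    for gen in range(1, cfg.n_generations + 1):
        year = cfg.base_year + 10 * gen
        new_records: list[PedigreeRecord] = []
        if cfg.mating_policy == "full_sib_line":
            matings = [(males[0], females[0])]
        elif cfg.mating_policy == "circular":
            k = min(len(males), len(females))
            matings = [(males[i], females[(i + 1) % k]) for i in range(k)]
        else:  # random / close_kin
            n_mat = cfg.n_matings or max(1, cfg.n_founders // 2)
            kin_prob = cfg.close_kin_prob
            if cfg.close_kin_schedule is not None:
                kin_prob = cfg.close_kin_schedule[gen - 1]
            matings = []
            for _ in range(n_mat):
                sire = males[rng.integers(len(males))]
                # drawn for both policies so close_kin(0) == random, draw for draw
                u = rng.random()
                use_kin = (cfg.mating_policy == "close_kin"
                           and u < kin_prob)
                dam = None
                if use_kin and sire in parents_of:
                    sibs = [f for f in females
                            if parents_of.get(f) == parents_of[sire] and f != sire]
                    if sibs:
                        dam = sibs[int(rng.integers(len(sibs)))]
                if dam is None:
                    dam = females[rng.integers(len(females))]
                matings.append((sire, dam))
        for m_idx, (sire, dam) in enumerate(matings):
            for c in range(cfg.progeny_per_mating):
                rid = f"G{gen}_{m_idx}_{c}"
                sex = "male" if c % 2 == 0 else "female"
                new_records.append(PedigreeRecord(rid, sire, dam, year, sex))
                parents_of[rid] = (sire, dam)
        records.extend(new_records)
        males = [r.id for r in new_records if r.sex == "male"]
        females = [r.id for r in new_records if r.sex == "female"]
        if not males or not females:
            raise ValueError("a generation lost one sex; increase progeny_per_mating")
    return Pedigree.from_records(records)


@dataclass
class GenomeSimConfig:
    """Genome and genotyping settings for gene-dropped genotypes.

    ``founder_freq`` is ("uniform", lo, hi) or ("beta", a, b) for the
    counted-allele frequency spectrum of founder haplotypes.
    """

    n_chromosomes: int = 31
    chrom_length_cM: float = 100.0
    markers_per_chromosome: int = 1000
    founder_freq: tuple = ("uniform", 0.05, 0.95)
    cm_per_mb: float = 1.0
    genotyping_error: float = 0.001
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.markers_per_chromosome < 2:
            raise ValueError("need at least 2 markers per chromosome")
        for r in (self.genotyping_error, self.missing_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.chrom_length_cM < 0:
            raise ValueError("negative chromosome length")


@dataclass
class TruthRecord:
    """Ground-truth autozygosity for one simulated individual."""

    id: str
    segments: pd.DataFrame   # chrom, start_bp, end_bp, length_mb, length_morgan
    autozygous_fraction: float
    generation: int


def _draw_freqs(cfg: GenomeSimConfig, rng: np.random.Generator, m: int) -> np.ndarray:
    kind, a, b = cfg.founder_freq
    if kind == "uniform":
        return rng.uniform(a, b, size=m)
    if kind == "beta":
        return rng.beta(a, b, size=m)
    raise ValueError(f"unknown founder frequency spectrum {kind!r}")


def _meiosis(rng, hapA, hapB, oriA, oriB, cm_pos, length_cm):
    """One Haldane gamete: mosaic of the two parental haplotypes."""
    n_xo = rng.poisson(length_cm / 100.0)
    start = int(rng.integers(2))
    if n_xo == 0:
        return (hapA, oriA) if start == 0 else (hapB, oriB)
    xo = np.sort(rng.uniform(0.0, length_cm, size=n_xo))
    phase = (start + np.searchsorted(xo, cm_pos, side="right")) % 2
    allele = np.where(phase == 0, hapA, hapB)
    origin = np.where(phase == 0, oriA, oriB)
    return allele, origin


def simulate_genotypes(ped: Pedigree, cfg: GenomeSimConfig
                       ) -> tuple[GenotypeMatrix, dict[str, TruthRecord]]:
    """Gene-drop genotypes along a pedigree, tracking founder-allele origin.

    Returns the (error- and missingness-perturbed) genotype matrix and a
    TruthRecord per individual whose segments mark where the two
    haplotypes descend from the same founder haplotype copy.  The true
    autozygous fraction is measured in genetic length over the mapped
    genome, matching the F_ROH denominator convention.
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(ped)
    m_per = cfg.markers_per_chromosome
    chroms = [f"chr{c + 1}" for c in range(cfg.n_chromosomes)]
    cm_pos = np.linspace(0.0, cfg.chrom_length_cM, m_per)
    bp_pos = np.round(cm_pos / cfg.cm_per_mb * 1e6).astype(np.int64)
    bp_pos = np.maximum.accumulate(bp_pos + np.arange(m_per))  # strictly increasing
    mmap = MarkerMap(
        np.repeat(chroms, m_per),
        np.tile(bp_pos, cfg.n_chromosomes),
        cM=np.tile(cm_pos, cfg.n_chromosomes),
        ids=[f"{c}_s{j}" for c in chroms for j in range(m_per)],
    )

    sp, dp = ped.sire_pos, ped.dam_pos
    geno = np.zeros((n, cfg.n_chromosomes * m_per), dtype=np.int8)
    truth_masks = np.zeros((n, cfg.n_chromosomes * m_per), dtype=bool)

    for c_idx, chrom in enumerate(chroms):
        freqs = _draw_freqs(cfg, rng, m_per)
        hap = np.zeros((n, 2, m_per), dtype=np.int8)
        ori = np.zeros((n, 2, m_per), dtype=np.int64)
        for i in range(n):
            s, d = sp[i], dp[i]
            for side, par in ((0, s), (1, d)):
                if par < 0:
                    hap[i, side] = (rng.random(m_per) < freqs).astype(np.int8)
                    ori[i, side] = 2 * i + side  # unique label per (individual, side)
                else:
                    a, o = _meiosis(rng, hap[par, 0], hap[par, 1],
                                    ori[par, 0], ori[par, 1],
                                    cm_pos, cfg.chrom_length_cM)
                    hap[i, side] = a
                    ori[i, side] = o
        sl = slice(c_idx * m_per, (c_idx + 1) * m_per)
        geno[:, sl] = hap[:, 0, :] + hap[:, 1, :]
        truth_masks[:, sl] = ori[:, 0, :] == ori[:, 1, :]

    # genotyping error: hom -> het, het -> random hom
    if cfg.genotyping_error > 0:
        err = rng.random(geno.shape) < cfg.genotyping_error
        flip_to = rng.integers(0, 2, size=geno.shape).astype(np.int8) * 2
        was_het = geno == 1
        geno = np.where(err & ~was_het, np.int8(1), geno)
        geno = np.where(err & was_het, flip_to, geno).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(geno.shape) < cfg.missing_rate
        geno = np.where(miss, np.int8(-1), geno).astype(np.int8)

    gm = GenotypeMatrix(ped.ids, geno, mmap)
    truth = _truth_records(ped, truth_masks, mmap, cfg)
    return gm, truth


def _truth_records(ped: Pedigree, masks: np.ndarray, mmap: MarkerMap,
                   cfg: GenomeSimConfig) -> dict[str, TruthRecord]:
    total_morgan = mmap.genome_length_morgan
    bp = mmap.table["bp"].to_numpy()
    cm = mmap.table["cM"].to_numpy()
    gens = _generation_index(ped)
    out = {}
    for i, iid in enumerate(ped.ids):
        rows = []
        covered = 0.0
        for chrom in mmap.chromosomes:
            sl = mmap.chrom_slice(chrom)
            a = masks[i, sl]
            if not a.any():
                continue
            edges = np.diff(a.astype(np.int8))
            starts = list(np.flatnonzero(edges == 1) + 1)
            ends = list(np.flatnonzero(edges == -1))
            if a[0]:
                starts.insert(0, 0)
            if a[-1]:
                ends.append(len(a) - 1)
            for s_, e_ in zip(starts, ends):
                gs, ge = sl.start + s_, sl.start + e_
                morgan = (cm[ge] - cm[gs]) / 100.0
                rows.append((chrom, int(bp[gs]), int(bp[ge]),
                             (bp[ge] - bp[gs]) / 1e6, morgan))
                covered += morgan
        seg = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                          "length_mb", "length_morgan"])
        frac = covered / total_morgan if total_morgan > 0 else 0.0
        out[iid] = TruthRecord(iid, seg, frac, gens[i])
    return out


def _generation_index(ped: Pedigree) -> np.ndarray:
    g = np.zeros(len(ped), dtype=np.int64)
    for i in range(len(ped)):
        ps = [p for p in (ped.sire_pos[i], ped.dam_pos[i]) if p >= 0]
        g[i] = 1 + max((g[p] for p in ps), default=-1)
    return g


def truth_fractions(truth: dict[str, TruthRecord]) -> pd.Series:
    """Per-individual true autozygous genome fraction."""
    return pd.Series({k: v.autozygous_fraction for k, v in truth.items()},
                     name="true_autozygosity")
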