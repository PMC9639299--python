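"""Runs of homozygosity: detection, F_ROH, and the Fisher length partition.

Two callers are provided:

* :func:`detect_roh_rule` — a deterministic scanner for maximal runs of
  homozygous calls, with configurable tolerance for heterozygous and
  missing calls, marker-count and physical-length minima, and a maximum
  inter-marker gap;
* :func:`detect_roh_hmm` — a two-state hidden-state model (autozygous /
  non-autozygous) decoded by Viterbi.  Transition probabilities follow an
  exponential segment-length model at a configurable rate per Morgan;
  emissions use the per-marker allele frequency and a genotyping-error
  channel (homozygote -> heterozygote, heterozygote -> random homozygote,
  each with the error probability).

F_ROH is the fraction of the mapped genome covered by retained segments.
The Fisher rule — an IBD segment born g generations ago has expected
length 1/(2g) Morgans — stratifies F_ROH into the generational series
F_ROH(2G) .. F_ROH(20G) by keeping only segments at least that long.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenotypeMatrix

SEGMENT_COLUMNS = ["individual", "chrom", "start_bp", "end_bp",
                   "n_markers", "length_mb", "length_morgan"]


def _empty_segments() -> pd.DataFrame:
    return pd.DataFrame(columns=SEGMENT_COLUMNS)


def segments_frame(rows: list) -> pd.DataFrame:
    if not rows:
        return _empty_segments()
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


# ---------------------------------------------------------------------------
# rule-based scanner
# ---------------------------------------------------------------------------

@dataclass
class RuleParams:
    """Thresholds for the rule-based scanner.

    ``miss_allow_per`` grants one missing call per that many homozygous
    calls inside a run (missing calls never terminate a run by themselves
    and are excluded from the marker count).
    """

    min_markers: int = 30
    min_length_mb: float = 1.0
    het_allow: int = 0
    miss_allow_per: int = 50
    max_gap_mb: float = 1.0


def detect_roh_rule(gm: GenotypeMatrix, params: RuleParams | None = None) -> pd.DataFrame:
    """Scan every individual x chromosome for homozygous runs.

    Boundaries sit on the first and last homozygous marker of a run
    (1-based inclusive bp).  Greedy left-to-right extension: a run closes
    when the heterozygote allowance is exhausted, the missing allowance is
    exceeded, or the inter-marker gap exceeds ``max_gap_mb``.
    """
    params = params or RuleParams()
    tab = gm.mmap.table
    bp_all = tab["bp"].to_numpy()
    cm_all = tab["cM"].to_numpy()
    rows = []
    for chrom in gm.mmap.chromosomes:
        sl = gm.mmap.chrom_slice(chrom)
        bp = bp_all[sl]
        cm = cm_all[sl]
        for k, iid in enumerate(gm.ids):
            g = gm.geno[k, sl]
            rows.extend(_scan_one(iid, chrom, g, bp, cm, params))
    return segments_frame(rows)


def _scan_one(iid, chrom, g, bp, cm, params: RuleParams) -> list:
    out = []
    m = len(g)
    i = 0
    max_gap = params.max_gap_mb * 1e6
    while i < m:
        # find the first homozygous call
        while i < m and not (g[i] == 0 or g[i] == 2):
            i += 1
        if i == m:
            break
        hom_idx = [i]
        het_used = 0
        miss_used = 0
        j = i + 1
        while j < m:
            if bp[j] - bp[j - 1] > max_gap:
                break
            if g[j] == 1:
                if het_used < params.het_allow:
                    het_used += 1
                    j += 1
                    continue
                break
            if g[j] < 0:
                if miss_used + 1 > max(1, len(hom_idx) // params.miss_allow_per):
                    break
                miss_used += 1
                j += 1
                continue
            hom_idx.append(j)
            j += 1
        first, last = hom_idx[0], hom_idx[-1]
        n_markers = sum(1 for t in range(first, last + 1) if g[t] >= 0)
        length_mb = (bp[last] - bp[first]) / 1e6
        if n_markers >= params.min_markers and length_mb >= params.min_length_mb:
            out.append((iid, chrom, int(bp[first]), int(bp[last]), int(n_markers),
                        float(length_mb), float((cm[last] - cm[first]) / 100.0)))
        i = max(j, last + 1)
    return out


# ---------------------------------------------------------------------------
# two-state hidden-state caller
# ---------------------------------------------------------------------------

@dataclass
class HMMParams:
    """Two-state autozygosity model parameters.

    ``error`` is the per-genotype error probability (default 0.001);
    ``rate`` is the segment-length exponential rate per Morgan (default
    12, i.e. expected segments of ~1/12 Morgan); ``mix`` the prior
    autozygosity weight; ``min_length_mb`` the emission threshold for
    reported segments.
    """

    error: float = 0.001
    rate: float = 12.0
    mix: float = 0.01
    min_length_mb: float = 1.0
    ind_block: int = 128


def _emission_logs(g_block: np.ndarray, p: np.ndarray, err: float) -> np.ndarray:
    """log P(obs | state) for a block of individuals; shape (n, m, 2).

    State 0 = autozygous, 1 = non-autozygous.  ``p`` is the counted-allele
    frequency; monomorphic or all-missing markers emit uninformatively.
    """
    p = np.where(np.isfinite(p), np.clip(p, 1e-6, 1 - 1e-6), 0.5)
    het_a = err
    hom2_a = (1 - err) * p
    hom0_a = (1 - err) * (1 - p)
    het_hwe = 2 * p * (1 - p)
    het_n = het_hwe * (1 - err) + (1 - het_hwe) * err
    hom2_n = p ** 2 * (1 - err) + het_hwe * err / 2
    hom0_n = (1 - p) ** 2 * (1 - err) + het_hwe * err / 2
    n, m = g_block.shape
    B = np.ones((n, m, 2))
    for code, pa, pn in ((0, hom0_a, hom0_n), (1, het_a * np.ones_like(p), het_n),
                         (2, hom2_a, hom2_n)):
        mask = g_block == code
        B[:, :, 0] = np.where(mask, pa[None, :], B[:, :, 0])
        B[:, :, 1] = np.where(mask, pn[None, :], B[:, :, 1])
    return np.log(np.maximum(B, 1e-300))


def detect_roh_hmm(gm: GenotypeMatrix, params: HMMParams | None = None) -> pd.DataFrame:
    """Most-probable autozygous segments under the two-state model.

    Viterbi-decodes each individual x chromosome; contiguous autozygous
    stretches spanning at least ``min_length_mb`` are reported with
    boundaries at their first/last marker.
    """
    params = params or HMMParams()
    tab = gm.mmap.table
    bp_all = tab["bp"].to_numpy()
    cm_all = tab["cM"].to_numpy()
    freq = gm.allele_freq
    rows = []
    for chrom in gm.mmap.chromosomes:
        sl = gm.mmap.chrom_slice(chrom)
        bp = bp_all[sl]
        cm = cm_all[sl]
        p = freq[sl]
        m = len(bp)
        d_morgan = np.diff(cm) / 100.0
        stay = np.exp(-params.rate * np.maximum(d_morgan, 1e-9))
        move = 1.0 - stay
        rho = params.mix
        # logT[j, s_from, s_to] for the transition into marker j+1
        logT = np.log(np.maximum(np.stack([
            np.stack([stay + move * rho, move * (1 - rho)], axis=-1),
            np.stack([move * rho, stay + move * (1 - rho)], axis=-1),
        ], axis=1), 1e-300))
        log_init = np.log(np.array([rho, 1.0 - rho]))
        for lo in range(0, gm.n_individuals, params.ind_block):
            hi = min(lo + params.ind_block, gm.n_individuals)
            g_block = gm.geno[lo:hi, sl]
            logB = _emission_logs(g_block, p, params.error)
            paths = _viterbi_batch(logB, logT, log_init)
            for k in range(hi - lo):
                rows.extend(_segments_from_path(
                    gm.ids[lo + k], chrom, paths[k], g_block[k], bp, cm,
                    params.min_length_mb))
    return segments_frame(rows)


def _viterbi_batch(logB: np.ndarray, logT: np.ndarray,
                   log_init: np.ndarray) -> np.ndarray:
    """Vectorised 2-state Viterbi over a block of sequences.

    logB: (n, m, 2); logT: (m-1, 2, 2); returns state paths (n, m) int8.
    """
    n, m, _ = logB.shape
    back = np.zeros((m, n, 2), dtype=np.int8)
    delta = log_init[None, :] + logB[:, 0, :]
    for j in range(1, m):
        # cand[s_from, :, s_to]
        cand0 = delta[:, 0][:, None] + logT[j - 1, 0, :][None, :]
        cand1 = delta[:, 1][:, None] + logT[j - 1, 1, :][None, :]
        take1 = cand1 > cand0
        best = np.where(take1, cand1, cand0)
        back[j] = take1.astype(np.int8)
        delta = best + logB[:, j, :]
    paths = np.zeros((n, m), dtype=np.int8)
    paths[:, -1] = np.argmax(delta, axis=1)
    for j in range(m - 1, 0, -1):
        paths[:, j - 1] = back[j][np.arange(n), paths[:, j]]
    return paths


def _segments_from_path(iid, chrom, path, g, bp, cm, min_length_mb) -> list:
    out = []
    auto = path == 0
    if not auto.any():
        return out
    edges = np.diff(auto.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if auto[0]:
        starts.insert(0, 0)
    if auto[-1]:
        ends.append(len(auto) - 1)
    for a, b in zip(starts, ends):
        length_mb = (bp[b] - bp[a]) / 1e6
        if length_mb < min_length_mb:
            continue
        n_markers = int((g[a:b + 1] >= 0).sum())
        out.append((iid, chrom, int(bp[a]), int(bp[b]), n_markers,
                    float(length_mb), float((cm[b] - cm[a]) / 100.0)))
    return out


# ---------------------------------------------------------------------------
# F_ROH and the Fisher generational partition
# ---------------------------------------------------------------------------

def f_roh(segments: pd.DataFrame, genome_length_mb: float,
          min_length_mb: float = 1.0, ids=None) -> pd.Series:
    """Fraction of the mapped genome covered by ROH, per individual.

    Segments shorter than ``min_length_mb`` are dropped; overlapping
    segments for one individual raise (they indicate an upstream bug).
    ``ids`` fixes the output index (individuals without segments get 0).
    """
    if genome_length_mb <= 0:
        raise ValueError("genome_length_mb must be positive")
    seg = segments[segments["length_mb"] >= min_length_mb]
    _check_overlaps(seg)
    total = seg.groupby("individual")["length_mb"].sum() / genome_length_mb
    if ids is not None:
        total = total.reindex(ids, fill_value=0.0)
    return total.rename("F_ROH")


def _check_overlaps(seg: pd.DataFrame) -> None:
    for (_, _), grp in seg.groupby(["individual", "chrom"]):
        s = grp.sort_values("start_bp")
        prev_end = -1
        for _, r in s.iterrows():
            if r["start_bp"] <= prev_end:
                raise ValueError(
                    f"overlapping ROH segments for {r['individual']} on {r['chrom']}")
            prev_end = r["end_bp"]


def fisher_threshold(g: int, cm_per_mb: float = 1.0) -> float:
    """Minimum segment length (Mb) for an inbreeding event g generations back.

    The expected IBD-segment length is 1/(2g) Morgans; at ``cm_per_mb``
    centimorgans per megabase that is 100/(2g)/cm_per_mb Mb.  Strictly
    decreasing in g.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    if cm_per_mb <= 0:
        raise ValueError("cm_per_mb must be positive")
    return 100.0 / (2.0 * g) / cm_per_mb


def fisher_threshold_display(g: int, cm_per_mb: float = 1.0) -> float:
    """The threshold truncated to one decimal (display convention)."""
    x = fisher_threshold(g, cm_per_mb)
    return math.floor(x * 10 + 1e-9) / 10.0


def generational_partition(segments: pd.DataFrame, genome_length_mb: float,
                           g_range=range(2, 21), ids=None) -> pd.DataFrame:
    """Length-stratified F_ROH: one column per generation horizon g.

    Column g keeps only segments of genetic length >= 1/(2g) Morgans, so
    the series is non-decreasing in g and bounded by the unrestricted
    F_ROH.  Segments must carry ``length_morgan``.
    """
    cols = {}
    morgan = segments["length_morgan"].to_numpy() if len(segments) else np.array([])
    for g in g_range:
        thr = 1.0 / (2.0 * g)
        keep = segments[morgan >= thr - 1e-12] if len(segments) else segments
        cols[g] = f_roh(keep, genome_length_mb, min_length_mb=0.0, ids=ids)
    out = pd.DataFrame(cols)
    if ids is not None:
        out = out.reindex(ids, fill_value=0.0)
    return out.astype(float).fillna(0.0)
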