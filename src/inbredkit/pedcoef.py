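"""Pedigree-based inbreeding coefficients and gene-origin statistics.

Two computational routes coexist, mirroring long-standing practice in
studbook analysis software:

* deterministic recursions — the tabular (additive relationship) method
  for Wright's classical F and its depth-truncated variants F3/F6/F9,
  Ballou's ancestral-inbreeding recursion, and the gene-origin statistics
  fe (effective founders) and fa (effective ancestors, Boichard's
  marginal-contribution algorithm);
* stochastic gene dropping — uniquely labelled founder alleles are
  transmitted down the pedigree many times; per-replicate identity of the
  two arriving labels gives Monte-Carlo estimates of F, Ballou's Fa, the
  Kalinowski split (Fa_Kal + Fnew_Kal = F, exact per replicate set), the
  ancestral history coefficient AHC, and founder-partial coefficients
  F_ij with sum_j F_ij = F exact.

Each transmitted allele copy carries a counter of IBD events experienced
along its path: when a parent is autozygous in a replicate, every allele
it transmits in that replicate has its counter incremented.  An
individual's own autozygosity therefore counts toward the copies it
passes on, never toward its own "ancestral" status.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "GeneDropConfig", "GeneDropResult",
    "relationship_matrix", "classical_F", "F_at_depth", "ballou_recursive",
    "gene_drop", "kalinowski_decomposition", "partial_inbreeding",
    "founder_contributions", "effective_founders", "effective_ancestors",
    "ancestor_contributions",
]


# ---------------------------------------------------------------------------
# deterministic coefficients
# ---------------------------------------------------------------------------

def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Additive (numerator) relationship matrix A by the tabular method.

    A[i, i] = 1 + F_i and A[i, j] twice the kinship between i and j.
    Dense; intended for pedigrees up to a few thousand individuals.
    """
    n = len(ped)
    A = np.zeros((n, n))
    sp, dp = ped.sire_pos, ped.dam_pos
    for i in range(n):
        s, d = sp[i], dp[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
        if i:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
    return A


def classical_F(ped: Pedigree) -> pd.Series:
    """Wright's inbreeding coefficient for every individual (tabular method)."""
    A = relationship_matrix(ped)
    return pd.Series(np.diag(A) - 1.0, index=ped.ids, name="F")


def F_at_depth(ped: Pedigree, g: int, ids: Optional[Sequence[str]] = None) -> pd.Series:
    """Classical F restricted to the ancestry traced ``g`` generations deep.

    For each individual the ancestor-restricted pedigree is cut at depth
    ``g`` (depth-g ancestors become founders) and F recomputed; loops that
    close beyond the horizon contribute nothing.  Non-decreasing in g.
    """
    ids = list(ids) if ids is not None else ped.ids
    out = {}
    for i in ids:
        sub = ped.truncate_to_depth(i, g)
        out[i] = float(classical_F(sub)[i])
    return pd.Series(out, name=f"F{g}")


def ballou_recursive(ped: Pedigree) -> pd.Series:
    """Ballou's ancestral inbreeding by its standard recursion.

    Fa(x) = 1/2 * sum over known parents p of [Fa(p) + (1 - Fa(p)) F(p)];
    a missing parent contributes zero.  The recursion treats the parental
    events as independent, so on pedigrees whose inbreeding loops overlap
    it deviates slightly from the gene-drop estimate (which is exact in
    expectation); both routes are exposed on purpose.
    """
    F = classical_F(ped).to_numpy()
    n = len(ped)
    fa = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for p in (ped.sire_pos[i], ped.dam_pos[i]):
            if p >= 0:
                acc += fa[p] + (1.0 - fa[p]) * F[p]
        fa[i] = 0.5 * acc
    return pd.Series(fa, index=ped.ids, name="Fa_Bal")


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

@dataclass
class GeneDropConfig:
    """Settings for Monte-Carlo gene dropping.

    ``n_replicates`` defaults to 100,000 independent drops; ``chunk``
    bounds memory by processing replicates in blocks (part of the
    reproducibility contract: same seed + same chunk -> identical draws).
    """

    n_replicates: int = 100_000
    seed: int = 1234
    chunk: int = 25_000
    track_founder_origin: bool = True

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class GeneDropResult:
    """Monte-Carlo coefficient estimates, indexed by individual id."""

    F: pd.Series
    Fa_Bal: pd.Series
    Fa_Kal: pd.Series
    Fnew_Kal: pd.Series
    AHC: pd.Series
    F_ij: pd.DataFrame  # long format: id, founder, value (autozygosity share)
    n_replicates: int
    seed: int

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame({
            "F_drop": self.F, "Fa_Bal_drop": self.Fa_Bal,
            "Fa_Kal": self.Fa_Kal, "Fnew_Kal": self.Fnew_Kal, "AHC": self.AHC,
        })


def gene_drop(ped: Pedigree, cfg: Optional[GeneDropConfig] = None) -> GeneDropResult:
    """Drop uniquely labelled founder alleles down the pedigree.

    Per replicate every founder receives two unique labels; each
    non-founder samples one allele from each parent's pair.  An individual
    is autozygous when its two labels coincide.  A transmitted copy's IBD
    counter is the parent's counter for that copy plus one if the parent
    itself is autozygous in the replicate.

    Estimators (averaged over replicates, and over the two alleles where
    an "arriving allele" is involved):

    * F: P(autozygous)
    * Fa_Bal: P(arriving allele counter >= 1)
    * Fa_Kal: P(autozygous and arriving counter >= 1)
    * Fnew_Kal: P(autozygous and arriving counter == 0)
    * AHC: E[arriving counter + 1{autozygous}]
    * F_ij: P(autozygous with the shared allele originating in founder j)

    The identities Fa_Kal + Fnew_Kal = F and sum_j F_ij = F hold exactly
    on the realised replicates, not just in expectation.
    """
    cfg = cfg or GeneDropConfig()
    n = len(ped)
    sp, dp = ped.sire_pos, ped.dam_pos
    founder_mask = (sp < 0) & (dp < 0)
    founder_pos = np.flatnonzero(founder_mask)
    f_index = np.full(n, -1, dtype=np.int64)
    f_index[founder_pos] = np.arange(len(founder_pos))
    nf = len(founder_pos)
    # label "halves": label // 2 identifies the source.  Halves < nf are real
    # founders; halves >= nf are per-slot pseudo-founders standing in for a
    # single unknown parent of a non-founder record.
    n_half = nf + 2 * n

    rng = np.random.default_rng(cfg.seed)
    auto_sum = np.zeros(n)
    fabal_sum = np.zeros(n)
    fakal_sum = np.zeros(n)
    fnew_sum = np.zeros(n)
    ahc_sum = np.zeros(n)
    fij_sum = np.zeros((n, n_half))

    done = 0
    while done < cfg.n_replicates:
        m = min(cfg.chunk, cfg.n_replicates - done)
        labels = np.zeros((n, 2, m), dtype=np.int64)
        counts = np.zeros((n, 2, m), dtype=np.int32)
        auto = np.zeros((n, m), dtype=bool)
        for i in range(n):
            if founder_mask[i]:
                labels[i, 0] = 2 * f_index[i]
                labels[i, 1] = 2 * f_index[i] + 1
                continue
            for side, par in ((0, sp[i]), (1, dp[i])):
                if par < 0:
                    labels[i, side] = 2 * (nf + 2 * i + side)
                else:
                    bits = rng.integers(0, 2, size=m)
                    labels[i, side] = np.where(bits == 1, labels[par, 1], labels[par, 0])
                    counts[i, side] = (
                        np.where(bits == 1, counts[par, 1], counts[par, 0])
                        + auto[par]
                    )
            auto[i] = labels[i, 0] == labels[i, 1]

        auto_sum += auto.sum(axis=1)
        anc = counts >= 1
        fabal_sum += anc.sum(axis=(1, 2)) / 2.0
        fakal_sum += (anc & auto[:, None, :]).sum(axis=(1, 2)) / 2.0
        fnew_sum += (~anc & auto[:, None, :]).sum(axis=(1, 2)) / 2.0
        ahc_sum += counts.sum(axis=(1, 2)) / 2.0 + auto.sum(axis=1)
        if cfg.track_founder_origin:
            for i in range(n):
                if founder_mask[i]:
                    continue
                hit = labels[i, 0, auto[i]] // 2
                if hit.size:
                    fij_sum[i] += np.bincount(hit, minlength=n_half)
        done += m

    N = float(cfg.n_replicates)
    ids = ped.ids
    res = GeneDropResult(
        F=pd.Series(auto_sum / N, index=ids, name="F_drop"),
        Fa_Bal=pd.Series(fabal_sum / N, index=ids, name="Fa_Bal_drop"),
        Fa_Kal=pd.Series(fakal_sum / N, index=ids, name="Fa_Kal"),
        Fnew_Kal=pd.Series(fnew_sum / N, index=ids, name="Fnew_Kal"),
        AHC=pd.Series(ahc_sum / N, index=ids, name="AHC"),
        F_ij=_fij_long(fij_sum / N, ped, nf, founder_pos),
        n_replicates=cfg.n_replicates,
        seed=cfg.seed,
    )
    return res


def _fij_long(fij: np.ndarray, ped: Pedigree, nf: int,
              founder_pos: np.ndarray) -> pd.DataFrame:
    """Collapse half-label shares to a long (id, founder, value) table."""
    rows = []
    ids = ped.ids
    for i in range(len(ped)):
        nz = np.flatnonzero(fij[i])
        acc: dict[str, float] = {}
        for h in nz:
            if h < nf:
                key = ids[founder_pos[h]]
            else:
                slot = h - nf
                ind, side = divmod(slot, 2)
                key = f"{ids[ind]}:{'sire' if side == 0 else 'dam'}_unknown"
            acc[key] = acc.get(key, 0.0) + fij[i, h]
        for k, v in acc.items():
            rows.append((ids[i], k, v))
    return pd.DataFrame(rows, columns=["id", "founder", "value"])


def kalinowski_decomposition(ped: Pedigree,
                             cfg: Optional[GeneDropConfig] = None
                             ) -> tuple[pd.Series, pd.Series]:
    """(Fa_Kal, Fnew_Kal) per individual; their sum equals the gene-drop F."""
    res = gene_drop(ped, cfg)
    return res.Fa_Kal, res.Fnew_Kal


def partial_inbreeding(ped: Pedigree,
                       cfg: Optional[GeneDropConfig] = None) -> pd.DataFrame:
    """Founder-partial inbreeding F_ij, long format (id, founder, value)."""
    return gene_drop(ped, cfg).F_ij


# ---------------------------------------------------------------------------
# gene-origin statistics (fe, fa)
# ---------------------------------------------------------------------------

def _upward_flow(ped: Pedigree, reference: Sequence[str],
                 blocked: Optional[np.ndarray] = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Gene-origin weight flowing from the reference set up the pedigree.

    Each reference individual starts with weight 1/N; every individual
    passes half of its weight to each known parent.  ``blocked``
    individuals absorb incoming weight instead of passing it upward (used
    by the marginal-contribution iteration).  Returns ``(received,
    total)``: weight received from descendants, and received plus the
    individual's own initial weight.  Weight reaching an unknown-parent
    slot is lost to an implicit pseudo-founder.
    """
    n = len(ped)
    ref_pos = [ped.position(r) for r in reference]
    init = np.zeros(n)
    for p in ref_pos:
        init[p] += 1.0 / len(ref_pos)
    w = init.copy()
    received = np.zeros(n)
    for i in range(n - 1, -1, -1):
        received[i] = w[i] - init[i]
        if blocked is not None and blocked[i]:
            continue
        for p in (ped.sire_pos[i], ped.dam_pos[i]):
            if p >= 0:
                w[p] += 0.5 * w[i]
    return received, received + init


def _escape_prob(ped: Pedigree, blocked: np.ndarray,
                 blocked_slots: Optional[set] = None) -> np.ndarray:
    """P(a gene lineage continuing upward from i terminates unexplained).

    A lineage terminates at a founder or unknown-parent slot; it is
    explained when it passes through a blocked (already selected)
    individual or ends in a blocked pseudo-founder slot.  esc = 1 at
    unblocked founders, 0 at blocked individuals.
    """
    blocked_slots = blocked_slots or set()
    n = len(ped)
    esc = np.ones(n)
    for i in range(n):
        if blocked[i]:
            esc[i] = 0.0
            continue
        s, d = ped.sire_pos[i], ped.dam_pos[i]
        if s < 0 and d < 0:
            esc[i] = 1.0
        else:
            acc = 0.0
            for side, p in ((0, s), (1, d)):
                if p >= 0:
                    acc += 0.5 * esc[p]
                elif (i, side) not in blocked_slots:
                    acc += 0.5
            esc[i] = acc
    return esc


def founder_contributions(ped: Pedigree, reference: Sequence[str]) -> pd.Series:
    """Mean expected founder contribution q_k to the reference set.

    Unknown single parents contribute through per-slot pseudo-founders so
    the contributions always sum to one.
    """
    if not reference:
        raise ValueError("reference set is empty")
    _, total = _upward_flow(ped, reference)
    founder_mask = (ped.sire_pos < 0) & (ped.dam_pos < 0)
    out = {}
    for i in np.flatnonzero(founder_mask):
        out[ped.ids[i]] = total[i]
    # mass lost through unknown single parents of non-founder records
    for i in range(len(ped)):
        if founder_mask[i]:
            continue
        for side, p in (("sire", ped.sire_pos[i]), ("dam", ped.dam_pos[i])):
            if p < 0:
                out[f"{ped.ids[i]}:{side}_unknown"] = 0.5 * float(total[i])
    s = pd.Series(out, name="q")
    return s[s > 0]


def effective_founders(ped: Pedigree, reference: Sequence[str]) -> float:
    """fe = 1 / sum_k q_k^2 over mean founder contributions."""
    q = founder_contributions(ped, reference)
    return float(1.0 / np.sum(q.to_numpy() ** 2))


def ancestor_contributions(ped: Pedigree, reference: Sequence[str],
                           tol: float = 1e-9,
                           max_ancestors: Optional[int] = None) -> pd.Series:
    """Marginal gene-origin contributions p_k, most important ancestor first.

    Boichard-style iteration: the marginal contribution of a candidate is
    the expected fraction of reference gene lineages that pass through it
    while avoiding every previously selected ancestor (whether the
    selected ancestor sits between the candidate and the reference, or
    above the candidate on the lineage's way to a founder).  It is
    computed as (weight received from descendants under blocking) x
    (upward escape probability); founders additionally count their own
    weight when they belong to the reference.  Ties break by pedigree
    order.  Iteration stops when the largest marginal contribution falls
    below ``tol`` or ``max_ancestors`` is reached.
    """
    if not reference:
        raise ValueError("reference set is empty")
    n = len(ped)
    founder_mask = (ped.sire_pos < 0) & (ped.dam_pos < 0)
    slots = [(i, side) for i in np.flatnonzero(~founder_mask)
             for side, p in ((0, ped.sire_pos[i]), (1, ped.dam_pos[i])) if p < 0]
    blocked = np.zeros(n, dtype=bool)
    blocked_slots: set = set()
    out: dict[str, float] = {}
    cap = max_ancestors if max_ancestors is not None else n + len(slots)
    for _ in range(cap):
        received, total = _upward_flow(ped, reference, blocked)
        esc = _escape_prob(ped, blocked, blocked_slots)
        marginal = np.where(founder_mask, total, received) * esc
        marginal[blocked] = -np.inf
        k = int(np.argmax(marginal))  # first max: pedigree order
        best, best_key = float(marginal[k]), ped.ids[k]
        best_slot = None
        # unknown-parent slots compete as pseudo-ancestors so that fe and
        # fa partition the same gene-origin mass
        for (i, side) in slots:
            if (i, side) in blocked_slots or blocked[i]:
                continue
            m_slot = 0.5 * float(total[i])
            if m_slot > best + 1e-15:
                best, best_slot = m_slot, (i, side)
                best_key = f"{ped.ids[i]}:{'sire' if side == 0 else 'dam'}_unknown"
        if best < tol:
            break
        out[best_key] = best
        if best_slot is None:
            blocked[k] = True
        else:
            blocked_slots.add(best_slot)
    return pd.Series(out, name="p")


def effective_ancestors(ped: Pedigree, reference: Sequence[str],
                        tol: float = 1e-9,
                        max_ancestors: Optional[int] = None) -> float:
    """fa = 1 / sum_k p_k^2 over Boichard marginal contributions."""
    p = ancestor_contributions(ped, reference, tol=tol, max_ancestors=max_ancestors)
    return float(1.0 / np.sum(p.to_numpy() ** 2))


def coefficient_table(ped: Pedigree, depths: Iterable[int] = (3, 6, 9),
                      drop_cfg: Optional[GeneDropConfig] = None) -> pd.DataFrame:
    """All eight pedigree coefficients as one individuals x estimators table.

    Columns: F3/F6/F9 (per ``depths``), F, Fa_Bal (recursive), plus the
    gene-drop estimates Fa_Kal, Fnew_Kal and AHC.
    """
    cols = {}
    for g in sorted(depths):
        cols[f"F{g}"] = F_at_depth(ped, g)
    cols["F"] = classical_F(ped)
    cols["Fa_Bal"] = ballou_recursive(ped)
    res = gene_drop(ped, drop_cfg)
    cols["Fa_Kal"] = res.Fa_Kal
    cols["Fnew_Kal"] = res.Fnew_Kal
    cols["AHC"] = res.AHC
    return pd.DataFrame(cols)
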