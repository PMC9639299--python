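"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the library code:
Wright's path-counting formula instead of the tabular method, exhaustive
enumeration of every gene-drop outcome instead of Monte Carlo, and a
direct triple-loop evaluation of the correlation discard rule.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from inbredkit.pedigree import Pedigree, PedigreeRecord


# ---------------------------------------------------------------------------
# Wright path counting
# ---------------------------------------------------------------------------

def _paths_up(parents: dict, x: str) -> list[tuple[str, ...]]:
    """All ancestor paths starting at x (x included), ending anywhere."""
    out = [(x,)]
    s, d = parents[x]
    for p in (s, d):
        if p is not None:
            out.extend((x,) + q for q in _paths_up(parents, p))
    return out


def wright_F(ped: Pedigree) -> dict[str, float]:
    """Inbreeding by summing (1/2)^(n+n'+1) (1+F_A) over disjoint path pairs."""
    parents = {r.id: (r.sire_id, r.dam_id) for r in ped.records}
    memo: dict[str, float] = {}

    def F(x: str) -> float:
        if x in memo:
            return memo[x]
        s, d = parents[x]
        if s is None or d is None:
            memo[x] = 0.0
            return 0.0
        total = 0.0
        for p1 in _paths_up(parents, s):
            for p2 in _paths_up(parents, d):
                if p1[-1] != p2[-1]:
                    continue
                a = p1[-1]
                if set(p1) & set(p2) != {a}:
                    continue
                n1, n2 = len(p1) - 1, len(p2) - 1
                total += 0.5 ** (n1 + n2 + 1) * (1.0 + F(a))
        memo[x] = total
        return total

    return {r.id: F(r.id) for r in ped.records}


# ---------------------------------------------------------------------------
# exhaustive gene-drop enumeration
# ---------------------------------------------------------------------------

def enumerate_gene_drop(ped: Pedigree) -> dict[str, dict[str, float]]:
    """Exact gene-drop expectations by enumerating every transmission choice.

    Feasible for pedigrees with a handful of non-founders (2 bits per
    individual with two known parents).  Returns, per individual, the
    exact F, Fa_Bal, Fa_Kal, Fnew_Kal, AHC and the founder map F_ij.
    """
    n = len(ped)
    slots = []  # (position, side) needing a transmission bit
    for i in range(n):
        for side, par in ((0, ped.sire_pos[i]), (1, ped.dam_pos[i])):
            if par >= 0:
                slots.append((i, side))
    nf_ids = ped.founders
    nf = len(nf_ids)
    founder_index = {ped.position(f): k for k, f in enumerate(nf_ids)}

    k = len(slots)
    if k > 22:
        raise ValueError("pedigree too deep for exhaustive enumeration")
    m = 2 ** k
    outcome = np.arange(m)
    bit_of_slot = {slot: ((outcome >> b) & 1).astype(bool)
                   for b, slot in enumerate(slots)}

    label = np.zeros((n, 2, m), dtype=np.int64)
    count = np.zeros((n, 2, m), dtype=np.int64)
    auto = np.zeros((n, m), dtype=bool)
    for i in range(n):
        for side, par in ((0, ped.sire_pos[i]), (1, ped.dam_pos[i])):
            if par < 0:
                label[i, side] = (2 * founder_index[i] + side
                                  if i in founder_index
                                  else 2 * (nf + 2 * i + side))
            else:
                b = bit_of_slot[(i, side)]
                label[i, side] = np.where(b, label[par, 1], label[par, 0])
                count[i, side] = np.where(b, count[par, 1], count[par, 0]) + auto[par]
        auto[i] = label[i, 0] == label[i, 1]

    acc = {}
    anc = count >= 1
    for i, r in enumerate(ped.records):
        fij = {f: 0.0 for f in nf_ids}
        hit = label[i, 0, auto[i]] // 2
        hit = hit[hit < nf]
        for h, c in zip(*np.unique(hit, return_counts=True)):
            fij[nf_ids[h]] = c / m
        acc[r.id] = {
            "F": auto[i].mean(),
            "Fa_Bal": anc[i].sum() / (2.0 * m),
            "Fa_Kal": (anc[i] & auto[i][None, :]).sum() / (2.0 * m),
            "Fnew_Kal": (~anc[i] & auto[i][None, :]).sum() / (2.0 * m),
            "AHC": count[i].sum() / (2.0 * m) + auto[i].mean(),
            "F_ij": fij,
        }
    return acc


# ---------------------------------------------------------------------------
# brute-force discard rule
# ---------------------------------------------------------------------------

def brute_force_pcit(corr, rule: str = "any"):
    """Direct evaluation of the epsilon discard rule over all trios."""
    cols = list(corr.columns)
    sig = {frozenset(p): True for p in itertools.combinations(cols, 2)}
    if len(cols) < 3:
        return sig

    def partial(rxy, rxz, ryz):
        return (rxy - rxz * ryz) / math.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))

    for x, y in itertools.combinations(cols, 2):
        verdicts = []
        for z in cols:
            if z in (x, y):
                continue
            rxy, rxz, ryz = corr.loc[x, y], corr.loc[x, z], corr.loc[y, z]
            rs = (rxy, rxz, ryz)
            if any(not np.isfinite(r) for r in rs) or any(abs(r) >= 1 for r in rs):
                continue
            if any(r == 0 for r in rs):
                continue
            pxy = partial(rxy, rxz, ryz)
            pxz = partial(rxz, rxy, ryz)
            pyz = partial(ryz, rxy, rxz)
            eps = (pxy / rxy + pxz / rxz + pyz / ryz) / 3.0
            verdicts.append(abs(rxy) <= abs(eps * rxz) and abs(rxy) <= abs(eps * ryz))
        if verdicts and (any(verdicts) if rule == "any" else all(verdicts)):
            sig[frozenset((x, y))] = False
    return sig


# ---------------------------------------------------------------------------
# random small pedigrees
# ---------------------------------------------------------------------------

def random_pedigree(rng: np.random.Generator, max_size: int = 12) -> Pedigree:
    """A random acyclic pedigree: parents drawn among earlier individuals."""
    n = int(rng.integers(3, max_size + 1))
    n_founders = int(rng.integers(2, max(3, n // 2 + 1)))
    records = [PedigreeRecord(f"I{k}") for k in range(n_founders)]
    for k in range(n_founders, n):
        pool = [r.id for r in records]
        sire = pool[int(rng.integers(len(pool)))]
        dam_choices = [p for p in pool if p != sire]
        dam = dam_choices[int(rng.integers(len(dam_choices)))]
        if rng.random() < 0.15:
            sire = None
        if rng.random() < 0.15:
            dam = None
        records.append(PedigreeRecord(f"I{k}", sire, dam))
    return Pedigree.from_records(records)
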