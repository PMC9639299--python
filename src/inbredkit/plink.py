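"""PLINK text PED/MAP reading and writing.

Dialect: MAP has four whitespace-separated columns (chromosome, marker
id, genetic position in cM, physical position in bp); PED has six leading
columns (family, individual, sire, dam, sex, phenotype) followed by two
allele calls per marker.  Alleles may be A/C/G/T or 1/2; ``0`` encodes a
missing call.  On reading, genotypes are recoded to 0/1/2 counts of the
minor allele per marker (frequency ties keep the allele that sorts last,
which makes write -> read round trips of minor-coded matrices exact).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genome import GenotypeMatrix, MarkerMap
from .pedigree import Pedigree

_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


def read_map(path, cm_per_mb: float = 1.0) -> MarkerMap:
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "id", "cM", "bp"], dtype={"chrom": str})
    cm = df["cM"].to_numpy(dtype=float)
    if np.allclose(cm, 0.0):
        cm = None  # derive from bp
    return MarkerMap(df["chrom"].to_numpy(), df["bp"].to_numpy(), cM=cm,
                     ids=df["id"].tolist(), cm_per_mb=cm_per_mb)


def read_plink(prefix, cm_per_mb: float = 1.0) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read ``prefix.ped`` / ``prefix.map``; returns (genotypes, fam table)."""
    prefix = str(prefix)
    mmap = read_map(prefix + ".map", cm_per_mb=cm_per_mb)
    L = len(mmap)
    ids, fam_rows = [], []
    rows = []
    with open(prefix + ".ped") as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * L:
                raise ValueError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * L} fields, got {len(tok)}")
            fam_rows.append(tok[:6])
            ids.append(tok[1])
            rows.append(tok[6:])
    if not rows:
        raise ValueError(f"{prefix}.ped: no individuals")
    alleles = np.asarray(rows, dtype="U4").reshape(len(rows), L, 2)
    geno = np.full((len(rows), L), -1, dtype=np.int8)
    for j in range(L):
        col = alleles[:, j, :]
        called = (col != "0").all(axis=1)
        obs = col[called].ravel()
        uniq, counts = np.unique(obs, return_counts=True)
        if uniq.size > 2:
            raise ValueError(f"marker {mmap.table['id'][j]}: more than two alleles")
        if uniq.size == 0:
            continue  # all missing; stays -1/0 counts of nothing
        if uniq.size == 1:
            counted = None  # monomorphic: count the absent allele -> all zeros
        else:
            # minor allele; tie -> lexicographically last
            if counts[0] < counts[1] or (counts[0] == counts[1] and uniq[0] > uniq[1]):
                counted = uniq[0]
            else:
                counted = uniq[1]
        if counted is None:
            geno[called, j] = 0
        else:
            geno[called, j] = (col[called] == counted).sum(axis=1)
    fam = pd.DataFrame(fam_rows, columns=["fid", "iid", "sire", "dam", "sex", "pheno"])
    return GenotypeMatrix(ids, geno, mmap), fam


def write_plink(gm: GenotypeMatrix, prefix, ped: Optional[Pedigree] = None) -> None:
    """Write PED/MAP text; counted allele is ``2``, the other ``1``.

    Matrices recoded with :meth:`GenotypeMatrix.to_minor` round-trip
    bit-identically through :func:`read_plink`.
    """
    if gm.n_markers == 0:
        raise ValueError("cannot write PLINK files with an empty marker set")
    prefix = str(prefix)
    Path(prefix).parent.mkdir(parents=True, exist_ok=True)
    tab = gm.mmap.table
    with open(prefix + ".map", "w") as fh:
        for _, r in tab.iterrows():
            fh.write(f"{r['chrom']}\t{r['id']}\t{r['cM']:.6f}\t{int(r['bp'])}\n")
    code = {2: "2 2", 1: "1 2", 0: "1 1", -1: "0 0"}
    with open(prefix + ".ped", "w") as fh:
        for k, iid in enumerate(gm.ids):
            sire = dam = "0"
            sex = "0"
            if ped is not None and iid in ped:
                rec = ped.record(iid)
                sire = rec.sire_id or "0"
                dam = rec.dam_id or "0"
                sex = _SEX_OUT.get(rec.sex, "0")
            lead = ["FAM", str(iid), sire, dam, sex, "-9"]
            calls = [code[int(g)] for g in gm.geno[k]]
            fh.write(" ".join(lead + calls) + "\n")
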