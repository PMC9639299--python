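"""End-to-end workflow: simulate -> pedigree coefficients -> genomic
coefficients -> correlation report.

A single YAML config drives four stages; every output is delimited text
plus a JSON run manifest with config snapshot, seeds and SHA-256
checksums, so a re-run with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import grm, pedcoef, roh
from .correlate import pcit_significance, trios_frame
from .genome import GenotypeMatrix
from .pedigree import Pedigree, write_pedigree
from .plink import write_plink
from .simulate import (GenomeSimConfig, PedSimConfig, simulate_genotypes,
                       simulate_pedigree, truth_fractions)

logger = logging.getLogger(__name__)

DEFAULTS = {
    "seed": 0,
    "out": "run_out",
    "depths": [3, 6, 9],
    "pedigree": {},
    "genome": {},
    "gene_drop": {"n_replicates": 100_000},
    "roh": {"method": "hmm"},
    "correlation": {"rule": "any"},
    "interval_years": 10,
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULTS))
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format="%.10g", **kw)
    return path


def run_pipeline(config_path, out_dir: Optional[str] = None,
                 seed: Optional[int] = None) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    cfg = load_config(config_path)
    if seed is not None:
        cfg["seed"] = seed
    out = Path(out_dir or cfg["out"])
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    base_seed = int(cfg["seed"])

    logger.info("stage simulate")
    ped_cfg = PedSimConfig(seed=base_seed, **cfg["pedigree"])
    gen_cfg = GenomeSimConfig(seed=base_seed + 1, **cfg["genome"])
    ped = simulate_pedigree(ped_cfg)
    gm, truth = simulate_genotypes(ped, gen_cfg)
    write_pedigree(ped, out / "pedigree.csv")
    files.append(out / "pedigree.csv")
    write_plink(gm.to_minor(), out / "genotypes", ped=ped)
    files += [out / "genotypes.ped", out / "genotypes.map"]
    tf = truth_fractions(truth)
    files.append(_write(tf.to_frame(), out / "truth_autozygosity.csv",
                        index_label="id"))

    logger.info("stage ped-coeffs")
    drop_cfg = pedcoef.GeneDropConfig(seed=base_seed + 2, **cfg["gene_drop"])
    ped_table = pedcoef.coefficient_table(ped, depths=cfg["depths"],
                                          drop_cfg=drop_cfg)
    files.append(_write(ped_table, out / "pedigree_coefficients.csv",
                        index_label="id"))
    fij = pedcoef.partial_inbreeding(ped, drop_cfg)
    files.append(_write(fij, out / "partial_inbreeding.csv", index=False))

    logger.info("stage gen-coeffs")
    gen_table, segments, partition = genomic_stage(ped, gm, cfg)
    files.append(_write(gen_table, out / "genomic_coefficients.csv",
                        index_label="id"))
    files.append(_write(segments, out / "roh_segments.csv", index=False))
    files.append(_write(partition, out / "froh_partition.csv", index_label="id"))

    logger.info("stage correlate")
    merged = ped_table.join(gen_table, how="left")
    files.append(_write(merged, out / "coefficient_table.csv", index_label="id"))
    res = pcit_significance(merged, rule=cfg["correlation"]["rule"])
    files.append(_write(res.corr, out / "correlations.csv", index_label="var"))
    files.append(_write(res.significant, out / "significance_flags.csv",
                        index_label="var"))
    tf_frame = trios_frame(res)
    files.append(_write(tf_frame, out / "trio_report.csv", index=False))
    curves = partition_correlation_curves(ped_table, partition)
    files.append(_write(curves, out / "partition_correlation_curves.csv",
                        index_label="g"))

    logger.info("stage summary")
    summary = interval_summary(ped, ped_table, fij, width=cfg["interval_years"],
                               drop_cfg=drop_cfg)
    files.append(_write(summary, out / "interval_summary.csv", index_label="interval"))

    manifest = {
        "config": cfg,
        "seeds": {"pedigree": base_seed, "genome": base_seed + 1,
                  "gene_drop": base_seed + 2},
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def genomic_stage(ped: Pedigree, gm: GenotypeMatrix, cfg: dict
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Genomic coefficient table, ROH segments, and the F_ROH partition."""
    method = cfg["roh"].get("method", "hmm")
    if method == "rule":
        seg = roh.detect_roh_rule(gm, roh.RuleParams(
            **{k: v for k, v in cfg["roh"].items() if k != "method"}))
    elif method == "hmm":
        seg = roh.detect_roh_hmm(gm, roh.HMMParams(
            **{k: v for k, v in cfg["roh"].items() if k != "method"}))
    else:
        raise ValueError(f"unknown ROH method {method!r}")
    gl = gm.mmap.genome_length_mb
    frz = roh.f_roh(seg, gl, ids=gm.ids)
    partition = roh.generational_partition(seg, gl, ids=gm.ids)
    A = pedcoef.relationship_matrix(ped)
    genotyped = np.array([ped.position(i) for i in gm.ids])
    table = pd.DataFrame({
        "F_RZ": frz,
        "F_G": grm.f_g(gm),
        "F_H": grm.f_h(A, grm.vanraden_G(gm), genotyped, ped.ids),
        "F_HOM": grm.f_hom(gm),
    })
    for g in (3, 6, 9):
        table[f"F_RZ{g}"] = partition[g]
    return table, seg, partition


def partition_correlation_curves(ped_table: pd.DataFrame,
                                 partition: pd.DataFrame) -> pd.DataFrame:
    """Correlation of each pedigree coefficient with F_ROH(gG), g = 2..20."""
    rows = {}
    common = ped_table.index.intersection(partition.index)
    for g in partition.columns:
        rows[g] = {
            col: ped_table.loc[common, col].corr(partition.loc[common, g])
            for col in ped_table.columns
        }
    return pd.DataFrame(rows).T


def interval_summary(ped: Pedigree, ped_table: pd.DataFrame, fij: pd.DataFrame,
                     width: int = 10,
                     drop_cfg: Optional[pedcoef.GeneDropConfig] = None
                     ) -> pd.DataFrame:
    """Per-generational-interval cohort statistics.

    For each 10-year (by default) birth interval: cohort size, mean F,
    number of contributing founders, fe, fa, fe/fa, mean common-ancestor
    count, and the mean positive founder-partial coefficient.
    """
    bins = ped.generational_intervals(width)
    fij_mean = fij[fij["value"] > 0].groupby("id")["value"].mean()
    rows = {}
    for interval in sorted(bins.dropna().unique()):
        cohort = bins.index[bins == interval].tolist()
        q = pedcoef.founder_contributions(ped, cohort)
        fe = float(1.0 / np.sum(q.to_numpy() ** 2))
        fa = pedcoef.effective_ancestors(ped, cohort)
        mca = float(np.mean([ped.common_ancestors(i) for i in cohort]))
        mfij = float(fij_mean.reindex(cohort).dropna().mean()) if len(fij_mean) else np.nan
        rows[int(interval)] = {
            "n": len(cohort),
            "mean_F": float(ped_table.loc[cohort, "F"].mean()),
            "founders": int((q > 0).sum()),
            "fe": fe,
            "fa": fa,
            "fe_fa": fe / fa,
            "mean_common_ancestors": mca,
            "mean_Fij": mfij,
        }
    return pd.DataFrame(rows).T
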