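"""Pairwise genetic relatedness between data of different omics types.

Data generated from the same individual carry (nearly) identical genotypes
regardless of platform, so a GRM-style standardized genotype product over
shared loci separates same-individual pairs (score near 1) from unrelated
pairs (score near 0).  For data j and k over M shared, non-missing loci:

    score(j, k) = (1/M) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with x the alt-allele dosage and p_i the alt-allele frequency pooled across
the two datasets being compared.  Loci outside the configured MAF band are
excluded from M; missing calls are removed pair-wise per locus.

The module also imports score tables computed by external GRM tools, and
provides a seeded SNP-subsampling benchmark that measures how pair
extraction at a score threshold degrades as fewer loci are used.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_qc import MISSING, LOCUS_COLUMNS, GenotypeMatrix

__all__ = [
    "RelatednessTable",
    "PairBenchmark",
    "compute_relatedness",
    "import_relatedness",
    "classify_pairs",
    "subsample_benchmark",
]

log = logging.getLogger(__name__)

#: Score above which a pair counts as "highly related" (strict inequality).
DEFAULT_THRESHOLD: float = 0.65

#: Recommended minimum number of shared common SNPs for a reliable score.
DEFAULT_MIN_SHARED_SNPS: int = 2000

#: Hard floor below which scores are refused outright.
HARD_FLOOR_SNPS: int = 200

TABLE_COLUMNS = ["data_a", "omics_a", "data_b", "omics_b", "score", "n_snps"]


@dataclass
class RelatednessTable:
    """Long-format table of pairwise relatedness scores.

    Each unordered data pair is stored once, in canonical orientation
    (``(omics_a, data_a) <= (omics_b, data_b)`` lexicographically).  Self
    pairs (same data_id and same omics) are forbidden and ``n_snps >= 1``
    for every row.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"relatedness table missing columns {missing}")
        df = df[TABLE_COLUMNS].copy()
        if len(df):
            if (df["n_snps"] < 1).any():
                raise ValueError("relatedness rows must have n_snps >= 1")
            self_pair = (df["data_a"] == df["data_b"]) & (
                df["omics_a"] == df["omics_b"]
            )
            if self_pair.any():
                raise ValueError("self pairs are not allowed")
            flip = list(
                map(
                    lambda a, oa, b, ob: (oa, a) > (ob, b),
                    df["data_a"], df["omics_a"], df["data_b"], df["omics_b"],
                )
            )
            flip = np.asarray(flip)
            if flip.any():
                fa, foa = df.loc[flip, "data_a"].copy(), df.loc[flip, "omics_a"].copy()
                df.loc[flip, ["data_a", "omics_a"]] = df.loc[
                    flip, ["data_b", "omics_b"]
                ].to_numpy()
                df.loc[flip, "data_b"] = fa.to_numpy()
                df.loc[flip, "omics_b"] = foa.to_numpy()
            dup = df.duplicated(subset=["data_a", "omics_a", "data_b", "omics_b"])
            if dup.any():
                log.warning("dropping %d duplicate pair rows", int(dup.sum()))
                df = df.loc[~dup]
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def concat(cls, tables: Sequence["RelatednessTable"]) -> "RelatednessTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RelatednessTable":
        df = pd.read_csv(path, sep="\t")
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
        bad = df["score"].isna()
        if bad.any():
            log.warning("dropping %d rows with unparseable score", int(bad.sum()))
            df = df.loc[~bad]
        return cls(df)


@dataclass
class PairBenchmark:
    """Confusion counts for pair extraction at a score threshold.

    A true positive is a pair of data from the same individual with score
    above the threshold; a true negative is a different-individual pair
    below it.  Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
    """

    comparison: tuple[str, str]
    n_subsampled: int
    tp: int
    tn: int
    fp: int
    fn: int
    replicate: int = 0

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else math.nan


def _shared_loci(ga: GenotypeMatrix, gb: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Indices into ga.loci / gb.loci of loci shared by (chrom,pos,ref,alt)."""
    la = ga.loci.reset_index(names="_ia")
    lb = gb.loci.reset_index(names="_ib")
    merged = la.merge(lb, on=list(LOCUS_COLUMNS), how="inner")
    return merged["_ia"].to_numpy(), merged["_ib"].to_numpy()


def _pooled_frequencies(calls_a: np.ndarray, calls_b: np.ndarray) -> np.ndarray:
    pooled = np.hstack([calls_a, calls_b])
    nm = pooled != MISSING
    denom = 2.0 * nm.sum(axis=1)
    alt = np.where(nm, pooled, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, alt / denom, np.nan)


def _pair_scores(
    calls_a: np.ndarray, calls_b: np.ndarray, p: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """GRM score and shared-locus count for every cross pair (vectorized)."""
    denom = np.sqrt(2.0 * p * (1.0 - p))
    ma = calls_a != MISSING
    mb = calls_b != MISSING
    za = np.where(ma, (calls_a - 2.0 * p[:, None]) / denom[:, None], 0.0)
    zb = np.where(mb, (calls_b - 2.0 * p[:, None]) / denom[:, None], 0.0)
    num = za.T @ zb
    counts = ma.T.astype(np.float64) @ mb.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(counts > 0, num / counts, np.nan)
    return scores, counts.astype(np.int64)


def compute_relatedness(
    ga: GenotypeMatrix,
    gb: GenotypeMatrix,
    maf_min: float = 0.01,
    min_shared_snps: int = DEFAULT_MIN_SHARED_SNPS,
    hard_floor: int = HARD_FLOOR_SNPS,
) -> RelatednessTable:
    """Score every cross-dataset data pair over shared loci.

    Allele frequencies are pooled over the union of both datasets' samples;
    loci with pooled frequency outside ``[maf_min, 1 - maf_min]`` are
    excluded.  Fewer than ``hard_floor`` usable shared loci is an error;
    fewer than ``min_shared_snps`` triggers a warning (scores become
    unreliable).  Missing calls are removed pair-wise, so each pair's
    ``n_snps`` may be smaller than the shared-locus count.
    """
    ia, ib = _shared_loci(ga, gb)
    calls_a = ga.calls[ia].astype(np.float64)
    calls_b = gb.calls[ib].astype(np.float64)
    calls_a[ga.calls[ia] == MISSING] = MISSING
    calls_b[gb.calls[ib] == MISSING] = MISSING
    p = _pooled_frequencies(ga.calls[ia], gb.calls[ib])
    informative = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if len(ia) and not informative.any():
        raise ValueError(
            f"all {len(ia)} loci shared by {ga.omics_type} and {gb.omics_type} "
            "are monomorphic"
        )
    keep = informative & (p >= maf_min) & (p <= 1.0 - maf_min)
    n_usable = int(keep.sum())
    if n_usable < hard_floor:
        raise ValueError(
            f"only {n_usable} usable shared SNPs between {ga.omics_type} and "
            f"{gb.omics_type} (hard floor {hard_floor})"
        )
    if n_usable < min_shared_snps:
        log.warning(
            "%s vs %s: %d shared SNPs after MAF filter, below the recommended "
            "%d; scores may be unreliable",
            ga.omics_type, gb.omics_type, n_usable, min_shared_snps,
        )
    scores, counts = _pair_scores(calls_a[keep], calls_b[keep], p[keep])

    same_dataset = ga is gb or (
        ga.omics_type == gb.omics_type and ga.data_ids == gb.data_ids
    )
    rows: list[tuple] = []
    for j, da in enumerate(ga.data_ids):
        for k, db in enumerate(gb.data_ids):
            if same_dataset and k <= j:
                continue
            if da == db and ga.omics_type == gb.omics_type:
                continue
            m = counts[j, k]
            if m < 1:
                log.warning(
                    "pair %s/%s vs %s/%s has no shared non-missing loci; dropped",
                    ga.omics_type, da, gb.omics_type, db,
                )
                continue
            rows.append(
                (da, ga.omics_type, db, gb.omics_type, float(scores[j, k]), int(m))
            )
    return RelatednessTable(pd.DataFrame(rows, columns=TABLE_COLUMNS))


def import_relatedness(
    path: str | Path,
    format: str,
    id_omics: Mapping[str, str] | None = None,
) -> RelatednessTable:
    """Import a relatedness table produced by an external tool.

    ``format="generic-tsv"`` expects the native six-column layout.
    ``format="gcta-grm-gz"`` expects a gzipped whitespace triplet file
    (1-based index_j, index_k, n_snps, score) with a companion ``.grm.id``
    file (FID/IID per line); ``id_omics`` must then map every data id to an
    omics label, and unknown ids raise a reconciliation error.
    Rows with unparseable scores are dropped with a warning.
    """
    path = Path(path)
    if format == "generic-tsv":
        return RelatednessTable.read_tsv(path)
    if format != "gcta-grm-gz":
        raise ValueError(f"unknown relatedness format {format!r}")

    prefix = str(path)
    if prefix.endswith(".grm.gz"):
        prefix = prefix[: -len(".grm.gz")]
    id_path = Path(prefix + ".grm.id")
    grm_path = Path(prefix + ".grm.gz")
    ids = [line.split()[1] for line in id_path.read_text().splitlines() if line.strip()]
    if id_omics is None:
        raise ValueError("gcta-grm-gz import requires an id -> omics mapping")
    orphans = sorted(set(ids) - set(id_omics))
    if orphans:
        raise ValueError(f"ids missing from omics mapping: {orphans}")

    rows = []
    n_bad = 0
    with gzip.open(grm_path, "rt") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 4:
                continue
            j, k, n = int(parts[0]), int(parts[1]), int(float(parts[2]))
            try:
                score = float(parts[3])
            except ValueError:
                n_bad += 1
                continue
            if math.isnan(score):
                n_bad += 1
                continue
            if j == k:
                continue  # self-relatedness diagonal
            da, db = ids[j - 1], ids[k - 1]
            rows.append((da, id_omics[da], db, id_omics[db], score, max(n, 1)))
    if n_bad:
        log.warning("dropped %d GRM rows with unparseable scores", n_bad)
    return RelatednessTable(pd.DataFrame(rows, columns=TABLE_COLUMNS))


def classify_pairs(
    table: RelatednessTable,
    truth_ids: Mapping[str, str],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[int, int, int, int]:
    """Confusion counts (tp, tn, fp, fn) of pair extraction at a threshold.

    ``truth_ids`` maps each data id to its true individual; a pair is a
    positive when both sides map to the same individual.  Scores strictly
    above the threshold are predicted positive.
    """
    df = table.df
    same = df["data_a"].map(truth_ids) == df["data_b"].map(truth_ids)
    pred = df["score"] > threshold
    tp = int((same & pred).sum())
    fn = int((same & ~pred).sum())
    fp = int((~same & pred).sum())
    tn = int((~same & ~pred).sum())
    return tp, tn, fp, fn


def subsample_benchmark(
    ga: GenotypeMatrix,
    gb: GenotypeMatrix,
    truth_ids: Mapping[str, str],
    sizes: Sequence[int],
    maf_band: str = "common",
    threshold: float = DEFAULT_THRESHOLD,
    replicates: int = 1,
    seed: int = 0,
) -> list[PairBenchmark]:
    """Sensitivity/specificity of pair extraction under SNP subsampling.

    For each requested size, draws that many shared loci uniformly at random
    from the MAF band (``common``: pooled MAF > 0.1; ``rare``: MAF < 0.1),
    recomputes all cross-pair scores, and classifies pairs at ``threshold``
    against ``truth_ids``.  Callers should restrict both matrices to samples
    whose identities are fully matched across omics, otherwise the truth
    labels are unreliable.  Sizes exceeding the available loci are skipped
    with a warning.
    """
    if maf_band not in ("common", "rare"):
        raise ValueError("maf_band must be 'common' or 'rare'")
    ia, ib = _shared_loci(ga, gb)
    calls_a = ga.calls[ia]
    calls_b = gb.calls[ib]
    p = _pooled_frequencies(calls_a, calls_b)
    maf = np.minimum(p, 1.0 - p)
    informative = np.isfinite(p) & (p > 0) & (p < 1)
    band = informative & ((maf > 0.1) if maf_band == "common" else (maf < 0.1))
    avail = int(band.sum())
    pool = np.flatnonzero(band)
    rng = np.random.default_rng(seed)
    comparison = (ga.omics_type, gb.omics_type)
    results: list[PairBenchmark] = []
    for size in sizes:
        if size > avail:
            log.warning(
                "%s vs %s: requested %d loci but only %d in %s band; skipped",
                ga.omics_type, gb.omics_type, size, avail, maf_band,
            )
            continue
        for rep in range(replicates):
            chosen = rng.choice(pool, size=size, replace=False)
            scores, counts = _pair_scores(
                calls_a[chosen].astype(np.float64),
                calls_b[chosen].astype(np.float64),
                p[chosen],
            )
            rows = []
            for j, da in enumerate(ga.data_ids):
                for k, db in enumerate(gb.data_ids):
                    if counts[j, k] < 1:
                        continue
                    rows.append(
                        (da, ga.omics_type, db, gb.omics_type,
                         float(scores[j, k]), int(counts[j, k]))
                    )
            tbl = RelatednessTable(pd.DataFrame(rows, columns=TABLE_COLUMNS))
            tp, tn, fp, fn = classify_pairs(tbl, truth_ids, threshold)
            results.append(
                PairBenchmark(comparison, size, tp, tn, fp, fn, replicate=rep)
            )
    return results
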