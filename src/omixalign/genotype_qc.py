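"""Genotype input, contamination screening and allele-frequency utilities.

This module is the entry point for per-omics genotype calls.  Genotypes are
read from VCF into a compact biallelic-SNP matrix (alt-allele dosage codes
0/1/2, missing calls preserved), from which we derive

* per-data heterozygous rates, a cheap contamination indicator
  (cross-individual contamination inflates apparent heterozygosity);
* contamination flags combining the heterozygous rate with an optional
  user-supplied FREEMIX estimate (fraction of non-reference bases at
  reference sites, produced by external BAM-level tools);
* per-locus alternate-allele frequencies feeding the relatedness kernel and
  the X-heterozygosity sex check.

Indels and multiallelic records are dropped at read time: the downstream
relatedness and inbreeding formulas assume biallelic SNPs.  Loci are keyed by
1-based VCF coordinates throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "ContaminationReport",
    "read_genotypes",
    "heterozygous_rate",
    "flag_contamination",
    "allele_frequencies",
    "write_contamination_tsv",
]

log = logging.getLogger(__name__)

#: Sentinel genotype code for a missing call ("./.").
MISSING: int = -1

#: Heterozygous-rate and FREEMIX cutoff above which a sample is considered
#: contaminated (both must exceed it when FREEMIX is available).
CONTAMINATION_CUTOFF: float = 0.3

LOCUS_COLUMNS = ("chrom", "pos", "ref", "alt")


def _chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Order autosomes numerically, then X/Y/MT and anything else by name."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    try:
        return (0, int(c), "")
    except ValueError:
        return (1, 0, c)


def _normalize_chrom(chrom: str) -> str:
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass
class GenotypeMatrix:
    """Biallelic-SNP genotype calls for one omics dataset.

    Attributes
    ----------
    omics_type:
        Label of the omics platform the calls came from (e.g. ``"WGS"``).
    data_ids:
        Ordered, unique data identifiers (one per column of ``calls``).
    loci:
        DataFrame with columns ``chrom, pos, ref, alt``; sorted by
        (chromosome, position) and free of duplicate records.
    calls:
        ``(n_loci, n_data)`` int8 array of alt-allele counts in {0, 1, 2},
        with :data:`MISSING` marking absent calls.
    """

    omics_type: str
    data_ids: list[str]
    loci: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.data_ids = list(self.data_ids)
        if len(set(self.data_ids)) != len(self.data_ids):
            raise ValueError(f"duplicate data_ids in {self.omics_type} matrix")
        if list(self.loci.columns[:4]) != list(LOCUS_COLUMNS):
            raise ValueError(f"loci must have columns {LOCUS_COLUMNS}")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.loci), len(self.data_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.loci)} loci x {len(self.data_ids)} data"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype calls must be 0, 1, 2 or missing")
        keys = list(
            zip(
                (_chrom_sort_key(c) for c in self.loci["chrom"]),
                self.loci["pos"].tolist(),
            )
        )
        if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("loci must be sorted by (chromosome, position)")
        if self.loci.duplicated(subset=list(LOCUS_COLUMNS)).any():
            raise ValueError("duplicate (chrom, pos, ref, alt) loci")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_data(self) -> int:
        return len(self.data_ids)

    def column(self, data_id: str) -> np.ndarray:
        """Calls for one data identifier (raises ``KeyError`` if absent)."""
        try:
            j = self.data_ids.index(data_id)
        except ValueError:
            raise KeyError(
                f"data_id {data_id!r} not present in {self.omics_type} matrix"
            ) from None
        return self.calls[:, j]

    def restrict_chromosomes(self, chroms: Iterable[str]) -> "GenotypeMatrix":
        """Return a copy restricted to the given chromosomes."""
        wanted = {_normalize_chrom(c) for c in chroms}
        keep = self.loci["chrom"].map(_normalize_chrom).isin(wanted).to_numpy()
        return GenotypeMatrix(
            self.omics_type,
            list(self.data_ids),
            self.loci.loc[keep].reset_index(drop=True),
            self.calls[keep],
        )


@dataclass
class ContaminationReport:
    """Per-data contamination verdict.

    ``contaminated`` is true when the heterozygous rate exceeds 0.3 and,
    if a FREEMIX value is available for the data, FREEMIX also exceeds 0.3.
    """

    data_id: str
    omics_type: str
    het_rate: float
    freemix: float | None
    contaminated: bool


def read_genotypes(
    path: str | Path,
    omics_type: str,
    region_filter: Iterable[str] | None = None,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records and non-SNP records (indels, symbolic alleles) are
    dropped.  GT fields are decoded to alt-allele counts; ``./.`` becomes
    :data:`MISSING`.  ``region_filter`` restricts to a chromosome set
    (``chr`` prefixes are ignored on both sides).
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise OSError(f"cannot read VCF {path}: {exc}") from exc

    wanted = {_normalize_chrom(c) for c in region_filter} if region_filter else None
    data_ids = list(vcf.samples)
    rows: list[tuple[str, int, str, str]] = []
    calls: list[np.ndarray] = []
    n_dropped = 0
    for var in vcf:
        if wanted is not None and _normalize_chrom(var.CHROM) not in wanted:
            continue
        ref = var.REF
        alts = var.ALT
        if len(alts) != 1 or len(ref) != 1 or len(alts[0]) != 1:
            n_dropped += 1
            continue
        if ref not in "ACGT" or alts[0] not in "ACGT":
            n_dropped += 1
            continue
        g = var.gt_types.astype(np.int8)  # gts012: 0/1/2, 3 = unknown
        g[g == 3] = MISSING
        rows.append((var.CHROM, var.POS, ref, alts[0]))
        calls.append(g)
    if n_dropped:
        log.info("%s: dropped %d multiallelic/non-SNP records", path.name, n_dropped)
    if not rows:
        filters = f"region_filter={sorted(wanted)}" if wanted else "no region filter"
        raise ValueError(
            f"no biallelic SNPs left in {path} after filtering "
            f"(multiallelic/indel records removed; {filters})"
        )

    loci = pd.DataFrame(rows, columns=list(LOCUS_COLUMNS))
    mat = np.vstack(calls)
    order = sorted(
        range(len(loci)),
        key=lambda i: (_chrom_sort_key(loci.at[i, "chrom"]), loci.at[i, "pos"]),
    )
    loci = loci.iloc[order].reset_index(drop=True)
    mat = mat[order]
    dup = loci.duplicated(subset=list(LOCUS_COLUMNS)).to_numpy()
    if dup.any():
        log.warning("%s: dropping %d duplicate loci", path.name, int(dup.sum()))
        loci = loci.loc[~dup].reset_index(drop=True)
        mat = mat[~dup]
    return GenotypeMatrix(omics_type, data_ids, loci, mat)


def heterozygous_rate(g: GenotypeMatrix, data_id: str) -> float:
    """Fraction of heterozygous calls among non-missing loci for one data.

    Returns ``nan`` (with a warning) when every locus is missing.
    """
    col = g.column(data_id)
    non_missing = col != MISSING
    n = int(non_missing.sum())
    if n == 0:
        log.warning("%s/%s: all loci missing, heterozygous rate undefined",
                    g.omics_type, data_id)
        return math.nan
    return float((col == 1).sum()) / n


def flag_contamination(
    het_rates: Mapping[str, float],
    freemix: Mapping[str, float] | None = None,
    omics_type: str = "",
) -> list[ContaminationReport]:
    """Flag contaminated data from heterozygous rates and optional FREEMIX.

    A data is contaminated when its heterozygous rate exceeds 0.3 *and* its
    FREEMIX exceeds 0.3; on platforms without FREEMIX (e.g. SNP arrays) the
    heterozygous rate alone decides.  When exactly one of the two indicators
    exceeds the cutoff a warning is logged but the data is not flagged.
    """
    if not het_rates:
        raise ValueError("het_rates is empty")
    reports = []
    for data_id, het in het_rates.items():
        fm = None if freemix is None else freemix.get(data_id)
        het_high = not math.isnan(het) and het > CONTAMINATION_CUTOFF
        if fm is None:
            contaminated = het_high
        else:
            fm_high = fm > CONTAMINATION_CUTOFF
            contaminated = het_high and fm_high
            if het_high != fm_high:
                log.warning(
                    "%s/%s: only one contamination indicator exceeds %.1f "
                    "(het_rate=%.3f, freemix=%.3f); not flagged",
                    omics_type, data_id, CONTAMINATION_CUTOFF, het, fm,
                )
        reports.append(
            ContaminationReport(data_id, omics_type, het, fm, contaminated)
        )
    return reports


def allele_frequencies(
    g: GenotypeMatrix,
    restrict_to: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-locus alternate-allele frequency p = (sum of alt counts) / (2 n).

    Missing calls are excluded from both numerator and denominator.  Loci
    where every call is missing get ``nan`` (reported via a warning) so the
    result stays aligned with ``g.loci``.
    """
    if g.n_loci == 0 or g.n_data == 0:
        raise ValueError("empty genotype matrix")
    if restrict_to is None:
        calls = g.calls
    else:
        idx = [g.data_ids.index(d) for d in restrict_to]
        if not idx:
            raise ValueError("restrict_to selects no data")
        calls = g.calls[:, idx]
    non_missing = calls != MISSING
    denom = 2.0 * non_missing.sum(axis=1)
    alt = np.where(non_missing, calls, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, alt / denom, np.nan)
    n_dropped = int(np.isnan(p).sum())
    if n_dropped:
        log.warning("%s: %d loci with all calls missing dropped from "
                    "allele frequencies", g.omics_type, n_dropped)
    return p


def write_contamination_tsv(
    reports: Iterable[ContaminationReport], path: str | Path
) -> None:
    """Write the contamination report table (TSV)."""
    df = pd.DataFrame(
        [
            {
                "data_id": r.data_id,
                "omics_type": r.omics_type,
                "het_rate": r.het_rate,
                "freemix": "" if r.freemix is None else r.freemix,
                "contaminated": r.contaminated,
            }
            for r in reports
        ]
    )
    df.to_csv(path, sep="\t", index=False)
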