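"""Genetics-based sex inference and sex-concordance rates.

Two independent readouts of a sample's genetic sex are supported:

* **F-value** — an X-chromosome inbreeding statistic,
  ``F = (O_hom - E_hom) / (L - E_hom)``, where ``O_hom`` is the observed
  homozygote count over the data's ``L`` non-missing X loci and
  ``E_hom = sum_i (1 - 2 p_i (1 - p_i))`` the Hardy–Weinberg expectation.
  Hemizygous males appear fully homozygous (F near 1); females track the
  Hardy–Weinberg expectation (F near 0).  The F distribution over a cohort
  is typically bimodal, and a valley between the two modes separates the
  sexes.  A Y-chromosome call rate can rescue ambiguous calls.

* **XIST expression** — XIST is a non-coding RNA expressed only in cells
  with at least two X chromosomes, so transcriptome data with XIST above
  2 TPM are called female.

The per-omics sex concordance rate (fraction of data whose reported sex
matches the SNP-inferred sex, unknowns excluded) doubles as the default
omics-priority weight in the re-alignment model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .genotype_qc import MISSING, GenotypeMatrix, allele_frequencies

__all__ = [
    "SexRecord",
    "compute_f_value",
    "infer_snp_sex",
    "infer_xist_sex",
    "sex_concordance_rate",
    "write_sex_table",
    "read_sex_table",
]

log = logging.getLogger(__name__)

XIST_TPM_CUTOFF: float = 2.0
DEFAULT_MIN_X_LOCI: int = 100
DEFAULT_AMBIGUITY_BAND: float = 0.1


@dataclass
class SexRecord:
    """Per-data sex evidence and verdicts."""

    data_id: str
    omics_type: str
    reported_sex: str = "unknown"
    f_value: float | None = None
    y_call_rate: float | None = None
    xist_tpm: float | None = None
    snp_sex: str = "unknown"
    xist_sex: str = "unknown"


def compute_f_value(
    gx: GenotypeMatrix,
    data_id: str,
    p: np.ndarray | None = None,
    min_loci: int = DEFAULT_MIN_X_LOCI,
) -> float | None:
    """X-heterozygosity F statistic for one data.

    ``gx`` must already be restricted to X-chromosome loci; ``p`` gives the
    per-locus allele frequencies (estimated from ``gx`` itself when omitted).
    Returns ``None`` (with a warning) when fewer than ``min_loci`` usable
    loci remain, or when the denominator ``L - E_hom`` degenerates to zero.
    """
    if p is None:
        p = allele_frequencies(gx)
    p = np.asarray(p, dtype=float)
    if p.shape[0] != gx.n_loci:
        raise ValueError("p must align with gx loci")
    col = gx.column(data_id)
    usable = (col != MISSING) & np.isfinite(p)
    L = int(usable.sum())
    if L < min_loci:
        log.warning(
            "%s/%s: only %d usable X loci (< %d); F-value not computed",
            gx.omics_type, data_id, L, min_loci,
        )
        return None
    pv = p[usable]
    o_hom = int(((col == 0) | (col == 2))[usable].sum())
    e_hom = float(np.sum(1.0 - 2.0 * pv * (1.0 - pv)))
    denom = L - e_hom
    if abs(denom) < 1e-9:
        log.warning("%s/%s: degenerate F denominator (L == E_hom)",
                    gx.omics_type, data_id)
        return None
    return (o_hom - e_hom) / denom


def _kde_valley(values: np.ndarray, band: float) -> tuple[float, float]:
    """Locate the density valley between the two largest modes of F.

    Uses a Gaussian KDE with the normal-reference (Scott) bandwidth.  Raises
    ``ValueError`` when the distribution is not bimodal, in which case the
    caller should supply explicit thresholds.
    """
    kde = gaussian_kde(values)
    pad = 0.05 + float(kde.factor) * float(np.std(values))
    grid = np.linspace(values.min() - pad, values.max() + pad, 512)
    dens = kde(grid)
    interior = np.arange(1, len(grid) - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    modes = interior[is_max]
    if len(modes) < 2:
        raise ValueError(
            "F-value distribution is not bimodal; automatic thresholding "
            "refused — supply explicit (f_low, f_high) thresholds"
        )
    top2 = modes[np.argsort(dens[modes])][-2:]
    lo, hi = int(top2.min()), int(top2.max())
    valley_idx = lo + int(np.argmin(dens[lo : hi + 1]))
    valley = float(grid[valley_idx])
    return valley - band, valley + band


def infer_snp_sex(
    f_values: Mapping[str, float | None],
    y_call_rates: Mapping[str, float] | None = None,
    thresholds: tuple[float, float] | None = None,
    band: float = DEFAULT_AMBIGUITY_BAND,
    min_data: int = 10,
) -> dict[str, str]:
    """Classify each data as male/female/unknown from its F-value.

    With explicit ``thresholds=(f_low, f_high)``: F above ``f_high`` is
    male, below ``f_low`` female, inside the band unknown.  Otherwise the
    cut is placed automatically at the deepest density valley between the
    two largest modes of the F distribution, with an ambiguity band of
    ``+-band`` around it.  When ``y_call_rates`` are given, data left
    unknown but with a Y call rate above half the male median are assigned
    male (hemizygous Y support).
    """
    known = {d: f for d, f in f_values.items() if f is not None and math.isfinite(f)}
    if thresholds is not None:
        f_low, f_high = thresholds
    else:
        if len(known) < min_data:
            raise ValueError(
                f"automatic thresholding needs >= {min_data} F-values "
                f"(got {len(known)})"
            )
        f_low, f_high = _kde_valley(np.asarray(list(known.values())), band)

    verdicts: dict[str, str] = {}
    for data_id, f in f_values.items():
        if f is None or not math.isfinite(f):
            verdicts[data_id] = "unknown"
        elif f > f_high:
            verdicts[data_id] = "male"
        elif f < f_low:
            verdicts[data_id] = "female"
        else:
            verdicts[data_id] = "unknown"

    if y_call_rates:
        male_rates = [
            y_call_rates[d]
            for d, v in verdicts.items()
            if v == "male" and d in y_call_rates
        ]
        if male_rates:
            cutoff = 0.5 * float(np.median(male_rates))
            for data_id, v in verdicts.items():
                if v == "unknown" and y_call_rates.get(data_id, -1.0) > cutoff:
                    verdicts[data_id] = "male"
    return verdicts


def infer_xist_sex(xist_tpm: Mapping[str, float]) -> dict[str, str]:
    """Female iff XIST expression is strictly above 2 TPM, else male."""
    out = {}
    for data_id, tpm in xist_tpm.items():
        if tpm < 0:
            raise ValueError(f"negative TPM for {data_id}: {tpm}")
        out[data_id] = "female" if tpm > XIST_TPM_CUTOFF else "male"
    return out


def sex_concordance_rate(records: Iterable[SexRecord], omics_type: str) -> float:
    """Fraction of data with reported_sex == snp_sex, among data where both
    are known, for one omics type.  Returns ``nan`` with a warning when no
    record is eligible."""
    eligible = [
        r
        for r in records
        if r.omics_type == omics_type
        and r.reported_sex in ("male", "female")
        and r.snp_sex in ("male", "female")
    ]
    if not eligible:
        log.warning("no records with known reported and inferred sex for %s",
                    omics_type)
        return math.nan
    matched = sum(r.reported_sex == r.snp_sex for r in eligible)
    return matched / len(eligible)


def write_sex_table(records: Sequence[SexRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "data_id": r.data_id,
                "omics_type": r.omics_type,
                "reported_sex": r.reported_sex,
                "f_value": "" if r.f_value is None else r.f_value,
                "y_call_rate": "" if r.y_call_rate is None else r.y_call_rate,
                "xist_tpm": "" if r.xist_tpm is None else r.xist_tpm,
                "snp_sex": r.snp_sex,
                "xist_sex": r.xist_sex,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_sex_table(path: str | Path) -> list[SexRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        def _opt(v):
            return None if (v is None or (isinstance(v, float) and math.isnan(v)) or v == "") else float(v)

        records.append(
            SexRecord(
                data_id=str(row.data_id),
                omics_type=str(row.omics_type),
                reported_sex=str(getattr(row, "reported_sex", "unknown")),
                f_value=_opt(getattr(row, "f_value", None)),
                y_call_rate=_opt(getattr(row, "y_call_rate", None)),
                xist_tpm=_opt(getattr(row, "xist_tpm", None)),
                snp_sex=str(getattr(row, "snp_sex", "unknown")),
                xist_sex=str(getattr(row, "xist_sex", "unknown")),
            )
        )
    return records
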