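"""Synthetic multi-omics mix-up datasets and the correction benchmark.

The generator emulates a cohort study in which every individual was assayed
on several omics platforms and a fraction of dataset IDs were swapped
during sample handling:

* ``n_samples`` individuals (half female, half male), processed in batches
  of 25 — swaps happen within a processing batch, as in real labs;
* one data per individual per omics type (3 to 6 platforms); every omics
  type is processed separately and therefore has its own random batch
  composition;
* per omics type, ``floor(shuffle_prop * n_samples)`` data are selected and
  their observed IDs deranged within each batch, so every selected data is
  genuinely mis-assigned;
* reported sexes are individual-level metadata and are mislabeled for 2%
  of individuals (consistently across all of that individual's data);
* ground-truth relatedness edges connect exactly the data pairs that share
  a true individual across omics types.  The edges are noise-free by
  default; optional dropout/false-edge knobs exist for robustness checks.

Running the full correction pipeline on such datasets and scoring the
fraction of mix-ups fixed (and of clean data broken) reproduces the
correction-performance surface over sample size, omics count and shuffle
proportion.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pair_graph import DataNode, PairEdge, build_groups, stringent_filter
from .realignment import Assignment, realign_groups

__all__ = [
    "SimConfig",
    "SimDataset",
    "SimMetrics",
    "simulate_dataset",
    "run_correction",
    "evaluate_correction",
    "run_grid",
]

log = logging.getLogger(__name__)

PAPER_SAMPLE_SIZES = (50, 100, 150, 200, 250, 300)
PAPER_OMICS_COUNTS = (3, 4, 5, 6)
PAPER_SHUFFLE_PROPS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset."""

    n_samples: int
    n_omics: int
    shuffle_prop: float
    batch_size: int = 25
    sex_mislabel_prop: float = 0.02
    replicates: int = 100
    seed: int = 0
    stringent: bool = True
    edge_dropout: float = 0.0
    false_edge_prop: float = 0.0

    def __post_init__(self) -> None:
        if not 3 <= self.n_omics <= 6:
            raise ValueError("n_omics must be between 3 and 6")
        if not 0.0 <= self.shuffle_prop <= 1.0:
            raise ValueError("shuffle_prop must be in [0, 1]")
        if self.n_samples < 1 or self.batch_size < 2:
            raise ValueError("invalid n_samples/batch_size")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @property
    def omics_labels(self) -> tuple[str, ...]:
        return tuple(f"omics{i + 1}" for i in range(self.n_omics))


@dataclass
class SimDataset:
    """One realized dataset: nodes, ground-truth edges, and truth masks.

    Node arrays are omics-major: node ``o * n_samples + i`` is individual
    ``i``'s data on omics ``o``.
    """

    config: SimConfig
    rep_index: int
    nodes: list[DataNode]
    true_ids: list[str]
    shuffle_mask: np.ndarray
    sexnoise_mask: np.ndarray
    edges: list[PairEdge]
    individuals: list[str] = field(default_factory=list)

    @property
    def n_mixups(self) -> int:
        return int(self.shuffle_mask.sum())

    def signature(self) -> str:
        """Deterministic text rendering (for reproducibility checks)."""
        rows = [
            f"{n.omics_type},{t},{n.data_id},{n.reported_sex},{n.snp_sex},"
            f"{int(s)},{int(x)}"
            for n, t, s, x in zip(
                self.nodes, self.true_ids, self.shuffle_mask, self.sexnoise_mask
            )
        ]
        return "\n".join(rows)


@dataclass
class SimMetrics:
    """Outcome of one correction run.

    ``corrected_prop``: mix-ups assigned their true ID / number of mix-ups.
    ``overcorrected_prop``: clean data assigned a wrong ID / number of
    mix-ups (the companion ``overcorrected_per_clean`` uses the clean-data
    count as denominator instead).
    """

    corrected_prop: float
    overcorrected_prop: float
    unresolved: int
    overcorrected_per_clean: float = 0.0


def _select_batch_counts(
    rng: np.random.Generator, batch_sizes: np.ndarray, k: int, max_tries: int = 100000
) -> np.ndarray:
    """Multivariate-hypergeometric batch counts with no singleton batch.

    A batch with exactly one selected data cannot be deranged, so such
    draws are rejected and redrawn.
    """
    for _ in range(max_tries):
        counts = rng.multivariate_hypergeometric(batch_sizes, k)
        if not np.any(counts == 1):
            return counts
    raise RuntimeError(
        "could not draw a derangeable within-batch selection; "
        "shuffle_prop/batch_size combination is too sparse"
    )


def _derangement(rng: np.random.Generator, m: int) -> np.ndarray:
    """Uniform random derangement of range(m), m >= 2, by rejection."""
    while True:
        perm = rng.permutation(m)
        if not np.any(perm == np.arange(m)):
            return perm


def simulate_dataset(cfg: SimConfig, rep_index: int = 0) -> SimDataset:
    """Generate one dataset; deterministic given (cfg, seed, rep_index)."""
    rng = np.random.default_rng(
        (cfg.seed, rep_index, cfg.n_samples, cfg.n_omics,
         int(round(cfg.shuffle_prop * 10000)))
    )
    n = cfg.n_samples
    individuals = [f"S{i + 1:04d}" for i in range(n)]
    idx_of = {s: i for i, s in enumerate(individuals)}
    n_batches = -(-n // cfg.batch_size)
    batch_sizes = np.bincount(np.arange(n) // cfg.batch_size, minlength=n_batches)

    # exactly half female before mislabeling, positions randomized
    true_sex = np.array(["male"] * n, dtype=object)
    true_sex[rng.permutation(n)[: n // 2]] = "female"
    reported_sex = true_sex.copy()
    k_noise = int(math.floor(cfg.sex_mislabel_prop * n))
    noisy = rng.choice(n, size=k_noise, replace=False) if k_noise else np.array([], int)
    sexnoise_individual = np.zeros(n, dtype=bool)
    for i in noisy:
        sexnoise_individual[i] = True
        reported_sex[i] = "female" if reported_sex[i] == "male" else "male"

    k = int(math.floor(cfg.shuffle_prop * n))
    if k == 1:
        raise ValueError(
            "shuffle_prop selects a single data per omics; a within-batch "
            "derangement needs at least two"
        )
    if cfg.shuffle_prop > 0 and k == 0:
        log.warning("shuffle_prop %.3f selects no data at n=%d; dataset has "
                    "no mix-ups", cfg.shuffle_prop, n)

    nodes: list[DataNode] = []
    true_ids: list[str] = []
    shuffle_mask = np.zeros(n * cfg.n_omics, dtype=bool)
    node_grid: list[list[DataNode]] = []
    for o, omics in enumerate(cfg.omics_labels):
        observed = np.array(individuals, dtype=object)
        if k >= 2:
            # each omics type is processed separately, so it gets its own
            # random batch composition
            layout = rng.permutation(n)
            batch_of = np.empty(n, dtype=int)
            batch_of[layout] = np.arange(n) // cfg.batch_size
            counts = _select_batch_counts(rng, batch_sizes, k)
            for b in range(n_batches):
                c = int(counts[b])
                if c == 0:
                    continue
                members = np.flatnonzero(batch_of == b)
                sel = rng.choice(members, size=c, replace=False)
                perm = _derangement(rng, c)
                observed[sel] = observed[sel][perm]
        omics_nodes: list[DataNode] = []
        for i in range(n):
            obs = observed[i]
            node = DataNode(
                data_id=str(obs),
                omics_type=omics,
                reported_sex=str(reported_sex[idx_of[obs]]),
                snp_sex=str(true_sex[i]),
                omics_priority=0.5,
            )
            omics_nodes.append(node)
            nodes.append(node)
            true_ids.append(individuals[i])
            shuffle_mask[o * n + i] = obs != individuals[i]
        node_grid.append(omics_nodes)

    sexnoise_mask = np.tile(sexnoise_individual, cfg.n_omics)

    edges: list[PairEdge] = []
    for i in range(n):
        for o1, o2 in itertools.combinations(range(cfg.n_omics), 2):
            if cfg.edge_dropout > 0 and rng.random() < cfg.edge_dropout:
                continue
            edges.append(PairEdge(node_grid[o1][i], node_grid[o2][i], score=1.0))
    if cfg.false_edge_prop > 0:
        n_false = int(round(cfg.false_edge_prop * len(edges)))
        for _ in range(n_false):
            o1, o2 = rng.choice(cfg.n_omics, size=2, replace=False)
            i, j = rng.choice(n, size=2, replace=False)
            edges.append(PairEdge(node_grid[o1][i], node_grid[o2][j], score=1.0))

    return SimDataset(
        cfg, rep_index, nodes, true_ids, shuffle_mask, sexnoise_mask, edges,
        individuals=individuals,
    )


def run_correction(
    ds: SimDataset, stringent: bool | None = None
) -> tuple[list[Assignment], list[DataNode]]:
    """Run the full grouping + re-alignment pipeline on a dataset.

    Returns the per-group assignments and the isolated (unassignable)
    nodes.  Deterministic given the dataset.
    """
    cfg = ds.config
    if stringent is None:
        stringent = cfg.stringent
    priorities = {omics: 0.5 for omics in cfg.omics_labels}
    groups, isolated = build_groups(ds.nodes, ds.edges)
    if stringent:
        groups = stringent_filter(groups)
    assignments, _model = realign_groups(groups, cfg.n_omics, priorities)
    return assignments, isolated


def evaluate_correction(
    ds: SimDataset, assignments: Sequence[Assignment]
) -> SimMetrics:
    """Score a correction run against the ground truth.

    Unresolved data (discarded groups, isolated nodes) keep their observed
    IDs, so an unresolved mix-up counts as not corrected.
    """
    final = {id(n): n.data_id for n in ds.nodes}  # default: keep observed
    unresolved = 0
    seen = set()
    for asg in assignments:
        for node in asg.nodes:
            seen.add(id(node))
            if asg.verdict_of(node) == "unresolved":
                unresolved += 1
            else:
                final[id(node)] = asg.final_id
    unresolved += sum(1 for n in ds.nodes if id(n) not in seen)

    n_mix = ds.n_mixups
    n_corrected = n_over = 0
    n_clean = len(ds.nodes) - n_mix
    for node, truth, mixed in zip(ds.nodes, ds.true_ids, ds.shuffle_mask):
        ok = final[id(node)] == truth
        if mixed and ok:
            n_corrected += 1
        elif not mixed and not ok:
            n_over += 1
    if n_mix == 0:
        log.warning("dataset has no mix-ups; corrected proportion undefined")
        return SimMetrics(
            math.nan,
            n_over / n_clean if n_clean else math.nan,
            unresolved,
            overcorrected_per_clean=n_over / n_clean if n_clean else math.nan,
        )
    return SimMetrics(
        n_corrected / n_mix,
        n_over / n_mix,
        unresolved,
        overcorrected_per_clean=n_over / n_clean if n_clean else math.nan,
    )


def run_replicates(cfg: SimConfig) -> list[SimMetrics]:
    """Simulate, correct and score ``cfg.replicates`` independent datasets."""
    out = []
    for rep in range(cfg.replicates):
        ds = simulate_dataset(cfg, rep)
        assignments, _ = run_correction(ds)
        out.append(evaluate_correction(ds, assignments))
    return out


def run_grid(
    sample_sizes: Sequence[int] = PAPER_SAMPLE_SIZES,
    omics_counts: Sequence[int] = PAPER_OMICS_COUNTS,
    shuffle_props: Sequence[float] = PAPER_SHUFFLE_PROPS,
    replicates: int = 100,
    seed: int = 0,
    stringent: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Correction performance over a (size x omics x shuffle) grid.

    Returns ``(long, summary, correlations)``: per-replicate metrics, the
    per-cell mean/SD of the corrected and overcorrected proportions (SD is
    0 by convention for a single replicate), and the cross-cell Pearson
    correlations of sample size against the mean and the SD of the
    corrected proportion.
    """
    if not (len(sample_sizes) and len(omics_counts) and len(shuffle_props)):
        raise ValueError("grid axes must be non-empty")
    rows = []
    for n, m, q in itertools.product(sample_sizes, omics_counts, shuffle_props):
        cfg = SimConfig(
            n_samples=n, n_omics=m, shuffle_prop=q,
            replicates=replicates, seed=seed, stringent=stringent,
        )
        for rep, metrics in enumerate(run_replicates(cfg)):
            rows.append(
                {
                    "n_samples": n,
                    "n_omics": m,
                    "shuffle_prop": q,
                    "replicate": rep,
                    "corrected_prop": metrics.corrected_prop,
                    "overcorrected_prop": metrics.overcorrected_prop,
                    "unresolved": metrics.unresolved,
                }
            )
    long = pd.DataFrame(rows)
    grouped = long.groupby(["n_samples", "n_omics", "shuffle_prop"])
    summary = grouped.agg(
        mean_corrected=("corrected_prop", "mean"),
        sd_corrected=("corrected_prop", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        mean_overcorrected=("overcorrected_prop", "mean"),
        sd_overcorrected=(
            "overcorrected_prop", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0
        ),
    ).reset_index()

    correlations: dict[str, float] = {}
    if summary["n_samples"].nunique() > 1:
        from scipy.stats import pearsonr

        correlations["corr_size_mean_corrected"] = float(
            pearsonr(summary["n_samples"], summary["mean_corrected"]).statistic
        )
        correlations["corr_size_sd_corrected"] = float(
            pearsonr(summary["n_samples"], summary["sd_corrected"]).statistic
        )
    return long, summary, correlations
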