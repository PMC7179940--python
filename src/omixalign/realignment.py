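"""Switch-direction inference and final ID assignment — the core method.

Every mismatched pair (A, B) inside a group poses the question: which of the
two observed IDs is the true one?  Three antisymmetric features feed a
logistic regression answering it:

* ``x1 = (n_b - n_a) / (N - 2)`` — relationship support: how many *other*
  data in the group carry B's ID versus A's, scaled by the number of omics
  types N (an ID echoed by more omics datasets is more credible);
* ``x2 = S_b - S_a`` — sex support: S_a awards 0.5 if A's reported sex
  matches A's genetics-based sex and another 0.5 if A's reported sex
  matches B's genetics-based sex (i.e. if A's ID were re-assigned to data
  B, would the sexes agree?); unknown sexes earn a neutral 0.25;
* ``x3 = P_b - P_a`` — omics priority: user confidence per platform, or
  the per-omics sex-concordance rate when no ranks are given.

The fitted model maps a pair to ``p = logistic(b0 + b1 x1 + b2 x2 + b3 x3)``;
``p > 0.5`` directs the edge A -> B (B's ID more plausible), ``p < 0.5`` the
reverse, ``p = 0.5`` leaves it uncertain.  The winning probability is
rescaled linearly to an edge weight ``|2p - 1|`` in [0, 1].

A modified topological sort then scores every node by weighted indegree
minus weighted outdegree (matched and uncertain edges contribute nothing);
the observed ID of the top-scoring node becomes the final ID for the whole
group.  Training pairs for the regression are mined automatically from
groups where a single deviant ID can be corrected unambiguously and the
correction is corroborated by sex.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit

from .pair_graph import DataNode, Group, PairEdge

__all__ = [
    "FeatureVector",
    "SwitchModel",
    "Assignment",
    "DEFAULT_BETAS",
    "compute_features",
    "extract_training_pairs",
    "fit_switch_model",
    "predict_switch",
    "edge_weight",
    "annotate_directions",
    "topo_scores",
    "assign_final_ids",
    "realign_groups",
    "write_corrections_tsv",
    "write_model",
    "read_model",
]

log = logging.getLogger(__name__)

#: Fallback coefficients (b0, b1, b2, b3) used when too few training pairs
#: exist: relationship evidence dominates, then sex, then omics priority.
DEFAULT_BETAS: tuple[float, float, float, float] = (0.0, 4.0, 2.0, 1.0)

DEFAULT_MIN_TRAINING: int = 10
DEFAULT_RIDGE: float = 1e-4
UNCERTAIN_EPS: float = 1e-9


@dataclass
class FeatureVector:
    """Antisymmetric features of one mismatched pair (see module docstring)."""

    x1: float
    x2: float
    x3: float
    pair: PairEdge | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3], dtype=float)


@dataclass
class SwitchModel:
    """Logistic switch-direction model ``logit(p) = b0 + b1 x1 + b2 x2 + b3 x3``."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    source: str = "default"  # fitted | default | user
    n_training_pairs: int = 0

    @property
    def betas(self) -> tuple[float, float, float, float]:
        return (self.beta0, self.beta1, self.beta2, self.beta3)


@dataclass
class Assignment:
    """Final ID decision for one group.

    ``node_scores`` holds each node's weighted indegree minus outdegree
    (they sum to zero within a group); ``verdicts`` maps every node to
    ``unchanged``/``corrected``/``unresolved``.
    """

    group_id: int
    node_scores: dict[int, float]  # keyed by id(node)
    final_id: str | None
    verdicts: dict[int, str]
    nodes: list[DataNode] = field(default_factory=list)

    def verdict_of(self, node: DataNode) -> str:
        return self.verdicts[id(node)]

    def score_of(self, node: DataNode) -> float:
        return self.node_scores[id(node)]


def _sex_match(reported: str, genetic: str) -> float:
    """Half-credit sex agreement: 0.5 match, 0 mismatch, 0.25 if unknown."""
    if reported not in ("male", "female") or genetic not in ("male", "female"):
        return 0.25
    return 0.5 if reported == genetic else 0.0


def compute_features(
    edge: PairEdge,
    group: Group,
    n_omics: int,
    priorities: Mapping[str, float],
) -> FeatureVector:
    """Features (x1, x2, x3) for a mismatched edge within its group.

    ``n_omics`` is the number of omics types N (combined platforms count
    once); at least three are required for the relationship feature to be
    informative.  ``priorities`` maps every omics label to P in [0, 1].
    """
    if n_omics < 3:
        raise ValueError("at least 3 omics types are required (N >= 3)")
    if edge.status != "mismatched":
        raise ValueError("features are defined for mismatched pairs only")
    a, b = edge.a, edge.b
    for node in (a, b):
        if node.omics_type not in priorities:
            raise ValueError(f"no priority configured for omics {node.omics_type!r}")

    n_a = n_b = 0
    for node in group.nodes:
        if node is a or node is b:
            continue
        if node.data_id == a.data_id:
            n_a += 1
        elif node.data_id == b.data_id:
            n_b += 1
    x1 = (n_b - n_a) / (n_omics - 2)
    x1 = max(-1.0, min(1.0, x1))

    s_a = _sex_match(a.reported_sex, a.snp_sex) + _sex_match(a.reported_sex, b.snp_sex)
    s_b = _sex_match(b.reported_sex, b.snp_sex) + _sex_match(b.reported_sex, a.snp_sex)
    x2 = s_b - s_a
    x3 = priorities[b.omics_type] - priorities[a.omics_type]
    return FeatureVector(x1, x2, x3, pair=edge)


def extract_training_pairs(
    groups: Iterable[Group],
    n_omics: int,
    priorities: Mapping[str, float],
) -> list[tuple[FeatureVector, int]]:
    """Mine high-confidence directed pairs for model training.

    A group contributes when (1) exactly one node's ID differs from the
    single ID shared by all other nodes, and (2) after relabeling that
    deviant node with the shared ID, the shared ID's reported sex matches
    the deviant data's genetics-based sex.  Every mismatched edge incident
    to the deviant then becomes a training example directed toward the
    shared-ID side (label 1 when the stored orientation is a -> b).
    """
    training: list[tuple[FeatureVector, int]] = []
    for g in groups:
        if g.discarded or len(g.nodes) < 3:
            continue
        counts = Counter(n.data_id for n in g.nodes)
        if len(counts) != 2:
            continue
        (id1, c1), (id2, c2) = counts.most_common()
        if c2 != 1 or c1 != len(g.nodes) - 1:
            continue
        shared_id, deviant_id = id1, id2
        deviant = next(n for n in g.nodes if n.data_id == deviant_id)
        shared_reported = next(
            (
                n.reported_sex
                for n in g.nodes
                if n.data_id == shared_id and n.reported_sex in ("male", "female")
            ),
            "unknown",
        )
        if deviant.snp_sex not in ("male", "female"):
            continue
        if shared_reported != deviant.snp_sex:
            continue
        for e in g.edges:
            if e.status != "mismatched":
                continue
            if e.a is not deviant and e.b is not deviant:
                continue
            fv = compute_features(e, g, n_omics, priorities)
            label = 1 if e.a is deviant else 0  # direction points to shared side
            training.append((fv, label))
    return training


def fit_switch_model(
    training: Sequence[tuple[FeatureVector, int]],
    symmetrize: bool = True,
    ridge: float = DEFAULT_RIDGE,
    min_training: int = DEFAULT_MIN_TRAINING,
) -> SwitchModel:
    """Maximum-likelihood logistic fit with a small L2 penalty.

    With ``symmetrize`` (default) every pair enters in both orientations
    with mirrored labels, which forces the intercept to zero and makes the
    fitted model orientation-invariant.  Fewer than ``min_training`` pairs
    falls back to :data:`DEFAULT_BETAS`.  The ridge penalty keeps
    coefficients finite when the training set is linearly separable.
    """
    if len(training) < min_training:
        log.info(
            "only %d training pairs (< %d); using default coefficients",
            len(training), min_training,
        )
        return SwitchModel(*DEFAULT_BETAS, source="default", n_training_pairs=0)

    X = np.array([fv.as_array() for fv, _ in training])
    y = np.array([label for _, label in training], dtype=int)
    if symmetrize:
        X = np.vstack([X, -X])
        y = np.concatenate([y, 1 - y])
    if np.allclose(X, 0.0):
        raise ValueError(
            "degenerate training design (all features zero); "
            "use the default model instead"
        )
    if len(np.unique(y)) < 2:
        raise ValueError(
            "training labels are single-class; use symmetrize=True or the "
            "default model"
        )
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(
        C=1.0 / max(ridge, 1e-12),
        fit_intercept=not symmetrize,
        solver="lbfgs",
        max_iter=2000,
        tol=1e-10,
    )
    clf.fit(X, y)
    b0 = float(clf.intercept_[0]) if not symmetrize else 0.0
    b1, b2, b3 = (float(v) for v in clf.coef_[0])
    return SwitchModel(b0, b1, b2, b3, source="fitted", n_training_pairs=len(training))


def predict_switch(
    model: SwitchModel,
    fv: FeatureVector,
    eps: float = UNCERTAIN_EPS,
) -> tuple[str, float]:
    """Direction and probability for one mismatched pair.

    ``p > 0.5`` yields ``a_to_b`` (B's ID more plausible), ``p < 0.5``
    yields ``b_to_a``; probabilities within ``eps`` of 0.5 are uncertain.
    """
    z = (
        model.beta0
        + model.beta1 * fv.x1
        + model.beta2 * fv.x2
        + model.beta3 * fv.x3
    )
    p = float(expit(z))
    if abs(p - 0.5) < eps:
        return "uncertain", p
    return ("a_to_b" if p > 0.5 else "b_to_a"), p


def edge_weight(p: float) -> float:
    """Linear rescaling of the winning-direction probability to [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability out of range: {p}")
    return abs(2.0 * p - 1.0)


def annotate_directions(
    groups: Iterable[Group],
    model: SwitchModel,
    n_omics: int,
    priorities: Mapping[str, float],
    eps: float = UNCERTAIN_EPS,
) -> None:
    """Set direction and weight on every mismatched edge of kept groups."""
    for g in groups:
        if g.discarded:
            continue
        for e in g.edges:
            if e.status != "mismatched":
                continue
            fv = compute_features(e, g, n_omics, priorities)
            direction, p = predict_switch(model, fv, eps=eps)
            if direction == "uncertain":
                e.direction, e.weight = "uncertain", 0.0
            else:
                e.direction, e.weight = direction, edge_weight(p)


def topo_scores(group: Group) -> dict[int, float]:
    """Weighted indegree minus weighted outdegree per node (keyed by id).

    Matched and uncertain edges contribute nothing; scores over a group
    always sum to zero since each directed edge adds +w and -w.
    """
    scores = {id(n): 0.0 for n in group.nodes}
    for e in group.edges:
        if e.direction == "a_to_b":
            scores[id(e.b)] += e.weight
            scores[id(e.a)] -= e.weight
        elif e.direction == "b_to_a":
            scores[id(e.a)] += e.weight
            scores[id(e.b)] -= e.weight
    return scores


def assign_final_ids(
    group: Group,
    scores: Mapping[int, float] | None = None,
    tie_tol: float = 1e-12,
) -> Assignment:
    """Pick the group's final ID from the top-scoring node.

    Ties within ``tie_tol`` are broken by (1) the larger number of group
    nodes already carrying the candidate ID, (2) the higher omics priority
    of the candidate node, (3) the lexicographically smaller ID.  Discarded
    groups yield ``unresolved`` verdicts for every node.
    """
    if group.discarded:
        zeros = {id(n): 0.0 for n in group.nodes}
        return Assignment(
            group.group_id,
            dict(scores) if scores is not None else zeros,
            None,
            {id(n): "unresolved" for n in group.nodes},
            nodes=list(group.nodes),
        )
    if scores is None:
        scores = topo_scores(group)
    carriers = Counter(n.data_id for n in group.nodes)
    best = max(scores[id(n)] for n in group.nodes)
    candidates = [n for n in group.nodes if scores[id(n)] >= best - tie_tol]
    winner = max(
        candidates,
        key=lambda n: (carriers[n.data_id], n.omics_priority, _neg_lex(n.data_id)),
    )
    final_id = winner.data_id
    verdicts = {
        id(n): ("unchanged" if n.data_id == final_id else "corrected")
        for n in group.nodes
    }
    return Assignment(group.group_id, dict(scores), final_id, verdicts,
                      nodes=list(group.nodes))


class _neg_lex(str):
    """Reverse lexicographic ordering helper (smaller ID wins a max())."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def realign_groups(
    groups: Sequence[Group],
    n_omics: int,
    priorities: Mapping[str, float],
    model: SwitchModel | None = None,
    min_training: int = DEFAULT_MIN_TRAINING,
    eps: float = UNCERTAIN_EPS,
) -> tuple[list[Assignment], SwitchModel]:
    """Full second-step pipeline over pre-built (and pre-filtered) groups.

    Trains the switch model on automatically mined high-confidence pairs
    (falling back to :data:`DEFAULT_BETAS` when scarce or degenerate),
    directs every mismatched edge, sorts nodes and assigns final IDs.
    """
    if model is None:
        training = extract_training_pairs(groups, n_omics, priorities)
        try:
            model = fit_switch_model(training, min_training=min_training)
        except ValueError as exc:
            log.warning("switch-model fit failed (%s); using defaults", exc)
            model = SwitchModel(*DEFAULT_BETAS, source="default")
    annotate_directions(groups, model, n_omics, priorities, eps=eps)
    assignments = [assign_final_ids(g) for g in groups]
    return assignments, model


def write_corrections_tsv(
    assignments: Iterable[Assignment],
    path: str | Path,
    model: SwitchModel | None = None,
    isolated: Iterable[DataNode] = (),
) -> None:
    """Write the per-data corrections table (one row per data)."""
    source = model.source if model is not None else ""
    with open(path, "w") as fh:
        fh.write(
            "omics_type\tdata_id_observed\tdata_id_final\tverdict\t"
            "group_id\tnode_score\tmodel_source\n"
        )
        for asg in assignments:
            for node in asg.nodes:
                verdict = asg.verdict_of(node)
                final = asg.final_id if verdict != "unresolved" else node.data_id
                fh.write(
                    f"{node.omics_type}\t{node.data_id}\t{final}\t{verdict}\t"
                    f"{asg.group_id}\t{asg.score_of(node):.6g}\t{source}\n"
                )
        for node in isolated:
            fh.write(
                f"{node.omics_type}\t{node.data_id}\t{node.data_id}\t"
                f"unresolved\t-1\t0\t{source}\n"
            )


def write_model(model: SwitchModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, b in enumerate(model.betas):
            fh.write(f"beta{i}={b!r}\n")
        fh.write(f"source={model.source}\n")
        fh.write(f"n_training_pairs={model.n_training_pairs}\n")


def read_model(path: str | Path) -> SwitchModel:
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
    return SwitchModel(
        float(kv["beta0"]),
        float(kv["beta1"]),
        float(kv["beta2"]),
        float(kv["beta3"]),
        source=kv.get("source", "user"),
        n_training_pairs=int(kv.get("n_training_pairs", 0)),
    )
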