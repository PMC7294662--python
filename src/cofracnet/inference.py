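"""Co-complex interaction scoring and precision-thresholded networks.

The classifier follows the established co-fractionation recipe: protein
pairs co-resident in at least one curated complex are true positives,
pairs of complex-annotated proteins that never share a complex are true
negatives, and a Gaussian naive-Bayes classifier over the co-elution
features assigns every candidate pair an interaction probability.
Labeled pairs are split into stratified folds; each fold's classifier is
trained on the remaining folds and scores all pairs, and the per-pair
median over folds is the final interaction score.  Walking down the
ranked list, the cumulative precision among gold-labeled pairs selects
the largest prefix still meeting the target precision (70% by default),
and every pair in that prefix — labeled or not — becomes a network edge.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

VARIANCE_FLOOR = 1e-12


class UntrainableFoldError(RuntimeError):
    """A cross-validation fold lacked usable training data for a class."""


@dataclass(frozen=True)
class GoldStandard:
    """Reference labels: intra-complex pairs positive, cross-complex negative."""

    positives: frozenset
    negatives: frozenset

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("a pair cannot be both positive and negative")

    def label(self, a: str, b: str) -> str:
        pair = frozenset((a, b))
        if pair in self.positives:
            return "positive"
        if pair in self.negatives:
            return "negative"
        return "unlabeled"


def build_gold_standard(complexes, universe) -> GoldStandard:
    """Derive labeled pairs from complex definitions restricted to ``universe``.

    ``complexes`` is a mapping complex id -> member iterable (or a bare
    iterable of member iterables).  Complexes with fewer than two members
    present contribute nothing.
    """
    if isinstance(complexes, dict):
        member_lists = list(complexes.values())
    else:
        member_lists = [list(m) for m in complexes]
    universe = set(universe)
    present = [sorted(set(m) & universe) for m in member_lists]
    positives: set[frozenset] = set()
    for members in present:
        positives.update(frozenset(p) for p in itertools.combinations(members, 2))
    gold_proteins = sorted({p for members in present for p in members})
    negatives = {
        frozenset(p)
        for p in itertools.combinations(gold_proteins, 2)
        if frozenset(p) not in positives
    }
    return GoldStandard(frozenset(positives), frozenset(negatives))


def read_complexes_tsv(path) -> dict[str, list[str]]:
    """Read complex definitions as TSV with columns (complex_id, member)."""
    complexes: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError("complex TSV needs complex_id and member columns")
        for line in fh:
            cid, member = line.rstrip("\n").split("\t")[:2]
            complexes.setdefault(cid, []).append(member)
    return complexes


def write_complexes_tsv(complexes: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("complex_id\tmember\n")
        for cid, members in complexes.items():
            for m in members:
                fh.write(f"{cid}\t{m}\n")


class _GaussianNB:
    """Gaussian naive Bayes tolerating missing features per sample.

    Missing features are simply dropped from the likelihood product of
    that sample; class-conditional variances are floored so constant
    features cannot produce infinite densities.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_GaussianNB":
        self.classes_ = np.array([0, 1])
        self.theta_ = np.empty((2, X.shape[1]))
        self.var_ = np.empty((2, X.shape[1]))
        self.log_prior_ = np.empty(2)
        for c in (0, 1):
            rows = X[y == c]
            if rows.shape[0] == 0 or not np.isfinite(rows).any():
                raise UntrainableFoldError(f"no training data for class {c}")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                self.theta_[c] = np.nanmean(rows, axis=0)
                self.var_[c] = np.nanvar(rows, axis=0)
            self.var_[c] = np.where(
                np.isfinite(self.var_[c]), self.var_[c], VARIANCE_FLOOR
            )
            self.var_[c] = np.maximum(self.var_[c], VARIANCE_FLOOR)
            self.theta_[c] = np.where(np.isfinite(self.theta_[c]), self.theta_[c], 0.0)
            self.log_prior_[c] = np.log(rows.shape[0] / X.shape[0])
        return self

    def log_odds(self, X: np.ndarray) -> np.ndarray:
        """log P(interaction | x) - log P(no interaction | x).

        Kept on the log-odds scale so that near-certain pairs stay
        strictly ordered instead of all rounding to posterior 1.0.
        NaN when every feature is missing.
        """
        obs = np.isfinite(X)
        logp = np.empty((X.shape[0], 2))
        for c in (0, 1):
            with np.errstate(invalid="ignore"):
                ll = -0.5 * (
                    np.log(2.0 * np.pi * self.var_[c])
                    + (X - self.theta_[c]) ** 2 / self.var_[c]
                )
            logp[:, c] = self.log_prior_[c] + np.where(obs, ll, 0.0).sum(axis=1)
        out = logp[:, 1] - logp[:, 0]
        out[~obs.any(axis=1)] = np.nan
        return out


@dataclass
class InteractionNetwork:
    """Undirected simple graph of proteins with per-edge provenance."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    condition: str = ""

    @classmethod
    def from_edges(cls, edges, condition: str = "") -> "InteractionNetwork":
        """Build from (a, b[, attrs]) tuples or bare pairs."""
        g = nx.Graph()
        for edge in edges:
            a, b, *rest = edge
            attrs = rest[0] if rest else {}
            g.add_edge(a, b, **attrs)
        return cls(g, condition=condition)

    @property
    def edge_set(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_a\tprotein_b\tscore\tlabel\tcondition\n")
            for a, b, attrs in sorted(self.graph.edges(data=True)):
                score = attrs.get("score", "")
                label = attrs.get("label", "")
                fh.write(f"{a}\t{b}\t{score}\t{label}\t{self.condition}\n")

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        g.graph["condition"] = self.condition
        nx.write_graphml(g, path)


def read_network_tsv(path) -> InteractionNetwork:
    g = nx.Graph()
    condition = ""
    with open(path) as fh:
        fh.readline()
        for line in fh:
            a, b, score, label, condition = line.rstrip("\n").split("\t")
            attrs = {}
            if score:
                attrs["score"] = float(score)
            if label:
                attrs["label"] = label
            g.add_edge(a, b, **attrs)
    return InteractionNetwork(g, condition=condition)


class CoComplexModel:
    """Naive-Bayes co-complex classifier over a pair-feature table.

    Parameters
    ----------
    features
        Pair-indexed feature table (``assemble_feature_table`` output or a
        single replicate frame); NaN = missing.
    gold
        Labeled reference pairs used for training and precision.

    ``fit`` runs the stratified cross-validation and returns a
    :class:`CoComplexResults`.
    """

    def __init__(self, features: pd.DataFrame, gold: GoldStandard) -> None:
        self.features = features
        self.gold = gold
        self.labels = pd.Series(
            [gold.label(a, b) for a, b in features.index],
            index=features.index,
            name="label",
        )

    def fit(self, n_folds: int = 10, seed: int = 0) -> "CoComplexResults":
        X = self.features.to_numpy(dtype=float)
        labeled = self.labels.isin(["positive", "negative"]).to_numpy()
        y = (self.labels == "positive").to_numpy().astype(int)
        n_pos = int(y[labeled].sum())
        n_neg = int(labeled.sum() - n_pos)
        if min(n_pos, n_neg) < n_folds:
            raise ValueError(
                f"need at least {n_folds} labeled pairs of each class "
                f"(have {n_pos} positive, {n_neg} negative)"
            )
        labeled_idx = np.flatnonzero(labeled)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold_scores = np.full((n_folds, X.shape[0]), np.nan)
        for f, (train, _test) in enumerate(skf.split(labeled_idx, y[labeled_idx])):
            train_rows = labeled_idx[train]
            clf = _GaussianNB().fit(X[train_rows], y[train_rows])
            fold_scores[f] = clf.log_odds(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            log_odds = np.nanmedian(fold_scores, axis=0)
        table = pd.DataFrame(
            {
                "score": expit(log_odds),
                "log_odds": log_odds,
                "label": self.labels.to_numpy(),
            },
            index=self.features.index,
        )
        unscored = table.index[~np.isfinite(log_odds)]
        table = table.loc[np.isfinite(table["log_odds"].to_numpy())]
        table = table.sort_values("log_odds", ascending=False, kind="mergesort")
        table["precision"] = cumulative_precision(table["label"].to_numpy())
        return CoComplexResults(self, table, list(unscored), n_folds=n_folds, seed=seed)


def cumulative_precision(labels: np.ndarray) -> np.ndarray:
    """Precision at each rank: gold positives over gold-labeled pairs so far.

    NaN until the first labeled pair is reached.
    """
    pos = np.cumsum(labels == "positive")
    lab = np.cumsum((labels == "positive") | (labels == "negative"))
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = pos / lab
    return np.where(lab > 0, prec, np.nan)


@dataclass
class CoComplexResults:
    """Ranked interaction scores with cumulative precision.

    ``table`` is sorted non-increasing by score with columns
    (score, label, precision).
    """

    model: CoComplexModel
    table: pd.DataFrame
    unscored: list
    n_folds: int
    seed: int

    @property
    def auc(self) -> float:
        from sklearn.metrics import roc_auc_score

        lab = self.table["label"]
        mask = lab.isin(["positive", "negative"])
        return float(
            roc_auc_score((lab[mask] == "positive").astype(int), self.table["score"][mask])
        )

    def network(
        self, target_precision: float = 0.70, condition: str = ""
    ) -> InteractionNetwork:
        return precision_threshold(self.table, target_precision, condition=condition)

    def summary(self) -> str:
        lab = self.table["label"]
        lines = [
            "Co-complex naive Bayes classifier",
            "=" * 40,
            f"pairs scored:        {len(self.table)}",
            f"pairs unscored:      {len(self.unscored)}",
            f"gold positives:      {(lab == 'positive').sum()}",
            f"gold negatives:      {(lab == 'negative').sum()}",
            f"cross-validation:    {self.n_folds} stratified folds (seed {self.seed})",
            f"held-out AUC:        {self.auc:.4f}",
        ]
        for target in (0.5, 0.7, 0.9):
            net = precision_threshold(self.table, target, warn=False)
            lines.append(f"edges at {target:.0%} precision: {net.n_edges}")
        return "\n".join(lines)


def precision_threshold(
    scored: pd.DataFrame,
    target_precision: float = 0.70,
    condition: str = "",
    warn: bool = True,
) -> InteractionNetwork:
    """Largest score-ranked prefix whose cumulative precision meets the target.

    Equal-score blocks enter or leave the network together.  All pairs in
    the prefix (labeled or unlabeled) become edges; the empty network is
    returned with a warning when even the best block misses the target.
    """
    scores = scored["score"].to_numpy()
    # rank on the log-odds scale when available: strictly monotone in the
    # posterior but free of float saturation ties at score 1.0
    key = (
        scored["log_odds"].to_numpy()
        if "log_odds" in scored.columns
        else scores
    )
    labels = scored["label"].to_numpy()
    if np.any(np.diff(key) > 0):
        raise ValueError("scored table must be sorted non-increasing by score")
    prec = (
        scored["precision"].to_numpy()
        if "precision" in scored.columns
        else cumulative_precision(labels)
    )
    n = len(scored)
    if n == 0:
        return InteractionNetwork(condition=condition)
    # candidate cutoffs: the last index of each equal-score block
    block_end = np.flatnonzero(np.diff(key) != 0)
    block_end = np.concatenate([block_end, [n - 1]])
    ok = [k for k in block_end if np.isfinite(prec[k]) and prec[k] >= target_precision]
    if not ok:
        if warn:
            warnings.warn(
                f"no prefix reaches target precision {target_precision}; "
                "returning an empty network",
                stacklevel=2,
            )
        return InteractionNetwork(condition=condition)
    cut = max(ok) + 1
    g = nx.Graph()
    for (a, b), score, label, p in zip(
        scored.index[:cut], scores[:cut], labels[:cut], prec[:cut]
    ):
        g.add_edge(a, b, score=float(score), label=label,
                   precision_at_inclusion=float(p) if np.isfinite(p) else None)
    return InteractionNetwork(g, condition=condition)


def score_pairs(
    features: pd.DataFrame, gold: GoldStandard, n_folds: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Functional wrapper: fit the classifier and return the ranked table."""
    return CoComplexModel(features, gold).fit(n_folds=n_folds, seed=seed).table


@dataclass(frozen=True)
class NetworkComparison:
    shared_edges: frozenset
    a_only_edges: frozenset
    b_only_edges: frozenset
    shared_nodes: frozenset
    a_only_nodes: frozenset
    b_only_nodes: frozenset

    @property
    def edge_proportions(self) -> dict[str, float]:
        total = len(self.shared_edges) + len(self.a_only_edges) + len(self.b_only_edges)
        if total == 0:
            return {"shared": 0.0, "a_only": 0.0, "b_only": 0.0}
        return {
            "shared": len(self.shared_edges) / total,
            "a_only": len(self.a_only_edges) / total,
            "b_only": len(self.b_only_edges) / total,
        }


def compare_networks(
    net_a: InteractionNetwork, net_b: InteractionNetwork
) -> NetworkComparison:
    """Set algebra on edges and nodes of two condition networks."""
    ea, eb = net_a.edge_set, net_b.edge_set
    na, nb = net_a.nodes, net_b.nodes
    return NetworkComparison(
        frozenset(ea & eb),
        frozenset(ea - eb),
        frozenset(eb - ea),
        frozenset(na & nb),
        frozenset(na - nb),
        frozenset(nb - na),
    )
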