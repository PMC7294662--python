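"""Condition-dependent interactome rewiring statistics.

Given interaction networks reconstructed independently for stimulated
and unstimulated cells, this module quantifies rewiring at three levels:

- **gene sets**: for each term, the difference in the number of
  interactions among its proteins between the two networks (delta n_PPI),
  referenced against paired degree-preserving rewirings of both networks
  and Benjamini-Hochberg corrected across terms;
- **edges**: enrichment of shared functional annotation between
  interacting pairs against rewired nulls, and log-odds z-tests on 2x2
  contingency tables;
- **proteins**: the correlation between a protein's stimulated and
  unstimulated chromatograms ("autocorrelation" in the rewiring sense),
  rank-normalized within each replicate and Stouffer-combined, so the
  lowest-scoring tier highlights rewired proteins; plus a
  Brunner-Munzel test for a shift in within-gene-set chromatogram
  correlations between conditions.

The degree-preserving null performs ``round(6.9 x |E|)`` attempted
double-edge swaps, the standard burn-in factor for Markov-chain edge
rewiring.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import brunnermunzel, norm, rankdata
from statsmodels.stats.multitest import multipletests

from .matrix import ChromatogramMatrix
from .inference import InteractionNetwork

REWIRE_ITER_FACTOR = 6.9
MIN_PAIRWISE_OBS = 5
#: GO evidence codes excluded when deriving gene sets from annotations
EXCLUDED_EVIDENCE = frozenset({"IPI", "IEA", "NAS", "ND"})


# ---------------------------------------------------------------------------
# gene-set collections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSetCollection:
    """Term id -> (name, annotated proteins), with filter provenance."""

    sets: dict[str, frozenset]
    names: dict[str, str] = field(default_factory=dict)
    size_filtered: bool = False
    propagated: bool = False

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)

    def name(self, term: str) -> str:
        return self.names.get(term, term)

    def filter_sizes(self, min_size: int = 2, max_size: int = 100) -> "GeneSetCollection":
        """Drop very broad terms (> ``max_size`` proteins) and tiny ones."""
        kept = {
            t: members
            for t, members in self.sets.items()
            if min_size <= len(members) <= max_size
        }
        return replace(self, sets=kept, size_filtered=True)

    def protein_to_terms(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for term, members in self.sets.items():
            for p in members:
                out.setdefault(p, set()).add(term)
        return out


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: term <tab> description <tab> member..."""
    sets: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = frozenset(m for m in fields[2:] if m)
            names[fields[0]] = fields[1]
    return GeneSetCollection(sets, names)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term, members in collection.sets.items():
            name = collection.name(term)
            fh.write("\t".join([term, name, *sorted(members)]) + "\n")


def build_gene_sets_from_annotations(
    annotations: pd.DataFrame,
    ontology=None,
    excluded_evidence: frozenset = EXCLUDED_EVIDENCE,
    excluded_qualifier: str = "NOT",
    min_size: int = 2,
    max_size: int = 100,
) -> GeneSetCollection:
    """Turn a per-protein annotation table into filtered gene sets.

    ``annotations`` needs columns ``protein`` and ``term``; optional
    ``evidence`` and ``qualifier`` columns trigger the standard
    exclusions (IPI, IEA, NAS, ND evidence; NOT qualifier).  ``ontology``
    may be a {term: parent terms} mapping or a directed graph with
    child -> parent edges; when given, annotations are propagated up it.
    """
    df = annotations
    if "evidence" in df.columns:
        df = df[~df["evidence"].isin(excluded_evidence)]
    if "qualifier" in df.columns:
        df = df[df["qualifier"].fillna("") != excluded_qualifier]

    if ontology is not None and not isinstance(ontology, dict):
        ontology = {t: list(ontology.successors(t)) for t in ontology.nodes}

    sets: dict[str, set[str]] = {}
    for protein, term in zip(df["protein"], df["term"]):
        stack = [term]
        seen: set[str] = set()
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            sets.setdefault(t, set()).add(protein)
            if ontology is not None:
                stack.extend(ontology.get(t, ()))
    collection = GeneSetCollection(
        {t: frozenset(m) for t, m in sets.items()}, propagated=ontology is not None
    )
    return collection.filter_sizes(min_size=min_size, max_size=max_size)


# ---------------------------------------------------------------------------
# degree-preserving rewiring
# ---------------------------------------------------------------------------

def _rewire_edge_list(
    edges: list[tuple], n_attempts: int, rng: np.random.Generator
) -> list[tuple]:
    """Attempted double-edge swaps on an undirected simple edge list.

    Each attempt draws two distinct edges (a,b), (c,d) and proposes
    (a,d), (c,b); the swap is rejected if it would create a self-loop or
    a multi-edge.  Degrees are invariant by construction.
    """
    edges = list(edges)
    m = len(edges)
    if m < 2 or n_attempts <= 0:
        return edges
    present = {frozenset(e) for e in edges}
    idx = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for (i, j), flip in zip(idx, flips):
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        if a == d or c == b:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in present or e2 in present:
            continue
        present.discard(frozenset((a, b)))
        present.discard(frozenset((c, d)))
        present.add(e1)
        present.add(e2)
        edges[i] = (a, d)
        edges[j] = (c, b)
    return edges


def rewire_degree_preserving(
    network: InteractionNetwork,
    n_iter_factor: float = REWIRE_ITER_FACTOR,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> InteractionNetwork:
    """Randomize a network by ``round(n_iter_factor x |E|)`` attempted swaps.

    Every node keeps its degree and the edge count is unchanged; graphs
    with a unique realization of their degree sequence come back equal.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    edges = [tuple(e) for e in network.graph.edges]
    n_attempts = int(round(n_iter_factor * len(edges)))
    new_edges = _rewire_edge_list(edges, n_attempts, rng)
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes)
    g.add_edges_from(new_edges)
    if sorted(dict(g.degree).values()) != sorted(dict(network.graph.degree).values()):
        raise AssertionError("degree sequence changed during rewiring")
    return InteractionNetwork(g, condition=network.condition)


# ---------------------------------------------------------------------------
# delta n_PPI gene-set permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RewiringResult:
    """Per-term rewiring statistics between two condition networks."""

    term: str
    name: str
    n_ppi_stim: int
    n_ppi_unstim: int
    delta: int
    null_mean: float
    null_sd: float
    z: float
    p: float
    q: float


@dataclass
class DeltaNPPITest:
    """Results of the paired rewiring permutation test over a term set."""

    results: list[RewiringResult]
    skipped: list[str]
    n_perm: int

    def __iter__(self):
        return iter(self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])

    def significant(self, fdr: float = 0.20) -> list[RewiringResult]:
        return [r for r in self.results if r.q <= fdr]


def _count_within(edge_sets: set[frozenset], members: list[str]) -> int:
    return sum(
        1 for pair in itertools.combinations(members, 2) if frozenset(pair) in edge_sets
    )


def delta_nppi_test(
    net_stim: InteractionNetwork,
    net_unstim: InteractionNetwork,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> DeltaNPPITest:
    """Test each gene set for a condition-dependent change in internal edges.

    For each term, delta = (edges among its proteins in the stimulated
    network) - (same in the unstimulated network).  Both networks are
    rewired ``n_perm`` times with paired degree-preserving swaps; the
    permutation mean and SD give a z-score, a two-tailed normal p, and
    Benjamini-Hochberg q-values across terms.  Terms whose null SD is
    zero get p = 1; terms with fewer than two annotated proteins in the
    networks are skipped.
    """
    rng = np.random.default_rng(seed)
    nodes = net_stim.nodes | net_unstim.nodes
    terms, member_lists, skipped = [], [], []
    for term, members in sets:
        present = sorted(set(members) & nodes)
        if len(present) < 2:
            skipped.append(term)
            continue
        terms.append(term)
        member_lists.append(present)

    stim_edges = [tuple(e) for e in net_stim.graph.edges]
    unstim_edges = [tuple(e) for e in net_unstim.graph.edges]
    stim_set = {frozenset(e) for e in stim_edges}
    unstim_set = {frozenset(e) for e in unstim_edges}
    obs = np.array(
        [
            _count_within(stim_set, m) - _count_within(unstim_set, m)
            for m in member_lists
        ],
        dtype=float,
    )
    obs_stim = [_count_within(stim_set, m) for m in member_lists]
    obs_unstim = [_count_within(unstim_set, m) for m in member_lists]

    n_attempts_s = int(round(REWIRE_ITER_FACTOR * len(stim_edges)))
    n_attempts_u = int(round(REWIRE_ITER_FACTOR * len(unstim_edges)))
    null = np.empty((n_perm, len(terms)))
    for b in range(n_perm):
        rs = {frozenset(e) for e in _rewire_edge_list(stim_edges, n_attempts_s, rng)}
        ru = {frozenset(e) for e in _rewire_edge_list(unstim_edges, n_attempts_u, rng)}
        null[b] = [
            _count_within(rs, m) - _count_within(ru, m) for m in member_lists
        ]

    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(len(terms))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mean) / sd
        p = 2.0 * norm.sf(np.abs(z))
    degenerate = ~np.isfinite(z)
    z = np.where(degenerate, 0.0, z)
    p = np.where(degenerate, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

    results = [
        RewiringResult(
            term=t,
            name=sets.name(t),
            n_ppi_stim=int(obs_stim[i]),
            n_ppi_unstim=int(obs_unstim[i]),
            delta=int(obs[i]),
            null_mean=float(mean[i]),
            null_sd=float(sd[i]),
            z=float(z[i]),
            p=float(p[i]),
            q=float(q[i]),
        )
        for i, t in enumerate(terms)
    ]
    results.sort(key=lambda r: r.p)
    return DeltaNPPITest(results, skipped, n_perm)


# ---------------------------------------------------------------------------
# annotation-sharing enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SharingEnrichment:
    observed: float
    null: np.ndarray
    p: float
    n_perm: int


def _sharing_proportion(edge_sets, protein_terms) -> float:
    if not edge_sets:
        return 0.0
    shared = 0
    for e in edge_sets:
        a, b = tuple(e)
        if protein_terms.get(a, set()) & protein_terms.get(b, set()):
            shared += 1
    return shared / len(edge_sets)


def pair_annotation_sharing_enrichment(
    network: InteractionNetwork,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> SharingEnrichment:
    """Do interacting pairs share annotations more than rewired nulls?

    The empirical p uses the add-one correction
    ``(1 + #{null >= observed}) / (1 + n_perm)`` and is therefore never
    smaller than ``1 / (1 + n_perm)``.
    """
    rng = np.random.default_rng(seed)
    protein_terms = sets.protein_to_terms()
    edges = [tuple(e) for e in network.graph.edges]
    observed = _sharing_proportion([frozenset(e) for e in edges], protein_terms)
    n_attempts = int(round(REWIRE_ITER_FACTOR * len(edges)))
    null = np.empty(n_perm)
    for b in range(n_perm):
        rewired = _rewire_edge_list(edges, n_attempts, rng)
        null[b] = _sharing_proportion([frozenset(e) for e in rewired], protein_terms)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return SharingEnrichment(observed, null, float(p), n_perm)


# ---------------------------------------------------------------------------
# per-protein stimulated-vs-unstimulated autocorrelation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AutocorrelationScore:
    """Per-protein chromatogram correlation between conditions.

    Low combined z marks proteins whose elution changes with stimulation.
    """

    protein: str
    r: dict[int, float]
    z: dict[int, float]
    combined_z: float


def _pairwise_complete_r(x: np.ndarray, y: np.ndarray, min_obs: int) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_obs:
        return np.nan
    xv, yv = x[ok], y[ok]
    if xv.std() == 0 or yv.std() == 0:
        return np.nan
    return float(np.corrcoef(xv, yv)[0, 1])


def _as_matrix_list(matrices) -> list[ChromatogramMatrix]:
    return [matrices] if isinstance(matrices, ChromatogramMatrix) else list(matrices)


def protein_autocorrelation(
    stim, unstim, min_obs: int = MIN_PAIRWISE_OBS
) -> list[AutocorrelationScore]:
    """Stouffer-combined condition correlation per protein across replicates.

    ``stim``/``unstim`` are matching replicate lists (or single matrices).
    Per replicate, each protein's Pearson r between its stimulated and
    unstimulated chromatograms (needing at least ``min_obs`` shared
    fractions) is transformed to a z-score by rank-based inverse-normal
    within the replicate; combined z = sum(z_i) / sqrt(k) over the
    replicates where the protein was measured.  Proteins with no usable
    replicate are omitted.
    """
    stim_l, unstim_l = _as_matrix_list(stim), _as_matrix_list(unstim)
    stim_by_rep = {m.replicate: m for m in stim_l}
    unstim_by_rep = {m.replicate: m for m in unstim_l}
    replicates = sorted(set(stim_by_rep) & set(unstim_by_rep))

    r_per_rep: dict[int, pd.Series] = {}
    z_per_rep: dict[int, pd.Series] = {}
    for rep in replicates:
        ms, mu = stim_by_rep[rep], unstim_by_rep[rep]
        common = [p for p in ms.proteins if p in set(mu.proteins)]
        r = pd.Series(
            [
                _pairwise_complete_r(ms.profile(p), mu.profile(p), min_obs)
                for p in common
            ],
            index=common,
        )
        defined = r.dropna()
        if len(defined) == 0:
            continue
        ranks = rankdata(defined.to_numpy())
        z = norm.ppf((ranks - 0.5) / len(defined))
        r_per_rep[rep] = defined
        z_per_rep[rep] = pd.Series(z, index=defined.index)

    proteins = sorted({p for s in z_per_rep.values() for p in s.index})
    scores = []
    for p in proteins:
        zs = {rep: float(z_per_rep[rep][p]) for rep in z_per_rep if p in z_per_rep[rep]}
        rs = {rep: float(r_per_rep[rep][p]) for rep in r_per_rep if p in r_per_rep[rep]}
        combined = sum(zs.values()) / np.sqrt(len(zs))
        scores.append(AutocorrelationScore(p, rs, zs, float(combined)))
    return scores


def autocorrelation_frame(scores: list[AutocorrelationScore]) -> pd.DataFrame:
    rows = {
        s.protein: {
            **{f"r_rep{k}": v for k, v in s.r.items()},
            **{f"z_rep{k}": v for k, v in s.z.items()},
            "combined_z": s.combined_z,
        }
        for s in scores
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "protein"
    return frame.sort_values("combined_z")


def stouffer(z_values) -> float:
    """Stouffer combination: sum(z) / sqrt(k)."""
    z = np.asarray(list(z_values), dtype=float)
    return float(z.sum() / np.sqrt(len(z)))


# ---------------------------------------------------------------------------
# gene-set correlation-shift test (Brunner-Munzel)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationShift:
    median_shift: float
    statistic: float
    p: float
    n_stim: int
    n_unstim: int
    defined: bool = True


def _within_set_correlations(matrices, gene_set, min_obs) -> np.ndarray:
    out = []
    for m in _as_matrix_list(matrices):
        present = [p for p in m.proteins if p in gene_set]
        values = {p: m.profile(p) for p in present}
        for a, b in itertools.combinations(present, 2):
            r = _pairwise_complete_r(values[a], values[b], min_obs)
            if np.isfinite(r):
                out.append(r)
    return np.asarray(out)


def correlation_shift_test(
    stim, unstim, gene_set, min_obs: int = MIN_PAIRWISE_OBS
) -> CorrelationShift:
    """Brunner-Munzel test for a shift in within-set chromatogram correlations.

    Pairwise Pearson correlations among set members are computed per
    condition (pooled over replicates; pairs with fewer than ``min_obs``
    shared observations are excluded) and the two correlation
    distributions are compared.  Fewer than three valid pairs in either
    condition leaves the test undefined.
    """
    gene_set = set(gene_set)
    rs = _within_set_correlations(stim, gene_set, min_obs)
    ru = _within_set_correlations(unstim, gene_set, min_obs)
    if len(rs) < 3 or len(ru) < 3:
        return CorrelationShift(np.nan, np.nan, np.nan, len(rs), len(ru), defined=False)
    shift = float(np.median(rs) - np.median(ru))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = brunnermunzel(rs, ru, alternative="two-sided")
    if not np.isfinite(stat):
        # degenerate rank variance: decide from the stochastic-dominance
        # estimate itself (identical distributions -> no shift)
        ranks = rankdata(np.concatenate([rs, ru]))
        p_hat = (ranks[len(rs):].mean() - (len(ru) + 1) / 2) / len(rs)
        stat, p = 0.0, (1.0 if np.isclose(p_hat, 0.5) else 0.0)
    return CorrelationShift(shift, float(stat), float(p), len(rs), len(ru))


# ---------------------------------------------------------------------------
# log-odds enrichment and enrichment-map edges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogOddsResult:
    log_odds: float
    z: float
    p: float


def log_odds_enrichment(a: int, b: int, c: int, d: int) -> LogOddsResult:
    """Woolf z-test of the log odds ratio of a 2x2 table.

    The Haldane-Anscombe +0.5 correction is applied to every cell when
    any cell is zero; SE = sqrt(sum of reciprocal cells).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("contingency counts must be nonnegative")
    if np.any(cells == 0):
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    log_or = float(np.log(a_ * d_ / (b_ * c_)))
    se = float(np.sqrt(np.sum(1.0 / cells)))
    z = log_or / se
    p = float(2.0 * norm.sf(abs(z)))
    return LogOddsResult(log_or, float(z), p)


def jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def enrichment_map_edges(
    sets: GeneSetCollection, jaccard_min: float = 0.33
) -> list[tuple[str, str, float]]:
    """Term pairs whose annotated sets overlap at Jaccard >= the threshold."""
    out = []
    items = sorted(sets.sets.items())
    for (t1, s1), (t2, s2) in itertools.combinations(items, 2):
        j = jaccard(s1, s2)
        if j >= jaccard_min:
            out.append((t1, t2, j))
    return out


def enrichment_map_json(
    test: DeltaNPPITest, sets: GeneSetCollection, jaccard_min: float = 0.33
) -> dict:
    """Nodes (terms with z and q) plus Jaccard edges, as a JSON-ready dict."""
    tested = {r.term for r in test.results}
    sub = GeneSetCollection(
        {t: m for t, m in sets.sets.items() if t in tested},
        names=sets.names,
        size_filtered=sets.size_filtered,
        propagated=sets.propagated,
    )
    nodes = [
        {"term": r.term, "name": r.name, "z": r.z, "q": r.q, "delta": r.delta}
        for r in test.results
    ]
    edges = [
        {"source": t1, "target": t2, "jaccard": j}
        for t1, t2, j in enrichment_map_edges(sub, jaccard_min)
    ]
    return {"nodes": nodes, "edges": edges}


# ---------------------------------------------------------------------------
# abundance annotation of edges
# ---------------------------------------------------------------------------

def annotate_edges_with_abundance(
    network: InteractionNetwork, fold_changes
) -> pd.DataFrame:
    """Per edge, the maximum |log2 fold change| over its endpoints.

    ``fold_changes`` maps protein -> log2FC (missing proteins ignored);
    edges with both endpoints missing are left unannotated (NaN).
    """
    fc = pd.Series(fold_changes, dtype=float)
    rows = []
    for a, b in sorted(network.graph.edges):
        vals = [abs(fc[p]) for p in (a, b) if p in fc.index and np.isfinite(fc[p])]
        rows.append((a, b, max(vals) if vals else np.nan))
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "max_abs_log2fc"])


def abundance_by_overlap_class(
    comparison, annotated_a: pd.DataFrame, annotated_b: pd.DataFrame
) -> pd.DataFrame:
    """Median per-edge |log2FC| for shared / a-only / b-only edge classes."""
    lookup: dict[frozenset, float] = {}
    for frame in (annotated_a, annotated_b):
        for _, row in frame.iterrows():
            lookup[frozenset((row["protein_a"], row["protein_b"]))] = row[
                "max_abs_log2fc"
            ]
    rows = []
    for cls, edges in (
        ("shared", comparison.shared_edges),
        ("a_only", comparison.a_only_edges),
        ("b_only", comparison.b_only_edges),
    ):
        vals = [lookup[e] for e in edges if e in lookup and np.isfinite(lookup[e])]
        rows.append((cls, len(edges), float(np.median(vals)) if vals else np.nan))
    return pd.DataFrame(rows, columns=["class", "n_edges", "median_max_abs_log2fc"])
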