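"""Pre-balanced repeated random forests and the synthetic-forest step.

Progression cohorts are heavily class-imbalanced, so every forest is
grown on a *pre-balanced* sample: all progressed patients plus an
equal-size random draw (without replacement) of the non-progressed.
Variable importance is permutation importance in the classical
random-forest sense -- the mean, over trees, of the decrease in
out-of-bag prediction accuracy when one variable's values are permuted
-- averaged over many balanced forests, each with a fresh draw of the
majority class.

The *synthetic forest* ranks individual trees as candidate algorithms:
the trees saved from a preliminary balanced forest become the predictor
"variables" of a second forest (one column per tree, holding that
tree's predicted class per patient), whose permutation importances
score the trees.  The procedure is repeated over several balanced
samples; runs whose synthetic-forest out-of-bag error diverges widely
from the preliminary forest's are discarded, and trees that rank
consistently highly across the retained runs are short-listed.  Each
tree's branch structure is frozen as an explicit boolean rule
(truth-table equivalent over its 2-3 input indicators).

Forests are built from individual ``DecisionTreeClassifier`` trees with
explicit bootstrap bookkeeping, so out-of-bag membership and per-tree
predictions are first-class objects rather than estimator internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .types import ReferenceOutcome, Rule, and_, leaf, or_


@dataclass(frozen=True)
class RFConfig:
    n_forests: int = 100
    n_trees_per_forest: int = 1000
    seed: int = 0
    mtry_rule: str = "SQRT_P"
    #: runs whose synthetic-forest OOB error differs from the preliminary
    #: forest's by more than this are dropped ("widely different")
    error_divergence_tolerance: float = 0.05
    #: a tree ranks "highly" in a run when inside this top fraction
    consistency_quantile: float = 0.10
    #: fraction of retained runs in which a tree must rank highly
    consistency_min_runs: float = 0.8
    #: balanced-sample repetitions of the synthetic-forest procedure
    n_synthetic_runs: int = 5

    def __post_init__(self) -> None:
        if self.n_forests < 1 or self.n_trees_per_forest < 1 or self.n_synthetic_runs < 1:
            raise ValueError("forest counts must be >= 1")
        if not (0.0 < self.error_divergence_tolerance < 1.0):
            raise ValueError("error_divergence_tolerance must lie in (0, 1)")
        if self.mtry_rule != "SQRT_P":
            raise ValueError(f"unsupported mtry rule {self.mtry_rule!r}")
        if not (0.0 < self.consistency_quantile <= 1.0):
            raise ValueError("consistency_quantile must lie in (0, 1]")
        if not (0.0 < self.consistency_min_runs <= 1.0):
            raise ValueError("consistency_min_runs must lie in (0, 1]")


@dataclass
class ImportanceResult:
    """Averaged permutation importance over repeated balanced forests."""

    per_variable_mean_importance: dict[str, float]
    per_forest_oob_error: list[float]
    #: variables by mean importance descending (ties broken by name)
    ranking: list[str]
    #: per-forest importances, variables x forests (for dispersion checks)
    per_forest_importance: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass
class TreeAlgorithm:
    """One distinct branching algorithm harvested from saved trees."""

    tree_id: str
    variables: tuple[str, ...]
    truth_table: tuple[bool, ...]
    rule: Rule
    #: mean synthetic-forest importance over the retained runs where seen
    importance_score: float
    #: (rank, n_distinct_rules) per retained run; None when not grown
    rank_history: list[Optional[tuple[int, int]]]
    source_forest_seed: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Balanced sampling
# ---------------------------------------------------------------------------


def balanced_sample(
    outcomes: Sequence[ReferenceOutcome],
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """All minority-class ids plus an equal-size draw of the majority.

    The majority draw is without replacement; input order is preserved
    within each class.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = [o.patient_id for o in outcomes if o.progressed]
    neg = [o.patient_id for o in outcomes if not o.progressed]
    if not pos or not neg:
        raise ValueError("balanced sampling requires both classes to be non-empty")
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    take = sorted(rng.choice(len(majority), size=len(minority), replace=False).tolist())
    return list(minority) + [majority[i] for i in take]


# ---------------------------------------------------------------------------
# Bagged forest with explicit out-of-bag bookkeeping
# ---------------------------------------------------------------------------


class BaggedForest:
    """Random forest as an explicit list of bootstrapped decision trees."""

    def __init__(self, n_trees: int, rng: np.random.Generator):
        self.n_trees = n_trees
        self._rng = rng
        self.trees: list[DecisionTreeClassifier] = []
        self.oob_masks: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedForest":
        n = len(y)
        mtry = max(1, int(round(math.sqrt(X.shape[1]))))
        for _ in range(self.n_trees):
            boot = self._rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[boot] = False
            tree = DecisionTreeClassifier(
                max_features=mtry,
                random_state=int(self._rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            self.trees.append(tree)
            self.oob_masks.append(oob)
        return self

    def oob_votes(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(votes for class 1, number of OOB votes) per sample."""
        n = len(X)
        votes = np.zeros(n)
        counts = np.zeros(n)
        for tree, oob in zip(self.trees, self.oob_masks):
            if not oob.any():
                continue
            votes[oob] += tree.predict(X[oob])
            counts[oob] += 1
        return votes, counts

    def oob_error(self, X: np.ndarray, y: np.ndarray) -> float:
        """Majority-vote misclassification rate on out-of-bag samples.

        Samples never out of bag are ignored (vanishingly rare beyond
        ~30 trees); vote ties break to the positive class.
        """
        votes, counts = self.oob_votes(X)
        covered = counts > 0
        pred = votes[covered] * 2 >= counts[covered]  # tie -> class 1
        return float(np.mean(pred != y[covered].astype(bool)))

    def permutation_importance(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Mean per-tree decrease in OOB accuracy per permuted variable."""
        p = X.shape[1]
        drops = np.zeros(p)
        n_used = 0
        for tree, oob in zip(self.trees, self.oob_masks):
            if not oob.any():
                continue
            Xo, yo = X[oob], y[oob]
            base = float(np.mean(tree.predict(Xo) == yo))
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = Xp[rng.permutation(len(Xo)), j]
                drops[j] += base - float(np.mean(tree.predict(Xp) == yo))
            n_used += 1
        return drops / max(n_used, 1)

    def tree_predictions(self, X: np.ndarray) -> np.ndarray:
        """Samples x trees matrix of per-tree predicted classes."""
        return np.column_stack([t.predict(X) for t in self.trees])


# ---------------------------------------------------------------------------
# Repeated pre-balanced importance
# ---------------------------------------------------------------------------


def _align(
    features: pd.DataFrame, outcomes: Sequence[ReferenceOutcome]
) -> tuple[pd.DataFrame, pd.Series]:
    y = pd.Series(
        {o.patient_id: o.progressed for o in outcomes}, name="progressed"
    ).reindex(features.index)
    if y.isna().any():
        missing = list(features.index[y.isna()])[:3]
        raise ValueError(f"outcomes missing for patients {missing}")
    return features, y.astype(int)


def repeated_importance(
    features: pd.DataFrame,
    outcomes: Sequence[ReferenceOutcome],
    config: Optional[RFConfig] = None,
) -> ImportanceResult:
    """Average permutation importance over repeated balanced forests.

    Each forest draws a fresh balanced sample (all minority plus an
    equal majority draw), fits ``n_trees_per_forest`` trees, and
    records its OOB error and per-variable importances; the means over
    ``n_forests`` repeats form the final ranking.  Constant variables
    are retained (their importance is ~0), never dropped.
    """
    config = config or RFConfig()
    if features.shape[1] < 1:
        raise ValueError("at least one variable is required")
    X_all, y_all = _align(features, outcomes)
    counts = y_all.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 patients per class")

    master = np.random.default_rng(config.seed)
    importances = np.zeros((config.n_forests, features.shape[1]))
    oob_errors: list[float] = []
    for f in range(config.n_forests):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        ids = balanced_sample(outcomes, rng)
        X = X_all.loc[ids].to_numpy(dtype=float)
        y = y_all.loc[ids].to_numpy()
        assert int(y.sum()) * 2 == len(y), "balanced sample must have equal classes"
        forest = BaggedForest(config.n_trees_per_forest, rng).fit(X, y)
        oob_errors.append(forest.oob_error(X, y))
        importances[f] = forest.permutation_importance(X, y, rng)

    mean_imp = dict(zip(features.columns, importances.mean(axis=0)))
    ranking = sorted(mean_imp, key=lambda v: (-mean_imp[v], v))
    per_forest = pd.DataFrame(
        importances.T, index=features.columns,
        columns=[f"forest_{i}" for i in range(config.n_forests)],
    )
    return ImportanceResult(
        per_variable_mean_importance=mean_imp,
        per_forest_oob_error=oob_errors,
        ranking=ranking,
        per_forest_importance=per_forest,
    )


# ---------------------------------------------------------------------------
# Rule extraction
# ---------------------------------------------------------------------------


def _is_monotone(table: Sequence[bool], k: int) -> bool:
    for a in range(2**k):
        for j in range(k):
            if not (a >> j) & 1:
                b = a | (1 << j)
                if table[a] and not table[b]:
                    return False
    return True


def rule_from_truth_table(variables: Sequence[str], table: Sequence[bool]) -> Rule:
    """Boolean rule equivalent to an arbitrary truth table.

    Monotone tables get an irredundant positive DNF (OR of ANDs of the
    minimal true points); non-monotone tables fall back to a full
    minterm DNF with NOT literals.  Bit order matches
    ``Rule.truth_table``: variable 0 is the most significant bit.
    """
    k = len(variables)
    if len(table) != 2**k:
        raise ValueError("truth table size must be 2**len(variables)")

    def bits_of(i: int) -> tuple[bool, ...]:
        return tuple(bool((i >> (k - 1 - j)) & 1) for j in range(k))

    true_rows = [i for i in range(2**k) if table[i]]
    if not true_rows:
        return Rule("FALSE")
    if len(true_rows) == 2**k:
        return Rule("TRUE")

    def term_and(literals: list[Rule]) -> Rule:
        return literals[0] if len(literals) == 1 else and_(*literals)

    if _is_monotone(list(table), k):
        # minimal true points under the bitwise order -> positive DNF
        minimal = []
        for i in true_rows:
            bi = bits_of(i)
            dominated = any(
                o != i
                and table[o]
                and all(ob <= b for ob, b in zip(bits_of(o), bi))
                for o in true_rows
            )
            if not dominated:
                minimal.append(bi)
        terms = []
        for bi in minimal:
            lits = [leaf(variables[j]) for j in range(k) if bi[j]]
            terms.append(term_and(lits))
        return terms[0] if len(terms) == 1 else or_(*terms)

    terms = []
    for i in true_rows:
        bi = bits_of(i)
        lits = [
            leaf(variables[j]) if bi[j] else Rule("NOT", children=(leaf(variables[j]),))
            for j in range(k)
        ]
        terms.append(term_and(lits))
    return terms[0] if len(terms) == 1 else or_(*terms)


def _tree_truth_table(tree: DecisionTreeClassifier, k: int) -> tuple[bool, ...]:
    grid = np.array(
        [[(i >> (k - 1 - j)) & 1 for j in range(k)] for i in range(2**k)], dtype=float
    )
    return tuple(bool(v) for v in tree.predict(grid))


# ---------------------------------------------------------------------------
# Synthetic forest
# ---------------------------------------------------------------------------


def synthetic_forest(
    features_subset: pd.DataFrame,
    outcomes: Sequence[ReferenceOutcome],
    config: Optional[RFConfig] = None,
) -> list[TreeAlgorithm]:
    """Rank saved trees as candidate algorithms via a second forest.

    For each of ``n_synthetic_runs`` balanced samples: fit a
    preliminary forest, save its trees, build the patients x trees
    prediction matrix, fit a second forest on it, and score each tree
    by its permutation importance there.  Runs whose synthetic OOB
    error differs from the preliminary forest's by more than the
    divergence tolerance are dropped.  Trees are deduplicated by rule
    (truth-table) equivalence, with per-run rank histories aggregated
    across retained runs.
    """
    config = config or RFConfig()
    k = features_subset.shape[1]
    if not (2 <= k <= 3):
        raise ValueError("the synthetic-forest step expects a 2- or 3-variable subset")
    variables = tuple(features_subset.columns)
    X_all, y_all = _align(features_subset, outcomes)

    master = np.random.default_rng(config.seed)
    run_records: list[dict[tuple[bool, ...], tuple[int, int, float]]] = []
    info: dict[tuple[bool, ...], dict] = {}
    degenerate_any = False

    for run in range(config.n_synthetic_runs):
        run_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(run_seed)
        ids = balanced_sample(outcomes, rng)
        X = X_all.loc[ids].to_numpy(dtype=float)
        y = y_all.loc[ids].to_numpy()

        preliminary = BaggedForest(config.n_trees_per_forest, rng).fit(X, y)
        e_pre = preliminary.oob_error(X, y)
        M = preliminary.tree_predictions(X)
        if np.unique(M, axis=1).shape[1] < 2:
            degenerate_any = True

        synth = BaggedForest(config.n_trees_per_forest, rng).fit(M, y)
        e_syn = synth.oob_error(M, y)
        if abs(e_syn - e_pre) > config.error_divergence_tolerance:
            continue  # widely different error rate: run not considered
        tree_scores = synth.permutation_importance(M, y, rng)

        # deduplicate trees by branch-structure truth table; a rule's
        # score in a run is the best score among its copies
        best: dict[tuple[bool, ...], float] = {}
        for t, tree in enumerate(preliminary.trees):
            table = _tree_truth_table(tree, k)
            score = float(tree_scores[t])
            if table not in best or score > best[table]:
                best[table] = score
            if table not in info:
                info[table] = {"seed": run_seed}
        ordered = sorted(best, key=lambda tb: (-best[tb], tb))
        n_distinct = len(ordered)
        run_records.append(
            {tb: (rank + 1, n_distinct, best[tb]) for rank, tb in enumerate(ordered)}
        )

    algorithms: list[TreeAlgorithm] = []
    for table, meta in info.items():
        history: list[Optional[tuple[int, int]]] = []
        scores: list[float] = []
        for rec in run_records:
            if table in rec:
                rank, n_distinct, score = rec[table]
                history.append((rank, n_distinct))
                scores.append(score)
            else:
                history.append(None)
        algorithms.append(
            TreeAlgorithm(
                tree_id="tt_" + "".join("1" if b else "0" for b in table),
                variables=variables,
                truth_table=table,
                rule=rule_from_truth_table(variables, table),
                importance_score=float(np.mean(scores)) if scores else 0.0,
                rank_history=history,
                source_forest_seed=meta["seed"],
                degenerate=degenerate_any,
            )
        )
    algorithms.sort(key=lambda a: (-a.importance_score, a.tree_id))
    return algorithms


def select_candidates(
    tree_algorithms: Sequence[TreeAlgorithm],
    config: Optional[RFConfig] = None,
) -> list[TreeAlgorithm]:
    """Shortlist of trees that ranked consistently highly.

    A tree qualifies when, in at least ``consistency_min_runs`` of the
    retained runs, its rank fell within the top
    ``consistency_quantile`` of distinct rules (always at least the
    single top rule).  Input is already deduplicated by rule
    equivalence; ordering is by importance descending.
    """
    config = config or RFConfig()
    if not tree_algorithms:
        raise ValueError("no tree algorithms to select from")
    n_runs = len(tree_algorithms[0].rank_history)
    if n_runs == 0:
        return []
    shortlist = []
    for alg in tree_algorithms:
        highly = 0
        for entry in alg.rank_history:
            if entry is None:
                continue
            rank, n_distinct = entry
            top_k = max(1, math.ceil(config.consistency_quantile * n_distinct))
            if rank <= top_k:
                highly += 1
        if highly / n_runs >= config.consistency_min_runs:
            shortlist.append(alg)
    return shortlist
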