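"""Random-forest reduction of amino-acid property tables.

The pipeline treats the 20 standard amino acids as samples, each property
(AAindex column) as an explanatory variable, and a binary hydropathy label
(hydrophobic vs. hydrophilic) as the response.  Reduction proceeds in four
stages:

1. drop incomplete indices (``aaindex.to_index_table``),
2. prune highly correlated indices by greedy backward elimination,
3. rank the survivors by permutation variable importance (VIM) averaged over
   repeated random-forest trials, keeping only positive mean VIM,
4. nested forward selection: refit forests on growing prefixes of the ranking
   and keep the longest prefix whose mean out-of-bag (OOB) error stays at or
   below a threshold.

The VIM of a variable is the mean, over the trees of a forest, of the increase
in OOB misclassification count when that variable's OOB values are permuted::

    VIM(x_i) = (1/ntree) * sum_t (err_OOB~_t - err_OOB_t)

where ``err_OOB~_t`` counts misclassifications of tree ``t`` on its OOB
samples after permuting column ``i`` and ``err_OOB_t`` counts them on the
intact OOB samples.  With only 20 samples a single forest's VIM is noisy, so
the report aggregates ``n_trials`` independent forests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .aaindex import RESIDUES, IndexTable, PropertyIndex, to_index_table
from .errors import DegenerateLabelsError, EmptySelectionError

HYDROPHOBIC = "hydrophobic"
HYDROPHILIC = "hydrophilic"

#: Residues with positive Kyte-Doolittle hydropathy.
_KD_HYDROPHOBIC = frozenset("ACFILMV")


@dataclass(frozen=True)
class HydropathyLabels:
    """Binary water-interaction labels for the 20 residues.

    The default scheme labels residues with positive Kyte-Doolittle hydropathy
    (A, C, F, I, L, M, V) as hydrophobic and the rest as hydrophilic.  Any
    two-class labelling over the 20 residues is accepted.
    """

    labels: dict[str, str]
    scheme_name: str = "custom"

    def __post_init__(self) -> None:
        if set(self.labels) != set(RESIDUES):
            raise ValueError("labels must cover exactly the 20 standard residues")
        classes = set(self.labels.values())
        if len(classes) != 2:
            raise DegenerateLabelsError(
                f"need exactly two label classes, got {sorted(classes)}"
            )

    @classmethod
    def kyte_doolittle(cls) -> "HydropathyLabels":
        return cls(
            labels={
                r: (HYDROPHOBIC if r in _KD_HYDROPHOBIC else HYDROPHILIC)
                for r in RESIDUES
            },
            scheme_name="kyte-doolittle",
        )

    def as_array(self) -> np.ndarray:
        """0/1 vector in canonical residue order (1 = lexicographically larger class)."""
        classes = sorted(set(self.labels.values()))
        return np.array([classes.index(self.labels[r]) for r in RESIDUES], dtype=int)


@dataclass(frozen=True)
class RFConfig:
    """Forest hyper-parameters.

    ntree
        Trees per forest.
    mtry
        Variables tried per split; the string ``"sqrt"`` applies the usual
        floor(sqrt(m)) rule.
    n_trials
        Independent forests whose VIM scores are aggregated.
    seed
        Root seed; every forest, bootstrap and permutation derives its own
        stream from it via ``numpy.random.SeedSequence`` spawning, so results
        are reproducible and trials are independent.
    """

    ntree: int = 500
    mtry: int | str = "sqrt"
    n_trials: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if isinstance(self.mtry, int) and self.mtry < 1:
            raise ValueError("mtry must be >= 1")

    def resolve_mtry(self, n_features: int) -> int:
        if self.mtry == "sqrt":
            return max(1, int(np.sqrt(n_features)))
        if isinstance(self.mtry, int):
            return min(self.mtry, n_features)
        raise ValueError(f"unrecognized mtry rule: {self.mtry!r}")


@dataclass
class VIMReport:
    """Per-property permutation-importance distribution over repeated trials.

    ``trials`` is an (n_trials x m) frame of per-forest VIM scores.  ``summary``
    holds mean, sd, median and the 1-based rank by decreasing mean (ties broken
    by accession).
    """

    trials: pd.DataFrame
    scheme_name: str
    config: RFConfig
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        mean = self.trials.mean(axis=0)
        sd = self.trials.std(axis=0, ddof=1) if len(self.trials) > 1 else self.trials.std(axis=0) * 0.0
        order = sorted(self.trials.columns, key=lambda a: (-mean[a], a))
        rank = pd.Series({a: i + 1 for i, a in enumerate(order)})
        self.summary = pd.DataFrame(
            {
                "mean": mean,
                "sd": sd.fillna(0.0),
                "median": self.trials.median(axis=0),
                "rank": rank,
            }
        ).sort_values("rank")


@dataclass
class NestedSelectionResult:
    """Outcome of nested forward selection along a fixed importance ranking."""

    ranked_properties: list[str]
    step_errors: pd.DataFrame  # (trials_per_step x k_max) per-trial OOB error %
    mean_step_errors: pd.Series  # indexed by prefix size k
    threshold_pct: float
    selected: list[str]


# ---------------------------------------------------------------------------
# Correlation pruning

def prune_correlated(
    table: IndexTable, threshold: float = 0.85
) -> tuple[IndexTable, list[dict[str, object]]]:
    """Greedy backward elimination of highly correlated properties.

    While some pair has Pearson ``|r| > threshold`` over the 20 residue
    values, the pair with the highest ``|r|`` is found and the member with the
    larger mean ``|r|`` against all remaining properties is dropped (ties
    broken toward the lexicographically larger accession).  The removal log
    records each dropped accession and the pair that triggered it.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"correlation threshold must lie in (0, 1], got {threshold}")
    df = table.to_frame()
    # Constant columns have undefined r; treat their correlation as 0.
    corr = df.corr().abs().fillna(0.0).to_numpy()
    np.fill_diagonal(corr, 0.0)
    names = list(df.columns)
    alive = list(range(len(names)))
    log: list[dict[str, object]] = []
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() <= threshold:
            break
        i_s, j_s = np.unravel_index(int(sub.argmax()), sub.shape)
        a, b = alive[i_s], alive[j_s]
        mean_a = sub[i_s].sum() / max(1, len(alive) - 1)
        mean_b = sub[j_s].sum() / max(1, len(alive) - 1)
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = a if names[a] > names[b] else b
        keep = b if drop == a else a
        log.append(
            {
                "dropped": names[drop],
                "partner": names[keep],
                "abs_r": float(corr[a, b]),
            }
        )
        alive.remove(drop)
    kept = [names[i] for i in alive]
    return table.subset(kept), log


# ---------------------------------------------------------------------------
# Forest machinery

def stratified_bootstrap(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """In-bag indices: sample each class with replacement to its own size."""
    parts = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        parts.append(rng.choice(idx, size=idx.size, replace=True))
    return np.concatenate(parts)


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    in_bag: np.ndarray,
    mtry: int,
    random_state: int = 0,
) -> DecisionTreeClassifier:
    """Fit one CART tree on the given in-bag sample."""
    tree = DecisionTreeClassifier(
        max_features=min(mtry, X.shape[1]), random_state=random_state
    )
    tree.fit(X[in_bag], y[in_bag])
    return tree


def tree_oob_permutation_delta(
    tree: DecisionTreeClassifier,
    X: np.ndarray,
    y: np.ndarray,
    oob: np.ndarray,
    column: int,
    permutation: Sequence[int],
) -> int:
    """``err_OOB~ - err_OOB`` of one tree for one variable and a fixed permutation.

    ``permutation`` indexes into the OOB rows and rearranges column ``column``
    among them; both error terms are misclassification *counts* on the OOB set.
    """
    X_oob = X[oob]
    err = int((tree.predict(X_oob) != y[oob]).sum())
    X_perm = X_oob.copy()
    X_perm[:, column] = X_oob[np.asarray(permutation), column]
    err_perm = int((tree.predict(X_perm) != y[oob]).sum())
    return err_perm - err


def single_tree_vim(
    X: np.ndarray,
    y: np.ndarray,
    in_bag: np.ndarray,
    column: int,
    permutation: Sequence[int],
    mtry: int | None = None,
    random_state: int = 0,
) -> int:
    """Permutation VIM of a one-tree forest with an explicit bootstrap.

    With ``ntree = 1`` the VIM formula reduces to the single tree's
    (permuted - unpermuted) OOB misclassification difference; this entry point
    exists so that the formula can be checked against hand-worked examples.
    """
    n = X.shape[0]
    oob = np.setdiff1d(np.arange(n), np.asarray(in_bag))
    tree = fit_tree(X, y, np.asarray(in_bag), mtry or X.shape[1], random_state)
    return tree_oob_permutation_delta(tree, X, y, oob, column, permutation)


def _forest_vim(
    X: np.ndarray, y: np.ndarray, config: RFConfig, rng: np.random.Generator
) -> np.ndarray:
    """VIM vector of one forest: mean over trees of permuted-minus-intact OOB errors."""
    n, m = X.shape
    mtry = config.resolve_mtry(m)
    deltas = np.zeros(m)
    all_idx = np.arange(n)
    for _ in range(config.ntree):
        in_bag = stratified_bootstrap(y, rng)
        oob = np.setdiff1d(all_idx, in_bag)
        tree = fit_tree(X, y, in_bag, mtry, random_state=int(rng.integers(2**31 - 1)))
        if oob.size == 0:
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        err = int((tree.predict(X_oob) != y_oob).sum())
        # One stacked predict call for all m permuted variants of the OOB block.
        stacked = np.broadcast_to(X_oob, (m,) + X_oob.shape).copy()
        for j in range(m):
            perm = rng.permutation(oob.size)
            stacked[j, :, j] = X_oob[perm, j]
        preds = tree.predict(stacked.reshape(m * oob.size, m)).reshape(m, oob.size)
        deltas += (preds != y_oob).sum(axis=1) - err
    return deltas / config.ntree


def permutation_vim(
    table: IndexTable, labels: HydropathyLabels, config: RFConfig
) -> VIMReport:
    """Permutation variable importance aggregated over repeated forests.

    Each trial fits one forest of ``config.ntree`` trees on stratified
    bootstrap samples of the 20 residues predicting the binary hydropathy
    label, and scores every property by the mean increase in OOB
    misclassification count under permutation of that property's OOB values.
    Trials use independent streams spawned from ``config.seed``.
    """
    X = table.to_numpy()
    y = labels.as_array()
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("labels contain a single class")
    children = np.random.SeedSequence(config.seed).spawn(config.n_trials)
    rows = [_forest_vim(X, y, config, np.random.default_rng(c)) for c in children]
    trials = pd.DataFrame(rows, columns=table.properties)
    return VIMReport(trials=trials, scheme_name=labels.scheme_name, config=config)


def filter_by_mean_vim(report: VIMReport) -> list[str]:
    """Accessions with strictly positive mean VIM, by decreasing mean.

    Ties are broken lexicographically by accession so the ranking is
    deterministic.  An empty result is allowed.
    """
    mean = report.trials.mean(axis=0)
    kept = [a for a in report.trials.columns if mean[a] > 0]
    return sorted(kept, key=lambda a: (-mean[a], a))


# ---------------------------------------------------------------------------
# Nested forward selection

def forest_oob_error_pct(
    X: np.ndarray, y: np.ndarray, ntree: int, mtry: int, rng: np.random.Generator
) -> float:
    """OOB error of one forest as a percentage of voted samples.

    Each sample is predicted by majority vote of the trees for which it was
    out of bag; ties go to the lexicographically smaller class.  Samples never
    out of bag (rare for ntree more than a few dozen) are excluded from the
    denominator.
    """
    n = X.shape[0]
    votes = np.zeros((n, 2), dtype=int)
    all_idx = np.arange(n)
    for _ in range(ntree):
        in_bag = stratified_bootstrap(y, rng)
        oob = np.setdiff1d(all_idx, in_bag)
        tree = fit_tree(X, y, in_bag, mtry, random_state=int(rng.integers(2**31 - 1)))
        if oob.size == 0:
            continue
        pred = tree.predict(X[oob]).astype(int)
        votes[oob, pred] += 1
    voted = votes.sum(axis=1) > 0
    if not voted.any():
        return float("nan")
    pred = (votes[:, 1] > votes[:, 0]).astype(int)  # tie -> class 0
    wrong = int((pred[voted] != y[voted]).sum())
    return 100.0 * wrong / int(voted.sum())


def nested_selection(
    ranked: Sequence[str],
    table: IndexTable,
    labels: HydropathyLabels,
    threshold_pct: float = 2.0,
    trials_per_step: int = 100,
    config: RFConfig | None = None,
) -> NestedSelectionResult:
    """Forward selection over growing prefixes of an importance ranking.

    For each prefix size ``k`` the mean OOB error percentage over
    ``trials_per_step`` forests is computed; the selected subset is the prefix
    ending just before the first step whose mean error exceeds
    ``threshold_pct`` (the full ranking if no step exceeds it).
    """
    config = config or RFConfig()
    ranked = list(ranked)
    missing = set(ranked) - set(table.properties)
    if missing:
        raise ValueError(f"ranked accessions absent from table: {sorted(missing)}")
    if not ranked:
        raise EmptySelectionError("ranking is empty", step_errors=None)
    y = labels.as_array()
    full = table.subset(ranked).to_numpy()
    children = np.random.SeedSequence(config.seed).spawn(len(ranked))
    step_cols: dict[int, np.ndarray] = {}
    means: dict[int, float] = {}
    stop_k: int | None = None
    for k, child in zip(range(1, len(ranked) + 1), children):
        Xk = full[:, :k]
        mtry = config.resolve_mtry(k)
        rng = np.random.default_rng(child)
        errs = np.array(
            [
                forest_oob_error_pct(Xk, y, config.ntree, mtry, rng)
                for _ in range(trials_per_step)
            ]
        )
        step_cols[k] = errs
        means[k] = float(np.nanmean(errs))
        if means[k] > threshold_pct:
            stop_k = k
            break
    step_errors = pd.DataFrame(step_cols)
    mean_step_errors = pd.Series(means, name="mean_oob_error_pct")
    if stop_k == 1:
        raise EmptySelectionError(
            f"mean OOB error {means[1]:.2f}% at the first step already exceeds "
            f"the {threshold_pct}% threshold",
            step_errors=step_errors,
        )
    selected = ranked[: (stop_k - 1) if stop_k is not None else len(ranked)]
    return NestedSelectionResult(
        ranked_properties=ranked,
        step_errors=step_errors,
        mean_step_errors=mean_step_errors,
        threshold_pct=threshold_pct,
        selected=selected,
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline

@dataclass
class PipelineResult:
    """Reduced table plus a machine-readable account of every stage."""

    table: IndexTable
    vim_report: VIMReport
    nested: NestedSelectionResult
    report: dict


def reduce_pipeline(
    indices: Iterable[PropertyIndex],
    labels: HydropathyLabels | None = None,
    config: RFConfig | None = None,
    *,
    corr_threshold: float = 0.85,
    error_threshold_pct: float = 2.0,
    trials_per_step: int = 100,
) -> PipelineResult:
    """Full reduction: NA removal, correlation pruning, VIM ranking, nesting.

    The returned report records the property count entering and leaving every
    stage, the per-property VIM summary, the per-step error curve, and the
    selected accessions.
    """
    labels = labels or HydropathyLabels.kyte_doolittle()
    config = config or RFConfig()
    indices = list(indices)
    table, dropped_na = to_index_table(indices)
    pruned, prune_log = prune_correlated(table, threshold=corr_threshold)
    vim = permutation_vim(pruned, labels, config)
    ranked = filter_by_mean_vim(vim)
    if not ranked:
        raise EmptySelectionError("no property has positive mean VIM")
    nested = nested_selection(
        ranked,
        pruned,
        labels,
        threshold_pct=error_threshold_pct,
        trials_per_step=trials_per_step,
        config=config,
    )
    selected_table = pruned.subset(nested.selected)
    report = {
        "labels_scheme": labels.scheme_name,
        "config": {
            "ntree": config.ntree,
            "mtry": config.mtry,
            "n_trials": config.n_trials,
            "seed": config.seed,
            "corr_threshold": corr_threshold,
            "error_threshold_pct": error_threshold_pct,
            "trials_per_step": trials_per_step,
        },
        "stage_counts": {
            "input": len(indices),
            "dropped_na": len(dropped_na),
            "after_na_removal": table.n_properties,
            "dropped_correlated": len(prune_log),
            "after_correlation_pruning": pruned.n_properties,
            "positive_mean_vim": len(ranked),
            "selected": len(nested.selected),
        },
        "dropped_na": dropped_na,
        "correlation_removals": prune_log,
        "vim_summary": vim.summary.to_dict(orient="index"),
        "step_mean_errors_pct": {int(k): v for k, v in nested.mean_step_errors.items()},
        "selected": nested.selected,
    }
    return PipelineResult(table=selected_table, vim_report=vim, nested=nested, report=report)
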