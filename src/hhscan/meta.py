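"""Cross-dataset meta-analysis of per-GO score effects with a permutation null.

For each dataset, the hypothesis-generation model fits one slope of the
selection score per singletized GO category. Each slope is shrunk one
standard error toward zero (clamped at zero), summed across datasets, and
compared against a pooled empirical null built by refitting the model under
size-preserving permutations of the gene -> GO assignment (OTHER genes,
including intergenic regions, are never permuted). GO categories whose
observed sum falls strictly below / above the pooled 90% interval form
Group 1 / Group 2 for the hypothesis-testing phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import OTHER
from .clogit import FitResult, ModelSpec, fit

logger = logging.getLogger(__name__)

N_PERMUTATIONS = 100
CI_LEVEL = 0.90
#: excluded from the group lists on biological grounds (catch-all category)
DEFAULT_EXCLUDE = ("GO:0044237",)


def heuristic_score(beta: float, sigma: float) -> float:
    """Effect size shrunk one standard error toward zero, clamped at zero.

    Odd in beta and non-expansive: |score| <= |beta|.
    """
    if sigma < 0:
        raise ValueError("standard error must be non-negative")
    if beta > sigma:
        return beta - sigma
    if beta < -sigma:
        return beta + sigma
    return 0.0


def sum_scores(per_dataset: Mapping[str, Mapping[str, float]]) -> dict[str, float]:
    """Sum shrunken scores across datasets; a GO absent from a dataset
    (no genes, or a failed fit) contributes zero."""
    out: dict[str, float] = {}
    for scores in per_dataset.values():
        for go, s in scores.items():
            out[go] = out.get(go, 0.0) + s
    return out


def permute_go(assignments: pd.Series, rng: np.random.Generator) -> pd.Series:
    """Shuffle singletized GO labels among non-OTHER genes.

    Every category keeps its exact size; OTHER genes are untouched.
    """
    out = assignments.copy()
    movable = assignments.index[assignments != OTHER]
    labels = assignments.loc[movable].to_numpy().copy()
    rng.shuffle(labels)
    out.loc[movable] = labels
    return out


def null_interval(pooled_sums: Sequence[float], level: float = CI_LEVEL
                  ) -> tuple[float, float]:
    """Pooled empirical central interval over all permutation x GO sums."""
    arr = np.asarray(pooled_sums, dtype=float)
    if arr.size == 0:
        raise ValueError("empty permutation pool")
    tail = (1.0 - level) / 2.0
    return float(np.quantile(arr, tail)), float(np.quantile(arr, 1.0 - tail))


def classify_groups(
    observed: Mapping[str, float],
    interval: tuple[float, float],
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Place each GO sum below / inside / above the interval.

    Ties go inside (strict inequalities). Excluded GO IDs are dropped from
    the group lists with a log entry, whatever their position.
    """
    low, high = interval
    if not observed:
        return pd.DataFrame(
            columns=["sum", "classification", "excluded"],
            index=pd.Index([], name="go"),
        )
    rows = []
    for go, s in observed.items():
        side = "below" if s < low else ("above" if s > high else "inside")
        excluded = go in set(exclude)
        if excluded and side != "inside":
            logger.info("GO %s is %s the interval but excluded by request", go, side)
        rows.append({"go": go, "sum": s, "classification": side,
                     "excluded": excluded})
    return pd.DataFrame(rows).set_index("go")


def group_lists(classification: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Group 1 = below the interval, Group 2 = above (exclusions removed)."""
    keep = ~classification["excluded"]
    g1 = classification.index[keep & (classification["classification"] == "below")]
    g2 = classification.index[keep & (classification["classification"] == "above")]
    return sorted(g1), sorted(g2)


# ---------------------------------------------------------------------------
# driver


@dataclass
class MetaResult:
    observed: pd.DataFrame  # per-GO: per-dataset scores, sum, classification
    interval: tuple[float, float]
    slopes: dict[str, pd.DataFrame]  # dataset -> per-GO (beta, se)
    group1: list[str]
    group2: list[str]
    n_permutations: int
    seed: int


def _go_slopes(result: FitResult, term: str) -> dict[str, tuple[float, float]]:
    """Per-GO (beta, se) of the ``term:go=<ID>`` interaction slopes."""
    prefix = f"{term}:go="
    out = {}
    for name in result.params.index:
        if name.startswith(prefix):
            go = name[len(prefix):]
            if go != OTHER:
                out[go] = (float(result.params[name]), float(result.bse[name]))
    return out


def _dataset_scores(df: pd.DataFrame, assignment: pd.Series, spec: ModelSpec,
                    score_term: str) -> dict[str, float]:
    data = df.copy()
    data["go"] = data["gene"].map(assignment).fillna(OTHER)
    try:
        res = fit(data, spec)
    except (ValueError, KeyError) as exc:  # degenerate permuted design
        logger.warning("fit failed (%s); dataset contributes 0", exc)
        return {}
    if not res.converged:
        logger.warning("fit did not converge (%s); dataset contributes 0",
                       res.message)
        return {}
    return {go: heuristic_score(b, s) for go, (b, s) in
            _go_slopes(res, score_term).items()}


def run_meta(
    studies: Mapping[str, pd.DataFrame],
    assignment: pd.Series,
    spec: ModelSpec,
    score_term: str = "hh",
    n_permutations: int = N_PERMUTATIONS,
    level: float = CI_LEVEL,
    seed: int = 0,
    exclude: Sequence[str] = DEFAULT_EXCLUDE,
) -> MetaResult:
    """Full meta-analysis: observed sums, permutation pool, classification.

    ``studies`` maps dataset name to a stratified SNP table with columns
    ``gene`` (NaN/absent gene means OTHER), the model's predictors and the
    response; ``assignment`` is the singletized gene -> GO mapping shared by
    all datasets, permuted as a whole in each of the ``n_permutations``
    rounds.
    """
    rng = np.random.default_rng(seed)
    per_dataset = {name: _dataset_scores(df, assignment, spec, score_term)
                   for name, df in studies.items()}
    observed_sums = sum_scores(per_dataset)

    pool: list[float] = []
    for _ in range(n_permutations):
        permuted = permute_go(assignment, rng)
        perm_scores = {name: _dataset_scores(df, permuted, spec, score_term)
                       for name, df in studies.items()}
        pool.extend(sum_scores(perm_scores).values())
    interval = null_interval(pool, level=level)
    classification = classify_groups(observed_sums, interval, exclude=exclude)

    slopes = {}
    for name, scores in per_dataset.items():
        df = pd.DataFrame.from_dict(scores, orient="index", columns=["score"])
        slopes[name] = df
        classification[f"score:{name}"] = classification.index.map(
            lambda go: scores.get(go, 0.0)
        )
    g1, g2 = group_lists(classification)
    return MetaResult(
        observed=classification,
        interval=interval,
        slopes=slopes,
        group1=g1,
        group2=g2,
        n_permutations=n_permutations,
        seed=seed,
    )
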