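"""Cohort-level edge rankings and brain-age-delta group comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EdgeRanking",
    "DeltaReport",
    "aggregate_edge_scores",
    "top_edges",
    "brain_age_delta",
    "compare_delta_groups",
]


@dataclass
class EdgeRanking:
    """Edges ordered by non-increasing mean score."""

    edges: list[tuple[int, int, float]]  # (row, col, score)
    labels: tuple[str, ...] | None
    quadrants: list[str]
    total_candidates: int
    symmetric: bool

    def index_pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j, _ in self.edges]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (i, j, score), q in zip(self.edges, self.quadrants):
            rows.append(
                {
                    "region_i": self.labels[i] if self.labels else str(i),
                    "region_j": self.labels[j] if self.labels else str(j),
                    "quadrant": q,
                    "score": score,
                }
            )
        return pd.DataFrame(rows, columns=["region_i", "region_j", "quadrant", "score"])


def aggregate_edge_scores(per_subject_S) -> np.ndarray:
    """Entrywise mean over per-subject (and per-run) edge-score matrices."""
    mats = [np.asarray(S, dtype=float) for S in per_subject_S]
    if not mats:
        raise ValueError("need at least one edge-score matrix")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("edge-score matrices must share a shape")
    return np.mean(mats, axis=0)


def _quadrant_of(i: int, j: int, half: int) -> str:
    return ("L" if i < half else "R") + ("L" if j < half else "R")


def top_edges(
    S_mean: np.ndarray,
    k: int,
    labels=None,
    symmetric: bool = False,
    magnitude: bool = False,
) -> EdgeRanking:
    """The k highest-scoring edges, ties broken by (row, col) index order.

    By default all n^2 entries are candidates (LR and RL blocks are distinct);
    with ``symmetric=True``, (i, j) and (j, i) are averaged and only
    off-diagonal pairs i < j are candidates. ``magnitude=True`` ranks by
    absolute score (attention scores carry an arbitrary sign: a downstream
    weight can negate them without changing the model), reporting |score|.
    """
    S = np.asarray(S_mean, dtype=float)
    if magnitude:
        S = np.abs(S)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("edge-score matrix must be square")
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    half = n // 2
    if symmetric:
        iu, ju = np.triu_indices(n, k=1)
        scores = (S[iu, ju] + S[ju, iu]) / 2.0
        cand = list(zip(iu.tolist(), ju.tolist(), scores.tolist()))
    else:
        ii, jj = np.unravel_index(np.arange(n * n), (n, n))
        cand = list(zip(ii.tolist(), jj.tolist(), S.ravel().tolist()))
    if k > len(cand):
        raise ValueError(f"k={k} exceeds the {len(cand)} candidate edges")
    cand.sort(key=lambda e: (-e[2], e[0], e[1]))
    chosen = cand[:k]
    return EdgeRanking(
        edges=chosen,
        labels=tuple(labels) if labels is not None else None,
        quadrants=[_quadrant_of(i, j, half) for i, j, _ in chosen],
        total_candidates=len(cand),
        symmetric=symmetric,
    )


def brain_age_delta(predicted, chronological) -> np.ndarray:
    """delta_i = predicted_i - chronological_i (days)."""
    p = np.asarray(predicted, dtype=float)
    c = np.asarray(chronological, dtype=float)
    if p.shape != c.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {c.shape}")
    return p - c


@dataclass
class DeltaComparison:
    age_group: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    statistic: float
    p_value: float
    significant: bool


@dataclass
class DeltaReport:
    comparisons: list[DeltaComparison]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.comparisons])


def compare_delta_groups(
    deltas,
    group_labels,
    age_group_labels,
    alpha: float = 0.05,
) -> DeltaReport:
    """Two-group location test on brain-age deltas within each age stratum.

    The test is the group-indicator linear model, i.e. the pooled-variance
    two-sample t-test, two-sided, flagged at p < ``alpha``.
    """
    deltas = np.asarray(deltas, dtype=float)
    groups = np.asarray(group_labels)
    strata = np.asarray(age_group_labels)
    if not (len(deltas) == len(groups) == len(strata)):
        raise ValueError("deltas, group labels, and age-group labels must align")
    if not np.all(np.isfinite(deltas)):
        raise ValueError("deltas must be finite")
    comparisons = []
    for stratum in sorted(set(strata.tolist()), key=str):
        mask = strata == stratum
        levels = sorted(set(groups[mask].tolist()), key=str)
        if len(levels) != 2:
            raise ValueError(
                f"age stratum {stratum!r} needs exactly 2 groups, found {levels}"
            )
        a = deltas[mask & (groups == levels[0])]
        b = deltas[mask & (groups == levels[1])]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"age stratum {stratum!r}: each group needs >= 2 subjects "
                f"(got {len(a)} and {len(b)})"
            )
        t, p = stats.ttest_ind(a, b, equal_var=True)
        comparisons.append(
            DeltaComparison(
                age_group=str(stratum),
                group_a=str(levels[0]),
                group_b=str(levels[1]),
                n_a=int(len(a)),
                n_b=int(len(b)),
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                statistic=float(t),
                p_value=float(p),
                significant=bool(p < alpha),
            )
        )
    return DeltaReport(comparisons=comparisons)
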