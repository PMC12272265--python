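"""Along-tract group statistics: Kruskal-Wallis omnibus, Dunn's pairwise
post hoc test, and Holm familywise adjustment, plus per-position profile
summaries. Implemented from the rank-based closed forms (with tie
correction); tests cross-check against library oracles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "TractProfile",
    "GroupComparison",
    "summarize_profile",
    "kruskal_wallis",
    "dunn_posthoc",
    "holm_adjust",
    "compare_groups",
    "read_profiles",
    "tract_report",
]


@dataclass
class TractProfile:
    tract_id: str
    subject_id: str
    group: str
    values: np.ndarray  # length-P metric samples along the tract

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("a tract profile is a 1D position series")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")


def summarize_profile(profiles: list[TractProfile], group: str):
    """Position-wise mean and standard-deviation band for one group."""
    members = [p for p in profiles if p.group == group]
    if not members:
        raise ValueError(f"no profiles in group {group!r}")
    lengths = {len(p.values) for p in members}
    if len(lengths) != 1:
        raise ValueError(f"profiles in group {group!r} have differing lengths {lengths}")
    stack = np.stack([p.values for p in members])
    return stack.mean(axis=0), stack.std(axis=0)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected H and its chi-square p-value ((g-1) df).

    H = 12/(N(N+1)) * sum R_j^2/n_j - 3(N+1), divided by the tie correction
    1 - sum(t^3 - t)/(N^3 - N). Identical constant groups give H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(groups)
    N = pooled.size
    if N < 3:
        raise ValueError("need a total of at least 3 observations")
    ranks = rankdata(pooled, method="average")
    H = 0.0
    offset = 0
    for g in groups:
        rj = ranks[offset : offset + g.size].sum()
        H += rj * rj / g.size
        offset += g.size
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    correction = 1.0 - _tie_term(pooled) / (N**3 - N)
    if correction == 0.0:
        return 0.0, 1.0  # every observation tied
    H /= correction
    p = float(stats.chi2.sf(H, df=len(groups) - 1))
    return float(H), p


def dunn_posthoc(groups) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Dunn z statistics and two-sided raw p-values.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)]
    with T the tie term over the pooled sample. Pairs are ordered by
    ``itertools.combinations`` over group index.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Dunn's test needs at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = rankdata(pooled, method="average")
    mean_ranks = []
    offset = 0
    for g in groups:
        mean_ranks.append(ranks[offset : offset + g.size].mean())
        offset += g.size
    var_base = N * (N + 1) / 12.0 - _tie_term(pooled) / (12.0 * (N - 1))
    zs, ps = [], []
    for i, j in itertools.combinations(range(len(groups)), 2):
        denom = np.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        zs.append(z)
        ps.append(float(2.0 * stats.norm.sf(abs(z))))
    return np.asarray(zs), np.asarray(ps)


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment.

    Sort ascending, multiply the i-th smallest by (m - i), enforce
    monotonicity with a running maximum, cap at 1, and restore input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, ix in enumerate(order):
        running = max(running, (m - i) * p[ix])
        adjusted[ix] = min(1.0, running)
    return adjusted


@dataclass
class GroupComparison:
    group_names: list[str]
    h_statistic: float
    omnibus_p: float
    pairs: list[tuple[str, str]]
    z_statistics: np.ndarray
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    significant_001: np.ndarray  # report flag mirroring "p < 0.01" labels
    significant_005: np.ndarray


def compare_groups(samples: dict[str, np.ndarray]) -> GroupComparison:
    """The full battery for one tract: Kruskal-Wallis, Dunn, Holm."""
    names = list(samples)
    groups = [np.asarray(samples[name], dtype=float) for name in names]
    H, p = kruskal_wallis(groups)
    z, raw = dunn_posthoc(groups)
    adj = holm_adjust(raw)
    return GroupComparison(
        group_names=names,
        h_statistic=H,
        omnibus_p=p,
        pairs=list(itertools.combinations(names, 2)),
        z_statistics=z,
        raw_p=raw,
        adjusted_p=adj,
        significant_001=adj < 0.01,
        significant_005=adj < 0.05,
    )


REQUIRED_COLUMNS = ("subject_id", "group", "position", "value")


def read_profiles(path: str, tract_column: str = "tract") -> pd.DataFrame:
    """Read a per-tract profile CSV, validating the schema row by row."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile CSV {path} is missing columns {missing}")
    for col in ("position", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based indexing
            raise ValueError(
                f"profile CSV {path}: non-numeric {col!r} at line {int(bad[0]) + 2}"
            )
        if coerced.isna().any():
            raise ValueError(
                f"profile CSV {path}: missing {col!r} at line "
                f"{int(df.index[coerced.isna()][0]) + 2}"
            )
        df[col] = coerced
    if tract_column not in df.columns:
        df[tract_column] = "tract_0"
    return df


def tract_report(df: pd.DataFrame, tract_column: str = "tract",
                 holm_scope: str = "tract") -> pd.DataFrame:
    """Run the battery per tract and per position-pooled metric.

    ``holm_scope`` is "tract" (adjust within each tract, the default) or
    "all" (adjust jointly across every tract's pairwise p-values).
    """
    if holm_scope not in ("tract", "all"):
        raise ValueError("holm_scope must be 'tract' or 'all'")
    rows = []
    raw_cache = []
    for tract, sub in df.groupby(tract_column, sort=True):
        samples = {
            str(grp): g["value"].to_numpy(float) for grp, g in sub.groupby("group", sort=True)
        }
        comp = compare_groups(samples)
        for (a, b), z, rp, ap in zip(comp.pairs, comp.z_statistics,
                                     comp.raw_p, comp.adjusted_p):
            rows.append(
                {
                    "tract": str(tract),
                    "H": comp.h_statistic,
                    "omnibus_p": comp.omnibus_p,
                    "group_a": a,
                    "group_b": b,
                    "z": float(z),
                    "raw_p": float(rp),
                    "adjusted_p": float(ap),
                }
            )
            raw_cache.append(float(rp))
    out = pd.DataFrame(rows)
    if holm_scope == "all" and len(out):
        out["adjusted_p"] = holm_adjust(np.asarray(raw_cache))
    if len(out):
        out["significant_005"] = out["adjusted_p"] < 0.05
        out["significant_001"] = out["adjusted_p"] < 0.01
    return out
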