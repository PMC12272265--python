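"""Synthetic aging-cohort simulator with known ground truth.

Generates cohorts with a bimodal age distribution and configurable trait
margins (two age clusters; three-allele genotype; binary sex, diet, and
immune-gene variants), a hub-structured symmetric connectome whose planted
edges decay linearly with a latent "effective brain age", and behavior metrics
that are monotone in that latent age. The planted structure is returned so
edge-recovery and group-contrast analyses can be scored against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cohort_io import (
    BehaviorMatrix,
    Cohort,
    Connectome,
    RegionAtlas,
    Subject,
    TraitVector,
    behavior_column_maxima,
    normalize_behavior,
    rank_normalize_connectome,
    write_cohort,
)

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "planted_edge_recovery",
           "write_simulated", "DEFAULT_METRICS"]

#: Water-maze style metrics: three time-based (capped at 60 s), three scaled by maximum.
DEFAULT_METRICS = (
    "time_to_platform",
    "time_in_target_quadrant",
    "time_thigmotaxis",
    "swim_distance",
    "swim_velocity",
    "winding_number",
)

AGE_CUTOFF_DAYS = 450.0  # 15-month boundary between the two clusters


@dataclass
class SimConfig:
    """Defaults mirror a two-cluster mouse aging cohort (N=170, 66 younger / 104 old;
    genotype 58/56/56; 82 M / 88 F; 95 mNos2 / 75 hNOS2; 113 control / 57 HFD),
    with per-age-cluster trait fractions."""

    n_subjects: int = 170
    n_regions: int = 32
    young_fraction: float = 66 / 170
    young_age_mean: float = 412.0
    young_age_sd: float = 22.0
    young_age_range: tuple[float, float] = (370.0, 449.0)
    old_age_mean: float = 520.0
    old_age_sd: float = 38.0
    old_age_range: tuple[float, float] = (450.0, 605.0)
    # per-age-cohort trait fractions (young, old)
    apoe_fractions: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (17 / 66, 24 / 66, 25 / 66),
        (41 / 104, 32 / 104, 31 / 104),
    )
    hfd_fraction: tuple[float, float] = (33 / 66, 24 / 104)
    hnos2_fraction: tuple[float, float] = (38 / 66, 37 / 104)
    male_fraction: tuple[float, float] = (32 / 66, 50 / 104)
    # planted aging signal
    planted_edge_count: int = 8
    edge_decay_slope: float = 0.004  # weight drop per effective-age day
    edge_weight_intercept: float = 0.92  # planted weight at the youngest age
    partner_baseline_boost: float = 0.0  # extra baseline for planted partner nodes
    diet_effect_days: float = 60.0   # applied in the old cluster only
    nos2_effect_days: float = 50.0   # applied in the old cluster only
    sex_effect_days: float = 40.0    # applied in the young cluster only
    behavior_midpoint_days: float = 465.0
    behavior_softness_days: float = 18.0
    effective_age_noise_sd: float = 8.0
    connectome_noise_sd: float = 0.05
    behavior_noise_sd: float = 0.10
    behavior_trials: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_regions % 2 != 0 or self.n_regions < 4:
            raise ValueError("n_regions must be an even number >= 4")
        if self.planted_edge_count % 2 != 0:
            raise ValueError("planted_edge_count must be even (edges are mirrored)")
        if self.planted_edge_count > self.n_regions - 4:
            raise ValueError("too many planted edges for this region count")
        fracs = [self.young_fraction, *self.hfd_fraction, *self.hnos2_fraction,
                 *self.male_fraction]
        fracs += [f for cohort in self.apoe_fractions for f in cohort]
        if any(not (0 <= f <= 1) for f in fracs):
            raise ValueError("all group fractions must lie in [0, 1]")


@dataclass
class GroundTruth:
    planted_edges: list[tuple[int, int]]  # (i, j) with i < j, mirrored pairs included
    hub_nodes: tuple[int, int]
    effective_age: dict[str, float]
    effects: dict[str, float]
    raw_connectomes: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    raw_behaviors: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_edges": [list(e) for e in self.planted_edges],
                "hub_nodes": list(self.hub_nodes),
                "effective_age": self.effective_age,
                "effects": self.effects,
            },
            indent=2,
            sort_keys=True,
        )


def _largest_remainder(n: int, fractions) -> list[int]:
    """Integer counts summing to n, proportional to fractions."""
    fr = np.asarray(fractions, dtype=float)
    fr = fr / fr.sum()
    raw = fr * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base.tolist()


def _binary_assignment(count_one: int, total: int, rng: np.random.Generator) -> np.ndarray:
    v = np.zeros(total)
    v[:count_one] = 1.0
    rng.shuffle(v)
    return v


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def simulate_cohort(cfg: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a normalized cohort plus the planted ground truth.

    Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_regions
    half = n // 2
    N = cfg.n_subjects
    n_young = int(round(cfg.young_fraction * N))
    n_old = N - n_young
    if n_young < 1 or n_old < 1:
        raise ValueError("both age clusters must be nonempty")

    ages = np.concatenate(
        [
            _truncated_normal(rng, cfg.young_age_mean, cfg.young_age_sd,
                              *cfg.young_age_range, n_young),
            _truncated_normal(rng, cfg.old_age_mean, cfg.old_age_sd,
                              *cfg.old_age_range, n_old),
        ]
    )
    is_old = np.concatenate([np.zeros(n_young), np.ones(n_old)])

    # per-cohort trait assignment matching the configured margins
    apoe = np.empty(N)
    sex = np.empty(N)
    diet = np.empty(N)
    nos2 = np.empty(N)
    for cohort_ix, sl in ((0, slice(0, n_young)), (1, slice(n_young, N))):
        size = sl.stop - sl.start
        counts = _largest_remainder(size, cfg.apoe_fractions[cohort_ix])
        block = np.concatenate(
            [np.full(c, v) for c, v in zip(counts, (0.0, 0.5, 1.0))]
        )
        rng.shuffle(block)
        apoe[sl] = block
        sex[sl] = _binary_assignment(int(round(cfg.male_fraction[cohort_ix] * size)), size, rng)
        diet[sl] = _binary_assignment(int(round(cfg.hfd_fraction[cohort_ix] * size)), size, rng)
        nos2[sl] = _binary_assignment(int(round(cfg.hnos2_fraction[cohort_ix] * size)), size, rng)
    # encoding: sex uses 0 = male, 1 = female in the trait vector; the
    # male_fraction margin applies to the 0 label
    sex = 1.0 - sex

    # effective brain age: chronological + trait accelerations + noise.
    # diet/NOS2 acceleration applies in the old cluster, sex in the young.
    trait_effect = (
        cfg.diet_effect_days * diet * is_old
        + cfg.nos2_effect_days * nos2 * is_old
        + cfg.sex_effect_days * (1.0 - sex) * (1.0 - is_old)
    )
    eff = ages + trait_effect + rng.normal(0.0, cfg.effective_age_noise_sd, size=N)

    # base connectome with two hemisphere-mirrored hub nodes
    base = rng.uniform(0.05, 0.45, size=(n, n))
    base = (base + base.T) / 2.0
    hub_l = half // 2
    hub_r = hub_l + half
    for hub in (hub_l, hub_r):
        base[hub, :] += 0.25
        base[:, hub] += 0.25
    np.fill_diagonal(base, 0.0)

    # planted edges attach to the hubs, mirrored across hemispheres
    per_side = cfg.planted_edge_count // 2
    candidates = [i for i in range(half) if i != hub_l]
    partners = rng.choice(candidates, size=per_side, replace=False)
    planted: list[tuple[int, int]] = []
    for p in partners:
        planted.append(tuple(sorted((hub_l, int(p)))))
        planted.append(tuple(sorted((hub_r, int(p) + half))))

    for p_ix in partners:
        for node in (int(p_ix), int(p_ix) + half):
            base[node, :] += cfg.partner_baseline_boost
            base[:, node] += cfg.partner_baseline_boost
    np.fill_diagonal(base, 0.0)

    atlas = RegionAtlas(
        tuple(f"L_region_{i:02d}" for i in range(half))
        + tuple(f"R_region_{i:02d}" for i in range(half))
    )
    ids = [f"m{k:03d}" for k in range(N)]
    eff_ref = float(cfg.young_age_range[0])

    raw_behaviors: dict[str, np.ndarray] = {}
    raw_connectomes: dict[str, np.ndarray] = {}
    trials = cfg.behavior_trials
    eff_span = cfg.old_age_range[1] + cfg.diet_effect_days + cfg.nos2_effect_days - eff_ref
    for k in range(N):
        m = base.copy()
        w = cfg.edge_weight_intercept - cfg.edge_decay_slope * (eff[k] - eff_ref)
        w = float(np.clip(w, 0.02, 1.2))
        for i, j in planted:
            m[i, j] = w
            m[j, i] = w
        if cfg.connectome_noise_sd > 0:
            noise = rng.normal(0.0, cfg.connectome_noise_sd, size=(n, n))
            noise = (noise + noise.T) / 2.0
            m = m + noise
            np.fill_diagonal(m, 0.0)
        raw_connectomes[ids[k]] = np.clip(m, 0.0, None)

        # saturating monotone map of effective age: behavior separates the
        # age clusters cleanly but carries little fine-grained age signal,
        # which stays in the connectome's planted edges
        a = float(1.0 / (1.0 + np.exp(-(eff[k] - cfg.behavior_midpoint_days)
                                      / cfg.behavior_softness_days)))
        trial_ix = np.arange(trials, dtype=float)
        nz = lambda: rng.normal(0.0, cfg.behavior_noise_sd, size=trials)  # noqa: E731
        cols = [
            np.clip(60 * (0.30 + 0.25 * a) - 1.2 * trial_ix + 60 * nz(), 1.0, 60.0),
            np.clip(60 * (0.50 - 0.18 * a) + 0.8 * trial_ix + 60 * nz(), 0.0, 60.0),
            np.clip(60 * (0.20 + 0.15 * a) + 60 * nz(), 0.0, 60.0),
            np.clip(8.0 + 4.5 * a - 0.3 * trial_ix + 10 * nz(), 0.5, None),
            np.clip(0.24 - 0.06 * a + 0.3 * nz(), 0.02, None),
            np.clip(3.0 + 3.5 * a + 8 * nz(), 0.0, None),
        ]
        raw_behaviors[ids[k]] = np.column_stack(cols)

    kinds = ["time", "time", "time", "scale", "scale", "scale"]
    col_max = behavior_column_maxima(list(raw_behaviors.values()))
    subjects = []
    label_sex = {0.0: "M", 1.0: "F"}
    label_diet = {0.0: "control", 1.0: "HFD"}
    label_nos2 = {0.0: "mNos2", 1.0: "hNOS2"}
    label_apoe = {0.0: "APOE2", 0.5: "APOE3", 1.0: "APOE4"}
    for k, sid in enumerate(ids):
        conn = rank_normalize_connectome(Connectome(raw_connectomes[sid], atlas))
        behav = normalize_behavior(raw_behaviors[sid], kinds, list(DEFAULT_METRICS),
                                   column_maxima=col_max)
        subjects.append(
            Subject(
                id=sid,
                age_days=float(ages[k]),
                traits=TraitVector(sex=sex[k], diet=diet[k], nos2=nos2[k], apoe=apoe[k]),
                behavior=behav,
                connectome=conn,
                raw_traits={
                    "sex": label_sex[sex[k]],
                    "diet": label_diet[diet[k]],
                    "nos2": label_nos2[nos2[k]],
                    "apoe": label_apoe[apoe[k]],
                },
            )
        )
    cohort = Cohort(subjects=subjects, atlas=atlas)
    truth = GroundTruth(
        planted_edges=planted,
        hub_nodes=(hub_l, hub_r),
        effective_age={sid: float(e) for sid, e in zip(ids, eff)},
        effects={
            "diet_effect_days": cfg.diet_effect_days,
            "nos2_effect_days": cfg.nos2_effect_days,
            "sex_effect_days": cfg.sex_effect_days,
            "edge_decay_slope": cfg.edge_decay_slope,
        },
        raw_connectomes=raw_connectomes,
        raw_behaviors=raw_behaviors,
    )
    return cohort, truth


def planted_edge_recovery(ranking, truth: GroundTruth, top_fraction: float):
    """Score an edge ranking against the planted set.

    ``ranking`` is an :class:`~connage.interpretation.EdgeRanking` (or any
    object with ordered ``edges`` index pairs and ``total_candidates``).
    Returns ``(recall within the top fraction, mean normalized rank)``; an
    edge counts as recovered if either orientation appears.
    """
    if not truth.planted_edges:
        raise ValueError("ground truth has no planted edges")
    if not (0 <= top_fraction <= 1):
        raise ValueError("top_fraction must lie in [0, 1]")
    pairs = [tuple(sorted(e)) for e in ranking.index_pairs()]
    total = ranking.total_candidates
    cutoff = int(np.floor(top_fraction * total))
    position: dict[tuple[int, int], int] = {}
    for rank, pair in enumerate(pairs):
        position.setdefault(pair, rank)
    planted = {tuple(sorted(e)) for e in truth.planted_edges}
    hits = 0
    norm_ranks = []
    for e in planted:
        pos = position.get(e)
        if pos is None:
            norm_ranks.append(1.0)
            continue
        norm_ranks.append((pos + 1) / total)
        if pos < cutoff:
            hits += 1
    recall = hits / len(planted)
    return recall, float(np.mean(norm_ranks))


def write_simulated(cohort: Cohort, truth: GroundTruth, out_dir: str) -> None:
    """Write the cohort CSV layout plus the ground-truth JSON file."""
    import os

    write_cohort(
        cohort,
        out_dir,
        raw_connectomes=truth.raw_connectomes or None,
        raw_behaviors=truth.raw_behaviors or None,
    )
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        fh.write(truth.to_json() + "\n")
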