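"""Cohort data model, tabular I/O, and input normalization.

All values entering the network are scaled into [0, 1]: connectomes by dense
rank normalization, binary traits to {0, 1}, the three-allele genotype to
{0, 0.5, 1}, and behavior columns either by the 60-second trial cap
(time-based metrics) or by their cohort-wide column maximum.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "RegionAtlas",
    "Connectome",
    "TraitVector",
    "BehaviorMatrix",
    "Subject",
    "Cohort",
    "TRAIT_ORDER",
    "APOE_ENCODING",
    "DEFAULT_BINARY_MAPS",
    "encode_traits",
    "rank_normalize_connectome",
    "normalize_behavior",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

TRIAL_CAP_SECONDS = 60.0

#: Order in which traits are laid out in the model's 1D input.
TRAIT_ORDER = ("sex", "diet", "nos2", "apoe")

APOE_ENCODING = {"APOE2": 0.0, "APOE3": 0.5, "APOE4": 1.0}

#: label -> {0, 1} dictionaries for the binary traits (configurable).
DEFAULT_BINARY_MAPS = {
    "sex": {"M": 0.0, "F": 1.0},
    "diet": {"control": 0.0, "HFD": 1.0},
    "nos2": {"mNos2": 0.0, "hNOS2": 1.0},
}


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered region labels, left-hemisphere block first."""

    region_labels: tuple[str, ...]

    def __post_init__(self):
        labels = tuple(str(x) for x in self.region_labels)
        object.__setattr__(self, "region_labels", labels)
        if self.n < 4 or self.n % 2 != 0:
            raise ValueError(f"atlas needs an even region count >= 4, got {self.n}")
        if len(set(labels)) != self.n:
            raise ValueError("atlas region labels must be unique")

    @property
    def n(self) -> int:
        return len(self.region_labels)

    @property
    def hemisphere_split(self) -> int:
        return self.n // 2


@dataclass
class Connectome:
    matrix: np.ndarray
    atlas: RegionAtlas
    normalized: bool = False
    raw_matrix: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError(f"connectome must be square, got shape {self.matrix.shape}")
        if self.matrix.shape[0] != self.atlas.n:
            raise ValueError(
                f"connectome size {self.matrix.shape[0]} does not match atlas n={self.atlas.n}"
            )
        if np.any(self.matrix < 0):
            raise ValueError("connectome entries must be nonnegative")


@dataclass(frozen=True)
class TraitVector:
    sex: float
    diet: float
    nos2: float
    apoe: float

    def __post_init__(self):
        for name in ("sex", "diet", "nos2"):
            v = getattr(self, name)
            if v not in (0.0, 1.0):
                raise ValueError(f"trait {name!r} must be 0 or 1, got {v}")
        if self.apoe not in (0.0, 0.5, 1.0):
            raise ValueError(f"trait 'apoe' must be in {{0, 0.5, 1}}, got {self.apoe}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in TRAIT_ORDER], dtype=float)


@dataclass
class BehaviorMatrix:
    values: np.ndarray  # trials x metrics, in [0, 1]
    metric_names: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.metric_names = tuple(self.metric_names)
        if self.values.ndim != 2:
            raise ValueError("behavior matrix must be 2D (trials x metrics)")
        if self.values.shape[1] != len(self.metric_names):
            raise ValueError("metric_names length must match column count")


@dataclass
class Subject:
    id: str
    age_days: float
    traits: TraitVector
    behavior: BehaviorMatrix
    connectome: Connectome
    raw_traits: dict[str, str] = field(default_factory=dict)


@dataclass
class Cohort:
    subjects: list[Subject]
    atlas: RegionAtlas

    def __len__(self) -> int:
        return len(self.subjects)

    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    def ages(self) -> np.ndarray:
        return np.array([s.age_days for s in self.subjects], dtype=float)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Stack (connectomes, traits, behavior, ages) for batched training."""
        X = np.stack([s.connectome.matrix for s in self.subjects])
        T = np.stack([s.traits.as_array() for s in self.subjects])
        Bm = np.stack([s.behavior.values for s in self.subjects])
        y = self.ages()
        return X, T, Bm, y

    def subset(self, indices) -> "Cohort":
        return Cohort([self.subjects[i] for i in indices], self.atlas)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def encode_traits(
    sex_raw: str,
    diet_raw: str,
    apoe_raw: str,
    nos2_raw: str,
    binary_maps: dict[str, dict[str, float]] | None = None,
) -> TraitVector:
    """Map raw labels onto the [0, 1] trait encoding.

    APOE2/3/4 map to 0/0.5/1; the binary traits use two-value dictionaries
    (defaults in :data:`DEFAULT_BINARY_MAPS`).
    """
    maps = binary_maps or DEFAULT_BINARY_MAPS
    if apoe_raw not in APOE_ENCODING:
        raise ValueError(
            f"unknown APOE label {apoe_raw!r}; permitted: {sorted(APOE_ENCODING)}"
        )
    vals = {}
    for name, raw in (("sex", sex_raw), ("diet", diet_raw), ("nos2", nos2_raw)):
        mapping = maps[name]
        if raw not in mapping:
            raise ValueError(
                f"unknown {name} label {raw!r}; permitted: {sorted(mapping)}"
            )
        vals[name] = float(mapping[raw])
    return TraitVector(sex=vals["sex"], diet=vals["diet"], nos2=vals["nos2"],
                       apoe=APOE_ENCODING[apoe_raw])


def rank_normalize_connectome(c: "Connectome | np.ndarray") -> "Connectome | np.ndarray":
    """Dense-rank the weight multiset and divide by the maximum rank.

    Equal weights share a rank; the minimum value maps to rank 0 so absent
    connections score 0 and the output lies in [0, 1]. An all-equal matrix
    maps to all zeros. Accepts a :class:`Connectome` (returned normalized,
    raw matrix preserved) or a bare square array (returns an array).
    """
    as_array = not isinstance(c, Connectome)
    m = np.asarray(c if as_array else c.matrix, dtype=float)
    if np.any(m < 0):
        raise ValueError("connectome entries must be nonnegative")
    ranks = rankdata(m.ravel(), method="dense").astype(float) - 1.0
    max_rank = ranks.max()
    if max_rank > 0:
        ranks /= max_rank
    out = ranks.reshape(m.shape)
    if as_array:
        return out
    return Connectome(matrix=out, atlas=c.atlas, normalized=True, raw_matrix=m)


def normalize_behavior(
    raw: np.ndarray,
    metric_kinds: list[str],
    metric_names: list[str] | None = None,
    column_maxima: np.ndarray | None = None,
) -> BehaviorMatrix:
    """Scale a trials x metrics block into [0, 1].

    Time-based columns (kind ``"time"``) are divided by the 60 s trial cap;
    any value above the cap is an error. Other columns are divided by
    ``column_maxima`` (cohort-wide maxima; computed from ``raw`` when absent),
    all-zero columns staying zero.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("behavior matrix must be 2D (trials x metrics)")
    if len(metric_kinds) != raw.shape[1]:
        raise ValueError("metric_kinds length must match column count")
    names = tuple(metric_names) if metric_names else tuple(
        f"metric_{j}" for j in range(raw.shape[1])
    )
    out = raw.copy()
    for j, kind in enumerate(metric_kinds):
        col = out[:, j]
        if kind == "time":
            if np.any(col > TRIAL_CAP_SECONDS):
                raise ValueError(
                    f"time metric {names[j]!r} exceeds the {TRIAL_CAP_SECONDS:.0f} s trial cap"
                )
            out[:, j] = col / TRIAL_CAP_SECONDS
        else:
            cmax = float(column_maxima[j]) if column_maxima is not None else float(col.max())
            if cmax > 0:
                out[:, j] = col / cmax
    return BehaviorMatrix(values=out, metric_names=names)


def behavior_column_maxima(blocks: list[np.ndarray]) -> np.ndarray:
    """Cohort-wide per-column maxima across all subjects' raw behavior blocks."""
    stacked = np.concatenate([np.asarray(b, dtype=float) for b in blocks], axis=0)
    return stacked.max(axis=0)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ("id", "age_days", "sex", "diet", "apoe", "nos2")


def _read_connectome_csv(path: str, subject_id: str) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(
            f"non-square connectome for subject {subject_id!r}: shape {mat.shape} in {path}"
        )
    return mat, [str(c) for c in df.columns]


def read_cohort(
    metadata_path: str,
    connectome_dir: str,
    behavior_dir: str,
    time_metrics: list[str] | None = None,
    binary_maps: dict | None = None,
) -> Cohort:
    """Load and normalize a cohort from the on-disk CSV layout.

    ``metadata_path`` lists one row per subject (columns ``id, age_days, sex,
    diet, apoe, nos2``); ``<connectome_dir>/<id>.csv`` is a labeled square
    matrix and ``<behavior_dir>/<id>.csv`` a trials x metrics table. Columns
    whose name appears in ``time_metrics`` (default: names starting with
    ``"time"``) are treated as time-based during behavior normalization.
    """
    meta = pd.read_csv(metadata_path, dtype={"id": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata is missing columns: {missing_cols}")

    atlas: RegionAtlas | None = None
    raw_connectomes: dict[str, np.ndarray] = {}
    raw_behaviors: dict[str, pd.DataFrame] = {}
    for sid in meta["id"]:
        cpath = os.path.join(connectome_dir, f"{sid}.csv")
        bpath = os.path.join(behavior_dir, f"{sid}.csv")
        if not os.path.exists(cpath):
            raise FileNotFoundError(f"no connectome file for subject {sid!r}: {cpath}")
        if not os.path.exists(bpath):
            raise FileNotFoundError(f"no behavior file for subject {sid!r}: {bpath}")
        mat, labels = _read_connectome_csv(cpath, sid)
        if atlas is None:
            atlas = RegionAtlas(tuple(labels))
        elif tuple(labels) != atlas.region_labels:
            raise ValueError(f"subject {sid!r} uses a different region atlas")
        raw_connectomes[sid] = mat
        raw_behaviors[sid] = pd.read_csv(bpath)

    assert atlas is not None
    first = next(iter(raw_behaviors.values()))
    metric_names = [str(c) for c in first.columns]
    for sid, df in raw_behaviors.items():
        if [str(c) for c in df.columns] != metric_names or df.shape != first.shape:
            raise ValueError(f"behavior shape/columns differ for subject {sid!r}")
    if time_metrics is None:
        kinds = ["time" if name.startswith("time") else "scale" for name in metric_names]
    else:
        kinds = ["time" if name in time_metrics else "scale" for name in metric_names]
    col_max = behavior_column_maxima([df.to_numpy(float) for df in raw_behaviors.values()])

    subjects = []
    for row in meta.itertuples(index=False):
        sid = str(row.id)
        traits = encode_traits(str(row.sex), str(row.diet), str(row.apoe), str(row.nos2),
                               binary_maps=binary_maps)
        conn = rank_normalize_connectome(Connectome(raw_connectomes[sid], atlas))
        behav = normalize_behavior(
            raw_behaviors[sid].to_numpy(float), kinds, metric_names, column_maxima=col_max
        )
        age = float(row.age_days)
        if age <= 0:
            raise ValueError(f"subject {sid!r} has nonpositive age_days {age}")
        subjects.append(
            Subject(
                id=sid,
                age_days=age,
                traits=traits,
                behavior=behav,
                connectome=conn,
                raw_traits={"sex": str(row.sex), "diet": str(row.diet),
                            "apoe": str(row.apoe), "nos2": str(row.nos2)},
            )
        )
    return Cohort(subjects=subjects, atlas=atlas)


def write_cohort(
    cohort: Cohort,
    out_dir: str,
    raw_connectomes: dict[str, np.ndarray] | None = None,
    raw_behaviors: dict[str, np.ndarray] | None = None,
    raw_trait_labels: dict[str, dict[str, str]] | None = None,
) -> None:
    """Write the CSV layout :func:`read_cohort` consumes.

    Raw (unnormalized) values are written when provided so that a read/write
    round trip re-derives identical normalized data.
    """
    os.makedirs(out_dir, exist_ok=True)
    cdir = os.path.join(out_dir, "connectomes")
    bdir = os.path.join(out_dir, "behavior")
    os.makedirs(cdir, exist_ok=True)
    os.makedirs(bdir, exist_ok=True)
    labels = list(cohort.atlas.region_labels)
    rows = []
    for s in cohort.subjects:
        raw = s.raw_traits if s.raw_traits else (raw_trait_labels or {}).get(s.id, {})
        rows.append(
            {
                "id": s.id,
                "age_days": repr(float(s.age_days)),
                "sex": raw.get("sex", s.traits.sex),
                "diet": raw.get("diet", s.traits.diet),
                "apoe": raw.get("apoe", s.traits.apoe),
                "nos2": raw.get("nos2", s.traits.nos2),
            }
        )
        cm = (
            raw_connectomes[s.id]
            if raw_connectomes is not None
            else (s.connectome.raw_matrix if s.connectome.raw_matrix is not None
                  else s.connectome.matrix)
        )
        pd.DataFrame(cm, index=labels, columns=labels).to_csv(
            os.path.join(cdir, f"{s.id}.csv"), float_format="%.12g"
        )
        bm = raw_behaviors[s.id] if raw_behaviors is not None else s.behavior.values
        pd.DataFrame(bm, columns=list(s.behavior.metric_names)).to_csv(
            os.path.join(bdir, f"{s.id}.csv"), index=False, float_format="%.12g"
        )
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "metadata.csv"), index=False)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_cohort(cohort: Cohort) -> list[str]:
    """Check all type invariants; returns a list of violations (empty = valid)."""
    violations: list[str] = []
    n = cohort.atlas.n
    if n % 2 != 0 or n < 4:
        violations.append(f"atlas: region count {n} is not an even number >= 4")
    behavior_shape = None
    for s in cohort.subjects:
        if s.age_days <= 0:
            violations.append(f"subject {s.id}: age_days must be positive, got {s.age_days}")
        m = s.connectome.matrix
        if m.shape != (n, n):
            violations.append(f"subject {s.id}: connectome shape {m.shape} != ({n}, {n})")
        if np.any(m < 0):
            violations.append(f"subject {s.id}: connectome has negative entries")
        if s.connectome.normalized:
            if m.size and (m.min() < 0 or m.max() > 1):
                violations.append(f"subject {s.id}: normalized connectome outside [0, 1]")
            if np.any(m > 0) and not np.isclose(m.max(), 1.0):
                violations.append(
                    f"subject {s.id}: normalized nonzero connectome must attain 1"
                )
        b = s.behavior.values
        if behavior_shape is None:
            behavior_shape = b.shape
        elif b.shape != behavior_shape:
            violations.append(
                f"subject {s.id}: behavior shape {b.shape} != cohort shape {behavior_shape}"
            )
        if b.size and (b.min() < 0 or b.max() > 1 + 1e-12):
            violations.append(f"subject {s.id}: behavior values outside [0, 1]")
        t = s.traits.as_array()
        if np.any((t < 0) | (t > 1)):
            violations.append(f"subject {s.id}: trait values outside [0, 1]")
    return violations
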