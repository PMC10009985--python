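"""Construction and diagnosis of blocked paired-choice designs.

The target design mirrors the study instrument: 24 paired tasks (48 job
profiles) from the 128-profile full factorial, blocked into 3 blocks of 8
tasks, two blocks per respondent.  The original design was produced by a
statistics package's orthogonal main-effects routine; only the criteria it
optimised are known — level balance, orthogonality, minimum overlap and
utility balance — so we build designs by a seeded random-swap search over
those criteria.

The search initialises every attribute column to an (as-)balanced shuffled
level assignment over the ``2 * n_tasks`` profile slots and then only ever
swaps two slots within one attribute column.  Level counts are invariant
under such moves, so level balance is optimal by construction and the
search minimises the remaining penalty terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import AttributeSchema, Profile, SchemaError, enumerate_full_factorial


@dataclass
class PairedDesign:
    """A blocked sequence of two-alternative choice tasks."""

    tasks: list  # of (task_id, profile_A, profile_B)
    block_of: dict  # task_id -> block index
    n_blocks: int
    blocks_per_respondent: int = 2

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    @property
    def n_profiles(self) -> int:
        return 2 * len(self.tasks)

    @property
    def tasks_per_block(self) -> int:
        return self.n_tasks // self.n_blocks

    def profiles(self) -> list:
        return [p for _, a, b in self.tasks for p in (a, b)]

    def block_tasks(self, block: int) -> list:
        return [tid for tid, _, _ in self.tasks if self.block_of[tid] == block]

    def to_csv(self, path, schema: AttributeSchema) -> None:
        rows = []
        for tid, pa, pb in self.tasks:
            for alt, prof in (("A", pa), ("B", pb)):
                rows.append(
                    {
                        "task_id": tid,
                        "block": self.block_of[tid],
                        "alternative": alt,
                        **dict(zip(schema.names, prof)),
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, schema: AttributeSchema, blocks_per_respondent: int = 2):
        df = pd.read_csv(path)
        tasks, block_of = [], {}
        for tid, grp in df.groupby("task_id", sort=True):
            grp = grp.set_index("alternative")
            pa = tuple(grp.loc["A", list(schema.names)])
            pb = tuple(grp.loc["B", list(schema.names)])
            tasks.append((int(tid), pa, pb))
            block_of[int(tid)] = int(grp["block"].iloc[0])
        n_blocks = df["block"].nunique()
        return cls(tasks, block_of, n_blocks, blocks_per_respondent)


@dataclass
class DesignDiagnostics:
    """The four classical design criteria, computed over all profiles.

    level_balance: attribute -> {level: frequency over all profiles}.
    orthogonality: max absolute pairwise Pearson correlation between
    encoded attribute columns.  overlap: per task, number of attributes
    with identical levels in both alternatives.  utility_balance: per
    task, choice probability of alternative A under the supplied prior.
    """

    level_balance: dict
    orthogonality: float
    overlap: np.ndarray
    mean_overlap: float
    utility_balance: np.ndarray
    max_utility_imbalance: float


def _profile_matrix(profiles, schema: AttributeSchema) -> np.ndarray:
    return np.array([schema.encode_profile(p) for p in profiles])


def diagnose_design(
    design: PairedDesign, schema: AttributeSchema, prior=None
) -> DesignDiagnostics:
    """Compute level balance, orthogonality, overlap and utility balance.

    ``prior`` is a coefficient vector over the encoded columns (defaults
    to zero, under which every task is perfectly utility-balanced at 0.5).
    """
    profiles = design.profiles()
    for p in profiles:
        schema.validate_profile(p)
    if prior is None:
        prior = np.zeros(len(schema.encoded_columns))
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (len(schema.encoded_columns),):
        raise ValueError("prior dimension does not match encoded schema")

    level_balance = {
        a.name: {lv: sum(p[i] == lv for p in profiles) for lv in a.levels}
        for i, a in enumerate(schema.attributes)
    }
    X = _profile_matrix(profiles, schema)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr)  # constant columns carry no correlation signal
    k = corr.shape[0]
    orth = float(np.max(np.abs(corr - np.eye(k)))) if k > 1 else 0.0

    overlap = np.array(
        [sum(la == lb for la, lb in zip(pa, pb)) for _, pa, pb in design.tasks]
    )
    xa = X[0::2]
    xb = X[1::2]
    pA = expit((xa - xb) @ prior)
    return DesignDiagnostics(
        level_balance=level_balance,
        orthogonality=orth,
        overlap=overlap,
        mean_overlap=float(overlap.mean()),
        utility_balance=pA,
        max_utility_imbalance=float(np.max(np.abs(pA - 0.5))),
    )


# ---------------------------------------------------------------------------
# Design search


def _encoding_luts(schema):
    """Per-attribute arrays mapping level index -> encoded columns."""
    return [
        np.array([a.encode_level(lv) for lv in a.levels]) for a in schema.attributes
    ]


def _penalty(cols, luts, prior, weights):
    """Weighted penalty over orthogonality, overlap and utility balance.

    ``cols``: level-index array of shape (n_profiles, n_attributes); rows
    2t and 2t+1 are the two alternatives of task t.  Level balance is held
    optimal by the move set and contributes 0 by construction.
    """
    X = np.hstack([luts[j][cols[:, j]] for j in range(cols.shape[1])])
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Z = Xc / sd
    corr = (Z.T @ Z) / len(Z)
    k = corr.shape[0]
    orth = float(np.sum((corr - np.eye(k)) ** 2)) / max(k * (k - 1), 1)

    same = cols[0::2] == cols[1::2]
    overlap = float(same.mean())

    pA = expit((X[0::2] - X[1::2]) @ prior)
    util = float(np.mean((pA - 0.5) ** 2))
    w_orth, w_overlap, w_util = weights
    return w_orth * orth + w_overlap * overlap + w_util * util


def _balanced_columns(schema, n_profiles, rng):
    """Per-attribute level assignment with counts differing by at most 1."""
    cols = np.empty((n_profiles, len(schema.attributes)), dtype=int)
    for j, a in enumerate(schema.attributes):
        reps = -(-n_profiles // len(a.levels))
        col = np.tile(np.arange(len(a.levels)), reps)[:n_profiles]
        rng.shuffle(col)
        cols[:, j] = col
    return cols


def build_paired_design(
    schema: AttributeSchema,
    n_tasks: int = 24,
    n_blocks: int = 3,
    prior=None,
    seed: int = 0,
    n_iter: int = 4000,
    weights=(1.0, 1.0, 1.0),
    blocks_per_respondent: int = 2,
):
    """Seeded stochastic search for a blocked paired main-effects design.

    Minimises a weighted penalty of encoded-column correlation, within-task
    attribute overlap and utility imbalance under ``prior`` (level balance
    is exact by construction).  Identical inputs and seed give identical
    designs.  Returns ``(PairedDesign, DesignDiagnostics)``.
    """
    if n_tasks % n_blocks != 0:
        raise ValueError("n_tasks must be divisible by n_blocks")
    n_full = schema.n_profiles
    if n_tasks > n_full * (n_full - 1) // 2:
        raise ValueError("n_tasks exceeds the number of distinct profile pairs")
    k = len(schema.encoded_columns)
    if prior is None:
        prior = np.zeros(k)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (k,):
        raise ValueError("prior dimension does not match encoded schema")

    rng = np.random.default_rng(seed)
    n_profiles = 2 * n_tasks
    cols = _balanced_columns(schema, n_profiles, rng)
    _repair_self_pairs(cols, rng)
    luts = _encoding_luts(schema)
    best = _penalty(cols, luts, prior, weights)
    penalty_trace = [best]
    n_attr = len(schema.attributes)
    for _ in range(n_iter):
        j = int(rng.integers(n_attr))
        i1, i2 = rng.choice(n_profiles, size=2, replace=False)
        if cols[i1, j] == cols[i2, j]:
            penalty_trace.append(best)
            continue
        cols[i1, j], cols[i2, j] = cols[i2, j], cols[i1, j]
        if _is_self_pair(cols, i1) or _is_self_pair(cols, i2):
            cols[i1, j], cols[i2, j] = cols[i2, j], cols[i1, j]
            penalty_trace.append(best)
            continue
        cand = _penalty(cols, luts, prior, weights)
        if cand <= best:
            best = cand
        else:
            cols[i1, j], cols[i2, j] = cols[i2, j], cols[i1, j]
        penalty_trace.append(best)

    profiles = [
        tuple(a.levels[cols[i, j]] for j, a in enumerate(schema.attributes))
        for i in range(n_profiles)
    ]
    tasks = [(t, profiles[2 * t], profiles[2 * t + 1]) for t in range(n_tasks)]
    block_of = _assign_task_blocks(tasks, schema, n_blocks, rng)
    design = PairedDesign(tasks, block_of, n_blocks, blocks_per_respondent)
    design.penalty_trace = penalty_trace
    diag = diagnose_design(design, schema, prior)
    return design, diag


def _is_self_pair(cols, i):
    t = i // 2
    return bool(np.all(cols[2 * t] == cols[2 * t + 1]))


def _repair_self_pairs(cols, rng):
    n_attr = cols.shape[1]
    for t in range(len(cols) // 2):
        guard = 0
        while np.all(cols[2 * t] == cols[2 * t + 1]):
            j = int(rng.integers(n_attr))
            i2 = int(rng.integers(len(cols)))
            cols[2 * t + 1, j], cols[i2, j] = cols[i2, j], cols[2 * t + 1, j]
            guard += 1
            if guard > 100:  # pathological one-attribute schemas
                raise ValueError("cannot avoid self-paired tasks for this schema")


def _assign_task_blocks(tasks, schema, n_blocks, rng):
    """Greedy penalty-balanced assignment of tasks to blocks.

    Tasks are assigned one at a time (in a seeded random order) to the
    unfilled block where they least increase the block-level level-count
    imbalance, then task order within the mapping is fixed by task id.
    """
    n_tasks = len(tasks)
    per_block = n_tasks // n_blocks
    level_index = {
        a.name: {lv: i for i, lv in enumerate(a.levels)} for a in schema.attributes
    }
    counts = [
        {a.name: np.zeros(len(a.levels)) for a in schema.attributes}
        for _ in range(n_blocks)
    ]
    sizes = [0] * n_blocks
    block_of = {}
    order = rng.permutation(n_tasks)
    for t in order:
        tid, pa, pb = tasks[t]
        best_b, best_cost = None, None
        for b in range(n_blocks):
            if sizes[b] >= per_block:
                continue
            cost = 0.0
            for prof in (pa, pb):
                for a, lv in zip(schema.attributes, prof):
                    c = counts[b][a.name].copy()
                    c[level_index[a.name][lv]] += 1
                    cost += float(np.var(c))
            if best_cost is None or cost < best_cost:
                best_b, best_cost = b, cost
        block_of[tid] = best_b
        sizes[best_b] += 1
        for prof in (pa, pb):
            for a, lv in zip(schema.attributes, prof):
                counts[best_b][a.name][level_index[a.name][lv]] += 1
    return block_of


def assign_blocks(
    design: PairedDesign,
    n_respondents: int,
    blocks_per_respondent: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform seeded draw of distinct blocks per respondent.

    Returns a table with one row per respondent and ordered columns
    ``block_1 .. block_k``; each respondent answers every task of each
    assigned block (e.g. 2 blocks x 8 tasks = 16 tasks).
    """
    if blocks_per_respondent > design.n_blocks:
        raise ValueError("blocks_per_respondent exceeds n_blocks")
    rng = np.random.default_rng(seed)
    rows = [
        rng.choice(design.n_blocks, size=blocks_per_respondent, replace=False)
        for _ in range(n_respondents)
    ]
    return pd.DataFrame(
        rows,
        columns=[f"block_{i + 1}" for i in range(blocks_per_respondent)],
        index=pd.RangeIndex(n_respondents, name="respondent_id"),
    )
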