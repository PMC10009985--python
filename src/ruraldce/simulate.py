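"""Synthetic respondents and choices under random utility theory.

The study's raw choices are not public, so every downstream stage is
exercised on simulated data whose preference structure matches the
published estimates: a mixed-logit process with the reported means and
standard deviations, a three-class latent-class process with shares
29.8/41.7/28.5%, and an optional age x service-year interaction (younger
respondents value the shorter mandatory service more).

Choices follow the random utility model: each alternative's utility is
x'beta plus an independent standard Gumbel disturbance and the alternative
with the larger utility is chosen, so P(A) = logistic(x_A'beta - x_B'beta).
Gumbel noise is generated by inverse-CDF transform of uniform draws for
portable determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AttributeSchema, ChoiceDataset, default_schema
from .design import PairedDesign, assign_blocks

#: Coefficient order shared with AttributeSchema.encoded_columns for the
#: default six-attribute schema.
DEFAULT_COLUMNS = (
    "salary",
    "housing_superior",
    "drug_supply_adequate",
    "service_oneyear",
    "management_supportive",
    "workload_normal",
)

#: Published mixed-logit estimates for the rural-job attributes
#: (means; SDs of the random coefficients; salary is fixed, per ETB/month).
REFERENCE_MIXL_MEANS = pd.Series(
    [0.0002371, 0.28, 1.01, 0.47, 0.44, 0.45], index=list(DEFAULT_COLUMNS)
)
REFERENCE_MIXL_SDS = pd.Series(
    [0.0, 0.65, 1.13, 0.98, 0.74, 0.01], index=list(DEFAULT_COLUMNS)
)

#: Published three-class latent-class estimates (per-class coefficient
#: vectors, same column order) and class shares.
REFERENCE_LCM_COEFS = pd.DataFrame(
    {
        "class_1": [0.0003078, 0.86, 1.47, 1.69, -0.22, 0.31],
        "class_2": [4.53e-06, 0.16, 0.91, -0.08, 0.71, 0.48],
        "class_3": [0.0006824, -0.26, -0.09, -0.01, 0.83, 0.56],
    },
    index=list(DEFAULT_COLUMNS),
)
REFERENCE_LCM_SHARES = np.array([0.298, 0.417, 0.285])

#: Published standard errors accompanying the estimates above.
REFERENCE_MIXL_SE_MEANS = pd.Series(
    [0.0000248, 0.11, 0.12, 0.10, 0.10, 0.09], index=list(DEFAULT_COLUMNS)
)
REFERENCE_MIXL_SE_SDS = pd.Series(
    [0.12, 0.14, 0.11, 0.14, 0.23], index=list(DEFAULT_COLUMNS[1:])
)
REFERENCE_LCM_SES = pd.DataFrame(
    {
        "class_1": [0.0000855, 0.28, 0.38, 0.30, 0.40, 0.34],
        "class_2": [0.0000429, 0.17, 0.17, 0.19, 0.14, 0.14],
        "class_3": [0.0001103, 0.30, 0.30, 0.29, 0.26, 0.29],
    },
    index=list(DEFAULT_COLUMNS),
)


def reference_mixl_result():
    """Published mixed-logit estimates packaged as a fit result.

    Coefficient covariances are not published, so the covariance matrix is
    diagonal at the printed standard errors — point post-estimation is
    exact, intervals are approximations that ignore parameter covariance.
    """
    from .estimation import MIXLResult

    random = tuple(DEFAULT_COLUMNS[1:])
    names = list(DEFAULT_COLUMNS) + [f"sd_{c}" for c in random]
    se = np.concatenate(
        [REFERENCE_MIXL_SE_MEANS.to_numpy(), REFERENCE_MIXL_SE_SDS.to_numpy()]
    )
    cov = pd.DataFrame(np.diag(se**2), index=names, columns=names)
    return MIXLResult(
        means=REFERENCE_MIXL_MEANS.copy(),
        sds=REFERENCE_MIXL_SDS[list(random)].copy(),
        se_means=REFERENCE_MIXL_SE_MEANS.copy(),
        se_sds=REFERENCE_MIXL_SE_SDS.copy(),
        cov=cov,
        loglik=float("nan"),
        n_draws=2000,
        draw_type="halton",
        random=random,
        n_observations=5632,
        converged=True,
    )


def reference_lcm_result():
    """Published three-class latent-class estimates packaged as a result."""
    from .estimation import LCMResult

    n_classes = REFERENCE_LCM_COEFS.shape[1]
    return LCMResult(
        class_coefs=REFERENCE_LCM_COEFS.copy(),
        class_ses=REFERENCE_LCM_SES.copy(),
        shares=REFERENCE_LCM_SHARES.copy(),
        loglik=float("nan"),
        aic=float("nan"),
        posterior=pd.DataFrame(columns=list(REFERENCE_LCM_COEFS.columns)),
        n_classes=n_classes,
        converged=True,
    )


@dataclass
class DataGeneratingProcess:
    """Preference structure from which synthetic respondents are drawn.

    kind
        "clogit" (homogeneous), "mixl" (independent normal random
        coefficients) or "latent_class" (finite mixture).
    mean
        Mean coefficient vector (clogit/mixl), indexed by encoded columns.
    sd
        Per-coefficient SDs (mixl); zeros allowed (degenerate mixing).
    class_coefs / class_shares
        Per-class coefficient vectors (columns) and positive shares
        summing to 1 (latent_class).
    interactions
        Sequence of ``(column, covariate, coefficient)``: an additive
        shift of that coefficient for respondents with covariate dummy 1.
        Supported covariate dummies: "male", "young" (age <= 24).
    """

    kind: str = "mixl"
    mean: pd.Series | None = None
    sd: pd.Series | None = None
    class_coefs: pd.DataFrame | None = None
    class_shares: np.ndarray | None = None
    interactions: tuple = ()

    def __post_init__(self):
        if self.kind not in ("clogit", "mixl", "latent_class"):
            raise ValueError(f"unknown DGP kind {self.kind!r}")
        if self.kind == "latent_class":
            shares = np.asarray(self.class_shares, dtype=float)
            if np.any(shares <= 0) or not np.isclose(shares.sum(), 1.0):
                raise ValueError("class shares must be positive and sum to 1")
            self.class_shares = shares
        if self.sd is not None and np.any(np.asarray(self.sd) < 0):
            raise ValueError("sd entries must be >= 0")

    @property
    def columns(self) -> list:
        if self.kind == "latent_class":
            return list(self.class_coefs.index)
        return list(self.mean.index)


def reference_mixl_dgp(interactions=()) -> DataGeneratingProcess:
    """Mixed-logit process at the published means/SDs (salary fixed)."""
    return DataGeneratingProcess(
        kind="mixl",
        mean=REFERENCE_MIXL_MEANS.copy(),
        sd=REFERENCE_MIXL_SDS.copy(),
        interactions=tuple(interactions),
    )


def reference_clogit_dgp() -> DataGeneratingProcess:
    """Homogeneous process at the published mixed-logit means."""
    return DataGeneratingProcess(kind="clogit", mean=REFERENCE_MIXL_MEANS.copy())


def reference_lcm_dgp() -> DataGeneratingProcess:
    """Three-class process at the published class coefficients and shares."""
    return DataGeneratingProcess(
        kind="latent_class",
        class_coefs=REFERENCE_LCM_COEFS.copy(),
        class_shares=REFERENCE_LCM_SHARES.copy(),
    )


def make_covariates(n_respondents: int, seed: int = 0) -> pd.DataFrame:
    """Respondent covariates matching the study sample.

    Sex is Bernoulli(0.75) male; age is a rounded normal with mean 24 and
    SD 1.3 years, clipped to the observed 21-28 support.
    """
    rng = np.random.default_rng(seed)
    sex = np.where(rng.random(n_respondents) < 0.75, "male", "female")
    age = np.clip(np.rint(rng.normal(24.0, 1.3, n_respondents)), 21, 28).astype(int)
    return pd.DataFrame(
        {"age": age, "sex": sex},
        index=pd.RangeIndex(n_respondents, name="respondent_id"),
    )


def draw_preferences(
    dgp: DataGeneratingProcess,
    n_respondents: int,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
):
    """Per-respondent coefficient vectors under the process.

    Returns ``(betas, classes)``: a (n_respondents x K) DataFrame and, for
    latent-class processes, the 0-based class label of each respondent
    (``None`` otherwise).  Interaction shifts are applied if ``covariates``
    is given.
    """
    rng = np.random.default_rng(seed)
    cols = dgp.columns
    classes = None
    if dgp.kind == "clogit":
        betas = np.tile(np.asarray(dgp.mean, dtype=float), (n_respondents, 1))
    elif dgp.kind == "mixl":
        mean = np.asarray(dgp.mean, dtype=float)
        sd = np.asarray(dgp.sd, dtype=float)
        betas = mean + sd * rng.standard_normal((n_respondents, len(cols)))
    else:
        classes = rng.choice(len(dgp.class_shares), size=n_respondents, p=dgp.class_shares)
        coefs = dgp.class_coefs.to_numpy(dtype=float).T  # class x K
        betas = coefs[classes]
    betas = pd.DataFrame(
        betas, columns=cols, index=pd.RangeIndex(n_respondents, name="respondent_id")
    )
    for col, covariate, coef in dgp.interactions:
        if covariates is None:
            raise ValueError("interaction DGP requires covariates")
        dummy = covariate_dummy(covariates, covariate)
        betas[col] = betas[col] + coef * dummy.to_numpy()
    return betas, classes


def covariate_dummy(covariates: pd.DataFrame, name: str) -> pd.Series:
    """Respondent-level 0/1 dummy: "male", or "young" (age 21-24)."""
    if name == "male":
        return (covariates["sex"] == "male").astype(float)
    if name == "young":
        return (covariates["age"] <= 24).astype(float)
    raise ValueError(f"unknown covariate dummy {name!r}")


def simulate_choices(
    design: PairedDesign,
    schema: AttributeSchema,
    assignment: pd.DataFrame,
    betas: pd.DataFrame,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
) -> ChoiceDataset:
    """Simulate every assigned task's choice under random utility.

    For each respondent-task, utility of each alternative is x'beta plus
    independent standard Gumbel noise (inverse-CDF of uniforms); the
    maximal-utility alternative is chosen.
    """
    if len(betas) != len(assignment):
        raise ValueError("preferences do not cover all assigned respondents")
    rng = np.random.default_rng(seed)
    enc = {tid: (schema.encode_profile(pa), schema.encode_profile(pb))
           for tid, pa, pb in design.tasks}
    task_levels = {tid: (pa, pb) for tid, pa, pb in design.tasks}
    block_cols = list(assignment.columns)

    rows = []
    for rid in assignment.index:
        beta = betas.loc[rid].to_numpy(dtype=float)
        task_ids = [
            tid for b in assignment.loc[rid, block_cols] for tid in design.block_tasks(int(b))
        ]
        u = rng.random((len(task_ids), 2))
        gumbel = -np.log(-np.log(u))
        for k, tid in enumerate(task_ids):
            xa, xb = enc[tid]
            ua = xa @ beta + gumbel[k, 0]
            ub = xb @ beta + gumbel[k, 1]
            chosen_a = int(ua > ub)
            pa, pb = task_levels[tid]
            for alt, prof, ch in (("A", pa, chosen_a), ("B", pb, 1 - chosen_a)):
                rows.append(
                    (rid, tid, alt, ch) + tuple(prof)
                )
    df = pd.DataFrame(
        rows, columns=["respondent_id", "task_id", "alt", "chosen"] + list(schema.names)
    )
    if covariates is not None:
        df = df.merge(covariates.reset_index(), on="respondent_id", how="left")
    return ChoiceDataset(df, schema)


def simulate_study(
    dgp: DataGeneratingProcess,
    design: PairedDesign,
    schema: AttributeSchema | None = None,
    n_respondents: int = 352,
    seed: int = 0,
    with_covariates: bool = True,
):
    """One-call study-scale simulation: covariates, preferences, choices.

    Child seeds for the covariate, preference, block-assignment and noise
    stages are spawned deterministically from ``seed``.  Defaults match
    the study: 352 respondents x 2 blocks x 8 tasks = 5,632 observations.
    Returns ``(ChoiceDataset, betas, classes)``.
    """
    schema = schema or default_schema()
    s_cov, s_pref, s_blocks, s_noise = spawn_seeds(seed, 4)
    covariates = make_covariates(n_respondents, seed=s_cov) if with_covariates else None
    betas, classes = draw_preferences(dgp, n_respondents, seed=s_pref, covariates=covariates)
    assignment = assign_blocks(
        design, n_respondents, design.blocks_per_respondent, seed=s_blocks
    )
    dataset = simulate_choices(
        design, schema, assignment, betas, seed=s_noise, covariates=covariates
    )
    return dataset, betas, classes


def spawn_seeds(seed: int, n: int) -> list:
    """Deterministic child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
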