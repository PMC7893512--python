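"""Synthetic two-arm randomized trial generator.

Emulates a psychotherapy trial comparing cognitive therapy (CT) and
interpersonal psychotherapy (IPT) for depression: ~150 participants
randomized 1:1, a few dozen baseline covariates of mixed type (continuous
scale scores, right-skewed event counts, binary history items) with
correlated blocks, longitudinal BDI-II follow-up on a fixed schedule, and
missingness injected after generation.

The outcome truth is a linear model on the average-BDI scale:

    mu_i(arm) = intercept + baseline effect + Σ predictor effects
                + arm effect · arm + Σ (moderator effect · z) · arm

with covariates entering standardized (per-SD effect sizes) and arm coded
CT=0 / IPT=1.  Realized follow-up trajectories are lines through the
schedule whose natural-cubic-spline AUC equals the model-implied outcome
times the follow-up span, plus optional visit-level measurement noise, so
the AUC readout downstream is an (approximately) unbiased measurement of
the generative truth.  The generator returns the ground truth needed for
recovery tests: true coefficient sets and each participant's expected
outcome under both arms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, ndtri

__all__ = [
    "GeneratorConfig",
    "TrialDataset",
    "GroundTruth",
    "generate",
    "inject_missingness",
    "save_dataset",
    "load_dataset",
]

ARM_CT = "CT"
ARM_IPT = "IPT"
BDI_MAX = 63.0
DEFAULT_SCHEDULE = (7, 8, 9, 10, 11, 12, 24)


def _default_kinds(p: int) -> list:
    """Covariate kind layout: binary history item first (the planted
    predictor), two event counts (the planted moderators), then a mix."""
    kinds = ["binary", "count", "count"]
    for j in range(3, p):
        if j % 5 == 3:
            kinds.append("count")
        elif j % 5 == 4:
            kinds.append("binary")
        else:
            kinds.append("continuous")
    return kinds[:p]


@dataclass
class GeneratorConfig:
    n_participants: int = 151
    n_covariates: int = 38
    covariate_kinds: list | None = None
    # the default covariate set emulates the post-screening battery: pairs
    # correlated above the 0.70 pruning cut have already been removed, so
    # default block targets stay below it
    correlated_block_specs: list = field(
        default_factory=lambda: [(4, 0.6), (4, 0.4)]
    )
    true_predictor_ids: tuple = (0,)
    predictor_effect_sizes: tuple = (3.2,)
    true_moderator_ids: tuple = (1, 2)
    moderator_effect_sizes: tuple = (6.4, 4.8)
    moderator_main_effects: tuple | None = None
    arm_effect: float = 0.0
    intercept: float = 15.0
    baseline_effect: float = 2.0
    baseline_outcome_mean: float = 25.0
    baseline_outcome_sd: float = 8.0
    residual_sd: float = 8.0
    # per-visit jitter is off by default: the spline-AUC integration weights
    # on the uneven 7..12,24 schedule amplify independent visit noise ~19x,
    # so outcome noise lives in residual_sd (participant level) instead
    visit_noise_sd: float = 0.0
    drift_sd: float = 0.15
    count_mean: float = 1.5
    binary_prevalence: float = 0.25
    outcome_schedule_months: tuple = DEFAULT_SCHEDULE
    include_month3: bool = True
    missing_rate_covariates: float = 0.004
    missing_rate_outcomes: float = 0.155
    mechanism: str = "MCAR"
    mar_driver: int | None = None
    mar_slope: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        p = self.n_covariates
        if self.n_participants <= 0 or p <= 0:
            raise ValueError("sizes must be positive")
        ids = list(self.true_predictor_ids) + list(self.true_moderator_ids)
        if any(i < 0 or i >= p for i in ids):
            raise ValueError("true-effect ids must be < n_covariates")
        if set(self.true_predictor_ids) & set(self.true_moderator_ids):
            raise ValueError("a moderator id cannot also be a predictor id")
        if len(self.true_predictor_ids) != len(self.predictor_effect_sizes):
            raise ValueError("predictor ids/effects length mismatch")
        if len(self.true_moderator_ids) != len(self.moderator_effect_sizes):
            raise ValueError("moderator ids/effects length mismatch")
        for r in (self.missing_rate_covariates, self.missing_rate_outcomes):
            if not 0 <= r < 1:
                raise ValueError("missing rates must lie in [0, 1)")
        sched = np.asarray(self.outcome_schedule_months, dtype=float)
        if np.any(np.diff(sched) <= 0):
            raise ValueError("outcome schedule must be strictly increasing")
        if not np.all(np.isfinite(
            list(self.predictor_effect_sizes) + list(self.moderator_effect_sizes)
        )):
            raise ValueError("effect sizes must be finite")
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError("mechanism must be MCAR or MAR")
        if self.covariate_kinds is not None and len(self.covariate_kinds) != p:
            raise ValueError("covariate_kinds length mismatch")

    def kinds(self) -> list:
        return (
            list(self.covariate_kinds)
            if self.covariate_kinds is not None
            else _default_kinds(self.n_covariates)
        )


@dataclass
class TrialDataset:
    """Participants × (arm, covariates, baseline, longitudinal outcomes).

    Missing cells are NaN; boolean masks are exposed via properties.
    """

    ids: pd.Index
    arm: pd.Series  # 'CT' / 'IPT'
    covariates: pd.DataFrame
    covariate_kinds: dict
    baseline_bdi: pd.Series
    outcomes: pd.DataFrame  # columns bdi_m<month>
    schedule: tuple
    month3: pd.Series | None = None
    clip_log: dict = field(default_factory=dict)

    def __post_init__(self):
        labels = set(self.arm.dropna().unique())
        if not labels <= {ARM_CT, ARM_IPT}:
            raise ValueError(f"unexpected arm labels: {labels}")
        for frame in (self.outcomes,):
            vals = frame.to_numpy(dtype=float)
            obs = vals[np.isfinite(vals)]
            if obs.size and (obs.min() < 0 or obs.max() > BDI_MAX):
                raise ValueError("observed BDI-II values outside [0, 63]")

    @property
    def covariate_mask(self) -> pd.DataFrame:
        """True where observed."""
        return self.covariates.notna()

    @property
    def outcome_mask(self) -> pd.DataFrame:
        return self.outcomes.notna()

    @property
    def arm_numeric(self) -> pd.Series:
        """CT=0, IPT=1."""
        return self.arm.map({ARM_CT: 0, ARM_IPT: 1}).astype(int)

    def copy(self) -> "TrialDataset":
        return TrialDataset(
            ids=self.ids.copy(),
            arm=self.arm.copy(),
            covariates=self.covariates.copy(),
            covariate_kinds=dict(self.covariate_kinds),
            baseline_bdi=self.baseline_bdi.copy(),
            outcomes=self.outcomes.copy(),
            schedule=tuple(self.schedule),
            month3=None if self.month3 is None else self.month3.copy(),
            clip_log=dict(self.clip_log),
        )


@dataclass
class GroundTruth:
    """Recovery-test oracle emitted alongside each synthetic dataset."""

    predictor_ids: tuple
    predictor_coefs: tuple
    moderator_ids: tuple
    moderator_interaction_coefs: tuple
    arm_effect: float
    intercept: float
    expected_avg_bdi_ct: pd.Series
    expected_avg_bdi_ipt: pd.Series
    true_optimal_arm: pd.Series  # 'CT' / 'IPT' / 'none'
    standardized_design: pd.DataFrame

    @property
    def true_pai(self) -> pd.Series:
        """True CT-minus-IPT expected-outcome difference (negative ⇒ CT)."""
        return self.expected_avg_bdi_ct - self.expected_avg_bdi_ipt


def _block_correlation(p: int, kinds, specs, true_ids):
    """Assign equicorrelated blocks to continuous covariates that carry no
    true effect; returns (correlation matrix, block id per covariate)."""
    corr = np.eye(p)
    block_of = np.full(p, -1)
    free = [j for j in range(p) if kinds[j] == "continuous" and j not in true_ids]
    cursor = 0
    for b, (size, rho) in enumerate(specs):
        if not 0 <= rho < 1:
            raise ValueError("block correlation target must lie in [0, 1)")
        members = free[cursor : cursor + size]
        if len(members) < size:
            raise ValueError("not enough free continuous covariates for blocks")
        cursor += size
        for i in members:
            for j in members:
                if i != j:
                    corr[i, j] = rho
            block_of[i] = b
    return corr, block_of


def _standardize_theoretical(x, kind, count_mean, prevalence):
    if kind == "count":
        return (x - count_mean) / np.sqrt(count_mean)
    if kind == "binary":
        return (x - prevalence) / np.sqrt(prevalence * (1 - prevalence))
    return x  # continuous latents are standard normal already


def generate(config: GeneratorConfig):
    """Draw one trial; returns ``(TrialDataset, GroundTruth)``.

    Fully reproducible: the same config (including seed) yields bit-identical
    matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_participants, config.n_covariates
    kinds = config.kinds()
    true_ids = set(config.true_predictor_ids) | set(config.true_moderator_ids)

    corr, block_of = _block_correlation(
        p, kinds, config.correlated_block_specs, true_ids
    )
    chol = np.linalg.cholesky(corr)
    latent = rng.standard_normal((n, p)) @ chol.T

    cov = np.empty((n, p))
    for j in range(p):
        if kinds[j] == "continuous":
            cov[:, j] = latent[:, j]
        elif kinds[j] == "count":
            u = stats.norm.cdf(latent[:, j])
            cov[:, j] = stats.poisson.ppf(u, config.count_mean)
        elif kinds[j] == "binary":
            cov[:, j] = (latent[:, j] > ndtri(1 - config.binary_prevalence)).astype(float)
        else:
            raise ValueError(f"unknown covariate kind {kinds[j]!r}")

    names = [f"x{j:02d}" for j in range(p)]
    ids = pd.RangeIndex(n, name="participant")
    # 1:1 randomization by permuted balanced assignment (76/75 at n=151)
    n_ct = (n + 1) // 2
    arm_num = np.zeros(n, dtype=int)
    arm_num[rng.permutation(n)[: n - n_ct]] = 1

    baseline = np.clip(
        rng.normal(config.baseline_outcome_mean, config.baseline_outcome_sd, n),
        0.0,
        BDI_MAX,
    )

    z = {
        j: _standardize_theoretical(
            cov[:, j], kinds[j], config.count_mean, config.binary_prevalence
        )
        for j in sorted(true_ids)
    }
    mod_mains = config.moderator_main_effects or tuple(
        0.0 for _ in config.true_moderator_ids
    )

    base_part = config.intercept + config.baseline_effect * (
        (baseline - config.baseline_outcome_mean) / config.baseline_outcome_sd
    )
    for j, beta in zip(config.true_predictor_ids, config.predictor_effect_sizes):
        base_part = base_part + beta * z[j]
    for j, beta in zip(config.true_moderator_ids, mod_mains):
        base_part = base_part + beta * z[j]
    inter_part = np.full(n, config.arm_effect)
    for j, gamma in zip(config.true_moderator_ids, config.moderator_effect_sizes):
        inter_part = inter_part + gamma * z[j]

    mu_ct = base_part
    mu_ipt = base_part + inter_part
    pai_true = mu_ct - mu_ipt
    optimal = np.where(pai_true < 0, ARM_CT, np.where(pai_true > 0, ARM_IPT, "none"))

    resid = rng.normal(0.0, config.residual_sd, n)
    realized_avg = np.where(arm_num == 0, mu_ct, mu_ipt) + resid

    sched = np.asarray(config.outcome_schedule_months, dtype=float)
    t_mid = 0.5 * (sched[0] + sched[-1])
    slope = rng.normal(0.0, config.drift_sd, n)
    traj = realized_avg[:, None] + slope[:, None] * (sched[None, :] - t_mid)
    if config.visit_noise_sd > 0:
        traj = traj + rng.normal(0.0, config.visit_noise_sd, traj.shape)
    n_clipped = int(np.sum((traj < 0) | (traj > BDI_MAX)))
    traj = np.clip(traj, 0.0, BDI_MAX)

    month3 = None
    if config.include_month3:
        m3 = baseline + 0.7 * (realized_avg - baseline) + rng.normal(0, 2.0, n)
        month3 = pd.Series(np.clip(m3, 0.0, BDI_MAX), index=ids, name="bdi_m3")

    dataset = TrialDataset(
        ids=ids,
        arm=pd.Series(np.where(arm_num == 0, ARM_CT, ARM_IPT), index=ids, name="arm"),
        covariates=pd.DataFrame(cov, index=ids, columns=names),
        covariate_kinds={names[j]: kinds[j] for j in range(p)},
        baseline_bdi=pd.Series(baseline, index=ids, name="bdi_baseline"),
        outcomes=pd.DataFrame(
            traj, index=ids, columns=[f"bdi_m{int(m)}" for m in sched]
        ),
        schedule=tuple(float(m) for m in sched),
        month3=month3,
        clip_log={"n_cells_clipped": n_clipped, "block_of": block_of.tolist()},
    )

    design = pd.DataFrame(
        {f"z_{names[j]}": z[j] for j in sorted(true_ids)}, index=ids
    )
    design["baseline_std"] = (
        baseline - config.baseline_outcome_mean
    ) / config.baseline_outcome_sd
    truth = GroundTruth(
        predictor_ids=tuple(config.true_predictor_ids),
        predictor_coefs=tuple(config.predictor_effect_sizes),
        moderator_ids=tuple(config.true_moderator_ids),
        moderator_interaction_coefs=tuple(config.moderator_effect_sizes),
        arm_effect=config.arm_effect,
        intercept=config.intercept,
        expected_avg_bdi_ct=pd.Series(mu_ct, index=ids),
        expected_avg_bdi_ipt=pd.Series(mu_ipt, index=ids),
        true_optimal_arm=pd.Series(optimal, index=ids),
        standardized_design=design,
    )

    if config.missing_rate_covariates > 0 or config.missing_rate_outcomes > 0:
        dataset = inject_missingness(
            dataset,
            rate_covariates=config.missing_rate_covariates,
            rate_outcomes=config.missing_rate_outcomes,
            mechanism=config.mechanism,
            mar_driver=config.mar_driver,
            mar_slope=config.mar_slope,
            seed=rng.integers(0, 2**31 - 1),
        )
    return dataset, truth


def _calibrate_intercept(driver, slope, target):
    """Find a on the logit scale so mean(sigmoid(a + slope*driver)) = target."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(mid + slope * driver).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def inject_missingness(
    data: TrialDataset,
    rate_covariates: float = 0.0,
    rate_outcomes: float = 0.0,
    mechanism: str = "MCAR",
    mar_driver: int | None = None,
    mar_slope: float = 1.0,
    seed: int = 0,
) -> TrialDataset:
    """Mask covariate and outcome cells at the stated rates.

    MCAR masks uniformly at random; MAR ties the outcome-missingness
    probability to a designated observed covariate through a logistic model
    whose intercept is calibrated so the marginal rate hits the target.
    A participant is never left without any observed outcome (one retained
    cell is forced at random when a full-row mask is drawn).
    """
    for r in (rate_covariates, rate_outcomes):
        if not 0 <= r < 1:
            raise ValueError("rates must lie in [0, 1)")
    if rate_covariates == 0 and rate_outcomes == 0:
        return data
    rng = np.random.default_rng(seed)
    out = data.copy()

    if rate_covariates > 0:
        mask = rng.random(out.covariates.shape) < rate_covariates
        cov = out.covariates.to_numpy(dtype=float)
        cov[mask] = np.nan
        out.covariates = pd.DataFrame(
            cov, index=out.covariates.index, columns=out.covariates.columns
        )

    if rate_outcomes > 0:
        shape = out.outcomes.shape
        if mechanism == "MCAR":
            prob = np.full(shape, rate_outcomes)
        elif mechanism == "MAR":
            if mar_driver is None:
                raise ValueError("MAR requires mar_driver covariate index")
            driver = data.covariates.iloc[:, mar_driver].to_numpy(dtype=float)
            driver = np.where(np.isfinite(driver), driver, np.nanmean(driver))
            driver = (driver - driver.mean()) / (driver.std() or 1.0)
            a = _calibrate_intercept(driver, mar_slope, rate_outcomes)
            prob = np.repeat(
                expit(a + mar_slope * driver)[:, None], shape[1], axis=1
            )
        else:
            raise ValueError("mechanism must be MCAR or MAR")
        mask = rng.random(shape) < prob
        full_rows = mask.all(axis=1)
        if full_rows.any():
            keep = rng.integers(0, shape[1], full_rows.sum())
            mask[np.flatnonzero(full_rows), keep] = False
        vals = out.outcomes.to_numpy(dtype=float)
        vals[mask] = np.nan
        out.outcomes = pd.DataFrame(
            vals, index=out.outcomes.index, columns=out.outcomes.columns
        )
    return out


def save_dataset(data: TrialDataset, csv_path, truth: GroundTruth | None = None):
    """Write one row per participant (empty cell = missing) plus a JSON
    sidecar with covariate kinds, schedule, and optionally the ground truth."""
    csv_path = Path(csv_path)
    frame = pd.concat(
        [data.arm, data.baseline_bdi, data.covariates, data.outcomes]
        + ([data.month3] if data.month3 is not None else []),
        axis=1,
    )
    frame.to_csv(csv_path, index_label="participant")
    meta = {
        "schedule": list(data.schedule),
        "covariate_kinds": data.covariate_kinds,
        "clip_log": data.clip_log,
    }
    if truth is not None:
        meta["ground_truth"] = {
            "predictor_ids": list(truth.predictor_ids),
            "predictor_coefs": list(truth.predictor_coefs),
            "moderator_ids": list(truth.moderator_ids),
            "moderator_interaction_coefs": list(truth.moderator_interaction_coefs),
            "arm_effect": truth.arm_effect,
            "intercept": truth.intercept,
            "expected_avg_bdi_ct": truth.expected_avg_bdi_ct.tolist(),
            "expected_avg_bdi_ipt": truth.expected_avg_bdi_ipt.tolist(),
            "true_optimal_arm": truth.true_optimal_arm.tolist(),
        }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_dataset(csv_path) -> TrialDataset:
    """Inverse of :func:`save_dataset` (ground truth is not reloaded)."""
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path, index_col="participant")
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    sched = tuple(meta["schedule"])
    out_cols = [f"bdi_m{int(m)}" for m in sched]
    cov_cols = list(meta["covariate_kinds"])
    month3 = frame["bdi_m3"] if "bdi_m3" in frame.columns else None
    return TrialDataset(
        ids=frame.index,
        arm=frame["arm"],
        covariates=frame[cov_cols],
        covariate_kinds=meta["covariate_kinds"],
        baseline_bdi=frame["bdi_baseline"],
        outcomes=frame[out_cols],
        schedule=sched,
        month3=month3,
        clip_log=meta.get("clip_log", {}),
    )
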