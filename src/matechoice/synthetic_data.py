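"""Synthetic isofemale-strain mate-choice studies.

Generates complete studies with the statistical structure the downstream
analysis assumes: a randomized-block design (blocks of four isofemale
strains) in which male mating success is scored in four contexts -- virgin
(V+) or non-virgin (V-) females, with (C+) or without (C-) male-male
competition -- plus inbreeding-depressed fitness/viability crosses and
strain-structured wing morphology.

Male strain effects are drawn once per study from a 4-variate normal whose
standard deviations and correlation matrix are configurable; the same
effects drive noncompetitive latency and competitive win propensity, which
is what a cross-context genetic correlation presupposes.  Latency follows a
log-normal race: log latency = log(baseline) - effect + noise, censored at
two hours, and the competitive winner is the male with the minimum latency.

Every generator is a pure function of (config, seed); the realized true
parameters are returned alongside the data so parameter recovery can be
asserted end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONTEXTS",
    "STATUSES",
    "COLORS",
    "SimConfig",
    "TrueParams",
    "SimStudy",
    "draw_strain_effects",
    "simulate_noncompetitive",
    "simulate_competitive",
    "simulate_fitness",
    "simulate_viability",
    "simulate_morphology",
    "simulate_study",
    "check_correlation_matrix",
]

#: Context labels, in the fixed order used for all vectors/matrices.
CONTEXTS = ("V+C+", "V-C+", "V+C-", "V-C-")
STATUSES = ("virgin", "nonvirgin")
COLORS = ("black", "blue", "green", "red")

#: Context index of the two noncompetitive contexts (female effects are
#: modeled there only; in competitive vials the female is shared by all
#: four males, so her responsiveness cannot bias the winner).
NONCOMP_CONTEXTS = ("V+C-", "V-C-")

# Seed offsets for per-operation generators, derived from the master seed.
SEED_OFFSETS = {
    "effects": 1,
    "noncompetitive": 2,
    "competitive": 3,
    "fitness": 4,
    "viability": 5,
    "morphology": 6,
}

_DEFAULT_CORR = (
    (1.00, 0.46, 0.43, 0.28),
    (0.46, 1.00, 0.18, 0.02),
    (0.43, 0.18, 1.00, 0.80),
    (0.28, 0.02, 0.80, 1.00),
)

# Approximate wing-vein landmark configuration (mm); landmarks 3 and 9 are
# the base/tip pair whose distance defines wing length (~1.67 mm).
_DEFAULT_SHAPE = (
    (0.20, 0.45),
    (0.35, 0.70),
    (0.15, 0.30),
    (0.80, 0.85),
    (1.20, 0.78),
    (0.90, 0.20),
    (1.40, 0.45),
    (1.10, 0.60),
    (1.82, 0.42),
)


def check_correlation_matrix(R: np.ndarray, name: str = "context_corr") -> np.ndarray:
    """Validate a correlation matrix (symmetric, unit diagonal, PSD)."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError(f"{name} must be square, got shape {R.shape}")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError(f"{name} must have a unit diagonal")
    evals = np.linalg.eigvalsh(R)
    if evals.min() < -1e-10:
        raise ValueError(
            f"{name} is not positive semi-definite (min eigenvalue {evals.min():.3g})"
        )
    return R


@dataclass
class SimConfig:
    """Study design and generative parameters.

    Defaults emulate the published design: 5 blocks x 4 strains, ~19/15
    noncompetitive trials per strain pair and status, 21/32 competitive
    vials per female strain and status, 2-h censoring, male-strain effect
    SDs and cross-context correlations at the scale of the reported
    posterior modes, ~90%/40% noncompetitive mating rates for virgin and
    non-virgin females, inbreeding-depressed within-strain crosses and a
    ~44% zero-egg rate in the viability assay.
    """

    n_blocks: int = 5
    strains_per_block: int = 4
    #: noncompetitive trials per (block, male strain x female strain) cell,
    #: one count per female status (virgin, nonvirgin)
    n_noncomp_trials_per_cell: tuple[int, int] = (19, 15)
    #: competitive vials per (block, female strain) cell, per status
    n_comp_vials_per_cell: tuple[int, int] = (21, 32)
    censor_minutes: float = 120.0
    #: male-strain effect SDs per context (V+C+, V-C+, V+C-, V-C-), shared
    #: between the log-latency and logit scales
    context_sds: tuple[float, float, float, float] = (0.27, 0.41, 0.32, 0.38)
    context_corr: tuple = _DEFAULT_CORR
    female_strain_sd: float = 0.5
    #: median noncompetitive latency (minutes) per status; with
    #: latency_log_sd = 1.5 these give ~91% / ~39% mating within 2 h
    baseline_latency: tuple[float, float] = (16.0, 183.0)
    #: per-male median latency in competitive vials; the 4-male race then
    #: mates in ~93% / ~47% of vials
    comp_baseline_latency: tuple[float, float] = (126.0, 580.0)
    latency_log_sd: float = 1.5
    #: color (dye) effects on the log-latency/logit scale, order as COLORS
    color_effects: tuple[float, float, float, float] = (0.15, -0.06, -0.21, 0.12)
    #: mean fitness-score deficit of within-strain crosses (log-ratio scale)
    inbreeding_effect: float = 0.64
    mf_interaction_sd: float = 0.47
    #: vial-level lognormal noise on both competitors' offspring rates;
    #: sets the residual variance of the log-ratio score (~2 sd^2)
    fitness_overdispersion_sd: float = 1.0
    #: per-block shifts of the wild-type offspring log-rate; None tiles
    #: the canonical 5-block pattern to n_blocks
    block_effects: tuple[float, ...] | None = None
    mean_offspring: float = 40.0
    n_fitness_reps: int = 10  # per between-strain cross and sex (within: x2)
    #: viability assay
    viability_rate: float = 0.66
    egg_zero_inflation: float = 0.44
    mean_eggs: float = 24.0
    viability_inbreeding_effect: float = 0.8  # logit scale
    viability_fstrain_sd: float = 0.5  # logit scale
    #: vial-level logit-scale viability noise (residual overdispersion)
    viability_overdispersion_sd: float = 1.0
    #: unfertilized clutches: eggs laid but no adults emerge
    unfertilized_rate: float = 0.05
    n_viability_reps: int = 10  # per between-strain cross (within: x2)
    #: morphology
    landmark_mean_shape: tuple = _DEFAULT_SHAPE
    landmark_noise_sd: float = 0.01
    strain_shape_sd: float = 0.005
    strain_size_sd: float = 0.02
    comb_mean: float = 21.0
    comb_sd: float = 1.2
    comb_strain_sd: float = 0.8
    n_wings_per_strain: int = 39
    outlier_rate: float = 0.0
    outlier_displacement: float = 15.0  # multiples of landmark_noise_sd
    #: apply the random rotation/translation/pixel-scale digitization
    #: nuisance (disable to inspect raw generative shapes)
    digitize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_noncomp_trials_per_cell, (int, np.integer)):
            n = int(self.n_noncomp_trials_per_cell)
            self.n_noncomp_trials_per_cell = (n, n)
        if isinstance(self.n_comp_vials_per_cell, (int, np.integer)):
            n = int(self.n_comp_vials_per_cell)
            self.n_comp_vials_per_cell = (n, n)
        if self.strains_per_block < 2:
            raise ValueError("strains_per_block must be >= 2")
        if self.censor_minutes <= 0:
            raise ValueError("censor_minutes must be positive")
        if self.mean_offspring < 0:
            raise ValueError("mean_offspring must be non-negative")
        if not 0.0 <= self.viability_rate <= 1.0:
            raise ValueError("viability_rate must be in [0, 1]")
        if not 0.0 <= self.egg_zero_inflation <= 1.0:
            raise ValueError("egg_zero_inflation must be in [0, 1]")
        sds = np.asarray(self.context_sds, float)
        if sds.shape != (4,) or (sds < 0).any():
            raise ValueError("context_sds must be 4 non-negative values")
        if self.female_strain_sd < 0 or self.mf_interaction_sd < 0:
            raise ValueError("effect SDs must be non-negative")
        check_correlation_matrix(np.asarray(self.context_corr, float))
        shape = np.asarray(self.landmark_mean_shape, float)
        if shape.shape != (9, 2):
            raise ValueError(
                f"landmark_mean_shape must be 9x2, got {shape.shape}"
            )
        if self.block_effects is None:
            base = (0.0, 0.3, -0.2, 0.5, -0.3)
            self.block_effects = tuple(
                base[i % len(base)] for i in range(self.n_blocks)
            )
        if len(self.block_effects) != self.n_blocks:
            raise ValueError("block_effects must have one entry per block")

    # -- design helpers -------------------------------------------------

    @property
    def n_strains(self) -> int:
        return self.n_blocks * self.strains_per_block

    def strain_names(self) -> list[str]:
        return [f"s{i + 1:02d}" for i in range(self.n_strains)]

    def block_names(self) -> list[str]:
        return [f"b{i + 1}" for i in range(self.n_blocks)]

    def block_strains(self, block_index: int) -> list[str]:
        k = self.strains_per_block
        names = self.strain_names()
        return names[block_index * k : (block_index + 1) * k]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["context_corr"] = np.asarray(self.context_corr, float).tolist()
        d["landmark_mean_shape"] = np.asarray(self.landmark_mean_shape, float).tolist()
        return d


@dataclass
class TrueParams:
    """Realized strain-level effects, stored exactly as generated.

    ``a[s, k]`` is the effect of male strain ``s`` in context ``k``
    (columns ordered as :data:`CONTEXTS`); its rows are drawn from
    MVN(0, diag(sd) * R * diag(sd)).  ``b[f, j]`` is the responsiveness
    effect of female strain ``f`` in noncompetitive context ``j``
    (columns ordered as :data:`NONCOMP_CONTEXTS`), ``u[m, f]`` the
    male-by-female cross effect on fitness, ``v[f]`` the female-strain
    effect on egg-to-adult viability (logit scale).
    """

    strains: list[str]
    a: np.ndarray
    b: np.ndarray
    u: np.ndarray
    v: np.ndarray
    size_effects: np.ndarray
    shape_effects: np.ndarray
    comb_effects: np.ndarray
    config: SimConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "strains": list(self.strains),
            "contexts": list(CONTEXTS),
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "u": self.u.tolist(),
            "v": self.v.tolist(),
            "size_effects": self.size_effects.tolist(),
            "shape_effects": self.shape_effects.tolist(),
            "comb_effects": self.comb_effects.tolist(),
            "config": self.config.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SimStudy:
    """One complete synthetic study plus its generating truth."""

    noncompetitive: pd.DataFrame
    competitive: pd.DataFrame
    fitness: pd.DataFrame
    viability: pd.DataFrame
    morphology: pd.DataFrame
    params: TrueParams
    config: SimConfig

    def write_dir(self, path: str | Path) -> None:
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        self.noncompetitive.to_csv(out / "noncompetitive.csv", index=False)
        self.competitive.to_csv(out / "competitive.csv", index=False)
        self.fitness.to_csv(out / "fitness.csv", index=False)
        self.viability.to_csv(out / "viability.csv", index=False)
        self.morphology.to_csv(out / "morphology.csv", index=False)
        self.params.to_json(out / "true_params.json")


# ---------------------------------------------------------------------------
# strain effects


def draw_strain_effects(config: SimConfig, seed: int | None = None) -> TrueParams:
    """Draw all strain-level effects for one study.

    Male-strain rows ``a[s, :]`` come from MVN(0, diag(sd) R diag(sd));
    everything else is independent normal at its configured SD.
    Deterministic given the seed.
    """
    if seed is None:
        seed = config.seed + SEED_OFFSETS["effects"]
    rng = np.random.default_rng(seed)
    R = check_correlation_matrix(np.asarray(config.context_corr, float))
    sds = np.asarray(config.context_sds, float)
    S = config.n_strains
    # a = z L' with L = diag(sd) chol(R + eps I); exact at sd = 0 too
    LR = np.linalg.cholesky(R + 1e-12 * np.eye(4))
    a = rng.standard_normal((S, 4)) @ (sds[:, None] * LR).T
    b = rng.normal(0.0, config.female_strain_sd, size=(S, 2))
    u = rng.normal(0.0, config.mf_interaction_sd, size=(S, S))
    v = rng.normal(0.0, config.viability_fstrain_sd, size=S)
    size_eff = rng.normal(0.0, config.strain_size_sd, size=S)
    shape_eff = rng.normal(0.0, config.strain_shape_sd, size=(S, 9, 2))
    comb_eff = rng.normal(0.0, config.comb_strain_sd, size=S)
    return TrueParams(
        strains=config.strain_names(),
        a=a, b=b, u=u, v=v,
        size_effects=size_eff, shape_effects=shape_eff, comb_effects=comb_eff,
        config=config,
    )


def _strain_index(params: TrueParams) -> dict[str, int]:
    return {s: i for i, s in enumerate(params.strains)}


# ---------------------------------------------------------------------------
# mating trials


def simulate_noncompetitive(
    params: TrueParams, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Single-pair latency trials, full factorial within each block.

    Per trial, log latency = log(baseline for the female's status)
    - (a[m, context] + b[f, context]) + Gaussian noise; the trial is
    censored (mated = False, latency empty) beyond ``censor_minutes``.
    """
    if seed is None:
        seed = config.seed + SEED_OFFSETS["noncompetitive"]
    rng = np.random.default_rng(seed)
    idx = _strain_index(params)
    rows: list[tuple] = []
    trial_no = 0
    for bi, block in enumerate(config.block_names()):
        strains = config.block_strains(bi)
        for si, status in enumerate(STATUSES):
            if status not in STATUSES:  # pragma: no cover - defensive
                raise ValueError(f"unknown status label: {status!r}")
            context = NONCOMP_CONTEXTS[si]
            k = CONTEXTS.index(context)
            n_cell = config.n_noncomp_trials_per_cell[si]
            base = config.baseline_latency[si]
            for m in strains:
                for f in strains:
                    eff = params.a[idx[m], k] + params.b[idx[f], si]
                    noise = rng.normal(0.0, config.latency_log_sd, size=n_cell)
                    lat = np.exp(np.log(base) - eff + noise)
                    for t in lat:
                        trial_no += 1
                        mated = t <= config.censor_minutes
                        rows.append(
                            (
                                block, status, context, f"nc{trial_no:05d}",
                                m, f,
                                float(t) if mated else np.nan,
                                bool(mated),
                            )
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "block", "status", "context", "vial",
            "male_strain", "female_strain", "latency_min", "mated",
        ],
    )


def simulate_competitive(
    params: TrueParams, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Four-male competition vials; the winner is the fastest male.

    Each male draws a log-normal latency with his strain and dye-color
    effects; the vial mates iff the minimum latency beats the censor time.
    Within a block each strain keeps one color; color-to-strain assignment
    is permuted across blocks.  Non-mating vials are retained but flagged
    (``mated = False``, no winner) so the preparation stage can drop them.
    """
    if seed is None:
        seed = config.seed + SEED_OFFSETS["competitive"]
    if config.strains_per_block != 4:
        raise ValueError(
            "competitive trials need exactly 4 strains per block "
            f"(got {config.strains_per_block})"
        )
    rng = np.random.default_rng(seed)
    idx = _strain_index(params)
    col_eff = dict(zip(COLORS, config.color_effects))
    rows: list[tuple] = []
    vial_no = 0
    for bi, block in enumerate(config.block_names()):
        strains = config.block_strains(bi)
        # one color per strain within the block, permuted across blocks
        perm = rng.permutation(4)
        strain_color = {s: COLORS[perm[j]] for j, s in enumerate(strains)}
        color_strain = {c: s for s, c in strain_color.items()}
        for si, status in enumerate(STATUSES):
            context = CONTEXTS[si]  # V+C+ or V-C+
            k = CONTEXTS.index(context)
            base = config.comp_baseline_latency[si]
            n_cell = config.n_comp_vials_per_cell[si]
            for f in strains:
                for _ in range(n_cell):
                    vial_no += 1
                    eff = np.array(
                        [
                            params.a[idx[s], k] + col_eff[strain_color[s]]
                            for s in strains
                        ]
                    )
                    lat = np.exp(
                        np.log(base) - eff
                        + rng.normal(0.0, config.latency_log_sd, size=4)
                    )
                    j = int(np.argmin(lat))
                    mated = lat[j] <= config.censor_minutes
                    rows.append(
                        (
                            block, status, context, f"cv{vial_no:05d}", f,
                            color_strain["black"], color_strain["blue"],
                            color_strain["green"], color_strain["red"],
                            strains[j] if mated else "",
                            strain_color[strains[j]] if mated else "",
                            float(lat[j]) if mated else np.nan,
                            bool(mated),
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "block", "status", "context", "vial", "female_strain",
            "male_black", "male_blue", "male_green", "male_red",
            "winner_strain", "winner_color", "latency_min", "mated",
        ],
    )


# ---------------------------------------------------------------------------
# fitness / viability crosses


def simulate_fitness(
    params: TrueParams, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Competitive fitness counts for the full-factorial strain crosses.

    Wild-type counts are Poisson with log-rate
    log(mean_offspring) + block + cross + u[m, f]; the brown-eyed
    competitor is Poisson(mean_offspring).  Within-strain crosses carry
    the inbreeding deficit and double replication (all between-strain
    crosses being reciprocal).
    """
    if seed is None:
        seed = config.seed + SEED_OFFSETS["fitness"]
    if config.mean_offspring < 0:
        raise ValueError("mean_offspring must be non-negative")
    rng = np.random.default_rng(seed)
    idx = _strain_index(params)
    rows: list[tuple] = []
    for bi, block in enumerate(config.block_names()):
        strains = config.block_strains(bi)
        beff = config.block_effects[bi]
        for m in strains:
            for f in strains:
                within = m == f
                n_rep = config.n_fitness_reps * (2 if within else 1)
                cross_eff = -config.inbreeding_effect if within else 0.0
                base = beff + cross_eff + params.u[idx[m], idx[f]]
                od = config.fitness_overdispersion_sd
                for sex in ("male", "female"):
                    e_wt = rng.normal(0.0, od, size=n_rep)
                    e_be = rng.normal(0.0, od, size=n_rep)
                    wt = rng.poisson(config.mean_offspring * np.exp(base + e_wt))
                    be = rng.poisson(config.mean_offspring * np.exp(e_be))
                    for w_, b_ in zip(wt, be):
                        rows.append(
                            (
                                block, m, f, sex,
                                "within" if within else "between",
                                int(w_), int(b_),
                            )
                        )
    return pd.DataFrame(
        rows,
        columns=["block", "m_strain", "f_strain", "sex", "cross", "wt", "be"],
    )


def simulate_viability(
    params: TrueParams, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Egg and adult counts per single-pair cross vial.

    Egg counts are zero-inflated Poisson (emulating unmated pairs);
    adults are Binomial(eggs, p) with logit p shifted by the female-strain
    effect and the within-cross inbreeding deficit.
    """
    if seed is None:
        seed = config.seed + SEED_OFFSETS["viability"]
    if not 0.0 <= config.viability_rate <= 1.0:
        raise ValueError("viability_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    idx = _strain_index(params)
    base_logit = np.log(config.viability_rate / (1.0 - config.viability_rate)) \
        if 0.0 < config.viability_rate < 1.0 else np.inf * np.sign(config.viability_rate - 0.5)
    rows: list[tuple] = []
    for bi, block in enumerate(config.block_names()):
        strains = config.block_strains(bi)
        for m in strains:
            for f in strains:
                within = m == f
                n_rep = config.n_viability_reps * (2 if within else 1)
                for _ in range(n_rep):
                    u01 = rng.random()
                    if u01 < config.egg_zero_inflation:
                        eggs = 0
                    else:
                        eggs = int(rng.poisson(config.mean_eggs))
                    unfertilized = (
                        u01 >= config.egg_zero_inflation
                        and u01 < config.egg_zero_inflation + config.unfertilized_rate
                    )
                    if config.viability_rate in (0.0, 1.0):
                        p = config.viability_rate
                    else:
                        logit = (
                            base_logit
                            + params.v[idx[f]]
                            - (config.viability_inbreeding_effect if within else 0.0)
                            + rng.normal(0.0, config.viability_overdispersion_sd)
                        )
                        p = 1.0 / (1.0 + np.exp(-logit))
                    if unfertilized:
                        adults = 0
                    else:
                        adults = int(rng.binomial(eggs, p)) if eggs > 0 else 0
                    rows.append(
                        (
                            block, m, f,
                            "within" if within else "between",
                            eggs, adults,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["block", "m_strain", "f_strain", "cross", "eggs", "adults"],
    )


# ---------------------------------------------------------------------------
# morphology


def simulate_morphology(
    params: TrueParams, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Nine-landmark wing configurations plus sex-comb tooth counts.

    Each wing is the strain mean shape (mean + strain shape effect) scaled
    by the strain size factor, plus isotropic landmark noise, then pushed
    through a random rotation, translation and digitization scale -- the
    nuisance transforms a Procrustes fit must remove.  A configured
    fraction of wings get one landmark displaced by
    ``outlier_displacement`` noise SDs (planted multivariate outliers).

    Wide table: one row per wing with ``x1..y9`` in digitized units and a
    ``scale`` factor (mm per digitized unit).
    """
    if seed is None:
        seed = config.seed + SEED_OFFSETS["morphology"]
    mean_shape = np.asarray(config.landmark_mean_shape, float)
    if mean_shape.shape != (9, 2):
        raise ValueError(f"landmark_mean_shape must be 9x2, got {mean_shape.shape}")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    wing_no = 0
    for bi, block in enumerate(config.block_names()):
        strains = config.block_strains(bi)
        for s in strains:
            si = params.strains.index(s)
            strain_shape = (mean_shape + params.shape_effects[si]) * (
                1.0 + params.size_effects[si]
            )
            for w in range(config.n_wings_per_strain):
                wing_no += 1
                coords = strain_shape + rng.normal(
                    0.0, config.landmark_noise_sd, size=(9, 2)
                )
                planted = bool(rng.random() < config.outlier_rate)
                if planted:
                    lm = rng.integers(0, 9)
                    direction = rng.normal(size=2)
                    direction /= np.linalg.norm(direction)
                    coords[lm] += (
                        direction
                        * config.outlier_displacement
                        * config.landmark_noise_sd
                    )
                # digitization nuisance: rotation, translation, pixel scale
                if config.digitize:
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                    rot = np.array(
                        [[np.cos(theta), -np.sin(theta)],
                         [np.sin(theta), np.cos(theta)]]
                    )
                    shift = rng.uniform(-2.0, 2.0, size=2)
                    scale = float(rng.uniform(0.8, 1.2))  # mm per unit
                    digitized = (coords @ rot.T + shift) / scale
                else:
                    scale = 1.0
                    digitized = coords
                row = {
                    "wing_id": f"w{wing_no:04d}",
                    "block": block,
                    "strain": s,
                    "vial": f"mv{bi + 1}{(w % 6) + 1}",
                    "scale": scale,
                    "comb_teeth": int(
                        round(
                            config.comb_mean
                            + params.comb_effects[si]
                            + rng.normal(0.0, config.comb_sd)
                        )
                    ),
                    "planted_outlier": planted,
                }
                for j in range(9):
                    row[f"x{j + 1}"] = digitized[j, 0]
                    row[f"y{j + 1}"] = digitized[j, 1]
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole study


def simulate_study(config: SimConfig, seed: int | None = None) -> SimStudy:
    """Generate a full study; per-stage seeds derive from the master seed."""
    master = config.seed if seed is None else seed
    params = draw_strain_effects(config, master + SEED_OFFSETS["effects"])
    return SimStudy(
        noncompetitive=simulate_noncompetitive(
            params, config, master + SEED_OFFSETS["noncompetitive"]
        ),
        competitive=simulate_competitive(
            params, config, master + SEED_OFFSETS["competitive"]
        ),
        fitness=simulate_fitness(params, config, master + SEED_OFFSETS["fitness"]),
        viability=simulate_viability(
            params, config, master + SEED_OFFSETS["viability"]
        ),
        morphology=simulate_morphology(
            params, config, master + SEED_OFFSETS["morphology"]
        ),
        params=params,
        config=config,
    )
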