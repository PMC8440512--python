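"""Synthetic study generator: trajectories, cohorts, ratings, ground truth.

The stimulus database of the original animation task is not deposited, so
every pipeline stage is exercised on synthetic inputs with known structure:

* :func:`gen_pure_frequency_trajectory` inverts the AFSD construction — a
  path whose tangent angle advances steadily while log speed oscillates at
  chosen angular frequencies, so its spectrum has known peaks;
* :func:`gen_study` emulates the full study: an animator cohort produces
  one 45 s, 133 Hz recording per word with word-conditioned kinematics, an
  observer cohort produces its own animations and rates eight
  speed-percentile exemplars per word, and trial accuracy follows a known
  hierarchical regression (coefficients, random-effect and residual SDs are
  recorded for recovery tests);
* :func:`gen_null_spectra` draws exchangeable five-group spectra from one
  smooth random-curve distribution to calibrate the cluster F-test.

Latent accuracy is written into the five 1-10 ratings as
``target = clip(baseline + accuracy)`` with near-constant non-target
ratings, so the accuracy score recovers the latent value up to clipping;
the clipping rate is reported in the ground-truth record.
"""

from __future__ import annotations


from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinematics import PX_TO_MM_DEFAULT, compute_kinematics
from .scoring import FeatureTable, accuracy_score, similarity_difference
from .trajectory_model import AnimationRecording, RatingTrial, WordCategory

__all__ = [
    "TrajectoryRecipe",
    "StudyRecipe",
    "StudyData",
    "WORD_TRAJECTORY_DEFAULTS",
    "DEFAULT_BETAS",
    "gen_pure_frequency_trajectory",
    "gen_study",
    "gen_null_spectra",
]


@dataclass(frozen=True)
class TrajectoryRecipe:
    """Recipe for one triangle's path with controlled spectral content.

    The tangent angle advances uniformly through ``tracings`` full turns
    over the recording while speed follows
    ``v(theta) = base_speed * exp(sum_i A_i sin(nu_i theta + phase_i))``,
    so the AFSD of the path peaks at the component frequencies ``nu_i``
    (cycles per 2*pi radians).  ``base_speed`` is in mm/s and is converted
    to pixels/frame with the standard pixel pitch.
    """

    components: tuple[tuple[float, float, float], ...] = ((2.0, 0.5, 0.0),)
    base_speed: float = 40.0  # mm/s
    duration_s: float = 45.0
    frame_rate_hz: float = 133.0
    tracings: float = 10.0
    rotation_rate_deg_per_frame: float = 0.5
    noise_sd: float = 0.0  # px, positional
    canvas_px: tuple[int, int] = (1920, 1080)
    margin_px: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("duration and frame rate must be positive")
        if self.tracings < 1.0:
            raise ValueError(
                "tracings must cover at least one full 2*pi of angular displacement"
            )


def _path_from_recipe(recipe: TrajectoryRecipe, rng: np.random.Generator):
    n = int(round(recipe.duration_s * recipe.frame_rate_hz))
    theta = 2 * np.pi * recipe.tracings * np.arange(n) / n
    log_gain = np.zeros(n)
    for nu, amp, phase in recipe.components:
        log_gain += amp * np.sin(nu * theta + phase)
    speed_px = (
        recipe.base_speed / (recipe.frame_rate_hz * PX_TO_MM_DEFAULT)
    ) * np.exp(log_gain)
    heading = theta + rng.uniform(0, 2 * np.pi)
    dx = speed_px * np.cos(heading)
    dy = speed_px * np.sin(heading)
    x = np.concatenate([[0.0], np.cumsum(dx)[:-1]])
    y = np.concatenate([[0.0], np.cumsum(dy)[:-1]])
    if recipe.noise_sd > 0:
        x = x + rng.normal(0, recipe.noise_sd, n)
        y = y + rng.normal(0, recipe.noise_sd, n)
    # fit the path into the canvas, preserving aspect ratio (an isotropic
    # rescaling shifts log speed by a constant, which the detrend removes)
    w, h = recipe.canvas_px
    span = max(x.max() - x.min(), y.max() - y.min(), 1e-9)
    scale = min((w - 2 * recipe.margin_px), (h - 2 * recipe.margin_px)) / span
    x = (x - x.min()) * scale + recipe.margin_px
    y = (y - y.min()) * scale + recipe.margin_px
    if x.max() > w or y.max() > h:
        raise ValueError("canvas overflow after scaling")
    rot = (recipe.rotation_rate_deg_per_frame * np.arange(n)) % 360.0
    return np.column_stack([x, y]), rot


def gen_pure_frequency_trajectory(
    recipe: TrajectoryRecipe,
    blue_recipe: TrajectoryRecipe | None = None,
    animation_id: str = "synthetic",
    animator_id: str = "generator",
    word: WordCategory = WordCategory.FOLLOWING,
) -> AnimationRecording:
    """Build a full two-triangle recording from one or two recipes.

    ``blue_recipe`` defaults to the red recipe with a different seed and
    phase, so the two triangles carry the same spectral content without
    being identical.
    """
    if blue_recipe is None:
        blue_recipe = replace(
            recipe,
            seed=recipe.seed + 1,
            components=tuple(
                (nu, amp, phase + np.pi / 3) for nu, amp, phase in recipe.components
            ),
        )
    red_xy, red_rot = _path_from_recipe(recipe, np.random.default_rng(recipe.seed))
    blue_xy, blue_rot = _path_from_recipe(
        blue_recipe, np.random.default_rng(blue_recipe.seed)
    )
    n = min(len(red_rot), len(blue_rot))
    return AnimationRecording(
        animation_id=animation_id,
        animator_id=animator_id,
        word=word,
        frame_rate_hz=recipe.frame_rate_hz,
        canvas_px=recipe.canvas_px,
        t=np.arange(n) / recipe.frame_rate_hz,
        red_xy=red_xy[:n],
        red_rot=red_rot[:n],
        blue_xy=blue_xy[:n],
        blue_rot=blue_rot[:n],
    )


#: Word-conditioned trajectory parameters.  These encode the qualitative
#: contrasts the task exhibits: fighting animations are fast and jerky with
#: high-frequency content, following animations are slow doodle-like paths
#: with low-frequency content, seducing is smooth and elliptical, surprising
#: carries pentagon-band content, mocking sits in between.
WORD_TRAJECTORY_DEFAULTS: dict[WordCategory, dict] = {
    WordCategory.MOCKING: dict(
        base_speed=45.0, components=((3.0, 0.45, 0.0),), rotation_rate=0.6,
        noise_sd=0.4,
    ),
    WordCategory.SEDUCING: dict(
        base_speed=35.0, components=((2.0, 0.5, 0.0),), rotation_rate=0.3,
        noise_sd=0.2,
    ),
    WordCategory.SURPRISING: dict(
        base_speed=55.0, components=((5.0, 0.5, 0.0),), rotation_rate=0.8,
        noise_sd=0.5,
    ),
    WordCategory.FOLLOWING: dict(
        base_speed=30.0, components=((0.8, 0.5, 0.0),), rotation_rate=0.2,
        noise_sd=0.2,
    ),
    WordCategory.FIGHTING: dict(
        base_speed=80.0, components=((8.5, 0.6, 0.0), (5.0, 0.2, 1.0)),
        rotation_rate=1.5, noise_sd=1.2,
    ),
}

#: Generative coefficients of the trial-level accuracy model (predictors are
#: z-scored jerk and jerk difference and the non-mental dummy; the mental
#: condition is the reference level).
DEFAULT_BETAS: dict[str, float] = {
    "intercept": 0.5,
    "jerk": -1.03,
    "jerk_diff": -0.38,
    "nonmental": 2.54,
    "jerk:jerk_diff": 0.0,
    "jerk:nonmental": 1.65,
    "jerk_diff:nonmental": 0.25,
    "jerk:jerk_diff:nonmental": 0.0,
}


@dataclass(frozen=True)
class StudyRecipe:
    """Study-level generative conditions.

    Defaults mirror the production/perception design: 51 animators each
    producing one 45 s animation per word, 37 observers each producing five
    own animations and rating eight speed-percentile exemplars per word on
    1-10 scales.
    """

    n_animators: int = 51
    n_observers: int = 37
    exemplars_per_word: int = 8
    duration_s: float = 45.0
    frame_rate_hz: float = 133.0
    betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETAS))
    subject_sd: float = 0.5
    item_sd: float = 0.5
    residual_sd: float = 1.0
    rating_baseline: float = 5.0
    nontarget_noise_sd: float = 0.1
    speed_spread: float = 0.35  # lognormal sd of per-animator speed multiplier
    amplitude_jitter: float = 0.1
    word_params: dict[WordCategory, dict] | None = None  # overrides defaults
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subject_sd", "item_sd", "residual_sd", "nontarget_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.exemplars_per_word > self.n_animators:
            raise ValueError(
                "exemplars_per_word cannot exceed the animations available per word"
            )


@dataclass
class StudyData:
    """Everything gen_study emits, plus the generative ground truth."""

    recordings: list[AnimationRecording]  # stimulus pool (animator cohort)
    productions: list[AnimationRecording]  # observers' own animations
    trials: list[RatingTrial]
    stimulus_features: pd.DataFrame  # indexed by animation_id
    production_features: pd.DataFrame  # indexed by (observer_id, word)
    trial_table: FeatureTable  # trial rows incl. z-scored predictors + truth cols
    truth: dict


def _make_recording(
    word: WordCategory,
    person_id: str,
    animation_id: str,
    recipe: StudyRecipe,
    speed_mult: float,
    amp_mult: float,
    seed: int,
) -> AnimationRecording:
    p = (recipe.word_params or WORD_TRAJECTORY_DEFAULTS)[word]
    traj = TrajectoryRecipe(
        components=tuple(
            (nu, amp * amp_mult, phase) for nu, amp, phase in p["components"]
        ),
        base_speed=p["base_speed"] * speed_mult,
        duration_s=recipe.duration_s,
        frame_rate_hz=recipe.frame_rate_hz,
        tracings=max(4.0, 10.0 * recipe.duration_s / 45.0),
        rotation_rate_deg_per_frame=p["rotation_rate"] * speed_mult,
        noise_sd=p["noise_sd"],
        seed=seed,
    )
    return gen_pure_frequency_trajectory(
        traj, animation_id=animation_id, animator_id=person_id, word=word
    )


def _feature_row(rec: AnimationRecording) -> dict:
    prof = compute_kinematics(rec)
    return {
        "mean_jerk": prof.mean_jerk,
        "mean_acceleration": prof.mean_acceleration,
        "mean_speed": prof.mean_speed,
        "mean_rotation": prof.mean_rotation,
        "simultaneous_movement": prof.simultaneous_movement,
        "relative_distance": prof.relative_distance,
    }


def gen_study(recipe: StudyRecipe) -> StudyData:
    """Generate a full synthetic study with known regression structure.

    The latent accuracy of each perception trial is
    ``X beta + u_subject + u_item + eps`` with X built from the z-scored
    stimulus jerk, the z-scored observer-animator jerk difference and the
    non-mental dummy (z-scoring is within the realized trial sample, as the
    analysis pipeline does it).  Ratings encode the latent accuracy;
    ``truth`` records coefficients, random effects, residuals, the clipping
    rate and the generative R-squared.
    """
    rng = np.random.default_rng(recipe.seed)
    words = list(WordCategory)

    recordings: list[AnimationRecording] = []
    stim_rows = {}
    for a in range(recipe.n_animators):
        animator = f"anim{a:03d}"
        speed_mult = float(rng.lognormal(0.0, recipe.speed_spread))
        for word in words:
            amp_mult = float(rng.lognormal(0.0, recipe.amplitude_jitter))
            anim_id = f"{animator}_{word.value}"
            rec = _make_recording(
                word, animator, anim_id, recipe, speed_mult, amp_mult,
                seed=int(rng.integers(2**31)),
            )
            recordings.append(rec)
            row = _feature_row(rec)
            row["word"] = word.value
            stim_rows[anim_id] = row
    stimulus_features = pd.DataFrame.from_dict(stim_rows, orient="index")
    stimulus_features.index.name = "animation_id"

    productions: list[AnimationRecording] = []
    prod_rows = {}
    for o in range(recipe.n_observers):
        observer = f"obs{o:03d}"
        speed_mult = float(rng.lognormal(0.0, recipe.speed_spread))
        for word in words:
            amp_mult = float(rng.lognormal(0.0, recipe.amplitude_jitter))
            rec = _make_recording(
                word, observer, f"{observer}_{word.value}", recipe,
                speed_mult, amp_mult, seed=int(rng.integers(2**31)),
            )
            productions.append(rec)
            prod_rows[(observer, word.value)] = _feature_row(rec)
    production_features = pd.DataFrame.from_dict(prod_rows, orient="index")
    production_features.index = pd.MultiIndex.from_tuples(
        production_features.index, names=["observer_id", "word"]
    )

    # percentile-based exemplar selection: per word, rank the pool by mean
    # speed into exemplars_per_word equal bins; each observer sees one
    # randomly drawn animation per bin.
    k = recipe.exemplars_per_word
    pools: dict[WordCategory, list[list[str]]] = {}
    for word in words:
        sub = stimulus_features[stimulus_features["word"] == word.value]
        ordered = sub.sort_values("mean_speed").index.to_list()
        bins = [list(chunk) for chunk in np.array_split(ordered, k)]
        pools[word] = bins

    rows = []
    for o in range(recipe.n_observers):
        observer = f"obs{o:03d}"
        for word in words:
            for b, pool in enumerate(pools[word]):
                anim_id = pool[int(rng.integers(len(pool)))]
                stim = stimulus_features.loc[anim_id]
                prod = production_features.loc[(observer, word.value)]
                row = {
                    "observer_id": observer,
                    "animation_id": anim_id,
                    "word": word.value,
                    "is_mental": word.is_mental,
                    "speed_bin": b + 1,
                    "jerk_diff_raw": similarity_difference(
                        stim["mean_jerk"], prod["mean_jerk"]
                    ),
                }
                for col in stimulus_features.columns:
                    if col != "word":
                        row[col] = stim[col]
                rows.append(row)
    df = pd.DataFrame(rows)

    def zscore(x: np.ndarray) -> np.ndarray:
        return (x - x.mean()) / x.std(ddof=0)

    df["jerk"] = zscore(df["mean_jerk"].to_numpy(dtype=float))
    df["jerk_diff"] = zscore(df["jerk_diff_raw"].to_numpy(dtype=float))
    df["nonmental"] = (~df["is_mental"].to_numpy(dtype=bool)).astype(float)

    b = recipe.betas
    X = (
        b.get("intercept", 0.0)
        + b.get("jerk", 0.0) * df["jerk"]
        + b.get("jerk_diff", 0.0) * df["jerk_diff"]
        + b.get("nonmental", 0.0) * df["nonmental"]
        + b.get("jerk:jerk_diff", 0.0) * df["jerk"] * df["jerk_diff"]
        + b.get("jerk:nonmental", 0.0) * df["jerk"] * df["nonmental"]
        + b.get("jerk_diff:nonmental", 0.0) * df["jerk_diff"] * df["nonmental"]
        + b.get("jerk:jerk_diff:nonmental", 0.0)
        * df["jerk"] * df["jerk_diff"] * df["nonmental"]
    ).to_numpy(dtype=float)

    observers = df["observer_id"].unique()
    items = df["animation_id"].unique()
    u_subj = dict(zip(observers, rng.normal(0, recipe.subject_sd, len(observers))))
    u_item = dict(zip(items, rng.normal(0, recipe.item_sd, len(items))))
    eps = rng.normal(0, recipe.residual_sd, len(df))
    latent = (
        X
        + df["observer_id"].map(u_subj).to_numpy()
        + df["animation_id"].map(u_item).to_numpy()
        + eps
    )
    df["latent_accuracy"] = latent

    base = recipe.rating_baseline
    trials = []
    clipped = 0
    for i, row in df.iterrows():
        word = WordCategory(row["word"])
        target_raw = base + latent[i]
        target = float(np.clip(target_raw, 1.0, 10.0))
        clipped += int(target != target_raw)
        ratings = {}
        for w in words:
            if w == word:
                ratings[w] = target
            else:
                ratings[w] = float(
                    np.clip(base + rng.normal(0, recipe.nontarget_noise_sd), 1, 10)
                )
        trials.append(
            RatingTrial(
                observer_id=row["observer_id"],
                animation_id=row["animation_id"],
                target_word=word,
                ratings=ratings,
            )
        )
    df["accuracy"] = [accuracy_score(tr) for tr in trials]

    var_fixed = float(np.var(X))
    var_total = float(np.var(latent))
    truth = {
        "betas": dict(b),
        "subject_sd": recipe.subject_sd,
        "item_sd": recipe.item_sd,
        "residual_sd": recipe.residual_sd,
        "subject_effects": u_subj,
        "item_effects": u_item,
        "clip_rate": clipped / len(df),
        "generative_r2_fixed": var_fixed / var_total if var_total else float("nan"),
        "jerk_z_params": (
            float(df["mean_jerk"].mean()), float(df["mean_jerk"].std(ddof=0))
        ),
    }
    return StudyData(
        recordings=recordings,
        productions=productions,
        trials=trials,
        stimulus_features=stimulus_features,
        production_features=production_features,
        trial_table=FeatureTable(df),
        truth=truth,
    )


def gen_null_spectra(
    n_per_group: int,
    n_points: int = 101,
    noise_model: str = "smooth",
    seed: int | None = None,
    n_harmonics: int = 12,
):
    """Exchangeable five-group unit-area spectra from one common distribution.

    Each spectrum is ``exp`` of a smooth random Fourier series with
    1/k-decaying harmonic amplitudes (``noise_model="smooth"``) or of white
    noise (``"white"``), normalized to unit trapezoidal area on the grid.

    Returns ``(spectra, labels, grid)`` with ``spectra`` of shape
    ``(5 * n_per_group, n_points)``.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 spectra per group")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.02, 10.0, n_points)
    s = np.linspace(0, np.pi, n_points)
    n_total = 5 * n_per_group
    spectra = np.empty((n_total, n_points))
    for i in range(n_total):
        if noise_model == "smooth":
            f = np.zeros(n_points)
            for k in range(1, n_harmonics + 1):
                a, ph = rng.normal(0, 1.0 / k), rng.uniform(0, 2 * np.pi)
                f += a * np.cos(k * s + ph)
        elif noise_model == "white":
            f = rng.normal(0, 0.5, n_points)
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
        d = np.exp(f)
        spectra[i] = d / np.trapezoid(d, grid)
    labels = [w for w in WordCategory for _ in range(n_per_group)]
    return spectra, labels, grid
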