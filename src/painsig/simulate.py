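"""Synthetic trial-level brain data with planted ground truth.

The generator emulates the statistical structure of multi-study thermal-pain
experiments: several calibrated stimulus intensity levels, ~50 painful
trials per subject, a nociceptive voxel pattern whose expression tracks
stimulus intensity, and an *endogenous* (intensity-independent) pattern with
pro-pain and anti-pain subregions whose trial-by-trial amplitude drives pain
ratings beyond intensity. Psychological manipulations (expectancy cues,
perceived control) shift the endogenous amplitude, so their effect on pain is
mediated through the planted pattern — giving every downstream stage
(residualization, decoding, group aggregation, mediation) a recoverable
target.

Design presets mirror two published trial designs:

* ``study6`` — 2x2 factorial (perceived control x expectancy), 8 runs of
  8 trials, 16 trials per cell, high/low heat delivered with 50% probability
  in every cell, perceived-control self-reports on a 0-100 scale.
* ``study5`` — auditory expectancy cues; the low-pain cue is followed by low
  or medium heat (50/50, LL/LM trial types), the high-pain cue by medium or
  high heat (50/50, HM/HH); medium-intensity trials are flagged for
  mediation analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .grid import GridSpec, WeightMap, make_grid

__all__ = [
    "GroundTruth",
    "StudyDesign",
    "TrialDataset",
    "TimingSpec",
    "BoldRun",
    "make_grid",
    "generate_reference_signature",
    "make_ground_truth",
    "study6_truth",
    "make_study_design",
    "generate_trial_dataset",
    "generate_subjects",
    "generate_bold_run",
]


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Planted patterns and effect sizes for the generative model.

    The per-trial generative model (painful trials) is::

        endo_amp  = sum_f a_f * code_f  (+ a*M1 routing for perceived control)
                    + u_subject + noise_endo * eps
        X[t]      = intensity_gain * level * nociceptive
                    + endogenous_gain * endo_amp * endogenous
                    + noise_shared * g_t . noise_patterns
                    + noise_vox * eps_vox
        rating*   = rating_intensity_gain * level
                    + mediator_pain_path * endo_amp
                    + direct_path * sum_f code_f + noise_rating * eps
        rating    = scale midpoint + rating_scale * rating*, clipped to bounds

    where ``a_f = manipulation_path`` for every condition factor, ``u_subject``
    is a between-subject offset with s.d. ``subject_sd``, and for a factor
    named ``control`` the condition code is routed through a per-trial
    perceived-control self-report M1 (three-path structure
    X -> M1 -> endogenous amplitude -> rating).

    Besides i.i.d. voxel noise, trials carry spatially structured noise:
    random amplitudes ``g_t`` on a few fixed unit-norm spatial modes
    (``noise_patterns``), emulating global and physiological fluctuations.
    These modes are rating-independent, so a multivariate decoder can learn
    to project them out while voxel-wise univariate decoding cannot — the
    property that gives pattern-based prediction its edge on real data.
    """

    grid: GridSpec
    nociceptive: np.ndarray
    endogenous: np.ndarray
    subregion_labels: np.ndarray  # int per voxel, 0 = background
    subregion_signs: dict  # label -> +1 / -1
    overlap: float  # realized fraction of endogenous support where noci != 0
    intensity_gain: float = 1.0
    endogenous_gain: float = 1.0
    manipulation_path: float = 0.3
    mediator_pain_path: float = 1.0
    direct_path: float = 0.1
    control_path: float = 0.8
    rating_intensity_gain: float = 1.0
    rating_scale: float = 1.0
    subject_sd: float = 0.5
    noise_endo: float = 1.0
    noise_vox: float = 0.5
    noise_rating: float = 0.8
    noise_control: float = 0.5
    noise_shared: float = 2.0
    noise_patterns: np.ndarray | None = None  # (k, n_vox) structured noise modes
    seed: int = 0

    def __post_init__(self):
        for name in ("nociceptive", "endogenous"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (self.grid.n_vox,):
                raise ValueError(f"{name} pattern is not on the grid")
            setattr(self, name, v)
        self.subregion_labels = np.asarray(self.subregion_labels, dtype=int)

    def to_json(self) -> str:
        """Serializable sidecar (patterns included as lists)."""
        d = {
            "shape": list(self.grid.shape),
            "overlap": self.overlap,
            "effect_sizes": {
                k: getattr(self, k)
                for k in (
                    "intensity_gain", "endogenous_gain", "manipulation_path",
                    "mediator_pain_path", "direct_path", "control_path",
                    "rating_intensity_gain", "rating_scale", "subject_sd",
                    "noise_endo", "noise_vox", "noise_rating", "noise_control",
                    "noise_shared",
                )
            },
            "seed": self.seed,
            "nociceptive": self.nociceptive.tolist(),
            "endogenous": self.endogenous.tolist(),
            "subregion_labels": self.subregion_labels.tolist(),
            "subregion_signs": {str(k): int(v) for k, v in self.subregion_signs.items()},
        }
        return json.dumps(d)


def generate_reference_signature(grid: GridSpec, support_fraction: float = 1.0,
                                 seed: int | None = 0) -> WeightMap:
    """Random unit-norm reference weight map (a nociceptive-signature stand-in).

    A ``support_fraction`` of in-mask voxels receive i.i.d. normal weights;
    the rest are zero; the map is scaled to unit Euclidean norm.
    """
    if not 0.0 < support_fraction <= 1.0:
        raise ValueError("support_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = grid.n_vox
    w = rng.standard_normal(n)
    if support_fraction < 1.0:
        k = max(1, int(round(support_fraction * n)))
        keep = rng.choice(n, size=k, replace=False)
        full = np.zeros(n)
        full[keep] = w[keep]
        w = full
    w /= np.linalg.norm(w)
    return WeightMap(grid=grid, values=w, name="reference")


def _place_blocks(grid: GridSpec, n_blocks: int, block_size: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Place non-overlapping cubic blocks inside the mask; return labels.

    All feasible block origins (cube fully in-mask) are enumerated, then
    drawn in shuffled order, greedily skipping overlaps — deterministic
    given the RNG and robust on small masks.
    """
    b = block_size
    feasible = [
        (i, j, k)
        for i in range(grid.shape[0] - b + 1)
        for j in range(grid.shape[1] - b + 1)
        for k in range(grid.shape[2] - b + 1)
        if grid.mask[i:i + b, j:j + b, k:k + b].all()
    ]
    order = rng.permutation(len(feasible))
    labels = np.zeros(grid.shape, dtype=int)
    placed = 0
    for pos in order:
        i, j, k = feasible[pos]
        sl = (slice(i, i + b), slice(j, j + b), slice(k, k + b))
        if labels[sl].any():
            continue
        labels[sl] = placed + 1
        placed += 1
        if placed == n_blocks:
            break
    if placed < n_blocks:
        raise ValueError(
            f"could not place {n_blocks} blocks of size {block_size} in the mask"
        )
    return labels


def make_ground_truth(grid: GridSpec, *, n_subregions: int = 6, block_size: int = 3,
                      overlap: float = 0.5, noci_support: float = 0.5,
                      seed: int = 0, **effects) -> GroundTruth:
    """Build planted patterns with labeled pro-/anti-pain subregions.

    The endogenous pattern is piecewise-constant over ``n_subregions``
    non-overlapping cubic blocks with alternating signs (pro-pain positive,
    anti-pain negative), unit Euclidean norm. The nociceptive pattern has
    random normal weights on roughly ``noci_support`` of voxels; within the
    endogenous support, nociceptive voxels are included with probability
    ``overlap`` (so spatial overlap between the two planted systems is
    configurable); the realized overlap fraction is recorded.

    Extra keyword arguments override :class:`GroundTruth` effect sizes.
    """
    rng = np.random.default_rng(seed)
    labels_vol = _place_blocks(grid, n_subregions, block_size, rng)
    labels = labels_vol[grid.mask]
    endo = np.zeros(grid.n_vox)
    signs = {}
    for k in range(1, n_subregions + 1):
        sign = 1 if (k % 2 == 1) else -1
        signs[k] = sign
        endo[labels == k] = sign
    endo /= np.linalg.norm(endo)

    in_endo = labels > 0
    support = np.where(
        in_endo,
        rng.random(grid.n_vox) < overlap,
        rng.random(grid.n_vox) < noci_support,
    )
    if not support.any():
        support[rng.integers(grid.n_vox)] = True
    noci = np.where(support, rng.standard_normal(grid.n_vox), 0.0)
    noci /= np.linalg.norm(noci)
    realized = float(support[in_endo].mean()) if in_endo.any() else 0.0

    n_modes = int(effects.pop("n_noise_modes", 5))
    modes = rng.standard_normal((n_modes, grid.n_vox))
    modes /= np.linalg.norm(modes, axis=1, keepdims=True)

    return GroundTruth(
        grid=grid, nociceptive=noci, endogenous=endo,
        subregion_labels=labels, subregion_signs=signs,
        overlap=realized, noise_patterns=modes, seed=seed, **effects,
    )


def study6_truth(grid: GridSpec, seed: int = 0, **overrides) -> GroundTruth:
    """Ground truth calibrated for the 2x2 control-by-expectancy design.

    Path strengths are set so the standardized indirect (manipulation ->
    endogenous amplitude -> rating) is ~0.06, the magnitude reported for
    cue and perceived-control mediation effects in this literature.
    """
    defaults = dict(manipulation_path=0.29, mediator_pain_path=0.5,
                    noise_rating=1.0, subject_sd=0.3, direct_path=0.05)
    defaults.update(overrides)
    return make_ground_truth(grid, seed=seed, **defaults)


# ---------------------------------------------------------------------------
# study designs


@dataclass
class StudyDesign:
    """A trial design: runs, intensity levels, condition factors, assignment.

    ``factors`` maps a factor name to a dict of ``label -> ±1`` codes.
    ``assignment`` maps a condition cell (tuple of factor labels, in
    ``factors`` order) to a probability row over ``intensity_levels``;
    every row must sum to 1.
    """

    study_label: str
    n_runs: int
    trials_per_run: int
    intensity_levels: list
    factors: dict = field(default_factory=dict)
    assignment: dict = field(default_factory=dict)
    rating_bounds: tuple = (0.0, 100.0)
    nonpainful_fraction: float = 0.0
    mediation_levels: list | None = None  # intensity levels kept for mediation
    balanced_cells: bool = True

    def __post_init__(self):
        for cell, row in self.assignment.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"assignment row for cell {cell!r} sums to {total}, not 1"
                )
            for lev in row:
                if lev not in self.intensity_levels:
                    raise ValueError(f"unknown intensity level {lev!r} in cell {cell!r}")

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run

    def cells(self) -> list:
        """All condition cells (cartesian product of factor labels)."""
        if not self.factors:
            return [()]
        out = [()]
        for labels in self.factors.values():
            out = [c + (lab,) for c in out for lab in labels]
        return out

    def trial_table(self, rng: np.random.Generator) -> pd.DataFrame:
        """Draw a per-trial table: run, trial, factor labels/codes, intensity.

        Condition cells are assigned in balanced fashion (equal counts,
        order shuffled); the intensity level of each trial is then drawn
        from its cell's probability row.
        """
        n = self.n_trials
        cells = self.cells()
        if self.balanced_cells and n % len(cells) == 0:
            cell_of_trial = np.repeat(np.arange(len(cells)), n // len(cells))
        else:
            cell_of_trial = rng.integers(0, len(cells), size=n)
        rng.shuffle(cell_of_trial)

        rows = []
        for t in range(n):
            cell = cells[cell_of_trial[t]]
            row = {"run": t // self.trials_per_run + 1,
                   "trial": t % self.trials_per_run + 1}
            for (fname, fmap), lab in zip(self.factors.items(), cell):
                row[fname] = lab
                row[f"{fname}_code"] = fmap[lab]
            prow = self.assignment.get(cell)
            if prow is None:
                level = self.intensity_levels[
                    rng.integers(len(self.intensity_levels))]
            else:
                levs = list(prow.keys())
                ps = np.array([prow[v] for v in levs], dtype=float)
                level = levs[rng.choice(len(levs), p=ps)]
            row["intensity_level"] = level
            rows.append(row)
        df = pd.DataFrame(rows)
        if self.mediation_levels is not None:
            df["mediation_flag"] = df["intensity_level"].isin(
                self.mediation_levels).astype(int)
        return df


def make_study_design(preset: str = "generic", **overrides) -> StudyDesign:
    """Construct a :class:`StudyDesign` from a named preset.

    Presets
    -------
    ``study6``
        8 runs x 8 trials; balanced 2x2 crossing of perceived control
        (HC/LC) and expectancy cue pair (LE/HE); low/high heat with 50%
        probability in every cell; perceived-control self-reports present.
    ``study5``
        6 runs x 8 trials; expectancy cue factor; the low cue is followed by
        low or medium heat with 50% chance (LL/LM) and the high cue by
        medium or high heat (HM/HH); medium trials flagged for mediation.
    ``generic``
        Configurable levels (default three, uniform), one balanced ±1 cue
        factor, 5 runs x 11 trials with a 10% non-painful fraction —
        about 50 painful trials per subject.
    """
    if preset == "study6":
        spec = dict(
            study_label="study6", n_runs=8, trials_per_run=8,
            intensity_levels=["low", "high"],
            factors={"control": {"HC": 1, "LC": -1},
                     "expectancy": {"LE": 1, "HE": -1}},
            assignment={
                (c, e): {"low": 0.5, "high": 0.5}
                for c in ("HC", "LC") for e in ("LE", "HE")
            },
            rating_bounds=(0.0, 100.0),
        )
    elif preset == "study5":
        spec = dict(
            study_label="study5", n_runs=6, trials_per_run=8,
            intensity_levels=["low", "medium", "high"],
            factors={"cue": {"L": 1, "H": -1}},
            assignment={
                ("L",): {"low": 0.5, "medium": 0.5},
                ("H",): {"medium": 0.5, "high": 0.5},
            },
            rating_bounds=(0.0, 10.0),
            mediation_levels=["medium"],
        )
    elif preset == "generic":
        spec = dict(
            study_label="generic", n_runs=5, trials_per_run=11,
            intensity_levels=[1, 2, 3],
            factors={"cue": {"A": 1, "B": -1}},
            assignment={},
            rating_bounds=(0.0, 100.0),
            nonpainful_fraction=0.10,
        )
    else:
        raise ValueError(f"unknown preset {preset!r}")
    spec.update(overrides)
    return StudyDesign(**spec)


# ---------------------------------------------------------------------------
# trial datasets


_LEVEL_VALUES = {"low": 1.0, "medium": 2.0, "high": 3.0}


def _level_value(level) -> float:
    """Numeric value of an intensity level code."""
    if isinstance(level, str):
        try:
            return _LEVEL_VALUES[level]
        except KeyError:
            raise ValueError(f"unknown intensity level code {level!r}") from None
    return float(level)


@dataclass
class TrialDataset:
    """One subject's trials-by-voxels data with per-trial metadata.

    ``excluded_flag``/``excluded_reason`` persist QC decisions instead of
    dropping rows, so trial counts remain auditable.
    """

    subject_id: str
    grid: GridSpec
    X: np.ndarray  # (n_trials, n_vox)
    ratings: np.ndarray
    intensity: np.ndarray  # level codes (object)
    conditions: pd.DataFrame  # one ±1 column per factor
    painful_flag: np.ndarray
    excluded_flag: np.ndarray
    excluded_reason: np.ndarray
    rating_bounds: tuple = (0.0, 100.0)
    perceived_control_rating: np.ndarray | None = None
    mediation_flag: np.ndarray | None = None
    run: np.ndarray | None = None
    endo_amp: np.ndarray | None = None  # generative ground truth, for tests

    def __post_init__(self):
        n = self.X.shape[0]
        if self.X.shape[1] != self.grid.n_vox:
            raise ValueError("X column count != grid n_vox")
        fields = {
            "ratings": self.ratings, "intensity": self.intensity,
            "painful_flag": self.painful_flag,
            "excluded_flag": self.excluded_flag,
            "excluded_reason": self.excluded_reason,
        }
        if self.perceived_control_rating is not None:
            fields["perceived_control_rating"] = self.perceived_control_rating
        if self.mediation_flag is not None:
            fields["mediation_flag"] = self.mediation_flag
        if self.run is not None:
            fields["run"] = self.run
        for name, v in fields.items():
            if len(v) != n:
                raise ValueError(f"{name} has {len(v)} rows, expected {n}")
        if len(self.conditions) != n:
            raise ValueError("conditions row count mismatch")
        lo, hi = self.rating_bounds
        r = np.asarray(self.ratings, dtype=float)
        if (r < lo - 1e-9).any() or (r > hi + 1e-9).any():
            raise ValueError("ratings outside scale bounds")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    def included(self) -> np.ndarray:
        """Boolean mask of painful, non-excluded trials."""
        return np.asarray(self.painful_flag, bool) & ~np.asarray(self.excluded_flag, bool)

    def intensity_values(self) -> np.ndarray:
        return np.array([_level_value(v) for v in self.intensity], dtype=float)

    def meta(self) -> pd.DataFrame:
        """Per-trial metadata table (the on-disk TSV layout)."""
        df = pd.DataFrame({
            "subject": self.subject_id,
            "run": self.run if self.run is not None else 1,
            "trial": np.arange(1, self.n_trials + 1),
            "intensity_level": self.intensity,
            "rating": self.ratings,
            "painful_flag": np.asarray(self.painful_flag, int),
            "excluded_flag": np.asarray(self.excluded_flag, int),
            "excluded_reason": self.excluded_reason,
        })
        for c in self.conditions.columns:
            df[c] = np.asarray(self.conditions[c])
        if self.perceived_control_rating is not None:
            df["perceived_control_rating"] = self.perceived_control_rating
        if self.mediation_flag is not None:
            df["mediation_flag"] = np.asarray(self.mediation_flag, int)
        return df


def generate_trial_dataset(design: StudyDesign, grid: GridSpec,
                           truth: GroundTruth, subject_id: str = "sub-01",
                           seed: int = 0) -> TrialDataset:
    """Simulate one subject's trial-level dataset under the planted model.

    See :class:`GroundTruth` for the generative equations. A
    ``design.nonpainful_fraction`` of trials is flagged non-painful: these
    carry no planted signal and near-zero ratings, mirroring the warmth
    trials removed before signature development.
    """
    if not truth.grid.matches(grid):
        raise ValueError("ground truth is not on the supplied grid")
    rng = np.random.default_rng(seed)
    table = design.trial_table(rng)
    n = len(table)
    levels = table["intensity_level"].to_numpy()
    level_vals = np.array([_level_value(v) for v in levels])

    factor_names = list(design.factors.keys())
    codes = {f: table[f"{f}_code"].to_numpy(dtype=float) for f in factor_names}

    painful = np.ones(n, dtype=bool)
    if design.nonpainful_fraction > 0:
        k = int(round(design.nonpainful_fraction * n))
        if k:
            idx = rng.choice(n, size=k, replace=False)
            painful[idx] = False

    # endogenous amplitude: manipulations + subject offset + trial noise
    u = truth.subject_sd * rng.standard_normal()
    endo_amp = u + truth.noise_endo * rng.standard_normal(n)
    control_rating = None
    for f in factor_names:
        if f == "control":
            # three-path routing: X -> perceived control (M1) -> amplitude
            m1 = (truth.control_path * codes[f]
                  + truth.noise_control * rng.standard_normal(n))
            endo_amp = endo_amp + truth.manipulation_path * m1
            control_rating = m1
        else:
            endo_amp = endo_amp + truth.manipulation_path * codes[f]
    endo_amp = np.where(painful, endo_amp, 0.0)

    drive = np.where(painful, level_vals, 0.0)
    X = (truth.intensity_gain * drive[:, None] * truth.nociceptive[None, :]
         + truth.endogenous_gain * endo_amp[:, None] * truth.endogenous[None, :]
         + truth.noise_vox * rng.standard_normal((n, grid.n_vox)))
    if truth.noise_shared > 0 and truth.noise_patterns is not None:
        g = rng.standard_normal((n, truth.noise_patterns.shape[0]))
        X = X + truth.noise_shared * g @ truth.noise_patterns

    direct = sum(codes[f] for f in factor_names) if factor_names else 0.0
    latent = (truth.rating_intensity_gain * drive
              + truth.mediator_pain_path * endo_amp
              + np.where(painful, truth.direct_path * direct, 0.0)
              + truth.noise_rating * rng.standard_normal(n) * painful)
    lo, hi = design.rating_bounds
    mid = 0.5 * (lo + hi)
    ratings = np.where(painful,
                       np.clip(mid + truth.rating_scale * latent, lo, hi),
                       np.clip(lo + 0.1 * np.abs(rng.standard_normal(n)), lo, hi))

    if control_rating is not None:
        # report M1 on the rating scale
        control_rating = np.clip(mid + truth.rating_scale * control_rating, lo, hi)

    conditions = pd.DataFrame({f"{f}_code": codes[f] for f in factor_names})
    mediation = (table["mediation_flag"].to_numpy()
                 if "mediation_flag" in table else None)
    return TrialDataset(
        subject_id=subject_id, grid=grid, X=X, ratings=ratings,
        intensity=levels, conditions=conditions, painful_flag=painful,
        excluded_flag=np.zeros(n, dtype=bool),
        excluded_reason=np.array([""] * n, dtype=object),
        rating_bounds=design.rating_bounds,
        perceived_control_rating=control_rating,
        mediation_flag=mediation,
        run=table["run"].to_numpy(),
        endo_amp=endo_amp,
    )


def generate_subjects(design: StudyDesign, grid: GridSpec, truth: GroundTruth,
                      n_subjects: int = 20, seed: int = 0) -> list:
    """Simulate a cohort; subject seeds are derived deterministically."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    return [
        generate_trial_dataset(design, grid, truth,
                               subject_id=f"sub-{i + 1:02d}", seed=int(s))
        for i, s in enumerate(seeds)
    ]


# ---------------------------------------------------------------------------
# raw BOLD runs (fixtures for the single-trial GLM)


@dataclass
class TimingSpec:
    """Scan timing for a simulated run."""

    n_scans: int
    tr: float
    onsets: np.ndarray  # seconds
    duration: float = 10.0

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.n_scans < 1 or self.tr <= 0:
            raise ValueError("need n_scans >= 1 and tr > 0")


@dataclass
class BoldRun:
    """A simulated voxels-by-time run plus its generative bookkeeping."""

    grid: GridSpec
    data: np.ndarray  # (n_scans, n_vox)
    events: pd.DataFrame  # onset, duration, trial
    amplitudes: np.ndarray  # (n_trials, n_vox) planted per-voxel amplitudes
    trial_amplitudes: np.ndarray  # (n_trials,) scalar drive per trial
    spikes: list


def generate_bold_run(design: StudyDesign, grid: GridSpec, truth: GroundTruth,
                      timing: TimingSpec, seed: int = 0,
                      spike_volumes=(), spike_size: float = 50.0,
                      noise_sd: float | None = None) -> BoldRun:
    """Simulate a BOLD run: each trial adds amplitude x (boxcar ⊗ HRF).

    Per-trial voxel amplitudes follow the same planted model as
    :func:`generate_trial_dataset`. Overlapping events are permitted — the
    planted amplitudes are recorded regardless of recoverability. Injected
    spikes add a ``spike_size``-sized offset to whole volumes and are
    returned in ``spikes``.
    """
    from .singletrial import canonical_hrf  # local import; no cycle at runtime

    rng = np.random.default_rng(seed)
    table = design.trial_table(rng)
    n_trials = min(len(table), len(timing.onsets))
    table = table.iloc[:n_trials]
    level_vals = np.array([_level_value(v) for v in table["intensity_level"]])

    endo_amp = (truth.subject_sd * rng.standard_normal()
                + truth.noise_endo * rng.standard_normal(n_trials))
    for f in design.factors:
        endo_amp = endo_amp + truth.manipulation_path * table[f"{f}_code"].to_numpy(float)

    amplitudes = (truth.intensity_gain * level_vals[:, None] * truth.nociceptive[None, :]
                  + truth.endogenous_gain * endo_amp[:, None] * truth.endogenous[None, :])

    hrf = canonical_hrf(timing.tr)
    t_grid = np.arange(timing.n_scans)
    data = np.zeros((timing.n_scans, grid.n_vox))
    for t in range(n_trials):
        onset_scan = timing.onsets[t] / timing.tr
        box = ((t_grid >= onset_scan)
               & (t_grid < onset_scan + timing.duration / timing.tr)).astype(float)
        reg = np.convolve(box, hrf)[: timing.n_scans]
        data += np.outer(reg, amplitudes[t])

    sd = truth.noise_vox if noise_sd is None else noise_sd
    if sd > 0:
        data = data + sd * rng.standard_normal(data.shape)
    spikes = sorted(int(v) for v in spike_volumes)
    for v in spikes:
        data[v] += spike_size

    events = pd.DataFrame({
        "onset": timing.onsets[:n_trials],
        "duration": timing.duration,
        "trial": np.arange(1, n_trials + 1),
    })
    return BoldRun(grid=grid, data=data, events=events, amplitudes=amplitudes,
                   trial_amplitudes=endo_amp, spikes=spikes)
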