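"""Synthetic cohort generation: subject tables and band-limited time series
with planted, group-specific coherence alterations.

The generator emulates a five-group resting-state study on the psychosis
continuum: healthy controls (HC), non-clinical individuals with
hallucinations (NC-H), schizophrenia-spectrum patients with hallucinations
(SCZ-H), and bipolar-I patients with (BD-H) and without (BD) lifetime
hallucinations.  Default group sizes are 228/40/99/74/42 (483 subjects) and
covariate distributions mimic the reference cohort's demographics.

Signals are white Gaussian noise band-passed to 0.01-0.15 Hz.  Coherence is
planted by mixing an *edge-set-specific* latent source, band-limited to
0.05-0.10 Hz, into every node its edge set touches:

    x_i(t) = sqrt(1 - S_i) * n_i(t) + sum_k sqrt(s_k) * z_k(t)

where ``s_k`` is effect k's ``shared_variance``, ``z_k`` its latent source
(one per effect, freshly drawn per subject) and ``S_i`` the total shared
variance at node i.  All node pairs within one effect's node set gain
coherence, the listed edges among them; connected planted components are
therefore representable at any shared_variance < 1.  ``increase`` effects
mix the source only into the target group's subjects; ``decrease`` effects
mix it into everyone *except* the target group, so the target group sits
below the cohort baseline on those edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .atlas import Atlas

GROUPS = ("HC", "NC-H", "SCZ-H", "BD-H", "BD")

#: Default group sizes of the emulated cohort (total 483).
DEFAULT_GROUP_SIZES = {"HC": 228, "NC-H": 40, "SCZ-H": 99, "BD-H": 74, "BD": 42}

#: Per-group covariate distributions: age mean/SD (years), male fraction,
#: relative mean displacement mean/SD (mm), lifetime auditory/visual
#: hallucination probabilities, symptom-score availability.
DEFAULT_COVARIATES = {
    "HC": dict(age=(40.7, 14.6), p_male=121 / 228, motion=(0.08, 0.03), p_aud=0.0, p_vis=0.0, scored=False),
    "NC-H": dict(age=(43.1, 14.5), p_male=10 / 40, motion=(0.08, 0.03), p_aud=1.0, p_vis=33 / 40, scored=True),
    "SCZ-H": dict(age=(32.3, 10.9), p_male=67 / 99, motion=(0.10, 0.04), p_aud=80 / 99, p_vis=53 / 99, scored=True),
    "BD-H": dict(age=(46.2, 11.6), p_male=37 / 74, motion=(0.10, 0.03), p_aud=39 / 74, p_vis=51 / 74, scored=False),
    "BD": dict(age=(52.3, 11.9), p_male=23 / 42, motion=(0.10, 0.03), p_aud=0.0, p_vis=0.0, scored=False),
}

#: Default sampling interval (s).  At fs = 1.6 Hz the level-4 wavelet scale
#: spans exactly [fs/32, fs/16] = 0.05-0.10 Hz.
DEFAULT_TR = 0.625


@dataclass(frozen=True)
class PlantedEffect:
    """A group-specific coherence alteration on a designated edge set.

    ``visual_only`` restricts an effect to subjects of the target group who
    have lifetime visual hallucinations, giving modality classifiers a
    recoverable signal.
    """

    target_group: str
    edges: tuple[tuple[int, int], ...]
    direction: str  # {"increase", "decrease"}
    shared_variance: float
    visual_only: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"direction must be increase/decrease, got {self.direction!r}")
        if not 0 <= self.shared_variance < 1:
            raise ValueError("shared_variance must be in [0, 1)")
        edges = tuple(tuple(sorted(e)) for e in self.edges)
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-pair ({i},{i}) in effect edge set")
        object.__setattr__(self, "edges", edges)


@dataclass
class CohortTimeSeries:
    """Per-subject regional signals: array (n_subjects, n_nodes, n_timepoints)."""

    data: np.ndarray
    subject_ids: list[str]
    sampling_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_subjects, n_nodes, n_timepoints)")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contain non-finite samples")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    @property
    def fs(self) -> float:
        return 1.0 / self.sampling_interval


def generate_cohort(
    group_sizes: dict[str, int] | None = None,
    covariate_params: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a subject table with demographics, motion and modality labels.

    Returns a DataFrame with columns subject_id, group, age, sex, motion,
    has_auditory, has_visual, symptom_score (NaN where the score was not
    assessed).  Deterministic given (arguments, seed).
    """
    sizes = dict(DEFAULT_GROUP_SIZES if group_sizes is None else group_sizes)
    params = dict(DEFAULT_COVARIATES)
    if covariate_params:
        for g, p in covariate_params.items():
            params[g] = {**params.get(g, {}), **p}
    unknown = set(sizes) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown groups {sorted(unknown)}")
    if any(n < 0 for n in sizes.values()):
        raise ValueError("group sizes must be nonnegative")
    if sum(sizes.values()) == 0:
        raise ValueError("at least one group must be nonempty")

    rng = np.random.default_rng(seed)
    rows = []
    for group in GROUPS:  # fixed iteration order for determinism
        n = sizes.get(group, 0)
        p = params[group]
        for k in range(n):
            age = float(np.clip(rng.normal(*p["age"]), 18.0, 90.0))
            sex = "m" if rng.random() < p["p_male"] else "f"
            motion = float(max(rng.normal(*p["motion"]), 0.005))
            if group in ("HC", "BD"):
                aud = vis = False
            else:
                aud = bool(rng.random() < p["p_aud"])
                vis = bool(rng.random() < p["p_vis"])
                if not (aud or vis):  # hallucination groups have >=1 modality
                    aud = True
            score = float(rng.gamma(shape=4.0, scale=2.0)) if p["scored"] else np.nan
            rows.append(
                dict(
                    subject_id=f"{group}_{k:03d}",
                    group=group,
                    age=round(age, 2),
                    sex=sex,
                    motion=round(motion, 4),
                    has_auditory=aud,
                    has_visual=vis,
                    symptom_score=np.nan if np.isnan(score) else round(score, 3),
                )
            )
    return pd.DataFrame(rows)


def _bandpass(white: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase band-pass along the last axis, then standardize to unit SD."""
    nyq = fs / 2
    hi = min(hi, 0.98 * nyq)
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    out = sps.sosfiltfilt(sos, white, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return (out - out.mean(axis=-1, keepdims=True)) / sd


def _effect_applies(eff: PlantedEffect, group: str, has_visual: bool) -> bool:
    in_target = group == eff.target_group and (not eff.visual_only or has_visual)
    if eff.direction == "increase":
        return in_target
    return not in_target  # decrease: baseline source everywhere but the target


def generate_timeseries(
    subjects: pd.DataFrame,
    atlas: Atlas,
    effects: list[PlantedEffect] | tuple[PlantedEffect, ...] = (),
    sampling_interval: float = DEFAULT_TR,
    timepoints: int = 256,
    seed: int = 0,
    baseline_band: tuple[float, float] = (0.01, 0.15),
    source_band: tuple[float, float] = (0.05, 0.10),
    motion_nuisance: float = 0.0,
    age_sex_coherence: float = 0.0,
) -> CohortTimeSeries:
    """Simulate regional signals for every subject in the table.

    motion_nuisance : float
        Amplitude of a broadband common source added to every node scaled by
        the subject's motion covariate (a crude shared-artifact model).
    age_sex_coherence : float
        If positive, a global band-limited source whose shared variance rises
        linearly with (standardized) age and male sex, exercising covariate
        adjustment downstream.
    """
    if timepoints < 64:
        raise ValueError("need at least 64 timepoints")
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be positive")
    n_nodes = atlas.n_nodes
    for eff in effects:
        if eff.target_group not in GROUPS:
            raise ValueError(f"effect targets unknown group {eff.target_group!r}")
        for i, j in eff.edges:
            if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise ValueError(f"effect edge ({i},{j}) outside atlas of {n_nodes} nodes")

    fs = 1.0 / sampling_interval
    pad = 64  # settle the zero-phase filter away from the kept window
    T = timepoints + 2 * pad
    rng = np.random.default_rng(seed)
    age_z = (subjects["age"] - subjects["age"].mean()) / max(subjects["age"].std(ddof=0), 1e-9)

    data = np.empty((len(subjects), n_nodes, timepoints))
    for s, row in enumerate(subjects.itertuples(index=False)):
        noise = _bandpass(rng.standard_normal((n_nodes, T)), fs, *baseline_band)
        shared = np.zeros((n_nodes, T))
        svar = np.zeros(n_nodes)
        for eff in effects:
            if not _effect_applies(eff, row.group, row.has_visual):
                continue
            nodes = sorted({n for e in eff.edges for n in e})
            z = _bandpass(rng.standard_normal(T), fs, *source_band)
            shared[nodes] += np.sqrt(eff.shared_variance) * z
            svar[nodes] += eff.shared_variance
        if age_sex_coherence > 0:
            v = float(np.clip(age_sex_coherence * (0.5 + 0.3 * age_z.iloc[s] + 0.3 * (row.sex == "m")), 0.0, 0.8))
            if v > 0:
                g = _bandpass(rng.standard_normal(T), fs, *source_band)
                shared += np.sqrt(v) * g
                svar += v
        if np.any(svar >= 1.0):
            raise ValueError("total planted shared variance >= 1 at some node; lower shared_variance")
        x = np.sqrt(1.0 - svar)[:, None] * noise + shared
        if motion_nuisance > 0:
            art = _bandpass(rng.standard_normal(T), fs, baseline_band[0], baseline_band[1])
            x = x + motion_nuisance * row.motion * art
        data[s] = x[:, pad : pad + timepoints]

    return CohortTimeSeries(data, subjects["subject_id"].tolist(), sampling_interval)
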