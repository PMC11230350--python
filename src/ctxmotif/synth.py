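"""Synthetic cohorts with a known two-timescale latent structure.

The generator emulates the structure the latent models assume: each subject's
multichannel timecourse is driven by a slowly varying per-block *context*
latent and a fast per-timestep *local* latent, mixed nonlinearly into the
observed channels.  Diagnosis groups differ in two ways with known ground
truth:

* the local process of patients (SZ) takes smaller steps than controls (HC),
  mimicking the reduced dynamic range reported for schizophrenia;
* patient context vectors are drawn from a small mixture of modes ("states"),
  one of which is occupied more by older patients and by patients with a worse
  cognition score.

Context changes once per non-overlapping length-W block, so overlapping
analysis windows see mixtures near block boundaries — a deliberate temporal
blur mimicking real data.  The local latent is a stationary AR(1) process with
unit marginal variance and group-specific innovation scale ``sigma_local``
(a standardized random walk in the small-step limit), so the mean consecutive
step distance is strictly monotone in ``sigma_local`` by construction.

Observation model: ``x_t = tanh(A u_t) + B u_t + eps`` with ``u_t = [c; z_t]``
and fixed mixing matrices A, B drawn once from ``mixing_seed``.  The tanh term
guarantees a purely linear connectivity baseline cannot capture everything.
Two seeds separate the "brain" (mixing) from the cohort draw, so one mixing
can generate independent cohorts.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .data import SubjectRecord

__all__ = ["SyntheticParams", "GroundTruth", "generate_cohort", "toy_fixture"]


@dataclasses.dataclass
class SyntheticParams:
    """Generator settings; defaults define the package's study conditions."""

    n_subjects_per_group: int = 150
    n_components: int = 53          #: observed channels N
    n_timesteps: int = 150          #: T per subject
    window_length: int = 30         #: W; context changes per length-W block
    context_dim_true: int = 2
    local_dim_true: int = 2
    sigma_local_hc: float = 1.0     #: local innovation scale, controls
    sigma_local_sz: float = 0.6     #: local innovation scale, patients
    context_modes_sz: int = 3       #: number of patient context modes
    context_mode_separation: float = 3.0  #: mode-center distance from origin
    context_within_sd: float = 0.5  #: within-mode context scatter
    age_effect: float = 1.0         #: designated-mode logit slope per sd of age
    score_effect: float = 1.0       #: designated-mode logit slope per -sd of score
    obs_noise_sd: float = 0.1
    mixing_seed: int = 7
    cohort_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_local_hc", "sigma_local_sz", "context_mode_separation",
                     "context_within_sd", "obs_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.sigma_local_hc <= 1 and 0 < self.sigma_local_sz <= 1):
            raise ValueError("sigma_local must be in (0, 1] (innovation scale of a "
                             "unit-variance AR(1) process)")
        if self.context_modes_sz < 1:
            raise ValueError("context_modes_sz must be >= 1")
        if self.context_dim_true + self.local_dim_true > self.n_components:
            raise ValueError("true latent dims must not exceed the channel count N")


@dataclasses.dataclass
class GroundTruth:
    """True latents aligned with the emitted SubjectRecords.

    ``context[sid]`` is ``[B, context_dim]`` (one row per length-W block),
    ``modes[sid]`` the per-block mode label (HC blocks are mode -1),
    ``local[sid]`` is ``[T, local_dim]``; ``occupancy`` maps subject_id to
    per-mode block counts (patients only).  ``age_mode`` is the index of the
    patient mode whose occupancy increases with age / decreases with score.
    """

    context: dict[str, np.ndarray]
    modes: dict[str, np.ndarray]
    local: dict[str, np.ndarray]
    occupancy: dict[str, np.ndarray]
    mode_centers: np.ndarray
    age_mode: int


def _mode_centers(params: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    """Patient mode centers on one side of the control mode (at the origin).

    Modes form a gradient away from controls — mode 0 the most separated (at
    distance ``context_mode_separation``), later modes progressively closer —
    fanned out at alternating angles so they are distinct clusters.  This
    mirrors the structure the generator emulates: patient window states
    ranging from control-like to almost completely separated, with the most
    separated state the one coupled to age and cognition.  One-sided placement
    keeps the groups linearly separable in the true context space.
    """
    k, d = params.context_modes_sz, params.context_dim_true
    radii = params.context_mode_separation * (k - np.arange(k)) / k
    centers = np.zeros((k, d))
    if d >= 2:
        fan = np.deg2rad(40.0)
        angles = np.array([0.0 if j == 0 else fan * (1 if j % 2 else -1) for j in range(k)])
        centers[:, 0] = radii * np.cos(angles)
        centers[:, 1] = radii * np.sin(angles)
    else:
        centers[:, 0] = radii
    return centers


def _ar1_local(rng: np.random.Generator, n_steps: int, dim: int, sigma: float) -> np.ndarray:
    """Stationary AR(1): z_{t+1} = sqrt(1-s^2) z_t + s eps, unit marginal variance."""
    carry = np.sqrt(1.0 - sigma**2)
    z = np.empty((n_steps, dim))
    z[0] = rng.standard_normal(dim)
    eps = rng.standard_normal((n_steps - 1, dim))
    for t in range(1, n_steps):
        z[t] = carry * z[t - 1] + sigma * eps[t - 1]
    return z


def generate_cohort(params: SyntheticParams) -> tuple[list[SubjectRecord], GroundTruth]:
    """Draw a two-group cohort with known context/local ground truth.

    Deterministic given ``(mixing_seed, cohort_seed)``.  Ages are uniform on
    18–65; cognition scores are Gaussian with group means/sds matching the
    cohort the generator emulates (SZ: -1.6 +- 1.2, HC: 0.0 +- 0.9).
    """
    mix_rng = np.random.default_rng(params.mixing_seed)
    d = params.context_dim_true + params.local_dim_true
    # mixing matrices drawn once per "brain"
    A = mix_rng.standard_normal((params.n_components, d)) / np.sqrt(d)
    B = mix_rng.standard_normal((params.n_components, d)) / np.sqrt(d)
    centers = _mode_centers(params, mix_rng)
    age_mode = 0  # designated age/score-coupled patient mode

    rng = np.random.default_rng(params.cohort_seed)
    T, W = params.n_timesteps, params.window_length
    n_blocks = int(np.ceil(T / W))

    records: list[SubjectRecord] = []
    context, modes, local, occupancy = {}, {}, {}, {}
    for group, sigma in (("SZ", params.sigma_local_sz), ("HC", params.sigma_local_hc)):
        for i in range(params.n_subjects_per_group):
            sid = f"{group.lower()}{i:03d}"
            age = rng.uniform(18.0, 65.0)
            score = rng.normal(-1.6 if group == "SZ" else 0.0,
                               1.2 if group == "SZ" else 0.9)

            # per-block context vectors
            if group == "SZ":
                logits = np.zeros(params.context_modes_sz)
                logits[age_mode] = (
                    params.age_effect * (age - 41.5) / 13.6
                    - params.score_effect * (score + 1.6) / 1.2
                )
                p = np.exp(logits - logits.max())
                p /= p.sum()
                block_modes = rng.choice(params.context_modes_sz, size=n_blocks, p=p)
                block_ctx = centers[block_modes] + params.context_within_sd * (
                    rng.standard_normal((n_blocks, params.context_dim_true))
                )
            else:
                block_modes = np.full(n_blocks, -1)
                block_ctx = params.context_within_sd * rng.standard_normal(
                    (n_blocks, params.context_dim_true)
                )

            z = _ar1_local(rng, T, params.local_dim_true, sigma)
            c_t = np.repeat(block_ctx, W, axis=0)[:T]          # context per timestep
            u = np.concatenate([c_t, z], axis=1)               # [T, d]
            clean = np.tanh(u @ A.T) + u @ B.T                 # [T, N]
            x = clean + params.obs_noise_sd * rng.standard_normal(clean.shape)

            records.append(
                SubjectRecord(
                    subject_id=sid,
                    diagnosis=group,
                    age=age,
                    sex="U",
                    cmnds_score=score,
                    timecourses=x.T,
                )
            )
            context[sid] = block_ctx
            modes[sid] = block_modes
            local[sid] = z
            if group == "SZ":
                occupancy[sid] = np.bincount(block_modes, minlength=params.context_modes_sz)

    truth = GroundTruth(
        context=context,
        modes=modes,
        local=local,
        occupancy=occupancy,
        mode_centers=centers,
        age_mode=age_mode,
    )
    return records, truth


def toy_fixture() -> tuple[list[SubjectRecord], GroundTruth]:
    """Tiny deterministic cohort for tests: 4 subjects, N=6, T=40, W=10."""
    params = SyntheticParams(
        n_subjects_per_group=2,
        n_components=6,
        n_timesteps=40,
        window_length=10,
        context_modes_sz=2,
        mixing_seed=7,
        cohort_seed=123,
    )
    return generate_cohort(params)
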