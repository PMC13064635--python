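"""Synthetic cohorts and beta maps with the statistical structure the
analysis pipeline assumes.

The cohort generator draws subject parameters from group distributions
anchored to reference group-level estimates (maximin weight alpha
concentrated near 0.95; agreeability threshold phi centered near -10 s
with wide, sign-varying between-subject spread; softmax inverse
temperature tau around 0.1) and simulates choices with the winning model
on a standard 150-trial design.  The beta-map generator plants a compact
3-D region whose voxel responses vary smoothly with each subject's phi, so
phi-similar subjects have similar maps inside the plant, against
independent Gaussian noise elsewhere — the structure the IS-RSA stage is
designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .choice_model import SubjectParams, simulate_choices, WINNING_MODEL
from .isrsa import BetaMaps
from .task_design import DesignConfig, sample_design


@dataclass(frozen=True)
class GroupParams:
    """Group-level distributions the subject truths are drawn from.

    alpha is logit-normal (location logit(alpha_mode), scale
    alpha_logit_sd); phi is Normal(phi_mean, phi_sd) in seconds; tau is
    log-normal around tau_median.
    """

    alpha_mode: float = 0.95
    alpha_logit_sd: float = 1.0
    phi_mean: float = -10.03
    phi_sd: float = 12.0
    tau_median: float = 0.1
    tau_log_sd: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.alpha_mode < 1:
            raise ValueError("alpha_mode must lie strictly in (0,1)")
        if min(self.alpha_logit_sd, self.phi_sd, self.tau_log_sd) < 0:
            raise ValueError("spread parameters must be nonnegative")
        if self.tau_median <= 0:
            raise ValueError("tau_median must be positive")

    def draw(self, n: int, rng: np.random.Generator) -> list[SubjectParams]:
        alpha = expit(rng.normal(logit(self.alpha_mode), self.alpha_logit_sd, n))
        phi = rng.normal(self.phi_mean, self.phi_sd, n)
        tau = np.exp(rng.normal(np.log(self.tau_median), self.tau_log_sd, n))
        return [SubjectParams(float(a), float(f), float(t))
                for a, f, t in zip(alpha, phi, tau)]


def generate_cohort(
    n_subjects: int = 68,
    design: pd.DataFrame | None = None,
    group_params: GroupParams | None = None,
    seed: int = 0,
    model: str = WINNING_MODEL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw subject parameters and simulate their choices.

    Returns ``(params, cohort)``: a per-subject parameter table
    (columns subject, alpha, phi, tau) and the stacked per-trial choice
    table with a ``subject`` column.  Fully reproducible under ``seed``.
    """
    group_params = group_params or GroupParams()
    rng = np.random.default_rng(seed)
    if design is None:
        design = sample_design(DesignConfig(seed=int(rng.integers(1 << 31))))
    truths = group_params.draw(n_subjects, rng)
    frames = []
    for s, p in enumerate(truths):
        df = simulate_choices(design, p, seed=rng, model=model)
        df.insert(0, "subject", s)
        frames.append(df)
    params = pd.DataFrame(
        {
            "subject": np.arange(n_subjects),
            "alpha": [p.alpha for p in truths],
            "phi": [p.phi for p in truths],
            "tau": [p.tau for p in truths],
        }
    )
    return params, pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class PlantSpec:
    """A rectangular region whose voxel response is a smooth monotone
    function of phi: beta(subject, voxel) = slope * weight(voxel) * phi,
    with weight tapering linearly from 1 at the region center to
    ``edge_weight`` at its boundary."""

    corner: tuple[int, int, int] = (4, 4, 4)
    size: tuple[int, int, int] = (5, 5, 5)
    slope: float = 1.0
    edge_weight: float = 0.5

    def voxel_weights(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        """(prod(shape),) flat weight map: zero outside the plant."""
        c, s = np.asarray(self.corner), np.asarray(self.size)
        if np.any(c < 0) or np.any(c + s > np.asarray(grid_shape)):
            raise ValueError("plant region extends outside the grid")
        w = np.zeros(grid_shape)
        idx = np.indices(grid_shape).reshape(3, -1).T
        inside = np.all((idx >= c) & (idx < c + s), axis=1)
        center = c + (s - 1) / 2.0
        # normalized Chebyshev distance to the region center
        denom = np.maximum((s - 1) / 2.0, 1e-12)
        rel = np.max(np.abs(idx[inside] - center) / denom, axis=1)
        w.ravel()[inside] = 1.0 - (1.0 - self.edge_weight) * rel
        return w.ravel()


def generate_beta_maps(
    params: pd.DataFrame,
    grid_shape: tuple[int, int, int] = (20, 20, 20),
    plant: PlantSpec | None = PlantSpec(),
    noise_sd: float = 1.0,
    null_sd: float = 1.0,
    seed: int = 0,
) -> BetaMaps:
    """Synthesize per-subject voxelwise responses to worst-off harm.

    Inside the planted region, responses are ``slope * weight * phi`` plus
    Gaussian noise of SD ``noise_sd``, so the absolute response difference
    between two subjects grows with their phi difference.  Outside, voxels
    are independent Gaussian noise of SD ``null_sd``.  Pass ``plant=None``
    for a fully null volume.
    """
    rng = np.random.default_rng(seed)
    phi = params["phi"].to_numpy(float)
    n_sub = len(phi)
    n_vox = int(np.prod(grid_shape))
    data = rng.normal(0.0, null_sd, size=(n_sub, n_vox))
    if plant is not None:
        w = plant.voxel_weights(grid_shape)
        inside = w > 0
        signal = plant.slope * np.outer(phi, w[inside])
        noise = (
            rng.normal(0.0, noise_sd, size=signal.shape)
            if noise_sd > 0 else 0.0
        )
        data[:, inside] = signal + noise
    return BetaMaps(
        data=data,
        shape=tuple(grid_shape),
        mask=None,
        subjects=list(params["subject"]),
    )
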