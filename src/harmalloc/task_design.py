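"""Harm-allocation task design.

Each trial pits harm to a single individual (``c_one`` seconds of cold-pressor
time) against harm to every member of a small group (``c_group`` seconds per
member, ``n_group`` members).  Valid trials satisfy

    c_group <= c_one <= c_group * n_group

so that choosing "the one" always minimizes total harm (the utilitarian
option) while choosing "the group" always minimizes the largest harm any
single person receives (the Rawlsian / maximin option).  A fixed set of
unique harm pairs is replicated under three default conditions (no default,
one-default, group-default) to separate Rawlsian from Kantian (inaction)
preferences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_CONDITIONS = ("none", "one_default", "group_default")
DEFAULT_GRID = tuple(range(30, 190, 10))
DEFAULT_GROUP_SIZES = (3, 4)

#: Trial timing metadata (seconds); carried for documentation only.
WAIT_PHASE_S = 3.0
RESPONSE_WINDOW_S = 2.5


class DesignError(ValueError):
    """Invalid design configuration or trial specification."""


@dataclass(frozen=True)
class TrialSpec:
    """One harm-allocation choice pair.

    Attributes
    ----------
    c_one : float
        Harm (s) to the single individual if "one" is chosen.
    c_group : float
        Harm (s) to each group member if "group" is chosen.
    n_group : int
        Number of individuals in the group (3 or 4 in the standard design).
    default_cond : str
        Which option is implemented by inaction: ``none``, ``one_default``
        or ``group_default``.
    trial_index : int
        Presentation position within the session.
    """

    c_one: float
    c_group: float
    n_group: int
    default_cond: str = "none"
    trial_index: int = 0

    def __post_init__(self) -> None:
        if not (self.c_group <= self.c_one <= self.c_group * self.n_group):
            raise DesignError(
                f"invalid trial: need c_group <= c_one <= c_group*n_group, "
                f"got ({self.c_one}, {self.c_group}, {self.n_group})"
            )
        if self.default_cond not in DEFAULT_CONDITIONS:
            raise DesignError(f"unknown default condition {self.default_cond!r}")

    @property
    def delta_total(self) -> float:
        """Extra total harm (s) of the group option: C_group*N_group - C_one."""
        return self.c_group * self.n_group - self.c_one

    @property
    def delta_single(self) -> float:
        """Extra worst-off harm (s) of the one option: C_one - C_group."""
        return self.c_one - self.c_group


@dataclass(frozen=True)
class DesignConfig:
    """Configuration for sampling a session design.

    ``n_pairs`` unique (c_one, c_group, n_group) triples are drawn from the
    valid set and each replicated once per default condition; presentation
    order and screen side are then shuffled under ``seed``.
    """

    value_grid: tuple = DEFAULT_GRID
    group_sizes: tuple = DEFAULT_GROUP_SIZES
    n_pairs: int = 50
    conditions: tuple = DEFAULT_CONDITIONS
    seed: int = 0
    alternate_group_sizes: bool = False
    pair_file: str | None = None

    def __post_init__(self) -> None:
        grid = tuple(self.value_grid)
        if len(grid) == 0:
            raise DesignError("value grid must be nonempty")
        if any(v <= 0 for v in grid):
            raise DesignError("harm values must be positive")
        if list(grid) != sorted(set(grid)):
            raise DesignError("value grid must be strictly increasing")


def enumerate_valid_pairs(
    grid: Sequence[float] = DEFAULT_GRID,
    group_sizes: Sequence[int] = DEFAULT_GROUP_SIZES,
) -> list[tuple[float, float, int]]:
    """All (c_one, c_group, n_group) triples on the grid with
    c_group <= c_one <= c_group*n_group, ordered by (c_group, c_one, n_group)."""
    grid = sorted(grid)
    if not grid:
        raise DesignError("value grid must be nonempty")
    if any(v <= 0 for v in grid):
        raise DesignError("harm values must be positive")
    out = []
    for c_group, c_one, n in itertools.product(grid, grid, sorted(group_sizes)):
        if c_group <= c_one <= c_group * n:
            out.append((float(c_one), float(c_group), int(n)))
    out.sort(key=lambda t: (t[1], t[0], t[2]))
    return out


def _sample_triples(config: DesignConfig, rng: np.random.Generator) -> list[tuple]:
    if config.pair_file is not None:
        df = pd.read_csv(config.pair_file, sep=None, engine="python")
        triples = [
            (float(r.c_one), float(r.c_group), int(r.n_group))
            for r in df.itertuples()
        ]
        for t in triples:  # validate against the constraint
            TrialSpec(*t)
        return triples

    if config.alternate_group_sizes:
        # strict 3/4 alternation across the ordered pair slots
        triples = []
        seen: set[tuple] = set()
        sizes = itertools.cycle(sorted(config.group_sizes))
        for _ in range(config.n_pairs):
            n = next(sizes)
            candidates = [
                t
                for t in enumerate_valid_pairs(config.value_grid, [n])
                if t not in seen
            ]
            if not candidates:
                raise DesignError("not enough valid pairs for requested design")
            pick = candidates[rng.integers(len(candidates))]
            seen.add(pick)
            triples.append(pick)
        return triples

    valid = enumerate_valid_pairs(config.value_grid, config.group_sizes)
    if config.n_pairs > len(valid):
        raise DesignError(
            f"requested {config.n_pairs} pairs but only {len(valid)} valid triples"
        )
    idx = rng.choice(len(valid), size=config.n_pairs, replace=False)
    return [valid[i] for i in idx]


def sample_design(config: DesignConfig | None = None) -> pd.DataFrame:
    """Sample a full session design.

    Returns a DataFrame with one row per trial and columns
    ``trial_index, c_one, c_group, n_group, default_cond, one_side``.
    Each sampled harm triple appears exactly once per default condition;
    presentation order and the side of the "one" option are randomized.
    """
    config = config or DesignConfig()
    rng = np.random.default_rng(config.seed)
    triples = _sample_triples(config, rng)

    rows = [
        (c_one, c_group, n, cond)
        for (c_one, c_group, n) in triples
        for cond in config.conditions
    ]
    order = rng.permutation(len(rows))
    sides = rng.choice(["left", "right"], size=len(rows))
    df = pd.DataFrame(
        [rows[i] for i in order],
        columns=["c_one", "c_group", "n_group", "default_cond"],
    )
    df.insert(0, "trial_index", np.arange(len(df)))
    df["one_side"] = sides
    return df


def design_to_trials(design: pd.DataFrame) -> list[TrialSpec]:
    """Validate a design table row-by-row into TrialSpec objects."""
    return [
        TrialSpec(
            c_one=float(r.c_one),
            c_group=float(r.c_group),
            n_group=int(r.n_group),
            default_cond=str(r.default_cond),
            trial_index=int(r.trial_index),
        )
        for r in design.itertuples()
    ]
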