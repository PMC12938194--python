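"""Task design, ground-truth parameter populations and the exclusion fixture.

The emulated experiment crosses 5 practice blocks with 3 rule-hierarchy
levels (the number of nested conditional rules a trial requires).  Each
participant completes ``trials_per_cell`` trials in every block x
hierarchy cell — 6 by default, i.e. 90 trials in 5 blocks of 18 — with
the hierarchy order randomised within block.

Ground truth for the simulator is a population of DDM parameters
(v, a, t0, z) defined per design cell.  Defaults reproduce the published
hierarchy-level and block-level posterior means of the original study
population; non-decision times are stored in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PARAMS",
    "N_BLOCKS",
    "N_HIERARCHIES",
    "N_CELLS",
    "cell_index",
    "CELL_BLOCK",
    "CELL_HIER",
    "PopulationParams",
    "hierarchy_population",
    "block_population",
    "additive_population",
    "generate_design",
    "draw_subject_params",
    "make_exclusion_fixture",
    "apply_exclusions",
    "write_trials_csv",
    "read_trials_csv",
]

PARAMS = ("v", "a", "t0", "z")
N_BLOCKS = 5
N_HIERARCHIES = 3
N_CELLS = N_BLOCKS * N_HIERARCHIES

# Published group-level posterior means used as generator defaults.
# Non-decision time is in seconds (the source table prints milliseconds).
HIERARCHY_MEANS = {
    "v": np.array([0.92, 0.60, 0.38]),
    "a": np.array([2.98, 5.17, 6.36]),
    "t0": np.array([731.20, 958.40, 950.60]) / 1000.0,
    "z": np.array([0.29, 0.18, 0.23]),
}
BLOCK_MEANS = {
    "v": np.array([0.48, 0.58, 0.62, 0.76, 0.72]),
    "a": np.array([5.08, 4.85, 4.71, 4.93, 4.61]),
    "t0": np.array([935.50, 940.70, 908.90, 766.80, 848.30]) / 1000.0,
    "z": np.array([0.26, 0.23, 0.24, 0.20, 0.23]),
}

# Between-subject spread of the generated population, per parameter.
DEFAULT_SDS = {"v": 0.10, "a": 0.10, "t0": 0.05, "z": 0.03}

# Constraint region for admissible DDM parameters.
LOWER = {"v": -np.inf, "a": 0.1, "t0": 0.0, "z": 0.0}
UPPER = {"v": np.inf, "a": np.inf, "t0": np.inf, "z": 1.0}


def cell_index(block, hierarchy):
    """Canonical 0-based cell index for (block 1-5, hierarchy 1-3)."""
    return (np.asarray(block) - 1) * N_HIERARCHIES + (np.asarray(hierarchy) - 1)


CELL_BLOCK = np.repeat(np.arange(1, N_BLOCKS + 1), N_HIERARCHIES)
CELL_HIER = np.tile(np.arange(1, N_HIERARCHIES + 1), N_BLOCKS)


@dataclass
class PopulationParams:
    """Group-level DDM parameter population over the 15 design cells.

    ``means[p]`` and ``sds[p]`` are length-15 arrays in canonical cell
    order (block-major, hierarchy-minor).  Start proportion ``z`` is the
    stored quantity; the absolute bias ``Z0 = z * a`` is always derived.
    """

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    def __post_init__(self):
        for p in PARAMS:
            self.means[p] = np.broadcast_to(
                np.asarray(self.means[p], dtype=float), (N_CELLS,)).copy()
            self.sds[p] = np.broadcast_to(
                np.asarray(self.sds.get(p, 0.0), dtype=float), (N_CELLS,)).copy()
        self.validate()

    def validate(self):
        if np.any(self.means["a"] <= 0.1):
            raise ValueError("all boundary-separation means must exceed 0.1")
        if np.any((self.means["z"] <= 0) | (self.means["z"] >= 1)):
            raise ValueError("all start-proportion means must lie in (0, 1)")
        if np.any(self.means["t0"] <= 0):
            raise ValueError("all non-decision-time means must be positive")
        for p in PARAMS:
            if np.any(self.sds[p] < 0):
                raise ValueError("group sds must be non-negative")

    def mean_matrix(self) -> np.ndarray:
        """(4, 15) array of cell means in PARAMS order."""
        return np.stack([self.means[p] for p in PARAMS])


def _expand(by_hier=None, by_block=None, combine="sum", center_block=True):
    """Broadcast hierarchy-level and/or block-level values onto the 15 cells."""
    out = {}
    for p in PARAMS:
        vals = np.zeros(N_CELLS)
        if by_hier is not None:
            vals = vals + np.asarray(by_hier[p])[CELL_HIER - 1]
        if by_block is not None:
            b = np.asarray(by_block[p], dtype=float)
            if center_block and by_hier is not None:
                b = b - b.mean()  # block deviations around the hierarchy profile
            vals = vals + b[CELL_BLOCK - 1]
        out[p] = vals
    return out


def hierarchy_population(sds=None) -> PopulationParams:
    """Population whose parameters vary with rule hierarchy only (Model 1 truth)."""
    return PopulationParams(means=_expand(by_hier=HIERARCHY_MEANS),
                            sds=dict(sds or DEFAULT_SDS))


def block_population(sds=None) -> PopulationParams:
    """Population whose parameters vary with block only (Model 2 truth)."""
    return PopulationParams(means=_expand(by_block=BLOCK_MEANS),
                            sds=dict(sds or DEFAULT_SDS))


def additive_population(sds=None, v_interaction: float = 0.0) -> PopulationParams:
    """Hierarchy profile plus mean-centred block deviations (Model 3 truth).

    ``v_interaction`` > 0 plants a hierarchy x block interaction on the
    drift rate: the hierarchy-1 minus hierarchy-3 drift gap grows by that
    amount per block (Model 4 truth), keeping the block-3 cells at their
    additive values.
    """
    means = _expand(by_hier=HIERARCHY_MEANS, by_block=BLOCK_MEANS)
    if v_interaction != 0.0:
        hl = CELL_HIER - 2   # -1, 0, +1 for hierarchy 1..3
        bl = CELL_BLOCK - 3  # centred block
        means["v"] = means["v"] - 0.5 * v_interaction * hl * bl
    return PopulationParams(means=means, sds=dict(sds or DEFAULT_SDS))


def generate_design(n_participants: int, trials_per_cell: int = 6,
                    seed: int = 0) -> pd.DataFrame:
    """Generate the chronological trial design for a cohort.

    Each participant runs the 5 blocks in order; within a block the
    sequence is a seeded shuffle of ``trials_per_cell`` repetitions of each
    hierarchy level.  ``rule_switch`` flags trials whose hierarchy differs
    from the immediately preceding trial (first trial of a participant: 0).

    Returns a tidy DataFrame with columns
    ``participant_id, block, rule_hierarchy, trial_index, rule_switch``.
    """
    if n_participants < 1 or trials_per_cell < 1:
        raise ValueError("n_participants and trials_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(1, n_participants + 1):
        prev = None
        idx = 0
        for block in range(1, N_BLOCKS + 1):
            seq = np.repeat(np.arange(1, N_HIERARCHIES + 1), trials_per_cell)
            rng.shuffle(seq)
            for h in seq:
                idx += 1
                rows.append((pid, block, int(h), idx,
                             0 if prev is None else int(h != prev)))
                prev = h
    return pd.DataFrame(rows, columns=["participant_id", "block",
                                       "rule_hierarchy", "trial_index",
                                       "rule_switch"])


def draw_subject_params(pop: PopulationParams, n_participants: int,
                        seed: int = 0) -> np.ndarray:
    """Draw per-subject cell parameters around the population means.

    Values are drawn Normal(mean, sd) per (parameter, cell), truncated by
    rejection to the admissible region (a > 0.1, z in (0,1), t0 > 0).
    With all sds zero the draws equal the group means exactly.

    Returns an array of shape ``(n_participants, 4, 15)`` in PARAMS order.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    pop.validate()
    rng = np.random.default_rng(seed)
    out = np.empty((n_participants, len(PARAMS), N_CELLS))
    for pi, p in enumerate(PARAMS):
        lo, hi = LOWER[p], UPPER[p]
        for c in range(N_CELLS):
            m, s = pop.means[p][c], pop.sds[p][c]
            if s == 0.0:
                out[:, pi, c] = m
                continue
            draws = rng.normal(m, s, size=n_participants)
            bad = (draws <= lo) | (draws >= hi)
            while np.any(bad):
                draws[bad] = rng.normal(m, s, size=int(bad.sum()))
                bad = (draws <= lo) | (draws >= hi)
            out[:, pi, c] = draws
    return out


def make_exclusion_fixture(seed: int = 0) -> pd.DataFrame:
    """Participant-screening fixture mirroring the study's exclusion structure.

    40 collected records; exactly 5 fail the learning-phase accuracy
    criterion (< 0.80) and exactly 1 (disjoint) failed to produce
    hierarchical responses — 6 exclusions, 15% of the cohort, 34 retained.
    """
    rng = np.random.default_rng(seed)
    n = 40
    flagged = rng.choice(n, size=6, replace=False)
    low_acc = flagged[:5]
    protocol = flagged[5:]
    learning = rng.uniform(0.82, 0.99, size=n)
    learning[low_acc] = rng.uniform(0.55, 0.79, size=5)
    ok = np.ones(n, dtype=int)
    ok[protocol] = 0
    return pd.DataFrame({
        "participant_id": np.arange(1, n + 1),
        "learning_accuracy": np.round(learning, 3),
        "hierarchical_response_ok": ok,
    })


def apply_exclusions(fixture: pd.DataFrame) -> pd.DataFrame:
    """Return the fixture rows that survive both screening rules."""
    keep = (fixture["learning_accuracy"] >= 0.80) & \
        (fixture["hierarchical_response_ok"] == 1)
    return fixture.loc[keep].reset_index(drop=True)


TRIAL_COLUMNS = ["participant_id", "block", "rule_hierarchy", "trial_index",
                 "rule_switch", "rt", "accuracy"]


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (RT in seconds, 6 decimal places)."""
    out = trials[TRIAL_COLUMNS].copy()
    out["rt"] = out["rt"].map(lambda x: f"{x:.6f}")
    out.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df
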