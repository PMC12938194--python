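"""The four-model space: which design factors each DDM parameter tracks.

Every model applies the same factor map to all four DDM parameters
(v, a, t0, z):

* Model 1 — rule hierarchy only (3 levels per parameter),
* Model 2 — block only (5 levels per parameter),
* Model 3 — additive: hierarchy baselines plus zero-sum block offsets
  (3 + 4 free coefficients per parameter),
* Model 4 — fully cell-wise (15 coefficients per parameter), i.e. both
  main effects and their interaction.

Each map is expressed as a (15, k) design matrix over the canonical cell
order; a subject's cell value for parameter p is ``X @ beta_p``.  For the
one-hot maps (Models 1, 2, 4) coefficients are the cell values themselves;
Model 3's block offsets are effect-coded (block 5 = minus the sum of the
first four), which pins the printed additive structure to
4 x (3 + 5 - 1) = 28 free group-level locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import CELL_BLOCK, CELL_HIER, N_CELLS, PARAMS

__all__ = ["ModelSpec", "model_spec", "count_free_params", "MODEL_NAMES"]

MODEL_NAMES = {
    1: "hierarchy main effect",
    2: "block main effect",
    3: "additive main effects",
    4: "main effects + interaction",
}


@dataclass(frozen=True)
class ModelSpec:
    """Factor map of one model, applied identically to v, a, t0 and z."""

    model_id: int
    X: np.ndarray                  # (15, k) design matrix
    coef_names: tuple              # length k, e.g. ("h1", "h2", "h3")
    is_offset: np.ndarray = field(default=None)  # (k,) True for effect-coded cols

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def name(self) -> str:
        return MODEL_NAMES[self.model_id]

    def cell_values(self, beta: np.ndarray) -> np.ndarray:
        """Map coefficients (.., k) to cell values (.., 15)."""
        return np.asarray(beta) @ self.X.T


def _onehot(levels: np.ndarray, names: tuple) -> np.ndarray:
    X = np.zeros((N_CELLS, len(names)))
    X[np.arange(N_CELLS), levels - 1] = 1.0
    return X


def model_spec(model_id: int) -> ModelSpec:
    """Construct the design matrix for one of the four models."""
    if model_id == 1:
        X = _onehot(CELL_HIER, ("h1", "h2", "h3"))
        names = ("h1", "h2", "h3")
    elif model_id == 2:
        X = _onehot(CELL_BLOCK, ("b1", "b2", "b3", "b4", "b5"))
        names = ("b1", "b2", "b3", "b4", "b5")
    elif model_id == 3:
        H = _onehot(CELL_HIER, ("h1", "h2", "h3"))
        B = np.zeros((N_CELLS, 4))
        for c in range(N_CELLS):
            b = CELL_BLOCK[c]
            if b <= 4:
                B[c, b - 1] = 1.0
            else:
                B[c, :] = -1.0  # block 5 offset = -(sum of offsets 1..4)
        X = np.hstack([H, B])
        names = ("h1", "h2", "h3", "db1", "db2", "db3", "db4")
    elif model_id == 4:
        X = np.eye(N_CELLS)
        names = tuple(f"b{b}h{h}" for b, h in zip(CELL_BLOCK, CELL_HIER))
    else:
        raise ValueError(f"model_id must be 1..4, got {model_id}")
    is_offset = np.array([n.startswith("d") for n in names])
    return ModelSpec(model_id=model_id, X=X, coef_names=names, is_offset=is_offset)


def count_free_params(spec: ModelSpec | int) -> int:
    """Free group-level location parameters: 4 DDM parameters x k coefficients."""
    if isinstance(spec, int):
        spec = model_spec(spec)
    return len(PARAMS) * spec.k
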