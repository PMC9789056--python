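"""Principal Coordinates Analysis (classical multidimensional scaling).

PCoA embeds samples from a distance matrix by eigendecomposing the
double-centered matrix of squared distances, B = -1/2 J D^2 J with
J = I - 11'/n.  Axes are eigenvectors scaled by the square root of
their (positive) eigenvalues.  Bray-Curtis matrices are generally
non-Euclidean, so some eigenvalues come out negative; those axes are
dropped and their total magnitude reported, with no Cailliez/Lingoes
correction applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dissimilarity import DistanceMatrix

_EIG_TOL = 1e-9


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray        # samples x retained axes
    eigenvalues: np.ndarray        # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float  # sum |lambda| over dropped axes
    truncated: bool = False        # n_axes exceeded the positive count

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        axes = [f"PCo{k+1}" for k in range(self.coordinates.shape[1])]
        coords = pd.DataFrame(self.coordinates, index=self.sample_ids,
                              columns=axes)
        coords.index.name = "sample"
        eigs = pd.DataFrame(
            {
                "axis": axes,
                "eigenvalue": self.eigenvalues[: len(axes)],
                "proportion_explained": self.proportion_explained[: len(axes)],
            }
        )
        return coords, eigs


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical scaling of a distance matrix.

    Deterministic up to axis sign; signs are fixed by forcing each
    axis's largest-magnitude loading positive.  Requesting more axes
    than there are positive eigenvalues truncates with a flag rather
    than failing.
    """
    d = dm.values
    n = d.shape[0]
    d2 = d ** 2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2  # guard symmetry against rounding
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    scale = max(abs(eigval[0]), 1.0) if n else 1.0
    pos = eigval > _EIG_TOL * scale
    pos_vals = eigval[pos]
    neg_mass = float(np.abs(eigval[eigval < -_EIG_TOL * scale]).sum())

    coords = eigvec[:, pos] * np.sqrt(pos_vals)
    for k in range(coords.shape[1]):  # reproducible axis orientation
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]

    truncated = False
    if n_axes is not None:
        if n_axes > coords.shape[1]:
            truncated = True
            n_axes = coords.shape[1]
        coords = coords[:, :n_axes]
        kept_vals = pos_vals[:n_axes]
    else:
        kept_vals = pos_vals

    total = pos_vals.sum()
    prop = kept_vals / total if total > 0 else np.zeros_like(kept_vals)
    return OrdinationResult(
        sample_ids=list(dm.sample_ids),
        coordinates=coords,
        eigenvalues=kept_vals,
        proportion_explained=prop,
        negative_eigenvalue_mass=neg_mass,
        truncated=truncated,
    )
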