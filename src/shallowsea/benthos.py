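"""Benthic endmember library, linear mixing and fully-constrained unmixing.

The seafloor albedo is modelled as a convex combination of a few pure
benthic spectra (sand, algae/seagrass, sediment-rock):
``ρ_alb(λ) = Σ_i ab_i · em_i(λ)`` with abundances non-negative and summing
to one (FCLU — fully constrained linear unmixing).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import ValidationError

__all__ = ["EndmemberLibrary", "mix_albedo", "fclu_unmix", "default_library"]


class EndmemberLibrary:
    """Named endmember albedo spectra on a common wavelength grid."""

    def __init__(self, grid_nm: np.ndarray, spectra: dict[str, np.ndarray]):
        if len(spectra) < 2:
            raise ValidationError("need at least two endmembers")
        self.grid_nm = np.asarray(grid_nm, float)
        self.names = list(spectra)
        self.matrix = np.column_stack([np.asarray(spectra[n], float) for n in self.names])
        if self.matrix.shape[0] != self.grid_nm.size:
            raise ValidationError("endmember spectra not aligned with grid")
        if self.matrix.min() < 0 or self.matrix.max() > 1:
            raise ValidationError("endmember albedo must lie in [0, 1]")
        for i in range(len(self.names)):
            for j in range(i + 1, len(self.names)):
                if np.allclose(self.matrix[:, i], self.matrix[:, j]):
                    raise ValidationError(
                        f"endmembers {self.names[i]!r} and {self.names[j]!r} identical")

    def __len__(self):
        return len(self.names)

    @classmethod
    def from_table(cls, path) -> "EndmemberLibrary":
        df = pd.read_csv(path, sep="\t", comment="#")
        grid = df["lambda_nm"].to_numpy(float)
        return cls(grid, {c: df[c].to_numpy(float) for c in df.columns if c != "lambda_nm"})

    def on_grid(self, grid_nm: np.ndarray) -> "EndmemberLibrary":
        """Library linearly interpolated to another wavelength grid."""
        grid_nm = np.asarray(grid_nm, float)
        return EndmemberLibrary(grid_nm, {
            n: np.interp(grid_nm, self.grid_nm, self.matrix[:, i])
            for i, n in enumerate(self.names)})

    def reorder(self, names) -> "EndmemberLibrary":
        return EndmemberLibrary(self.grid_nm, {
            n: self.matrix[:, self.names.index(n)] for n in names})


def default_library() -> EndmemberLibrary:
    """The bundled synthetic three-endmember library (sand, algae, sediment)."""
    with resources.as_file(resources.files("shallowsea.data") / "endmembers.tsv") as p:
        return EndmemberLibrary.from_table(p)


def _check_simplex(ab: np.ndarray, n: int, tol: float = 1e-6):
    ab = np.asarray(ab, float)
    if ab.shape[-1] != n:
        raise ValidationError(f"expected {n} abundances, got {ab.shape[-1]}")
    if ab.min() < -tol or np.any(np.abs(ab.sum(axis=-1) - 1.0) > tol):
        raise ValidationError("abundances must be non-negative and sum to one")
    return ab


def mix_albedo(ab: np.ndarray, lib: EndmemberLibrary) -> np.ndarray:
    """Bottom albedo of the abundance mixture ``Σ ab_i · em_i(λ)``.

    ``ab`` may carry leading pixel axes: (..., n_endmembers) → (..., ngrid).
    """
    ab = _check_simplex(ab, len(lib))
    return ab @ lib.matrix.T


def fclu_unmix(spectrum: np.ndarray, lib: EndmemberLibrary,
               constraint_weight: float = 1e6) -> tuple[np.ndarray, float]:
    """Fully-constrained (non-negative, sum-to-one) least-squares unmixing.

    Solved as non-negative least squares on the system augmented with a
    heavily weighted sum-to-one row.  Returns ``(abundances, residual)``
    where the residual is the root-mean-square spectral misfit.
    """
    s = np.asarray(spectrum, float)
    E = lib.matrix
    if s.shape != (E.shape[0],):
        raise ValidationError("spectrum not on library grid")
    if np.linalg.matrix_rank(E) < 2:
        raise ValidationError("degenerate endmember library (rank < 2)")
    A = np.vstack([E, constraint_weight * np.ones((1, E.shape[1]))])
    b = np.concatenate([s, [constraint_weight]])
    ab, _ = nnls(A, b)
    resid = float(np.sqrt(np.mean((E @ ab - s) ** 2)))
    return ab, resid
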