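"""Conventional single-tensor diffusion model and its scalar maps.

Fits the log-linear tensor system by weighted least squares and derives the
standard rotation-invariant scalars: fractional anisotropy (FA), mean
diffusivity (MD), radial diffusivity (RD, mean of the two smallest
eigenvalues) and axial diffusivity (AD, the largest eigenvalue).
"""

from __future__ import annotations

import numpy as np

from .gradients import GradientScheme

__all__ = ["DiffusionTensorModel", "TensorResults", "fit_single_tensor", "tensor_scalars"]


def tensor_scalars(eigenvalues: np.ndarray) -> dict[str, np.ndarray]:
    """Scalar maps from sorted eigenvalue triples.

    Parameters
    ----------
    eigenvalues : array, shape (..., 3)
        Eigenvalues sorted descending, lam1 >= lam2 >= lam3 >= 0, in mm^2/s.

    Returns
    -------
    dict with keys ``fa``, ``md``, ``rd``, ``ad``. FA is
    sqrt(3/2) * ||lam - MD|| / ||lam||, dimensionless in [0, 1]; the
    diffusivities keep the input units.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("eigenvalues must have trailing dimension 3")
    if np.any(lam < -1e-12):
        raise ValueError("eigenvalues must be nonnegative (clamp first)")
    md = lam.mean(axis=-1)
    norm = np.linalg.norm(lam, axis=-1)
    if np.all(norm == 0):
        raise ValueError("FA undefined for an all-zero eigenvalue triple")
    dev = lam - md[..., None]
    # all-zero voxels (fully clamped, e.g. pure noise) report FA 0 rather
    # than poisoning a whole map; callers see them via the clamp flag
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(
            norm > 0, np.sqrt(1.5) * np.linalg.norm(dev, axis=-1) / np.where(norm > 0, norm, 1.0), 0.0
        )
    return {
        "fa": np.clip(fa, 0.0, 1.0),
        "md": md,
        "rd": (lam[..., 1] + lam[..., 2]) / 2.0,
        "ad": lam[..., 0],
    }


def _tensor_from_params(d6: np.ndarray) -> np.ndarray:
    """(..., 6) packed (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) -> (..., 3, 3)."""
    D = np.empty(d6.shape[:-1] + (3, 3))
    D[..., 0, 0] = d6[..., 0]
    D[..., 1, 1] = d6[..., 1]
    D[..., 2, 2] = d6[..., 2]
    D[..., 0, 1] = D[..., 1, 0] = d6[..., 3]
    D[..., 0, 2] = D[..., 2, 0] = d6[..., 4]
    D[..., 1, 2] = D[..., 2, 1] = d6[..., 5]
    return D


class TensorResults:
    """Fitted tensors for a block of voxels.

    Attributes
    ----------
    tensor : (n_voxels, 3, 3) fitted symmetric tensors, mm^2/s
    eigenvalues : (n_voxels, 3) descending, clamped at zero
    eigenvectors : (n_voxels, 3, 3) columns matching the eigenvalues
    s0_hat : (n_voxels,) fitted non-DW amplitude
    fa, md, rd, ad : (n_voxels,) scalar maps
    clamped : (n_voxels,) bool, True where a negative eigenvalue was clamped
    """

    def __init__(self, tensor, s0_hat, clamped):
        self.tensor = tensor
        self.s0_hat = s0_hat
        raw_vals, vecs = np.linalg.eigh(tensor)
        order = np.argsort(raw_vals, axis=-1)[..., ::-1]
        vals = np.take_along_axis(raw_vals, order, axis=-1)
        self.eigenvectors = np.take_along_axis(vecs, order[..., None, :], axis=-1)
        self.clamped = clamped | (vals[..., -1] < 0)
        self.eigenvalues = np.clip(vals, 0.0, None)
        sc = tensor_scalars(self.eigenvalues)
        self.fa = sc["fa"]
        self.md = sc["md"]
        self.rd = sc["rd"]
        self.ad = sc["ad"]

    def summary(self) -> str:
        n = self.fa.size
        lines = [
            "Single diffusion tensor fit (weighted log-linear least squares)",
            f"voxels: {n}   clamped eigenvalues: {int(self.clamped.sum())}",
            f"FA  mean {self.fa.mean():.4f}  sd {self.fa.std():.4f}",
            f"MD  mean {self.md.mean():.3e} mm^2/s",
            f"RD  mean {self.rd.mean():.3e} mm^2/s",
            f"AD  mean {self.ad.mean():.3e} mm^2/s",
        ]
        return "\n".join(lines)


class DiffusionTensorModel:
    """Single-tensor model for a fixed gradient scheme.

    Fit is ordinary least squares on log signals followed by one weighted
    refinement pass with weights equal to the squared predicted signal — the
    standard WLS estimator for the log-linearized tensor system. S0 is a
    joint unknown of the linear system rather than the b0 mean, so multiple
    b0 volumes are treated consistently.
    """

    def __init__(self, scheme: GradientScheme):
        self.scheme = scheme
        self.design = scheme.design_matrix()
        if np.linalg.matrix_rank(self.design) < 7:
            raise ValueError(
                "gradient scheme is rank deficient: need >= 6 non-collinear "
                "directions plus a b0 volume"
            )

    def fit(self, signals: np.ndarray) -> TensorResults:
        """Fit each voxel.

        Parameters
        ----------
        signals : array (n_volumes,) or (n_voxels, n_volumes), > 0 on b0s.
        """
        S = np.atleast_2d(np.asarray(signals, dtype=float))
        if S.shape[1] != self.scheme.n_volumes:
            raise ValueError("signals do not match the scheme's volume count")
        if np.any(S[:, self.scheme.b0_mask] <= 0):
            raise ValueError("non-positive b0 signal: cannot log-linearize")

        logS = np.log(np.clip(S, 1e-12, None))
        X = self.design
        # OLS pass
        beta, *_ = np.linalg.lstsq(X, logS.T, rcond=None)
        # one WLS refinement, weights = squared predicted signal
        pred = np.exp(X @ beta)  # (n_volumes, n_voxels)
        w = pred**2
        XtWX = np.einsum("vi,vn,vj->nij", X, w, X)
        XtWy = np.einsum("vi,vn,vn->ni", X, w, logS.T)
        beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0].T  # (7, n_voxels)

        s0_hat = np.exp(beta[0])
        tensors = _tensor_from_params(beta[1:].T)
        res = TensorResults(tensors, s0_hat, np.zeros(S.shape[0], dtype=bool))
        if np.isscalar(signals[0]) and np.ndim(signals) == 1:
            pass  # results stay vectorized; single-voxel callers index [0]
        return res


def fit_single_tensor(signals: np.ndarray, scheme: GradientScheme) -> TensorResults:
    """Convenience wrapper: ``DiffusionTensorModel(scheme).fit(signals)``."""
    return DiffusionTensorModel(scheme).fit(signals)
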