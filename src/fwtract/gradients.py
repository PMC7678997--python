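"""Single-shell gradient schemes and FSL-dialect bval/bvec I/O.

A scheme is the acquisition design: one or two b0 volumes per series
followed by diffusion-weighted volumes whose directions are spread over a
half sphere together with their antipodes, all at one nonzero b-value.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = ["GradientScheme", "make_gradient_scheme", "read_bval_bvec", "write_bval_bvec"]

# internal seed for the repulsion layout; fixed so schemes are reproducible
_LAYOUT_SEED = 20201120


@dataclasses.dataclass(frozen=True)
class GradientScheme:
    """Per-volume b-values, unit directions and series tags.

    ``bvecs`` rows are unit 3-vectors for diffusion-weighted volumes and the
    zero vector for b0 volumes.
    """

    bvals: np.ndarray  # (n_volumes,) s/mm^2
    bvecs: np.ndarray  # (n_volumes, 3)
    series_id: np.ndarray  # (n_volumes,) int

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        series = np.asarray(self.series_id, dtype=int)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError("bvecs must have shape (n_volumes, 3)")
        if series.shape != (bvals.size,):
            raise ValueError("series_id must have one entry per volume")
        dw = bvals > 0
        if not (~dw).any():
            raise ValueError("scheme needs at least one b=0 volume")
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("nonzero-b directions must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "series_id", series)

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def dw_mask(self) -> np.ndarray:
        return self.bvals > 0

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def design_matrix(self) -> np.ndarray:
        """Log-linear tensor design: columns (1, -b gx^2, -b gy^2, -b gz^2,
        -2b gxgy, -2b gxgz, -2b gygz) so that X @ (ln S0, Dxx..Dyz) = ln S."""
        b = self.bvals
        g = self.bvecs
        return np.column_stack(
            [
                np.ones_like(b),
                -b * g[:, 0] ** 2,
                -b * g[:, 1] ** 2,
                -b * g[:, 2] ** 2,
                -2 * b * g[:, 0] * g[:, 1],
                -2 * b * g[:, 0] * g[:, 2],
                -2 * b * g[:, 1] * g[:, 2],
            ]
        )


def _repulsion_half_sphere(n: int, n_iter: int = 200) -> np.ndarray:
    """Deterministic electrostatic-repulsion layout of n points on a half
    sphere (z >= 0 pole convention after sign-folding).

    Points interact with each other and with every antipode, the standard
    criterion for diffusion sampling where g and -g are equivalent.
    """
    rng = np.random.default_rng(_LAYOUT_SEED)
    # golden-spiral start: already well spread, repulsion then polishes it
    k = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * k
    z = k / n  # half sphere only
    r = np.sqrt(1 - z**2)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts += 1e-3 * rng.standard_normal(pts.shape)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)

    step = 0.05
    for _ in range(n_iter):
        diff = pts[:, None, :] - pts[None, :, :]
        dsum = pts[:, None, :] + pts[None, :, :]
        d2 = (diff**2).sum(-1)
        s2 = (dsum**2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        force = (diff / (d2**1.5 + 1e-12)[..., None]).sum(1)
        force += (dsum / (s2**1.5 + 1e-12)[..., None]).sum(1)
        # project force onto the tangent plane
        force -= (force * pts).sum(1, keepdims=True) * pts
        fmax = np.abs(force).max()
        if fmax > 0:
            pts = pts + step * force / fmax
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    # fold everything into one half sphere (z >= 0; ties broken on y then x)
    flip = (pts[:, 2] < 0) | ((pts[:, 2] == 0) & (pts[:, 1] < 0))
    pts[flip] *= -1
    return pts


def make_gradient_scheme(
    n_dirs_half: int = 21, bvalue: float = 1000.0, n_series: int = 2
) -> GradientScheme:
    """Build a single-shell scheme: per series, b0 volume(s) plus
    ``n_dirs_half`` directions on a half sphere and their antipodes.

    The first series carries one b0, subsequent series two, mirroring a
    typical two-run acquisition. Deterministic: the direction layout uses a
    fixed internal seed.

    Parameters
    ----------
    n_dirs_half : int
        Unique directions per half sphere; at least 6 for tensor
        identifiability.
    bvalue : float
        Shell b-value in s/mm^2, > 0.
    n_series : int
        Number of acquisition series to concatenate.
    """
    if n_dirs_half < 6:
        raise ValueError(
            "n_dirs_half must be >= 6: a diffusion tensor has 6 degrees of "
            "freedom and is not identifiable from fewer directions"
        )
    if bvalue <= 0:
        raise ValueError("bvalue must be > 0")
    if n_series < 1:
        raise ValueError("n_series must be >= 1")

    half = _repulsion_half_sphere(n_dirs_half)
    dirs = np.vstack([half, -half])

    bvals, bvecs, series = [], [], []
    for s in range(n_series):
        n_b0 = 1 if s == 0 else 2
        for _ in range(n_b0):
            bvals.append(0.0)
            bvecs.append(np.zeros(3))
            series.append(s)
        for d in dirs:
            bvals.append(bvalue)
            bvecs.append(d)
            series.append(s)
    return GradientScheme(np.array(bvals), np.array(bvecs), np.array(series))


def write_bval_bvec(scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write FSL-dialect text gradient tables: bvals on one row, bvecs as
    three rows (x, y, z), space separated."""
    Path(bval_path).write_text(" ".join(f"{v:g}" for v in scheme.bvals) + "\n")
    rows = [" ".join(f"{v:.10f}" for v in scheme.bvecs[:, i]) for i in range(3)]
    Path(bvec_path).write_text("\n".join(rows) + "\n")


def read_bval_bvec(
    bval_path: str | Path, bvec_path: str | Path, series_id: np.ndarray | None = None
) -> GradientScheme:
    """Read FSL-dialect bval/bvec text files into a scheme.

    FSL files carry no series tags; pass ``series_id`` to restore them,
    otherwise all volumes are tagged series 0.
    """
    bvals = np.loadtxt(bval_path, ndmin=1)
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL convention: 3 rows of n entries
    if series_id is None:
        series_id = np.zeros(bvals.size, dtype=int)
    # renormalize DW rows: text round-trip loses a few ulps
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    bvecs[dw] /= norms[:, None]
    return GradientScheme(bvals, bvecs, series_id)
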