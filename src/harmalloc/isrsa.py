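"""Intersubject representational similarity analysis (IS-RSA).

Between-subject similarity in a behavioral quantity (here a fitted model
parameter) is related to between-subject similarity in voxelwise neural
responses.  All similarities use the same transform of Euclidean distance,

    s_ij = 1 / (1 + d(S_i, S_j)),

mapping every variable into (0, 1].  Per voxel, the n(n-1)/2 dyadic
similarities are regressed on the behavioral similarities with a mixed
model carrying multi-membership random intercepts (each dyad loads on both
members' intercepts), estimated exactly by REML/GLS through a one-time
eigendecomposition of the dyad-membership Gram matrix.  Voxelwise p-values
are FDR-corrected (Benjamini-Hochberg) and surviving voxels are grouped
into face-connected clusters with a minimum-size threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests


@dataclass
class BetaMaps:
    """Per-subject voxelwise parametric responses.

    data : (n_subjects, n_voxels) array of in-mask voxel values.
    shape : 3-D grid shape the flat voxel axis indexes (C order).
    mask : optional boolean flat array selecting in-mask voxels; when None
        every grid voxel is in-mask and n_voxels == prod(shape).
    affine : voxel-to-world matrix carried through NIfTI round trips.
    """

    data: np.ndarray
    shape: tuple[int, int, int]
    mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subjects: list | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2:
            raise ValueError("beta map data must be (subjects, voxels)")
        n_vox = int(np.prod(self.shape)) if self.mask is None else int(
            np.sum(self.mask))
        if self.data.shape[1] != n_vox:
            raise ValueError(
                f"data has {self.data.shape[1]} voxels, grid/mask implies {n_vox}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("beta maps contain non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def to_volume(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-voxel vector back onto the 3-D grid."""
        vol = np.full(int(np.prod(self.shape)), fill)
        if self.mask is None:
            vol[:] = values
        else:
            vol[self.mask] = values
        return vol.reshape(self.shape)


def similarity_matrix(values: np.ndarray, label: str = "") -> np.ndarray:
    """Similarity s_ij = 1/(1 + Euclidean distance) between subjects.

    ``values`` is (n_subjects,) for scalar measures (distance = absolute
    difference) or (n_subjects, k) for vector-valued ones.  The result is
    symmetric with unit diagonal and entries in (0, 1].
    """
    arr = np.asarray(values, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] < 2:
        raise ValueError("similarity needs at least 2 subjects")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in similarity input")
    d = squareform(pdist(arr, metric="euclidean"))
    return 1.0 / (1.0 + d)


def dyad_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i, j) indices: all unordered subject pairs."""
    return np.triu_indices(n, k=1)


class _DyadGLS:
    """Exact GLS/REML for dyadic data with multi-membership random intercepts.

    Model per voxel: y = X b + Z u + e, u ~ N(0, s2_u I_n) subject
    intercepts, e ~ N(0, s2_e I), where Z (dyads x subjects) has ones at
    both members of each dyad.  V = s2_e (I + theta * Z Z') with
    theta = s2_u / s2_e; Z Z' is fixed across voxels, so one
    eigendecomposition serves every voxel and the REML profile reduces to a
    1-D optimization in theta.
    """

    def __init__(self, n_subjects: int, X: np.ndarray):
        ii, jj = dyad_indices(n_subjects)
        n_dyads = len(ii)
        Z = np.zeros((n_dyads, n_subjects))
        Z[np.arange(n_dyads), ii] = 1.0
        Z[np.arange(n_dyads), jj] = 1.0
        lam, Q = np.linalg.eigh(Z @ Z.T)
        self.lam = np.clip(lam, 0.0, None)
        self.Q = Q
        self.X = X
        self.Xt = Q.T @ X
        self.n, self.p = X.shape

    def _profile(self, theta: float, yt: np.ndarray):
        w = 1.0 / (1.0 + theta * self.lam)
        Xw = self.Xt * w[:, None]
        XtWX = self.Xt.T @ Xw
        XtWy = Xw.T @ yt
        beta = np.linalg.solve(XtWX, XtWy)
        resid = yt - self.Xt @ beta
        rss = float(np.sum(w * resid * resid))
        s2e = rss / (self.n - self.p)  # REML scale
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        reml = -0.5 * (
            (self.n - self.p) * np.log(s2e)
            - np.sum(np.log(w))
            + logdet_xwx
            + (self.n - self.p)
        )
        return reml, beta, s2e, XtWX

    def fit(self, y: np.ndarray) -> dict:
        yt = self.Q.T @ y
        obj = lambda log_theta: -self._profile(float(np.exp(log_theta)), yt)[0]
        res = optimize.minimize_scalar(obj, bounds=(-12.0, 8.0),
                                       method="bounded")
        theta = float(np.exp(res.x))
        # compare against the no-random-effect boundary
        reml0, *_ = self._profile(0.0, yt)
        if -res.fun < reml0:
            theta = 0.0
        reml, beta, s2e, XtWX = self._profile(theta, yt)
        cov = s2e * np.linalg.inv(XtWX)
        se = np.sqrt(np.diag(cov))
        z = beta / se
        p = 2.0 * norm.sf(np.abs(z))
        return {
            "coef": beta,
            "se": se,
            "z": z,
            "p": p,
            "s2_subject": theta * s2e,
            "s2_resid": s2e,
        }


def dyadic_regress_voxelwise(
    neural: BetaMaps,
    phi_sim: np.ndarray,
    alpha_sim: np.ndarray,
) -> pd.DataFrame:
    """Voxelwise dyadic regression of neural similarity on behavioral
    similarity.

    For each voxel, the pairwise neural similarity 1/(1+|beta_i - beta_j|)
    is regressed on the agreeability (phi) similarity with the maximin
    (alpha) similarity as covariate, in a mixed model with participant
    multi-membership random intercepts.  Returns one row per voxel with the
    phi-similarity coefficient, its SE and Wald p-value; voxels whose
    neural similarities have zero variance are flagged undefined (NaN
    statistics) rather than failing.
    """
    n = neural.n_subjects
    if phi_sim.shape != (n, n) or alpha_sim.shape != (n, n):
        raise ValueError("similarity matrices must match the subject set")
    if n < 3:
        raise ValueError("dyadic regression needs at least 3 subjects")
    ii, jj = dyad_indices(n)
    X = np.column_stack([
        np.ones(len(ii)),
        phi_sim[ii, jj],
        alpha_sim[ii, jj],
    ])
    gls = _DyadGLS(n, X)

    b = neural.data
    # pairwise |beta_i - beta_j| per voxel, vectorized over voxels
    d = np.abs(b[ii, :] - b[jj, :])
    ysim = 1.0 / (1.0 + d)

    n_vox = b.shape[1]
    out = {
        "voxel": np.arange(n_vox),
        "coef_phi": np.full(n_vox, np.nan),
        "se_phi": np.full(n_vox, np.nan),
        "p_phi": np.full(n_vox, np.nan),
        "coef_alpha": np.full(n_vox, np.nan),
        "s2_subject": np.full(n_vox, np.nan),
        "s2_resid": np.full(n_vox, np.nan),
        "defined": np.zeros(n_vox, dtype=bool),
    }
    for v in range(n_vox):
        y = ysim[:, v]
        if np.ptp(y) == 0.0:
            continue
        res = gls.fit(y)
        out["coef_phi"][v] = res["coef"][1]
        out["se_phi"][v] = res["se"][1]
        out["p_phi"][v] = res["p"][1]
        out["coef_alpha"][v] = res["coef"][2]
        out["s2_subject"][v] = res["s2_subject"]
        out["s2_resid"][v] = res["s2_resid"]
        out["defined"][v] = True
    return pd.DataFrame(out)


def permutation_test_phi(
    neural: BetaMaps,
    phi_values: np.ndarray,
    alpha_sim: np.ndarray,
    voxel: int,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Subject-level permutation p-value for the phi-similarity coefficient
    at one voxel: shuffle phi over subjects, rebuild the similarity matrix,
    refit.  Two-sided."""
    rng = np.random.default_rng(seed)
    obs = dyadic_regress_voxelwise(
        _single_voxel(neural, voxel),
        similarity_matrix(phi_values), alpha_sim,
    )["coef_phi"].iloc[0]
    count = 1
    for _ in range(n_perm):
        perm = rng.permutation(len(phi_values))
        coef = dyadic_regress_voxelwise(
            _single_voxel(neural, voxel),
            similarity_matrix(phi_values[perm]), alpha_sim,
        )["coef_phi"].iloc[0]
        if np.abs(coef) >= np.abs(obs):
            count += 1
    return count / (n_perm + 1)


def _single_voxel(neural: BetaMaps, voxel: int) -> BetaMaps:
    return BetaMaps(neural.data[:, [voxel]], (1, 1, 1),
                    mask=np.array([True]), affine=neural.affine,
                    subjects=neural.subjects)


def fdr_threshold(p_values: np.ndarray, q: float = 0.05) -> dict:
    """Benjamini-Hochberg adjustment.

    NaN entries (undefined voxels) are excluded from the correction and
    never survive.  Returns the survivor mask and adjusted q-values.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    qvals = np.full(p.shape, np.nan)
    survivors = np.zeros(p.shape, dtype=bool)
    if finite.any():
        rej, q_adj, *_ = multipletests(p[finite], alpha=q, method="fdr_bh")
        qvals[finite] = q_adj
        survivors[finite] = rej
    return {"survivors": survivors, "q_values": qvals}


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_clusters(
    survivor_volume: np.ndarray,
    min_size: int = 5,
    connectivity: int = 6,
) -> dict:
    """Connected components of surviving voxels on the 3-D grid.

    Components smaller than ``min_size`` voxels are discarded.  Default
    connectivity is face adjacency (6); 18/26 are available.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    vol = np.asarray(survivor_volume, bool)
    if vol.ndim != 3:
        raise ValueError("survivor volume must be 3-D")
    labels, n = ndimage.label(vol, structure=_STRUCTURES[connectivity])
    sizes = ndimage.sum_labels(vol, labels, index=np.arange(1, n + 1))
    out = np.zeros_like(labels)
    kept = []
    next_label = 1
    for lab, size in enumerate(sizes, start=1):
        if size >= min_size:
            out[labels == lab] = next_label
            kept.append(int(size))
            next_label += 1
    return {"labels": out, "sizes": kept, "n_clusters": len(kept)}


def run_isrsa(
    neural: BetaMaps,
    phi_values: np.ndarray,
    alpha_values: np.ndarray,
    q: float = 0.05,
    min_cluster: int = 5,
    connectivity: int = 6,
    standardize: bool = False,
) -> dict:
    """Full IS-RSA pipeline on beta maps.

    ``standardize`` optionally z-scores the behavioral values before the
    distance computation (default keeps the raw scale of the similarity
    formula).
    """
    phi = np.asarray(phi_values, float)
    alpha = np.asarray(alpha_values, float)
    if standardize:
        phi = (phi - phi.mean()) / phi.std(ddof=1)
        alpha = (alpha - alpha.mean()) / alpha.std(ddof=1)
    phi_sim = similarity_matrix(phi)
    alpha_sim = similarity_matrix(alpha)
    table = dyadic_regress_voxelwise(neural, phi_sim, alpha_sim)
    fdr = fdr_threshold(table["p_phi"].to_numpy(), q=q)
    survivor_vol = neural.to_volume(
        fdr["survivors"].astype(float), fill=0.0).astype(bool)
    clusters = extract_clusters(survivor_vol, min_size=min_cluster,
                                connectivity=connectivity)
    return {
        "table": table,
        "q_values": fdr["q_values"],
        "survivors": fdr["survivors"],
        "survivor_volume": survivor_vol,
        "clusters": clusters,
        "coef_volume": neural.to_volume(table["coef_phi"].to_numpy()),
    }
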