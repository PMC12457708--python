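"""Landmark morphometrics: Procrustes, shape PCA, outliers, regressions.

Nine 2D wing landmarks per fly are superimposed by generalized (full)
Procrustes analysis -- translation, scale and rotation removed, leaving
2 * 9 - 4 = 14 shape dimensions.  PCA of the aligned coordinates yields
exactly 14 nonzero-variance components; PC1 is the wing-shape measure.
Multivariate outliers are flagged on the 14 PCs plus centroid size by
squared Mahalanobis distance against chi-square(15) (upper 0.001 tail,
critical value 37.70).  Wing length is the landmark 3-9 distance in mm
(raw coordinates times the per-image scale factor), and strain-mean
multiple regressions relate mating success to wing length, PC1 and sex
comb tooth number (marginal F on 1 and n - 4 df).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "ShapeSpace",
    "landmarks_from_table",
    "read_tps",
    "write_tps",
    "read_landmarks_long",
    "gpa_align",
    "shape_pca",
    "mahalanobis_outliers",
    "wing_length",
    "wing_lengths",
    "centroid_size",
    "strain_trait_regression",
    "morphology_pipeline",
]

N_LANDMARKS = 9
COORD_COLS = [f"{ax}{i}" for i in range(1, N_LANDMARKS + 1) for ax in ("x", "y")]


@dataclass
class ShapeSpace:
    """Aligned configurations with sizes and (optionally) PCA results."""

    wing_ids: list[str]
    aligned: np.ndarray  # (n, 9, 2), centroid at origin, unit centroid size
    centroid_sizes: np.ndarray  # pre-scaling sizes, digitized units
    mean_shape: np.ndarray  # (9, 2)
    n_iter: int
    eigenvalues: np.ndarray | None = None
    scores: np.ndarray | None = None
    loadings: np.ndarray | None = None  # (18, n_pc), rows x1,y1..x9,y9


def landmarks_from_table(table: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Extract (wing ids, (n, 9, 2) coordinate array) from a wide table."""
    ids = list(table["wing_id"].astype(str))
    xs = table[[f"x{i}" for i in range(1, N_LANDMARKS + 1)]].to_numpy(float)
    ys = table[[f"y{i}" for i in range(1, N_LANDMARKS + 1)]].to_numpy(float)
    return ids, np.stack([xs, ys], axis=2)


def centroid_size(coords: np.ndarray) -> np.ndarray:
    """Root summed squared landmark distances from the centroid."""
    coords = np.asarray(coords, float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    c = coords - coords.mean(axis=1, keepdims=True)
    cs = np.sqrt((c**2).sum(axis=(1, 2)))
    return float(cs[0]) if single else cs


def _optimal_rotation(src: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rotation (no reflection) best mapping src onto ref (both centered)."""
    u, _, vt = np.linalg.svd(src.T @ ref)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, d])
    return u @ s @ vt


def gpa_align(
    table_or_coords,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ShapeSpace:
    """Generalized full Procrustes superimposition.

    Each configuration is centered, scaled to unit centroid size and
    rotated to the current mean shape; the mean (itself re-normalized to
    unit size each round, starting from the first wing) is iterated until
    it changes by less than ``tol``.  Centroid sizes are retained from
    before scaling.
    """
    if isinstance(table_or_coords, pd.DataFrame):
        ids, coords = landmarks_from_table(table_or_coords)
    else:
        coords = np.asarray(table_or_coords, float)
        ids = [f"w{i}" for i in range(len(coords))]
    if coords.ndim != 3 or coords.shape[1:] != (N_LANDMARKS, 2):
        raise ValueError(f"need (n, 9, 2) coordinates, got {coords.shape}")
    if len(coords) < 2:
        raise ValueError("need at least 2 wings")
    sizes = centroid_size(coords)
    if (sizes < 1e-12).any():
        bad = np.where(sizes < 1e-12)[0]
        raise ValueError(f"degenerate (all-coincident) landmarks in wings {bad}")
    X = (coords - coords.mean(axis=1, keepdims=True)) / sizes[:, None, None]
    mean = X[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(len(X)):
            X[i] = X[i] @ _optimal_rotation(X[i], mean)
        new_mean = X.mean(axis=0)
        new_mean /= centroid_size(new_mean)
        delta = np.abs(new_mean - mean).max()
        mean = new_mean
        if delta < tol:
            break
    return ShapeSpace(
        wing_ids=ids,
        aligned=X,
        centroid_sizes=sizes,
        mean_shape=mean,
        n_iter=n_iter,
    )


def _tangent_basis(mean_flat: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 4 similarity directions at the mean shape
    (x/y translation, scaling along the mean, infinitesimal rotation)."""
    k = N_LANDMARKS
    tx = np.zeros(2 * k)
    tx[0::2] = 1.0 / np.sqrt(k)
    ty = np.zeros(2 * k)
    ty[1::2] = 1.0 / np.sqrt(k)
    m = mean_flat / np.linalg.norm(mean_flat)
    rot = np.empty(2 * k)
    rot[0::2] = -mean_flat[1::2]
    rot[1::2] = mean_flat[0::2]
    rot /= np.linalg.norm(rot)
    return np.column_stack([tx, ty, m, rot])


def shape_pca(space: ShapeSpace) -> ShapeSpace:
    """PCA of the aligned coordinates (scores, eigenvalues, loadings).

    Deviations from the mean shape are first projected into the tangent
    space orthogonal to the four similarity directions (translation,
    scale, rotation), so for 9 2D landmarks exactly 2*9-4 = 14
    eigenvalues are nonzero.  Component signs are fixed so each PC's
    loading on landmark 2's x-coordinate is non-negative (falling back to
    the first nonzero loading), making reruns reproducible.
    """
    n = len(space.aligned)
    flat = space.aligned.reshape(n, 2 * N_LANDMARKS)
    B = _tangent_basis(space.mean_shape.reshape(-1))
    dev = flat - space.mean_shape.reshape(-1)
    dev -= (dev @ B) @ B.T
    centered = dev - dev.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: landmark 2 x-coordinate is flat index 2
    for j in range(evecs.shape[1]):
        pivot = evecs[2, j]
        if abs(pivot) < 1e-12:
            nz = np.flatnonzero(np.abs(evecs[:, j]) >= 1e-12)
            pivot = evecs[nz[0], j] if len(nz) else 1.0
        if pivot < 0:
            evecs[:, j] = -evecs[:, j]
    scores = centered @ evecs
    space.eigenvalues = evals
    space.scores = scores
    space.loadings = evecs
    return space


def n_nonzero_components(space: ShapeSpace, rel_tol: float = 1e-9) -> int:
    ev = space.eigenvalues
    if ev is None:
        raise ValueError("run shape_pca first")
    return int((ev > ev.max() * rel_tol).sum())


def mahalanobis_outliers(
    traits: np.ndarray, alpha: float = 0.001
) -> tuple[np.ndarray, np.ndarray, float]:
    """Flag multivariate outliers by squared Mahalanobis distance.

    Distances are to the sample mean under the sample covariance; a row is
    flagged when D^2 exceeds the upper-``alpha`` chi-square quantile at
    df = number of traits (df 15, alpha 0.001 -> 37.70).

    Returns (flags, squared distances, critical value).
    """
    X = np.asarray(traits, float)
    if X.ndim != 2:
        raise ValueError("traits must be 2-D (observations x traits)")
    n, p = X.shape
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    rank = np.linalg.matrix_rank(cov)
    if rank < p:
        raise ValueError(
            f"singular trait covariance (rank {rank} < {p} traits)"
        )
    d2 = np.einsum("ij,ji->i", (X - mean) @ np.linalg.inv(cov), (X - mean).T)
    crit = float(stats.chi2.ppf(1.0 - alpha, df=p))
    return d2 > crit, d2, crit


def wing_length(
    coords: np.ndarray, scale: float = 1.0, lm_a: int = 3, lm_b: int = 9
) -> float:
    """Distance between two landmarks (1-based; default 3 and 9) in mm."""
    coords = np.asarray(coords, float)
    if scale <= 0:
        raise ValueError("scale must be positive")
    return float(
        np.linalg.norm(coords[lm_a - 1] - coords[lm_b - 1]) * scale
    )


def wing_lengths(table: pd.DataFrame) -> pd.Series:
    """Per-wing landmark 3-9 distances in mm from a wide landmark table."""
    _, coords = landmarks_from_table(table)
    scale = table["scale"].to_numpy(float) if "scale" in table else np.ones(len(table))
    d = np.linalg.norm(coords[:, 2] - coords[:, 8], axis=1) * scale
    return pd.Series(d, index=table.index, name="wing_length")


def strain_trait_regression(
    strain_table: pd.DataFrame,
    response: str,
    predictors: tuple[str, ...] = ("wing_length", "pc1", "comb_teeth"),
) -> pd.DataFrame:
    """OLS of strain-mean mating success on strain-mean morphology.

    One row per strain; each predictor's marginal F statistic is t^2 on
    (1, n - 1 - #predictors) df (n - 4 for the three standard traits).
    """
    missing = [c for c in (response, *predictors) if c not in strain_table]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    n = len(strain_table)
    X = sm.add_constant(strain_table[list(predictors)].astype(float))
    fit = sm.OLS(strain_table[response].astype(float), X).fit()
    df_den = int(n - 1 - len(predictors))
    rows = []
    for p in predictors:
        F = float(fit.tvalues[p] ** 2)
        rows.append(
            {
                "predictor": p,
                "F": F,
                "df_num": 1,
                "df_den": df_den,
                "p": float(stats.f.sf(F, 1, df_den)),
            }
        )
    return pd.DataFrame(rows)


def morphology_pipeline(
    table: pd.DataFrame, alpha: float = 0.001
) -> tuple[pd.DataFrame, ShapeSpace, np.ndarray]:
    """Align, run PCA, flag outliers; return per-wing traits.

    Output columns: wing_id, strain, centroid_size, wing_length, pc1,
    comb_teeth, mahalanobis_d2, outlier.
    """
    space = shape_pca(gpa_align(table))
    n_pc = n_nonzero_components(space)
    traits = np.column_stack([space.scores[:, :n_pc], space.centroid_sizes])
    flags, d2, _ = mahalanobis_outliers(traits, alpha=alpha)
    out = pd.DataFrame(
        {
            "wing_id": space.wing_ids,
            "strain": table["strain"].to_numpy(),
            "centroid_size": space.centroid_sizes,
            "wing_length": wing_lengths(table).to_numpy(),
            "pc1": space.scores[:, 0],
            "comb_teeth": table["comb_teeth"].to_numpy()
            if "comb_teeth" in table
            else np.nan,
            "mahalanobis_d2": d2,
            "outlier": flags,
        }
    )
    return out, space, flags


# ---------------------------------------------------------------------------
# landmark file I/O


def read_tps(path: str | Path) -> pd.DataFrame:
    """Read a TPS landmark file into the wide table schema."""
    rows = []
    cur: dict | None = None
    coords: list[tuple[float, float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key = key.upper()
        if key == "LM":
            if cur is not None:
                rows.append(_tps_row(cur, coords))
            cur = {"scale": 1.0}
            coords = []
        elif key in ("IMAGE", "ID"):
            if cur is None:
                raise ValueError("TPS coordinate block must start with LM=")
            cur["wing_id"] = val
        elif key == "SCALE":
            cur["scale"] = float(val)
        else:
            x, y = line.split()
            coords.append((float(x), float(y)))
    if cur is not None:
        rows.append(_tps_row(cur, coords))
    return pd.DataFrame(rows)


def _tps_row(cur: dict, coords: list) -> dict:
    if len(coords) != N_LANDMARKS:
        raise ValueError(
            f"expected {N_LANDMARKS} landmarks, got {len(coords)} "
            f"for {cur.get('wing_id', '?')}"
        )
    row = {"wing_id": cur.get("wing_id", ""), "scale": cur.get("scale", 1.0)}
    for i, (x, y) in enumerate(coords, start=1):
        row[f"x{i}"] = x
        row[f"y{i}"] = y
    return row


def write_tps(table: pd.DataFrame, path: str | Path) -> None:
    """Write a wide landmark table as a TPS file."""
    buf = io.StringIO()
    for _, r in table.iterrows():
        buf.write(f"LM={N_LANDMARKS}\n")
        for i in range(1, N_LANDMARKS + 1):
            buf.write(f"{r[f'x{i}']:.6f} {r[f'y{i}']:.6f}\n")
        buf.write(f"IMAGE={r['wing_id']}\n")
        buf.write(f"ID={r['wing_id']}\n")
        buf.write(f"SCALE={r.get('scale', 1.0):.6f}\n")
    Path(path).write_text(buf.getvalue())


def read_landmarks_long(path: str | Path) -> pd.DataFrame:
    """Read the long CSV alternative (wing_id, landmark, x, y, scale)."""
    long = pd.read_csv(path)
    need = {"wing_id", "landmark", "x", "y"}
    if not need.issubset(long.columns):
        raise ValueError(f"long landmark CSV needs columns {sorted(need)}")
    rows = []
    for wid, grp in long.groupby("wing_id", sort=False):
        grp = grp.sort_values("landmark")
        if list(grp["landmark"]) != list(range(1, N_LANDMARKS + 1)):
            raise ValueError(f"wing {wid}: landmarks must be 1..{N_LANDMARKS}")
        row = {
            "wing_id": wid,
            "scale": float(grp["scale"].iloc[0]) if "scale" in grp else 1.0,
        }
        for _, r in grp.iterrows():
            row[f"x{int(r['landmark'])}"] = r["x"]
            row[f"y{int(r['landmark'])}"] = r["y"]
        rows.append(row)
    return pd.DataFrame(rows)
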