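"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — nested loops, flood fill, direct
formula evaluation — and shares no code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np


def trilinear_oracle(data: np.ndarray, geometry, point) -> np.ndarray:
    """Trilinear interpolation by explicit weighting of the 8 surrounding voxels."""
    idx = np.asarray(geometry.index_from_world(np.asarray(point, dtype=float)))
    base = np.floor(idx).astype(int)
    frac = idx - base
    shape = data.shape[:3]
    acc = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[0] if dx else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dz else 1 - frac[2])
                )
                i = min(max(base[0] + dx, 0), shape[0] - 1)
                j = min(max(base[1] + dy, 0), shape[1] - 1)
                k = min(max(base[2] + dz, 0), shape[2] - 1)
                acc = acc + w * data[i, j, k]
    return acc


def rigid_objective(X: np.ndarray, Y: np.ndarray, R: np.ndarray) -> float:
    """Sum of squared residuals of rotation R with its own optimal translation."""
    xc = X - X.mean(axis=0)
    yc = Y - Y.mean(axis=0)
    return float(np.sum((xc @ R.T - yc) ** 2))


def best_objective_over_rotations(X, Y, rotations) -> float:
    """Smallest least-squares objective over an explicit set of rotations."""
    return min(rigid_objective(X, Y, R) for R in rotations)


def axis_angle_grid(step_deg: float = 5.0, n_axes: int = 400) -> np.ndarray:
    """Dense rotation grid: Fibonacci-sphere axes x angles in 5-degree steps."""
    from scipy.spatial.transform import Rotation

    i = np.arange(n_axes)
    phi = np.arccos(1 - 2 * (i + 0.5) / n_axes)
    theta = np.pi * (1 + 5**0.5) * i
    axes = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )
    angles = np.deg2rad(np.arange(step_deg, 180.0 + 1e-9, step_deg))
    rotvecs = (axes[:, None, :] * angles[None, :, None]).reshape(-1, 3)
    rotvecs = np.vstack([[0.0, 0.0, 0.0], rotvecs])
    return Rotation.from_rotvec(rotvecs).as_matrix()


def flood_fill_components(mask: np.ndarray) -> int:
    """Count 26-connected components of a boolean volume by explicit BFS."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    shape = mask.shape
    neighbours = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    count = 0
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        count += 1
        stack = [start]
        visited[start] = True
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in neighbours:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (
                    0 <= nx < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nz < shape[2]
                    and mask[nx, ny, nz]
                    and not visited[nx, ny, nz]
                ):
                    visited[nx, ny, nz] = True
                    stack.append((nx, ny, nz))
    return count


def pearson_loop(x, y) -> float:
    """Pearson r from the textbook covariance/sigma formula, by explicit loop."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        cov += (xi - mx) * (yi - my)
        sxx += (xi - mx) ** 2
        syy += (yi - my) ** 2
    return cov / (sxx**0.5 * syy**0.5)


def mae_loop(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute difference by per-voxel loop over the flattened arrays."""
    total = 0.0
    n = 0
    for va, vb in zip(a.ravel(), b.ravel()):
        total += abs(va - vb)
        n += 1
    return total / n


def jacobian_stencil_oracle(dvf) -> np.ndarray:
    """det(I + grad d) at interior voxels by explicit central-difference slices.

    Independent of the package path (no np.gradient, no einsum); assumes an
    axis-aligned grid (identity direction).
    """
    data = dvf.data
    sp = dvf.geometry.spacing
    shape = data.shape[:3]
    out = np.full(shape, np.nan)
    for i in range(1, shape[0] - 1):
        for j in range(1, shape[1] - 1):
            for k in range(1, shape[2] - 1):
                J = np.empty((3, 3))
                for a in range(3):
                    J[a, 0] = (data[i + 1, j, k, a] - data[i - 1, j, k, a]) / (2 * sp[0])
                    J[a, 1] = (data[i, j + 1, k, a] - data[i, j - 1, k, a]) / (2 * sp[1])
                    J[a, 2] = (data[i, j, k + 1, a] - data[i, j, k - 1, a]) / (2 * sp[2])
                out[i, j, k] = np.linalg.det(np.eye(3) + J)
    return out
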