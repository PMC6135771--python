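"""Free-energy profiles and surfaces, minimal-energy paths, and PCA
landscapes of conformational ensembles.

A free-energy grid is ``F = -kT ln p`` over histogram bins, shifted so the
minimum over occupied bins is zero; empty bins are masked.  Contour levels
are integer multiples of kT.  Integer-valued reaction coordinates (e.g.
native H-bond counts) are binned at unit width centred on the integers;
continuous coordinates default to 0.5 A bins.

The "minimal energy path" between two basins is defined here as the
bottleneck-optimal path over the unmasked grid with 8-connected moves: it
minimizes the maximum F along the path, with ties broken by the smaller
total F and then lexicographically, which makes the result deterministic.

PCA follows the usual conformational-ensemble recipe: frames are
superposed onto the pooled mean structure by Kabsch least-squares rotation
(two align/re-mean iterations), the covariance of the flattened CA
coordinates is diagonalized, and frames are projected onto the top two
eigenvectors.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FESurface",
    "integer_bin_edges",
    "continuous_bin_edges",
    "fe_profile_1d",
    "fe_surface_2d",
    "minimal_energy_path",
    "kabsch_superpose",
    "PCAResult",
    "joint_pca",
    "pca_fe_surface",
    "loop_distance_distributions",
]

DEFAULT_DISTANCE_BIN_WIDTH = 0.5


@dataclass
class FESurface:
    """A 1D or 2D free-energy grid.

    ``free_energy`` is min-shifted to zero over unmasked bins; ``mask`` is
    True where a bin is empty; ``norm`` is the probability of the most
    populated bin, so ``p = norm * exp(-F/kT)`` recovers the normalized
    histogram.
    """

    axis_names: tuple[str, ...]
    bin_edges: tuple[np.ndarray, ...]
    free_energy: np.ndarray
    mask: np.ndarray
    kt: float
    norm: float

    def __post_init__(self) -> None:
        if len(self.axis_names) != len(self.bin_edges):
            raise ValueError("one name per axis is required")
        if self.free_energy.shape != self.mask.shape:
            raise ValueError("free_energy and mask shapes differ")

    @property
    def ndim(self) -> int:
        return self.free_energy.ndim

    @property
    def bin_centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.bin_edges)

    @property
    def contour_levels(self) -> np.ndarray:
        """Contour levels at every kT up to the unmasked maximum."""
        fmax = float(self.free_energy[~self.mask].max())
        n_levels = int(np.floor(fmax / self.kt))
        return self.kt * np.arange(0, n_levels + 1)

    def probabilities(self) -> np.ndarray:
        """Normalized bin probabilities (zero on masked bins)."""
        p = np.where(self.mask, 0.0, self.norm * np.exp(-self.free_energy / self.kt))
        return p

    def barrier_height(self) -> float | None:
        """For a 1D profile: lowest pass separating the two outermost
        minima, minus the higher minimum.  None when the profile has fewer
        than two local minima (single-basin / downhill)."""
        if self.ndim != 1:
            raise ValueError("barrier_height is defined for 1D profiles")
        f = self.free_energy[~self.mask]
        minima = [
            i
            for i in range(len(f))
            if (i == 0 or f[i] <= f[i - 1]) and (i == len(f) - 1 or f[i] <= f[i + 1])
        ]
        # collapse plateaus
        distinct = []
        for i in minima:
            if not distinct or i > distinct[-1] + 1 or f[i] != f[distinct[-1]]:
                distinct.append(i)
        if len(distinct) < 2:
            return None
        i0, i1 = distinct[0], distinct[-1]
        pass_height = float(f[i0 : i1 + 1].max())
        return pass_height - max(float(f[i0]), float(f[i1]))

    def to_text(self) -> str:
        """Plain-text rendering of the grid (masked bins as '....')."""
        lines = [f"# axes: {', '.join(self.axis_names)}; kT = {self.kt:g}"]
        grid = np.atleast_2d(self.free_energy)
        mask = np.atleast_2d(self.mask)
        for i in range(grid.shape[0]):
            lines.append(
                " ".join(
                    "...." if mask[i, j] else f"{grid[i, j]:6.2f}"
                    for j in range(grid.shape[1])
                )
            )
        return "\n".join(lines)


def integer_bin_edges(max_value: int, min_value: int = 0) -> np.ndarray:
    """Unit-width bin edges centred on the integers min_value..max_value."""
    return np.arange(min_value, max_value + 2) - 0.5


def continuous_bin_edges(
    values: np.ndarray, width: float = DEFAULT_DISTANCE_BIN_WIDTH
) -> np.ndarray:
    """Uniform bin edges of the given width spanning the data."""
    values = np.asarray(values, dtype=float)
    lo = np.floor(values.min() / width) * width
    hi = np.ceil(values.max() / width) * width
    if hi <= lo:
        hi = lo + width
    return np.arange(lo, hi + width / 2, width)


def _fe_from_hist(hist: np.ndarray, kt: float) -> tuple[np.ndarray, np.ndarray, float]:
    total = hist.sum()
    if total <= 0:
        raise ValueError("no samples fall inside the binning range")
    p = hist / total
    mask = p == 0
    with np.errstate(divide="ignore"):
        f = -kt * np.log(np.where(mask, 1.0, p))
    fmin = f[~mask].min()
    f = np.where(mask, np.nan, f - fmin)
    norm = float(p.max())
    return f, mask, norm


def fe_profile_1d(
    values: np.ndarray,
    kt: float,
    bin_edges: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    axis_name: str = "coordinate",
) -> FESurface:
    """1D free-energy profile ``-kT ln p`` from samples of one coordinate."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no samples supplied")
    if bin_edges is None:
        bin_edges = continuous_bin_edges(values)
    hist, edges = np.histogram(values, bins=bin_edges, weights=weights)
    f, mask, norm = _fe_from_hist(hist.astype(float), kt)
    return FESurface(
        axis_names=(axis_name,),
        bin_edges=(np.asarray(edges, dtype=float),),
        free_energy=f,
        mask=mask,
        kt=kt,
        norm=norm,
    )


def fe_surface_2d(
    x_values: np.ndarray,
    y_values: np.ndarray,
    kt: float,
    x_edges: np.ndarray | None = None,
    y_edges: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    axis_names: tuple[str, str] = ("x", "y"),
) -> FESurface:
    """2D free-energy surface over two per-frame coordinates.

    The grid is indexed ``free_energy[i, j]`` with ``i`` along x and ``j``
    along y (matrix convention of ``numpy.histogram2d``).
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y sample arrays must have the same shape")
    if x.size == 0:
        raise ValueError("no samples supplied")
    if x_edges is None:
        x_edges = continuous_bin_edges(x)
    if y_edges is None:
        y_edges = continuous_bin_edges(y)
    hist, xe, ye = np.histogram2d(x, y, bins=(x_edges, y_edges), weights=weights)
    f, mask, norm = _fe_from_hist(hist, kt)
    return FESurface(
        axis_names=tuple(axis_names),
        bin_edges=(np.asarray(xe, dtype=float), np.asarray(ye, dtype=float)),
        free_energy=f,
        mask=mask,
        kt=kt,
        norm=norm,
    )


def marginalize(surface: FESurface, axis: int) -> FESurface:
    """Collapse a 2D surface to the 1D profile of the *other* axis by
    summing probabilities."""
    if surface.ndim != 2:
        raise ValueError("marginalize expects a 2D surface")
    p = surface.probabilities().sum(axis=axis)
    keep = 1 - axis
    mask = p == 0
    with np.errstate(divide="ignore"):
        f = -surface.kt * np.log(np.where(mask, 1.0, p))
    fmin = f[~mask].min()
    return FESurface(
        axis_names=(surface.axis_names[keep],),
        bin_edges=(surface.bin_edges[keep],),
        free_energy=np.where(mask, np.nan, f - fmin),
        mask=mask,
        kt=surface.kt,
        norm=float(p.max()),
    )


def minimal_energy_path(
    surface: FESurface, start_bin: tuple[int, int], end_bin: tuple[int, int]
) -> list[tuple[int, int]]:
    """Bottleneck-optimal path between two unmasked bins of a 2D surface.

    Minimizes the maximum free energy along the path over 8-connected grid
    moves; ties are broken by the smaller total F along the path, then by
    lexicographic order of the bin sequence.  Raises when either endpoint is
    masked or no connected path exists.
    """
    if surface.ndim != 2:
        raise ValueError("minimal_energy_path expects a 2D surface")
    f = surface.free_energy
    mask = surface.mask
    start = tuple(int(v) for v in start_bin)
    end = tuple(int(v) for v in end_bin)
    for name, b in (("start", start), ("end", end)):
        if not (0 <= b[0] < f.shape[0] and 0 <= b[1] < f.shape[1]):
            raise ValueError(f"{name} bin {b} outside the grid {f.shape}")
        if mask[b]:
            raise ValueError(f"{name} bin {b} is empty (masked)")
    if start == end:
        return [start]

    # Pass 1: bottleneck Dijkstra for the minimal attainable max-F.
    best_bottleneck = _bottleneck(f, mask, start, end)
    if best_bottleneck is None:
        raise ValueError("no connected path of occupied bins between the endpoints")
    # Pass 2: restrict to bins at or below the bottleneck and find the
    # minimum-total-F path, lexicographically smallest among equals.
    allowed = (~mask) & (f <= best_bottleneck + 1e-12)
    dist: dict[tuple[int, int], tuple[float, tuple]] = {}
    queue: list[tuple[float, tuple, tuple[int, int]]] = [(float(f[start]), (start,), start)]
    while queue:
        total, path, node = heapq.heappop(queue)
        if node in dist:
            continue
        dist[node] = (total, path)
        if node == end:
            return list(path)
        for nb in _neighbors(node, f.shape):
            if allowed[nb] and nb not in dist:
                heapq.heappush(queue, (total + float(f[nb]), path + (nb,), nb))
    raise ValueError("no connected path of occupied bins between the endpoints")


def _neighbors(node: tuple[int, int], shape: tuple[int, int]):
    i, j = node
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ni, nj = i + di, j + dj
            if 0 <= ni < shape[0] and 0 <= nj < shape[1]:
                yield (ni, nj)


def _bottleneck(f, mask, start, end) -> float | None:
    best: dict[tuple[int, int], float] = {}
    queue = [(float(f[start]), start)]
    while queue:
        bott, node = heapq.heappop(queue)
        if node in best:
            continue
        best[node] = bott
        if node == end:
            return bott
        for nb in _neighbors(node, f.shape):
            if not mask[nb] and nb not in best:
                heapq.heappush(queue, (max(bott, float(f[nb])), nb))
    return None


def kabsch_superpose(
    moving: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``moving`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with the proper rotation
    (det = +1) and translation such that ``moving @ rotation.T +
    translation`` best fits the reference.  Degenerate inputs (< 3 points or
    a collinear set) are an error.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3) with equal n")
    n = moving.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    mc = moving - moving.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(mc, tol=1e-9) < 2 or np.linalg.matrix_rank(rc, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point set")
    h = mc.T @ rc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = reference.mean(axis=0) - moving.mean(axis=0) @ rotation.T
    fitted = moving @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return rotation, translation, rmsd


@dataclass
class PCAResult:
    """PCA of pooled, superposed CA coordinate ensembles."""

    mean_structure: np.ndarray          # (n_atoms, 3)
    eigenvalues: np.ndarray             # all, non-increasing
    components: np.ndarray              # (2, 3 * n_atoms) top eigenvectors
    projections: np.ndarray             # (n_frames, 2)
    labels: np.ndarray                  # per-frame ensemble label

    def projections_for(self, label: str) -> np.ndarray:
        return self.projections[self.labels == label]


def joint_pca(ensembles: dict[str, np.ndarray], n_iterations: int = 2) -> PCAResult:
    """Joint PCA over one or more labeled CA-coordinate ensembles.

    Each value of ``ensembles`` is an (n_frames, n_atoms, 3) stack drawn
    from one peptide's production window; all stacks must share the atom
    count.  Frames are superposed onto the pooled mean (align -> re-mean,
    ``n_iterations`` times), the pooled covariance of flattened coordinates
    is diagonalized, and every frame is projected onto the top two
    components, keeping its ensemble label.
    """
    if not ensembles:
        raise ValueError("no ensembles supplied")
    stacks, labels = [], []
    n_atoms = None
    for label, coords in ensembles.items():
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"ensemble {label!r} must be (n_frames, n_atoms, 3)")
        if n_atoms is None:
            n_atoms = coords.shape[1]
        elif coords.shape[1] != n_atoms:
            raise ValueError(
                f"ensemble {label!r} has {coords.shape[1]} atoms; expected {n_atoms}"
            )
        stacks.append(coords)
        labels.extend([label] * coords.shape[0])
    pooled = np.concatenate(stacks, axis=0)
    labels = np.asarray(labels, dtype=object)
    n_frames = pooled.shape[0]

    # center each frame, then iterate align -> recompute mean
    pooled = pooled - pooled.mean(axis=1, keepdims=True)
    mean = pooled.mean(axis=0)
    for _ in range(n_iterations):
        aligned = np.empty_like(pooled)
        for k in range(n_frames):
            rot, trans, _ = kabsch_superpose(pooled[k], mean)
            aligned[k] = pooled[k] @ rot.T + trans
        pooled = aligned
        mean = pooled.mean(axis=0)

    flat = pooled.reshape(n_frames, -1)
    centered = flat - mean.reshape(1, -1)
    cov = (centered.T @ centered) / max(n_frames - 1, 1)
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = eigenvectors[:, order]
    # deterministic sign convention: largest-magnitude entry positive
    for c in range(eigenvectors.shape[1]):
        pivot = np.argmax(np.abs(eigenvectors[:, c]))
        if eigenvectors[pivot, c] < 0:
            eigenvectors[:, c] = -eigenvectors[:, c]
    components = eigenvectors[:, :2].T
    projections = centered @ components.T
    return PCAResult(
        mean_structure=mean,
        eigenvalues=eigenvalues,
        components=components,
        projections=projections,
        labels=labels,
    )


def pca_fe_surface(
    pca: PCAResult,
    kt: float,
    label: str | None = None,
    n_bins: int = 50,
) -> FESurface:
    """Free-energy surface over the first two principal components.

    Bin edges span the pooled projection range (range / ``n_bins`` wide), so
    per-peptide surfaces from a joint PCA share a common grid.
    """
    proj = pca.projections
    edges = []
    for d in range(2):
        lo, hi = proj[:, d].min(), proj[:, d].max()
        pad = 1e-9 * max(1.0, abs(hi - lo))
        edges.append(np.linspace(lo - pad, hi + pad, n_bins + 1))
    sel = proj if label is None else pca.projections_for(label)
    if sel.shape[0] == 0:
        raise ValueError(f"no frames with label {label!r}")
    return fe_surface_2d(
        sel[:, 0],
        sel[:, 1],
        kt,
        x_edges=edges[0],
        y_edges=edges[1],
        axis_names=("PC1", "PC2"),
    )


def loop_distance_distributions(
    loop_distances: dict[str, np.ndarray],
    labels: dict[str, np.ndarray],
    bin_edges: np.ndarray | None = None,
) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Normalized folded/unfolded loop-distance densities per peptide.

    ``loop_distances[peptide]`` are per-frame distances and
    ``labels[peptide]`` the matching state labels.  Returns
    ``{peptide: {state: (bin_edges, density)}}``; an empty sub-ensemble is
    omitted with a warning.
    """
    if bin_edges is None:
        pooled = np.concatenate(list(loop_distances.values()))
        bin_edges = continuous_bin_edges(pooled)
    out: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for peptide, values in loop_distances.items():
        values = np.asarray(values, dtype=float)
        lab = np.asarray(labels[peptide])
        if values.shape != lab.shape:
            raise ValueError(f"distances and labels differ in length for {peptide!r}")
        out[peptide] = {}
        for state in ("folded", "unfolded"):
            sel = values[lab == state]
            if sel.size == 0:
                warnings.warn(
                    f"{peptide}: no {state} frames; omitting that density",
                    stacklevel=2,
                )
                continue
            density, edges = np.histogram(sel, bins=bin_edges, density=True)
            out[peptide][state] = (edges, density)
    return out
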