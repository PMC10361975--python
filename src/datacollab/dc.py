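"""Data-collaboration (DC) analysis: confidential cross-institution
data integration through dimension-reduced intermediate representations.

The scheme has two roles.  Each *worker* i holds private data
X_i in R^{m_i x d} over a common feature space and publishes only its
intermediate representation X~_i = f_i(X_i) in R^{m_i x l_i}, where f_i
is a private linear dimension-reduction map (PCA here) with l_i < d.
Because each worker may choose a different f_i (and even a different
l_i), the intermediate representations are not directly comparable.  A
shared synthetic *anchor* matrix X^anc in R^{r x d} — built from public
reference ranges, never from private data — is passed through every
worker's map, and the *master* aligns the anchor images: it chooses a
common r x k orthonormal target Z (top-k left singular vectors of the
concatenated anchor intermediates) and solves, per worker, the least
squares problem

    G_i = argmin_G || X~_i^anc G - Z ||_F ,

so that the collaborative representations X^_i = X~_i G_i live in one
k-dimensional space where the anchors approximately coincide across
workers.  The master then stacks the X^_i sample-wise and analyses them
as a single data set.

The master-side API accepts only intermediate representations and
labels, never raw worker data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntermediateMap",
    "AnchorData",
    "CollaborationMap",
    "CollaborativeDataset",
    "default_intermediate_dim",
    "fit_intermediate_map",
    "apply_map",
    "generate_anchor",
    "compute_collaboration_maps",
    "build_collaborative_dataset",
    "anchor_alignment_residual",
    "Worker",
]


def _fix_signs(M: np.ndarray) -> np.ndarray:
    """Deterministic orientation: the largest-magnitude entry of each
    column is made positive."""
    M = M.copy()
    idx = np.argmax(np.abs(M), axis=0)
    signs = np.sign(M[idx, np.arange(M.shape[1])])
    signs[signs == 0] = 1.0
    return M * signs


def default_intermediate_dim(d: int) -> int:
    """Default l_i = min(d - 1, ceil(0.75 d)): a genuine compression
    (l < d is required) that still keeps most of the variance."""
    return min(d - 1, int(np.ceil(0.75 * d)))


@dataclass
class IntermediateMap:
    """A worker's private linear dimension-reduction map f_i: R^d -> R^l."""

    method: str                # "pca" or "svd"
    center: np.ndarray         # (d,), zero for svd
    components: np.ndarray     # (d, l), orthonormal columns
    fitted_on: str = ""

    @property
    def d(self) -> int:
        return self.components.shape[0]

    @property
    def l(self) -> int:
        return self.components.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return apply_map(self, X)


@dataclass
class AnchorData:
    """Shared synthetic reference matrix X^anc in R^{r x d}."""

    A: np.ndarray
    strategy: str
    seed: int

    @property
    def r(self) -> int:
        return self.A.shape[0]

    @property
    def d(self) -> int:
        return self.A.shape[1]


@dataclass
class CollaborationMap:
    """Master-side reconversion g_i: R^{l_i} -> R^k with shared target Z."""

    G: np.ndarray  # (l_i, k)
    Z: np.ndarray  # (r, k), orthonormal columns

    @property
    def k(self) -> int:
        return self.G.shape[1]


@dataclass
class CollaborativeDataset:
    """Stacked collaborative representations of all workers."""

    X: np.ndarray            # (sum m_i, k)
    y: np.ndarray            # (sum m_i,)
    provenance: np.ndarray   # worker label per row


def fit_intermediate_map(X: np.ndarray, method: str = "pca",
                         l: int | None = None, fitted_on: str = "") -> IntermediateMap:
    """Fit a worker's dimension-reduction map.

    ``pca`` centres on the column means and keeps the top-l principal
    directions; ``svd`` keeps the top-l right singular vectors of the
    raw matrix.  The compressed dimension must satisfy l < d, and the
    (centred) data must have rank at least l.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    m, d = X.shape
    if l is None:
        l = default_intermediate_dim(d)
    if not 1 <= l < d:
        raise ValueError(f"intermediate dimension must satisfy 1 <= l < d "
                         f"(got l={l}, d={d})")
    if method == "pca":
        center = X.mean(axis=0)
    elif method == "svd":
        center = np.zeros(d)
    else:
        raise ValueError(f"unknown method {method!r}")
    Xc = X - center
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    if np.sum(s > tol) < l:
        raise ValueError(f"data rank {int(np.sum(s > tol))} is below the "
                         f"requested dimension l={l}")
    P = _fix_signs(Vt[:l].T)
    return IntermediateMap(method=method, center=center, components=P,
                           fitted_on=fitted_on)


def apply_map(f: IntermediateMap, X: np.ndarray) -> np.ndarray:
    """X~ = (X - center) P; used identically for worker data and anchors."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != f.d:
        raise ValueError(f"expected {f.d} columns, got {X.shape[1]}")
    return (X - f.center) @ f.components


def generate_anchor(d: int, r: int, bounds, strategy: str = "uniform",
                    seed: int = 0, reference: np.ndarray | None = None) -> AnchorData:
    """Shared anchor matrix.

    ``uniform``: entries i.i.d. uniform within per-feature (lo, hi)
    bounds taken from public reference ranges.  ``resample-interpolate``:
    SMOTE-style random convex combinations of pairs of rows of a public
    reference table.
    """
    if r < 1:
        raise ValueError("anchor count r must be >= 1")
    rng = np.random.default_rng(seed)
    if strategy == "uniform":
        bounds = list(bounds)
        if len(bounds) != d:
            raise ValueError(f"need bounds for all {d} features, got {len(bounds)}")
        lo = np.array([b[0] for b in bounds], dtype=float)
        hi = np.array([b[1] for b in bounds], dtype=float)
        if np.any(lo >= hi):
            raise ValueError("each bound must satisfy lo < hi")
        A = rng.uniform(lo, hi, size=(r, d))
    elif strategy == "resample-interpolate":
        if reference is None or len(reference) < 2:
            raise ValueError("resample-interpolate needs a reference table "
                             "with at least 2 rows")
        ref = np.asarray(reference, dtype=float)
        if ref.shape[1] != d:
            raise ValueError("reference table width does not match d")
        i = rng.integers(0, len(ref), size=r)
        j = rng.integers(0, len(ref), size=r)
        u = rng.random((r, 1))
        A = ref[i] + u * (ref[j] - ref[i])
    else:
        raise ValueError(f"unknown anchor strategy {strategy!r}")
    return AnchorData(A=A, strategy=strategy, seed=seed)


def compute_collaboration_maps(anchor_intermediates: list[np.ndarray],
                               k: int | None = None) -> list[CollaborationMap]:
    """Master step: align anchor images into a common k-space.

    Concatenates the workers' anchor intermediates column-wise, takes the
    top-k left singular vectors as the shared orthonormal target Z, and
    solves min_G ||X~_i^anc G - Z||_F per worker by least squares.
    """
    mats = [np.asarray(M, dtype=float) for M in anchor_intermediates]
    if not mats:
        raise ValueError("need at least one worker")
    r = mats[0].shape[0]
    if any(M.shape[0] != r for M in mats):
        raise ValueError("anchor intermediates must share the row count r")
    min_l = min(M.shape[1] for M in mats)
    if k is None:
        k = min_l
    if not 1 <= k <= min_l:
        raise ValueError(f"k must satisfy 1 <= k <= min l_i ({min_l})")
    C = np.concatenate(mats, axis=1)
    U, _, _ = np.linalg.svd(C, full_matrices=False)
    Z = _fix_signs(U[:, :k])
    out = []
    for i, M in enumerate(mats):
        G, _, rank, _ = np.linalg.lstsq(M, Z, rcond=None)
        if rank < k:
            raise ValueError(
                f"worker {i}: anchor intermediate has rank {rank} < k={k}; "
                "increase the anchor count or lower k"
            )
        out.append(CollaborationMap(G=G, Z=Z))
    return out


def build_collaborative_dataset(intermediates: list[np.ndarray],
                                labels: list[np.ndarray],
                                g_maps: list[CollaborationMap],
                                worker_names: list[str] | None = None
                                ) -> CollaborativeDataset:
    """Stack X^_i = X~_i G_i sample-wise into a single analysable set.

    Operates purely on intermediate representations — raw worker data
    never reach this function.
    """
    if not (len(intermediates) == len(labels) == len(g_maps)):
        raise ValueError("one intermediate, label vector and map per worker")
    ks = {g.k for g in g_maps}
    if len(ks) != 1:
        raise ValueError(f"mismatched integrated dimensions k: {sorted(ks)}")
    if worker_names is None:
        worker_names = [f"worker{i}" for i in range(len(g_maps))]
    blocks, ys, prov = [], [], []
    for Xt, y, g, name in zip(intermediates, labels, g_maps, worker_names):
        Xt = np.asarray(Xt, dtype=float)
        if Xt.shape[1] != g.G.shape[0]:
            raise ValueError("intermediate width does not match its map")
        blocks.append(Xt @ g.G)
        ys.append(np.asarray(y))
        prov.append(np.full(Xt.shape[0], name, dtype=object))
    return CollaborativeDataset(
        X=np.concatenate(blocks, axis=0),
        y=np.concatenate(ys),
        provenance=np.concatenate(prov),
    )


def anchor_alignment_residual(g_maps: list[CollaborationMap],
                              anchor_intermediates: list[np.ndarray]) -> float:
    """Sum over worker pairs of ||X~_i^anc G_i - X~_j^anc G_j||_F: the
    degree to which the aligned anchors fail to coincide."""
    aligned = [np.asarray(M, dtype=float) @ g.G
               for M, g in zip(anchor_intermediates, g_maps)]
    total = 0.0
    for i in range(len(aligned)):
        for j in range(i + 1, len(aligned)):
            total += float(np.linalg.norm(aligned[i] - aligned[j]))
    return total


# ---------------------------------------------------------------------------
# Serialisation: shared artefacts (anchors, intermediates, maps) as
# portable .npz archives with shape/type metadata.

_ARTIFACT_TYPES = {"IntermediateMap", "AnchorData", "CollaborationMap"}


def save_artifact(obj, path) -> None:
    """Write an anchor, intermediate map or collaboration map (or a bare
    intermediate-representation matrix) to a portable ``.npz`` file."""
    if isinstance(obj, IntermediateMap):
        np.savez(path, artifact="IntermediateMap", method=obj.method,
                 fitted_on=obj.fitted_on, center=obj.center,
                 components=obj.components)
    elif isinstance(obj, AnchorData):
        np.savez(path, artifact="AnchorData", strategy=obj.strategy,
                 seed=obj.seed, A=obj.A)
    elif isinstance(obj, CollaborationMap):
        np.savez(path, artifact="CollaborationMap", G=obj.G, Z=obj.Z)
    elif isinstance(obj, np.ndarray):
        np.savez(path, artifact="matrix", M=obj)
    else:
        raise TypeError(f"cannot serialise {type(obj).__name__}")


def load_artifact(path):
    with np.load(path, allow_pickle=False) as data:
        kind = str(data["artifact"])
        if kind == "IntermediateMap":
            return IntermediateMap(method=str(data["method"]),
                                   center=data["center"],
                                   components=data["components"],
                                   fitted_on=str(data["fitted_on"]))
        if kind == "AnchorData":
            return AnchorData(A=data["A"], strategy=str(data["strategy"]),
                              seed=int(data["seed"]))
        if kind == "CollaborationMap":
            return CollaborationMap(G=data["G"], Z=data["Z"])
        if kind == "matrix":
            return data["M"]
    raise ValueError(f"unknown artifact type {kind!r}")


class Worker:
    """Worker role: holds raw data privately, publishes intermediates.

    By default the worker standardises its columns (with its own private
    means and SDs) before fitting the compression map: clinical features
    mix units whose raw variances span four orders of magnitude, and an
    unscaled variance-based projection would discard low-variance but
    informative attributes (HbA1c most of all).  The scaling statistics,
    like the map itself, never leave the worker; anchors and new samples
    pass through the identical private pipeline.

    Only :meth:`intermediate`, :meth:`anchor_intermediate`, the labels
    and the fitted map's dimensions are exposed; the raw matrix and the
    scaling statistics stay in private attributes.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, name: str = "",
                 method: str = "pca", l: int | None = None,
                 scale: bool = True):
        self.__X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.name = name
        if scale:
            self.__mu = self.__X.mean(axis=0)
            sd = self.__X.std(axis=0)
            sd[sd == 0] = 1.0
            self.__sd = sd
        else:
            self.__mu = np.zeros(self.__X.shape[1])
            self.__sd = np.ones(self.__X.shape[1])
        self._map = fit_intermediate_map(self.__prep(self.__X), method=method,
                                         l=l, fitted_on=name)

    def __prep(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.__mu) / self.__sd

    @property
    def l(self) -> int:
        return self._map.l

    @property
    def d(self) -> int:
        return self._map.d

    def intermediate(self) -> np.ndarray:
        return apply_map(self._map, self.__prep(self.__X))

    def anchor_intermediate(self, anchor: AnchorData) -> np.ndarray:
        return apply_map(self._map, self.__prep(anchor.A))

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        """Apply the worker's own pipeline to new (e.g. test) samples."""
        return apply_map(self._map, self.__prep(X_new))
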