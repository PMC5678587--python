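"""Iterated graph-cut figure/ground segmentation (GrabCut).

The classic interactive segmentation loop: full-covariance Gaussian mixture
color models for foreground and background are alternated with a binary
min-cut on the 4-connected pixel grid.  The cut minimizes

    E(alpha) = sum_p  -log p(z_p | GMM_alpha(p))
             + gamma * sum_{p~q} [alpha_p != alpha_q] * exp(-beta ||z_p - z_q||^2)

where ``beta`` is set from the mean squared neighbor color difference so the
contrast term adapts to the image.  An initial rectangle marks the probable
foreground; everything outside it is definite background, and user markers
are hard constraints with infinite-capacity terminal links.

The min-cut is solved exactly with :func:`scipy.sparse.csgraph.maximum_flow`
on integer-scaled capacities; the partition is recovered from the residual
graph.  All randomness (mixture initialization) is seeded, so results are
deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

__all__ = ["GrabCutConfig", "GrabCutResult", "grabcut"]

_CAP_SCALE = 64          # float energy -> integer capacity quantization
_HARD = np.int64(1) << 40  # effectively infinite terminal capacity


@dataclass
class GrabCutConfig:
    n_components: int = 5      # GMM components per color model
    gamma: float = 50.0        # smoothness weight
    iters: int = 5             # model-refit / cut rounds
    tol_changed: float = 1e-3  # early stop when < this fraction of pixels flips
    reg: float = 1e-3          # covariance floor: ~8/255 std per channel
    outlier: float = 1e-4      # uniform mixture weight bounding the data terms
    marker_radius: int = 4     # px: a marker constrains a small disk, like a tap
    bg_bias: float = 8.0       # energy bias toward background outside the rect


@dataclass
class GrabCutResult:
    mask: np.ndarray           # bool foreground
    degenerate: bool           # empty (or full) foreground, or no color contrast
    n_iters: int


class _GMM:
    """Full-covariance mixture with closed-form refits (no EM inside).

    A small uniform "outlier" component is mixed in so the negative
    log-likelihood is bounded: without it, a near-degenerate component
    fitted to a uniform region (sky, white sheet) can dominate the energy
    by tens of nats and flood the cut.
    """

    def __init__(self, k: int, reg: float, outlier: float = 1e-4):
        self.k = k
        self.reg = reg
        self.outlier = outlier
        self.means = np.zeros((k, 3))
        self.inv_cov = np.tile(np.eye(3), (k, 1, 1))
        self.log_det = np.zeros(k)
        self.log_weights = np.full(k, -np.log(k))

    def init_kmeans(self, x: np.ndarray, rng: np.random.Generator) -> None:
        n = len(x)
        sub = x[rng.choice(n, min(n, 4000), replace=False)]
        # k-means++-lite: seeded farthest-point init then a few Lloyd rounds
        centers = [sub[rng.integers(len(sub))]]
        for _ in range(self.k - 1):
            d2 = np.min([((sub - c) ** 2).sum(1) for c in centers], axis=0)
            total = d2.sum()
            if total < 1e-12:   # (near-)uniform region: any point will do
                centers.append(sub[rng.integers(len(sub))])
            else:
                centers.append(sub[rng.choice(len(sub), p=d2 / total)])
        centers = np.array(centers)
        for _ in range(8):
            lbl = ((sub[:, None, :] - centers[None]) ** 2).sum(2).argmin(1)
            for j in range(self.k):
                if (lbl == j).any():
                    centers[j] = sub[lbl == j].mean(0)
        self.fit(x, ((x[:, None, :] - centers[None]) ** 2).sum(2).argmin(1))

    def fit(self, x: np.ndarray, assignment: np.ndarray) -> None:
        for j in range(self.k):
            sel = assignment == j
            n_j = int(sel.sum())
            if n_j < 10:
                self.log_weights[j] = -1e3
                continue
            xj = x[sel]
            mu = xj.mean(0)
            cov = np.cov(xj.T) + self.reg * np.eye(3)
            self.means[j] = mu
            self.inv_cov[j] = np.linalg.inv(cov)
            sign, logdet = np.linalg.slogdet(cov)
            self.log_det[j] = logdet
            self.log_weights[j] = np.log(n_j / len(x))

    def component_scores(self, x: np.ndarray) -> np.ndarray:
        """(n, k) log pi_j + log N(x | mu_j, Sigma_j)."""
        d = x[:, None, :] - self.means[None]          # n x k x 3
        maha = np.einsum("nki,kij,nkj->nk", d, self.inv_cov, d)
        return (self.log_weights[None]
                - 0.5 * (maha + self.log_det[None] + 3 * np.log(2 * np.pi)))

    def neg_log_likelihood(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import logsumexp

        ll = logsumexp(self.component_scores(x), axis=1)
        # mixture with a uniform density on the unit color cube
        return -np.logaddexp(np.log1p(-self.outlier) + ll, np.log(self.outlier))

    def assign(self, x: np.ndarray) -> np.ndarray:
        return self.component_scores(x).argmax(1)


def _pairwise_capacities(img: np.ndarray, gamma: float):
    h, w = img.shape[:2]
    idx = np.arange(h * w).reshape(h, w)
    dx = ((img[:, :-1] - img[:, 1:]) ** 2).sum(-1)
    dy = ((img[:-1, :] - img[1:, :]) ** 2).sum(-1)
    mean_d2 = (dx.sum() + dy.sum()) / (dx.size + dy.size)
    beta = 1.0 / (2 * mean_d2 + 1e-12)
    cap_x = gamma * np.exp(-beta * dx)
    cap_y = gamma * np.exp(-beta * dy)
    a = np.concatenate([idx[:, :-1].ravel(), idx[:-1, :].ravel()])
    b = np.concatenate([idx[:, 1:].ravel(), idx[1:, :].ravel()])
    c = np.rint(np.concatenate([cap_x.ravel(), cap_y.ravel()]) * _CAP_SCALE).astype(np.int64)
    return a, b, c, float(mean_d2)


def _min_cut(n: int, pair_a, pair_b, pair_cap, src_cap, sink_cap) -> np.ndarray:
    s, t = n, n + 1
    rows = np.concatenate([pair_a, pair_b, np.full(n, s), np.arange(n)])
    cols = np.concatenate([pair_b, pair_a, np.arange(n), np.full(n, t)])
    caps = np.concatenate([pair_cap, pair_cap, src_cap, sink_cap])
    graph = csr_matrix((caps, (rows, cols)), shape=(n + 2, n + 2))
    result = maximum_flow(graph, s, t)
    residual = graph - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reach = breadth_first_order(residual, s, directed=True, return_predecessors=False)
    fg = np.zeros(n + 2, dtype=bool)
    fg[reach] = True
    return fg[:n]


def grabcut(
    image: np.ndarray,
    rect: tuple[int, int, int, int],
    markers: list | tuple = (),
    iters: int | None = None,
    seed: int = 0,
    config: GrabCutConfig | None = None,
) -> GrabCutResult:
    """Segment ``image`` (uint8 RGB) given an init rectangle and markers.

    ``rect`` is (x0, y0, x1, y1) half-open and denotes the *potential*
    foreground: it initializes the color models but does not clamp the
    labeling, so the segmentation may grow beyond it.  The four image
    corners are definite-background seeds.  ``markers`` are (point, label)
    hard constraints with ``point=(x, y)`` and ``label``
    "foreground"/"background"; marked pixels always carry their label in
    the output.
    """
    cfg = config or GrabCutConfig()
    if iters is None:
        iters = cfg.iters
    if iters < 1:
        raise ValueError("iters must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = image.shape[:2]
    n = h * w
    img = image.astype(np.float64) / 255.0
    x = img.reshape(n, 3)

    x0, y0, x1, y1 = rect
    in_rect = np.zeros((h, w), dtype=bool)
    in_rect[y0:y1, x0:x1] = True
    in_rect = in_rect.ravel()

    hard_fg = np.zeros(n, dtype=bool)
    hard_bg = np.zeros((h, w), dtype=bool)
    c = max(4, min(h, w) // 25)       # corner background-seed patches
    hard_bg[:c, :c] = hard_bg[:c, -c:] = hard_bg[-c:, :c] = hard_bg[-c:, -c:] = True
    hard_bg = hard_bg.ravel()
    hard_fg = hard_fg.reshape(h, w)
    hard_bg = hard_bg.reshape(h, w)
    r = cfg.marker_radius
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (yy ** 2 + xx ** 2) <= r ** 2
    for (px, py), label in markers:
        if not (0 <= px < w and 0 <= py < h):
            raise ValueError(f"marker ({px}, {py}) outside image {w}x{h}")
        stamp = np.zeros((h, w), dtype=bool)
        y0s, y1s = max(0, py - r), min(h, py + r + 1)
        x0s, x1s = max(0, px - r), min(w, px + r + 1)
        stamp[y0s:y1s, x0s:x1s] = disk[(y0s - py + r):(y1s - py + r),
                                       (x0s - px + r):(x1s - px + r)]
        if label == "foreground":
            hard_fg |= stamp
            hard_bg &= ~stamp
        elif label == "background":
            hard_bg |= stamp
            hard_fg &= ~stamp
        else:
            raise ValueError(f"invalid marker label {label!r}")
    hard_fg = hard_fg.ravel()
    hard_bg = hard_bg.ravel()

    pair_a, pair_b, pair_cap, mean_d2 = _pairwise_capacities(img, cfg.gamma)
    if mean_d2 < 1e-8:
        # uniform image: no color evidence to separate figure from ground
        return GrabCutResult(mask=np.zeros((h, w), dtype=bool),
                             degenerate=True, n_iters=0)

    alpha = in_rect.copy()
    alpha[hard_fg] = True
    alpha[hard_bg] = False
    if not alpha.any() or alpha.all():
        return GrabCutResult(mask=alpha.reshape(h, w), degenerate=True, n_iters=0)

    fg_gmm = _GMM(cfg.n_components, cfg.reg, cfg.outlier)
    bg_gmm = _GMM(cfg.n_components, cfg.reg, cfg.outlier)
    fg_gmm.init_kmeans(x[alpha], rng)
    bg_gmm.init_kmeans(x[~alpha], rng)

    n_done = 0
    for it in range(iters):
        d_fg = fg_gmm.neg_log_likelihood(x)
        d_bg = bg_gmm.neg_log_likelihood(x)
        # shifting both terminal links of a pixel by a common offset leaves
        # the minimum cut unchanged; do so to keep capacities non-negative
        # without clipping away the (often negative) log-density range
        # soft prior: pixels outside the init rectangle lean background, so
        # a weak color model cannot flood the frame, while genuinely
        # leaf-colored regions beyond the rectangle can still flip
        d_fg = d_fg + np.where(in_rect, 0.0, cfg.bg_bias)
        shift = np.minimum(d_fg, d_bg)
        src = np.rint(np.clip(d_bg - shift, 0, 1e5) * _CAP_SCALE).astype(np.int64)
        snk = np.rint(np.clip(d_fg - shift, 0, 1e5) * _CAP_SCALE).astype(np.int64)
        src[hard_fg] = _HARD
        snk[hard_fg] = 0
        snk[hard_bg] = _HARD
        src[hard_bg] = 0
        new_alpha = _min_cut(n, pair_a, pair_b, pair_cap, src, snk)
        new_alpha[hard_fg] = True
        new_alpha[hard_bg] = False
        changed = np.mean(new_alpha != alpha)
        alpha = new_alpha
        n_done = it + 1
        if not alpha.any() or alpha.all():
            return GrabCutResult(mask=alpha.reshape(h, w), degenerate=True,
                                 n_iters=n_done)
        if changed < cfg.tol_changed and it > 0:
            break
        fg_gmm.fit(x[alpha], fg_gmm.assign(x[alpha]))
        bg_gmm.fit(x[~alpha], bg_gmm.assign(x[~alpha]))

    return GrabCutResult(mask=alpha.reshape(h, w), degenerate=False, n_iters=n_done)
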