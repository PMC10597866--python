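"""Reinforcement-learning lesion segmentation.

Training learns three things from images paired with manual masks:

1. **Sub-image dimensions** — candidate tilings compete as agents, each
   Q-learning-segmenting the stream of sub-images; a control agent kills an
   agent whose dissimilarity rose over three consecutive sub-images and, at
   the end of each pass, the live agent with the worst current dissimilarity.
   The last surviving tiling wins.
2. **A strategy table (Q-table)** — per sub-image the agent picks an action
   (threshold index, opening radius), applies "intensity <= tau is lesion"
   followed by a morphological opening, and is rewarded R1 when the
   dissimilarity against the manual mask strictly drops, R2 otherwise.
   States discretize area fraction, compactness 4πA/P², object count and
   tile position.  An episode ends at the first non-improving action, so the
   learned greedy policy is a hill-descent on dissimilarity with a learned
   stopping rule.
3. **A post-processing radius** — opening-then-closing disk radius chosen by
   argmin mean dissimilarity over candidates (trial and error).

Dissimilarity is XOR(machine, manual) / total pixels.  Thresholds are stored
as *indices* into an evenly spaced grid over each sub-image's [gmin, gmax],
so one table generalizes across sub-images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import morphology

#: state-bin counts (area, compactness, object count, position) per mode
MODE_BINS = {1: (9, 5, 4, 4), 2: (4, 4, 3, 3)}


@dataclass
class SegmenterConfig:
    mode: int = 1
    n_thresholds: int = 8
    radii: tuple[int, ...] = (0, 1, 2, 3)
    lr: float = 0.1
    discount: float = 0.9
    eps_start: float = 0.5
    eps_end: float = 0.05
    episodes: int = 50              # training passes over the image stream
    max_steps: int = 8              # per-sub-image episode / rollout cap
    filter_radius: float = 1.5      # neighborhood distance n of the mean filter
    candidate_dims: tuple[tuple[int, int], ...] | None = None  # default squares 16/32/64
    dim_select_episodes: int = 8    # passes used during the agent competition
    postproc_radii: tuple[int, ...] = (1, 2, 3, 4, 5)
    reward_improve: float = 1.0     # R1
    reward_other: float = -1.0      # R2
    seed: int = 0


# -- elementary image operations --------------------------------------------

def _disk_offsets(n: float) -> np.ndarray:
    """Boolean kernel of pixels at Euclidean distance < n from the center."""
    r = int(np.ceil(n))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (np.hypot(yy, xx) < n).astype(float)


def smooth_image(img: np.ndarray, n: float) -> np.ndarray:
    """Mean filter over the neighborhood {p* : dist(p, p*) < n}.

    n = 0 returns the input unchanged; near the border the mean is taken
    over the in-image part of the neighborhood.  Output clipped to [0, 255].
    """
    if n < 0:
        raise ValueError("neighborhood distance must be >= 0")
    img = np.asarray(img, dtype=float)
    if n == 0:
        return img.copy()
    kernel = _disk_offsets(n)
    num = ndimage.convolve(img, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(img), kernel, mode="constant", cval=0.0)
    return np.clip(num / den, 0.0, 255.0)


@dataclass
class SubImageGrid:
    """Row-major disjoint tiling; edge tiles clipped to the image."""

    tile_height: int
    tile_width: int
    image_shape: tuple[int, int]
    offsets: list[tuple[int, int]]  # top-left (row, col) per tile

    def __len__(self):
        return len(self.offsets)

    def extract(self, img: np.ndarray, k: int) -> np.ndarray:
        r, c = self.offsets[k]
        return img[r:r + self.tile_height, c:c + self.tile_width]

    def stitch(self, tiles: list[np.ndarray]) -> np.ndarray:
        out = np.zeros(self.image_shape, dtype=tiles[0].dtype)
        for (r, c), t in zip(self.offsets, tiles):
            out[r:r + t.shape[0], c:c + t.shape[1]] = t
        return out


def split_into_subimages(img: np.ndarray, dims: tuple[int, int]) -> SubImageGrid:
    li, wi = dims
    h, w = img.shape
    if not (1 <= li <= h and 1 <= wi <= w):
        raise ValueError("tile dims must fit inside the image")
    offsets = [(r, c) for r in range(0, h, li) for c in range(0, w, wi)]
    return SubImageGrid(li, wi, (h, w), offsets)


def dissimilarity(machine: np.ndarray, manual: np.ndarray) -> float:
    """Fraction of pixels where the two binary masks disagree (XOR / total)."""
    machine = np.asarray(machine)
    manual = np.asarray(manual)
    if machine.shape != manual.shape:
        raise ValueError("mask dimensions differ")
    return float(np.mean((machine > 0) ^ (manual > 0)))


def apply_action(sub: np.ndarray, tau: float, radius: int) -> np.ndarray:
    """Threshold (intensity <= tau is lesion) then open with a disk of
    ``radius``; radius 0 skips the opening."""
    mask = np.asarray(sub, dtype=float) <= tau
    if radius > 0:
        mask = morphology.opening(mask, morphology.disk(radius))
    return mask.astype(np.uint8)


def threshold_grid(sub: np.ndarray, n_thresholds: int) -> np.ndarray:
    """Evenly spaced threshold levels spanning the sub-image's [gmin, gmax]."""
    gmin, gmax = float(np.min(sub)), float(np.max(sub))
    if gmin == gmax:
        # degenerate constant tile: all thresholds select everything; shift
        # below gmin so the policy can also produce the empty mask
        return np.concatenate([[gmin - 1.0], np.full(n_thresholds - 1, gmin)])
    return np.linspace(gmin, gmax, n_thresholds)


def compute_state(mask: np.ndarray, tile_offset: tuple[int, int],
                  image_shape: tuple[int, int], mode: int = 1) -> tuple[int, int, int, int]:
    """Discretized state (area, compactness, object count, position).

    Area fraction and compactness 4πA/P² are binned uniformly on [0, 1];
    the connected-component count is capped at the last bin; position is the
    image quadrant of the tile center mapped into the mode's bin count.
    Empty masks map to the lowest bins (compactness of an empty mask is 0).
    """
    n1, n2, n3, n4 = MODE_BINS[mode]
    mask = np.asarray(mask) > 0
    area = int(mask.sum())
    frac = area / mask.size
    x1 = min(int(frac * n1), n1 - 1)
    if area == 0:
        x2 = 0
        x3 = 0
    else:
        from skimage.measure import perimeter as _perim

        p = float(_perim(mask, neighborhood=4))
        compact = 4.0 * np.pi * area / p**2 if p > 0 else 1.0
        x2 = min(int(np.clip(compact, 0.0, 1.0) * n2), n2 - 1)
        _, n_obj = ndimage.label(mask)
        x3 = min(n_obj, n3 - 1)
    r, c = tile_offset
    h, w = image_shape
    cy = r + mask.shape[0] / 2.0
    cx = c + mask.shape[1] / 2.0
    quadrant = (2 if cy >= h / 2.0 else 0) + (1 if cx >= w / 2.0 else 0)
    x4 = quadrant * n4 // 4
    return (x1, x2, x3, x4)


def reward(d_after: float, d_before: float, r1: float = 1.0, r2: float = -1.0) -> float:
    """R1 on strict improvement of the dissimilarity, R2 otherwise."""
    return r1 if d_after < d_before else r2


# -- the strategy table ------------------------------------------------------

class QTable:
    """Strategy table: discretized state → value of each (threshold, radius).

    Actions are flat indices t_idx * n_radii + r_idx.  Stored dense so the
    greedy argmax is a single vector op.
    """

    def __init__(self, mode: int, n_thresholds: int, radii: tuple[int, ...]):
        self.mode = mode
        self.n_thresholds = n_thresholds
        self.radii = tuple(radii)
        self.n_actions = n_thresholds * len(radii)
        self.q = np.zeros(MODE_BINS[mode] + (self.n_actions,))

    def action(self, flat: int) -> tuple[int, int]:
        return divmod(flat, len(self.radii))

    def update(self, s, a: int, r: float, s_next, lr: float, discount: float,
               terminal: bool = False) -> None:
        """One-step Q-learning: Q(s,a) += lr (r + γ max_a' Q(s',a') − Q(s,a))."""
        target = r if terminal else r + discount * float(np.max(self.q[s_next]))
        self.q[s][a] += lr * (target - self.q[s][a])

    def greedy(self, s) -> int:
        return int(np.argmax(self.q[s]))

    def to_json(self) -> str:
        entries = {}
        nz = np.nonzero(self.q)
        for idx in zip(*nz):
            state_key = ",".join(map(str, idx[:-1]))
            t_idx, r_idx = self.action(int(idx[-1]))
            entries.setdefault(state_key, {})[f"{t_idx},{self.radii[r_idx]}"] = float(
                self.q[idx])
        return json.dumps({
            "mode": self.mode, "n_thresholds": self.n_thresholds,
            "radii": list(self.radii), "values": entries,
        })

    @classmethod
    def from_json(cls, text: str) -> "QTable":
        data = json.loads(text)
        qt = cls(data["mode"], data["n_thresholds"], tuple(data["radii"]))
        radius_pos = {r: i for i, r in enumerate(qt.radii)}
        for state_key, actions in data["values"].items():
            s = tuple(int(v) for v in state_key.split(","))
            for action_key, val in actions.items():
                t_idx, radius = (int(v) for v in action_key.split(","))
                qt.q[s][t_idx * len(qt.radii) + radius_pos[radius]] = val
        return qt


# -- agent competition for sub-image dimensions ------------------------------

@dataclass
class AgentRecord:
    agent_id: int
    dims: tuple[int, int]
    history: list = field(default_factory=list)  # dissimilarity per sub-image
    alive: bool = True


def control_agent_filter(agents: list[AgentRecord], k: int,
                         end_of_pass: bool = False) -> list[AgentRecord]:
    """Kill rule of the controlling agent.

    An agent dies when its dissimilarity strictly increased over three
    consecutive sub-images; at the end of a pass the live agent with the
    maximal current dissimilarity also dies (ties → lowest id).  The last
    live agent is never killed.
    """
    if not agents:
        raise ValueError("empty agent list")
    live = [a for a in agents if a.alive]
    for a in live:
        if len([x for x in agents if x.alive]) <= 1:
            break
        h = a.history
        if len(h) >= 3 and h[-1] > h[-2] > h[-3]:
            a.alive = False
    live = [a for a in agents if a.alive]
    if end_of_pass and len(live) > 1:
        worst = max(live, key=lambda a: (a.history[-1], -a.agent_id))
        worst.alive = False
    return agents


# -- training ----------------------------------------------------------------

def _subimage_stream(pairs, dims, filter_radius):
    """Yield (tile, manual tile, offset, image shape) across all pairs."""
    out = []
    for img, manual in pairs:
        smoothed = smooth_image(img, filter_radius)
        grid = split_into_subimages(smoothed, dims)
        for k in range(len(grid)):
            out.append((grid.extract(smoothed, k),
                        grid.extract(np.asarray(manual), k),
                        grid.offsets[k], grid.image_shape))
    return out


def _run_episode(qtable: QTable, tile, manual, offset, shape, config,
                 rng, eps: float) -> float:
    """One training episode on one sub-image; returns the final dissimilarity.

    Starts from the canonical full-mask action (highest threshold, no
    opening) and ends at the first action that fails to strictly improve.
    """
    taus = threshold_grid(tile, config.n_thresholds)
    n_r = len(config.radii)
    start = (config.n_thresholds - 1) * n_r
    t_idx, r_idx = qtable.action(start)
    mask = apply_action(tile, taus[t_idx], config.radii[r_idx])
    d = dissimilarity(mask, manual)
    s = compute_state(mask, offset, shape, config.mode)
    for _ in range(config.max_steps):
        if rng.random() < eps:
            a = int(rng.integers(qtable.n_actions))
        else:
            a = qtable.greedy(s)
        t_idx, r_idx = qtable.action(a)
        mask2 = apply_action(tile, taus[t_idx], config.radii[r_idx])
        d2 = dissimilarity(mask2, manual)
        s2 = compute_state(mask2, offset, shape, config.mode)
        improved = d2 < d
        r = config.reward_improve if improved else config.reward_other
        qtable.update(s, a, r, s2, config.lr, config.discount,
                      terminal=not improved)
        if not improved:
            break
        s, d, mask = s2, d2, mask2
    return d


def greedy_rollout(qtable: QTable, tile, offset, shape, config) -> np.ndarray:
    """Greedy segmentation of one sub-image using the learned stopping rule.

    Follows argmax actions while their value is positive (the table predicts
    an improvement); stops at a non-positive value or a mask fixed point.
    """
    taus = threshold_grid(tile, config.n_thresholds)
    start = (config.n_thresholds - 1) * len(config.radii)
    t_idx, r_idx = qtable.action(start)
    mask = apply_action(tile, taus[t_idx], config.radii[r_idx])
    s = compute_state(mask, offset, shape, config.mode)
    for _ in range(config.max_steps):
        a = qtable.greedy(s)
        if qtable.q[s][a] <= 0:
            break
        t_idx, r_idx = qtable.action(a)
        mask2 = apply_action(tile, taus[t_idx], config.radii[r_idx])
        if np.array_equal(mask2, mask):
            break
        mask = mask2
        s = compute_state(mask, offset, shape, config.mode)
    return mask


def _epsilon(ep: int, total: int, config: SegmenterConfig) -> float:
    if total <= 1:
        return config.eps_end
    frac = ep / (total - 1)
    return config.eps_start + frac * (config.eps_end - config.eps_start)


def _train_qtable(stream, config: SegmenterConfig, rng, episodes: int) -> QTable:
    """Q-learning over the sub-image stream for ``episodes`` passes."""
    qt = QTable(config.mode, config.n_thresholds, config.radii)
    for ep in range(episodes):
        eps = _epsilon(ep, episodes, config)
        for tile, manual, offset, shape in stream:
            _run_episode(qt, tile, manual, offset, shape, config, rng, eps)
    return qt


def default_candidate_dims(image_shape: tuple[int, int]) -> tuple[tuple[int, int], ...]:
    """Square tilings 16/32/64 clipped to the image size, deduplicated."""
    h, w = image_shape
    dims = []
    for s in (16, 32, 64):
        d = (min(s, h), min(s, w))
        if d not in dims:
            dims.append(d)
    return tuple(dims)


def select_subimage_dims(pairs, candidate_dims, config: SegmenterConfig,
                         rng=None) -> tuple[int, int]:
    """Multi-agent competition over candidate tilings; survivor's dims win.

    Each candidate is an agent training its own strategy table over the
    sub-image stream; the control agent prunes per the kill rule.  If
    several agents survive all passes, the lowest-mean-dissimilarity one
    wins.
    """
    if not candidate_dims:
        raise ValueError("need at least one candidate dimension")
    if len(candidate_dims) == 1:
        return tuple(candidate_dims[0])
    rng = rng or np.random.default_rng(config.seed)
    agents = [AgentRecord(i, tuple(d)) for i, d in enumerate(candidate_dims)]
    # per-agent stream grouped by source image so the control agent compares
    # agents at aligned points (tilings differ in sub-image count)
    grouped = {a.agent_id: [_subimage_stream([pair], a.dims, config.filter_radius)
                            for pair in pairs] for a in agents}
    tables = {a.agent_id: QTable(config.mode, config.n_thresholds, config.radii)
              for a in agents}
    n_img = len(pairs)
    for ep in range(config.dim_select_episodes):
        eps = _epsilon(ep, config.dim_select_episodes, config)
        for k in range(n_img):
            for a in agents:
                if not a.alive:
                    continue
                ds = [_run_episode(tables[a.agent_id], tile, manual, offset,
                                   shape, config, rng, eps)
                      for tile, manual, offset, shape in grouped[a.agent_id][k]]
                a.history.append(float(np.mean(ds)))
            control_agent_filter(agents, k)
        control_agent_filter(agents, n_img - 1, end_of_pass=True)
        if sum(a.alive for a in agents) == 1:
            break
    live = [a for a in agents if a.alive]
    best = min(live, key=lambda a: (float(np.mean(a.history[-n_img:])), a.agent_id))
    return best.dims


# -- the frozen model --------------------------------------------------------

@dataclass
class SegmenterModel:
    qtable: QTable
    dims: tuple[int, int]
    postproc_radius: int
    filter_radius: float
    config: SegmenterConfig

    def to_json(self) -> str:
        return json.dumps({
            "qtable": json.loads(self.qtable.to_json()),
            "dims": list(self.dims),
            "postproc_radius": self.postproc_radius,
            "filter_radius": self.filter_radius,
            "mode": self.config.mode,
            "n_thresholds": self.config.n_thresholds,
            "radii": list(self.config.radii),
            "max_steps": self.config.max_steps,
        })

    @classmethod
    def from_json(cls, text: str) -> "SegmenterModel":
        data = json.loads(text)
        qt = QTable.from_json(json.dumps(data["qtable"]))
        config = SegmenterConfig(mode=data["mode"],
                                 n_thresholds=data["n_thresholds"],
                                 radii=tuple(data["radii"]),
                                 max_steps=data["max_steps"],
                                 filter_radius=data["filter_radius"])
        return cls(qt, tuple(data["dims"]), data["postproc_radius"],
                   data["filter_radius"], config)


def _postprocess(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return mask
    se = morphology.disk(radius)
    return morphology.closing(morphology.opening(mask.astype(bool), se), se).astype(np.uint8)


def select_postproc_radius(pairs, model: "SegmenterModel",
                           candidate_radii) -> int:
    """argmin over candidate disk radii of the mean dissimilarity after
    opening-then-closing the greedy segmentations (ties → smallest)."""
    if not candidate_radii:
        raise ValueError("need at least one candidate radius")
    raw = [(segment(img, model, postprocess=False), manual) for img, manual in pairs]
    best_r, best_d = None, np.inf
    for lam in sorted(candidate_radii):
        d = float(np.mean([dissimilarity(_postprocess(m, lam), manual)
                           for m, manual in raw]))
        if d < best_d:
            best_r, best_d = lam, d
    return best_r


def train_segmenter(pairs, config: SegmenterConfig | None = None) -> SegmenterModel:
    """Full training: dimension selection, Q-learning, post-processing radius.

    ``pairs`` is a sequence of (gray image, manual {0,1} mask).
    Deterministic given ``config.seed``.
    """
    if not pairs:
        raise ValueError("empty training set")
    config = config or SegmenterConfig()
    rng = np.random.default_rng(config.seed)
    shape = np.asarray(pairs[0][0]).shape
    candidates = config.candidate_dims or default_candidate_dims(shape)
    dims = select_subimage_dims(pairs, candidates, config, rng)
    stream = _subimage_stream(pairs, dims, config.filter_radius)
    qt = _train_qtable(stream, config, rng, config.episodes)
    model = SegmenterModel(qt, dims, 0, config.filter_radius, config)
    model.postproc_radius = select_postproc_radius(pairs, model,
                                                   config.postproc_radii)
    return model


def segment(img: np.ndarray, model: SegmenterModel,
            postprocess: bool = True) -> np.ndarray:
    """Segment a new image with the frozen model.

    smooth → tile at the learned dims → greedy per-tile action → stitch →
    opening-then-closing at the learned radius.
    """
    if model.qtable is None:
        raise ValueError("untrained model")
    smoothed = smooth_image(np.asarray(img, dtype=float), model.filter_radius)
    dims = (min(model.dims[0], smoothed.shape[0]),
            min(model.dims[1], smoothed.shape[1]))
    grid = split_into_subimages(smoothed, dims)
    tiles = [greedy_rollout(model.qtable, grid.extract(smoothed, k),
                            grid.offsets[k], grid.image_shape, model.config)
             for k in range(len(grid))]
    mask = grid.stitch(tiles)
    if postprocess:
        mask = _postprocess(mask, model.postproc_radius)
    return mask.astype(np.uint8)
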