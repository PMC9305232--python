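"""Synthetic hyphal-network rasters with known ground truth.

The generator grows a population of hyphal tips by a biased random walk:
each live tip advances ``step_len_px`` per iteration with a Gaussian heading
jitter, may bifurcate (branching) and may terminate when it runs into an
existing strand (an anastomosis analogue).  Growth halts when the rasterized
mask reaches ``target_coverage_frac`` or every tip has terminated.  Strands
are drawn as Bresenham lines stamped to ``strand_width_px``, keeping masks
strictly binary; optional salt (speckle) noise exercises the cleaning stage
downstream.

The module also provides exact analytic fixtures (filled square, line,
single pixel, Sierpinski carpet) whose mass fractal dimensions are known in
closed form — the oracles for the box-counting estimator.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from skimage.draw import line as _bresenham

from .images import NetworkImage

__all__ = [
    "SyntheticNetworkParams",
    "AnalyticFixture",
    "generate_network",
    "generate_gradient_series",
    "make_fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class SyntheticNetworkParams:
    """Parameters of the tip-growth network generator.

    Defaults emulate the sparse extraradical networks of the canonical
    640 x 640 px^2 regions of interest: a few percent surface coverage,
    curvilinear strands ~2 px wide, branching topology.
    """

    image_size_px: int = 640
    n_seeds: int = 12
    step_len_px: float = 4.0
    angle_jitter_rad: float = 0.25
    branch_prob: float = 0.04
    fusion_prob: float = 0.10
    strand_width_px: int = 2
    target_coverage_frac: float = 0.05
    noise_speckle_frac: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("branch_prob", "fusion_prob", "noise_speckle_frac"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.image_size_px < 64:
            raise ValueError("image_size_px must be >= 64")
        if self.strand_width_px < 1:
            raise ValueError("strand_width_px must be >= 1")
        if not 0.0 < self.target_coverage_frac < 1.0:
            raise ValueError("target_coverage_frac must be in (0, 1)")
        if self.n_seeds < 0:
            raise ValueError("n_seeds must be non-negative")
        if self.step_len_px <= 0:
            raise ValueError("step_len_px must be positive")


@dataclass(frozen=True)
class AnalyticFixture:
    """A binary raster with a known mass fractal dimension and coverage."""

    name: str
    image: np.ndarray
    true_dimension: float
    true_coverage_frac: float


def _stamp_offsets(width: int) -> np.ndarray:
    """Pixel offsets realizing a ``width``-px stroke around a 1-px line."""
    lo = -(width // 2)
    return np.array(
        [(dr, dc) for dr in range(lo, lo + width) for dc in range(lo, lo + width)],
        dtype=np.int64,
    )


class _Tip:
    __slots__ = ("r", "c", "heading")

    def __init__(self, r: float, c: float, heading: float) -> None:
        self.r, self.c, self.heading = r, c, heading


def generate_network(params: SyntheticNetworkParams) -> NetworkImage:
    """Grow one synthetic network and return it as a binary :class:`NetworkImage`.

    Ground truth is attached in ``metadata``: realized ``coverage_frac``
    (before noise), ``skeleton_length_px`` (1-px centreline pixel count),
    ``branch_count``, ``n_growth_rounds`` and a ``target_reached`` flag that
    is False when every tip terminated before the coverage target.
    The noise-free mask itself is attached as ``metadata['clean_truth']``.
    Output is a pure function of ``params`` (bit-identical across runs).
    """
    n = params.image_size_px
    rng = np.random.default_rng(params.rng_seed)
    mask = np.zeros((n, n), dtype=bool)
    skel = np.zeros((n, n), dtype=bool)
    offsets = _stamp_offsets(params.strand_width_px)
    margin = params.strand_width_px + 1

    tips = [
        _Tip(
            rng.uniform(margin, n - margin),
            rng.uniform(margin, n - margin),
            rng.uniform(0.0, 2.0 * math.pi),
        )
        for _ in range(params.n_seeds)
    ]

    target_px = params.target_coverage_frac * n * n
    branch_count = 0
    rounds = 0
    max_rounds = 20000
    covered = 0

    while tips and covered < target_px and rounds < max_rounds:
        rounds += 1
        survivors: list[_Tip] = []
        born: list[_Tip] = []
        for tip in tips:
            tip.heading += rng.normal(0.0, params.angle_jitter_rad)
            r1 = tip.r + params.step_len_px * math.sin(tip.heading)
            c1 = tip.c + params.step_len_px * math.cos(tip.heading)
            if not (margin <= r1 < n - margin and margin <= c1 < n - margin):
                continue  # tip dies at the boundary
            rr, cc = _bresenham(round(tip.r), round(tip.c), round(r1), round(c1))
            # anastomosis: meeting an existing strand (not the segment origin)
            hit = bool(skel[rr[2:], cc[2:]].any()) if rr.size > 2 else False
            skel[rr, cc] = True
            pr = np.clip(rr[:, None] + offsets[:, 0], 0, n - 1)
            pc = np.clip(cc[:, None] + offsets[:, 1], 0, n - 1)
            mask[pr, pc] = True
            tip.r, tip.c = r1, c1
            if hit and rng.random() < params.fusion_prob:
                continue  # fused into the network; tip terminates
            survivors.append(tip)
            if rng.random() < params.branch_prob:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                born.append(_Tip(r1, c1, tip.heading + sign * rng.uniform(0.4, 1.2)))
                branch_count += 1
        tips = survivors + born
        covered = int(np.count_nonzero(mask))

    coverage = covered / (n * n)
    clean_truth = mask.copy()
    if params.noise_speckle_frac > 0.0:
        k = int(round(params.noise_speckle_frac * n * n))
        flat = rng.choice(n * n, size=k, replace=False)
        mask.flat[flat] = True

    return NetworkImage(
        mask,
        provenance=f"synthetic(seed={params.rng_seed})",
        metadata={
            "params": dataclasses.asdict(params),
            "coverage_frac": coverage,
            "skeleton_length_px": int(np.count_nonzero(skel)),
            "branch_count": branch_count,
            "n_growth_rounds": rounds,
            "target_reached": covered >= target_px,
            "clean_truth": clean_truth,
        },
    )


def generate_gradient_series(
    params: SyntheticNetworkParams,
    n_locations: int,
    coverage_fracs: list[float],
) -> list[NetworkImage]:
    """Generate a barrier-to-centre series of ROI images with set coverages.

    Emulates the study design of sampling regions of interest along the axis
    from the partner-compartment barrier towards the centre of the fungal
    compartment; position labels 1..n are attached in that order.  Each
    location is grown independently (seed offset by its position index) with
    its own coverage target, so the ground-truth coverages follow
    ``coverage_fracs`` to within one growth-step increment.
    """
    if n_locations < 1:
        raise ValueError("n_locations must be >= 1")
    if len(coverage_fracs) != n_locations:
        raise ValueError("coverage_fracs must have length n_locations")
    series = []
    for i, frac in enumerate(coverage_fracs):
        p = dataclasses.replace(
            params, target_coverage_frac=float(frac), rng_seed=params.rng_seed + i
        )
        img = generate_network(p)
        img.metadata["label"] = i + 1
        img.provenance = f"synthetic-gradient(seed={params.rng_seed}, location={i + 1})"
        series.append(img)
    return series


FIXTURE_NAMES = ("filled_square", "hline", "single_pixel", "sierpinski_carpet")


def make_fixture(name: str, size_px: int) -> AnalyticFixture:
    """Build an analytic binary fixture with known dimension and coverage.

    ``filled_square`` (D=2), ``hline`` (D=1, one full 1-px row),
    ``single_pixel`` (D=0) and ``sierpinski_carpet`` (D=log8/log3,
    ``size_px`` must be a power of 3; coverage (8/9)^k at depth k).
    """
    if size_px < 1:
        raise ValueError("size_px must be positive")
    if name == "filled_square":
        img = np.ones((size_px, size_px), dtype=bool)
        return AnalyticFixture(name, img, 2.0, 1.0)
    if name == "hline":
        img = np.zeros((size_px, size_px), dtype=bool)
        img[size_px // 2, :] = True
        return AnalyticFixture(name, img, 1.0, 1.0 / size_px)
    if name == "single_pixel":
        img = np.zeros((size_px, size_px), dtype=bool)
        img[size_px // 2, size_px // 2] = True
        return AnalyticFixture(name, img, 0.0, 1.0 / size_px**2)
    if name == "sierpinski_carpet":
        depth = round(math.log(size_px, 3))
        if 3**depth != size_px:
            raise ValueError(
                f"sierpinski_carpet requires size_px a power of 3, got {size_px}"
            )
        cell = np.ones((3, 3), dtype=np.uint8)
        cell[1, 1] = 0
        img = np.ones((1, 1), dtype=np.uint8)
        for _ in range(depth):
            img = np.kron(img, cell)
        # single int/int division matches the pixel-count ratio bit-for-bit
        return AnalyticFixture(name, img.astype(bool), math.log(8) / math.log(3), 8**depth / 9**depth)
    raise ValueError(f"unknown fixture {name!r}; supported: {', '.join(FIXTURE_NAMES)}")
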