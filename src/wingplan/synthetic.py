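"""Ground-truth generators for validating the estimators and statistics.

Three families of synthetic objects:

* parametric wing planforms whose exact area is known in closed form (and
  cross-checkable by the shoelace formula on a dense boundary polygon) —
  oracles for both the folded-wing closed forms and the image pipeline;
* paired folded/spread measurement tables with controlled multiplicative
  measurement noise — emulating a specimen series measured with both
  methods;
* lambda-Brownian trait simulation on a phylogeny — known-parameter data
  for PGLS recovery tests.

All stochastic outputs are reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compare import PairedEstimates
from .estimators import (
    FoldedWingMeasurements,
    GeometryViolationError,
    PlanformModel,
    total_wing_area,
)
from .pgls import Phylogeny, lambda_transform, phylo_vcv
from .spreadwing import WingImage

__all__ = [
    "SyntheticPlanform",
    "NoiseModel",
    "make_planform",
    "shoelace_area",
    "rasterize",
    "make_paired_dataset",
    "simulate_lambda_brownian",
    "random_yule_phylogeny",
]

MAX_RASTER_PIXELS = 200_000_000  # resource guard for rasterize


def shoelace_area(vertices: np.ndarray) -> float:
    """Unsigned polygon area by the shoelace formula; vertices (n, 2)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(
        float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    )


@dataclass(frozen=True)
class SyntheticPlanform:
    """A wing planform with exact closed-form component areas.

    Geometry (cm, x along the span, leading edge straight at y = 0):
    a medial rectangle of width ``WS - 2*WL`` and depth ``S1``, flanked by
    two mirrored hand-wings of extent ``WL``.  Each hand-wing's trailing
    edge is a quarter ellipse over a fraction ``f`` of ``S1`` stacked on a
    right triangle over the remaining ``(1 - f) * S1``, so its depth at
    distance u from the hand-wing root is::

        d(u) = f*S1*sqrt(1 - (u/WL)^2) + (1 - f)*S1*(1 - u/WL)

    ``f = 0`` is the pure triangle wing, ``f = 1`` the quarter-ellipse
    wing, ``f = 2/3`` the ellipse-triangle composite.
    """

    wing_length: float
    wing_width: float
    wingspan: float
    ellipse_fraction: float
    true_hand_area: float
    true_box_area: float

    @property
    def true_total_area(self) -> float:
        return self.true_hand_area + self.true_box_area

    @property
    def model(self) -> PlanformModel:
        return PlanformModel.mixture(self.ellipse_fraction)

    @property
    def measurements(self) -> FoldedWingMeasurements:
        return FoldedWingMeasurements(
            wingspan=self.wingspan,
            wing_length=self.wing_length,
            wing_width=self.wing_width,
        )

    def depth(self, x) -> np.ndarray:
        """Trailing-edge depth below the leading edge at span position x.

        x is measured from the planform centre; the profile is symmetric.
        """
        x = np.abs(np.asarray(x, dtype=float))
        half = self.wingspan / 2.0
        x0 = half - self.wing_length  # hand-wing root
        d = np.zeros_like(x)
        inside_box = x <= x0
        d[inside_box] = self.wing_width
        hand = (~inside_box) & (x <= half)
        u = (x[hand] - x0) / self.wing_length
        f, s1 = self.ellipse_fraction, self.wing_width
        d[hand] = f * s1 * np.sqrt(np.clip(1.0 - u**2, 0.0, None)) + (
            1.0 - f
        ) * s1 * (1.0 - u)
        return d

    def outline(self, n_vertices: int = 2048) -> np.ndarray:
        """Closed boundary polygon (counter-clockwise), (n, 2) in cm."""
        half = self.wingspan / 2.0
        x_top = np.linspace(-half, half, max(4, n_vertices // 2))
        top = np.column_stack([x_top, np.zeros_like(x_top)])
        x_bot = x_top[::-1][1:-1]
        bottom = np.column_stack([x_bot, -self.depth(x_bot)])
        return np.vstack([top, bottom])


def make_planform(
    wing_length: float,
    wing_width: float,
    wingspan: float,
    ellipse_fraction: float = 1.0,
) -> SyntheticPlanform:
    """Build a planform with its exact component areas attached.

    Per-wing hand area is ``f*(pi/4)*WL*S1 + (1-f)*WL*S1/2``; both wings
    double that, reproducing the mixture estimator ``WL*S1*(f*pi/2+1-f)``
    exactly, so the generator and the estimators share one closed form.
    """
    if min(wing_length, wing_width, wingspan) <= 0:
        raise ValueError("all dimensions must be positive")
    if not 0.0 <= ellipse_fraction <= 1.0:
        raise ValueError(f"ellipse_fraction must be in [0,1], got {ellipse_fraction}")
    if wingspan < 2.0 * wing_length:
        raise GeometryViolationError(
            f"wingspan {wingspan} < 2 * wing length {wing_length}"
        )
    f = ellipse_fraction
    hand_per_wing = (
        f * math.pi / 4.0 * wing_length * wing_width
        + (1.0 - f) * 0.5 * wing_length * wing_width
    )
    return SyntheticPlanform(
        wing_length=wing_length,
        wing_width=wing_width,
        wingspan=wingspan,
        ellipse_fraction=f,
        true_hand_area=2.0 * hand_per_wing,
        true_box_area=(wingspan - 2.0 * wing_length) * wing_width,
    )


def rasterize(
    planform: SyntheticPlanform,
    px_per_cm: float,
    *,
    margin_cm: float = 1.0,
    wing_intensity: int = 30,
    background_intensity: int = 220,
):
    """Render a planform as a grayscale image plus its exact binary stencil.

    Pixels are binary (no anti-aliasing): a pixel belongs to the wing when
    its centre lies inside the outline.  Returns ``(WingImage, stencil)``
    where the stencil is the boolean mask the image was painted from, so
    segmentation tests can compare against the generator's own truth.
    The pixel-count area converges to ``true_total_area`` at rate
    O(perimeter / px_per_cm) as resolution grows.
    """
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    width_cm = planform.wingspan + 2 * margin_cm
    height_cm = planform.wing_width + 2 * margin_cm
    n_cols = int(round(width_cm * px_per_cm))
    n_rows = int(round(height_cm * px_per_cm))
    if n_rows * n_cols > MAX_RASTER_PIXELS:
        raise MemoryError(
            f"raster {n_rows}x{n_cols} exceeds the {MAX_RASTER_PIXELS}-pixel cap"
        )
    # pixel-centre coordinates, origin at planform centre / leading edge
    xs = (np.arange(n_cols) + 0.5) / px_per_cm - width_cm / 2.0
    ys = (np.arange(n_rows) + 0.5) / px_per_cm - margin_cm  # y down from leading edge
    depth = planform.depth(xs)  # per column
    stencil = (ys[:, None] > 0.0) & (ys[:, None] < depth[None, :])
    image = np.full((n_rows, n_cols), background_intensity, dtype=np.uint8)
    image[stencil] = wing_intensity
    return WingImage(image, px_per_cm), stencil


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal measurement noise with a stated CV.

    Each length measurement is multiplied by an independent log-normal
    factor with mean 1 and coefficient of variation ``measurement_cv``
    (percent).  Multiplicative noise keeps lengths positive and mimics
    proportional measurement error.
    """

    measurement_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.measurement_cv < 0:
            raise ValueError("measurement_cv must be >= 0")

    def factors(self, rng: np.random.Generator, shape) -> np.ndarray:
        cv = self.measurement_cv / 100.0
        if cv == 0:
            return np.ones(shape)
        sigma2 = math.log1p(cv * cv)
        sigma = math.sqrt(sigma2)
        return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=shape)


def make_paired_dataset(
    n_specimens: int,
    base: FoldedWingMeasurements,
    *,
    ellipse_fraction: float = 1.0,
    estimator: PlanformModel = PlanformModel.ELLIPSE,
    noise: NoiseModel = NoiseModel(),
    individual_cv: float = 5.0,
    species: str = "Synthetica exempli",
):
    """Paired spread/folded area estimates for a synthetic specimen series.

    Each specimen jitters the base (WL, S1, WS) by a log-normal individual
    factor of CV ``individual_cv`` percent (real between-specimen size
    variation, shared across the three lengths) and then perturbs each
    length independently per the ``noise`` model (measurement error).  The
    "spread" value is the true area of the specimen's planform with the
    given ``ellipse_fraction`` (computed from noise-free lengths); the
    "folded" value applies ``estimator`` to the noisy lengths.  With zero
    noise and a model-matched estimator the two agree exactly.

    Returns ``(PairedEstimates, morphometrics DataFrame)``.
    """
    if n_specimens < 2:
        raise ValueError("need at least 2 specimens")
    rng = np.random.default_rng(noise.seed)
    size_cv = individual_cv / 100.0
    if size_cv > 0:
        s2 = math.log1p(size_cv**2)
        size_factor = rng.lognormal(-s2 / 2.0, math.sqrt(s2), n_specimens)
    else:
        size_factor = np.ones(n_specimens)
    meas_factor = noise.factors(rng, (n_specimens, 3))

    rows, morpho = [], []
    for i in range(n_specimens):
        k = size_factor[i]
        true = make_planform(
            base.wing_length * k, base.wing_width * k, base.wingspan * k,
            ellipse_fraction,
        )
        wl, s1, ws = (
            base.wing_length * k * meas_factor[i, 0],
            base.wing_width * k * meas_factor[i, 1],
            base.wingspan * k * meas_factor[i, 2],
        )
        m = FoldedWingMeasurements(
            wingspan=ws, wing_length=wl, wing_width=s1,
            specimen_id=f"SYN{i:04d}", species=species,
        )
        folded = total_wing_area(estimator, m, clamp=True).total_area
        rows.append(
            {
                "id": m.specimen_id,
                "species": species,
                "value_spread": true.true_total_area,
                "value_folded": folded,
            }
        )
        morpho.append(
            {
                "specimen_id": m.specimen_id,
                "species": species,
                "wingspan": ws,
                "wing_length": wl,
                "s1": s1,
            }
        )
    pairs = PairedEstimates(pd.DataFrame(rows), quantity="area")
    return pairs, pd.DataFrame(morpho)


def random_yule_phylogeny(
    n_tips: int, seed: int = 0, *, min_tip_fraction: float = 0.05
) -> Phylogeny:
    """Random pure-birth (Yule) tree for simulation studies.

    Every terminal branch is lengthened by ``min_tip_fraction`` of the tree
    depth (the tree stays ultrametric): pure-birth simulators stopped at a
    fixed tip count can end just after a split, leaving near-zero terminal
    branches that make the tip covariance numerically singular and any GLS
    on it meaningless.
    """
    import random as _random

    import dendropy as _dendropy
    from dendropy.simulate import treesim

    taxa = _dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        taxon_namespace=taxa,
        rng=_random.Random(seed),
    )
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + min_tip_fraction * depth
    return Phylogeny(tree)


def simulate_lambda_brownian(
    tree: Phylogeny,
    lam: float,
    sigma2: float,
    root: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
):
    """Simulate tip traits under lambda-scaled Brownian motion.

    Draws from a multivariate normal with mean ``root`` and covariance
    ``sigma2 * lambda_transform(V, lam)`` where V is the Brownian tip
    covariance of the tree.  Returns a DataFrame with one column per tip
    (in tree tip order) and ``n_replicates`` rows.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0,1], got {lam}")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    V, labels = phylo_vcv(tree)
    cov = sigma2 * lambda_transform(V, lam)
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        draws = np.full((n_replicates, len(labels)), float(root))
    else:
        try:
            L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(labels)))
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"covariance not positive definite: {exc}") from exc
        draws = root + rng.standard_normal((n_replicates, len(labels))) @ L.T
    return pd.DataFrame(draws, columns=labels)
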