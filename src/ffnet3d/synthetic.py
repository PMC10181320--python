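"""Procedural generation of labeled plant-like point clouds.

The generator emulates the geometry that makes organ segmentation of real
daily plant scans hard: a dominant planar ground patch, a thin near-vertical
stem that contributes only a few percent of the points (the minority class
that drives the class-weighted loss), and several curved leaf sheets whose
drooping tips approach the stem radius scale.  Growth series scale organ
sizes and point counts multiplicatively, mimicking the strongly
stage-dependent cloud sizes of daily scans.

It does not attempt photorealism: no occlusion, no sensor-specific noise
anisotropy, no per-leaf instance detail beyond the shared ``leaf`` class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import SEMANTIC_CLASSES, DatasetBundle, LabeledPointCloud

__all__ = ["PlantRecipe", "generate_plant", "generate_growth_series"]


@dataclass(frozen=True)
class PlantRecipe:
    """Parameters of one synthetic plant (lengths in arbitrary units).

    Defaults describe a young maize-like plant on a metre scale with the
    stem holding ≈5.5% of the points — the class imbalance typical of real
    organ-labeled scans.
    """

    n_points_target: int = 20000
    ground_extent: float = 0.6
    stem_height: float = 0.4
    stem_radius: float = 0.012
    n_leaves: int = 6
    leaf_length: float = 0.25
    leaf_width: float = 0.05
    droop_angle: float = 0.7       # radians the midrib bends tip-ward
    stem_fraction: float = 0.055
    noise_sd: float = 0.001
    seed: int = 0
    whorl: bool = False            # extra top leaf cluster around the stem

    def __post_init__(self):
        if not (0.0 < self.stem_fraction < 0.5):
            raise ValueError("stem_fraction must lie in (0, 0.5)")
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be ≥ 1")
        for name in ("ground_extent", "stem_height", "stem_radius",
                     "leaf_length", "leaf_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if self.n_points_target < 10:
            raise ValueError("n_points_target must be ≥ 10")


def _leaf_surface(rng: np.random.Generator, n: int, attach: np.ndarray,
                  azimuth: float, length: float, width: float,
                  droop: float, min_z: float,
                  base_offset: float = 0.0) -> np.ndarray:
    """Sample a curved leaf sheet attached at ``attach``.

    The midrib leaves the stem surface (``base_offset`` outward from the
    attachment point, so the sheet never interpenetrates the stem) at an
    upward elevation and bends down by ``droop`` along its length; the
    blade tapers toward the base the way a leaf narrows into its collar,
    and the cross-section is a shallow arc.  The whole sheet is lifted if
    the drooping tip would dip below ``min_z``.
    """
    u = rng.random(n)                       # along the midrib, 0..1
    taper = np.minimum(0.15 + 0.85 * u / 0.25, 1.0)  # basal narrowing
    v = (rng.random(n) - 0.5) * width * taper        # across the sheet
    elev0 = 0.55                            # initial elevation, radians
    theta = elev0 - droop * u
    if droop > 1e-9:
        # closed-form arc-length integrals of (cos θ(u), sin θ(u))
        horiz = (np.sin(elev0) - np.sin(theta)) / droop
        vert = (np.cos(theta) - np.cos(elev0)) / droop
    else:
        horiz = np.cos(elev0) * u
        vert = np.sin(elev0) * u
    out_dir = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
    w_dir = np.array([-np.sin(azimuth), np.cos(azimuth), 0.0])
    pts = (
        attach[None, :]
        + (base_offset + length * horiz)[:, None] * out_dir[None, :]
        + v[:, None] * w_dir[None, :]
    )
    pts[:, 2] += length * vert
    # shallow arc across the width so the sheet is not perfectly flat
    pts[:, 2] += 0.15 * width * (1.0 - (2.0 * v / width) ** 2)
    deficit = min_z - pts[:, 2].min()
    if deficit > 0:
        pts[:, 2] += deficit
    return pts


def generate_plant(recipe: PlantRecipe) -> LabeledPointCloud:
    """Deterministically sample one labeled plant cloud from a recipe.

    Organ point counts are drawn from a multinomial at the target fractions
    — ground and leaf split the non-stem mass evenly — so realized class
    shares fluctuate the way scanner point densities do.
    """
    rng = np.random.default_rng(recipe.seed)
    s = recipe.stem_fraction
    fracs = np.array([(1 - s) / 2, s, (1 - s) / 2])
    n_ground, n_stem, n_leaf = rng.multinomial(recipe.n_points_target, fracs)
    n_stem = max(int(n_stem), 1)
    n_leaf = max(int(n_leaf), recipe.n_leaves)

    # ground: uniformly jittered planar patch at z = 0
    half = recipe.ground_extent / 2
    ground = np.column_stack(
        [
            rng.uniform(-half, half, n_ground),
            rng.uniform(-half, half, n_ground),
            np.zeros(n_ground),
        ]
    )

    # stem: solid, slightly curved vertical cylinder
    h = rng.random(n_stem) * recipe.stem_height
    bow = 0.03 * recipe.stem_height
    axis_x = bow * np.sin(np.pi * h / recipe.stem_height)
    ang = rng.random(n_stem) * 2 * np.pi
    rad = recipe.stem_radius * np.sqrt(rng.random(n_stem))
    stem = np.column_stack(
        [axis_x + rad * np.cos(ang), rad * np.sin(ang), h]
    )

    # leaves: curved sheets attached at distinct stem heights
    leaf_floor = 1.5 * recipe.stem_radius
    attach_h = np.linspace(
        0.35 * recipe.stem_height, 0.95 * recipe.stem_height, recipe.n_leaves
    )
    golden = 2.399963229728653  # radians between successive leaves
    per_leaf = np.full(recipe.n_leaves, n_leaf // recipe.n_leaves)
    per_leaf[: n_leaf % recipe.n_leaves] += 1
    leaf_parts = []
    for i in range(recipe.n_leaves):
        az = golden * i + rng.uniform(-0.2, 0.2)
        attach = np.array(
            [
                bow * np.sin(np.pi * attach_h[i] / recipe.stem_height),
                0.0,
                attach_h[i],
            ]
        )
        leaf_parts.append(
            _leaf_surface(
                rng, int(per_leaf[i]), attach, az, recipe.leaf_length,
                recipe.leaf_width, recipe.droop_angle, leaf_floor,
                base_offset=recipe.stem_radius,
            )
        )
    if recipe.whorl:
        # small cluster of short leaves wrapping the stem tip ("stems
        # surrounded by leaves" failure mode)
        top = np.array([axis_x[-1] if n_stem else 0.0, 0.0,
                        0.98 * recipe.stem_height])
        for j in range(3):
            leaf_parts.append(
                _leaf_surface(
                    rng, max(per_leaf.min() // 3, 8), top,
                    golden * (recipe.n_leaves + j),
                    0.35 * recipe.leaf_length, recipe.leaf_width,
                    recipe.droop_angle * 1.3, leaf_floor,
                    base_offset=recipe.stem_radius,
                )
            )
    leaves = np.vstack(leaf_parts)

    coords = np.vstack([ground, stem, leaves])
    labels = np.concatenate(
        [
            np.zeros(len(ground), dtype=np.int64),
            np.ones(len(stem), dtype=np.int64),
            np.full(len(leaves), 2, dtype=np.int64),
        ]
    )
    if recipe.noise_sd > 0:
        coords = coords + rng.normal(0.0, recipe.noise_sd, coords.shape)
    perm = rng.permutation(len(coords))
    return LabeledPointCloud(
        coords=coords[perm],
        labels=labels[perm],
        class_names=list(SEMANTIC_CLASSES),
        plant_id=f"synthetic-{recipe.seed}",
        day=0,
        source="synthetic",
    )


def generate_growth_series(
    base: PlantRecipe,
    n_days: int,
    growth_rate: float,
    plant_id: str | None = None,
    split: str = "train",
) -> DatasetBundle:
    """A daily series for one plant: day *t* scales stem height, leaf length
    and the point budget by ``(1 + growth_rate)^t``."""
    if n_days < 1:
        raise ValueError("n_days must be ≥ 1")
    if growth_rate < 0:
        raise ValueError("growth_rate must be ≥ 0")
    pid = plant_id or f"synthetic-{base.seed}"
    clouds = []
    for t in range(n_days):
        scale = (1.0 + growth_rate) ** t
        recipe = replace(
            base,
            stem_height=base.stem_height * scale,
            leaf_length=base.leaf_length * scale,
            n_points_target=int(round(base.n_points_target * scale)),
            seed=int((base.seed + 99991 * t) % (2**31)),
        )
        cloud = generate_plant(recipe)
        cloud.plant_id = pid
        cloud.day = t
        clouds.append(cloud)
    return DatasetBundle(
        clouds=clouds,
        split={pid: split},
        provenance=f"synthetic growth series (rate={growth_rate})",
    )
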