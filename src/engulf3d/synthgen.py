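"""Synthetic fluorescence volumes and factorial cohorts with known truth.

Every downstream stage of the pipeline (segmentation, overlap metrics,
counting, statistics) is validated against volumes generated here, where the
true masks, the true engulfed fraction and the true group effects are known
by construction.

A section emulates the structure of the real assay: branched microglia-like
cells (soma spheres plus dilated random-walk branches) rendered into an
``iba1`` channel; lysosomal sub-compartments strictly inside the somata
(``cd68``); and a dense field of synaptic-scale puncta (``marker``) of which
a controlled fraction is centred inside the lysosome-in-cell compartment.
Rendering applies a Gaussian PSF, Poisson shot noise, a constant background
and Gaussian read noise — the standard microscopy forward model.

Geometry is constructed on the voxel lattice with physical (micrometre)
distances, and containment is guaranteed, not merely probable:

* lysosome centres lie within ``r_soma - r_lyso - margin`` of a soma centre,
  with ``margin >= puncta_radius``, so no punctum placed outside the cell can
  ever reach a lysosome;
* engulfed puncta centres lie within ``r_lyso - r_punctum`` of a lysosome
  centre, so an engulfed punctum is wholly inside the lysosome mask.

Consequently a requested engulfed fraction of 0 or 1 is realised *exactly*
on the true masks, and intermediate fractions are binomial in the number of
puncta.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawning (one child per animal, one
grandchild per section), so cohorts are extensible without disturbing
earlier draws and identical seeds give bit-identical stacks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imgio import ChannelStack, SectionRecord, VoxelSize

__all__ = [
    "CellModelParams",
    "PunctaFieldParams",
    "OpticsParams",
    "GroundTruth",
    "CohortDesign",
    "make_section",
    "make_cohort",
    "make_apoptosis_sections",
    "in_hemisection",
    "voxel_to_uv",
]

#: Default acquisition geometry for synthetic sections: the 20x preset.
DEFAULT_VOXEL = VoxelSize(dx=0.3, dy=0.3, dz=0.67)
DEFAULT_SHAPE = (24, 128, 128)


@dataclass(frozen=True)
class CellModelParams:
    """Morphology of the simulated microglia-like cells.

    Two-tuples are uniform sampling ranges (micrometres where applicable).
    ``lysosome_margin_um`` is the minimum distance from a lysosome surface to
    the soma surface; it is raised to the puncta radius at generation time so
    extracellular puncta can never overlap a lysosome.
    """

    n_cells: int = 2
    soma_radius_um: tuple[float, float] = (2.8, 3.6)
    n_branches: tuple[int, int] = (3, 5)
    branch_length_um: tuple[float, float] = (8.0, 14.0)
    branch_radius_um: tuple[float, float] = (0.6, 0.9)
    lysosome_count: tuple[int, int] = (4, 7)
    lysosome_radius_um: tuple[float, float] = (1.2, 1.8)
    lysosome_margin_um: float = 0.8

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in (
            "soma_radius_um",
            "branch_length_um",
            "branch_radius_um",
            "lysosome_radius_um",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range {lo, hi} invalid")


@dataclass(frozen=True)
class PunctaFieldParams:
    """Density field of synaptic-scale puncta.

    ``puncta_density`` is puncta per 1000 um^3 of imaged volume;
    ``engulfed_fraction`` is the probability that a punctum is placed inside
    the lysosome-in-cell compartment — the ground truth for "% engulfed".
    """

    puncta_density: float = 25.0
    puncta_radius_um: float = 0.5
    engulfed_fraction: float = 0.04

    def __post_init__(self) -> None:
        if not 0 <= self.engulfed_fraction <= 1:
            raise ValueError("engulfed_fraction must lie in [0, 1]")
        if self.puncta_density < 0:
            raise ValueError("puncta_density must be non-negative")
        if self.puncta_radius_um <= 0:
            raise ValueError("puncta_radius_um must be positive")


@dataclass(frozen=True)
class OpticsParams:
    """Forward optical model: Gaussian PSF + Poisson/Gaussian noise.

    ``psf_sigma_um`` is the PSF standard deviation per axis (z, y, x);
    ``photon_scale`` the mean photon count at unit structure intensity;
    ``background_level`` a constant photon background; ``read_noise_sd`` an
    additive Gaussian noise floor (counts).
    """

    psf_sigma_um: tuple[float, float, float] = (0.5, 0.15, 0.15)
    photon_scale: float = 200.0
    read_noise_sd: float = 2.0
    background_level: float = 10.0

    def __post_init__(self) -> None:
        if min(self.psf_sigma_um) < 0 or min(
            self.photon_scale, self.read_noise_sd, self.background_level
        ) < 0:
            raise ValueError("optics parameters must be non-negative")


@dataclass
class GroundTruth:
    """Latent truth of a synthetic section — the oracle for recovery tests.

    ``true_engulfed_fraction`` always equals
    ``(marker & lysosome).sum() / marker.sum()`` computed on the true masks
    (0 when the marker mask is empty).  ``centroids`` is populated for
    apoptosis sections (cell centres, voxel units, plus normalised (u, v)).
    """

    cell_mask: np.ndarray | None
    lysosome_mask: np.ndarray | None
    marker_mask: np.ndarray | None
    true_engulfed_fraction: float
    centroids: list[tuple[float, float, float]] | None = None
    centroids_uv: list[tuple[float, float]] | None = None
    clipped: bool = False

    def verify(self) -> None:
        """Re-derive the engulfed fraction from the masks (consistency)."""
        if self.marker_mask is None or self.lysosome_mask is None:
            return
        m = int(self.marker_mask.sum())
        ov = int((self.marker_mask & self.lysosome_mask).sum())
        frac = ov / m if m else 0.0
        if frac != self.true_engulfed_fraction:
            raise AssertionError(
                f"ground truth inconsistent: stored {self.true_engulfed_fraction}"
                f" recomputed {frac}"
            )


# ---------------------------------------------------------------------------
# lattice geometry helpers


def _ellipsoid_offsets(radius_um: float, voxel: VoxelSize) -> np.ndarray:
    """Voxel offsets (k, 3) whose centres lie within radius_um (anisotropic)."""
    rz = int(math.floor(radius_um / voxel.dz))
    ry = int(math.floor(radius_um / voxel.dy))
    rx = int(math.floor(radius_um / voxel.dx))
    zz, yy, xx = np.mgrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    d2 = (
        (zz * voxel.dz) ** 2 + (yy * voxel.dy) ** 2 + (xx * voxel.dx) ** 2
    )
    keep = d2 <= radius_um**2 + 1e-12
    return np.stack([zz[keep], yy[keep], xx[keep]], axis=1)


def _paint(mask: np.ndarray, centres: np.ndarray, offsets: np.ndarray) -> None:
    """Set mask voxels covered by offsets around each centre (in place)."""
    if len(centres) == 0:
        return
    centres = np.atleast_2d(np.asarray(centres, dtype=np.int64))
    coords = centres[:, None, :] + offsets[None, :, :]
    coords = coords.reshape(-1, 3)
    ok = np.all((coords >= 0) & (coords < np.array(mask.shape)), axis=1)
    coords = coords[ok]
    mask[coords[:, 0], coords[:, 1], coords[:, 2]] = True


def _lattice_ball_voxels(
    centre: np.ndarray, radius_um: float, voxel: VoxelSize, shape
) -> np.ndarray:
    """In-bounds voxels within radius_um of a lattice centre, as (k, 3)."""
    offs = _ellipsoid_offsets(radius_um, voxel)
    coords = np.asarray(centre, dtype=np.int64)[None, :] + offs
    ok = np.all((coords >= 0) & (coords < np.array(shape)), axis=1)
    return coords[ok]


def render_channel(
    mask: np.ndarray,
    optics: OpticsParams,
    voxel: VoxelSize,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render a binary structure into a noisy uint16 fluorescence image."""
    img = mask.astype(np.float32)
    sig = [s / d for s, d in zip(optics.psf_sigma_um, voxel.zyx)]
    if any(s > 0 for s in sig):
        img = gaussian_filter(img, sigma=sig)
    lam = img * optics.photon_scale + optics.background_level
    counts = rng.poisson(lam).astype(np.float32)
    if optics.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, optics.read_noise_sd, counts.shape)
    return np.clip(np.rint(counts), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# single-section generator


def _uniform(rng: np.random.Generator, rng_pair: tuple[float, float]) -> float:
    lo, hi = rng_pair
    return float(rng.uniform(lo, hi))


def _uniform_int(rng: np.random.Generator, rng_pair: tuple[int, int]) -> int:
    lo, hi = rng_pair
    return int(rng.integers(lo, hi + 1))


def _build_cells(
    cell_params: CellModelParams,
    margin_um: float,
    voxel: VoxelSize,
    shape: tuple[int, int, int],
    rng: np.random.Generator,
    max_tries: int = 50,
):
    """Paint cell + lysosome masks; return (cell, lyso, lysosome list)."""
    cell = np.zeros(shape, dtype=bool)
    lyso = np.zeros(shape, dtype=bool)
    lysosomes: list[tuple[np.ndarray, float]] = []  # (centre voxel, radius)
    dims_um = np.array(shape) * np.array(voxel.zyx)
    step_um = min(voxel.zyx)

    for _ in range(cell_params.n_cells):
        r_soma = _uniform(rng, cell_params.soma_radius_um)
        # soma fully inside xy, as deep as z allows
        lo = np.array(
            [
                min(r_soma, dims_um[0] / 2),
                min(r_soma, dims_um[1] / 2),
                min(r_soma, dims_um[2] / 2),
            ]
        )
        centre_um = rng.uniform(lo, np.maximum(dims_um - lo, lo))
        centre = np.rint(centre_um / np.array(voxel.zyx)).astype(np.int64)
        centre = np.clip(centre, 0, np.array(shape) - 1)
        _paint(cell, centre[None, :], _ellipsoid_offsets(r_soma, voxel))

        # branches: jittered random walks from the soma centre, dilated
        n_br = _uniform_int(rng, cell_params.n_branches)
        r_br = _uniform(rng, cell_params.branch_radius_um)
        br_offs = _ellipsoid_offsets(r_br, voxel)
        skel: list[np.ndarray] = []
        for _b in range(n_br):
            length = _uniform(rng, cell_params.branch_length_um)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            pos = centre_um.copy()
            for _s in range(int(length / step_um)):
                pos = pos + d * step_um
                d = d + rng.normal(0.0, 0.25, size=3)
                d /= np.linalg.norm(d)
                vox = np.rint(pos / np.array(voxel.zyx)).astype(np.int64)
                if np.all(vox >= 0) and np.all(vox < np.array(shape)):
                    skel.append(vox)
        if skel:
            _paint(cell, np.array(skel), br_offs)

        # lysosomes strictly inside the soma with a protective margin
        n_ly = _uniform_int(rng, cell_params.lysosome_count)
        for _l in range(n_ly):
            r_ly = _uniform(rng, cell_params.lysosome_radius_um)
            reach = r_soma - r_ly - margin_um
            if reach < 0:
                raise ValueError(
                    f"lysosome of radius {r_ly:.2f} um (+ margin {margin_um:.2f})"
                    f" cannot fit inside soma of radius {r_soma:.2f} um"
                )
            placed = False
            for _t in range(max_tries):
                cand = _lattice_ball_voxels(centre, reach, voxel, shape)
                if len(cand) == 0:
                    break
                ly_centre = cand[rng.integers(len(cand))]
                lysosomes.append((ly_centre, r_ly))
                _paint(lyso, ly_centre[None, :], _ellipsoid_offsets(r_ly, voxel))
                placed = True
                break
            if not placed:
                raise ValueError(
                    "could not place lysosome inside cell after bounded retries"
                )
    return cell, lyso, lysosomes


def make_section(
    cell_params: CellModelParams | None = None,
    puncta_params: PunctaFieldParams | None = None,
    optics: OpticsParams | None = None,
    voxel: VoxelSize = DEFAULT_VOXEL,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    seed: int | np.random.SeedSequence = 0,
    render: bool = True,
) -> tuple[ChannelStack | None, GroundTruth]:
    """Generate one synthetic 3-channel section plus its ground truth.

    Returns ``(stack, truth)``; ``stack`` is None when ``render=False``
    (mask-only generation, used by fast truth-path analyses).
    """
    cell_params = cell_params or CellModelParams()
    puncta_params = puncta_params or PunctaFieldParams()
    optics = optics or OpticsParams()
    rng = np.random.default_rng(seed)

    margin = max(cell_params.lysosome_margin_um, puncta_params.puncta_radius_um)
    cell, lyso, lysosomes = _build_cells(cell_params, margin, voxel, shape, rng)

    # --- puncta field -----------------------------------------------------
    total_vol = float(np.prod(shape)) * voxel.volume_um3
    n_puncta = int(rng.poisson(puncta_params.puncta_density * total_vol / 1000.0))
    n_eng = int(rng.binomial(n_puncta, puncta_params.engulfed_fraction))
    marker = np.zeros(shape, dtype=bool)
    p_offs = _ellipsoid_offsets(puncta_params.puncta_radius_um, voxel)

    if n_eng > 0:
        if not lysosomes:
            raise ValueError("engulfed puncta requested but no lysosomes exist")
        # candidate centres per lysosome: within r_lyso - r_punctum
        cands = []
        for ly_centre, r_ly in lysosomes:
            reach = r_ly - puncta_params.puncta_radius_um
            if reach < 0:
                continue
            cands.append(_lattice_ball_voxels(ly_centre, reach, voxel, shape))
        if not cands:
            raise ValueError(
                "puncta radius exceeds every lysosome radius; cannot engulf"
            )
        pool = np.concatenate(cands, axis=0)
        # greedy minimum-distance selection: engulfed puncta crowd into
        # small lysosome cores, and mutual overlap would erode the realised
        # voxel fraction below the requested one
        order = rng.permutation(len(pool))
        min_d2 = (2 * puncta_params.puncta_radius_um) ** 2
        scale = np.array(voxel.zyx)
        chosen: list[np.ndarray] = []
        for j in order:
            c = pool[j]
            if chosen:
                d2 = (((np.array(chosen) - c) * scale) ** 2).sum(axis=1)
                if d2.min() < min_d2:
                    continue
            chosen.append(c)
            if len(chosen) == n_eng:
                break
        if len(chosen) < n_eng:  # pool exhausted: accept overlaps for the rest
            extra = pool[rng.integers(len(pool), size=n_eng - len(chosen))]
            chosen.extend(extra)
        _paint(marker, np.array(chosen), p_offs)

    n_out = n_puncta - n_eng
    if n_out > 0:
        outside = np.argwhere(~cell)
        if len(outside) == 0:
            raise ValueError("no extracellular space left for puncta")
        centres = outside[rng.integers(len(outside), size=n_out)]
        _paint(marker, centres, p_offs)

    m = int(marker.sum())
    frac = float((marker & lyso).sum() / m) if m else 0.0
    truth = GroundTruth(
        cell_mask=cell,
        lysosome_mask=lyso,
        marker_mask=marker,
        true_engulfed_fraction=frac,
    )

    stack = None
    if render:
        stack = ChannelStack(
            data=np.stack(
                [
                    render_channel(cell, optics, voxel, rng),
                    render_channel(lyso, optics, voxel, rng),
                    render_channel(marker, optics, voxel, rng),
                ]
            ),
            voxel=voxel,
            channel_names=("iba1", "cd68", "marker"),
            provenance=f"synthetic seed={seed}",
        )
    return stack, truth


# ---------------------------------------------------------------------------
# factorial cohorts


@dataclass
class CohortDesign:
    """A 2 (sex) x 2 (neonatal incision) x 2 (adult incision) cohort plan.

    Group means are ``base + sum(effects for active levels)``; an active
    level is sex ``M``, neonatal ``+`` or adult ``+``.  Animal values add a
    Normal(0, between_animal_sd) effect, section values a
    Normal(0, within_animal_sd) jitter; engulfed fractions are clipped to
    [0, 1] with a flag.  Restrict a factor to one level (e.g.
    ``adult_levels=("-",)``) to obtain a 2x2 design.
    """

    n_per_group: int = 4
    sections_per_animal: int = 6
    sexes: tuple[str, ...] = ("F", "M")
    neonatal_levels: tuple[str, ...] = ("-", "+")
    adult_levels: tuple[str, ...] = ("-",)
    base_engulfed_fraction: float = 0.04
    base_density: float = 25.0
    engulfed_effects: dict = field(default_factory=dict)  # {"sex"|"neonatal"|"adult": shift}
    density_effects: dict = field(default_factory=dict)
    cell_volume_effects: dict = field(default_factory=dict)  # relative soma-radius scale
    between_animal_sd: float = 0.008
    within_animal_sd: float = 0.004
    density_rel_sd_between: float = 0.10
    density_rel_sd_within: float = 0.05
    seed: int = 0
    voxel: VoxelSize = DEFAULT_VOXEL
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    cell_params: CellModelParams = field(default_factory=CellModelParams)
    optics: OpticsParams = field(default_factory=OpticsParams)
    puncta_radius_um: float = 0.5
    marker_kind: str = "VGAT"

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in (
            "between_animal_sd",
            "within_animal_sd",
            "density_rel_sd_between",
            "density_rel_sd_within",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def groups(self) -> list[tuple[str, str, str]]:
        return list(
            itertools.product(self.sexes, self.neonatal_levels, self.adult_levels)
        )

    def _shift(self, effects: dict, sex: str, neo: str, adult: str) -> float:
        s = 0.0
        if sex == "M":
            s += effects.get("sex", 0.0)
        if neo == "+":
            s += effects.get("neonatal", 0.0)
        if adult == "+":
            s += effects.get("adult", 0.0)
        return s


def make_cohort(
    design: CohortDesign, render: bool = False
) -> tuple[list[SectionRecord], pd.DataFrame]:
    """Generate a full factorial cohort and its latent truth table.

    Returns ``(sections, truth)`` where ``truth`` holds one row per animal
    with its factor levels and latent true values.  With ``render=False``
    each section carries only a :class:`GroundTruth` whose
    ``true_engulfed_fraction`` is the latent section-level value (no image
    data) — the fast path for statistical simulations.
    """
    root = np.random.SeedSequence(design.seed)
    groups = design.groups()
    animal_seeds = root.spawn(len(groups) * design.n_per_group)

    sections: list[SectionRecord] = []
    rows = []
    k = 0
    for sex, neo, adult in groups:
        g_engulf = design.base_engulfed_fraction + design._shift(
            design.engulfed_effects, sex, neo, adult
        )
        g_dens = design.base_density * (
            1.0 + design._shift(design.density_effects, sex, neo, adult)
        )
        g_cellscale = 1.0 + design._shift(
            design.cell_volume_effects, sex, neo, adult
        )
        for i in range(design.n_per_group):
            aseed = animal_seeds[k]
            k += 1
            animal_id = f"an{k:03d}_{sex}{neo}{adult}"
            arng = np.random.default_rng(aseed)
            a_engulf = g_engulf + arng.normal(0.0, design.between_animal_sd)
            a_dens = g_dens * (
                1.0 + arng.normal(0.0, design.density_rel_sd_between)
            )
            clipped = not (0.0 <= a_engulf <= 1.0)
            a_engulf = float(np.clip(a_engulf, 0.0, 1.0))
            a_dens = max(a_dens, 0.0)

            sec_seeds = aseed.spawn(design.sections_per_animal)
            sec_fracs = []
            for s_idx, sseed in enumerate(sec_seeds):
                srng = np.random.default_rng(sseed)
                s_engulf = a_engulf + srng.normal(0.0, design.within_animal_sd)
                s_clip = not (0.0 <= s_engulf <= 1.0)
                s_engulf = float(np.clip(s_engulf, 0.0, 1.0))
                s_dens = max(
                    a_dens
                    * (1.0 + srng.normal(0.0, design.density_rel_sd_within)),
                    0.0,
                )
                sec_fracs.append(s_engulf)
                if render:
                    soma_lo, soma_hi = design.cell_params.soma_radius_um
                    cp = CellModelParams(
                        n_cells=design.cell_params.n_cells,
                        soma_radius_um=(
                            soma_lo * g_cellscale,
                            soma_hi * g_cellscale,
                        ),
                        n_branches=design.cell_params.n_branches,
                        branch_length_um=design.cell_params.branch_length_um,
                        branch_radius_um=design.cell_params.branch_radius_um,
                        lysosome_count=design.cell_params.lysosome_count,
                        lysosome_radius_um=design.cell_params.lysosome_radius_um,
                        lysosome_margin_um=design.cell_params.lysosome_margin_um,
                    )
                    pp = PunctaFieldParams(
                        puncta_density=s_dens,
                        puncta_radius_um=design.puncta_radius_um,
                        engulfed_fraction=s_engulf,
                    )
                    stack, truth = make_section(
                        cp,
                        pp,
                        design.optics,
                        design.voxel,
                        design.shape,
                        seed=sseed,
                        render=True,
                    )
                    truth.clipped = s_clip or clipped
                else:
                    stack = None
                    truth = GroundTruth(
                        cell_mask=None,
                        lysosome_mask=None,
                        marker_mask=None,
                        true_engulfed_fraction=s_engulf,
                        clipped=s_clip or clipped,
                    )
                sections.append(
                    SectionRecord(
                        animal_id=animal_id,
                        section_index=s_idx,
                        stack=stack,
                        marker_kind=design.marker_kind,
                        ground_truth=truth,
                    )
                )
            rows.append(
                {
                    "animal_id": animal_id,
                    "sex": sex,
                    "neonatal_incision": neo,
                    "adult_incision": adult,
                    "true_engulfed_fraction": a_engulf,
                    "true_section_mean_fraction": float(np.mean(sec_fracs)),
                    "true_density": a_dens,
                    "clipped": clipped,
                }
            )
    return sections, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# apoptosis sections: Poisson counts on a hemisection template


def in_hemisection(u: float, v: float) -> bool:
    """Membership in the unit half-ellipse hemisection template.

    The flat medial edge lies at u=0; the template is
    ``{(u, v): 0 <= u, u^2 + (2 v - 1)^2 <= 1}``.
    """
    return 0.0 <= u and u * u + (2.0 * v - 1.0) ** 2 <= 1.0


def voxel_to_uv(
    centroid_zyx: Sequence[float], shape: Sequence[int]
) -> tuple[float, float]:
    """Map a voxel-space centroid to normalised hemisection (u, v)."""
    _, ny, nx = shape[-3:]
    z, y, x = centroid_zyx
    return (x / max(nx - 1, 1), y / max(ny - 1, 1))


def _sample_uv(
    hotspots: Sequence[tuple[tuple[float, float], float]] | None,
    hotspot_sigma: float,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> tuple[float, float]:
    if hotspots:
        weights = np.array([w for _, w in hotspots], dtype=float)
        weights /= weights.sum()
        idx = rng.choice(len(hotspots), p=weights)
        cu, cv = hotspots[idx][0]
        for _ in range(max_tries):
            u = cu + rng.normal(0.0, hotspot_sigma)
            v = cv + rng.normal(0.0, hotspot_sigma)
            if in_hemisection(u, v):
                return (u, v)
        return (cu, cv)
    for _ in range(max_tries):
        u, v = rng.uniform(0, 1), rng.uniform(0, 1)
        if in_hemisection(u, v):
            return (u, v)
    return (0.5, 0.5)


def make_apoptosis_sections(
    rate_per_section_control: float = 0.2,
    rate_incision: float = 0.43,
    n_animals: int = 8,
    sections: int = 8,
    hemisection_hotspots: Sequence[tuple[tuple[float, float], float]] | None = None,
    seed: int = 0,
    shape: tuple[int, int, int] = (6, 128, 128),
    voxel: VoxelSize = DEFAULT_VOXEL,
    cell_radius_um: float = 2.0,
    hotspot_sigma: float = 0.06,
    optics: OpticsParams | None = None,
    render: bool = True,
) -> tuple[list[SectionRecord], pd.DataFrame]:
    """Generate caspase-3 sections with Poisson cell counts and hotspots.

    Per-section counts are Poisson with the group rate (``control`` vs
    ``incision``, ``n_animals`` per group); cell locations follow a mixture
    of Gaussian kernels at ``hemisection_hotspots`` (``((u, v), weight)``),
    or are uniform on the template when none are given.  Returns the section
    records (single ``caspase3`` channel when rendered) and a manifest of
    animal ids, groups and true counts.
    """
    if min(rate_per_section_control, rate_incision) < 0:
        raise ValueError("rates must be non-negative")
    optics = optics or OpticsParams()
    root = np.random.SeedSequence(seed)
    animal_seeds = root.spawn(2 * n_animals)

    records: list[SectionRecord] = []
    rows = []
    nz, ny, nx = shape
    for g_idx, (group, rate) in enumerate(
        [("control", rate_per_section_control), ("incision", rate_incision)]
    ):
        for a in range(n_animals):
            aseed = animal_seeds[g_idx * n_animals + a]
            animal_id = f"{group[:3]}{a + 1:02d}"
            total = 0
            for s_idx, sseed in enumerate(aseed.spawn(sections)):
                rng = np.random.default_rng(sseed)
                count = int(rng.poisson(rate))
                total += count
                cents, uvs = [], []
                mask = np.zeros(shape, dtype=bool)
                for _c in range(count):
                    u, v = _sample_uv(hemisection_hotspots, hotspot_sigma, rng)
                    x = u * (nx - 1)
                    y = v * (ny - 1)
                    # keep cells in the central z third: counting emulates a
                    # widefield image, and edge-clipped somata would fall
                    # below any sane volume filter
                    z = rng.uniform(nz / 3, 2 * nz / 3)
                    cents.append((z, y, x))
                    uvs.append((u, v))
                if count and render:
                    vox = np.rint(np.array(cents)).astype(np.int64)
                    _paint(mask, vox, _ellipsoid_offsets(cell_radius_um, voxel))
                truth = GroundTruth(
                    cell_mask=None,
                    lysosome_mask=None,
                    marker_mask=None,
                    true_engulfed_fraction=0.0,
                    centroids=cents,
                    centroids_uv=uvs,
                )
                stack = None
                if render:
                    stack = ChannelStack(
                        data=render_channel(mask, optics, voxel, rng)[None],
                        voxel=voxel,
                        channel_names=("caspase3",),
                        provenance=f"synthetic apoptosis {animal_id} s{s_idx}",
                    )
                records.append(
                    SectionRecord(
                        animal_id=animal_id,
                        section_index=s_idx,
                        stack=stack,
                        marker_kind="CASPASE3",
                        ground_truth=truth,
                    )
                )
            rows.append(
                {
                    "animal_id": animal_id,
                    "group": group,
                    "rate": rate,
                    "n_sections": sections,
                    "true_total_cells": total,
                }
            )
    return records, pd.DataFrame(rows)
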