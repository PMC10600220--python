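"""Synthetic rod-nucleus images with known heterochromatin organization.

Each nucleus is a bright disk on a dark background.  The heterochromatin
intensity excess (above euchromatin) is split between a peripheral shell
(weight ``tether_strength``) and interior chromocenters (weight
``1 - tether_strength``), so that ``tether_strength = 0`` produces a fully
inverted nucleus (bright central chromocenters, dim margin) and
``tether_strength = 1`` a conventionally tethered one (bright peripheral
ring).  Chromocenter radial position likewise interpolates from the
nuclear center toward the periphery as tethering increases.

Ground truth (noiseless margin ratio, chromocenter centroids, organization
label) is recorded so downstream morphometry can be validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..morphometry import NucleusImage

BACKGROUND_INTENSITY = 10.0
EUCHROMATIN_INTENSITY = 60.0


@dataclass
class NucleusSpec:
    radius_px: int = 40
    pixel_size_um: float = 0.05
    tether_strength: float = 0.0
    n_chromocenters: int = 3
    chromocenter_radius_px: int = 5
    shell_width_frac: float = 0.3
    het_eu_contrast: float = 3.0
    noise_sd: float = 4.0
    ellipticity: float = 1.0  # minor/major axis ratio; 1 = circle
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_px < 8:
            raise ValueError("radius_px must be >= 8")
        if not 0.0 <= self.tether_strength <= 1.0:
            raise ValueError("tether_strength must lie in [0, 1]")
        if self.het_eu_contrast <= 0:
            raise ValueError("het_eu_contrast must be > 0")
        if self.n_chromocenters < 0:
            raise ValueError("n_chromocenters must be >= 0")
        if not 0.0 < self.shell_width_frac < 1.0:
            raise ValueError("shell_width_frac must lie in (0, 1)")
        if not 0.0 < self.ellipticity <= 1.0:
            raise ValueError("ellipticity must lie in (0, 1]")


@dataclass
class NucleusTruth:
    chromocenter_centroids: list[tuple[float, float]]
    true_margin_ratio: float
    organization_label: str  # inverted / intermediate / conventional
    noiseless_total_intensity: float = 0.0
    analytic_total_intensity: float = 0.0
    mask: np.ndarray = field(default=None, repr=False)


def _organization_label(theta: float) -> str:
    if theta < 1.0 / 3.0:
        return "inverted"
    if theta > 2.0 / 3.0:
        return "conventional"
    return "intermediate"


def _place_chromocenters(spec: NucleusSpec, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Rejection-sample chromocenter centers inside the disk.

    Radial position interpolates with tethering: the allowed band runs out
    to (0.4 + 0.6*theta) of the deepest admissible radius, so fully
    inverted nuclei keep chromocenters within 0.4 R of the center while
    tethered nuclei push them toward the periphery.  Centers must be at
    least 2 chromocenter radii apart; placement fails after 1000 attempts.
    """
    r_max = spec.radius_px * min(1.0, spec.ellipticity) - spec.chromocenter_radius_px - 1
    if spec.n_chromocenters > 0 and r_max <= 0:
        raise ValueError("chromocenters cannot fit inside the nucleus")
    hi = (0.4 + 0.6 * spec.tether_strength) * r_max
    centers: list[tuple[float, float]] = []
    min_sep = 2.0 * spec.chromocenter_radius_px
    attempts = 0
    while len(centers) < spec.n_chromocenters:
        attempts += 1
        if attempts > 1000:
            raise ValueError("could not place chromocenters inside the disk")
        r = hi * np.sqrt(rng.uniform())  # uniform over the allowed disk
        phi = rng.uniform(0.0, 2.0 * np.pi)
        x, y = r * np.cos(phi), r * np.sin(phi)
        if all(np.hypot(x - cx, y - cy) >= min_sep for cx, cy in centers):
            centers.append((float(x), float(y)))
    return centers


def _margin_ratio_from_fields(
    values: np.ndarray, mask: np.ndarray, boundary_dist: np.ndarray, band_px: float
) -> float:
    band = mask & (boundary_dist <= band_px)
    return float(values[band].mean() / values[mask].mean())


def generate_nucleus_image(spec: NucleusSpec) -> tuple[NucleusImage, NucleusTruth]:
    """Render one synthetic nucleus and its ground truth.

    Deterministic in ``spec.seed``.  The returned image is 8-bit-like:
    Gaussian noise of ``noise_sd`` is added and the result clipped to
    [0, 255]; truth statistics are computed on the noiseless field.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.radius_px
    pad = max(6, R // 4)
    half = R + pad
    size = 2 * half + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)

    a, b = float(R), float(R) * spec.ellipticity
    # normalized elliptical radius; 1.0 at the margin
    rho = np.sqrt((xx / a) ** 2 + (yy / b) ** 2)
    mask = rho <= 1.0
    # distance (px) from the margin, exact for circles
    boundary_dist = (1.0 - rho) * min(a, b)

    theta = spec.tether_strength
    excess = (spec.het_eu_contrast - 1.0) * EUCHROMATIN_INTENSITY
    values = np.full((size, size), BACKGROUND_INTENSITY)
    values[mask] = EUCHROMATIN_INTENSITY

    shell_px = spec.shell_width_frac * min(a, b)
    shell = mask & (boundary_dist <= shell_px)
    values[shell] += theta * excess

    centers = _place_chromocenters(spec, rng)
    for cx, cy in centers:
        blob = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.chromocenter_radius_px**2
        values[blob & mask] = EUCHROMATIN_INTENSITY + (1.0 - theta) * excess

    noiseless = values.copy()
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, values.shape)
    img = np.clip(np.rint(values), 0, 255).astype(np.uint8)

    # analytic mass bookkeeping: background + euchromatin + shell/chromocenter excess
    n_px = size * size
    disk_area = np.pi * a * b
    inner_frac = 1.0 - shell_px / min(a, b)
    shell_area = np.pi * a * b * (1.0 - inner_frac**2)
    cc_area = len(centers) * np.pi * spec.chromocenter_radius_px**2
    cc_in_shell = 0.0  # chromocenters overwrite the shell where they overlap
    for cx, cy in centers:
        blob = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.chromocenter_radius_px**2
        cc_in_shell += float((blob & shell).sum())
    analytic = (
        BACKGROUND_INTENSITY * (n_px - disk_area)
        + EUCHROMATIN_INTENSITY * disk_area
        + theta * excess * (shell_area - cc_in_shell)
        + (1.0 - theta) * excess * cc_area
    )

    truth = NucleusTruth(
        chromocenter_centroids=[(cx + half, cy + half) for cx, cy in centers],
        true_margin_ratio=_margin_ratio_from_fields(noiseless, mask, boundary_dist, 3.0),
        organization_label=_organization_label(theta),
        noiseless_total_intensity=float(noiseless.sum()),
        analytic_total_intensity=float(analytic),
        mask=mask,
    )
    return NucleusImage(img.astype(float), spec.pixel_size_um), truth


def generate_cohort(
    n_per_group: int,
    group_specs: dict[str, NucleusSpec],
    n_replicates: int = 3,
) -> tuple[dict[tuple[str, str, str], NucleusImage], pd.DataFrame]:
    """A cohort of nuclei: ``n_replicates`` biological replicates per group,
    ``n_per_group`` cells per replicate.

    Per-cell seeds are derived deterministically from each group spec's
    seed, so the same specs always yield byte-identical truth tables.
    Returns the images keyed by (group, replicate, cell) and a tidy truth
    table.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if not group_specs:
        raise ValueError("group_specs must not be empty")
    images: dict[tuple[str, str, str], NucleusImage] = {}
    rows = []
    for group in sorted(group_specs):
        spec = group_specs[group]
        ss = np.random.SeedSequence(spec.seed)
        child_seeds = ss.generate_state(n_replicates * n_per_group) % (2**31)
        i = 0
        for rep in range(1, n_replicates + 1):
            for cell in range(1, n_per_group + 1):
                cell_spec = NucleusSpec(**{**spec.__dict__, "seed": int(child_seeds[i])})
                i += 1
                img, truth = generate_nucleus_image(cell_spec)
                key = (group, f"rep{rep}", f"cell{cell}")
                images[key] = img
                rows.append(
                    {
                        "group": group,
                        "replicate": f"rep{rep}",
                        "cell": f"cell{cell}",
                        "tether_strength": spec.tether_strength,
                        "true_margin_ratio": truth.true_margin_ratio,
                        "n_chromocenters": len(truth.chromocenter_centroids),
                        "organization_label": truth.organization_label,
                    }
                )
    return images, pd.DataFrame(rows)
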