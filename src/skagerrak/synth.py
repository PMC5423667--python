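"""Synthetic genotype cohorts and ocean scenarios with known ground truth.

The genotype generator uses the F-model: each population's allele
frequencies at a locus are a Dirichlet draw around shared ancestral
frequencies with concentration ``(1 - F) / F``, so the divergence parameter
F is, in expectation, exactly the quantity the Weir-Cockerham estimator
targets — giving clean parameter-recovery tests. Genotypes are drawn under
within-population Hardy-Weinberg proportions, missingness is completely at
random, and allele labels are mapped to plausible even fragment sizes in the
published ranges of the six-marker oyster panel.

The ocean generator builds a rectangular basin with a donor coast to the
south and a recipient coast to the north, a divergence-free current carrying
water between them (stream-function construction), and a smooth temperature
field with a seasonal cycle, a north-south gradient, and a scenario offset.
The cold / moderate / warm presets move only the temperature offset, so the
temperature gate — not circulation — is the single cause of differences
between scenario outcomes, emulating the cold-1990s vs warm-2000s contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dispersal import OceanFields, ReleaseSpec, build_release_schedule
from .genotypes import MISSING, GenotypeTable

__all__ = [
    "GenoSimConfig",
    "OceanSimConfig",
    "DEFAULT_LOCI",
    "simulate_genotypes",
    "make_hwe_violating_population",
    "generate_ocean_scenario",
    "recipient_region",
    "SCENARIO_OFFSETS",
]

#: Marker panel emulated by default: (name, smallest fragment size in bp).
#: Ranges follow the published six-locus C. gigas panel; alleles step by 2 bp
#: (dinucleotide repeats).
DEFAULT_LOCI: tuple[tuple[str, int], ...] = (
    ("L10", 109),
    ("Cgsili44", 337),
    ("AMY", 196),
    ("L48", 96),
    ("CGE009", 102),
    ("CG49", 128),
)

#: Default cohort layout: six sampling locations with the study's sample sizes.
DEFAULT_POPS: tuple[tuple[str, int], ...] = (
    ("N_B", 12),
    ("N_G", 50),
    ("N_I", 50),
    ("N_O", 50),
    ("S_S", 50),
    ("D_A", 50),
)


@dataclass
class GenoSimConfig:
    """Configuration of the F-model genotype generator.

    ``sizes`` are per-population sample sizes; ``F`` is the divergence
    parameter (scalar, or one value per population). ``n_alleles`` is the
    ancestral allele count per locus. ``missing_rate`` is the per-genotype
    probability of a missing call (default 0.004, the sporadic level of the
    emulated data set: a handful of failures among ~1600 genotype calls).
    """

    pop_names: Sequence[str] = tuple(p for p, _ in DEFAULT_POPS)
    sizes: Sequence[int] = tuple(n for _, n in DEFAULT_POPS)
    loci: Sequence[tuple[str, int]] = DEFAULT_LOCI
    n_alleles: int = 12
    F: float | Sequence[float] = 0.03
    missing_rate: float = 0.004
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.pop_names) != len(self.sizes):
            raise ValueError("pop_names and sizes must align")
        fs = self.f_values()
        if any(not 0.0 <= f < 1.0 for f in fs):
            raise ValueError("F must satisfy 0 <= F < 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_alleles < 1:
            raise ValueError("n_alleles must be >= 1")

    def f_values(self) -> list[float]:
        if np.isscalar(self.F):
            return [float(self.F)] * len(self.pop_names)
        out = [float(f) for f in self.F]  # type: ignore[union-attr]
        if len(out) != len(self.pop_names):
            raise ValueError("per-population F must align with pop_names")
        return out


def simulate_genotypes(
    cfg: GenoSimConfig, seed: int | np.random.Generator | None = None
) -> GenotypeTable:
    """Draw a diploid genotype cohort from the F-model.

    Ancestral frequencies per locus come from a flat Dirichlet over
    ``n_alleles`` labels; each population's frequencies are Dirichlet with
    parameters ``p0 * (1 - F) / F`` (for F = 0 the population copies the
    ancestral frequencies exactly — the documented special case, no division
    by zero). Genotypes are two independent gene copies per individual
    (within-population HWE); missingness is applied completely at random.
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    fs = cfg.f_values()
    n_pops = len(cfg.pop_names)
    L = len(cfg.loci)
    K = cfg.n_alleles

    individuals: list[str] = []
    populations: list[str] = []
    total = int(sum(cfg.sizes))
    calls = np.zeros((total, L, 2), dtype=np.int64)

    # per-locus allele label maps (even bp sizes from the panel's range start)
    labels = [base + 2 * np.arange(K) for _, base in cfg.loci]

    row = 0
    p0 = [rng.dirichlet(np.ones(K)) for _ in range(L)]
    for ipop, (pname, n) in enumerate(zip(cfg.pop_names, cfg.sizes)):
        Fp = fs[ipop]
        for j in range(L):
            if Fp == 0.0:
                p = p0[j]
            else:
                conc = p0[j] * (1.0 - Fp) / Fp
                # Dirichlet with tiny concentrations can underflow; floor it
                p = rng.dirichlet(np.maximum(conc, 1e-9))
            copies = rng.choice(K, size=(n, 2), p=p)
            calls[row : row + n, j, :] = labels[j][copies]
        for i in range(n):
            individuals.append(f"{pname}_{i + 1:03d}")
            populations.append(pname)
        row += n

    if cfg.missing_rate > 0:
        miss = rng.random((total, L)) < cfg.missing_rate
        calls[miss] = MISSING
    return GenotypeTable(individuals, populations, list(n for n, _ in cfg.loci), calls)


def make_hwe_violating_population(
    n: int,
    f_is: float,
    n_alleles: int = 2,
    freqs: Sequence[float] | None = None,
    seed: int | np.random.Generator | None = None,
    pop_name: str = "SIM",
    locus: str = "L1",
) -> GenotypeTable:
    """One-locus population with inbreeding-like distortion of heterozygosity.

    Genotype probabilities follow the F_IS parameterization:
    ``P(het i,j) = 2 p_i p_j (1 - f_is)`` and
    ``P(hom i) = p_i^2 + f_is p_i (1 - p_i)``. Positive ``f_is`` gives a
    heterozygote deficit, negative an excess (down to -1 = every individual
    heterozygous, for two equifrequent alleles); ``f_is = 0`` is exact HWE,
    the null fixture for test calibration.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not -1.0 <= f_is < 1.0:
        raise ValueError("f_is must be in [-1, 1)")
    rng = np.random.default_rng(seed)
    p = np.asarray(freqs, dtype=float) if freqs is not None else np.full(n_alleles, 1.0 / n_alleles)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("freqs must sum to 1")
    K = p.size
    probs = []
    genos = []
    for i in range(K):
        for j in range(i, K):
            if i == j:
                pr = p[i] ** 2 + f_is * p[i] * (1 - p[i])
            else:
                pr = 2 * p[i] * p[j] * (1 - f_is)
            probs.append(max(pr, 0.0))
            genos.append((i, j))
    probs_arr = np.asarray(probs)
    if probs_arr.sum() <= 0:
        raise ValueError("degenerate genotype distribution")
    probs_arr = probs_arr / probs_arr.sum()
    pick = rng.choice(len(genos), size=n, p=probs_arr)
    labels = 100 + 2 * np.arange(K)
    calls = np.zeros((n, 1, 2), dtype=np.int64)
    for row, g in enumerate(pick):
        i, j = genos[g]
        calls[row, 0, :] = (labels[i], labels[j])
    return GenotypeTable(
        [f"{pop_name}_{i + 1:03d}" for i in range(n)], [pop_name] * n, [locus], calls
    )


# -- ocean scenarios ------------------------------------------------------

#: Temperature offsets (C) of the named presets. Only the offset differs
#: between presets, isolating the temperature gate as the cause of outcome
#: differences between "years".
SCENARIO_OFFSETS: dict[str, float] = {"cold": -6.0, "moderate": 0.0, "warm": 4.0}


@dataclass
class OceanSimConfig:
    """Configuration of the parametric basin generator.

    The basin is ``nx x ny`` cells of ``dx x dy`` meters with land strips of
    ``land_strip`` cells on the south (donor) and north (recipient) edges.
    ``pattern`` is "uniform" (northward stream, transit set by
    ``transit_days`` over the water distance) or "gyre" (single
    stream-function gyre). Temperature (C) is
    ``baseline + seasonal_amplitude * sin(pi * t / duration) +
    meridional_gradient * y_km + offset``; ``meridional_gradient`` is in
    C per km (negative = colder northward). ``seed`` is unused unless noise
    is enabled (the default scenarios are deliberately noise-free so every
    simulation property is exact).
    """

    nx: int = 75
    ny: int = 60
    dx: float = 4000.0
    dy: float = 4000.0
    duration_days: float = 75.0
    field_dt: float = 6 * 3600.0
    land_strip: int = 2
    pattern: str = "uniform"
    transit_days: float = 12.0
    gyre_speed: float = 0.25
    baseline_temp: float = 19.0
    seasonal_amplitude: float = 2.5
    meridional_gradient: float = -0.012
    offset: float = 0.0
    n_sites: int = 44
    release_start_day: float = 1.0
    release_end_day: float = 14.0
    release_every_days: float = 2.0
    noise: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell size must be positive")
        if self.pattern not in ("uniform", "gyre"):
            raise ValueError("pattern must be 'uniform' or 'gyre'")
        if self.ny <= 2 * self.land_strip + 2:
            raise ValueError("domain too small for the land strips")


def _stream_function(cfg: OceanSimConfig) -> np.ndarray:
    """Stream function on cell corners, (ny+1, nx+1)."""
    xc = cfg.dx * np.arange(cfg.nx + 1)
    yc = cfg.dy * np.arange(cfg.ny + 1)
    X, Y = np.meshgrid(xc, yc)
    if cfg.pattern == "uniform":
        water_m = (cfg.ny - 2 * cfg.land_strip) * cfg.dy
        speed = water_m / (cfg.transit_days * 86400.0)
        return speed * X
    Lx, Ly = cfg.nx * cfg.dx, cfg.ny * cfg.dy
    psi0 = cfg.gyre_speed * Lx / np.pi
    return psi0 * np.sin(np.pi * X / Lx) * np.sin(np.pi * Y / Ly)


def generate_ocean_scenario(
    cfg: OceanSimConfig | None = None, preset: str | None = None, **overrides
) -> tuple[OceanFields, ReleaseSpec]:
    """Build an :class:`OceanFields` basin and its release schedule.

    ``preset`` ("cold" / "moderate" / "warm") sets the temperature offset
    only. Velocities derive from a stream function evaluated on cell corners
    (finite differences of a scalar are exactly divergence-free on the
    interior). Release sites sit on water cells adjacent to the donor
    (south) coast, evenly spaced in x.
    """
    if cfg is None:
        kw = dict(overrides)
        if preset is not None:
            kw.setdefault("offset", SCENARIO_OFFSETS[preset])
        cfg = OceanSimConfig(**kw)
    elif preset is not None:
        from dataclasses import replace

        cfg = replace(cfg, offset=SCENARIO_OFFSETS[preset])

    ny, nx = cfg.ny, cfg.nx
    mask = np.ones((ny, nx), dtype=bool)
    mask[: cfg.land_strip, :] = False  # donor (south) coast
    mask[ny - cfg.land_strip :, :] = False  # recipient (north) coast

    psi = _stream_function(cfg)
    # cell-center velocities from corner stream function: u = -dpsi/dy,
    # v = dpsi/dx (averaged over the two opposing cell faces)
    u = -(psi[1:, :-1] + psi[1:, 1:] - psi[:-1, :-1] - psi[:-1, 1:]) / (2 * cfg.dy)
    v = (psi[:-1, 1:] + psi[1:, 1:] - psi[:-1, :-1] - psi[1:, :-1]) / (2 * cfg.dx)
    u = np.where(mask, u, 0.0)
    v = np.where(mask, v, 0.0)

    nt = int(np.floor(cfg.duration_days * 86400.0 / cfg.field_dt)) + 1
    t = cfg.field_dt * np.arange(nt)
    y_km = (cfg.dy * (np.arange(ny) + 0.5)) / 1000.0
    seasonal = cfg.seasonal_amplitude * np.sin(np.pi * t / (cfg.duration_days * 86400.0))
    temp = (
        cfg.baseline_temp
        + cfg.offset
        + seasonal[:, None, None]
        + (cfg.meridional_gradient * y_km)[None, :, None]
        + np.zeros((1, 1, nx))
    )
    if cfg.noise > 0:
        rng = np.random.default_rng(cfg.seed)
        temp = temp + cfg.noise * rng.standard_normal(temp.shape)

    fields = OceanFields(
        x0=0.0, y0=0.0, dx=cfg.dx, dy=cfg.dy, t0=0.0, dt=cfg.field_dt,
        mask=mask, u=u[None], v=v[None], temp=temp,
    )

    # donor-coast sites: centers of water cells in the first water row
    row = cfg.land_strip
    xs = np.linspace(0.5, nx - 0.5, cfg.n_sites + 2)[1:-1] * cfg.dx
    ys = np.full(cfg.n_sites, (row + 0.5) * cfg.dy)
    sites = pd.DataFrame(
        {"site_id": [f"site{i + 1:02d}" for i in range(cfg.n_sites)], "x": xs, "y": ys}
    )
    release = build_release_schedule(
        sites, cfg.release_start_day, cfg.release_end_day, cfg.release_every_days, fields=fields
    )
    return fields, release


def recipient_region(fields: OceanFields, fraction: float = 0.75):
    """Shapely box covering the northern (recipient-coast) part of the basin,
    used to attribute landings to the far shore."""
    import shapely.geometry as geom

    Ly = fields.ny * fields.dy
    Lx = fields.nx * fields.dx
    return geom.box(fields.x0, fields.y0 + fraction * Ly, fields.x0 + Lx, fields.y0 + Ly)
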