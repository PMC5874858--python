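"""1-D condensed-history proton transport with depth-dose and LET scoring.

This module is a desk-scale surrogate for a full Monte Carlo treatment head
simulation: protons are tracked along the beam axis only (no lateral
scatter), losing energy continuously at the Bethe electronic stopping power
of the local material, with optional Gaussian (Bohr) energy-loss straggling
and an optional exponential attenuation of the primary fluence standing in
for nonelastic nuclear interactions. It produces central-axis depth-dose
and track-averaged LET curves for a Gaussian-energy beam entering a stack
of slab materials, which is all the downstream quenching-correction
machinery needs.

Units: energies MeV, lengths mm, densities g/cm³, stopping power MeV/mm,
mean excitation energies eV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .profiles import DepthProfile

# physical constants
_K = 0.307075            # MeV cm^2 / mol  (4*pi*N_A*r_e^2*m_e*c^2)
_ME_C2 = 0.51099895      # MeV, electron rest energy
_MP_C2 = 938.2720882     # MeV, proton rest energy
_BOHR = 0.1569           # MeV^2 cm^2/g, 4*pi*N_A*r_e^2*(m_e c^2)^2

E_MIN = 0.1              # MeV, lower edge of the stopping-power domain
E_MAX = 250.0            # MeV, upper edge
E_CUTOFF = 0.5           # MeV, transport cutoff; residual range deposited locally

# element symbol -> (Z, A g/mol)
ELEMENTS = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Ar": (18, 39.948),
}


@dataclass(frozen=True)
class Material:
    """Slab material characterised by density, composition and mean I.

    ``composition`` is a list of ``(element symbol, mass fraction)`` pairs;
    fractions must sum to one. ``mean_excitation_energy`` (eV) is the
    material-level I entering the Bethe formula directly; the tabulated
    defaults used by the built-ins are water 75 eV, PMMA 74 eV and
    polyvinyltoluene 64.7 eV. ``refractive_index`` is carried as metadata
    for the optical modules and plays no role in transport.
    """

    name: str
    density: float
    composition: tuple
    mean_excitation_energy: float
    refractive_index: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "composition", tuple(self.composition))
        total = sum(w for _, w in self.composition)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mass fractions of {self.name} sum to {total}, not 1")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.mean_excitation_energy <= 0:
            raise ValueError("mean excitation energy must be positive")
        for sym, _ in self.composition:
            if sym not in ELEMENTS:
                raise ValueError(f"unknown element {sym!r}")

    @property
    def z_over_a(self) -> float:
        """Effective Z/A (mol/g) by Bragg additivity over mass fractions."""
        return sum(w * ELEMENTS[s][0] / ELEMENTS[s][1] for s, w in self.composition)


def _pvt_fractions(h_to_c_atoms: float = 1.104) -> tuple:
    """Mass fractions of polyvinyltoluene from its H:C atom ratio."""
    m_h = h_to_c_atoms * ELEMENTS["H"][1]
    m_c = ELEMENTS["C"][1]
    tot = m_h + m_c
    return (("H", m_h / tot), ("C", m_c / tot))


BC408 = Material(
    name="BC-408",
    density=1.03,
    composition=_pvt_fractions(1.104),
    mean_excitation_energy=64.7,
    refractive_index=1.58,
)

WATER = Material(
    name="water",
    density=1.0,
    composition=(("H", 0.111894), ("O", 0.888106)),
    mean_excitation_energy=75.0,
    refractive_index=1.33,
)

# C5H8O2
_PMMA_M = 5 * ELEMENTS["C"][1] + 8 * ELEMENTS["H"][1] + 2 * ELEMENTS["O"][1]
PMMA = Material(
    name="PMMA",
    density=1.19,
    composition=(
        ("H", 8 * ELEMENTS["H"][1] / _PMMA_M),
        ("C", 5 * ELEMENTS["C"][1] / _PMMA_M),
        ("O", 2 * ELEMENTS["O"][1] / _PMMA_M),
    ),
    mean_excitation_energy=74.0,
    refractive_index=1.49,
)

AIR = Material(
    name="air",
    density=1.20479e-3,
    composition=(("C", 0.000124), ("N", 0.755267), ("O", 0.231781), ("Ar", 0.012827)),
    mean_excitation_energy=85.7,
    refractive_index=1.0,
)

MATERIALS = {m.name.lower(): m for m in (BC408, WATER, PMMA, AIR)}
MATERIALS["bc408"] = BC408


def get_material(name: str) -> Material:
    key = name.lower().replace("_", "-").replace(" ", "")
    key = {"bc-408": "bc-408"}.get(key, key)
    for cand in (key, key.replace("-", "")):
        if cand in MATERIALS:
            return MATERIALS[cand]
    raise KeyError(f"no built-in material named {name!r}")


@dataclass(frozen=True)
class BeamSpec:
    """Gaussian-energy proton beam upstream of the stack.

    The defaults describe the study beam: 60 MeV mean with 0.36 MeV
    standard deviation, a 25 mm circular collimator, and 70 mm of air
    between the nozzle and the entrance face. The air gap is traversed
    (with energy loss and straggling) before depth scoring starts at z = 0.
    """

    mean_energy: float = 60.0
    energy_sigma: float = 0.36
    collimator_diameter: float = 25.0
    air_gap: float = 70.0
    n_protons: int = 100_000
    rng_seed: int = 0

    def __post_init__(self):
        if self.mean_energy <= 0:
            raise ValueError("mean_energy must be positive")
        if self.energy_sigma < 0:
            raise ValueError("energy_sigma must be non-negative")
        if self.n_protons < 1:
            raise ValueError("need at least one proton")


@dataclass
class MaterialStack:
    """Ordered slabs the beam traverses; z = 0 at the first layer's face."""

    layers: list  # list of (Material, thickness mm)

    def __post_init__(self):
        if not self.layers:
            raise ValueError("stack must contain at least one layer")
        for _, t in self.layers:
            if t <= 0:
                raise ValueError("layer thicknesses must be positive")

    @property
    def total_thickness(self) -> float:
        return float(sum(t for _, t in self.layers))

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([t for _, t in self.layers])])


def stopping_power(energy, material: Material):
    """Electronic stopping power of protons, MeV/mm (Bethe formula).

    Valid for 0.1–250 MeV; uses the material's density, effective Z/A and
    mean excitation energy. Shell and density-effect corrections are
    omitted — they matter below ~1 MeV and above several hundred MeV
    respectively, outside the regime this package addresses.
    """
    e = np.asarray(energy, dtype=float)
    if np.any(e < E_MIN) or np.any(e > E_MAX):
        raise ValueError(f"energy outside the {E_MIN}-{E_MAX} MeV domain")
    gamma = 1.0 + e / _MP_C2
    beta2 = 1.0 - 1.0 / gamma**2
    bg2 = beta2 * gamma**2
    ratio = _ME_C2 / _MP_C2
    tmax = 2 * _ME_C2 * bg2 / (1 + 2 * gamma * ratio + ratio**2)
    i_mev = material.mean_excitation_energy * 1e-6
    bracket = 0.5 * np.log(2 * _ME_C2 * bg2 * tmax / i_mev**2) - beta2
    s_mass = _K * material.z_over_a / beta2 * bracket          # MeV cm^2/g
    s = s_mass * material.density / 10.0                       # MeV/mm
    return float(s) if np.isscalar(energy) else s


# per-material cached CSDA range tables (energy grid, cumulative range)
_range_cache: dict = {}


def _range_table(material: Material):
    key = (material.name, material.density, material.mean_excitation_energy,
           material.composition)
    if key not in _range_cache:
        e = np.geomspace(E_MIN, E_MAX, 4000)
        inv_s = 1.0 / stopping_power(e, material)
        r = cumulative_trapezoid(inv_s, e, initial=0.0)        # mm, from E_MIN
        _range_cache[key] = (e, r)
    return _range_cache[key]


def csda_range(energy, material: Material, cutoff: float = E_CUTOFF):
    """CSDA range in mm: integral of dE/S(E) from ``cutoff`` up to ``energy``.

    The sub-cutoff residual (a few µm in condensed media) is neglected;
    transport deposits it locally instead.
    """
    e_grid, r_grid = _range_table(material)
    e = np.asarray(energy, dtype=float)
    if np.any(e < cutoff) or np.any(e > E_MAX):
        raise ValueError(f"energy outside the {cutoff}-{E_MAX} MeV domain")
    r = np.interp(e, e_grid, r_grid) - np.interp(cutoff, e_grid, r_grid)
    return float(r) if np.isscalar(energy) else r


def _energy_from_range(residual_range_mm, material: Material,
                       cutoff: float = E_CUTOFF):
    """Inverse of :func:`csda_range`: energy with the given residual range."""
    e_grid, r_grid = _range_table(material)
    r0 = np.interp(cutoff, e_grid, r_grid)
    return np.interp(np.asarray(residual_range_mm, dtype=float) + r0, r_grid, e_grid)


def degrade_energy(energy: float, degrader: Material, thickness: float) -> float:
    """Residual mean energy after CSDA slowing through ``thickness`` mm.

    Raises if the degrader is thick enough to stop the beam.
    """
    if thickness < 0:
        raise ValueError("thickness must be non-negative")
    if thickness == 0:
        return float(energy)
    r = csda_range(energy, degrader)
    if thickness >= r:
        raise ValueError(
            f"{thickness} mm of {degrader.name} stops a {energy} MeV beam "
            f"(range {r:.2f} mm)")
    return float(_energy_from_range(r - thickness, degrader))


def thickness_for_energy(e_in: float, e_out: float, degrader: Material) -> float:
    """Degrader thickness (mm) that slows ``e_in`` to ``e_out`` in CSDA."""
    if not e_out < e_in:
        raise ValueError("e_out must be below e_in")
    return csda_range(e_in, degrader) - csda_range(e_out, degrader)


def simulate_depth_curves(
    beam: BeamSpec,
    stack: MaterialStack,
    bin_width: float = 0.125,
    straggling: bool = True,
    nuclear_attenuation: bool = True,
    nuclear_mfp_mm: float = 1100.0,
    max_step: float = 0.1,
):
    """Monte Carlo depth-dose and track-averaged LET in a slab stack.

    Each history samples its initial energy from the beam's Gaussian,
    crosses the air gap, then steps through the stack depositing
    ``S(E)·Δs`` per step with optional Bohr straggling. Steps are capped at
    ``max_step`` mm and at 1% of the residual range. Nuclear interactions
    are modelled (optionally) as exponential removal of primaries with mean
    free path ``nuclear_mfp_mm`` in water-equivalent (density-scaled)
    length; removed protons deposit nothing locally.

    Returns ``(dose, let)`` :class:`~scintqa.profiles.DepthProfile` objects
    on bin centres. ``dose`` holds total energy deposited per bin (MeV);
    ``let`` the track-average of S(E) over primaries crossing each bin
    (MeV/mm). ``dose.meta`` records totals, the escape flag and the seed.
    Fixed ``beam.rng_seed`` gives bit-identical profiles.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rng = np.random.default_rng(beam.rng_seed)
    n = beam.n_protons

    total = stack.total_thickness
    deepest_range = csda_range(min(beam.mean_energy + 5 * beam.energy_sigma, E_MAX),
                               stack.layers[-1][0])
    if total < deepest_range * 0.5 and stack.layers[-1][1] < deepest_range:
        warnings.warn("final layer may be too thin to stop the beam", stacklevel=2)

    n_bins = int(np.ceil(total / bin_width - 1e-9))
    max_step = min(max_step, bin_width)     # a step never spans > 2 bins
    edges = stack.edges
    mats = [m for m, _ in stack.layers]
    densities = np.array([m.density for m in mats])
    zovera = np.array([m.z_over_a for m in mats])

    e = np.full(n, beam.mean_energy)
    if beam.energy_sigma > 0:
        e = e + beam.energy_sigma * rng.standard_normal(n)
    e = np.clip(e, E_CUTOFF * 2, E_MAX)
    pos = np.full(n, -float(beam.air_gap))          # mm; z=0 at stack entrance
    alive = np.ones(n, dtype=bool)

    dose = np.zeros(n_bins)
    let_sum = np.zeros(n_bins)
    let_cnt = np.zeros(n_bins)
    e_initial = e.sum()
    e_deposited_total = 0.0       # includes air gap and sub-grid deposits
    escaped = 0

    # residual-range tables per layer material for the adaptive step
    r_tabs = [_range_table(m) for m in mats]

    while alive.any():
        idx = np.nonzero(alive)[0]
        ei = e[idx]
        pi = pos[idx]

        in_air_gap = pi < 0
        layer = np.clip(np.searchsorted(edges, pi, side="right") - 1, 0, len(mats) - 1)

        # stopping power & residual range in the local material
        s_loc = np.empty(len(idx))
        res_range = np.empty(len(idx))
        boundary = np.empty(len(idx))
        for li in range(len(mats)):
            sel = (~in_air_gap) & (layer == li)
            if sel.any():
                s_loc[sel] = stopping_power(ei[sel], mats[li])
                eg, rg = r_tabs[li]
                res_range[sel] = np.interp(ei[sel], eg, rg)
                boundary[sel] = edges[li + 1] - pi[sel]
        if in_air_gap.any():
            s_loc[in_air_gap] = stopping_power(ei[in_air_gap], AIR)
            eg, rg = _range_table(AIR)
            res_range[in_air_gap] = np.interp(ei[in_air_gap], eg, rg)
            boundary[in_air_gap] = -pi[in_air_gap]

        step = np.minimum(max_step, 0.01 * res_range)
        # upstream of the scoring grid (air gap) resolution is irrelevant:
        # let the 1%-of-range rule alone govern the step there
        step = np.where(in_air_gap, 0.01 * res_range, step)
        step = np.minimum(step, np.maximum(boundary, 1e-6) + 1e-9)
        step = np.maximum(step, 1e-6)

        de = s_loc * step
        if straggling:
            dens = np.where(in_air_gap, AIR.density, densities[layer])
            za = np.where(in_air_gap, AIR.z_over_a, zovera[layer])
            gamma = 1.0 + ei / _MP_C2
            beta2 = 1.0 - 1.0 / gamma**2
            var = _BOHR * za * dens * (step / 10.0) * (1 - beta2 / 2) / (1 - beta2)
            de = de + np.sqrt(var) * rng.standard_normal(len(idx))
        de = np.clip(de, 0.0, ei)

        removed = np.zeros(len(idx), dtype=bool)
        if nuclear_attenuation:
            dens = np.where(in_air_gap, AIR.density, densities[layer])
            p_rm = dens * step / nuclear_mfp_mm
            removed = rng.random(len(idx)) < p_rm

        stopping = (ei - de) <= E_CUTOFF
        de = np.where(stopping, ei, de)             # dump residual locally
        de = np.where(removed, 0.0, de)

        # distribute each step's deposit over the (at most two) bins it
        # overlaps, proportionally to overlap length; midpoint binning
        # would alias the common ~0.1 mm step against the 0.125 mm grid
        lo = pi
        hi = pi + step
        b_lo = np.floor(lo / bin_width).astype(int)
        b_hi = np.floor(hi / bin_width).astype(int)
        b_hi = np.minimum(b_hi, b_lo + 1)
        edge = b_hi * bin_width
        w_lo = np.where(b_hi > b_lo,
                        np.clip((edge - lo) / np.maximum(step, 1e-300), 0, 1), 1.0)
        for bins, w in ((b_lo, w_lo), (b_hi, 1.0 - w_lo)):
            in_grid = (bins >= 0) & (bins < n_bins) & ~removed & (w > 0)
            if in_grid.any():
                dose += np.bincount(bins[in_grid], weights=(de * w)[in_grid],
                                    minlength=n_bins)
                # track-averaged LET: path-length-weighted mean of S over
                # the primary tracks in each bin (sum S*ds / sum ds)
                let_sum += np.bincount(bins[in_grid],
                                       weights=(s_loc * step * w)[in_grid],
                                       minlength=n_bins)
                let_cnt += np.bincount(bins[in_grid],
                                       weights=(step * w)[in_grid],
                                       minlength=n_bins)
        e_deposited_total += de[~removed].sum()

        e[idx] = ei - de
        pos[idx] = pi + step
        exit_mask = pos[idx] >= total - 1e-12
        escaped += int(np.count_nonzero(exit_mask & ~(stopping | removed)))
        alive[idx] = ~(stopping | removed | exit_mask)

    depths = (np.arange(n_bins) + 0.5) * bin_width
    meta = {
        "n_protons": n,
        "rng_seed": beam.rng_seed,
        "e_initial_total": float(e_initial),
        "e_deposited_total": float(e_deposited_total),
        "escaped_protons": escaped,
        "beam_exits_stack": escaped > 0,
        "straggling": straggling,
        "nuclear_attenuation": nuclear_attenuation,
    }
    if escaped > 0:
        warnings.warn(f"{escaped} protons exited the distal face", stacklevel=2)
    with np.errstate(invalid="ignore"):
        let_vals = np.where(let_cnt > 0, let_sum / np.maximum(let_cnt, 1e-300), 0.0)
    dose_p = DepthProfile(depths, dose, "dose", meta=dict(meta))
    let_p = DepthProfile(depths, let_vals, "let", meta=dict(meta))
    return dose_p, let_p


def bragg_peak_depth(profile: DepthProfile, n_fit: int = 5) -> float:
    """Peak depth via a parabolic fit through the bins around the maximum.

    Suppresses single-bin noise; ties break to the shallowest bin.
    """
    v = profile.values
    z = profile.depths
    i = int(np.argmax(v))
    half = n_fit // 2
    lo, hi = max(0, i - half), min(len(v), i + half + 1)
    if hi - lo < 3:
        return float(z[i])
    c = np.polyfit(z[lo:hi], v[lo:hi], 2)
    if c[0] >= 0:                      # not concave: fall back to the max bin
        return float(z[i])
    zp = -c[1] / (2 * c[0])
    return float(np.clip(zp, z[lo], z[hi - 1]))
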