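"""QA metrics and study-level procedures for depth-dose profiles.

Range points on the distal falloff (d90/d80/d50), peak-to-plateau ratio,
tolerance-based profile comparison for daily constancy checks, spread-out
Bragg peak (SOBP) synthesis with per-component quenching, and the
characterization suite (reproducibility, dose linearity, dose-rate
independence, range versus energy) run on synthetic fixtures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .profiles import DepthProfile, distal_crossing, register_profiles
from .quenching import QuenchModel, correct_profile, correction_curve, quench_light
from .transport import (BeamSpec, Material, MaterialStack, bragg_peak_depth,
                        csda_range, simulate_depth_curves)

DEFAULT_PLATEAU_WINDOW = (2.0, 7.0)
DEFAULT_TOLERANCES = {"range_mm": 0.2, "peak_plateau_pct": 3.0}


@dataclass
class QAReport:
    """Range and peak metrics of one profile, plus comparison results."""

    range_d90: float
    range_d80: float
    range_d50: float
    peak_plateau_ratio: float
    peak_depth: float
    tail_fraction: float = 0.0
    comparisons: list = field(default_factory=list)

    def __post_init__(self):
        if not self.range_d90 <= self.range_d80 <= self.range_d50:
            raise ValueError("distal range points must be ordered d90<=d80<=d50")
        if self.peak_plateau_ratio <= 0:
            raise ValueError("peak/plateau ratio must be positive")

    @property
    def all_pass(self) -> bool:
        return all(c["passed"] for c in self.comparisons)

    def as_dict(self) -> dict:
        return {
            "range_d90_mm": self.range_d90,
            "range_d80_mm": self.range_d80,
            "range_d50_mm": self.range_d50,
            "peak_plateau_ratio": self.peak_plateau_ratio,
            "peak_depth_mm": self.peak_depth,
            "tail_fraction": self.tail_fraction,
            "comparisons": self.comparisons,
        }


def distal_range(profile: DepthProfile, level: float) -> float:
    """Depth past the peak where the profile falls to ``level``×max (mm)."""
    return distal_crossing(profile, level)


def peak_plateau(profile: DepthProfile,
                 plateau_window: tuple = DEFAULT_PLATEAU_WINDOW) -> float:
    """Ratio of the profile maximum to its entrance-plateau mean.

    The plateau window (mm) must lie on the grid and upstream of the peak.
    """
    lo, hi = plateau_window
    z = profile.depths
    sel = (z >= lo) & (z <= hi)
    if not sel.any():
        raise ValueError("plateau window lies outside the depth grid")
    plateau = profile.values[sel].mean()
    if plateau <= 0:
        raise ValueError("plateau mean is zero")
    return float(profile.values.max() / plateau)


def tail_fraction(profile: DepthProfile, offset_mm: float = 2.0,
                  width_mm: float = 4.0) -> float:
    """Mean value in a window past the distal 20% point, as fraction of peak."""
    try:
        z20 = distal_crossing(profile, 0.2)
    except ValueError:
        return 0.0
    z = profile.depths
    sel = (z >= z20 + offset_mm) & (z <= z20 + offset_mm + width_mm)
    if not sel.any():
        return 0.0
    return float(profile.values[sel].mean() / profile.values.max())


def profile_report(profile: DepthProfile,
                   plateau_window: tuple = DEFAULT_PLATEAU_WINDOW) -> QAReport:
    """QAReport of a single profile (no comparisons)."""
    return QAReport(
        range_d90=distal_range(profile, 0.9),
        range_d80=distal_range(profile, 0.8),
        range_d50=distal_range(profile, 0.5),
        peak_plateau_ratio=peak_plateau(profile, plateau_window),
        peak_depth=bragg_peak_depth(profile),
        tail_fraction=tail_fraction(profile),
    )


def compare_profiles(test: DepthProfile, reference: DepthProfile,
                     tolerances: dict | None = None,
                     plateau_window: tuple = DEFAULT_PLATEAU_WINDOW) -> QAReport:
    """Compare a measured profile against a reference with QA tolerances.

    Range metrics are compared in the absolute depth frame (a shifted
    profile fails the range check); for the point-wise deviation maps the
    test profile is first registered to the reference at the distal 50%
    point. Comparison entries carry (metric, reference, delta, tolerance,
    passed).
    """
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    if test.depths[-1] < reference.depths[0] or test.depths[0] > reference.depths[-1]:
        raise ValueError("profiles do not overlap in depth")

    report = profile_report(test, plateau_window)
    ref_rep = profile_report(reference, plateau_window)

    comparisons = []

    def _add(metric, ref_val, delta, tolerance):
        comparisons.append({
            "metric": metric, "reference": float(ref_val),
            "delta": float(delta), "tolerance": float(tolerance),
            "passed": bool(abs(delta) <= tolerance),
        })

    _add("range_d90_mm", ref_rep.range_d90,
         report.range_d90 - ref_rep.range_d90, tol["range_mm"])
    pp_delta_pct = (report.peak_plateau_ratio / ref_rep.peak_plateau_ratio - 1) * 100
    _add("peak_plateau_pct", ref_rep.peak_plateau_ratio, pp_delta_pct,
         tol["peak_plateau_pct"])

    registered = register_profiles(test, reference)
    ref_n = reference.values / reference.values.max()
    tst_n = registered.values / max(registered.values.max(), 1e-300)
    z = reference.depths
    lo, hi = plateau_window
    plateau_sel = (z >= lo) & (z <= hi)
    peak_sel = ref_n >= 0.8
    for name, sel in (("plateau_max_rel_dev_pct", plateau_sel),
                      ("peak_max_rel_dev_pct", peak_sel)):
        if sel.any():
            dev = np.max(np.abs(tst_n[sel] - ref_n[sel]) / ref_n[sel].max()) * 100
            _add(name, 0.0, dev, tol["peak_plateau_pct"])

    report.comparisons = comparisons
    return report


# --- SOBP -----------------------------------------------------------------

_pristine_cache: dict = {}


def pristine_curves(energies, material: Material, energy_sigma: float = 0.36,
                    n_protons: int = 4000, bin_width: float = 0.125,
                    base_seed: int = 7000):
    """Simulated pristine dose and LET curves per energy on one common grid."""
    energies = tuple(float(e) for e in energies)
    key = (energies, material.name, energy_sigma, n_protons, bin_width, base_seed)
    if key in _pristine_cache:
        return _pristine_cache[key]
    depth = csda_range(max(energies), material) + 15.0
    stack = MaterialStack([(material, depth)])
    doses, lets = [], []
    for e in energies:
        # seed keyed to the energy so a component's curve is identical no
        # matter which energy list it appears in
        beam = BeamSpec(mean_energy=e, energy_sigma=energy_sigma,
                        n_protons=n_protons,
                        rng_seed=base_seed + int(e * 1000) % 100_000)
        d, l = simulate_depth_curves(beam, stack, bin_width=bin_width)
        doses.append(d)
        lets.append(l)
    _pristine_cache[key] = (doses, lets)
    return doses, lets


def synthesize_sobp(energies, weights, material: Material,
                    quench: QuenchModel | None = None, **sim_kw):
    """Weighted sum of pristine Bragg peaks on a common depth grid.

    With ``quench`` given, also returns the companion quenched-light SOBP,
    built by quenching each pristine component with its own LET before the
    weighted summation (quenching is per-beam, not applied to the sum).
    Returns ``dose`` or ``(dose, light)``.
    """
    energies = list(energies)
    weights = np.asarray(list(weights), dtype=float)
    if len(energies) != len(weights):
        raise ValueError("energies and weights must have equal length")
    if np.any(weights < 0) or not np.any(weights > 0):
        raise ValueError("weights must be non-negative and not all zero")
    doses, lets = pristine_curves(energies, material, **sim_kw)
    grid = doses[0].depths
    dose_sum = sum(w * d.values for w, d in zip(weights, doses))
    dose = DepthProfile(grid, dose_sum, "dose",
                        meta={"energies": energies, "weights": weights.tolist()})
    if quench is None:
        return dose
    light_sum = sum(w * quench_light(d, l, quench).values
                    for w, d, l in zip(weights, doses, lets))
    light = DepthProfile(grid, light_sum, "light", meta=dict(dose.meta))
    return dose, light


def sobp_weights_flat(energies, target_interval, material: Material,
                      **sim_kw):
    """Non-negative least-squares weights for a flat SOBP over an interval.

    Returns ``(weights, flatness)`` where flatness is the RMS relative
    deviation from flat inside ``target_interval`` (mm). Raises if the
    interval reaches beyond the deepest component's range; warns on
    (near-)duplicate energies, which make the problem degenerate.
    """
    energies = list(energies)
    if len(energies) < 2:
        raise ValueError("need at least two energies")
    if len(set(round(e, 6) for e in energies)) < len(energies):
        warnings.warn("duplicate energies make the weight problem degenerate",
                      stacklevel=2)
    lo, hi = target_interval
    deepest = csda_range(max(energies), material)
    if hi >= deepest:
        raise ValueError(
            f"interval end {hi} mm is beyond the deepest range {deepest:.1f} mm")
    doses, _ = pristine_curves(energies, material, **sim_kw)
    grid = doses[0].depths
    sel = (grid >= lo) & (grid <= hi)
    if not sel.any():
        raise ValueError("target interval contains no grid points")
    A = np.stack([d.values[sel] / d.values.max() for d in doses], axis=1)
    w, _ = optimize.nnls(A, np.ones(A.shape[0]))
    flat = A @ w
    flatness = float(np.sqrt(np.mean((flat / flat.mean() - 1.0) ** 2)))
    return w, flatness


# --- closed loop and characterization ------------------------------------

def closed_loop(render, normalization: str = "plateau") -> dict:
    """Render → pipeline → quenching correction → comparison with truth.

    Runs the image pipeline on a rendered scene, registers the measured
    light profile to the simulated quenched light at the distal 50% point,
    applies the simulation-derived correction curve, and reports range and
    peak/plateau errors of the corrected profile against the ground-truth
    dose.
    """
    from .image_pipeline import run_pipeline

    measured = run_pipeline(render.pipeline_config,
                            beam_stack=render.beam_on,
                            dark_stack=render.dark,
                            flat_stack=render.flat)
    truth_dose = render.truth_dose
    truth_let = render.truth_let
    model = render.phantom.quench
    sim_light = render.truth_light
    registered = register_profiles(measured, sim_light)
    curve = correction_curve(truth_dose, truth_let, model)
    corrected = correct_profile(registered, curve, normalization=normalization)

    d90_truth = distal_range(truth_dose, 0.9)
    d90_corr = distal_range(corrected, 0.9)
    pp_truth = peak_plateau(truth_dose)
    pp_corr = peak_plateau(corrected)
    return {
        "measured": measured,
        "corrected": corrected,
        "d90_truth_mm": d90_truth,
        "d90_corrected_mm": d90_corr,
        "d90_error_mm": d90_corr - d90_truth,
        "peak_plateau_truth": pp_truth,
        "peak_plateau_corrected": pp_corr,
        "peak_plateau_error_pct": (pp_corr / pp_truth - 1.0) * 100.0,
        "registration_shift_mm": registered.meta.get("registration_shift_mm", 0.0),
    }


def _integrated_signal(render) -> float:
    """Dose surrogate: depth-integrated measured light of a rendered scene."""
    from .image_pipeline import run_pipeline

    measured = run_pipeline(render.pipeline_config, beam_stack=render.beam_on,
                            dark_stack=render.dark, flat_stack=render.flat)
    return float(np.trapezoid(measured.values, measured.depths))


def characterization_suite(fixture_dir=None, repeatability=None,
                           dose_series=None, dose_rate_series=None,
                           energy_series=None, json_path=None) -> dict:
    """Detector characterization: reproducibility, linearity, rate, energy.

    Series may be given in memory (rendered scenes, see
    :mod:`scintqa.synthetic_data`) or loaded from a fixture directory
    written by :func:`~scintqa.synthetic_data.write_fixture`; missing
    series are skipped with a warning. ``dose_series`` pairs renders with
    their delivered doses via ``render.phantom.dose_gy``;
    ``energy_series`` is the output of
    :func:`~scintqa.synthetic_data.make_energy_series`. Returns a JSON-
    serializable report (optionally written to ``json_path``) with a
    human-readable ``summary`` line per section.
    """
    if fixture_dir is not None:
        from pathlib import Path

        from .synthetic_data import load_scene

        root = Path(fixture_dir)
        manifest = json.loads((root / "manifest.json").read_text())
        series = manifest.get("series", {})
        if "repeatability" in series and repeatability is None:
            repeatability = [load_scene(root / p) for p in series["repeatability"]]
        if "dose_series" in series and dose_series is None:
            dose_series = [load_scene(root / e["path"])
                           for e in series["dose_series"]]
        if "dose_rate" in series and dose_rate_series is None:
            dose_rate_series = [load_scene(root / p) for p in series["dose_rate"]]
        if "energy_series" in series and energy_series is None:
            energy_series = [
                (load_scene(root / e["path"]), e["energy_mev"], e["truth_d90_mm"])
                for e in series["energy_series"]]

    report: dict = {"sections": {}, "summary": []}

    if repeatability is not None:
        sig = np.array([_integrated_signal(r) for r in repeatability])
        cv = float(sig.std(ddof=1) / sig.mean()) if len(sig) > 1 else 0.0
        report["sections"]["repeatability"] = {
            "n": len(sig), "cv": cv, "signals": sig.tolist()}
        report["summary"].append(
            f"repeatability: CV {cv:.3%} over {len(sig)} repeats")
    else:
        warnings.warn("repeatability series missing; section skipped", stacklevel=2)

    if dose_series is not None:
        doses = np.array([r.phantom.dose_gy for r in dose_series])
        sig = np.array([_integrated_signal(r) for r in dose_series])
        res = stats.linregress(doses, sig)
        resid = sig - (res.slope * doses + res.intercept)
        report["sections"]["dose_linearity"] = {
            "doses_gy": doses.tolist(), "signals": sig.tolist(),
            "r_squared": float(res.rvalue ** 2),
            "slope": float(res.slope), "intercept": float(res.intercept),
            "max_rel_residual": float(np.max(np.abs(resid)) / sig.max()),
        }
        report["summary"].append(
            f"dose linearity: R^2 {res.rvalue**2:.5f} over "
            f"{doses.min():.2f}-{doses.max():.2f} Gy")
    else:
        warnings.warn("dose series missing; section skipped", stacklevel=2)

    if dose_rate_series is not None:
        sig = np.array([_integrated_signal(r) for r in dose_rate_series])
        cv = float(sig.std(ddof=1) / sig.mean()) if len(sig) > 1 else 0.0
        report["sections"]["dose_rate"] = {"n": len(sig), "cv": cv}
        report["summary"].append(f"dose-rate independence: CV {cv:.3%}")
    else:
        warnings.warn("dose-rate series missing; section skipped", stacklevel=2)

    if energy_series is not None:
        rows = []
        for render, energy, truth_d90 in energy_series:
            loop = closed_loop(render)
            rows.append({
                "energy_mev": float(energy),
                "truth_d90_mm": float(truth_d90),
                "measured_d90_mm": float(loop["d90_corrected_mm"]),
                "delta_mm": float(loop["d90_corrected_mm"] - truth_d90),
            })
        max_d = max(abs(r["delta_mm"]) for r in rows)
        report["sections"]["energy_response"] = {
            "table": rows, "max_abs_delta_mm": float(max_d)}
        report["summary"].append(
            f"range vs energy: max |Δd90| {max_d:.3f} mm over {len(rows)} energies")
    else:
        warnings.warn("energy series missing; section skipped", stacklevel=2)

    if json_path is not None:
        from pathlib import Path
        Path(json_path).write_text(json.dumps(report, indent=2))
    return report
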