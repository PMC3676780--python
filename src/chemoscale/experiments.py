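"""Named, fully pinned scenarios exercising every model tier at desk scale.

Each scenario is self-contained: :func:`make_fixture` returns a ``Scenario``
with all parameters and the seed pinned, and :func:`run_scenario` executes it
and returns a machine-readable summary (optionally writing CSV/JSON outputs).
The same seed always yields a byte-identical summary.

Scenarios
---------
step_response, double_step
    Excitation-adaptation model: single and staircase stimulus steps.
tar_family, tsr_family, mixed_tar_tsr, tsr_invitro
    Receptor-cluster dose-response families over expression multipliers,
    mixed Tar/Tsr compositions and methylation labels, with Hill fits.
cooperativity_regimes
    Hill coefficients of the three canonical cooperativity cases: a
    single-effective-site unit, a single trimer of dimers, and a strongly
    coupled six-trimer cluster, on a shared parameter set.
run_and_tumble_stats
    Unstimulated velocity-jump statistics (mean run interval, run-duration
    distribution, diffusion coefficient).
agents_vs_pks
    Agent histogram vs the derived continuum equation for a piecewise-linear
    signal peaked at mid-domain.
liquid_aggregation, swarm_ring, adler_band, spiral_streams
    Coupled agents + reaction-diffusion pattern scenarios (reduced scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import cartoon, fields, hill, mwc_cluster, pks
from .agents import AgentParams, run_statistics, simulate_population

__all__ = ["Scenario", "make_fixture", "run_scenario", "list_scenarios"]

# expression multiplier -> trimer count: n = max(1, round(mult * base)),
# base trimer count at native expression (configurable per family)
_EXPRESSION_BASE = 1


def _expression_to_count(mult: float, base: int = _EXPRESSION_BASE) -> int:
    return max(1, int(round(mult * base)))


# shared parameter set for the cooperativity-regime comparisons: three equal
# sequential Kds per state, inactive state binding 25x tighter (attractant),
# ligand-free offset -6 kBT
_REGIME_TRIMER = mwc_cluster.TrimerParams(
    receptor_type="Tar",
    m="QEQE",
    e_on=-6.0,
    e_off=0.0,
    kd_on=(0.5, 0.5, 0.5),
    kd_off=(0.02, 0.02, 0.02),
)


@dataclass(frozen=True)
class Scenario:
    """A pinned scenario: name, parameter overrides, seed, output directory."""

    name: str
    overrides: dict = dc_field(default_factory=dict)
    seed: int = 0
    out_dir: str | None = None


def list_scenarios() -> list[str]:
    return sorted(_RUNNERS)


def make_fixture(name: str, seed: int = 0, out_dir: str | None = None, **overrides) -> Scenario:
    """Return the canonical, fully specified scenario of the given name."""
    if name not in _RUNNERS:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(list_scenarios())}"
        )
    return Scenario(name=name, overrides=dict(overrides), seed=seed, out_dir=out_dir)


def run_scenario(scenario: Scenario) -> dict:
    """Execute a scenario; return its summary (and write outputs if asked)."""
    summary = _RUNNERS[scenario.name](scenario)
    summary = {"scenario": scenario.name, "seed": scenario.seed, **summary}
    if scenario.out_dir is not None:
        out = Path(scenario.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"{scenario.name}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# excitation-adaptation scenarios
# ---------------------------------------------------------------------------

_CARTOON = dict(tau_e=0.1, tau_a=10.0, s0=1.0, dt=0.005)


def _run_step_response(sc: Scenario) -> dict:
    p = {**_CARTOON, **sc.overrides}
    params = cartoon.CartoonParams(tau_e=p["tau_e"], tau_a=p["tau_a"])
    t_end = 20.0 * p["tau_a"]
    protocol = cartoon.StimulusProtocol.step(p["s0"])
    traj = cartoon.integrate_cartoon(params, protocol, dt=p["dt"], t_end=t_end)
    i_peak = int(traj["u1"].idxmax())
    if sc.out_dir:
        traj.to_csv(Path(sc.out_dir) / "step_response.csv", index=False)
    return {
        "peak_u1": float(traj["u1"].max()),
        "t_peak": float(traj["t"][i_peak]),
        "u1_final": float(traj["u1"].iloc[-1]),
        "u2_final": float(traj["u2"].iloc[-1]),
        "adapted": bool(abs(traj["u1"].iloc[-1]) < 1e-6),
    }


def _run_double_step(sc: Scenario) -> dict:
    p = {**_CARTOON, **sc.overrides}
    params = cartoon.CartoonParams(tau_e=p["tau_e"], tau_a=p["tau_a"])
    gap = 20.0 * p["tau_a"]
    protocol = cartoon.StimulusProtocol(
        [
            cartoon.Segment(0.0, gap, p["s0"]),
            cartoon.Segment(gap, 2.0 * gap, 2.0 * p["s0"]),
        ]
    )
    traj = cartoon.integrate_cartoon(params, protocol, dt=p["dt"], t_end=2.0 * gap)
    first = traj[traj["t"] < gap]
    second = traj[traj["t"] >= gap]
    if sc.out_dir:
        traj.to_csv(Path(sc.out_dir) / "double_step.csv", index=False)
    return {
        "peak_u1_first": float(first["u1"].max()),
        "peak_u1_second": float(second["u1"].max()),
    }


# ---------------------------------------------------------------------------
# receptor-cluster scenarios
# ---------------------------------------------------------------------------


def _family_summary(curves: dict[str, mwc_cluster.DoseResponse]) -> dict:
    out = {}
    for label, curve in curves.items():
        fit = hill.fit_hill(curve)
        out[label] = {
            "n_H": fit.n_H,
            "K_half": fit.K_half,
            "A_high": fit.A_high,
            "A_low": fit.A_low,
            "class": hill.cooperativity_class(fit),
        }
    return out


def _run_tar_family(sc: Scenario) -> dict:
    multipliers = sc.overrides.get("multipliers", (1.0, 2.0, 6.0))
    tar = mwc_cluster.default_tar()
    grid = mwc_cluster.transition_grid(tar, n_points=100)
    curves = {}
    for mult in multipliers:
        n = _expression_to_count(mult)
        curves[f"{mult}x"] = mwc_cluster.dose_response(tar, grid, n=n)
    if sc.out_dir:
        for label, c in curves.items():
            c.to_csv(Path(sc.out_dir) / f"tar_{label}.csv")
    return {"fits": _family_summary(curves)}


def _run_tsr_family(sc: Scenario) -> dict:
    multipliers = sc.overrides.get("multipliers", (0.3, 0.7, 5.0))
    tsr = mwc_cluster.default_tsr()
    grid = mwc_cluster.transition_grid(tsr, n_points=100)
    curves = {}
    for mult in multipliers:
        n = _expression_to_count(mult)
        curves[f"{mult}x"] = mwc_cluster.dose_response(tsr, grid, n=n)
    return {"fits": _family_summary(curves)}


def _run_mixed(sc: Scenario) -> dict:
    """Native-level Tsr plus varied Tar, responding to the Tar ligand."""
    multipliers = sc.overrides.get("multipliers", (0.0, 0.6, 1.0, 2.0, 6.0))
    n_s = sc.overrides.get("n_s", 6)
    base = sc.overrides.get("tar_base", 6)
    tar = mwc_cluster.default_tar()
    tsr = mwc_cluster.default_tsr()
    grid = mwc_cluster.transition_grid(tar, n_points=100)
    out = {}
    for mult in multipliers:
        n_a = int(round(mult * base))
        if n_a == 0:
            spec = mwc_cluster.ClusterSpec(n_a=0, n_s=n_s, tar=tar, tsr=tsr)
        else:
            spec = mwc_cluster.ClusterSpec(n_a=n_a, n_s=n_s, tar=tar, tsr=tsr)
        # a Tar-free cluster gives a constant (ligand-independent) response
        p = np.broadcast_to(
            np.atleast_1d(mwc_cluster.p_on_mixed(spec, grid, ligand_target="Tar")),
            grid.shape,
        )
        out[f"{mult}x"] = {
            "n_a": n_a,
            "amplitude": float(p.max() - p.min()),
            "baseline": float(p[0]),
        }
    return {"responses": out}


def _run_tsr_invitro(sc: Scenario) -> dict:
    """Single Tsr trimer at the three methylation labels."""
    out = {}
    for m in ("EEEE", "QEQE", "QQQQ"):
        tsr = mwc_cluster.default_tsr(m=m)
        grid = mwc_cluster.transition_grid(tsr, n_points=100)
        curve = mwc_cluster.dose_response(tsr, grid, n=1)
        fit = hill.fit_hill(curve)
        out[m] = {
            "ligand_free_activity": float(mwc_cluster.p_on_trimer(tsr, 0.0)),
            "n_H": fit.n_H,
            "K_half": fit.K_half,
        }
    return {"methylation": out}


def _run_cooperativity_regimes(sc: Scenario) -> dict:
    """Hill coefficients of the three canonical cooperativity regimes."""
    trimer = sc.overrides.get("trimer", _REGIME_TRIMER)
    n_cluster = sc.overrides.get("n_cluster", 6)

    grid1 = mwc_cluster.transition_grid(trimer, n_points=100)
    fit_trimer = hill.fit_hill(mwc_cluster.dose_response(trimer, grid1, n=1))
    gridn = mwc_cluster.transition_grid(trimer, n_points=100)
    fit_cluster = hill.fit_hill(mwc_cluster.dose_response(trimer, gridn, n=n_cluster))

    # single-effective-site unit: same Kds, transition energy between them
    dE = sc.overrides.get("dE_single_site", -2.0)
    kd_on, kd_off = trimer.kd_on[0], trimer.kd_off[0]
    from scipy.optimize import brentq

    f = lambda L: dE + np.log1p(L / kd_off) - np.log1p(L / kd_on)
    l_half = brentq(f, 1e-8, 1e8) if f(1e-8) * f(1e8) < 0 else np.sqrt(kd_on * kd_off)
    grid_s = np.geomspace(l_half / 100.0, l_half * 100.0, 100)
    p_s = mwc_cluster.p_on_single_site(dE, kd_on, kd_off, grid_s)
    fit_single = hill.fit_hill(mwc_cluster.DoseResponse(grid_s, p_s))

    return {
        "single_site": {"n_H": fit_single.n_H, "class": hill.cooperativity_class(fit_single)},
        "single_trimer": {"n_H": fit_trimer.n_H, "class": hill.cooperativity_class(fit_trimer)},
        "cluster": {
            "n": n_cluster,
            "n_H": fit_cluster.n_H,
            "class": hill.cooperativity_class(fit_cluster),
        },
    }


# ---------------------------------------------------------------------------
# agent / continuum scenarios
# ---------------------------------------------------------------------------


def _run_rt_stats(sc: Scenario) -> dict:
    n_cells = sc.overrides.get("n_cells", 1000)
    t_end = sc.overrides.get("t_end", 100.0)
    dt = sc.overrides.get("dt", 0.005)
    params = AgentParams(dim=1)
    traj = simulate_population(
        params, n_cells=n_cells, t_end=t_end, dt=dt, signal=None, seed=sc.seed,
        sample_every=20,
    )
    stats = run_statistics(traj)
    return {
        "mean_run_interval": stats.mean_run,
        "n_events": stats.n_events,
        "diffusion": stats.diffusion,
        "diffusion_theory": params.s0**2 / (params.dim * params.lambda0),
    }


def _run_agents_vs_pks(sc: Scenario) -> dict:
    n_cells = sc.overrides.get("n_cells", 10_000)
    t_end = sc.overrides.get("t_end", 400.0)
    x_max = sc.overrides.get("x_max", 4000.0)
    # gamma0 chosen so b = lambda0/gamma0 = 4
    params = AgentParams(dim=1, s0=20.0, lambda0=1.0, gamma0=0.25)
    signal = pks.peaked_linear_signal(x_peak=x_max / 2.0, x_max=x_max, s_max=1.0)
    report = pks.compare_agents_to_pks(
        params,
        signal,
        x_max=x_max,
        n_cells=n_cells,
        t_end=t_end,
        output_times=np.array([t_end / 2.0, t_end]),
        seed=sc.seed,
    )
    if sc.out_dir:
        with open(Path(sc.out_dir) / "agents_vs_pks.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    return {
        "l1": report.l1.tolist(),
        "max_norm": report.max_norm.tolist(),
        "gradient_validity": report.gradient_validity,
        "valid_regime": report.valid_regime,
        "b": pks.consistency_b_from_turning_rate(params),
    }


def _run_pattern(name: str, sc: Scenario) -> dict:
    res = fields.run_pattern_scenario(name, seed=sc.seed, **sc.overrides)
    late = res.times >= res.times[-1] / 2.0
    speed, r2 = _fit_speed(res.times[late], res.mean_position[late, 0])
    return {
        "variance_initial": float(res.density_variance[0]),
        "variance_final": float(res.density_variance[-1]),
        "variance_ratio": float(
            res.density_variance[-1] / max(res.density_variance[0], 1e-12)
        ),
        "front_speed": speed,
        "front_speed_r2": r2,
    }


def _fit_speed(t: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, x, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((x - pred) ** 2))
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(r2)


_RUNNERS = {
    "step_response": _run_step_response,
    "double_step": _run_double_step,
    "tar_family": _run_tar_family,
    "tsr_family": _run_tsr_family,
    "mixed_tar_tsr": _run_mixed,
    "tsr_invitro": _run_tsr_invitro,
    "cooperativity_regimes": _run_cooperativity_regimes,
    "run_and_tumble_stats": _run_rt_stats,
    "agents_vs_pks": _run_agents_vs_pks,
    "liquid_aggregation": lambda sc: _run_pattern("liquid_aggregation", sc),
    "swarm_ring": lambda sc: _run_pattern("swarm_ring", sc),
    "adler_band": lambda sc: _run_pattern("adler_band", sc),
    "spiral_streams": lambda sc: _run_pattern("spiral_streams", sc),
}
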