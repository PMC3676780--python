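"""Equilibrium activity of chemoreceptor trimer-of-dimer clusters.

Two-state (MWC) statistical-mechanics model of the core chemotaxis signalling
unit, the trimer of receptor homodimers.  At a fixed methylation level a
trimer occupies eight free-energy levels: {active, inactive} x {0..3 ligands
bound}.  With sequential dissociation constants Kd1, Kd2, Kd3 for each
activity state, the ligand-free levels are E_on (active) and E_off
(inactive) and binding j ligands lowers the level by the log of the
corresponding term of the three-site binding polynomial

    P(L) = 1 + 3 L/Kd1 + 3 L^2/(Kd1 Kd2) + L^3/(Kd1 Kd2 Kd3).

Boltzmann statistics then give the activity of a single trimer as

    p_on = 1 / (1 + exp(delta_f)),
    delta_f = E_on - E_off + log[P_off(L) / P_on(L)],

and, because cluster energy is additive over trimers, an n-trimer cluster has
p_on = 1/(1 + exp(n*delta_f)).  Mixed Tar/Tsr clusters add the two types'
contributions: p_on = 1/(1 + exp(n_a*df_a + n_s*df_s)), the non-target type
held at its ligand-free free-energy difference.

Attractant convention: attractant binding inhibits the kinase, so attractant
parameter sets bind the inactive state more tightly (Kd_off < Kd_on) and
dose-response curves decrease with ligand concentration.

All free energies are in units of kB*T; all energy arithmetic is done in log
space with a stable log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logsumexp

__all__ = [
    "TrimerParams",
    "ClusterSpec",
    "DoseResponse",
    "FreeEnergyLevels",
    "free_energy_levels",
    "delta_f",
    "p_on_trimer",
    "p_on_cluster",
    "p_on_mixed",
    "dose_response",
    "default_tar",
    "default_tsr",
    "METHYLATION_OFFSETS",
]

# Ligand-free offset E_on - E_off by methylation label.  More methylation
# stabilises the active state, so the ligand-free activity orders
# EEEE < QEQE < QQQQ (the values themselves are documented package defaults;
# the parameter sets behind the published mutant experiments are not public).
METHYLATION_OFFSETS: dict[str, float] = {"EEEE": 1.0, "QEQE": -1.0, "QQQQ": -3.0}


@dataclass(frozen=True)
class TrimerParams:
    """Free energies and sequential dissociation constants for one trimer.

    ``kd_on``/``kd_off`` are the triples (Kd1, Kd2, Kd3) of the active and
    inactive state; ``e_on`` is the active ligand-free level (depends on the
    methylation label ``m``), ``e_off`` the inactive one (independent of m).
    Energies in kB*T, Kds in concentration units (arbitrary but consistent).
    """

    receptor_type: str = "Tar"
    m: str = "QEQE"
    e_on: float = -1.0
    e_off: float = 0.0
    kd_on: tuple[float, float, float] = (0.5, 0.5, 0.5)
    kd_off: tuple[float, float, float] = (0.02, 0.02, 0.02)

    def __post_init__(self) -> None:
        if len(self.kd_on) != 3 or len(self.kd_off) != 3:
            raise ValueError("kd_on and kd_off must be triples")
        if any(k <= 0 for k in self.kd_on) or any(k <= 0 for k in self.kd_off):
            raise ValueError("dissociation constants must be positive")
        if not (np.isfinite(self.e_on) and np.isfinite(self.e_off)):
            raise ValueError("free energies must be finite")

    @classmethod
    def from_dict(cls, d: dict) -> "TrimerParams":
        d = dict(d)
        for key in ("kd_on", "kd_off"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        return cls(**d)


def default_tar(m: str = "QEQE", expression: float = 1.0) -> TrimerParams:
    """Documented default Tar parameter set (attractant: MeAsp-like)."""
    return TrimerParams(
        receptor_type="Tar",
        m=m,
        e_on=METHYLATION_OFFSETS[m],
        e_off=0.0,
        kd_on=(0.5, 0.5, 0.5),
        kd_off=(0.02, 0.02, 0.02),
    )


def default_tsr(m: str = "QEQE") -> TrimerParams:
    """Documented default Tsr parameter set (attractant: serine-like)."""
    return TrimerParams(
        receptor_type="Tsr",
        m=m,
        e_on=METHYLATION_OFFSETS[m] + 0.5,
        e_off=0.0,
        kd_on=(5.0, 5.0, 5.0),
        kd_off=(0.1, 0.1, 0.1),
    )


@dataclass(frozen=True)
class ClusterSpec:
    """Composition of a coupled cluster: n_a Tar trimers and n_s Tsr trimers."""

    n_a: int
    n_s: int
    tar: TrimerParams = field(default_factory=default_tar)
    tsr: TrimerParams = field(default_factory=default_tsr)

    def __post_init__(self) -> None:
        if self.n_a < 0 or self.n_s < 0:
            raise ValueError("trimer counts must be non-negative")
        if int(self.n_a) != self.n_a or int(self.n_s) != self.n_s:
            raise ValueError("trimer counts must be integers")
        if self.n_a + self.n_s < 1:
            raise ValueError("cluster must contain at least one trimer")


@dataclass
class DoseResponse:
    """Tabulated activity p_on over an increasing ligand grid."""

    L: np.ndarray
    p_on: np.ndarray

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, float)
        self.p_on = np.asarray(self.p_on, float)
        if self.L.shape != self.p_on.shape:
            raise ValueError("L and p_on must have the same length")
        if np.any(np.diff(self.L) <= 0):
            raise ValueError("ligand grid must be strictly increasing")
        if np.any((self.p_on < 0) | (self.p_on > 1)):
            raise ValueError("p_on must lie in [0, 1]")

    def to_csv(self, path) -> None:
        pd.DataFrame({"L": self.L, "p_on": self.p_on}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DoseResponse":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


@dataclass
class FreeEnergyLevels:
    """The eight levels of one trimer at ligand level L.

    ``energy[state][j]`` is the level with j ligands bound for
    state in {"on", "off"}; ``occupied[state][j]`` is False when the level
    carries zero Boltzmann weight (ligand-bound states at L = 0), in which
    case the energy entry is NaN rather than +inf.
    """

    energy: dict[str, np.ndarray]
    occupied: dict[str, np.ndarray]


def _log_poly_terms(L: float, kds: Sequence[float]) -> np.ndarray:
    """Log Boltzmann-factor of binding j=0..3 ligands: log of the terms of
    the three-site binding polynomial 1, 3L/K1, 3L^2/K1K2, L^3/K1K2K3."""
    k1, k2, k3 = kds
    if L == 0:
        return np.array([0.0, -np.inf, -np.inf, -np.inf])
    logL = np.log(L)
    return np.array(
        [
            0.0,
            np.log(3.0) + logL - np.log(k1),
            np.log(3.0) + 2 * logL - np.log(k1) - np.log(k2),
            3 * logL - np.log(k1) - np.log(k2) - np.log(k3),
        ]
    )


def free_energy_levels(trimer: TrimerParams, L: float) -> FreeEnergyLevels:
    """Eight labeled free-energy levels (kB*T) of one trimer at ligand L."""
    if L < 0:
        raise ValueError("ligand concentration must be >= 0")
    energy: dict[str, np.ndarray] = {}
    occupied: dict[str, np.ndarray] = {}
    for state, e0, kds in (
        ("on", trimer.e_on, trimer.kd_on),
        ("off", trimer.e_off, trimer.kd_off),
    ):
        terms = _log_poly_terms(L, kds)
        occ = np.isfinite(terms)
        lev = np.where(occ, e0 - terms, np.nan)
        energy[state] = lev
        occupied[state] = occ
    return FreeEnergyLevels(energy=energy, occupied=occupied)


def delta_f(trimer: TrimerParams, L: float | np.ndarray) -> float | np.ndarray:
    """Free-energy difference (active minus inactive) per trimer, kB*T.

    delta_f = e_on - e_off + log[P_off(L)/P_on(L)] with P the three-site
    binding polynomial of each state; computed with log-sum-exp so it is
    overflow-safe at any L.
    """
    L_arr = np.atleast_1d(np.asarray(L, float))
    if np.any(L_arr < 0):
        raise ValueError("ligand concentration must be >= 0")
    out = np.empty_like(L_arr)
    for i, l in enumerate(L_arr):
        log_p_off = logsumexp(_log_poly_terms(l, trimer.kd_off))
        log_p_on = logsumexp(_log_poly_terms(l, trimer.kd_on))
        out[i] = trimer.e_on - trimer.e_off + log_p_off - log_p_on
    return out if np.ndim(L) else float(out[0])


def p_on_trimer(trimer: TrimerParams, L: float | np.ndarray) -> float | np.ndarray:
    """Activity probability of a single trimer: 1/(1 + exp(delta_f))."""
    return expit(-np.asarray(delta_f(trimer, L)))[()]


def p_on_cluster(
    n: int, trimer: TrimerParams, L: float | np.ndarray
) -> float | np.ndarray:
    """Activity of a strongly coupled cluster of n identical trimers.

    Cluster free energy is additive over trimers, so
    p_on = 1/(1 + exp(n * delta_f)).
    """
    if n < 1 or int(n) != n:
        raise ValueError("n must be a positive integer")
    return expit(-n * np.asarray(delta_f(trimer, L)))[()]


def p_on_mixed(
    spec: ClusterSpec, L: float | np.ndarray, ligand_target: str = "Tar"
) -> float | np.ndarray:
    """Activity of a mixed Tar/Tsr cluster responding to one ligand.

    The targeted receptor type sees the ligand; the other contributes its
    ligand-free free-energy difference as a constant offset.
    """
    if ligand_target not in ("Tar", "Tsr"):
        raise ValueError(f"unknown ligand target: {ligand_target!r}")
    la = L if ligand_target == "Tar" else 0.0
    ls = L if ligand_target == "Tsr" else 0.0
    df_a = np.asarray(delta_f(spec.tar, la)) if spec.n_a else 0.0
    df_s = np.asarray(delta_f(spec.tsr, ls)) if spec.n_s else 0.0
    return expit(-(spec.n_a * df_a + spec.n_s * df_s))[()]


def dose_response(
    spec: ClusterSpec | TrimerParams,
    L_grid: np.ndarray,
    n: int = 1,
    ligand_target: str = "Tar",
) -> DoseResponse:
    """Tabulate p_on over an increasing ligand grid (>= 20 points).

    Pass a ``TrimerParams`` with cluster size ``n`` for a pure-type cluster,
    or a ``ClusterSpec`` for a mixed cluster.
    """
    L_grid = np.asarray(L_grid, float)
    if L_grid.size == 0:
        raise ValueError("empty ligand grid")
    if L_grid.size < 20:
        raise ValueError("ligand grid must have at least 20 points")
    if isinstance(spec, TrimerParams):
        p = p_on_cluster(n, spec, L_grid)
    else:
        p = p_on_mixed(spec, L_grid, ligand_target)
    return DoseResponse(L=L_grid, p_on=np.asarray(p))


def transition_grid(trimer: TrimerParams, n: int = 1, n_points: int = 100) -> np.ndarray:
    """Log-spaced ligand grid spanning the activity transition of a cluster.

    Brackets the delta_f = 0 crossing (if any) with two decades of margin on
    each side; falls back to a grid around the geometric mean of the Kds.
    """
    from scipy.optimize import brentq

    lo, hi = 1e-8, 1e8
    f = lambda x: delta_f(trimer, x)
    if f(lo) * f(hi) < 0:
        l_half = brentq(f, lo, hi)
    else:
        l_half = float(np.sqrt(trimer.kd_on[0] * trimer.kd_off[0]))
    return np.geomspace(l_half / 100.0, l_half * 100.0, n_points)


def p_on_single_site(
    dE: float, kd_on: float, kd_off: float, L: float | np.ndarray
) -> float | np.ndarray:
    """Activity of a two-state unit with ONE effective ligand-binding site.

    p_on = 1/(1 + exp(dE + log((1 + L/kd_off)/(1 + L/kd_on)))); the
    low-cooperativity reference case (fitted Hill coefficient = 1 exactly,
    since the curve is a Moebius function of L).
    """
    L_arr = np.atleast_1d(np.asarray(L, float))
    if np.any(L_arr < 0):
        raise ValueError("ligand concentration must be >= 0")
    df = dE + np.log1p(L_arr / kd_off) - np.log1p(L_arr / kd_on)
    out = expit(-df)
    return out if np.ndim(L) else float(out[0])


def trimer_from_yaml(path) -> TrimerParams:
    with open(path) as fh:
        return TrimerParams.from_dict(yaml.safe_load(fh))
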