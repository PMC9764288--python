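"""Ground-truth generators: kinetic basin simulator, design libraries, protocols.

MD trajectories of an enzyme-substrate complex dwell in conformational
basins — pro-S-reactive, pro-R-reactive, and nonproductive arrangements —
with rare hops between them.  This module models that behaviour as a
continuous-time Markov chain over labeled states with Gaussian emission
distributions for the NAC descriptors (d, theta1, theta2) of each
hydrogen.  The chain's stationary distribution is available in closed form
(solve pi Q = 0), which makes every downstream estimate — NAC percentages,
predicted epimeric excess, site tallies, protocol bias — testable against
an analytic truth.  This is a deliberately minimal kinetic caricature of
MD, not a physical simulation: it reproduces basin dwell, rare-state
undersampling and the benefit of many independent replicas, nothing more.

The module also plants known signals for the other pipeline stages:
paired pro-S/pro-R design libraries with position-specific amino-acid
preferences and injected higher-energy duplicate sequences, synthetic
rotamer/pose sets with known redundancy, and an evaluator that compares
few-long-replica vs many-short-replica sampling protocols at equal total
simulated time.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq, least_squares
from scipy.sparse.csgraph import connected_components

from .errors import ConfigurationError, ReconstructionError
from .geometry import (PRO_R, PRO_S, AtomRecord, GeometrySample, NACCriteria,
                       ReactionCenter, classify_nac, evaluate_geometry)
from .pipeline import ReplicaResult, aggregate_replicas, score_samples

# Fixed scaffold geometry for reconstructed frames (Angstrom).
_FE = np.zeros(3)
_OXO = np.array([0.0, 0.0, 1.62])
_PYRROLE_R = 2.05

# Emission truncation windows: distances and angles must stay physical.
_D_RANGE = (0.5, 12.0)
_ANGLE_RANGE = (0.0, 180.0)


# ---------------------------------------------------------------------------
# emissions and basin model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryEmission:
    """Truncated-normal (mean, sd) for each NAC descriptor of one hydrogen."""

    d: tuple
    theta1: tuple
    theta2: tuple

    def draw(self, n: int, rng: np.random.Generator) -> tuple:
        out = []
        for (mean, sd), (lo, hi) in zip(
                (self.d, self.theta1, self.theta2),
                (_D_RANGE, _ANGLE_RANGE, _ANGLE_RANGE)):
            if sd < 0:
                raise ValueError("emission sd must be >= 0")
            if sd == 0:
                out.append(np.full(n, float(mean)))
            else:
                a, b = (lo - mean) / sd, (hi - mean) / sd
                out.append(stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                               size=n, random_state=rng))
        return tuple(out)


def nac_emission() -> GeometryEmission:
    """Emission centred well inside the NAC criteria box."""
    return GeometryEmission(d=(2.3, 0.1), theta1=(120.0, 5.0), theta2=(160.0, 6.0))


def nonreactive_emission() -> GeometryEmission:
    """Emission far outside the NAC box (substrate drifted off the oxo)."""
    return GeometryEmission(d=(5.0, 0.8), theta1=(115.0, 15.0), theta2=(110.0, 15.0))


def _nac_hydrogen_of_state(label: str) -> Optional[str]:
    """Which hydrogen a NAC-labeled basin holds in a reactive arrangement."""
    if label == "proS_NAC":
        return PRO_S
    if label == "proR_NAC":
        return PRO_R
    if label.startswith("NAC@"):
        return label[4:]
    return None


@dataclass
class BasinModel:
    """Labeled conformational basins with transition rates and emissions.

    ``rates`` is the generator matrix Q in 1/ps: off-diagonal entries are
    transition rates, rows sum to zero.  ``emissions`` maps state label ->
    hydrogen label -> :class:`GeometryEmission`; every state must emit for
    the same hydrogen set.  States labeled ``proS_NAC`` / ``proR_NAC`` (or
    ``NAC@<hydrogen>``) must emit NAC-classified geometry for their
    hydrogen with probability >= 0.99, checked at construction by sampling.
    """

    state_labels: tuple
    rates: np.ndarray
    emissions: dict
    initial_distribution: np.ndarray
    criteria: NACCriteria = field(default_factory=NACCriteria)

    def __post_init__(self):
        self.state_labels = tuple(self.state_labels)
        n = len(self.state_labels)
        Q = np.asarray(self.rates, dtype=float)
        if Q.shape != (n, n):
            raise ConfigurationError(f"rate matrix shape {Q.shape}, expected {(n, n)}")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ConfigurationError("off-diagonal rates must be >= 0")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-9:
            raise ConfigurationError("rate-matrix rows must sum to zero")
        self.rates = Q
        p0 = np.asarray(self.initial_distribution, dtype=float)
        if p0.shape != (n,) or np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-9:
            raise ConfigurationError("initial_distribution must be a probability "
                                     f"vector of length {n}")
        self.initial_distribution = p0
        # irreducibility: strong connectivity of the positive-rate digraph
        ncomp, _ = connected_components(off > 0, directed=True, connection="strong")
        if n > 1 and ncomp != 1:
            raise ConfigurationError("rate matrix is reducible; basin chain must "
                                     "be irreducible")
        hyd_sets = {frozenset(self.emissions[s]) for s in self.state_labels}
        if len(hyd_sets) != 1:
            raise ConfigurationError("all states must emit for the same hydrogens")
        self._validate_nac_states()

    def _validate_nac_states(self, n_draws: int = 4000, min_p: float = 0.99):
        rng = np.random.default_rng(20260921)
        for label in self.state_labels:
            hyd = _nac_hydrogen_of_state(label)
            if hyd is None:
                continue
            if hyd not in self.emissions[label]:
                raise ConfigurationError(
                    f"NAC state {label!r} lacks an emission for hydrogen {hyd!r}")
            d, t1, t2 = self.emissions[label][hyd].draw(n_draws, rng)
            frac = np.mean((d <= self.criteria.d_max)
                           & (self.criteria.theta1_min < t1)
                           & (t1 < self.criteria.theta1_max)
                           & (t2 > self.criteria.theta2_min))
            if frac < min_p:
                raise ConfigurationError(
                    f"NAC state {label!r} emits NAC geometry with probability "
                    f"{frac:.3f} < {min_p}; tighten its emission")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def hydrogen_labels(self) -> tuple:
        return tuple(sorted(self.emissions[self.state_labels[0]]))

    @classmethod
    def from_dict(cls, d: dict) -> "BasinModel":
        labels = [s["label"] for s in d["states"]]
        emissions = {
            s["label"]: {hyd: GeometryEmission(d=tuple(e["d"]),
                                               theta1=tuple(e["theta1"]),
                                               theta2=tuple(e["theta2"]))
                         for hyd, e in s["emissions"].items()}
            for s in d["states"]
        }
        return cls(state_labels=tuple(labels),
                   rates=np.asarray(d["rates"], dtype=float),
                   emissions=emissions,
                   initial_distribution=np.asarray(d["initial_distribution"],
                                                   dtype=float))

    @classmethod
    def from_yaml(cls, path) -> "BasinModel":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_basin_model(occupancies: dict, hop_rate_per_ps: float = 0.5,
                     extra_hydrogens: Sequence[str] = (),
                     initial_distribution: Optional[Sequence[float]] = None) -> BasinModel:
    """Build a basin model with prescribed stationary occupancies.

    ``occupancies`` maps state labels to target stationary probabilities
    (must sum to 1).  Off-diagonal rates are ``hop_rate_per_ps * pi_j``,
    which has exactly the requested stationary distribution and lets one
    parameter set the overall hopping speed.  Emissions follow the label
    convention of :func:`_nac_hydrogen_of_state`; every other state emits
    nonreactive geometry for every hydrogen.  The initial distribution
    defaults to the stationary one (independent replica initialization
    relaxes into a random basin with its equilibrium weight).
    """
    labels = tuple(occupancies)
    pi = np.array([occupancies[s] for s in labels], dtype=float)
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ConfigurationError("occupancies must be positive and sum to 1")
    if hop_rate_per_ps <= 0:
        raise ConfigurationError("hop_rate_per_ps must be positive")
    n = len(labels)
    Q = hop_rate_per_ps * np.tile(pi, (n, 1))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    hydrogens = {PRO_S, PRO_R, *extra_hydrogens}
    hydrogens |= {h for s in labels if (h := _nac_hydrogen_of_state(s))}
    emissions = {}
    for label in labels:
        reactive_h = _nac_hydrogen_of_state(label)
        emissions[label] = {
            h: (nac_emission() if h == reactive_h else nonreactive_emission())
            for h in sorted(hydrogens)
        }
    p0 = pi if initial_distribution is None else np.asarray(initial_distribution, float)
    return BasinModel(state_labels=labels, rates=Q, emissions=emissions,
                      initial_distribution=p0)


# ---------------------------------------------------------------------------
# analytic oracle and Gillespie sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTruth:
    """Stationary occupancies and the epimeric excess they imply."""

    pi: dict                    # state label -> probability
    true_ee: Optional[float]

    @classmethod
    def from_model(cls, model: BasinModel) -> "SyntheticTruth":
        pi = stationary_distribution(model)
        pid = dict(zip(model.state_labels, pi))
        ps = sum(p for s, p in pid.items() if _nac_hydrogen_of_state(s) == PRO_S)
        pr = sum(p for s, p in pid.items() if _nac_hydrogen_of_state(s) == PRO_R)
        ee = None if ps + pr == 0 else 100.0 * (ps - pr) / (ps + pr)
        return cls(pi=pid, true_ee=ee)


def stationary_distribution(model: BasinModel) -> np.ndarray:
    """Solve pi Q = 0, sum(pi) = 1 — the analytic oracle for recovery tests."""
    Q = model.rates
    _, _, vt = np.linalg.svd(Q.T)
    pi = vt[-1]
    pi = np.abs(pi) / np.abs(pi).sum()
    residual = float(np.max(np.abs(pi @ Q)))
    if residual > 1e-10:
        raise ConfigurationError(f"stationary solve residual {residual:.2e}; "
                                 "is the chain irreducible?")
    return pi


@dataclass
class StatePath:
    """A Gillespie realization: jump times (starting at 0) and visited states."""

    times: np.ndarray           # ps, times[0] == 0
    states: np.ndarray          # state indices, same length
    duration: float             # ps

    def state_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.duration):
            raise ValueError("sample time outside [0, duration]")
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.states[idx]

    def occupancy(self) -> np.ndarray:
        """Fraction of total time spent in each state."""
        bounds = np.append(self.times, self.duration)
        dwell = np.diff(bounds)
        occ = np.zeros(int(self.states.max()) + 1)
        np.add.at(occ, self.states, dwell)
        return occ / self.duration


def simulate_ctmc(model: BasinModel, duration_ps: float, seed,
                  initial_state: Optional[int] = None) -> StatePath:
    """Exact Gillespie simulation of the basin chain.

    Holding times are exponential with the state's total exit rate; jump
    targets are drawn proportionally to the outgoing rates.  Deterministic
    given ``seed``; the initial state is drawn from the model's initial
    distribution unless given explicitly.
    """
    if duration_ps <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = model.n_states
    exit_rate = -np.diag(model.rates)
    # per-state cumulative jump distributions (rows with zero exit are absorbing)
    cum = np.zeros((n, n))
    for i in range(n):
        if exit_rate[i] > 0:
            p = model.rates[i].copy()
            p[i] = 0.0
            cum[i] = np.cumsum(p / exit_rate[i])
    state = (int(initial_state) if initial_state is not None
             else int(rng.choice(n, p=model.initial_distribution)))
    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        k = exit_rate[state]
        if k <= 0:
            break
        t += rng.exponential(1.0 / k)
        if t >= duration_ps:
            break
        state = int(np.searchsorted(cum[state], rng.random(), side="right"))
        times.append(t)
        states.append(state)
    return StatePath(times=np.array(times), states=np.array(states, dtype=int),
                     duration=float(duration_ps))


def emit_geometries(path: StatePath, model: BasinModel, sample_times, seed) -> dict:
    """Draw (d, theta1, theta2) per hydrogen at each sample time.

    Returns ``{hydrogen_label: {"d": ..., "theta1": ..., "theta2": ...,
    "state": ...}}`` with arrays aligned to ``sample_times``.  Deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    sample_times = np.asarray(sample_times, dtype=float)
    idx = path.state_at(sample_times)
    out = {h: {"d": np.empty(idx.size), "theta1": np.empty(idx.size),
               "theta2": np.empty(idx.size), "state": idx.copy()}
           for h in model.hydrogen_labels}
    for s in range(model.n_states):
        mask = idx == s
        if not mask.any():
            continue
        label = model.state_labels[s]
        for h in model.hydrogen_labels:
            d, t1, t2 = model.emissions[label][h].draw(int(mask.sum()), rng)
            out[h]["d"][mask] = d
            out[h]["theta1"][mask] = t1
            out[h]["theta2"][mask] = t2
    return out


def geometries_to_samples(emitted: dict, replica_id: str = "replica") -> list:
    """Flatten :func:`emit_geometries` output into GeometrySample objects."""
    samples = []
    for h, arrs in emitted.items():
        for i in range(arrs["d"].size):
            samples.append(GeometrySample(
                hydrogen_label=h, d=float(arrs["d"][i]),
                theta1=float(arrs["theta1"][i]), theta2=float(arrs["theta2"][i]),
                frame_index=i, replica_id=replica_id))
    return samples


# ---------------------------------------------------------------------------
# sampling protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolSpec:
    """Replica-count and timing layout of one sampling protocol (all ps)."""

    n_replicas: int
    warmup_ps: float
    equilibration_ps: float
    production_ps: float
    snapshot_interval_ps: float
    nac_eval_interval_ps: float
    name: str = "protocol"

    def __post_init__(self):
        for f in ("warmup_ps", "equilibration_ps", "production_ps",
                  "snapshot_interval_ps", "nac_eval_interval_ps"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{f} must be >= 0")
        if self.n_replicas < 1:
            raise ConfigurationError("n_replicas must be >= 1")
        if self.nac_eval_interval_ps > self.production_ps:
            raise ConfigurationError("NAC eval interval exceeds production length")

    @property
    def production_start_ps(self) -> float:
        return self.warmup_ps + self.equilibration_ps

    @property
    def total_ps(self) -> float:
        return self.production_start_ps + self.production_ps

    def sample_times(self, interval: float) -> np.ndarray:
        """Production-phase sample times, inclusive of the production start.

        ``floor(production/interval) + 1`` times: t0, t0+dt, ..., so a
        50 ps production at 5 ps spacing yields 11 samples.
        """
        n = int(np.floor(self.production_ps / interval + 1e-9)) + 1
        return self.production_start_ps + interval * np.arange(n)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(**d)


#: Few-long preset: 5 replicas, 2 ns equilibration, 20 ns production,
#: snapshots every 50 ps, NAC evaluation every 1 ps.
LONG_PROTOCOL = ProtocolSpec(n_replicas=5, warmup_ps=30.0,
                             equilibration_ps=2000.0, production_ps=20000.0,
                             snapshot_interval_ps=50.0, nac_eval_interval_ps=1.0,
                             name="long_5x20ns")

#: Many-short preset: 50 replicas, 30 ps warm-up, 20 ps equilibration,
#: 50 ps production, snapshots every 5 ps, NAC evaluation every 20 fs.
SHORT_PROTOCOL = ProtocolSpec(n_replicas=50, warmup_ps=30.0,
                              equilibration_ps=20.0, production_ps=50.0,
                              snapshot_interval_ps=5.0, nac_eval_interval_ps=0.02,
                              name="short_50x100ps")


def equal_time_protocols(total_production_ps: float = 5000.0,
                         eval_interval_ps: float = 1.0) -> tuple:
    """Few-long vs many-short protocol pair with equal total production time.

    Both arms evaluate NACs at the same interval so they differ only in how
    the fixed simulation budget is split across independent replicas.
    """
    long = ProtocolSpec(n_replicas=5, warmup_ps=30.0, equilibration_ps=20.0,
                        production_ps=total_production_ps / 5,
                        snapshot_interval_ps=50.0,
                        nac_eval_interval_ps=eval_interval_ps,
                        name="long_5_replicas")
    short = ProtocolSpec(n_replicas=50, warmup_ps=30.0, equilibration_ps=20.0,
                         production_ps=total_production_ps / 50,
                         snapshot_interval_ps=5.0,
                         nac_eval_interval_ps=eval_interval_ps,
                         name="short_50_replicas")
    return long, short


def simulate_replica_samples(model: BasinModel, protocol: ProtocolSpec, seed,
                             replica_id: str = "replica",
                             criteria: Optional[NACCriteria] = None) -> ReplicaResult:
    """One replica: simulate, discard warm-up/equilibration, emit, classify.

    Warm-up and equilibration are simulated (the chain evolves through
    them) but only production-phase samples are scored.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    path_seed, emit_seed = ss.spawn(2)
    path = simulate_ctmc(model, protocol.total_ps, path_seed)
    times = protocol.sample_times(protocol.nac_eval_interval_ps)
    emitted = emit_geometries(path, model, times, emit_seed)
    return score_samples(geometries_to_samples(emitted, replica_id),
                         criteria=criteria or model.criteria,
                         replica_id=replica_id)


def simulate_protocol(model: BasinModel, protocol: ProtocolSpec, seed,
                      criteria: Optional[NACCriteria] = None) -> list:
    """All replicas of one protocol, hierarchically seeded."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    return [simulate_replica_samples(model, protocol, child,
                                     replica_id=f"replica_{i:03d}",
                                     criteria=criteria)
            for i, child in enumerate(ss.spawn(protocol.n_replicas))]


# ---------------------------------------------------------------------------
# coordinate reconstruction and PDB output
# ---------------------------------------------------------------------------

def _hydrogen_position(d: float, theta1: float, phi) -> np.ndarray:
    """Hydrogen position(s) realizing (d, theta1) around the Fe-O axis.

    theta1 is measured at the oxygen between the rays O->Fe and O->H, so
    the direction makes angle theta1 with -z; phi is the free azimuth.
    Accepts scalar or array phi.
    """
    phi = np.asarray(phi, dtype=float)
    st, ct = np.sin(np.radians(theta1)), np.cos(np.radians(theta1))
    dirs = np.stack([st * np.cos(phi), st * np.sin(phi),
                     np.full_like(phi, -ct)], axis=-1)
    return _OXO + d * dirs


def _angle_at(vertex: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized angle (degrees) at ``vertex`` between rays to a and b."""
    u = a - vertex
    w = b - vertex
    cross = np.linalg.norm(np.cross(u, w), axis=-1)
    dot = np.sum(u * w, axis=-1)
    return np.degrees(np.arctan2(cross, dot))


def reconstruct_coordinates(geometries: dict, seed=0) -> list:
    """Embed per-hydrogen (d, theta1, theta2) triples into frame coordinates.

    ``geometries`` maps ``pro_S`` and ``pro_R`` to (d, theta1, theta2)
    triples.  The frame holds Fe at the origin, the four pyrrole nitrogens
    as a square in z=0, the oxo at (0, 0, 1.62), one shared target carbon
    and the two hydrogens.  The pro-S triple is honored by construction
    (carbon placed exactly on the theta2 cone of the pro-S hydrogen); the
    pro-R azimuth is then root-found so its theta2 also matches.  Free
    azimuths are drawn from the seeded stream; infeasible triples raise
    :class:`ReconstructionError`.
    """
    for lab in (PRO_S, PRO_R):
        if lab not in geometries:
            raise ReconstructionError(f"missing geometry for hydrogen {lab!r}")
    dS, t1S, t2S = (float(v) for v in geometries[PRO_S])
    dR, t1R, t2R = (float(v) for v in geometries[PRO_R])
    for name, d, t1, t2 in (("pro_S", dS, t1S, t2S), ("pro_R", dR, t1R, t2R)):
        if d <= 1e-6:
            raise ReconstructionError(f"{name}: O-H distance {d} must be positive")
        for aname, v in (("theta1", t1), ("theta2", t2)):
            if not (0.0 <= v <= 180.0):
                raise ReconstructionError(f"{name}: {aname}={v} outside [0, 180]")
        # H collides with Fe iff d equals the Fe-O length and theta1 = 0
        h_fe_sq = d * d + _OXO[2] ** 2 - 2 * _OXO[2] * d * np.cos(np.radians(t1))
        if h_fe_sq <= 1e-12:
            raise ReconstructionError(f"{name}: hydrogen coincides with the iron")

    rng = np.random.default_rng(seed)

    def carbon_for(h_s, psi, t_len):
        """A carbon exactly on the theta2_S cone of h_s (any psi, t_len > 0)."""
        u = (_OXO - h_s)
        u = u / np.linalg.norm(u)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, u)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        rad = np.radians(t2S)
        cdir = np.cos(rad) * u + np.sin(rad) * (np.cos(psi) * e1 + np.sin(psi) * e2)
        return h_s + t_len * cdir

    def theta2R_error(c, phi):
        h = _hydrogen_position(dR, t1R, phi)
        if np.linalg.norm(h - c) <= 1e-6 or np.linalg.norm(h - _OXO) <= 1e-6:
            return 1e3
        return float(_angle_at(h, c, _OXO) - t2R)

    # The free parameters are the two hydrogen azimuths, the carbon azimuth
    # around the H_S -> O axis and its distance from H_S.  The pro-S triple
    # and the carbon's theta2_S cone membership hold exactly by construction;
    # the one remaining equation (theta2 of pro-R) is scanned on a broadcast
    # grid over all four parameters, then polished by brentq/least-squares.
    phi_s_grid = rng.uniform(0, 2 * np.pi) + np.linspace(0, 2 * np.pi, 13)[:-1]
    psi_grid = rng.uniform(0, 2 * np.pi) + np.linspace(0, 2 * np.pi, 13)[:-1]
    t_grid = np.exp(np.linspace(np.log(0.7), np.log(8.0), 8))
    phi_r_grid = np.linspace(0.0, 2 * np.pi, 121)

    h_s_grid = _hydrogen_position(dS, t1S, phi_s_grid)            # (nS, 3)
    u = _OXO - h_s_grid
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    helper = np.where(np.abs(u[:, :1]) > 0.9, [0.0, 1.0, 0.0], [1.0, 0.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
    e2 = np.cross(u, e1)
    rad_s = np.radians(t2S)
    cdir = (np.cos(rad_s) * u[:, None, :]
            + np.sin(rad_s) * (np.cos(psi_grid)[None, :, None] * e1[:, None, :]
                               + np.sin(psi_grid)[None, :, None] * e2[:, None, :]))
    c_grid = (h_s_grid[:, None, None, :]
              + t_grid[None, None, :, None] * cdir[:, :, None, :])  # (nS,npsi,nt,3)
    h_r_grid = _hydrogen_position(dR, t1R, phi_r_grid)              # (nR, 3)
    v1 = c_grid[:, :, :, None, :] - h_r_grid                        # to carbon
    v2 = _OXO - h_r_grid                                            # to oxygen
    cross = np.linalg.norm(np.cross(v1, v2), axis=-1)
    dot = np.sum(v1 * v2, axis=-1)
    f = np.degrees(np.arctan2(cross, dot)) - t2R                    # (nS,npsi,nt,nR)

    solution = None
    sign_flip = np.diff(np.sign(f), axis=-1) != 0
    if sign_flip.any():
        iS, ip, it, ir = np.unravel_index(
            int(np.argmax(sign_flip)), sign_flip.shape)
        h_s = h_s_grid[iS]
        c = c_grid[iS, ip, it]
        phiR = brentq(lambda p: theta2R_error(c, p),
                      phi_r_grid[ir], phi_r_grid[ir + 1], xtol=1e-14)
        if abs(theta2R_error(c, phiR)) < 1e-8:
            solution = (h_s, c, _hydrogen_position(dR, t1R, phiR))
    if solution is None:
        # no bracketing cell: polish from the best grid point; the carbon
        # stays on the theta2_S cone so the pro-S triple remains exact
        iS, ip, it, ir = np.unravel_index(int(np.argmin(np.abs(f))), f.shape)

        def residual(x):
            phiR, phiS, psi, log_t = x
            c = carbon_for(_hydrogen_position(dS, t1S, phiS), psi, np.exp(log_t))
            return [theta2R_error(c, phiR)]

        x0 = [phi_r_grid[ir], phi_s_grid[iS], psi_grid[ip], np.log(t_grid[it])]
        res = least_squares(residual, x0=x0, xtol=1e-15, ftol=1e-15)
        if abs(res.fun[0]) < 1e-8:
            h_s = _hydrogen_position(dS, t1S, res.x[1])
            c = carbon_for(h_s, res.x[2], np.exp(res.x[3]))
            solution = (h_s, c, _hydrogen_position(dR, t1R, res.x[0]))
    if solution is None:
        raise ReconstructionError(
            f"no shared-carbon embedding found for pro_S=({dS}, {t1S}, {t2S}), "
            f"pro_R=({dR}, {t1R}, {t2R}): theta2 constraints are jointly "
            "unreachable from the hydrogen circles")
    h_s, c, h_r = solution

    def atom(serial, name, resname, resseq, element, coord):
        return AtomRecord(serial=serial, name=name, resname=resname, chain="A",
                          resseq=resseq, element=element, coord=coord)

    n_coords = [np.array([_PYRROLE_R, 0, 0]), np.array([0, _PYRROLE_R, 0]),
                np.array([-_PYRROLE_R, 0, 0]), np.array([0, -_PYRROLE_R, 0])]
    return [
        atom(1, "FE", "HEM", 1, "FE", _FE),
        atom(2, "NA", "HEM", 1, "N", n_coords[0]),
        atom(3, "NB", "HEM", 1, "N", n_coords[1]),
        atom(4, "NC", "HEM", 1, "N", n_coords[2]),
        atom(5, "ND", "HEM", 1, "N", n_coords[3]),
        atom(6, "O1", "HEM", 1, "O", _OXO),
        atom(7, "C6", "CPT", 2, "C", c),
        atom(8, "H6R", "CPT", 2, "H", h_r),
        atom(9, "H6S", "CPT", 2, "H", h_s),
    ]


def reconstruction_selection() -> dict:
    """Selection-spec dict matching frames written by this module."""
    return {
        "fe": {"name": "FE"}, "oxo": {"name": "O1"},
        "c_target": {"name": "C6"},
        "h_pro_r": {"name": "H6R"}, "h_pro_s": {"name": "H6S"},
        "pyrrole": [{"name": "NA"}, {"name": "NB"}, {"name": "NC"},
                    {"name": "ND"}],
        "allow_virtual_oxo": False,
    }


def _format_pdb_atom(a: AtomRecord) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (f"HETATM{a.serial:5d} {name}{'':1s}{a.resname:>3s} {a.chain}"
            f"{a.resseq:4d}    {a.coord[0]:8.3f}{a.coord[1]:8.3f}"
            f"{a.coord[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}")


def write_frames_pdb(frames: Sequence[Sequence[AtomRecord]], path) -> None:
    """Write reconstructed frames as a multi-model PDB file."""
    lines = []
    for i, atoms in enumerate(frames, start=1):
        lines.append(f"MODEL     {i:4d}")
        lines.extend(_format_pdb_atom(a) for a in atoms)
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_synthetic_trajectory(model: BasinModel, protocol: ProtocolSpec, seed,
                               out_dir) -> dict:
    """Write one multi-model PDB per replica plus a JSON truth sidecar.

    Frames are snapshots during the production phase only (warm-up and
    equilibration are simulated but not written), taken at the protocol's
    snapshot interval and including the production-start frame.  The
    sidecar records the seed, the stationary occupancies and the analytic
    epimeric excess so recovery can be checked without the model object.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = SyntheticTruth.from_model(model)
    ss = np.random.SeedSequence(seed)
    paths = []
    n_frames = None
    for i, child in enumerate(ss.spawn(protocol.n_replicas)):
        path_seed, emit_seed, recon_seed = child.spawn(3)
        state_path = simulate_ctmc(model, protocol.total_ps, path_seed)
        times = protocol.sample_times(protocol.snapshot_interval_ps)
        emitted = emit_geometries(state_path, model, times, emit_seed)
        recon_rng = np.random.default_rng(recon_seed)
        frames = []
        for j in range(times.size):
            geo = {h: (emitted[h]["d"][j], emitted[h]["theta1"][j],
                       emitted[h]["theta2"][j])
                   for h in (PRO_S, PRO_R)}
            frames.append(reconstruct_coordinates(geo, seed=recon_rng))
        n_frames = len(frames)
        pdb_path = out / f"replica_{i:02d}.pdb"
        write_frames_pdb(frames, pdb_path)
        paths.append(pdb_path)
    sidecar = {
        "seed": int(seed) if np.isscalar(seed) else None,
        "states": list(model.state_labels),
        "pi": truth.pi,
        "true_ee": truth.true_ee,
        "protocol": asdict(protocol),
        "n_replicas": protocol.n_replicas,
        "frames_per_replica": n_frames,
        "selection": reconstruction_selection(),
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(sidecar, indent=2))
    return {"replica_paths": paths, "truth_path": truth_path, "truth": truth}


# ---------------------------------------------------------------------------
# design-library generator
# ---------------------------------------------------------------------------

def make_position_distributions(positions: Sequence[int],
                                biases: Optional[dict] = None) -> dict:
    """Uniform per-position amino-acid distributions with optional biases.

    ``biases`` maps position -> {aa: probability}; remaining mass at a
    position is spread uniformly over the unbiased amino acids.
    """
    from .enrichment import AA_ALPHABET
    biases = biases or {}
    dists = {}
    for p in positions:
        b = biases.get(p, {})
        mass = sum(b.values())
        if mass > 1.0 + 1e-9 or any(v < 0 for v in b.values()):
            raise ConfigurationError(f"position {p}: bias mass {mass} invalid")
        rest = [aa for aa in AA_ALPHABET if aa not in b]
        fill = (1.0 - mass) / len(rest) if rest else 0.0
        dists[p] = {aa: b.get(aa, fill) for aa in AA_ALPHABET}
    return dists


def _default_energy(residues: dict, rng: np.random.Generator) -> float:
    """Boltzmann-flavoured score: base + stable per-residue offsets + noise."""
    base = 130.0
    offset = sum((zlib.crc32(f"{p}:{aa}".encode()) % 1000) / 500.0 - 1.0
                 for p, aa in residues.items())
    return base + offset + float(rng.normal(0.0, 0.5))


def generate_design_library(positions: Sequence[int], dist_s: dict, dist_r: dict,
                            n: int = 2000, duplicate_rate: float = 0.1,
                            seed=0, out_dir=None, energy_model=None,
                            unique_base: bool = False) -> tuple:
    """Sample paired pro-S / pro-R design ensembles with planted preferences.

    Each mode draws ``n`` base records, residues sampled independently per
    position from that mode's distribution, then ``round(duplicate_rate*n)``
    duplicate records are appended that copy a random base record with a
    strictly higher energy (so lowest-energy dedup keeps the original).
    With ``unique_base`` the base sequences are resampled to be pairwise
    distinct, making the injected duplicates the *only* redundancy.

    Returns ``(ensemble_s, ensemble_r, info)`` where ``info`` records the
    injected duplicate ids per mode; writes ``pro_S.tsv`` / ``pro_R.tsv``
    under ``out_dir`` when given.
    """
    from .enrichment import AA_ALPHABET, DesignEnsemble, DesignRecord, save_designs

    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if duplicate_rate < 0:
        raise ConfigurationError("duplicate_rate must be >= 0")
    positions = tuple(positions)
    energy_model = energy_model or _default_energy
    rng = np.random.default_rng(seed)
    info = {}
    ensembles = {}
    for mode, dists in (("pro_S", dist_s), ("pro_R", dist_r)):
        probs = {}
        for p in positions:
            if p not in dists:
                raise ConfigurationError(f"{mode}: no distribution for position {p}")
            vec = np.array([dists[p].get(aa, 0.0) for aa in AA_ALPHABET])
            if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"{mode}: distribution at position {p} must sum to 1")
            probs[p] = vec / vec.sum()
        # vectorized draw: one categorical sample per (record, position)
        seqs: list[tuple] = []
        seen: set = set()
        needed = n
        for _ in range(50):
            draws = {p: rng.choice(20, size=needed, p=probs[p])
                     for p in positions}
            for i in range(needed):
                key = tuple(AA_ALPHABET[draws[p][i]] for p in positions)
                if unique_base:
                    if key in seen:
                        continue
                    seen.add(key)
                seqs.append(key)
            needed = n - len(seqs)
            if needed == 0:
                break
        else:
            raise ConfigurationError(
                f"{mode}: could not draw {n} distinct sequences; "
                "distributions too concentrated")
        records = []
        for i, key in enumerate(seqs):
            residues = dict(zip(positions, key))
            records.append(DesignRecord(design_id=f"{mode}_{i:05d}",
                                        residues=residues,
                                        energy=energy_model(residues, rng)))
        n_dup = int(round(duplicate_rate * n))
        dup_ids = []
        dup_sources = {}
        for j in range(n_dup):
            src = records[int(rng.integers(0, n))]
            did = f"{mode}_dup{j:05d}"
            records.append(DesignRecord(
                design_id=did, residues=dict(src.residues),
                energy=src.energy + float(rng.uniform(0.5, 3.0))))
            dup_ids.append(did)
            dup_sources[did] = src.design_id
        ensembles[mode] = DesignEnsemble(mode=mode, designable_positions=positions,
                                         records=records, deduped=False)
        info[mode] = {"n_base": n, "duplicate_ids": dup_ids,
                      "duplicate_sources": dup_sources,
                      "n_unique_base": len({r.sequence_key(positions)
                                            for r in records[:n]})}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_designs(ensembles["pro_S"], out / "pro_S.tsv")
        save_designs(ensembles["pro_R"], out / "pro_R.tsv")
    return ensembles["pro_S"], ensembles["pro_R"], info


# ---------------------------------------------------------------------------
# synthetic pose sets
# ---------------------------------------------------------------------------

def generate_pose_set(n_distinct: int = 50, n_total: int = 120,
                      n_atoms: int = 5, separation: float = 0.6,
                      jitter: float = 0.05, seed=0) -> list:
    """Rotamer-like pose set with known redundancy.

    ``n_distinct`` well-separated poses (pairwise RMSD >= separation) come
    first, followed by near-duplicates of random originals displaced by an
    RMSD well below ``separation`` (about ``jitter``), so a greedy overlap
    pass at any threshold between the two scales keeps exactly the
    originals.
    """
    from .pose_cluster import LigandPose, pose_rmsd

    if n_total < n_distinct:
        raise ConfigurationError("n_total must be >= n_distinct")
    rng = np.random.default_rng(seed)
    names = tuple(f"C{i+1}" for i in range(n_atoms))
    originals = []
    while len(originals) < n_distinct:
        center = rng.uniform(-8, 8, size=3)
        coords = center + rng.normal(0, 1.0, size=(n_atoms, 3))
        pose = LigandPose(pose_id=f"pose_{len(originals):03d}", atom_names=names,
                          coords=coords, energy=float(rng.normal(-8, 1.0)))
        if all(pose_rmsd(pose, o) >= separation for o in originals):
            originals.append(pose)
    copies = []
    for j in range(n_total - n_distinct):
        src = originals[int(rng.integers(0, n_distinct))]
        disp = rng.normal(0, 1.0, size=(n_atoms, 3))
        disp *= jitter / max(np.sqrt(np.mean(np.sum(disp ** 2, axis=1))), 1e-12)
        copies.append(LigandPose(pose_id=f"copy_{j:03d}", atom_names=names,
                                 coords=src.coords + disp,
                                 energy=src.energy + float(rng.uniform(0.1, 1.0))))
    return originals + copies


# ---------------------------------------------------------------------------
# protocol evaluation
# ---------------------------------------------------------------------------

def evaluate_protocol(model: BasinModel, protocols: Sequence[ProtocolSpec],
                      n_repeats: int = 10, seed=0,
                      criteria: Optional[NACCriteria] = None):
    """Bias, RMSE and rare-state detection of each protocol on one model.

    Each repeat runs the full generate -> score -> aggregate pipeline with
    hierarchically split seeds.  The minority NAC state is the less
    occupied of the pro-S / pro-R basins; its detection rate is the
    fraction of repeats in which at least one minority-NAC sample occurred.
    Repeats where neither hydrogen ever samples a NAC have an undefined
    e.e. and are excluded from bias/RMSE (counted in ``n_ee_defined``).
    """
    import pandas as pd

    if n_repeats < 10:
        raise ValueError("n_repeats must be >= 10")
    truth = SyntheticTruth.from_model(model)
    pi_s = sum(p for s, p in truth.pi.items()
               if _nac_hydrogen_of_state(s) == PRO_S)
    pi_r = sum(p for s, p in truth.pi.items()
               if _nac_hydrogen_of_state(s) == PRO_R)
    minority = PRO_R if pi_s >= pi_r else PRO_S
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rows = []
    for proto, proto_ss in zip(protocols, ss.spawn(len(protocols))):
        ees, detected = [], 0
        for rep_ss in proto_ss.spawn(n_repeats):
            results = simulate_protocol(model, proto, rep_ss, criteria=criteria)
            summary = aggregate_replicas(results)
            if any(r.nac_count.get(minority, 0) > 0 for r in results):
                detected += 1
            if summary.ee_pred is not None:
                ees.append(summary.ee_pred)
        ees = np.array(ees)
        bias = float(np.mean(ees - truth.true_ee)) if ees.size else np.nan
        rmse = float(np.sqrt(np.mean((ees - truth.true_ee) ** 2))) if ees.size else np.nan
        rows.append({
            "protocol": proto.name, "n_replicas": proto.n_replicas,
            "production_ps": proto.production_ps,
            "total_production_ps": proto.n_replicas * proto.production_ps,
            "n_repeats": n_repeats, "n_ee_defined": int(ees.size),
            "mean_ee": float(np.mean(ees)) if ees.size else np.nan,
            "true_ee": truth.true_ee, "bias": bias, "rmse": rmse,
            "minority_label": minority,
            "detection_rate": detected / n_repeats,
        })
    return pd.DataFrame(rows)
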