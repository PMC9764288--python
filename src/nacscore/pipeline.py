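"""Trajectory scoring: from multi-model PDB files to predicted epimeric excess.

The pipeline reads trajectory frames, resolves the reaction-center atoms in
each frame from a role-based selection, measures and classifies the NAC
descriptors for every hydrogen of interest, and aggregates replicas into a
stereoselectivity prediction

    ee_pred = 100 * (NAC_S - NAC_R) / (NAC_S + NAC_R)

where NAC_S and NAC_R are the percentages of evaluated frames obeying the
pro-S and pro-R NAC criteria.  When neither hydrogen ever samples a NAC the
prediction is *undefined* (returned as ``None``), never 0: a value of 0
would claim a perfectly racemic outcome that the data cannot support.

Uncertainty is quantified by a replica-level bootstrap, resampling whole
replicas with replacement and recomputing the pooled prediction.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, SelectionError, StructureMismatchError,
                     TrajectoryParseError)
from .geometry import (PRO_R, PRO_S, AtomRecord, GeometrySample, NACCriteria,
                       ReactionCenter, classify_nac, evaluate_geometry,
                       heme_plane_normal, place_virtual_oxo)

__all__ = [
    "TrajectoryFrame", "AtomMatcher", "SelectionSpec", "ReplicaResult",
    "NACSummary", "OccupancyMap", "SiteTally",
    "read_multimodel_pdb", "resolve_reaction_center", "score_trajectory",
    "score_samples", "predicted_ee", "aggregate_replicas", "bootstrap_ci",
    "occupancy_map", "occupancy_maps", "tally_sites", "apply_reactivity_filter",
    "samples_to_dataframe",
]


# ---------------------------------------------------------------------------
# frames and selections
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryFrame:
    """One frame of a trajectory; atoms are looked up by (chain, resseq, name)."""

    frame_index: int
    atoms: list[AtomRecord]
    time: Optional[float] = None  # ps

    def __post_init__(self):
        self._index = {}
        for a in self.atoms:
            if a.key in self._index:
                raise StructureMismatchError(
                    f"duplicate atom key {a.key} in frame {self.frame_index}")
            self._index[a.key] = a

    @property
    def keys(self) -> frozenset:
        return frozenset(self._index)


@dataclass(frozen=True)
class AtomMatcher:
    """Matches atoms by name, optionally restricted to a chain and residue."""

    name: str
    chain: Optional[str] = None
    resseq: Optional[int] = None

    def matches(self, atom: AtomRecord) -> bool:
        return (atom.name == self.name
                and (self.chain is None or atom.chain == self.chain)
                and (self.resseq is None or atom.resseq == self.resseq))

    @classmethod
    def from_dict(cls, d) -> "AtomMatcher":
        if isinstance(d, str):
            return cls(name=d)
        return cls(name=d["name"], chain=d.get("chain"), resseq=d.get("resseq"))


@dataclass
class SelectionSpec:
    """Role-to-atom mapping for resolving the reaction center in each frame.

    ``pyrrole`` (four matchers) is only required when ``allow_virtual_oxo``
    is set and the structure carries no explicit ferryl oxygen: the oxo is
    then synthesized along the heme-plane normal, oriented toward the
    target carbon (the substrate side of the heme).
    """

    fe: AtomMatcher
    c_target: AtomMatcher
    h_pro_r: AtomMatcher
    h_pro_s: AtomMatcher
    oxo: Optional[AtomMatcher] = None
    extra_h: dict = field(default_factory=dict)     # site label -> AtomMatcher
    pyrrole: Optional[Sequence[AtomMatcher]] = None
    allow_virtual_oxo: bool = False
    oxo_bond_length: float = 1.62

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionSpec":
        m = AtomMatcher.from_dict
        return cls(
            fe=m(d["fe"]), c_target=m(d["c_target"]),
            h_pro_r=m(d["h_pro_r"]), h_pro_s=m(d["h_pro_s"]),
            oxo=m(d["oxo"]) if d.get("oxo") else None,
            extra_h={k: m(v) for k, v in d.get("extra_h", {}).items()},
            pyrrole=[m(v) for v in d["pyrrole"]] if d.get("pyrrole") else None,
            allow_virtual_oxo=bool(d.get("allow_virtual_oxo", False)),
            oxo_bond_length=float(d.get("oxo_bond_length", 1.62)),
        )


@dataclass
class ReplicaResult:
    """Classified samples and per-label NAC counts for one replica."""

    replica_id: str
    frames_evaluated: int
    nac_count: dict          # hydrogen label -> count
    samples: list            # of GeometrySample
    used_virtual_oxo: bool = False

    def nac_pct(self, label: str) -> float:
        if self.frames_evaluated == 0:
            return 0.0
        return 100.0 * self.nac_count.get(label, 0) / self.frames_evaluated


@dataclass
class NACSummary:
    """Pooled-frame NAC percentages and the epimeric-excess prediction."""

    nac_s_pct: float
    nac_r_pct: float
    ee_pred: Optional[float]
    n_replicas: int
    n_frames_total: int
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_level: Optional[float] = None
    per_replica: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "nac_s_pct": self.nac_s_pct, "nac_r_pct": self.nac_r_pct,
            "ee_pred": self.ee_pred, "n_replicas": self.n_replicas,
            "n_frames_total": self.n_frames_total,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "ci_level": self.ci_level, "per_replica": self.per_replica,
        }


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def read_multimodel_pdb(path) -> list[TrajectoryFrame]:
    """Parse a multi-model PDB file into a list of frames.

    Frames are MODEL/ENDMDL blocks (a file without MODEL records yields one
    frame).  ATOM and HETATM records are both kept, so heme and ligand atoms
    are available for selection.  All frames must expose the same
    (chain, resseq, name) atom keys; a missing or extra key raises
    :class:`StructureMismatchError` naming it.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure("traj", str(path))
    except PDBConstructionException as exc:
        raise TrajectoryParseError(f"{path}: {exc}") from exc

    frames: list[TrajectoryFrame] = []
    for i, model in enumerate(structure):
        atoms = []
        for chain in model:
            for res in chain:
                for atom in res:
                    atoms.append(AtomRecord(
                        serial=atom.get_serial_number() or 0,
                        name=atom.get_name(),
                        resname=res.get_resname().strip(),
                        chain=chain.id,
                        resseq=res.id[1],
                        element=(atom.element or "").strip(),
                        coord=np.asarray(atom.coord, dtype=float),
                    ))
        if not atoms:
            raise TrajectoryParseError(f"{path}: model {i} contains no atoms")
        frames.append(TrajectoryFrame(frame_index=i, atoms=atoms))

    if not frames:
        raise TrajectoryParseError(f"{path}: no frames found")
    ref = frames[0].keys
    for f in frames[1:]:
        if f.keys != ref:
            missing = sorted(ref - f.keys)
            extra = sorted(f.keys - ref)
            detail = []
            if missing:
                detail.append(f"missing {missing}")
            if extra:
                detail.append(f"unexpected {extra}")
            raise StructureMismatchError(
                f"{path}: frame {f.frame_index} atom set differs from frame 0: "
                + "; ".join(detail))
    return frames


# ---------------------------------------------------------------------------
# reaction-center resolution and scoring
# ---------------------------------------------------------------------------

def _find_one(frame: TrajectoryFrame, matcher: AtomMatcher, role: str) -> AtomRecord:
    hits = [a for a in frame.atoms if matcher.matches(a)]
    if len(hits) == 1:
        return hits[0]
    if not hits:
        raise SelectionError(
            f"role {role!r}: no atom matches {matcher} in frame {frame.frame_index}")
    raise SelectionError(
        f"role {role!r}: matcher {matcher} is ambiguous in frame "
        f"{frame.frame_index}; candidates: {[a.key for a in hits]}")


def resolve_reaction_center(frame: TrajectoryFrame, spec: SelectionSpec) -> ReactionCenter:
    """Bind every reaction-center role to exactly one atom of ``frame``.

    If the oxo matcher finds nothing (or none is configured) and
    ``allow_virtual_oxo`` is set, a virtual ferryl oxygen is synthesized on
    the heme-plane normal at ``oxo_bond_length`` from the iron, oriented
    toward the target carbon.
    """
    fe = _find_one(frame, spec.fe, "fe")
    c_target = _find_one(frame, spec.c_target, "c_target")

    oxo = None
    if spec.oxo is not None:
        hits = [a for a in frame.atoms if spec.oxo.matches(a)]
        if len(hits) > 1:
            raise SelectionError(
                f"role 'oxo': ambiguous matches {[a.key for a in hits]}")
        if hits:
            oxo = hits[0]
    virtual = False
    if oxo is None:
        if not spec.allow_virtual_oxo:
            raise SelectionError("role 'oxo': no atom matched and "
                                 "allow_virtual_oxo is disabled")
        if not spec.pyrrole or len(spec.pyrrole) != 4:
            raise ConfigurationError(
                "virtual oxo requires four pyrrole-nitrogen matchers")
        n_atoms = [_find_one(frame, m, f"pyrrole[{i}]")
                   for i, m in enumerate(spec.pyrrole)]
        normal = heme_plane_normal(*[a.coord for a in n_atoms],
                                   toward=c_target.coord)
        coord = place_virtual_oxo(fe.coord, normal, spec.oxo_bond_length)
        oxo = AtomRecord(serial=0, name="OXO", resname=fe.resname,
                         chain=fe.chain, resseq=fe.resseq, element="O",
                         coord=coord, virtual=True)
        virtual = True

    return ReactionCenter(
        fe=fe, oxo=oxo, c_target=c_target,
        h_pro_r=_find_one(frame, spec.h_pro_r, "h_pro_r"),
        h_pro_s=_find_one(frame, spec.h_pro_s, "h_pro_s"),
        extra_h=tuple((label, _find_one(frame, m, f"extra_h[{label}]"))
                      for label, m in spec.extra_h.items()),
        virtual_oxo=virtual,
    )


def score_trajectory(frames: Sequence[TrajectoryFrame], spec: SelectionSpec,
                     criteria: NACCriteria = NACCriteria(),
                     sample_stride: int = 1,
                     replica_id: str = "replica") -> ReplicaResult:
    """Classify every hydrogen of every ``sample_stride``-th frame.

    Returns the per-label NAC counts together with the full sample stream,
    so downstream consumers (occupancy maps, site tallies) need no second
    pass over the trajectory.
    """
    if sample_stride < 1:
        raise ValueError("sample_stride must be >= 1")
    samples: list[GeometrySample] = []
    counts: dict[str, int] = {}
    evaluated = 0
    used_virtual = False
    for frame in frames[::sample_stride]:
        try:
            rc = resolve_reaction_center(frame, spec)
        except (SelectionError, ConfigurationError) as exc:
            raise type(exc)(
                f"replica {replica_id}, frame {frame.frame_index}: {exc}") from exc
        used_virtual = used_virtual or rc.virtual_oxo
        evaluated += 1
        for label in rc.hydrogen_labels():
            s = classify_nac(
                evaluate_geometry(rc, label, frame_index=frame.frame_index,
                                  replica_id=replica_id),
                criteria)
            samples.append(s)
            counts.setdefault(label, 0)
            if s.is_nac:
                counts[label] += 1
    return ReplicaResult(replica_id=replica_id, frames_evaluated=evaluated,
                         nac_count=counts, samples=samples,
                         used_virtual_oxo=used_virtual)


def score_samples(samples: Iterable[GeometrySample],
                  criteria: NACCriteria = NACCriteria(),
                  replica_id: str = "replica") -> ReplicaResult:
    """Build a :class:`ReplicaResult` directly from geometry samples.

    Used when descriptors come from the synthetic basin simulator without a
    coordinate round-trip.  Frames are counted as the number of distinct
    frame indices seen.
    """
    classified: list[GeometrySample] = []
    counts: dict[str, int] = {}
    frame_ids = set()
    for s in samples:
        c = classify_nac(s, criteria) if s.is_nac is None else s
        classified.append(c)
        frame_ids.add(c.frame_index)
        counts.setdefault(c.hydrogen_label, 0)
        if c.is_nac:
            counts[c.hydrogen_label] += 1
    return ReplicaResult(replica_id=replica_id, frames_evaluated=len(frame_ids),
                         nac_count=counts, samples=classified)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def predicted_ee(nac_s_pct: float, nac_r_pct: float) -> Optional[float]:
    """Epimeric excess predicted from pro-S / pro-R NAC percentages.

    ``100 * (NAC_S - NAC_R) / (NAC_S + NAC_R)``; positive values favor the
    pro-S product.  Returns ``None`` (no reactive sampling) when both
    percentages are zero.
    """
    for v in (nac_s_pct, nac_r_pct):
        if not (0 <= v <= 100):
            raise ValueError(f"NAC percentage {v} outside [0, 100]")
    total = nac_s_pct + nac_r_pct
    if total == 0:
        return None
    return 100.0 * (nac_s_pct - nac_r_pct) / total


def _pooled_counts(results: Sequence[ReplicaResult]) -> tuple[int, int, int]:
    n_frames = sum(r.frames_evaluated for r in results)
    n_s = sum(r.nac_count.get(PRO_S, 0) for r in results)
    n_r = sum(r.nac_count.get(PRO_R, 0) for r in results)
    return n_frames, n_s, n_r


def aggregate_replicas(results: Sequence[ReplicaResult]) -> NACSummary:
    """Pool frames across replicas and predict the epimeric excess.

    Percentages are total NAC counts over total frames evaluated, i.e. the
    frame-weighted mean of per-replica percentages; the per-replica
    breakdown is retained in the summary so a replica-averaged view can be
    recovered without rescoring.
    """
    results = list(results)
    if not results:
        raise ValueError("aggregate_replicas needs at least one replica")
    n_frames, n_s, n_r = _pooled_counts(results)
    if n_frames == 0:
        raise ValueError("no frames evaluated across replicas")
    nac_s = 100.0 * n_s / n_frames
    nac_r = 100.0 * n_r / n_frames
    per_replica = [
        {"replica_id": r.replica_id, "frames_evaluated": r.frames_evaluated,
         "nac_s_pct": r.nac_pct(PRO_S), "nac_r_pct": r.nac_pct(PRO_R),
         "ee_pred": predicted_ee(r.nac_pct(PRO_S), r.nac_pct(PRO_R))}
        for r in results
    ]
    return NACSummary(nac_s_pct=nac_s, nac_r_pct=nac_r,
                      ee_pred=predicted_ee(nac_s, nac_r),
                      n_replicas=len(results), n_frames_total=n_frames,
                      per_replica=per_replica)


def bootstrap_ci(results: Sequence[ReplicaResult], n_boot: int = 1000,
                 seed: int = 0, level: float = 0.9) -> tuple[float, float]:
    """Percentile bootstrap interval for the pooled epimeric excess.

    Whole replicas are resampled with replacement; resamples with no
    reactive sampling at all carry no e.e. information and are dropped.
    With fewer than two replicas the interval is undefined: ``(nan, nan)``
    is returned with a warning rather than an exception.
    """
    results = list(results)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    if len(results) < 2:
        warnings.warn("bootstrap_ci needs >= 2 replicas; returning (nan, nan)")
        return (math.nan, math.nan)
    frames = np.array([r.frames_evaluated for r in results], dtype=float)
    ns = np.array([r.nac_count.get(PRO_S, 0) for r in results], dtype=float)
    nr = np.array([r.nac_count.get(PRO_R, 0) for r in results], dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(results), size=(n_boot, len(results)))
    tot_f = frames[idx].sum(axis=1)
    tot_s = ns[idx].sum(axis=1)
    tot_r = nr[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ee = 100.0 * (tot_s - tot_r) / (tot_s + tot_r)
    ee = ee[np.isfinite(ee) & (tot_f > 0)]
    if ee.size == 0:
        warnings.warn("all bootstrap resamples had zero reactive sampling")
        return (math.nan, math.nan)
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(ee, [alpha, 100.0 - alpha])
    return (float(lo), float(hi))


def summarize(results: Sequence[ReplicaResult], n_boot: int = 1000,
              seed: int = 0, level: float = 0.9) -> NACSummary:
    """:func:`aggregate_replicas` plus a bootstrap confidence interval."""
    summary = aggregate_replicas(results)
    if len(list(results)) >= 2:
        lo, hi = bootstrap_ci(results, n_boot=n_boot, seed=seed, level=level)
        summary.ci_low, summary.ci_high, summary.ci_level = lo, hi, level
    return summary


# ---------------------------------------------------------------------------
# occupancy maps and site tallies
# ---------------------------------------------------------------------------

def default_d_edges() -> np.ndarray:
    """1.5 to 8.0 Angstrom in 0.1 Angstrom bins."""
    return np.linspace(1.5, 8.0, 66)


def default_theta2_edges() -> np.ndarray:
    """60 to 180 degrees in 2 degree bins."""
    return np.linspace(60.0, 180.0, 61)


@dataclass
class OccupancyMap:
    """2D (theta2 x d) histogram of one hydrogen's sampled descriptors.

    ``red_box_count`` counts samples inside the two-criteria rectangle
    (d <= d_max and theta2 > theta2_min).  The rectangle ignores theta1, so
    it is always a superset of the fully classified NAC set.
    """

    hydrogen_label: str
    d_edges: np.ndarray
    theta2_edges: np.ndarray
    counts: np.ndarray          # shape (n_theta2_bins, n_d_bins)
    overflow: int
    red_box_count: int
    n_samples: int

    def to_dataframe(self) -> pd.DataFrame:
        d_labels = [f"{lo:.2f}-{hi:.2f}"
                    for lo, hi in zip(self.d_edges[:-1], self.d_edges[1:])]
        t_labels = [f"{lo:.1f}-{hi:.1f}"
                    for lo, hi in zip(self.theta2_edges[:-1], self.theta2_edges[1:])]
        return pd.DataFrame(self.counts, index=pd.Index(t_labels, name="theta2"),
                            columns=pd.Index(d_labels, name="d"))


def occupancy_map(samples: Sequence[GeometrySample],
                  d_edges: Optional[np.ndarray] = None,
                  theta2_edges: Optional[np.ndarray] = None,
                  criteria: NACCriteria = NACCriteria()) -> OccupancyMap:
    """Histogram (theta2, d) for samples of a single hydrogen label."""
    samples = list(samples)
    if not samples:
        raise ValueError("no samples to map")
    labels = {s.hydrogen_label for s in samples}
    if len(labels) > 1:
        raise ValueError(f"mixed hydrogen labels {sorted(labels)}; "
                         "use occupancy_maps()")
    d_edges = default_d_edges() if d_edges is None else np.asarray(d_edges, float)
    theta2_edges = (default_theta2_edges() if theta2_edges is None
                    else np.asarray(theta2_edges, float))
    for name, edges in (("d_edges", d_edges), ("theta2_edges", theta2_edges)):
        if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
            raise ValueError(f"{name} must be strictly increasing with >= 2 entries")
    d = np.array([s.d for s in samples])
    t2 = np.array([s.theta2 for s in samples])
    counts, _, _ = np.histogram2d(t2, d, bins=[theta2_edges, d_edges])
    overflow = int(len(samples) - counts.sum())
    red_box = int(np.sum((d <= criteria.d_max) & (t2 > criteria.theta2_min)))
    return OccupancyMap(hydrogen_label=labels.pop(), d_edges=d_edges,
                        theta2_edges=theta2_edges, counts=counts.astype(int),
                        overflow=overflow, red_box_count=red_box,
                        n_samples=len(samples))


def occupancy_maps(samples: Sequence[GeometrySample], **kwargs) -> dict:
    """One :func:`occupancy_map` per hydrogen label present in ``samples``."""
    by_label: dict[str, list] = {}
    for s in samples:
        by_label.setdefault(s.hydrogen_label, []).append(s)
    return {label: occupancy_map(group, **kwargs)
            for label, group in sorted(by_label.items())}


@dataclass
class SiteTally:
    """Pooled NAC percentage of one candidate abstraction site."""

    site: str
    nac_pct: float
    bde: Optional[float] = None        # kcal/mol, user supplied
    reactive_flag: Optional[bool] = None


def tally_sites(results: Sequence[ReplicaResult],
                site_labels: Optional[Sequence[str]] = None) -> list[SiteTally]:
    """Pooled NAC percentage per extra abstraction site across replicas.

    ``site_labels`` defaults to every non-pro-R/S label that was scored;
    requesting an unscored label raises :class:`SelectionError`.
    """
    results = list(results)
    scored: set[str] = set()
    for r in results:
        scored.update(r.nac_count)
    if site_labels is None:
        site_labels = sorted(scored - {PRO_R, PRO_S})
    n_frames = sum(r.frames_evaluated for r in results)
    tallies = []
    for label in site_labels:
        if label not in scored:
            raise SelectionError(f"site {label!r} was not scored; "
                                 f"available: {sorted(scored)}")
        count = sum(r.nac_count.get(label, 0) for r in results)
        pct = 100.0 * count / n_frames if n_frames else 0.0
        tallies.append(SiteTally(site=label, nac_pct=pct))
    return tallies


def apply_reactivity_filter(tallies: Sequence[SiteTally], bde_table: dict,
                            window: float = 5.0) -> list[SiteTally]:
    """Annotate tallies with chemical reactivity from C-H bond strengths.

    A site is flagged reactive when its bond dissociation energy lies
    within ``window`` kcal/mol of the weakest tallied bond (allylic C-H
    bonds are typically 10-20 kcal/mol weaker than alkylic/vinylic ones,
    so only near-minimum sites are plausible abstraction targets).  Flags
    annotate; no tally is removed.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    tallies = list(tallies)
    missing = [t.site for t in tallies if t.site not in bde_table]
    if missing:
        raise ConfigurationError(f"BDE table missing entries for sites {missing}")
    if not tallies:
        return []
    min_bde = min(bde_table[t.site] for t in tallies)
    return [replace(t, bde=bde_table[t.site],
                    reactive_flag=(bde_table[t.site] - min_bde) <= window)
            for t in tallies]


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def samples_to_dataframe(results: Sequence[ReplicaResult]) -> pd.DataFrame:
    """Flatten all classified samples into one row-per-sample table."""
    rows = [
        {"replica_id": s.replica_id, "frame_index": s.frame_index,
         "hydrogen_label": s.hydrogen_label, "d": s.d,
         "theta1": s.theta1, "theta2": s.theta2, "is_nac": s.is_nac}
        for r in results for s in r.samples
    ]
    return pd.DataFrame(rows, columns=["replica_id", "frame_index",
                                       "hydrogen_label", "d", "theta1",
                                       "theta2", "is_nac"])
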