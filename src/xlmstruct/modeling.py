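"""Cross-link-restrained coarse-grained Bayesian structure determination.

The protein is represented by one bead per residue. Beads are grouped into
rigid bodies (domains with known structure, moved as units) and flexible
strings (linkers and unresolved segments, moved bead-by-bead). The
posterior of a configuration combines

* a cross-link likelihood: each observed link contributes
  ``log[ψ + (1 − 2ψ) f(d)]`` where ``f`` is a logistic forward model of the
  probability of observing a link at bead–bead distance ``d`` and ``ψ`` is
  a sampled nuisance parameter for the probability that the link is
  spurious — one ψ for links consistently identified across experiments
  (``consistent``) and one for links identified once (``single``);
* priors: soft-sphere excluded volume between beads of different bodies,
  upper-harmonic sequence connectivity between consecutive beads of a
  chain, and a harmonic restraint on each disulfide bond.

Sampling is replica-exchange Metropolis Monte Carlo over rigid-body
translations/rotations, flexible-bead translations, and Gaussian ψ moves.
Ensembles are analyzed by core superposition, k-means clustering on bead
coordinates (Euclidean feature distance ∝ RMSD), cluster precision and
accuracy, per-domain localization densities, and restraint-satisfaction
reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from xlmstruct.core import CrossLink
from xlmstruct.errors import RepresentationError
from xlmstruct.struct import StructureModel, nearest_resolved

CONSISTENT = "consistent"
SINGLE = "single"

RIGID_BEAD_RADIUS = 2.4  # Å, Cα packing within structured domains
FLEXIBLE_BEAD_RADIUS = 3.0  # Å


# ---------------------------------------------------------------------------
# Representation


@dataclass
class Representation:
    """One-bead-per-residue coarse graining partitioned into bodies and strings."""

    residues: np.ndarray  # (N,) representative residue of each bead
    radii: np.ndarray  # (N,) bead radii, Å
    positions0: np.ndarray  # (N, 3) initial coordinates, Å
    bodies: list[np.ndarray]  # rigid bodies as bead-index arrays
    body_names: list[str]
    strings: list[np.ndarray]  # flexible strings as bead-index arrays
    core_body: int  # index into bodies: the superposition / fixed body
    chains: list[tuple[int, int]]  # residue ranges for sequence connectivity

    def __post_init__(self) -> None:
        n = len(self.residues)
        counted = np.zeros(n, dtype=int)
        for grp in list(self.bodies) + list(self.strings):
            counted[grp] += 1
        if not np.all(counted == 1):
            raise RepresentationError("bodies and strings must partition the beads")
        if len(set(self.residues.tolist())) != n:
            raise RepresentationError("every residue must map to exactly one bead")
        if not self.bodies or len(self.bodies[self.core_body]) == 0:
            raise RepresentationError("core selection must be non-empty")
        self.bead_of = {int(r): i for i, r in enumerate(self.residues)}
        # body id per bead; each flexible string is its own "body" for
        # excluded-volume purposes
        self.body_id = np.empty(n, dtype=int)
        for b, grp in enumerate(self.bodies):
            self.body_id[grp] = b
        for s, grp in enumerate(self.strings):
            self.body_id[grp] = len(self.bodies) + s

    @property
    def n_beads(self) -> int:
        return len(self.residues)

    @property
    def core_indices(self) -> np.ndarray:
        return self.bodies[self.core_body]

    def bead_index(self, residue: int) -> int:
        try:
            return self.bead_of[int(residue)]
        except KeyError:
            raise RepresentationError(
                f"residue {residue} is not represented by any bead"
            ) from None

    def domain_beads(self, segments: Iterable[tuple[int, int]]) -> np.ndarray:
        idx = [
            self.bead_of[r]
            for a, b in segments
            for r in range(a, b + 1)
            if r in self.bead_of
        ]
        return np.array(sorted(idx), dtype=int)


@dataclass
class RepresentationConfig:
    """Rigid-body/flexible partition in residue ranges (see data/c3_rigid_bodies.yaml)."""

    protein_id: str
    chains: list[tuple[int, int]]
    rigid_bodies: dict[str, list[tuple[int, int]]]
    flexible: dict[str, list[tuple[int, int]]]
    core: str
    disulfides: list[tuple[int, int]] = field(default_factory=list)


def load_representation_config(source, chains: Optional[Sequence[tuple[int, int]]] = None) -> RepresentationConfig:
    """Read a rigid-body config from YAML (path, file object or string)."""
    from pathlib import Path

    if isinstance(source, (str, Path)) and "\n" not in str(source):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(source)
    cfg_chains = chains or raw.get("chains") or [(1, 645), (650, 1641)]
    return RepresentationConfig(
        protein_id=raw.get("protein_id", "protein"),
        chains=[tuple(c[-2:]) if len(c) == 3 else tuple(c) for c in cfg_chains],
        rigid_bodies={k: [tuple(s) for s in v] for k, v in raw["rigid_bodies"].items()},
        flexible={k: [tuple(s) for s in v] for k, v in raw.get("flexible", {}).items()},
        core=raw["core"],
        disulfides=[tuple(d) for d in raw.get("disulfides", [])],
    )


def build_representation(
    structure: StructureModel, config: RepresentationConfig
) -> Representation:
    """Build beads from a crystal structure and a rigid-body partition.

    Rigid-body beads sit on the Cα of their residue (nearest resolved
    residue when unresolved). Flexible segments — those listed as flexible
    plus any chain residues not claimed by a rigid body — get one bead per
    residue, initially interpolated between the flanking placed residues.
    """
    claimed: dict[int, str] = {}
    for name, segs in config.rigid_bodies.items():
        for a, b in segs:
            for r in range(a, b + 1):
                if r in claimed:
                    raise RepresentationError(
                        f"residue {r} claimed by both {claimed[r]} and {name}"
                    )
                claimed[r] = name
    chain_residues = [r for a, b in config.chains for r in range(a, b + 1)]
    residues = sorted(set(chain_residues))
    for name, segs in config.rigid_bodies.items():
        for a, b in segs:
            for r in range(a, b + 1):
                if r not in set(residues):
                    raise RepresentationError(
                        f"rigid body {name} residue {r} lies outside every chain"
                    )

    n = len(residues)
    res_arr = np.array(residues, dtype=int)
    positions = np.zeros((n, 3))
    radii = np.full(n, FLEXIBLE_BEAD_RADIUS)
    body_groups: dict[str, list[int]] = {name: [] for name in config.rigid_bodies}
    flexible_idx: list[int] = []

    for i, r in enumerate(residues):
        name = claimed.get(r)
        if name is not None:
            positions[i] = structure.ca(nearest_resolved(structure, r))
            radii[i] = RIGID_BEAD_RADIUS
            body_groups[name].append(i)
        else:
            flexible_idx.append(i)

    # interpolate flexible beads between flanking rigid positions
    placed = np.zeros(n, dtype=bool)
    for grp in body_groups.values():
        placed[grp] = True
    for i in flexible_idx:
        if structure.is_resolved(res_arr[i]):
            positions[i] = structure.ca(int(res_arr[i]))
            continue
        left = next((j for j in range(i - 1, -1, -1) if placed[j]), None)
        right = next((j for j in range(i + 1, n) if placed[j]), None)
        if left is not None and right is not None:
            t = (i - left) / (right - left)
            positions[i] = (1 - t) * positions[left] + t * positions[right]
        elif left is not None:
            positions[i] = positions[left] + [3.8 * (i - left), 0, 0]
        elif right is not None:
            positions[i] = positions[right] - [3.8 * (right - i), 0, 0]

    bodies = [np.array(body_groups[name], dtype=int) for name in config.rigid_bodies]
    body_names = list(config.rigid_bodies)
    # split flexible beads into contiguous strings
    strings: list[np.ndarray] = []
    cur: list[int] = []
    for i in flexible_idx:
        if cur and (i != cur[-1] + 1 or res_arr[i] != res_arr[cur[-1]] + 1):
            strings.append(np.array(cur, dtype=int))
            cur = []
        cur.append(i)
    if cur:
        strings.append(np.array(cur, dtype=int))

    return Representation(
        residues=res_arr,
        radii=radii,
        positions0=positions,
        bodies=bodies,
        body_names=body_names,
        strings=strings,
        core_body=body_names.index(config.core),
        chains=[tuple(c) for c in config.chains],
    )


# ---------------------------------------------------------------------------
# Restraints and scoring


@dataclass
class RestraintSet:
    """Cross-link restraints with ψ classes, plus disulfides."""

    crosslinks: list[tuple[CrossLink, str]]
    disulfides: list[tuple[int, int]] = field(default_factory=lambda: [(851, 1491)])
    satisfaction_threshold: float = 35.0

    def __post_init__(self) -> None:
        for _, cls in self.crosslinks:
            if cls not in (CONSISTENT, SINGLE):
                raise ValueError(f"unknown ψ class {cls!r}")
        if self.satisfaction_threshold <= 0:
            raise ValueError("satisfaction_threshold must be > 0")


def read_restraints(path, linker=None, annotation=None, **kwargs) -> RestraintSet:
    """Read a restraint TSV with columns res_a, res_b, class."""
    from xlmstruct.core import ResidueRef, annotate_residue

    df = pd.read_csv(path, sep="\t")
    col = "class" if "class" in df.columns else "psi_class"
    links = []
    for _, row in df.iterrows():
        if annotation is not None:
            a = annotate_residue(int(row["res_a"]), annotation)
            b = annotate_residue(int(row["res_b"]), annotation)
        else:
            a = ResidueRef(int(row["res_a"]))
            b = ResidueRef(int(row["res_b"]))
        links.append((CrossLink(a, b, linker), str(row[col])))
    return RestraintSet(crosslinks=links, **kwargs)


@dataclass
class ScoringParams:
    """Forward-model and prior constants (Å and Å⁻² units)."""

    forward_d0: float = 35.0  # logistic inflection: f(d0) = 1/2
    forward_lambda: float = 2.0  # logistic steepness
    forward_form: str = "logistic"  # "logistic" | "step" (hard cutoff at d0)
    k_excluded: float = 1.0  # per Å², soft-sphere overlap
    k_connect: float = 1.0  # per Å², sequence connectivity
    connect_rest_per_gap: float = 4.0  # Å per sequence-gap unit
    disulfide_rest: float = 6.0  # Å
    k_disulfide: float = 10.0  # per Å²
    ev_min_separation: int = 2  # no EV between beads this close in sequence
    psi_min: float = 0.01
    psi_max: float = 0.49

    def __post_init__(self) -> None:
        if self.forward_lambda <= 0:
            raise ValueError("forward_lambda must be > 0")
        if not (0 < self.psi_min < self.psi_max < 0.5):
            raise ValueError("ψ bounds must satisfy 0 < min < max < 0.5")


def forward_model_probability(d, params: ScoringParams = ScoringParams()):
    """Probability of observing a cross-link at bead–bead distance ``d`` (Å).

    Two forms, both monotone non-increasing with f(d0) = 1/2:

    * ``logistic`` (default): 1 at contact, 1/2 at ``forward_d0``, 0 far
      away, steepness ``forward_lambda``;
    * ``step``: 1 below ``forward_d0``, 0 above (1/2 exactly at d0) — the
      matched model when detection is a hard distance cutoff; within the
      likelihood the ψ terms keep probabilities strictly inside (0, 1).

    Accepts scalars or arrays.
    """
    d = np.asarray(d, dtype=float)
    if params.forward_form == "step":
        out = np.where(d < params.forward_d0, 1.0, 0.0) + np.where(
            d == params.forward_d0, 0.5, 0.0
        )
    else:
        out = 1.0 / (1.0 + np.exp((d - params.forward_d0) / params.forward_lambda))
    return float(out) if out.ndim == 0 else out


class Scorer:
    """Precomputed index arrays for fast repeated score evaluation."""

    def __init__(
        self,
        rep: Representation,
        restraints: RestraintSet,
        params: Optional[ScoringParams] = None,
    ):
        self.rep = rep
        self.restraints = restraints
        self.params = params or ScoringParams()

        self.link_i = np.array(
            [rep.bead_index(ln.a.position) for ln, _ in restraints.crosslinks], dtype=int
        )
        self.link_j = np.array(
            [rep.bead_index(ln.b.position) for ln, _ in restraints.crosslinks], dtype=int
        )
        self.link_class = np.array(
            [0 if cls == CONSISTENT else 1 for _, cls in restraints.crosslinks], dtype=int
        )

        n = rep.n_beads
        iu, ju = np.triu_indices(n, k=1)
        diff_body = rep.body_id[iu] != rep.body_id[ju]
        # bonded and near-bonded neighbors are never EV-penalized: consecutive
        # Cα beads sit closer than the sum of their radii by construction
        bonded = (
            np.abs(rep.residues[iu] - rep.residues[ju]) <= self.params.ev_min_separation
        )
        diff_body &= ~bonded
        self.ev_i, self.ev_j = iu[diff_body], ju[diff_body]
        self.ev_rsum = rep.radii[self.ev_i] + rep.radii[self.ev_j]

        conn_i, conn_j, conn_rest = [], [], []
        order = np.argsort(rep.residues)
        res_sorted = rep.residues[order]
        for a, b in rep.chains:
            in_chain = order[(res_sorted >= a) & (res_sorted <= b)]
            for u, v in zip(in_chain, in_chain[1:]):
                gap = abs(int(rep.residues[v]) - int(rep.residues[u]))
                conn_i.append(u)
                conn_j.append(v)
                conn_rest.append(self.params.connect_rest_per_gap * gap)
        self.conn_i = np.array(conn_i, dtype=int)
        self.conn_j = np.array(conn_j, dtype=int)
        self.conn_rest = np.array(conn_rest, dtype=float)

        self.ss_i = np.array([rep.bead_index(a) for a, _ in restraints.disulfides], dtype=int)
        self.ss_j = np.array([rep.bead_index(b) for _, b in restraints.disulfides], dtype=int)

        self._group_cache: dict = {}

    # -- components ---------------------------------------------------------

    def crosslink_loglik(self, positions: np.ndarray, psi: np.ndarray) -> float:
        if len(self.link_i) == 0:
            return 0.0
        d = np.linalg.norm(positions[self.link_i] - positions[self.link_j], axis=1)
        f = forward_model_probability(d, self.params)
        p = psi[self.link_class] + (1.0 - 2.0 * psi[self.link_class]) * f
        return float(np.sum(np.log(p)))

    def excluded_volume(self, positions: np.ndarray) -> float:
        if len(self.ev_i) == 0:
            return 0.0
        d = np.linalg.norm(positions[self.ev_i] - positions[self.ev_j], axis=1)
        overlap = np.maximum(0.0, self.ev_rsum - d)
        return float(self.params.k_excluded * np.sum(overlap**2))

    def connectivity(self, positions: np.ndarray) -> float:
        if len(self.conn_i) == 0:
            return 0.0
        d = np.linalg.norm(positions[self.conn_i] - positions[self.conn_j], axis=1)
        excess = np.maximum(0.0, d - self.conn_rest)
        return float(self.params.k_connect * np.sum(excess**2))

    def disulfide(self, positions: np.ndarray) -> float:
        if len(self.ss_i) == 0:
            return 0.0
        d = np.linalg.norm(positions[self.ss_i] - positions[self.ss_j], axis=1)
        return float(self.params.k_disulfide * np.sum((d - self.params.disulfide_rest) ** 2))

    def prior(self, positions: np.ndarray) -> float:
        return self.excluded_volume(positions) + self.connectivity(positions) + self.disulfide(positions)

    def psi_neglog_prior(self, psi: np.ndarray) -> float:
        p = self.params
        if np.any(psi < p.psi_min) or np.any(psi > p.psi_max):
            return math.inf
        return 0.0  # uniform prior: constant inside the bounds

    def total(self, positions: np.ndarray, psi: np.ndarray) -> float:
        """Negative log posterior (lower is better)."""
        return (
            -self.crosslink_loglik(positions, psi)
            + self.prior(positions)
            + self.psi_neglog_prior(psi)
        )

    # -- incremental evaluation for the sampler -----------------------------

    def _group_selection(self, key, beads: np.ndarray):
        """Pair indices with exactly one endpoint in the moved bead group.

        Pairs with both endpoints inside the group keep their distance under
        a rigid move and drop out of the score difference.
        """
        sel = self._group_cache.get(key)
        if sel is None:
            mask = np.zeros(self.rep.n_beads, dtype=bool)
            mask[beads] = True
            sel = (
                np.where(mask[self.ev_i] ^ mask[self.ev_j])[0],
                np.where(mask[self.conn_i] ^ mask[self.conn_j])[0],
                np.where(mask[self.link_i] ^ mask[self.link_j])[0],
                np.where(mask[self.ss_i] ^ mask[self.ss_j])[0]
                if len(self.ss_i)
                else np.array([], dtype=int),
            )
            self._group_cache[key] = sel
        return sel

    def _partial(self, positions: np.ndarray, psi: np.ndarray, sel) -> float:
        ev_s, conn_s, link_s, ss_s = sel
        p = self.params
        out = 0.0
        if len(ev_s):
            d = np.linalg.norm(positions[self.ev_i[ev_s]] - positions[self.ev_j[ev_s]], axis=1)
            out += p.k_excluded * np.sum(np.maximum(0.0, self.ev_rsum[ev_s] - d) ** 2)
        if len(conn_s):
            d = np.linalg.norm(
                positions[self.conn_i[conn_s]] - positions[self.conn_j[conn_s]], axis=1
            )
            out += p.k_connect * np.sum(np.maximum(0.0, d - self.conn_rest[conn_s]) ** 2)
        if len(ss_s):
            d = np.linalg.norm(positions[self.ss_i[ss_s]] - positions[self.ss_j[ss_s]], axis=1)
            out += p.k_disulfide * np.sum((d - p.disulfide_rest) ** 2)
        if len(link_s):
            d = np.linalg.norm(
                positions[self.link_i[link_s]] - positions[self.link_j[link_s]], axis=1
            )
            f = forward_model_probability(d, p)
            pc = psi[self.link_class[link_s]]
            out -= float(np.sum(np.log(pc + (1.0 - 2.0 * pc) * f)))
        return float(out)

    def move_delta(
        self,
        old_positions: np.ndarray,
        new_positions: np.ndarray,
        group_key,
        beads: np.ndarray,
        psi: np.ndarray,
    ) -> float:
        """Score change for a rigid/flexible move of ``beads`` (ψ unchanged)."""
        sel = self._group_selection(group_key, beads)
        return self._partial(new_positions, psi, sel) - self._partial(
            old_positions, psi, sel
        )

    def psi_delta(self, positions: np.ndarray, old_psi: np.ndarray, new_psi: np.ndarray) -> float:
        """Score change when only ψ moves (likelihood + ψ prior terms)."""
        return (
            -self.crosslink_loglik(positions, new_psi)
            + self.psi_neglog_prior(new_psi)
            + self.crosslink_loglik(positions, old_psi)
            - self.psi_neglog_prior(old_psi)
        )


def crosslink_log_likelihood(
    positions: np.ndarray,
    rep: Representation,
    restraints: RestraintSet,
    psi: Mapping[str, float],
    params: Optional[ScoringParams] = None,
) -> float:
    """Sum over links of log[ψ_class + (1 − 2ψ_class) f(d)]."""
    sc = Scorer(rep, restraints, params)
    return sc.crosslink_loglik(positions, np.array([psi[CONSISTENT], psi[SINGLE]]))


def prior_score(
    positions: np.ndarray,
    rep: Representation,
    restraints: RestraintSet,
    params: Optional[ScoringParams] = None,
) -> float:
    """Excluded volume + sequence connectivity + disulfide harmonics."""
    return Scorer(rep, restraints, params).prior(positions)


def total_score(
    positions: np.ndarray,
    rep: Representation,
    restraints: RestraintSet,
    psi: Mapping[str, float],
    params: Optional[ScoringParams] = None,
) -> float:
    """Negative log posterior of a configuration (lower is better)."""
    sc = Scorer(rep, restraints, params)
    return sc.total(positions, np.array([psi[CONSISTENT], psi[SINGLE]]))


# ---------------------------------------------------------------------------
# Monte Carlo


@dataclass
class SamplerConfig:
    """Replica-exchange Metropolis Monte Carlo settings.

    The shipped default is the desk-scale profile (8 replicas, 20,000
    recorded models, one run). The publication-scale protocol for a system
    of this kind is 32 replicas, temperatures 1.0–2.5, two independent runs
    and 200,000 recorded models; move magnitudes below match it.
    """

    n_replicas: int = 8
    temperature_min: float = 1.0
    temperature_max: float = 2.5
    max_translate: float = 4.0  # Å, rigid-body translation
    max_rotate: float = 0.03  # rad, rigid-body rotation about the centroid
    max_bead_translate: float = 5.0  # Å, flexible beads
    psi_step: float = 0.01  # sd of the Gaussian ψ move (reflected at bounds)
    n_models_total: int = 20_000
    n_best: int = 200
    n_runs: int = 1
    steps_per_model: int = 10  # MC steps per replica between recorded models
    init_radius: float = 150.0  # Å, random initial placement sphere
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.temperature_max < self.temperature_min:
            raise ValueError("temperatures must be ascending")
        for name in ("max_translate", "max_rotate", "max_bead_translate", "psi_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def temperatures(self) -> np.ndarray:
        """Geometric ladder from temperature_min to temperature_max."""
        if self.n_replicas == 1:
            return np.array([self.temperature_min])
        return np.geomspace(self.temperature_min, self.temperature_max, self.n_replicas)


@dataclass
class MCState:
    positions: np.ndarray
    psi: np.ndarray  # [ψ_consistent, ψ_single]
    score: float


def metropolis_accept(delta: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: always accept downhill, else with prob exp(−Δ/T)."""
    if delta <= 0:
        return True
    return rng.random() < math.exp(-delta / temperature)


def _random_rotation(max_angle: float, rng: np.random.Generator) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle)
    k = axis
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    y = (x - lo) % (2 * width)
    if y < 0:
        y += 2 * width
    return lo + (y if y <= width else 2 * width - y)


def mc_step(
    state: MCState,
    scorer: Scorer,
    config: SamplerConfig,
    rng: np.random.Generator,
    temperature: float = 1.0,
) -> tuple[MCState, bool]:
    """One Metropolis move: returns (possibly-updated state, accepted flag).

    Uniform choice among the applicable move kinds: rigid translation,
    rigid rotation, flexible-bead translation, ψ perturbation. The core
    body never moves.
    """
    rep = scorer.rep
    movable = [b for b in range(len(rep.bodies)) if b != rep.core_body]
    kinds = []
    if movable:
        kinds += ["rigid_translate", "rigid_rotate"]
    if rep.strings:
        kinds.append("flex_translate")
    if len(scorer.link_i) > 0:
        kinds.append("psi")
    kind = kinds[rng.integers(len(kinds))]

    positions = state.positions
    psi = state.psi
    if kind == "rigid_translate":
        b = movable[rng.integers(len(movable))]
        body = rep.bodies[b]
        vec = rng.normal(size=3)
        vec *= rng.uniform(0.0, config.max_translate) / np.linalg.norm(vec)
        positions = positions.copy()
        positions[body] += vec
        delta = scorer.move_delta(state.positions, positions, ("body", b), body, psi)
    elif kind == "rigid_rotate":
        b = movable[rng.integers(len(movable))]
        body = rep.bodies[b]
        R = _random_rotation(config.max_rotate, rng)
        positions = positions.copy()
        centroid = positions[body].mean(axis=0)
        positions[body] = (positions[body] - centroid) @ R.T + centroid
        delta = scorer.move_delta(state.positions, positions, ("body", b), body, psi)
    elif kind == "flex_translate":
        string = rep.strings[rng.integers(len(rep.strings))]
        bead = int(string[rng.integers(len(string))])
        vec = rng.normal(size=3)
        vec *= rng.uniform(0.0, config.max_bead_translate) / np.linalg.norm(vec)
        positions = positions.copy()
        positions[bead] += vec
        delta = scorer.move_delta(
            state.positions, positions, ("bead", bead), np.array([bead]), psi
        )
    else:  # psi
        psi = psi.copy()
        which = rng.integers(len(psi))
        psi[which] = _reflect(
            psi[which] + rng.normal(0.0, config.psi_step),
            scorer.params.psi_min,
            scorer.params.psi_max,
        )
        delta = scorer.psi_delta(positions, state.psi, psi)

    if metropolis_accept(delta, temperature, rng):
        return MCState(positions, psi, state.score + delta), True
    return state, False


def _initial_state(
    scorer: Scorer, config: SamplerConfig, rng: np.random.Generator
) -> MCState:
    """Random rigid-body placement in a sphere around the fixed core."""
    rep = scorer.rep
    positions = rep.positions0.copy()
    core_centroid = positions[rep.core_indices].mean(axis=0)
    for b, body in enumerate(rep.bodies):
        if b == rep.core_body:
            continue
        R = _random_rotation(math.pi, rng)
        centroid = positions[body].mean(axis=0)
        local = positions[body] - centroid
        target = core_centroid + rng.normal(size=3) * config.init_radius / 3.0
        shift = np.linalg.norm(target - core_centroid)
        if shift > config.init_radius:
            target = core_centroid + (target - core_centroid) * config.init_radius / shift
        positions[body] = local @ R.T + target
    for string in rep.strings:
        positions[string] += rng.normal(scale=2.0, size=(len(string), 3))
    # start ψ at the prior midpoint
    psi = np.full(2, 0.5 * (scorer.params.psi_min + scorer.params.psi_max))
    return MCState(positions, psi, scorer.total(positions, psi))


@dataclass
class Model:
    positions: np.ndarray
    psi: np.ndarray
    score: float
    run: int = 0
    index: int = 0


@dataclass
class Ensemble:
    models: list[Model]
    representation: Representation
    acceptance_rate: float = 0.0
    swap_rate: float = 0.0

    def scores(self) -> np.ndarray:
        return np.array([m.score for m in self.models])


def replica_exchange_sample(
    rep: Representation,
    restraints: RestraintSet,
    config: SamplerConfig,
    params: Optional[ScoringParams] = None,
) -> Ensemble:
    """Replica-exchange MC; records models from the lowest-temperature replica.

    Neighbor swaps follow min(1, exp[(1/Tᵢ − 1/Tⱼ)(Sᵢ − Sⱼ)]) after each
    batch of ``steps_per_model`` per-replica moves. ``n_runs`` independent
    runs (different random initial configurations, shared total model
    budget) are concatenated; the run label on each model supports
    convergence comparisons between runs.
    """
    scorer = Scorer(rep, restraints, params)
    temps = config.temperatures()
    models: list[Model] = []
    n_accept = n_moves = n_swap_acc = n_swap_try = 0
    per_run = max(1, config.n_models_total // max(1, config.n_runs))

    for run in range(config.n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, run]))
        states = [_initial_state(scorer, config, rng) for _ in temps]
        for it in range(per_run):
            for r, T in enumerate(temps):
                for _ in range(config.steps_per_model):
                    states[r], ok = mc_step(states[r], scorer, config, rng, T)
                    n_accept += ok
                    n_moves += 1
            offset = it % 2
            for r in range(offset, len(temps) - 1, 2):
                si, sj = states[r].score, states[r + 1].score
                arg = (1.0 / temps[r] - 1.0 / temps[r + 1]) * (si - sj)
                n_swap_try += 1
                if arg >= 0 or rng.random() < math.exp(arg):
                    states[r], states[r + 1] = states[r + 1], states[r]
                    n_swap_acc += 1
            st = states[0]
            models.append(
                Model(st.positions.copy(), st.psi.copy(), st.score, run=run, index=it)
            )

    return Ensemble(
        models=models,
        representation=rep,
        acceptance_rate=n_accept / max(1, n_moves),
        swap_rate=n_swap_acc / max(1, n_swap_try),
    )


def select_best(ensemble: Ensemble, n: int) -> list[Model]:
    """The n lowest-score models; ties broken by recording order (stable)."""
    if n > len(ensemble.models):
        raise ValueError("n exceeds ensemble size")
    order = sorted(range(len(ensemble.models)), key=lambda i: (ensemble.models[i].score, i))
    return [ensemble.models[i] for i in order[:n]]


# ---------------------------------------------------------------------------
# Superposition and ensemble analysis


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation/translation of ``mobile`` onto ``reference`` (SVD)."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose_core(
    positions: np.ndarray,
    reference: np.ndarray,
    core_indices: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Superpose on the core beads; the transform is applied to all beads.

    Returns the transformed coordinates and the core RMSD after fitting.
    """
    R, t = kabsch_superpose(positions[core_indices], reference[core_indices])
    moved = positions @ R.T + t
    return moved, rmsd(moved[core_indices], reference[core_indices])


@dataclass
class ClusterResult:
    assignments: np.ndarray  # (n_models,) cluster labels
    center_indices: list[int]  # per cluster: member minimizing mean RMSD to co-members
    members: list[list[int]]
    satisfaction: list[float]  # per cluster: fraction of links satisfied (any member)
    best_cluster: int


def cluster_solutions(
    solutions: Sequence[Model],
    k: int,
    rep: Representation,
    restraints: Optional[RestraintSet] = None,
    seed: int = 0,
) -> ClusterResult:
    """k-means on post-superposition bead coordinates.

    All solutions are superposed on the core beads of the first solution, so
    Euclidean distance in the flattened feature space is proportional to
    all-bead RMSD. The center of each cluster is the member minimizing mean
    RMSD to its co-members; when restraints are given, the cluster whose
    members best satisfy them (fraction of links under the threshold in at
    least one member) is flagged as ``best_cluster``.
    """
    from sklearn.cluster import KMeans

    if k < 1:
        raise ValueError("k must be >= 1")
    core = rep.core_indices
    ref = solutions[0].positions
    coords = np.stack([superpose_core(m.positions, ref, core)[0] for m in solutions])
    X = coords.reshape(len(solutions), -1)
    if k == 1:
        labels = np.zeros(len(solutions), dtype=int)
    else:
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = km.fit_predict(X)

    members = [[i for i in range(len(solutions)) if labels[i] == c] for c in range(k)]
    center_indices = []
    for mem in members:
        if not mem:
            center_indices.append(-1)
            continue
        sub = coords[mem]
        # pairwise RMSD within the cluster
        d2 = ((sub[:, None] - sub[None, :]) ** 2).sum(axis=-1).mean(axis=-1)
        mean_rmsd = np.sqrt(d2).mean(axis=1)
        center_indices.append(mem[int(np.argmin(mean_rmsd))])

    satisfaction = []
    for mem in members:
        if restraints is None or not mem or not restraints.crosslinks:
            satisfaction.append(float("nan"))
            continue
        rep_report = satisfaction_report([solutions[i] for i in mem], rep, restraints)
        satisfaction.append(rep_report.fraction_satisfied)
    if restraints is not None and any(np.isfinite(s) for s in satisfaction):
        best = int(np.nanargmax(satisfaction))
    else:
        sizes = [len(m) for m in members]
        best = int(np.argmax(sizes))
    return ClusterResult(labels, center_indices, members, satisfaction, best)


def precision_accuracy(
    cluster_models: Sequence[Model],
    center: Model,
    rep: Representation,
    reference: Optional[np.ndarray] = None,
    domains: Optional[Mapping[str, np.ndarray]] = None,
) -> dict:
    """Cluster precision, optional accuracy, and per-domain breakdowns.

    precision: mean RMSD of members to the cluster center after core
    superposition. accuracy: mean RMSD of members to the reference
    coordinates, likewise. Per-domain values restrict the RMSD to each
    domain's beads (superposition stays on the core).
    """
    if not cluster_models:
        raise ValueError("cluster is empty")
    core = rep.core_indices
    domains = domains or {}
    out = {
        "precision": 0.0,
        "accuracy": None,
        "per_domain_precision": {},
        "per_domain_accuracy": {},
    }
    sup_center = [superpose_core(m.positions, center.positions, core)[0] for m in cluster_models]
    out["precision"] = float(np.mean([rmsd(s, center.positions) for s in sup_center]))
    for name, idx in domains.items():
        out["per_domain_precision"][name] = float(
            np.mean([rmsd(s[idx], center.positions[idx]) for s in sup_center])
        )
    if reference is not None:
        sup_ref = [superpose_core(m.positions, reference, core)[0] for m in cluster_models]
        out["accuracy"] = float(np.mean([rmsd(s, reference) for s in sup_ref]))
        for name, idx in domains.items():
            out["per_domain_accuracy"][name] = float(
                np.mean([rmsd(s[idx], reference[idx]) for s in sup_ref])
            )
    return out


@dataclass
class DensityGrid:
    """Occupancy probability of a domain on a voxel grid, in [0, 1]."""

    values: np.ndarray  # (nx, ny, nz)
    origin: np.ndarray  # (3,) Å
    voxel_size: float  # Å

    def write_ccp4(self, path) -> None:
        import gemmi

        nx, ny, nz = self.values.shape
        grid = gemmi.FloatGrid(nx, ny, nz)
        grid.set_unit_cell(
            gemmi.UnitCell(
                nx * self.voxel_size, ny * self.voxel_size, nz * self.voxel_size,
                90, 90, 90,
            )
        )
        grid.spacegroup = gemmi.SpaceGroup("P1")
        np.asarray(grid, dtype=np.float32)[...] = self.values.astype(np.float32)
        ccp4 = gemmi.Ccp4Map()
        ccp4.grid = grid
        ccp4.update_ccp4_header()
        ccp4.write_ccp4_map(str(path))


def localization_density(
    cluster_models: Sequence[Model],
    domain_indices: np.ndarray,
    rep: Representation,
    voxel_size: float = 5.0,
    reference: Optional[np.ndarray] = None,
) -> DensityGrid:
    """Per-voxel probability that a domain occupies the voxel across a cluster.

    Models are superposed on the core beads of ``reference`` (the first
    member by default). A voxel counts as occupied by a member when its
    center lies within any of the member's domain bead spheres. Invariant
    to member ordering; values in [0, 1].
    """
    if not cluster_models:
        raise ValueError("cluster is empty")
    core = rep.core_indices
    ref = reference if reference is not None else cluster_models[0].positions
    coords = [
        superpose_core(m.positions, ref, core)[0][domain_indices] for m in cluster_models
    ]
    radii = rep.radii[domain_indices]
    rmax = float(radii.max())
    allpts = np.concatenate(coords)
    lo = allpts.min(axis=0) - rmax - voxel_size
    hi = allpts.max(axis=0) + rmax + voxel_size
    shape = np.maximum(1, np.ceil((hi - lo) / voxel_size).astype(int))
    counts = np.zeros(tuple(shape), dtype=float)
    axes = [lo[d] + (np.arange(shape[d]) + 0.5) * voxel_size for d in range(3)]
    for pts in coords:
        occ = np.zeros(tuple(shape), dtype=bool)
        for center, radius in zip(pts, radii):
            i0 = np.maximum(0, ((center - radius - lo) / voxel_size).astype(int))
            i1 = np.minimum(shape, ((center + radius - lo) / voxel_size).astype(int) + 2)
            gx = axes[0][i0[0]:i1[0]]
            gy = axes[1][i0[1]:i1[1]]
            gz = axes[2][i0[2]:i1[2]]
            dx2 = (gx - center[0])[:, None, None] ** 2
            dy2 = (gy - center[1])[None, :, None] ** 2
            dz2 = (gz - center[2])[None, None, :] ** 2
            occ[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= (
                dx2 + dy2 + dz2 <= radius**2
            )
        counts += occ
    return DensityGrid(values=counts / len(cluster_models), origin=lo, voxel_size=voxel_size)


@dataclass
class LinkSatisfaction:
    crosslink: CrossLink
    psi_class: str
    min_distance: float
    center_distance: Optional[float]
    satisfied: bool  # below threshold in at least one member
    satisfied_in_center: Optional[bool]


@dataclass
class SatisfactionReport:
    per_link: list[LinkSatisfaction]
    fraction_satisfied: float
    contact_map: Optional[np.ndarray] = None  # (n_beads, n_beads) contact frequency

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "res_a": [ls.crosslink.a.position for ls in self.per_link],
                "res_b": [ls.crosslink.b.position for ls in self.per_link],
                "class": [ls.psi_class for ls in self.per_link],
                "min_distance": [ls.min_distance for ls in self.per_link],
                "satisfied": [ls.satisfied for ls in self.per_link],
            }
        )


def satisfaction_report(
    cluster_models: Sequence[Model],
    rep: Representation,
    restraints: RestraintSet,
    center: Optional[Model] = None,
    contact_cutoff: Optional[float] = None,
) -> SatisfactionReport:
    """Per-link satisfaction over a cluster plus an optional contact map.

    A link is satisfied when its bead–bead distance is below the threshold
    in at least one member (the ensemble is read as a set of coexisting
    alternative conformations); the per-center-model call is also reported
    when a center is given. ``contact_cutoff`` (Å) switches on the
    bead–bead contact-frequency map (quadratic in bead count).
    """
    thr = restraints.satisfaction_threshold
    ii = np.array([rep.bead_index(ln.a.position) for ln, _ in restraints.crosslinks])
    jj = np.array([rep.bead_index(ln.b.position) for ln, _ in restraints.crosslinks])
    n_links = len(restraints.crosslinks)
    min_d = np.full(n_links, np.inf)
    for m in cluster_models:
        d = np.linalg.norm(m.positions[ii] - m.positions[jj], axis=1)
        min_d = np.minimum(min_d, d)
    center_d = None
    if center is not None:
        center_d = np.linalg.norm(center.positions[ii] - center.positions[jj], axis=1)
    per_link = []
    for idx, (ln, cls) in enumerate(restraints.crosslinks):
        per_link.append(
            LinkSatisfaction(
                crosslink=ln,
                psi_class=cls,
                min_distance=float(min_d[idx]),
                center_distance=float(center_d[idx]) if center_d is not None else None,
                satisfied=bool(min_d[idx] < thr),
                satisfied_in_center=bool(center_d[idx] < thr) if center_d is not None else None,
            )
        )
    frac = float(np.mean([ls.satisfied for ls in per_link])) if per_link else 1.0

    cmap = None
    if contact_cutoff is not None:
        n = rep.n_beads
        cmap = np.zeros((n, n))
        for m in cluster_models:
            diff = m.positions[:, None, :] - m.positions[None, :, :]
            cmap += (np.sqrt((diff**2).sum(axis=-1)) < contact_cutoff).astype(float)
        cmap /= len(cluster_models)
    return SatisfactionReport(per_link=per_link, fraction_satisfied=frac, contact_map=cmap)


# ---------------------------------------------------------------------------
# Ensemble I/O


def write_ensemble_pdb(models: Sequence[Model], rep: Representation, path) -> None:
    """Multi-model PDB: one pseudo-atom (CA) per bead."""
    with open(path, "w") as fh:
        for mi, m in enumerate(models, start=1):
            fh.write(f"MODEL     {mi:4d}\n")
            for i, res in enumerate(rep.residues):
                x, y, z = m.positions[i]
                fh.write(
                    f"ATOM  {i + 1:5d}  CA  GLY A{int(res) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_run_metadata(ensemble: Ensemble, config: SamplerConfig, path) -> None:
    meta = {
        "n_models": len(ensemble.models),
        "acceptance_rate": ensemble.acceptance_rate,
        "swap_rate": ensemble.swap_rate,
        "config": {
            "n_replicas": config.n_replicas,
            "temperature_min": config.temperature_min,
            "temperature_max": config.temperature_max,
            "n_models_total": config.n_models_total,
            "n_runs": config.n_runs,
            "seed": config.seed,
        },
        "best_score": float(min(m.score for m in ensemble.models)),
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)
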