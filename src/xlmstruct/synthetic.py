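"""Ground-truthed simulators for every stage of the package.

The simulated system is a deliberately simple stand-in for a two-chain,
multi-domain protein caught in two (or three) conformational states: each
domain is a compact cluster of one-residue beads, states differ only by
rigid-body rearrangements of whole domains (mimicking the relocation of a
domain from one end of a molecule to the other), and short flexible linkers
join consecutive domains.

On top of the coordinates the generators emulate the observable layers:

* distance-limited cross-link detection with a small spurious-link rate;
* heavy/light quantitation tables with log-normal peak-area noise, a
  per-sample condition-mixing bias, label-swapped replica pairs in two
  experiments, and 1–3 supporting peptide pairs per residue pair.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from xlmstruct.core import CrossLink, LinkerSpec, ResidueRef, default_bs3_linker
from xlmstruct.modeling import (
    CONSISTENT,
    FLEXIBLE_BEAD_RADIUS,
    RIGID_BEAD_RADIUS,
    SINGLE,
    Representation,
)
from xlmstruct.quant import Category, Detection, QuantRecord

REACTIVE_TYPES = ("K", "K", "S", "T", "Y")  # lysine twice: dominant reactive site


@dataclass
class ToyProteinSpec:
    """Geometry of the simulated multi-domain protein.

    ``states`` maps a state name to per-domain rigid placements: a list of
    (rotation angle about z in rad, translation vector) — one entry per
    domain, identity for the reference arrangement. All states share the
    topology and differ only in placements.
    """

    n_domains: int = 3
    residues_per_domain: int = 24
    linker_length: int = 6
    domain_spacing: float = 25.0  # Å between neighboring domain centers
    reactive_fraction: float = 0.4
    states: Mapping[str, Sequence[tuple[float, Sequence[float]]]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 2:
            raise ValueError("need at least 2 domains")


@dataclass
class ToyProtein:
    """Realized toy protein: coordinates per state plus residue bookkeeping."""

    spec: ToyProteinSpec
    segments: list[tuple[int, int]]  # residue range of each domain
    residue_types: dict[int, str]
    coords: dict[str, np.ndarray]  # state name -> (n_residues, 3)
    residues: np.ndarray  # (n_residues,)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def domain_of(self, pos: int) -> int:
        for d, (a, b) in enumerate(self.segments):
            if a <= pos <= b:
                return d
        return -1

    def residue_ref(self, pos: int) -> ResidueRef:
        d = self.domain_of(pos)
        return ResidueRef(
            pos,
            domain=f"D{d + 1}" if d >= 0 else "unknown",
            residue_type=self.residue_types.get(pos, "unknown"),
        )

    def representation(
        self,
        state: str,
        core_domain: int = 0,
        rigid_groups: Optional[Sequence[Sequence[int]]] = None,
    ) -> Representation:
        """Coarse-grained representation of a state.

        By default each domain is its own rigid body and linker residues are
        flexible strings. ``rigid_groups`` fuses sets of domain indices into
        single bodies (together with the linkers that join consecutive fused
        domains), emulating a core whose internal arrangement is known from
        a reference structure. ``core_domain`` names the fixed superposition
        core by the group (or domain) that contains it.
        """
        n = self.n_residues
        radii = np.full(n, FLEXIBLE_BEAD_RADIUS)
        bodies, names = [], []
        claimed = np.zeros(n, dtype=bool)
        if rigid_groups is None:
            rigid_groups = [[d] for d in range(len(self.segments))]
        core_body = next(
            g for g, grp in enumerate(rigid_groups) if core_domain in grp
        )
        for grp in rigid_groups:
            grp = sorted(grp)
            members = []
            for d in grp:
                a, b = self.segments[d]
                members.append(np.where((self.residues >= a) & (self.residues <= b))[0])
            for d1, d2 in zip(grp, grp[1:]):
                if d2 == d1 + 1:  # fuse the linker between consecutive domains
                    a = self.segments[d1][1] + 1
                    b = self.segments[d2][0] - 1
                    members.append(np.where((self.residues >= a) & (self.residues <= b))[0])
            idx = np.sort(np.concatenate(members))
            radii[idx] = RIGID_BEAD_RADIUS
            bodies.append(idx)
            names.append("+".join(f"D{d + 1}" for d in grp))
            claimed[idx] = True
        strings = []
        cur: list[int] = []
        for i in range(n):
            if claimed[i]:
                if cur:
                    strings.append(np.array(cur, dtype=int))
                    cur = []
            else:
                cur.append(i)
        if cur:
            strings.append(np.array(cur, dtype=int))
        return Representation(
            residues=self.residues.copy(),
            radii=radii,
            positions0=self.coords[state].copy(),
            bodies=bodies,
            body_names=names,
            strings=strings,
            core_body=core_body,
            chains=[(int(self.residues[0]), int(self.residues[-1]))],
        )


def _compact_domain(n: int, rng: np.random.Generator) -> np.ndarray:
    """A compact cluster of n beads threaded as a chain (~4 Å between neighbors).

    Beads snake through a cubic grid so that sequence-consecutive residues
    are also spatial neighbors, as in a folded chain.
    """
    side = int(np.ceil(n ** (1 / 3)))
    pts = []
    for z in range(side):
        ys = range(side) if z % 2 == 0 else range(side - 1, -1, -1)
        for yi, y in enumerate(ys):
            flip = (z * side + yi) % 2
            xs = range(side) if flip == 0 else range(side - 1, -1, -1)
            for x in xs:
                pts.append((x, y, z))
    pts = np.array(pts[:n], dtype=float) * 4.0
    pts += rng.normal(scale=0.4, size=pts.shape)
    return pts - pts.mean(axis=0)


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def make_toy_protein(spec: ToyProteinSpec) -> ToyProtein:
    """Realize coordinates for every state of a toy protein spec.

    Domains are compact bead clusters placed along x at ``domain_spacing``;
    each state applies its per-domain rigid transform to that base layout.
    Linker residues are interpolated between the flanking domain ends.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    segments = []
    pos = 1
    for _ in range(spec.n_domains):
        segments.append((pos, pos + spec.residues_per_domain - 1))
        pos += spec.residues_per_domain + spec.linker_length
    last_res = segments[-1][1]
    residues = np.arange(1, last_res + 1)

    shapes = [_compact_domain(spec.residues_per_domain, rng) for _ in range(spec.n_domains)]
    base_centers = [
        np.array([d * spec.domain_spacing, 0.0, 0.0]) for d in range(spec.n_domains)
    ]

    # reactive sites are evenly interleaved along the chain (linker-reactive
    # residues are abundant and well spread in real sequences), so every face
    # of every domain carries candidate sites; types are drawn at random
    types: dict[int, str] = {}
    stride = max(1, int(round(1.0 / max(1e-6, spec.reactive_fraction))))
    for a, b in segments:
        for r in range(a, b + 1):
            if (r - a) % stride == 0:
                types[r] = REACTIVE_TYPES[rng.integers(len(REACTIVE_TYPES))]
            else:
                types[r] = "A"

    states = dict(spec.states) or {"A": [(0.0, (0.0, 0.0, 0.0))] * spec.n_domains}
    coords: dict[str, np.ndarray] = {}
    for name, placements in states.items():
        if len(placements) != spec.n_domains:
            raise ValueError(f"state {name!r} must place all {spec.n_domains} domains")
        xyz = np.zeros((len(residues), 3))
        placed = np.zeros(len(residues), dtype=bool)
        for d, ((a, b), shape) in enumerate(zip(segments, shapes)):
            angle, shift = placements[d]
            dom = shape @ _rot_z(angle).T + base_centers[d] + np.asarray(shift, float)
            idx = slice(a - 1, b)
            xyz[idx] = dom
            placed[a - 1 : b] = True
        # relax domain placements until no two domains interpenetrate: the
        # planted configuration must itself be physically realizable
        dom_slices = [slice(a - 1, b) for a, b in segments]
        for _ in range(300):
            moved = False
            for d1 in range(len(dom_slices)):
                for d2 in range(d1 + 1, len(dom_slices)):
                    p1, p2 = xyz[dom_slices[d1]], xyz[dom_slices[d2]]
                    diff = p1[:, None, :] - p2[None, :, :]
                    dist = np.sqrt((diff**2).sum(axis=-1))
                    overlap = 4.8 - dist.min()  # bead diameter at rigid radius
                    if overlap > 0:
                        v = p2.mean(axis=0) - p1.mean(axis=0)
                        v /= max(1e-9, np.linalg.norm(v))
                        xyz[dom_slices[d1]] -= v * min(0.25, overlap / 2)
                        xyz[dom_slices[d2]] += v * min(0.25, overlap / 2)
                        moved = True
            if not moved:
                break
        unplaced = np.where(~placed)[0]
        for i in unplaced:
            left = i - 1
            right = next((j for j in range(i + 1, len(residues)) if placed[j]), None)
            if right is None:
                xyz[i] = xyz[left] + [3.8, 0, 0]
                placed[i] = True
            else:
                # walk toward the next placed residue in even steps
                t = 1.0 / (right - i + 1)
                xyz[i] = (1 - t) * xyz[left] + t * xyz[right]
                placed[i] = True
        # route linkers around (not through) the domains: Laplacian smoothing
        # toward even bond lengths with per-bead collision resolution against
        # domain beads (clearance = sum of flexible and rigid bead radii)
        dom_pts = np.concatenate([xyz[a - 1 : b] for a, b in segments])
        clear_dom = FLEXIBLE_BEAD_RADIUS + RIGID_BEAD_RADIUS + 0.1
        clear_flex = 2 * FLEXIBLE_BEAD_RADIUS + 0.1
        unplaced_arr = np.array(unplaced, dtype=int)

        def resolve(p: np.ndarray, i: int) -> np.ndarray:
            others = unplaced_arr[np.abs(unplaced_arr - i) > 2]
            for _ in range(8):
                moved_any = False
                for pts, clear in ((dom_pts, clear_dom), (xyz[others], clear_flex)):
                    if len(pts) == 0:
                        continue
                    d = np.linalg.norm(pts - p, axis=1)
                    k = int(np.argmin(d))
                    if d[k] < clear:
                        v = p - pts[k]
                        norm = float(np.linalg.norm(v))
                        if norm < 1e-9:
                            v, norm = np.array([0.0, 0.0, 1.0]), 1.0
                        p = pts[k] + v / norm * clear
                        moved_any = True
                if not moved_any:
                    break
            return p

        max_bond = 5.0  # linker bond-length cap, Å

        def cap_bond(i: int) -> None:
            v = xyz[i] - xyz[i - 1]
            norm = float(np.linalg.norm(v))
            if norm > max_bond:
                xyz[i] = xyz[i - 1] + v / norm * max_bond

        for _ in range(30):
            for i in unplaced:
                if i + 1 < len(residues):
                    xyz[i] = resolve(0.5 * (xyz[i - 1] + xyz[i + 1]), i)

        def collides(i: int) -> bool:
            others = unplaced_arr[np.abs(unplaced_arr - i) > 2]
            if np.linalg.norm(dom_pts - xyz[i], axis=1).min() < clear_dom - 1e-6:
                return True
            return bool(
                len(others)
                and np.linalg.norm(xyz[others] - xyz[i], axis=1).min() < clear_flex - 1e-6
            )

        # enforce bond caps and clear residual collisions: the planted state
        # must itself be clean under the modeling priors
        for _ in range(60):
            for i in unplaced:
                cap_bond(i)
                xyz[i] = resolve(xyz[i], i)
            dirty = [i for i in unplaced if i + 1 < len(residues) and collides(i)]
            bonds_ok = all(
                np.linalg.norm(xyz[i] - xyz[i - 1]) <= max_bond + 1e-6 for i in unplaced
            )
            if not dirty and bonds_ok:
                break
        coords[name] = xyz
    return ToyProtein(
        spec=spec, segments=segments, residue_types=types, coords=coords, residues=residues
    )


# ---------------------------------------------------------------------------
# Cross-link detection


@dataclass
class SimLink:
    crosslink: CrossLink
    is_noise: bool
    distance: float


def simulate_crosslinks(
    protein: ToyProtein,
    state: str,
    linker: Optional[LinkerSpec] = None,
    detection_cutoff: float = 20.0,
    noise_rate: float = 0.05,
    p_detect: float = 0.5,
    seed: int = 0,
    min_separation: int = 3,
) -> list[SimLink]:
    """Distance-limited cross-link detection with a spurious-link tail.

    True links are sampled (each with probability ``p_detect``) from
    reactive-residue pairs whose Cα distance in ``state`` is at most the
    cutoff; noise links are drawn uniformly from pairs above the cutoff so
    that the expected noise fraction of the emitted list is ``noise_rate``.

    Detectability is drawn per residue pair (keyed by seed and the pair),
    not per state: calling with the same seed for two states of the same
    protein detects a pair in every state where it is within the cutoff, so
    state-exclusive links reflect geometry, not detection dropout.
    Deterministic given ``seed``.
    """
    import zlib

    if not 0 <= noise_rate < 1:
        raise ValueError("noise_rate must be in [0, 1)")
    linker = linker or default_bs3_linker()
    xyz = protein.coords[state]
    reactive = [
        r for r in protein.residues if protein.residue_types.get(r) in linker.reactive_residues
    ]
    near_pairs, far_pairs = [], []
    for i, j in itertools.combinations(reactive, 2):
        if j - i < min_separation:
            continue
        d = float(np.linalg.norm(xyz[i - 1] - xyz[j - 1]))
        (near_pairs if d <= detection_cutoff else far_pairs).append((i, j, d))

    def pair_draw(i: int, j: int) -> float:
        return float(np.random.default_rng(np.random.SeedSequence([seed, 11, i, j])).random())

    links = [
        SimLink(
            CrossLink(protein.residue_ref(i), protein.residue_ref(j), linker),
            is_noise=False,
            distance=d,
        )
        for i, j, d in near_pairs
        if pair_draw(i, j) < p_detect
    ]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13, zlib.crc32(state.encode())]))
    if far_pairs and links and noise_rate > 0:
        n_noise = rng.binomial(len(links), noise_rate / (1.0 - noise_rate))
        pick = rng.choice(len(far_pairs), size=min(n_noise, len(far_pairs)), replace=False)
        for k in np.sort(pick):
            i, j, d = far_pairs[int(k)]
            links.append(
                SimLink(
                    CrossLink(protein.residue_ref(i), protein.residue_ref(j), linker),
                    is_noise=True,
                    distance=d,
                )
            )
    return links


# ---------------------------------------------------------------------------
# Quantitation simulation


@dataclass
class QuantDesign:
    """Two experiments, each a label-swapped pair of samples."""

    experiments: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: {"I": ("I-1", "I-2"), "II": ("II-1", "II-2")}
    )

    def samples(self):
        for exp, (s1, s2) in self.experiments.items():
            # first sample: condition1 heavy; second: label-swapped
            yield s1, exp, "condition1"
            yield s2, exp, "condition2"


@dataclass
class SimulationTruth:
    """Everything the generators planted, keyed for end-to-end checks."""

    categories: dict[CrossLink, Category]
    effects: dict[CrossLink, float]
    noise_links: set[CrossLink]
    mixing_bias: dict[str, float]
    coordinates: dict[str, np.ndarray]


def simulate_quant(
    links_state1: Sequence[SimLink],
    links_state2: Sequence[SimLink],
    protein: ToyProtein,
    design: Optional[QuantDesign] = None,
    effect_size: float = 2.0,
    enriched_fraction: float = 0.08,
    lognormal_sd: float = 0.3,
    mixing_bias_sd: float = 0.5,
    noise_effect_sd: float = 0.4,
    seed: int = 0,
) -> tuple[list[QuantRecord], SimulationTruth]:
    """Simulate heavy/light peak-area tables for a two-state comparison.

    Links detected in both states yield doublets whose log2(condition1 /
    condition2) ratio is the planted effect plus peptide-level noise plus a
    per-sample mixing bias; an ``enriched_fraction`` of them (per side) gets
    the ±``effect_size`` enrichment effect, the rest are mutual (effect 0,
    but spurious links carry a small random effect so the outlier test sees
    a realistic null spread). State-exclusive links appear as singlets with
    the correct label orientation in every sample. Each residue pair is
    supported by 1–3 peptide pairs.
    """
    design = design or QuantDesign()
    rng = np.random.default_rng(seed)

    set1 = {sl.crosslink: sl for sl in links_state1}
    set2 = {sl.crosslink: sl for sl in links_state2}
    shared = sorted(set(set1) & set(set2), key=lambda ln: ln.positions)
    only1 = sorted(set(set1) - set(set2), key=lambda ln: ln.positions)
    only2 = sorted(set(set2) - set(set1), key=lambda ln: ln.positions)

    noise_links = {sl.crosslink for sl in list(links_state1) + list(links_state2) if sl.is_noise}

    categories: dict[CrossLink, Category] = {}
    effects: dict[CrossLink, float] = {}
    genuine_shared = [ln for ln in shared if ln not in noise_links]
    n_enriched = int(round(enriched_fraction * len(genuine_shared)))
    picks = list(
        rng.choice(len(genuine_shared), size=min(2 * n_enriched, len(genuine_shared)), replace=False)
    )
    for rank, k in enumerate(picks):
        ln = genuine_shared[int(k)]
        if rank < n_enriched:
            categories[ln], effects[ln] = Category.ENRICHED_1, effect_size
        else:
            categories[ln], effects[ln] = Category.ENRICHED_2, -effect_size
    for ln in shared:
        if ln in categories:
            continue
        categories[ln] = Category.MUTUAL
        effects[ln] = float(rng.normal(0.0, noise_effect_sd)) if ln in noise_links else 0.0
    for ln in only1:
        categories[ln] = Category.UNIQUE_1
    for ln in only2:
        categories[ln] = Category.UNIQUE_2

    mixing_bias = {s: float(rng.normal(0.0, mixing_bias_sd)) for s, _, _ in design.samples()}
    n_peptides = {ln: int(rng.integers(1, 4)) for ln in categories}

    records: list[QuantRecord] = []
    for sample_id, exp_id, heavy_condition in design.samples():
        bias = mixing_bias[sample_id]
        for ln, cat in categories.items():
            for p in range(n_peptides[ln]):
                pep_id = f"pep_{ln.a.position}_{ln.b.position}_{p}"
                base = float(2.0 ** rng.normal(20.0, 1.0))  # condition-2 abundance scale
                if cat in (Category.UNIQUE_1, Category.UNIQUE_2):
                    cond = 1 if cat is Category.UNIQUE_1 else 2
                    area = base * 2.0 ** float(rng.normal(0.0, lognormal_sd))
                    heavy = heavy_condition == f"condition{cond}"
                    records.append(
                        QuantRecord(
                            sample_id=sample_id,
                            experiment_id=exp_id,
                            label_orientation=heavy_condition,
                            peptide_pair_id=pep_id,
                            crosslink=ln,
                            area_light=0.0 if heavy else area,
                            area_heavy=area if heavy else 0.0,
                            detection=(
                                Detection.SINGLET_CONDITION1
                                if cond == 1
                                else Detection.SINGLET_CONDITION2
                            ),
                        )
                    )
                    continue
                log_ratio = effects[ln] + bias + float(rng.normal(0.0, lognormal_sd))
                area_c2 = base
                area_c1 = base * 2.0**log_ratio
                if heavy_condition == "condition1":
                    area_heavy, area_light = area_c1, area_c2
                else:
                    area_heavy, area_light = area_c2, area_c1
                records.append(
                    QuantRecord(
                        sample_id=sample_id,
                        experiment_id=exp_id,
                        label_orientation=heavy_condition,
                        peptide_pair_id=pep_id,
                        crosslink=ln,
                        area_light=area_light,
                        area_heavy=area_heavy,
                        detection=Detection.DOUBLET,
                    )
                )

    truth = SimulationTruth(
        categories=categories,
        effects=effects,
        noise_links=noise_links,
        mixing_bias=mixing_bias,
        coordinates={k: v.copy() for k, v in protein.coords.items()},
    )
    return records, truth


# ---------------------------------------------------------------------------
# The two-state preset


@dataclass
class TwoStateSimulation:
    protein: ToyProtein
    links_state1: list[SimLink]
    links_state2: list[SimLink]
    records: list[QuantRecord]
    truth: SimulationTruth
    detection_cutoff: float = 12.0


#: Generator defaults of the two-state preset (see docs/methods.md).
PRESET_DETECTION_CUTOFF = 12.0
PRESET_P_DETECT = 0.7
PRESET_NOISE_RATE = 0.05


def two_state_preset(seed: int = 0, **quant_kwargs) -> TwoStateSimulation:
    """The default end-to-end scenario: a relocating domain on a fixed core.

    The chain carries four domains D1–D2–D3–D4. D1, D2 and the folded-back
    D3 form a rigid core whose arrangement is shared by both states (the
    analog of a crystallized, conformationally stable body). The terminal
    domain D4 is docked on top of D3 in state A and relocates into the
    three-sided pocket formed by D1, D2 and D3 in state B — a long-range
    domain relocation like a thioester domain swinging along the molecule.

    Cross-links are detected per state with a 12 Å Cα cutoff, 70% per-pair
    detection efficiency and a 5% spurious-link rate; quantitation uses two
    experiments with label-swapped replica pairs; state A is condition 1.
    """
    spec = ToyProteinSpec(
        n_domains=4,
        residues_per_domain=24,
        linker_length=12,
        domain_spacing=15.0,
        reactive_fraction=0.5,
        states={
            "A": [
                (0.0, (0, 0, 0)),
                (0.0, (0, 0, 0)),
                (0.0, (-22.5, 0.0, 13.0)),  # D3 folds back over D1-D2
                (0.0, (-37.5, 0.0, 28.0)),  # D4 docked on top of D3
            ],
            "B": [
                (0.0, (0, 0, 0)),
                (0.0, (0, 0, 0)),
                (0.0, (-22.5, 0.0, 13.0)),
                (0.6, (-37.5, 11.0, 6.0)),  # D4 relocated into the pocket
            ],
        },
        seed=seed,
    )
    protein = make_toy_protein(spec)
    links_a = simulate_crosslinks(
        protein,
        "A",
        detection_cutoff=PRESET_DETECTION_CUTOFF,
        noise_rate=PRESET_NOISE_RATE,
        p_detect=PRESET_P_DETECT,
        seed=seed + 1,
    )
    links_b = simulate_crosslinks(
        protein,
        "B",
        detection_cutoff=PRESET_DETECTION_CUTOFF,
        noise_rate=PRESET_NOISE_RATE,
        p_detect=PRESET_P_DETECT,
        seed=seed + 1,
    )
    records, truth = simulate_quant(
        links_a, links_b, protein, seed=seed + 3, **quant_kwargs
    )
    return TwoStateSimulation(
        protein=protein,
        links_state1=links_a,
        links_state2=links_b,
        records=records,
        truth=truth,
        detection_cutoff=PRESET_DETECTION_CUTOFF,
    )


@dataclass
class ModelingScenario:
    """Everything needed to model state B of the preset and check recovery."""

    representation: "Representation"  # built from state A (the known structure)
    restraints: object  # RestraintSet on the state-B link observations
    params: object  # ScoringParams matched to the generator
    truth_positions: np.ndarray  # planted state-B coordinates
    mobile_body: int  # index of the relocated body in the representation
    declared_precision: float = 5.0  # Å, on the mobile domain after core superposition


def modeling_scenario(sim: TwoStateSimulation) -> ModelingScenario:
    """Set up cross-link-restrained modeling of the preset's state B.

    The three core domains (and the linkers joining them) are fused into a
    single fixed body, as their arrangement is shared with state A; the
    relocated terminal domain is the mobile rigid body; the state-B link
    observations become restraints (spurious links fall into the ``single``
    ψ class, genuine ones into ``consistent``). The forward model is the
    step form matched to the generator's hard detection cutoff, with half a
    bead radius of slack; connectivity rest length matches the generator's
    linker bond cap.
    """
    from xlmstruct.modeling import RestraintSet, ScoringParams

    rep = sim.protein.representation("A", core_domain=0, rigid_groups=[[0, 1, 2], [3]])
    restraints = RestraintSet(
        crosslinks=[
            (sl.crosslink, SINGLE if sl.is_noise else CONSISTENT)
            for sl in sim.links_state2
        ],
        disulfides=[],
        satisfaction_threshold=sim.detection_cutoff + 1.0,
    )
    params = ScoringParams(
        forward_d0=sim.detection_cutoff + 0.5,
        forward_form="step",
        connect_rest_per_gap=5.0,
    )
    return ModelingScenario(
        representation=rep,
        restraints=restraints,
        params=params,
        truth_positions=sim.protein.coords["B"].copy(),
        mobile_body=1,
    )
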