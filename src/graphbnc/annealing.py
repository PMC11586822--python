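"""Rigid-body placement of a nanocluster on a protein surface by
Metropolis simulated annealing.

The loss combines three terms evaluated on the coarse-grained system
(CA beads vs ligand-head beads):

* a geometric well per ligand, g(d) = theta/d^4 - exp(-(d - d0)^2 / sigma)
  with theta = d0^4 / 3, where d is the minimum head-to-CA distance --
  repulsive at short range, minimal near the target contact distance d0,
  and decaying to zero at large separation;
* a steric barrier sum(1 / (t_j - c)^4) over CA beads whose distance t_j
  to the cluster centre satisfies (t_j - c) < 5.5 A, with c the minimum
  centre-to-head distance, keeping the cluster out of the protein body;
* -k * sum(phi_j) over ligand-residue pairs within 5.5 A, pulling the
  cluster toward strongly interacting (phi ~ 1) residues.

Proposals translate the cluster along a random direction and rotate it
about its centre of mass; acceptance follows the Metropolis criterion
P = min(1, exp(-dL / k_B T)) with k_B = 1 (reduced units).  Step sizes
adapt to hold the acceptance fraction inside the 40-60% band.  Final
centre-of-mass points from many independent runs are clustered
(complete-linkage agglomerative) to rank candidate sites, and the best
member of each top site is refined with an all-atom restricted anneal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering

from .geometry import fibonacci_sphere, random_rotation, rotation_about_axis
from .structures import ClusterModel, CoarseProtein, RigidPose

logger = logging.getLogger(__name__)

BARRIER_CAP = 1e6
ADAPT_WINDOW = 50
ACCEPT_LOW, ACCEPT_HIGH = 0.40, 0.60
STEP_UP, STEP_DOWN = 1.1, 0.9
TRANS_STEP_BOUNDS = (1e-3, 20.0)
ROT_STEP_BOUNDS = (1e-3, np.pi)


@dataclass
class LossParams:
    """Knobs of the annealing loss (distances in Angstrom)."""

    d0: float = 5.0            # target head-CA contact distance
    sigma: float = 2.0         # Gaussian well width (A^2)
    k: float = 1.0             # weight of the interaction-strength term
    close_margin: float = 5.5  # barrier selection margin on (t_j - c)
    pair_cutoff: float = 5.5   # pair inclusion cutoff for the phi sum
    barrier_cap: float = BARRIER_CAP

    def __post_init__(self):
        if self.d0 <= 0 or self.sigma <= 0 or self.k < 0:
            raise ValueError("require d0 > 0, sigma > 0, k >= 0")

    @property
    def theta(self) -> float:
        return self.d0 ** 4 / 3.0


@dataclass
class PlacementState:
    """Rigid pose of the cluster plus the bookkeeping of one MC chain."""

    pose: RigidPose
    loss: float = np.inf
    temperature: float = 1.0
    trans_step: float = 2.0
    rot_step: float = 0.3


def geometric_well(d, params: LossParams):
    """Per-ligand geometric term g(d); minimum of depth 1 - theta/d0^4 near d0."""
    d = np.asarray(d, dtype=float)
    return params.theta / np.maximum(d, 1e-6) ** 4 - np.exp(
        -((d - params.d0) ** 2) / params.sigma)


class CoarseLoss:
    """Loss evaluator on the CA / ligand-head coarse-grained system."""

    def __init__(self, protein: CoarseProtein, cluster: ClusterModel,
                 phi: np.ndarray, params: LossParams | None = None):
        self.ca = protein.ca_coords
        self.heads_ref = cluster.head_centroids
        self.com_ref = cluster.com
        self.phi = np.asarray(phi, dtype=float)
        if self.phi.shape != (len(self.heads_ref), len(self.ca)):
            raise ValueError("phi table shape must be (n_ligands, n_residues)")
        self.params = params or LossParams()
        # c: minimum centre-to-head distance, fixed by the cluster geometry
        self.c = float(np.linalg.norm(self.heads_ref - self.com_ref, axis=1).min())

    def __call__(self, pose: RigidPose) -> float:
        p = self.params
        heads = pose.apply(self.heads_ref)
        center = self.com_ref + pose.translation
        d = cdist(heads, self.ca)
        L = geometric_well(d.min(axis=1), p).sum()
        t = np.linalg.norm(self.ca - center, axis=1)
        gap = t - self.c
        close = gap < p.close_margin
        if close.any():
            barrier = np.where(gap[close] > 0,
                               1.0 / np.maximum(gap[close], 1e-12) ** 4,
                               p.barrier_cap)
            L += np.minimum(barrier, p.barrier_cap).sum()
        L -= p.k * self.phi[d <= p.pair_cutoff].sum()
        return float(L)


class AllAtomLoss:
    """Restricted all-atom loss for the refinement stage.

    Distances use all heavy atoms: the per-ligand well distance is the
    minimum ligand-atom to protein-atom distance, and a (ligand, residue)
    pair enters the phi sum when any of their atoms are within the pair
    cutoff.  Proposals violating the steric floor (interatomic < 1.5 A) or
    leaving the restriction sphere are rejected upstream.
    """

    def __init__(self, protein_coords, protein_residue_index, ca_coords,
                 cluster: ClusterModel, phi, params: LossParams | None = None,
                 steric_floor: float = 1.5):
        self.pa = np.asarray(protein_coords, dtype=float)
        res_idx = np.asarray(protein_residue_index, dtype=int)
        order = np.argsort(res_idx, kind="stable")
        self.pa = self.pa[order]
        res_sorted = res_idx[order]
        self.res_starts = np.searchsorted(res_sorted, np.arange(res_sorted.max() + 1))
        self.ca = np.asarray(ca_coords, dtype=float)
        self.params = params or LossParams()
        self.phi = np.asarray(phi, dtype=float)
        self.steric_floor = steric_floor
        self.cluster_ref = cluster.coords
        self.com_ref = cluster.com
        lig_atoms, lig_starts = [], [0]
        for lig in cluster.topology.ligands:
            atoms = (list(lig.head_atom_indices) + list(lig.ring_atom_indices)
                     + ([lig.sulfur_index] if lig.sulfur_index is not None else []))
            lig_atoms.extend(atoms)
            lig_starts.append(len(lig_atoms))
        self.lig_atom_idx = np.array(lig_atoms, dtype=int)
        self.lig_starts = np.array(lig_starts[:-1], dtype=int)
        heads = cluster.head_centroids
        self.c = float(np.linalg.norm(heads - self.com_ref, axis=1).min())

    def min_interatomic(self, pose: RigidPose) -> float:
        moved = pose.apply(self.cluster_ref)
        return float(cdist(moved, self.pa).min())

    def __call__(self, pose: RigidPose) -> float:
        p = self.params
        moved = pose.apply(self.cluster_ref)
        d_all = cdist(moved[self.lig_atom_idx], self.pa)  # (M, A)
        # min over ligand-atom blocks then residue-atom blocks
        per_lig = np.minimum.reduceat(d_all, self.lig_starts, axis=0)
        per_pair = np.minimum.reduceat(per_lig, self.res_starts, axis=1)
        L = geometric_well(per_pair.min(axis=1), p).sum()
        center = self.com_ref + pose.translation
        t = np.linalg.norm(self.ca - center, axis=1)
        gap = t - self.c
        close = gap < p.close_margin
        if close.any():
            barrier = np.where(gap[close] > 0,
                               1.0 / np.maximum(gap[close], 1e-12) ** 4,
                               p.barrier_cap)
            L += np.minimum(barrier, p.barrier_cap).sum()
        L -= p.k * self.phi[per_pair <= p.pair_cutoff].sum()
        return float(L)


# ---------------------------------------------------------------------------
# Metropolis machinery


def metropolis_accept(delta: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """P = min(1, exp(-dL / k_B T)), k_B = 1; T <= 0 accepts only downhill."""
    if delta <= 0:
        return True
    if temperature <= 0:
        return False
    return rng.random() < np.exp(-delta / temperature)


def adapt_steps(acceptance: float, trans_step: float, rot_step: float):
    """Multiply steps by 1.1 above 60% acceptance, by 0.9 below 40%."""
    if acceptance > ACCEPT_HIGH:
        f = STEP_UP
    elif acceptance < ACCEPT_LOW:
        f = STEP_DOWN
    else:
        f = 1.0
    return (float(np.clip(trans_step * f, *TRANS_STEP_BOUNDS)),
            float(np.clip(rot_step * f, *ROT_STEP_BOUNDS)))


def propose(pose: RigidPose, trans_step: float, rot_step: float,
            rng: np.random.Generator) -> RigidPose:
    """Random translation plus rotation about the current centre of mass."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    dt = direction * rng.uniform(0, trans_step)
    axis = rng.normal(size=3)
    angle = rng.uniform(0, rot_step)
    dR = rotation_about_axis(axis, angle)
    return RigidPose(rotation=dR @ pose.rotation,
                     translation=pose.translation + dt,
                     pivot=pose.pivot)


@dataclass
class ChainResult:
    pose: RigidPose
    loss: float
    com_trace: np.ndarray       # (n_recorded, 3)
    acceptance_flags: np.ndarray
    loss_trace: np.ndarray
    final_steps: tuple = (0.0, 0.0)


def run_chain(evaluator, pose0: RigidPose, n_steps: int,
              temperature, rng: np.random.Generator,
              trans_step: float = 2.0, rot_step: float = 0.3,
              adapt_window: int = ADAPT_WINDOW,
              constraint=None, com_ref=None) -> ChainResult:
    """One Metropolis chain.

    ``temperature`` is either a constant or a callable step -> T.
    ``constraint(pose)`` may veto proposals outright (hard constraints).
    """
    t_of = temperature if callable(temperature) else (lambda _k: temperature)
    pose = pose0
    loss = evaluator(pose)
    com_ref = evaluator.com_ref if com_ref is None else com_ref
    coms = np.empty((n_steps + 1, 3))
    losses = np.empty(n_steps + 1)
    accepted = np.zeros(n_steps, dtype=bool)
    coms[0] = com_ref + pose.translation
    losses[0] = loss
    adapt_every = max(1, adapt_window // 5)
    for step in range(n_steps):
        cand = propose(pose, trans_step, rot_step, rng)
        ok = constraint is None or constraint(cand)
        if ok:
            cand_loss = evaluator(cand)
            if metropolis_accept(cand_loss - loss, t_of(step), rng):
                pose, loss = cand, cand_loss
                accepted[step] = True
        # trailing-window control, evaluated every adapt_window//5 proposals
        if step + 1 >= adapt_window and (step + 1) % adapt_every == 0:
            frac = accepted[step + 1 - adapt_window:step + 1].mean()
            trans_step, rot_step = adapt_steps(frac, trans_step, rot_step)
        coms[step + 1] = com_ref + pose.translation
        losses[step + 1] = loss
    return ChainResult(pose=pose, loss=loss, com_trace=coms,
                       acceptance_flags=accepted, loss_trace=losses,
                       final_steps=(trans_step, rot_step))


# ---------------------------------------------------------------------------
# Annealing driver


@dataclass
class Schedule:
    """Geometric cooling: T = T0 * alpha^(step // block).

    The loss is dimensionless and its barrier scale is pinned by
    construction (the geometric well has depth 2/3 per engaged ligand and
    the phi term is O(k) per in-range pair), so the default T0 = 1 sits at
    the well-hopping scale regardless of the system; over 5,000 steps the
    default schedule cools to 0.077 T0, freezing chains into the deepest
    wells they have found.  ``t0=None`` requests probe calibration
    (:func:`calibrate_t0`) instead of the fixed default.
    """

    t0: float | None = 1.0
    alpha: float = 0.95
    block: int = 100
    n_steps: int = 5000

    @property
    def mid_temperature(self) -> float:
        """Temperature at the schedule midpoint (for fixed-T diagnostics)."""
        t0 = 1.0 if self.t0 is None else self.t0
        return t0 * self.alpha ** (self.n_steps // 2 // self.block)

    def temperature_fn(self, t0: float):
        return lambda step: t0 * self.alpha ** (step // self.block)


def calibrate_t0(evaluator, pose0: RigidPose, rng: np.random.Generator,
                 n_probe: int = 200, target_acceptance: float = 0.8,
                 trans_step: float = 2.0, rot_step: float = 0.3,
                 constraint=None) -> float:
    """T0 such that typical uphill moves accept at ~``target_acceptance``.

    A 200-step accept-all probe chain explores the landscape from the
    start pose (including well escapes, which set the relevant barrier
    scale); T0 = mean positive dL / -ln(target acceptance).
    """
    pose, loss = pose0, evaluator(pose0)
    ups = []
    for _ in range(n_probe):
        cand = propose(pose, trans_step, rot_step, rng)
        if constraint is not None and not constraint(cand):
            continue
        cand_loss = evaluator(cand)
        delta = cand_loss - loss
        if delta > 0:
            ups.append(min(delta, 1e3))
        pose, loss = cand, cand_loss
    if not ups:
        return 1.0
    return float(np.mean(ups) / (-np.log(target_acceptance)))


def initial_poses(protein: CoarseProtein, cluster: ClusterModel, n_runs: int,
                  rng: np.random.Generator, clearance: float = 2.0,
                  contact_distance: float = 5.0) -> list:
    """Evenly distributed approach directions (Fibonacci sphere), random
    initial orientations, starting just outside contact.

    Each cluster is brought in along its direction until the closest
    head-to-CA distance reaches ``contact_distance + clearance``, i.e.
    just outside the geometric well, where the loss gradient is alive.
    """
    center = protein.ca_coords.mean(axis=0)
    r_max = protein.bounding_radius + cluster.radius + 30.0
    target = contact_distance + clearance
    poses = []
    for direction in fibonacci_sphere(n_runs):
        R = random_rotation(rng)
        heads0 = (cluster.head_centroids - cluster.com) @ R.T
        lo, hi = 0.0, r_max
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            d = cdist(heads0 + center + mid * direction, protein.ca_coords).min()
            if d < target:
                lo = mid
            else:
                hi = mid
        poses.append(RigidPose(rotation=R,
                               translation=center + hi * direction - cluster.com,
                               pivot=cluster.com))
    return poses


def anneal(protein: CoarseProtein, cluster: ClusterModel, phi: np.ndarray,
           params: LossParams | None = None, schedule: Schedule | None = None,
           n_runs: int = 64, seed: int = 0,
           confine_margin: float = 5.0) -> list:
    """Independent annealing runs; returns a list of ChainResult.

    The sampler confines the cluster COM to a shell of
    ``protein bounding radius + cluster radius + confine_margin`` around
    the protein centroid (proposals beyond it are rejected): the loss
    vanishes at large separation, so an unconfined chain at
    migration-capable temperatures would simply evaporate instead of
    sampling the surface.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    params = params or LossParams()
    schedule = schedule or Schedule()
    evaluator = CoarseLoss(protein, cluster, phi, params)
    master = np.random.SeedSequence(seed)
    init_rng = np.random.default_rng(master.spawn(1)[0])
    poses = initial_poses(protein, cluster, n_runs, init_rng,
                          contact_distance=params.d0)
    center = protein.ca_coords.mean(axis=0)
    r_conf = protein.bounding_radius + cluster.radius + confine_margin
    com_ref = cluster.com

    def constraint(pose: RigidPose) -> bool:
        return np.linalg.norm(com_ref + pose.translation - center) <= r_conf

    t0 = schedule.t0
    if t0 is None:
        t0 = calibrate_t0(evaluator, poses[0], init_rng, constraint=constraint)
        logger.info("calibrated T0 = %.3f", t0)
    run_seeds = master.spawn(n_runs + 1)[1:]
    results = []
    for i in range(n_runs):
        rng = np.random.default_rng(run_seeds[i])
        results.append(run_chain(evaluator, poses[i], schedule.n_steps,
                                 schedule.temperature_fn(t0), rng,
                                 constraint=constraint))
    return results


# ---------------------------------------------------------------------------
# Site selection


def interaction_total(evaluator: CoarseLoss, pose: RigidPose,
                      table: np.ndarray) -> float:
    """Sum of table entries over in-range (<= pair cutoff) pairs at a pose."""
    heads = pose.apply(evaluator.heads_ref)
    d = cdist(heads, evaluator.ca)
    return float(table[d <= evaluator.params.pair_cutoff].sum())


@dataclass
class Site:
    member_count: int
    member_indices: list
    representative_index: int
    representative_pose: RigidPose
    predicted_energy: float
    centroid: np.ndarray


@dataclass
class SiteRanking:
    sites: list  # ordered by member count descending
    com_points: np.ndarray
    labels: np.ndarray


def select_sites(results: list, evaluator: CoarseLoss, energy_table: np.ndarray,
                 n: int = 3, cluster_diameter: float = 10.0) -> SiteRanking:
    """Cluster final COM points and rank candidate sites by membership.

    The representative of each site is the member pose with the lowest
    (most negative) predicted total interaction energy, computed from the
    raw predicted pair-energy table over in-range pairs.
    """
    points = np.array([r.com_trace[-1] for r in results])
    if len(points) < 2 * n:
        logger.warning("only %d sampled points for %d sites", len(points), n)
    if len(points) == 1:
        labels = np.zeros(1, dtype=int)
    else:
        agg = AgglomerativeClustering(n_clusters=None,
                                      distance_threshold=cluster_diameter,
                                      linkage="complete")
        labels = agg.fit_predict(points)
    n_found = labels.max() + 1
    if n_found < n:
        logger.warning("found %d site clusters, fewer than requested %d", n_found, n)
    order = np.argsort([-np.sum(labels == c) for c in range(n_found)], kind="stable")
    sites = []
    for c in order[:n]:
        members = np.nonzero(labels == c)[0]
        energies = [interaction_total(evaluator, results[i].pose, energy_table)
                    for i in members]
        best = members[int(np.argmin(energies))]
        sites.append(Site(member_count=len(members),
                          member_indices=members.tolist(),
                          representative_index=int(best),
                          representative_pose=results[best].pose,
                          predicted_energy=float(min(energies)),
                          centroid=points[members].mean(axis=0)))
    return SiteRanking(sites=sites, com_points=points, labels=labels)


# ---------------------------------------------------------------------------
# All-atom restricted refinement


@dataclass
class RefineResult:
    pose: RigidPose
    loss: float
    clash_free: bool
    com_trace: np.ndarray


def refine(protein_coords, protein_residue_index, ca_coords,
           cluster: ClusterModel, phi: np.ndarray, site_pose: RigidPose,
           params: LossParams | None = None, restrict_radius: float = 8.0,
           steric_floor: float = 1.5, n_steps: int = 2000,
           seed: int = 0, d0: float = 4.0) -> RefineResult:
    """Restricted all-atom anneal around a selected site.

    The centre of mass must stay within ``restrict_radius`` of the site
    pose and no interatomic distance may drop below the steric floor;
    proposals violating either are rejected outright.  The contact target
    d0 tightens to the all-atom scale (default 4.0 A) and the chain is
    cooled to zero temperature, so the final loss never exceeds that of
    the best feasible pose encountered.
    """
    params = replace(params or LossParams(), d0=d0)
    evaluator = AllAtomLoss(protein_coords, protein_residue_index, ca_coords,
                            cluster, phi, params, steric_floor)
    site_com = cluster.com + site_pose.translation
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def constraint(pose: RigidPose) -> bool:
        if np.linalg.norm(cluster.com + pose.translation - site_com) > restrict_radius:
            return False
        return evaluator.min_interatomic(pose) >= steric_floor

    pose0 = site_pose
    if evaluator.min_interatomic(pose0) < steric_floor:
        pose0 = _resolve_clashes(evaluator, pose0, site_com, restrict_radius,
                                 steric_floor, rng)
    t0 = calibrate_t0(evaluator, pose0, rng, trans_step=1.0, rot_step=0.15)
    sched = Schedule(t0=t0, alpha=0.85, block=100, n_steps=n_steps)
    res = run_chain(evaluator, pose0, n_steps, sched.temperature_fn(t0), rng,
                    trans_step=1.0, rot_step=0.15, constraint=constraint)
    clash_free = evaluator.min_interatomic(res.pose) >= steric_floor
    if not clash_free:
        logger.warning("refinement could not resolve all steric clashes")
    return RefineResult(pose=res.pose, loss=res.loss, clash_free=clash_free,
                        com_trace=res.com_trace)


def _resolve_clashes(evaluator, pose, site_com, restrict_radius, steric_floor,
                     rng, max_tries: int = 500):
    """Nudge a clashing start pose outward until it clears the steric floor."""
    best_pose, best_gap = pose, evaluator.min_interatomic(pose)
    center = evaluator.pa.mean(axis=0)
    outward = site_com - center
    outward = outward / max(np.linalg.norm(outward), 1e-9)
    for i in range(max_tries):
        shift = outward * 0.25 * (i % 20) + rng.normal(scale=0.5, size=3)
        cand = RigidPose(pose.rotation, pose.translation + shift, pose.pivot)
        if np.linalg.norm(evaluator.com_ref + cand.translation - site_com) > restrict_radius:
            continue
        gap = evaluator.min_interatomic(cand)
        if gap >= steric_floor:
            return cand
        if gap > best_gap:
            best_pose, best_gap = cand, gap
    logger.warning("clash resolution failed; starting from best-found pose")
    return best_pose
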