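"""Synthetic longitudinal microbiota with known gLV ground truth.

The generator emulates the structure of a weekly oropharyngeal swab
study: ~30 participants (a mix of smokers and nonsmokers), each sampled
weekly for ~30 weeks, each carrying a small core community of OTUs whose
dynamics follow a noisy Ricker-map gLV model, sequenced to a fixed library
size by multinomial read sampling. Every downstream stage (filtering,
diversity, inference, stability) can therefore be tested against known
interaction matrices without any external download.

Scales are chosen to look like relative-abundance data at weekly
resolution: per-taxon equilibria of a few percent to ~20% of the
community, interaction coefficients of order one, hence intrinsic growth
rates of order 0.1 per week and gentle, near-equilibrium dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .data_model import OtuTable, PhyloTree, StudyMetadata
from .glv import GlvModel


class SimulationError(RuntimeError):
    """Raised when a trajectory diverges or a community goes extinct."""


def random_glv(n: int, connectance: float = 0.3, strength_sd: float = 0.5,
               diag_mean: float = -1.0, seed: int = 0) -> GlvModel:
    """Random gLV model: sparse off-diagonal interactions, negative diagonal.

    Off-diagonal A_ij is nonzero with probability ``connectance`` and then
    drawn from N(0, strength_sd^2); diagonal entries are negative, drawn
    uniformly within 50% of ``diag_mean`` (self-limitation); growth rates
    are positive.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= connectance <= 1:
        raise ValueError("connectance must be in [0, 1]")
    if strength_sd <= 0:
        raise ValueError("strength_sd must be > 0")
    if diag_mean >= 0:
        raise ValueError("diag_mean must be < 0")
    rng = np.random.default_rng(seed)
    mask = rng.random((n, n)) < connectance
    A = np.where(mask, rng.normal(0.0, strength_sd, (n, n)), 0.0)
    diag = diag_mean * rng.uniform(0.5, 1.5, n)
    np.fill_diagonal(A, diag)
    r = rng.uniform(0.05, 0.5, n)
    return GlvModel(A, r, [f"sp{i}" for i in range(n)])


def random_stable_glv(n: int, connectance: float = 0.3,
                      strength_sd: float = 0.5, seed: int = 0,
                      x_star_range: tuple[float, float] = (0.02, 0.15),
                      max_tries: int = 200) -> tuple[GlvModel, np.ndarray]:
    """Random gLV model with a feasible, locally stable interior equilibrium.

    The equilibrium x* is drawn first (on a relative-abundance scale) and
    r = -A x* set to place it; candidates are rejected until the Ricker map
    is locally stable there (spectral radius of I + diag(x*) A below 1) and
    not marginal. Returns (model, x_star).
    """
    base = np.random.default_rng(seed)
    for attempt in range(max_tries):
        sub_seed = int(base.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        model = random_glv(n, connectance, strength_sd, -1.0, sub_seed)
        x_star = rng.uniform(*x_star_range, n)
        r = -model.A @ x_star
        J = x_star[:, None] * model.A
        eig = np.linalg.eigvals(np.eye(n) + J)
        lam_cont = np.max(np.linalg.eigvals(J).real)
        if np.max(np.abs(eig)) < 0.999 and lam_cont < -1e-3:
            return GlvModel(model.A, r, model.otu_ids), x_star
    raise RuntimeError(f"no stable model found in {max_tries} tries")


def simulate_ricker(model: GlvModel, x0: np.ndarray, T: int,
                    noise_sigma: float = 0.0, seed: int = 0,
                    extinction_floor: float = 1e-6,
                    overflow: float = 1e6) -> np.ndarray:
    """Iterate the noisy Ricker map for T steps; returns a (T+1, n) array.

    x_i(t+1) = x_i(t) exp(r_i + (A x(t))_i + eps_i(t)), eps ~ N(0, sigma^2).
    Multiplicative noise in the exponent matches the log-linear regression
    model used for inference. Values below ``extinction_floor`` are set to
    0 and stay 0. Deterministic when noise_sigma = 0.
    """
    x0 = np.asarray(x0, dtype=float)
    if T < 1:
        raise ValueError("T must be >= 1")
    if np.any(x0 <= 0):
        raise ValueError("x0 must be positive elementwise")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    n = model.n
    traj = np.empty((T + 1, n))
    traj[0] = x0
    x = x0.copy()
    for t in range(T):
        growth = model.r + model.A @ x
        if noise_sigma > 0:
            growth = growth + rng.normal(0.0, noise_sigma, n)
        x = x * np.exp(growth)
        x[x < extinction_floor] = 0.0
        if not np.all(np.isfinite(x)) or np.any(x > overflow):
            raise SimulationError(
                f"trajectory diverged at step {t + 1} "
                f"(max abundance {np.nanmax(x):.3g})")
        traj[t + 1] = x
    return traj


def batch_min_abundance(model: GlvModel, starts: np.ndarray, steps: int,
                        overflow: float = 1e6) -> float:
    """Minimum abundance reached over noiseless Ricker runs from many starts.

    ``starts`` is (m, n): all m trajectories are advanced together, which
    makes long permanence cross-checks (10^4 steps) cheap. Divergence past
    ``overflow`` raises.
    """
    X = np.asarray(starts, dtype=float).copy()
    if np.any(X <= 0):
        raise ValueError("starts must be positive")
    lowest = float(X.min())
    for t in range(steps):
        X = X * np.exp(model.r + X @ model.A.T)
        if not np.all(np.isfinite(X)) or np.any(X > overflow):
            raise SimulationError(f"batch trajectory diverged at step {t + 1}")
        lowest = min(lowest, float(X.min()))
    return lowest


def counts_from_trajectory(trajectory: np.ndarray, library_size: int = 10000,
                           seed: int = 0, sample_ids=None,
                           otu_ids=None) -> OtuTable:
    """Multinomial read sampling of each time point at a fixed library size."""
    traj = np.asarray(trajectory, dtype=float)
    if np.any(traj < 0):
        raise ValueError("trajectory must be non-negative")
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    sums = traj.sum(axis=1)
    if np.any(sums == 0):
        dead = np.nonzero(sums == 0)[0]
        raise SimulationError(f"community extinct at time point(s) {dead.tolist()}")
    rng = np.random.default_rng(seed)
    T, n = traj.shape
    counts = np.empty((T, n), dtype=np.int64)
    for t in range(T):
        counts[t] = rng.multinomial(library_size, traj[t] / sums[t])
    sample_ids = sample_ids or [f"S{t:03d}" for t in range(T)]
    otu_ids = otu_ids or [f"OTU{j:04d}" for j in range(n)]
    return OtuTable(counts, sample_ids, otu_ids)


def random_coalescent_tree(otu_ids: list[str], seed: int = 0) -> PhyloTree:
    """Random ultrametric tree over the OTUs (Kingman-coalescent heights)."""
    rng = np.random.default_rng(seed)
    nodes = [(TreeNode(name=o), 0.0) for o in otu_ids]
    if len(nodes) == 1:
        root, _ = nodes[0]
        root.length = 0.0
        return PhyloTree(root)
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, ha), (b, hb) = nodes[i], nodes[j]
        a.length = height - ha
        b.length = height - hb
        parent = TreeNode(children=[a, b])
        nodes = [nodes[m] for m in range(k) if m not in (i, j)]
        nodes.append((parent, height))
    root, _ = nodes[0]
    root.length = 0.0
    return PhyloTree(root)


def perturbation_series(model: GlvModel, x_star: np.ndarray,
                        n_epochs: int = 20, steps: int = 10,
                        noise_sigma: float = 0.0, seed: int = 0,
                        perturbation: float = 0.5,
                        extinction_floor: float = 1e-6):
    """Core time series from repeated perturbation-relaxation epochs.

    Each epoch restarts the community at the equilibrium jittered by a
    lognormal factor (``perturbation`` log-sd, i.e. ~1.6-fold abundance
    excursions) and follows its relaxation for ``steps`` weeks; epochs are
    separated by week gaps so inference never regresses across a restart.
    A single converging trajectory explores essentially one direction of
    state space once its transient has died, which leaves the lagged-
    abundance design nearly collinear; restarted excursions make every
    interaction identifiable.
    """
    from .community import CoreTimeSeries

    rng = np.random.default_rng(seed)
    weeks, rows = [], []
    w = 0
    for _ in range(n_epochs):
        x0 = np.clip(x_star * np.exp(rng.normal(0.0, perturbation, model.n)),
                     10 * extinction_floor, None)
        traj = simulate_ricker(model, x0, steps, noise_sigma,
                               seed=int(rng.integers(2**31 - 1)),
                               extinction_floor=extinction_floor)
        rows.append(traj)
        weeks.append(np.arange(w, w + steps + 1))
        w += steps + 3  # gap > 1 week breaks the transition chain
    ab = np.clip(np.vstack(rows), 0.0, 1.0)
    return CoreTimeSeries("synthetic", np.concatenate(weeks), ab,
                          model.otu_ids, 0.001, 0.85)


@dataclass
class FixtureConfig:
    """Knobs for the study-scale synthetic fixture."""

    library_size: int = 10000
    pool_size: int = 50
    connectance: float = 0.3
    strength_sd: float = 0.5
    noise_sigma: float = 0.05
    cold_fraction: float = 0.05
    antibiotic_fraction: float = 0.03
    smoker_fraction: float = 0.4  # 12 of 30 participants
    extinction_floor: float = 1e-6


@dataclass
class ParticipantDataset:
    """Ground truth and observables for one simulated participant."""

    participant_id: str
    model: GlvModel
    x_star: np.ndarray
    trajectory: np.ndarray
    core_otu_ids: list[str]
    noise_sigma: float
    seed: int


@dataclass
class StudyFixture:
    """A full simulated study: counts + metadata + tree + ground truth."""

    table: OtuTable
    metadata: StudyMetadata
    tree: PhyloTree
    participants: dict[str, ParticipantDataset] = field(default_factory=dict)


def make_study_fixture(participants: int = 30, weeks: int = 30,
                       n_core: int = 10, seed: int = 0,
                       config: FixtureConfig | None = None) -> StudyFixture:
    """Simulate a weekly longitudinal study with known gLV ground truth.

    Each participant carries a core community of ``n_core`` OTUs drawn from
    a shared pool, simulated with a participant-specific stable gLV model
    and sequenced by multinomial sampling at the configured library size.
    Metadata flags a configurable fraction of weeks as cold/antibiotics.
    """
    if participants < 1:
        raise ValueError("participants must be >= 1")
    if weeks < 2:
        raise ValueError("weeks must be >= 2")
    config = config or FixtureConfig()
    if config.pool_size < n_core:
        raise ValueError("pool_size must be >= n_core")
    rng = np.random.default_rng(seed)
    pool = [f"OTU{j:04d}" for j in range(config.pool_size)]
    tree = random_coalescent_tree(pool, seed=int(rng.integers(2**31 - 1)))

    n_smokers = int(round(config.smoker_fraction * participants))
    all_counts, meta_rows, per_participant = [], [], {}
    sample_ids = []
    for p in range(participants):
        pid = f"P{p + 1:02d}"
        p_seed = int(rng.integers(2**31 - 1))
        p_rng = np.random.default_rng(p_seed)
        core_idx = np.sort(p_rng.choice(config.pool_size, n_core, replace=False))
        core_ids = [pool[j] for j in core_idx]
        model, x_star = random_stable_glv(
            n_core, config.connectance, config.strength_sd, seed=p_seed)
        model = GlvModel(model.A, model.r, core_ids)
        x0 = x_star * np.exp(p_rng.normal(0.0, config.noise_sigma, n_core))
        traj = simulate_ricker(model, x0, weeks - 1, config.noise_sigma,
                               seed=p_seed,
                               extinction_floor=config.extinction_floor)
        counts_core = counts_from_trajectory(
            traj, config.library_size, seed=p_seed,
            sample_ids=[f"{pid}_W{w:02d}" for w in range(1, weeks + 1)],
            otu_ids=core_ids)
        full = np.zeros((weeks, config.pool_size), dtype=np.int64)
        full[:, core_idx] = counts_core.counts
        all_counts.append(full)

        smoking = "smoker" if p < n_smokers else "nonsmoker"
        sex = "female" if p_rng.random() < 0.7 else "male"
        age = int(p_rng.integers(18, 41))
        health = np.array(["healthy"] * weeks, dtype=object)
        n_cold = int(round(config.cold_fraction * weeks))
        n_abx = int(round(config.antibiotic_fraction * weeks))
        flagged = p_rng.choice(weeks, size=min(weeks, n_cold + n_abx),
                               replace=False)
        health[flagged[:n_cold]] = "cold"
        health[flagged[n_cold:]] = "antibiotics"
        for w in range(weeks):
            sid = f"{pid}_W{w + 1:02d}"
            sample_ids.append(sid)
            meta_rows.append({
                "sample_id": sid, "participant_id": pid, "week": w + 1,
                "smoking": smoking, "health": health[w], "sex": sex,
                "age": age,
            })
        per_participant[pid] = ParticipantDataset(
            participant_id=pid, model=model, x_star=x_star, trajectory=traj,
            core_otu_ids=core_ids, noise_sigma=config.noise_sigma,
            seed=p_seed)

    table = OtuTable(np.vstack(all_counts), sample_ids, pool)
    metadata = StudyMetadata(pd.DataFrame(meta_rows))
    return StudyFixture(table=table, metadata=metadata, tree=tree,
                        participants=per_participant)
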