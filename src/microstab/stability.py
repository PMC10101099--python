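"""Local stability, permanence (global stability) and invasibility of gLV
communities.

Local stability is judged at the interior equilibrium x* (solving
A x* = -r) through the continuous-time gLV Jacobian J = diag(x*) A: the
equilibrium is locally stable when every eigenvalue of J has negative real
part, summarized by the dominant (most positive real part) eigenvalue.

Permanence — no species tends to extinction from any interior start — is
certified by Jansen's sufficient condition: a weight vector p > 0 such
that the p-weighted sum of invasion growth rates, sum_i p_i (r_i + (A x)_i),
is strictly positive at every boundary equilibrium x (every fixed point
with at least one species absent). Finding p is a linear program. The
condition is sufficient, not necessary: a feasible LP plus a
dissipativity check proves permanence; an infeasible LP proves nothing.

Invasibility follows the zero-rows/columns convention: the community is
augmented with an invader that neither affects nor is affected by the
residents, and the dominant eigenvalue of the augmented Jacobian — whose
new diagonal entry is the invader's growth rate at the resident
equilibrium — decides whether the invader can increase when rare.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .glv import GlvModel

LP_MARGIN = 1e-6          # strictness margin delta for the Jansen LP
STABILITY_TOL = 1e-9      # |lambda| below this is reported as marginal
BOUNDARY_DEDUP_TOL = 1e-10
N_MAX_BOUNDARY = 20


class StabilityError(RuntimeError):
    """Raised when a stability computation cannot be carried out."""


def interior_equilibrium(model: GlvModel) -> tuple[np.ndarray, bool]:
    """Solve A x* = -r; feasible means all entries strictly positive.

    Infeasible equilibria are returned with the flag, never clamped.
    """
    cond = np.linalg.cond(model.A)
    if not np.isfinite(cond) or cond > 1e12:
        raise StabilityError(
            f"interaction matrix is singular or ill-conditioned "
            f"(cond={cond:.3g})")
    x_star = np.linalg.solve(model.A, -model.r)
    return x_star, bool(np.all(x_star > 0))


def jacobian(model: GlvModel, x_star: np.ndarray) -> np.ndarray:
    """Continuous-time gLV Jacobian at a (possibly boundary) equilibrium.

    Interior rows are x*_i A_ij; a species at zero abundance contributes a
    decoupled row whose diagonal entry is its invasion rate r_i + (A x*)_i.
    """
    x_star = np.asarray(x_star, dtype=float)
    if np.any(x_star < 0):
        raise ValueError("equilibrium must be non-negative")
    J = x_star[:, None] * model.A
    growth = model.r + model.A @ x_star
    zero = x_star == 0
    J[zero, :] = 0.0
    J[zero, zero] = growth[zero]
    return J


def dominant_eigenvalue(J: np.ndarray) -> float:
    """Maximum real part over the spectrum of J."""
    J = np.asarray(J, dtype=float)
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian must be finite")
    return float(np.max(np.linalg.eigvals(J).real))


def boundary_equilibria(model: GlvModel,
                        n_max: int = N_MAX_BOUNDARY) -> list[tuple[tuple[int, ...], np.ndarray]]:
    """All non-negative equilibria with at least one species absent.

    For every proper subset S (including the empty set -> origin) the
    restricted system A_SS x_S = -r_S is solved; solutions with any
    negative entry are discarded, the rest embedded with zeros. Coincident
    points are deduplicated.
    """
    n = model.n
    if n > n_max:
        raise StabilityError(
            f"boundary enumeration is 2^n; n={n} exceeds n_max={n_max} "
            "(raise n_max or analyse a subcommunity)")
    found: list[tuple[tuple[int, ...], np.ndarray]] = [((), np.zeros(n))]
    for size in range(1, n):
        for S in itertools.combinations(range(n), size):
            idx = np.array(S)
            A_SS = model.A[np.ix_(idx, idx)]
            if np.linalg.cond(A_SS) > 1e12:
                continue
            x_S = np.linalg.solve(A_SS, -model.r[idx])
            if np.any(x_S < 0):
                continue
            x_hat = np.zeros(n)
            x_hat[idx] = x_S
            if any(np.max(np.abs(x_hat - prev)) < BOUNDARY_DEDUP_TOL
                   for _, prev in found):
                continue
            found.append((S, x_hat))
    return found


def dissipativity_check(model: GlvModel) -> bool:
    """Operational dissipativity proxy: strict self-limitation everywhere.

    True when every diagonal entry of A is strictly negative and each
    single-species carrying capacity r_i / (-a_ii) is finite, so no species
    can grow without bound on its own.
    """
    diag = np.diag(model.A)
    if np.any(diag >= 0):
        return False
    return bool(np.all(np.isfinite(model.r / -diag)))


def verify_certificate(model: GlvModel, p: np.ndarray,
                       boundary: list[tuple[tuple[int, ...], np.ndarray]],
                       margin: float = LP_MARGIN / 2) -> bool:
    """Independently re-check a Lyapunov weight vector against every
    boundary constraint with at least half the LP's strictness margin."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        return False
    for _, x_hat in boundary:
        if float(p @ (model.r + model.A @ x_hat)) < margin:
            return False
    return True


def permanence_lp(model: GlvModel,
                  boundary: list[tuple[tuple[int, ...], np.ndarray]] | None = None
                  ) -> tuple[bool, np.ndarray | None]:
    """Jansen's average-Lyapunov-function condition as a linear program.

    Find p with p_i >= 1 such that sum_i p_i (r_i + (A x_hat)_i) >= delta
    at every boundary equilibrium x_hat. Feasibility (together with
    dissipativity) certifies permanence; the certificate is re-verified
    before being reported. p_i >= 1 is a harmless normalization: the
    condition is scale-invariant in p.
    """
    x_star, feasible = interior_equilibrium(model)
    if not feasible:
        return False, None
    if boundary is None:
        boundary = boundary_equilibria(model)
    F = np.array([model.r + model.A @ x_hat for _, x_hat in boundary])
    res = linprog(c=np.ones(model.n), A_ub=-F,
                  b_ub=-np.full(len(boundary), LP_MARGIN),
                  bounds=[(1.0, None)] * model.n, method="highs")
    if res.status == 2:  # proven infeasible
        return False, None
    if res.status != 0:
        raise StabilityError(f"LP solver failure: {res.message}")
    p = np.asarray(res.x)
    if not verify_certificate(model, p, boundary):
        raise StabilityError("LP returned a certificate that fails "
                             "independent re-verification")
    if not dissipativity_check(model):
        return False, None
    return True, p


def invasibility_test(model: GlvModel, r_inv: float = 0.0,
                      a_inv_inv: float = 0.0,
                      tol: float = STABILITY_TOL) -> tuple[bool, float]:
    """Invasion analysis under the zero-rows/columns augmentation.

    The invader interacts with nobody (its row and column of A are zero
    except its own diagonal ``a_inv_inv``) and has growth rate ``r_inv``.
    At the resident equilibrium with the invader at zero abundance, the
    augmented Jacobian is block diagonal: the resident Jacobian plus the
    invader's invasion rate r_inv. Invasible when the augmented dominant
    eigenvalue exceeds ``tol``.
    """
    x_star, feasible = interior_equilibrium(model)
    J = jacobian(model, np.clip(x_star, 0.0, None))
    lam_res = dominant_eigenvalue(J)
    if not (feasible and lam_res < -tol):
        warnings.warn("resident community is not at a feasible, locally "
                      "stable equilibrium; invasion verdict reported anyway",
                      stacklevel=2)
    n = model.n
    J_aug = np.zeros((n + 1, n + 1))
    J_aug[:n, :n] = J
    J_aug[n, n] = r_inv  # invader at 0: its row is its invasion rate
    lam_aug = dominant_eigenvalue(J_aug)
    return bool(lam_aug > tol), lam_aug


@dataclass
class StabilityReport:
    """Full stability verdicts and certificates for one community."""

    participant_id: str
    equilibrium: np.ndarray
    feasible: bool
    jacobian: np.ndarray
    dominant_eigenvalue: float
    dominant_eigenvalue_A: float
    locally_stable: bool
    marginal: bool
    permanent: bool
    lyapunov_certificate: np.ndarray | None
    dissipative: bool
    invasible: bool
    augmented_dominant_eigenvalue: float
    invader_config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "equilibrium": [float(v) for v in self.equilibrium],
            "feasible": self.feasible,
            "dominant_eigenvalue": self.dominant_eigenvalue,
            "dominant_eigenvalue_A": self.dominant_eigenvalue_A,
            "locally_stable": self.locally_stable,
            "marginal": self.marginal,
            "permanent": self.permanent,
            "lyapunov_certificate": (
                None if self.lyapunov_certificate is None
                else [float(v) for v in self.lyapunov_certificate]),
            "dissipative": self.dissipative,
            "invasible": self.invasible,
            "augmented_dominant_eigenvalue": self.augmented_dominant_eigenvalue,
            "invader_config": self.invader_config,
        }


def assess_stability(model: GlvModel, participant_id: str = "",
                     r_inv: float = 0.0, a_inv_inv: float = 0.0,
                     tol: float = STABILITY_TOL) -> StabilityReport:
    """Run the full local / global / invasibility analysis on one model."""
    x_star, feasible = interior_equilibrium(model)
    # infeasible equilibria (negative entries) are evaluated clipped at 0;
    # the feasibility flag preserves the information
    J = jacobian(model, np.clip(x_star, 0.0, None))
    lam = dominant_eigenvalue(J)
    lam_A = dominant_eigenvalue(model.A)
    marginal = abs(lam) <= tol
    locally_stable = lam < -tol
    dissipative = dissipativity_check(model)
    if feasible:
        permanent, cert = permanence_lp(model)
    else:
        permanent, cert = False, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        invasible, lam_aug = invasibility_test(model, r_inv, a_inv_inv, tol)
    return StabilityReport(
        participant_id=participant_id,
        equilibrium=x_star,
        feasible=feasible,
        jacobian=J,
        dominant_eigenvalue=lam,
        dominant_eigenvalue_A=lam_A,
        locally_stable=locally_stable,
        marginal=marginal,
        permanent=permanent,
        lyapunov_certificate=cert,
        dissipative=dissipative,
        invasible=invasible,
        augmented_dominant_eigenvalue=lam_aug,
        invader_config={"r_inv": r_inv, "a_inv_inv": a_inv_inv},
    )
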