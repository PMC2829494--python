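"""Metabolic control analysis valid under kinetic rank deficiency.

Classical control analysis removes moiety conservations with a link matrix
built from the independent rows of the stoichiometric matrix N, and assumes
the reduced matrix N_r . eps' . L is invertible.  That assumption fails when
rank(N . eps') < rank(N) — which happens whenever reactions carry zero
reference flux, since those contribute all-zero rows to the unscaled
elasticity matrix eps'.  Here the link matrix is instead built from the
independent rows of A = diag(c)^-1 . N . eps' using a Moore-Penrose
pseudoinverse, L = A . A_r^+, which stays well defined in the rank-deficient
regime and reduces to the classical construction when the ranks agree.

With N_r the volume-normalized stoichiometry restricted to the independent
rows r, the unscaled control coefficients are

    C^S' = -L (N_r eps' L)^-1 N_r          (m x n, concentrations)
    C^J' = I + eps' C^S'                   (n x n, fluxes)

from which the summation theorems (C^J' v* = v*, C^S' v* = 0) and
connectivity theorems (C^J' eps' L = 0, C^S' eps' L = -L) follow, and which
:func:`verify_theorems` checks numerically.  Scaled flux control
coefficients follow the standard convention C^J_ij = C^J'_ij v*_j / v*_i,
masked (not zeroed) where a reference flux vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError
from .kinetics import LinlogModel, unscaled_elasticity_matrix

RECONSTRUCTION_RTOL = 1e-8


def numerical_rank(M: np.ndarray, rank_tolerance: float) -> int:
    """Rank with singular values below rank_tolerance * sigma_max zeroed."""
    if M.size == 0:
        return 0
    s = np.linalg.svd(M, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    return int(np.sum(s > rank_tolerance * s[0]))


def _independent_rows(M: np.ndarray, m0: int, rank_tolerance: float) -> np.ndarray:
    """First m0 linearly independent rows of M, in natural row order.

    Greedy modified Gram-Schmidt: a row is kept when its residual after
    projection onto the span of the rows already kept exceeds the rank
    tolerance (relative to the largest singular value).  Falls back to
    pivoted-QR selection if the greedy sweep undershoots m0 on badly scaled
    input.
    """
    s_max = np.linalg.svd(M, compute_uv=False)[0]
    thresh = rank_tolerance * s_max
    basis: list[np.ndarray] = []
    chosen: list[int] = []
    for i, row in enumerate(M):
        resid = row.astype(float).copy()
        for q in basis:
            resid -= (q @ resid) * q
        nrm = np.linalg.norm(resid)
        if nrm > thresh:
            basis.append(resid / nrm)
            chosen.append(i)
            if len(chosen) == m0:
                break
    if len(chosen) < m0:
        from scipy.linalg import qr

        _, _, piv = qr(M.T, mode="economic", pivoting=True)
        chosen = sorted(piv[:m0])
    return np.asarray(chosen, dtype=int)


@dataclass
class LinkDecomposition:
    """Pseudoinverse link-matrix decomposition of A = diag(c)^-1 N eps'."""

    A: np.ndarray               # m x m
    independent_rows: np.ndarray  # r, length m0
    A_r: np.ndarray             # m0 x m
    L: np.ndarray               # m x m0
    rank_N: int
    rank_A: int                 # m0
    rank_tolerance: float
    N_hat: np.ndarray           # volume-normalized N, m x n


def link_decomposition(
    N: np.ndarray,
    epsilon_prime: np.ndarray,
    volumes: np.ndarray | None = None,
    rank_tolerance: float = 1e-9,
) -> LinkDecomposition:
    """Build the link matrix L = A . A_r^+ from A = diag(c)^-1 N eps'.

    ``r`` holds the first (in metabolite order) m0 linearly independent rows
    of A at the given rank tolerance; the rows of L at positions r form the
    identity, and A = L . A_r to reconstruction tolerance.
    """
    N = np.asarray(N, dtype=float)
    epsilon_prime = np.asarray(epsilon_prime, dtype=float)
    m, n = N.shape
    if epsilon_prime.shape != (n, m):
        raise ValueError(
            f"epsilon_prime must be n x m = {(n, m)}, got "
            f"{epsilon_prime.shape}"
        )
    if volumes is None:
        volumes = np.ones(m)
    volumes = np.asarray(volumes, dtype=float)
    N_hat = N / volumes[:, None]
    A = N_hat @ epsilon_prime

    rank_N = numerical_rank(N_hat, rank_tolerance)
    m0 = numerical_rank(A, rank_tolerance)
    if m0 == 0:
        raise NumericalError(
            "no independent metabolites: N . eps' vanishes (all-zero "
            "dynamics)"
        )
    r = _independent_rows(A, m0, rank_tolerance)
    A_r = A[r, :]
    L = A @ np.linalg.pinv(A_r)
    scale = np.max(np.abs(A))
    err = np.max(np.abs(A - L @ A_r))
    if err > RECONSTRUCTION_RTOL * scale:
        raise NumericalError(
            f"link-matrix reconstruction error {err:.3g} exceeds "
            f"{RECONSTRUCTION_RTOL:.0e} * ||A||; try a larger rank_tolerance"
        )
    return LinkDecomposition(
        A=A,
        independent_rows=r,
        A_r=A_r,
        L=L,
        rank_N=rank_N,
        rank_A=m0,
        rank_tolerance=rank_tolerance,
        N_hat=N_hat,
    )


@dataclass
class ControlCoefficients:
    """Unscaled and scaled control coefficients plus theorem residuals.

    ``C_J_scaled`` carries NaN where a reference flux is zero; ``scaled_mask``
    is True exactly where the scaled coefficient is defined.
    """

    C_J_unscaled: np.ndarray  # n x n
    C_S_unscaled: np.ndarray  # m x n
    C_J_scaled: np.ndarray    # n x n, NaN-masked
    scaled_mask: np.ndarray   # n x n bool
    theorem_residuals: dict[str, float]


def control_coefficients(
    link: LinkDecomposition,
    epsilon_prime: np.ndarray,
    v_star: np.ndarray,
) -> ControlCoefficients:
    """Unscaled flux/concentration control coefficients via the link matrix.

    Requires the m0 x m0 matrix N_r . eps' . L to be invertible at working
    precision; a singular matrix indicates an inconsistent independent-row
    selection and suggests a larger rank tolerance.
    """
    epsilon_prime = np.asarray(epsilon_prime, dtype=float)
    v_star = np.asarray(v_star, dtype=float)
    r = link.independent_rows
    N_r = link.N_hat[r, :]
    M = N_r @ epsilon_prime @ link.L
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise NumericalError(
            f"N_r . eps' . L is numerically singular (cond={cond:.3g}); "
            "increase rank_tolerance so the independent rows are consistent"
        )
    C_S = -link.L @ np.linalg.solve(M, N_r)
    n = epsilon_prime.shape[0]
    C_J = np.eye(n) + epsilon_prime @ C_S

    nz = v_star != 0.0
    mask = np.outer(nz, nz)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.outer(1.0 / np.where(nz, v_star, np.nan), v_star)
    C_J_scaled = np.where(mask, C_J * scale, np.nan)

    cc = ControlCoefficients(
        C_J_unscaled=C_J,
        C_S_unscaled=C_S,
        C_J_scaled=C_J_scaled,
        scaled_mask=mask,
        theorem_residuals={},
    )
    cc.theorem_residuals = verify_theorems(cc, link, epsilon_prime, v_star)
    return cc


def verify_theorems(
    cc: ControlCoefficients,
    link: LinkDecomposition,
    epsilon_prime: np.ndarray,
    v_star: np.ndarray,
    tolerance: float = 1e-6,
) -> dict[str, float]:
    """Max relative residuals of the summation and connectivity theorems.

    summation-flux:   C^J' v* - v*
    summation-conc:   C^S' v*
    connectivity-flux: C^J' eps' L
    connectivity-conc: C^S' eps' L + L
    """
    v_star = np.asarray(v_star, dtype=float)
    EL = epsilon_prime @ link.L

    def rel(x: np.ndarray, scale: float) -> float:
        return float(np.max(np.abs(x)) / max(1.0, scale)) if x.size else 0.0

    v_scale = float(np.max(np.abs(v_star))) if v_star.size else 0.0
    residuals = {
        "summation-flux": rel(cc.C_J_unscaled @ v_star - v_star, v_scale),
        "summation-conc": rel(cc.C_S_unscaled @ v_star, v_scale),
        "connectivity-flux": rel(cc.C_J_unscaled @ EL,
                                 float(np.max(np.abs(EL)))),
        "connectivity-conc": rel(cc.C_S_unscaled @ EL + link.L,
                                 float(np.max(np.abs(link.L)))),
    }
    residuals["passed"] = float(
        all(v <= tolerance for k, v in residuals.items() if k != "passed")
    )
    return residuals


def perturbation_oracle(
    model: LinlogModel,
    reaction: str | int,
    delta: float = 1e-6,
    rank_tolerance: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Finite-perturbation estimate of one column of the control matrices.

    Multiplies reaction j's rate by (1 + delta), solves the linearized
    system for the displaced steady state, and returns
    (new concentrations, C^S'-column estimate, C^J'-column estimate)
    where the estimates are Delta x / (delta v*_j) and
    Delta v / (delta v*_j).  A zero reference flux (or delta = 0) perturbs
    nothing and yields zero estimates.
    """
    asm = model.assembly
    j = (asm.reaction_ids.index(reaction)
         if isinstance(reaction, str) else int(reaction))
    m = len(asm.metabolite_ids)
    n = len(asm.reaction_ids)
    v_j = asm.v_star[j]
    if delta == 0.0 or v_j == 0.0:
        return asm.x_star.copy(), np.zeros(m), np.zeros(n)

    eps_prime = unscaled_elasticity_matrix(asm)
    link = link_decomposition(
        model.N, eps_prime, asm.volumes, rank_tolerance
    )
    r = link.independent_rows
    N_r = link.N_hat[r, :]
    M = N_r @ eps_prime @ link.L
    rhs = -delta * v_j * N_r[:, j]
    try:
        x_r = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"perturbed steady-state system singular for reaction "
            f"{asm.reaction_ids[j]!r}: {exc}"
        ) from exc
    dx = link.L @ x_r
    dv = eps_prime @ dx
    dv[j] += delta * v_j
    scale = delta * v_j
    return asm.x_star + dx, dx / scale, dv / scale


def reder_equivalence_check(
    N: np.ndarray,
    epsilon_prime: np.ndarray,
    volumes: np.ndarray | None = None,
    rank_tolerance: float = 1e-9,
    v_star: np.ndarray | None = None,
) -> tuple[bool, float | None]:
    """Compare the pseudoinverse route with the classical construction.

    The classical route picks the independent rows of N itself and builds
    L' = N . N_r'^+.  When rank(N . eps') = rank(N) the two link matrices
    span the same space and the control coefficients coincide; the check
    returns (True, max elementwise deviation).  When the ranks differ the
    classical route does not apply and (False, None) is returned.
    """
    N = np.asarray(N, dtype=float)
    epsilon_prime = np.asarray(epsilon_prime, dtype=float)
    m, n = N.shape
    if v_star is None:
        v_star = np.zeros(n)
    link = link_decomposition(N, epsilon_prime, volumes, rank_tolerance)
    if link.rank_A != link.rank_N:
        return False, None
    cc = control_coefficients(link, epsilon_prime, v_star)

    N_hat = link.N_hat
    r_cl = _independent_rows(N_hat, link.rank_N, rank_tolerance)
    N_r = N_hat[r_cl, :]
    L_cl = N_hat @ np.linalg.pinv(N_r)
    M = N_r @ epsilon_prime @ L_cl
    C_S_cl = -L_cl @ np.linalg.solve(M, N_r)
    C_J_cl = np.eye(n) + epsilon_prime @ C_S_cl

    dev = max(
        float(np.max(np.abs(cc.C_S_unscaled - C_S_cl))),
        float(np.max(np.abs(cc.C_J_unscaled - C_J_cl))),
    )
    return True, dev
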