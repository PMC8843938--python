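"""Convex joint multi-energy reconstruction / element decomposition solver.

The model reconstructs the per-channel attenuation images F (M x N) and the
nonnegative convexified coefficient matrix X = rho * V (M x E) jointly:

    min_{F, X >= 0}  1/2 ||P F - B||_F^2 + beta/2 ||F - X A||_F^2
                     + alpha1 sum_i ||W f_i||_1 + alpha2 sum_j ||x_j||_1,

where P is the (kVp-tagged, per-channel) projection operator, W the tight
frame, and A = Lambda K + K_EC the dictionary-to-attenuation operator.  The
problem is solved by ADMM with an auxiliary frame-coefficient variable U
(outer splitting) and a nested inner ADMM with a nonnegative auxiliary Y for
the X-subproblem.  All updates are derived from the stationarity conditions
of the augmented Lagrangians:

    F-update: (P^T P + (beta + mu1) I) f_i = P_i^T b_i + beta (X A)_i
                                              + mu1 W^T (u_i - eta1_i)
    U-update: signed soft-thresholding of W F + eta1 at alpha1 / mu1
    X-update: X = (beta F A^T + mu2 (Y - eta2)) (beta A A^T + mu2 I)^{-1}
    Y-update: max(X + eta2 - alpha2 / mu2, 0)

(The W^T W = I tightness is used in the F normal operator.)  Setting
beta = 0 decouples the channels and yields the single-energy tight-frame
iterative reconstruction used as a comparison method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionary import KMatrices, MaterialDictionary
from .geometry import SystemMatrix, build_system_matrix, fbp_reconstruct
from .simulate import MultiChannelSinogram
from .spectral import HOI_A, HOI_Z, WATER_ELECTRONS_PER_GRAM_MOL
from .tightframe import TightFrameOperator

__all__ = [
    "HyperParams",
    "ADMMState",
    "DecompositionMaps",
    "MeerResult",
    "objective_value",
    "solve_F_subproblem",
    "update_U",
    "solve_X_subproblem",
    "meer_reconstruct",
    "single_energy_reconstruct",
    "recover_decomposition",
]


@dataclass(frozen=True)
class HyperParams:
    """Model weights and solver controls.

    ``beta`` couples the channel images to the decomposition model,
    ``alpha1`` weighs tight-frame sparsity of the images, ``alpha2`` weighs
    dictionary-coefficient sparsity; ``mu1``/``mu2`` are the ADMM penalty
    parameters (convergence rate only).  Defaults are the tuned operating
    point beta=50, alpha1=1.0, alpha2=0.001.  ``mu2 = None`` auto-scales to
    ``beta * sqrt(median(d) * max(d))`` with ``d = diag(A A^T)`` -- near the
    geometric mean of the curvature spread of beta A A^T (soft-tissue vs
    iodine rows), which the inner splitting needs for a usable rate.
    """

    beta: float = 50.0
    alpha1: float = 1.0
    alpha2: float = 0.001
    mu1: float = 20.0
    mu2: float | None = None
    tol: float = 1e-3
    inner_tol: float = 1e-7
    k_max: int = 40
    p_max: int = 300
    cg_iters: int = 600
    cg_tol: float = 1e-6
    rng_seed: int = 0

    def __post_init__(self):
        if self.mu1 <= 0 or (self.mu2 is not None and self.mu2 <= 0):
            raise ValueError("mu1 and mu2 must be positive")
        if min(self.beta, self.alpha1, self.alpha2) < 0:
            raise ValueError("beta, alpha1, alpha2 must be nonnegative")
        if self.k_max < 1 or self.p_max < 1:
            raise ValueError("iteration caps must be >= 1")


@dataclass
class ADMMState:
    """Mutable solver state and convergence traces."""

    F: np.ndarray  # (ny, nx, N)
    X: np.ndarray  # (M, E)
    U: np.ndarray  # (N, 9, ny, nx)
    Y: np.ndarray  # (M, E)
    eta1: np.ndarray  # shape of U
    eta2: np.ndarray  # shape of X
    k: int = 0
    p: int = 0
    objective_trace: list = field(default_factory=list)
    rel_change_F: list = field(default_factory=list)
    rel_change_X: list = field(default_factory=list)


@dataclass
class DecompositionMaps:
    """Derived physical maps from the coefficient matrix X.

    ``rho`` is the relative electron density, ``V`` the dictionary
    coefficients (rows summing to one where defined), ``lam`` the (H, O, I)
    mass fractions, and ``iodine_mg_per_ml`` the iodine density map.  Voxels
    with ``rho`` below the threshold have undefined composition
    (``defined`` mask False) rather than 0/0 rows.
    """

    rho: np.ndarray
    V: np.ndarray
    lam: np.ndarray
    defined: np.ndarray
    iodine_mg_per_ml: np.ndarray
    stock_mg_per_ml: float

    @property
    def iodine_stock_fraction(self) -> np.ndarray:
        return self.iodine_mg_per_ml / self.stock_mg_per_ml


@dataclass
class MeerResult:
    F: np.ndarray  # (ny, nx, N), clipped nonnegative
    X: np.ndarray  # (M, E)
    state: ADMMState
    converged: bool


# ----------------------------------------------------------------------
# pieces


def objective_value(
    F: np.ndarray,
    X: np.ndarray,
    B_blocks: list[np.ndarray],
    P_blocks: list[SystemMatrix],
    W: TightFrameOperator,
    A: np.ndarray,
    params: HyperParams,
) -> float:
    """Value of the joint convex objective (model term included iff beta>0)."""
    ny, nx, N = F.shape
    if len(B_blocks) != N or len(P_blocks) != N:
        raise ValueError("need one sinogram block and projector per channel")
    val = 0.0
    for i in range(N):
        r = P_blocks[i].apply(F[:, :, i]) - B_blocks[i]
        val += 0.5 * float(np.sum(r * r))
        val += params.alpha1 * float(np.sum(np.abs(W.analyze(F[:, :, i]))))
    if params.beta > 0:
        model = F.reshape(-1, N) - X @ A
        val += 0.5 * params.beta * float(np.sum(model * model))
        val += params.alpha2 * float(np.sum(np.abs(X)))
    return val


def _cg(apply_op, rhs, x0, tol, max_iter, precond=None):
    """Jacobi-preconditioned conjugate gradients on a flattened SPD system."""
    x = x0.copy()
    r = rhs - apply_op(x)
    rhs_norm = float(np.linalg.norm(rhs))
    if rhs_norm == 0.0:
        return np.zeros_like(rhs), 0
    z = r / precond if precond is not None else r
    p = z.copy()
    rz = float(r @ z)
    res = float(np.linalg.norm(r))
    it = 0
    while res / rhs_norm > tol and it < max_iter:
        Ap = apply_op(p)
        alpha = rz / float(p @ Ap)
        x += alpha * p
        r -= alpha * Ap
        z = r / precond if precond is not None else r
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
        res = float(np.linalg.norm(r))
        it += 1
    if res / rhs_norm > tol:
        raise RuntimeError(
            f"CG did not converge in {max_iter} iterations "
            f"(relative residual {res / rhs_norm:.3e})"
        )
    return x, it


def solve_F_subproblem(
    F: np.ndarray,
    B_blocks: list[np.ndarray],
    P_blocks: list[SystemMatrix],
    W: TightFrameOperator,
    U: np.ndarray,
    eta1: np.ndarray,
    XA: np.ndarray | None,
    params: HyperParams,
) -> tuple[np.ndarray, int]:
    """Solve the per-channel normal equations of the F-update by CG.

    The normal operator ``P_i^T P_i + (beta + mu1) I`` uses the tight-frame
    identity W^T W = I; the right-hand side carries the mu1-scaled frame
    term.  Warm-started from the incoming F; returns (F_new, CG iterations).
    Raises RuntimeError when CG fails to reach ``cg_tol`` in ``cg_iters``.
    """
    ny, nx, N = F.shape
    shift = params.beta + params.mu1
    F_new = np.empty_like(F)
    total_iters = 0
    for i in range(N):
        P = P_blocks[i].matrix
        # Jacobi preconditioner: diag(P^T P) + shift (cached on the projector)
        d0 = getattr(P_blocks[i], "_ptp_diag", None)
        if d0 is None:
            d0 = np.asarray(P.multiply(P).sum(axis=0)).ravel()
            P_blocks[i]._ptp_diag = d0
        diag = d0 + shift

        def apply_op(v):
            return P.T @ (P @ v) + shift * v

        rhs = (P.T @ B_blocks[i].ravel()) + params.mu1 * W.synthesize(
            U[i] - eta1[i]
        ).ravel()
        if XA is not None:
            rhs = rhs + params.beta * XA[:, i]
        sol, it = _cg(
            apply_op, rhs, F[:, :, i].ravel(), params.cg_tol, params.cg_iters,
            precond=diag,
        )
        F_new[:, :, i] = sol.reshape(ny, nx)
        total_iters += it
    return F_new, total_iters


def update_U(WF: np.ndarray, eta1: np.ndarray, alpha1: float, mu1: float) -> np.ndarray:
    """Signed soft-thresholding of WF + eta1 at alpha1 / mu1."""
    if alpha1 < 0 or mu1 <= 0:
        raise ValueError("need alpha1 >= 0 and mu1 > 0")
    t = alpha1 / mu1
    z = WF + eta1
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def default_mu2(A: np.ndarray, beta: float) -> float:
    """Auto-scaled inner ADMM penalty for the X-subproblem.

    The curvature of the smooth term spans diag(beta A A^T) from the
    near-degenerate soft-tissue rows to the iodine row; the geometric mean
    of its median and maximum balances the per-direction rates.
    """
    d = np.einsum("ij,ij->i", A, A)
    if beta <= 0 or d.max() <= 0:
        return 1.0
    return float(beta * np.sqrt(np.median(d) * d.max()))


def solve_X_subproblem(
    F: np.ndarray,
    A: np.ndarray,
    params: HyperParams,
    Y: np.ndarray | None = None,
    eta2: np.ndarray | None = None,
    X0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Inner ADMM for min_{X>=0} beta/2 ||F - X A||^2 + alpha2 ||X||_1.

    ``F`` may be (ny, nx, N) or (M, N).  Iterates the closed-form X-update,
    the one-sided nonnegative shrinkage of Y, and the multiplier step until
    the relative change of X drops below ``inner_tol`` or ``p_max`` is hit.
    Returns ``(X, Y, eta2, iterations)`` where the returned X is the
    nonnegative-feasible Y (final projection through the constraint
    variable).
    """
    Fm = F.reshape(-1, A.shape[1])
    M, E = Fm.shape[0], A.shape[0]
    mu2 = params.mu2 if params.mu2 is not None else default_mu2(A, params.beta)
    if Y is None:
        Y = np.zeros((M, E))
    if eta2 is None:
        eta2 = np.zeros((M, E))
    X = Y.copy() if X0 is None else X0.copy()
    G = params.beta * (A @ A.T) + mu2 * np.eye(E)
    G_inv = np.linalg.inv(G)
    bFA = params.beta * (Fm @ A.T)
    thresh = params.alpha2 / mu2
    p = 0
    while p < params.p_max:
        X_prev = X
        X = (bFA + mu2 * (Y - eta2)) @ G_inv
        Y = np.maximum(X + eta2 - thresh, 0.0)
        eta2 = eta2 - (Y - X)
        p += 1
        denom = np.linalg.norm(X)
        if denom > 0 and np.linalg.norm(X - X_prev) / denom < params.inner_tol:
            break
    return Y.copy(), Y, eta2, p


# ----------------------------------------------------------------------
# drivers


def _initial_F(
    B_blocks: list[np.ndarray],
    P_blocks: list[SystemMatrix],
    geometry,
) -> np.ndarray:
    """Per-channel FBP from each channel's own views (speed-only choice)."""
    N = len(B_blocks)
    F0 = np.empty(geometry.image_shape + (N,))
    for i in range(N):
        F0[:, :, i] = fbp_reconstruct(
            B_blocks[i], geometry, views=P_blocks[i].views, filter_name="hann"
        )
    return F0


def _channel_blocks(
    sinogram: MultiChannelSinogram,
    P_per_channel: list[SystemMatrix] | None,
):
    geometry = sinogram.geometry
    N = sinogram.n_channels
    B_blocks = [sinogram.channel_block(i) for i in range(N)]
    if P_per_channel is None:
        P_per_channel = [
            build_system_matrix(geometry, sinogram.views_of_channel(i))
            for i in range(N)
        ]
    return B_blocks, P_per_channel


def meer_reconstruct(
    sinogram: MultiChannelSinogram,
    dictionary: MaterialDictionary,
    k_matrices: KMatrices,
    params: HyperParams = HyperParams(),
    P_per_channel: list[SystemMatrix] | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> MeerResult:
    """Joint reconstruction of the channel images F and coefficients X.

    Outer ADMM loop: F-subproblem (CG), U soft-thresholding, nested
    X-subproblem, multiplier update.  Stops at ``k_max`` outer iterations or
    when the relative successive change of F falls below ``tol``.  Raises
    RuntimeError if the objective increases over five consecutive outer
    iterations.  Deterministic for fixed inputs.
    """
    geometry = sinogram.geometry
    B_blocks, P_blocks = _channel_blocks(sinogram, P_per_channel)
    N = sinogram.n_channels
    A = k_matrices.A
    if A.shape[1] != N:
        raise ValueError("K matrices channel count does not match the scan")
    W = TightFrameOperator()

    if init is None:
        F = _initial_F(B_blocks, P_blocks, geometry)
        X = np.zeros((geometry.n_pixels, dictionary.n_materials))
        X[:, dictionary.water_index] = 1.0
    else:
        F, X = init[0].copy(), init[1].copy()
    U = np.stack([W.analyze(F[:, :, i]) for i in range(N)])
    eta1 = np.zeros_like(U)
    Y = X.copy()
    eta2 = np.zeros_like(X)

    state = ADMMState(F=F, X=X, U=U, Y=Y, eta1=eta1, eta2=eta2)
    converged = False
    n_increases = 0
    prev_obj = np.inf
    for k in range(params.k_max):
        XA = state.X @ A
        F_new, _ = solve_F_subproblem(
            state.F, B_blocks, P_blocks, W, state.U, state.eta1, XA, params
        )
        WF = np.stack([W.analyze(F_new[:, :, i]) for i in range(N)])
        state.U = update_U(WF, state.eta1, params.alpha1, params.mu1)
        X_new, state.Y, state.eta2, state.p = solve_X_subproblem(
            F_new, A, params, Y=state.Y, eta2=state.eta2, X0=state.X
        )
        state.eta1 = state.eta1 - (state.U - WF)

        relF = np.linalg.norm(F_new - state.F) / max(np.linalg.norm(F_new), 1e-30)
        relX = np.linalg.norm(X_new - state.X) / max(np.linalg.norm(X_new), 1e-30)
        state.F, state.X = F_new, X_new
        state.k = k + 1
        obj = objective_value(state.F, state.X, B_blocks, P_blocks, W, A, params)
        state.objective_trace.append(obj)
        state.rel_change_F.append(relF)
        state.rel_change_X.append(relX)
        if obj > prev_obj * (1.0 + 1e-6):
            n_increases += 1
            if n_increases >= 5:
                raise RuntimeError(
                    "objective increased over five consecutive outer "
                    f"iterations (last value {obj:.6e}); diverging ADMM"
                )
        else:
            n_increases = 0
        prev_obj = obj
        if relF < params.tol and k >= 1:
            converged = True
            break
    return MeerResult(
        F=np.maximum(state.F, 0.0), X=state.X, state=state, converged=converged
    )


def single_energy_reconstruct(
    b_channel: np.ndarray,
    P_channel: SystemMatrix,
    params: HyperParams = HyperParams(),
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, ADMMState]:
    """Tight-frame iterative reconstruction of one channel (beta = 0).

    Solves min_f 1/2 ||P f - b||^2 + alpha1 ||W f||_1 with the same outer
    ADMM (F-subproblem + U soft-thresholding), ignoring the inter-channel
    model.  Returns the nonnegative-clipped image and the solver state.
    """
    geometry = P_channel.geometry
    se = HyperParams(
        beta=0.0,
        alpha1=params.alpha1,
        alpha2=params.alpha2,
        mu1=params.mu1,
        mu2=params.mu2,
        tol=params.tol,
        inner_tol=params.inner_tol,
        k_max=params.k_max,
        p_max=params.p_max,
        cg_iters=params.cg_iters,
        cg_tol=params.cg_tol,
    )
    W = TightFrameOperator()
    if init is None:
        f = fbp_reconstruct(
            b_channel, geometry, views=P_channel.views, filter_name="hann"
        )
    else:
        f = init.copy()
    F = f[:, :, None]
    U = W.analyze(f)[None]
    eta1 = np.zeros_like(U)
    dummy_X = np.zeros((geometry.n_pixels, 1))
    state = ADMMState(F=F, X=dummy_X, U=U, Y=dummy_X, eta1=eta1, eta2=dummy_X)
    n_increases = 0
    prev_obj = np.inf
    for k in range(se.k_max):
        F_new, _ = solve_F_subproblem(
            state.F, [b_channel], [P_channel], W, state.U, state.eta1, None, se
        )
        WF = W.analyze(F_new[:, :, 0])[None]
        state.U = update_U(WF, state.eta1, se.alpha1, se.mu1)
        state.eta1 = state.eta1 - (state.U - WF)
        relF = np.linalg.norm(F_new - state.F) / max(np.linalg.norm(F_new), 1e-30)
        state.F = F_new
        state.k = k + 1
        r = P_channel.apply(F_new[:, :, 0]) - b_channel
        obj = 0.5 * float(np.sum(r * r)) + se.alpha1 * float(np.sum(np.abs(WF)))
        state.objective_trace.append(obj)
        state.rel_change_F.append(relF)
        if obj > prev_obj * (1.0 + 1e-6):
            n_increases += 1
            if n_increases >= 5:
                raise RuntimeError("diverging single-energy iteration")
        else:
            n_increases = 0
        prev_obj = obj
        if relF < se.tol and k >= 1:
            break
    return np.maximum(state.F[:, :, 0], 0.0), state


def recover_decomposition(
    X: np.ndarray,
    dictionary: MaterialDictionary,
    stock_mg_per_ml: float = 175.0,
    rho_threshold: float = 1e-6,
) -> DecompositionMaps:
    """Physical maps from X: rho = diag(X 1), V = rho^-1 X, lam = V Lambda.

    The iodine density converts the iodine mass fraction and the mass
    density implied by the relative electron density and composition:
    ``rho_m = rho * (mol e / g)_water / (mol e / g)_mixture``.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < -1e-9):
        raise ValueError("X must be nonnegative")
    rho = X.sum(axis=1)
    defined = rho > rho_threshold
    V = np.zeros_like(X)
    V[defined] = X[defined] / rho[defined, None]
    lam = V @ dictionary.Lambda
    mol_e_per_g = lam @ (HOI_Z / HOI_A)
    mass_density = np.zeros_like(rho)
    mass_density[defined] = (
        rho[defined] * WATER_ELECTRONS_PER_GRAM_MOL / mol_e_per_g[defined]
    )
    iodine = 1000.0 * lam[:, 2] * mass_density
    return DecompositionMaps(
        rho=rho,
        V=V,
        lam=lam,
        defined=defined,
        iodine_mg_per_ml=iodine,
        stock_mg_per_ml=stock_mg_per_ml,
    )
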