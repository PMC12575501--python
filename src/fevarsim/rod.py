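"""Discrete elastic rod surrogate for the renal artery under breathing.

The artery centerline is discretized into nodes at (nominally) 1 mm
spacing.  The rod carries a stretching energy per segment and a bending
energy per interior node,

    E = sum_i ks/(2 h_i) (|e_i| - h_i)^2
      + sum_j kb_j/h_j (1 - cos(theta_j - theta_j_rest)),

where e_i are the segment vectors, h_i the rest lengths, and theta_j the
turning angle between consecutive segments.  The rest configuration is
stress-free.  The ostium end is clamped in position and tangent (the two
proximal nodes are fixed, consistent with a rigid aorta at the ostium);
the distal node is displaced by the breathing vector with its orientation
left free.  A stented interval carries an elevated bending rigidity.

The stretch stiffness defaults to 1e2 x (baseline bending rigidity)/h,
which keeps axial strains around 1e-4 under physiological transverse
loads — inextensible for all practical purposes — while leaving the
stiffness matrix well enough conditioned to drive the gradient below the
1e-8 N convergence tolerance in double precision (the achievable gradient
floor is roughly the stiffest Hessian entry times the position ulp).

Static equilibrium is found by incremental loading with trust-region
Newton steps on an analytic gradient and Hessian, followed by a damped
Newton polish on the gradient; the solver is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from .centerline import Centerline
from .errors import InvalidInputError, NonConvergenceError

DEFAULT_SPACING_MM = 1.0
DEFAULT_ARTERY_RIGIDITY = 100.0  # N*mm^2, soft arterial wall (config knob)
GRAD_TOL_N = 1e-8


@dataclass
class RodModel:
    """Discretized rod: rest geometry, stiffnesses, boundary conditions."""

    rest_points: np.ndarray  # (N, 3) mm
    rest_lengths: np.ndarray  # (N-1,) mm
    stretch_stiffness: float  # N
    bend_rigidity: np.ndarray  # (N-2,) N*mm^2, per interior node
    stented_interval: tuple | None = None  # (s_lo, s_hi) on the rod, mm

    def __post_init__(self) -> None:
        self.rest_points = np.asarray(self.rest_points, dtype=float)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float)
        n = len(self.rest_points)
        if n < 5:
            raise InvalidInputError("rod needs at least 5 nodes")
        if self.stretch_stiffness <= 0 or np.any(self.bend_rigidity <= 0):
            raise InvalidInputError("all stiffnesses must be positive")
        if len(self.bend_rigidity) != n - 2:
            raise InvalidInputError("need one bending rigidity per interior node")
        # rest turning angles (cos, sin), unsigned
        u = np.diff(self.rest_points, axis=0)
        self._rest_cos, self._rest_sin = _turning_cos_sin(u[:-1], u[1:])
        # bending prefactor per interior node: kb / mean adjacent rest length
        hbar = 0.5 * (self.rest_lengths[:-1] + self.rest_lengths[1:])
        self._bend_k = self.bend_rigidity / hbar

    @property
    def n_nodes(self) -> int:
        return len(self.rest_points)

    @property
    def arc_lengths(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.rest_lengths)])


@dataclass
class EquilibriumSolution:
    """Deformed rod state at static equilibrium."""

    positions: np.ndarray  # (N, 3) mm
    energy: float  # N*mm
    iterations: int
    converged: bool
    grad_norm: float  # inf-norm of the free-node gradient, N


def _turning_cos_sin(u: np.ndarray, v: np.ndarray):
    lu = np.linalg.norm(u, axis=1)
    lv = np.linalg.norm(v, axis=1)
    c = np.einsum("ij,ij->i", u, v) / (lu * lv)
    s = np.linalg.norm(np.cross(u, v), axis=1) / (lu * lv)
    return np.clip(c, -1.0, 1.0), s


def build_rod(
    centerline: Centerline,
    artery_rigidity: float = DEFAULT_ARTERY_RIGIDITY,
    stretch_stiffness: float | None = None,
    deployed_sg=None,
    rigidity_ratio: float = 1.0,
    spacing_mm: float = DEFAULT_SPACING_MM,
) -> RodModel:
    """Discretize a branch centerline into a rod model.

    Nodes are uniformly spaced at ``spacing_mm`` (1 mm by default, matching
    the metric sampling; the final interval may be shorter).  Interior
    nodes whose arc length falls inside the deployed stent's in-artery
    interval carry ``artery_rigidity * rigidity_ratio``; all others carry
    the baseline ``artery_rigidity``.
    """
    if centerline.length < 10.0:
        raise InvalidInputError("centerline must be at least 10 mm long")
    if rigidity_ratio < 1.0:
        raise InvalidInputError("rigidity ratio must be >= 1")
    res = centerline.resample(spacing_mm)
    pts = res.points
    h = res.segment_lengths()
    cum = res.arc_lengths()

    kb = np.full(len(pts) - 2, float(artery_rigidity))
    interval = None
    if deployed_sg is not None:
        s_lo, s_hi = max(0.0, deployed_sg.s_start), deployed_sg.s_end
        interior_s = cum[1:-1]
        kb[(interior_s >= s_lo - 1e-9) & (interior_s <= s_hi + 1e-9)] *= rigidity_ratio
        interval = (s_lo, s_hi)

    if stretch_stiffness is None:
        stretch_stiffness = 1e2 * artery_rigidity / spacing_mm
    return RodModel(pts, h, float(stretch_stiffness), kb, interval)


# regularization width for the |sin(theta)| kink at theta = 0: the unsigned
# turning angle is not differentiable where a node straightens completely,
# which is exactly where breathing loads drive it; writing sin(theta) as
# sqrt(1 - cos^2 + eps^2) - eps makes the energy C-infinity while changing
# it by less than eps per node (see the methods note)
_SIN_EPS = 1e-4


def _bend_terms(rod: RodModel, c: np.ndarray):
    """phi(c), phi'(c), phi''(c) of the per-node bending energy.

    With q = sin^2(theta) = 1 - c^2, the bending energy
    k (1 - c*cos(rest) - sin_eps(theta)*sin(rest)) is a smooth scalar
    function of c = cos(theta) alone.
    """
    cbar, sbar = rod._rest_cos, rod._rest_sin
    k = rod._bend_k
    r = np.sqrt(1.0 - c**2 + _SIN_EPS**2)
    s = r - _SIN_EPS
    phi = k * (1.0 - c * cbar - s * sbar)
    dphi = k * (-cbar + sbar * c / r)
    d2phi = k * sbar * (r**2 + c**2) / r**3
    return phi, dphi, d2phi


def _energy_grad(rod: RodModel, P: np.ndarray):
    """Total elastic energy and its gradient w.r.t. all node positions."""
    e = np.diff(P, axis=0)
    l = np.linalg.norm(e, axis=1)
    h = rod.rest_lengths
    ks = rod.stretch_stiffness

    stretch = float(np.sum(ks / (2.0 * h) * (l - h) ** 2))
    f = (ks / h * (l - h) / l)[:, None] * e  # dE/de per segment
    grad = np.zeros_like(P)
    grad[:-1] -= f
    grad[1:] += f

    u, v = e[:-1], e[1:]
    lu, lv = l[:-1], l[1:]
    a = 1.0 / (lu * lv)
    c = np.einsum("ij,ij->i", u, v) * a

    phi, dphi, _ = _bend_terms(rod, c)
    bend = float(np.sum(phi))

    # dc/du and dc/dv per interior node
    alpha, beta = 1.0 / lu**2, 1.0 / lv**2
    pu = a[:, None] * v - (c * alpha)[:, None] * u
    pv = a[:, None] * u - (c * beta)[:, None] * v
    gu = dphi[:, None] * pu
    gv = dphi[:, None] * pv

    # interior node j: u = e[j-1], v = e[j]; contributions to j-1, j, j+1
    grad[:-2] -= gu
    grad[1:-1] += gu - gv
    grad[2:] += gv

    return stretch + bend, grad


def _hessian(rod: RodModel, P: np.ndarray) -> np.ndarray:
    """Exact Hessian of the energy w.r.t. all node coordinates (3N x 3N)."""
    N = len(P)
    e = np.diff(P, axis=0)
    l = np.linalg.norm(e, axis=1)
    h = rod.rest_lengths
    ks = rod.stretch_stiffness
    H = np.zeros((N, 3, N, 3))
    eye = np.eye(3)

    # stretch: per-segment block ks/h [ee^T + (1 - h/l)(I - ee^T)]
    ehat = e / l[:, None]
    outer = np.einsum("ij,ik->ijk", ehat, ehat)
    He = (ks / h)[:, None, None] * (
        outer + (1.0 - h / l)[:, None, None] * (eye[None] - outer)
    )
    idx = np.arange(N - 1)
    H[idx, :, idx, :] += He
    H[idx + 1, :, idx + 1, :] += He
    H[idx, :, idx + 1, :] -= He
    H[idx + 1, :, idx, :] -= He

    # bending: per interior node, chain rule through c(u, v)
    u, v = e[:-1], e[1:]
    lu, lv = l[:-1], l[1:]
    a = 1.0 / (lu * lv)
    alpha, beta = 1.0 / lu**2, 1.0 / lv**2
    c = np.einsum("ij,ij->i", u, v) * a
    _, dphi, d2phi = _bend_terms(rod, c)

    pu = a[:, None] * v - (c * alpha)[:, None] * u
    pv = a[:, None] * u - (c * beta)[:, None] * v

    def op(x, y):
        return np.einsum("ij,ik->ijk", x, y)

    cuu = (
        -(a * alpha)[:, None, None] * (op(v, u) + op(u, v))
        + (3.0 * c * alpha**2)[:, None, None] * op(u, u)
        - (c * alpha)[:, None, None] * eye[None]
    )
    cvv = (
        -(a * beta)[:, None, None] * (op(u, v) + op(v, u))
        + (3.0 * c * beta**2)[:, None, None] * op(v, v)
        - (c * beta)[:, None, None] * eye[None]
    )
    cuv = (
        a[:, None, None] * eye[None]
        - (a * beta)[:, None, None] * op(v, v)
        - (a * alpha)[:, None, None] * op(u, u)
        + (c * alpha * beta)[:, None, None] * op(u, v)
    )

    A = d2phi[:, None, None] * op(pu, pu) + dphi[:, None, None] * cuu
    D = d2phi[:, None, None] * op(pv, pv) + dphi[:, None, None] * cvv
    B = d2phi[:, None, None] * op(pu, pv) + dphi[:, None, None] * cuv

    # map (du, dv) blocks onto nodes (j-1, j, j+1):
    # du = dP_j - dP_{j-1},  dv = dP_{j+1} - dP_j
    j = np.arange(1, N - 1)
    Bt = np.swapaxes(B, 1, 2)
    H[j - 1, :, j - 1, :] += A
    H[j - 1, :, j, :] += -A + B
    H[j, :, j - 1, :] += -A + Bt
    H[j, :, j, :] += A - B - Bt + D
    H[j - 1, :, j + 1, :] += -B
    H[j + 1, :, j - 1, :] += -Bt
    H[j, :, j + 1, :] += B - D
    H[j + 1, :, j, :] += Bt - D
    H[j + 1, :, j + 1, :] += D

    return H.reshape(3 * N, 3 * N)


def solve_equilibrium(
    rod: RodModel,
    breathing_vector: np.ndarray,
    grad_tol: float = GRAD_TOL_N,
    max_iter: int = 5000,
    strict: bool = True,
) -> EquilibriumSolution:
    """Static equilibrium under a prescribed distal displacement.

    The two proximal nodes are clamped at their rest positions (ostium
    position + tangent); the distal node is moved by ``breathing_vector``
    with free orientation.  Converged means the free-node gradient
    inf-norm is below ``grad_tol`` (N).  Raises
    :class:`NonConvergenceError` (carrying the last iterate) when strict
    and not converged.
    """
    bv = np.asarray(breathing_vector, dtype=float)
    N = rod.n_nodes
    free = np.arange(2, N - 1)

    if np.allclose(bv, 0.0):
        # identity load: the rest shape is the exact equilibrium
        return EquilibriumSolution(rod.rest_points.copy(), 0.0, 0, True, 0.0)

    # work in branch-local coordinates: the energy is translation
    # invariant, and smaller coordinate magnitudes lower the rounding
    # floor of the gradient (ulp of the positions times the stiffest
    # Hessian entry), which the 1e-8 N tolerance sits close to
    origin = rod.rest_points.mean(axis=0)
    rest = rod.rest_points - origin

    s = rod.arc_lengths
    ramp = np.clip((s - s[1]) / (s[-1] - s[1]), 0.0, 1.0)

    free_coords = (free[:, None] * 3 + np.arange(3)).ravel()

    def make_fun(tail):
        def fun(x):
            Q = rest.copy()
            Q[-1] = tail
            Q[free] = x.reshape(-1, 3)
            E, G = _energy_grad(rod, Q)
            return E, G[free].ravel()

        def hess(x):
            Q = rest.copy()
            Q[-1] = tail
            Q[free] = x.reshape(-1, 3)
            return _hessian(rod, Q)[np.ix_(free_coords, free_coords)]

        return fun, hess

    # incremental loading (continuation): apply the displacement in steps
    # of at most ~2.5 mm, warm-starting each step from the previous
    # equilibrium, so Newton stays inside its convergence basin
    n_steps = max(1, int(np.ceil(np.linalg.norm(bv) / 2.5)))
    x = (rest[free] + ramp[free, None] * (bv / n_steps)[None, :]).ravel()
    iterations = 0
    fun = hess = None
    for k in range(1, n_steps + 1):
        frac = k / n_steps
        fun, hess = make_fun(rest[-1] + frac * bv)
        if k > 1:
            # shift the warm start by the next load increment
            x = x + (ramp[free, None] * (bv / n_steps)[None, :]).ravel()
        res = scipy.optimize.minimize(
            fun,
            x,
            jac=True,
            hess=hess,
            method="trust-exact",
            options={"maxiter": min(300, max_iter), "gtol": 1e-6},
        )
        x = res.x
        iterations += int(res.nit)

    # Newton polish on the gradient: near the minimum, energy differences
    # fall below the double-precision resolution of E long before the
    # gradient reaches 1e-8 N, so progress must be judged on the gradient
    # norm alone
    x, E, g, it = _newton_polish(fun, hess, x, grad_tol)
    iterations += it

    if float(np.abs(g).max()) >= grad_tol:
        # last resort: Powell hybrid root-find on the gradient field
        sol_root = scipy.optimize.root(
            lambda xk: fun(xk)[1], x, jac=lambda xk: hess(xk), method="hybr"
        )
        E_r, g_r = fun(sol_root.x)
        if float(np.abs(g_r).max()) < float(np.abs(g).max()):
            x, E, g = sol_root.x, E_r, g_r
        iterations += int(sol_root.nfev)

    gnorm = float(np.abs(g).max())
    converged = gnorm < grad_tol
    P_final = rest.copy()
    P_final[-1] = rest[-1] + bv
    P_final[free] = x.reshape(-1, 3)
    P_final += origin
    if strict and not converged:
        raise NonConvergenceError(
            f"equilibrium gradient stalled at {gnorm:.3e} N (tol {grad_tol:.0e})",
            last_positions=P_final,
            grad_norm=gnorm,
        )
    return EquilibriumSolution(P_final, float(E), iterations, converged, gnorm)


def _newton_polish(fun, hess, x, grad_tol: float, max_outer: int = 100):
    """Drive the gradient to ``grad_tol`` by damped Newton on grad = 0.

    Acceptance is on gradient-norm decrease (with step backtracking and
    Levenberg damping), never on energy, which is numerically unresolvable
    at this scale.
    """
    E, g = fun(x)
    lam = 0.0
    iterations = 0
    for _ in range(max_outer):
        gnorm = float(np.abs(g).max())
        if gnorm < grad_tol:
            break
        H = hess(x)
        improved = False
        for _ in range(20):
            try:
                A = H + lam * np.eye(len(x)) if lam > 0 else H
                step = scipy.linalg.solve(A, -g, assume_a="sym")
            except scipy.linalg.LinAlgError:
                lam = max(10.0 * lam, 1e-6)
                continue
            for alpha in (1.0, 0.5, 0.25, 0.1):
                E_new, g_new = fun(x + alpha * step)
                if np.isfinite(E_new) and float(np.abs(g_new).max()) < gnorm:
                    x = x + alpha * step
                    E, g = E_new, g_new
                    lam = lam / 10.0 if lam > 1e-10 else 0.0
                    improved = True
                    break
            if improved:
                break
            lam = max(10.0 * lam, 1e-6)
        iterations += 1
        if not improved:
            break
    return x, E, g, iterations


def _fd_hessian(fun, x, g0, eps: float = 1e-6, bandwidth: int = 8):
    """Forward-difference Hessian from the analytic gradient.

    Exploits the rod's banded coupling (a node interacts only with nodes
    up to two hops away, i.e. coordinate offsets within ``bandwidth``):
    coordinates separated by more than 2*bandwidth are perturbed in the
    same evaluation, cutting the cost from n to ~2*bandwidth+1 calls.
    """
    n = len(x)
    H = np.zeros((n, n))
    stride = 2 * bandwidth + 1
    offsets = np.arange(-bandwidth, bandwidth + 1)
    for color in range(min(stride, n)):
        cols = np.arange(color, n, stride)
        xp = x.copy()
        xp[cols] += eps
        _, gp = fun(xp)
        diff = (gp - g0) / eps
        for i in cols:
            rows = i + offsets
            rows = rows[(rows >= 0) & (rows < n)]
            H[rows, i] = diff[rows]
    return 0.5 * (H + H.T)


def simulate_breathing(
    patient,
    deployed: dict | None,
    bc,
    artery_rigidity: float = DEFAULT_ARTERY_RIGIDITY,
    rigidity_ratio_fn=None,
) -> tuple[dict, dict]:
    """Two-state breathing simulation for both renal branches.

    Inspiration is the rest geometry; expiration is the rod equilibrium
    under the per-branch breathing displacement.  ``deployed`` maps branch
    name ('left'/'right') to a :class:`~fevarsim.stents.DeployedSG` (or is
    None for the pre-EVAR configuration); identical boundary conditions
    are applied with and without a device, so pre/post comparisons isolate
    the stent effect.  ``rigidity_ratio_fn(deployed_sg)`` may override how
    the stented rigidity ratio is obtained; the default derives it from
    the catalog materials via
    :func:`~fevarsim.stents.effective_bending_rigidity`.

    Returns ``(inspiration, expiration)``: each a dict mapping branch name
    to a :class:`~fevarsim.centerline.Centerline` on the rod's nodes.
    """
    from .stents import MaterialProperties, StrutCrossSection, effective_bending_rigidity

    if rigidity_ratio_fn is None:
        mat, xs = MaterialProperties(), StrutCrossSection()

        def rigidity_ratio_fn(sg):
            total = effective_bending_rigidity(mat, xs, sg.spec, 6, artery_rigidity)
            # beyond ~200x the stented segment is rigid for all practical
            # purposes; capping keeps the stiffness matrix conditioned
            return min(total / artery_rigidity, 200.0)

    inspiration, expiration = {}, {}
    for side, branch in patient.branches.items():
        sg = (deployed or {}).get(side)
        ratio = rigidity_ratio_fn(sg) if sg is not None else 1.0
        rod = build_rod(
            branch,
            artery_rigidity=artery_rigidity,
            deployed_sg=sg,
            rigidity_ratio=ratio,
        )
        sol = solve_equilibrium(rod, bc.displacements[side])
        meta = dict(branch.metadata)
        inspiration[side] = Centerline(rod.rest_points.copy(), metadata={**meta, "state": "inspiration"})
        expiration[side] = Centerline(sol.positions, metadata={**meta, "state": "expiration"})
    return inspiration, expiration
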