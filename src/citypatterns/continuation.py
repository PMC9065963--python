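"""Numerical continuation of patterned steady states in mean population.

Steady states of the (mass-conserving) model form branches parameterised by
the mean population density ``pbar``. Each branch point solves the
discretized steady-state equations on a 1-D periodic grid, with

* the conserved-mass null direction replaced by the constraint
  ``mean(p) = pbar``, and
* the translation symmetry removed by restricting to the even (cosine)
  subspace of the periodic domain — solutions are mirror-symmetric about
  ``x = 0``, which pins the pattern phase more robustly than an integral
  phase condition.

The predictor is a secant (pseudo-arclength) step, so folds — where a
patterned branch turns back on itself and typically sheds stability — are
traversed rather than terminating the branch. Stability is read from the
eigenvalues of the full-space linearization (even and odd perturbations),
ignoring the two structural neutral modes (mass and translation,
``|Re| < 1e-8``); metastable multi-bump states show up as points whose
leading non-structural eigenvalue is positive but tiny.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import ModelParams, RhsEvaluator
from .errors import BranchEndError, ParameterError
from .grids import ScalarField, SpatialGrid

__all__ = ["BranchPoint", "ContinuationBranch", "continue_branch", "max_stable_pbar"]

# |Re| below this -> structural neutral mode (mass & translation). The
# finite-difference linearization resolves eigenvalues to ~1e-7 / yr, so the
# threshold sits above that noise floor and far below any dynamically
# meaningful rate (metastable coarsening rates are >= 1e-3 / yr here).
_NEUTRAL_TOL = 1e-6
_RESID_TOL = 1e-10  # scaled (1/yr) steady-state residual per Newton solve


# ---- even-subspace plumbing -------------------------------------------

def _half_size(n: int) -> int:
    return n // 2 + 1


def _expand_even(half: np.ndarray, n: int) -> np.ndarray:
    """Mirror half-grid values (indices 0..n/2) onto the full periodic grid."""
    full = np.empty(n)
    m = _half_size(n)
    full[:m] = half
    full[m:] = half[1 : n - m + 1][::-1]
    return full


def _restrict_even(full: np.ndarray) -> np.ndarray:
    return full[: _half_size(len(full))].copy()


def _half_weights(n: int) -> np.ndarray:
    """Multiplicity of each half-grid index on the full grid (sums to n)."""
    m = _half_size(n)
    w = np.full(m, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    return w


def _symmetrize(values: np.ndarray) -> np.ndarray:
    return 0.5 * (values + np.roll(values[::-1], 1))


@dataclass
class BranchPoint:
    pbar: float
    p: np.ndarray
    s: np.ndarray
    stable: bool | None
    leading_eigenvalue: float | None

    @property
    def max_p(self) -> float:
        return float(np.max(self.p))

    @property
    def amplitude(self) -> float:
        return float(np.max(self.p) - np.min(self.p))


@dataclass
class ContinuationBranch:
    """A family of steady states with stability flags and fold markers."""

    points: list  # of BranchPoint
    folds: list = field(default_factory=list)  # pbar at folds
    grid: SpatialGrid | None = None
    params: ModelParams | None = None

    @property
    def pbar(self) -> np.ndarray:
        return np.array([pt.pbar for pt in self.points])

    def bump_count(self) -> int:
        """Number of population clusters at the first branch point.

        A cluster is a contiguous above-mean segment of the periodic
        profile, so a city with a central density crater (two nearby maxima)
        counts once.
        """
        v = self.points[0].p
        if not len(v):
            return 0
        above = v > v.mean()
        return int(np.sum(above & ~np.roll(above, 1)))

    def stable_points(self) -> list:
        return [pt for pt in self.points if pt.stable]


class _SteadyProblem:
    """Steady-state residual and FD Jacobians in the even subspace."""

    def __init__(self, grid: SpatialGrid, params: ModelParams):
        if grid.dimension != 1:
            raise ParameterError("continuation is implemented on 1-D grids")
        self.grid = grid
        self.params = params
        self.ev = RhsEvaluator(grid, params)
        self.n = grid.points[0]
        self.m = _half_size(self.n)
        self.w = _half_weights(self.n)
        self.scale_p = 1.0  # set per solve from pbar

    # -- residual in scaled units (1/yr) --------------------------------
    def residual(self, u: np.ndarray, pbar: float) -> np.ndarray:
        m = self.m
        p = _expand_even(u[:m] * self.scale_p, self.n)
        s = _expand_even(u[m:], self.n)
        # evaluated raw: clipping would zero Jacobian columns when a Newton
        # trial step overshoots the admissible set
        dp, ds = self.ev.both(p, s)
        rp = _restrict_even(dp) / self.scale_p
        rp[0] = (np.dot(self.w, u[:m]) * self.scale_p / self.n - pbar) / self.scale_p
        return np.concatenate([rp, _restrict_even(ds)])

    def pack(self, p: np.ndarray, s: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [_restrict_even(p) / self.scale_p, _restrict_even(s)]
        )

    def unpack(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = self.m
        return (
            _expand_even(u[:m] * self.scale_p, self.n),
            _expand_even(u[m:], self.n),
        )

    def _fd_jacobian(self, fun, u0: np.ndarray, f0: np.ndarray) -> np.ndarray:
        nu = len(u0)
        J = np.empty((len(f0), nu))
        for i in range(nu):
            h = 1e-7 * max(abs(u0[i]), 1e-3)
            up = u0.copy()
            up[i] += h
            J[:, i] = (fun(up) - f0) / h
        return J

    def newton(self, u0: np.ndarray, pbar: float, max_iter: int = 12) -> np.ndarray:
        u = u0.copy()
        for _ in range(max_iter):
            f = self.residual(u, pbar)
            if np.max(np.abs(f)) < _RESID_TOL:
                return u
            J = self._fd_jacobian(lambda v: self.residual(v, pbar), u, f)
            try:
                du = np.linalg.solve(J, -f)
            except np.linalg.LinAlgError as exc:
                raise BranchEndError(f"singular Newton system: {exc}") from exc
            # damped update guards against leaving the admissible set
            lam = 1.0
            f_norm = np.max(np.abs(f))
            for _ in range(6):
                u_try = u + lam * du
                if np.max(np.abs(self.residual(u_try, pbar))) < f_norm:
                    u = u_try
                    break
                lam /= 2.0
            else:
                raise BranchEndError("Newton line search failed")
        f = self.residual(u, pbar)
        if np.max(np.abs(f)) < _RESID_TOL:
            return u
        raise BranchEndError("Newton did not converge")

    # -- stability -------------------------------------------------------
    def full_jacobian(self, p: np.ndarray, s: np.ndarray) -> np.ndarray:
        """FD linearization of the full (p, s) system, unit-balanced.

        Rows/columns use p measured in units of ``scale_p`` so that both
        blocks are O(1) and the eigenproblem is well conditioned; the
        eigenvalues (1/yr) are unchanged by this diagonal similarity.
        """
        n = self.n
        f0 = np.concatenate(self.ev.both(p, s))
        J = np.empty((2 * n, 2 * n))
        hp = 1e-6 * self.scale_p
        for i in range(n):
            pp = p.copy()
            pp[i] += hp
            dp, ds = self.ev.both(pp, s)
            J[:, i] = np.concatenate([dp, ds * self.scale_p]) - np.concatenate(
                [f0[:n], f0[n:] * self.scale_p]
            )
            J[:, i] /= hp
        hs = 1e-8
        for i in range(n):
            ss = s.copy()
            ss[i] += hs
            dp, ds = self.ev.both(p, ss)
            J[:, n + i] = (
                np.concatenate([dp, ds * self.scale_p])
                - np.concatenate([f0[:n], f0[n:] * self.scale_p])
            ) / (hs * self.scale_p)
        # undo the p-column scaling consistently: columns for p were
        # perturbed by hp = scale_p * h, rows for s were multiplied by
        # scale_p; net effect is a similarity transform, eigenvalues intact
        return J

    def leading_nonstructural_eigenvalue(self, p: np.ndarray, s: np.ndarray) -> float:
        J = self.full_jacobian(p, s)
        vals = np.linalg.eigvals(J).real
        vals.sort()
        vals = vals[::-1]
        dropped = 0
        for v in vals:
            if dropped < 2 and abs(v) < _NEUTRAL_TOL:
                dropped += 1
                continue
            return float(v)
        return float(vals[-1])


def continue_branch(
    p: ScalarField,
    s: ScalarField,
    params: ModelParams,
    pbar_max: float,
    pbar_min: float = 0.0,
    step: float = 250.0,
    min_step: float = 2.0,
    max_points: int = 200,
    compute_stability: bool = True,
) -> ContinuationBranch:
    """Trace the steady-state branch through ``(pbar, p, s)`` space.

    ``p, s`` must be (close to) a steady state; it is symmetrized into the
    even subspace and Newton-polished at its own mean population before
    continuation starts. The branch is followed towards ``pbar_max`` by
    secant prediction and pseudo-arclength correction; after a fold it runs
    back down until ``pbar_min``, ``max_points`` or Newton failure at the
    minimum step ends it.
    """
    prob = _SteadyProblem(p.grid, params)
    pbar0 = p.mean()
    prob.scale_p = max(pbar0, 1.0)

    u = prob.pack(_symmetrize(p.values), _symmetrize(s.values))
    u = prob.newton(u, pbar0)

    def make_point(u: np.ndarray, pbar: float) -> BranchPoint:
        pf, sf = prob.unpack(u)
        if compute_stability:
            lead = prob.leading_nonstructural_eigenvalue(pf, sf)
            return BranchPoint(pbar, pf, sf, lead < 0.0, lead)
        return BranchPoint(pbar, pf, sf, None, None)

    points = [make_point(u, pbar0)]
    folds: list[float] = []

    # --- second point by natural continuation --------------------------
    h = step
    direction = 1.0 if pbar_max >= pbar0 else -1.0
    u_prev, pbar_prev = u, pbar0
    while True:
        try:
            pbar1 = pbar0 + direction * h
            u1 = prob.newton(u.copy(), pbar1)
            break
        except BranchEndError:
            h /= 2.0
            if h < min_step:
                raise
    points.append(make_point(u1, pbar1))

    # --- pseudo-arclength loop -----------------------------------------
    # arclength coordinates: (u, pbar / scale_p); u already scaled
    U_prev = np.append(u_prev, pbar_prev / prob.scale_p)
    U = np.append(u1, pbar1 / prob.scale_p)
    h = np.linalg.norm(U - U_prev)
    h_max = 4.0 * h

    def arc_residual(Uv: np.ndarray, U_pred: np.ndarray, tang: np.ndarray) -> np.ndarray:
        r = prob.residual(Uv[:-1], Uv[-1] * prob.scale_p)
        return np.append(r, np.dot(Uv - U_pred, tang))

    for _ in range(max_points - 2):
        tang = U - U_prev
        nrm = np.linalg.norm(tang)
        if nrm == 0:
            break
        tang = tang / nrm
        stepped = False
        while h >= min_step / prob.scale_p:
            U_pred = U + h * tang
            Uv = U_pred.copy()
            ok = True
            for _ in range(12):
                f = arc_residual(Uv, U_pred, tang)
                if np.max(np.abs(f)) < _RESID_TOL:
                    break
                Jf = np.empty((len(f), len(Uv)))
                for i in range(len(Uv)):
                    hh = 1e-7 * max(abs(Uv[i]), 1e-3)
                    Up = Uv.copy()
                    Up[i] += hh
                    Jf[:, i] = (arc_residual(Up, U_pred, tang) - f) / hh
                try:
                    Uv = Uv + np.linalg.solve(Jf, -f)
                except np.linalg.LinAlgError:
                    ok = False
                    break
            else:
                ok = False
            if ok and np.max(np.abs(arc_residual(Uv, U_pred, tang))) < _RESID_TOL:
                # reject steps that raced past a fold or jumped branches
                if abs(Uv[-1] - U[-1]) * prob.scale_p <= 2.0 * step and np.max(
                    np.abs(Uv[:-1] - U[:-1])
                ) <= 0.5:
                    stepped = True
                    break
            h /= 2.0
        if not stepped:
            break
        # fold detection: pbar direction reversal
        d_prev = U[-1] - U_prev[-1]
        d_new = Uv[-1] - U[-1]
        if d_prev * d_new < 0:
            folds.append(float(U[-1] * prob.scale_p))
        U_prev, U = U, Uv
        h = min(1.3 * h, h_max)
        pbar_here = float(U[-1] * prob.scale_p)
        points.append(make_point(U[:-1], pbar_here))
        if pbar_here > max(pbar_max, pbar0) + 1e-9 or pbar_here < pbar_min - 1e-9:
            break

    return ContinuationBranch(points, folds, p.grid, params)


def max_stable_pbar(branch: ContinuationBranch) -> float:
    """Largest mean population at which the branch is stable.

    Refined by linear interpolation of the leading eigenvalue between the
    last stable and first unstable consecutive points; at a fold where the
    branch simply ends while stable, the fold location itself is the edge.
    """
    stable = branch.stable_points()
    if not stable:
        raise ParameterError("branch has no stable points")
    best = max(pt.pbar for pt in stable)
    # eigenvalue zero crossing between adjacent points
    pts = branch.points
    for a, b in zip(pts[:-1], pts[1:]):
        if a.stable is None or b.stable is None:
            continue
        if a.stable != b.stable and a.leading_eigenvalue is not None:
            la, lb = a.leading_eigenvalue, b.leading_eigenvalue
            if (lb - la) != 0:
                cross = a.pbar + (0.0 - la) * (b.pbar - a.pbar) / (lb - la)
                if min(a.pbar, b.pbar) <= cross <= max(a.pbar, b.pbar):
                    best = max(best, float(cross))
    return float(best)
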