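"""Phase-coexistence solvers built on the rG-RPA+FH free energy.

Two modes:

* restricted -- the salt-ion concentration is uniform across phases;
  coexistence is a common-tangent construction on the one-dimensional
  free energy f(rho_p) with counterions slaved to electroneutrality.
* unrestricted -- ion partitioning is free; equilibria are formulated in
  neutral components (A = chain + |Q|/zc counterions, B = salt ion +
  zs/zc counterions), which fixes the Donnan bookkeeping without an
  explicit Galvani potential unknown.

Chemical potentials are assembled from analytic derivatives of the ideal
mixing entropy plus finite differences of the smooth excess part
(FH + charge correlations); this keeps the equations well conditioned even
for extremely dilute coexisting branches at deep quench.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, root

from .rgrpa import EnergyParams, SolutionState, free_energy
from .seqcharge import ChargeSequence

__all__ = [
    "BinodalPoint", "Tieline", "PhaseDiagram",
    "binodal_fixed_salt", "ucst", "salt_polymer_diagram",
    "tieline_at", "tieline_slope", "min_counterion_line",
]

EQ_TOL = 1e-8       # relative |d mu|, |d Pi| tolerance, restricted pairs
TIELINE_TOL = 1e-6  # relative tolerance for unrestricted tielines


@dataclass(frozen=True)
class BinodalPoint:
    T: float
    rho_p_dilute: float
    rho_p_dense: float
    rho_s_dilute: float
    rho_s_dense: float
    rho_c_dilute: float
    rho_c_dense: float

    def lever_fractions(self, rho_p_overall: float) -> tuple[float, float]:
        lam = ((rho_p_overall - self.rho_p_dense)
               / (self.rho_p_dilute - self.rho_p_dense))
        return lam, 1.0 - lam


@dataclass(frozen=True)
class Tieline:
    dilute: tuple[float, float]   # (rho_p, rho_s)
    dense: tuple[float, float]

    @property
    def slope(self) -> float:
        dp = self.dense[0] - self.dilute[0]
        return (self.dense[1] - self.dilute[1]) / dp if dp != 0 else math.nan


@dataclass
class PhaseDiagram:
    mode: str
    boundary: list[tuple[float, float]] = field(default_factory=list)
    tielines: list[Tieline] = field(default_factory=list)
    critical_point: tuple[float, float] | None = None
    truncated: bool = False


# ---------------------------------------------------------------------------
# free-energy plumbing in neutral components

def _xlogx(v: float) -> float:
    return v * math.log(v) if v > 0.0 else 0.0


class _Model:
    """Neutral-component view of the free energy at fixed T."""

    def __init__(self, cs: ChargeSequence, params: EnergyParams, T: float,
                 fast: bool = False):
        self.cs = cs
        self.params = params
        self.T = T
        self.fast = fast  # second-order instead of fourth-order excess FD
        self.qc = abs(cs.Q) / params.zc
        self.sc = params.zs / params.zc
        self.N = cs.N

    def state(self, rho_a: float, rho_b: float) -> SolutionState:
        rho_c = self.qc * rho_a + self.sc * rho_b
        return SolutionState(rho_p=rho_a, rho_c=rho_c, rho_s=rho_b, T=self.T)

    def phi_w(self, rho_a: float, rho_b: float) -> float:
        return (1.0 - self.N * rho_a - (self.qc * rho_a + self.sc * rho_b)
                - rho_b)

    def rho_a_max(self, rho_b: float, phi_max: float = 0.9995) -> float:
        occ = rho_b * (1.0 + self.sc)
        top = (phi_max - occ) / (self.N + self.qc)
        if top <= 0:
            raise ValueError("salt occupies the whole volume")
        return top

    # ---- ideal part, analytic ----
    def f_ideal(self, rho_a: float, rho_b: float) -> float:
        phi_p = self.N * rho_a
        rho_c = self.qc * rho_a + self.sc * rho_b
        return (_xlogx(phi_p) / self.N + _xlogx(rho_c) + _xlogx(rho_b)
                + _xlogx(self.phi_w(rho_a, rho_b)))

    def mu_a_ideal(self, rho_a: float, rho_b: float) -> float:
        phi_p = self.N * rho_a
        rho_c = self.qc * rho_a + self.sc * rho_b
        pw = self.phi_w(rho_a, rho_b)
        if phi_p <= 0 or pw <= 0 or (self.qc > 0 and rho_c <= 0):
            raise ValueError("mu_a undefined at the composition boundary")
        val = math.log(phi_p) + 1.0 - (self.N + self.qc) * (math.log(pw) + 1.0)
        if self.qc > 0:
            val += self.qc * (math.log(rho_c) + 1.0)
        return val

    def mu_b_ideal(self, rho_a: float, rho_b: float) -> float:
        rho_c = self.qc * rho_a + self.sc * rho_b
        pw = self.phi_w(rho_a, rho_b)
        if rho_b <= 0 or pw <= 0 or (self.sc > 0 and rho_c <= 0):
            raise ValueError("mu_b undefined at the composition boundary")
        val = math.log(rho_b) + 1.0 - (1.0 + self.sc) * (math.log(pw) + 1.0)
        if self.sc > 0:
            val += self.sc * (math.log(rho_c) + 1.0)
        return val

    # ---- excess part (FH + correlations), finite differenced ----
    def f_excess(self, rho_a: float, rho_b: float) -> float:
        br = free_energy(self.cs, self.state(rho_a, rho_b), self.params)
        return br.f_fh + br.f_el

    def _fd(self, fn, v: float, scale: float) -> float:
        h = max(v * 1e-3, scale * 1e-7)
        if v - h >= 0.0:
            if self.fast:
                return (fn(v + h) - fn(v - h)) / (2.0 * h)
            d1 = (fn(v + h) - fn(v - h)) / (2.0 * h)
            d2 = (fn(v + h / 2) - fn(v - h / 2)) / h
            return (4.0 * d2 - d1) / 3.0
        return (-3.0 * fn(v) + 4.0 * fn(v + h) - fn(v + 2 * h)) / (2.0 * h)

    def mu_a_excess(self, rho_a: float, rho_b: float) -> float:
        top = self.rho_a_max(rho_b)
        return self._fd(lambda r: self.f_excess(r, rho_b),
                        rho_a, min(top, 1e-3))

    def mu_b_excess(self, rho_a: float, rho_b: float) -> float:
        return self._fd(lambda r: self.f_excess(rho_a, r), rho_b, 1e-3)

    # ---- assembled quantities ----
    def f(self, rho_a: float, rho_b: float) -> float:
        return self.f_ideal(rho_a, rho_b) + self.f_excess(rho_a, rho_b)

    def mu_a(self, rho_a: float, rho_b: float) -> float:
        return (self.mu_a_ideal(rho_a, rho_b)
                + self.mu_a_excess(rho_a, rho_b))

    def mu_b(self, rho_a: float, rho_b: float) -> float:
        return (self.mu_b_ideal(rho_a, rho_b)
                + self.mu_b_excess(rho_a, rho_b))

    def omega(self, rho_a: float, rho_b: float, mu_a: float | None = None,
              mu_b: float | None = None) -> float:
        """Grand-potential density -Pi = f - rho_a mu_a - rho_b mu_b."""
        if mu_a is None:
            mu_a = self.mu_a(rho_a, rho_b)
        val = self.f(rho_a, rho_b) - rho_a * mu_a
        if rho_b > 0.0:
            if mu_b is None:
                mu_b = self.mu_b(rho_a, rho_b)
            val -= rho_b * mu_b
        return val


# ---------------------------------------------------------------------------
# restricted mode

def _lower_hull_gap(rho: np.ndarray, g: np.ndarray):
    """Widest miscibility gap from the lower convex hull of (rho, g)."""
    hull = [0]
    for k in range(1, len(rho)):
        while len(hull) >= 2:
            i, j = hull[-2], hull[-1]
            cross = ((rho[j] - rho[i]) * (g[k] - g[i])
                     - (g[j] - g[i]) * (rho[k] - rho[i]))
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(k)
    best = None
    for a, b in zip(hull[:-1], hull[1:]):
        if b - a > 1:
            if best is None or (rho[b] - rho[a]) > (rho[best[1]] - rho[best[0]]):
                best = (a, b)
    return best


def _grid_gap(model: _Model, rho_b: float, n_grid: int):
    top = model.rho_a_max(rho_b) * (1.0 - 3e-3)  # headroom for FD steps
    rho = np.geomspace(1e-12, top, n_grid)
    vals = np.array([model.f(r, rho_b) for r in rho])
    gap = _lower_hull_gap(rho, vals)
    if gap is None:
        return None
    return rho[gap[0]], rho[gap[1]]


def _maxwell_restricted(model: _Model, rho_b: float, n_grid: int = 90,
                        max_iter: int = 60):
    """Double-tangent construction by Newton iteration on the coexistence
    chemical potential mu*.

    The two branch densities solve mu(rho) = mu* on either side of the
    spinodal; since d omega/d mu* = -rho along each branch, the Newton step
    for equal grand potentials is exact and the scheme is robust at any
    quench depth (the dilute branch may be arbitrarily small -- the ideal
    part of mu is analytic).
    """
    top = model.rho_a_max(rho_b) * (1.0 - 3e-3)  # headroom for FD steps
    rho = np.geomspace(1e-12, top, n_grid)
    mu = np.empty(n_grid)
    for i, r in enumerate(rho):
        mu[i] = model.mu_a(r, rho_b)
    dmu = np.diff(mu)
    if np.all(dmu > 0):
        return None
    neg = np.nonzero(dmu < 0)[0]
    i1, i2 = neg[0], neg[-1] + 1          # spinodal-ish bounds on the grid
    if i2 >= n_grid - 1:
        return None                        # unstable up to the ceiling
    mu_hi = mu[i1]                         # local max on the dilute side
    mu_lo = mu[i2]                         # local min on the dense side
    if not mu_lo < mu_hi:
        return None

    def mu_of(r):
        return model.mu_a(r, rho_b)

    rtol = 1e-10 if model.fast else 1e-14
    phi_tol = (1e-6 if model.fast else EQ_TOL)
    brackets = {}   # root brackets reused between mu* iterations

    def root_in(key, mu_star, lo0, hi0):
        lo, hi = brackets.get(key, (lo0, hi0))
        f = lambda r: mu_of(r) - mu_star
        if not f(lo) < 0 < f(hi):      # previous bracket no longer valid
            lo, hi = lo0, hi0
            if key == "dilute":
                while f(lo) > 0:
                    lo *= 1e-6
                    if lo < 1e-200:
                        raise RuntimeError("dilute branch underflow")
        r = brentq(f, lo, hi, xtol=1e-300, rtol=rtol)
        span = 0.2 * r
        brackets[key] = (max(r - span, lo0), min(r + span, hi0))
        return r

    mu_star = 0.5 * (mu_lo + mu_hi)
    lo_b, hi_b = mu_lo, mu_hi              # bisection safeguard bracket
    a = b = None
    for _ in range(max_iter):
        try:
            a = root_in("dilute", mu_star, rho[0], rho[i1])
            b = root_in("dense", mu_star, rho[i2], top)
        except ValueError:
            mu_star = 0.5 * (lo_b + hi_b)
            continue
        om_a = model.f(a, rho_b) - a * mu_star
        om_b = model.f(b, rho_b) - b * mu_star
        phi = om_a - om_b
        # omega decreases faster on the dense branch; phi > 0 means mu* is
        # too high (dense phase favored) -> adjust the safeguard bracket
        if phi > 0:
            hi_b = mu_star
        else:
            lo_b = mu_star
        step = phi / (b - a)
        if abs(phi) < phi_tol * max(abs(om_a), abs(om_b), 1e-12):
            break
        mu_new = mu_star - step
        mu_star = mu_new if lo_b < mu_new < hi_b else 0.5 * (lo_b + hi_b)
    if a is None or b is None or not a < b:
        return None
    return a, b


def _common_tangent(cs: ChargeSequence, params: EnergyParams, rho_s: float,
                    T: float, n_grid: int = 90, fast: bool = False):
    model = _Model(cs, params, T, fast=fast)
    return _maxwell_restricted(model, rho_s, n_grid)


def has_instability(cs: ChargeSequence, params: EnergyParams, rho_s: float,
                    T: float, n_grid: int = 110) -> bool:
    """True if the restricted free energy is non-convex in rho_p."""
    return _grid_gap(_Model(cs, params, T), rho_s, n_grid) is not None


def binodal_fixed_salt(cs: ChargeSequence, params: EnergyParams,
                       salt_conc: float, T_grid, n_grid: int = 90,
                       fast: bool = False) -> list[BinodalPoint]:
    """Restricted-mode binodal points over a temperature grid.

    Non-convergent grid temperatures are skipped with a warning; nothing is
    interpolated.  ``salt_conc`` is the uniform salt-ion concentration in
    b^-3.
    """
    points = []
    for T in T_grid:
        try:
            pair = _common_tangent(cs, params, salt_conc, float(T),
                                   n_grid=n_grid, fast=fast)
        except Exception as exc:  # solver failure is reported, never hidden
            warnings.warn(f"binodal solve failed at T={T}: {exc}")
            continue
        if pair is None:
            continue
        a, b = pair
        qc = abs(cs.Q) / params.zc
        sc = params.zs / params.zc
        points.append(BinodalPoint(
            T=float(T), rho_p_dilute=a, rho_p_dense=b,
            rho_s_dilute=salt_conc, rho_s_dense=salt_conc,
            rho_c_dilute=qc * a + sc * salt_conc,
            rho_c_dense=qc * b + sc * salt_conc))
    return points


def ucst(cs: ChargeSequence, params: EnergyParams, salt_conc: float,
         T_window: tuple[float, float] = (100.0, 1500.0),
         tol: float = 0.05) -> float | None:
    """Critical (maximum) temperature of the restricted phase diagram.

    Bisects on the existence of a non-convex region of f(rho_p); for the
    one-dimensional restricted model instability exists exactly for
    T < Tcr, so this locates the binodal maximum.  Returns None if there is
    no phase separation anywhere in the window.
    """
    t_lo, t_hi = T_window
    if not has_instability(cs, params, salt_conc, t_lo):
        return None
    if has_instability(cs, params, salt_conc, t_hi):
        raise RuntimeError(f"T window {T_window} does not bracket the UCST")
    while t_hi - t_lo > tol:
        t_mid = 0.5 * (t_lo + t_hi)
        if has_instability(cs, params, salt_conc, t_mid):
            t_lo = t_mid
        else:
            t_hi = t_mid
    return 0.5 * (t_lo + t_hi)


# ---------------------------------------------------------------------------
# unrestricted (Donnan) mode

def tieline_at(cs: ChargeSequence, params: EnergyParams, T: float,
               rho_b_dilute: float, seed: tuple | None = None) -> Tieline | None:
    """Solve one unrestricted tieline given the dilute-phase salt level.

    Unknowns are (rho_a_dilute, rho_a_dense, rho_b_dense); the equations
    equate mu_A, mu_B and Pi between phases with per-phase
    electroneutrality built into the component map.
    """
    model = _Model(cs, params, T)
    if seed is None:
        pair = _common_tangent(cs, params, rho_b_dilute, T)
        if pair is None:
            return None
        seed = (pair[0], pair[1], rho_b_dilute)
    # unknowns: (log a1, log(a2/a1 - 1), log b2); the ratio form keeps the
    # dense phase strictly denser and blocks collapse onto the trivial root
    u0 = [math.log(seed[0]), math.log(seed[1] / seed[0] - 1.0),
          math.log(max(seed[2], 1e-12))]

    def unpack(u):
        a1 = math.exp(u[0])
        a2 = a1 * (1.0 + math.exp(u[1]))
        return a1, a2, math.exp(u[2])

    def eqs(u):
        try:
            a1, a2, b2 = unpack(u)
            mua1, mub1 = model.mu_a(a1, rho_b_dilute), model.mu_b(a1, rho_b_dilute)
            mua2, mub2 = model.mu_a(a2, b2), model.mu_b(a2, b2)
            om1 = model.omega(a1, rho_b_dilute, mua1, mub1)
            om2 = model.omega(a2, b2, mua2, mub2)
            s = max(1.0, abs(mua1))
            return [(mua1 - mua2) / s, mub1 - mub2,
                    (om1 - om2) / max(abs(om1), abs(om2), 1e-30)]
        except (ValueError, OverflowError, ZeroDivisionError):
            return [1e6, 1e6, 1e6]

    sol = root(eqs, u0, method="hybr", options={"xtol": 1e-13, "eps": 1e-6})
    a1, a2, b2 = unpack(sol.x)
    if not a2 > a1 * 1.001:
        return None
    res = eqs(sol.x)
    if max(abs(r) for r in res) > TIELINE_TOL:
        return None
    return Tieline(dilute=(a1, rho_b_dilute), dense=(a2, b2))


def salt_polymer_diagram(cs: ChargeSequence, params: EnergyParams, T: float,
                         rho_b_grid=None, n_tielines: int = 10,
                         rho_b_max: float = 0.33) -> PhaseDiagram:
    """Two-dimensional (rho_p, rho_s) phase diagram with tielines at fixed T.

    ``rho_b_max`` defaults to roughly a 10 M-equivalent axis limit.  The
    boundary polyline runs along the dilute branch then back along the
    dense branch; it is truncated (flagged) at the axis limit.
    """
    if rho_b_grid is None:
        rho_b_grid = np.concatenate([[1e-8], np.geomspace(1e-4, rho_b_max,
                                                          n_tielines - 1)])
    tielines = []
    for rb in rho_b_grid:
        tl = tieline_at(cs, params, T, float(rb))
        if tl is not None:
            tielines.append(tl)
    diagram = PhaseDiagram(mode="unrestricted", tielines=tielines,
                           truncated=True)
    diagram.boundary = ([t.dilute for t in tielines]
                        + [t.dense for t in reversed(tielines)])
    return diagram


def tieline_slope(cs: ChargeSequence, params: EnergyParams, T: float,
                  anchor: tuple[float, float], tol: float = 0.05) -> float:
    """Signed slope d rho_s / d rho_p of the tieline through ``anchor``.

    The anchor (rho_p, rho_s) must fall inside the coexistence region; the
    dilute-phase salt level is bisected until the anchor sits on the
    tieline segment (lever-rule consistency).
    """
    rho_p0, rho_s0 = anchor

    def miss(rb):
        tl = tieline_at(cs, params, T, rb)
        if tl is None:
            raise ValueError(f"anchor {anchor} outside the coexistence region")
        lam = ((rho_p0 - tl.dense[0]) / (tl.dilute[0] - tl.dense[0]))
        if not -0.2 <= lam <= 1.2:
            raise ValueError(f"anchor {anchor} outside the coexistence region")
        rs_pred = lam * tl.dilute[1] + (1 - lam) * tl.dense[1]
        return rs_pred - rho_s0, tl

    lo, hi = rho_s0 * 0.2, rho_s0 * 1.5
    m_lo, tl_lo = miss(lo)
    m_hi, tl_hi = miss(hi)
    if m_lo * m_hi > 0:
        tl = tl_lo if abs(m_lo) < abs(m_hi) else tl_hi
        return tl.slope
    rb = brentq(lambda r: miss(r)[0], lo, hi, xtol=rho_s0 * tol)
    return miss(rb)[1].slope


def min_counterion_line(cs: ChargeSequence, params: EnergyParams,
                        rho_p_grid) -> np.ndarray:
    """Minimum counterion concentration |Q| rho_p / zc for electroneutrality
    at zero salt (the inclined feasibility line of the high-valency maps)."""
    rho_p = np.asarray(rho_p_grid, dtype=float)
    return abs(cs.Q) * rho_p / params.zc


def _restricted_f(cs: ChargeSequence, params: EnergyParams, rho_s: float,
                  T: float):
    """f(rho_p) at uniform salt (testing hook for the hull oracle)."""
    model = _Model(cs, params, T)
    return lambda rho_a: model.f(rho_a, rho_s)
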