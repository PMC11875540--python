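"""Coarse-grained explicit-ion MD: energy model, Langevin dynamics, and
slab analysis.

Potential energy ``U_T = U_el + U_sr + U_bond``:

* ``U_el``: Coulomb in a uniform relative permittivity, truncated and
  shifted to zero at the electrostatic cutoff, decomposed into
  polymer-polymer, polymer-ion, and ion-ion parts;
* ``U_sr``: Ashbaugh-Hatch pairwise potential -- a Lennard-Jones well whose
  attractive branch is scaled by a per-pair stickiness ``lam_ij`` (plain LJ
  at ``lam=1``, purely repulsive at ``lam=0``);
* ``U_bond``: harmonic bonds between consecutive beads of each chain.

Units: kcal/mol, Angstrom, Da; the intrinsic time unit is then
sqrt(Da A^2 mol / kcal) ~ 48.9 fs.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np

KB_KCAL = 0.0019872041  # kcal/(mol K)
COULOMB_KCAL = 332.06371  # kcal A / (mol e^2)
_ION_SPECIES = {"NA", "CL", "MG", "X"}


def _load_species_table() -> dict:
    table = {}
    src = importlib.resources.files("ionphase").joinpath("data/sr_params.tsv")
    for line in src.read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("species"):
            continue
        sp, sigma, lam, charge, mass = line.split()
        table[sp] = {"sigma": float(sigma), "lam": float(lam),
                     "charge": float(charge), "mass": float(mass)}
    return table


SPECIES_TABLE = _load_species_table()


@dataclass(frozen=True)
class MDParams:
    epsilon_r: float = 80.0
    eps_sr: float = 0.2          # kcal/mol LJ energy scale
    sr_cutoff: float = 25.0      # Angstrom
    el_cutoff: float = 35.0      # Angstrom
    k_bond: float = 10.0         # kcal/mol/A^2 in U = k/2 (r - r0)^2
    r0_bond: float = 3.8
    friction: float = 0.5        # 1 / time unit
    dt: float = 0.05             # time units
    species_table: dict = field(default_factory=lambda: SPECIES_TABLE)

    def pair_well_depth(self, sp_a: str, sp_b: str) -> float:
        """Depth of the attractive well for a pair (0 for lam = 0 pairs)."""
        la = self.species_table[sp_a]["lam"]
        lb = self.species_table[sp_b]["lam"]
        return 0.5 * (la + lb) * self.eps_sr


@dataclass
class Configuration:
    """Bead coordinates with species labels and chain ids in a periodic box.

    ``chain_ids`` >= 0 mark chain membership (bonded beads are consecutive
    in index within a chain); -1 marks free ions.  Coordinates are wrapped
    into the box on construction.
    """

    coords: np.ndarray
    species: list[str]
    chain_ids: list[int]
    box: tuple[float, float, float]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.species) != len(self.coords) or len(self.chain_ids) != len(self.coords):
            raise ValueError("species/chain/coordinate lengths differ")
        box = np.asarray(self.box, dtype=float)
        if np.any(box <= 0):
            raise ValueError("box lengths must be positive")
        self.coords = np.mod(self.coords, box)
        self.box = tuple(box)

    @property
    def n(self) -> int:
        return len(self.species)


@dataclass
class Trajectory:
    frames: list[Configuration]
    times: list[float]


def _bonded_pairs(cfg: Configuration) -> np.ndarray:
    ids = np.asarray(cfg.chain_ids)
    same = (ids[:-1] == ids[1:]) & (ids[:-1] >= 0)
    idx = np.nonzero(same)[0]
    return np.column_stack([idx, idx + 1])


def _pair_table(cfg: Configuration, params: MDParams):
    t = params.species_table
    try:
        sig = np.array([t[s]["sigma"] for s in cfg.species])
        lam = np.array([t[s]["lam"] for s in cfg.species])
        q = np.array([t[s]["charge"] for s in cfg.species])
        m = np.array([t[s]["mass"] for s in cfg.species])
    except KeyError as exc:
        raise KeyError(f"unknown species {exc.args[0]!r}") from None
    return sig, lam, q, m


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def energy(cfg: Configuration, params: MDParams) -> dict:
    """Energy decomposition {U_total, U_el, U_el_pp, U_el_pi, U_el_ii,
    U_sr, U_bond} in kcal/mol."""
    n = cfg.n
    box = np.asarray(cfg.box)
    sig, lam, q, _ = _pair_table(cfg, params)
    is_ion = np.array([s in _ION_SPECIES for s in cfg.species])

    iu, ju = np.triu_indices(n, k=1)
    d = _min_image(cfg.coords[iu] - cfg.coords[ju], box)
    r = np.linalg.norm(d, axis=1)
    if n > 1 and r.min() < 1e-9:
        raise ValueError("overlapping beads at zero distance")

    bonds = _bonded_pairs(cfg)
    bonded_mask = np.zeros(len(iu), dtype=bool)
    if len(bonds):
        key = iu.astype(np.int64) * n + ju
        bkey = bonds[:, 0].astype(np.int64) * n + bonds[:, 1]
        bonded_mask = np.isin(key, bkey)

    # electrostatics: truncated & shifted Coulomb
    qq = q[iu] * q[ju]
    el_mask = (~bonded_mask) & (qq != 0.0) & (r < params.el_cutoff)
    u_el_pair = np.zeros(len(iu))
    u_el_pair[el_mask] = (COULOMB_KCAL / params.epsilon_r * qq[el_mask]
                          * (1.0 / r[el_mask] - 1.0 / params.el_cutoff))
    both_ion = is_ion[iu] & is_ion[ju]
    both_pol = ~is_ion[iu] & ~is_ion[ju]
    u_el_pp = float(u_el_pair[both_pol].sum())
    u_el_ii = float(u_el_pair[both_ion].sum())
    u_el_pi = float(u_el_pair.sum()) - u_el_pp - u_el_ii

    # short range Ashbaugh-Hatch
    sij = 0.5 * (sig[iu] + sig[ju])
    lij = 0.5 * (lam[iu] + lam[ju])
    sr_mask = (~bonded_mask) & (r < params.sr_cutoff)
    u_sr = 0.0
    if np.any(sr_mask):
        rr = r[sr_mask]
        ss = sij[sr_mask]
        ll = lij[sr_mask]
        x6 = (ss / rr) ** 6
        ulj = 4.0 * params.eps_sr * (x6 * x6 - x6)
        rmin = 2.0 ** (1.0 / 6.0) * ss
        inner = rr <= rmin
        vals = np.where(inner, ulj + (1.0 - ll) * params.eps_sr, ll * ulj)
        u_sr = float(vals.sum())

    u_bond = 0.0
    if len(bonds):
        db = _min_image(cfg.coords[bonds[:, 0]] - cfg.coords[bonds[:, 1]], box)
        rb = np.linalg.norm(db, axis=1)
        u_bond = float((0.5 * params.k_bond * (rb - params.r0_bond) ** 2).sum())

    u_el = u_el_pp + u_el_pi + u_el_ii
    return {"U_total": u_el + u_sr + u_bond, "U_el": u_el,
            "U_el_pp": u_el_pp, "U_el_pi": u_el_pi, "U_el_ii": u_el_ii,
            "U_sr": u_sr, "U_bond": u_bond}


def forces(cfg: Configuration, params: MDParams) -> np.ndarray:
    """Analytic forces -grad U, shape (n, 3), kcal/mol/A."""
    n = cfg.n
    box = np.asarray(cfg.box)
    sig, lam, q, _ = _pair_table(cfg, params)
    f = np.zeros((n, 3))
    if n < 2:
        return f

    iu, ju = np.triu_indices(n, k=1)
    d = _min_image(cfg.coords[iu] - cfg.coords[ju], box)
    r = np.linalg.norm(d, axis=1)
    if r.min() < 1e-9:
        raise ValueError("overlapping beads at zero distance")

    bonds = _bonded_pairs(cfg)
    bonded_mask = np.zeros(len(iu), dtype=bool)
    if len(bonds):
        key = iu.astype(np.int64) * n + ju
        bkey = bonds[:, 0].astype(np.int64) * n + bonds[:, 1]
        bonded_mask = np.isin(key, bkey)

    # -dU/dr for each pair term
    dudr = np.zeros(len(iu))
    qq = q[iu] * q[ju]
    el_mask = (~bonded_mask) & (qq != 0.0) & (r < params.el_cutoff)
    dudr[el_mask] += -COULOMB_KCAL / params.epsilon_r * qq[el_mask] / r[el_mask] ** 2

    sij = 0.5 * (sig[iu] + sig[ju])
    lij = 0.5 * (lam[iu] + lam[ju])
    sr_mask = (~bonded_mask) & (r < params.sr_cutoff)
    if np.any(sr_mask):
        rr = r[sr_mask]
        ss = sij[sr_mask]
        x6 = (ss / rr) ** 6
        dulj = 4.0 * params.eps_sr * (-12.0 * x6 * x6 + 6.0 * x6) / rr
        rmin = 2.0 ** (1.0 / 6.0) * ss
        scale = np.where(rr <= rmin, 1.0, lij[sr_mask])
        dudr[sr_mask] += scale * dulj

    pair_f = (-dudr / r)[:, None] * d  # force on iu from ju
    np.add.at(f, iu, pair_f)
    np.add.at(f, ju, -pair_f)

    if len(bonds):
        db = _min_image(cfg.coords[bonds[:, 0]] - cfg.coords[bonds[:, 1]], box)
        rb = np.linalg.norm(db, axis=1)
        fb = (-params.k_bond * (rb - params.r0_bond) / rb)[:, None] * db
        np.add.at(f, bonds[:, 0], fb)
        np.add.at(f, bonds[:, 1], -fb)
    return f


def kinetic_temperature(vel: np.ndarray, mass: np.ndarray) -> float:
    ke = 0.5 * float(np.sum(mass[:, None] * vel**2))
    return 2.0 * ke / (3.0 * len(mass) * KB_KCAL)


def langevin_run(cfg: Configuration, params: MDParams, T: float, steps: int,
                 seed: int, save_every: int = 100,
                 zero_velocities: bool = False) -> Trajectory:
    """BAOAB Langevin dynamics; seeded and bitwise reproducible.

    Raises on energy blow-up (non-finite coordinates or forces).
    """
    rng = np.random.Generator(np.random.Philox(seed))
    box = np.asarray(cfg.box)
    _, _, _, mass = _pair_table(cfg, params)
    x = cfg.coords.copy()
    if zero_velocities or T == 0.0:
        v = np.zeros_like(x)
    else:
        v = rng.normal(0.0, 1.0, x.shape) * np.sqrt(KB_KCAL * T / mass)[:, None]
    dt = params.dt
    c1 = math.exp(-params.friction * dt)
    c2 = math.sqrt(max(1.0 - c1 * c1, 0.0))
    sd = np.sqrt(KB_KCAL * T / mass)[:, None]

    def frame(xx):
        return Configuration(coords=xx.copy(), species=list(cfg.species),
                             chain_ids=list(cfg.chain_ids), box=cfg.box)

    cur = frame(x)
    f = forces(cur, params)
    frames, times = [frame(x)], [0.0]
    for step in range(1, steps + 1):
        v += 0.5 * dt * f / mass[:, None]
        x += 0.5 * dt * v
        v = c1 * v + c2 * sd * rng.normal(0.0, 1.0, v.shape)
        x += 0.5 * dt * v
        x = np.mod(x, box)
        cur = frame(x)
        f = forces(cur, params)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(f))):
            raise RuntimeError(f"energy blow-up at step {step}")
        v += 0.5 * dt * f / mass[:, None]
        if step % save_every == 0:
            frames.append(frame(x))
            times.append(step * dt)
    return Trajectory(frames=frames, times=times)


# ---------------------------------------------------------------------------
# slab analysis

@dataclass
class SlabProfile:
    z_centers: np.ndarray
    mass_density: np.ndarray     # mg/ml
    number_conc: np.ndarray      # mM
    species: str
    box: tuple[float, float, float]
    n_frames: int


_MGML = 1660.5390                 # (Da / A^3) -> mg/ml
_MM = 1.0 / 6.02214076e-7         # (1 / A^3) -> mM


def _recenter_z(z: np.ndarray, lz: float) -> float:
    """Circular center of mass of z positions; returns the shift that puts
    it at lz/2."""
    theta = 2.0 * np.pi * z / lz
    ang = math.atan2(np.mean(np.sin(theta)), np.mean(np.cos(theta)))
    com = (ang % (2.0 * np.pi)) * lz / (2.0 * np.pi)
    return 0.5 * lz - com


def slab_profiles(traj, bins: int = 100, recenter: bool = True) -> dict:
    """Per-species z-density profiles averaged over frames.

    The dense slab is recentered each frame using the circular center of
    mass of the chain beads (all beads if the frame has no chains).
    """
    frames = traj.frames if isinstance(traj, Trajectory) else list(traj)
    if not frames:
        raise ValueError("empty frame selection")
    box = frames[0].box
    lz = box[2]
    edges = np.linspace(0.0, lz, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    area = box[0] * box[1]
    dv = area * (edges[1] - edges[0])
    species_set = sorted(set().union(*[set(f.species) for f in frames]))
    counts = {s: np.zeros(bins) for s in species_set}
    for f in frames:
        sp = np.asarray(f.species)
        z = f.coords[:, 2]
        if recenter:
            ids = np.asarray(f.chain_ids)
            sel = z[ids >= 0] if np.any(ids >= 0) else z
            z = np.mod(z + _recenter_z(sel, lz), lz)
        for s in species_set:
            counts[s] += np.histogram(z[sp == s], bins=edges)[0]
    out = {}
    nf = len(frames)
    for s in species_set:
        mean_n = counts[s] / nf
        mass = SPECIES_TABLE.get(s, {"mass": 0.0})["mass"]
        out[s] = SlabProfile(z_centers=centers,
                             mass_density=_MGML * mass * mean_n / dv,
                             number_conc=_MM * mean_n / dv,
                             species=s, box=box, n_frames=nf)
    return out


def extract_plateaus(profile: SlabProfile, use: str = "mass") -> tuple[float, float]:
    """(dense, dilute) plateau values from a recentered two-plateau profile.

    The dense plateau averages bins above the midpoint between the profile
    extremes (trimmed near the interfaces), the dilute plateau those below.
    Raises if the plateaus are not separated (near-critical profile).
    """
    y = profile.mass_density if use == "mass" else profile.number_conc
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi <= 0:
        raise ValueError("no plateau separation (near-critical profile)")
    mid = 0.5 * (lo + hi)
    mask = y > mid
    # positional trimming: drop bins close to any interface (mask
    # transition) rather than by value, to avoid biasing the plateau means
    n = len(y)
    trans = np.nonzero(mask != np.roll(mask, 1))[0]
    if len(trans) == 0:
        raise ValueError("no plateau separation (near-critical profile)")
    pos = np.arange(n)
    dist = np.min([np.minimum(np.abs(pos - t), n - np.abs(pos - t))
                   for t in trans], axis=0)
    margin = max(2, n // 20)
    far = dist >= margin
    dense_bins = y[mask & far]
    dilute_bins = y[~mask & far]
    if len(dense_bins) == 0 or len(dilute_bins) == 0:
        raise ValueError("no plateau separation (near-critical profile)")
    dense = float(np.mean(dense_bins))
    dilute = float(np.mean(dilute_bins))
    noise = float(np.std(dense_bins) + np.std(dilute_bins))
    if dense - dilute < 2.0 * noise:
        raise ValueError("no plateau separation (near-critical profile)")
    return dense, dilute


def binodal_from_slabs(profiles_by_T: dict, beta: float = 0.325,
                       Tcr0: float | None = None, use: str = "mass") -> dict:
    """Dilute/dense branches vs T and a critical-point estimate.

    Fits the order parameter (rho_d - rho_l) = A (Tcr - T)^beta together
    with the rectilinear-diameter law (rho_d + rho_l)/2 = rho_cr + B(Tcr - T)
    by least squares.  Needs >= 3 temperatures with separated plateaus.
    """
    from scipy.optimize import least_squares

    temps, dense, dilute = [], [], []
    for T in sorted(profiles_by_T):
        try:
            d, l = extract_plateaus(profiles_by_T[T], use=use)
        except ValueError:
            continue
        temps.append(float(T))
        dense.append(d)
        dilute.append(l)
    if len(temps) < 3:
        raise ValueError("need >= 3 temperatures with clear plateaus")
    temps = np.array(temps)
    dense = np.array(dense)
    dilute = np.array(dilute)
    dd = dense - dilute
    mid = 0.5 * (dense + dilute)

    def resid(p):
        a, b, rho_c, tc = p
        dt = np.clip(tc - temps, 1e-9, None)
        return np.concatenate([a * dt**beta - dd, rho_c + b * dt - mid])

    t_max = temps.max()
    p0 = [dd.max() / max((t_max * 1.1 - temps.min()) ** beta, 1e-9),
          0.0, mid.mean(), t_max * 1.1]
    fit = least_squares(resid, p0, bounds=([0, -np.inf, 0, t_max],
                                           [np.inf, np.inf, np.inf, np.inf]))
    a, b, rho_c, tcr = fit.x
    out = {"T": temps, "dense": dense, "dilute": dilute,
           "Tcr": float(tcr), "rho_cr": float(rho_c),
           "amplitude": float(a), "diameter_slope": float(b)}
    if Tcr0 is not None:
        out["Tcr_over_Tcr0"] = float(tcr) / Tcr0
    return out


def build_chain_system(sequence: str, n_chains: int, box, counterion: str,
                       n_salt_pairs: int = 0, seed: int = 0,
                       py_positions: tuple[int, ...] = ()) -> Configuration:
    """Random-coil chains plus neutralizing counterions and optional NaCl.

    Chains are placed as random walks with the bond length as step; the
    counterion count follows electroneutrality with monovalent ions.
    """
    rng = np.random.Generator(np.random.Philox(seed))
    box = np.asarray(box, dtype=float)
    species, chains, coords = [], [], []
    labels = [("y" if (i + 1) in py_positions else a)
              for i, a in enumerate(sequence)]
    q_chain = sum(SPECIES_TABLE[s]["charge"] for s in labels)
    for c in range(n_chains):
        pos = rng.uniform(0, 1, 3) * box
        for s in labels:
            species.append(s)
            chains.append(c)
            coords.append(pos.copy())
            step = rng.normal(0, 1, 3)
            pos = pos + 3.8 * step / np.linalg.norm(step)
    n_ci = int(round(abs(q_chain) * n_chains))
    ci = counterion
    co = "CL" if ci == "NA" else "NA"
    for _ in range(n_ci):
        species.append(ci)
        chains.append(-1)
        coords.append(rng.uniform(0, 1, 3) * box)
    for _ in range(n_salt_pairs):
        for s in ("NA", "CL"):
            species.append(s)
            chains.append(-1)
            coords.append(rng.uniform(0, 1, 3) * box)
    return Configuration(coords=np.asarray(coords), species=species,
                         chain_ids=chains, box=tuple(box))
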