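"""Lattice field-theoretic simulation via complex-Langevin (CL) dynamics.

The field Hamiltonian couples two complex fields -- an electrostatic field
``psi`` and an excluded-volume field ``w`` -- to single-molecule partition
functions of bead-charge-sequenced species (a protein chain, a short
6-bead ATP-Mg chain, monovalent ions):

    H[w, psi] = Int dr [ (grad psi)^2 / (8 pi lB) + w^2 / (2 v2) ]
                - sum_m n_m ln Q_m[w_s, psi_s]

with Gaussian-smeared fields (subscript s).  CL evolves both fields in a
fictitious time with real white noise; thermal averages are CL-time
averages whose imaginary parts must vanish within sampling error.

The integrator is first-order semi-implicit with the linearized (RPA)
density response folded into the implicit part, which keeps lB ~ 7 b
tractable at modest time steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

try:  # low-overhead path: the pocketfft kernel scipy.fft wraps
    from scipy.fft._pocketfft.pypocketfft import c2c as _c2c
except ImportError:  # pragma: no cover - fallback for other scipy builds
    _c2c = None


def _fft3(a, axes, forward):
    """fftn/ifftn via the pocketfft kernel without dispatch overhead."""
    if _c2c is not None:
        return _c2c(np.ascontiguousarray(a), axes=axes, forward=forward,
                    inorm=0 if forward else 2, nthreads=1)
    return (sfft.fftn(a, axes=axes) if forward
            else sfft.ifftn(a, axes=axes))

__all__ = [
    "SpeciesSpec", "FTSConfig", "FTSSystem", "FieldState",
    "CorrelationEstimate", "build_system", "single_molecule_partition",
    "cl_step", "run_fts", "estimate_correlations", "residue_contact_profile",
    "ATP_MG_BEAD_CHARGES",
]

#: 6-bead (ATP-Mg)2- model: a tetravalent phosphate-like tail followed by
#: two +1 beads representing the complexed divalent magnesium
ATP_MG_BEAD_CHARGES = (-1, -1, -1, -1, 1, 1)


@dataclass(frozen=True)
class SpeciesSpec:
    label: str
    bead_charges: tuple[int, ...]
    rho: float | None = None       # bulk BEAD density, b^-3 (None = free)
    smear_a: float | None = None   # per-species smearing width (None = global)

    @property
    def n_beads(self) -> int:
        return len(self.bead_charges)

    @property
    def net_charge(self) -> int:
        return int(sum(self.bead_charges))


@dataclass(frozen=True)
class FTSConfig:
    dims: tuple[int, int, int] = (16, 16, 16)
    spacing: float = 1.0           # lattice spacing, b
    smear_a: float = 1.0 / math.sqrt(6.0)
    lb: float = 7.0                # Bjerrum length, b
    v2: float = 0.0068             # excluded volume, b^3
    dt: float = 5e-3
    kuhn_l: float = 1.0            # bond (Kuhn) length of chain species, b
    seed: int = 0
    n_therm: int = 2000
    n_prod: int = 4000
    sample_every: int = 20

    def __post_init__(self):
        if self.dt <= 0 or self.smear_a <= 0 or self.v2 < 0 or self.lb <= 0:
            raise ValueError("dt, smear_a, lb must be positive, v2 >= 0")


@dataclass
class FieldState:
    w: np.ndarray
    psi: np.ndarray
    t: float = 0.0


@dataclass
class CorrelationEstimate:
    r: np.ndarray
    mean: np.ndarray               # real part of <rho_m rho_n>(r)
    stderr: np.ndarray
    imag_mean: np.ndarray
    imag_stderr: np.ndarray
    rho_m0: float
    rho_n0: float

    @property
    def normalized(self) -> np.ndarray:
        return self.mean / (self.rho_m0 * self.rho_n0)

    @property
    def normalized_stderr(self) -> np.ndarray:
        return self.stderr / (self.rho_m0 * self.rho_n0)


def _block_stats(samples: np.ndarray, n_blocks: int = 8):
    """Mean and blocked standard error along axis 0."""
    n = len(samples)
    nb = max(2, min(n_blocks, n))
    cut = (n // nb) * nb
    blocks = samples[:cut].reshape(nb, cut // nb, *samples.shape[1:]).mean(axis=1)
    mean = blocks.mean(axis=0)
    err = blocks.std(axis=0, ddof=1) / math.sqrt(nb)
    return mean, err


class FTSSystem:
    """Precomputed lattice operators + species bookkeeping."""

    def __init__(self, species: list[SpeciesSpec], config: FTSConfig):
        self.species = list(species)
        self.config = config
        dims = config.dims
        self.V = dims[0] * dims[1] * dims[2] * config.spacing**3
        ks = [2.0 * np.pi * np.fft.fftfreq(n, d=config.spacing) for n in dims]
        kx, ky, kz = np.meshgrid(*ks, indexing="ij")
        self.k2 = kx**2 + ky**2 + kz**2
        self.gamma_k = np.exp(-0.5 * config.smear_a**2 * self.k2)
        # per-species smearing (hydrated small ions may be smeared wider
        # than chain beads); identical widths share one array
        self._gammas = {}
        self.gamma_by_label = {}
        for s in self.species:
            a = s.smear_a if s.smear_a is not None else config.smear_a
            if a not in self._gammas:
                self._gammas[a] = np.exp(-0.5 * a**2 * self.k2)
            self.gamma_by_label[s.label] = self._gammas[a]
        self.bond_k = np.exp(-self.k2 * config.kuhn_l**2 / 6.0)
        if any(s.rho is None for s in self.species):
            raise ValueError("unresolved species density; use build_system")
        charge = sum((s.rho / s.n_beads) * s.net_charge for s in self.species)
        if abs(charge) > 1e-12:
            raise ValueError(f"system not electroneutral (charge {charge:g})")
        # linearized density response for the semi-implicit integrator
        a_psi = np.zeros_like(self.k2)
        a_w = np.zeros_like(self.k2)
        for s in self.species:
            rho_mol = s.rho / s.n_beads
            sig = np.asarray(s.bead_charges, dtype=float)
            m = s.n_beads
            c_sig = np.correlate(sig, sig, mode="full")[m - 1:]
            s_sig = c_sig[0] * np.ones_like(self.k2)
            s_den = float(m) * np.ones_like(self.k2)
            ph = np.ones_like(self.k2)
            for d in range(1, m):
                ph = ph * self.bond_k
                s_sig += 2.0 * c_sig[d] * ph
                s_den += 2.0 * (m - d) * ph
            g2 = self.gamma_by_label[s.label] ** 2
            a_psi += rho_mol * s_sig * g2
            a_w += rho_mol * s_den * g2
        # implicit part: Gaussian term plus the RPA response of each
        # field's own conjugate density (linearized-force stabilization);
        # the species smearing is already folded into a_psi / a_w
        self.L_psi = self.k2 / (4.0 * np.pi * config.lb) + a_psi
        # v2 = 0 disables the excluded-volume field entirely (w frozen at 0)
        self.L_w = 1.0 / config.v2 + a_w if config.v2 > 0 else None

    # -- spectral helpers --
    def smear(self, field_k: np.ndarray) -> np.ndarray:
        return field_k * self.gamma_k

    def bond_convolve(self, arr: np.ndarray) -> np.ndarray:
        return _fft3(_fft3(arr, (0, 1, 2), True) * self.bond_k,
                     (0, 1, 2), False)

    def bond_convolve_pair(self, a: np.ndarray, b: np.ndarray):
        stack = np.stack([a, b])
        out = _fft3(_fft3(stack, (1, 2, 3), True) * self.bond_k,
                    (1, 2, 3), False)
        return out[0], out[1]

    def species_by_label(self, label: str) -> SpeciesSpec:
        for s in self.species:
            if s.label == label:
                return s
        raise KeyError(label)


def build_system(species: list[SpeciesSpec], config: FTSConfig) -> FTSSystem:
    """Resolve the free ion species by electroneutrality and build a system.

    At most one species may have ``rho=None``; its density is set to cancel
    the net charge of the rest (error if impossible).
    """
    free = [i for i, s in enumerate(species) if s.rho is None]
    if len(free) > 1:
        raise ValueError("at most one species may be left free")
    resolved = list(species)
    if free:
        i = free[0]
        s = resolved[i]
        others = sum(sp.rho / sp.n_beads * sp.net_charge
                     for j, sp in enumerate(resolved) if j != i)
        rho_mol = -others / s.net_charge
        if rho_mol < -1e-15:
            raise ValueError("free species has the wrong charge sign to "
                             "neutralize the system")
        resolved[i] = SpeciesSpec(s.label, s.bead_charges,
                                  rho=max(rho_mol, 0.0) * s.n_beads,
                                  smear_a=s.smear_a)
    else:
        total = sum(s.rho / s.n_beads * s.net_charge for s in resolved)
        if abs(total) > 1e-12:
            raise ValueError("unneutralizable composition: no free species "
                             f"and net charge {total:g}")
    return FTSSystem(resolved, config)


def single_molecule_partition(state: FieldState, spec: SpeciesSpec,
                              system: FTSSystem):
    """Q_m and the per-bead density operator fields for one species.

    Chain propagator recursion with a Gaussian bond transfer; the density
    of bead i is n_mol q_i qbar_i / (V Q_m F_i) where F_i is the bead's
    local Boltzmann field factor.  Single-bead species reduce to
    Q = <F> and rho = rho_bulk F / <F>.
    """
    gk = system.gamma_by_label.get(spec.label, system.gamma_k)
    ax = (0, 1, 2)
    w_s = _fft3(_fft3(state.w, ax, True) * gk, ax, False)
    psi_s = _fft3(_fft3(state.psi, ax, True) * gk, ax, False)
    sig = spec.bead_charges
    m = spec.n_beads
    fac = {s: np.exp(1j * (s * psi_s + w_s)) for s in set(sig)}
    # forward and backward propagators advance together so each bond
    # transfer costs one batched FFT pair
    q_fwd: list = [None] * m
    q_bwd: list = [None] * m
    q_fwd[0] = fac[sig[0]]
    q_bwd[m - 1] = fac[sig[m - 1]]
    for t in range(m - 1):
        cf, cb = system.bond_convolve_pair(q_fwd[t], q_bwd[m - 1 - t])
        q_fwd[t + 1] = fac[sig[t + 1]] * cf
        q_bwd[m - 2 - t] = fac[sig[m - 2 - t]] * cb
    q_m = q_fwd[-1].mean()
    rho_mol = (spec.rho / m) if spec.rho else 0.0
    dens = [rho_mol * q_fwd[i] * q_bwd[i] / (fac[sig[i]] * q_m)
            for i in range(m)]
    return q_m, dens


def _drift_densities(state: FieldState, system: FTSSystem):
    """Smeared charge/total density spectra and per-species bead densities.

    The conjugate density of each species is smeared with that species'
    own Gamma, so the accumulation happens in k space.
    """
    rho_ch_k = np.zeros(system.config.dims, dtype=complex)
    rho_tot_k = np.zeros(system.config.dims, dtype=complex)
    per_species = {}
    for spec in system.species:
        _, dens = single_molecule_partition(state, spec, system)
        per_species[spec.label] = dens
        ch = np.zeros(system.config.dims, dtype=complex)
        tot = np.zeros(system.config.dims, dtype=complex)
        for s_i, d_i in zip(spec.bead_charges, dens):
            ch += s_i * d_i
            tot += d_i
        gk = system.gamma_by_label[spec.label]
        rho_ch_k += gk * _fft3(ch, (0, 1, 2), True)
        rho_tot_k += gk * _fft3(tot, (0, 1, 2), True)
    return rho_ch_k, rho_tot_k, per_species


def cl_step(state: FieldState, system: FTSSystem, dt: float,
            rng: np.random.Generator, densities=None) -> FieldState:
    """One semi-implicit CL update of both fields (in place on copies).

    Real Gaussian noise with covariance 2 dt / dV per lattice site; the
    k = 0 mode of psi (a gauge mode for neutral systems) is pinned to zero.
    Raises on field blow-up.
    """
    cfg = system.config
    if densities is None:
        rho_ch_k, rho_tot_k, _ = _drift_densities(state, system)
    else:
        rho_ch_k, rho_tot_k = densities
    dv = cfg.spacing**3
    std = math.sqrt(2.0 * dt / dv)
    psi_k = sfft.fftn(state.psi)
    # nonlinear drift parts (full drift minus L * field)
    nl_psi = -1j * rho_ch_k \
        - (system.L_psi - system.k2 / (4.0 * np.pi * cfg.lb)) * psi_k
    eta_psi = sfft.fftn(rng.normal(0.0, std, cfg.dims))
    psi_k = (psi_k - dt * nl_psi + eta_psi) / (1.0 + dt * system.L_psi)
    psi_k.flat[0] = 0.0
    if system.L_w is not None:
        w_k = sfft.fftn(state.w)
        nl_w = -1j * rho_tot_k \
            - (system.L_w - 1.0 / cfg.v2) * w_k
        eta_w = sfft.fftn(rng.normal(0.0, std, cfg.dims))
        w_k = (w_k - dt * nl_w + eta_w) / (1.0 + dt * system.L_w)
        w = sfft.ifftn(w_k)
    else:
        w = state.w
    new = FieldState(w=w, psi=sfft.ifftn(psi_k), t=state.t + dt)
    if not (np.all(np.isfinite(new.w)) and np.all(np.isfinite(new.psi))) \
            or max(np.abs(new.w).max(), np.abs(new.psi).max()) > 1e8:
        raise RuntimeError(f"CL divergence at t = {new.t:g}")
    return new


# ---------------------------------------------------------------------------
# production runs with online accumulation

def _radial_bins(system: FTSSystem):
    cfg = system.config
    idx = [np.fft.fftfreq(n, d=1.0 / n) for n in cfg.dims]  # signed indices
    dx, dy, dz = np.meshgrid(*idx, indexing="ij")
    r = np.sqrt(dx**2 + dy**2 + dz**2) * cfg.spacing
    edges = np.arange(0.0, r.max() + cfg.spacing, cfg.spacing)
    which = np.digitize(r.ravel(), edges) - 1
    counts = np.bincount(which, minlength=len(edges) - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return which, counts, centers


def _cross_correlation(a: np.ndarray, b: np.ndarray, V: float) -> np.ndarray:
    """g(Delta) = <rho_a(r) rho_b(r + Delta)>_r for complex lattice fields."""
    ax = (0, 1, 2)
    ak_neg = np.conj(_fft3(np.conj(a), ax, True))   # A(-k) for complex a
    bk = _fft3(b, ax, True)
    return _fft3(ak_neg * bk, ax, False) / a.size


@dataclass
class FTSRun:
    system: FTSSystem
    state: FieldState
    r: np.ndarray
    pair_samples: dict = field(default_factory=dict)   # (m,n) -> [radial g]
    contact_samples: dict = field(default_factory=dict)  # q -> [len-N arrays]
    density_checks: dict = field(default_factory=dict)
    n_samples: int = 0


def run_fts(system: FTSSystem, pairs=(), contact_ion: str | None = None,
            rcontact: float = 1.5, protein_label: str = "p",
            progress: bool = False) -> FTSRun:
    """Thermalize then sample; correlations are accumulated online.

    ``pairs`` are (m, n) species-label pairs for radially averaged
    G_mn(r); ``contact_ion`` requests the per-residue integrated contact
    profile of the protein with that ion species.
    """
    cfg = system.config
    rng = np.random.Generator(np.random.Philox(cfg.seed))
    state = FieldState(w=np.zeros(cfg.dims, dtype=complex),
                       psi=np.zeros(cfg.dims, dtype=complex))
    which, bin_counts, centers = _radial_bins(system)
    run = FTSRun(system=system, state=state, r=centers)
    for pair in pairs:
        run.pair_samples[tuple(pair)] = []
    if contact_ion is not None:
        run.contact_samples[contact_ion] = []
    # contact offsets: lattice displacements within rcontact
    rng_off = int(math.ceil(rcontact / cfg.spacing))
    offsets = [(i, j, k) for i in range(-rng_off, rng_off + 1)
               for j in range(-rng_off, rng_off + 1)
               for k in range(-rng_off, rng_off + 1)
               if (i * i + j * j + k * k) * cfg.spacing**2 <= rcontact**2]

    total = cfg.n_therm + cfg.n_prod
    for step in range(total):
        rho_ch_k, rho_tot_k, per_species = _drift_densities(state, system)
        if step >= cfg.n_therm and (step - cfg.n_therm) % cfg.sample_every == 0:
            _accumulate(run, per_species, which, bin_counts, offsets,
                        contact_ion, protein_label)
        state = cl_step(state, system, cfg.dt, rng,
                        densities=(rho_ch_k, rho_tot_k))
    run.state = state
    if run.n_samples == 0:
        raise RuntimeError("no production samples accumulated")
    return run


def _accumulate(run: FTSRun, per_species, which, bin_counts, offsets,
                contact_ion, protein_label):
    system = run.system

    def smeared_total(label):
        dens = per_species[label]
        tot = np.zeros_like(dens[0])
        for d in dens:
            tot += d
        ax = (0, 1, 2)
        return _fft3(_fft3(tot, ax, True) * system.gamma_by_label[label],
                     ax, False)

    cache = {}

    def get(label):
        if label not in cache:
            cache[label] = smeared_total(label)
        return cache[label]

    for (m, n) in run.pair_samples:
        g = _cross_correlation(get(m), get(n), system.V)
        radial = np.bincount(which, weights=g.real.ravel(),
                             minlength=len(bin_counts)) \
            + 1j * np.bincount(which, weights=g.imag.ravel(),
                               minlength=len(bin_counts))
        run.pair_samples[(m, n)].append(radial[:len(bin_counts)] / bin_counts)
    if contact_ion is not None:
        dens_p = per_species[protein_label]
        ion = get(contact_ion)
        dv = system.config.spacing**3
        gk_p = system.gamma_by_label[protein_label]
        # sum the ion field over the contact offsets once, then integrate
        # each residue density against it
        ion_sum = np.zeros_like(ion)
        for off in offsets:
            ion_sum += np.roll(ion, off, axis=(0, 1, 2))
        ax = (0, 1, 2)
        prof = np.empty(len(dens_p), dtype=complex)
        for i, d_i in enumerate(dens_p):
            d_s = _fft3(_fft3(d_i, ax, True) * gk_p, ax, False)
            prof[i] = np.mean(d_s * ion_sum) * dv
        run.contact_samples[contact_ion].append(prof)
    # canonical bookkeeping: mean bead density per species
    for spec in system.species:
        tot = sum(d.mean() for d in per_species[spec.label])
        run.density_checks.setdefault(spec.label, []).append(tot)
    run.n_samples += 1


def estimate_correlations(run: FTSRun, pairs=None) -> dict:
    """Block-averaged CorrelationEstimate per requested pair."""
    if pairs is None:
        pairs = list(run.pair_samples)
    out = {}
    for pair in pairs:
        key = tuple(pair)
        samples = np.asarray(run.pair_samples[key])
        if len(samples) < 2:
            raise ValueError("insufficient production samples")
        mean_r, err_r = _block_stats(samples.real)
        mean_i, err_i = _block_stats(samples.imag)
        rho_m = run.system.species_by_label(key[0]).rho
        rho_n = run.system.species_by_label(key[1]).rho
        out[key] = CorrelationEstimate(
            r=run.r, mean=mean_r, stderr=err_r, imag_mean=mean_i,
            imag_stderr=err_i, rho_m0=rho_m, rho_n0=rho_n)
    return out


def residue_contact_profile(run: FTSRun, ion_label: str) -> dict:
    """Normalized per-residue integrated contact G_pq(i)/(rho_p,i0 rho_q0)."""
    samples = np.asarray(run.contact_samples[ion_label])
    if len(samples) < 2:
        raise ValueError("insufficient production samples")
    mean_r, err_r = _block_stats(samples.real)
    mean_i, err_i = _block_stats(samples.imag)
    prot = run.system.species_by_label("p")
    rho_i0 = prot.rho / prot.n_beads     # bulk density of each residue
    rho_q0 = run.system.species_by_label(ion_label).rho
    norm = rho_i0 * rho_q0
    return {"profile": mean_r / norm, "stderr": err_r / norm,
            "imag": mean_i / norm, "imag_stderr": err_i / norm}
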