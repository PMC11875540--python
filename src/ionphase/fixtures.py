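"""Built-in sequences and deterministic synthetic-input generators.

All generators are pure functions of their parameters and a seed, backed by
a counter-based RNG (Philox) so streams are identical across platforms.

The built-in ``caprin1_wt`` entry is a 103-residue model of the Caprin1
C-terminal IDR constructed to match every published compositional
constraint of the construct: 15 R, 1 K, 3 D (net charge +13), 7 Y,
exactly one L, six aliphatic (L/I/V/M) and ten hydrophobic/aromatic
(L/I/V/M/F/W) residues, with the positively charged residues concentrated
near the N-terminus and shortly before the C-terminus.  It is a model
stand-in, not the literal UniProt fragment.
"""

from __future__ import annotations

import numpy as np

from .cgmd import Configuration
from .seqcharge import ResidueSequence, make_variant

__all__ = [
    "builtin_sequence", "BUILTIN_SEQUENCE_NAMES",
    "rng", "planted_bridges_snapshot", "ideal_gas_snapshot",
    "two_plateau_slab", "synthetic_coexistence",
]

_CAPRIN1_MODEL = (
    "GSQGRPNRSYHRGFQRSVTRAGQRSMPNGYHSLQGFARGSQDGYPNRSHDGQVSRTADGY"
    "QSRPNMGWHKSQGAYGSRQGFPRNYSHRGIQRSTAGRQYSPNG"
)

#: 1-based arginine positions of the model sequence, N-terminal to C-terminal
CAPRIN1_R_POSITIONS = (5, 8, 12, 16, 20, 24, 38, 47, 55, 63, 78, 83, 88, 92, 97)
#: 1-based tyrosine positions (all seven are phosphosites in the pY model)
CAPRIN1_Y_POSITIONS = (10, 30, 44, 60, 75, 85, 99)

BUILTIN_SEQUENCE_NAMES = (
    "caprin1_wt", "py_caprin1",
    "15Rto15K", "4Rto4K_N", "4Rto4K_M", "4Rto4K_C",
)


def builtin_sequence(name: str) -> ResidueSequence:
    """Return a built-in fixture sequence by name."""
    wt = ResidueSequence(name="caprin1_wt", residues=_CAPRIN1_MODEL)
    if name == "caprin1_wt":
        return wt
    if name == "py_caprin1":
        return ResidueSequence(name="py_caprin1", residues=_CAPRIN1_MODEL,
                               ptm=CAPRIN1_Y_POSITIONS)
    if name == "15Rto15K":
        subs = [(p, "R", "K") for p in CAPRIN1_R_POSITIONS]
    elif name == "4Rto4K_N":
        subs = [(p, "R", "K") for p in CAPRIN1_R_POSITIONS[:4]]
    elif name == "4Rto4K_M":
        subs = [(p, "R", "K") for p in CAPRIN1_R_POSITIONS[6:10]]
    elif name == "4Rto4K_C":
        subs = [(p, "R", "K") for p in CAPRIN1_R_POSITIONS[-4:]]
    else:
        raise KeyError(f"unknown builtin sequence {name!r}; "
                       f"choose from {BUILTIN_SEQUENCE_NAMES}")
    return make_variant(wt, subs, name=name)


def rng(seed: int) -> np.random.Generator:
    """Counter-based RNG shared by all generators."""
    return np.random.Generator(np.random.Philox(seed))


# ---------------------------------------------------------------------------
# snapshot generators (shared Configuration type with the MD module)

def ideal_gas_snapshot(n: int, box, seed: int, species: str = "X") -> Configuration:
    """n uniformly random beads of one species in a periodic box."""
    if n <= 0:
        raise ValueError("n must be positive")
    box = np.asarray(box, dtype=float)
    pos = rng(seed).uniform(0.0, 1.0, size=(n, 3)) * box
    return Configuration(coords=pos, species=[species] * n,
                         chain_ids=[-1] * n, box=tuple(box))


def planted_bridges_snapshot(planted, box=None, cutoff: float = 11.0,
                             seed: int = 0) -> Configuration:
    """Snapshot containing exactly the planted Arg-Cl-Arg geometries.

    ``planted`` is a list of (R, d, kind) tuples: Arg-Arg distance R, the
    perpendicular offset d of the Cl from the Arg-Arg axis midpoint, and
    ``kind`` in {"true", "neutralizing", "intermediate"} used only for
    sanity checking feasibility against the geometric rule.  Units follow
    the caller (Angstrom by convention).  Groups are placed on a lattice
    with > 2*cutoff separation so no cross-group configurations arise; each
    pair of arginines goes on its own pair of chains.
    """
    planted = list(planted)
    spacing = 4.0 * cutoff + 30.0
    per_side = max(1, int(np.ceil(len(planted) ** (1.0 / 3.0))))
    if box is None:
        box = (spacing * (per_side + 1),) * 3
    box = tuple(float(b) for b in box)
    coords, species, chains = [], [], []
    chain_id = 0
    for idx, (big_r, d_off, _kind) in enumerate(planted):
        if big_r > 2.0 * cutoff:
            raise ValueError(f"planted R={big_r} exceeds 2*cutoff, infeasible")
        ix, iy, iz = (idx % per_side, (idx // per_side) % per_side,
                      idx // per_side**2)
        origin = np.array([ix + 0.5, iy + 0.5, iz + 0.5]) * spacing
        if origin[0] + big_r + cutoff > box[0]:
            raise ValueError("box too small for planted geometry")
        a1 = origin
        a2 = origin + np.array([big_r, 0.0, 0.0])
        cl = origin + np.array([big_r / 2.0, d_off, 0.0])
        for p, sp, ch in ((a1, "R", chain_id), (a2, "R", chain_id + 1),
                          (cl, "CL", -1)):
            coords.append(p)
            species.append(sp)
            chains.append(ch)
        chain_id += 2
    if not coords:
        coords = np.zeros((0, 3))
    return Configuration(coords=np.asarray(coords, dtype=float),
                         species=species, chain_ids=chains, box=box)


def two_plateau_slab(rho_dense: float, rho_dilute: float, box,
                     interface_width: float = 0.0, dense_fraction: float = 0.3,
                     seed: int = 0, species: str = "X") -> Configuration:
    """Two-density slab along z: a dense band in the middle of the box.

    Bead counts are deterministic (rounded from the planted densities); the
    interface is an optional linear ramp of width ``interface_width``.
    """
    if rho_dense <= rho_dilute:
        raise ValueError("need rho_dense > rho_dilute")
    box = np.asarray(box, dtype=float)
    lx, ly, lz = box
    g = rng(seed)
    z_lo = 0.5 * lz * (1.0 - dense_fraction)
    z_hi = 0.5 * lz * (1.0 + dense_fraction)

    def band(rho, za, zb):
        n = int(round(rho * lx * ly * (zb - za)))
        pos = np.empty((n, 3))
        pos[:, 0] = g.uniform(0, lx, n)
        pos[:, 1] = g.uniform(0, ly, n)
        pos[:, 2] = g.uniform(za, zb, n)
        return pos

    parts = [band(rho_dilute, 0.0, z_lo - interface_width / 2),
             band(rho_dense, z_lo + interface_width / 2,
                  z_hi - interface_width / 2),
             band(rho_dilute, z_hi + interface_width / 2, lz)]
    if interface_width > 0:
        for za, zb, rising in ((z_lo - interface_width / 2,
                                z_lo + interface_width / 2, True),
                               (z_hi - interface_width / 2,
                                z_hi + interface_width / 2, False)):
            mid = 0.5 * (rho_dense + rho_dilute)
            n = int(round(mid * lx * ly * (zb - za)))
            u = g.uniform(0, 1, n)
            z = za + (zb - za) * (np.sqrt(u) if rising else 1 - np.sqrt(1 - u))
            pos = np.column_stack([g.uniform(0, lx, n), g.uniform(0, ly, n), z])
            parts.append(pos)
    coords = np.vstack(parts)
    n_tot = len(coords)
    return Configuration(coords=coords, species=[species] * n_tot,
                         chain_ids=[-1] * n_tot, box=tuple(box))


def synthetic_coexistence(cs, params, salt_concs, T_grid, noise: float = 0.0,
                          seed: int = 0, sequence_label: str = "synthetic",
                          **solver_kwargs):
    """Coexistence dataset generated from the restricted binodal solver.

    Returns a :class:`ionphase.fhfit.CoexistenceDataset`; concentrations are
    in chains per b^3 with optional multiplicative lognormal noise.
    """
    from .coexist import binodal_fixed_salt
    from .fhfit import CoexistenceDataset

    g = rng(seed)
    rows = []
    for salt in salt_concs:
        points = binodal_fixed_salt(cs, params, salt, T_grid, **solver_kwargs)
        for pt in points:
            for phase, rho in (("dilute", pt.rho_p_dilute),
                               ("dense", pt.rho_p_dense)):
                fac = float(np.exp(g.normal(0.0, noise))) if noise > 0 else 1.0
                rows.append({"T": pt.T, "salt": salt, "phase": phase,
                             "rho_p": rho * fac, "sequence": sequence_label})
    if not rows:
        raise ValueError("no coexistence at the requested conditions")
    return CoexistenceDataset(rows=rows)
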