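"""Counterion-bridging analysis of coarse-grained snapshots.

A putative bridge is one anion within a cutoff of two positively charged
arginine beads on *different* chains.  With unit-magnitude charges the
energetic true/neutralizing distinction reduces to pure geometry: the
unfavorable (+/+) Coulomb term 1/R plus the favorable term -1/d_far is
negative exactly when d_far < R, evaluated against both edges of the 2 A
R-bin a configuration falls in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .cgmd import KB_KCAL, COULOMB_KCAL, Configuration
from .trajio import read_snapshots, write_snapshots  # re-exported

__all__ = [
    "BridgeConfiguration", "HeatMap", "read_snapshots", "write_snapshots",
    "rdf", "fraction_within", "enumerate_putative_bridges", "classify",
    "per_ion_statistics", "heatmap", "isolated_three_bead",
]

DEFAULT_CUTOFF = 11.0     # A; the rdf minimum reported for Arg+/Cl-
DEFAULT_BIN = 2.0         # A; R-bin width for classification


@dataclass(frozen=True)
class BridgeConfiguration:
    frame: int
    arg_a: int
    arg_b: int
    cl: int
    R: float          # Arg-Arg distance
    d_near: float
    d_far: float
    d: float          # distance of Cl from the Arg-Arg line
    x: float          # projection of Cl on the Arg-Arg axis (from arg_a)
    label: str | None = None


@dataclass
class HeatMap:
    x_edges: np.ndarray
    d_edges: np.ndarray
    P: np.ndarray            # P(x, d), symmetric in d by construction
    n_configs: float

    @property
    def P_over_absd(self) -> np.ndarray:
        dc = 0.5 * (self.d_edges[:-1] + self.d_edges[1:])
        out = np.zeros_like(self.P)
        nz = np.abs(dc) > 1e-12
        out[:, nz] = self.P[:, nz] / np.abs(dc[nz])
        return out

    def peak_cell(self) -> tuple[int, int]:
        return tuple(np.unravel_index(np.argmax(self.P_over_absd),
                                      self.P.shape))


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _select(cfg: Configuration, species) -> np.ndarray:
    if isinstance(species, str):
        species = (species,)
    sp = np.asarray(cfg.species)
    return np.nonzero(np.isin(sp, species))[0]


def rdf(snapshots, center_species, around_species, dr: float = 0.25,
        rmax: float = 30.0):
    """Radial number density rho(r) of ``around`` beads about ``center``
    beads, shell-volume normalized and averaged over frames and centers.

    Returns (bin centers, rho(r)); rho(r) tends to the bulk density of the
    ``around`` species at large r for a homogeneous system.
    """
    edges = np.arange(0.0, rmax + dr, dr)
    counts = np.zeros(len(edges) - 1)
    n_pairs_norm = 0
    for cfg in snapshots:
        box = np.asarray(cfg.box)
        ic = _select(cfg, center_species)
        ia = _select(cfg, around_species)
        if len(ic) == 0 or len(ia) == 0:
            raise ValueError("empty species selection")
        d = _min_image(cfg.coords[ia][None, :, :] - cfg.coords[ic][:, None, :],
                       box)
        r = np.linalg.norm(d, axis=-1).ravel()
        r = r[r > 1e-9]  # drop self pairs when species overlap
        counts += np.histogram(r, bins=edges)[0]
        n_pairs_norm += len(ic)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / (n_pairs_norm * shell)


def fraction_within(snapshots, cutoff: float = DEFAULT_CUTOFF,
                    center_species="R", ion_species="CL") -> float:
    """Fraction of (ion, frame) instances with >= 1 center within cutoff.

    Denominator is n_frames * n_ions, matching the per-frame per-ion
    counting convention.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    hits = 0
    total = 0
    for cfg in snapshots:
        box = np.asarray(cfg.box)
        ic = _select(cfg, center_species)
        ii = _select(cfg, ion_species)
        total += len(ii)
        if len(ic) == 0:
            continue
        d = _min_image(cfg.coords[ii][:, None, :] - cfg.coords[ic][None, :, :],
                       box)
        r = np.linalg.norm(d, axis=-1)
        hits += int(np.sum(np.any(r <= cutoff, axis=1)))
    if total == 0:
        raise ValueError("no ions in the selection")
    return hits / total


def enumerate_putative_bridges(snapshot: Configuration,
                               cutoff: float = DEFAULT_CUTOFF,
                               positive_species=("R",),
                               ion_species: str = "CL",
                               frame: int = 0) -> list[BridgeConfiguration]:
    """All interchain (Arg+, Cl-, Arg+) configurations for one snapshot.

    For an ion whose in-range positive beads fall on chains c with counts
    k_c the number of configurations is sum_{c<c'} k_c k_c'; pairs on the
    same chain never count.  Lysines are included by passing
    ``positive_species=("R", "K")``.
    """
    box = np.asarray(snapshot.box)
    ipos = _select(snapshot, positive_species)
    iion = _select(snapshot, ion_species)
    chains = np.asarray(snapshot.chain_ids)
    out = []
    if len(ipos) == 0 or len(iion) == 0:
        return out
    pos_xyz = snapshot.coords[ipos]
    for ion in iion:
        v = _min_image(pos_xyz - snapshot.coords[ion], box)
        r = np.linalg.norm(v, axis=1)
        sel = np.nonzero(r <= cutoff)[0]
        if len(sel) < 2:
            continue
        for ai in range(len(sel)):
            for bi in range(ai + 1, len(sel)):
                ja, jb = ipos[sel[ai]], ipos[sel[bi]]
                if chains[ja] == chains[jb]:
                    continue
                va, vb = -v[sel[ai]], -v[sel[bi]]   # ion -> arg vectors
                axis = _min_image(snapshot.coords[jb] - snapshot.coords[ja],
                                  box)
                big_r = float(np.linalg.norm(axis))
                ra, rb = float(r[sel[ai]]), float(r[sel[bi]])
                u = axis / big_r
                # Cl position relative to arg_a
                w = _min_image(snapshot.coords[ion] - snapshot.coords[ja], box)
                x = float(w @ u)
                d_perp = float(np.linalg.norm(w - x * u))
                out.append(BridgeConfiguration(
                    frame=frame, arg_a=int(ja), arg_b=int(jb), cl=int(ion),
                    R=big_r, d_near=min(ra, rb), d_far=max(ra, rb),
                    d=d_perp, x=x))
    return out


def classify(configs, bin_width: float = DEFAULT_BIN):
    """Label configurations true/neutralizing/intermediate by R-bin.

    With unit charges the Coulomb criterion holds for every R in the bin
    exactly when d_far < bin lower edge (true) or d_far >= bin upper edge
    (neutralizing); anything else is intermediate.
    """
    labeled = []
    counts = {"true": 0, "neutralizing": 0, "intermediate": 0}
    for c in configs:
        lo = math.floor(c.R / bin_width) * bin_width
        hi = lo + bin_width
        if c.d_far < lo:
            lab = "true"
        elif c.d_far >= hi:
            lab = "neutralizing"
        else:
            lab = "intermediate"
        counts[lab] += 1
        labeled.append(replace(c, label=lab))
    return labeled, counts


def p_at_least_one_true(p_true: float, n: int) -> float:
    """1 - (1 - p_true)^n under the independence approximation."""
    if not 0.0 <= p_true <= 1.0:
        raise ValueError("p_true must be a probability")
    return 1.0 - (1.0 - p_true) ** n


def per_ion_statistics(labeled_configs, n_frames: int, n_ions: int) -> dict:
    """Per-ion bridging statistics with the (frames x ions) denominator."""
    if not labeled_configs:
        return {"fraction_bridging": 0.0, "mean_configs_per_bridging_ion": None,
                "p_true": None, "p_at_least_one_true": None}
    ions = {(c.frame, c.cl) for c in labeled_configs}
    n_conf = len(labeled_configs)
    n_true = sum(1 for c in labeled_configs if c.label == "true")
    nbar = n_conf / len(ions)
    p_true = n_true / n_conf
    return {
        "fraction_bridging": len(ions) / (n_frames * n_ions),
        "mean_configs_per_bridging_ion": nbar,
        "p_true": p_true,
        "p_at_least_one_true": p_at_least_one_true(p_true, int(nbar)),
    }


def heatmap(configs, cell: float = 0.5, x_max: float = 25.0,
            d_max: float = 12.0) -> HeatMap:
    """Accumulate P(x, d) over configurations.

    Each configuration deposits half its mass at +/-d (the distribution is
    symmetric in d by construction) and is symmetrized between the two
    equivalent arginine endpoints (x and R - x), so total mass equals the
    number of configurations.
    """
    x_edges = np.arange(-cell * math.ceil(5.0 / cell), x_max + cell, cell)
    d_edges = np.arange(-d_max, d_max + cell, cell)
    grid = np.zeros((len(x_edges) - 1, len(d_edges) - 1))
    pts_x, pts_d, wts = [], [], []
    for c in configs:
        for xx, ww in ((c.x, 0.5), (c.R - c.x, 0.5)):
            for dd in (c.d, -c.d):
                pts_x.append(xx)
                pts_d.append(dd)
                wts.append(0.5 * ww)
    if pts_x:
        grid += np.histogram2d(pts_x, pts_d, bins=(x_edges, d_edges),
                               weights=wts)[0]
    return HeatMap(x_edges=x_edges, d_edges=d_edges, P=grid,
                   n_configs=float(len(configs)))


def isolated_three_bead(R: float, T: float, epsilon_r: float = 80.0,
                        sigma: float = 5.48, eps_rep: float = 0.2,
                        cutoff: float = DEFAULT_CUTOFF, cell: float = 0.5,
                        x_max: float = 25.0, d_max: float = 12.0,
                        oversample: int = 8) -> HeatMap:
    """Boltzmann-averaged Cl- distribution around two fixed Arg+ beads.

    The potential is the Coulomb interaction of the Cl- with both Arg+
    (unit charges, relative permittivity ``epsilon_r``) plus a purely
    repulsive (WCA-type) short-range wall of diameter ``sigma``; the domain
    mirrors the MD putative-bridge condition d_far <= cutoff.  P(x, d) is
    the density integrated over the azimuthal circle of radius |d| (hence
    the 2 pi |d| weight), normalized to unit total mass.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    x_edges = np.arange(-cell * math.ceil(5.0 / cell), x_max + cell, cell)
    d_edges = np.arange(-d_max, d_max + cell, cell)
    sub = oversample
    xs = x_edges[0] + (np.arange((len(x_edges) - 1) * sub) + 0.5) * cell / sub
    ds = (np.arange(int(d_max / cell * sub)) + 0.5) * cell / sub
    X, D = np.meshgrid(xs, ds, indexing="ij")
    r1 = np.sqrt(X**2 + D**2)
    r2 = np.sqrt((X - R) ** 2 + D**2)
    beta = 1.0 / (KB_KCAL * T)
    coul = COULOMB_KCAL / epsilon_r * (-1.0 / np.maximum(r1, 1e-6)
                                       - 1.0 / np.maximum(r2, 1e-6))

    def wca(r):
        x6 = (sigma / np.maximum(r, 1e-6)) ** 6
        u = 4.0 * eps_rep * (x6 * x6 - x6) + eps_rep
        return np.where(r < 2 ** (1 / 6) * sigma, u, 0.0)

    u_tot = coul + wca(r1) + wca(r2)
    w = np.exp(-beta * (u_tot - u_tot.min())) * 2.0 * np.pi * D
    w[np.maximum(r1, r2) > cutoff] = 0.0
    # fold oversampled cells into the output grid, mirroring in d
    wx = w.reshape(len(x_edges) - 1, sub, -1).sum(axis=1)
    wxd = wx.reshape(wx.shape[0], -1, sub).sum(axis=2)
    nd_half = wxd.shape[1]
    grid = np.zeros((len(x_edges) - 1, len(d_edges) - 1))
    mid = (len(d_edges) - 1) // 2
    grid[:, mid:mid + nd_half] = 0.5 * wxd
    grid[:, mid - nd_half:mid] = 0.5 * wxd[:, ::-1]
    total = grid.sum()
    if total <= 0:
        raise ValueError("empty accessible domain (quadrature failure)")
    return HeatMap(x_edges=x_edges, d_edges=d_edges, P=grid / total,
                   n_configs=1.0)
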