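"""Residue sequences, per-residue charges, and solution electroneutrality.

The charge sequence ``sigma`` (one integer per residue) is the common
currency of the analytical theory, the field simulator, and the MD energy
model.  Charge assignment follows the neutral-pH convention: R, K -> +1;
D, E -> -1; phosphotyrosine -> -2; everything else (including H at pH 7.4
and the chain termini of an internal IDR fragment) -> 0.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np

from .constants import PHOSPHO_MASS, RESIDUE_MASS, WATER_MASS

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: default phosphotyrosine charge at pH 7.4 (the experimental value is ~ -2)
PY_CHARGE = -2


@dataclass(frozen=True)
class ResidueSequence:
    """An amino-acid sequence with optional phosphotyrosine marks.

    ``ptm`` holds 1-based positions of phosphorylated tyrosines.
    """

    name: str
    residues: str
    ptm: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("empty sequence")
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValueError(f"invalid residue code(s): {sorted(bad)}")
        for p in self.ptm:
            if not (1 <= p <= len(self.residues)):
                raise ValueError(f"PTM position {p} out of range 1..{len(self.residues)}")
            if self.residues[p - 1] != "Y":
                raise ValueError(f"PTM position {p} is {self.residues[p-1]}, not Y")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def molar_mass(self) -> float:
        """Chain molar mass in Da (residue masses + one water + phosphates)."""
        m = sum(RESIDUE_MASS[a] for a in self.residues) + WATER_MASS
        return m + PHOSPHO_MASS * len(self.ptm)


@dataclass(frozen=True)
class ChargeSequence:
    sigma: tuple[int, ...]

    def __post_init__(self):
        bad = set(self.sigma) - {0, 1, -1, -2}
        if bad:
            raise ValueError(f"invalid charges {sorted(bad)}")

    @property
    def N(self) -> int:
        return len(self.sigma)

    @property
    def Q(self) -> int:
        return int(sum(self.sigma))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.sigma, dtype=float)


@dataclass(frozen=True)
class IonSpecies:
    """A small-ion species: monoatomic (one bead) or a short bead chain."""

    label: str
    bead_charges: tuple[int, ...]
    role: str = "counterion"  # "counterion" | "salt"

    @property
    def valency(self) -> int:
        return int(sum(self.bead_charges))


def parse_sequence(text: str, ptm: list[int] | None = None, name: str | None = None) -> ResidueSequence:
    """Parse a raw one-letter string or single/multi-record FASTA.

    Lower-case ``y`` marks an inline phosphotyrosine; any other case
    difference is normalized away.  ``ptm`` gives additional 1-based pY
    positions (side-channel convention).  For multi-record FASTA the first
    record is used unless ``name`` selects one by header word.
    """

    text = text.strip()
    if not text:
        raise ValueError("empty input")
    label = name or "seq"
    if text.startswith(">"):
        records: dict[str, str] = {}
        order: list[str] = []
        cur = None
        for line in io.StringIO(text):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                cur = line[1:].split()[0] if len(line) > 1 else f"rec{len(order)}"
                records[cur] = ""
                order.append(cur)
            else:
                if cur is None:
                    raise ValueError("sequence data before FASTA header")
                records[cur] += line
        if not order:
            raise ValueError("no FASTA records")
        key = name if (name is not None and name in records) else order[0]
        raw, label = records[key], key
    else:
        raw = re.sub(r"\s+", "", text)

    inline_py = [i + 1 for i, a in enumerate(raw) if a == "y"]
    residues = raw.upper()
    positions = sorted(set(inline_py) | set(ptm or [])) if (inline_py or ptm) else []
    return ResidueSequence(name=label, residues=residues, ptm=tuple(positions))


def charge_sequence(seq: ResidueSequence, py_charge: int = PY_CHARGE) -> ChargeSequence:
    """Map residues to integer charges at pH 7.4."""
    ptm = set(seq.ptm)
    sig = []
    for i, a in enumerate(seq.residues, start=1):
        if i in ptm:
            sig.append(py_charge)
        elif a in "RK":
            sig.append(1)
        elif a in "DE":
            sig.append(-1)
        else:
            sig.append(0)
    return ChargeSequence(sigma=tuple(sig))


def sequence_metrics(cs: ChargeSequence) -> dict:
    """Q, NCPR = Q/N and FCR = fraction of charged residues."""
    n_charged = sum(1 for s in cs.sigma if s != 0)
    return {"Q": cs.Q, "NCPR": cs.Q / cs.N, "FCR": n_charged / cs.N}


def neutralize(Q: float, rho_p: float, zs: int, zc: int, rho_s: float) -> float:
    """Counterion concentration enforcing |Q| rho_p + zs rho_s = zc rho_c.

    Works identically for concentrations and for discrete counts; in count
    mode a non-integer result signals an inconsistent discrete system.
    """
    if zs < 1 or zc < 1:
        raise ValueError("valencies must be >= 1")
    if rho_p < 0 or rho_s < 0:
        raise ValueError("concentrations must be >= 0")
    return (abs(Q) * rho_p + zs * rho_s) / zc


def electroneutrality_residual(Q: float, rho_p: float, rho_c: float,
                               rho_s: float, zs: int, zc: int) -> float:
    return abs(Q) * rho_p + zs * rho_s - zc * rho_c


def make_variant(seq: ResidueSequence, substitutions: list[tuple],
                 name: str | None = None) -> ResidueSequence:
    """Apply point substitutions.

    Each substitution is ``(pos, new)`` or ``(pos, old, new)`` with 1-based
    ``pos``; the three-element form verifies the original residue first.
    """
    res = list(seq.residues)
    for sub in substitutions:
        if len(sub) == 3:
            pos, old, new = sub
        else:
            pos, new = sub
            old = None
        if not (1 <= pos <= len(res)):
            raise ValueError(f"substitution position {pos} out of range")
        if old is not None and res[pos - 1] != old.upper():
            raise ValueError(
                f"position {pos} holds {res[pos-1]}, expected {old.upper()}")
        res[pos - 1] = new.upper()
    return ResidueSequence(name=name or f"{seq.name}_variant",
                           residues="".join(res), ptm=seq.ptm)
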