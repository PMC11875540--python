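"""Fitting (epsilon_r, eps_h, eps_s) to coexistence data by repeated
restricted-binodal solves.

Residuals are log-ratios of predicted to observed concentrations so that
the objective is invariant under concentration-unit changes; dilute and
dense arms are weighted equally.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from . import constants
from .coexist import binodal_fixed_salt
from .rgrpa import EnergyParams
from .seqcharge import ChargeSequence, ResidueSequence

__all__ = ["CoexistenceDataset", "load_coexistence", "save_coexistence",
           "fit_parameters"]

_PHASES = ("dilute", "dense")

#: supported concentration units -> conversion to chains per b^3
#: (uM and mg/ml need the sequence molar mass)
CONC_UNITS = ("b-3", "uM", "mM", "M", "mg/ml")


@dataclass
class CoexistenceDataset:
    """Rows of {T [K], salt [b^-3 salt ions], phase, rho_p [b^-3], sequence}."""

    rows: list[dict] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for i, r in enumerate(self.rows):
            if r["phase"] not in _PHASES:
                raise ValueError(f"row {i}: phase must be dilute|dense")
            key = (round(r["T"], 9), round(r["salt"], 12), r["phase"],
                   r.get("sequence", ""))
            if key in seen:
                raise ValueError(f"row {i}: duplicate {r['phase']} record "
                                 f"at T={r['T']}, salt={r['salt']}")
            seen.add(key)

    def conditions(self):
        """Sorted unique (salt, T) pairs."""
        return sorted({(r["salt"], r["T"]) for r in self.rows})

    def n_temperatures(self) -> int:
        return len({r["T"] for r in self.rows})


def _conc_to_b3(value: float, unit: str, seq: ResidueSequence | None) -> float:
    if unit == "b-3":
        return value
    if unit in ("uM", "mM", "M"):
        molar = value * {"uM": 1e-6, "mM": 1e-3, "M": 1.0}[unit]
        return constants.molar_to_per_b3(molar)
    if unit == "mg/ml":
        if seq is None:
            raise ValueError("mg/ml conversion needs the sequence")
        molar = value / seq.molar_mass / 1e3 * 1e3  # mg/ml -> g/L -> mol/L
        return constants.molar_to_per_b3(molar)
    raise ValueError(f"unknown concentration unit {unit!r}")


def load_coexistence(path_or_text, sequence: ResidueSequence | None = None
                     ) -> CoexistenceDataset:
    """Read a TSV with header: T, T_unit, salt, salt_unit, phase, conc,
    conc_unit, sequence.  Temperatures in C are converted to K, all
    concentrations to b^-3."""
    if hasattr(path_or_text, "read"):
        fh = path_or_text
    elif isinstance(path_or_text, str) and "\t" in path_or_text:
        fh = io.StringIO(path_or_text)
    else:
        fh = open(path_or_text)
    try:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "T" not in reader.fieldnames:
            raise ValueError("missing header row with a 'T' column")
        rows = []
        for ln, rec in enumerate(reader, start=2):
            try:
                t = float(rec["T"])
                if rec.get("T_unit", "K").upper().startswith("C"):
                    t += 273.15
                salt = _conc_to_b3(float(rec["salt"]),
                                   rec.get("salt_unit", "b-3"), sequence)
                conc = _conc_to_b3(float(rec["conc"]),
                                   rec.get("conc_unit", "b-3"), sequence)
                rows.append({"T": t, "salt": salt, "phase": rec["phase"],
                             "rho_p": conc,
                             "sequence": rec.get("sequence", "")})
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"malformed row at line {ln}: {exc}") from exc
    finally:
        if fh is not path_or_text:
            fh.close()
    return CoexistenceDataset(rows=rows)


def save_coexistence(dataset: CoexistenceDataset, path) -> None:
    """Write internal-unit TSV (round-trips through load_coexistence)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["T", "T_unit", "salt", "salt_unit", "phase", "conc",
                    "conc_unit", "sequence"])
        for r in dataset.rows:
            w.writerow([repr(r["T"]), "K", repr(r["salt"]), "b-3", r["phase"],
                        repr(r["rho_p"]), "b-3", r.get("sequence", "")])


# ---------------------------------------------------------------------------

def _predict(cs: ChargeSequence, params: EnergyParams, dataset,
             cache: dict, solver: dict) -> dict:
    """Predicted (dilute, dense) rho_p per (salt, T) condition."""
    out = {}
    for salt, T in dataset.conditions():
        key = (round(params.epsilon_r, 10), round(params.eps_h, 10),
               round(params.eps_s, 10), params.zs, params.zc, salt, T)
        if key not in cache:
            pts = binodal_fixed_salt(cs, params, salt, [T], **solver)
            cache[key] = (pts[0].rho_p_dilute, pts[0].rho_p_dense) if pts \
                else None
        out[(salt, T)] = cache[key]
    return out


def fit_parameters(datasets, share_epsilon_r: bool = True,
                   x0: dict | None = None,
                   bounds: dict | None = None,
                   solver: dict | None = None,
                   method: str = "trf",
                   maxiter: int = 200, xatol: float = 1e-3):
    """Least-squares fit of (epsilon_r, eps_h, eps_s) to coexistence data.

    ``datasets`` is a list of (label, CoexistenceDataset, ChargeSequence,
    EnergyParams-template); epsilon_r is shared across datasets when
    ``share_epsilon_r`` (each keeps its own eps_h, eps_s).  The default
    optimizer is bounded trust-region least squares on the log-residual
    vector (finite-difference Jacobian with steps well above the binodal
    solver's noise floor); ``method="nm"`` selects derivative-free
    Nelder-Mead instead.  Binodal solves are cached by parameter hash.
    """
    if solver is None:
        solver = {"n_grid": 60, "fast": True}
    bounds = bounds or {"epsilon_r": (20.0, 120.0), "eps_h": (0.0, 5.0),
                        "eps_s": (-5.0, 5.0)}
    for label, ds, _, _ in datasets:
        if ds.n_temperatures() < 2:
            raise ValueError(f"dataset {label}: need >= 2 temperatures")
    x0 = x0 or {}
    p0 = [x0.get("epsilon_r", 80.0)]
    lo_b = [bounds["epsilon_r"][0]]
    hi_b = [bounds["epsilon_r"][1]]
    for label, _, _, _ in datasets:
        p0 += [x0.get(f"eps_h:{label}", 1.0), x0.get(f"eps_s:{label}", 0.0)]
        lo_b += [bounds["eps_h"][0], bounds["eps_s"][0]]
        hi_b += [bounds["eps_h"][1], bounds["eps_s"][1]]
    if not share_epsilon_r:
        raise NotImplementedError("per-dataset epsilon_r is not supported")

    cache: dict = {}
    trace: list[float] = []

    def residual_vector(p):
        out = []
        for k, (label, ds, cs, tmpl) in enumerate(datasets):
            eh, es = p[1 + 2 * k], p[2 + 2 * k]
            params = replace(tmpl, epsilon_r=float(p[0]), eps_h=float(eh),
                             eps_s=float(es))
            pred = _predict(cs, params, ds, cache, solver)
            for r in ds.rows:
                pq = pred[(r["salt"], r["T"])]
                if pq is None:
                    out.append(5.0)  # no predicted coexistence here
                    continue
                model = pq[0] if r["phase"] == "dilute" else pq[1]
                out.append(math.log(model / r["rho_p"]))
        trace.append(float(np.dot(out, out)))
        return np.asarray(out)

    if method == "trf":
        from scipy.optimize import least_squares
        fit = least_squares(residual_vector, p0, bounds=(lo_b, hi_b),
                            diff_step=5e-3, xtol=1e-10, ftol=1e-12,
                            max_nfev=maxiter)
        res_x, res_fun = fit.x, 2.0 * fit.cost
        success = bool(fit.success)
    elif method == "nm":
        def objective(p):
            pen = sum(max(0.0, l - v) + max(0.0, v - h)
                      for v, l, h in zip(p, lo_b, hi_b))
            if pen > 0:
                trace.append(1e4 * pen)
                return 1e4 * pen
            r = residual_vector(p)
            return float(r @ r)

        res = minimize(objective, p0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": xatol,
                                "fatol": 1e-12, "adaptive": True})
        res_x, res_fun, success = res.x, float(res.fun), bool(res.success)
    else:
        raise ValueError(f"unknown method {method!r}")
    fitted = {"epsilon_r": float(res_x[0])}
    for k, (label, _, _, _) in enumerate(datasets):
        fitted[f"eps_h:{label}"] = float(res_x[1 + 2 * k])
        fitted[f"eps_s:{label}"] = float(res_x[2 + 2 * k])
    residuals = []
    for k, (label, ds, cs, tmpl) in enumerate(datasets):
        params = replace(tmpl, epsilon_r=float(res_x[0]),
                         eps_h=float(res_x[1 + 2 * k]),
                         eps_s=float(res_x[2 + 2 * k]))
        pred = _predict(cs, params, ds, cache, solver)
        for r in ds.rows:
            pq = pred[(r["salt"], r["T"])]
            model = (None if pq is None
                     else (pq[0] if r["phase"] == "dilute" else pq[1]))
            residuals.append({
                "dataset": label, "T": r["T"], "salt": r["salt"],
                "phase": r["phase"], "observed": r["rho_p"],
                "predicted": model,
                "log_residual": (math.log(model / r["rho_p"])
                                 if model else None)})
    return {"params": fitted, "objective": float(res_fun),
            "n_evals": len(trace), "trace": trace, "residuals": residuals,
            "converged": success}
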