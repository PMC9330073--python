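"""One-site isothermal-titration-calorimetry model: simulation and fitting.

A titration injects ligand (syringe species) stepwise into a cell holding
the macromolecule; each injection releases heat proportional to the newly
formed complex.  Under the standard constant-volume perfusion convention,
injection volume v displaces cell content, so after injection i the total
concentrations are

    Mt_i = M0 * d**i,      Lt_i = Ls * (1 - d**i),      d = 1 - v/V0

and the bound concentration follows the one-site mass-action quadratic

    [ML] = ((n*Mt + Lt + Kd) - sqrt((n*Mt + Lt + Kd)**2 - 4*n*Mt*Lt)) / 2.

Per-injection heat (microcal): dH * V0 * ([ML]_i - [ML]_{i-1} * d) plus a
constant dilution offset.  Normalized heats divide by moles injected and
are reported in kcal/mol of injectant — the instrument axis convention.

Fit quality is governed by the Wiseman c-value, c = n * M0 / Kd; the
sigmoid is sharp for c >> 10 and shallow for c near 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "TitrationProtocol",
    "BindingModelParams",
    "Thermogram",
    "FitResult",
    "bound_concentration",
    "simulate_titration",
    "fit_one_site",
    "affinity_regime_check",
    "read_thermogram_tsv",
    "write_thermogram_tsv",
]


@dataclass(frozen=True)
class TitrationProtocol:
    """Injection schedule and concentrations (SI units: M, L, K).

    ``cell_conc`` is the binding-competent macromolecule booked per nominal
    monomer; the roles are agnostic to which protein sits where — only
    "injectant" vs "cell species" matter.
    """

    cell_conc: float
    syringe_conc: float
    cell_volume: float = 200e-6
    injection_volume: float = 3e-6
    n_injections: int = 13
    temperature: float = 298.15

    def __post_init__(self) -> None:
        for name in ("cell_conc", "syringe_conc", "cell_volume", "injection_volume",
                     "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_injections < 1:
            raise ValueError("n_injections must be >= 1")
        if self.injection_volume > 0.1 * self.cell_volume:
            raise ValueError("injection volume must be small relative to the cell volume")

    def totals(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(Mt_i, Lt_i, molar_ratio_i) after injections i = 1..n."""
        i = np.arange(1, self.n_injections + 1)
        d = 1.0 - self.injection_volume / self.cell_volume
        mt = self.cell_conc * d ** i
        lt = self.syringe_conc * (1.0 - d ** i)
        return mt, lt, lt / mt


@dataclass(frozen=True)
class BindingModelParams:
    """One-site model: Kd (M), stoichiometry N, dH (cal/mol injectant), offset."""

    kd: float
    n_sites: float = 1.0
    dh: float = -10000.0
    q_dilution: float = 0.0  # microcal per injection

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")


@dataclass
class Thermogram:
    injections: np.ndarray  # 1-based injection index
    molar_ratio: np.ndarray  # injectant total / cell-species total
    heat_ucal: np.ndarray
    ndh_kcal_per_mol: np.ndarray

    def __post_init__(self) -> None:
        self.injections = np.asarray(self.injections, dtype=int)
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        self.heat_ucal = np.asarray(self.heat_ucal, dtype=float)
        self.ndh_kcal_per_mol = np.asarray(self.ndh_kcal_per_mol, dtype=float)
        if np.any(np.diff(self.molar_ratio) <= 0):
            raise ValueError("molar ratio must be strictly increasing")
        if not (np.all(np.isfinite(self.heat_ucal)) and np.all(np.isfinite(self.ndh_kcal_per_mol))):
            raise ValueError("heats must be finite")


@dataclass
class FitResult:
    params: BindingModelParams
    stderr: dict[str, float]
    residuals: np.ndarray
    c_value: float
    n_evaluations: int = 0
    message: str = ""


def bound_concentration(mt: float, lt: float, kd: float, n: float = 1.0) -> float:
    """Bound complex concentration [ML] from the one-site quadratic.

    Satisfies 0 <= [ML] <= min(n*mt, lt); exact closed form of mass action
    with n identical independent sites per macromolecule.
    """
    if mt < 0 or lt < 0 or kd < 0 or n < 0:
        raise ValueError("concentrations, kd and n must be nonnegative")
    if mt == 0 or lt == 0:
        return 0.0
    b = n * mt + lt + kd
    disc = b * b - 4.0 * n * mt * lt
    # stable smaller root: 2ac/(b + sqrt(disc)) avoids cancellation when [ML] << b
    ml = 2.0 * n * mt * lt / (b + math.sqrt(max(disc, 0.0)))
    return float(min(max(ml, 0.0), min(n * mt, lt)))


def _heats_ucal(protocol: TitrationProtocol, params: BindingModelParams) -> np.ndarray:
    mt, lt, _ = protocol.totals()
    d = 1.0 - protocol.injection_volume / protocol.cell_volume
    ml = np.array([bound_concentration(m, l, params.kd, params.n_sites)
                   for m, l in zip(mt, lt)])
    prev = np.concatenate([[0.0], ml[:-1]])
    # cal/mol * L * M = cal; report microcal
    return params.dh * protocol.cell_volume * (ml - prev * d) * 1e6 + params.q_dilution


def simulate_titration(protocol: TitrationProtocol, params: BindingModelParams,
                       noise_sd: float = 0.0, seed: Optional[int] = None) -> Thermogram:
    """Simulate per-injection heats; ``noise_sd`` is iid Gaussian in microcal."""
    heats = _heats_ucal(protocol, params)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    _, _, ratio = protocol.totals()
    moles_per_injection = protocol.syringe_conc * protocol.injection_volume
    ndh = heats * 1e-6 / moles_per_injection / 1000.0  # microcal -> kcal/mol
    return Thermogram(np.arange(1, protocol.n_injections + 1), ratio, heats, ndh)


def fit_one_site(thermogram: Thermogram, protocol: TitrationProtocol,
                 init: Optional[BindingModelParams] = None,
                 weights: Optional[np.ndarray] = None,
                 discard_first: bool = False) -> FitResult:
    """Weighted least-squares fit of (Kd, N, dH, offset) to normalized heats.

    Deterministic given data and initialization.  Default initialization:
    N = 1, dH from the first-injection normalized heat, Kd = the cell-species
    total concentration at the half-saturation molar ratio.  Kd is optimized
    on a log10 scale to enforce positivity.  A Wiseman c outside [1, 1000]
    triggers a warning (shape barely constrains Kd there).
    """
    y = thermogram.ndh_kcal_per_mol.copy()
    idx = np.arange(len(y))
    if discard_first:
        idx = idx[1:]
    if len(idx) < 6:
        raise ValueError("need >= 6 injections to fit")
    if float(np.std(y[idx])) < 1e-12:
        raise ValueError("degenerate (flat) thermogram; one-site fit is unidentifiable")
    w = np.ones(len(idx)) if weights is None else np.asarray(weights, dtype=float)[idx]
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    sw = np.sqrt(w)

    mt, _, ratio = protocol.totals()
    moles_per_injection = protocol.syringe_conc * protocol.injection_volume

    if init is None:
        h0 = y[idx][0]
        half = np.argmin(np.abs(y[idx] - h0 / 2.0))
        kd0 = max(float(mt[idx][half]), 1e-9)
        init = BindingModelParams(kd=kd0, n_sites=1.0, dh=h0 * 1000.0, q_dilution=0.0)

    def model_ndh(x: np.ndarray) -> np.ndarray:
        p = BindingModelParams(kd=10.0 ** x[0], n_sites=x[1], dh=x[2] * 1000.0,
                               q_dilution=x[3])
        heats = _heats_ucal(protocol, p)
        return heats * 1e-6 / moles_per_injection / 1000.0

    def residual(x: np.ndarray) -> np.ndarray:
        return sw * (model_ndh(x)[idx] - y[idx])

    x0 = np.array([math.log10(init.kd), init.n_sites, init.dh / 1000.0, init.q_dilution])
    lb = [-12.0, 1e-3, -np.inf, -np.inf]
    ub = [0.0, 100.0, np.inf, np.inf]
    res = least_squares(residual, x0, bounds=(lb, ub), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000)
    if res.status <= 0:
        raise RuntimeError(
            f"one-site fit did not converge ({res.message}); "
            f"best-so-far kd={10 ** res.x[0]:.3e} M, n={res.x[1]:.3f}"
        )
    kd = 10.0 ** res.x[0]
    params = BindingModelParams(kd=kd, n_sites=float(res.x[1]), dh=float(res.x[2]) * 1000.0,
                                q_dilution=float(res.x[3]))

    # standard errors from the Jacobian at the solution
    m, p = len(idx), 4
    stderr = {k: float("nan") for k in ("kd", "n_sites", "dh", "q_dilution")}
    if m > p:
        try:
            JTJ = res.jac.T @ res.jac
            cov = np.linalg.inv(JTJ) * (2.0 * res.cost / (m - p))
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            stderr = {
                "kd": float(kd * math.log(10.0) * se[0]),
                "n_sites": float(se[1]),
                "dh": float(se[2] * 1000.0),
                "q_dilution": float(se[3]),
            }
        except np.linalg.LinAlgError:
            pass

    c = params.n_sites * protocol.cell_conc / params.kd
    if not 1.0 <= c <= 1000.0:
        warnings.warn(f"Wiseman c = {c:.2f} outside [1, 1000]; "
                      "fitted Kd is weakly constrained by the curve shape", stacklevel=2)
    residuals = model_ndh(res.x)[idx] - y[idx]
    return FitResult(params, stderr, residuals, float(c), int(res.nfev), res.message)


def bound_concentration_numeric(mt: float, lt: float, kd: float, n: float = 1.0) -> float:
    """Mass-action root-finder solution (independent cross-check of the quadratic)."""
    if mt == 0 or lt == 0:
        return 0.0

    def f(ml: float) -> float:
        return (n * mt - ml) * (lt - ml) - kd * ml

    hi = min(n * mt, lt)
    return float(brentq(f, 0.0, hi, xtol=1e-18, rtol=1e-15))


def affinity_regime_check(params: BindingModelParams) -> str:
    """Advisory regime for complex-prediction reliability.

    Weak associations (Kd > 20 uM) are hard to predict reliably; strong
    (Kd < 1 uM) are the comfortable regime.  The 20 uM boundary is closed
    on the moderate side.
    """
    kd_um = params.kd * 1e6
    if kd_um > 20.0:
        return "weak"
    if kd_um < 1.0:
        return "strong"
    return "moderate"


def write_thermogram_tsv(thermogram: Thermogram, path) -> None:
    df = pd.DataFrame({
        "injection": thermogram.injections,
        "molar_ratio": thermogram.molar_ratio,
        "heat_ucal": thermogram.heat_ucal,
        "ndh_kcal_per_mol": thermogram.ndh_kcal_per_mol,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_thermogram_tsv(path) -> Thermogram:
    df = pd.read_csv(path, sep="\t")
    required = {"injection", "molar_ratio", "heat_ucal", "ndh_kcal_per_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing thermogram columns {sorted(missing)}")
    return Thermogram(df["injection"].to_numpy(), df["molar_ratio"].to_numpy(),
                      df["heat_ucal"].to_numpy(), df["ndh_kcal_per_mol"].to_numpy())
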