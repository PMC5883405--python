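"""Allometric-Arrhenius model of standard metabolic rate.

The metabolic-theory model is

    ln SMR = ln B0 + b * ln M - E * (1/kT)

with B0 a normalization constant, b the allometric (mass) exponent, E the
activation energy in eV, k Boltzmann's constant in eV/K and T the absolute
temperature.  Fitting the two-predictor linear model on natural-log SMR
yields (lnB0, b, E); the two corrected rates are

    tSMR = ln SMR + E * (1/kT)   (temperature removed; = lnB0 + b lnM + resid)
    mSMR = ln SMR - b * ln M     (mass removed;        = lnB0 - E/kT  + resid)

b and E may instead be fixed at supplied values (e.g. the canonical 0.75 and
0.65 eV) for sensitivity analysis; the remaining coefficients are then
estimated by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trait_data import TraitTable

#: Boltzmann's constant, eV per kelvin
BOLTZMANN_EV_PER_K = 8.617333e-5

#: 0 degC in kelvin
KELVIN_OFFSET = 273.15


class MTEError(ValueError):
    pass


def inv_kT(temperature_C) -> np.ndarray | float:
    """1/(k*T) in 1/eV for temperature in degC.  Errors at/below absolute zero."""
    t = np.asarray(temperature_C, dtype=float)
    if np.any(t <= -KELVIN_OFFSET):
        raise MTEError("temperature at or below absolute zero")
    out = 1.0 / (BOLTZMANN_EV_PER_K * (t + KELVIN_OFFSET))
    return float(out) if np.isscalar(temperature_C) else out


@dataclass(frozen=True)
class MTEFit:
    """Estimated (or partly fixed) parameters of the allometric-Arrhenius model.

    ``E`` uses the sign convention that E > 0 means rates increase with
    temperature.  Standard errors are 0 for fixed parameters.
    """

    lnB0: float
    b: float
    E: float
    se_lnB0: float
    se_b: float
    se_E: float
    n: int
    r2: float
    b_fixed: bool = False
    E_fixed: bool = False


@dataclass(frozen=True)
class CorrectedRates:
    """Per-species log rates and corrections, aligned with the input table."""

    species: list[str]
    ln_smr: np.ndarray
    t_smr: np.ndarray
    m_smr: np.ndarray
    ln_mass: np.ndarray
    inv_kT: np.ndarray


def _design(table: TraitTable):
    ln_smr = np.log([r.smr for r in table])
    ln_m = np.log([r.body_mass_g for r in table])
    ikt = inv_kT(np.array([r.temperature_C for r in table]))
    return ln_smr, ln_m, ikt


def fit_mte(
    table: TraitTable,
    fixed_b: float | None = None,
    fixed_E: float | None = None,
) -> MTEFit:
    """Least-squares fit of ln SMR = lnB0 + b lnM - E/kT.

    Either exponent can be fixed; the rest are estimated.  Raises when the
    free predictors do not vary (rank deficiency: a constant temperature
    makes E unidentifiable, a constant mass makes b unidentifiable).
    """
    ln_smr, ln_m, ikt = _design(table)
    n = len(ln_smr)
    if n < 4:
        raise MTEError("need at least 4 species to fit three coefficients")
    y = ln_smr.copy()
    cols = [np.ones(n)]
    names = ["lnB0"]
    if fixed_b is None:
        if np.ptp(ln_m) < 1e-12:
            raise MTEError(
                "body mass is constant across species: b is unidentifiable; "
                "supply fixed_b"
            )
        cols.append(ln_m)
        names.append("b")
    else:
        y = y - fixed_b * ln_m
    if fixed_E is None:
        if np.ptp(ikt) < 1e-12:
            raise MTEError(
                "temperature is constant across species: E is unidentifiable; "
                "supply fixed_E"
            )
        cols.append(-ikt)
        names.append("E")
    else:
        y = y + fixed_E * ikt
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise MTEError("collinear predictors: lnM and 1/kT do not vary independently")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - X.shape[1]
    sigma2 = rss / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    est = dict(zip(names, beta))
    se_map = dict(zip(names, se))
    return MTEFit(
        lnB0=float(est["lnB0"]),
        b=float(est.get("b", fixed_b if fixed_b is not None else np.nan)),
        E=float(est.get("E", fixed_E if fixed_E is not None else np.nan)),
        se_lnB0=float(se_map["lnB0"]),
        se_b=float(se_map.get("b", 0.0)),
        se_E=float(se_map.get("E", 0.0)),
        n=n,
        r2=float(min(max(r2, 0.0), 1.0)),
        b_fixed=fixed_b is not None,
        E_fixed=fixed_E is not None,
    )


def correct(table: TraitTable, fit: MTEFit) -> CorrectedRates:
    """Temperature- and mass-corrected log rates.

    tSMR = lnSMR + E/kT removes the Boltzmann factor; mSMR = lnSMR - b lnM
    removes the mass allometry.  Both identities hold elementwise by
    construction: tSMR - lnSMR = E * (1/kT), lnSMR - mSMR = b * lnM.
    """
    if not (np.isfinite(fit.b) and np.isfinite(fit.E)):
        raise MTEError("fit must have finite b and E")
    ln_smr, ln_m, ikt = _design(table)
    return CorrectedRates(
        species=table.species,
        ln_smr=ln_smr,
        t_smr=ln_smr + fit.E * ikt,
        m_smr=ln_smr - fit.b * ln_m,
        ln_mass=ln_m,
        inv_kT=ikt,
    )


def fit_summary(fit: MTEFit) -> str:
    """Key-value text block describing a fit."""
    lines = [
        f"n = {fit.n}",
        f"lnB0 = {fit.lnB0:.6g} (se {fit.se_lnB0:.3g})",
        f"b = {fit.b:.6g} (se {fit.se_b:.3g}){' [fixed]' if fit.b_fixed else ''}",
        f"E = {fit.E:.6g} eV (se {fit.se_E:.3g}){' [fixed]' if fit.E_fixed else ''}",
        f"r2 = {fit.r2:.4f}",
    ]
    return "\n".join(lines) + "\n"
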