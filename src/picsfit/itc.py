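"""Isothermal titration calorimetry: forward models, fitting, and profiling.

Implements single-site and two-independent-sites binding isotherms for a
perfusion (overfill) cell instrument such as the VP-ITC, least-squares
fitting of titration data, a chi-square profile over the two dissociation
constants, and thermodynamic conversions between affinity and free energy.

Units convention
----------------
Concentrations are in uM, cell volume in mL, injection volumes in uL,
enthalpies and normalized heats in kcal/mol of injectant, raw injection
heats in ucal, temperature in kelvin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "R_KCAL",
    "InjectionProtocol",
    "OneSiteParams",
    "TwoSiteParams",
    "Titration",
    "FitResult",
    "Chi2Profile",
    "bound_fraction_one_site",
    "free_ligand_two_sites",
    "model_heats",
    "simulate_titration",
    "fit_one_site",
    "fit_two_sites",
    "chi2_profile_two_sites",
    "delta_g",
    "ddg_ratio",
    "wiseman_c",
]

#: gas constant in kcal/(mol*K)
R_KCAL = 1.987204259e-3


@dataclass(frozen=True)
class InjectionProtocol:
    """Injection schedule and cell/syringe composition for one titration.

    Parameters
    ----------
    cell_volume:
        Active cell volume V0 in mL.
    cell_conc:
        Initial macromolecule concentration in the cell, uM (monomer basis).
    syringe_conc:
        Ligand concentration in the syringe, uM.
    injection_volumes:
        Volume of each injection, uL.  At least two injections.
    temperature:
        Experiment temperature in kelvin (default 298.15, i.e. 25 C).
    """

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    injection_volumes: tuple[float, ...]
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.cell_volume <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("cell volume and concentrations must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        vols = tuple(float(v) for v in self.injection_volumes)
        if len(vols) < 2:
            raise ValueError("at least 2 injections are required")
        if any(v <= 0 for v in vols):
            raise ValueError("injection volumes must be positive")
        object.__setattr__(self, "injection_volumes", vols)

    @classmethod
    def uniform(
        cls,
        n_injections: int,
        injection_volume: float,
        cell_volume: float,
        cell_conc: float,
        syringe_conc: float,
        temperature: float = 298.15,
    ) -> "InjectionProtocol":
        """Protocol with `n_injections` equal injections of `injection_volume` uL."""
        return cls(
            cell_volume=cell_volume,
            cell_conc=cell_conc,
            syringe_conc=syringe_conc,
            injection_volumes=(injection_volume,) * n_injections,
            temperature=temperature,
        )

    def totals(self) -> tuple[np.ndarray, np.ndarray]:
        """Total macromolecule and ligand concentration in the cell after each injection.

        Uses the perfusion-cell displaced-volume convention: each injection of
        volume dV dilutes the species already in the cell by
        (1 - dV/(2 V0)) / (1 + dV/(2 V0)), while the freshly injected ligand
        enters at syringe_conc * dV/V0 reduced by the half-displacement factor
        1 / (1 + dV/(2 V0)).
        """
        v0 = self.cell_volume * 1e3  # uL
        mt = np.empty(len(self.injection_volumes))
        lt = np.empty(len(self.injection_volumes))
        m, l = self.cell_conc, 0.0
        for i, dv in enumerate(self.injection_volumes):
            half = dv / (2.0 * v0)
            f = (1.0 - half) / (1.0 + half)
            m = m * f
            l = l * f + self.syringe_conc * (dv / v0) / (1.0 + half)
            mt[i] = m
            lt[i] = l
        return mt, lt


@dataclass
class OneSiteParams:
    """Single class of N identical independent sites per macromolecule.

    N is dimensionless sites/monomer, Kd in uM, dH in kcal/mol of ligand,
    offset is a constant dilution-heat baseline in kcal/mol of injectant.
    """

    N: float
    Kd: float
    dH: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise ValueError("Kd must be positive")
        if self.N <= 0:
            raise ValueError("N must be positive")

    def perturbed(self, factor: float = 1.5) -> "OneSiteParams":
        """Multiplicatively perturb every thermodynamic parameter (fit starts)."""
        return OneSiteParams(self.N * factor, self.Kd * factor, self.dH * factor, self.offset)


@dataclass
class TwoSiteParams:
    """Two independent site classes, one site of each per macromolecule.

    Kd1/Kd2 in uM, dH1/dH2 in kcal/mol; the per-class stoichiometries N1, N2
    are fixed at 1.0 in fitting mode but kept as fields for forward modelling.
    """

    Kd1: float
    Kd2: float
    dH1: float
    dH2: float
    offset: float = 0.0
    N1: float = 1.0
    N2: float = 1.0

    def __post_init__(self) -> None:
        if self.Kd1 <= 0 or self.Kd2 <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.N1 <= 0 or self.N2 <= 0:
            raise ValueError("site counts must be positive")

    def ordered(self) -> "TwoSiteParams":
        """Return the label-exchange representative with Kd1 <= Kd2."""
        if self.Kd1 <= self.Kd2:
            return self
        return TwoSiteParams(self.Kd2, self.Kd1, self.dH2, self.dH1, self.offset, self.N2, self.N1)

    def perturbed(self, factor: float = 1.5) -> "TwoSiteParams":
        return TwoSiteParams(
            self.Kd1 * factor, self.Kd2 * factor,
            self.dH1 * factor, self.dH2 * factor,
            self.offset, self.N1, self.N2,
        )


@dataclass
class Titration:
    """An injection protocol together with observed per-injection heats (ucal)."""

    protocol: InjectionProtocol
    heats: np.ndarray

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if self.heats.shape != (len(self.protocol.injection_volumes),):
            raise ValueError("heats length must equal the number of injections")

    @property
    def normalized(self) -> np.ndarray:
        """Heat per mole of injectant, kcal/mol."""
        dv = np.asarray(self.protocol.injection_volumes)
        moles = self.protocol.syringe_conc * 1e-6 * dv * 1e-6  # mol
        return self.heats * 1e-9 / moles

    @property
    def molar_ratio(self) -> np.ndarray:
        """Cumulative ligand:macromolecule molar ratio in the cell."""
        mt, lt = self.protocol.totals()
        return lt / mt


def bound_fraction_one_site(Mt: float, Lt: float, params: OneSiteParams) -> float:
    """Concentration (uM) of bound ligand for one class of N identical sites.

    Solves the mass-balance quadratic for the complex concentration
    [ML] in [0, min(Lt, N*Mt)]:

        [ML]^2 - (N*Mt + Lt + Kd) [ML] + N*Mt*Lt = 0

    taking the smaller root (the physical one).
    """
    if Mt < 0 or Lt < 0:
        raise ValueError("concentrations must be non-negative")
    if Lt == 0.0 or Mt == 0.0:
        return 0.0
    sites = params.N * Mt
    b = sites + Lt + params.Kd
    disc = b * b - 4.0 * sites * Lt
    # disc >= Kd^2 > 0 always; numerically stable smaller root
    root = 2.0 * sites * Lt / (b + np.sqrt(disc))
    return float(min(root, min(Lt, sites)))


def free_ligand_two_sites(Mt: float, Lt: float, params: TwoSiteParams) -> float:
    """Free ligand concentration (uM) for two independent site classes.

    Solves the monotone mass balance

        Lt = L + N1*Mt*L/(Kd1 + L) + N2*Mt*L/(Kd2 + L)

    for the unique root L in [0, Lt] by Brent's method.
    """
    if Mt < 0 or Lt < 0:
        raise ValueError("concentrations must be non-negative")
    if Lt == 0.0:
        return 0.0
    if Mt == 0.0:
        return float(Lt)

    def balance(L: float) -> float:
        return (
            L
            + params.N1 * Mt * L / (params.Kd1 + L)
            + params.N2 * Mt * L / (params.Kd2 + L)
            - Lt
        )

    # balance(0) = -Lt < 0, balance(Lt) >= 0: bracketed
    return float(brentq(balance, 0.0, Lt, xtol=1e-14, rtol=1e-15, maxiter=200))


def _bound_per_class(mt: np.ndarray, lt: np.ndarray, params) -> np.ndarray:
    """Per-injection bound-ligand concentration for each site class.

    Returns shape (n_injections, n_classes); one class for OneSiteParams,
    two for TwoSiteParams.
    """
    if isinstance(params, OneSiteParams):
        out = np.empty((len(mt), 1))
        for i in range(len(mt)):
            out[i, 0] = bound_fraction_one_site(mt[i], lt[i], params)
        return out
    out = np.empty((len(mt), 2))
    for i in range(len(mt)):
        L = free_ligand_two_sites(mt[i], lt[i], params)
        out[i, 0] = params.N1 * mt[i] * L / (params.Kd1 + L)
        out[i, 1] = params.N2 * mt[i] * L / (params.Kd2 + L)
    return out


def _heats_from_occupancy(
    protocol: InjectionProtocol, bound: np.ndarray, dHs: Sequence[float]
) -> np.ndarray:
    """Raw injection heats (ucal) from per-class bound concentrations.

    Cumulative heat content Q_i = V0 * sum_s dH_s * bound_{i,s}; the observed
    injection heat corrects for the aliquot displaced into the overfill
    tube:  q_i = Q_i - Q_{i-1} + (dV_i/V0) * (Q_i + Q_{i-1}) / 2.
    """
    v0_l = protocol.cell_volume * 1e-3  # L
    dhs = np.asarray(dHs, dtype=float)
    q_cum = v0_l * (bound * 1e-6) @ dhs  # kcal
    dv = np.asarray(protocol.injection_volumes) * 1e-3  # mL
    q_prev = np.concatenate([[0.0], q_cum[:-1]])
    frac = dv / protocol.cell_volume
    q_inj = q_cum - q_prev + frac * (q_cum + q_prev) / 2.0
    return q_inj * 1e9  # ucal


def model_heats(
    protocol: InjectionProtocol, params: OneSiteParams | TwoSiteParams
) -> np.ndarray:
    """Normalized model heats (kcal/mol of injectant) for every injection."""
    mt, lt = protocol.totals()
    bound = _bound_per_class(mt, lt, params)
    if isinstance(params, OneSiteParams):
        raw = _heats_from_occupancy(protocol, bound, [params.dH])
    else:
        raw = _heats_from_occupancy(protocol, bound, [params.dH1, params.dH2])
    dv = np.asarray(protocol.injection_volumes)
    moles = protocol.syringe_conc * 1e-6 * dv * 1e-6
    return raw * 1e-9 / moles + params.offset


def simulate_titration(
    protocol: InjectionProtocol,
    params: OneSiteParams | TwoSiteParams,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Titration:
    """Forward-simulate a titration; `noise_sd` is gaussian noise on the
    normalized heats (kcal/mol). noise_sd = 0 is deterministic."""
    norm = model_heats(protocol, params)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        norm = norm + rng.normal(0.0, noise_sd, size=norm.shape)
    dv = np.asarray(protocol.injection_volumes)
    moles = protocol.syringe_conc * 1e-6 * dv * 1e-6
    heats = norm * moles * 1e9  # back to ucal (offset included as real heat)
    return Titration(protocol=protocol, heats=heats)


@dataclass
class FitResult:
    """Converged parameters, chi-square, and diagnostics of one fit."""

    params: OneSiteParams | TwoSiteParams
    chi2: float
    success: bool
    message: str
    n_injections: int
    model: str
    kd_identifiable: bool = True
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = {k: float(v) for k, v in asdict(self.params).items()}
        return {
            "model": self.model,
            "params": d,
            "chi2": float(self.chi2),
            "success": bool(self.success),
            "message": self.message,
            "n_injections": int(self.n_injections),
            "kd_identifiable": bool(self.kd_identifiable),
            "degenerate": bool(self.degenerate),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _default_one_site_init(titration: Titration) -> OneSiteParams:
    """Coarse grid scan for a starting point when the caller gives none."""
    y = titration.normalized
    m0 = titration.protocol.cell_conc
    best, best_chi2 = None, np.inf
    dh0 = y[np.argmax(np.abs(y))]
    if dh0 == 0.0:
        dh0 = -1.0
    for n in (0.5, 1.0, 2.0):
        for kd in m0 * np.array([0.05, 0.2, 1.0, 5.0, 20.0]):
            cand = OneSiteParams(n, float(kd), float(dh0))
            chi2 = float(np.sum((y - model_heats(titration.protocol, cand)) ** 2))
            if chi2 < best_chi2:
                best, best_chi2 = cand, chi2
    return best


def fit_one_site(
    titration: Titration,
    init: OneSiteParams | None = None,
    fix_N: float | None = None,
    skip_first: bool = False,
    fit_offset: bool = False,
) -> FitResult:
    """Least-squares fit of the single-site model.

    Minimizes chi2 = sum_i (normalized_obs_i - normalized_model_i)^2 by
    varying N, Kd and dH; with `fix_N`, N is held at that value, and with
    `fit_offset` a constant dilution-heat baseline floats as well
    (otherwise it stays at the init value, default 0).  `skip_first` drops
    the first injection from the residuals (common ITC practice for the
    diffusion-compromised first aliquot).
    """
    y = titration.normalized
    if len(y) < 4:
        raise ValueError("one-site fit requires at least 4 injections")
    use = np.ones(len(y), dtype=bool)
    if skip_first:
        use[0] = False
    if init is None:
        init = _default_one_site_init(titration)

    float_n = fix_N is None
    n_val = init.N if float_n else float(fix_N)
    off_val = init.offset

    def unpack(x):
        vals = list(x)
        n = vals.pop(0) if float_n else n_val
        kd, dh = vals.pop(0), vals.pop(0)
        off = vals.pop(0) if fit_offset else off_val
        return OneSiteParams(n, kd, dh, off)

    def resid(x):
        return (model_heats(titration.protocol, unpack(x)) - y)[use]

    x0, lo = [], []
    if float_n:
        x0.append(init.N)
        lo.append(1e-6)
    x0 += [init.Kd, init.dH]
    lo += [1e-9, -np.inf]
    if fit_offset:
        x0.append(init.offset)
        lo.append(-np.inf)
    hi = [np.inf] * len(x0)
    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    params = unpack(sol.x)
    chi2 = float(np.sum(sol.fun**2))
    identifiable = abs(params.dH) > 1e-6 * max(1.0, abs(params.offset))
    return FitResult(
        params=params,
        chi2=chi2,
        success=bool(sol.success),
        message=sol.message,
        n_injections=len(y),
        model="one_site",
        kd_identifiable=identifiable,
    )


def fit_two_sites(
    titration: Titration,
    init: TwoSiteParams | None = None,
    skip_first: bool = False,
) -> FitResult:
    """Least-squares fit of the two-independent-sites model, N1 = N2 = 1.

    Free parameters are (Kd1, Kd2, dH1, dH2, offset); the site-label
    exchange symmetry is resolved by reporting Kd1 <= Kd2.  A near-equal
    pair of dissociation constants is flagged `degenerate`, not an error.
    """
    y = titration.normalized
    if len(y) < 6:
        raise ValueError("two-site fit requires at least 6 injections")
    use = np.ones(len(y), dtype=bool)
    if skip_first:
        use[0] = False
    if init is None:
        one = fit_one_site(titration)
        p = one.params
        init = TwoSiteParams(p.Kd / 2.0, p.Kd * 2.0, p.dH, p.dH, p.offset)

    def unpack(x):
        return TwoSiteParams(x[0], x[1], x[2], x[3], x[4], N1=1.0, N2=1.0)

    def resid(x):
        return (model_heats(titration.protocol, unpack(x)) - y)[use]

    x0 = [init.Kd1, init.Kd2, init.dH1, init.dH2, init.offset]
    lo = [1e-9, 1e-9, -np.inf, -np.inf, -np.inf]
    hi = [np.inf] * 5
    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    params = unpack(sol.x).ordered()
    chi2 = float(np.sum(sol.fun**2))
    degenerate = abs(np.log(params.Kd1 / params.Kd2)) < 0.05
    return FitResult(
        params=params,
        chi2=chi2,
        success=bool(sol.success),
        message=sol.message,
        n_injections=len(y),
        model="two_sites",
        degenerate=degenerate,
    )


@dataclass
class Chi2Profile:
    """Chi-square surface over a (Kd1, Kd2) lattice with nuisance parameters
    (both enthalpies and the baseline) re-optimized at every node."""

    kd1_grid: np.ndarray
    kd2_grid: np.ndarray
    chi2: np.ndarray  # shape (len(kd1_grid), len(kd2_grid))
    chi2_min: float
    threshold: float
    region: list[tuple[float, float]] = field(default_factory=list)
    kd1_range: tuple[float, float] | None = None
    kd2_range: tuple[float, float] | None = None

    def to_frame(self):
        import pandas as pd

        k1, k2 = np.meshgrid(self.kd1_grid, self.kd2_grid, indexing="ij")
        return pd.DataFrame(
            {"Kd1_uM": k1.ravel(), "Kd2_uM": k2.ravel(), "chi2": self.chi2.ravel()}
        )


def chi2_profile_two_sites(
    titration: Titration,
    kd1_grid: Sequence[float],
    kd2_grid: Sequence[float],
    threshold: float,
    skip_first: bool = False,
) -> Chi2Profile:
    """Profile chi2 over fixed (Kd1, Kd2) pairs.

    The normalized heats are exactly linear in (dH1, dH2, offset), so the
    nuisance re-optimization at each node is a closed-form linear
    least-squares solve (variable projection).
    """
    kd1_grid = np.asarray(kd1_grid, dtype=float)
    kd2_grid = np.asarray(kd2_grid, dtype=float)
    if np.any(kd1_grid <= 0) or np.any(kd2_grid <= 0):
        raise ValueError("grids must be strictly positive")
    if np.any(np.diff(kd1_grid) <= 0) or np.any(np.diff(kd2_grid) <= 0):
        raise ValueError("grids must be sorted strictly increasing")

    y = titration.normalized
    use = np.ones(len(y), dtype=bool)
    if skip_first:
        use[0] = False
    mt, lt = titration.protocol.totals()
    dv = np.asarray(titration.protocol.injection_volumes)
    moles = titration.protocol.syringe_conc * 1e-6 * dv * 1e-6

    chi2 = np.empty((len(kd1_grid), len(kd2_grid)))
    for i, k1 in enumerate(kd1_grid):
        for j, k2 in enumerate(kd2_grid):
            node = TwoSiteParams(k1, k2, 1.0, 1.0)
            bound = _bound_per_class(mt, lt, node)
            # per-class normalized heat at unit enthalpy
            a1 = _heats_from_occupancy(titration.protocol, bound, [1.0, 0.0]) * 1e-9 / moles
            a2 = _heats_from_occupancy(titration.protocol, bound, [0.0, 1.0]) * 1e-9 / moles
            A = np.column_stack([a1, a2, np.ones(len(y))])[use]
            resid = A @ np.linalg.lstsq(A, y[use], rcond=None)[0] - y[use]
            chi2[i, j] = float(resid @ resid)

    chi2_min = float(chi2.min())
    region = [
        (float(kd1_grid[i]), float(kd2_grid[j]))
        for i, j in zip(*np.nonzero(chi2 <= threshold))
    ]
    kd1_range = kd2_range = None
    if region:
        k1s = [p[0] for p in region]
        k2s = [p[1] for p in region]
        kd1_range = (min(k1s), max(k1s))
        kd2_range = (min(k2s), max(k2s))
    return Chi2Profile(
        kd1_grid=kd1_grid,
        kd2_grid=kd2_grid,
        chi2=chi2,
        chi2_min=chi2_min,
        threshold=float(threshold),
        region=region,
        kd1_range=kd1_range,
        kd2_range=kd2_range,
    )


def delta_g(Kd: float, T: float = 298.15) -> float:
    """Standard binding free energy dG = R T ln(Kd / 1 M), kcal/mol, Kd in uM."""
    if Kd <= 0 or T <= 0:
        raise ValueError("Kd and T must be positive")
    return R_KCAL * T * np.log(Kd * 1e-6)


def ddg_ratio(ratio: float, T: float = 298.15) -> float:
    """Free-energy difference ddG = R T ln(ratio) for a fold change in Kd."""
    if ratio <= 0 or T <= 0:
        raise ValueError("ratio and T must be positive")
    return R_KCAL * T * np.log(ratio)


def wiseman_c(N: float, cell_conc: float, Kd: float) -> float:
    """Dimensionless Wiseman parameter c = N * M0 / Kd governing isotherm curvature."""
    return N * cell_conc / Kd
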