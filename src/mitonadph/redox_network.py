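"""Mass-action ODE model of the mitochondrial H2O2 clearance network.

The model follows the cytosolic H2O2-clearance framework of Adimora and
co-workers, restricted to the mitochondrial matrix and extended with four
matrix-specific processes:

* a chemogenetic H2O2 source: D-amino acid oxidase (DAAO) oxidising matrix
  D-alanine (``v_daao = k_gen_h2o2 * dala_mito``), fed by passive membrane
  permeation of external D-alanine (``k_perm = P * surface_to_volume``);
* a first-order NADPH regeneration term lumping the matrix NADP+-reducing
  enzymes (IDH2, ME3, NNT, MTHFD2): ``v_regen = k_gen_nadph * nadp``;
* a stress-dependent NADPH influx representing cytosol-to-matrix transfer of
  reducing equivalents through metabolite shuttles, proportional to the
  total H2O2 generation flux (see :func:`stress_flux`);
* glutathione exchange (constant influx, first-order degradation) replacing
  cytosolic glutathione synthesis, and no thioredoxin turnover.

Species are tracked in micromolar; time is seconds internally and minutes at
the I/O boundary.  External D-alanine is supplied in millimolar and held
constant (HeLa cells have no endogenous DAAO, so the only sink for matrix
D-alanine is the expressed enzyme).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from mitonadph.errors import ConfigurationError, IntegrationError, PreconditionError

#: Species order used by every array-valued interface in the package.
SPECIES = (
    "h2o2",
    "prx_sh",
    "prx_soh",
    "prx_ss",
    "prx_so2h",
    "trx_sh",
    "trx_ss",
    "gsh",
    "gssg",
    "psh",
    "psoh",
    "pssg",
    "nadph",
    "nadp",
    "dala_mito",
)

#: Names of the fitted parameter subset, in canonical order.
THETA_NAMES = ("p_dala", "k_gen_h2o2", "k_gen_nadph", "alpha")

#: Flux columns reported along a trajectory (uM/s).
FLUX_NAMES = ("v_daao", "v_h2o2_total", "v_nadph_regen", "v_alpha")

_IDX = {name: i for i, name in enumerate(SPECIES)}


@dataclass
class RedoxState:
    """Concentrations (uM) of every matrix species tracked by the model.

    Peroxiredoxin is carried in four redox forms (thiol, sulfenic acid,
    disulfide, sulfinic acid), thioredoxin and glutathione in two each,
    generic protein thiols in three (thiol, sulfenic, glutathionylated),
    the pyridine pool as NADPH/NADP+, plus matrix D-alanine.  The disulfide
    form ``prx_ss`` is counted monomerically, so the conserved peroxiredoxin
    moiety is the plain sum of the four forms.
    """

    h2o2: float = 0.0
    prx_sh: float = 0.0
    prx_soh: float = 0.0
    prx_ss: float = 0.0
    prx_so2h: float = 0.0
    trx_sh: float = 0.0
    trx_ss: float = 0.0
    gsh: float = 0.0
    gssg: float = 0.0
    psh: float = 0.0
    psoh: float = 0.0
    pssg: float = 0.0
    nadph: float = 0.0
    nadp: float = 0.0
    dala_mito: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "RedoxState":
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(SPECIES),):
            raise ValueError(f"expected {len(SPECIES)} species, got shape {arr.shape}")
        return cls(**{name: float(arr[i]) for i, name in enumerate(SPECIES)})

    def validate(self, tol: float = -1e-9) -> None:
        """Raise :class:`PreconditionError` if any concentration is negative."""
        for name in SPECIES:
            if getattr(self, name) < tol:
                raise PreconditionError(f"negative concentration for {name}: {getattr(self, name)}")

    # conserved moieties -------------------------------------------------
    @property
    def prx_total(self) -> float:
        return self.prx_sh + self.prx_soh + self.prx_ss + self.prx_so2h

    @property
    def trx_total(self) -> float:
        return self.trx_sh + self.trx_ss

    @property
    def nadp_total(self) -> float:
        return self.nadph + self.nadp


@dataclass
class Geometry:
    """Cell geometry used to convert the D-alanine permeability coefficient
    (cm/s) into a first-order exchange constant (1/s).

    ``surface_to_volume`` is the effective membrane area per matrix volume.
    The default is derived (not measured): it is chosen so that, with the
    fitted permeability and DAAO rate constant, the quasi-steady DAAO flux
    at 50 mM external D-alanine equals the model-predicted 70.7 uM/s (see
    :func:`calibrated_surface_to_volume`).
    """

    cell_radius_um: float = 10.0
    mito_volume_fraction: float = 0.1
    surface_to_volume_cm: float = 2.0768e6

    def __post_init__(self) -> None:
        if self.cell_radius_um <= 0:
            raise ConfigurationError("cell_radius_um must be positive")
        if not 0 < self.mito_volume_fraction < 1:
            raise ConfigurationError("mito_volume_fraction must be in (0, 1)")
        if self.surface_to_volume_cm <= 0:
            raise ConfigurationError("surface_to_volume_cm must be positive")

    def k_perm(self, p_dala: float) -> float:
        """First-order D-alanine exchange constant (1/s) for permeability ``p_dala`` (cm/s)."""
        return p_dala * self.surface_to_volume_cm


def calibrated_surface_to_volume(
    v_daao_anchor: float = 70.7,
    dala_ext_anchor_mm: float = 50.0,
    p_dala: float = 6.92e-10,
    k_gen_h2o2: float = 8.83e-2,
) -> float:
    """Surface-to-volume ratio (1/cm) implied by a quasi-steady DAAO flux anchor.

    At quasi-steady matrix D-alanine the DAAO flux is
    ``v = k_gen * k_perm * dala_ext / (k_perm + k_gen)`` with
    ``k_perm = P * s2v``.  Solving for ``k_perm`` at the anchor condition and
    dividing by ``P`` gives the geometric constant.  With the default anchors
    this evaluates to ~2.08e6 1/cm.
    """
    dala_um = dala_ext_anchor_mm * 1e3
    denom = k_gen_h2o2 * dala_um - v_daao_anchor
    if denom <= 0:
        raise ConfigurationError("anchor flux exceeds the DAAO capacity k_gen*dala_ext")
    k_perm = v_daao_anchor * k_gen_h2o2 / denom
    return k_perm / p_dala


#: Stress-flux gating modes accepted by :func:`stress_flux`.
STRESS_MODES = ("excess-gated", "literal", "off")


@dataclass
class KineticParameters:
    """Rate constants of the clearance network plus the fitted subset.

    Second-order constants are in 1/(uM*s); first-order constants in 1/s;
    zeroth-order fluxes in uM/s.  The fitted subset ``theta`` consists of
    ``p_dala`` (D-alanine permeability, cm/s), ``k_gen_h2o2`` (DAAO turnover
    of matrix D-alanine, 1/s), ``k_gen_nadph`` (lumped NADPH regeneration,
    1/s) and ``alpha`` (dimensionless stress-flux coefficient); defaults are
    the study's fitted values.

    The remaining constants default to literature-scale values for the
    mitochondrial matrix, calibrated once so that the basal operating point
    of the assembled network reproduces the reference state (H2O2 ~3.3 nM at
    a basal generation flux of 4 uM/s; see ``docs/methods.md``).
    """

    # H2O2 sources
    v_basal_h2o2: float = 4.0

    # peroxiredoxin cycle
    k_prx_ox: float = 19.7        # PrxSH + H2O2 -> PrxSOH
    k_prx_cond: float = 10.0      # PrxSOH -> PrxSS (condensation)
    k_prx_sulf: float = 1.0e-4    # PrxSOH + H2O2 -> PrxSO2H (hyperoxidation)
    k_srx: float = 5.0e-3         # PrxSO2H -> PrxSOH (sulfiredoxin recovery)
    k_prx_red: float = 0.15      # PrxSS + TrxSH -> PrxSH + TrxSS
    k_trxr: float = 0.10          # TrxSS + NADPH -> TrxSH + NADP+

    # glutathione cycle; GPx is modelled as an enzyme-limited flux,
    # first order in H2O2 and saturable in GSH (ping-pong limit)
    k_gpx: float = 2.0            # 1/s: v = k_gpx * h2o2 * gsh/(gsh + km_gpx_gsh)
    km_gpx_gsh: float = 50.0      # uM, GSH half-saturation of the GPx flux
    k_gr: float = 4.5e-3          # GSSG + NADPH -> 2 GSH + NADP+
    k_gsh_transport: float = 0.3  # constant GSH influx, uM/s
    k_gsh_degradation: float = 1.0e-4  # first-order GSH removal, 1/s
    k_gssg_export: float = 0.0    # optional first-order GSSG efflux, 1/s

    # generic protein thiols
    k_psh_ox: float = 1.0e-3      # PSH + H2O2 -> PSOH
    k_psoh_gsh: float = 1.0e-6    # PSOH + GSH -> PSSG
    k_grx: float = 1.0e-3         # PSSG + GSH -> PSH + GSSG (glutaredoxin)

    # fitted subset (theta)
    p_dala: float = 6.92e-10      # cm/s
    k_gen_h2o2: float = 8.83e-2   # 1/s
    k_gen_nadph: float = 1.59     # 1/s
    alpha: float = 80.9           # dimensionless

    # stress-flux handling
    stress_mode: str = "excess-gated"
    s_cal: float = 5.0e-7         # calibration scale applied to alpha*v (see stress_flux)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "stress_mode":
                continue
            value = getattr(self, f.name)
            if value < 0:
                raise ConfigurationError(f"rate constant {f.name} must be non-negative, got {value}")
        if self.stress_mode not in STRESS_MODES:
            raise ConfigurationError(
                f"unknown stress_mode {self.stress_mode!r}; expected one of {STRESS_MODES}"
            )

    @property
    def theta(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in THETA_NAMES}

    def with_theta(self, **values: float) -> "KineticParameters":
        unknown = set(values) - set(THETA_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown theta component(s): {sorted(unknown)}")
        return replace(self, **values)

    @classmethod
    def from_dict(cls, values: dict) -> "KineticParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ConfigurationError(
                f"unknown rate constant(s) in configuration: {sorted(unknown)}"
            )
        return cls(**values)

    def rate_constant_names(self) -> tuple[str, ...]:
        """Names of every numeric parameter (used by the sensitivity sweep)."""
        return tuple(f.name for f in fields(self) if f.name != "stress_mode")


@dataclass
class Condition:
    """One perturbation: external D-alanine (mM) held constant for ``t_end_min``."""

    dala_ext_mm: float = 0.0
    t_end_min: float = 60.0
    dt_report_min: float = 3.0

    def __post_init__(self) -> None:
        if self.dala_ext_mm < 0:
            raise PreconditionError("dala_ext_mm must be non-negative")
        if self.t_end_min <= 0:
            raise PreconditionError("t_end_min must be positive")
        if self.dt_report_min <= 0:
            raise PreconditionError("dt_report_min must be positive")

    @property
    def dala_ext_um(self) -> float:
        return self.dala_ext_mm * 1e3

    def report_times_min(self) -> np.ndarray:
        n = int(round(self.t_end_min / self.dt_report_min))
        return np.linspace(0.0, n * self.dt_report_min, n + 1)


@dataclass
class Trajectory:
    """Simulated time course: times (min), states (uM) and fluxes (uM/s)."""

    times_min: np.ndarray
    states: np.ndarray            # shape (n_times, n_species), SPECIES order
    fluxes: np.ndarray            # shape (n_times, 4), FLUX_NAMES order
    condition: Condition = field(default_factory=Condition)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.fluxes = np.asarray(self.fluxes, dtype=float)
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")

    def species(self, name: str) -> np.ndarray:
        return self.states[:, _IDX[name]]

    def state_at(self, t_min: float) -> RedoxState:
        i = int(np.argmin(np.abs(self.times_min - t_min)))
        return RedoxState.from_array(self.states[i])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time_min", self.times_min)
        for j, name in enumerate(FLUX_NAMES):
            df[name] = self.fluxes[:, j]
        return df


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def stress_flux(v_h2o2_total: float, params: KineticParameters, mode: str | None = None) -> float:
    """Stress-dependent NADPH influx (uM/s) as a function of the total H2O2 flux.

    The influx models shuttle-mediated transfer of cytosolic reducing
    equivalents into the matrix, engaged by elevated H2O2 production.  Two
    functional forms are provided:

    ``excess-gated`` (default)
        ``alpha * s_cal * max(0, v_total - v_basal)`` - the transfer responds
        to H2O2 generation in excess of the basal flux, so it vanishes at the
        basal operating point.
    ``literal``
        ``alpha * s_cal * v_total`` - proportional to the total flux,
        including the basal contribution.

    ``s_cal`` is a calibration scale: because the influx adds to the pyridine
    pool without a matching NADP+ sink, its time integral equals the growth
    of the total NADPH+NADP+ pool, which constrains it to be orders of
    magnitude smaller than the raw product ``alpha * v_total`` (that product
    is ~300 uM/s at basal, versus a ~40 uM pool).  The default is calibrated
    so the 50 mM trajectory reaches the reference 7.9 uM NADPH endpoint.
    """
    if v_h2o2_total < 0:
        raise PreconditionError("v_h2o2_total must be non-negative")
    mode = mode or params.stress_mode
    if mode == "off":
        return 0.0
    if mode == "excess-gated":
        excess = max(0.0, v_h2o2_total - params.v_basal_h2o2)
        return params.alpha * params.s_cal * excess
    if mode == "literal":
        return params.alpha * params.s_cal * v_h2o2_total
    raise ConfigurationError(f"unknown stress_flux mode {mode!r}; expected one of {STRESS_MODES}")


def _rhs_arrays(
    y: np.ndarray, params: KineticParameters, k_perm: float, dala_ext_um: float
) -> tuple[np.ndarray, tuple[float, float, float, float]]:
    """Core mass-action right-hand side on a raw state array.

    Returns (dy/dt, (v_daao, v_h2o2_total, v_nadph_regen, v_alpha)).
    """
    (h2o2, prx_sh, prx_soh, prx_ss, prx_so2h, trx_sh, trx_ss,
     gsh, gssg, psh, psoh, pssg, nadph, nadp, dala) = y

    p = params
    v_prx_ox = p.k_prx_ox * h2o2 * prx_sh
    v_cond = p.k_prx_cond * prx_soh
    v_sulf = p.k_prx_sulf * h2o2 * prx_soh
    v_srx = p.k_srx * prx_so2h
    v_prx_red = p.k_prx_red * prx_ss * trx_sh
    v_trxr = p.k_trxr * trx_ss * nadph
    gpx_denom = gsh + p.km_gpx_gsh
    v_gpx = p.k_gpx * h2o2 * gsh / gpx_denom if gpx_denom > 0 else 0.0
    v_gr = p.k_gr * gssg * nadph
    v_psh = p.k_psh_ox * h2o2 * psh
    v_psoh = p.k_psoh_gsh * psoh * gsh
    v_grx = p.k_grx * pssg * gsh

    v_daao = p.k_gen_h2o2 * dala
    v_total = p.v_basal_h2o2 + v_daao
    v_regen = p.k_gen_nadph * nadp
    v_alpha = stress_flux(v_total, p)

    dy = np.empty_like(y)
    dy[0] = v_total - v_prx_ox - v_sulf - v_gpx - v_psh          # h2o2
    dy[1] = v_prx_red - v_prx_ox                                  # prx_sh
    dy[2] = v_prx_ox - v_cond - v_sulf + v_srx                    # prx_soh
    dy[3] = v_cond - v_prx_red                                    # prx_ss
    dy[4] = v_sulf - v_srx                                        # prx_so2h
    dy[5] = v_trxr - v_prx_red                                    # trx_sh
    dy[6] = v_prx_red - v_trxr                                    # trx_ss
    dy[7] = (p.k_gsh_transport - p.k_gsh_degradation * gsh
             - 2.0 * v_gpx + 2.0 * v_gr - v_psoh - v_grx)         # gsh
    dy[8] = v_gpx - v_gr + v_grx - p.k_gssg_export * gssg         # gssg
    dy[9] = v_grx - v_psh                                         # psh
    dy[10] = v_psh - v_psoh                                       # psoh
    dy[11] = v_psoh - v_grx                                       # pssg
    dy[12] = v_regen + v_alpha - v_trxr - v_gr                    # nadph
    dy[13] = v_trxr + v_gr - v_regen                              # nadp
    dy[14] = k_perm * (dala_ext_um - dala) - v_daao               # dala_mito
    return dy, (v_daao, v_total, v_regen, v_alpha)


def rhs(
    state: RedoxState,
    params: KineticParameters,
    geometry: Geometry,
    dala_ext_mm: float = 0.0,
) -> RedoxState:
    """Time derivatives (uM/s) of every species at the given state.

    External D-alanine is supplied in mM and converted to uM internally.
    Raises :class:`PreconditionError` on negative input concentrations.
    """
    state.validate()
    if dala_ext_mm < 0:
        raise PreconditionError("dala_ext_mm must be non-negative")
    dy, _ = _rhs_arrays(
        state.to_array(), params, geometry.k_perm(params.p_dala), dala_ext_mm * 1e3
    )
    return RedoxState.from_array(dy)


def fluxes_at(
    state: RedoxState, params: KineticParameters
) -> dict[str, float]:
    """The four reported fluxes (uM/s) at a state."""
    v_daao = params.k_gen_h2o2 * state.dala_mito
    v_total = params.v_basal_h2o2 + v_daao
    return {
        "v_daao": v_daao,
        "v_h2o2_total": v_total,
        "v_nadph_regen": params.k_gen_nadph * state.nadp,
        "v_alpha": stress_flux(v_total, params),
    }


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(
    initial: RedoxState,
    params: KineticParameters,
    geometry: Geometry,
    condition: Condition,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    times_min: Iterable[float] | None = None,
) -> Trajectory:
    """Integrate the network over a constant-D-alanine condition.

    Reporting times default to ``0 .. t_end`` at ``dt_report`` spacing
    (minutes).  A stiff solver (LSODA) is used; on step-size collapse an
    :class:`IntegrationError` naming the last successful time is raised.
    """
    initial.validate()
    t_report_min = (
        np.asarray(list(times_min), dtype=float)
        if times_min is not None
        else condition.report_times_min()
    )
    t_report_s = t_report_min * 60.0
    k_perm = geometry.k_perm(params.p_dala)
    dala_ext_um = condition.dala_ext_um

    def f(t: float, y: np.ndarray) -> np.ndarray:
        return _rhs_arrays(y, params, k_perm, dala_ext_um)[0]

    sol = solve_ivp(
        f,
        (t_report_s[0], t_report_s[-1]),
        initial.to_array(),
        method="LSODA",
        t_eval=t_report_s,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = sol.t[-1] / 60.0 if sol.t.size else t_report_min[0]
        raise IntegrationError(
            f"integration failed at t = {last:.3f} min: {sol.message}", last_time=last
        )
    states = sol.y.T
    flux = np.empty((states.shape[0], 4))
    for i, row in enumerate(states):
        flux[i] = _rhs_arrays(row, params, k_perm, dala_ext_um)[1]
    return Trajectory(times_min=t_report_min, states=states, fluxes=flux, condition=condition)


def daao_rate_table(
    params: KineticParameters,
    geometry: Geometry,
    dala_ext_list_mm: Sequence[float],
) -> pd.DataFrame:
    """Quasi-steady DAAO and total H2O2 generation fluxes per dose.

    Matrix D-alanine relaxes on a ~10 s timescale to
    ``dala* = k_perm * dala_ext / (k_perm + k_gen)``, so over the 60-min
    experiment the DAAO flux is effectively ``k_gen * dala*``, exactly linear
    in the external dose.
    """
    k_perm = geometry.k_perm(params.p_dala)
    rows = []
    for dala_mm in dala_ext_list_mm:
        if dala_mm < 0:
            raise PreconditionError("D-alanine concentrations must be non-negative")
        dala_star = k_perm * dala_mm * 1e3 / (k_perm + params.k_gen_h2o2)
        v_daao = params.k_gen_h2o2 * dala_star
        rows.append(
            {
                "dala_ext_mm": dala_mm,
                "dala_mito_um": dala_star,
                "v_daao": v_daao,
                "v_h2o2_total": params.v_basal_h2o2 + v_daao,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Michaelis-Menten assay fit
# ---------------------------------------------------------------------------

def fit_michaelis_menten(
    substrate_mm: Sequence[float], rate: Sequence[float]
) -> tuple[float, float, float]:
    """Fit ``v = v_max * S / (K_m + S)`` to an enzyme assay.

    Parameters
    ----------
    substrate_mm : substrate concentrations (mM), at least three distinct levels.
    rate : observed rates (any consistent unit, e.g. M/s).

    Returns
    -------
    (v_max, k_m_mm, residual_norm).  If all rates are zero the data carry no
    kinetic information: v_max = 0 is returned with K_m = nan as the
    unidentifiable flag.
    """
    s = np.asarray(substrate_mm, dtype=float)
    v = np.asarray(rate, dtype=float)
    if s.shape != v.shape:
        raise PreconditionError("substrate and rate arrays must have equal length")
    if np.unique(s).size < 3:
        raise PreconditionError("need at least 3 distinct substrate levels")
    if np.any(v < 0):
        raise PreconditionError("rates must be non-negative")
    if np.all(v == 0):
        return 0.0, float("nan"), 0.0

    # fit on a normalized rate scale so the two parameters are comparable
    v_scale = float(v.max())
    vn = v / v_scale

    def mm(sub, vmax, km):
        return vmax * sub / (km + sub)

    popt, _ = curve_fit(
        mm, s, vn, p0=[1.2, float(np.median(s))], bounds=(0, np.inf),
        xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
    )
    vmax_hat, km_hat = float(popt[0]) * v_scale, float(popt[1])
    resid = float(np.linalg.norm(v - vmax_hat * s / (km_hat + s)))
    return vmax_hat, km_hat, resid
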