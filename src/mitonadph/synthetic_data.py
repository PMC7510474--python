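"""Synthetic data generation for every input the analysis pipeline consumes.

The study's raw measurements (per-cell sensor time courses, GC/MS
mass-isotopomer distributions, the DAAO activity assay) are not deposited,
so this module generates statistically realistic stand-ins from the model
itself: sensor readout series are model trajectories passed through the
observation map with per-cell lognormal scale factors and per-timepoint
additive noise; lactate MIDs are two-channel pathway mixtures convolved
with natural isotope abundance; the enzyme assay is a noisy
Michaelis-Menten hyperbola.  Seeds are mandatory; identical seeds give
bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mitonadph.errors import PreconditionError
from mitonadph.redox_network import Condition, Geometry, KineticParameters, simulate
from mitonadph.sensor import ReadoutSeries, SensorCalibration, readout_of_concentration
from mitonadph.steady_state import MoietyTotals, initialize_oxidized_species
from mitonadph.tracer import MID, apply_natural_abundance

#: Doses (mM D-alanine) and matched cell counts of the sensor study design,
#: ordered 50 -> 0 mM as in the imaging experiment.
DEFAULT_CONDITIONS_MM = (50.0, 25.0, 15.0, 10.0, 5.0, 1.0, 0.0)
DEFAULT_N_CELLS = (21, 13, 12, 10, 14, 17, 21)


@dataclass
class SyntheticStudyDesign:
    """Design of the emulated imaging experiment.

    Per-condition cell counts follow the study's reported group sizes.  The
    noise model places a lognormal scale factor on each cell's whole readout
    trace (cell-to-cell expression/loading variability, ``sigma_cell`` in
    log units) and additive Gaussian noise on each timepoint
    (``sigma_meas``, readout units).  Both magnitudes are assumptions - the
    study reports error bars only - chosen so control-condition aggregate
    scatter stays within the documented 13% band.
    """

    conditions_mm: tuple[float, ...] = DEFAULT_CONDITIONS_MM
    n_cells: tuple[int, ...] = DEFAULT_N_CELLS
    t_end_min: float = 60.0
    dt_min: float = 3.0
    sigma_cell: float = 0.08
    sigma_meas: float = 0.01

    def __post_init__(self) -> None:
        if len(self.conditions_mm) != len(self.n_cells):
            raise PreconditionError("conditions and n_cells must have equal length")
        if any(n < 1 for n in self.n_cells):
            raise PreconditionError("every condition needs at least one cell")
        if self.sigma_cell < 0 or self.sigma_meas < 0:
            raise PreconditionError("noise magnitudes must be non-negative")

    def times_min(self) -> np.ndarray:
        n = int(round(self.t_end_min / self.dt_min))
        return np.linspace(0.0, n * self.dt_min, n + 1)


def generate_fluorescence_dataset(
    design: SyntheticStudyDesign,
    seed: int,
    theta_true: dict[str, float] | None = None,
    params: KineticParameters | None = None,
    geometry: Geometry | None = None,
    totals: MoietyTotals | None = None,
    calibration: SensorCalibration | None = None,
) -> tuple[pd.DataFrame, list[ReadoutSeries]]:
    """Per-cell readout traces plus per-condition aggregates (mean +- SEM).

    The deterministic backbone is the model trajectory under each condition,
    mapped through the sensor calibration to an absolute effective readout
    R'(t).  Returns the long-format per-cell table and one aggregated
    :class:`ReadoutSeries` per condition (absolute units, SEM = SD/sqrt(n)).
    """
    rng = np.random.default_rng(seed)
    params = params or KineticParameters()
    if theta_true:
        params = params.with_theta(**theta_true)
    geometry = geometry or Geometry()
    totals = totals or MoietyTotals()
    calibration = calibration or SensorCalibration()

    initial = initialize_oxidized_species(totals, params, geometry)
    times = design.times_min()
    cells_rows = []
    aggregates = []
    for dose, n_cells in zip(design.conditions_mm, design.n_cells):
        cond = Condition(dala_ext_mm=dose, t_end_min=design.t_end_min, dt_report_min=design.dt_min)
        traj = simulate(initial, params, geometry, cond, times_min=times)
        r_true = readout_of_concentration(traj.species("nadph"), calibration)

        scale = np.exp(rng.normal(0.0, design.sigma_cell, size=n_cells))
        noise = rng.normal(0.0, design.sigma_meas, size=(n_cells, times.size))
        traces = np.clip(scale[:, None] * r_true[None, :] + noise, 1e-6, None)

        for c in range(n_cells):
            for j, t in enumerate(times):
                cells_rows.append(
                    {
                        "condition_mM": dose,
                        "cell": c,
                        "time_min": t,
                        "r_prime": traces[c, j],
                    }
                )
        mean = traces.mean(axis=0)
        sem = (
            traces.std(axis=0, ddof=1) / np.sqrt(n_cells)
            if n_cells > 1
            else np.zeros_like(mean)
        )
        aggregates.append(
            ReadoutSeries(
                times_min=times,
                r_prime=mean,
                sem=sem,
                n_cells=n_cells,
                condition_mm=dose,
                normalized=False,
            )
        )
    return pd.DataFrame(cells_rows), aggregates


#: Lactate MID channels from [1,2-13C2]glucose: glycolysis yields equal
#: M+0/M+2 (the two trioses of one hexose), the oxPPP route yields M+1.
GLYCOLYSIS_LACTATE = np.array([0.5, 0.0, 0.5, 0.0])
OXPPP_LACTATE = np.array([0.0, 1.0, 0.0, 0.0])


def _lactate_true_mid(phi_oxppp: float) -> np.ndarray:
    """True lactate MID whose M1/(M1+M2) statistic equals ``phi_oxppp``.

    The statistic excludes M+0, and the glycolytic channel carries one
    unlabeled sibling triose per M+2 triose, so the channel weights are
    solved from m1/(m1+m2) = phi rather than used as molar fractions:
    with s = 1/(2 - phi), the MID (m0, m1, m2) = ((1-phi)s, phi*s, (1-phi)s).
    """
    s = 1.0 / (2.0 - phi_oxppp)
    return np.array([(1 - phi_oxppp) * s, phi_oxppp * s, (1 - phi_oxppp) * s, 0.0])


def generate_mid_dataset(
    phi_oxppp: float,
    n_reps: int,
    noise_sd: float,
    seed: int,
    condition: str = "synthetic",
    time_hr: float = 2.0,
) -> list[MID]:
    """Replicate lactate MIDs for a given oxPPP share of triose production.

    The true MID is the ``phi_oxppp``-weighted mixture of the oxPPP (M+1)
    and glycolytic (M+0/M+2) channels, forward-convolved with natural 13C
    abundance; replicates add Gaussian noise and renormalize.  By
    construction, correcting the noise-free output and computing the M+1
    share recovers ``phi_oxppp`` exactly.
    """
    if not 0.0 <= phi_oxppp <= 1.0:
        raise PreconditionError("phi_oxppp must lie in [0, 1]")
    if n_reps < 1:
        raise PreconditionError("need at least one replicate")
    rng = np.random.default_rng(seed)
    true = _lactate_true_mid(phi_oxppp)
    raw = apply_natural_abundance(
        MID("lactate", true, 3, condition=condition, time_hr=time_hr)
    )
    out = []
    for rep in range(n_reps):
        noisy = raw.fractions + rng.normal(0.0, noise_sd, size=raw.fractions.size)
        noisy = np.clip(noisy, 0.0, None)
        noisy = noisy / noisy.sum()
        out.append(
            MID("lactate", noisy, 3, condition=f"{condition}_rep{rep}", time_hr=time_hr)
        )
    return out


def generate_tca_mids(
    p_m2: float,
    p_m3: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition: str = "synthetic",
    time_hr: float = 2.0,
) -> list[MID]:
    """First-turn TCA labeling from [U-13C6]glucose.

    ``p_m2`` is the fraction of metabolite molecules carrying an M+2 label
    (PDH route, M+2 acetyl-CoA); ``p_m3`` the fraction carrying M+3
    (pyruvate carboxylase route, four-carbon intermediates only).  Higher
    turns are not modelled.  Output is forward-convolved with natural
    abundance and optionally perturbed with Gaussian noise.
    """
    if p_m2 < 0 or p_m3 < 0 or p_m2 + p_m3 > 1:
        raise PreconditionError("label fractions must be non-negative and sum to <= 1")
    rng = np.random.default_rng(seed)
    from mitonadph.tracer import TCA_CARBONS

    mids = []
    for met, nc in TCA_CARBONS.items():
        fractions = np.zeros(nc + 1)
        fractions[2] = p_m2
        if nc >= 4 and met != "citrate" and met != "akg":
            fractions[3] = p_m3
            fractions[0] = 1.0 - p_m2 - p_m3
        else:
            fractions[0] = 1.0 - p_m2
        raw = apply_natural_abundance(
            MID(met, fractions / fractions.sum(), nc, condition=condition, time_hr=time_hr)
        )
        vals = raw.fractions
        if noise_sd > 0:
            vals = np.clip(vals + rng.normal(0.0, noise_sd, size=vals.size), 0.0, None)
            vals = vals / vals.sum()
        mids.append(MID(met, vals, nc, condition=condition, time_hr=time_hr))
    return mids


def generate_mm_assay(
    v_max: float = 2.0e-4,
    k_m_mm: float = 10.4,
    substrate_grid_mm: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0),
    noise_frac: float = 0.05,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy Michaelis-Menten assay table, v = Vmax*S/(Km+S) * (1 + eps).

    Defaults mirror the DAAO characterisation: Vmax 2.0e-4 M/s per cell and
    Km 10.4 mM over a dose ladder of D-alanine.
    """
    if v_max <= 0 or k_m_mm <= 0:
        raise PreconditionError("v_max and k_m must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        for s in substrate_grid_mm:
            v = v_max * s / (k_m_mm + s)
            v_noisy = v * (1.0 + rng.normal(0.0, noise_frac)) if noise_frac > 0 else v
            rows.append({"replicate": rep, "substrate_mM": s, "rate": max(v_noisy, 0.0)})
    return pd.DataFrame(rows)
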