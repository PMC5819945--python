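"""Respirometry, gross-energy-intake and doubly-labelled-water calculations.

Open-flow respirometry: oxygen consumption from dry flow and the O2
fractions of incurrent and excurrent air,

    VO2 = FD · (FiO2 − FeO2) / (1 − FiO2 · (1 − RQ)),

with FD in l/h at STPD and the result converted to ml O2/h.  RQ defaults by
feeding state: 0.85 for animals fed ad libitum (mixed diet), 0.70 for
intermittently fasted animals (fat oxidation).

Gross energy intake: mass of food eaten × the caloric content of its
proximate composition (protein 23.3, fat 39.6, fibre/NFE 17.5 kJ/g; water
contributes nothing).

Doubly labelled water: total body water by isotope dilution, fat-free mass
via the 73.2% hydration coefficient, and CO2 production from the
differential elimination of 18O and 2H fitted over all post-equilibration
samples (multi-point protocol).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

HYDRATION_COEFFICIENT = 0.732
E_PROTEIN = 23.3   # kJ/g
E_FAT = 39.6       # kJ/g
E_NFE = 17.5       # kJ/g

RQ_AD_LIBITUM = 0.85
RQ_FASTED = 0.70

STANDARD_PRESSURE_KPA = 101.325
MOLAR_VOLUME_L = 22.414
WATER_MOLAR_MASS = 18.0153

# isotope dilution spaces exceed total body water by small fixed factors
DILUTION_SPACE_FACTOR_D = 1.041
DILUTION_SPACE_FACTOR_O = 1.007

# energy released per litre O2 / CO2 (Weir): EE[kJ] = 16.318·VO2[l] + 4.602·VCO2[l]
WEIR_O2 = 16.318
WEIR_CO2 = 4.602


@dataclass(frozen=True)
class RespirometryRecord:
    """One open-flow respirometry sample (flow at STPD, fractional O2)."""

    fd: float          # dry flow, l/h at STPD
    fio2: float        # fractional O2 in
    feo2: float        # fractional O2 out
    rq: float = RQ_AD_LIBITUM
    timestamp: float = 0.0  # min

    def __post_init__(self) -> None:
        if not 0 < self.fio2 < 1:
            raise ValueError("FiO2 must be a fraction in (0, 1)")
        if self.feo2 > self.fio2:
            raise ValueError("FeO2 exceeds FiO2: check for sensor drift")
        if self.feo2 <= 0:
            raise ValueError("FeO2 must be positive")
        if self.fd <= 0:
            raise ValueError("flow must be positive")
        if not 0.7 <= self.rq <= 1.0:
            raise ValueError("RQ must lie in [0.7, 1.0]")


@dataclass(frozen=True)
class DietComposition:
    """Proximate composition (mass fractions) and caloric constants."""

    fraction_protein: float
    fraction_fat: float
    fraction_nfe: float
    fraction_water: float
    e_protein: float = E_PROTEIN
    e_fat: float = E_FAT
    e_nfe: float = E_NFE

    def __post_init__(self) -> None:
        fracs = (self.fraction_protein, self.fraction_fat,
                 self.fraction_nfe, self.fraction_water)
        if any(f < 0 for f in fracs):
            raise ValueError("mass fractions must be non-negative")
        if sum(fracs) > 1 + 1e-9:
            raise ValueError("mass fractions sum to more than 1")
        if min(self.e_protein, self.e_fat, self.e_nfe) <= 0:
            raise ValueError("energy constants must be positive")

    @property
    def energy_density(self) -> float:
        """kJ per gram of fresh mass; water contributes nothing."""
        return (self.fraction_protein * self.e_protein
                + self.fraction_fat * self.e_fat
                + self.fraction_nfe * self.e_nfe)

    @classmethod
    def cat_food(cls) -> "DietComposition":
        """Pelleted cat food: 30% protein, 10% fat, 40% fibre/NFE, 9% water."""
        return cls(0.30, 0.10, 0.40, 0.09)

    @classmethod
    def apple(cls) -> "DietComposition":
        """Raw apple, USDA proximate composition per fresh mass."""
        return cls(0.003, 0.002, 0.137, 0.856)


@dataclass(frozen=True)
class DLWSampleSet:
    """Dose, background and post-dose enrichments for both isotopes.

    Enrichments are fractional isotope abundances; ``sample_times`` are days
    post-dose, strictly increasing, the first one taken as the equilibration
    (plateau) sample.
    """

    dose_mass: float               # g of dose water
    dose_enrichment_d: float
    dose_enrichment_o: float
    background_d: float
    background_o: float
    sample_times: np.ndarray       # days
    enrichment_d: np.ndarray
    enrichment_o: np.ndarray
    body_mass: float               # g

    def __post_init__(self) -> None:
        times = np.asarray(self.sample_times, dtype=float)
        ed = np.asarray(self.enrichment_d, dtype=float)
        eo = np.asarray(self.enrichment_o, dtype=float)
        object.__setattr__(self, "sample_times", times)
        object.__setattr__(self, "enrichment_d", ed)
        object.__setattr__(self, "enrichment_o", eo)
        if times.size < 2:
            raise ValueError("at least two post-dose samples required")
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(ed <= self.background_d) or np.any(eo <= self.background_o):
            raise ValueError("post-dose enrichments must exceed background")
        if self.dose_mass <= 0 or self.body_mass <= 0:
            raise ValueError("dose and body mass must be positive")


@dataclass(frozen=True)
class BodyComposition:
    tbw: float        # g
    ffm: float        # g
    fm: float         # g
    body_mass: float  # g
    fm_negative: bool = False


@dataclass(frozen=True)
class EnergyBudget:
    tee: float        # kJ/day
    rh2o: float       # g/day
    rco2: float       # mol/day
    k_o: float        # /day
    k_d: float        # /day
    n_o: float        # 18O dilution space, g
    n_d: float        # 2H dilution space, g
    rq: float
    equation: str
    valid: bool = True


def vo2(rec: RespirometryRecord) -> float:
    """Oxygen consumption in ml O2/h from one open-flow record."""
    lph = rec.fd * (rec.fio2 - rec.feo2) / (1 - rec.fio2 * (1 - rec.rq))
    return lph * 1000.0


def vo2_series(fd, fio2, feo2, rq: float = RQ_AD_LIBITUM) -> np.ndarray:
    """Vectorized open-flow VO2 (ml O2/h); inputs validated elementwise."""
    fd = np.asarray(fd, dtype=float)
    fio2 = np.asarray(fio2, dtype=float)
    feo2 = np.asarray(feo2, dtype=float)
    if np.any(feo2 > fio2):
        raise ValueError("FeO2 exceeds FiO2 in at least one record")
    if np.any(fd <= 0):
        raise ValueError("flow must be positive")
    return 1000.0 * fd * (fio2 - feo2) / (1 - fio2 * (1 - rq))


def stpd_correct(flow_measured: float, temp_c: float,
                 pressure_kpa: float = STANDARD_PRESSURE_KPA,
                 water_vapour_kpa: float = 0.0) -> float:
    """Convert a measured flow (l/h) to STPD (0 °C, 101.325 kPa, dry)."""
    if pressure_kpa <= 0:
        raise ValueError("pressure must be positive")
    dry = pressure_kpa - water_vapour_kpa
    if dry <= 0:
        raise ValueError("water vapour pressure at or above total pressure")
    return (flow_measured * (273.15 / (273.15 + temp_c))
            * (dry / STANDARD_PRESSURE_KPA))


def mr_summaries(times_min, vo2_ml_h, night_window=(1080.0, 360.0),
                 habituation_min: float = 1440.0):
    """ADMR, MR-day and MR-night (ml O2/h) from a VO2 time series.

    The first ``habituation_min`` minutes are excluded; the remaining samples
    are averaged with equal time weights over 24-h (ADMR), photophase
    (MR-day) and scotophase (MR-night) windows.
    """
    t = np.asarray(times_min, dtype=float)
    v = np.asarray(vo2_ml_h, dtype=float)
    keep = t >= habituation_min
    if not np.any(keep):
        raise ValueError("habituation exclusion removed every sample")
    t, v = t[keep], v[keep]
    minute = t % 1440.0
    ns, ne = night_window
    night = (minute >= ns) | (minute < ne)
    admr = float(v.mean())
    mr_night = float(v[night].mean()) if np.any(night) else float("nan")
    mr_day = float(v[~night].mean()) if np.any(~night) else float("nan")
    return admr, mr_day, mr_night


def gross_energy_intake(mass_eaten_g: float, diet: DietComposition) -> float:
    """Gross energy (kJ) in ``mass_eaten_g`` grams of food."""
    if mass_eaten_g < 0:
        raise ValueError("mass eaten cannot be negative")
    return mass_eaten_g * diet.energy_density


def fresh_equivalent_mass(remaining_g: float, dm_fraction_remaining: float,
                          dm_fraction_fresh: float) -> float:
    """Correct a leftover food mass for water loss since provisioning.

    Perishable items (apple) dry out between provisioning and weigh-back;
    comparing masses on a dry-matter basis avoids counting evaporated water
    as consumption.  Returns the fresh-mass equivalent of the leftover.
    """
    if not 0 < dm_fraction_fresh <= 1 or not 0 < dm_fraction_remaining <= 1:
        raise ValueError("dry-matter fractions must lie in (0, 1]")
    return remaining_g * dm_fraction_remaining / dm_fraction_fresh


def cumulative_energy(weekly_kj, n_weeks: int | None = None):
    """Cumulative intake Ecum (MJ) and weekly mean Ecum_mean (MJ/week).

    Missing weeks (NaN) are flagged and excluded from the sum, never
    zero-filled; ``n_weeks`` defaults to the series length and is the divisor
    for the weekly mean (the study-period length in weeks).
    """
    w = np.asarray(weekly_kj, dtype=float)
    if w.size == 0:
        raise ValueError("empty weekly energy series")
    missing = np.flatnonzero(np.isnan(w))
    ecum_mj = float(np.nansum(w)) / 1000.0
    if n_weeks is None:
        n_weeks = w.size
    return ecum_mj, ecum_mj / n_weeks, missing.tolist()


def _dilution_space_g(dose_mass: float, dose_enr: float, background: float,
                      excess: float) -> float:
    """Dilution space (g water) from dose dilution at a given excess."""
    if excess <= 0:
        raise ValueError("enrichment at or below background")
    return dose_mass * (dose_enr - background) / excess


def body_composition_from_dilution(s: DLWSampleSet) -> BodyComposition:
    """TBW, FFM and FM by the plateau (single-sample equilibration) method.

    TBW is the 18O dilution space divided by its space factor; FFM = TBW /
    0.732 (hydration coefficient); FM = body mass − FFM, flagged when
    negative.
    """
    plateau_excess = float(s.enrichment_o[0]) - s.background_o
    n_o = _dilution_space_g(s.dose_mass, s.dose_enrichment_o, s.background_o,
                            plateau_excess)
    tbw = n_o / DILUTION_SPACE_FACTOR_O
    ffm = tbw / HYDRATION_COEFFICIENT
    fm = s.body_mass - ffm
    flagged = fm < 0
    if flagged:
        warnings.warn("fat mass negative: TBW inconsistent with body mass",
                      stacklevel=2)
    return BodyComposition(tbw=tbw, ffm=ffm, fm=fm, body_mass=s.body_mass,
                           fm_negative=bool(flagged))


def _washout_fit(times: np.ndarray, enrichment: np.ndarray, background: float):
    """Least-squares slope of log excess enrichment vs time.

    Returns (k, equilibration_excess), the fitted excess evaluated at the
    first (plateau) sample time — isotope elimination starts at
    equilibration, so the dilution space is anchored there.  With exactly two
    samples this reduces to the closed-form two-point solution.
    """
    excess = enrichment - background
    res = stats.linregress(times, np.log(excess))
    e_plateau = math.exp(res.intercept + res.slope * float(times[0]))
    return -float(res.slope), float(e_plateau)


def dlw_energy_budget(s: DLWSampleSet, rq: float = RQ_AD_LIBITUM,
                      equation: str = "two_pool") -> EnergyBudget:
    """TEE, water turnover and CO2 production by the multi-point DLW method.

    Elimination constants come from log-linear fits over *all* post-dose
    samples; dilution spaces from the fitted initial excesses.  CO2
    production uses the two-pool equation with a fixed dilution-space ratio
    (Speakman 1997):

        rCO2 [mol/day] = (N/2.078)·(k_o − k_d) − 0.0062·k_d·N,

    with N the 18O dilution space in mol.  TEE converts rCO2 with the Weir
    factors at the supplied RQ; rH2O = k_d · N_d in g/day.  k_o ≤ k_d is
    physiologically invalid (negative CO2 production) and flags the budget.
    """
    if equation != "two_pool":
        raise ValueError("only the two-pool rCO2 equation is implemented")
    k_d, e0_d = _washout_fit(s.sample_times, s.enrichment_d, s.background_d)
    k_o, e0_o = _washout_fit(s.sample_times, s.enrichment_o, s.background_o)
    n_d = _dilution_space_g(s.dose_mass, s.dose_enrichment_d, s.background_d, e0_d)
    n_o = _dilution_space_g(s.dose_mass, s.dose_enrichment_o, s.background_o, e0_o)
    n_o_mol = n_o / WATER_MOLAR_MASS
    rco2 = (n_o_mol / 2.078) * (k_o - k_d) - 0.0062 * k_d * n_o_mol
    valid = k_o > k_d and rco2 > 0
    if not valid:
        warnings.warn("k_o <= k_d: CO2 production non-positive, budget flagged",
                      stacklevel=2)
    rco2_l = rco2 * MOLAR_VOLUME_L
    tee = rco2_l * (WEIR_O2 / rq + WEIR_CO2)
    rh2o = k_d * n_d
    return EnergyBudget(tee=float(tee), rh2o=float(rh2o), rco2=float(rco2),
                        k_o=k_o, k_d=k_d, n_o=n_o, n_d=n_d, rq=rq,
                        equation=equation, valid=bool(valid))
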