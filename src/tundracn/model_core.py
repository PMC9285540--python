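"""Core state, parameters, fluxes and mass-balance derivatives.

The model tracks five pools for a moist acidic tundra ecosystem — vegetation
carbon ``BC`` and nitrogen ``BN``, detritus + soil organic carbon ``DC`` and
nitrogen ``DN``, and inorganic nitrogen ``N`` — driven by atmospheric CO2,
temperature, external N inputs, and a prescribed small-mammal ("vole")
density.  Plant and microbial acquisition fluxes are regulated by an
allometric constraint S (a saturating function of vegetation C representing
effective photosynthesizing / absorbing surface) and by two stoichiometric
constraints, the ratios of actual to optimum C:N for vegetation (Psi) and
soil (Phi).  Six metabolic processes carry Q10 temperature multipliers;
vole ingestion and respiration instead *decline* with warming because less
energy is needed for thermoregulation.

Vole density is a driver (top-down controlled), carried in voles/ha; the
1/10,000 ha→m2 conversion lives only inside the three per-capita flux
equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)

__all__ = [
    "ParameterSet",
    "EcosystemState",
    "DriverState",
    "Diagnostics",
    "FluxSet",
    "PoolDerivatives",
    "DegenerateStateError",
    "DriverError",
    "TABLE1_STATE",
    "TABLE1_DRIVERS",
    "allometric_constraint",
    "stoichiometric_ratios",
    "compute_fluxes",
    "state_derivatives",
    "FLUX_NAMES",
    "STOCK_NAMES",
]


class DegenerateStateError(ValueError):
    """A pool needed as a divisor (BN or DN) is zero or negative."""


class DriverError(ValueError):
    """Driver values outside the model domain (Ca <= 0, V < 0, Nin < 0)."""


@dataclass(frozen=True, slots=True)
class ParameterSet:
    """All model parameters.

    Defaults are the published reference values for the aggregated
    (vole-implicit) calibration; :func:`tundracn.calibration.calibrate`
    re-derives the rate parameters in closed form from the flux targets so
    the reference state is an exact steady state.

    Units: rates yr^-1 unless noted; half-saturations kC in umol/mol, kN and
    kNm in gN/m2; C:N ratios gC/gN; per-capita vole rates per vole per year.
    """

    # allometry and stoichiometry
    alpha: float = 0.002231   # m2/gC
    gamma: float = 0.01100    # m2/gC
    qB: float = 42.62         # optimum vegetation C:N
    qD: float = 23.41         # optimum soil C:N
    # photosynthesis
    gC: float = 1.423
    kC: float = 100.0
    Q10Ps: float = 1.550
    # autotrophic respiration
    rB: float = 0.09069
    Q10Ra: float = 2.700
    # vegetation turnover
    mCB: float = 0.2449
    mNB: float = 0.2612
    # plant N uptake
    gN: float = 0.05191
    kN: float = 1.000
    Q10U: float = 2.000
    # heterotrophic respiration
    rD: float = 0.003651
    Q10Rh: float = 3.000
    # microbial N uptake (immobilization)
    gNm: float = 0.001796
    kNm: float = 1.000
    Q10Um: float = 1.950
    # soil organic N turnover (gross mineralization)
    mNm: float = 0.01099
    Q10m: float = 2.160
    # voles (per-capita, voles/ha basis with /10,000 inside the equations)
    nV: float = 22.0          # nesting material, gC/vole/yr
    gV: float = 3512.0        # ingestion, gC/vole/yr
    epsV: float = 52.0        # temperature slope of metabolism, gC/vole/degC/yr
    T0: float = 10.0          # summer-to-annual temperature offset, degC
    qV: float = 19.15         # C:N of forage + nest material
    rV: float = 0.3           # base respiration fraction of ingestion
    mNV: float = 11.00        # urine N, gN/vole/yr
    # losses
    qDOM: float = 14.69       # C:N of DOM loss
    betaN: float = 0.005926   # inorganic N loss rate
    betaNR: float = 0.0001581  # refractory N loss rate

    def __post_init__(self) -> None:
        positive = (
            "alpha gamma qB qD gC kC Q10Ps rB Q10Ra mCB mNB gN kN Q10U rD "
            "Q10Rh gNm kNm Q10Um mNm Q10m nV gV qV mNV qDOM betaN betaNR"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if not 0.0 < self.rV < 1.0:
            raise ValueError("rV must lie in (0, 1)")
        if self.qB <= self.qV:
            raise ValueError("qB must exceed qV (forage is N-richer than whole plant)")
        if self.epsV < 0:
            raise ValueError("epsV must be non-negative")


@dataclass(frozen=True, slots=True)
class EcosystemState:
    """The five pools (gC/m2 or gN/m2); defaults are the reference steady state."""

    BC: float = 878.0
    BN: float = 20.6
    DC: float = 19452.0
    DN: float = 831.0
    N: float = 0.27

    def __post_init__(self) -> None:
        for name in ("BC", "BN", "DC", "DN", "N"):
            if getattr(self, name) < 0:
                raise ValueError(f"pool {name} must be non-negative")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.BC, self.BN, self.DC, self.DN, self.N)


@dataclass(frozen=True, slots=True)
class DriverState:
    """Annual driver values: CO2 (umol/mol), temperature (degC on the
    summer-calibrated scale), N inputs (gN/m2/yr), vole density (voles/ha)."""

    Ca: float = 400.0
    T: float = 10.0
    Nin: float = 0.133
    V: float = 0.0

    def __post_init__(self) -> None:
        if self.Ca <= 0:
            raise DriverError("Ca must be strictly positive")
        if self.V < 0:
            raise DriverError("V must be non-negative")
        if self.Nin < 0:
            raise DriverError("Nin must be non-negative")


TABLE1_STATE = EcosystemState()
TABLE1_DRIVERS = DriverState()


@dataclass(frozen=True, slots=True)
class Diagnostics:
    """Constraint diagnostics: allometric surface S (gC/m2) and the
    dimensionless stoichiometric ratios Psi (vegetation) and Phi (soil)."""

    S: float
    Psi: float
    Phi: float


@dataclass(frozen=True, slots=True)
class FluxSet:
    """The 17 process rates plus derived production terms (per m2 per yr).

    Carbon: Ps photosynthesis, Ra autotrophic respiration, LitC litter-fall C,
    Rh heterotrophic (microbial) respiration, GC vole offtake from vegetation,
    RV vole respiration, LVC vole-mediated C input to soil, QCR refractory C
    loss.  Nitrogen: UN plant uptake, LitN litter-fall N, Nmin gross
    mineralization, UNm microbial immobilization, GN vole N offtake, LVN
    vole-mediated N input to soil, VUN vole urine N to the inorganic pool,
    QNR refractory N loss, QDIN inorganic N loss.  Derived: GPP = Ps,
    NPP = Ps - Ra, NEP = Ps - Ra - Rh - RV (net atmosphere-ecosystem C
    exchange; lateral losses QCR are reported separately).
    """

    Ps: float
    Ra: float
    LitC: float
    Rh: float
    GC: float
    RV: float
    LVC: float
    QCR: float
    UN: float
    LitN: float
    Nmin: float
    UNm: float
    GN: float
    LVN: float
    VUN: float
    QNR: float
    QDIN: float
    GPP: float
    NPP: float
    NEP: float


FLUX_NAMES = (
    "Ps", "Ra", "LitC", "Rh", "GC", "RV", "LVC", "QCR",
    "UN", "LitN", "Nmin", "UNm", "GN", "LVN", "VUN", "QNR", "QDIN",
    "GPP", "NPP", "NEP",
)
STOCK_NAMES = ("BC", "BN", "DC", "DN", "N")


@dataclass(frozen=True, slots=True)
class PoolDerivatives:
    """Annual mass-balance derivatives of the five pools."""

    dBC: float
    dBN: float
    dDC: float
    dDN: float
    dN: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.dBC, self.dBN, self.dDC, self.dDN, self.dN)

    def max_abs(self) -> float:
        return max(abs(v) for v in self.as_tuple())


def allometric_constraint(BC: float, params: ParameterSet) -> float:
    """Effective photosynthesizing/absorbing surface S (gC/m2).

    S = BC (alpha BC + 1) / (gamma BC + 1): linear in BC for small biomass,
    approaching the ratio alpha/gamma times BC for large biomass.
    """
    if BC < 0:
        raise ValueError("BC must be non-negative")
    return BC * (params.alpha * BC + 1.0) / (params.gamma * BC + 1.0)


def stoichiometric_ratios(
    state: EcosystemState, params: ParameterSet
) -> tuple[float, float]:
    """Return (Psi, Phi): actual-to-optimum C:N ratios for vegetation and soil.

    Both equal 1 at the calibration state; departures up- or down-regulate
    acquisition fluxes (C:N acclimation).
    """
    if state.BN <= 0 or state.DN <= 0:
        raise DegenerateStateError(
            "BN and DN must be strictly positive to evaluate C:N constraints"
        )
    if state.BC <= 0:
        raise DegenerateStateError(
            "BC must be strictly positive (Psi = 0 makes litter N unbounded)"
        )
    psi = (state.BC / state.BN) / params.qB
    phi = (state.DC / state.DN) / params.qD
    return psi, phi


def diagnostics(state: EcosystemState, params: ParameterSet) -> Diagnostics:
    """Bundle S, Psi, Phi for a state."""
    psi, phi = stoichiometric_ratios(state, params)
    return Diagnostics(S=allometric_constraint(state.BC, params), Psi=psi, Phi=phi)


def compute_fluxes(
    state: EcosystemState, drivers: DriverState, params: ParameterSet
) -> FluxSet:
    """Evaluate all process rates at one state under one set of drivers.

    Temperature enters plant/microbial processes as Q10**(T/10) multipliers
    (T on the summer-calibrated scale, 10 degC at calibration); vole ingestion
    and respiration decline linearly with warming above T0 and are floored at
    zero.  Stoichiometric regulation: Psi divides photosynthesis (rising
    plant C:N down-regulates C gain), multiplies plant N uptake and
    autotrophic respiration, and divides litter N; Phi multiplies microbial
    N uptake and heterotrophic respiration and divides gross mineralization.
    """
    p = params
    S = allometric_constraint(state.BC, p)
    psi, phi = stoichiometric_ratios(state, p)
    T = drivers.T
    tfac = T / 10.0

    Ps = p.gC / psi * S * drivers.Ca / (p.kC + drivers.Ca) * p.Q10Ps**tfac
    UN = p.gN * psi * S * state.N / (p.kN + state.N) * p.Q10U**tfac
    LitC = p.mCB * state.BC
    LitN = p.mNB * state.BN / psi
    Ra = p.rB * state.BC * psi * p.Q10Ra**tfac
    UNm = p.gNm * phi * state.DC * state.N / (p.kNm + state.N) * p.Q10Um**tfac

    # vole fluxes: per-capita rates on a voles/ha basis, /10,000 to m2
    v = drivers.V / 10_000.0
    percap = p.nV + p.gV - p.epsV * (T - p.T0)
    GC = max(percap, 0.0) * v
    GN = GC / p.qV
    RV = p.rV * max(GC - p.nV * v, 0.0)
    VUN = p.mNV * v
    LVC = GC - RV
    LVN = GN - VUN

    Rh = p.rD * state.DC * phi * p.Q10Rh**tfac
    Nmin = p.mNm * state.DN / phi * p.Q10m**tfac
    QNR = p.betaNR * state.DN
    QCR = p.qDOM * QNR
    QDIN = p.betaN * state.N

    GPP = Ps
    NPP = Ps - Ra
    NEP = Ps - Ra - Rh - RV
    return FluxSet(
        Ps=Ps, Ra=Ra, LitC=LitC, Rh=Rh, GC=GC, RV=RV, LVC=LVC, QCR=QCR,
        UN=UN, LitN=LitN, Nmin=Nmin, UNm=UNm, GN=GN, LVN=LVN, VUN=VUN,
        QNR=QNR, QDIN=QDIN, GPP=GPP, NPP=NPP, NEP=NEP,
    )


def state_derivatives(
    state: EcosystemState, fluxes: FluxSet, drivers: DriverState
) -> PoolDerivatives:
    """Annual mass-balance derivatives of the five pools.

    dBC = Ps - LitC - Ra - GC
    dBN = UN - LitN - GN
    dDC = LitC + LVC - Rh - QCR
    dDN = LitN + UNm + LVN - Nmin - QNR
    dN  = Nin + Nmin + VUN - UN - UNm - QDIN
    """
    f = fluxes
    return PoolDerivatives(
        dBC=f.Ps - f.LitC - f.Ra - f.GC,
        dBN=f.UN - f.LitN - f.GN,
        dDC=f.LitC + f.LVC - f.Rh - f.QCR,
        dDN=f.LitN + f.UNm + f.LVN - f.Nmin - f.QNR,
        dN=drivers.Nin + f.Nmin + f.VUN - f.UN - f.UNm - f.QDIN,
    )
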