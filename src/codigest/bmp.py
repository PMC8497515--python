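"""Theoretical biomethane potential (BMP) from proximate and ultimate analysis.

A substrate characterised by total solids (TS), volatile solids (VS) and the
elemental mass fractions C, H, N, S, O of its dry matter supports three
classical theoretical methane-yield estimates:

* **Buswell** (``bmp_buswell``): convert the composition to an empirical
  formula C_a H_b O_c N_d S_e and balance the Buswell–Boyle digestion
  reaction; the CH4 stoichiometric coefficient times the molar volume of an
  ideal gas (22,400 mL/mol at STP) gives mL CH4 per gram.
* **Forgacs** (``bmp_forgacs``): theoretical oxygen demand (ThOD, a COD
  surrogate) times the COD-to-methane equivalence of 350 mL CH4 per g O2.
* **Dulong** (``bmp_dulong``): higher heating value from the Dulong formula,
  divided by the volumetric energy density of methane (37.78 MJ/m3).

All per-gram quantities are computed per gram TS and divided by the VS/TS
fraction to express them per gram VS, the basis on which digestion yields are
conventionally reported.  The numeric constants live in
:class:`BMPConstants` and can be overridden.

The module also provides the additive mixture model for co-digestion
(VS-weighted mean of component BMPs) and the synergy index
observed/expected, whose value above 1 marks a synergistic mixture.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import CompositionError, ValidationError

__all__ = [
    "UltimateAnalysis",
    "EmpiricalFormula",
    "BuswellCoefficients",
    "BMPConstants",
    "BMPResult",
    "DEFAULT_CONSTANTS",
    "validate_ultimate_analysis",
    "empirical_formula",
    "buswell_stoichiometry",
    "thod",
    "hhv_dulong",
    "bmp_buswell",
    "bmp_forgacs",
    "bmp_dulong",
    "characterize",
    "mixture_bmp",
    "synergy_index",
]

# Integer atomic masses; the classical BMP formulas are defined with these.
MASS_C, MASS_H, MASS_O, MASS_N, MASS_S = 12.0, 1.0, 16.0, 14.0, 32.0

_ELEMENTS = ("c", "h", "n", "s", "o")


@dataclass(frozen=True)
class BMPConstants:
    """Physical constants and empirical coefficients used by the BMP models.

    molar_volume
        mL of CH4 per mole at standard temperature and pressure.
    cod_to_ch4
        mL CH4 produced per gram of chemical oxygen demand removed.
    ch4_energy_density
        MJ per cubic metre of methane (higher heating basis).
    dulong_c/h/s/n
        Dulong-formula coefficients, kJ/kg per mass-percent of C,
        (H - O/8), S and N respectively.
    """

    molar_volume: float = 22_400.0
    cod_to_ch4: float = 350.0
    ch4_energy_density: float = 37.78
    dulong_c: float = 337.0
    dulong_h: float = 1419.0
    dulong_s: float = 93.0
    dulong_n: float = 23.26

    def __post_init__(self) -> None:
        for name in (
            "molar_volume",
            "cod_to_ch4",
            "ch4_energy_density",
            "dulong_c",
            "dulong_h",
            "dulong_s",
            "dulong_n",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"BMP constant {name!r} must be strictly positive")

    def as_provenance(self) -> str:
        """Compact ``key=value`` string naming the constants used in an output file."""
        return ";".join(
            f"{k}={getattr(self, k):g}"
            for k in (
                "molar_volume",
                "cod_to_ch4",
                "ch4_energy_density",
                "dulong_c",
                "dulong_h",
                "dulong_s",
                "dulong_n",
            )
        )


DEFAULT_CONSTANTS = BMPConstants()


@dataclass(frozen=True)
class UltimateAnalysis:
    """Proximate plus elemental composition of one substrate.

    ``ts`` is the total-solids fraction of wet mass, ``vs_of_ts`` the
    volatile-solids fraction of TS, and ``c``..``o`` are mass fractions of TS
    (their sum may be below 1; the remainder is ash).  ``sd`` optionally
    carries per-field standard deviations on the same fraction scale.
    """

    name: str
    ts: float
    vs_of_ts: float
    c: float
    h: float
    n: float
    s: float
    o: float
    sd: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for fname in ("ts", "vs_of_ts", "c", "h", "n", "s", "o"):
            value = getattr(self, fname)
            if not math.isfinite(value):
                raise ValidationError(f"{self.name}: field {fname!r} is not finite")
            if value < 0:
                raise ValidationError(f"{self.name}: field {fname!r} is negative ({value})")
        if not 0 < self.ts <= 1:
            raise ValidationError(f"{self.name}: ts must be in (0, 1], got {self.ts}")
        if not 0 < self.vs_of_ts <= 1:
            raise ValidationError(
                f"{self.name}: vs_of_ts must be in (0, 1], got {self.vs_of_ts}"
            )
        for fname in _ELEMENTS:
            if getattr(self, fname) >= 1:
                raise ValidationError(f"{self.name}: field {fname!r} must be below 1")
        total = self.elemental_sum
        if total > 1 + 1e-9:
            raise ValidationError(
                f"{self.name}: elemental mass fractions sum to {total:.4f} > 1"
            )
        if total <= 0:
            raise ValidationError(f"{self.name}: all elemental fractions are zero")

    @property
    def elemental_sum(self) -> float:
        return self.c + self.h + self.n + self.s + self.o


def validate_ultimate_analysis(raw: Mapping[str, object]) -> UltimateAnalysis:
    """Build a validated :class:`UltimateAnalysis` from a row of percentages.

    Expects the conventional reporting scales: ``ts_pct`` as % of wet mass,
    ``vs_pct_ts`` as % of TS, and ``c_pct``..``o_pct`` as % of TS.  Optional
    ``*_sd`` keys carry standard deviations on the same percent scales.
    """
    try:
        name = str(raw["name"])
        values = {
            "ts": float(raw["ts_pct"]) / 100.0,  # type: ignore[arg-type]
            "vs_of_ts": float(raw["vs_pct_ts"]) / 100.0,  # type: ignore[arg-type]
        }
        for el in _ELEMENTS:
            values[el] = float(raw[f"{el}_pct"]) / 100.0  # type: ignore[arg-type]
    except KeyError as exc:
        raise ValidationError(f"substrate row is missing required field {exc}") from exc
    sd = None
    sd_keys = {k for k in raw if str(k).endswith("_sd")}
    if sd_keys:
        sd = {str(k)[: -len("_sd")]: float(raw[k]) / 100.0 for k in sorted(sd_keys)}  # type: ignore[arg-type]
    return UltimateAnalysis(name=name, sd=sd, **values)


@dataclass(frozen=True)
class EmpiricalFormula:
    """Molar subscripts of C_a H_b O_c N_d S_e.

    ``normalized_to`` records the element whose subscript was scaled to 1:
    sulfur by default, carbon when the composition is sulfur-free.
    """

    a_c: float
    b_h: float
    c_o: float
    d_n: float
    e_s: float
    normalized_to: str = "S"

    def __post_init__(self) -> None:
        for fname in ("a_c", "b_h", "c_o", "d_n", "e_s"):
            if getattr(self, fname) < 0:
                raise ValidationError(f"formula subscript {fname!r} is negative")
        if self.molar_mass <= 0:
            raise ValidationError("empirical formula has non-positive molar mass")

    @property
    def molar_mass(self) -> float:
        """Gram per mole of one formula unit (integer atomic masses)."""
        return (
            MASS_C * self.a_c
            + MASS_H * self.b_h
            + MASS_O * self.c_o
            + MASS_N * self.d_n
            + MASS_S * self.e_s
        )

    def __str__(self) -> str:
        def sub(symbol: str, value: float) -> str:
            if value == 0:
                return ""
            if abs(value - round(value)) < 1e-9:
                value = round(value)
                return symbol if value == 1 else f"{symbol}{value:d}"
            return f"{symbol}{value:.3f}"

        return "".join(
            sub(sym, v)
            for sym, v in (
                ("C", self.a_c),
                ("H", self.b_h),
                ("O", self.c_o),
                ("N", self.d_n),
                ("S", self.e_s),
            )
        )


def empirical_formula(ua: UltimateAnalysis, integer: bool = False) -> EmpiricalFormula:
    """Molar-ratio empirical formula of the dry organic matter.

    Ratios are C/12 : H/1 : O/16 : N/14 : S/32, rescaled so that the sulfur
    subscript equals 1.  For sulfur-free compositions the formula is
    normalized to carbon instead (a = 1) and a warning is emitted, since the
    S-normalized form is undefined.  With ``integer=True`` subscripts are
    rounded to the nearest integer after scaling.
    """
    moles = {
        "a_c": ua.c / MASS_C,
        "b_h": ua.h / MASS_H,
        "c_o": ua.o / MASS_O,
        "d_n": ua.n / MASS_N,
        "e_s": ua.s / MASS_S,
    }
    if ua.s > 0:
        scale = moles["e_s"]
        normalized_to = "S"
    else:
        warnings.warn(
            f"{ua.name}: sulfur-free composition; normalizing empirical formula "
            "to carbon (a=1) instead of sulfur",
            stacklevel=2,
        )
        if moles["a_c"] <= 0:
            raise CompositionError(f"{ua.name}: carbon-free, sulfur-free composition")
        scale = moles["a_c"]
        normalized_to = "C"
    subscripts = {k: v / scale for k, v in moles.items()}
    if integer:
        subscripts = {k: float(round(v)) for k, v in subscripts.items()}
    return EmpiricalFormula(normalized_to=normalized_to, **subscripts)


@dataclass(frozen=True)
class BuswellCoefficients:
    """Stoichiometric coefficients of the Buswell–Boyle digestion reaction.

    C_a H_b O_c N_d S_e + water·H2O -> ch4·CH4 + co2·CO2 + nh3·NH3 + h2s·H2S
    """

    water: float
    ch4: float
    co2: float
    nh3: float
    h2s: float


def buswell_stoichiometry(f: EmpiricalFormula) -> BuswellCoefficients:
    """Balance the Buswell–Boyle reaction for an empirical formula.

    Raises :class:`CompositionError` when the composition is too oxidized to
    yield methane (negative CH4 coefficient).
    """
    a, b, c, d, e = f.a_c, f.b_h, f.c_o, f.d_n, f.e_s
    water = a - b / 4 - c / 2 + 3 * d / 4 + e / 2
    ch4 = a / 2 + b / 8 - c / 4 - 3 * d / 8 - e / 4
    co2 = a / 2 - b / 8 + c / 4 + 3 * d / 8 + e / 4
    if ch4 < 0:
        raise CompositionError("composition too oxidized to yield methane")
    return BuswellCoefficients(water=water, ch4=ch4, co2=co2, nh3=d, h2s=e)


def thod(ua: UltimateAnalysis) -> float:
    """Theoretical oxygen demand in g O2 per g VS.

    Oxidation basis: C -> CO2, H -> H2O, N -> NH3 (nitrogen is *not*
    oxidized, it consumes hydrogen as ammonia); sulfur is left unoxidized.
    Per gram TS the O2 requirement is 32·(C/12 + H/4 - O/32 - 3N/56) with
    mass fractions of TS, then divided by VS/TS.
    """
    mol_o2_per_g_ts = ua.c / 12 + ua.h / 4 - ua.o / 32 - 3 * ua.n / 56
    if mol_o2_per_g_ts < 0:
        raise CompositionError(f"{ua.name}: composition already fully oxidized")
    return 32.0 * mol_o2_per_g_ts / ua.vs_of_ts


def hhv_dulong(ua: UltimateAnalysis, constants: BMPConstants = DEFAULT_CONSTANTS) -> float:
    """Higher heating value by the Dulong formula, MJ per tonne TS (= kJ/kg).

    HHV = 337·C% + 1419·(H% - O%/8) + 93·S% + 23.26·N% with percentages of TS.
    """
    value = (
        constants.dulong_c * ua.c * 100
        + constants.dulong_h * (ua.h * 100 - ua.o * 100 / 8)
        + constants.dulong_s * ua.s * 100
        + constants.dulong_n * ua.n * 100
    )
    if value <= 0:
        raise CompositionError(f"{ua.name}: non-combustible composition")
    return value


def bmp_buswell(ua: UltimateAnalysis, constants: BMPConstants = DEFAULT_CONSTANTS) -> float:
    """Buswell–Boyle BMP in mL CH4 per g VS.

    The mass-fraction form C/24 + H/8 - O/64 - 3N/112 - S/128 is the CH4
    stoichiometric coefficient per gram of TS; multiplying by the molar
    volume and dividing by VS/TS yields the per-VS methane volume.
    """
    mol_ch4_per_g_ts = ua.c / 24 + ua.h / 8 - ua.o / 64 - 3 * ua.n / 112 - ua.s / 128
    if mol_ch4_per_g_ts < 0:
        raise CompositionError(f"{ua.name}: composition too oxidized to yield methane")
    return constants.molar_volume * mol_ch4_per_g_ts / ua.vs_of_ts


def bmp_forgacs(ua: UltimateAnalysis, constants: BMPConstants = DEFAULT_CONSTANTS) -> float:
    """COD-equivalence BMP: 350 mL CH4 per g O2 times the ThOD, mL CH4/g VS."""
    return constants.cod_to_ch4 * thod(ua)


def bmp_dulong(ua: UltimateAnalysis, constants: BMPConstants = DEFAULT_CONSTANTS) -> float:
    """Calorific BMP: Dulong HHV divided by the energy density of methane.

    MJ/t divided by MJ/m3 gives m3 per tonne, numerically equal to mL per
    gram.  Note the division is by the TS-based heating value with no
    further VS correction; see the package methods note for the reporting
    basis of this quantity.
    """
    return bmp_dulong_from_hhv(hhv_dulong(ua, constants), constants)


def bmp_dulong_from_hhv(hhv: float, constants: BMPConstants = DEFAULT_CONSTANTS) -> float:
    """Dulong-route BMP from an already-known HHV in MJ/t."""
    return hhv / constants.ch4_energy_density


@dataclass(frozen=True)
class BMPResult:
    """Bundle of the derived quantities for one substrate."""

    name: str
    formula: EmpiricalFormula
    thod: float
    hhv: float
    bmp_f: float
    bmp_b: float
    bmp_d: float

    def bmp(self, model: str) -> float:
        """BMP value for model letter ``f`` (Forgacs), ``b`` (Buswell) or ``d`` (Dulong)."""
        try:
            return {"f": self.bmp_f, "b": self.bmp_b, "d": self.bmp_d}[model.lower()]
        except KeyError:
            raise ValidationError(f"unknown BMP model {model!r}; expected one of f, b, d")


def characterize(
    ua: UltimateAnalysis, constants: BMPConstants = DEFAULT_CONSTANTS
) -> BMPResult:
    """Full theoretical characterization of one substrate.

    Computes the empirical formula, ThOD, Dulong HHV and all three BMPs.
    Errors raised by any component carry the substrate name.
    """
    t = thod(ua)
    hhv = hhv_dulong(ua, constants)
    return BMPResult(
        name=ua.name,
        formula=empirical_formula(ua),
        thod=t,
        hhv=hhv,
        bmp_f=constants.cod_to_ch4 * t,
        bmp_b=bmp_buswell(ua, constants),
        bmp_d=bmp_dulong_from_hhv(hhv, constants),
    )


def mixture_bmp(components: Iterable[tuple[float, float]]) -> float:
    """Additive mixture BMP: VS-weighted mean of component BMPs.

    ``components`` is a sequence of ``(bmp_mL_per_gVS, vs_mass_share)``
    pairs.  Shares must be positive and sum to 1; deviations up to 1e-6 are
    renormalized with a warning, larger ones are rejected.
    """
    comps: Sequence[tuple[float, float]] = list(components)
    if not comps:
        raise ValidationError("mixture_bmp requires at least one component")
    shares = [share for _, share in comps]
    if any(share <= 0 for share in shares):
        raise ValidationError("mixture shares must be strictly positive")
    total = sum(shares)
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"mixture shares sum to {total:.8f}, expected 1")
    if total != 1.0:
        warnings.warn(
            f"mixture shares sum to {total!r}; renormalizing to 1", stacklevel=2
        )
    return sum(bmp * share for bmp, share in comps) / total


def synergy_index(observed_bmp: float, expected_bmp: float) -> float:
    """Ratio of observed mixture BMP to the additive expectation.

    Values above 1 indicate synergy, below 1 antagonism.
    """
    if expected_bmp <= 0:
        raise ValidationError(f"expected BMP must be positive, got {expected_bmp}")
    return observed_bmp / expected_bmp
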