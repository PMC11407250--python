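"""Wavelength-dependent tissue optical properties.

Absorption is composed from hemoglobin, water, fat and melanin contributions;
reduced scattering follows a power-law decay referenced to 500 nm.  The fetal
cardiac pulse is modelled as a fractional increase of the arterial blood
compartment in fetal brain and muscle.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .phantom import FLUID_LABELS, PULSATILE_LABELS, TetMesh, TissueLabel

#: reference wavelength (nm) for the scattering power law
LAMBDA0 = 500.0

#: simulation wavelength set (nm)
DEFAULT_WAVELENGTHS = (730.0, 750.0, 770.0, 790.0, 810.0, 830.0, 850.0)


class CardiacPhase(str, enum.Enum):
    STATIC = "static"
    DIASTOLE = "diastole"
    SYSTOLE = "systole"


class ChromophoreTable:
    """Extinction/absorption spectra on a uniform wavelength grid.

    Columns: eps_HbO, eps_Hb in cm^-1 uM^-1; mua_water, mua_fat, mua_melanin
    in cm^-1.  Lookups interpolate linearly and refuse to extrapolate.
    """

    def __init__(self, wavelengths, eps_hbo, eps_hb, mua_water, mua_fat,
                 mua_melanin):
        self.wavelengths = np.asarray(wavelengths, dtype=float)
        self.eps_hbo = np.asarray(eps_hbo, dtype=float)
        self.eps_hb = np.asarray(eps_hb, dtype=float)
        self.mua_water = np.asarray(mua_water, dtype=float)
        self.mua_fat = np.asarray(mua_fat, dtype=float)
        self.mua_melanin = np.asarray(mua_melanin, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        for name in ("eps_hbo", "eps_hb", "mua_water", "mua_fat",
                     "mua_melanin"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} contains negative values")

    @classmethod
    def default(cls) -> "ChromophoreTable":
        path = resources.files("fetaldot.data").joinpath("chromophores.csv")
        lines = [
            ln for ln in path.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        data = np.loadtxt(lines[1:], delimiter=",")  # lines[0] is the header
        return cls(*(data[:, i] for i in range(6)))

    def _interp(self, column: np.ndarray, lam: float) -> float:
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not lo <= lam <= hi:
            raise ValueError(
                f"wavelength {lam} nm outside table range [{lo}, {hi}]"
            )
        return float(np.interp(lam, self.wavelengths, column))

    def __call__(self, lam: float) -> dict[str, float]:
        return {
            "eps_hbo": self._interp(self.eps_hbo, lam),
            "eps_hb": self._interp(self.eps_hb, lam),
            "mua_water": self._interp(self.mua_water, lam),
            "mua_fat": self._interp(self.mua_fat, lam),
            "mua_melanin": self._interp(self.mua_melanin, lam),
        }


_DEFAULT_TABLE: ChromophoreTable | None = None


def default_table() -> ChromophoreTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = ChromophoreTable.default()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class TissueOpticalParams:
    """Per-tissue inputs for the absorption/scattering models.

    Maternal tissues carry a single ``sto2``; fetal tissues carry arterial
    and venous saturations with 25 / 75 % compartment split.  ``vp`` is the
    fractional arterial volume increase at systole (fetal brain/muscle only).
    """

    hbt: float  # uM
    v_water: float
    v_fat: float
    v_melanin: float
    a: float  # mus' at 500 nm, cm^-1
    b: float  # scattering power
    n: float  # refractive index
    sto2: float | None = None
    sao2: float | None = None
    svo2: float | None = None
    va: float = 0.25
    vv: float = 0.75
    vp: float = 0.0

    def __post_init__(self):
        for name in ("sto2", "sao2", "svo2"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("v_water", "v_fat", "v_melanin"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(self.va + self.vv - 1.0) > 1e-12:
            raise ValueError("va + vv must equal 1")
        if self.a <= 0:
            raise ValueError("scattering amplitude a must be > 0")
        if self.hbt < 0:
            raise ValueError("hbt must be >= 0")


# Per-tissue parameter database.  Amniotic fluid and CSF are handled by the
# water override in assign_properties; their entries only carry n.
DEFAULT_TISSUE_PARAMS: dict[TissueLabel, TissueOpticalParams] = {
    TissueLabel.MATERNAL_FAT: TissueOpticalParams(
        hbt=12.2, sto2=0.75, v_water=0.23, v_fat=0.72, v_melanin=0.0,
        a=9.69, b=0.81, n=1.4),
    TissueLabel.MATERNAL_MUSCLE_UTERUS: TissueOpticalParams(
        hbt=26.2, sto2=0.75, v_water=0.76, v_fat=0.0, v_melanin=0.0,
        a=15.42, b=0.89, n=1.4),
    TissueLabel.FETAL_BRAIN: TissueOpticalParams(
        hbt=39.7, sao2=0.50, svo2=0.40, v_water=0.76, v_fat=0.0,
        v_melanin=0.0, a=22.52, b=1.56, n=1.3, vp=0.05),
    TissueLabel.FETAL_SKULL_SPINAL: TissueOpticalParams(
        hbt=39.7, sao2=0.50, svo2=0.40, v_water=0.16, v_fat=0.0,
        v_melanin=0.0, a=22.90, b=0.72, n=1.3, vp=0.0),
    TissueLabel.FETAL_MUSCLE: TissueOpticalParams(
        hbt=33.5, sao2=0.50, svo2=0.40, v_water=0.76, v_fat=0.0,
        v_melanin=0.0, a=15.42, b=0.89, n=1.3, vp=0.05),
}

FLUID_MUSP = 0.1  # cm^-1, both clear-fluid compartments
FLUID_N = 1.33


def _background(params: TissueOpticalParams, chromo: dict[str, float]) -> float:
    return (params.v_water * chromo["mua_water"]
            + params.v_fat * chromo["mua_fat"]
            + params.v_melanin * chromo["mua_melanin"])


def mua_static(params: TissueOpticalParams, lam: float,
               table: ChromophoreTable | None = None) -> float:
    """Absorption coefficient (cm^-1) of a tissue with a single StO2."""
    if params.sto2 is None:
        raise ValueError("mua_static requires sto2")
    table = table or default_table()
    c = table(lam)
    hb_term = (params.hbt * params.sto2 * c["eps_hbo"]
               + params.hbt * (1.0 - params.sto2) * c["eps_hb"])
    return hb_term + _background(params, c)


def mua_pulsatile(params: TissueOpticalParams, lam: float,
                  phase: CardiacPhase | str,
                  table: ChromophoreTable | None = None) -> float:
    """Fetal absorption (cm^-1) with an arterial/venous compartment split.

    At systole the arterial compartment is inflated by the pulsatile volume
    fraction ``vp``; at diastole it is not.
    """
    if params.sao2 is None or params.svo2 is None:
        raise ValueError("mua_pulsatile requires sao2 and svo2")
    phase = CardiacPhase(phase)
    if phase is CardiacPhase.STATIC:
        raise ValueError("pulsatile phase must be diastole or systole")
    table = table or default_table()
    c = table(lam)
    hbo_a = params.hbt * params.va * params.sao2
    hb_a = params.hbt * params.va * (1.0 - params.sao2)
    hbo_v = params.hbt * params.vv * params.svo2
    hb_v = params.hbt * params.vv * (1.0 - params.svo2)
    gain = 1.0 + params.vp if phase is CardiacPhase.SYSTOLE else 1.0
    hb_term = ((hbo_a * gain + hbo_v) * c["eps_hbo"]
               + (hb_a * gain + hb_v) * c["eps_hb"])
    return hb_term + _background(params, c)


def musp(a: float, b: float, lam: float, lam0: float = LAMBDA0) -> float:
    """Reduced scattering coefficient (cm^-1): a * (lam/lam0)^(-b)."""
    if a <= 0:
        raise ValueError("a must be > 0")
    if lam <= 0:
        raise ValueError("wavelength must be > 0")
    return a * (lam / lam0) ** (-b)


@dataclass
class PropertyField:
    """Per-element optical properties at one wavelength and cardiac phase."""

    wavelength: float
    phase: CardiacPhase
    mua: np.ndarray  # cm^-1, per element
    musp: np.ndarray  # cm^-1, per element
    n: np.ndarray  # per element

    def __post_init__(self):
        self.mua = np.asarray(self.mua, dtype=float)
        self.musp = np.asarray(self.musp, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if np.any(self.mua < 0):
            raise ValueError("mua must be non-negative")
        if np.any(self.musp <= 0):
            raise ValueError("musp must be positive")

    @property
    def kappa(self) -> np.ndarray:
        """Diffusion coefficient 1/(3(mua + musp)), cm."""
        return 1.0 / (3.0 * (self.mua + self.musp))

    def scaled_mua(self, factor: float) -> "PropertyField":
        return replace(self, mua=self.mua * factor)


def assign_properties(
    mesh: TetMesh,
    lam: float,
    phase: CardiacPhase | str = CardiacPhase.DIASTOLE,
    param_db: dict[TissueLabel, TissueOpticalParams] | None = None,
    table: ChromophoreTable | None = None,
) -> PropertyField:
    """Map tissue labels to per-element (mua, musp, n) at one wavelength.

    Clear fluids (amniotic fluid, CSF) get water absorption, musp = 0.1 cm^-1
    and n = 1.33.  Maternal tissues are static; fetal brain and muscle follow
    the pulsatile model; fetal skull/spinal uses the diastolic-form fetal
    absorption at every phase.
    """
    phase = CardiacPhase(phase)
    param_db = param_db or DEFAULT_TISSUE_PARAMS
    table = table or default_table()
    chromo = table(lam)

    ne = mesh.num_elements
    mua = np.empty(ne)
    mus = np.empty(ne)
    n = np.empty(ne)
    for lab in np.unique(mesh.element_labels):
        label = TissueLabel(lab)
        mask = mesh.element_labels == lab
        if label in FLUID_LABELS:
            mua[mask] = chromo["mua_water"]
            mus[mask] = FLUID_MUSP
            n[mask] = FLUID_N
            continue
        try:
            p = param_db[label]
        except KeyError:
            raise KeyError(f"no optical parameters for tissue {label!r}")
        if p.sto2 is not None:
            mua[mask] = mua_static(p, lam, table)
        elif label in PULSATILE_LABELS:
            ph = CardiacPhase.DIASTOLE if phase is CardiacPhase.STATIC else phase
            mua[mask] = mua_pulsatile(p, lam, ph, table)
        else:
            # non-pulsing fetal tissue: diastolic form at both phases
            mua[mask] = mua_pulsatile(p, lam, CardiacPhase.DIASTOLE, table)
        mus[mask] = musp(p.a, p.b, lam)
        n[mask] = p.n
    return PropertyField(wavelength=lam, phase=phase, mua=mua, musp=mus, n=n)
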