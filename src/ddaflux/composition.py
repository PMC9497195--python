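"""Cell inventory and elemental quotas of a diatom-diazotroph association (DDA).

A DDA couples one diatom host with a small number of cyanobacterial
filaments (trichomes), each built from photosynthesising vegetative cells
plus a single heterocyst specialised in N2 fixation.  Cellular carbon
content is estimated from cell volume with log-log allometric regressions
(pg C per cell as a power law of volume in µm³) and converted to nitrogen
with a single Redfield-type C:N molar ratio applied to every compartment.

Quotas are stored *pooled per association*: one value for the diatom, one
for all vegetative cells together and one for all heterocysts together,
because the mass balances operate on per-association sums.  Per-cell values
are recovered by dividing by the cell counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "CellClass",
    "AllometricCoefficients",
    "DDAComposition",
    "Quotas",
    "carbon_quota_from_volume",
    "build_quotas",
    "DEFAULT_ALLOMETRY",
    "DEFAULT_COMPOSITION",
    "PG_C_PER_PMOL",
    "DEFAULT_RCN",
]

#: grams per mole of carbon scaled to pg per pmol.
PG_C_PER_PMOL = 12.011

#: canonical marine (Redfield) C:N molar ratio used for all compartments.
DEFAULT_RCN = 6.6


class CellClass(str, Enum):
    """The three cell classes of the association.

    Heterocysts never photosynthesise; the diatom and vegetative cells
    never fix N2.
    """

    DIATOM = "diatom"
    VEGETATIVE = "vegetative"
    HETEROCYST = "heterocyst"


@dataclass(frozen=True)
class AllometricCoefficients:
    """Per-class volume-to-carbon regressions, log10(pg C) = a + b·log10(V).

    Defaults: the large-diatom regression for the diatom host (its volume
    is well above the large-cell breakpoint) and the general protist
    regression for the small cyanobacterial cells.
    """

    diatom: tuple[float, float] = (-0.933, 0.881)
    vegetative: tuple[float, float] = (-0.665, 0.939)
    heterocyst: tuple[float, float] = (-0.665, 0.939)

    def __post_init__(self) -> None:
        for cls in CellClass:
            _, exponent = self.coefficients(cls)
            if exponent <= 0:
                raise ValueError(
                    f"allometric exponent for {cls.value} must be > 0, got {exponent}"
                )

    def coefficients(self, cell_class: CellClass) -> tuple[float, float]:
        """Return ``(log10-intercept, exponent)`` for one cell class."""
        return getattr(self, CellClass(cell_class).value)


@dataclass(frozen=True)
class DDAComposition:
    """Cell counts and per-cell volumes (µm³) of one association.

    Defaults are the typical Hemiaulus-Richelia configuration: one diatom
    hosting two trichomes, each of four vegetative cells and one heterocyst.
    """

    n_trichomes: int = 2
    vegetative_per_trichome: int = 4
    heterocysts_per_trichome: int = 1
    volume_diatom: float = 3493.5
    volume_vegetative: float = 18.8
    volume_heterocyst: float = 61.0

    def __post_init__(self) -> None:
        for name in ("n_trichomes", "vegetative_per_trichome", "heterocysts_per_trichome"):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool) or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        for name in ("volume_diatom", "volume_vegetative", "volume_heterocyst"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")

    @property
    def n_vegetative(self) -> int:
        return self.n_trichomes * self.vegetative_per_trichome

    @property
    def n_heterocysts(self) -> int:
        return self.n_trichomes * self.heterocysts_per_trichome


@dataclass(frozen=True)
class Quotas:
    """Pooled elemental quotas per association (pmol C / pmol N).

    ``qcd``/``qnd`` refer to the diatom, ``qcv``/``qnv`` to all vegetative
    cells together and ``qch``/``qnh`` to all heterocysts together.
    """

    qcd: float
    qcv: float
    qch: float
    qnd: float
    qnv: float
    qnh: float

    def __post_init__(self) -> None:
        for name in ("qcd", "qcv", "qch", "qnd", "qnv", "qnh"):
            if not getattr(self, name) > 0:
                raise ValueError(f"quota {name} must be > 0")

    @property
    def total_carbon(self) -> float:
        return self.qcd + self.qcv + self.qch

    @property
    def total_nitrogen(self) -> float:
        return self.qnd + self.qnv + self.qnh

    @property
    def trichome_carbon(self) -> float:
        return self.qcv + self.qch

    @property
    def diatom_carbon_fraction(self) -> float:
        return self.qcd / self.total_carbon

    def scaled(self, factor: float) -> "Quotas":
        """All six quotas multiplied by ``factor`` (> 0)."""
        return Quotas(*(getattr(self, f) * factor for f in
                        ("qcd", "qcv", "qch", "qnd", "qnv", "qnh")))


DEFAULT_ALLOMETRY = AllometricCoefficients()
DEFAULT_COMPOSITION = DDAComposition()


def carbon_quota_from_volume(
    volume: float,
    cell_class: CellClass,
    coeffs: AllometricCoefficients = DEFAULT_ALLOMETRY,
) -> float:
    """Carbon content of a single cell, in pmol C.

    Applies the class-specific power law ``pg C = 10^a · V^b`` and converts
    pg C to pmol C with the molar mass of carbon.

    Parameters
    ----------
    volume : float
        Cell volume in µm³; must be > 0.
    cell_class : CellClass
        Which regression to apply.
    coeffs : AllometricCoefficients
        The regression table.
    """
    if not volume > 0:
        raise ValueError(f"cell volume must be > 0, got {volume!r}")
    intercept, exponent = coeffs.coefficients(cell_class)
    pg_c = 10.0 ** (intercept + exponent * math.log10(volume))
    return pg_c / PG_C_PER_PMOL


def build_quotas(
    comp: DDAComposition = DEFAULT_COMPOSITION,
    coeffs: AllometricCoefficients = DEFAULT_ALLOMETRY,
    rcn: float = DEFAULT_RCN,
) -> Quotas:
    """Pooled C and N quotas of one association.

    Vegetative and heterocyst pools scale linearly with the trichome count;
    N quotas are C quotas divided by the C:N ratio ``rcn``.
    """
    if not rcn > 0:
        raise ValueError(f"rcn must be > 0, got {rcn!r}")
    qcd = carbon_quota_from_volume(comp.volume_diatom, CellClass.DIATOM, coeffs)
    qcv = comp.n_vegetative * carbon_quota_from_volume(
        comp.volume_vegetative, CellClass.VEGETATIVE, coeffs
    )
    qch = comp.n_heterocysts * carbon_quota_from_volume(
        comp.volume_heterocyst, CellClass.HETEROCYST, coeffs
    )
    return Quotas(qcd=qcd, qcv=qcv, qch=qch,
                  qnd=qcd / rcn, qnv=qcv / rcn, qnh=qch / rcn)
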