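"""Kitchen-measure recipes -> molar initial concentrations.

The bench protocol mixes a vitamin C stock (one effervescent tablet
dissolved in water), Lugol's 3% w/v iodine, warm water and 3% hydrogen
peroxide.  This module converts such a recipe into the two concentrations
the model needs: ``c0``, the initial ascorbic-acid concentration, and
``m0 = a0 + 2*b0``, the total iodine-ATOM concentration (each I2 molecule
contributes two atoms), both in mol per litre of the combined reaction
volume.

Lugol's solution is a 1:2 w/v mixture of molecular iodine (I2) and
potassium iodide (KI); at 3% w/v it carries 1 + 2*126.9/166 = 2.5289 g of
iodine per 100 ml.  The split between I2 and KI within that total is not
known a priori, which is exactly why the iodine fraction phi = b0/m0 is
left to the parameter fit downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ClockValidationError

__all__ = [
    "Recipe",
    "StoichiometryConstants",
    "lugol_iodine_content",
    "vitc_stock_concentration",
    "recipe_to_concentrations",
]


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, sig - 1 - floor(log10(abs(x))))


@dataclass(frozen=True)
class StoichiometryConstants:
    """Molar masses and Lugol's composition.

    ``lugol_total_iodine_g_per_100ml`` is the 5-significant-figure rounded
    total; the rounded value (not the unrounded 2.52892...) is used in
    concentration computations so that recomputed m0 values match tables
    derived with the same convention.
    """

    M_I: float = 126.9  # iodine atom, g/mol
    M_KI: float = 166.0  # potassium iodide, g/mol
    M_vitC: float = 176.12  # ascorbic acid, g/mol
    lugol_I2_g_per_100ml: float = 1.0
    lugol_KI_g_per_100ml: float = 2.0

    @property
    def lugol_total_iodine_g_per_100ml(self) -> float:
        """Iodine (atom) mass per 100 ml of Lugol's 3% w/v, rounded to 5 s.f."""
        total = self.lugol_I2_g_per_100ml + self.lugol_KI_g_per_100ml * self.M_I / self.M_KI
        return _round_sig(total, 5)


DEFAULT_STOICHIOMETRY = StoichiometryConstants()


@dataclass(frozen=True)
class Recipe:
    """One experimental condition in kitchen measures.

    Volumes in ml, tablet mass in mg.  ``water_ml`` is the *total* added
    water (both halves of the standard protocol); the reaction volume is
    water + stock aliquot + peroxide + Lugol's.
    """

    vitc_tablet_mg: float
    vitc_dilution_ml: float
    lugol_ml: float
    stock_aliquot_ml: float = 5.0
    water_ml: float = 120.0
    peroxide_ml: float = 15.0

    def __post_init__(self) -> None:
        if self.vitc_tablet_mg <= 0:
            raise ClockValidationError("vitc_tablet_mg must be > 0")
        for name in ("vitc_dilution_ml", "stock_aliquot_ml", "water_ml", "peroxide_ml"):
            if getattr(self, name) <= 0:
                raise ClockValidationError(f"{name} must be > 0")
        if self.lugol_ml < 0:
            raise ClockValidationError("lugol_ml must be >= 0")

    @property
    def total_volume_ml(self) -> float:
        return self.water_ml + self.stock_aliquot_ml + self.peroxide_ml + self.lugol_ml


def lugol_iodine_content(
    constants: StoichiometryConstants = DEFAULT_STOICHIOMETRY,
) -> float:
    """Grams of iodine atoms per 100 ml of Lugol's 3% w/v (5 s.f.): 2.5289."""
    return constants.lugol_total_iodine_g_per_100ml


def vitc_stock_concentration(tablet_mg: float, dilution_ml: float) -> float:
    """Stock molarity of a vitamin C tablet dissolved in ``dilution_ml`` of water.

    (tablet_mg / 1000 / M_vitC) mol in dilution_ml/1000 litres; e.g. a
    1000 mg tablet in 30 ml gives 0.18926 mol/l, in 120 ml 0.04731 mol/l.
    """
    if tablet_mg < 0 or dilution_ml <= 0:
        raise ClockValidationError("tablet_mg must be >= 0 and dilution_ml > 0")
    return (tablet_mg / 1000.0 / DEFAULT_STOICHIOMETRY.M_vitC) / (dilution_ml / 1000.0)


def recipe_to_concentrations(
    recipe: Recipe, constants: StoichiometryConstants = DEFAULT_STOICHIOMETRY
) -> tuple[float, float, float]:
    """(c0, m0, total_volume_ml) for a recipe.

    c0 [mol/l]: stock molarity diluted by aliquot/total volume.
    m0 [mol/l]: total iodine-atom concentration from the Lugol's volume,
    using the rounded 2.5289 g/100 ml content and M_I = 126.9 g/mol.
    """
    total_ml = recipe.total_volume_ml
    stock = vitc_stock_concentration(recipe.vitc_tablet_mg, recipe.vitc_dilution_ml)
    c0 = stock * recipe.stock_aliquot_ml / total_ml
    iodine_g = recipe.lugol_ml * constants.lugol_total_iodine_g_per_100ml / 100.0
    m0 = (iodine_g / constants.M_I) / (total_ml / 1000.0)
    return c0, m0, total_ml
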