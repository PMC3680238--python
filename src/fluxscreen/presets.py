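"""Reference growth-condition constraint sets.

:func:`production_conditions` builds the constraint set used for
screening a secondary-metabolite producer grown on a polymeric carbon
source with amino-acid co-feeding: a measured carbon uptake rate, a
common cap on every amino-acid uptake, and the measured product
secretion rate enforced as the lower bound of the product exchange.

Exchange identifiers differ between reconstructions, so the mapping
from roles to reaction ids is always supplied explicitly (via config),
never guessed from reaction names.
"""

from __future__ import annotations

from typing import Iterable

from .model import ConstraintSet, DEFAULT_BOUND, MetabolicModel, ModelError

__all__ = ["production_conditions", "UMOL_PER_MMOL"]

UMOL_PER_MMOL = 1000.0

#: default specific rates, mmol/gDCW/h (product given in μmol/gDCW/h)
CARBON_UPTAKE = 3.472
AMINO_ACID_UPTAKE = 0.050
PRODUCT_MIN_UMOL = 1.61


def production_conditions(
    carbon_exchange: str,
    amino_acid_exchanges: Iterable[str] = (),
    product_exchange: str | None = None,
    carbon_uptake: float = CARBON_UPTAKE,
    amino_acid_uptake: float = AMINO_ACID_UPTAKE,
    product_min_umol: float = PRODUCT_MIN_UMOL,
    model: MetabolicModel | None = None,
) -> ConstraintSet:
    """Constraint set for the measured production condition.

    Parameters
    ----------
    carbon_exchange:
        Exchange reaction of the principal carbon source; its lower
        bound is set to ``−carbon_uptake`` (uptake is negative flux).
    amino_acid_exchanges:
        Exchange reactions of the co-fed amino acids; each gets a lower
        bound of ``−amino_acid_uptake`` (individual caps, not pooled).
    product_exchange:
        Product export reaction; its lower bound is set to the measured
        secretion rate.  Given in μmol/gDCW/h and converted to the
        canonical mmol/gDCW/h here (1.61 μmol → 0.00161 mmol).
    model:
        When given, the mapping is validated against it immediately and
        unmapped identifiers raise a configuration error listing them.
    """
    overrides: dict[str, tuple[float, float]] = {
        carbon_exchange: (-carbon_uptake, DEFAULT_BOUND)
    }
    for rid in amino_acid_exchanges:
        overrides[rid] = (-amino_acid_uptake, DEFAULT_BOUND)
    if product_exchange is not None:
        overrides[product_exchange] = (
            product_min_umol / UMOL_PER_MMOL,
            DEFAULT_BOUND,
        )
    cs = ConstraintSet(
        overrides,
        notes=(
            f"production condition: carbon uptake {carbon_uptake} mmol/gDCW/h; "
            f"amino-acid uptakes capped at {amino_acid_uptake} mmol/gDCW/h; "
            f"product minimum {product_min_umol} umol/gDCW/h "
            f"(converted to {product_min_umol / UMOL_PER_MMOL} mmol/gDCW/h)"
        ),
    )
    if model is not None:
        missing = [rid for rid in overrides if rid not in model.reactions]
        if missing:
            raise ModelError(
                f"exchange mapping names reactions absent from the model: {missing}"
            )
    return cs
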