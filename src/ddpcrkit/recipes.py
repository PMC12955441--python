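"""Duplex reaction compositions and volume bookkeeping.

Encodes the two 20 µL duplex recipes (target/spike and target/reference)
and derives quantities such as the maximum template volume: water is the
only displaceable component besides the template, so the template can
grow until it absorbs all the water.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

_TOL = 1e-9

WATER = "water"
TEMPLATE = "template"


@dataclass
class ReactionRecipe:
    """Named reaction composition; component volumes must sum to the total."""

    name: str
    total_volume_ul: float
    components: Dict[str, float]


@dataclass
class RecipeValidation:
    passed: bool
    discrepancies: List[str] = field(default_factory=list)


def validate_recipe(recipe: ReactionRecipe) -> RecipeValidation:
    """Check component volumes: non-negative and summing to the total."""
    problems = []
    for name, vol in recipe.components.items():
        if vol < 0:
            problems.append(f"component {name!r} has negative volume {vol} uL")
    total = sum(recipe.components.values())
    if abs(total - recipe.total_volume_ul) > _TOL:
        problems.append(
            f"components sum to {total} uL, total is {recipe.total_volume_ul} uL "
            f"({recipe.total_volume_ul - total:+g} uL discrepancy)"
        )
    return RecipeValidation(passed=not problems, discrepancies=problems)


def max_template_volume(recipe: ReactionRecipe) -> float:
    """Largest template volume the recipe admits (water fully replaced).

    total − Σ(fixed components), where fixed means everything except
    water and the template itself.
    """
    fixed = sum(v for k, v in recipe.components.items() if k not in (WATER, TEMPLATE))
    if fixed - recipe.total_volume_ul > _TOL:
        raise ValueError("fixed components exceed the total reaction volume")
    return recipe.total_volume_ul - fixed


def cif_spike_recipe(template_ul: float = 2.0) -> ReactionRecipe:
    """20 µL target/spike duplex: supermix, target oligos, spike primers
    and probe, water, template."""
    fixed = {"supermix": 10.0, "cif_oligo_set": 1.0, "spike_primer_mix": 1.0, "spike_probe": 0.5}
    water = 20.0 - sum(fixed.values()) - template_ul
    if water < 0:
        raise ValueError("template volume exceeds the recipe's capacity")
    return ReactionRecipe("cif/spike", 20.0, {**fixed, WATER: water, TEMPLATE: template_ul})


def cif_reference_recipe(template_ul: float = 2.0) -> ReactionRecipe:
    """20 µL target/reference-gene duplex: supermix, two oligo sets,
    water, template."""
    fixed = {"supermix": 10.0, "cif_oligo_set": 1.0, "reference_oligo_set": 1.0}
    water = 20.0 - sum(fixed.values()) - template_ul
    if water < 0:
        raise ValueError("template volume exceeds the recipe's capacity")
    return ReactionRecipe("cif/beta-spec", 20.0, {**fixed, WATER: water, TEMPLATE: template_ul})
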