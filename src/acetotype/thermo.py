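"""Stoichiometric electron bookkeeping and Gibbs-energy landscapes.

Models the three competing ruminal H2 sinks — classic glucose fermentation,
Wood-Ljungdahl (reductive) acetogenesis, and hydrogenotrophic methanogenesis
— at the level the field argues about them: reducing equivalents ([H] = one
proton plus one electron) and dissolved H2. ΔG = ΔG°' + RT ln Q, with [H]
realized as half an H2 in reaction quotients, water at unit activity, and
ΔG°' from an editable constants table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import yaml
from scipy.optimize import brentq

H_TOKEN = "[H]"

#: elemental composition (C, H, O) of each species; [H] counts one hydrogen
#: and carries one electron
_COMPOSITION: dict[str, tuple[int, int, int]] = {
    "glucose": (6, 12, 6),
    "acetate": (2, 4, 2),   # as acetic acid CH3COOH
    "CO2": (1, 0, 2),
    "CH4": (1, 4, 0),
    "H2": (0, 2, 0),
    "H2O": (0, 2, 1),
    "formate": (1, 2, 2),   # as formic acid HCOOH
    H_TOKEN: (0, 1, 0),
}


class BalanceError(ValueError):
    """A reaction fails elemental balance for a named element."""


@dataclass(frozen=True)
class Reaction:
    """A signed-stoichiometry reaction (negative = consumed)."""

    name: str
    stoich: Mapping[str, float]
    dG0_prime: float  # kJ/mol at 25 degC, pH 7

    def check_balance(self) -> None:
        for idx, element in enumerate("CHO"):
            total = sum(
                coeff * _COMPOSITION[sp][idx]
                for sp, coeff in self.stoich.items()
                if sp in _COMPOSITION
            )
            unknown = [sp for sp in self.stoich if sp not in _COMPOSITION]
            if unknown:
                raise BalanceError(f"{self.name}: unknown species {unknown}")
            if abs(total) > 1e-9:
                raise BalanceError(f"{self.name}: element {element} unbalanced by {total}")

    def reversed(self) -> "Reaction":
        return Reaction(
            name=f"{self.name}_reversed",
            stoich={sp: -c for sp, c in self.stoich.items()},
            dG0_prime=-self.dG0_prime,
        )

    def h2_exponent(self) -> float:
        """Net H2 exponent in the quotient, counting [H] as half an H2."""
        return self.stoich.get("H2", 0.0) + 0.5 * self.stoich.get(H_TOKEN, 0.0)


def combine(name: str, *reactions: Reaction) -> Reaction:
    """Sum reactions (cancelling shared intermediates such as [H])."""
    stoich: dict[str, float] = {}
    for rxn in reactions:
        for sp, c in rxn.stoich.items():
            stoich[sp] = stoich.get(sp, 0.0) + c
    stoich = {sp: c for sp, c in stoich.items() if abs(c) > 1e-12}
    return Reaction(name=name, stoich=stoich,
                    dG0_prime=sum(r.dG0_prime for r in reactions))


@dataclass(frozen=True)
class Conditions:
    """Temperature and molar activities for quotient evaluation."""

    temperature_K: float = 312.65    # 39.5 degC, rumen
    R: float = 0.008314462618        # kJ/mol/K
    activities: Mapping[str, float] = field(default_factory=dict)
    henry_h2_M_per_atm: float = 7.8e-4

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        for sp, a in self.activities.items():
            if a <= 0:
                raise ValueError(f"activity of {sp} must be positive")

    def with_h2(self, dissolved_M: float) -> "Conditions":
        acts = dict(self.activities)
        acts["H2"] = dissolved_M
        return replace(self, activities=acts)

    def h2_from_headspace(self, partial_pressure_atm: float) -> float:
        """Dissolved H2 (mol/L) from a headspace partial pressure."""
        return self.henry_h2_M_per_atm * partial_pressure_atm


def electron_balance(rxn: Reaction) -> int:
    """Net reducing equivalents produced (+) or consumed (−) per unit reaction.

    Counts the [H] token directly and molecular H2 as two [H]; requires the
    reaction to be elementally balanced first.
    """
    rxn.check_balance()
    electrons = rxn.stoich.get(H_TOKEN, 0.0) + 2.0 * rxn.stoich.get("H2", 0.0)
    rounded = round(electrons)
    if abs(electrons - rounded) > 1e-9:
        raise ValueError(f"{rxn.name}: non-integer electron count {electrons}")
    return int(rounded)


def load_constants(path: str | None = None) -> tuple[dict[str, Reaction], Conditions]:
    """Load the reaction set and default conditions from YAML config."""
    if path is None:
        text = resources.files("acetotype.data").joinpath("thermo.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    reactions = {
        name: Reaction(name=name, stoich=dict(spec["stoich"]),
                       dG0_prime=float(spec["dG0_prime"]))
        for name, spec in raw["reactions"].items()
    }
    cond_raw = raw.get("conditions", {})
    conditions = Conditions(
        temperature_K=float(cond_raw.get("temperature_K", 312.65)),
        R=float(cond_raw.get("R_kJ_per_mol_K", 0.008314462618)),
        activities=dict(cond_raw.get("activities", {})),
        henry_h2_M_per_atm=float(cond_raw.get("henry_h2_M_per_atm", 7.8e-4)),
    )
    return reactions, conditions


def pathway_yield(mode: str, glucose_mol: float = 1.0) -> float:
    """Mol acetate per ``glucose_mol`` mol glucose, from the shipped reactions.

    ``fermentation_only`` runs classic fermentation (2 acetate/glucose);
    ``fermentation_plus_wl`` couples it to the Wood-Ljungdahl sink, whose 8
    [H] demand exactly matches fermentation's 8 [H] output, adding a third
    acetate.
    """
    reactions, _ = load_constants()
    ferm = reactions["glucose_fermentation"]
    if mode == "fermentation_only":
        rxn = ferm
    elif mode == "fermentation_plus_wl":
        rxn = combine("heterotrophic_acetogenesis", ferm, reactions["wl_acetogenesis"])
        if abs(rxn.stoich.get(H_TOKEN, 0.0)) > 1e-9:
            raise ValueError("reducing equivalents do not cancel in combined pathway")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    acetate_per_glucose = rxn.stoich["acetate"] / -rxn.stoich["glucose"]
    return acetate_per_glucose * glucose_mol


def delta_g(rxn: Reaction, cond: Conditions) -> float:
    """ΔG (kJ/mol) at the given conditions: ΔG°' + RT ln Q.

    The quotient runs over all species with nonzero coefficients; [H] enters
    as half an H2, water uses its configured activity (default 1).
    """
    ln_q = 0.0
    h2_exp = 0.0
    for sp, coeff in rxn.stoich.items():
        if sp == H_TOKEN:
            h2_exp += 0.5 * coeff
            continue
        if sp == "H2":
            h2_exp += coeff
            continue
        act = cond.activities.get(sp)
        if act is None:
            if sp == "H2O":
                act = 1.0
            else:
                raise KeyError(f"{rxn.name}: no activity for species {sp!r}")
        ln_q += coeff * math.log(act)
    if h2_exp != 0.0:
        a_h2 = cond.activities.get("H2")
        if a_h2 is None:
            raise KeyError(f"{rxn.name}: no activity for species 'H2'")
        ln_q += h2_exp * math.log(a_h2)
    return rxn.dG0_prime + cond.R * cond.temperature_K * ln_q


def h2_threshold(rxn: Reaction, cond: Conditions,
                 bracket: tuple[float, float] = (1e-15, 1.0)) -> float:
    """Dissolved H2 (mol/L) at which the reaction's ΔG crosses zero.

    ΔG is strictly monotone in ln(a_H2) whenever the net H2 exponent is
    nonzero, so the root is unique; found by Brent's method on ln(a_H2) to
    relative tolerance 1e-9.
    """
    n_h2 = rxn.h2_exponent()
    if n_h2 == 0.0:
        raise ValueError(f"{rxn.name}: ΔG does not depend on H2")

    def g_of_log(x: float) -> float:
        return delta_g(rxn, cond.with_h2(math.exp(x)))

    lo, hi = math.log(bracket[0]), math.log(bracket[1])
    if g_of_log(lo) * g_of_log(hi) > 0:
        raise ValueError(f"{rxn.name}: ΔG does not change sign on the bracket")
    root = brentq(g_of_log, lo, hi, rtol=1e-12, xtol=1e-12)
    return math.exp(root)


def delta_g_sweep(rxn: Reaction, cond: Conditions,
                  h2_min: float, h2_max: float, n: int = 50) -> list[tuple[float, float]]:
    """(dissolved H2, ΔG) pairs on a log-spaced H2 grid."""
    if h2_min <= 0 or h2_max <= h2_min:
        raise ValueError("need 0 < h2_min < h2_max")
    pts = []
    for i in range(n):
        h2 = math.exp(math.log(h2_min) + (math.log(h2_max) - math.log(h2_min)) * i / (n - 1))
        pts.append((h2, delta_g(rxn, cond.with_h2(h2))))
    return pts
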