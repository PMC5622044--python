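"""Counterfactual emission scenarios built from the embodied-emission tensor.

Six scenarios isolate the contribution of different trade channels to each
province's emissions:

1. baseline — the production-based totals;
2. no international exports — emissions embodied in foreign-bound exports
   removed from each producing province;
3. interprovincial relocation — emissions embodied in interprovincial
   exports replaced by those embodied in interprovincial imports (emissions
   located at consumption instead of production; the national total is
   conserved, and the foreign-export component stays with the producer);
4-6. partner-group variants of scenario 2 — only exports to a configured
   set of foreign partners are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mrio import AccountingResult, EmbodiedEmissionTensor


class ScenarioError(ValueError):
    """Raised for invalid scenario specifications."""


_DESCRIPTIONS = {
    1: "baseline production-based emissions",
    2: "international exports removed",
    3: "interprovincial exports replaced by imports",
    4: "exports to partner group removed",
    5: "exports to partner group removed",
    6: "exports to partner group removed",
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One counterfactual: id 1-6 plus a foreign partner group for 4-6."""

    scenario_id: int
    partner_group: tuple[str, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        if self.scenario_id not in range(1, 7):
            raise ScenarioError(f"scenario_id must be 1..6, got {self.scenario_id}")
        if self.scenario_id in (4, 5, 6) and not self.partner_group:
            raise ScenarioError("scenarios 4-6 require a nonempty partner group")
        if self.scenario_id not in (4, 5, 6) and self.partner_group:
            raise ScenarioError("only scenarios 4-6 take a partner group")
        if not self.description:
            object.__setattr__(self, "description", _DESCRIPTIONS[self.scenario_id])


@dataclass
class ScenarioEmissions:
    """Per-province emissions (Mt) under one counterfactual.

    ``values`` has shape (n_pollutants, n_domestic); scenario-3 relocation
    keeps entries nonnegative because imports are added where exports are
    removed, but no elementwise ordering against the baseline is implied.
    """

    spec: ScenarioSpec
    pollutants: list[str]
    regions: list[str]  # domestic only
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        P, R = self.values.shape
        pi, ri = np.meshgrid(np.arange(P), np.arange(R), indexing="ij")
        return pd.DataFrame(
            {
                "scenario": self.spec.scenario_id,
                "pollutant": np.asarray(self.pollutants)[pi.ravel()],
                "region": np.asarray(self.regions)[ri.ravel()],
                "emission_Mt": self.values.ravel(),
            }
        )


def default_scenarios(foreign_regions: list[str]) -> list[ScenarioSpec]:
    """Specs 1-6 with partner groups 4-6 partitioning the foreign set."""
    groups = [tuple(foreign_regions[i::3]) for i in range(3)]
    groups = [g for g in groups if g]
    specs = [ScenarioSpec(1), ScenarioSpec(2), ScenarioSpec(3)]
    for k, g in enumerate(groups):
        specs.append(ScenarioSpec(4 + k, partner_group=g))
    return specs


def build_scenario(
    tensor: EmbodiedEmissionTensor,
    accounts: AccountingResult,
    spec: ScenarioSpec,
) -> ScenarioEmissions:
    """Evaluate one counterfactual emission vector for the domestic regions."""
    nd = tensor.n_domestic
    dom_names = tensor.regions[:nd]
    E_p = accounts.E_p[:, :nd]

    if spec.scenario_id == 1:
        values = E_p.copy()
    elif spec.scenario_id == 2:
        values = E_p - accounts.foreign_out[:, :nd]
    elif spec.scenario_id == 3:
        values = (
            E_p - accounts.domestic_out[:, :nd] + accounts.domestic_in[:, :nd]
        )
    else:
        foreign_names = tensor.regions[nd:]
        bad = set(spec.partner_group) - set(foreign_names)
        if bad:
            raise ScenarioError(
                f"partner group contains non-foreign regions: {sorted(bad)}"
            )
        cols = [tensor.regions.index(r) for r in spec.partner_group]
        removal = tensor.values[:, :nd, :, :][:, :, :, cols].sum(axis=(2, 3))
        values = E_p - removal

    return ScenarioEmissions(
        spec=spec,
        pollutants=list(tensor.pollutants),
        regions=list(dom_names),
        values=values,
    )


def scenario_delta(
    baseline: ScenarioEmissions, counterfactual: ScenarioEmissions
) -> np.ndarray:
    """Signed elementwise difference counterfactual - baseline (Mt)."""
    if (
        baseline.regions != counterfactual.regions
        or baseline.pollutants != counterfactual.pollutants
    ):
        raise ScenarioError("mismatched region or pollutant indices")
    return counterfactual.values - baseline.values
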