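"""Cell-assembly extraction and the unique/shared neuron census.

A cell assembly (CA) for one test instance and area is the set of e-cells
whose rate estimate exceeds 75% of the area's maximally responsive cell
(strict inequality); if even the maximum stays below the 0.01 response floor
the area counts as non-responding and the CA is empty. Comparing the CAs of
a category's three trained instances classifies each participating cell as
unique (responds to exactly one instance), pair-shared or triple-shared —
model correlates of instance-specific versus category-general coding. The
gain statistic quantifies how counts change from the primary areas (V1,
M1_L), where stimulation arrives, to the central connector-hub areas (AT,
PF_L): gain = (n_central - n_primary) / n_primary * 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architecture import AREA_NAMES
from .protocol import TestResponse, StudyResult

CA_FRACTION = 0.75
RESPONSE_FLOOR = 0.01

PRIMARY_EXTRA = ("V1", "M1_L")
CENTRAL_EXTRA = ("AT", "PF_L")
PRIMARY_ALL = ("V1", "M1_L", "A1", "M1_i")
CENTRAL_ALL = ("AT", "PF_L", "PB", "PF_i")


@dataclass(frozen=True)
class CellAssembly:
    instance_id: int
    area: str
    cells: frozenset[int]


def extract_ca(response: TestResponse, area: str) -> CellAssembly:
    """Cells firing above 75% of the area maximum; empty below the 0.01 floor."""
    rates = response.area_rates(area)
    peak = float(rates.max())
    if peak < RESPONSE_FLOOR:
        cells: frozenset[int] = frozenset()
    else:
        cells = frozenset(np.flatnonzero(rates > CA_FRACTION * peak).tolist())
    return CellAssembly(instance_id=response.instance_id, area=area, cells=cells)


def classify_neurons(cas: list[CellAssembly], area: str | None = None
                     ) -> tuple[int, int, int]:
    """Multiplicity histogram (unique, pair-shared, triple-shared) of 3 CAs."""
    if len(cas) != 3:
        raise ValueError("classification needs the 3 trained instances' CAs")
    if area is not None and any(ca.area != area for ca in cas):
        raise ValueError("mismatched areas")
    counts: dict[int, int] = {}
    for ca in cas:
        for c in ca.cells:
            counts[c] = counts.get(c, 0) + 1
    mult = np.array(list(counts.values())) if counts else np.array([], dtype=int)
    return (int((mult == 1).sum()), int((mult == 2).sum()), int((mult == 3).sum()))


def per_instance_counts(cas: list[CellAssembly]) -> list[tuple[int, int]]:
    """(n_unique, n_shared) of each instance's own CA among the 3 trained CAs.

    A cell of instance i's CA is unique if no other trained instance of the
    category activates it, shared if at least one other does.
    """
    if len(cas) != 3:
        raise ValueError("needs the 3 trained instances' CAs")
    out = []
    for k, ca in enumerate(cas):
        others = set().union(*(c.cells for j, c in enumerate(cas) if j != k))
        shared = len(ca.cells & others)
        out.append((len(ca.cells) - shared, shared))
    return out


def assembly_table(study: StudyResult) -> pd.DataFrame:
    """Tidy per-(instantiation, condition, category, instance, area) CA census.

    Columns n_unique / n_shared are the per-instance counts; unique /
    pair_shared / triple_shared give the category-level multiplicity
    decomposition (identical across the category's three rows).
    """
    stim = study.stimuli
    rows = []
    trained_by_cat: dict[int, list[int]] = {}
    for g in stim.trained_instances():
        trained_by_cat.setdefault(g.category_id, []).append(g.instance_id)
    for i, per_cond in enumerate(study.responses):
        for label, responses in zip(study.conditions, per_cond):
            by_id = {r.instance_id: r for r in responses}
            for cat, inst_ids in sorted(trained_by_cat.items()):
                for area in AREA_NAMES:
                    cas = [extract_ca(by_id[iid], area) for iid in sorted(inst_ids)]
                    uniq, pair, trip = classify_neurons(cas, area)
                    for (iid, (n_u, n_s)) in zip(sorted(inst_ids), per_instance_counts(cas)):
                        rows.append({
                            "instantiation": i, "condition": label,
                            "category": cat, "instance": iid, "area": area,
                            "ca_size": len([c for c in cas if c.instance_id == iid][0].cells),
                            "n_unique": n_u, "n_shared": n_s,
                            "unique": uniq, "pair_shared": pair,
                            "triple_shared": trip,
                        })
    return pd.DataFrame(rows)


def neuron_counts(table: pd.DataFrame, areas=None) -> pd.DataFrame:
    """Mean per-instance unique/shared counts per (instantiation, condition).

    Averages per instance first, then across instances, areas and categories,
    within each instantiation. `areas` defaults to all areas in the table.
    """
    t = table if areas is None else table[table["area"].isin(areas)]
    agg = (t.groupby(["instantiation", "condition"])[["n_unique", "n_shared"]]
           .mean().reset_index())
    return agg


def area_profile(table: pd.DataFrame) -> pd.DataFrame:
    """Per-area mean counts (condition x area x neuron type), for profile plots."""
    agg = (table.groupby(["condition", "area"])[["n_unique", "n_shared"]]
           .mean().reset_index())
    return agg.melt(id_vars=["condition", "area"],
                    value_vars=["n_unique", "n_shared"],
                    var_name="neuron_type", value_name="mean_count")


@dataclass
class GainRecord:
    condition: str
    neuron_type: str        # "unique" | "shared"
    n_primary: float
    n_central: float
    instantiation: int | None = None

    @property
    def gain_percent(self) -> float | None:
        if self.n_primary <= 0:
            return None
        return (self.n_central - self.n_primary) / self.n_primary * 100.0


def gain(table: pd.DataFrame, primary=PRIMARY_EXTRA, central=CENTRAL_EXTRA
         ) -> pd.DataFrame:
    """Central-vs-primary percentage gain per (instantiation, condition, type).

    n_primary / n_central are mean per-instance counts over the respective
    area pairs; rows with zero primary count carry a missing gain.
    """
    rows = []
    for (inst, cond), grp in table.groupby(["instantiation", "condition"]):
        for col, label in (("n_unique", "unique"), ("n_shared", "shared")):
            rec = GainRecord(
                condition=cond, neuron_type=label, instantiation=inst,
                n_primary=float(grp.loc[grp["area"].isin(primary), col].mean()),
                n_central=float(grp.loc[grp["area"].isin(central), col].mean()),
            )
            rows.append({
                "instantiation": inst, "condition": cond, "neuron_type": label,
                "n_primary": rec.n_primary, "n_central": rec.n_central,
                "gain_percent": rec.gain_percent,
            })
    return pd.DataFrame(rows)
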