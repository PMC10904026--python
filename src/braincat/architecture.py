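"""The 12-area cortical architecture and its between-area connectivity.

Six perisylvian areas model the language cortex — the auditory stream
(A1, AB, PB) and the inferior-frontal articulatory stream (PF_i, PM_i, M1_i) —
and six extrasylvian areas model the sensorimotor cortex: the ventral visual
stream (V1, TO, AT) and the dorsolateral hand-motor stream (PF_L, PM_L, M1_L).
Links are reciprocal and come in three neuroanatomically motivated classes:
next-neighbour links along each stream plus two between-system bridges
(AT-PB, PF_i-PF_L), second-neighbour "jumping" links, and long-distance
cortico-cortical links converging on the central connector-hub areas
(AT, PF_L, PB, PF_i).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AreaSpec:
    name: str
    system: str   # "perisylvian" | "extrasylvian"
    tier: str     # "primary" | "secondary" | "central"


AREAS: tuple[AreaSpec, ...] = (
    AreaSpec("V1", "extrasylvian", "primary"),
    AreaSpec("TO", "extrasylvian", "secondary"),
    AreaSpec("AT", "extrasylvian", "central"),
    AreaSpec("PF_L", "extrasylvian", "central"),
    AreaSpec("PM_L", "extrasylvian", "secondary"),
    AreaSpec("M1_L", "extrasylvian", "primary"),
    AreaSpec("A1", "perisylvian", "primary"),
    AreaSpec("AB", "perisylvian", "secondary"),
    AreaSpec("PB", "perisylvian", "central"),
    AreaSpec("PF_i", "perisylvian", "central"),
    AreaSpec("PM_i", "perisylvian", "secondary"),
    AreaSpec("M1_i", "perisylvian", "primary"),
)

AREA_NAMES: tuple[str, ...] = tuple(a.name for a in AREAS)
AREA_INDEX: dict[str, int] = {a.name: i for i, a in enumerate(AREAS)}

EXTRASYLVIAN: tuple[str, ...] = tuple(a.name for a in AREAS if a.system == "extrasylvian")
PERISYLVIAN: tuple[str, ...] = tuple(a.name for a in AREAS if a.system == "perisylvian")
PRIMARY_AREAS: tuple[str, ...] = tuple(a.name for a in AREAS if a.tier == "primary")
CENTRAL_AREAS: tuple[str, ...] = tuple(a.name for a in AREAS if a.tier == "central")

# Undirected between-area links with their anatomical class.
NEXT_NEIGHBOR_LINKS: tuple[tuple[str, str], ...] = (
    ("A1", "AB"), ("AB", "PB"),
    ("PF_i", "PM_i"), ("PM_i", "M1_i"),
    ("V1", "TO"), ("TO", "AT"),
    ("PF_L", "PM_L"), ("PM_L", "M1_L"),
    ("AT", "PB"), ("PF_i", "PF_L"),      # between-system bridges
)
JUMPING_LINKS: tuple[tuple[str, str], ...] = (
    ("A1", "PB"), ("PF_i", "M1_i"), ("V1", "AT"), ("PF_L", "M1_L"),
)
LONG_DISTANCE_LINKS: tuple[tuple[str, str], ...] = (
    ("PF_i", "PB"), ("PB", "PM_i"), ("AB", "PF_i"),
    ("AT", "PF_L"), ("AT", "PM_L"), ("TO", "PF_L"),
    ("PB", "PF_L"), ("AT", "PF_i"),
)


@dataclass(frozen=True)
class ConnectivityGraph:
    """Undirected area pairs with their link class; all links are reciprocal."""

    links: tuple[tuple[str, str, str], ...]   # (area_a, area_b, link_class)

    def pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, _ in self.links]

    def directed_pairs(self) -> list[tuple[str, str]]:
        out = []
        for a, b, _ in self.links:
            out.append((a, b))
            out.append((b, a))
        return out

    def degree(self, area: str) -> int:
        return sum(1 for a, b, _ in self.links if area in (a, b))


def build_architecture() -> tuple[list[AreaSpec], ConnectivityGraph]:
    links = (
        tuple((a, b, "next-neighbor") for a, b in NEXT_NEIGHBOR_LINKS)
        + tuple((a, b, "jumping") for a, b in JUMPING_LINKS)
        + tuple((a, b, "long-distance") for a, b in LONG_DISTANCE_LINKS)
    )
    for a, b, _ in links:
        if a not in AREA_INDEX or b not in AREA_INDEX:
            raise ValueError(f"unknown area in link {a}-{b}")
    return list(AREAS), ConnectivityGraph(links=links)
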