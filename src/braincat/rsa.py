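"""Representational similarity analysis.

For each area and condition, the 625-long firing-rate vectors elicited by the
test instances are compared pairwise by Euclidean distance and organized in a
symmetric representational dissimilarity matrix (RDM). Unordered instance
pairs fall into six classes by category membership (within/between) and
training status (trained-trained, trained-novel, novel-novel); the summaries
of interest are the class means over the upper triangle — averaged first
within an area, then unweighted across areas — and the generalization index
DissimDiff = |mean(W-TN) - mean(W-TT)|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .architecture import AREA_NAMES, EXTRASYLVIAN
from .protocol import TestResponse, StudyResult

PAIR_CLASSES = ("W-TT", "W-TN", "W-NN", "B-TT", "B-TN", "B-NN")


@dataclass
class RDM:
    area: str
    matrix: np.ndarray          # (n, n) symmetric, zero diagonal
    condition: str | None = None

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM must be square")


def compute_rdm(responses: list[TestResponse], area: str,
                condition: str | None = None) -> RDM:
    """Pairwise Euclidean distances between the area's rate vectors."""
    responses = sorted(responses, key=lambda r: r.instance_id)
    X = np.stack([r.area_rates(area) for r in responses])
    return RDM(area=area, matrix=squareform(pdist(X, metric="euclidean")),
               condition=condition)


def classify_pairs(n_categories: int = 10, instances_per_category: int = 6,
                   n_trained: int = 3) -> dict[tuple[int, int], str]:
    """Partition all unordered instance pairs into the six dissimilarity classes.

    Instances are numbered category-major, trained before novel within each
    category (the battery's layout).
    """
    n = n_categories * instances_per_category

    def cat(i: int) -> int:
        return i // instances_per_category

    def trained(i: int) -> bool:
        return i % instances_per_category < n_trained

    out: dict[tuple[int, int], str] = {}
    for i in range(n):
        for j in range(i + 1, n):
            within = "W" if cat(i) == cat(j) else "B"
            nt = trained(i) + trained(j)
            kind = {2: "TT", 1: "TN", 0: "NN"}[nt]
            out[(i, j)] = f"{within}-{kind}"
    return out


@dataclass
class DissimSummary:
    condition: str
    area_set: str                      # "extrasylvian-6" | "all-12"
    class_means: dict[str, float]
    instantiation: int | None = None

    @property
    def dissim_diff(self) -> float:
        return abs(self.class_means["W-TN"] - self.class_means["W-TT"])


def summarize(rdms: list[RDM], classes: dict[tuple[int, int], str],
              area_set: str = "extrasylvian-6",
              condition: str = "", instantiation: int | None = None) -> DissimSummary:
    """Class means over upper-triangle entries, averaged across areas.

    Entries are averaged per class within each area first; areas are then
    averaged unweighted (all areas contribute the same pair counts).
    """
    wanted = EXTRASYLVIAN if area_set == "extrasylvian-6" else AREA_NAMES
    use = [r for r in rdms if r.area in wanted]
    if not use:
        raise ValueError(f"no RDMs for area set {area_set!r}")
    idx_by_class: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for label in PAIR_CLASSES:
        pairs = [(i, j) for (i, j), lab in classes.items() if lab == label]
        if not pairs:
            raise ValueError(f"empty pair class {label}")
        ii, jj = zip(*pairs)
        idx_by_class[label] = (np.array(ii), np.array(jj))
    means: dict[str, float] = {}
    for label, (ii, jj) in idx_by_class.items():
        per_area = [r.matrix[ii, jj].mean() for r in use]
        means[label] = float(np.mean(per_area))
    return DissimSummary(condition=condition, area_set=area_set,
                         class_means=means, instantiation=instantiation)


def study_rdms(study: StudyResult) -> dict[tuple[int, str, str], RDM]:
    """All RDMs of a study, keyed by (instantiation, condition, area)."""
    out: dict[tuple[int, str, str], RDM] = {}
    for i, per_cond in enumerate(study.responses):
        for label, responses in zip(study.conditions, per_cond):
            for area in AREA_NAMES:
                out[(i, label, area)] = compute_rdm(responses, area, condition=label)
    return out


def summarize_study(study: StudyResult, area_set: str = "extrasylvian-6",
                    rdms: dict | None = None) -> pd.DataFrame:
    """Tidy per-(instantiation, condition) dissimilarity summary table."""
    stim = study.stimuli
    classes = classify_pairs(n_categories=stim.n_categories)
    if rdms is None:
        rdms = study_rdms(study)
    rows = []
    for i in range(study.n_instantiations):
        for label in study.conditions:
            area_rdms = [rdms[(i, label, a)] for a in AREA_NAMES]
            s = summarize(area_rdms, classes, area_set=area_set,
                          condition=label, instantiation=i)
            row = {"instantiation": i, "condition": label, "area_set": area_set}
            row.update(s.class_means)
            row["dissim_diff"] = s.dissim_diff
            rows.append(row)
    return pd.DataFrame(rows)


def rdm_long_table(rdms: dict[tuple[int, str, str], RDM]) -> pd.DataFrame:
    """Long-format (instantiation, condition, area, i, j, distance) export."""
    rows = []
    for (inst, cond, area), r in rdms.items():
        n = r.matrix.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        rows.append(pd.DataFrame({
            "instantiation": inst, "condition": cond, "area": area,
            "i": iu, "j": ju, "distance": r.matrix[iu, ju],
        }))
    return pd.concat(rows, ignore_index=True)
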