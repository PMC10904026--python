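"""End-to-end orchestration: patterns -> train -> test -> RSA -> CA -> stats.

`run_all` executes the whole study deterministically from one seed and
returns (optionally writing to disk) a ReportBundle of tidy tables: the
dissimilarity summaries, the cell-assembly census and gains, the ANOVA and
pairwise tables, plus a flat dictionary of headline quantities addressable by
names such as "W-TT[CT]" for expectation checks via `compare_report`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assemblies as ca
from . import patterns, protocol, rsa, stats
from .config import RunConfig

logger = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    config: RunConfig
    dissim_extra: pd.DataFrame       # per (instantiation, condition), 6 extrasylvian areas
    dissim_all: pd.DataFrame         # same over all 12 areas
    assembly: pd.DataFrame           # per-instance CA census
    counts_extra: pd.DataFrame       # mean unique/shared counts (extrasylvian)
    gains: pd.DataFrame              # central-vs-primary gains
    anova: pd.DataFrame              # stacked ANOVA tables (analysis column)
    pairwise: pd.DataFrame           # Bonferroni pairwise table
    quantities: dict = field(default_factory=dict)
    study: protocol.StudyResult | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "dissim_extrasylvian": self.dissim_extra,
            "dissim_all_areas": self.dissim_all,
            "assembly_census": self.assembly,
            "neuron_counts_extrasylvian": self.counts_extra,
            "gains": self.gains,
            "anova": self.anova,
            "pairwise": self.pairwise,
        }


def _melt_dissim(df: pd.DataFrame, classes: tuple[str, str],
                 value_name: str = "dissim") -> pd.DataFrame:
    m = df.melt(id_vars=["instantiation", "condition"], value_vars=list(classes),
                var_name="measure", value_name=value_name)
    return m


def _headline(df: pd.DataFrame, col: str, by: str = "condition") -> dict[str, float]:
    return df.groupby(by)[col].mean().to_dict()


def run_all(config: RunConfig) -> ReportBundle:
    """Run the configured study end to end; deterministic given the seed."""
    config.validate()
    t0 = time.time()
    ss = np.random.SeedSequence(config.seed)
    pattern_seed, *inst_seeds = [int(s % 2**31) for s in
                                 ss.generate_state(1 + config.n_instantiations)]
    stimuli = patterns.generate_stimulus_set(pattern_seed,
                                             n_categories=config.n_categories)
    violations = patterns.validate_constraints(stimuli)
    if violations:
        raise RuntimeError(f"invalid stimulus battery: {violations[:3]}")
    logger.info("stimulus battery: %d instances, %d categories",
                stimuli.n_instances, stimuli.n_categories)

    study = protocol.run_study(inst_seeds, stimuli, params=config.params,
                               design=config.design,
                               trial_scale=config.trial_scale,
                               progress=config.progress)
    logger.info("study complete after %.1fs", time.time() - t0)

    rdms = rsa.study_rdms(study)
    dissim_extra = rsa.summarize_study(study, "extrasylvian-6", rdms=rdms)
    dissim_all = rsa.summarize_study(study, "all-12", rdms=rdms)

    table = ca.assembly_table(study)
    from .architecture import EXTRASYLVIAN
    counts_extra = ca.neuron_counts(table, areas=EXTRASYLVIAN)
    gains = ca.gain(table)

    conds = list(study.conditions)
    anovas = []
    n_subj = study.n_instantiations
    if n_subj >= 2:
        # category learning: condition x dissimilarity type (W-TT / B-TT)
        cat_df = _melt_dissim(dissim_extra, ("W-TT", "B-TT"))
        anovas.append(stats.rm_anova(cat_df, "dissim", ["condition", "measure"],
                                     "instantiation").assign(analysis="category_learning"))
        # generalization: condition x (W-TT / W-TN)
        gen_df = _melt_dissim(dissim_extra, ("W-TT", "W-TN"))
        anovas.append(stats.rm_anova(gen_df, "dissim", ["condition", "measure"],
                                     "instantiation").assign(analysis="generalization"))
        # cell assemblies: condition x neuron type
        cnt_df = counts_extra.melt(id_vars=["instantiation", "condition"],
                                   value_vars=["n_unique", "n_shared"],
                                   var_name="measure", value_name="count")
        anovas.append(stats.rm_anova(cnt_df, "count", ["condition", "measure"],
                                     "instantiation").assign(analysis="neuron_counts"))
        # gains: condition x neuron type (only where defined)
        if gains["gain_percent"].notna().all():
            anovas.append(stats.rm_anova(gains, "gain_percent",
                                         ["condition", "neuron_type"],
                                         "instantiation").assign(analysis="gain"))
    anova = (pd.concat(anovas, ignore_index=True) if anovas else
             pd.DataFrame(columns=["effect", "F", "df1", "df2", "p", "p_gg",
                                   "eps", "df1_gg", "df2_gg", "eta2_partial",
                                   "eta2_generalized", "mauchly_W", "mauchly_p",
                                   "p_report", "analysis"]))

    # pairwise follow-ups on the category-learning analysis (family of 10)
    pairs = []
    for cls in ("W-TT", "B-TT"):
        sub = dissim_extra.sort_values("instantiation")
        for a, b in _level_pairs(conds):
            pairs.append((f"{cls}[{a}] vs {cls}[{b}]",
                          sub[sub.condition == a][cls].to_numpy(),
                          sub[sub.condition == b][cls].to_numpy()))
    for cond in conds:
        sub = dissim_extra[dissim_extra.condition == cond].sort_values("instantiation")
        pairs.append((f"W-TT[{cond}] vs B-TT[{cond}]",
                      sub["W-TT"].to_numpy(), sub["B-TT"].to_numpy()))
    # generalization follow-up on DissimDiff
    for a, b in _level_pairs(conds):
        sub = dissim_extra.sort_values("instantiation")
        pairs.append((f"DissimDiff[{a}] vs DissimDiff[{b}]",
                      sub[sub.condition == a]["dissim_diff"].to_numpy(),
                      sub[sub.condition == b]["dissim_diff"].to_numpy()))
    family = 10 if len(conds) == 3 else len(pairs)
    pairwise = (stats.bonferroni_pairwise(pairs, family_size=family)
                if n_subj >= 2 else
                pd.DataFrame(columns=["contrast", "t", "df", "p",
                                      "p_bonferroni", "significant", "mean_diff"]))

    quantities: dict[str, float] = {}
    for cls in ("W-TT", "W-TN", "W-NN", "B-TT"):
        for cond, v in _headline(dissim_extra, cls).items():
            quantities[f"{cls}[{cond}]"] = float(v)
    for cond, v in _headline(dissim_extra, "dissim_diff").items():
        quantities[f"DissimDiff[{cond}]"] = float(v)
    for col, label in (("n_unique", "n_unique"), ("n_shared", "n_shared")):
        for cond, v in _headline(counts_extra, col).items():
            quantities[f"{label}[{cond}]"] = float(v)
    for (cond, ntype), grp in gains.groupby(["condition", "neuron_type"]):
        vals = grp["gain_percent"].dropna()
        if len(vals):
            quantities[f"gain_{ntype}[{cond}]"] = float(vals.mean())

    bundle = ReportBundle(config=config, dissim_extra=dissim_extra,
                          dissim_all=dissim_all, assembly=table,
                          counts_extra=counts_extra, gains=gains,
                          anova=anova, pairwise=pairwise,
                          quantities=quantities, study=study)
    if config.out_dir:
        write_report(bundle, config.out_dir)
    return bundle


def _level_pairs(levels):
    return [(levels[i], levels[j]) for i in range(len(levels))
            for j in range(i + 1, len(levels))]


def write_report(bundle: ReportBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables().items():
        df.to_csv(out / f"{name}.csv", index=False)
    with open(out / "quantities.json", "w") as fh:
        json.dump(bundle.quantities, fh, indent=1, sort_keys=True)
    if bundle.config.make_heatmaps and bundle.study is not None:
        _write_heatmaps(bundle, out)


def _write_heatmaps(bundle: ReportBundle, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    study = bundle.study
    rdms = rsa.study_rdms(study)
    from .architecture import AREA_NAMES
    for cond in study.conditions:
        fig, axes = plt.subplots(1, len(AREA_NAMES), figsize=(3 * len(AREA_NAMES), 3))
        mean_by_area = {
            a: np.mean([rdms[(i, cond, a)].matrix
                        for i in range(study.n_instantiations)], axis=0)
            for a in AREA_NAMES
        }
        for ax, a in zip(np.atleast_1d(axes), AREA_NAMES):
            ax.imshow(mean_by_area[a], cmap="viridis")
            ax.set_title(f"{a} ({cond})", fontsize=8)
            ax.set_xticks([])
            ax.set_yticks([])
        fig.tight_layout()
        fig.savefig(out / f"rdm_{cond}.png", dpi=110)
        plt.close(fig)


# --- expectation checking ----------------------------------------------------

_OPS = {
    "<": lambda a, b, tol: a < b + tol,
    ">": lambda a, b, tol: a > b - tol,
    "<=": lambda a, b, tol: a <= b + tol,
    ">=": lambda a, b, tol: a >= b - tol,
    "==": lambda a, b, tol: abs(a - b) <= tol,
}


def compare_report(bundle_or_quantities, expectations_file) -> pd.DataFrame:
    """Check (quantity comparator value-or-quantity [tolerance]) expectations.

    Each non-empty, non-comment line of the file reads e.g.
    ``W-TT[CT] < W-TT[NoS]`` or ``n_shared[CT] >= 5 0.1``. Returns one row per
    expectation with a pass/fail verdict; unknown quantities or malformed
    comparators raise.
    """
    q = (bundle_or_quantities.quantities
         if isinstance(bundle_or_quantities, ReportBundle)
         else dict(bundle_or_quantities))
    rows = []
    with open(expectations_file) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) not in (3, 4):
                raise ValueError(f"line {lineno}: expected 'LHS OP RHS [TOL]'")
            lhs_key, op, rhs_tok = toks[0], toks[1], toks[2]
            tol = float(toks[3]) if len(toks) == 4 else 0.0
            if op not in _OPS:
                raise ValueError(f"line {lineno}: malformed comparator {op!r}")
            if lhs_key not in q:
                raise KeyError(f"line {lineno}: unknown quantity {lhs_key!r}")
            lhs = float(q[lhs_key])
            try:
                rhs = float(rhs_tok)
            except ValueError:
                if rhs_tok not in q:
                    raise KeyError(f"line {lineno}: unknown quantity {rhs_tok!r}")
                rhs = float(q[rhs_tok])
            rows.append({"expectation": line, "lhs": lhs, "rhs": rhs,
                         "passed": bool(_OPS[op](lhs, rhs, tol))})
    return pd.DataFrame(rows, columns=["expectation", "lhs", "rhs", "passed"])
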