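"""Inferential layer: repeated-measures ANOVA and Bonferroni pairwise tests.

The study is a within-subject design with the model instantiation as the
subject (n = 12 at full scale): a condition factor (3 or 4 levels) crossed
with a two-level measure factor (e.g. W-TT/B-TT dissimilarity, or
unique/shared neuron counts). Sphericity is assessed with Mauchly's test and
the Greenhouse-Geisser correction is reported alongside the uncorrected p;
pairwise follow-ups are two-tailed paired t-tests with Bonferroni adjustment
against the conservative 0.005 significance threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

ALPHA = 0.005


def rm_anova(data: pd.DataFrame, dv: str, within: list[str], subject: str
             ) -> pd.DataFrame:
    """Two-factor (or one-factor) repeated-measures ANOVA on a balanced table.

    Returns one row per effect with F, dfs, uncorrected and GG-corrected p,
    the GG epsilon, partial and generalized eta squared, and (for factors
    with at least three levels) Mauchly's sphericity test. `p_report` is the
    GG-corrected p whenever Mauchly rejects sphericity at 0.05, else the
    uncorrected p.
    """
    cells = data.groupby([subject] + list(within))[dv].count()
    n_expected = data[subject].nunique()
    for f in within:
        n_expected *= data[f].nunique()
    if (cells != 1).any() or len(cells) != n_expected:
        raise ValueError("design must be complete and balanced "
                         "(exactly one observation per subject x cell)")
    a_np2 = pg.rm_anova(data=data, dv=dv, within=within, subject=subject,
                        detailed=True, effsize="np2")
    a_ng2 = pg.rm_anova(data=data, dv=dv, within=within, subject=subject,
                        detailed=True, effsize="ng2")
    out_rows = []
    for k, row in a_np2.iterrows():
        effect = row["Source"]
        if effect == "Residual" or (isinstance(effect, str) and effect.startswith("Error")):
            continue
        factors = [f.strip() for f in str(effect).split("*")]
        mauchly_w = mauchly_p = np.nan
        if len(factors) == 1 and data[factors[0]].nunique() > 2:
            sph = pg.sphericity(data=data, dv=dv, subject=subject,
                                within=factors[0])
            mauchly_w, mauchly_p = float(sph.W), float(sph.pval)
        p_unc = float(row["p_unc"])
        p_gg = float(row["p_GG_corr"]) if "p_GG_corr" in row and np.isfinite(row.get("p_GG_corr", np.nan)) else p_unc
        eps = float(row["eps"]) if "eps" in row and np.isfinite(row.get("eps", np.nan)) else 1.0
        use_gg = np.isfinite(mauchly_p) and mauchly_p < 0.05
        out_rows.append({
            "effect": str(effect).replace(" * ", ":"),
            "F": float(row["F"]),
            "df1": float(row["ddof1"]), "df2": float(row["ddof2"]),
            "p": p_unc, "p_gg": p_gg, "eps": eps,
            "df1_gg": float(row["ddof1"]) * eps, "df2_gg": float(row["ddof2"]) * eps,
            "eta2_partial": float(row["np2"]),
            "eta2_generalized": float(a_ng2.loc[k, "ng2"]),
            "mauchly_W": mauchly_w, "mauchly_p": mauchly_p,
            "p_report": p_gg if use_gg else p_unc,
        })
    return pd.DataFrame(out_rows)


def bonferroni_pairwise(pairs: list[tuple[str, np.ndarray, np.ndarray]],
                        family_size: int | None = None,
                        alpha: float = ALPHA) -> pd.DataFrame:
    """Two-tailed paired t-tests with Bonferroni adjustment.

    `pairs` is a list of (contrast label, sample_a, sample_b) with the two
    samples paired on the same subjects. The family size defaults to the
    number of contrasts; adjusted p = min(1, m * p).
    """
    m = family_size if family_size is not None else len(pairs)
    rows = []
    for label, a, b in pairs:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"contrast {label!r}: unequal pairing")
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(a, b)
        p_adj = min(1.0, m * float(p))
        rows.append({
            "contrast": label, "t": float(t), "df": a.size - 1,
            "p": float(p), "p_bonferroni": p_adj,
            "significant": p_adj < alpha,
            "mean_diff": float(np.mean(a - b)),
        })
    return pd.DataFrame(rows)


def paired_cells(df: pd.DataFrame, dv: str, subject: str, factor: str,
                 level_a: str, level_b: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract two paired sample vectors (sorted by subject) for a contrast."""
    a = df[df[factor] == level_a].sort_values(subject)[dv].to_numpy()
    b = df[df[factor] == level_b].sort_values(subject)[dv].to_numpy()
    if a.size != b.size:
        raise ValueError("unequal pairing")
    return a, b
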