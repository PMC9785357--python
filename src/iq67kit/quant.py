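"""Expression, qPCR and fruit-shape quantification.

Three groups of operations:

* expression-matrix preparation for heatmaps — elementwise log2(x+1) with
  optional per-gene z-scaling (constant rows map to zero);
* relative qPCR quantification by the 2^-ddCt method — technical replicates
  are averaged first, then dCt (target minus reference), ddCt (sample minus
  calibrator) and fold change per biological replicate, summarized as
  mean +/- sd;
* fruit-shape statistics — FSI (vertical over horizontal diameter), percent
  increase vs a control, Welch two-sample tests with the figure-legend star
  convention (* <0.05, ** <0.01, *** <0.001, **** <0.0001, strictly below),
  Holm-adjusted pairwise comparisons summarized as a compact letter display,
  and OLS regression of FSI on expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .protparam import round_half_up

TISSUES = ("Rt", "S", "L", "FF", "MF", "O", "G", "R", "C", "P")

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_code(p: float) -> str:
    """Significance stars; p must be strictly below a threshold to earn it."""
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


# ---------------------------------------------------------------- expression

def heatmap_matrix(expr: pd.DataFrame, transform: str = "log2p1") -> pd.DataFrame:
    """log2(x+1)-transform a nonnegative genes x tissues matrix.

    ``log2p1_zscore`` additionally z-scales each gene row (population sd);
    constant rows become all-zero.
    """
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression matrix must be nonnegative")
    out = np.log2(expr.astype(float) + 1.0)
    if transform == "log2p1":
        return out
    if transform == "log2p1_zscore":
        mean = out.mean(axis=1)
        sd = out.std(axis=1, ddof=0)
        z = out.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
        return z.fillna(0.0)
    raise ValueError(f"unknown transform {transform!r}")


# --------------------------------------------------------------------- qPCR

@dataclass(frozen=True)
class QpcrResult:
    sample: str
    target_gene: str
    delta_ct: float          # mean over biological replicates
    delta_delta_ct: float
    fold: float              # 2^-ddCt of the mean ddCt
    fold_mean: float         # mean of per-biological-replicate folds
    fold_sd: float
    n_biological: int


def delta_delta_ct(
    ct_table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
    target_gene: str | None = None,
) -> list[QpcrResult]:
    """Relative expression by 2^-ddCt from a long-format Ct table.

    ``ct_table`` columns: sample, gene, bio_rep, tech_rep, ct. Technical
    replicates are averaged first; dCt = Ct_target - Ct_reference per
    biological replicate; ddCt subtracts the calibrator sample's mean dCt.
    The calibrator's fold (of its mean ddCt) is exactly 1.
    """
    required = {"sample", "gene", "bio_rep", "ct"}
    if missing := required - set(ct_table.columns):
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    genes = set(ct_table["gene"])
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")
    targets = ([target_gene] if target_gene is not None
               else sorted(genes - {reference_gene}))
    # technical replicates -> one Ct per (sample, gene, bio_rep)
    ct = (ct_table.groupby(["sample", "gene", "bio_rep"], sort=True)["ct"]
          .mean().reset_index())
    results = []
    for gene in targets:
        tgt = ct[ct["gene"] == gene].set_index(["sample", "bio_rep"])["ct"]
        ref = ct[ct["gene"] == reference_gene].set_index(["sample", "bio_rep"])["ct"]
        dct = (tgt - ref).dropna()
        if calibrator_sample not in dct.index.get_level_values("sample"):
            raise ValueError(f"calibrator sample {calibrator_sample!r} missing for {gene}")
        calib_dct = dct.loc[calibrator_sample].mean()
        for sample, grp in dct.groupby(level="sample"):
            ddct = grp - calib_dct
            folds = 2.0 ** (-ddct)
            mean_ddct = float(ddct.mean())
            results.append(QpcrResult(
                sample=str(sample),
                target_gene=gene,
                delta_ct=float(grp.mean()),
                delta_delta_ct=mean_ddct,
                fold=2.0 ** (-mean_ddct),
                fold_mean=float(folds.mean()),
                fold_sd=float(folds.std(ddof=1)) if len(folds) > 1 else 0.0,
                n_biological=len(folds),
            ))
    return results


def qpcr_table(results: list[QpcrResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# -------------------------------------------------------------- fruit shape

def fsi(vertical: float, horizontal: float) -> float:
    """Fruit shape index: longitudinal over transverse diameter."""
    if vertical <= 0 or horizontal <= 0:
        raise ValueError("diameters must be positive")
    return vertical / horizontal


def percent_increase(treatment_mean: float, control_mean: float) -> float:
    """100 x (treatment - control) / control, 1 decimal half-up."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return round_half_up(100.0 * (treatment_mean - control_mean) / control_mean, 1)


def welch_test(a, b) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_groups(
    measures: pd.DataFrame,
    value_col: str,
    group_col: str,
    control: str | None = None,
) -> pd.DataFrame:
    """Welch tests per contrast with star codes.

    With ``control``, each other group is tested against it; otherwise all
    pairs are tested. Groups with fewer than 2 observations raise.
    """
    groups = {g: grp[value_col].to_numpy(float)
              for g, grp in measures.groupby(group_col, sort=True)}
    if control is not None:
        if control not in groups:
            raise ValueError(f"control group {control!r} not found")
        contrasts = [(g, control) for g in groups if g != control]
    else:
        names = sorted(groups)
        contrasts = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for a, b in contrasts:
        t, p = welch_test(groups[a], groups[b])
        rows.append({
            "group": a, "versus": b,
            "mean": float(np.mean(groups[a])), "versus_mean": float(np.mean(groups[b])),
            "t": t, "p": p, "stars": star_code(p),
        })
    return pd.DataFrame(rows, columns=["group", "versus", "mean", "versus_mean", "t", "p", "stars"])


def pairwise_significance(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> dict[tuple[str, str], bool]:
    """Holm-adjusted pairwise Welch tests; True where the pair differs."""
    names = sorted(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    if not pairs:
        return {}
    pvals = [welch_test(groups[a], groups[b])[1] for a, b in pairs]
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return {pair: bool(rej) for pair, rej in zip(pairs, reject)}


def significance_letters(
    groups: dict[str, "np.ndarray | list[float]"], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display from Holm-adjusted pairwise Welch tests.

    Insert-and-absorb construction: groups share a letter iff the adjusted
    comparison does not separate them. Letters are ordered by descending
    group mean ('a' = highest).
    """
    groups = {k: np.asarray(v, float) for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sig = pairwise_significance(groups, alpha=alpha)
    names = sorted(groups, key=lambda g: -float(np.mean(groups[g])))
    # letters as sets of group names; start with one letter covering all
    letters: list[set[str]] = [set(names)]
    for (a, b), different in sig.items():
        if not different:
            continue
        new_letters = []
        for letter in letters:
            if a in letter and b in letter:
                new_letters.append(letter - {a})
                new_letters.append(letter - {b})
            else:
                new_letters.append(letter)
        # absorb: drop any letter set contained in another
        letters = [
            s for i, s in enumerate(new_letters)
            if s and not any(s < t or (s == t and i > j)
                             for j, t in enumerate(new_letters) if j != i)
        ]
    # order letters by best (highest-mean) member for stable a, b, c labels
    letters.sort(key=lambda s: min(names.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for sym, letter in zip(alphabet, letters):
        for g in letter:
            out[g] += sym
    return {g: "".join(sorted(out[g])) for g in names}


def expression_fsi_regression(expression_values, fsi_values) -> tuple[float, float, float]:
    """OLS of FSI on expression: (slope, intercept, R^2)."""
    x = np.asarray(expression_values, float)
    y = np.asarray(fsi_values, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs of at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in expression values")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue) ** 2


@dataclass(frozen=True)
class FruitStatsResult:
    line: str
    n: int
    mean_fsi: float
    sd_fsi: float
    percent_increase_vs_control: float
    p_vs_control: float
    stars: str


def fruit_stats(
    measures: pd.DataFrame,
    control_line: str = "WT",
    stage: str | None = "mature",
) -> list[FruitStatsResult]:
    """Per-line FSI summary vs the control line at one stage.

    ``measures`` columns: line, fruit_id, stage, vertical, horizontal.
    """
    df = measures if stage is None else measures[measures["stage"].astype(str) == str(stage)]
    if df.empty:
        raise ValueError(f"no measurements at stage {stage!r}")
    df = df.assign(fsi=df["vertical"] / df["horizontal"])
    if control_line not in set(df["line"]):
        raise ValueError(f"control line {control_line!r} not found")
    ctrl = df.loc[df["line"] == control_line, "fsi"].to_numpy(float)
    results = []
    for line, grp in df.groupby("line", sort=True):
        vals = grp["fsi"].to_numpy(float)
        if line == control_line:
            pct, p, stars = 0.0, 1.0, "ns"
        else:
            pct = percent_increase(float(vals.mean()), float(ctrl.mean()))
            _, p = welch_test(vals, ctrl)
            stars = star_code(p)
        results.append(FruitStatsResult(
            line=str(line), n=len(vals),
            mean_fsi=round_half_up(float(vals.mean()), 2),
            sd_fsi=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            percent_increase_vs_control=pct, p_vs_control=float(p), stars=stars,
        ))
    return results


def fruit_stats_table(results: list[FruitStatsResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
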