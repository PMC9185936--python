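"""Multi-environment line x tester ANOVA and combining-ability estimation.

The combined analysis of variance partitions testcross variation into
environment, replicate-within-environment, incomplete-block, line (GCA),
tester (GCA), line x tester (SCA) and their interactions with
environment, using sequential (Type I) least-squares sums of squares.
Hybrids are treated as fixed; environment and the design strata as
random, so factor F-ratios use the matching factor x environment mean
square as denominator when that term is fitted.

General and specific combining-ability effects follow the classical
factorial decomposition of testcross cell means:

    g_i   = x_i.. - x...          (line GCA)
    g_j   = x_.j. - x...          (tester GCA)
    s_ij  = x_ij. - x_i.. - x_.j. + x...
    HSGCA = g_i + s_ij  =  x_ij. - x_.j.

Variance components are obtained by equating observed to expected mean
squares for the balanced design (method of moments), which is exact for
balanced data and fully reproducible; negative estimates are truncated
at zero and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from lxt.trial_io import Condition, EntryRole, LxTDesign

SIGNIFICANCE_LADDER = ((0.0001, "†"), (0.001, "***"), (0.01, "**"), (0.05, "*"))

ANOVA_SOURCES = [
    "environment",
    "rep_in_env",
    "block_in_rep_env",
    "hybrid",
    "line_gca",
    "tester_gca",
    "line_x_tester_sca",
    "hybrid_x_env",
    "line_x_env",
    "tester_x_env",
    "line_x_tester_x_env",
    "error",
]


def significance_code(p: float) -> str:
    """Map a p-value onto the *, **, ***, † ladder (0.05/0.01/0.001/0.0001)."""
    if p is None or np.isnan(p):
        return ""
    for cut, code in SIGNIFICANCE_LADDER:
        if p < cut:
            return code
    return ""


@dataclass
class AnovaTable:
    """Sequential ANOVA for one trait under one research condition."""

    trait: str
    condition: str
    table: pd.DataFrame  # indexed by source: df, ss, ms, f, p
    n_env: int
    n_rep: int
    n_lines: int
    n_testers: int
    n_obs: int
    balanced: bool
    notes: list[str] = field(default_factory=list)

    def df(self, source: str) -> int:
        return int(self.table.loc[source, "df"])

    def ss(self, source: str) -> float:
        return float(self.table.loc[source, "ss"])

    def ms(self, source: str) -> float:
        return float(self.table.loc[source, "ms"])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["sig"] = [significance_code(p) for p in out["p"]]
        return out


@dataclass
class CombiningAbilityResult:
    """GCA/SCA/HSGCA effects with standard errors and significance."""

    trait: str
    condition: str
    grand_mean: float
    gca_line: pd.Series
    gca_tester: pd.Series
    sca: pd.DataFrame  # lines x testers
    hsgca: pd.DataFrame  # lines x testers
    se_gca_line: float
    se_gca_tester: float
    se_sca: float
    p_gca_line: pd.Series
    p_gca_tester: pd.Series
    p_sca: pd.DataFrame
    mse: float
    error_df: int
    n_env: int
    n_rep: int

    def effects_frame(self) -> pd.DataFrame:
        """Table-shaped summary: one row per line with GCA and per-tester SCA."""
        rows = []
        for line in self.gca_line.index:
            row = {
                "line": line,
                "gca": self.gca_line[line],
                "gca_sig": significance_code(self.p_gca_line[line]),
            }
            for tester in self.gca_tester.index:
                row[f"sca_{tester}"] = self.sca.loc[line, tester]
                row[f"hsgca_{tester}"] = self.hsgca.loc[line, tester]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class VarianceComponents:
    """Method-of-moments variance components and derived genetic ratios."""

    sigma2_gca_line: float
    sigma2_gca_tester: float
    sigma2_sca: float
    sigma2_line_x_env: float
    sigma2_tester_x_env: float
    sigma2_sca_x_env: float
    sigma2_error: float
    f_coefficient: float
    sigma2_a: float
    sigma2_d: float
    sigma2_ge: float
    h2_narrow: float
    repeatability: float
    n_env: int
    n_rep: int
    truncated: list[str] = field(default_factory=list)


def _testcross_subset(frame: pd.DataFrame, trait: str, condition) -> pd.DataFrame:
    condition = Condition(condition).value
    sub = frame[
        (frame["condition"] == condition)
        & (frame["entry_role"] == EntryRole.TESTCROSS.value)
    ]
    sub = sub.dropna(subset=[trait])
    if sub.empty:
        raise ValueError(
            f"no testcross observations for trait {trait!r} under {condition!r}"
        )
    return sub


def _dummies(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels.astype(str)).to_numpy(dtype=float)


def _sequential_ss(y: np.ndarray, blocks: list[tuple[str, np.ndarray]]):
    """Residual SS and model rank after each cumulative block of columns.

    Returns {name: (rss, rank)} for the model including all blocks up to
    and including *name*, plus the intercept-only entry under "1".
    """
    n = len(y)
    out = {}
    tss = float(np.sum((y - y.mean()) ** 2))
    out["1"] = (tss, 1)
    x = np.ones((n, 1))
    yty = float(y @ y)
    for name, cols in blocks:
        x = np.hstack([x, cols])
        # SVD projection: dummy matrices are exactly collinear, so rank
        # needs a scaled tolerance rather than lstsq's default
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        rank = int(np.sum(s > s[0] * max(x.shape) * np.finfo(float).eps))
        proj = u[:, :rank].T @ y
        rss = max(yty - float(proj @ proj), 0.0)
        out[name] = (rss, rank)
    return out


def anova_line_by_tester(
    frame: pd.DataFrame,
    trait: str,
    condition,
    design: LxTDesign | None = None,
) -> AnovaTable:
    """Combined line x tester ANOVA across environments for one trait.

    Checks and the tester-cross hybrid are excluded before partitioning.
    Sums of squares are sequential in the model order
    env, rep(env), block(env x rep), line, tester, line x tester,
    line x env, tester x env, line x tester x env, residual.
    With a single environment the env-interaction rows are omitted and
    factors are tested against the residual mean square.
    """
    sub = _testcross_subset(frame, trait, condition)
    y = sub[trait].to_numpy(dtype=float)
    n = len(y)

    env = sub["environment"].astype(str)
    rep = env + ":" + sub["replicate"].astype(str)
    blk = rep + ":" + sub["block"].astype(str)
    line = sub["line"].astype(str)
    tester = sub["tester"].astype(str)
    lxt = line + ":" + tester
    n_env = env.nunique()
    n_rep = sub.groupby("environment")["replicate"].nunique().max()
    n_lines = line.nunique()
    n_testers = tester.nunique()

    cell_counts = sub.groupby(
        [env.rename("e"), rep.rename("r"), lxt.rename("h")]
    ).size()
    expected_cells = n_env * n_rep * n_lines * n_testers
    balanced = len(cell_counts) == expected_cells and cell_counts.nunique() == 1
    notes = []
    if not balanced:
        notes.append("unbalanced core: least-squares fit on available data")

    multi_env = n_env > 1
    blocks = [
        ("environment", _dummies(env)),
        ("rep_in_env", _dummies(rep)),
        ("block_in_rep_env", _dummies(blk)),
        ("line_gca", _dummies(line)),
        ("tester_gca", _dummies(tester)),
        ("line_x_tester_sca", _dummies(lxt)),
    ]
    if multi_env:
        blocks += [
            ("line_x_env", _dummies(line + "@" + env)),
            ("tester_x_env", _dummies(tester + "@" + env)),
            ("line_x_tester_x_env", _dummies(lxt + "@" + env)),
        ]
    else:
        notes.append("single environment: env-interaction rows omitted")

    path = _sequential_ss(y, blocks)

    order = ["1"] + [name for name, _ in blocks]
    rows = {}
    for prev, cur in zip(order[:-1], order[1:]):
        rss_prev, rank_prev = path[prev]
        rss_cur, rank_cur = path[cur]
        rows[cur] = {"df": rank_cur - rank_prev, "ss": max(rss_prev - rss_cur, 0.0)}
    rss_full, rank_full = path[order[-1]]
    rows["error"] = {"df": n - rank_full, "ss": rss_full}

    # hybrid spans line + tester + line x tester; same for the env interactions
    rows["hybrid"] = {
        "df": sum(rows[s]["df"] for s in ("line_gca", "tester_gca", "line_x_tester_sca")),
        "ss": sum(rows[s]["ss"] for s in ("line_gca", "tester_gca", "line_x_tester_sca")),
    }
    if multi_env:
        rows["hybrid_x_env"] = {
            "df": sum(
                rows[s]["df"]
                for s in ("line_x_env", "tester_x_env", "line_x_tester_x_env")
            ),
            "ss": sum(
                rows[s]["ss"]
                for s in ("line_x_env", "tester_x_env", "line_x_tester_x_env")
            ),
        }

    source_order = [s for s in ANOVA_SOURCES if s in rows]
    table = pd.DataFrame.from_dict(rows, orient="index").loc[source_order]
    table["ms"] = np.where(table["df"] > 0, table["ss"] / table["df"].where(table["df"] > 0, 1), np.nan)

    # F-ratio denominators: factor x env MS when fitted, else error MS;
    # environment against rep(env); design strata against error.
    def _denom(src: str) -> str | None:
        if src == "environment":
            return "rep_in_env"
        if src in ("rep_in_env", "block_in_rep_env"):
            return "error"
        if src in ("hybrid", "line_gca", "tester_gca", "line_x_tester_sca"):
            inter = {
                "hybrid": "hybrid_x_env",
                "line_gca": "line_x_env",
                "tester_gca": "tester_x_env",
                "line_x_tester_sca": "line_x_tester_x_env",
            }[src]
            return inter if inter in rows else "error"
        if src.endswith("_x_env"):
            return "error"
        return None

    fvals, pvals = [], []
    for src in source_order:
        den = _denom(src)
        if den is None or np.isnan(table.loc[src, "ms"]):
            fvals.append(np.nan)
            pvals.append(np.nan)
            continue
        ms_den = table.loc[den, "ms"]
        df_num = table.loc[src, "df"]
        df_den = table.loc[den, "df"]
        if not np.isfinite(ms_den) or ms_den <= 0 or df_den <= 0 or df_num <= 0:
            fvals.append(np.nan)
            pvals.append(np.nan)
            continue
        f = table.loc[src, "ms"] / ms_den
        fvals.append(f)
        pvals.append(float(stats.f.sf(f, df_num, df_den)))
    table["f"] = fvals
    table["p"] = pvals

    return AnovaTable(
        trait=trait,
        condition=Condition(condition).value,
        table=table,
        n_env=int(n_env),
        n_rep=int(n_rep),
        n_lines=int(n_lines),
        n_testers=int(n_testers),
        n_obs=n,
        balanced=bool(balanced),
        notes=notes,
    )


def estimate_gca_sca(
    frame: pd.DataFrame,
    trait: str,
    condition,
    anova: AnovaTable | None = None,
) -> CombiningAbilityResult:
    """GCA, SCA and HSGCA effects from testcross cell means.

    Effects are computed from raw line x tester means pooled over
    replicates and environments, so the centering identities
    (sum of GCA per factor = 0, SCA margins = 0) hold exactly.
    Standard errors use the error mean square of the combined ANOVA:
    SE(g_line) = sqrt(MSE/(r e t)), SE(g_tester) = sqrt(MSE/(r e l)),
    SE(s) = sqrt(MSE/(r e)); two-sided t-tests on the error df.
    """
    sub = _testcross_subset(frame, trait, condition)
    if anova is None:
        anova = anova_line_by_tester(frame, trait, condition)

    cell = sub.groupby(["line", "tester"])[trait].mean().unstack("tester")
    line_means = cell.mean(axis=1)
    tester_means = cell.mean(axis=0)
    grand = float(cell.to_numpy().mean())

    gca_line = line_means - grand
    gca_tester = tester_means - grand
    sca = cell.sub(line_means, axis=0).sub(tester_means, axis=1) + grand
    hsgca = sca.add(gca_line, axis=0)

    r, e = anova.n_rep, anova.n_env
    t, l = anova.n_testers, anova.n_lines
    mse = anova.ms("error")
    edf = anova.df("error")
    if edf > 0 and np.isfinite(mse):
        se_gl = float(np.sqrt(mse / (r * e * t)))
        se_gt = float(np.sqrt(mse / (r * e * l)))
        se_s = float(np.sqrt(mse / (r * e)))
        p_gl = pd.Series(
            2 * stats.t.sf(np.abs(gca_line / se_gl), edf), index=gca_line.index
        )
        p_gt = pd.Series(
            2 * stats.t.sf(np.abs(gca_tester / se_gt), edf), index=gca_tester.index
        )
        p_s = pd.DataFrame(
            2 * stats.t.sf(np.abs(sca / se_s), edf),
            index=sca.index,
            columns=sca.columns,
        )
    else:  # zero error df: effects still valid, inference is not
        se_gl = se_gt = se_s = float("nan")
        p_gl = pd.Series(np.nan, index=gca_line.index)
        p_gt = pd.Series(np.nan, index=gca_tester.index)
        p_s = pd.DataFrame(np.nan, index=sca.index, columns=sca.columns)

    return CombiningAbilityResult(
        trait=trait,
        condition=Condition(condition).value,
        grand_mean=grand,
        gca_line=gca_line,
        gca_tester=gca_tester,
        sca=sca,
        hsgca=hsgca,
        se_gca_line=se_gl,
        se_gca_tester=se_gt,
        se_sca=se_s,
        p_gca_line=p_gl,
        p_gca_tester=p_gt,
        p_sca=p_s,
        mse=float(mse),
        error_df=int(edf),
        n_env=e,
        n_rep=r,
    )


def _truncate(value: float, name: str, flags: list[str]) -> float:
    if value < 0:
        flags.append(name)
        return 0.0
    return value


def estimate_variance_components(
    anova: AnovaTable, f_coefficient: float = 1.0
) -> VarianceComponents:
    """Variance components by equating observed to expected mean squares.

    For the balanced design with centered random effects:

        sigma2_sca        = (MS_lxt - MS_lxt.e) / (r e)
        sigma2_gca_line   = (MS_line - MS_line.e) / (r e t)
        sigma2_gca_tester = (MS_tester - MS_tester.e) / (r e l)
        sigma2_sca_x_env  = (MS_lxt.e - MS_error) / r
        sigma2_line_x_env = (MS_line.e - MS_lxt.e) / (r t)
        sigma2_tester_x_env = (MS_tester.e - MS_lxt.e) / (r l)

    With both parents inbred (coefficient of inbreeding F, default 1):

        sigma2_A = [4/(1+F)] (sigma2_gca_line + sigma2_gca_tester)
        sigma2_D = [4/(1+F)^2] sigma2_sca

    Narrow-sense heritability on an entry-mean basis uses
    sigma2_A / (sigma2_A + sigma2_D + sigma2_GE/e + sigma2_error/(r e))
    where sigma2_GE aggregates the additive- and dominance-by-environment
    components on the same scale. Negative estimates are truncated to
    zero and their names recorded in ``truncated``.
    """
    r, e = anova.n_rep, anova.n_env
    l, t = anova.n_lines, anova.n_testers
    mse = anova.ms("error")
    flags: list[str] = []

    have_env = "line_x_tester_x_env" in anova.table.index
    if have_env:
        ms_lte = anova.ms("line_x_tester_x_env")
        ms_le = anova.ms("line_x_env")
        ms_te = anova.ms("tester_x_env")
    else:
        # single environment (or interactions not fitted): factors are
        # tested and estimated against the error mean square
        ms_lte = ms_le = ms_te = mse

    s2_sca = _truncate((anova.ms("line_x_tester_sca") - ms_lte) / (r * e), "sigma2_sca", flags)
    s2_gl = _truncate((anova.ms("line_gca") - ms_le) / (r * e * t), "sigma2_gca_line", flags)
    s2_gt = _truncate((anova.ms("tester_gca") - ms_te) / (r * e * l), "sigma2_gca_tester", flags)
    if have_env:
        s2_se = _truncate((ms_lte - mse) / r, "sigma2_sca_x_env", flags)
        s2_le = _truncate((ms_le - ms_lte) / (r * t), "sigma2_line_x_env", flags)
        s2_te = _truncate((ms_te - ms_lte) / (r * l), "sigma2_tester_x_env", flags)
    else:
        s2_se = s2_le = s2_te = 0.0

    f1 = 1.0 + f_coefficient
    s2_a = (4.0 / f1) * (s2_gl + s2_gt)
    s2_d = (4.0 / f1**2) * s2_sca
    s2_ge = (4.0 / f1) * (s2_le + s2_te) + (4.0 / f1**2) * s2_se

    denom = s2_a + s2_d + s2_ge / e + mse / (r * e)
    h2 = s2_a / denom if denom > 0 else float("nan")
    h2 = float(min(max(h2, 0.0), 1.0)) if np.isfinite(h2) else h2

    return VarianceComponents(
        sigma2_gca_line=s2_gl,
        sigma2_gca_tester=s2_gt,
        sigma2_sca=s2_sca,
        sigma2_line_x_env=s2_le,
        sigma2_tester_x_env=s2_te,
        sigma2_sca_x_env=s2_se,
        sigma2_error=float(mse),
        f_coefficient=f_coefficient,
        sigma2_a=s2_a,
        sigma2_d=s2_d,
        sigma2_ge=s2_ge,
        h2_narrow=h2,
        repeatability=repeatability(anova),
        n_env=e,
        n_rep=r,
        truncated=flags,
    )


def repeatability(anova: AnovaTable) -> float:
    """Entry-mean repeatability of hybrid performance across environments.

    R = sigma2_h / (sigma2_h + sigma2_hxe/e + sigma2_error/(r e)) with
    sigma2_h = (MS_hybrid - MS_hybrid.env)/(r e) and
    sigma2_hxe = (MS_hybrid.env - MS_error)/r; negatives truncated at 0.
    """
    r, e = anova.n_rep, anova.n_env
    mse = anova.ms("error")
    ms_h = anova.ms("hybrid")
    ms_he = anova.ms("hybrid_x_env") if "hybrid_x_env" in anova.table.index else mse
    s2_h = max((ms_h - ms_he) / (r * e), 0.0)
    s2_he = max((ms_he - mse) / r, 0.0)
    denom = s2_h + s2_he / e + mse / (r * e)
    if denom <= 0:
        return float("nan")
    return float(min(max(s2_h / denom, 0.0), 1.0))
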