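"""Standard heterosis, infestation yield loss, and heterotic grouping.

Two complementary classifiers assign candidate lines to the heterotic
groups represented by the two testers (HGA by T1, HGB by T2):

* the SCA + yield rule — a line goes to the group *opposite* the tester
  it combines best with: positive SCA above a threshold with one tester,
  negative with the other, and testcross yield not significantly below
  the tester-cross (T1 x T2) check;
* the HSGCA rule — the sign of HSGCA (= GCA + SCA) with each tester
  decides; when both testers give the same sign, the tester with the
  smaller HSGCA value decides (most-negative reading of the tie-break,
  with a toggle for the closest-to-zero reading).

Group naming is a fixed constant: evidence with T1 maps to HGB and
evidence with T2 maps to HGA, because a line that nicks with a tester
belongs to the complementary group.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lxt.combining_ability import AnovaTable, CombiningAbilityResult


class Group(str, enum.Enum):
    HGA = "HGA"
    HGB = "HGB"
    UNASSIGNED = "unassigned"
    INCONSISTENT = "inconsistent"


class TieRule(str, enum.Enum):
    MIN_VALUE = "min_value"  # smaller HSGCA (most negative) decides
    MAX_VALUE = "max_value"  # larger HSGCA decides (closest-to-zero for negatives)


@dataclass(frozen=True)
class GroupAssignment:
    line: str
    method: str  # "sca_yield" | "hsgca"
    condition: str
    group: Group
    evidence: Mapping[str, float | str] = field(default_factory=dict)


def standard_heterosis(f1: float, ck: float) -> float:
    """Percent yield advantage of a testcross over the tester-cross check.

    H = 100 (F1 - CK) / CK, where CK is the mean of the hybrid between
    the two testers.
    """
    if ck == 0:
        raise ZeroDivisionError("check mean is zero: standard heterosis undefined")
    return 100.0 * (f1 - ck) / ck


def yield_loss(y_noninfested: float, y_infested: float) -> tuple[float, bool]:
    """Percent grain-yield loss under infestation relative to clean plots.

    Returns ``(loss_percent, gained)``; ``gained`` is True when the
    infested yield exceeded the non-infested yield (negative loss).
    """
    if y_noninfested <= 0:
        raise ValueError("non-infested yield must be positive")
    loss = 100.0 * (y_noninfested - y_infested) / y_noninfested
    return loss, loss < 0


def heterosis_table(
    entry_means: pd.Series, ck_mean: float, trait: str = "yield", condition: str = ""
) -> pd.DataFrame:
    """Standard heterosis for every entry in *entry_means* against *ck_mean*."""
    rows = [
        {
            "entry": entry,
            "trait": trait,
            "condition": condition,
            "f1": f1,
            "ck": ck_mean,
            "h_percent": standard_heterosis(f1, ck_mean),
        }
        for entry, f1 in entry_means.items()
    ]
    return pd.DataFrame(rows)


def lsd_yield(anova: AnovaTable, alpha: float = 0.05) -> float:
    """Least significant difference between two entry means.

    LSD = t(alpha/2, df_error) * sqrt(2 MSE / (r e)) from the combined
    ANOVA; used as the yield gate in the SCA + yield classifier.
    """
    mse = anova.ms("error")
    edf = anova.df("error")
    r, e = anova.n_rep, anova.n_env
    tcrit = stats.t.ppf(1 - alpha / 2, edf)
    return float(tcrit * np.sqrt(2 * mse / (r * e)))


# Fixed group map: a line nicking with T1 joins the group opposite T1.
def _group_for_tester(tester_idx: int) -> Group:
    return Group.HGB if tester_idx == 0 else Group.HGA


def assign_groups_sca_yield(
    ca: CombiningAbilityResult,
    testcross_means: pd.DataFrame,
    ck_mean: float,
    lsd: float,
    sca_threshold: float = 100.0,
) -> list[GroupAssignment]:
    """SCA + testcross-yield heterotic grouping (two testers).

    *testcross_means* is a lines x testers table of mean grain yields.
    A line joins HGB when sca(line, T1) > sca_threshold, sca(line, T2)
    < 0, and mean(line x T1) >= ck_mean - lsd (not significantly below
    the tester-cross); symmetrically for HGA via T2. Otherwise the line
    stays unassigned, with the evidence recorded.
    """
    testers = list(ca.sca.columns)
    if len(testers) != 2:
        raise ValueError("SCA + yield grouping requires exactly two testers")
    if lsd <= 0:
        raise ValueError("lsd must be positive")
    out = []
    for line in ca.sca.index:
        evidence: dict[str, float | str] = {"lsd": lsd, "ck_mean": ck_mean}
        group = Group.UNASSIGNED
        for idx, (this_t, other_t) in enumerate(
            [(testers[0], testers[1]), (testers[1], testers[0])]
        ):
            s_this = ca.sca.loc[line, this_t]
            s_other = ca.sca.loc[line, other_t]
            evidence[f"sca_{this_t}"] = float(s_this)
            try:
                mean_this = float(testcross_means.loc[line, this_t])
            except KeyError:
                evidence["reason"] = "insufficient data"
                continue
            evidence[f"mean_{this_t}"] = mean_this
            if np.isnan(mean_this):
                evidence["reason"] = "insufficient data"
                continue
            if s_this > sca_threshold and s_other < 0 and mean_this >= ck_mean - lsd:
                group = _group_for_tester(idx)
                evidence["deciding_tester"] = this_t
                break
        out.append(
            GroupAssignment(
                line=line,
                method="sca_yield",
                condition=ca.condition,
                group=group,
                evidence=evidence,
            )
        )
    return out


def hsgca_effects(ca: CombiningAbilityResult) -> pd.DataFrame:
    """HSGCA(i, j) = GCA(line i) + SCA(i, j), a lines x testers table.

    In balanced data this equals the testcross mean of i x j minus the
    mean over all lines of testcrosses with tester j.
    """
    return ca.sca.add(ca.gca_line, axis=0)


def assign_groups_hsgca(
    hsgca: pd.DataFrame,
    tie_rule: TieRule | str = TieRule.MIN_VALUE,
    condition: str = "",
    dead_zone: float = 0.0,
) -> list[GroupAssignment]:
    """HSGCA heterotic grouping (two testers).

    Positive HSGCA with T1 assigns to HGB; positive with T2 assigns to
    HGA. When both testers give the same sign, the tie rule decides:
    under ``min_value`` (default) the tester with the smaller HSGCA
    (most negative) decides and the line takes that tester's mapped
    group; ``max_value`` uses the larger value instead. Values within
    ``dead_zone`` of zero count as neither positive nor negative; a line
    whose values both fall in the dead zone, or with a missing value,
    is left unassigned.
    """
    tie_rule = TieRule(tie_rule)
    testers = list(hsgca.columns)
    if len(testers) != 2:
        raise ValueError("HSGCA grouping requires exactly two testers")
    out = []
    for line in hsgca.index:
        v1, v2 = float(hsgca.loc[line, testers[0]]), float(hsgca.loc[line, testers[1]])
        evidence = {f"hsgca_{testers[0]}": v1, f"hsgca_{testers[1]}": v2}
        if np.isnan(v1) or np.isnan(v2):
            group = Group.UNASSIGNED
            evidence["reason"] = "missing HSGCA value"
        else:
            pos1 = v1 > dead_zone
            pos2 = v2 > dead_zone
            neg1 = v1 < -dead_zone
            neg2 = v2 < -dead_zone
            if pos1 and not pos2:
                group, evidence["deciding_tester"] = _group_for_tester(0), testers[0]
            elif pos2 and not pos1:
                group, evidence["deciding_tester"] = _group_for_tester(1), testers[1]
            elif (pos1 and pos2) or (neg1 and neg2):
                if tie_rule is TieRule.MIN_VALUE:
                    idx = 0 if v1 <= v2 else 1
                else:
                    idx = 0 if v1 >= v2 else 1
                group = _group_for_tester(idx)
                evidence["deciding_tester"] = testers[idx]
                evidence["tie_rule"] = tie_rule.value
            else:  # both inside the dead zone
                group = Group.UNASSIGNED
                evidence["reason"] = "values inside dead zone"
        out.append(
            GroupAssignment(
                line=line,
                method="hsgca",
                condition=condition,
                group=group,
                evidence=evidence,
            )
        )
    return out


def consensus_groups(
    assignments: Sequence[GroupAssignment],
) -> pd.DataFrame:
    """Per-line consensus over conditions, per method.

    A line gets a consensus group iff all its non-unassigned condition
    calls agree; ``inconsistent`` otherwise; ``unassigned`` if no
    condition produced a call. ``n_conditions`` counts the conditions
    with a real call (coverage).
    """
    rows = []
    frame = pd.DataFrame(
        [
            {
                "line": a.line,
                "method": a.method,
                "condition": a.condition,
                "group": a.group.value,
            }
            for a in assignments
        ]
    )
    for (line, method), grp in frame.groupby(["line", "method"]):
        calls = [g for g in grp["group"] if g != Group.UNASSIGNED.value]
        if not calls:
            consensus = Group.UNASSIGNED.value
        elif len(set(calls)) == 1:
            consensus = calls[0]
        else:
            consensus = Group.INCONSISTENT.value
        rows.append(
            {
                "line": line,
                "method": method,
                "consensus": consensus,
                "n_conditions": len(calls),
                "n_total": len(grp),
            }
        )
    return pd.DataFrame(rows)
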