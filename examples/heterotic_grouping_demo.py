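"""Heterosis and heterotic-group assignment on a simulated trial.

Computes standard heterosis of each testcross against the tester-cross
check, the infestation yield loss of the checks, and classifies the
lines into the two tester-defined heterotic groups with both rules
(SCA + yield, HSGCA), then forms the cross-condition consensus.
"""

from lxt import (
    TrialSimConfig,
    anova_line_by_tester,
    assign_groups_hsgca,
    assign_groups_sca_yield,
    cell_means,
    consensus_groups,
    estimate_gca_sca,
    hsgca_effects,
    simulate_trial,
    standard_heterosis,
    yield_loss,
)
from lxt.heterosis_grouping import lsd_yield
from lxt.synthetic_data import CHECK_SUSCEPTIBLE, TESTER_CROSS

frame, _ = simulate_trial(TrialSimConfig(seed=42))

by = frame.groupby(["condition", "entry"])["yield"].mean()
for entry in (CHECK_SUSCEPTIBLE, TESTER_CROSS):
    loss, _ = yield_loss(by["non_infested"][entry], by["infested"][entry])
    print(f"{entry}: {loss:.0f}% grain-yield loss under infestation")

ck = by["infested"][TESTER_CROSS]
means = cell_means(frame, "yield", "infested").set_index("entry")["mean"]
h = means.drop(TESTER_CROSS).map(lambda f1: standard_heterosis(f1, ck))
print(f"\nstandard heterosis vs {TESTER_CROSS}: "
      f"min {h.min():.0f}%, max {h.max():.0f}% "
      "(positive = testcross out-yields the tester-cross check)\n")

assignments = []
for condition in ("infested", "non_infested"):
    an = anova_line_by_tester(frame, "yield", condition)
    res = estimate_gca_sca(frame, "yield", condition, anova=an)
    tc = (
        frame[(frame["condition"] == condition)
              & (frame["entry_role"] == "testcross")]
        .groupby(["line", "tester"])["yield"].mean().unstack("tester")
    )
    ck_c = frame[frame["entry"] == TESTER_CROSS]
    ck_mean = ck_c[ck_c["condition"] == condition]["yield"].mean()
    assignments += assign_groups_sca_yield(
        res, tc, ck_mean, lsd_yield(an), sca_threshold=100.0
    )
    assignments += assign_groups_hsgca(hsgca_effects(res), condition=condition)

consensus = consensus_groups(assignments)
print("consensus group per line and method (HGA = nicks with T2, "
      "HGB = nicks with T1):")
print(consensus.pivot(index="line", columns="method", values="consensus")
      .to_string())
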