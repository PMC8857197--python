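"""Community integration of inference methods and gold-standard scoring.

Combines two disagreeing ranked prediction lists by average rank position
(missing entries penalized with list length + 1), prunes the aggregate,
and scores individual and community rankings against a gold standard.
"""

from grnkit import (
    GRN,
    RankedPredictions,
    RegulatoryInteraction,
    integrate,
    integrate_scores,
    pr_curve,
    prune_top,
    restrict_to_gold,
)

gold = GRN(
    [RegulatoryInteraction("tfA", "g1"), RegulatoryInteraction("tfA", "g2"),
     RegulatoryInteraction("tfB", "g3")],
    label="gold-standard",
)

method_1 = RankedPredictions.from_scores(
    [("tfA", "g1", 0.9), ("tfB", "g3", 0.8), ("tfA", "g4", 0.7), ("tfB", "g1", 0.6)],
    method_label="binding-sites",
)
method_2 = RankedPredictions.from_scores(
    [("tfA", "g2", 5.0), ("tfA", "g1", 4.0), ("tfB", "g4", 3.0)],
    method_label="expression",
)

for score in integrate_scores([method_1, method_2]):
    print(f"  {score.interaction}: mean rank {score.mean_rank:.1f} "
          f"(in {score.support}/2 lists)")

community = prune_top(integrate([method_1, method_2]), 4)
for label, ranking in [("method 1", method_1), ("method 2", method_2),
                       ("community", community)]:
    aupr = pr_curve(restrict_to_gold(ranking, gold), gold).auc
    print(f"{label:>10}: AUPR = {aupr:.3f}")
# tfA->g1 is ranked 1 and 2 by the two methods, so it tops the community
# list (mean rank 1.5); interactions seen by only one list carry the
# length+1 penalty from the list that missed them.
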