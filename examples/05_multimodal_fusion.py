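"""Majority-vote fusion of voice and tremor decisions over synthetic patients.

Trains three classifiers per modality, composes multi-instance patient
profiles, and applies the 2-of-3 majority vote with contradiction
resolution and the 60% average-score threshold.
"""

import pdscreen as pds
from pdscreen.cli import run_fusion_chain
from pdscreen.tremor import feature_names

voice = pds.simulate_feature_table(40, 40, seed=21)
tremor = pds.simulate_feature_table(
    40, 40, feature_names=feature_names(),
    effect=pds.default_effect_profile(feature_names(), 3.0), seed=22)

decisions = run_fusion_chain(voice, tremor, instances=3, folds=5, seed=1)
correct = sum(1 for d, truth in decisions if d.final_status == truth)
resolved_first = sum(1 for d, _ in decisions if d.instances_used == 1)

print(f"patients fused:        {len(decisions)}")
print(f"fused accuracy:        {100 * correct / len(decisions):.1f}%")
print(f"agreed on instance 1:  {resolved_first}")
d0 = decisions[0][0]
print(f"example patient {d0.patient_id}: status={d0.final_status}, "
      f"instances used={d0.instances_used}, average score={d0.average_score:.2f}")
# Fused accuracy should meet or exceed the better single-modality accuracy:
# a patient is non-PD only when both modalities vote negative.
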