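"""Published clinical benchmark confusion matrices.

Pooled 2×2 confusion matrices reported for the original clinical
evaluation of this method: 270 mobile-phone pull-to-sit videos of 41
high-risk infants, scored over 30 repeated 5-fold stratified
cross-validations (8100 pooled test results), once with the full
thirteen-keypoint skeleton and once with the five-keypoint
domain-knowledge subset. The raw videos are not public; these pooled
counts are the study's published summary and serve here as reference
inputs for the metric operations.

Keys are ``(subset, task)`` with subset in {'thirteen', 'five'} and task
in {'level0_vs_rest', 'level3_vs_rest'}.
"""

from __future__ import annotations

from .evaluate import ConfusionMatrix2x2

CLINICAL_POOLED_CONFUSION: dict[tuple[str, str], ConfusionMatrix2x2] = {
    ("thirteen", "level0_vs_rest"): ConfusionMatrix2x2(
        tp=2498, fn=22, fp=1787, tn=3793, positive_class="level 0"
    ),
    ("five", "level0_vs_rest"): ConfusionMatrix2x2(
        tp=2468, fn=52, fp=915, tn=4665, positive_class="level 0"
    ),
    ("thirteen", "level3_vs_rest"): ConfusionMatrix2x2(
        tp=2156, fn=244, fp=76, tn=5624, positive_class="level 3"
    ),
    ("five", "level3_vs_rest"): ConfusionMatrix2x2(
        tp=2053, fn=347, fp=112, tn=5588, positive_class="level 3"
    ),
}

#: Class sizes of the clinical collection (level -> number of videos).
CLINICAL_CLASS_COUNTS: dict[int, int] = {0: 84, 1: 106, 3: 80}
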