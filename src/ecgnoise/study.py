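"""Reference numbers from the original annotated study cohort.

The annotated long-term-monitoring database behind this package is private;
what is public are its summary figures: the instance counts per class and
noise type, and the per-held-out-patient confusion matrices of the tuned
single-layer perceptron.  They are kept here so the metric arithmetic can be
exercised and reported without access to the raw signals.
"""

from __future__ import annotations

from .models import ConfusionCounts

#: 5-s instance counts of the full annotated database, per binary class
#: and per clinical-noise type (T4 segments are excluded from modelling).
DATABASE_CLASS_COUNTS = {"clean": 3867, "noisy": 2881}
DATABASE_TYPE_COUNTS = {"T0": 2236, "T1": 1631, "T2": 2204, "T3": 677}
DATABASE_TOTAL = 6748

#: patients retained for model design (both classes >= 25% of instances)
RETAINED_PATIENTS = ("2", "4", "6", "7", "9", "10")

#: per-held-out-patient confusion counts of the tuned perceptron
#: (positive class = clean)
SLP_TEST_CONFUSIONS: dict[str, ConfusionCounts] = {
    "2": ConfusionCounts(tp=174, fn=67, fp=52, tn=320),
    "4": ConfusionCounts(tp=124, fn=4, fp=10, tn=371),
    "6": ConfusionCounts(tp=180, fn=66, fp=243, tn=76),
    "7": ConfusionCounts(tp=211, fn=3, fp=79, tn=36),
    "9": ConfusionCounts(tp=92, fn=64, fp=4, tn=128),
    "10": ConfusionCounts(tp=223, fn=109, fp=12, tn=170),
}
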