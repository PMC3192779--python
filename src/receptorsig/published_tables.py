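"""Published validation confusion matrices for the three receptor signatures.

These are the reported cross-tabulations of predictor calls against clinical
receptor status for the GEO cohorts on which the 24-gene ER, 14-gene ERBB2
and 51-gene PR signatures (and their single-probe EM baselines) were
validated. Rows follow the reporting convention: the predictor-negative row
holds (tn, fn) and the predictor-positive row (fp, tp), with columns ordered
clinically-negative, clinically-positive. They serve as worked-example
inputs for the evaluation battery — every headline percentage and Fisher p
is recomputable from them with :func:`receptorsig.evaluation.metrics`.

Keys are ``(receptor, accession, method)`` with method ``"signature"`` or
``"best_probe"``.
"""

from __future__ import annotations

from .evaluation import ConfusionMatrix

__all__ = ["VALIDATION_TABLES", "ERBB2_U133A_DATASETS"]

VALIDATION_TABLES: dict[tuple[str, str, str], ConfusionMatrix] = {
    # ER: training GSE3494, validation GSE2034/GSE7390/GSE2603/GSE20271/GSE20194
    ("ER", "GSE3494", "signature"): ConfusionMatrix(tp=188, fp=3, tn=31, fn=25),
    ("ER", "GSE3494", "best_probe"): ConfusionMatrix(tp=191, fp=5, tn=29, fn=22),
    ("ER", "GSE2034", "signature"): ConfusionMatrix(tp=183, fp=9, tn=68, fn=26),
    ("ER", "GSE7390", "signature"): ConfusionMatrix(tp=124, fp=12, tn=52, fn=10),
    ("ER", "GSE2603", "signature"): ConfusionMatrix(tp=54, fp=0, tn=41, fn=2),
    ("ER", "GSE20271", "signature"): ConfusionMatrix(tp=61, fp=13, tn=54, fn=16),
    ("ER", "GSE20194", "signature"): ConfusionMatrix(tp=147, fp=11, tn=103, fn=17),
    # ERBB2: training GSE2603 + GSE20271, validation GSE20194/GSE16446
    ("ERBB2", "GSE2603", "signature"): ConfusionMatrix(tp=7, fp=4, tn=75, fn=2),
    ("ERBB2", "GSE2603", "best_probe"): ConfusionMatrix(tp=7, fp=2, tn=78, fn=1),
    ("ERBB2", "GSE20271", "signature"): ConfusionMatrix(tp=13, fp=7, tn=115, fn=9),
    ("ERBB2", "GSE20271", "best_probe"): ConfusionMatrix(tp=9, fp=7, tn=115, fn=13),
    ("ERBB2", "GSE20194", "signature"): ConfusionMatrix(tp=45, fp=1, tn=218, fn=14),
    ("ERBB2", "GSE16446", "signature"): ConfusionMatrix(tp=26, fp=1, tn=61, fn=5),
    # PR: training GSE3494, validation GSE20271/GSE20194/GSE9195
    ("PR", "GSE3494", "signature"): ConfusionMatrix(tp=159, fp=16, tn=45, fn=31),
    ("PR", "GSE3494", "best_probe"): ConfusionMatrix(tp=173, fp=32, tn=29, fn=17),
    ("PR", "GSE20271", "signature"): ConfusionMatrix(tp=50, fp=16, tn=63, fn=15),
    ("PR", "GSE20194", "signature"): ConfusionMatrix(tp=99, fp=50, tn=107, fn=22),
    ("PR", "GSE9195", "signature"): ConfusionMatrix(tp=40, fp=6, tn=9, fn=24),
}

#: HG-U133A cohorts entering the ERBB2 cross-dataset confidence intervals
#: (GSE16446, on HG-U133 Plus 2.0, is the held-out platform)
ERBB2_U133A_DATASETS = ("GSE2603", "GSE20271", "GSE20194")
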