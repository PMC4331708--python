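"""Published reference values for the viral pre-miRNA benchmark.

``REPORTED_FSCORES`` are the F-scores reported for the 54 features on the
original benchmark (263 experimentally validated viral pre-miRNAs from 26
virus species against virus-genome fragment negatives).  They are shipped so
users can reproduce the published compact model (features scoring >= 0.60)
without access to the original miRBase-derived datasets.

``BENCHMARK_CONFUSION`` holds the published confusion counts of the final SVM
predictor on two independent test sets: a held-out split of the benchmark
(63 positives / 189 genome-fragment negatives) and newly released viral
pre-miRNAs (32 positives / 96 genome-fragment negatives).  They serve as
fixed inputs for checking the metric identities.
"""

from __future__ import annotations

from .metrics import ConfusionCounts

#: Published per-feature F-scores (feature name -> score), canonical names.
REPORTED_FSCORES: dict[str, float] = {
    "G(((": 1.09,
    "C(((": 1.08,
    "G((.": 1.04,
    "U(((": 1.03,
    "A(((": 1.01,
    "C(.(": 1.01,
    "U.((": 1.00,
    "U((.": 1.00,
    "A.((": 1.00,
    "C((.": 0.99,
    "G(..": 0.97,
    "G.((": 0.97,
    "A(..": 0.96,
    "A(.(": 0.95,
    "C.(.": 0.94,
    "ConsecBP": 0.94,
    "A((.": 0.91,
    "U..(": 0.87,
    "dP": 0.83,
    "%(G-C)/stems": 0.81,
    "G(.(": 0.80,
    "|A-U|/L": 0.78,
    "Diversity": 0.78,
    "C.((": 0.77,
    "|G-C|/L": 0.76,
    "U(.(": 0.75,
    "MFEI_1": 0.72,
    "Frequency": 0.71,
    "U...": 0.71,
    "A..(": 0.70,
    "%(A-U)/stems": 0.69,
    "dG": 0.66,
    "%(G-U)/stems": 0.66,
    "loop length": 0.66,
    "C(..": 0.66,
    "%G+C": 0.65,
    "MFEI_2": 0.63,
    "MFEI_3": 0.63,
    "Avg_BP_Stem": 0.61,
    "|G-U|/L": 0.60,
    "G.(.": 0.58,
    "C...": 0.58,
    "U.(.": 0.57,
    "zP": 0.56,
    "A.(.": 0.54,
    "MFEI_4": 0.51,
    "U(..": 0.48,
    "zG": 0.47,
    "hairpin length": 0.43,
    "G..(": 0.43,
    "G...": 0.41,
    "C..(": 0.37,
    "sequence length": 0.34,
    "A...": 0.32,
}

#: Published confusion counts of the final SVM predictor on independent data.
BENCHMARK_CONFUSION: dict[str, ConfusionCounts] = {
    # 63 positives / 189 negatives held out from the benchmark
    "heldout_split": ConfusionCounts(tp=50, tn=164, fp=25, fn=13),
    # 32 newly released positives / 96 genome-fragment negatives
    "new_release": ConfusionCounts(tp=25, tn=85, fp=11, fn=7),
}
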